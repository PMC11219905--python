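"""State construction, action spaces, rewards, BOB adjustment, DQN
training mechanics."""

import numpy as np
import pytest

from faidsim.drl import (DQN, DQNBank, Experience, ReplayMemory, TrainConfig,
                         adjust_bolus, build_state, choose_action,
                         compute_reward, default_action_grid,
                         meal_label_for_time, select_sas)
from faidsim.nn import MLP


class TestBuildState:
    def test_constant_in_range(self):
        s = build_state(np.full(48, 120.0))
        assert s.g_max == s.g_min == 120.0
        assert s.auc == 0.0
        assert np.all(s.g_recent == 120.0)
        assert s.as_array().shape == (15,)

    def test_constant_hyperglycemic_auc(self):
        s = build_state(np.full(48, 200.0))
        # 20 mg/dL excess for 240 min
        assert s.auc == pytest.approx(20.0 * 240.0)

    def test_ramp_auc_matches_brute_force(self):
        g = np.linspace(100.0, 190.0, 48)
        s = build_state(g)
        brute = sum(max(v - 180.0, 0.0) + max(70.0 - v, 0.0) for v in g) * 5.0
        assert s.auc == pytest.approx(brute)
        assert s.g_max == 190.0 and s.g_min == 100.0

    def test_hypo_and_hyper_both_count(self):
        g = np.concatenate([np.full(24, 60.0), np.full(24, 190.0)])
        s = build_state(g)
        assert s.auc == pytest.approx((10.0 * 24 + 10.0 * 24) * 5.0)

    def test_wrong_length_fails(self):
        with pytest.raises(ValueError):
            build_state(np.full(30, 120.0))
        # relaxed mode accepts truncated windows
        s = build_state(np.full(30, 120.0), strict=False)
        assert s.g_max == 120.0

    def test_recent_samples_are_last_hour(self):
        g = np.arange(48, dtype=float) + 100.0
        s = build_state(g)
        np.testing.assert_array_equal(s.g_recent, g[-12:])


class TestSelectSas:
    @pytest.mark.parametrize("g_bm,expected", [
        (210.0, 1), (200.0, 1), (199.9, 2), (180.0, 2), (165.0, 3),
        (140.0, 4), (120.0, 5), (100.0, 6), (80.0, 7), (79.0, 8), (40.0, 8),
    ])
    def test_band_edges(self, g_bm, expected):
        assert select_sas(g_bm) == expected

    def test_partition_is_total(self, rng):
        for g in rng.uniform(1.0, 400.0, size=500):
            assert select_sas(g) in range(1, 9)


class TestReward:
    @pytest.mark.parametrize("gmax,gmin,expected", [
        (150.0, 100.0, 50.0),    # normoglycemic window
        (185.0, 90.0, 20.0),
        (210.0, 100.0, 10.0),
        (240.0, 80.0, -5.0),
        (260.0, 75.0, -15.0),
        (320.0, 90.0, -20.0),
        (150.0, 67.0, -30.0),
        (150.0, 62.0, -40.0),
        (150.0, 57.0, -50.0),
        (150.0, 52.0, -60.0),
        (150.0, 47.0, -70.0),
        (150.0, 40.0, -80.0),
        (260.0, 40.0, -80.0),    # hypo precedence over hyper
        (310.0, 66.0, -30.0),    # precedence at the mild end too
        (70.0, 70.0, 50.0),      # boundary of the target band
        (180.0, 80.0, 20.0),
    ])
    def test_piecewise_values(self, gmax, gmin, expected):
        assert compute_reward(gmax, gmin) == expected

    def test_codomain_is_the_12_printed_values(self, rng):
        values = {compute_reward(*sorted(rng.uniform(30.0, 350.0, 2))[::-1])
                  for _ in range(5000)}
        allowed = {50, 20, 10, -5, -15, -20, -30, -40, -50, -60, -70, -80}
        assert values <= allowed

    def test_rejects_inverted_extrema(self):
        with pytest.raises(ValueError):
            compute_reward(100.0, 150.0)


class TestAdjustBolus:
    @pytest.mark.parametrize("a_j,ratio,g_bm,expected", [
        (5.0, 2.0, 200.0, 3.0),    # subtract BOB ratio when hyper
        (4.0, 5.0, 150.0, 3.8),    # −5%
        (4.0, 5.0, 130.0, 3.6),    # −10%
        (4.0, 5.0, 100.0, 3.2),    # −20%
        (4.0, 3.0, 150.0, 4.0),    # otherwise branch
        (4.0, 5.0, 60.0, 4.0),     # below 80: otherwise branch
        (1.0, 5.0, 200.0, 1.0),    # hyper but a_j < ratio: otherwise
    ])
    def test_five_branches(self, a_j, ratio, g_bm, expected):
        assert adjust_bolus(a_j, ratio, 1.0, g_bm) == pytest.approx(expected)

    def test_k_bob_scales_ratio(self):
        # BOB 10 with k_bob 2 behaves as ratio 5
        assert adjust_bolus(4.0, 10.0, 2.0, 130.0) == pytest.approx(3.6)

    def test_huge_bob_hyper_branch(self):
        # a_j just above the ratio: nearly the whole bolus is withheld
        assert adjust_bolus(5.0, 4.9, 1.0, 250.0) == pytest.approx(0.1)

    def test_never_negative(self, rng):
        for _ in range(300):
            u = adjust_bolus(float(rng.uniform(0, 10)),
                             float(rng.uniform(0, 20)),
                             float(rng.uniform(0.5, 3)),
                             float(rng.uniform(40, 300)))
            assert u >= 0.0


class TestChooseAction:
    def test_uniform_when_epsilon_one(self, rng):
        from scipy import stats

        q = np.zeros(15)
        draws = np.array([choose_action(q, 1.0, rng) for _ in range(15000)])
        counts = np.bincount(draws, minlength=15)
        chi2 = ((counts - 1000.0) ** 2 / 1000.0).sum()
        assert chi2 < stats.chi2.ppf(0.999, df=14)

    def test_greedy_unique_max(self, rng):
        q = np.zeros(15)
        q[7] = 1.0
        assert choose_action(q, 0.0, rng) == 7

    def test_tie_breaks_to_smaller_bolus(self, rng):
        q = np.zeros(15)
        q[3] = q[9] = 2.0
        assert choose_action(q, 0.0, rng) == 3


class TestActionGrids:
    def test_monotone_nonnegative(self):
        for meal in ("breakfast", "lunch", "dinner"):
            for sas in range(1, 9):
                g = default_action_grid(meal, sas, tdi=40.0)
                assert g.shape == (15,)
                assert g[0] >= 0.0 and np.all(np.diff(g) >= 0)

    def test_hyper_sas_shifted_up(self):
        low = default_action_grid("lunch", 5, tdi=40.0)
        high = default_action_grid("lunch", 1, tdi=40.0)
        assert np.all(high >= low)

    def test_scales_with_tdi(self):
        assert default_action_grid("dinner", 5, 60.0)[-1] > \
            default_action_grid("dinner", 5, 30.0)[-1]


class TestMealLabel:
    @pytest.mark.parametrize("clock_h,label", [
        (7.5, "breakfast"), (13.0, "lunch"), (17.2, "dinner"),
        (20.0, "dinner"), (23.5, "dinner"), (3.0, "breakfast"),
    ])
    def test_time_bins(self, clock_h, label):
        assert meal_label_for_time(clock_h * 60.0) == label


class TestReplayMemory:
    def _exp(self, i):
        return Experience(s=np.full(15, float(i)), a=i % 15, r=float(i),
                          s_next=np.zeros(15))

    def test_capacity_evicts_oldest(self):
        mem = ReplayMemory(capacity=5)
        for i in range(8):
            mem.push(self._exp(i))
        assert len(mem) == 5
        assert mem._items[0].r == 3.0

    def test_sample_without_replacement(self, rng):
        mem = ReplayMemory()
        for i in range(10):
            mem.push(self._exp(i))
        batch = mem.sample(10, rng)
        assert sorted(e.r for e in batch) == list(map(float, range(10)))
        with pytest.raises(ValueError):
            mem.sample(11, rng)


class TestArchitecture:
    def test_bank_has_24_networks(self):
        bank = DQNBank(tdi=40.0, seed=0)
        assert len(bank.nets) == 24
        assert {m for m, _ in bank.nets} == {"breakfast", "lunch", "dinner"}
        assert {s for _, s in bank.nets} == set(range(1, 9))

    def test_network_shape(self):
        net = MLP((15, 28, 28, 28, 15), seed=0)
        shapes = [w.shape for w in net.W]
        assert shapes == [(15, 28), (28, 28), (28, 28), (28, 15)]
        q = net(np.zeros(15))
        assert q.shape == (15,)

    def test_target_shares_architecture(self):
        dqn = DQN(seed=3)
        assert [w.shape for w in dqn.online.W] == \
            [w.shape for w in dqn.target.W]

    def test_save_load_roundtrip(self, tmp_path):
        bank = DQNBank(tdi=40.0, seed=4)
        s = np.linspace(80, 200, 15)
        q_before = bank.nets[("lunch", 3)].q_values(s)
        bank.save(tmp_path / "bank")
        loaded = DQNBank.load(tmp_path / "bank")
        np.testing.assert_allclose(loaded.nets[("lunch", 3)].q_values(s),
                                   q_before, rtol=1e-12)


class TestTrainingMechanics:
    def test_bellman_fixed_point_no_bootstrap(self, rng):
        """gamma=0: repeated updates drive Q(s,a) to r exactly."""
        dqn = DQN(seed=0)
        exp = Experience(s=np.full(15, 120.0), a=4, r=-15.0,
                         s_next=np.full(15, 140.0))
        for _ in range(800):
            dqn.update([exp] * 8, gamma=0.0, lr=3e-3)
        assert dqn.q_values(exp.s)[4] == pytest.approx(-15.0, abs=0.2)

    def test_loss_decreases_under_small_steps(self, rng):
        dqn = DQN(seed=1)
        batch = [Experience(s=rng.uniform(80, 200, 15), a=int(rng.integers(15)),
                            r=float(rng.choice([50, 20, -30])),
                            s_next=rng.uniform(80, 200, 15))
                 for _ in range(32)]
        first = dqn.update(batch, gamma=0.0, lr=1e-4)
        for _ in range(50):
            last = dqn.update(batch, gamma=0.0, lr=1e-4)
        assert last < first

    def test_target_frozen_between_syncs(self, rng):
        """The regression target for a fixed batch is constant until the
        target network is synchronised."""
        dqn = DQN(seed=2)
        s_next = np.full(15, 150.0)
        before = dqn.target.forward(s_next / 1.0).max()
        batch = [Experience(s=rng.uniform(80, 200, 15),
                            a=int(rng.integers(15)), r=10.0, s_next=s_next)
                 for _ in range(8)]
        for _ in range(14):
            dqn.update(batch, gamma=0.9, lr=1e-3)
        after = dqn.target.forward(s_next / 1.0).max()
        assert after == before
        dqn.sync_target()
        assert dqn.target.forward(s_next / 1.0).max() != before

    def test_bandit_matches_exhaustive_oracle(self, rng):
        """Two-state bandit with known rewards: the greedy policy after
        training equals the brute-force optimal action per state."""
        dqn = DQN(seed=5)
        s_a = np.full(15, 100.0)
        s_b = np.full(15, 220.0)
        rewards = {(0, 2): 50.0, (0, 11): -40.0, (1, 2): -20.0, (1, 11): 20.0}
        batch = []
        for (state_id, action), r in rewards.items():
            s = s_a if state_id == 0 else s_b
            batch.extend([Experience(s=s, a=action, r=r, s_next=s)] * 4)
        for i in range(600):
            dqn.update(batch, gamma=0.0, lr=3e-3)
        qa, qb = dqn.q_values(s_a), dqn.q_values(s_b)
        assert qa[2] > qa[11]
        assert qb[11] > qb[2]


class TestTrainConfig:
    def test_epsilon_anneal_endpoints(self):
        cfg = TrainConfig(epsilon_start=1.0, epsilon_end=0.05)
        assert cfg.epsilon_at(0, 300) == 1.0
        assert cfg.epsilon_at(299, 300) == pytest.approx(0.05)
        assert cfg.epsilon_at(150, 300) == pytest.approx(0.525, abs=0.01)

    def test_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(gamma=1.0)
        with pytest.raises(ValueError):
            TrainConfig(epsilon_start=1.5)
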