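"""Deep-reinforcement-learning bolus calculator.

A bank of 24 deep Q-networks — one per (meal, subaction-space) pair,
with three meals and eight pre-meal-glucose-banded subaction spaces
(SAS) — selects a discrete insulin bolus whenever a meal is announced or
detected.  The 15-dimensional state summarises 4 h of CGM (extrema, the
out-of-range area under the curve, and the last hour of samples); the
selected bolus is adjusted downward according to the bolus insulin on
board (BOB) before delivery.  The reward grades the 4-h postprandial
window, with hypoglycemia penalised ahead of any hyperglycemia credit.

Training follows the classic DQN recipe: an experience-replay memory per
network filled by a random-action simulation, epsilon-greedy acting, and
squared Bellman-error updates against a target network synchronised
every 15 training iterations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from faidsim.nn import MLP

__all__ = [
    "RLState", "ActionSpace", "Experience", "ReplayMemory", "DQN",
    "DQNBank", "TrainConfig", "build_state", "select_sas", "choose_action",
    "adjust_bolus", "compute_reward", "meal_label_for_time",
    "default_action_grid", "generate_memory", "train", "faid_bolus",
    "MEALS", "N_SAS", "N_ACTIONS", "STATE_DIM",
]

MEALS = ("breakfast", "lunch", "dinner")
N_SAS = 8
N_ACTIONS = 15
STATE_DIM = 15
WINDOW_SAMPLES = 48          # 4 h of 5-min CGM samples
RECENT_SAMPLES = 12          # last hour
CGM_PERIOD = 5.0

#: nominal carbohydrate content per meal (g), midpoints of the protocol
#: ranges, used to anchor the per-meal action grids
NOMINAL_CHO = {"breakfast": 40.0, "lunch": 60.0, "dinner": 70.0}

#: fixed input scaling applied before the Q-network (glucose channels
#: are O(100) mg/dL, the AUC channel O(10^3) mg/dL·min)
_STATE_SCALE = np.array([200.0, 200.0] + [200.0] * RECENT_SAMPLES + [5000.0])


# --------------------------------------------------------------------------
# state construction
# --------------------------------------------------------------------------

@dataclass
class RLState:
    """15-number summary of a 4-h CGM window."""

    g_max: float
    g_min: float
    g_recent: np.ndarray      # last 12 samples of the window (mg/dL)
    auc: float                # out-of-range area (mg/dL·min)

    def as_array(self) -> np.ndarray:
        return np.concatenate(([self.g_max, self.g_min],
                               self.g_recent, [self.auc]))


def out_of_range_auc(cgm: np.ndarray, lo: float = 70.0, hi: float = 180.0,
                     dt: float = CGM_PERIOD) -> float:
    """Area outside [lo, hi]: each sample contributes its absolute excess
    over the violated bound times the sampling period."""
    cgm = np.asarray(cgm, dtype=float)
    excess = np.maximum(cgm - hi, 0.0) + np.maximum(lo - cgm, 0.0)
    return float(excess.sum() * dt)


def build_state(cgm_history, anchor: str = "pre-prandial",
                strict: bool = True) -> RLState:
    """Summarise a 4-h CGM window into the RL state.

    ``cgm_history`` holds 48 five-minute samples ordered oldest→newest
    (the 4 h before a detection for the current state, or the 4 h after
    for the next state).  With ``strict=False`` a truncated window of at
    least 13 samples is accepted — used when a postprandial window is
    cut short by the next bolus event.
    """
    if anchor not in ("pre-prandial", "post-prandial"):
        raise ValueError(f"unknown anchor: {anchor!r}")
    g = np.asarray(cgm_history, dtype=float)
    if strict and g.size != WINDOW_SAMPLES:
        raise ValueError(f"expected {WINDOW_SAMPLES} samples, got {g.size}")
    if g.size < RECENT_SAMPLES + 1:
        raise ValueError("window too short to summarise")
    return RLState(g_max=float(g.max()), g_min=float(g.min()),
                   g_recent=g[-RECENT_SAMPLES:].copy(),
                   auc=out_of_range_auc(g))


# --------------------------------------------------------------------------
# action space
# --------------------------------------------------------------------------

#: lower band edges of the 8 subaction spaces, highest glucose first
SAS_EDGES = (200.0, 180.0, 160.0, 140.0, 120.0, 100.0, 80.0)


def select_sas(g_bm: float) -> int:
    """Map the pre-meal CGM value onto a subaction-space index 1..8."""
    if g_bm <= 0:
        raise ValueError("g_bm must be positive")
    for i, edge in enumerate(SAS_EDGES, start=1):
        if g_bm >= edge:
            return i
    return 8


@dataclass
class ActionSpace:
    """Ordered menu of 15 bolus magnitudes for one (meal, SAS) pair."""

    meal: str
    sas_index: int
    actions: np.ndarray

    def __post_init__(self) -> None:
        self.actions = np.asarray(self.actions, dtype=float)
        if self.actions.size != N_ACTIONS:
            raise ValueError(f"exactly {N_ACTIONS} actions required")
        if np.any(self.actions < 0) or np.any(np.diff(self.actions) < 0):
            raise ValueError("actions must be non-negative, non-decreasing")


def default_action_grid(meal: str, sas_index: int, tdi: float) -> np.ndarray:
    """Bolus menu anchored on the patient's insulin requirement.

    The guideline meal bolus is CHO_nominal·TDI/500 (the 500 rule); the
    menu spans 0 to 1.8× that value in 15 steps, shifted upward for the
    hyperglycemic subaction spaces by half a guideline correction dose
    (band midpoint excess over 140 mg/dL divided by the 1800-rule
    correction factor).  The near- and below-hypoglycemic bands offer a
    tapered menu (×0.75 for 80–100 mg/dL, ×0.5 below 80), following the
    standard dosing guidance of reducing meal insulin when pre-meal
    glucose is under target.
    """
    guideline = NOMINAL_CHO[meal] * tdi / 500.0
    taper = {7: 0.75, 8: 0.5}.get(sas_index, 1.0)
    grid = np.linspace(0.0, 1.8 * guideline * taper, N_ACTIONS)
    mids = {1: 210.0, 2: 190.0, 3: 170.0, 4: 150.0,
            5: 130.0, 6: 110.0, 7: 90.0, 8: 70.0}
    cf = 1800.0 / tdi
    shift = 0.5 * max(0.0, mids[sas_index] - 140.0) / cf
    return grid + shift


def meal_label_for_time(clock_min: float) -> str:
    """Assign a detection to a meal bank by time of day.

    Bins: [05:00, 11:00) breakfast, [11:00, 17:00) lunch,
    [17:00, 23:00) dinner; outside those, the nearest meal's bank
    (before 05:00 → breakfast, from 23:00 → dinner).
    """
    c = clock_min % 1440.0
    if 5 * 60 <= c < 11 * 60:
        return "breakfast"
    if 11 * 60 <= c < 17 * 60:
        return "lunch"
    if 17 * 60 <= c < 23 * 60:
        return "dinner"
    return "dinner" if c >= 23 * 60 else "breakfast"


# --------------------------------------------------------------------------
# reward and safety adjustment
# --------------------------------------------------------------------------

def compute_reward(g_maxp: float, g_minp: float) -> float:
    """Immediate reward for a 4-h postprandial window.

    Any postprandial hypoglycemia (g_minp < 70) takes precedence over
    the hyperglycemia branches, graded by severity; otherwise the
    maximum glucose decides, with full credit for staying in 70–180.
    """
    if g_minp > g_maxp:
        raise ValueError("g_minp cannot exceed g_maxp")
    if g_minp < 70.0:
        if g_minp < 45.0:
            return -80.0
        if g_minp < 50.0:
            return -70.0
        if g_minp < 55.0:
            return -60.0
        if g_minp < 60.0:
            return -50.0
        if g_minp < 65.0:
            return -40.0
        return -30.0
    if g_maxp < 180.0:
        return 50.0
    if g_maxp < 200.0:
        return 20.0
    if g_maxp < 230.0:
        return 10.0
    if g_maxp < 250.0:
        return -5.0
    if g_maxp < 300.0:
        return -15.0
    return -20.0


def adjust_bolus(a_j: float, bob_hat: float, k_bob: float,
                 g_bm: float) -> float:
    """Scale the selected bolus by the bolus insulin on board.

    With r = BOB̂/k_BOB: subtract r when the bolus exceeds it and the
    patient is hyperglycemic (≥180); otherwise, if the bolus is below r,
    trim it by 5% / 10% / 20% for pre-meal glucose in [140, 180) /
    [120, 140) / [80, 120); any other combination leaves it unchanged.
    Result is clamped at zero.
    """
    if min(a_j, bob_hat, k_bob, g_bm) < 0 or k_bob == 0:
        raise ValueError("inputs must be non-negative with k_bob > 0")
    ratio = bob_hat / k_bob
    if a_j > ratio and g_bm >= 180.0:
        u_ad = a_j - ratio
    elif a_j < ratio and 140.0 <= g_bm < 180.0:
        u_ad = 0.95 * a_j
    elif a_j < ratio and 120.0 <= g_bm < 140.0:
        u_ad = 0.90 * a_j
    elif a_j < ratio and 80.0 <= g_bm < 120.0:
        u_ad = 0.80 * a_j
    else:
        u_ad = a_j
    return max(u_ad, 0.0)


def choose_action(q_values: np.ndarray, epsilon: float,
                  rng: np.random.Generator) -> int:
    """Epsilon-greedy over 0-based action indices.

    Greedy ties break toward the lowest index, i.e. the smaller bolus.
    """
    if not (0.0 <= epsilon <= 1.0):
        raise ValueError("epsilon must be in [0, 1]")
    q = np.asarray(q_values, dtype=float)
    if rng.random() < epsilon:
        return int(rng.integers(q.size))
    return int(np.argmax(q))  # argmax returns the first (lowest) maximum


# --------------------------------------------------------------------------
# experience replay
# --------------------------------------------------------------------------

@dataclass
class Experience:
    s: np.ndarray
    a: int
    r: float
    s_next: np.ndarray


class ReplayMemory:
    """Bounded experience buffer with uniform mini-batch sampling."""

    def __init__(self, capacity: int = 100_000) -> None:
        self.capacity = capacity
        self._items: list[Experience] = []

    def push(self, exp: Experience) -> None:
        if len(self._items) >= self.capacity:
            self._items.pop(0)
        self._items.append(exp)

    def sample(self, batch_size: int,
               rng: np.random.Generator) -> list[Experience]:
        """Uniform sample without replacement within the mini-batch."""
        n = len(self._items)
        if batch_size > n:
            raise ValueError("not enough experiences to sample")
        idx = rng.choice(n, size=batch_size, replace=False)
        return [self._items[i] for i in idx]

    def __len__(self) -> int:
        return len(self._items)


# --------------------------------------------------------------------------
# DQN and the 24-network bank
# --------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Hyperparameters of memory generation and DQN training."""

    gamma: float = 0.9
    alpha: float = 1e-3
    epsilon_start: float = 1.0
    epsilon_end: float = 0.05
    batch_size: int = 32
    updates_per_event: int = 1        # replay mini-batches per meal event
    target_sync_period: int = 15      # iterations between target syncs
    memory_days: int = 1500
    train_iterations: int = 1500      # one iteration = one simulated day
    memory_capacity: int = 100_000
    k_bob: float = 1.0                # default BOB divisor, per (meal, SAS)
    k_bob_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.gamma < 1.0):
            raise ValueError("gamma must lie in [0, 1)")
        for eps in (self.epsilon_start, self.epsilon_end):
            if not (0.0 <= eps <= 1.0):
                raise ValueError("epsilon must lie in [0, 1]")

    def epsilon_at(self, iteration: int, total: int) -> float:
        """Linear anneal from start to end over ``total`` iterations."""
        if total <= 1:
            return self.epsilon_end
        frac = min(1.0, iteration / (total - 1))
        return self.epsilon_start + frac * (self.epsilon_end - self.epsilon_start)

    def k_bob_for(self, meal: str, sas: int) -> float:
        return self.k_bob_overrides.get((meal, sas), self.k_bob)


class DQN:
    """Online + target network pair for one (meal, SAS) agent.

    The output layer starts at zero: an agent that has never been
    updated returns identical Q-values, and the greedy tie-break then
    selects the smallest bolus — untrained agents are safe by default.
    """

    def __init__(self, seed: int = 0) -> None:
        self.online = MLP((STATE_DIM, 28, 28, 28, N_ACTIONS), seed=seed,
                          zero_final=True)
        self.target = self.online.clone()
        self.updates = 0

    def q_values(self, state_vec: np.ndarray) -> np.ndarray:
        return self.online(np.asarray(state_vec, dtype=float) / _STATE_SCALE)

    def sync_target(self) -> None:
        self.target.set_weights(self.online.get_weights())

    def update(self, batch: list[Experience], gamma: float,
               lr: float) -> float:
        """One squared-Bellman-error step on a mini-batch."""
        s = np.stack([e.s for e in batch]) / _STATE_SCALE
        s_next = np.stack([e.s_next for e in batch]) / _STATE_SCALE
        a = np.array([e.a for e in batch], dtype=int)
        r = np.array([e.r for e in batch], dtype=float)
        q_next = self.target.forward(s_next)
        targets = r + gamma * q_next.max(axis=1)
        loss = self.online.train_step(s, a, targets, lr=lr)
        self.updates += 1
        return loss


class DQNBank:
    """24 agents (3 meals × 8 SAS) with their replay memories and menus."""

    def __init__(self, tdi: float, seed: int = 0,
                 memory_capacity: int = 100_000,
                 action_grids: dict | None = None) -> None:
        self.tdi = tdi
        self.seed = seed
        self.nets: dict[tuple[str, int], DQN] = {}
        self.memories: dict[tuple[str, int], ReplayMemory] = {}
        self.spaces: dict[tuple[str, int], ActionSpace] = {}
        for mi, meal in enumerate(MEALS):
            for sas in range(1, N_SAS + 1):
                key = (meal, sas)
                grid = (action_grids or {}).get(
                    key, default_action_grid(meal, sas, tdi))
                self.spaces[key] = ActionSpace(meal, sas, grid)
                self.nets[key] = DQN(seed=seed * 101 + mi * N_SAS + sas)
                self.memories[key] = ReplayMemory(memory_capacity)

    def keys(self):
        return self.nets.keys()

    def actions_for(self, meal: str, sas: int) -> np.ndarray:
        return self.spaces[(meal, sas)].actions

    def sync_all_targets(self) -> None:
        for net in self.nets.values():
            net.sync_target()

    # --- serialization ----------------------------------------------------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {"tdi": self.tdi, "seed": self.seed,
                    "architecture": [STATE_DIM, 28, 28, 28, N_ACTIONS],
                    "files": {}}
        for (meal, sas), net in self.nets.items():
            name = f"dqn_{meal}_sas{sas}.npz"
            weights = net.online.get_weights()
            np.savez(directory / name,
                     *weights, actions=self.spaces[(meal, sas)].actions)
            manifest["files"][f"{meal}:{sas}"] = name
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "DQNBank":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        bank = cls(tdi=manifest["tdi"], seed=manifest["seed"])
        for key_str, name in manifest["files"].items():
            meal, sas = key_str.split(":")
            key = (meal, int(sas))
            with np.load(directory / name) as data:
                weights = [data[f"arr_{i}"] for i in range(8)]
                bank.nets[key].online.set_weights(weights)
                bank.nets[key].sync_target()
                bank.spaces[key] = ActionSpace(meal, int(sas),
                                               data["actions"])
        return bank


# --------------------------------------------------------------------------
# bolus policies over the bank
# --------------------------------------------------------------------------

def faid_bolus(cgm_history, g_bm: float, clock_min: float, bank: DQNBank,
               bob_hat: float, cfg: TrainConfig,
               epsilon: float = 0.0,
               rng: np.random.Generator | None = None) -> tuple[float, dict]:
    """Full bolus decision for one detected (or announced) meal.

    Composes state construction → SAS selection → (epsilon-)greedy
    action choice → BOB adjustment.  Returns the bolus in U and a
    bookkeeping dict (meal, sas, action index, raw action, state).
    """
    rng = rng or np.random.default_rng()
    state = build_state(cgm_history, "pre-prandial",
                        strict=len(cgm_history) == WINDOW_SAMPLES)
    meal = meal_label_for_time(clock_min)
    sas = select_sas(g_bm)
    key = (meal, sas)
    q = bank.nets[key].q_values(state.as_array())
    a_idx = choose_action(q, epsilon, rng)
    a_j = float(bank.actions_for(meal, sas)[a_idx])
    u_ad = adjust_bolus(a_j, bob_hat, cfg.k_bob_for(meal, sas), g_bm)
    info = {"meal": meal, "sas": sas, "action_idx": a_idx, "a_j": a_j,
            "state": state.as_array(), "bolus": u_ad}
    return u_ad, info


# --------------------------------------------------------------------------
# memory generation and training (closed-loop)
# --------------------------------------------------------------------------

def _finalize_events(loop, bank: DQNBank, start_ptr: int,
                     on_experience=None) -> int:
    """Convert completed bolus events of a running loop into experiences.

    An event is complete once its 4-h postprandial window has elapsed or
    the next bolus event truncates it.  Returns the new pointer into the
    loop's event list.
    """
    events = loop.events
    n_samples = len(loop.trace_cgm)
    ptr = start_ptr
    while ptr < len(events):
        ev = events[ptr]
        nxt = events[ptr + 1] if ptr + 1 < len(events) else None
        end = ev.idx + 1 + WINDOW_SAMPLES
        if nxt is not None:
            end = min(end, nxt.idx + 1)
        if end > n_samples and (nxt is None or nxt.idx + 1 > n_samples):
            break  # window still open
        window = np.asarray(loop.trace_cgm[ev.idx + 1:end])
        ptr += 1
        if ev.state_pre is None or ev.action_idx is None:
            continue  # non-RL bolus (e.g. SBC arm)
        if window.size < RECENT_SAMPLES + 1:
            continue  # too truncated to grade
        r = compute_reward(float(window.max()), float(window.min()))
        s_next = build_state(window, "post-prandial", strict=False)
        exp = Experience(s=ev.state_pre, a=ev.action_idx, r=r,
                         s_next=s_next.as_array())
        key = (ev.meal, ev.sas)
        bank.memories[key].push(exp)
        if on_experience is not None:
            on_experience(key, exp)
    return ptr


def generate_memory(params, bank: DQNBank, cfg: TrainConfig,
                    days: int | None = None, seed: int = 0,
                    mode: str = "announced", variability=None) -> dict:
    """Fill the replay memories by acting uniformly at random.

    Simulates ``days`` of closed-loop control under the training meal
    protocol; at every bolus event an action is drawn uniformly from the
    SAS selected by the pre-meal CGM, and the graded experience is
    routed to that (meal, SAS) agent's memory.  Returns per-agent memory
    sizes.  Agents whose memory stays below the batch size are reported
    so that training can defer them until data accrues.
    """
    from faidsim.loop import ClosedLoop, RLPolicy

    days = days or cfg.memory_days
    policy = RLPolicy(bank, cfg, epsilon=1.0,
                      rng=np.random.default_rng(seed + 7))
    loop = ClosedLoop.for_training(params, days=days, seed=seed,
                                   mode=mode, policy=policy,
                                   variability=variability)
    loop.run(days)
    _finalize_events(loop, bank, 0)
    sizes = {key: len(mem) for key, mem in bank.memories.items()}
    starved = [k for k, n in sizes.items() if 0 < n < cfg.batch_size]
    return {"sizes": sizes, "starved": starved}


def train(params, bank: DQNBank, cfg: TrainConfig,
          iterations: int | None = None, seed: int = 0,
          mode: str = "announced", variability=None) -> "pd.DataFrame":
    """Train the bank by epsilon-greedy closed-loop interaction.

    One iteration is one simulated day under the training protocol.  At
    each meal event the acting agent takes an epsilon-greedy action; the
    new experience joins its memory and one mini-batch Bellman update is
    applied to that agent.  All target networks are synchronised every
    ``cfg.target_sync_period`` iterations.  Returns the training log
    (per-day reward, loss, epsilon, hypoglycemia event count).

    Raises ``RuntimeError`` on divergence (non-finite loss or weights).
    """
    import pandas as pd

    from faidsim.loop import ClosedLoop, RLPolicy
    from faidsim.metrics import count_hypo_events

    iterations = iterations or cfg.train_iterations
    rng = np.random.default_rng(seed + 13)
    policy = RLPolicy(bank, cfg, epsilon=cfg.epsilon_start, rng=rng)
    loop = ClosedLoop.for_training(params, days=iterations, seed=seed + 1,
                                   mode=mode, policy=policy,
                                   variability=variability)
    log = []
    ptr = 0
    pending: list[tuple[tuple[str, int], Experience]] = []

    def collect(key, exp):
        pending.append((key, exp))

    for it in range(iterations):
        policy.epsilon = cfg.epsilon_at(it, iterations)
        day_start = len(loop.trace_cgm)
        loop.run(1)
        ptr = _finalize_events(loop, bank, ptr, on_experience=collect)
        losses, rewards = [], []
        while pending:
            key, exp = pending.pop(0)
            rewards.append(exp.r)
            mem = bank.memories[key]
            if len(mem) >= cfg.batch_size:
                for _ in range(cfg.updates_per_event):
                    batch = mem.sample(cfg.batch_size, rng)
                    loss = bank.nets[key].update(batch, cfg.gamma, cfg.alpha)
                    if not np.isfinite(loss):
                        raise RuntimeError(
                            f"training diverged at iteration {it} on {key}")
                    losses.append(loss)
        if (it + 1) % cfg.target_sync_period == 0:
            bank.sync_all_targets()
        day_cgm = np.asarray(loop.trace_cgm[day_start:])
        log.append({
            "iteration": it,
            "epsilon": policy.epsilon,
            "mean_reward": float(np.mean(rewards)) if rewards else np.nan,
            "mean_loss": float(np.mean(losses)) if losses else np.nan,
            "n_updates": len(losses),
            "hypo_events": count_hypo_events(day_cgm),
        })
    return pd.DataFrame(log)
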