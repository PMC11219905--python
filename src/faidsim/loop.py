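"""Closed-loop simulation engine.

Runs a virtual patient against the PD+SAFE+IFB controller on the 5-min
CGM grid, with meal boluses decided by a pluggable policy — a standard
bolus calculator, a DQN bank, a random explorer, or nothing.  Bolus
events are triggered either by meal announcements (hybrid mode) or by
the UKF meal detector (fully automatic mode); in the latter case the
true meal times are visible only to the trace, never to the policy or
controller.

Order of operations per tick: sense CGM → ingest due meals → detector →
bolus decision → PD + SAFE + IFB → deliver → advance patient.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
import pandas as pd

from faidsim.controller import ControllerConfig, PDController
from faidsim.detector import MealDetector, DetectorTuning
from faidsim.patient import (CGM_PERIOD, MealEvent, PatientParams,
                             VariabilityConfig, VirtualPatient,
                             generate_scenario)

__all__ = ["ClosedLoop", "BolusEvent", "BolusContext", "RLPolicy",
           "SBCPolicy", "NoBolusPolicy"]

DAY_TICKS = 288
MIN_HISTORY = 13   # samples of CGM history a policy needs before acting


@dataclass
class BolusEvent:
    """One bolus decision, kept for training and detector scoring."""

    idx: int                  # sample index into the trace
    time_min: float
    meal: str | None = None   # meal bank that acted (RL policies)
    sas: int | None = None
    action_idx: int | None = None
    a_j: float | None = None
    bolus: float = 0.0
    g_bm: float = 0.0
    state_pre: np.ndarray | None = None


@dataclass
class BolusContext:
    """Everything a bolus policy may look at."""

    cgm_history: np.ndarray   # up to 48 most recent samples, oldest first
    g_bm: float               # CGM sample immediately before the meal/flag
    clock_min: float          # absolute simulation time (min)
    bob_hat: float            # bolus-only insulin on board (U)
    iob_hat: float            # controller's total IOB estimate (U)
    announced_cho: float | None = None   # g, hybrid arms only


class NoBolusPolicy:
    """Never issues a bolus (PD-only control)."""

    def __call__(self, ctx: BolusContext) -> tuple[float, dict]:
        return 0.0, {}


class SBCPolicy:
    """Standard bolus calculator with optional CHO misestimation."""

    def __init__(self, therapy, cho_mu: float = 0.0, cho_sigma: float = 0.2,
                 rng: np.random.Generator | None = None) -> None:
        self.therapy = therapy
        self.cho_mu = cho_mu
        self.cho_sigma = cho_sigma
        self.rng = rng or np.random.default_rng()

    def __call__(self, ctx: BolusContext) -> tuple[float, dict]:
        from faidsim.sbc import misestimate_cho, standard_bolus

        if ctx.announced_cho is None:
            return 0.0, {}
        cho = misestimate_cho(ctx.announced_cho, self.rng,
                              mu=self.cho_mu, sigma=self.cho_sigma)
        u = standard_bolus(cho, ctx.g_bm, self.therapy, ctx.iob_hat)
        return u, {"cho_used": cho}


class RLPolicy:
    """DQN-bank policy; epsilon=1 explores uniformly, epsilon=0 is greedy."""

    def __init__(self, bank, cfg, epsilon: float = 0.0,
                 rng: np.random.Generator | None = None) -> None:
        self.bank = bank
        self.cfg = cfg
        self.epsilon = epsilon
        self.rng = rng or np.random.default_rng()

    def __call__(self, ctx: BolusContext) -> tuple[float, dict]:
        from faidsim.drl import faid_bolus

        return faid_bolus(ctx.cgm_history, ctx.g_bm, ctx.clock_min,
                          self.bank, ctx.bob_hat, self.cfg,
                          epsilon=self.epsilon, rng=self.rng)


class ClosedLoop:
    """One patient, one controller, one policy, many days."""

    def __init__(self, params: PatientParams,
                 scenario: list[list[MealEvent]],
                 mode: str = "announced",
                 policy=None,
                 variability: VariabilityConfig | None = None,
                 ctrl_cfg: ControllerConfig | None = None,
                 detector: MealDetector | None = None,
                 detector_tuning: DetectorTuning | None = None,
                 seed: int = 0,
                 safe_enabled: bool = True) -> None:
        if mode not in ("announced", "faid", "none"):
            raise ValueError(f"unknown mode: {mode!r}")
        self.params = params
        self.mode = mode
        self.policy = policy if policy is not None else NoBolusPolicy()
        var = variability if variability is not None else VariabilityConfig(seed=seed)
        self.patient = VirtualPatient(params, var,
                                      rng=np.random.default_rng(seed + 1000))
        cfg = ctrl_cfg or ControllerConfig.for_patient(params)
        self.controller = PDController(cfg, params, safe_enabled=safe_enabled)
        if mode == "faid":
            self.detector = detector or MealDetector(
                model_params=params, tuning=detector_tuning)
        else:
            self.detector = None
        # bolus-only IOB estimator (two-compartment, same kdia as the
        # controller's IOB model, fed exclusively by boluses)
        self._cb1 = 0.0
        self._cb2 = 0.0
        self._kdia = cfg.kdia
        # absolute-time meal queue
        self._meals: list[tuple[float, MealEvent]] = []
        for day, meals in enumerate(scenario):
            for ev in meals:
                self._meals.append((day * 1440.0 + ev.time_of_day, ev))
        self._meals.sort(key=lambda pair: pair[0])
        self._meal_ptr = 0
        self._last_u = params.ubl
        self._cgm_hist: deque[float] = deque(maxlen=48)
        self.events: list[BolusEvent] = []
        self.detection_events: list[tuple[float, float]] = []  # (t, cc)
        self.trace_time: list[float] = []
        self.trace_cgm: list[float] = []
        self.trace_basal: list[float] = []
        self.trace_bolus: list[float] = []
        self.trace_meal: list[float] = []
        self.trace_flag: list[int] = []

    @classmethod
    def for_training(cls, params: PatientParams, days: int, seed: int,
                     mode: str = "announced", policy=None,
                     variability: VariabilityConfig | None = None,
                     **kwargs) -> "ClosedLoop":
        """Loop under the 3-meal training protocol."""
        scenario = generate_scenario("training", days, seed + 17)
        return cls(params, scenario, mode=mode, policy=policy,
                   variability=variability, seed=seed, **kwargs)

    @property
    def bob_hat(self) -> float:
        return self._cb1 + self._cb2

    def _update_bob(self, bolus: float, dt: float) -> None:
        if bolus > 0:
            self._cb1 += bolus
        a = float(np.exp(-self._kdia * dt))
        self._cb2 = self._cb2 * a + self._kdia * dt * a * self._cb1
        self._cb1 = self._cb1 * a

    def _decide_bolus(self, cgm: float, t: float,
                      announced: MealEvent | None) -> float:
        if len(self._cgm_hist) < MIN_HISTORY:
            return 0.0
        ctx = BolusContext(
            cgm_history=np.asarray(self._cgm_hist),
            g_bm=cgm, clock_min=t, bob_hat=self.bob_hat,
            iob_hat=self.controller.st.iob,
            announced_cho=announced.cho if announced is not None else None)
        bolus, info = self.policy(ctx)
        self.events.append(BolusEvent(
            idx=len(self.trace_cgm), time_min=t,
            meal=info.get("meal"), sas=info.get("sas"),
            action_idx=info.get("action_idx"), a_j=info.get("a_j"),
            bolus=bolus, g_bm=cgm, state_pre=info.get("state")))
        return bolus

    def tick(self) -> None:
        t = self.patient.t
        cgm = self.patient.cgm()
        self._cgm_hist.append(cgm)
        # ingest meals due at or before this tick
        meal_g = 0.0
        announced: MealEvent | None = None
        while (self._meal_ptr < len(self._meals)
               and self._meals[self._meal_ptr][0] <= t):
            _, ev = self._meals[self._meal_ptr]
            self.patient.ingest_meal(ev.cho, ev.absorption_rate_multiplier)
            meal_g += ev.cho
            if self.mode == "announced":
                announced = ev
            self._meal_ptr += 1
        # detection (fully automatic mode only)
        flag = False
        if self.detector is not None:
            flag, _ = self.detector.step(cgm, self._last_u, t)
            if flag:
                cc = self.detector.state.cc_buffer[-1] \
                    if self.detector.state.cc_buffer else float("nan")
                self.detection_events.append((t, float(cc)))
        # bolus decision
        bolus = 0.0
        if self.mode == "announced" and announced is not None:
            bolus = self._decide_bolus(cgm, t, announced)
        elif self.mode == "faid" and flag:
            bolus = self._decide_bolus(cgm, t, None)
        # control + delivery
        u = self.controller.tick(cgm, bolus, dt=CGM_PERIOD)
        self._update_bob(bolus, CGM_PERIOD)
        self.trace_time.append(t)
        self.trace_cgm.append(cgm)
        self.trace_basal.append(u - bolus * 60.0 / CGM_PERIOD)
        self.trace_bolus.append(bolus)
        self.trace_meal.append(meal_g)
        self.trace_flag.append(int(flag))
        self.patient.step(u, dt=CGM_PERIOD)
        self._last_u = u

    def run(self, days: float) -> None:
        for _ in range(int(round(days * DAY_TICKS))):
            self.tick()

    @property
    def trace(self) -> pd.DataFrame:
        """EpisodeTrace: one row per 5-min sample."""
        return pd.DataFrame({
            "time_min": self.trace_time,
            "cgm": self.trace_cgm,
            "basal_U_per_h": self.trace_basal,
            "bolus_U": self.trace_bolus,
            "meal_g": self.trace_meal,
            "meal_detected": self.trace_flag,
        })

    @property
    def detections(self) -> pd.DataFrame:
        """Detection events as (time_min, cross_cov_value) rows."""
        return pd.DataFrame(self.detection_events,
                            columns=["time_min", "cross_cov_value"])
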