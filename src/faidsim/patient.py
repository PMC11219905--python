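"""Synthetic virtual patient for type 1 diabetes closed-loop simulation.

The plant is an extended Bergman minimal model: a glucose compartment
driven by a meal-appearance flux, remote insulin action, a first-order
subcutaneous glucose sensor, and a two-compartment subcutaneous insulin
absorption chain feeding plasma insulin.  Meals are absorbed through a
two-compartment chain with a configurable time-to-peak, so the meal flux
``D(t)`` enters the glucose equation exactly like the disturbance state
the meal detector estimates.

Intra-patient variability covers circadian (sinusoidal) insulin
sensitivity, per-meal absorption-rate randomness, and additive Gaussian
CGM noise.  A small cohort is produced by log-normal jitter around the
default parameter set.

Units: glucose mg/dL, insulin concentration mU/L, subcutaneous insulin
depots U, meal mass mg, rates per minute, pump commands U/h.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "PatientParams",
    "PatientState",
    "MealEvent",
    "VariabilityConfig",
    "VirtualPatient",
    "minimal_model_rhs",
    "step_patient",
    "sample_cgm",
    "generate_scenario",
    "generate_cohort",
    "basal_plasma_insulin",
]

#: minutes in a day
DAY_MIN = 1440.0
#: CGM sampling period (min)
CGM_PERIOD = 5.0
#: floor applied to CGM samples and plasma glucose (mg/dL)
GLUCOSE_FLOOR = 0.0


@dataclass
class PatientParams:
    """Physiological parameters of the extended minimal model.

    Defaults describe a nominal adult with type 1 diabetes; a cohort is
    derived from them by :func:`generate_cohort`.
    """

    p1: float = 0.015         # insulin-independent glucose utilisation (1/min)
    p2: float = 0.028         # remote-insulin disappearance rate (1/min)
    p3: float = 4.0e-5        # insulin sensitivity (1/min per mU/L)
    Gbl: float = 130.0        # basal glucose (mg/dL)
    Vg: float = 110.0         # glucose distribution volume (dL)
    Vi: float = 12.0          # insulin distribution volume (L)
    kf: float = 0.138         # fractional plasma-insulin disappearance (1/min)
    tmaxI: float = 55.0       # time to maximum insulin absorption (min)
    kdia: float = 0.02        # insulin-action (IOB) time constant (1/min)
    tau_s: float = 10.0       # subcutaneous sensor time constant (min)
    g_s: float = 1.0          # sensor static gain
    TDI: float = 40.0         # total daily insulin (U)
    ubl: float = 0.9          # basal insulin rate (U/h)
    body_weight: float = 70.0  # kg
    tmax_meal: float = 40.0   # time-to-peak of meal absorption (min)
    bioavailability: float = 0.8  # fraction of CHO reaching plasma

    def __post_init__(self) -> None:
        for name in ("p1", "p2", "p3", "Vg", "Vi", "kf", "tmaxI", "kdia",
                     "tau_s", "tmax_meal"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not (70.0 <= self.Gbl <= 180.0):
            raise ValueError("Gbl must lie in [70, 180] mg/dL")
        if self.TDI <= 0:
            raise ValueError("TDI must be positive")


@dataclass
class PatientState:
    """Instantaneous state of the virtual patient."""

    Gpl: float                # plasma glucose (mg/dL)
    Gs: float                 # subcutaneous glucose (mg/dL)
    X: float = 0.0            # remote insulin action (1/min)
    I: float = 0.0            # plasma insulin (mU/L)
    S1: float = 0.0           # subcutaneous insulin depot 1 (U)
    S2: float = 0.0           # subcutaneous insulin depot 2 (U)
    M1: float = 0.0           # meal compartment 1 (mg)
    M2: float = 0.0           # meal compartment 2 (mg)

    def as_array(self) -> np.ndarray:
        return np.array([self.Gpl, self.Gs, self.X, self.I,
                         self.S1, self.S2, self.M1, self.M2])

    @classmethod
    def from_array(cls, x: np.ndarray) -> "PatientState":
        return cls(*(float(v) for v in x))


@dataclass
class MealEvent:
    """A single meal in a daily scenario."""

    time_of_day: float        # minutes since midnight
    cho: float                # carbohydrate mass (g)
    absorption_rate_multiplier: float = 1.0
    announced: bool = True
    label: str = "meal"       # breakfast / lunch / snack / dinner

    def __post_init__(self) -> None:
        if self.cho <= 0:
            raise ValueError("cho must be positive")
        if self.absorption_rate_multiplier <= 0:
            raise ValueError("absorption_rate_multiplier must be positive")


@dataclass
class VariabilityConfig:
    """Intra-patient variability and sensor-noise settings."""

    si_amplitude: float = 0.3     # fractional circadian amplitude of p3
    si_phase: float = 720.0       # phase shift (min); default puts the
                                  # sensitivity minimum near 06:00
    absorption_cv: float = 0.2    # CV of the meal absorption-rate multiplier
    cgm_noise_sd: float = 2.0     # mg/dL
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.si_amplitude < 1.0):
            raise ValueError("si_amplitude must lie in [0, 1)")
        if self.cgm_noise_sd < 0 or self.absorption_cv < 0:
            raise ValueError("noise levels must be non-negative")


def basal_plasma_insulin(params: PatientParams) -> float:
    """Steady-state plasma insulin (mU/L) under the basal rate ``ubl``."""
    return 1000.0 * (params.ubl / 60.0) / (params.kf * params.Vi)


def circadian_p3(params: PatientParams, var: VariabilityConfig | None,
                 t_min: float) -> float:
    """Effective insulin sensitivity at clock time ``t_min``."""
    if var is None or var.si_amplitude == 0.0:
        return params.p3
    phase = 2.0 * math.pi * (t_min - var.si_phase) / DAY_MIN
    return params.p3 * (1.0 + var.si_amplitude * math.sin(phase))


def minimal_model_rhs(x: np.ndarray, params: PatientParams,
                      insulin_rate: float, meal_rate_mg: float = 0.0,
                      p3_eff: float | None = None) -> np.ndarray:
    """Time derivative of the 8-state plant.

    ``x`` may be a single state vector of length 8 or an (8, k) array of
    column states (used to push UKF sigma points through the same
    dynamics).  ``insulin_rate`` is in U/h, ``meal_rate_mg`` in mg/min of
    carbohydrate already scaled by bioavailability.
    """
    Gpl, Gs, X, I, S1, S2, M1, M2 = x
    p3 = params.p3 if p3_eff is None else p3_eff
    Ib = basal_plasma_insulin(params)
    u_min = insulin_rate / 60.0                      # U/min
    kabs = 1.0 / params.tmax_meal
    D = kabs * M2                                    # mg/min appearance

    dGpl = -(params.p1 + X) * Gpl + params.p1 * params.Gbl + D / params.Vg
    dGs = (params.g_s * Gpl - Gs) / params.tau_s
    dX = -params.p2 * X + p3 * (I - Ib)
    dI = -params.kf * I + 1000.0 * S2 / (params.tmaxI * params.Vi)
    dS1 = u_min - S1 / params.tmaxI
    dS2 = (S1 - S2) / params.tmaxI
    dM1 = meal_rate_mg - kabs * M1
    dM2 = kabs * (M1 - M2)
    return np.array([dGpl, dGs, dX, dI, dS1, dS2, dM1, dM2])


def _rk4(x: np.ndarray, h: float, params: PatientParams, insulin_rate: float,
         meal_rate_mg: float, p3_eff: float | None) -> np.ndarray:
    k1 = minimal_model_rhs(x, params, insulin_rate, meal_rate_mg, p3_eff)
    k2 = minimal_model_rhs(x + 0.5 * h * k1, params, insulin_rate, meal_rate_mg, p3_eff)
    k3 = minimal_model_rhs(x + 0.5 * h * k2, params, insulin_rate, meal_rate_mg, p3_eff)
    k4 = minimal_model_rhs(x + h * k3, params, insulin_rate, meal_rate_mg, p3_eff)
    return x + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


def step_patient(state: PatientState, params: PatientParams,
                 insulin_rate: float, meal_rate: float = 0.0,
                 dt: float = CGM_PERIOD, p3_eff: float | None = None,
                 substep: float = 1.0) -> PatientState:
    """Advance the patient ODEs by ``dt`` minutes with fixed-step RK4.

    ``meal_rate`` is carbohydrate ingestion in g/min; bioavailability is
    applied on entry to the absorption chain.  Raises on non-finite
    states; plasma glucose is clamped at a floor with a warning.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if insulin_rate < 0 or meal_rate < 0:
        raise ValueError("inputs must be non-negative")
    meal_mg = params.bioavailability * 1000.0 * meal_rate
    x = state.as_array()
    n = max(1, int(round(dt / substep)))
    h = dt / n
    for _ in range(n):
        x = _rk4(x, h, params, insulin_rate, meal_mg, p3_eff)
    if not np.all(np.isfinite(x)):
        raise FloatingPointError(f"patient state became non-finite: {x}")
    if x[0] < GLUCOSE_FLOOR:
        warnings.warn("plasma glucose clamped at floor", RuntimeWarning)
        x[0] = GLUCOSE_FLOOR
    x[1] = max(x[1], GLUCOSE_FLOOR)
    return PatientState.from_array(x)


def sample_cgm(state: PatientState, noise: VariabilityConfig,
               rng: np.random.Generator) -> float:
    """CGM reading: subcutaneous glucose plus additive Gaussian noise."""
    value = state.Gs
    if noise.cgm_noise_sd > 0:
        value += rng.normal(0.0, noise.cgm_noise_sd)
    return max(value, GLUCOSE_FLOOR)


# --- meal scenarios ---------------------------------------------------------

# (label, nominal clock time min, CHO lo g, CHO hi g)
TRAINING_PROTOCOL = (
    ("breakfast", 8 * 60.0, 30.0, 50.0),
    ("lunch", 14 * 60.0, 50.0, 70.0),
    ("dinner", 20 * 60.0, 60.0, 80.0),
)
TESTING_PROTOCOL = (
    ("breakfast", 7 * 60.0, 30.0, 50.0),
    ("lunch", 13 * 60.0, 50.0, 70.0),
    ("snack", 17 * 60.0, 30.0, 50.0),
    ("dinner", 20 * 60.0, 60.0, 80.0),
)
MEAL_TIME_JITTER = 30.0  # ± min, testing protocol only


def generate_scenario(kind: str, days: int, seed: int,
                      absorption_cv: float = 0.2) -> list[list[MealEvent]]:
    """Generate a reproducible meal schedule, one list of meals per day.

    ``training``: three meals at fixed clock times (08:00 / 14:00 /
    20:00) with carbohydrate drawn uniformly from the protocol ranges.
    ``testing``: four meals (adds a 17:00 snack) with ±30 min uniform
    meal-time jitter.  Per-meal absorption-rate multipliers are drawn
    log-normally with coefficient of variation ``absorption_cv``.
    """
    if days < 1:
        raise ValueError("days must be >= 1")
    if kind == "training":
        protocol, jitter = TRAINING_PROTOCOL, 0.0
    elif kind == "testing":
        protocol, jitter = TESTING_PROTOCOL, MEAL_TIME_JITTER
    else:
        raise ValueError(f"unknown scenario kind: {kind!r}")
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log(1.0 + absorption_cv**2)) if absorption_cv > 0 else 0.0
    schedule: list[list[MealEvent]] = []
    for _ in range(days):
        day: list[MealEvent] = []
        for label, t_nom, lo, hi in protocol:
            t = t_nom + (rng.uniform(-jitter, jitter) if jitter else 0.0)
            cho = rng.uniform(lo, hi)
            mult = float(np.exp(rng.normal(-0.5 * sigma**2, sigma))) if sigma else 1.0
            day.append(MealEvent(time_of_day=t, cho=cho,
                                 absorption_rate_multiplier=mult, label=label))
        schedule.append(day)
    return schedule


def generate_cohort(n: int, seed: int = 1234,
                    base: PatientParams | None = None,
                    cv: float = 0.15) -> list[PatientParams]:
    """Log-normal jitter (CV ``cv``) around the default parameter set.

    Basal rate is re-derived from the jittered TDI so each patient's
    basal/bolus split stays physiological.
    """
    base = base or PatientParams()
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log(1.0 + cv**2))
    jittered_fields = ("p1", "p2", "p3", "Vg", "Vi", "kf", "tmaxI",
                       "tau_s", "TDI", "tmax_meal")
    cohort = []
    for _ in range(n):
        kwargs = {}
        for name in jittered_fields:
            factor = float(np.exp(rng.normal(-0.5 * sigma**2, sigma)))
            kwargs[name] = getattr(base, name) * factor
        kwargs["ubl"] = 0.5 * kwargs["TDI"] / 24.0
        kwargs["Gbl"] = float(np.clip(rng.normal(base.Gbl, 8.0), 110.0, 150.0))
        cohort.append(replace(base, **kwargs))
    return cohort


class VirtualPatient:
    """Stateful wrapper running one patient forward in time.

    Tracks absolute simulation time (minutes since midnight of day 0),
    applies circadian insulin-sensitivity modulation, ingests meals as
    impulses into the absorption chain, and produces noisy CGM samples.
    """

    def __init__(self, params: PatientParams | None = None,
                 variability: VariabilityConfig | None = None,
                 rng: np.random.Generator | None = None) -> None:
        self.params = params or PatientParams()
        self.variability = variability or VariabilityConfig()
        self.rng = rng or np.random.default_rng(self.variability.seed)
        self.t = 0.0
        self.state = self.basal_state()
        self._meal_multiplier = 1.0

    def basal_state(self) -> PatientState:
        """Closed-form equilibrium under the basal infusion rate."""
        p = self.params
        u_min = p.ubl / 60.0
        S = u_min * p.tmaxI
        return PatientState(Gpl=p.Gbl, Gs=p.g_s * p.Gbl, X=0.0,
                            I=basal_plasma_insulin(p), S1=S, S2=S)

    def reset(self, t0: float = 0.0) -> None:
        self.t = t0
        self.state = self.basal_state()
        self._meal_multiplier = 1.0

    def ingest_meal(self, cho_g: float, multiplier: float = 1.0) -> None:
        """Add a meal impulse (g of CHO) to the absorption chain."""
        p = self.params
        mg = p.bioavailability * 1000.0 * cho_g
        self.state = replace(self.state, M1=self.state.M1 + mg)
        self._meal_multiplier = multiplier

    def step(self, insulin_rate: float, bolus: float = 0.0,
             dt: float = CGM_PERIOD) -> PatientState:
        """Advance ``dt`` minutes under a pump command.

        ``insulin_rate`` is the continuous infusion in U/h; ``bolus`` is
        an impulse in U delivered at the start of the step (added to the
        first subcutaneous depot, matching pump square-wave delivery at
        the 1-min integration scale).
        """
        if bolus > 0:
            self.state = replace(self.state, S1=self.state.S1 + bolus)
        p3_eff = circadian_p3(self.params, self.variability, self.t)
        params = self.params
        if self._meal_multiplier != 1.0:
            params = replace(params,
                             tmax_meal=params.tmax_meal / self._meal_multiplier)
        self.state = step_patient(self.state, params, insulin_rate,
                                  meal_rate=0.0, dt=dt, p3_eff=p3_eff)
        self.t += dt
        return self.state

    def cgm(self) -> float:
        return sample_cgm(self.state, self.variability, self.rng)

    @property
    def clock(self) -> float:
        """Time of day in minutes since midnight."""
        return self.t % DAY_MIN
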