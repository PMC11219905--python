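"""Continuous insulin delivery: PD control with insulin feedback and a
sliding-mode insulin-on-board safety layer.

The inner loop is a proportional-derivative law on the CGM error with
gain tied to the patient's total daily insulin, kp = 60·TDI/(tau_d·1500)
in U/h per mg/dL.  Insulin feedback (IFB) attenuates the command in
proportion to the estimated plasma-insulin excess over its basal steady
state.  The outer SAFE layer bounds insulin on board (IOB): a sliding
surface on the two-compartment IOB estimate drives a discontinuous
switching signal which, after first-order low-pass filtering, raises the
glucose reference so the PD loop withholds insulin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from faidsim.patient import PatientParams, basal_plasma_insulin

__all__ = ["ControllerConfig", "ControllerState", "PDController",
           "pd_action", "update_iob", "safe_layer", "ifb_correction",
           "proportional_gain", "default_iob_max"]


def proportional_gain(tdi: float, tau_d: float = 90.0) -> float:
    """kp = 60·TDI / (tau_d·1500), in U/h per mg/dL."""
    return 60.0 * tdi / (tau_d * 1500.0)


def default_iob_max(tdi: float, dia_hours: float = 4.0,
                    multiple: float = 1.5) -> float:
    """Per-patient IOB bound: a multiple of basal insulin over one DIA."""
    return multiple * (tdi / 24.0) * dia_hours


@dataclass
class ControllerConfig:
    """Tunables of the PD + SAFE + IFB controller."""

    kp: float                      # proportional gain (U/h per mg/dL)
    tau_d: float = 90.0            # derivative time constant (min)
    Gref: float = 120.0            # glucose reference (mg/dL)
    IOB_max: float = 10.0          # upper IOB bound (U)
    tau_sm: float = 20.0           # sliding-surface time constant (min)
    nu_plus: float = 100.0         # switching amplitude (mg/dL)
    lam: float = 0.05              # low-pass filter rate (1/min)
    eta: float = 0.05              # IFB gain (U/h per mU/L)
    kdia: float = 0.02             # IOB-model time constant (1/min)
    pump_max: float = 150.0        # pump ceiling on the commanded rate (U/h)

    def __post_init__(self) -> None:
        if self.IOB_max <= 0 or self.lam <= 0 or self.kp <= 0:
            raise ValueError("kp, IOB_max and lam must be positive")

    @classmethod
    def for_patient(cls, params: PatientParams, **overrides) -> "ControllerConfig":
        kwargs = dict(kp=proportional_gain(params.TDI),
                      IOB_max=default_iob_max(params.TDI),
                      kdia=params.kdia)
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass
class ControllerState:
    """Internal state of the controller between 5-min ticks."""

    c1: float = 0.0            # IOB compartment 1 (U)
    c2: float = 0.0            # IOB compartment 2 (U)
    nu_f: float = 0.0          # filtered switching signal (mg/dL)
    Gvref: float = 120.0       # virtual glucose reference (mg/dL)
    prev_cgm: float | None = None
    ip_hat: float = 0.0        # estimated plasma insulin (mU/L)
    ipss_hat: float = 0.0      # its basal steady state (mU/L)
    es1: float = 0.0           # estimator subcutaneous depots (U)
    es2: float = 0.0
    last_s: float = 0.0        # last sliding-surface value (diagnostic)

    @property
    def iob(self) -> float:
        return self.c1 + self.c2


def pd_action(cgm: float, dG_dt: float, cfg: ControllerConfig,
              st: ControllerState, ubl: float, ubolus_rate: float = 0.0) -> float:
    """Inner PD control action in U/h, clamped to [0, pump_max].

    ``ubolus_rate`` is the bolus expressed as a rate over the current
    step (a one-step impulse).  The error is taken against the virtual
    reference maintained by the SAFE layer.
    """
    if cgm <= 0:
        raise ValueError("cgm must be positive")
    e = cgm - st.Gvref
    u = cfg.kp * (e + cfg.tau_d * dG_dt) + ubl + ubolus_rate
    return float(np.clip(u, 0.0, cfg.pump_max))


def update_iob(st: ControllerState, u: float, kdia: float,
               dt: float) -> ControllerState:
    """Advance the two-compartment IOB model by ``dt`` minutes.

    dc1/dt = u − kdia·c1, dc2/dt = kdia·(c1 − c2), with u in U/min
    (converted from the U/h pump command); IOB ≡ c1 + c2.  Exact
    discretisation of the linear system at fixed input.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    u_min = u / 60.0
    a = np.exp(-kdia * dt)
    c1_new = st.c1 * a + (u_min / kdia) * (1.0 - a)
    # c2' = kdia (c1 - c2); integrate with c1(t) known analytically
    #   c2(t) = c2 a + kdia t a c1 + (u/kdia)(1 - a - kdia t a)
    c2_new = (st.c2 * a + kdia * dt * a * st.c1
              + (u_min / kdia) * (1.0 - a - kdia * dt * a))
    st.c1, st.c2 = float(c1_new), float(c2_new)
    return st


def iob_derivative(st: ControllerState, u: float, kdia: float) -> float:
    """d(IOB)/dt in U/min given pump command ``u`` in U/h."""
    return u / 60.0 - kdia * st.c2


def safe_layer(st: ControllerState, cfg: ControllerConfig, u: float,
               dt: float) -> float:
    """Advance the SMRC layer one step; returns the virtual reference.

    The sliding surface s = (IOB − IOB_max) + tau_sm·dIOB/dt uses a
    constant bound (its derivative is zero).  When s > 0 the switching
    signal nu = nu_plus is turned on; the first-order filter
    dnu_f/dt = −lam·(nu_f − nu) smooths it, and Gvref = Gref + nu_f.
    """
    s = (st.iob - cfg.IOB_max) + cfg.tau_sm * iob_derivative(st, u, cfg.kdia)
    nu = cfg.nu_plus if s > 0 else 0.0
    a = np.exp(-cfg.lam * dt)
    st.nu_f = float(nu + (st.nu_f - nu) * a)
    st.Gvref = cfg.Gref + st.nu_f
    st.last_s = float(s)
    return st.Gvref


def ifb_correction(u: float, st: ControllerState, eta: float,
                   pump_max: float = 150.0) -> float:
    """Insulin feedback: attenuate by the plasma-insulin excess.

    u_IFB = u − eta·(ip_hat − ipss_hat), clamped to [0, pump_max].
    """
    u_ifb = u - eta * (st.ip_hat - st.ipss_hat)
    return float(np.clip(u_ifb, 0.0, pump_max))


def _update_insulin_estimator(st: ControllerState, params: PatientParams,
                              u: float, dt: float, substep: float = 1.0) -> None:
    """Propagate the plasma-insulin estimate with the insulin submodel,
    driven by the delivered insulin rate (U/h)."""
    n = max(1, int(round(dt / substep)))
    h = dt / n
    u_min = u / 60.0
    for _ in range(n):
        ds1 = u_min - st.es1 / params.tmaxI
        ds2 = (st.es1 - st.es2) / params.tmaxI
        di = -params.kf * st.ip_hat + 1000.0 * st.es2 / (params.tmaxI * params.Vi)
        st.es1 += h * ds1
        st.es2 += h * ds2
        st.ip_hat += h * di


class PDController:
    """Stateful 5-min-tick controller combining PD, SAFE, and IFB."""

    def __init__(self, cfg: ControllerConfig, params: PatientParams,
                 safe_enabled: bool = True) -> None:
        self.cfg = cfg
        self.params = params
        self.safe_enabled = safe_enabled
        self.st = ControllerState(Gvref=cfg.Gref)
        # start estimator and IOB model at the basal fixed point
        u_min = params.ubl / 60.0
        self.st.c1 = u_min / cfg.kdia
        self.st.c2 = self.st.c1
        self.st.es1 = u_min * params.tmaxI
        self.st.es2 = self.st.es1
        self.st.ip_hat = basal_plasma_insulin(params)
        self.st.ipss_hat = self.st.ip_hat

    def tick(self, cgm: float, bolus: float = 0.0, dt: float = 5.0) -> float:
        """One control cycle; returns the delivered rate in U/h.

        The bolus (U) is injected as a one-step impulse added to the
        infusion command.  Order: derivative estimate → PD → IFB →
        pump clamp → IOB model + SAFE reference update for the next tick.
        """
        st, cfg = self.st, self.cfg
        dG_dt = 0.0 if st.prev_cgm is None else (cgm - st.prev_cgm) / dt
        st.prev_cgm = cgm
        ubolus_rate = bolus * 60.0 / dt
        u = pd_action(cgm, dG_dt, cfg, st, self.params.ubl, ubolus_rate)
        u = ifb_correction(u, st, cfg.eta, cfg.pump_max)
        update_iob(st, u, cfg.kdia, dt)
        if self.safe_enabled:
            safe_layer(st, cfg, u, dt)
        _update_insulin_estimator(st, self.params, u, dt)
        return u
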