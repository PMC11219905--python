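"""Standard bolus calculator (SBC) — the hybrid-system baseline.

u_bolus = CHO/CR + (BG − BG_T)/CF − IOB̂, clamped at zero, with the
carbohydrate-to-insulin ratio CR and correction factor CF derived from
total daily insulin by the clinical 500 and 1800 rules.  Carbohydrate
misestimation is modelled as a multiplicative Gaussian error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TherapyParams", "standard_bolus", "misestimate_cho",
           "derive_therapy"]


@dataclass
class TherapyParams:
    """Clinician-style open-loop therapy settings."""

    CR: float           # carbohydrate-to-insulin ratio (g/U)
    CF: float           # correction factor (mg/dL per U)
    BG_T: float = 120.0  # target glucose (mg/dL)

    def __post_init__(self) -> None:
        if self.CR <= 0 or self.CF <= 0:
            raise ValueError("CR and CF must be positive")


def standard_bolus(cho: float, bg_k: float, therapy: TherapyParams,
                   iob_hat: float = 0.0) -> float:
    """Meal + correction bolus net of insulin on board, in U (>= 0)."""
    if cho < 0:
        raise ValueError("cho must be non-negative")
    u = cho / therapy.CR + (bg_k - therapy.BG_T) / therapy.CF - iob_hat
    return max(u, 0.0)


def misestimate_cho(true_cho: float, rng: np.random.Generator,
                    mu: float = 0.0, sigma: float = 0.2,
                    max_draws: int = 100) -> float:
    """Patient-estimated CHO: true value times (1 + Gaussian error).

    The multiplicative error has mean ``mu`` and standard deviation
    ``sigma``; draws forcing a non-positive estimate are rejected and
    redrawn so the result is always positive.
    """
    if true_cho <= 0:
        raise ValueError("true_cho must be positive")
    if sigma == 0.0:
        return true_cho * (1.0 + mu)
    for _ in range(max_draws):
        est = true_cho * (1.0 + rng.normal(mu, sigma))
        if est > 0:
            return est
    return true_cho * 0.05  # pathological sigma: fall back to a small meal


def derive_therapy(tdi: float, bg_target: float = 120.0,
                   cr: float | None = None,
                   cf: float | None = None) -> TherapyParams:
    """Guideline therapy parameters: CR = 500/TDI, CF = 1800/TDI.

    Explicit ``cr``/``cf`` overrides win over the derived values.
    """
    if tdi <= 0:
        raise ValueError("tdi must be positive")
    return TherapyParams(CR=cr if cr is not None else 500.0 / tdi,
                         CF=cf if cf is not None else 1800.0 / tdi,
                         BG_T=bg_target)
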