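"""Consensus CGM outcome metrics and paired comparison across arms.

Implements the standardized core CGM metrics (time-in-range bands, CV,
GMI, GRI), insulin totals, hypoglycemia event counting, and per-metric
Wilcoxon signed-rank comparison between two study arms.

Published coefficient sets are used for the derived indices:
GMI(%) = 3.31 + 0.02392·mean CGM, and
GRI = 3.0·(%<54) + 2.4·(%54–69) + 1.6·(%>250) + 0.8·(%181–250),
capped at 100.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["MetricsReport", "cgm_metrics", "insulin_totals",
           "paired_compare", "count_hypo_events", "time_in_band"]

#: exhaustive glucose partition (mg/dL), half-open [lo, hi)
BANDS = {
    "below_54": (0.0, 54.0),
    "54_69": (54.0, 70.0),
    "70_140": (70.0, 141.0),
    "141_180": (141.0, 181.0),
    "181_250": (181.0, 251.0),
    "above_250": (251.0, np.inf),
}


def time_in_band(cgm: np.ndarray, lo: float, hi: float) -> float:
    """Percent of samples with lo <= cgm < hi."""
    cgm = np.asarray(cgm, dtype=float)
    return 100.0 * float(np.mean((cgm >= lo) & (cgm < hi)))


@dataclass
class MetricsReport:
    """One arm × one patient summary, Table-of-consensus-metrics shaped."""

    mean_cgm: float
    median_cgm: float
    max_cgm: float
    min_cgm: float
    cv: float                  # %
    gmi: float                 # %
    pct_below_54: float
    pct_54_69: float
    pct_70_140: float
    pct_70_180: float
    pct_181_250: float
    pct_above_250: float
    gri: float
    basal_u_day: float = float("nan")
    bolus_u_day: float = float("nan")
    tdi_u_day: float = float("nan")

    @property
    def pct_below_70(self) -> float:
        return self.pct_below_54 + self.pct_54_69

    @property
    def pct_above_180(self) -> float:
        return self.pct_181_250 + self.pct_above_250

    def as_dict(self) -> dict:
        d = asdict(self)
        d["pct_below_70"] = self.pct_below_70
        d["pct_above_180"] = self.pct_above_180
        return d


def cgm_metrics(trace: pd.DataFrame) -> MetricsReport:
    """Consensus CGM metrics from an EpisodeTrace (>= 1 day of samples)."""
    if len(trace) == 0:
        raise ValueError("empty trace")
    g = trace["cgm"].to_numpy(dtype=float)
    mean = float(g.mean())
    pct = {name: time_in_band(g, lo, hi) for name, (lo, hi) in BANDS.items()}
    gri = (3.0 * pct["below_54"] + 2.4 * pct["54_69"]
           + 1.6 * pct["above_250"] + 0.8 * pct["181_250"])
    report = MetricsReport(
        mean_cgm=mean,
        median_cgm=float(np.median(g)),
        max_cgm=float(g.max()),
        min_cgm=float(g.min()),
        cv=100.0 * float(g.std(ddof=1)) / mean if mean > 0 else float("nan"),
        gmi=3.31 + 0.02392 * mean,
        pct_below_54=pct["below_54"],
        pct_54_69=pct["54_69"],
        pct_70_140=pct["70_140"],
        pct_70_180=pct["70_140"] + pct["141_180"],
        pct_181_250=pct["181_250"],
        pct_above_250=pct["above_250"],
        gri=min(gri, 100.0),
    )
    if {"basal_U_per_h", "bolus_U"} <= set(trace.columns):
        basal, bolus, tdi = insulin_totals(trace)
        report.basal_u_day = basal
        report.bolus_u_day = bolus
        report.tdi_u_day = tdi
    return report


def insulin_totals(trace: pd.DataFrame,
                   dt_min: float = 5.0) -> tuple[float, float, float]:
    """(basal U/day, bolus U/day, TDI U/day) from the delivery columns.

    Basal is the time integral of the rate column; boluses are summed.
    """
    days = len(trace) * dt_min / 1440.0
    basal = float(trace["basal_U_per_h"].sum() * dt_min / 60.0) / days
    bolus = float(trace["bolus_U"].sum()) / days
    return basal, bolus, basal + bolus


def count_hypo_events(cgm: np.ndarray, threshold: float = 70.0,
                      min_duration_min: float = 15.0,
                      dt_min: float = 5.0) -> int:
    """Number of hypoglycemia events: runs of CGM < threshold lasting at
    least ``min_duration_min`` (ADA convention, 15 min)."""
    below = np.asarray(cgm, dtype=float) < threshold
    min_run = int(np.ceil(min_duration_min / dt_min))
    events = 0
    run = 0
    for b in below:
        if b:
            run += 1
            if run == min_run:
                events += 1
        else:
            run = 0
    return events


def paired_compare(reports_a: list[MetricsReport],
                   reports_b: list[MetricsReport]) -> pd.DataFrame:
    """Per-metric two-sided Wilcoxon signed-rank test across patients.

    Rows are metrics; columns give median (IQR) per arm and the p-value.
    Identical arms (all zero differences) give p = 1.
    """
    if len(reports_a) != len(reports_b):
        raise ValueError("arms must contain the same patients")
    n = len(reports_a)
    if n < 6:
        warnings.warn("fewer than 6 pairs: exact Wilcoxon p is coarse",
                      UserWarning)
    rows = []
    metric_names = list(reports_a[0].as_dict())
    for name in metric_names:
        a = np.array([r.as_dict()[name] for r in reports_a], dtype=float)
        b = np.array([r.as_dict()[name] for r in reports_b], dtype=float)
        if np.all(np.isnan(a)) or np.all(np.isnan(b)):
            continue
        diffs = a - b
        if np.allclose(diffs, 0.0):
            p = 1.0
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, p = stats.wilcoxon(a, b, zero_method="wilcox")
        rows.append({
            "metric": name,
            "arm_a_median": float(np.median(a)),
            "arm_a_q25": float(np.quantile(a, 0.25)),
            "arm_a_q75": float(np.quantile(a, 0.75)),
            "arm_b_median": float(np.median(b)),
            "arm_b_q25": float(np.quantile(b, 0.25)),
            "arm_b_q75": float(np.quantile(b, 0.75)),
            "p_value": float(p),
        })
    return pd.DataFrame(rows).set_index("metric")
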