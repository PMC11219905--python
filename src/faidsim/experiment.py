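"""Experiment orchestration: the three insulin-delivery arms.

Wires the virtual patient, PD+SAFE controller, meal detector, standard
bolus calculator, and DQN bank into the three study arms:

* ``HAID_SBC_MCHO`` — hybrid delivery, standard bolus calculator at true
  meal times with Gaussian carbohydrate misestimation;
* ``HAID_DRL`` — hybrid delivery, DQN bolus at true meal times;
* ``FAID`` — fully automatic delivery, DQN bolus at detector flags only.

All arms share the PD closed loop.  In hybrid arms the detector is
never consulted; in the FAID arm true meal times are visible only to
the scorer.  Training that fails to converge for a patient flags and
excludes that patient from cohort reports, never silently.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from faidsim.detector import DetectorTuning, score_detections
from faidsim.drl import DQNBank, TrainConfig, generate_memory, train
from faidsim.loop import ClosedLoop, RLPolicy, SBCPolicy
from faidsim.metrics import MetricsReport, cgm_metrics, paired_compare
from faidsim.patient import (PatientParams, VariabilityConfig,
                             generate_cohort, generate_scenario)
from faidsim.sbc import derive_therapy

__all__ = ["ExperimentConfig", "run_arm", "train_cohort", "ArmResult",
           "ARMS"]

ARMS = ("HAID_SBC_MCHO", "HAID_DRL", "FAID")


@dataclass
class ExperimentConfig:
    """Study configuration shared by training and evaluation."""

    arm: str = "FAID"
    n_patients: int = 3
    days: int = 14
    seed: int = 1
    detector_mode: str = "trade_off"
    cho_mu: float = 0.0
    cho_sigma: float = 0.2           # CHO misestimation CV (SBC arm)
    si_amplitude: float = 0.3
    absorption_cv: float = 0.2
    cgm_noise_sd: float = 2.0
    train: TrainConfig = field(default_factory=TrainConfig)

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValueError(f"unknown arm {self.arm!r}; expected one of {ARMS}")

    def variability(self, seed: int) -> VariabilityConfig:
        return VariabilityConfig(si_amplitude=self.si_amplitude,
                                 absorption_cv=self.absorption_cv,
                                 cgm_noise_sd=self.cgm_noise_sd, seed=seed)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        train_raw = raw.pop("train", {})
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for key, value in train_raw.items():
            if not hasattr(cfg.train, key):
                raise ValueError(f"unknown train config key: {key}")
            setattr(cfg.train, key, value)
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["train"].pop("k_bob_overrides", None)
        return d


@dataclass
class ArmResult:
    """Per-patient outcome of one arm."""

    patient_idx: int
    trace: pd.DataFrame
    report: MetricsReport
    detection: object | None = None   # DetectionScore, FAID arm only
    detections: pd.DataFrame | None = None  # (time_min, cross_cov_value)


def train_cohort(cfg: ExperimentConfig,
                 cohort: list[PatientParams] | None = None,
                 mode: str = "announced",
                 log_dir: str | Path | None = None,
                 ) -> tuple[dict[int, DQNBank], list[int]]:
    """Train one DQN bank per patient; returns (banks, excluded ids).

    ``log_dir`` saves each patient's training log (iteration, reward,
    loss, epsilon, daily hypoglycemia events) as CSV.

    A patient whose training diverges is flagged and excluded, matching
    the policy of dropping non-converging patients from cohort reports.
    """
    cohort = cohort or generate_cohort(cfg.n_patients, cfg.seed)
    banks: dict[int, DQNBank] = {}
    excluded: list[int] = []
    for i, params in enumerate(cohort):
        seed = cfg.seed + 1000 * (i + 1)
        bank = DQNBank(params.TDI, seed=seed,
                       memory_capacity=cfg.train.memory_capacity)
        var = cfg.variability(seed)
        try:
            generate_memory(params, bank, cfg.train, seed=seed,
                            mode=mode, variability=var)
            log = train(params, bank, cfg.train, seed=seed, mode=mode,
                        variability=var)
            if log_dir is not None:
                Path(log_dir).mkdir(parents=True, exist_ok=True)
                log.to_csv(Path(log_dir) / f"training_patient{i}.csv",
                           index=False)
        except RuntimeError as err:
            warnings.warn(f"patient {i} excluded: {err}", UserWarning)
            excluded.append(i)
            continue
        banks[i] = bank
    return banks, excluded


def _make_policy(cfg: ExperimentConfig, params: PatientParams,
                 bank: DQNBank | None, rng: np.random.Generator):
    if cfg.arm == "HAID_SBC_MCHO":
        therapy = derive_therapy(params.TDI)
        return SBCPolicy(therapy, cho_mu=cfg.cho_mu,
                         cho_sigma=cfg.cho_sigma, rng=rng)
    if bank is None:
        raise ValueError(
            f"arm {cfg.arm} needs a trained DQN bank; run training first")
    return RLPolicy(bank, cfg.train, epsilon=0.0, rng=rng)


def run_arm(cfg: ExperimentConfig,
            banks: dict[int, DQNBank] | None = None,
            cohort: list[PatientParams] | None = None,
            detector_enabled: bool = True,
            out_dir: str | Path | None = None) -> list[ArmResult]:
    """Simulate one arm over the cohort for ``cfg.days`` days.

    ``banks`` maps patient index → trained bank (DRL arms); patients
    without a bank (excluded at training) are skipped with a warning.
    ``detector_enabled=False`` in the FAID arm degenerates to PD-only
    control (a wiring check).  Writes traces/reports under ``out_dir``
    when given.
    """
    cohort = cohort or generate_cohort(cfg.n_patients, cfg.seed)
    results: list[ArmResult] = []
    for i, params in enumerate(cohort):
        seed = cfg.seed + 10_000 + 97 * i
        if cfg.arm != "HAID_SBC_MCHO" and banks is not None and i not in banks:
            warnings.warn(f"patient {i} has no trained bank; skipped",
                          UserWarning)
            continue
        rng = np.random.default_rng(seed)
        policy = _make_policy(cfg, params,
                              None if cfg.arm == "HAID_SBC_MCHO"
                              else (banks or {}).get(i), rng)
        scenario = generate_scenario("testing", cfg.days, seed + 3,
                                     absorption_cv=cfg.absorption_cv)
        mode = "faid" if cfg.arm == "FAID" else "announced"
        if cfg.arm == "FAID" and not detector_enabled:
            mode = "none"
        loop = ClosedLoop(params, scenario, mode=mode, policy=policy,
                          variability=cfg.variability(seed),
                          detector_tuning=DetectorTuning.preset(
                              cfg.detector_mode),
                          seed=seed)
        loop.run(cfg.days)
        trace = loop.trace
        detection = None
        detections = None
        if cfg.arm == "FAID" and detector_enabled:
            detection = score_detections(trace)
            detections = loop.detections
        results.append(ArmResult(patient_idx=i, trace=trace,
                                 report=cgm_metrics(trace),
                                 detection=detection,
                                 detections=detections))
    if out_dir is not None:
        _write_results(cfg, results, Path(out_dir))
    return results


def _write_results(cfg: ExperimentConfig, results: list[ArmResult],
                   out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    summary = {}
    for res in results:
        stem = f"{cfg.arm}_patient{res.patient_idx}"
        res.trace.to_csv(out_dir / f"{stem}_trace.csv", index=False)
        if res.detections is not None:
            res.detections.to_csv(out_dir / f"{stem}_detections.csv",
                                  index=False)
        summary[stem] = res.report.as_dict()
        if res.detection is not None:
            summary[stem]["detector"] = {
                "tp": res.detection.tp, "fp": res.detection.fp,
                "fn": res.detection.fn,
                "sensitivity_pct": res.detection.sensitivity,
                "median_latency_min": res.detection.median_latency,
            }
    payload = {"config": cfg.to_dict(), "patients": summary}
    (out_dir / f"{cfg.arm}_report.json").write_text(
        json.dumps(payload, indent=2))


def compare_arms(results_a: list[ArmResult],
                 results_b: list[ArmResult]) -> pd.DataFrame:
    """Wilcoxon signed-rank comparison of two arms, paired by patient."""
    ids = sorted({r.patient_idx for r in results_a}
                 & {r.patient_idx for r in results_b})
    a = {r.patient_idx: r.report for r in results_a}
    b = {r.patient_idx: r.report for r in results_b}
    return paired_compare([a[i] for i in ids], [b[i] for i in ids])
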