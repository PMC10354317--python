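"""Diagnostic-accuracy statistics.

Confusion counts, sensitivity/specificity with exact Clopper–Pearson 95%
confidence intervals, trapezoidal/midrank ROC AUC, stage-stratified and
pooled sensitivities, and Buderer's prevalence-adjusted sample-size formula
for diagnostic studies.

The Clopper–Pearson interval for x successes in n trials is
``(Beta(α/2; x, n−x+1), Beta(1−α/2; x+1, n−x))`` with the conventions
low = 0 at x = 0 and high = 1 at x = n; it is exact (conservative) by
construction.  Pooled stage sensitivities are computed from summed counts,
never by averaging percentages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

EARLY_STAGES = ("I", "II")
LATE_STAGES = ("III", "IV")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def diseased(self) -> int:
        return self.tp + self.fn

    @property
    def non_diseased(self) -> int:
        return self.tn + self.fp

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricWithCi:
    estimate: float
    ci_low: float
    ci_high: float
    level: float = 0.95
    method: str = "clopper_pearson"

    def __post_init__(self) -> None:
        if not 0 <= self.ci_low <= self.estimate <= self.ci_high <= 1:
            raise ValueError(
                f"CI ordering violated: {self.ci_low} ≤ {self.estimate} ≤ {self.ci_high}"
            )

    def as_percent(self, dp: int = 1) -> tuple[float, float, float]:
        return (
            round_half_up(100 * self.estimate, dp),
            round_half_up(100 * self.ci_low, dp),
            round_half_up(100 * self.ci_high, dp),
        )


def round_half_up(x: float, dp: int = 1) -> float:
    """Decimal half-up rounding (0.05 at 1 dp rounds to 0.1, not 0.0)."""
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(10) ** -dp
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def clopper_pearson(x: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact two-sided binomial confidence interval via beta quantiles."""
    if n < 1:
        raise ValueError("n must be ≥ 1")
    if not 0 <= x <= n:
        raise ValueError(f"x = {x} outside [0, {n}]")
    alpha = 1.0 - level
    low = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
    high = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return low, high


def infer_counts_from_rate(n: int, percent: float, dp: int = 1) -> list[int]:
    """All integer success counts x ≤ n whose percentage rounds (half-up, dp
    decimals) to the printed value — used to recover counts from reported
    sensitivities/specificities."""
    return [x for x in range(n + 1) if round_half_up(100 * x / n, dp) == percent]


@dataclass(frozen=True)
class SensSpec:
    sensitivity: MetricWithCi | None
    specificity: MetricWithCi | None


def sens_spec(conf: ConfusionCounts, level: float = 0.95) -> SensSpec:
    """Sensitivity tp/(tp+fn) and specificity tn/(tn+fp), each with an exact
    CI.  A zero denominator yields None (flagged undefined), never silent 0."""
    sens = spec = None
    if conf.diseased >= 1:
        lo, hi = clopper_pearson(conf.tp, conf.diseased, level)
        sens = MetricWithCi(conf.tp / conf.diseased, lo, hi, level)
    if conf.non_diseased >= 1:
        lo, hi = clopper_pearson(conf.tn, conf.non_diseased, level)
        spec = MetricWithCi(conf.tn / conf.non_diseased, lo, hi, level)
    return SensSpec(sens, spec)


def roc_auc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Area under the empirical ROC curve (trapezoidal).

    Computed through midranks so ties contribute half a concordance, making
    the value identical to the Mann–Whitney pairwise-concordance probability.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D and equal length")
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("ROC AUC needs both classes present")
    ranks = stats.rankdata(scores, method="average")
    return float((ranks[labels].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


@dataclass(frozen=True)
class StageCount:
    detected: int
    total: int

    @property
    def sensitivity(self) -> float | None:
        return self.detected / self.total if self.total else None


@dataclass(frozen=True)
class StageBreakdown:
    per_stage: dict[str, StageCount]
    early: StageCount
    late: StageCount

    def to_dict(self) -> dict:
        d = {
            s: {"detected": c.detected, "total": c.total, "sensitivity": c.sensitivity}
            for s, c in self.per_stage.items()
        }
        d["early_I_II"] = {
            "detected": self.early.detected,
            "total": self.early.total,
            "sensitivity": self.early.sensitivity,
        }
        d["late_III_IV"] = {
            "detected": self.late.detected,
            "total": self.late.total,
            "sensitivity": self.late.sensitivity,
        }
        return d


def pooled_from_counts(counts: Mapping[str, tuple[int, int]]) -> StageBreakdown:
    """Build a breakdown from per-stage (detected, total) pairs; pooled early
    (I–II) and late (III–IV) rates are sums of counts."""
    per = {s: StageCount(*counts.get(s, (0, 0))) for s in ("I", "II", "III", "IV")}
    early = StageCount(
        sum(per[s].detected for s in EARLY_STAGES),
        sum(per[s].total for s in EARLY_STAGES),
    )
    late = StageCount(
        sum(per[s].detected for s in LATE_STAGES),
        sum(per[s].total for s in LATE_STAGES),
    )
    return StageBreakdown(per, early, late)


def stage_sensitivity(predictions, truths) -> StageBreakdown:
    """Per-stage and pooled detection rates among diseased patients.

    ``predictions`` is an iterable with ``patient_id`` and ``label`` fields
    (label 'crc' = detected); ``truths`` carry ``patient_id``, ``is_crc`` and
    ``stage``.  A diseased patient with stage 'none' is an input error.
    """
    label_by_pid = {p.patient_id: p.label for p in predictions}
    counts: dict[str, list[int]] = {s: [0, 0] for s in ("I", "II", "III", "IV")}
    for t in truths:
        if not t.is_crc:
            continue
        if t.stage not in counts:
            raise ValueError(f"diseased patient {t.patient_id} has stage {t.stage!r}")
        if t.patient_id not in label_by_pid:
            raise ValueError(f"no prediction for diseased patient {t.patient_id}")
        counts[t.stage][1] += 1
        if label_by_pid[t.patient_id] == "crc":
            counts[t.stage][0] += 1
    return pooled_from_counts({s: (d, n) for s, (d, n) in counts.items()})


@dataclass(frozen=True)
class SampleSizeSpec:
    target_proportion: float  # expected sensitivity or specificity
    precision: float  # absolute CI half-width d
    prevalence: float
    alpha: float = 0.05

    def __post_init__(self) -> None:
        for name in ("target_proportion", "precision", "alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1); got {v}")
        if not 0 < self.prevalence <= 1:
            raise ValueError(f"prevalence must be in (0, 1]; got {self.prevalence}")


def buderer_sample_size(spec: SampleSizeSpec) -> int:
    """Recruited participants needed to pin a test proportion to ±d.

    ``n = ⌊ z²·p(1−p) / d² / prevalence ⌋``: the single-proportion normal
    approximation inflated by disease prevalence so the relevant subgroup is
    large enough.  Truncation is floor (0.90/0.10/0.05 at α = 0.05 gives
    691.49 → 691).  For a specificity target the divisor is (1 − prevalence);
    pass the prevalence of the *relevant* group either way — the caller
    states which subgroup the proportion refers to.
    """
    z = stats.norm.ppf(1 - spec.alpha / 2)
    p, d = spec.target_proportion, spec.precision
    n_subgroup = z**2 * p * (1 - p) / d**2
    return int(np.floor(n_subgroup / spec.prevalence))


# --- full report -------------------------------------------------------------

@dataclass
class StratumResult:
    name: str
    n: int
    counts: ConfusionCounts
    sensitivity: MetricWithCi | None
    specificity: MetricWithCi | None
    auc: float | None

    def to_dict(self) -> dict:
        def _m(m: MetricWithCi | None):
            if m is None:
                return None
            return {
                "estimate": m.estimate,
                "ci_low": m.ci_low,
                "ci_high": m.ci_high,
                "level": m.level,
                "method": m.method,
            }

        return {
            "name": self.name,
            "n": self.n,
            "counts": {"tp": self.counts.tp, "fp": self.counts.fp,
                       "tn": self.counts.tn, "fn": self.counts.fn},
            "sensitivity": _m(self.sensitivity),
            "specificity": _m(self.specificity),
            "auc": self.auc,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "StratumResult":
        def _m(x):
            return None if x is None else MetricWithCi(**x)

        return cls(
            name=d["name"],
            n=d["n"],
            counts=ConfusionCounts(**d["counts"]),
            sensitivity=_m(d["sensitivity"]),
            specificity=_m(d["specificity"]),
            auc=d["auc"],
        )


@dataclass
class DxReport:
    """Everything the evaluation reports: per-stratum accuracy, stage
    breakdown, and patient-flow accounting."""

    strata: list[StratumResult]
    stage_breakdown: StageBreakdown | None = None
    exclusion_report: dict = field(default_factory=dict)
    level: float = 0.95

    def to_dict(self) -> dict:
        return {
            "level": self.level,
            "strata": [s.to_dict() for s in self.strata],
            "stage_breakdown": None if self.stage_breakdown is None else self.stage_breakdown.to_dict(),
            "exclusion_report": self.exclusion_report,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "DxReport":
        sb = d.get("stage_breakdown")
        breakdown = None
        if sb is not None:
            breakdown = pooled_from_counts(
                {s: (sb[s]["detected"], sb[s]["total"]) for s in ("I", "II", "III", "IV")}
            )
        return cls(
            strata=[StratumResult.from_dict(s) for s in d["strata"]],
            stage_breakdown=breakdown,
            exclusion_report=dict(d.get("exclusion_report", {})),
            level=d.get("level", 0.95),
        )

    def to_stratum_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.strata:
            sens = s.sensitivity.as_percent() if s.sensitivity else (None,) * 3
            spec = s.specificity.as_percent() if s.specificity else (None,) * 3
            rows.append(
                {
                    "stratum": s.name, "n": s.n,
                    "tp": s.counts.tp, "fp": s.counts.fp,
                    "tn": s.counts.tn, "fn": s.counts.fn,
                    "sensitivity_pct": sens[0], "sens_ci_low_pct": sens[1],
                    "sens_ci_high_pct": sens[2],
                    "specificity_pct": spec[0], "spec_ci_low_pct": spec[1],
                    "spec_ci_high_pct": spec[2],
                    "auc": s.auc,
                }
            )
        return pd.DataFrame(rows)

    def to_markdown(self) -> str:
        lines = [
            "| Stratum | n | Sensitivity | Specificity | AUC |",
            "|---|---|---|---|---|",
        ]
        for s in self.strata:
            def fmt(m: MetricWithCi | None) -> str:
                if m is None:
                    return "undefined"
                e, lo, hi = m.as_percent()
                return f"{e} ({lo}% to {hi}%)"

            auc = "n/a" if s.auc is None else f"{s.auc:.2f}"
            lines.append(f"| {s.name} | {s.n} | {fmt(s.sensitivity)} | {fmt(s.specificity)} | {auc} |")
        if self.stage_breakdown is not None:
            lines += ["", "| Stage | Detected | Total | Sensitivity |", "|---|---|---|---|"]
            for stage, c in self.stage_breakdown.per_stage.items():
                pct = "n/a" if c.sensitivity is None else f"{round_half_up(100 * c.sensitivity)}%"
                lines.append(f"| {stage} | {c.detected} | {c.total} | {pct} |")
            for label, c in (("I–II", self.stage_breakdown.early), ("III–IV", self.stage_breakdown.late)):
                pct = "n/a" if c.sensitivity is None else f"{round_half_up(100 * c.sensitivity)}%"
                lines.append(f"| {label} | {c.detected} | {c.total} | {pct} |")
        if self.exclusion_report:
            lines += ["", "Patient flow: " + ", ".join(f"{k}: {v}" for k, v in self.exclusion_report.items())]
        return "\n".join(lines) + "\n"


def build_report(
    predictions,
    cohort,
    strata: Mapping[str, Iterable[str]],
    truths=None,
    level: float = 0.95,
    exclusion_report: Mapping | None = None,
) -> DxReport:
    """Assemble the full diagnostic report.

    ``predictions``: PatientPrediction-like (patient_id, probability, label).
    ``cohort``: PatientRecord list giving the reference diagnosis.
    ``strata``: stratum name → patient ids in that stratum.
    ``truths``: optional GroundTruth list for the stage breakdown.
    """
    by_pid = {p.patient_id: p for p in predictions}
    diag = {r.patient_id: r.diagnosis for r in cohort}
    for pid in by_pid:
        if pid not in diag:
            raise ValueError(f"prediction for patient {pid} absent from cohort")

    strata_results = []
    for name, pids in strata.items():
        pids = list(pids)
        tp = fp = tn = fn = 0
        scores, labels = [], []
        for pid in pids:
            if pid not in by_pid:
                raise ValueError(f"stratum {name!r}: no prediction for patient {pid}")
            pred = by_pid[pid]
            diseased = diag[pid] == "crc"
            positive = pred.label == "crc"
            tp += diseased and positive
            fn += diseased and not positive
            fp += (not diseased) and positive
            tn += (not diseased) and not positive
            scores.append(pred.probability)
            labels.append(diseased)
        counts = ConfusionCounts(tp=int(tp), fp=int(fp), tn=int(tn), fn=int(fn))
        ss = sens_spec(counts, level)
        auc = None
        if any(labels) and not all(labels):
            auc = roc_auc(scores, labels)
        strata_results.append(
            StratumResult(name, len(pids), counts, ss.sensitivity, ss.specificity, auc)
        )
    breakdown = stage_sensitivity(predictions, truths) if truths is not None else None
    return DxReport(
        strata=strata_results,
        stage_breakdown=breakdown,
        exclusion_report=dict(exclusion_report or {}),
        level=level,
    )
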