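"""Cohort construction: propensity matching, exclusions, stratification.

The training cohort is built 1:1 case–control matched on age and sex via
propensity scores (logistic model, greedy nearest-neighbour on the logit,
caliper 0.2 SD of the logit — the standard Rosenbaum–Rubin defaults).  The
prospective evaluation applies the study's patient-flow rules: patients
whose only reference investigation was flexible sigmoidoscopy are excluded,
as are patients without a reference test or without a final diagnosis;
results are then stratified by reference standard (colonoscopy only, and
colonoscopy plus CT colonography).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression

from .spectra_io import PatientRecord


class SeparationError(ValueError):
    """Complete covariate separation: propensity model is degenerate.

    Re-run with ``caliper=None`` (caliper-free matching) if matching on a
    degenerate score is genuinely intended.
    """


@dataclass
class MatchResult:
    pairs: list[tuple[str, str]]  # (case patient_id, control patient_id)
    propensity: dict[str, float]
    balance: dict[str, dict[str, float]]  # covariate -> {"smd_before", "smd_after"}
    caliper_logit: float | None


def _covariate_matrix(patients: Sequence[PatientRecord], covariates: Sequence[str]) -> np.ndarray:
    cols = []
    for cov in covariates:
        if cov == "age":
            cols.append([p.age for p in patients])
        elif cov == "sex":
            cols.append([1.0 if p.sex == "M" else 0.0 for p in patients])
        else:
            raise ValueError(f"unknown covariate {cov!r}")
    return np.array(cols, dtype=float).T


def _smd(x_case: np.ndarray, x_ctrl: np.ndarray) -> float:
    """Standardised mean difference with the pooled-SD denominator."""
    sd = np.sqrt((np.var(x_case, ddof=1) + np.var(x_ctrl, ddof=1)) / 2.0)
    if sd == 0:
        return 0.0
    return float((x_case.mean() - x_ctrl.mean()) / sd)


def propensity_match(
    cases: Sequence[PatientRecord],
    controls: Sequence[PatientRecord],
    covariates: Sequence[str] = ("age", "sex"),
    caliper: float | None = 0.2,
) -> MatchResult:
    """Greedy 1:1 nearest-neighbour matching on the propensity-score logit.

    Cases are matched in order of descending propensity (ties broken by
    patient id), each to the nearest unused control within the caliper
    (``caliper`` × SD of the logit; ``None`` disables it).  Deterministic:
    no randomness anywhere.
    """
    if not cases or not controls:
        raise ValueError("both cases and controls must be non-empty")
    everyone = list(cases) + list(controls)
    X = _covariate_matrix(everyone, covariates)
    y = np.array([1] * len(cases) + [0] * len(controls))

    # C → ∞: effectively unpenalised maximum likelihood
    model = LogisticRegression(C=1e12, max_iter=1000)
    model.fit(X, y)
    p = model.predict_proba(X)[:, 1]
    separated = p[y == 1].min() > 0.999 and p[y == 0].max() < 0.001
    if separated and caliper is None:
        # with a caliper, degenerate scores simply fall outside it and yield
        # zero pairs; without one, every pairing would be arbitrary
        raise SeparationError(
            "complete covariate separation between cases and controls; "
            "caliper-free matching on a degenerate propensity score is arbitrary"
        )
    p = np.clip(p, 1e-12, 1 - 1e-12)
    logit = np.log(p / (1 - p))
    propensity = {pt.patient_id: float(pi) for pt, pi in zip(everyone, p)}

    sd_logit = float(np.std(logit, ddof=1))
    cal = caliper * sd_logit if caliper is not None else None

    case_logit = {c.patient_id: lg for c, lg in zip(cases, logit[: len(cases)])}
    ctrl_logit = {c.patient_id: lg for c, lg in zip(controls, logit[len(cases):])}
    order = sorted(case_logit, key=lambda pid: (-case_logit[pid], pid))
    available = dict(sorted(ctrl_logit.items()))
    pairs: list[tuple[str, str]] = []
    for cid in order:
        if not available:
            break
        best, best_d = None, np.inf
        for kid, lg in available.items():
            d = abs(case_logit[cid] - lg)
            if d < best_d:  # ties keep the lowest patient_id (iteration order)
                best, best_d = kid, d
        if cal is not None and best_d > cal:
            continue
        pairs.append((cid, best))
        del available[best]

    matched_case_ids = {c for c, _ in pairs}
    matched_ctrl_ids = {k for _, k in pairs}
    Xc = _covariate_matrix(list(cases), covariates)
    Xk = _covariate_matrix(list(controls), covariates)
    case_index = {c.patient_id: i for i, c in enumerate(cases)}
    ctrl_index = {c.patient_id: i for i, c in enumerate(controls)}
    balance = {}
    for j, cov in enumerate(covariates):
        before = _smd(Xc[:, j], Xk[:, j])
        if pairs:
            sel_c = [case_index[c] for c, _ in pairs]
            sel_k = [ctrl_index[k] for _, k in pairs]
            after = _smd(Xc[sel_c, j], Xk[sel_k, j])
        else:
            after = float("nan")
        balance[cov] = {"smd_before": before, "smd_after": after}
    _ = matched_case_ids, matched_ctrl_ids
    return MatchResult(pairs=pairs, propensity=propensity, balance=balance, caliper_logit=cal)


# --- exclusions and stratification -------------------------------------------

EXCLUSION_REASONS = ("flexible_sigmoidoscopy", "missing_reference", "missing_diagnosis")


@dataclass
class ExclusionReport:
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def retained(self) -> int:
        return self.counts.get("retained", 0)

    def total(self) -> int:
        return sum(self.counts.values())

    def to_dict(self) -> dict:
        return dict(self.counts)


def apply_exclusions(patients: Iterable[PatientRecord]) -> tuple[list[PatientRecord], ExclusionReport]:
    """Patient-flow rules of the prospective evaluation.

    Exclusion reasons partition the input (checked in order): flexible
    sigmoidoscopy as the only reference investigation; no reference test;
    missing final diagnosis.  Everyone else is retained.
    """
    patients = list(patients)
    counts = {r: 0 for r in EXCLUSION_REASONS}
    retained: list[PatientRecord] = []
    for p in patients:
        if p.reference_test == "flexible_sigmoidoscopy":
            counts["flexible_sigmoidoscopy"] += 1
        elif p.reference_test == "none":
            counts["missing_reference"] += 1
        elif p.diagnosis == "unknown":
            counts["missing_diagnosis"] += 1
        else:
            retained.append(p)
    counts["retained"] = len(retained)
    report = ExclusionReport(counts=counts)
    assert report.total() == len(patients), "exclusion accounting must reconcile"
    return retained, report


def stratify_by_reference(patients: Iterable[PatientRecord]) -> dict[str, list[PatientRecord]]:
    """Nested reference-standard strata: colonoscopy alone (gold standard)
    and colonoscopy together with CT colonography.  Input must already be
    exclusion-filtered; any other reference value is an error."""
    colonoscopy: list[PatientRecord] = []
    combined: list[PatientRecord] = []
    for p in patients:
        if p.reference_test == "colonoscopy":
            colonoscopy.append(p)
            combined.append(p)
        elif p.reference_test == "ct_colonography":
            combined.append(p)
        else:
            raise ValueError(
                f"patient {p.patient_id} has reference {p.reference_test!r}; "
                "exclusions must be applied before stratification"
            )
    return {"colonoscopy_only": colonoscopy, "colonoscopy_plus_ctc": combined}
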