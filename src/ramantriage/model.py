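"""Random-forest spectral classification with patient-level aggregation.

Spectra (not patients) are the rows of the feature matrix, but everything
that matters clinically happens per patient: cross-validation folds group
all of a patient's replicate spectra together (splitting replicates across
folds would leak within-patient correlation), and the classifier's
per-spectrum cancer probabilities are averaged per patient before the fixed
0.5 decision threshold is applied — probability ≥ 0.5 classifies as 'crc',
< 0.5 as 'non_cancer'.

Prediction is structurally blind: :func:`predict_patients` takes processed
spectra only, with no channel through which a diagnosis could flow.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedGroupKFold

from .dxstats import roc_auc
from .preprocess import ProcessedSpectrum

DEFAULT_HYPERPARAMS = {"n_estimators": 500, "max_features": "sqrt", "max_depth": None}


class GridMismatchError(ValueError):
    pass


def grid_fingerprint(grid: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(np.asarray(grid, float)).tobytes()).hexdigest()[:16]


def build_feature_matrix(
    spectra: Sequence[ProcessedSpectrum],
    labels: Mapping[str, bool] | None = None,
) -> tuple[pd.DataFrame, pd.Series | None]:
    """Stack processed spectra into a (spectra × grid) matrix indexed by
    (patient_id, replicate_id).  ``labels`` maps patient_id → is_crc; the
    returned outcome series is per spectrum (replicates share the label)."""
    if not spectra:
        raise ValueError("no spectra")
    ref = spectra[0].grid
    for s in spectra:
        if not np.array_equal(s.grid, ref):
            raise GridMismatchError(
                f"spectrum ({s.patient_id}, {s.replicate_id}) grid fingerprint "
                f"{grid_fingerprint(s.grid)} != {grid_fingerprint(ref)}"
            )
    index = pd.MultiIndex.from_tuples(
        [(s.patient_id, s.replicate_id) for s in spectra], names=["patient_id", "replicate_id"]
    )
    X = pd.DataFrame(np.vstack([s.values for s in spectra]), index=index,
                     columns=[f"wn_{w:.1f}" for w in ref])
    if X.isna().any().any():
        raise ValueError("feature matrix contains missing values")
    y = None
    if labels is not None:
        missing = sorted({pid for pid, _ in index} - set(labels))
        if missing:
            raise ValueError(f"no outcome label for patients: {missing}")
        y = pd.Series([bool(labels[pid]) for pid, _ in index], index=index, name="is_crc")
    return X, y


@dataclass
class ForestArtifact:
    model: RandomForestClassifier
    hyperparams: dict
    seed: int
    grid: np.ndarray
    feature_names: list[str]

    @property
    def grid_fingerprint(self) -> str:
        return grid_fingerprint(self.grid)


def train_forest(
    X: pd.DataFrame,
    y: pd.Series,
    hyperparams: Mapping | None = None,
    seed: int = 0,
    grid: np.ndarray | None = None,
) -> ForestArtifact:
    """Fit the random-forest ensemble on per-spectrum rows.  Reproducible
    given the seed; refuses single-class training sets."""
    if y.nunique() < 2:
        raise ValueError("training set contains a single class")
    hp = dict(DEFAULT_HYPERPARAMS)
    hp.update(hyperparams or {})
    clf = RandomForestClassifier(random_state=seed, n_jobs=1, **hp)
    clf.fit(X.to_numpy(), y.to_numpy().astype(int))
    if grid is None:
        try:
            grid = np.array([float(str(c).split("_", 1)[1]) for c in X.columns])
        except (IndexError, ValueError):
            grid = np.arange(X.shape[1], dtype=float)
    return ForestArtifact(model=clf, hyperparams=hp, seed=seed,
                          grid=np.asarray(grid, float), feature_names=list(X.columns))


@dataclass(frozen=True)
class PatientPrediction:
    patient_id: str
    probability: float
    label: str = field(init=False)

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError(f"probability {self.probability} outside [0, 1]")
        object.__setattr__(self, "label", "crc" if self.probability >= 0.5 else "non_cancer")


def aggregate_patient_probabilities(
    per_spectrum: Mapping[tuple[str, str], float] | pd.Series,
) -> list[PatientPrediction]:
    """Arithmetic mean of a patient's per-spectrum cancer probabilities;
    the boundary 0.5 classifies as 'crc'."""
    if isinstance(per_spectrum, pd.Series):
        items = list(per_spectrum.items())
    else:
        items = list(per_spectrum.items())
    by_pid: dict[str, list[float]] = {}
    for (pid, _rid), prob in items:
        by_pid.setdefault(pid, []).append(float(prob))
    return [
        PatientPrediction(pid, float(np.mean(probs)))
        for pid, probs in sorted(by_pid.items())
    ]


def predict_patients(
    artifact: ForestArtifact, spectra: Sequence[ProcessedSpectrum]
) -> list[PatientPrediction]:
    """One prediction per distinct patient.  Takes no diagnosis input —
    blinding is enforced by the signature."""
    if not spectra:
        return []
    fp = artifact.grid_fingerprint
    for s in spectra:
        if grid_fingerprint(s.grid) != fp:
            raise GridMismatchError(
                f"spectrum ({s.patient_id}, {s.replicate_id}) grid "
                f"{grid_fingerprint(s.grid)} does not match model grid {fp}"
            )
    X = np.vstack([s.values for s in spectra])
    probs = artifact.model.predict_proba(X)[:, list(artifact.model.classes_).index(1)]
    series = pd.Series(
        probs,
        index=pd.MultiIndex.from_tuples(
            [(s.patient_id, s.replicate_id) for s in spectra]
        ),
    )
    return aggregate_patient_probabilities(series)


# --- cross-validation --------------------------------------------------------

@dataclass
class FoldMetrics:
    repeat: int
    fold: int
    sensitivity: float | None
    specificity: float | None
    auc: float
    n_patients: int


@dataclass
class CvResult:
    folds: list[FoldMetrics]
    k: int
    repeats: int

    def _vals(self, attr: str) -> np.ndarray:
        return np.array([getattr(f, attr) for f in self.folds if getattr(f, attr) is not None])

    @property
    def mean_auc(self) -> float:
        return float(self._vals("auc").mean())

    @property
    def sd_auc(self) -> float:
        return float(self._vals("auc").std(ddof=1))

    @property
    def mean_sensitivity(self) -> float:
        return float(self._vals("sensitivity").mean())

    @property
    def mean_specificity(self) -> float:
        return float(self._vals("specificity").mean())

    @property
    def typical_fold(self) -> FoldMetrics:
        """The fold whose AUC is the median (lower median for even counts)."""
        ordered = sorted(self.folds, key=lambda f: f.auc)
        return ordered[(len(ordered) - 1) // 2]

    def summary(self) -> dict:
        return {
            "k": self.k,
            "repeats": self.repeats,
            "mean_auc": self.mean_auc,
            "sd_auc": self.sd_auc,
            "mean_sensitivity": self.mean_sensitivity,
            "mean_specificity": self.mean_specificity,
            "typical_fold_auc": self.typical_fold.auc,
        }


def cross_validate(
    X: pd.DataFrame,
    y: pd.Series,
    k: int = 5,
    repeats: int = 5,
    hyperparams: Mapping | None = None,
    seed: int = 0,
) -> CvResult:
    """Repeated k-fold cross-validation, stratified by class and grouped by
    patient.  Metrics (sensitivity/specificity at the 0.5 patient threshold,
    patient-level AUC) are computed after per-patient aggregation."""
    pids = X.index.get_level_values("patient_id")
    patient_label = y.groupby(level="patient_id").first()
    n_per_class = patient_label.value_counts()
    if n_per_class.min() < k:
        raise ValueError(
            f"need ≥ {k} patients per class for {k}-fold CV; got {dict(n_per_class)}"
        )
    folds: list[FoldMetrics] = []
    Xa = X.to_numpy()
    ya = y.to_numpy().astype(int)
    groups = pids.to_numpy()
    for rep in range(repeats):
        splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed + rep)
        for fold_i, (tr, te) in enumerate(splitter.split(Xa, ya, groups=groups)):
            assert not set(groups[tr]) & set(groups[te]), "patient leaked across folds"
            hp = dict(DEFAULT_HYPERPARAMS)
            hp.update(hyperparams or {})
            clf = RandomForestClassifier(random_state=seed + rep, n_jobs=1, **hp)
            clf.fit(Xa[tr], ya[tr])
            probs = clf.predict_proba(Xa[te])[:, list(clf.classes_).index(1)]
            series = pd.Series(probs, index=X.index[te])
            preds = aggregate_patient_probabilities(series)
            truth = {pid: bool(patient_label[pid]) for pid in set(groups[te])}
            tp = sum(1 for p in preds if truth[p.patient_id] and p.label == "crc")
            fn = sum(1 for p in preds if truth[p.patient_id] and p.label != "crc")
            tn = sum(1 for p in preds if not truth[p.patient_id] and p.label != "crc")
            fp_ = sum(1 for p in preds if not truth[p.patient_id] and p.label == "crc")
            sens = tp / (tp + fn) if (tp + fn) else None
            spec = tn / (tn + fp_) if (tn + fp_) else None
            auc = roc_auc([p.probability for p in preds], [truth[p.patient_id] for p in preds])
            folds.append(FoldMetrics(rep, fold_i, sens, spec, auc, len(preds)))
    return CvResult(folds=folds, k=k, repeats=repeats)
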