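"""Reading, writing and validation of spectra files and cohort tables.

All spectra travel as long-format CSV (columns ``wavenumber_cm1, intensity,
patient_id, replicate_id``), either one file per cohort (``spectra.csv``) or
one file per patient (``spectra_<patient_id>.csv``).  The cohort table is a
CSV with columns ``patient_id, age_years, sex, reference_test, diagnosis,
uicc_stage``.  Dialect is fixed: UTF-8, comma-separated, header required,
'.' decimal.  Wavenumbers are cm⁻¹ throughout.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SEXES = ("M", "F")
REFERENCE_TESTS = ("colonoscopy", "ct_colonography", "flexible_sigmoidoscopy", "none")
DIAGNOSES = ("crc", "non_crc", "other_cancer", "unknown")
STAGES = ("I", "II", "III", "IV", "none")

SPECTRA_COLUMNS = ["wavenumber_cm1", "intensity", "patient_id", "replicate_id"]
COHORT_COLUMNS = ["patient_id", "age_years", "sex", "reference_test", "diagnosis", "uicc_stage"]


class ValidationError(ValueError):
    """A file or bundle violated the documented schema."""


@dataclass(frozen=True)
class RawSpectrum:
    """One acquired spectrum: strictly increasing wavenumber axis + intensities."""

    patient_id: str
    replicate_id: str
    axis: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        axis = np.asarray(self.axis, dtype=float)
        intens = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "axis", axis)
        object.__setattr__(self, "intensities", intens)
        if axis.shape != intens.shape or axis.ndim != 1:
            raise ValidationError(
                f"spectrum ({self.patient_id}, {self.replicate_id}): axis and "
                f"intensities must be 1-D and equal length"
            )
        if not np.all(np.diff(axis) > 0):
            raise ValidationError(
                f"spectrum ({self.patient_id}, {self.replicate_id}): axis not strictly increasing"
            )
        if not np.all(np.isfinite(intens)):
            raise ValidationError(
                f"spectrum ({self.patient_id}, {self.replicate_id}): non-finite intensities"
            )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RawSpectrum):
            return NotImplemented
        return (
            self.patient_id == other.patient_id
            and self.replicate_id == other.replicate_id
            and np.array_equal(self.axis, other.axis)
            and np.array_equal(self.intensities, other.intensities)
        )


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    age: float
    sex: str
    reference_test: str
    diagnosis: str
    uicc_stage: str

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValidationError(f"patient {self.patient_id}: unknown sex {self.sex!r}")
        if self.reference_test not in REFERENCE_TESTS:
            raise ValidationError(
                f"patient {self.patient_id}: unknown reference_test {self.reference_test!r}"
            )
        if self.diagnosis not in DIAGNOSES:
            raise ValidationError(
                f"patient {self.patient_id}: unknown diagnosis {self.diagnosis!r}"
            )
        if self.uicc_stage not in STAGES:
            raise ValidationError(
                f"patient {self.patient_id}: unknown uicc_stage {self.uicc_stage!r}"
            )
        if self.uicc_stage != "none" and self.diagnosis != "crc":
            raise ValidationError(
                f"patient {self.patient_id}: uicc_stage {self.uicc_stage!r} with "
                f"non-CRC diagnosis {self.diagnosis!r}"
            )


@dataclass
class LoadReport:
    patients_read: int = 0
    spectra_read: int = 0
    warnings: list[str] = field(default_factory=list)


@dataclass
class CohortBundle:
    """Patients + spectra with a guaranteed patient↔spectrum linkage."""

    patients: list[PatientRecord]
    spectra: list[RawSpectrum]
    load_report: LoadReport = field(default_factory=LoadReport)

    def __post_init__(self) -> None:
        known = {p.patient_id for p in self.patients}
        if len(known) != len(self.patients):
            dupes = pd.Series([p.patient_id for p in self.patients])
            dupes = sorted(dupes[dupes.duplicated()].unique())
            raise ValidationError(f"duplicate patient ids: {dupes}")
        orphans = sorted({s.patient_id for s in self.spectra} - known)
        if orphans:
            raise ValidationError(f"spectra reference unknown patient ids: {orphans}")
        keys = [(s.patient_id, s.replicate_id) for s in self.spectra]
        if len(set(keys)) != len(keys):
            seen: set[tuple[str, str]] = set()
            dupes2 = sorted({k for k in keys if k in seen or seen.add(k)})
            raise ValidationError(f"duplicate (patient_id, replicate_id): {dupes2}")

    def spectra_for(self, patient_id: str) -> list[RawSpectrum]:
        return [s for s in self.spectra if s.patient_id == patient_id]

    def patient(self, patient_id: str) -> PatientRecord:
        for p in self.patients:
            if p.patient_id == patient_id:
                return p
        raise KeyError(patient_id)


def spectra_to_frame(spectra: Iterable[RawSpectrum]) -> pd.DataFrame:
    parts = [
        pd.DataFrame(
            {
                "wavenumber_cm1": s.axis,
                "intensity": s.intensities,
                "patient_id": s.patient_id,
                "replicate_id": s.replicate_id,
            }
        )
        for s in spectra
    ]
    if not parts:
        return pd.DataFrame(columns=SPECTRA_COLUMNS)
    return pd.concat(parts, ignore_index=True)[SPECTRA_COLUMNS]


def frame_to_spectra(frame: pd.DataFrame) -> list[RawSpectrum]:
    missing = [c for c in SPECTRA_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"spectra table missing columns: {missing}")
    out: list[RawSpectrum] = []
    for (pid, rid), grp in frame.groupby(["patient_id", "replicate_id"], sort=True):
        out.append(
            RawSpectrum(
                patient_id=str(pid),
                replicate_id=str(rid),
                axis=grp["wavenumber_cm1"].to_numpy(dtype=float),
                intensities=grp["intensity"].to_numpy(dtype=float),
            )
        )
    return out


def patients_to_frame(patients: Iterable[PatientRecord]) -> pd.DataFrame:
    rows = [
        {
            "patient_id": p.patient_id,
            "age_years": p.age,
            "sex": p.sex,
            "reference_test": p.reference_test,
            "diagnosis": p.diagnosis,
            "uicc_stage": p.uicc_stage,
        }
        for p in patients
    ]
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def frame_to_patients(frame: pd.DataFrame) -> list[PatientRecord]:
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"cohort table missing columns: {missing}")
    out: list[PatientRecord] = []
    for idx, row in frame.iterrows():
        try:
            out.append(
                PatientRecord(
                    patient_id=str(row["patient_id"]),
                    age=float(row["age_years"]),
                    sex=str(row["sex"]),
                    reference_test=str(row["reference_test"]),
                    diagnosis=str(row["diagnosis"]),
                    uicc_stage=str(row["uicc_stage"]),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"cohort row {idx}: {exc}") from exc
    return out


def write_cohort(bundle: CohortBundle, directory: str | Path) -> None:
    """Write a bundle as ``cohort.csv`` + ``spectra.csv`` in the documented dialect."""
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create fixture directory {directory}: {exc}") from exc
    patients_to_frame(bundle.patients).to_csv(directory / "cohort.csv", index=False)
    spectra_to_frame(bundle.spectra).to_csv(directory / "spectra.csv", index=False)


def read_cohort(directory_or_files: str | Path | Sequence[str | Path]) -> CohortBundle:
    """Read and validate a cohort from a directory (or explicit file list).

    Accepts either a single ``spectra.csv`` or multiple ``spectra_*.csv``
    per-patient files.  Returns a validated :class:`CohortBundle` with a
    :class:`LoadReport` recording counts and warnings.  Orphan spectra,
    non-monotone axes and unknown enum values are hard errors.
    """
    if isinstance(directory_or_files, (str, Path)):
        directory = Path(directory_or_files)
        if not directory.is_dir():
            raise FileNotFoundError(f"cohort directory not found: {directory}")
        cohort_files = [directory / "cohort.csv"]
        spectra_files = sorted(directory.glob("spectra*.csv"))
    else:
        paths = [Path(p) for p in directory_or_files]
        cohort_files = [p for p in paths if p.name == "cohort.csv"]
        spectra_files = [p for p in paths if p.name.startswith("spectra")]
    if not cohort_files or not cohort_files[0].exists():
        raise FileNotFoundError("cohort.csv not found")

    # round_trip parsing keeps write→read bit-exact for float columns
    patients = frame_to_patients(
        pd.read_csv(cohort_files[0], float_precision="round_trip")
    )
    report = LoadReport(patients_read=len(patients))

    frames = [
        pd.read_csv(p, float_precision="round_trip") for p in spectra_files if p.exists()
    ]
    frames = [f for f in frames if len(f)]
    if frames:
        spectra = frame_to_spectra(pd.concat(frames, ignore_index=True))
    else:
        spectra = []
        report.warnings.append("no spectra found for non-empty cohort table")
    report.spectra_read = len(spectra)
    return CohortBundle(patients=patients, spectra=spectra, load_report=report)


# --- diagnostic report output -------------------------------------------------

REPORT_FORMATS = ("json", "csv", "markdown")


def write_report(report, path: str | Path, format: str = "json") -> Path:
    """Serialise a DxReport.  JSON is lossless; markdown mirrors the two
    clinical tables (per-stratum sensitivity/specificity, stage breakdown);
    CSV holds one row per reference-standard stratum."""
    from .dxstats import DxReport  # local import: avoids a module cycle

    if format not in REPORT_FORMATS:
        raise ValueError(f"unknown report format {format!r}; choose from {REPORT_FORMATS}")
    if not isinstance(report, DxReport):
        raise TypeError("write_report expects a DxReport")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "json":
        path.write_text(json.dumps(report.to_dict(), indent=2) + "\n")
    elif format == "csv":
        report.to_stratum_frame().to_csv(path, index=False)
    else:
        path.write_text(report.to_markdown())
    return path
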