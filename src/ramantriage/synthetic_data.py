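"""Synthetic serum Raman cohorts with known ground truth.

The generator emulates the data a symptomatic-referral triage study would
collect: several hundred patients at low colorectal-cancer prevalence, a few
replicate spectra per patient, serum-like peaks on a broad fluorescence
background, detector noise, optional cosmic-ray spikes and axis
miscalibration.  Every parameter is a config field so tests can dial the
conditions they need; the defaults describe the study regime the package is
built around (532 patients, 29 cancers, stage mix 4/10/12/3, 300-patient
50:50 matched training sets).

Spectral content is a stylised model — Gaussian/Lorentzian bands at
serum-typical Raman shifts (phenylalanine 1004 cm⁻¹, amide I 1655 cm⁻¹,
carotenoids 1157/1518 cm⁻¹, ...).  Real serum spectra are not described
numerically anywhere public, so the peak library is a documented stand-in,
not a claim about serum.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .spectra_io import (
    CohortBundle,
    PatientRecord,
    RawSpectrum,
    ValidationError,
    patients_to_frame,
    read_cohort,
    spectra_to_frame,
    write_cohort,
)

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class PeakSpec:
    """One spectral band: centre/width in cm⁻¹ (width = FWHM), amplitude in counts."""

    center: float
    width: float
    amplitude: float
    shape: str = "gaussian"

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError(f"peak at {self.center}: width must be > 0")
        if self.amplitude < 0:
            raise ValueError(f"peak at {self.center}: amplitude must be ≥ 0")
        if self.shape not in ("gaussian", "lorentzian"):
            raise ValueError(f"peak at {self.center}: unknown shape {self.shape!r}")

    def profile(self, axis: np.ndarray) -> np.ndarray:
        d = axis - self.center
        if self.shape == "gaussian":
            sigma = self.width * _FWHM_TO_SIGMA
            return self.amplitude * np.exp(-0.5 * (d / sigma) ** 2)
        gamma = self.width / 2.0
        return self.amplitude * gamma**2 / (d**2 + gamma**2)


def default_peaks() -> list[PeakSpec]:
    """Serum-typical fingerprint bands (600–1800 cm⁻¹), amplitudes in counts."""
    return [
        PeakSpec(621.0, 14.0, 30.0),    # phenylalanine C–C twist
        PeakSpec(643.0, 14.0, 25.0),    # tyrosine
        PeakSpec(757.0, 16.0, 35.0),    # tryptophan
        PeakSpec(852.0, 18.0, 45.0),    # tyrosine ring breathing
        PeakSpec(1004.0, 10.0, 120.0),  # phenylalanine ring breathing
        PeakSpec(1157.0, 16.0, 60.0),   # carotenoid C–C stretch
        PeakSpec(1246.0, 30.0, 50.0),   # amide III
        PeakSpec(1336.0, 24.0, 55.0),   # CH deformation / nucleic acids
        PeakSpec(1450.0, 26.0, 90.0),   # CH₂ bending (lipids/proteins)
        PeakSpec(1518.0, 16.0, 50.0),   # carotenoid C=C stretch
        PeakSpec(1655.0, 36.0, 100.0),  # amide I
    ]


def default_effect_map() -> dict[float, float]:
    """Case-vs-control amplitude factors.

    Carotenoid depletion and raised nucleic-acid/amide-III signal are the
    directions reported for cancer sera; the magnitudes are calibrated so the
    default pipeline operates in the 0.8-class held-out AUC regime.
    """
    return {1157.0: 0.855, 1518.0: 0.840, 1336.0: 1.123, 1246.0: 1.083, 852.0: 0.914}


def scaled_effect_map(base: Mapping[float, float], scale: float) -> dict[float, float]:
    """Scale every factor's log-distance from 1 by ``scale`` (0 → no effect)."""
    return {c: float(np.exp(scale * np.log(f))) for c, f in base.items()}


_DEFAULT_STAGES = {"I": 4 / 29, "II": 10 / 29, "III": 12 / 29, "IV": 3 / 29}
# reference-test mix of a 532-patient referral cohort: 248 colonoscopy,
# 157 CT colonography, the rest excluded (flexi-sig or no reference test)
_DEFAULT_REFERENCE_MIX = {
    "colonoscopy": 248 / 532,
    "ct_colonography": 157 / 532,
    "flexible_sigmoidoscopy": 64 / 532,
    "none": 63 / 532,
}


@dataclass
class SimConfig:
    axis_range: tuple[float, float] = (600.0, 1800.0)
    points_per_spectrum: int = 601
    peaks: list[PeakSpec] = field(default_factory=default_peaks)
    effect_map: dict[float, float] = field(default_factory=default_effect_map)
    baseline_params: dict = field(default_factory=lambda: {"order": 3, "scale": 400.0})
    noise_sd: float = 4.0
    shot_noise: bool = False
    spike_rate: float = 0.0
    spike_amplitude: float = 800.0
    miscalibration: tuple[float, float] = (0.0, 1.0)  # (offset cm⁻¹, gain)
    replicates_per_patient: int = 3
    n_patients: int = 532
    prevalence: float = 29 / 532
    fixed_prevalence: bool = True
    stage_distribution: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_STAGES))
    reference_mix: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_REFERENCE_MIX))
    missing_diagnosis_rate: float = 0.0
    # biological variability: between-patient overall scale, per-peak patient
    # jitter, and per-replicate baseline scale jitter (all lognormal sd)
    patient_sigma: float = 0.08
    peak_sigma: float = 0.20
    baseline_jitter: float = 0.10
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.axis_range
        if not lo < hi:
            raise ValueError("axis_range lower bound must be < upper bound")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must be in (0, 1)")
        if self.replicates_per_patient < 1:
            raise ValueError("replicates_per_patient must be ≥ 1")
        total = sum(self.stage_distribution.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(
                f"stage_distribution must sum to 1 (got {total:.6f})"
            )
        if set(self.stage_distribution) != {"I", "II", "III", "IV"}:
            raise ValueError("stage_distribution must cover exactly stages I–IV")
        for p in self.peaks:
            if not lo <= p.center <= hi:
                raise ValueError(f"peak centre {p.center} outside axis range {self.axis_range}")

    # -- serialisation (JSON/YAML-friendly) ----------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["axis_range"] = list(self.axis_range)
        d["miscalibration"] = list(self.miscalibration)
        d["peaks"] = [dataclasses.asdict(p) for p in self.peaks]
        d["effect_map"] = {str(k): v for k, v in self.effect_map.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        d["axis_range"] = tuple(d.get("axis_range", (600.0, 1800.0)))
        d["miscalibration"] = tuple(d.get("miscalibration", (0.0, 1.0)))
        d["peaks"] = [PeakSpec(**p) for p in d.get("peaks", [])] or default_peaks()
        d["effect_map"] = {float(k): float(v) for k, v in d.get("effect_map", {}).items()}
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})


@dataclass(frozen=True)
class GroundTruth:
    patient_id: str
    is_crc: bool
    stage: str
    reference_test: str

    def __post_init__(self) -> None:
        if (self.stage == "none") == self.is_crc:
            raise ValueError(
                f"patient {self.patient_id}: stage must be none iff not CRC"
            )


def _axis(config: SimConfig) -> np.ndarray:
    lo, hi = config.axis_range
    return np.linspace(lo, hi, config.points_per_spectrum)


def _baseline(axis: np.ndarray, params: Mapping, rng: np.random.Generator) -> np.ndarray:
    """Broad fluorescence-like background: random nonnegative polynomial in
    normalised position, scaled to counts."""
    order = int(params.get("order", 3))
    scale = float(params.get("scale", 400.0))
    t = (axis - axis[0]) / (axis[-1] - axis[0])
    coeffs = rng.uniform(0.2, 1.0, size=order + 1) / (1.0 + np.arange(order + 1))
    # decreasing trend toward high wavenumber, as fluorescence typically decays
    return scale * np.polyval(coeffs[::-1], 1.0 - t)


def _assign_counts(n: int, fractions: Mapping[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment of n items over fractional targets."""
    keys = list(fractions)
    raw = np.array([fractions[k] for k in keys], dtype=float) * n
    base = np.floor(raw).astype(int)
    rem = n - int(base.sum())
    order = np.argsort(-(raw - base))
    for i in order[:rem]:
        base[i] += 1
    return dict(zip(keys, base.tolist()))


def simulate_cohort(
    config: SimConfig,
) -> tuple[list[RawSpectrum], list[PatientRecord], list[GroundTruth]]:
    """Draw a full cohort: spectra (replicates per patient), patient records
    and ground truth.  Deterministic for a fixed config (including seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients

    if config.fixed_prevalence:
        n_cases = int(round(n * config.prevalence))
    else:
        n_cases = int(rng.binomial(n, config.prevalence))
    case_flags = np.zeros(n, dtype=bool)
    case_flags[rng.choice(n, size=n_cases, replace=False)] = True

    stages = list(config.stage_distribution)
    stage_p = np.array([config.stage_distribution[s] for s in stages])

    # reference tests: cancers always get a definitive reference (colonoscopy
    # or CT colonography, proportional to their mix); flexi-sig / missing
    # references fall on non-cancer patients
    ref_counts = _assign_counts(n, config.reference_mix)
    case_def_mix = {
        "colonoscopy": config.reference_mix["colonoscopy"],
        "ct_colonography": config.reference_mix["ct_colonography"],
    }
    tot = sum(case_def_mix.values())
    case_def_mix = {k: v / tot for k, v in case_def_mix.items()}
    case_ref_counts = _assign_counts(n_cases, case_def_mix)

    refs = np.empty(n, dtype=object)
    case_idx = np.flatnonzero(case_flags)
    ctrl_idx = np.flatnonzero(~case_flags)
    pool = (
        ["colonoscopy"] * case_ref_counts["colonoscopy"]
        + ["ct_colonography"] * case_ref_counts["ct_colonography"]
    )
    refs[case_idx] = np.array(pool, dtype=object)[rng.permutation(n_cases)] if n_cases else []
    ctrl_pool = (
        ["colonoscopy"] * (ref_counts["colonoscopy"] - case_ref_counts["colonoscopy"])
        + ["ct_colonography"] * (ref_counts["ct_colonography"] - case_ref_counts["ct_colonography"])
        + ["flexible_sigmoidoscopy"] * ref_counts["flexible_sigmoidoscopy"]
        + ["none"] * ref_counts["none"]
    )
    refs[ctrl_idx] = np.array(ctrl_pool, dtype=object)[rng.permutation(len(ctrl_pool))]

    axis = _axis(config)
    width = len(str(max(n - 1, 1)))
    spectra: list[RawSpectrum] = []
    patients: list[PatientRecord] = []
    truths: list[GroundTruth] = []
    for i in range(n):
        pid = f"P{i:0{width}d}"
        is_crc = bool(case_flags[i])
        stage = stages[int(rng.choice(len(stages), p=stage_p))] if is_crc else "none"
        ref = str(refs[i])
        if is_crc:
            age = float(np.clip(rng.normal(72.0, 8.0), 50.0, 95.0))
            sex = "M" if rng.random() < 0.60 else "F"
            diagnosis = "crc"
        else:
            age = float(np.clip(rng.normal(68.0, 9.0), 50.0, 95.0))
            sex = "M" if rng.random() < 0.45 else "F"
            diagnosis = "non_crc" if ref != "none" else "unknown"
        if not is_crc and config.missing_diagnosis_rate > 0 and rng.random() < config.missing_diagnosis_rate:
            diagnosis = "unknown"
        patients.append(
            PatientRecord(pid, age, sex, ref, diagnosis, stage if is_crc else "none")
        )
        truths.append(GroundTruth(pid, is_crc, stage, ref))

        # patient-level amplitudes: overall serum scale × per-peak jitter × effect
        overall = float(np.exp(rng.normal(0.0, config.patient_sigma)))
        amps = []
        for p in config.peaks:
            a = p.amplitude * overall * float(np.exp(rng.normal(0.0, config.peak_sigma)))
            if is_crc:
                a *= config.effect_map.get(p.center, 1.0)
            amps.append(a)
        patient_peaks = [
            dataclasses.replace(p, amplitude=a) for p, a in zip(config.peaks, amps)
        ]
        for r in range(config.replicates_per_patient):
            signal = np.zeros_like(axis)
            for p in patient_peaks:
                signal += p.profile(axis)
            bscale = float(np.exp(rng.normal(0.0, config.baseline_jitter)))
            baseline = _baseline(axis, config.baseline_params, rng) * bscale
            y = signal + baseline
            if config.shot_noise:
                y = y + rng.normal(0.0, np.sqrt(np.clip(y, 0.0, None)))
            y = y + rng.normal(0.0, config.noise_sd, size=axis.shape)
            spectrum = RawSpectrum(pid, f"r{r}", axis.copy(), y)
            if config.spike_rate > 0 or config.miscalibration != (0.0, 1.0):
                spectrum = inject_artifacts(spectrum, config, rng=rng)
            spectra.append(spectrum)
    return spectra, patients, truths


def inject_artifacts(
    spectrum: RawSpectrum,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> RawSpectrum:
    """Apply cosmic-ray spikes (Poisson count, isolated single-point positive
    excursions) and an affine axis miscalibration ``axis' = gain·axis + offset``."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    y = spectrum.intensities.copy()
    if config.spike_rate > 0:
        k = int(rng.poisson(config.spike_rate))
        if k:
            pos = rng.choice(len(y), size=min(k, len(y)), replace=False)
            y[pos] += config.spike_amplitude * rng.uniform(0.5, 1.5, size=len(pos))
    offset, gain = config.miscalibration
    axis = gain * spectrum.axis + offset
    return RawSpectrum(spectrum.patient_id, spectrum.replicate_id, axis, y)


def training_config(
    n_patients: int = 300,
    replicates_per_patient: int = 3,
    seed: int = 0,
    **overrides,
) -> SimConfig:
    """Config for a matched-training-style cohort: 50:50 cases/controls,
    all with definitive reference tests."""
    cfg = SimConfig(
        n_patients=n_patients,
        prevalence=0.5,
        fixed_prevalence=True,
        replicates_per_patient=replicates_per_patient,
        reference_mix={
            "colonoscopy": 0.7,
            "ct_colonography": 0.3,
            "flexible_sigmoidoscopy": 0.0,
            "none": 0.0,
        },
        seed=seed,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


# --- fixtures on disk ---------------------------------------------------------

def truths_to_frame(truths):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "patient_id": t.patient_id,
                "is_crc": t.is_crc,
                "stage": t.stage,
                "reference_test": t.reference_test,
            }
            for t in truths
        ],
        columns=["patient_id", "is_crc", "stage", "reference_test"],
    )


def write_fixture(
    cohort: tuple[list[RawSpectrum], list[PatientRecord], list[GroundTruth]],
    directory: str | Path,
    config: SimConfig | None = None,
) -> Path:
    """Persist a simulated cohort (spectra.csv, cohort.csv, ground_truth.csv,
    config.json) so it round-trips bit-exactly through :mod:`spectra_io`."""
    spectra, patients, truths = cohort
    directory = Path(directory)
    write_cohort(CohortBundle(patients=patients, spectra=spectra), directory)
    truths_to_frame(truths).to_csv(directory / "ground_truth.csv", index=False)
    if config is not None:
        (directory / "config.json").write_text(json.dumps(config.to_dict(), indent=2) + "\n")
    return directory


def read_ground_truth(directory: str | Path) -> list[GroundTruth]:
    import pandas as pd

    frame = pd.read_csv(Path(directory) / "ground_truth.csv")
    return [
        GroundTruth(str(r.patient_id), bool(r.is_crc), str(r.stage), str(r.reference_test))
        for r in frame.itertuples()
    ]
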