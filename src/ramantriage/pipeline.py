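"""End-to-end study runs: simulate/load → preprocess → match → train →
blind-predict → evaluate.

A run mirrors the two-cohort design of a triage-test evaluation: a
retrospective case–control cohort is propensity-matched (age, sex) into a
50:50 training set for the random forest; a prospective symptomatic cohort
is then exclusion-filtered, predicted blind (the prediction stage never
sees a diagnosis), and scored per reference-standard stratum with exact
binomial confidence intervals.

One top-level seed is fanned out deterministically to the stages, so a
single integer reproduces a whole study bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from . import cohort as cohort_mod
from . import dxstats
from .model import build_feature_matrix, cross_validate, predict_patients, train_forest
from .preprocess import PreprocessConfig, run_preprocessing
from .spectra_io import CohortBundle, read_cohort, write_report
from .synthetic_data import (
    GroundTruth,
    SimConfig,
    read_ground_truth,
    simulate_cohort,
    training_config,
)


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    # exactly one source per cohort: a simulation config XOR a fixture directory
    train_sim: SimConfig | None = None
    eval_sim: SimConfig | None = None
    train_dir: str | None = None
    eval_dir: str | None = None
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    hyperparams: dict = field(default_factory=dict)
    caliper: float | None = 0.2
    cv_k: int = 5
    cv_repeats: int = 5
    run_cv: bool = False
    level: float = 0.95
    out_dir: str | None = None
    seed: int = 0

    def validate(self) -> None:
        for name, sim, d in (("train", self.train_sim, self.train_dir),
                             ("eval", self.eval_sim, self.eval_dir)):
            if (sim is None) == (d is None):
                raise ConfigError(
                    f"{name} cohort needs exactly one data source "
                    f"(simulation config XOR fixture directory)"
                )

    @classmethod
    def default_synthetic(cls, seed: int = 0, **overrides) -> "RunConfig":
        """The standard synthetic study: 300-patient 50:50 matched training
        pool, 532-patient prospective cohort at 5% prevalence."""
        cfg = cls(
            train_sim=training_config(n_patients=360, seed=seed),
            eval_sim=SimConfig(seed=seed + 1),
            seed=seed,
        )
        cfg.train_sim.prevalence = 150 / 360  # pool: 150 cases, 210 controls
        for k, v in overrides.items():
            setattr(cfg, k, v)
        return cfg


@dataclass
class StudyResult:
    report: dxstats.DxReport
    cv_summary: dict | None
    match_pairs: int
    log: list[dict]


def _load(sim: SimConfig | None, directory: str | None):
    if sim is not None:
        spectra, patients, truths = simulate_cohort(sim)
        return CohortBundle(patients=patients, spectra=spectra), truths
    bundle = read_cohort(directory)
    truths_path = Path(directory) / "ground_truth.csv"
    truths = read_ground_truth(directory) if truths_path.exists() else None
    return bundle, truths


def run_study(config: RunConfig) -> StudyResult:
    config.validate()
    log: list[dict] = []
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    def stage(name: str, **info):
        log.append({"stage": name, **info})
        if out:
            with open(out / "log.jsonl", "a") as fh:
                fh.write(json.dumps(log[-1]) + "\n")

    # --- training cohort: match, preprocess, fit -----------------------------
    train_bundle, train_truths = _load(config.train_sim, config.train_dir)
    if train_truths is None:
        raise ConfigError("training cohort requires ground truth (outcome labels)")
    truth_by_pid = {t.patient_id: t for t in train_truths}
    stage("load_train", patients=len(train_bundle.patients), spectra=len(train_bundle.spectra))

    cases = [p for p in train_bundle.patients if truth_by_pid[p.patient_id].is_crc]
    controls = [p for p in train_bundle.patients if not truth_by_pid[p.patient_id].is_crc]
    match = cohort_mod.propensity_match(cases, controls, caliper=config.caliper)
    matched_ids = {c for c, _ in match.pairs} | {k for _, k in match.pairs}
    stage("match", cases=len(cases), controls=len(controls), pairs=len(match.pairs))

    train_spectra = [s for s in train_bundle.spectra if s.patient_id in matched_ids]
    processed_train = run_preprocessing(
        CohortBundle(
            patients=[p for p in train_bundle.patients if p.patient_id in matched_ids],
            spectra=train_spectra,
        ),
        config.preprocess,
    )
    labels = {pid: truth_by_pid[pid].is_crc for pid in matched_ids}
    X, y = build_feature_matrix(processed_train, labels)
    stage("preprocess_train", spectra=len(processed_train))

    cv_summary = None
    if config.run_cv:
        cv = cross_validate(X, y, k=config.cv_k, repeats=config.cv_repeats,
                            hyperparams=config.hyperparams, seed=config.seed + 2)
        cv_summary = cv.summary()
        stage("cross_validate", **cv_summary)

    artifact = train_forest(X, y, hyperparams=config.hyperparams, seed=config.seed + 3)
    stage("train", n_spectra=len(X), n_patients=len(matched_ids))

    # --- prospective cohort: exclude, blind-predict, evaluate ----------------
    eval_bundle, eval_truths = _load(config.eval_sim, config.eval_dir)
    stage("load_eval", patients=len(eval_bundle.patients), spectra=len(eval_bundle.spectra))

    retained, excl = cohort_mod.apply_exclusions(eval_bundle.patients)
    strata_patients = cohort_mod.stratify_by_reference(retained)
    retained_ids = {p.patient_id for p in retained}
    stage("exclusions", **excl.to_dict())

    eval_spectra = [s for s in eval_bundle.spectra if s.patient_id in retained_ids]
    processed_eval = run_preprocessing(
        CohortBundle(patients=retained, spectra=eval_spectra), config.preprocess
    )
    predictions = predict_patients(artifact, processed_eval)  # no diagnosis in sight
    stage("predict", patients=len(predictions))

    truths_for_stage = None
    if eval_truths is not None:
        truths_for_stage = [t for t in eval_truths if t.patient_id in retained_ids]
    report = dxstats.build_report(
        predictions,
        retained,
        {name: [p.patient_id for p in pts] for name, pts in strata_patients.items()},
        truths=truths_for_stage,
        level=config.level,
        exclusion_report=excl.to_dict(),
    )
    stage("evaluate", strata={k: len(v) for k, v in strata_patients.items()})

    if out:
        write_report(report, out / "report.json", "json")
        write_report(report, out / "report.md", "markdown")
        write_report(report, out / "report.csv", "csv")
        resolved = {
            "seed": config.seed,
            "train_sim": config.train_sim.to_dict() if config.train_sim else config.train_dir,
            "eval_sim": config.eval_sim.to_dict() if config.eval_sim else config.eval_dir,
            "preprocess": dataclasses.asdict(config.preprocess),
            "hyperparams": artifact.hyperparams,
            "caliper": config.caliper,
            "cv": {"k": config.cv_k, "repeats": config.cv_repeats, "ran": config.run_cv},
            "level": config.level,
        }
        (out / "resolved_config.json").write_text(json.dumps(resolved, indent=2) + "\n")
        import pandas as pd

        pd.DataFrame(
            [{"patient_id": p.patient_id, "probability": p.probability, "label": p.label}
             for p in predictions]
        ).to_csv(out / "predictions.csv", index=False)

    return StudyResult(report=report, cv_summary=cv_summary,
                       match_pairs=len(match.pairs), log=log)
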