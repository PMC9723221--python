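"""End-to-end orchestration: generate/read -> preprocess -> select -> fit ->
evaluate -> stratify, as one reproducible run.

A single master seed deterministically derives every stage seed, so a run is
fully reproducible from its config file; the manifest written next to the
artifacts records the config hash, the derived seeds and library versions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError
from .evaluation import EvalConfig, cross_validated_predictions, evaluate_model
from .model import PUBLISHED_PREDICTORS
from .preprocess import (
    OUTCOME_COL,
    EpvRule,
    OutcomeRule,
    add_outcome,
    epv_screen,
    impute,
    transform_predictors,
)
from .selection import SelectionConfig, bootstrap_consensus, fit_final
from .stratification import build_report, select_thresholds
from .synthetic import GeneratorConfig, generate_cohort, read_cohort, write_cohort

__all__ = ["RunConfig", "run_pipeline", "default_candidates"]


@dataclass
class RunConfig:
    """One reproducible pipeline run.

    ``cohort_path=None`` generates a synthetic cohort instead of reading
    one. Subgroup switches mirror the robustness re-analyses: restrict to
    under-fives, or count admissions of any duration as positive.
    """

    master_seed: int = 0
    cohort_path: str | None = None
    n_patients: int = 1612
    target_event_rate: float = 0.226
    noise_predictor_count: int = 0
    n_bootstrap: int = 2000
    inclusion_threshold: float = 0.80
    min_events: int = 10
    n_folds: int = 10
    n_bootstrap_metrics: int = 2000
    n_bootstrap_calibration: int = 1000
    target_sensitivity: float = 0.90
    target_specificity: float = 0.90
    under5_only: bool = False
    all_admissions: bool = False
    extra_candidates: list[str] = field(default_factory=list)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - fields
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        canon = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def stage_seeds(self) -> dict[str, int]:
        ss = np.random.SeedSequence(self.master_seed)
        names = ("generator", "selection", "evaluation", "stratification")
        return {
            name: int(child.generate_state(1)[0] % (2**31))
            for name, child in zip(names, ss.spawn(len(names)))
        }


def default_candidates(cohort: pd.DataFrame, extra: list[str] = ()) -> list[str]:
    """Candidate predictors: the nine model terms (transformed names),
    respiratory rate, any ``noise_k`` decoys, plus configured extras."""
    cands = list(PUBLISHED_PREDICTORS) + ["respiratory_rate_bpm"]
    cands += [c for c in cohort.columns if c.startswith("noise_")]
    cands += [c for c in extra if c in cohort.columns]
    return [c for c in cands if c in cohort.columns]


def run_pipeline(config: RunConfig, output_dir) -> dict:
    """Execute every stage and write the artifact set to ``output_dir``.

    Artifacts: cohort.csv (when generated), exclusions.csv, selection.csv,
    model.json, evaluation.json, stratification.json, stratification.txt,
    manifest.json, log.txt. Returns a dict with the in-memory results.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = config.stage_seeds()
    log: list[str] = [f"config hash {config.config_hash()}"]

    if config.cohort_path is None:
        gen = GeneratorConfig(
            n_patients=config.n_patients,
            seed=seeds["generator"],
            target_event_rate=config.target_event_rate,
            noise_predictor_count=config.noise_predictor_count,
        )
        cohort = generate_cohort(gen)
        write_cohort(cohort, out / "cohort.csv")
        log.append(f"generated cohort n={len(cohort)} seed={seeds['generator']}")
    else:
        cohort = read_cohort(config.cohort_path)
        log.append(f"read cohort n={len(cohort)} from {config.cohort_path}")

    if config.under5_only:
        cohort = cohort[cohort["age_months"] < 60].reset_index(drop=True)
        log.append(f"under-5 subgroup: n={len(cohort)}")

    rule = OutcomeRule(count_all_admissions=config.all_admissions)
    cohort = add_outcome(cohort, rule)
    log.append(
        f"outcome positives: {int(cohort[OUTCOME_COL].sum())}/{len(cohort)}"
        + (" (all admissions counted)" if config.all_admissions else "")
    )
    cohort = impute(cohort)
    cohort = transform_predictors(cohort)

    candidates = default_candidates(cohort, config.extra_candidates)
    kept, exclusions = epv_screen(cohort, candidates, EpvRule(config.min_events))
    exclusions.to_csv(out / "exclusions.csv", index=False)
    for _, r in exclusions[~exclusions["kept"]].iterrows():
        log.append(f"EPV screen dropped {r['predictor']} (events={r['event_count']})")

    sel_cfg = SelectionConfig(
        n_bootstrap=config.n_bootstrap,
        inclusion_threshold=config.inclusion_threshold,
        seed=seeds["selection"],
    )
    selection = bootstrap_consensus(cohort, kept, sel_cfg)
    selection.to_frame().to_csv(out / "selection.csv", index=False)
    log.append(
        f"bootstrap consensus: {len(selection.consensus_set)} predictors from "
        f"{selection.n_converged_replicates} converged replicates "
        f"({selection.n_skipped_replicates} skipped)"
    )

    model = fit_final(cohort, selection.consensus_set)
    model.to_json(out / "model.json")
    if model.notes:
        log.append(f"final fit: {model.notes}")

    eval_cfg = EvalConfig(
        n_folds=config.n_folds,
        n_bootstrap_metrics=config.n_bootstrap_metrics,
        n_bootstrap_calibration=config.n_bootstrap_calibration,
        seed=seeds["evaluation"],
    )
    oof = cross_validated_predictions(cohort, model.predictors, eval_cfg)
    thresholds = select_thresholds(
        oof,
        cohort[OUTCOME_COL],
        config.target_sensitivity,
        config.target_specificity,
    )
    report = evaluate_model(
        cohort,
        model.predictors,
        eval_cfg,
        thresholds=(thresholds.low, thresholds.high),
    )
    (out / "evaluation.json").write_text(json.dumps(report, indent=2) + "\n")
    log.append(f"pooled CV AUROC: {report['pooled_auroc']['point']:.3f}")

    strat = build_report(
        cohort,
        oof,
        thresholds,
        n_bootstrap_ci=max(min(config.n_bootstrap_metrics, 500), 100),
        seed=seeds["stratification"],
    )
    (out / "stratification.json").write_text(
        json.dumps(strat.to_dict(), indent=2) + "\n"
    )
    (out / "stratification.txt").write_text(strat.to_text() + "\n")
    log.append(
        f"thresholds: low={thresholds.low:.4f} high={thresholds.high:.4f}"
        + (" (degenerate)" if thresholds.degenerate else "")
    )

    manifest = {
        "config": dataclasses.asdict(config),
        "config_hash": config.config_hash(),
        "stage_seeds": seeds,
        "versions": {
            "pedtriage": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "artifacts": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    (out / "log.txt").write_text("\n".join(log) + "\n")

    return {
        "cohort": cohort,
        "selection": selection,
        "model": model,
        "evaluation": report,
        "oof_risks": oof,
        "thresholds": thresholds,
        "stratification": strat,
        "log": log,
    }
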