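"""End-to-end orchestration: cohort report and meta report.

The cohort report composes the stages in the order the analysis runs:
trial exclusion -> dyad scoring -> bias indices -> error-rate check ->
symptom normalization -> imbalance/TAB correlation -> stepwise regressions ->
multicollinearity and nonparametric robustness -> per-patient bimodality ->
iterated peak-distance/symptom-sum correlation -> augmented-avoidance
sensitivity re-run.  Reports are plain JSON-serializable dicts, fully
determined by (inputs, config, seed); no timestamps are embedded, so the
same inputs reproduce byte-identical files.

Sign orientations.  Dyad biases and the toward/away indices use the
configured ``bias_sign`` convention (default toward-positive: bias =
RT_neutral - RT_angry).  The imbalance-TAB correlation is computed, by
default, on the literal angry-minus-neutral orientation
(``imbalance_tab_orientation = "literal"``): with imbalance defined as
avoidance minus re-experiencing, that is the orientation under which
avoidance-dominated patients (slow threat detection) produce a positive
correlation; set ``"convention"`` to correlate against the toward-positive
TAB instead (the model then predicts a negative r).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import yaml

from . import bcfs_scoring, bimodality, meta_harmonize, symptom_scores
from .association_stats import (
    CorrelationResult,
    multicollinearity_check,
    needs_nonparametric,
    pearson_one_tailed,
    spearman_check,
    stepwise_regress,
)
from .errors import ValidationError

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1.0"


@dataclass(frozen=True)
class PipelineConfig:
    """Fixed constants of the analysis; defaults follow the method's stated
    values (5 SD exclusion, delta-AIC threshold 2, 100 k-means iterations,
    one-tailed correlation tests)."""

    bias_sign: str = "toward_positive"
    imbalance_tab_orientation: str = "literal"  # "literal" | "convention"
    exclusion_sd_multiplier: float = 5.0
    gmm_restarts: int = 20
    gmm_tol: float = 1e-6
    gmm_max_iter: int = 500
    delta_aic_threshold: float = 2.0
    kmeans_iterations: int = 100
    p_enter: float = 0.05
    p_remove: float = 0.10
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.bias_sign not in bcfs_scoring.SIGN_CONVENTIONS:
            raise ValidationError(
                f"bias_sign must be one of {bcfs_scoring.SIGN_CONVENTIONS}"
            )
        if self.imbalance_tab_orientation not in ("literal", "convention"):
            raise ValidationError(
                "imbalance_tab_orientation must be 'literal' or 'convention'"
            )

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update(overrides)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _corr_dict(res: CorrelationResult) -> dict:
    return {
        "r": res.r,
        "p_one_tailed": res.p_one_tailed,
        "n": res.n,
        "direction": res.direction,
        "method": res.method,
    }


def _corr_with_robustness(x, y, direction: str = "positive") -> dict:
    block = {"pearson": _corr_dict(pearson_one_tailed(x, y, direction))}
    flagged = needs_nonparametric(x) or needs_nonparametric(y)
    block["has_outliers_beyond_2sd"] = bool(flagged)
    if flagged:
        block["spearman"] = _corr_dict(spearman_check(x, y, direction))
    return block


def _stepwise_dict(res) -> dict:
    return {
        "selected": list(res.selected),
        "coefficients": {
            name: {"beta": b, "p": p, "selected": sel}
            for name, (b, p, sel) in res.coefficients.items()
        },
        "r_squared": res.r_squared,
        "df": list(res.df) if res.df else None,
        "model_p": res.model_p,
        "p_enter": res.p_enter,
        "p_remove": res.p_remove,
    }


def _stepwise_block(y_by_subject: dict, predictors: dict, config: PipelineConfig) -> dict:
    """Stepwise regression over subjects that have the outcome defined."""
    subjects = [s for s, v in y_by_subject.items() if v is not None]
    dropped = sorted(set(y_by_subject) - set(subjects))
    y = [y_by_subject[s] for s in subjects]
    cands = {name: [vals[s] for s in subjects] for name, vals in predictors.items()}
    try:
        res = stepwise_regress(y, cands, config.p_enter, config.p_remove)
    except ValidationError as exc:
        return {"error": str(exc), "n_subjects": len(subjects), "dropped_subjects": dropped}
    block = _stepwise_dict(res)
    block["n_subjects"] = len(subjects)
    block["dropped_subjects"] = dropped
    return block


def run_experiment_pipeline(
    trials: Union[str, Sequence[bcfs_scoring.TrialRecord]],
    symptoms: Union[str, Sequence[symptom_scores.SymptomProfile]],
    config: Optional[PipelineConfig] = None,
) -> dict:
    """Full per-cohort analysis; returns a JSON-serializable report."""
    config = config or PipelineConfig()
    if isinstance(trials, (str, os.PathLike)):
        trials = bcfs_scoring.read_trial_table(trials)
    else:
        trials = list(trials)
    if isinstance(symptoms, (str, os.PathLike)):
        symptoms = symptom_scores.read_symptom_table(symptoms)
    else:
        symptoms = list(symptoms)

    profile_by_subject = {p.subject_id: p for p in symptoms}
    trial_subjects = sorted({t.subject_id for t in trials})
    missing = [s for s in trial_subjects if s not in profile_by_subject]
    if missing:
        raise ValidationError(f"symptom table missing subjects present in trials: {missing}")

    master = np.random.SeedSequence(config.seed)
    bimod_seeds = {
        s: int(child.generate_state(1)[0] % (2**31))
        for s, child in zip(trial_subjects, master.spawn(len(trial_subjects)))
    }
    distance_seed = int(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(999,)).generate_state(1)[0]
        % (2**31)
    )

    # --- per-subject scoring and bimodality ------------------------------
    per_subject: dict[str, dict] = {}
    summaries: dict[str, bcfs_scoring.BiasSummary] = {}
    samples: dict[str, bimodality.RTSample] = {}
    for subject in trial_subjects:
        sub_trials = [t for t in trials if t.subject_id == subject]
        summary, dyads, report = bcfs_scoring.score_subject(
            sub_trials, config.exclusion_sd_multiplier, config.bias_sign
        )
        kept, _ = bcfs_scoring.exclude_trials(sub_trials, config.exclusion_sd_multiplier)
        sample = bimodality.normalize_conditions(
            [t.rt for t in kept], [t.expression for t in kept], subject_id=subject
        )
        bres, fit1, fit2 = bimodality.analyze_subject(
            sample,
            seed=bimod_seeds[subject],
            n_restarts=config.gmm_restarts,
            tol=config.gmm_tol,
            max_iter=config.gmm_max_iter,
            threshold=config.delta_aic_threshold,
        )
        summaries[subject] = summary
        samples[subject] = sample
        per_subject[subject] = {
            "bias": {
                k: v for k, v in summary.__dict__.items() if k != "subject_id"
            },
            "bimodality": {
                "delta_aic": bres.delta_aic,
                "preferred": bres.preferred,
                "centers_ms": list(bres.centers),
                "peak_distance_ms": bres.peak_distance,
                "aic_k1": fit1.aic,
                "aic_k2": fit2.aic,
                "seed": bimod_seeds[subject],
            },
        }

    # --- symptom normalization ------------------------------------------
    norms = {s: symptom_scores.symptom_imbalance(profile_by_subject[s]) for s in trial_subjects}
    hyper = {s: symptom_scores.hypervigilance_norm(profile_by_subject[s]) for s in trial_subjects}
    imbalance = {s: norms[s].imbalance for s in trial_subjects}
    symptom_sum = {s: norms[s].symptom_sum for s in trial_subjects}
    re_norm = {s: norms[s].re_norm for s in trial_subjects}
    avoid_norm = {s: norms[s].avoid_norm for s in trial_subjects}

    # --- cohort-level statistics ----------------------------------------
    tab_toward = {
        s: (summaries[s].tab if config.bias_sign == "toward_positive" else -summaries[s].tab)
        for s in trial_subjects
    }
    tab_literal = {s: -v for s, v in tab_toward.items()}
    tab_for_corr = tab_literal if config.imbalance_tab_orientation == "literal" else tab_toward

    imb_vec = [imbalance[s] for s in trial_subjects]
    tab_vec = [tab_for_corr[s] for s in trial_subjects]

    err_t, err_df, err_p = bcfs_scoring.compare_error_rates(
        bcfs_scoring.trials_to_frame(trials)
    )

    predictors = {"re_experiencing": re_norm, "avoidance": avoid_norm, "hypervigilance": hyper}
    pred_vectors = {
        name: [vals[s] for s in trial_subjects] for name, vals in predictors.items()
    }
    r_frame, p_frame = multicollinearity_check(pred_vectors)

    distance = bimodality.distance_symptom_correlation(
        [samples[s] for s in trial_subjects],
        [symptom_sum[s] for s in trial_subjects],
        n_iterations=config.kmeans_iterations,
        seed=distance_seed,
    )

    report_dict: dict = {
        "schema_version": SCHEMA_VERSION,
        "config": config.to_dict(),
        "n_subjects": len(trial_subjects),
        "per_subject": per_subject,
        "error_rate_comparison": {"t": err_t, "df": err_df, "p_two_tailed": err_p},
        "tab_imbalance": {
            "orientation": config.imbalance_tab_orientation,
            **_corr_with_robustness(imb_vec, tab_vec, "positive"),
        },
        "stepwise": {
            "ab_toward": _stepwise_block(
                {s: summaries[s].ab_toward for s in trial_subjects}, predictors, config
            ),
            "ab_away": _stepwise_block(
                {s: summaries[s].ab_away for s in trial_subjects}, predictors, config
            ),
            "sd_toward": _stepwise_block(
                {s: summaries[s].sd_toward for s in trial_subjects}, predictors, config
            ),
            "sd_away": _stepwise_block(
                {s: summaries[s].sd_away for s in trial_subjects}, predictors, config
            ),
        },
        "multicollinearity": {
            "r": {a: {b: float(r_frame.loc[a, b]) for b in r_frame.columns} for a in r_frame.index},
            "p_two_tailed": {
                a: {b: float(p_frame.loc[a, b]) for b in p_frame.columns} for a in p_frame.index
            },
        },
        "distance_symptom_correlation": {
            "n_iterations": distance.n_iterations,
            "mean_r": distance.mean_r,
            "r_range": list(distance.r_range),
            "mean_p": distance.mean_p,
            "p_range": list(distance.p_range),
            "seed": distance_seed,
        },
        "pct_toward": {
            "mean": float(
                np.mean([summaries[s].pct_toward for s in trial_subjects
                         if summaries[s].pct_toward is not None])
            ),
            "range": [
                float(min(summaries[s].pct_toward for s in trial_subjects
                          if summaries[s].pct_toward is not None)),
                float(max(summaries[s].pct_toward for s in trial_subjects
                          if summaries[s].pct_toward is not None)),
            ],
        },
    }

    # --- augmented-avoidance sensitivity re-run -------------------------
    try:
        aug = {
            s: symptom_scores.augmented_avoidance(profile_by_subject[s])
            for s in trial_subjects
        }
    except ValidationError as exc:
        report_dict["augmented_avoidance"] = {"skipped": str(exc)}
    else:
        aug_imb = [aug[s].imbalance for s in trial_subjects]
        aug_predictors = dict(predictors)
        aug_predictors["avoidance"] = {s: aug[s].avoid_norm for s in trial_subjects}
        report_dict["augmented_avoidance"] = {
            "tab_imbalance": _corr_with_robustness(aug_imb, tab_vec, "positive"),
            "stepwise_ab_away": _stepwise_block(
                {s: summaries[s].ab_away for s in trial_subjects}, aug_predictors, config
            ),
            "stepwise_ab_toward": _stepwise_block(
                {s: summaries[s].ab_toward for s in trial_subjects}, aug_predictors, config
            ),
        }

    n_tests = 3 + 4 + 1 + 1  # correlations + stepwise blocks + error rate + distance
    report_dict["n_statistical_tests_flagged"] = n_tests
    return report_dict


def run_meta_pipeline(
    records: Union[str, Sequence[meta_harmonize.StudyRecord]],
    config: Optional[PipelineConfig] = None,
) -> dict:
    """Meta-analysis report per outcome kind present in the table."""
    config = config or PipelineConfig()
    if isinstance(records, (str, os.PathLike)):
        records = meta_harmonize.read_meta_table(records)
    else:
        records = list(records)
    if not records:
        raise ValidationError("meta table contains no records")

    report: dict = {"schema_version": SCHEMA_VERSION, "config": config.to_dict()}

    def block(kind: str, ptsd_only: bool) -> Optional[dict]:
        try:
            res = meta_harmonize.run_meta(records, kind, ptsd_only=ptsd_only)
        except ValidationError:
            return None
        return {
            "n_populations": res.n_populations,
            "imbalances": list(res.imbalances),
            "outcomes": list(res.outcomes),
            "correlation": _corr_dict(res.correlation),
        }

    behavioral = block("tab_ms", ptsd_only=False)
    if behavioral is not None:
        report["behavioral"] = behavioral
        ptsd = block("tab_ms", ptsd_only=True)
        if ptsd is not None:
            report["behavioral_ptsd_only"] = ptsd
    for kind, name in (("amygdala_left", "imaging_left"), ("amygdala_right", "imaging_right")):
        b = block(kind, ptsd_only=False)
        if b is not None:
            report[name] = b
    if len(report) == 2:  # only schema + config
        raise ValidationError("no outcome kind had >= 3 records")
    return report


def write_report(report: dict, path) -> None:
    """Deterministic JSON serialization (sorted keys, no timestamps)."""
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
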