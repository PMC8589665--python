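"""Study-level meta-analysis: harmonized symptom imbalance vs. behavioral or
amygdala outcomes.

Each record holds one participant population's mean symptom-cluster scores
(with the instrument bounds needed for normalization) and one outcome: a
dot-probe traditional attentional bias (TAB, ms) or an amygdala BOLD response
(z-score; reported t statistics are converted via probability matching,
z = Phi^-1(F_t(t; df))).  Left- and right-amygdala outcomes are analyzed
separately.  The meta statistic is the unweighted one-tailed Pearson
correlation (positive direction) between population symptom imbalance and
the harmonized outcome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .association_stats import CorrelationResult, pearson_one_tailed
from .errors import ValidationError
from .symptom_scores import SymptomProfile, SymptomScale, symptom_imbalance

OUTCOME_KINDS = ("tab_ms", "amygdala_left", "amygdala_right")
Z_CLAMP = 8.0


@dataclass(frozen=True)
class StudyRecord:
    study_id: str
    population_id: str
    n: int
    is_ptsd_diagnosed: bool
    profile: SymptomProfile  # population-mean cluster scores + bounds
    outcome_kind: str
    outcome_value: float
    raw_stat_kind: str = "z"  # "z" | "t"; meaningful for imaging outcomes
    t_df: Optional[float] = None

    def __post_init__(self) -> None:
        if self.outcome_kind not in OUTCOME_KINDS:
            raise ValidationError(f"outcome_kind must be one of {OUTCOME_KINDS}")
        if self.raw_stat_kind not in ("z", "t"):
            raise ValidationError("raw_stat_kind must be 'z' or 't'")
        if self.raw_stat_kind == "t" and not (self.t_df and self.t_df > 0):
            raise ValidationError(
                f"{self.study_id}/{self.population_id}: t statistic requires t_df > 0"
            )


@dataclass(frozen=True)
class MetaResult:
    outcome_kind: str
    ptsd_only: bool
    n_populations: int
    imbalances: tuple[float, ...]
    outcomes: tuple[float, ...]
    correlation: CorrelationResult


def t_to_z(t: float, df: float) -> float:
    """Probability-matched t -> z conversion: z = Phi^-1(F_t(t; df)).

    Strictly increasing and odd in t; clamped to +/- 8 to avoid infinities in
    extreme tails.
    """
    if not math.isfinite(t):
        raise ValidationError(f"t statistic must be finite, got {t}")
    if not df > 0:
        raise ValidationError(f"degrees of freedom must be positive, got {df}")
    if t < 0:
        return -t_to_z(-t, df)
    # work in the upper tail for numerical accuracy at large |t|
    z = float(stats.norm.isf(stats.t.sf(t, df)))
    return float(np.clip(z, -Z_CLAMP, Z_CLAMP))


def harmonize_study(record: StudyRecord) -> tuple[float, float]:
    """(symptom imbalance, harmonized outcome) for one study record."""
    imbalance = symptom_imbalance(record.profile).imbalance
    if record.outcome_kind == "tab_ms" or record.raw_stat_kind == "z":
        outcome = float(record.outcome_value)
    else:
        outcome = t_to_z(record.outcome_value, record.t_df)
    return imbalance, outcome


def run_meta(
    records: Iterable[StudyRecord],
    outcome_kind: str,
    ptsd_only: bool = False,
) -> MetaResult:
    """Filter records, harmonize, and correlate imbalance with the outcome."""
    if outcome_kind not in OUTCOME_KINDS:
        raise ValidationError(f"outcome_kind must be one of {OUTCOME_KINDS}")
    retained = [
        r
        for r in records
        if r.outcome_kind == outcome_kind and (r.is_ptsd_diagnosed or not ptsd_only)
    ]
    if len(retained) < 3:
        raise ValidationError(
            f"run_meta needs >= 3 records of kind {outcome_kind!r}, got {len(retained)}"
        )
    pairs = [harmonize_study(r) for r in retained]
    imbalances = tuple(p[0] for p in pairs)
    outcomes = tuple(p[1] for p in pairs)
    corr = pearson_one_tailed(imbalances, outcomes, direction="positive")
    return MetaResult(
        outcome_kind=outcome_kind,
        ptsd_only=ptsd_only,
        n_populations=len(retained),
        imbalances=imbalances,
        outcomes=outcomes,
        correlation=corr,
    )


# ---------------------------------------------------------------------------
# CSV interchange

META_COLUMNS = [
    "study_id", "population_id", "n", "is_ptsd", "dsm_version",
    "re_exp", "re_exp_min", "re_exp_max",
    "avoid", "avoid_min", "avoid_max",
    "numb", "numb_min", "numb_max",
    "hyper", "hyper_min", "hyper_max",
    "depder", "depder_min", "depder_max",
    "outcome_kind", "outcome_value", "raw_stat_kind", "t_df",
]


def _opt(row, name: str) -> Optional[float]:
    if name not in row.index or pd.isna(row[name]):
        return None
    return float(row[name])


def _opt_bounds(row, prefix: str):
    lo, hi = _opt(row, f"{prefix}_min"), _opt(row, f"{prefix}_max")
    if lo is None or hi is None:
        return None
    return (lo, hi)


def read_meta_table(path) -> list[StudyRecord]:
    df = pd.read_csv(path)
    if df.empty:
        raise ValidationError("meta table is empty")
    records = []
    for _, row in df.iterrows():
        scale = SymptomScale(
            instrument="table",
            dsm_version=str(row["dsm_version"]).strip(),
            re_experiencing=(float(row["re_exp_min"]), float(row["re_exp_max"])),
            avoidance=(float(row["avoid_min"]), float(row["avoid_max"])),
            hypervigilance=(float(row["hyper_min"]), float(row["hyper_max"])),
            numbing=_opt_bounds(row, "numb"),
            depersonalization_derealization=_opt_bounds(row, "depder"),
        )
        profile = SymptomProfile(
            subject_id=str(row["population_id"]),
            scale=scale,
            re_experiencing=float(row["re_exp"]),
            avoidance=float(row["avoid"]),
            hypervigilance=float(row["hyper"]),
            numbing=_opt(row, "numb"),
            depersonalization_derealization=_opt(row, "depder"),
        )
        raw_kind = str(row["raw_stat_kind"]).strip() if not pd.isna(row["raw_stat_kind"]) else "z"
        records.append(
            StudyRecord(
                study_id=str(row["study_id"]),
                population_id=str(row["population_id"]),
                n=int(row["n"]),
                is_ptsd_diagnosed=bool(row["is_ptsd"]),
                profile=profile,
                outcome_kind=str(row["outcome_kind"]).strip(),
                outcome_value=float(row["outcome_value"]),
                raw_stat_kind=raw_kind,
                t_df=_opt(row, "t_df"),
            )
        )
    return records


def write_meta_table(records: Sequence[StudyRecord], path) -> None:
    rows = []
    for r in records:
        p, s = r.profile, r.profile.scale
        rows.append({
            "study_id": r.study_id,
            "population_id": r.population_id,
            "n": r.n,
            "is_ptsd": r.is_ptsd_diagnosed,
            "dsm_version": s.dsm_version,
            "re_exp": p.re_experiencing,
            "re_exp_min": s.re_experiencing[0], "re_exp_max": s.re_experiencing[1],
            "avoid": p.avoidance,
            "avoid_min": s.avoidance[0], "avoid_max": s.avoidance[1],
            "numb": p.numbing,
            "numb_min": s.numbing[0] if s.numbing else None,
            "numb_max": s.numbing[1] if s.numbing else None,
            "hyper": p.hypervigilance,
            "hyper_min": s.hypervigilance[0], "hyper_max": s.hypervigilance[1],
            "depder": p.depersonalization_derealization,
            "depder_min": s.depersonalization_derealization[0]
            if s.depersonalization_derealization else None,
            "depder_max": s.depersonalization_derealization[1]
            if s.depersonalization_derealization else None,
            "outcome_kind": r.outcome_kind,
            "outcome_value": r.outcome_value,
            "raw_stat_kind": r.raw_stat_kind,
            "t_df": r.t_df,
        })
    pd.DataFrame(rows, columns=META_COLUMNS).to_csv(path, index=False)


def plot_meta(result: MetaResult, path) -> None:
    """Scatter of population imbalance vs. harmonized outcome."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(result.imbalances, result.outcomes, color="tab:blue")
    ax.axvline(0, color="0.7", lw=0.8)
    ax.axhline(0, color="0.7", lw=0.8)
    ax.set_xlabel("symptom imbalance (avoidance - re-experiencing, normalized)")
    ylabel = "TAB (ms)" if result.outcome_kind == "tab_ms" else "amygdala response (z)"
    ax.set_ylabel(ylabel)
    ax.set_title(
        f"{result.outcome_kind}: r = {result.correlation.r:.2f}, "
        f"one-tailed p = {result.correlation.p_one_tailed:.3f}"
    )
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
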