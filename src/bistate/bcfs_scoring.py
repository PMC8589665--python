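"""Trial filtering, dyad construction, and attentional-bias indices for the
breaking continuous flash suppression (b-CFS) task.

A session presents 6 face identities x 2 expressions (angry/neutral) x 4
screen positions = 48 trials; the outcome per trial is the detection reaction
time (RT, ms).  Trials are paired into dyads: one angry and one neutral trial
sharing face identity and position.  Each dyad carries a signed bias score;
under the default ``toward_positive`` convention

    bias = RT(neutral) - RT(angry)

so a positive bias means the angry face broke suppression faster (attention
toward threat).  The ``literal`` convention negates this (angry - neutral).

Per-subject indices:

* TAB    -- mean of all dyad biases (traditional attentional bias),
* AB_TOWARD -- mean of the strictly positive biases,
* AB_AWAY   -- absolute mean of the strictly negative biases,
* ABV    -- SD of all dyad biases (attentional bias variability),
* sd_toward / sd_away -- SD within each sign class,
* pct_toward -- percentage of signed (non-zero) dyads that are positive.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

logger = logging.getLogger(__name__)

EXPRESSIONS = ("angry", "neutral")
SIGN_CONVENTIONS = ("toward_positive", "literal")


@dataclass(frozen=True)
class TrialRecord:
    subject_id: str
    face_id: int
    expression: str
    position: int
    rt: float  # milliseconds
    correct: bool

    def __post_init__(self) -> None:
        if self.expression not in EXPRESSIONS:
            raise ValidationError(f"expression must be one of {EXPRESSIONS}")
        if not (math.isfinite(self.rt) and self.rt > 0):
            raise ValidationError(
                f"{self.subject_id}: rt must be finite and positive, got {self.rt}"
            )


@dataclass(frozen=True)
class Dyad:
    face_id: int
    position: int
    rt_angry: float
    rt_neutral: float
    bias: float


@dataclass(frozen=True)
class ExclusionReport:
    removed: tuple[tuple[TrialRecord, str], ...]  # (trial, reason)
    n_total: int

    @property
    def n_excluded(self) -> int:
        return len(self.removed)

    @property
    def excluded_fraction(self) -> float:
        return self.n_excluded / self.n_total if self.n_total else 0.0


@dataclass(frozen=True)
class BiasSummary:
    subject_id: str
    tab: float
    ab_toward: Optional[float]
    ab_away: Optional[float]  # stored as an absolute value
    abv: Optional[float]
    sd_toward: Optional[float]
    sd_away: Optional[float]
    pct_toward: Optional[float]
    n_dyads: int
    n_excluded_trials: int
    excluded_fraction: float


def exclude_trials(
    trials: Iterable[TrialRecord], sd_multiplier: float = 5.0
) -> tuple[list[TrialRecord], ExclusionReport]:
    """Drop incorrect trials and extreme slow outliers.

    Outliers are trials with RT more than ``sd_multiplier`` sample SDs above
    the subject-by-expression mean, with mean and SD computed leave-one-out
    over that condition's other correct trials (one-sided rule: only slow
    outliers are removed).  Leave-one-out matters: within a condition of n
    trials the largest possible include-the-point z score is (n-1)/sqrt(n)
    (about 4.7 at n = 24), so a 5 SD rule whose statistics include the
    candidate trial could never fire at this session length.
    """
    trials = list(trials)
    removed: list[tuple[TrialRecord, str]] = []
    kept: list[TrialRecord] = []
    correct = [t for t in trials if t.correct]
    removed.extend((t, "incorrect") for t in trials if not t.correct)

    sums_by_cond: dict[tuple[str, str], tuple[int, float, float]] = {}
    for key in {(t.subject_id, t.expression) for t in correct}:
        rts = np.array([t.rt for t in correct if (t.subject_id, t.expression) == key])
        if rts.size < 2:
            raise ValidationError(
                f"subject {key[0]}: fewer than 2 correct {key[1]} trials; "
                "cannot compute the outlier threshold"
            )
        sums_by_cond[key] = (rts.size, float(rts.sum()), float((rts**2).sum()))

    for t in correct:
        n, s1, s2 = sums_by_cond[(t.subject_id, t.expression)]
        if n < 3:  # leave-one-out SD undefined; no outlier screening possible
            kept.append(t)
            continue
        loo_mean = (s1 - t.rt) / (n - 1)
        loo_ss = max(s2 - t.rt**2 - (n - 1) * loo_mean**2, 0.0)
        loo_sd = math.sqrt(loo_ss / (n - 2))
        if t.rt > loo_mean + sd_multiplier * loo_sd:
            removed.append((t, "outlier"))
        else:
            kept.append(t)

    report = ExclusionReport(removed=tuple(removed), n_total=len(trials))
    if report.n_total and report.excluded_fraction >= 0.03:
        warnings.warn(
            f"excluded fraction {report.excluded_fraction:.1%} >= 3% of trials",
            stacklevel=2,
        )
    return kept, report


def build_dyads(
    trials: Iterable[TrialRecord], bias_sign: str = "toward_positive"
) -> tuple[list[Dyad], int]:
    """Pair kept trials into (face_id, position) dyads for a single subject.

    Returns (dyads, n_incomplete_cells); cells missing either member are
    dropped whole, never imputed.
    """
    if bias_sign not in SIGN_CONVENTIONS:
        raise ValidationError(f"bias_sign must be one of {SIGN_CONVENTIONS}")
    by_cell: dict[tuple[int, int], dict[str, TrialRecord]] = {}
    for t in trials:
        cell = by_cell.setdefault((t.face_id, t.position), {})
        if t.expression in cell:
            raise ValidationError(
                f"duplicate trial for subject {t.subject_id}, face {t.face_id}, "
                f"{t.expression}, position {t.position}"
            )
        cell[t.expression] = t
    dyads: list[Dyad] = []
    incomplete = 0
    for (face_id, position), cell in sorted(by_cell.items()):
        if len(cell) < 2:
            incomplete += 1
            continue
        rt_a, rt_n = cell["angry"].rt, cell["neutral"].rt
        bias = rt_n - rt_a if bias_sign == "toward_positive" else rt_a - rt_n
        dyads.append(Dyad(face_id, position, rt_a, rt_n, bias))
    return dyads, incomplete


def summarize_bias(
    dyads: list[Dyad],
    subject_id: str = "",
    n_excluded_trials: int = 0,
    excluded_fraction: float = 0.0,
) -> BiasSummary:
    """Attentional-bias indices from a subject's dyads.

    Zero-valued biases (exact RT ties) count in TAB and ABV but belong to
    neither sign class.
    """
    if not dyads:
        raise ValidationError("cannot summarize an empty dyad set")
    biases = np.array([d.bias for d in dyads])
    pos = biases[biases > 0]
    neg = biases[biases < 0]

    def _sd(v: np.ndarray) -> Optional[float]:
        return float(v.std(ddof=1)) if v.size >= 2 else None

    n_signed = pos.size + neg.size
    return BiasSummary(
        subject_id=subject_id,
        tab=float(biases.mean()),
        ab_toward=float(pos.mean()) if pos.size else None,
        ab_away=float(abs(neg.mean())) if neg.size else None,
        abv=_sd(biases),
        sd_toward=_sd(pos),
        sd_away=_sd(neg),
        pct_toward=100.0 * pos.size / n_signed if n_signed else None,
        n_dyads=len(dyads),
        n_excluded_trials=n_excluded_trials,
        excluded_fraction=excluded_fraction,
    )


def score_subject(
    trials: Iterable[TrialRecord],
    sd_multiplier: float = 5.0,
    bias_sign: str = "toward_positive",
) -> tuple[BiasSummary, list[Dyad], ExclusionReport]:
    """Exclusion -> dyads -> summary for one subject's trials."""
    trials = list(trials)
    subjects = {t.subject_id for t in trials}
    if len(subjects) != 1:
        raise ValidationError(f"score_subject expects one subject, got {sorted(subjects)}")
    kept, report = exclude_trials(trials, sd_multiplier)
    dyads, _ = build_dyads(kept, bias_sign)
    summary = summarize_bias(
        dyads,
        subject_id=subjects.pop(),
        n_excluded_trials=report.n_excluded,
        excluded_fraction=report.excluded_fraction,
    )
    return summary, dyads, report


def compare_error_rates(trials: Iterable[TrialRecord]):
    """Paired t test of percent error rate between angry and neutral trials.

    Returns (t, df, p_two_tailed) across subjects; df = n_subjects - 1.
    """
    df_t = trials_to_frame(trials) if not isinstance(trials, pd.DataFrame) else trials
    subjects = sorted(df_t["subject_id"].unique())
    if len(subjects) < 2:
        raise ValidationError("error-rate comparison requires >= 2 subjects")
    angry, neutral = [], []
    for s in subjects:
        sub = df_t[df_t["subject_id"] == s]
        for expr, out in (("angry", angry), ("neutral", neutral)):
            cond = sub[sub["expression"] == expr]
            if cond.empty:
                raise ValidationError(f"subject {s} has no {expr} trials")
            out.append(100.0 * (1.0 - cond["correct"].mean()))
    diffs = np.asarray(angry) - np.asarray(neutral)
    if diffs.std(ddof=1) == 0:
        # degenerate paired case: identical vectors are a perfect null
        if diffs.mean() == 0:
            return 0.0, len(subjects) - 1, 1.0
        return math.copysign(math.inf, diffs.mean()), len(subjects) - 1, 0.0
    res = stats.ttest_rel(angry, neutral)
    return float(res.statistic), len(subjects) - 1, float(res.pvalue)


# ---------------------------------------------------------------------------
# CSV interchange

TRIAL_COLUMNS = ["subject_id", "face_id", "expression", "position", "rt_ms", "correct"]


def trials_to_frame(trials: Iterable[TrialRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "subject_id": t.subject_id,
                "face_id": t.face_id,
                "expression": t.expression,
                "position": t.position,
                "rt_ms": t.rt,
                "correct": t.correct,
            }
            for t in trials
        ],
        columns=TRIAL_COLUMNS,
    )


def frame_to_trials(df: pd.DataFrame) -> list[TrialRecord]:
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"trial table missing columns: {sorted(missing)}")
    rt = df["rt_ms"].astype(float)
    # RTs below 20 are assumed to be seconds and converted to milliseconds.
    if len(rt) and float(rt.median()) < 20:
        logger.info("trial RTs look like seconds (median %.3f); converting to ms", rt.median())
        rt = rt * 1000.0
    return [
        TrialRecord(
            subject_id=str(row.subject_id),
            face_id=int(row.face_id),
            expression=str(row.expression),
            position=int(row.position),
            rt=float(r),
            correct=bool(row.correct),
        )
        for row, r in zip(df.itertuples(index=False), rt)
    ]


def read_trial_table(path) -> list[TrialRecord]:
    return frame_to_trials(pd.read_csv(path))


def write_trial_table(trials: Iterable[TrialRecord], path) -> None:
    trials_to_frame(trials).to_csv(path, index=False)


def summaries_to_frame(summaries: Iterable[BiasSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])
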