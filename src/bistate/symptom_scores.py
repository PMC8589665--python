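"""Symptom-cluster scores, normalization, and the symptom-imbalance statistic.

PTSD instruments score several symptom clusters (re-experiencing, avoidance,
emotional numbing, hypervigilance, depersonalization/derealization) on
instrument-specific ranges.  To compare patients and study populations that
were assessed with different instruments and different DSM editions, each
cluster score is mapped onto the unit interval (minimum possible value -> 0,
maximum possible value -> 1).  DSM-IV instruments report a single combined
avoidance/numbing cluster; DSM-5 instruments report avoidance and numbing
separately, so the two raw scores (and their bounds) are summed before
normalization to stay comparable with DSM-IV scores.

Two derived statistics index the balance between the hypothesized emotional
over- and undermodulatory states:

* ``imbalance = avoid_norm - re_norm`` in [-1, 1] (positive: avoidance-
  dominated, i.e. overmodulatory; negative: re-experiencing-dominated).
* ``symptom_sum = re_norm + avoid_norm`` in [0, 2], a proxy for how far apart
  the two states are within a patient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .errors import ValidationError

Bounds = tuple[float, float]

_CLUSTERS = (
    "re_experiencing",
    "avoidance",
    "numbing",
    "hypervigilance",
    "depersonalization_derealization",
)


def _check_bounds(name: str, bounds: Optional[Bounds]) -> None:
    if bounds is None:
        return
    lo, hi = bounds
    if not (math.isfinite(lo) and math.isfinite(hi)):
        raise ValidationError(f"{name}: scale bounds must be finite, got {bounds}")
    if lo < 0:
        raise ValidationError(f"{name}: scale bounds must be nonnegative, got {bounds}")
    if not hi > lo:
        raise ValidationError(f"{name}: scale maximum must exceed minimum, got {bounds}")


@dataclass(frozen=True)
class SymptomScale:
    """Instrument scale: per-cluster minimum/maximum possible raw scores."""

    instrument: str
    dsm_version: str  # "IV" or "V"
    re_experiencing: Bounds
    avoidance: Bounds
    hypervigilance: Bounds
    numbing: Optional[Bounds] = None
    depersonalization_derealization: Optional[Bounds] = None

    def __post_init__(self) -> None:
        if self.dsm_version not in ("IV", "V"):
            raise ValidationError(
                f"dsm_version must be 'IV' or 'V', got {self.dsm_version!r}"
            )
        for name in _CLUSTERS:
            _check_bounds(name, getattr(self, name))
        if self.dsm_version == "V" and self.numbing is None:
            raise ValidationError(
                "DSM-V scales must define numbing bounds (avoidance and numbing "
                "are separate clusters in DSM-V)"
            )

    def bounds_of(self, cluster: str) -> Optional[Bounds]:
        return getattr(self, cluster)


def caps_iv() -> SymptomScale:
    """CAPS (DSM-IV) preset: 0-8 per item.

    Re-experiencing: 5 items (B1-B5), combined avoidance/numbing: 7 items
    (C1-C7), hypervigilance: 5 items (D1-D5), associated depersonalization +
    derealization: 2 items.
    """
    return SymptomScale(
        instrument="CAPS",
        dsm_version="IV",
        re_experiencing=(0.0, 40.0),
        avoidance=(0.0, 56.0),
        hypervigilance=(0.0, 40.0),
        depersonalization_derealization=(0.0, 16.0),
    )


@dataclass(frozen=True)
class SymptomProfile:
    """Raw per-cluster scores for one subject (or one population mean)."""

    subject_id: str
    scale: SymptomScale
    re_experiencing: float
    avoidance: float
    hypervigilance: float
    numbing: Optional[float] = None
    depersonalization_derealization: Optional[float] = None

    def __post_init__(self) -> None:
        for name in _CLUSTERS:
            raw = getattr(self, name)
            if raw is None:
                continue
            bounds = self.scale.bounds_of(name)
            if bounds is None:
                raise ValidationError(
                    f"{self.subject_id}: {name} score given but the scale "
                    "defines no bounds for it"
                )
            lo, hi = bounds
            if not math.isfinite(raw) or raw < lo or raw > hi:
                raise ValidationError(
                    f"{self.subject_id}: {name} score {raw} outside scale "
                    f"bounds [{lo}, {hi}]"
                )


@dataclass(frozen=True)
class NormalizedSymptoms:
    """Unit-interval cluster scores and the derived imbalance statistics."""

    re_norm: float
    avoid_norm: float
    imbalance: float
    symptom_sum: float


def normalize_cluster(raw: float, lo: float, hi: float, cluster: str = "score") -> float:
    """Map a raw cluster score onto [0, 1] given its scale bounds."""
    _check_bounds(cluster, (lo, hi))
    if not math.isfinite(raw) or raw < lo or raw > hi:
        raise ValidationError(f"{cluster}: raw score {raw} outside bounds [{lo}, {hi}]")
    return (raw - lo) / (hi - lo)


def harmonize_avoidance(profile: SymptomProfile) -> tuple[float, Bounds]:
    """Combined avoidance score and bounds, comparable across DSM editions.

    DSM-IV: the avoidance cluster already includes numbing; returned unchanged.
    DSM-V: avoidance + numbing scores are summed, bounds summed element-wise.
    """
    scale = profile.scale
    if scale.dsm_version == "IV":
        return profile.avoidance, scale.avoidance
    if profile.numbing is None:
        raise ValidationError(
            f"{profile.subject_id}: DSM-V profile is missing the numbing score"
        )
    assert scale.numbing is not None  # enforced by SymptomScale
    lo = scale.avoidance[0] + scale.numbing[0]
    hi = scale.avoidance[1] + scale.numbing[1]
    return profile.avoidance + profile.numbing, (lo, hi)


def _normalized(profile: SymptomProfile, avoid_raw: float, avoid_bounds: Bounds) -> NormalizedSymptoms:
    re_norm = normalize_cluster(
        profile.re_experiencing, *profile.scale.re_experiencing, cluster="re_experiencing"
    )
    avoid_norm = normalize_cluster(avoid_raw, *avoid_bounds, cluster="avoidance")
    return NormalizedSymptoms(
        re_norm=re_norm,
        avoid_norm=avoid_norm,
        imbalance=avoid_norm - re_norm,
        symptom_sum=re_norm + avoid_norm,
    )


def symptom_imbalance(profile: SymptomProfile) -> NormalizedSymptoms:
    """Normalized scores, imbalance (avoid - re) and symptom sum (re + avoid)."""
    avoid_raw, avoid_bounds = harmonize_avoidance(profile)
    return _normalized(profile, avoid_raw, avoid_bounds)


def augmented_avoidance(profile: SymptomProfile) -> NormalizedSymptoms:
    """Sensitivity variant: avoidance augmented with dissociative symptoms.

    The combined (DSM-harmonized) avoidance score is replaced by its sum with
    the depersonalization/derealization score before normalization; bounds are
    summed accordingly.
    """
    if (
        profile.depersonalization_derealization is None
        or profile.scale.depersonalization_derealization is None
    ):
        raise ValidationError(
            f"{profile.subject_id}: depersonalization/derealization score or "
            "bounds absent; cannot compute the augmented-avoidance variant"
        )
    avoid_raw, avoid_bounds = harmonize_avoidance(profile)
    dd_lo, dd_hi = profile.scale.depersonalization_derealization
    combined = avoid_raw + profile.depersonalization_derealization
    bounds = (avoid_bounds[0] + dd_lo, avoid_bounds[1] + dd_hi)
    return _normalized(profile, combined, bounds)


def hypervigilance_norm(profile: SymptomProfile) -> float:
    return normalize_cluster(
        profile.hypervigilance, *profile.scale.hypervigilance, cluster="hypervigilance"
    )


# ---------------------------------------------------------------------------
# CSV interchange

_TABLE_COLUMNS = [
    "subject_id", "dsm_version",
    "re_exp", "re_exp_min", "re_exp_max",
    "avoid", "avoid_min", "avoid_max",
    "numb", "numb_min", "numb_max",
    "hyper", "hyper_min", "hyper_max",
    "depder", "depder_min", "depder_max",
]


def _opt(row: pd.Series, name: str) -> Optional[float]:
    if name not in row.index or pd.isna(row[name]):
        return None
    return float(row[name])


def _opt_bounds(row: pd.Series, prefix: str) -> Optional[Bounds]:
    lo, hi = _opt(row, f"{prefix}_min"), _opt(row, f"{prefix}_max")
    if lo is None or hi is None:
        return None
    return (lo, hi)


def read_symptom_table(path) -> list[SymptomProfile]:
    """Read the one-row-per-subject symptom CSV into SymptomProfile objects."""
    df = pd.read_csv(path)
    required = {"subject_id", "dsm_version", "re_exp", "re_exp_min", "re_exp_max",
                "avoid", "avoid_min", "avoid_max", "hyper", "hyper_min", "hyper_max"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"symptom table missing columns: {sorted(missing)}")
    profiles = []
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
        profiles.append(
            SymptomProfile(
                subject_id=str(row["subject_id"]),
                scale=scale,
                re_experiencing=float(row["re_exp"]),
                avoidance=float(row["avoid"]),
                hypervigilance=float(row["hyper"]),
                numbing=_opt(row, "numb"),
                depersonalization_derealization=_opt(row, "depder"),
            )
        )
    return profiles


def write_symptom_table(profiles: list[SymptomProfile], path) -> None:
    rows = []
    for p in profiles:
        s = p.scale
        row = {
            "subject_id": p.subject_id,
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
        }
        rows.append(row)
    pd.DataFrame(rows, columns=_TABLE_COLUMNS).to_csv(path, index=False)
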