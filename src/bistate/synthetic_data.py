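"""Synthetic cohorts and meta tables with the two-state structure the
analysis pipeline assumes.

The generator embodies a minimal two-state alternation process:

* each patient carries a hidden binary state (under- vs. overmodulatory)
  evolving across the 48 trials of a b-CFS session as a two-state Markov
  chain with per-state stay probabilities;
* the overmodulatory state slows all detections by a fixed state offset, and
  the threat effect is state dependent: angry faces break suppression faster
  than neutral in the under state (speedup delta_u) but slower in the over
  state (slowdown delta_o):

      rt = base_rt + offset*1[over]
           - delta_u*1[angry]*1[under] + delta_o*1[angry]*1[over] + noise

* per-patient under- and over-state severities (independent draws from
  ``severity_range``) scale delta_u and delta_o respectively: a deeper
  under state means faster threat detection, a deeper over state slower;
* symptom-cluster scores couple to the hidden process: the re-experiencing
  mean grows with (realized under-state occupancy) x delta_u and the
  avoidance mean with (over-state occupancy) x delta_o, then Gaussian noise
  is added and scores are clipped to CAPS-like bounds.

Consequences that the analysis stages should recover: pooled RTs are bimodal
with peak separation ~ offset + (delta_u + delta_o)/2; the symptom sum
tracks the combined state depth and hence the peak distance; toward-class
dyad magnitudes track delta_u (re-experiencing) and away-class magnitudes
delta_o (avoidance); occupancy imbalance together with the asymmetric threat
effects drives both the sign of the mean dyad bias and the
re-experiencing-vs-avoidance imbalance.

Meta tables are generated separately: population imbalances drawn uniformly
and outcomes built as rho * standardized imbalance + sqrt(1-rho^2) * noise,
so the planted population correlation equals ``target_rho`` exactly; a
configured fraction of imaging outcomes is emitted as t statistics (with
drawn dfs) chosen so that probability-matched conversion recovers the
underlying z.

Everything is a pure function of (config, seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence, Union

import numpy as np

from .bcfs_scoring import TrialRecord
from .errors import ValidationError
from .meta_harmonize import StudyRecord
from .symptom_scores import SymptomProfile, SymptomScale, caps_iv


def _seed_for(*key) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=key[0], spawn_key=tuple(key[1:]))


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for a simulated b-CFS cohort.

    Defaults emulate the regime of a 20-patient CAPS/DSM-IV assessed cohort:
    detection times on the order of 2 s, a state separation large relative
    to trial noise (so per-patient bimodality is detectable from 48 trials),
    a modest threat effect, an error rate below the 3% exclusion warning
    band, and CAPS totals near 80.
    """

    n_patients: int = 20
    n_faces: int = 6
    n_positions: int = 4
    # state dynamics
    markov_stay_prob: float = 0.66         # used when per-state probs are not drawn
    stay_prob_under_range: tuple[float, float] = (0.60, 0.72)
    stay_prob_over_range: tuple[float, float] = (0.64, 0.76)
    # reaction-time model (ms)
    base_rt: float = 1800.0
    state_offset: float = 400.0
    threat_effect: float = 350.0           # base delta, scaled per patient/state
    rt_noise_sd: float = 150.0
    severity_range: tuple[float, float] = (0.5, 1.5)
    error_rate: float = 0.02
    lognormal_noise: bool = False
    # symptom coupling (score points per ms of occupancy-weighted threat effect)
    re_coupling: float = 0.07
    avoid_coupling: float = 0.09
    hyper_coupling: float = 0.0
    dissoc_coupling: float = 0.03
    re_base: float = 8.0
    avoid_base: float = 10.0
    hyper_base: float = 18.0
    dissoc_base: float = 2.0
    symptom_noise_sd: float = 3.0
    scale: SymptomScale = field(default_factory=caps_iv)
    seed: int = 0

    def __post_init__(self) -> None:
        probs = [self.markov_stay_prob, self.error_rate,
                 *self.stay_prob_under_range, *self.stay_prob_over_range]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValidationError("all probabilities must lie in [0, 1]")
        if self.rt_noise_sd < 0 or self.symptom_noise_sd < 0:
            raise ValidationError("noise SDs must be nonnegative")
        if self.threat_effect < 0:
            raise ValidationError("threat_effect must be nonnegative")
        if self.n_patients < 1 or self.n_faces < 1 or self.n_positions < 1:
            raise ValidationError("counts must be positive")


@dataclass(frozen=True)
class PatientTruth:
    subject_id: str
    states: tuple[int, ...]          # 0 = under, 1 = over, one per trial
    under_occupancy: float
    severity: tuple[float, float]    # (under-state, over-state) multipliers
    stay_probs: tuple[float, float]
    true_peak_separation: float      # offset + (delta_u + delta_o)/2
    true_cluster_means: dict[str, float]


@dataclass(frozen=True)
class CohortTruth:
    patients: tuple[PatientTruth, ...]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump([asdict(p) for p in self.patients], fh, indent=2, sort_keys=True)


def _rt_noise(rng: np.random.Generator, n: int, config: CohortConfig) -> np.ndarray:
    if not config.lognormal_noise:
        return rng.normal(0.0, config.rt_noise_sd, size=n)
    # right-skewed alternative: centred lognormal rescaled to the same SD
    sigma = 0.5
    raw = rng.lognormal(mean=0.0, sigma=sigma, size=n)
    mean = math.exp(sigma**2 / 2)
    sd = mean * math.sqrt(math.exp(sigma**2) - 1.0)
    return (raw - mean) * (config.rt_noise_sd / sd)


def simulate_patient(
    config: CohortConfig,
    index: int,
    stay_probs: Optional[tuple[float, float]] = None,
    severity: Union[float, tuple[float, float]] = 1.0,
    start_state: Optional[int] = None,
) -> tuple[list[TrialRecord], PatientTruth]:
    """One 48-trial session (deterministic under (config.seed, index)).

    ``stay_probs`` are (P(stay | under), P(stay | over)); both default to
    ``config.markov_stay_prob``.  ``severity`` is a scalar or an
    (under-state, over-state) pair scaling the state-dependent threat
    effects delta_u and delta_o.
    """
    rng = np.random.default_rng(_seed_for(config.seed, 1, index))
    subject_id = f"P{index + 1:03d}"
    p_under, p_over = stay_probs if stay_probs is not None else (
        config.markov_stay_prob, config.markov_stay_prob
    )
    sev_u, sev_o = severity if isinstance(severity, tuple) else (severity, severity)

    design = [
        (face, expr, pos)
        for face in range(1, config.n_faces + 1)
        for expr in ("angry", "neutral")
        for pos in range(1, config.n_positions + 1)
    ]
    order = rng.permutation(len(design))
    n_trials = len(design)

    states = np.empty(n_trials, dtype=int)
    states[0] = start_state if start_state is not None else rng.integers(0, 2)
    for t in range(1, n_trials):
        stay = p_under if states[t - 1] == 0 else p_over
        states[t] = states[t - 1] if rng.random() < stay else 1 - states[t - 1]

    delta_u = sev_u * config.threat_effect   # angry speedup in the under state
    delta_o = sev_o * config.threat_effect   # angry slowdown in the over state
    noise = _rt_noise(rng, n_trials, config)
    trials: list[TrialRecord] = []
    for t, idx in enumerate(order):
        face, expr, pos = design[idx]
        state = states[t]
        rt = config.base_rt + config.state_offset * state + noise[t]
        if expr == "angry":
            rt += delta_o if state == 1 else -delta_u
        rt = max(rt, 100.0)  # physical floor; keeps RTs positive
        correct = bool(rng.random() > config.error_rate)
        trials.append(TrialRecord(subject_id, face, expr, pos, float(rt), correct))

    occupancy = float((states == 0).mean())
    true_means = {
        "re_experiencing": config.re_base + config.re_coupling * occupancy * delta_u,
        "avoidance": config.avoid_base + config.avoid_coupling * (1 - occupancy) * delta_o,
        "hypervigilance": config.hyper_base + config.hyper_coupling * occupancy * delta_u,
        "depersonalization_derealization":
            config.dissoc_base + config.dissoc_coupling * (1 - occupancy) * delta_o,
    }
    truth = PatientTruth(
        subject_id=subject_id,
        states=tuple(int(s) for s in states),
        under_occupancy=occupancy,
        severity=(float(sev_u), float(sev_o)),
        stay_probs=(float(p_under), float(p_over)),
        true_peak_separation=float(config.state_offset + (delta_u + delta_o) / 2.0),
        true_cluster_means=true_means,
    )
    return trials, truth


def _clip(value: float, bounds: tuple[float, float]) -> float:
    return float(min(max(value, bounds[0]), bounds[1]))


def simulate_cohort(
    config: CohortConfig,
) -> tuple[list[TrialRecord], list[SymptomProfile], CohortTruth]:
    """Heterogeneous cohort: trials, symptom profiles, and ground truth."""
    cohort_rng = np.random.default_rng(_seed_for(config.seed, 2))
    trials: list[TrialRecord] = []
    truths: list[PatientTruth] = []
    profiles: list[SymptomProfile] = []
    scale = config.scale
    for i in range(config.n_patients):
        stay_u = cohort_rng.uniform(*config.stay_prob_under_range)
        stay_o = cohort_rng.uniform(*config.stay_prob_over_range)
        sev_u = cohort_rng.uniform(*config.severity_range)
        sev_o = cohort_rng.uniform(*config.severity_range)
        patient_trials, truth = simulate_patient(
            config, i, stay_probs=(stay_u, stay_o), severity=(sev_u, sev_o)
        )
        trials.extend(patient_trials)
        truths.append(truth)

        m = truth.true_cluster_means
        noise = cohort_rng.normal(0.0, config.symptom_noise_sd, size=4)
        profiles.append(
            SymptomProfile(
                subject_id=truth.subject_id,
                scale=scale,
                re_experiencing=_clip(m["re_experiencing"] + noise[0], scale.re_experiencing),
                avoidance=_clip(m["avoidance"] + noise[1], scale.avoidance),
                hypervigilance=_clip(m["hypervigilance"] + noise[2], scale.hypervigilance),
                depersonalization_derealization=_clip(
                    m["depersonalization_derealization"] + noise[3],
                    scale.depersonalization_derealization,
                )
                if scale.depersonalization_derealization
                else None,
            )
        )
    return trials, profiles, CohortTruth(patients=tuple(truths))


def strong_coupling_config(seed: int = 0, n_patients: int = 20) -> CohortConfig:
    """High state-symptom coupling: wide severity spread, low symptom noise."""
    return CohortConfig(
        n_patients=n_patients,
        threat_effect=500.0,
        severity_range=(0.3, 1.7),
        rt_noise_sd=120.0,
        re_coupling=0.055,
        avoid_coupling=0.070,
        symptom_noise_sd=1.0,
        seed=seed,
    )


def zero_coupling_config(seed: int = 0, n_patients: int = 20) -> CohortConfig:
    """Null condition: symptom scores are pure noise around their bases."""
    return CohortConfig(
        n_patients=n_patients,
        re_coupling=0.0,
        avoid_coupling=0.0,
        hyper_coupling=0.0,
        dissoc_coupling=0.0,
        re_base=20.0,
        avoid_base=28.0,
        hyper_base=20.0,
        dissoc_base=8.0,
        symptom_noise_sd=6.0,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Meta tables


@dataclass(frozen=True)
class MetaConfig:
    n_studies: int = 16
    target_rho: float = 0.55
    outcome_kind: str = "tab_ms"
    outcome_scale: float = 30.0      # SD of the outcome (ms for TAB, z units otherwise)
    outcome_center: float = 5.0
    t_fraction: float = 0.5          # imaging outcomes emitted as t statistics
    df_range: tuple[int, int] = (15, 40)
    imbalance_range: tuple[float, float] = (-0.4, 0.4)
    dsm_v_fraction: float = 0.5
    ptsd_fraction: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_studies < 3:
            raise ValidationError("n_studies must be >= 3")
        if not (-1.0 <= self.target_rho <= 1.0):
            raise ValidationError("target_rho must lie in [-1, 1]")
        for p in (self.t_fraction, self.dsm_v_fraction, self.ptsd_fraction):
            if not (0.0 <= p <= 1.0):
                raise ValidationError("fractions must lie in [0, 1]")
        if self.outcome_scale < 0:
            raise ValidationError("outcome_scale must be nonnegative")


def _meta_scale(dsm_v: bool) -> SymptomScale:
    if not dsm_v:
        return caps_iv()
    # DSM-V style split of the combined 0-56 cluster: active avoidance 0-24,
    # numbing 0-32; sums match the DSM-IV combined bounds.
    return SymptomScale(
        instrument="synthetic-dsm5",
        dsm_version="V",
        re_experiencing=(0.0, 40.0),
        avoidance=(0.0, 24.0),
        numbing=(0.0, 32.0),
        hypervigilance=(0.0, 40.0),
    )


def simulate_meta_table(config: MetaConfig) -> list[StudyRecord]:
    """Study-level records with a planted imbalance-outcome correlation."""
    rng = np.random.default_rng(_seed_for(config.seed, 3))
    lo, hi = config.imbalance_range
    imbalances = rng.uniform(lo, hi, size=config.n_studies)
    x_sd = (hi - lo) / math.sqrt(12.0)
    z_signal = (imbalances - (lo + hi) / 2.0) / x_sd
    rho = config.target_rho
    latent = rho * z_signal + math.sqrt(1.0 - rho**2) * rng.normal(size=config.n_studies)
    outcomes = config.outcome_center + config.outcome_scale * latent

    records: list[StudyRecord] = []
    for i in range(config.n_studies):
        imb = imbalances[i]
        re_norm = 0.5 - imb / 2.0
        avoid_norm = 0.5 + imb / 2.0
        dsm_v = bool(rng.random() < config.dsm_v_fraction)
        scale = _meta_scale(dsm_v)
        re_raw = re_norm * scale.re_experiencing[1]
        if dsm_v:
            avoid_raw = avoid_norm * scale.avoidance[1]
            numb_raw = avoid_norm * scale.numbing[1]
        else:
            avoid_raw, numb_raw = avoid_norm * scale.avoidance[1], None
        hyper_raw = 0.5 * scale.hypervigilance[1]
        profile = SymptomProfile(
            subject_id=f"pop{i + 1:02d}",
            scale=scale,
            re_experiencing=float(re_raw),
            avoidance=float(avoid_raw),
            hypervigilance=float(hyper_raw),
            numbing=float(numb_raw) if numb_raw is not None else None,
        )

        outcome_value = float(outcomes[i])
        raw_kind, t_df = "z", None
        if config.outcome_kind != "tab_ms" and rng.random() < config.t_fraction:
            from scipy import stats as _st

            df = int(rng.integers(config.df_range[0], config.df_range[1] + 1))
            # choose t so that probability matching recovers the z exactly
            z = float(np.clip(outcome_value, -8.0, 8.0))
            outcome_value = float(_st.t.ppf(_st.norm.cdf(z), df))
            raw_kind, t_df = "t", float(df)

        records.append(
            StudyRecord(
                study_id=f"S{i + 1:02d}",
                population_id=f"pop{i + 1:02d}",
                n=int(rng.integers(15, 61)),
                is_ptsd_diagnosed=bool(rng.random() < config.ptsd_fraction),
                profile=profile,
                outcome_kind=config.outcome_kind,
                outcome_value=outcome_value,
                raw_stat_kind=raw_kind,
                t_df=t_df,
            )
        )
    return records
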