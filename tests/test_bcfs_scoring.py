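import math

import numpy as np
import pytest

import _oracles
from bistate import (
    TrialRecord,
    ValidationError,
    build_dyads,
    compare_error_rates,
    exclude_trials,
    summarize_bias,
)
from bistate.bcfs_scoring import frame_to_trials, trials_to_frame


def full_session(subject="s1", base=1500.0, jitter=None):
    """Complete 48-trial session; optional per-trial RT jitter array."""
    trials = []
    i = 0
    for face in range(1, 7):
        for expr in ("angry", "neutral"):
            for pos in range(1, 5):
                rt = base + (jitter[i] if jitter is not None else 10.0 * i)
                trials.append(TrialRecord(subject, face, expr, pos, rt, True))
                i += 1
    return trials


class TestExcludeTrials:
    def test_clean_session_keeps_everything(self):
        rng = np.random.default_rng(1)
        trials = full_session(jitter=rng.normal(0, 50, 48))
        kept, report = exclude_trials(trials)
        assert len(kept) == 48
        assert report.n_excluded == 0

    def test_planted_slow_outlier_is_the_only_exclusion(self):
        rng = np.random.default_rng(2)
        jitter = rng.normal(0, 50, 48)
        trials = full_session(jitter=jitter)
        # plant one angry trial at condition mean + 6 SD (computed without it)
        angry = [t for t in trials if t.expression == "angry"]
        rts = np.array([t.rt for t in angry[1:]])
        outlier_rt = rts.mean() + 6.0 * rts.std(ddof=1)
        bad = angry[0]
        trials[trials.index(bad)] = TrialRecord(
            bad.subject_id, bad.face_id, bad.expression, bad.position, outlier_rt, True
        )
        kept, report = exclude_trials(trials)
        assert report.n_excluded == 1
        removed, reason = report.removed[0]
        assert reason == "outlier"
        assert removed.rt == pytest.approx(outlier_rt)

    def test_fast_outliers_are_not_removed(self):
        rng = np.random.default_rng(3)
        trials = full_session(jitter=rng.normal(0, 50, 48))
        t0 = trials[0]
        trials[0] = TrialRecord(t0.subject_id, t0.face_id, t0.expression, t0.position, 1.0, True)
        kept, report = exclude_trials(trials)
        assert report.n_excluded == 0  # rule is one-sided (slow tail only)

    def test_incorrect_trial_removed_with_reason(self):
        trials = full_session(jitter=np.zeros(48) + np.arange(48))
        t0 = trials[5]
        trials[5] = TrialRecord(t0.subject_id, t0.face_id, t0.expression, t0.position, t0.rt, False)
        kept, report = exclude_trials(trials)
        assert len(kept) == 47
        assert report.removed[0][1] == "incorrect"

    def test_high_exclusion_fraction_warns(self):
        trials = full_session()
        for i in range(2):  # 2/48 = 4.2% >= 3%
            t = trials[i]
            trials[i] = TrialRecord(t.subject_id, t.face_id, t.expression, t.position, t.rt, False)
        with pytest.warns(UserWarning, match="3%"):
            exclude_trials(trials)

    def test_too_few_correct_trials_in_condition_errors(self):
        trials = [
            TrialRecord("s", 1, "angry", 1, 1000.0, True),
            TrialRecord("s", 1, "neutral", 1, 1000.0, True),
            TrialRecord("s", 2, "neutral", 1, 1100.0, True),
        ]
        with pytest.raises(ValidationError, match="fewer than 2"):
            exclude_trials(trials)


class TestBuildDyads:
    def test_complete_session_yields_24_dyads(self):
        dyads, incomplete = build_dyads(full_session())
        assert len(dyads) == 24
        assert incomplete == 0

    def test_missing_member_drops_cell(self):
        trials = full_session()
        trials = [t for t in trials if not (t.face_id == 3 and t.expression == "angry" and t.position == 2)]
        dyads, incomplete = build_dyads(trials)
        assert len(dyads) == 23
        assert incomplete == 1

    def test_empty_input_gives_empty_dyads(self):
        assert build_dyads([]) == ([], 0)

    def test_duplicate_cell_rejected(self):
        trials = full_session()
        trials.append(trials[0])
        with pytest.raises(ValidationError, match="duplicate"):
            build_dyads(trials)

    def test_sign_conventions_are_mirror_images(self):
        trials = full_session(jitter=np.random.default_rng(5).normal(0, 100, 48))
        toward, _ = build_dyads(trials, "toward_positive")
        literal, _ = build_dyads(trials, "literal")
        for a, b in zip(toward, literal):
            assert a.bias == pytest.approx(-b.bias)


class TestSummarizeBias:
    def make(self, biases):
        return [
            type("D", (), {"bias": b, "face_id": i, "position": 1, "rt_angry": 0, "rt_neutral": 0})()
            for i, b in enumerate(biases)
        ]

    def test_hand_computed_example(self):
        s = summarize_bias(self.make([100.0, 50.0, -30.0]))
        assert s.tab == pytest.approx(40.0)
        assert s.ab_toward == pytest.approx(75.0)
        assert s.ab_away == pytest.approx(30.0)
        assert s.pct_toward == pytest.approx(200.0 / 3.0)

    def test_symmetric_pair(self):
        s = summarize_bias(self.make([80.0, -80.0]))
        assert s.tab == pytest.approx(0.0)
        assert s.ab_toward == s.ab_away == pytest.approx(80.0)

    def test_all_positive_has_no_away_class(self):
        s = summarize_bias(self.make([10.0, 20.0, 30.0]))
        assert s.ab_away is None
        assert s.sd_away is None
        assert s.pct_toward == pytest.approx(100.0)

    def test_zero_biases_count_in_tab_but_no_sign_class(self):
        s = summarize_bias(self.make([0.0, 50.0, -50.0]))
        assert s.tab == pytest.approx(0.0)
        assert s.pct_toward == pytest.approx(50.0)
        assert s.n_dyads == 3

    def test_empty_dyads_rejected(self):
        with pytest.raises(ValidationError):
            summarize_bias([])

    def test_decomposition_identity(self):
        rng = np.random.default_rng(8)
        biases = list(rng.normal(0, 120, 24))
        s = summarize_bias(self.make(biases))
        n_pos = sum(b > 0 for b in biases)
        n_neg = sum(b < 0 for b in biases)
        recomposed = (n_pos * s.ab_toward - n_neg * s.ab_away) / s.n_dyads
        assert recomposed == pytest.approx(s.tab, abs=1e-9)

    def test_translation_invariance_of_indices(self):
        rng = np.random.default_rng(9)
        jitter = rng.normal(0, 100, 48)
        base = full_session(jitter=jitter)
        shifted = [
            TrialRecord(t.subject_id, t.face_id, t.expression, t.position, t.rt + 500.0, t.correct)
            for t in base
        ]
        s1 = summarize_bias(build_dyads(base)[0])
        s2 = summarize_bias(build_dyads(shifted)[0])
        assert s1.tab == pytest.approx(s2.tab, abs=1e-9)
        assert s1.abv == pytest.approx(s2.abv, abs=1e-9)
        assert s1.ab_toward == pytest.approx(s2.ab_toward, abs=1e-9)


class TestCompareErrorRates:
    def subject_trials(self, subject, angry_correct, neutral_correct):
        out = []
        for i, ok in enumerate(angry_correct):
            out.append(TrialRecord(subject, i % 6 + 1, "angry", i % 4 + 1, 1000.0 + i, bool(ok)))
        for i, ok in enumerate(neutral_correct):
            out.append(TrialRecord(subject, i % 6 + 1, "neutral", i % 4 + 1, 1000.0 + i, bool(ok)))
        return out

    def test_identical_error_vectors_give_t_zero(self):
        trials = []
        for s in range(4):
            trials += self.subject_trials(f"s{s}", [1, 1, 0, 1], [1, 0, 1, 1])
        t, df, p = compare_error_rates(trials)
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_matches_paired_t_oracle(self):
        rng = np.random.default_rng(10)
        trials = []
        angry_err, neutral_err = [], []
        for s in range(5):
            a = rng.random(8) > 0.2
            n = rng.random(8) > 0.1
            trials += self.subject_trials(f"s{s}", a, n)
            angry_err.append(100 * (1 - a.mean()))
            neutral_err.append(100 * (1 - n.mean()))
        t, df, p = compare_error_rates(trials)
        t_o, df_o, p_o = _oracles.paired_t(angry_err, neutral_err)
        assert t == pytest.approx(t_o, abs=1e-10)
        assert df == df_o
        assert p == pytest.approx(p_o, abs=1e-6)

    def test_df_is_subjects_minus_one(self):
        rng = np.random.default_rng(11)
        trials = []
        for s in range(20):
            trials += self.subject_trials(f"s{s:02d}", rng.random(4) > 0.1, rng.random(4) > 0.1)
        _, df, _ = compare_error_rates(trials)
        assert df == 19

    def test_single_subject_rejected(self):
        with pytest.raises(ValidationError):
            compare_error_rates(self.subject_trials("only", [1, 1], [1, 1]))


class TestTrialTableIO:
    def test_roundtrip(self):
        trials = full_session()
        back = frame_to_trials(trials_to_frame(trials))
        assert back == trials

    def test_seconds_autodetected(self):
        frame = trials_to_frame(full_session())
        frame["rt_ms"] = frame["rt_ms"] / 1000.0
        back = frame_to_trials(frame)
        assert back[0].rt == pytest.approx(full_session()[0].rt)
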