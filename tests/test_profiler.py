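"""Dataset profiler: scale inference, normality decisions, tree driving."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from statselect import (
    HypothesisConfig,
    answers_from_profile,
    make_paired_dataset,
    profile_dataset,
    run_answers,
)
from statselect.errors import (
    InsufficientDataError,
    MissingColumnError,
    UnanswerableQuestionError,
)

PAIRED = HypothesisConfig(analysis_columns=("before", "after"), design="paired")


class TestScaleInference:
    def test_binary_column(self):
        df = pd.DataFrame({"x": [0, 1, 1, 0, 1, 0, 1]})
        prof = profile_dataset(df, HypothesisConfig(
            analysis_columns=("x",), design="one_sample"))
        assert prof.variables["x"].scale == "binary"
        a, just = prof.derived_answers["q_binomial"]
        assert a.is_yes and "2 distinct" in just

    def test_continuous_column(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"x": rng.normal(size=50)})
        prof = profile_dataset(df, HypothesisConfig(
            analysis_columns=("x",), design="one_sample"))
        assert prof.variables["x"].scale == "continuous"

    def test_ordinal_requires_declared_ordering(self):
        df = pd.DataFrame({"grade": [1, 2, 3, 1, 2, 3, 2, 1]})
        base = HypothesisConfig(analysis_columns=("grade",),
                                design="one_sample")
        assert profile_dataset(df, base).variables["grade"].scale == "nominal"
        ordered = HypothesisConfig(
            analysis_columns=("grade",), design="one_sample",
            ordered_levels={"grade": [1, 2, 3]})
        assert profile_dataset(df, ordered).variables["grade"].scale == "ordinal"

    def test_missing_column_and_insufficient_data(self):
        df = pd.DataFrame({"x": [1.0, 2.0]})
        with pytest.raises(MissingColumnError):
            profile_dataset(df, HypothesisConfig(analysis_columns=("y",)))
        with pytest.raises(InsufficientDataError):
            profile_dataset(df, HypothesisConfig(analysis_columns=("x",),
                                                 design="one_sample"))


class TestNormalityDecision:
    def test_matches_reference_shapiro_on_identical_sample(self):
        rng = np.random.default_rng(42)
        values = rng.standard_normal(200)
        df = pd.DataFrame({"x": values})
        prof = profile_dataset(df, HypothesisConfig(
            analysis_columns=("x",), design="one_sample"))
        stat, p = stats.shapiro(values)
        assert prof.normality.statistic == pytest.approx(stat)
        assert prof.normality.p_value == pytest.approx(p)
        assert prof.normality.verdict == ("normal" if p > 0.05 else "not_normal")

    def test_paired_design_tests_the_differences(self):
        df = make_paired_dataset(15, effect=4.0, noise="heavy_tailed", seed=1)
        prof = profile_dataset(df, PAIRED)
        d = (df["after"] - df["before"]).to_numpy(dtype=float)
        stat, p = stats.shapiro(d)
        assert prof.normality.on == "differences(after-before)"
        assert prof.normality.statistic == pytest.approx(stat)
        assert prof.normality.verdict == "not_normal"
        assert prof.dependent and prof.n_samples == 2

    def test_small_sample_is_flagged_in_justification(self):
        df = make_paired_dataset(15, noise="normal", seed=0)
        prof = profile_dataset(df, PAIRED)
        assert "n < 30" in prof.derived_answers["q_normal"][1]

    def test_type_one_error_calibration(self):
        """Fraction of normal n=30 samples judged non-normal ~ alpha."""
        rng = np.random.default_rng(2024)
        rejections = 0
        n_sim = 1000
        for _ in range(n_sim):
            df = pd.DataFrame({"x": rng.standard_normal(30)})
            prof = profile_dataset(df, HypothesisConfig(
                analysis_columns=("x",), design="one_sample"))
            rejections += prof.normality.verdict == "not_normal"
        assert abs(rejections / n_sim - 0.05) <= 0.02


class TestTreeDriving:
    def test_blood_pressure_scenario_reaches_wilcoxon_or_sign(self, kb):
        df = make_paired_dataset(15, effect=4.0, noise="heavy_tailed", seed=1)
        prof = profile_dataset(df, PAIRED)
        vector, trace = answers_from_profile(prof, kb)
        assert trace.outcome.label(kb) == \
            "Wilcoxon signed rank test or Sign test"
        assert len(trace.steps) == 7
        assert all(s.justification for s in trace.steps)

    def test_outcome_equals_run_answers_on_extracted_vector(self, kb):
        """The profiler adds no routing logic of its own."""
        df = make_paired_dataset(40, effect=1.0, noise="normal", seed=5)
        prof = profile_dataset(df, PAIRED)
        vector, trace = answers_from_profile(prof, kb)
        assert run_answers(kb, vector).outcome.id == trace.outcome.id

    def test_independent_variant_reaches_mann_whitney(self, kb):
        """Same non-normal two-sample facts, independent groups."""
        df = make_paired_dataset(15, effect=4.0, noise="heavy_tailed", seed=1)
        long = pd.DataFrame({
            "bp": np.r_[df["before"].to_numpy(), df["after"].to_numpy()],
            "grp": ["pre"] * 15 + ["post"] * 15,
        })
        prof = profile_dataset(long, HypothesisConfig(
            analysis_columns=("bp",), group_column="grp",
            design="independent_groups"))
        assert not prof.dependent
        # force the same non-normal verdict side of the branch if needed
        if prof.normality.is_normal:
            pytest.skip("pooled sample happened to look normal")
        vector, trace = answers_from_profile(prof, kb)
        assert "Mann-Whitney U test" in trace.outcome.label(kb)

    def test_count_data_without_person_time_config_is_unanswerable(self, kb):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame({"events": rng.poisson(0.8, size=40) + 0.0})
        cfg = HypothesisConfig(analysis_columns=("events",),
                               design="one_sample")
        prof = profile_dataset(counts, cfg)
        assert "q_person_time" not in prof.derived_answers
        with pytest.raises(UnanswerableQuestionError) as exc:
            answers_from_profile(prof, kb)
        assert exc.value.question_id == "q_person_time"

    def test_person_time_config_unblocks_the_question(self, kb):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame({"events": rng.poisson(0.8, size=40) + 0.0})
        cfg = HypothesisConfig(analysis_columns=("events",),
                               design="one_sample", person_time=False,
                               extra_answers={"q_count_rare": True})
        prof = profile_dataset(counts, cfg)
        vector, trace = answers_from_profile(prof, kb)
        assert trace.outcome.id == "r_one_sample_poisson"

    def test_profiling_is_deterministic(self, kb):
        df = make_paired_dataset(15, effect=4.0, noise="heavy_tailed", seed=1)
        v1, t1 = answers_from_profile(profile_dataset(df, PAIRED), kb)
        v2, t2 = answers_from_profile(profile_dataset(df, PAIRED), kb)
        assert v1 == v2 and t1.outcome.id == t2.outcome.id
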