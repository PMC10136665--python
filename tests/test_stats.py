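"""Paired nonparametric statistics against brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from odorans import (
    kendall_correlation,
    normality_check,
    paired_wilcoxon,
    score_identification,
)
from odorans.protocol import DEFAULT_STIMULUS_LABELS
from odorans.stats import (
    compare_phases,
    compare_sessions,
    significance_marker,
    validate_feature_table,
)
from odorans.errors import (
    ConfigurationError,
    DegenerateSampleError,
    InsufficientDataError,
    NoInformationError,
)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def wilcoxon_exact_enumeration(diffs):
    """Two-sided signed-rank p by enumerating all 2^n sign assignments.

    Independent of any scipy code path: ranks |d|, computes the observed
    positive-rank sum W+, and counts assignments whose min(W+, W-) is at
    least as extreme.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = pd.Series(np.abs(d)).rank().to_numpy()
    w_obs = min(ranks[d > 0].sum(), ranks[d < 0].sum())
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w_plus = sum(r for r, s in zip(ranks, signs) if s)
        if min(w_plus, ranks.sum() - w_plus) <= w_obs + 1e-9:
            count += 1
    return count / 2**n


def kendall_tau_enumeration(x, y):
    """tau-a by exhaustive concordant/discordant pair counting (no ties)."""
    n = len(x)
    c = d = 0
    for i in range(n):
        for j in range(i + 1, n):
            s = np.sign((x[i] - x[j]) * (y[i] - y[j]))
            c += s > 0
            d += s < 0
    return (c - d) / (n * (n - 1) / 2)


# ---------------------------------------------------------------------------
# elementary tests
# ---------------------------------------------------------------------------

class TestNormalityCheck:
    def test_constant_sample_degenerate(self):
        with pytest.raises(DegenerateSampleError):
            normality_check([1.0] * 10)

    def test_bounds_on_sample_size(self):
        with pytest.raises(InsufficientDataError):
            normality_check([1.0, 2.0])

    def test_type_one_rate_near_nominal_for_gaussian_data(self):
        rng = np.random.default_rng(0)
        rejections = sum(
            not normality_check(rng.standard_normal(100))[2] for _ in range(500)
        )
        assert 0.03 <= rejections / 500 <= 0.07

    def test_power_against_exponential(self):
        rng = np.random.default_rng(1)
        rejections = sum(
            not normality_check(rng.exponential(size=50))[2] for _ in range(100)
        )
        assert rejections / 100 > 0.5


class TestPairedWilcoxon:
    def test_eleven_consistent_increases_exact_p(self):
        """All 11 differences positive: the only equally extreme assignments
        are all-plus and all-minus, so p = 2/2^11."""
        t0 = np.arange(11, dtype=float)
        t1 = t0 + np.linspace(1, 2, 11)
        _, p, n = paired_wilcoxon(t0, t1)
        assert n == 11
        assert p == pytest.approx(2 / 2048, rel=1e-9)

    @pytest.mark.parametrize("n", [6, 9, 12])
    def test_matches_enumeration_oracle(self, n):
        rng = np.random.default_rng(n)
        d = rng.standard_normal(n) + 0.4
        _, p, _ = paired_wilcoxon(np.zeros(n), d)
        assert p == pytest.approx(wilcoxon_exact_enumeration(d), abs=1e-12)

    def test_identical_sessions_carry_no_information(self):
        v = np.arange(8, dtype=float)
        with pytest.raises(NoInformationError):
            paired_wilcoxon(v, v)

    def test_two_sided_symmetry_under_session_swap(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=10), rng.normal(size=10)
        assert paired_wilcoxon(a, b)[1] == pytest.approx(
            paired_wilcoxon(b, a)[1], rel=1e-12
        )

    def test_too_few_nonzero_differences(self):
        with pytest.raises(InsufficientDataError):
            paired_wilcoxon([1, 1, 1, 1, 1, 1], [1, 1, 1, 1, 1, 2])


class TestKendall:
    def test_monotone_sequences(self):
        x = [1.0, 2.0, 3.0, 5.0]
        assert kendall_correlation(x, [2.0, 3.0, 8.0, 9.0])[0] == pytest.approx(1.0)
        assert kendall_correlation(x, [9.0, 8.0, 3.0, 2.0])[0] == pytest.approx(-1.0)

    def test_matches_pair_enumeration(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 3.0, 2.0, 4.0])
        tau, _ = kendall_correlation(x, y)
        assert tau == pytest.approx(kendall_tau_enumeration(x, y))
        rng = np.random.default_rng(2)
        for _ in range(10):
            xv, yv = rng.normal(size=8), rng.normal(size=8)
            assert kendall_correlation(xv, yv)[0] == pytest.approx(
                kendall_tau_enumeration(xv, yv), abs=1e-12
            )

    def test_constant_vector_undefined(self):
        with pytest.raises(DegenerateSampleError):
            kendall_correlation([1, 1, 1, 1], [1, 2, 3, 4])


# ---------------------------------------------------------------------------
# comparison tables
# ---------------------------------------------------------------------------

def _long_table(values):
    """values: {(subject, session, phase, feature): value}"""
    return pd.DataFrame(
        [
            {"subject": s, "session": ses, "phase": ph, "feature": f, "value": v}
            for (s, ses, ph, f), v in values.items()
        ]
    )


def _paired_cohort(feature, t0_values, t1_values, phase="Baseline"):
    vals = {}
    for i, (a, b) in enumerate(zip(t0_values, t1_values)):
        vals[(f"S{i}", "T0", phase, feature)] = a
        vals[(f"S{i}", "T1", phase, feature)] = b
    return _long_table(vals)


class TestCompareSessions:
    def test_single_feature_single_row_with_consistent_marker(self):
        rng = np.random.default_rng(3)
        t0 = rng.normal(70, 5, size=11)
        table = _paired_cohort("HR", t0, t0 - 6.0)
        out = compare_sessions(table)
        assert len(out) == 1
        row = out.iloc[0]
        assert row["n_pairs"] == 11
        assert row["mean_t1"] < row["mean_t0"]
        assert row["p_value"] == pytest.approx(2 / 2048, rel=1e-9)
        assert row["marker"] == "**"

    def test_sample_sd_convention(self):
        t0 = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        table = _paired_cohort("HR", t0, t0 + 1)
        out = compare_sessions(table)
        assert out.iloc[0]["sd_t0"] == pytest.approx(np.std(t0, ddof=1))

    def test_insufficient_pairs_yield_missing_p(self):
        t0 = np.array([1.0, 2.0, 3.0])
        out = compare_sessions(_paired_cohort("HR", t0, t0 + 1))
        assert np.isnan(out.iloc[0]["p_value"])
        assert out.iloc[0]["marker"] == ""

    def test_duplicate_rows_rejected(self):
        table = _paired_cohort("HR", [1.0], [2.0])
        dup = pd.concat([table, table])
        with pytest.raises(ConfigurationError):
            validate_feature_table(dup)

    def test_feature_rows_ordered_cardiac_then_conductance(self):
        vals = {}
        for i in range(6):
            for ses, off in [("T0", 0.0), ("T1", 1.0)]:
                vals[(f"S{i}", ses, "Baseline", "Tonic")] = 1.0 + i + off
                vals[(f"S{i}", ses, "Baseline", "HR")] = 70.0 + i - off
        out = compare_sessions(_long_table(vals))
        assert list(out["feature"]) == ["HR", "Tonic"]


class TestComparePhases:
    def test_task_elevated_hr_flagged(self):
        rng = np.random.default_rng(4)
        base = rng.normal(70, 5, size=11)
        vals = {}
        for i, b in enumerate(base):
            vals[(f"S{i}", "T0", "Baseline", "HR")] = b
            vals[(f"S{i}", "T0", "Task", "HR")] = b + 5.0
            vals[(f"S{i}", "T0", "Recovery", "HR")] = b + rng.normal(0, 0.5)
        out = compare_phases(_long_table(vals), "T0")
        bt = out[out["phase"] == "Baseline vs Task"].iloc[0]
        assert bt["p_value"] < 0.05
        assert bt["mean_t1"] > bt["mean_t0"]  # Task above Baseline

    def test_identical_phases_give_missing_p(self):
        vals = {}
        for i in range(8):
            for ph in ("Baseline", "Task"):
                vals[(f"S{i}", "T0", ph, "HR")] = 70.0 + i
        out = compare_phases(_long_table(vals), "T0", pairs=(("Baseline", "Task"),))
        assert np.isnan(out.iloc[0]["p_value"])


class TestMarkers:
    @pytest.mark.parametrize(
        "p, expected",
        [(0.004, "**"), (0.03, "*"), (0.05, ""), (0.3, ""), (np.nan, "")],
    )
    def test_thresholds(self, p, expected):
        assert significance_marker(p) == expected

    def test_double_marker_implies_single(self):
        for p in np.linspace(0.001, 0.2, 50):
            m = significance_marker(p)
            if m == "**":
                assert p < 0.01
            if m:
                assert p < 0.05


class TestIdentification:
    def test_perfect_and_null_scores(self):
        key = DEFAULT_STIMULUS_LABELS
        responses = {
            "S1": {"T0": list(key), "T1": ["nothing"] * 10},
        }
        score = score_identification(responses, key)
        t0 = score.counts.query("session == 'T0'")["correct"].iloc[0]
        t1 = score.counts.query("session == 'T1'")["correct"].iloc[0]
        assert t0 == 10 and t1 == 0

    def test_partial_score_and_cohort_mean(self):
        key = DEFAULT_STIMULUS_LABELS
        four_right = list(key[:4]) + ["wrong"] * 6
        responses = {
            "S1": {"T0": four_right},
            "S2": {"T0": list(key[:6]) + ["wrong"] * 4},
        }
        score = score_identification(responses, key)
        assert sorted(score.counts["correct"]) == [4, 6]
        assert score.summary.iloc[0]["mean"] == pytest.approx(5.0)

    def test_case_insensitive_and_synonyms(self):
        key = ("Rose", "Fig")
        responses = {"S1": {"T0": ["ROSE", "dried fig"]}}
        score = score_identification(responses, key, synonyms={"dried fig": "fig"})
        assert score.counts["correct"].iloc[0] == 2

    def test_paired_improvement_p_value(self):
        key = DEFAULT_STIMULUS_LABELS
        responses = {}
        for i in range(11):
            k = 3 + (i % 3)
            responses[f"S{i}"] = {
                "T0": list(key[:k]) + ["wrong"] * (10 - k),
                "T1": list(key[: k + 2]) + ["wrong"] * (8 - k),
            }
        score = score_identification(responses, key)
        assert score.p_value < 0.05
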