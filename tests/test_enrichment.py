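import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_design, make_matrix

from ipqms import ValidationError
from ipqms.enrichment import (
    ComparisonSpec,
    Thresholds,
    bait_normalize,
    differential_enrichment,
    igg_filter,
    intersect_for_comparison,
    run_comparison,
    significant_counts,
)
from ipqms.ingest import impute_lowest_detected
from ipqms.simulate import simulate_ip_experiment, study_like_config


def welch_oracle(x, y):
    """Textbook Welch t-test: statistic, Welch-Satterthwaite df, p."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = len(x), len(y)
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    return t, 2.0 * stats.t.sf(abs(t), df)


def bh_oracle(p):
    """Step-up BH: sort, p*m/rank, cumulative minimum from the right."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


class TestIgGFilter:
    def _matrix(self, values):
        return make_matrix(values, make_design(n_reps=3, igg_reps=3))

    def test_fold_change_arithmetic(self):
        matrix = self._matrix({"P1": [3.0, 3.0, 3.0, 1.0, 1.0, 1.0]})
        retained, fc = igg_filter(matrix, ("BRG1", "MLS"))
        assert fc["P1"] == pytest.approx(3.0)
        assert retained == {"P1"}

    def test_boundary_exactly_threshold_is_kept(self):
        # the rule removes strictly below the cutoff
        matrix = self._matrix({"P1": [1.5, 1.5, 1.5, 1.0, 1.0, 1.0]})
        retained, fc = igg_filter(matrix, ("BRG1", "MLS"), igg_fc_min=1.5)
        assert fc["P1"] == pytest.approx(1.5)
        assert "P1" in retained

    def test_below_threshold_removed(self):
        matrix = self._matrix({"P1": [1.4, 1.4, 1.4, 1.0, 1.0, 1.0]})
        retained, _ = igg_filter(matrix, ("BRG1", "MLS"))
        assert retained == set()

    def test_null_simulation_matches_bruteforce_recount(self, catalog):
        config = study_like_config(n_proteins=500, seed=17)
        matrix, _ = simulate_ip_experiment(config, catalog)
        matrix = impute_lowest_detected(matrix)
        retained, fc = igg_filter(matrix, ("BRG1", "MLS"), igg_fc_min=1.5)
        ip_cols = matrix.design.samples_for("BRG1", "MLS")
        igg_cols = matrix.design.igg_samples("MLS")
        oracle = {
            p
            for p in matrix.proteins
            if matrix.values.loc[p, ip_cols].mean()
            / matrix.values.loc[p, igg_cols].mean()
            >= 1.5
        }
        assert retained == oracle


class TestIntersect:
    def test_toy(self):
        assert intersect_for_comparison({"A", "B", "C"}, {"B", "C", "D"}) == {"B", "C"}

    def test_identity(self):
        s = {"A", "B"}
        assert intersect_for_comparison(s, set(s)) == s

    def test_empty_errors(self):
        with pytest.raises(ValidationError, match="empty"):
            intersect_for_comparison({"A"}, {"B"})


class TestBaitNormalize:
    def test_bait_row_becomes_one(self):
        design = make_design(n_reps=2, igg_reps=2)
        matrix = make_matrix(
            {"BRG1": [2.0, 4.0, 1.0, 1.0], "P1": [4.0, 8.0, 1.0, 1.0]}, design
        )
        normalized = bait_normalize(matrix, "BRG1")
        assert (normalized.values.loc["BRG1"] == 1.0).all()
        assert (normalized.values.loc["P1"] == [2.0, 2.0, 1.0, 1.0]).all()
        assert normalized.provenance == "normalized"

    def test_equals_elementwise_oracle(self, catalog):
        matrix, _ = simulate_ip_experiment(
            study_like_config(n_proteins=100, seed=19), catalog
        )
        matrix = impute_lowest_detected(matrix)
        normalized = bait_normalize(matrix, "BRG1")
        oracle = matrix.values / matrix.values.loc["BRG1"]
        pd.testing.assert_frame_equal(normalized.values, oracle)

    def test_zero_bait_names_replicate(self):
        design = make_design(n_reps=2, igg_reps=2)
        matrix = make_matrix(
            {"BRG1": [2.0, 0.0, 1.0, 1.0], "P1": [1, 1, 1, 1]}, design
        )
        with pytest.raises(ValidationError, match="BRG1_MLS_r2"):
            bait_normalize(matrix, "BRG1")

    def test_restricted_columns_pass_through(self):
        design = make_design(n_reps=2, igg_reps=2)
        matrix = make_matrix(
            {"BRG1": [2.0, 4.0, 5.0, 5.0], "P1": [4.0, 8.0, 7.0, 7.0]}, design
        )
        ip_cols = design.samples_for("BRG1", "MLS")
        normalized = bait_normalize(matrix, "BRG1", samples=ip_cols)
        igg_cols = design.igg_samples("MLS")
        assert (normalized.values.loc["P1", igg_cols] == [7.0, 7.0]).all()


def _blocks(a_rows, b_rows, index=None):
    index = index or [f"P{i}" for i in range(len(a_rows))]
    return (
        pd.DataFrame(a_rows, index=index),
        pd.DataFrame(b_rows, index=index),
    )


class TestDifferentialEnrichment:
    def test_mean_ratio_arithmetic(self):
        a, b = _blocks([[1.0, 1.2, 1.4]], [[0.5, 0.6, 0.7]])
        table = differential_enrichment(a, b)
        assert table["fold_change"].iloc[0] == pytest.approx(2.0)

    def test_swap_inverts_fold_change_preserves_p(self):
        rng = np.random.default_rng(5)
        a = pd.DataFrame(rng.lognormal(0, 0.3, (50, 3)))
        b = pd.DataFrame(rng.lognormal(0.2, 0.3, (50, 3)))
        ab = differential_enrichment(a, b)
        ba = differential_enrichment(b, a)
        np.testing.assert_allclose(
            ab["fold_change"], 1.0 / ba["fold_change"], rtol=1e-12
        )
        np.testing.assert_allclose(ab["p_value"], ba["p_value"], rtol=1e-12)
        swapped = ba["significant_in"].map({"a": "b", "b": "a", "none": "none"})
        assert (ab["significant_in"] == swapped).all()

    def test_welch_matches_textbook_oracle(self):
        rng = np.random.default_rng(7)
        a = pd.DataFrame(rng.lognormal(0, 0.4, (200, 4)))
        b = pd.DataFrame(rng.lognormal(0.1, 0.2, (200, 3)))
        table = differential_enrichment(a, b)
        for i in range(len(table)):
            _, p = welch_oracle(a.iloc[i], b.iloc[i])
            assert table["p_value"].iloc[i] == pytest.approx(p, abs=1e-12)

    def test_fdr_matches_bh_oracle_and_dominates_p(self):
        rng = np.random.default_rng(8)
        a = pd.DataFrame(rng.lognormal(0, 0.4, (300, 3)))
        b = pd.DataFrame(rng.lognormal(0, 0.4, (300, 3)))
        table = differential_enrichment(a, b)
        np.testing.assert_allclose(
            table["fdr"], bh_oracle(table["p_value"].to_numpy()), atol=1e-12
        )
        assert (table["fdr"] >= table["p_value"] - 1e-15).all()

    def test_degenerate_zero_variance_equal_means(self):
        a, b = _blocks([[1.0, 1.0, 1.0]], [[1.0, 1.0, 1.0]])
        table = differential_enrichment(a, b)
        assert table["degenerate"].iloc[0]
        assert table["p_value"].iloc[0] == 1.0
        assert table["significant_in"].iloc[0] == "none"

    def test_zero_denominator_flagged_out(self):
        a, b = _blocks([[1.0, 1.1, 0.9]], [[0.0, 0.0, 0.0]])
        table = differential_enrichment(a, b)
        assert np.isnan(table["fold_change"].iloc[0])
        assert table["significant_in"].iloc[0] == "none"

    def test_significance_requires_both_fc_and_p(self):
        # large fold change but tiny replicate support -> p too big
        a, b = _blocks([[10.0, 0.1, 5.0]], [[1.0, 1.0, 1.0]])
        table = differential_enrichment(a, b)
        assert table["significant_in"].iloc[0] == "none"

    def test_mismatched_index_errors(self):
        a = pd.DataFrame([[1.0, 2.0]], index=["X"])
        b = pd.DataFrame([[1.0, 2.0]], index=["Y"])
        with pytest.raises(ValidationError, match="index"):
            differential_enrichment(a, b)

    def test_single_replicate_errors(self):
        a = pd.DataFrame([[1.0]])
        b = pd.DataFrame([[1.0, 2.0]])
        with pytest.raises(ValidationError, match="replicates"):
            differential_enrichment(a, b)

    def test_monotone_in_fc_threshold(self):
        rng = np.random.default_rng(9)
        a = pd.DataFrame(rng.lognormal(0.3, 0.3, (200, 3)))
        b = pd.DataFrame(rng.lognormal(0.0, 0.3, (200, 3)))
        previous = None
        for fc_min in (1.0, 1.2, 1.5, 2.0, 3.0):
            table = differential_enrichment(a, b, Thresholds(comparison_fc_min=fc_min))
            counts = significant_counts(table)
            if previous is not None:
                assert counts[0] <= previous[0]
                assert counts[1] <= previous[1]
            previous = counts

    def test_log_scale_option(self):
        rng = np.random.default_rng(10)
        a = pd.DataFrame(rng.lognormal(0.5, 0.3, (50, 3)))
        b = pd.DataFrame(rng.lognormal(0.0, 0.3, (50, 3)))
        linear = differential_enrichment(a, b, Thresholds(log_scale=False))
        logged = differential_enrichment(a, b, Thresholds(log_scale=True))
        # fold changes identical, p-values differ
        np.testing.assert_allclose(linear["fold_change"], logged["fold_change"])
        assert not np.allclose(linear["p_value"], logged["p_value"])
        for i in range(10):
            _, p = welch_oracle(np.log2(a.iloc[i]), np.log2(b.iloc[i]))
            assert logged["p_value"].iloc[i] == pytest.approx(p, abs=1e-12)


class TestSignificantCounts:
    def test_none_pass(self):
        a, b = _blocks([[1.0, 1.0, 1.1]] * 3, [[1.0, 1.0, 1.1]] * 3)
        table = differential_enrichment(a, b)
        assert significant_counts(table) == (0, 0)

    def test_bait_excluded(self):
        table = pd.DataFrame(
            {"significant_in": ["a", "a", "b"]}, index=["BRG1", "P1", "P2"]
        )
        assert significant_counts(table, bait="BRG1") == (1, 1)
        assert significant_counts(table) == (2, 1)


class TestRunComparison:
    def test_planted_enrichment_detected(self, catalog):
        config = study_like_config(
            n_proteins=800,
            seed=23,
            planted_enrichment={"interactor": {"DDIT3:MLS": 40.0}},
        )
        matrix, truth = simulate_ip_experiment(config, catalog)
        matrix = impute_lowest_detected(matrix)
        result = run_comparison(
            matrix, ComparisonSpec(("DDIT3", "MLS"), ("BRG1", "MLS")), "BRG1"
        )
        interactors = set(truth.index[truth["true_class"] == "interactor"])
        sig_a = set(result.table.index[result.table["significant_in"] == "a"])
        # planted 10x fold change dwarfs replicate noise: most recovered
        assert len(sig_a & interactors) / len(interactors & result.compared) > 0.8

    def test_bait_always_compared_with_unit_fc(self, catalog):
        matrix, _ = simulate_ip_experiment(
            study_like_config(n_proteins=200, seed=29), catalog
        )
        matrix = impute_lowest_detected(matrix)
        result = run_comparison(
            matrix, ComparisonSpec(("DDIT3", "MLS"), ("BRG1", "MLS")), "BRG1"
        )
        assert "BRG1" in result.compared
        assert result.table.loc["BRG1", "fold_change"] == pytest.approx(1.0)

    def test_compared_set_is_intersection(self, catalog):
        matrix, _ = simulate_ip_experiment(
            study_like_config(n_proteins=300, seed=31), catalog
        )
        matrix = impute_lowest_detected(matrix)
        spec = ComparisonSpec(("BRG1", "MLS"), ("BRG1", "EWS"))
        result = run_comparison(matrix, spec, "BRG1")
        assert result.compared == result.retained_a & result.retained_b
        assert set(result.table.index) == result.compared

    def test_same_sides_rejected(self):
        with pytest.raises(ValidationError, match="differ"):
            ComparisonSpec(("BRG1", "MLS"), ("BRG1", "MLS"))
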