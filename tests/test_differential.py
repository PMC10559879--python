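import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from redoxtmt import (
    FoldChangeMatrix,
    ValidationError,
    benjamini_hochberg,
    compute_fold_changes,
    filter_min_replicates,
    invert_overall_oxidation,
    median_normalize,
    normalize_site_to_protein,
    rollup_sites,
    summarize_counts,
)
from redoxtmt import test_differential as differential_test

from conftest import make_peptide_table


def fc_matrix(values, entities=None, layer="proteome", timepoint="4h", **flags):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n = values.shape[1]
    cols = pd.MultiIndex.from_tuples(
        [(1, i + 1) for i in range(n)], names=["run", "replicate"]
    )
    entities = entities or [f"E{i}" for i in range(values.shape[0])]
    return FoldChangeMatrix(
        layer=layer, timepoint=timepoint,
        values=pd.DataFrame(values, index=entities, columns=cols), **flags,
    )


class TestFoldChanges:
    @pytest.mark.parametrize(
        "treated,control,expected",
        [(200.0, 100.0, 1.0), (100.0, 100.0, 0.0), (50.0, 100.0, -1.0)],
    )
    def test_log2_ratio(self, mini_design, treated, control, expected):
        rows = [("prot-1", "P1", "AAAK", "", {"126": control, "127": treated})]
        q = rollup_sites(
            make_peptide_table(rows, ["126", "127", "128", "129"]),
            mini_design, "proteome",
        )
        fc = compute_fold_changes(q, mini_design, "4h")
        assert fc.values.loc["P1"].iloc[0] == pytest.approx(expected)

    def test_zero_control_is_missing(self, mini_design):
        rows = [("prot-1", "P1", "AAAK", "", {"126": 0.0, "127": 100.0})]
        q = rollup_sites(
            make_peptide_table(rows, ["126", "127", "128", "129"]),
            mini_design, "proteome",
        )
        fc = compute_fold_changes(q, mini_design, "4h")
        assert len(fc.values) == 0  # all-missing entities are dropped

    def test_unknown_timepoint_rejected(self, mini_design):
        rows = [("prot-1", "P1", "AAAK", "", {"126": 1.0, "127": 1.0})]
        q = rollup_sites(
            make_peptide_table(rows, ["126", "127", "128", "129"]),
            mini_design, "proteome",
        )
        with pytest.raises(ValidationError, match="absent from design"):
            compute_fold_changes(q, mini_design, "48h")


class TestFilter:
    def test_below_threshold_removed_and_boundary_kept(self):
        row_2 = [0.1, 0.2] + [np.nan] * 10
        row_3 = [0.1, 0.2, 0.3] + [np.nan] * 9
        fc = filter_min_replicates(fc_matrix([row_2, row_3]), k=3)
        assert list(fc.values.index) == ["E1"]

    def test_k1_keeps_all_observed(self):
        fc = filter_min_replicates(
            fc_matrix([[0.1] + [np.nan] * 11, [np.nan] * 12]), k=1
        )
        assert list(fc.values.index) == ["E0"]

    def test_k0_rejected(self):
        with pytest.raises(ValidationError):
            filter_min_replicates(fc_matrix([[0.1, 0.2]]), k=0)


class TestMedianNormalize:
    def test_median_subtraction(self):
        fc = median_normalize(
            fc_matrix([[1.0], [0.5], [-0.5]], entities=["a", "b", "c"])
        )
        assert fc.values.to_numpy().ravel().tolist() == [0.5, 0.0, -1.0]

    def test_idempotent_on_centered_data(self):
        fc = fc_matrix([[1.0], [0.0], [-1.0]])
        out = median_normalize(median_normalize(fc))
        assert np.allclose(out.values, median_normalize(fc).values)

    def test_single_entity_column_becomes_zero(self):
        fc = median_normalize(fc_matrix([[0.7]]))
        assert fc.values.iloc[0, 0] == 0.0

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(0, 2**31 - 1))
    def test_postcondition_zero_median(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.normal(size=(rng.integers(1, 30), rng.integers(1, 12)))
        fc = median_normalize(fc_matrix(values))
        assert np.allclose(fc.values.median(axis=0), 0.0, atol=1e-9)


class TestInversion:
    def test_negates_and_keeps_layer(self):
        fc = invert_overall_oxidation(fc_matrix([[0.5, 0.0]], layer="ox_all"))
        assert fc.layer == "ox_all"
        assert fc.values.to_numpy().ravel().tolist() == [-0.5, 0.0]

    def test_involution_with_guard_off(self):
        fc = fc_matrix([[0.5, -0.3]], layer="ox_all")
        twice = invert_overall_oxidation(
            invert_overall_oxidation(fc), enforce_once=False
        )
        assert np.allclose(twice.values, fc.values)

    def test_double_application_guarded(self):
        once = invert_overall_oxidation(fc_matrix([[0.5]], layer="ox_all"))
        with pytest.raises(ValidationError, match="already inverted"):
            invert_overall_oxidation(once)

    def test_wrong_layer_rejected(self):
        with pytest.raises(ValidationError, match="ox_all"):
            invert_overall_oxidation(fc_matrix([[0.5]], layer="ox_rev"))


class TestProteinNormalization:
    def test_log_space_subtraction_and_cancellation(self):
        site = fc_matrix([[1.2], [0.5]], entities=["P1_C5", "P2_S9"], layer="phospho")
        prot = fc_matrix([[1.0], [0.5]], entities=["P1", "P2"], layer="proteome")
        out = normalize_site_to_protein(site, prot)
        assert out.values.loc["P1_C5"].iloc[0] == pytest.approx(0.2)
        assert out.values.loc["P2_S9"].iloc[0] == pytest.approx(0.0)

    def test_unquantified_parent_dropped(self):
        site = fc_matrix([[1.2]], entities=["P9_C5"], layer="ox_rev")
        prot = fc_matrix([[1.0]], entities=["P1"], layer="proteome")
        out = normalize_site_to_protein(site, prot)
        assert len(out.values) == 0

    def test_layer_mismatch_rejected(self):
        prot = fc_matrix([[1.0]], entities=["P1"], layer="proteome")
        with pytest.raises(ValidationError, match="not a PTM layer"):
            normalize_site_to_protein(prot, prot)


class TestBenjaminiHochberg:
    def test_worked_example(self):
        assert np.allclose(
            benjamini_hochberg([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04]
        )

    def test_nan_excluded_from_family(self):
        out = benjamini_hochberg([0.01, np.nan, 0.02])
        assert np.isnan(out[1])
        assert np.allclose(out[[0, 2]], [0.02, 0.02])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12))
    def test_matches_statsmodels(self, pvals):
        from statsmodels.stats.multitest import multipletests

        expected = multipletests(pvals, method="fdr_bh")[1]
        assert np.allclose(benjamini_hochberg(np.array(pvals)), expected, atol=1e-12)


class TestDifferentialTest:
    def test_three_replicate_worked_example(self):
        res = differential_test(fc_matrix([[0.5, 0.7, 0.9]]))
        t = 0.7 / (0.2 / math.sqrt(3))
        # closed-form t CDF for df = 2: F(t) = 1/2 (1 + t / sqrt(2 + t^2))
        p = 1.0 - t / math.sqrt(2.0 + t * t)
        assert res["log2fc_mean"].iloc[0] == pytest.approx(0.7)
        assert res["t_stat"].iloc[0] == pytest.approx(t)
        assert res["p"].iloc[0] == pytest.approx(p, abs=1e-12)
        assert res["p"].iloc[0] == pytest.approx(0.0262, abs=2e-4)

    def test_zero_variance_excluded(self):
        res = differential_test(fc_matrix([[0.0, 0.0, 0.0], [0.1, 0.5, 0.9]]))
        degenerate = res.set_index("entity").loc["E0"]
        assert np.isnan(degenerate["p"]) and not degenerate["significant"]
        assert not np.isnan(res.set_index("entity").loc["E1", "p"])

    def test_matches_scipy_ttest(self):
        rng = np.random.default_rng(4)
        values = rng.normal(0.2, 0.5, size=(20, 8))
        res = differential_test(fc_matrix(values))
        ref = stats.ttest_1samp(values, 0.0, axis=1)
        assert np.allclose(res["t_stat"], ref.statistic, atol=1e-12)
        assert np.allclose(res["p"], ref.pvalue, atol=1e-12)

    def test_unfiltered_input_rejected(self):
        with pytest.raises(ValidationError, match="filter"):
            differential_test(fc_matrix([[0.5] + [np.nan] * 11]))

    def test_entity_order_invariance(self):
        rng = np.random.default_rng(9)
        values = rng.normal(size=(15, 6))
        fc = fc_matrix(values)
        perm = rng.permutation(15)
        fc_perm = fc_matrix(values[perm], entities=[f"E{i}" for i in perm])
        a = differential_test(fc).set_index("entity").sort_index()
        b = differential_test(fc_perm).set_index("entity").sort_index()
        pd.testing.assert_frame_equal(a, b)


class TestSummarizeCounts:
    def _res(self, means, significant):
        return pd.DataFrame(
            {
                "entity": [f"E{i}" for i in range(len(means))],
                "layer": "proteome",
                "timepoint": "4h",
                "log2fc_mean": means,
                "significant": significant,
            }
        )

    def test_up_down_counting(self):
        counts = summarize_counts(self._res([1.0, -1.0, 2.0], [True, True, False]))
        assert counts[["n_up", "n_down"]].iloc[0].tolist() == [1, 1]

    def test_no_significant(self):
        counts = summarize_counts(self._res([1.0], [False]))
        assert counts[["n_up", "n_down"]].iloc[0].tolist() == [0, 0]

    def test_exact_zero_counted_in_neither(self):
        counts = summarize_counts(self._res([0.0], [True]))
        assert counts[["n_up", "n_down"]].iloc[0].tolist() == [0, 0]
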