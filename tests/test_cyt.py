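"""TPM normalization, cytolytic index, quartile strata, group comparisons."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crcyt.cyt import bh_adjust, compare_cyt_groups, compare_groups, compute_cyt, compute_tpm, stratify_cyt
from crcyt.io import ExpressionMatrix, ValidationError


def _expr(counts, lengths, samples=None):
    samples = samples or [f"S{i}" for i in range(np.asarray(counts).shape[1])]
    genes = [f"g{i}" for i in range(np.asarray(counts).shape[0])]
    meta = pd.DataFrame({"tissue": "tumor", "dataset": "COAD"}, index=pd.Index(samples, name="sample_id"))
    return ExpressionMatrix(
        counts=pd.DataFrame(counts, index=pd.Index(genes, name="gene"), columns=samples),
        lengths=pd.Series(lengths, index=genes),
        sample_meta=meta,
    )


class TestTpm:
    def test_equal_coverages_split_evenly(self):
        expr = _expr([[10], [20], [30]], [1000, 2000, 3000])
        tpm = compute_tpm(expr, offset=0.0)
        np.testing.assert_allclose(tpm.tpm.iloc[:, 0], 1e6 / 3)

    def test_single_gene_forced_to_1e6(self):
        expr = _expr([[17]], [500])
        tpm = compute_tpm(expr, offset=0.01)
        assert tpm.tpm.iloc[0, 0] == pytest.approx(1e6 + 0.01)

    def test_zero_count_gene_gets_exact_offset(self):
        expr = _expr([[0], [10]], [1000, 1000])
        tpm = compute_tpm(expr, offset=0.01)
        assert tpm.tpm.iloc[0, 0] == 0.01

    def test_columns_sum_to_1e6_before_offset(self, small_cohort):
        expr = small_cohort["expression"]
        tpm = compute_tpm(expr, offset=0.0)
        np.testing.assert_allclose(tpm.tpm.sum(axis=0), 1e6, rtol=1e-9)

    def test_all_zero_sample_rejected_by_name(self):
        with pytest.raises(ValidationError, match="S1"):
            compute_tpm(_expr([[1, 0], [2, 0]], [100, 100], ["S0", "S1"]))


class TestCyt:
    def _tpm_from(self, gzma, prf1):
        from crcyt.cyt import TpmMatrix

        df = pd.DataFrame({"S": [gzma, prf1]}, index=["GZMA", "PRF1"])
        return TpmMatrix(tpm=df, offset=0.01)

    def test_geometric_mean_of_4_and_9_is_6(self):
        assert compute_cyt(self._tpm_from(4, 9))["cyt_raw"].iloc[0] == pytest.approx(6)

    def test_equal_genes_idempotent(self):
        assert compute_cyt(self._tpm_from(7.3, 7.3))["cyt_raw"].iloc[0] == pytest.approx(7.3)

    def test_reciprocal_pair_gives_unity(self):
        assert compute_cyt(self._tpm_from(100, 0.01))["cyt_raw"].iloc[0] == pytest.approx(1)

    def test_missing_gene_named(self, small_cohort):
        tpm = compute_tpm(small_cohort["expression"])
        with pytest.raises(ValidationError, match="NOPE"):
            compute_cyt(tpm, ["GZMA", "NOPE"])

    def test_scale_equivariance_and_am_gm(self, small_cohort):
        from crcyt.cyt import TpmMatrix

        tpm = compute_tpm(small_cohort["expression"])
        cyt = compute_cyt(tpm)
        scaled = TpmMatrix(tpm=tpm.tpm * 3.0, offset=tpm.offset)
        np.testing.assert_allclose(compute_cyt(scaled)["cyt_raw"], cyt["cyt_raw"] * 3.0)
        arith = tpm.tpm.loc[["GZMA", "PRF1"]].mean(axis=0)
        assert (cyt["cyt_raw"] <= arith + 1e-9).all()


class TestStratify:
    def test_400_distinct_values_give_100_100_200(self):
        rng = np.random.default_rng(0)
        cyt = pd.Series(rng.lognormal(3, 1, 400), index=[f"S{i:04d}" for i in range(400)])
        strat = stratify_cyt(cyt, 0.25)
        vc = strat["stratum"].value_counts()
        assert vc["CYT-high"] == 100 and vc["CYT-low"] == 100 and vc["middle"] == 200
        assert strat.loc[strat["stratum"] == "CYT-high", "cyt_raw"].min() >= \
            strat.loc[strat["stratum"] == "CYT-low", "cyt_raw"].max()

    def test_all_ties_resolved_lexicographically(self):
        cyt = pd.Series(1.0, index=[f"S{i}" for i in range(8)])
        strat = stratify_cyt(cyt, 0.25)
        assert (strat.loc[["S0", "S1"], "stratum"] == "CYT-high").all()
        assert (strat.loc[["S6", "S7"], "stratum"] == "CYT-low").all()

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        cyt = pd.Series(rng.random(40), index=[f"S{i:02d}" for i in range(40)])
        a = stratify_cyt(cyt, 0.25)["stratum"].sort_index()
        b = stratify_cyt(cyt.sample(frac=1, random_state=3), 0.25)["stratum"].sort_index()
        pd.testing.assert_series_equal(a, b)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValidationError):
            stratify_cyt(pd.Series([1.0, 2.0], index=["a", "b"]), 0.25)


class TestCompare:
    def test_identical_groups_p_is_one(self):
        vals = np.array([1.0, 2, 3, 1, 2, 3])
        groups = np.array(["a", "a", "a", "b", "b", "b"])
        _, p = compare_groups(vals, groups)
        assert p == pytest.approx(1.0)

    def test_fully_separated_groups_exact_p(self):
        # all 3 of one group below all 3 of the other: U = 0, p = 2/20
        vals = np.array([1.0, 2, 3, 10, 11, 12])
        groups = np.array(["a", "a", "a", "b", "b", "b"])
        u, p = compare_groups(vals, groups)
        assert u == 0
        assert p == pytest.approx(0.1)

    def test_three_groups_use_kruskal(self):
        rng = np.random.default_rng(0)
        vals = rng.random(30)
        groups = np.repeat(["a", "b", "c"], 10)
        stat, p = compare_groups(vals, groups)
        assert 0 <= p <= 1

    def test_small_group_rejected(self):
        with pytest.raises(ValidationError):
            compare_groups(np.array([1.0, 2, 3]), np.array(["a", "a", "b"]))

    def test_bh_step_up_hand_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_batch_comparison_shares_bh(self):
        rng = np.random.default_rng(2)
        comp = {
            f"c{i}": (rng.random(20), np.repeat(["x", "y"], 10)) for i in range(4)
        }
        out = compare_cyt_groups(comp)
        assert set(out.columns) == {"statistic", "p", "q"}
        np.testing.assert_allclose(out["q"], bh_adjust(out["p"].to_numpy()))
        assert (out["q"] >= out["p"] - 1e-12).all()


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.lists(st.floats(0.1, 1e5), min_size=9, max_size=40, unique=True))
def test_strata_sizes_and_disjointness(values):
    cyt = pd.Series(values, index=[f"S{i:03d}" for i in range(len(values))])
    strat = stratify_cyt(cyt, 0.25)
    k = int(np.floor(0.25 * len(values)))
    vc = strat["stratum"].value_counts()
    assert vc.get("CYT-high", 0) == k and vc.get("CYT-low", 0) == k
    high = strat[strat["stratum"] == "CYT-high"].index
    low = strat[strat["stratum"] == "CYT-low"].index
    assert len(high.intersection(low)) == 0
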