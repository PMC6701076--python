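"""CPM filter, Welch-t differential expression, checkpoint associations."""

import numpy as np
import pandas as pd
import pytest

from crcyt.cyt import compute_cyt, compute_tpm
from crcyt.expression import (
    checkpoint_by_msi,
    checkpoint_correlation,
    differential_expression,
    filter_low_expression,
)
from crcyt.io import ExpressionMatrix, ValidationError


def _expr(counts, samples=None):
    arr = np.asarray(counts)
    samples = samples or [f"S{i}" for i in range(arr.shape[1])]
    genes = [f"g{i}" for i in range(arr.shape[0])]
    return ExpressionMatrix(
        counts=pd.DataFrame(arr, index=pd.Index(genes, name="gene"), columns=samples),
        lengths=pd.Series(1000, index=genes),
        sample_meta=pd.DataFrame(
            {"tissue": "tumor", "dataset": "COAD"}, index=pd.Index(samples, name="sample_id")
        ),
    )


class TestFilter:
    def test_all_zero_gene_removed(self):
        expr = _expr([[0, 0], [100, 100]])
        assert "g0" not in filter_low_expression(expr).genes

    def test_boundary_exactly_half_kept(self):
        # g0 reaches 1 CPM in exactly 50% of 4 samples: kept (>= boundary)
        counts = np.array(
            [
                [100, 100, 0, 0],
                [999_900, 999_900, 1_000_000, 1_000_000],
            ]
        )
        kept = filter_low_expression(_expr(counts), cpm_threshold=1.0, sample_fraction=0.5)
        assert "g0" in kept.genes

    def test_equals_brute_force_on_fixture(self, small_cohort):
        expr = small_cohort["expression"]
        kept = filter_low_expression(expr)
        cpm = expr.counts / expr.counts.sum(axis=0) * 1e6
        expected = expr.genes[((cpm >= 1.0).mean(axis=1) >= 0.5)]
        assert list(kept.genes) == list(expected)

    def test_zero_library_rejected(self):
        with pytest.raises(ValidationError):
            filter_low_expression(_expr([[0, 1], [0, 1]]))


class TestDe:
    def _strata(self, n_high, n_low):
        idx = [f"S{i}" for i in range(n_high + n_low)]
        return pd.Series(["CYT-high"] * n_high + ["CYT-low"] * n_low, index=idx)

    def test_planted_gene_called_null_genes_not(self):
        rng = np.random.default_rng(0)
        n = 20
        counts = rng.poisson(100, size=(30, 2 * n))
        counts[0, :n] = rng.poisson(800, size=n)  # strong planted up-shift
        expr = _expr(counts)
        out = differential_expression(expr, self._strata(n, n))
        assert out.loc["g0", "called"]
        assert out.loc["g0", "log2fc"] > 1

    def test_stratum_swap_negates_log2fc(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(100, size=(10, 12))
        expr = _expr(counts)
        s = self._strata(6, 6)
        out1 = differential_expression(expr, s)
        out2 = differential_expression(expr, s.map({"CYT-high": "CYT-low", "CYT-low": "CYT-high"}))
        np.testing.assert_allclose(out1["log2fc"], -out2.loc[out1.index, "log2fc"])
        np.testing.assert_allclose(out1["p"], out2.loc[out1.index, "p"])

    def test_q_bounds_p(self):
        rng = np.random.default_rng(2)
        expr = _expr(rng.poisson(50, size=(40, 12)))
        out = differential_expression(expr, self._strata(6, 6))
        assert (out["q"] >= out["p"] - 1e-12).all()
        assert (out["q"] <= 1.0).all()
        assert (out.loc[out["called"], "q"] < 0.1).all()

    def test_small_stratum_rejected(self):
        expr = _expr(np.ones((5, 5), dtype=int))
        with pytest.raises(ValidationError):
            differential_expression(expr, self._strata(2, 3))


class TestCheckpoints:
    def test_gene_copy_of_cyt_gene_correlates_perfectly(self, small_cohort):
        expr = small_cohort["expression"]
        tpm = compute_tpm(expr)
        cyt = compute_cyt(tpm, ["GZMA", "GZMA"])  # index driven by GZMA alone
        out = checkpoint_correlation(tpm, np.log2(cyt["cyt_raw"] + 1).rename("cyt_index"), ["GZMA"])
        # cyt_index = log2(tpm+1) of GZMA: monotone transform, near-perfect linear on logs
        assert out.loc["GZMA", "pearson_r"] > 0.99

    def test_affine_rescale_invariance(self, small_cohort):
        tpm = compute_tpm(small_cohort["expression"])
        cyt = compute_cyt(tpm)["cyt_index"]
        r1 = checkpoint_correlation(tpm, cyt, ["CD274"]).loc["CD274", "pearson_r"]
        r2 = checkpoint_correlation(tpm, 3.0 * cyt + 7.0, ["CD274"]).loc["CD274", "pearson_r"]
        assert r1 == pytest.approx(r2)

    def test_missing_gene_rejected(self, small_cohort):
        tpm = compute_tpm(small_cohort["expression"])
        cyt = compute_cyt(tpm)["cyt_index"]
        with pytest.raises(ValidationError, match="NOPE"):
            checkpoint_correlation(tpm, cyt, ["NOPE"])

    def test_msi_panel_bh_equals_hand_step_up(self, small_cohort):
        tpm = compute_tpm(small_cohort["expression"])
        msi = small_cohort["truth"]["msi"]
        panel = ["CD274", "CTLA4", "PDCD1", "LAG3"]
        out = checkpoint_by_msi(tpm, msi, panel)
        p = out["p"].to_numpy()
        m = len(p)
        order = np.argsort(p)
        hand = np.empty(m)
        running = 1.0
        for rank in range(m - 1, -1, -1):
            running = min(running, p[order[rank]] * m / (rank + 1))
            hand[order[rank]] = running
        np.testing.assert_allclose(out["q"].to_numpy(), hand)

    def test_msi_direction_recovered(self, small_cohort):
        tpm = compute_tpm(small_cohort["expression"])
        msi = small_cohort["truth"]["msi"]
        out = checkpoint_by_msi(tpm, msi, ["CD274", "CTLA4", "TIGIT"])
        assert (out["direction"] == "MSI").all()

    def test_empty_group_rejected(self, small_cohort):
        tpm = compute_tpm(small_cohort["expression"])
        msi = pd.Series("MSI", index=small_cohort["truth"].index)
        with pytest.raises(ValidationError):
            checkpoint_by_msi(tpm, msi, ["CD274"])
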