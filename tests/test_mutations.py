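"""MSI calling, burden, spectra, VAF/MATH, Fisher associations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crcyt.io import NONSYNONYMOUS_CLASSES
from crcyt.mutations import (
    classify_msi_from_maf,
    compute_vaf,
    gene_stratum_association,
    math_score,
    mutation_spectrum,
    nonsyn_burden,
    pairwise_fisher,
    sample_math_scores,
)
from tests.conftest import make_maf

MMR = ("MLH1", "MLH3", "MSH2", "MSH3", "MSH4", "MSH5", "MSH6", "PMS1", "PMS2")


class TestMsi:
    def test_missense_in_mmr_gene_calls_msi(self):
        maf = make_maf([("S1", "MSH2", "Missense_Mutation", "C", "T", 50, 50)])
        assert classify_msi_from_maf(maf, MMR)["S1"] == "MSI"

    def test_nonsense_in_mmr_gene_stays_mss(self):
        # the rule is literally missense-only
        maf = make_maf([("S1", "MLH1", "Nonsense_Mutation", "C", "T", 50, 50)])
        assert classify_msi_from_maf(maf, MMR)["S1"] == "MSS"

    def test_missense_outside_mmr_stays_mss(self):
        maf = make_maf([("S1", "TP53", "Missense_Mutation", "C", "T", 50, 50)])
        assert classify_msi_from_maf(maf, MMR)["S1"] == "MSS"

    def test_empty_maf_all_mss(self):
        maf = make_maf([]).iloc[0:0]
        out = classify_msi_from_maf(maf, MMR, samples=["S1", "S2"])
        assert (out == "MSS").all()

    def test_recovers_planted_labels(self, small_cohort):
        msi = classify_msi_from_maf(
            small_cohort["maf"], MMR, samples=small_cohort["truth"].index
        )
        pd.testing.assert_series_equal(
            msi.sort_index(), small_cohort["truth"]["msi"].sort_index(),
            check_names=False,
        )


class TestBurden:
    def test_silent_excluded(self):
        rows = [("S1", "A", "Missense_Mutation", "C", "T", 5, 5)] * 3 + [
            ("S1", "B", "Silent", "C", "T", 5, 5)
        ] * 2
        assert nonsyn_burden(make_maf(rows))["S1"] == 3

    def test_empty_sample_zero(self):
        maf = make_maf([("S1", "A", "Missense_Mutation", "C", "T", 5, 5)])
        assert nonsyn_burden(maf, samples=["S1", "S2"])["S2"] == 0

    def test_equals_brute_force_on_fixture(self, small_cohort):
        maf = small_cohort["maf"]
        burden = nonsyn_burden(maf)
        for sid in burden.index[:10]:
            expected = sum(
                1
                for _, r in maf[maf["sample_id"] == sid].iterrows()
                if r["variant_classification"] in NONSYNONYMOUS_CLASSES
            )
            assert burden[sid] == expected


class TestSpectrum:
    def test_complement_and_fractions(self):
        rows = [
            ("S1", "A", "Missense_Mutation", "C", "T", 5, 5),
            ("S1", "B", "Missense_Mutation", "C", "T", 5, 5),
            ("S1", "C", "Missense_Mutation", "G", "A", 5, 5),  # complements to C>T
            ("S1", "D", "Missense_Mutation", "T", "G", 5, 5),
        ]
        spec = mutation_spectrum(make_maf(rows))
        assert spec.loc["S1", "C>T"] == pytest.approx(0.75)
        assert spec.loc["S1", "T>G"] == pytest.approx(0.25)
        assert spec.loc["S1"].sum() == pytest.approx(1.0)

    def test_single_snv_is_unit_mass(self):
        spec = mutation_spectrum(make_maf([("S1", "A", "Silent", "T", "C", 5, 5)]))
        assert spec.loc["S1", "T>C"] == 1.0

    def test_non_snv_records_skipped(self):
        rows = [
            ("S1", "A", "Frame_Shift_Del", "AC", "-", 5, 5),
            ("S1", "B", "Missense_Mutation", "C", "A", 5, 5),
        ]
        spec = mutation_spectrum(make_maf(rows))
        assert spec.loc["S1", "C>A"] == 1.0

    def test_order_invariant(self, small_cohort):
        maf = small_cohort["maf"]
        a = mutation_spectrum(maf).sort_index()
        b = mutation_spectrum(maf.sample(frac=1, random_state=0)).sort_index()
        pd.testing.assert_frame_equal(a, b)

    def test_rows_sum_to_one(self, small_cohort):
        spec = mutation_spectrum(small_cohort["maf"]).dropna()
        np.testing.assert_allclose(spec.sum(axis=1), 1.0)


class TestVafMath:
    @pytest.mark.parametrize("alt,ref,expected", [(5, 5, 0.5), (0, 30, 0.0), (3, 7, 0.3)])
    def test_vaf_arithmetic(self, alt, ref, expected):
        maf = make_maf([("S1", "A", "Missense_Mutation", "C", "T", ref, alt)])
        assert compute_vaf(maf).iloc[0] == pytest.approx(expected)

    def test_vaf_unavailable_at_zero_depth(self):
        maf = make_maf([("S1", "A", "Missense_Mutation", "C", "T", 0, 0)])
        assert np.isnan(compute_vaf(maf).iloc[0])

    def test_constant_vafs_give_zero(self):
        assert math_score([0.3] * 6) == 0.0

    def test_hand_computed_example(self):
        assert math_score([0.2, 0.25, 0.3, 0.35, 0.4]) == pytest.approx(24.71, abs=0.005)

    def test_scaling_invariance(self):
        v = [0.1, 0.15, 0.2, 0.3, 0.42]
        assert math_score(v) == pytest.approx(math_score([2.0 * x for x in v]))

    def test_below_minimum_unavailable(self):
        assert np.isnan(math_score([0.2, 0.3, 0.4, 0.5]))

    def test_zero_median_unavailable(self):
        assert np.isnan(math_score([0.0] * 7))

    def test_per_sample_scores_on_fixture(self, small_cohort):
        scores = sample_math_scores(small_cohort["maf"])
        assert (scores.dropna() >= 0).all()
        assert len(scores) > 0


def brute_force_fisher(table):
    """Two-sided Fisher p by hypergeometric enumeration over all tables
    with the observed margins."""
    a, b = table[0]
    c, d = table[1]
    n, row1, col1 = a + b + c + d, a + b, a + c
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    probs = {k: stats.hypergeom.pmf(k, n, row1, col1) for k in range(lo, hi + 1)}
    p_obs = probs[a]
    return min(1.0, sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9)))


class TestPairwiseFisher:
    def test_perfect_cooccurrence_p(self):
        rows = [("S%d" % i, g, "Missense_Mutation", "C", "T", 5, 5)
                for i in range(3) for g in ("A", "B")]
        rows += [("S%d" % i, "C", "Missense_Mutation", "C", "T", 5, 5) for i in range(3, 6)]
        out = pairwise_fisher(make_maf(rows), ["A", "B"], samples=[f"S{i}" for i in range(6)])
        assert out["p"].iloc[0] == pytest.approx(0.1)
        assert out["odds_direction"].iloc[0] == "co-occurring"

    def test_gene_in_all_samples_skipped(self):
        rows = [(f"S{i}", "A", "Missense_Mutation", "C", "T", 5, 5) for i in range(4)]
        rows += [("S0", "B", "Missense_Mutation", "C", "T", 5, 5)]
        out = pairwise_fisher(make_maf(rows), ["A", "B"], samples=[f"S{i}" for i in range(4)])
        assert len(out) == 0

    def test_matches_enumeration_oracle_small_n(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            n = int(rng.integers(4, 13))
            pa = rng.random(n) < 0.5
            pb = rng.random(n) < 0.5
            if not (0 < pa.sum() < n and 0 < pb.sum() < n):
                continue
            rows = [(f"S{i}", "A", "Missense_Mutation", "C", "T", 5, 5) for i in range(n) if pa[i]]
            rows += [(f"S{i}", "B", "Missense_Mutation", "C", "T", 5, 5) for i in range(n) if pb[i]]
            out = pairwise_fisher(make_maf(rows), ["A", "B"], samples=[f"S{i}" for i in range(n)])
            table = [
                [int((pa & pb).sum()), int((pa & ~pb).sum())],
                [int((~pa & pb).sum()), int((~pa & ~pb).sum())],
            ]
            assert out["p"].iloc[0] == pytest.approx(brute_force_fisher(table), rel=1e-9)


class TestGeneStratum:
    def _strata(self):
        return pd.Series(
            ["CYT-high"] * 3 + ["CYT-low"] * 3, index=[f"S{i}" for i in range(6)]
        )

    def test_high_only_gene(self):
        rows = [(f"S{i}", "A", "Missense_Mutation", "C", "T", 5, 5) for i in range(3)]
        out = gene_stratum_association(make_maf(rows), self._strata(), ["A"])
        assert out["p"].iloc[0] == pytest.approx(0.1)
        assert out["enriched_stratum"].iloc[0] == "CYT-high"

    def test_equal_fractions_p_one(self):
        rows = [("S0", "A", "Missense_Mutation", "C", "T", 5, 5),
                ("S3", "A", "Missense_Mutation", "C", "T", 5, 5)]
        out = gene_stratum_association(make_maf(rows), self._strata(), ["A"])
        assert out["p"].iloc[0] == pytest.approx(1.0)
        assert out["enriched_stratum"].iloc[0] == "none"

    def test_label_swap_flips_direction_only(self):
        rows = [(f"S{i}", "A", "Missense_Mutation", "C", "T", 5, 5) for i in (0, 1, 3)]
        strata = self._strata()
        out1 = gene_stratum_association(make_maf(rows), strata, ["A"])
        swapped = strata.map({"CYT-high": "CYT-low", "CYT-low": "CYT-high"})
        out2 = gene_stratum_association(make_maf(rows), swapped, ["A"])
        assert out1["p"].iloc[0] == pytest.approx(out2["p"].iloc[0])
        assert {out1["enriched_stratum"].iloc[0], out2["enriched_stratum"].iloc[0]} == {
            "CYT-high", "CYT-low"
        }
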