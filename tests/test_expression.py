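"""Expression dynamic-range operations: normalization, DE, bins, variance."""

import numpy as np
import pytest

from chromshift import (
    CountsSpec,
    SimSpec,
    ValidationError,
    bin_proportions,
    classify_de,
    cpm_normalize,
    de_frame,
    decile_bins,
    detected_genes,
    expression_variance_test,
    make_counts,
    quintile_fc_distribution,
)

GROUPS_2x2 = {"WT_1": "WT", "WT_2": "WT", "KO_1": "KO", "KO_2": "KO"}


def matrix_from(counts, group_of=GROUPS_2x2):
    counts = np.asarray(counts)
    return cpm_normalize(
        counts,
        group_of=group_of,
        gene_ids=[f"g{i:03d}" for i in range(counts.shape[0])],
        sample_ids=list(group_of),
    )


class TestCpmNormalize:
    def test_single_gene_is_one_million(self):
        m = matrix_from([[10, 10, 10, 10]])
        assert np.allclose(m.cpm, 1e6)

    def test_library_scale_invariance(self):
        a = matrix_from([[10, 20, 10, 10], [90, 180, 90, 90]])
        b = matrix_from([[10, 10, 10, 10], [90, 90, 90, 90]])
        assert np.allclose(a.cpm, b.cpm)

    def test_columns_sum_to_one_million(self, rng):
        m = matrix_from(rng.integers(0, 300, (50, 4)) + 1)
        assert np.allclose(m.cpm.sum(axis=0), 1e6)

    def test_matches_direct_formula(self, rng):
        raw = rng.integers(1, 500, (20, 4))
        m = matrix_from(raw)
        assert np.allclose(m.cpm, raw / raw.sum(axis=0) * 1e6)
        assert np.allclose(m.log2cpm, np.log2(m.cpm + 1))

    def test_all_zero_sample_rejected(self):
        with pytest.raises(ValidationError):
            matrix_from([[1, 0, 2, 3]])


class TestDetectedGenes:
    def test_all_zero_but_one(self):
        m = matrix_from([[5, 5, 5, 5], [0, 0, 0, 0], [3, 1, 2, 2]])
        counts = detected_genes(m, min_cpm=1.0)
        assert counts == {"WT": 2, "KO": 2}

    def test_threshold_is_inclusive(self):
        # gene 0 lands at exactly min_cpm in every sample
        m = matrix_from([[1, 1, 1, 1], [999999, 999999, 999999, 999999]])
        assert detected_genes(m, min_cpm=1.0) == {"WT": 2, "KO": 2}
        assert detected_genes(m, min_cpm=1.0 + 1e-9) == {"WT": 1, "KO": 1}

    def test_ko_only_genes_raise_ko_count_by_planted_number(self):
        sim = make_counts(SimSpec(seed=5, counts=CountsSpec(
            n_genes=800, de_up=0, de_down=0, ko_only=37,
            baseline_meanlog=np.log(200), baseline_sdlog=0.4,
        )))
        m = cpm_normalize(sim.table, group_of=sim.group_of)
        counts = detected_genes(m)
        assert counts["KO"] - counts["WT"] == 37


class TestClassifyDE:
    def test_identical_groups_all_unchanged(self):
        counts = np.tile([[40], [400], [4000]], (1, 4))
        res = classify_de(matrix_from(counts))
        assert all(r.de_class == "unchanged" for r in res)

    def test_planted_shift_recovered(self, rng):
        """A 2-log2-unit planted shift in a few genes is classified up."""
        stable = rng.integers(200, 400, 980)
        shifted = rng.integers(200, 400, 20)
        wt = np.concatenate([stable, shifted])
        ko = np.concatenate([stable, shifted * 4])
        counts = np.column_stack([wt, wt + 1, ko, ko + 1])
        res = classify_de(matrix_from(counts))
        up = [r for r in res[980:]]
        assert all(r.de_class == "up" for r in up)
        # CPM composition shifts the measured lfc slightly below the planted 2
        assert np.allclose([r.log2fc for r in up], 2.0, atol=0.2)
        assert all(r.de_class == "unchanged" for r in res[:980])

    def test_antisymmetric_under_group_swap(self, rng):
        counts = rng.integers(10, 1000, (30, 4))
        m1 = matrix_from(counts)
        swapped = {"WT_1": "KO", "WT_2": "KO", "KO_1": "WT", "KO_2": "WT"}
        m2 = matrix_from(counts, group_of=swapped)
        lfc1 = np.array([r.log2fc for r in classify_de(m1)])
        lfc2 = np.array([r.log2fc for r in classify_de(m2)])
        assert np.allclose(lfc1, -lfc2)

    def test_bh_adjustment_is_monotone(self, rng):
        counts = rng.integers(1, 2000, (300, 4))
        df = de_frame(classify_de(matrix_from(counts))).sort_values("p")
        assert (np.diff(df["p_adj"].values) >= -1e-12).all()

    def test_small_group_rejected(self):
        m = matrix_from([[1, 2, 3]], group_of={"a": "WT", "b": "KO", "c": "KO"})
        with pytest.raises(ValidationError):
            classify_de(m)

    def test_type_one_error_near_alpha_under_null(self):
        """With no planted effects, the raw-p false positive rate ~ alpha."""
        sim = make_counts(SimSpec(seed=11, counts=CountsSpec(
            n_genes=10_000, de_up=0, de_down=0, compression_gamma=1.0,
        )))
        m = cpm_normalize(sim.table, group_of=sim.group_of)
        p = np.array([r.p for r in classify_de(m)])
        rate = (p < 0.05).mean()
        # Welch t at n=4 per group on NB log2 CPM is approximately calibrated
        assert abs(rate - 0.05) < 0.02


class TestBins:
    def test_ten_genes_ten_bins_lowest_first(self):
        counts = np.tile(2 ** np.arange(10).reshape(-1, 1), (1, 4)) * 10
        m = matrix_from(counts)
        a = decile_bins(m, K=10, min_cpm=0.0)
        assert [a.bin_of[f"g{i:03d}"] for i in range(10)] == list(range(1, 11))

    def test_bin_sizes_differ_by_at_most_one(self, rng):
        counts = rng.integers(50, 5000, (103, 4))
        a = decile_bins(matrix_from(counts), K=10)
        sizes = [len(a.genes_in(k)) for k in range(1, 11)]
        assert max(sizes) - min(sizes) <= 1 and sum(sizes) == 103

    def test_permutation_invariance_of_gene_order(self, rng):
        counts = rng.integers(50, 5000, (60, 4))
        ids = [f"g{i:03d}" for i in range(60)]
        m1 = cpm_normalize(counts, group_of=GROUPS_2x2, gene_ids=ids,
                           sample_ids=list(GROUPS_2x2))
        perm = rng.permutation(60)
        m2 = cpm_normalize(counts[perm], group_of=GROUPS_2x2,
                           gene_ids=[ids[i] for i in perm], sample_ids=list(GROUPS_2x2))
        a1 = decile_bins(m1, K=5)
        a2 = decile_bins(m2, K=5)
        assert a1.bin_of == a2.bin_of

    def test_proportions_sum_to_one(self, rng):
        counts = rng.integers(10, 5000, (200, 4))
        m = matrix_from(counts)
        props = bin_proportions(decile_bins(m, K=10), m)
        assert np.allclose(props.sum(axis=0), 1.0, atol=1e-9)

    def test_fewer_genes_than_bins_rejected(self):
        m = matrix_from(np.full((3, 4), 100))
        with pytest.raises(ValidationError):
            decile_bins(m, K=10, min_cpm=0.0)

    def test_compression_depletes_extreme_bins(self):
        """A KO dynamic-range compression moves mass out of bins 1 and 10."""
        sim = make_counts(SimSpec(seed=9, counts=CountsSpec(
            n_genes=6_000, de_up=0, de_down=0, compression_gamma=0.7,
        )))
        m = cpm_normalize(sim.table, group_of=sim.group_of)
        props = bin_proportions(decile_bins(m, reference_group="WT", K=10), m)
        wt = props[[s for s in m.sample_ids if s.startswith("WT")]].mean(axis=1)
        ko = props[[s for s in m.sample_ids if s.startswith("KO")]].mean(axis=1)
        assert ko["bin_1"] < wt["bin_1"]
        assert ko["bin_10"] < wt["bin_10"]
        middle = [f"bin_{k}" for k in range(4, 8)]
        assert ko[middle].sum() > wt[middle].sum()


class TestQuintileFoldChange:
    def test_no_change_all_medians_zero(self):
        counts = np.tile((np.arange(1, 26) * 40).reshape(-1, 1), (1, 4))
        m = matrix_from(counts)
        out = quintile_fc_distribution(m, classify_de(m), min_cpm=0.0)
        assert np.allclose(out["median_log2fc"], 0.0, atol=1e-9)

    def test_planted_shift_confined_to_one_quintile(self, rng):
        n = 100
        base = (np.arange(n) + 1) * 50
        ko = base.copy()
        lowest = np.argsort(base)[:20]
        ko[lowest] = base[lowest] * 4  # upshift only the lowest quintile
        counts = np.column_stack([base, base, ko, ko])
        m = matrix_from(counts)
        out = quintile_fc_distribution(m, classify_de(m), min_cpm=0.0)
        others = out.loc[2:, "median_log2fc"]
        # unshifted quintiles share the small CPM composition offset exactly
        assert others.max() - others.min() < 0.01
        assert out.loc[1, "median_log2fc"] - others.mean() == pytest.approx(2.0, abs=0.1)

    def test_planted_downshift_in_top_quintile(self, rng):
        n = 100
        base = (np.arange(n) + 1) * 50
        ko = base.copy()
        highest = np.argsort(base)[-20:]
        ko[highest] = base[highest] // 4
        m = matrix_from(np.column_stack([base, base, ko, ko]))
        out = quintile_fc_distribution(m, classify_de(m), min_cpm=0.0)
        others = out.loc[1:4, "median_log2fc"]
        assert others.max() - others.min() < 0.01
        assert out.loc[5, "median_log2fc"] - others.mean() == pytest.approx(-2.0, abs=0.1)


class TestVarianceTest:
    def test_self_comparison(self, rng):
        counts = rng.integers(10, 10_000, (100, 4))
        m = matrix_from(counts)
        var_a, var_b, F, p = expression_variance_test(m, "WT_1", "WT_1")
        assert var_a == var_b and F == 1.0 and p == pytest.approx(1.0)

    def test_toy_vectors_closed_form(self):
        """log2 CPM vectors {x, 2x, 3x} vs {y, 3y, 5y}: F = 1/4 and, with
        F(2,2) CDF = x/(1+x), two-sided p = 2 * 0.25/1.25 = 0.4."""
        # counts chosen so log2cpm (pc=0) differences are exactly 1,2,3 / 1,3,5
        a = 2.0 ** np.array([1, 2, 3])
        b = 2.0 ** np.array([1, 3, 5])
        counts = np.column_stack([a, a, b, b]).astype(int)
        m = cpm_normalize(counts * 1000, group_of=GROUPS_2x2, pseudocount=1e-12,
                          gene_ids=["g1", "g2", "g3"], sample_ids=list(GROUPS_2x2))
        var_a, var_b, F, p = expression_variance_test(m, "WT_1", "KO_1", min_cpm=0.0)
        assert F == pytest.approx(0.25)
        assert p == pytest.approx(0.4, abs=1e-9)

    def test_compression_factor_recovered_as_variance_ratio(self):
        """Planted KO log-shrinkage gamma yields var_KO / var_WT ~ gamma^2.

        The analytic expectation holds when measurement noise and
        detection truncation are negligible next to the between-gene
        variance, so the fixture uses well-expressed genes and near-zero
        dispersion.
        """
        gamma = 0.8
        sim = make_counts(SimSpec(seed=13, counts=CountsSpec(
            n_genes=8_000, de_up=0, de_down=0, compression_gamma=gamma,
            nb_dispersion=0.001, baseline_meanlog=np.log(1000), baseline_sdlog=1.0,
        )))
        m = cpm_normalize(sim.table, group_of=sim.group_of)
        _, _, F, _ = expression_variance_test(m, "KO_1", "WT_1")
        assert F == pytest.approx(gamma**2, abs=0.05)
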