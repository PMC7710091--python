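"""Association scans: OLS oracle equivalence, permutations, peaks, intervals."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from doeqtl import scan, simulate, genotype, pipeline
from doeqtl.scan import (
    FounderScanner,
    assign_regulating_strain,
    bayes_credible_interval,
    classify_cis_trans,
    design_matrix,
    fdr_across_genes,
    fit_marker,
    permutation_pvalue,
    select_peaks,
)

from conftest import toy_marker_map


def ols_oracle(y, X):
    """Independent minimum-norm normal-equations fit: beta, rss, and F-test p."""
    beta = np.linalg.pinv(X.T @ X) @ X.T @ y
    resid = y - X @ beta
    return beta, float(resid @ resid)


def random_dosage_matrix(rng, n):
    """Valid founder dosages at one marker, rows summing to 2."""
    raw = rng.gamma(1.0, size=(n, 36))
    probs = raw / raw.sum(axis=1, keepdims=True)
    return genotype.collapse_to_dosage(probs[:, None, :])[:, 0, :]


class TestDesignMatrix:
    def _meta(self, sexes, diets, batches=None, generations=None):
        n = len(sexes)
        return pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(n)],
                "sex": sexes,
                "diet": diets,
                "batch": batches or ["B0"] * n,
                "generation": generations or ["G0"] * n,
            }
        )

    def test_two_by_two_design_has_interaction(self):
        meta = self._meta(["M", "M", "F", "F"], ["chow", "high-fat", "chow", "high-fat"])
        X = design_matrix(meta, "all")
        assert list(X.columns) == ["intercept", "sex", "diet", "sex:diet"]
        assert np.linalg.matrix_rank(X.to_numpy()) == 4

    def test_single_sex_dataset_drops_sex_columns(self):
        meta = self._meta(["M", "M", "F", "F"], ["chow", "high-fat", "chow", "high-fat"])
        X = design_matrix(meta, "male")
        assert "sex" not in X.columns and "sex:diet" not in X.columns
        assert len(X) == 2

    def test_aliased_covariates_are_dropped_to_full_rank(self):
        # generation exactly mirrors batch -> one of the dummies is aliased
        meta = self._meta(
            ["M", "F", "M", "F"],
            ["chow", "chow", "high-fat", "high-fat"],
            batches=["B0", "B0", "B1", "B1"],
            generations=["G0", "G0", "G1", "G1"],
        )
        X = design_matrix(meta, "all")
        assert np.linalg.matrix_rank(X.to_numpy()) == X.shape[1]

    def test_constant_covariate_is_dropped(self):
        meta = self._meta(["M", "F", "M", "F"], ["chow"] * 4)
        X = design_matrix(meta, "all")
        assert "diet" not in X.columns


class TestFitMarker:
    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(12, 30))
            D = random_dosage_matrix(rng, n)
            C = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
            y = rng.normal(size=n)
            fit = fit_marker(y, D, C)
            beta, rss = ols_oracle(y, np.hstack([C, D]))
            _, rss0 = ols_oracle(y, C)
            assert fit.rss_full == pytest.approx(rss, abs=1e-10, rel=1e-10)
            assert fit.rss_null == pytest.approx(rss0, abs=1e-10, rel=1e-10)
            founder_beta = beta[-8:]
            np.testing.assert_allclose(
                fit.coefficients, founder_beta - founder_beta.mean(), atol=1e-10
            )

    def test_perfect_fit_caps_lod_and_names_the_founder(self, rng):
        n = 16
        D = random_dosage_matrix(rng, n)
        y = D[:, 5].copy()  # y exactly equals CAST dosage
        fit = fit_marker(y, D, np.ones((n, 1)))
        assert fit.lod == scan.LOD_CAP
        assert int(np.argmax(np.abs(fit.coefficients))) == 5

    def test_coefficients_sum_to_zero(self, rng):
        D = random_dosage_matrix(rng, 25)
        fit = fit_marker(rng.normal(size=25), D, np.ones((25, 1)))
        assert fit.coefficients.sum() == pytest.approx(0.0, abs=1e-9)

    def test_zero_variance_phenotype_warns_lod_zero(self, rng):
        D = random_dosage_matrix(rng, 20)
        with pytest.warns(UserWarning, match="zero variance"):
            fit = fit_marker(np.ones(20), D, np.ones((20, 1)))
        assert fit.lod == 0.0

    def test_null_pvalue_calibration_at_one_marker(self, rng):
        # 2,000 independent null phenotypes at one marker: p<0.05 in 5% +/- 1%
        n = 100
        D = random_dosage_matrix(rng, n)[:, None, :]
        scanner = FounderScanner(D, np.ones((n, 1)))
        Y = rng.normal(size=(n, 2000))
        lods = scanner.lod_matrix(Y)[0]
        pvals = 10.0 ** (-lods)
        frac = float(np.mean(pvals < 0.05))
        assert frac == pytest.approx(0.05, abs=0.01)

    def test_scanner_lod_agrees_with_direct_fit(self, rng):
        n = 40
        raw = rng.gamma(1.0, size=(n, 6, 36))
        probs = raw / raw.sum(axis=-1, keepdims=True)
        D = genotype.collapse_to_dosage(probs)
        C = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.normal(size=n)
        scanner = FounderScanner(D, C)
        fast = scanner.lod_profile(y)
        direct = [fit_marker(y, D[:, m, :], C).lod for m in range(6)]
        np.testing.assert_allclose(fast, direct, atol=1e-8)


class TestScanInvariance:
    def test_affine_transform_of_phenotype_leaves_scan_unchanged(self, small_bundle):
        from doeqtl.expression import rankz_transform

        b = small_bundle
        X = design_matrix(b.meta, "all")
        D = b.dosages
        scanner = FounderScanner(D, X.to_numpy())
        y_raw = b.expr.loc["g_cast"].to_numpy()
        lod1 = scanner.lod_profile(rankz_transform(y_raw))
        lod2 = scanner.lod_profile(rankz_transform(3.0 * y_raw + 7.0))
        np.testing.assert_allclose(lod1, lod2, atol=1e-12)


class TestPermutations:
    def _scanner(self, rng, n=60, m=8):
        raw = rng.gamma(1.0, size=(n, m, 36))
        probs = raw / raw.sum(axis=-1, keepdims=True)
        return FounderScanner(genotype.collapse_to_dosage(probs), np.ones((n, 1)))

    def test_pvalue_formula_extremes(self, rng):
        maxima = np.linspace(1.0, 2.0, 200)
        assert scan._grid_pvalue(5.0, maxima) == pytest.approx(1 / 201)
        assert scan._grid_pvalue(0.5, maxima) == pytest.approx(1.0)

    def test_pvalue_in_grid_range_and_decreasing_in_lod(self, rng):
        scanner = self._scanner(rng)
        y = rng.normal(size=60)
        maxima = scan.permutation_maxima(y, scanner, 150, seed=3)
        lods = np.linspace(0, 10, 25)
        ps = [scan._grid_pvalue(l, maxima) for l in lods]
        assert all(1 / 151 <= p <= 1.0 for p in ps)
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_null_permutation_p_uniform_on_grid(self, rng):
        # observed max for a null gene should look like one more permutation
        scanner = self._scanner(rng, n=50, m=5)
        n_perm = 60
        ps = []
        for _ in range(150):
            y = rng.normal(size=50)
            obs = scanner.lod_profile(y).max()
            maxima = scan.permutation_maxima(y, scanner, n_perm, seed=int(rng.integers(2**31)))
            ps.append(scan._grid_pvalue(obs, maxima))
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01

    def test_permutation_pvalue_requires_100_perms(self, rng):
        scanner = self._scanner(rng)
        with pytest.raises(ValueError, match="at least 100"):
            permutation_pvalue(rng.normal(size=60), None, None, n_perm=50, scanner=scanner)


class TestPeaksAndFdr:
    def _scan_frame(self, lods_by_chrom):
        rows = []
        k = 0
        for chrom, lods in lods_by_chrom.items():
            for i, lod in enumerate(lods):
                rows.append(
                    {"marker_id": f"m{k}", "chrom": chrom, "pos_bp": (i + 1) * 1000, "lod": lod}
                )
                k += 1
        return pd.DataFrame(rows)

    def test_two_significant_chromosomes_give_two_candidates(self):
        frame = self._scan_frame({"2": [1.0, 8.0], "9": [6.0, 2.0], "5": [0.5, 0.2]})
        maxima = np.full(200, 3.0)  # both 8.0 and 6.0 beat every permutation
        peaks = select_peaks(frame, maxima)
        assert set(peaks["chrom"]) == {"2", "9"}
        assert peaks["is_global_best"].sum() == 1

    def test_one_chromosome_keeps_only_its_best_marker(self):
        frame = self._scan_frame({"2": [7.0, 8.0, 7.5]})
        peaks = select_peaks(frame, np.full(100, 1.0))
        assert len(peaks) == 1
        assert peaks["lod"].iloc[0] == 8.0

    def test_global_best_forwarded_even_when_not_significant(self):
        frame = self._scan_frame({"1": [1.0, 1.2], "2": [0.9, 0.8]})
        maxima = np.full(100, 5.0)  # nothing is significant
        peaks = select_peaks(frame, maxima)
        assert len(peaks) == 1
        assert peaks["chrom"].iloc[0] == "1"
        assert peaks["perm_p"].iloc[0] == 1.0

    def test_bh_hand_example(self):
        q = fdr_across_genes([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, 0.04)

    def test_bh_all_ones_and_singleton(self):
        np.testing.assert_allclose(fdr_across_genes([1.0, 1.0, 1.0]), 1.0)
        np.testing.assert_allclose(fdr_across_genes([0.03]), [0.03])


class TestCredibleInterval:
    def ci_oracle(self, pos, lod, level=0.95):
        """Brute-force cumulative-sum quantiles on a dense linear grid."""
        grid = np.linspace(pos[0], pos[-1], 200_001)
        dens = np.interp(grid, pos, (lod / max(lod.max(), 1e-12)) ** 10)
        cum = np.cumsum(dens)
        cum = cum / cum[-1]
        lo = grid[np.searchsorted(cum, (1 - level) / 2)]
        hi = grid[np.searchsorted(cum, 1 - (1 - level) / 2)]
        return lo, hi

    def test_point_mass_gives_degenerate_interval(self):
        pos = np.arange(1, 12) * 1_000_000.0
        lod = np.zeros(11)
        lod[5] = 12.0
        start, end = bayes_credible_interval(pos, lod)
        assert end - start < 1_000_000  # narrower than the marker spacing
        assert start <= pos[5] <= end

    def test_flat_lod_gives_central_95_percent(self):
        pos = np.linspace(0, 10_000_000, 101)
        lod = np.full(101, 4.0)
        start, end = bayes_credible_interval(pos, lod)
        assert start == pytest.approx(250_000, rel=1e-6)
        assert end == pytest.approx(9_750_000, rel=1e-6)

    def test_two_equal_peaks_span_both_and_match_oracle(self, rng):
        pos = np.linspace(0, 50_000_000, 51)
        lod = np.zeros(51)
        lod[10] = lod[40] = 9.0
        start, end = bayes_credible_interval(pos, lod)
        o_start, o_end = self.ci_oracle(pos, lod)
        spacing = pos[1] - pos[0]
        assert start <= pos[10] and end >= pos[40]
        assert abs(start - o_start) <= spacing
        assert abs(end - o_end) <= spacing

    def test_random_curves_match_cumulative_sum_oracle(self, rng):
        for _ in range(50):
            m = int(rng.integers(10, 40))
            pos = np.sort(rng.choice(np.arange(1, 10_000), size=m, replace=False)) * 10_000.0
            lod = rng.uniform(0, 8, size=m)
            start, end = bayes_credible_interval(pos, lod)
            o_start, o_end = self.ci_oracle(pos, lod)
            spacing = np.diff(pos).max()
            assert abs(start - o_start) <= spacing
            assert abs(end - o_end) <= spacing

    def test_nested_levels(self, rng):
        pos = np.linspace(0, 30_000_000, 40)
        lod = rng.uniform(0, 6, size=40)
        s90, e90 = bayes_credible_interval(pos, lod, level=0.90)
        s95, e95 = bayes_credible_interval(pos, lod, level=0.95)
        assert s95 <= s90 and e90 <= e95

    def test_all_zero_lod_warns_whole_chromosome(self):
        pos = np.array([1.0, 2.0, 3.0]) * 1e6
        with pytest.warns(UserWarning, match="whole chromosome"):
            start, end = bayes_credible_interval(pos, np.zeros(3))
        assert (start, end) == (1e6, 3e6)


class TestRegulatingStrain:
    def test_largest_positive_coefficient_wins(self):
        strain, direction = assign_regulating_strain([0, 0, 0, 0, 0, 3.0, -1.0, 0])
        assert strain == "CAST/EiJ" and direction == "up"

    def test_negative_coefficient_gives_down_direction(self):
        strain, direction = assign_regulating_strain([0, 0, 0, 0, -2.0, 0, 0, 0])
        assert strain == "NZO/HILtJ" and direction == "down"

    def test_tie_breaks_to_lower_index_with_warning(self):
        with pytest.warns(UserWarning, match="tied"):
            strain, _ = assign_regulating_strain([2.0, -2.0, 0, 0, 0, 0, 0, 0])
        assert strain == "A/J"

    def test_all_zero_vector_is_an_error(self):
        with pytest.raises(ValueError, match="all-zero"):
            assign_regulating_strain([0.0] * 8)


class TestCisTrans:
    def _tads(self):
        return pd.DataFrame(
            {
                "chrom": ["2", "2", "2"],
                "start": [1, 10_000_001, 20_000_001],
                "end": [10_000_000, 20_000_000, 30_000_000],
            }
        )

    def test_overlapping_interval_is_cis(self):
        call = classify_cis_trans("2", (11e6, 13e6), "2", 11_500_000, self._tads())
        assert call == "cis"

    def test_different_chromosome_is_trans(self):
        assert classify_cis_trans("9", (1e6, 2e6), "10", 1_500_000, self._tads()) == "trans"

    def test_adjacent_but_disjoint_interval_is_trans(self):
        # TSS in TAD [1, 10 Mb]; interval starts at 10,000,001
        call = classify_cis_trans("2", (10_000_001, 12_000_000), "2", 5_000_000, self._tads())
        assert call == "trans"

    def test_partition_over_records(self, small_bundle):
        records = scan.scan_dataset(
            small_bundle.expr,
            small_bundle.dosages,
            small_bundle.samples,
            small_bundle.mmap,
            small_bundle.meta,
            dataset="all",
            n_perm=100,
            seed=2,
            gene_annot=small_bundle.gene_annot,
            tads=small_bundle.tads,
        )
        assert records["cis_trans"].isin(["cis", "trans"]).all()
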