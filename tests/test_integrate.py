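import numpy as np
import pandas as pd
import pytest

import quadclip as qc
from quadclip.integrate import NONTARGET_BIN, ExpressionTable

from oracles import halflife_normal_equations, ks_two_sample_enumerated


class TestNormalizeCounts:
    def test_cpm_sums_to_one_million(self):
        counts = pd.DataFrame({"rna_wt_1": [10, 0, 30]}, index=list("abc"))
        out = qc.normalize_counts(counts, "cpm")
        assert out["rna_wt_1"].sum() == pytest.approx(1e6)
        assert out.at["b", "rna_wt_1"] == 0.0

    def test_median_of_ratios_hand_case(self):
        # sample B = 2 x sample A: size factors in ratio 2, normalized equal
        counts = pd.DataFrame(
            {"rna_wt_1": [10, 20, 40], "rna_wt_2": [20, 40, 80]}, index=list("abc")
        )
        out = qc.normalize_counts(counts, "median_of_ratios")
        pd.testing.assert_series_equal(
            out["rna_wt_1"], out["rna_wt_2"], check_names=False
        )

    def test_genes_with_zeros_excluded_from_factor_estimation(self):
        counts = pd.DataFrame(
            {"s1": [10, 20, 0], "s2": [20, 40, 1000]}, index=list("abc")
        )
        out = qc.normalize_counts(counts, "median_of_ratios")
        # factors determined by genes a, b only -> ratio 2
        assert out.at["a", "s1"] == pytest.approx(out.at["a", "s2"])

    def test_control_gene_normalization_ignores_shifted_genes(self):
        # gene c quadruples in s2; controls a, b pin the size factor at 1
        counts = pd.DataFrame(
            {"s1": [10, 20, 100], "s2": [10, 20, 400]}, index=list("abc")
        )
        out = qc.normalize_counts(counts, "median_of_ratios", control_genes=["a", "b"])
        assert out.at["a", "s1"] == pytest.approx(out.at["a", "s2"])
        assert out.at["c", "s2"] / out.at["c", "s1"] == pytest.approx(4.0)

    def test_control_genes_must_exist(self):
        counts = pd.DataFrame({"s1": [1], "s2": [2]}, index=["a"])
        with pytest.raises(ValueError, match="control genes"):
            qc.normalize_counts(counts, "median_of_ratios", control_genes=["zz"])

    def test_all_zero_column_rejected(self):
        counts = pd.DataFrame({"s1": [1, 2], "s2": [0, 0]}, index=list("ab"))
        with pytest.raises(ValueError, match="all-zero"):
            qc.normalize_counts(counts, "cpm")

    def test_unknown_method_rejected(self):
        counts = pd.DataFrame({"s1": [1]}, index=["a"])
        with pytest.raises(ValueError, match="method"):
            qc.normalize_counts(counts, "quantile")


class TestLog2FC:
    def test_fourfold_change(self):
        ko = pd.Series({"a": 4.0})
        wt = pd.Series({"a": 1.0})
        assert qc.log2fc(ko, wt, pseudocount=1e-12)["a"] == pytest.approx(2.0)

    def test_identity(self):
        x = pd.Series({"a": 7.0})
        assert qc.log2fc(x, x)["a"] == 0.0

    def test_pseudocount_floors_zeros(self):
        zero = pd.Series({"a": 0.0})
        assert qc.log2fc(zero, zero, pseudocount=1.0)["a"] == 0.0

    def test_pseudocount_must_be_positive(self):
        with pytest.raises(ValueError):
            qc.log2fc(pd.Series({"a": 1.0}), pd.Series({"a": 1.0}), pseudocount=0.0)


class TestTranslationalEfficiency:
    def _frames(self, rna_wt, rna_ko, rpf_wt, rpf_ko):
        idx = pd.Index(["a"], name="gene_id")
        mk = lambda v: pd.DataFrame({"r1": [v]}, index=idx)
        return mk(rna_wt), mk(rna_ko), mk(rpf_wt), mk(rpf_ko)

    def test_te_is_rpf_over_rna(self):
        out = qc.translational_efficiency(*self._frames(5, 5, 10, 10), min_abund=0.0)
        assert out.at["a", "te_wt"] == pytest.approx(2.0)

    def test_mrna_gain_without_rpf_gain_halves_te(self):
        out = qc.translational_efficiency(*self._frames(5, 10, 10, 10), min_abund=0.0)
        assert out.at["a", "delta_te"] == pytest.approx(-1.0)

    def test_low_abundance_flagged_not_dropped(self):
        out = qc.translational_efficiency(*self._frames(0.5, 5, 10, 10), min_abund=1.0)
        assert bool(out.at["a", "te_flagged"])
        assert np.isnan(out.at["a", "delta_te"])
        assert "a" in out.index

    def test_mismatched_universe_rejected(self):
        rna_wt, rna_ko, rpf_wt, _ = self._frames(1, 1, 1, 1)
        rpf_ko = pd.DataFrame({"r1": [1.0]}, index=pd.Index(["zzz"], name="gene_id"))
        with pytest.raises(ValueError, match="universe"):
            qc.translational_efficiency(rna_wt, rna_ko, rpf_wt, rpf_ko)


class TestBinTargets:
    @pytest.fixture()
    def profiles(self):
        return pd.DataFrame(
            {
                "n_clusters": [3, 1, 0, 5],
                "nxpm": [150.0, 5.0, 0.0, 50.0],
                "nxpm_utr3": [150.0, 0.0, 0.0, 2.0],
            },
            index=pd.Index(["a", "b", "c", "d"], name="gene_id"),
        )

    def test_value_falls_in_top_bin(self, profiles):
        bins = qc.bin_targets(profiles, "nxpm", [0, 10, 100])
        assert bins["a"] == "[100, inf)"
        assert bins["b"] == "[0, 10)"

    def test_zero_cluster_gene_is_nontarget(self, profiles):
        bins = qc.bin_targets(profiles, "nxpm", [0, 10, 100])
        assert bins["c"] == NONTARGET_BIN

    def test_genes_absent_from_profiles_are_nontarget(self, profiles):
        bins = qc.bin_targets(profiles, "nxpm", [0, 10], universe=["a", "zz"])
        assert bins["zz"] == NONTARGET_BIN

    def test_region_metric_selects_region_occupancy(self, profiles):
        bins = qc.bin_targets(profiles, "nxpm_utr3", [0, 10, 100])
        assert bins["a"] == "[100, inf)"
        assert bins["d"] == "[0, 10)"

    def test_partition_property(self, profiles):
        universe = ["a", "b", "c", "d", "e", "f"]
        bins = qc.bin_targets(profiles, "nxpm", [0, 10, 100], universe=universe)
        assert set(bins.index) == set(universe)
        assert bins.value_counts().sum() == len(universe)

    def test_non_increasing_bounds_rejected(self, profiles):
        with pytest.raises(ValueError, match="increasing"):
            qc.bin_targets(profiles, "nxpm", [0, 10, 10])


class TestCdfKsCompare:
    def test_identical_distributions(self):
        vals = {"ref": [1.0, 2.0, 3.0], "bin": [1.0, 2.0, 3.0]}
        out = qc.cdf_ks_compare(vals, "ref", min_size=3)
        assert out.loc[0, "D"] == 0.0
        assert out.loc[0, "p"] == pytest.approx(1.0)

    def test_disjoint_supports(self):
        vals = {"ref": [4.0, 5.0, 6.0], "bin": [1.0, 2.0, 3.0]}
        out = qc.cdf_ks_compare(vals, "ref", min_size=3)
        assert out.loc[0, "D"] == 1.0

    def test_small_bins_skipped_with_warning(self):
        vals = {"ref": [1.0, 2.0, 3.0], "tiny": [1.0]}
        with pytest.warns(UserWarning, match="skipped"):
            out = qc.cdf_ks_compare(vals, "ref", min_size=10)
        assert out.empty

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            qc.cdf_ks_compare({"ref": [], "bin": [1.0]}, "ref")

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=4)
        y = rng.normal(loc=1.0, size=4)
        d_oracle, p_oracle = ks_two_sample_enumerated(x, y)
        out = qc.cdf_ks_compare({"ref": y, "bin": x}, "ref", min_size=2)
        assert out.loc[0, "D"] == pytest.approx(d_oracle)
        assert out.loc[0, "p"] == pytest.approx(p_oracle, abs=1e-12)


class TestFitHalflife:
    def test_exact_exponential(self):
        fit = qc.fit_halflife([0, 4, 8], [1.0, 0.5, 0.25])
        assert fit.half_life == pytest.approx(4.0)
        assert fit.r_squared == pytest.approx(1.0)
        assert not fit.non_decaying

    def test_flat_series_flagged_non_decaying(self):
        fit = qc.fit_halflife([0, 2, 4, 8], [1.0, 1.0, 1.0, 1.0])
        assert fit.k == pytest.approx(0.0)
        assert fit.non_decaying
        assert np.isnan(fit.half_life)

    def test_noisy_fit_matches_normal_equations(self):
        rng = np.random.default_rng(17)
        t = np.array([0.0, 2.0, 4.0, 8.0])
        levels = np.exp(-0.2 * t) * np.exp(rng.normal(0, 0.1, size=4))
        fit = qc.fit_halflife(t, levels)
        k_oracle, hl_oracle = halflife_normal_equations(t, levels)
        assert fit.k == pytest.approx(k_oracle, abs=1e-10)
        assert fit.half_life == pytest.approx(hl_oracle, abs=1e-10)

    def test_nonpositive_level_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            qc.fit_halflife([0, 2, 4], [1.0, 0.0, 0.5])

    def test_too_few_timepoints_rejected(self):
        with pytest.raises(ValueError, match="timepoints"):
            qc.fit_halflife([0, 2], [1.0, 0.5])

    def test_recovers_planted_rate_with_small_bias_under_noise(self):
        """Log-normal measurement noise at 10% CV: <2% bias over 1000 genes."""
        rng = np.random.default_rng(31)
        t = np.array([0.0, 2.0, 4.0, 8.0])
        k_true = 0.3
        ks = []
        for _ in range(1000):
            y = np.exp(-k_true * t) * rng.lognormal(0, 0.1, size=4)
            ks.append(qc.fit_halflife(t, y).k)
        assert abs(np.mean(ks) - k_true) / k_true < 0.02

    def test_long_format_table(self):
        table = pd.DataFrame(
            {
                "gene_id": ["a"] * 3 + ["b"] * 3,
                "time_h": [0, 4, 8] * 2,
                "level": [1, 0.5, 0.25, 1, 1, 1],
            }
        )
        fits = qc.fit_halflives(table)
        assert fits.at["a", "half_life"] == pytest.approx(4.0)
        assert bool(fits.at["b", "non_decaying"])


class TestCTCF:
    def test_stated_formula(self):
        assert qc.ctcf(1000, 50, 2).value == 900.0

    def test_zero_background_is_identity(self):
        assert qc.ctcf(123.0, 50, 0).value == 123.0

    def test_negative_result_flagged(self):
        result = qc.ctcf(100, 100, 2)
        assert result.value == -100.0
        assert result.negative

    def test_negative_area_rejected(self):
        with pytest.raises(ValueError):
            qc.ctcf(100, -1, 2)


class TestExpressionTable:
    def test_sample_metadata_parsed(self, small_sim):
        table = small_sim["table"]
        assert set(table.samples["assay"]) == {"rna", "rpf"}
        assert set(table.samples["condition"]) == {"wt", "ko"}
        assert table.subset("rna", "wt").shape[1] == 3

    def test_bad_column_name_rejected(self):
        counts = pd.DataFrame({"sampleX": [1]}, index=["a"])
        with pytest.raises(ValueError, match="sampleX"):
            ExpressionTable(counts)

    def test_negative_counts_rejected(self):
        counts = pd.DataFrame({"rna_wt_1": [-1]}, index=["a"])
        with pytest.raises(ValueError, match="non-negative"):
            ExpressionTable(counts)

    def test_tsv_roundtrip(self, small_sim, tmp_path):
        path = tmp_path / "counts.tsv"
        small_sim["table"].to_tsv(path)
        again = ExpressionTable.from_tsv(path)
        pd.testing.assert_frame_equal(small_sim["table"].counts, again.counts)
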