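"""Cell QC, relative-FNR/ADO estimation, FDR estimation, SNP site filters."""

import numpy as np
import pandas as pd
import pytest

from scexome import SimConfig, estimate_ado, estimate_ado_cell, estimate_fdr, \
    mito_fdr_crosscheck, qc_cells, relative_fnr, simulate_observations, \
    simulate_population, simulate_tissue_normal, snp_site_filter
from scexome.errors import snp_site_filter_frame


def _ado_sim(ado, seed, n_sites=100_000):
    cfg = SimConfig(n_tumor_cells=4, n_normal_cells=1, n_ancestral_muts=1,
                    n_cloneB_muts=1, n_cloneC_muts=1, n_neutral_tail_muts=0,
                    n_germline_het_sites=n_sites, n_hom_background_sites=10,
                    ado_het=ado, seed=seed)
    truth = simulate_population(cfg)
    obs = simulate_observations(truth)
    tissue = simulate_tissue_normal(truth)
    cell = truth.normal_cells[0]
    return obs[obs.cell_id == cell], tissue, truth.germline_sites()


class TestRelativeFNR:
    def test_arithmetic(self):
        assert relative_fnr(0.5, 1.0, 0.3, 1.0) == pytest.approx(0.4)

    def test_identity_when_rates_equal(self):
        assert relative_fnr(0.5, 1.0, 0.5, 1.0) == 0.0

    def test_negative_when_tissue_below_cell(self):
        assert relative_fnr(0.5, 1.0, 0.6, 1.0) == pytest.approx(-0.2)

    def test_undefined_tissue_rate_flagged(self):
        with pytest.raises(ValueError, match="tissue"):
            relative_fnr(0.0, 1.0, 0.3, 1.0)


class TestADO:
    def test_recovers_injected_041(self):
        cell_obs, tissue, germ = _ado_sim(0.41, seed=21)
        est = estimate_ado_cell(cell_obs, tissue, germ)
        assert abs(est - 0.41) < 0.03

    def test_noise_free_cell_estimates_zero(self):
        cell_obs, tissue, germ = _ado_sim(0.0, seed=22, n_sites=20_000)
        assert estimate_ado_cell(cell_obs, tissue, germ) == pytest.approx(0.0)

    def test_population_ado_is_mean_of_cells(self):
        ests = []
        for ado, seed in ((0.3, 23), (0.5, 24)):
            cell_obs, tissue, germ = _ado_sim(ado, seed, n_sites=30_000)
            ests.append(estimate_ado_cell(cell_obs, tissue, germ))
        assert abs(np.mean(ests) - 0.4) < 0.03

    def test_monotone_recovery_over_ado_grid(self):
        grid = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6]
        ests = []
        for i, ado in enumerate(grid):
            cell_obs, tissue, germ = _ado_sim(ado, seed=30 + i)
            est = estimate_ado_cell(cell_obs, tissue, germ)
            assert abs(est - ado) < 0.03
            ests.append(est)
        assert all(b > a for a, b in zip(ests, ests[1:]))

    def test_insufficient_depth_strata_raise(self, small_tissue, small_truth):
        one = small_truth.germline_sites().head(20)
        cell = pd.DataFrame({
            "cell_id": "X", "chrom": one.chrom, "pos": one.pos,
            "depth": 10, "mut_reads": 5, "qual": 99, "ranksum_p": 0.5,
            "genotype": "NC"})
        with pytest.raises(ValueError, match="depth strata"):
            estimate_ado_cell(cell, small_tissue, one, min_sites_per_depth=1)


class TestFDR:
    def test_discrepant_over_covered_arithmetic(self):
        sites = pd.DataFrame({"chrom": "chr1", "pos": np.arange(1, 30_001)})
        geno = np.full(30_000, "NN", dtype=object)
        geno[:2] = "NC"
        obs = pd.DataFrame({
            "cell_id": "BN01", "chrom": "chr1", "pos": sites.pos,
            "depth": 30, "mut_reads": 0, "qual": 99, "ranksum_p": 0.5,
            "genotype": geno})
        fdr, per_cell = estimate_fdr(obs, sites)
        assert fdr == pytest.approx(2 / 30_000)

    def test_unbiased_on_rate_grid(self):
        for i, rate in enumerate((1e-5, 6.7e-5, 1e-4)):
            cfg = SimConfig(n_tumor_cells=4, n_normal_cells=11,
                            n_ancestral_muts=1, n_cloneB_muts=1,
                            n_cloneC_muts=1, n_neutral_tail_muts=0,
                            n_germline_het_sites=10,
                            n_hom_background_sites=60_000,
                            fdr_per_site=rate, seed=40 + i)
            truth = simulate_population(cfg)
            obs = simulate_observations(truth)
            est, _ = estimate_fdr(obs, truth.hom_background_sites(),
                                  truth.normal_cells)
            n_pairs = 60_000 * 11 * 0.886 * 0.9
            se = np.sqrt(rate / n_pairs)
            assert abs(est - rate) < 3 * se + 1e-7

    def test_zero_injected_errors_estimate_zero(self, noise_free_truth,
                                                noise_free_obs):
        est, _ = estimate_fdr(noise_free_obs,
                              noise_free_truth.hom_background_sites(),
                              noise_free_truth.normal_cells)
        assert est == 0.0

    def test_empty_subset_raises(self, small_obs):
        with pytest.raises(ValueError, match="empty"):
            estimate_fdr(small_obs, pd.DataFrame(columns=["chrom", "pos"]))


class TestMitoCrosscheck:
    def test_seven_singletons_over_eleven_cells(self):
        v = pd.DataFrame({"cell_id": [f"BN{i:02d}" for i in range(7)],
                          "pos": np.arange(7) * 100 + 1,
                          "mut_reads": [6, 7, 9, 5, 11, 8, 30]})
        est = mito_fdr_crosscheck(v, n_cells=11, genome_len=16_561)
        assert est == pytest.approx(7 / (11 * 16_561))

    def test_no_variants_gives_zero(self):
        v = pd.DataFrame(columns=["cell_id", "pos", "mut_reads"])
        assert mito_fdr_crosscheck(v, 11) == 0.0

    def test_single_variant_single_cell(self):
        v = pd.DataFrame({"cell_id": ["BN01"], "pos": [5], "mut_reads": [9]})
        assert mito_fdr_crosscheck(v, 1, 16_561) == pytest.approx(6.04e-5,
                                                                  rel=1e-2)

    def test_low_read_and_shared_variants_excluded(self):
        v = pd.DataFrame({
            "cell_id": ["BN01", "BN02", "BN03", "BN03"],
            "pos": [5, 5, 9, 12],
            "mut_reads": [9, 9, 8, 4]})  # pos 5 shared, pos 12 under-read
        est = mito_fdr_crosscheck(v, n_cells=3, genome_len=100)
        assert est == pytest.approx(1 / 300)


class TestSNPFilter:
    GOOD = dict(qual=30, depth=10, allele_qual_p=0.5, dist_nearest=100,
                het_qual_ratio=1.0)

    def test_clean_record_passes(self):
        ok, reasons = snp_site_filter(self.GOOD)
        assert ok and reasons == []

    @pytest.mark.parametrize("field,value,reason", [
        ("qual", 19, "min_quality"),
        ("depth", 4, "min_reads"),
        ("allele_qual_p", 0.01, "allele_quality_p"),
        ("dist_nearest", 4, "snp_distance"),
        ("het_qual_ratio", 0.25, "allele_quality_ratio"),
        ("het_qual_ratio", 3.5, "allele_quality_ratio"),
    ])
    def test_single_violations(self, field, value, reason):
        rec = dict(self.GOOD, **{field: value})
        ok, reasons = snp_site_filter(rec)
        assert not ok and reasons == [reason]

    def test_missing_field_is_named(self):
        rec = dict(self.GOOD)
        del rec["dist_nearest"]
        with pytest.raises(KeyError, match="dist_nearest"):
            snp_site_filter(rec)

    def test_frame_version_agrees_with_scalar(self):
        rows = [dict(self.GOOD),
                dict(self.GOOD, depth=3),
                dict(self.GOOD, qual=10, het_qual_ratio=5.0)]
        df = pd.DataFrame(rows)
        expect = [snp_site_filter(r)[0] for r in rows]
        assert snp_site_filter_frame(df).tolist() == expect


def _qc_obs(cell_id, n_auto=1000, n_x=0, auto_het=0, x_het=0, n_skip=0):
    chroms = ["chr1"] * n_auto + ["chrX"] * n_x
    pos = list(range(1, n_auto + 1)) + list(range(1, n_x + 1))
    geno = (["NC"] * auto_het + ["NN"] * (n_auto - auto_het)
            + ["NC"] * x_het + ["NN"] * (n_x - x_het))
    df = pd.DataFrame({"cell_id": cell_id, "chrom": chroms, "pos": pos,
                       "depth": 20, "mut_reads": 0, "qual": 99,
                       "ranksum_p": 0.5, "genotype": geno})
    return df.iloc[n_skip:]


class TestCellQC:
    def _targets(self, n_auto=1000, n_x=0):
        rows = [("chr1", i, i + 1) for i in range(n_auto)]
        rows += [("chrX", i, i + 1) for i in range(n_x)]
        return pd.DataFrame(rows, columns=["chrom", "start", "end"])

    def test_well_covered_cell_qualifies(self):
        obs = _qc_obs("BC01", n_auto=886, auto_het=2)
        rep = qc_cells(obs, self._targets(1000), sex="male")[0]
        assert rep.qualified and rep.exome_coverage_fraction == pytest.approx(0.886)

    def test_low_coverage_cell_fails_with_reason(self):
        obs = _qc_obs("BC02", n_auto=699)
        rep = qc_cells(obs, self._targets(1000), sex="male")[0]
        assert not rep.qualified and "low coverage" in rep.reason

    def test_x_false_het_excess_disqualifies_male_cell(self):
        obs = _qc_obs("BC03", n_auto=10_000, n_x=10_000, auto_het=2,
                      x_het=200)  # 100x the autosomal false-het rate
        rep = qc_cells(obs, self._targets(10_000, 10_000), sex="male")[0]
        assert not rep.qualified and "X false-het" in rep.reason

    def test_female_sample_skips_x_check(self):
        obs = _qc_obs("BC04", n_auto=10_000, n_x=10_000, auto_het=2, x_het=200)
        rep = qc_cells(obs, self._targets(10_000, 10_000), sex="female")[0]
        assert rep.qualified

    def test_unknown_chromosome_raises(self):
        obs = _qc_obs("BC05", n_auto=10)
        obs.loc[obs.index[:1], "chrom"] = "chr99"
        with pytest.raises(ValueError, match="chr99"):
            qc_cells(obs, self._targets(10), sex="male")

    def test_reports_invariant_under_cell_order(self):
        a = pd.concat([_qc_obs("BC01", 800), _qc_obs("BC02", 900)])
        b = pd.concat([_qc_obs("BC02", 900), _qc_obs("BC01", 800)])
        ra = {r.cell_id: r for r in qc_cells(a, self._targets(1000), "male")}
        rb = {r.cell_id: r for r in qc_cells(b, self._targets(1000), "male")}
        assert ra.keys() == rb.keys()
        for k in ra:
            assert ra[k] == rb[k]
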