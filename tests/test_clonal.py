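"""Genotype posterior machinery, H matrix, subclone clustering,
exclusivity, divergence and cohort recurrence."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from scexome import ErrorRates, SimConfig, build_h_matrix, \
    cluster_cells_genes, divergence_generations, exclusivity_test, \
    genotype_likelihood, genotype_prior, h_score, pca_cells, posterior, \
    simulate_observations, simulate_population, simulate_tissue_normal, \
    survey_recurrence
from scexome.clonal import genotype_likelihood_arrays, linkage_to_newick
from scexome.pipeline import RunConfig, run_pipeline


class TestPrior:
    def test_high_quality_tissue_nn(self):
        np.testing.assert_allclose(genotype_prior("NN", 30, 0.5),
                                   [0.99, 0.005, 0.005])

    def test_low_quality_collapses_to_uniform(self):
        np.testing.assert_allclose(genotype_prior("NN", 5, 0.5),
                                   [1 / 3, 1 / 3, 1 / 3])

    def test_low_ranksum_p_collapses_to_uniform(self):
        np.testing.assert_allclose(genotype_prior("NN", 50, 0.01),
                                   [1 / 3, 1 / 3, 1 / 3])

    def test_mid_quality_tissue_het(self):
        np.testing.assert_allclose(genotype_prior("NC", 15, 0.5),
                                   [0.05, 0.9, 0.05])

    def test_tissue_homozygous_mutant_rejected(self):
        with pytest.raises(ValueError, match="germline"):
            genotype_prior("CC", 30, 0.5)


class TestLikelihood:
    def test_observed_reference_homozygote(self, study_rates):
        lik = genotype_likelihood("NN", 0, 30, study_rates)
        expect_nn = 0.59 * (1 - 6.7e-5) ** 30
        assert lik[0] == pytest.approx(expect_nn, rel=1e-9)
        assert lik[0] == pytest.approx(0.5888, abs=5e-4)

    def test_kept_heterozygote_branch(self, study_rates):
        lik = genotype_likelihood("NC", 15, 30, study_rates)
        assert lik[1] == pytest.approx(1 - 0.41)

    def test_noise_free_rates_are_deterministic(self):
        rates = ErrorRates(ado_het=0.0, fdr=0.0)
        lik = genotype_likelihood("NN", 0, 30, rates)
        assert lik[0] == 1.0 and lik[2] == 0.0

    def test_corrected_variant_drops_homozygote_dropout_factor(self, study_rates):
        raw = genotype_likelihood("NN", 0, 30, study_rates)
        cor = genotype_likelihood("NN", 0, 30, study_rates, corrected=True)
        assert cor[0] == pytest.approx(raw[0] / 0.59)

    def test_vectorized_matches_scalar(self, study_rates):
        rng = np.random.default_rng(12)
        obs = rng.choice(["NN", "NC", "CC"], 40)
        n = rng.integers(1, 60, 40)
        m = rng.integers(0, n + 1)
        arr = genotype_likelihood_arrays(obs, m, n, study_rates)
        for i in range(40):
            np.testing.assert_allclose(
                arr[i], genotype_likelihood(obs[i], m[i], n[i], study_rates))

    def test_zero_depth_rejected(self, study_rates):
        with pytest.raises(ValueError):
            genotype_likelihood("NN", 0, 0, study_rates)


class TestPosteriorAndH:
    @given(st.lists(st.floats(1e-6, 1.0), min_size=3, max_size=3),
           st.lists(st.floats(1e-12, 1.0), min_size=3, max_size=3))
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_posterior_normalizes(self, prior, lik):
        pp = posterior(np.array(prior) / sum(prior), np.array(lik))
        assert abs(pp.sum() - 1.0) < 1e-12

    @pytest.mark.parametrize("pp,expect", [
        ((1 / 3, 1 / 3, 1 / 3), math.log10(2)),
        ((0.5, 0.5, 0.0), 0.0),
        ((0.005, 0.5, 0.495), math.log10(199)),
    ])
    def test_h_score_values(self, pp, expect):
        assert h_score(np.array(pp)) == pytest.approx(expect, abs=1e-6)

    def test_h_score_finite_at_degenerate_posterior(self):
        assert np.isfinite(h_score(np.array([0.0, 1.0, 0.0])))

    def test_sign_coherence_on_noise_free_data(self, noise_free_truth,
                                               noise_free_obs):
        truth, obs = noise_free_truth, noise_free_obs
        rates = ErrorRates(ado_het=1e-9, fdr=1e-9)
        tissue = simulate_tissue_normal(truth)
        som = truth.somatic_sites()
        H = build_h_matrix(obs, tissue, rates, truth.normal_cells,
                           sites=som[["chrom", "pos", "gene"]],
                           bn_filter_threshold=np.inf)
        cells = list(H.site_values.index)
        cell_ix = {c: i for i, c in enumerate(truth.cells.cell_id)}
        site_ix = {f"{c}:{p}": i for i, (c, p) in
                   enumerate(zip(truth.sites.chrom, truth.sites.pos))}
        raw = H.site_values.mask(H.imputed_mask)
        for cell in cells:
            for site in H.site_values.columns:
                v = raw.loc[cell, site]
                if np.isnan(v):
                    continue
                g = truth.genotypes[cell_ix[cell], site_ix[site]]
                assert (v > 0) == (g > 0)


class TestHMatrix:
    def _toy(self):
        rows = []
        for cell, geno, depth in (("BC01", "NC", 30), ("BC02", "NC", 25),
                                  ("BN01", "NN", 28)):
            rows.append((cell, "chr1", 100, "A", "T", depth,
                         depth // 2 if geno == "NC" else 0, 99, 0.5, geno))
        # second site uncovered in BC02
        rows.append(("BC01", "chr1", 200, "G", "C", 30, 15, 99, 0.5, "NC"))
        rows.append(("BN01", "chr1", 200, "G", "C", 30, 0, 99, 0.5, "NN"))
        obs = pd.DataFrame(rows, columns=["cell_id", "chrom", "pos", "ref",
                                          "alt", "depth", "mut_reads",
                                          "qual", "ranksum_p", "genotype"])
        tissue = pd.DataFrame({"chrom": ["chr1"] * 2, "pos": [100, 200],
                               "qual": 99, "ranksum_p": 0.5,
                               "genotype": "NN"})
        return obs, tissue

    def test_imputed_entries_equal_site_means(self, study_rates):
        obs, tissue = self._toy()
        H = build_h_matrix(obs, tissue, study_rates, ["BN01"],
                           bn_filter_threshold=np.inf)
        site = "chr1:200"
        covered = H.site_values.loc[["BC01", "BN01"], site]
        assert H.imputed_mask.loc["BC02", site]
        assert H.site_values.loc["BC02", site] == pytest.approx(covered.mean())

    def test_suspicious_gene_filtered_on_raw_normal_values(self, study_rates):
        obs, tissue = self._toy()
        # make the normal cell look mutant at site 100
        obs.loc[(obs.cell_id == "BN01") & (obs.pos == 100),
                ["genotype", "mut_reads"]] = ["NC", 14]
        sites = pd.DataFrame({"chrom": ["chr1"] * 2, "pos": [100, 200],
                              "gene": ["G1", "G2"]})
        H = build_h_matrix(obs, tissue, study_rates, ["BN01"], sites=sites)
        assert H.filtered_genes == ["G1"]
        assert H.retained_genes == ["G2"]

    def test_all_genes_suspicious_raises(self, study_rates):
        obs, tissue = self._toy()
        obs.loc[obs.cell_id == "BN01", ["genotype", "mut_reads"]] = \
            ["NC", 14]
        with pytest.raises(ValueError, match="suspicious"):
            build_h_matrix(obs, tissue, study_rates, ["BN01"])


def _structured_run(seed, **kw):
    cfg = SimConfig(seed=seed, n_germline_het_sites=300,
                    n_hom_background_sites=300, **kw)
    truth = simulate_population(cfg)
    obs = simulate_observations(truth)
    tissue = simulate_tissue_normal(truth)
    rates = ErrorRates(ado_het=cfg.ado_het, fdr=max(cfg.fdr_per_site, 1e-12))
    som = truth.somatic_sites()
    # heatmap over planted nonsynonymous gene sites, as the pipeline does
    from scexome.calling import call_somatic
    calls = call_somatic(obs, tissue, truth.normal_cells, truth.tumor_cells,
                         site_annotations=truth.sites)
    ns = calls[calls.csq_class == "NS"]
    common = ns[ns.n_cancer_mutant >= 0.2 * ns.n_cancer_covered]
    H = build_h_matrix(obs, tissue, rates, truth.normal_cells,
                       sites=common[["chrom", "pos", "gene"]])
    return truth, H


class TestClustering:
    def test_recovers_three_subclones_and_normal_cluster(self):
        truth, H = _structured_run(7)
        assign = cluster_cells_genes(H)
        labels = assign.cell_labels
        tl = truth.cells.set_index("cell_id").clone.reindex(labels.index)
        # normal cells form one cluster apart from tumor cells
        assert tl[labels == labels[truth.normal_cells[0]]].eq("N").all()
        tumor_labels = labels[tl != "N"]
        assert tumor_labels.nunique() == 3
        assert adjusted_rand_score(tl, labels) >= 0.9

    def test_single_clone_population_yields_two_clusters(self):
        truth, H = _structured_run(31, n_cloneB_muts=0, n_cloneC_muts=0,
                                   n_neutral_tail_muts=0)
        assign = cluster_cells_genes(H)
        assert assign.k_cells == 2

    def test_partition_invariant_under_cell_order(self):
        truth, H = _structured_run(8)
        a = cluster_cells_genes(H)
        perm = np.random.default_rng(0).permutation(len(H.values))
        from scexome.clonal import HMatrix
        H2 = HMatrix(values=H.values.iloc[perm],
                     site_values=H.site_values.iloc[perm],
                     imputed_mask=H.imputed_mask.iloc[perm],
                     retained_genes=H.retained_genes,
                     filtered_genes=H.filtered_genes)
        b = cluster_cells_genes(H2)
        pa = a.cell_labels.sort_index()
        pb = b.cell_labels.sort_index()
        assert adjusted_rand_score(pa, pb) == 1.0

    def test_gene_groups_match_planted_mutation_groups(self):
        truth, H = _structured_run(9)
        assign = cluster_cells_genes(H)
        grp = truth.sites.set_index("gene").group.to_dict()
        for label, genes in assign.subclone_genes.items():
            planted = {grp.get(g) for g in genes}
            # each signature group is dominated by one planted clone
            top = pd.Series([grp.get(g) for g in genes]).mode()[0]
            frac = np.mean([grp.get(g) == top for g in genes])
            assert frac >= 0.8

    def test_too_few_cells_rejected(self, study_rates):
        from scexome.clonal import HMatrix
        v = pd.DataFrame(np.zeros((2, 3)), index=["a", "b"])
        H = HMatrix(values=v, site_values=v, imputed_mask=v.astype(bool),
                    retained_genes=[0, 1, 2], filtered_genes=[])
        with pytest.raises(ValueError):
            cluster_cells_genes(H)

    def test_newick_export_parses(self):
        truth, H = _structured_run(10)
        assign = cluster_cells_genes(H)
        nwk = linkage_to_newick(assign.cell_linkage, list(H.values.index))
        import dendropy
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        assert len(tree.leaf_nodes()) == len(H.values)


def hypergeom_tail_oracle(table, side):
    """Exhaustive hypergeometric enumeration for a 2x2 table."""
    a, b = table[0]
    c, d = table[1]
    n = a + b + c + d
    row1, col1 = a + b, a + c
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    def prob(x):
        return (math.comb(col1, x) * math.comb(n - col1, row1 - x)
                / math.comb(n, row1))
    if side == "less":
        return sum(prob(x) for x in range(lo, a + 1))
    return sum(prob(x) for x in range(a, hi + 1))


class TestExclusivity:
    def _matrix(self, sets, n_cells=44):
        cells = [f"c{i}" for i in range(n_cells)]
        data = {g: [i in s for i in range(n_cells)] for g, s in sets.items()}
        return pd.DataFrame(data, index=cells)

    def test_disjoint_genes_closed_form(self):
        mm = self._matrix({"a": set(range(15)), "b": set(range(15, 30))})
        res = exclusivity_test(mm, "a", "b")
        expect = math.comb(29, 15) / math.comb(44, 15)
        assert res["exclusivity_p"] == pytest.approx(expect, rel=1e-9)

    def test_identical_genes(self):
        mm = self._matrix({"a": set(range(15)), "b": set(range(15))})
        res = exclusivity_test(mm, "a", "b")
        assert res["exclusivity_p"] == pytest.approx(1.0)
        assert res["concurrence_p"] < 1e-6

    def test_all_cells_mutant_degenerate(self):
        mm = self._matrix({"a": set(range(44)), "b": set(range(10))})
        res = exclusivity_test(mm, "a", "b")
        assert res["concurrence_p"] == pytest.approx(1.0)
        assert res["exclusivity_p"] == pytest.approx(1.0)

    def test_agrees_with_enumeration_oracle_on_small_tables(self):
        rng = np.random.default_rng(13)
        for _ in range(60):
            n = int(rng.integers(4, 21))
            a = set(rng.choice(n, rng.integers(1, n), replace=False).tolist())
            b = set(rng.choice(n, rng.integers(1, n), replace=False).tolist())
            mm = self._matrix({"a": a, "b": b}, n_cells=n)
            res = exclusivity_test(mm, "a", "b")
            table = res["table"]
            assert res["exclusivity_p"] == pytest.approx(
                hypergeom_tail_oracle(table, "less"), rel=1e-8)
            assert res["concurrence_p"] == pytest.approx(
                hypergeom_tail_oracle(table, "greater"), rel=1e-8)

    def test_not_shown_convention(self):
        mm = self._matrix({"a": set(range(20)), "b": set(range(10, 30))})
        res = exclusivity_test(mm, "a", "b")
        assert res["concurrence_shown"] == (res["concurrence_p"] < 0.3)


class TestDivergence:
    def test_study_operating_point_forty_generations(self):
        est = divergence_generations(12, mu=5e-9, S=6e7)
        assert est.generations == 40

    def test_zero_mutations_zero_generations(self):
        assert divergence_generations(0).generations == 0

    def test_doubling_size_halves_generations(self):
        a = divergence_generations(12, mu=5e-9, S=6e7).generations
        b = divergence_generations(12, mu=5e-9, S=1.2e8).generations
        assert b * 2 == a


class TestRecurrence:
    COHORT = pd.DataFrame({
        "patient": [f"P{i}" for i in range(7)] + ["P0", "P1", "P2", "P0"],
        "gene": ["CFTR"] * 7 + ["ATM"] * 3 + ["ONEOFF"],
    })

    def test_known_recurrent_gene(self):
        out = survey_recurrence(["CFTR"], self.COHORT)
        assert out.n_patients.iloc[0] == 7 and out.recurrent.iloc[0]

    def test_absent_gene(self):
        out = survey_recurrence(["NOPE"], self.COHORT)
        assert out.n_patients.iloc[0] == 0 and not out.recurrent.iloc[0]

    def test_threshold_boundary_three_patients(self):
        out = survey_recurrence(["ATM", "ONEOFF"], self.COHORT)
        assert out.set_index("gene").recurrent.to_dict() == {
            "ATM": True, "ONEOFF": False}


class TestPCA:
    def test_first_component_separates_tumor_from_normal(self):
        cfg = SimConfig(seed=14, n_germline_het_sites=100,
                        n_hom_background_sites=100)
        truth = simulate_population(cfg)
        obs = simulate_observations(truth)
        som = truth.somatic_sites()
        keys = set(zip(som.chrom, som.pos))
        o = obs[[(c, p) in keys for c, p in zip(obs.chrom.astype(str), obs.pos)]]
        g = (o.assign(d=o.genotype.astype(str).map({"NN": 0.0, "NC": 1.0,
                                                    "CC": 2.0}))
             .pivot_table(index="cell_id", columns="pos", values="d",
                          observed=True))
        coords, _, evr = pca_cells(g)
        tumor = set(truth.tumor_cells)
        pc1_t = coords.PC1[[c in tumor for c in coords.index]]
        pc1_n = coords.PC1[[c not in tumor for c in coords.index]]
        assert pc1_t.min() > pc1_n.max() or pc1_t.max() < pc1_n.min()
        assert (np.diff(evr) <= 1e-12).all()

    def test_constant_matrix_rejected(self):
        g = pd.DataFrame(np.ones((5, 4)))
        with pytest.raises(ValueError, match="constant"):
            pca_cells(g)
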