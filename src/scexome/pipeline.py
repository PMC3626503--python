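"""End-to-end orchestration: QC -> error model -> thresholds -> calling ->
frequency spectrum -> clonal structure, on synthetic or loaded inputs."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import calling, clonal, errors, io, sim, smafs

__version__ = "0.1.0"


@dataclass
class RunConfig:
    """One reproducible run: inputs, thresholds and estimator choices."""

    sim: sim.SimConfig = field(default_factory=sim.SimConfig)
    seed: int = 0
    exome_size: float = 5e7
    coverage_min: float = 0.70
    qc_alpha: float = 0.01
    sex: str = "male"
    bn_filter: float = 0.5
    bulk_min_reads: int = 1
    recurrence_min: int = 3
    estimator: str = "count"          # or "ml"
    normal_model: str = "operating_point"
    normal_operating_point: int = 6
    heatmap_min_mut_fraction: float = 0.20
    divergence_mu: float = 5e-9
    divergence_S: float = 6e7
    out: str | None = None

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        d["sim"] = self.sim.to_dict()
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()[:12]


def _snp_filter_fields(obs: pd.DataFrame) -> pd.DataFrame:
    """Derive the SNP-filter fields available for synthetic records.

    Distance to the nearest other site comes from the site catalog; the
    rank-sum p doubles as the allele-quality balance p; synthetic reads
    carry no per-base qualities, so the heterozygous quality ratio is the
    neutral 1.0.
    """
    sites = obs[["chrom", "pos"]].drop_duplicates().copy()
    sites["chrom"] = sites["chrom"].astype(str)
    dists = {}
    for chrom, sub in sites.groupby("chrom"):
        p = np.sort(sub.pos.to_numpy())
        if len(p) == 1:
            d = np.array([np.inf])
        else:
            gap = np.diff(p)
            d = np.minimum(np.r_[np.inf, gap], np.r_[gap, np.inf])
        dists.update({(chrom, int(x)): float(dd) for x, dd in zip(p, d)})
    o = obs.copy()
    key = list(zip(o.chrom.astype(str), o.pos.astype(int)))
    o["dist_nearest"] = [dists[k] for k in key]
    o["allele_qual_p"] = o["ranksum_p"]
    o["het_qual_ratio"] = 1.0
    return o


class StageError(RuntimeError):
    def __init__(self, stage, cause):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the statistics report.

    All randomness derives from ``config.seed``; two runs with the same
    configuration are bit-identical.  With ``config.out`` set, the report,
    call VCF and stage tables are written under that directory.
    """
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
    }
    simcfg = dataclasses.replace(config.sim, seed=config.seed)

    # -- simulate ----------------------------------------------------------
    try:
        truth = sim.simulate_population(simcfg)
        obs = sim.simulate_observations(truth)
        tissue = sim.simulate_tissue_normal(truth)
        bulk = sim.simulate_bulk(truth)
        targets = sim.target_bed(truth)
    except Exception as e:  # pragma: no cover - config errors
        raise StageError("simulate", e) from e

    # -- cell QC -----------------------------------------------------------
    try:
        qc = errors.qc_cells(obs, targets, sex=config.sex,
                             coverage_min=config.coverage_min,
                             alpha=config.qc_alpha,
                             germline_sites=truth.germline_sites())
        qualified = {r.cell_id for r in qc if r.qualified}
        normal_q = [c for c in truth.normal_cells if c in qualified]
        tumor_q = [c for c in truth.tumor_cells if c in qualified]
        report["qc"] = {
            "n_cells": len(qc),
            "n_qualified": len(qualified),
            "n_tumor_qualified": len(tumor_q),
            "n_normal_qualified": len(normal_q),
            "mean_coverage": float(np.mean(
                [r.exome_coverage_fraction for r in qc if r.qualified])),
        }
        if not normal_q:
            raise ValueError("no qualified normal cells")
    except StageError:
        raise
    except Exception as e:
        raise StageError("qc", e) from e

    # -- error model -------------------------------------------------------
    try:
        germ = truth.germline_sites()
        # depth strata need enough sites each; scale with catalog size
        min_per_depth = int(max(3, min(50, len(germ) // 100)))
        ado_hat, ado_cells = errors.estimate_ado(
            obs, tissue, germ, normal_q, min_sites_per_depth=min_per_depth)
        fdr_hat, fdr_cells = errors.estimate_fdr(
            obs, truth.hom_background_sites(), normal_q)
        rates = errors.ErrorRates(ado_het=ado_hat,
                                  fdr=max(fdr_hat, 1e-12),
                                  per_cell_ado=ado_cells,
                                  per_cell_fdr=fdr_cells)
        report["error_model"] = {"ado": ado_hat, "fdr": fdr_hat,
                                 "per_cell_ado": ado_cells}
    except Exception as e:
        raise StageError("error_model", e) from e

    # -- thresholds --------------------------------------------------------
    try:
        min_cancer = calling.min_mutant_cancer_cells(
            max(fdr_hat, 1e-30), len(tumor_q), config.exome_size)
        min_normal = calling.min_normal_cells_covered(
            ado_hat, len(normal_q), config.exome_size,
            model=config.normal_model,
            operating_point=config.normal_operating_point)
        report["thresholds"] = {"min_cancer_mutant": min_cancer,
                                "min_normal_covered": min_normal}
    except Exception as e:
        raise StageError("thresholds", e) from e

    # -- site filtering + somatic calling ----------------------------------
    try:
        with_fields = _snp_filter_fields(obs)
        keep = errors.snp_site_filter_frame(with_fields)
        filtered = obs[keep.to_numpy()]
        filtered = filtered[filtered.cell_id.isin(qualified)]
        calls = calling.call_somatic(
            filtered, tissue, normal_q, tumor_q,
            min_normal_covered=min_normal, min_cancer_mutant=min_cancer,
            site_annotations=truth.sites)
        calls, bulk_pct = calling.bulk_support(calls, bulk,
                                               min_reads=config.bulk_min_reads)
        summary = calling.summarize_calls(calls)
        report["calls"] = {
            "n_calls": len(calls),
            "not_evaluable": calls.attrs.get("not_evaluable", 0),
            "bulk_supported_pct": bulk_pct,
            "summary": summary,
        }
    except Exception as e:
        raise StageError("calling", e) from e

    # -- SMAFS -------------------------------------------------------------
    try:
        freqs = calls.cell_frequency.to_numpy()
        classes = calls.csq_class.fillna("NA").to_numpy()
        spectrum = smafs.build_spectrum(freqs, classes)
        fit = smafs.fit_hyperbolic(spectrum)
        ns_f = freqs[classes == "NS"]
        s_f = freqs[classes == "S"]
        ns_p = ns_table = None
        ns_p_nopeak = None
        if ns_f.size and s_f.size:
            ns_p, ns_table = smafs.test_ns_shift(ns_f, s_f)
            try:
                ns_p_nopeak, _ = smafs.test_ns_shift(ns_f, s_f,
                                                     exclude_peak=True)
            except ValueError:
                pass
        b = bulk.copy()
        b["chrom"] = b["chrom"].astype(str)
        merged = calls.merge(b, on=["chrom", "pos"], how="inner",
                             suffixes=("", "_bulkref"))
        bf = merged.mut_reads / (merged.mut_reads + merged.ref_reads)
        r2 = smafs.correlate_with_bulk(merged.cell_frequency, bf) \
            if len(merged) >= 3 else None
        report["smafs"] = {
            "spectrum": spectrum.counts.tolist(),
            "hyperbolic_p": fit.pvalue,
            "peak_excess": fit.peak_excess,
            "hyperbolic_scale": fit.scale,
            "ns_shift_p": ns_p,
            "ns_shift_p_excluding_peak": ns_p_nopeak,
            "ns_shift_table": None if ns_table is None else ns_table.tolist(),
            "bulk_r2": r2,
        }
        if config.estimator == "ml":
            site_key = set(zip(calls.chrom.astype(str), calls.pos))
            fobs = filtered[filtered.cell_id.isin(tumor_q)].copy()
            fobs["chrom"] = fobs["chrom"].astype(str)
            mlf = {}
            for (chrom, pos), sub in fobs.groupby(["chrom", "pos"], observed=True):
                if (chrom, pos) in site_key:
                    mlf[f"{chrom}:{pos}"] = smafs.ml_frequency(sub, rates)
            report["smafs"]["ml_frequencies"] = mlf
    except Exception as e:
        raise StageError("smafs", e) from e

    # -- clonal structure --------------------------------------------------
    try:
        ns_calls = calls[calls.csq_class == "NS"]
        common = ns_calls[
            ns_calls.n_cancer_mutant
            >= config.heatmap_min_mut_fraction * ns_calls.n_cancer_covered]
        hsites = common[["chrom", "pos", "gene"]]
        hobs = filtered[filtered.cell_id.isin(qualified)]
        H = clonal.build_h_matrix(hobs, tissue, rates, normal_q,
                                  sites=hsites,
                                  bn_filter_threshold=config.bn_filter)
        assignment = clonal.cluster_cells_genes(H)
        truth_labels = truth.cells.set_index("cell_id").clone
        joint = pd.DataFrame({
            "found": assignment.cell_labels,
            "truth": truth_labels.reindex(assignment.cell_labels.index)})
        ari = float(adjusted_rand_score(joint.truth, joint.found))
        tumor_labels = assignment.cell_labels[
            assignment.cell_labels.index.isin(tumor_q)]
        n_tumor_clusters = int(tumor_labels.nunique())

        mut_mat = (
            hobs[hobs.cell_id.isin(tumor_q)]
            .assign(chrom=lambda d: d.chrom.astype(str))
            .merge(hsites.assign(chrom=lambda d: d.chrom.astype(str)),
                   on=["chrom", "pos"])
            .assign(is_mut=lambda d: d.genotype.astype(str).isin(calling.MUTANT))
            .pivot_table(index="cell_id", columns="gene", values="is_mut",
                         aggfunc="max", fill_value=False, observed=True)
            .astype(bool))
        groups = truth.sites.loc[truth.sites.group.isin(["cloneB", "cloneC"]),
                                 ["gene", "group"]]
        gb = [g for g in groups.loc[groups.group == "cloneB", "gene"]
              if g in mut_mat.columns]
        gc = [g for g in groups.loc[groups.group == "cloneC", "gene"]
              if g in mut_mat.columns]
        n_pairs = n_excl = 0
        best_p = {g: 1.0 for g in gb + gc}
        for a in gb:
            for bgene in gc:
                res = clonal.exclusivity_test(mut_mat, a, bgene)
                n_pairs += 1
                n_excl += res["exclusivity_p"] < 0.05
                best_p[a] = min(best_p[a], res["exclusivity_p"])
                best_p[bgene] = min(best_p[bgene], res["exclusivity_p"])
        n_excl_genes = sum(p < 0.05 for p in best_p.values())
        largest_specific = max(
            (len(v) for v in assignment.subclone_genes.values()), default=0)
        div = clonal.divergence_generations(
            largest_specific or 12, mu=config.divergence_mu,
            S=config.divergence_S)

        gmat = (
            hobs[["cell_id", "chrom", "pos", "genotype"]]
            .assign(chrom=lambda d: d.chrom.astype(str))
            .merge(calls[["chrom", "pos"]].assign(
                chrom=lambda d: d.chrom.astype(str)), on=["chrom", "pos"])
            .assign(dosage=lambda d: d.genotype.astype(str).map(
                {"NN": 0.0, "NC": 1.0, "CC": 2.0}))
            .pivot_table(index="cell_id", columns="pos", values="dosage",
                         observed=True))
        coords, _, evr = clonal.pca_cells(gmat, n_components=2,
                                          seed=config.seed)
        pc1_tumor = coords.loc[coords.index.isin(tumor_q), "PC1"]
        pc1_normal = coords.loc[coords.index.isin(normal_q), "PC1"]
        pc1_separates = bool(pc1_tumor.min() > pc1_normal.max()
                             or pc1_tumor.max() < pc1_normal.min())

        report["clonal"] = {
            "n_heatmap_genes": len(H.retained_genes),
            "n_filtered_genes": len(H.filtered_genes),
            "k_cells": assignment.k_cells,
            "n_tumor_clusters": n_tumor_clusters,
            "ari_vs_truth": ari,
            "exclusive_pairs": [n_excl, n_pairs],
            "exclusive_genes": [n_excl_genes, len(best_p)],
            "divergence": div.to_dict(),
            "pca_pc1_separates_tumor_normal": pc1_separates,
            "pca_explained_variance": evr.tolist(),
        }
    except Exception as e:
        raise StageError("clonal", e) from e

    if config.out:
        _write_outputs(config, report, calls, obs, tissue, bulk, rates, H,
                       assignment)
    return report


def _write_outputs(config, report, calls, obs, tissue, bulk, rates, H,
                   assignment) -> None:
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    io.write_json(report, out / "report.json")
    io.write_vcf(calls, out / "somatic_calls.vcf")
    io.write_error_rates(rates, out / "error_rates.json")
    H.values.to_csv(out / "h_matrix.tsv", sep="\t")
    (out / "dendrogram_cells.nwk").write_text(
        clonal.linkage_to_newick(assignment.cell_linkage,
                                 list(H.values.index)))
    (out / "dendrogram_genes.nwk").write_text(
        clonal.linkage_to_newick(assignment.gene_linkage,
                                 list(H.values.columns)))
    md = [f"# Pipeline report (seed {report['seed']}, "
          f"config {report['config_hash']})", ""]
    for k, v in report.items():
        if isinstance(v, dict):
            md.append(f"## {k}")
            for kk, vv in v.items():
                md.append(f"- {kk}: {vv}")
            md.append("")
    (out / "report.md").write_text("\n".join(md))
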