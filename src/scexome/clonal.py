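"""Bayesian mutant-evidence scores, subclone clustering and lineage analyses.

At every covered (cell, site) the three diploid genotypes A in {NN, NC, CC}
get a prior from the matched-tissue genotype (weighted by a quality tier
Pn in {1/3, 0.9, 0.99}), a likelihood calibrated by ADO and FDR, and a
posterior Pp(A | O).  The heat-map score is the log-odds of mutant vs normal

    H = log10[(Pp(NC|O) + Pp(CC|O)) / Pp(NN|O)].

Cells x genes H matrices (uncovered entries imputed by the site mean over
covered cells) are clustered hierarchically on both axes to recover the
subclone structure; gene-pair concurrence/exclusivity is tested by Fisher's
exact test on the binary mutation matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

EPS = 1e-12
GENOTYPES = ("NN", "NC", "CC")
_GCODE = {"NN": 0, "NC": 1, "CC": 2}


def quality_prior_weight(quality: float, ranksum_p: float) -> float:
    """Tiered confidence Pn of the tissue genotype."""
    if quality < 10 or ranksum_p < 0.05:
        return 1.0 / 3.0
    if quality < 20:
        return 0.9
    return 0.99


def genotype_prior(tissue_genotype: str, quality: float,
                   ranksum_p: float = 1.0) -> np.ndarray:
    """Prior over (NN, NC, CC) from the matched-tissue genotype.

    The tissue genotype receives weight Pn; Pr(CC) is always (1-Pn)/2 (a
    homozygous-mutant germline is not expected) and the remaining diploid
    genotype takes the rest.
    """
    pn = quality_prior_weight(quality, ranksum_p)
    half = (1.0 - pn) / 2.0
    if tissue_genotype == "NN":
        return np.array([pn, half, half])
    if tissue_genotype == "NC":
        return np.array([half, pn, half])
    raise ValueError("unexpected homozygous-mutant germline (tissue CC)")


def genotype_likelihood(observed_genotype: str, m: int, n: int, rates,
                        corrected: bool = False) -> np.ndarray:
    """P(O | A) for A in (NN, NC, CC) given m mutant of n reads.

    The heterozygous branch depends on the observed genotype: dropout of
    either allele (probability f_heter, split evenly) yields an apparent
    homozygote whose reads then follow the per-site error binomial; without
    dropout the heterozygous call is kept with probability 1 - f_heter.
    The homozygous branches carry a (1 - f_homo) factor mirroring the
    heterozygous branch; since dropout cannot change a homozygote's
    genotype, ``corrected`` drops it.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= m <= n:
        raise ValueError("require 0 <= m <= n")
    f_het, f_hom, f_p = rates.ado_het, rates.ado_hom, rates.fdr
    hom_factor = 1.0 if corrected else (1.0 - f_hom)
    bin_ref = stats.binom.pmf(m, n, f_p)        # reads from an NN product
    bin_alt = stats.binom.pmf(n - m, n, f_p)    # reads from a CC product
    l_nn = hom_factor * bin_ref
    l_cc = hom_factor * bin_alt
    if observed_genotype == "NN":
        l_nc = 0.5 * f_het * bin_ref
    elif observed_genotype == "NC":
        l_nc = 1.0 - f_het
    elif observed_genotype == "CC":
        l_nc = 0.5 * f_het * bin_alt
    else:
        raise ValueError(f"unknown genotype '{observed_genotype}'")
    return np.array([l_nn, l_nc, l_cc])


def genotype_likelihood_arrays(observed, m, n, rates,
                               corrected: bool = False) -> np.ndarray:
    """Vectorized :func:`genotype_likelihood` -> array (N, 3)."""
    obs = np.asarray(observed)
    m = np.asarray(m, dtype=np.int64)
    n = np.asarray(n, dtype=np.int64)
    if np.any(n < 1):
        raise ValueError("n must be >= 1")
    f_het, f_hom, f_p = rates.ado_het, rates.ado_hom, rates.fdr
    hom_factor = 1.0 if corrected else (1.0 - f_hom)
    bin_ref = stats.binom.pmf(m, n, f_p)
    bin_alt = stats.binom.pmf(n - m, n, f_p)
    l_nn = hom_factor * bin_ref
    l_cc = hom_factor * bin_alt
    l_nc = np.where(obs == "NC", 1.0 - f_het,
                    np.where(obs == "NN", 0.5 * f_het * bin_ref,
                             0.5 * f_het * bin_alt))
    return np.stack([l_nn, l_nc, l_cc], axis=1)


def posterior(prior: np.ndarray, likelihood: np.ndarray) -> np.ndarray:
    """Normalized genotype posterior Pp(A | O)."""
    w = np.asarray(prior) * np.asarray(likelihood)
    tot = w.sum(axis=-1, keepdims=True)
    if np.any(tot <= 0):
        raise ValueError("zero posterior mass")
    return w / tot


def h_score(pp: np.ndarray) -> float:
    """log10 odds of mutant (NC or CC) vs normal (NN), floored at EPS."""
    pp = np.clip(np.asarray(pp, dtype=float), EPS, None)
    return float(np.log10((pp[..., 1] + pp[..., 2]) / pp[..., 0]))


@dataclass
class HMatrix:
    """Cells x genes mutant-evidence matrix with provenance."""

    values: pd.DataFrame            # cells x genes (post filter)
    site_values: pd.DataFrame       # cells x sites, imputed
    imputed_mask: pd.DataFrame      # cells x sites, True where imputed
    retained_genes: list
    filtered_genes: list


def build_h_matrix(obs: pd.DataFrame, tissue: pd.DataFrame, rates,
                   normal_cells: list,
                   sites: pd.DataFrame | None = None,
                   bn_filter_threshold: float = 0.5,
                   gene_agg: str = "max",
                   corrected: bool = False) -> HMatrix:
    """Posterior H scores per (cell, site), imputed and aggregated to genes.

    ``sites`` (chrom, pos, gene) restricts and maps sites to genes; by
    default every observed site is its own gene.  Uncovered entries are
    imputed with the mean H of covered cells at that site before gene
    aggregation (max over the gene's sites, or sum with ``gene_agg='sum'``).
    Genes whose H reaches ``bn_filter_threshold`` in any normal cell are
    suspicious (likely mutant in normal cells) and removed.
    """
    o = obs.copy()
    o["chrom"] = o["chrom"].astype(str)
    o["site"] = o["chrom"] + ":" + o["pos"].astype(str)
    t = tissue.copy()
    t["chrom"] = t["chrom"].astype(str)
    t["site"] = t["chrom"] + ":" + t["pos"].astype(str)

    if sites is not None:
        s = sites.copy()
        s["chrom"] = s["chrom"].astype(str)
        s["site"] = s["chrom"] + ":" + s["pos"].astype(str)
        if "gene" not in s:
            s["gene"] = s["site"]
        gene_of = dict(zip(s.site, s.gene))
        o = o[o.site.isin(gene_of)]
    else:
        gene_of = {site: site for site in o.site.unique()}

    t = t.set_index("site")
    tiss_geno = t["genotype"].astype(str)
    pn = np.array([quality_prior_weight(q, p)
                   for q, p in zip(t["qual"], t["ranksum_p"])])
    prior_tab = pd.DataFrame({
        "pn": pn, "tissue_genotype": tiss_geno.to_numpy()}, index=t.index)
    if (prior_tab.tissue_genotype == "CC").any():
        raise ValueError("unexpected homozygous-mutant germline (tissue CC)")

    o = o.join(prior_tab, on="site", how="inner")
    half = (1.0 - o.pn.to_numpy()) / 2.0
    is_nn = (o.tissue_genotype == "NN").to_numpy()
    prior = np.empty((len(o), 3))
    prior[:, 0] = np.where(is_nn, o.pn, half)
    prior[:, 1] = np.where(is_nn, half, o.pn)
    prior[:, 2] = half

    lik = genotype_likelihood_arrays(
        o.genotype.astype(str).to_numpy(), o.mut_reads.to_numpy(),
        o.depth.to_numpy(), rates, corrected=corrected)
    pp = posterior(prior, lik)
    pp = np.clip(pp, EPS, None)
    o["H"] = np.log10((pp[:, 1] + pp[:, 2]) / pp[:, 0])

    raw_h = o.pivot_table(index="cell_id", columns="site", values="H",
                          observed=True)
    imputed = raw_h.isna()
    site_h = raw_h.fillna(raw_h.mean(axis=0))
    site_h = site_h.dropna(axis=1, how="all")  # sites covered in no cell
    imputed = imputed[site_h.columns]
    raw_h = raw_h[site_h.columns]

    genes = pd.Index([gene_of[sname] for sname in site_h.columns], name="gene")
    if gene_agg == "max":
        gene_h = site_h.T.groupby(genes).max().T
        gene_h_raw = raw_h.T.groupby(genes).max().T
    elif gene_agg == "sum":
        gene_h = site_h.T.groupby(genes).sum().T
        gene_h_raw = raw_h.T.groupby(genes).sum().T
    else:
        raise ValueError(f"unknown gene_agg '{gene_agg}'")

    # suspicious-gene screen uses raw (covered, non-imputed) values only:
    # imputation at tumor-dominated sites would wrongly paint normal cells
    bn = [c for c in normal_cells if c in gene_h.index]
    suspicious = gene_h_raw.loc[bn].max(axis=0) >= bn_filter_threshold if bn \
        else pd.Series(False, index=gene_h.columns)
    filtered = sorted(gene_h.columns[suspicious])
    retained = [g for g in gene_h.columns if g not in set(filtered)]
    if not retained:
        raise ValueError("all genes filtered as suspicious")
    return HMatrix(values=gene_h[retained], site_values=site_h,
                   imputed_mask=imputed, retained_genes=retained,
                   filtered_genes=filtered)


@dataclass
class CloneAssignment:
    cell_labels: pd.Series          # 1..K, ordered by decreasing clone size
    gene_labels: pd.Series          # "I", "II", ... or "other"
    k_cells: int
    k_genes: int
    cell_linkage: np.ndarray
    gene_linkage: np.ndarray
    subclone_genes: dict = field(default_factory=dict)
    cell_silhouettes: dict = field(default_factory=dict)
    gene_silhouettes: dict = field(default_factory=dict)
    method: str = "two-stage ward/euclidean"


def _relabel_by_size(lab: np.ndarray) -> np.ndarray:
    order = pd.Series(lab).value_counts().index.tolist()
    remap = {old: i + 1 for i, old in enumerate(order)}
    return np.array([remap[v] for v in lab])


def _silhouette_cut(X: np.ndarray, k_range) -> tuple[np.ndarray, np.ndarray, dict]:
    Z = hierarchy.linkage(X, method="ward", metric="euclidean")
    scores = {}
    for k in k_range:
        if k >= len(X):
            continue
        lab = hierarchy.fcluster(Z, t=k, criterion="maxclust")
        if len(np.unique(lab)) < 2:
            continue
        scores[k] = float(silhouette_score(X, lab))
    if not scores:
        return np.ones(len(X), dtype=int), Z, scores
    k_best = max(scores, key=scores.get)
    return hierarchy.fcluster(Z, t=k_best, criterion="maxclust"), Z, scores


def coherent_gene_groups(Ht: pd.DataFrame, shared_threshold: float = 0.6,
                         min_group_size: int = 3,
                         min_mean_corr: float = 0.3,
                         k_range=range(2, 6)) -> tuple[list, dict]:
    """Subclone-signature gene groups among tumor cells.

    Genes mutant (H > 0.5) in fewer than ``shared_threshold`` of tumor cells
    are candidate subclone markers; they are Ward-clustered across tumor
    cells (silhouette-selected cut) and a cluster is kept as a signature
    group when it has >= ``min_group_size`` genes whose mean pairwise
    correlation exceeds ``min_mean_corr`` — clone-specific genes co-occur in
    their clone's cells, low-frequency passenger mutations correlate with
    nothing.  Returns (list of gene lists, silhouette scores).
    """
    mut_frac = (Ht > 0.5).mean(axis=0)
    cand = Ht.columns[mut_frac < shared_threshold]
    if len(cand) < max(min_group_size, 3):
        return [], {}
    Xg = Ht[cand].to_numpy().T
    Zg = hierarchy.linkage(Xg, method="ward", metric="euclidean")
    corr = np.corrcoef(Xg)

    def mean_corr(idx):
        return corr[np.ix_(idx, idx)][np.triu_indices(len(idx), 1)].mean()

    # scan every cut depth; clusters of a hierarchy are nested across cuts,
    # so keeping maximal coherent clusters yields disjoint gene groups
    coherent: list[frozenset] = []
    scores = {}
    k_max = min(max(k_range), len(cand) - 1)
    for k in range(2, k_max + 1):
        lab = hierarchy.fcluster(Zg, t=k, criterion="maxclust")
        if len(np.unique(lab)) >= 2:
            scores[k] = float(silhouette_score(Xg, lab))
        for c in np.unique(lab):
            idx = np.flatnonzero(lab == c)
            if len(idx) < min_group_size:
                continue
            if mean_corr(idx) > min_mean_corr:
                coherent.append(frozenset(idx))
    maximal = [s for s in coherent
               if not any(s < t for t in coherent)]
    groups = sorted({s: [cand[i] for i in sorted(s)]
                     for s in maximal}.values(), key=len, reverse=True)
    return groups, scores


def cluster_cells_genes(h: HMatrix, k_range=range(2, 7),
                        method: str = "two-stage",
                        shared_threshold: float = 0.6) -> CloneAssignment:
    """Recover the subclone structure from the H matrix.

    The default two-stage procedure first separates mutant-rich (tumor)
    from mutant-poor (normal) cells by a Ward cut at k = 2 over all genes,
    then identifies coherent subclone gene groups among the tumor cells
    (:func:`coherent_gene_groups`) and cuts the tumor subtree into
    (number of signature groups + 1) clusters — each group marks one
    derived subclone, plus the base clone carrying none of them.  With
    ``method='silhouette'`` a single silhouette-selected cut over all cells
    is used instead.  Cluster labels are ordered by decreasing size; gene
    groups are labelled "I" (shared by most tumor cells), "II", "III", ...
    (signature groups, largest first) and "other".
    """
    X = h.values.to_numpy()
    cells = h.values.index
    if X.shape[0] < 3:
        raise ValueError("need >= 3 cells to cluster")
    Zc = hierarchy.linkage(X, method="ward", metric="euclidean")
    Zg = hierarchy.linkage(X.T, method="ward", metric="euclidean")

    if method == "silhouette":
        lab, _, sc = _silhouette_cut(X, k_range)
        glab_num, _, sg = _silhouette_cut(X.T, k_range)
        gene_lab = pd.Series([str(v) for v in _relabel_by_size(glab_num)],
                             index=h.values.columns, name="group")
        cell_lab = _relabel_by_size(lab)
        return CloneAssignment(
            cell_labels=pd.Series(cell_lab, index=cells, name="clone"),
            gene_labels=gene_lab, k_cells=len(np.unique(cell_lab)),
            k_genes=len(np.unique(gene_lab)), cell_linkage=Zc,
            gene_linkage=Zg, cell_silhouettes=sc, gene_silhouettes=sg,
            method="silhouette ward/euclidean")

    # stage 1: mutant-rich vs mutant-poor cells
    lab2 = hierarchy.fcluster(Zc, t=2, criterion="maxclust")
    mean_h = [X[lab2 == c].mean() for c in (1, 2)]
    tumor_side = 1 + int(np.argmax(mean_h))
    tumor_cells = cells[lab2 == tumor_side]
    Ht = h.values.loc[tumor_cells]

    # stage 2: subclone cut driven by coherent signature gene groups
    groups, sg = coherent_gene_groups(Ht, shared_threshold=shared_threshold)
    keep = [g for grp in groups for g in grp]
    labels = pd.Series(0, index=cells, dtype=int)
    sc = {}
    if groups and len(keep) >= 2 and len(tumor_cells) > len(groups) + 1:
        k_tumor = len(groups) + 1
        Zt = hierarchy.linkage(Ht[keep].to_numpy(), method="ward")
        tl = hierarchy.fcluster(Zt, t=k_tumor, criterion="maxclust")
        labels.loc[tumor_cells] = tl
    else:
        labels.loc[tumor_cells] = 1
    cell_lab = _relabel_by_size(labels.to_numpy())

    mut_frac = (Ht > 0.5).mean(axis=0)
    gene_lab = pd.Series("other", index=h.values.columns, name="group")
    gene_lab[mut_frac[mut_frac >= shared_threshold].index] = "I"
    roman = ["II", "III", "IV", "V", "VI"]
    subclone_genes = {}
    for i, grp in enumerate(groups[: len(roman)]):
        gene_lab[grp] = roman[i]
        subclone_genes[roman[i]] = list(grp)
    n_groups = int(gene_lab.nunique())
    return CloneAssignment(
        cell_labels=pd.Series(cell_lab, index=cells, name="clone"),
        gene_labels=gene_lab, k_cells=len(np.unique(cell_lab)),
        k_genes=n_groups, cell_linkage=Zc, gene_linkage=Zg,
        subclone_genes=subclone_genes, cell_silhouettes=sc,
        gene_silhouettes=sg)


def linkage_to_newick(Z: np.ndarray, labels: list) -> str:
    """Serialize a scipy linkage matrix as a newick tree string."""
    tree = hierarchy.to_tree(Z)

    def walk(node):
        if node.is_leaf():
            return str(labels[node.id])
        left, right = walk(node.left), walk(node.right)
        return f"({left}:{node.dist:.6g},{right}:{node.dist:.6g})"

    return walk(tree) + ";"


def exclusivity_test(mut_matrix: pd.DataFrame, gene_a: str,
                     gene_b: str, not_shown_above: float = 0.3
                     ) -> dict:
    """Fisher concurrence/exclusivity p-values for one gene pair.

    ``mut_matrix`` is a cells x genes boolean frame.  Concurrence tests
    enrichment of co-mutant cells, exclusivity tests depletion; p-values at
    or above ``not_shown_above`` are additionally marked not-shown (the
    convention used when rendering the pairwise matrix).
    """
    a = mut_matrix[gene_a].astype(bool).to_numpy()
    b = mut_matrix[gene_b].astype(bool).to_numpy()
    if a.sum() == 0 or b.sum() == 0:
        raise ValueError("both genes must be mutant in >= 1 cell")
    table = np.array([[int((a & b).sum()), int((a & ~b).sum())],
                      [int((~a & b).sum()), int((~a & ~b).sum())]])
    _, p_conc = stats.fisher_exact(table, alternative="greater")
    _, p_excl = stats.fisher_exact(table, alternative="less")
    return {"table": table, "concurrence_p": float(p_conc),
            "exclusivity_p": float(p_excl),
            "concurrence_shown": p_conc < not_shown_above,
            "exclusivity_shown": p_excl < not_shown_above}


def exclusivity_test_permutation(mut_matrix: pd.DataFrame, gene_a: str,
                                 gene_b: str, n_perm: int = 10_000,
                                 seed: int = 0) -> dict:
    """Permutation version: shuffle one gene's cell labels."""
    rng = np.random.default_rng(seed)
    a = mut_matrix[gene_a].astype(bool).to_numpy()
    b = mut_matrix[gene_b].astype(bool).to_numpy()
    obs_overlap = int((a & b).sum())
    perm = np.array([
        int((a & rng.permutation(b)).sum()) for _ in range(n_perm)])
    p_conc = (1 + (perm >= obs_overlap).sum()) / (n_perm + 1)
    p_excl = (1 + (perm <= obs_overlap).sum()) / (n_perm + 1)
    return {"concurrence_p": float(p_conc), "exclusivity_p": float(p_excl)}


@dataclass
class DivergenceEstimate:
    clone_mutation_count: int
    mutation_rate: float
    callable_size: float
    generations: int

    def to_dict(self) -> dict:
        return {"clone_mutation_count": self.clone_mutation_count,
                "mutation_rate_per_bp_per_generation": self.mutation_rate,
                "callable_size_bp": self.callable_size,
                "generations": self.generations}


def divergence_generations(clone_mut_count: int, mu: float = 5e-9,
                           S: float = 6e7) -> DivergenceEstimate:
    """Upper bound on clone divergence time: count / (mu * S) generations."""
    if mu <= 0 or S <= 0:
        raise ValueError("mu and S must be positive")
    gen = 0 if clone_mut_count == 0 else math.ceil(clone_mut_count / (mu * S))
    return DivergenceEstimate(clone_mut_count, mu, S, gen)


def survey_recurrence(genes, cohort: pd.DataFrame,
                      min_patients: int = 3) -> pd.DataFrame:
    """Distinct patients with non-silent mutations per queried gene."""
    counts = cohort.groupby("gene")["patient"].nunique()
    rows = [{"gene": g, "n_patients": int(counts.get(g, 0))} for g in genes]
    out = pd.DataFrame(rows)
    out["recurrent"] = out.n_patients >= min_patients
    return out


def pca_cells(gmatrix: pd.DataFrame, n_components: int = 2,
              max_iter: int = 25, tol: float = 1e-6, seed: int = 0):
    """PCA of cells over somatic-site genotype dosages with iterative
    low-rank imputation of missing entries.

    Missing values start at column means and are refined from the rank-k
    reconstruction until convergence (a lightweight probabilistic-PCA-style
    imputation).  Returns (coordinates, components, explained_variance_ratio).
    """
    X = gmatrix.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need >= 2 cells")
    mask = np.isnan(X)
    col_mean = np.nanmean(np.where(mask, np.nan, X), axis=0)
    col_mean = np.nan_to_num(col_mean)
    if np.allclose(np.nanstd(X, axis=0), 0):
        raise ValueError("constant genotype matrix")
    Xf = np.where(mask, col_mean, X)
    n_components = min(n_components, X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=n_components, random_state=seed)
    prev = None
    for _ in range(max_iter):
        scores = pca.fit_transform(Xf)
        recon = pca.inverse_transform(scores)
        Xf = np.where(mask, recon, X)
        if prev is not None and np.max(np.abs(recon - prev)) < tol:
            break
        prev = recon
    coords = pd.DataFrame(scores, index=gmatrix.index,
                          columns=[f"PC{i+1}" for i in range(n_components)])
    return coords, pca.components_, pca.explained_variance_ratio_
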