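"""Synthetic single-cell exome populations with clonal structure and WGA noise.

The generator emulates a tumor/normal single-cell exome experiment: a tumor
cell population descended from one ancestral cell (so every tumor cell carries
the ancestral heterozygous mutations), two later subclones with their own
mutation groups, a neutral-expansion tail of low-frequency mutations whose
carrier counts follow the ~1/k spectrum of an expanding population, germline
heterozygous background sites, and a homozygous background used for
false-discovery estimation.  Observations pass through per-cell allele dropout
(ADO), per-site false positives (FDR) and overdispersed coverage.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# integer genotype codes used throughout
NN, NC, CC = 0, 1, 2
GENOTYPE_LABELS = np.array(["NN", "NC", "CC"])

AUTOSOMES = [f"chr{i}" for i in range(1, 23)]
CHRX = "chrX"

#: consequence-class mix of the non-clonal (neutral tail) mutations.  Clonal
#: group mutations are nonsynonymous by construction; the tail carries the
#: remaining mix of coding and non-coding classes seen in exome+flank calls.
TAIL_CLASS_PROBS = {
    "NS": 0.261,
    "S": 0.147,
    "3UTR": 0.035,
    "5UTR": 0.020,
    "intron": 0.517,
    "intergenic": 0.020,
}


@dataclass
class SimConfig:
    """Parameters of the simulated single-cell experiment.

    Defaults mirror the study conditions the pipeline is designed for:
    44 tumor + 11 normal cells, three subclones at fractions (0.30, 0.35,
    0.35), 22 ancestral / 7 clone-B / 12 clone-C mutant genes, ADO 0.41,
    FDR 6.7e-5, 40x mean single-cell depth with 88.6% target coverage,
    a 50 Mb exome design, 28x normal-tissue and 137x tumor-tissue depth.
    """

    n_tumor_cells: int = 44
    n_normal_cells: int = 11
    clone_fractions: tuple = (0.30, 0.35, 0.35)
    n_ancestral_muts: int = 22
    n_cloneB_muts: int = 7
    n_cloneC_muts: int = 12
    n_neutral_tail_muts: int = 400
    n_germline_het_sites: int = 20_000
    n_hom_background_sites: int = 50_000
    exome_size_bp: int = 50_000_000
    ado_het: float = 0.41
    ado_hom: float = 0.41
    fdr_per_site: float = 6.7e-5
    per_read_error: float = 1e-3
    mean_depth: float = 40.0
    depth_dispersion: float = 8.0
    coverage_fraction: float = 0.886
    tissue_normal_depth: float = 28.0
    tissue_tumor_depth: float = 137.0
    x_hom_fraction: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if abs(sum(self.clone_fractions) - 1.0) > 1e-9:
            raise ValueError("clone_fractions must sum to 1")
        for name in ("ado_het", "ado_hom", "fdr_per_site", "per_read_error",
                     "coverage_fraction", "x_hom_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("n_tumor_cells", "n_normal_cells", "n_ancestral_muts",
                     "n_cloneB_muts", "n_cloneC_muts", "n_neutral_tail_muts",
                     "n_germline_het_sites", "n_hom_background_sites"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.exome_size_bp <= 0:
            raise ValueError("exome_size_bp must be positive")
        if self.mean_depth <= 0 or self.depth_dispersion <= 0:
            raise ValueError("depth parameters must be positive")

    def clone_cell_counts(self) -> dict:
        """Integer cells per clone (largest-remainder rounding)."""
        fracs = np.asarray(self.clone_fractions, dtype=float)
        raw = fracs * self.n_tumor_cells
        counts = np.floor(raw).astype(int)
        rem = self.n_tumor_cells - counts.sum()
        order = np.argsort(-(raw - counts))
        counts[order[:rem]] += 1
        out = dict(zip("ABC", counts.tolist()))
        for clone, n in out.items():
            if n == 0:
                raise ValueError(
                    f"clone {clone} receives zero cells under "
                    f"fractions {self.clone_fractions} with "
                    f"{self.n_tumor_cells} tumor cells")
        return out

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["clone_fractions"] = list(self.clone_fractions)
        return d


@dataclass
class SimTruth:
    """Ground truth of a simulated population."""

    config: SimConfig
    cells: pd.DataFrame          # cell_id, clone (A/B/C/N), is_tumor
    sites: pd.DataFrame          # chrom, pos, ref, alt, group, csq_class, gene, true_frequency
    genotypes: np.ndarray        # cells x sites, int8 codes NN/NC/CC

    @property
    def tumor_cells(self) -> list:
        return self.cells.loc[self.cells.is_tumor, "cell_id"].tolist()

    @property
    def normal_cells(self) -> list:
        return self.cells.loc[~self.cells.is_tumor, "cell_id"].tolist()

    def cell_to_clone(self) -> dict:
        return dict(zip(self.cells.cell_id, self.cells.clone))

    def mutation_groups(self) -> pd.Series:
        return self.sites.set_index(self.sites.chrom + ":" + self.sites.pos.astype(str))["group"]

    def germline_sites(self) -> pd.DataFrame:
        return self.sites.loc[self.sites.group == "germline", ["chrom", "pos"]]

    def hom_background_sites(self) -> pd.DataFrame:
        return self.sites.loc[self.sites.group == "hom_background", ["chrom", "pos"]]

    def somatic_sites(self) -> pd.DataFrame:
        m = self.sites.group.isin(["ancestral", "cloneB", "cloneC", "neutral_tail"])
        return self.sites.loc[m]

    def truth_json(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "cell_to_clone": self.cell_to_clone(),
            "mutation_groups": {
                f"{c}:{p}": g for c, p, g in
                zip(self.sites.chrom, self.sites.pos, self.sites.group)
            },
            "true_site_frequency": {
                f"{c}:{p}": float(f) for c, p, f in
                zip(self.sites.chrom, self.sites.pos, self.sites.true_frequency)
            },
            "error_rates": {
                "ado_het": self.config.ado_het,
                "ado_hom": self.config.ado_hom,
                "fdr": self.config.fdr_per_site,
            },
        }


def _draw_positions(rng, chroms, n):
    """Assign n sites to chromosomes with >=10 bp spacing within a chromosome."""
    chrom_idx = rng.integers(0, len(chroms), size=n)
    chrom = np.asarray(chroms, dtype=object)[chrom_idx]
    pos = np.empty(n, dtype=np.int64)
    for ci in np.unique(chrom_idx):
        m = chrom_idx == ci
        gaps = rng.integers(10, 2000, size=m.sum())
        pos[m] = 1 + np.cumsum(gaps)
    return chrom, pos


def _neutral_carrier_counts(rng, n_muts, n_cells):
    """Carrier counts k with P(k) ∝ 1/k, k in 1..n_cells.

    The ~1/f spectrum of neutral mutations accumulating in an expanding
    population, expressed at the level of heterozygous carrier cells.
    """
    k = np.arange(1, n_cells + 1)
    p = (1.0 / k) / (1.0 / k).sum()
    return rng.choice(k, size=n_muts, p=p)


def simulate_population(config: SimConfig, rng=None) -> SimTruth:
    """Build the ground-truth cell population and mutation catalog."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)

    clone_counts = config.clone_cell_counts()
    clones = (["A"] * clone_counts["A"] + ["B"] * clone_counts["B"]
              + ["C"] * clone_counts["C"])
    cell_ids = [f"BC{i+1:02d}" for i in range(config.n_tumor_cells)]
    cell_ids += [f"BN{i+1:02d}" for i in range(config.n_normal_cells)]
    cells = pd.DataFrame({
        "cell_id": cell_ids,
        "clone": clones + ["N"] * config.n_normal_cells,
        "is_tumor": [True] * config.n_tumor_cells + [False] * config.n_normal_cells,
    })

    blocks = []  # (group, n, chrom list, class assignment, gene prefix)
    tail_classes = list(TAIL_CLASS_PROBS)
    tail_p = np.array([TAIL_CLASS_PROBS[c] for c in tail_classes])

    def make_block(group, n, chroms, classes, genes):
        chrom, pos = _draw_positions(rng, chroms, n)
        bases = np.array(list("ACGT"))
        ref = rng.choice(bases, size=n)
        alt_shift = rng.integers(1, 4, size=n)
        alt = bases[(np.searchsorted(bases, ref) + alt_shift) % 4]
        blocks.append(pd.DataFrame({
            "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
            "group": group, "csq_class": classes, "gene": genes,
        }))

    make_block("ancestral", config.n_ancestral_muts, AUTOSOMES,
               ["NS"] * config.n_ancestral_muts,
               [f"GA{i+1:03d}" for i in range(config.n_ancestral_muts)])
    make_block("cloneB", config.n_cloneB_muts, AUTOSOMES,
               ["NS"] * config.n_cloneB_muts,
               [f"GB{i+1:03d}" for i in range(config.n_cloneB_muts)])
    make_block("cloneC", config.n_cloneC_muts, AUTOSOMES,
               ["NS"] * config.n_cloneC_muts,
               [f"GC{i+1:03d}" for i in range(config.n_cloneC_muts)])
    make_block("neutral_tail", config.n_neutral_tail_muts, AUTOSOMES,
               rng.choice(tail_classes, size=config.n_neutral_tail_muts, p=tail_p),
               [f"GT{i+1:04d}" for i in range(config.n_neutral_tail_muts)])
    make_block("germline", config.n_germline_het_sites, AUTOSOMES,
               ["NA"] * config.n_germline_het_sites,
               ["NA"] * config.n_germline_het_sites)
    n_hom = config.n_hom_background_sites
    n_hom_x = int(round(n_hom * config.x_hom_fraction))
    hom_chroms = ([CHRX] * 1)
    # homozygous background split between autosomes and chrX (male sample:
    # chrX carries no true heterozygotes, which the X-QC check relies on)
    chrom_a, pos_a = _draw_positions(rng, AUTOSOMES, n_hom - n_hom_x)
    chrom_x, pos_x = _draw_positions(rng, [CHRX], n_hom_x)
    bases = np.array(list("ACGT"))
    ref = rng.choice(bases, size=n_hom)
    alt = bases[(np.searchsorted(bases, ref) + rng.integers(1, 4, size=n_hom)) % 4]
    blocks.append(pd.DataFrame({
        "chrom": np.concatenate([chrom_a, chrom_x]),
        "pos": np.concatenate([pos_a, pos_x]),
        "ref": ref, "alt": alt, "group": "hom_background",
        "csq_class": "NA", "gene": "NA",
    }))

    sites = pd.concat(blocks, ignore_index=True)
    # de-duplicate any (chrom, pos) collisions across blocks
    sites = sites.drop_duplicates(["chrom", "pos"]).reset_index(drop=True)

    n_cells = len(cells)
    n_sites = len(sites)
    G = np.zeros((n_cells, n_sites), dtype=np.int8)
    tumor_idx = np.flatnonzero(cells.is_tumor.to_numpy())
    group = sites.group.to_numpy()

    G[:, group == "germline"] = NC                      # all cells
    G[np.ix_(tumor_idx, np.flatnonzero(group == "ancestral"))] = NC
    for clone, g in (("B", "cloneB"), ("C", "cloneC")):
        cidx = np.flatnonzero((cells.clone == clone).to_numpy())
        G[np.ix_(cidx, np.flatnonzero(group == g))] = NC

    tail_idx = np.flatnonzero(group == "neutral_tail")
    if tail_idx.size:
        ks = _neutral_carrier_counts(rng, tail_idx.size, config.n_tumor_cells)
        for j, k in zip(tail_idx, ks):
            carriers = rng.choice(tumor_idx, size=k, replace=False)
            G[carriers, j] = NC

    # true mutant-haploid frequency: somatic groups over tumor haploids,
    # germline over all haploids
    Gt = G[tumor_idx]
    freq = (Gt == NC).sum(axis=0) + 2 * (Gt == CC).sum(axis=0)
    freq = freq / (2.0 * len(tumor_idx))
    is_germ = group == "germline"
    allf = ((G == NC).sum(axis=0) + 2 * (G == CC).sum(axis=0)) / (2.0 * n_cells)
    sites = sites.assign(true_frequency=np.where(is_germ, allf, freq))

    return SimTruth(config=config, cells=cells, sites=sites, genotypes=G)


def _nb_depth(rng, mean, dispersion, size):
    """Overdispersed depth: negative binomial with given mean and size."""
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def simulate_observations(truth: SimTruth, config: SimConfig | None = None,
                          rng=None) -> pd.DataFrame:
    """Observe the truth through coverage, depth, ADO, FDR and read noise.

    Returns the per-cell, per-site observation table (only covered sites
    appear).  Genotype calls follow the post-error allele content: a
    heterozygote that drops an allele is called the corresponding homozygote;
    a true homozygote flips to a false heterozygote with probability
    ``fdr_per_site``; the per-read error rate only feeds the mutant-read
    count at homozygous sites.
    """
    cfg = config or truth.config
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)

    n_sites = len(truth.sites)
    chrom = truth.sites.chrom.to_numpy()
    pos = truth.sites.pos.to_numpy()
    ref = truth.sites.ref.to_numpy()
    alt = truth.sites.alt.to_numpy()

    frames = []
    for i, cell in enumerate(truth.cells.cell_id):
        covered = rng.random(n_sites) < cfg.coverage_fraction
        depth = _nb_depth(rng, cfg.mean_depth, cfg.depth_dispersion, n_sites)
        covered &= depth > 0
        idx = np.flatnonzero(covered)
        if idx.size == 0:
            continue
        g = truth.genotypes[i, idx].copy()
        n = depth[idx]

        het = g == NC
        drop = het & (rng.random(idx.size) < cfg.ado_het)
        # dropped allele chosen uniformly: falls back to NN or CC
        g[drop] = np.where(rng.random(drop.sum()) < 0.5, NN, CC)
        hom = (g != NC) & (truth.genotypes[i, idx] != NC)
        flip = hom & (rng.random(idx.size) < cfg.fdr_per_site)
        g[flip] = NC

        p_read = np.choose(g, [cfg.per_read_error, 0.5, 1.0 - cfg.per_read_error])
        m = rng.binomial(n, p_read)

        qual = rng.choice(np.array([99, 15, 5]), size=idx.size,
                          p=[0.95, 0.04, 0.01])
        u = rng.random(idx.size)
        low = rng.random(idx.size) < 0.02
        ranksum_p = np.where(low, 0.05 * u, 0.05 + 0.95 * u)

        frames.append(pd.DataFrame({
            "cell_id": cell,
            "chrom": chrom[idx], "pos": pos[idx],
            "ref": ref[idx], "alt": alt[idx],
            "depth": n.astype(np.int32), "mut_reads": m.astype(np.int32),
            "qual": qual.astype(np.int16),
            "ranksum_p": np.round(ranksum_p, 6),
            "genotype": GENOTYPE_LABELS[g],
        }))
    obs = pd.concat(frames, ignore_index=True)
    obs["cell_id"] = obs["cell_id"].astype("category")
    obs["chrom"] = obs["chrom"].astype("category")
    obs["genotype"] = obs["genotype"].astype("category")
    return obs


def simulate_tissue_normal(truth: SimTruth, mean_depth: float | None = None,
                           rng=None) -> pd.DataFrame:
    """Matched normal-tissue consensus genotypes with per-site depth/quality."""
    cfg = truth.config
    if mean_depth is None:
        mean_depth = cfg.tissue_normal_depth
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 2)
    n_sites = len(truth.sites)
    depth = np.maximum(_nb_depth(rng, mean_depth, cfg.depth_dispersion, n_sites), 1)
    geno = np.where(truth.sites.group.to_numpy() == "germline", "NC", "NN")
    qual = rng.choice(np.array([99, 15]), size=n_sites, p=[0.99, 0.01])
    u = rng.random(n_sites)
    low = rng.random(n_sites) < 0.01
    ranksum_p = np.where(low, 0.05 * u, 0.05 + 0.95 * u)
    return pd.DataFrame({
        "chrom": truth.sites.chrom, "pos": truth.sites.pos,
        "ref": truth.sites.ref, "alt": truth.sites.alt,
        "depth": depth.astype(np.int32),
        "qual": qual.astype(np.int16),
        "ranksum_p": np.round(ranksum_p, 6),
        "genotype": geno,
    })


def simulate_bulk(truth: SimTruth, mean_depth: float | None = None,
                  rng=None) -> pd.DataFrame:
    """Bulk tumor-tissue read counts: mut_reads ~ Binomial(depth, f)."""
    cfg = truth.config
    if mean_depth is None:
        mean_depth = cfg.tissue_tumor_depth
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 3)
    n_sites = len(truth.sites)
    depth = np.maximum(_nb_depth(rng, mean_depth, cfg.depth_dispersion, n_sites), 1)
    f = truth.sites.true_frequency.to_numpy()
    err = cfg.per_read_error
    p_eff = f * (1 - err) + (1 - f) * err
    mut = rng.binomial(depth, p_eff)
    return pd.DataFrame({
        "chrom": truth.sites.chrom, "pos": truth.sites.pos,
        "ref_reads": (depth - mut).astype(np.int32),
        "mut_reads": mut.astype(np.int32),
    })


def target_bed(truth: SimTruth) -> pd.DataFrame:
    """Target regions as 0-based half-open single-base intervals per site."""
    return pd.DataFrame({
        "chrom": truth.sites.chrom,
        "start": truth.sites.pos - 1,
        "end": truth.sites.pos,
    })
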