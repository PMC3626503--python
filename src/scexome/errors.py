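"""Cell QC and estimation of the two single-cell error parameters.

Allele dropout (ADO) is estimated per normal cell from a germline
heterozygous background: at each sequencing depth the heterozygous rate of
the cell is compared with that of matched tissue sequencing through the
relative false-negative rate

    relFNR(n) = (HR_T/CR_T - HR_S/CR_S) / (HR_T/CR_T)

and the cell's ADO is the median of relFNR over non-outlier depths (depths
where the tissue rate falls below the cell's are discarded).  The population
ADO is the mean over qualified normal cells.

The false discovery rate (FDR; a truly homozygous site called heterozygous)
is the fraction of discrepant sites in a high-confidence homozygous subset
(top quality tier, depth inside the central 95% Poisson interval), averaged
over normal cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ErrorRates:
    """ADO/FDR parameters consumed by callers and the posterior model."""

    ado_het: float              # f_heter = p_a
    fdr: float                  # f_p
    ado_hom: float | None = None  # f_homo; defaults to ado_het
    per_cell_ado: dict = field(default_factory=dict)
    per_cell_fdr: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.ado_hom is None:
            self.ado_hom = self.ado_het
        for name in ("ado_het", "ado_hom", "fdr"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")

    def to_dict(self) -> dict:
        return {"ado_het": self.ado_het, "ado_hom": self.ado_hom,
                "fdr": self.fdr, "per_cell_ado": self.per_cell_ado,
                "per_cell_fdr": self.per_cell_fdr}


@dataclass
class CellQCReport:
    cell_id: str
    exome_coverage_fraction: float
    x_het_rate: float
    x_het_pvalue: float
    qualified: bool
    reason: str = ""


def _merge_sites(obs: pd.DataFrame, sites: pd.DataFrame) -> pd.DataFrame:
    key = sites[["chrom", "pos"]].copy()
    key["chrom"] = key["chrom"].astype(str)
    o = obs.copy()
    o["chrom"] = o["chrom"].astype(str)
    return o.merge(key, on=["chrom", "pos"], how="inner")


def qc_cells(obs: pd.DataFrame, targets: pd.DataFrame, sex: str = "male",
             coverage_min: float = 0.70, alpha: float = 0.01,
             germline_sites: pd.DataFrame | None = None) -> list[CellQCReport]:
    """Qualify cells on exome coverage and (males) X-chromosome false hets.

    Coverage is the fraction of target bases covered by at least one read.
    For a male sample every heterozygous call on chrX is spurious, so the
    X het rate is tested one-sided (binomial) against the cell's autosomal
    false-het rate computed outside the germline catalog.
    """
    if targets is None or len(targets) == 0:
        raise ValueError("targets must be nonempty")
    target_chroms = set(targets.chrom.astype(str))
    obs_chroms = set(obs.chrom.astype(str).unique())
    unknown = obs_chroms - target_chroms
    if unknown:
        raise ValueError(f"observation chromosomes absent from targets: {sorted(unknown)}")
    total_bp = int((targets.end - targets.start).sum())

    # membership test of 1-bp site positions against target intervals
    tkey = {}
    for chrom, sub in targets.groupby("chrom", observed=True):
        starts = np.sort(sub.start.to_numpy())
        ends = sub.end.to_numpy()[np.argsort(sub.start.to_numpy())]
        tkey[str(chrom)] = (starts, ends)

    germ_keys = set()
    if germline_sites is not None and len(germline_sites):
        germ_keys = set(zip(germline_sites.chrom.astype(str),
                            germline_sites.pos.astype(int)))

    reports = []
    for cell, sub in obs.groupby("cell_id", observed=True, sort=False):
        chroms = sub.chrom.astype(str).to_numpy()
        pos = sub.pos.to_numpy()
        in_target = np.zeros(len(sub), dtype=bool)
        for chrom in np.unique(chroms):
            starts, ends = tkey[chrom]
            m = chroms == chrom
            j = np.searchsorted(starts, pos[m] - 1, side="right") - 1
            ok = (j >= 0) & (pos[m] - 1 < ends[np.clip(j, 0, None)])
            in_target[m] = ok
        covered_bp = len(set(zip(chroms[in_target], pos[in_target])))
        coverage = covered_bp / total_bp

        het = (sub.genotype.astype(str) == "NC").to_numpy()
        on_x = chroms == "chrX"
        is_germ = np.fromiter(
            ((c, p) in germ_keys for c, p in zip(chroms, pos)),
            dtype=bool, count=len(sub)) if germ_keys else np.zeros(len(sub), bool)

        auto_bg = ~on_x & ~is_germ
        n_auto = int(auto_bg.sum())
        p0 = het[auto_bg].sum() / n_auto if n_auto else 0.0
        p0 = max(p0, 1.0 / (n_auto + 1)) if n_auto else 1.0

        n_x = int(on_x.sum())
        k_x = int(het[on_x].sum())
        x_rate = k_x / n_x if n_x else 0.0
        if sex == "male" and n_x > 0:
            x_p = stats.binomtest(k_x, n_x, p0, alternative="greater").pvalue
        else:
            x_p = 1.0

        reasons = []
        if coverage < coverage_min:
            reasons.append("low coverage")
        if x_p < alpha:
            reasons.append("X false-het excess")
        reports.append(CellQCReport(
            cell_id=str(cell), exome_coverage_fraction=coverage,
            x_het_rate=x_rate, x_het_pvalue=float(x_p),
            qualified=not reasons, reason="; ".join(reasons)))
    return reports


def relative_fnr(hr_t: float, cr_t: float, hr_s: float, cr_s: float) -> float:
    """Relative false-negative rate at one depth stratum.

    May be negative when the tissue het rate falls below the single cell's;
    such depths are treated as outliers by the ADO estimator.
    """
    if cr_t <= 0 or hr_t <= 0:
        raise ValueError("tissue heterozygous rate undefined at this depth")
    if cr_s <= 0:
        raise ValueError("cell covered rate is zero at this depth")
    rt = hr_t / cr_t
    rs = hr_s / cr_s
    return (rt - rs) / rt


def depth_profile(cell_obs: pd.DataFrame, tissue_obs: pd.DataFrame,
                  germline_sites: pd.DataFrame) -> pd.DataFrame:
    """Per-depth het/covered rates of one cell and the tissue over germline sites."""
    total = len(germline_sites)
    if total == 0:
        raise ValueError("empty germline subset")
    cg = _merge_sites(cell_obs, germline_sites)
    tg = _merge_sites(tissue_obs, germline_sites)

    def rates(df):
        d = df.assign(is_het=(df.genotype.astype(str) == "NC"))
        grp = d.groupby("depth")
        cov = grp.size()
        het = grp.is_het.sum()
        return pd.DataFrame({"n_sites": cov, "cr": cov / total, "hr": het / total})

    rc = rates(cg).add_suffix("_s")
    rt = rates(tg).add_suffix("_t")
    return rc.join(rt, how="inner")


def estimate_ado_cell(cell_obs: pd.DataFrame, tissue_obs: pd.DataFrame,
                      germline_sites: pd.DataFrame,
                      min_sites_per_depth: int = 50) -> float:
    """ADO of one normal cell: median relFNR over non-outlier depth strata."""
    prof = depth_profile(cell_obs, tissue_obs, germline_sites)
    lo, hi = prof.index.to_series().quantile([0.01, 0.99])
    prof = prof[(prof.index >= lo) & (prof.index <= hi)]
    prof = prof[(prof.n_sites_s >= min_sites_per_depth)
                & (prof.n_sites_t >= min_sites_per_depth)
                & (prof.hr_t > 0)]
    if len(prof) == 0:
        raise ValueError("insufficient depth strata")
    fnr = 1.0 - (prof.hr_s / prof.cr_s) / (prof.hr_t / prof.cr_t)
    fnr = fnr[fnr >= 0]  # negative relFNR depths are outliers
    if len(fnr) < 3:
        raise ValueError("insufficient depth strata")
    return float(fnr.median())


def estimate_ado(obs: pd.DataFrame, tissue_obs: pd.DataFrame,
                 germline_sites: pd.DataFrame, normal_cells: list,
                 min_sites_per_depth: int = 50) -> tuple[float, dict]:
    """Population ADO: mean of per-cell estimates over qualified normal cells."""
    per_cell = {}
    for cell in normal_cells:
        sub = obs[obs.cell_id == cell]
        per_cell[cell] = estimate_ado_cell(sub, tissue_obs, germline_sites,
                                           min_sites_per_depth)
    return float(np.mean(list(per_cell.values()))), per_cell


def estimate_fdr(obs: pd.DataFrame, hom_sites: pd.DataFrame,
                 normal_cells: list | None = None,
                 qual_min: int = 99, poisson_ci: float = 0.95) -> tuple[float, dict]:
    """Population FDR from the high-confidence homozygous background.

    Per cell: discrepant (heterozygous-called) sites divided by covered
    subset sites, the subset being top-quality records whose depth lies in
    the central ``poisson_ci`` interval of a Poisson with the cell's mean
    depth.  Population value is the mean over cells.
    """
    if len(hom_sites) == 0:
        raise ValueError("empty homozygous subset")
    sub = _merge_sites(obs, hom_sites)
    if normal_cells is not None:
        sub = sub[sub.cell_id.isin(normal_cells)]
    if len(sub) == 0:
        raise ValueError("no observations over the homozygous subset")
    tail = (1.0 - poisson_ci) / 2.0
    per_cell = {}
    for cell, s in sub.groupby("cell_id", observed=True):
        mu = s.depth.mean()
        lo, hi = stats.poisson.ppf([tail, 1 - tail], mu)
        hi_conf = s[(s.qual >= qual_min) & (s.depth >= lo) & (s.depth <= hi)]
        if len(hi_conf) == 0:
            continue
        n_disc = int((hi_conf.genotype.astype(str) == "NC").sum())
        per_cell[str(cell)] = n_disc / len(hi_conf)
    if not per_cell:
        raise ValueError("empty high-confidence homozygous subset")
    return float(np.mean(list(per_cell.values()))), per_cell


def mito_fdr_crosscheck(variants: pd.DataFrame, n_cells: int,
                        genome_len: int = 16_561,
                        min_mut_reads: int = 5) -> float:
    """All-false-positive FDR bound from per-cell mitochondrial variants.

    ``variants`` needs columns cell_id, pos, mut_reads.  Variants below
    ``min_mut_reads`` are discarded; a variant recurring in two or more
    cells is excluded (the premise that everything counted is false assumes
    no two cells share a mutation).  Returns retained variants divided by
    n_cells x genome_len; the denominator is exposed so alternative callable
    -size conventions can be applied.
    """
    if genome_len <= 0:
        raise ValueError("genome_len must be positive")
    if len(variants) == 0:
        return 0.0
    v = variants[variants.mut_reads >= min_mut_reads]
    if len(v) == 0:
        return 0.0
    shared = v.groupby("pos")["cell_id"].nunique()
    singleton_pos = shared[shared == 1].index
    n = int(v[v.pos.isin(singleton_pos)].shape[0])
    return n / (n_cells * genome_len)


SNP_FILTER_FIELDS = ("qual", "depth", "allele_qual_p", "dist_nearest",
                     "het_qual_ratio")


def snp_site_filter(record) -> tuple[bool, list]:
    """Site-level SNP filters: quality, depth, allele-quality balance,
    inter-SNP distance and heterozygous allele-quality ratio.

    Returns (passed, reasons); every violated criterion is listed.
    """
    for f in SNP_FILTER_FIELDS:
        if f not in record:
            raise KeyError(f"snp_site_filter record missing field '{f}'")
    reasons = []
    if record["qual"] < 20:
        reasons.append("min_quality")
    if record["depth"] < 5:
        reasons.append("min_reads")
    if record["allele_qual_p"] <= 0.01:
        reasons.append("allele_quality_p")
    if record["dist_nearest"] < 5:
        reasons.append("snp_distance")
    r = record["het_qual_ratio"]
    if not (1.0 / 3.0 <= r <= 3.0):
        reasons.append("allele_quality_ratio")
    return (not reasons), reasons


def snp_site_filter_frame(df: pd.DataFrame) -> pd.Series:
    """Vectorized pass/fail of :func:`snp_site_filter` over a frame."""
    for f in SNP_FILTER_FIELDS:
        if f not in df.columns:
            raise KeyError(f"snp_site_filter record missing field '{f}'")
    ok = ((df.qual >= 20) & (df.depth >= 5) & (df.allele_qual_p > 0.01)
          & (df.dist_nearest >= 5)
          & (df.het_qual_ratio >= 1.0 / 3.0) & (df.het_qual_ratio <= 3.0))
    return ok
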