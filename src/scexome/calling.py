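"""Binomial cell-count thresholds and population-level somatic calling.

A candidate somatic mutation must be (1) homozygous normal in all covered
normal cells, with at least ``min_normal_covered`` normal cells covered,
(2) consistent with a homozygous-normal genotype in matched normal tissue,
and (3) mutant in at least ``min_cancer_mutant`` cancer cells.  The cancer
-cell threshold is derived from a binomial test: the smallest cell count i
for which the genome-wide expected number of coincidental error calls

    C(n, i) * p^i * (1-p)^(n-i) * S

drops below one (n qualified cells, p the per-site error rate, S the exome
size).  With p = 6.7e-5, n = 44 and S = 5e7 this gives i = 3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

MUTANT = ("NC", "CC")


@dataclass
class ThresholdDerivation:
    error_rate: float
    n_cells: int
    exome_size: float
    chosen_i: int
    pmf_at_i: float
    model: str = "binomial"


def _scan_binomial(p: float, n: int, S: float) -> ThresholdDerivation:
    for i in range(1, n + 1):
        pmf = stats.binom.pmf(i, n, p)
        if pmf * S < 1.0:
            return ThresholdDerivation(p, n, S, i, float(pmf))
    raise ValueError(
        f"no cell count i <= {n} satisfies C(n,i) p^i (1-p)^(n-i) S < 1")


def min_mutant_cancer_cells(p_f: float, n: int, S: float) -> int:
    """Minimum mutant cancer cells so expected false genome-wide calls < 1."""
    if not 0.0 < p_f < 1.0:
        raise ValueError("p_f must be in (0, 1)")
    if n < 1 or S < 1:
        raise ValueError("n and S must be >= 1")
    return _scan_binomial(p_f, n, S).chosen_i


def min_normal_cells_covered(p_a: float, n: int, S: float,
                             model: str = "operating_point",
                             operating_point: int = 6) -> int:
    """Minimum read-covered normal cells for criterion (1).

    No single-term binomial reading of the ADO-based rule reproduces the
    study operating point of six, so the probability model is pluggable:

    - ``operating_point``: the study operating point (default 6),
      supplied by configuration rather than derivation;
    - ``binomial``: the same scan as the cancer-cell threshold with p = p_a;
    - ``ado_power``: smallest i with (p_a/2)**i * S < 1 (all covered normal
      cells drop the same allele).
    """
    if not 0.0 <= p_a < 1.0:
        raise ValueError("p_a must be in [0, 1)")
    if n < 1 or S < 1:
        raise ValueError("n and S must be >= 1")
    if p_a == 0.0:
        return 1
    if model == "operating_point":
        if operating_point > n:
            raise ValueError("operating point exceeds available normal cells")
        return operating_point
    if model == "binomial":
        return _scan_binomial(p_a, n, S).chosen_i
    if model == "ado_power":
        half = p_a / 2.0
        for i in range(1, n + 1):
            if half ** i * S < 1.0:
                return i
        raise ValueError(f"no cell count i <= {n} satisfies (p_a/2)^i S < 1")
    raise ValueError(f"unknown model '{model}'")


def call_somatic(obs: pd.DataFrame, tissue: pd.DataFrame,
                 normal_cells: list, tumor_cells: list,
                 min_normal_covered: int = 6,
                 min_cancer_mutant: int = 3,
                 site_annotations: pd.DataFrame | None = None) -> pd.DataFrame:
    """Apply criteria (1)-(3) across the cell population.

    Returns one row per passing site with per-population counts and the
    count-based cell frequency; the attribute ``.attrs['not_evaluable']``
    carries the number of candidate sites without any covered normal cell.
    """
    o = obs.copy()
    o["chrom"] = o["chrom"].astype(str)
    o["genotype"] = o["genotype"].astype(str)
    o["is_normal"] = o.cell_id.isin(normal_cells)
    o["is_tumor"] = o.cell_id.isin(tumor_cells)
    o = o[o.is_normal | o.is_tumor]
    o["is_mut"] = o.genotype.isin(MUTANT)

    tab = o.assign(
        normal_mut=o.is_normal & o.is_mut,
        tumor_mut=o.is_tumor & o.is_mut,
        tumor_het=o.is_tumor & (o.genotype == "NC"),
        tumor_hom=o.is_tumor & (o.genotype == "CC"),
    ).groupby(["chrom", "pos"], observed=True).agg(
        n_normal_covered=("is_normal", "sum"),
        n_normal_mutant=("normal_mut", "sum"),
        n_cancer_covered=("is_tumor", "sum"),
        n_cancer_mutant=("tumor_mut", "sum"),
        n_cancer_het=("tumor_het", "sum"),
        n_cancer_hom=("tumor_hom", "sum"),
        ref=("ref", "first"),
        alt=("alt", "first"),
    ).reset_index()

    t = tissue[["chrom", "pos", "genotype"]].copy()
    t["chrom"] = t["chrom"].astype(str)
    t = t.rename(columns={"genotype": "tissue_genotype"})
    tab = tab.merge(t, on=["chrom", "pos"], how="left")

    not_evaluable = int((tab.n_normal_covered == 0).sum())
    keep = (
        (tab.n_normal_covered >= min_normal_covered)
        & (tab.n_normal_mutant == 0)
        & (tab.tissue_genotype == "NN")
        & (tab.n_cancer_mutant >= min_cancer_mutant)
        & (tab.n_cancer_covered > 0)
    )
    calls = tab[keep].copy()
    calls["cell_frequency"] = (
        (calls.n_cancer_het + 2 * calls.n_cancer_hom)
        / (2.0 * calls.n_cancer_covered))

    if site_annotations is not None:
        ann = site_annotations[["chrom", "pos", "csq_class", "gene"]].copy()
        ann["chrom"] = ann["chrom"].astype(str)
        calls = calls.merge(ann, on=["chrom", "pos"], how="left")
    def chrom_key(col):
        def one(c):
            c = str(c).removeprefix("chr")
            return (0, int(c), "") if c.isdigit() else (1, 0, c)
        return col.map(one)

    calls = calls.sort_values(["chrom", "pos"], key=lambda col: (
        chrom_key(col) if col.name == "chrom" else col)).reset_index(drop=True)
    calls.attrs["not_evaluable"] = not_evaluable
    return calls


CLASS_ORDER = ["NS", "S", "3UTR", "5UTR", "intron", "intergenic"]


def summarize_calls(calls: pd.DataFrame) -> dict:
    """Per-class counts/percentages, NS/S ratio and bulk-support strata."""
    n = len(calls)
    out = {"total": n, "by_class": {}, "ns_s_ratio": None}
    if n == 0:
        out["by_class"] = {c: {"n": 0, "pct": 0.0} for c in CLASS_ORDER}
        return out
    cls = calls["csq_class"] if "csq_class" in calls else pd.Series([], dtype=str)
    counts = cls.value_counts()
    for c in CLASS_ORDER:
        k = int(counts.get(c, 0))
        out["by_class"][c] = {"n": k, "pct": round(100.0 * k / n, 2)}
    ns, s = out["by_class"]["NS"]["n"], out["by_class"]["S"]["n"]
    out["ns_s_ratio"] = round(ns / s, 2) if s else None
    if "bulk_supported" in calls:
        sup = calls[calls.bulk_supported]
        out["bulk"] = {
            "supported": int(len(sup)),
            "pct": round(100.0 * len(sup) / n, 2),
        }
        sup_cls = sup["csq_class"].value_counts() if "csq_class" in sup else {}
        for c in CLASS_ORDER:
            tot_c = out["by_class"][c]["n"]
            k = int(sup_cls.get(c, 0)) if len(sup) else 0
            out["bulk"][f"{c}_supported_pct"] = (
                round(100.0 * k / tot_c, 2) if tot_c else None)
    return out


def bulk_support(calls: pd.DataFrame, bulk: pd.DataFrame,
                 min_reads: int = 1) -> tuple[pd.DataFrame, float]:
    """Flag calls supported by >= min_reads mutant reads in bulk tissue.

    Sites absent from the bulk table are unsupported and counted in
    ``.attrs['bulk_uncovered']``.  Returns (flagged calls, percent supported).
    """
    b = bulk[["chrom", "pos", "mut_reads"]].copy()
    b["chrom"] = b["chrom"].astype(str)
    b = b.rename(columns={"mut_reads": "bulk_mut_reads"})
    out = calls.copy()
    out["chrom"] = out["chrom"].astype(str)
    out = out.merge(b, on=["chrom", "pos"], how="left")
    uncovered = int(out.bulk_mut_reads.isna().sum())
    out["bulk_supported"] = out.bulk_mut_reads.fillna(-1) >= min_reads
    pct = round(100.0 * out.bulk_supported.sum() / len(out), 2) if len(out) else 0.0
    out.attrs["bulk_uncovered"] = uncovered
    return out, float(pct)


def tissue_detection_sensitivity(n_detected: int, n_total: int) -> float:
    """Percent of single-cell calls recoverable from bulk-tissue consensus."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return round(100.0 * n_detected / n_total, 2)


def validation_concordance(n_concordant: int, n_tested: int) -> float:
    """Percent of orthogonally genotyped sites concordant with the calls."""
    if n_tested <= 0:
        raise ValueError("n_tested must be positive")
    return round(100.0 * n_concordant / n_tested, 2)
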