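"""Readers and writers for the pipeline's tabular and VCF interchange formats.

All TSVs carry 1-based positions; internal interval arithmetic (target BED)
is 0-based half-open, matching the BED convention.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

OBS_COLUMNS = ("cell_id", "chrom", "pos", "ref", "alt", "depth",
               "mut_reads", "qual", "ranksum_p", "genotype")
TISSUE_COLUMNS = ("chrom", "pos", "ref", "alt", "depth", "qual",
                  "ranksum_p", "genotype")
BULK_COLUMNS = ("chrom", "pos", "ref_reads", "mut_reads")
VALID_GENOTYPES = {"NN", "NC", "CC"}


def _check_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")


def _check_genotypes(df: pd.DataFrame, path) -> None:
    bad = ~df.genotype.astype(str).isin(VALID_GENOTYPES)
    if bad.any():
        lines = (df.index[bad] + 2).tolist()[:10]  # 1-based incl. header
        raise ValueError(f"{path}: invalid genotype token at line(s) {lines}")


def read_observations(path) -> pd.DataFrame:
    """Load and validate a per-cell, per-site observation TSV."""
    df = pd.read_csv(path, sep="\t")
    _check_columns(df, OBS_COLUMNS, path)
    for col in ("pos", "depth", "mut_reads", "qual"):
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise ValueError(f"{path}: non-numeric values in column '{col}'")
    _check_genotypes(df, path)
    df["cell_id"] = df["cell_id"].astype("category")
    df["chrom"] = df["chrom"].astype("category")
    return df


def write_observations(obs: pd.DataFrame, path) -> None:
    obs.to_csv(path, sep="\t", index=False, columns=list(OBS_COLUMNS))


def read_tissue(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _check_columns(df, TISSUE_COLUMNS, path)
    _check_genotypes(df, path)
    return df


def write_tissue(tissue: pd.DataFrame, path) -> None:
    tissue.to_csv(path, sep="\t", index=False, columns=list(TISSUE_COLUMNS))


def read_bulk(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _check_columns(df, BULK_COLUMNS, path)
    return df


def write_bulk(bulk: pd.DataFrame, path) -> None:
    bulk.to_csv(path, sep="\t", index=False, columns=list(BULK_COLUMNS))


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end"], usecols=[0, 1, 2])
    return df


def write_bed(targets: pd.DataFrame, path) -> None:
    targets.to_csv(path, sep="\t", index=False, header=False,
                   columns=["chrom", "start", "end"])


def write_error_rates(rates, path) -> None:
    with open(path, "w") as fh:
        json.dump(rates.to_dict(), fh, indent=2)


def read_error_rates(path):
    from .errors import ErrorRates
    with open(path) as fh:
        d = json.load(fh)
    return ErrorRates(ado_het=d["ado_het"], fdr=d["fdr"],
                      ado_hom=d.get("ado_hom"),
                      per_cell_ado=d.get("per_cell_ado", {}),
                      per_cell_fdr=d.get("per_cell_fdr", {}))


def _natural_chrom_key(c: str):
    c = str(c).removeprefix("chr")
    return (0, int(c)) if c.isdigit() else (1, c)


def write_vcf(calls: pd.DataFrame, path, sample_desc: str = "single-cell somatic calls") -> None:
    """Write the somatic call set as VCF 4.2 with per-call INFO annotations.

    INFO: NCM (mutant cancer cells), NNC (covered normal cells), CSQCLASS
    (consequence class), BULKSUP (1 if supported by bulk reads).  Calls must
    be sorted by chromosome and position.
    """
    c = calls.copy()
    c["chrom"] = c["chrom"].astype(str)
    keys = list(zip(c.chrom.map(_natural_chrom_key), c.pos))
    if keys != sorted(keys):
        raise ValueError("calls must be sorted by chrom, pos before writing VCF")

    header = pysam.VariantHeader()
    header.add_meta("source", sample_desc)
    for chrom in sorted(c.chrom.unique(), key=_natural_chrom_key):
        length = int(c.loc[c.chrom == chrom, "pos"].max()) + 1000
        header.contigs.add(chrom, length=length)
    if len(c) == 0:
        header.contigs.add("chr1", length=1000)
    header.info.add("NCM", 1, "Integer", "Number of mutant cancer cells")
    header.info.add("NNC", 1, "Integer", "Number of covered normal cells")
    header.info.add("CSQCLASS", 1, "String", "Consequence class")
    header.info.add("BULKSUP", 1, "Integer",
                    "1 if supported by >=1 mutant bulk read")

    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for row in c.itertuples():
            rec = vf.new_record(contig=row.chrom, start=int(row.pos) - 1,
                                alleles=(str(row.ref), str(row.alt)))
            rec.info["NCM"] = int(row.n_cancer_mutant)
            rec.info["NNC"] = int(row.n_normal_covered)
            if hasattr(row, "csq_class") and isinstance(row.csq_class, str):
                rec.info["CSQCLASS"] = row.csq_class
            if hasattr(row, "bulk_supported"):
                rec.info["BULKSUP"] = int(bool(row.bulk_supported))
            vf.write(rec)


def read_vcf(path) -> pd.DataFrame:
    """Read a somatic call VCF back into the call-set frame."""
    rows = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            rows.append({
                "chrom": rec.contig, "pos": rec.pos,
                "ref": rec.ref, "alt": rec.alts[0] if rec.alts else None,
                "n_cancer_mutant": rec.info.get("NCM"),
                "n_normal_covered": rec.info.get("NNC"),
                "csq_class": rec.info.get("CSQCLASS"),
                "bulk_supported": bool(rec.info.get("BULKSUP", 0)),
            })
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt",
                                       "n_cancer_mutant", "n_normal_covered",
                                       "csq_class", "bulk_supported"])


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonify))


def _jsonify(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (pd.Series,)):
        return o.to_dict()
    raise TypeError(f"not JSON serializable: {type(o)}")
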