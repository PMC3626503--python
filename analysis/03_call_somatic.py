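#!/usr/bin/env python
"""Derive calling thresholds and call somatic mutations across the population.

The cancer-cell threshold comes from the binomial rule (expected genome-wide
false calls below one): with the estimated FDR, 44 qualified cancer cells
and a 50 Mb exome it lands on 3 mutant cells, the study operating point;
the normal-cell coverage requirement ships at the study operating point
of 6. Calls require homozygous-normal agreement across covered normal cells
and matched tissue. Bulk support and the summary-table arithmetic follow.

Writes results/03_somatic_calls.vcf and results/03_call_summary.json.
"""

import argparse
import json
from pathlib import Path

from scexome import ErrorRates, SimConfig, bulk_support, \
    min_mutant_cancer_cells, min_normal_cells_covered, simulate_bulk, \
    simulate_observations, simulate_population, simulate_tissue_normal, \
    summarize_calls
from scexome.calling import call_somatic
from scexome.io import write_vcf

RESULTS = Path(__file__).resolve().parent.parent / "results"
EXOME_SIZE = 5e7


def load_rates() -> ErrorRates:
    path = RESULTS / "02_error_model.json"
    if path.exists():
        d = json.loads(path.read_text())
        return ErrorRates(ado_het=d["ado_het"], fdr=max(d["fdr"], 1e-12))
    return ErrorRates(ado_het=0.41, fdr=6.7e-5)


def main(seed: int) -> None:
    rates = load_rates()
    cfg = SimConfig(seed=seed, n_germline_het_sites=300,
                    n_hom_background_sites=300)
    truth = simulate_population(cfg)
    obs = simulate_observations(truth)
    tissue = simulate_tissue_normal(truth)
    bulk = simulate_bulk(truth, mean_depth=137.0)

    min_cancer = min_mutant_cancer_cells(rates.fdr, cfg.n_tumor_cells,
                                         EXOME_SIZE)
    min_normal = min_normal_cells_covered(rates.ado_het, cfg.n_normal_cells,
                                          EXOME_SIZE)
    calls = call_somatic(obs, tissue, truth.normal_cells, truth.tumor_cells,
                         min_normal_covered=min_normal,
                         min_cancer_mutant=min_cancer,
                         site_annotations=truth.sites)
    calls, bulk_pct = bulk_support(calls, bulk)
    summary = summarize_calls(calls)

    planted = truth.somatic_sites()
    called = set(zip(calls.chrom, calls.pos))
    carriers3 = planted[planted.true_frequency * 2 * cfg.n_tumor_cells >= 2 * min_cancer]
    recall = sum((c, p) in called for c, p in
                 zip(carriers3.chrom, carriers3.pos)) / len(carriers3)

    RESULTS.mkdir(exist_ok=True)
    write_vcf(calls, RESULTS / "03_somatic_calls.vcf")
    out = {
        "seed": seed,
        "thresholds": {"min_cancer_mutant": min_cancer,
                       "min_normal_covered": min_normal},
        "n_calls": int(len(calls)),
        "bulk_supported_pct": bulk_pct,
        "recall_of_recallable_planted_sites": round(recall, 4),
        "summary": summary,
    }
    (RESULTS / "03_call_summary.json").write_text(json.dumps(out, indent=2))
    print(f"thresholds: >= {min_cancer} mutant cancer cells, "
          f">= {min_normal} covered normal cells")
    print(f"{len(calls)} somatic calls; {bulk_pct}% bulk-supported; "
          f"recall of recallable planted sites {recall:.1%}; "
          f"NS/S = {summary['ns_s_ratio']}")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    main(ap.parse_args().seed)
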