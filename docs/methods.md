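# Methods

This note records the models the package implements, the choices made where
the design was genuinely open, and what the synthetic experiments do and do
not establish.

## The synthetic population

The generator (`scexome.sim`) emulates a single-patient single-cell exome
experiment on a tumor of monoclonal origin:

- **Cells.** 44 tumor + 11 normal cells by default.  Tumor cells belong to
  clones A/B/C at fractions (0.30, 0.35, 0.35) via largest-remainder
  rounding; a clone that would receive zero cells is an error.
- **Mutations.** 22 ancestral nonsynonymous mutant genes heterozygous in
  every tumor cell (the monoclonal-origin signature: true frequency exactly
  0.5 of tumor haploids); 7 clone-B and 12 clone-C specific genes
  heterozygous in exactly their clone's cells; a 400-mutation neutral tail
  whose per-mutation carrier count k is drawn with P(k) ∝ 1/k over
  k ∈ {1..44} — the stationary frequency spectrum of neutral mutations
  accumulating in an expanding population, used instead of simulating the
  growth process itself; 20,000 germline heterozygous sites (all cells NC);
  50,000 homozygous background sites (5% on chrX; the donor is male, so
  chrX carries no true heterozygotes and every X het call is an artifact —
  the X QC check depends on this).
- **Tail consequence classes** follow the exome+flank mix of the study's
  call table once the 41 clonal nonsynonymous genes are subtracted
  (NS 0.261, S 0.147, 3'UTR 0.035, 5'UTR 0.020, intron 0.517,
  intergenic 0.020).
- **Observation model.** A site is covered in a cell with probability
  0.886 (the study's mean exome coverage) and receives a negative-binomial
  depth (mean 40, dispersion 8 — WGA coverage is strongly overdispersed;
  the study states only the 40x mean).  A true heterozygote drops one
  allele (chosen uniformly) with probability `ado_het` = 0.41 and is then
  *called* the corresponding homozygote; a true homozygote flips to a
  false heterozygote with probability `fdr_per_site` = 6.7e-5.  Mutant-read
  counts are binomial given the post-error allele content with per-read
  error 1e-3 (not stated in the source material; it only feeds read counts
  at homozygous sites, never genotype calls).  Quality scores are tiered
  (99 / 15 / 5 with probabilities 0.95 / 0.04 / 0.01) and rank-sum p-values
  mostly uniform above 0.05, so every prior-weight branch is exercised.
- **Matched tissue.** Normal tissue is simulated noise-free at 28x
  (consensus sequencing of millions of cells; its genotype error is
  negligible next to WGA error), tumor bulk at 137x with binomial
  mutant-read counts at the true population frequency.

What this does **not** emulate: amplification-bias correlation along the
genome, chimeric reads, CNV/LOH, doublets, or site-specific error
hotspots.  Passing tests show the estimators and the clustering recover
truth under the stated error model, not that they are robust to artifacts
outside it.

## Error-rate estimation

ADO per normal cell is the median over depth strata of
relFNR(n) = 1 − (HR_S/CR_S)/(HR_T/CR_T) over the germline catalog, using
only non-outlier strata (relFNR ≥ 0; a stratum where the tissue rate falls
below the cell's carries no dropout signal), strata within the 1st–99th
depth percentiles, and strata holding at least 50 germline sites (the
pipeline scales this floor down for small catalogs, `max(3, n/100)`).
Population ADO is the mean over qualified normal cells.  `ado_hom` is
never estimated separately (the data cannot distinguish it); it defaults
to `ado_het` and is configurable — it only enters the posterior model
through the (1−f_homo) factor.

FDR per cell is the heterozygous-called fraction of a high-confidence
homozygous subset: top quality tier (Q = 99) and depth inside the central
95% interval of a Poisson at the cell's mean depth.  The mitochondrial
cross-check divides retained singleton variants (≥ 5 mutant reads, not
shared by two cells) by cells × 16,561 bp; its denominator is exposed
because the effective callable size is a convention (7 variants over 11
cells gives 3.84e-5 with the full genome length; a smaller callable
fraction gives correspondingly larger rates).

## Thresholds and calling

The cancer-cell threshold is the smallest i with
C(n,i)·p^i·(1−p)^(n−i)·S < 1 — the boundary of the feasible region; for the
relevant tiny p the pmf is decreasing in i there, so all larger counts also
satisfy the inequality.  The normal-cell coverage threshold is shipped as
the operating point 6: no single-term binomial reading of the ADO-based
rule reproduces that number, so the model is pluggable
(`operating_point`, `binomial`, `ado_power`) rather than silently chosen.

Calls require: ≥ 6 covered normal cells, all of them homozygous normal,
tissue genotype NN, and ≥ 3 mutant cancer cells.  Sites with zero covered
normal cells are tallied as not evaluable.  Consequence classes are
consumed as an input column, never predicted.

## Frequency spectra

`count_frequency` is (n_het + 2·n_hom)/(2·n_covered).  Under the uniform
dropout model it is unbiased (dropout to NN and to CC cancel in
expectation) but noisy; `ml_frequency` maximizes the per-site likelihood
Σ_cells log Σ_g P(obs|g)·P(g|f) with Hardy–Weinberg P(g|f) on a 1e-3 grid
with bounded local refinement, and has ~25% lower RMSE at clonal sites
because the read counts separate dropout-to-CC from true homozygotes.
The cell-vs-bulk R² analyses therefore use the ML estimator.

The spectrum uses left-closed bins, final bin closed; "the peak" is bins
5–6 (40–60%).  The hyperbolic fit minimizes Pearson chi-square for
E_b = c/f_mid on the non-peak bins, then computes the goodness-of-fit
statistic over all ten bins (df = bins − 2), so a clonal peak appears as
lack of fit; `peak_excess` flags observed > 3× fitted in the peak bins.
An intercept variant (c/f + d) is available by flag.

**Known limitation.** The midpoint c/f bin model is not the binned form of
the 1/k carrier-count law (the first bin holds 63% of 1/k mass but 47% of
midpoint-c/f mass), so the chi-square p-value rejects structurally on
large pure-neutral samples.  The peak-excess flag is calibrated on such
samples (false-flag rate 0% over 200 replicates of 400 mutations); the
p-value is calibrated only against the fitted model itself (8% rejection
at the 5% level).  Conclusions should rest on the flag, with the p-value
as a descriptive measure of departure from c/f.

The nonsynonymous-shift test is a one-sided Fisher exact on
{NS, S} × {f > 0.1, f ≤ 0.1}, optionally excluding the 40–60% peak;
two-sided by flag.

## Posterior scores and subclone reconstruction

Priors follow the tissue genotype with weight Pn (1/3 below Q10 or
rank-sum p < 0.05; 0.9 for Q10–19; 0.99 at Q ≥ 20); Pr(CC) is always
(1−Pn)/2 — a homozygous-mutant germline is an input error.  Likelihoods
keep the printed (1−f_homo) factor on the homozygous branches even though
dropout cannot change a homozygote's genotype; a corrected variant drops it
by flag.  The heterozygous branch reads the homozygous-observation error
rate as f_p on both sides (mirror symmetry).  Posteriors are floored at
1e-12 so H stays finite.

H is computed per site, imputed at uncovered (cell, site) entries with the
site mean over covered cells, and aggregated per gene by maximum (a gene is
mutant if any of its sites is; sum by flag).  The suspicious-gene screen
(any normal cell ≥ 0.5) is applied to **raw, non-imputed** values: at a
tumor-dominated site the imputed value is positive by construction and
would wrongly paint every uncovered normal cell as mutant.

Genes enter the heat map when they are nonsynonymous calls mutant in at
least 20% of covered tumor cells; under ADO 0.41 a clone at 35% cell
fraction is observed mutant in ~30% of cells, so a higher cutoff clips
true clone genes.

Clustering is Ward on Euclidean distance (average linkage chains badly
under the bimodal dropout noise of H).  The cut is two-stage:

1. k = 2 over all genes separates mutant-rich (tumor) from mutant-poor
   (normal) cells — this split is unambiguous.
2. Among tumor cells, subclone **signature gene groups** are identified:
   candidate genes (mutant in < 60% of tumor cells, i.e. not ancestral)
   are Ward-clustered across cells, every cut depth is scanned, and
   maximal clusters with ≥ 3 genes and mean pairwise correlation > 0.3 are
   kept (clusters of a hierarchy are nested across cuts, so maximal
   coherent clusters are disjoint).  Clone-specific genes co-occur in
   their clone's cells and correlate near 0.7; neutral-tail genes
   correlate near 0.  The tumor subtree is then cut into
   (number of signature groups + 1) clusters — one subclone per signature
   plus the base clone carrying none.
3. A single silhouette-selected cut (`method="silhouette"`) is retained
   for comparison; it reliably finds the tumor/normal split but the mean
   silhouette is flat between that split and the finer subclone structure,
   so it under-cuts roughly half the time.

Over 60 seeded replicates of the default population (three disjoint
20-seed panels) the two-stage procedure recovers the planted partition at
adjusted Rand index ≥ 0.9 in 60/60.

Gene-pair concurrence/exclusivity is Fisher exact on the 2×2 cell-count
table (one-sided each way; a seeded permutation variant is provided);
p ≥ 0.3 is marked not-shown for display.  Gene-level exclusivity — the
unit in which the study reports "almost all mutually exclusive" — counts a
subclone gene as exclusive when its smallest cross-group p is below 0.05.
Per-pair power is limited: with ADO 0.41 and 88.6% coverage a 15-cell
clone yields margins of 10–12 mutant cells out of 44, where the exact test
sits near p ≈ 0.05, so only ~70% of individual pairs reach significance
even for perfectly disjoint clones.

The divergence bound is generations = ⌈count/(μ·S)⌉ with defaults
μ = 5e-9 per bp per cell generation and S = 6e7 callable bp; both inputs
are caller-supplied and echoed in the output, and the count defaults to
the larger clone-specific signature (12 genes → 40 generations).
Recurrence surveying counts distinct cohort patients with non-silent
mutations per gene and flags ≥ 3.  PCA runs on 0/1/2 genotype dosages at
called sites with iterative low-rank imputation of missing entries
(column-mean start, reconstruction refinement to 1e-6); an all-constant
matrix is rejected.

## Problem sizes and determinism

Every stochastic stage takes an explicit seed and is bit-reproducible; the
pipeline derives all stage seeds from one run seed.  The analysis drivers
and the acceptance script choose problem sizes so that Monte-Carlo error
is small relative to each quantity: 50,000 germline sites for ADO
(s.e.m. ≈ 1e-3), four independent 600,000-site homozygous backgrounds for
FDR (≈ 2.3e7 site–cell pairs, s.e. ≈ 2e-6), and 300-site backgrounds where
only the somatic architecture matters.  The full default population
(70,423 sites × 55 cells) runs end-to-end in under a minute.
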