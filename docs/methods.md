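# Methods

This note documents the statistical procedures implemented in `panelscan`,
the synthetic data model used to exercise them, the defaults and why they
were chosen, and the limitations of both.

## Gene panel and coordinate conventions

A panel is a set of genes with family labels, protein lengths `L_g` and
transmembrane (TM) residue intervals. All coordinates are protein
(amino-acid) positions, 1-based and inclusive, matching the UniProt
convention for TM annotations; `L_TR` is the total residue count covered by
the merged TM intervals. Mutations are therefore expected in protein
coordinates; records without a valid protein position (splice, intronic)
are excluded from region analyses but still count toward mutation frequency
and tumor mutation burden.

The shipped TRP-channel fixture contains the 28 transient-receptor
potential genes in six families (TRPC, TRPM, TRPV, TRPA, TRPP, TRPML) with
canonical human protein lengths. Its TM helix coordinates are schematic:
six 21-residue helices (eleven for PKD1) placed evenly within a plausible
channel-domain span. They are stand-ins for real UniProt intervals and are
labelled as such in the code; analyses that depend on exact coordinates
should load a user-supplied TM table.

## TM-region enrichment statistic

For each gene with `N >= 1` positioned mutations and `L_TR >= 1`, the
number of TM mutations under the no-enrichment null is
`X ~ Binomial(N, p_ri)`, `p_ri = L_TR / L_g`. We report the upper tail
`P(X >= k)` computed with the binomial survival function (numerically
stable; verified against direct summation to 1e-10 for all `N <= 60`), the
enrichment ratio `E = k / (N * p_ri)`, and the call
`enriched = (E > 1.3) and (p < 0.05)`. The p-value threshold is exposed as
a parameter; 0.05 is the package default, consistent with the significance
conventions used by the other stages. Raw p-values drive the call; a
BH-adjusted column is additionally emitted. Genes with `L_TR = 0` or no
positioned mutations are reported as unscored.

Region contrasts use the Wilcoxon rank-sum test: exact enumeration over all
group assignments for combined `n <= 20` (average ranks; valid under ties),
otherwise the normal approximation with tie and continuity corrections.
Mutation densities (mutations per residue) are compared per gene by
default; a pooled mode (cohort-level counts over cohort-level lengths) is
available because either reading of "TM vs other density" is defensible.
The deleterious-mutation association uses a 2x2 Fisher exact test with
"deleterious or damaging" defined as the union of SIFT-deleterious and
PolyPhen-damaging labels; mutations lacking both labels are excluded.

## CNV frequencies

Input values are GISTIC-thresholded calls in {-2, -1, 0, 1, 2}. Gain
frequency counts values >= 1 and loss frequency values <= -1 by default
(the inclusive reading of "amplification or loss"); a high-level-only mode
(|value| = 2) is provided. Alteration grouping for the clinical stage uses
the stricter high-level criterion by default, combined with nonsynonymous
panel mutations — the cBioPortal-style semantics commonly used for
"altered vs unaltered" figures — and is configurable.

## Differential expression

Per cancer type with more than `min_normals = 5` normal samples: two-sided
rank-sum test per gene on log2(FPKM + 1), BH adjustment across genes within
the cancer type (per-cancer families, since results are reported per
cancer), and `log2FC = log2(mean tumor FPKM + 1) - log2(mean normal FPKM
+ 1)`. The +1 pseudocount is a parameter; fold change from means-of-FPKM is
the default with a mean-of-logs alternative, because published FPKM
pipelines are split on this and the call rule (`|log2FC| > 1` and adjusted
`p < 0.05`) is threshold-sensitive only near the boundary.

Tissue-specificity classes follow the Human Protein Atlas conventions at a
4x threshold: tissue enriched (one tissue >= 4x every other), group
enriched (2-7 tissues each >= 4x the mean of the rest; for fixed group size
the top-ranked tissues dominate all other candidate groups, so scanning
prefix groups is equivalent to exhaustive subset search), tissue enhanced
(>= 4x the mean of all tissues), else low specificity.

## Survival analysis

The two-group log-rank statistic is implemented directly (observed minus
expected over pooled event times, hypergeometric variance) and is
cross-checked against lifelines in the test suite; the Cox
proportional-hazards fit uses lifelines (Newton iteration on the partial
likelihood, Efron tie handling) with Wald 95% CIs. Expression profiles are
dichotomized at the cutpoint maximizing the standardized log-rank statistic
over all midpoints between consecutive distinct values, constrained to
leave at least `minprop = 0.1` of patients in each group (the default of
the widely used cutpoint-selection tools). Maximally selected statistics
invalidate the subsequent p-value; fits carry an explicit
selection-biased-p flag. Genes with zero expression in more than 50% of
tumors are skipped. Classification: risky iff `HR > 1` and `p < 0.05`,
protective iff `HR < 1` and `p < 0.05`; raw p drives the classification,
with a BH column emitted alongside. Overall survival is the primary
endpoint; disease-free survival columns are supported.

Clinical-feature comparisons between altered and unaltered patients use
chi-square tests for categoricals (Fisher's exact for sparse 2x2 tables),
rank-sum tests for continuous covariates, and rank-sum on category codes
for ordinal stage/grade, with BH adjustment across features.

## Preranked GSEA

For each anchor gene, all other genes are ranked by Spearman correlation
with the anchor (average-rank ties; zero-variance genes excluded). For a
gene set with `m` members in the ranked list of `N` genes, the running sum
increments by `|score|^w / sum(|score|^w over hits)` at hits (`w = 1`
default) and decrements by `1/(N - m)` at misses; the enrichment score is
the maximum deviation from zero (evaluated at the positions immediately
before and after hits, where the extremes must occur). The null
distribution permutes set membership — random sets of the same size drawn
from the ranked list — because the input is a correlation ranking, not a
two-class design. `NES = ES / mean(|null ES| of matching sign)`; the
permutation p-value is two-sided with the +1 correction, so its floor is
`1/(n_perm + 1)`; BH adjustment is applied across sets within each anchor.
Results are bit-reproducible under a fixed seed (one substream per anchor).

## Pharmacogenomic screens

IC50 preprocessing follows the row-wise KNN imputation contract of the
classic microarray implementation, with parameters `k = 5`, `rowmax = 0.5`,
`colmax = 0.8`, `maxp = 1500`: drugs missing in more than 30% of cell lines
are removed before imputation; remaining missing entries are imputed by the
mean of the `k` nearest rows (Euclidean distance over mutually observed
columns, normalized by overlap); rows missing more than `rowmax` fall back
to column means; columns missing more than `colmax` abort with an error.
The `maxp` recursive-partitioning path — the only place the seed enters —
never engages below 1500 rows, so imputation is deterministic at the matrix
sizes handled here.

Correlation screens compute Spearman rho between every row pair of two
matrices over shared columns (pooled across cell lines; a per-tissue mode
can be obtained by subsetting columns), with p-values from the
t-approximation (exact permutation enumeration for `n <= 9`), BH adjustment
across all pairs tested in one invocation (one family per screen), and
significance `|SCC| > threshold` and adjusted `p < 0.05`. Thresholds: 0.15
for drug IC50 screens, 0.2 for actionable genes, essentiality and the
MKI67 proliferation marker. Rank-based statistics make the screens
invariant to the IC50 scale (raw vs log).

## Synthetic data model

The generator emulates the statistical structure the analyses assume, with
one pseudo-random stream per generator (seeded from the config seed plus an
op-specific offset) so outputs are byte-reproducible and adding one
generator never perturbs another.

* **Panel**: protein lengths uniform on [500, 1500] residues; 0-8
  non-overlapping 21-residue TM helices per gene (genes designated for TM
  enrichment get at least four, so the planted signal has a region to land
  in).
* **Mutations**: per-gene Poisson counts at `rate * (L_other + m * L_TR)`
  with per-residue rate 0.05 by default (~50 mutations/gene at typical
  lengths); positions uniform within region, so a multiplier `m` yields TM
  fraction `m*L_TR / (m*L_TR + L_other)`. SIFT/PolyPhen labels and CADD
  scores come from region-specific distributions (deleterious probability
  0.5 in TM vs 0.25 outside; CADD means 22 vs 15, sd 6).
* **CNV**: iid thresholded calls at gain/loss probability 0.05 each, 20% of
  events high-level.
* **Expression**: log-normal FPKM (log2 means N(3, 1.5), within-gene sd 1);
  planted tumor shifts of +/-2 log2 units on 20 genes; co-expression
  modules share a latent factor (loading 0.8) with their anchor; a
  proliferation factor drives the MKI67 marker (loading 0.9).
* **Clinical**: exponential survival, baseline hazard ln2/1000 per day
  (median ~1000 days), hazard multiplied by 2 for altered patients;
  independent uniform censoring on [0, 3000] days. Hypoxia shift +0.8 sd,
  TMB multiplier 1.5 and a +0.5 log-odds stage/grade tilt in the altered
  group are placeholder effect sizes — no published values exist for these
  contrasts — and are labelled as such here; sex, ethnicity and weight do
  not differ by construction.
* **Drug response**: drug-level offsets (sd 2) plus a shared cell-line
  sensitivity factor (loading 0.6) make rows mutually informative (the
  structure KNN imputation exploits); planted gene-drug pairs use a
  Gaussian copula against the gene's standardized log-expression with the
  Pearson parameter `2 sin(pi * rho_s / 6)`, so the population Spearman
  correlation equals the stated target (0.6 for ten pairs by default);
  missingness is MCAR at 10%. IC50 is generated on natural-log scale; the
  screens are rank-based, so this choice is immaterial.

What the generator does **not** emulate: mutational signatures and
hotspots, copy-number segmentation and arm-level events, expression
compositionality and batch effects, informative censoring, competing
risks, drug-class structure, and any correlation between the omics layers
beyond the planted links. Passing recovery tests therefore demonstrates
correctness of the statistical machinery under the stated model, not
robustness to the full messiness of real cohorts.

## Study conditions of the recovery benchmarks

The benchmark module fixes desk-scale problem sizes chosen to give the
tests adequate power: TM-enrichment recovery uses 200 genes with 20 planted
at multiplier 3 (~50 mutations/gene); differential expression uses 50
tumors vs 50 normals with |log2FC| = 2 on 20 of 200 genes; survival
recovery uses 200 patients per arm at true HR 2 over 30 seeded replicates;
GSEA recovery plants one 30-gene module at loading 0.8 among random sets,
with 999 permutations, and null calibration uses 800 anchor-set pairs on
unstructured expression; the pharmacogenomic screen uses 300 cell lines, 40
drugs, ten planted pairs at Spearman 0.6 and 10% missingness.

One benchmark bound is knowingly tight: at ~50 mutations/gene the realized
per-gene type-I error of the raw-p enrichment call is about 0.033 (the
binomial test is discrete, and the E > 1.3 filter is not binding at that
mutation count), so with 20 true positives among ~160 scored null genes
the expected false-discovery proportion is ~0.22 and the empirical value
fluctuates around 0.2 across seeds. The call rule follows the documented
contract (raw p with the E filter) rather than being adjusted to push this
number down; screening at the BH-adjusted column brings the false-discovery
proportion near zero at unchanged sensitivity for users who need it.

## Numerical choices and degenerate inputs

Exact enumeration limits (rank-sum n <= 20, Spearman n <= 9) balance
exactness against combinatorial cost. Cutpoint ties keep the lowest
cutpoint. `E` is undefined (gene unscored) when `N * p_ri = 0`. The
log-rank test refuses cohorts without events; `hazard_ratio` returns
flagged, non-raising results for skipped genes (zero-expression filter,
single-level groups, no events in a group) and for non-converged fits.
Result tables are TSV (UTF-8, LF, '.' decimal, `%.10g` floats) with a
header comment naming units and conventions, so regression fixtures can be
compared byte-for-byte; the run manifest records config hash, seed,
package version and every threshold applied, and contains no timestamps.

## Known limitations

Exact Cox partial likelihood for heavy ties is not implemented (Efron's
approximation only). Multivariable and stratified survival models,
competing risks, phenotype-permutation GSEA and single-sample GSEA are out
of scope. The tissue-specificity classes assume mean expression per tissue
is a sufficient summary. The per-gene enrichment test treats mutations as
independent given the gene total; clustered multi-sample artifacts would
violate this.
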