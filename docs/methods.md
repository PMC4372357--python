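# Methods

## Scope and data model

`locus2drug` operationalizes a GWAS post-association workflow: risk SNPs →
candidate genes → seven-criterion evidence scores → biological risk genes
→ chromatin-peak enrichment and drug-target repositioning statistics.
External tools that would normally produce the inputs (variant annotation,
text mining, seed-connectivity network scans, eQTL mapping, term
enrichment backends, interactome and drug databases) are consumed as
tables; the package implements the integration, scoring and statistics,
not those upstream tools.

All coordinates are 0-based half-open internally (the BED convention);
1-based table positions are converted exactly once at the parsing
boundary.  Gene identity is the upper-cased symbol string — the workflow
operates entirely on symbols, and no identifier-mapping service is
involved.  Strand is read but ignored: the proximity notion here is
strand-free gene-body distance.

## Locus definition and candidate genes

A risk locus is the span of the lead SNP and its LD proxies with
r² strictly above the threshold (default 0.80), optionally flanked.
Candidate genes are those whose bodies intersect the span, always unioned
with the gene nearest to the lead (distance 0 inside the body, basepairs
to the nearer edge outside; ties break by smaller start, then symbol).
The exact algorithm of the original locus-to-gene lookup tool is
unpublished database plumbing; LD-span × gene-body intersection plus a
guaranteed nearest gene is the simplest fully testable stand-in consistent
with "proximity, as well as linkage disequilibrium".  Loci sharing a gene
keep separate SNP–gene pairs.

## The seven criteria

Per pair, each criterion contributes 0 or 1; every significance threshold
is strict `<`:

1. **missense** — the lead or a qualifying proxy is annotated missense in
   this gene.
2. **cis-eQTL** — a row links the SNP to the gene with FDR < 0.50,
   p < 0.0016 and SNP–probe distance < 250 kb.  If the lead rsid is
   absent from the eQTL table entirely, the highest-r² proxy present
   substitutes (ties by smaller recorded distance).
3. **text mining** and 4. **PPI seed connectivity** — per-gene p < 0.05
   in the respective externally produced table; an absent gene scores 0.
5. **somatic mutation** — case-insensitive membership in the somatic-gene
   set.
6. **knockout-mouse phenotype** and 7. **functional terms** — membership
   in at least one category significantly enriched (hypergeometric upper
   tail, p < 0.05) among the distinct candidate genes.  This is the only
   reading consistent with both category-level enrichment reporting and
   gene-level indicator columns.  An EASE-style conservative tail
   (overlap − 1) is available behind `ease_correction`, default off,
   because the analysis is defined in terms of the plain hypergeometric
   test.

The score is the plain sum of the seven indicators (0–7); the
nearest-gene flag never contributes (verified against the transcribed
table's row sums).  Pairs with score ≥ 2 are biological risk genes; the
threshold is ≥ (not >) because the printed table contains score-2 rows.
Criterion correlations are reported as Pearson r with zero-variance
columns left undefined (never coerced to 0).

## Hypergeometric engine

The shared primitive is the exact upper tail P(X ≥ k) for
X ~ Hypergeometric(N, K, n), summed in log space from log-factorials
(`gammaln`), skipping unachievable terms; k ≤ 0 returns exactly 1.  The
universe size N is an explicit input (`gene_universe_n`, defaulting to
the PPI node count) because it is a property of the interactome snapshot,
not derivable from the other sets.  Tests check the tail against
brute-force pmf enumeration in exact rational arithmetic for all small
universes (tolerance 1e-12) and against an independent library
implementation.

## Drug-target overlap

Biological risk genes seed a one-hop expansion: x = seeds ∪ direct PPI
neighbors; seeds missing from the network stay in x.  Overlap tests
against y (approved-CRC-drug targets) and z (all drug targets) report
expected count K·n/N, fold k/expected, and the exact tail.  The relative
fold (k_y/K_y)/(k_z/K_z) is compared by a one-sided Fisher exact test on
[[k_y, K_y−k_y], [k_z', K_z'−k_z']]; by default the second row uses
z \ y counts so the rows are disjoint (y ⊆ z in real drug tables); the
`fisher_exclude_y_from_z` switch restores the as-given construction.
Connection paths (risk SNP → risk gene → targeted neighbor → drug)
deduplicate on (risk gene, target, drug) and sort lexicographically, with
TSV and DOT exports.

The packaged overlap fixture realizes the cardinalities N = 11303,
|x| = 584 (31 seeds + 553 neighbors), |y| = 8, |z| = 871, |x∩y| = 5,
|x∩z| = 70; its statistics (folds 12.0965 and 1.5555, relative fold
7.7768, tails 1.78×10⁻⁵ and 1.21×10⁻⁴) depend only on those
cardinalities, which tests verify by label permutation.  The 584-member
expanded set is the only size consistent with all four statistics at
N = 11303.

## Chromatin permutation test

A locus overlaps a peak set when any member SNP (lead or qualifying
proxy) falls inside any peak; point-in-peaks queries use the coverage
identity #(starts ≤ p) > #(ends ≤ p), exact even for overlapping peaks.
The null redraws |loci| positions uniformly without replacement from a
user-supplied SNP universe, treating each drawn position as a single-SNP
locus; p = (1 + #{null ≥ observed})/(1 + iterations) (add-one, so p is
never 0 and always ≤ 1).  Each cell type gets a deterministic seed
derived from the global seed plus a stable hash of its name, so scans are
reproducible and cell types are independent.

The single-position null is deliberately simple and is **anti-conservative
for multi-SNP loci**: a locus with m member SNPs has more chances to hit
a peak than one redrawn position.  `locus_size_matched_null` redraws m
positions per locus and counts the pseudo-locus once if any lands in a
peak; calibration tests of real multi-proxy loci use this matched null.
No MAF, LD-block-size or TSS-distance matching is attempted.

## Synthetic bundles and ground truth

The generator builds complete bundles on abstract chromosomes
("chrS1"…): non-overlapping gene bodies with random lengths (5–40 kb) and
gaps (10–60 kb); loci as runs of adjacent genes (run length
1 + Poisson(genes_per_locus_mean − 1)) with the lead SNP inside the first
gene and two qualifying proxies pinning the LD span to the run (plus one
sub-threshold proxy to exercise the r² filter).

Construction is **inverse**: the desired indicator matrix is drawn first —
pair-level for criteria 1–2, gene-level for 3–7, Bernoulli at
`elevated_rate` (default 0.8) for planted genes and `criterion_rates`
(default 0.05) otherwise — and resources are then emitted so evidence
evaluation recovers it: consequence rows (half via the lead, half via a
proxy), qualifying eQTL rows (with ~20% of loci exercising the
proxy-substitution path), p-value tables with sub-threshold decoys,
somatic sets padded with non-candidate genes.  Enriched categories
contain exactly the indicator-1 candidates plus a small non-candidate
filler; background categories contain only non-candidates.  Because
criteria 6–7 pass through the enrichment test, their ground-truth columns
are finalized by applying the same hypergeometric rule the pipeline uses;
with the default effect sizes the drawn and final columns coincide, and
the recovery tests assert exact matrix equality.

The PPI graph is Erdős–Rényi over all genes (edge probability 0.004)
plus planted links between planted genes and the CRC-drug targets
(probability 0.5); CRC targets are non-candidate genes so they enter x
only through those links.  The ground-truth drug-overlap fold is the fold
implied by the truth matrix (genes truly scoring ≥ 2, expanded through
the true network) — a perfect pipeline recovers it exactly, so the
recovery criterion measures pipeline correctness rather than sampling
noise.  One cell type's peaks additionally cover each lead position with
probability 0.8 against 5% background coverage.  `null_bundle` switches
every planted effect off and draws categories independently of candidacy
(a genuine enrichment null).

Default sizes mirror the study conditions (50 loci, ~2.8 genes per locus,
31 planted genes, 34 cell types, 10⁵ permutation iterations); tests and
the acceptance script use smaller bundles (400–800 genes, 8–40 loci, 1–8
cell types, 2×10³–10⁴ iterations, 20 recovery seeds) — sizes chosen so
the statistical checks retain power while the whole suite runs in well
under a minute apart from the calibration loops.

What the generator does **not** emulate: realistic LD structure or MAF
spectra, expression-level noise behind the eQTL table, scale-free
interactome topology, or correlated criteria.  Passing recovery tests
therefore demonstrates correctness of the integration arithmetic, not
robustness to real-data pathologies.

## Numerical and calibration choices

* Printed-value comparisons of folds are truncation-tolerant (the source
  tables truncate mantissas: 12.0965 → 12.09, 1.5555 → 1.55).
* The permutation-uniformity check draws calibration loci from the
  universe itself — 200 replicates of 1000 single-SNP loci at 2000
  iterations over ~25% peak coverage.  The granularity matters: with few
  achievable overlap counts, the tied atoms of the add-one estimator
  shift E[p] to 0.5(1 + Σ pmf²) and the discrete staircase alone
  approaches the Kolmogorov–Smirnov critical deviation; 1000 loci keep
  the lattice fine enough for the continuous-uniform reference to apply.
* Degenerate inputs are flagged, not silently defaulted: empty seed sets
  yield a report with undefined tests; zero-variance criterion columns
  yield undefined correlations; a zero denominator makes the relative
  fold undefined (NaN).
* Determinism: one global seed; per-cell-type seeds are
  `(seed + blake2s(name)) mod 2³¹`; reruns are bit-identical and the run
  manifest records config, input digests and timings.

## Known limitations

* The evidence criteria are treated as exchangeable 0/1 indicators; no
  weighting or probabilistic calibration is attempted.
* The candidate count at real loci depends on the annotation snapshot
  behind the LD and gene tables; the package asserts no particular count.
* The hypergeometric universe for somatic/phenotype overlaps must be
  supplied by the user; published overlap p-values that depend on an
  unstated universe are not asserted.
* Real chromatin analyses additionally require genotyping-array universes
  and consortium peak calls; the permutation machinery is validated on
  synthetic data only.
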