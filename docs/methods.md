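# Methods

## The analysis model

`delscan` treats a population deletion survey as a four-stage inference:

1. **Per-sample consensus.** Two SV callers are run independently per
   sample; a deletion is accepted when both report it with reciprocal
   overlap RO ≥ `ro_threshold` (default 0.5) after restricting both callsets
   to the `min_len`–`max_len` size window (defaults 500 bp and 100 kb,
   bounds inclusive: "500–100 kb" is read as a closed range, and "overlap of
   50%" includes exactly 50%). Matching is greedy in descending RO with
   deterministic tie-breaks (smaller start distance, then smaller secondary
   start, then physical coordinates), and one-to-one: a single broad call
   from one caller cannot validate several fragmented calls from the other.
   The consensus call carries the primary caller's coordinates and genotype
   (secondary genotype only if the primary is missing); which caller is
   primary is a configuration choice (`primary_caller`), not an inference.

2. **Locus construction.** Consensus calls are clustered across samples by
   single-linkage using the same RO threshold; each connected component is
   one deletion locus. The representative interval is the component-wise
   median of member starts/ends with even-count ties resolved toward the
   smaller coordinate, making it deterministic and, for identical member
   intervals, exact. Per-population allele frequency = (deleted-allele
   count) / (2 × samples with a non-missing genotype); a cohort sample with
   no call at a locus is counted homozygous reference, the usual
   absence-of-evidence convention in multi-sample SV merging. Its failure
   mode — dropouts deflate AF — is the same one real pipelines have, and is
   visible in the noisy-recovery tests.

3. **Effect classification and gene catalog.** One class per locus by
   severity priority (coding exon > intronic > regulatory > intergenic).
   "Coding" means overlap with any exon of a protein-coding gene rather than
   strictly CDS, because minimal annotations often lack CDS features; a
   CDS-style restriction would need transcript models the generator does not
   emit. The regulatory flank (default 1000 bp) extends the gene span on
   both sides, strand-ignoring. The catalog admits genes contacted in the
   body (exon or intron) by a locus whose **maximum per-population** AF is
   strictly greater than `af_threshold` (default 0.05); flank-only contacts
   go to a separate regulatory catalog. Max-over-populations is one of
   several defensible AF poolings; it is deterministic and favors
   population-restricted deletions, which is the object of interest in a
   between-population comparison. A pooled-frequency mode can be obtained by
   passing a single-population sample map.

4. **Enrichment.** One-sided hypergeometric over-representation
   (over-representation only — depletion is not tested), computed through
   the survival function in log space, with BH step-up adjustment applied
   within each gene-set database separately (pooled adjustment available).
   Significance is declared on adjusted q < `alpha` = 0.05: the 0.05 level
   is coupled to the FDR adjustment rather than applied to raw p-values.

Marker anchoring is a separate, annotation-level utility: best hit per
marker by (e-value ↑, bitscore ↓, alignment length ↓) with residual full
ties kept but flagged `ambiguous` rather than dropped; minus-strand hits are
normalized to start < end with strand kept as metadata. No e-value or
identity cutoff is applied by default; both exist as optional thresholds.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, not
the sequencing process:

- **Annotation**: non-overlapping genes (default 300 over three 10 Mb
  chromosomes, 2–20 kb long, 2–8 exons, ~10% non-coding) placed
  left-to-right with random gaps.
- **Truth deletions** (default 300): sizes log-uniform on 100 bp–200 kb so
  the 500 bp/100 kb filter is genuinely exercised on both sides; a planted
  effect-class mix (25/25/20/30% coding/intronic/regulatory/intergenic)
  realized by targeted proposals that are *verified* against the pipeline's
  own classifier, so planted class ≡ classified class by construction.
  Per-population allele frequencies are Beta(0.6, 2.4) draws (mean 0.2,
  mass near zero — rare deletions dominate, as in real cohorts); genotypes
  are Hardy–Weinberg draws, redrawn until each deletion segregates in the
  cohort (a deletion nobody carries is unobservable and would make exact
  truth comparisons ill-posed).
- **Callers**: two contrasting profiles — a short-FP-heavy caller
  (sensitivity 0.85, 30 false positives/sample, lognormal sizes around
  10^2.9 bp) and a long-FP-light caller (0.80, 8/sample, around 10^3.6 bp) —
  reflecting the characteristic biases of split-read vs assembly-based
  deletion callers. Each carrier genotype is emitted independently with
  probability = sensitivity; breakpoints get independent uniform ±50 bp
  jitter per end; genotypes flip HET↔HOM at `genotype_error_rate`
  (default 0).

Three separation guarantees make ground truth exactly scorable:

- truth deletions are mutually separated below the RO threshold **with a
  worst-case jitter margin**, so no two jittered emissions of different
  truths can ever link;
- false positives are rejection-sampled to stay below the threshold against
  every (jitter-expanded) truth deletion;
- the second caller's false positives additionally avoid the first
  caller's for the same sample, so no cross-caller FP pair can survive the
  consensus.

Consequently consensus output contains zero false loci for every seed, and
the recovery of a carrier genotype is an independent Bernoulli event with
probability sensitivity_A × sensitivity_B — the exact binomial reference
used by the robustness tests. Recovery is tallied over truths whose length
keeps them inside the size window under worst-case jitter (margin = 2 ×
jitter per boundary), because near-boundary deletions can be jittered out of
the window, which is a property of the size filter, not of the matcher.
A `hard_mode` flag lifts the FP separation constraints for stress testing.

What the generator does **not** emulate — and what passing tests therefore
do not establish about real data: read-level evidence and coverage
heterogeneity (sensitivity is constant across samples, so the caller-count
R² between the two simulated callers is attenuated relative to real cohorts,
where shared per-sample depth drives both callers' counts up and down
together); overlapping or nested segregating deletions (real loci can chain
under single-linkage); breakpoint microhomology; population structure
beyond independent per-population allele frequencies; and any SV type other
than deletions.

## Numerical and degenerate-input choices

- Internal coordinates are 0-based half-open everywhere; conversion happens
  only at format boundaries (VCF POS for a symbolic deletion is the padding
  base, so printed POS equals the 0-based deleted start; GFF3 is 1-based
  inclusive). When a symbolic record carries both `END` and an inconsistent
  `SVLEN`, `END` wins (it is positional; `SVLEN` is derived) with a logged
  warning — note htslib itself resolves the conflict the other way, so the
  reader recovers the printed `END` from the record text.
- Multi-allelic SV records and allele indices > 1 are rejected with a
  warning tally: the analysis is biallelic, and silently splitting risks
  genotype misassignment. Missing GT ⇒ MISSING, which never enters allele
  counts or denominators.
- Hypergeometric tail: k = 0 returns exactly 1.0; k > min(K, n) exactly
  0.0; otherwise the log-space survival function (agrees with exact
  rational enumeration to < 1e-12 for all N ≤ 60). BH: step-up with cap at
  1, returned in input order; input p outside [0, 1] is a hard error.
  Note BH is *not* idempotent in general (e.g. bh([0.25, 1.0]) = [0.5, 1.0]
  but bh([0.5, 1.0]) = [1.0, 1.0]); it is a fixed point on already-flat
  adjusted vectors such as the worked example in the tests.
- Sample standard deviations use the n−1 denominator; single-sample
  populations report SD as undefined (None/NA) rather than 0.
- Caller-agreement R² is the squared Pearson correlation of per-sample raw
  call counts after size filtering but before consensus ("calls each caller
  made per sample"); zero variance in either vector returns None with a
  notice rather than NaN.
- Locus clustering uses a start-sorted sweep, so its edge set equals the
  full quadratic comparison (verified against a transitive-closure oracle).

## Problem sizes

Defaults used by the test suite and the acceptance script: 3 populations ×
8 samples, 300 truth deletions, 300 genes on 30 Mb, 20 gene sets of 50 over
a ~270-gene background, 500-marker anchoring panels; oracle comparisons run
on 100–200-call instances and the robustness checks across 20 seeds. These
sizes give tight statistical resolution (≈1500 carrier genotypes per cohort
for the binomial recovery check) while keeping any single test in seconds.

## Known limitations

- Allele frequencies are taken from caller genotypes as-is; there is no
  genotype re-calling or imputation from read evidence.
- Single-linkage clustering can chain distinct but overlapping segregating
  deletions into one locus in real data (the generator's separation
  guarantee removes this by construction — deliberately, so that truth
  comparisons are exact).
- The enrichment stage tests over-representation against a user-supplied
  background; it does not model annotation bias or gene length.
- Marker "unmapped" status means no hit row present (or none surviving the
  optional thresholds); the tool does not distinguish low-quality mapping
  from absence without those thresholds.
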