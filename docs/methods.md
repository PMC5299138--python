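# Methods

## Read processing and RPM quantification

Reads are 50 bp single-end sequences of adapter-ligated small RNAs. The
quantifier is deliberately minimal and fully specified, trading the
flexibility of general-purpose trimmers and aligners for an exactly
reproducible contract:

* **Adapter trimming.** The read is cut before the leftmost position where a
  prefix of the 3′ adapter aligns ungapped with overlap ≥ `min_overlap`
  (default 5) and mismatch rate ≤ `max_adapter_mismatch_rate` (default 0.1).
  Defaults follow common cutadapt practice; the default adapter is the
  TruSeq small-RNA 3′ adapter `TGGAATTCTCGGGTGCCAAGG`.
* **Filtering.** Keep a trimmed read iff ≥ `min_quality_fraction` (0.8) of
  its bases are at Phred ≥ `min_quality` (20), its length lies in
  [`min_len`, `max_len`] = [16, 27], and it contains no N when matching is
  mismatch-free. All bounds are closed.
* **Matching.** Ungapped, equal-length comparison against mature miRNA
  sequences (16–28 nt, miRBase-style FASTA, U→T), at most `max_mismatches`
  substitutions (default 0). Mature miRNAs are short enough that indel-free
  matching loses essentially nothing. Ambiguous reads are discarded by
  default (`first_by_reference_order` available).
* **RPM.** counts × 10⁶ / (miRNA-mapped total). The denominator is mapped
  reads, not raw library size, so RPM columns always sum to 10⁶.

## Differential gating

A miRNA is differential when max(RPM_early, RPM_late) ≥ `min_rpm` (100) and
|signed fold| ≥ `min_fold` (2). The *either-timepoint* reading of the
expression gate is deliberate: profiles contain genuine risers whose early
expression is near zero (e.g. 2.3 → 122.5 RPM), which any stricter reading
would discard. Signed fold is late/early for increases and −(early/late) for
decreases, so magnitude is ≥ 1 and the sign is the direction. A zero RPM
raises an error rather than producing an infinite fold; an optional
pseudocount (off by default, 1.0 typical when RPMs come from finite read
counts) handles count-derived zeros. Rounding (half-up on the magnitude, one
decimal) exists only in the presentation layer; every computation keeps full
precision.

Calls are then restricted to miRNAs carrying a conserved seed-family label,
because targeting is counted at family resolution: members of a family share
a seed and therefore a target-site repertoire. Note the up and down family
sets may intersect — one member of the miR-15 family can rise while another
falls — and the statistic below treats the strata independently, so an
intersecting family can contribute both +1 and −1 to the same gene.

## Targeting-shift statistic and permutation null

For gene g with family set F_g (families with ≥ 1 conserved 3′UTR site;
site multiplicity deliberately ignored, since the evidence unit is "family
targets gene"):

    Δ_g = |F_g ∩ U| − |F_g ∩ D|

with U, D the observed up/down family sets. The null replaces (U, D) by
random draws from the conserved-family universe: per iteration, a size-|U|
set and a size-|D| set, each uniform without replacement, drawn
independently of each other so they may overlap (matching the observed
strata, which can themselves overlap); fully disjoint sampling is available
as `sampling="disjoint"`. The empirical p-value is the fraction of
iterations with permuted Δ ≥ observed Δ — the comparison is inclusive.
`p_estimator="paper_literal"` divides by the iteration count and can return
an exact 0; `add_one` returns (count+1)/(iterations+1), never 0, and is the
right choice when p-values feed downstream procedures. Default 100,000
iterations; a fixed `rng_seed` reproduces p-values bit-exactly.

Implementation: sampling is vectorized in blocks of 4,096 iterations —
uniform sort keys are drawn per iteration (within a block, all up-set keys
then all down-set keys) and the n smallest keys per row select the set,
which is a uniform draw without replacement; permuted deltas are computed as
one indicator-matrix product per block. Iteration i always consumes row i of
the block's key matrices, so results are independent of the block size only
in distribution; the reproducibility contract is tied to the released draw
order (seed → identical output, any machine).

`exact_pvalues_small` enumerates every (up-set, down-set) assignment
(refusing above 10⁶ combinations) and is the oracle the Monte-Carlo path is
tested against.

Genes are gated at FPKM ≥ `min_fpkm` (1.0, closed bound; genes missing from
the expression table drop), ranked by ascending p with ties broken by
descending Δ then gene id — the tie-break is this package's convention, not
an inherited one. No multiple-testing correction by default, since the raw
permutation p-values are the quantity of interest; `bh_adjust` offers
Benjamini–Hochberg for reuse.

### Discreteness and calibration

Δ is integer-valued, so inclusive empirical p-values are *super-uniform*:
P(p ≤ α) equals the largest attainable p-value below α, never α itself. The
shortfall is about half the tail atom P(Δ = d*) ≈ φ(z_α)/sd(Δ), and sd(Δ) is
bounded near ~3 for any realistic family universe (≤ ~200 families, strata
≤ half the universe). Two practical consequences, verified by the suite:

* the test is conservative — the fraction of null genes at p ≤ 0.05 is below
  0.05, typically 0.02–0.04 (asserted as a super-uniformity property test);
* calibration checks need a *dense* null instance to be informative. The
  calibration test uses incidence density 0.30 (a typical gene carrying
  conserved sites for ~24 of 80 families, in line with conserved-target
  tables for expressed genes) rather than the sparse recovery surrogate
  (density 0.03), where a typical 2-family gene cannot attain p ≤ 0.10 at
  all. Even at density 0.30 the expected fraction sits near the lower edge
  of a 0.05 ± 0.02 band (measured 0.024–0.032 across seeds), so this check
  is inherently tight; the conservativeness, not exact uniformity, is the
  guaranteed property.

## Synthetic data generator

The generator emulates the statistical shape of a two-timepoint cortical
small-RNA study; its defaults are the study conditions for every simulation
test.

| parameter | default | rationale |
|---|---|---|
| n_mirnas / n_families | 300 / 80 | order of an expressed miRNA complement and of the conserved-family universe |
| family_size_mean | 3.5 | Poisson (floor 1); observed conserved families span ~1–6 members |
| n_genes | 2,000 | desk-scale surrogate for the expressed, target-indexed gene set |
| targeting_density | 0.03 | sparse background incidence so planted enrichment is the signal |
| n_spiked_up / n_spiked_down | 30 / 3 | echoes the observed 32-up/3-down split |
| spike_fold_range | (5, 150), log-uniform | echoes the observed 2.2–180 fold span while staying recoverable (see below) |
| base_expression_log_mean / sd | 7.0 / 1.5 (natural log) | median ~1,100 RPM, heavy right tail, column sums near 10⁶ pre-normalization |
| n_enriched_genes / extra up families | 20 / 8 | planted positives for the ranking stage |
| n_reads | 100,000 | desk-scale library; 100 RPM ≈ 10 reads |
| read_error_rate | 0.01 | typical per-base substitution rate |

Spiked-up miRNAs are planted on low-to-mid expressers (30–1,000 RPM early)
and spiked-down on mid-to-high expressers, as in real profiles where the
extreme risers start low. This matters: because both timepoints are
renormalized to RPM, the mass the spikes add to the late pool divides every
observed fold. With spikes on low expressers the compression factor stays
~1.1–1.3 and planted folds ≥ 5 remain recoverable through the two-fold gate;
spikes planted uniformly would inflate the pool ~3× and silently destroy
recovery. The residual compression still pushes a slice of the background
(whose true ratio band is ±1.5-fold) past the −2-fold gate — a composition
artifact real RPM data share; recovery tests therefore score recall of
planted spikes, not false-positive counts.

Reads are mature sequence + adapter truncated to 50 nt, drawn multinomially
with probabilities ∝ RPM, with substitution errors at `read_error_rate`
(errored bases at Q14, others Q37) and the origin miRNA recorded in the read
id. FPKMs are log-normal with an exact, configurable fraction forced below
the 1-FPKM gate. All randomness in one seeded generator per call.

**What passing simulation tests does and does not show.** The generator
emulates marginal expression shapes, family structure and independent
Bernoulli incidence. It does not model 3′UTR sequence or conservation,
correlated targeting across related genes, isomiRs, ligation bias, or
replicate variance (there are no replicates anywhere in this design). Tests
passing on it demonstrate the pipeline's correctness and power under these
idealized conditions, not performance on real libraries.

## Test and acceptance problem sizes

The suite runs the permutation/oracle comparisons at 10,000–100,000
iterations on ≤ 8-family universes, calibration on a 500-gene instance at
10,000 iterations, and ranking recovery on 20 generator repeats at 2,000
iterations — sizes chosen so the whole suite completes in well under a
minute of compute per stage while keeping Monte-Carlo tolerances (3–4 SE)
meaningful. `scripts/acceptance.py` is fully deterministic: it recomputes
the bundled cortical table's headline numbers through the pipeline.

## Known limitations

* The RPM denominator is miRNA-mapped reads; profiles over a *subset* of
  miRNAs (like the bundled table) are not "complete" and expression shares
  are computed against the 10⁶ pool, not the subset sum.
* Matching is equal-length, substitution-only; isomiRs with templated or
  untemplated end variation map only at ≥ 1 allowed mismatch or not at all.
* The permutation null treats families as exchangeable; it does not condition
  on family target-set sizes, so genes targeted by promiscuous families are
  judged against the same null as genes targeted by selective ones.
* Reported fold changes recomputed from rounded published RPMs can differ in
  the last decimal from folds computed on unrounded internal values; the
  bundled dataset documents the rows where the printed folds are exactly
  reproducible and the regression tests restrict themselves to those.
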