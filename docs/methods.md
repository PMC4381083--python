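# Methods

This note documents the models and procedures implemented in
`ribotradeoff`, the parameter defaults and why they were chosen, what the
synthetic-data generator does and does not emulate, and the numerical
conventions used throughout.

## Model overview

The pipeline quantifies whether protein-coding regions couple synonymous
codon choice to local mRNA secondary structure.  The underlying
elongation model assumes translation of a codon is rate-limited by
diffusion of the cognate aminoacyl-tRNA to the ribosomal A-site, so each
sense codon carries a fixed translation time in arbitrary units (a.u.),
inversely related to its cognate tRNA pool.  Local structure is measured
either experimentally (PARS-style per-nucleotide scores: positive values
indicate double-stranded propensity) or computationally (minimum free
energy of a 101-nt sliding window centred on each nucleotide).

The analysis proceeds gene by gene:

1. **Trimming.** The first and last 51 nt (17 codons) of every CDS are
   removed before any analysis, to keep initiation- and
   termination-specific effects (start-codon accessibility, ramp codon
   bias) out of the statistics.  Genes of ≤ 102 nt are excluded.
2. **Region extraction.** Per-nucleotide structure values are classified
   high (PARS > 0; MFE < −35 kcal/mol) or low (PARS ≤ 0; MFE > −20
   kcal/mol).  For MFE, values in (−35, −20) are deliberately
   unclassified — a buffer that keeps marginal windows out of both
   classes.  Maximal runs of uniformly classified, defined positions of
   length ≥ *R*<sub>l</sub> (default 20 nt, studied over {10, 20, 30})
   become regions.  Runs are maximal: a 25-nt run yields one region, not
   several 20-nt sub-regions.
3. **Codon assignment.** A codon belongs to a region only when all three
   of its nucleotides lie inside it; boundary-straddling codons stay
   unassigned.  This is conservative and unambiguous; a majority rule
   (≥ 2 nt) is available as a sensitivity switch.
4. **The trade-off statistic.** Codon times are pooled genome-wide per
   class.  Because time distributions are discrete and skewed, classes
   are compared by medians with interquartile ranges:
   Δt = median(low) − median(high), positive when structured regions
   favour fast codons.  The negation, the *trade-off score*
   (median(high) − median(low), more negative = stronger trade-off), is
   carried as a separate field so the two sign conventions cannot be
   confused.  Significance uses a two-sided Mann–Whitney test.
   Region-level mean pooling (one value per region instead of one per
   codon) is available via `pooling="region_means"`.

Smoothed speed profiles (27-nt = 9-codon centred window, the approximate
ribosome footprint) are provided for trace inspection; region statistics
use instantaneous codon times.  Smoothing windows are truncated at the
ends (mean over available codons) so every codon keeps a smoothed value.

## Rank tests

Genome-scale pools are compared with the tie-corrected normal
approximation of the Mann–Whitney test.  Small samples (min(n, m) ≤ 8,
≤ 50 000 arrangements) instead use exact enumeration of the permutation
distribution of the average-rank U statistic — necessary because codon
times take only 61 distinct values, so ties are the norm and textbook
exact tables do not apply.  The one-sample Wilcoxon signed-rank test used
by the null-model comparison enumerates all 2^n sign assignments for
n ≤ 14 and otherwise uses the tie-corrected normal approximation.
Two-sided p-values are `min(1, 2·min(P(T ≤ t), P(T ≥ t)))` under the
enumerated null.

## Folding backends

Window MFE profiles accept any backend exposing `fold_mfe(seq)`.  Two are
shipped:

* **`NussinovEngine` (default).**  A base-pair-maximisation dynamic
  program (minimum hairpin loop 3 nt) with *stability-weighted* pairs:
  G:C = 1.4, A:U = 0.07, G:U = 0.04 kcal/mol per pair.  The strong G:C
  dominance is intentional and is the engine's central design decision:
  with uniform pair weights a maximum matching saturates at ~90 % of
  nucleotides for almost any composition, so every 101-nt window scores
  alike and the −35/−20 thresholds cannot discriminate.  Weighting by
  pair stability makes the window score track G:C pairing capacity, so
  scores span the classification band: a fully paired G:C window reaches
  about −67, GC-rich windows −38…−45, A-rich windows ≈ 0, and mixed
  windows fall near the unclassified buffer.  These constants are
  calibration constants of a surrogate scoring model, not thermodynamic
  parameters.  The per-gene profile is computed with a banded dynamic
  program over spans ≤ window length, which evaluates every centred
  window of a gene from one shared table (the optimum of a window depends
  only on its own subsequence); this is algebraically identical to
  folding each window separately and ~30× faster.
* **`ViennaEngine`.**  Thermodynamic MFE through the ViennaRNA Python
  bindings — the backend to use on real genomes.  The −35/−20 kcal/mol
  defaults correspond to this thermodynamic scale.

Window energies are assigned to the centre nucleotide; positions within
50 nt of either end are undefined rather than computed with truncated
windows, which would bias MFE towards zero.  Step size is 1 nt.

## Randomization null models

Two per-gene shuffles destroy ordering while conserving the codon
multiset exactly: synonymous shuffling (permute codons within each amino
acid's position set; protein conserved) and whole-codon shuffling
(permute all codon positions; protein not conserved).  For each of the
100 randomized genomes the structure landscape is recomputed with the
same engine/window/thresholds and the trade-off score re-evaluated;
experimental (PARS) structure cannot be re-measured for shuffled
sequences, so null models require the MFE channel.  A single seeded
generator is threaded through genes in sorted-id order, making the
pipeline independent of input order and bit-reproducible given the seed.
Replicates in which one region class vanishes yield NaN and are reported
as such.  The observed score is compared against the null distribution
with a two-sided one-sample Wilcoxon test of the null values against the
observed value (the orientation whose p shrinks with both replicate count
and separation), plus the null median and central 95 % interval.

## Expression analysis and CAI

For a synonymous variant library, each variant receives its own
trade-off score (median(high) − median(low) over that single gene's
pools).  Variants lacking one region class are excluded from correlation
rather than scored 0 — a difference of medians with an empty pool is
undefined.  Expression is correlated with the score by Pearson R
(two-sided p) and an ordinary least-squares fit of expression on score;
expression is used in absolute units with no log transform, matching the
linear model.  CAI uses the classical relative-adaptiveness form: per
amino acid w = count/count(majority codon) in a reference set, geometric
mean over a gene's codons, excluding Met, Trp and stops.  Codons unseen
in the reference receive half the smallest observed weight of their amino
acid so the geometric mean stays defined; amino acids absent from the
reference get uninformative weights of 1.

## Synthetic data

The generator emulates exactly the statistical structure the pipeline
tests for, with planted ground truth:

* Genes are built from alternating high/low structural blocks (default
  60 nt; block length is a multiple of 3 so blocks align with codons),
  with 17 untracked terminal codons on each side that the trimming step
  removes.  Amino acids are uniform over the 20, so amino-acid
  composition carries no structure signal and synonymous shuffling alone
  suffices to destroy the planted effect.
* Codon choice couples to block class with strength β: inside high
  blocks each amino acid's *fastest* codon (per the active time table) is
  chosen with probability β, otherwise a uniform synonymous draw; low
  blocks mirror with the slowest codon.  β = 0 decouples codon choice
  from structure; β = 1 is the deterministic limit.
* Structure truth is emitted as PARS-like scores: block mean +1 (high)
  or −1 (low) plus Gaussian noise (default sd 0.5, at which individual
  nucleotides misclassify at ~2 % but 20-nt runs of the wrong class are
  vanishingly rare).  This channel decouples structure truth from
  sequence content, making the planted effect analytically exact.
* `expected_delta_t` computes the planted Δt in closed form: each class's
  codon-time law is a finite mixture over amino acids and synonymous
  codons, and the medians are read off the exact CDF.  When the CDF hits
  0.5 exactly at a support point the convention is the midpoint to the
  next point, matching the large-sample behaviour of the sample median.
  The quantity is 0 at β = 0 and monotone non-decreasing in β.
* The MFE-consistent mode (`structure_mode="mfe"`) emits no scores;
  structure must be predicted from the sequence.  It works because the
  packaged time tables make fast codons GC-rich and G/C-balanced and slow
  codons A-rich, so high blocks fold strongly under the default engine
  and low blocks barely fold.  This mode exercises the folding path end
  to end, at the price of an intrinsic partial confound (structure and
  speed share the GC axis), which is exactly the situation the
  randomization null models are designed to probe.
* Variant libraries recode one random protein across a β grid (default
  0.25–1.0, 30 variants, 400-codon core, 150-nt blocks) and plant
  expression = 12 + slope·score + N(0, 0.5) with slope −0.09, where
  score = −expected_delta_t(β); defaults produce a scatter with R ≈ −0.6
  against the recovered scores, a realistic effect size for a
  30-variant library.

### Packaged time tables

`data/codon_times_synthetic_{ecoli,scer}.tsv` are deterministic
**synthetic stand-in** tables (all 61 sense codons, distinct positive
times in a ~50–140 a.u. range).  Construction: a GC-content trend
(GC-rich codons faster), a G/C-imbalance penalty (balanced codons
faster, making fast codons pairing-competent under the fallback engine),
a mild A-content penalty (A-rich codons slowest, making slow blocks
unpairable), and a large fixed codon-specific component independent of
composition.  That last component matters: it makes the planted
fastest-vs-slowest gap substantially larger than the purely GC-driven
gap, so the trade-off measured on an intact genome clearly exceeds the
composition-selection effect that any GC-based structure classifier
induces even on randomized sequences.  Real organism-specific time
tables are a user input in the same TSV format.

## Problem sizes of the validation studies

The shipped validation studies (`tests/test_acceptance.py`,
`scripts/acceptance.py`) use synthetic genomes sized for rapid, fully
reproducible desk runs: 200 genes × 300 codons for the recovery grid
(≈ 6 × 10⁴ codons per genome, six replicate genomes per β for the
Monte-Carlo standard error), 80 genes × 200 codons with 150-nt blocks for
the 100-genome null-model study, and a 30-variant × 400-codon library for
expression recovery.  Replicate-based standard errors are used for the
recovery check because the sample median of a discrete mixture does not
concentrate at β = 1 (the mixture CDF hits 0.5 exactly); the
across-replicate spread captures that atom-flipping, which a
single-genome bootstrap can underestimate.

## What passing tests do and do not show

The generator plants clean block structure, uniform amino-acid usage,
stationary codon choice and independent Gaussian PARS noise.  Real
genomes violate all of these: structure is not block-wise, amino-acid
composition correlates with structure, codon bias varies with expression
level and gene function, and experimental structure scores have
position-dependent coverage.  Passing the validation studies therefore
demonstrates correctness of the machinery (region extraction, pooling,
statistics, shuffles, calibration of estimator against analytic truth) —
not that any particular real genome exhibits the trade-off.  Conclusions
about real data require running the pipeline on real CDS sets,
experimental structure data and organism-specific time tables, with the
thermodynamic folding backend.

## Known limitations

* The fallback engine scores composition-driven pairing capacity; it has
  no stacking, loop entropies or pseudoknot awareness, and its absolute
  scale is calibrated, not physical.  Use ViennaRNA for real analyses.
* Codon translation times are fixed per codon: no wobble or tRNA
  modification effects, no ribosome queueing or collision kinetics.
* The Mann–Whitney normal approximation is used above the exact-path
  size limits; p-values below ~1e-300 underflow to 0.
* GenBank parsing extracts non-pseudo CDS features only; programmed
  frameshifts and selenocysteine recoding are not handled.
* Multiple-testing correction across *R*<sub>l</sub> values is
  deliberately not applied; the per-R_l rows are views of one dataset,
  not independent hypotheses.
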