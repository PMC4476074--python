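# Methods

## Problem and model

Given spliced alignments for two or more replicates each of a treatment and
a control condition, plus a gene annotation, the task is to decide for every
annotated intron whether it is differentially retained in treatment. The
package implements two complementary detectors over one shared feature
table, plus the synthetic-data generator used to validate them.

## Coordinates and the intron catalog

All internal coordinates are 0-based half-open; GFF3/GTF (1-based inclusive)
is converted once at the parsing boundary and the catalog is exchangeable as
6-column BED. Introns are the gaps between consecutive exons of any
transcript, deduplicated genome-wide on (chrom, start, end, strand); when
transcripts disagree on flanking exons, the first defining transcript in
input order wins — a deterministic rule chosen over merging, which would
make flank-dependent counts ambiguous. Splice-site sides follow strand: on
minus-strand introns the donor (5') site is the higher coordinate.
Unstranded annotations default to plus-strand orientation with a logged
warning. The catalog size is entirely annotation-driven; nothing is assumed
about genome scale.

## Feature extraction

A read participates only if uniquely mapped: NH tag equal to 1 or, absent
the tag, mapping quality ≥ 20 (configurable). "Within" always means full
containment of the aligned span, not overlap; this keeps the count features
mutually exclusive — a boundary-straddling read is splice-site evidence,
not intron evidence, and a spliced read can contribute only to the junction
count. Junction reads must match the intron's gap exactly with ≥ 4 aligned
bases on each side (the same minimum anchor the upstream aligner would
enforce); splice-site reads need ≥ 1 base of overhang on both the exonic
and intronic side (configurable — the feature is defined geometrically, so
the floor of one aligned base on each side is the weakest meaningful
requirement). Coverage counts positions under any aligned block, so
spliced-block bases inside an intron do count. Paired-end mates are treated
as independent single-end reads, and duplicates are not removed.

Expression is gene-level RPKM, `1e9 * reads / (total * union_exon_bp)`,
computed internally rather than through a transcript-quantification tool:
the removal criteria and ratio features only need a depth- and
length-normalized gene signal, and a gene-level measure keeps the pipeline
free of an assembly/EM step.

## Normalization

The standard normalization scale (SNS) is the minimum per-sample total of
mapped reads; each sample's counts are scaled by `SNS / total`, so the most
shallowly sequenced sample is the unit. Per condition, count features are
the sum of scaled replicate counts, and stay fractional. Coverage is a
fraction, not a count, so it is computed on the pooled (unscaled) replicate
reads. Condition-level RPKM uses the pooled scaled exonic count against an
effective library size of `SNS × replicates`.

## Rank-based calling

Removal criteria are strict inequalities evaluated in a fixed order (the
audit reports the first failure per intron, and its counts always partition
the input). The expression-ratio criterion keeps an intron only when
`log2(TNexpression / CNexpression)` lies in the open band
`(log2(2/3), log2(3/2))`: an expression shift between conditions scales
every count feature proportionally and would otherwise masquerade as
retention. The band is symmetric and configurable.

Delta features use a pseudo-count (default 1) on every count entering
IE = N_intron/N_exon and IJ = N_intron/N_junc, since control-side intron
counts of zero are the norm, and IC = e^coverage, whose log-ratio reduces to
`(cov_t − cov_c)·log2 e`. Candidates with any delta ≤ 0 carry no evidence of
retention gain and are excluded as noise. Each surviving delta is divided by
its maximum over the surviving candidate set — not over all introns — so
every normalized delta lies in (0, 1] and a singleton candidate scores
exactly 1. Weights default to equal thirds and must sum to 1. Ranking ties
break on descending DIC then ascending intron id (determinism only);
top-n% uses the ceiling, so any n > 0 returns at least one event.

Raw counts enter IE unadjusted for the length difference between introns
and exons; the ratio is compared across conditions for the same intron, so
the length factor cancels.

## Classifier

Vote labeling requires exact coordinate match between external prediction
intervals and catalog introns (a reciprocal-overlap mode, threshold 0.9, is
available for boundary-shifted inputs but off by default). Introns hit by
exactly one predictor are ambiguous and enter neither class. Negative
sampling is seeded and uses the 3525/741 ≈ 4.76 negatives-per-positive
ratio by default, capped at the pool size.

The 17-column matrix fixes its column order (14 condition features, then
DIE, DIJ, DIC) and sorts rows by intron id, so serialization is
byte-stable. Deltas here use the same pseudo-count policy as the caller but
no positivity filter — negatives legitimately have non-positive deltas.

The tree classifier is a single entropy-split decision tree pruned by
cost-complexity, with the pruning strength selected by internal stratified
cross-validation over the tree's pruning path (capped at 12 candidate
strengths); exact C4.5 rule pruning is not reproduced — the contract is a
single pruned information-gain tree. The forest is bagged, 10 trees, 5
candidate features per split, majority vote. Cross-validation is stratified
(fold class proportions within one example of global), metrics pooled over
held-out predictions; AUC scores are the positive-class probability — leaf
frequency for the tree, fraction of voting trees for the forest.

Information-gain ranking discretizes each base feature's
`treatment / (control + 1)` ratio into 10 equal-frequency bins (duplicate
bin edges merged, so a constant feature has one bin and zero gain) and
reports `H(label) − Σ_b p(b) H(label | b)` in bits.

## Synthetic data generator

The generator emulates a small two-replicate differential-IR experiment:
20 genes × 4 exons (60 introns), 200 bp exons, 150 bp introns, 50 bp
single-end uniquely-mapped reads, 30 exon reads per exon and 8 junction
reads per intron per replicate — depths at which every expressed gene
clears the expression criterion and junction evidence clears the control
criteria with margin, as in a moderately sequenced bulk experiment. Ten
percent of introns are planted as true IR and ten percent as each
false-positive archetype:

* **true IR** — treatment-only: the intron is tiled to full coverage
  (tiling step = half read length guarantees coverage 1.0) plus 2–6 random
  interior reads that vary retention strength, and 5 straddling reads per
  splice site; the control keeps junction evidence only.
* **boundary pile-up** — straddling reads with no interior signal; the
  intronic extension of a straddler is at most 40 bp per side, so coverage
  stays ≤ ~0.53 and the coverage criterion removes it.
* **interior cluster** — 12 reads confined to a window of 40% of the
  intron, capping coverage below 0.5.
* **expression shift** — gene-level and therefore assigned to whole genes:
  treatment doubles exon, junction, intron and boundary reads while the
  control keeps the 1× pattern, including moderate intron tiling in both
  conditions; every count criterion passes, and only the expression-ratio
  band removes it — the archetype the band exists for.

Reads are alignment records written directly as SAM (no base sequences, no
error model, no aligner in the loop): the detectors consume alignments, so
simulating bases would only add an untested dependency. Placement is
seeded uniform sampling; records are sorted, so identical configs produce
byte-identical files.

What the generator does **not** emulate: mapping ambiguity and multimapper
noise, sequencing errors and soft-clipping, paired-end fragments, length
and GC biases, overlapping genes, alternative flanking exons, or realistic
depth profiles. Passing tests therefore demonstrate the correctness of the
counting, normalization, scoring and training logic under clean alignments
— not robustness to alignment artifacts in real libraries.

## Numerical choices and degenerate inputs

* Pseudo-count 1 everywhere a count enters a ratio; configurable.
* Weights validated to sum to 1 within 1e-9.
* Score ties broken deterministically (DIC, then intron id).
* Empty candidate set after filtering returns an empty call table with a
  complete audit rather than an error; an empty feature table is an error.
* Equal-frequency binning with dropped duplicate edges makes the gain of a
  constant feature 0 by construction, not an error.
* `qcut`-style binning on heavily tied ratios can collapse bins; the gain
  is then computed over the remaining bins.

## Problem sizes used in validation

The shipped checks run the default 60-intron, 2×2-sample simulation
(~3,000–3,600 reads per sample), repeated over ten seeds for recall
stability, and a 500-row synthetic matrix with a 5-pooled-SD shift on 3 of
17 features for classifier calibration. These sizes give deterministic,
fully separable truth; they measure correctness of the implementation, not
field performance.

## Known limitations

Single-end logic only (mates are independent reads); no statistical
significance on calls — the caller is rank-based by design; no handling of
trans-splicing or annotation repair; vote labeling assumes external
predictions share the annotation's coordinate conventions after BED
conversion.
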