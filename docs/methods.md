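# Methods

This note documents the models, estimators and design choices behind
`satkit`, and what its synthetic-data validation does and does not show.

## Alignment and divergence estimation

Reads are aligned to one reference per satellite family: the consensus
monomer repeated twice (a *dimer*), or, for monomers shorter than 100 bp,
the smallest whole-number concatemer reaching 200 bp. A dimer/concatemer
of roughly two read lengths lets a read align across the monomer junction
regardless of its phase in the array.

Masking is seed-and-extend: a (read, family, strand) pair is considered
only if the read shares at least one exact 12-mer with that strand of the
reference (pure dynamic programming over all pairs would be prohibitively
slow, and a 12-mer seed retains, e.g., ≈ 99% detection power for
full-length 150-bp reads even at 25% divergence, where the per-position
seed-hit rate is 0.75¹² ≈ 0.03 over ~139 positions). Candidates are
aligned with an affine-gap Smith–Waterman (numba-compiled) under
match +1, mismatch −1, gap open −4, gap extend −1, with a deterministic
traceback (diagonal over up over left on ties). Per read, hits are
extracted iteratively: the highest-scoring hit is accepted (ties to the
lower-ranked family), its read span is masked, and the remainder is
re-aligned until nothing reaches the score floor — so a long window tiles
into several non-overlapping records and each read region is credited to
exactly one family. Records with score < 18 or fewer than 30 aligned
columns are dropped. All thresholds are exposed on the CLI; no claim of
bit-for-bit equivalence with any other masker is made.

Each record's divergence is the Kimura 2-parameter distance
`K = −½·ln[(1−2P−Q)·√(1−2Q)]` computed from its gapped alignment, with
gap columns excluded from the aligned-column count and ambiguity-code
columns excluded entirely. Alignments outside the K2P log domain
(saturated) are discarded rather than credited at an arbitrary value;
at the default score floor this is a pathological corner. No CpG
adjustment is applied.

## Per-family statistics

* **Genome proportion**: 100 × (read-span bp credited to the family) /
  (total sampled bp).
* **Landscape**: each record contributes its credited bp (as percent of
  sampled bp) to the integer bin `floor(K2P %)`. Bin width 1 point with
  floor binning follows the common landscape convention; the bins sum
  exactly to the family's genome proportion.
* **TSI**: internal reads / all reads aligned to the family, where a read
  is internal when a *single* alignment covers ≥ 89% of its length. A read
  with several partial hits to the same family counts once, as external
  — the index is read-based, not record-based. Zero aligned reads yield a
  missing value, not 0.
* **DivPeak**: the bin with maximal abundance (ties: smallest bin).
* **RSP**: abundance within ±2 bins of DivPeak — a 5-bin window truncated
  at bin 0 — divided by the family's total abundance. The integer-bin
  reading is the only one under which a zero-divergence family has an RSP
  of exactly 1.00.
* **Landscape shape labels**: leptokurtic iff RSP ≥ 0.8 and DivPeak ≤ 5;
  platykurtic iff RSP ≤ 0.3 and DivPeak ≥ 15; else mesokurtic. These
  thresholds operationalize qualitative usage (recent expansion vs
  degeneration) and are configuration-exposed, not field constants.
* **Summary rows**: arithmetic mean, sample SD (n−1; 0 for a single row),
  and median per numeric column; rounding (2 decimals, 5 for proportions)
  happens only in the report writer. The packaged published table is kept
  at 17 entries — the family with two monomer-length variants contributes
  two rows and the telomeric repeat is an ordinary row — because only that
  convention reproduces its printed summary statistics. Its printed total
  (1.2422) differs slightly from the column sum (1.23996); the package
  always reports its own sum.

## Cross-sample comparison

Abundances are already normalized percentages, so samples of different
sizes need no rescaling. Per family, the change versus a reference sample
is `log2(sample/reference)`, classified lower/similar/higher at a strict
±0.6 threshold. A family is called *present* when it reaches ≥ 1e-4% of
sampled bp **and** ≥ 10 aligned reads — an invented operationalization
(no standard criterion exists), exposed in configuration and reported
alongside results; log2 ratios are only computed between present pairs.
Spearman's rho is the Pearson correlation of mean ranks with a
t-approximation p-value (adequate at n ≈ 17). The exact Wilcoxon
signed-rank test drops zero differences, assigns average ranks to tied
magnitudes, and evaluates `min(1, 2·min(P(W⁺≤w), P(W⁺≥w)))` under the
exact null distribution of the positive-rank sum, computed by a
characteristic-polynomial convolution equivalent to enumerating all 2ⁿ
sign assignments (the test suite checks it against literal enumeration).

## The synthetic-data generator

The generator emulates the study conditions of low-coverage satellitome
sequencing: an i.i.d. background at a configurable A+T fraction (default
0.59, a typical AT-rich mammalian value), tandem arrays of each family's
monomer, and uniform single-end shearing at a target fold coverage
(default 2× of the genome, 150-bp reads; read count =
round(coverage × genome / read length)). Pairing is not simulated — no
computed statistic uses insert information. No sequencing-error model is
applied by default: every statistic here is driven by repeat divergence,
and a flat error would only blur the recovery targets.

Each monomer copy is mutated independently from the consensus (a star
phylogeny — no duplication history or concerted-evolution structure):
per site, a transition occurs with probability P and a transversion with
probability Q, where (P, Q) solve the K2P forward model

    P = 1/4 + 1/4·e^(−4βt) − 1/2·e^(−2(α+β)t),   Q = 1/2 − 1/2·e^(−4βt)

with βt = K/(κ+2), αt = κK/(κ+2), so the expected estimated K2P distance
of a copy equals the requested divergence K at transition/transversion
rate ratio κ (default 2). Optional single-base indels occur at a per-site
rate (default 0). Array lengths are gamma-distributed with a configurable
coefficient of variation (minimum one monomer) across `n_arrays` arrays —
a simple two-parameter control of clusterization for TSI experiments.
Arrays are placed in random order separated by at least two read lengths
of background, so no read bridges two arrays; total family bp lands within
1% of the requested proportion (monomer granularity permitting). The
emitted truth table (bp, proportion, realized mean per-copy substitution
divergence, array intervals) is the recovery oracle for all tests.
Multi-"species" simulation reuses one monomer pool with per-species
abundance multipliers and divergence offsets — the library-hypothesis
scenario — with per-species child seeds spawned from one top-level seed.

What passing recovery tests on these data do **not** show: robustness to
sequencing error and quality artifacts, paired-end effects, transposable
elements or other non-satellite repeats competing for alignments,
higher-order repeat structure, or concerted-evolution dynamics. They show
that the estimators recover what the generative model encodes.

## Tandem-period detection

The discovery step is a quantitative stand-in for visual dotplot
inspection: for each candidate lag p, the mean base identity between the
contig and itself shifted by p; the call is the smallest p within 0.01
identity of the maximum (the fundamental period, not a multiple), rejected
below 0.6 identity ("no tandem structure"). The threshold makes the
noiseless case exact. The consensus is the per-column majority over the
stacked period-length windows (gap-majority columns dropped, base ties
broken A<C<G<T); monomer start is arbitrary in a tandem array, so family
comparison uses the lexicographically smallest rotation. Families are
named `<tag>Sat<rank>-<length>` by decreasing proportion, ties broken by
longer monomer then monomer sequence.

## Numerical and degenerate-input conventions

Coordinates are 0-based half-open internally, converted to 1-based
inclusive only in report writers. All randomness flows from one integer
seed through `numpy.random.Generator`; every pipeline output is
byte-reproducible for a fixed seed. Zero-divergence requests return the
monomer unchanged; empty landscapes raise for DivPeak/RSP rather than
returning sentinels; constant vectors raise for Spearman; an all-zero
difference vector returns p = 1 for the signed-rank test by convention.

## Validation scale and known limitations

The recovery experiments in the test suite and acceptance script run at
desk scale — 1–2 Mb genomes at 2–4× coverage — chosen so each simulated
family still yields tens to hundreds of aligned reads. At that scale,
proportion recovery is accurate to a few percent relative for abundant
families, but the least abundant simulated family (0.1% of a 2-Mb genome
at 2×, ≈ 30 aligned reads) has a read-sampling CV of ≈ 11% on its
proportion, and the landscape mode (DivPeak) of a high-divergence family
is intrinsically noisy: a 150-bp read estimates K2P divergence with an
sd of √(p(1−p)/140)·dK/dp ≈ 3.4–4.3 points at 12–20% divergence, so with
tens of reads the modal bin wanders by 1–3 bins around a value itself
shifted ≈ −0.5 bin by floor binning and the convexity of the K2P
transform. Mean divergence and RSP are far more stable than the mode at
small n; DivPeak should be read with that caveat whenever a family has
few aligned reads. Assembly masking deduplicates overlapping window hits
by genomic coordinate but inherits whatever collapse the assembly itself
suffers — by design, since quantifying that underestimation is one of its
uses.
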