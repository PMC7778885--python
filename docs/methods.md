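# Methods

## Coordinate model

The reference genome is partitioned into fixed-size bins (`binsize` r, in
bp); a chromosome of length L contributes ⌈L/r⌉ bins, the last possibly
partial.  Global bin ids are contiguous in *input* chromosome order — never
lexicographically sorted — so results are deterministic across naming
dialects.  Internally all coordinates are 0-based half-open.  User-facing
position dialects (the SV table, the fragment-order spec, edit-script bin
intervals) are 1-based inclusive and converted at parse time; BED-family
formats (BEDPE, BED, bedGraph, sparse triples with bin starts, the
interaction-table export, chrom.sizes) keep their field-standard 0-based
half-open convention, because a 1-based BED would silently break interop
with every other genomics tool.

A breakpoint landing mid-bin is assigned to its bin by floor division, and a
junction bin partially covered by a fragment is retained in that fragment.
Consequently both junction bins of an intra-chromosomal deletion can survive
in the derivative.  This is a documented package choice: rearranged maps in
practice show breakpoint-spanning bins, and no truncation rule is obviously
more correct at bin granularity.

## Breakend fusion algebra

"Side 3 at p" denotes the segment [0, p) read in + orientation (ending at
p); "side 5 at p" the segment [p, L) (starting at p).  A junction fusing
side s1 of pos1 with side s2 of pos2 yields:

| orientation | derivative |
|---|---|
| 3to5 | `[c1:0-p1 +] ⊕ [c2:p2-L2 +]` |
| 5to3 | `[c2:0-p2 +] ⊕ [c1:p1-L1 +]` (canonicalized) |
| 3to3 | `[c1:0-p1 +] ⊕ [c2:0-p2 −]` |
| 5to5 | `[c1:p1-L1 −] ⊕ [c2:p2-L2 +]` |

For intra-chromosomal records this makes 3to5 a deletion of [p1, p2), 5to3
a tandem duplication of it, and 3to3/5to5 the two inversion junctions.  The
deletion case is the single normative anchor of the convention (its junction
bins and fused map are independently checkable); the other three rows follow
by the side algebra.  A 5to5 junction cannot begin with a + fragment — both
kept segments start at their breakpoint — so its canonical form starts with
the − fragment of chrom1.  Type/orientation mismatches (e.g. a DEL declared
5to3) are tolerated as annotations by default and rejected under strict
mode, since pan-cancer SV tables are heterogeneous.  A TRA record accepts
any orientation; a reciprocal translocation is two records, each producing
one derivative.

## The bin map and its edits

Every rearrangement reduces to a bin map: parallel arrays of source bin,
orientation (±1) and fragment id, where each fragment is a maximal run
stepping +1 (or −1 for − runs) through source bins.  Edits operate on the
*current* derivative axis — what a user looking at the rearranged map sees —
not on reference coordinates:

* delete removes an axis interval;
* invert reverses it and flips orientations (an involution);
* duplicate inserts a tandem copy immediately after the interval;
* join fuses two derivatives at cut points using the same 3/5 side algebra
  as breakends (side 3 keeps the prefix before the cut, side 5 the suffix).

Fragment ids are recomputed canonically after every edit (new run wherever
the walk breaks), and an undo stack of state snapshots gives exact reversal
of any edit sequence.

Materialization fills `M'[a,b] = M[src(a), src(b)]`, so a duplicated
segment replicates its source rows/columns, including a duplicate-duplicate
block equal to the source self-block.  Real duplicated alleles would each
carry their own contacts; copying the observed block is the only choice
computable from a single observed matrix and is documented as such.  The
trans-enhancement weight w multiplies entries whose *source* bins lie on
different chromosomes; it is applied at materialization only (display
semantics) and never persisted into counts.  With w = 1 materialization of
the identity map is bit-identical to the source.

## Normalization

**Coverage.**  `value(i,j) = counts(i,j) / (m_i · m_j) · S` with m the
per-bin marginals (diagonal counted once) and S restoring the total mass.
This marginal-product scaling deliberately replaces regression-based
coverage correction; a `normalizer` callable hook accepts any substitute.
Zero-coverage bins yield zero values and are returned as a flag list.

**Distance.**  `expected(d)` is the mean contact value over *all* cis pairs
at bin distance d — structural zeros included in the denominator, which
keeps the estimate deterministic and makes the mean cis fold change exactly
1 at every distance by construction.  Optional log-space moving-average
smoothing (window in bins, default 1 = off) with a floor of 1e-8 guards
against empty long-range diagonals.  Per-chromosome scope is the default
(each chromosome gets its own curve); pooled scope combines all
chromosomes and is what derivative-axis lookups use.  Trans pairs are
divided by the pooled trans mean.  The normal-sample preset (5 kb bins,
cis ≤ 2 Mb) and cancer preset (40 kb, cis + trans) are configuration, not
hard-coded behaviour.

## Junction smoothness

For an axis cut j and window k, the score is

    S = mean over a ∈ [j−k, j), b ∈ [j, j+k) of M'[a,b] / expected(b − a)

with the expectation evaluated at the derivative-axis distance — that is
the neo-adjacency hypothesis under test.  Pairs whose expected value sits at
the floor are excluded and counted; windows truncate at axis ends but need
at least one bin per side.  The background profile should be estimated *on
the rearranged axis* (`expected_from_rearranged`), treating each derivative
block as a chromosome: a reference-coordinate profile of the same sample is
biased low by the deletion's zero-count bins (its pairs enter the
denominators), which would inflate S by roughly the deleted fraction.
Scoring is done at w = 1.

Interpretation: a correct junction scores ≈ 1 (cross-junction contacts
follow the normal decay); the same breakpoint scored without rearrangement
scores ≈ 0 (one window lies in the deleted, contact-free region); a
breakpoint misplaced by Δ bins scores ≈ ((1+d)/(1+d+Δ))^α < 1 because the
true contact distance exceeds the axis distance.

## Synthetic generator

The generator emulates how a rearranged genome reads out through Hi-C
mapped to the reference.  Contacts are sampled on the derivative axis:

    λ_cis(a,b)  = A · (1 + |a−b|)^(−α) · (β if same TAD)      same derivative
    λ_trans     = t · A                                        different derivatives

with Poisson emission, then every sampled pair is projected to its source
reference bin pair and accumulated.  Defaults: A = 100 (short-range counts
per bin pair), α = 1.0 (typical contact-decay slope near 1 at tens-of-kb to
Mb scales), β = 2.0 within-TAD boost, t = 0.02 trans background, r = 40 kb.
The seed is mandatory; one `numpy` generator drives TAD placement then
sampling, so an empty SV list reproduces the unrearranged simulation
bit-for-bit.

TADs are a reference property: each reference bin carries a TAD label,
derivative bins inherit the label of their source bin, and the boost applies
only within one fragment — a junction therefore splits domains, creating the
fused-TAD geometry the rearrangement analysis is meant to reveal.  Each
chromosome may be consumed by at most one SV record per simulation
(multi-hit chains are expressed through the edit or order-spec interfaces).
Deleted bins receive no counts; bins covered twice by a duplication
accumulate both copies, mimicking reads from two alleles piling onto one
reference bin; total counts are conserved by the projection.

What the generator does **not** emulate: A/B compartments, loops/anchored
peaks, copy-number-dependent coverage, mappability and restriction-site
bias, and overdispersion (Poisson, not negative binomial — an extension
hook).  Passing tests therefore demonstrate correctness of the coordinate
algebra, the normalization identities and the smoothness statistic under a
clean decay-plus-TAD model, not robustness to every artefact of real data.

## Numerical and design choices

* Expected-profile floor 1e-8; smoothness excludes floored pairs rather than
  dividing by them.
* The decay-exponent estimator is the unweighted least-squares slope of
  log expected(d) on log(1+d) over d ≥ 1 with positive expectation, negated;
  it requires ≥ 50 usable distances.
* Problem sizes in the test and acceptance workloads (matrices of 100–300
  bins for the randomized equivalence trials, 250-bin chromosomes for the
  simulation recoveries, 10 replicates for the smoothness discrimination)
  are chosen so the statistics of interest are well separated — e.g. the
  decay slope's sampling error is well under the ±0.1 check — while the
  whole suite runs in seconds.
* Cooler-layout HDF5 I/O (schema v3 single resolution: `chroms`, `bins`,
  `pixels`, `indexes`) is implemented natively on h5py; multi-resolution
  pyramids and read-level ingestion are out of scope.
* Rendering is non-interactive; SVG output uses a fixed hash salt and no
  timestamp so identical inputs give identical files.  "Triangle" mode
  shows the upper triangle; boundaries are drawn as separators and fragment
  orientations as directional glyphs.

## Known limitations

* Copy-number alterations are not modelled: expected values are not rescaled
  by copy state, so amplified regions will show inflated fold changes.
* The smoothness statistic assumes the background decay is estimable from
  the rearranged map itself; on maps dominated by rearrangement (little
  contiguous sequence) the profile is noisy.
* SV calling, TAD calling, and detection of breakpoint enrichment are out of
  scope — SVs are inputs, not outputs.
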