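# Methods

This note records the models, conventions and numerical choices behind
`utrscreen`, and what the synthetic studies do and do not establish.

## Canonical seed sites

A mature miRNA (≥ 8 nt; typically 15–30 nt) defines a seed (positions
2–7) and an extended seed (2–8). Target-strand patterns, 5′→3′:

| class | pattern | span |
|---|---|---|
| 6mer | revcomp(seed) | 6 |
| 7mer-m8 | revcomp(extended seed) | 7 |
| 7mer-A1 | revcomp(seed) + `A` | 7 |
| 8mer | revcomp(extended seed) + `A` | 8 |

Matching is exact Watson–Crick with no G:U wobble. The 7mer-A1/8mer
adenine is a literal target `A` regardless of the miRNA's first
nucleotide, the standard canonical-site convention. Each occurrence of
the 6mer core yields exactly one reported site, labeled with the maximal
class supported at that position, so one physical site is never counted
under several classes; overlapping core occurrences are each reported.
Coordinates are 1-based inclusive on the fragment; BED output converts
to 0-based half-open at the writer boundary only. DNA input is accepted
and normalized to RNA (T→U, uppercase), since UTR libraries are
distributed as DNA.

Non-goals: non-canonical and 3′-compensatory sites, wobble pairing,
context-style efficacy scores.

## Fragment tiling

UTRs longer than `target_len` (default 675 nt) are tiled with
`n = ceil((L − overlap)/(target_len − overlap))` fragments
(`overlap` = 30 nt): the minimal count such that no fragment exceeds the
target. Lengths are as equal as possible (difference ≤ 1 nt; the extra
nucleotide goes to earlier fragments — a deterministic tie-break), and
every junction overlaps by exactly `overlap` nt. This is a stated
convention for "approximately 675 bp", not a claim of bit-identity to
any vendor's tiling. Synthesis failures are modeled as an exclusion
list, nothing more.

## Secondary structure

The primary path ingests externally computed structures (Vienna
dot-bracket; RNAfold output is consumed verbatim), because reproducing a
thermodynamic folding engine bit-for-bit is out of scope. For
self-contained fixtures, `fold_baseline` computes a maximum-weight
nested pairing by dynamic programming with pair weights G-C = 3,
A-U = 2, G-U = 1 (a hydrogen-bond proxy), a minimum hairpin loop of 3
unpaired bases, and deterministic tie-breaks (3′ base left unpaired
first, then the 5′-most partner). The optimum is post-filtered to drop
helix-terminal G-U pairs and isolated (length-1) helices, mirroring the
usual `RNAfold` options of disallowing terminal G-U pairs and lonely
pairs. Pseudoknots, dangling-end models, temperatures and ensemble
(partition-function) accessibility are not implemented; the structure is
a single MFE-style proxy.

Site accessibility is the percentage of paired bases (`(` or `)`) in
the site interval extended by a window of 0, 5 or 50 nt on each side,
clipped to the molecule.

## Layout and coverage score

The structure is a graph G = (V, E): vertices are bases; edges are the
backbone path plus base-pair bonds. `layout_2d` draws it
deterministically: the exterior loop on a straight line, every interior
loop as a circle sized so adjacent members sit one unit apart, helices
as two parallel strands with unit rung spacing. Layouts (computed or
imported from GML) are rescaled so the **mean backbone-adjacent distance
is exactly 1**; this defines the "length unit" in which all radii are
expressed, since the drawing tools themselves define no physical unit.

The coverage score of a site S at radius r sums, over the site's bases,
the number of vertices within a **closed** Euclidean ball (‖·‖₂ ≤ r; the
base counts itself) and divides by |S|. It is ≥ 1, ≤ |V| and
non-decreasing in r. With several sites on a fragment the minimum-score
(most accessible) site is used, ties broken toward the 5′-most site.
The default radius sweep is {0.8, 1, 1.5, 2, 2.5, 3, 4, 5, 6} length
units, spanning the useful range from "only immediate neighbours" to
"most of a typical loop region"; both endpoints of the sweep are
supported rather than asserting one canonical maximum.

For the windowed paired-fraction metrics a single representative site is
needed; the default (`site_selection="min_coverage"`) is the site with
minimal coverage score at a selection radius of 2 length units (an
intermediate radius that discriminates loop from helix neighbourhoods);
`five_prime_most` is available as the alternative. The coverage-score
metric itself takes the per-radius minimum over sites.

## Screen statistics

Measurements are firefly/renilla pairs in 4 biological replicates ×
2 technical duplicates, for each construct with the miRNA expression
plasmid and with the empty vector. Technical duplicates share a lysate
and are therefore averaged within each replicate before any testing,
giving n = 4 per group. The normalized RLU is the replicate-paired ratio
of ratios (test ratio / same-replicate control ratio); the Welch t test
(two-sided, unequal variances, Welch–Satterthwaite df) compares the four
test ratios against the four control ratios.

An MTI is **validated** iff mean normalized RLU < 0.90 **and** p < 0.05
(nominal; a Benjamini–Hochberg column is emitted as supplementary output
but never used for validation). RLU categories: strong < 0.70, moderate
[0.70, 0.90), none [0.90, 1.10], upregulated > 1.10 with p < 0.05 — the
up-regulation threshold is chosen symmetric to the 0.90 cutoff since
screens observe occasional significant activation without a published
criterion. Genes tiled into several fragments are summarized by the
minimum mean RLU and the minimum p over fragments (reported
independently — they may come from different fragments); a gene is
validated when any fragment is, so adding fragments can never
un-validate a gene.

Networks treat gene-level MTIs as edges of a complete bipartite gene ×
miRNA graph with per-edge evidence flags; validation implies testing,
while prediction is independent evidence. Rates are reported to one
decimal, as are validation percentages and fold increases
(new/prior validated counts).

## Correlation analysis

Pearson's sample correlation with its two-sided t-based p value
(t = r·√((n−2)/(1−r²))), computed per miRNA × metric × radius cell.
Cells with fewer than 3 observations or a constant column are returned
flagged `defined=False` instead of being dropped, so sparse screens
remain visible. A display threshold of p < 10⁻⁵ marks strongly reduced
sites in plots; it plays no role in any computation.

## Synthetic studies

`generate_study` emulates the screen at desk scale:

* **Sequences** — uniform-random UTRs (default 200–4000 nt, matching
  the span of real 3′UTR libraries) with 1–3 planted canonical sites per
  gene at known positions. Guard bases adjacent to each planted core pin
  the site to exactly the requested class, and any spuriously arising
  core for a screened miRNA is re-rolled locally (bounded at 1,000
  attempts), so scanning recovers exactly the planted truth — the basis
  of the recovery tests.
* **Effects** — per fragment × miRNA: repressed with probability 0.60
  (true mean uniform on [0.40, 0.88]), up-regulated with probability
  0.02 (true mean 1.30), otherwise null (1.00); one sensor construct per
  miRNA (two perfect complements, true mean 0.15) stands in for the
  positive controls. The repressed range and the up-regulation level
  bracket the effect sizes such reporter screens report; the 60%
  repressed share matches a typical overall validation rate.
* **Noise** — per-replicate normalized ratios are Normal(true mean,
  sd 0.05) truncated at 0; the control replicate ratio is exactly 1.0
  (all noise on the test ratio, so the normalized ratio is exactly
  Normal); technical duplicates sit symmetrically around the replicate
  value and renilla levels carry log-normal variation that cancels in
  the ratios. Everything is deterministic given `rng_seed`, and the
  seed plus a config hash appear in every output header.

What this does **not** model: plate positional effects, transfection
efficiency drift, heteroskedastic or heavy-tailed luminescence noise,
control degradation, sequence-dependent synthesis failures, and any
coupling between structure and measured repression. Passing calibration
tests therefore demonstrates the correctness and calibration of the
*pipeline* under its stated noise model, not the biological accuracy of
the screen itself.

Structure fixtures (folding every fragment) are produced when
`fold_structures=True`; the default is off because the accessibility
stage primarily ingests external structures and the folding baseline is
cubic in sequence length.

## Problem sizes and tolerances

The shipped test suite runs entirely on generated data: oracle
equivalence on 1,000 random fragment/miRNA pairs (≤ 500 nt) and 200
random folded structures (30–90 nt); statistical calibration on 2,000
null and 1,000 repressed constructs (type-I ≤ 5%, power > 95% at true
mean 0.6, sd 0.05, n = 4); truth recovery on a ~2,000-construct study
(effect means within ±0.01); tiling invariants exhaustively for lengths
1..10,000. Welch and Pearson implementations are checked against
independent closed-form computations to 1e-10. Floating-point
comparisons in the coverage oracle use the same closed-ball predicate on
both sides, so equality is exact up to 1e-9.

## Known limitations

* The folding baseline optimizes pair weights, not free energy; its
  structures agree with thermodynamic folds only qualitatively.
* The radial layout does not avoid overlaps in large multiloops; the
  coverage score is defined on whatever planar embedding is supplied,
  and scores from different layout programs are comparable only after
  the unit rescaling applied here.
* Pre-normalized input mode tests each construct against an exact
  reference of 1.0 and therefore ignores control-side variance.
* The generator plants at most one site class per core; composite or
  overlapping planted sites are rejected rather than resolved.
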