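# Methods

This note documents the models, parameter choices and numerical details
behind `hceanchor`, and what the simulation-based tests do and do not
demonstrate.

## The anchoring model

The pipeline treats highly conserved elements (HCE) as landmarks assumed to
occur once per genome and to survive between related genomes nearly
unchanged.  Both assumptions are enforced rather than trusted: an element
only becomes an anchor after passing a perfect-and-unique filter on the
reference (100% identity within aligned blocks, ≥ 99% of its length
aligned, exactly one such placement) and a unique-placement filter on the
target (coverage ≥ `min_ali`, exactly one surviving placement).  Gaps are
permitted inside the "100% identity" reference filter — identity is defined
over aligned columns, `matches/(matches+misMatches)` — because small indels
lengthen an alignment without contradicting per-base conservation.  The
99%-length criterion counts aligned query bases (block columns, N included),
not gap columns.

Uniqueness is counted over placements that pass the identity/coverage
filters: an element with one perfect hit plus one 91%-identity hit is kept,
because sub-threshold hits fail the method's own criteria.  A
`strict_unique` switch counts every reported hit instead, for users who
prefer the conservative reading; the default is the permissive one.

## Aligner

The aligner is a seed-and-extend local aligner specialised for 40 bp – 5 kb
queries at ≥ 80–90% identity.

* **Seeding.** k-mers (k = 11) sampled every 5 bp across the genome, held
  in a sorted-array index.  k-mers containing N are never indexed.  An
  optional occurrence threshold removes k-mers whose total genome count
  exceeds it — the usual defence against repeats seeding everywhere.
* **Clustering.** Seed hits are grouped by sequence and diagonal band
  (width 32); overlapping candidate windows merge, so each locus is
  extended once.
* **Extension.** The whole query is aligned inside the candidate window
  with an edit-distance-optimal alignment (edlib).  Because unit costs can
  fragment one long gap into several equal-cost pieces, any alignment
  containing indels is re-aligned under the affine scheme
  (match +1, mismatch −1, gap open −3, gap extend −1) with a vectorised
  Gotoh pass (free end-gaps on the target side; the horizontal gap state
  uses a running-max scan, exact because gap-adjacent-to-gap is never
  affine-optimal).  Problems above 4M DP cells keep the edit-distance
  blocks.
* **Local trimming.** The extension aligns the full query, so a Kadane pass
  over per-column scores (with inter-block gap penalties charged between
  columns) restricts each alignment to its maximum-scoring contiguous
  sub-path.  This is what makes a truncated element report ~90% coverage
  instead of dragging a chance-matching tail to ~98%.
* **Gapless preference.** In normal mode both a gapless single-diagonal
  interpretation and the gapped one are computed; the higher-scoring wins
  and gapless wins ties, so substitution-only loci never acquire spurious
  indels.  Fast mode reports only the gapless interpretation and rejects
  queries over 5 kb with an error directing the caller to split them
  (`split_long_hce` handles this).
* **Reported records** are PSL; identity is `matches/(matches+misMatches)`
  (1.0 when no non-N columns), coverage `(matches+misMatches+nCount)/qSize`.
  N columns are never counted as matches or mismatches.  A gap-inclusive
  identity is not used; the matches/mismatches definition is the module's
  contract and the one the filters reference.

Tests hold the aligner to two oracle properties on small instances: every
reported alignment's affine score is within one gap-open penalty of a full
Smith–Waterman on the same window, and planted loci sharing an exact seeded
k-mer at identity above threshold are never missed.

## Anchor transfer

An anchor's two placements are composed into one gapless scaffold-versus-
chromosome PSL record: strand is the product of the two placement strands;
when the reference and target spans differ (a gapped element alignment) the
block takes the shorter span, anchored at the interval starts after
orientation.  Base-level structure inside the element is deliberately
collapsed — chaining needs block geometry, not base correspondence, and
sub-element correspondence would require re-alignment the method avoids by
design.

## Chaining and netting

Blocks are grouped by (chromosome, scaffold, orientation).  Within a group
an O(n²) sparse DP finds the maximum-score chain — successors must strictly
increase in reference and orientation-adjusted scaffold coordinates —
scoring Σ len·100 − Σ gap(dt, dq).  Chains are extracted best-first; each
block belongs to at most one chain; chains below `min_score` = 3000 are
dropped.  Blocks whose intervals overlap within a chain are trimmed at the
midpoint of the overlap (an order-independent policy; some policy is
required because adjacent anchors can map overlapping intervals).  The
recorded chain score is the re-scoring of the emitted, trimmed chain, so it
always reconciles with the chain file.

The gap cost is piecewise linear in max(dt, dq) with marginal costs
30/3/1/0.3 over breakpoints 0/100/1000/10000, plus an opening cost of 400
when both sides gap at once.  The `medium` preset triples the marginal
costs; `loose` (the default for anchor chaining, where anchors are sparse
and real gaps between them are large) is the table above.  These tables are
explicit configuration with documented defaults — only the preset names and
the minimum score are fixed by convention, and no claim of numerical
fidelity to any particular external chaining tool is made.

Netting is greedy by descending score: each chain contributes the pieces of
its reference span that land in currently unfilled gaps of ≥ `min_space` =
25 bp (small enough to admit any meaningful fill); pieces become fill
nodes, the chain's internal block gaps become gap children available to
lower-scoring chains, and residual space in a gap stays open for siblings.
Chains compete globally per chromosome, across scaffolds.  Fills are
annotated against their nearest ancestor fill: same scaffold and strand →
`syn`, same scaffold flipped strand → `inv`, different scaffold →
`nonSyn`, top-level → `top`.

The scaffold report aggregates fills per (scaffold, chromosome): reference
span, majority-by-bases orientation, number of anchors whose reference
midpoint falls in a fill, fraction of the scaffold inside fills, and a
split flag when a scaffold appears on more than one chromosome.

## Evaluation

The intersecting fraction compares two mappings as block sets in scaffold
coordinates.  The printed formula "F = Σ C/Z" read literally is a sum of
per-scaffold ratios and can exceed 1; since F is reported as a percentage
≤ 100, the aggregate is implemented as ΣC/ΣZ, with the per-scaffold mean of
C/Z also reported and the choice noted in output metadata.  The comparison
covers all baseline scaffolds (scaffolds with zero baseline bases are
excluded and flagged); restricting to scaffolds mapped by both methods is
not the default because it would hide recall differences.

Inconsistency classes: `FULL_CONFLICT` (both mappings single-chromosome,
different ones), `PARTIAL_SPLIT` (split across ≥ 2 chromosomes in one
mapping, single in the other), `BOUNDARY` (same chromosome and position,
block ends differing beyond 1000 bp — a tolerance chosen because such cases
are scoring artifacts of overlapping adjacent alignments, not biological
conflicts).

Scaffold statistics (N50, median, totals) are restricted to scaffolds
≥ 10 kb by default, the conventional cutoff for "placeable" scaffolds.

## Synthetic data

The generator models conservation purely as differential substitution
pressure: background sequence diverges at 8% and planted elements at 1% by
default, with indels (rate 5·10⁻⁴/bp, geometric lengths ≤ 20) suppressed
inside elements, then large inversions and translocations, then
fragmentation into scaffolds whose N50 is resampled until within 20% of the
150 kb target.  Element lengths are lognormal (median 200 bp, clipped to
40–2000 bp); placements keep ≥ 100 bp spacing; 2% of elements are
duplicated to a second locus and 1% are built from a shared tandem motif,
so the uniqueness and over-representation filters are exercised rather than
vacuous.  Every edit passes through an explicit segment map, so each
scaffold's true chromosome, span and orientation — and each element's
target location — are exact, not estimated.  All randomness flows from one
`numpy` PCG64 generator seeded from `SimParams.seed`, so output is
reproducible across platforms.

What the simulation does **not** model: repeat landscapes, GC isochores,
gene structure, segmental duplication, polyploidy, assembly errors.
Passing tests therefore demonstrate the pipeline's logic and its behaviour
under the stated divergence structure; they do not certify performance on
real genomes with rich repeat content, where the occurrence threshold and
uniqueness filters carry far more load.

The default simulation size (2 × 5 Mb, 2,000 elements) was chosen as the
largest pair that exercises every pipeline stage — multiple chromosomes,
both rearrangement types, ~100 scaffolds above the 10 kb cutoff — while
remaining comfortable on a single CPU; the divergent-pair scenario used for
the relaxation analysis (background 40%, elements 12%, 1 × 1 Mb, 400
elements) models the distant-genome regime where only relaxed thresholds
(80/80) recover anchors.

## Known limitations

* The aligner trusts exact 11-mer seeding; diverged loci with no shared
  sampled 11-mer are invisible.  At 12% divergence this is negligible for
  ≥ 100 bp elements but grows for 40–60 bp elements.
* Elements straddling scaffold or rearrangement boundaries align partially
  and are usually lost to the coverage filter; the per-scaffold metrics are
  insensitive to this, the per-element counts are not.
* Chain scores are anchor-geometry scores, not sequence-alignment scores;
  comparing them across parameter settings is meaningful, comparing them to
  scores from sequence-level chaining tools is not.
* `transfer_to_reference` start-anchors the composed block when spans
  differ; sub-element coordinate error up to the span difference (typically
  a few bases) is possible and irrelevant at chaining resolution.
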