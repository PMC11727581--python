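# Methods

## Signal model

A target-primed reverse transcription (TPRT) insertion writes, onto the
reference genome, the block

    TSD · oriented(element · A^k) · TSD

where the TSD is a direct repeat of the integration site (7–20 nt in the
insertions this package targets) and `A^k` is the poly(A) tail (k ≥ 5).
For minus-strand insertions the middle part is reverse-complemented, so
the tail appears as poly(T) immediately inside the 5' TSD on the
reference strand.

In a pairwise whole-genome alignment net, such a block produces a *gap*
(reference sequence absent from the query at that locus) containing a
*fill* one synteny level deeper whose query coordinates point at the
parental locus. Detection therefore iterates over every (gap, child
fill) pair, at any depth of the net hierarchy — the canonical case is a
level-2 fill inside a level-1 fill's gap, but deeper nesting occurs in
real nets and is treated identically.

## Net file handling

Coordinates are 0-based half-open; the reference is always plus strand
and query coordinates live on the strand named in the record, following
the format's own documentation. Indentation is one space per nesting
level (tabs are tolerated on input, never emitted), a fill's children are
gaps and vice versa, child intervals must be contained in their parent,
and every attribute pair after the six coordinate fields is preserved
verbatim and in order. Because nothing beyond the coordinates is
interpreted, both raw chainNet output and netSyntenic-annotated dialects
are accepted, and parse → write round-trips byte-identically (a property
the test suite checks on simulator output and random trees).

## TSD search

Around each fill `[s, e)` two flanks are cut: left `[s − out, s + in)`
and right `[e − in, e + out)` with `out = in = 30` nt by default. The 30
nt default leaves margin above the longest TSD the model expects (20 nt)
plus the emulated alignment-boundary fuzz; the inward extension matters
because a real aligner may absorb the TSD or tail into the fill.

The search returns the best-scoring local alignment between a left-flank
substring and a right-flank substring subject to:

* aligned length ≥ 7 (`min_tsd_len`);
* mismatches + indels ≤ 1 (`max_tsd_mismatches`);
* anchoring — the left copy must end, and the right copy must begin,
  within `extend_in` bases of the respective fill edge;
* terminal columns must match (a dangling edit would pad the reported
  length without adding evidence — the same reasoning fixes the poly(A)
  run's termini to A).

Scoring is unit-per-base: +1 match, −1 mismatch, −1 gap. With at most
one edit every admissible alignment decomposes into maximal exact match
runs joined by single edits, so the implementation enumerates all
maximal runs per diagonal (the classic run-length dynamic program) and
stitches them across one mismatch (only possible at a run end) or one
indel (possible at any interior position, resuming on the adjacent
diagonal). This enumeration is exhaustive for edit budgets ≤ 1 — the
test suite proves it equal to a brute-force scan of every substring pair
on hundreds of random flank pairs — and for larger budgets it chains
further, omitting only alignments with two immediately adjacent edits.
Ties are broken deterministically: longer alignment, then fewer
mismatches, then smaller distance of the left copy to the fill edge,
then smaller coordinates.

## Poly(A) search

Within a window inside the called 3' TSD, the best run must end within 5
nt of the TSD's inner edge (`polya_max_gap_from_tsd`), start and end on
A, contain at most one internal non-A (`max_polya_interruptions`) and
reach 5 nt. Runs are ranked by length, then score (`aCount −
interruptions`), then proximity to the TSD. For the minus orientation
the identical search runs on the reverse complement, so reference-strand
poly(T) stretches are found symmetrically.

Both orientations of each region are searched in full; the orientation
with the higher total score wins and exact ties go to plus. The
insertion interval is reported between the inner edges of the two TSD
copies.

The score filter defaults to `min_score = 12 = 7 + 5`, i.e. it is
implied by the two length floors and acts as an independent knob only
when raised. Typical passing candidates in the simulations score in the
low-to-mid 20s (TSD 7–20 plus tail 5–20), consistent with the additive
unit scheme.

## Simulation protocol

The benchmark plants `n_true` TPRT blocks and `n_control` bare elements
at uniform positions ≥ 1 kb apart in an i.i.d. random genome, with TSD
length uniform on [7, 20], tail length uniform on [5, 20] and random
strand. One parental copy of the element is placed first; emulated
level-2 fills point their query coordinates at it. The bundled element
is a synthetic ~1 kb sequence with realistic base composition (its 3'
terminus is deliberately non-A so the planted tail length stays
unambiguous); it is not a biological consensus, and any element FASTA
may be substituted.

The emulated net contains one level-1 fill over the whole backbone, a
gap per inserted block, and a level-2 fill covering the element body —
TSDs and tail fall outside the fill, as they have no counterpart at the
parental locus. Each fill edge is independently jittered by up to ±3 nt
(clamped inside its gap) to stand in for the boundary fuzz a real
aligner introduces. Scale defaults are desk-sized — 5 Mb genome with
200 + 200 insertions, about two seconds per run — while the full-scale
60 Mb / 1000 + 1000 configuration runs in a few minutes.

Matching rule: a planted insertion counts as recovered when a
filter-passing candidate's insertion interval overlaps the truth
interval extended by 20 nt (`match_tolerance`); specificity is the
fraction of controls with no passing candidate. The ROC sweeps a score
threshold over each locus's best matched candidate score (loci with no
candidate never turn positive); the trapezoidal AUC equals the
Mann–Whitney rank statistic, which the tests verify to 1e-9 alongside an
external cross-check.

At these settings the caller recovers roughly 94–98% of planted
insertions per seed with specificity ≈ 1.0. The residual misses are
informative about real data: when a short planted tail abuts a flanking
base that happens to extend the TSD alignment, the detected TSD eats
into the tail and drops it below the 5 nt floor, and occasionally a
coincidental flank duplication outcompetes the true TSD — both analogous
to the boundary ambiguity real alignments exhibit. Conversely a rare
control acquires a coincidental TSD-plus-tail signature in random
sequence (~0.3% of controls), so specificity is near, not exactly, 1.

What the simulation does *not* model: 5' truncation, twin priming,
transductions, nested insertions, element divergence from the parent,
and genuine aligner failure modes (chain breaks, fills dropped by
scoring). Passing benchmarks therefore demonstrate the correctness of
the TSD/poly(A)/scoring logic under clean alignment topology, not
end-to-end performance on a real lastz/chainNet product — those can be
supplied directly to the detector when available.

### TPRT motif planting

With `motif_mode="tprt"` the simulator writes the endonuclease hexamer
(`TTAAAA`) so that its 3' end lies a fixed distance (default 10 nt)
upstream — in element orientation — of the element's 5' start, the edge
the caller reports. Motif bases falling inside the target site are
written into the TSD sequence itself (hence into both duplicated
copies, preserving the repeat), and bases beyond it into the flanking
genome. The annotate module's strand-aware scan then recovers the
planted geometry: the modal exact-motif offset equals minus the planted
distance, smeared by a few nt where TSD boundary calls shift.

## Annotation conventions

Categories are supplied as BED interval files, one per category, and a
candidate takes the highest-priority category overlapping its insertion
interval by at least one base; the default priority is repeat > CDS >
UTR > exon > intron > promoter, with `intergenic` for no overlap. The
priority order is a design choice (overlap resolution is rarely stated
in published accountings; repeats first matches the repeat-dominant
composition of real catalogues) and is fully configurable.

Motif scanning covers ±20 nt around the 5' insertion edge on the
candidate's strand. "Similar" means Hamming distance ≤ 1 from the
hexamer — the smallest well-defined neighbourhood; exact hits are a
subset of similar hits by construction. Offsets are measured from the
motif's 3' end to the insertion edge, negative meaning upstream in
element orientation.

## Expression conventions

RPM = count / library size × 1e6, with library sizes supplied or
defaulting to column sums. The log transform is log2(RPM + 1); the
pseudocount of 1 keeps zero counts at exactly zero and is the main
unstated constant in this part of the pipeline. Per-tissue values are
means of log2(RPM + 1) over the tissue's samples (means, not maxima, so
that replicate count does not bias the profile). Tau is computed on
those per-tissue means:

    tau = Σᵢ (1 − xᵢ/max(x)) / (n − 1)

Tau is invariant to positive rescaling, 0 for a uniform profile, 1 for a
single-tissue profile, and undefined (reported missing) for an all-zero
profile. Both cuts are strict as worded: expressed means **more than**
20 reads in at least 2 samples, and tissue specific means tau **greater
than** 0.8. Peak-tissue ties resolve to the lexicographically first
tissue name.

## Numerical and degenerate-input choices

* All randomness flows through one seeded generator per simulation;
  identical config ⇒ byte-identical genomes, nets and tables.
* Flanks clamped at chromosome edges keep their coordinate maps; a fill
  on an unknown chromosome raises a lookup error.
* A gap with no child fill yields no candidate; an empty net yields an
  empty candidate list; an empty truth set is an error for evaluation
  (no positive instances).
* Candidate ids are assigned `<species>-retrotransposon-N` after sorting
  by (chromosome, start), so output order is stable.
* Jitter that would collapse an emulated fill is clamped to keep at
  least one base inside the gap.

## Known limitations

* Edit budgets ≥ 2 in the TSD search skip alignments whose edits are
  immediately adjacent; the default budget is 1, where the search is
  provably exhaustive.
* The caller assumes the net's gap/fill topology is trustworthy; it does
  not re-align or re-chain.
* The expressed-feature filter operates on whatever counts are supplied;
  multi-mapping and counting policy are upstream concerns.
* Self-mode versus cross-mode is a labelling distinction only — the
  detection logic is identical and the choice lives in which net file is
  supplied.
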