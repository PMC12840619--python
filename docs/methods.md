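# Methods

`sinetrace` re-implements, as a reusable and fully tested pipeline, the
comparative-genomics workflow used to study young SINE families such as the
~100 bp Platy-1 elements of New World primates: ascertain full-length
copies from repeat annotations, genotype their presence/absence across a
panel of genomes by flank alignment and gap detection, classify the
resulting patterns into a specificity taxonomy, quantify the surrounding
repeat landscape, characterize the hallmarks of target-primed reverse
transcription (TPRT), and discover young subfamilies from lineage-specific
copies. Because the real inputs are cluster-scale whole-genome assemblies,
every stage is exercised against a clade simulator with known planted
truth.

## Coordinate model and I/O

All internal intervals are 1-based inclusive (the RepeatMasker `.out`
convention); conversion to 0-based half-open happens only at the BED
boundary. Strand is kept verbatim (`+`/`C`) so `.out` round trips are
bit-exact. `C`-strand consensus coordinates are normalized on input so
`cons_begin <= cons_end` always refers to consensus positions. N bases are
allowed in genomes and never match in alignment or k-mer seeding.

## The clade simulator

The simulator is the package's statement of the data-generating process the
analysis assumes, not a fixture. An ancestral genome (uniform A/C/G/T;
default 5 Mb) is pre-seeded with background Alu/L1 consensus copies (L1s 5'
truncated at random, ~12% of the genome) and then evolved down a Newick
species tree (default: five species, `((A:1,B:1):1,(C:1,(D:1,E:1):0.5):0.5);`,
plus a 1.0-unit stem above the root that produces fixed-present loci).
Along each branch:

- the whole genome accumulates Jukes–Cantor substitutions at rate mu per
  site per unit time (default 0.025, giving ~5% divergence from root to
  leaf, ~10% between distant leaves — "moderate" divergence for flank
  alignment);
- new SINE insertions arrive as a Poisson process (default 12 per unit
  branch length, ~80 insertions over the default tree), each drawn from a
  subfamily consensus, given a geometric A-tail (mean 15 bp, with a 2%
  heavy tail of 60–120 bp mimicking occasional >100 bp tails), a
  target-site duplication of 6–20 bp copied from the insertion site, and
  mutated for the residual branch time after its (uniform) insertion time;
- insertion sites are biased (probability 0.8) to fall just 3' of a TT
  motif, emulating the endonuclease preference for T-rich nick sites, and
  with probability `nested_fraction` (default 0.10, inside the nine-to-
  fourteen-percent range typical of such surveys) the site is chosen in the
  interior of a pre-existing Alu/L1 copy, splitting the host into two
  fragments that share a run ID;
- with probability 0.25 a TTTT termination signal is written at a known
  offset 5–60 bp downstream of the 3' TSD and any closer natural TTTT is
  scrubbed, so the planted offset is the true nearest signal.

Truth records per insertion: branch of origin, presence set (exactly the
leaves below that branch), subfamily, per-carrier coordinates, TSD, A-tail
length, nesting host and termination offset. Optional injectors plant
5'-truncated decoys (to exercise the full-length filter), parallel
insertions with a non-clade presence set whose pre-integration site is
restored in non-carriers (to exercise the ILS flag), and large deletions
that remove a fixed locus plus 300 bp of flank in one leaf (the
"deletion-involved" anomaly).

Three simulator-side site constraints make the zero-divergence limit
exactly recoverable rather than almost-surely recoverable:

1. the first two TSD bases are non-A, so the A-tail/TSD boundary is
   unambiguous to any tail detector;
2. the base 5' of the TSD differs from the base following the duplicated
   site, so the planted TSD is the unique longest exact duplication;
3. insertion sites across the *whole clade* keep >= 1.3 kb of ancestral
   separation, tracked through per-lineage liftover arrays. Without this,
   independent insertions in different lineages occasionally land within
   one flank length of each other's orthologous position, and such
   near-parallel insertions are genuinely undecidable from local evidence.

What the simulator does **not** emulate: indels outside of insertions,
segmental duplication, inversion, assembly error or gaps, CpG-elevated
mutation, strand asymmetry (all planted elements are `+`), and realistic
repeat taxonomies (one Alu-like and one L1-like synthetic consensus stand
in for the real libraries; all consensus sequences are synthetic and
generated from a fixed internal seed). Tests passing on this generator
therefore demonstrate correctness of the pipeline's logic under the model's
assumptions, not robustness to every artifact of real assemblies.

## Ascertainment

A copy is full length when its consensus alignment starts within 4 bp of
the 5' end (`cons_begin <= 5` in 1-based terms) and reaches consensus
position >= 103 (configurable per subfamily). Retained copies are packaged
with up to 500 bp flanks; flanks truncated at contig edges keep their
actual lengths, and loci with a flank under 50 bp are flagged rather than
dropped — they tend to genotype `?` downstream, mirroring separate
missing-value accounting.

The annotated element interval covers the consensus-aligned element only;
the A-tail and the 3' TSD copy follow immediately after it. This keeps the
tail measurable as an extension beyond the element 3' end (a tail folded
into the annotation would be invisible to the detector by construction).

## Cross-genome genotyping

Each locus is located in a target genome by exact 14-mer seeding from both
flanks (k-mers with more than 50 genomic hits are skipped as repetitive,
analogous to overused-tile masking). Hits are projected to an implied locus
start and clustered with an 800 bp gap tolerance — wide enough that the
diagonal shift introduced by an absent element or a mid-size deletion keeps
both flanks in one window. Windows (padded 1 kb) are aligned locally under
affine scoring (+1/−1, open −4, extend −0.5).

Calls:

- **1 (present)**: both flanks align (coverage >= 0.80 each, identity >=
  0.85) and >= 80% of the element span is matched.
- **0 (absent)**: both flanks align around a net query-only gap covering
  the element span, with gap length in `[0.6 L, 1.3 (L + 100)]` for element
  span L. The accepted window scales with element length because the gap
  left by a missing element includes its A-tail and one TSD copy; for a
  ~100 bp element this is the classic "~85 bp and upward" signature.
  Spurious short matches inside a long deletion fragment the gap, so
  overlapping net gaps are summed. The first `max_a_tail + 25` bp of the
  right flank are exempt from the coverage requirement since the tail and
  TSD legitimately vanish at a pre-integration site.
- **? (missing)**: everything else, always with a machine-readable reason
  (`no_hit`, `one_flank_only`, `flank_quality`, `ambiguous_multi_hit`,
  `short_flank`, `partial_element`, `gap_outside_window`). Manual
  inspection is replaced by these reasons plus exported evidence; nothing
  is silently resolved. A split-flank rescue pass re-examines ambiguous
  calls: when both flanks anchor independently (>= 60 bp at >= 0.85
  identity, in order) and the net span between them exceeds the accepted
  gap, the call becomes `gap_outside_window` — the signature of a genomic
  deletion larger than the element, which a single affine alignment cannot
  bridge profitably.

Loci ascertained independently from several carriers are merged when their
presence evidence reciprocally overlaps the partners' source intervals
(union-find; the lexicographically smallest locus id represents the group,
making merging order-independent). The source species of every member is
forced to 1. For merged cells, a definitive 1 outranks 0 outranks `?`.

## Specificity classification

With N species, precedence is: **MV** if `?` count >= ceil((N+1)/2)
(the simple-majority generalization of "seven or more of thirteen"), then
**FP** if every non-missing code is 1, then **LS** if exactly one carrier
and all other non-missing codes are 0, else **Poly**. A Poly row gets the
named clade whose species set equals the carrier set once missing species
are excluded; otherwise `Other`, flagged ILS when the carrier set is not a
clade of the master tree (the signature of incomplete lineage sorting in
otherwise homoplasy-free presence/absence data) and flagged
deletion-involved when any contributing call failed on an oversized gap.
The per-species summary tallies categories over the loci ascertained from
that species; categories partition each species' total and Poly
sub-categories partition its Poly count.

## Landscape statistics

Distance between intervals counts the bases strictly between them (overlap
and direct adjacency are distance 0); the proximity report counts focal
elements with a neighbor of each class within 50 bp, inclusive, on raw
annotation rows with self-exclusion. Genome content merges same-class
overlaps before counting and treats classes independently. Divergence
histograms bin annotation `pct_div` by `floor(div / width)` with bp or
count weights; totals conserve masked bp per class. Nested detection uses
the fragment-run rule first — flanking rows sharing a run ID and repeat
name whose consensus coordinates continue within ±20 bp — and strict
interval containment as a fallback. All three agree exactly with
brute-force oracles kept in the test suite.

## TPRT hallmarks

The A-tail extends from the element 3' end while the trailing 10-base
window stays >= 90% A and no more than 2 consecutive non-A bases occur,
then trims trailing non-A; this tolerates the single interruptions seen in
long imperfect tails without a formal published rule. The TSD search
compares the 5' flank suffix against the sequence just after the tail —
both copies anchored, only the length (6–25 bp) free — preferring the
longest exact duplication (precise) over a longer single-mismatch one.
Cleavage grading compares the 6 bp straddling the 5' TSD start (4 upstream
+ first 2 TSD bases) to the canonical 5'-TTTT/AA-3' site: canonical /
near (1 mismatch) / none. Termination is the distance to the first exact
TTTT within 200 bp after the 3' TSD. On shuffled-flank nulls the TSD
false-positive rate is under 2% at defaults.

## Subfamily discovery, scoring and trees

Assignment aligns an element to every library consensus (same affine
scheme, score ×10 as an integer); best score wins, ties break by lower
divergence then library order. Only score differences and rankings are
meaningful; no attempt is made to reproduce any other tool's absolute
scores, whose matrices are unpublished. Divergence is the p-distance over
aligned non-gap columns ×100.

Discovery projects each copy onto the parent consensus (pairwise
anchor alignment), drops exact matches, collects candidate diagnostics
(position, derived base) carried by >= `min_count` (default 10) copies,
seeds with the candidate pair whose joint carrier set is largest, at least
`min_count`, and either above the independence expectation or perfectly
co-segregating, then greedily extends with diagnostics that keep >= 80% of
the current carrier set. Members are carriers of every selected
diagnostic; their column-majority (ties to the parent base) defines the new
consensus. Rounds repeat on the remainder; models are named `sf0`, `sf1`,
… by descending size, following the conventional numbering of
subfamily-reconstruction tools. The default `min_count=10` reflects that
~70 lineage-specific copies typically support about two daughter
subfamilies.

Neighbor joining is the classic Saitou–Nei agglomeration on p-distances
over a star alignment anchored at the longest input; negative branch
lengths are clamped to 0 and the unrooted result is written with a
trifurcating root. Bootstrap resamples alignment columns with replacement
(seeded, deterministic); supports are the percentage of replicates
containing each internal bipartition. On additive matrices NJ provably
recovers the generating topology, which the suite verifies exhaustively
against random trees, and an independent library implementation serves as
a cross-check on noisy matrices.

## Problem sizes and numerical choices

The suite runs the full stated study conditions — five species at ~5 Mb
with ~80 planted loci — once for the truth-recovery check, and scaled-down
clades (120–400 kb) everywhere else; these sizes make every stage's
behavior measurable in seconds while leaving the full-scale condition
covered. Determinism: a single seeded NumPy generator drives each
simulation; reruns are byte-identical, and the pipeline manifest records
seeds and SHA-256 checksums of every output. Degenerate inputs are
explicit: empty locus lists give empty matrices, empty libraries and
sub-3-taxon trees raise, too-few elements for discovery return an empty
result rather than an error.

## Known limitations

- Genotyping assumes the orthologous site is recoverable by exact k-mer
  seeding; heavily diverged (>~15%) or rearranged flanks drift to `?`
  rather than being chased with more sensitive seeding.
- Only `+`-strand loci are simulated; reverse-strand handling is exercised
  at the I/O level (strand C normalization, BED export) but not end to end.
- The specificity classifier treats the master tree as known; it flags
  tree-incompatible sets as ILS but cannot distinguish ILS from precise
  parallel insertion, which matches the field's practice of reporting such
  loci rather than resolving them.
- Subfamily discovery is a greedy stand-in for full co-segregation
  clustering; it recovers planted daughters reliably at >= 3% background
  divergence but makes no claim of matching any specific tool's output on
  borderline inputs.
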