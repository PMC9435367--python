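# Methods

## The system being modelled

RAG-like (RAGL) transposons are DNA transposons whose transposase genes
(RAG1L, and in complete elements RAG2L) are homologous to the vertebrate
V(D)J recombinase. Structurally an element is a pair of bipartite,
RSS-like terminal inverted repeats (TIRs) bracketing one or two
single-exon genes, flanked by a short target-site duplication (TSD)
created on insertion. For the pelagophyte AanRAGL element the TIR consists
of a 13-bp conserved block (consensus `CACACCCAAACCT`) and a 10-bp block
(`CCTCAAYAYG`), separated by a 4-bp spacer in one TIR and a 13-bp spacer
in the other (asymmetric TIRs), with 5-bp TSDs; gene content is an
upstream RAG2L and a downstream RAG1L, convergent in most RAGL elements
and tandem in AanRAGL. Transib elements carry a single RAG1-homologous
gene. `raglscan` implements the computational side of characterizing such
elements: motif modelling and scanning, structural annotation, protein
domain classification, insertion-polymorphism calling, and
identity/clustering summaries, plus a synthetic-data generator that
produces genomes with planted elements and full ground truth.

## Bipartite TIR model

A `BipartiteMotifModel` holds two position frequency matrices (PFMs), an
allowed spacer-length set, a background composition and a pseudocount.
Conventions:

* PFMs store **raw column frequencies**; the pseudocount (default 0.1 per
  base per column) is applied at scoring time, `p' = (p + c)/(1 + 4c)`.
  This keeps generation exact (sampling a one-hot column at mutation rate
  0 reproduces the consensus) while scoring remains finite on small
  training sets.
* All scores are log-odds in bits, `S = log2(p'/q)`; information content
  is relative entropy vs background (weblogo convention), so one-hot
  columns carry exactly 2 bits under a uniform background.
* The spacer is unscored (uniform model): the biology constrains spacer
  *length*, not content. A window score is `score1 + score2`.
* `N` bases score their background expectation per column.
* Degenerate consensus positions (the two `[C/T]` in the 10-bp block) are
  split 50/50; the real per-position proportions exist only graphically.

Scanning evaluates every (position, spacer, strand) combination and
reports all windows at or above a threshold; overlapping-hit resolution is
deliberately deferred to the annotator so the scanner stays a pure
function. The mouse RSS (heptamer/nonamer, 12/23-bp spacers) ships as a
preset of the same type, unvalidated against real RSS data.

### Threshold calibration

`calibrate_threshold` returns the empirical `(1 - FPR)` quantile of the
null total score over i.i.d. background windows (deterministic per seed;
a warning fires below 10/FPR samples). For the small default target the
pipeline instead uses `null_score_threshold`, an exact
dynamic-programming convolution of the per-column score distributions on
a 0.01-bit grid, with head-room for the accumulated rounding error
(raising a threshold can only lower the FPR).

The default per-window target FPR is **1e-6**. At 1e-4 a 200-kb study
genome carries ~80 false TIR hits — enough to assemble spurious inverted
pairs and fragmented calls and visibly erode precision; at 1e-6 the
expected false-hit count per study genome is below one while a
consensus-quality TIR (~36 bits) retains a >20-bit margin over the
threshold, so sensitivity at the simulated mutation rates is unaffected.

A caveat observed during development: a model built directly from a
consensus string has 21 identical columns, so its null score distribution
is a coarse lattice; quantiles of lattice distributions cannot hit an
arbitrary target FPR exactly. Models trained from real or sampled
alignments do not show this degeneracy.

### Block segmentation

`segment_blocks` recovers the block–spacer–block structure from unaligned
TIR sequences: sequences are left- and right-anchored, and block lengths
`(a, b)` maximize the summed per-column information content of the two
blocks **minus a penalty of 0.25 bits per column** subject to
`a + b <= min length`. Raw IC is nonnegative, so an unpenalized criterion
degenerately prefers maximal blocks; 0.25 bits sits far above the
finite-sample IC bias (≈ 3/(2·n·ln2) ≈ 0.04 bits at n = 50) and far below
the IC of a conserved column (≈ 1–1.7 bits), so the choice is insensitive
over a wide range.

## Synthetic data

The generator emulates the study conditions the annotator assumes:
uniform-composition background genomes (GC configurable), elements built
from the printed TIR consensus with per-position substitution at a
configurable rate (default 0 for clean studies, 0.05 for robustness
suites), 5-bp TSDs duplicated from the 5' side of the insertion point
(`out = g[:p] + element + g[p-k:p] + g[p:]`), random-codon single-exon
ORFs (RAG1L 400 codons, RAG2L 300 by default — labels, not real coding
sequence, since homology search is out of scope), and the three
architectures (convergent, tandem, single-gene). Strain pairs share a
pre-insertion ancestor; sample-only loci leave a single TSD copy at the
empty reference site, which is exactly the arithmetic the polymorphism
caller exploits. Flank reads are splinkerette-style: a TIR stub plus
genomic flank, reported on the strand leaving the element, error-free by
default with an optional substitution rate.

What the generator does **not** model: sequencing error profiles or read
qualities, transposition chemistry (excision footprints), nested or
decayed copies, repetitive backgrounds, and real coding sequence. Passing
round-trip tests therefore demonstrates the internal consistency of the
inference machinery under its stated assumptions, not performance on real
genomes — in particular, uniform backgrounds make the analytic FPR
calibration exact, which repeat-rich genomes would not.

Seeding: every generator takes an explicit seed or numpy Generator; a run
seed fans out per-locus sub-seeds via `SeedSequence.spawn`, so studies
are bit-reproducible end to end. Locus placement uses an
order-statistics construction (draw in a shrunken interval, sort, add
back separations) that cannot fail for feasible densities.

## Element annotation

`annotate_genome` composes scan → pair → TSD → ORFs → architecture.

* **Pairing**: candidates are a `+` hit followed downstream by a `-` hit
  (inverted repeats facing inward) with inner distance in the gap window
  (default 500 bp – 30 kb; the elements studied here are ~2–10 kb, and no
  size bound is otherwise established). Conflicts are resolved by
  maximum-weight non-overlapping selection (weighted interval scheduling
  on combined bit score), with ties going to more pairs, then smaller
  spans. Pure greedy score-descending selection was tried first and
  rejected: when two elements sit adjacent, the spanning pair of their
  two outermost TIRs often outscores either true pair and masks both.
* **TSD**: exact-match, largest-k-wins search over k = 2..10 (5 bp is
  what the elements actually carry, but the annotator must recover it,
  never presuppose it). Homopolymeric flanks force k_max by definition;
  elements at contig edges yield no TSD and are reported, never extended.
* **ORFs**: maximal ATG→stop frames on both strands, standard code; ORF
  length in codons counts start and stop (a 300-sense-codon insert reads
  as 302). Only stop-terminated frames are reported.
* **Labels**: gene identity comes from a pluggable labeler. The default
  ranks ORFs of ≥ 200 codons by length (longest → RAG1L, second → RAG2L),
  which is correct by construction for the synthetic study and doubles as
  a false-call filter: random ORFs of ≥ 200 codons are rare (~7e-5 per
  ATG). Real use would label via the domain classifier or config.
* **Architecture**: RAG1L+RAG2L on opposite strands transcribed toward
  each other → convergent; same strand with RAG2L upstream → tandem; a
  single RAG1L → Transib-like; labelled genes with a failed TIR pair or
  missing TSD → fragmented. Divergently transcribed pairs have no
  defined class and map to fragmented with a note. Unpaired TIR hits are
  promoted to fragmented calls when a labelled ORF lies within the gap
  window on their inward side.

## Domain classification

Seven diagnostic regions are matched as degenerate motifs by best sliding
window, scored as matched fraction (X in the protein scores 1/20). The
clan table: α11–α12 ∧ CTT1 ∧ PreRNH β1–β3 loop → RAG1L; α11–α12 ∧ CTT1 ∧
no loop → Transib subgroup I; no α11–α12 ∧ CTT2 → subgroup II; anything
else unclassified. NBD-GRP, α1 and α17 corroborate but never decide. When
both CTT profiles exceed threshold the higher score wins, exact ties
yield `none` with a note.

The shipped profiles are **synthetic placeholders** (the real diagnostic
alignments are published only as figures); they exist so the classifier
and its round trip with the protein generator are fully testable.
`min_score` defaults to 0.65: at a 10% motif substitution rate a 13-mer
still matches with probability ≈ 0.99 (needs ≥ 9/13 identities), while a
random window reaches 9/13 with probability ~1e-9.

## Polymorphism calling

`strip_stub` locates the reverse-complemented TIR terminus motif near the
element-proximal end of a flank read (score floor 10 bits; on ties the
match closest to the genomic side wins, i.e. maximal stripping) and
removes everything through it. Stripped flanks are aligned to the
reference with a seed-anchored aligner: exact 15-mer seeds vote for
(contig, diagonal) clusters; the top clusters are extended by local
affine-gap alignment (match +2, mismatch −3, gap open −5, extend −2)
within a banded reference window. One best hit is kept; near-tied hits
(≥ 95% of the best score) at distinct loci mean multi-mapping and reject
the read; identity < 90% or query coverage < 80% also reject.

Status logic is TSD arithmetic on the mapped flank junction
(`offset = right.start - left.end`):

* `offset == -k` (k = TSD length; ±0 tolerance by default) → the flanks
  share exactly one duplicated TSD copy → element in the sample only,
  reference carries the empty site ("seamless join").
* `offset == 0` → flanks abut without duplication → footprint-free
  reference locus (consistent with loss of a copy from the reference;
  reported as such, not asserted).
* `offset` within element bounds **and** the intervening reference
  interval starts and ends with the TIR terminus motif → element present
  in both genomes.
* anything else, strand/contig inconsistencies, stripping or alignment
  failures → unmapped, never aborting a batch.

## Identities, distances, trees

Global identities use Needleman–Wunsch with BLOSUM62, gap open −10,
extend −0.5; identity = identical columns / all alignment columns
(gap-inclusive denominator by default, switchable). Since the original
identity-computation protocol for the published group averages is
unstated (aligner, gap costs, core-region boundaries), these numbers are
data- and protocol-dependent; the package asserts only the robust
qualitative ordering — between-clan average below both within-clan
averages on two-clan families — which the simulation study reproduces.
Distances are p-distance or Poisson-corrected. Neighbor joining is the
textbook Saitou–Nei algorithm with the Q-criterion, deterministic
lexicographic tie-breaking, and closed-form termination at three nodes;
on additive matrices it reproduces the generating tree metric exactly
(tested against patristic distances and an independent library
implementation). The clan-partition check asks whether any tree edge
bipartitions the taxa exactly into the two labelled clans — the
desk-scale surrogate for a two-clan phylogeny; it deliberately does not
attempt maximum-likelihood inference.

## Problem sizes and determinism

Default study sizes — 200-kb genomes with 5 planted elements, 20-seed
robustness suites, 50-TIR segmentation sets, 30-protein classification
batches, 6-locus strain pairs (100–200 loci for noise sweeps) — were
chosen so every structural statistic is measured with comfortable margins
while a full study runs in seconds on one CPU. All stages are
deterministic given the run seed; reports embed the config hash.

## Known limitations

* Uniform-background calibration does not transfer to repetitive or
  compositionally biased genomes without re-calibration on a matched null.
* The TSD search is exact-match; a single substitution inside a real TSD
  hides it (the call then degrades to fragmented/footprint-free).
* The default length-based ORF labeler is a synthetic-study convenience;
  it will mislabel real loci where RAG2L exceeds RAG1L in length.
* "Fragmented" is a structural proxy (incomplete TIR/TSD evidence), not a
  statement about element age or activity.
* The domain profiles shipped are placeholders; clan calls on real
  proteins require user-supplied profiles.
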