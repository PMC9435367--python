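"""Synthetic genomes, elements, strain pairs, flank reads and proteins.

This generator emulates the study system the downstream stages assume:
genomes carrying RAGL/Transib insertions built from the AanRAGL TIR
consensus (13-bp + 10-bp conserved elements, 4/13-bp spacers), 5-bp target
site duplications (TSDs), single-exon RAG1L/RAG2L ORFs in convergent or
tandem orientation, strain pairs differing by polymorphic insertions, and
proteins carrying planted diagnostic domain motifs. A machine-readable
truth table accompanies every genome so recovery can be scored.

Coordinate/TSD conventions: 0-based half-open spans; on insertion at point
p the ``tsd_len`` bases immediately 5' of p are duplicated, so the element
ends up flanked by identical TSD copies. All generators are
bit-reproducible for a fixed seed (a run seed fans out per-locus sub-seeds
via numpy SeedSequence spawning).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._seq import AA_ALPHABET, DNA_ALPHABET, as_rng, revcomp
from .tir_model import BipartiteMotifModel, aan_ragl_model

logger = logging.getLogger(__name__)

ELEMENT_KINDS = ("RAGL_convergent", "RAGL_tandem", "Transib_single")

# Minimum ORF size (codons) the annotator searches for; specs must plant
# genes at least this long or the round-trip is unscoreable.
MIN_ORF_CODONS = 100

STOP_CODONS = ("TAA", "TAG", "TGA")
_ALL_CODONS = [a + b + c for a in DNA_ALPHABET for b in DNA_ALPHABET for c in DNA_ALPHABET]
NON_STOP_CODONS = [c for c in _ALL_CODONS if c not in STOP_CODONS]

_DEFAULT_GENES = {
    "RAGL_convergent": {"RAG2L": 300, "RAG1L": 400},
    "RAGL_tandem": {"RAG2L": 300, "RAG1L": 400},
    "Transib_single": {"RAG1L": 400},
}


@dataclass
class ElementSpec:
    """Blueprint for one synthetic RAGL/Transib element."""

    element_kind: str = "RAGL_convergent"
    tir_model: BipartiteMotifModel = field(default_factory=aan_ragl_model)
    spacer_assignment: tuple[int, int] = (4, 13)
    tsd_len: int = 5
    gene_lengths: dict | None = None  # gene name -> ORF length in codons
    per_position_mutation_rate: float = 0.0
    intergenic_len: int = 60

    def __post_init__(self):
        if self.gene_lengths is None:
            self.gene_lengths = dict(_DEFAULT_GENES[self.element_kind])
        self.validate()

    def validate(self) -> None:
        errs = []
        if self.element_kind not in ELEMENT_KINDS:
            errs.append(f"element_kind must be one of {ELEMENT_KINDS}")
        if self.tsd_len < 0:
            errs.append("tsd_len must be >= 0")
        if not 0.0 <= self.per_position_mutation_rate <= 1.0:
            errs.append("per_position_mutation_rate must be in [0, 1]")
        allowed = self.tir_model.allowed_spacers
        for sp in self.spacer_assignment:
            if sp not in allowed:
                errs.append(f"spacer {sp} not in model's allowed set {sorted(allowed)}")
        n_genes = len(self.gene_lengths)
        if self.element_kind in ("RAGL_convergent", "RAGL_tandem") and n_genes != 2:
            errs.append(f"{self.element_kind} requires exactly two genes, got {n_genes}")
        if self.element_kind == "Transib_single" and n_genes != 1:
            errs.append(f"Transib_single requires exactly one gene, got {n_genes}")
        for g, L in self.gene_lengths.items():
            if L < MIN_ORF_CODONS:
                errs.append(f"gene {g}: ORF length {L} codons below minimum {MIN_ORF_CODONS}")
        if errs:
            raise ValueError("invalid ElementSpec: " + "; ".join(errs))


@dataclass
class TruthRecord:
    """Ground truth for one planted element (post-insertion coordinates)."""

    locus_id: str
    genome_id: str
    insertion_start: int
    element_length: int
    tsd_sequence: str
    element_kind: str
    strand: str = "+"
    features: tuple = ()  # (start, end, strand, type, label) in genome coords

    @property
    def end(self) -> int:
        return self.insertion_start + self.element_length


@dataclass
class SyntheticProteinSpec:
    target_class: str  # RAG1L | Transib_I | Transib_II
    planted_motifs: tuple
    scaffold_length: int = 400
    motif_mutation_rate: float = 0.0


# N->C order in which domain motifs are laid out on the scaffold.
MOTIF_ORDER = ("NBD_GRP", "ALPHA1", "PRERNH_LOOP", "A11_A12", "ALPHA17", "CTT1", "CTT2")

# Motif sets consistent with the domain classifier's decision table.
CLASS_MOTIFS = {
    "RAG1L": ("NBD_GRP", "ALPHA1", "PRERNH_LOOP", "A11_A12", "ALPHA17", "CTT1"),
    "Transib_I": ("NBD_GRP", "ALPHA1", "A11_A12", "ALPHA17", "CTT1"),
    "Transib_II": ("NBD_GRP", "CTT2"),
}


def protein_spec_for_class(target_class: str, scaffold_length: int = 400,
                           motif_mutation_rate: float = 0.0) -> SyntheticProteinSpec:
    if target_class not in CLASS_MOTIFS:
        raise ValueError(f"unknown class {target_class!r}; expected {sorted(CLASS_MOTIFS)}")
    return SyntheticProteinSpec(target_class, CLASS_MOTIFS[target_class],
                                scaffold_length, motif_mutation_rate)


# ---------------------------------------------------------------------------
# Nucleotide-level generators
# ---------------------------------------------------------------------------

def _place_loci(rng, lo: int, hi: int, n: int, min_sep: int) -> list[int]:
    """n positions in [lo, hi) with pairwise separation >= min_sep.

    Order-statistics construction: draw n values in the interval shrunk by
    (n-1)*min_sep, sort, and add the separations back — always succeeds
    when the interval is large enough.
    """
    span = hi - lo - (n - 1) * min_sep
    if span < n:
        raise ValueError(
            f"cannot place {n} loci with separation {min_sep} in [{lo}, {hi})"
        )
    draws = np.sort(rng.integers(0, span, size=n))
    # enforce strict distinctness of the shrunken draws
    for i in range(1, n):
        if draws[i] <= draws[i - 1]:
            draws[i] = draws[i - 1] + 1
    if n and draws[-1] >= span:
        draws -= draws[-1] - span + 1
    return [int(lo + d + i * min_sep) for i, d in enumerate(draws)]


def random_genome(length: int, gc: float = 0.5, seed=0) -> str:
    """I.i.d. random genome with the given GC fraction (default uniform)."""
    rng = as_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return "".join(DNA_ALPHABET[i] for i in idx)


def _sample_from_pfm(pfm: np.ndarray, rng) -> np.ndarray:
    cum = np.cumsum(pfm, axis=1)
    u = rng.random(pfm.shape[0])
    return (u[:, None] > cum).sum(axis=1).astype(int)


def _mutate_bases(idx: np.ndarray, rate: float, rng) -> np.ndarray:
    if rate <= 0:
        return idx
    mask = rng.random(idx.shape[0]) < rate
    shift = rng.integers(1, 4, size=idx.shape[0])
    out = idx.copy()
    out[mask] = (out[mask] + shift[mask]) % 4
    return out


def sample_tir(model: BipartiteMotifModel, spacer_len: int, mutation_rate: float,
               seed=0) -> str:
    """Draw one TIR: element1 + uniform-random spacer + element2.

    Element bases are sampled from the model PFM columns, then hit by
    independent per-position substitution (to a different base) at
    ``mutation_rate``. Total length is L1 + spacer_len + L2.
    """
    if spacer_len not in model.allowed_spacers:
        raise ValueError(
            f"spacer_len {spacer_len} not allowed; allowed set is "
            f"{sorted(model.allowed_spacers)}"
        )
    if not 0.0 <= mutation_rate <= 1.0:
        raise ValueError("mutation_rate must be in [0, 1]")
    rng = as_rng(seed)
    e1 = _mutate_bases(_sample_from_pfm(model.pfm1, rng), mutation_rate, rng)
    spacer = rng.integers(0, 4, size=spacer_len)
    e2 = _mutate_bases(_sample_from_pfm(model.pfm2, rng), mutation_rate, rng)
    return "".join(DNA_ALPHABET[i] for i in np.concatenate([e1, spacer, e2]))


def make_orf(n_codons: int, rng) -> str:
    """Random single-exon ORF: ATG + (n-2) non-stop codons + TAA."""
    if n_codons < 2:
        raise ValueError("ORF needs at least start and stop codons")
    body = rng.choice(len(NON_STOP_CODONS), size=n_codons - 2)
    return "ATG" + "".join(NON_STOP_CODONS[i] for i in body) + "TAA"


def build_element(spec: ElementSpec, seed=0) -> tuple[str, list]:
    """Assemble one element: 5'TIR .. gene cassette(s) .. inverted 3'TIR.

    The 3' TIR is the reverse complement of a fresh sample from the same
    model, so the two TIRs are inverted repeats facing inward. Returns the
    sequence and a feature list of (start, end, strand, type, label) with
    0-based half-open spans relative to the element start.
    """
    rng = as_rng(seed)
    rate = spec.per_position_mutation_rate
    tir5 = sample_tir(spec.tir_model, spec.spacer_assignment[0], rate, rng)
    tir3 = revcomp(sample_tir(spec.tir_model, spec.spacer_assignment[1], rate, rng))
    ig = spec.intergenic_len

    parts: list[str] = []
    feats: list[tuple] = []
    pos = 0

    def add(seq, ftype=None, strand="+", label=""):
        nonlocal pos
        parts.append(seq)
        if ftype:
            feats.append((pos, pos + len(seq), strand, ftype, label))
        pos += len(seq)

    def spacer_dna(n):
        return "".join(DNA_ALPHABET[i] for i in rng.integers(0, 4, size=n))

    add(tir5, "terminal_inverted_repeat", "+", "TIR5")
    add(spacer_dna(ig))

    if spec.element_kind == "RAGL_convergent":
        # RAG2L on '+' upstream, RAG1L on '-' downstream: 3' ends adjacent.
        add(make_orf(spec.gene_lengths["RAG2L"], rng), "ORF", "+", "RAG2L")
        add(spacer_dna(ig))
        add(revcomp(make_orf(spec.gene_lengths["RAG1L"], rng)), "ORF", "-", "RAG1L")
    elif spec.element_kind == "RAGL_tandem":
        # RAG2L upstream of RAG1L, both transcribed in the same direction.
        add(make_orf(spec.gene_lengths["RAG2L"], rng), "ORF", "+", "RAG2L")
        add(spacer_dna(ig))
        add(make_orf(spec.gene_lengths["RAG1L"], rng), "ORF", "+", "RAG1L")
    else:  # Transib_single
        (gene, length), = spec.gene_lengths.items()
        add(make_orf(length, rng), "ORF", "+", gene)

    add(spacer_dna(ig))
    add(tir3, "terminal_inverted_repeat", "-", "TIR3")
    return "".join(parts), feats


def plant_insertions(genome: str, specs, positions="random", seed=0,
                     genome_id: str = "chr1", margin: int = 1000,
                     min_separation: int = 2000):
    """Insert elements with TSD duplication; return (genome, truth records).

    At each insertion point p the ``tsd_len`` bases immediately 5' of p are
    duplicated so that the element is flanked by identical TSD copies:
    out = g[:p] + element + g[p-k:p] + g[p:]. Truth records carry final
    (post-insertion) coordinates. Overlapping/too-close insertion points
    are rejected with the conflicting pair reported.
    """
    specs = list(specs)
    if not genome:
        raise ValueError("genome must be non-empty")
    if not specs:
        return genome, []
    rng = as_rng(seed)
    max_tsd = max(s.tsd_len for s in specs)

    if isinstance(positions, str) and positions == "random":
        lo = max(margin, max_tsd)
        hi = len(genome) - margin
        if hi <= lo:
            raise ValueError("genome too short for the requested margin")
        positions = _place_loci(rng, lo, hi, len(specs), min_separation)
    positions = [int(p) for p in positions]
    if len(positions) != len(specs):
        raise ValueError("positions and specs must have equal length")

    order = sorted(range(len(positions)), key=lambda i: positions[i])
    for a, b in zip(order, order[1:]):
        gap = positions[b] - positions[a]
        if gap < max(specs[a].tsd_len, 1):
            raise ValueError(
                f"overlapping insertions: positions {positions[a]} and {positions[b]} "
                f"conflict (separation {gap} < {max(specs[a].tsd_len, 1)})"
            )
    for i in order:
        if positions[i] < specs[i].tsd_len or positions[i] > len(genome):
            raise ValueError(f"insertion point {positions[i]} out of range for tsd_len "
                             f"{specs[i].tsd_len}")

    locus_seeds = np.random.SeedSequence(int(rng.integers(0, 2**31))).spawn(len(specs))

    out_parts = []
    truths = []
    prev = 0
    offset = 0
    for rank, i in enumerate(order):
        p = positions[i]
        spec = specs[i]
        element, feats = build_element(spec, np.random.default_rng(locus_seeds[rank]))
        k = spec.tsd_len
        tsd = genome[p - k:p] if k > 0 else ""
        out_parts.append(genome[prev:p])
        start = p + offset
        out_parts.append(element)
        out_parts.append(tsd)
        prev = p
        shifted = tuple((s + start, e + start, st, ft, lb) for (s, e, st, ft, lb) in feats)
        truths.append(TruthRecord(
            locus_id=f"L{rank + 1:03d}", genome_id=genome_id, insertion_start=start,
            element_length=len(element), tsd_sequence=tsd,
            element_kind=spec.element_kind, strand="+", features=shifted,
        ))
        offset += len(element) + k
    out_parts.append(genome[prev:])
    return "".join(out_parts), truths


@dataclass
class StrainLocus:
    """Truth for one locus of a simulated strain pair."""

    locus_id: str
    status: str  # shared | sample_only
    base_position: int
    ref_start: int           # element start (shared) or empty-site point (sample_only)
    sample_start: int
    element_length: int
    tsd_sequence: str
    element_kind: str


def simulate_strain_pair(reference: str, shared_loci: int, sample_only_loci: int,
                         spec: ElementSpec, seed=0, margin: int = 1000,
                         min_separation: int = 2000):
    """Plant elements so that some loci are shared and some sample-only.

    The input sequence is the pre-insertion ancestor. Shared loci carry the
    element in both output genomes; sample-only loci carry it only in the
    sample genome, the reference keeping a single TSD copy at the empty
    site. Returns (reference_genome, sample_genome, truth_table).
    """
    if shared_loci < 0 or sample_only_loci < 0:
        raise ValueError("locus counts must be >= 0")
    n = shared_loci + sample_only_loci
    if n == 0:
        return reference, reference, []
    rng = as_rng(seed)
    lo = max(margin, spec.tsd_len)
    hi = len(reference) - margin
    positions = _place_loci(rng, lo, hi, n, min_separation)
    statuses = ["shared"] * shared_loci + ["sample_only"] * sample_only_loci
    rng.shuffle(statuses)

    seed_for_plant = int(rng.integers(0, 2**31))
    order = sorted(range(n), key=lambda i: positions[i])
    sample_genome, sample_truth = plant_insertions(
        reference, [spec] * n, [positions[i] for i in order],
        seed=seed_for_plant, genome_id="sample",
    )
    # Re-plant only shared loci into the reference with the same per-locus
    # element sequences: replay plant_insertions' sub-seed fan-out.
    locus_seeds = np.random.SeedSequence(
        int(np.random.default_rng(seed_for_plant).integers(0, 2**31))
    ).spawn(n)

    ref_parts = []
    prev = 0
    offset = 0
    ref_starts = {}
    for j, i in enumerate(order):
        p = positions[i]
        if statuses[i] == "shared":
            element, _ = build_element(spec, np.random.default_rng(locus_seeds[j]))
            k = spec.tsd_len
            ref_parts.append(reference[prev:p])
            ref_starts[j] = p + offset
            ref_parts.append(element)
            ref_parts.append(reference[p - k:p] if k else "")
            prev = p
            offset += len(element) + k
        else:
            ref_starts[j] = p + offset  # empty-site junction point in ref coords
    ref_parts.append(reference[prev:])
    ref_genome = "".join(ref_parts)

    truth = []
    for j, i in enumerate(order):
        rec = sample_truth[j]
        truth.append(StrainLocus(
            locus_id=rec.locus_id, status=statuses[i], base_position=positions[i],
            ref_start=ref_starts[j], sample_start=rec.insertion_start,
            element_length=rec.element_length, tsd_sequence=rec.tsd_sequence,
            element_kind=rec.element_kind,
        ))
    return ref_genome, sample_genome, truth


@dataclass
class FlankPair:
    """Paired outward-facing flank reads of one element locus."""

    locus_id: str
    read5: str | None
    read3: str | None
    stub_len: int


def synth_flank_reads(sample_genome: str, truth, read_len: int = 300,
                      tir_stub_len: int = 30, substitution_rate: float = 0.0,
                      seed=0) -> list[FlankPair]:
    """Emit splinkerette-style flank reads for each planted locus.

    The 5' read is the last ``tir_stub_len`` bases of the 5' TIR plus the
    upstream genomic flank, reported on the strand leaving the element
    (i.e. the reverse complement of the genome top strand); the 3' read is
    symmetric on the top strand. Each read contains the adjacent TSD copy.
    Loci too close to a contig end for a full read are skipped with a
    warning.
    """
    if read_len <= tir_stub_len:
        raise ValueError("read_len must exceed tir_stub_len")
    rng = as_rng(seed)

    def maybe_mutate(s):
        if substitution_rate <= 0 or s is None:
            return s
        chars = list(s)
        for i in range(len(chars)):
            if rng.random() < substitution_rate:
                alt = [b for b in DNA_ALPHABET if b != chars[i]]
                chars[i] = alt[int(rng.integers(0, 3))]
        return "".join(chars)

    flank = read_len - tir_stub_len
    pairs = []
    for rec in truth:
        s = rec.insertion_start if hasattr(rec, "insertion_start") else rec.sample_start
        e = s + rec.element_length
        read5 = read3 = None
        if s - flank >= 0:
            read5 = revcomp(sample_genome[s - flank:s + tir_stub_len])
        else:
            logger.warning("locus %s: 5' read skipped (too close to contig start)",
                           rec.locus_id)
        if e + flank <= len(sample_genome):
            read3 = sample_genome[e - tir_stub_len:e + flank]
        else:
            logger.warning("locus %s: 3' read skipped (too close to contig end)",
                           rec.locus_id)
        pairs.append(FlankPair(rec.locus_id, maybe_mutate(read5), maybe_mutate(read3),
                               tir_stub_len))
    return pairs


# ---------------------------------------------------------------------------
# Protein-level generators
# ---------------------------------------------------------------------------

def synth_protein(spec: SyntheticProteinSpec, library: dict, seed=0) -> str:
    """Random scaffold with domain motifs planted in N->C order.

    ``library`` maps profile ids to objects with a ``motif`` attribute (or
    plain strings). Motifs are placed non-overlapping, evenly spaced, in
    the canonical domain order; each motif residue is substituted with
    probability ``motif_mutation_rate``.
    """
    rng = as_rng(seed)
    for m in spec.planted_motifs:
        if m not in library:
            raise ValueError(f"planted motif {m!r} not in profile library")
    motifs = sorted(spec.planted_motifs, key=MOTIF_ORDER.index)
    motif_seqs = [
        library[m].motif if hasattr(library[m], "motif") else str(library[m])
        for m in motifs
    ]
    total = sum(len(s) for s in motif_seqs)
    min_len = total + 8 * (len(motifs) + 1)
    if spec.scaffold_length < min_len:
        raise ValueError(
            f"scaffold_length {spec.scaffold_length} too short for "
            f"{len(motifs)} motifs; required minimum is {min_len}"
        )
    scaffold = [AA_ALPHABET[i] for i in rng.integers(0, 20, size=spec.scaffold_length)]
    gap = (spec.scaffold_length - total) // (len(motifs) + 1) if motifs else 0
    pos = gap
    for mseq in motif_seqs:
        chars = list(mseq)
        for i in range(len(chars)):
            if rng.random() < spec.motif_mutation_rate:
                alt = [a for a in AA_ALPHABET if a != chars[i]]
                chars[i] = alt[int(rng.integers(0, 19))]
        scaffold[pos:pos + len(chars)] = chars
        pos += len(chars) + gap
    return "".join(scaffold)


def mutate_protein(seq: str, rate: float, rng) -> str:
    chars = list(seq)
    for i in range(len(chars)):
        if rng.random() < rate:
            alt = [a for a in AA_ALPHABET if a != chars[i]]
            chars[i] = alt[int(rng.integers(0, 19))]
    return "".join(chars)


def evolve_protein_family(ancestor: str, n: int, divergence: float, seed=0) -> list[str]:
    """n independent descendants of an ancestor at a per-site divergence."""
    rng = as_rng(seed)
    return [mutate_protein(ancestor, divergence, rng) for _ in range(n)]


def random_protein(length: int, seed=0) -> str:
    rng = as_rng(seed)
    return "".join(AA_ALPHABET[i] for i in rng.integers(0, 20, size=length))
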