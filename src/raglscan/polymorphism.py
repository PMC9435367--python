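"""Insertion-polymorphism calling from paired element-flanking sequences.

Given the two outward-facing flanking sequences of a transposon locus in a
sample strain (splinkerette-style products: a TIR stub followed by genomic
flank), decide the insertion's status relative to a reference genome:

* ``sample_only_empty_ref`` — the two stripped flanks map adjacently in
  the reference and their junction overlaps by exactly the TSD length with
  identical bases ("seamlessly joined"): the element is present in the
  sample but the reference carries the empty site with a single TSD copy.
* ``shared_present_in_ref`` — the flanks map on either side of a reference
  interval whose ends match the TIR model: the element is in both genomes.
* ``footprint_free_ref`` — the flanks map adjacently with no duplicated
  overlap (flanks align without TIRs and TSDs), consistent with loss of a
  copy from the reference.
* ``unmapped`` — anything else (different contigs, multi-mapping, no
  alignment, inconsistent strands).

Target-site-duplication arithmetic drives the "seamless join" call: the
empty site carries one TSD copy while each flank read carries one, so the
two mapped flanks overlap by exactly the TSD length.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._seq import revcomp
from .tir_model import BipartiteMotifModel, log_odds, window_scores, _scoring_with_n
from ._seq import encode

logger = logging.getLogger(__name__)

STATUSES = ("sample_only_empty_ref", "shared_present_in_ref",
            "footprint_free_ref", "unmapped")


class StripError(ValueError):
    """Raised when a read has no usable TIR stub."""


@dataclass
class AlignmentHit:
    contig: str
    start: int
    end: int
    strand: str
    identity: float  # percent
    score: float
    coverage: float  # aligned query fraction
    note: str = ""


@dataclass
class PresenceCall:
    locus_id: str
    status: str
    ref_contig: str | None = None
    flank5_span: tuple | None = None
    flank3_span: tuple | None = None
    junction_offset: int | None = None  # signed bp between mapped flanks
    tsd_at_junction: str | None = None
    note: str = ""


def _rc_matrix(S: np.ndarray) -> np.ndarray:
    """Score matrix of the reverse complement motif (rows and bases flipped)."""
    return S[::-1, [3, 2, 1, 0]]


def strip_stub(read: str, model: BipartiteMotifModel, floor_bits: float = 10.0,
               search_extra: int = 40):
    """Remove the TIR stub from the element-proximal end of a flank read.

    Flank reads start inside the element and run outward, so they begin
    with the reverse complement of the TIR terminus (the outermost
    conserved element). The best-scoring match of that motif within the
    first L1 + ``search_extra`` bases marks the element boundary; the
    remainder is the genomic portion. Returns (genomic_portion, score).
    """
    L1 = model.L1
    if len(read) <= L1:
        raise StripError("read shorter than the minimal stub window")
    S1 = log_odds(model.pfm1, model.background, model.pseudocount)
    S = _scoring_with_n(_rc_matrix(S1), model.background)
    window = read[: min(len(read), L1 + search_extra)].upper()
    scores = window_scores(encode(window), S)
    if scores.size == 0:
        raise StripError("read shorter than the minimal stub window")
    best = float(scores.max())
    if best < floor_bits:
        raise StripError(f"no TIR stub above the score floor ({best:.2f} < {floor_bits} bits)")
    # On ties keep the match closest to the genomic side (maximal stripping).
    pos = int(np.flatnonzero(scores >= best - 1e-9)[-1])
    genomic = read[pos + L1:]
    if not genomic:
        raise StripError("read is all stub (no genomic portion)")
    return genomic, best


class FlankAligner:
    """Seed-anchored local aligner against a reference genome.

    Exact k-mer seeds (default k=15) anchor candidate diagonals; each
    candidate is extended by an affine-gap local alignment (match +2,
    mismatch -3, gap open -5, gap extend -2) restricted to a banded window
    of the reference around the seed diagonal. The single best hit is
    returned; near-tied hits at distinct loci are treated as multi-mapping
    and rejected.
    """

    def __init__(self, reference: dict, seed_k: int = 15, match: float = 2.0,
                 mismatch: float = -3.0, gap_open: float = -5.0,
                 gap_extend: float = -2.0, band: int = 50,
                 min_identity: float = 90.0, min_coverage: float = 0.8):
        from Bio import Align

        if isinstance(reference, str):
            reference = {"ref": reference}
        self.reference = {k: v.upper() for k, v in reference.items()}
        self.seed_k = seed_k
        self.band = band
        self.min_identity = min_identity
        self.min_coverage = min_coverage
        self.aligner = Align.PairwiseAligner()
        self.aligner.mode = "local"
        self.aligner.match_score = match
        self.aligner.mismatch_score = mismatch
        self.aligner.open_gap_score = gap_open
        self.aligner.extend_gap_score = gap_extend
        self.index: dict[str, list] = {}
        for contig, seq in self.reference.items():
            for i in range(len(seq) - seed_k + 1):
                self.index.setdefault(seq[i:i + seed_k], []).append((contig, i))

    def _candidates(self, q: str):
        """Cluster seed hits into (contig, diagonal) candidates."""
        k = self.seed_k
        clusters: dict[tuple, int] = {}
        step = max(1, k // 3)
        for i in range(0, max(1, len(q) - k + 1), step):
            for contig, pos in self.index.get(q[i:i + k], ()):
                diag = pos - i
                key = (contig, diag // self.band)
                clusters[key] = clusters.get(key, 0) + 1
        ranked = sorted(clusters.items(), key=lambda kv: (-kv[1], kv[0]))
        return [k for k, _ in ranked[:8]]

    def _extend(self, q: str, contig: str, diag_bucket: int):
        seq = self.reference[contig]
        diag = diag_bucket * self.band
        lo = max(0, diag - self.band)
        hi = min(len(seq), diag + len(q) + 2 * self.band)
        window = seq[lo:hi]
        if not window:
            return None
        alns = self.aligner.align(window, q)
        if len(alns) == 0:
            return None
        aln = alns[0]
        t_blocks, q_blocks = aln.aligned
        if len(t_blocks) == 0:
            return None
        counts = aln.counts()
        columns = counts.identities + counts.mismatches + counts.gaps
        identity = 100.0 * counts.identities / columns if columns else 0.0
        q_aligned = int(sum(b - a for a, b in q_blocks))
        coverage = q_aligned / len(q)
        start = lo + int(t_blocks[0][0])
        end = lo + int(t_blocks[-1][1])
        return (float(aln.score), contig, start, end, identity, coverage)

    def align(self, query: str) -> AlignmentHit | None:
        """Best local alignment of the query (either strand) or None."""
        if not query:
            raise ValueError("empty query")
        query = query.upper()
        results = []
        for strand in "+-":
            q = query if strand == "+" else revcomp(query)
            for contig, bucket in self._candidates(q):
                res = self._extend(q, contig, bucket)
                if res is not None:
                    results.append((res, strand))
        if not results:
            return None
        results.sort(key=lambda r: (-r[0][0], r[0][1], r[0][2], r[1]))
        (score, contig, start, end, ident, cov), strand = results[0]
        # Multi-mapping: a near-tied hit at a distinct locus.
        for (s2, c2, st2, en2, _, _), _str2 in results[1:]:
            distinct = c2 != contig or st2 >= end + len(query) or en2 <= start - len(query)
            if distinct and s2 >= 0.95 * score:
                return AlignmentHit(contig, start, end, strand, ident, score, cov,
                                    note="multi_hit")
        if ident < self.min_identity or cov < self.min_coverage:
            return AlignmentHit(contig, start, end, strand, ident, score, cov,
                                note="low_identity_or_coverage")
        return AlignmentHit(contig, start, end, strand, ident, score, cov)


def align_flank(query: str, reference, **kwargs) -> AlignmentHit | None:
    """Convenience one-shot wrapper around FlankAligner."""
    return FlankAligner(reference, **kwargs).align(query)


def _interval_has_tir_ends(interval: str, model: BipartiteMotifModel,
                           floor_bits: float, slop: int = 5) -> bool:
    """Does a reference interval start and end with the TIR terminal motif?"""
    if len(interval) < 2 * model.L1:
        return False
    S1 = _scoring_with_n(log_odds(model.pfm1, model.background, model.pseudocount),
                         model.background)
    S1rc = _scoring_with_n(_rc_matrix(log_odds(model.pfm1, model.background,
                                               model.pseudocount)), model.background)
    head = interval[: model.L1 + slop]
    tail = interval[-(model.L1 + slop):]
    s_head = window_scores(encode(head), S1)
    s_tail = window_scores(encode(tail), S1rc)
    return (s_head.size > 0 and float(s_head.max()) >= floor_bits
            and s_tail.size > 0 and float(s_tail.max()) >= floor_bits)


@dataclass
class CallerConfig:
    tsd_k: int = 5
    junction_tolerance: int = 0
    stub_floor_bits: float = 10.0
    min_element_len: int = 100
    max_element_len: int = 30_000


def call_locus(pair, reference, model: BipartiteMotifModel,
               aligner: FlankAligner | None = None,
               config: CallerConfig | None = None) -> PresenceCall:
    """Decide one locus's insertion status relative to the reference."""
    cfg = config or CallerConfig()
    if isinstance(reference, str):
        reference = {"ref": reference}
    if aligner is None:
        aligner = FlankAligner(reference)
    if pair.read5 is None or pair.read3 is None:
        return PresenceCall(pair.locus_id, "unmapped", note="missing_read")
    try:
        g5, _ = strip_stub(pair.read5, model, cfg.stub_floor_bits)
        g3, _ = strip_stub(pair.read3, model, cfg.stub_floor_bits)
    except StripError as e:
        return PresenceCall(pair.locus_id, "unmapped", note=f"strip_failed:{e}")
    # read5 runs outward on the bottom strand; flip it to top-strand sense.
    h5 = aligner.align(revcomp(g5))
    h3 = aligner.align(g3)
    if h5 is None or h3 is None:
        return PresenceCall(pair.locus_id, "unmapped", note="flank_unaligned")
    if h5.note or h3.note:
        return PresenceCall(pair.locus_id, "unmapped", note=(h5.note or h3.note))
    if h5.contig != h3.contig:
        return PresenceCall(pair.locus_id, "unmapped",
                            note=f"flanks_on_different_contigs:{h5.contig},{h3.contig}")
    if h5.strand != h3.strand:
        return PresenceCall(pair.locus_id, "unmapped", note="inconsistent_strands")
    left, right = (h5, h3) if h5.strand == "+" else (h3, h5)
    offset = right.start - left.end
    seq = reference[h5.contig] if isinstance(reference, dict) else reference
    base = PresenceCall(pair.locus_id, "unmapped", ref_contig=h5.contig,
                        flank5_span=(h5.start, h5.end), flank3_span=(h3.start, h3.end),
                        junction_offset=offset)
    tol = cfg.junction_tolerance
    if abs(offset + cfg.tsd_k) <= tol or offset == -cfg.tsd_k:
        base.status = "sample_only_empty_ref"
        base.tsd_at_junction = seq[right.start:left.end]
        return base
    if abs(offset) <= tol or offset == 0:
        base.status = "footprint_free_ref"
        return base
    if cfg.min_element_len <= offset <= cfg.max_element_len:
        interval = seq[left.end:right.start]
        if _interval_has_tir_ends(interval, model, cfg.stub_floor_bits):
            base.status = "shared_present_in_ref"
            return base
        base.note = "intervening_interval_without_tir_ends"
        return base
    base.note = f"unexpected_junction_offset:{offset}"
    return base


def call_all(pairs, reference, model: BipartiteMotifModel,
             config: CallerConfig | None = None):
    """Call every pair; per-pair failures become unmapped, never aborting.

    Returns (DataFrame, summary dict of status counts).
    """
    import pandas as pd

    cfg = config or CallerConfig()
    if isinstance(reference, str):
        reference = {"ref": reference}
    aligner = FlankAligner(reference)
    calls = []
    for pair in sorted(pairs, key=lambda p: p.locus_id):
        try:
            calls.append(call_locus(pair, reference, model, aligner, cfg))
        except Exception as e:  # pragma: no cover - defensive batch behaviour
            logger.warning("locus %s failed: %s", pair.locus_id, e)
            calls.append(PresenceCall(pair.locus_id, "unmapped", note=f"error:{e}"))
    rows = [{
        "locus_id": c.locus_id, "status": c.status,
        "ref_contig": c.ref_contig or "",
        "flank5_start": c.flank5_span[0] if c.flank5_span else -1,
        "flank5_end": c.flank5_span[1] if c.flank5_span else -1,
        "flank3_start": c.flank3_span[0] if c.flank3_span else -1,
        "flank3_end": c.flank3_span[1] if c.flank3_span else -1,
        "junction_offset": c.junction_offset if c.junction_offset is not None else 0,
        "tsd_at_junction": c.tsd_at_junction or "",
        "note": c.note,
    } for c in calls]
    df = pd.DataFrame(rows, columns=[
        "locus_id", "status", "ref_contig", "flank5_start", "flank5_end",
        "flank3_start", "flank3_end", "junction_offset", "tsd_at_junction",
        "note"])
    summary = {s: 0 for s in STATUSES}
    for c in calls:
        summary[c.status] += 1
    return df, summary


def calls_to_bed(df) -> str:
    """BED of inferred insertion sites in the reference (sample-only loci)."""
    lines = []
    for _, r in df.iterrows():
        if r["status"] != "sample_only_empty_ref":
            continue
        # junction: the empty-site TSD copy in the reference
        start = r["flank3_start"]
        end = start + len(r["tsd_at_junction"])
        lines.append(f"{r['ref_contig']}\t{start}\t{end}\t{r['locus_id']}")
    return "\n".join(lines) + ("\n" if lines else "")
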