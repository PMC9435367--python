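"""Diagnostic protein-domain matching and RAG1L/Transib clan assignment.

The classifier implements the domain decision table that separates RAG1L
proteins from the two Transib subgroups:

* RAG1L:      α11–α12 present  ∧ CTT1 ∧ PreRNH β1–β3 loop present
* Transib I:  α11–α12 present  ∧ CTT1 ∧ loop absent
* Transib II: α11–α12 absent   ∧ CTT2
* anything else -> unclassified

NBD-GRP, α1 and α17 are recorded as corroborating flags only (the NBD is
expected in all three classes; partial α1/α17 are expected absent in
Subgroup II).

Profiles are small degenerate motifs scored by matched fraction over a
sliding window. The shipped default library contains *synthetic
placeholder* motifs so that the pipeline is testable end to end; real use
requires profiles built from the user's own alignments of the diagnostic
regions.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from ._seq import AA_ALPHABET

PROFILE_IDS = ("NBD_GRP", "A11_A12", "CTT1", "CTT2", "PRERNH_LOOP", "ALPHA1", "ALPHA17")
CLANS = ("RAG1L", "Transib_I", "Transib_II", "unclassified")

_X_SCORE = 1.0 / 20.0  # an X position scores its background match expectation


@dataclass(frozen=True)
class DomainProfile:
    profile_id: str
    motif: str
    min_score: float = 0.65  # matched fraction threshold

    def __post_init__(self):
        if not self.motif:
            raise ValueError("profile motif must be non-empty")
        if not (self.min_score == self.min_score and abs(self.min_score) != float("inf")):
            raise ValueError("min_score must be finite")


@dataclass(frozen=True)
class DomainMatch:
    present: bool
    position: int  # best window start
    score: float


@dataclass
class ProteinClassification:
    sequence_id: str
    flags: dict  # profile_id -> DomainMatch
    ctt_type: str  # CTT1 | CTT2 | none
    clan: str
    notes: list = field(default_factory=list)


def match_domain(protein: str, profile: DomainProfile) -> DomainMatch:
    """Best sliding-window match of a motif; present iff score >= min_score.

    Score is the matched fraction of motif positions; an 'X' in the
    protein contributes the background expectation 1/20.
    """
    if not protein:
        raise ValueError("empty protein sequence")
    protein = protein.upper()
    m = profile.motif.upper()
    L = len(m)
    if len(protein) < L:
        return DomainMatch(False, 0, 0.0)
    best_score, best_pos = -1.0, 0
    for i in range(len(protein) - L + 1):
        window = protein[i:i + L]
        s = 0.0
        for a, b in zip(window, m):
            if a == "X":
                s += _X_SCORE
            elif a == b:
                s += 1.0
        s /= L
        if s > best_score:
            best_score, best_pos = s, i
    return DomainMatch(best_score >= profile.min_score, best_pos, best_score)


def _decide_clan(a11: bool, ctt_type: str, loop: bool):
    if a11 and ctt_type == "CTT1" and loop:
        return "RAG1L", []
    if a11 and ctt_type == "CTT1" and not loop:
        return "Transib_I", []
    if not a11 and ctt_type == "CTT2":
        return "Transib_II", []
    notes = []
    if a11 and ctt_type == "CTT2":
        notes.append("contradictory_evidence:a11_with_CTT2")
    return "unclassified", notes


def classify_protein(protein: str, library: dict,
                     sequence_id: str = "seq") -> ProteinClassification:
    """Apply all seven profiles and the clan decision table."""
    missing = [p for p in PROFILE_IDS if p not in library]
    if missing:
        raise ValueError(f"profile library missing {missing}")
    flags = {pid: match_domain(protein, library[pid]) for pid in PROFILE_IDS}

    notes = []
    c1, c2 = flags["CTT1"], flags["CTT2"]
    if c1.present and c2.present:
        if c1.score > c2.score:
            ctt_type = "CTT1"
        elif c2.score > c1.score:
            ctt_type = "CTT2"
        else:
            ctt_type = "none"
            notes.append("ctt_tie")
    elif c1.present:
        ctt_type = "CTT1"
    elif c2.present:
        ctt_type = "CTT2"
    else:
        ctt_type = "none"

    clan, clan_notes = _decide_clan(flags["A11_A12"].present, ctt_type,
                                    flags["PRERNH_LOOP"].present)
    notes.extend(clan_notes)
    # Corroborating-only flags: noted when they contradict the clan.
    if clan in ("RAG1L", "Transib_I", "Transib_II") and not flags["NBD_GRP"].present:
        notes.append("NBD_GRP_absent")
    if clan == "Transib_II" and (flags["ALPHA1"].present or flags["ALPHA17"].present):
        notes.append("alpha1_or_alpha17_present_in_subgroup_II")
    return ProteinClassification(sequence_id, flags, ctt_type, clan, notes)


def classify_batch(records, library):
    """Classify many proteins; returns (DataFrame, per-clan summary dict).

    ``records`` is a dict id -> sequence, an iterable of (id, seq) pairs,
    or a FASTA path. Duplicate ids raise an error listing them.
    """
    import collections
    import os

    import pandas as pd

    if isinstance(records, (str, os.PathLike)):
        from .io import read_fasta
        pairs = list(read_fasta(records).items())
    elif isinstance(records, dict):
        pairs = list(records.items())
    else:
        pairs = list(records)
    ids = [i for i, _ in pairs]
    dups = [i for i, n in collections.Counter(ids).items() if n > 1]
    if dups:
        raise ValueError(f"duplicate sequence ids: {sorted(dups)}")

    rows = []
    for sid, seq in pairs:
        cls = classify_protein(seq, library, sid)
        row = {"sequence_id": sid, "clan": cls.clan, "ctt_type": cls.ctt_type,
               "notes": ",".join(cls.notes)}
        for pid in PROFILE_IDS:
            m = cls.flags[pid]
            row[f"{pid}_present"] = m.present
            row[f"{pid}_score"] = round(m.score, 4)
            row[f"{pid}_pos"] = m.position
        rows.append(row)
    df = pd.DataFrame(rows)
    summary = dict.fromkeys(CLANS, 0)
    for r in rows:
        summary[r["clan"]] += 1
    return df, summary


def make_default_library(min_score: float = 0.65) -> dict:
    """Synthetic placeholder profiles for the seven diagnostic regions.

    The motif strings are arbitrary distinctive 13-mers (the real
    diagnostic alignments are not machine-readable); they make the
    classifier and the round-trip with the protein generator fully
    testable. Substitute your own profiles for real data.
    """
    motifs = {
        "NBD_GRP": "SWKEGRPNVLHDM",
        "ALPHA1": "MDRELWAKYTQHS",
        "PRERNH_LOOP": "GQYDSWHTKRPLE",
        "A11_A12": "HEKWLRDQAYTFG",
        "ALPHA17": "FNWQHKEDRGYLT",
        "CTT1": "WYQKHDGLRTMFE",
        "CTT2": "PHRFWEDNKYGAV",
    }
    return {pid: DomainProfile(pid, m, min_score) for pid, m in motifs.items()}


def write_profiles(library: dict, path) -> None:
    with open(path, "w") as fh:
        fh.write("profile_id\tmotif\tmin_score\n")
        for pid in sorted(library):
            p = library[pid]
            fh.write(f"{p.profile_id}\t{p.motif}\t{p.min_score}\n")


def read_profiles(path) -> dict:
    library = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("profile_id"):
            raise ValueError(f"{path}: expected a profile_id/motif/min_score header")
        for ln in fh:
            if not ln.strip():
                continue
            pid, motif, thr = ln.rstrip("\n").split("\t")
            library[pid] = DomainProfile(pid, motif, float(thr))
    return library
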