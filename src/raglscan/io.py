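"""FASTA / TSV / GFF3 plumbing shared by the CLI and pipeline."""
from __future__ import annotations

import os


def read_fasta(path) -> dict:
    """Read a FASTA file into an ordered dict id -> sequence."""
    from Bio import SeqIO

    if not os.path.exists(path):
        raise IOError(f"cannot read FASTA file {path!r}: no such file")
    out = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(records: dict, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def truth_to_tsv(truths, path=None) -> str:
    """Truth table as TSV (locus_id, genome_id, start, end, kind, tsd, strand)."""
    lines = ["locus_id\tgenome_id\tstart\tend\telement_kind\ttsd\tstrand"]
    for t in truths:
        lines.append("\t".join([
            t.locus_id, t.genome_id, str(t.insertion_start),
            str(t.insertion_start + t.element_length), t.element_kind,
            t.tsd_sequence, t.strand,
        ]))
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def truth_to_gff3(truths, path=None) -> str:
    """Internal element annotations (ground truth) as GFF3."""
    lines = ["##gff-version 3"]
    for t in truths:
        eid = t.locus_id
        lines.append("\t".join([
            t.genome_id, "raglscan_sim", "mobile_genetic_element",
            str(t.insertion_start + 1), str(t.insertion_start + t.element_length),
            ".", t.strand, ".", f"ID={eid};element_kind={t.element_kind};tsd={t.tsd_sequence}",
        ]))
        for (s, e, strand, ftype, label) in t.features:
            lines.append("\t".join([
                t.genome_id, "raglscan_sim", ftype, str(s + 1), str(e), ".",
                strand, ".", f"Parent={eid};label={label}",
            ]))
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def flank_pairs_to_fasta(pairs, path) -> None:
    """Flank pairs as FASTA with the locusID/5, locusID/3 naming convention."""
    with open(path, "w") as fh:
        for p in pairs:
            if p.read5 is not None:
                fh.write(f">{p.locus_id}/5 stub={p.stub_len}\n{p.read5}\n")
            if p.read3 is not None:
                fh.write(f">{p.locus_id}/3 stub={p.stub_len}\n{p.read3}\n")


def read_flank_pairs(path, stub_len: int):
    """Parse locusID/5, locusID/3 FASTA into FlankPair objects."""
    from Bio import SeqIO

    from .simulate import FlankPair

    reads: dict[str, dict[str, str]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if "/" not in rec.id:
            raise ValueError(f"flank read id {rec.id!r} lacks the /5 or /3 suffix")
        locus, side = rec.id.rsplit("/", 1)
        reads.setdefault(locus, {})[side] = str(rec.seq).upper()
    return [FlankPair(locus, d.get("5"), d.get("3"), stub_len)
            for locus, d in sorted(reads.items())]
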