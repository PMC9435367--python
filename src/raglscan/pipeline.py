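"""End-to-end simulation study: generate -> scan -> annotate -> classify ->
call polymorphisms -> summarize, with config validation and a reproducible
report.

Stages communicate via standard-format files (FASTA, GFF3, TSV) so any
stage can be rerun standalone; the whole study is deterministic for a
fixed seed (a single run seed fans out per-stage sub-seeds), and every
output header records the config hash.
"""
from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np

from . import __version__
from ._seq import revcomp
from .annotate import AnnotatorConfig, annotate_genome, calls_to_gff3, calls_to_table, \
    match_calls_to_truth, recall_precision
from .domains import classify_batch, make_default_library
from .evostats import (clan_partition_check, distance_matrix,
                       group_identity_matrix, nj_tree, pairwise_identity_matrix,
                       summary_to_tsv)
from .io import flank_pairs_to_fasta, truth_to_gff3, truth_to_tsv, write_fasta
from .polymorphism import CallerConfig, call_all
from .simulate import (ElementSpec, evolve_protein_family, plant_insertions,
                       protein_spec_for_class, random_genome, random_protein,
                       simulate_strain_pair, synth_flank_reads, synth_protein)
from .tir_model import aan_ragl_model

logger = logging.getLogger(__name__)

_SCHEMA = {
    "seed": int,
    "genome": {"length": int, "gc": float},
    "elements": {"count": int, "kind": str, "spacer_assignment": list,
                 "tsd_len": int, "mutation_rate": float, "gene_lengths": dict},
    "annotator": {"target_fpr": float, "k_min": int, "k_max": int,
                  "min_gap": int, "max_gap": int, "min_orf_codons": int},
    "strain_pair": {"shared": int, "sample_only": int},
    "flank_reads": {"read_len": int, "tir_stub_len": int},
    "proteins": {"per_class": int, "scaffold_length": int, "motif_mutation_rate": float},
    "identity_study": {"family_size": int, "within_divergence": float,
                       "between_divergence": float},
    "outdir": str,
}

DEFAULT_CONFIG = {
    "seed": 42,
    "genome": {"length": 200_000, "gc": 0.5},
    "elements": {"count": 5, "kind": "RAGL_convergent",
                 "spacer_assignment": [4, 13], "tsd_len": 5, "mutation_rate": 0.0,
                 "gene_lengths": {"RAG2L": 300, "RAG1L": 400}},
    "annotator": {"target_fpr": 1e-6, "k_min": 2, "k_max": 10,
                  "min_gap": 500, "max_gap": 30_000, "min_orf_codons": 100},
    "strain_pair": {"shared": 3, "sample_only": 3},
    "flank_reads": {"read_len": 300, "tir_stub_len": 30},
    "proteins": {"per_class": 10, "scaffold_length": 400, "motif_mutation_rate": 0.0},
    "identity_study": {"family_size": 5, "within_divergence": 0.1,
                       "between_divergence": 0.6},
    "outdir": "raglscan_study",
}


@dataclass
class RunConfig:
    data: dict

    def __getitem__(self, key):
        return self.data[key]

    @property
    def seed(self) -> int:
        return self.data["seed"]

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.data, sort_keys=True).encode()
        ).hexdigest()[:16]


def _check_types(node, schema, path, errors):
    for key, val in node.items():
        if key not in schema:
            errors.append(f"unknown key {path}{key}")
            continue
        expected = schema[key]
        if isinstance(expected, dict):
            if not isinstance(val, dict):
                errors.append(f"{path}{key}: expected a mapping")
            else:
                _check_types(val, expected, f"{path}{key}.", errors)
        elif expected is float:
            if not isinstance(val, (int, float)):
                errors.append(f"{path}{key}: expected a number, got {val!r}")
        elif not isinstance(val, expected):
            errors.append(f"{path}{key}: expected {expected.__name__}, got {val!r}")


def validate_config(source) -> tuple[RunConfig | None, list]:
    """Parse + schema-validate a config; returns (config, all violations).

    ``source`` is a YAML path or a dict. Values omitted fall back to the
    shipped defaults; unknown keys are rejected. The complete violation
    list (not just the first) is returned.
    """
    import yaml

    if isinstance(source, dict):
        user = source
    else:
        if not os.path.exists(source):
            raise IOError(f"cannot read config file {source!r}")
        with open(source) as fh:
            user = yaml.safe_load(fh) or {}

    errors: list[str] = []
    _check_types(user, _SCHEMA, "", errors)

    merged = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(merged.get(key), dict):
            merged[key].update(val)
        else:
            merged[key] = val

    el = merged["elements"]
    if el["tsd_len"] < 0:
        errors.append("elements.tsd_len: must be >= 0")
    if el["count"] < 0:
        errors.append("elements.count: must be >= 0")
    if not 0 <= el["mutation_rate"] <= 1:
        errors.append("elements.mutation_rate: must be in [0, 1]")
    an = merged["annotator"]
    if an["min_gap"] > an["max_gap"]:
        errors.append("annotator.min_gap > annotator.max_gap")
    if not 0 < an["target_fpr"] < 1:
        errors.append("annotator.target_fpr: must be in (0, 1)")
    if not 1 <= an["k_min"] <= an["k_max"]:
        errors.append("annotator: require 1 <= k_min <= k_max")
    fr = merged["flank_reads"]
    if fr["read_len"] <= fr["tir_stub_len"]:
        errors.append("flank_reads.read_len must exceed tir_stub_len")
    if merged["genome"]["length"] <= 0:
        errors.append("genome.length: must be positive")
    if not 0 <= merged["genome"]["gc"] <= 1:
        errors.append("genome.gc: must be in [0, 1]")

    if errors:
        return None, errors
    return RunConfig(merged), []


@dataclass
class StudyReport:
    metrics: dict
    provenance: dict
    files: dict = field(default_factory=dict)

    def to_text(self) -> str:
        lines = [f"# raglscan study report (version {self.provenance['version']})"]
        lines.append(f"# config_hash={self.provenance['config_hash']} "
                     f"seed={self.provenance['seed']}")
        for k in sorted(self.metrics):
            lines.append(f"{k}\t{self.metrics[k]}")
        return "\n".join(lines) + "\n"


def run_study(config: RunConfig, outdir=None) -> StudyReport:
    """Execute every stage on synthetic data; write files + report."""
    if not isinstance(config, RunConfig):
        config, errors = validate_config(config)
        if errors:
            raise ValueError("invalid config: " + "; ".join(errors))
    outdir = outdir or config["outdir"]
    os.makedirs(outdir, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).spawn(6)
    model = aan_ragl_model()
    metrics: dict = {}
    files: dict = {}

    def emit(name, text):
        path = os.path.join(outdir, name)
        header = f"# raglscan {__version__} config_hash={config.hash()}\n"
        with open(path, "w") as fh:
            if name.endswith((".tsv", ".txt", ".bed")):
                fh.write(header)
            fh.write(text)
        files[name] = path

    # --- stage 1: genome simulation ------------------------------------
    el = config["elements"]
    spec = ElementSpec(
        element_kind=el["kind"], tir_model=model,
        spacer_assignment=tuple(el["spacer_assignment"]), tsd_len=el["tsd_len"],
        gene_lengths=dict(el["gene_lengths"]) if el["kind"] != "Transib_single"
        else {"RAG1L": el["gene_lengths"].get("RAG1L", 400)},
        per_position_mutation_rate=el["mutation_rate"],
    )
    base = random_genome(config["genome"]["length"], config["genome"]["gc"],
                         np.random.default_rng(seeds[0]))
    genome, truths = plant_insertions(
        base, [spec] * el["count"], "random", np.random.default_rng(seeds[5]))
    write_fasta({"chr1": genome}, os.path.join(outdir, "genome.fasta"))
    files["genome.fasta"] = os.path.join(outdir, "genome.fasta")
    emit("truth.tsv", truth_to_tsv(truths))
    emit("truth.gff3", truth_to_gff3(truths))

    # --- stage 2: structural annotation ---------------------------------
    an = config["annotator"]
    acfg = AnnotatorConfig(target_fpr=an["target_fpr"], k_min=an["k_min"],
                           k_max=an["k_max"], min_gap=an["min_gap"],
                           max_gap=an["max_gap"], min_orf_codons=an["min_orf_codons"])
    calls = annotate_genome({"chr1": genome}, model, acfg)
    emit("calls.gff3", calls_to_gff3(calls))
    emit("calls.tsv", calls_to_table(calls).to_csv(sep="\t", index=False))
    recall, precision = recall_precision(calls, truths)
    metrics["element_recall"] = round(recall, 4)
    metrics["element_precision"] = round(precision, 4)
    matches, _, _ = match_calls_to_truth(calls, truths)
    if matches:
        metrics["tsd_len_mode"] = int(np.bincount(
            [len(c.tsd) for c, _ in matches if c.tsd]).argmax())
        metrics["architecture_accuracy"] = round(
            sum(c.architecture == t.element_kind for c, t in matches) / len(matches), 4)

    # --- stage 3: strain pair + polymorphism calling ---------------------
    sp = config["strain_pair"]
    base2 = random_genome(max(60_000, config["genome"]["length"] // 2),
                          config["genome"]["gc"], np.random.default_rng(seeds[1]))
    ref_g, sample_g, strain_truth = simulate_strain_pair(
        base2, sp["shared"], sp["sample_only"], spec, np.random.default_rng(seeds[2]))
    fr = config["flank_reads"]
    pairs = synth_flank_reads(sample_g, strain_truth, fr["read_len"], fr["tir_stub_len"])
    write_fasta({"ref": ref_g}, os.path.join(outdir, "reference.fasta"))
    flank_pairs_to_fasta(pairs, os.path.join(outdir, "flanks.fasta"))
    ccfg = CallerConfig(tsd_k=el["tsd_len"])
    call_df, summary = call_all(pairs, {"ref": ref_g}, model, ccfg)
    emit("presence_calls.tsv", call_df.to_csv(sep="\t", index=False))
    status_by_locus = dict(zip(call_df["locus_id"], call_df["status"]))
    expected = {"shared": "shared_present_in_ref",
                "sample_only": "sample_only_empty_ref"}
    correct = sum(status_by_locus.get(t.locus_id) == expected[t.status]
                  for t in strain_truth)
    metrics["polymorphism_accuracy"] = round(correct / len(strain_truth), 4) \
        if strain_truth else 1.0
    for status, count in sorted(summary.items()):
        metrics[f"polymorphism_n_{status}"] = count

    # --- stage 4: protein classification ---------------------------------
    pr = config["proteins"]
    library = make_default_library()
    prot_seeds = seeds[3].spawn(max(1, 3 * pr["per_class"]))
    records, expected_clan = {}, {}
    i = 0
    for cls in ("RAG1L", "Transib_I", "Transib_II"):
        for rep in range(pr["per_class"]):
            pspec = protein_spec_for_class(cls, pr["scaffold_length"],
                                           pr["motif_mutation_rate"])
            sid = f"{cls}_{rep:02d}"
            records[sid] = synth_protein(pspec, library,
                                         np.random.default_rng(prot_seeds[i]))
            expected_clan[sid] = cls
            i += 1
    if records:
        df, clan_counts = classify_batch(records, library)
        emit("protein_classifications.tsv", df.to_csv(sep="\t", index=False))
        acc = sum(df["clan"][k] == expected_clan[sid]
                  for k, sid in enumerate(df["sequence_id"])) / len(df)
        metrics["classification_accuracy"] = round(acc, 4)
        import pandas as pd
        confusion = pd.crosstab(
            pd.Series([expected_clan[s] for s in df["sequence_id"]], name="truth"),
            pd.Series(list(df["clan"]), name="called"))
        emit("protein_confusion.tsv", confusion.to_csv(sep="\t"))

    # --- stage 5: identity summary + NJ clan partition --------------------
    ist = config["identity_study"]
    rngs = seeds[4].spawn(4)
    anc_rag1l = random_protein(300, np.random.default_rng(rngs[0]))
    anc_transib = mutate_to_divergence(anc_rag1l, ist["between_divergence"],
                                       np.random.default_rng(rngs[1]))
    fam_a = evolve_protein_family(anc_rag1l, ist["family_size"],
                                  ist["within_divergence"],
                                  np.random.default_rng(rngs[2]))
    fam_b = evolve_protein_family(anc_transib, ist["family_size"],
                                  ist["within_divergence"],
                                  np.random.default_rng(rngs[3]))
    fam_seqs = {f"RAG1L_{i}": s for i, s in enumerate(fam_a)}
    fam_seqs.update({f"Transib_{i}": s for i, s in enumerate(fam_b)})
    fam_labels = {k: ("RAG1L" if k.startswith("RAG1L") else "Transib")
                  for k in fam_seqs}
    pw = pairwise_identity_matrix(fam_seqs)
    emit("identity_matrix.tsv", pw.round(2).to_csv(sep="\t"))
    summary = group_identity_matrix(fam_seqs, fam_labels, pairwise=pw)
    emit("group_identity.tsv", summary_to_tsv(summary))
    for g, v in summary.within.items():
        if v is not None:
            metrics[f"identity_within_{g}"] = round(v, 2)
    metrics["identity_between_clans"] = round(summary.combined, 2)
    newick = nj_tree(distance_matrix(pw))
    with open(os.path.join(outdir, "nj_tree.nwk"), "w") as fh:
        fh.write(newick + "\n")
    files["nj_tree.nwk"] = os.path.join(outdir, "nj_tree.nwk")
    two_clans, _ = clan_partition_check(newick, fam_labels)
    metrics["clan_partition"] = bool(two_clans)

    report = StudyReport(
        metrics=metrics,
        provenance={"version": __version__, "config_hash": config.hash(),
                    "seed": config.seed},
        files=files,
    )
    emit("report.txt", report.to_text())
    emit("report.tsv", "metric\tvalue\n" + "".join(
        f"{k}\t{metrics[k]}\n" for k in sorted(metrics)))
    return report


def mutate_to_divergence(seq: str, divergence: float, rng) -> str:
    from .simulate import mutate_protein

    return mutate_protein(seq, divergence, rng)
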