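"""Synthetic genomes, elements, strain pairs, flank reads and proteins."""
import re

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from raglscan import (ElementSpec, build_element, classify_protein,
                      plant_insertions, random_genome, sample_tir,
                      simulate_strain_pair, synth_flank_reads, synth_protein)
from raglscan._seq import revcomp
from raglscan.simulate import (CLASS_MOTIFS, FlankPair, TruthRecord,
                               protein_spec_for_class)

TIR10_RE = re.compile(r"CCTCAA[CT]A[CT]G")


class TestSampleTir:
    def test_rate_zero_matches_printed_consensus(self, model):
        """Clean draws reproduce the 13-bp block and Y-degenerate 10-bp block."""
        for seed in range(10):
            tir = sample_tir(model, 4, 0.0, seed)
            assert tir[:13] == "CACACCCAAACCT"
            assert TIR10_RE.fullmatch(tir[-10:])
            assert len(tir) == 13 + 4 + 10

    def test_disallowed_spacer_lists_allowed_set(self, model):
        with pytest.raises(ValueError, match=r"allowed set is \[4, 13\]"):
            sample_tir(model, 7, 0.0, 0)

    def test_reproducible_for_fixed_seed(self, model):
        assert sample_tir(model, 13, 0.2, 99) == sample_tir(model, 13, 0.2, 99)

    def test_expected_hamming_distance_to_consensus(self, model):
        """Mean IUPAC-aware mismatch count matches the analytic expectation.

        21 fixed positions mismatch with prob m; at the 2 degenerate [C/T]
        positions a substitution still matches Y with prob 1/3, so the
        expectation is m*(21 + 2*(2/3)).
        """
        m = 0.05
        n = 5000
        rng = np.random.default_rng(7)
        expected = m * (21 + 2 * (2 / 3))
        consensus = "CACACCCAAACCT" + "CCTCAAYAYG"
        total = 0
        for _ in range(n):
            tir = sample_tir(model, 13, m, rng)
            s = tir[:13] + tir[-10:]
            for a, c in zip(s, consensus):
                if c == "Y":
                    total += a not in "CT"
                else:
                    total += a != c
        se = np.sqrt(expected / n)  # near-Poisson count variance
        assert abs(total / n - expected) < 3 * se


class TestBuildElement:
    def _orf_feats(self, feats):
        return [(s, e, strand, label) for (s, e, strand, t, label) in feats
                if t == "ORF"]

    def test_convergent_orientation(self, model):
        """RAG1L/RAG2L on opposite strands with 3' ends adjacent."""
        seq, feats = build_element(ElementSpec(element_kind="RAGL_convergent"), 1)
        orfs = self._orf_feats(feats)
        assert len(orfs) == 2
        (s2, e2, st2, lb2), (s1, e1, st1, lb1) = orfs
        assert (lb2, st2) == ("RAG2L", "+")
        assert (lb1, st1) == ("RAG1L", "-")
        assert s1 > s2  # RAG2L upstream, RAG1L downstream, facing inward

    def test_tandem_orientation(self, model):
        """RAG2L upstream of RAG1L, both transcribed the same way."""
        seq, feats = build_element(ElementSpec(element_kind="RAGL_tandem"), 1)
        orfs = self._orf_feats(feats)
        assert [lb for *_, lb in orfs] == ["RAG2L", "RAG1L"]
        assert {st for _, _, st, _ in orfs} == {"+"}

    def test_single_gene_element(self, model):
        seq, feats = build_element(ElementSpec(element_kind="Transib_single"), 1)
        assert len(self._orf_feats(feats)) == 1

    def test_tirs_are_inward_facing_inverted_repeats(self, model):
        spec = ElementSpec(per_position_mutation_rate=0.0)
        seq, feats = build_element(spec, 5)
        tirs = [f for f in feats if f[3] == "terminal_inverted_repeat"]
        (s5, e5, _, _, _), (s3, e3, _, _, _) = tirs
        assert seq[s5:s5 + 13] == "CACACCCAAACCT"          # 5' TIR matches on +
        assert revcomp(seq[e3 - 13:e3]) == "CACACCCAAACCT"  # 3' TIR matches on -

    def test_feature_spans_tile_the_annotated_parts(self, model):
        seq, feats = build_element(ElementSpec(), 2)
        for s, e, *_ in feats:
            assert 0 <= s < e <= len(seq)

    def test_bad_spec_rejected(self, model):
        with pytest.raises(ValueError, match="exactly two genes"):
            ElementSpec(element_kind="RAGL_convergent", gene_lengths={"RAG1L": 300})
        with pytest.raises(ValueError, match="below minimum"):
            ElementSpec(gene_lengths={"RAG1L": 50, "RAG2L": 300})


class TestPlantInsertions:
    def test_single_insertion_duplicates_tsd(self):
        genome = "AAAAACGTTGGGGG"
        spec = ElementSpec(tsd_len=5)
        out, truths = plant_insertions(genome, [spec], [9], seed=0)
        t = truths[0]
        element = out[t.insertion_start:t.end]
        assert out == "AAAAACGTT" + element + "ACGTTGGGGG"
        assert t.tsd_sequence == "ACGTT"

    def test_empty_spec_list_is_identity(self):
        g = random_genome(500, seed=1)
        out, truths = plant_insertions(g, [], seed=0)
        assert out == g and truths == []

    def test_length_arithmetic_exact(self):
        g = random_genome(100_000, seed=3)
        spec = ElementSpec()
        out, truths = plant_insertions(g, [spec] * 5, "random", seed=11)
        assert len(out) == len(g) + sum(t.element_length + 5 for t in truths)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_length_arithmetic_property(self, seed):
        rng = np.random.default_rng(seed)
        g = random_genome(int(rng.integers(8000, 15000)), seed=rng)
        k = int(rng.integers(0, 6))
        spec = ElementSpec(tsd_len=k)
        n = int(rng.integers(1, 3))
        out, truths = plant_insertions(g, [spec] * n, "random", seed=rng,
                                       margin=500, min_separation=3500)
        assert len(out) == len(g) + sum(t.element_length + k for t in truths)
        for t in truths:
            assert t.insertion_start + t.element_length <= len(out)
            assert len(t.tsd_sequence) == k

    def test_flanking_copies_identical(self):
        g = random_genome(20_000, seed=5)
        out, truths = plant_insertions(g, [ElementSpec()], "random", seed=6)
        t = truths[0]
        assert out[t.insertion_start - 5:t.insertion_start] == t.tsd_sequence
        assert out[t.end:t.end + 5] == t.tsd_sequence

    def test_conflicting_positions_reported(self):
        g = random_genome(5000, seed=0)
        with pytest.raises(ValueError, match="2000 and 2003"):
            plant_insertions(g, [ElementSpec()] * 2, [2000, 2003], seed=0)

    def test_reproducible(self):
        g = random_genome(10_000, seed=2)
        a = plant_insertions(g, [ElementSpec()], "random", seed=9)
        b = plant_insertions(g, [ElementSpec()], "random", seed=9)
        assert a[0] == b[0]


class TestStrainPair:
    def test_length_difference_matches_sample_only_loci(self):
        base = random_genome(40_000, seed=1)
        spec = ElementSpec()
        ref, sample, truth = simulate_strain_pair(base, 3, 3, spec, seed=5)
        extra = sum(t.element_length + 5 for t in truth if t.status == "sample_only")
        assert len(sample) - len(ref) == extra

    def test_shared_locus_identical_between_genomes(self):
        base = random_genome(20_000, seed=2)
        ref, sample, truth = simulate_strain_pair(base, 1, 0, ElementSpec(), seed=3)
        assert ref == sample

    def test_sample_only_reference_keeps_single_tsd_copy(self):
        """Excising element + one TSD copy from the sample restores the ref."""
        base = random_genome(20_000, seed=4)
        ref, sample, truth = simulate_strain_pair(base, 0, 1, ElementSpec(), seed=7)
        t = truth[0]
        s, e = t.sample_start, t.sample_start + t.element_length
        excised = sample[:s] + sample[e + 5:]
        assert excised == ref
        assert ref[t.ref_start - 5:t.ref_start] == t.tsd_sequence

    def test_zero_counts_identity(self):
        base = random_genome(5000, seed=0)
        ref, sample, truth = simulate_strain_pair(base, 0, 0, ElementSpec(), seed=0)
        assert ref == sample == base and truth == []


class TestFlankReads:
    def test_reads_contain_tsd_adjacent_to_stub(self):
        g = random_genome(30_000, seed=1)
        out, truths = plant_insertions(g, [ElementSpec()], "random", seed=2)
        pairs = synth_flank_reads(out, truths, read_len=300, tir_stub_len=30)
        p, t = pairs[0], truths[0]
        # 5' read: stub then revcomp'd upstream flank starting with the TSD
        assert revcomp(p.read5[30:])[-5:] == t.tsd_sequence
        # 3' read: stub then downstream flank starting with the TSD copy
        assert p.read3[30:35] == t.tsd_sequence

    def test_read_len_le_stub_rejected(self):
        with pytest.raises(ValueError, match="read_len must exceed"):
            synth_flank_reads("ACGT" * 100, [], read_len=30, tir_stub_len=30)

    def test_edge_locus_skips_only_the_truncated_side(self, caplog):
        g = random_genome(5000, seed=3)
        out, truths = plant_insertions(g, [ElementSpec()], [100], seed=4,
                                       margin=100)
        pairs = synth_flank_reads(out, truths, read_len=300, tir_stub_len=30)
        assert pairs[0].read5 is None
        assert pairs[0].read3 is not None


class TestSynthProtein:
    @pytest.mark.parametrize("cls", sorted(CLASS_MOTIFS))
    def test_round_trip_classification(self, cls, library):
        p = synth_protein(protein_spec_for_class(cls), library, 3)
        assert classify_protein(p, library).clan == cls

    def test_transib_ii_lacks_alpha11_alpha12(self, library):
        p = synth_protein(protein_spec_for_class("Transib_II"), library, 1)
        c = classify_protein(p, library)
        assert c.flags["CTT2"].present
        assert not c.flags["A11_A12"].present

    def test_empty_motif_set_unclassified(self, library):
        from raglscan.simulate import SyntheticProteinSpec
        p = synth_protein(SyntheticProteinSpec("RAG1L", ()), library, 0)
        assert classify_protein(p, library).clan == "unclassified"

    def test_scaffold_too_short_reports_minimum(self, library):
        with pytest.raises(ValueError, match="required minimum"):
            synth_protein(protein_spec_for_class("RAG1L", scaffold_length=50),
                          library, 0)

    def test_unknown_motif_rejected(self, library):
        from raglscan.simulate import SyntheticProteinSpec
        with pytest.raises(ValueError, match="not in profile library"):
            synth_protein(SyntheticProteinSpec("RAG1L", ("NOPE",)), library, 0)
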