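"""TIR pairing, TSD detection, ORF finding, architecture classification."""
import numpy as np
import pytest

from raglscan import (AnnotatorConfig, ElementSpec, annotate_genome,
                      classify_architecture, detect_tsd, find_orfs,
                      pair_tirs, plant_insertions, random_genome)
from raglscan._seq import revcomp
from raglscan.annotate import Orf, calls_to_gff3, recall_precision
from raglscan.simulate import make_orf
from raglscan.tir_model import TIRHit


def hit(start, end, strand, spacer=4, score=30.0):
    return TIRHit("c", start, end, strand, spacer, score / 2, score / 2, score)


def brute_force_orfs(seq, min_len_codons):
    """Independent oracle: every ATG extended to its in-frame stop, kept
    only if no earlier in-frame ATG shares the same stop (maximality)."""
    stops = {"TAA", "TAG", "TGA"}
    out = set()
    for strand in "+-":
        s = seq if strand == "+" else revcomp(seq)
        n = len(s)
        runs = {}  # stop position -> earliest ATG
        for i in range(n - 2):
            if s[i:i + 3] != "ATG":
                continue
            j = i
            while j + 3 <= n and s[j:j + 3] not in stops:
                j += 3
            if j + 3 > n:
                continue  # no stop: incomplete ORF, not reported
            end = j + 3
            if (end - i) // 3 < min_len_codons:
                continue
            key = (end, i % 3)
            if key not in runs or i < runs[key]:
                runs[key] = i
        for (end, _), start in runs.items():
            if strand == "+":
                out.add((start, end, "+"))
            else:
                out.add((n - end, n - start, "-"))
    return sorted(out)


class TestDetectTsd:
    def test_planted_five_bp_tsd(self):
        g = random_genome(20_000, seed=1)
        out, truths = plant_insertions(g, [ElementSpec()], "random", seed=2)
        t = truths[0]
        res = detect_tsd(out, t.insertion_start, t.end, 2, 10)
        assert res == (t.tsd_sequence, 5)

    def test_homopolymer_flanks_return_k_max(self):
        contig = "A" * 30 + "CGCGCGCG" + "A" * 30
        res = detect_tsd(contig, 30, 38, 2, 10)
        assert res == ("A" * 10, 10)

    def test_contig_edge_returns_none(self, caplog):
        contig = "ACGTACGTACGT"
        assert detect_tsd(contig, 1, 11, 2, 10) is None

    def test_random_flanks_rarely_show_tsd(self):
        """P(some k in 4..10 matches) is ~sum 4^-k ~ 0.52%; assert rarity."""
        rng = np.random.default_rng(3)
        none_count = 0
        trials = 1000
        for _ in range(trials):
            flanks = "".join("ACGT"[i] for i in rng.integers(0, 4, 40))
            contig = flanks[:20] + "X" * 0 + flanks[20:]  # spans 20..20 (empty span)
            if detect_tsd(contig, 20, 20, 4, 10) is None:
                none_count += 1
        assert none_count / trials > 0.98

    def test_bad_k_range_rejected(self):
        with pytest.raises(ValueError):
            detect_tsd("ACGT" * 20, 10, 20, 5, 2)


class TestFindOrfs:
    def test_single_forward_orf_codon_convention(self, rng):
        """ATG + 300 sense codons + TAA counts as 302 codons incl. stop."""
        orf = make_orf(302, rng)
        pad = "CCCCC"
        res = find_orfs(pad + orf + pad, min_len_codons=100)
        assert len(res) == 1
        o = res[0]
        assert (o.start, o.end, o.strand) == (5, 5 + 906, "+")
        assert o.n_codons == 302

    def test_reverse_strand_symmetry(self, rng):
        orf = make_orf(150, rng)
        seq = "GGGG" + orf + "GGGG"
        fwd = find_orfs(seq, 100)
        rev = find_orfs(revcomp(seq), 100)
        n = len(seq)
        assert sorted((n - o.end, n - o.start, "-" if o.strand == "+" else "+")
                      for o in fwd) == sorted((o.start, o.end, o.strand) for o in rev)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_six_frame_oracle(self, seed):
        g = random_genome(8000, seed=seed)
        got = sorted((o.start, o.end, o.strand) for o in find_orfs(g, 20))
        assert got == brute_force_orfs(g, 20)

    def test_min_len_validated(self):
        with pytest.raises(ValueError):
            find_orfs("ATGAAATAA", 0)


class TestPairTirs:
    def test_inward_facing_pair_within_gap_window(self):
        hits = [hit(100, 127, "+"), hit(8100, 8127, "-")]
        pairs = pair_tirs(hits, 1000, 20_000)
        assert len(pairs) == 1
        assert pairs[0].spacer_pair == (4, 4)
        assert pairs[0].symmetry == "symmetric"

    def test_direct_repeat_is_not_paired(self):
        hits = [hit(100, 127, "+"), hit(8100, 8127, "+")]
        assert pair_tirs(hits, 1000, 20_000) == []

    def test_outward_facing_not_paired(self):
        hits = [hit(100, 127, "-"), hit(8100, 8127, "+")]
        assert pair_tirs(hits, 1000, 20_000) == []

    def test_greedy_resolution_prefers_higher_score_then_smaller_span(self):
        """A middle '-' hit pairable with either end goes to the best pair."""
        h_left = hit(0, 27, "+", score=40.0)
        h_mid = hit(5000, 5027, "-", score=30.0)
        h_right_minus = hit(12_000, 12_027, "-", score=10.0)
        pairs = pair_tirs([h_left, h_mid, h_right_minus], 1000, 20_000)
        # left+mid (70) beats left+right (50); non-overlap excludes the rest
        assert len(pairs) == 1
        assert (pairs[0].start, pairs[0].end) == (0, 5027)
        # equal scores: smaller span wins
        h_a = hit(0, 27, "+", score=30.0)
        pairs = pair_tirs([h_a, h_mid, hit(20_000, 20_027, "-", score=30.0)],
                          1000, 30_000)
        assert (pairs[0].start, pairs[0].end) == (0, 5027)

    def test_bad_gap_window(self):
        with pytest.raises(ValueError, match="min_gap"):
            pair_tirs([], 100, 50)


class TestClassifyArchitecture:
    def orf(self, start, n_codons, strand):
        return Orf(start, start + 3 * n_codons, strand)

    def test_convergent(self):
        labeled = [(self.orf(100, 300, "+"), "RAG2L"), (self.orf(1200, 400, "-"), "RAG1L")]
        arch, _ = classify_architecture(labeled, True, True)
        assert arch == "RAGL_convergent"

    def test_tandem(self):
        labeled = [(self.orf(100, 300, "+"), "RAG2L"), (self.orf(1200, 400, "+"), "RAG1L")]
        arch, _ = classify_architecture(labeled, True, True)
        assert arch == "RAGL_tandem"

    def test_single_rag1l_is_transib_like(self):
        arch, _ = classify_architecture([(self.orf(100, 400, "+"), "RAG1L")], True, True)
        assert arch == "Transib_like"

    def test_missing_tsd_means_fragmented(self):
        labeled = [(self.orf(100, 300, "+"), "RAG2L"), (self.orf(1200, 400, "-"), "RAG1L")]
        arch, _ = classify_architecture(labeled, True, False)
        assert arch == "fragmented"

    def test_divergent_orientation_flagged(self):
        labeled = [(self.orf(100, 300, "-"), "RAG2L"), (self.orf(1200, 400, "+"), "RAG1L")]
        arch, notes = classify_architecture(labeled, True, True)
        assert arch == "fragmented" and "divergent_orientation" in notes

    def test_duplicate_labels_flagged_expanded(self):
        labeled = [(self.orf(100, 400, "+"), "RAG1L"),
                   (self.orf(2000, 350, "+"), "RAG1L")]
        arch, notes = classify_architecture(labeled, True, True)
        assert arch == "Transib_like" and "expanded:RAG1L" in notes

    def test_no_labelled_orfs_yields_no_class(self):
        arch, _ = classify_architecture([(self.orf(0, 120, "+"), "unknown")], True, True)
        assert arch is None


@pytest.fixture(scope="module")
def planted(model):
    g = random_genome(100_000, seed=10)
    genome, truths = plant_insertions(g, [ElementSpec()] * 5, "random", seed=20)
    return genome, truths


class TestAnnotateGenome:
    def test_recovers_all_planted_convergent_elements(self, planted, model):
        genome, truths = planted
        calls = annotate_genome({"chr1": genome}, model)
        assert len(calls) == 5
        assert all(c.architecture == "RAGL_convergent" for c in calls)
        assert all(c.tsd and len(c.tsd) == 5 for c in calls)
        recall, precision = recall_precision(calls, truths)
        assert recall == 1.0 and precision == 1.0

    def test_planted_asymmetric_spacers_labelled_asymmetric(self, planted, model):
        genome, _ = planted
        for c in annotate_genome({"chr1": genome}, model):
            assert sorted(c.spacer_pair) == [4, 13]
            assert c.symmetry == "asymmetric"

    def test_reported_tsd_matches_truth(self, planted, model):
        genome, truths = planted
        calls = annotate_genome({"chr1": genome}, model)
        from raglscan.annotate import match_calls_to_truth
        matches, _, _ = match_calls_to_truth(calls, truths)
        assert len(matches) == 5
        for call, truth in matches:
            assert call.tsd == truth.tsd_sequence

    def test_null_genome_has_no_calls(self, model):
        g = random_genome(100_000, seed=31)
        assert annotate_genome({"chr1": g}, model) == []

    def test_ablated_tir_yields_fragmented(self, model):
        g = random_genome(40_000, seed=12)
        genome, truths = plant_insertions(g, [ElementSpec()], "random", seed=13)
        t = truths[0]
        # ablate the 5' TIR (first 27 bp of the element) with random bases
        rng = np.random.default_rng(0)
        junk = "".join("ACGT"[i] for i in rng.integers(0, 4, 27))
        mutated = genome[:t.insertion_start] + junk + genome[t.insertion_start + 27:]
        calls = annotate_genome({"chr1": mutated}, model)
        assert len(calls) == 1
        assert calls[0].architecture == "fragmented"
        assert "single_tir" in calls[0].notes

    def test_gff3_output_is_byte_identical_across_runs(self, planted, model):
        genome, _ = planted
        a = calls_to_gff3(annotate_genome({"chr1": genome}, model))
        b = calls_to_gff3(annotate_genome({"chr1": genome}, model))
        assert a == b
        assert a.startswith("##gff-version 3\n")
        assert "mobile_genetic_element" in a and "target_site_duplication" in a

    def test_symmetric_spacer_pairs_labelled_symmetric(self, model):
        g = random_genome(30_000, seed=14)
        spec = ElementSpec(spacer_assignment=(4, 4))
        genome, truths = plant_insertions(g, [spec], "random", seed=15)
        calls = annotate_genome({"chr1": genome}, model)
        assert len(calls) == 1 and calls[0].symmetry == "symmetric"
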