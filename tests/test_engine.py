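"""Seed indexing, ungapped extension and whole-genome self-comparison."""

from __future__ import annotations

import subprocess

import numpy as np
import pytest

from rouscan.engine import (HSP, Scoring, SeedMatch, build_seed_index,
                            enumerate_seed_matches, extend_ungapped,
                            read_blast_tabular, self_compare)
from rouscan.seqio import GenomeSequence, reverse_complement, write_genome_fasta
from rouscan.synth import PlantSpec, generate_background, make_fixture

from conftest import planted_pair, random_unit


class TestScoring:
    def test_defaults_reproduce_reference_parameters(self):
        sc = Scoring()
        assert (sc.word_size, sc.match_reward, sc.mismatch_penalty) == (50, 1, -20)
        assert sc.effective_min_score == 50
        assert sc.effective_xdrop == 40

    @pytest.mark.parametrize("kwargs", [
        {"word_size": 4},
        {"match_reward": 0},
        {"mismatch_penalty": 2},
        {"min_score": 0},
        {"xdrop": -1},
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            Scoring(**kwargs)


class TestSeedIndex:
    def test_repeated_word_maps_to_all_offsets(self):
        idx = build_seed_index(GenomeSequence("t", "ACGTACGT"), 4)
        assert idx.occurrences("ACGT") == [0, 4]

    def test_reverse_complement_not_in_forward_index(self):
        idx = build_seed_index(GenomeSequence("t", "AAAA"), 4)
        assert idx.occurrences("AAAA") == [0]
        assert "TTTT" not in idx

    def test_word_size_longer_than_genome_rejected(self):
        with pytest.raises(ValueError, match="word_size"):
            build_seed_index(GenomeSequence("t", "ACGT"), 8)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_random_100kb_has_no_duplicated_50mer(self, seed):
        # collision probability ~ L^2 * 4^-50 ~ 1e-20
        g = generate_background(100_000, seed=seed)
        idx = build_seed_index(g, 50)
        assert max(len(v) for v in idx.words.values()) == 1

    def test_masked_words_absent(self):
        g = GenomeSequence("t", "ACGTNACGTACGT")
        idx = build_seed_index(g, 4)
        assert "GTNA" not in idx
        assert idx.occurrences("ACGT") == [0, 5, 9]


class TestEnumerateSeeds:
    def test_toy_duplication_gives_one_plus_seed(self):
        g = GenomeSequence("t", "ACGTACGT")
        seeds = enumerate_seed_matches(build_seed_index(g, 4), g)
        plus = [s for s in seeds if s.strand == "+"]
        assert plus == [SeedMatch(q_pos=0, s_pos=4, strand="+", span=4)]
        # ACGT is its own reverse complement: palindromic minus seeds exist
        assert all(s.strand == "-" for s in set(seeds) - set(plus))

    def test_planted_exact_duplicate_coalesces_to_one_seed(self):
        g = planted_pair(random_unit(600, 1))
        seeds = enumerate_seed_matches(build_seed_index(g, 50), g)
        assert len(seeds) == 1
        (s,) = seeds
        assert (s.strand, s.span, s.q_pos, s.s_pos) == ("+", 600, 200, 1500)

    def test_repeat_free_genome_yields_no_seeds(self):
        g = generate_background(2000, seed=5)
        assert enumerate_seed_matches(build_seed_index(g, 50), g) == []


class TestExtension:
    def test_planted_exact_600bp_duplicate(self):
        g = planted_pair(random_unit(600, 2))
        seeds = enumerate_seed_matches(build_seed_index(g, 50), g)
        h = extend_ungapped(g, seeds[0], Scoring())
        assert (h.length, h.score, h.mismatches) == (600, 600, 0)
        assert (h.q_start, h.q_end, h.s_start, h.s_end) == (200, 800, 1500, 2100)

    def test_single_mismatch_bridged_by_twenty_matches(self):
        # 50 matches, 1 mismatch, 20 matches: the 71 bp segment ties the
        # 50 bp exact core at score 50 and the longest segment is kept
        g = planted_pair(random_unit(71, 3), mut_offsets=(50,))
        (h,) = self_compare(g)
        assert (h.length, h.score, h.mismatches) == (71, 50, 1)

    def test_single_mismatch_not_bridged_by_nineteen_matches(self):
        # extension through the mismatch would score 49 < 50
        g = planted_pair(random_unit(70, 3), mut_offsets=(50,))
        (h,) = self_compare(g)
        assert (h.length, h.score, h.mismatches) == (50, 50, 0)

    def test_mismatch_cluster_splits_alignment(self):
        g = planted_pair(random_unit(300, 4), mut_offsets=(148, 149, 150))
        hsps = self_compare(g)
        assert sorted(h.length for h in hsps) == [148, 149]
        assert all(h.mismatches == 0 for h in hsps)


class TestSelfCompare:
    def test_planted_direct_and_inverted_repeats(self):
        g, _ = make_fixture(20_000, [PlantSpec(600, 2),
                                     PlantSpec(300, 2, orientations=("+", "-"))],
                            seed=11)
        hsps = self_compare(g)
        assert len(hsps) == 2
        by_strand = {h.strand: h for h in hsps}
        assert by_strand["+"].length >= 600
        assert by_strand["-"].length >= 300

    def test_full_length_self_identity_never_reported(self):
        g = planted_pair(random_unit(200, 6), bg_len=2000, c2=1200)
        for h in self_compare(g):
            assert not (h.strand == "+" and h.length == len(g))

    def test_deterministic_output(self):
        g, _ = make_fixture(5000, [PlantSpec(200, 3)], seed=13)
        assert self_compare(g) == self_compare(g)

    def test_strand_symmetry_under_reverse_complement(self):
        g, _ = make_fixture(8000, [PlantSpec(400, 2, orientations=("+", "-")),
                                   PlantSpec(150, 2)], seed=17)
        fwd = self_compare(g)
        rev = self_compare(g.reverse_complement())
        key = lambda hs: sorted((h.length, h.score, h.strand) for h in hs)
        assert key(fwd) == key(rev)

    def test_score_formula_and_exact_core_hold(self):
        g, _ = make_fixture(10_000, [PlantSpec(300, 2, mismatches=((), (150,))),
                                     PlantSpec(200, 2, orientations=("+", "-"))],
                            seed=19)
        sc = Scoring()
        hsps = self_compare(g, sc)
        assert hsps
        for h in hsps:
            q = g.seq[h.q_start:h.q_end]
            s = g.seq[h.s_start:h.s_end]
            if h.strand == "-":
                s = reverse_complement(s)
            mm = sum(1 for a, b in zip(q, s) if a != b)
            assert mm == h.mismatches
            assert h.score == sc.match_reward * (h.length - mm) + sc.mismatch_penalty * mm
            assert h.score >= sc.effective_min_score
            # at least one exact run >= word_size
            runs, cur = [], 0
            for a, b in zip(q, s):
                cur = cur + 1 if a == b else 0
                runs.append(cur)
            assert max(runs) >= sc.word_size

    def test_extension_stops_at_masked_residue(self):
        g = planted_pair(random_unit(300, 7))
        s = bytearray(g.seq, "ascii")
        s[200 + 120] = ord("N")  # inside the first copy
        masked = GenomeSequence("m", s.decode())
        lengths = sorted(h.length for h in self_compare(masked))
        assert lengths == [120, 179]


class TestCircularMode:
    def test_origin_spanning_copy_found_only_in_circular_mode(self):
        unit = random_unit(200, 21)
        bg = generate_background(5000, seed=22)
        s = bytearray(bg.seq, "ascii")
        s[2000:2200] = unit.encode()
        # second copy wraps the origin: last 100 bp ... first 100 bp
        s[4900:5000] = unit[:100].encode()
        s[0:100] = unit[100:].encode()
        g = GenomeSequence("circ", s.decode())
        # linearly the wrapped copy is only visible as its two ~100 bp pieces
        assert max(h.length for h in self_compare(g, circular=False)) < 200
        hits = self_compare(g, circular=True)
        assert any(h.length >= 200 for h in hits)
        assert all(h.length <= len(g) for h in hits)

    def test_linear_repeats_identical_in_both_modes(self):
        g, _ = make_fixture(6000, [PlantSpec(250, 2)], seed=23)
        lin = self_compare(g, circular=False)
        circ = self_compare(g, circular=True)
        assert set(lin) == set(circ)


class TestBlastCrossValidation:
    def test_exact_planted_repeat_agrees_with_blastn(self, tmp_path):
        """blastn with the reference parameters reports the same exact
        600 bp duplicate interval pair as the engine."""
        g = planted_pair(random_unit(600, 31), bg_len=4000, c2=2500)
        fasta = tmp_path / "g.fasta"
        write_genome_fasta(g, fasta)
        out = tmp_path / "hits.tsv"
        subprocess.run(
            ["blastn", "-query", str(fasta), "-subject", str(fasta),
             "-word_size", "50", "-reward", "1", "-penalty", "-20",
             "-ungapped", "-dust", "no", "-evalue", "10000",
             "-outfmt", "6", "-out", str(out)],
            check=True,
        )
        blast = {(h.q_start, h.q_end, h.s_start, h.s_end, h.strand)
                 for h in read_blast_tabular(out)}
        ours = {(h.q_start, h.q_end, h.s_start, h.s_end, h.strand)
                for h in self_compare(g)}
        assert ours <= blast
        assert (200, 800, 2500, 3100, "+") in ours


def test_read_blast_tabular_parses_and_canonicalises(tmp_path):
    p = tmp_path / "b6.tsv"
    p.write_text(
        "g\tg\t100.0\t600\t0\t0\t201\t800\t2501\t3100\t0.0\t1100\n"   # A->B
        "g\tg\t100.0\t600\t0\t0\t2501\t3100\t201\t800\t0.0\t1100\n"   # reciprocal
        "g\tg\t100.0\t300\t1\t0\t101\t400\t900\t601\t0.0\t500\n"      # minus strand
        "g\tg\t100.0\t4000\t0\t0\t1\t4000\t1\t4000\t0.0\t7000\n"      # self-identity
        "g\tg\t95.0\t100\t2\t1\t10\t110\t500\t601\t0.0\t150\n"        # gapped: drop
    )
    hsps = read_blast_tabular(p)
    assert len(hsps) == 2
    plus = next(h for h in hsps if h.strand == "+")
    minus = next(h for h in hsps if h.strand == "-")
    assert (plus.q_start, plus.q_end, plus.s_start, plus.s_end) == (200, 800, 2500, 3100)
    assert (minus.q_start, minus.q_end, minus.s_start, minus.s_end) == (100, 400, 600, 900)
    assert minus.mismatches == 1 and minus.score == 299 - 20
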