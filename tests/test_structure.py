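"""LTR-pair detection, element feature annotation, dot plot, masking coverage."""

import numpy as np
import pytest

from ltrdomains import simulate, structure
from ltrdomains.simulate import _random_nt, _revcomp, mutate_nt
from ltrdomains.structure import (
    detect_dual_rnaseh,
    detect_pbs,
    detect_ppt,
    detect_tir,
    dotplot,
    find_ltr_pairs,
    find_orfs,
    mask_coverage,
)


class TestFindLtrPairs:
    def test_planted_identical_ltrs(self, rng):
        ltr = "TG" + _random_nt(np.random.default_rng(1), 996) + "CA"
        internal = _random_nt(np.random.default_rng(2), 11000)
        bg1 = _random_nt(np.random.default_rng(3), 3000)
        bg2 = _random_nt(np.random.default_rng(4), 3000)
        seq = bg1 + ltr + internal + ltr + bg2
        models = find_ltr_pairs(seq)
        assert len(models) == 1
        m = models[0]
        assert m.ltr5 == (3000, 4000)
        assert m.ltr3 == (3000 + 12000, 4000 + 12000)
        assert m.ltr_identity == 1.0

    def test_giant_ltrs_need_raised_cap(self, library):
        """6,425 bp LTRs are rejected at the 3,000 bp default cap but found at 7,000."""
        g = simulate.GenomeSimSpec(
            species_id="Pa",
            genome_len=40000,
            elements=(simulate.reference_element_spec(),),
            seed=1,
        )
        records, _ = simulate.generate_genome(g, library)
        _, seq = records[0]
        assert find_ltr_pairs(seq) == []
        models = find_ltr_pairs(seq, max_ltr_len=7000)
        assert len(models) == 1
        assert models[0].ltr_len == 6425

    def test_boundary_accuracy_at_5pct_divergence(self, library):
        """Boundaries track truth: 90% of replicates within +/-5 nt, all within 15."""
        spec = simulate.gypsy_odd_spec(copy_number=1, divergence=0.05)
        errs = []
        for seed in range(20):
            g = simulate.GenomeSimSpec(
                species_id="s", genome_len=20000, elements=(spec,), seed=500 + seed
            )
            records, truth = simulate.generate_genome(g, library)
            _, seq = records[0]
            models = find_ltr_pairs(seq)
            assert models, f"no pair found for replicate {seed}"
            m = max(models, key=lambda m: m.ltr_identity * m.ltr_len)
            lt = sorted(
                (f.start, f.end)
                for f in truth[0].features
                if f.kind in ("LTR5", "LTR3")
            )
            det = [m.ltr5, m.ltr3]
            errs.append(
                max(abs(det[i][j] - lt[i][j]) for i in range(2) for j in range(2))
            )
        errs = sorted(errs)
        assert errs[int(0.9 * len(errs)) - 1] <= 5
        assert errs[-1] <= 15

    def test_strand_symmetry(self, library):
        spec = simulate.gypsy_odd_spec(copy_number=1, divergence=0.0)
        g = simulate.GenomeSimSpec(
            species_id="s", genome_len=20000, elements=(spec,), seed=11
        )
        records, _ = simulate.generate_genome(g, library)
        _, seq = records[0]
        n = len(seq)
        (f,) = find_ltr_pairs(seq)
        (r,) = find_ltr_pairs(_revcomp(seq))
        assert (n - r.end, n - r.start) == (f.start, f.end)

    def test_no_pairs_on_element_free_genomes(self, library):
        for seed in range(10):
            g = simulate.GenomeSimSpec(
                species_id="s", genome_len=30000, elements=(), seed=600 + seed
            )
            records, _ = simulate.generate_genome(g, library)
            assert find_ltr_pairs(records[0][1]) == []


class TestDetectTir:
    def test_constructed_tir(self):
        ltr = "TGTAC" + "G" * 500 + "GTACA"
        assert detect_tir(ltr) == 5

    def test_no_inverted_termini(self):
        ltr = "AAAA" + "G" * 500 + "AAAA"
        assert detect_tir(ltr) == 0

    def test_equals_brute_force(self, rng):
        for _ in range(20):
            ltr = "".join(rng.choice(list("ACGT"), 60))
            got = detect_tir(ltr)
            brute = 0
            for t in range(3, 13):
                if _revcomp(ltr[:t]) == ltr[-t:]:
                    brute = max(brute, t)
            assert got == brute


class TestFindOrfs:
    def test_designed_orfs_recovered(self, library):
        seq, feats = simulate.generate_element(
            simulate.gypsy_odd_spec(copy_number=1), library, seed=31
        )
        ltr5 = next(f for f in feats if f.kind == "LTR5")
        ltr3 = next(f for f in feats if f.kind == "LTR3")
        internal = seq[ltr5.end : ltr3.start]
        orfs = [o for o in find_orfs(internal) if o.strand == "+"]
        assert [o.aa_length for o in orfs] == [1100, 320]

    def test_all_stop_sequence_empty(self):
        assert find_orfs("TAATAGTGA" * 200) == []

    def test_equals_per_frame_scan_oracle(self, rng):
        from Bio.Seq import Seq

        seq = "".join(rng.choice(list("ACGT"), 2000))
        got = {(o.start, o.end, o.strand) for o in find_orfs(seq, min_aa=20)}
        oracle = set()
        n = len(seq)
        for strand, s in (("+", seq), ("-", _revcomp(seq))):
            for frame in range(3):
                codons = [s[i : i + 3] for i in range(frame, n - 2, 3)]
                start = None
                for i, c in enumerate(codons + ["TAA"]):
                    terminal = i == len(codons)
                    if c in ("TAA", "TAG", "TGA"):
                        if start is not None and i - start >= 20:
                            a = frame + 3 * start
                            b = frame + 3 * i + (0 if terminal else 3)
                            if strand == "-":
                                a, b = n - b, n - a
                            oracle.add((a, b, strand))
                        start = None
                    elif c == "ATG" and start is None:
                        start = i
        assert got == oracle


class TestDetectPbs:
    def test_planted_trna_arg_pbs(self, library):
        trna = dict(library.trnas)["tRNA-Arg"]
        window = _revcomp(trna[-14:]) + _random_nt(np.random.default_rng(5), 60)
        rec = detect_pbs(window, list(library.trnas))
        assert rec is not None
        assert rec.trna == "tRNA-Arg"
        assert (rec.start, rec.end) == (0, 14)

    def test_no_complement_none(self, library):
        assert detect_pbs("ACGT" * 20, list(library.trnas), min_match=14) is None

    def test_matches_substring_oracle(self, library):
        trna = dict(library.trnas)["tRNA-Lys"]
        probe = _revcomp(trna[-13:])
        window = "CCCCC" + probe + "GGGGGGGGGGGG"
        rec = detect_pbs(window, list(library.trnas))
        assert rec.trna == "tRNA-Lys"
        assert rec.start == window.find(probe)


class TestDetectPpt:
    def test_planted_purine_run(self):
        window = "CTCTCTCTCT" + "AGAGAGAGAGAG" + "CTCTCTCTCTCTCTCTCTCTCTCTCTCT"
        rec = detect_ppt(window)
        assert rec is not None
        assert rec.purine_fraction == 1.0
        assert (rec.start, rec.end) == (10, 22)

    def test_pyrimidine_window_none(self):
        assert detect_ppt("CT" * 30) is None

    def test_equals_run_enumeration(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 50))
        got = detect_ppt(seq, window=50, min_len=10, min_purine=0.85)
        best = None
        for i in range(41):
            for j in range(i + 10, 51):
                frac = sum(c in "AG" for c in seq[i:j]) / (j - i)
                if frac >= 0.85:
                    key = (frac, j - i, i)
                    if best is None or key > best[0]:
                        best = (key, (i, j, frac))
        if best is None:
            assert got is None
        else:
            assert (got.start, got.end) == best[1][:2]
            assert got.purine_fraction == pytest.approx(best[1][2])


class TestDualRnaseH:
    def test_two_cassettes_counted(self, library, gypsy_polyprotein=None):
        seq, feats = simulate.generate_element(
            simulate.gypsy_odd_spec(copy_number=1), library, seed=32
        )
        from Bio.Seq import Seq

        orf1 = next(f for f in feats if f.kind == "ORF" and f.label == "ORF1")
        aa = str(Seq(seq[orf1.start : orf1.end]).translate())
        rh = next(p for p in library.profiles if p.family == "RNaseH")
        assert detect_dual_rnaseh(aa, rh) == 2

    def test_zero_when_absent(self, library, rng):
        rh = next(p for p in library.profiles if p.family == "RNaseH")
        aa = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 800))
        assert detect_dual_rnaseh(aa, rh) == 0

    def test_equals_greedy_nonoverlap_oracle(self, library):
        from ltrdomains.pssm import scan_frame_scores

        rh = next(p for p in library.profiles if p.family == "RNaseH")
        aa = "G" * 20 + rh.master + "G" * 10 + rh.master + "G" * 20
        scores = scan_frame_scores(aa, rh)
        cutoff = 1.5 * len(rh)
        hits = sorted(
            [(-s, i) for i, s in enumerate(scores) if s >= cutoff]
        )
        chosen = []
        for _, i in hits:
            if all(abs(i - j) >= len(rh) for j in chosen):
                chosen.append(i)
        assert detect_dual_rnaseh(aa, rh) == len(chosen) == 2


class TestDotplot:
    def test_ltr_off_diagonal_segment(self):
        r = np.random.default_rng(8)
        ltr = _random_nt(r, 300)
        seq = ltr + _random_nt(r, 2000) + ltr
        pts = dotplot(seq, word=15)
        offset = 2300
        off_diag = [(x, y) for x, y, s in pts if s == "+" and y - x == offset]
        assert len(off_diag) == 300 - 15 + 1

    def test_random_sequence_diagonal_only(self):
        seq = _random_nt(np.random.default_rng(9), 3000)
        pts = dotplot(seq, word=15)
        fwd_off = [(x, y) for x, y, s in pts if s == "+" and x != y]
        assert len(fwd_off) == 0  # expected duplicate 15-mers ~ n^2/4^15 << 1

    def test_symmetric(self):
        seq = _random_nt(np.random.default_rng(10), 500) * 2
        pts = {(x, y, s) for x, y, s in dotplot(seq, word=15)}
        for x, y, s in pts:
            assert (y, x, s) in pts

    def test_equals_brute_force_word_matching(self):
        seq = _random_nt(np.random.default_rng(11), 400) + _random_nt(
            np.random.default_rng(11), 100
        )
        word = 15
        got = set(dotplot(seq, word=word))
        oracle = set()
        words = [seq[i : i + word] for i in range(len(seq) - word + 1)]
        for x, wx in enumerate(words):
            for y, wy in enumerate(words):
                if wx == wy:
                    oracle.add((x, y, "+"))
                if _revcomp(wx) == wy:
                    oracle.add((x, y, "-"))
        assert got == oracle


class TestMaskCoverage:
    def test_two_full_copies_arithmetic(self):
        r = np.random.default_rng(12)
        lib_seq = _random_nt(r, 2000)
        bg = _random_nt(r, 6000)
        genome = [("c", bg[:3000] + lib_seq + bg[3000:5000] + lib_seq + bg[5000:])]
        masked = mask_coverage(genome, [("lib", lib_seq)])
        assert masked.masked_bp == 4000
        assert masked.coverage == pytest.approx(4000 / 10000)

    def test_thirty_pct_divergence_rejected(self):
        r = np.random.default_rng(13)
        lib_seq = _random_nt(r, 2000)
        diverged, _ = mutate_nt(lib_seq, 0.30, r)
        genome = [("c", _random_nt(r, 3000) + diverged + _random_nt(r, 3000))]
        masked = mask_coverage(genome, [("lib", lib_seq)], max_divergence=0.20)
        assert masked.coverage < 0.01

    def test_masked_bp_tracks_truth_at_10pct(self):
        """Masked bases within 2% of the implanted bases, 10 seeds."""
        for seed in range(10):
            r = np.random.default_rng(700 + seed)
            lib_seq = _random_nt(r, 1500)
            copy, _ = mutate_nt(lib_seq, 0.10, r)
            genome = [("c", _random_nt(r, 2500) + copy + _random_nt(r, 2500))]
            masked = mask_coverage(genome, [("lib", lib_seq)])
            assert abs(masked.masked_bp - 1500) <= 0.02 * 1500

    def test_gap_aware_coverage_ordering(self):
        r = np.random.default_rng(14)
        lib_seq = _random_nt(r, 1000)
        genome = [("c", "N" * 2000 + lib_seq + _random_nt(r, 2000))]
        masked = mask_coverage(genome, [("lib", lib_seq)])
        assert masked.gap_bp == 2000
        assert masked.coverage <= masked.coverage_excluding_gaps
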