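import numpy as np
import pytest

from saltlnc.align import (
    LocalMatch,
    ScoringParams,
    classify_by_homology,
    export_tabular_alignments,
    find_local_matches,
    import_tabular_alignments,
)
from saltlnc.core import Transcript, reverse_complement

from .oracles import diagonal_scan_best


def random_transcript(rng, name, length, gc=0.45):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return Transcript(name, "".join(rng.choice(list("ACGT"), size=length, p=p)))


def plant_segment(rng, host_seq, segment, pos, n_sub):
    """Insert a copy of `segment` with n_sub evenly spread substitutions."""
    seg = list(segment)
    if n_sub:
        positions = np.linspace(3, len(seg) - 4, n_sub).astype(int)
        for p in positions:
            seg[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seg[p]]
    return host_seq[:pos] + "".join(seg) + host_seq[pos + len(seg):]


class TestFindLocalMatches:
    def test_self_alignment(self):
        rng = np.random.default_rng(0)
        t = random_transcript(rng, "t", 200)
        best = find_local_matches(t, [t], mode="sense")[0]
        assert best.length == 200 and best.identity == 1.0
        assert best.q_start == 0 and best.s_start == 0

    def test_reverse_complement_found_antisense(self):
        rng = np.random.default_rng(1)
        t = random_transcript(rng, "t", 200)
        rc = Transcript("rc", reverse_complement(t.seq))
        best = find_local_matches(t, [rc], mode="both")[0]
        assert best.strand == "antisense" and best.length == 200 and best.identity == 1.0

    def test_planted_segment_matches_expectations(self):
        rng = np.random.default_rng(2)
        q = random_transcript(rng, "q", 400)
        s_raw = random_transcript(rng, "s", 400)
        s = Transcript("s", plant_segment(rng, s_raw.seq, q.seq[100:260], 120, 12))
        best = find_local_matches(q, [s], mode="sense", word_size=8)[0]
        assert best.length >= 150
        assert 0.90 <= best.identity <= 0.95

    def test_word_size_floor(self):
        t = Transcript("t", "ACGT" * 30)
        with pytest.raises(ValueError):
            find_local_matches(t, [t], word_size=7)

    def test_empty_subjects(self):
        t = Transcript("t", "ACGT" * 30)
        assert find_local_matches(t, []) == []


class TestOracleEquivalence:
    def test_best_score_equals_diagonal_scan(self):
        """Seed-and-extend equals the exhaustive diagonal/window maximum on
        pairs sharing a planted segment (50 seeded pairs, <= 300 nt)."""
        rng = np.random.default_rng(3)
        for i in range(50):
            L = int(rng.integers(150, 300))
            q = random_transcript(rng, "q", L)
            s_raw = random_transcript(rng, "s", L)
            seg_len = int(rng.integers(60, L - 40))
            n_sub = int(seg_len * rng.uniform(0, 0.08))
            seg = q.seq[20 : 20 + seg_len]
            if rng.random() < 0.5:
                seg = reverse_complement(seg)
            s = Transcript("s", plant_segment(rng, s_raw.seq, seg, 10, n_sub))
            engine = max(
                h.score for h in find_local_matches(q, [s], mode="both", word_size=8)
            )
            oracle = diagonal_scan_best(q.seq, s.seq)
            assert engine == oracle, f"pair {i}: engine {engine} != oracle {oracle}"

    def test_score_symmetry(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            L = int(rng.integers(100, 500))
            a = random_transcript(rng, "a", L)
            b_raw = random_transcript(rng, "b", L)
            b = Transcript("b", plant_segment(rng, b_raw.seq, a.seq[10:90], 15, 4))
            fwd = max(h.score for h in find_local_matches(a, [b], mode="both", word_size=8))
            rev = max(h.score for h in find_local_matches(b, [a], mode="both", word_size=8))
            assert fwd == rev

    def test_antisense_consistency(self):
        """Hits against a reverse-complemented subject equal sense hits with
        the strand flipped and subject coordinates mirrored."""
        rng = np.random.default_rng(5)
        q = random_transcript(rng, "q", 250)
        s_raw = random_transcript(rng, "s", 250)
        s = Transcript("s", plant_segment(rng, s_raw.seq, q.seq[50:200], 40, 8))
        s_rc = Transcript("s", reverse_complement(s.seq))
        sense = find_local_matches(q, [s], mode="both", word_size=8)
        flipped = find_local_matches(q, [s_rc], mode="both", word_size=8)
        n = s.length
        mirrored = {
            (h.q_start, h.q_end, n - h.s_end, n - h.s_start,
             "antisense" if h.strand == "sense" else "sense", h.score)
            for h in flipped
        }
        original = {
            (h.q_start, h.q_end, h.s_start, h.s_end, h.strand, h.score) for h in sense
        }
        assert original == mirrored


class TestClassifyByHomology:
    def make_db(self, rng):
        hairpin = random_transcript(rng, "hp1", 100)
        decoys = [random_transcript(rng, f"d{i}", 120) for i in range(5)]
        return hairpin, decoys

    def test_embedded_reference_is_a_hit(self):
        rng = np.random.default_rng(6)
        hairpin, decoys = self.make_db(rng)
        lnc = Transcript("lnc", "A" * 0 + random_transcript(rng, "x", 150).seq + hairpin.seq + random_transcript(rng, "y", 150).seq)
        hits = classify_by_homology([lnc], [hairpin, *decoys], 0.90, 1e-1)
        assert hits["lnc"] is not None and hits["lnc"].subject_id == "hp1"

    def test_empty_reference_gives_none(self):
        t = Transcript("t", "ACGT" * 60)
        assert classify_by_homology([t], [], 0.90, 1e-1) == {"t": None}

    def test_degraded_copy_below_identity_threshold(self):
        rng = np.random.default_rng(7)
        hairpin, decoys = self.make_db(rng)
        flank5 = random_transcript(rng, "x", 150).seq
        flank3 = random_transcript(rng, "y", 150).seq
        degraded = plant_segment(rng, flank5 + hairpin.seq + flank3, hairpin.seq, 150, 15)
        lnc = Transcript("lnc", degraded)
        hits = classify_by_homology([lnc], [hairpin, *decoys], 0.90, 1e-1, word_size=8)
        assert hits["lnc"] is None

    def test_threshold_monotonicity(self):
        """Raising min_identity or lowering max_evalue never adds hits."""
        rng = np.random.default_rng(8)
        hairpin, decoys = self.make_db(rng)
        queries = []
        for i in range(10):
            host = random_transcript(rng, f"q{i}", 300)
            n_sub = int(rng.integers(0, 14))
            queries.append(Transcript(f"q{i}", plant_segment(rng, host.seq, hairpin.seq, 50, n_sub)))
        db = [hairpin, *decoys]
        base = {q for q, h in classify_by_homology(queries, db, 0.85, 1e-1).items() if h}
        stricter_id = {q for q, h in classify_by_homology(queries, db, 0.95, 1e-1).items() if h}
        stricter_ev = {q for q, h in classify_by_homology(queries, db, 0.85, 1e-6).items() if h}
        assert stricter_id <= base and stricter_ev <= base


class TestTabularImport:
    def test_coordinate_conventions(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(
            "q1\ts1\t100.00\t100\t0\t0\t1\t100\t100\t1\t1e-20\t180\n"
            "q2\ts2\t95.00\t80\t4\t2\t5\t84\t10\t89\t1e-5\t90\n"
        )
        first, second = import_tabular_alignments(path)
        assert first.strand == "antisense" and (first.s_start, first.s_end) == (0, 100)
        assert first.identity == 1.0 and not first.gapped
        assert second.gapped and second.strand == "sense"
        assert (second.q_start, second.q_end) == (4, 84)

    def test_malformed_row_reports_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("q1\ts1\t100.0\n")
        with pytest.raises(ValueError, match="1"):
            import_tabular_alignments(path)

    def test_export_import_round_trip(self, tmp_path):
        rng = np.random.default_rng(9)
        t = random_transcript(rng, "t", 200)
        hits = find_local_matches(t, [Transcript("s", t.seq)], mode="sense")
        path = tmp_path / "out.tsv"
        export_tabular_alignments(hits, path)
        back = import_tabular_alignments(path)
        assert back[0].identity == 1.0
        assert (back[0].q_start, back[0].q_end) == (hits[0].q_start, hits[0].q_end)


def test_evalue_decreases_with_score():
    scoring = ScoringParams()
    evs = [scoring.evalue(s, 300, 300) for s in range(10, 60, 10)]
    assert all(a > b for a, b in zip(evs, evs[1:]))
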