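"""Internal seed-and-extend ungapped local aligner and homology classifier.

Desk-scale stand-in for BLASTn-style searches: exact-word seeds are extended
ungapped in both directions with an X-drop criterion, overlapping extensions
on one diagonal are merged to the maximal-scoring window, and significance is
scored with a Karlin-Altschul style e-value E = K * m * n * exp(-lambda * S),
where n is the total reference-set length.  The constants mimic, but do not
reproduce, BLASTn.  Gapped alignment is delegated to the tabular import path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

from .core import Transcript, reverse_complement

Mode = Literal["sense", "antisense", "both"]

X_DROP = 20  # score units
MIN_WORD_SIZE = 8


@dataclass(frozen=True)
class ScoringParams:
    """Match/mismatch scores and Karlin-Altschul constants.

    Defaults (+1/-2 with lambda=1.28, K=0.46) approximate ungapped BLASTn
    statistics for that scoring scheme.
    """

    match: int = 1
    mismatch: int = -2
    lambda_ka: float = 1.28
    k_ka: float = 0.46

    def __post_init__(self) -> None:
        if not (self.match > 0 > self.mismatch):
            raise ValueError("require match > 0 > mismatch")
        if self.lambda_ka <= 0 or self.k_ka <= 0:
            raise ValueError("Karlin-Altschul constants must be positive")

    def evalue(self, score: int, m: int, n: int) -> float:
        return self.k_ka * m * n * math.exp(-self.lambda_ka * score)


@dataclass(frozen=True)
class LocalMatch:
    """One ungapped local alignment window between two sequences.

    Coordinates are 0-based half-open on the *forward* strand of both
    sequences; ``strand == "antisense"`` means the query window matches the
    reverse complement of the subject window.
    """

    query_id: str
    subject_id: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: Literal["sense", "antisense"]
    length: int
    identity: float
    score: int
    evalue: float
    gapped: bool = False

    def __post_init__(self) -> None:
        if not self.gapped:
            if self.q_end - self.q_start != self.length or self.s_end - self.s_start != self.length:
                raise ValueError("ungapped match: window lengths must equal length")
        if not (0.0 <= self.identity <= 1.0):
            raise ValueError("identity must be in [0, 1]")


def _seed_positions(seq: str, word_size: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for j in range(len(seq) - word_size + 1):
        word = seq[j : j + word_size]
        if "N" in word:
            continue
        index.setdefault(word, []).append(j)
    return index


def best_windows_on_seeded_diagonals(
    query: str,
    subject: str,
    scoring: ScoringParams = ScoringParams(),
    word_size: int = 11,
) -> list[tuple[int, int, int, int, int]]:
    """Seed, extend with X-drop, merge per diagonal.

    Returns one window per seeded diagonal as
    (q_start, length, matches, score, s_start); N never matches anything.
    """
    return _windows_with_subject_coords(query, subject, scoring, word_size)


def _bases_match(a: str, b: str) -> bool:
    return a == b and a != "N"


def find_local_matches(
    query: Transcript,
    subjects: Sequence[Transcript],
    scoring: ScoringParams = ScoringParams(),
    mode: Mode = "both",
    word_size: int = 11,
    db_length: int | None = None,
) -> list[LocalMatch]:
    """All maximal ungapped windows between the query and each subject.

    One window per seeded diagonal and orientation.  ``db_length`` overrides
    the search-space subject length used for e-values (defaults to the total
    length of ``subjects``).
    """
    if word_size < MIN_WORD_SIZE:
        raise ValueError(f"word_size must be >= {MIN_WORD_SIZE}")
    if mode not in ("sense", "antisense", "both"):
        raise ValueError(f"unknown mode {mode!r}")
    n_total = db_length if db_length is not None else sum(s.length for s in subjects)
    results: list[LocalMatch] = []
    for subject in subjects:
        orientations: list[str] = (
            ["sense", "antisense"] if mode == "both" else [mode]
        )
        for strand in orientations:
            sseq = subject.seq if strand == "sense" else reverse_complement(subject.seq)
            for q_start, length, matches, score, s_start in _windows_with_subject_coords(
                query.seq, sseq, scoring, word_size
            ):
                if strand == "sense":
                    s0, s1 = s_start, s_start + length
                else:
                    s0, s1 = subject.length - (s_start + length), subject.length - s_start
                results.append(
                    LocalMatch(
                        query_id=query.id,
                        subject_id=subject.id,
                        q_start=q_start,
                        q_end=q_start + length,
                        s_start=s0,
                        s_end=s1,
                        strand=strand,  # type: ignore[arg-type]
                        length=length,
                        identity=matches / length if length else 0.0,
                        score=score,
                        evalue=scoring.evalue(score, query.length, max(n_total, 1)),
                    )
                )
    results.sort(key=lambda h: (-h.score, h.evalue, h.subject_id, h.q_start))
    return results


def _windows_with_subject_coords(
    query: str, subject: str, scoring: ScoringParams, word_size: int
) -> list[tuple[int, int, int, int, int]]:
    """Like best_windows_on_seeded_diagonals but returning subject starts."""
    index = _seed_positions(subject, word_size)
    m, n = len(query), len(subject)
    seeds_by_diag: dict[int, list[int]] = {}
    for i in range(m - word_size + 1):
        word = query[i : i + word_size]
        if "N" in word:
            continue
        for j in index.get(word, ()):
            seeds_by_diag.setdefault(i - j, []).append(i)
    out: list[tuple[int, int, int, int, int]] = []
    for d in sorted(seeds_by_diag):
        window = _best_window_on_diagonal(
            query, subject, d, seeds_by_diag[d], scoring, word_size
        )
        if window is not None:
            q_start, length, matches, score = window
            out.append((q_start, length, matches, score, q_start - d))
    return out


def _best_window_on_diagonal(
    query: str,
    subject: str,
    d: int,
    seed_starts: list[int],
    scoring: ScoringParams,
    word_size: int,
    x_drop: int = X_DROP,
) -> tuple[int, int, int, int] | None:
    m, n = len(query), len(subject)
    lo, hi = max(0, d), min(m, n + d)
    match, mismatch = scoring.match, scoring.mismatch
    best: tuple[int, int, int, int] | None = None  # (score, -q_start, q_end, matches)
    done_upto = lo - 1
    for i0 in sorted(seed_starts):
        if i0 + word_size <= done_upto:
            continue
        score = word_size * match
        best_right, best_score_r = i0 + word_size, score
        cur = score
        for i in range(i0 + word_size, hi):
            cur += match if _bases_match(query[i], subject[i - d]) else mismatch
            if cur > best_score_r:
                best_score_r, best_right = cur, i + 1
            elif best_score_r - cur > x_drop:
                break
        best_left, best_score = i0, best_score_r
        cur = best_score_r
        for i in range(i0 - 1, lo - 1, -1):
            cur += match if _bases_match(query[i], subject[i - d]) else mismatch
            if cur > best_score:
                best_score, best_left = cur, i
            elif best_score - cur > x_drop:
                break
        done_upto = max(done_upto, best_right)
        matches = sum(
            1 for i in range(best_left, best_right) if _bases_match(query[i], subject[i - d])
        )
        cand = (best_score, -best_left, best_right, matches)
        if best is None or cand > best:
            best = cand
    if best is None:
        return None
    score, neg_qs, q_end, matches = best
    return (-neg_qs, q_end - (-neg_qs), matches, score)


def classify_by_homology(
    queries: Sequence[Transcript],
    reference_db: Sequence[Transcript],
    min_identity: float,
    max_evalue: float,
    mode: Mode = "both",
    scoring: ScoringParams = ScoringParams(),
    word_size: int = 11,
) -> dict[str, LocalMatch | None]:
    """Best qualifying hit per query, or None.

    A query is a hit iff some match has identity >= min_identity AND
    evalue <= max_evalue.  Best = highest score, ties broken by lowest
    e-value then lexicographic subject id (total, deterministic order).
    """
    if not (0.0 < min_identity <= 1.0):
        raise ValueError("min_identity must be in (0, 1]")
    if max_evalue <= 0:
        raise ValueError("max_evalue must be positive")
    out: dict[str, LocalMatch | None] = {}
    for q in queries:
        hits = [
            h
            for h in find_local_matches(q, reference_db, scoring, mode, word_size)
            if h.identity >= min_identity and h.evalue <= max_evalue
        ]
        out[q.id] = min(hits, key=lambda h: (-h.score, h.evalue, h.subject_id)) if hits else None
    return out


TABULAR_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def import_tabular_alignments(path: str | Path) -> list[LocalMatch]:
    """Import BLAST outfmt-6 style rows (1-based inclusive coordinates).

    sstart > send encodes an antisense hit.  Rows with gap openings are
    retained but flagged ``gapped`` (downstream NAT logic excludes them).
    """
    matches: list[LocalMatch] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(f"{path}:{lineno}: expected 12 columns, got {len(fields)}")
            try:
                qid, sid = fields[0], fields[1]
                pident = float(fields[2])
                length = int(fields[3])
                gapopen = int(fields[5])
                qstart, qend = int(fields[6]), int(fields[7])
                sstart, send = int(fields[8]), int(fields[9])
                evalue = float(fields[10])
                bitscore = float(fields[11])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed row ({exc})") from None
            if sstart > send:
                strand, s0, s1 = "antisense", send - 1, sstart
            else:
                strand, s0, s1 = "sense", sstart - 1, send
            matches.append(
                LocalMatch(
                    query_id=qid,
                    subject_id=sid,
                    q_start=qstart - 1,
                    q_end=qend,
                    s_start=s0,
                    s_end=s1,
                    strand=strand,  # type: ignore[arg-type]
                    length=length,
                    identity=pident / 100.0,
                    score=int(round(bitscore)),
                    evalue=evalue,
                    gapped=gapopen > 0,
                )
            )
    return matches


def export_tabular_alignments(matches: Iterable[LocalMatch], path: str | Path) -> None:
    """Write matches in the 12-column tabular dialect (1-based inclusive)."""
    with open(path, "w") as fh:
        for h in matches:
            if h.strand == "sense":
                sstart, send = h.s_start + 1, h.s_end
            else:
                sstart, send = h.s_end, h.s_start + 1
            mismatches = round(h.length * (1 - h.identity))
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        h.query_id, h.subject_id, f"{h.identity * 100:.2f}", h.length,
                        mismatches, 1 if h.gapped else 0, h.q_start + 1, h.q_end,
                        sstart, send, f"{h.evalue:.3g}", h.score,
                    )
                )
                + "\n"
            )


def best_match_score(query: Transcript, subject: Transcript, **kwargs) -> int:
    """Convenience: score of the best ungapped window (0 if none found)."""
    hits = find_local_matches(query, [subject], **kwargs)
    return hits[0].score if hits else 0
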