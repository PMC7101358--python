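"""MISA-style perfect microsatellite (SSR) detection.

Searches primitive 2-6 nt motifs with per-length minimum repeat counts
(6, 5, 5, 4, 4 by default).  Only perfect tandem runs are reported;
compound/interrupted SSRs and mononucleotide runs are out of scope.
Sub-period re-descriptions (e.g. (AT)6 re-read as (ATAT)3) are suppressed
because non-primitive motifs are never considered.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .core import Transcript, reverse_complement

DEFAULT_MIN_REPEATS: dict[int, int] = {2: 6, 3: 5, 4: 5, 5: 4, 6: 4}


def is_primitive(motif: str) -> bool:
    """True iff the motif is not a repetition of a shorter motif."""
    k = len(motif)
    for d in range(1, k):
        if k % d == 0 and motif == motif[:d] * (k // d):
            return False
    return True


def _rotations(motif: str) -> list[str]:
    return [motif[i:] + motif[:i] for i in range(len(motif))]


def canonical_motif(motif: str) -> str:
    """Canonical class label in the "AG/CT" style.

    The class representative is the lexicographically smallest string among
    all rotations of the motif and of its reverse complement; the label is
    "<representative>/<its reverse complement>".  Invariant under rotation
    and reverse complement of the argument.
    """
    if not (2 <= len(motif) <= 6):
        raise ValueError(f"motif length must be 2-6, got {motif!r}")
    if not is_primitive(motif):
        raise ValueError(f"motif {motif!r} is not primitive")
    candidates = _rotations(motif) + _rotations(reverse_complement(motif))
    rep = min(candidates)
    return f"{rep}/{reverse_complement(rep)}"


@dataclass(frozen=True)
class SsrLocus:
    """One perfect tandem repeat; coordinates 0-based half-open."""

    transcript_id: str
    motif: str
    canonical: str
    repeat_count: int
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.motif) * self.repeat_count:
            raise ValueError("locus span must equal motif_length * repeat_count")

    @property
    def motif_length(self) -> int:
        return len(self.motif)


def find_ssrs(
    transcript: Transcript,
    min_repeats: Mapping[int, int] = DEFAULT_MIN_REPEATS,
) -> list[SsrLocus]:
    """Every maximal perfect tandem run of a primitive motif meeting its
    per-length minimum repeat count, sorted by start."""
    if any(not (2 <= k <= 6) for k in min_repeats):
        raise ValueError("min_repeats keys must be motif lengths 2-6")
    seq = transcript.seq
    L = len(seq)
    loci: list[SsrLocus] = []
    for k in sorted(min_repeats):
        threshold = min_repeats[k]
        i = 0
        while i + k * threshold <= L:
            motif = seq[i : i + k]
            if "N" in motif or not is_primitive(motif):
                i += 1
                continue
            j = i + k
            while seq[j : j + k] == motif:
                j += k
            count = (j - i) // k
            # left-maximality: a run continuing a full period leftwards was
            # already visited at an earlier start
            left_maximal = i < k or seq[i - k : i] != motif
            if count >= threshold and left_maximal:
                loci.append(
                    SsrLocus(transcript.id, motif, canonical_motif(motif), count, i, i + k * count)
                )
                i = i + k * count
            else:
                i += 1
    loci.sort(key=lambda s: (s.start, s.motif_length))
    return loci


@dataclass
class SsrSummary:
    n_loci: int
    n_transcripts_with_ssr: int
    by_motif_length: dict[int, int]
    by_motif_length_pct: dict[int, float]
    by_canonical: dict[str, int]
    by_canonical_pct: dict[str, float]


def ssr_summary(loci: Sequence[SsrLocus]) -> SsrSummary:
    """Composition by motif length and canonical class (percentages over all
    loci); transcripts with one or more loci are counted once."""
    n = len(loci)
    by_len: dict[int, int] = {}
    by_canon: dict[str, int] = {}
    for locus in loci:
        by_len[locus.motif_length] = by_len.get(locus.motif_length, 0) + 1
        by_canon[locus.canonical] = by_canon.get(locus.canonical, 0) + 1
    pct = lambda c: (100.0 * c / n) if n else 0.0
    return SsrSummary(
        n_loci=n,
        n_transcripts_with_ssr=len({s.transcript_id for s in loci}),
        by_motif_length={k: by_len.get(k, 0) for k in range(2, 7)},
        by_motif_length_pct={k: pct(by_len.get(k, 0)) for k in range(2, 7)},
        by_canonical=dict(sorted(by_canon.items())),
        by_canonical_pct={c: pct(v) for c, v in sorted(by_canon.items())},
    )


def write_ssr_report(loci: Iterable[SsrLocus], path: str | Path) -> None:
    """MISA-like TSV; coordinates 1-based inclusive in the report."""
    with open(path, "w") as fh:
        fh.write("id\tssr_nr\tmotif\tcanonical\tsize\tstart\tend\trepeat_count\n")
        counter: dict[str, int] = {}
        for s in loci:
            counter[s.transcript_id] = counter.get(s.transcript_id, 0) + 1
            fh.write(
                f"{s.transcript_id}\t{counter[s.transcript_id]}\t{s.motif}\t{s.canonical}\t"
                f"{s.motif_length}\t{s.start + 1}\t{s.end}\t{s.repeat_count}\n"
            )
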