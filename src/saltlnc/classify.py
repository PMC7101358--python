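"""lncRNA identification: length filter, coding-potential union rule,
homology subclassification with pre-miRNA / conserved-lncRNA rescue,
greedy redundancy removal and transposon flagging.

Decision order per transcript:

1. length < 200 nt            -> TOO_SHORT
2. coding potential           -> CODING      (protein hit OR long ORF OR hexamer score)
3. hairpin-precursor homology -> PRE_MIRNA_LNCRNA   (rescue, before step 5)
4. conserved-lncRNA homology  -> CONSERVED_LNCRNA   (rescue, before step 5)
5. known-ncRNA homology       -> KNOWN_SRNA  (excluded from the lncRNA set)
6. otherwise                  -> LNCRNA

The final lncRNA reference is the union of PRE_MIRNA_LNCRNA,
CONSERVED_LNCRNA and LNCRNA.  Steps 3-4 running before 5 implement the
rescue of probable miRNA precursors and conserved lncRNAs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Literal, NamedTuple, Sequence

import numpy as np
from Bio.Seq import Seq

from .align import LocalMatch, ScoringParams, _windows_with_subject_coords, classify_by_homology
from .core import Transcript, reverse_complement

TOO_SHORT = "TOO_SHORT"
CODING = "CODING"
KNOWN_SRNA = "KNOWN_SRNA"
PRE_MIRNA_LNCRNA = "PRE_MIRNA_LNCRNA"
CONSERVED_LNCRNA = "CONSERVED_LNCRNA"
LNCRNA = "LNCRNA"

ALL_LABELS = (TOO_SHORT, CODING, KNOWN_SRNA, PRE_MIRNA_LNCRNA, CONSERVED_LNCRNA, LNCRNA)
#: labels that make up the final lncRNA reference set
LNCRNA_LABELS = frozenset({PRE_MIRNA_LNCRNA, CONSERVED_LNCRNA, LNCRNA})

MIN_LNCRNA_LENGTH = 200
HOMOLOGY_MIN_IDENTITY = 0.90
HOMOLOGY_MAX_EVALUE = 1e-1
PROTEIN_MAX_EVALUE = 1e-5

STOP_CODONS = {"TAA", "TAG", "TGA"}
Frame = Literal[1, 2, 3, -1, -2, -3]


@dataclass(frozen=True)
class OrfHit:
    """An open reading frame; coordinates on the forward strand, half-open.

    Complete ORFs span ATG..stop inclusive of the stop codon, so
    aa_length == (end - start) / 3 - 1.  Partial hits are the longest
    stop-free codon run of a frame (no start/stop requirement).
    """

    frame: int
    start: int
    end: int
    aa_length: int
    partial: bool = False

    def __post_init__(self) -> None:
        if (self.end - self.start) % 3 != 0:
            raise ValueError("ORF span must be a whole number of codons")


def _forward_frame_orfs(seq: str, offset: int) -> list[tuple[int, int, int]]:
    """(start, end, aa_length) of all complete ORFs in one forward frame."""
    orfs = []
    open_starts: list[int] = []
    for pos in range(offset, len(seq) - 2, 3):
        codon = seq[pos : pos + 3]
        if codon == "ATG":
            open_starts.append(pos)
        elif codon in STOP_CODONS:
            for s in open_starts:
                orfs.append((s, pos + 3, (pos + 3 - s) // 3 - 1))
            open_starts = []
    return orfs


def _longest_stop_free(seq: str, offset: int) -> tuple[int, int]:
    """(start, end) of the longest stop-free codon run in one forward frame."""
    best = (offset, offset)
    run_start = offset
    pos = offset
    for pos in range(offset, len(seq) - 2, 3):
        if seq[pos : pos + 3] in STOP_CODONS:
            if pos - run_start > best[1] - best[0]:
                best = (run_start, pos)
            run_start = pos + 3
    end = offset + ((len(seq) - offset) // 3) * 3
    if end - run_start > best[1] - best[0]:
        best = (run_start, end)
    return best


def find_orfs(transcript: Transcript) -> list[OrfHit]:
    """All complete ATG->stop ORFs in six frames, plus the longest stop-free
    span per frame flagged partial."""
    if transcript.length < 3:
        raise ValueError("sequence too short for ORF search")
    L = transcript.length
    hits: list[OrfHit] = []
    for strand, seq in ((1, transcript.seq), (-1, reverse_complement(transcript.seq))):
        for offset in range(3):
            frame = strand * (offset + 1)
            for s, e, aa in _forward_frame_orfs(seq, offset):
                if strand == 1:
                    hits.append(OrfHit(frame, s, e, aa))
                else:
                    hits.append(OrfHit(frame, L - e, L - s, aa))
            s, e = _longest_stop_free(seq, offset)
            if e > s:
                aa = (e - s) // 3
                if strand == 1:
                    hits.append(OrfHit(frame, s, e, aa, partial=True))
                else:
                    hits.append(OrfHit(frame, L - e, L - s, aa, partial=True))
    hits.sort(key=lambda h: (-h.aa_length, h.partial, h.start, h.frame))
    return hits


def longest_complete_orf(transcript: Transcript) -> OrfHit | None:
    complete = [h for h in find_orfs(transcript) if not h.partial]
    return complete[0] if complete else None


HEXAMERS = ["".join(p) for p in itertools.product("ACGT", repeat=6)]


@dataclass
class CodingModel:
    """Hexamer log-odds stand-in for coding-potential feature scoring."""

    hexamer_logodds: dict[str, float]
    pseudocount: float = 1.0
    min_orf_aa: int = 100

    def score(self, hexamer: str) -> float:
        return self.hexamer_logodds.get(hexamer, 0.0)

    def mean_orf_score(self, orf_seq: str) -> float:
        """Mean log-odds over in-frame hexamers of an ORF sequence."""
        scores = [self.score(orf_seq[i : i + 6]) for i in range(0, len(orf_seq) - 5, 3)]
        return float(np.mean(scores)) if scores else 0.0


def _hexamer_freqs(seqs: Iterable[str], step: int) -> dict[str, float]:
    counts: dict[str, int] = {}
    total = 0
    for seq in seqs:
        for i in range(0, len(seq) - 5, step):
            h = seq[i : i + 6]
            if "N" in h:
                continue
            counts[h] = counts.get(h, 0) + 1
            total += 1
    if total == 0:
        return {}
    return {h: c / total for h, c in counts.items()}


def train_hexamer_model(
    coding_set: Sequence[str],
    background_set: Sequence[str],
    pseudocount: float = 1.0,
    min_orf_aa: int = 100,
) -> CodingModel:
    """s(h) = log2((freq_coding(h) + pc) / (freq_background(h) + pc)).

    Coding frequencies are over in-frame (frame +1) hexamers of the coding
    ORF sequences; background frequencies are over all-frame hexamers.
    """
    if not coding_set or not background_set:
        raise ValueError("both training sets must be non-empty")
    fc = _hexamer_freqs(coding_set, step=3)
    fb = _hexamer_freqs(background_set, step=1)
    logodds = {
        h: float(np.log2((fc.get(h, 0.0) + pseudocount) / (fb.get(h, 0.0) + pseudocount)))
        for h in set(fc) | set(fb)
    }
    return CodingModel(logodds, pseudocount, min_orf_aa)


class ProteinSeq(NamedTuple):
    """A reference protein (amino-acid sequence)."""

    id: str
    seq: str


def translate_frames(transcript: Transcript) -> dict[int, str]:
    """Six-frame translation; ambiguous codons become X."""
    out: dict[int, str] = {}
    for strand, seq in ((1, transcript.seq), (-1, reverse_complement(transcript.seq))):
        for offset in range(3):
            trimmed = seq[offset : offset + ((len(seq) - offset) // 3) * 3]
            aa = str(Seq(trimmed).translate()) if trimmed else ""
            out[strand * (offset + 1)] = aa.replace("*", "X")
    return out


def protein_search(
    transcripts: Sequence[Transcript],
    protein_db: Sequence[ProteinSeq],
    max_evalue: float = PROTEIN_MAX_EVALUE,
    scoring: ScoringParams = ScoringParams(),
    word_size: int = 4,
) -> dict[str, LocalMatch | None]:
    """Six-frame translated search against a protein set.

    Exact amino-acid word seeding with ungapped identity-scored extension;
    the e-value reuses the nucleotide-scale Karlin-Altschul mimic.  Returns
    the best hit with evalue <= max_evalue per transcript (or None).
    """
    n_total = sum(len(p.seq) for p in protein_db)
    out: dict[str, LocalMatch | None] = {}
    for t in transcripts:
        best: LocalMatch | None = None
        for frame, aa in translate_frames(t).items():
            if len(aa) < word_size:
                continue
            for prot in protein_db:
                for q_start, length, matches, score, s_start in _windows_with_subject_coords(
                    aa, prot.seq, scoring, word_size
                ):
                    ev = scoring.evalue(score, len(aa), max(n_total, 1))
                    if ev > max_evalue:
                        continue
                    hit = LocalMatch(
                        query_id=t.id,
                        subject_id=prot.id,
                        q_start=q_start,
                        q_end=q_start + length,
                        s_start=s_start,
                        s_end=s_start + length,
                        strand="sense" if frame > 0 else "antisense",
                        length=length,
                        identity=matches / length,
                        score=score,
                        evalue=ev,
                    )
                    if best is None or (-hit.score, hit.evalue, hit.subject_id) < (
                        -best.score, best.evalue, best.subject_id
                    ):
                        best = hit
        out[t.id] = best
    return out


def coding_potential(
    transcript: Transcript,
    model: CodingModel | None,
    protein_hit: LocalMatch | None,
    min_orf_aa: int = 100,
) -> tuple[str, float]:
    """Union rule: coding iff protein homology (evalue <= 1e-5) OR a complete
    ORF of >= min_orf_aa codons OR positive mean hexamer score over the
    longest ORF (the last only when a trained model is supplied).

    Returns ("coding" | "noncoding", score) where score is the hexamer mean
    over the longest complete ORF (0.0 if none).
    """
    if model is not None:
        min_orf_aa = model.min_orf_aa
    orf = longest_complete_orf(transcript)
    hex_score = 0.0
    if orf is not None and model is not None:
        if orf.frame > 0:
            orf_seq = transcript.seq[orf.start : orf.end]
        else:
            orf_seq = reverse_complement(transcript.seq[orf.start : orf.end])
        hex_score = model.mean_orf_score(orf_seq)
    if protein_hit is not None and protein_hit.evalue <= PROTEIN_MAX_EVALUE:
        return "coding", hex_score
    if orf is not None and orf.aa_length >= min_orf_aa:
        return "coding", hex_score
    if model is not None and orf is not None and hex_score > 0:
        return "coding", hex_score
    return "noncoding", hex_score


@dataclass
class ReferenceSets:
    """Reference databases driving homology subclassification."""

    protein_db: list[ProteinSeq] = field(default_factory=list)
    hairpin_db: list[Transcript] = field(default_factory=list)
    conserved_db: list[Transcript] = field(default_factory=list)
    ncrna_db: list[Transcript] = field(default_factory=list)
    transposon_db: list[Transcript] = field(default_factory=list)


@dataclass
class TranscriptClass:
    label: str
    evidence: list[tuple[str, object]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.label not in ALL_LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if self.label != LNCRNA and not self.evidence:
            raise ValueError(f"label {self.label} requires evidence")


def classify_transcripts(
    transcripts: Sequence[Transcript],
    refs: ReferenceSets,
    model: CodingModel | None = None,
    min_length: int = MIN_LNCRNA_LENGTH,
    min_identity: float = HOMOLOGY_MIN_IDENTITY,
    max_evalue: float = HOMOLOGY_MAX_EVALUE,
    min_orf_aa: int = 100,
    word_size: int = 11,
) -> dict[str, TranscriptClass]:
    """Assign exactly one label per transcript (see module docstring)."""
    long_enough = [t for t in transcripts if t.length >= min_length]
    protein_hits = (
        protein_search(long_enough, refs.protein_db) if refs.protein_db else {}
    )
    result: dict[str, TranscriptClass] = {}
    noncoding: list[Transcript] = []
    for t in transcripts:
        if t.length < min_length:
            result[t.id] = TranscriptClass(TOO_SHORT, [("length", t.length)])
            continue
        verdict, score = coding_potential(t, model, protein_hits.get(t.id), min_orf_aa)
        if verdict == "coding":
            ev: list[tuple[str, object]] = []
            if protein_hits.get(t.id) is not None:
                ev.append(("protein_hit", protein_hits[t.id]))
            orf = longest_complete_orf(t)
            if orf is not None:
                ev.append(("longest_orf", orf))
            if score > 0:
                ev.append(("hexamer_score", score))
            result[t.id] = TranscriptClass(CODING, ev)
            continue
        noncoding.append(t)

    homology_args = dict(min_identity=min_identity, max_evalue=max_evalue, word_size=word_size)
    hairpin_hits = classify_by_homology(noncoding, refs.hairpin_db, **homology_args)
    conserved_hits = classify_by_homology(noncoding, refs.conserved_db, **homology_args)
    ncrna_hits = classify_by_homology(noncoding, refs.ncrna_db, **homology_args)
    for t in noncoding:
        if hairpin_hits[t.id] is not None:
            result[t.id] = TranscriptClass(PRE_MIRNA_LNCRNA, [("hairpin_hit", hairpin_hits[t.id])])
        elif conserved_hits[t.id] is not None:
            result[t.id] = TranscriptClass(
                CONSERVED_LNCRNA, [("conserved_hit", conserved_hits[t.id])]
            )
        elif ncrna_hits[t.id] is not None:
            result[t.id] = TranscriptClass(KNOWN_SRNA, [("ncrna_hit", ncrna_hits[t.id])])
        else:
            result[t.id] = TranscriptClass(LNCRNA)
    return result


def lncrna_ids(classes: dict[str, TranscriptClass]) -> set[str]:
    """The final lncRNA reference: union of the three lncRNA labels."""
    return {tid for tid, c in classes.items() if c.label in LNCRNA_LABELS}


def deduplicate_transcripts(
    transcripts: Sequence[Transcript],
    identity_threshold: float = 0.90,
    coverage_threshold: float = 0.80,
    word_size: int = 11,
) -> tuple[list[Transcript], dict[str, str]]:
    """Greedy longest-first clustering (CD-HIT-EST-style, simplified).

    A sequence joins an existing cluster iff its best match against the
    representative has identity >= identity_threshold over a window covering
    >= coverage_threshold of its own length; otherwise it founds a cluster.
    Returns (representatives, member_id -> representative_id).
    """
    if not (0 < identity_threshold <= 1 and 0 < coverage_threshold <= 1):
        raise ValueError("thresholds must be in (0, 1]")
    from .align import find_local_matches

    ordered = sorted(
        range(len(transcripts)), key=lambda i: (-transcripts[i].length, i)
    )
    reps: list[Transcript] = []
    assignment: dict[str, str] = {}
    for i in ordered:
        t = transcripts[i]
        placed = False
        for rep in reps:
            hits = find_local_matches(t, [rep], mode="both", word_size=word_size)
            for h in hits:
                if h.identity >= identity_threshold and h.length >= coverage_threshold * t.length:
                    assignment[t.id] = rep.id
                    placed = True
                    break
            if placed:
                break
        if not placed:
            reps.append(t)
            assignment[t.id] = t.id
    return reps, assignment


def flag_transposons(
    transcripts: Sequence[Transcript],
    transposon_db: Sequence[Transcript],
    min_identity: float = HOMOLOGY_MIN_IDENTITY,
    max_evalue: float = HOMOLOGY_MAX_EVALUE,
    word_size: int = 11,
) -> set[str]:
    """Ids of transcripts matching the transposon set at (0.90, 1e-1).

    The flag is an annotation; it never changes a transcript's class.
    """
    hits = classify_by_homology(
        transcripts, transposon_db, min_identity, max_evalue, word_size=word_size
    )
    return {tid for tid, h in hits.items() if h is not None}
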