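"""Transcript records, FASTA / count-matrix I/O and descriptive statistics.

Coordinates are 0-based half-open on the forward strand everywhere inside the
package; report files use 1-based inclusive (BLAST-like) coordinates.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: maximum tolerated fraction of ambiguous bases in a transcript
MAX_N_FRACTION = 0.10


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    """GC fraction over non-N bases (0.0 for an all-N or empty sequence)."""
    denom = len(seq) - seq.count("N")
    if denom == 0:
        return 0.0
    return (seq.count("G") + seq.count("C")) / denom


@dataclass(frozen=True)
class Transcript:
    """One assembled transcript: the unit flowing through every stage."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("transcript id must be non-empty")
        bad = set(self.seq) - set("ACGTN")
        if bad:
            raise ValueError(f"transcript {self.id!r}: non-IUPAC-DNA characters {sorted(bad)}")
        if self.seq and self.seq.count("N") / len(self.seq) > MAX_N_FRACTION:
            raise ValueError(f"transcript {self.id!r}: more than {MAX_N_FRACTION:.0%} N bases")

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def gc_fraction(self) -> float:
        return gc_fraction(self.seq)

    def reverse_complement(self) -> "Transcript":
        return Transcript(self.id, reverse_complement(self.seq))


def normalize_sequence(raw: str) -> str:
    """Upper-case and map RNA U to DNA T."""
    return raw.upper().replace("U", "T")


def _check_unique_ids(transcripts: Iterable[Transcript]) -> None:
    seen: set[str] = set()
    for t in transcripts:
        if t.id in seen:
            raise ValueError(f"duplicate transcript id: {t.id!r}")
        seen.add(t.id)


def read_fasta(path: str | Path) -> list[Transcript]:
    """Read a (multi-)FASTA file into Transcript records.

    The header token before the first whitespace is the id.  Sequences are
    upper-cased and U is mapped to T.  Duplicate ids are a hard error.
    """
    path = Path(path)
    records = [
        Transcript(rec.id, normalize_sequence(str(rec.seq)))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        logger.warning("FASTA file %s contains no records", path)
    _check_unique_ids(records)
    return records


def write_fasta(transcripts: Sequence[Transcript], path: str | Path, width: int = 70) -> None:
    """Write transcripts in input order, wrapped at `width` columns."""
    with open(path, "w") as fh:
        for t in transcripts:
            fh.write(f">{t.id}\n")
            for i in range(0, t.length, width):
                fh.write(t.seq[i : i + width] + "\n")


CULTIVARS = ("Ghazvini", "Sarakhs")
TIMEPOINTS_H = (0, 6, 24)

# compact paper-style names: Gc, Gt6, Gt24, Sc, St6
_COMPACT_RE = re.compile(r"^([GS])(c|t(\d+))$")
_VERBOSE_RE = re.compile(r"^(Ghazvini|Sarakhs)_(\d+)h$", re.IGNORECASE)


@dataclass(frozen=True)
class SampleMeta:
    name: str
    cultivar: str
    timepoint_h: int

    def __post_init__(self) -> None:
        if self.cultivar not in CULTIVARS:
            raise ValueError(f"unknown cultivar {self.cultivar!r}")
        if self.timepoint_h not in TIMEPOINTS_H:
            raise ValueError(f"unknown timepoint {self.timepoint_h!r}")


def parse_sample_name(name: str) -> SampleMeta:
    """Parse cultivar/timepoint metadata from a sample name.

    Accepts the compact style used in the study (``Gc``, ``Gt6``, ``Gt24``,
    ``Sc``, ``St6``) and a verbose ``<cultivar>_<timepoint>h`` style.
    """
    m = _COMPACT_RE.match(name)
    if m:
        cultivar = "Ghazvini" if m.group(1) == "G" else "Sarakhs"
        tp = 0 if m.group(2) == "c" else int(m.group(3))
        return SampleMeta(name, cultivar, tp)
    m = _VERBOSE_RE.match(name)
    if m:
        return SampleMeta(name, m.group(1).capitalize(), int(m.group(2)))
    raise ValueError(f"cannot parse sample metadata from name {name!r}")


@dataclass
class CountMatrix:
    """Raw counts per (transcript, sample)."""

    transcript_ids: list[str]
    samples: list[SampleMeta]
    counts: np.ndarray  # shape (n_transcripts, n_samples), non-negative ints

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.transcript_ids), len(self.samples)):
            raise ValueError("counts shape does not match ids/samples")
        if not np.issubdtype(self.counts.dtype, np.integer):
            raise ValueError("counts must be integers")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if len(set(self.transcript_ids)) != len(self.transcript_ids):
            raise ValueError("duplicate transcript ids in count matrix")
        names = [s.name for s in self.samples]
        if len(set(names)) != len(names):
            raise ValueError("duplicate sample names in count matrix")
        keys = [(s.cultivar, s.timepoint_h) for s in self.samples]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (cultivar, timepoint) in count matrix")

    @property
    def sample_names(self) -> list[str]:
        return [s.name for s in self.samples]

    def column(self, sample_name: str) -> np.ndarray:
        try:
            j = self.sample_names.index(sample_name)
        except ValueError:
            raise KeyError(f"sample {sample_name!r} not in matrix") from None
        return self.counts[:, j]

    def library_sizes(self) -> dict[str, int]:
        return {s.name: int(self.counts[:, j].sum()) for j, s in enumerate(self.samples)}


def read_count_matrix(path: str | Path, metadata_path: str | Path | None = None) -> CountMatrix:
    """Read a TSV count matrix (first column ``transcript_id``, then samples).

    Sample metadata is parsed from the column names unless a sidecar TSV with
    columns (name, cultivar, timepoint_h) is given.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected a transcript_id column plus sample columns")
    ids = df.iloc[:, 0].tolist()
    sample_names = list(df.columns[1:])
    counts = np.empty((len(ids), len(sample_names)), dtype=np.int64)
    for j, col in enumerate(sample_names):
        for i, cell in enumerate(df[col]):
            try:
                value = int(cell)
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}: non-integer count {cell!r} at row {i + 1}, column {col!r}"
                ) from None
            if value < 0:
                raise ValueError(f"{path}: negative count at row {i + 1}, column {col!r}")
            counts[i, j] = value
    if metadata_path is not None:
        meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
        lookup = {
            row["name"]: SampleMeta(row["name"], row["cultivar"], int(row["timepoint_h"]))
            for _, row in meta.iterrows()
        }
        samples = [lookup[n] for n in sample_names]
    else:
        samples = [parse_sample_name(n) for n in sample_names]
    return CountMatrix(ids, samples, counts)


def write_count_matrix(matrix: CountMatrix, path: str | Path) -> None:
    df = pd.DataFrame(matrix.counts, columns=matrix.sample_names)
    df.insert(0, "transcript_id", matrix.transcript_ids)
    df.to_csv(path, sep="\t", index=False)


@dataclass
class TranscriptStats:
    n: int
    mean_length: float
    median_length: float
    n50: int
    gc_mean: float
    length_histogram: dict[tuple[int, int], int] = field(default_factory=dict)


def n50(lengths: Sequence[int]) -> int:
    """Largest L such that transcripts of length >= L cover >= half of all bases."""
    if not lengths:
        raise ValueError("n50 of an empty collection")
    ordered = sorted(lengths, reverse=True)
    half = sum(ordered) / 2
    acc = 0
    for length in ordered:
        acc += length
        if acc >= half:
            return length
    raise AssertionError("unreachable")


def transcript_stats(
    transcripts: Sequence[Transcript], bins: Sequence[int] = (200, 600, 1000, 2000, 5000)
) -> TranscriptStats:
    """Length/GC summary in the style of assembly reports.

    `bins` are right-open breakpoints; lengths below the first breakpoint and
    at/above the last get their own bins, so histogram counts always sum to n.
    """
    if not transcripts:
        raise ValueError("transcript_stats of an empty collection")
    lengths = [t.length for t in transcripts]
    edges = [0, *bins, int(max(max(lengths) + 1, bins[-1] + 1))]
    hist: dict[tuple[int, int], int] = {}
    for lo, hi in zip(edges[:-1], edges[1:]):
        hist[(lo, hi)] = sum(1 for L in lengths if lo <= L < hi)
    return TranscriptStats(
        n=len(transcripts),
        mean_length=float(np.mean(lengths)),
        median_length=float(np.median(lengths)),
        n50=n50(lengths),
        gc_mean=float(np.mean([t.gc_fraction for t in transcripts])),
        length_histogram=hist,
    )
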