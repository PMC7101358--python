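"""miRNA precursor annotation among lncRNAs, family normalization,
hairpin plausibility checking, plant-style target prediction and
regulation-direction summaries.

The hairpin check is a documented stand-in for structure-based precursor
webservers: a Nussinov maximum base-pairing fold (GC/AU/GU pairs, minimum
hairpin loop 3) with stem-length and pairing-fraction thresholds.  A pass
means "plausible hairpin", nothing more.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np

from .align import LocalMatch, classify_by_homology
from .core import Transcript

HOMOLOGY_MIN_IDENTITY = 0.90
HOMOLOGY_MAX_EVALUE = 1e-1

_NAME_RE = re.compile(
    r"^(?:(?P<species>[a-z]{2,5})-)?mir(?P<number>\d+)(?P<variant>[a-z]*)(?:-(?P<arm>[35]p))?$",
    re.IGNORECASE,
)


def normalize_precursor_name(name: str) -> str:
    """Lowercase and strip a species prefix (e.g. "ath-miR396a" -> "mir396a")."""
    m = _NAME_RE.match(name.strip())
    if not m:
        raise ValueError(f"cannot parse miRNA name {name!r}")
    arm = f"-{m.group('arm').lower()}" if m.group("arm") else ""
    return f"mir{m.group('number')}{m.group('variant').lower()}{arm}"


def mirna_family(name: str) -> str:
    """Family label: strip species prefix, arm suffix and trailing variant
    letters, keeping "mir<number>" (mir396a, mir396d -> mir396)."""
    m = _NAME_RE.match(name.strip())
    if not m:
        raise ValueError(f"cannot parse miRNA name {name!r}")
    return f"mir{m.group('number')}"


# ---------------------------------------------------------------------------
# hairpin plausibility (Nussinov maximum base pairing)

_PAIRABLE = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}
MIN_HAIRPIN_LOOP = 3


def _can_pair(x: str, y: str) -> bool:
    return (x, y) in _PAIRABLE


def nussinov_max_pairs(seq: str) -> tuple[int, list[tuple[int, int]]]:
    """Maximum base-pairing DP with traceback.

    Returns (max pairs N(0, n-1), pair list).  The traceback prefers closing
    the (i, j) pair when optimal, which keeps planted stems stacked.
    """
    n = len(seq)
    if n == 0:
        return 0, []
    N = np.zeros((n, n), dtype=np.int32)
    pairable = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + MIN_HAIRPIN_LOOP + 1, n):
            pairable[i, j] = _can_pair(seq[i], seq[j])
    for span in range(MIN_HAIRPIN_LOOP + 1, n):
        for i in range(n - span):
            j = i + span
            best = max(N[i + 1, j], N[i, j - 1])
            if pairable[i, j]:
                best = max(best, N[i + 1, j - 1] + 1)
            if j > i + 1:
                k = np.arange(i + 1, j)
                best = max(best, int(np.max(N[i, k] + N[k + 1, j])))
            N[i, j] = best

    pairs: list[tuple[int, int]] = []
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or N[i, j] == 0:
            continue
        if pairable[i, j] and N[i, j] == N[i + 1, j - 1] + 1:
            pairs.append((i, j))
            stack.append((i + 1, j - 1))
        elif N[i, j] == N[i + 1, j]:
            stack.append((i + 1, j))
        elif N[i, j] == N[i, j - 1]:
            stack.append((i, j - 1))
        else:
            for k in range(i + 1, j):
                if N[i, k] + N[k + 1, j] == N[i, j]:
                    stack.append((i, k))
                    stack.append((k + 1, j))
                    break
    pairs.sort()
    return int(N[0, n - 1]), pairs


def _dot_bracket(n: int, pairs: Sequence[tuple[int, int]]) -> str:
    chars = ["."] * n
    for i, j in pairs:
        chars[i], chars[j] = "(", ")"
    return "".join(chars)


def _longest_stem(pairs: Sequence[tuple[int, int]]) -> tuple[int, tuple[int, int] | None]:
    """Longest run of stacked pairs (i,j), (i+1,j-1), ...; returns
    (stem length, innermost pair of that stem)."""
    pair_set = set(pairs)
    best_len, best_inner = 0, None
    for i, j in pairs:
        if (i - 1, j + 1) in pair_set:
            continue  # not the outermost pair of a stack
        length = 0
        while (i + length, j - length) in pair_set:
            length += 1
        if length > best_len:
            best_len = length
            best_inner = (i + length - 1, j - length + 1)
    return best_len, best_inner


@dataclass
class HairpinResult:
    structure: str
    max_pairs: int
    longest_stem: int
    loop_size: int
    passes: bool
    reason: str = ""


def hairpin_check(
    seq: str,
    min_stem: int = 15,
    min_pair_fraction: float = 0.3,
    min_length: int = 40,
    max_length: int = 400,
) -> HairpinResult:
    """Plausible-hairpin verdict: max-pairing fold must contain a stacked
    stem of >= min_stem pairs and pair >= min_pair_fraction of the bases.

    Sequences outside [min_length, max_length] are pass-ineligible (the
    fold is still reported when the sequence is short enough to fold)."""
    n = len(seq)
    max_pairs, pairs = nussinov_max_pairs(seq) if n <= max_length else (0, [])
    stem_len, inner = _longest_stem(pairs)
    loop = inner[1] - inner[0] - 1 if inner else 0
    result = HairpinResult(
        structure=_dot_bracket(n, pairs),
        max_pairs=max_pairs,
        longest_stem=stem_len,
        loop_size=loop,
        passes=False,
    )
    if not (min_length <= n <= max_length):
        result.reason = f"length {n} outside [{min_length}, {max_length}]"
        return result
    if stem_len < min_stem:
        result.reason = f"longest stem {stem_len} < {min_stem}"
        return result
    if max_pairs < min_pair_fraction * n:
        result.reason = f"{max_pairs} pairs < {min_pair_fraction:.0%} of {n} nt"
        return result
    result.passes = True
    return result


# ---------------------------------------------------------------------------
# precursor annotation and Table-1-style summaries

@dataclass(frozen=True)
class MirnaAnnotation:
    lnc_id: str
    precursor_name: str
    family: str
    match: LocalMatch
    hairpin_ok: bool

    def __post_init__(self) -> None:
        if mirna_family(self.precursor_name) != self.family:
            raise ValueError("family must be the normalized precursor name")


def annotate_premirnas(
    lnc_set: Sequence[Transcript],
    hairpin_db: Sequence[Transcript],
    min_identity: float = HOMOLOGY_MIN_IDENTITY,
    max_evalue: float = HOMOLOGY_MAX_EVALUE,
    hairpin_margin: int = 20,
    word_size: int = 11,
) -> list[MirnaAnnotation]:
    """lncRNAs homologous to known hairpins at (0.90, 1e-1), both strands.

    The precursor name is the subject name with any species prefix stripped;
    the hairpin check runs on the matched lncRNA region +/- hairpin_margin.
    """
    hits = classify_by_homology(
        lnc_set, hairpin_db, min_identity, max_evalue, mode="both", word_size=word_size
    )
    by_id = {t.id: t for t in lnc_set}
    annotations: list[MirnaAnnotation] = []
    for lnc_id, hit in hits.items():
        if hit is None:
            continue
        name = normalize_precursor_name(hit.subject_id)
        seq = by_id[lnc_id].seq
        region = seq[max(0, hit.q_start - hairpin_margin) : hit.q_end + hairpin_margin]
        annotations.append(
            MirnaAnnotation(
                lnc_id=lnc_id,
                precursor_name=name,
                family=mirna_family(name),
                match=hit,
                hairpin_ok=hairpin_check(region).passes,
            )
        )
    annotations.sort(key=lambda a: (a.lnc_id, a.precursor_name))
    return annotations


@dataclass
class MirnaTableSummary:
    per_contrast_entries: dict[str, int]
    per_contrast_families: dict[str, int]
    pooled_distinct_precursors: int
    pooled_distinct_families: int
    specific_families: dict[str, set[str]]
    family_sets: dict[str, set[str]]


def summarize_mirna_tables(
    entries_per_contrast: Mapping[str, Sequence[tuple[str, str]]],
) -> MirnaTableSummary:
    """Per-contrast and pooled precursor/family counts.

    ``entries_per_contrast`` maps contrast label -> (lnc_id, precursor_name)
    entries.  Distinct precursors are keyed on precursor name (two lncRNAs
    may carry the same precursor).  Contrast-specific families are those in
    no other contrast.
    """
    family_sets = {
        c: {mirna_family(name) for _, name in entries}
        for c, entries in entries_per_contrast.items()
    }
    all_precursors = {
        name for entries in entries_per_contrast.values() for _, name in entries
    }
    specific = {
        c: fams - set().union(*(f for c2, f in family_sets.items() if c2 != c), set())
        for c, fams in family_sets.items()
    }
    return MirnaTableSummary(
        per_contrast_entries={c: len(e) for c, e in entries_per_contrast.items()},
        per_contrast_families={c: len(f) for c, f in family_sets.items()},
        pooled_distinct_precursors=len(all_precursors),
        pooled_distinct_families=len({mirna_family(n) for n in all_precursors}),
        specific_families=specific,
        family_sets=family_sets,
    )


def pairwise_specific_families(
    family_sets: Mapping[str, set[str]], contrast: str, other: str
) -> set[str]:
    """Families in ``contrast`` absent from ``other`` (pairwise Venn logic)."""
    return family_sets[contrast] - family_sets[other]


# ---------------------------------------------------------------------------
# plant-style target prediction (expectation-score convention)

@dataclass(frozen=True)
class TargetScoring:
    """Penalty weights for the expectation score E of a miRNA-target site."""

    mismatch_w: float = 1.0
    gu_w: float = 0.5
    gap_w: float = 2.0
    seed_start: int = 2  # 1-based positions from the miRNA 5' end
    seed_end: int = 13
    seed_multiplier: float = 2.0
    e_cutoff: float = 5.0

    def __post_init__(self) -> None:
        if min(self.mismatch_w, self.gu_w, self.gap_w, self.seed_multiplier) < 0:
            raise ValueError("weights must be >= 0")


@dataclass(frozen=True)
class TargetHit:
    mirna_name: str
    target_id: str
    expectation: float
    start: int  # alignment span on the target, 0-based half-open
    end: int
    direction: str = "ns"


_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "T"), ("T", "G")}


def site_expectation(mature: str, site: str, scoring: TargetScoring = TargetScoring()) -> float:
    """E of one candidate site (same length as the mature sequence).

    The site is read on the target's sense strand; the mature miRNA pairs
    antiparallel, so position p (1-based from the miRNA 5' end) faces
    site[L - p].  Watson-Crick pairs cost 0, G:U wobbles gu_w, mismatches
    mismatch_w; penalties double inside seed positions 2-13.
    """
    L = len(mature)
    if len(site) != L:
        raise ValueError("site must have the mature length")
    e = 0.0
    for p in range(1, L + 1):
        x, y = mature[p - 1], site[L - p]
        if (x, y) in _WC:
            penalty = 0.0
        elif (x, y) in _GU:
            penalty = scoring.gu_w
        else:
            penalty = scoring.mismatch_w
        if scoring.seed_start <= p <= scoring.seed_end:
            penalty *= scoring.seed_multiplier
        e += penalty
    return e


def predict_targets(
    mature_seq: str,
    mirna_name: str,
    candidate_transcripts: Sequence[Transcript],
    scoring: TargetScoring = TargetScoring(),
    de_directions: Mapping[str, str] | None = None,
) -> list[TargetHit]:
    """Best window per transcript with expectation E <= e_cutoff.

    Gap-free sliding of the mature sequence (18-24 nt) against every window
    of each candidate transcript.
    """
    mature = mature_seq.upper().replace("U", "T")
    L = len(mature)
    if not (18 <= L <= 24):
        raise ValueError(f"mature length must be 18-24 nt, got {L}")
    penalties = _site_penalty_tables(mature, scoring)
    hits: list[TargetHit] = []
    for t in candidate_transcripts:
        if t.length < L:
            continue
        codes = np.fromiter((_BASE_CODE[b] for b in t.seq), dtype=np.int8, count=t.length)
        windows = np.lib.stride_tricks.sliding_window_view(codes, L)
        e = np.zeros(windows.shape[0])
        for p in range(1, L + 1):
            e += penalties[p - 1][windows[:, L - p]]
        best = int(np.argmin(e))
        if e[best] <= scoring.e_cutoff:
            direction = (de_directions or {}).get(t.id, "ns")
            hits.append(
                TargetHit(mirna_name, t.id, float(e[best]), best, best + L, direction)
            )
    hits.sort(key=lambda h: (h.expectation, h.target_id))
    return hits


_BASE_CODE = {b: i for i, b in enumerate("ACGTN")}


def _site_penalty_tables(mature: str, scoring: TargetScoring) -> list[np.ndarray]:
    """Per-position penalty lookup (target base code -> penalty)."""
    tables = []
    for p in range(1, len(mature) + 1):
        x = mature[p - 1]
        row = np.empty(5)
        for y, code in _BASE_CODE.items():
            if (x, y) in _WC:
                row[code] = 0.0
            elif (x, y) in _GU:
                row[code] = scoring.gu_w
            else:
                row[code] = scoring.mismatch_w
        if scoring.seed_start <= p <= scoring.seed_end:
            row *= scoring.seed_multiplier
        tables.append(row)
    return tables


@dataclass
class RegulationSummary:
    pct_up: float
    n_directed: int
    pattern: Literal["positive-regulator", "negative-regulator", "unclassified"]


def regulation_summary(
    mirna_direction: str, target_hits: Sequence[TargetHit]
) -> RegulationSummary:
    """Fraction of directed targets that are up-regulated, and the
    regulator pattern: a down-regulated miRNA whose targets are >50% up is a
    positive regulator of tolerance; an up-regulated miRNA with <=50% target
    up-regulation is a negative regulator."""
    directed = [h for h in target_hits if h.direction in ("up", "down")]
    if not directed:
        raise ValueError("no targets with a known DE direction")
    pct_up = 100.0 * sum(1 for h in directed if h.direction == "up") / len(directed)
    if mirna_direction == "down" and pct_up > 50:
        pattern = "positive-regulator"
    elif mirna_direction == "up" and pct_up <= 50:
        pattern = "negative-regulator"
    else:
        pattern = "unclassified"
    return RegulationSummary(pct_up=pct_up, n_directed=len(directed), pattern=pattern)
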