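"""Natural antisense transcript (NAT) pair detection and confirmation.

Candidates: an ungapped match of >= 150 nt at >= 90% identity between a
salt-responsive lncRNA and a salt-responsive coding transcript (both
orientations searched; the orientation is stored).  Confirmation: a
gap-free sliding-duplex free-energy scan; the pair is confirmed when the
normalized free energy ndG = dG / L of the best window is at or below the
cutoff (default -0.1 kcal/mol/nt).  Expression concordance classifies
confirmed pairs as up_up / down_down / discordant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np

from .align import LocalMatch, ScoringParams, find_local_matches
from .core import Transcript

logger = logging.getLogger(__name__)

NAT_MIN_LENGTH = 150
NAT_MIN_IDENTITY = 0.90

Concordance = Literal["up_up", "down_down", "discordant", "unknown"]


@dataclass(frozen=True)
class EnergyParams:
    """Per-pair duplex energies in kcal/mol (gap-free, no stacking model)."""

    e_gc: float = -3.0
    e_au: float = -2.0
    e_gu: float = -1.0
    mismatch_penalty: float = 1.0
    ndg_cutoff: float = -0.1

    def __post_init__(self) -> None:
        if not (self.e_gc <= self.e_au <= self.e_gu < 0 <= self.mismatch_penalty):
            raise ValueError("require e_gc <= e_au <= e_gu < 0 <= mismatch_penalty")


@dataclass(frozen=True)
class HybridResult:
    dg: float
    window_length: int
    ndg: float
    offset: int

    def __post_init__(self) -> None:
        if self.window_length < 1:
            raise ValueError("window_length must be >= 1")


_CODE = {b: i for i, b in enumerate("ACGTN")}


def _energy_matrix(params: EnergyParams) -> np.ndarray:
    """5x5 duplex energy for (base of strand 1, base of strand 2)."""
    E = np.full((5, 5), params.mismatch_penalty)
    pairs = {
        ("A", "T"): params.e_au,
        ("T", "A"): params.e_au,
        ("G", "C"): params.e_gc,
        ("C", "G"): params.e_gc,
        ("G", "T"): params.e_gu,
        ("T", "G"): params.e_gu,
    }
    for (x, y), e in pairs.items():
        E[_CODE[x], _CODE[y]] = e
    return E


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_CODE[b] for b in seq), dtype=np.int8, count=len(seq))


def hybridize(seq_a: str, seq_b: str, params: EnergyParams = EnergyParams()) -> HybridResult:
    """Best gap-free antiparallel duplex between two transcripts.

    The shorter sequence slides along the reverse of the longer at every
    offset with overlap >= 1; at each offset the pair energies over the
    overlap are summed (Watson-Crick and G:U pairs negative, anything else
    the mismatch penalty).  Returns the offset minimizing total dG, with
    L = overlap length and ndG = dG / L.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    short, long_ = (seq_a, seq_b) if len(seq_a) <= len(seq_b) else (seq_b, seq_a)
    s = _encode(short)
    r = _encode(long_[::-1])  # antiparallel: 5' of one faces 3' of the other
    E = _energy_matrix(params)
    a, b = len(s), len(r)
    best: tuple[float, int, int] | None = None  # (dg, overlap, offset)
    for offset in range(-(a - 1), b):
        i0 = max(0, -offset)
        i1 = min(a, b - offset)
        window = E[s[i0:i1], r[i0 + offset : i1 + offset]]
        dg = float(window.sum())
        cand = (dg, i1 - i0, offset)
        if best is None or dg < best[0]:
            best = cand
    dg, overlap, offset = best  # type: ignore[misc]
    return HybridResult(dg=dg, window_length=overlap, ndg=dg / overlap, offset=offset)


@dataclass
class NatPair:
    """A (candidate or confirmed) lncRNA-mRNA NAT pair."""

    lnc_id: str
    mrna_id: str
    match: LocalMatch
    hybrid: HybridResult | None = None
    confirmed: bool = False
    concordance: Concordance = "unknown"
    min_length: int = NAT_MIN_LENGTH
    min_identity: float = NAT_MIN_IDENTITY

    def __post_init__(self) -> None:
        if self.match.gapped:
            raise ValueError("NAT pairs require gap-free matches")
        if self.match.length < self.min_length or self.match.identity < self.min_identity:
            raise ValueError(
                f"match ({self.match.length} nt, {self.match.identity:.2%}) below the "
                f"{self.min_length}-nt / {self.min_identity:.0%} NAT rule"
            )


def find_nat_candidates(
    lnc_ids: Sequence[str],
    mrna_ids: Sequence[str],
    sequences: Mapping[str, Transcript],
    min_length: int = NAT_MIN_LENGTH,
    min_identity: float = NAT_MIN_IDENTITY,
    scoring: ScoringParams = ScoringParams(),
    word_size: int = 11,
) -> list[NatPair]:
    """All (lncRNA, mRNA) pairs with a qualifying ungapped match.

    One candidate per pair, keeping the best match (score, then e-value).
    """
    pairs: list[NatPair] = []
    for lnc_id in lnc_ids:
        lnc = sequences[lnc_id]
        for mrna_id in mrna_ids:
            if mrna_id == lnc_id:
                continue
            mrna = sequences[mrna_id]
            hits = [
                h
                for h in find_local_matches(lnc, [mrna], scoring, "both", word_size)
                if h.length >= min_length and h.identity >= min_identity
            ]
            if hits:
                best = min(hits, key=lambda h: (-h.score, h.evalue, h.q_start))
                pairs.append(
                    NatPair(lnc_id, mrna_id, best, min_length=min_length, min_identity=min_identity)
                )
    return pairs


def _concordance(d_lnc: str | None, d_mrna: str | None) -> Concordance:
    if d_lnc in ("up", "down") and d_mrna in ("up", "down"):
        if d_lnc == d_mrna:
            return "up_up" if d_lnc == "up" else "down_down"
        return "discordant"
    return "unknown"


@dataclass
class ConcordanceSummary:
    n_confirmed: int
    n_classified: int
    similar_pct: float
    up_pct: float
    down_pct: float
    opposite_pct: float


def summarize_concordance(pairs: Sequence[NatPair]) -> ConcordanceSummary:
    """Percentages (1 d.p.) over confirmed pairs with known concordance."""
    confirmed = [p for p in pairs if p.confirmed]
    classified = [p for p in confirmed if p.concordance != "unknown"]
    n = len(classified)
    count = lambda c: sum(1 for p in classified if p.concordance == c)
    pct = lambda c: round(100.0 * count(c) / n, 1) if n else 0.0
    up, down = pct("up_up"), pct("down_down")
    return ConcordanceSummary(
        n_confirmed=len(confirmed),
        n_classified=n,
        similar_pct=round(100.0 * (count("up_up") + count("down_down")) / n, 1) if n else 0.0,
        up_pct=up,
        down_pct=down,
        opposite_pct=pct("discordant"),
    )


def evaluate_nat_pairs(
    candidates: Sequence[NatPair],
    de_directions: Mapping[str, str],
    sequences: Mapping[str, Transcript],
    params: EnergyParams = EnergyParams(),
) -> tuple[list[NatPair], ConcordanceSummary]:
    """Hybridize every candidate, confirm by ndG <= cutoff, classify
    concordance from the two DE directions.

    Pairs whose members lack a DE direction get concordance "unknown" and are
    excluded from the percentages (with a warning).
    """
    evaluated: list[NatPair] = []
    for pair in candidates:
        hybrid = hybridize(sequences[pair.lnc_id].seq, sequences[pair.mrna_id].seq, params)
        confirmed = hybrid.ndg <= params.ndg_cutoff
        conc = _concordance(de_directions.get(pair.lnc_id), de_directions.get(pair.mrna_id))
        if conc == "unknown":
            logger.warning(
                "NAT pair (%s, %s): missing DE direction, excluded from concordance",
                pair.lnc_id,
                pair.mrna_id,
            )
        evaluated.append(
            NatPair(
                pair.lnc_id,
                pair.mrna_id,
                pair.match,
                hybrid=hybrid,
                confirmed=confirmed,
                concordance=conc,
                min_length=pair.min_length,
                min_identity=pair.min_identity,
            )
        )
    return evaluated, summarize_concordance(evaluated)


def count_targets(
    lnc_ids: Sequence[str],
    coding_ids: Sequence[str],
    sequences: Mapping[str, Transcript],
    params: EnergyParams = EnergyParams(),
) -> dict[str, int]:
    """Per-lncRNA count of coding transcripts passing the hybridization
    cutoff (the target-count criterion of the expression-based method)."""
    out: dict[str, int] = {}
    for lnc_id in lnc_ids:
        lnc_seq = sequences[lnc_id].seq
        n = 0
        for cid in coding_ids:
            if cid == lnc_id:
                continue
            if hybridize(lnc_seq, sequences[cid].seq, params).ndg <= params.ndg_cutoff:
                n += 1
        out[lnc_id] = n
    return out


def top_k_by_targets(target_counts: Mapping[str, int], k: int = 5) -> list[str]:
    """Top-k lncRNAs by target count, deterministic tie-break (count desc,
    then id asc)."""
    return [tid for tid, _ in sorted(target_counts.items(), key=lambda kv: (-kv[1], kv[0]))[:k]]
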