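"""Replicate-free negative-binomial differential expression.

With one library per condition a dispersion cannot be estimated from the
data, so an assumed dispersion phi is used (default 0.4, conservative, in
squared-BCV units).  The test conditions on the library-size-adjusted total
of the two counts and sums the probabilities of outcomes no more probable
than the observed one (two-sided exact test); at phi = 0 it reduces to the
exact binomial test.  Fold changes are CPM-style library-size normalized
with a pseudocount, significance is Benjamini-Hochberg FDR, and the
up/down call requires |log2FC| >= tau AND q < alpha.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .core import CountMatrix

Direction = Literal["up", "down", "ns"]


@dataclass(frozen=True)
class DeConfig:
    dispersion: float = 0.4
    pseudocount: float = 0.5
    lfc_threshold: float = 2.0
    fdr_threshold: float = 0.01

    def __post_init__(self) -> None:
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        if not (0 < self.fdr_threshold < 1):
            raise ValueError("fdr_threshold must be in (0, 1)")


@dataclass(frozen=True)
class DeResult:
    transcript_id: str
    contrast: str
    log2fc: float
    p: float
    q: float
    direction: Direction


def nb_exact_test(
    count_a: int, count_b: int, lib_a: float, lib_b: float, phi: float = 0.4
) -> float:
    """Two-sided exact test of equal (library-size-scaled) expression.

    Conditions on s = count_a + count_b: under the null both counts follow
    NB distributions with means proportional to library size; the
    conditional probability of each split (k, s-k) is evaluated and all
    splits no more probable than the observed one are summed.  phi = 0
    reduces exactly to Binomial(s, lib_a / (lib_a + lib_b)).
    """
    if count_a < 0 or count_b < 0:
        raise ValueError("counts must be non-negative")
    if lib_a <= 0 or lib_b <= 0:
        raise ValueError("library sizes must be positive")
    s = count_a + count_b
    if s == 0:
        return 1.0
    pa = lib_a / (lib_a + lib_b)
    k = np.arange(s + 1)
    if phi == 0:
        logp = stats.binom.logpmf(k, s, pa)
    else:
        r = 1.0 / phi
        mu_a, mu_b = s * pa, s * (1 - pa)
        logp = stats.nbinom.logpmf(k, r, r / (r + mu_a)) + stats.nbinom.logpmf(
            s - k, r, r / (r + mu_b)
        )
        logp -= logsumexp_stable(logp)
    p_obs = logp[count_a]
    pval = float(np.exp(logsumexp_stable(logp[logp <= p_obs + 1e-12])))
    return min(max(pval, np.nextafter(0, 1)), 1.0)


def logsumexp_stable(logx: np.ndarray) -> float:
    m = np.max(logx)
    return float(m + np.log(np.sum(np.exp(logx - m))))


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving.

    q_i = min over j with p_j >= p_i of p_j * m / rank_j, with monotone
    enforcement; output permutes with the input.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must be in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def compute_de(
    matrix: CountMatrix,
    sample_a: str,
    sample_b: str,
    config: DeConfig = DeConfig(),
) -> list[DeResult]:
    """Per-transcript contrast ``sample_a`` vs ``sample_b`` (log2FC of a over b)."""
    for name in (sample_a, sample_b):
        if name not in matrix.sample_names:
            raise ValueError(f"contrast names missing sample {name!r}")
    counts_a = matrix.column(sample_a)
    counts_b = matrix.column(sample_b)
    libs = matrix.library_sizes()
    lib_a, lib_b = libs[sample_a], libs[sample_b]
    c = config.pseudocount
    lfc = np.log2(((counts_a + c) / lib_a) / ((counts_b + c) / lib_b))
    pvals = np.array(
        [
            nb_exact_test(int(a), int(b), lib_a, lib_b, config.dispersion)
            for a, b in zip(counts_a, counts_b)
        ]
    )
    qvals = bh_fdr(pvals)
    contrast = f"{sample_a}-{sample_b}"
    results = []
    for tid, fc, p, q in zip(matrix.transcript_ids, lfc, pvals, qvals):
        if q < config.fdr_threshold and fc >= config.lfc_threshold:
            direction: Direction = "up"
        elif q < config.fdr_threshold and fc <= -config.lfc_threshold:
            direction = "down"
        else:
            direction = "ns"
        results.append(DeResult(tid, contrast, float(fc), float(p), float(q), direction))
    return results


def de_ids(results: Sequence[DeResult]) -> set[str]:
    """Transcripts flagged differentially expressed (either direction)."""
    return {r.transcript_id for r in results if r.direction != "ns"}


def directions(results: Sequence[DeResult]) -> dict[str, Direction]:
    return {r.transcript_id: r.direction for r in results}


@dataclass
class SetOpsResult:
    region_sizes: dict[str, int]
    early_only: set[str]
    late_only: set[str]
    both: set[str]
    genotype_filtered: set[str]


def de_set_ops(
    early: set[str],
    late: set[str],
    genotype_contrast: set[str] | None = None,
) -> SetOpsResult:
    """Early/late/common split plus the genotype-filtered triple intersection.

    ``early``/``late`` are DE sets at 6 h and 24 h versus control; the
    genotype filter intersects a between-cultivar DE set with both.
    """
    both = early & late
    genotype_filtered = (
        genotype_contrast & early & late if genotype_contrast is not None else set()
    )
    regions = {
        "early_only": len(early - late),
        "late_only": len(late - early),
        "both": len(both),
        "union": len(early | late),
    }
    if genotype_contrast is not None:
        regions["genotype_and_early"] = len(genotype_contrast & early)
        regions["genotype_and_late"] = len(genotype_contrast & late)
        regions["triple_intersection"] = len(genotype_filtered)
    return SetOpsResult(regions, early - late, late - early, both, genotype_filtered)


def venn3_regions(a: set[str], b: set[str], c: set[str]) -> dict[str, int]:
    """Sizes of the seven regions of a three-set Venn diagram."""
    return {
        "a_only": len(a - b - c),
        "b_only": len(b - a - c),
        "c_only": len(c - a - b),
        "ab_only": len((a & b) - c),
        "ac_only": len((a & c) - b),
        "bc_only": len((b & c) - a),
        "abc": len(a & b & c),
    }


@dataclass(frozen=True)
class PfafflInput:
    """Amplification efficiencies and delta-Ct values (control - treated)."""

    e_target: float
    e_ref: float
    dct_target: float
    dct_ref: float

    def __post_init__(self) -> None:
        for e in (self.e_target, self.e_ref):
            if not (1.0 <= e <= 2.0):
                raise ValueError("amplification efficiency must be in [1, 2]")


def pfaffl_ratio(inp: PfafflInput) -> float:
    """Relative expression ratio E_target^dCt_target / E_ref^dCt_ref."""
    return inp.e_target**inp.dct_target / inp.e_ref**inp.dct_ref
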