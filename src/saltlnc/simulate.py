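"""Seeded synthetic transcriptomes with planted, machine-readable truth.

The generator emulates the structure of a de-novo assembled mixed plant
transcriptome under a two-cultivar (tolerant Ghazvini / sensitive Sarakhs)
x three-timepoint (0, 6, 24 h) salt-stress design:

* coding transcripts carry a planted complete ORF (GC ~ 0.40) whose
  translation is in the mock protein set;
* plain lncRNAs are random sequence at GC ~ 0.36 with no long ORF;
* pre-miRNA lncRNAs embed an exact copy of a named mock hairpin
  (stem-loop-reverse-complement-stem, miRBase-style names);
* conserved lncRNAs embed a segment of a mock conserved-lncRNA entry;
* known-sRNA transcripts are high-identity copies of mock ncRNA entries;
* NAT pairs share a planted antisense overlap (default 200 nt at 93%
  identity) between a lncRNA and a coding transcript's 3' UTR;
* SSR tracts and transposon fragments are inserted at recorded positions;
* counts are negative-binomial with planted fold changes and library
  sizes within a factor of two of each other.

Background transcripts are rejection-sampled against the mock reference
sets (and against chance SSRs / long ORFs), so the planted truth labels
are exactly consistent with the pipeline's own thresholds; every output
is a pure function of (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .align import classify_by_homology
from .classify import ProteinSeq, ReferenceSets, longest_complete_orf
from .classify import TOO_SHORT, CODING, KNOWN_SRNA, PRE_MIRNA_LNCRNA, CONSERVED_LNCRNA, LNCRNA
from .core import CountMatrix, Transcript, parse_sample_name, reverse_complement
from .mirna import normalize_precursor_name
from .ssr import DEFAULT_MIN_REPEATS, find_ssrs, is_primitive

SAMPLES = ("Gc", "Gt6", "Gt24", "Sc", "St6")

#: per-sample mean multipliers of each planted expression pattern, given a
#: fold change f = 2**lfc applied to the responding samples
PATTERNS = {
    "G_early": lambda f: {"Gt6": f},
    "G_late": lambda f: {"Gt24": f},
    "G_both": lambda f: {"Gt6": f, "Gt24": f},  # enters the triple intersection
    "S_early": lambda f: {"St6": f},
    "shared_both": lambda f: {"Gt6": f, "Gt24": f, "St6": f},
}

CONTRASTS = (("Gt6", "Gc"), ("Gt24", "Gc"), ("St6", "Sc"), ("St6", "Gt6"))


@dataclass
class SynthConfig:
    seed: int
    n_coding: int = 60
    n_lncrna: int = 90
    n_premirna: int = 12
    n_conserved: int = 10
    n_srna: int = 12
    n_short: int = 16
    n_nat_pairs: int = 8
    n_ssr_loci: int = 15
    n_transposon: int = 8
    n_triple: int = 6  # lncRNAs DE in all of St6-Gt6, Gt6-Gc, Gt24-Gc
    orf_codon_range: tuple[int, int] = (120, 200)
    gc_coding: float = 0.40
    gc_lnc: float = 0.36
    lnc_length_range: tuple[int, int] = (250, 700)
    nat_overlap_len: int = 200
    nat_identity: float = 0.93
    target_island_len: int = 140  # < 150 so islands never form NAT candidates
    de_fraction: float = 0.15
    de_log2fc_range: tuple[float, float] = (2.5, 4.0)
    planted_log2fc: float = 4.0  # fold change of feature-carrying DE transcripts
    nb_dispersion: float = 0.05
    #: background baseline means, drawn log-uniformly (heavy-tailed, so the
    #: planted fold changes stay a small share of total library mass, as in
    #: real libraries where normalization-relevant mass is mostly non-DE)
    mean_range: tuple[float, float] = (50.0, 20000.0)
    planted_mean_range: tuple[float, float] = (150.0, 400.0)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("n_coding", "n_lncrna", "n_premirna", "n_conserved", "n_srna",
                     "n_short", "n_nat_pairs", "n_ssr_loci", "n_transposon", "n_triple"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 < self.gc_coding < 1 and 0 < self.gc_lnc < 1):
            raise ValueError("gc values must be in (0, 1)")
        if self.n_nat_pairs + self.n_triple + self.n_transposon > self.n_lncrna:
            raise ValueError("planted features exceed available lncRNAs")
        if self.n_nat_pairs > self.n_coding:
            raise ValueError("NAT pairs exceed available coding transcripts")


@dataclass
class SyntheticTruth:
    """Planted ground truth, serialized alongside the FASTA/TSV outputs."""

    labels: dict[str, str] = field(default_factory=dict)
    ssr_loci: list[dict] = field(default_factory=list)
    nat_pairs: list[dict] = field(default_factory=list)
    premirnas: dict[str, str] = field(default_factory=dict)
    transposon_ids: list[str] = field(default_factory=list)
    de_table: list[dict] = field(default_factory=list)
    triple_lnc_ids: list[str] = field(default_factory=list)
    target_counts: dict[str, int] = field(default_factory=dict)
    mature_sites: dict[str, list[str]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(**json.load(fh))

    def de_directions(self, contrast: str) -> dict[str, str]:
        return {
            row["transcript_id"]: row["direction"]
            for row in self.de_table
            if row["contrast"] == contrast
        }


# ---------------------------------------------------------------------------
# low-level sequence builders

BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(BASES, size=length, p=p))


_STOPS = ("TAA", "TAG", "TGA")


def _random_orf(rng: np.random.Generator, n_codons: int, gc: float) -> str:
    codons = []
    while len(codons) < n_codons - 1:
        codon = _random_seq(rng, 3, gc)
        if codon not in _STOPS and codon != "ATG":
            codons.append(codon)
    return "ATG" + "".join(codons) + _STOPS[rng.integers(3)]


def _mutate(rng: np.random.Generator, seq: str, n_sub: int, margin: int = 3) -> str:
    """Substitute n_sub distinct interior positions to a different base."""
    chars = list(seq)
    positions = rng.choice(np.arange(margin, len(seq) - margin), size=n_sub, replace=False)
    for pos in positions:
        alternatives = [b for b in "ACGT" if b != chars[pos]]
        chars[pos] = alternatives[rng.integers(3)]
    return "".join(chars)


def _insert(seq: str, pos: int, fragment: str) -> str:
    return seq[:pos] + fragment + seq[pos:]


# ---------------------------------------------------------------------------
# mock reference sets

HAIRPIN_NAMES = [
    "pve-mir396a", "pve-mir396d", "pve-mir166g", "pve-mir166a", "pve-mir160i",
    "pve-mir393b", "pve-mir164a", "pve-mir169o", "pve-mir167c", "pve-mir319a",
    "pve-mir477", "pve-mir156g", "pve-mir156b", "pve-mir397a",
    "ath-mir172a", "osa-mir159a", "ptc-mir398b", "zma-mir408",
]

STEM_LEN = 35
LOOP_LEN = 10
MATURE_LEN = 21


def make_mock_references(
    rng: np.random.Generator,
) -> tuple[ReferenceSets, dict[str, str]]:
    """Mock hairpin/conserved/ncRNA/transposon sets plus mature sequences.

    Hairpins are perfect stem-loop-RC(stem) structures; the mature arm is
    the first 21 nt of the stem, keyed by family-bearing precursor name.
    The protein set is filled in later from the planted coding ORFs.
    """
    def cross_clean(build, *screened_dbs):
        """Resample a reference entry until it shares no near-qualifying
        match with already-built sets (loose e-value margin, so chance
        cross-set micro-matches cannot deadlock transcript planting)."""
        for _ in range(100):
            candidate = build()
            if all(
                classify_by_homology([candidate], db, 0.90, 0.5, mode="both",
                                     word_size=_CHECK_WORD_SIZE)[candidate.id] is None
                for db in screened_dbs
                if db
            ):
                return candidate
        raise RuntimeError("could not build a cross-clean mock reference entry")

    hairpins: list[Transcript] = []
    matures: dict[str, str] = {}
    for name in HAIRPIN_NAMES:
        def build(name=name):
            stem = _random_seq(rng, STEM_LEN, 0.5)
            loop = _random_seq(rng, LOOP_LEN, 0.4)
            return Transcript(name, stem + loop + reverse_complement(stem))

        hairpin = cross_clean(build, hairpins)
        hairpins.append(hairpin)
        matures[normalize_precursor_name(name)] = hairpin.seq[:MATURE_LEN]
    conserved = [
        cross_clean(
            lambda i=i: Transcript(
                f"ConsLnc_{i:03d}", _random_seq(rng, int(rng.integers(300, 600)), 0.38)
            ),
            hairpins,
        )
        for i in range(10)
    ]
    ncrna = [
        cross_clean(
            lambda i=i: Transcript(
                f"URS{i:07d}", _random_seq(rng, int(rng.integers(200, 300)), 0.45)
            ),
            hairpins,
            conserved,
        )
        for i in range(12)
    ]
    transposons = [
        cross_clean(
            lambda i=i: Transcript(
                f"TE_{i:03d}", _random_seq(rng, int(rng.integers(400, 800)), 0.42)
            ),
            hairpins,
            conserved,
            ncrna,
        )
        for i in range(8)
    ]
    refs = ReferenceSets(
        protein_db=[],
        hairpin_db=hairpins,
        conserved_db=conserved,
        ncrna_db=ncrna,
        transposon_db=transposons,
    )
    return refs, matures


# ---------------------------------------------------------------------------
# rejection-sampling checks

_CHECK_WORD_SIZE = 11
_CHECK_IDENTITY = 0.90
_CHECK_EVALUE = 1e-1


def _hits_db(t: Transcript, db: Sequence[Transcript]) -> bool:
    if not db:
        return False
    hit = classify_by_homology(
        [t], db, _CHECK_IDENTITY, _CHECK_EVALUE, mode="both", word_size=_CHECK_WORD_SIZE
    )[t.id]
    return hit is not None


def _has_long_orf(t: Transcript, min_aa: int = 100) -> bool:
    orf = longest_complete_orf(t)
    return orf is not None and orf.aa_length >= min_aa


def _is_clean_background(t: Transcript, refs: ReferenceSets) -> bool:
    """No chance SSR, no long ORF, no homology to any mock reference set."""
    return not (
        find_ssrs(t)
        or _has_long_orf(t)
        or _hits_db(t, refs.hairpin_db)
        or _hits_db(t, refs.conserved_db)
        or _hits_db(t, refs.ncrna_db)
        or _hits_db(t, refs.transposon_db)
    )


def _sample_until(rng: np.random.Generator, build, check, max_tries: int = 100):
    for _ in range(max_tries):
        candidate = build(rng)
        if check(candidate):
            return candidate
    raise RuntimeError("rejection sampling failed; loosen the configuration")


# ---------------------------------------------------------------------------
# transcriptome generation

def generate_transcriptome(
    config: SynthConfig,
) -> tuple[list[Transcript], SyntheticTruth, ReferenceSets, dict[str, str]]:
    """Build the mixed transcriptome with planted truth.

    Returns (transcripts, truth, reference_sets, mature_sequences).
    """
    rng = np.random.default_rng(config.seed)
    refs, matures = make_mock_references(rng)
    truth = SyntheticTruth()
    transcripts: list[Transcript] = []

    # --- coding transcripts: UTR5 + planted ORF + UTR3 -------------------
    for i in range(config.n_coding):
        def build(r, i=i):
            n_codons = int(r.integers(*config.orf_codon_range))
            orf = _random_orf(r, n_codons, config.gc_coding)
            utr5 = _random_seq(r, int(r.integers(30, 80)), config.gc_coding)
            utr3 = _random_seq(r, int(r.integers(80, 200)), config.gc_coding)
            return Transcript(f"CODING_{i:04d}", utr5 + orf + utr3)

        t = _sample_until(
            rng, build, lambda t: not find_ssrs(t) and not _hits_db(t, refs.transposon_db)
        )
        transcripts.append(t)
        truth.labels[t.id] = CODING
    # protein set = translations of the planted ORFs
    from Bio.Seq import Seq

    for t in transcripts:
        orf = longest_complete_orf(t)
        assert orf is not None and orf.frame > 0
        aa = str(Seq(t.seq[orf.start : orf.end - 3]).translate())
        refs.protein_db.append(ProteinSeq(f"PROT_{t.id}", aa))

    # --- plain lncRNAs ----------------------------------------------------
    for i in range(config.n_lncrna):
        def build(r, i=i):
            length = int(r.integers(*config.lnc_length_range))
            return Transcript(f"LNC_{i:04d}", _random_seq(r, length, config.gc_lnc))

        t = _sample_until(rng, build, lambda t: _is_clean_background(t, refs))
        transcripts.append(t)
        truth.labels[t.id] = LNCRNA

    # --- pre-miRNA lncRNAs: embed an exact hairpin copy -------------------
    hairpin_choices = rng.choice(len(refs.hairpin_db), size=config.n_premirna, replace=True)
    for i in range(config.n_premirna):
        hairpin = refs.hairpin_db[int(hairpin_choices[i])]

        def build(r, i=i, hairpin=hairpin):
            flank5 = _random_seq(r, int(r.integers(60, 150)), config.gc_lnc)
            flank3 = _random_seq(r, int(r.integers(60, 150)), config.gc_lnc)
            return Transcript(f"PREMIR_{i:04d}", flank5 + hairpin.seq + flank3)

        t = _sample_until(
            rng, build,
            lambda t: not (
                find_ssrs(t) or _has_long_orf(t)
                or _hits_db(t, refs.ncrna_db) or _hits_db(t, refs.transposon_db)
            ),
        )
        transcripts.append(t)
        truth.labels[t.id] = PRE_MIRNA_LNCRNA
        truth.premirnas[t.id] = normalize_precursor_name(hairpin.id)

    # --- conserved lncRNAs: embed a conserved-set segment ------------------
    cons_choices = rng.choice(len(refs.conserved_db), size=config.n_conserved, replace=True)
    for i in range(config.n_conserved):
        source = refs.conserved_db[int(cons_choices[i])]

        def build(r, i=i, source=source):
            seg_len = int(r.integers(150, min(250, source.length)))
            start = int(r.integers(0, source.length - seg_len + 1))
            segment = source.seq[start : start + seg_len]
            flank5 = _random_seq(r, int(r.integers(40, 120)), config.gc_lnc)
            flank3 = _random_seq(r, int(r.integers(40, 120)), config.gc_lnc)
            return Transcript(f"CONSLNC_{i:04d}", flank5 + segment + flank3)

        t = _sample_until(
            rng, build,
            lambda t: not (
                find_ssrs(t) or _has_long_orf(t)
                or _hits_db(t, refs.hairpin_db) or _hits_db(t, refs.transposon_db)
            ),
        )
        transcripts.append(t)
        truth.labels[t.id] = CONSERVED_LNCRNA

    # --- known sRNAs: high-identity copies of ncRNA entries ----------------
    srna_choices = rng.choice(len(refs.ncrna_db), size=config.n_srna, replace=True)
    for i in range(config.n_srna):
        source = refs.ncrna_db[int(srna_choices[i])]

        def build(r, i=i, source=source):
            n_sub = max(1, round(0.02 * source.length))
            return Transcript(f"SRNA_{i:04d}", _mutate(r, source.seq, n_sub))

        t = _sample_until(
            rng, build,
            lambda t: not (
                find_ssrs(t) or _has_long_orf(t)
                or _hits_db(t, refs.hairpin_db) or _hits_db(t, refs.conserved_db)
                or _hits_db(t, refs.transposon_db)
            ),
        )
        transcripts.append(t)
        truth.labels[t.id] = KNOWN_SRNA

    # --- short transcripts --------------------------------------------------
    for i in range(config.n_short):
        t = Transcript(f"SHORT_{i:04d}", _random_seq(rng, int(rng.integers(100, 180)), 0.40))
        transcripts.append(t)
        truth.labels[t.id] = TOO_SHORT

    by_id = {t.id: t for t in transcripts}
    lnc_ids = [t.id for t in transcripts if truth.labels[t.id] == LNCRNA]
    coding_ids = [t.id for t in transcripts if truth.labels[t.id] == CODING]

    # --- NAT pairs: shared antisense overlap lnc <-> coding 3' UTR ----------
    nat_lncs = lnc_ids[: config.n_nat_pairs]
    nat_codings = coding_ids[: config.n_nat_pairs]
    for lnc_id, mrna_id in zip(nat_lncs, nat_codings):
        for _ in range(100):
            segment = _random_seq(rng, config.nat_overlap_len, 0.40)
            n_sub = round((1 - config.nat_identity) * config.nat_overlap_len)
            mutated = _mutate(rng, segment, n_sub)
            mrna = by_id[mrna_id]
            new_mrna = Transcript(mrna_id, mrna.seq + segment)  # appended 3' UTR
            lnc = by_id[lnc_id]
            pos = int(rng.integers(20, lnc.length - 20))
            new_lnc = Transcript(lnc_id, _insert(lnc.seq, pos, reverse_complement(mutated)))
            if (
                not find_ssrs(new_mrna)
                and not find_ssrs(new_lnc)
                and not _has_long_orf(new_lnc)
                and not _hits_db(new_lnc, refs.hairpin_db)
                and not _hits_db(new_lnc, refs.conserved_db)
                and not _hits_db(new_lnc, refs.ncrna_db)
                and not _hits_db(new_lnc, refs.transposon_db)
                and not _hits_db(new_mrna, refs.transposon_db)
            ):
                by_id[mrna_id] = new_mrna
                by_id[lnc_id] = new_lnc
                truth.nat_pairs.append(
                    {
                        "lnc_id": lnc_id,
                        "mrna_id": mrna_id,
                        "overlap_len": config.nat_overlap_len,
                        "identity": 1 - n_sub / config.nat_overlap_len,
                        "orientation": "antisense",
                    }
                )
                break
        else:
            raise RuntimeError("could not plant NAT pair")

    # --- triple-response lncRNAs with planted target islands ----------------
    # shorter hosts keep the island's share of the best duplex window high,
    # so the planted targets clear the normalized-energy cutoff cleanly
    available = lnc_ids[config.n_nat_pairs :]
    short_lncs = [tid for tid in available if by_id[tid].length <= 450]
    if len(short_lncs) < config.n_triple:
        raise RuntimeError("not enough short lncRNAs for target-island planting")
    triple_lncs = short_lncs[: config.n_triple]
    remaining_lncs = [tid for tid in available if tid not in set(triple_lncs)]
    truth.triple_lnc_ids = list(triple_lncs)
    # island hosts: G-responsive coding transcripts (planted below); counts
    # descend so the top-k ordering is unambiguous
    island_hosts = coding_ids[config.n_nat_pairs :]
    host_cursor = 0
    for rank, lnc_id in enumerate(triple_lncs):
        n_targets = config.n_triple - rank  # n_triple, ..., 1
        lnc = by_id[lnc_id]
        start = int(rng.integers(0, lnc.length - config.target_island_len + 1))
        island_src = lnc.seq[start : start + config.target_island_len]
        for _ in range(n_targets):
            host_id = island_hosts[host_cursor]
            host_cursor += 1
            host = by_id[host_id]
            candidate = Transcript(host_id, host.seq + reverse_complement(island_src))
            if find_ssrs(candidate) or _hits_db(candidate, refs.transposon_db):
                # junction artifacts are vanishingly rare; fall back to a
                # shifted island rather than fail generation
                island_alt = lnc.seq[: config.target_island_len]
                candidate = Transcript(host_id, host.seq + reverse_complement(island_alt))
            by_id[host_id] = candidate
        truth.target_counts[lnc_id] = n_targets
    island_host_ids = island_hosts[:host_cursor]

    # --- SSR tracts ----------------------------------------------------------
    ssr_hosts = (
        remaining_lncs
        + [cid for cid in coding_ids if cid not in set(nat_codings) | set(island_host_ids)]
    )
    motif_lengths = [2, 3, 4, 5, 6]
    for i in range(config.n_ssr_loci):
        host_id = ssr_hosts[i]
        host = by_id[host_id]
        k = motif_lengths[i % len(motif_lengths)]
        for _ in range(100):
            motif = _random_seq(rng, k, 0.5)
            if "N" in motif or not is_primitive(motif):
                continue
            count = DEFAULT_MIN_REPEATS[k] + int(rng.integers(0, 3))
            tract = motif * count
            pos = int(rng.integers(10, host.length - 10))
            candidate = Transcript(host_id, _insert(host.seq, pos, tract))
            found = find_ssrs(candidate)
            if (
                len(found) == 1
                and found[0].motif == motif
                and found[0].repeat_count == count
                and found[0].start == pos
            ):
                # keep lncRNA hosts ORF-free and homology-clean (coding hosts
                # stay coding anyway, their label is decided first)
                if _hits_db(candidate, refs.transposon_db):
                    continue
                if truth.labels[host_id] != CODING and (
                    _has_long_orf(candidate)
                    or _hits_db(candidate, refs.hairpin_db)
                    or _hits_db(candidate, refs.conserved_db)
                    or _hits_db(candidate, refs.ncrna_db)
                ):
                    continue
                by_id[host_id] = candidate
                truth.ssr_loci.append(
                    {
                        "transcript_id": host_id,
                        "motif": motif,
                        "repeat_count": count,
                        "start": pos,
                        "end": pos + k * count,
                    }
                )
                break
        else:
            raise RuntimeError("could not plant SSR locus")

    # --- transposon fragments ------------------------------------------------
    te_hosts = remaining_lncs[config.n_ssr_loci : config.n_ssr_loci + config.n_transposon]
    if len(te_hosts) < config.n_transposon:
        raise RuntimeError("not enough lncRNAs for transposon planting")
    te_choices = rng.choice(len(refs.transposon_db), size=config.n_transposon, replace=True)
    for host_id, te_idx in zip(te_hosts, te_choices):
        te = refs.transposon_db[int(te_idx)]
        for _ in range(100):
            frag_len = 300
            start = int(rng.integers(0, te.length - frag_len + 1))
            fragment = te.seq[start : start + frag_len]
            host = by_id[host_id]
            pos = int(rng.integers(10, host.length - 10))
            candidate = Transcript(host_id, _insert(host.seq, pos, fragment))
            if (
                not find_ssrs(candidate)
                and not _has_long_orf(candidate)
                and not _hits_db(candidate, refs.hairpin_db)
                and not _hits_db(candidate, refs.conserved_db)
                and not _hits_db(candidate, refs.ncrna_db)
            ):
                by_id[host_id] = candidate
                truth.transposon_ids.append(host_id)
                break
        else:
            raise RuntimeError("could not plant transposon fragment")

    # --- planted differential expression ------------------------------------
    _plant_de(rng, config, truth, lnc_ids, coding_ids, nat_lncs, nat_codings,
              triple_lncs, island_host_ids)

    # --- mature-miRNA target sites in up-regulated coding hosts --------------
    _plant_mature_sites(rng, truth, by_id, matures)

    ordered = [by_id[t.id] for t in transcripts]
    return ordered, truth, refs, matures


def _plant_de(
    rng: np.random.Generator,
    config: SynthConfig,
    truth: SyntheticTruth,
    lnc_ids: list[str],
    coding_ids: list[str],
    nat_lncs: list[str],
    nat_codings: list[str],
    triple_lncs: list[str],
    island_hosts: list[str],
) -> None:
    """Assign expression patterns; record the true per-contrast log2FC table."""
    multipliers: dict[str, dict[str, float]] = {}

    def assign(tid: str, pattern: str, lfc: float) -> None:
        multipliers[tid] = PATTERNS[pattern](2.0**lfc)

    # NAT members: strong G-responsive signal with balanced directions so the
    # planted fold changes do not skew library-size totals (composition bias)
    concordance_plan = [
        "up" if i % 2 == 0 else ("down" if i % 4 == 1 else "discordant")
        for i in range(config.n_nat_pairs)
    ]
    for (lnc_id, mrna_id), kind in zip(zip(nat_lncs, nat_codings), concordance_plan):
        pattern = "G_early"
        s = config.planted_log2fc
        if kind == "up":
            assign(lnc_id, pattern, s)
            assign(mrna_id, pattern, s)
        elif kind == "down":
            assign(lnc_id, pattern, -s)
            assign(mrna_id, pattern, -s)
        else:
            assign(lnc_id, pattern, s)
            assign(mrna_id, pattern, -s)

    # triple lncRNAs: G_both pattern (DE in Gt6-Gc, Gt24-Gc and St6-Gt6);
    # signs alternate to keep library composition balanced
    for rank, lnc_id in enumerate(triple_lncs):
        sign = 1 if rank % 2 == 0 else -1
        assign(lnc_id, "G_both", sign * config.planted_log2fc)
    # island hosts must be G-responsive coding transcripts (the target file)
    for rank, host_id in enumerate(island_hosts):
        if host_id not in multipliers:
            sign = 1 if rank % 2 == 0 else -1
            assign(host_id, "G_both", sign * config.planted_log2fc)

    # pre-miRNA lncRNAs: down-regulated under stress (one up, mimicking the
    # single up-regulated precursor seen in real data)
    premir_ids = sorted(truth.premirnas)
    for i, tid in enumerate(premir_ids):
        pattern = ("G_early", "G_late", "shared_both")[i % 3]
        lfc = config.planted_log2fc if i == 0 else -config.planted_log2fc
        assign(tid, pattern, lfc)

    # mature-site hosts: coding transcripts up-regulated in every
    # treated-vs-control contrast, so any contrast's target file holds them
    shared_up_hosts = [cid for cid in coding_ids if cid not in multipliers][:6]
    for cid in shared_up_hosts:
        assign(cid, "shared_both", config.planted_log2fc)

    # ordinary DE among the remaining background transcripts
    remaining = [
        tid for tid in lnc_ids + coding_ids if tid not in multipliers
    ]
    n_ordinary = round(config.de_fraction * len(remaining))
    chosen = rng.choice(remaining, size=n_ordinary, replace=False)
    for tid in chosen:
        pattern = ("G_early", "G_late", "shared_both", "S_early")[int(rng.integers(4))]
        lfc = float(rng.uniform(*config.de_log2fc_range)) * (1 if rng.random() < 0.5 else -1)
        assign(tid, pattern, lfc)

    truth_rows = []
    for tid, mult in sorted(multipliers.items()):
        for a, b in CONTRASTS:
            lfc = float(np.log2(mult.get(a, 1.0) / mult.get(b, 1.0)))
            if lfc != 0.0:
                truth_rows.append(
                    {
                        "transcript_id": tid,
                        "contrast": f"{a}-{b}",
                        "log2fc": lfc,
                        "direction": "up" if lfc > 0 else "down",
                    }
                )
    truth.de_table = truth_rows
    truth._multipliers = multipliers  # type: ignore[attr-defined]


def _plant_mature_sites(
    rng: np.random.Generator,
    truth: SyntheticTruth,
    by_id: dict[str, Transcript],
    matures: Mapping[str, str],
) -> None:
    """Perfect complementary sites for two planted down-regulated precursor
    families in three coding transcripts that are up in every contrast."""
    down_lncs = {
        row["transcript_id"]
        for row in truth.de_table
        if row["direction"] == "down" and row["transcript_id"] in truth.premirnas
    }
    planted_precursors = sorted({truth.premirnas[tid] for tid in down_lncs})[:2]
    up_contrast_sets = []
    for contrast in ("Gt6-Gc", "Gt24-Gc", "St6-Sc"):
        up_contrast_sets.append(
            {
                row["transcript_id"]
                for row in truth.de_table
                if row["contrast"] == contrast
                and row["direction"] == "up"
                and row["transcript_id"] in truth.labels
                and truth.labels[row["transcript_id"]] == CODING
            }
        )
    up_g_coding = sorted(set.intersection(*up_contrast_sets))
    cursor = 0
    for precursor in planted_precursors:
        mature = matures.get(precursor)
        if mature is None:
            continue
        hosts = []
        for _ in range(3):
            if cursor >= len(up_g_coding):
                break
            host_id = up_g_coding[cursor]
            cursor += 1
            host = by_id[host_id]
            by_id[host_id] = Transcript(host_id, host.seq + reverse_complement(mature))
            hosts.append(host_id)
        if hosts:
            truth.mature_sites[precursor] = hosts


# ---------------------------------------------------------------------------
# count generation

def generate_counts(
    truth: SyntheticTruth,
    config: SynthConfig,
    transcript_ids: Sequence[str],
    rng: np.random.Generator | None = None,
) -> CountMatrix:
    """NB-distributed counts with planted fold changes.

    Baseline means are uniform in ``mean_range`` (``planted_mean_range`` for
    transcripts carrying planted DE so recovery margins are generous);
    library-size factors are within a factor of two of each other; counts
    are NB(mean, dispersion).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    multipliers: dict[str, dict[str, float]] = getattr(truth, "_multipliers", None) or {}
    if not multipliers:
        # reconstruct per-sample multipliers from the truth DE table
        multipliers = _multipliers_from_table(truth)
    means = {}
    for tid in transcript_ids:
        if tid in multipliers:
            means[tid] = float(rng.uniform(*config.planted_mean_range))
        else:
            lo, hi = config.mean_range
            means[tid] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    lib_factors = {s: float(rng.uniform(0.7, 1.4)) for s in SAMPLES}
    phi = config.nb_dispersion
    counts = np.empty((len(transcript_ids), len(SAMPLES)), dtype=np.int64)
    for i, tid in enumerate(transcript_ids):
        for j, sample in enumerate(SAMPLES):
            mu = means[tid] * multipliers.get(tid, {}).get(sample, 1.0) * lib_factors[sample]
            if phi == 0:
                counts[i, j] = rng.poisson(mu)
            else:
                r = 1.0 / phi
                counts[i, j] = rng.negative_binomial(r, r / (r + mu))
    samples = [parse_sample_name(s) for s in SAMPLES]
    return CountMatrix(list(transcript_ids), samples, counts)


def _multipliers_from_table(truth: SyntheticTruth) -> dict[str, dict[str, float]]:
    out: dict[str, dict[str, float]] = {}
    for row in truth.de_table:
        a, b = row["contrast"].split("-")
        if b in ("Gc", "Sc"):  # treated-vs-control rows define the multipliers
            out.setdefault(row["transcript_id"], {})[a] = 2.0 ** row["log2fc"]
    return out


# ---------------------------------------------------------------------------
# focused generators for calibration / power studies

def generate_null_pairs(
    n: int, mean: float, phi: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """n independent NB count pairs with a common mean (null hypothesis)."""
    rng = np.random.default_rng(seed)
    if phi == 0:
        return rng.poisson(mean, size=n), rng.poisson(mean, size=n)
    r = 1.0 / phi
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=n), rng.negative_binomial(r, p, size=n)


def generate_power_matrix(
    n_de: int, n_null: int, mean: float, lfc: float, phi: float, seed: int
) -> tuple[CountMatrix, dict[str, str]]:
    """Two-sample matrix with ``n_de`` planted shifts of magnitude ``lfc``
    (alternating up/down, so the planted signal does not skew library-size
    normalization) at the given baseline mean.

    Returns (matrix, planted id -> true direction).
    """
    rng = np.random.default_rng(seed)
    ids = [f"T{i:05d}" for i in range(n_de + n_null)]
    planted = {tid: ("up" if i % 2 == 0 else "down") for i, tid in enumerate(ids[:n_de])}
    r = 1.0 / phi
    high = mean * 2.0**lfc
    # mirrored design: "up" goes mean -> high, "down" goes high -> mean, so
    # both library totals are exchangeable and CPM normalization is unbiased
    mu_a = np.array([high if planted.get(t) == "up" else mean for t in ids])
    mu_b = np.array([high if planted.get(t) == "down" else mean for t in ids])
    counts = np.column_stack(
        [
            rng.negative_binomial(r, r / (r + mu_a)),
            rng.negative_binomial(r, r / (r + mu_b)),
        ]
    ).astype(np.int64)
    samples = [parse_sample_name("Gt6"), parse_sample_name("Gc")]
    return CountMatrix(ids, samples, counts), planted


def generate_target_set(
    mature: str, n_with_site: int, n_without: int, seed: int, length: int = 400
) -> tuple[list[Transcript], set[str]]:
    """Transcripts with/without one planted perfect complementary site."""
    rng = np.random.default_rng(seed)
    transcripts: list[Transcript] = []
    with_site: set[str] = set()
    for i in range(n_with_site + n_without):
        seq = _random_seq(rng, length, 0.40)
        tid = f"TGT_{i:04d}"
        if i < n_with_site:
            pos = int(rng.integers(0, length - len(mature)))
            seq = seq[:pos] + reverse_complement(mature.upper().replace("U", "T")) + seq[pos + len(mature):]
            with_site.add(tid)
        transcripts.append(Transcript(tid, seq))
    return transcripts, with_site


# ---------------------------------------------------------------------------
# packaged worked-example fixture

def table1_fixture() -> dict[str, list[tuple[str, str]]]:
    """The packaged per-contrast (lncRNA id, precursor name) lists."""
    text = (
        resources.files("saltlnc").joinpath("data/table1_mirna_lncrnas.tsv").read_text()
    )
    out: dict[str, list[tuple[str, str]]] = {}
    for line in text.strip().splitlines()[1:]:
        contrast, lnc_id, name = line.split("\t")
        out.setdefault(contrast, []).append((lnc_id, name))
    return out
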