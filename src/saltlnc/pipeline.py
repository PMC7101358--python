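"""File-based orchestration of the full analysis.

A run directory holds the inputs (``transcripts.fasta``, ``counts.tsv``,
``refs/``) and one output file per stage; every stage is a pure function of
the saved inputs/intermediates plus the resolved configuration, so rerunning
a single stage reproduces its output byte-identically and rerunning the
whole pipeline with the same seeds yields an identical manifest (except
timestamps).

Stage order: classify -> ssr/transposon -> de -> setops -> nat -> mirna ->
report.
"""

from __future__ import annotations

import copy
import csv
import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

from . import __version__
from .classify import (
    CODING,
    ProteinSeq,
    ReferenceSets,
    classify_transcripts,
    deduplicate_transcripts,
    flag_transposons,
)
from .core import (
    CountMatrix,
    Transcript,
    read_count_matrix,
    read_fasta,
    transcript_stats,
    write_count_matrix,
    write_fasta,
)
from .de import DeConfig, compute_de, de_set_ops, venn3_regions
from .mirna import (
    MirnaAnnotation,
    annotate_premirnas,
    predict_targets,
    regulation_summary,
    summarize_mirna_tables,
)
from .nat import (
    EnergyParams,
    count_targets,
    evaluate_nat_pairs,
    find_nat_candidates,
    top_k_by_targets,
)
from .ssr import find_ssrs, write_ssr_report

DEFAULT_CONFIG: dict[str, dict[str, Any]] = {
    "classify": {
        "min_length": 200,
        "min_identity": 0.90,
        "max_evalue": 1e-1,
        "min_orf_aa": 100,
        "word_size": 11,
        "dedup": False,
        "dedup_identity": 0.90,
        "dedup_coverage": 0.80,
    },
    "ssr": {"min_repeats": {2: 6, 3: 5, 4: 5, 5: 4, 6: 4}},
    "de": {
        "dispersion": 0.4,
        "pseudocount": 0.5,
        "lfc_threshold": 2.0,
        "fdr_threshold": 0.01,
        "contrasts": [["Gt6", "Gc"], ["Gt24", "Gc"], ["St6", "Sc"], ["St6", "Gt6"]],
    },
    "nat": {"min_length": 150, "min_identity": 0.90, "ndg_cutoff": -0.1},
    "targets": {"ndg_cutoff": -0.7, "top_k": 5},
    "mirna": {"min_identity": 0.90, "max_evalue": 1e-1, "target_e_cutoff": 5.0},
    "simulate": {},
}

STAGES = ("classify", "ssr", "de", "setops", "nat", "mirna", "report")


def resolve_config(overrides: Mapping[str, Any] | None = None) -> dict[str, Any]:
    """Defaults deep-merged with overrides; unknown keys are rejected."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    for section, values in (overrides or {}).items():
        if section not in cfg:
            raise ValueError(f"unknown config section {section!r}")
        if section == "simulate":
            cfg[section] = dict(values)
            continue
        for key, value in values.items():
            if key not in cfg[section]:
                raise ValueError(f"unknown config key {section}.{key}")
            cfg[section][key] = value
    return cfg


def load_config(path: str | Path | None) -> dict[str, Any]:
    if path is None:
        return resolve_config()
    with open(path) as fh:
        return resolve_config(yaml.safe_load(fh) or {})


@dataclass
class RunManifest:
    version: str
    input_checksums: dict[str, str]
    config: dict[str, Any]
    stage_counts: dict[str, int] = field(default_factory=dict)
    timestamp: str = ""

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# run-directory input handling

def prepare_run_dir(
    run_dir: str | Path,
    transcripts: Sequence[Transcript],
    counts: CountMatrix,
    refs: ReferenceSets,
    matures: Mapping[str, str] | None = None,
) -> Path:
    """Write the canonical inputs of a run directory."""
    run_dir = Path(run_dir)
    (run_dir / "refs").mkdir(parents=True, exist_ok=True)
    write_fasta(transcripts, run_dir / "transcripts.fasta")
    write_count_matrix(counts, run_dir / "counts.tsv")
    for name in ("hairpin", "conserved", "ncrna", "transposon"):
        write_fasta(getattr(refs, f"{name}_db"), run_dir / "refs" / f"{name}.fasta")
    with open(run_dir / "refs" / "proteins.tsv", "w") as fh:
        for p in refs.protein_db:
            fh.write(f"{p.id}\t{p.seq}\n")
    if matures:
        with open(run_dir / "refs" / "matures.tsv", "w") as fh:
            for name in sorted(matures):
                fh.write(f"{name}\t{matures[name]}\n")
    return run_dir


def load_refs(run_dir: Path) -> ReferenceSets:
    refs_dir = run_dir / "refs"
    proteins = []
    protein_path = refs_dir / "proteins.tsv"
    if protein_path.exists():
        for line in protein_path.read_text().splitlines():
            pid, seq = line.split("\t")
            proteins.append(ProteinSeq(pid, seq))
    return ReferenceSets(
        protein_db=proteins,
        hairpin_db=read_fasta(refs_dir / "hairpin.fasta"),
        conserved_db=read_fasta(refs_dir / "conserved.fasta"),
        ncrna_db=read_fasta(refs_dir / "ncrna.fasta"),
        transposon_db=read_fasta(refs_dir / "transposon.fasta"),
    )


def load_matures(run_dir: Path) -> dict[str, str]:
    path = run_dir / "refs" / "matures.tsv"
    if not path.exists():
        return {}
    return dict(line.split("\t") for line in path.read_text().splitlines())


def _read_tsv(path: Path) -> list[dict[str, str]]:
    with open(path) as fh:
        return list(csv.DictReader(fh, delimiter="\t"))


def _require(run_dir: Path, filename: str, stage: str) -> Path:
    path = run_dir / filename
    if not path.exists():
        raise FileNotFoundError(f"stage {stage!r}: missing input {path}")
    return path


# ---------------------------------------------------------------------------
# stages

def stage_classify(run_dir: Path, cfg: Mapping[str, Any]) -> int:
    transcripts = read_fasta(_require(run_dir, "transcripts.fasta", "classify"))
    refs = load_refs(run_dir)
    c = cfg["classify"]
    if c["dedup"]:
        transcripts, _ = deduplicate_transcripts(
            transcripts, c["dedup_identity"], c["dedup_coverage"], c["word_size"]
        )
    classes = classify_transcripts(
        transcripts,
        refs,
        min_length=c["min_length"],
        min_identity=c["min_identity"],
        max_evalue=c["max_evalue"],
        min_orf_aa=c["min_orf_aa"],
        word_size=c["word_size"],
    )
    with open(run_dir / "classification.tsv", "w") as fh:
        fh.write("id\tlabel\tevidence_rule\tevidence_ref\tidentity\tevalue\n")
        for t in transcripts:
            cls = classes[t.id]
            rule, ref, ident, ev = "", "", "", ""
            if cls.evidence:
                rule, obj = cls.evidence[0]
                ref = getattr(obj, "subject_id", str(obj))
                ident = f"{getattr(obj, 'identity', float('nan')):.4f}" if hasattr(obj, "identity") else ""
                ev = f"{getattr(obj, 'evalue', float('nan')):.3g}" if hasattr(obj, "evalue") else ""
            fh.write(f"{t.id}\t{cls.label}\t{rule}\t{ref}\t{ident}\t{ev}\n")
    return len(transcripts)


def read_classification(run_dir: Path) -> dict[str, str]:
    return {
        row["id"]: row["label"]
        for row in _read_tsv(_require(run_dir, "classification.tsv", "downstream"))
    }


def stage_ssr(run_dir: Path, cfg: Mapping[str, Any]) -> int:
    transcripts = read_fasta(run_dir / "transcripts.fasta")
    labels = read_classification(run_dir)
    refs = load_refs(run_dir)
    min_repeats = {int(k): v for k, v in cfg["ssr"]["min_repeats"].items()}
    analyzed = [t for t in transcripts if labels.get(t.id) not in ("TOO_SHORT", None)]
    loci = [locus for t in analyzed for locus in find_ssrs(t, min_repeats)]
    write_ssr_report(loci, run_dir / "ssr.tsv")
    flagged = flag_transposons(analyzed, refs.transposon_db, word_size=cfg["classify"]["word_size"])
    with open(run_dir / "transposons.tsv", "w") as fh:
        fh.write("id\n")
        for tid in sorted(flagged):
            fh.write(tid + "\n")
    return len(loci)


def stage_de(run_dir: Path, cfg: Mapping[str, Any]) -> int:
    counts = read_count_matrix(_require(run_dir, "counts.tsv", "de"))
    c = cfg["de"]
    de_config = DeConfig(c["dispersion"], c["pseudocount"], c["lfc_threshold"], c["fdr_threshold"])
    with open(run_dir / "de.tsv", "w") as fh:
        fh.write("id\tcontrast\tlog2fc\tp\tq\tdirection\n")
        n = 0
        for a, b in c["contrasts"]:
            for r in compute_de(counts, a, b, de_config):
                fh.write(
                    f"{r.transcript_id}\t{r.contrast}\t{r.log2fc:.4f}\t{r.p:.6g}\t"
                    f"{r.q:.6g}\t{r.direction}\n"
                )
                n += 1
    return n


def read_de(run_dir: Path) -> list[dict[str, str]]:
    return _read_tsv(_require(run_dir, "de.tsv", "setops/nat/mirna"))


def de_sets_by_contrast(
    rows: Sequence[Mapping[str, str]], labels: Mapping[str, str], stratum: str
) -> dict[str, set[str]]:
    """Per-contrast DE id sets restricted to one stratum ("lnc" or "coding")."""
    lnc_labels = {"LNCRNA", "PRE_MIRNA_LNCRNA", "CONSERVED_LNCRNA"}
    keep = lnc_labels if stratum == "lnc" else {CODING}
    out: dict[str, set[str]] = {}
    for row in rows:
        out.setdefault(row["contrast"], set())
        if row["direction"] != "ns" and labels.get(row["id"]) in keep:
            out[row["contrast"]].add(row["id"])
    return out


def de_direction_map(rows: Sequence[Mapping[str, str]], contrasts: Sequence[str]) -> dict[str, str]:
    """Per-transcript direction, first non-ns contrast in priority order."""
    out: dict[str, str] = {}
    for contrast in contrasts:
        for row in rows:
            if row["contrast"] == contrast and row["direction"] != "ns":
                out.setdefault(row["id"], row["direction"])
    return out


def stage_setops(run_dir: Path, cfg: Mapping[str, Any]) -> int:
    labels = read_classification(run_dir)
    lnc_sets = de_sets_by_contrast(read_de(run_dir), labels, "lnc")
    early = lnc_sets.get("Gt6-Gc", set())
    late = lnc_sets.get("Gt24-Gc", set())
    genotype = lnc_sets.get("St6-Gt6", set())
    result = de_set_ops(early, late, genotype)
    venn = venn3_regions(lnc_sets.get("St6-Sc", set()), early, late)
    with open(run_dir / "setops.tsv", "w") as fh:
        fh.write("region\tsize\n")
        for name, size in sorted(result.region_sizes.items()):
            fh.write(f"{name}\t{size}\n")
        for name, size in sorted(venn.items()):
            fh.write(f"venn_St6Sc_Gt6Gc_Gt24Gc.{name}\t{size}\n")
    with open(run_dir / "triple_intersection.tsv", "w") as fh:
        fh.write("id\n")
        for tid in sorted(result.genotype_filtered):
            fh.write(tid + "\n")
    return len(result.genotype_filtered)


def stage_nat(run_dir: Path, cfg: Mapping[str, Any]) -> int:
    transcripts = {t.id: t for t in read_fasta(run_dir / "transcripts.fasta")}
    labels = read_classification(run_dir)
    de_rows = read_de(run_dir)
    lnc_sets = de_sets_by_contrast(de_rows, labels, "lnc")
    coding_sets = de_sets_by_contrast(de_rows, labels, "coding")
    # salt-responsive sets of the tolerant cultivar (early or late)
    lnc_resp = sorted(lnc_sets.get("Gt6-Gc", set()) | lnc_sets.get("Gt24-Gc", set()))
    coding_resp = sorted(coding_sets.get("Gt6-Gc", set()) | coding_sets.get("Gt24-Gc", set()))
    c = cfg["nat"]
    candidates = find_nat_candidates(
        lnc_resp, coding_resp, transcripts,
        min_length=c["min_length"], min_identity=c["min_identity"],
        word_size=cfg["classify"]["word_size"],
    )
    directions = de_direction_map(de_rows, ["Gt6-Gc", "Gt24-Gc"])
    params = EnergyParams(ndg_cutoff=c["ndg_cutoff"])
    evaluated, summary = evaluate_nat_pairs(candidates, directions, transcripts, params)
    with open(run_dir / "nat.tsv", "w") as fh:
        fh.write(
            "lnc_id\tmrna_id\tq_start\tq_end\ts_start\ts_end\tstrand\tlength\t"
            "identity\tdg\tndg\tconfirmed\tconcordance\n"
        )
        for p in evaluated:
            m, h = p.match, p.hybrid
            fh.write(
                f"{p.lnc_id}\t{p.mrna_id}\t{m.q_start + 1}\t{m.q_end}\t{m.s_start + 1}\t"
                f"{m.s_end}\t{m.strand}\t{m.length}\t{m.identity:.4f}\t{h.dg:.2f}\t"
                f"{h.ndg:.4f}\t{int(p.confirmed)}\t{p.concordance}\n"
            )
    with open(run_dir / "nat_summary.json", "w") as fh:
        json.dump(asdict(summary), fh, indent=1, sort_keys=True)
    return len(evaluated)


def stage_mirna(run_dir: Path, cfg: Mapping[str, Any]) -> int:
    transcripts = {t.id: t for t in read_fasta(run_dir / "transcripts.fasta")}
    labels = read_classification(run_dir)
    refs = load_refs(run_dir)
    matures = load_matures(run_dir)
    de_rows = read_de(run_dir)
    lnc_sets = de_sets_by_contrast(de_rows, labels, "lnc")
    coding_sets = de_sets_by_contrast(de_rows, labels, "coding")
    c = cfg["mirna"]
    contrast_cultivar = {"St6-Sc": "S", "Gt6-Gc": "G", "Gt24-Gc": "G"}

    annotations: dict[str, list[MirnaAnnotation]] = {}
    for contrast in ("St6-Sc", "Gt6-Gc", "Gt24-Gc"):
        members = [transcripts[tid] for tid in sorted(lnc_sets.get(contrast, set()))]
        annotations[contrast] = annotate_premirnas(
            members, refs.hairpin_db, c["min_identity"], c["max_evalue"],
            word_size=cfg["classify"]["word_size"],
        )
    with open(run_dir / "mirna.tsv", "w") as fh:
        fh.write("contrast\tlnc_id\tprecursor\tfamily\tidentity\tevalue\thairpin_ok\n")
        for contrast, anns in annotations.items():
            for a in anns:
                fh.write(
                    f"{contrast}\t{a.lnc_id}\t{a.precursor_name}\t{a.family}\t"
                    f"{a.match.identity:.4f}\t{a.match.evalue:.3g}\t{int(a.hairpin_ok)}\n"
                )
    table = {
        contrast: [(a.lnc_id, a.precursor_name) for a in anns]
        for contrast, anns in annotations.items()
    }
    summary = summarize_mirna_tables(table)

    # target prediction for contrast-specific families, searched in the
    # salt-responsive coding set of the matching cultivar
    per_contrast_dirs = {
        contrast: {
            row["id"]: row["direction"]
            for row in de_rows
            if row["contrast"] == contrast and row["direction"] != "ns"
        }
        for contrast in ("St6-Sc", "Gt6-Gc", "Gt24-Gc")
    }
    regulation: dict[str, dict[str, Any]] = {}
    for contrast, anns in annotations.items():
        specific = summary.specific_families[contrast]
        for a in anns:
            if a.family in regulation:
                continue
            mature = matures.get(a.precursor_name)
            if mature is None:
                continue
            candidates = [
                transcripts[tid] for tid in sorted(coding_sets.get(contrast, set()))
            ]
            hits = predict_targets(
                mature, a.precursor_name, candidates,
                de_directions=per_contrast_dirs[contrast],
            )
            mirna_dir = per_contrast_dirs[contrast].get(a.lnc_id, "ns")
            entry: dict[str, Any] = {
                "contrast": contrast,
                "precursor": a.precursor_name,
                "contrast_specific": a.family in specific,
                "n_targets": len(hits),
                "mirna_direction": mirna_dir,
            }
            try:
                reg = regulation_summary(mirna_dir, hits)
                entry.update(pct_up=reg.pct_up, pattern=reg.pattern)
            except ValueError:
                entry.update(pct_up=None, pattern="no-directed-targets")
            regulation[a.family] = entry

    # expression-pattern method: target counts for the triple intersection
    triple = [row["id"] for row in _read_tsv(_require(run_dir, "triple_intersection.tsv", "mirna"))]
    coding_resp = sorted(coding_sets.get("Gt6-Gc", set()) | coding_sets.get("Gt24-Gc", set()))
    tcfg = cfg["targets"]
    target_counts = count_targets(
        sorted(triple), coding_resp, transcripts, EnergyParams(ndg_cutoff=tcfg["ndg_cutoff"])
    )
    top = top_k_by_targets(target_counts, tcfg["top_k"])
    with open(run_dir / "targets.tsv", "w") as fh:
        fh.write("lnc_id\ttarget_count\tselected\n")
        for tid in sorted(target_counts, key=lambda t: (-target_counts[t], t)):
            fh.write(f"{tid}\t{target_counts[tid]}\t{int(tid in top)}\n")

    out = {
        "per_contrast_entries": summary.per_contrast_entries,
        "per_contrast_families": summary.per_contrast_families,
        "pooled_distinct_precursors": summary.pooled_distinct_precursors,
        "pooled_distinct_families": summary.pooled_distinct_families,
        "specific_families": {k: sorted(v) for k, v in summary.specific_families.items()},
        "regulation": regulation,
        "top_lncrnas_by_targets": top,
    }
    with open(run_dir / "mirna_summary.json", "w") as fh:
        json.dump(out, fh, indent=1, sort_keys=True)
    return sum(len(a) for a in annotations.values())


def stage_report(run_dir: Path, cfg: Mapping[str, Any]) -> int:
    transcripts = read_fasta(run_dir / "transcripts.fasta")
    labels = read_classification(run_dir)
    lnc_labels = {"LNCRNA", "PRE_MIRNA_LNCRNA", "CONSERVED_LNCRNA"}
    lnc = [t for t in transcripts if labels.get(t.id) in lnc_labels]
    coding = [t for t in transcripts if labels.get(t.id) == CODING]
    report: dict[str, Any] = {"label_counts": {}}
    for label in sorted(set(labels.values())):
        report["label_counts"][label] = sum(1 for v in labels.values() if v == label)

    def stats_block(group: list[Transcript]) -> dict[str, Any]:
        if not group:
            return {"n": 0}
        s = transcript_stats(group)
        return {
            "n": s.n,
            "mean_length": round(s.mean_length, 1),
            "median_length": round(s.median_length, 1),
            "n50": s.n50,
            "gc_mean_pct": round(100 * s.gc_mean, 1),
        }

    report["lncrna_stats"] = stats_block(lnc)
    report["coding_stats"] = stats_block(coding)

    loci_rows = _read_tsv(run_dir / "ssr.tsv") if (run_dir / "ssr.tsv").exists() else []
    by_len: dict[str, int] = {}
    for row in loci_rows:
        by_len[row["size"]] = by_len.get(row["size"], 0) + 1
    n_loci = len(loci_rows)
    report["ssr"] = {
        "n_loci": n_loci,
        "pct_by_motif_length": {
            k: round(100 * v / n_loci, 1) if n_loci else 0.0 for k, v in sorted(by_len.items())
        },
    }
    de_rows = read_de(run_dir) if (run_dir / "de.tsv").exists() else []
    de_counts: dict[str, int] = {}
    for row in de_rows:
        if row["direction"] != "ns":
            de_counts[row["contrast"]] = de_counts.get(row["contrast"], 0) + 1
    report["de_counts"] = dict(sorted(de_counts.items()))
    for name in ("setops.tsv",):
        if (run_dir / name).exists():
            report["set_regions"] = {
                row["region"]: int(row["size"]) for row in _read_tsv(run_dir / name)
            }
    if (run_dir / "nat_summary.json").exists():
        report["nat"] = json.loads((run_dir / "nat_summary.json").read_text())
    if (run_dir / "mirna_summary.json").exists():
        report["mirna"] = json.loads((run_dir / "mirna_summary.json").read_text())
    with open(run_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    lines = ["stage summary", "============="]
    lines.append(f"transcripts: {len(transcripts)}")
    for label, count in report["label_counts"].items():
        lines.append(f"  {label}: {count}")
    lines.append(f"lncRNA stratum: {report['lncrna_stats']}")
    lines.append(f"coding stratum: {report['coding_stats']}")
    (run_dir / "report.txt").write_text("\n".join(lines) + "\n")
    return len(report)


_STAGE_FUNCS = {
    "classify": stage_classify,
    "ssr": stage_ssr,
    "de": stage_de,
    "setops": stage_setops,
    "nat": stage_nat,
    "mirna": stage_mirna,
    "report": stage_report,
}


def run_pipeline(
    run_dir: str | Path,
    config: Mapping[str, Any] | None = None,
    stages: Sequence[str] | None = None,
) -> RunManifest:
    """Run the (selected) stages over a prepared run directory."""
    run_dir = Path(run_dir)
    cfg = resolve_config(config)
    selected = list(stages) if stages is not None else list(STAGES)
    for stage in selected:
        if stage not in _STAGE_FUNCS:
            raise ValueError(f"unknown stage {stage!r}")
    checksums = {}
    for name in ("transcripts.fasta", "counts.tsv"):
        path = run_dir / name
        if path.exists():
            checksums[name] = _sha256(path)
    manifest = RunManifest(
        version=__version__,
        input_checksums=checksums,
        config=json.loads(json.dumps(cfg)),
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    with open(run_dir / "config.resolved.yaml", "w") as fh:
        yaml.safe_dump(manifest.config, fh, sort_keys=True)
    for stage in STAGES:
        if stage in selected:
            manifest.stage_counts[stage] = _STAGE_FUNCS[stage](run_dir, cfg)
    manifest.to_json(run_dir / "manifest.json")
    return manifest
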