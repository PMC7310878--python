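"""End-to-end orchestration: reads -> alignments -> counts -> signatures -> tests.

``run_all`` executes the full small-RNA analysis for every library in a run
configuration and writes plain-text outputs (family group table, SAM
alignments, count and signature TSVs, test summaries and a run manifest).
Every stage is a pure function of (inputs, config, seed), so re-running an
identical configuration reproduces identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .align import Alignment, ReferenceIndex, apportion, align_reads, write_sam
from .config import RunConfig
from .quantify import (
    LibraryMeta,
    classify_by_size,
    count_families,
    low_count_filter,
    mirna_total,
    normalize_counts,
    remove_rrna,
)
from .reference import RefCategory, load_fasta, member_to_group, write_group_table
from .signatures import SIGNATURE_COLUMNS, compare_signatures, signature_table
from .synthetic_data import read_fastq

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunResult:
    out_dir: Path
    counts: pd.DataFrame
    signatures: pd.DataFrame
    tests: dict = field(default_factory=dict)
    filter_log: dict = field(default_factory=dict)


def _library_signatures(
    alignments_by_read: dict[str, list[Alignment]],
    groups,
    consensus_by_id,
    library_id: str,
    thresholds,
) -> pd.DataFrame:
    apportioned: list[Alignment] = []
    for read_id in sorted(alignments_by_read):
        apportioned.extend(apportion(alignments_by_read[read_id]))
    return signature_table(
        apportioned,
        groups,
        consensus_by_id,
        library_id=library_id,
        pp_max_offset=thresholds.pp_max_offset,
        max_d=thresholds.max_d,
    )


def run_all(config: RunConfig) -> RunResult:
    """Run the whole pipeline for one configuration; returns in-memory tables."""
    if not config.libraries:
        raise PipelineError("config", "no libraries configured")
    th = config.thresholds
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    try:
        te_refs = load_fasta(config.te_fasta, RefCategory.TE)
        mirna_refs = load_fasta(config.mirna_fasta, RefCategory.MIRNA)
        rrna_refs = (
            load_fasta(config.rrna_fasta, RefCategory.RRNA) if config.rrna_fasta else []
        )
    except (OSError, ValueError) as exc:
        raise PipelineError("reference", str(exc)) from exc
    if not te_refs:
        raise PipelineError("reference", "TE reference FASTA is empty")

    from .reference import collapse_redundant

    groups = collapse_redundant(te_refs)
    write_group_table(groups, out / "family_groups.tsv")
    consensus_by_id = {r.id: r for r in te_refs}
    te_index = ReferenceIndex(te_refs)
    meta = [
        LibraryMeta(lib.library_id, lib.genotype, lib.replicate)
        for lib in config.libraries
    ]

    count_frames: list[pd.DataFrame] = []
    signature_frames: list[pd.DataFrame] = []
    filter_log: dict[str, dict] = {}
    mirna_totals: dict[str, int] = {}
    for lib in config.libraries:
        stage = f"library:{lib.library_id}"
        try:
            reads = read_fastq(lib.fastq)
            classes = classify_by_size(reads)
            pirna = remove_rrna(classes["piRNA"], rrna_refs, max_mm=th.max_mm)
            n_rrna_removed = len(classes["piRNA"]) - len(pirna)
            mi_total = mirna_total(classes["miRNA"], mirna_refs, max_mm=th.mirna_max_mm)
            mirna_totals[lib.library_id] = mi_total
            hits = align_reads(pirna, te_index, max_mm=th.max_mm)
            apportioned = {rid: apportion(alns) for rid, alns in hits.items()}
            counts, count_stats = count_families(
                apportioned, groups, library_id=lib.library_id
            )
            write_sam(
                (a for alns in apportioned.values() for a in alns),
                te_refs,
                out / f"{lib.library_id}.sam",
                read_seqs={r.read_id: r.seq for r in pirna},
            )
            count_frames.append(counts)
            signature_frames.append(
                _library_signatures(
                    apportioned, groups, consensus_by_id, lib.library_id, th
                )
            )
            filter_log[lib.library_id] = {
                "input_reads": len(reads),
                "pirna_candidates": len(classes["piRNA"]),
                "mirna_candidates": len(classes["miRNA"]),
                "other_size": len(classes["other"]),
                "rrna_removed": n_rrna_removed,
                "mirna_total": mi_total,
                **count_stats,
            }
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc

    counts_all = pd.concat(count_frames, ignore_index=True)
    counts_all = normalize_counts(counts_all, mirna_totals)
    counts_all = low_count_filter(counts_all, meta, min_avg=th.min_avg)
    counts_all.to_csv(out / "counts.tsv", sep="\t", index=False)

    signatures_all = pd.concat(signature_frames, ignore_index=True)
    # restrict signature reporting to families passing the low-count filter
    kept = set(counts_all["group_id"])
    signatures_all = signatures_all[signatures_all["group_id"].isin(kept)]
    signatures_all = signatures_all.reset_index(drop=True)[SIGNATURE_COLUMNS]
    signatures_all.to_csv(out / "signatures.tsv", sep="\t", index=False)

    tests = _genotype_contrasts(signatures_all, meta)
    with open(out / "tests.json", "w") as handle:
        json.dump(tests, handle, indent=2, sort_keys=True)

    manifest = {
        "pirnasig_version": __version__,
        "seed": config.seed,
        "thresholds": asdict(th),
        "libraries": [lib.library_id for lib in config.libraries],
        "config_hash": _config_hash(config),
        "filter_log": filter_log,
    }
    with open(out / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)

    return RunResult(out, counts_all, signatures_all, tests, filter_log)


def genotype_mean_signatures(signatures: pd.DataFrame, meta) -> dict[str, pd.DataFrame]:
    """Average each signature over a genotype's replicate libraries."""
    lib_to_geno = {m.library_id: m.genotype for m in meta}
    tagged = signatures.copy()
    tagged["genotype"] = tagged["library_id"].map(lib_to_geno)
    out: dict[str, pd.DataFrame] = {}
    for genotype, sub in tagged.groupby("genotype"):
        out[genotype] = (
            sub.groupby("group_id", as_index=False)[["ppf", "d1", "u1"]].mean()
        )
    return out


def _genotype_contrasts(signatures: pd.DataFrame, meta) -> dict:
    """Paired Wilcoxon tests on each signature for every genotype pair."""
    per_geno = genotype_mean_signatures(signatures, meta)
    genotypes = sorted(per_geno)
    results: dict[str, dict] = {}
    for i, ga in enumerate(genotypes):
        for gb in genotypes[i + 1 :]:
            for metric in ("ppf", "d1", "u1"):
                try:
                    res = compare_signatures(per_geno[ga], per_geno[gb], metric=metric)
                except ValueError as exc:
                    logger.warning("contrast %s vs %s (%s) skipped: %s", ga, gb, metric, exc)
                    continue
                results[f"{ga}_vs_{gb}:{metric}"] = {
                    "method": res.method,
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                    "n": res.n,
                    "direction": res.direction.value,
                }
    return results


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(
        {
            "te": str(config.te_fasta),
            "mirna": str(config.mirna_fasta),
            "rrna": str(config.rrna_fasta),
            "libraries": [
                [str(l.fastq), l.library_id, l.genotype, l.replicate]
                for l in config.libraries
            ],
            "thresholds": asdict(config.thresholds),
            "seed": config.seed,
        },
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
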