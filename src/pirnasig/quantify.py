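"""Size classification, rRNA removal, family counting and normalization.

Reads are partitioned by length into piRNA candidates (23-30 nt) and miRNA
candidates (18-22 nt). rRNA-matching reads are removed. piRNA candidates
aligned to TE consensuses are counted per family group and strand with the
once-only rule: a read whose alignments all fall inside one family group
contributes a single count to that group; a read spanning two or more
non-redundant groups is discarded. Counts are normalized to the library's
miRNA total (reported per million miRNAs), families below 50 mean counts in
every genotype are dropped, and fold changes are classified with the
category thresholds (2-fold for TEs, 1.5-fold for genes).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .align import Alignment, ReferenceIndex, SmallRead, align_reads
from .reference import ConsensusRecord, FamilyGroup, member_to_group

logger = logging.getLogger(__name__)

PIRNA_RANGE = (23, 30)
MIRNA_RANGE = (18, 22)

COUNT_COLUMNS = ["group_id", "library_id", "strand", "raw", "normalized"]


@dataclass(frozen=True)
class LibraryMeta:
    library_id: str
    genotype: str
    replicate: int


def classify_by_size(reads: Iterable[SmallRead]) -> dict[str, list[SmallRead]]:
    """Partition reads into piRNA candidates, miRNA candidates and other."""
    out: dict[str, list[SmallRead]] = {"piRNA": [], "miRNA": [], "other": []}
    for read in reads:
        n = len(read)
        if PIRNA_RANGE[0] <= n <= PIRNA_RANGE[1]:
            out["piRNA"].append(read)
        elif MIRNA_RANGE[0] <= n <= MIRNA_RANGE[1]:
            out["miRNA"].append(read)
        else:
            out["other"].append(read)
    return out


def remove_rrna(
    reads: Sequence[SmallRead],
    rrna_refs: Sequence[ConsensusRecord],
    max_mm: int = 2,
) -> list[SmallRead]:
    """Drop reads that align to any rRNA reference with <= max_mm mismatches."""
    if not rrna_refs:
        return list(reads)
    index = ReferenceIndex(rrna_refs)
    hits = align_reads(reads, index, max_mm=max_mm)
    kept = [read for read in reads if not hits[read.read_id]]
    logger.info("rRNA removal: %d of %d reads removed", len(reads) - len(kept), len(reads))
    return kept


def mirna_total(
    mirna_candidates: Sequence[SmallRead],
    mirna_refs: Sequence[ConsensusRecord],
    max_mm: int = 0,
) -> int:
    """Number of 18-22 nt reads matching the miRNA reference.

    Each read counts once no matter how many miRNAs it hits. Zero matches
    raise, because the miRNA total is a normalization denominator.
    """
    index = ReferenceIndex(mirna_refs)
    hits = align_reads(mirna_candidates, index, max_mm=max_mm)
    total = sum(1 for read in mirna_candidates if hits[read.read_id])
    if total == 0:
        raise ValueError("no reads matched the miRNA reference; normalization undefined")
    return total


def count_families(
    alignments_by_read: Mapping[str, Sequence[Alignment]],
    groups: Sequence[FamilyGroup],
    library_id: str = "lib",
    weighted: bool = False,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per family-group sense/antisense counts for one library.

    Default (once-only) mode: a read whose alignments all fall in a single
    family group contributes count 1 to that group, assigned to the strand
    carrying the majority of its alignment weight (ties split 0.5/0.5).
    Reads spanning >= 2 groups are discarded. ``weighted`` mode instead sums
    the apportioned weights per (group, strand).

    Returns the long-form count table (raw counts; sense = plus strand of
    the consensus) and a tally of discarded / unaligned reads.
    """
    mapping = member_to_group(groups)
    counts: dict[tuple[str, str], float] = {}
    stats = {"counted": 0, "cross_group_discarded": 0, "unaligned": 0}
    for read_id in sorted(alignments_by_read):
        alns = alignments_by_read[read_id]
        if not alns:
            stats["unaligned"] += 1
            continue
        read_groups = {mapping[a.family] for a in alns}
        if len(read_groups) > 1:
            stats["cross_group_discarded"] += 1
            continue
        group_id = next(iter(read_groups))
        stats["counted"] += 1
        if weighted:
            for a in alns:
                strand = "sense" if a.strand == "plus" else "antisense"
                counts[(group_id, strand)] = counts.get((group_id, strand), 0.0) + a.weight
        else:
            plus_w = sum(a.weight for a in alns if a.strand == "plus")
            minus_w = sum(a.weight for a in alns if a.strand == "minus")
            if math.isclose(plus_w, minus_w):
                for strand in ("sense", "antisense"):
                    counts[(group_id, strand)] = counts.get((group_id, strand), 0.0) + 0.5
            else:
                strand = "sense" if plus_w > minus_w else "antisense"
                counts[(group_id, strand)] = counts.get((group_id, strand), 0.0) + 1.0
    rows = [
        {"group_id": g, "library_id": library_id, "strand": s, "raw": c}
        for (g, s), c in sorted(counts.items())
    ]
    table = pd.DataFrame(rows, columns=["group_id", "library_id", "strand", "raw"])
    return table, stats


def normalize_counts(table: pd.DataFrame, mirna_totals: Mapping[str, int]) -> pd.DataFrame:
    """Add a ``normalized`` column: raw / library miRNA total x 10^6."""
    out = table.copy()
    totals = out["library_id"].map(mirna_totals)
    if totals.isna().any():
        missing = sorted(out.loc[totals.isna(), "library_id"].unique())
        raise KeyError(f"no miRNA total for libraries {missing}")
    if (totals <= 0).any():
        raise ValueError("miRNA totals must be positive")
    out["normalized"] = out["raw"] / totals * 1e6
    return out


def low_count_filter(
    table: pd.DataFrame,
    meta: Sequence[LibraryMeta],
    min_avg: float = 50.0,
) -> pd.DataFrame:
    """Drop family groups with a low mean raw count in every genotype.

    A group is retained iff its mean raw count (sense + antisense summed per
    library, averaged over that genotype's replicates) reaches ``min_avg``
    in at least one genotype. Libraries absent from the table count as zero.
    """
    by_genotype: dict[str, list[str]] = {}
    for m in meta:
        by_genotype.setdefault(m.genotype, []).append(m.library_id)
    per_lib = (
        table.groupby(["group_id", "library_id"], as_index=False)["raw"].sum()
        .pivot(index="group_id", columns="library_id", values="raw")
        .reindex(columns=[m.library_id for m in meta])
        .fillna(0.0)
    )
    keep: list[str] = []
    for group_id, row in per_lib.iterrows():
        means = [row[libs].mean() for libs in by_genotype.values()]
        if max(means) >= min_avg:
            keep.append(group_id)
    dropped = per_lib.shape[0] - len(keep)
    logger.info("low-count filter: %d of %d groups dropped", dropped, per_lib.shape[0])
    return table[table["group_id"].isin(keep)].reset_index(drop=True)


def fold_change(
    table: pd.DataFrame,
    meta: Sequence[LibraryMeta],
    genotype_a: str,
    genotype_b: str,
    threshold: float = 2.0,
    pseudocount: float = 0.0,
    strand: str | None = None,
) -> pd.DataFrame:
    """Per-group log2 fold change of normalized counts, A over B.

    Replicates are averaged within each genotype before the ratio. ``threshold``
    is the linear fold-change cutoff for the up/down call (2 for TE families,
    1.5 for protein-coding genes). With the default pseudocount of 0 a zero
    denominator yields +inf (classified up) and 0/0 yields class NA.
    """
    sub = table if strand is None else table[table["strand"] == strand]
    libs = {m.library_id: m.genotype for m in meta}
    sub = sub[sub["library_id"].isin(libs)]
    per_lib = (
        sub.groupby(["group_id", "library_id"], as_index=False)["normalized"].sum()
    )
    per_lib["genotype"] = per_lib["library_id"].map(libs)
    means = (
        per_lib.groupby(["group_id", "genotype"])["normalized"].mean().unstack()
        .reindex(columns=[genotype_a, genotype_b]).fillna(0.0)
    )
    rows = []
    for group_id, row in means.iterrows():
        a = row[genotype_a] + pseudocount
        b = row[genotype_b] + pseudocount
        if a == 0 and b == 0:
            lfc, cls = np.nan, "NA"
        elif b == 0:
            lfc, cls = np.inf, "up"
        elif a == 0:
            lfc, cls = -np.inf, "down"
        else:
            lfc = float(np.log2(a / b))
            if lfc > np.log2(threshold):
                cls = "up"
            elif lfc < -np.log2(threshold):
                cls = "down"
            else:
                cls = "unchanged"
        rows.append({"group_id": group_id, "log2FC": lfc, "class": cls})
    return pd.DataFrame(rows, columns=["group_id", "log2FC", "class"])
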