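"""Consensus reference handling.

Loads FASTA reference sets (TE consensuses, protein-coding transcripts,
miRNAs, rRNAs) and collapses near-identical TE consensuses into family
groups, so that reads hitting several redundant copies of the same family
are counted once.

Redundancy is defined by global pairwise alignment: two consensuses belong
to the same family group when they are more than 90% identical across more
than 90% of the shorter sequence, and groups are the connected components
of that relation (single linkage).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
from Bio import SeqIO
from Bio.Align import PairwiseAligner

logger = logging.getLogger(__name__)

_ALPHABET = set("ACGTN")


class RefCategory(str, Enum):
    TE = "TE"
    GENE = "gene"
    MIRNA = "miRNA"
    RRNA = "rRNA"


@dataclass(frozen=True)
class ConsensusRecord:
    """One reference sequence (TE family consensus, transcript, miRNA or rRNA)."""

    id: str
    seq: str
    category: RefCategory

    def __post_init__(self) -> None:
        if len(self.seq) < 1:
            raise ValueError(f"empty sequence for record {self.id!r}")
        bad = set(self.seq) - _ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r} contains characters outside ACGTN: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class FamilyGroup:
    """A cluster of redundant TE consensuses counted as one family.

    ``group_id`` is the lexicographically smallest member id, which makes
    the grouping deterministic and order-independent.
    """

    group_id: str
    members: set[str] = field(default_factory=set)

    def __contains__(self, member_id: str) -> bool:
        return member_id in self.members


def load_fasta(path: str | Path, category: RefCategory | str) -> list[ConsensusRecord]:
    """Read a FASTA file into :class:`ConsensusRecord` objects.

    Sequences are uppercased and U is converted to T (references may be
    distributed as RNA). Duplicate ids raise a ``ValueError``.
    """
    category = RefCategory(category)
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[ConsensusRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise ValueError(f"duplicate FASTA id {entry.id!r} in {path}")
        seen.add(entry.id)
        seq = str(entry.seq).upper().replace("U", "T")
        if not seq:
            raise ValueError(f"malformed FASTA: record {entry.id!r} has empty sequence")
        try:
            records.append(ConsensusRecord(entry.id, seq, category))
        except ValueError as exc:
            raise ValueError(f"malformed FASTA record {entry.id!r}: {exc}") from exc
    if not records:
        logger.warning("FASTA file %s contained no records", path)
    return records


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    # terminal gaps are free so a short consensus can sit inside a longer one
    aligner.end_gap_score = 0
    return aligner


def pairwise_identity(a: ConsensusRecord, b: ConsensusRecord) -> tuple[float, float]:
    """Global identity and coverage between two consensus sequences.

    Alignment scoring: match +1, mismatch -1, gap -2, terminal gaps free.
    Identity is matches over aligned columns excluding terminal-gap columns
    (internal gap columns and columns containing N count against identity).
    Coverage is the fraction of the shorter sequence that falls inside the
    non-terminal-gap core of the alignment. Both values lie in [0, 1].
    """
    if not a.seq or not b.seq:
        raise ValueError("pairwise_identity requires non-empty sequences")
    aligner = _make_aligner()
    aln = aligner.align(a.seq, b.seq)[0]
    row_a, row_b = str(aln[0]), str(aln[1])

    def core_span(row: str) -> tuple[int, int]:
        first = len(row) - len(row.lstrip("-"))
        last = len(row.rstrip("-"))
        return first, last

    a0, a1 = core_span(row_a)
    b0, b1 = core_span(row_b)
    start, end = max(a0, b0), min(a1, b1)
    if end <= start:
        return 0.0, 0.0

    matches = 0
    columns = 0
    short_in_core = 0
    shorter_row = row_a if len(a.seq) <= len(b.seq) else row_b
    for i in range(start, end):
        ca, cb = row_a[i], row_b[i]
        columns += 1
        if ca == cb and ca != "-" and ca != "N":
            matches += 1
        if shorter_row[i] != "-":
            short_in_core += 1
    identity = matches / columns
    coverage = short_in_core / min(len(a.seq), len(b.seq))
    return identity, coverage


def collapse_redundant(
    records: Sequence[ConsensusRecord],
    id_thresh: float = 0.90,
    cov_thresh: float = 0.90,
) -> list[FamilyGroup]:
    """Cluster redundant TE consensuses into family groups.

    An edge joins two consensuses when identity > ``id_thresh`` AND coverage
    > ``cov_thresh`` (strict inequalities); groups are connected components.
    The output partitions the input: every record id appears in exactly one
    group.
    """
    for rec in records:
        if rec.category is not RefCategory.TE:
            raise ValueError(f"collapse_redundant expects TE records, got {rec.category}")
    graph: nx.Graph = nx.Graph()
    ordered = sorted(records, key=lambda r: r.id)
    graph.add_nodes_from(r.id for r in ordered)
    for i, a in enumerate(ordered):
        for b in ordered[i + 1 :]:
            ident, cov = pairwise_identity(a, b)
            if ident > id_thresh and cov > cov_thresh:
                graph.add_edge(a.id, b.id)
    groups = [
        FamilyGroup(group_id=min(component), members=set(component))
        for component in nx.connected_components(graph)
    ]
    groups.sort(key=lambda g: g.group_id)
    return groups


def member_to_group(groups: Iterable[FamilyGroup]) -> dict[str, str]:
    """Map each member consensus id to its family group id."""
    mapping: dict[str, str] = {}
    for group in groups:
        for member in group.members:
            mapping[member] = group.group_id
    return mapping


def write_group_table(groups: Iterable[FamilyGroup], path: str | Path) -> None:
    """Write the family grouping as a two-column TSV (group_id, member_id)."""
    with open(path, "w") as handle:
        handle.write("group_id\tmember_id\n")
        for group in sorted(groups, key=lambda g: g.group_id):
            for member in sorted(group.members):
                handle.write(f"{group.group_id}\t{member}\n")
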