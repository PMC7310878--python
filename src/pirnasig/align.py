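"""Mismatch-limited ungapped alignment of small reads to consensus references.

Small RNA reads (18-30 nt) are placed end-to-end on consensus-sized
references, on both strands, keeping every placement with at most ``max_mm``
Hamming mismatches. Multi-mapping reads are apportioned: each retained
alignment carries weight 1/n so a read never contributes more than one unit
of evidence.

The search is a pigeonhole seed-and-verify scan: a read aligned with at most
m mismatches must contain at least one exact k-mer block with
k = floor(L / (m + 1)), so exact k-mer lookups against an index of the
references enumerate every candidate offset, which is then verified by a
direct Hamming count. This is complete (no heuristic losses) for ungapped
alignment; reads containing N fall back to a full scan.

Coordinates in the public data model are 1-based inclusive on the consensus
plus strand. For a minus-strand hit the read's 5' end corresponds to ``end``.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam

from .reference import ConsensusRecord

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SmallRead:
    """An adaptor-trimmed small-RNA read."""

    read_id: str
    seq: str

    def __post_init__(self) -> None:
        if not 1 <= len(self.seq) <= 50:
            raise ValueError(f"read {self.read_id!r}: length must be in [1, 50]")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Alignment:
    """One placement of a read on a consensus (1-based inclusive span)."""

    read_id: str
    family: str
    strand: str  # "plus" | "minus"
    start: int
    end: int
    mismatches: int
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.strand not in ("plus", "minus"):
            raise ValueError(f"bad strand {self.strand!r}")
        if self.start > self.end:
            raise ValueError("start must be <= end")

    @property
    def five_prime(self) -> int:
        """5' end coordinate on the consensus plus strand."""
        return self.start if self.strand == "plus" else self.end

    @property
    def three_prime(self) -> int:
        return self.end if self.strand == "plus" else self.start


class ReferenceIndex:
    """Exact k-mer index over a set of references for seeded alignment."""

    def __init__(self, refs: Sequence[ConsensusRecord]):
        if not refs:
            raise ValueError("empty reference list")
        self.refs = list(refs)
        self.by_id = {r.id: r for r in self.refs}
        if len(self.by_id) != len(self.refs):
            raise ValueError("duplicate reference ids")
        self.arrays = {
            r.id: np.frombuffer(r.seq.encode(), dtype=np.uint8) for r in self.refs
        }
        self._kmer_maps: dict[int, dict[str, list[tuple[str, int]]]] = {}

    def _kmer_map(self, k: int) -> dict[str, list[tuple[str, int]]]:
        cached = self._kmer_maps.get(k)
        if cached is not None:
            return cached
        table: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for ref in self.refs:
            seq = ref.seq
            for pos in range(len(seq) - k + 1):
                table[seq[pos : pos + k]].append((ref.id, pos))
        self._kmer_maps[k] = table
        return table

    def _verify(self, ref_id: str, offset: int, read_arr: np.ndarray) -> int | None:
        ref_arr = self.arrays[ref_id]
        L = read_arr.size
        if offset < 0 or offset + L > ref_arr.size:
            return None
        window = ref_arr[offset : offset + L]
        # N (ASCII 78) never matches on either side, including N vs N
        mm = int(np.count_nonzero((window != read_arr) | (read_arr == 78) | (window == 78)))
        return mm

    def _candidates_seeded(self, oriented: str, max_mm: int) -> set[tuple[str, int]]:
        L = len(oriented)
        k = max(1, L // (max_mm + 1))
        table = self._kmer_map(k)
        cands: set[tuple[str, int]] = set()
        for block in range(max_mm + 1):
            seed_start = block * k
            seed = oriented[seed_start : seed_start + k]
            for ref_id, pos in table.get(seed, ()):
                cands.add((ref_id, pos - seed_start))
        return cands

    def _candidates_full(self, length: int) -> Iterable[tuple[str, int]]:
        for ref in self.refs:
            for offset in range(len(ref.seq) - length + 1):
                yield ref.id, offset

    def align(self, read: SmallRead, max_mm: int = 2, best_stratum: bool = False) -> list[Alignment]:
        """All placements of ``read`` with at most ``max_mm`` mismatches.

        With ``best_stratum`` only minimum-mismatch placements are kept.
        """
        L = len(read)
        hits: list[Alignment] = []
        full_scan = "N" in read.seq
        for strand, oriented in (("plus", read.seq), ("minus", revcomp(read.seq))):
            arr = np.frombuffer(oriented.encode(), dtype=np.uint8)
            if full_scan:
                cands: Iterable[tuple[str, int]] = self._candidates_full(L)
            else:
                cands = sorted(self._candidates_seeded(oriented, max_mm))
            for ref_id, offset in cands:
                mm = self._verify(ref_id, offset, arr)
                if mm is not None and mm <= max_mm:
                    hits.append(
                        Alignment(
                            read_id=read.read_id,
                            family=ref_id,
                            strand=strand,
                            start=offset + 1,
                            end=offset + L,
                            mismatches=mm,
                        )
                    )
        if best_stratum and hits:
            best = min(h.mismatches for h in hits)
            hits = [h for h in hits if h.mismatches == best]
        hits.sort(key=lambda h: (h.family, h.start, h.strand))
        return hits


def align_read(
    read: SmallRead,
    refs: Sequence[ConsensusRecord] | ReferenceIndex,
    max_mm: int = 2,
    best_stratum: bool = False,
) -> list[Alignment]:
    """Align one read against a reference set (see :class:`ReferenceIndex`)."""
    index = refs if isinstance(refs, ReferenceIndex) else ReferenceIndex(refs)
    return index.align(read, max_mm=max_mm, best_stratum=best_stratum)


def align_reads(
    reads: Iterable[SmallRead],
    refs: Sequence[ConsensusRecord] | ReferenceIndex,
    max_mm: int = 2,
    best_stratum: bool = False,
) -> dict[str, list[Alignment]]:
    """Align many reads; returns read_id -> retained alignments (may be empty).

    Identical sequences are aligned once and the placements reused.
    """
    index = refs if isinstance(refs, ReferenceIndex) else ReferenceIndex(refs)
    cache: dict[str, list[Alignment]] = {}
    out: dict[str, list[Alignment]] = {}
    for read in reads:
        hits = cache.get(read.seq)
        if hits is None:
            hits = index.align(
                SmallRead("_proto", read.seq), max_mm=max_mm, best_stratum=best_stratum
            )
            cache[read.seq] = hits
        out[read.read_id] = [replace(h, read_id=read.read_id) for h in hits]
    return out


def apportion(alignments_of_one_read: Sequence[Alignment]) -> list[Alignment]:
    """Divide a read's unit count equally over its retained alignments."""
    if not alignments_of_one_read:
        return []
    ids = {a.read_id for a in alignments_of_one_read}
    if len(ids) != 1:
        raise ValueError("apportion expects alignments of a single read")
    w = 1.0 / len(alignments_of_one_read)
    return [replace(a, weight=w) for a in alignments_of_one_read]


# --- SAM import/export -------------------------------------------------------

_WEIGHT_TAG = "XW"


def _sam_header(refs: Sequence[ConsensusRecord]) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": r.id, "LN": len(r.seq)} for r in refs],
        }
    )


def write_sam(
    alignments: Iterable[Alignment],
    refs: Sequence[ConsensusRecord],
    path: str | Path,
    read_seqs: dict[str, str] | None = None,
) -> None:
    """Write alignments as plain-text SAM.

    SAM stores the reference-forward sequence, so minus-strand records carry
    the reverse complement of the read. Mismatch counts go to the NM tag and
    apportioned weights to the XW tag. If ``read_seqs`` is omitted the
    sequence is reconstructed from the reference (mismatch bases are then
    lost, but coordinates, strand, NM and weights round-trip exactly).
    """
    header = _sam_header(refs)
    by_id = {r.id: r for r in refs}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for aln in alignments:
            if aln.family not in by_id:
                raise ValueError(f"alignment references unknown consensus {aln.family!r}")
            seg = pysam.AlignedSegment(header)
            seg.query_name = aln.read_id
            seg.flag = 0 if aln.strand == "plus" else 16
            seg.reference_id = header.get_tid(aln.family)
            seg.reference_start = aln.start - 1  # pysam is 0-based
            seg.mapping_quality = 255
            length = aln.end - aln.start + 1
            seg.cigarstring = f"{length}M"
            if read_seqs is not None and aln.read_id in read_seqs:
                seq = read_seqs[aln.read_id]
                seg.query_sequence = seq if aln.strand == "plus" else revcomp(seq)
            else:
                seg.query_sequence = by_id[aln.family].seq[aln.start - 1 : aln.end]
            seg.set_tag("NM", aln.mismatches)
            seg.set_tag(_WEIGHT_TAG, float(aln.weight))
            out.write(seg)


def read_sam(path: str | Path) -> list[Alignment]:
    """Read alignments back from SAM (inverse of :func:`write_sam`)."""
    alignments: list[Alignment] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as handle:
        names = set(handle.references)
        for seg in handle:
            if seg.is_unmapped:
                continue
            if seg.reference_name not in names:
                raise ValueError(f"SAM record references unknown sequence {seg.reference_name!r}")
            alignments.append(
                Alignment(
                    read_id=seg.query_name,
                    family=seg.reference_name,
                    strand="minus" if seg.is_reverse else "plus",
                    start=seg.reference_start + 1,
                    end=seg.reference_end,
                    mismatches=int(seg.get_tag("NM")) if seg.has_tag("NM") else 0,
                    weight=float(seg.get_tag(_WEIGHT_TAG)) if seg.has_tag(_WEIGHT_TAG) else 1.0,
                )
            )
    return alignments
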