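"""piRNA biogenesis signatures: ping-pong fraction, phasing d1, +1-U.

Three per-family diagnostics of how piRNAs are produced:

* **Ping-pong fraction (ppf)** — reciprocal Slicer cleavage between sense
  and antisense piRNA intermediates leaves pairs whose 5' ends overlap by
  exactly 10 nt. For each piRNA species the fraction of its opposite-strand
  5'-overlapping partners (overlap 1..30 nt) sitting at the 10-nt register
  is computed; the weighted mean of these fractions over *all* species in
  the family (species without partners contribute 0) is the ping-pong
  fraction.
* **d1 proportion** — Zucchini-mediated phased biogenesis chops a precursor
  into head-to-tail piRNAs, so the distance from one piRNA's 3' end to the
  next piRNA's 5' end on the same strand is often exactly 1 nt. Distances
  1..22 nt are histogrammed with pair weights w_i * w_j; d1 is the weight at
  distance 1 over the total.
* **+1-U proportion** — Zucchini cleaves preferentially before a uridine,
  so the consensus base immediately after a piRNA's 3' end is often U. The
  weighted proportion of piRNAs whose +1 base is U(T) is reported.

All three are computed over weighted piRNA *species* (reads collapsed by
strand and 5'/3' coordinates, weights summed); with the product pair
weighting used here this is mathematically identical to enumerating reads.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .align import Alignment
from .reference import ConsensusRecord, FamilyGroup
from .stats import TestResult, wilcoxon_signed_rank

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

SIGNATURE_COLUMNS = [
    "group_id", "library_id", "ppf", "d1", "u1",
    "total_weight", "n_pairs_pp", "n_pairs_d", "n_ends_u",
]


@dataclass
class EndProfile:
    """Weighted piRNA species of one family group.

    Species are keyed by (strand, five_prime, three_prime) with summed
    apportioned weights. Coordinates are 1-based on the consensus plus
    strand; for minus-strand species the 5' end is the rightmost base, so
    five_prime >= three_prime there.
    """

    group_id: str
    species: dict[tuple[str, int, int], float] = field(default_factory=dict)

    def add(self, strand: str, five_prime: int, three_prime: int, weight: float) -> None:
        if weight <= 0:
            raise ValueError("species weight must be positive")
        if strand == "plus" and five_prime > three_prime:
            raise ValueError("plus-strand species must have 5' <= 3'")
        if strand == "minus" and five_prime < three_prime:
            raise ValueError("minus-strand species must have 5' >= 3'")
        key = (strand, five_prime, three_prime)
        self.species[key] = self.species.get(key, 0.0) + weight

    @property
    def total_weight(self) -> float:
        return sum(self.species.values())

    def five_prime_weights(self, strand: str) -> dict[int, float]:
        out: dict[int, float] = defaultdict(float)
        for (s, p5, _p3), w in self.species.items():
            if s == strand:
                out[p5] += w
        return dict(out)

    def three_prime_weights(self, strand: str) -> dict[int, float]:
        out: dict[int, float] = defaultdict(float)
        for (s, _p5, p3), w in self.species.items():
            if s == strand:
                out[p3] += w
        return dict(out)


def build_end_profile(
    apportioned_alignments: Iterable[Alignment],
    group: FamilyGroup,
) -> EndProfile:
    """Collapse a group's apportioned alignments into weighted species."""
    profile = EndProfile(group_id=group.group_id)
    for aln in apportioned_alignments:
        if aln.family not in group.members:
            raise ValueError(
                f"alignment on {aln.family!r} does not belong to group {group.group_id!r}"
            )
        profile.add(aln.strand, aln.five_prime, aln.three_prime, aln.weight)
    return profile


def ping_pong_fraction(
    profile: EndProfile, max_offset: int = 30
) -> tuple[float, dict[str, float]]:
    """Weighted ping-pong fraction of a family's piRNAs.

    The 5'-5' overlap between a plus-strand species with 5' end p and a
    minus-strand species with 5' end q is o = q - p + 1. For each focal
    species, f = (opposite-strand weight at o = 10) / (opposite-strand
    weight over o in [1, max_offset]), or 0 with no partners; the fraction
    is sum(w_i * f_i) / sum(w_i) over every species on both strands.

    Returns (ppf, support) where support carries the total weight and the
    pair weight at the 10-nt register; ppf is NaN for an empty profile.
    """
    total = profile.total_weight
    if total == 0:
        return math.nan, {"total_weight": 0.0, "n_pairs_pp": 0.0}
    w_plus5 = profile.five_prime_weights("plus")
    w_minus5 = profile.five_prime_weights("minus")
    numerator = 0.0
    pair_w10 = 0.0
    for (strand, p5, _p3), w in profile.species.items():
        if strand == "plus":
            partners = w_minus5
            # overlap o maps the partner 5' end to p5 + o - 1
            at10 = partners.get(p5 + 9, 0.0)
            tot = sum(partners.get(p5 + o - 1, 0.0) for o in range(1, max_offset + 1))
        else:
            partners = w_plus5
            at10 = partners.get(p5 - 9, 0.0)
            tot = sum(partners.get(p5 - o + 1, 0.0) for o in range(1, max_offset + 1))
        if tot > 0:
            numerator += w * (at10 / tot)
            pair_w10 += w * at10
    return numerator / total, {"total_weight": total, "n_pairs_pp": pair_w10}


def d1_proportion(
    profile: EndProfile, max_d: int = 22
) -> tuple[float, dict[str, float]]:
    """Proportion of 1-nt 3'-to-5' distances between same-strand piRNAs.

    For an upstream species i and downstream species j on the same strand
    the distance is d = 5'_j - 3'_i (plus strand) or d = 3'_i - 5'_j (minus
    strand, where downstream means further left). Distances in [1, max_d]
    are tallied with weight w_i * w_j; d1 = H[1] / sum(H). NaN when no pair
    falls in the window.
    """
    hist = np.zeros(max_d + 1)
    for strand, sign in (("plus", +1), ("minus", -1)):
        w3 = profile.three_prime_weights(strand)
        w5 = profile.five_prime_weights(strand)
        for x, w_up in w3.items():
            for d in range(1, max_d + 1):
                w_down = w5.get(x + sign * d, 0.0)
                if w_down:
                    hist[d] += w_up * w_down
    total = float(hist[1:].sum())
    if total == 0:
        return math.nan, {"n_pairs_d": 0.0}
    return float(hist[1] / total), {"n_pairs_d": total}


def u1_proportion(
    profile: EndProfile, consensus: ConsensusRecord
) -> tuple[float, dict[str, float]]:
    """Weighted proportion of piRNAs followed by a uridine on the consensus.

    The +1 base of a plus-strand species ending at e is consensus[e+1]; for
    a minus-strand species with 3' end at s it is the complement of
    consensus[s-1]. Species whose +1 position falls off the consensus, or
    is N, are excluded. NaN when every species is excluded.
    """
    seq = consensus.seq
    n = len(seq)
    u_weight = 0.0
    included = 0.0
    for (strand, _p5, p3), w in profile.species.items():
        if strand == "plus":
            pos = p3 + 1
            if pos > n:
                continue
            base = seq[pos - 1]
        else:
            pos = p3 - 1
            if pos < 1:
                continue
            base = _COMP[seq[pos - 1]]
        if base == "N":
            continue
        included += w
        if base == "T":
            u_weight += w
    if included == 0:
        return math.nan, {"n_ends_u": 0.0}
    return u_weight / included, {"n_ends_u": included}


def signature_table(
    alignments: Iterable[Alignment],
    groups: Sequence[FamilyGroup],
    consensus_by_id: Mapping[str, ConsensusRecord],
    library_id: str = "lib",
    pp_max_offset: int = 30,
    max_d: int = 22,
) -> pd.DataFrame:
    """Compute all three signatures per family group for one library.

    ``alignments`` are apportioned 23-30 nt alignments over the whole
    reference set; they are split by family group here. The +1-U base is
    read off the group's representative consensus. Signatures with zero
    supporting weight are NaN.
    """
    by_group: dict[str, list[Alignment]] = defaultdict(list)
    mapping = {m: g.group_id for g in groups for m in g.members}
    for aln in alignments:
        group_id = mapping.get(aln.family)
        if group_id is not None:
            by_group[group_id].append(aln)
    rows = []
    for group in groups:
        alns = by_group.get(group.group_id, [])
        profile = EndProfile(group_id=group.group_id)
        for aln in alns:
            profile.add(aln.strand, aln.five_prime, aln.three_prime, aln.weight)
        ppf, s_pp = ping_pong_fraction(profile, max_offset=pp_max_offset)
        d1, s_d = d1_proportion(profile, max_d=max_d)
        u1, s_u = u1_proportion(profile, consensus_by_id[group.group_id])
        rows.append(
            {
                "group_id": group.group_id,
                "library_id": library_id,
                "ppf": ppf,
                "d1": d1,
                "u1": u1,
                "total_weight": profile.total_weight,
                "n_pairs_pp": s_pp["n_pairs_pp"],
                "n_pairs_d": s_d["n_pairs_d"],
                "n_ends_u": s_u["n_ends_u"],
            }
        )
    return pd.DataFrame(rows, columns=SIGNATURE_COLUMNS)


def compare_signatures(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    metric: str = "ppf",
) -> TestResult:
    """Paired Wilcoxon signed-rank test of a signature between conditions.

    Tables are paired by family group (replicates should already be
    averaged per condition); NaN pairs are dropped (pairwise deletion).
    Raises when fewer than two shared families remain.
    """
    a = table_a.set_index("group_id")[metric]
    b = table_b.set_index("group_id")[metric]
    shared = a.index.intersection(b.index)
    paired = pd.DataFrame({"a": a.loc[shared], "b": b.loc[shared]}).dropna()
    if len(paired) < 2:
        raise ValueError(
            f"compare_signatures needs >= 2 shared families with defined {metric}, "
            f"got {len(paired)}"
        )
    return wilcoxon_signed_rank(paired["a"].to_numpy(), paired["b"].to_numpy())


def split_by_direction(
    table_mut: pd.DataFrame, table_rescue: pd.DataFrame, metric: str = "ppf"
) -> tuple[list[str], list[str]]:
    """Partition families by the sign of mutant minus rescue for a signature.

    Returns (decreased_in_mutant, increased_in_mutant); families with a
    zero or undefined difference appear in neither list.
    """
    a = table_mut.set_index("group_id")[metric]
    b = table_rescue.set_index("group_id")[metric]
    diff = (a - b).dropna()
    decreased = sorted(diff.index[diff < 0])
    increased = sorted(diff.index[diff > 0])
    return decreased, increased
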