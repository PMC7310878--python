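"""Synthetic small-RNA pools with controlled piRNA biogenesis structure.

Generates consensus references and read pools that carry the generative
features the signature statistics detect, together with exact ground truth:

* ping-pong pairs — an antisense read is emitted with a sense partner whose
  5' end gives exactly a 10-nt 5'-5' overlap, at rate ``pp_rho``;
* phased trails — same-strand reads laid head-to-tail with 1-nt spacing
  along a per-family *cleavage lattice* fixed at reference-construction
  time. Lattice cut sites are chosen preferentially at positions where the
  base after a cut is already U (probability ``u1_bias`` of taking a
  U-candidate when one exists), emulating Zucchini's preference for
  cleaving before a uridine. Because the lattice is a property of the
  reference, phasing and +1-U structure are consistent across every
  library simulated against the same reference set, and the consensus
  itself is never modified;
* a uniform background of 23-30 nt reads split sense/antisense, an 18-22 nt
  miRNA pool for normalization, near-identical redundant consensus copies
  to exercise family collapsing, optional rRNA contamination, and per-base
  substitution noise.

Randomness is organised as per-family substreams derived from
(seed, family index, stream tag), so adding a family, or raising ``pp_rho``,
does not perturb the placements already drawn for other events — which
makes ping-pong recovery monotone in ``pp_rho`` under a shared seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .align import SmallRead, revcomp
from .reference import ConsensusRecord, RefCategory

_BASES = np.array(list("ACGT"))

# stream tags keep draw order stable across parameter changes
_S_REF, _S_PLACE, _S_PP, _S_PHASE, _S_MUT, _S_MIRNA = range(6)


@dataclass
class SimParams:
    """Generator settings; defaults are the standard study conditions."""

    n_families: int = 20
    consensus_len: int = 1000
    gc: float = 0.5
    reads_per_family: int = 2000
    antisense_frac: float = 0.7
    pp_rho: float = 0.0
    phase_frac: float = 0.0
    trail_len: int = 4
    u1_bias: float = 0.9
    len_range: tuple[int, int] = (23, 30)
    mut_rate: float = 0.0
    mirna_species: int = 50
    mirna_total: int = 20000
    n_redundant_pairs: int = 0
    n_rrna: int = 2
    rrna_reads: int = 0
    min_spacing: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("gc", "antisense_frac", "pp_rho", "phase_frac", "u1_bias"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.consensus_len < 200:
            raise ValueError("consensus_len must be >= 200")
        lo, hi = self.len_range
        if not (1 <= lo <= hi <= 50):
            raise ValueError("len_range must satisfy 1 <= lo <= hi <= 50")
        if self.n_redundant_pairs > self.n_families:
            raise ValueError("n_redundant_pairs cannot exceed n_families")

    def to_json(self) -> str:
        d = asdict(self)
        d["len_range"] = list(self.len_range)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimParams":
        d = json.loads(text)
        d["len_range"] = tuple(d["len_range"])
        return cls(**d)


@dataclass
class FamilyTruth:
    family: str
    n_background: int = 0
    n_pp_pairs: int = 0
    n_phased: int = 0
    n_trails: int = 0
    n_sense: int = 0
    n_antisense: int = 0

    @property
    def total_reads(self) -> int:
        return self.n_sense + self.n_antisense


@dataclass
class SimTruth:
    """Realized ground truth of one simulated pool."""

    params: SimParams
    families: dict[str, FamilyTruth] = field(default_factory=dict)
    n_mirna_reads: int = 0
    n_rrna_reads: int = 0

    @property
    def total_reads(self) -> int:
        return (
            sum(f.total_reads for f in self.families.values())
            + self.n_mirna_reads
            + self.n_rrna_reads
        )

    def to_json(self) -> str:
        d = {
            "params": json.loads(self.params.to_json()),
            "families": {k: asdict(v) for k, v in self.families.items()},
            "n_mirna_reads": self.n_mirna_reads,
            "n_rrna_reads": self.n_rrna_reads,
            "total_reads": self.total_reads,
        }
        return json.dumps(d, indent=2, sort_keys=True)


@dataclass
class SimReferences:
    """Reference bundle: sequences plus the per-family cleavage lattices.

    ``lattice[family][strand]`` is the ordered list of phased cut
    coordinates (1-based); consecutive cuts delimit one potential phased
    piRNA, and the base at each interior cut is U-enriched per ``u1_bias``.
    """

    te: list[ConsensusRecord]
    mirna: list[ConsensusRecord]
    rrna: list[ConsensusRecord]
    lattice: dict[str, dict[str, list[int]]] = field(default_factory=dict)


def _rng(params: SimParams, *tags: int) -> np.random.Generator:
    return np.random.default_rng([params.seed, *tags])


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=length, p=p))


def _cleavage_lattice(
    rng: np.random.Generator, seq: str, lo: int, hi: int, u1_bias: float
) -> dict[str, list[int]]:
    """Phased cut coordinates per strand, preferring cuts before a U.

    Plus strand: ascending cuts c0 < c1 < ...; a phased read occupies
    [c_i, c_{i+1} - 1], so its +1 base is seq[c_{i+1}]. With probability
    ``u1_bias`` the next cut is drawn uniformly from the candidate spacings
    (lo..hi nt) whose base is T, when any exists; otherwise uniformly from
    all candidates. The minus-strand lattice descends and prefers A (U
    after complementing).
    """
    n = len(seq)
    lattice: dict[str, list[int]] = {}
    for strand, step, want in (("plus", 1, "T"), ("minus", -1, "A")):
        cuts = [1 if strand == "plus" else n]
        while True:
            c = cuts[-1]
            candidates = [c + step * d for d in range(lo, hi + 1)]
            candidates = [x for x in candidates if 1 <= x <= n]
            if len(candidates) < hi - lo + 1:
                break  # ran off the consensus
            preferred = [x for x in candidates if seq[x - 1] == want]
            if preferred and rng.random() < u1_bias:
                cuts.append(preferred[int(rng.integers(len(preferred)))])
            else:
                cuts.append(candidates[int(rng.integers(len(candidates)))])
        lattice[strand] = cuts
    return lattice


def make_references(params: SimParams) -> SimReferences:
    """TE consensuses (plus 5%-diverged redundant copies), miRNAs and rRNAs.

    The first ``n_redundant_pairs`` families each get a duplicate consensus
    with 5% of positions substituted (95% identity, full coverage), which
    family collapsing should merge back into one group. Each family also
    carries its fixed phased-cleavage lattice (see :class:`SimReferences`).
    """
    lo, hi = params.len_range
    te: list[ConsensusRecord] = []
    lattices: dict[str, dict[str, list[int]]] = {}
    for fam in range(params.n_families):
        rng = _rng(params, _S_REF, fam)
        seq = _random_seq(rng, params.consensus_len, params.gc)
        te.append(ConsensusRecord(f"TE{fam:03d}", seq, RefCategory.TE))
        lattices[te[-1].id] = _cleavage_lattice(rng, seq, lo, hi, params.u1_bias)
    for fam in range(params.n_redundant_pairs):
        rng = _rng(params, _S_REF, params.n_families + fam)
        base = list(te[fam].seq)
        n_sub = max(1, round(0.05 * len(base)))
        sites = rng.choice(len(base), size=n_sub, replace=False)
        for pos in sites:
            choices = [b for b in "ACGT" if b != base[pos]]
            base[pos] = choices[rng.integers(3)]
        te.append(ConsensusRecord(f"TE{fam:03d}_dup", "".join(base), RefCategory.TE))

    rng_mi = _rng(params, _S_REF, 10_000)
    mirna = [
        ConsensusRecord(
            f"mir{i:03d}",
            _random_seq(rng_mi, int(rng_mi.integers(18, 23)), params.gc),
            RefCategory.MIRNA,
        )
        for i in range(params.mirna_species)
    ]
    rng_rr = _rng(params, _S_REF, 20_000)
    rrna = [
        ConsensusRecord(f"rRNA{i}", _random_seq(rng_rr, 500, params.gc), RefCategory.RRNA)
        for i in range(params.n_rrna)
    ]
    return SimReferences(te=te, mirna=mirna, rrna=rrna, lattice=lattices)


def _emit_read(consensus: list[str], strand: str, five_prime: int, length: int) -> str | None:
    """Copy a read off the (possibly edited) consensus; 1-based 5' coordinate."""
    n = len(consensus)
    if strand == "plus":
        start, end = five_prime, five_prime + length - 1
    else:
        start, end = five_prime - length + 1, five_prime
    if start < 1 or end > n:
        return None
    frag = "".join(consensus[start - 1 : end])
    return frag if strand == "plus" else revcomp(frag)


def simulate_pool(
    params: SimParams, references: SimReferences
) -> tuple[list[SmallRead], SimTruth, SimReferences]:
    """Generate the read pool and ground truth for one library.

    The references are read-only: with ``mut_rate`` 0 every read is an
    exact copy of the consensus, and any number of libraries (different
    seeds, different ping-pong/phasing rates) can be simulated against the
    same reference bundle. Phased trails walk the family's fixed cleavage
    lattice, so the d1 and +1-U structure is shared across libraries.
    """
    lo, hi = params.len_range
    margin = hi + 15
    truth = SimTruth(params=params)
    reads: list[SmallRead] = []

    for fam_idx in range(params.n_families):
        fam_id = f"TE{fam_idx:03d}"
        consensus = list(next(r.seq for r in references.te if r.id == fam_id))
        lattice = references.lattice.get(fam_id, {})
        n = len(consensus)
        ft = FamilyTruth(family=fam_id)
        truth.families[fam_id] = ft
        rng_place = _rng(params, _S_PLACE, fam_idx)
        rng_pp = _rng(params, _S_PP, fam_idx)
        rng_phase = _rng(params, _S_PHASE, fam_idx)

        planned: list[tuple[str, int, int, str]] = []  # (strand, 5', length, kind)
        for event in range(params.reads_per_family):
            # fixed per-event draw order on rng_place keeps placements
            # identical when pp_rho or phase_frac change on rng_pp/rng_phase
            if params.min_spacing is not None:
                anchor = margin + event * params.min_spacing
                if anchor > n - margin:
                    break
            else:
                anchor = int(rng_place.integers(margin, n - margin + 1))
            is_antisense = bool(rng_place.random() < params.antisense_frac)
            length = int(rng_place.integers(lo, hi + 1))
            u_phase = rng_phase.random()
            u_pp = rng_pp.random()

            if u_phase < params.phase_frac and lattice:
                # phased trail: consecutive cuts of the family lattice
                strand = "minus" if is_antisense else "plus"
                cuts = lattice[strand]
                start = int(rng_phase.integers(0, max(1, len(cuts) - 1)))
                ft.n_trails += 1
                for i in range(params.trail_len):
                    j = start + i
                    if j + 1 >= len(cuts):
                        break  # trail runs off the lattice: truncate
                    p5, nxt = cuts[j], cuts[j + 1]
                    tl = abs(nxt - p5)
                    planned.append((strand, p5, tl, "ph"))
                    ft.n_phased += 1
            elif is_antisense and u_pp < params.pp_rho:
                # antisense read with a sense partner at the 10-nt register
                partner_len = int(rng_pp.integers(lo, hi + 1))
                planned.append(("minus", anchor, length, "ppA"))
                planned.append(("plus", anchor - 9, partner_len, "ppS"))
                ft.n_pp_pairs += 1
            else:
                strand = "minus" if is_antisense else "plus"
                planned.append((strand, anchor, length, "bg"))
                ft.n_background += 1

        for serial, (strand, p5, length, kind) in enumerate(planned):
            seq = _emit_read(consensus, strand, p5, length)
            if seq is None:  # margins make this unreachable
                raise AssertionError("planned read outside consensus")
            reads.append(SmallRead(f"{fam_id}:{kind}:{serial}", seq))
            if strand == "plus":
                ft.n_sense += 1
            else:
                ft.n_antisense += 1

    # substitution noise
    if params.mut_rate > 0:
        rng_mut = _rng(params, _S_MUT)
        mutated: list[SmallRead] = []
        for read in reads:
            chars = list(read.seq)
            hits = np.nonzero(rng_mut.random(len(chars)) < params.mut_rate)[0]
            for pos in hits:
                choices = [b for b in "ACGT" if b != chars[pos]]
                chars[pos] = choices[rng_mut.integers(3)]
            mutated.append(SmallRead(read.read_id, "".join(chars)))
        reads = mutated

    rng_mi = _rng(params, _S_MIRNA)
    for i in range(params.mirna_total):
        ref = references.mirna[int(rng_mi.integers(len(references.mirna)))]
        reads.append(SmallRead(f"mirna:{i}", ref.seq))
        truth.n_mirna_reads += 1
    for i in range(params.rrna_reads):
        ref = references.rrna[int(rng_mi.integers(len(references.rrna)))]
        length = int(rng_mi.integers(lo, hi + 1))
        start = int(rng_mi.integers(0, len(ref.seq) - length + 1))
        reads.append(SmallRead(f"rrna:{i}", ref.seq[start : start + length]))
        truth.n_rrna_reads += 1

    return reads, truth, references


_PRESETS: dict[str, dict] = {
    # emulate the mutant vs transgenic-rescue contrast: ping-pong and phased
    # biogenesis collapse in the mutant and recover under the rescues
    "mutant-like": {"pp_rho": 0.0, "phase_frac": 0.0},
    "rescue-like": {"pp_rho": 0.6, "phase_frac": 0.3},
    "weak-rescue": {"pp_rho": 0.45, "phase_frac": 0.22},
}


def scenario_presets(name: str, **overrides) -> SimParams:
    """Named parameter bundles for the mutant / rescue scenarios."""
    if name not in _PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}")
    kwargs = {**_PRESETS[name], **overrides}
    return SimParams(**kwargs)


def preset_names() -> list[str]:
    return sorted(_PRESETS)


# --- plain-text I/O ----------------------------------------------------------


def write_fastq(reads: Sequence[SmallRead], path: str | Path) -> None:
    with open(path, "w") as handle:
        for read in reads:
            handle.write(f"@{read.read_id}\n{read.seq}\n+\n{'I' * len(read.seq)}\n")


def read_fastq(path: str | Path) -> list[SmallRead]:
    from Bio import SeqIO

    return [
        SmallRead(rec.id, str(rec.seq).upper().replace("U", "T"))
        for rec in SeqIO.parse(str(path), "fastq")
    ]


def write_fasta(records: Sequence[ConsensusRecord], path: str | Path) -> None:
    with open(path, "w") as handle:
        for rec in records:
            handle.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), 70):
                handle.write(rec.seq[i : i + 70] + "\n")
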