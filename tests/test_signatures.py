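"""Ping-pong fraction, d1 and +1-U: worked examples, oracles, invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pirnasig import (
    Alignment,
    ConsensusRecord,
    EndProfile,
    FamilyGroup,
    RefCategory,
    build_end_profile,
    compare_signatures,
    d1_proportion,
    ping_pong_fraction,
    signature_table,
    split_by_direction,
    u1_proportion,
)

from oracles import brute_d1, brute_ppf, brute_u1, random_species


def profile_from(species):
    profile = EndProfile(group_id="g")
    for strand, p5, p3, w in species:
        profile.add(strand, p5, p3, w)
    return profile


class TestBuildEndProfile:
    def test_identical_loci_merge(self):
        group = FamilyGroup("fam", {"fam"})
        alns = [
            Alignment("r1", "fam", "plus", 20, 45, 0, 1.0),
            Alignment("r2", "fam", "plus", 20, 45, 0, 1.0),
        ]
        profile = build_end_profile(alns, group)
        assert profile.species == {("plus", 20, 45): 2.0}

    def test_strand_end_conventions(self):
        group = FamilyGroup("fam", {"fam"})
        plus = build_end_profile([Alignment("r", "fam", "plus", 20, 45, 0, 1.0)], group)
        minus = build_end_profile([Alignment("r", "fam", "minus", 4, 29, 0, 1.0)], group)
        assert ("plus", 20, 45) in plus.species
        assert ("minus", 29, 4) in minus.species  # 5' is the rightmost base

    def test_foreign_alignment_rejected(self):
        group = FamilyGroup("fam", {"fam"})
        with pytest.raises(ValueError, match="belong"):
            build_end_profile([Alignment("r", "other", "plus", 1, 24, 0, 1.0)], group)


class TestPingPongFraction:
    def test_plus_only_profile_is_zero(self):
        ppf, _ = ping_pong_fraction(profile_from([("plus", 20, 45, 1.0)]))
        assert ppf == 0.0

    def test_single_pair_at_register_ten(self):
        species = [("plus", 20, 45, 1.0), ("minus", 29, 5, 1.0)]
        ppf, support = ping_pong_fraction(profile_from(species))
        assert ppf == 1.0
        assert support["total_weight"] == 2.0

    def test_weighted_three_species_example(self):
        # A (plus, w=2) pairs B at o=10; C sits at o=31 from A, outside the window
        species = [
            ("plus", 20, 45, 2.0),
            ("minus", 29, 5, 1.0),
            ("minus", 50, 26, 1.0),
        ]
        ppf, _ = ping_pong_fraction(profile_from(species))
        assert ppf == pytest.approx(0.75, abs=1e-12)
        assert brute_ppf(species) == pytest.approx(0.75, abs=1e-12)

    def test_empty_profile_is_nan(self):
        ppf, _ = ping_pong_fraction(EndProfile("g"))
        assert math.isnan(ppf)


class TestD1Proportion:
    def test_adjacent_pair_gives_one(self):
        d1, _ = d1_proportion(profile_from([("plus", 10, 35, 1.0), ("plus", 36, 60, 1.0)]))
        assert d1 == 1.0

    def test_mixed_distances_half(self):
        species = [
            ("plus", 10, 35, 1.0),
            ("plus", 36, 60, 1.0),  # d = 1 from first
            ("plus", 65, 88, 1.0),  # d = 5 from second
        ]
        d1, _ = d1_proportion(profile_from(species))
        assert d1 == pytest.approx(0.5)
        assert brute_d1(species) == pytest.approx(0.5)

    def test_single_species_is_nan(self):
        d1, _ = d1_proportion(profile_from([("plus", 10, 35, 1.0)]))
        assert math.isnan(d1)

    def test_minus_strand_distance_direction(self):
        # downstream on the minus strand means further left
        species = [("minus", 60, 36, 1.0), ("minus", 35, 11, 1.0)]
        d1, _ = d1_proportion(profile_from(species))
        assert d1 == 1.0


class TestU1Proportion:
    def consensus(self, seq):
        return ConsensusRecord("fam", seq, RefCategory.TE)

    def test_plus_strand_reads_base_after_three_prime(self):
        cons = self.consensus("A" * 30 + "T" + "A" * 30)
        u1, _ = u1_proportion(profile_from([("plus", 5, 30, 1.0)]), cons)
        assert u1 == 1.0
        u1, _ = u1_proportion(profile_from([("plus", 4, 29, 1.0)]), cons)
        assert u1 == 0.0

    def test_minus_strand_uses_complement(self):
        # minus species 3' at 31; +1 position is 30; complement(A)=T
        cons = self.consensus("G" * 29 + "A" + "G" * 31)
        u1, _ = u1_proportion(profile_from([("minus", 55, 31, 1.0)]), cons)
        assert u1 == 1.0

    def test_weighted_mix(self):
        cons = self.consensus("C" * 30 + "T" + "C" * 9 + "A" + "C" * 20)
        species = [("plus", 5, 30, 2.0), ("plus", 15, 40, 1.0)]
        u1, _ = u1_proportion(profile_from(species), cons)
        assert u1 == pytest.approx(2 / 3)
        assert brute_u1(species, cons.seq) == pytest.approx(2 / 3)

    def test_off_consensus_species_excluded(self):
        cons = self.consensus("A" * 30)
        u1, _ = u1_proportion(profile_from([("plus", 5, 30, 1.0)]), cons)
        assert math.isnan(u1)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(12))
    def test_signatures_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        species = random_species(rng, int(rng.integers(2, 120)))
        profile = profile_from(species)
        consensus = ConsensusRecord(
            "fam", "".join(rng.choice(list("ACGT"), size=600)), RefCategory.TE
        )
        merged = [(s, p5, p3, w) for (s, p5, p3), w in profile.species.items()]
        ppf, _ = ping_pong_fraction(profile)
        d1, _ = d1_proportion(profile)
        u1, _ = u1_proportion(profile, consensus)
        assert ppf == pytest.approx(brute_ppf(merged), abs=1e-9)
        for mine, oracle in ((d1, brute_d1(merged)), (u1, brute_u1(merged, consensus.seq))):
            if math.isnan(oracle):
                assert math.isnan(mine)
            else:
                assert mine == pytest.approx(oracle, abs=1e-9)


class TestInvariants:
    @given(st.integers(0, 10_000), st.floats(0.1, 50.0))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_scale_invariance_and_range(self, seed, scale):
        rng = np.random.default_rng(seed)
        species = random_species(rng, 40)
        base = profile_from(species)
        scaled = profile_from([(s, p5, p3, w * scale) for s, p5, p3, w in species])
        for fn in (ping_pong_fraction, d1_proportion):
            v0, _ = fn(base)
            v1, _ = fn(scaled)
            assert v0 == pytest.approx(v1, abs=1e-9)
            assert math.isnan(v0) or 0.0 <= v0 <= 1.0

    def test_pure_ping_pong_construction_is_exactly_one(self):
        # isolated pairs at the 10-nt register, far apart
        species = []
        for i in range(10):
            base = 100 + 200 * i
            species.append(("plus", base, base + 25, 1.0 + i))
            species.append(("minus", base + 9, base - 16, 2.0))
        ppf, _ = ping_pong_fraction(profile_from(species))
        assert ppf == 1.0


class TestCompareSignatures:
    def table(self, values, library="lib"):
        import pandas as pd

        return pd.DataFrame(
            {"group_id": [f"g{i}" for i in range(len(values))],
             "library_id": library, "ppf": values}
        )

    def test_identical_tables_p_one(self):
        t = self.table([0.1, 0.2, 0.3])
        res = compare_signatures(t, t, metric="ppf")
        assert res.p_value == 1.0

    def test_uniform_shift_detected(self):
        rng = np.random.default_rng(5)
        base = rng.uniform(0.1, 0.5, size=20)
        res = compare_signatures(self.table(base + 0.1), self.table(base))
        assert res.p_value < 0.01
        assert res.direction.value == "A_greater"

    def test_disjoint_families_error(self):
        a = self.table([0.1, 0.2])
        b = self.table([0.1, 0.2])
        b["group_id"] = ["x1", "x2"]
        with pytest.raises(ValueError, match="shared"):
            compare_signatures(a, b)

    def test_nan_pairs_dropped(self):
        a = self.table([0.4, 0.5, float("nan"), 0.7])
        b = self.table([0.1, 0.2, 0.3, 0.4])
        res = compare_signatures(a, b)
        assert res.n == 3

    def test_split_by_direction(self):
        mut = self.table([0.1, 0.5, 0.3])
        rescue = self.table([0.2, 0.4, 0.3])
        down, up = split_by_direction(mut, rescue)
        assert down == ["g0"] and up == ["g1"]


def test_signature_table_assembles_all_groups(rng):
    from conftest import random_record

    refs = [random_record(rng, f"f{i}", 400) for i in range(2)]
    groups = [FamilyGroup(r.id, {r.id}) for r in refs]
    alns = [
        Alignment("r1", "f0", "plus", 20, 45, 0, 1.0),
        Alignment("r2", "f0", "minus", 5, 29, 0, 1.0),
    ]
    table = signature_table(alns, groups, {r.id: r for r in refs})
    assert list(table["group_id"]) == ["f0", "f1"]
    row0 = table.iloc[0]
    assert row0["ppf"] == 1.0 and row0["total_weight"] == 2.0
    assert math.isnan(table.iloc[1]["ppf"])  # no reads, no signature
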