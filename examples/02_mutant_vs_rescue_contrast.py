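"""Compare ping-pong between a mutant-like and a rescue-like condition.

Simulates two pools against one shared reference set — the mutant with
collapsed ping-pong/phasing and the rescue with both active — then runs the
paired Wilcoxon signed-rank test over per-family ping-pong fractions, the
same comparison used to contrast genotypes in small-RNA studies.
"""

from pirnasig import (
    ReferenceIndex,
    SimParams,
    align_reads,
    apportion,
    classify_by_size,
    collapse_redundant,
    compare_signatures,
    make_references,
    scenario_presets,
    signature_table,
    simulate_pool,
)


def signatures(params, refs):
    reads, _truth, refs = simulate_pool(params, refs)
    pirna = classify_by_size(reads)["piRNA"]
    hits = align_reads(pirna, ReferenceIndex(refs.te), max_mm=2)
    groups = collapse_redundant(refs.te)
    apportioned = [a for alns in hits.values() for a in apportion(alns)]
    return signature_table(apportioned, groups, {r.id: r for r in refs.te})


common = dict(n_families=15, reads_per_family=600)
refs = make_references(SimParams(seed=21, **common))
rescue = signatures(scenario_presets("rescue-like", seed=21, **common), refs)
mutant = signatures(scenario_presets("mutant-like", seed=22, **common), refs)

res = compare_signatures(rescue, mutant, metric="ppf")
print(f"mean ppf: rescue {rescue['ppf'].mean():.3f}  mutant {mutant['ppf'].mean():.3f}")
print(f"paired Wilcoxon signed-rank over {res.n} families: p = {res.p_value:.2e}")
print(f"direction: {res.direction.value} (A = rescue)")
print(
    "\nA small p-value with direction A_greater reproduces the qualitative"
    " pattern that functional rescue restores ping-pong amplification"
    " family by family."
)
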