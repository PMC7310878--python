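"""Direction-bias and independence statistics for the piRNA pipeline.

Exact sign / binomial tests (two-sided by tail doubling), the 2x2 Pearson
chi-square test of independence, the paired Wilcoxon signed-rank test used
for family-level signature comparisons, and the genomic auto-immunity
analysis that asks whether a piRNA-pathway transgene represses host
protein-coding genes and whether one allele represses more genes than the
other.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)


class Direction(str, Enum):
    A_GREATER = "A_greater"
    B_GREATER = "B_greater"
    NONE = "none"


@dataclass(frozen=True)
class TestResult:
    method: str
    statistic: float
    p_value: float
    n: int
    direction: Direction = Direction.NONE

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value out of range: {self.p_value}")


def binomial_test(k: int, n: int, p0: float = 0.5, method: str = "double") -> TestResult:
    """Exact two-sided binomial test of k successes in n trials.

    ``method='double'`` (default) doubles the smaller tail and caps at 1:
    p = min(1, 2 * min(P(X <= k), P(X >= k))). ``method='minlike'`` sums all
    outcomes with point probability at most that of k (the scipy default
    convention).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("k must be in [0, n]")
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must be in (0, 1)")
    if method == "double":
        lower = sps.binom.cdf(k, n, p0)
        upper = sps.binom.sf(k - 1, n, p0)
        p = min(1.0, 2.0 * min(lower, upper))
    elif method == "minlike":
        p = float(sps.binomtest(k, n, p0, alternative="two-sided").pvalue)
    else:
        raise ValueError(f"unknown method {method!r}")
    if k / n > p0:
        direction = Direction.A_GREATER
    elif k / n < p0:
        direction = Direction.B_GREATER
    else:
        direction = Direction.NONE
    return TestResult("binomial", float(k), float(p), n, direction)


def sign_test(k: int, n: int, method: str = "double") -> TestResult:
    """Exact two-sided sign test: binomial test at p0 = 0.5."""
    result = binomial_test(k, n, p0=0.5, method=method)
    return TestResult("sign", result.statistic, result.p_value, n, result.direction)


def chisq_2x2(a: int, b: int, c: int, d: int, yates: bool = True) -> TestResult:
    """Pearson chi-square test of independence on the 2x2 table [[a, b], [c, d]].

    Yates continuity correction is applied by default; every row and column
    margin must be positive.
    """
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table < 0).any():
        raise ValueError("cell counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("chi-square test undefined with a zero margin")
    stat, p, _dof, _exp = sps.chi2_contingency(table, correction=yates)
    return TestResult("chisq_2x2", float(stat), float(p), int(table.sum()))


def wilcoxon_signed_rank(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided paired Wilcoxon signed-rank test.

    NaN pairs and zero differences are dropped; tied magnitudes are
    mid-ranked. The exact null distribution is used for n <= 25 without
    ties, otherwise the normal approximation with tie and continuity
    correction. All-zero differences give p = 1 (no evidence of shift).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    diffs = x[keep] - y[keep]
    if diffs.size < 2:
        raise ValueError("need >= 2 non-NaN pairs")
    nonzero = diffs[diffs != 0]
    n = nonzero.size
    if n == 0:
        return TestResult("wilcoxon_signed_rank", 0.0, 1.0, diffs.size, Direction.NONE)
    ranks = sps.rankdata(np.abs(nonzero))
    has_ties = np.unique(np.abs(nonzero)).size < n
    method = "exact" if (n <= 25 and not has_ties) else "approx"
    res = sps.wilcoxon(
        nonzero, zero_method="wilcox", correction=True, method=method,
        alternative="two-sided",
    )
    w_plus = float(ranks[nonzero > 0].sum())
    w_minus = float(ranks[nonzero < 0].sum())
    if w_plus > w_minus:
        direction = Direction.A_GREATER
    elif w_minus > w_plus:
        direction = Direction.B_GREATER
    else:
        direction = Direction.NONE
    return TestResult(
        "wilcoxon_signed_rank", float(res.statistic), float(res.pvalue), n, direction
    )


# --- genomic auto-immunity ---------------------------------------------------


@dataclass
class AutoimmunityResult:
    """Gene-level regulation table plus the summary tests of the analysis."""

    table: pd.DataFrame
    tests: dict[str, TestResult] = field(default_factory=dict)
    venn: dict[str, int] = field(default_factory=dict)
    down_counts: dict[str, int] = field(default_factory=dict)
    up_counts: dict[str, int] = field(default_factory=dict)


def antisense_eligibility(
    antisense_means: pd.DataFrame, min_avg: float = 50.0
) -> pd.Series:
    """Which genes have enough antisense piRNAs to compare between rescues.

    Eligible iff the mean antisense piRNA count exceeds ``min_avg`` in at
    least one genotype (strictly greater; a mean of exactly 50 is not
    enough). Expects columns gene_id, genotype, mean_count.
    """
    pivot = antisense_means.pivot_table(
        index="gene_id", columns="genotype", values="mean_count", aggfunc="mean"
    )
    return pivot.max(axis=1) > min_avg


def autoimmunity_analysis(
    gene_fc: Mapping[str, pd.DataFrame],
    expr_fc_a_vs_b: pd.DataFrame,
    pirna_fc: pd.DataFrame | None = None,
    antisense_means: pd.DataFrame | None = None,
    fc_thresh: float = 1.5,
    min_avg: float = 50.0,
) -> AutoimmunityResult:
    """Host-gene repression comparison between two rescue transgenes.

    ``gene_fc`` maps each of exactly two transgene labels (e.g. 'mel',
    'sim') to a per-gene table (gene_id, log2FC) of rescue-vs-mutant
    expression. A gene is called down (up) under a transgene when its
    expression changes more than ``fc_thresh``-fold in that direction. The
    analysis reports per-transgene down/up counts with a binomial test, a
    2x2 chi-square comparing down-gene counts between transgenes, the
    overlap of down-gene sets, and — over the union of down genes — sign
    tests on the direction of the between-rescue expression fold change and
    (when provided) of the sense/antisense genic piRNA fold changes
    restricted to genes with enough antisense piRNAs.
    """
    if len(gene_fc) != 2:
        raise ValueError("autoimmunity_analysis requires exactly two transgene tables")
    (label_a, fc_a), (label_b, fc_b) = sorted(gene_fc.items())
    cut = np.log2(fc_thresh)

    merged = (
        fc_a.set_index("gene_id")["log2FC"].rename(f"log2FC_{label_a}").to_frame()
        .join(fc_b.set_index("gene_id")["log2FC"].rename(f"log2FC_{label_b}"), how="outer")
    )
    for label in (label_a, label_b):
        lfc = merged[f"log2FC_{label}"]
        merged[f"down_{label}"] = lfc < -cut
        merged[f"up_{label}"] = lfc > cut

    tests: dict[str, TestResult] = {}
    down_counts: dict[str, int] = {}
    up_counts: dict[str, int] = {}
    for label in (label_a, label_b):
        n_down = int(merged[f"down_{label}"].sum())
        n_up = int(merged[f"up_{label}"].sum())
        down_counts[label] = n_down
        up_counts[label] = n_up
        if n_down + n_up == 0:
            logger.warning("no genes change > %.1f-fold under %s; binomial test skipped",
                           fc_thresh, label)
            continue
        tests[f"binomial_down_vs_up_{label}"] = binomial_test(n_down, n_down + n_up)

    n_genes = len(merged)
    if down_counts.get(label_a, 0) + down_counts.get(label_b, 0) > 0:
        tests["chisq_down_between_transgenes"] = chisq_2x2(
            down_counts[label_a], n_genes - down_counts[label_a],
            down_counts[label_b], n_genes - down_counts[label_b],
        )

    set_a = set(merged.index[merged[f"down_{label_a}"]])
    set_b = set(merged.index[merged[f"down_{label_b}"]])
    venn = {
        f"only_{label_a}": len(set_a - set_b),
        f"only_{label_b}": len(set_b - set_a),
        "both": len(set_a & set_b),
    }
    union = sorted(set_a | set_b)

    expr = expr_fc_a_vs_b.set_index("gene_id")["log2FC"]
    merged["log2FC_between_rescues"] = expr.reindex(merged.index)
    down_expr = expr.reindex(union).dropna()
    signed = down_expr[down_expr != 0]
    if len(signed) >= 1:
        tests["sign_expression_down_genes"] = sign_test(int((signed > 0).sum()), len(signed))
    elif union:
        logger.warning("no nonzero between-rescue expression fold-changes among down genes")

    if antisense_means is not None:
        eligible = antisense_eligibility(antisense_means, min_avg=min_avg)
        merged["antisense_eligible"] = eligible.reindex(merged.index).fillna(False)
    else:
        merged["antisense_eligible"] = False

    if pirna_fc is not None:
        for strand in ("sense", "antisense"):
            sub = pirna_fc[pirna_fc["strand"] == strand].set_index("gene_id")["log2FC"]
            merged[f"pirna_{strand}_log2FC"] = sub.reindex(merged.index)
            pool = sub.reindex(union).dropna()
            pool = pool[merged.loc[pool.index, "antisense_eligible"]]
            pool = pool[pool != 0]
            if len(pool) >= 1:
                tests[f"sign_pirna_{strand}_down_genes"] = sign_test(
                    int((pool > 0).sum()), len(pool)
                )

    merged.index.name = "gene_id"
    return AutoimmunityResult(
        table=merged.reset_index(),
        tests=tests,
        venn=venn,
        down_counts=down_counts,
        up_counts=up_counts,
    )
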