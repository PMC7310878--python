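"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive — full scans, exhaustive pair
enumeration, explicit enumeration of null distributions — and shares no
code with the package internals it checks.
"""

from __future__ import annotations

from itertools import product
from math import comb

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def brute_align(read_seq: str, refs: dict[str, str], max_mm: int):
    """Every ungapped placement with <= max_mm mismatches, both strands.

    Returns a set of (ref_id, strand, start, end, mismatches) with 1-based
    inclusive coordinates. N on either side counts as a mismatch.
    """
    hits = set()
    for strand, oriented in (("plus", read_seq), ("minus", rc(read_seq))):
        L = len(oriented)
        for ref_id, ref_seq in refs.items():
            for off in range(len(ref_seq) - L + 1):
                mm = sum(
                    1
                    for a, b in zip(oriented, ref_seq[off : off + L])
                    if a != b or a == "N" or b == "N"
                )
                if mm <= max_mm:
                    hits.add((ref_id, strand, off + 1, off + L, mm))
    return hits


# species: list of (strand, five_prime, three_prime, weight)


def brute_ppf(species, max_offset: int = 30) -> float:
    """Ping-pong fraction by full enumeration of opposite-strand pairs."""
    total = sum(w for *_x, w in species)
    if total == 0:
        return float("nan")
    num = 0.0
    for strand, p5, _p3, w in species:
        at10 = 0.0
        tot = 0.0
        for s2, q5, _q3, w2 in species:
            if s2 == strand:
                continue
            o = (q5 - p5 + 1) if strand == "plus" else (p5 - q5 + 1)
            if 1 <= o <= max_offset:
                tot += w2
                if o == 10:
                    at10 += w2
        if tot > 0:
            num += w * at10 / tot
    return num / total


def brute_d1(species, max_d: int = 22) -> float:
    """d1 proportion by enumerating every ordered same-strand pair."""
    hist = {d: 0.0 for d in range(1, max_d + 1)}
    for strand, _p5, p3, w in species:
        for s2, q5, _q3, w2 in species:
            if s2 != strand:
                continue
            d = (q5 - p3) if strand == "plus" else (p3 - q5)
            if 1 <= d <= max_d:
                hist[d] += w * w2
    total = sum(hist.values())
    if total == 0:
        return float("nan")
    return hist[1] / total


def brute_u1(species, consensus: str) -> float:
    """+1-U proportion by direct weighted tally on the consensus."""
    n = len(consensus)
    u = inc = 0.0
    for strand, _p5, p3, w in species:
        if strand == "plus":
            pos = p3 + 1
            if pos > n:
                continue
            base = consensus[pos - 1]
        else:
            pos = p3 - 1
            if pos < 1:
                continue
            base = _COMP[consensus[pos - 1]]
        if base == "N":
            continue
        inc += w
        if base == "T":
            u += w
    return u / inc if inc else float("nan")


def random_species(rng, n: int, span: int = 400):
    """Random weighted piRNA species for oracle-equivalence checks."""
    out = []
    for _ in range(n):
        strand = "plus" if rng.random() < 0.5 else "minus"
        a = int(rng.integers(1, span))
        length = int(rng.integers(23, 31))
        if strand == "plus":
            p5, p3 = a, a + length - 1
        else:
            p5, p3 = a + length - 1, a
        out.append((strand, p5, p3, float(rng.integers(1, 5))))
    return out


def binom_two_sided_double(k: int, n: int, p0: float = 0.5) -> float:
    """Tail-doubled two-sided binomial p-value by direct pmf summation."""
    pmf = [comb(n, i) * p0**i * (1 - p0) ** (n - i) for i in range(n + 1)]
    lower = sum(pmf[: k + 1])
    upper = sum(pmf[k:])
    return min(1.0, 2.0 * min(lower, upper))


def wilcoxon_exact_enum(diffs) -> float:
    """Two-sided exact signed-rank p by enumerating all 2^n sign patterns.

    Magnitudes are assumed untied and nonzero; mid-ranking is irrelevant in
    that case.
    """
    mags = sorted(abs(d) for d in diffs)
    assert all(m > 0 for m in mags) and len(set(mags)) == len(mags)
    n = len(diffs)
    ranks = {m: i + 1 for i, m in enumerate(mags)}
    w_plus_obs = sum(ranks[abs(d)] for d in diffs if d > 0)
    total = n * (n + 1) / 2
    w_obs = min(w_plus_obs, total - w_plus_obs)
    count = 0
    for signs in product((0, 1), repeat=n):
        w_plus = sum((i + 1) for i, s in enumerate(signs) if s)
        if min(w_plus, total - w_plus) <= w_obs:
            count += 1
    return count / 2**n


def nw_score(a: str, b: str, match=1, mismatch=-1, gap=-2) -> float:
    """Optimal global alignment score with free terminal gaps (plain DP)."""
    n, m = len(a), len(b)
    prev = [0.0] * (m + 1)  # free leading gaps
    for i in range(1, n + 1):
        cur = [0.0] + [float("-inf")] * m
        for j in range(1, m + 1):
            diag = prev[j - 1] + (match if a[i - 1] == b[j - 1] else mismatch)
            up = prev[j] + (gap if j < m else 0)  # free trailing gap in b
            left = cur[j - 1] + (gap if i < n else 0)
            cur[j] = max(diag, up, left)
        prev = cur
    return prev[m]
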