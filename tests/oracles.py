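"""Independent brute-force oracles used to verify the package's statistics.

Everything here is written from the textbook definition, deliberately
avoiding the code paths (scipy closed forms, vectorized formulas) that the
package itself uses.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np


def hypergeom_upper_tail(hits: int, n_bg: int, k_set: int, n_draw: int) -> float:
    """P(X >= hits) by exact-rational summation of the hypergeometric pmf."""
    denom = math.comb(n_bg, n_draw)
    lo = max(hits, 0, n_draw - (n_bg - k_set))
    hi = min(k_set, n_draw)
    total = Fraction(0)
    for k in range(lo, hi + 1):
        total += Fraction(math.comb(k_set, k) * math.comb(n_bg - k_set, n_draw - k),
                          denom)
    return float(min(total, Fraction(1)))


def hypergeom_tail_table(n_bg: int, k_set: int, n_draw: int
                         ) -> tuple[list[float], int, int]:
    """Upper tails P(X >= h) for every achievable h, one exact pmf pass."""
    lo = max(0, n_draw - (n_bg - k_set))
    hi = min(k_set, n_draw)
    denom = math.comb(n_bg, n_draw)
    pmf = [Fraction(math.comb(k_set, k) * math.comb(n_bg - k_set, n_draw - k), denom)
           for k in range(lo, hi + 1)]
    tails: list[Fraction] = []
    acc = Fraction(0)
    for v in reversed(pmf):
        acc += v
        tails.append(acc)
    tails.reverse()
    return [float(min(t, Fraction(1))) for t in tails], lo, hi


def bh_stepup(p: list[float]) -> list[float]:
    """BH q-values straight from the step-up definition."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * m / rank)
        q[i] = min(val, 1.0)
        prev = val
    return q


def welch_t(a: list[float], b: list[float]) -> tuple[float, float]:
    """Welch t and Satterthwaite df from the scalar textbook formulas."""
    n1, n2 = len(a), len(b)
    m1 = sum(a) / n1
    m2 = sum(b) / n2
    v1 = sum((x - m1) ** 2 for x in a) / (n1 - 1)
    v2 = sum((x - m2) ** 2 for x in b) / (n2 - 1)
    se2 = v1 / n1 + v2 / n2
    t = (m1 - m2) / math.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    return t, df


def average_ranks(x: list[float]) -> list[float]:
    """Average ranks (1-based) computed by direct tie-group averaging."""
    order = sorted(range(len(x)), key=lambda i: x[i])
    ranks = [0.0] * len(x)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and x[order[j + 1]] == x[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_rho(x: list[float], y: list[float]) -> float:
    """Spearman rho = Pearson correlation of average ranks."""
    rx, ry = average_ranks(x), average_ranks(y)
    mx = sum(rx) / len(rx)
    my = sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den


def spearman_exact_p(x: list[float], y: list[float]) -> float:
    """Two-sided exact permutation p for Spearman rho (all n! orderings)."""
    obs = abs(spearman_rho(x, y))
    count = 0
    total = 0
    for perm in itertools.permutations(y):
        total += 1
        if abs(spearman_rho(x, list(perm))) >= obs - 1e-12:
            count += 1
    return count / total


def ranksum_complete_separation_p(n1: int, n2: int) -> float:
    """Exact two-sided rank-sum p when one group entirely exceeds the other."""
    return 2.0 / math.comb(n1 + n2, n1)


def count_edges_bruteforce(stats_rows: dict, threshold: float, metric: str) -> int:
    """Independent tally of retained directed edges from an MGP stats dict.

    ``stats_rows`` maps (gi, gj) -> (statistic, p, q).
    """
    idx = {"p": 1, "q": 2}[metric]
    edges = 0
    seen = set()
    for (gi, gj), row in stats_rows.items():
        key = frozenset((gi, gj))
        if key in seen:
            continue
        seen.add(key)
        rev = stats_rows[(gj, gi)]
        for cand in (row, rev):
            if cand[idx] <= threshold and cand[0] > 0:
                edges += 1
                break
    return edges


def binomial_99_band(p0: float, n: int) -> tuple[float, float]:
    """Two-sided 99% normal-approximation band for a binomial proportion."""
    half = 2.5758293035489004 * math.sqrt(p0 * (1 - p0) / n)
    return p0 - half, p0 + half


def degree_recount(edges: list[tuple[str, str]], nodes: list[str]) -> dict:
    out = {t: 0 for t in nodes}
    inn = {t: 0 for t in nodes}
    for a, b in edges:
        out[a] += 1
        inn[b] += 1
    return {"out": out, "in": inn}


def random_stats_table(rng: np.random.Generator, genes: list[str],
                       gene_to_type: dict[str, str]):
    """A random but internally consistent MGP stats table (antisymmetric
    statistics, mirrored p) as both a DataFrame and a plain dict."""
    import pandas as pd

    m = len(genes)
    pairs = [(genes[i], genes[j]) for i in range(m) for j in range(m) if i != j]
    stat = {}
    p = {}
    for i in range(m):
        for j in range(i + 1, m):
            s = rng.normal()
            pv = rng.uniform()
            stat[(genes[i], genes[j])] = s
            stat[(genes[j], genes[i])] = -s
            p[(genes[i], genes[j])] = pv
            p[(genes[j], genes[i])] = pv
    idx = pd.MultiIndex.from_tuples(pairs, names=["gene_i", "gene_j"])
    df = pd.DataFrame({
        "type_i": [gene_to_type[a] for a, _ in pairs],
        "type_j": [gene_to_type[b] for _, b in pairs],
        "statistic": [stat[pr] for pr in pairs],
        "p": [p[pr] for pr in pairs],
    }, index=idx)
    from braincci import bh_fdr

    df["q"] = bh_fdr(df["p"].to_numpy())
    rows = {pr: (df.loc[pr, "statistic"], df.loc[pr, "p"], df.loc[pr, "q"])
            for pr in pairs}
    return df, rows
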