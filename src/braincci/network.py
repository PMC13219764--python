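"""Directed gene network and cell-pair (CCI) enrichment.

Significant marker-gene pairs are collapsed to one directed edge per
unordered gene pair — the direction with the higher log ratio in cases (or
the positive severity correlation).  Each ordered cell-type pair X->Y is
then tested for enrichment of edges running from X-specific to Y-specific
markers: with f the background rate of significant pairs over the full
ordered marker-pair universe M(M-1), the expected edge count is L_X * L_Y * f,
the enrichment ratio ER = observed / expected, and significance comes from a
one-sided Fisher exact test on the 2x2 table (cross-pair X->Y vs not) x
(edge present vs not).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .association import bh_fdr
from .data_io import logger


def count_directed_cell_pairs(t: int) -> int:
    """Number of ordered cell-type pairs among t types (self-pairs excluded)."""
    if t < 2:
        raise ValueError(f"need at least 2 cell types, got {t}")
    return t * (t - 1)


@dataclass
class GenePairNetwork:
    """Directed gene-gene network of significant marker pairs.

    ``edges`` has columns source, target, statistic, p, q; ``n_total`` is the
    size of the ordered marker-pair universe the significance gate ran over,
    so the background rate is ``n_sig / n_total``.
    """

    edges: pd.DataFrame
    gene_to_type: dict[str, str]
    n_total: int

    @property
    def n_sig(self) -> int:
        return len(self.edges)

    @property
    def nodes(self) -> list[str]:
        return list(self.gene_to_type)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for gene, cell_type in self.gene_to_type.items():
            g.add_node(gene, cell_type=cell_type)
        for row in self.edges.itertuples(index=False):
            g.add_edge(row.source, row.target, statistic=row.statistic, q=row.q)
        return g


def build_directed_network(
    stats_table: pd.DataFrame,
    q_threshold: float = 0.05,
    metric: str = "q",
) -> GenePairNetwork:
    """Collapse an MGP statistics table into a directed gene network.

    For every unordered gene pair whose test passes ``metric <= q_threshold``,
    only the direction with the positive statistic (higher in cases /
    positive severity correlation) is kept; reciprocal exclusivity is
    verified on every run.
    """
    if metric not in ("q", "p"):
        raise ValueError("metric must be 'q' or 'p'")
    if not 0 < q_threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    gene_to_type = dict(zip(
        [*stats_table.index.get_level_values(0), *stats_table.index.get_level_values(1)],
        [*stats_table["type_i"], *stats_table["type_j"]],
    ))
    sig = stats_table[(stats_table[metric] <= q_threshold)
                      & (stats_table["statistic"] > 0)]
    seen: set[frozenset[str]] = set()
    for gi, gj in sig.index:
        key = frozenset((gi, gj))
        if key in seen:
            raise ValueError(
                f"reciprocal pair {gi}/{gj} both claim a positive statistic; "
                "antisymmetry violated upstream"
            )
        seen.add(key)
    edges = pd.DataFrame({
        "source": sig.index.get_level_values(0),
        "target": sig.index.get_level_values(1),
        "statistic": sig["statistic"].to_numpy(),
        "p": sig["p"].to_numpy(),
        "q": sig["q"].to_numpy(),
    }).reset_index(drop=True)
    logger.info("directed network: %d edges from %d ordered pairs at %s<=%g",
                len(edges), len(stats_table), metric, q_threshold)
    return GenePairNetwork(edges=edges, gene_to_type=gene_to_type,
                           n_total=len(stats_table))


def cci_enrichment(
    net: GenePairNetwork,
    cross_only_background: bool = False,
    alternative: str = "greater",
    n_permutations: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Enrichment of directed edges between every ordered cell-type pair.

    Within-type pairs (X->X) are not tested as cell pairs, but by default
    they remain part of the background universe.  ``n_permutations > 0`` adds
    a gene-label permutation p-value column (``perm_p``) alongside the Fisher
    p; Fisher remains the primary test.
    """
    g2t = net.gene_to_type
    types = sorted(set(g2t.values()))
    if len(types) < 2:
        raise ValueError("need at least 2 cell types for CCI enrichment")
    L = {t: sum(1 for v in g2t.values() if v == t) for t in types}
    m = len(g2t)
    full_universe = m * (m - 1)
    within = sum(l * (l - 1) for l in L.values())
    if net.n_total not in (full_universe,):
        raise ValueError(
            f"network universe {net.n_total} inconsistent with M(M-1)={full_universe}"
        )
    src_t = net.edges["source"].map(g2t)
    tgt_t = net.edges["target"].map(g2t)
    if cross_only_background:
        n_total = full_universe - within
        cross = src_t.to_numpy() != tgt_t.to_numpy()
        n_sig = int(cross.sum())
    else:
        n_total = full_universe
        n_sig = net.n_sig
    f = n_sig / n_total if n_total else 0.0

    counts = pd.crosstab(src_t, tgt_t) if len(net.edges) else pd.DataFrame()
    rows = []
    for x in types:
        for y in types:
            if x == y:
                continue
            observed = int(counts.loc[x, y]) if (x in counts.index and y in counts.columns) else 0
            slots = L[x] * L[y]
            expected = slots * f
            if expected > 0:
                er = observed / expected
            elif observed > 0:
                raise ValueError(f"observed {observed} edges for {x}->{y} with "
                                 "empty significant-pair universe")
            else:
                er = np.nan
            if n_sig == 0:
                p = 1.0
            elif alternative == "greater":
                p = float(stats.hypergeom.sf(observed - 1, n_total, n_sig, slots))
            elif alternative == "two-sided":
                table = [[observed, slots - observed],
                         [n_sig - observed, n_total - slots - (n_sig - observed)]]
                p = float(stats.fisher_exact(table, alternative="two-sided")[1])
            else:
                raise ValueError("alternative must be 'greater' or 'two-sided'")
            rows.append({"source_type": x, "target_type": y, "L_x": L[x], "L_y": L[y],
                         "observed": observed, "expected": expected, "er": er,
                         "fisher_p": p})
    cci = pd.DataFrame(rows)
    cci["q"] = bh_fdr(cci["fisher_p"].to_numpy())
    if n_permutations > 0:
        cci["perm_p"] = _permutation_p(net, cci, n_permutations, seed)
    logger.info("cci_enrichment: %d types, %d ordered pairs, f=%.4g (n_sig=%d/%d)",
                len(types), len(cci), f, n_sig, n_total)
    return cci.set_index(["source_type", "target_type"])


def _permutation_p(net: GenePairNetwork, cci: pd.DataFrame,
                   n_permutations: int, seed: int) -> np.ndarray:
    """Gene-label permutation p for each observed edge count (type labels
    shuffled over marker genes, set sizes preserved)."""
    rng = np.random.default_rng(seed)
    genes = np.array(net.nodes)
    labels = np.array([net.gene_to_type[g] for g in genes])
    src = net.edges["source"].to_numpy()
    tgt = net.edges["target"].to_numpy()
    gene_idx = {g: i for i, g in enumerate(genes)}
    si = np.array([gene_idx[g] for g in src], dtype=int)
    ti = np.array([gene_idx[g] for g in tgt], dtype=int)
    pair_keys = cci.index if isinstance(cci.index, pd.MultiIndex) else \
        pd.MultiIndex.from_frame(cci[["source_type", "target_type"]])
    key_pos = {k: i for i, k in enumerate(pair_keys)}
    observed = cci["observed"].to_numpy()
    ge = np.zeros(len(cci), dtype=int)
    for _ in range(n_permutations):
        perm = labels[rng.permutation(len(labels))]
        cnt = np.zeros(len(cci), dtype=int)
        for a, b in zip(perm[si], perm[ti]):
            pos = key_pos.get((a, b))
            if pos is not None:
                cnt[pos] += 1
        ge += cnt >= observed
    return (1.0 + ge) / (1.0 + n_permutations)


def hierarchy_layers(cci: pd.DataFrame, q_threshold: float = 0.05) -> pd.DataFrame:
    """Rank cell types by their position in the significant-CCI graph.

    Degrees are counted over CCIs with q <= threshold; the layer rank orders
    types by descending (out-degree - in-degree), ties broken by higher
    out-degree then name, rank 1 = top (net sender).
    """
    sig = cci[cci["q"] <= q_threshold]
    types = sorted(set(cci.index.get_level_values(0)) |
                   set(cci.index.get_level_values(1)))
    out_deg = {t: 0 for t in types}
    in_deg = {t: 0 for t in types}
    for x, y in sig.index:
        out_deg[x] += 1
        in_deg[y] += 1
    df = pd.DataFrame({
        "cell_type": types,
        "out_degree": [out_deg[t] for t in types],
        "in_degree": [in_deg[t] for t in types],
    })
    df["net_out"] = df["out_degree"] - df["in_degree"]
    df = df.sort_values(["net_out", "out_degree", "cell_type"],
                        ascending=[False, False, True], kind="stable")
    df["layer_rank"] = np.arange(1, len(df) + 1)
    return df.drop(columns="net_out").set_index("cell_type")


def er_concordance(cci_a: pd.DataFrame, cci_b: pd.DataFrame) -> tuple[float, float]:
    """Spearman correlation between two runs' enrichment-ratio vectors.

    Tables are aligned on the ordered cell-pair index; pairs with an
    undefined ER in either table are dropped pairwise.
    """
    shared = cci_a.index.intersection(cci_b.index)
    a = cci_a.loc[shared, "er"].to_numpy(dtype=float)
    b = cci_b.loc[shared, "er"].to_numpy(dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    if int(ok.sum()) < 4:
        raise ValueError("fewer than 4 shared cell pairs with finite ER")
    rho, p = stats.spearmanr(a[ok], b[ok])
    return float(rho), float(p)


def write_edge_list(net: GenePairNetwork, path: str) -> None:
    """Edge list TSV: source, target, statistic, q (plus p)."""
    net.edges.to_csv(path, sep="\t", index=False)


def write_dot(net: GenePairNetwork, path: str) -> None:
    """Minimal DOT export for graph viewers."""
    with open(path, "w") as fh:
        fh.write("digraph mgp {\n")
        for gene, t in net.gene_to_type.items():
            fh.write(f'  "{gene}" [cell_type="{t}"];\n')
        for row in net.edges.itertuples(index=False):
            fh.write(f'  "{row.source}" -> "{row.target}" [q={row.q:.3g}];\n')
        fh.write("}\n")
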