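"""Marker-gene-pair (MGP) log-ratio matrix construction.

The elementary feature of the pipeline: for M retained marker genes and S
samples, every ordered pair (g_i, g_j), i != j, gets a per-sample log2
expression ratio, giving an M(M-1) x S matrix.  Antisymmetry
value(i->j, s) == -value(j->i, s) holds exactly because each entry is a
difference of the same two log2 values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd

from .data_io import ExpressionMatrix, MarkerSetCollection, logger


@dataclass
class MGPMatrix:
    """All ordered marker-gene-pair log2 ratios (M(M-1) rows x S samples)."""

    pairs: list[tuple[str, str]]
    sample_ids: list[str]
    values: np.ndarray  # (len(pairs), len(sample_ids))
    gene_to_type: dict[str, str]

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def marker_genes(self) -> list[str]:
        return list(self.gene_to_type)

    def pair_index(self) -> dict[tuple[str, str], int]:
        return {p: k for k, p in enumerate(self.pairs)}

    def to_frame(self) -> pd.DataFrame:
        idx = pd.MultiIndex.from_tuples(self.pairs, names=["gene_i", "gene_j"])
        return pd.DataFrame(self.values, index=idx, columns=self.sample_ids)


def _retained_markers(expr: ExpressionMatrix, markers: MarkerSetCollection,
                      min_markers: int = 3) -> MarkerSetCollection:
    """Uniquely-typed markers present in the expression matrix."""
    return markers.dedup("drop").restrict_to(expr.gene_ids, min_markers=min_markers)


def iter_mgp_blocks(
    expr: ExpressionMatrix,
    markers: MarkerSetCollection,
    pseudocount: float = 1.0,
    block_rows: int = 200_000,
    min_markers: int = 3,
) -> Iterator[tuple[list[tuple[str, str]], np.ndarray]]:
    """Yield (pairs, values) blocks of the MGP matrix without materializing it.

    Rows are generated gene-major: for each i, all j != i in order.  Blocks
    hold at most ``block_rows`` rows so M ~ 2000 markers (~4M rows) can be
    streamed through the association stage in constant memory.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    # pseudocount 0 on linear data containing zeros is rejected by log2_values
    retained = _retained_markers(expr, markers, min_markers)
    genes = retained.all_genes
    m = len(genes)
    if m < 2:
        raise ValueError(f"need >=2 retained marker genes, have {m}")
    log_e = expr.log2_values(pseudocount).loc[genes].to_numpy(dtype=float)
    buf_pairs: list[tuple[str, str]] = []
    buf_vals: list[np.ndarray] = []
    n_buf = 0
    for i in range(m):
        others = [j for j in range(m) if j != i]
        block = log_e[i][None, :] - log_e[others]  # (m-1, S)
        buf_pairs.extend((genes[i], genes[j]) for j in others)
        buf_vals.append(block)
        n_buf += m - 1
        if n_buf >= block_rows:
            yield buf_pairs, np.vstack(buf_vals)
            buf_pairs, buf_vals, n_buf = [], [], 0
    if buf_pairs:
        yield buf_pairs, np.vstack(buf_vals)


def build_mgp_matrix(
    expr: ExpressionMatrix,
    markers: MarkerSetCollection,
    pseudocount: float = 1.0,
    min_markers: int = 3,
) -> MGPMatrix:
    """Materialize the full ordered-pair log2-ratio matrix.

    Both within-type and cross-type pairs are included: the cell-pair
    enrichment stage needs the full pair universe for its background rate.
    """
    retained = _retained_markers(expr, markers, min_markers)
    gene_to_type = retained.gene_to_type()
    pairs: list[tuple[str, str]] = []
    blocks: list[np.ndarray] = []
    for p, v in iter_mgp_blocks(expr, markers, pseudocount, min_markers=min_markers):
        pairs.extend(p)
        blocks.append(v)
    values = np.vstack(blocks)
    logger.info("MGP matrix: M=%d markers -> %d ordered pairs x %d samples",
                len(gene_to_type), len(pairs), values.shape[1])
    return MGPMatrix(pairs=pairs, sample_ids=expr.sample_ids, values=values,
                     gene_to_type=gene_to_type)


def write_mgp(mgp: MGPMatrix, path: str) -> None:
    """Persist as TSV: pair_id column 'GENE1|GENE2', one column per sample."""
    df = pd.DataFrame(mgp.values, columns=mgp.sample_ids)
    df.insert(0, "pair_id", [f"{a}|{b}" for a, b in mgp.pairs])
    df.to_csv(path, sep="\t", index=False)
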