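"""Rank-based per-sample cell signature scores (BASE-style).

For each sample, genes are sorted by descending expression and a weighted
running sum walks down the list: marker genes add a foreground increment
proportional to their expression magnitude, non-markers subtract a uniform
background step.  The raw score is the maximum deviation of this running
sum; it is then centered on the mean raw score over random gene-label
permutations and scaled by their mean absolute centered deviation, so a
score near 0 means the set's markers sit no higher in the ranking than
chance, and a higher score means a greater inferred relative abundance of
that cell type.  The centering matters: the signed extreme of a weighted
excursion has a positive expectation even for random marker labels.

A pure rank-weight variant (foreground weights = average expression ranks)
is exactly invariant to any monotone transform of a sample's expression
vector and is available via ``variant="rank"``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import ExpressionMatrix, MarkerSetCollection, SampleMetadata, logger


def _running_sum_extreme(pos: np.ndarray, w: np.ndarray, n_genes: int) -> np.ndarray:
    """Signed maximum deviation of the marker running sum.

    ``pos``: (k, m) marker positions in the descending-expression order,
    sorted ascending per row; ``w``: matching foreground weights, rows sum
    to 1.  Background decrement is uniform 1/(G - m).  Works on k
    arrangements at once.
    """
    k, m = pos.shape
    if n_genes <= m:
        return np.ones(k)
    step = 1.0 / (n_genes - m)
    cw = np.cumsum(w, axis=1)
    i = np.arange(m)
    after = cw - (pos - i) * step            # running sum just after marker i
    before = np.where(i == 0, 0.0, cw - w) - (pos - i) * step
    hi = after.max(axis=1)
    lo = np.minimum(before.min(axis=1), 0.0)
    return np.where(hi >= -lo, hi, lo)


def base_scores(
    expr: ExpressionMatrix,
    markers: MarkerSetCollection,
    n_perm: int = 200,
    seed: int = 0,
    variant: str = "expression",
) -> pd.DataFrame:
    """Per-sample, per-cell-type rank-based signature scores.

    Scores are reproducible bit-for-bit for a given (expr, markers, n_perm,
    seed).  The random null marker positions are drawn once per set and
    shared by all samples (they do not depend on the data), so the
    Monte-Carlo error of the normalization is common-mode across samples and
    cancels from between-sample comparisons; editing one sample can never
    change another sample's scores.
    """
    if variant not in ("expression", "rank"):
        raise ValueError("variant must be 'expression' or 'rank'")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    genes = np.array(expr.gene_ids)
    n_genes = len(genes)
    # linear-scale magnitudes drive the foreground weights
    mat = expr.data.to_numpy(dtype=float)
    if expr.scale == "log2":
        mat = np.exp2(mat)
    gene_pos = {g: i for i, g in enumerate(genes)}
    set_members = {}
    for cell_type, gs in markers.sets.items():
        present = [gene_pos[g] for g in gs if g in gene_pos]
        if not present:
            warnings.warn(f"no markers of {cell_type!r} present in expression; "
                          "scores set to NA")
        set_members[cell_type] = np.array(present, dtype=int)

    # one shared set of null marker positions per set size
    null_positions = {}
    for t_idx, (cell_type, members) in enumerate(set_members.items()):
        m = len(members)
        if m == 0 or m >= n_genes:
            continue
        rng = np.random.default_rng([seed, t_idx])
        null_positions[cell_type] = np.sort(
            rng.random((n_perm, n_genes)).argsort(axis=1)[:, :m], axis=1)

    out = pd.DataFrame(np.nan, index=expr.sample_ids, columns=list(markers.sets))
    for s_idx, sample in enumerate(expr.sample_ids):
        x = mat[:, s_idx]
        # descending expression, deterministic tie-break by gene id
        order = np.lexsort((genes, -x))
        pos_of = np.empty(n_genes, dtype=int)
        pos_of[order] = np.arange(n_genes)
        if variant == "expression":
            weight_source = x[order]
        else:
            # average ranks, larger for higher expression
            weight_source = stats.rankdata(x)[order]
        for cell_type, members in set_members.items():
            m = len(members)
            if m == 0:
                continue
            pos = np.sort(pos_of[members])
            w = weight_source[pos].astype(float)
            tot = w.sum()
            w = w / tot if tot > 0 else np.full(m, 1.0 / m)
            raw = _running_sum_extreme(pos[None, :], w[None, :], n_genes)[0]
            if cell_type not in null_positions:
                out.loc[sample, cell_type] = 0.0
                continue
            perm_pos = null_positions[cell_type]
            pw = weight_source[perm_pos].astype(float)
            sums = pw.sum(axis=1, keepdims=True)
            pw = np.where(sums > 0, pw / np.where(sums == 0, 1, sums), 1.0 / m)
            null = _running_sum_extreme(perm_pos, pw, n_genes)
            center = null.mean()
            scale = np.abs(null - center).mean()
            out.loc[sample, cell_type] = ((raw - center) / scale if scale > 0
                                          else 0.0)
    logger.info("base_scores(%s): %d samples x %d cell types, n_perm=%d",
                variant, out.shape[0], out.shape[1], n_perm)
    return out


def compare_scores(
    scores: pd.DataFrame,
    meta: SampleMetadata,
    mode: str = "group_wilcoxon",
    add_fdr: bool = False,
) -> pd.DataFrame:
    """Compare per-type signature scores across groups or against severity.

    ``group_wilcoxon``: two-sided rank-sum test, effect = mean score
    difference (case - control).  ``severity_spearman``: Spearman rho vs the
    severity column.  Raw p-values by default; ``add_fdr`` appends BH q.
    """
    rows = []
    if mode == "group_wilcoxon":
        if meta.group is None:
            raise ValueError("metadata has no group column")
        grp = meta.group.loc[scores.index]
        case = scores.loc[grp == "case"]
        ctrl = scores.loc[grp == "control"]
        if len(case) == 0 or len(ctrl) == 0:
            raise ValueError("a group has no samples")
        for cell_type in scores.columns:
            a = case[cell_type].dropna()
            b = ctrl[cell_type].dropna()
            if len(a) == 0 or len(b) == 0:
                rows.append({"cell_type": cell_type, "effect": np.nan, "p": 1.0})
                continue
            pooled = np.concatenate([a, b])
            no_ties = np.unique(pooled).size == pooled.size
            method = "exact" if (no_ties and pooled.size <= 60) else "auto"
            _, p = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
            rows.append({"cell_type": cell_type,
                         "effect": float(a.mean() - b.mean()), "p": float(p)})
    elif mode == "severity_spearman":
        if meta.severity is None:
            raise ValueError("metadata has no severity column")
        sev = meta.severity.loc[scores.index].astype(float)
        for cell_type in scores.columns:
            pair = pd.DataFrame({"s": scores[cell_type], "v": sev}).dropna()
            if len(pair) < 4:
                rows.append({"cell_type": cell_type, "effect": np.nan, "p": 1.0})
                continue
            rho, p = stats.spearmanr(pair["s"], pair["v"])
            rows.append({"cell_type": cell_type, "effect": float(rho), "p": float(p)})
    else:
        raise ValueError("mode must be 'group_wilcoxon' or 'severity_spearman'")
    df = pd.DataFrame(rows).set_index("cell_type")
    if add_fdr:
        from .association import bh_fdr

        df["q"] = bh_fdr(df["p"].to_numpy())
    return df
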