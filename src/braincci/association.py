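"""Association statistics: per-MGP and per-gene tests, FDR, enrichment.

Every marker-gene pair (or gene) is scored for association with the
case/control label or with a continuous severity score:

* ``t_test`` — Welch two-sample t per row (pooled-variance optional);
* ``linear_model`` — per-row least squares on a group indicator plus
  covariates, with optional empirical-Bayes moderation of the residual
  variances (moderated t in the limma style);
* severity — per-row Spearman correlation, average ranks on ties,
  t-approximation p for n >= 10 and an exact permutation p below that.

Multiple testing is controlled with Benjamini-Hochberg step-up q-values,
and marker-set enrichment among DE genes uses the hypergeometric upper tail.
"""

from __future__ import annotations

import itertools
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .data_io import ExpressionMatrix, MarkerSetCollection, SampleMetadata, logger
from .mgp import MGPMatrix

# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------


def bh_fdr(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    q(i) = min over j >= i of p(j) * m / j on the sorted p-values, clipped
    at 1; order of the input is preserved.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if np.isnan(p).any():
        raise ValueError("NaN p-value passed to bh_fdr")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# row-wise two-group tests
# ---------------------------------------------------------------------------


def _welch_rows(case: np.ndarray, ctrl: np.ndarray, equal_var: bool = False
                ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized two-sample t over rows; returns (t, p) with sign = case - control."""
    n1, n2 = case.shape[1], ctrl.shape[1]
    m1, m2 = case.mean(axis=1), ctrl.mean(axis=1)
    v1 = case.var(axis=1, ddof=1)
    v2 = ctrl.var(axis=1, ddof=1)
    diff = m1 - m2
    if equal_var:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se2 = sp2 * (1 / n1 + 1 / n2)
        df = np.full_like(se2, n1 + n2 - 2)
    else:
        a, b = v1 / n1, v2 / n2
        se2 = a + b
        with np.errstate(divide="ignore", invalid="ignore"):
            df = se2**2 / (a**2 / (n1 - 1) + b**2 / (n2 - 1))
    zero = se2 == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-variance rows in two-group test",
                      stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
        p = 2.0 * stats.t.sf(np.abs(t), df)
    # degenerate rows: constant within both groups
    t = np.where(zero & (diff == 0), 0.0, t)
    p = np.where(zero, np.where(diff == 0, 1.0, 0.0), p)
    return t, p


def _design_matrix(meta: SampleMetadata, sample_ids: Sequence[str],
                   covariates: Sequence[str] | None) -> tuple[np.ndarray, list[str], int]:
    """Intercept + group indicator (case=1) + one-hot covariates.

    Returns (X, kept_sample_ids, group_column_index).  Samples with missing
    covariate values are dropped listwise with a warning.
    """
    tab = meta.table.loc[list(sample_ids)]
    cols: dict[str, pd.Series] = {}
    grp = tab["group"].map({"control": 0.0, "case": 1.0})
    cols["group"] = grp
    if covariates:
        cov = meta.covariate_frame(covariates).loc[list(sample_ids)]
        for name in covariates:
            col = cov[name]
            if pd.api.types.is_numeric_dtype(col):
                cols[name] = col.astype(float)
            else:
                dummies = pd.get_dummies(col.astype("category"), prefix=name,
                                         drop_first=True, dtype=float)
                for dcol in dummies.columns:
                    cols[dcol] = dummies[dcol]
    design = pd.DataFrame(cols, index=tab.index)
    keep = design.notna().all(axis=1)
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} samples with missing covariates",
                      stacklevel=2)
        design = design.loc[keep]
    design.insert(0, "intercept", 1.0)
    X = design.to_numpy(dtype=float)
    return X, list(design.index), list(design.columns).index("group")


def _trigamma_inverse(y: np.ndarray | float) -> np.ndarray:
    """Solve trigamma(x) = y by Newton iteration (limma-style)."""
    y = np.atleast_1d(np.asarray(y, dtype=float))
    x = np.where(y > 1e7, 1.0 / np.sqrt(y), 0.5 + 1.0 / y)
    x = np.where(y < 1e-6, 1.0 / y, x)
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if np.all(np.abs(dif) < 1e-10 * x):
            break
    return x


def _fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment estimate of the scaled-F prior (d0, s0^2) for residual variances."""
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(np.mean(s2[ok])) if ok.any() else 0.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if e_var <= 0:
        # no excess spread over the chi-square expectation: fully pooled variance
        return np.inf, float(np.mean(s2[ok]))
    d0 = 2.0 * float(_trigamma_inverse(e_var)[0])
    s0sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0sq


def _ols_rows(Y: np.ndarray, X: np.ndarray, coef_idx: int, moderated: bool
              ) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise OLS t-statistics for one coefficient, optionally EB-moderated."""
    n, k = X.shape
    df = n - k
    if df < 1:
        raise ValueError(f"linear model has no residual degrees of freedom (n={n}, k={k})")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = Y @ (xtx_inv @ X.T).T  # (rows, k)
    resid = Y - beta @ X.T
    s2 = (resid**2).sum(axis=1) / df
    c = xtx_inv[coef_idx, coef_idx]
    b = beta[:, coef_idx]
    if moderated:
        d0, s0sq = _fit_f_dist(s2, df)
        df_pooled = float(s2.size * df)  # cap: no more information than all rows pooled
        if np.isinf(d0):
            s2_post = np.full_like(s2, s0sq)
            df_total = df_pooled
        else:
            s2_post = (d0 * s0sq + df * s2) / (d0 + df)
            df_total = min(df + d0, df_pooled)
    else:
        s2_post, df_total = s2, df
    zero = s2_post == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-variance rows in linear model",
                      stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = b / np.sqrt(s2_post * c)
    t = np.where(zero & (b == 0), 0.0, t)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where(zero, np.where(b == 0, 1.0, 0.0), p)
    return t, p


# ---------------------------------------------------------------------------
# row-wise Spearman
# ---------------------------------------------------------------------------


def _spearman_rows(values: np.ndarray, severity: np.ndarray,
                   exact_below: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Spearman rho and two-sided p against one severity vector."""
    n = severity.size
    if np.unique(severity).size < 2:
        raise ValueError("severity vector is constant")
    r_sev = stats.rankdata(severity)
    rc = r_sev - r_sev.mean()
    rc_norm = np.sqrt((rc**2).sum())
    R = stats.rankdata(values, axis=1)
    Rc = R - R.mean(axis=1, keepdims=True)
    row_norm = np.sqrt((Rc**2).sum(axis=1))
    const = row_norm == 0
    if const.any():
        warnings.warn(f"{int(const.sum())} constant rows in Spearman test",
                      stacklevel=2)
    safe_norm = np.where(const, 1.0, row_norm)
    rho = (Rc @ rc) / (safe_norm * rc_norm)
    rho = np.clip(np.where(const, 0.0, rho), -1.0, 1.0)
    if n >= exact_below:
        with np.errstate(divide="ignore", invalid="ignore"):
            t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
        p = 2.0 * stats.t.sf(np.abs(t), n - 2)
        p = np.where(np.abs(rho) >= 1.0, 0.0, p)
    else:
        # exact permutation null: all n! orderings of the severity ranks
        perms = np.array(list(itertools.permutations(rc)))  # (n!, n)
        p = np.empty(values.shape[0])
        block = max(1, 5_000_000 // perms.shape[0])
        for start in range(0, values.shape[0], block):
            sl = slice(start, min(start + block, values.shape[0]))
            null = (Rc[sl] @ perms.T) / (safe_norm[sl, None] * rc_norm)
            obs = np.abs(rho[sl])[:, None]
            p[sl] = (np.abs(null) >= obs - 1e-12).mean(axis=1)
    p = np.where(const, 1.0, np.clip(p, 0.0, 1.0))
    return rho, p


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def _stats_frame(pairs, gene_to_type, stat, p, kind: str) -> pd.DataFrame:
    if kind == "group":
        direction = np.where(stat > 0, "case_higher",
                             np.where(stat < 0, "control_higher", "none"))
    else:
        direction = np.where(stat > 0, "positive",
                             np.where(stat < 0, "negative", "none"))
    idx = pd.MultiIndex.from_tuples(pairs, names=["gene_i", "gene_j"])
    df = pd.DataFrame({
        "type_i": [gene_to_type[a] for a, _ in pairs],
        "type_j": [gene_to_type[b] for _, b in pairs],
        "statistic": stat,
        "effect_direction": direction,
        "p": p,
        "q": bh_fdr(p),
    }, index=idx)
    return df


def mgp_group_test(
    mgp: MGPMatrix,
    meta: SampleMetadata,
    method: str = "t_test",
    covariates: Sequence[str] | None = None,
    equal_var: bool = False,
    moderated: bool | None = None,
) -> pd.DataFrame:
    """Test every MGP log-ratio row for a case vs control difference.

    Returns a table indexed by (gene_i, gene_j) with the signed statistic
    (positive = higher in cases), two-sided p and BH q over all rows.
    """
    if meta.group is None:
        raise ValueError("metadata has no group column")
    grp = meta.group.loc[mgp.sample_ids]
    case_ids = [s for s in mgp.sample_ids if grp[s] == "case"]
    ctrl_ids = [s for s in mgp.sample_ids if grp[s] == "control"]
    if len(case_ids) < 2 or len(ctrl_ids) < 2:
        raise ValueError(f"need >=2 samples per group, have {len(case_ids)} case / "
                         f"{len(ctrl_ids)} control")
    col = {s: k for k, s in enumerate(mgp.sample_ids)}
    if method == "t_test":
        if covariates:
            raise ValueError("covariates require method='linear_model'")
        case = mgp.values[:, [col[s] for s in case_ids]]
        ctrl = mgp.values[:, [col[s] for s in ctrl_ids]]
        stat, p = _welch_rows(case, ctrl, equal_var=equal_var)
    elif method == "linear_model":
        if moderated is None:
            moderated = True
        X, kept, gidx = _design_matrix(meta, mgp.sample_ids, covariates)
        Y = mgp.values[:, [col[s] for s in kept]]
        stat, p = _ols_rows(Y, X, gidx, moderated)
    else:
        raise ValueError(f"unknown method {method!r}")
    logger.info("mgp_group_test(%s): %d pairs, %d case vs %d control",
                method, mgp.n_pairs, len(case_ids), len(ctrl_ids))
    return _stats_frame(mgp.pairs, mgp.gene_to_type, stat, p, "group")


def mgp_severity_test(mgp: MGPMatrix, meta: SampleMetadata) -> pd.DataFrame:
    """Spearman correlation of every MGP row with a continuous severity score."""
    if meta.severity is None:
        raise ValueError("metadata has no severity column")
    sev = meta.severity.loc[mgp.sample_ids].astype(float)
    keep = sev.notna()
    if int(keep.sum()) < 4:
        raise ValueError("need >=4 samples with non-missing severity")
    col = {s: k for k, s in enumerate(mgp.sample_ids)}
    vals = mgp.values[:, [col[s] for s in sev.index[keep]]]
    rho, p = _spearman_rows(vals, sev[keep].to_numpy())
    logger.info("mgp_severity_test: %d pairs, %d samples", mgp.n_pairs, int(keep.sum()))
    return _stats_frame(mgp.pairs, mgp.gene_to_type, rho, p, "severity")


def gene_de_test(
    expr: ExpressionMatrix,
    meta: SampleMetadata,
    method: str = "t_test",
    fc_min: float = 1.5,
    q_max: float = 0.05,
    covariates: Sequence[str] | None = None,
    pseudocount: float = 1.0,
    equal_var: bool = False,
    moderated: bool | None = None,
) -> pd.DataFrame:
    """Per-gene differential expression between cases and controls.

    log2 fold changes are case-minus-control means on the log2 scale;
    ``status`` is ``up``/``down`` when |FC| > fc_min and q < q_max, else
    ``ns``.
    """
    if meta.group is None:
        raise ValueError("metadata has no group column")
    log_e = expr.log2_values(pseudocount)
    grp = meta.group.loc[expr.sample_ids]
    case_ids = [s for s in expr.sample_ids if grp[s] == "case"]
    ctrl_ids = [s for s in expr.sample_ids if grp[s] == "control"]
    if len(case_ids) < 2 or len(ctrl_ids) < 2:
        raise ValueError("need >=2 samples per group")
    case = log_e[case_ids].to_numpy()
    ctrl = log_e[ctrl_ids].to_numpy()
    lfc = case.mean(axis=1) - ctrl.mean(axis=1)
    if method == "t_test":
        stat, p = _welch_rows(case, ctrl, equal_var=equal_var)
    elif method == "linear_model":
        if moderated is None:
            moderated = True
        X, kept, gidx = _design_matrix(meta, expr.sample_ids, covariates)
        stat, p = _ols_rows(log_e[kept].to_numpy(), X, gidx, moderated)
    else:
        raise ValueError(f"unknown method {method!r}")
    q = bh_fdr(p)
    lfc_min = np.log2(fc_min) if np.isfinite(fc_min) else np.inf
    status = np.where((q < q_max) & (lfc > lfc_min), "up",
                      np.where((q < q_max) & (lfc < -lfc_min), "down", "ns"))
    out = pd.DataFrame({
        "gene": expr.gene_ids, "log2_fc": lfc, "statistic": stat,
        "p": p, "q": q, "status": status,
    }).set_index("gene")
    logger.info("gene_de_test(%s): %d genes, %d up / %d down at |FC|>%g, q<%g",
                method, len(out), int((status == "up").sum()),
                int((status == "down").sum()), fc_min, q_max)
    return out


def marker_enrichment(
    de: pd.DataFrame,
    markers: MarkerSetCollection,
    direction: str = "up",
) -> pd.DataFrame:
    """Hypergeometric enrichment of each marker set among DE genes.

    Background = all tested genes; per set, fold = (hits/|DE|)/(set/background)
    and p = P(X >= hits) upper tail; score = -log10(p).
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    background = list(de.index)
    bg = set(background)
    n_bg = len(bg)
    de_genes = set(de.index[de["status"] == direction])
    n_de = len(de_genes)
    rows = []
    for cell_type, genes in markers.sets.items():
        in_bg = [g for g in genes if g in bg]
        k_set = len(in_bg)
        hits = sum(1 for g in in_bg if g in de_genes)
        if n_de == 0 or k_set == 0:
            fold, p = np.nan, 1.0
        else:
            fold = (hits / n_de) / (k_set / n_bg)
            p = float(stats.hypergeom.sf(hits - 1, n_bg, k_set, n_de))
        rows.append({"cell_type": cell_type, "set_size": k_set, "de_size": n_de,
                     "hits": hits, "fold": fold, "p": p,
                     "score": -np.log10(max(p, np.finfo(float).tiny))})
    return pd.DataFrame(rows).set_index("cell_type")
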