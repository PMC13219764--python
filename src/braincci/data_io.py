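"""Input/output and the core tabular data model.

Expression matrices are held as pandas DataFrames (genes x samples) with a
declared scale (``linear`` or ``log2``); microarray probeset matrices are
collapsed to gene level with platform-appropriate rules (per-gene mean for
two-channel arrays, max-mean probeset for one-channel arrays).  Marker gene
sets are read from standard GMT files into a :class:`MarkerSetCollection`,
which enforces the unambiguous gene-to-cell-type assignment the downstream
cross-type pair counting requires.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("braincci")

LINEAR = "linear"
LOG2 = "log2"

#: accepted spellings for the two phenotype groups in metadata files
_GROUP_ALIASES = {
    "ad": "case",
    "case": "case",
    "patient": "case",
    "disease": "case",
    "control": "control",
    "ctrl": "control",
    "ctl": "control",
    "healthy": "control",
    "normal": "control",
}


def _sep_for(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Gene-level expression matrix (genes x samples) with a declared scale.

    The scale declaration drives the log-ratio contract downstream: on
    ``linear`` data log2 ratios use ``log2(x + pseudocount)``, on ``log2``
    data the ratio is a plain difference.
    """

    data: pd.DataFrame
    scale: str = LINEAR

    def __post_init__(self) -> None:
        if self.scale not in (LINEAR, LOG2):
            raise ValueError(f"scale must be 'linear' or 'log2', got {self.scale!r}")
        idx = self.data.index
        if idx.duplicated().any():
            dups = idx[idx.duplicated()].unique().tolist()[:5]
            raise ValueError(f"duplicate gene ids: {dups}")
        if self.data.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        vals = self.data.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise ValueError("expression values must be finite (no NaN/inf)")
        if self.scale == LINEAR and (vals < 0).any():
            raise ValueError("linear-scale expression must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def log2_values(self, pseudocount: float = 1.0) -> pd.DataFrame:
        """Expression on log2 scale under the declared-scale contract."""
        if self.scale == LOG2:
            return self.data.astype(float)
        if pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        if pseudocount == 0 and (self.data.to_numpy() == 0).any():
            raise ValueError("pseudocount 0 with zero expression values would give -inf")
        return np.log2(self.data.astype(float) + pseudocount)

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)], self.scale)


@dataclass
class ProbesetMatrix:
    """Probeset-level matrix plus a (possibly many-to-one) probeset->gene map."""

    data: pd.DataFrame  # probesets x samples
    probeset_to_gene: Mapping[str, str]
    channel_mode: str = "one_channel"  # or "two_channel"

    def __post_init__(self) -> None:
        if self.channel_mode not in ("one_channel", "two_channel"):
            raise ValueError("channel_mode must be 'one_channel' or 'two_channel'")
        if not np.isfinite(self.data.to_numpy(dtype=float)).all():
            raise ValueError("probeset values must be finite (no NaN/inf)")
        unknown = set(self.probeset_to_gene) - set(self.data.index)
        if unknown:
            raise ValueError(f"mapped probesets absent from matrix: {sorted(unknown)[:5]}")


def collapse_probesets(pm: ProbesetMatrix, scale: str = LINEAR) -> ExpressionMatrix:
    """Collapse a probeset matrix to gene level.

    Two-channel arrays: per-gene mean across its probesets.  One-channel
    arrays: the single probeset with the highest mean intensity across
    samples represents the gene.  Unmapped probesets are dropped.
    """
    mapping = {p: g for p, g in pm.probeset_to_gene.items() if g}
    if not mapping:
        raise ValueError("no gene-level rows: every probeset is unmapped")
    sub = pm.data.loc[list(mapping)]
    genes = pd.Series({p: mapping[p] for p in sub.index}, name="gene")
    if pm.channel_mode == "two_channel":
        collapsed = sub.groupby(genes).mean()
    else:
        # max-mean probeset: pick one input row verbatim per gene
        means = sub.mean(axis=1)
        best = (
            pd.DataFrame({"gene": genes, "mean": means})
            .sort_values(["gene", "mean"], kind="stable")
            .groupby("gene")
            .tail(1)
        )
        collapsed = sub.loc[best.index]
        collapsed.index = best["gene"].values
        collapsed = collapsed.sort_index()
    collapsed.index.name = pm.data.index.name or "gene"
    n_dropped = pm.data.shape[0] - sub.shape[0]
    logger.info(
        "collapse_probesets: %d probesets -> %d genes (%s, %d unmapped dropped)",
        pm.data.shape[0], collapsed.shape[0], pm.channel_mode, n_dropped,
    )
    return ExpressionMatrix(collapsed, scale)


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------


@dataclass
class SampleMetadata:
    """Per-sample phenotype table indexed by sample id.

    ``group`` holds ``case``/``control`` labels, ``severity`` a numeric
    ordinal outcome (e.g. Braak stage or CDR); any additional columns are
    treated as covariates, except the optional ``region`` column used for
    stratified analyses.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            raise ValueError("duplicate sample ids in metadata")
        if "group" in self.table:
            bad = set(self.table["group"].dropna().unique()) - {"case", "control"}
            if bad:
                raise ValueError(f"group labels must be case/control, got {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def group(self) -> pd.Series | None:
        return self.table["group"] if "group" in self.table else None

    @property
    def severity(self) -> pd.Series | None:
        return self.table["severity"] if "severity" in self.table else None

    @property
    def region(self) -> pd.Series | None:
        return self.table["region"] if "region" in self.table else None

    def covariate_frame(self, names: Sequence[str]) -> pd.DataFrame:
        missing = [c for c in names if c not in self.table]
        if missing:
            raise KeyError(f"covariates absent from metadata: {missing}")
        return self.table[list(names)]

    def check_matches(self, expr: ExpressionMatrix) -> None:
        if set(self.sample_ids) != set(expr.sample_ids):
            raise ValueError("metadata sample ids do not match expression matrix")

    def subset(self, sample_ids: Sequence[str]) -> "SampleMetadata":
        return SampleMetadata(self.table.loc[list(sample_ids)])


# ---------------------------------------------------------------------------
# marker gene sets
# ---------------------------------------------------------------------------


@dataclass
class MarkerSetCollection:
    """Mapping cell type -> marker gene list (order-preserving).

    ``L`` exposes per-type retained marker counts.  ``dedup`` enforces the
    unambiguous gene->type assignment that cross-type pair counting needs;
    ``restrict_to`` drops markers absent from an expression matrix and
    excludes types that fall below ``min_markers``.
    """

    sets: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(genes) != len(set(genes)):
                seen: set[str] = set()
                deduped = [g for g in genes if not (g in seen or seen.add(g))]
                self.sets[name] = deduped

    @property
    def cell_types(self) -> list[str]:
        return list(self.sets)

    @property
    def L(self) -> dict[str, int]:
        return {t: len(g) for t, g in self.sets.items()}

    @property
    def all_genes(self) -> list[str]:
        out: list[str] = []
        for genes in self.sets.values():
            out.extend(genes)
        return out

    def gene_to_type(self) -> dict[str, str]:
        mapping: dict[str, str] = {}
        for t, genes in self.sets.items():
            for g in genes:
                if g in mapping:
                    raise ValueError(
                        f"gene {g!r} assigned to both {mapping[g]!r} and {t!r}; "
                        "run dedup() first"
                    )
                mapping[g] = t
        return mapping

    def dedup(self, keep: str = "drop") -> "MarkerSetCollection":
        """Resolve genes shared between sets.

        ``drop`` removes a shared gene from every set (default); ``first``
        keeps it in the first set that lists it.
        """
        if keep not in ("drop", "first"):
            raise ValueError("keep must be 'drop' or 'first'")
        counts: dict[str, int] = {}
        for genes in self.sets.values():
            for g in genes:
                counts[g] = counts.get(g, 0) + 1
        shared = {g for g, c in counts.items() if c > 1}
        if shared:
            logger.warning("dedup: %d marker genes shared between sets (%s)",
                           len(shared), keep)
        new: dict[str, list[str]] = {}
        claimed: set[str] = set()
        for t, genes in self.sets.items():
            kept = []
            for g in genes:
                if g not in shared:
                    kept.append(g)
                elif keep == "first" and g not in claimed:
                    kept.append(g)
                    claimed.add(g)
            new[t] = kept
        return MarkerSetCollection(new)

    def restrict_to(self, genes: Sequence[str], min_markers: int = 3) -> "MarkerSetCollection":
        present = set(genes)
        new: dict[str, list[str]] = {}
        for t, gs in self.sets.items():
            kept = [g for g in gs if g in present]
            lost = len(gs) - len(kept)
            if lost:
                logger.warning("markers: %d/%d %s markers absent from expression, dropped",
                               lost, len(gs), t)
            if len(kept) >= min_markers:
                new[t] = kept
            else:
                logger.warning("markers: cell type %s has %d (<%d) markers, excluded",
                               t, len(kept), min_markers)
        return MarkerSetCollection(new)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_expression(path: str | Path, scale: str = LINEAR) -> ExpressionMatrix:
    """Read a TSV/CSV expression table: first column gene id, header = samples."""
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    if df.isna().any().any():
        raise ValueError(f"{path}: missing values in expression table")
    return ExpressionMatrix(df.astype(float), scale)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.data.rename_axis("gene").to_csv(path, sep=_sep_for(path))


def read_metadata(path: str | Path) -> SampleMetadata:
    """Read a metadata TSV with a ``sample_id`` column; AD/Control-style group
    labels are normalized to ``case``/``control``."""
    df = pd.read_csv(path, sep=_sep_for(path))
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: metadata needs a 'sample_id' column")
    df["sample_id"] = df["sample_id"].astype(str).str.strip()
    df = df.set_index("sample_id")
    if "group" in df.columns:
        raw = df["group"].astype(str).str.strip().str.lower()
        unknown = set(raw.dropna().unique()) - set(_GROUP_ALIASES)
        if unknown:
            raise ValueError(f"{path}: unrecognized group labels {sorted(unknown)}")
        df["group"] = raw.map(_GROUP_ALIASES)
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    meta.table.rename_axis("sample_id").to_csv(path, sep=_sep_for(path))


def read_markers_gmt(path: str | Path) -> MarkerSetCollection:
    """Read marker sets from GMT: set name, description, then gene symbols."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT set with no genes")
            name = fields[0].strip()
            genes = [g.strip() for g in fields[2:] if g.strip()]
            if not genes:
                raise ValueError(f"{path}:{lineno}: GMT set {name!r} is empty")
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = genes
    if not sets:
        raise ValueError(f"{path}: no marker sets found")
    return MarkerSetCollection(sets)


def write_markers_gmt(markers: MarkerSetCollection, path: str | Path,
                      description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in markers.sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write any result table as TSV/CSV with a header row."""
    df.to_csv(path, sep=_sep_for(path), index=index)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=_sep_for(path))
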