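"""End-to-end orchestration: expression + metadata + markers -> CCI report.

Runs data ingestion, MGP construction, association testing, directed
network construction, cell-pair enrichment, hierarchy layering and
(optionally) signature scoring; with a region column the whole analysis
repeats independently per region with per-region FDR.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import pandas as pd

from .association import mgp_group_test, mgp_severity_test
from .data_io import (
    ExpressionMatrix,
    MarkerSetCollection,
    SampleMetadata,
    logger,
    read_expression,
    read_markers_gmt,
    read_metadata,
    write_table,
)
from .mgp import build_mgp_matrix
from .network import (
    GenePairNetwork,
    build_directed_network,
    cci_enrichment,
    er_concordance,
    hierarchy_layers,
    write_edge_list,
)
from .signature import base_scores, compare_scores


@dataclass
class RunConfig:
    """One analysis run: outcome, method and thresholds."""

    outcome: str = "group"              # "group" | "severity"
    method: str = "t_test"              # "t_test" | "linear_model"
    covariates: list[str] = field(default_factory=list)
    pseudocount: float = 1.0
    min_markers: int = 3
    mgp_sig_metric: str = "q"           # gate for network construction
    mgp_sig_threshold: float = 0.05
    cci_q: float = 0.05
    cross_only_background: bool = False
    region_column: str | None = None
    compute_scores: bool = False
    n_perm: int = 200                   # signature permutations
    seed: int = 0

    def validate(self) -> None:
        if self.outcome not in ("group", "severity"):
            raise ValueError("outcome must be 'group' or 'severity'")
        if not 0 < self.mgp_sig_threshold <= 1 or not 0 < self.cci_q <= 1:
            raise ValueError("thresholds must lie in (0, 1]")


@dataclass
class RunResult:
    """Tables produced by one (sub)run."""

    mgp_stats: pd.DataFrame
    network: GenePairNetwork
    cci: pd.DataFrame
    hierarchy: pd.DataFrame
    scores: pd.DataFrame | None
    score_tests: pd.DataFrame | None
    summary: dict
    regions: dict[str, "RunResult"] = field(default_factory=dict)


def _run_single(expr: ExpressionMatrix, meta: SampleMetadata,
                markers: MarkerSetCollection, cfg: RunConfig) -> RunResult:
    mgp = build_mgp_matrix(expr, markers.dedup("drop")
                           .restrict_to(expr.gene_ids, cfg.min_markers),
                           pseudocount=cfg.pseudocount)
    if cfg.outcome == "group":
        stats = mgp_group_test(mgp, meta, method=cfg.method,
                               covariates=cfg.covariates or None)
    else:
        stats = mgp_severity_test(mgp, meta)
    net = build_directed_network(stats, cfg.mgp_sig_threshold, cfg.mgp_sig_metric)
    cci = cci_enrichment(net, cross_only_background=cfg.cross_only_background)
    hierarchy = hierarchy_layers(cci, cfg.cci_q)
    scores = score_tests = None
    if cfg.compute_scores:
        scores = base_scores(expr, markers.dedup("drop"), n_perm=cfg.n_perm,
                             seed=cfg.seed)
        mode = "group_wilcoxon" if cfg.outcome == "group" else "severity_spearman"
        score_tests = compare_scores(scores, meta, mode=mode)
    sig_cci = cci[cci["q"] <= cfg.cci_q]
    summary = {
        "n_samples": expr.shape[1],
        "n_genes": expr.shape[0],
        "n_markers": len(mgp.gene_to_type),
        "n_mgp_rows": mgp.n_pairs,
        "n_sig_mgps": int((stats[cfg.mgp_sig_metric] <= cfg.mgp_sig_threshold).sum()),
        "n_edges": net.n_sig,
        "n_cell_pairs": len(cci),
        "n_sig_ccis": len(sig_cci),
        "sig_ccis": [f"{x}->{y}" for x, y in sig_cci.index],
        "top_hierarchy": hierarchy.index[:3].tolist(),
    }
    return RunResult(mgp_stats=stats, network=net, cci=cci, hierarchy=hierarchy,
                     scores=scores, score_tests=score_tests, summary=summary)


def run_pipeline(
    expr: ExpressionMatrix | str | Path,
    meta: SampleMetadata | str | Path,
    markers: MarkerSetCollection | str | Path,
    cfg: RunConfig | None = None,
    scale: str = "linear",
    outdir: str | Path | None = None,
) -> RunResult:
    """Execute the full pipeline; inputs may be in-memory objects or paths.

    With ``cfg.region_column`` set, the analysis repeats independently per
    region (per-region FDR); the top-level tables then come from the pooled
    data and ``result.regions`` holds the per-region results.
    """
    cfg = cfg or RunConfig()
    cfg.validate()
    if not isinstance(expr, ExpressionMatrix):
        expr = read_expression(expr, scale)
    if not isinstance(meta, SampleMetadata):
        meta = read_metadata(meta)
    if not isinstance(markers, MarkerSetCollection):
        markers = read_markers_gmt(markers)
    meta.check_matches(expr)
    meta = meta.subset(expr.sample_ids)

    try:
        result = _run_single(expr, meta, markers, cfg)
    except Exception as err:  # annotate with stage context
        raise RuntimeError(f"pipeline failed on pooled data: {err}") from err

    if cfg.region_column:
        regions = meta.table[cfg.region_column]
        for region in sorted(regions.dropna().unique()):
            ids = [s for s in expr.sample_ids if regions[s] == region]
            logger.info("region %s: %d samples", region, len(ids))
            try:
                result.regions[str(region)] = _run_single(
                    expr.subset_samples(ids), meta.subset(ids), markers, cfg)
            except Exception as err:
                raise RuntimeError(f"pipeline failed in region {region!r}: {err}"
                                   ) from err
        result.summary["regions"] = {
            r: res.summary for r, res in result.regions.items()
        }

    if outdir is not None:
        _write_outputs(result, cfg, Path(outdir))
    return result


def _write_outputs(result: RunResult, cfg: RunConfig, outdir: Path,
                   prefix: str = "") -> None:
    tables = outdir / "tables"
    networks = outdir / "networks"
    for d in (tables, networks, outdir / "logs"):
        d.mkdir(parents=True, exist_ok=True)
    write_table(result.mgp_stats.reset_index(), tables / f"{prefix}mgp_stats.tsv")
    write_table(result.cci.reset_index(), tables / f"{prefix}cci.tsv")
    write_table(result.hierarchy.reset_index(), tables / f"{prefix}hierarchy.tsv")
    if result.scores is not None:
        write_table(result.scores.rename_axis("sample_id").reset_index(),
                    tables / f"{prefix}signature_scores.tsv")
    if result.score_tests is not None:
        write_table(result.score_tests.reset_index(),
                    tables / f"{prefix}signature_tests.tsv")
    write_edge_list(result.network, networks / f"{prefix}gene_network.tsv")
    for region, res in result.regions.items():
        _write_outputs(res, cfg, outdir, prefix=f"{region}_")
    if not prefix:
        payload = {"config": asdict(cfg), "summary": result.summary}
        (outdir / "summary.json").write_text(json.dumps(payload, indent=2,
                                                        sort_keys=True) + "\n")


def cross_dataset_report(run_a: RunResult, run_b: RunResult,
                         q_threshold: float = 0.05) -> dict:
    """Concordance of two runs: ER Spearman correlation + significant-CCI overlap."""
    shared = run_a.cci.index.intersection(run_b.cci.index)
    if len(shared) == 0:
        raise ValueError("runs share no cell-type pairs")
    rho, p = er_concordance(run_a.cci, run_b.cci)
    sig_a = {f"{x}->{y}" for x, y in run_a.cci[run_a.cci["q"] <= q_threshold].index}
    sig_b = {f"{x}->{y}" for x, y in run_b.cci[run_b.cci["q"] <= q_threshold].index}
    inter = sig_a & sig_b
    return {
        "er_scc": rho,
        "er_scc_p": p,
        "n_shared_pairs": int(len(shared)),
        "n_sig_a": len(sig_a),
        "n_sig_b": len(sig_b),
        "n_sig_overlap": len(inter),
        "sig_overlap": sorted(inter),
    }


def configure_logging(level: int = logging.INFO,
                      logfile: str | Path | None = None) -> None:
    """Attach a simple handler to the package logger (CLI convenience)."""
    logger.setLevel(level)
    handler: logging.Handler
    handler = logging.FileHandler(logfile) if logfile else logging.StreamHandler()
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
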