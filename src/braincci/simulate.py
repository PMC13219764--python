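"""Synthetic bulk cohorts with known cell-type composition.

A bulk profile is modelled as a fraction-weighted mixture of cell-type
signature profiles: each type's markers are expressed at ``marker_fold``
in their own type and 1 elsewhere, background genes at 1 everywhere.
Per-sample mixing fractions are drawn from a Dirichlet around a baseline
composition; case samples (or increasing severity) tilt the baseline by a
per-type multiplicative effect, emulating e.g. neuron loss with glial gain.
Multiplicative log-normal noise is applied gene-wise on the log2 scale.

Because the mixture, effects and noise are fully specified, every
downstream stage can be tested against the planted truth without any
external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import (
    ExpressionMatrix,
    MarkerSetCollection,
    SampleMetadata,
    write_expression,
    write_markers_gmt,
    write_metadata,
    write_table,
)

#: cortex-like composition for the six major brain cell types
DEFAULT_TYPES = ("neu", "ast", "oli", "mic", "opc", "end")
DEFAULT_FRACTIONS = (0.40, 0.20, 0.20, 0.10, 0.05, 0.05)


@dataclass
class SimulationConfig:
    """Study-condition parameters of the synthetic cohort generator.

    ``effect_map`` multiplies a type's baseline fraction in cases (group
    mode) or is the fraction multiplier reached at severity 1 (severity
    mode, linear in the severity score); fractions are renormalized to sum
    to 1.  ``noise_sd`` is the sd of additive Gaussian noise on the log2
    scale, ``dirichlet_concentration`` controls sample-level fraction
    jitter (larger = tighter around the baseline).
    """

    n_cell_types: int = 6
    markers_per_type: int = 10
    n_background_genes: int = 500
    n_case: int = 50
    n_control: int = 50
    baseline_fractions: tuple[float, ...] | None = None
    effect_map: dict[str, float] = field(default_factory=dict)
    severity_mode: bool = False
    marker_fold: float = 8.0
    noise_sd: float = 0.4
    dirichlet_concentration: float = 50.0
    seed: int = 0

    def cell_type_names(self) -> list[str]:
        if self.n_cell_types == len(DEFAULT_TYPES):
            return list(DEFAULT_TYPES)
        return [f"ct{i + 1:02d}" for i in range(self.n_cell_types)]

    def baseline(self) -> np.ndarray:
        if self.baseline_fractions is not None:
            b = np.asarray(self.baseline_fractions, dtype=float)
        elif self.n_cell_types == len(DEFAULT_FRACTIONS):
            b = np.asarray(DEFAULT_FRACTIONS)
        else:
            b = np.full(self.n_cell_types, 1.0 / self.n_cell_types)
        if b.size != self.n_cell_types:
            raise ValueError("baseline_fractions length != n_cell_types")
        if abs(b.sum() - 1.0) > 1e-9:
            raise ValueError("baseline fractions must sum to 1")
        if (b <= 0).any():
            raise ValueError("baseline fractions must be positive")
        return b

    def effects(self) -> np.ndarray:
        names = self.cell_type_names()
        unknown = set(self.effect_map) - set(names)
        if unknown:
            raise ValueError(f"effect_map for unknown cell types: {sorted(unknown)}")
        e = np.array([self.effect_map.get(t, 1.0) for t in names], dtype=float)
        if (e <= 0).any():
            raise ValueError("effects must be positive (fractions cannot reach <= 0)")
        return e

    def validate(self) -> None:
        for name in ("n_cell_types", "markers_per_type", "n_background_genes",
                     "n_case", "n_control"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_cell_types < 2:
            raise ValueError("need at least 2 cell types")
        if self.marker_fold <= 1:
            raise ValueError("marker_fold must exceed 1")
        if self.noise_sd < 0 or self.dirichlet_concentration <= 0:
            raise ValueError("noise_sd must be >= 0 and concentration > 0")
        self.baseline()
        self.effects()


@dataclass
class SyntheticCohort:
    """A simulated bulk cohort plus its planted ground truth."""

    expr: ExpressionMatrix
    meta: SampleMetadata
    markers: MarkerSetCollection
    truth: pd.DataFrame  # per-sample true fractions (samples x cell types)
    effect_map: dict[str, float]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_expression(self.expr, outdir / "expression.tsv")
        write_metadata(self.meta, outdir / "metadata.tsv")
        write_markers_gmt(self.markers, outdir / "markers.gmt")
        write_table(self.truth.rename_axis("sample_id").reset_index(),
                    outdir / "truth_fractions.tsv")


def simulate_cohort(cfg: SimulationConfig) -> SyntheticCohort:
    """Draw one cohort under the configured study conditions.

    Same config (including seed) gives byte-identical output.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    types = cfg.cell_type_names()
    base = cfg.baseline()
    eff = cfg.effects()
    t = cfg.n_cell_types

    marker_names = [f"{ct}M{k + 1:02d}" for ct in types
                    for k in range(cfg.markers_per_type)]
    bg_names = [f"BG{k + 1:04d}" for k in range(cfg.n_background_genes)]
    genes = marker_names + bg_names
    n_genes = len(genes)

    # signature profiles: markers at marker_fold in their own type, else 1
    profiles = np.ones((n_genes, t))
    for ti in range(t):
        rows = slice(ti * cfg.markers_per_type, (ti + 1) * cfg.markers_per_type)
        profiles[rows, ti] = cfg.marker_fold

    n = cfg.n_case + cfg.n_control
    sample_ids = [f"S{k + 1:04d}" for k in range(n)]
    meta_cols: dict[str, object] = {}
    if cfg.severity_mode:
        severity = rng.uniform(0.0, 1.0, n)
        tilt = base[None, :] * (1.0 + (eff - 1.0)[None, :] * severity[:, None])
        meta_cols["severity"] = severity
    else:
        group = np.array(["control"] * cfg.n_control + ["case"] * cfg.n_case)
        tilt = np.where(group[:, None] == "case", base * eff, base)
        meta_cols["group"] = group
    alphas = tilt / tilt.sum(axis=1, keepdims=True)

    fracs = np.empty((n, t))
    expr = np.empty((n_genes, n))
    for s in range(n):
        fracs[s] = rng.dirichlet(cfg.dirichlet_concentration * alphas[s])
        clean = profiles @ fracs[s]
        noise = rng.normal(0.0, cfg.noise_sd, n_genes)
        expr[:, s] = clean * np.exp2(noise)

    expr_df = pd.DataFrame(expr, index=genes, columns=sample_ids)
    meta = SampleMetadata(pd.DataFrame(meta_cols, index=pd.Index(sample_ids,
                                                                 name="sample_id")))
    markers = MarkerSetCollection({
        ct: marker_names[ti * cfg.markers_per_type:(ti + 1) * cfg.markers_per_type]
        for ti, ct in enumerate(types)
    })
    truth = pd.DataFrame(fracs, index=sample_ids, columns=types)
    effect_map = {ct: float(e) for ct, e in zip(types, eff)}
    return SyntheticCohort(expr=ExpressionMatrix(expr_df, "linear"), meta=meta,
                           markers=markers, truth=truth, effect_map=effect_map)


def expected_case_fractions(cfg: SimulationConfig) -> np.ndarray:
    """Analytic mean fractions for case samples (group mode)."""
    tilt = cfg.baseline() * cfg.effects()
    return tilt / tilt.sum()
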