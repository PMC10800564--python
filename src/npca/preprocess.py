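"""Single-cell RNA-seq preprocessing: QC filters, total-count normalization
and log transform, and highly-variable-gene selection.

The pipeline follows the standard scRNA-seq recipe: drop genes seen in fewer
than 3 cells; drop cells expressing fewer than 200 or more than 2,500 genes,
or whose mitochondrial read fraction exceeds the threshold; normalize each
cell to 10,000 total counts; apply log10(x + 1); optionally keep the top
200/500/1000 highly variable genes.  Boundary semantics are strict
inequalities ("fewer than", "more than"), and the mitochondrial cutoff
defaults to 0.95 (configurable — conventional workflows use much lower
values such as 0.05–0.20).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import DataMatrix

__all__ = [
    "CountMatrix",
    "QCParams",
    "QCReport",
    "filter_genes",
    "filter_cells",
    "qc_filter",
    "normalize_and_log",
    "select_hvg",
    "preprocess",
]


@dataclass
class CountMatrix:
    """Integer n-cells × g-genes count matrix with identifiers and a
    mitochondrial-gene mask."""

    counts: np.ndarray
    gene_names: list[str]
    cell_ids: list[str]
    mito_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D cells × genes matrix")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if not np.issubdtype(self.counts.dtype, np.integer):
            rounded = np.rint(self.counts)
            if not np.allclose(self.counts, rounded):
                raise ValueError("counts must be integer-valued")
            self.counts = rounded.astype(np.int64)
        n, g = self.counts.shape
        if len(self.gene_names) != g:
            raise ValueError("gene_names length must equal gene count")
        if len(self.cell_ids) != n:
            raise ValueError("cell_ids length must equal cell count")
        if len(set(self.gene_names)) != g or len(set(self.cell_ids)) != n:
            raise ValueError("gene names and cell ids must be unique")
        if self.mito_mask is not None:
            self.mito_mask = np.asarray(self.mito_mask, dtype=bool)
            if self.mito_mask.shape != (g,):
                raise ValueError("mito_mask length must equal gene count")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]


@dataclass
class QCParams:
    """Quality-control thresholds; defaults follow the strict-inequality
    conventions described in the module docstring."""

    min_cells_per_gene: int = 3
    min_genes_per_cell: int = 200
    max_genes_per_cell: int = 2500
    max_mito_fraction: float = 0.95
    scale_total: float = 1e4
    mito_prefix: str = "MT-"

    def __post_init__(self) -> None:
        if self.min_genes_per_cell >= self.max_genes_per_cell:
            raise ValueError("min_genes_per_cell must be < max_genes_per_cell")
        if not (0.0 <= self.max_mito_fraction <= 1.0):
            raise ValueError("max_mito_fraction must be in [0, 1]")
        if self.scale_total <= 0:
            raise ValueError("scale_total must be positive")


@dataclass
class QCReport:
    """Bookkeeping of what the filters removed; fully determined by the
    input and parameters."""

    genes_in: int = 0
    genes_out: int = 0
    cells_in: int = 0
    cells_out: int = 0
    removed_by_rule: dict = field(default_factory=dict)
    rule_order: list = field(default_factory=list)
    n_passes: int = 0

    def check_conserved(self) -> bool:
        cell_rules = ("low_gene_cells", "high_gene_cells", "high_mito_cells")
        removed = sum(self.removed_by_rule.get(r, 0) for r in cell_rules)
        return self.cells_in == self.cells_out + removed


def _mito_mask(C: CountMatrix, params: QCParams) -> np.ndarray:
    if C.mito_mask is not None:
        return C.mito_mask
    prefix = params.mito_prefix.lower()
    return np.array([g.lower().startswith(prefix) for g in C.gene_names])


def filter_genes(C: CountMatrix, params: QCParams | None = None) -> CountMatrix:
    """Keep genes with nonzero counts in at least ``min_cells_per_gene``
    cells."""
    params = params or QCParams()
    prevalence = (C.counts > 0).sum(axis=0)
    keep = prevalence >= params.min_cells_per_gene
    if not keep.any():
        raise ValueError("gene filter removed every gene; check the input")
    mask = _mito_mask(C, params)
    return CountMatrix(
        counts=C.counts[:, keep],
        gene_names=[g for g, k in zip(C.gene_names, keep) if k],
        cell_ids=list(C.cell_ids),
        mito_mask=mask[keep],
    )


def filter_cells(
    C: CountMatrix, params: QCParams | None = None
) -> tuple[CountMatrix, QCReport]:
    """Remove low-complexity, high-complexity and mitochondria-dominated
    cells, in that rule order (a cell violating several rules is counted
    under the first)."""
    params = params or QCParams()
    mask = _mito_mask(C, params)
    expressed = (C.counts > 0).sum(axis=1)
    totals = C.counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(
            totals > 0, C.counts[:, mask].sum(axis=1) / np.maximum(totals, 1), 1.0
        )
    low = expressed < params.min_genes_per_cell
    high = ~low & (expressed > params.max_genes_per_cell)
    mito = ~low & ~high & (mito_frac > params.max_mito_fraction)
    keep = ~(low | high | mito)
    if not keep.any():
        raise ValueError("cell filters removed every cell; check the thresholds")
    report = QCReport(
        genes_in=C.n_genes,
        genes_out=C.n_genes,
        cells_in=C.n_cells,
        cells_out=int(keep.sum()),
        removed_by_rule={
            "low_gene_cells": int(low.sum()),
            "high_gene_cells": int(high.sum()),
            "high_mito_cells": int(mito.sum()),
        },
        rule_order=["low_gene_cells", "high_gene_cells", "high_mito_cells"],
        n_passes=1,
    )
    out = CountMatrix(
        counts=C.counts[keep],
        gene_names=list(C.gene_names),
        cell_ids=[c for c, k in zip(C.cell_ids, keep) if k],
        mito_mask=mask,
    )
    return out, report


def qc_filter(
    C: CountMatrix, params: QCParams | None = None
) -> tuple[CountMatrix, QCReport]:
    """Gene filter then cell filters, iterated to a fixed point.

    Removing cells can push genes back under the prevalence threshold (and
    vice versa), so a single pass is not idempotent in general; iterating
    until nothing changes makes the whole pipeline idempotent.  Per-rule
    counts are accumulated over passes.
    """
    params = params or QCParams()
    report = QCReport(
        genes_in=C.n_genes,
        cells_in=C.n_cells,
        removed_by_rule={
            "low_prevalence_genes": 0,
            "low_gene_cells": 0,
            "high_gene_cells": 0,
            "high_mito_cells": 0,
        },
        rule_order=[
            "low_prevalence_genes",
            "low_gene_cells",
            "high_gene_cells",
            "high_mito_cells",
        ],
    )
    current = C
    while True:
        report.n_passes += 1
        genes_before = current.n_genes
        current = filter_genes(current, params)
        report.removed_by_rule["low_prevalence_genes"] += genes_before - current.n_genes
        cells_before = current.n_cells
        current, pass_report = filter_cells(current, params)
        for rule in ("low_gene_cells", "high_gene_cells", "high_mito_cells"):
            report.removed_by_rule[rule] += pass_report.removed_by_rule[rule]
        if genes_before == current.n_genes and cells_before == current.n_cells:
            break
    report.genes_out = current.n_genes
    report.cells_out = current.n_cells
    return current, report


def normalize_and_log(
    C: CountMatrix, params: QCParams | None = None
) -> DataMatrix:
    """Scale each cell to ``scale_total`` counts, then log10(x + 1).

    value(cell, gene) = log10(count · scale_total / cell_total + 1).
    """
    params = params or QCParams()
    totals = C.counts.sum(axis=1, dtype=np.float64)
    if np.any(totals == 0):
        bad = C.cell_ids[int(np.argmax(totals == 0))]
        raise ValueError(f"cell {bad!r} has zero total counts; filter cells first")
    normalized = C.counts * (params.scale_total / totals)[:, None]
    return DataMatrix(
        values=np.log10(normalized + 1.0),
        feature_names=list(C.gene_names),
        sample_ids=list(C.cell_ids),
    )


def hvg_scores(X: DataMatrix, n_bins: int = 20) -> pd.Series:
    """Dispersion score per gene: var/mean of the log-normalized values,
    z-scored within 20 equal-width mean bins (so highly variable genes are
    those unusually dispersed for their expression level)."""
    df = X.to_dataframe()
    means = df.mean(axis=0)
    var = df.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        dispersion = var / means
    dispersion = dispersion.replace([np.inf, -np.inf], np.nan).fillna(0.0)
    bins = pd.cut(means, bins=n_bins, labels=False, duplicates="drop")
    grouped = dispersion.groupby(bins)
    mu = grouped.transform("mean")
    sd = grouped.transform("std").replace(0.0, np.nan)
    z = (dispersion - mu) / sd
    # singleton or zero-spread bins have no within-bin scale; fall back to
    # the global z-score so extreme-mean outlier genes can still rank
    g_sd = dispersion.std(ddof=1)
    global_z = (dispersion - dispersion.mean()) / (g_sd if g_sd > 0 else 1.0)
    return z.fillna(global_z)


def select_hvg(X: DataMatrix, n_top: int) -> DataMatrix:
    """Keep the ``n_top`` most variable genes by binned normalized
    dispersion; original gene order is preserved, ties broken by gene name."""
    m = X.n_features
    if not (1 <= n_top <= m):
        raise ValueError(f"n_top={n_top} out of range [1, {m}]")
    if n_top == m:
        return X
    scores = hvg_scores(X)
    order = sorted(
        range(m),
        key=lambda j: (-scores.iloc[j], X.feature_names[j]),
    )
    keep = sorted(order[:n_top])
    return DataMatrix(
        values=X.values[:, keep],
        feature_names=[X.feature_names[j] for j in keep],
        sample_ids=list(X.sample_ids),
    )


def preprocess(
    C: CountMatrix,
    params: QCParams | None = None,
    n_top_genes: int | None = None,
) -> tuple[DataMatrix, QCReport]:
    """Full pipeline: QC filters → normalization → log → optional HVG
    subset.  A pure function of its inputs."""
    params = params or QCParams()
    filtered, report = qc_filter(C, params)
    X = normalize_and_log(filtered, params)
    if n_top_genes is not None:
        X = select_hvg(X, n_top_genes)
    return X, report
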