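"""Seeded synthetic-data generators.

Two regimes are emulated, matching the two kinds of benchmark input the
method is aimed at:

* :func:`make_manifold` — continuous data whose features are smooth nonlinear
  functions of a 2-D latent plus Gaussian noise.  A linear decoder cannot
  fully invert a nonlinear map, so a free linear encoder trained against a
  nonlinear decoder can find a better 2-D projection than PCA — the regime
  where the neural method should win.  The ``linear`` map is the degenerate
  control where both should tie.

* :func:`make_counts` — cluster-structured negative-binomial count matrices
  with log-normal library sizes, mitochondrial genes and deliberately planted
  QC-violating cells, so each preprocessing rule can be exercised without any
  external download.  No attempt is made to match real pancreas gene-level
  statistics; there are no batch effects, ambient RNA or doublets.

All generators are pure functions of their spec: the same spec (including
seed) reproduces bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import DataMatrix
from .metrics import ClusterLabels
from .preprocess import CountMatrix

__all__ = ["ManifoldSpec", "CountSpec", "make_manifold", "make_counts"]

_MAPS = ("quadratic", "swiss_roll_like", "sinusoidal", "linear")


@dataclass
class ManifoldSpec:
    """Continuous manifold generator settings.

    ``noise_sd`` is the standard deviation of the additive Gaussian noise on
    each feature; the noiseless features have roughly unit scale, so 0.1 is a
    ~10% noise level.
    """

    n: int = 500
    m: int = 10
    noise_sd: float = 0.1
    map_name: str = "quadratic"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 3:
            raise ValueError("need at least 3 features")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.map_name not in _MAPS:
            raise ValueError(f"unknown map_name {self.map_name!r}; choose from {_MAPS}")


@dataclass
class CountSpec:
    """Negative-binomial count generator settings.

    ``nb_dispersion`` is the NB shape r in var = μ + μ²/r (smaller = more
    overdispersed).  ``planted_bad_cells`` is a (low-gene, high-gene,
    high-mito) triple of cells built to violate each QC rule strictly.
    Defaults give ~500 cells × 3000 genes with 3 cell types, a regime where
    each type is recoverable by clustering after preprocessing.
    """

    n_cells: int = 500
    n_genes: int = 3000
    n_types: int = 3
    mito_genes: int = 50
    libsize_log_sd: float = 0.4
    de_fraction: float = 0.1
    de_fold: float = 4.0
    nb_dispersion: float = 0.5
    planted_bad_cells: tuple[int, int, int] = (0, 0, 0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cells", "n_genes", "n_types", "mito_genes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.de_fraction <= 1):
            raise ValueError("de_fraction must be in (0, 1]")
        if self.de_fraction * self.n_genes < 1:
            raise ValueError("de_fraction too small: no differential genes")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")


def make_manifold(spec: ManifoldSpec) -> tuple[DataMatrix, np.ndarray]:
    """Generate (observed DataMatrix, true n×2 latent).

    The latent (u, v) is uniform on [−1, 1]²; each feature is a fixed smooth
    function of the latent with seeded random coefficients, plus independent
    N(0, noise_sd²) noise.
    """
    rng = np.random.default_rng(spec.seed)
    u = rng.uniform(-1.0, 1.0, size=spec.n)
    v = rng.uniform(-1.0, 1.0, size=spec.n)
    latent = np.column_stack([u, v])

    if spec.map_name == "linear":
        basis = np.column_stack([u, v])
        linear_rows = (0, 1)
    elif spec.map_name == "quadratic":
        basis = np.column_stack([u, v, u**2, v**2, u * v])
        linear_rows = (0, 1)
    elif spec.map_name == "sinusoidal":
        basis = np.column_stack(
            [u, v, np.sin(np.pi * u), np.cos(np.pi * v), np.sin(np.pi * u * v)]
        )
        linear_rows = (0, 1)
    else:  # swiss_roll_like: roll the first latent axis, keep the second
        t = np.pi * (1.0 + u)
        basis = np.column_stack([t * np.cos(t) / np.pi, v, t * np.sin(t) / np.pi])
        linear_rows = (1,)

    coef = rng.normal(size=(basis.shape[1], spec.m))
    # both latent coordinates must be solidly expressed in the features, or
    # no 2-D projection could recover them: give the linear terms a
    # magnitude floor instead of a bare Gaussian draw
    for row in linear_rows:
        coef[row] = rng.uniform(0.7, 1.5, size=spec.m) * rng.choice(
            [-1.0, 1.0], size=spec.m
        )
    clean = basis @ coef
    noise = rng.normal(scale=spec.noise_sd, size=clean.shape) if spec.noise_sd > 0 else 0.0
    X = DataMatrix(values=clean + noise)
    return X, latent


def _plant_low_gene(rng, n_genes, mito_start):
    """Cell expressing 150 genes — strictly below the 200-gene floor."""
    row = np.zeros(n_genes, dtype=np.int64)
    genes = rng.choice(mito_start, size=150, replace=False)
    row[genes] = rng.integers(1, 4, size=150)
    return row


def _plant_high_gene(rng, n_genes, max_genes):
    """Cell expressing max_genes + 100 genes — strictly above the ceiling."""
    target = min(max_genes + 100, n_genes)
    row = np.zeros(n_genes, dtype=np.int64)
    genes = rng.choice(n_genes, size=target, replace=False)
    row[genes] = rng.integers(1, 4, size=target)
    return row


def _plant_high_mito(rng, n_genes, n_mito):
    """Cell with ~97.5% mitochondrial reads but a normal gene count."""
    row = np.zeros(n_genes, dtype=np.int64)
    row[n_genes - n_mito :] = 200  # mito block
    others = rng.choice(n_genes - n_mito, size=250, replace=False)
    row[others] = 1
    return row


def make_counts(spec: CountSpec) -> tuple[CountMatrix, ClusterLabels]:
    """Generate (CountMatrix, true type labels for every cell).

    Per-type mean profiles share a log-normal baseline; each type upregulates
    its own random ``de_fraction`` of genes by ``de_fold``.  Counts are
    negative binomial around mean · library-size factor.  Planted bad cells
    are appended after the normal cells with ids ``bad_low_*``, ``bad_high_*``
    and ``bad_mito_*``; their labels are 0 (they are meant to be discarded by
    QC before any clustering).
    """
    rng = np.random.default_rng(spec.seed)
    g, n_mito = spec.n_genes, min(spec.mito_genes, spec.n_genes - 1)
    mito_start = g - n_mito

    base = rng.lognormal(mean=-0.5, sigma=1.0, size=g)
    type_means = np.tile(base, (spec.n_types, 1))
    n_de = max(1, int(round(spec.de_fraction * g)))
    for t in range(spec.n_types):
        de_genes = rng.choice(mito_start, size=min(n_de, mito_start), replace=False)
        type_means[t, de_genes] *= spec.de_fold

    labels = rng.integers(0, spec.n_types, size=spec.n_cells)
    libfactor = rng.lognormal(mean=0.0, sigma=spec.libsize_log_sd, size=spec.n_cells)
    mu = type_means[labels] * libfactor[:, None]
    r = spec.nb_dispersion
    counts = rng.negative_binomial(n=r, p=r / (r + mu))

    n_low, n_high, n_mito_cells = spec.planted_bad_cells
    bad_rows, bad_ids = [], []
    for i in range(n_low):
        bad_rows.append(_plant_low_gene(rng, g, mito_start))
        bad_ids.append(f"bad_low_{i}")
    for i in range(n_high):
        bad_rows.append(_plant_high_gene(rng, g, 2500))
        bad_ids.append(f"bad_high_{i}")
    for i in range(n_mito_cells):
        bad_rows.append(_plant_high_mito(rng, g, n_mito))
        bad_ids.append(f"bad_mito_{i}")

    if bad_rows:
        counts = np.vstack([counts, np.array(bad_rows)])
        labels = np.concatenate([labels, np.zeros(len(bad_rows), dtype=np.int64)])

    gene_names = [f"GENE{j}" for j in range(mito_start)] + [
        f"MT-{j}" for j in range(n_mito)
    ]
    cell_ids = [f"cell{i}" for i in range(spec.n_cells)] + bad_ids
    C = CountMatrix(
        counts=counts,
        gene_names=gene_names,
        cell_ids=cell_ids,
        mito_mask=np.arange(g) >= mito_start,
    )
    return C, ClusterLabels(labels=labels, k=spec.n_types)
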