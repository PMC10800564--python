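"""Dense data matrices, per-feature standardization, and SVD-based PCA.

The central container is :class:`DataMatrix`, an n-samples × m-features dense
real matrix with feature names and sample identifiers.  Standardization uses
the population (ddof=0) convention so that, on standardized data, the total
per-entry mean square is exactly 1 — which is what makes the reconstruction
loss ``E = ½·mean((y − x)²)`` interpretable as half the un-captured variance
fraction, and ``(1 − 2E)·100`` the percentage of variance captured.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DataMatrix",
    "StandardizationStats",
    "PCABasis",
    "standardize",
    "svd_pca",
    "pca_scores",
    "linear_pca_variance_captured",
]


@dataclass
class DataMatrix:
    """Dense n×m numeric matrix: rows are samples, columns are features."""

    values: np.ndarray
    feature_names: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("DataMatrix values must be 2-dimensional")
        n, m = self.values.shape
        if n < 1 or m < 2:
            raise ValueError(f"need at least 1 sample and 2 features, got {n}×{m}")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value at row {bad[0]}, column {bad[1]}; "
                "missing values are not supported"
            )
        if not self.feature_names:
            self.feature_names = [f"f{j}" for j in range(m)]
        if not self.sample_ids:
            self.sample_ids = [f"s{i}" for i in range(n)]
        if len(self.feature_names) != m:
            raise ValueError("feature_names length does not match column count")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match row count")
        if len(set(self.feature_names)) != m:
            raise ValueError("feature names must be unique")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "DataMatrix":
        return cls(
            values=df.to_numpy(dtype=np.float64),
            feature_names=[str(c) for c in df.columns],
            sample_ids=[str(i) for i in df.index],
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.feature_names
        )


@dataclass
class StandardizationStats:
    """Per-feature means and scales; ``scales`` are population standard
    deviations (strictly positive)."""

    means: np.ndarray
    scales: np.ndarray

    def apply(self, values: np.ndarray) -> np.ndarray:
        return (values - self.means) / self.scales

    def invert(self, values: np.ndarray) -> np.ndarray:
        return values * self.scales + self.means


def standardize(X: DataMatrix) -> tuple[DataMatrix, StandardizationStats]:
    """Center each feature to mean 0 and scale to unit population variance.

    Raises
    ------
    ValueError
        If any feature has zero variance (the offending feature is named).
    """
    means = X.values.mean(axis=0)
    scales = X.values.std(axis=0, ddof=0)
    zero = np.flatnonzero(scales == 0.0)
    if zero.size:
        names = ", ".join(X.feature_names[j] for j in zero[:5])
        raise ValueError(
            f"feature(s) with zero variance cannot be standardized: {names}. "
            "Remove constant features before fitting."
        )
    stats = StandardizationStats(means=means, scales=scales)
    out = DataMatrix(
        values=stats.apply(X.values),
        feature_names=list(X.feature_names),
        sample_ids=list(X.sample_ids),
    )
    return out, stats


@dataclass
class PCABasis:
    """Top-k principal directions of a centered matrix.

    ``loadings`` is m×k with orthonormal columns (the conventional PCA
    projection for row-sample matrices, i.e. top right singular vectors);
    ``singular_values`` holds all min(n, m) singular values, nonincreasing;
    ``explained_fraction`` is λ_j / Σλ for the k kept components.
    """

    loadings: np.ndarray
    singular_values: np.ndarray
    explained_fraction: np.ndarray


def _fix_signs(loadings: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: the largest-magnitude entry of each
    column is positive (first occurrence wins ties)."""
    out = loadings.copy()
    for j in range(out.shape[1]):
        i = int(np.argmax(np.abs(out[:, j])))
        if out[i, j] < 0:
            out[:, j] = -out[:, j]
    return out


def svd_pca(X: DataMatrix, k: int) -> PCABasis:
    """PCA of ``X`` via singular value decomposition of the centered matrix.

    The caller normally passes standardized data (correlation-scale PCA);
    uncentered input is centered here so the decomposition is always of the
    mean-removed matrix.
    """
    n, m = X.values.shape
    if not (1 <= k <= min(n, m)):
        raise ValueError(f"k={k} out of range [1, {min(n, m)}]")
    centered = X.values - X.values.mean(axis=0)
    # right singular vectors = eigenvectors of the covariance; these are the
    # PCA projection directions for row-sample matrices
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    loadings = _fix_signs(vt[:k].T)
    lam = s**2
    total = lam.sum()
    explained = lam[:k] / total if total > 0 else np.zeros(k)
    return PCABasis(
        loadings=loadings, singular_values=s, explained_fraction=explained
    )


def pca_scores(X: DataMatrix, basis: PCABasis) -> np.ndarray:
    """Project (already centered/standardized) data onto the basis."""
    return X.values @ basis.loadings


def linear_pca_variance_captured(X: DataMatrix, k: int = 2) -> float:
    """Variance captured (%) by the purely linear rank-k PCA autoencoder.

    Encodes with the top-k loadings and decodes with their transpose — the
    best linear decoder for an orthonormal encoder.  On standardized data this
    equals 100·(λ₁+…+λ_k)/Σλ and is the linear-limit baseline the frozen
    encoder network should approach.
    """
    from .network import reconstruction_loss, variance_captured

    basis = svd_pca(X, k)
    recon = (X.values @ basis.loadings) @ basis.loadings.T
    return variance_captured(reconstruction_loss(recon, X.values))
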