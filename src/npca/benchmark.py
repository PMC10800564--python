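"""Benchmark harness: preprocess → reduce to 2-D with several linear
methods → k-means with the true category count → ARI, mean silhouette and
(for the neural methods) variance captured.

The neural method and its frozen-encoder PCA counterpart are this package's
own implementation; ICA, MDS and FA are standard methods delegated to
scikit-learn.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .data import DataMatrix
from .metrics import adjusted_rand, kmeans, mean_silhouette
from .model import NPCA
from .preprocess import CountMatrix, QCParams, preprocess

__all__ = ["RunConfig", "BenchmarkRecord", "reduce_2d", "run_benchmark"]

METHODS = ("npca", "pca_frozen", "ica", "mds", "fa")


@dataclass
class RunConfig:
    """Settings for one benchmark run over a dataset."""

    dataset_id: str = "dataset"
    hvg_sizes: Sequence[Optional[int]] = (None,)
    methods: Sequence[str] = ("npca", "pca_frozen")
    qc: QCParams = field(default_factory=QCParams)
    run_qc: bool = True
    learning_rate: float = 0.01
    epochs: int = 2000
    batch_size: int = 32
    seed: int = 0
    hidden_width: int = 32
    activation: str = "tanh"

    def __post_init__(self) -> None:
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown method(s) {sorted(unknown)}; choose from {METHODS}")


@dataclass
class BenchmarkRecord:
    dataset_id: str
    hvg_size: Optional[int]
    method: str
    ari: Optional[float]
    silhouette: float
    variance_captured_pct: Optional[float]


def reduce_2d(X: DataMatrix, method: str, config: RunConfig) -> tuple[np.ndarray, Optional[float]]:
    """Reduce standardized-on-the-fly data to n×2 with the named method;
    returns (embedding, variance_captured_pct or None)."""
    if method in ("npca", "pca_frozen"):
        model = NPCA(
            X,
            hidden_width=config.hidden_width,
            activation=config.activation,
            freeze_encoder=(method == "pca_frozen"),
        )
        res = model.fit(
            learning_rate=config.learning_rate,
            epochs=config.epochs,
            batch_size=config.batch_size,
            seed=config.seed,
        )
        return res.embedding, res.variance_captured
    from .data import standardize

    Z, _ = standardize(X)
    if method == "ica":
        from sklearn.decomposition import FastICA

        emb = FastICA(n_components=2, random_state=config.seed).fit_transform(Z.values)
    elif method == "mds":
        from sklearn.manifold import MDS

        emb = MDS(
            n_components=2, random_state=config.seed, normalized_stress="auto"
        ).fit_transform(Z.values)
    elif method == "fa":
        from sklearn.decomposition import FactorAnalysis

        emb = FactorAnalysis(n_components=2, random_state=config.seed).fit_transform(
            Z.values
        )
    else:
        raise ValueError(f"unknown method {method!r}")
    return emb, None


def run_benchmark(
    data: CountMatrix | DataMatrix,
    config: RunConfig,
    true_labels: Optional[np.ndarray] = None,
    label_ids: Optional[list[str]] = None,
    n_clusters: Optional[int] = None,
) -> list[BenchmarkRecord]:
    """Run the full protocol and return one record per (hvg size, method).

    ``true_labels`` (aligned with ``label_ids`` or with the input rows) is
    required for ARI; ``n_clusters`` defaults to the number of distinct true
    labels.
    """
    if true_labels is None and n_clusters is None:
        raise ValueError("provide true_labels or n_clusters for k-means")

    records: list[BenchmarkRecord] = []
    for hvg in config.hvg_sizes:
        if isinstance(data, CountMatrix) and config.run_qc:
            X, _ = preprocess(data, config.qc, n_top_genes=hvg)
        elif isinstance(data, CountMatrix):
            from .preprocess import normalize_and_log, select_hvg

            X = normalize_and_log(data, config.qc)
            if hvg is not None:
                X = select_hvg(X, hvg)
        else:
            X = data
            if hvg is not None:
                from .preprocess import select_hvg

                X = select_hvg(X, hvg)

        labels = None
        if true_labels is not None:
            if label_ids is not None:
                lookup = dict(zip(label_ids, true_labels))
                missing = [s for s in X.sample_ids if s not in lookup]
                if missing:
                    raise ValueError(f"no true label for sample(s) {missing[:5]}")
                labels = np.array([lookup[s] for s in X.sample_ids])
            else:
                if len(true_labels) != X.n_samples:
                    raise ValueError(
                        "true_labels length does not match the sample count; "
                        "pass label_ids to align after filtering"
                    )
                labels = np.asarray(true_labels)
        k = n_clusters or len(np.unique(labels))

        for method in config.methods:
            emb, vc = reduce_2d(X, method, config)
            pred = kmeans(emb, k, seed=config.seed)
            ari = adjusted_rand(pred, labels) if labels is not None else None
            sh = mean_silhouette(emb, pred).mean_sh
            records.append(
                BenchmarkRecord(
                    dataset_id=config.dataset_id,
                    hvg_size=hvg,
                    method=method,
                    ari=ari,
                    silhouette=sh,
                    variance_captured_pct=vc,
                )
            )
    return records


def write_records(
    records: list[BenchmarkRecord], out_dir: str, header: str = ""
) -> tuple[str, str]:
    """Emit the records as TSV and JSON; returns the two paths."""
    os.makedirs(out_dir, exist_ok=True)
    df = pd.DataFrame([asdict(r) for r in records])
    tsv = os.path.join(out_dir, "benchmark.tsv")
    with open(tsv, "w") as fh:
        if header:
            fh.write(header + "\n")
        df.to_csv(fh, sep="\t", index=False)
    js = os.path.join(out_dir, "benchmark.json")
    with open(js, "w") as fh:
        json.dump([asdict(r) for r in records], fh, indent=2)
    return tsv, js
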