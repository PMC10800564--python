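"""Model/Results interface for neural PCA.

``NPCA`` wraps the training machinery in the style of statsmodels: the model
is constructed from data, ``fit()`` runs the optimisation and returns an
``NPCAResults`` carrying the estimated projection, the loss trajectory, the
variance-captured diagnostic and a ``summary()`` table.  The frozen-encoder
PCA benchmark is the same model with ``freeze_encoder=True``.
"""

from __future__ import annotations

from typing import Optional, Union

import numpy as np
import pandas as pd

from .data import (
    DataMatrix,
    StandardizationStats,
    standardize,
    svd_pca,
)
from .network import (
    N_COMPONENTS,
    NPCAParams,
    TrainConfig,
    TrainResult,
    encode,
    forward,
    init_model,
    reconstruction_loss,
    train,
    variance_captured,
)

__all__ = ["NPCA", "NPCAResults"]


class NPCA:
    """Neural PCA: linear 2-D encoder + nonlinear MLP decoder.

    Parameters
    ----------
    data : DataMatrix or array-like or DataFrame
        n-samples × m-features matrix.
    hidden_width : int
        Width d of the two nonlinear decoder layers (default 32).
    activation : str
        Decoder nonlinearity: ``tanh`` (default), ``sigmoid`` or ``relu``.
    freeze_encoder : bool
        If True, the encoder stays fixed at the PCA loadings — the PCA
        benchmark network against which nPCA's loss is compared.
    scale : bool
        Standardize features to zero mean / unit variance before training
        (default True; required for the variance-captured metric to be a
        percentage of total variance).

    Examples
    --------
    >>> model = NPCA(data)
    >>> res = model.fit(seed=0)
    >>> res.variance_captured
    >>> res.embedding          # n×2 linear projection of the data
    """

    def __init__(
        self,
        data,
        hidden_width: int = 32,
        activation: str = "tanh",
        freeze_encoder: bool = False,
        scale: bool = True,
    ):
        if isinstance(data, pd.DataFrame):
            data = DataMatrix.from_dataframe(data)
        elif not isinstance(data, DataMatrix):
            data = DataMatrix(values=np.asarray(data, dtype=np.float64))
        self.raw_data = data
        self.hidden_width = hidden_width
        self.activation = activation
        self.freeze_encoder = freeze_encoder
        self.scale = scale
        if scale:
            self.data, self.scaler = standardize(data)
        else:
            self.data = data
            self.scaler = StandardizationStats(
                means=np.zeros(data.n_features), scales=np.ones(data.n_features)
            )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "NPCA":
        return cls(DataMatrix.from_dataframe(df), **kwargs)

    def fit(
        self,
        learning_rate: float = 0.01,
        epochs: int = 2000,
        batch_size: Union[int, str] = 32,
        seed: int = 0,
        snapshot_every: int = 0,
        patience: int = 50,
        min_delta: float = 1e-7,
        start_params: Optional[NPCAParams] = None,
    ) -> "NPCAResults":
        """Run seeded mini-batch SGD and return the results object."""
        config = TrainConfig(
            learning_rate=learning_rate,
            epochs=epochs,
            batch_size=batch_size,
            seed=seed,
            freeze_encoder=self.freeze_encoder,
            snapshot_every=snapshot_every,
            patience=patience,
            min_delta=min_delta,
        )
        if start_params is None:
            start_params = init_model(
                self.data,
                hidden_width=self.hidden_width,
                activation_name=self.activation,
                seed=seed,
            )
        result = train(self.data, config, start_params)
        return NPCAResults(self, result, config)


class NPCAResults:
    """Fitted nPCA projection with training diagnostics.

    Attributes
    ----------
    loadings : DataFrame (m×2)
        The learned linear projection, one row per feature.
    embedding : ndarray (n×2)
        Projection of the training data.
    final_loss, loss_history, variance_captured : training diagnostics.
    """

    def __init__(self, model: NPCA, result: TrainResult, config: TrainConfig):
        self.model = model
        self.params = result.model
        self.config = config
        self.final_loss = result.final_loss
        self.loss_history = result.loss_history
        self.embedding_snapshots = result.embedding_snapshots
        self.variance_captured = result.variance_captured_pct
        self.n_epochs_run = len(result.loss_history)

    @property
    def loadings(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.params.encoder_weights,
            index=self.model.data.feature_names,
            columns=[f"npc{j + 1}" for j in range(N_COMPONENTS)],
        )

    @property
    def embedding(self) -> np.ndarray:
        return encode(self.params, self.model.data)

    def transform(self, new_data) -> np.ndarray:
        """Project new samples: standardize with the training statistics,
        then apply the linear encoder."""
        if isinstance(new_data, pd.DataFrame):
            new_data = DataMatrix.from_dataframe(new_data)
        values = new_data.values if isinstance(new_data, DataMatrix) else np.asarray(
            new_data, dtype=np.float64
        )
        return self.model.scaler.apply(values) @ self.params.encoder_weights

    def reconstruct(self) -> np.ndarray:
        """Decoder output on the training data (standardized scale)."""
        _, recon = forward(self.params, self.model.data)
        return recon

    def pca_variance_captured(self) -> float:
        """Variance captured (%) by plain rank-2 PCA on the same data — the
        linear baseline the frozen-encoder network approaches."""
        from .data import linear_pca_variance_captured

        return linear_pca_variance_captured(self.model.data, N_COMPONENTS)

    def summary(self) -> str:
        basis = svd_pca(self.model.data, N_COMPONENTS)
        pca_vc = 100.0 * basis.explained_fraction.sum()
        mode = "frozen encoder (PCA benchmark)" if self.config.freeze_encoder else "free encoder (nPCA)"
        lines = [
            "Neural PCA Results",
            "=" * 58,
            f"{'No. samples:':<28}{self.model.data.n_samples}",
            f"{'No. features:':<28}{self.model.data.n_features}",
            f"{'Decoder width (d):':<28}{self.params.hidden_width}",
            f"{'Activation:':<28}{self.params.activation_name}",
            f"{'Mode:':<28}{mode}",
            f"{'Epochs run:':<28}{self.n_epochs_run}",
            f"{'Learning rate:':<28}{self.config.learning_rate}",
            f"{'Final loss E:':<28}{self.final_loss:.6f}",
            f"{'Variance captured:':<28}{self.variance_captured:.2f}%",
            f"{'Rank-2 PCA variance:':<28}{pca_vc:.2f}%",
            "=" * 58,
        ]
        return "\n".join(lines)

    def save(self, path: str) -> None:
        """Persist the fitted model as a single .npz container with named
        arrays and a format-version field."""
        np.savez(
            path,
            format_version=np.array([1]),
            encoder_weights=self.params.encoder_weights,
            decoder_w1=self.params.decoder_weights[0],
            decoder_w2=self.params.decoder_weights[1],
            decoder_w3=self.params.decoder_weights[2],
            decoder_b1=self.params.decoder_biases[0],
            decoder_b2=self.params.decoder_biases[1],
            decoder_b3=self.params.decoder_biases[2],
            hidden_width=np.array([self.params.hidden_width]),
            activation=np.array([self.params.activation_name]),
            scaler_means=self.model.scaler.means,
            scaler_scales=self.model.scaler.scales,
            feature_names=np.array(self.model.data.feature_names),
        )


def load_params(path: str) -> tuple[NPCAParams, StandardizationStats, list[str]]:
    """Load a model container written by :meth:`NPCAResults.save`."""
    with np.load(path, allow_pickle=False) as z:
        if int(z["format_version"][0]) != 1:
            raise ValueError("unsupported model container version")
        params = NPCAParams(
            encoder_weights=z["encoder_weights"],
            decoder_weights=[z["decoder_w1"], z["decoder_w2"], z["decoder_w3"]],
            decoder_biases=[z["decoder_b1"], z["decoder_b2"], z["decoder_b3"]],
            hidden_width=int(z["hidden_width"][0]),
            activation_name=str(z["activation"][0]),
        )
        scaler = StandardizationStats(means=z["scaler_means"], scales=z["scaler_scales"])
        features = [str(f) for f in z["feature_names"]]
    return params, scaler, features
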