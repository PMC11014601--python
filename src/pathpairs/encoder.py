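"""Auto-encoder compression of feature blocks to a fraction of their width.

Metabolite and pathway blocks share one atom-color vocabulary, so a single
auto-encoder is trained on the two blocks stacked vertically (the pathway
block *before* de-duplication, so widths agree) and then applied to each
block separately.  Compressing to one tenth turns 14,655 columns into
floor(14,655 x 0.1) = 1,465 latent features.  Inputs are min-max scaled
feature-wise before training, and the latent outputs are min-max scaled
again (with parameters fit on the stacked encoded rows) to form the final
encoded features.

The network is a symmetric fully-connected encoder/decoder with one hidden
layer between input and latent, ReLU activations, mean-squared-error
reconstruction loss, mini-batch Adam, and optional early stopping on a
held-out reconstruction loss.  It is built on scikit-learn's multilayer
perceptron regressor fit to reproduce its own input; encoding runs the
input through the first half of the trained network.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from sklearn.neural_network import MLPRegressor

from .exceptions import ConfigError, SchemaError
from .matrix import FeatureMatrix, ScaleParams, minmax_apply, minmax_fit

__all__ = ["EncoderTrainConfig", "EncoderModel", "fit_autoencoder",
           "encode_block", "latent_width"]


def latent_width(n_features: int, ratio: float) -> int:
    """Width of the latent layer: floor(n_features * ratio), data-independent."""
    if not 0.0 < ratio < 1.0:
        raise ConfigError(f"ratio must lie in (0, 1), got {ratio}")
    w = math.floor(n_features * ratio)
    if w < 1:
        raise ConfigError(
            f"{n_features} columns at ratio {ratio} give an empty latent"
        )
    return w


@dataclass
class EncoderTrainConfig:
    """Training knobs for the auto-encoder.

    ``hidden_width=None`` defaults to twice the latent width, keeping the
    funnel monotone for any compression ratio.
    """

    hidden_width: int | None = None
    max_epochs: int = 400
    batch_size: int | str = "auto"
    learning_rate_init: float = 1e-3
    early_stopping: bool = True
    validation_fraction: float = 0.1
    n_iter_no_change: int = 20
    tol: float = 1e-6
    seed: int = 0


@dataclass
class EncoderModel:
    """A trained encode transform (decode is used only during training)."""

    input_width: int
    latent_width: int
    net: MLPRegressor
    post_scale: ScaleParams
    config: EncoderTrainConfig

    def encode(self, X: np.ndarray) -> np.ndarray:
        """Forward pass through the encoder half (input -> hidden -> latent)."""
        X = np.asarray(X, dtype=np.float64)
        if X.shape[1] != self.input_width:
            raise SchemaError(
                f"expected {self.input_width} columns, got {X.shape[1]}"
            )
        h = np.maximum(X @ self.net.coefs_[0] + self.net.intercepts_[0], 0.0)
        z = np.maximum(h @ self.net.coefs_[1] + self.net.intercepts_[1], 0.0)
        return z

    def save(self, path: str | Path) -> None:
        cfg = asdict(self.config)
        np.savez(
            path,
            meta=json.dumps(
                {"input_width": self.input_width,
                 "latent_width": self.latent_width,
                 "config": cfg,
                 "n_layers": len(self.net.coefs_)}
            ),
            post_mins=self.post_scale.mins,
            post_maxs=self.post_scale.maxs,
            **{f"coef_{i}": c for i, c in enumerate(self.net.coefs_)},
            **{f"intercept_{i}": b for i, b in enumerate(self.net.intercepts_)},
        )

    @classmethod
    def load(cls, path: str | Path) -> "EncoderModel":
        with np.load(path, allow_pickle=False) as f:
            meta = json.loads(str(f["meta"]))
            coefs = [f[f"coef_{i}"] for i in range(meta["n_layers"])]
            intercepts = [f[f"intercept_{i}"] for i in range(meta["n_layers"])]
            post_mins = f["post_mins"]
            post_maxs = f["post_maxs"]
        cfg = EncoderTrainConfig(**meta["config"])
        net = MLPRegressor(activation="relu")
        net.coefs_ = coefs
        net.intercepts_ = intercepts
        latent = meta["latent_width"]
        post = ScaleParams(
            [f"z{i}" for i in range(latent)], post_mins, post_maxs
        )
        return cls(meta["input_width"], latent, net, post, cfg)


def fit_autoencoder(
    stacked: FeatureMatrix,
    ratio: float = 0.1,
    train_cfg: EncoderTrainConfig | None = None,
) -> EncoderModel:
    """Train the auto-encoder on the vertically stacked, min-max-scaled blocks.

    Parameters
    ----------
    stacked
        Metabolite rows and (non-de-duplicated) pathway rows stacked, already
        min-max scaled feature-wise into [0, 1].
    ratio
        Compression ratio in (0, 1); the latent width is
        ``floor(n_features * ratio)``.
    """
    latent = latent_width(stacked.n_features, ratio)
    if stacked.values.max(initial=0.0) > 1.0 + 1e-9:
        raise SchemaError("auto-encoder input must be min-max scaled into [0, 1]")
    cfg = train_cfg or EncoderTrainConfig()
    hidden = cfg.hidden_width if cfg.hidden_width is not None else 2 * latent
    net = MLPRegressor(
        hidden_layer_sizes=(hidden, latent, hidden),
        activation="relu",
        solver="adam",
        max_iter=cfg.max_epochs,
        batch_size=cfg.batch_size,
        learning_rate_init=cfg.learning_rate_init,
        early_stopping=cfg.early_stopping and stacked.n_rows >= 20,
        validation_fraction=cfg.validation_fraction,
        n_iter_no_change=cfg.n_iter_no_change,
        tol=cfg.tol,
        random_state=cfg.seed,
    )
    X = stacked.values.astype(np.float64)
    net.fit(X, X)
    model = EncoderModel(
        stacked.n_features, latent, net,
        ScaleParams([f"z{i}" for i in range(latent)],
                    np.zeros(latent), np.ones(latent)),
        cfg,
    )
    z = model.encode(X)
    model.post_scale = ScaleParams(
        [f"z{i}" for i in range(latent)], z.min(axis=0), z.max(axis=0)
    )
    return model


def encode_block(model: EncoderModel, m: FeatureMatrix) -> FeatureMatrix:
    """Encode a scaled block and min-max scale the latents.

    The post-encoding scale parameters were fit on the stacked encoded rows,
    so the fitting blocks land in [0, 1]; bond-level metadata does not
    survive encoding.
    """
    if m.n_features != model.input_width:
        raise SchemaError(
            f"block has {m.n_features} columns; model expects {model.input_width}"
        )
    z = model.encode(m.values)
    latent_ids = list(model.post_scale.feature_ids)
    raw = FeatureMatrix(list(m.row_ids), latent_ids, z, None)
    return minmax_apply(raw, model.post_scale)
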