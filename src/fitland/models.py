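"""Supervised sequence->fitness predictors and their ensembles.

Four architectures mirror four inductive biases about the landscape:

* :class:`LinearFitnessRegressor` -- one additive weight per (position,
  amino acid); cannot represent epistasis.
* :class:`DenseFitnessRegressor` -- fully connected network (FCN) on the
  flattened one-hot encoding; can capture nonlinear, epistatic effects.
* :class:`ConvFitnessRegressor` -- 1-D convolutions along the sequence (CNN);
  parameters are shared across positions.
* :class:`GraphConvFitnessRegressor` -- graph convolutions over a residue
  contact graph (GCN); shares parameters across structural neighborhoods.

All estimators follow the scikit-learn protocol (``fit``/``predict``,
``get_params``/``set_params``, fitted attributes with trailing underscores)
and accept either a list of equal-length sequences or a pre-encoded one-hot
array of shape ``(n, L, 20)`` / ``(n, L*20)``.

:class:`FitnessEnsemble` aggregates many independently initialized members:
``aggregation="median"`` is the average-case predictor (EnsM-style), while
``aggregation="percentile"`` with the default 5th percentile is the
conservative predictor (EnsC-style) -- 95% of members predict at least its
output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin, clone

from . import _nn
from .sequences import AMINO_ACIDS, encode_batch

N_AA = len(AMINO_ACIDS)


def _as_onehot(X, expected_L: int | None = None) -> np.ndarray:
    """Coerce sequences / arrays into a ``(n, L, 20)`` float64 tensor."""
    if isinstance(X, str):
        raise TypeError("pass a list of sequences, not a single string")
    if isinstance(X, (list, tuple)) or (
        isinstance(X, np.ndarray) and X.dtype.kind in "US"
    ):
        arr = encode_batch(list(X))
    else:
        arr = np.asarray(X, dtype=np.float64)
        if arr.ndim == 2:
            if arr.shape[1] % N_AA != 0:
                raise ValueError(
                    f"2-D input width {arr.shape[1]} is not a multiple of {N_AA}"
                )
            arr = arr.reshape(arr.shape[0], arr.shape[1] // N_AA, N_AA)
        elif arr.ndim != 3:
            raise ValueError("expected sequences or a 2-D/3-D numeric array")
    if expected_L is not None and arr.shape[1] != expected_L:
        raise ValueError(
            f"sequence length {arr.shape[1]} does not match model length {expected_L}"
        )
    return arr


@dataclass
class ContactGraph:
    """Symmetric residue adjacency with the distance threshold that built it."""

    adjacency: np.ndarray
    threshold_angstrom: float

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency diagonal must be zero")
        self.adjacency = a.astype(np.float64)

    @property
    def n_residues(self) -> int:
        return self.adjacency.shape[0]


def contact_graph(coords: np.ndarray, threshold_angstrom: float = 8.0) -> ContactGraph:
    """Build a residue contact graph from per-residue 3-D coordinates.

    Residues i != j are adjacent iff ``0 < ||c_i - c_j|| <= threshold``.
    The default 8 Angstrom threshold is a common alpha-carbon contact cutoff.
    """
    c = np.asarray(coords, dtype=np.float64)
    if c.ndim != 2 or c.shape[1] != 3:
        raise ValueError("coords must have shape (L, 3)")
    if not np.isfinite(c).all():
        raise ValueError("missing or non-finite coordinates")
    diff = c[:, None, :] - c[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=2))
    adj = ((dist > 0) & (dist <= threshold_angstrom)).astype(np.float64)
    np.fill_diagonal(adj, 0.0)
    return ContactGraph(adj, threshold_angstrom)


class _BaseFitnessRegressor(BaseEstimator, RegressorMixin):
    """Shared training harness: minibatch Adam on MSE with early stopping.

    Training records per-epoch train/validation loss in ``history_`` and the
    fitted network carries the weights from the best-validation epoch.
    """

    def __init__(
        self,
        learning_rate: float = 1e-3,
        max_epochs: int = 200,
        batch_size: int = 64,
        patience: int = 10,
        validation_fraction: float = 0.1,
        random_state: int = 0,
    ) -> None:
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.batch_size = batch_size
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    # -- architecture hook -------------------------------------------------
    def _make_layers(self, L: int, rng: np.random.Generator) -> list[_nn.Layer]:
        raise NotImplementedError

    def build(self, L: int) -> "_BaseFitnessRegressor":
        """Initialize the network for sequences of length ``L`` without training.

        Two builds with the same ``random_state`` are parameter-identical.
        """
        rng = np.random.default_rng(self.random_state)
        self.L_ = L
        self.net_ = _nn.Network(self._make_layers(L, rng))
        self.n_parameters_ = self.net_.n_params()
        return self

    def fit(self, X, y, X_val=None, y_val=None):
        Xa = _as_onehot(X)
        y = np.asarray(y, dtype=np.float64)
        if len(Xa) != len(y):
            raise ValueError("X and y lengths differ")
        if len(y) == 0:
            raise ValueError("empty training split")
        if not np.isfinite(y).all():
            raise ValueError("non-finite fitness targets")
        self.build(Xa.shape[1])
        rng = np.random.default_rng(self.random_state + 1)
        if X_val is None:
            n_val = max(1, int(round(self.validation_fraction * len(y)))) if len(y) > 4 else 0
            perm = rng.permutation(len(y))
            val_idx, train_idx = perm[:n_val], perm[n_val:]
            Xv, yv = Xa[val_idx], y[val_idx]
            Xt, yt = Xa[train_idx], y[train_idx]
        else:
            Xv = _as_onehot(X_val, self.L_)
            yv = np.asarray(y_val, dtype=np.float64)
            if len(Xv) != len(yv) or len(yv) == 0:
                raise ValueError("invalid validation split")
            if not np.isfinite(yv).all():
                raise ValueError("non-finite validation targets")
            Xt, yt = Xa, y
        if len(Xt) == 0:
            raise ValueError("empty training split after validation holdout")
        have_val = len(Xv) > 0

        history = []
        best_val = np.inf
        best_weights = self.net_.get_weights()
        best_epoch = 0
        since_best = 0
        n = len(Xt)
        bs = min(self.batch_size, n)
        for epoch in range(self.max_epochs):
            order = rng.permutation(n)
            for start in range(0, n, bs):
                idx = order[start : start + bs]
                self.net_.train_step(Xt[idx], yt[idx], self.learning_rate)
            train_loss = float(np.mean((self.net_.predict(Xt) - yt) ** 2))
            if have_val:
                val_loss = float(np.mean((self.net_.predict(Xv) - yv) ** 2))
            else:
                val_loss = train_loss
            history.append(
                {"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss}
            )
            if val_loss < best_val - 1e-12:
                best_val = val_loss
                best_weights = self.net_.get_weights()
                best_epoch = epoch
                since_best = 0
            else:
                since_best += 1
                if since_best > self.patience:
                    break
        self.net_.set_weights(best_weights)
        self.history_ = pd.DataFrame(history)
        self.best_epoch_ = best_epoch
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "net_"):
            raise RuntimeError("predictor is not built/fitted")
        Xa = _as_onehot(X, self.L_)
        out = self.net_.predict(Xa)
        if not np.isfinite(out).all():
            raise FloatingPointError("non-finite model output")
        return out


class LinearFitnessRegressor(_BaseFitnessRegressor):
    """Position-independent additive model: one weight per (position, aa).

    Predictions are exactly additive in the substitutions, so for any pair
    of single mutants the predicted double-mutant effect equals the sum of
    the single-mutant effects.
    """

    def _make_layers(self, L, rng):
        return [_nn.Flatten(), _nn.Dense(L * N_AA, 1, rng)]

    @property
    def coefficients_(self) -> np.ndarray:
        """Fitted weights reshaped to ``(L, 20)`` in alphabet order."""
        return self.net_.layers[1].w.reshape(self.L_, N_AA)


class DenseFitnessRegressor(_BaseFitnessRegressor):
    """Fully connected network (FCN) on the flattened one-hot encoding."""

    def __init__(
        self,
        hidden_layer_sizes: tuple[int, ...] = (100, 100),
        learning_rate: float = 1e-3,
        max_epochs: int = 200,
        batch_size: int = 64,
        patience: int = 10,
        validation_fraction: float = 0.1,
        random_state: int = 0,
    ) -> None:
        super().__init__(
            learning_rate, max_epochs, batch_size, patience,
            validation_fraction, random_state,
        )
        self.hidden_layer_sizes = hidden_layer_sizes

    def _make_layers(self, L, rng):
        layers: list[_nn.Layer] = [_nn.Flatten()]
        n_in = L * N_AA
        for width in self.hidden_layer_sizes:
            layers += [_nn.Dense(n_in, width, rng), _nn.ReLU()]
            n_in = width
        layers.append(_nn.Dense(n_in, 1, rng))
        return layers


class ConvFitnessRegressor(_BaseFitnessRegressor):
    """Sequence CNN: stacked 1-D convolutions plus a dense head.

    The convolution kernels are shared across sequence positions, so the
    convolutional feature maps are translation-equivariant (up to edges).
    """

    def __init__(
        self,
        n_filters: int = 32,
        kernel_size: int = 5,
        n_conv_layers: int = 2,
        dense_units: int = 64,
        learning_rate: float = 1e-3,
        max_epochs: int = 200,
        batch_size: int = 64,
        patience: int = 10,
        validation_fraction: float = 0.1,
        random_state: int = 0,
    ) -> None:
        super().__init__(
            learning_rate, max_epochs, batch_size, patience,
            validation_fraction, random_state,
        )
        self.n_filters = n_filters
        self.kernel_size = kernel_size
        self.n_conv_layers = n_conv_layers
        self.dense_units = dense_units

    def _make_layers(self, L, rng):
        layers: list[_nn.Layer] = []
        c_in = N_AA
        for _ in range(self.n_conv_layers):
            layers += [_nn.Conv1D(c_in, self.n_filters, self.kernel_size, rng), _nn.ReLU()]
            c_in = self.n_filters
        layers += [
            _nn.Flatten(),
            _nn.Dense(L * c_in, self.dense_units, rng),
            _nn.ReLU(),
            _nn.Dense(self.dense_units, 1, rng),
        ]
        return layers

    def feature_maps(self, X) -> np.ndarray:
        """Activations after the convolutional stack, shape ``(n, L, filters)``."""
        Xa = _as_onehot(X, self.L_)
        out = Xa
        for layer in self.net_.layers[: 2 * self.n_conv_layers]:
            out = layer.forward(out)
        return out


class GraphConvFitnessRegressor(_BaseFitnessRegressor):
    """Structure-aware GCN over a residue contact graph.

    Each graph-convolution layer mixes a residue's features with those of
    its structural neighbours through a fixed, symmetrically normalized
    propagator built from the contact adjacency.
    """

    def __init__(
        self,
        adjacency: np.ndarray | ContactGraph | None = None,
        channels: int = 32,
        n_gc_layers: int = 2,
        dense_units: int = 64,
        learning_rate: float = 1e-3,
        max_epochs: int = 200,
        batch_size: int = 64,
        patience: int = 10,
        validation_fraction: float = 0.1,
        random_state: int = 0,
    ) -> None:
        super().__init__(
            learning_rate, max_epochs, batch_size, patience,
            validation_fraction, random_state,
        )
        self.adjacency = adjacency
        self.channels = channels
        self.n_gc_layers = n_gc_layers
        self.dense_units = dense_units

    def _adjacency_matrix(self) -> np.ndarray:
        if self.adjacency is None:
            raise ValueError("GraphConvFitnessRegressor requires an adjacency")
        if isinstance(self.adjacency, ContactGraph):
            return self.adjacency.adjacency
        return np.asarray(self.adjacency, dtype=np.float64)

    def _make_layers(self, L, rng):
        adj = self._adjacency_matrix()
        if adj.shape != (L, L):
            raise ValueError(
                f"adjacency shape {adj.shape} does not match sequence length {L}"
            )
        a_hat = _nn.normalize_adjacency(adj)
        layers: list[_nn.Layer] = []
        c_in = N_AA
        for _ in range(self.n_gc_layers):
            layers += [_nn.GraphConv(a_hat, c_in, self.channels, rng), _nn.ReLU()]
            c_in = self.channels
        layers += [
            _nn.Flatten(),
            _nn.Dense(L * c_in, self.dense_units, rng),
            _nn.ReLU(),
            _nn.Dense(self.dense_units, 1, rng),
        ]
        return layers


class FitnessEnsemble(BaseEstimator, RegressorMixin):
    """Aggregate of independently initialized predictors.

    ``aggregation="median"`` returns the member-wise median prediction;
    ``aggregation="percentile"`` returns the ``percentile``-th percentile
    computed with the lower-interpolation convention on the sorted member
    outputs (frozen so the conservative predictor is an order statistic of
    actual member predictions).  The 5th percentile never exceeds the median.
    """

    def __init__(
        self,
        members: Sequence[_BaseFitnessRegressor] = (),
        aggregation: str = "median",
        percentile: float = 5.0,
    ) -> None:
        self.members = list(members)
        self.aggregation = aggregation
        self.percentile = percentile

    def _validate(self) -> None:
        if len(self.members) < 1:
            raise ValueError("ensemble needs at least one member")
        if self.aggregation not in ("median", "percentile"):
            raise ValueError(f"unknown aggregation {self.aggregation!r}")
        if not 0 < self.percentile < 100:
            raise ValueError("percentile must lie in (0, 100)")

    def fit(self, X, y, X_val=None, y_val=None):
        self._validate()
        for member in self.members:
            member.fit(X, y, X_val=X_val, y_val=y_val)
        return self

    def member_predictions(self, X) -> np.ndarray:
        """Stacked member outputs, shape ``(n_members, n_sequences)``."""
        self._validate()
        return np.vstack([m.predict(X) for m in self.members])

    def predict(self, X) -> np.ndarray:
        preds = self.member_predictions(X)
        if self.aggregation == "median":
            return np.median(preds, axis=0)
        return np.percentile(preds, self.percentile, axis=0, method="lower")


def make_ensemble(
    base_estimator: _BaseFitnessRegressor,
    n_members: int = 100,
    aggregation: str = "median",
    percentile: float = 5.0,
    base_seed: int = 0,
) -> FitnessEnsemble:
    """Clone ``base_estimator`` ``n_members`` times with distinct seeds.

    Members share architecture, hyperparameters and (when fitted on the same
    data) training data; only the initialization seed differs.
    """
    members = []
    for i in range(n_members):
        m = clone(base_estimator)
        m.set_params(random_state=base_seed + i)
        members.append(m)
    return FitnessEnsemble(members, aggregation=aggregation, percentile=percentile)


# ---------------------------------------------------------------------------
# Spec-style functional wrappers and checkpoints
# ---------------------------------------------------------------------------

ARCHITECTURES = {
    "linear": LinearFitnessRegressor,
    "fcn": DenseFitnessRegressor,
    "cnn": ConvFitnessRegressor,
    "gcn": GraphConvFitnessRegressor,
}


@dataclass
class PredictorSpec:
    """Declarative description of a predictor: architecture tag + knobs."""

    architecture: str
    seed: int = 0
    hyperparameters: dict = field(default_factory=dict)
    adjacency: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture tag {self.architecture!r}")
        if self.architecture == "gcn" and self.adjacency is None:
            raise ValueError("gcn spec requires an adjacency")


def build_model(spec: PredictorSpec) -> _BaseFitnessRegressor:
    """Instantiate an untrained predictor from a :class:`PredictorSpec`."""
    cls = ARCHITECTURES[spec.architecture]
    kwargs = dict(spec.hyperparameters)
    kwargs["random_state"] = spec.seed
    if spec.architecture == "gcn":
        kwargs["adjacency"] = spec.adjacency
    return cls(**kwargs)


def train(model: _BaseFitnessRegressor, dataset, **fit_kwargs):
    """Fit a predictor on a :class:`~fitland.landscape.FitnessDataset`.

    Uses the dataset's train split for optimization and its val split for
    early stopping.  Returns the fitted estimator.
    """
    train_df = dataset.split_frame("train")
    val_df = dataset.split_frame("val")
    model.fit(
        list(train_df["sequence"]),
        train_df["fitness"].to_numpy(),
        X_val=list(val_df["sequence"]) if len(val_df) else None,
        y_val=val_df["fitness"].to_numpy() if len(val_df) else None,
        **fit_kwargs,
    )
    return model


def predict(model, seqs) -> np.ndarray:
    return model.predict(seqs)


def ensemble_predict(ensemble: FitnessEnsemble, seqs) -> np.ndarray:
    return ensemble.predict(seqs)


def save_checkpoint(model: _BaseFitnessRegressor, path: str | Path) -> None:
    """Serialize a fitted predictor to a self-describing JSON container."""
    params = {}
    for key, value in model.get_params(deep=False).items():
        if isinstance(value, ContactGraph):
            value = value.adjacency
        if isinstance(value, np.ndarray):
            value = {"__ndarray__": value.tolist()}
        if isinstance(value, tuple):
            value = list(value)
        params[key] = value
    payload = {
        "class": type(model).__name__,
        "params": params,
        "L": int(model.L_),
        "weights": [w.tolist() for w in model.net_.get_weights()],
        "history": model.history_.to_dict(orient="list") if hasattr(model, "history_") else None,
    }
    Path(path).write_text(json.dumps(payload))


def load_checkpoint(path: str | Path) -> _BaseFitnessRegressor:
    payload = json.loads(Path(path).read_text())
    cls = {c.__name__: c for c in ARCHITECTURES.values()}[payload["class"]]
    params = {}
    for key, value in payload["params"].items():
        if isinstance(value, dict) and "__ndarray__" in value:
            value = np.asarray(value["__ndarray__"])
        if key == "hidden_layer_sizes" and isinstance(value, list):
            value = tuple(value)
        params[key] = value
    model = cls(**params)
    model.build(payload["L"])
    model.net_.set_weights([np.asarray(w) for w in payload["weights"]])
    if payload["history"] is not None:
        model.history_ = pd.DataFrame(payload["history"])
    return model
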