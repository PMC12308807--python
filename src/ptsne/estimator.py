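"""Parametric t-SNE: a neural-network embedder trained on the t-SNE loss.

Unlike classical t-SNE, which optimizes the low-dimensional coordinates of
the training samples directly, parametric t-SNE trains an explicit map
``f_w: R^m -> R^d`` (a small feedforward network) whose outputs minimize the
Kullback–Leibler divergence between feature-space Gaussian affinities P and
embedding-space Student-t affinities Q.  The trained network then embeds
*out-of-sample* points — the property that makes the method usable as a
collective-variable generator for molecular simulations, where new frames
arrive continuously.

Training is minibatched: P is calibrated independently within every batch
(a global n x n affinity matrix would be quadratic in the trajectory
length), and the network parameters are updated with Adam.  A held-out
validation split is embedded every epoch with its own per-batch P, and
training stops early once the validation loss stops improving.
"""

from __future__ import annotations

import json

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import affinity, divergence
from .network import ACTIVATIONS, MLP, Adam

__all__ = ["ParametricTSNE", "split_dataset", "save_model", "load_model"]

_FORMAT_VERSION = 1


def _check_X(X, name: str = "X") -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.ndim != 2:
        raise ValueError(f"{name} must be 2-D, got shape {X.shape}")
    if not np.isfinite(X).all():
        bad = int(np.flatnonzero(~np.isfinite(X).all(axis=1))[0])
        raise ValueError(f"non-finite values in {name} row {bad}")
    return X


def _rng_from(random_state) -> np.random.Generator:
    if isinstance(random_state, np.random.Generator):
        return random_state
    return np.random.default_rng(random_state)


def split_dataset(n_samples: int, val_fraction: float = 0.2,
                  random_state=None) -> tuple[np.ndarray, np.ndarray]:
    """Seeded shuffle split into training and validation index sets.

    The validation set holds ``round(val_fraction * n)`` samples; the two
    index sets are disjoint and together cover every sample.
    """
    if not 0.0 < val_fraction < 1.0:
        raise ValueError(f"val_fraction must be in (0, 1), got {val_fraction}")
    n_val = int(np.floor(val_fraction * n_samples + 0.5))
    if n_val == 0 or n_val == n_samples:
        raise ValueError(
            f"val_fraction={val_fraction} leaves an empty split at n={n_samples}"
        )
    perm = _rng_from(random_state).permutation(n_samples)
    return np.sort(perm[n_val:]), np.sort(perm[:n_val])


class ParametricTSNE(TransformerMixin, BaseEstimator):
    """Neural-network t-SNE embedder with out-of-sample transform.

    Parameters
    ----------
    n_components : int, default=2
        Dimensionality d of the embedding.
    hidden_fractions : tuple of float, default=(0.75, 0.75)
        Width of each hidden layer as a fraction of the input width;
        two hidden layers at 75% of the input size by default.  Widths are
        ``floor(fraction * n_features)``, minimum 1.
    activation : {'relu', 'tanh', 'identity'}, default='relu'
    perplexity : float, default=30.0
        Target effective neighbor count for the per-batch Gaussian
        affinity calibration; must be below ``batch_size - 1``.
    batch_size : int, default=1000
    max_epochs : int, default=500
        ``max_epochs=0`` returns the freshly initialized (untrained)
        network; ``transform`` still works.
    learning_rate : float, default=1e-3
        Adam step size (remaining Adam constants at their defaults).
    val_fraction : float, default=0.2
        Held-out fraction used for the early-stopping criterion.
    early_stop_delta : float, default=1e-6
        Convergence precision: training stops once successive validation
        losses differ by less than this for a full patience window.
    early_stop_patience : int, default=10
        Length of the flat window (in epochs) that declares convergence.
    alpha : float or None, default=None
        Student-t degrees of freedom; ``None`` means ``n_components``.
    exaggeration : float, default=1.0
        Optional multiplier applied to P during training (1 = off).
    standardize : bool, default=True
        Per-feature zero-mean/unit-variance scaling, statistics taken from
        the training split only.
    calibration_tol : float, default=1e-5
        Tolerance on the achieved per-row perplexity.
    check_invariants : bool, default=False
        Assert on every training batch that P and Q are unit-mass (1e-9)
        and symmetric; intended for test mode.
    random_state : int, Generator or None
        Seeds the split, the weight initialization and the epoch shuffles.

    Attributes
    ----------
    network_ : MLP
        The trained map f_w.
    loss_history_ : dict with keys 'train', 'val'
        Per-epoch mean KL losses (nats).
    train_idx_, val_idx_ : ndarray
        The split used during fit.
    mean_, scale_ : ndarray or None
        Standardization statistics (None when ``standardize=False``).
    n_epochs_ : int
        Epochs actually run (early stopping included).
    """

    def __init__(
        self,
        n_components: int = 2,
        hidden_fractions: tuple = (0.75, 0.75),
        activation: str = "relu",
        perplexity: float = 30.0,
        batch_size: int = 1000,
        max_epochs: int = 500,
        learning_rate: float = 1e-3,
        val_fraction: float = 0.2,
        early_stop_delta: float = 1e-6,
        early_stop_patience: int = 10,
        alpha: float | None = None,
        exaggeration: float = 1.0,
        standardize: bool = True,
        calibration_tol: float = 1e-5,
        check_invariants: bool = False,
        random_state=None,
    ):
        self.n_components = n_components
        self.hidden_fractions = hidden_fractions
        self.activation = activation
        self.perplexity = perplexity
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.learning_rate = learning_rate
        self.val_fraction = val_fraction
        self.early_stop_delta = early_stop_delta
        self.early_stop_patience = early_stop_patience
        self.alpha = alpha
        self.exaggeration = exaggeration
        self.standardize = standardize
        self.calibration_tol = calibration_tol
        self.check_invariants = check_invariants
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _validate_params_(self):
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2")
        if not self.perplexity < self.batch_size - 1:
            raise ValueError(
                f"perplexity ({self.perplexity}) must be below "
                f"batch_size - 1 ({self.batch_size - 1})"
            )
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.max_epochs < 0:
            raise ValueError("max_epochs must be >= 0")

    def _min_batch(self) -> int:
        return int(max(self.perplexity + 2, 16))

    def _batches(self, idx: np.ndarray) -> list[np.ndarray]:
        chunks = [idx[i:i + self.batch_size]
                  for i in range(0, len(idx), self.batch_size)]
        if len(chunks) > 1 and len(chunks[-1]) < self._min_batch():
            chunks = chunks[:-1]  # calibration ill-posed below the perplexity
        if len(chunks[0]) < self.perplexity + 2:
            raise ValueError(
                f"batch of {len(chunks[0])} samples cannot support "
                f"perplexity {self.perplexity}"
            )
        return chunks

    def _batch_P(self, Xb: np.ndarray) -> np.ndarray:
        P = affinity.joint_affinities(
            Xb, self.perplexity, tol=self.calibration_tol
        )
        if self.check_invariants:
            assert abs(P.sum() - 1.0) <= 1e-9, "P mass deviates from 1"
            assert np.abs(P - P.T).max() <= 1e-12, "P not symmetric"
        if self.exaggeration != 1.0:
            P = P * self.exaggeration
        return P

    def _epoch_loss(self, X: np.ndarray, batches, alpha: float,
                    train: bool, opt: Adam | None) -> float:
        total, count = 0.0, 0
        for idx in batches:
            Xb = X[idx]
            P = self._batch_P(Xb)
            Z = self.network_.forward(Xb, cache=train)
            Q = divergence.student_q_matrix(Z, alpha)
            if self.check_invariants:
                assert abs(Q.sum() - 1.0) <= 1e-9, "Q mass deviates from 1"
            loss = divergence.kl_divergence(P, Q)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite KL loss ({loss}) on a batch of {len(idx)} "
                    "samples; lower the learning rate or check the inputs"
                )
            if train:
                dZ = divergence.kl_gradient(P, Z, alpha)
                grads = self.network_.backward(dZ)
                opt.step(self.network_, grads)
            total += loss * len(idx)
            count += len(idx)
        return total / count

    # ------------------------------------------------------------------
    def fit(self, X, y=None):
        """Train the embedding network on ``X`` (ignores ``y``)."""
        self._validate_params_()
        X = _check_X(X)
        n, m = X.shape
        if n < 5:
            raise ValueError(f"need at least 5 samples to fit, got {n}")
        rng = _rng_from(self.random_state)

        train_idx, val_idx = split_dataset(n, self.val_fraction, rng)
        self.train_idx_, self.val_idx_ = train_idx, val_idx
        self.n_features_in_ = m

        if self.standardize:
            self.mean_ = X[train_idx].mean(axis=0)
            sd = X[train_idx].std(axis=0)
            sd[sd == 0.0] = 1.0
            self.scale_ = sd
            Xs = (X - self.mean_) / self.scale_
        else:
            self.mean_ = self.scale_ = None
            Xs = X

        hidden = [max(1, int(np.floor(f * m))) for f in self.hidden_fractions]
        self.network_ = MLP([m, *hidden, self.n_components],
                            self.activation, rng)
        self.alpha_ = float(self.alpha if self.alpha is not None
                            else self.n_components)
        self.loss_history_ = {"train": [], "val": []}
        self.n_epochs_ = 0
        if self.max_epochs == 0:
            return self

        if len(val_idx) < self.perplexity + 2:
            raise ValueError(
                f"validation split of {len(val_idx)} samples cannot support "
                f"perplexity {self.perplexity}"
            )
        opt = Adam(lr=self.learning_rate)
        prev_val = np.inf
        flat = 0
        for epoch in range(self.max_epochs):
            shuffled = train_idx[rng.permutation(len(train_idx))]
            tr_loss = self._epoch_loss(Xs, self._batches(shuffled),
                                       self.alpha_, train=True, opt=opt)
            val_loss = self._epoch_loss(Xs, self._batches(val_idx),
                                        self.alpha_, train=False, opt=None)
            self.loss_history_["train"].append(tr_loss)
            self.loss_history_["val"].append(val_loss)
            self.n_epochs_ = epoch + 1
            # converged once successive validation losses agree to within
            # early_stop_delta for a full patience window; a transiently
            # rising loss (embedding reorganization) is not convergence
            if abs(prev_val - val_loss) < self.early_stop_delta:
                flat += 1
                if flat >= self.early_stop_patience:
                    break
            else:
                flat = 0
            prev_val = val_loss
        return self

    def transform(self, X) -> np.ndarray:
        """Embed ``X`` with the trained network (deterministic, row-wise)."""
        check_is_fitted(self, "network_")
        X = _check_X(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, the fitted network expects "
                f"{self.n_features_in_}"
            )
        if self.mean_ is not None:
            X = (X - self.mean_) / self.scale_
        return self.network_.forward(X)

    # ------------------------------------------------------------------
    def save(self, path) -> None:
        """Persist weights, architecture, config and scaling to ``path`` (.npz)."""
        check_is_fitted(self, "network_")
        payload = self.network_.state()
        payload["format_version"] = np.asarray(_FORMAT_VERSION)
        params = self.get_params()
        if not isinstance(params["random_state"], (int, type(None))):
            params["random_state"] = None  # live Generators do not serialize
        payload["config_json"] = np.frombuffer(
            json.dumps(params).encode(), dtype=np.uint8
        )
        if self.mean_ is not None:
            payload["mean"] = self.mean_
            payload["scale"] = self.scale_
        np.savez(path, **payload)

    @classmethod
    def load(cls, path) -> "ParametricTSNE":
        """Restore an estimator saved with :meth:`save`."""
        with np.load(path) as data:
            if "format_version" not in data:
                raise ValueError(f"{path} is not a saved ParametricTSNE model")
            version = int(data["format_version"])
            if version != _FORMAT_VERSION:
                raise ValueError(
                    f"model format version {version} not supported "
                    f"(expected {_FORMAT_VERSION})"
                )
            params = json.loads(bytes(data["config_json"]).decode())
            params["hidden_fractions"] = tuple(params["hidden_fractions"])
            est = cls(**params)
            state = {k: data[k] for k in data.files}
        est.network_ = MLP.from_state(state, est.activation)
        est.n_features_in_ = est.network_.layer_dims[0]
        est.alpha_ = float(est.alpha if est.alpha is not None
                           else est.n_components)
        if "mean" in state:
            est.mean_ = np.asarray(state["mean"])
            est.scale_ = np.asarray(state["scale"])
        else:
            est.mean_ = est.scale_ = None
        return est


def save_model(estimator: ParametricTSNE, path) -> None:
    """Function-style alias for :meth:`ParametricTSNE.save`."""
    estimator.save(path)


def load_model(path) -> ParametricTSNE:
    """Function-style alias for :meth:`ParametricTSNE.load`."""
    return ParametricTSNE.load(path)
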