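"""Small stochastic softmax networks and leave-one-out evaluation.

Each classifier is a 3-layer perceptron (n_inputs : 3 hidden tanh units :
2 softmax outputs) trained full-batch on cross-entropy with Moller's
scaled conjugate gradient (SCG). The softmax outputs are interpreted as
Bayesian posterior probabilities of the two classes (tumor, healthy);
by construction they are non-negative and sum to one.

Stochasticity enters only through the seeded random weight initialization:
a fixed seed gives bit-identical training, different seeds give the
independent models that the ensemble-variance machinery needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .features import FeatureMatrix

TUMOR_VECTOR = (1, 0)  # one-hot convention: [1,0] tumor, [0,1] healthy
HEALTHY_VECTOR = (0, 1)

_SEED_MOD = 2**31 - 1

STANDARD_CONFIGS = {"FPHW": 9, "FP": 6, "HW": 3}


@dataclass
class NetworkConfig:
    """Architecture and training parameters of one network."""

    n_inputs: int
    n_hidden: int = 3
    n_outputs: int = 2
    max_epochs: int = 1000
    grad_tol: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_inputs < 1 or self.n_hidden < 1 or self.n_outputs != 2:
            raise ValidationError(
                "network must have >= 1 input, >= 1 hidden, exactly 2 outputs"
            )
        if self.max_epochs < 1:
            raise ValidationError("max_epochs must be >= 1")


@dataclass
class NetworkModel:
    """Trained weights plus the input scaling learned from training data."""

    config: NetworkConfig
    input_min: np.ndarray
    input_max: np.ndarray
    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    converged: bool
    final_loss: float


@dataclass
class LabeledFeatures:
    """A feature matrix plus one-hot class targets.

    targets[i] is [1,0] for tumor, [0,1] for healthy. ``gold_standard_source``
    records whether the labels came from histology or autonomous k-means.
    """

    features: FeatureMatrix
    targets: np.ndarray
    gold_standard_source: str = "kmeans"

    def __post_init__(self) -> None:
        self.targets = np.asarray(self.targets, dtype=float)
        if self.targets.shape != (self.features.n_targets, 2):
            raise ValidationError(
                f"targets must be (n_targets, 2); got {self.targets.shape}"
            )
        finite = np.isfinite(self.targets).all(axis=1)
        ok = ~finite | (
            (np.abs(self.targets.sum(axis=1) - 1.0) < 1e-12)
            & np.isin(self.targets, (0.0, 1.0)).all(axis=1)
        )
        if not ok.all():
            raise ValidationError("each labeled target must be one-hot [1,0] or [0,1]")

    @classmethod
    def from_labels(
        cls,
        features: FeatureMatrix,
        labels: Sequence[str],
        source: str = "kmeans",
    ) -> "LabeledFeatures":
        if len(labels) != features.n_targets:
            raise ValidationError("label count must match feature rows")
        t = np.array(
            [
                TUMOR_VECTOR if lab == "tumor" else HEALTHY_VECTOR
                for lab in labels
            ],
            dtype=float,
        )
        return cls(features, t, source)

    def class_labels(self) -> np.ndarray:
        return np.where(self.targets[:, 0] == 1.0, "tumor", "healthy")


def _scale_minmax(X: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    span = hi - lo
    out = np.zeros_like(X)
    nz = span > 0
    out[:, nz] = 2.0 * (X[:, nz] - lo[nz]) / span[nz] - 1.0
    return out


def _unpack(params: np.ndarray, ni: int, nh: int, no: int):
    i = 0
    W1 = params[i : i + ni * nh].reshape(ni, nh)
    i += ni * nh
    b1 = params[i : i + nh]
    i += nh
    W2 = params[i : i + nh * no].reshape(nh, no)
    i += nh * no
    b2 = params[i : i + no]
    return W1, b1, W2, b2


def _forward(X: np.ndarray, W1, b1, W2, b2):
    H = np.tanh(X @ W1 + b1)
    A = H @ W2 + b2
    A = A - A.max(axis=1, keepdims=True)
    E = np.exp(A)
    P = E / E.sum(axis=1, keepdims=True)
    return H, P


def _loss_grad(params, X, T, ni, nh, no):
    n = X.shape[0]
    W1, b1, W2, b2 = _unpack(params, ni, nh, no)
    H, P = _forward(X, W1, b1, W2, b2)
    eps = 1e-300
    loss = -np.sum(T * np.log(P + eps)) / n
    dA = (P - T) / n
    gW2 = H.T @ dA
    gb2 = dA.sum(axis=0)
    dH = (dA @ W2.T) * (1.0 - H * H)
    gW1 = X.T @ dH
    gb1 = dH.sum(axis=0)
    grad = np.concatenate([gW1.ravel(), gb1, gW2.ravel(), gb2])
    return loss, grad


def _scg_minimize(fun, x0, max_iter, grad_tol):
    """Moller's scaled conjugate gradient for batch network training.

    ``fun(x)`` returns (loss, gradient). Returns (x, loss, converged).
    """
    sigma0 = 1e-4
    lam = 1e-6
    lam_bar = 0.0
    x = x0.copy()
    f, g = fun(x)
    r = -g
    p = r.copy()
    success = True
    n_params = len(x)
    delta = 1.0
    converged = False
    for k in range(1, max_iter + 1):
        if np.max(np.abs(g)) < grad_tol or f < 1e-10:
            converged = True
            break
        p_norm2 = float(p @ p)
        if p_norm2 <= 0:
            converged = True
            break
        if success:
            sigma = sigma0 / np.sqrt(p_norm2)
            _, g_sigma = fun(x + sigma * p)
            s = (g_sigma - g) / sigma
            delta = float(p @ s)
        delta = delta + (lam - lam_bar) * p_norm2
        if delta <= 0:  # make the Hessian surrogate positive definite
            lam_bar = 2.0 * (lam - delta / p_norm2)
            delta = -delta + lam * p_norm2
            lam = lam_bar
        mu = float(p @ r)
        alpha = mu / delta
        f_new, g_new = fun(x + alpha * p)
        comparison = 2.0 * delta * (f - f_new) / (mu * mu)
        if comparison >= 0:
            x = x + alpha * p
            f_old_r = r
            f, g = f_new, g_new
            r_new = -g
            lam_bar = 0.0
            success = True
            if k % n_params == 0:
                p = r_new.copy()
            else:
                beta = float((r_new @ r_new - r_new @ f_old_r) / mu)
                p = r_new + beta * p
            r = r_new
            if comparison >= 0.75:
                lam = max(lam * 0.25, 1e-15)
        else:
            lam_bar = lam
            success = False
        if comparison < 0.25:
            lam = lam + delta * (1.0 - comparison) / p_norm2
        if lam > 1e100:  # numerically stuck; nothing further to gain
            break
    else:
        converged = np.max(np.abs(g)) < grad_tol
    return x, f, converged


def train_network(data: LabeledFeatures, config: NetworkConfig) -> NetworkModel:
    """Train one softmax network on all rows of ``data``.

    Features are min-max scaled to [-1, 1] using training-set statistics;
    weights start from a seeded small-magnitude uniform distribution, so
    training is stochastic across seeds and deterministic for a fixed seed.
    """
    X_raw = data.features.values
    T = data.targets
    if X_raw.shape[1] != config.n_inputs:
        raise ValidationError(
            f"feature width {X_raw.shape[1]} != n_inputs {config.n_inputs}"
        )
    classes = set(np.asarray(data.class_labels()))
    if len(classes) < 2:
        raise ValidationError("training set contains a single class")
    lo = X_raw.min(axis=0)
    hi = X_raw.max(axis=0)
    X = _scale_minmax(X_raw, lo, hi)
    ni, nh, no = config.n_inputs, config.n_hidden, config.n_outputs
    rng = np.random.default_rng(config.seed % _SEED_MOD)
    lim1 = np.sqrt(6.0 / (ni + nh))
    lim2 = np.sqrt(6.0 / (nh + no))
    x0 = np.concatenate(
        [
            rng.uniform(-lim1, lim1, ni * nh),
            np.zeros(nh),
            rng.uniform(-lim2, lim2, nh * no),
            np.zeros(no),
        ]
    )
    fun = lambda w: _loss_grad(w, X, T, ni, nh, no)
    w_opt, loss, converged = _scg_minimize(
        fun, x0, config.max_epochs, config.grad_tol
    )
    W1, b1, W2, b2 = _unpack(w_opt, ni, nh, no)
    return NetworkModel(
        config=config,
        input_min=lo,
        input_max=hi,
        W1=W1.copy(),
        b1=b1.copy(),
        W2=W2.copy(),
        b2=b2.copy(),
        converged=converged,
        final_loss=float(loss),
    )


def predict_proba(model: NetworkModel, features: Sequence[float]) -> tuple[float, float]:
    """(P_tumor, P_healthy) for one feature row; softmax, sums to 1."""
    x = np.asarray(features, dtype=float).reshape(1, -1)
    if x.shape[1] != model.config.n_inputs:
        raise ValidationError(
            f"feature length {x.shape[1]} != n_inputs {model.config.n_inputs}"
        )
    xs = _scale_minmax(x, model.input_min, model.input_max)
    _, P = _forward(xs, model.W1, model.b1, model.W2, model.b2)
    return float(P[0, 0]), float(P[0, 1])


def fold_seed(base_seed: int, cycle_index: int, fold_index: int) -> int:
    """Documented seed schedule: base*1e6 + cycle*1e3 + fold (mod 2^31-1)."""
    return (base_seed * 1_000_000 + cycle_index * 1_000 + fold_index) % _SEED_MOD


def loo_round_robin(
    data: LabeledFeatures,
    config: NetworkConfig,
    cycle_index: int = 0,
    train_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Leave-one-out round robin: each target scored by a net that never saw it.

    Fold i trains on every *training-eligible* row except i (all rows by
    default; ``train_mask`` restricts eligibility, e.g. to histology
    end-member quintiles) with weight-init seed ``fold_seed(config.seed,
    cycle_index, i)``, then predicts row i. Returns n P_tumor values in
    dataset order. There is no internal validation split.
    """
    n = data.features.n_targets
    if n < 3:
        raise ValidationError("leave-one-out requires at least 3 targets")
    if train_mask is None:
        train_mask = np.ones(n, dtype=bool)
    train_mask = np.asarray(train_mask, dtype=bool)
    if train_mask.shape != (n,):
        raise ValidationError("train_mask length must match target count")
    X = data.features.values
    probs = np.empty(n)
    for i in range(n):
        sel = train_mask.copy()
        sel[i] = False
        if sel.sum() < 2:
            raise ValidationError(f"fold {i}: fewer than 2 training targets remain")
        sub_features = FeatureMatrix(
            target_ids=[data.features.target_ids[j] for j in np.where(sel)[0]],
            feature_set=data.features.feature_set,
            values=X[sel],
            band_labels=data.features.band_labels,
            band_centers=data.features.band_centers,
        )
        sub = LabeledFeatures(
            sub_features, data.targets[sel], data.gold_standard_source
        )
        fold_cfg = NetworkConfig(
            n_inputs=config.n_inputs,
            n_hidden=config.n_hidden,
            n_outputs=config.n_outputs,
            max_epochs=config.max_epochs,
            grad_tol=config.grad_tol,
            seed=fold_seed(config.seed, cycle_index, i),
        )
        try:
            model = train_network(sub, fold_cfg)
        except ValidationError as exc:
            raise ValidationError(
                f"fold {i} (target {data.features.target_ids[i]}): {exc}"
            ) from exc
        probs[i] = predict_proba(model, X[i])[0]
    return probs
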