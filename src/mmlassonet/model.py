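"""LassoNet core: residual network, objective, hierarchical prox, path training.

The model class is the set of residual feed-forward networks

    f(x) = theta^T x + g_W(x)

where ``theta`` is an L1-penalised linear skip layer and ``g_W`` is a
one-hidden-layer ReLU network (width K, scalar output).  The objective is

    L(theta, W) + lambda_eff * ||theta||_1
    subject to  ||W^(1)_j||_inf <= M * |theta_j|   for every feature j,

with L the mean binary cross-entropy on sigmoid(f(x)).  The hierarchy
constraint ties each feature's first-layer weights to its skip weight, so a
feature participates in the nonlinear part only while its skip weight is
active; when the prox drives theta_j to exactly 0 the feature leaves the
network entirely.  ``lambda_eff = c * lambda`` where c is the structural
(DTI-derived) penalty multiplier; c = 1 recovers the standard LassoNet.

Training is proximal gradient descent on a regularisation path: a dense
(lambda = 0, unconstrained) warm start, then per penalty level B epochs of
full-batch gradient descent with momentum, each epoch followed by the
hierarchical prox.  Full-batch updates keep runs bit-reproducible and the
active-feature count non-increasing along the path.
"""

from __future__ import annotations

import copy
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from ._errors import InputError
from .metrics import MetricSet, compute_metrics, confusion, roc_auc

__all__ = [
    "NetworkParams",
    "PathConfig",
    "PathPoint",
    "init_params",
    "forward",
    "empirical_loss",
    "objective",
    "hier_prox",
    "train_dense",
    "fit_path",
    "fit_grid",
    "select_model",
    "predict",
    "DEFAULT_LAMBDA_GRID",
]

logger = logging.getLogger(__name__)

#: explicit penalty grid mirroring the lambda-in-(0.1, 1) selection protocol
DEFAULT_LAMBDA_GRID: tuple[float, ...] = tuple(round(0.1 * i, 1) for i in range(1, 11))


@dataclass
class NetworkParams:
    """theta: skip weights (d,); W1: first hidden layer (d, K); then b1, w2, b2."""

    theta: np.ndarray
    W1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: float

    @property
    def d(self) -> int:
        return self.theta.shape[0]

    @property
    def K(self) -> int:
        return self.W1.shape[1]

    def copy(self) -> "NetworkParams":
        return NetworkParams(
            theta=self.theta.copy(),
            W1=self.W1.copy(),
            b1=self.b1.copy(),
            w2=self.w2.copy(),
            b2=float(self.b2),
        )

    def k_active(self) -> int:
        """Number of features with a nonzero skip weight (exact zeros)."""
        return int(np.count_nonzero(self.theta))


@dataclass
class PathConfig:
    """Hyperparameters of the proximal training loop.

    M: hierarchy multiplier; epsilon: multiplicative path step (lambda grows
    by 1+epsilon); epochs_per_lambda: B full-batch epochs at each penalty
    level; learning_rate: alpha; lambda_start: initial penalty (None = found
    by bisection so that ~all features survive the first prox);
    dti_compound: literal compounding update lambda <- (1+eps)*lambda*c
    instead of the default fixed-multiplier lambda_eff = c*lambda;
    prox_stepsize_scaled: threshold = alpha*lambda_eff (standard proximal
    semantics) vs the unscaled lambda_eff.
    """

    M: float = 1.0
    epsilon: float = 0.02
    epochs_per_lambda: int = 100
    learning_rate: float = 1e-2
    lambda_start: float | None = None
    dti_compound: bool = False
    max_path_steps: int = 600
    seed: int = 0
    hidden_K: int = 32
    momentum: float = 0.9
    prox_stepsize_scaled: bool = True
    dense_epochs: int | None = None  # defaults to epochs_per_lambda

    def __post_init__(self) -> None:
        for name in ("M", "epsilon", "learning_rate"):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.lambda_start is not None and self.lambda_start <= 0:
            raise InputError(f"lambda_start must be > 0, got {self.lambda_start}")
        if self.epochs_per_lambda < 1 or self.max_path_steps < 1:
            raise InputError("epochs_per_lambda and max_path_steps must be >= 1")


@dataclass
class PathPoint:
    lambda_val: float
    params: NetworkParams
    k_active: int
    valid_metrics: MetricSet | None = None
    lambda_eff: float = field(default=0.0)


def init_params(d: int, K: int, rng: np.random.Generator) -> NetworkParams:
    """Small Gaussian initialisation, scaled by fan-in."""
    return NetworkParams(
        theta=rng.normal(0.0, 1.0 / np.sqrt(d), size=d),
        W1=rng.normal(0.0, np.sqrt(2.0 / d), size=(d, K)),
        b1=np.zeros(K),
        w2=rng.normal(0.0, np.sqrt(2.0 / K), size=K),
        b2=0.0,
    )


def forward(params: NetworkParams, X: np.ndarray) -> np.ndarray:
    """Scores theta^T x + g_W(x) per row of X."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != params.d:
        raise InputError(f"feature width {X.shape[1]} != d = {params.d}")
    h = np.maximum(X @ params.W1 + params.b1, 0.0)
    return X @ params.theta + h @ params.w2 + params.b2


def empirical_loss(params: NetworkParams, X: np.ndarray, y: np.ndarray) -> float:
    """Mean binary cross-entropy of sigmoid(score) against 0/1 labels."""
    y = np.asarray(y, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise InputError("labels must be binary 0/1")
    s = forward(params, X)
    # log(1 + e^s) - y*s, numerically stable
    return float(np.mean(np.logaddexp(0.0, s) - y * s))


def objective(
    params: NetworkParams, X: np.ndarray, y: np.ndarray, lambda_eff: float
) -> float:
    """Penalised objective L + lambda_eff * ||theta||_1.

    The hierarchy constraint is not part of the value; it is enforced by the
    prox, so any post-prox iterate is feasible by construction.
    """
    if lambda_eff < 0:
        raise InputError(f"lambda_eff must be >= 0, got {lambda_eff}")
    return empirical_loss(params, X, y) + lambda_eff * float(np.abs(params.theta).sum())


def _gradients(params: NetworkParams, X: np.ndarray, y: np.ndarray):
    n = X.shape[0]
    z = X @ params.W1 + params.b1
    h = np.maximum(z, 0.0)
    s = X @ params.theta + h @ params.w2 + params.b2
    p = 1.0 / (1.0 + np.exp(-s))
    g = (p - y) / n
    dz = np.outer(g, params.w2) * (z > 0)
    return (
        X.T @ g,            # dtheta
        X.T @ dz,           # dW1
        dz.sum(axis=0),     # db1
        h.T @ g,            # dw2
        g.sum(),            # db2
    )


def hier_prox(
    theta_in: np.ndarray,
    W1_in: np.ndarray,
    threshold: float,
    M: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Hierarchical proximal operator, applied per feature.

    For each feature j this returns the exact minimiser of

        1/2 (theta - theta_in_j)^2 + 1/2 ||W - W1_in_j||^2 + threshold*|theta|
        subject to ||W||_inf <= M * |theta|

    via the closed form: sort |W1_in_j| descending, compute for n = 0..K

        w_n = M/(1 + n M^2) * SoftThreshold_threshold(|theta_j| + M * S_n)

    (S_n = sum of the n largest |W| entries) and keep the first n* whose w
    falls between the (n*+1)-th and n*-th sorted magnitudes (sentinels +inf
    and 0).  Then theta_out = sign(theta) * w_* / M and W entries are
    clipped to magnitude w_*.  Vectorised over features.  A zero theta uses
    sign +1 so that theta_out = 0 implies W1_out = 0 exactly.
    """
    if M <= 0:
        raise InputError(f"M must be > 0, got {M}")
    if threshold < 0:
        raise InputError(f"threshold must be >= 0, got {threshold}")
    theta = np.atleast_1d(np.asarray(theta_in, dtype=float))
    W1 = np.atleast_2d(np.asarray(W1_in, dtype=float))
    d, K = W1.shape
    if theta.shape[0] != d:
        raise InputError(f"theta length {theta.shape[0]} != W1 rows {d}")

    absW = np.abs(W1)
    W_sorted = -np.sort(-absW, axis=1, kind="stable")  # descending
    S = np.concatenate([np.zeros((d, 1)), np.cumsum(W_sorted, axis=1)], axis=1)
    u = np.maximum(np.abs(theta)[:, None] + M * S - threshold, 0.0)
    n_range = np.arange(K + 1)
    w = (M / (1.0 + n_range * M * M))[None, :] * u  # (d, K+1)

    padded = np.concatenate(
        [np.full((d, 1), np.inf), W_sorted, np.zeros((d, 1))], axis=1
    )  # (d, K+2)
    cond = (padded[:, 1:] <= w) & (w <= padded[:, :-1])
    # the first satisfying n always exists; guard against fp pathologies
    has = cond.any(axis=1)
    n_star = np.where(has, np.argmax(cond, axis=1), K)
    w_star = w[np.arange(d), n_star]

    sgn_theta = np.where(theta >= 0.0, 1.0, -1.0)
    theta_out = sgn_theta * w_star / M
    W1_out = np.sign(W1) * np.minimum(w_star[:, None], absW)
    return theta_out, W1_out


def _epoch(params, X, y, vel, lr, mu):
    """One full-batch momentum step in place; vel is the velocity dict."""
    dth, dW1, db1, dw2, db2 = _gradients(params, X, y)
    vel["theta"] = mu * vel["theta"] - lr * dth
    vel["W1"] = mu * vel["W1"] - lr * dW1
    vel["b1"] = mu * vel["b1"] - lr * db1
    vel["w2"] = mu * vel["w2"] - lr * dw2
    vel["b2"] = mu * vel["b2"] - lr * db2
    params.theta = params.theta + vel["theta"]
    params.W1 = params.W1 + vel["W1"]
    params.b1 = params.b1 + vel["b1"]
    params.w2 = params.w2 + vel["w2"]
    params.b2 = params.b2 + vel["b2"]


def _new_velocity(params: NetworkParams) -> dict:
    return {
        "theta": np.zeros_like(params.theta),
        "W1": np.zeros_like(params.W1),
        "b1": np.zeros_like(params.b1),
        "w2": np.zeros_like(params.w2),
        "b2": 0.0,
    }


def train_dense(
    X: np.ndarray,
    y: np.ndarray,
    config: PathConfig,
    rng: np.random.Generator,
    init: NetworkParams | None = None,
) -> NetworkParams:
    """Unpenalised, unconstrained warm start (lambda = 0) for the path."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    params = init.copy() if init is not None else init_params(X.shape[1], config.hidden_K, rng)
    vel = _new_velocity(params)
    epochs = config.dense_epochs if config.dense_epochs is not None else config.epochs_per_lambda
    for _ in range(epochs):
        _epoch(params, X, y, vel, config.learning_rate, config.momentum)
    return params


def _prox_threshold(config: PathConfig, lambda_eff: float) -> float:
    return config.learning_rate * lambda_eff if config.prox_stepsize_scaled else lambda_eff


def _auto_lambda_start(
    params: NetworkParams,
    X: np.ndarray,
    y: np.ndarray,
    config: PathConfig,
    dti_scalar: float,
) -> float:
    """Largest lambda at which the model stays (almost) dense.

    Bisection on a short prox-gradient probe from the warm start: a single
    prox application is far weaker than the iterated prox (whose repeated
    clipping cascades), so the probe runs a few epochs of the actual
    training step.  Starting the path here makes the first recorded point
    still dense and the multiplicative schedule sweeps dense -> empty.
    """
    d = params.d
    target = max(1, int(0.98 * d))
    probe_epochs = min(10, config.epochs_per_lambda)

    def k_at(lam: float) -> int:
        p = params.copy()
        vel = _new_velocity(p)
        thr = _prox_threshold(config, dti_scalar * lam)
        for _ in range(probe_epochs):
            _epoch(p, X, y, vel, config.learning_rate, config.momentum)
            p.theta, p.W1 = hier_prox(p.theta, p.W1, thr, config.M)
        return p.k_active()

    lo, hi = 1e-8, 1e-6
    while k_at(hi) >= target and hi < 1e8:
        lo, hi = hi, hi * 4.0
    for _ in range(30):
        mid = np.sqrt(lo * hi)  # bisect on the log scale
        if k_at(mid) >= target:
            lo = mid
        else:
            hi = mid
    return lo


def _evaluate_split(params: NetworkParams, X, y) -> MetricSet:
    labels, probs = predict(params, X)
    counts = confusion(y, labels)
    auc = None
    if len(np.unique(y)) == 2:
        _, auc = roc_auc(y, probs)
    return compute_metrics(counts, auc=auc)


def fit_path(
    train: tuple[np.ndarray, np.ndarray],
    valid: tuple[np.ndarray, np.ndarray],
    config: PathConfig,
    dti_scalar: float = 1.0,
    init: NetworkParams | None = None,
    prox_callback=None,
) -> list[PathPoint]:
    """Fit the full regularisation path, dense to empty.

    Each path step runs B epochs of (gradient step, then hier_prox at
    threshold alpha * lambda_eff), records a PathPoint with validation
    metrics, and increases lambda by the factor (1 + epsilon); the loop
    exits when no feature is active.  ``prox_callback(theta, W1)`` — if
    given — is invoked after every prox application (used by invariant
    checks).
    """
    Xtr, ytr = np.asarray(train[0], float), np.asarray(train[1], float)
    Xva, yva = np.asarray(valid[0], float), np.asarray(valid[1], float)
    rng = np.random.default_rng(config.seed)
    params = train_dense(Xtr, ytr, config, rng, init=init)

    lam = config.lambda_start
    if lam is None:
        lam = _auto_lambda_start(params, Xtr, ytr, config, dti_scalar)

    path: list[PathPoint] = []
    for step in range(config.max_path_steps):
        if config.dti_compound:
            # literal compounding update: lambda <- (1+eps) * lambda * c
            lam = (1.0 + config.epsilon) * lam * dti_scalar if step > 0 else lam
            lambda_eff = lam
        else:
            lambda_eff = dti_scalar * lam
        thr = _prox_threshold(config, lambda_eff)
        vel = _new_velocity(params)
        for _ in range(config.epochs_per_lambda):
            _epoch(params, Xtr, ytr, vel, config.learning_rate, config.momentum)
            params.theta, params.W1 = hier_prox(params.theta, params.W1, thr, config.M)
            if prox_callback is not None:
                prox_callback(params.theta, params.W1)
        k = params.k_active()
        path.append(
            PathPoint(
                lambda_val=lam,
                params=params.copy(),
                k_active=k,
                valid_metrics=_evaluate_split(params, Xva, yva),
                lambda_eff=lambda_eff,
            )
        )
        if k == 0:
            break
        if not config.dti_compound:
            lam = (1.0 + config.epsilon) * lam
    else:
        warnings.warn(
            f"regularisation path did not reach k_active = 0 within "
            f"{config.max_path_steps} steps; returning the partial path"
        )
        logger.warning("path truncated at max_path_steps=%d", config.max_path_steps)
    return path


def fit_grid(
    train: tuple[np.ndarray, np.ndarray],
    valid: tuple[np.ndarray, np.ndarray],
    config: PathConfig,
    dti_scalar: float = 1.0,
    lambdas: tuple[float, ...] = DEFAULT_LAMBDA_GRID,
    init: NetworkParams | None = None,
) -> list[PathPoint]:
    """Fit one model per penalty level on an explicit grid.

    Every grid point warm-starts from the same dense solution, so points
    are independent of each other and the grid mirrors selecting lambda on
    a fixed interval by validation accuracy.
    """
    Xtr, ytr = np.asarray(train[0], float), np.asarray(train[1], float)
    Xva, yva = np.asarray(valid[0], float), np.asarray(valid[1], float)
    rng = np.random.default_rng(config.seed)
    dense = train_dense(Xtr, ytr, config, rng, init=init)

    points: list[PathPoint] = []
    for lam in lambdas:
        lambda_eff = dti_scalar * lam
        thr = _prox_threshold(config, lambda_eff)
        params = dense.copy()
        vel = _new_velocity(params)
        for _ in range(config.epochs_per_lambda):
            _epoch(params, Xtr, ytr, vel, config.learning_rate, config.momentum)
            params.theta, params.W1 = hier_prox(params.theta, params.W1, thr, config.M)
        points.append(
            PathPoint(
                lambda_val=float(lam),
                params=params,
                k_active=params.k_active(),
                valid_metrics=_evaluate_split(params, Xva, yva),
                lambda_eff=lambda_eff,
            )
        )
    return points


def select_model(path: list[PathPoint]) -> PathPoint:
    """Validation-accuracy argmax; ties resolved toward smaller lambda."""
    if not path:
        raise InputError("select_model needs a non-empty path")
    if any(p.valid_metrics is None for p in path):
        raise InputError("select_model needs validation metrics on every point")
    best = None
    for p in path:
        if best is None or p.valid_metrics.acc > best.valid_metrics.acc or (
            p.valid_metrics.acc == best.valid_metrics.acc
            and p.lambda_val < best.lambda_val
        ):
            best = p
    return best


def predict(
    params: NetworkParams, X: np.ndarray, threshold: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Class probabilities sigmoid(score) and labels (prob >= threshold)."""
    s = forward(params, X)
    probs = 1.0 / (1.0 + np.exp(-s))
    return (probs >= threshold).astype(int), probs
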