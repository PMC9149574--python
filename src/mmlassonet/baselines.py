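"""Lasso-family comparison selectors, SVM classification, and the
repeated-comparison harness.

The four linear selectors minimise squared-error objectives on labels coded
as +1/-1 (standard lasso-screening practice for a classification target):

* lasso:              (1/n) ||y - XW||_2^2 + lam ||W||_1
* group lasso:        ||y - sum_l X_l W_l||_2^2 + lam sum_l sqrt(p_l) ||W_l||_2
* sparse group lasso: ||y - sum_l X_l W_l||_2^2 + lam1 sum_l ||W_l||_2 + lam2 ||W||_1
* elastic net:        ||y - XW||_2^2 + lam2 ||W||_2^2 + lam1 ||W||_1

Lasso and elastic net delegate to scikit-learn's coordinate-descent solvers
with an objective-scale mapping; no installed package provides the group
variants, so those use a FISTA (accelerated proximal gradient) solver with
exact block/soft-threshold proximal maps.  Selected features then feed a
linear-kernel SVM, and ``run_comparison`` produces a per-method mean +/- SD
metric table over repeated runs on one fixed train/valid/test split.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import ElasticNet as _SkElasticNet
from sklearn.linear_model import Lasso as _SkLasso
from sklearn.svm import SVC

from ._errors import InputError
from .metrics import MetricSet, compute_metrics, confusion, roc_auc
from .model import DEFAULT_LAMBDA_GRID as _DEFAULT_GRID

__all__ = [
    "LinearSelector",
    "fit_lasso",
    "fit_group_lasso",
    "fit_sparse_group_lasso",
    "fit_elastic_net",
    "select_features",
    "svm_classify",
    "run_comparison",
    "ComparisonReport",
    "roi_groups",
    "DEFAULT_HYPER_GRID",
]

logger = logging.getLogger(__name__)

#: hyperparameter grid searched on the validation split
DEFAULT_HYPER_GRID: tuple[float, ...] = (0.01, 0.05, 0.1, 0.2, 0.5, 1.0)


@dataclass
class LinearSelector:
    weights: np.ndarray
    method: str
    hyperparams: dict
    groups: list[np.ndarray] | None = None


def _as_xy(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise InputError(f"X has {X.shape[0]} rows but y has {y.shape[0]}")
    return X, y


def _check_groups(groups, d: int) -> list[np.ndarray]:
    if groups is None or len(groups) == 0:
        raise InputError("group methods need a non-empty group partition")
    cover = np.concatenate([np.asarray(g, dtype=int) for g in groups])
    if sorted(cover.tolist()) != list(range(d)):
        raise InputError("groups must partition feature indices 0..d-1")
    return [np.asarray(g, dtype=int) for g in groups]


def roi_groups(T: int, R: int) -> list[np.ndarray]:
    """One group per ROI under ROI-major flattening (R groups of T features)."""
    return [np.arange(r * T, (r + 1) * T) for r in range(R)]


def fit_lasso(X, y, lam: float, tol: float = 1e-10) -> LinearSelector:
    """Minimise (1/n)||y - XW||^2 + lam*||W||_1 (no intercept).

    scikit-learn's Lasso minimises (1/(2n))||y - Xw||^2 + a||w||_1, so
    a = lam/2 gives the same minimiser.  lam = 0 falls back to least
    squares.
    """
    X, y = _as_xy(X, y)
    if lam < 0:
        raise InputError(f"lam must be >= 0, got {lam}")
    if lam == 0:
        w = np.linalg.lstsq(X, y, rcond=None)[0]
    else:
        est = _SkLasso(alpha=lam / 2.0, fit_intercept=False, max_iter=100000, tol=tol)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(X, y)
        w = est.coef_.copy()
    return LinearSelector(weights=w, method="lasso", hyperparams={"lam": lam})


def fit_elastic_net(
    X, y, lam1: float, lam2: float, tol: float = 1e-10, max_iter: int = 100000
) -> LinearSelector:
    """Minimise ||y - XW||^2 + lam2*||W||_2^2 + lam1*||W||_1.

    Mapped onto scikit-learn's ElasticNet parametrisation
    (1/(2n))||y - Xw||^2 + a*r*||w||_1 + a*(1-r)/2*||w||_2^2 via
    a*r = lam1/(2n), a*(1-r) = lam2/n.  lam1 = lam2 = 0 is plain least
    squares; lam1 = 0 uses the ridge closed form.
    """
    X, y = _as_xy(X, y)
    if lam1 < 0 or lam2 < 0:
        raise InputError(f"lam1/lam2 must be >= 0, got {lam1}, {lam2}")
    n, d = X.shape
    if lam1 == 0 and lam2 == 0:
        w = np.linalg.lstsq(X, y, rcond=None)[0]
    elif lam1 == 0:
        w = np.linalg.solve(X.T @ X + lam2 * np.eye(d), X.T @ y)
    else:
        a = lam1 / (2.0 * n) + lam2 / n
        r = (lam1 / (2.0 * n)) / a
        est = _SkElasticNet(
            alpha=a, l1_ratio=r, fit_intercept=False, max_iter=max_iter, tol=tol
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(X, y)
        w = est.coef_.copy()
    return LinearSelector(
        weights=w, method="elastic_net", hyperparams={"lam1": lam1, "lam2": lam2}
    )


def _fista(X, y, prox, n_iter: int = 20000, tol: float = 1e-12) -> np.ndarray:
    """FISTA on ||y - Xw||^2 + penalty, with ``prox(v, step)`` the penalty prox.

    The gradient is evaluated as 2 X^T (Xw - y), which costs O(nd) per
    iteration and stays cheap in the d >> n regime these selectors face.
    """
    n, d = X.shape
    # Lipschitz constant of the gradient 2 X^T(Xw - y)
    L = 2.0 * np.linalg.norm(X, ord=2) ** 2
    step = 1.0 / max(L, 1e-12)
    w = np.zeros(d)
    z = w.copy()
    t = 1.0
    prev_obj = np.inf
    for it in range(n_iter):
        grad = 2.0 * (X.T @ (X @ z - y))
        w_new = prox(z - step * grad, step)
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        z = w_new + ((t - 1.0) / t_new) * (w_new - w)
        w, t = w_new, t_new
        if it % 25 == 0:
            r = y - X @ w
            obj = float(r @ r)
            if abs(prev_obj - obj) < tol * max(1.0, abs(obj)):
                break
            prev_obj = obj
    return w


def _block_soft_threshold_factory(groups):
    """Return ``block(v, thresholds)`` applying the group soft-threshold.

    Uses a vectorised reduceat path when the groups are contiguous and in
    order (the ROI-major layout); falls back to a per-group loop otherwise.
    """
    d = sum(len(g) for g in groups)
    starts = []
    pos = 0
    contiguous = True
    for g in groups:
        g = np.asarray(g)
        if not np.array_equal(g, np.arange(pos, pos + len(g))):
            contiguous = False
            break
        starts.append(pos)
        pos += len(g)
    if contiguous:
        starts = np.array(starts, dtype=int)
        sizes = np.array([len(g) for g in groups], dtype=int)

        def block(v, thr):
            nrm = np.sqrt(np.add.reduceat(v * v, starts))
            scale = np.where(nrm > thr, 1.0 - thr / np.maximum(nrm, 1e-300), 0.0)
            return v * np.repeat(scale, sizes)

        return block

    def block(v, thr):
        out = v.copy()
        for g, t in zip(groups, np.broadcast_to(thr, (len(groups),))):
            nrm = np.linalg.norm(v[g])
            out[g] = 0.0 if nrm <= t else (1.0 - t / nrm) * v[g]
        return out

    return block


def fit_group_lasso(X, y, groups, lam: float) -> LinearSelector:
    """Minimise ||y - XW||^2 + lam * sum_l sqrt(p_l) * ||W_l||_2.

    The sqrt(p_l) weighting makes the penalty comparable across unequal
    group sizes; within a group, coefficients are jointly zero or jointly
    active (block soft-threshold prox).
    """
    X, y = _as_xy(X, y)
    if lam < 0:
        raise InputError(f"lam must be >= 0, got {lam}")
    groups = _check_groups(groups, X.shape[1])
    weights_l = np.array([np.sqrt(len(g)) for g in groups])
    block = _block_soft_threshold_factory(groups)

    def prox(v, step):
        return block(v, step * lam * weights_l)

    w = np.linalg.lstsq(X, y, rcond=None)[0] if lam == 0 else _fista(X, y, prox)
    return LinearSelector(
        weights=w, method="group_lasso", hyperparams={"lam": lam}, groups=groups
    )


def fit_sparse_group_lasso(X, y, groups, lam1: float, lam2: float) -> LinearSelector:
    """Minimise ||y - XW||^2 + lam1 * sum_l ||W_l||_2 + lam2 * ||W||_1.

    Prox = coordinate soft-threshold (L1) followed by block soft-threshold
    (unweighted group norm), the exact proximal map of the compound penalty.
    """
    X, y = _as_xy(X, y)
    if lam1 < 0 or lam2 < 0:
        raise InputError(f"lam1/lam2 must be >= 0, got {lam1}, {lam2}")
    groups = _check_groups(groups, X.shape[1])
    block = _block_soft_threshold_factory(groups)
    thr1 = np.full(len(groups), lam1)

    def prox(v, step):
        u = np.sign(v) * np.maximum(np.abs(v) - step * lam2, 0.0)
        return block(u, step * thr1)

    if lam1 == 0 and lam2 == 0:
        w = np.linalg.lstsq(X, y, rcond=None)[0]
    else:
        w = _fista(X, y, prox)
    return LinearSelector(
        weights=w,
        method="sparse_group_lasso",
        hyperparams={"lam1": lam1, "lam2": lam2},
        groups=groups,
    )


def select_features(selector: LinearSelector, tol: float = 1e-8) -> np.ndarray:
    """Indices with |W_j| > tol, in increasing order."""
    return np.flatnonzero(np.abs(selector.weights) > tol)


def svm_classify(
    X_train_selected, y_train, X_eval_selected, C: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Linear-kernel SVM on the selected features.

    Returns predicted 0/1 labels and signed decision scores for the
    evaluation rows.  An empty feature set falls back to the majority
    training class (constant scores), with a warning.
    """
    Xtr = np.asarray(X_train_selected, dtype=float)
    ytr = np.asarray(y_train).astype(int)
    Xev = np.asarray(X_eval_selected, dtype=float)
    if Xtr.ndim != 2 or Xtr.shape[1] == 0:
        warnings.warn("empty feature set: falling back to majority-class prediction")
        maj = int(np.bincount(ytr).argmax())
        n = Xev.shape[0] if Xev.ndim == 2 else len(Xev)
        score = 1.0 if maj == 1 else -1.0
        return np.full(n, maj, dtype=int), np.full(n, score)
    if len(np.unique(ytr)) < 2:
        raise InputError("svm_classify needs both classes in the training labels")
    clf = SVC(kernel="linear", C=C)
    clf.fit(Xtr, ytr)
    return clf.predict(Xev).astype(int), clf.decision_function(Xev)


@dataclass
class ComparisonReport:
    """Per-method mean +/- SD of ACC/SEN/SPE/GMean/F1 over repeats, plus ROC."""

    methods: list[str]
    mean: dict[str, MetricSet]
    sd: dict[str, MetricSet]
    roc: dict[str, np.ndarray] = field(default_factory=dict)
    per_repeat: dict[str, list[MetricSet]] = field(default_factory=dict)

    def to_table(self) -> "object":
        """Rows method x columns 'ACC (%) +/- SD' ... as a pandas DataFrame."""
        import pandas as pd

        rows = {}
        for m in self.methods:
            mu = self.mean[m].as_percent_dict()
            sd = self.sd[m].as_percent_dict()
            rows[m] = {
                f"{k} (%) ± SD": f"{mu[k]:.2f} ± {sd[k]:.2f}"
                for k in ("ACC", "SEN", "SPE", "GMean", "F1")
            }
        return pd.DataFrame.from_dict(rows, orient="index")


def _aggregate(metric_sets: list[MetricSet]) -> tuple[MetricSet, MetricSet]:
    arr = np.array(
        [[m.acc, m.sen, m.spe, m.gmean, m.f1] for m in metric_sets], dtype=float
    )
    aucs = [m.auc for m in metric_sets if m.auc is not None]
    mu = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=0)
    mean = MetricSet(*mu, auc=float(np.mean(aucs)) if aucs else None)
    sdm = MetricSet(*sd, auc=float(np.std(aucs)) if aucs else None)
    return mean, sdm


def _fit_selector_method(method, Xtr, ytr, Xva, yva, groups, grid):
    """Select hyperparameters on the validation split by accuracy (ties ->
    sparsest model), return the refit selector."""
    ypm = 2.0 * ytr - 1.0  # +/-1 coding for the squared-error selectors
    best = None
    candidates = []
    if method == "lasso":
        candidates = [{"lam": l} for l in grid]
    elif method == "group_lasso":
        candidates = [{"lam": l} for l in grid]
    elif method in ("sparse_group_lasso", "elastic_net"):
        candidates = [{"lam1": l1, "lam2": l2} for l1 in grid for l2 in grid]
    else:
        raise InputError(f"unknown selector method {method!r}")

    # harness fits use a looser solver tolerance than the unit-level default:
    # feature selection is insensitive to coefficient error below ~1e-4
    for hp in candidates:
        if method == "lasso":
            sel = fit_lasso(Xtr, ypm, hp["lam"], tol=1e-7)
        elif method == "group_lasso":
            sel = fit_group_lasso(Xtr, ypm, groups, hp["lam"])
        elif method == "sparse_group_lasso":
            sel = fit_sparse_group_lasso(Xtr, ypm, groups, hp["lam1"], hp["lam2"])
        else:
            sel = fit_elastic_net(Xtr, ypm, hp["lam1"], hp["lam2"], tol=1e-7, max_iter=5000)
        feats = select_features(sel)
        if feats.size == 0:
            acc = 0.0
        else:
            pred, _ = svm_classify(Xtr[:, feats], ytr, Xva[:, feats])
            acc = float(np.mean(pred == yva))
        k = feats.size
        if best is None or acc > best[0] or (acc == best[0] and k < best[1]):
            best = (acc, k, sel)
    return best[2]


def run_comparison(
    dataset,
    methods: list[str],
    repeats: int = 10,
    seed: int = 0,
    split_seed: int | None = None,
    path_config=None,
    lambdas=None,
) -> ComparisonReport:
    """Repeated evaluation of selectors + SVM and the multi-modal LassoNet.

    One fixed, stratified 6:2:2 subject split (derived from ``split_seed``,
    default ``seed``) is reused across methods and repeats; per repeat only
    training randomness (network initialisation) varies, so the
    deterministic lasso-family pipelines have zero SD by construction.
    Hyperparameters are chosen once per method on the validation split.
    ``methods`` may contain: lasso, grouplasso, sgl, enet, mmlassonet,
    lassonet (the c = 1 ablation).
    """
    from .io import SplitSpec, split_dataset
    from .pipeline import fit_multimodal

    if repeats < 1:
        raise InputError("repeats must be >= 1")
    labels = dataset.labels
    if len(np.unique(labels)) < 2:
        raise InputError("run_comparison needs both classes in the dataset")

    spec = SplitSpec(seed=seed if split_seed is None else split_seed)
    train, valid, test = split_dataset(dataset, spec)
    Xtr, ytr = train.features(), train.labels
    Xva, yva = valid.features(), valid.labels
    Xte, yte = test.features(), test.labels

    # z-score on the training split; reused for valid/test
    mu, sdv = Xtr.mean(axis=0), Xtr.std(axis=0)
    sdv[sdv == 0] = 1.0
    Xtr = (Xtr - mu) / sdv
    Xva = (Xva - mu) / sdv
    Xte = (Xte - mu) / sdv

    T = train.samples[0].timeseries.shape[0]
    R = train.samples[0].timeseries.shape[1]
    groups = roi_groups(T, R)
    grid = DEFAULT_HYPER_GRID

    alias = {
        "lasso": "lasso",
        "grouplasso": "group_lasso",
        "sgl": "sparse_group_lasso",
        "enet": "elastic_net",
    }

    report = ComparisonReport(methods=list(methods), mean={}, sd={}, roc={}, per_repeat={})
    for method in methods:
        per_repeat: list[MetricSet] = []
        if method in alias:
            sel = _fit_selector_method(alias[method], Xtr, ytr, Xva, yva, groups, grid)
            feats = select_features(sel)
            for _ in range(repeats):
                if feats.size == 0:
                    pred, score = svm_classify(Xtr[:, []], ytr, Xte[:, []])
                else:
                    pred, score = svm_classify(Xtr[:, feats], ytr, Xte[:, feats])
                counts = confusion(yte, pred)
                try:
                    _, auc = roc_auc(yte, score)
                except InputError:
                    auc = None
                per_repeat.append(compute_metrics(counts, auc=auc))
                roc_scores = score
        elif method in ("mmlassonet", "lassonet"):
            rng = np.random.default_rng(seed)
            for r in range(repeats):
                fit = fit_multimodal(
                    train,
                    valid,
                    use_dti=(method == "mmlassonet"),
                    config=path_config,
                    lambdas=lambdas if lambdas is not None else _DEFAULT_GRID,
                    init_seed=int(rng.integers(2**31 - 1)),
                )
                labels_pred, probs = fit.predict(test)
                counts = confusion(yte, labels_pred)
                try:
                    _, auc = roc_auc(yte, probs)
                except InputError:
                    auc = None
                per_repeat.append(compute_metrics(counts, auc=auc))
                roc_scores = probs
        else:
            raise InputError(f"unknown method {method!r}")
        report.per_repeat[method] = per_repeat
        report.mean[method], report.sd[method] = _aggregate(per_repeat)
        try:
            pts, _ = roc_auc(yte, roc_scores)
            report.roc[method] = pts
        except InputError:
            pass
    return report
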