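"""End-to-end multi-modal fit: standardisation, structural penalty, model
selection, prediction, checkpointing.

``fit_multimodal`` wires the pieces together exactly once: the penalty
bandwidth sigma and the scalar multiplier c (mean of the training subjects'
maximal penalty-matrix eigenvalues) come from the *training* split only;
features are z-scored with training statistics; the penalty level is chosen
on the validation split (explicit grid by default, multiplicative path
optionally); test data stay untouched until the caller evaluates.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._errors import InputError
from .dti import compute_sigma, dti_vector, penalty_matrix, penalty_scalar
from .io import config_hash
from .model import (
    DEFAULT_LAMBDA_GRID,
    NetworkParams,
    PathConfig,
    PathPoint,
    fit_grid,
    fit_path,
    init_params,
    predict,
    select_model,
)
from .synthetic import CohortDataset

__all__ = ["FittedModel", "fit_multimodal", "save_model", "load_model", "write_path_log"]

logger = logging.getLogger(__name__)


@dataclass
class FittedModel:
    """A selected path point plus everything needed to score new subjects."""

    params: NetworkParams
    lambda_val: float
    dti_scalar: float
    sigma: float | None
    feature_mean: np.ndarray
    feature_sd: np.ndarray
    path: list[PathPoint]
    config: PathConfig
    T: int
    R: int

    def transform(self, dataset_or_X) -> np.ndarray:
        X = (
            dataset_or_X.features()
            if isinstance(dataset_or_X, CohortDataset)
            else np.asarray(dataset_or_X, dtype=float)
        )
        return (X - self.feature_mean) / self.feature_sd

    def predict(self, dataset_or_X, threshold: float = 0.5):
        """0/1 labels and class probabilities for subjects or raw features."""
        return predict(self.params, self.transform(dataset_or_X), threshold)


def fit_multimodal(
    train: CohortDataset,
    valid: CohortDataset,
    use_dti: bool = True,
    config: PathConfig | None = None,
    lambdas: tuple[float, ...] | None = DEFAULT_LAMBDA_GRID,
    init_seed: int | None = None,
) -> FittedModel:
    """Fit the multi-modal LassoNet on a train/valid pair of cohorts.

    ``use_dti=False`` forces the structural multiplier to 1 (plain
    LassoNet ablation).  ``lambdas=None`` switches from the explicit grid
    to the multiplicative dense-to-sparse path; selection is by validation
    accuracy either way.  ``init_seed`` overrides only the network
    initialisation (used by repeat protocols that vary training
    randomness while keeping the data fixed).
    """
    config = config or PathConfig()
    Xtr, ytr = train.features(), train.labels
    Xva, yva = valid.features(), valid.labels
    if len(np.unique(ytr)) < 2:
        raise InputError("training split must contain both classes")
    T, R = train.samples[0].timeseries.shape

    mu = Xtr.mean(axis=0)
    sd = Xtr.std(axis=0)
    sd[sd == 0] = 1.0
    Xtr = (Xtr - mu) / sd
    Xva = (Xva - mu) / sd

    sigma = None
    c = 1.0
    if use_dti:
        networks = train.fa_networks()
        if any(fa is None for fa in networks):
            raise InputError(
                "multi-modal fit requested but some training subjects have no "
                "FA network; pass use_dti=False"
            )
        est = compute_sigma(networks)
        sigma = est.sigma
        pms = [
            penalty_matrix(fa, sigma, subject_id=s.subject_id)
            for fa, s in zip(networks, train.samples)
        ]
        vec = dti_vector(pms)
        c = penalty_scalar(vec, set(train.subject_ids))
        logger.info("structural penalty: sigma=%.6g, scalar c=%.6g", sigma, c)

    seed = config.seed if init_seed is None else init_seed
    rng = np.random.default_rng(seed)
    init = init_params(Xtr.shape[1], config.hidden_K, rng)

    if lambdas is not None:
        path = fit_grid((Xtr, ytr), (Xva, yva), config, dti_scalar=c,
                        lambdas=tuple(lambdas), init=init)
    else:
        path = fit_path((Xtr, ytr), (Xva, yva), config, dti_scalar=c, init=init)
    best = select_model(path)
    return FittedModel(
        params=best.params,
        lambda_val=best.lambda_val,
        dti_scalar=c,
        sigma=sigma,
        feature_mean=mu,
        feature_sd=sd,
        path=path,
        config=config,
        T=T,
        R=R,
    )


def save_model(model: FittedModel, path) -> Path:
    """JSON checkpoint: parameters, scaler, config, path summary, config hash."""
    cfg = {
        "M": model.config.M,
        "epsilon": model.config.epsilon,
        "epochs_per_lambda": model.config.epochs_per_lambda,
        "learning_rate": model.config.learning_rate,
        "lambda_start": model.config.lambda_start,
        "dti_compound": model.config.dti_compound,
        "max_path_steps": model.config.max_path_steps,
        "seed": model.config.seed,
        "hidden_K": model.config.hidden_K,
        "momentum": model.config.momentum,
        "prox_stepsize_scaled": model.config.prox_stepsize_scaled,
    }
    doc = {
        "config": cfg,
        "config_hash": config_hash(cfg),
        "lambda": model.lambda_val,
        "dti_scalar": model.dti_scalar,
        "sigma": model.sigma,
        "T": model.T,
        "R": model.R,
        "theta": model.params.theta.tolist(),
        "W1": model.params.W1.tolist(),
        "b1": model.params.b1.tolist(),
        "w2": model.params.w2.tolist(),
        "b2": model.params.b2,
        "feature_mean": model.feature_mean.tolist(),
        "feature_sd": model.feature_sd.tolist(),
        "path_summary": [
            {
                "lambda": p.lambda_val,
                "lambda_eff": p.lambda_eff,
                "k_active": p.k_active,
                "valid_acc": p.valid_metrics.acc if p.valid_metrics else None,
            }
            for p in model.path
        ],
    }
    path = Path(path)
    path.write_text(json.dumps(doc))
    return path


def load_model(path) -> FittedModel:
    doc = json.loads(Path(path).read_text())
    cfg = PathConfig(**doc["config"])
    params = NetworkParams(
        theta=np.array(doc["theta"]),
        W1=np.array(doc["W1"]),
        b1=np.array(doc["b1"]),
        w2=np.array(doc["w2"]),
        b2=float(doc["b2"]),
    )
    return FittedModel(
        params=params,
        lambda_val=doc["lambda"],
        dti_scalar=doc["dti_scalar"],
        sigma=doc["sigma"],
        feature_mean=np.array(doc["feature_mean"]),
        feature_sd=np.array(doc["feature_sd"]),
        path=[],
        config=cfg,
        T=doc["T"],
        R=doc["R"],
    )


def write_path_log(model: FittedModel, path) -> Path:
    """TSV path log: step, lambda, lambda_eff, k_active, valid accuracy."""
    lines = ["step\tlambda\tlambda_eff\tk_active\tvalid_acc"]
    for i, p in enumerate(model.path):
        acc = p.valid_metrics.acc if p.valid_metrics else float("nan")
        lines.append(f"{i}\t{p.lambda_val:.8g}\t{p.lambda_eff:.8g}\t{p.k_active}\t{acc:.6f}")
    path = Path(path)
    path.write_text("\n".join(lines) + "\n")
    return path
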