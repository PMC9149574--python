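"""Cohort file formats and subject-level dataset splitting.

On-disk cohort layout (all plain text):

* ``<subject>_ts.csv``  — T rows x R columns, header = ROI labels
* ``<subject>_fa.csv``  — R x R FA matrix (same header)
* ``manifest.tsv``      — subject_id, label (0/1), group_name
* ``truth.json``        — generator ground truth, when the cohort is synthetic
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._errors import InputError, SplitError
from .synthetic import CohortDataset, SubjectSample

__all__ = ["SplitSpec", "write_cohort", "read_cohort", "split_dataset", "config_hash"]

logger = logging.getLogger(__name__)

_FA_SYM_TOL = 1e-9


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serialisable config, embedded in outputs."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


@dataclass(frozen=True)
class SplitSpec:
    """Stratified train:valid:test ratios (default 6:2:2).

    Sizes follow floor(ratio * n) for valid and test with the remainder
    going to train (85 subjects -> 51/17/17); stratification keeps the
    label mix in every split.
    """

    train: float = 0.6
    valid: float = 0.2
    test: float = 0.2
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.train, self.valid, self.test) <= 0:
            raise InputError("split ratios must be positive")
        if abs(self.train + self.valid + self.test - 1.0) > 1e-9:
            raise InputError("split ratios must sum to 1")


def write_cohort(dataset: CohortDataset, out_dir) -> Path:
    """Write a cohort directory; returns the directory path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    R = dataset.samples[0].timeseries.shape[1]
    roi_cols = [f"ROI{r + 1}" for r in range(R)]
    rows = []
    for s in dataset.samples:
        pd.DataFrame(s.timeseries, columns=roi_cols).to_csv(
            out / f"{s.subject_id}_ts.csv", index=False, float_format="%.17g"
        )
        pd.DataFrame(s.fa_network, columns=roi_cols).to_csv(
            out / f"{s.subject_id}_fa.csv", index=False, float_format="%.17g"
        )
        rows.append(
            {
                "subject_id": s.subject_id,
                "label": s.label,
                "group_name": f"group{s.label}",
            }
        )
    pd.DataFrame(rows).to_csv(out / "manifest.tsv", sep="\t", index=False)
    if dataset.truth:
        (out / "truth.json").write_text(json.dumps(dataset.truth, indent=2))
    return out


def read_cohort(in_dir) -> CohortDataset:
    """Read a cohort directory; validates shapes and FA symmetry.

    Missing FA files leave ``fa_network`` empty for those subjects; the
    multi-modal penalty is then unavailable (logged).
    """
    d = Path(in_dir)
    manifest_path = d / "manifest.tsv"
    if not manifest_path.exists():
        raise InputError(f"no manifest.tsv in {d}")
    manifest = pd.read_csv(manifest_path, sep="\t")
    samples: list[SubjectSample] = []
    shape = None
    missing_fa = 0
    for _, row in manifest.iterrows():
        sid = str(row["subject_id"])
        raw = row["label"]
        try:
            label = int(raw)
        except (TypeError, ValueError):
            raise InputError(f"unknown label {raw!r} for subject {sid}") from None
        if label not in (0, 1):
            raise InputError(f"unknown label {raw!r} for subject {sid}")
        ts_path = d / f"{sid}_ts.csv"
        if not ts_path.exists():
            raise InputError(f"missing time-series file for subject {sid}")
        ts = pd.read_csv(ts_path).to_numpy(dtype=float)
        if np.isnan(ts).any():
            raise InputError(f"time series of subject {sid} has missing values")
        if shape is None:
            shape = ts.shape
        elif ts.shape != shape:
            raise InputError(
                f"subject {sid} has time-series shape {ts.shape}, expected {shape}"
            )
        fa_path = d / f"{sid}_fa.csv"
        if fa_path.exists():
            fa = pd.read_csv(fa_path).to_numpy(dtype=float)
            if fa.shape != (shape[1], shape[1]):
                raise InputError(
                    f"subject {sid} has FA shape {fa.shape}, expected "
                    f"({shape[1]}, {shape[1]})"
                )
            if not np.allclose(fa, fa.T, atol=_FA_SYM_TOL, rtol=0.0):
                raise InputError(f"FA matrix of subject {sid} is asymmetric")
            fa = 0.5 * (fa + fa.T)
        else:
            fa = None
            missing_fa += 1
        samples.append(
            SubjectSample(subject_id=sid, timeseries=ts, fa_network=fa, label=label)
        )
    if missing_fa:
        logger.warning(
            "%d subjects have no FA matrix: multi-modal mode unavailable", missing_fa
        )
    truth = {}
    truth_path = d / "truth.json"
    if truth_path.exists():
        truth = json.loads(truth_path.read_text())
    return CohortDataset(samples=samples, truth=truth)


def _largest_remainder(targets: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation summing to ``total``, proportional to ``targets``."""
    base = np.floor(targets).astype(int)
    rem = targets - base
    short = total - base.sum()
    order = np.argsort(-rem, kind="stable")
    for i in range(short):
        base[order[i % len(base)]] += 1
    return base


def split_dataset(
    dataset: CohortDataset, spec: SplitSpec
) -> tuple[CohortDataset, CohortDataset, CohortDataset]:
    """Disjoint subject-level train/valid/test split, reproducible from seed."""
    n = len(dataset)
    labels = dataset.labels
    classes = np.unique(labels)
    n_test = int(np.floor(spec.test * n))
    n_valid = int(np.floor(spec.valid * n))
    rng = np.random.default_rng(spec.seed)

    if spec.stratified:
        for c in classes:
            if np.sum(labels == c) < 5:
                raise SplitError(
                    f"class {c} has fewer than 5 subjects; cannot stratify"
                )
        class_idx = {c: np.flatnonzero(labels == c) for c in classes}
        for c in classes:
            rng.shuffle(class_idx[c])
        counts = np.array([len(class_idx[c]) for c in classes], dtype=float)
        test_alloc = _largest_remainder(counts * spec.test, n_test)
        valid_alloc = _largest_remainder(counts * spec.valid, n_valid)
        test_ids, valid_ids, train_ids = [], [], []
        for c, t_k, v_k in zip(classes, test_alloc, valid_alloc):
            idx = class_idx[c]
            test_ids.extend(idx[:t_k])
            valid_ids.extend(idx[t_k : t_k + v_k])
            train_ids.extend(idx[t_k + v_k :])
    else:
        perm = rng.permutation(n)
        test_ids = perm[:n_test].tolist()
        valid_ids = perm[n_test : n_test + n_valid].tolist()
        train_ids = perm[n_test + n_valid :].tolist()

    def subset(ids) -> CohortDataset:
        ids = sorted(ids)
        return CohortDataset(
            samples=[dataset.samples[i] for i in ids], truth=dataset.truth
        )

    train, valid, test = subset(train_ids), subset(valid_ids), subset(test_ids)
    for name, part in (("train", train), ("valid", valid), ("test", test)):
        if len(np.unique(part.labels)) < 2:
            raise SplitError(f"{name} split ended up with a single class")
    return train, valid, test
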