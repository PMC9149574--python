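"""Structural-network penalty: D = exp(-rho^2 / sigma) and its spectrum.

Stronger white-matter (FA) connections produce penalty entries closer to 0,
so the L1 penalty on the skip weights is *relaxed* where structure supports
function — the "inverse proportional" coupling penalty.  Each subject's
penalty matrix is summarised by its maximal eigenvalue; the per-subject
eigenvalues are reduced to one scalar multiplier on the shared penalty by
averaging over the training subjects (the skip weights are shared across
subjects, so a per-subject penalty scale has no direct home).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from ._errors import DegenerateInputError, InputError

__all__ = [
    "PenaltyMatrix",
    "SigmaEstimate",
    "DTIVector",
    "compute_sigma",
    "penalty_matrix",
    "max_eigenvalue",
    "dti_vector",
    "penalty_scalar",
]

_SYM_TOL = 1e-8


@dataclass(frozen=True)
class PenaltyMatrix:
    """R x R matrix D with D_ji = exp(-rho_ji^2 / sigma); entries in (0, 1]."""

    values: np.ndarray
    subject_id: str = ""


@dataclass(frozen=True)
class SigmaEstimate:
    """Bandwidth sigma: mean over subjects of the sample SD of FA entries."""

    sigma: float
    n_subjects_used: int


@dataclass(frozen=True)
class DTIVector:
    """Per-subject maximal eigenvalues of D, in subject order."""

    entries: np.ndarray
    subject_ids: tuple[str, ...]


def _check_symmetric(m: np.ndarray, tol: float = _SYM_TOL) -> None:
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise InputError(f"expected a square matrix, got shape {m.shape}")
    if not np.allclose(m, m.T, atol=tol, rtol=0.0):
        raise InputError(f"matrix is asymmetric beyond tolerance {tol}")


def compute_sigma(networks: list[np.ndarray]) -> SigmaEstimate:
    """sigma = mean over subjects of the sample SD (ddof=1) of each subject's
    upper-triangle off-diagonal FA entries.

    Computed from training-set networks only and then reused for
    validation/test subjects, to keep model selection leakage-free.
    """
    if len(networks) == 0:
        raise InputError("compute_sigma needs at least one network")
    sds = []
    for m in networks:
        _check_symmetric(m)
        m = np.asarray(m, dtype=float)
        iu = np.triu_indices(m.shape[0], k=1)
        vals = m[iu]
        if vals.size < 2:
            raise InputError("network too small for a sample SD (need R >= 3)")
        sds.append(np.std(vals, ddof=1))
    sigma = float(np.mean(sds))
    if sigma <= 0.0:
        raise DegenerateInputError(
            "sigma = 0 (all networks constant): penalty matrix undefined"
        )
    return SigmaEstimate(sigma=sigma, n_subjects_used=len(networks))


def penalty_matrix(
    network: np.ndarray, sigma: float, subject_id: str = ""
) -> PenaltyMatrix:
    """Elementwise D_ji = exp(-rho_ji^2 / sigma).

    The input FA diagonal is expected to be 0 (self-FA is undefined), so
    D's diagonal is 1, which merely shifts all eigenvalues equally.
    """
    if sigma <= 0:
        raise InputError(f"sigma must be > 0, got {sigma}")
    rho = np.asarray(network, dtype=float)
    D = np.exp(-(rho**2) / sigma)
    return PenaltyMatrix(values=D, subject_id=subject_id)


def max_eigenvalue(matrix: np.ndarray) -> float:
    """Largest eigenvalue of a symmetric matrix (real by symmetry)."""
    _check_symmetric(matrix)
    m = np.asarray(matrix, dtype=float)
    m = 0.5 * (m + m.T)
    # eigvalsh returns ascending eigenvalues; ask only for the top one
    w = scipy.linalg.eigh(m, eigvals_only=True, subset_by_index=[m.shape[0] - 1, m.shape[0] - 1])
    return float(w[-1])


def dti_vector(penalty_matrices: list[PenaltyMatrix]) -> DTIVector:
    """Stack per-subject maximal eigenvalues, preserving subject order."""
    if len(penalty_matrices) == 0:
        raise InputError("dti_vector needs at least one penalty matrix")
    shapes = {pm.values.shape for pm in penalty_matrices}
    if len(shapes) != 1:
        raise InputError(f"inconsistent penalty-matrix dimensions: {sorted(shapes)}")
    entries = np.array([max_eigenvalue(pm.values) for pm in penalty_matrices])
    ids = tuple(pm.subject_id for pm in penalty_matrices)
    return DTIVector(entries=entries, subject_ids=ids)


def penalty_scalar(vec: DTIVector, training_ids: set[str]) -> float:
    """Arithmetic mean of the eigenvalues of the training subjects.

    This is the scalar multiplier c applied to the shared L1 penalty
    (lambda_eff = c * lambda): the mean preserves the cohort-level
    magnitude of the per-subject quantities.
    """
    mask = [sid in training_ids for sid in vec.subject_ids]
    if not any(mask):
        raise InputError("no DTI vector entry matches the training ids")
    return float(np.mean(vec.entries[np.asarray(mask)]))
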