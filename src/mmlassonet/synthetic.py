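"""Synthetic multimodal cohort generator.

Emulates the statistical structure a multi-modal sparse classifier assumes:
per-subject band-limited BOLD-like ROI time series with block (community)
functional covariance, symmetric fractional-anisotropy (FA) structural
networks coupled to the functional correlation, and a group-differential
signal confined to a known set of informative ROIs. The ground truth
(which ROIs carry signal) is recorded so that feature-selection methods
can be scored for support recovery without any real scans.

The generative model per subject:

* Time series: a lag-1 autoregressive Gaussian process, ``x_t = a x_{t-1}
  + e_t`` with innovations drawn from ``N(0, (1 - a^2) C)`` so the
  stationary marginal variance of every ROI is ~1.  ``C`` has unit
  diagonal and correlation ``fc_block_corr`` within each of six
  contiguous ROI blocks (a crude community structure), zero across
  blocks.
* Group signal: subjects in group 1 receive a fixed sinusoid of period
  T/8, scaled by ``effect_size`` (in stationary-noise-SD units), added to
  the informative ROIs only.  Because classifiers here consume the
  flattened time-point-by-ROI features, this makes specific (t, roi)
  features discriminative.
* FA network: ``clip(coupling * |functional correlation| +
  (1 - coupling) * baseline + N(0, fa_noise_sd), 0, 1)``, symmetrised,
  zero diagonal.  The coupling term encodes the structure-function
  coupling assumption that motivates the DTI-derived penalty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._errors import ConfigurationError

__all__ = [
    "CohortConfig",
    "SubjectSample",
    "CohortDataset",
    "generate_subject",
    "generate_cohort",
]

#: off-diagonal FA level before coupling and noise (mid-range white-matter FA)
FA_BASELINE = 0.3

#: number of contiguous ROI blocks used for the functional covariance
N_BLOCKS = 6


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic cohort.

    Defaults are the desk-scale study conditions used throughout the test
    suite: 30 subjects per group, 60 time points, 30 ROIs, 5 informative
    ROIs, effect size 2.0 noise-SDs — small enough to run in seconds while
    keeping the d >> n regime (d = T*R = 1800 features vs n = 60 subjects).
    """

    n_per_group: int = 30
    T: int = 60
    R: int = 30
    informative_rois: tuple[int, ...] = (0, 1, 2, 3, 4)
    effect_size: float = 2.0
    ar_coeff: float = 0.3
    fc_block_corr: float = 0.3
    coupling: float = 0.6
    fa_noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.T < 2:
            raise ConfigurationError(f"T must be >= 2, got {self.T}")
        if self.R < 2:
            raise ConfigurationError(f"R must be >= 2, got {self.R}")
        if self.n_per_group < 1:
            raise ConfigurationError(
                f"n_per_group must be >= 1, got {self.n_per_group}"
            )
        if not all(0 <= r < self.R for r in self.informative_rois):
            raise ConfigurationError(
                f"informative_rois must be within 0..{self.R - 1}, "
                f"got {self.informative_rois}"
            )
        if not 0.0 <= self.ar_coeff < 1.0:
            raise ConfigurationError(f"ar_coeff must be in [0,1), got {self.ar_coeff}")
        if not 0.0 <= self.fc_block_corr < 1.0:
            raise ConfigurationError(
                f"fc_block_corr must be in [0,1), got {self.fc_block_corr}"
            )
        if not 0.0 <= self.coupling <= 1.0:
            raise ConfigurationError(f"coupling must be in [0,1], got {self.coupling}")
        if self.effect_size < 0:
            raise ConfigurationError(
                f"effect_size must be >= 0, got {self.effect_size}"
            )
        if self.fa_noise_sd < 0:
            raise ConfigurationError(
                f"fa_noise_sd must be >= 0, got {self.fa_noise_sd}"
            )


@dataclass
class SubjectSample:
    """One subject: T x R time series, R x R FA network, binary label."""

    subject_id: str
    timeseries: np.ndarray
    fa_network: np.ndarray
    label: int


@dataclass
class CohortDataset:
    """An ordered cohort plus the generator's ground-truth record."""

    samples: list[SubjectSample]
    truth: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.samples], dtype=int)

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.samples]

    def features(self) -> np.ndarray:
        """Flatten every subject's time series to a feature row.

        ROI-major order: all T time points of ROI 0, then ROI 1, etc., so
        feature f maps back to (roi, t) = (f // T, f % T).
        """
        return np.stack([s.timeseries.T.reshape(-1) for s in self.samples])

    def fa_networks(self) -> list[np.ndarray]:
        return [s.fa_network for s in self.samples]


def _block_covariance(R: int, rho: float) -> np.ndarray:
    """Unit-diagonal covariance with correlation rho inside contiguous blocks."""
    C = np.eye(R)
    bounds = np.array_split(np.arange(R), N_BLOCKS)
    for idx in bounds:
        if len(idx) == 0:
            continue
        lo, hi = idx[0], idx[-1] + 1
        C[lo:hi, lo:hi] = rho
    np.fill_diagonal(C, 1.0)
    return C


def _group_waveform(T: int) -> np.ndarray:
    """Deterministic low-frequency signal: sinusoid of period T/8."""
    t = np.arange(T)
    return np.sin(2.0 * np.pi * t / (T / 8.0))


def generate_subject(
    config: CohortConfig, group: int, rng: np.random.Generator
) -> SubjectSample:
    """Draw one subject from the generative model.

    Group-1 subjects get the fixed waveform (scaled by ``effect_size``)
    added to the informative ROIs; group-0 subjects are pure noise. With
    ``effect_size = 0`` the two groups are identical in law.
    """
    if group not in (0, 1):
        raise ConfigurationError(f"group must be 0 or 1, got {group}")
    T, R = config.T, config.R
    C = _block_covariance(R, config.fc_block_corr)
    L = np.linalg.cholesky(C)

    a = config.ar_coeff
    # innovations scaled so the stationary marginal variance is C
    innov = rng.standard_normal((T, R)) @ L.T
    ts = np.empty((T, R))
    ts[0] = innov[0]
    scale = np.sqrt(1.0 - a * a)
    for t in range(1, T):
        ts[t] = a * ts[t - 1] + scale * innov[t]

    if group == 1 and config.effect_size > 0 and config.informative_rois:
        wave = config.effect_size * _group_waveform(T)
        ts[:, list(config.informative_rois)] += wave[:, None]

    fc = np.abs(np.corrcoef(ts, rowvar=False))
    base = np.full((R, R), FA_BASELINE)
    noise = rng.normal(0.0, config.fa_noise_sd, size=(R, R)) if config.fa_noise_sd > 0 else 0.0
    fa = config.coupling * fc + (1.0 - config.coupling) * base + noise
    fa = 0.5 * (fa + fa.T)
    fa = np.clip(fa, 0.0, 1.0)
    np.fill_diagonal(fa, 0.0)

    return SubjectSample(subject_id="", timeseries=ts, fa_network=fa, label=group)


def generate_cohort(config: CohortConfig) -> CohortDataset:
    """Generate a balanced two-group cohort, reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    samples: list[SubjectSample] = []
    for group in (0, 1):
        for i in range(config.n_per_group):
            s = generate_subject(config, group, rng)
            s.subject_id = f"sub-{group}{i:03d}"
            samples.append(s)
    truth = {
        "informative_rois": sorted(config.informative_rois),
        "config": {
            "n_per_group": config.n_per_group,
            "T": config.T,
            "R": config.R,
            "effect_size": config.effect_size,
            "ar_coeff": config.ar_coeff,
            "fc_block_corr": config.fc_block_corr,
            "coupling": config.coupling,
            "fa_noise_sd": config.fa_noise_sd,
            "seed": config.seed,
        },
    }
    return CohortDataset(samples=samples, truth=truth)
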