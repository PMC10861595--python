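"""Synthetic data: Gaussian domain-shift experiments and a two-cohort
fall-risk-like fixture.

Three experiment families probe the robustness of adaptation methods, each
with scenarios (a)-(d):

* ``sample_size`` — two-class Gaussians with randomly drawn means and
  random-orthogonal-transform covariances, at 50/100/200/500 samples per
  class;
* ``overlap`` — a fixed 2-D parameterization where the target's class-2
  mean walks toward class 1 from scenario (a) to (d), at 100 samples per
  class;
* ``noise`` — the randomized design at 100 samples per class with additive
  uniform noise of half-width 1/2/3/4.

``synth_fall_cohort`` emulates the shape of a two-cohort gait study: 171
community-dwelling older adults (source) and 49 osteoporosis patients
(target), 50 features in two correlated blocks (28 "linear" + 22
"nonlinear") whose correlation structure is identical across domains, with
imbalanced binary labels (non-faller=1, faller=2).

All randomness flows from explicit integer seeds through named generators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import ortho_group

from .datasets import DomainDataset

__all__ = [
    "DomainSpec",
    "ScenarioConfig",
    "SampleSizeRanges",
    "random_covariance",
    "sample_domain",
    "add_uniform_noise",
    "make_experiment",
    "synth_fall_cohort",
    "OVERLAP_SOURCE",
    "OVERLAP_TARGETS",
    "NOISE_RANGES",
    "SAMPLE_SIZE_COUNTS",
]

EXPERIMENTS = ("sample_size", "overlap", "noise")
SCENARIOS = ("a", "b", "c", "d")

# Fixed 2-D overlap design: per class, (mean, covariance).
OVERLAP_SOURCE = {
    1: (np.array([2.5, 7.5]), np.diag([3.0, 1.0])),
    2: (np.array([7.0, 4.0]), np.diag([2.0, 1.0])),
}
OVERLAP_TARGETS = {
    "a": {
        1: (np.array([3.0, 6.0]), np.diag([8.0, 2.0])),
        2: (np.array([13.0, 0.0]), np.diag([6.0, 1.0])),
    },
    "b": {
        1: (np.array([3.0, 6.0]), np.diag([8.0, 2.0])),
        2: (np.array([8.0, 1.0]), np.diag([6.0, 1.0])),
    },
    "c": {
        1: (np.array([3.0, 6.0]), np.diag([8.0, 2.0])),
        2: (np.array([8.0, 2.0]), np.diag([6.0, 2.0])),
    },
    "d": {
        1: (np.array([2.5, 6.0]), np.diag([8.0, 2.0])),
        2: (np.array([7.0, 4.0]), np.diag([6.0, 2.0])),
    },
}
SAMPLE_SIZE_COUNTS = {"a": 50, "b": 100, "c": 200, "d": 500}
NOISE_RANGES = {"a": (-1.0, 1.0), "b": (-2.0, 2.0), "c": (-3.0, 3.0), "d": (-4.0, 4.0)}


@dataclass
class DomainSpec:
    """Per-class Gaussian parameters and sample counts for one domain."""

    means: list[np.ndarray]
    covs: list[np.ndarray]
    n_per_class: list[int]

    def __post_init__(self) -> None:
        if not (len(self.means) == len(self.covs) == len(self.n_per_class)):
            raise ValueError("means, covs and n_per_class must align per class")
        if len(self.means) < 1:
            raise ValueError("at least one class required")
        self.means = [np.asarray(m, float) for m in self.means]
        self.covs = [np.asarray(S, float) for S in self.covs]
        d = self.means[0].shape[0]
        for m, S, n in zip(self.means, self.covs, self.n_per_class):
            if m.shape != (d,) or S.shape != (d, d):
                raise ValueError("inconsistent dimensions across classes")
            if not np.allclose(S, S.T):
                raise ValueError("covariance must be symmetric")
            if np.linalg.eigvalsh(S).min() <= 0:
                raise ValueError("covariance must be positive definite")
            if n < 1:
                raise ValueError("n per class must be >= 1")

    @property
    def dim(self) -> int:
        return self.means[0].shape[0]


@dataclass
class ScenarioConfig:
    """Full parameterization of one simulation experiment."""

    source: DomainSpec
    target: DomainSpec
    noise_range: tuple[float, float] = (0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        a, b = self.noise_range
        if a > b:
            raise ValueError("noise_range must satisfy a <= b")
        if self.source.dim != self.target.dim:
            raise ValueError("source and target dimensions differ")


@dataclass
class SampleSizeRanges:
    """Uniform ranges for the randomized experiment parameters."""

    class1_mean: tuple[float, float] = (2.0, 5.0)
    class2_mean: tuple[float, float] = (4.0, 9.0)
    source_diag: tuple[float, float] = (1.0, 3.0)
    target_diag: tuple[float, float] = (4.0, 6.0)
    dim: tuple[int, int] = (2, 20)


def random_covariance(dim: int, diag_range: tuple[float, float], seed: int) -> np.ndarray:
    """Sigma = Q diag(d_1..d_dim) Q' with d_i ~ Uniform[low, high] and Q a
    seeded random orthogonal matrix; the eigenvalues of Sigma are the drawn
    diagonal values."""
    low, high = diag_range
    if not 0 < low <= high:
        raise ValueError("diag_range must satisfy 0 < low <= high")
    if dim < 1:
        raise ValueError("dim must be positive")
    rng = np.random.default_rng(seed)
    diag = rng.uniform(low, high, dim)
    if dim == 1:
        return np.array([[diag[0]]])
    Q = ortho_group.rvs(dim, random_state=rng)
    S = (Q * diag) @ Q.T
    return 0.5 * (S + S.T)


def sample_domain(config: ScenarioConfig, domain: str) -> DomainDataset:
    """Draw one domain's dataset: per class c, n_c Gaussian samples with
    that class's (mu, Sigma); labels 1..C attached.  Deterministic under the
    config seed (source and target use distinct substreams)."""
    if domain not in ("source", "target"):
        raise ValueError("domain must be 'source' or 'target'")
    spec = config.source if domain == "source" else config.target
    rng = np.random.default_rng([config.seed, 0 if domain == "source" else 1])
    parts, labels = [], []
    for c, (mu, S, n) in enumerate(zip(spec.means, spec.covs, spec.n_per_class), 1):
        parts.append(rng.multivariate_normal(mu, S, size=n, method="cholesky"))
        labels.append(np.full(n, c, dtype=np.int64))
    return DomainDataset(
        np.vstack(parts), np.concatenate(labels), None, domain_tag=domain
    )


def add_uniform_noise(
    data: DomainDataset, a: float, b: float, seed: int
) -> DomainDataset:
    """Perturb every feature cell with an independent Uniform[a, b] draw;
    labels unchanged."""
    if a > b:
        raise ValueError("noise bounds must satisfy a <= b")
    rng = np.random.default_rng(seed)
    noise = rng.uniform(a, b, size=data.features.shape)
    return DomainDataset(
        data.features + noise, data.labels, data.feature_names, data.domain_tag
    )


def _randomized_config(
    seed: int,
    n_per_class: int,
    ranges: SampleSizeRanges,
    noise_range: tuple[float, float] = (0.0, 0.0),
) -> ScenarioConfig:
    """Randomized two-class design with genuine domain shift: each domain
    draws its own class means from the same class-specific ranges and its
    own covariance (source diagonals lighter than target), with random
    orthogonal mixing of the covariance axes.  The dimension is shared."""
    rng = np.random.default_rng([seed, 99])
    dim = int(rng.integers(ranges.dim[0], ranges.dim[1] + 1))
    cov_seeds = rng.integers(0, 2**31 - 1, size=4)
    specs = []
    for i, diag_range in enumerate((ranges.source_diag, ranges.target_diag)):
        mu1 = rng.uniform(*ranges.class1_mean, dim)
        mu2 = rng.uniform(*ranges.class2_mean, dim)
        specs.append(
            DomainSpec(
                means=[mu1, mu2],
                covs=[
                    random_covariance(dim, diag_range, int(cov_seeds[2 * i])),
                    random_covariance(dim, diag_range, int(cov_seeds[2 * i + 1])),
                ],
                n_per_class=[n_per_class, n_per_class],
            )
        )
    return ScenarioConfig(specs[0], specs[1], noise_range=noise_range, seed=seed)


def make_experiment(
    name: str,
    scenario: str,
    seed: int,
    ranges: SampleSizeRanges | None = None,
    noise_domains: str = "both",
    return_config: bool = False,
):
    """Generate one (source, target) pair for an experiment scenario.

    ``name`` is one of ``sample_size``/``overlap``/``noise``; ``scenario``
    one of ``a``-``d``.  ``noise_domains`` ('both' or 'target') controls
    which domains receive additive noise in the noise experiment.  With
    ``return_config`` the true generating parameters are returned as well.
    """
    if name not in EXPERIMENTS:
        raise ValueError(f"unknown experiment {name!r}; choose from {EXPERIMENTS}")
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    if noise_domains not in ("both", "target"):
        raise ValueError("noise_domains must be 'both' or 'target'")
    ranges = ranges or SampleSizeRanges()

    if name == "overlap":
        src_params, tgt_params = OVERLAP_SOURCE, OVERLAP_TARGETS[scenario]
        config = ScenarioConfig(
            source=DomainSpec(
                means=[src_params[1][0], src_params[2][0]],
                covs=[src_params[1][1], src_params[2][1]],
                n_per_class=[100, 100],
            ),
            target=DomainSpec(
                means=[tgt_params[1][0], tgt_params[2][0]],
                covs=[tgt_params[1][1], tgt_params[2][1]],
                n_per_class=[100, 100],
            ),
            seed=seed,
        )
    elif name == "sample_size":
        config = _randomized_config(seed, SAMPLE_SIZE_COUNTS[scenario], ranges)
    else:  # noise
        config = _randomized_config(
            seed, 100, ranges, noise_range=NOISE_RANGES[scenario]
        )

    source = sample_domain(config, "source")
    target = sample_domain(config, "target")
    a, b = config.noise_range
    if b > a:
        if noise_domains == "both":
            source = add_uniform_noise(source, a, b, seed=int(
                np.random.default_rng([seed, 2]).integers(0, 2**31 - 1)
            ))
        target = add_uniform_noise(target, a, b, seed=int(
            np.random.default_rng([seed, 3]).integers(0, 2**31 - 1)
        ))
    if return_config:
        return source, target, config
    return source, target


def synth_fall_cohort(
    n_source: int = 171,
    n_target: int = 49,
    n_features: int = 50,
    minority_fraction: float = 0.2,
    seed: int = 0,
    n_linear: int = 28,
    return_params: bool = False,
):
    """Two-cohort synthetic stand-in for a private gait-feature study.

    Both cohorts share one block correlation structure (within-block
    correlation 0.5 for the 28 linear and 22 nonlinear blocks, 0.05 between
    blocks) but differ in class-mean geometry: the target cohort's features
    are mean-shifted and its covariance scaled by 1.3.  The minority class
    (fallers, label 2) makes up ``minority_fraction`` of each cohort.
    Feature names carry group prefixes (``lin_*``/``nl_*``) so the grouped
    reduction path can recover the split.
    """
    if not 0 < minority_fraction <= 0.5:
        raise ValueError("minority_fraction must be in (0, 0.5]")
    if n_source < 2 or n_target < 2 or not 0 < n_linear < n_features:
        raise ValueError("invalid cohort sizes or feature split")
    d = n_features
    rng = np.random.default_rng([seed, 7])

    corr = np.full((d, d), 0.05)
    corr[:n_linear, :n_linear] = 0.5
    corr[n_linear:, n_linear:] = 0.5
    np.fill_diagonal(corr, 1.0)
    L = np.linalg.cholesky(corr)

    effect = np.zeros(d)
    effect[rng.choice(d, size=15, replace=False)] = 0.8  # class-2 mean shift
    target_shift = rng.uniform(-0.5, 0.5, d)
    target_scale = np.sqrt(1.3)

    names = [f"lin_{j + 1:02d}" for j in range(n_linear)] + [
        f"nl_{j + 1:02d}" for j in range(d - n_linear)
    ]

    def draw(n: int, tag: str) -> DomainDataset:
        n_minor = max(1, int(round(n * minority_fraction)))
        labels = np.concatenate(
            [np.full(n - n_minor, 1, np.int64), np.full(n_minor, 2, np.int64)]
        )
        z = rng.standard_normal((n, d)) @ L.T
        X = z + np.where(labels[:, None] == 2, effect[None, :], 0.0)
        if tag == "target":
            X = X * target_scale + target_shift
        return DomainDataset(X, labels, list(names), domain_tag=tag)

    source = draw(n_source, "source")
    target = draw(n_target, "target")
    if return_params:
        params = {
            "correlation": corr,
            "effect": effect,
            "target_shift": target_shift,
            "target_scale": float(target_scale),
            "n_linear": n_linear,
        }
        return source, target, params
    return source, target
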