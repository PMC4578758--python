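"""Synthetic data-generating processes for high-dimensional two-class benchmarks.

Three scenarios are provided:

* ``block-mvn`` — multivariate normal features with unit variance, an
  exchangeable correlation ``rho`` inside consecutive blocks of
  ``block_size`` variables (independent across blocks), and a mean shift
  ``mu2`` on the first ``n_de`` variables in class 2.  This is the standard
  gene-expression-like benchmark: a small set of differentially expressed
  (DE) variables buried among correlated null ones.
* ``null-independent`` — iid standard normal features with labels assigned
  independently of the features; the true error rate of any classifier is
  0.5.  Used to study overfitting of the base trees.
* ``variance-shift`` — a "complex separation": both classes share the mean
  (50 everywhere), but 20 informative variables have variance 12.5 in
  class 1 and 3.125 in class 2, so one class is nested inside the other.

All generators are deterministic given a seed.  Within one replicate the
training set is drawn first and the test set second from a single RNG
stream, so the pair is reproducible as a unit.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import yaml

from .datasets import LabeledDataset

SCENARIOS = ("block-mvn", "null-independent", "variance-shift")


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass
class SimulationConfig:
    """Parameters of the block-correlated MVN data-generating process.

    Parameters
    ----------
    p : int
        Number of variables.
    n_train : int
        Training-set size; classes are balanced so it must be even.
    mu2 : float
        Mean of the DE variables in class 2 (class 1 means are all zero).
    rho : float
        Within-block exchangeable correlation, in [0, 1).
    block_size : int
        Variables per correlated block; must divide ``p`` for block-mvn.
    n_de : int
        Number of differentially expressed variables (the first ``n_de``
        columns).
    n_test_per_class : int
        Independent test samples per class (default 500).
    scenario : str
        One of ``block-mvn``, ``null-independent``, ``variance-shift``.
    seed : int
        RNG seed.
    """

    p: int = 1000
    n_train: int = 50
    mu2: float = 0.7
    rho: float = 0.8
    block_size: int = 10
    n_de: int = 100
    n_test_per_class: int = 500
    scenario: str = "block-mvn"
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ConfigurationError(f"unknown scenario {self.scenario!r}")
        if self.p < 1:
            raise ConfigurationError("p must be >= 1")
        if self.n_train < 2 or self.n_train % 2:
            raise ConfigurationError("n_train must be even and >= 2 "
                                     "(balanced classes)")
        if not 0.0 <= self.rho < 1.0:
            raise ConfigurationError("rho must lie in [0, 1)")
        if self.n_de > self.p:
            raise ConfigurationError("n_de cannot exceed p")
        if self.scenario == "block-mvn" and self.p % self.block_size:
            raise ConfigurationError("block_size must divide p")
        if self.n_test_per_class < 1:
            raise ConfigurationError("n_test_per_class must be >= 1")

    # -- serialization -------------------------------------------------
    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "SimulationConfig":
        return cls(**json.loads(s))


def _draw_block_mvn(rng: np.random.Generator, n: int, config: SimulationConfig,
                    shifted: bool) -> np.ndarray:
    """Draw ``n`` samples with exchangeable within-block correlation.

    The exchangeable block with unit variances factors exactly as
    ``x_j = sqrt(rho) * u + sqrt(1 - rho) * e_j`` with ``u`` shared per
    block, so no p x p matrix is ever formed.
    """
    p, bs, rho = config.p, config.block_size, config.rho
    n_blocks = p // bs
    shared = rng.standard_normal((n, n_blocks))
    noise = rng.standard_normal((n, p))
    X = (np.sqrt(rho) * np.repeat(shared, bs, axis=1)
         + np.sqrt(1.0 - rho) * noise)
    if shifted:
        X[:, :config.n_de] += config.mu2
    return X


def simulate_block_mvn(
    config: SimulationConfig,
) -> tuple[LabeledDataset, LabeledDataset]:
    """Generate a balanced train/test pair from the block-MVN scenario.

    Class 1 has mean zero everywhere; class 2 has mean ``mu2`` on the
    first ``n_de`` variables.  All variances are 1 and the correlation is
    ``rho`` within consecutive blocks of ``block_size`` variables, zero
    across blocks.  The training set holds ``n_train/2`` samples per class
    and the test set ``n_test_per_class`` per class, drawn train-first
    from one seeded stream.
    """
    if config.scenario != "block-mvn":
        raise ConfigurationError("config.scenario must be 'block-mvn'")
    rng = np.random.default_rng(config.seed)

    def draw(n_per_class: int) -> LabeledDataset:
        X1 = _draw_block_mvn(rng, n_per_class, config, shifted=False)
        X2 = _draw_block_mvn(rng, n_per_class, config, shifted=True)
        X = np.vstack([X1, X2])
        y = np.repeat([1, 2], n_per_class)
        return LabeledDataset(X, y)

    train = draw(config.n_train // 2)
    test = draw(config.n_test_per_class)
    return train, test


def simulate_null_independent(p: int, n: int, seed: int = 0) -> LabeledDataset:
    """iid standard-normal features with class labels independent of them.

    Labels are half class 1, half class 2 (``n`` must be even); any
    apparent separability is pure overfitting, as the Bayes error is 0.5.
    """
    if p < 1:
        raise ConfigurationError("p must be >= 1")
    if n < 2 or n % 2:
        raise ConfigurationError("n must be even and >= 2")
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    y = np.repeat([1, 2], n // 2)
    return LabeledDataset(X, y)


def simulate_variance_shift(
    p_null: int = 980,
    seed: int = 0,
    n_train_per_class: int = 50,
    n_test_per_class: int = 500,
    informative_variance_ratio: float = 4.0,
) -> tuple[LabeledDataset, LabeledDataset]:
    """Complex-separation scenario: classes differ only in spread.

    ``p_null`` null variables are N(50, 12.5) in both classes; 20
    informative variables have variance 12.5 in class 1 and
    ``12.5 / informative_variance_ratio`` in class 2 (default 3.125, a
    fourfold shrinkage that nests class 2 inside class 1).  Setting the
    ratio to 1 makes the classes indistinguishable — a useful null hook.
    """
    if p_null < 0:
        raise ConfigurationError("p_null must be >= 0")
    if informative_variance_ratio <= 0:
        raise ConfigurationError("informative_variance_ratio must be > 0")
    rng = np.random.default_rng(seed)
    n_inf = 20
    p = p_null + n_inf
    sd_null = np.sqrt(12.5)
    sd_inf_c1 = np.sqrt(12.5)
    sd_inf_c2 = np.sqrt(12.5 / informative_variance_ratio)

    def draw(n_per_class: int) -> LabeledDataset:
        X = 50.0 + sd_null * rng.standard_normal((2 * n_per_class, p))
        inf = X[:, :n_inf]  # first 20 columns are informative
        inf[:n_per_class] = 50.0 + sd_inf_c1 * rng.standard_normal(
            (n_per_class, n_inf))
        inf[n_per_class:] = 50.0 + sd_inf_c2 * rng.standard_normal(
            (n_per_class, n_inf))
        y = np.repeat([1, 2], n_per_class)
        return LabeledDataset(X, y)

    train = draw(n_train_per_class)
    test = draw(n_test_per_class)
    return train, test


def make_imbalanced_fixture(n_min: int, n_max: int, p: int,
                            seed: int = 0) -> LabeledDataset:
    """Null-feature dataset with ``n_min`` class-1 and ``n_max`` class-2
    samples, for exercising the majority-class down-sizing operator."""
    if n_min > n_max:
        raise ConfigurationError("n_min must not exceed n_max")
    rng = np.random.default_rng(seed)
    n = n_min + n_max
    X = rng.standard_normal((n, p))
    y = np.repeat([1, 2], [n_min, n_max])
    return LabeledDataset(X, y)
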