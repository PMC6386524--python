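"""Synthetic dependence relationships for benchmarking independence tests.

Twenty joint distributions of ``(X, Y)`` spanning monotone (1-5) and
non-monotone (6-19) dependence plus one independent pair (20). Each recipe is
parameterized by the sample size ``n``, the dimension ``p`` of X (the
dimension ``q`` of Y is fixed per relationship), and a noise level ``kappa``.

Conventions shared by the whole family:

* ``w = (1, 1/2, ..., 1/p)`` is a decaying weight vector, so ``w^T x``
  aggregates dimensions with diminishing influence — added dimensions make
  the high-dimensional versions *harder*, not easier.
* ``kappa`` scales the additive noise; the benchmark convention is
  ``kappa = 1`` for one-dimensional settings and ``kappa = 0`` (noiseless)
  for ``p > 1``, which is also the default when ``kappa`` is not given.
  Jitter terms that are part of X's own distribution (e.g. the 0.4
  perturbation of the circle, the 0.05p smear of the square) are always on.
* Noise ``eps`` is standard normal unless a recipe states otherwise (the two
  parabolas use uniform noise).

``q = p`` for the joint normal, logarithmic, both sines, square, diamond,
multiplicative noise, and multimodal independence; all other relationships
have scalar Y.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SimulationSpec",
    "DatasetPair",
    "decay_weights",
    "sample_relationship",
    "SIMULATION_NAMES",
    "MONOTONE_TYPES",
    "NONMONOTONE_TYPES",
]

SIMULATION_NAMES = {
    1: "linear",
    2: "exponential",
    3: "cubic",
    4: "joint_normal",
    5: "step",
    6: "quadratic",
    7: "w_shape",
    8: "spiral",
    9: "uncorrelated_bernoulli",
    10: "logarithmic",
    11: "fourth_root",
    12: "sine_4pi",
    13: "sine_16pi",
    14: "square",
    15: "two_parabolas",
    16: "circle",
    17: "ellipse",
    18: "diamond",
    19: "multiplicative_noise",
    20: "multimodal_independence",
}

MONOTONE_TYPES = tuple(range(1, 6))
NONMONOTONE_TYPES = tuple(range(6, 20))

_Q_EQUALS_P = {4, 10, 12, 13, 14, 18, 19, 20}


def y_dimension(type_id: int, p: int) -> int:
    """Dimension of Y for a given relationship and X-dimension."""
    return p if type_id in _Q_EQUALS_P else 1


@dataclass(frozen=True)
class SimulationSpec:
    """One benchmark relationship with its sampling parameters.

    ``kappa=None`` applies the benchmark convention: 1 when ``p == 1``,
    0 otherwise.
    """

    type_id: int
    n: int
    p: int = 1
    kappa: float | None = None
    seed: int | None = None

    def __post_init__(self):
        if self.type_id not in SIMULATION_NAMES:
            raise ValueError(f"unknown relationship type {self.type_id}; valid ids are 1..20")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.p < 1:
            raise ValueError("p must be >= 1")

    @property
    def effective_kappa(self) -> float:
        if self.kappa is not None:
            return float(self.kappa)
        return 1.0 if self.p == 1 else 0.0

    @property
    def q(self) -> int:
        return y_dimension(self.type_id, self.p)

    @property
    def name(self) -> str:
        return SIMULATION_NAMES[self.type_id]


@dataclass
class DatasetPair:
    """A paired sample (X, Y) drawn from one benchmark relationship."""

    X: np.ndarray  # (n, p)
    Y: np.ndarray  # (n, q)
    spec: SimulationSpec


def decay_weights(p: int) -> np.ndarray:
    """The decaying weight vector ``(1, 1/2, ..., 1/p)``."""
    if p < 1:
        raise ValueError("p must be >= 1")
    return 1.0 / np.arange(1, p + 1)


def sample_relationship(spec: SimulationSpec, rng: np.random.Generator | None = None) -> DatasetPair:
    """Draw ``n`` paired observations from the relationship in ``spec``.

    A ``rng`` may be passed to draw from an existing stream (e.g. inside a
    power simulation); otherwise one is created from ``spec.seed``.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n, p, k = spec.n, spec.p, spec.effective_kappa
    t = spec.type_id
    w = decay_weights(p)

    if t == 1:  # linear
        X = rng.uniform(-1, 1, (n, p))
        Y = X @ w + k * rng.standard_normal(n)
    elif t == 2:  # exponential
        X = rng.uniform(0, 3, (n, p))
        Y = np.exp(X @ w) + 10 * k * rng.standard_normal(n)
    elif t == 3:  # cubic
        X = rng.uniform(-1, 1, (n, p))
        s = X @ w - 1.0 / 3.0
        Y = 128 * s**3 + 48 * s**2 - 12 * s + 80 * k * rng.standard_normal(n)
    elif t == 4:  # joint normal
        rho = 1.0 / (2.0 * p)
        cov = np.eye(2 * p)
        cov[p:, p:] *= 1 + 0.5 * k
        cov[:p, p:] = rho
        cov[p:, :p] = rho
        Z = rng.multivariate_normal(np.zeros(2 * p), cov, size=n, method="cholesky")
        X, Y = Z[:, :p], Z[:, p:]
    elif t == 5:  # step function
        X = rng.uniform(-1, 1, (n, p))
        Y = (X @ w > 0).astype(float) + k * rng.standard_normal(n)
    elif t == 6:  # quadratic
        X = rng.uniform(-1, 1, (n, p))
        Y = (X @ w) ** 2 + 0.5 * k * rng.standard_normal(n)
    elif t == 7:  # w shape
        U = rng.uniform(-1, 1, (n, p))
        X = rng.uniform(-1, 1, (n, p))
        Y = 4 * (((X @ w) ** 2 - 0.5) ** 2 + (U @ w) / 500.0) + 0.5 * k * rng.standard_normal(n)
    elif t == 8:  # spiral
        U = rng.uniform(0, 5, n)
        eps = rng.standard_normal(n)
        X = np.empty((n, p))
        su, cu = np.sin(np.pi * U), np.cos(np.pi * U)
        for d in range(1, p):
            X[:, d - 1] = U * su * cu**d
        X[:, p - 1] = U * cu**p
        Y = U * su + 0.4 * p * k * eps
    elif t == 9:  # uncorrelated bernoulli
        U = rng.binomial(1, 0.5, n)
        eps1 = rng.standard_normal((n, p))
        eps2 = rng.standard_normal(n)
        X = rng.binomial(1, 0.5, (n, p)) + 0.5 * k * eps1
        Y = (2 * U - 1) * (X @ w) + 0.5 * k * eps2
    elif t == 10:  # logarithmic
        X = rng.standard_normal((n, p))
        Y = 2 * np.log2(np.abs(X)) + 3 * k * rng.standard_normal((n, p))
    elif t == 11:  # fourth root
        X = rng.uniform(-1, 1, (n, p))
        Y = np.abs(X @ w) ** 0.25 + (k / 4.0) * rng.standard_normal(n)
    elif t in (12, 13):  # sine, period 4*pi / 16*pi
        theta = 4 * np.pi if t == 12 else 16 * np.pi
        noise_scale = k if t == 12 else 0.5 * k
        U = rng.uniform(-1, 1, n)
        V = rng.standard_normal((n, p))
        X = U[:, None] + 0.02 * p * V
        Y = np.sin(theta * X) + noise_scale * rng.standard_normal((n, p))
    elif t in (14, 18):  # square / diamond (rotated squares)
        theta = -np.pi / 8 if t == 14 else -np.pi / 4
        U = rng.uniform(-1, 1, n)
        V = rng.uniform(-1, 1, n)
        eps = rng.standard_normal((n, p))
        X = (U * np.cos(theta) + V * np.sin(theta))[:, None] + 0.05 * p * eps
        Y = np.tile((-U * np.sin(theta) + V * np.cos(theta))[:, None], (1, p))
    elif t == 15:  # two parabolas (uniform noise)
        eps = rng.uniform(0, 1, n)
        U = rng.binomial(1, 0.5, n)
        X = rng.uniform(-1, 1, (n, p))
        Y = ((X @ w) ** 2 + 2 * k * eps) * (U - 0.5)
    elif t in (16, 17):  # circle / ellipse
        r = 1.0 if t == 16 else 5.0
        U = rng.uniform(-1, 1, (n, p))
        eps = rng.standard_normal((n, p))
        X = np.empty((n, p))
        cosprod = np.ones(n)
        for d in range(1, p):
            cosprod = cosprod * np.cos(np.pi * U[:, d - 1])
            X[:, d - 1] = r * (np.sin(np.pi * U[:, d]) * cosprod + 0.4 * eps[:, d - 1])
        cosprod = cosprod * np.cos(np.pi * U[:, p - 1])
        X[:, p - 1] = r * (cosprod + 0.4 * eps[:, p - 1])
        Y = np.sin(np.pi * U[:, 0])
    elif t == 19:  # multiplicative noise
        U = rng.standard_normal((n, p))
        X = rng.standard_normal((n, p))
        Y = U * X
    else:  # 20: multimodal independence
        U = rng.standard_normal((n, p))
        V = rng.standard_normal((n, p))
        Ub = rng.binomial(1, 0.5, (n, p))
        Vb = rng.binomial(1, 0.5, (n, p))
        X = U / 3.0 + 2 * Ub - 1
        Y = V / 3.0 + 2 * Vb - 1

    X = np.asarray(X, dtype=float).reshape(n, -1)
    Y = np.asarray(Y, dtype=float).reshape(n, -1)
    return DatasetPair(X=X, Y=Y, spec=spec)
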