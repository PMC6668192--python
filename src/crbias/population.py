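"""Confounded covariate generation.

A population consists of an unmeasured confounder ``U ~ N(0, 1)`` and a binary
treatment indicator ``Z`` with prevalence ``P(Z = 1) = pi`` and a prescribed
Pearson correlation ``Corr(U, Z) = rho``.

The pair is constructed by latent bivariate-normal thresholding: draw
``(U, V)`` bivariate standard normal with latent correlation ``r`` and set
``Z = 1{V > c}`` where ``c`` is the ``(1 - pi)`` standard-normal quantile, so
that ``P(Z = 1) = pi`` exactly.  Because ``E[U | V = v] = r v``,

    Corr(U, Z) = r * phi(c) / sqrt(pi * (1 - pi)),

which is linear in ``r``; the attainable correlation is therefore bounded by
``phi(c) / sqrt(pi * (1 - pi))`` (0.7979 at pi = 0.5), and the latent
correlation needed for a target ``rho`` follows by inversion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "InfeasibleCorrelationError",
    "PopulationParams",
    "Population",
    "max_abs_correlation",
    "latent_correlation",
    "generate_confounded_covariates",
    "read_population_csv",
    "write_population_csv",
]


class InfeasibleCorrelationError(ValueError):
    """Requested |Corr(U, Z)| exceeds the bound imposed by the prevalence."""


def _check_pi(pi: float) -> None:
    if not (0.0 < pi < 1.0):
        raise ValueError(f"treatment prevalence pi must lie in (0, 1), got {pi!r}")


def max_abs_correlation(pi: float) -> float:
    """Largest attainable |Corr(U, Z)| for U ~ N(0,1), Z ~ Bernoulli(pi).

    Under the latent-threshold construction the bound is
    ``phi(c) / sqrt(pi (1 - pi))`` with ``c = Phi^{-1}(1 - pi)``; it is
    symmetric in ``pi <-> 1 - pi`` and equals 0.7979 at ``pi = 0.5``.
    """
    _check_pi(pi)
    c = stats.norm.ppf(1.0 - pi)
    return float(stats.norm.pdf(c) / math.sqrt(pi * (1.0 - pi)))


def latent_correlation(rho: float, pi: float) -> float:
    """Latent bivariate-normal correlation giving Corr(U, Z) = rho after thresholding.

    Inverse of the (linear) dichotomised-normal correlation map:
    ``r = rho * sqrt(pi (1 - pi)) / phi(c)``.

    Raises
    ------
    InfeasibleCorrelationError
        If ``|rho|`` exceeds :func:`max_abs_correlation`.
    """
    bound = max_abs_correlation(pi)
    if abs(rho) > bound:
        raise InfeasibleCorrelationError(
            f"|rho| = {abs(rho):.6g} is not attainable at pi = {pi:.6g}; "
            f"the latent-threshold bound is {bound:.6g}"
        )
    c = stats.norm.ppf(1.0 - pi)
    return float(rho * math.sqrt(pi * (1.0 - pi)) / stats.norm.pdf(c))


@dataclass(frozen=True)
class PopulationParams:
    """Parameters of one confounded population draw."""

    n: int
    rho: float
    pi: float
    seed: int | np.random.SeedSequence | None = None

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"population size must be at least 2, got {self.n}")
        _check_pi(self.pi)
        # raises InfeasibleCorrelationError when rho is out of range
        latent_correlation(self.rho, self.pi)


@dataclass
class Population:
    """Per-subject confounder values ``u`` and treatment indicators ``z``."""

    u: np.ndarray
    z: np.ndarray

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.z = np.asarray(self.z, dtype=np.int8)
        if self.u.shape != self.z.shape or self.u.ndim != 1:
            raise ValueError("u and z must be 1-d arrays of equal length")
        if not np.isin(self.z, (0, 1)).all():
            raise ValueError("z must contain only 0 and 1")

    @property
    def n(self) -> int:
        return self.u.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"id": np.arange(self.n), "u": self.u, "z": self.z.astype(int)}
        )


def generate_confounded_covariates(params: PopulationParams) -> Population:
    """Draw (U, Z) with the requested prevalence and correlation.

    Reproducible given ``params.seed``; sample moments converge to
    ``E[U] = 0``, ``Var[U] = 1``, ``P(Z = 1) = pi`` and ``Corr(U, Z) = rho``.
    """
    r = latent_correlation(params.rho, params.pi)
    c = stats.norm.ppf(1.0 - params.pi)
    rng = np.random.default_rng(params.seed)
    x1 = rng.standard_normal(params.n)
    x2 = rng.standard_normal(params.n)
    u = x1
    v = r * x1 + math.sqrt(max(0.0, 1.0 - r * r)) * x2
    z = (v > c).astype(np.int8)
    return Population(u=u, z=z)


def write_population_csv(pop: Population, path) -> None:
    pop.to_frame().to_csv(path, index=False)


def read_population_csv(path) -> Population:
    df = pd.read_csv(path)
    return Population(u=df["u"].to_numpy(), z=df["z"].to_numpy())
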