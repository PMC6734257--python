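"""Cost-type distributions.

The non-monetary burden of adhering to a prophylactic therapy (time, side
effects, emotional distress) is heterogeneous across individuals and is
modeled as a non-negative random cost type ``c`` with CDF ``F`` and density
``f``.  Decision rules compare ``c`` with a scalar threshold, so the model
layer only needs the CDF, the density, partial first moments
``\\int_a^b c f(c) dc`` and a sampler.
"""

from __future__ import annotations

import abc

import numpy as np
from scipy import integrate
from scipy import stats

__all__ = ["CostModel", "UniformCostModel"]

# Truncation point of the (possibly unbounded) support for quadrature:
# smallest c with cdf(c) >= 1 - _TAIL_MASS.
_TAIL_MASS = 1e-12
_QUAD_TOL = 1e-10


class CostModel(abc.ABC):
    """Distribution of the non-monetary cost type ``c`` on ``[0, inf)``.

    Subclasses provide the CDF, the density and a sampler; the partial first
    moment defaults to adaptive quadrature of ``c * pdf(c)`` (absolute
    tolerance ``1e-10``) but should be overridden where a closed form exists.
    """

    @abc.abstractmethod
    def cdf(self, c: float) -> float:
        """P(cost <= c).  Must be 0 for c < 0 and reach 1 in the right tail."""

    @abc.abstractmethod
    def pdf(self, c: float) -> float:
        """Density f(c), zero outside the support."""

    @abc.abstractmethod
    def sample(self, n: int, rng: np.random.Generator | int) -> np.ndarray:
        """Draw ``n`` cost types; ``rng`` is a Generator or an integer seed."""

    @property
    @abc.abstractmethod
    def support_upper(self) -> float:
        """Effective upper end of the support (may be ``inf``)."""

    def partial_mean(self, a: float, b: float) -> float:
        """``\\int_a^b c f(c) dc`` (a partial first moment, not a conditional mean)."""
        a = max(a, 0.0)
        if b <= a:
            return 0.0
        upper = min(b, self._quad_upper())
        if upper <= a:
            return 0.0
        value, _ = integrate.quad(
            lambda c: c * self.pdf(c), a, upper, epsabs=_QUAD_TOL, limit=200
        )
        return value

    def _quad_upper(self) -> float:
        upper = self.support_upper
        if np.isfinite(upper):
            return upper
        # bisect for the (1 - _TAIL_MASS) quantile
        hi = 1.0
        while self.cdf(hi) < 1.0 - _TAIL_MASS:
            hi *= 2.0
            if hi > 1e12:  # pragma: no cover - pathological tail
                break
        return hi


class UniformCostModel(CostModel):
    """Cost types uniform on ``[0, c_max]`` — the reference specification.

    All moments are closed-form: ``F(c) = c / c_max`` on the support and
    ``\\int_0^x c f(c) dc = x^2 / (2 c_max)``.
    """

    def __init__(self, c_max: float):
        if not c_max > 0:
            raise ValueError(f"c_max must be > 0, got {c_max}")
        self.c_max = float(c_max)
        self._dist = stats.uniform(loc=0.0, scale=self.c_max)

    def cdf(self, c: float) -> float:
        return float(self._dist.cdf(c))

    def pdf(self, c: float) -> float:
        return float(self._dist.pdf(c))

    @property
    def support_upper(self) -> float:
        return self.c_max

    def partial_mean(self, a: float, b: float) -> float:
        a = min(max(a, 0.0), self.c_max)
        b = min(max(b, 0.0), self.c_max)
        if b <= a:
            return 0.0
        return (b * b - a * a) / (2.0 * self.c_max)

    def sample(self, n: int, rng: np.random.Generator | int) -> np.ndarray:
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        return rng.uniform(0.0, self.c_max, size=int(n))

    def __repr__(self) -> str:
        return f"UniformCostModel(c_max={self.c_max!r})"
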