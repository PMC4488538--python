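"""Parametric two-group scenarios: true Youden Index and calibration.

A simulation scenario pairs a parametric distribution for the
non-diseased group with one for the diseased group.  For continuous
distributions the true Youden Index is

    J = max_c [ F_X(c) - F_Y(c) ]

(strict and non-strict inequalities coincide).  The module computes J
for a given pair, solves for the diseased-group parameter that attains a
target J (the calibration used to build coverage tables), and draws
seeded samples from a scenario.

Supported families and their parameters:

* ``normal``: mean, variance
* ``gamma``: shape kappa, rate theta (density theta^k / Gamma(k) *
  x^(k-1) * exp(-theta x), mean kappa/theta)
* ``student_t``: df (standard, unscaled)
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize, stats

from .estimate import TwoGroupSample

__all__ = [
    "DistributionSpec",
    "ScenarioSpec",
    "true_youden",
    "solve_diseased_parameter",
    "sample_scenario",
    "make_scenario",
]

_FAMILIES = {
    "normal": ("mean", "variance"),
    "gamma": ("shape", "rate"),
    "student_t": ("df",),
}


@dataclass(frozen=True)
class DistributionSpec:
    """One parametric family with its parameters (see module docstring)."""

    family: str
    params: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(
                f"unknown family {self.family!r}; choose from {sorted(_FAMILIES)}"
            )
        names = _FAMILIES[self.family]
        if len(self.params) != len(names):
            raise ValueError(
                f"{self.family} takes parameters {names}, got {self.params!r}"
            )
        object.__setattr__(self, "params", tuple(float(p) for p in self.params))
        if self.family == "normal" and self.params[1] <= 0:
            raise ValueError("normal variance must be positive")
        if self.family == "gamma" and (self.params[0] <= 0 or self.params[1] <= 0):
            raise ValueError("gamma shape and rate must be positive")
        if self.family == "student_t" and self.params[0] <= 0:
            raise ValueError("student_t df must be positive")

    @classmethod
    def normal(cls, mean: float, variance: float) -> "DistributionSpec":
        return cls("normal", (mean, variance))

    @classmethod
    def gamma(cls, shape: float, rate: float) -> "DistributionSpec":
        """Rate-parameterised gamma: mean = shape / rate."""
        return cls("gamma", (shape, rate))

    @classmethod
    def student_t(cls, df: float) -> "DistributionSpec":
        return cls("student_t", (df,))

    def frozen(self):
        """The scipy.stats frozen distribution."""
        if self.family == "normal":
            mean, var = self.params
            return stats.norm(loc=mean, scale=np.sqrt(var))
        if self.family == "gamma":
            shape, rate = self.params
            return stats.gamma(shape, scale=1.0 / rate)
        return stats.t(self.params[0])


@dataclass(frozen=True)
class ScenarioSpec:
    """A calibrated scenario: distribution pair, true J and cut, sizes."""

    non_diseased: DistributionSpec
    diseased: DistributionSpec
    true_j: float
    true_cut: float
    m: int
    n: int

    def __post_init__(self) -> None:
        if self.m < 1 or self.n < 1:
            raise ValueError("sample sizes m and n must be >= 1")

    def with_sizes(self, m: int, n: int) -> "ScenarioSpec":
        return replace(self, m=m, n=n)


_GRID_POINTS = 513
_EXTREME_Q = 1e-4


def true_youden(dx: DistributionSpec, dy: DistributionSpec) -> tuple[float, float]:
    """True Youden Index and optimal cut for a continuous pair.

    g(c) = F_X(c) - F_Y(c) can be multimodal when the densities cross
    twice (unequal variances or shapes), so a coarse grid over the union
    of both distributions' extreme-quantile ranges locates the global
    mode before a bounded scalar refinement sharpens the cut to ~1e-8.
    """
    fx, fy = dx.frozen(), dy.frozen()
    lo = min(fx.ppf(_EXTREME_Q), fy.ppf(_EXTREME_Q))
    hi = max(fx.ppf(1 - _EXTREME_Q), fy.ppf(1 - _EXTREME_Q))
    grid = np.linspace(lo, hi, _GRID_POINTS)
    g = fx.cdf(grid) - fy.cdf(grid)
    if not np.all(np.isfinite(g)):
        raise FloatingPointError("non-finite CDF values while maximising F_X - F_Y")
    k = int(np.argmax(g))
    a = grid[max(k - 1, 0)]
    b = grid[min(k + 1, _GRID_POINTS - 1)]
    res = optimize.minimize_scalar(
        lambda c: fy.cdf(c) - fx.cdf(c),
        bounds=(a, b),
        method="bounded",
        options={"xatol": 1e-10},
    )
    cut = float(res.x)
    return float(fx.cdf(cut) - fy.cdf(cut)), cut


def _with_free_param(template: DistributionSpec, free_param: str, value: float):
    if free_param == "normal_mean":
        if template.family != "normal":
            raise ValueError("normal_mean requires a normal diseased template")
        return DistributionSpec.normal(value, template.params[1])
    if free_param == "gamma_rate":
        if template.family != "gamma":
            raise ValueError("gamma_rate requires a gamma diseased template")
        return DistributionSpec.gamma(template.params[0], value)
    raise ValueError(f"unknown free_param {free_param!r}")


def solve_diseased_parameter(
    dx: DistributionSpec,
    dy_template: DistributionSpec,
    free_param: str,
    target_j: float,
) -> float:
    """Solve for the diseased-group parameter attaining a target J.

    ``free_param`` is ``"normal_mean"`` (J increases with the mean) or
    ``"gamma_rate"`` (J increases as the rate drops below the value that
    matches the group means, since the diseased mean is shape/rate).  A
    sign-changing bracket is grown automatically, then Brent's method
    solves true_youden - target to |dJ| < 1e-6.
    """
    if not 0.0 < target_j < 1.0:
        raise ValueError(f"target_j must lie in (0, 1), got {target_j!r}")

    def f(value: float) -> float:
        return true_youden(dx, _with_free_param(dy_template, free_param, value))[0] - target_j

    if free_param == "normal_mean":
        # J -> 0 as the means coincide; grow the upper end until J > target
        lo = float(dx.frozen().mean())
        hi = lo + 1.0
        for _ in range(60):
            if f(hi) > 0:
                break
            hi = lo + 2.0 * (hi - lo)
        else:
            raise ValueError(
                f"could not bracket target_j={target_j}: J({hi})={f(hi)+target_j:.4f}"
            )
    else:
        # small rate -> large diseased mean -> J near 1; grow hi until J < target
        lo = 1e-4
        hi = 0.5
        for _ in range(60):
            if f(hi) < 0:
                break
            hi *= 2.0
        else:
            raise ValueError(
                f"could not bracket target_j={target_j}: J({hi})={f(hi)+target_j:.4f}"
            )
        if f(lo) < 0:
            raise ValueError(
                f"target_j={target_j} unreachable: J({lo})={f(lo)+target_j:.4f} at both ends"
            )
    return float(optimize.brentq(f, lo, hi, xtol=1e-10, rtol=8.9e-16))


def make_scenario(
    dx: DistributionSpec, dy: DistributionSpec, m: int, n: int
) -> ScenarioSpec:
    """Build a ScenarioSpec with its true J and cut filled in."""
    j, cut = true_youden(dx, dy)
    return ScenarioSpec(dx, dy, j, cut, m, n)


def sample_scenario(
    spec: ScenarioSpec, seed: int | np.random.Generator | np.random.SeedSequence
) -> TwoGroupSample:
    """Draw m non-diseased and n diseased values; deterministic per seed."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = spec.non_diseased.frozen().rvs(size=spec.m, random_state=rng)
    y = spec.diseased.frozen().rvs(size=spec.n, random_state=rng)
    return TwoGroupSample(x, y)
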