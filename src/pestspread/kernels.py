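"""Dispersal kernels parameterized by quantile constraints.

A dispersal kernel is the probability distribution of the distance a
propagule travels from its source.  Kernels here are specified not by
their natural (rate/shape) parameters but by two quantiles with direct
biological meaning:

* ``d50`` — the median dispersal distance (half of all propagules travel
  further);
* ``d99`` — the 99th-percentile distance (only 1% travel further).

Two families are supported.  The exponential family (thin-tailed,
diffusion-like spread) has one free parameter, so fixing either quantile
determines the other: ``d99/d50 = ln 0.01 / ln 0.5 ≈ 6.64``.  The Weibull
family with shape ``k < 1`` is leptokurtic (fat-tailed): holding ``d99``
fixed and shrinking ``d50`` concentrates mass near the origin while
inflating the far tail, producing rare long-distance jumps and satellite
foci.  Both families admit closed-form quantile inversion, so fitting and
sampling are exact.

Distances are in metres throughout.  Displacements are isotropic: the
direction is uniform on ``[0, 2π)`` and independent of distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "KernelSpec",
    "fit_kernel",
    "tail_probability",
    "sample_distances",
    "sample_displacements",
    "PRESETS",
    "preset",
    "EXP_QUANTILE_RATIO",
]

_LN2 = math.log(2.0)
_LN100 = math.log(100.0)

#: Fixed d99/d50 ratio of the one-parameter exponential family.
EXP_QUANTILE_RATIO = math.log(0.01) / math.log(0.5)  # ≈ 6.6439


class KernelError(ValueError):
    """Raised for infeasible or inconsistent quantile constraints."""


@dataclass(frozen=True)
class KernelSpec:
    """A fitted dispersal-distance distribution.

    Parameters
    ----------
    family
        ``"exponential"`` or ``"weibull"``.
    d50, d99
        Median and 99th-percentile dispersal distances (m).
    shape
        Weibull shape ``k`` (dimensionless); ``None`` for exponential.
    scale
        Scale parameter (m): the distribution is ``1 − exp(−x/scale)``
        (exponential) or ``1 − exp(−(x/scale)^k)`` (Weibull).
    """

    family: str
    d50: float
    d99: float
    shape: float | None
    scale: float

    def cdf(self, d):
        """P(distance ≤ d)."""
        d = np.asarray(d, dtype=float)
        if self.family == "exponential":
            return np.where(d < 0, 0.0, -np.expm1(-d / self.scale))
        return np.where(d < 0, 0.0, -np.expm1(-((np.maximum(d, 0.0) / self.scale) ** self.shape)))

    def sf(self, d):
        """P(distance > d), the survival (tail) function."""
        d = np.asarray(d, dtype=float)
        if self.family == "exponential":
            return np.where(d < 0, 1.0, np.exp(-d / self.scale))
        return np.where(d < 0, 1.0, np.exp(-((np.maximum(d, 0.0) / self.scale) ** self.shape)))

    def quantile(self, q):
        """Inverse CDF: the distance exceeded by a fraction 1 − q of propagules."""
        q = np.asarray(q, dtype=float)
        if np.any((q < 0) | (q >= 1)):
            raise KernelError("quantile level must lie in [0, 1)")
        if self.family == "exponential":
            return -self.scale * np.log1p(-q)
        return self.scale * (-np.log1p(-q)) ** (1.0 / self.shape)

    @property
    def mean(self) -> float:
        """Mean dispersal distance (m)."""
        if self.family == "exponential":
            return self.scale
        return self.scale * math.gamma(1.0 + 1.0 / self.shape)


def fit_kernel(family: str, d50: float | None = None, d99: float | None = None) -> KernelSpec:
    """Solve a kernel's natural parameters from its quantile constraints.

    Exponential kernels have one free parameter: give exactly one of
    ``d50``/``d99`` (or both, if mutually consistent).  Weibull kernels
    need both; feasibility requires ``d50 < d99 · ln 0.5 / ln 0.01``
    (i.e. shape < 1, the leptokurtic regime).

    Closed forms::

        exponential:  scale = d99 / ln 100          (= d50 / ln 2)
        weibull:      k     = ln(ln 0.01 / ln 0.5) / ln(d99 / d50)
                      scale = d50 / (ln 2)^(1/k)
    """
    if family == "exponential":
        if d50 is None and d99 is None:
            raise KernelError("exponential kernel needs d50 or d99")
        if d50 is not None and d99 is not None:
            if not math.isclose(d99 / d50, EXP_QUANTILE_RATIO, rel_tol=1e-6):
                raise KernelError(
                    f"inconsistent exponential quantiles: d99/d50 = {d99 / d50:.4f}, "
                    f"family requires {EXP_QUANTILE_RATIO:.4f}"
                )
        if d99 is None:
            d99 = d50 * EXP_QUANTILE_RATIO
        if d99 <= 0:
            raise KernelError("d99 must be positive")
        scale = d99 / _LN100
        return KernelSpec("exponential", scale * _LN2, d99, None, scale)

    if family == "weibull":
        if d50 is None or d99 is None:
            raise KernelError("weibull kernel needs both d50 and d99")
        if not 0 < d50 < d99:
            raise KernelError("require 0 < d50 < d99")
        if d99 / d50 <= EXP_QUANTILE_RATIO:
            raise KernelError(
                "weibull quantiles must satisfy d99/d50 > ln(0.01)/ln(0.5) "
                "(fatter-tailed than exponential)"
            )
        k = math.log(EXP_QUANTILE_RATIO) / math.log(d99 / d50)
        scale = d50 / _LN2 ** (1.0 / k)
        return KernelSpec("weibull", d50, d99, k, scale)

    raise KernelError(f"unknown kernel family {family!r}")


def tail_probability(spec: KernelSpec, d: float):
    """P(dispersal distance > d)."""
    return spec.sf(d)


def sample_distances(spec: KernelSpec, n: int, rng: np.random.Generator,
                     min_distance: float = 0.0) -> np.ndarray:
    """Draw ``n`` dispersal distances by inverse-CDF transform.

    ``min_distance > 0`` samples from the kernel conditioned on
    ``distance ≥ min_distance`` (used by the spread engine, which thins
    away draws that cannot leave the source pixel; conditioning keeps the
    conditional law exact rather than rejection-sampling).
    """
    u = rng.random(n)
    if min_distance > 0.0:
        lo = float(spec.cdf(min_distance))
        u = lo + u * (1.0 - lo)
    if spec.family == "exponential":
        return -spec.scale * np.log1p(-u)
    return spec.scale * (-np.log1p(-u)) ** (1.0 / spec.shape)


def sample_displacements(spec: KernelSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` isotropic planar offsets ``(Δx, Δy)`` in metres.

    Distance comes from the kernel, direction uniform on ``[0, 2π)``,
    independently.
    """
    r = sample_distances(spec, n, rng)
    theta = rng.uniform(0.0, 2.0 * np.pi, n)
    return np.column_stack((r * np.cos(theta), r * np.sin(theta)))


#: Named kernel presets: two non-leptokurtic exponentials and three
#: leptokurtic Weibulls spanning dispersal distance and kurtosis.
PRESETS: dict[str, KernelSpec] = {
    "Exp": fit_kernel("exponential", d99=5.0),
    "Exp+": fit_kernel("exponential", d99=10.0),
    "Wei": fit_kernel("weibull", d50=0.05, d99=5.0),
    "Wei-": fit_kernel("weibull", d50=0.025, d99=2.5),
    "Wei+": fit_kernel("weibull", d50=0.0005, d99=5.0),
}


def preset(name: str) -> KernelSpec:
    """Look up a named kernel preset (Exp, Exp+, Wei, Wei-, Wei+)."""
    try:
        return PRESETS[name]
    except KeyError:
        raise KernelError(f"unknown kernel preset {name!r}; choose from {sorted(PRESETS)}") from None
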