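"""Within-pixel population dynamics.

Each colonized pixel produces propagules once per timestep (nominally a
month) as a deterministic function of its age — the time since it was
first colonized.  Production is zero until reproduction starts at age
``t_0``, reaches half the per-generation maximum ``p_max`` at ``t_50``,
and saturates at ``p_max``.  The saturating form used is

    p(age) = round( p_max · (1 − 2^(−(age − t_0)/(t_50 − t_0))) ),  age > t_0

the simplest monotone curve anchored exactly at both landmarks.  It is
isolated behind :func:`propagule_count` so an alternative maturation
curve can be swapped in without touching the spread engine.

Each propagule establishes with probability ``p_estab`` if it lands on
suitable habitat.  ``r_0`` (nominal rate of spread, m/year) is carried
for configuration completeness and logging but plays no role in the
production curve: realised spread rate is an emergent property of the
kernel and establishment, not an input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PopulationParams", "propagule_count", "propagule_table", "establishing_subset"]


@dataclass(frozen=True)
class PopulationParams:
    """Population-dynamics parameters (defaults: study baseline).

    p_max : maximum propagules per pixel per generation (10 000)
    r_0 : nominal rate of spread, m/year (informational; unused by the
        default production curve)
    t_0 : months from colonization to onset of reproduction (5)
    t_50 : months from colonization to half-maximum production (15)
    p_estab : establishment probability per propagule on suitable
        habitat (0.01)
    """

    p_max: int = 10_000
    r_0: float = 1.0
    t_0: float = 5.0
    t_50: float = 15.0
    p_estab: float = 0.01

    def __post_init__(self):
        if self.p_max < 0:
            raise ValueError("p_max must be >= 0")
        if not 0.0 <= self.p_estab <= 1.0:
            raise ValueError("p_estab must lie in [0, 1]")
        if not 0 <= self.t_0 < self.t_50:
            raise ValueError("require 0 <= t_0 < t_50")


def propagule_count(age, params: PopulationParams):
    """Propagules produced this timestep by a pixel of the given age.

    Vectorized over ``age`` (months since colonization, >= 0).
    """
    age = np.asarray(age, dtype=float)
    frac = -np.expm1(np.log(0.5) * (age - params.t_0) / (params.t_50 - params.t_0))
    out = np.where(age > params.t_0, np.rint(params.p_max * frac), 0.0)
    if out.ndim == 0:
        return int(out)
    return out.astype(np.int64)


def propagule_table(params: PopulationParams, max_age: int) -> np.ndarray:
    """Lookup table ``table[age] = propagule_count(age)`` for 0..max_age."""
    return np.asarray(propagule_count(np.arange(max_age + 1), params), dtype=np.int64)


def establishing_subset(n_prop, p_estab: float, rng: np.random.Generator):
    """Binomial thinning: the establishment candidates among n_prop propagules.

    The spread engine disperses only this subset and establishes every
    candidate that lands on suitable, uncolonized habitat — per
    destination pixel this is distributionally identical to dispersing
    all ``n_prop`` propagules and thinning by ``p_estab`` at the landing
    site (tested), and ~1/p_estab cheaper.
    """
    return rng.binomial(n_prop, p_estab)
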