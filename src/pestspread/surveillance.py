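"""Surveillance schemes and the detection overlay.

A surveillance scheme is a set of sampling points (pixels), a periodic
visiting schedule and a per-visit detection probability.  Three spatial
arrangements are supported, all placing the same total number of points
at equal density so arrangements are comparable:

* ``grid`` — deterministic: each field is divided into ``density``
  near-square congruent cells with a point at each cell centre.  At the
  lowest density (0.5 points/field) one centre point is placed in each
  field of a checkerboard subset, with the subset alternating between
  replicates (``parity``).
* ``random`` — the same per-field point count, but locations are drawn
  uniformly within each field, redrawn each replicate.
* ``strategic`` — border-protecting: one centre point in every interior
  field, with the rest of the budget spaced evenly along the outermost
  suitable pixels of the border fields.

Detection is overlaid on a finished spread history: at each scheduled
visit, every sampling point whose pixel is infested triggers an
independent Bernoulli(p_detect) trial, and the first visit with a
success is the detection time ``T``.  At ``T`` the five outcome
measures are evaluated: time to detection, maximum spread distance from
the incursion point, infested area, number of fields infested, and
cumulative escapes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .landscape import Landscape
from .spread import SpreadRecord

__all__ = [
    "DENSITIES",
    "FREQUENCIES",
    "DETECTION_PROBS",
    "ARRANGEMENTS",
    "SurveillanceScheme",
    "DetectionOutcome",
    "generate_points",
    "build_scheme",
    "sampling_times",
    "overlay_detection",
    "detection_metrics",
]

#: Factorial levels of the study design.
DENSITIES = (0.5, 1, 2, 4, 9, 16, 25)
FREQUENCIES = (1, 2, 3, 4, 6, 8, 12)
DETECTION_PROBS = (0.01, 0.25, 0.75, 1.00)
ARRANGEMENTS = ("grid", "random", "strategic")


class SchemeError(ValueError):
    """Raised for unsupported or infeasible scheme parameters."""


@dataclass(frozen=True)
class SurveillanceScheme:
    """One surveillance strategy: where, how often, how well."""

    arrangement: str
    density: float
    frequency: int
    p_detect: float
    points_x: np.ndarray  # pixel indices
    points_y: np.ndarray
    parity: int = 0

    def __post_init__(self):
        if not 0.0 <= self.p_detect <= 1.0:
            raise SchemeError("p_detect must lie in [0, 1]")
        if self.frequency < 1:
            raise SchemeError("frequency must be >= 1 month")

    @property
    def n_points(self) -> int:
        return len(self.points_x)


@dataclass(frozen=True)
class DetectionOutcome:
    """The five outcome measures at first detection.

    If the invasion was never detected by the simulation horizon,
    ``detected`` is False and the state measures are reported at the
    horizon.
    """

    detected: bool
    T: int
    max_dist: float
    area: float
    n_fields: int
    escapes: int


def _grid_cell_shape(n: int) -> tuple[int, int]:
    """Most-square factorization rows × cols of n points per field."""
    a = int(np.sqrt(n))
    while n % a:
        a -= 1
    return a, n // a


def _checkerboard_fields(landscape: Landscape, parity: int):
    n = landscape.layout.fields_per_side
    return [(fx, fy) for fy in range(n) for fx in range(n) if (fx + fy) % 2 == parity]


def _all_fields(landscape: Landscape):
    n = landscape.layout.fields_per_side
    return [(fx, fy) for fy in range(n) for fx in range(n)]


def _to_pixel(landscape: Landscape, x, y):
    px = landscape.layout.pixel_size
    return int(x / px), int(y / px)


def generate_points(arrangement: str, density: float, landscape: Landscape,
                    rng: np.random.Generator | None = None,
                    parity: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Place sampling points for one arrangement at one density.

    Returns pixel-index arrays ``(xs, ys)``; every point lies on a
    suitable pixel and the total count is ``round(density · n_fields)``
    for every arrangement (checkerboard parity makes the 0.5 total 12 or
    13 on the default farm).
    """
    if density not in DENSITIES and not (density == round(density) and density >= 1):
        raise SchemeError(f"unsupported density {density}")
    lay = landscape.layout

    if arrangement == "grid":
        pts = []
        if density == 0.5:
            for fx, fy in _checkerboard_fields(landscape, parity):
                x0, y0, x1, y1 = landscape.field_bounds(fx, fy)
                pts.append(_to_pixel(landscape, (x0 + x1) / 2, (y0 + y1) / 2))
        else:
            rows, cols = _grid_cell_shape(round(density))
            for fx, fy in _all_fields(landscape):
                x0, y0, *_ = landscape.field_bounds(fx, fy)
                for i in range(rows):
                    for j in range(cols):
                        x = x0 + (j + 0.5) * lay.field_size / cols
                        y = y0 + (i + 0.5) * lay.field_size / rows
                        pts.append(_to_pixel(landscape, x, y))

    elif arrangement == "random":
        if rng is None:
            raise SchemeError("random arrangement needs an rng")
        pts = []
        fields = (_checkerboard_fields(landscape, parity) if density == 0.5
                  else _all_fields(landscape))
        per_field = 1 if density == 0.5 else round(density)
        side = round(lay.field_size / lay.pixel_size)
        for fx, fy in fields:
            x0, y0, *_ = landscape.field_bounds(fx, fy)
            i0, j0 = _to_pixel(landscape, x0, y0)
            # distinct pixels within the field
            flat = rng.choice(side * side, size=per_field, replace=False)
            for f in flat:
                pts.append((i0 + int(f) // side, j0 + int(f) % side))

    elif arrangement == "strategic":
        pts = _strategic_points(landscape, density)

    else:
        raise SchemeError(f"unknown arrangement {arrangement!r}")

    xs = np.array([p[0] for p in pts], dtype=np.int64)
    ys = np.array([p[1] for p in pts], dtype=np.int64)
    if not landscape.suitable[xs, ys].all():
        raise AssertionError("sampling point placed on unsuitable pixel")
    return xs, ys


def _strategic_points(landscape: Landscape, density: float):
    """One centre point per interior field; rest evenly around the border ring."""
    lay = landscape.layout
    n = lay.fields_per_side
    total = round(density * landscape.n_fields)
    interior = [(fx, fy) for fx in range(1, n - 1) for fy in range(1, n - 1)]
    budget = total - len(interior)
    if budget < 0:
        raise SchemeError(
            f"strategic budget {total} smaller than interior-field count {len(interior)}")
    pts = []
    for fx, fy in interior:
        x0, y0, x1, y1 = landscape.field_bounds(fx, fy)
        pts.append(_to_pixel(landscape, (x0 + x1) / 2, (y0 + y1) / 2))
    if budget == 0:
        return pts

    # ordered ring of pixel positions along the outermost field edge
    b0 = round(lay.buffer_width / lay.pixel_size)
    b1 = lay.n_pixels - b0 - 1
    ring = (
        [(x, b0) for x in range(b0, b1 + 1)]
        + [(b1, y) for y in range(b0 + 1, b1 + 1)]
        + [(x, b1) for x in range(b1 - 1, b0 - 1, -1)]
        + [(b0, y) for y in range(b1 - 1, b0, -1)]
    )
    L = len(ring)
    used: set[tuple[int, int]] = set()
    for i in range(budget):
        target = round((i + 0.5) * L / budget) % L
        for delta in range(L):  # nearest suitable, unused ring pixel
            for cand in (ring[(target + delta) % L], ring[(target - delta) % L]):
                if cand not in used and landscape.suitable[cand[0], cand[1]]:
                    used.add(cand)
                    pts.append(cand)
                    break
            else:
                continue
            break
    return pts


def build_scheme(arrangement: str, density: float, frequency: int, p_detect: float,
                 landscape: Landscape, rng: np.random.Generator | None = None,
                 parity: int = 0) -> SurveillanceScheme:
    """Generate points and wrap everything into a SurveillanceScheme."""
    xs, ys = generate_points(arrangement, density, landscape, rng=rng, parity=parity)
    return SurveillanceScheme(arrangement, density, frequency, p_detect, xs, ys, parity)


def sampling_times(frequency: int, t_max: int) -> np.ndarray:
    """Visit months {1, 1 + f, 1 + 2f, ...} within [1, t_max].

    Surveillance starts in the first month regardless of frequency — the
    program begins when monitoring begins, and a sparser frequency only
    stretches the interval between visits.  (With this phase, halving
    the frequency delays detection by about one extra inter-visit wait,
    which is what the study's monthly-vs-yearly detection-time gaps
    show.)
    """
    if frequency < 1:
        raise SchemeError("frequency must be >= 1")
    return np.arange(1, t_max + 1, frequency)


def detection_metrics(record: SpreadRecord, T: int) -> tuple[float, float, int, int]:
    """(max_dist, area, n_fields, cumulative escapes) of a record at time T."""
    ct = record.colonization_time
    mask = (ct >= 0) & (ct <= T)
    xs, ys = np.nonzero(mask)
    px = record.landscape.layout.pixel_size
    ox, oy = record.origin
    max_dist = float(np.hypot((xs - ox) * px, (ys - oy) * px).max())
    area = float(len(xs) * px ** 2)
    n_fields = int(len(np.unique(record.landscape.field_id[xs, ys])))
    escapes = int(record.escapes_by_step[1:T + 1].sum())
    return max_dist, area, n_fields, escapes


def overlay_detection(record: SpreadRecord, scheme: SurveillanceScheme,
                      rng: np.random.Generator | None = None,
                      trial=None) -> DetectionOutcome:
    """Overlay stochastic detection on a finished spread history.

    Detection trials at distinct points and visits are independent; a
    visit inspects a point's own pixel only.  ``trial(t, xs, ys)`` may
    be supplied to control the uniform variates (e.g. to couple runs in
    dominance tests); by default fresh uniforms come from ``rng``.
    """
    if trial is None:
        if rng is None:
            raise ValueError("need an rng (or an explicit trial function)")

        def trial(t, xs, ys):
            return rng.random(len(xs))

    ct = record.colonization_time
    xs, ys = scheme.points_x, scheme.points_y
    for t in sampling_times(scheme.frequency, record.t_max):
        col = ct[xs, ys]
        hit = (col >= 0) & (col <= t)
        if not hit.any():
            continue
        u = trial(int(t), xs[hit], ys[hit])
        if (u < scheme.p_detect).any():
            md, area, nf, esc = detection_metrics(record, int(t))
            return DetectionOutcome(True, int(t), md, area, nf, esc)
    md, area, nf, esc = detection_metrics(record, record.t_max)
    return DetectionOutcome(False, record.t_max, md, area, nf, esc)
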