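"""The simulated farm landscape.

A square raster of 1 × 1 m pixels (size configurable) containing a block
of ``fields_per_side × fields_per_side`` square fields of suitable
habitat, separated by narrow unsuitable divisions (roads, windbreaks)
and surrounded by an unsuitable buffer.  The pest can only establish
inside fields; propagules landing past the outer buffer edge count as
escapes from the surveyed area.

Coordinates are continuous with origin at the domain's lower-left
corner; pixel ``(i, j)`` covers the half-open square
``[i, i+1) × [j, j+1)`` m (times ``pixel_size``) and its location, where
one is needed, is its centre.  Rasters are indexed ``[i, j]`` = (x, y)
pixel indices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LandscapeLayout", "Landscape", "build_landscape", "LayoutError"]


class LayoutError(ValueError):
    """Raised for geometrically invalid layout parameters."""


@dataclass(frozen=True)
class LandscapeLayout:
    """Geometry of the simulated farm.

    Defaults: a 5 × 5 block of 100 × 100 m fields separated by 2 m
    divisions inside a 50 m buffer, rasterized at 1 m — 250 000 suitable
    pixels, total side 608 m.
    """

    fields_per_side: int = 5
    field_size: float = 100.0
    division_width: float = 2.0
    buffer_width: float = 50.0
    pixel_size: float = 1.0

    def __post_init__(self):
        if self.fields_per_side < 1:
            raise LayoutError("fields_per_side must be >= 1")
        for name in ("field_size", "division_width", "buffer_width", "pixel_size"):
            v = getattr(self, name)
            if v <= 0 and not (name == "division_width" and v == 0):
                raise LayoutError(f"{name} must be positive")
            ratio = v / self.pixel_size
            if abs(ratio - round(ratio)) > 1e-9:
                raise LayoutError(f"{name} ({v}) must be an integer multiple of pixel_size")

    @property
    def total_side(self) -> float:
        """Domain side length (m): fields + internal divisions + both buffers."""
        n = self.fields_per_side
        return n * self.field_size + (n - 1) * self.division_width + 2 * self.buffer_width

    @property
    def n_pixels(self) -> int:
        """Raster side length in pixels."""
        return round(self.total_side / self.pixel_size)


class Landscape:
    """Rasterized farm: suitability mask, field-id map and geometry.

    Field ids run 1..n² row-major from the lower-left field; 0 marks
    unsuitable pixels (divisions and buffer).
    """

    def __init__(self, layout: LandscapeLayout):
        self.layout = layout
        self.total_side = layout.total_side
        n_pix = layout.n_pixels
        px = layout.pixel_size

        # classify each pixel by its centre; all widths are integral in
        # pixels, so centre vs corner classification agree.
        centres = (np.arange(n_pix) + 0.5) * px
        band, idx = self._axis_classify(centres)
        fx = np.where(band[:, None] == 0, idx[:, None], -1)  # broadcast x
        fy = np.where(band[None, :] == 0, idx[None, :], -1)
        infield = (fx >= 0) & (fy >= 0)
        self.field_id = np.where(
            infield, fy * layout.fields_per_side + fx + 1, 0
        ).astype(np.int16)
        self.suitable = self.field_id > 0
        # divisions exist only within the field block; the buffer wins
        # wherever either axis lies in the buffer band
        inner = band != 2
        self._division = (inner[:, None] & inner[None, :]) & ~infield
        self._suitable_coords: np.ndarray | None = None

    def _axis_classify(self, u):
        """Per-axis classification of coordinates.

        Returns ``(band, idx)``: band 0 = inside a field (idx = field
        index along the axis), 1 = internal division, 2 = buffer.
        """
        lay = self.layout
        u = np.asarray(u, dtype=float)
        band = np.full(u.shape, 2, dtype=np.int8)
        idx = np.full(u.shape, -1, dtype=np.int64)
        inner = (u >= lay.buffer_width) & (u < self.total_side - lay.buffer_width)
        v = u - lay.buffer_width
        period = lay.field_size + lay.division_width
        f = np.floor_divide(v, period).astype(np.int64)
        within = v - f * period
        fld = inner & (within < lay.field_size)
        band[fld] = 0
        idx[fld] = f[fld]
        band[inner & ~fld] = 1
        return band, idx

    @property
    def n_fields(self) -> int:
        return self.layout.fields_per_side ** 2

    @property
    def suitable_coords(self) -> np.ndarray:
        """(N, 2) int array of all suitable pixel indices (cached)."""
        if self._suitable_coords is None:
            self._suitable_coords = np.argwhere(self.suitable)
        return self._suitable_coords

    def classify(self, x: float, y: float):
        """Class of the continuous point (x, y).

        Returns ``"outside"``, ``"buffer"``, ``"division"`` or the
        integer field id of the containing pixel.
        """
        if not (0 <= x < self.total_side and 0 <= y < self.total_side):
            return "outside"
        i = int(x / self.layout.pixel_size)
        j = int(y / self.layout.pixel_size)
        fid = int(self.field_id[i, j])
        if fid > 0:
            return fid
        return "division" if self._division[i, j] else "buffer"

    def field_bounds(self, fx: int, fy: int):
        """(x0, y0, x1, y1) bounds in metres of field at grid position (fx, fy)."""
        lay = self.layout
        period = lay.field_size + lay.division_width
        x0 = lay.buffer_width + fx * period
        y0 = lay.buffer_width + fy * period
        return x0, y0, x0 + lay.field_size, y0 + lay.field_size


def build_landscape(layout: LandscapeLayout | None = None) -> Landscape:
    """Construct the farm raster from a layout (defaults if omitted)."""
    return Landscape(layout or LandscapeLayout())
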