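"""Physical image grids.

All images in this package live on a square grid of pixel centers with a
physical pitch in millimetres.  The grid origin is at the *center* of the
image, x increases to the right (columns) and y increases upward (rows run
top to bottom), so ``values[i, j]`` sits at physical position
``(x[j], y[i])``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GridSpec", "ImageGrid", "blank_grid"]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a square image grid.

    Parameters
    ----------
    size_mm : float
        Physical side length of the imaged square, mm.
    pitch : float
        Pixel pitch, mm per pixel.
    """

    size_mm: float = 50.0
    pitch: float = 0.1

    def __post_init__(self) -> None:
        if self.size_mm <= 0 or self.pitch <= 0:
            raise ValueError("size_mm and pitch must be positive")

    @property
    def n(self) -> int:
        """Number of pixels along one side."""
        return int(round(self.size_mm / self.pitch))


@dataclass
class ImageGrid:
    """A 2D scalar field (initial pressure or reconstruction) on a physical grid.

    ``values`` is an ``(n, n)`` array; ``pitch`` is mm per pixel; ``origin``
    is the physical coordinate of the grid center.  Reconstructions may hold
    signed values (negative artifacts are meaningful); phantoms are
    non-negative.
    """

    values: np.ndarray
    pitch: float
    origin: tuple[float, float] = (0.0, 0.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("ImageGrid requires a square 2D array")
        if self.pitch <= 0:
            raise ValueError("pitch must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("ImageGrid values must be finite")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def size_mm(self) -> float:
        return self.n * self.pitch

    @property
    def x(self) -> np.ndarray:
        """Physical x coordinate of each column, mm."""
        n = self.n
        return self.origin[0] + (np.arange(n) - (n - 1) / 2.0) * self.pitch

    @property
    def y(self) -> np.ndarray:
        """Physical y coordinate of each row, mm (row 0 on top, y up)."""
        n = self.n
        return self.origin[1] + ((n - 1) / 2.0 - np.arange(n)) * self.pitch

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) physical coordinates of every pixel center."""
        return np.meshgrid(self.x, self.y)

    def blank_like(self) -> "ImageGrid":
        return ImageGrid(np.zeros_like(self.values), self.pitch, self.origin)

    def copy(self) -> "ImageGrid":
        return ImageGrid(self.values.copy(), self.pitch, self.origin, dict(self.meta))


def blank_grid(spec: GridSpec) -> ImageGrid:
    """An all-zero :class:`ImageGrid` matching ``spec``."""
    return ImageGrid(np.zeros((spec.n, spec.n)), spec.pitch)
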