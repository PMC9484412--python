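"""Numerical initial-pressure phantoms.

Three stock phantoms exercise the circular-scan pipeline:

* ``points``  — five 0.5 mm point absorbers, one at the scan center and four
  10 mm off-center on the axes, probing the spatially variant lateral blur;
* ``vessel``  — a procedural binary branching vessel (seeded, reproducible);
* ``spheres`` — eight absorbing disks with diameters 10..3 mm and graded
  initial pressures 0.1..0.8, probing amplitude fidelity.

All phantoms live on a 50 x 50 mm grid by default and are kept zero inside a
2 mm absorbing boundary margin.  Disk rasterization is binary: a pixel
belongs to a disk iff its center lies within the radius.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate as _interp

from .grids import GridSpec, ImageGrid, blank_grid

__all__ = [
    "BOUNDARY_MARGIN_MM",
    "PhantomSpec",
    "make_point_sources",
    "make_vessel",
    "make_absorbing_spheres",
    "make_phantom",
]

#: Width of the absorbing layer at the grid boundary; phantoms stay clear of it.
BOUNDARY_MARGIN_MM = 2.0

DEFAULT_POINT_OFFSET_MM = 10.0
DEFAULT_POINT_DIAMETER_MM = 0.5


@dataclass(frozen=True)
class PhantomSpec:
    """Declarative phantom description used by the CLI and config files."""

    kind: str = "points"  # points | vessel | spheres | custom
    grid: GridSpec = field(default_factory=GridSpec)
    seed: int = 0
    centers: tuple | None = None  # points only, mm
    diameter: float = DEFAULT_POINT_DIAMETER_MM  # points only, mm

    def __post_init__(self) -> None:
        if self.kind not in ("points", "vessel", "spheres", "custom"):
            raise ValueError(f"unknown phantom kind {self.kind!r}")


def _usable_halfwidth(spec: GridSpec) -> float:
    return spec.size_mm / 2.0 - BOUNDARY_MARGIN_MM


def _stamp_disk(img: ImageGrid, center: tuple[float, float], radius: float,
                value: float = 1.0) -> None:
    """Set pixels whose centers fall within ``radius`` of ``center``."""
    x, y = img.x, img.y
    cx, cy = center
    jj = np.flatnonzero(np.abs(x - cx) <= radius + img.pitch)
    ii = np.flatnonzero(np.abs(y - cy) <= radius + img.pitch)
    if jj.size == 0 or ii.size == 0:
        return
    dx = x[jj] - cx
    dy = y[ii] - cy
    inside = (dy[:, None] ** 2 + dx[None, :] ** 2) <= radius ** 2
    sub = img.values[np.ix_(ii, jj)]
    sub[inside] = value
    img.values[np.ix_(ii, jj)] = sub


def make_point_sources(
    grid_spec: GridSpec | None = None,
    centers: list[tuple[float, float]] | None = None,
    diameter: float = DEFAULT_POINT_DIAMETER_MM,
) -> ImageGrid:
    """Binary disks of the given diameter at the given centers (mm).

    Defaults to the five-point layout: one source at the origin and four at
    10 mm offsets along the axes.
    """
    grid_spec = grid_spec or GridSpec()
    if diameter < 2 * grid_spec.pitch:
        raise ValueError(
            f"diameter {diameter} mm must be at least two pixels "
            f"({2 * grid_spec.pitch} mm)"
        )
    if centers is None:
        d = DEFAULT_POINT_OFFSET_MM
        centers = [(0.0, 0.0), (d, 0.0), (-d, 0.0), (0.0, d), (0.0, -d)]
    img = blank_grid(grid_spec)
    radius = diameter / 2.0
    limit = _usable_halfwidth(grid_spec) - radius
    for cx, cy in centers:
        if abs(cx) > limit or abs(cy) > limit:
            raise ValueError(
                f"point source at ({cx}, {cy}) mm does not fit inside the "
                f"usable area (|x|,|y| <= {limit:.2f} mm)"
            )
        _stamp_disk(img, (cx, cy), radius, 1.0)
    img.meta.update(kind="points", diameter=diameter, centers=list(centers))
    return img


def make_absorbing_spheres(grid_spec: GridSpec | None = None,
                           ring_radius: float = 14.0) -> ImageGrid:
    """Eight absorbing disks, diameters 10..3 mm, initial pressure 0.1..0.8.

    The largest, faintest disk sits at the top of a ring of centers and the
    disks shrink (and brighten) clockwise around it.  Placement is validated
    to be non-overlapping and inside the usable area.
    """
    grid_spec = grid_spec or GridSpec()
    diameters = np.arange(10.0, 2.9, -1.0)  # 10, 9, ..., 3
    amplitudes = np.round(np.arange(0.1, 0.81, 0.1), 10)  # 0.1 .. 0.8
    angles = np.deg2rad(90.0 - 45.0 * np.arange(8))  # top, clockwise
    centers = [(ring_radius * np.cos(a), ring_radius * np.sin(a)) for a in angles]

    limit = _usable_halfwidth(grid_spec)
    for (cx, cy), d in zip(centers, diameters):
        if abs(cx) + d / 2 > limit or abs(cy) + d / 2 > limit:
            raise ValueError("disk layout exceeds the usable area")
    for i in range(8):
        for j in range(i + 1, 8):
            dist = np.hypot(centers[i][0] - centers[j][0],
                            centers[i][1] - centers[j][1])
            if dist <= (diameters[i] + diameters[j]) / 2:
                raise ValueError("disk layout produced overlapping disks")

    img = blank_grid(grid_spec)
    for (cx, cy), d, a in zip(centers, diameters, amplitudes):
        _stamp_disk(img, (cx, cy), d / 2.0, float(a))
    img.meta.update(kind="spheres", diameters=list(diameters),
                    amplitudes=[float(a) for a in amplitudes])
    return img


def _spline_points(ctrl: np.ndarray, n: int) -> np.ndarray:
    """Densely sample a smooth curve through the control points (N, 2)."""
    tck, _ = _interp.splprep([ctrl[:, 0], ctrl[:, 1]], s=0,
                             k=min(3, len(ctrl) - 1))
    u = np.linspace(0.0, 1.0, n)
    xs, ys = _interp.splev(u, tck)
    return np.column_stack([xs, ys])


def make_vessel(grid_spec: GridSpec | None = None, seed: int = 0) -> ImageGrid:
    """Procedural binary vessel: a curved tapering trunk with three branches.

    The geometry is drawn from ``seed`` (reproducible) as a smooth spline
    trunk crossing the field of view, with branches rooted on the trunk so
    the phantom is a single connected component.  Values are strictly
    binary.
    """
    grid_spec = grid_spec or GridSpec()
    rng = np.random.default_rng(seed)
    span = min(16.0, _usable_halfwidth(grid_spec) - 2.0)

    # Trunk: lower-left to upper-right with seeded lateral wobble.
    t = np.linspace(0.0, 1.0, 7)
    base = np.column_stack([-span + 2 * span * t, -0.7 * span + 1.5 * span * t])
    normal = np.column_stack([-np.ones_like(t), 1.3 * np.ones_like(t)])
    normal /= np.linalg.norm(normal, axis=1, keepdims=True)
    wobble = rng.uniform(-3.0, 3.0, size=len(t))
    wobble[0] = wobble[-1] = 0.0
    ctrl = base + wobble[:, None] * normal
    trunk = _spline_points(ctrl, 600)

    img = blank_grid(grid_spec)
    limit = _usable_halfwidth(grid_spec) - 1.0

    def draw(path: np.ndarray, w0: float, w1: float) -> None:
        widths = np.linspace(w0, w1, len(path))
        for (px, py), w in zip(path, widths):
            if abs(px) < limit and abs(py) < limit:
                _stamp_disk(img, (px, py), w, 1.0)

    draw(trunk, 0.8, 0.3)

    # Branches rooted on the trunk, fanning off with seeded direction/length.
    n_branches = 3
    roots = rng.choice(np.arange(120, 480), size=n_branches, replace=False)
    for root in roots:
        p0 = trunk[root]
        tangent = trunk[min(root + 5, len(trunk) - 1)] - trunk[root - 5]
        tangent /= np.linalg.norm(tangent)
        side = rng.choice([-1.0, 1.0])
        ang = side * rng.uniform(np.pi / 5, np.pi / 2.8)
        c, s = np.cos(ang), np.sin(ang)
        direction = np.array([c * tangent[0] - s * tangent[1],
                              s * tangent[0] + c * tangent[1]])
        length = rng.uniform(6.0, 11.0)
        bend = rng.uniform(-1.5, 1.5)
        perp = np.array([-direction[1], direction[0]])
        ctrl_b = np.array([p0,
                           p0 + direction * length * 0.5 + perp * bend,
                           p0 + direction * length])
        draw(_spline_points(ctrl_b, 250), 0.45, 0.2)

    img.meta.update(kind="vessel", seed=seed)
    return img


def make_phantom(spec: PhantomSpec) -> ImageGrid:
    """Dispatch on ``spec.kind``; ``custom`` must be supplied as an image."""
    if spec.kind == "points":
        centers = list(spec.centers) if spec.centers is not None else None
        return make_point_sources(spec.grid, centers, spec.diameter)
    if spec.kind == "vessel":
        return make_vessel(spec.grid, spec.seed)
    if spec.kind == "spheres":
        return make_absorbing_spheres(spec.grid)
    raise ValueError("custom phantoms are supplied directly as ImageGrid files")
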