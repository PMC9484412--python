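"""Universal back-projection reconstruction for the circular scan.

Each detector contributes the back-projection term

    b(r0, t) = 2 p_d(r0, t) - 2 t dp_d/dt

evaluated at the time of flight t = |r0 - r| / c0 for every pixel r, with
linear interpolation between time samples.  Contributions are combined with
solid-angle weights; for a full equiangular ring the uniform approximation
1/n_angles is the default, with the exact per-pixel weighting available for
partial or uneven coverage.

The output is deliberately *not* clipped to non-negative values: the
negative rims around strong absorbers are real properties of the inversion
and are the input the projection-domain correction (:mod:`coda.abp`) is
designed to remove.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .forward import PASinogram
from .grids import GridSpec, ImageGrid

__all__ = ["ReconImage", "time_derivative", "back_project"]

log = logging.getLogger(__name__)


@dataclass
class ReconImage(ImageGrid):
    """Reconstructed image; signed values, with provenance of the run."""

    provenance: dict = field(default_factory=dict)


def time_derivative(series: np.ndarray, dt: float) -> np.ndarray:
    """Centered finite difference along the last axis; one-sided at the ends."""
    series = np.asarray(series, dtype=float)
    if series.shape[-1] < 3:
        raise ValueError("need at least 3 samples for a centered derivative")
    return np.gradient(series, dt, axis=-1)


def back_project(sinogram: PASinogram, grid_spec: GridSpec | None = None,
                 weighting: str = "uniform") -> ReconImage:
    """Universal back-projection of a full-ring sinogram onto ``grid_spec``.

    ``weighting`` is ``"uniform"`` (1/n_angles, the full-ring approximation)
    or ``"solid_angle"`` (per-pixel weights proportional to the solid angle
    subtended by each element, normalized per pixel).
    """
    if weighting not in ("uniform", "solid_angle"):
        raise ValueError("weighting must be 'uniform' or 'solid_angle'")
    grid_spec = grid_spec or GridSpec()
    geom = sinogram.geometry
    if geom.n_angles * geom.angle_step < 360.0 - 1e-9:
        raise ValueError("back projection requires full 360 degree coverage")

    t = sinogram.times_ns
    b = 2.0 * sinogram.signals - 2.0 * t[None, :] * time_derivative(
        sinogram.signals, sinogram.dt_ns)

    img = ImageGrid(np.zeros((grid_spec.n, grid_spec.n)), grid_spec.pitch)
    X, Y = img.meshgrid()
    c = sinogram.medium.mm_per_ns
    centers = geom.element_centers()

    acc = np.zeros_like(X)
    wsum = np.zeros_like(X)
    out_of_window = 0
    t_end = t[-1]
    for k in range(geom.n_angles):
        dx, dy = centers[k]
        dist = np.hypot(X - dx, Y - dy)
        tof = dist / c
        out_of_window += int(np.count_nonzero(tof > t_end))
        vals = np.interp(tof, t, b[k], left=0.0, right=0.0)
        if weighting == "uniform":
            w = 1.0
            acc += vals
            wsum += 1.0
        else:
            # Solid angle of a flat element of width a at distance d seen
            # under obliquity psi: dOmega ~ a cos(psi) / d (2D ring analogue).
            inward = -centers[k] / geom.radius
            cos_psi = ((X - dx) * inward[0] + (Y - dy) * inward[1]) / dist
            w = np.clip(cos_psi, 0.0, None) / np.maximum(dist, grid_spec.pitch)
            acc += w * vals
            wsum += w
    if out_of_window:
        log.info("back_project: %d pixel/detector samples beyond the recorded "
                 "window contributed zero", out_of_window)
    values = acc / np.maximum(wsum, np.finfo(float).tiny)
    return ReconImage(values, grid_spec.pitch,
                      provenance={"algorithm": "ubp", "weighting": weighting,
                                  "radius_mm": geom.radius,
                                  "aperture_mm": geom.aperture_diameter,
                                  "n_angles": geom.n_angles,
                                  "out_of_window": out_of_window})
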