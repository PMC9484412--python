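"""File I/O: HDF5 array containers, TIFF/PNG images, CSV traces.

The package's native container is HDF5: images store values + pitch +
provenance, sinograms store the per-angle signals together with the full
acquisition geometry so a reconstruction can be re-run from the file alone.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .forward import AcousticMedium, PASinogram, ScanGeometry
from .grids import ImageGrid
from .recon import ReconImage

__all__ = [
    "save_image", "load_image", "save_sinogram", "load_sinogram",
    "write_tiff", "read_tiff", "write_png", "export_trace_csv",
]


def _json_safe(obj):
    if isinstance(obj, dict):
        return {k: _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def save_image(path, image: ImageGrid) -> None:
    """Write an :class:`ImageGrid`/:class:`ReconImage` to an HDF5 container."""
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=image.values, compression="gzip")
        f.attrs["pitch"] = image.pitch
        f.attrs["origin"] = list(image.origin)
        meta = dict(getattr(image, "meta", {}) or {})
        prov = dict(getattr(image, "provenance", {}) or {})
        f.attrs["meta"] = json.dumps(_json_safe(meta))
        f.attrs["provenance"] = json.dumps(_json_safe(prov))


def load_image(path) -> ImageGrid:
    with h5py.File(path, "r") as f:
        values = f["values"][...]
        pitch = float(f.attrs["pitch"])
        origin = tuple(f.attrs.get("origin", (0.0, 0.0)))
        meta = json.loads(f.attrs.get("meta", "{}"))
        prov = json.loads(f.attrs.get("provenance", "{}"))
    if prov:
        img = ReconImage(values, pitch, origin, provenance=prov)
        img.meta.update(meta)
        return img
    img = ImageGrid(values, pitch, origin)
    img.meta.update(meta)
    return img


def save_sinogram(path, sinogram: PASinogram) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("signals", data=sinogram.signals, compression="gzip")
        f.attrs["dt_ns"] = sinogram.dt_ns
        f.attrs["t0_ns"] = sinogram.t0_ns
        g = sinogram.geometry
        f.attrs["radius_mm"] = g.radius
        f.attrs["n_angles"] = g.n_angles
        f.attrs["aperture_mm"] = g.aperture_diameter
        f.attrs["n_subelements"] = g.n_subelements
        f.attrs["sound_speed_m_s"] = sinogram.medium.sound_speed
        f.attrs["snr_db"] = sinogram.snr_db if sinogram.snr_db is not None else "none"
        f.attrs["seed"] = sinogram.seed if sinogram.seed is not None else "none"


def load_sinogram(path) -> PASinogram:
    with h5py.File(path, "r") as f:
        signals = f["signals"][...]
        dt_ns = float(f.attrs["dt_ns"])
        t0_ns = float(f.attrs["t0_ns"])
        geometry = ScanGeometry(radius=float(f.attrs["radius_mm"]),
                                n_angles=int(f.attrs["n_angles"]),
                                aperture_diameter=float(f.attrs["aperture_mm"]),
                                n_subelements=int(f.attrs["n_subelements"]))
        medium = AcousticMedium(sound_speed=float(f.attrs["sound_speed_m_s"]))
        snr = f.attrs["snr_db"]
        seed = f.attrs["seed"]
    snr_db = None if isinstance(snr, str) else float(snr)
    seed_v = None if isinstance(seed, str) else int(seed)
    return PASinogram(signals, dt_ns, geometry, medium, t0_ns=t0_ns,
                      snr_db=snr_db, seed=seed_v)


def write_tiff(path, image: ImageGrid) -> None:
    """Single-channel float TIFF; pixel pitch recorded as resolution."""
    px_per_mm = 1.0 / image.pitch
    tifffile.imwrite(path, image.values.astype(np.float32),
                     resolution=(px_per_mm, px_per_mm),
                     resolutionunit="NONE",
                     metadata={"pitch_mm": image.pitch})


def read_tiff(path, pitch: float | None = None) -> ImageGrid:
    with tifffile.TiffFile(path) as tf:
        values = tf.asarray().astype(float)
        if pitch is None:
            try:
                meta = tf.shaped_metadata[0]
                pitch = float(meta["pitch_mm"])
            except (TypeError, KeyError, IndexError):
                raise ValueError("TIFF lacks pitch metadata; pass pitch=...")
    return ImageGrid(values, pitch)


def write_png(path, image: ImageGrid) -> None:
    """8-bit preview: non-negative part, max-normalized."""
    import imageio.v3 as iio
    v = np.clip(image.values, 0.0, None)
    if v.max() > 0:
        v = v / v.max()
    iio.imwrite(path, (255 * v).astype(np.uint8))


def export_trace_csv(path, sinogram: PASinogram, angle_index: int) -> None:
    """Two-column CSV (time_ns, amplitude) of one detector's trace."""
    t = sinogram.times_ns
    s = sinogram.signals[angle_index]
    arr = np.column_stack([t, s])
    header = f"time_ns,amplitude (angle index {angle_index})"
    np.savetxt(path, arr, delimiter=",", header=header)
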