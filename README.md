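# coda — circular-scan photoacoustic tomography with finite-aperture detectors

In circular-scanning photoacoustic computed tomography (PACT) a transducer
orbits the object and records laser-induced pressure waves; back-projection
then recovers the initial pressure `p0` (optical absorption). Real
transducers have a finite receiving aperture, and the mismatch with the
point-detector assumption produces two characteristic artifacts: tangential
("spinning") blur that grows with distance from the scan center, and
negative rims at the edges of strong absorbers.

This package implements, end to end, the CODA strategy for suppressing
both: acquire with a small (damped) aperture, then clean the remaining
artifacts with an adaptive back-projection (ABP) correction in the Radon
domain. It provides

* **phantoms** — seeded numerical targets (five point sources, a
  procedural vessel, eight graded absorbing disks) on a physical grid;
* **forward** — an analytic 2D wave-equation simulator of circular scans
  with finite flat apertures, band-limited receive response and calibrated
  noise;
* **recon** — universal back-projection,

  `p0(r) = (1/Ω0) ∫ dΩ0 [ 2 p_d(r0, t) − 2t ∂p_d/∂t ]`,  `t = |r0 − r|/c0`;
* **abp** — the correction: Otsu segmentation of the BP image, Radon
  transform of target and background, per-angle target-shadow intervals
  `[m_θ, n_θ]`, linear background interpolation across them, tangent-shaped
  adaptive attenuation `K·(w/w_max)·R_T` with
  `w = tan(R_T/R_max · (π/2 − k))`, and inversion of the corrected
  projections;
* **metrics** — PSNR, SSIM, line profiles, FWHM and edge-based MTF, plus a
  driver that reproduces the full five-method × three-phantom study table;
* a `coda` command-line tool and YAML-configured, provenance-stamped
  experiment bundles.

## Worked example

```python
from coda import (GridSpec, ScanGeometry, make_vessel, simulate_scan,
                  back_project, run_abp, psnr, ssim)

grid = GridSpec(size_mm=50.0, pitch=0.2)          # 250 x 250 pixels
phantom = make_vessel(grid, seed=0)               # binary branching vessel

scan = ScanGeometry(radius=23.0, n_angles=360, aperture_diameter=2.0)
sino = simulate_scan(phantom, scan, snr_db=40.0, seed=1)   # 360 x 2226
bp = back_project(sino, grid)                     # universal BP, signed
coda = run_abp(bp)                                # ABP correction

for name, img in [("BP", bp), ("CODA", coda)]:
    print(f"{name}: PSNR {psnr(phantom, img):.2f} dB, "
          f"SSIM {ssim(phantom, img):.3f}, "
          f"min/max {img.values.min() / img.values.max():+.3f}")
```

prints

```
BP: PSNR 20.98 dB, SSIM 0.884, min/max -0.349
CODA: PSNR 21.26 dB, SSIM 0.942, min/max -0.002
```

— the correction removes the negative rims (the minimum rises from −35% of
the peak to about zero), suppresses the rotational background, and improves
both quality metrics. The same comparison across apertures {10, 6, 2} mm
and all three phantoms:

```bash
coda run-paper-sim --outdir study/     # 5 methods x 3 phantoms CSV + table
```

Individual stages are also available as `coda phantom`, `coda simulate`,
`coda reconstruct --method {bp,abp}`, `coda evaluate`, and `coda run
--config cfg.yaml` for fully configured, reproducible bundles.

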