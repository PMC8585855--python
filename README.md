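# sliderasl

Super-resolution reconstruction, simulation and quantification for
shifted-slice (SLIDER-type) simultaneous-multi-slice arterial spin
labeling (ASL) perfusion MRI.

ASL measures cerebral blood flow (CBF) without contrast agents, but its
low SNR usually forces 3-4 mm voxels.  Acquiring `n` thick-slice stacks
(each `n` thin slices wide) shifted by one thin slice between stacks
trades slice resolution for SNR at acquisition time and recovers 2-mm
slices computationally: per in-plane voxel the stacked measurements obey

    A x = b,      x = (AᵀA + λI)⁻¹ Aᵀ b

where `A` is the banded boxcar slice-averaging matrix of all shifted
stacks and the Tikhonov inverse is computed through the SVD of `A` with
filter factors `σᵢ/(σᵢ² + λ)`.  The package provides, for researchers
developing or evaluating such protocols:

* **geometry** — protocol arithmetic (slice grids, coverage, SMS band
  placement, slice-group timing) with presets for two/three/four-shift
  protocols (4/6/8 mm thick slices) and the interleaved two-pass 2-mm
  reference;
* **forward / recon** — the averaging operator and the SVD/Tikhonov
  inversion with spectral diagnostics;
* **simulate** — a digital brain phantom and acquisition simulator with
  g-factor-amplified thermal noise and AR(1) physiological noise, so the
  entire pipeline is testable without scanner data;
* **metrics** — even/odd sum-difference spatial SNR, temporal SNR,
  one-slice-shift blur correlation, and Gaussian blur matching;
* **snr** — the analytic SNR-efficiency model (averaged noise variance
  with effective measurement counts, √N_set sampling gain);
* **quant** — single-compartment CBF quantification with slice-dependent
  post-labeling-delay correction and ROI means;
* **io / pipeline / cli** — NIfTI + JSON-sidecar I/O, a reproducible
  staged pipeline, and a `sliderasl` command with `simulate`,
  `reconstruct`, `metrics`, `snr-theory`, `quantify` and `run`
  subcommands.

Conventions: the slice direction is the third array axis, slice 0 is the
most inferior slice, and thick-slice values are the *mean* of their
thin-slice footprint, so perfusion and M0 units match across resolutions.
See `docs/methods.md` for the model, noise calibration and limitations.

## Worked example

Simulate the two- and four-shift protocols and the thin-slice reference on
a shared phantom, reconstruct at λ = 0.1, and compare metrics:

```python
from sliderasl.pipeline import run_pipeline

run_pipeline({"presets": ["slider2", "slider4", "reference"],
              "n_meas": 20, "lambda": 0.1,
              "phantom": {"shape": [32, 32, 96], "seed": 7},
              "write_volumes": False},
             seed=42, out_dir="demo")
```

`demo/snr_reports.json` from this exact run:

| condition | sSNR | tSNR | blur r | GM CBF (ml/100 g/min) |
|-----------|------|------|--------|----------------------|
| reference | 3.65 | 0.57 | 0.44   | 60.46 |
| slider2   | 4.98 | 0.72 | 0.38   | 59.90 |
| slider4   | 7.33 | 0.91 | 0.46   | 59.98 |

Reading the numbers: at λ = 0.1 the two-shift reconstruction gains ~37 %
spatial SNR over the matched-scan-time thin-slice reference and the
four-shift version ~101 %, temporal SNR is ordered the same way, and blur
(the one-slice-shift correlation) grows with the shift count while the
ground-truth GM perfusion of 60 ml/100 g/min is recovered within ~1 % in
all conditions.  The same trade-off drives the λ choice: larger λ raises
SNR but blurs the slice direction, and λ ≈ 0.1 is the recommended
operating point.

The analytic calculator gives the idealised efficiency bound for a noise
budget:

```python
from sliderasl import NoiseBudget, snr_efficiency_ratio
snr_efficiency_ratio(NoiseBudget(n_set=2, n_meas=40, n_full=40,
                                 var_thermal=1.0, var_physio=0.0))
# 1.4142...  (sqrt(N_set) in the thermal-only, matched-budget limit)
```

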