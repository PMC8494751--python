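# paraft

A toolbox for reconstructing and analyzing multispectral photoacoustic
(optoacoustic) tomography data. Pulsed laser light absorbed by tissue
launches ultrasound waves; recording them on a circular transducer array at
several illumination wavelengths allows the absorbed-energy image to be
reconstructed per wavelength and unmixed into oxy-/deoxy-hemoglobin maps and
oxygen saturation, SO₂ = [HbO₂]/([HbO₂]+[Hb]). The package is aimed at
preclinical imaging groups who want a transparent, configuration-driven
alternative to vendor processing, and at methods developers who need exact
synthetic ground truth to validate reconstruction chains.

## What it does

* **Data model** — HDF5 frame stores (frames × transducers × time samples
  with per-frame wavelength/energy/timestamp metadata and a detector-geometry
  group), read lazily one frame at a time.
* **Analytical phantoms** — random paraboloid absorbers with closed-form
  acoustic signals for ideal point detectors, and a dynamic multispectral
  generator emulating a breathing-gas challenge with exponential SO₂
  transitions and known ground truth.
* **Forward models** — sparse operators `M = (1/2πν_s)·D_t·W` in two
  discretizations: curve sampling with bilinear interpolation (`dimmi`) and
  exact circle–cell arc lengths (`cdmmi`).
* **Reconstruction** — LSQR, a non-negative accelerated projected-gradient
  solver (never emits a negative pixel), and 2-D universal backprojection;
  solving `min‖MI − d‖₂ (+ λ‖I‖₂)` per frame, parallelized across frames with
  worker-count-invariant results.
* **Preconditioning** — laser-energy calibration, mean subtraction, Wiener
  deconvolution, zero-phase band-pass (50 kHz–7 MHz default), Beer's-law
  water-absorption compensation, temporal regridding.
* **Multispectral filtering** — sliding-window assembly and fixed-gain
  Kalata α / αβ tracking filters with gains derived from a tracking index.
* **Unmixing** — pseudoinverse or non-negative least squares against a
  shipped HbO₂/Hb absorption table (700–900 nm, CSV-overridable), plus SO₂.
* **Metrics & statistics** — bias/L1/L2 error norms, SSIM, relative
  residual, negative-pixel indicator maps, binned Bland–Altman, Welch
  t-score maps, relative Cohen's d, centered correlation maps, Fisher-Z
  comparison, and a 7-parameter exponential gas-response fit.
* **Pipeline** — YAML-configured end-to-end runs
  (load → precondition → reconstruct → filter → unmix → metrics) with a
  provenance record that reproduces outputs bit-exactly.

## Worked example

Simulate a 36-frame synthetic gas challenge and process it with the
constrained chain (non-negative reconstruction, α Kalata filter, constrained
unmixing):

```python
import numpy as np
from paraft import make_image_coords, ring_geometry, open_dataset
from paraft.phantom import simulate_dynamic_dataset
from paraft.studies import make_gas_challenge_spec, gas_challenge_study

result = gas_challenge_study("gas.h5", seed=1)
print(f"median SO2-waveform correlation, unconstrained: "
      f"{result.correlation_unconstrained:.3f}")
print(f"median SO2-waveform correlation, constrained+alpha: "
      f"{result.correlation_constrained_alpha:.3f}")
print(f"negative concentrations, constrained: {result.negative_conc_constrained}")
```

prints (seed 1):

```
median SO2-waveform correlation, unconstrained: 0.312
median SO2-waveform correlation, constrained+alpha: 0.381
negative concentrations, constrained: 0
```

The constrained chain tracks the inhaled-gas waveform better because the
non-negativity constraint removes unphysical concentration values and the α
filter suppresses frame-to-frame noise, at the price of a small tracking lag.
It also guarantees SO₂ ∈ [0, 1] wherever defined, while the unconstrained
chain produces tens of thousands of negative concentration values on the
same data.

A full pipeline run is driven by a YAML file:

```yaml
input: gas.h5
recon: {method: nnapcg, model_kind: cdmmi, resolution: 50}
spectral: {filter: alpha, tracking_index: 2.0}
unmix: {method: nonneg}
```

```bash
paraft run config.yaml --output-dir out/
```

which writes `images.h5`, `unmixed.h5`, `metrics.csv`, and
`provenance.json` (re-runnable via `paraft.pipeline.run_from_provenance`).

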