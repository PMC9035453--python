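# rmoct

Simulation toolkit for **reflection-matrix optical coherence tomography
(RM-OCT) wavefront shaping**: delivering light energy deep into turbid media
by measuring a scattering sample's reflection matrix, calibrating its
time-reversal decomposition with Tikhonov regularization, and steering
multiply scattered photons into high-transmission ("open") channels with a
phase-only spatial light modulator.

The package is aimed at computational-optics researchers who want a
reproducible, desk-scale testbed for matrix-based deep-tissue focusing: it
bundles a calibrated scattering-medium simulator, so every stage of the
published three-step protocol — acquire, invert, re-acquire — can be run and
scored end to end without hardware.

## The method

A raster of 31 x 31 focused inputs scans a 70 x 70 um field of view; for
each input the complex reflected field (heterodyne lock-in detection in the
physical instrument, an idealized quadrature model here) fills one column of
the reflection matrix, `E_out = R E_in`.  The SVD

```
R = U S V^T,    s_1 >= s_2 >= ... >= s_n
```

is the time-reversal decomposition: strong singular states carry the
single-scattering-like, strongly backscattering channels.  Inversion is
stabilized with Tikhonov filter factors

```
f_i = s_i^2 / (s_i^2 + lambda^2)
```

with `lambda` selected on a logarithmic grid (1e-8..1e8) by a deviation
criterion `eta = ||e_est - e_mea|| / ||e_mea||` against re-measured probe
inputs.  The **model energy matrix** `E_m = V F S V^T` acts as a camera
inside the sample: the squared modulus of its i-th column, reshaped to the
scan grid, maps where the energy launched at scan point i ends up.  Matched
incident wavefronts `k(i) = V F S^+ U^dagger e_des` are reshaped to 2D phase
maps, projected to phase-only modulation, and re-acquired against the same
frozen medium; comparing singular spectra and energy maps before and after
quantifies open-channel redistribution and delivered-energy enhancement.

## Worked example

```python
from rmoct.pipeline import ExperimentConfig, run_step1, run_step2, run_step3

cfg = ExperimentConfig()            # 64x64 grid, 31x31 scan, defaults in docs/methods.md
s1 = run_step1(cfg, depth_smfp=14.4)     # acquire + decompose + calibrate
wfs = run_step2(s1)                      # invert RM for matched wavefronts
s3 = run_step3(s1, wfs)                  # re-acquire shaped, compare

print(f"selected lambda     : {s1.reg.lam:.3g}")
print(f"pooled enhancement  : {s3.pooled_enhancement:.1f}")
print(f"central fraction    : {s1.focus_reports[(16, 16)].central_fraction:.3f}")
```

prints, for the default seed,

```
selected lambda     : 0.316
pooled enhancement  : 11.8
central fraction    : 0.044
```

meaning: the deviation criterion picked `lambda = 0.316` from the grid; at
14.4 SMFP the unshaped reversal map keeps only ~4% of its energy in the
central disk (the beam is thoroughly defocused); and shaping multiplies the
energy delivered into the central disk at the probe points by ~12 — the
order-of-magnitude enhancement at ultra-deep positions that motivates the
method.

A command-line interface wraps the same pipeline:

```
rmoct run --seed 1 --out results/          # full 5-depth protocol + report
rmoct compare --depth 7.2 --out results/   # single-depth before/after JSON
```

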