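# Methods

## The problem and the model

`rmoct` simulates wide-field reflection-matrix optical coherence tomography
(RM-OCT) of a turbid medium and the wavefront-shaping protocol built on it:
measure the monostatic reflection matrix R of a scattering sample with a
raster of focused inputs, decompose it by SVD (the time-reversal
decomposition), stabilize its inversion with Tikhonov filter factors, map the
internal energy distribution with the model energy matrix
`E_m = V F S V^T`, invert R for matched incident wavefronts, and re-acquire
with the shaped inputs to quantify photon-class redistribution and
delivered-energy enhancement at depth.

The scattering medium is a stack of thin random phase screens with Gaussian
autocorrelation, separated by free-space gaps and traversed twice (in and
out) in front of a reflective imaging plane.  Propagation is split-step
angular spectrum.  Each elementary operator (free-space step, unit-modulus
screen, absorber window) is a symmetric matrix in the pixel basis, so the
double-pass operator is symmetric: the medium is reciprocal by construction,
which the reciprocity tests verify to machine precision.

Scattering strength is calibrated in scattering-mean-free-path (SMFP) units:
a Gaussian random phase of variance `sigma^2` transmits the ballistic (DC)
component with power `exp(-sigma^2)`, so `n` screens with
`sigma = sqrt(d/n)` realize an optical depth of `d` SMFP exactly; a
Monte-Carlo estimator cross-checks this at build time.  Physical thicknesses
(for example, 760 um at 14.4 SMFP for a 52.8 um SMFP) are carried as
metadata; the simulated stack is geometrically compressed (4 um gaps) so the
70 x 70 um field of view can contain the beam.

## Study conditions (defaults) and why

| parameter | default | rationale |
|---|---|---|
| field grid | 64 x 64 px, 1.09 um pitch | 70 x 70 um field of view |
| wavelength | 0.8 um | near-infrared ultrafast band |
| scan raster | 31 x 31, 2 px spacing | 961 focused inputs over the FOV |
| pupil radius | n/4 px (NA ~ 0.18) | first Airy null ~ 1.2 scan steps |
| depths | 2.4, 4.8, 7.2, 9.6, 14.4 SMFP | the published depth series |
| screens | 2 per SMFP, corr. length 2 px, 4 um gaps | developed speckle at depth |
| absorber | 8 px cosine frame | lateral losses of wandering light |
| detection noise | absolute floor 4e-3 per pixel | lock-in background; deep RMs noise-dominated |
| lambda grid | 1e-8 .. 1e8, 33 log-spaced points | the published regularization range |
| modulation | phase-only | the spatial light modulator constraint |

The 2 px screen correlation length was chosen so that multiple scattering
actually develops speckle within the compressed stack; with smoother screens
the frozen-medium double pass retains an angular-memory focus at every depth
and no depth degradation appears.  The cost is that shallow (2.4 SMFP) maps
are slightly below the ideal Airy encircled energy, and the outermost rows of
the scan raster overlap the absorbing frame on the 64 px grid, so the
"diffraction-limited" criterion is evaluated on the interior probe report
set (6,6), (6,26), (16,16), (26,6), (26,26).

The detection noise is an absolute per-pixel floor rather than a
signal-relative SNR.  A floor models a heterodyne detector whose background
does not shrink with the depth-attenuated signal: shallow acquisitions are
effectively noiseless while the deep reflection matrices become
noise-dominated, which is the regime in which the Tikhonov calibration and
the singular-value threshold matter at all.

## Pipeline details

**Monostatic projection and the E_m gauge.**  The raw acquisition stores the
camera-pixel matrix (4096 x 961).  For decomposition the outputs are
projected onto the input (focused-spot) basis, `R_s = B^T R`; reciprocity
makes `R_s` symmetric and it is symmetrized explicitly to average detection
noise.  `E_m = V F S V^T` is only well defined once the SVD phase gauge is
fixed: `decompose` aligns each singular pair with the Takagi factorization of
a symmetric matrix (`conj(u_j) ~ v_j`), under which `E_m` is exactly the
conjugate of the Tikhonov-filtered RM — the "denoised reversal result" whose
squared columns are the per-scan-point internal intensity maps.

**Deviation-criterion calibration.**  A random 10% of the scan inputs is
measured a second time with independent noise; each measured probe output is
passed through the filtered inverse `V F S^+ U^dagger` and compared with the
pattern that should have been delivered (a delta at the probe's scan
position).  `eta(lambda)` is the pooled normalized residual; the grid
minimizer is selected, ties resolving toward the smallest lambda.  Noiseless
systems therefore select the smallest grid value; the selected lambda grows
with the injected noise level.  Step 3 repeats this calibration on the
shaped acquisition.

**Matched wavefronts.**  `k(i) = V F S^+ U^dagger e_des`, normalized to unit
power so enhancement measures redistribution, not injected power.  The
default desired output `e_des` is an Airy-weighted patch at the target — the
diffraction-limited achievable focus.  A delta target (`desired_output:
delta`) is also provided: it requests content beyond the diffraction limit,
which pushes the inverse into the weak singular channels.  The two settings
probe different physics:

* the patch inversion maximizes *delivered energy*: at 14.4 SMFP the
  central-disk energy at the probe points grows by roughly an order of
  magnitude (pooled ratio ~ 10-25 across seeds), and against a zero-depth
  mirror the protocol is a near-no-op (ratio 0.8-0.9, the phase-only
  residual);
* the delta (full-inverse) wavefronts maximize *channel redistribution*: the
  count-based share of singular states above the random-matrix threshold
  rises by ~ 5 percentage points at 7.2 SMFP, the simulator's analogue of
  steering multiply scattered photons into open channels.  Under the patch
  default this share does not rise — shaping diagonalizes the RM and
  dismantles the collective singular modes of the unshaped matrix — so the
  redistribution experiment uses the delta wavefronts explicitly.

**Photon classification.**  Singular values above a threshold are the
single-scattering-like (before shaping) or open-channel (after shaping)
part.  The default threshold is the Marchenko-Pastur bulk edge with the
noise scale estimated robustly from the median squared singular value.  Both
energy-weighted (`sum s_j^2` shares) and state-count bookkeeping are
implemented; the published percentages do not disambiguate the two, and in
this simulator only the count-based share shows the expected
before-to-after gain, so the pipeline reports count-based fractions by
default and the energy-weighted ones on request.  The before/after
comparison always reuses the before-shaping threshold.

**Enhancement.**  Delivered energy is scored on the model-energy maps (the
experimentally accessible observable): the in-disk energy (radius 1.5 scan
pixels, about the first Airy null) at the incident point, shaped over
unshaped, pooled over the five probe points.  Inputs are unit-power and maps
share the acquisition scale, so the ratio is physical.

## What the simulator does and does not capture

It captures: reciprocity, speckle statistics of the deep reflection matrix,
ballistic attenuation `exp(-d)`, depth-monotone degradation of the reversal
maps (median central fraction falls from ~0.8 at 2.4 SMFP to ~0.03 at 14.4;
peak-shift detections increase; peak intensity falls by ~2.5 orders), noise-
driven selection of the regularization strength, and order-of-magnitude
delivery enhancement from RM inversion at depth.

It does not capture: coherence (time) gating — every gate-passing photon in
the model has touched the imaging plane, so there is no ungated multiple-
scattering background beyond the detector floor and the published tiny
single-scattering percentages (~1%) are not reproduced quantitatively;
vectorial light; bulk backscatter away from the imaging plane; dynamic
decorrelation.  Two known consequences are documented: the unshaped deep
relative peak decays to ~3e-3 of the shallow reference rather than below
1e-3 (the frozen-medium double pass coherently enhances deep return peaks),
and passing tests demonstrate behavior of this surrogate, not of the
physical phantom.

## Numerical choices

SVD via LAPACK `gesdd`; filter factors `s^2/(s^2+lambda^2)` with the
`lambda = 0` limit defined as the pseudoinverse; the printed inversion form
with a plain transpose on U is replaced by the conjugate transpose
(`V F S^+ U^dagger`), the form that reproduces the dense ridge solve to
1e-10.  Peak ties break lexicographically; FWHM by radial-profile
interpolation at half maximum; phases live in (-pi, pi] and all phase-map
resampling interpolates the unit-modulus phasor, never the wrapped phase.
Degenerate inputs (all-zero maps, empty spectra, zero-norm references,
mismatched phantom seeds) raise informative errors.

## Problem sizes used in tests and the acceptance script

The full protocol (five depths, 961 inputs, shaping at 7.2 and 14.4 SMFP) is
run with 3 seeds in the test suite and 3-5 seeds in
`scripts/acceptance.py`; the Monte-Carlo ballistic check uses 150 stack
realizations; the phase-only penalty uses 16 random unitaries at N = 256.
These sizes are the package's desk-scale profile; all experiments accept
larger seed sets through the same functions.
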