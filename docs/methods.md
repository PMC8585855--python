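# Methods

## The reconstruction problem

A shifted thick-slice (SLIDER-type) SMS ASL protocol acquires `n_set`
stacks of thick slices (`n_set` thin slices wide), each stack shifted along
the slice direction by one thin slice.  Because slice selection averages
the magnetisation across the slice, the acquisition is linear in the
thin-slice signal and decouples over in-plane position: for each in-plane
voxel the stacked measurements satisfy `A x = b`, where `A` is a banded
averaging matrix (rows = thick slices of all shift sets, columns = thin
slices) built from the boxcar slice profile.  The package works in the
*mean* signal convention: a thick-slice value is the mean of its thin-slice
footprint, so M0 and perfusion units are identical at both resolutions and
every row of `A` sums to one in the slab interior.

The thin-slice profile is recovered by Tikhonov-regularised inversion
through the SVD of `A`:

    x = V diag(s_i / (s_i^2 + lambda)) U' b

At `lambda = 0` singular values below `1e-10 * s_max` are dropped
(Moore-Penrose fallback, reported in the diagnostics).  `lambda` acts on
the singular values of the mean-convention operator, whose largest singular
value is ~1 for every protocol, so the same `lambda` is comparable across
SLIDER2/3/4.  The boundary rows of shifted sets that extend past the
nominal slab keep only their in-slab weights, without renormalisation
(zero-signal-outside-slab assumption); this keeps the published thin-slice
counts (48/72/96) and leaves `A` full rank (condition numbers ~60-130), so
noise-free data invert exactly at `lambda = 0`.  Label/control pairs are
subtracted into perfusion-difference frames *before* reconstruction; by
linearity the order is immaterial for the estimate, and M0 volumes are
reconstructed separately with the same operator and `lambda`.

## Geometry conventions

Slice 0 is the most inferior slice; thin-slice centres live at
`(i + 0.5) * thin_thickness` in a half-open slab.  Thick slice `t` of shift
set `k` covers thin slices `t*n_set + k .. t*n_set + k + n_set - 1` (the
shift sign is configurable).  Thick slice `t` belongs to SMS slice group
`t mod n_groups`; group `g` is read out at `g * group_readout_ms` (45 ms,
270 ms total for six groups).  The printed band spacings (20/30/40 mm for
4/6/8 mm slices) equal `(n_groups - 1) * thick_thickness`, i.e. the
edge-to-edge gap between adjacent simultaneous bands of the interleaved
excitation order; the constructor validates that identity.  The thin-slice
reference is modelled as two interleaved passes (even slices, then odd
slices) with a 100 % gap per pass, merged into one gap-free 2-mm stack.
Band geometry is validated but otherwise unused: SMS unaliasing is upstream
of this package and the simulator emits already-unaliased volumes.

## Simulator

The phantom is a nested-ellipsoid head (CSF core, WM shell, GM rim) with a
seeded smooth radial modulation so that tissue boundaries cut obliquely
across many thin slices.  Defaults: GM/WM/CSF perfusion 60/20/0
ml/100 g/min, M0 1000/700/1300 a.u., 2 mm isotropic voxels.  The GM
"probability" map is binary by construction, so thresholding at 0.9
recovers the GM label exactly.

The perfusion-difference signal is generated by inverting the
single-compartment quantification model, `dM = k(PLD_i) * M0 * CBF`, with
the slice-dependent PLD of the (set 0) slice group containing each thin
slice.  This makes simulate -> reconstruct -> quantify exactly
self-consistent and exercises the PLD correction; the resulting GM dM/M0
is ~0.6 %, a realistic single-average difference amplitude.  Thin slices
overlapped by several shifted groups inherit the unshifted group's timing;
at 45 ms granularity the alternatives are nearly indistinguishable.  No T1
decay of the label, motion, or background-suppression efficiency is
modelled.

Noise model and its calibration:

* `var_thermal` is the thermal variance of one perfusion-difference image
  at *thin-slice* signal calibration; each frame of a pair receives half of
  it.  Raw coil noise per image is independent of slice thickness while
  signal grows with it, so in mean-signal units the simulator scales the
  thermal sd of a thick-slice acquisition by `thin/thick = 1/n_set`.  The
  thick-slice SNR advantage that drives super-resolution SNR efficiency
  therefore lives entirely in the noise bookkeeping.  A per-voxel in-plane
  g-factor map (>= 1) multiplies the thermal sd only.
* Physiological noise is an AR(1) process over label/control pairs with
  marginal variance `var_physio` and lag-1 correlation `rho`, added in
  image space after thick-slice projection (it is a property of the
  acquired measurement), split `+-p/2` across the pair so the difference
  image carries exactly `var_physio`, and not amplified by g.
* Defaults `var_thermal = 100`, `var_physio = 20`, `rho = 0.5`: GM
  single-difference SNR ~0.6 and 40-pair spatial SNR of a few units —
  thermal-dominated at 2 mm, with a minority correlated physiological
  share, which is the regime thin-voxel ASL difference images occupy.

What the simulator does *not* emulate: in-plane structure of real coil
noise, EPI distortion, motion, slice-profile imperfections, and — most
consequentially — any physiological-noise spectrum other than AR(1) (see
the last section).  Passing tests therefore validate the algebra, the
noise bookkeeping and the metric implementations, not in-vivo effect sizes.

## SNR-efficiency model

For one condition the averaged noise variance is
`g^2 var_thermal / N + var_physio / N'`, with `N'` the effective number of
measurements of the correlated physiological noise; for the simulator's
AR(1) process, `N' = N / (1 + 2 sum_{k<N} (1 - k/N) rho^k)`
(asymptotically `N (1-rho)/(1+rho)`), which `ar1_effective_n` provides.
The SNR-efficiency ratio multiplies the averaged-noise sd ratio by
`sqrt(N_set)` — the idealised sampling argument that every thin-slice
position is covered by every measurement of every set.

The package's own simulations quantify how far boxcar encoding falls short
of that idealisation.  `sqrt(N_set)` is exact for an *orthogonal* encoding
(Hadamard-type, out of scope here); for boxcar averaging the Tikhonov
deblurring penalty `mean[(s_i/(s_i^2+lambda))^2]` is ~4.9 (two shifts) and
~10.3 (four shifts) at `lambda = 0.01`, so near-zero regularisation
*loses* ~11 % spatial SNR against the matched-scan-time thin reference,
and the net gain only appears at practical regularisation: ~+37 % (two
shifts) and ~+101 % (four shifts) at `lambda = 0.1` in the thermal regime,
where regularisation blur suppresses the ill-conditioned high-frequency
slice modes.  This is why `lambda ~ 0.1` is the recommended operating
point, and why larger `lambda` keeps raising SNR while blurring more.

## Evaluation metrics

* Spatial SNR: even/odd perfusion frames are averaged, added and
  subtracted; sSNR = mean(sum image) / (sd(difference image)/sqrt(2)) in
  the mask.  Note the even/odd subtraction evaluates the noise spectrum at
  the Nyquist frequency of the pair sequence.
* Temporal SNR: per-voxel mean/sd over frames, averaged in the mask
  (default; ratio-of-means also exposed).  Zero-variance voxels are
  excluded and counted; fully degenerate inputs return flagged sentinels,
  never a silent division by zero.
* Slice blurring: Pearson correlation between the volume and its
  one-slice-shifted copy over the overlapping slab, all voxels collapsed
  (optional mask policy).  Blur matching smooths along the slice axis only
  (Gaussian, reflect boundaries to avoid edge darkening) and bisects the
  FWHM until the correlation meets the target within 1e-3; correlation is
  monotone in FWHM, so bisection is exact up to that tolerance.

## CBF quantification

Single-compartment model with consensus constants (labeling efficiency
0.85, blood T1 1650 ms, partition coefficient 0.9 ml/g), labeling duration
and PLD from the protocol (1500/1800 ms defaults).  The slice-dependent
PLD correction adds each thin slice's group readout offset to the nominal
PLD.  Voxels with M0 below 10 % of the robust (99th-percentile) maximum
are masked, counted and reported.  Because Tikhonov reconstruction at
`lambda > 0` attenuates both dM and M0 by the same spectral filter, the
dM/M0 ratio — and hence CBF — is unbiased to first order; the simulation
round trip recovers the 60 ml/100 g/min GM value within 2 % at
`lambda = 0.1`.  Blur from larger `lambda` or more shifts mixes tissue
signals and biases small-structure CBF toward neighbouring tissue — the
direction, not the in-vivo magnitude, is what the phantom can show.

## Problem sizes

Simulation-backed tests run at 16-32 voxel in-plane matrices with the full
96-slice thin grid, 12-40 pairs per set and 5-20 replicate seeds; the
reconstruction operators are at most 96 x 96, so the SVD is exact and
cheap.  These sizes put Monte-Carlo standard errors at the percent level,
adequate for the orderings and ratios under test.

## Known limitations and an honest negative result

Under this noise model, blur-matched spatial SNR of the two-, three- and
four-shift protocols does **not** converge: the even/odd difference image
suppresses AR(1) physiological noise by `(1-rho)/(1+rho)`, leaving the
sSNR noise floor `var_thermal/n_set^2 + var_physio (1-rho)/(1+rho)`, whose
`n_set`-dependent thermal term cannot be hidden by any parameter choice
without simultaneously erasing the (thermal-driven) temporal-SNR ordering.
The two claims — blur-matched sSNR convergence *and* tSNR ordering — are
mutually exclusive for every AR(1) parameter setting, while in-vivo data
show both.  The resolution is spectral: real ASL physiological noise
(cardiac/respiratory aliasing at a 5-s TR) carries power at the even/odd
frequency that an AR(1) process lacks.  A two-component physiological
model (AR(1) drift plus a white aliased component) would reconcile the
pair and is the natural next step for the simulator.
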