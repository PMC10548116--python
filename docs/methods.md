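# Methods

This note documents the models behind `spifi`, the parameters that matter,
what the synthetic data do and do not emulate, and the numerical choices
made where the design was genuinely open.

## Forward model

The reticle transmission is modelled in polar coordinates as

    M(r, theta) = 1/2 {1 + cos[k (r0 + r) theta]},

with chirp rate `k` (mm^-1 per radian), pattern offset `r0` (mm) and the
cursor coordinate `r` measured from the inner end of the active span.
While the mask spins at `nu_c` rotations per second, the pixel at `r`
blinks at `k (r0 + r) nu_c` Hz; equivalently the pattern presents a
spatial frequency `f_r(t) = k theta(t) / 2 pi` sweeping linearly across
the cursor.  The cosine profile is canonical; a duty-cycled binary
profile emulates manufactured masks and adds odd-harmonic content that
the tests deliberately do not rely on.

A single-element detector integrates the modulated intensity over the
cursor.  For contrast order `p` (p = 1 linear, p = 2 two-photon / SHG)
the detected signal involves `M^(2p)`, whose exact cosine series has
2p + 1 terms: `{3, 4, 1}/8` for p = 1 and `{35, 56, 28, 8, 1}/128` for
p = 2 (general p via `cos^(2n)(u/2) = 4^-n [C(2n,n) + 2 sum C(2n,n-q)
cos qu]`, all coefficients dyadic and therefore exact in floating
point).  Harmonic q carries q-fold spatial-frequency support — the
origin of the enhanced resolution of the higher-order images — at the
cost of the smaller series coefficient.

Two synthesis paths exist and are held equivalent by a standing test at
1e-6 relative: direct spatial integration of `I^p M^(2p) C_p` (the
oracle) and the harmonic sum over the object's Fourier transform
evaluated at `q f_r(t)`.  Mask-mount wobble enters both paths as a
common phase added to the pattern argument, so harmonic q carries
`q phi(t)` exactly as in the detected-signal model.

Noise model: shot noise is Poisson resampling of the trace scaled to a
photon budget per sample; detector noise is additive Gaussian; carrier
phase jitter is a per-trace random offset of the pattern argument
emulating rotation-trigger / motor-speed inconsistency.  Every
stochastic path requires an explicit seed.  PMT pulse shapes and the
laser's 10 MHz intra-trace pulse structure are not modelled.

## Reconstruction

The one-sided FFT of a trace is the line image.  Order q is isolated by
zeroing all bins outside a band centred (in "auto" mode) at q times the
median pixel frequency, with edges at the geometric midpoints to the
adjacent orders.  Averaging is performed on FFT magnitudes, never raw
signals: magnitude averaging is carrier-phase-insensitive, which is what
makes many-trace averaging viable when the rotation trigger drifts.  The
comparison test runs sparse-Poisson traces with carrier phase jitter and
checks that magnitude averaging preserves the peak SNR that raw
averaging destroys; with perfectly phase-locked traces coherent raw
averaging would not be worse, so the jitter term is part of that
scenario by design.

Motor-speed variation is corrected by piecewise-linear time-warping of
each trace so its timing fiducials land on an evenly spaced canonical
sequence (linear interpolation of the signal; fiducial density makes
higher-order interpolation unnecessary).  The frequency axis is
converted to micrometres by a least-squares slope through known feature
positions (bar-target centres); sub-bin feature localization uses an
intensity-weighted centroid over +-3..8 bins, and a Hann analysis window
suppresses the sinc-tail interference between neighbouring features that
otherwise biases the slope at the percent level.

Position axes scale as `slope x (f - f_band_min) / q`: the same
temporal-frequency width maps to half the position width at order 2.

**Resolvability criterion.**  A simulated point source produces a
band-limited (sinc- or window-shaped) amplitude peak, and a pair of
points at 1.2x the order-1 FWHM always exhibits two local maxima at both
orders, so a bare peak-count cannot express "unresolved".  The package
uses half-maximum separability: two features are resolved when the
valley between the two strongest maxima falls below 50% of the lower
one, i.e. the features separate at the same level that defines the
FWHM.  Under this criterion the 1.2x-FWHM pair is unresolved at order 1
(valley ~0.58 of peak) and clearly resolved at order 2 (valley < 0.01).

## Wobble estimation and correction

An off-centre mount modulates every encoded frequency with a
rotation-periodic phase `phi(t)`.  It is measured once per system from a
point-like emitter: isolate the reference order, track its instantaneous
frequency with a Gabor transform (Gaussian window
`exp[-4 ln2 ((t-tau)/wg)^2]`, temporal FWHM `wg`), centroid the
spectrogram, and integrate `2 pi (centroid - mean)` cumulatively over
tau; the stored phase is divided by the reference order so it is always
the order-1 phase.  Defaults: `wg` = 12 carrier periods (midpoint of the
practical 8-16x range; wider windows trade frequency for time
resolution), `n_tau` = 256 window centres, intensity-weighted centroid
rather than argmax (noise-robust).  The centroid is referenced to its
*full-range* mean: the trace spans exactly one rotation, hence an
integer number of cycles of any rotation-periodic wobble; an
interior-window mean would carry a nonzero average of the centroid
oscillation and integrate into a spurious linear phase ramp.  Window
centres within one `wg` of the trace boundaries are biased by window
truncation and are excluded from quantitative comparisons.

Correction: isolate order q, multiply by `exp(-i q phi(t))` (linear
interpolation of phi with edge hold — the phase varies on the rotation
timescale), transform back.  The factor is unit-modulus, so in-band
power is conserved to 1e-9 relative.

Study conditions for the tests: the standard scenario uses 200-240
pattern cycles per rotation at `nu_c` = 60 Hz and 2^14 samples per
rotation, with the emitter placed on an integer-cycle grid position.
Phase recovery is checked at a 0.8 rad once-per-rotation sinusoidal
wobble (5% RMS over interior windows).  For the PSF-blur scenario a
0.8 rad wobble shifts the instantaneous frequency by well under one
spectral bin and broadens the peak only a few percent, so the
blur/restore check uses a strongly wobbled 2.0 rad mount, which broadens
the first-order peak by ~1.9x; the measured correction restores it to
within 0.1% of the wobble-free width.  At still larger amplitudes the
smeared peak splits into two horns and its FWHM is no longer a
monotone blur metric, which bounds the stated test grid (0.5-2.0 rad).

The geometric generator maps a mount offset `eps` to an equivalent
common phase `phi(t) = -k pi eps cos(2 pi nu_c t + psi0)` — the radial
excursion of the cursor under an off-centre rotation times a
representative mid-rotation pattern angle.  This small-offset
approximation is periodic by construction (the exact pattern phase wraps
with the printed azimuth); its validity is established by round-trip
through the estimator (<=10% RMS), not by derivation.

## Metrology

* `fwhm`: background (median of the outer 10% of samples) subtracted,
  half-maximum crossings located by linear interpolation around the
  global peak.
* MTF: each modulated line profile is normalized by the unmodulated
  reference over the region where the reference exceeds 5% of its peak,
  Hann-windowed, transformed with 8x zero padding (scalloping below the
  noise), and reduced to (peak spatial frequency, modulation depth
  2|X_pk| / DC).  A profile is excluded when a second distinct spectral
  peak (separated by more than two pre-padding bins) exceeds 50% of the
  highest — beating/aliasing of under-resolved mask features — or when
  the peak is weaker than 3x the spectral noise floor.  Remaining points
  are fitted to `a exp[-2 (x/b)^c]` (bounded least squares, initialized
  at a = max amplitude, b = frequency nearest half amplitude, c = 6).
* NA = lambda0 x fc from the highest non-excluded spatial frequency.
  Theoretical point-focus FWHMs: `0.51 lambda0 / NA` (linear) and
  `0.64 lambda0 sqrt(ln2 / 2) / NA` (two-photon); the two-photon
  constant `sqrt(ln2/2) ~ 0.589` is the Gaussian-focus reduction of the
  intensity-squared profile.  Raw values are kept at full precision;
  reported values use half-up rounding to two decimals (plain half-even
  float rounding is representation-sensitive at exact midpoints such as
  1.275).
* Axial correction: true coverslip thickness over scanned interface
  distance, applied multiplicatively to z axes.
* Axial sectioning: a phenomenological Gaussian-beam model (Rayleigh
  range `lambda0 / pi NA^2`) of the integrated order-p interface signal:
  `(1+u^2)^(1-p)` for a point focus, `(1+u^2)^((1-p)/2)` for a line, and
  the line response weighted by the surviving modulation contrast
  `(1 + m^2/2)/(3/2)` with `m = (1+u^2)^(-1/2)` for the modulated line.
  It reproduces the qualitative ordering (point < SPIFI-line < line) and
  nothing more; no vectorial focusing.

## Wavelength-domain subsystem

The Martinez compressor with the mask in its spectral Fourier plane is
reduced to a 1-D model: angular frequency maps linearly onto the mask
radius across the active span, so the mask cosine is a pair of linear
spectral phases — pulse replicas at delay `tau(theta) = k theta
dr/domega` with amplitudes 1/2, 1/4, 1/4.  A grating offset `dz` adds
`GDD = -2 dz lambda0^3 / (pi c^2 d^2 cos^3 theta_Littrow)` (standard
grating-pair dispersion per unit separation, double pass), and
downstream material GDD is added as quadratic spectral phase.  The
detector records the second-order signal `integral |E(t)|^4 dt`, which
versus mask angle is an interferometric-autocorrelation-like fringe
pattern; its peak-detected envelope FWHM is minimal when the net GDD
vanishes.  Default pulse: Gaussian spectrum at 1035 nm with a 210 fs
transform-limited intensity FWHM on a 2048-point grid; sweeps use 4096
mask angles over +-2 pi (several samples per fringe at ~460 fringes per
half-sweep).

Because the real geometry (beam paths, incidence angles, spot sizes) is
not modelled, the absolute mm scale of `dz` is configuration-dependent:
only self-consistency is asserted — the swept offset that minimizes the
envelope FWHM cancels the injected downstream GDD within one grid step
and simultaneously maximizes the peak signal, and the envelope width is
unimodal in `dz`.  At zero net GDD the envelope width tracks the pulse's
interferometric autocorrelation within ~25% (the unequal replica
weights and the theta-dependent total transmission make the
correspondence approximate).  Third-order dispersion and spatial chirp
are out of scope.

## What the synthetic data do not show

Synthetic objects (points, bar triplets, bead fields, band-limited
textures) are noiseless geometric idealizations on the cursor grid: no
optical aberrations, no pupil truncation of the diffracted mask orders,
no fluorophore photophysics, no depth structure.  Passing tests
demonstrate the correctness of the encoding/decoding chain and of the
metrology arithmetic under the stated models — not instrument-level
accuracy.  Hardware-dependent published quantities (a um/Hz calibration
slope of order 1e-8, measured PSF widths, retrieved pulse durations)
depend on the physical instrument and are deliberately not asserted;
the simulated analogues cover the mechanisms.

## Problem sizes

Default simulations use 2^13-2^14 samples per rotation, 200-2000 cursor
samples, 30-trace averaging ensembles, 2048-point spectral grids and
11-point dz sweeps.  These sizes keep the full test suite under half a
minute while leaving every measured effect at least an order of
magnitude above its numerical floor.
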