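"""Forward simulation of single-pixel SPIFI time traces.

A line cursor of illumination intensity I(r) is modulated by the rotating
mask and imaged onto an object with contrast C(r).  The single-element
detector integrates over the cursor, so for a process of order p
(p = 1 linear fluorescence, p = 2 two-photon / SHG) the trace is

    S(t) = integral dr  I(r)^p  M(r, t)^(2p)  C_p(r),

where the mask power expands into a finite cosine series.  For the
canonical cosine mask M = 1/2 (1 + cos u) the series for M^(2p) has 2p + 1
terms: {3, 4, 1}/8 for p = 1 and {35, 56, 28, 8, 1}/128 for p = 2.  Each
harmonic q carries q-fold spatial-frequency support, which is the origin of
the enhanced resolution in the higher-order images.

Two synthesis paths are provided: :func:`generate_trace` integrates the
modulated intensity directly over the cursor (the oracle), while
:func:`generate_trace_analytic` builds the same trace as the harmonic sum

    S(t) = sum_q c_q H_q(t) Re{ exp(i q phi(t)) exp(i 2 pi q f_r(t) r0)
                                 conj(W_hat[q f_r(t)]) },

with W_hat the Fourier transform of the weighted object
w(r) = I(r)^p C_p(r).  The two must agree to numerical precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, List, Optional, Sequence

import numpy as np

from .mask_model import MaskSpec, RotationState

__all__ = [
    "LineCursor",
    "SampleObject",
    "SampleObject2D",
    "HarmonicSeries",
    "NoiseSpec",
    "TimeTrace",
    "harmonic_expansion",
    "generate_trace",
    "generate_trace_analytic",
    "scan_object",
]


@dataclass
class LineCursor:
    """Sampled illumination intensity I(r) along the line cursor (r in mm)."""

    r: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.r.ndim != 1 or self.r.shape != self.intensity.shape:
            raise ValueError("r and intensity must be matching 1-D arrays")
        dr = np.diff(self.r)
        if dr.size and not np.allclose(dr, dr[0], rtol=1e-9):
            raise ValueError("cursor sampling must be uniform")
        if np.any(self.intensity < 0):
            raise ValueError("illumination intensity must be >= 0")

    @classmethod
    def uniform(cls, r_min: float, r_max: float, n: int, intensity: float = 1.0) -> "LineCursor":
        r = np.linspace(r_min, r_max, n)
        return cls(r=r, intensity=np.full(n, float(intensity)))

    @property
    def dr(self) -> float:
        return float(self.r[1] - self.r[0])


@dataclass
class SampleObject:
    """Nonnegative contrast profile of the sample along the cursor.

    ``response`` is C(r) for linear contrast or C_2P(r) (the two-photon
    spatial response) for p = 2; arbitrary units.
    """

    r: np.ndarray
    response: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.r.shape != self.response.shape:
            raise ValueError("r and response must share a grid")
        if np.any(self.response < 0):
            raise ValueError("object response must be >= 0")

    def on_grid(self, r: np.ndarray) -> "SampleObject":
        """Linear resample onto another cursor grid (zero outside support)."""
        if self.r.shape == np.shape(r) and np.allclose(self.r, r):
            return self
        resp = np.interp(r, self.r, self.response, left=0.0, right=0.0)
        return SampleObject(r=np.asarray(r, float), response=resp, meta=dict(self.meta))


@dataclass
class SampleObject2D:
    """2-D object map: rows along the scan axis y (um), columns along r (mm)."""

    y: np.ndarray            # scan-axis positions, um
    r: np.ndarray            # cursor positions, mm
    response: np.ndarray     # shape (len(y), len(r))
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.response.shape != (self.y.size, self.r.size):
            raise ValueError("response must have shape (len(y), len(r))")
        if np.any(self.response < 0):
            raise ValueError("object response must be >= 0")

    def row_at(self, y: float) -> SampleObject:
        """Linear interpolation between rows at scan position ``y`` (um)."""
        resp = np.array([
            np.interp(y, self.y, self.response[:, j], left=0.0, right=0.0)
            for j in range(self.r.size)
        ])
        return SampleObject(r=self.r, response=np.clip(resp, 0, None))


@dataclass
class HarmonicSeries:
    """Exact cosine-series coefficients of M(r, t)^(2p).

    ``coefficients[0]`` is the DC term, ``coefficients[q]`` multiplies
    cos(q u); they sum to 1 (the value of M^(2p) at the modulation peak).
    ``envelopes`` are optional per-order amplitude functions H_q(t)
    (modulation/vignetting); default is the constant 1.
    """

    p: int
    coefficients: np.ndarray
    envelopes: Optional[Sequence[Callable[[np.ndarray], np.ndarray]]] = None

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if not np.all(self.coefficients > 0):
            raise ValueError("all harmonic coefficients must be > 0")
        if not math.isclose(float(self.coefficients.sum()), 1.0, rel_tol=1e-12):
            raise ValueError("harmonic coefficients must sum to 1")

    @property
    def n_orders(self) -> int:
        return self.coefficients.size - 1


def harmonic_expansion(p: int) -> HarmonicSeries:
    """Cosine-series coefficients of [1/2 (1 + cos u)]^(2p).

    Using cos^(2n)(u/2) = 4^-n [C(2n, n) + 2 sum_q C(2n, n-q) cos(q u)] with
    n = 2p.  For p = 1 this is {3, 4, 1}/8; for p = 2, {35, 56, 28, 8, 1}/128.
    All coefficients are dyadic rationals and therefore exact in binary
    floating point.
    """
    if not (isinstance(p, (int, np.integer)) and p >= 1):
        raise ValueError(f"process order p must be an integer >= 1, got {p!r}")
    n = 2 * int(p)
    denom = 4 ** n
    coeffs = [math.comb(2 * n, n) / denom]
    coeffs += [2 * math.comb(2 * n, n - q) / denom for q in range(1, n + 1)]
    return HarmonicSeries(p=int(p), coefficients=np.array(coeffs))


@dataclass
class NoiseSpec:
    """Stochastic model applied to a synthesized trace.

    photons_per_sample
        Mean photon count per time sample at the trace's mean level; the
        trace is Poisson-resampled at that budget (shot noise).  ``None``
        disables shot noise.
    additive_rms
        RMS of additive Gaussian detector noise (trace units).
    carrier_phase_jitter
        RMS of a random per-trace phase offset (rad) added to the pattern
        argument, emulating rotation-trigger / motor-speed inconsistency.
    seed
        Mandatory whenever any stochastic term is active.
    """

    photons_per_sample: Optional[float] = None
    additive_rms: float = 0.0
    carrier_phase_jitter: float = 0.0
    seed: Optional[int] = None

    @property
    def stochastic(self) -> bool:
        return (
            self.photons_per_sample is not None
            or self.additive_rms > 0
            or self.carrier_phase_jitter > 0
        )

    def rng(self) -> np.random.Generator:
        if self.stochastic and self.seed is None:
            raise ValueError("NoiseSpec with stochastic terms requires a seed")
        return np.random.default_rng(self.seed)


@dataclass
class TimeTrace:
    """Single-pixel detector signal over one mask rotation."""

    t: np.ndarray
    signal: np.ndarray
    nu_c: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.t.shape != self.signal.shape:
            raise ValueError("t and signal must share a grid")
        if self.t.size < 2:
            raise ValueError("a trace needs at least 2 samples")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def uniform(self) -> bool:
        d = np.diff(self.t)
        return bool(np.allclose(d, d[0], rtol=1e-9, atol=0.0))


def _nyquist_check(mask: MaskSpec, rot: RotationState, p: int) -> float:
    f_max = 2 * p * mask.k * (mask.r0 + mask.r_max) * rot.nu_c
    dt = rot.t[1] - rot.t[0]
    if f_max >= 0.5 / dt:
        raise ValueError(
            f"Nyquist violation: highest encoded frequency {f_max:.6g} Hz "
            f"(order {2 * p} at r = r_max) >= half the sampling rate {0.5 / dt:.6g} Hz"
        )
    return f_max


def _trace_meta(mask: MaskSpec, rot: RotationState, p: int, noise: Optional[NoiseSpec]) -> dict:
    r_med = 0.5 * (mask.r_min + mask.r_max)
    meta = dict(mask.to_dict())
    meta.update(
        p=int(p),
        pixel_freq_min=mask.k * (mask.r0 + mask.r_min) * rot.nu_c,
        pixel_freq_median=mask.k * (mask.r0 + r_med) * rot.nu_c,
        pixel_freq_max=mask.k * (mask.r0 + mask.r_max) * rot.nu_c,
        fiducials=rot.fiducial_times(8).tolist(),
    )
    if noise is not None and noise.stochastic:
        meta["seed"] = noise.seed
    return meta


def _apply_noise(signal: np.ndarray, noise: Optional[NoiseSpec],
                 rng: Optional[np.random.Generator]) -> np.ndarray:
    if noise is None or not noise.stochastic:
        return signal
    out = signal
    if noise.photons_per_sample is not None:
        mean = float(np.mean(out))
        if mean > 0:
            gain = noise.photons_per_sample / mean
            out = rng.poisson(np.clip(out, 0, None) * gain) / gain
    if noise.additive_rms > 0:
        out = out + rng.normal(0.0, noise.additive_rms, size=out.shape)
    return out


def _weights(cursor: LineCursor, obj: SampleObject, p: int) -> np.ndarray:
    obj = obj.on_grid(cursor.r)
    return cursor.intensity ** p * obj.response * cursor.dr


def generate_trace(
    mask: MaskSpec,
    rot: RotationState,
    cursor: LineCursor,
    obj: SampleObject,
    p: int = 1,
    noise: Optional[NoiseSpec] = None,
) -> TimeTrace:
    """Direct-integration synthesis of the detector trace (the oracle path).

    The wobble phase ``rot.phi_of_t`` (and any carrier phase jitter) enters
    as a common offset of the pattern argument, so harmonic q of the
    detected signal carries the phase q * phi(t).
    """
    _nyquist_check(mask, rot, p)
    if np.any(cursor.r < mask.r_min - 1e-12) or np.any(cursor.r > mask.r_max + 1e-12):
        raise ValueError("cursor extends outside the mask's active span")
    rng = noise.rng() if noise is not None and noise.stochastic else None
    psi = 0.0
    if noise is not None and noise.carrier_phase_jitter > 0:
        psi = float(rng.normal(0.0, noise.carrier_phase_jitter))
    w = _weights(cursor, obj, p)
    common = rot.phi_of_t + psi
    signal = np.zeros_like(rot.t)
    # chunk over time to bound the (n_r, n_t) temporary
    chunk = max(1, int(4e6 // max(cursor.r.size, 1)))
    kr = mask.k * (mask.r0 + cursor.r)
    for i0 in range(0, rot.t.size, chunk):
        sl = slice(i0, i0 + chunk)
        u = kr[:, None] * rot.theta_of_t[None, sl] + common[None, sl]
        m = 0.5 * (1.0 + np.cos(u))
        signal[sl] = w @ m ** (2 * p)
    signal = _apply_noise(signal, noise, rng)
    meta = _trace_meta(mask, rot, p, noise)
    if psi:
        meta["carrier_phase_offset"] = psi
    return TimeTrace(t=rot.t.copy(), signal=signal, nu_c=rot.nu_c, meta=meta)


def generate_trace_analytic(
    mask: MaskSpec,
    rot: RotationState,
    cursor: LineCursor,
    obj: SampleObject,
    p: int = 1,
    noise: Optional[NoiseSpec] = None,
    series: Optional[HarmonicSeries] = None,
) -> TimeTrace:
    """Harmonic-sum synthesis via the object's Fourier transform.

    Must agree with :func:`generate_trace` to numerical precision for
    noiseless inputs (a standing property of the package).
    """
    _nyquist_check(mask, rot, p)
    if series is None:
        series = harmonic_expansion(p)
    rng = noise.rng() if noise is not None and noise.stochastic else None
    psi = 0.0
    if noise is not None and noise.carrier_phase_jitter > 0:
        psi = float(rng.normal(0.0, noise.carrier_phase_jitter))
    w = _weights(cursor, obj, p)
    fr = mask.k * rot.theta_of_t / (2 * np.pi)  # instantaneous spatial frequency
    common = rot.phi_of_t + psi
    coeffs = series.coefficients
    signal = np.full(rot.t.size, coeffs[0] * w.sum())
    if series.envelopes is not None and len(series.envelopes) != series.n_orders:
        raise ValueError("need one envelope per order")
    chunk = max(1, int(4e6 // max(cursor.r.size, 1)))
    for q in range(1, coeffs.size):
        hq = (series.envelopes[q - 1](rot.t)
              if series.envelopes is not None else 1.0)
        for i0 in range(0, rot.t.size, chunk):
            sl = slice(i0, i0 + chunk)
            fq = q * fr[sl]
            # conj(W_hat(q f_r)) = sum_r w(r) exp(+i 2 pi q f_r r)
            what_conj = np.exp(2j * np.pi * np.outer(fq, cursor.r)) @ w.astype(complex)
            phase = np.exp(1j * (q * common[sl] + 2 * np.pi * fq * mask.r0))
            term = coeffs[q] * np.real(phase * what_conj)
            signal[sl] += (hq[sl] if np.ndim(hq) else hq) * term
    signal = _apply_noise(signal, noise, rng)
    meta = _trace_meta(mask, rot, p, noise)
    meta["synthesis"] = "analytic"
    if psi:
        meta["carrier_phase_offset"] = psi
    return TimeTrace(t=rot.t.copy(), signal=signal, nu_c=rot.nu_c, meta=meta)


def scan_object(
    mask: MaskSpec,
    rot: RotationState,
    cursor: LineCursor,
    obj2d: SampleObject2D,
    p: int = 1,
    noise: Optional[NoiseSpec] = None,
    scan_step: float = 0.5,
    n_steps: Optional[int] = None,
    stage_jitter_rms: float = 0.0,
    seed: Optional[int] = None,
) -> List[TimeTrace]:
    """Line-scanning acquisition: one trace per stage position.

    ``scan_step`` is in um along the scan axis; ``stage_jitter_rms`` (um)
    models stage repeatability error (the commanded position is recorded
    alongside the true, jittered one).
    """
    if scan_step <= 0:
        raise ValueError("scan_step must be > 0")
    if n_steps is None:
        n_steps = int(round((obj2d.y[-1] - obj2d.y[0]) / scan_step)) + 1
    y_cmd = obj2d.y[0] + np.arange(n_steps) * scan_step
    if stage_jitter_rms > 0:
        if seed is None:
            raise ValueError("stage jitter requires a seed")
        y_true = y_cmd + np.random.default_rng(seed).normal(0, stage_jitter_rms, n_steps)
    else:
        y_true = y_cmd.copy()
    traces = []
    for i, (yc, yt) in enumerate(zip(y_cmd, y_true)):
        row = obj2d.row_at(yt)
        ns = None
        if noise is not None and noise.stochastic:
            ns = replace(noise, seed=(noise.seed or 0) + i)
        tr = generate_trace(mask, rot, cursor, row, p=p, noise=ns)
        tr.meta["y_commanded_um"] = float(yc)
        tr.meta["y_true_um"] = float(yt)
        traces.append(tr)
    return traces
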