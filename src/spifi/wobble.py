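"""Mask-wobble estimation and correction.

An off-centre mounted mask adds a rotation-periodic phase phi(t) to every
encoded frequency; order q of the detected signal carries q * phi(t),
which smears the spectral peaks and blurs the reconstructed PSF.  The
phase is measured once per system from a point-like emitter:

1. isolate the reference order in the FFT,
2. track its instantaneous frequency through the rotation with a Gabor
   transform (sliding Gaussian-windowed FFT, window FWHM w_g),
3. centroid the spectrogram, cumulatively integrate the centroid relative
   to its mean and multiply by 2 pi to obtain phi(tau),
4. store the order-1 phase (divide by the reference order).

Correction of any subsequent image: isolate order q, inverse transform,
multiply by exp(-i q phi(t)), transform again.  The phase factor is
unit-modulus, so the correction is unitary on the isolated band.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple, Union

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .forward_sim import TimeTrace
from .reconstruct import OrderImage, Spectrum, isolate_order

__all__ = [
    "GaborSpec",
    "Spectrogram",
    "WobblePhase",
    "gabor_transform",
    "estimate_wobble",
    "apply_wobble_correction",
]

_4LN2 = 4.0 * np.log(2.0)


@dataclass(frozen=True)
class GaborSpec:
    """Gabor-transform parameters.

    wg
        Temporal FWHM of the Gaussian window (s).  The window is
        exp[-4 ln 2 ((t - tau)/wg)^2] so its half-maximum points sit at
        +/- wg/2.  A practical choice is 8-16 carrier periods (default
        factory uses 12): wider windows trade frequency resolution for
        time resolution.
    n_tau
        Number of window centres across the trace (>= 8).
    f_range
        Analysis band in Hz (None = all positive frequencies).
    """

    wg: float
    n_tau: int = 256
    f_range: Optional[Tuple[float, float]] = None

    def __post_init__(self) -> None:
        if not self.wg > 0:
            raise ValueError("window width wg must be > 0")
        if self.n_tau < 8:
            raise ValueError("need at least 8 window centres")

    @classmethod
    def for_carrier(cls, f_carrier: float, periods: float = 12.0,
                    n_tau: int = 256,
                    f_range: Optional[Tuple[float, float]] = None) -> "GaborSpec":
        """Window spanning ``periods`` cycles of the carrier ``f_carrier``."""
        return cls(wg=periods / f_carrier, n_tau=n_tau, f_range=f_range)


@dataclass
class Spectrogram:
    tau: np.ndarray          # window centres, s
    freq: np.ndarray         # Hz
    power: np.ndarray        # |G(tau, f)|^2, shape (n_tau, n_freq)

    def centroid(self) -> np.ndarray:
        """Intensity-weighted mean frequency per window centre."""
        w = self.power
        tot = w.sum(axis=1)
        if np.any(tot <= 0):
            raise ValueError("empty spectrogram column; check f_range")
        return (w @ self.freq) / tot


@dataclass
class WobblePhase:
    """Estimated wobble phase phi(tau), the per-system correction record.

    ``phi`` is referred to order 1 and zero-mean by construction;
    ``centroid`` is the tracked instantaneous frequency (Hz).
    """

    tau: np.ndarray
    phi: np.ndarray
    centroid: np.ndarray
    mean_freq: float
    wg: float = 0.0
    meta: dict = field(default_factory=dict)

    def interp(self, t: np.ndarray) -> np.ndarray:
        """Linear interpolation onto a new time grid, edge values held."""
        t = np.asarray(t, dtype=float)
        span = t[-1] - t[0]
        covered = (min(self.tau[-1], t[-1]) - max(self.tau[0], t[0]))
        if covered < 0.8 * span:
            raise ValueError(
                "wobble phase grid does not cover the trace time span"
            )
        return np.interp(t, self.tau, self.phi)

    def interior(self, margin: Optional[float] = None) -> np.ndarray:
        """Boolean mask of window centres at least one window width away
        from the trace boundaries (edge windows are biased)."""
        m = self.wg if margin is None else margin
        return (self.tau >= self.tau[0] + m) & (self.tau <= self.tau[-1] - m)


def gabor_transform(
    x: np.ndarray,
    t: np.ndarray,
    spec: GaborSpec,
) -> Spectrogram:
    """Sliding Gaussian-windowed Fourier transform of ``x(t)``.

    ``x`` may be real or complex (e.g. an isolated-order analytic signal).
    Window centres are ``spec.n_tau`` points spanning the trace; for each
    centre the windowed FFT is restricted to ``spec.f_range``.
    """
    x = np.asarray(x)
    t = np.asarray(t, dtype=float)
    if x.shape != t.shape:
        raise ValueError("x and t must share a grid")
    dt = t[1] - t[0]
    if not np.allclose(np.diff(t), dt, rtol=1e-9):
        raise ValueError("x must be on a uniform time grid")
    if spec.wg < 4 * dt:
        raise ValueError(
            f"window width {spec.wg:.3g} s too small: needs >= 4 sample intervals"
        )
    n = x.size
    freq_full = np.fft.fftfreq(n, d=dt)
    if spec.f_range is None:
        fsel = freq_full > 0
    else:
        fsel = (freq_full >= spec.f_range[0]) & (freq_full <= spec.f_range[1])
    if not np.any(fsel):
        raise ValueError("f_range selects no frequency bins")
    tau = np.linspace(t[0], t[-1], spec.n_tau)
    power = np.empty((spec.n_tau, int(fsel.sum())))
    for i, tc in enumerate(tau):
        w = np.exp(-_4LN2 * ((t - tc) / spec.wg) ** 2)
        G = np.fft.fft(w * x)
        power[i] = np.abs(G[fsel]) ** 2
    order = np.argsort(freq_full[fsel])
    return Spectrogram(tau=tau, freq=freq_full[fsel][order], power=power[:, order])


def estimate_wobble(
    trace_or_spectrum: Union[TimeTrace, Spectrum],
    q_ref: int = 1,
    spec: Optional[GaborSpec] = None,
    band: Union[str, Tuple[float, float]] = "auto",
) -> WobblePhase:
    """Estimate phi(t) from a point-emitter trace via order ``q_ref``.

    The stored phase is divided by ``q_ref`` so it is always the order-1
    phase; applying it to order q multiplies by q again (Eq.-of-motion
    q * phi scaling).  Raises if the isolated band shows no dominant
    spectral ridge (the trace is not point-like).
    """
    from .reconstruct import fft_line

    if isinstance(trace_or_spectrum, TimeTrace):
        spectrum = fft_line(trace_or_spectrum)
    else:
        spectrum = trace_or_spectrum
    osig = isolate_order(spectrum, q_ref, band=band)
    # ridge dominance: a point-like emitter concentrates the in-band power
    # in a narrow cluster of bins; an extended object spreads it
    power = np.abs(np.fft.fft(osig.z)[: osig.z.size // 2]) ** 2
    total = float(power.sum())
    ipk = int(np.argmax(power))
    near = power[max(0, ipk - 10): ipk + 11].sum()
    if total <= 0 or near / total < 0.5:
        raise ValueError(
            "no dominant spectral ridge in the isolated order; "
            "wobble estimation needs a point-like emitter"
        )
    if spec is None:
        f_pix = osig.meta.get("pixel_freq_median")
        fc = q_ref * f_pix if f_pix else 0.5 * (osig.band[0] + osig.band[1])
        spec = GaborSpec.for_carrier(fc, f_range=osig.band)
    elif spec.f_range is None:
        spec = GaborSpec(wg=spec.wg, n_tau=spec.n_tau, f_range=osig.band)
    sg = gabor_transform(osig.z, osig.t, spec)
    cen = sg.centroid()
    # the trace spans one full rotation and the wobble is rotation-periodic,
    # so the full-range mean sees an integer number of wobble cycles; a
    # partial-range mean would bias the integrated phase with a linear ramp
    mean_c = float(np.mean(cen))
    phi = 2 * np.pi * cumulative_trapezoid(cen - mean_c, sg.tau, initial=0.0)
    phi = phi / q_ref
    phi = phi - np.mean(phi)
    return WobblePhase(tau=sg.tau, phi=phi, centroid=cen, mean_freq=mean_c,
                       wg=spec.wg, meta={"q_ref": q_ref, "band": osig.band})


def apply_wobble_correction(
    spectrum: Spectrum,
    q: int,
    wphase: WobblePhase,
    band: Union[str, Tuple[float, float]] = "auto",
    pad: int = 1,
) -> OrderImage:
    """Correct order q: isolate, multiply by exp(-i q phi(t)), re-transform.

    ``pad`` zero-pads the corrected signal before the final FFT for
    sub-bin PSF width measurements.  The order-q correction applies
    q x the stored order-1 phase (e.g. exp(-i 2 phi) for q = 2).
    """
    osig = isolate_order(spectrum, q, band=band)
    phi_t = wphase.interp(osig.t)
    zc = osig.z * np.exp(-1j * q * phi_t)
    nfft = osig.z.size * int(pad)
    # z carries 2x the one-sided amplitude; halve so that with phi = 0 the
    # result reproduces the uncorrected band spectrum bin-for-bin
    Z = 0.5 * np.fft.fft(zc, n=nfft)
    freq = np.fft.fftfreq(nfft, d=osig.dt)
    # retain the (positive-frequency) isolation band, slightly widened so
    # energy shifted by the correction at the band edge is kept
    guard = 2.0 / (osig.z.size * osig.dt)
    sel = (freq >= osig.band[0] - guard) & (freq <= osig.band[1] + guard)
    order = np.argsort(freq[sel])
    return OrderImage(
        q=q,
        freq=freq[sel][order],
        amplitude=np.abs(Z[sel][order]),
        complexv=Z[sel][order],
        meta={**osig.meta, "band": osig.band, "wobble_corrected": True},
    )
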