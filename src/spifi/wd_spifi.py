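"""Wavelength-domain SPIFI: 1-D pulse model of the dispersion optimizer.

A Martinez compressor (grating - lens - lens - grating, 4f) with a SPIFI
mask in its spectral Fourier plane produces diffracted copies of the pulse
whose relative time delay sweeps as the mask rotates: the mask cosine
across the spectral coordinate is a pair of linear spectral phases
exp[+/- i k theta (r0 + r(omega))], i.e. replicas delayed by
tau(theta) = k theta dr/domega.  A specimen responding at second order
(2PEF / SHG) then yields an interferometric-autocorrelation-like signal
versus mask angle.  Offsetting the output grating by dz from the 4f
condition adds negative group-delay dispersion (GDD), so sweeping dz and
minimizing the FWHM of the signal envelope finds the offset that cancels
the downstream material dispersion - the shortest pulse at the sample.

Units: wavelengths nm, time fs, angular frequency rad/fs, GDD fs^2,
grating geometry mm.  The spectral model is deliberately 1-D (no ray
tracing); the absolute dz scale depends on the real geometry and only the
self-consistency of gdd_from_offset with the envelope minimum is asserted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import signal as sps

from .mask_model import MaskSpec, mask_value
from .metrics import fwhm as _fwhm

__all__ = [
    "PulseSpec",
    "CompressorSpec",
    "WdTrace",
    "OffsetScan",
    "gdd_from_offset",
    "wd_trace",
    "envelope_fwhm",
    "optimize_offset",
    "interferometric_autocorrelation",
]

C_NM_FS = 299.792458  # speed of light, nm/fs


@dataclass
class PulseSpec:
    """Ultrafast pulse: spectral amplitude and phase on an omega grid.

    ``omega`` is absolute angular frequency (rad/fs); ``spectrum`` the
    field amplitude; ``phase`` the spectral phase.  ``tl_duration`` is the
    transform-limited intensity FWHM (fs) for reference.
    """

    lambda0: float                 # centre wavelength, nm
    omega: np.ndarray              # rad/fs
    spectrum: np.ndarray           # amplitude >= 0
    phase: np.ndarray              # rad
    tl_duration: float             # fs

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, dtype=float)
        self.spectrum = np.asarray(self.spectrum, dtype=float)
        self.phase = np.asarray(self.phase, dtype=float)
        if np.any(self.spectrum < 0):
            raise ValueError("spectral amplitude must be >= 0")
        if not (self.omega.shape == self.spectrum.shape == self.phase.shape):
            raise ValueError("omega, spectrum and phase must share a grid")

    @property
    def omega0(self) -> float:
        return 2 * np.pi * C_NM_FS / self.lambda0

    @property
    def domega(self) -> float:
        return float(self.omega[1] - self.omega[0])

    @classmethod
    def gaussian(cls, lambda0: float = 1035.0, tl_fwhm: float = 210.0,
                 n: int = 2048, span_sigmas: float = 40.0) -> "PulseSpec":
        """Gaussian spectrum for a transform-limited intensity FWHM
        ``tl_fwhm`` (fs) at centre wavelength ``lambda0`` (nm).

        The grid spans ``span_sigmas`` spectral standard deviations, which
        sets the usable time window 2 pi / domega.
        """
        w0 = 2 * np.pi * C_NM_FS / lambda0
        # field e(t) = exp(-2 ln2 t^2 / dt^2)  ->  A(w) ~ exp(-w'^2 dt^2 / (8 ln2))
        sigma = 2.0 * np.sqrt(np.log(2.0)) / tl_fwhm
        omega = w0 + np.linspace(-span_sigmas / 2, span_sigmas / 2, n) * sigma
        amp = np.exp(-((omega - w0) ** 2) / (2 * sigma ** 2))
        return cls(lambda0=lambda0, omega=omega, spectrum=amp,
                   phase=np.zeros(n), tl_duration=tl_fwhm)


@dataclass(frozen=True)
class CompressorSpec:
    """Martinez compressor geometry.

    dz is the output-grating offset from the 4f condition (mm); positive
    dz (grating beyond focus) adds negative GDD.  ``downstream_gdd`` is
    the material dispersion (fs^2) after the compressor that the offset
    should cancel.
    """

    groove_density: float = 1000.0   # mm^-1
    littrow_angle: Optional[float] = None  # rad; None = from lambda0 at use time
    focal_length: float = 100.0      # mm
    dz: float = 0.0                  # mm
    downstream_gdd: float = 0.0      # fs^2

    def __post_init__(self) -> None:
        if abs(self.dz) >= self.focal_length:
            raise ValueError("|dz| must stay below the focal length")


def gdd_from_offset(comp: CompressorSpec, lambda0: float = 1035.0) -> float:
    """GDD (fs^2) added by an output-grating offset dz (double pass).

    GDD = -2 dz G with the grating-pair dispersion per unit separation at
    Littrow incidence,  G = lambda0^3 / (pi c^2 d^2 cos^3 theta_L),
    d = groove period.  dz = 0 (exact 4f) gives zero; dz > 0 gives
    negative GDD; the model is linear in dz.
    """
    d_nm = 1e6 / comp.groove_density          # groove period, nm
    if comp.littrow_angle is None:
        sin_l = lambda0 / (2 * d_nm)
        if not 0 < sin_l < 1:
            raise ValueError("wavelength/groove density admit no Littrow angle")
        theta_l = np.arcsin(sin_l)
    else:
        theta_l = comp.littrow_angle
    # per-mm separation dispersion, in fs^2/mm (c in nm/fs, lengths in nm)
    g_per_nm = lambda0 ** 3 / (np.pi * C_NM_FS ** 2 * d_nm ** 2 * np.cos(theta_l) ** 3)
    g_per_mm = g_per_nm * 1e6
    return -2.0 * comp.dz * g_per_mm


@dataclass
class WdTrace:
    """Nonlinear detector signal versus mask angle for one grating offset."""

    theta: np.ndarray            # mask angles, rad
    delay: np.ndarray            # replica delay tau(theta), fs
    signal: np.ndarray           # integral |E(t)|^4 dt per angle
    envelope: Optional[np.ndarray] = None
    env_fwhm: Optional[float] = None
    meta: dict = field(default_factory=dict)


def _map_r(mask: MaskSpec, omega: np.ndarray) -> Tuple[np.ndarray, float]:
    """Linear omega -> mask-radius map across the active span (ideal
    grating-lens Fourier plane).  Returns r(omega) and dr/domega."""
    span = mask.r_max - mask.r_min
    dr_domega = span / (omega[-1] - omega[0])
    r = mask.r_min + (omega - omega[0]) * dr_domega
    return r, dr_domega


def wd_trace(
    pulse: PulseSpec,
    comp: CompressorSpec,
    mask: MaskSpec,
    theta_grid: np.ndarray,
    block: int = 256,
) -> WdTrace:
    """Second-order signal over a mask rotation at one grating offset.

    For each angle the mask cosine is applied across the spectral
    coordinate, total GDD (grating offset + downstream material) is added
    as quadratic spectral phase, and the detector records
    integral |E(t)|^4 dt.  theta = 0 (replicas degenerate) gives the
    autocorrelation peak; the signal is symmetric in theta.
    """
    theta_grid = np.asarray(theta_grid, dtype=float)
    r_of_w, dr_domega = _map_r(mask, pulse.omega)
    gdd = gdd_from_offset(comp, pulse.lambda0) + comp.downstream_gdd
    wrel = pulse.omega - pulse.omega0
    base = pulse.spectrum * np.exp(1j * (pulse.phase + 0.5 * gdd * wrel ** 2))
    # max replica delay must fit in the FFT time window
    tau_max = float(np.max(np.abs(mask.k * theta_grid)) * dr_domega)
    t_window = 2 * np.pi / pulse.domega
    if 2 * tau_max > 0.9 * t_window:
        raise ValueError(
            f"spectral grid too coarse: replica delay {tau_max:.0f} fs does not "
            f"fit the {t_window:.0f} fs time window (Nyquist in omega)"
        )
    n = pulse.omega.size
    sig = np.empty(theta_grid.size)
    dt = t_window / n
    for i0 in range(0, theta_grid.size, block):
        th = theta_grid[i0:i0 + block]
        trans = 0.5 * (1.0 + np.cos(mask.k * (mask.r0 + r_of_w)[None, :] * th[:, None]))
        field_w = base[None, :] * trans
        e_t = np.fft.ifft(field_w, axis=1)
        sig[i0:i0 + th.size] = np.sum(np.abs(e_t) ** 4, axis=1) * dt
    delay = mask.k * theta_grid * dr_domega
    return WdTrace(theta=theta_grid, delay=delay, signal=sig,
                   meta={"gdd_total_fs2": gdd, "dz_mm": comp.dz,
                         "tau_max_fs": tau_max})


def envelope_fwhm(trace: WdTrace, prominence: float = 0.02,
                  use_delay: bool = True) -> float:
    """FWHM of the peak-detected signal envelope.

    Local maxima above a relative prominence threshold define the
    envelope (linear interpolation through the peaks); the width comes
    from :func:`spifi.metrics.fwhm`, so the far-delay background is
    subtracted.  Requires at least 5 envelope peaks.
    """
    y = trace.signal
    prom = prominence * (float(y.max()) - float(y.min()))
    peaks, _ = sps.find_peaks(y, prominence=prom)
    # the global maximum is part of the envelope even if find_peaks skips
    # it at the array edge
    imax = int(np.argmax(y))
    if imax not in peaks:
        peaks = np.sort(np.append(peaks, imax))
    if peaks.size < 5:
        raise ValueError(
            f"only {peaks.size} envelope peaks found; need >= 5 "
            "(theta grid too coarse or sweep too narrow)"
        )
    x = trace.delay if use_delay else trace.theta
    env = np.interp(x, x[peaks], y[peaks])
    trace.envelope = env
    width = _fwhm(env, x)
    trace.env_fwhm = width
    return width


def interferometric_autocorrelation(pulse: PulseSpec, tau: np.ndarray) -> np.ndarray:
    """Direct IAC oracle: integral |(e(t) + e(t - tau))|^4 dt on a tau grid."""
    base = pulse.spectrum * np.exp(1j * pulse.phase)
    e0 = np.fft.ifft(base)
    out = np.empty(np.asarray(tau).size)
    for i, tv in enumerate(np.asarray(tau, dtype=float)):
        shifted = np.fft.ifft(base * np.exp(1j * pulse.omega * tv))
        out[i] = float(np.sum(np.abs(e0 + shifted) ** 4))
    return out


@dataclass
class OffsetScan:
    dz: np.ndarray
    env_fwhm: np.ndarray
    peak_signal: np.ndarray
    gdd: np.ndarray
    dz_opt: float
    traces: Optional[list] = None


def optimize_offset(
    pulse: PulseSpec,
    mask: MaskSpec,
    dz_grid: Sequence[float],
    theta_grid: np.ndarray,
    downstream_gdd: float = 0.0,
    comp: Optional[CompressorSpec] = None,
    keep_traces: bool = False,
) -> OffsetScan:
    """Sweep the output-grating offset and minimize the envelope FWHM.

    Returns the offset dz* whose compressor GDD cancels
    ``downstream_gdd`` (within one grid step); the same offset also
    maximizes the peak signal.  Raises if the minimum sits on the edge of
    the grid (the sweep does not bracket the compensating offset).
    """
    if comp is None:
        comp = CompressorSpec()
    dz_grid = np.asarray(dz_grid, dtype=float)
    widths = np.empty(dz_grid.size)
    peaks = np.empty(dz_grid.size)
    gdds = np.empty(dz_grid.size)
    traces = [] if keep_traces else None
    for i, dz in enumerate(dz_grid):
        ci = replace(comp, dz=float(dz), downstream_gdd=downstream_gdd)
        tr = wd_trace(pulse, ci, mask, theta_grid)
        widths[i] = envelope_fwhm(tr)
        peaks[i] = float(tr.signal.max())
        gdds[i] = gdd_from_offset(ci, pulse.lambda0)
        if keep_traces:
            traces.append(tr)
    iopt = int(np.argmin(widths))
    if iopt in (0, dz_grid.size - 1):
        raise ValueError(
            "envelope-FWHM minimum at the edge of the dz grid; widen the sweep"
        )
    return OffsetScan(dz=dz_grid, env_fwhm=widths, peak_signal=peaks,
                      gdd=gdds, dz_opt=float(dz_grid[iopt]), traces=traces)
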