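"""Rotating-reticle (SPIFI mask) mathematics.

The modulation mask is a chirped pattern printed on a spinning disk,

    M(r, theta) = 1/2 * {1 + cos[k (r0 + r) theta]},

so that while the disk rotates every radial position ``r`` along the line
cursor blinks at its own temporal frequency ``k (r0 + r) nu_c``.  The same
pattern can be written with a time-dependent spatial frequency
``f_r(t) = k theta(t) / (2 pi)`` sweeping across the cursor,
``M = 1/2 {1 + cos[2 pi f_r(t) (r0 + r)]}``.

Unit conventions used throughout the package
--------------------------------------------
lengths in mm, angles in rad, temporal frequencies in Hz (cycles/s),
spatial frequencies in mm^-1 (cycles/mm), time in s.  The cursor coordinate
``r`` is measured from the inner end of the active span (``r = 0`` sits at
the physical radius represented by the pattern offset); conversion to the
lab frame is the caller's job.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

logger = logging.getLogger(__name__)

_PROFILES = ("cosine", "binary")


@dataclass(frozen=True)
class MaskSpec:
    """Chirp-rate / offset parameters of the rotating reticle.

    Parameters
    ----------
    k : float
        Chirp rate in mm^-1 per radian of mask rotation.  Must be > 0.
    r0 : float
        Radial offset of the pattern in mm.  Must be >= 0.
    r_min, r_max : float
        Active radial span of the line cursor on the mask (mm).
    profile : {"cosine", "binary"}
        ``cosine`` is the canonical analytic profile; ``binary`` emulates a
        manufactured chrome-on-glass mask (duty-cycled hard threshold).
    duty : float
        Fractional duty cycle of the binary profile (ignored for cosine).
    min_feature : float, optional
        Smallest printable half-period in mm.  Metadata only; used to warn
        about under-resolved raster renders.
    """

    k: float
    r0: float
    r_min: float = 0.0
    r_max: float = 1.0
    profile: str = "cosine"
    duty: float = 0.5
    min_feature: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.k > 0:
            raise ValueError(f"chirp rate k must be > 0, got {self.k}")
        if self.r0 < 0:
            raise ValueError(f"radial offset r0 must be >= 0, got {self.r0}")
        if not (self.r_max > self.r_min >= 0):
            raise ValueError(
                f"need r_max > r_min >= 0, got r_min={self.r_min}, r_max={self.r_max}"
            )
        if self.profile not in _PROFILES:
            raise ValueError(f"profile must be one of {_PROFILES}, got {self.profile!r}")
        if not 0 < self.duty < 1:
            raise ValueError(f"duty cycle must lie in (0, 1), got {self.duty}")

    # -- serialization (key=value config blocks, see spifi.io) ------------
    def to_dict(self) -> dict:
        d = {
            "mask.k": self.k,
            "mask.r0": self.r0,
            "mask.r_min": self.r_min,
            "mask.r_max": self.r_max,
            "mask.profile": self.profile,
            "mask.duty": self.duty,
        }
        if self.min_feature is not None:
            d["mask.min_feature"] = self.min_feature
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MaskSpec":
        def get(key, default=None, cast=float):
            v = d.get(f"mask.{key}", default)
            return v if v is None or isinstance(v, str) else cast(v)

        return cls(
            k=float(d["mask.k"]),
            r0=float(d["mask.r0"]),
            r_min=float(d.get("mask.r_min", 0.0)),
            r_max=float(d.get("mask.r_max", 1.0)),
            profile=str(d.get("mask.profile", "cosine")),
            duty=float(d.get("mask.duty", 0.5)),
            min_feature=(None if d.get("mask.min_feature") is None
                         else float(d["mask.min_feature"])),
        )


@dataclass
class RotationState:
    """One mask rotation: time grid, angle, and optional wobble phase.

    ``theta_of_t`` is non-decreasing and spans exactly 2*pi over the trace
    when no speed jitter is present.  ``phi_of_t`` is the common wobble
    phase added to the pattern argument (zero when the mask is perfectly
    centred); order q of the detected signal picks up ``q * phi(t)``.
    """

    nu_c: float                      # carrier rotation frequency, Hz
    t: np.ndarray                    # time grid over one rotation, s
    theta_of_t: np.ndarray           # rotation angle per sample, rad
    phi_of_t: np.ndarray             # wobble phase per sample, rad
    jitter: Optional[dict] = None    # speed-modulation record, if any

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.theta_of_t = np.asarray(self.theta_of_t, dtype=float)
        self.phi_of_t = np.asarray(self.phi_of_t, dtype=float)
        if self.t.shape != self.theta_of_t.shape or self.t.shape != self.phi_of_t.shape:
            raise ValueError("t, theta_of_t and phi_of_t must share one grid")
        if np.any(np.diff(self.theta_of_t) < 0):
            raise ValueError("theta_of_t must be non-decreasing")

    @classmethod
    def make(
        cls,
        nu_c: float,
        n_samples: int = 2 ** 14,
        wobble: "Callable[[np.ndarray], np.ndarray] | np.ndarray | None" = None,
        speed_drift: float = 0.0,
    ) -> "RotationState":
        """Build one rotation at carrier ``nu_c`` sampled ``n_samples`` times.

        ``speed_drift`` is a fractional linear ramp of the rotation speed
        (-drift at the start, +drift at the end); the angle still spans
        exactly 2*pi so the rotation period is preserved.
        ``wobble`` may be a callable phi(t) or an array on the same grid.
        """
        if nu_c <= 0:
            raise ValueError("nu_c must be > 0")
        T = 1.0 / nu_c
        t = np.arange(n_samples) / n_samples * T
        if speed_drift:
            # theta(t) = 2 pi nu_c [t + d (t^2/T - t)]; theta(T) = 2 pi exactly
            theta = 2 * np.pi * nu_c * (t + speed_drift * (t ** 2 / T - t))
            jitter = {"kind": "linear-drift", "fraction": speed_drift}
        else:
            theta = 2 * np.pi * nu_c * t
            jitter = None
        if wobble is None:
            phi = np.zeros_like(t)
        elif callable(wobble):
            phi = np.asarray(wobble(t), dtype=float)
        else:
            phi = np.asarray(wobble, dtype=float)
        return cls(nu_c=nu_c, t=t, theta_of_t=theta, phi_of_t=phi, jitter=jitter)

    @property
    def period(self) -> float:
        return 1.0 / self.nu_c

    def fiducial_times(self, n_fid: int = 8) -> np.ndarray:
        """Times at which theta crosses j * 2*pi / n_fid (timing-laser pulses)."""
        targets = np.arange(n_fid) * 2 * np.pi / n_fid
        return np.interp(targets, self.theta_of_t, self.t)


def _check_r(spec: MaskSpec, r) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    if np.any(r < spec.r_min - 1e-12) or np.any(r > spec.r_max + 1e-12):
        raise ValueError(
            f"r outside active span [{spec.r_min}, {spec.r_max}] mm"
        )
    return r


def mask_value(spec: MaskSpec, r, theta):
    """Mask transmission at cursor position ``r`` (mm) and angle ``theta`` (rad).

    Cosine profile: 1/2 {1 + cos[k (r0 + r) theta]}, values in [0, 1].
    Binary profile: the cosine thresholded at the level giving the requested
    duty cycle, values in {0, 1}.
    """
    r = _check_r(spec, r)
    u = spec.k * (spec.r0 + r) * np.asarray(theta, dtype=float)
    c = np.cos(u)
    if spec.profile == "cosine":
        return 0.5 * (1.0 + c)
    # fraction of a period with cos(u) >= cos(pi * duty) equals duty
    return (c >= np.cos(np.pi * spec.duty)).astype(float)


def pixel_temporal_frequency(spec: MaskSpec, r, nu_c: float):
    """Temporal blink frequency (Hz) of cursor pixel ``r`` at rotation rate ``nu_c``.

    Each position r is encoded at k (r0 + r) cycles per rotation, hence
    k (r0 + r) * nu_c cycles per second.
    """
    if nu_c <= 0:
        raise ValueError("nu_c must be > 0")
    r = _check_r(spec, r)
    return spec.k * (spec.r0 + r) * nu_c


def instantaneous_spatial_frequency(spec: MaskSpec, theta):
    """Spatial frequency f_r = k * theta / (2 pi) across the cursor at angle theta.

    Sweeps through zero at theta = 0; negative theta yields negative
    frequencies (the mirror-image sweep direction).
    """
    return spec.k * np.asarray(theta, dtype=float) / (2 * np.pi)


def render_mask_raster(spec: MaskSpec, x: np.ndarray, y: np.ndarray, theta: float) -> np.ndarray:
    """Render the mask on a cartesian grid at angle ``theta`` (visualization,
    camera-style MTF simulation).

    ``x`` and ``y`` are 1-D coordinate vectors in the cursor frame (mm); the
    pattern argument uses the polar radius ``hypot(x, y)`` in place of r, so
    the central row (y = 0) reproduces the 1-D ``mask_value`` along r.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if spec.min_feature is not None:
        step = max(
            float(np.max(np.abs(np.diff(x)))) if x.size > 1 else 0.0,
            float(np.max(np.abs(np.diff(y)))) if y.size > 1 else 0.0,
        )
        if step > spec.min_feature:
            logger.warning(
                "raster grid step %.3g mm is coarser than min_feature %.3g mm; "
                "pattern will be under-resolved", step, spec.min_feature,
            )
    rr = np.hypot(x[None, :], y[:, None])
    u = spec.k * (spec.r0 + rr) * float(theta)
    c = np.cos(u)
    if spec.profile == "cosine":
        return 0.5 * (1.0 + c)
    return (c >= np.cos(np.pi * spec.duty)).astype(float)
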