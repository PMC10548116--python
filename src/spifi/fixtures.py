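"""Deterministic synthetic objects, wobble phases and MTF profiles.

Every generator is pure given (params, seed): the same call yields the
same arrays.  Objects emulate the samples used to characterize a SPIFI
microscope - sub-resolution point emitters (fluorescent nanodiamonds),
resolution-target bar groups, sparse bead fields and smooth textures - so
that every module is testable without any recorded data.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np

from .mask_model import MaskSpec
from .forward_sim import SampleObject, SampleObject2D
from .metrics import super_gaussian

__all__ = [
    "make_object",
    "make_geometric_wobble",
    "make_mtf_profiles",
    "OBJECT_NAMES",
]

# USAF-1951 group 6 line pitches (um), elements 1..6: 2^(6 + (e-1)/6) lp/mm
USAF_GROUP6_PITCH_UM = tuple(1e3 / (2 ** (6 + (e - 1) / 6)) for e in range(1, 7))

OBJECT_NAMES = ("point", "two_point", "bar_triplet", "texture", "bead_field")


def _grid(params: dict) -> np.ndarray:
    r_min = float(params.get("r_min", 0.0))
    r_max = float(params.get("r_max", 1.0))
    n = int(params.get("n", 512))
    return np.linspace(r_min, r_max, n)


def make_object(name: str, seed: Optional[int] = None, **params):
    """Build a named synthetic object.

    point         sub-resolution delta at ``position`` (mm); unit integral.
    two_point     two deltas separated by ``separation`` (mm) about
                  ``center``.
    bar_triplet   three bars at ``pitch_um`` centre-to-centre (default
                  7.81 um, USAF group 6 element 6), ``bar_width`` fraction
                  of the pitch.
    texture       band-limited nonnegative random profile (needs seed).
    bead_field    2-D: ``n_beads`` Gaussian spots over (y [um], r [mm])
                  (needs seed).

    Ground-truth feature positions are recorded in ``meta``.
    """
    if name == "point":
        r = _grid(params)
        pos = float(params.get("position", 0.5 * (r[0] + r[-1])))
        idx = int(np.argmin(np.abs(r - pos)))
        resp = np.zeros_like(r)
        resp[idx] = 1.0 / (r[1] - r[0])
        return SampleObject(r=r, response=resp,
                            meta={"name": name, "position": float(r[idx])})
    if name == "two_point":
        r = _grid(params)
        center = float(params.get("center", 0.5 * (r[0] + r[-1])))
        sep = float(params["separation"])
        resp = np.zeros_like(r)
        pos = []
        for s in (-0.5, 0.5):
            idx = int(np.argmin(np.abs(r - (center + s * sep))))
            resp[idx] += 1.0 / (r[1] - r[0])
            pos.append(float(r[idx]))
        return SampleObject(r=r, response=resp,
                            meta={"name": name, "positions": pos})
    if name == "bar_triplet":
        r = _grid(params)
        pitch = float(params.get("pitch_um", USAF_GROUP6_PITCH_UM[-1])) * 1e-3  # mm
        width = float(params.get("bar_width", 0.5)) * pitch
        center = float(params.get("center", 0.5 * (r[0] + r[-1])))
        resp = np.zeros_like(r)
        centers = [center - pitch, center, center + pitch]
        rendered = []
        for c in centers:
            sel = np.abs(r - c) <= width / 2
            resp[sel] = 1.0
            # the grid-rendered bar centroid, which is what an imaging
            # measurement actually localizes
            rendered.append(float(np.mean(r[sel])) if np.any(sel) else c)
        return SampleObject(r=r, response=resp,
                            meta={"name": name, "pitch_um": pitch * 1e3,
                                  "bar_centers": rendered,
                                  "bar_centers_requested": centers})
    if name == "texture":
        if seed is None:
            raise ValueError("texture requires a seed")
        r = _grid(params)
        cutoff = float(params.get("cutoff_cycles", 8.0))  # cycles over the span
        rng = np.random.default_rng(seed)
        spec = np.zeros(r.size, dtype=complex)
        kmax = max(1, int(cutoff))
        spec[1:kmax + 1] = rng.normal(size=kmax) + 1j * rng.normal(size=kmax)
        prof = np.real(np.fft.ifft(spec)) * r.size
        prof -= prof.min()
        prof += 0.05 * max(prof.max(), 1e-12)
        return SampleObject(r=r, response=prof,
                            meta={"name": name, "seed": seed, "cutoff": cutoff})
    if name == "bead_field":
        if seed is None:
            raise ValueError("bead_field requires a seed")
        rng = np.random.default_rng(seed)
        r = _grid(params)
        ny = int(params.get("ny", 64))
        y_span = float(params.get("y_span_um", 32.0))
        n_beads = int(params.get("n_beads", 10))
        radius_mm = float(params.get("bead_radius_mm", 0.01))
        radius_um = float(params.get("bead_radius_um", 1.0))
        y = np.linspace(0.0, y_span, ny)
        resp = np.zeros((ny, r.size))
        beads = []
        margin_r = 0.1 * (r[-1] - r[0])
        for _ in range(n_beads):
            rc = rng.uniform(r[0] + margin_r, r[-1] - margin_r)
            yc = rng.uniform(0.1 * y_span, 0.9 * y_span)
            amp = rng.uniform(0.5, 1.0)
            resp += amp * np.exp(
                -(((r[None, :] - rc) / radius_mm) ** 2
                  + ((y[:, None] - yc) / radius_um) ** 2)
            )
            beads.append({"r_mm": float(rc), "y_um": float(yc), "amp": float(amp)})
        return SampleObject2D(y=y, r=r, response=resp,
                              meta={"name": name, "seed": seed, "beads": beads})
    raise ValueError(f"unknown object {name!r}; choose one of {OBJECT_NAMES}")


def make_geometric_wobble(
    center_offset: float,
    mask: MaskSpec,
    nu_c: float,
    t: np.ndarray,
    psi0: float = 0.0,
) -> np.ndarray:
    """Common wobble phase from an off-centre mask mount.

    A pattern centre displaced by ``center_offset`` (mm) from the rotation
    axis makes the pattern radius seen by a fixed cursor pixel oscillate
    once per rotation, delta_r(t) = -eps cos(theta(t) + psi0).  The
    equivalent common phase uses the mid-rotation pattern angle pi as the
    representative multiplier (small-offset approximation, periodic with
    the rotation by construction):

        phi(t) = -k * pi * eps * cos(2 pi nu_c t + psi0).

    Zero offset returns phi = 0 identically.
    """
    eps = float(center_offset)
    if eps < 0:
        raise ValueError("center_offset must be >= 0")
    if eps > 0.05 * (mask.r0 + mask.r_min):
        warnings.warn(
            "center offset exceeds 5% of the pattern radius; the small-"
            "offset phase approximation degrades", stacklevel=2,
        )
    t = np.asarray(t, dtype=float)
    return -mask.k * np.pi * eps * np.cos(2 * np.pi * nu_c * t + psi0)


def make_mtf_profiles(
    sf_um: np.ndarray,
    mtf_params: tuple = (1.0, 0.386, 6.24),
    pixel_cal: float = 0.2,
    n_px: int = 512,
    noise_rms: float = 0.01,
    seed: Optional[int] = None,
    beating_at: Optional[np.ndarray] = None,
):
    """Synthetic camera line profiles for an MTF measurement.

    Each profile is a Gaussian reference beam carrying a cosine
    modulation at spatial frequency ``sf_um[i]`` (um^-1) with modulation
    depth drawn from the super-Gaussian ``mtf_params`` (a, b, c); optional
    multiplicative Gaussian noise of relative RMS ``noise_rms``.  Indices
    listed in ``beating_at`` receive a second tone (an aliased/beating
    profile that a measurement must exclude).

    Returns (profiles, reference).
    """
    sf = np.asarray(sf_um, dtype=float)
    if noise_rms > 0 and seed is None:
        raise ValueError("noisy profiles require a seed")
    rng = np.random.default_rng(seed)
    x = np.arange(n_px) * pixel_cal
    ref = np.exp(-(((x - x.mean()) / (0.3 * x.max())) ** 2))
    depth = super_gaussian(sf, *mtf_params)
    profiles = np.empty((sf.size, n_px))
    beat = set(int(i) for i in (beating_at if beating_at is not None else []))
    for i, f in enumerate(sf):
        mod = 0.5 * (1.0 + depth[i] * np.cos(2 * np.pi * f * x))
        if i in beat:
            mod += 0.5 * depth[i] * np.cos(2 * np.pi * 0.7 * f * x)
        prof = ref * np.clip(mod, 0.0, None)
        if noise_rms > 0:
            prof = prof * (1.0 + rng.normal(0.0, noise_rms, n_px))
        profiles[i] = np.clip(prof, 0.0, None)
    return profiles, ref
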