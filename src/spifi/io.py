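"""File formats shared by all modules.

Traces, wobble phases and MTF curves are persisted as human-diffable
columnar text with a ``# key = value`` metadata header; traces also have
an equivalent compact binary container (NumPy ``.npz``) with an identical
schema for large sweeps.  Images are 32-bit float grayscale TIFF with the
axis calibration stored as JSON in the description tag.  Run
configuration is flat ``key = value`` text (ini-style sections allowed,
flattened to ``section.key``); unknown keys are rejected.
"""

from __future__ import annotations

import configparser
import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import tifffile

from .forward_sim import TimeTrace
from .metrics import MTFCurve
from .wobble import WobblePhase

__all__ = [
    "read_trace",
    "write_trace",
    "read_image",
    "write_image",
    "read_wobble",
    "write_wobble",
    "write_mtf",
    "read_config",
    "CONFIG_DEFAULTS",
]

_TRACE_MAGIC = "spifi-trace 1"


class SchemaError(ValueError):
    """Malformed file header or missing required key."""


def write_trace(path: Union[str, Path], trace: TimeTrace, fmt: str = "text") -> Path:
    """Write a trace; ``fmt`` is "text" (default interchange) or "npz".

    Text round-trips to 1e-12 relative (17 significant digits, i.e.
    exactly for double precision); npz round-trips bit-exact.
    """
    path = Path(path)
    if fmt == "npz":
        np.savez(path, t=trace.t, signal=trace.signal,
                 nu_c=np.float64(trace.nu_c),
                 meta_json=np.bytes_(json.dumps(trace.meta).encode()))
        return path
    if fmt != "text":
        raise ValueError(f"unknown trace format {fmt!r}")
    lines = [f"# {_TRACE_MAGIC}", f"# nu_c = {trace.nu_c!r}"]
    for key in sorted(trace.meta):
        lines.append(f"# meta.{key} = {json.dumps(trace.meta[key])}")
    lines.append("# columns = time_s signal")
    body = "\n".join(f"{tv:.17g} {sv:.17g}" for tv, sv in zip(trace.t, trace.signal))
    path.write_text("\n".join(lines) + "\n" + body + "\n")
    return path


def read_trace(path: Union[str, Path]) -> TimeTrace:
    """Read a trace written by :func:`write_trace` (either format)."""
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path) as z:
            meta = json.loads(bytes(z["meta_json"]).decode())
            return TimeTrace(t=z["t"], signal=z["signal"],
                             nu_c=float(z["nu_c"]), meta=meta)
    nu_c = None
    meta: dict = {}
    t_vals, s_vals = [], []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            content = line[1:].strip()
            if content == _TRACE_MAGIC or content.startswith("columns"):
                continue
            if "=" not in content:
                raise SchemaError(f"{path}:{lineno}: malformed header line {raw!r}")
            key, _, val = content.partition("=")
            key, val = key.strip(), val.strip()
            if key == "nu_c":
                nu_c = float(val)
            elif key.startswith("meta."):
                meta[key[5:]] = json.loads(val)
            else:
                raise SchemaError(f"{path}:{lineno}: unknown header key {key!r}")
            continue
        parts = line.split()
        if len(parts) != 2:
            raise SchemaError(f"{path}:{lineno}: expected two columns, got {raw!r}")
        t_vals.append(float(parts[0]))
        s_vals.append(float(parts[1]))
    if nu_c is None:
        raise SchemaError(f"{path}: required header key 'nu_c' missing")
    return TimeTrace(t=np.array(t_vals), signal=np.array(s_vals),
                     nu_c=nu_c, meta=meta)


def write_image(path: Union[str, Path], image: np.ndarray,
                axes: Optional[dict] = None) -> Path:
    """Write a 2-D image as 32-bit float grayscale TIFF.

    ``axes`` is a JSON-serializable dict (e.g. {"x_um_per_px": ...,
    "y_um_per_px": ..., "x_unit": "um"}) stored in the description tag.
    Non-finite pixels are rejected.
    """
    path = Path(path)
    img = np.asarray(image, dtype=np.float32)
    if img.ndim != 2:
        raise ValueError("image must be 2-D (use a 1xN image for single lines)")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite pixels")
    tifffile.imwrite(path, img, description=json.dumps(axes or {}))
    return path


def read_image(path: Union[str, Path]):
    """Read a TIFF written by :func:`write_image`; returns (image, axes)."""
    with tifffile.TiffFile(path) as tf:
        img = tf.asarray()
        desc = tf.pages[0].description or "{}"
    try:
        axes = json.loads(desc)
    except json.JSONDecodeError:
        axes = {}
    return img, axes


def write_wobble(path: Union[str, Path], wp: WobblePhase) -> Path:
    """Persist a wobble phase as two-column text (tau_s, phi_rad)."""
    path = Path(path)
    lines = [
        "# spifi-wobble 1",
        f"# mean_freq = {wp.mean_freq!r}",
        f"# wg = {wp.wg!r}",
        f"# meta = {json.dumps(wp.meta)}",
        "# columns = tau_s phi_rad centroid_hz",
    ]
    body = "\n".join(
        f"{tv:.17g} {pv:.17g} {cv:.17g}"
        for tv, pv, cv in zip(wp.tau, wp.phi, wp.centroid)
    )
    path.write_text("\n".join(lines) + "\n" + body + "\n")
    return path


def read_wobble(path: Union[str, Path]) -> WobblePhase:
    path = Path(path)
    mean_freq = None
    wg = 0.0
    meta: dict = {}
    tau, phi, cen = [], [], []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            content = line[1:].strip()
            if "=" not in content:
                continue
            key, _, val = content.partition("=")
            key, val = key.strip(), val.strip()
            if key == "mean_freq":
                mean_freq = float(val)
            elif key == "wg":
                wg = float(val)
            elif key == "meta":
                meta = json.loads(val)
            continue
        parts = line.split()
        if len(parts) != 3:
            raise SchemaError(f"{path}:{lineno}: expected three columns")
        tau.append(float(parts[0]))
        phi.append(float(parts[1]))
        cen.append(float(parts[2]))
    if mean_freq is None:
        raise SchemaError(f"{path}: required header key 'mean_freq' missing")
    return WobblePhase(tau=np.array(tau), phi=np.array(phi),
                       centroid=np.array(cen), mean_freq=mean_freq,
                       wg=wg, meta=meta)


def write_mtf(path: Union[str, Path], curve: MTFCurve) -> Path:
    """Persist an MTF curve as columnar text with the fit in the header."""
    path = Path(path)
    a, b, c = curve.fit
    lines = [
        "# spifi-mtf 1",
        f"# fit_a = {a!r}",
        f"# fit_b = {b!r}",
        f"# fit_c = {c!r}",
        f"# fit_rmse = {curve.fit_rmse!r}",
        "# columns = sf_per_um amplitude excluded_reason",
    ]
    body = "\n".join(
        f"{s:.17g} {m:.17g} {reason or '-'}"
        for s, m, reason in zip(curve.sf, curve.amp, curve.excluded)
    )
    path.write_text("\n".join(lines) + "\n" + body + "\n")
    return path


CONFIG_DEFAULTS: dict = {
    "mask.k": 10.0,
    "mask.r0": 20.0,
    "mask.r_min": 0.0,
    "mask.r_max": 4.0,
    "mask.profile": "cosine",
    "mask.duty": 0.5,
    "mask.min_feature": None,
    "rotation.nu_c": 60.0,
    "rotation.n_samples": 16384,
    "rotation.speed_drift": 0.0,
    "noise.photons_per_sample": None,
    "noise.additive_rms": 0.0,
    "noise.carrier_phase_jitter": 0.0,
    "object.name": "point",
    "object.n": 512,
    "object.position": None,
    "object.separation": None,
    "reconstruct.order": 1,
    "reconstruct.band": "auto",
    "reconstruct.window": None,
    "wobble.wg_periods": 12.0,
    "wobble.n_tau": 256,
    "sim.p": 1,
    "seed": 0,
    "output.dir": ".",
}


def read_config(path: Union[str, Path]) -> dict:
    """Load a flat key=value config (ini sections flattened to section.key).

    Unknown keys raise :class:`SchemaError`; absent keys take the
    documented defaults in :data:`CONFIG_DEFAULTS`.
    """
    parser = configparser.ConfigParser()
    text = Path(path).read_text()
    # allow a section-less prologue
    parser.read_string("[_root]\n" + text)
    cfg = dict(CONFIG_DEFAULTS)
    for section in parser.sections():
        for key, raw in parser.items(section):
            name = key if section == "_root" else f"{section}.{key}"
            if name not in CONFIG_DEFAULTS:
                raise SchemaError(f"unknown config key {name!r}")
            default = CONFIG_DEFAULTS[name]
            if raw.lower() in ("none", ""):
                cfg[name] = None
            elif isinstance(default, bool):
                cfg[name] = raw.lower() in ("1", "true", "yes")
            elif isinstance(default, int) and not isinstance(default, bool):
                cfg[name] = int(raw)
            elif isinstance(default, float):
                cfg[name] = float(raw)
            elif default is None:
                try:
                    cfg[name] = float(raw)
                except ValueError:
                    cfg[name] = raw
            else:
                cfg[name] = raw
    return cfg
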