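# spifi

Simulation, reconstruction and metrology toolkit for **spatial-frequency
modulation imaging (SPIFI)** — single-pixel structured-illumination
microscopy with a rotating chirped reticle — including the
wavelength-domain variant used for in-line group-delay-dispersion (GDD)
optimization of ultrafast excitation pulses.

## Who this is for

SPIFI encodes a line focus so that every position `r` along it blinks at
its own temporal frequency: the spinning mask

    M(r, theta) = 1/2 {1 + cos[k (r0 + r) theta]}

maps position to frequency `k (r0 + r) nu_c`, so a single photodiode or
PMT trace Fourier-transforms directly into a line image.  Because the
detected intensity involves `M^(2p)` (p = 1 linear, p = 2 for 2PEF/SHG),
the spectrum contains harmonics `q = 1 .. 2p`; order q samples the
object's spatial spectrum at `q f_r(t)` and therefore delivers up to
2p-fold enhanced resolution at reduced amplitude:

    M^2  = 1/8  {3 + 4 cos u + cos 2u}
    M^4  = 1/128{35 + 56 cos u + 28 cos 2u + 8 cos 3u + cos 4u}

The package is for microscopists and instrument builders who want to
prototype SPIFI acquisition and processing chains without hardware:
forward simulation of single-pixel traces (with shot noise, detector
noise, motor-speed drift and mask-mount wobble), FFT reconstruction with
higher-order extraction, Gabor-transform wobble correction, frequency-to-
position calibration, MTF/PSF/NA metrology, and a 1-D pulse model of the
wavelength-domain SPIFI dispersion optimizer (Martinez compressor with
the mask in the spectral Fourier plane).

## Worked example

Simulate a sub-resolution two-photon emitter and extract the first- and
second-order line images:

```python
import numpy as np
from spifi import (MaskSpec, RotationState, LineCursor,
                   generate_trace, fft_line, order_image)
from spifi.fixtures import make_object
from spifi.metrics import fwhm

mask = MaskSpec(k=10.0, r0=20.0, r_min=0.0, r_max=4.0)   # 200-240 cycles/rot
rot = RotationState.make(nu_c=60.0, n_samples=2**14)
cursor = LineCursor.uniform(0.0, 4.0, 401)
obj = make_object("point", r_min=0.0, r_max=4.0, n=401, position=1.3)
trace = generate_trace(mask, rot, cursor, obj, p=2)       # two-photon contrast

spec = fft_line(trace, window="hann", pad=8)
for q in (1, 2):
    img = order_image(spec, q)
    centre = img.freq[np.argmax(img.amplitude)]
    width = fwhm(img.amplitude, img.freq) / (q * mask.k * rot.nu_c) * 1e3
    print(f"order {q}: centre {centre:8.1f} Hz, position FWHM {width:5.1f} um")
```

prints

```
order 1: centre  12780.0 Hz, position FWHM 200.0 um
order 2: centre  25560.0 Hz, position FWHM 100.0 um
```

The emitter at r = 1.3 mm blinks at 10 x (20 + 1.3) x 60 = 12780 Hz; the
second-order image sits at exactly twice that frequency and, after the
order-aware frequency-to-position mapping, is half as wide — the
enhanced-resolution mechanism.  The widths equal the band-limit
1/(q k) = 100/q um of a mask sweeping 10 cycles/mm per rotation (times
the Hann analysis-window factor of 2).

The same chain is available from the shell:

```sh
spifi simulate trace.txt --seed 1
spifi reconstruct trace.txt line.tif --order 2
spifi wobble-estimate trace.txt wobble.txt
spifi wobble-correct trace.txt wobble.txt corrected.tif --order 2
spifi mtf --out mtf_report.txt
spifi wd-scan --out wd_scan.tsv --downstream-gdd 40000
```

Other highlights, each exercised by the test suite:

* **Wobble correction** — a 2 rad once-per-rotation mount wobble broadens
  the first-order point image ~1.9x; estimating phi(t) from the Gabor
  spectrogram centroid and applying `exp(-i q phi)` restores the width to
  within 0.1% of the wobble-free value.
* **FFT-magnitude averaging** — with sparse Poisson photons and an
  unstable rotation trigger, averaging 30 FFT magnitudes preserves the
  image peak that raw-signal averaging washes out.
* **Dispersion optimization** — sweeping the compressor output-grating
  offset, the envelope FWHM of the nonlinear signal is unimodal and its
  minimum cancels the injected downstream GDD within one grid step while
  maximizing the peak signal.

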