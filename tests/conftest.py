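"""Shared simulation fixtures.

The standard scenario is a mask with 200-240 pattern cycles per rotation
(k = 10 mm^-1, r0 = 20 mm, 4 mm cursor) spinning at 60 Hz, sampled 2^14
times per rotation, with a sub-resolution point emitter placed on a grid
point so its 213 cycles/rotation tone is exactly periodic over the trace.
"""

import numpy as np
import pytest

from spifi import (
    LineCursor,
    MaskSpec,
    RotationState,
    generate_trace,
)
from spifi.fixtures import make_object

NU_C = 60.0
N_SAMPLES = 2 ** 14
N_CURSOR = 401            # dr = 0.01 mm over [0, 4]
POINT_R = 1.3             # mm -> k (r0 + r) = 213 cycles per rotation


@pytest.fixture(scope="session")
def std_mask():
    return MaskSpec(k=10.0, r0=20.0, r_min=0.0, r_max=4.0)


@pytest.fixture(scope="session")
def std_rot():
    return RotationState.make(NU_C, N_SAMPLES)


@pytest.fixture(scope="session")
def std_cursor():
    return LineCursor.uniform(0.0, 4.0, N_CURSOR)


@pytest.fixture(scope="session")
def point_obj():
    return make_object("point", r_min=0.0, r_max=4.0, n=N_CURSOR, position=POINT_R)


@pytest.fixture(scope="session")
def point_trace(std_mask, std_rot, std_cursor, point_obj):
    return generate_trace(std_mask, std_rot, std_cursor, point_obj, p=1)


@pytest.fixture(scope="session")
def point_trace_p2(std_mask, std_rot, std_cursor, point_obj):
    return generate_trace(std_mask, std_rot, std_cursor, point_obj, p=2)


@pytest.fixture(scope="session")
def point_freq(std_mask):
    return std_mask.k * (std_mask.r0 + POINT_R) * NU_C   # 12780 Hz
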