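import struct

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "octmorph",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("octmorph")


def write_imagej_roi(path, xy, roi_type=5):
    """Write a minimal ImageJ .roi file (int16 coordinates, polyline=5).

    Synthetic test helper mirroring the classic RoiEncoder layout: "Iout"
    magic, version, type byte, int16 bounds, N, coordinates from offset 64 as
    x-offsets then y-offsets relative to (left, top).
    """
    xy = np.asarray(xy, dtype=int)
    left, top = int(xy[:, 0].min()), int(xy[:, 1].min())
    right, bottom = int(xy[:, 0].max()), int(xy[:, 1].max())
    n = xy.shape[0]
    header = bytearray(64)
    header[0:4] = b"Iout"
    struct.pack_into(">h", header, 4, 228)  # version
    header[6] = roi_type
    struct.pack_into(">4h", header, 8, top, left, bottom, right)
    struct.pack_into(">H", header, 16, n)
    xs = (xy[:, 0] - left).astype(">i2").tobytes()
    ys = (xy[:, 1] - top).astype(">i2").tobytes()
    path.write_bytes(bytes(header) + xs + ys)
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
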