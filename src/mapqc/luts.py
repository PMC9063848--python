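"""False-colour lookup tables for projection images.

The "glow" table ramps black → red → yellow → white, the classic
heated-body palette used for standard-deviation and maximum-value
projections, where it can reveal faint mask ghosts that a grayscale
rendering hides.  The 256×3 table here is generated analytically as a
synthetic reconstruction of that palette (piecewise-linear channel ramps),
not copied from any external LUT file.
"""

from __future__ import annotations

import numpy as np

__all__ = ["glow_lut"]


def glow_lut() -> np.ndarray:
    """256×3 uint8 table: black→red over [0,96], →yellow over [96,192], →white."""
    idx = np.arange(256, dtype=np.float64)
    red = np.clip(idx / 96.0, 0.0, 1.0)
    green = np.clip((idx - 96.0) / 96.0, 0.0, 1.0)
    blue = np.clip((idx - 192.0) / 63.0, 0.0, 1.0)
    table = np.stack([red, green, blue], axis=1)
    return np.round(table * 255.0).astype(np.uint8)
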