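"""Leaf-clip geometry helpers.

Narrow wheat laminae do not fill the standard leaf-clip field of view, so a
mask with an elliptical cut-out is used to restrict the aperture; the gasket
around it blocks stray light.  The aperture area enters any per-area
normalisation of clip measurements.
"""

from __future__ import annotations

import math


def elliptical_aperture_area(width_cm: float = 1.15, height_cm: float = 1.4) -> float:
    """Area (cm^2) of an elliptical mask aperture given its full axes.

    The default 1.15 cm x 1.4 cm opening suits wheat leaves; its area is
    pi * (1.15/2) * (1.4/2) ~= 1.264 cm^2.
    """
    if width_cm <= 0 or height_cm <= 0:
        raise ValueError("aperture axes must be positive")
    return math.pi * (width_cm / 2.0) * (height_cm / 2.0)
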