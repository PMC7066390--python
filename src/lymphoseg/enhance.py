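"""Narendra-Fitch local contrast enhancement.

Each pixel is re-expressed relative to the statistics of the square window
centered on it:

    p_enhanced = m + (c / sigma) * (p - m)

where m and sigma are the mean and (population) standard deviation of the
intensities inside the window and c > 0 is a fixed weight.  Pixels whose
window is constant (sigma = 0) are left at m, which equals p there.  The
transform amplifies weak local contrast (sigma < c) and damps strong local
contrast (sigma > c), flattening staining inhomogeneity before the
floating-threshold sweep.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .imgio import GreyImage

__all__ = ["EnhanceParams", "narendra_fitch_enhance"]


@dataclass(frozen=True)
class EnhanceParams:
    """Weight ``c`` and odd window edge length of the enhancement."""

    c: float
    window: int

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError("c must be > 0")
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be an odd integer >= 3")


def narendra_fitch_enhance(img: GreyImage, params: EnhanceParams) -> GreyImage:
    """Apply the local enhancement with reflect padding at borders.

    The window mean and standard deviation are computed with uniform
    filters in floating point; the output is rounded and clipped to
    [0, 255] at the very end.
    """
    p = img.astype_float()
    size = params.window
    m = ndimage.uniform_filter(p, size=size, mode="reflect")
    m2 = ndimage.uniform_filter(p * p, size=size, mode="reflect")
    var = np.maximum(m2 - m * m, 0.0)  # guard tiny negative round-off
    sigma = np.sqrt(var)
    out = m.copy()
    nz = sigma > 0
    out[nz] = m[nz] + (params.c / sigma[nz]) * (p[nz] - m[nz])
    out = np.clip(np.round(out), 0, 255).astype(np.uint8)
    return GreyImage(out, pixel_size_um=img.pixel_size_um)
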