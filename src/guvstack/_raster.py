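"""Bilinear raster resampling shared by patch preparation and the simulator."""

from __future__ import annotations

import numpy as np
from scipy import ndimage


def resample_bilinear(image: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    """Resample ``image`` to ``out_shape`` with bilinear interpolation.

    Output pixel (i, j) samples the input at the affinely mapped position
    ``i * (H_in - 1) / (H_out - 1)`` (endpoints map to endpoints), so the
    corner pixel centers of input and output coincide.
    """
    image = np.asarray(image, dtype=float)
    h_in, w_in = image.shape
    h_out, w_out = out_shape
    ys = np.linspace(0.0, h_in - 1.0, h_out)
    xs = np.linspace(0.0, w_in - 1.0, w_out)
    yy, xx = np.meshgrid(ys, xs, indexing="ij")
    return ndimage.map_coordinates(image, [yy, xx], order=1, mode="nearest")
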