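"""A simple multi-scale saliency stand-in used as a baseline null density.

Low-level conspicuity is approximated by centre-surround intensity contrast
(differences of Gaussians at several scales) plus oriented contrast energy
(Gabor magnitude at four orientations), each channel max-normalised before
summation.  The result is a non-negative map normalised to unit mass, suitable
as a Monte-Carlo null density.  Any user-supplied map of matching dimensions
can be plugged in instead; this module makes no claim to reproduce any
specific published saliency model.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.filters import gabor

__all__ = ["saliency_map"]


def saliency_map(
    image: np.ndarray,
    scales: tuple[float, ...] = (4.0, 8.0, 16.0),
    weights: tuple[float, float] = (1.0, 1.0),
    n_orientations: int = 4,
) -> np.ndarray:
    """Normalised saliency density for a grayscale stimulus image.

    Parameters
    ----------
    image:
        2D grayscale array (any numeric range).
    scales:
        Centre Gaussian widths in px; the surround is 4x wider.
    weights:
        (intensity, orientation) channel weights.
    """
    img = np.asarray(image, float)
    if img.ndim != 2:
        raise ValueError("image must be 2D grayscale")
    rng_span = img.max() - img.min()
    img = (img - img.min()) / rng_span if rng_span > 0 else np.zeros_like(img)

    sal = np.zeros_like(img)
    w_int, w_ori = weights
    for s in scales:
        cs = np.abs(gaussian_filter(img, s) - gaussian_filter(img, 4 * s))
        if cs.max() > 0:
            sal += w_int * cs / cs.max()
    for theta in np.arange(n_orientations) * np.pi / n_orientations:
        real, imag = gabor(img, frequency=1.0 / (4 * scales[0]), theta=theta)
        energy = np.hypot(real, imag)
        if energy.max() > 0:
            sal += (w_ori / n_orientations) * energy / energy.max()

    # small uniform floor keeps the density usable as a sampling null
    sal += 1e-3 * sal.max() if sal.max() > 0 else 1.0
    total = sal.sum()
    if total <= 0:
        raise ValueError("saliency map has zero mass")
    return sal / total
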