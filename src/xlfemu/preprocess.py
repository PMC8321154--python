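"""Pre-processing of raw light-fields into analysis-ready form.

The chain mirrors a standard X-ray workflow: flat-field (open-beam)
normalization per PHI, conversion to absorbance so the signal is additive
along rays, background subtraction against a box-blurred copy of each PHI
(removing smooth structures such as a curved container wall), and contrast
inversion so that low-attenuation features (air bubbles in gel) carry
positive signal.  A foreground mask is derived from the depth-summed focal
stack to suppress depth estimates over empty background.

Two stock pipelines are provided: :func:`preprocess_branch` (normalize +
absorbance — absorbing features are already positive) and
:func:`preprocess_bubbles` (adds background subtraction and inversion).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.ndimage import uniform_filter
from skimage.filters import threshold_otsu
from skimage.measure import label

from .lightfield import LightField

__all__ = [
    "normalize",
    "absorbance",
    "background_subtract",
    "invert_contrast",
    "compute_mask",
    "preprocess_branch",
    "preprocess_bubbles",
]

#: floor applied to transmission before any logarithm
TRANSMISSION_EPS = 1e-6


def normalize(lf: LightField) -> LightField:
    """Per-pixel open-beam normalization: transmission = raw / flat.

    Each PHI is divided by the flat acquired at the same source/detector
    position.  Values are floored at ``TRANSMISSION_EPS`` so a downstream
    logarithm is always defined.
    """
    if lf.flats is None:
        raise ValueError("light-field has no flats; cannot normalize")
    bad = np.where(~np.all(lf.flats > 0, axis=(1, 2)))[0]
    if bad.size:
        raise ValueError(
            f"flat image has non-positive pixels in view(s) {bad.tolist()}"
        )
    trans = np.maximum(lf.images / lf.flats, TRANSMISSION_EPS)
    variance = None
    if lf.variance is not None:
        # first-order propagation of raw/flat Poisson noise
        variance = trans**2 * (
            1.0 / np.maximum(lf.images, 1.0) + 1.0 / np.maximum(lf.flats, 1.0)
        )
    return lf.with_images(trans, "normalize", variance=variance)


def absorbance(lf: LightField) -> LightField:
    """−log of transmission: recovers ∫μ dl up to noise, making the signal
    additive along rays (the natural domain for shift-and-add refocusing)."""
    trans = np.maximum(lf.images, TRANSMISSION_EPS)
    variance = None if lf.variance is None else lf.variance / trans**2
    return lf.with_images(-np.log(trans), "absorbance", variance=variance)


def background_subtract(lf: LightField, kernel: int = 21) -> LightField:
    """Subtract a box-blurred copy of each PHI from itself.

    A ``kernel``×``kernel`` uniform filter (reflected edges) estimates the
    smooth background — e.g. the curved container signal — which is then
    removed, leaving compact features.
    """
    if kernel % 2 == 0:
        raise ValueError("kernel must be odd")
    ny, nx = lf.images.shape[1:]
    if kernel > min(ny, nx):
        raise ValueError(f"kernel {kernel} larger than image ({ny}×{nx})")
    blurred = uniform_filter(
        lf.images, size=(1, kernel, kernel), mode="reflect"
    )
    variance = None
    if lf.variance is not None:
        # Var(X − box(X)) = σ²(1 − 1/k²) for the center pixel's own term
        variance = lf.variance * (1.0 - 1.0 / kernel**2)
    return lf.with_images(
        lf.images - blurred, f"background_subtract(kernel={kernel})",
        variance=variance,
    )


def invert_contrast(lf: LightField) -> LightField:
    """Negate the (signed, post-subtraction) pixel values; applying twice
    restores the input.  Gives transmission-excess features (bubbles)
    positive signal."""
    return lf.with_images(-lf.images, "invert_contrast")


def compute_mask(
    stack_images: np.ndarray, min_component_frac: float = 1e-3
) -> np.ndarray:
    """Foreground mask from a focal stack.

    The stack is summed along depth, thresholded with Otsu's method, and
    connected components smaller than ``min_component_frac`` of the image
    area are dropped.  A degenerate (all-equal) sum yields an all-invalid
    mask with a warning.
    """
    summed = np.asarray(stack_images).sum(axis=0)
    if np.ptp(summed) < 1e-12:
        warnings.warn("degenerate focal-stack sum; mask is empty")
        return np.zeros(summed.shape, dtype=bool)
    fg = summed > threshold_otsu(summed)
    labels, n = label(fg, return_num=True)
    if n == 0:
        return fg
    min_pixels = min_component_frac * fg.size
    keep = np.zeros(summed.shape, dtype=bool)
    for comp in range(1, n + 1):
        component = labels == comp
        if component.sum() > min_pixels:
            keep |= component
    return keep


def preprocess_branch(lf: LightField) -> LightField:
    """Pipeline for absorbing (branch-like) samples: normalize, absorbance."""
    return absorbance(normalize(lf))


def preprocess_bubbles(lf: LightField, kernel: int = 21) -> LightField:
    """Pipeline for bubble-in-gel samples: normalize, absorbance, 21-pixel
    background subtraction, contrast inversion (bubbles become positive)."""
    return invert_contrast(background_subtract(absorbance(normalize(lf)), kernel))
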