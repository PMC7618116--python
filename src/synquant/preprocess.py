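"""Channel preprocessing: background subtraction, blur, smooth, contrast.

The four steps mirror a standard FIJI macro chain and are applied in a fixed
order: rolling-ball-style background subtraction → Gaussian blur → 3×3 mean
smoothing → percentile contrast stretch.  Contrast enhancement is meant for
the *detection* copy of a channel only; intensity quantification must always
read the raw channel (see :func:`synquant.puncta.detect_puncta`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import morphology, transform

from synquant.image_io import CalibratedImage


@dataclass
class PreprocessParams:
    """Parameters for the fixed four-step preprocessing chain.

    Scales are physical (μm) so the same configuration applies across
    magnifications.  Any step can be disabled by setting its field to
    ``None`` (or ``smooth=False``).

    Attributes
    ----------
    background_radius
        Rolling-ball radius in μm for background subtraction, or ``None``.
    gaussian_sigma
        Gaussian blur sigma in μm, or ``None``.
    smooth
        Apply a 3×3 mean filter (ImageJ "Smooth" semantics).
    contrast_saturation_fraction
        Fraction of pixels saturated at each tail by the percentile
        contrast stretch; in ``[0, 0.05)``; ``None`` disables.
    """

    background_radius: float | None = 5.0
    gaussian_sigma: float | None = 0.05
    smooth: bool = True
    contrast_saturation_fraction: float | None = 0.0035

    def __post_init__(self) -> None:
        if self.background_radius is not None and not (self.background_radius > 0):
            raise ValueError("background_radius must be > 0 when enabled")
        if self.gaussian_sigma is not None and not (self.gaussian_sigma > 0):
            raise ValueError("gaussian_sigma must be > 0 when enabled")
        if self.contrast_saturation_fraction is not None and not (
            0 <= self.contrast_saturation_fraction < 0.05
        ):
            raise ValueError("contrast_saturation_fraction must be in [0, 0.05)")


def subtract_background(plane: np.ndarray, radius_px: float) -> np.ndarray:
    """Subtract a morphological (grey-opening) background estimate.

    Equivalent in spirit to ImageJ's rolling-ball: structures smaller than
    the ball survive, smooth background is removed.  For large radii the
    background is estimated on a downscaled copy (as ImageJ does) to keep
    the cost independent of radius.
    """
    plane = np.asarray(plane, dtype=np.float64)
    shrink = max(1, int(radius_px // 16))
    if shrink > 1:
        small = transform.downscale_local_mean(plane, (shrink, shrink))
        r = max(1, round(radius_px / shrink))
        bg_small = morphology.opening(small, morphology.disk(r, decomposition="sequence"))
        bg = transform.resize(bg_small, plane.shape, order=1, mode="edge", anti_aliasing=False)
    else:
        r = max(1, round(radius_px))
        bg = morphology.opening(plane, morphology.disk(r, decomposition="sequence"))
    return np.clip(plane - bg, 0, None)


def stretch_contrast(plane: np.ndarray, saturation_fraction: float) -> np.ndarray:
    """Percentile stretch saturating ``saturation_fraction`` of pixels per tail.

    Output is rescaled to the input's original [min, max] span so intensity
    units stay comparable; constant planes are returned unchanged.
    """
    plane = np.asarray(plane, dtype=np.float64)
    lo = np.percentile(plane, 100 * saturation_fraction)
    hi = np.percentile(plane, 100 * (1 - saturation_fraction))
    if hi <= lo:
        return plane.copy()
    out = np.clip((plane - lo) / (hi - lo), 0, 1)
    return out * (plane.max() - plane.min()) + plane.min()


def preprocess_plane(
    plane: np.ndarray, pixel_size_xy: float, params: PreprocessParams
) -> np.ndarray:
    if not np.all(np.isfinite(plane)):
        raise ValueError("non-finite pixel values")
    out = np.asarray(plane, dtype=np.float64)
    if params.background_radius is not None:
        out = subtract_background(out, params.background_radius / pixel_size_xy)
    if params.gaussian_sigma is not None:
        out = ndimage.gaussian_filter(out, sigma=params.gaussian_sigma / pixel_size_xy)
    if params.smooth:
        out = ndimage.uniform_filter(out, size=3)
    if params.contrast_saturation_fraction is not None:
        out = stretch_contrast(out, params.contrast_saturation_fraction)
    return np.clip(out, 0, None)


def preprocess_channel(
    img: CalibratedImage, channel: int | str, params: PreprocessParams
) -> CalibratedImage:
    """Return a new image with the named channel preprocessed.

    Only the named channel changes.  For z-stacks each slice is processed
    independently (the macro chain is 2D).
    """
    data = img.channel(channel)
    if data.ndim == 3:
        out = np.stack(
            [preprocess_plane(sl, img.pixel_size_xy, params) for sl in data]
        )
    else:
        out = preprocess_plane(data, img.pixel_size_xy, params)
    return img.with_channel(channel, out)
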