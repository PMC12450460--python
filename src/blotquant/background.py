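"""Two-step background correction for dot-blot scans.

The correction follows the standard densitometry recipe: (1) suppress
pixel noise with a Gaussian blur (default sigma = 2 px), (2) estimate
the smooth local background of the *blurred* image with the rolling-ball
algorithm (default radius = 35 px), (3) subtract that background from
the *original* image, clipping at zero.

The rolling ball is implemented exactly as grayscale morphological
opening with a spherical-cap structuring element — the surface traced by
a ball of the given radius rolled beneath the intensity landscape. No
image shrinking/downsampling is performed; images at plate-scan scale
are small enough for the exact computation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .plate_io import RasterImage


@dataclass(frozen=True)
class CorrectionParams:
    """Parameters of the two-step correction.

    gaussian_sigma : blur scale in pixels (>= 0; 0 disables the blur)
    ball_radius    : rolling-ball radius in pixels (integer >= 1)
    border_mode    : boundary handling for both steps (reflect)
    """

    gaussian_sigma: float = 2.0
    ball_radius: int = 35
    border_mode: str = "reflect"

    def __post_init__(self) -> None:
        if self.gaussian_sigma < 0:
            raise ValueError("gaussian_sigma must be >= 0")
        if int(self.ball_radius) != self.ball_radius or self.ball_radius < 1:
            raise ValueError("ball_radius must be an integer >= 1")
        if self.border_mode != "reflect":
            raise ValueError("only 'reflect' border handling is supported")


def gaussian_blur(image: RasterImage, sigma: float) -> RasterImage:
    """Separable Gaussian convolution with reflective borders.

    ``sigma = 0`` returns the input unchanged.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return RasterImage(image.pixels.copy(), image.source_bit_depth)
    blurred = ndimage.gaussian_filter(image.pixels, sigma=sigma, mode="reflect")
    # convolution with a normalized kernel cannot produce negatives, but
    # guard against tiny float undershoot
    return RasterImage(np.maximum(blurred, 0.0), None)


def ball_element(radius: int) -> tuple[np.ndarray, np.ndarray]:
    """Spherical-cap structuring element for a ball of the given radius.

    Returns ``(footprint, heights)`` on the (2r+1)² integer offset grid:
    the footprint is the disc d <= r and the height profile is
    h(d) = sqrt(r² − d²), the upper surface of the ball.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    r = int(radius)
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    d2 = dx * dx + dy * dy
    footprint = d2 <= r * r
    heights = np.where(footprint, np.sqrt(np.maximum(r * r - d2, 0.0)), 0.0)
    return footprint, heights


def rolling_ball_background(image: RasterImage, radius: int) -> RasterImage:
    """Rolling-ball background: grayscale opening with a ball element.

    Erosion then dilation with the spherical-cap height profile, both
    with reflective borders. The result is anti-extensive: background
    <= input at every pixel.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    if radius > image.height and radius > image.width:
        raise ValueError(
            f"ball radius {radius} exceeds both image dimensions "
            f"{image.height}x{image.width}"
        )
    footprint, heights = ball_element(radius)
    eroded = ndimage.grey_erosion(
        image.pixels, footprint=footprint, structure=heights, mode="reflect"
    )
    opened = ndimage.grey_dilation(
        eroded, footprint=footprint, structure=heights, mode="reflect"
    )
    # opening is anti-extensive but erosion/dilation subtract and re-add
    # the cap height, so enforce the bound against float round-off
    opened = np.minimum(opened, image.pixels)
    return RasterImage(np.maximum(opened, 0.0), None)


def correct(image: RasterImage, params: CorrectionParams | None = None) -> RasterImage:
    """Full correction: original − rolling_ball(blur(original)), clipped at 0.

    The background is estimated on the blurred image but subtracted from
    the original, so spot amplitudes are not attenuated by the blur.
    """
    if params is None:
        params = CorrectionParams()
    blurred = gaussian_blur(image, params.gaussian_sigma)
    background = rolling_ball_background(blurred, params.ball_radius)
    corrected = np.clip(image.pixels - background.pixels, 0.0, None)
    return RasterImage(corrected, None)
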