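"""Image conditioning chain: inverted grayscale, rolling-ball background
subtraction, median denoising.

The chain mirrors the classic brightfield-densitometry recipe: a scanned
RGB (or grayscale) section is reduced to 16-bit gray, inverted so that dark
chromogen deposit maps to large values, the slowly varying background is
estimated by morphological opening with a ball-shaped structuring element
("rolling ball", default radius 500 px) and subtracted, and residual
shot-like noise is removed with a disk median filter (default radius 5 px).

The rolling ball uses a true hemispherical (non-flat) structuring element:
the background is the grayscale opening of the intensity landscape by a ball
of the given radius, i.e. the highest surface a ball rolled beneath the
landscape can touch.  For radii too large for direct morphology the estimate
is computed on a downsampled grid with a correspondingly subsampled ball and
interpolated back; the coarse estimate is clamped below the image so the
``output <= input`` contract always holds.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .image import MAX_GRAY, SectionImage

__all__ = [
    "to_inverted_gray",
    "rolling_ball_subtract",
    "median_denoise",
    "preprocess_chain",
    "ball_structure",
    "disk_footprint",
]

# ITU-R 601 luminance weights for RGB reduction.
_LUMA = np.array([0.299, 0.587, 0.114])

# Largest radius handled by direct grayscale morphology; beyond this the
# background is estimated on a downsampled grid.
_EXACT_RADIUS_LIMIT = 16


def to_inverted_gray(
    raw: np.ndarray, pixel_size_um: float = 1.0
) -> SectionImage:
    """Convert a 1- or 3-channel integer image to inverted 16-bit gray.

    3-channel input is reduced by ITU-R 601 luminance weighting and rescaled
    to the 16-bit range; 8-bit input is rescaled by 257 so that 255 maps to
    65535.  The result is complemented (``65535 - gray``) so that stronger
    staining (darker pixels) yields larger values.
    """
    arr = np.asarray(raw)
    if not np.issubdtype(arr.dtype, np.integer):
        raise TypeError("input image must be integer-valued")
    if arr.ndim == 3 and arr.shape[2] == 3:
        gray = arr.astype(np.float64) @ _LUMA
        peak = 255.0 if arr.dtype.itemsize == 1 else float(MAX_GRAY)
        gray16 = np.rint(gray * (MAX_GRAY / peak)).astype(np.int64)
    elif arr.ndim == 2:
        if arr.dtype.itemsize == 1:
            gray16 = arr.astype(np.int64) * 257  # 255 * 257 == 65535
        else:
            gray16 = arr.astype(np.int64)
    else:
        raise ValueError(
            f"unsupported channel layout: shape {arr.shape}; "
            "expected (H, W) or (H, W, 3)"
        )
    inverted = (MAX_GRAY - np.clip(gray16, 0, MAX_GRAY)).astype(np.uint16)
    return SectionImage(
        pixels=inverted,
        pixel_size_um=pixel_size_um,
        provenance=[{"op": "to_inverted_gray", "luma": "itu-r-601"}],
    )


def ball_structure(radius: int, step: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Hemispherical structuring element sampled every ``step`` pixels.

    Returns ``(footprint, heights)`` where ``heights[d] = sqrt(r^2 - |d|^2)``
    on the sampled grid (gray-level units), and the footprint marks offsets
    with ``|d| <= r``.
    """
    n = int(radius // step)
    coords = np.arange(-n, n + 1) * step
    dy, dx = np.meshgrid(coords, coords, indexing="ij")
    d2 = dy.astype(np.float64) ** 2 + dx.astype(np.float64) ** 2
    footprint = d2 <= radius**2
    heights = np.zeros_like(d2)
    heights[footprint] = np.sqrt(radius**2 - d2[footprint])
    return footprint, heights


def _opening_background(pixels: np.ndarray, radius: int) -> np.ndarray:
    """Grayscale opening by a hemispherical ball (edge-replicated borders)."""
    footprint, heights = ball_structure(radius)
    img = pixels.astype(np.float64)
    eroded = ndimage.grey_erosion(
        img, footprint=footprint, structure=heights, mode="nearest"
    )
    return ndimage.grey_dilation(
        eroded, footprint=footprint, structure=heights, mode="nearest"
    )


def _coarse_background(pixels: np.ndarray, radius: int) -> np.ndarray:
    """Downsample -> opening with subsampled ball -> upsample."""
    step = int(np.ceil(radius / _EXACT_RADIUS_LIMIT))
    img = pixels.astype(np.float64)
    coarse = img[::step, ::step]
    footprint, heights = ball_structure(radius, step=step)
    eroded = ndimage.grey_erosion(
        coarse, footprint=footprint, structure=heights, mode="nearest"
    )
    opened = ndimage.grey_dilation(
        eroded, footprint=footprint, structure=heights, mode="nearest"
    )
    zoom = (pixels.shape[0] / coarse.shape[0], pixels.shape[1] / coarse.shape[1])
    back = ndimage.zoom(opened, zoom, order=1, mode="nearest", grid_mode=True)
    return np.minimum(back, img)  # opening never exceeds the image


def rolling_ball_subtract(image: SectionImage, radius: int = 500) -> SectionImage:
    """Subtract the rolling-ball background estimate, flooring at zero."""
    if radius < 1:
        raise ValueError("radius must be >= 1")
    h, w = image.shape
    if radius > h and radius > w:
        raise ValueError(
            f"rolling-ball radius {radius} exceeds both image dimensions {h}x{w}"
        )
    if radius <= _EXACT_RADIUS_LIMIT:
        background = _opening_background(image.pixels, radius)
        method = "exact"
    else:
        background = _coarse_background(image.pixels, radius)
        method = "downsampled"
    out = np.clip(np.rint(image.pixels.astype(np.float64) - background), 0, MAX_GRAY)
    return image.with_pixels(
        out.astype(np.uint16), "rolling_ball_subtract", radius=radius, method=method
    )


def disk_footprint(radius: int) -> np.ndarray:
    """Boolean Euclidean disk: offsets with ``dy^2 + dx^2 <= r^2``."""
    coords = np.arange(-radius, radius + 1)
    dy, dx = np.meshgrid(coords, coords, indexing="ij")
    return (dy**2 + dx**2) <= radius**2


def median_denoise(image: SectionImage, radius: int = 5) -> SectionImage:
    """Disk median filter with edge replication at the borders.

    For neighborhoods with an even pixel count the upper of the two central
    order statistics is taken (rank ``n // 2``), matching
    :func:`scipy.ndimage.median_filter`.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    out = ndimage.median_filter(
        image.pixels, footprint=disk_footprint(radius), mode="nearest"
    )
    return image.with_pixels(out, "median_denoise", radius=radius)


def preprocess_chain(
    image: SectionImage,
    rolling_ball_radius: int = 500,
    median_radius: int = 5,
) -> SectionImage:
    """Rolling-ball subtraction followed by median denoising.

    Inversion to 16-bit gray (``to_inverted_gray``) is applied upstream when
    the input is a raw multichannel scan; simulated sections are already
    emitted in the inverted convention.
    """
    out = rolling_ball_subtract(image, rolling_ball_radius)
    return median_denoise(out, median_radius)
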