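"""Core image container for single-channel section images.

A :class:`SectionImage` wraps a 2-D integer pixel grid in the inverted
densitometric convention (stronger chromogen deposit -> larger value), a
physical pixel size, and an append-only provenance trail recording every
operation applied to it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["SectionImage", "MAX_GRAY"]

#: Maximum representable gray level (16-bit unsigned).
MAX_GRAY = 65535


@dataclass(frozen=True)
class SectionImage:
    """A single-channel 16-bit section image with physical calibration.

    Parameters
    ----------
    pixels : ndarray of shape (H, W)
        Non-negative integer gray values in ``[0, 65535]``.
    pixel_size_um : float
        Micrometers per pixel (isotropic), strictly positive.
    provenance : list of dict
        Ordered records of the operations applied so far.  Treated as
        append-only: derived images carry a copy extended by one entry.
    """

    pixels: np.ndarray
    pixel_size_um: float
    provenance: list[dict[str, Any]] = field(default_factory=list)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {px.shape}")
        if not np.issubdtype(px.dtype, np.integer):
            raise TypeError(f"pixels must be integer-valued, got dtype {px.dtype}")
        if px.size and (int(px.min()) < 0 or int(px.max()) > MAX_GRAY):
            raise ValueError("pixel values must lie in [0, 65535]")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def with_pixels(self, pixels: np.ndarray, op: str, **params: Any) -> "SectionImage":
        """Return a derived image with ``op`` appended to the provenance."""
        record = {"op": op, **params}
        return SectionImage(
            pixels=np.asarray(pixels),
            pixel_size_um=self.pixel_size_um,
            provenance=[*self.provenance, record],
        )

    def um_to_px(self, micrometers: float) -> float:
        return micrometers / self.pixel_size_um
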