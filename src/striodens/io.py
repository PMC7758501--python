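"""File I/O: 16-bit TIFF images, PNG masks, landmark JSON, cohort export."""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .geometry import LandmarkSet
from .image import SectionImage
from .segmentation import CompartmentResult

__all__ = [
    "read_section_tiff",
    "write_section_tiff",
    "write_mask_png",
    "read_mask_png",
    "write_compartment_png",
    "export_cohort",
    "mask_to_rle",
    "rle_to_mask",
]


def mask_to_rle(mask: np.ndarray) -> dict:
    """Run-length encode a boolean mask (row-major; runs start with False)."""
    flat = np.asarray(mask, dtype=bool).ravel()
    edges = np.flatnonzero(np.diff(flat))
    lengths = np.diff(np.concatenate([[0], edges + 1, [flat.size]]))
    runs = lengths.tolist()
    if flat.size and flat[0]:
        runs = [0] + runs
    return {"shape": list(mask.shape), "runs": runs}


def rle_to_mask(doc: dict) -> np.ndarray:
    shape = tuple(doc["shape"])
    flat = np.zeros(int(np.prod(shape)), dtype=bool)
    pos = 0
    value = False
    for run in doc["runs"]:
        if value:
            flat[pos : pos + run] = True
        pos += run
        value = not value
    return flat.reshape(shape)


def write_section_tiff(image: SectionImage, path: str | Path) -> None:
    tifffile.imwrite(
        str(path),
        image.pixels.astype(np.uint16),
        resolution=(1e4 / image.pixel_size_um, 1e4 / image.pixel_size_um),
        resolutionunit="CENTIMETER",
        metadata=None,
    )
    sidecar = Path(str(path) + ".json")
    sidecar.write_text(
        json.dumps(
            {"pixel_size_um": image.pixel_size_um, "provenance": image.provenance},
            indent=1,
        )
    )


def read_section_tiff(path: str | Path, pixel_size_um: float | None = None) -> SectionImage:
    """Read a single-channel or RGB TIFF; RGB is converted downstream."""
    pixels = tifffile.imread(str(path))
    provenance: list = []
    sidecar = Path(str(path) + ".json")
    if sidecar.exists():
        doc = json.loads(sidecar.read_text())
        pixel_size_um = pixel_size_um or doc.get("pixel_size_um")
        provenance = doc.get("provenance", [])
    if pixel_size_um is None:
        pixel_size_um = 1.0
    if pixels.ndim == 3:
        from .preprocess import to_inverted_gray

        return to_inverted_gray(pixels, pixel_size_um)
    return SectionImage(
        pixels=pixels.astype(np.uint16), pixel_size_um=pixel_size_um,
        provenance=provenance,
    )


def write_mask_png(mask: np.ndarray, path: str | Path) -> None:
    iio.imwrite(str(path), (np.asarray(mask, dtype=bool) * np.uint8(255)))


def read_mask_png(path: str | Path) -> np.ndarray:
    return np.asarray(iio.imread(str(path))) > 127


#: striosome red, matrix gray, excluded blue on black background.
_COMPARTMENT_COLORS = {
    "striosome": (220, 50, 50),
    "matrix": (160, 160, 160),
    "excluded": (60, 90, 220),
}


def write_compartment_png(result: CompartmentResult, path: str | Path) -> None:
    h, w = result.sector_mask.shape
    rgb = np.zeros((h, w, 3), dtype=np.uint8)
    for name, color in _COMPARTMENT_COLORS.items():
        mask = getattr(result, f"{name}_mask")
        rgb[mask] = color
    iio.imwrite(str(path), rgb)


def export_cohort(samples, metadata, out_dir: str | Path, write_masks: bool = True) -> Path:
    """Write a generated cohort: TIFFs, landmark JSONs, truth PNGs, CSV."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "landmarks").mkdir(exist_ok=True)
    if write_masks:
        (out / "truth").mkdir(exist_ok=True)
    for sample in samples:
        sid = sample.meta["section_id"]
        write_section_tiff(sample.image, out / "images" / f"{sid}.tif")
        sample.landmarks.save(out / "landmarks" / f"{sid}.json")
        if write_masks:
            write_mask_png(sample.truth.striosome_mask, out / "truth" / f"{sid}_striosome.png")
            write_mask_png(sample.truth.fiber_mask, out / "truth" / f"{sid}_fiber.png")
    metadata = metadata.copy()
    metadata["image"] = ["images/" + s + ".tif" for s in metadata["section_id"]]
    metadata["landmarks"] = ["landmarks/" + s + ".json" for s in metadata["section_id"]]
    metadata.to_csv(out / "metadata.csv", index=False)
    return out
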