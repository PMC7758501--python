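"""Per-region compartment metrics.

For every region (whole caudoputamen and, at rostral levels, the DM/DL/VM/VL
sectors) of every hemisphere the pipeline reports:

``percent_area``
    striosome pixels / (sector pixels - excluded pixels), as a fraction;
``strio_intensity`` / ``matrix_intensity``
    arithmetic mean processed gray value over the compartment mask;
``ismp``
    index of striosome-to-matrix predominance, the ratio
    striosome intensity / matrix intensity (predominance > 1);
``total_intensity``
    strio_intensity x percent_area, the whole striosomal signal of the
    region (integrated mean intensity per unit analyzable area).

Records with an empty compartment (no detectable striosomes, or everything
excluded) carry ``valid=False``; percent_area and total_intensity are still
reported as 0 when the striosome mask is empty but the denominator is not,
since "no striosomal signal" is a measurement, not a failure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .image import SectionImage
from .segmentation import CompartmentResult

__all__ = [
    "MetricsRecord",
    "percent_area",
    "mean_intensity",
    "ismp",
    "total_intensity",
    "measure_region",
    "metrics_table",
    "summarize_groups",
]


def percent_area(
    striosome_mask: np.ndarray, sector_mask: np.ndarray, excluded_mask: np.ndarray
) -> float:
    """Striosome area fraction of the analyzable (non-excluded) sector."""
    denom = int(np.count_nonzero(sector_mask)) - int(np.count_nonzero(excluded_mask))
    if denom <= 0:
        raise ValueError("sector empty after fiber exclusion")
    return int(np.count_nonzero(striosome_mask)) / denom


def mean_intensity(image: SectionImage | np.ndarray, mask: np.ndarray) -> float:
    pixels = image.pixels if isinstance(image, SectionImage) else np.asarray(image)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask has no mean intensity")
    return float(pixels[mask].mean())


def ismp(strio_intensity: float, matrix_intensity: float) -> float:
    """Striosome-to-matrix predominance ratio (striosome in the numerator)."""
    if not matrix_intensity > 0:
        raise ValueError("matrix intensity must be positive for ISMP")
    return strio_intensity / matrix_intensity


def total_intensity(strio_intensity: float, percent_area_fraction: float) -> float:
    return strio_intensity * percent_area_fraction


@dataclass
class MetricsRecord:
    """One region of one caudoputamen sample, joined to cohort metadata."""

    section_id: str
    animal_id: str
    genotype: str
    age: float
    level: str
    hemisphere: str
    sector: str
    percent_area: float = math.nan
    strio_intensity: float = math.nan
    matrix_intensity: float = math.nan
    ismp: float = math.nan
    total_intensity: float = math.nan
    integrated_strio_density: float = math.nan  # sum of striosome gray values
    li_threshold: float = math.nan
    fiber_threshold: float = math.nan
    n_pixels: int = 0
    n_excluded: int = 0
    valid: bool = True
    note: str = ""

    meta: dict = field(default_factory=dict, repr=False)


def measure_region(
    image: SectionImage,
    result: CompartmentResult,
    *,
    section_id: str = "",
    animal_id: str = "",
    genotype: str = "",
    age: float = math.nan,
    level: str = "",
    hemisphere: str = "",
    sector: str = "",
) -> MetricsRecord:
    """Compute all metrics of one segmented region.

    An empty striosome mask (region with no detectable striosomes) yields
    percent_area = 0 and total_intensity = 0 with ``valid=False`` and NaN
    intensities/ISMP; an empty matrix mask likewise invalidates the record.
    """
    rec = MetricsRecord(
        section_id=section_id,
        animal_id=animal_id,
        genotype=genotype,
        age=age,
        level=level,
        hemisphere=hemisphere,
        sector=sector,
        li_threshold=math.nan if result.li_threshold is None else result.li_threshold,
        fiber_threshold=(
            math.nan if result.fiber_threshold is None else result.fiber_threshold
        ),
        n_pixels=int(np.count_nonzero(result.sector_mask)),
        n_excluded=int(np.count_nonzero(result.excluded_mask)),
        note=result.note,
    )
    denom = rec.n_pixels - rec.n_excluded
    if denom <= 0:
        rec.valid = False
        rec.note = (rec.note + "; " if rec.note else "") + "all pixels excluded"
        return rec

    has_strio = result.striosome_mask.any()
    has_matrix = result.matrix_mask.any()
    rec.percent_area = percent_area(
        result.striosome_mask, result.sector_mask, result.excluded_mask
    )
    if has_strio:
        rec.strio_intensity = mean_intensity(image, result.striosome_mask)
        rec.integrated_strio_density = float(
            image.pixels[result.striosome_mask].astype(np.float64).sum()
        )
        rec.total_intensity = total_intensity(rec.strio_intensity, rec.percent_area)
    else:
        rec.total_intensity = 0.0
        rec.integrated_strio_density = 0.0
    if has_matrix:
        rec.matrix_intensity = mean_intensity(image, result.matrix_mask)
    if has_strio and has_matrix and rec.matrix_intensity > 0:
        rec.ismp = ismp(rec.strio_intensity, rec.matrix_intensity)
    rec.valid = bool(has_strio and has_matrix)
    return rec


_COLUMNS = [
    "section_id",
    "animal_id",
    "genotype",
    "age",
    "level",
    "hemisphere",
    "sector",
    "percent_area",
    "strio_intensity",
    "matrix_intensity",
    "ismp",
    "total_intensity",
    "integrated_strio_density",
    "li_threshold",
    "fiber_threshold",
    "n_pixels",
    "n_excluded",
    "valid",
    "note",
]


def metrics_table(records: list[MetricsRecord]) -> pd.DataFrame:
    """Long-format table: one row per section x hemisphere x region."""
    rows = [{c: getattr(r, c) for c in _COLUMNS} for r in records]
    return pd.DataFrame(rows, columns=_COLUMNS)


def average_hemispheres(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse the two hemispheres of each animal x level x sector to their
    mean — the sensitivity variant where animals, not caudoputamina, are the
    analysis units."""
    value_cols = [
        c
        for c in (
            "percent_area",
            "strio_intensity",
            "matrix_intensity",
            "ismp",
            "total_intensity",
            "integrated_strio_density",
        )
        if c in table
    ]
    keys = [
        c
        for c in ("animal_id", "genotype", "age", "level", "sector")
        if c in table
    ]
    return table.groupby(keys, dropna=False, as_index=False)[value_cols].mean()


def summarize_groups(
    table: pd.DataFrame,
    value_cols: tuple[str, ...] = (
        "percent_area",
        "strio_intensity",
        "matrix_intensity",
        "ismp",
        "total_intensity",
    ),
    by: tuple[str, ...] = ("level", "age", "sector", "genotype"),
) -> pd.DataFrame:
    """Group means +/- SEM in the reporting convention of the field."""
    grouped = table.groupby(list(by), dropna=False)
    out = []
    for keys, sub in grouped:
        row = dict(zip(by, keys if isinstance(keys, tuple) else (keys,)))
        for col in value_cols:
            vals = sub[col].dropna()
            row[f"{col}_mean"] = vals.mean() if len(vals) else math.nan
            row[f"{col}_sem"] = (
                vals.std(ddof=1) / math.sqrt(len(vals)) if len(vals) > 1 else math.nan
            )
            row[f"{col}_n"] = len(vals)
        out.append(row)
    return pd.DataFrame(out)
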