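"""Striosome/matrix segmentation by minimum cross-entropy thresholding and
fiber-bundle exclusion.

Each caudoputamen region is thresholded independently with the Li method:
the gray level minimizing the Li & Tam cross-entropy between the image and
its two-class approximation.  In the inverted convention the supra-threshold
class is the striosome compartment (stronger mu-opioid-receptor staining)
and the infra-threshold class is the matrix; ties at the threshold go to
matrix so results are bit-reproducible.

Non-neuronal fiber is excluded with the control-square rule: the mean gray
value of small squares placed on the corpus callosum and anterior
commissure is averaged across squares and truncated to an integer; every
pixel at or below that value is moved to the excluded class.  Exclusion is
applied after compartment segmentation (applying it before would change the
Li thresholds); the ordering is recorded in provenance by the pipeline.

A region whose Li split separates the class means by no more than
``min_separation_sds`` pooled within-class standard deviations is reported
as having no detectable striosomes (empty striosome mask): a unimodal noise
histogram always splits somewhere, and the relative guard — which is
invariant under global intensity rescaling — distinguishes that case from a
genuinely bimodal compartment structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import ControlSquare, GeometryError
from .image import SectionImage

__all__ = [
    "CompartmentResult",
    "DegenerateSectorError",
    "li_threshold",
    "li_threshold_image",
    "segment_sector",
    "fiber_threshold",
    "apply_fiber_exclusion",
]


class DegenerateSectorError(ValueError):
    """Histogram carries no threshold information (fewer than 2 levels)."""


@dataclass
class CompartmentResult:
    """Compartment masks and thresholds for one region of one section."""

    region_id: str
    li_threshold: int | None
    striosome_mask: np.ndarray
    matrix_mask: np.ndarray
    excluded_mask: np.ndarray
    sector_mask: np.ndarray
    fiber_threshold: int | None = None
    detectable: bool = True
    note: str = ""
    provenance: list = field(default_factory=list)


def _class_score(counts: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Li cross-entropy merit of every split point (larger is better).

    For the split after index ``k`` (lower class ``values <= values[k]``)
    the criterion to minimize is ``-(A0*log(mu0) + A1*log(mu1))`` with
    ``A`` the class mass ``sum(count*value)`` and ``mu`` the class mean;
    the additive ``sum(count*value*log(value))`` term is split-independent.
    ``0 * log(0)`` is taken as 0.
    """
    counts = counts.astype(np.float64)
    values = values.astype(np.float64)
    w = np.cumsum(counts)
    a = np.cumsum(counts * values)
    w_tot, a_tot = w[-1], a[-1]
    w0, a0 = w[:-1], a[:-1]
    w1, a1 = w_tot - w0, a_tot - a0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = np.where(w0 > 0, a0 / w0, 0.0)
        mu1 = np.where(w1 > 0, a1 / w1, 0.0)
        t0 = np.where(a0 > 0, a0 * np.log(np.where(mu0 > 0, mu0, 1.0)), 0.0)
        t1 = np.where(a1 > 0, a1 * np.log(np.where(mu1 > 0, mu1, 1.0)), 0.0)
    score = t0 + t1
    score[(w0 == 0) | (w1 == 0)] = -np.inf  # both classes must be nonempty
    return score


def _li_fixed_point(counts: np.ndarray, values: np.ndarray) -> float:
    """Li & Tam mean-ratio iteration; converges when |dt| < 0.5 gray level."""
    counts = counts.astype(np.float64)
    values = values.astype(np.float64)
    eps = 1e-12
    t = float(np.average(values, weights=counts))
    for _ in range(200):
        lower = values <= t
        w0 = counts[lower].sum()
        w1 = counts[~lower].sum()
        if w0 == 0 or w1 == 0:
            break
        mu0 = max(float(np.average(values[lower], weights=counts[lower])), eps)
        mu1 = max(float(np.average(values[~lower], weights=counts[~lower])), eps)
        if mu0 == mu1:
            break
        t_new = (mu0 - mu1) / (np.log(mu0) - np.log(mu1))
        if abs(t_new - t) < 0.5:
            t = t_new
            break
        t = t_new
    return t


def li_threshold(counts: np.ndarray, values: np.ndarray) -> int:
    """Minimum cross-entropy threshold of a gray-level histogram.

    Runs the Li & Tam fixed-point iteration and guarantees that the returned
    threshold achieves the global minimum of the cross-entropy criterion by
    checking it against an exhaustive scan of all split points (the iterate
    is kept whenever its split is globally optimal; on plateaus — e.g. a
    two-level histogram — any threshold between the classes is optimal and
    the fixed point picks the canonical one).

    Parameters
    ----------
    counts, values : 1-D arrays
        Histogram counts and the gray value of each bin.  Values need not be
        sorted; empty bins are ignored.

    Returns
    -------
    int
        Threshold ``t``; the lower class is ``value <= t``.
    """
    counts = np.asarray(counts, dtype=np.float64)
    values = np.asarray(values, dtype=np.float64)
    keep = counts > 0
    counts, values = counts[keep], values[keep]
    order = np.argsort(values)
    counts, values = counts[order], values[order]
    if values.size < 2:
        raise DegenerateSectorError("histogram has fewer than 2 distinct gray levels")

    score = _class_score(counts, values)
    best = score.max()
    t_iter = _li_fixed_point(counts, values)
    k_iter = int(np.searchsorted(values, t_iter, side="right")) - 1
    if 0 <= k_iter < score.size and score[k_iter] >= best - 1e-9 * abs(best):
        t = t_iter
        k = k_iter
    else:
        k = int(np.argmax(score))
        t = 0.5 * (values[k] + values[k + 1])
    # Integer threshold preserving the chosen split: any integer in
    # [values[k], values[k+1]) yields the same two classes.
    t_int = int(np.floor(t))
    lo = int(np.ceil(values[k]))
    hi = int(np.ceil(values[k + 1])) - 1
    return int(np.clip(t_int, lo, max(lo, hi)))


def li_threshold_image(pixels: np.ndarray, nbins: int = 256) -> int:
    """Li threshold of an image/region, binned to ``nbins`` levels.

    16-bit data are binned to ``nbins`` equal-width bins spanning the
    observed range for the threshold computation and the result is mapped
    back to the original gray scale; when the region has no more distinct
    values than bins the exact value histogram is used.
    """
    vals = np.asarray(pixels).ravel()
    if vals.size == 0:
        raise DegenerateSectorError("empty region")
    uniq, counts = np.unique(vals, return_counts=True)
    if uniq.size <= nbins:
        return li_threshold(counts, uniq.astype(np.float64))
    counts, edges = np.histogram(vals, bins=nbins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return li_threshold(counts, centers)


def segment_sector(
    image: SectionImage,
    sector_mask: np.ndarray,
    region_id: str = "",
    nbins: int = 256,
    min_separation_sds: float = 6.0,
    max_striosome_fraction: float = 0.6,
    exclude_below: int | None = None,
) -> CompartmentResult:
    """Split one sector into striosome (``> t``) and matrix (``<= t``).

    The threshold is computed from this sector's own histogram; whole-region
    and sector thresholds are never shared.  When ``exclude_below`` is given
    (normally the control-square fiber threshold) pixels at or below it are
    left out of the histogram, so dim fiber bundles cannot drag the Li
    threshold into the fiber/tissue gap in sectors where striosomes are
    sparse; the mask-level exclusion itself is a separate step
    (:func:`apply_fiber_exclusion`).  Constant sectors and sectors failing
    the class-separation guard are returned with an empty striosome mask
    and ``detectable=False``.
    """
    sector_mask = np.asarray(sector_mask, dtype=bool)
    if not sector_mask.any():
        raise ValueError(f"empty sector mask: {region_id!r}")
    vals = image.pixels[sector_mask]
    if exclude_below is not None:
        kept = vals[vals > exclude_below]
        vals = kept if kept.size else vals
    empty = np.zeros_like(sector_mask)

    def undetectable(note: str, thr: int | None) -> CompartmentResult:
        return CompartmentResult(
            region_id=region_id,
            li_threshold=thr,
            striosome_mask=empty.copy(),
            matrix_mask=sector_mask.copy(),
            excluded_mask=empty.copy(),
            sector_mask=sector_mask,
            detectable=False,
            note=note,
        )

    try:
        thr = li_threshold_image(vals, nbins=nbins)
    except DegenerateSectorError:
        return undetectable("constant gray level; sector unsegmentable", None)

    strio = sector_mask & (image.pixels > thr)
    matrix = sector_mask & (image.pixels <= thr)
    if not strio.any():
        return undetectable("no supra-threshold pixels", thr)
    strio_fraction = strio.sum() / sector_mask.sum()
    if strio_fraction > max_striosome_fraction:
        # Striosomes are the minority compartment; a majority supra-threshold
        # class means the split is not compartmental (e.g. a dim partial-
        # volume rim at the outline border became the lower class).
        return undetectable(
            f"supra-threshold fraction {strio_fraction:.2f} > "
            f"{max_striosome_fraction:g}; split is not compartmental",
            thr,
        )

    sv = image.pixels[strio].astype(np.float64)
    mv = image.pixels[matrix].astype(np.float64)
    separation = sv.mean() - mv.mean()
    pooled_var = (sv.size * sv.var() + mv.size * mv.var()) / (sv.size + mv.size)
    pooled_sd = float(np.sqrt(pooled_var))
    if separation <= min_separation_sds * pooled_sd:
        return undetectable(
            f"class separation {separation:.2f} <= "
            f"{min_separation_sds:g} x pooled SD {pooled_sd:.2f}",
            thr,
        )

    return CompartmentResult(
        region_id=region_id,
        li_threshold=thr,
        striosome_mask=strio,
        matrix_mask=matrix,
        excluded_mask=empty.copy(),
        sector_mask=sector_mask,
    )


def fiber_threshold(
    image: SectionImage, control_squares: list[ControlSquare]
) -> int:
    """Integer fiber-exclusion threshold from the control squares.

    The mean gray value of each square (50 um side by default, converted to
    pixels) is computed, the square means are averaged, and the result is
    truncated after the decimal point.
    """
    if not control_squares:
        raise GeometryError("at least one control square required")
    h, w = image.shape
    means = []
    for i, square in enumerate(control_squares):
        ys, xs = square.slices(image.pixel_size_um)
        if ys.start < 0 or xs.start < 0 or ys.stop > h or xs.stop > w:
            raise GeometryError(
                f"control square {i} ({square.label or 'unlabeled'}) "
                "extends outside the image"
            )
        means.append(float(image.pixels[ys, xs].mean()))
    return int(np.floor(np.mean(means)))


def apply_fiber_exclusion(
    result: CompartmentResult, image: SectionImage, threshold: int
) -> CompartmentResult:
    """Move pixels at or below ``threshold`` into the excluded class.

    Preserves the partition ``striosome | matrix | excluded == sector`` and
    is monotone: a larger threshold never shrinks the excluded mask.
    """
    if threshold < 0:
        raise ValueError("fiber threshold must be >= 0")
    dim = result.sector_mask & (image.pixels <= threshold)
    return replace(
        result,
        striosome_mask=result.striosome_mask & ~dim,
        matrix_mask=result.matrix_mask & ~dim,
        excluded_mask=result.excluded_mask | dim,
        fiber_threshold=int(threshold),
    )
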