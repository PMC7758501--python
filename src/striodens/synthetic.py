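"""Synthetic striatal-section generator with ground truth.

Emulates the features of MOR1-immunostained coronal sections that the
densitometry pipeline assumes, so every downstream stage can be validated
against known truth:

* two caudoputamen outlines (jittered ellipses) with the anatomical
  landmarks the sector construction needs (anterior-commissure lateral
  tips, accumbens-shell upper tips);
* labyrinthine striosome patches from thresholded Gaussian-smoothed noise,
  with placement probability increasing toward the dorsal rim;
* fiber structures: corpus callosum band over the dorsal rim, anterior
  commissure blobs near the midline (carrying the control squares), and
  small pencil-fiber bundles inside the caudoputamen;
* a genotype x age x level x sector effect model in which striosome
  intensity rises before matrix intensity with age in the mutant, and
  wildtype caudal sections have essentially no striosomal signal
  (``caudal_wt_striosome_gain ~ 0``);
* per-animal random intercepts (one integer offset per compartment),
  multiplicative low-frequency shading and additive Gaussian noise.

All intensities are integers and the noise-free expected image is integer
valued, so stored ground-truth metrics are reproduced *exactly* by the
measurement code on noise-free renders.  Everything is a pure function of
(design, effects, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping

import numpy as np
import pandas as pd
from scipy import ndimage

from .geometry import (
    ControlSquare,
    GeometryError,
    LandmarkSet,
    SECTORS,
    construct_sectors,
    rasterize_polygon,
)
from .image import MAX_GRAY, SectionImage

__all__ = [
    "CohortDesign",
    "EffectModel",
    "GroundTruth",
    "SectionSample",
    "default_effect_model",
    "null_effect_model",
    "scale_effects",
    "generate_striosome_pattern",
    "generate_section",
    "render_section",
    "generate_cohort",
]

DEFAULT_SHAPE = (160, 224)  # rows (y), cols (x); ~3.2 x 4.5 mm at 20 um/px
DEFAULT_PIXEL_SIZE_UM = 20.0


class DesignError(ValueError):
    """Invalid cohort design."""


@dataclass(frozen=True)
class CohortDesign:
    """Cohort layout: genotype x age cells, two levels per animal."""

    genotypes: tuple[str, ...] = ("WT", "MUT")
    ages: tuple[int, ...] = (3, 6, 12, 19)
    levels: tuple[str, ...] = ("rostral", "caudal")
    n_per_cell: int = 8  # animals per genotype x age cell
    hemispheres_per_animal: int = 2
    seed: int = 0
    image_shape: tuple[int, int] = DEFAULT_SHAPE
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        if self.n_per_cell < 1:
            raise DesignError("n_per_cell must be >= 1")
        if not self.ages:
            raise DesignError("ages must be nonempty")


@dataclass(frozen=True)
class EffectModel:
    """Expected compartment intensities and noise structure.

    ``strio_shifts`` / ``matrix_shifts`` map ``(genotype, level, age,
    sector)`` to an additive intensity shift on the corresponding base
    value; caudal sections use sector key ``"whole"``.  For wildtype caudal
    sections the striosome mean is pulled toward the matrix mean by
    ``caudal_wt_striosome_gain`` (0 = striosomes invisible).
    """

    matrix_intensity: int = 120
    striosome_intensity: int = 180
    strio_shifts: Mapping[tuple[str, str, int, str], int] = field(default_factory=dict)
    matrix_shifts: Mapping[tuple[str, str, int, str], int] = field(default_factory=dict)
    caudal_wt_striosome_gain: float = 0.0
    noise_sd: float = 5.0
    shading_amplitude: float = 0.03
    fiber_intensity: int = 60
    background_intensity: int = 10
    animal_sd: float = 3.0
    striosome_density: Mapping[str, float] = field(
        default_factory=lambda: {"rostral": 0.15, "caudal": 0.12}
    )
    dorsal_gradient: float = 0.8
    blob_sigma: float = 2.5
    n_internal_bundles: int = 2

    def matrix_mean(self, genotype: str, age: int, level: str, sector: str) -> float:
        return self.matrix_intensity + self.matrix_shifts.get(
            (genotype, level, age, sector), 0
        )

    def strio_mean(self, genotype: str, age: int, level: str, sector: str) -> float:
        value = self.striosome_intensity + self.strio_shifts.get(
            (genotype, level, age, sector), 0
        )
        if level == "caudal" and genotype == "WT":
            mat = self.matrix_mean(genotype, age, level, sector)
            value = mat + self.caudal_wt_striosome_gain * (value - mat)
        return value


def default_effect_model(**overrides) -> EffectModel:
    """Study conditions: striosome effect precedes matrix effect with age.

    Mutant rostral striosome intensity is elevated in the dorsolateral
    sector from the earliest age, spreads to most sectors by 12 months, and
    to all sectors at 19 months; mutant matrix intensity rises only at the
    later ages.  Caudal wildtype striosomes are invisible (gain 0) while
    caudal mutant striosomes are strong at every age.
    """
    strio: dict[tuple[str, str, int, str], int] = {}
    matrix: dict[tuple[str, str, int, str], int] = {}
    for sector in ("DL",):
        strio[("MUT", "rostral", 3, sector)] = 30
        strio[("MUT", "rostral", 6, sector)] = 30
    for sector in ("DM", "DL", "VL"):
        strio[("MUT", "rostral", 12, sector)] = 30
    for sector in SECTORS:
        strio[("MUT", "rostral", 19, sector)] = 40
        matrix[("MUT", "rostral", 19, sector)] = 30
    for sector in ("DL", "VL"):
        matrix[("MUT", "rostral", 12, sector)] = 15
    strio[("MUT", "caudal", 12, "whole")] = 20
    strio[("MUT", "caudal", 19, "whole")] = 30
    params = dict(strio_shifts=strio, matrix_shifts=matrix)
    params.update(overrides)
    return EffectModel(**params)


def null_effect_model(**overrides) -> EffectModel:
    """No genotype effects anywhere; striosomes visible at both levels."""
    params = dict(
        strio_shifts={}, matrix_shifts={}, caudal_wt_striosome_gain=1.0
    )
    params.update(overrides)
    return EffectModel(**params)


def scale_effects(model: EffectModel, factor: float) -> EffectModel:
    """Multiply every genotype shift by ``factor`` (rounded to integers)."""
    return replace(
        model,
        strio_shifts={k: int(round(v * factor)) for k, v in model.strio_shifts.items()},
        matrix_shifts={
            k: int(round(v * factor)) for k, v in model.matrix_shifts.items()
        },
    )


@dataclass
class GroundTruth:
    """Noise-free truth for one rendered section."""

    striosome_mask: np.ndarray
    fiber_mask: np.ndarray
    sector_masks: dict[str, dict[str, np.ndarray]]  # hemi -> region -> mask
    expected_image: np.ndarray  # integer-valued noise-free pixel expectations
    true_metrics: dict[tuple[str, str], dict[str, float]]
    genotype: str = "WT"
    age: int = 3
    level: str = "rostral"
    strio_offset: int = 0
    matrix_offset: int = 0


@dataclass
class SectionSample:
    image: SectionImage
    landmarks: LandmarkSet
    truth: GroundTruth
    meta: dict


# ---------------------------------------------------------------------------
# striosome pattern


def generate_striosome_pattern(
    outline: np.ndarray,
    image_shape: tuple[int, int],
    level: str = "rostral",
    density: float = 0.15,
    seed: int | np.random.Generator = 0,
    dorsal_gradient: float = 0.8,
    sigma: float = 2.5,
) -> np.ndarray:
    """Labyrinthine striosome mask inside an outline at a target density.

    A Gaussian-smoothed white-noise field (correlation length ``sigma``) is
    biased by a linear dorsoventral gradient — ``dorsal_gradient`` raises
    the field near the dorsal (small-y) rim — and thresholded at the
    ``1 - density`` quantile of its in-outline values, so the realized area
    fraction matches ``density`` up to pixel discreteness.
    """
    if not 0 <= density <= 0.4:
        raise ValueError("density must lie in [0, 0.4]")
    inside = rasterize_polygon(outline, image_shape)
    n_in = int(inside.sum())
    if n_in == 0:
        raise GeometryError("degenerate outline: encloses no pixels")
    if density == 0:
        return np.zeros(image_shape, dtype=bool)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    noise = rng.standard_normal(image_shape)
    fld = ndimage.gaussian_filter(noise, sigma)
    fld /= max(fld.std(), 1e-12)
    ys = np.nonzero(inside)[0]
    y0, y1 = ys.min(), ys.max()
    depth = (np.arange(image_shape[0]) - y0) / max(y1 - y0, 1)
    fld = fld + dorsal_gradient * (1.0 - np.clip(depth, 0, 1))[:, None]
    thr = np.quantile(fld[inside], 1.0 - density)
    return inside & (fld > thr)


# ---------------------------------------------------------------------------
# section anatomy


def _ellipse_outline(
    center: tuple[float, float],
    semi: tuple[float, float],
    rng: np.random.Generator,
    n_vertices: int = 48,
    irregularity: float = 0.02,
) -> np.ndarray:
    theta = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    radial = np.ones_like(theta)
    for k in (2, 3, 4):
        radial += (
            rng.normal(0, irregularity) * np.cos(k * theta)
            + rng.normal(0, irregularity) * np.sin(k * theta)
        )
    x = center[0] + semi[0] * radial * np.cos(theta)
    y = center[1] + semi[1] * radial * np.sin(theta)
    return np.column_stack([x, y])


def _ellipse_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    semi: tuple[float, float],
    angle: float = 0.0,
) -> np.ndarray:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    dx = xx - center[0]
    dy = yy - center[1]
    c, s = np.cos(angle), np.sin(angle)
    u = (c * dx + s * dy) / semi[0]
    v = (-s * dx + c * dy) / semi[1]
    return u**2 + v**2 <= 1.0


def _place_control_square(
    center: tuple[float, float],
    fiber_mask: np.ndarray,
    pixel_size_um: float,
    rng: np.random.Generator,
    label: str,
    max_tries: int = 20,
) -> ControlSquare:
    """Control square fully inside the fiber mask, jittered if necessary."""
    h, w = fiber_mask.shape
    cand = np.asarray(center, dtype=float)
    for _ in range(max_tries):
        sq = ControlSquare(center=(float(cand[0]), float(cand[1])), label=label)
        ys, xs = sq.slices(pixel_size_um)
        if (
            0 <= ys.start
            and 0 <= xs.start
            and ys.stop <= h
            and xs.stop <= w
            and fiber_mask[ys, xs].all()
        ):
            return sq
        cand = np.asarray(center) + rng.uniform(-3, 3, size=2)
    raise GeometryError(f"could not place control square on {label}")


def generate_section(
    level: str,
    effects: EffectModel,
    rng: np.random.Generator,
    image_shape: tuple[int, int] = DEFAULT_SHAPE,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    genotype: str = "WT",
    age: int = 3,
    strio_offset: int = 0,
    matrix_offset: int = 0,
    max_attempts: int = 10,
) -> tuple[LandmarkSet, GroundTruth]:
    """Build one section's anatomy, landmarks and ground truth (no noise).

    Outline jitter can occasionally tilt the inter-hemispheric tangent far
    enough that the sector construction becomes degenerate; such anatomies
    are re-drawn (bounded retries), as a human annotator would never emit
    geometrically inconsistent landmarks.
    """
    last_error: GeometryError | None = None
    for _ in range(max_attempts):
        try:
            return _generate_section_once(
                level,
                effects,
                rng,
                image_shape,
                pixel_size_um,
                genotype,
                age,
                strio_offset,
                matrix_offset,
            )
        except GeometryError as exc:
            last_error = exc
    raise GeometryError(f"section anatomy failed after {max_attempts} attempts: {last_error}")


def _generate_section_once(
    level: str,
    effects: EffectModel,
    rng: np.random.Generator,
    image_shape: tuple[int, int],
    pixel_size_um: float,
    genotype: str,
    age: int,
    strio_offset: int,
    matrix_offset: int,
) -> tuple[LandmarkSet, GroundTruth]:
    h, w = image_shape
    mid_x = w / 2.0
    cy = h * 0.49
    a, b = w * 0.17, h * 0.19  # caudoputamen semi-axes
    offset_x = w * 0.232

    outlines: dict[str, np.ndarray] = {}
    cp_masks: dict[str, np.ndarray] = {}
    ac_tips: dict[str, tuple[float, float]] = {}
    nacc_tips: dict[str, tuple[float, float]] = {}
    fiber = np.zeros(image_shape, dtype=bool)
    for hemi, sign in (("left", -1.0), ("right", 1.0)):
        center = (mid_x + sign * offset_x, cy)
        outline = _ellipse_outline(center, (a, b), rng)
        outlines[hemi] = outline
        cp_masks[hemi] = rasterize_polygon(outline, image_shape)

        # corpus callosum: band hugging the dorsal rim of the outline
        yy, xx = np.mgrid[0:h, 0:w]
        norm = np.sqrt(((xx - center[0]) / a) ** 2 + ((yy - center[1]) / b) ** 2)
        cc = (norm >= 1.02) & (norm <= 1.28) & (yy < cy - 0.15 * b)
        fiber |= cc & ~cp_masks[hemi]

        # anterior commissure blob near the midline, ventral
        ac_y = cy + 0.6 * b
        ac_center = (mid_x + sign * w * 0.031, ac_y)
        ac_blob = _ellipse_mask(image_shape, ac_center, (w * 0.036, b * 0.14))
        fiber |= ac_blob & ~cp_masks[hemi]
        ac_tips[hemi] = (mid_x + sign * w * 0.067, ac_y)

        # accumbens-shell upper tip: outline vertex nearest the
        # medio-ventral direction
        direction = np.array([-sign * 0.6 * a, 0.8 * b])
        target = np.asarray(center) + direction
        idx = int(np.argmin(np.sum((outline - target) ** 2, axis=1)))
        nacc_tips[hemi] = (float(outline[idx, 0]), float(outline[idx, 1]))

        # small pencil-fiber bundles inside the caudoputamen
        for _ in range(effects.n_internal_bundles):
            for _try in range(10):
                u = rng.uniform(-0.7, 0.7, size=2)
                if u[0] ** 2 + u[1] ** 2 <= 0.55:
                    break
            bc = (center[0] + u[0] * a, center[1] + u[1] * b)
            bundle = _ellipse_mask(
                image_shape, bc, (2.5, 1.5), angle=rng.uniform(0, np.pi)
            )
            fiber |= bundle & cp_masks[hemi]

    squares = [
        _place_control_square(
            (mid_x + offset_x, cy - 1.15 * b), fiber, pixel_size_um, rng,
            "corpus_callosum",
        ),
        _place_control_square(
            (mid_x + w * 0.031, cy + 0.6 * b), fiber, pixel_size_um, rng,
            "anterior_commissure",
        ),
    ]

    landmarks = LandmarkSet(
        cp_outline_left=outlines["left"],
        cp_outline_right=outlines["right"],
        ac_lateral_tip_left=ac_tips["left"],
        ac_lateral_tip_right=ac_tips["right"],
        nacc_shell_upper_tip_left=nacc_tips["left"],
        nacc_shell_upper_tip_right=nacc_tips["right"],
        fiber_control_squares=squares,
        pixel_size_um=pixel_size_um,
        image_shape=image_shape,
    )

    regions = construct_sectors(landmarks, image_shape)

    density = effects.striosome_density.get(level, 0.15)
    strio = np.zeros(image_shape, dtype=bool)
    for hemi in ("left", "right"):
        strio |= generate_striosome_pattern(
            outlines[hemi],
            image_shape,
            level=level,
            density=density,
            seed=rng,
            dorsal_gradient=effects.dorsal_gradient,
            sigma=effects.blob_sigma,
        )
    strio &= ~fiber  # striosome and fiber classes are disjoint

    expected = np.full(image_shape, effects.background_intensity, dtype=np.int64)
    sector_names = SECTORS if level == "rostral" else ("whole",)
    for hemi in ("left", "right"):
        for sector in sector_names:
            lookup = sector if level == "rostral" else "whole"
            smask = regions.mask(hemi, sector)
            mat = int(round(effects.matrix_mean(genotype, age, level, lookup))) + matrix_offset
            stv = int(round(effects.strio_mean(genotype, age, level, lookup))) + strio_offset
            expected[smask] = mat
            expected[smask & strio] = stv
    expected[fiber] = effects.fiber_intensity
    expected = np.clip(expected, 0, MAX_GRAY)

    truth = GroundTruth(
        striosome_mask=strio,
        fiber_mask=fiber,
        sector_masks=regions.masks,
        expected_image=expected,
        true_metrics={},
        genotype=genotype,
        age=age,
        level=level,
        strio_offset=strio_offset,
        matrix_offset=matrix_offset,
    )
    truth.true_metrics = _true_metrics(truth, level)
    return landmarks, truth


def _true_metrics(
    truth: GroundTruth, level: str
) -> dict[tuple[str, str], dict[str, float]]:
    """Noise-free metrics from integer pixel sums over the truth masks."""
    out: dict[tuple[str, str], dict[str, float]] = {}
    exp = truth.expected_image.astype(np.int64)
    regions = ("whole",) + (SECTORS if level == "rostral" else ())
    for hemi in ("left", "right"):
        for region in regions:
            mask = truth.sector_masks[hemi][region]
            fib = mask & truth.fiber_mask
            strio = mask & truth.striosome_mask
            matrix = mask & ~truth.striosome_mask & ~fib
            denom = int(mask.sum()) - int(fib.sum())
            if denom <= 0:
                continue
            n_s = int(strio.sum())
            pct = n_s / denom
            strio_sum = int(exp[strio].sum())
            mat_sum = int(exp[matrix].sum())
            s_int = strio_sum / n_s if n_s else float("nan")
            m_int = mat_sum / int(matrix.sum()) if matrix.any() else float("nan")
            out[(hemi, region)] = {
                "percent_area": pct,
                "strio_intensity": s_int,
                "matrix_intensity": m_int,
                "ismp": s_int / m_int if n_s and m_int else float("nan"),
                "total_intensity": (s_int * pct) if n_s else 0.0,
            }
    return out


def render_section(
    truth: GroundTruth,
    effects: EffectModel,
    seed: int | np.random.Generator,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
) -> SectionImage:
    """Noisy render: expected image x shading field + Gaussian noise."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    exp = truth.expected_image.astype(np.float64)
    if effects.shading_amplitude > 0:
        raw = rng.standard_normal(exp.shape)
        smooth = ndimage.gaussian_filter(raw, sigma=min(exp.shape) / 4.0)
        peak = max(float(np.abs(smooth).max()), 1e-12)
        exp = exp * (1.0 + effects.shading_amplitude * smooth / peak)
    if effects.noise_sd > 0:
        exp = exp + rng.normal(0.0, effects.noise_sd, size=exp.shape)
    pixels = np.clip(np.rint(exp), 0, MAX_GRAY).astype(np.uint16)
    return SectionImage(
        pixels=pixels,
        pixel_size_um=pixel_size_um,
        provenance=[
            {
                "op": "synthetic_render",
                "level": truth.level,
                "noise_sd": effects.noise_sd,
                "shading_amplitude": effects.shading_amplitude,
            }
        ],
    )


# ---------------------------------------------------------------------------
# cohort


def _iter_animals(design: CohortDesign) -> Iterator[tuple[str, str, int]]:
    for genotype in design.genotypes:
        for age in design.ages:
            for i in range(design.n_per_cell):
                yield f"{genotype}-{age}m-{i:02d}", genotype, age


def generate_cohort(
    design: CohortDesign, effects: EffectModel | None = None
) -> tuple[list[SectionSample], pd.DataFrame]:
    """Full cohort: one section per animal x level, reproducible from seed.

    Per-animal compartment intercepts (one integer offset per compartment)
    are drawn once per animal and shared by that animal's sections.
    """
    effects = effects if effects is not None else default_effect_model()
    ss = np.random.SeedSequence(design.seed)
    animals = list(_iter_animals(design))
    children = ss.spawn(len(animals))
    samples: list[SectionSample] = []
    rows = []
    for (animal_id, genotype, age), child in zip(animals, children):
        rng = np.random.default_rng(child)
        strio_off = int(round(rng.normal(0, effects.animal_sd)))
        matrix_off = int(round(rng.normal(0, effects.animal_sd)))
        for level in design.levels:
            landmarks, truth = generate_section(
                level,
                effects,
                rng,
                image_shape=design.image_shape,
                pixel_size_um=design.pixel_size_um,
                genotype=genotype,
                age=age,
                strio_offset=strio_off,
                matrix_offset=matrix_off,
            )
            image = render_section(
                truth, effects, rng, pixel_size_um=design.pixel_size_um
            )
            section_id = f"{animal_id}-{level}"
            meta = {
                "section_id": section_id,
                "animal_id": animal_id,
                "genotype": genotype,
                "age": age,
                "level": level,
            }
            samples.append(
                SectionSample(image=image, landmarks=landmarks, truth=truth, meta=meta)
            )
            rows.append(meta)
    return samples, pd.DataFrame(rows)
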