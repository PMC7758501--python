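"""Landmark-driven caudoputamen sector geometry.

The caudoputamen of each hemisphere is partitioned into dorsomedial (DM),
dorsolateral (DL), ventromedial (VM) and ventrolateral (VL) sectors by a
ruler-and-compass construction from four anatomical landmarks per
hemisphere: the caudoputamen outline, the lateral tip of the anterior
commissure, and the upper tip of the nucleus accumbens shell.  Per
hemisphere the construction is:

1. line 1 — the inter-hemispheric tangent, taken as the line through the
   medial extreme points of the left and right outlines (roughly horizontal
   in a coronal section);
2. line 2 — parallel to line 1 through the anterior-commissure lateral tip;
3. line 3 — from the accumbens-shell upper tip to the point where line 2
   meets the lateral margin of the outline;
4. line 4 — perpendicular to line 1 from the accumbens-shell upper tip,
   taken as the chord running dorsally through the outline;
5. line 5 — parallel to line 3 through the midpoint of line 4;
6. line 6 — through the midpoints of the striatal chords of lines 3 and 5,
   extended to the outline boundary.

Line 5 is the dorsal/ventral divider and line 6 the medial/lateral divider;
each sector is the intersection of the outline with a quadrant of those two
lines.  Masks are rasterized with pixel-center membership (even-odd fill),
so the four sector masks partition the whole-outline mask exactly by
construction.  A pixel falling exactly on a divider counts as dorsal
(line 5) and medial (line 6), which realizes the DM-first tie rule.

Image coordinates follow raster convention: origin top-left, x rightward
(columns), y downward (rows); "dorsal" is therefore the small-y side.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path as FsPath
from typing import Iterable

import numpy as np
from matplotlib.path import Path as MplPath
from shapely.geometry import LineString, Point, Polygon, box

__all__ = [
    "ControlSquare",
    "LandmarkSet",
    "RegionSet",
    "GeometryError",
    "SECTORS",
    "construct_sectors",
    "validate_landmarks",
    "rasterize_polygon",
]

SECTORS = ("DM", "DL", "VM", "VL")
HEMISPHERES = ("left", "right")


class GeometryError(ValueError):
    """Missing landmark or degenerate construction geometry."""


@dataclass(frozen=True)
class ControlSquare:
    """Square control region on a fiber tract, side given in micrometers."""

    center: tuple[float, float]  # (x, y) pixel coordinates
    side_um: float = 50.0
    label: str = ""

    def side_px(self, pixel_size_um: float) -> int:
        """Side length in pixels: 50 um converted and rounded, at least 1."""
        return max(1, int(round(self.side_um / pixel_size_um)))

    def slices(self, pixel_size_um: float) -> tuple[slice, slice]:
        side = self.side_px(pixel_size_um)
        x0 = int(round(self.center[0] - side / 2))
        y0 = int(round(self.center[1] - side / 2))
        return slice(y0, y0 + side), slice(x0, x0 + side)


@dataclass
class LandmarkSet:
    """Anatomical landmarks for one section (both hemispheres).

    Outlines are closed polygons given as (x, y) vertex arrays; points are
    (x, y) pixel coordinates.
    """

    cp_outline_left: np.ndarray
    cp_outline_right: np.ndarray
    ac_lateral_tip_left: tuple[float, float]
    ac_lateral_tip_right: tuple[float, float]
    nacc_shell_upper_tip_left: tuple[float, float]
    nacc_shell_upper_tip_right: tuple[float, float]
    fiber_control_squares: list[ControlSquare] = field(default_factory=list)
    pixel_size_um: float = 20.0
    image_shape: tuple[int, int] | None = None

    def outline(self, hemisphere: str) -> np.ndarray:
        return getattr(self, f"cp_outline_{hemisphere}")

    def ac_tip(self, hemisphere: str) -> tuple[float, float]:
        return getattr(self, f"ac_lateral_tip_{hemisphere}")

    def nacc_tip(self, hemisphere: str) -> tuple[float, float]:
        return getattr(self, f"nacc_shell_upper_tip_{hemisphere}")

    # -- JSON round trip ---------------------------------------------------

    def to_json(self) -> dict:
        return {
            "pixel_size_um": self.pixel_size_um,
            "image_shape": list(self.image_shape) if self.image_shape else None,
            "points": {
                "ac_lateral_tip_left": list(self.ac_lateral_tip_left),
                "ac_lateral_tip_right": list(self.ac_lateral_tip_right),
                "nacc_shell_upper_tip_left": list(self.nacc_shell_upper_tip_left),
                "nacc_shell_upper_tip_right": list(self.nacc_shell_upper_tip_right),
            },
            "polygons": {
                "cp_outline_left": np.asarray(self.cp_outline_left).tolist(),
                "cp_outline_right": np.asarray(self.cp_outline_right).tolist(),
            },
            "control_squares": [
                {"center": list(s.center), "side_um": s.side_um, "label": s.label}
                for s in self.fiber_control_squares
            ],
        }

    @classmethod
    def from_json(cls, doc: dict) -> "LandmarkSet":
        pts = doc.get("points", {})
        polys = doc.get("polygons", {})
        required = [
            "ac_lateral_tip_left",
            "ac_lateral_tip_right",
            "nacc_shell_upper_tip_left",
            "nacc_shell_upper_tip_right",
        ]
        for key in required:
            if key not in pts:
                raise GeometryError(f"missing landmark point: {key}")
        for key in ("cp_outline_left", "cp_outline_right"):
            if key not in polys:
                raise GeometryError(f"missing landmark polygon: {key}")
        shape = doc.get("image_shape")
        return cls(
            cp_outline_left=np.asarray(polys["cp_outline_left"], dtype=float),
            cp_outline_right=np.asarray(polys["cp_outline_right"], dtype=float),
            ac_lateral_tip_left=tuple(pts["ac_lateral_tip_left"]),
            ac_lateral_tip_right=tuple(pts["ac_lateral_tip_right"]),
            nacc_shell_upper_tip_left=tuple(pts["nacc_shell_upper_tip_left"]),
            nacc_shell_upper_tip_right=tuple(pts["nacc_shell_upper_tip_right"]),
            fiber_control_squares=[
                ControlSquare(
                    center=tuple(s["center"]),
                    side_um=s.get("side_um", 50.0),
                    label=s.get("label", ""),
                )
                for s in doc.get("control_squares", [])
            ],
            pixel_size_um=doc.get("pixel_size_um", 20.0),
            image_shape=tuple(shape) if shape else None,
        )

    def save(self, path: str | FsPath) -> None:
        FsPath(path).write_text(json.dumps(self.to_json(), indent=1))

    @classmethod
    def load(cls, path: str | FsPath) -> "LandmarkSet":
        return cls.from_json(json.loads(FsPath(path).read_text()))


@dataclass
class RegionSet:
    """Boolean sector masks per hemisphere: whole + DM/DL/VM/VL."""

    masks: dict[str, dict[str, np.ndarray]]  # hemisphere -> region -> mask
    dividers: dict[str, dict[str, tuple]] = field(default_factory=dict)

    def mask(self, hemisphere: str, region: str) -> np.ndarray:
        return self.masks[hemisphere][region]

    def regions(self, hemisphere: str) -> Iterable[str]:
        return self.masks[hemisphere].keys()


# -- construction ---------------------------------------------------------


def rasterize_polygon(vertices: np.ndarray, image_shape: tuple[int, int]) -> np.ndarray:
    """Pixel-center membership mask of a closed polygon (even-odd fill)."""
    h, w = image_shape
    verts = np.asarray(vertices, dtype=float)
    # Path treats the last vertex as the CLOSEPOLY dummy: repeat the first.
    path = MplPath(np.vstack([verts, verts[:1]]), closed=True)
    x0 = max(0, int(np.floor(verts[:, 0].min())))
    x1 = min(w - 1, int(np.ceil(verts[:, 0].max())))
    y0 = max(0, int(np.floor(verts[:, 1].min())))
    y1 = min(h - 1, int(np.ceil(verts[:, 1].max())))
    mask = np.zeros((h, w), dtype=bool)
    if x1 < x0 or y1 < y0:
        return mask
    xs, ys = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1))
    pts = np.column_stack([xs.ravel(), ys.ravel()])
    inside = path.contains_points(pts)
    mask[y0 : y1 + 1, x0 : x1 + 1] = inside.reshape(ys.shape)
    return mask


def _unit(v: np.ndarray) -> np.ndarray:
    n = float(np.hypot(*v))
    if n == 0:
        raise GeometryError("degenerate direction vector")
    return v / n


def _cross(d: np.ndarray, v: np.ndarray) -> np.ndarray:
    return d[0] * v[..., 1] - d[1] * v[..., 0]


def _longest_chord(line: LineString, poly: Polygon) -> LineString:
    inter = line.intersection(poly)
    if inter.is_empty:
        raise GeometryError("construction line does not cross the outline")
    if inter.geom_type == "LineString":
        return inter
    if inter.geom_type in ("MultiLineString", "GeometryCollection"):
        pieces = [g for g in inter.geoms if g.geom_type == "LineString"]
        if not pieces:
            raise GeometryError("construction line meets outline only at points")
        return max(pieces, key=lambda g: g.length)
    raise GeometryError(f"unexpected intersection type {inter.geom_type}")


def _infinite_line(point: np.ndarray, direction: np.ndarray, reach: float) -> LineString:
    return LineString([point - direction * reach, point + direction * reach])


def _medial_extreme(outline: np.ndarray, hemisphere: str) -> np.ndarray:
    verts = np.asarray(outline, dtype=float)
    idx = np.argmax(verts[:, 0]) if hemisphere == "left" else np.argmin(verts[:, 0])
    return verts[idx]


def construct_sectors(
    landmarks: LandmarkSet,
    image_shape: tuple[int, int] | None = None,
    hemispheres: Iterable[str] = HEMISPHERES,
) -> RegionSet:
    """Build whole/DM/DL/VM/VL masks per hemisphere from the landmarks."""
    shape = image_shape or landmarks.image_shape
    if shape is None:
        raise GeometryError("image_shape required (not stored in landmark set)")
    h, w = shape
    reach = 4.0 * float(np.hypot(h, w))

    p_med_l = _medial_extreme(landmarks.cp_outline_left, "left")
    p_med_r = _medial_extreme(landmarks.cp_outline_right, "right")
    if np.allclose(p_med_l, p_med_r):
        raise GeometryError("cannot define inter-hemispheric tangent (line 1)")
    d1 = _unit(p_med_r - p_med_l)  # line 1 direction
    midline = 0.5 * (p_med_l + p_med_r)

    masks: dict[str, dict[str, np.ndarray]] = {}
    dividers: dict[str, dict[str, tuple]] = {}
    for hemi in hemispheres:
        outline = np.asarray(landmarks.outline(hemi), dtype=float)
        poly = Polygon(outline)
        if not poly.is_valid or poly.area == 0:
            raise GeometryError(f"invalid or degenerate outline: {hemi}")
        ac = np.asarray(landmarks.ac_tip(hemi), dtype=float)
        nacc = np.asarray(landmarks.nacc_tip(hemi), dtype=float)

        # line 2: parallel to line 1 through the AC lateral tip; its lateral
        # crossing of the outline margin is the far endpoint of line 3.
        line2 = _infinite_line(ac, d1, reach)
        boundary_pts = line2.intersection(poly.exterior)
        if boundary_pts.is_empty:
            raise GeometryError(f"line 2 misses the {hemi} outline")
        candidates = (
            [boundary_pts]
            if boundary_pts.geom_type == "Point"
            else [g for g in boundary_pts.geoms if g.geom_type == "Point"]
        )
        centroid = np.asarray(poly.centroid.coords[0])
        u = d1 if float(np.dot(centroid - midline, d1)) > 0 else -d1
        q = max(candidates, key=lambda p: float(np.dot(np.asarray(p.coords[0]) - midline, u)))
        q = np.asarray(q.coords[0])

        # line 3 and its striatal chord midpoint.
        d3 = _unit(q - nacc)
        chord3 = _longest_chord(LineString([nacc, q]), poly)
        m3 = np.asarray(chord3.interpolate(0.5, normalized=True).coords[0])

        # line 4: perpendicular to line 1 through the accumbens tip, running
        # dorsally through the outline.
        n1 = np.array([-d1[1], d1[0]])
        if n1[1] > 0:  # ensure the perpendicular points dorsally (small y)
            n1 = -n1
        chord4 = _longest_chord(_infinite_line(nacc, n1, reach), poly)
        ends4 = np.asarray(chord4.coords)
        dorsal_end = ends4[np.argmax([np.dot(e - nacc, n1) for e in ends4])]
        m4 = np.asarray(chord4.interpolate(0.5, normalized=True).coords[0])

        # line 5: parallel to line 3 through the midpoint of line 4.
        chord5 = _longest_chord(_infinite_line(m4, d3, reach), poly)
        m5 = np.asarray(chord5.interpolate(0.5, normalized=True).coords[0])

        # line 6: through the two chord midpoints, extended to the boundary.
        if np.allclose(m3, m5):
            raise GeometryError(f"lines 3 and 5 coincide in {hemi} hemisphere")
        d6 = _unit(m5 - m3)

        whole = rasterize_polygon(outline, (h, w))
        ys, xs = np.nonzero(whole)
        pts = np.column_stack([xs, ys]).astype(float)

        s5 = _cross(d3, pts - m4)
        dorsal_sign = np.sign(_cross(d3, dorsal_end - m4)) or 1.0
        s6 = _cross(d6, pts - m3)
        med_ref = _medial_extreme(outline, hemi)
        medial_sign = np.sign(_cross(d6, med_ref - m3))
        if medial_sign == 0:
            medial_sign = np.sign(_cross(d6, midline - m3)) or 1.0

        # On-divider pixels count as dorsal and medial (DM-first tie rule).
        dorsal = np.where(s5 == 0, True, s5 * dorsal_sign > 0)
        medial = np.where(s6 == 0, True, s6 * medial_sign > 0)

        hemi_masks = {"whole": whole}
        for name, sel in (
            ("DM", dorsal & medial),
            ("DL", dorsal & ~medial),
            ("VM", ~dorsal & medial),
            ("VL", ~dorsal & ~medial),
        ):
            m = np.zeros((h, w), dtype=bool)
            m[ys[sel], xs[sel]] = True
            hemi_masks[name] = m
        masks[hemi] = hemi_masks
        dividers[hemi] = {
            "line5": (tuple(m4), tuple(d3)),
            "line6": (tuple(m3), tuple(d6)),
            "line3": (tuple(nacc), tuple(q)),
        }
    return RegionSet(masks=masks, dividers=dividers)


def validate_landmarks(landmarks: LandmarkSet) -> list[str]:
    """Pure report of landmark problems; empty list means all checks pass."""
    findings: list[str] = []
    polys = {}
    for hemi in HEMISPHERES:
        outline = landmarks.outline(hemi)
        if outline is None or len(np.asarray(outline)) < 3:
            findings.append(f"cp_outline_{hemi}: missing or fewer than 3 vertices")
            continue
        ring = LineString(
            np.vstack([np.asarray(outline, dtype=float), np.asarray(outline, dtype=float)[:1]])
        )
        if not ring.is_simple:
            findings.append(f"cp_outline_{hemi}: self-intersection")
        else:
            polys[hemi] = Polygon(np.asarray(outline, dtype=float))
        for name in (f"ac_lateral_tip_{hemi}", f"nacc_shell_upper_tip_{hemi}"):
            if getattr(landmarks, name, None) is None:
                findings.append(f"{name}: missing")
    for i, square in enumerate(landmarks.fiber_control_squares):
        side = square.side_px(landmarks.pixel_size_um)
        x0 = square.center[0] - side / 2
        y0 = square.center[1] - side / 2
        sq = box(x0, y0, x0 + side, y0 + side)
        for hemi, poly in polys.items():
            if sq.intersects(poly):
                findings.append(
                    f"control_square[{i}] ({square.label or 'unlabeled'}): "
                    f"overlaps cp_outline_{hemi}"
                )
    return findings
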