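"""Vessel calibers in zone B and summary CRAE/CRVE equivalents.

Widths of arterioles and venules that pass completely through the annulus
0.5-1 disc diameter from the disc margin (zone B) are summarised into the
central retinal arteriolar/venular equivalents (CRAE/CRVE) with the revised
Parr-Hubbard ("big six") formulas of Knudtson et al.: the six largest vessels
of each type are combined by iteratively pairing the largest with the
smallest, ``w = c * sqrt(w_max^2 + w_min^2)``, carrying the middle value when
the count is odd, until a single trunk equivalent remains.

Width at a skeleton point is estimated from the Euclidean distance
transform of the binary mask (full local vessel thickness); a
vessel's width is the median over its skeleton points inside the zone. This
diverges from intensity-profile (edge-based) measurement used by grading
software; at the scales simulated here the two agree to within a pixel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.morphology import skeletonize

from .segment import CALIBER_ZONE, ZoneSpec

__all__ = [
    "KNUDTSON_COEFF",
    "VesselWidth",
    "VesselWidthSet",
    "CaliberSummary",
    "knudtson_equivalent",
    "measure_widths",
    "caliber_summary",
    "TreeLabeler",
]

# Branching coefficients of the revised Parr-Hubbard formulas
# (Knudtson et al., Curr Eye Res 2003): arteriolar 0.88, venular 0.95.
KNUDTSON_COEFF = {"arteriole": 0.88, "venule": 0.95}


def knudtson_equivalent(
    widths: Sequence[float],
    vessel_type: Literal["arteriole", "venule"],
    strict: bool = True,
) -> float:
    """Trunk caliber equivalent from the six largest vessel widths (um).

    Pairing schedule: sort, combine largest with smallest via
    ``c * sqrt(a^2 + b^2)``, carry the middle value when the count is odd;
    repeat until one value remains (6 -> 3 -> 2 -> 1). With ``strict`` the
    input must be exactly six positive widths; otherwise any count >= 1 is
    accepted (reduced-branch variant, flagged with a warning).
    """
    w = np.asarray(widths, dtype=float)
    if vessel_type not in KNUDTSON_COEFF:
        raise ValueError("vessel_type must be 'arteriole' or 'venule'")
    if w.size == 0 or np.any(w <= 0) or np.any(~np.isfinite(w)):
        raise ValueError("widths must be positive and finite")
    if strict and w.size != 6:
        raise ValueError(f"expected exactly 6 widths, got {w.size}")
    if not strict and w.size != 6:
        warnings.warn(f"reduced-branch equivalent from {w.size} widths")
    c = KNUDTSON_COEFF[vessel_type]
    vals = np.sort(w)[::-1]
    while vals.size > 1:
        n = vals.size
        paired = c * np.sqrt(vals[: n // 2] ** 2 + vals[::-1][: n // 2] ** 2)
        if n % 2:
            paired = np.append(paired, vals[n // 2])
        vals = np.sort(paired)[::-1]
    return float(vals[0])


@dataclass
class VesselWidth:
    """One vessel crossing the measurement zone."""

    vessel_id: int
    label: Literal["arteriole", "venule"]
    width_um: float
    n_points: int          # skeleton points inside the zone
    zone_length_px: float  # in-zone skeleton length, used to break width ties


@dataclass
class VesselWidthSet:
    vessels: list[VesselWidth] = field(default_factory=list)

    def of_type(self, label: str) -> list[VesselWidth]:
        return [v for v in self.vessels if v.label == label]


@dataclass
class CaliberSummary:
    crae_um: float
    crve_um: float
    n_arterioles_used: int
    n_venules_used: int
    reduced: bool = False  # True when fewer than six vessels of a type


class TreeLabeler:
    """Assign ground-truth vessel identity/type to mask pixels.

    Built from a synthetic :class:`~retivasc.synth.VesselTree`: every segment
    polyline is sampled densely and labelled with its trunk-path id (side
    branches count as separate vessels) and arteriole/venule type; queries
    return the nearest sample's labels. This stands in for the manual arteriole/venule grading of real
    images, which is out of scope.
    """

    def __init__(self, tree) -> None:
        pts, ids, labels = [], [], []
        for seg in tree.segments:
            p = np.asarray(seg.points, dtype=float)
            # resample at ~1 px spacing so nearest-neighbour lookup is dense
            d = np.linalg.norm(np.diff(p, axis=0), axis=1)
            s = np.concatenate([[0.0], np.cumsum(d)])
            n = max(2, int(s[-1]) + 1)
            si = np.linspace(0, s[-1], n)
            rows = np.interp(si, s, p[:, 0])
            cols = np.interp(si, s, p[:, 1])
            pts.append(np.column_stack([rows, cols]))
            ids.extend([seg.path_id] * n)
            labels.extend([seg.label] * n)
        self._tree = cKDTree(np.concatenate(pts))
        self._ids = np.asarray(ids)
        self._labels = np.asarray(labels)

    def __call__(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        _, idx = self._tree.query(np.asarray(points, dtype=float))
        return self._ids[idx], self._labels[idx]


def measure_widths(
    mask: np.ndarray,
    disc_center: tuple[float, float],
    disc_radius: float,
    px_per_micron: float,
    labeler,
    zone: ZoneSpec = CALIBER_ZONE,
    traverse_tol_px: float = 4.0,
) -> VesselWidthSet:
    """Per-vessel widths inside the caliber zone.

    Only vessels whose skeleton fully traverses the annulus (reaches within
    ``traverse_tol_px`` of both the inner and outer zone boundary) are
    retained. ``labeler`` maps an (n, 2) array of skeleton points to
    ``(vessel_ids, labels)``; for synthetic scenes use :class:`TreeLabeler`.
    """
    mask = np.asarray(mask).astype(bool)
    if px_per_micron <= 0:
        raise ValueError("px_per_micron must be positive")
    r_in, r_out = zone.radii(disc_radius)
    skel = skeletonize(mask)
    edt = ndimage.distance_transform_edt(mask)

    pts = np.argwhere(skel)
    if len(pts) == 0:
        warnings.warn("no skeleton pixels: empty width set")
        return VesselWidthSet()
    d = np.sqrt((pts[:, 0] - disc_center[0]) ** 2 + (pts[:, 1] - disc_center[1]) ** 2)
    in_zone = (d >= r_in) & (d < r_out)
    if not in_zone.any():
        warnings.warn("no skeleton pixels inside the caliber zone")
        return VesselWidthSet()

    ids, labels = labeler(pts)
    out = VesselWidthSet()
    for vid in np.unique(ids):
        sel = ids == vid
        dz = d[sel]
        if dz.min() > r_in + traverse_tol_px or dz.max() < r_out - traverse_tol_px:
            continue  # does not traverse the full annulus
        zsel = sel & in_zone
        if not zsel.any():
            continue
        # 2*EDT - 0.5: EDT reaches the centre of the first background pixel,
        # which lies between 0 (generic orientation) and 1 px (axis-aligned)
        # beyond the half-width; subtract the orientation-averaged excess
        calibers_px = 2.0 * edt[pts[zsel, 0], pts[zsel, 1]] - 0.5
        width_um = float(np.median(calibers_px) / px_per_micron)
        label = str(labels[sel][0])
        out.vessels.append(
            VesselWidth(
                vessel_id=int(vid),
                label=label,  # type: ignore[arg-type]
                width_um=width_um,
                n_points=int(zsel.sum()),
                zone_length_px=float(zsel.sum()),  # 1 px spacing on the skeleton
            )
        )
    if not out.vessels:
        warnings.warn("no vessels traverse the caliber zone")
    return out


def _select_largest(vessels: Iterable[VesselWidth], n: int) -> list[VesselWidth]:
    return sorted(vessels, key=lambda v: (v.width_um, v.zone_length_px), reverse=True)[:n]


def caliber_summary(widths: VesselWidthSet, n_select: int = 6) -> CaliberSummary:
    """CRAE/CRVE from the six largest arterioles and venules.

    Falls back to the reduced-branch variant (flagged) when fewer than six
    vessels of a type traverse the zone; returns NaN for a type with none.
    """
    arts = _select_largest(widths.of_type("arteriole"), n_select)
    vens = _select_largest(widths.of_type("venule"), n_select)
    reduced = len(arts) < n_select or len(vens) < n_select

    def _equiv(sel: list[VesselWidth], vtype: str) -> float:
        if not sel:
            return float("nan")
        return knudtson_equivalent([v.width_um for v in sel], vtype, strict=len(sel) == n_select)

    return CaliberSummary(
        crae_um=_equiv(arts, "arteriole"),
        crve_um=_equiv(vens, "venule"),
        n_arterioles_used=len(arts),
        n_venules_used=len(vens),
        reduced=reduced,
    )
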