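"""Geometric metrics of a binary vessel mask.

Three summary statistics of the segmented retinal microvascular network:

* **Fractal dimension** ``D_f`` — box-counting scaling exponent of the vessel
  pattern. Boxes of side ``delta`` are slid across the mask and the number of
  boxes ``N(delta)`` containing at least one vessel pixel is recorded;
  ``D_f`` is minus the slope of ``log N`` against ``log delta``. Higher values
  indicate a denser, more space-filling network.
* **Lacunarity** ``L`` — a gap-structure statistic complementary to ``D_f``,
  built from the standard deviation of the per-box vessel-pixel count over the
  same box grid. Lower values indicate more homogeneous filling.
* **Tortuosity index** ``tau`` — mean per-branch chord-to-arc length ratio of
  the skeletonised network (straight branch = 1, curvier branches < 1).

All metrics are meant to be computed on a zone-restricted mask (an annulus
0.5–2 disc diameters from the optic-disc margin); the zone handling itself
lives in :mod:`retivasc.segment`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize

__all__ = [
    "BoxGrid",
    "BoxStats",
    "BranchSegment",
    "GeometrySummary",
    "box_counts",
    "fractal_dimension",
    "lacunarity",
    "gliding_box_curve",
    "extract_branches",
    "tortuosity_index",
    "geometry_summary",
    "default_deltas",
]


# ---------------------------------------------------------------------------
# box grids and counts
# ---------------------------------------------------------------------------

def default_deltas(shape: tuple[int, int]) -> tuple[int, ...]:
    """Dyadic box sides 2, 4, 8, ... up to min(shape)/4."""
    top = min(shape) // 4
    deltas = []
    d = 2
    while d <= top:
        deltas.append(d)
        d *= 2
    return tuple(deltas)


@dataclass(frozen=True)
class BoxGrid:
    """Box sides and stride for the (sliding) box count.

    ``stride_fraction`` = 1 gives the classic non-overlapping grid; values
    below 1 slide the box with stride ``max(1, floor(stride_fraction *
    delta))``.
    """

    deltas: tuple[int, ...]
    stride_fraction: float = 1.0

    def __post_init__(self) -> None:
        d = np.asarray(self.deltas)
        if len(d) < 4:
            raise ValueError("need at least 4 box sizes for a log-log fit")
        if np.any(d < 2) or np.any(np.diff(d) <= 0):
            raise ValueError("deltas must be >= 2 and strictly increasing")
        if not 0 < self.stride_fraction <= 1:
            raise ValueError("stride_fraction must be in (0, 1]")

    @classmethod
    def for_shape(cls, shape: tuple[int, int], stride_fraction: float = 1.0) -> "BoxGrid":
        return cls(default_deltas(shape), stride_fraction)

    def stride(self, delta: int) -> int:
        return max(1, int(np.floor(self.stride_fraction * delta)))


@dataclass
class BoxStats:
    """Per-delta occupancy and mass statistics of the box grid."""

    deltas: np.ndarray          # box side lengths
    n_boxes: np.ndarray         # N(delta): positions containing >=1 vessel pixel
    mean_count: np.ndarray      # mu(delta): mean vessel pixels per box position
    sd_count: np.ndarray        # sigma_N(delta): SD of per-box counts (ddof=0)
    n_positions: np.ndarray     # total box positions evaluated per delta
    empty_mask: bool = False


def box_counts(mask: np.ndarray, grid: BoxGrid | None = None) -> BoxStats:
    """Count vessel mass per box position for every box side in the grid.

    Boxes are anchored at ``(i*stride, j*stride)`` for all anchors covering the
    mask; boxes overhanging the edge are kept and the outside counts as empty.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    if grid is None:
        grid = BoxGrid.for_shape(mask.shape)
    H, W = mask.shape
    # integral image with leading zero row/col: S[i, j] = sum mask[:i, :j]
    S = np.zeros((H + 1, W + 1), dtype=np.int64)
    np.cumsum(np.cumsum(mask, axis=0), axis=1, out=S[1:, 1:])

    n_list, mu_list, sd_list, npos_list = [], [], [], []
    for delta in grid.deltas:
        stride = grid.stride(delta)
        r0 = np.arange(0, H, stride)
        c0 = np.arange(0, W, stride)
        r1 = np.minimum(r0 + delta, H)
        c1 = np.minimum(c0 + delta, W)
        counts = (
            S[np.ix_(r1, c1)] - S[np.ix_(r0, c1)]
            - S[np.ix_(r1, c0)] + S[np.ix_(r0, c0)]
        )
        n_list.append(int(np.count_nonzero(counts)))
        mu_list.append(float(counts.mean()))
        sd_list.append(float(counts.std()))
        npos_list.append(counts.size)

    stats = BoxStats(
        deltas=np.asarray(grid.deltas, dtype=float),
        n_boxes=np.asarray(n_list, dtype=float),
        mean_count=np.asarray(mu_list, dtype=float),
        sd_count=np.asarray(sd_list, dtype=float),
        n_positions=np.asarray(npos_list, dtype=float),
        empty_mask=not mask.any(),
    )
    if stats.empty_mask:
        warnings.warn("empty mask: N(delta)=0, fractal dimension undefined")
    return stats


def _loglog_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """OLS slope and R^2 of log(y) on log(x) (natural logs)."""
    lx, ly = np.log(x), np.log(y)
    slope, intercept = np.polyfit(lx, ly, 1)
    fit = slope * lx + intercept
    ss_res = float(np.sum((ly - fit) ** 2))
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(slope), r2


def fractal_dimension(stats: BoxStats, with_r2: bool = False):
    """Box-counting fractal dimension: minus the slope of log N vs log delta."""
    keep = stats.n_boxes >= 1
    if keep.sum() < 4:
        raise ValueError("need >= 4 box sizes with N(delta) >= 1")
    n = stats.n_boxes[keep]
    if np.all(n == n[0]):
        warnings.warn("degenerate box counts (all equal); returning D_f = 0")
        return (0.0, 0.0) if with_r2 else 0.0
    slope, r2 = _loglog_slope(stats.deltas[keep], n)
    df = -slope
    return (df, r2) if with_r2 else df


def lacunarity(
    stats: BoxStats,
    definition: Literal["two_minus_slope", "slope"] = "two_minus_slope",
    with_r2: bool = False,
):
    """Lacunarity from the scaling of the per-box count SD.

    Default definition: ``L = 2 - slope(log sigma_N vs log delta)``, which for
    typical vessel masks lies in (0, 1) and moves opposite to the fractal
    dimension (denser network -> higher D_f, lower L). The raw slope is
    available via ``definition='slope'``.
    """
    keep = stats.sd_count > 0
    if keep.sum() < 4:
        warnings.warn("lacunarity undefined: fewer than 4 deltas with sigma_N > 0")
        return (float("nan"), float("nan")) if with_r2 else float("nan")
    slope, r2 = _loglog_slope(stats.deltas[keep], stats.sd_count[keep])
    lac = 2.0 - slope if definition == "two_minus_slope" else slope
    return (lac, r2) if with_r2 else lac


def gliding_box_curve(stats: BoxStats) -> np.ndarray:
    """Classic gliding-box lacunarity curve Lambda(delta) = (sigma/mu)^2 + 1."""
    with np.errstate(divide="ignore", invalid="ignore"):
        lam = (stats.sd_count / stats.mean_count) ** 2 + 1.0
    return lam


# ---------------------------------------------------------------------------
# skeleton branches and tortuosity
# ---------------------------------------------------------------------------

_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class BranchSegment:
    """Skeleton polyline between two branch/end nodes."""

    points: np.ndarray  # (n, 2) float (row, col)
    arc_length: float = field(init=False)
    chord_length: float = field(init=False)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or len(pts) < 2:
            raise ValueError("polyline needs >= 2 points")
        self.points = pts
        steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        self.arc_length = float(steps.sum())
        self.chord_length = float(np.linalg.norm(pts[-1] - pts[0]))

    def tortuosity(self, convention: str = "chord_over_arc") -> float:
        if self.arc_length == 0:
            return float("nan")
        ratio = self.chord_length / self.arc_length
        return ratio if convention == "chord_over_arc" else 1.0 / ratio


def _smooth_polyline(points: np.ndarray, window: int) -> np.ndarray:
    """Moving-average smoothing that keeps the endpoints fixed.

    Suppresses the staircase length inflation of 8-connected digital paths,
    which would otherwise bias chord/arc tortuosity down even for straight
    vessels.
    """
    if window <= 1 or len(points) <= 2:
        return points
    w = min(window, len(points) if len(points) % 2 == 1 else len(points) - 1)
    if w < 3:
        return points
    pad = w // 2
    padded = np.pad(points.astype(float), ((pad, pad), (0, 0)), mode="edge")
    kernel = np.ones(w) / w
    sm = np.column_stack([
        np.convolve(padded[:, 0], kernel, mode="valid"),
        np.convolve(padded[:, 1], kernel, mode="valid"),
    ])
    sm[0] = points[0]
    sm[-1] = points[-1]
    return sm


def extract_branches(
    mask: np.ndarray,
    min_branch_len: float = 10.0,
    smooth_window: int = 5,
) -> list[BranchSegment]:
    """Skeletonise a mask and split the skeleton into branch segments.

    Skeleton pixels are classified by 8-neighbour count (end = 1, link = 2,
    node >= 3); maximal runs of link pixels between nodes become segments,
    extended by their terminal node pixels. Segments shorter than
    ``min_branch_len`` pixels of arc are discarded; polylines are lightly
    smoothed (endpoints pinned) before length measurement.
    """
    mask = np.asarray(mask).astype(bool)
    skel = skeletonize(mask)
    if not skel.any():
        return []
    nbr_kernel = np.ones((3, 3), dtype=int)
    nbr_kernel[1, 1] = 0
    nbrs = ndimage.convolve(skel.astype(int), nbr_kernel, mode="constant")
    node = skel & (nbrs >= 3)
    link = skel & ~node  # includes end pixels (degree <= 2)

    lbl, nlbl = ndimage.label(link, structure=np.ones((3, 3), dtype=int))
    node_idx = {tuple(p) for p in np.argwhere(node)}
    segments: list[BranchSegment] = []

    slices = ndimage.find_objects(lbl)
    for k in range(1, nlbl + 1):
        sl = slices[k - 1]
        if sl is None:
            continue
        sub = lbl[sl] == k
        pts = {(int(r) + sl[0].start, int(c) + sl[1].start) for r, c in np.argwhere(sub)}
        # endpoints of this run: <=1 neighbour inside the run
        ends = []
        for p in pts:
            deg = sum((p[0] + dr, p[1] + dc) in pts for dr, dc in _NEIGHBORS)
            if deg <= 1:
                ends.append(p)
        if not ends:
            continue  # pure cycle without nodes: no defined endpoints, skip
        # walk the run from one endpoint
        start = min(ends)
        order = [start]
        seen = {start}
        cur = start
        while True:
            nxt = None
            for dr, dc in _NEIGHBORS:
                q = (cur[0] + dr, cur[1] + dc)
                if q in pts and q not in seen:
                    nxt = q
                    break
            if nxt is None:
                break
            order.append(nxt)
            seen.add(nxt)
            cur = nxt
        # attach adjacent node pixels at both ends, if any
        def _adjacent_node(p):
            for dr, dc in _NEIGHBORS:
                q = (p[0] + dr, p[1] + dc)
                if q in node_idx:
                    return q
            return None

        head = _adjacent_node(order[0])
        tail = _adjacent_node(order[-1])
        coords = ([head] if head else []) + order + ([tail] if tail and tail != head else [])
        if len(coords) < 2:
            continue
        pts_arr = _smooth_polyline(np.asarray(coords, dtype=float), smooth_window)
        seg = BranchSegment(pts_arr)
        if seg.arc_length >= min_branch_len:
            segments.append(seg)
    return segments


def tortuosity_index(
    segments: Sequence[BranchSegment],
    convention: Literal["chord_over_arc", "arc_over_chord"] = "chord_over_arc",
) -> float:
    """Unweighted mean per-branch tortuosity; chord/arc by default (<= 1)."""
    if not segments:
        raise ValueError("no branch segments")
    vals = []
    for seg in segments:
        if seg.arc_length <= 0:
            warnings.warn("skipping zero-length segment")
            continue
        vals.append(seg.tortuosity(convention))
    if not vals:
        raise ValueError("no usable branch segments")
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# combined summary
# ---------------------------------------------------------------------------

@dataclass
class GeometrySummary:
    fractal_dimension: float
    lacunarity: float
    tortuosity: float
    n_branches: int
    df_r2: float
    lac_r2: float


def geometry_summary(
    mask: np.ndarray,
    grid: BoxGrid | None = None,
    min_branch_len: float = 10.0,
    lacunarity_definition: str = "two_minus_slope",
    tortuosity_convention: str = "chord_over_arc",
) -> GeometrySummary:
    """Fractal dimension, lacunarity and tortuosity of one (zone-masked) mask."""
    stats = box_counts(mask, grid)
    df, df_r2 = fractal_dimension(stats, with_r2=True)
    lac, lac_r2 = lacunarity(stats, definition=lacunarity_definition, with_r2=True)
    branches = extract_branches(mask, min_branch_len=min_branch_len)
    tau = tortuosity_index(branches, convention=tortuosity_convention) if branches else float("nan")
    return GeometrySummary(df, lac, tau, len(branches), df_r2, lac_r2)
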