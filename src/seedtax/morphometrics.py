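"""Six-variable seed morphometrics measured from a segmented seed image.

The variables are the classic diagnostic set for curved, pitted seeds:
projected area, outline perimeter, the two sides of the minimum-area
rotated bounding rectangle (length ``rect_a`` and width ``rect_b``), the
bend angle of the seed axis (180 deg = straight, ~90 deg = U-shaped), and
the number of pits on the seed coat.  All lengths are in pixels; no
physical calibration is applied.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from shapely.geometry import Polygon
from skimage import measure, morphology

from .errors import AmbiguousShapeError, NoForegroundError

#: Canonical feature order used by every feature table in the package.
FEATURE_NAMES = ("area", "perimeter", "rect_a", "rect_b", "bend_angle", "pit_count")

_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass
class MorphometricRecord:
    """The six measured variables plus taxon/population labels."""

    area: float
    perimeter: float
    rect_a: float
    rect_b: float
    bend_angle: float
    pit_count: int
    class_id: int | None = None
    population_id: str | None = None

    def as_vector(self) -> np.ndarray:
        return np.array(
            [self.area, self.perimeter, self.rect_a, self.rect_b,
             self.bend_angle, float(self.pit_count)],
            dtype=float,
        )

    def validate(self) -> None:
        if not (self.rect_a >= self.rect_b > 0):
            raise ValueError("rectangle sides must satisfy rect_a >= rect_b > 0")
        if self.area > self.rect_a * self.rect_b * (1 + 1e-9):
            raise ValueError("area cannot exceed the bounding rectangle area")
        if self.perimeter < 2.0 * np.sqrt(np.pi * self.area) * (1 - 1e-9):
            raise ValueError("perimeter below the isoperimetric minimum")
        if not (0 < self.bend_angle <= 180):
            raise ValueError("bend angle must lie in (0, 180]")
        if self.pit_count < 0:
            raise ValueError("pit count must be non-negative")


def _as_bool_mask(mask) -> np.ndarray:
    arr = np.asarray(getattr(mask, "mask", mask))
    if arr.ndim != 2:
        raise ValueError("mask must be a 2-D array")
    return arr.astype(bool)


def _require_single_component(mask) -> np.ndarray:
    arr = _as_bool_mask(mask)
    labels, n = ndimage.label(arr, structure=_EIGHT)
    if n == 0:
        raise NoForegroundError("empty mask")
    if n > 1:
        raise ValueError(f"mask has {n} connected components; expected 1")
    return arr


def measure_area(mask) -> float:
    """Foreground pixel count of a single-component mask."""
    arr = _require_single_component(mask)
    return float(arr.sum())


def _outer_contour(arr: np.ndarray) -> np.ndarray:
    padded = np.pad(arr.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        raise NoForegroundError("no contour found")
    return max(contours, key=len) - 1.0  # undo padding offset


def _smooth_closed_contour(contour: np.ndarray, window: int = 5) -> np.ndarray:
    """Moving-average smoothing of a (closed) contour polygon.

    The raw marching-squares polygon staircases along rasterized smooth
    boundaries and overestimates length by up to ~7%; a short wrap-around
    moving average removes the staircase while barely rounding corners.
    """
    closed = np.allclose(contour[0], contour[-1])
    pts = contour[:-1] if closed else contour
    if len(pts) <= window:
        return contour
    kernel = np.ones(window) / window
    out = np.empty_like(pts)
    for d in range(2):
        wrapped = np.r_[pts[-window:, d], pts[:, d], pts[:window, d]]
        out[:, d] = np.convolve(wrapped, kernel, mode="same")[window:-window]
    return np.vstack([out, out[:1]]) if closed else out


def measure_perimeter(mask) -> float:
    """Length of the smoothed sub-pixel outer boundary polygon."""
    arr = _require_single_component(mask)
    contour = _smooth_closed_contour(_outer_contour(arr))
    diffs = np.diff(contour, axis=0)
    return float(np.hypot(diffs[:, 0], diffs[:, 1]).sum())


def min_area_rect(mask) -> tuple[float, float, float]:
    """Minimum-area rotated bounding rectangle as ``(rect_a, rect_b, angle_deg)``.

    ``rect_a`` is the longer side.  Degenerate (line-like) masks report
    ``rect_b`` of at least 1 px.
    """
    arr = _require_single_component(mask)
    contour = _outer_contour(arr)
    poly = Polygon(contour)
    rect = poly.minimum_rotated_rectangle
    coords = np.asarray(rect.exterior.coords)[:-1]
    if len(coords) < 4:  # degenerate: point or segment
        span = float(np.linalg.norm(coords[-1] - coords[0])) if len(coords) > 1 else 1.0
        return max(span, 1.0), 1.0, 0.0
    e1 = coords[1] - coords[0]
    e2 = coords[2] - coords[1]
    s1, s2 = float(np.linalg.norm(e1)), float(np.linalg.norm(e2))
    a, b = max(s1, s2), min(s1, s2)
    edge = e1 if s1 >= s2 else e2
    angle = float(np.degrees(np.arctan2(edge[0], edge[1]))) % 180.0
    return a, max(b, 1.0), angle


def _skeleton_graph(skel: np.ndarray):
    """Return skeleton pixel coordinates and an adjacency list (8-connectivity)."""
    coords = np.argwhere(skel)
    index = {tuple(p): i for i, p in enumerate(coords)}
    adj: list[list[int]] = [[] for _ in coords]
    for i, (r, c) in enumerate(coords):
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                j = index.get((r + dr, c + dc))
                if j is not None:
                    adj[i].append(j)
    return coords, adj


def _bfs_farthest(adj, start: int):
    """BFS returning (farthest node, parents) from ``start``."""
    parents = {start: -1}
    queue = deque([start])
    last = start
    while queue:
        u = queue.popleft()
        last = u
        for v in adj[u]:
            if v not in parents:
                parents[v] = u
                queue.append(v)
    return last, parents


def _trace(parents, end: int) -> list[int]:
    path = [end]
    while parents[path[-1]] != -1:
        path.append(parents[path[-1]])
    return path[::-1]


def _extend_to_cap_center(pts: np.ndarray, arr: np.ndarray,
                          edt: np.ndarray) -> np.ndarray:
    """Extend a skeleton path to the medial-axis cap centers.

    Discrete skeletonization trims the path short of the rounded tips.
    Each end is marched along its local tangent to the mask tip, then
    pulled back by the local half-width, which lands on the cap center
    of a capsule-like shape.
    """
    h, w = arr.shape
    ends = []
    for endpoint, inner in ((pts[0], pts[min(8, len(pts) - 1)]),
                            (pts[-1], pts[-1 - min(8, len(pts) - 1)])):
        tangent = endpoint - inner
        norm = np.linalg.norm(tangent)
        if norm == 0:
            ends.append(endpoint)
            continue
        tangent = tangent / norm
        radius = float(edt[int(round(endpoint[0])), int(round(endpoint[1]))])
        d = 0.0
        while True:
            probe = endpoint + (d + 0.5) * tangent
            r, c = int(round(probe[0])), int(round(probe[1]))
            if not (0 <= r < h and 0 <= c < w) or not arr[r, c]:
                break
            d += 0.5
        ends.append(endpoint + max(d - radius, 0.0) * tangent)
    return np.vstack([ends[0], pts, ends[1]])


def bend_angle(mask, spur_tolerance: float = 0.35) -> float:
    """Bend angle of an elongated mask, in degrees.

    The medial axis is traced to its longest path; boundary spurs at the
    rounded tips (where the local half-width collapses) are trimmed and
    the path extended to the cap centers.  The angle at the arc-length
    midpoint M between the two endpoints E1, E2 is returned: a straight
    seed gives ~180 deg, a semicircular (U-shaped) seed ~90 deg.  Side
    branches longer than ``spur_tolerance`` times the main path (beyond
    the cap scale) raise :class:`AmbiguousShapeError`.
    """
    arr = _require_single_component(mask)
    # medial_axis breaks thinning-order ties randomly unless seeded
    skel = morphology.medial_axis(arr, rng=0)
    if skel.sum() < 3:
        raise AmbiguousShapeError("skeleton too short to define an axis")
    coords, adj = _skeleton_graph(skel)
    degrees = np.array([len(a) for a in adj])
    endpoints = np.flatnonzero(degrees <= 1)
    if len(endpoints) < 2:
        raise AmbiguousShapeError("skeleton has no endpoints (closed or blob-like shape)")
    # Longest path via double BFS from any endpoint.
    far, _ = _bfs_farthest(adj, int(endpoints[0]))
    far2, parents = _bfs_farthest(adj, far)
    path = _trace(parents, far2)
    pts = coords[path].astype(float)
    edt = ndimage.distance_transform_edt(arr)
    path_edt = edt[pts[:, 0].astype(int), pts[:, 1].astype(int)]
    half_width = float(np.median(path_edt))
    # Trim tip spurs: medial-axis branches running to the boundary have a
    # collapsing inscribed-disk radius, unlike the constant-width axis.
    lo = int(np.argmax(path_edt >= 0.85 * half_width))
    hi = len(pts) - int(np.argmax(path_edt[::-1] >= 0.85 * half_width))
    pts = pts[lo:hi]
    if len(pts) < 3:
        raise AmbiguousShapeError("axis vanishes after tip trimming")
    pts = _extend_to_cap_center(pts, arr, edt)
    seg = np.hypot(*np.diff(pts, axis=0).T)
    total = float(seg.sum())
    if total <= 0:
        raise AmbiguousShapeError("degenerate skeleton path")
    if total < 0.5 * half_width:
        # round/blob-like mask: the medial axis collapses toward a point
        raise AmbiguousShapeError("mask is not elongated enough for a bend axis")
    # Prune check: any endpoint off the main path hanging on a long branch.
    on_path = set(path)
    for e in endpoints:
        if int(e) in on_path:
            continue
        _, par = _bfs_farthest(adj, int(e))
        reach = [n for n in par if n in on_path]
        if not reach:
            raise AmbiguousShapeError("disconnected skeleton branch")
        branch_len = min(len(_trace(par, n)) for n in reach) - 1
        if branch_len > max(spur_tolerance * total, 1.5 * half_width):
            raise AmbiguousShapeError("skeleton has a major side branch")
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    mid_idx = int(np.searchsorted(cum, total / 2.0))
    e1, e2, m = pts[0], pts[-1], pts[mid_idx]
    v1, v2 = e1 - m, e2 - m
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise AmbiguousShapeError("midpoint coincides with an endpoint")
    cosang = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def count_pits(
    image,
    mask,
    erosion_px: int = 3,
    min_prominence: float = 10.0,
    min_radius: float = 2.0,
    smooth_sigma: float = 1.0,
) -> int:
    """Count locally dark pit blobs on the seed coat.

    The image is lightly smoothed, the mask eroded by ``erosion_px`` to
    avoid boundary shading, and pixels darker than the interior median by
    ``min_prominence`` gray levels are grouped into blobs; blobs whose
    equivalent radius reaches ``min_radius`` are counted.
    """
    arr = _require_single_component(mask)
    img = np.asarray(image, dtype=float)
    if img.shape != arr.shape:
        raise ValueError("image and mask shapes differ")
    interior = ndimage.binary_erosion(arr, structure=morphology.disk(erosion_px))
    if not interior.any():
        return 0
    smooth = ndimage.gaussian_filter(img, smooth_sigma)
    background = float(np.median(smooth[interior]))
    candidates = interior & (smooth < background - min_prominence)
    labels, n = ndimage.label(candidates, structure=_EIGHT)
    if n == 0:
        return 0
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    min_area = np.pi * min_radius**2
    return int(np.count_nonzero(sizes >= min_area))


def extract_features(
    image,
    mask,
    class_id: int | None = None,
    population_id: str | None = None,
) -> MorphometricRecord:
    """Measure all six variables on a preprocessed, separable seed."""
    arr = _require_single_component(mask)
    a, b, _ = min_area_rect(arr)
    rec = MorphometricRecord(
        area=measure_area(arr),
        perimeter=measure_perimeter(arr),
        rect_a=a,
        rect_b=b,
        bend_angle=bend_angle(arr),
        pit_count=count_pits(image, arr),
        class_id=class_id,
        population_id=population_id,
    )
    return rec
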