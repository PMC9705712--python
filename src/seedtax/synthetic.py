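"""Synthetic SEM-style seed image and feature-table generator.

Emulates a microscope seed-imaging study: 8-bit grayscale frames of
1024x768 px, one bent-capsule seed per frame on a noisy background with
debris blobs and a metadata bar, organized into taxa (classes) and
populations.  Every image carries an analytic ground-truth mask and
ground-truth morphometrics so that segmentation, measurement and
classification can be validated without any real data.

The seed body is a *bent capsule*: a stadium of length ``l`` and width
``w`` whose centerline (length ``l - w``) is bent along a circular arc.
Bending is parameterized by the bend angle ``beta`` in (0, 180]: the angle
subtended at the arc midpoint by the two centerline endpoints, so 180 deg
is straight and 90 deg a semicircular U.  Bending preserves area and
perimeter, giving closed forms:

    area      = (l - w) * w + pi * (w / 2)**2
    perimeter = 2 * (l - w) + pi * w

Seed-coat pits are non-overlapping darker disks placed inside the eroded
seed body with a ground-truth count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely import affinity
from shapely.geometry import LineString

from .errors import RenderBoundsError
from .morphometrics import FEATURE_NAMES, MorphometricRecord

#: Frame geometry (rows, cols) of every rendered image.
IMAGE_SHAPE = (768, 1024)

_MAX_SEED = 2**31 - 1


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SeedPhenotype:
    """Class-level seed geometry and coat texture (all lengths in px)."""

    class_id: int
    mean_length: float
    mean_width: float
    mean_bend_angle: float  # degrees in (0, 180]; 180 = straight
    pit_density: float      # pits per 1000 px^2 of seed area
    pit_radius: float
    coat_contrast: float    # fraction of seed/background contrast
    within_class_cv: float  # CV applied to each geometric parameter

    def __post_init__(self):
        if not (self.mean_length > self.mean_width > 0):
            raise ValueError("require mean_length > mean_width > 0")
        if not (0 < self.mean_bend_angle <= 180):
            raise ValueError("mean_bend_angle must lie in (0, 180]")
        if self.mean_bend_angle < min_bend_angle(self.mean_length, self.mean_width):
            raise ValueError(
                "bend too strong for this aspect ratio: the inner arc radius "
                "would go negative and the capsule would self-intersect")
        if self.pit_density < 0:
            raise ValueError("pit_density must be non-negative")
        if not (0 <= self.coat_contrast <= 1):
            raise ValueError("coat_contrast must lie in [0, 1]")
        if self.within_class_cv < 0:
            raise ValueError("within_class_cv must be non-negative")


@dataclass(frozen=True)
class PopulationSpec:
    """One population: a phenotype, an identifier, and an image count."""

    phenotype: SeedPhenotype
    population_id: str
    n_images: int

    def __post_init__(self):
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")


@dataclass(frozen=True)
class SyntheticScene:
    """Background, noise, debris and metadata-bar configuration."""

    background_level: float = 40.0
    noise_sd: float = 5.0
    n_debris: int = 3
    metadata_bar_height: int = 60
    allow_contact: bool = False
    seed_level: float = 185.0

    def __post_init__(self):
        if not (0 <= self.background_level <= 255):
            raise ValueError("background_level must lie in [0, 255]")
        if self.metadata_bar_height >= IMAGE_SHAPE[0]:
            raise ValueError("metadata bar taller than the image")
        if self.metadata_bar_height < 0 or self.noise_sd < 0 or self.n_debris < 0:
            raise ValueError("negative scene parameter")


@dataclass
class SyntheticSeedImage:
    """A rendered frame with its analytic ground truth."""

    pixels: np.ndarray       # uint8, IMAGE_SHAPE
    truth_mask: np.ndarray   # bool, IMAGE_SHAPE
    truth_features: MorphometricRecord
    class_id: int
    population_id: str | None
    seed_value: int


@dataclass(frozen=True)
class FeatureDistributionSpec:
    """Per-class Gaussian feature model: means, covariances, priors."""

    means: np.ndarray   # (K, 6)
    covs: np.ndarray    # (K, 6, 6)
    priors: np.ndarray  # (K,)

    def __post_init__(self):
        means = np.atleast_2d(np.asarray(self.means, dtype=float))
        covs = np.asarray(self.covs, dtype=float)
        priors = np.asarray(self.priors, dtype=float)
        if covs.shape != (means.shape[0], means.shape[1], means.shape[1]):
            raise ValueError("covariance stack shape mismatch")
        if priors.shape != (means.shape[0],) or not np.isclose(priors.sum(), 1.0):
            raise ValueError("priors must be a vector summing to 1")
        for k, cov in enumerate(covs):
            if not np.allclose(cov, cov.T, atol=1e-10):
                raise ValueError(f"covariance {k} not symmetric")
            w = np.linalg.eigvalsh(cov)
            if w.min() < -1e-9 * max(1.0, abs(w).max()):
                raise ValueError(f"covariance {k} not positive semi-definite")
        object.__setattr__(self, "means", means)
        object.__setattr__(self, "covs", covs)
        object.__setattr__(self, "priors", priors)

    @property
    def n_classes(self) -> int:
        return self.means.shape[0]


# ---------------------------------------------------------------------------
# Capsule geometry
# ---------------------------------------------------------------------------

def min_bend_angle(length: float, width: float, safety: float = 0.98) -> float:
    """Smallest valid bend angle for a capsule of this aspect ratio.

    Two failure modes bound the bend.  The inner tube radius goes
    negative once the half central angle alpha exceeds (l - w) / w
    radians; and beyond a semicircle (alpha > pi/2) the curled end caps
    approach each other and overlap once the endpoint chord
    2 R sin(alpha) drops below w.  Both break the area/perimeter closed
    forms, so generated bends are floored at the tighter limit (with a
    small safety margin).
    """
    arc_len = length - width
    alpha_inner = safety * arc_len / width
    alpha_cap = min(alpha_inner, math.pi - 1e-9)
    if alpha_cap > math.pi / 2:
        # chord condition: safety * arc_len * sin(a) / a >= width
        def gap(a):
            return safety * arc_len * math.sin(a) / a - width

        if gap(math.pi / 2) <= 0:
            alpha_cap = math.pi / 2
        elif gap(alpha_cap) < 0:
            from scipy.optimize import brentq
            alpha_cap = brentq(gap, math.pi / 2, alpha_cap)
    return 180.0 - math.degrees(alpha_cap)


def capsule_area(length: float, width: float) -> float:
    return (length - width) * width + math.pi * (width / 2.0) ** 2


def capsule_perimeter(length: float, width: float) -> float:
    return 2.0 * (length - width) + math.pi * width


def _centerline_points(length: float, width: float, bend_deg: float,
                       n: int = 200) -> np.ndarray:
    """Centerline arc of the bent capsule in a local (x, y) frame."""
    arc_len = length - width
    alpha = math.radians(180.0 - bend_deg)  # half the central angle
    t = np.linspace(-1.0, 1.0, n)
    if alpha < 1e-4:
        return np.column_stack([t * arc_len / 2.0, np.zeros(n)])
    radius = arc_len / (2.0 * alpha)
    ang = t * alpha
    return np.column_stack([radius * np.sin(ang), radius * (1.0 - np.cos(ang))])


def capsule_outline(length: float, width: float, bend_deg: float):
    """Shapely polygon of the bent capsule in its local frame."""
    pts = _centerline_points(length, width, bend_deg)
    return LineString(pts).buffer(width / 2.0, quad_segs=64)


def capsule_rect_sides(length: float, width: float, bend_deg: float) -> tuple[float, float]:
    """Sides (a >= b) of the minimum-area rotated rectangle of the capsule."""
    rect = capsule_outline(length, width, bend_deg).minimum_rotated_rectangle
    coords = np.asarray(rect.exterior.coords)[:-1]
    s1 = float(np.linalg.norm(coords[1] - coords[0]))
    s2 = float(np.linalg.norm(coords[2] - coords[1]))
    return max(s1, s2), min(s1, s2)


def phenotype_feature_means(ph: SeedPhenotype) -> np.ndarray:
    """Expected 6-feature vector of a phenotype (FEATURE_NAMES order)."""
    a = capsule_area(ph.mean_length, ph.mean_width)
    p = capsule_perimeter(ph.mean_length, ph.mean_width)
    ra, rb = capsule_rect_sides(ph.mean_length, ph.mean_width, ph.mean_bend_angle)
    pits = ph.pit_density * a / 1000.0
    return np.array([a, p, ra, rb, ph.mean_bend_angle, pits])


# ---------------------------------------------------------------------------
# Phenotype library
# ---------------------------------------------------------------------------

_BASE = dict(length=430.0, width=175.0, bend=150.0, pit_density=0.45,
             pit_radius=4.0, coat_contrast=0.25, cv=0.04)


def make_phenotype_library(n_classes: int, separation: float,
                           rng_seed: int) -> list[SeedPhenotype]:
    """Deterministic library of ``n_classes`` phenotypes.

    Geometric means are displaced from a common base along class-specific
    random directions; the displacement amplitude scales linearly with
    ``separation`` (0 collapses every class onto the base geometry).
    """
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    rng = np.random.default_rng(rng_seed)
    u = rng.uniform(-1.0, 1.0, size=(n_classes, 4))
    phenos = []
    for k in range(n_classes):
        length = _BASE["length"] * (1.0 + 0.22 * separation * u[k, 0])
        width = _BASE["width"] * (1.0 + 0.18 * separation * u[k, 1])
        width = min(width, 0.7 * length)
        bend_floor = max(40.0, min_bend_angle(length, width))
        bend = float(np.clip(_BASE["bend"] + 35.0 * separation * u[k, 2],
                             bend_floor, 180.0))
        pit_density = max(0.0, _BASE["pit_density"] * (1.0 + 0.5 * separation * u[k, 3]))
        phenos.append(SeedPhenotype(
            class_id=k,
            mean_length=length,
            mean_width=width,
            mean_bend_angle=bend,
            pit_density=pit_density,
            pit_radius=_BASE["pit_radius"],
            coat_contrast=_BASE["coat_contrast"],
            within_class_cv=_BASE["cv"],
        ))
    return phenos


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _sample_instance(ph: SeedPhenotype, rng) -> tuple[float, float, float]:
    cv = ph.within_class_cv
    length = ph.mean_length * (1.0 + cv * rng.standard_normal())
    width = ph.mean_width * (1.0 + cv * rng.standard_normal())
    width = min(max(width, 10.0), 0.8 * length)
    length = max(length, 20.0)
    bend_floor = max(20.0, min_bend_angle(length, width))
    bend = float(np.clip(ph.mean_bend_angle * (1.0 + cv * rng.standard_normal()),
                         bend_floor, 180.0))
    return length, width, bend


def _arc_distance_field(shape_bbox, origin, theta, length, width, bend_deg):
    """Distance from pixel centers in ``shape_bbox`` to the centerline arc."""
    (r0, r1), (c0, c1) = shape_bbox
    yy, xx = np.mgrid[r0:r1, c0:c1].astype(float)
    # world -> local: translate then rotate by -theta
    x = xx - origin[0]
    y = yy - origin[1]
    ct, st = math.cos(-theta), math.sin(-theta)
    xl = ct * x - st * y
    yl = st * x + ct * y
    arc_len = length - width
    alpha = math.radians(180.0 - bend_deg)
    if alpha < 1e-4:
        half = arc_len / 2.0
        xc = np.clip(xl, -half, half)
        return np.hypot(xl - xc, yl)
    radius = arc_len / (2.0 * alpha)
    # circle center at (0, radius) in the local frame
    dx = xl
    dy = yl - radius
    ang = np.arctan2(dx, -dy)  # 0 at arc midpoint, +/-alpha at endpoints
    r = np.hypot(dx, dy)
    d_arc = np.abs(r - radius)
    e1 = np.array([radius * math.sin(alpha), radius * (1 - math.cos(alpha))])
    e2 = np.array([-e1[0], e1[1]])
    d_end = np.minimum(np.hypot(xl - e1[0], yl - e1[1]),
                       np.hypot(xl - e2[0], yl - e2[1]))
    return np.where(np.abs(ang) <= alpha, d_arc, d_end)


def _place_pits(mask: np.ndarray, n_pits: int, pit_radius: float, rng,
                clearance: float) -> np.ndarray:
    """Choose up to ``n_pits`` non-overlapping pit centers inside the mask."""
    erode_r = int(math.ceil(pit_radius + clearance))
    allowed = ndimage.binary_erosion(mask, structure=np.ones((3, 3)),
                                     iterations=erode_r)
    cand = np.argwhere(allowed)
    if len(cand) == 0 or n_pits == 0:
        return np.empty((0, 2), dtype=int)
    order = rng.permutation(len(cand))
    min_d2 = (2.0 * pit_radius + 3.0) ** 2
    accepted: list[np.ndarray] = []
    for idx in order:
        p = cand[idx]
        if accepted:
            d2 = np.sum((np.asarray(accepted) - p) ** 2, axis=1)
            if d2.min() < min_d2:
                continue
        accepted.append(p)
        if len(accepted) == n_pits:
            break
    return np.asarray(accepted, dtype=int).reshape(-1, 2)


def _disk_indices(center, radius, shape):
    r0 = max(int(center[0] - radius - 1), 0)
    r1 = min(int(center[0] + radius + 2), shape[0])
    c0 = max(int(center[1] - radius - 1), 0)
    c1 = min(int(center[1] + radius + 2), shape[1])
    yy, xx = np.mgrid[r0:r1, c0:c1]
    inside = (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2
    return (slice(r0, r1), slice(c0, c1)), inside


def _draw_metadata_bar(canvas: np.ndarray, bar_height: int, rng) -> None:
    if bar_height <= 0:
        return
    h, w = canvas.shape
    canvas[h - bar_height:, :] = 12.0
    baseline = h - bar_height // 2
    col = 20
    while col < w - 30:
        gw = int(rng.integers(2, 7))
        gh = int(rng.integers(8, min(15, bar_height)))
        if rng.random() < 0.8:  # glyph; otherwise a word gap
            canvas[baseline - gh: baseline, col: col + gw] = 230.0
        col += gw + int(rng.integers(2, 6))


def render_seed_image(phenotype: SeedPhenotype, scene: SyntheticScene,
                      rng_seed: int,
                      population_id: str | None = None) -> SyntheticSeedImage:
    """Render one seed plus scene clutter; returns image with ground truth."""
    rng = np.random.default_rng(rng_seed)
    h, w = IMAGE_SHAPE
    length, width, bend = _sample_instance(phenotype, rng)

    theta = rng.uniform(0.0, 2.0 * math.pi)
    outline = affinity.rotate(capsule_outline(length, width, bend),
                              math.degrees(theta), origin=(0, 0))
    minx, miny, maxx, maxy = outline.bounds
    margin = 6.0
    usable_h = h - scene.metadata_bar_height
    lo_x, hi_x = margin - minx, w - margin - maxx
    lo_y, hi_y = margin - miny, usable_h - margin - maxy
    if lo_x > hi_x or lo_y > hi_y:
        raise RenderBoundsError(
            f"seed of length {length:.0f} px cannot fit inside the frame")
    ox = rng.uniform(lo_x, hi_x)
    oy = rng.uniform(lo_y, hi_y)

    r0 = max(int(miny + oy) - 2, 0)
    r1 = min(int(maxy + oy) + 3, h)
    c0 = max(int(minx + ox) - 2, 0)
    c1 = min(int(maxx + ox) + 3, w)
    dist = _arc_distance_field(((r0, r1), (c0, c1)), (ox, oy), theta,
                               length, width, bend)
    mask = np.zeros(IMAGE_SHAPE, dtype=bool)
    mask[r0:r1, c0:c1] = dist <= width / 2.0

    canvas = np.full(IMAGE_SHAPE, scene.background_level, dtype=float)
    canvas[mask] = scene.seed_level

    # Seed-coat pits: darker disks with a countable ground truth.
    area = capsule_area(length, width)
    n_pits = int(round(phenotype.pit_density * area / 1000.0))
    centers = _place_pits(mask, n_pits, phenotype.pit_radius, rng, clearance=5.0)
    pit_level = scene.seed_level - phenotype.coat_contrast * (
        scene.seed_level - scene.background_level)
    for center in centers:
        sl, inside = _disk_indices(center, phenotype.pit_radius, IMAGE_SHAPE)
        region = canvas[sl]
        region[inside] = pit_level
    pit_count = len(centers)

    # Debris blobs: ellipses kept clear of the seed unless contact is allowed.
    seed_dist = ndimage.distance_transform_edt(~mask)
    for i in range(scene.n_debris):
        ax1 = rng.uniform(8, 28)
        ax2 = rng.uniform(6, ax1)
        ang = rng.uniform(0, math.pi)
        level = scene.seed_level + rng.uniform(-45, 25)
        placed = False
        for _ in range(60):
            if scene.allow_contact and i == 0:
                # force contact: center just outside the seed boundary
                edge = np.argwhere(mask & ~ndimage.binary_erosion(mask))
                p = edge[rng.integers(len(edge))]
                normal = rng.uniform(0, 2 * math.pi)
                gap = rng.uniform(2.0, 2.8)
                cy = p[0] + (ax2 + gap) * math.sin(normal)
                cx = p[1] + (ax2 + gap) * math.cos(normal)
            else:
                cy = rng.uniform(10, h - scene.metadata_bar_height - 10)
                cx = rng.uniform(10, w - 10)
            rr0 = max(int(cy - ax1 - 1), 0)
            rr1 = min(int(cy + ax1 + 2), h - scene.metadata_bar_height)
            cc0 = max(int(cx - ax1 - 1), 0)
            cc1 = min(int(cx + ax1 + 2), w)
            if rr1 <= rr0 or cc1 <= cc0:
                continue
            yy, xx = np.mgrid[rr0:rr1, cc0:cc1].astype(float)
            ca, sa = math.cos(ang), math.sin(ang)
            u = (ca * (xx - cx) + sa * (yy - cy)) / ax1
            v = (-sa * (xx - cx) + ca * (yy - cy)) / ax2
            blob = u**2 + v**2 <= 1.0
            if not blob.any():
                continue
            if scene.allow_contact and i == 0:
                sub = mask[rr0:rr1, cc0:cc1]
                if (sub & blob).any():
                    continue  # must touch, not merge
                gap_px = seed_dist[rr0:rr1, cc0:cc1][blob].min()
                # a 2-px gap survives thresholding as a separate component
                # yet bridges after one dilation step
                if not (2.0 <= gap_px <= 2.9):
                    continue
            else:
                gap_px = seed_dist[rr0:rr1, cc0:cc1][blob].min()
                if gap_px < 4.0:
                    continue
            canvas[rr0:rr1, cc0:cc1][blob] = level
            placed = True
            break
        del placed

    _draw_metadata_bar(canvas, scene.metadata_bar_height, rng)

    if scene.noise_sd > 0:
        canvas = canvas + rng.normal(0.0, scene.noise_sd, IMAGE_SHAPE)
    pixels = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)

    rect_a, rect_b = capsule_rect_sides(length, width, bend)
    truth = MorphometricRecord(
        area=area,
        perimeter=capsule_perimeter(length, width),
        rect_a=rect_a,
        rect_b=rect_b,
        bend_angle=bend,
        pit_count=pit_count,
        class_id=phenotype.class_id,
        population_id=population_id,
    )
    return SyntheticSeedImage(
        pixels=pixels, truth_mask=mask, truth_features=truth,
        class_id=phenotype.class_id, population_id=population_id,
        seed_value=int(rng_seed),
    )


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------

def _population_phenotype(ph: SeedPhenotype, rng, population_effect: float) -> SeedPhenotype:
    """Apply a small per-population offset to the class geometry."""
    if population_effect <= 0:
        return ph
    j = rng.uniform(-population_effect, population_effect, size=3)
    length = ph.mean_length * (1.0 + j[0])
    width = min(ph.mean_width * (1.0 + j[1]), 0.7 * length)
    bend_floor = max(40.0, min_bend_angle(length, width))
    return replace(
        ph,
        mean_length=length,
        mean_width=width,
        mean_bend_angle=float(np.clip(ph.mean_bend_angle * (1.0 + j[2]),
                                      bend_floor, 180.0)),
    )


def iter_image_dataset(pop_specs: Sequence[PopulationSpec], rng_seed: int,
                       scene: SyntheticScene | None = None,
                       population_effect: float = 0.03,
                       ) -> Iterator[SyntheticSeedImage]:
    """Lazily render one image per requested seed, in population order."""
    if not pop_specs:
        raise ValueError("pop_specs must be nonempty")
    ids = [p.population_id for p in pop_specs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate population_id in pop_specs")
    scene = scene or SyntheticScene()
    rng = np.random.default_rng(rng_seed)
    for spec in pop_specs:
        ph = _population_phenotype(spec.phenotype, rng, population_effect)
        for _ in range(spec.n_images):
            seed_value = int(rng.integers(_MAX_SEED))
            yield render_seed_image(ph, scene, seed_value,
                                    population_id=spec.population_id)


def generate_image_dataset(pop_specs: Sequence[PopulationSpec], rng_seed: int,
                           scene: SyntheticScene | None = None,
                           population_effect: float = 0.03,
                           ) -> list[SyntheticSeedImage]:
    """Materialized version of :func:`iter_image_dataset` (small datasets)."""
    return list(iter_image_dataset(pop_specs, rng_seed, scene, population_effect))


# ---------------------------------------------------------------------------
# Study-layout preset: 12 taxa, 28 populations, 1299 images
# ---------------------------------------------------------------------------

#: (population_id, taxon acronym, image count) for the study-like layout.
TABLE1_POPULATIONS: tuple[tuple[str, str, int], ...] = (
    ("alsHU", "als", 50), ("alsPL1", "als", 51), ("alsPL2", "als", 45),
    ("bracUSA", "bra", 50),
    ("broMO", "bro", 50), ("broSP", "bro", 50),
    ("calUSA", "cal", 50),
    ("camIT", "cam", 50), ("camSP", "cam", 55),
    ("gusIT(L)", "gus", 50), ("gusIT(S)", "gus", 50),
    ("gusMAL", "gus", 50), ("gusSP", "gus", 50),
    ("hexPL1", "hex", 33), ("hexPL2", "hex", 50),
    ("hunHU", "hun", 50), ("hunRUS", "hun", 50),
    ("hunSLO(O)", "hun", 25), ("hunSLO(S)", "hun", 24),
    ("hydHU", "hyd", 50), ("hydPL", "hyd", 50),
    ("macIT", "mac", 50), ("macSP", "mac", 50),
    ("ortCZ", "ort", 50), ("ortFI1", "ort", 25), ("ortFI2", "ort", 50),
    ("triHU", "tri", 41), ("triPL1", "tri", 50),
)

TAXA: tuple[str, ...] = ("als", "bra", "bro", "cal", "cam", "gus",
                         "hex", "hun", "hyd", "mac", "ort", "tri")


def image_separable_phenotypes(cv: float = 0.03) -> list[SeedPhenotype]:
    """Twelve classes distinct in the scale-normalized image space.

    Standardization rescales every seed crop to 128x128, erasing absolute
    size; classes that differ mainly in length are indistinguishable to
    an image classifier even when trivially separable on measured area.
    This preset therefore spreads the classes on a grid of scale-invariant
    characters — aspect ratio (width/length) x bend angle — with grid
    spacing of at least ~5 within-class standard deviations, so the
    classes are separable for the image route by construction.
    """
    grid = [
        (0.25, 180.0), (0.25, 150.0), (0.25, 120.0), (0.25, 90.0), (0.25, 60.0),
        (0.40, 172.0), (0.40, 147.0), (0.40, 122.0), (0.40, 97.0),
        (0.55, 180.0), (0.55, 158.0), (0.55, 136.0),
    ]
    length = 420.0
    return [
        SeedPhenotype(class_id=k, mean_length=length,
                      mean_width=aspect * length,
                      mean_bend_angle=max(bend, min_bend_angle(length, aspect * length)),
                      pit_density=0.45, pit_radius=4.0, coat_contrast=0.25,
                      within_class_cv=cv)
        for k, (aspect, bend) in enumerate(grid)
    ]


def table1_population_specs(separation: float = 1.0, rng_seed: int = 0,
                            images_per_population: int | None = None,
                            ) -> list[PopulationSpec]:
    """The 28-population / 12-taxon study layout (1299 images total).

    ``images_per_population`` overrides every count with a fixed small
    number for scaled-down runs while keeping the class/population layout.
    """
    library = make_phenotype_library(len(TAXA), separation, rng_seed)
    by_acronym = dict(zip(TAXA, library))
    return [
        PopulationSpec(phenotype=by_acronym[taxon], population_id=pid,
                       n_images=images_per_population or n)
        for pid, taxon, n in TABLE1_POPULATIONS
    ]


# ---------------------------------------------------------------------------
# Direct feature-table sampling
# ---------------------------------------------------------------------------

def sample_feature_table(spec: FeatureDistributionSpec, n_per_class: int,
                         rng_seed: int) -> pd.DataFrame:
    """Draw ``n_per_class`` rows per class from the class-conditional Gaussians."""
    if n_per_class < 2:
        raise ValueError("n_per_class must be >= 2")
    rng = np.random.default_rng(rng_seed)
    frames = []
    for k in range(spec.n_classes):
        x = rng.multivariate_normal(spec.means[k], spec.covs[k],
                                    size=n_per_class, method="svd")
        df = pd.DataFrame(x, columns=list(FEATURE_NAMES))
        df["class_id"] = k
        df["population_id"] = f"synth{k}"
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def feature_spec_from_phenotypes(phenotypes: Iterable[SeedPhenotype],
                                 rel_sd: float = 0.05) -> FeatureDistributionSpec:
    """Gaussian feature model implied by a phenotype library.

    Means come from the capsule closed forms; covariances are diagonal
    with standard deviation ``rel_sd`` of each mean (floored at a small
    absolute value so that zero-pit classes stay non-degenerate).
    """
    means = np.array([phenotype_feature_means(p) for p in phenotypes])
    sds = np.maximum(rel_sd * np.abs(means), 1e-3)
    covs = np.array([np.diag(s**2) for s in sds])
    k = means.shape[0]
    return FeatureDistributionSpec(means=means, covs=covs,
                                   priors=np.full(k, 1.0 / k))


def heteroscedastic_feature_spec(n_classes: int = 12, n_features: int = 6,
                                 elongation: float = 30.0,
                                 rng_seed: int = 0) -> FeatureDistributionSpec:
    """Classes identical in mean but with strongly class-specific covariances.

    Each class covariance is an elongated ellipsoid with a class-specific
    random orientation, so the covariance *orientation* carries the class
    signal: a pooled-covariance (linear) classifier is nearly blind while
    a per-class-covariance (quadratic) classifier separates well.
    """
    rng = np.random.default_rng(rng_seed)
    means = np.zeros((n_classes, n_features))
    covs = np.empty((n_classes, n_features, n_features))
    scales = np.ones(n_features)
    scales[0] = elongation
    for k in range(n_classes):
        q, _ = np.linalg.qr(rng.standard_normal((n_features, n_features)))
        covs[k] = q @ np.diag(scales) @ q.T
    return FeatureDistributionSpec(means=means, covs=covs,
                                   priors=np.full(n_classes, 1.0 / n_classes))


def equal_covariance_feature_spec(n_classes: int = 12, n_features: int = 6,
                                  separation: float = 3.0,
                                  rng_seed: int = 0) -> FeatureDistributionSpec:
    """Classes sharing one covariance, with means spread by ``separation``."""
    rng = np.random.default_rng(rng_seed)
    means = separation * rng.standard_normal((n_classes, n_features))
    a = rng.standard_normal((n_features, n_features))
    cov = a @ a.T / n_features + np.eye(n_features)
    covs = np.repeat(cov[None], n_classes, axis=0)
    return FeatureDistributionSpec(means=means, covs=covs,
                                   priors=np.full(n_classes, 1.0 / n_classes))
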