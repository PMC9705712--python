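"""Deterministic 86-variant augmentation of standardized seed images.

Five fixed families, always emitted in this order:

1. brightness/contrast — 5 variants (four gains + one percentile stretch)
2. unsharp-mask sharpening x flip state — 2 strengths x 3 flips = 6
3. Gaussian blur x flip state — 4 widths x 3 flips = 12
4. rotation in 15-degree steps combined with flips — 61 variants
5. plain horizontal / vertical flips — 2 variants

The 61 rotation variants are 23 pure rotations (15..345 deg), plus the
0..270-deg rotations of the horizontally flipped image (19) and of the
vertically flipped image (19).  The engine is fully deterministic: no
randomness anywhere, so a source image always yields the same 86 outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np
from scipy import ndimage

from .errors import InvalidPlanError, LeakageError
from .preprocess import StandardImage

FLIP_STATES = ("none", "h", "v")


def _default_rotation_entries() -> tuple[tuple[float, str], ...]:
    pure = tuple((float(a), "none") for a in range(15, 360, 15))        # 23
    flipped_h = tuple((float(a), "h") for a in range(0, 285, 15))       # 19
    flipped_v = tuple((float(a), "v") for a in range(0, 285, 15))       # 19
    return pure + flipped_h + flipped_v


@dataclass(frozen=True)
class AugmentationPlan:
    """Exact per-family parameter lists; cardinalities are 5/6/12/61/2."""

    brightness_contrast: tuple = (
        ("gain", 0.8), ("gain", 0.9), ("gain", 1.1), ("gain", 1.2),
        ("stretch", 2.0, 98.0),
    )
    sharpen_strengths: tuple[float, ...] = (0.5, 1.0)
    blur_sigmas: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0)
    rotation_entries: tuple[tuple[float, str], ...] = field(
        default_factory=_default_rotation_entries)
    flip_axes: tuple[str, ...] = ("h", "v")

    def validate(self) -> None:
        families = {
            "brightness_contrast": (self.brightness_contrast, 5),
            "sharpen": (tuple((s, f) for s in self.sharpen_strengths
                              for f in FLIP_STATES), 6),
            "blur": (tuple((s, f) for s in self.blur_sigmas
                           for f in FLIP_STATES), 12),
            "rotation": (self.rotation_entries, 61),
            "flip": (self.flip_axes, 2),
        }
        for name, (entries, expected) in families.items():
            if len(entries) != expected:
                raise InvalidPlanError(
                    f"family '{name}' has {len(entries)} entries, expected {expected}")
            if len(set(entries)) != len(entries):
                raise InvalidPlanError(f"family '{name}' has duplicate entries")

    @property
    def n_variants(self) -> int:
        return (len(self.brightness_contrast)
                + 3 * len(self.sharpen_strengths)
                + 3 * len(self.blur_sigmas)
                + len(self.rotation_entries)
                + len(self.flip_axes))


DEFAULT_PLAN = AugmentationPlan()


def _flip(arr: np.ndarray, state: str) -> np.ndarray:
    if state == "none":
        return arr
    if state == "h":
        return arr[:, ::-1]
    if state == "v":
        return arr[::-1, :]
    raise ValueError(f"unknown flip state {state!r}")


def _derived(img: StandardImage, pixels: np.ndarray) -> StandardImage:
    out = np.clip(pixels, 0.0, 1.0).astype(np.float32)
    return replace(img, pixels=out)


def _check_trainable(img: StandardImage) -> None:
    if img.partition == "test":
        raise LeakageError("refusing to augment a test-partition image")


def brightness_contrast_variants(img: StandardImage,
                                 plan: AugmentationPlan = DEFAULT_PLAN,
                                 ) -> list[StandardImage]:
    """Five photometric variants: gain rescalings and a percentile stretch."""
    _check_trainable(img)
    x = img.pixels.astype(float)
    out = []
    for entry in plan.brightness_contrast:
        kind = entry[0]
        if kind == "gain":
            y = entry[1] * x
        elif kind == "offset":
            y = x + entry[1]
        elif kind == "stretch":
            lo, hi = np.percentile(x, [entry[1], entry[2]])
            y = (x - lo) / (hi - lo) if hi > lo else x
        else:
            raise InvalidPlanError(f"unknown brightness entry {entry!r}")
        out.append(_derived(img, y))
    return out


def _unsharp(x: np.ndarray, strength: float, sigma: float = 1.0) -> np.ndarray:
    return x + strength * (x - ndimage.gaussian_filter(x, sigma, mode="reflect"))


def sharpen_variants(img: StandardImage,
                     plan: AugmentationPlan = DEFAULT_PLAN) -> list[StandardImage]:
    """Unsharp masking at each strength, in all three flip states."""
    _check_trainable(img)
    x = img.pixels.astype(float)
    return [
        _derived(img, _flip(_unsharp(x, s), f))
        for s in plan.sharpen_strengths for f in FLIP_STATES
    ]


def blur_variants(img: StandardImage,
                  plan: AugmentationPlan = DEFAULT_PLAN) -> list[StandardImage]:
    """Gaussian blur at each width, in all three flip states."""
    _check_trainable(img)
    x = img.pixels.astype(float)
    return [
        _derived(img, _flip(ndimage.gaussian_filter(x, s, mode="reflect"), f))
        for s in plan.blur_sigmas for f in FLIP_STATES
    ]


def _border_median(x: np.ndarray) -> float:
    return float(np.median(np.concatenate(
        [x[0, :], x[-1, :], x[1:-1, 0], x[1:-1, -1]])))


def rotate_image(x: np.ndarray, angle_deg: float) -> np.ndarray:
    """Bilinear rotation about the image center, border-median fill."""
    if angle_deg % 360 == 0:
        return x.copy()
    return ndimage.rotate(x, angle_deg, reshape=False, order=1,
                          mode="constant", cval=_border_median(x),
                          prefilter=False)


def rotation_variants(img: StandardImage,
                      plan: AugmentationPlan = DEFAULT_PLAN) -> list[StandardImage]:
    """The 61 rotation/flip combinations of the plan."""
    _check_trainable(img)
    x = img.pixels.astype(float)
    flipped = {f: _flip(x, f) for f in FLIP_STATES}
    return [
        _derived(img, rotate_image(np.ascontiguousarray(flipped[f]), angle))
        for angle, f in plan.rotation_entries
    ]


def flip_variants(img: StandardImage,
                  plan: AugmentationPlan = DEFAULT_PLAN) -> list[StandardImage]:
    """Horizontal and vertical mirror images."""
    _check_trainable(img)
    x = img.pixels.astype(float)
    return [_derived(img, _flip(x, f)) for f in plan.flip_axes]


def augment_image(img: StandardImage,
                  plan: AugmentationPlan = DEFAULT_PLAN) -> list[StandardImage]:
    """All 86 variants in fixed family order; deterministic."""
    plan.validate()
    variants = (
        brightness_contrast_variants(img, plan)
        + sharpen_variants(img, plan)
        + blur_variants(img, plan)
        + rotation_variants(img, plan)
        + flip_variants(img, plan)
    )
    return variants


def iter_augmented(images: Iterable[StandardImage],
                   plan: AugmentationPlan = DEFAULT_PLAN,
                   ) -> Iterator[StandardImage]:
    """Lazily yield every variant of every image (memory-safe)."""
    plan.validate()
    for img in images:
        yield from augment_image(img, plan)


def augment_dataset(images: Sequence[StandardImage],
                    plan: AugmentationPlan = DEFAULT_PLAN,
                    ) -> list[StandardImage]:
    """Materialized augmentation of a (small) image set."""
    return list(iter_augmented(images, plan))


def dihedral_rotations(pixels: np.ndarray, labels: np.ndarray,
                       flips: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Exact quarter-turn (optionally also mirrored) copies of an image stack.

    A cheap, interpolation-free subset of the rotation/flip families used
    by desk-scale CNN training to teach orientation invariance: the
    identity plus 90/180/270-degree rotations (8 variants with ``flips``).
    ``pixels`` has shape (N, H, W); labels are repeated accordingly.
    """
    bases = [pixels, pixels[:, :, ::-1]] if flips else [pixels]
    out_x, out_y = [], []
    for base in bases:
        for k in range(4):
            out_x.append(np.rot90(base, k, axes=(1, 2)))
            out_y.append(labels)
    return np.ascontiguousarray(np.concatenate(out_x)), np.concatenate(out_y)
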