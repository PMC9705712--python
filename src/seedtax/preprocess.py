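"""Raw frame -> standardized 128x128 classifier input, or a reasoned exclusion.

The stages mirror a classical single-object microscopy pipeline:

1. global automatic thresholding (Otsu) with polarity resolved by the
   majority border label, plus a light morphological opening;
2. a contact check — frames where the seed touches other objects are
   excluded rather than split;
3. mask cleaning: metadata-bar region and small components removed, the
   single most prominent component kept;
4. bounding-box crop expanded by a margin and padded to a square;
5. bilinear rescale to 128x128 with gray values mapped to [0, 1].

Coordinates are 0-based, row-major, origin top-left; boxes are half-open
``[r0, r1) x [c0, c1)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy import ndimage
from skimage import filters, transform

from .errors import NoForegroundError

STANDARD_SIZE = 128

_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass
class ForegroundMask:
    """Binary foreground mask with lazy connected-component bookkeeping."""

    mask: np.ndarray  # bool, same geometry as the source image

    def __post_init__(self):
        self.mask = np.asarray(self.mask).astype(bool)
        self._labels = None
        self._sizes = None

    def _label(self):
        if self._labels is None:
            labels, n = ndimage.label(self.mask, structure=_EIGHT)
            self._labels = labels
            self._sizes = ndimage.sum_labels(
                np.ones_like(labels), labels, index=np.arange(1, n + 1)
            ).astype(int)
        return self._labels, self._sizes

    @property
    def component_labels(self) -> np.ndarray:
        return self._label()[0]

    @property
    def component_sizes(self) -> np.ndarray:
        return self._label()[1]

    @property
    def n_components(self) -> int:
        return len(self.component_sizes)


@dataclass
class StandardImage:
    """128x128 grayscale classifier input, values in [0, 1]."""

    pixels: np.ndarray
    source: str | None = None
    bbox: tuple[int, int, int, int] | None = None  # r0, c0, r1, c1
    class_id: int | None = None
    population_id: str | None = None
    partition: str | None = None  # "train" / "test" / None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.shape != (STANDARD_SIZE, STANDARD_SIZE):
            raise ValueError("StandardImage must be 128x128")
        if self.pixels.min() < -1e-6 or self.pixels.max() > 1 + 1e-6:
            raise ValueError("StandardImage values must lie in [0, 1]")


@dataclass
class Excluded:
    """Marker for a frame dropped by the pipeline, with the reason."""

    reason: str
    source: str | None = None
    class_id: int | None = None
    population_id: str | None = None


def _largest_component(labels: np.ndarray, sizes: np.ndarray) -> int:
    """1-based label of the most prominent component.

    Tie-break: larger area first, then the component whose centroid comes
    first in row-major order.
    """
    order = np.flatnonzero(sizes == sizes.max()) + 1
    if len(order) == 1:
        return int(order[0])
    centroids = ndimage.center_of_mass(np.ones(labels.shape), labels, index=order)
    ranked = sorted(zip(centroids, order))
    return int(ranked[0][1])


def segment_foreground(image) -> ForegroundMask:
    """Automatic global threshold + opening; polarity-invariant.

    The thresholded side holding the majority of border pixels is taken as
    background, so bright-on-dark and dark-on-bright images segment
    identically.
    """
    img = np.asarray(image)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("image must be a nonempty 2-D grayscale array")
    if img.min() == img.max():
        raise NoForegroundError("constant image has no foreground")
    t = filters.threshold_otsu(img)
    high = img > t
    border = np.concatenate([high[0, :], high[-1, :], high[1:-1, 0], high[1:-1, -1]])
    background_is_high = border.mean() > 0.5
    fg = ~high if background_is_high else high
    fg = ndimage.binary_opening(fg, structure=_EIGHT)
    if not fg.any():
        raise NoForegroundError("no foreground after thresholding")
    return ForegroundMask(fg)


def clean_mask(fm: ForegroundMask, min_area_frac: float = 0.05,
               metadata_bar_height: int = 0,
               metadata_bar_edge: str = "bottom") -> ForegroundMask:
    """Keep exactly the most prominent component.

    Components intersecting the metadata-bar strip are removed first, then
    components smaller than ``min_area_frac`` times the largest survivor,
    then everything but the single most prominent component.
    """
    labels, sizes = fm.component_labels, fm.component_sizes
    if len(sizes) == 0:
        raise NoForegroundError("empty mask")
    keep = np.ones(len(sizes), dtype=bool)
    if metadata_bar_height > 0:
        h = labels.shape[0]
        if metadata_bar_edge == "bottom":
            strip = labels[h - metadata_bar_height:, :]
        elif metadata_bar_edge == "top":
            strip = labels[:metadata_bar_height, :]
        else:
            raise ValueError("metadata_bar_edge must be 'top' or 'bottom'")
        in_bar = np.unique(strip[strip > 0])
        keep[in_bar - 1] = False
    if not keep.any():
        raise NoForegroundError("mask empty after metadata-bar removal")
    largest = sizes[keep].max()
    keep &= sizes >= min_area_frac * largest
    masked_sizes = np.where(keep, sizes, 0)
    winner = _largest_component(labels, masked_sizes)
    return ForegroundMask(labels == winner)


def check_separable(raw_mask: ForegroundMask) -> bool:
    """True when the main object does not contact any other component.

    Contact means the largest pre-cleaning component becomes 8-connected
    to another component after one dilation step.
    """
    labels, sizes = raw_mask.component_labels, raw_mask.component_sizes
    if len(sizes) <= 1:
        return len(sizes) == 1
    main = _largest_component(labels, sizes)
    dilated = ndimage.binary_dilation(labels == main, structure=_EIGHT)
    merged, _ = ndimage.label(dilated | raw_mask.mask, structure=_EIGHT)
    main_label = np.unique(merged[labels == main])
    other = (labels > 0) & (labels != main)
    return not np.isin(merged[other], main_label).any()


def crop_pad_square(image, fm: ForegroundMask, margin: int = 4,
                    ) -> tuple[np.ndarray, tuple[int, int, int, int]]:
    """Crop to the mask bounding box + margin and pad to a centered square.

    Padding uses the median border gray of the source image.  Returns the
    square array and the half-open source box ``(r0, c0, r1, c1)`` used.
    """
    img = np.asarray(image)
    mask = fm.mask
    if not mask.any():
        raise NoForegroundError("empty mask")
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    r0, r1 = int(rows[0]), int(rows[-1]) + 1
    c0, c1 = int(cols[0]), int(cols[-1]) + 1
    box_h, box_w = r1 - r0, c1 - c0
    side = max(box_h, box_w) + 2 * margin
    fill = float(np.median(np.concatenate(
        [img[0, :], img[-1, :], img[1:-1, 0], img[1:-1, -1]])))
    out = np.full((side, side), fill, dtype=float)
    # source region including margin, clipped to the frame
    sr0, sr1 = max(r0 - margin, 0), min(r1 + margin, img.shape[0])
    sc0, sc1 = max(c0 - margin, 0), min(c1 + margin, img.shape[1])
    # destination offset keeping the bbox centered in the square
    dr = (side - box_h) // 2 - (r0 - sr0)
    dc = (side - box_w) // 2 - (c0 - sc0)
    out[dr: dr + (sr1 - sr0), dc: dc + (sc1 - sc0)] = img[sr0:sr1, sc0:sc1]
    return out, (r0, c0, r1, c1)


def standardize(square, source: str | None = None,
                bbox: tuple[int, int, int, int] | None = None) -> StandardImage:
    """Bilinear rescale to 128x128 and map 8-bit grays to [0, 1]."""
    arr = np.asarray(square, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("standardize expects a square grayscale array")
    resized = transform.resize(arr, (STANDARD_SIZE, STANDARD_SIZE), order=1,
                               mode="edge", anti_aliasing=False,
                               preserve_range=True)
    pixels = np.clip(resized / 255.0, 0.0, 1.0)
    return StandardImage(pixels=pixels, source=source, bbox=bbox)


def preprocess_image(image, *, min_area_frac: float = 0.05, margin: int = 4,
                     metadata_bar_height: int = 60,
                     metadata_bar_edge: str = "bottom",
                     source: str | None = None,
                     ) -> StandardImage | Excluded:
    """Full pipeline: segment -> contact check -> clean -> crop/pad -> scale."""
    try:
        raw = segment_foreground(image)
    except NoForegroundError as err:
        return Excluded(reason=f"no-foreground: {err}", source=source)
    if not check_separable(raw):
        return Excluded(reason="contact", source=source)
    try:
        cleaned = clean_mask(raw, min_area_frac=min_area_frac,
                             metadata_bar_height=metadata_bar_height,
                             metadata_bar_edge=metadata_bar_edge)
    except NoForegroundError as err:
        return Excluded(reason=f"no-foreground: {err}", source=source)
    square, bbox = crop_pad_square(image, cleaned, margin=margin)
    return standardize(square, source=source, bbox=bbox)


def preprocess_dataset(images: Iterable, **kwargs
                       ) -> tuple[list[StandardImage], list[Excluded]]:
    """Preprocess synthetic frames, carrying labels; excluded frames split out."""
    kept: list[StandardImage] = []
    dropped: list[Excluded] = []
    for im in images:
        result = preprocess_image(im.pixels, source=str(im.seed_value), **kwargs)
        if isinstance(result, Excluded):
            result.class_id = im.class_id
            result.population_id = im.population_id
            dropped.append(result)
        else:
            result.class_id = im.class_id
            result.population_id = im.population_id
            kept.append(result)
    return kept, dropped
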