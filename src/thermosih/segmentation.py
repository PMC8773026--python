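"""Animal detection and body/tail splitting on thermal frames.

Detection thresholds the temperature histogram by the Otsu criterion: the
animal is warmer than the arena floor, so maximizing between-class variance
separates the two pixel populations without any user-set temperature level.
Because the tail sits only a few degrees above background, a pure Otsu cut
tends to amputate it; the detected blob is therefore grown to a rescue level
``threshold - margin_delta`` restricted to pixels 8-connected to the blob.

The body/tail split comes in two modes: an automatic morphological mode
(opening removes thin appendages; elongated residue components become the
tail) and a coarse-ROI mode where the user supplies a rectangle containing
the tail and excluding the body.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
from skimage import measure as skmeasure
from skimage import morphology as skmorph

from thermosih.thermal_io import ThermalFrame

BACKGROUND = 0
BODY = 1
TAIL = 2

_FOOT8 = np.ones((3, 3), dtype=bool)  # 8-neighbour connectivity footprint


class SegmentationError(ValueError):
    """Raised when a frame cannot be segmented under the stated contract."""


class NoAnimalError(SegmentationError):
    """No connected warm component of sufficient size was found."""


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable parameters of the detection and splitting stages.

    margin_delta is the tail-rescue margin below the Otsu threshold, in degC.
    The automatic threshold settles between the tail and body temperature
    clusters, so the margin must span the tail-to-threshold gap while staying
    above the arena background; 4.0 degC does both for typical mouse scenes
    (body ~29, tail ~24, floor ~20 degC).
    """

    bin_width: float = 0.1
    margin_delta: float = 4.0
    opening_radius_px: int = 3
    min_tail_elongation: float = 4.0
    min_animal_px: int = 50
    max_animal_frac: float = 0.25

    def __post_init__(self) -> None:
        if self.bin_width <= 0 or self.margin_delta <= 0:
            raise ValueError("bin_width and margin_delta must be positive")
        if self.margin_delta >= 10:
            raise ValueError("margin_delta must be < 10 degC")
        if self.opening_radius_px < 1 or self.min_animal_px < 1:
            raise ValueError("opening_radius_px and min_animal_px must be >= 1")
        if self.min_tail_elongation <= 0:
            raise ValueError("min_tail_elongation must be positive")
        if not 0.0 < self.max_animal_frac <= 1.0:
            raise ValueError("max_animal_frac must be in (0, 1]")


@dataclass
class RegionMask:
    """Per-pixel labels over {background, body, tail} for one frame."""

    labels: np.ndarray
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2-D grid")
        if not np.isin(self.labels, (BACKGROUND, BODY, TAIL)).all():
            raise ValueError("labels must be in {0 background, 1 body, 2 tail}")
        self.labels = self.labels.astype(np.uint8)

    @property
    def body(self) -> np.ndarray:
        return self.labels == BODY

    @property
    def tail(self) -> np.ndarray:
        return self.labels == TAIL

    @property
    def animal(self) -> np.ndarray:
        return self.labels != BACKGROUND

    @property
    def animal_pixel_count(self) -> int:
        return int(np.count_nonzero(self.labels))


@dataclass(frozen=True)
class QCResult:
    """Frame-level usability decision with machine-readable reasons."""

    usable: bool
    reasons: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.usable != (len(self.reasons) == 0):
            raise ValueError("usable must hold exactly when no reasons are present")


def otsu_threshold(temperatures: Iterable[float] | np.ndarray, bin_width: float = 0.1) -> float:
    """Otsu threshold of a temperature sample on a fixed-width histogram.

    Bins are anchored on the sample minimum (bin centres at
    ``min + k*bin_width``), which makes the threshold equivariant under
    adding a constant to every value.  The returned level is the histogram
    bin edge maximizing the between-class variance
    ``sigma_b^2 = w0*w1*(mu0 - mu1)^2``; when several consecutive edges tie
    (the histogram has an empty gap), the midpoint of the tied run is
    returned.

    Raises :class:`SegmentationError` if fewer than two bins are occupied
    (e.g. a constant frame), since no two-class split exists.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    t = np.asarray(temperatures, dtype=float).ravel()
    if t.size < 2:
        raise SegmentationError("need at least two temperature samples")
    lo = float(t.min())
    span = float(t.max()) - lo
    nbins = int(np.ceil((span + bin_width / 2) / bin_width))
    nbins = max(nbins, 1)
    edges = lo - bin_width / 2 + bin_width * np.arange(nbins + 1)
    counts, _ = np.histogram(t, bins=edges)
    if np.count_nonzero(counts) < 2:
        raise SegmentationError("constant input: fewer than two occupied bins, no threshold exists")
    centers = (edges[:-1] + edges[1:]) / 2
    p = counts / counts.sum()
    w0 = np.cumsum(p)[:-1]               # class 0 = bins below split k (k = 1..nbins-1)
    w1 = 1.0 - w0
    m = np.cumsum(p * centers)
    mu_t = m[-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = m[:-1] / w0
        mu1 = (mu_t - m[:-1]) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b = np.where(np.isfinite(sigma_b), sigma_b, -np.inf)
    best = int(np.argmax(sigma_b))
    tol = 1e-9 * max(abs(sigma_b[best]), 1.0)
    tied = sigma_b >= sigma_b[best] - tol
    first = best
    while first > 0 and tied[first - 1]:
        first -= 1
    last = best
    while last < tied.size - 1 and tied[last + 1]:
        last += 1
    # split index k corresponds to edge edges[k + 1]... careful: split after
    # bin k uses edge edges[k + 1]; sigma_b[k] is the split between bins
    # 0..k and k+1.., i.e. at edge index k + 1.
    return float((edges[first + 1] + edges[last + 1]) / 2)


def _largest_component(mask: np.ndarray, min_size: int = 1) -> Optional[np.ndarray]:
    lab = skmeasure.label(mask, connectivity=2)
    if lab.max() == 0:
        return None
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    if sizes.max() < min_size:
        return None
    return lab == int(np.argmax(sizes))


def segment_animal(frame: ThermalFrame, params: SegmentationParams = SegmentationParams()) -> RegionMask:
    """Detect the animal: Otsu seed, largest component, tail rescue.

    The seed mask contains pixels at or above the Otsu threshold; the animal
    is the largest 8-connected seed component grown (by geodesic dilation) to
    every pixel at or above ``threshold - margin_delta`` that is 8-connected
    to it.  All animal pixels are labelled body; splitting into body and tail
    is a separate step.
    """
    thr = otsu_threshold(frame.pixels, params.bin_width)
    seed = frame.pixels >= thr
    core = _largest_component(seed, params.min_animal_px)
    if core is None:
        raise NoAnimalError(
            f"no warm component of at least {params.min_animal_px} px above {thr:.2f} degC"
        )
    rescue = frame.pixels >= thr - params.margin_delta
    grown = skmorph.reconstruction(
        core.astype(np.uint8), rescue.astype(np.uint8), method="dilation", footprint=_FOOT8
    ).astype(bool)
    if grown.sum() > params.max_animal_frac * grown.size:
        # On tri-modal scenes the Otsu argmax sometimes settles in the
        # background/tail gap; the whole animal is then already in the seed
        # and the rescue margin dips into the arena background.  A rescue
        # that floods an implausible share of the frame is abandoned.
        grown = core
    labels = np.zeros(frame.pixels.shape, dtype=np.uint8)
    labels[grown] = BODY
    return RegionMask(labels)


def _elongation(component: np.ndarray) -> float:
    """Skeleton-based elongation: skeleton length over mean width.

    With mean width estimated as area / skeleton length this reduces to
    ``len(skeleton)^2 / area``; compact blobs score near zero, tails score
    well above the default gate.
    """
    area = int(np.count_nonzero(component))
    if area == 0:
        return 0.0
    skel_len = int(np.count_nonzero(skmorph.skeletonize(component)))
    return skel_len * skel_len / area


def split_body_tail_auto(
    mask: RegionMask,
    frame: ThermalFrame,
    params: SegmentationParams = SegmentationParams(),
) -> RegionMask:
    """Split the detected animal into body and tail morphologically.

    Opening with a disc of ``opening_radius_px`` removes structures thinner
    than the disc; the largest surviving component is the body core.  Among
    the residue components (animal minus body core) the largest one whose
    skeleton elongation reaches ``min_tail_elongation`` becomes the tail;
    all other residue pixels (boundary shavings from the opening) are merged
    back into the body.  Absence of a tail is a flagged, non-fatal outcome.
    """
    animal = mask.animal
    if not animal.any():
        raise SegmentationError("mask contains no animal")
    opened = skmorph.opening(animal, footprint=skmorph.disk(params.opening_radius_px))
    core = _largest_component(opened)
    flags: set[str] = set()
    tail = np.zeros_like(animal)
    if core is None:
        # Whole animal thinner than the disc: treat everything as body.
        flags.add("no_tail")
    else:
        residue = animal & ~core
        rlab = skmeasure.label(residue, connectivity=2)
        best_area = 0
        best_id = 0
        for rid in range(1, rlab.max() + 1):
            comp = rlab == rid
            area = int(np.count_nonzero(comp))
            if area <= best_area:
                continue
            if _elongation(comp) >= params.min_tail_elongation:
                best_area = area
                best_id = rid
        if best_id:
            tail = rlab == best_id
        else:
            flags.add("no_tail")
    labels = np.zeros_like(mask.labels)
    labels[animal] = BODY
    labels[tail] = TAIL
    return RegionMask(labels, flags=frozenset(flags))


def split_body_tail_roi(
    mask: RegionMask,
    frame: ThermalFrame,
    tail_box: tuple[int, int, int, int],
) -> RegionMask:
    """Split body/tail from a coarse user rectangle containing the tail.

    ``tail_box`` is ``(row, col, height, width)`` in 0-based pixel
    coordinates.  Animal pixels inside the box become tail, the rest body.
    The box must lie within the frame and must exclude at least part of the
    body; a box containing no animal pixels yields an empty, flagged tail.
    """
    r, c, h, w = tail_box
    H, W = mask.labels.shape
    if r < 0 or c < 0 or h < 1 or w < 1 or r + h > H or c + w > W:
        raise SegmentationError(f"tail_box {tail_box} outside frame bounds {H}x{W}")
    animal = mask.animal
    if not animal.any():
        raise SegmentationError("mask contains no animal")
    inbox = np.zeros((H, W), dtype=bool)
    inbox[r : r + h, c : c + w] = True
    tail = animal & inbox
    body = animal & ~inbox
    flags: set[str] = set()
    if not body.any():
        raise SegmentationError("tail_box covers the whole animal; it must exclude the body")
    if not tail.any():
        flags.add("empty_tail")
    labels = np.zeros((H, W), dtype=np.uint8)
    labels[body] = BODY
    labels[tail] = TAIL
    return RegionMask(labels, flags=frozenset(flags))


def qc_frame(
    mask: RegionMask,
    session_median_area: float,
    require_tail: bool = True,
    area_bounds: tuple[float, float] = (0.5, 1.5),
) -> QCResult:
    """Rule-based usability check standing in for 'full body visible'.

    A frame is usable when the animal does not touch the frame border, its
    area lies within ``area_bounds`` times the session median (rearing or
    partially hidden animals project a much smaller blob), and a tail was
    found whenever the analysis needs one.
    """
    reasons: set[str] = set()
    animal = mask.animal
    if not animal.any():
        reasons.add("no_animal")
    else:
        if animal[0, :].any() or animal[-1, :].any() or animal[:, 0].any() or animal[:, -1].any():
            reasons.add("touches_border")
        area = mask.animal_pixel_count
        lo, hi = area_bounds
        if not lo * session_median_area <= area <= hi * session_median_area:
            reasons.add("area_out_of_range")
        if require_tail and not mask.tail.any():
            reasons.add("no_tail_when_required")
    return QCResult(usable=not reasons, reasons=frozenset(reasons))


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap of two boolean masks (1.0 when both are empty)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.count_nonzero(a & b) / denom


def write_mask_image(mask: RegionMask, path) -> None:
    """Export labels as an 8-bit image (0 background, 1 body, 2 tail)."""
    import imageio.v3 as iio

    iio.imwrite(path, mask.labels)
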