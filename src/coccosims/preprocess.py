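"""Plane alignment, accumulation, and ROI segmentation.

Alignment registers blocks of consecutive planes on the 44Ca channel with
integer pixel shifts (single planes are too sparse at the count rates of
coccolith work for per-plane registration, and integer shifts keep counts
integral).  Segmentation classifies the accumulated field of view into
coccolith, contaminant, and background regions; it automates what is
traditionally drawn by hand, and externally supplied ROI maps are accepted
everywhere a :class:`~coccosims.stack_io.RoiMap` is consumed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

from .stack_io import CA_MASS, ELEMENT_TO_MASS, IonImageStack, RoiMap


class AlignmentError(Exception):
    pass


@dataclass
class AlignmentTrace:
    """Integer (dy, dx) offset applied to each plane, plus the crop window."""

    offsets: np.ndarray  # (P, 2) int
    reference_block: int
    crop: tuple[int, int, int, int]  # (row0, row1, col0, col1), half-open

    def block_offsets(self, block_size: int) -> np.ndarray:
        return self.offsets[::block_size]


def _shift2d(img: np.ndarray, dy: int, dx: int) -> np.ndarray:
    """Shift an image by integer offsets, zero-filling uncovered pixels."""
    out = np.zeros_like(img)
    h, w = img.shape
    ys = slice(max(dy, 0), h + min(dy, 0))
    xs = slice(max(dx, 0), w + min(dx, 0))
    ysrc = slice(max(-dy, 0), h + min(-dy, 0))
    xsrc = slice(max(-dx, 0), w + min(-dx, 0))
    out[ys, xs] = img[ysrc, xsrc]
    return out


def _best_shift(ref: np.ndarray, img: np.ndarray, max_shift: int) -> tuple[int, int]:
    """Integer shift of ``img`` maximising its cross-correlation with ``ref``."""
    best = (0, 0)
    best_score = -np.inf
    for dy in range(-max_shift, max_shift + 1):
        for dx in range(-max_shift, max_shift + 1):
            score = float(np.sum(ref * _shift2d(img, dy, dx)))
            # deterministic tie-break: prefer the smaller shift
            if score > best_score or (
                score == best_score and (abs(dy) + abs(dx)) < (abs(best[0]) + abs(best[1]))
            ):
                best_score = score
                best = (dy, dx)
    return best


def align_stack(
    stack: IonImageStack,
    max_shift_px: int = 4,
    block_size_planes: int = 50,
) -> tuple[IonImageStack, AlignmentTrace]:
    """Register plane blocks on 44Ca and apply the shifts to every mass.

    Shifts are estimated per block of ``block_size_planes`` planes by
    maximising the cross-correlation of the block's accumulated 44Ca image
    against the running accumulated reference; the same integer shift is
    applied to all masses of that block.  The output is cropped to the window
    valid under every applied shift.
    """
    if max_shift_px < 0:
        raise ValueError("max_shift_px must be >= 0")
    if block_size_planes < 1:
        raise ValueError("block_size_planes must be >= 1")
    ca = stack.counts[CA_MASS]
    p, h, w = ca.shape
    offsets = np.zeros((p, 2), dtype=int)
    if max_shift_px > 0:
        if ca.sum() == 0:
            raise AlignmentError(
                "44Ca image is all zero; alignment is undefined "
                "(bypass with max_shift_px=0)"
            )
        starts = list(range(0, p, block_size_planes))
        ref = ca[0:block_size_planes].sum(axis=0).astype(np.float64)
        for s in starts[1:]:
            block = ca[s : s + block_size_planes].sum(axis=0).astype(np.float64)
            dy, dx = _best_shift(ref, block, max_shift_px)
            offsets[s : s + block_size_planes] = (dy, dx)
            ref += _shift2d(block, dy, dx)

    aligned: dict[str, np.ndarray] = {}
    for mass, arr in stack.counts.items():
        out = np.empty_like(arr)
        for i in range(p):
            dy, dx = offsets[i]
            out[i] = arr[i] if (dy == 0 and dx == 0) else _shift2d(arr[i], dy, dx)
        aligned[mass] = out

    r0 = int(max(0, offsets[:, 0].max()))
    r1 = int(h + min(0, offsets[:, 0].min()))
    c0 = int(max(0, offsets[:, 1].max()))
    c1 = int(w + min(0, offsets[:, 1].min()))
    if r0 >= r1 or c0 >= c1:
        raise AlignmentError("crop window empty: shifts exceed the frame")
    aligned = {m: a[:, r0:r1, c0:c1] for m, a in aligned.items()}
    trace = AlignmentTrace(offsets=offsets, reference_block=0, crop=(r0, r1, c0, c1))
    return IonImageStack(aligned, meta=stack.meta), trace


def accumulate(
    stack: IonImageStack, plane_range: tuple[int, int] | None = None
) -> dict[str, np.ndarray]:
    """Elementwise sum over a half-open plane range (full depth by default)."""
    p = stack.planes
    lo, hi = (0, p) if plane_range is None else plane_range
    if not (0 <= lo < hi <= p):
        raise ValueError(f"plane range ({lo}, {hi}) outside [0, {p})")
    return {m: arr[lo:hi].sum(axis=0, dtype=np.int64) for m, arr in stack.counts.items()}


#: Elements that participate in the contaminant enrichment test.  Sr is
#: excluded deliberately: contaminant particles are enriched in Na/Mg/K/Ba but
#: never in Sr, so Sr enrichment alone must not create a contaminant ROI.
CONTAMINANT_TEST_ELEMENTS = ("Na", "Mg", "K", "Ba")


def segment(
    accumulated: dict[str, np.ndarray],
    ca_quantile: float | None = None,
    enrichment_factor: float = 3.0,
    min_area_px: int = 20,
    contaminant_min_area_px: int = 5,
    contaminant_min_counts: float = 5.0,
) -> RoiMap:
    """Partition the accumulated field of view into classed ROIs.

    Coccolith ROIs are connected components of bright-44Ca pixels with area
    >= ``min_area_px``.  The brightness threshold defaults to Otsu's method
    on the accumulated 44Ca image (scale-invariant); passing ``ca_quantile``
    switches to the quantile-of-nonzero-Ca-pixels rule instead.

    Contaminant ROIs are connected components where the 3x3-mean-smoothed
    accumulated El/Ca count ratio of any of Na, Mg, K or Ba (when measured)
    exceeds ``enrichment_factor`` times the median ratio over coccolith
    pixels; pixels qualifying for both classes are classed contaminant
    (the conservative choice where a particle overlaps a coccolith).
    ``contaminant_min_counts`` guards the ratio test against meaningless
    low-count ratios on the bare filter.

    When no coccolith is found the result is an empty map with ``warning``
    set, not an exception.
    """
    ca = np.asarray(accumulated[CA_MASS], dtype=np.float64)
    if enrichment_factor <= 1:
        raise ValueError("enrichment_factor must be > 1")
    if ca_quantile is not None and not (0.0 < ca_quantile < 1.0):
        raise ValueError("ca_quantile must be in (0, 1)")

    nonzero = ca[ca > 0]
    if nonzero.size == 0:
        return RoiMap(np.zeros(ca.shape, dtype=np.int32), {},
                      warning="no 44Ca signal; empty ROI map")
    if ca_quantile is not None:
        thr = float(np.quantile(nonzero, ca_quantile))
    else:
        thr = float(threshold_otsu(ca))
    bright = ca >= max(thr, 1.0)

    # contrast guard: a structureless (noise-only) field also yields a
    # threshold split, but its "foreground" is barely brighter than the
    # typical pixel, while coccoliths are orders of magnitude brighter than
    # the filter (assumed to dominate the raster; the median estimates it)
    if not bright.any() or ca[bright].mean() < 5.0 * max(float(np.median(ca)), 1.0):
        return RoiMap(np.zeros(ca.shape, dtype=np.int32), {},
                      warning="no coccolith-like contrast in 44Ca; empty ROI map")

    cocco_cc = cc_label(bright, connectivity=2)
    labels = np.zeros(ca.shape, dtype=np.int32)
    next_label = 1
    for lab in range(1, cocco_cc.max() + 1):
        comp = cocco_cc == lab
        if comp.sum() >= min_area_px:
            labels[comp] = next_label
            next_label += 1
    cocco_labels = list(range(1, next_label))
    if not cocco_labels:
        return RoiMap(np.zeros(ca.shape, dtype=np.int32), {},
                      warning="no coccolith ROI found")
    cocco_mask = labels > 0

    # contaminant enrichment test on smoothed accumulated counts
    sm_ca = uniform_filter(ca, size=3)
    contaminated = np.zeros(ca.shape, dtype=bool)
    for el in CONTAMINANT_TEST_ELEMENTS:
        mass = ELEMENT_TO_MASS[el]
        if mass not in accumulated:
            continue
        sm_el = uniform_filter(np.asarray(accumulated[mass], dtype=np.float64), size=3)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(sm_ca > 0, sm_el / np.where(sm_ca > 0, sm_ca, 1.0), np.inf)
        ratio[sm_el <= 0] = 0.0
        med = float(np.median(ratio[cocco_mask & np.isfinite(ratio)]))
        if not np.isfinite(med) or med <= 0:
            continue
        contaminated |= (ratio > enrichment_factor * med) & (sm_el >= contaminant_min_counts)

    cont_cc = cc_label(contaminated, connectivity=2)
    classes: dict[int, str] = {l: "coccolith" for l in cocco_labels}
    overlap_flag = False
    for lab in range(1, cont_cc.max() + 1):
        comp = cont_cc == lab
        if comp.sum() < contaminant_min_area_px:
            continue
        if (comp & cocco_mask).any():
            overlap_flag = True
        labels[comp] = next_label  # overlap pixels reassigned: conservative
        classes[next_label] = "contaminant"
        next_label += 1

    # background: everything else, as one labelled region
    bg_mask = labels == 0
    if bg_mask.any():
        labels[bg_mask] = next_label
        classes[next_label] = "background"

    warning = "contaminant overlaps a coccolith ROI; overlap classed contaminant" if overlap_flag else ""
    return RoiMap(labels=labels, classes=classes, warning=warning)
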