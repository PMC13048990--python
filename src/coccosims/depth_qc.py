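"""Depth-profile QC: Poisson-corrected CV and stable-window selection.

Each coccolith ROI yields, per trace element, a depth profile of El/Ca
ion-count ratios evaluated on blocks of consecutive planes (5 by default;
single planes are too sparse).  The observed coefficient of variation of the
block ratios mixes true depth structure (insufficient pre-sputtering, surface
contamination, complete ablation) with the irreducible Poisson counting
noise.  The counting contribution is removed in quadrature:

    CV_P       = sqrt( mean_b( 1/n_el(b) + 1/n_Ca(b) ) )
    CV_corr    = sqrt( max(CV_obs^2 - CV_P^2, 0) )

``CV_P`` is the first-order relative standard deviation of a ratio of two
independent Poisson sums, evaluated at the realised counts.  ``CV_corr`` is
the residual depth variability and is reported as the precision of the
El/Ca measurement.  Quantification then uses the longest contiguous block
window whose residual CV is acceptably small, preferring late (deep) windows
because surface contamination and yield drift concentrate early.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .stack_io import CA_MASS, ELEMENT_TO_MASS, IonImageStack, RoiMap

DEFAULT_BLOCK_SIZE = 5
DEFAULT_CV_TARGET = 0.10
DEFAULT_MIN_FRACTION = 0.5


class DepthQcError(Exception):
    pass


@dataclass
class DepthProfile:
    """Per-depth-block element and Ca counts for one ROI and element."""

    roi_label: int
    element: str
    block_size_planes: int
    n_el: np.ndarray  # per retained block
    n_ca: np.ndarray
    block_index: np.ndarray  # original indices of retained blocks
    n_dropped: int = 0  # blocks dropped for n_Ca == 0

    @property
    def ratios(self) -> np.ndarray:
        return self.n_el / self.n_ca

    @property
    def n_blocks(self) -> int:
        return len(self.n_ca)


@dataclass
class DepthQc:
    """Depth-variability verdict for one profile (or window of it)."""

    cv_obs: float
    cv_poisson: float
    cv_corrected: float
    window: tuple[int, int]  # (first block, last block), inclusive
    flags: set[str] = field(default_factory=set)


def block_counts(counts: np.ndarray, pixel_mask: np.ndarray,
                 block_size: int) -> np.ndarray:
    """Sum counts over masked pixels per depth block -> (n_blocks,) int64.

    A trailing short block is dropped.
    """
    p = counts.shape[0]
    nb = p // block_size
    if nb == 0:
        raise DepthQcError(f"fewer planes ({p}) than one block ({block_size})")
    trimmed = counts[: nb * block_size]
    per_plane = trimmed[:, pixel_mask].sum(axis=1, dtype=np.int64)
    return per_plane.reshape(nb, block_size).sum(axis=1)


def blockwise_pixel_counts(counts: np.ndarray, block_size: int) -> np.ndarray:
    """Per-pixel per-block sums -> (n_blocks, H, W); trailing short block dropped."""
    p, h, w = counts.shape
    nb = p // block_size
    if nb == 0:
        raise DepthQcError(f"fewer planes ({p}) than one block ({block_size})")
    return counts[: nb * block_size].reshape(nb, block_size, h, w).sum(axis=1, dtype=np.int64)


def build_profile(
    stack: IonImageStack,
    roi_map: RoiMap,
    roi_label: int,
    element: str,
    block_size_planes: int = DEFAULT_BLOCK_SIZE,
    gate_min_ca: int = 0,
    exclude_contaminant_pixels: bool = True,
) -> DepthProfile:
    """Depth profile of one element's block counts over a coccolith ROI.

    With ``gate_min_ca`` > 0, each (pixel, block) cell contributes only when
    its 44Ca block count reaches the gate (Ca-gated accumulation); cells are
    ungated otherwise.  Pixels belonging to contaminant ROIs are excluded from
    the pixel set by default.  Blocks whose total Ca count is zero are dropped
    and counted in ``n_dropped``.
    """
    if element == "Ca" or ELEMENT_TO_MASS.get(element) == CA_MASS:
        raise DepthQcError("element must be a trace element, not 44Ca")
    if roi_map.classes.get(roi_label) != "coccolith":
        raise DepthQcError(f"ROI {roi_label} is not a coccolith ROI")
    pixel_mask = roi_map.mask(roi_label)
    if exclude_contaminant_pixels:
        pixel_mask = pixel_mask & ~roi_map.class_mask("contaminant")
    if not pixel_mask.any():
        raise DepthQcError(f"ROI {roi_label} has no usable pixels")

    el_counts = stack.element_counts(element)
    ca_counts = stack.counts[CA_MASS]
    if gate_min_ca > 0:
        ca_blocks = blockwise_pixel_counts(ca_counts, block_size_planes)[:, pixel_mask]
        el_blocks = blockwise_pixel_counts(el_counts, block_size_planes)[:, pixel_mask]
        gate = ca_blocks >= gate_min_ca
        n_el = np.where(gate, el_blocks, 0).sum(axis=1)
        n_ca = np.where(gate, ca_blocks, 0).sum(axis=1)
    else:
        n_el = block_counts(el_counts, pixel_mask, block_size_planes)
        n_ca = block_counts(ca_counts, pixel_mask, block_size_planes)

    if n_ca.sum() == 0:
        raise DepthQcError(f"ROI {roi_label} has zero 44Ca counts")
    keep = n_ca > 0
    return DepthProfile(
        roi_label=roi_label,
        element=element,
        block_size_planes=block_size_planes,
        n_el=n_el[keep],
        n_ca=n_ca[keep],
        block_index=np.nonzero(keep)[0],
        n_dropped=int((~keep).sum()),
    )


def _poisson_relvar(n_el: np.ndarray, n_ca: np.ndarray) -> np.ndarray:
    """Per-block first-order relative variance of the ratio, 1/n_el + 1/n_Ca.

    Blocks with zero element counts contribute 1/max(n_el, 1): the counting
    variance cannot be evaluated at zero, and one count is the resolution
    floor of the measurement.
    """
    return 1.0 / np.maximum(n_el, 1) + 1.0 / n_ca


def poisson_cv(profile: DepthProfile) -> float:
    """Expected CV of the block ratio series from counting statistics alone."""
    if profile.n_blocks < 2:
        raise DepthQcError("need at least 2 retained blocks")
    return float(np.sqrt(np.mean(_poisson_relvar(profile.n_el, profile.n_ca))))


def _window_qc(n_el: np.ndarray, n_ca: np.ndarray, window: tuple[int, int],
               cv_target: float) -> DepthQc:
    r = n_el / n_ca
    mean = r.mean()
    cv_obs = float(r.std(ddof=1) / mean) if mean > 0 else float("inf")
    cv_p = float(np.sqrt(np.mean(_poisson_relvar(n_el, n_ca))))
    cv_corr = float(np.sqrt(max(cv_obs**2 - cv_p**2, 0.0)))
    flags = set()
    if cv_corr > cv_target:
        flags.add("unstable")
    return DepthQc(cv_obs=cv_obs, cv_poisson=cv_p, cv_corrected=cv_corr,
                   window=window, flags=flags)


def corrected_cv(profile: DepthProfile, cv_target: float = DEFAULT_CV_TARGET) -> DepthQc:
    """Observed, Poisson, and residual CV over the whole profile."""
    if profile.n_blocks < 2:
        raise DepthQcError("need at least 2 retained blocks")
    return _window_qc(profile.n_el, profile.n_ca,
                      (0, profile.n_blocks - 1), cv_target)


def select_stable_window(
    profile: DepthProfile,
    cv_target: float = DEFAULT_CV_TARGET,
    min_fraction: float = DEFAULT_MIN_FRACTION,
) -> tuple[tuple[int, int], DepthQc]:
    """Longest contiguous block window with residual CV within target.

    Candidate windows cover at least ``min_fraction`` of the retained blocks.
    Among windows with ``cv_corrected <= cv_target`` the longest wins; ties
    break on (a) larger total Ca counts, then (b) deeper start.  If none
    qualifies the window minimising ``cv_corrected`` is returned with the
    ``unstable`` flag set.  The search is exhaustive over the O(B^2)
    contiguous windows.

    The returned window indexes retained blocks of the profile; convert to
    planes via ``profile.block_index`` and ``block_size_planes``.
    """
    if not (0.0 < min_fraction <= 1.0):
        raise ValueError("min_fraction must be in (0, 1]")
    if profile.n_blocks < 2:
        raise DepthQcError("need at least 2 retained blocks")
    b = profile.n_blocks
    min_len = max(2, int(np.ceil(min_fraction * b)))

    n_el = profile.n_el.astype(np.float64)
    n_ca = profile.n_ca.astype(np.float64)
    r = n_el / n_ca
    q = _poisson_relvar(profile.n_el, profile.n_ca)
    cs_r = np.concatenate([[0.0], np.cumsum(r)])
    cs_r2 = np.concatenate([[0.0], np.cumsum(r * r)])
    cs_q = np.concatenate([[0.0], np.cumsum(q)])
    cs_ca = np.concatenate([[0.0], np.cumsum(n_ca)])

    best_pass = None  # (length, total_ca, start, end, qc-tuple)
    best_fail = None  # (cv_corr, start, end, qc-tuple)
    for s in range(0, b - min_len + 1):
        ends = np.arange(s + min_len - 1, b)
        ns = ends - s + 1.0
        sum_r = cs_r[ends + 1] - cs_r[s]
        sum_r2 = cs_r2[ends + 1] - cs_r2[s]
        mean = sum_r / ns
        var = np.maximum(sum_r2 - ns * mean**2, 0.0) / (ns - 1.0)
        cv_obs = np.sqrt(var) / mean
        cv_p2 = (cs_q[ends + 1] - cs_q[s]) / ns
        cv_corr = np.sqrt(np.maximum(cv_obs**2 - cv_p2, 0.0))
        tot_ca = cs_ca[ends + 1] - cs_ca[s]

        ok = cv_corr <= cv_target
        if ok.any():
            for i in np.nonzero(ok)[0]:
                cand = (int(ns[i]), float(tot_ca[i]), s, int(ends[i]))
                key = (cand[0], cand[1], cand[2])
                if best_pass is None or key > (best_pass[0], best_pass[1], best_pass[2]):
                    best_pass = (cand[0], cand[1], cand[2], cand[3])
        i = int(np.argmin(cv_corr))
        if best_fail is None or cv_corr[i] < best_fail[0]:
            best_fail = (float(cv_corr[i]), s, int(ends[i]))

    if best_pass is not None:
        s, e = best_pass[2], best_pass[3]
        window = (s, e)
        qc = _window_qc(profile.n_el[s : e + 1], profile.n_ca[s : e + 1], window, cv_target)
    else:
        s, e = best_fail[1], best_fail[2]
        window = (s, e)
        qc = _window_qc(profile.n_el[s : e + 1], profile.n_ca[s : e + 1], window, cv_target)
        qc.flags.add("unstable")
    if window[0] > 0 or window[1] < b - 1:
        qc.flags.add("planes_excluded")
    return window, qc
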