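"""Per-coccolith El/Ca quantification.

For each coccolith ROI and trace element the pipeline

1. builds the Ca-gated depth profile and selects the stable block window
   (:mod:`coccosims.depth_qc`),
2. accumulates element and 44Ca counts over that window with Ca-gating:
   a (pixel, 5-plane-block) cell contributes only when at least
   ``gate_min_ca`` 44Ca ions were detected in it, which suppresses
   particle-like contamination sitting on Ca-free material without discarding
   the pixel for all depths,
3. corrects the mass-88 sums for the (44Ca)2+ dimer
   (``corrected = max(raw - delta * n_Ca, 0)``, equivalently
   ``R_Sr_corr = R_Sr_raw - delta`` under the proportional model),
4. converts ion-count ratios to molar ratios via per-element proportional
   calibration slopes fitted on synthetic calcite standards.

K/Ca stays in ion-count units: no calibration standard with known K content
exists.  The 138Ba multimer interference is negligible and not corrected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import depth_qc
from .stack_io import CA_MASS, IonImageStack, RoiMap

#: Relative calibration uncertainty per element (slope accuracy bound).
DEFAULT_REL_UNCERTAINTY = {"Na": 0.20, "Mg": 0.21, "Sr": 0.05, "Ba": 0.04}

#: Ba results whose Poisson relative error exceeds this are flagged low-precision.
BA_POISSON_FLAG_THRESHOLD = 0.25

#: Fraction of excluded depth blocks above which a result is flagged
#: surface-contaminated.
SURFACE_EXCLUSION_FLAG_FRACTION = 0.10


class QuantifyError(Exception):
    pass


# ---------------------------------------------------------------------------
# calibration


def fit_proportional_slope(ion_ratios, molar_ratios, weights: str = "relative") -> float:
    """Through-origin least-squares slope mapping ion ratio -> molar ratio.

    ``weights="relative"`` (default) minimises relative residuals
    (weights 1/y^2), matching the multiplicative error structure of ratio
    data; ``weights="none"`` is ordinary through-origin least squares.
    """
    x = np.asarray(ion_ratios, dtype=float)
    y = np.asarray(molar_ratios, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y) & (x > 0) & (y > 0)
    x, y = x[keep], y[keep]
    if x.size < 2:
        raise QuantifyError("need at least 2 paired calibration points")
    if weights == "relative":
        w = 1.0 / y**2
    elif weights == "none":
        w = np.ones_like(y)
    else:
        raise ValueError(f"unknown weighting {weights!r}")
    return float(np.sum(w * x * y) / np.sum(w * x * x))


@dataclass
class CalibrationRelation:
    """Per-element proportional slope (mmol/mol per unit ion-count ratio).

    ``rel_uncertainty`` is the relative accuracy of each slope; reported
    molar ratios are never more accurate than this.
    """

    slopes: dict[str, float]
    rel_uncertainty: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_REL_UNCERTAINTY))

    def __post_init__(self) -> None:
        for el, a in self.slopes.items():
            if not np.isfinite(a) or a <= 0:
                raise QuantifyError(f"calibration slope for {el} must be > 0")
        for el, u in self.rel_uncertainty.items():
            if u < 0:
                raise QuantifyError(f"relative uncertainty for {el} must be >= 0")

    def has(self, element: str) -> bool:
        return element in self.slopes

    def to_json(self, path: str | Path) -> None:
        payload = {
            el: {"slope": self.slopes[el],
                 "rel_uncertainty": self.rel_uncertainty.get(el, 0.0)}
            for el in self.slopes
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationRelation":
        path = Path(path)
        if not path.exists():
            raise QuantifyError(f"missing calibration file {path}")
        payload = json.loads(path.read_text())
        slopes = {el: float(v["slope"]) for el, v in payload.items()}
        unc = {el: float(v.get("rel_uncertainty", 0.0)) for el, v in payload.items()}
        return cls(slopes=slopes, rel_uncertainty=unc)


def load_reference_table() -> pd.DataFrame:
    """Published per-sample mean El/Ca table for *E. huxleyi* coccoliths.

    Six culture and seven field samples; per sample: N, mean ion-count ratios
    with SE and Tukey letter groups, and mean molar ratios (mmol/mol) with SE
    where a calibration exists (K has none; field Ba/K were not measured).
    Values are stored exactly as printed, so trailing decimals reflect the
    reported precision.
    """
    with resources.files("coccosims.data").joinpath("ehux_cohort_means.csv").open() as fh:
        return pd.read_csv(fh)


def default_calibration(weights: str = "relative") -> CalibrationRelation:
    """Calibration fitted to the paired ion/molar columns of the reference table.

    Molar ratios in that table were obtained from ion-count ratios through
    per-element proportional calibrations on synthetic calcite standards;
    fitting a through-origin slope to the printed pairs recovers those
    relations for Na, Mg, Sr and Ba.
    """
    table = load_reference_table()
    slopes = {}
    for el in ("Na", "Mg", "Sr", "Ba"):
        x = table[f"{el.lower()}_ion"]
        y = table[f"{el.lower()}_molar"]
        slopes[el] = fit_proportional_slope(x, y, weights=weights)
    return CalibrationRelation(slopes=slopes)


def calibrate(
    ion_ratio: float,
    precision_cv: float,
    calibration: CalibrationRelation,
    element: str,
) -> tuple[float, float]:
    """Convert an ion-count ratio to (molar ratio, molar uncertainty).

    ``molar = slope * ion_ratio``; the uncertainty combines the measurement
    precision (residual CV) with the slope's relative uncertainty in
    quadrature.  Accuracy is never better than the slope uncertainty.
    """
    if not calibration.has(element):
        raise QuantifyError(f"no calibration slope for element {element}")
    a = calibration.slopes[element]
    u = calibration.rel_uncertainty.get(element, 0.0)
    molar = a * ion_ratio
    unc = molar * float(np.hypot(precision_cv, u))
    return molar, unc


# ---------------------------------------------------------------------------
# gated accumulation and the dimer correction


@dataclass
class GatedCounts:
    """Ca-gated count sums over a window, with bookkeeping."""

    n_el: int
    n_ca: int
    gated_fraction: float  # included / total (pixel, block) cells
    n_pixels: int
    n_blocks: int

    @property
    def ratio(self) -> float:
        return self.n_el / self.n_ca

    @property
    def poisson_rel_se(self) -> float:
        """First-order relative SE of the ratio from counting statistics."""
        return float(np.sqrt(1.0 / max(self.n_el, 1) + 1.0 / self.n_ca))


def gated_ratio(
    stack: IonImageStack,
    pixel_mask: np.ndarray,
    element: str,
    window: tuple[int, int] | None = None,
    block_size_planes: int = depth_qc.DEFAULT_BLOCK_SIZE,
    gate_min_ca: int = 1,
) -> GatedCounts:
    """El/Ca ion-count ratio with Ca-gated accumulation over a block window.

    ``window`` is (first block, last block) inclusive over the stack's
    depth blocks (default: all).  ``gate_min_ca=0`` bypasses the gate, making
    the result the plain ratio of window sums.
    """
    if gate_min_ca < 0:
        raise QuantifyError("gate_min_ca must be >= 0")
    pixel_mask = np.asarray(pixel_mask, dtype=bool)
    if not pixel_mask.any():
        raise QuantifyError("empty pixel mask")
    ca_blocks = depth_qc.blockwise_pixel_counts(stack.counts[CA_MASS], block_size_planes)
    el_blocks = depth_qc.blockwise_pixel_counts(stack.element_counts(element), block_size_planes)
    nb = ca_blocks.shape[0]
    lo, hi = (0, nb - 1) if window is None else window
    if not (0 <= lo <= hi < nb):
        raise QuantifyError(f"window ({lo}, {hi}) outside [0, {nb})")
    ca_w = ca_blocks[lo : hi + 1][:, pixel_mask]
    el_w = el_blocks[lo : hi + 1][:, pixel_mask]
    if gate_min_ca > 0:
        gate = ca_w >= gate_min_ca
    else:
        gate = np.ones_like(ca_w, dtype=bool)
    n_el = int(el_w[gate].sum())
    n_ca = int(ca_w[gate].sum())
    if n_ca == 0:
        raise QuantifyError("zero included (pixel, block) cells after gating")
    return GatedCounts(
        n_el=n_el,
        n_ca=n_ca,
        gated_fraction=float(gate.mean()),
        n_pixels=int(pixel_mask.sum()),
        n_blocks=hi - lo + 1,
    )


def dimer_correct(raw_sr_counts: float, ca_counts: float, delta: float) -> tuple[float, bool]:
    """Remove the (44Ca)2+ dimer contribution from mass-88 count sums.

    ``delta`` is the expected dimer counts per detected 44Ca ion (an
    instrument/session constant).  Returns the corrected counts, floored at
    zero, and whether the floor was binding.
    """
    if delta < 0:
        raise QuantifyError("delta must be >= 0")
    corrected = raw_sr_counts - delta * ca_counts
    return (max(corrected, 0.0), corrected < 0.0)


def estimate_delta(stack: IonImageStack, sr_free_mask: np.ndarray) -> float:
    """Estimate the dimer yield ratio from a Sr-free reference region.

    Mean mass-88 / mass-44 count ratio over the region; never auto-applied.
    """
    sr_free_mask = np.asarray(sr_free_mask, dtype=bool)
    ca = int(stack.counts[CA_MASS][:, sr_free_mask].sum())
    sr = int(stack.counts["88Sr"][:, sr_free_mask].sum())
    if ca == 0:
        raise QuantifyError("Sr-free region has no 44Ca counts")
    return sr / ca


# ---------------------------------------------------------------------------
# per-coccolith orchestration


@dataclass
class ElementResult:
    """One element's quantification within one coccolith."""

    element: str
    ion_ratio: float
    precision_cv: float
    poisson_rel_se: float
    molar_ratio: float | None
    molar_uncertainty: float | None
    window_blocks: tuple[int, int]
    blocks_used: int
    blocks_total: int
    gated_fraction: float
    flags: set[str] = field(default_factory=set)


@dataclass
class LithResult:
    """Per-coccolith record: one ElementResult per measured trace element."""

    sample_id: str
    roi_label: int
    pixels_used: int
    elements: dict[str, ElementResult] = field(default_factory=dict)
    flags: set[str] = field(default_factory=set)

    def to_row(self) -> dict:
        row: dict = {
            "sample_id": self.sample_id,
            "roi_label": self.roi_label,
            "pixels_used": self.pixels_used,
            "flags": ";".join(sorted(self.flags)),
        }
        for el, res in self.elements.items():
            key = el.lower()
            row[f"ratio_{key}"] = res.ion_ratio
            row[f"precision_cv_{key}"] = res.precision_cv
            row[f"poisson_se_{key}"] = res.poisson_rel_se
            row[f"molar_{key}"] = res.molar_ratio if res.molar_ratio is not None else np.nan
            row[f"molar_unc_{key}"] = (
                res.molar_uncertainty if res.molar_uncertainty is not None else np.nan
            )
            row[f"blocks_used_{key}"] = res.blocks_used
            row[f"gated_fraction_{key}"] = res.gated_fraction
            row[f"flags_{key}"] = ";".join(sorted(res.flags))
        return row


def quantify_lith(
    stack: IonImageStack,
    roi_map: RoiMap,
    roi_label: int,
    calibration: CalibrationRelation,
    block_size_planes: int = depth_qc.DEFAULT_BLOCK_SIZE,
    gate_min_ca: int = 1,
    cv_target: float = depth_qc.DEFAULT_CV_TARGET,
    min_fraction: float = depth_qc.DEFAULT_MIN_FRACTION,
    delta: float = 0.0,
) -> LithResult:
    """Quantify every measured trace element in one coccolith ROI.

    Orchestrates profile -> stable window -> gated accumulation -> dimer
    correction (Sr only) -> calibration.  Contaminant-ROI pixels are excluded
    from the coccolith pixel set even where they overlap the coccolith ROI.
    """
    pixel_mask = roi_map.mask(roi_label) & ~roi_map.class_mask("contaminant")
    result = LithResult(
        sample_id=stack.meta.sample_id or "sample",
        roi_label=roi_label,
        pixels_used=int(pixel_mask.sum()),
    )
    for element in stack.elements:
        try:
            profile = depth_qc.build_profile(
                stack, roi_map, roi_label, element,
                block_size_planes=block_size_planes, gate_min_ca=gate_min_ca,
            )
            window, qc = depth_qc.select_stable_window(
                profile, cv_target=cv_target, min_fraction=min_fraction
            )
            # map window over retained blocks back to absolute block indices
            abs_window = (int(profile.block_index[window[0]]),
                          int(profile.block_index[window[1]]))
            gated = gated_ratio(
                stack, pixel_mask, element, window=abs_window,
                block_size_planes=block_size_planes, gate_min_ca=gate_min_ca,
            )
        except (depth_qc.DepthQcError, QuantifyError) as err:
            raise QuantifyError(f"ROI {roi_label}, element {element}: {err}") from err

        n_el: float = gated.n_el
        flags = set(qc.flags)
        if element == "Sr" and delta > 0:
            n_el, floored = dimer_correct(gated.n_el, gated.n_ca, delta)
            if floored:
                flags.add("dimer_floor")
        ratio = n_el / gated.n_ca

        total_blocks = profile.n_blocks + profile.n_dropped
        blocks_used = gated.n_blocks
        if (total_blocks - blocks_used) / total_blocks > SURFACE_EXCLUSION_FLAG_FRACTION:
            flags.add("surface_contaminated")
        poisson_se = float(np.sqrt(1.0 / max(n_el, 1.0) + 1.0 / gated.n_ca))
        if element == "Ba" and poisson_se > BA_POISSON_FLAG_THRESHOLD:
            flags.add("low_precision")

        if calibration.has(element):
            molar, molar_unc = calibrate(ratio, qc.cv_corrected, calibration, element)
        else:
            molar, molar_unc = None, None  # e.g. K: no calibration standard

        result.elements[element] = ElementResult(
            element=element,
            ion_ratio=float(ratio),
            precision_cv=qc.cv_corrected,
            poisson_rel_se=poisson_se,
            molar_ratio=molar,
            molar_uncertainty=molar_unc,
            window_blocks=abs_window,
            blocks_used=blocks_used,
            blocks_total=total_blocks,
            gated_fraction=gated.gated_fraction,
            flags=flags,
        )
        result.flags |= flags
    return result


def quantify_all(
    stack: IonImageStack,
    roi_map: RoiMap,
    calibration: CalibrationRelation,
    **kwargs,
) -> list[LithResult]:
    """Quantify every coccolith ROI in the map."""
    return [
        quantify_lith(stack, roi_map, label, calibration, **kwargs)
        for label in roi_map.labels_of_class("coccolith")
    ]
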