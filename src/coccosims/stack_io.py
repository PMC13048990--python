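"""Read/write ion-count image stacks, ROI maps, and per-coccolith result tables.

NanoSIMS vendors ship proprietary stack formats; this package uses open ones
instead: one multi-page TIFF per detected mass (page ``k`` = acquisition plane
``k``) plus a JSON sidecar (``stack.json``) naming the masses and carrying the
acquisition metadata.  ROI maps are a single-page integer TIFF plus a JSON
class map.  Per-coccolith results are a flat CSV, one row per coccolith.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

#: Masses this pipeline understands, in canonical order.
SUPPORTED_MASSES = ("23Na", "24Mg", "39K", "44Ca", "88Sr", "138Ba")

#: Trace elements quantified against Ca, keyed by chemical symbol.
ELEMENT_TO_MASS = {"Na": "23Na", "Mg": "24Mg", "K": "39K", "Sr": "88Sr", "Ba": "138Ba"}
MASS_TO_ELEMENT = {m: e for e, m in ELEMENT_TO_MASS.items()}
CA_MASS = "44Ca"

ROI_CLASSES = ("coccolith", "contaminant", "background")

SIDECAR_NAME = "stack.json"


class StackIOError(Exception):
    """Raised for malformed stack directories, sidecars, or result tables."""


@dataclass
class StackMeta:
    """Acquisition metadata carried alongside the count arrays."""

    fov_um: float = 10.0
    dwell_time_us_per_pixel: float = 1000.0
    session_id: str = ""
    sample_id: str = ""

    def to_dict(self) -> dict:
        return {
            "fov_um": self.fov_um,
            "dwell_time_us_per_pixel": self.dwell_time_us_per_pixel,
            "session_id": self.session_id,
            "sample_id": self.sample_id,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StackMeta":
        return cls(
            fov_um=float(d.get("fov_um", 10.0)),
            dwell_time_us_per_pixel=float(d.get("dwell_time_us_per_pixel", 1000.0)),
            session_id=str(d.get("session_id", "")),
            sample_id=str(d.get("sample_id", "")),
        )


@dataclass
class IonImageStack:
    """Per-mass 3-D integer count arrays (plane x row x col) plus metadata.

    All masses share an identical ``(P, H, W)`` shape and counts are
    non-negative integers.
    """

    counts: dict[str, np.ndarray]
    meta: StackMeta = field(default_factory=StackMeta)

    def __post_init__(self) -> None:
        if not self.counts:
            raise StackIOError("stack has no masses")
        shapes = set()
        for mass, arr in self.counts.items():
            if mass not in SUPPORTED_MASSES:
                raise StackIOError(f"unsupported mass label: {mass!r}")
            arr = np.asarray(arr)
            if arr.ndim != 3:
                raise StackIOError(f"{mass}: counts must be 3-D (P, H, W)")
            if not np.issubdtype(arr.dtype, np.integer):
                if np.issubdtype(arr.dtype, np.floating) and np.all(arr == np.round(arr)):
                    arr = arr.astype(np.int64)
                else:
                    raise StackIOError(f"{mass}: counts must be integers")
            if arr.size and arr.min() < 0:
                raise StackIOError(f"{mass}: negative counts")
            self.counts[mass] = arr
            shapes.add(arr.shape)
        if len(shapes) != 1:
            raise StackIOError(f"masses disagree on shape: {sorted(shapes)}")
        (shape,) = shapes
        if shape[0] < 1:
            raise StackIOError("stack needs at least one plane")

    @property
    def masses(self) -> tuple[str, ...]:
        return tuple(self.counts)

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.counts.values())).shape

    @property
    def planes(self) -> int:
        return self.shape[0]

    @property
    def pixel_pitch_um(self) -> float:
        """Physical width of one pixel; the raster is assumed square."""
        return self.meta.fov_um / self.shape[2]

    def element_counts(self, element: str) -> np.ndarray:
        """Counts array for a trace element given by symbol (e.g. ``"Na"``)."""
        mass = ELEMENT_TO_MASS.get(element)
        if mass is None:
            raise KeyError(f"unknown element {element!r}")
        if mass not in self.counts:
            raise KeyError(f"mass {mass} not present in this stack")
        return self.counts[mass]

    @property
    def elements(self) -> tuple[str, ...]:
        """Trace-element symbols measured in this stack (Ca excluded)."""
        return tuple(MASS_TO_ELEMENT[m] for m in self.masses if m in MASS_TO_ELEMENT)


@dataclass
class RoiMap:
    """Integer label image partitioning pixels into classed regions.

    ``labels`` is H x W with 0 = unassigned; every nonzero label has an entry
    in ``classes`` mapping it to one of :data:`ROI_CLASSES`.
    """

    labels: np.ndarray
    classes: dict[int, str]
    warning: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise StackIOError("RoiMap labels must be 2-D")
        self.classes = {int(k): v for k, v in self.classes.items()}
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.classes)
        if missing:
            raise StackIOError(f"labels without a class: {sorted(missing)}")
        bad = set(self.classes.values()) - set(ROI_CLASSES)
        if bad:
            raise StackIOError(f"unknown ROI classes: {sorted(bad)}")

    def labels_of_class(self, cls: str) -> list[int]:
        return sorted(l for l, c in self.classes.items() if c == cls)

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label

    def class_mask(self, cls: str) -> np.ndarray:
        out = np.zeros(self.labels.shape, dtype=bool)
        for l in self.labels_of_class(cls):
            out |= self.labels == l
        return out


# ---------------------------------------------------------------------------
# stack directories


def write_stack(stack: IonImageStack, dirpath: str | Path) -> None:
    """Write one multi-page TIFF per mass plus the JSON sidecar.

    Counts are stored as uint16 where they fit, uint32 otherwise; the
    round-trip through :func:`read_stack` is lossless.
    """
    dirpath = Path(dirpath)
    dirpath.mkdir(parents=True, exist_ok=True)
    for mass, arr in stack.counts.items():
        dtype = np.uint16 if (arr.size == 0 or arr.max() < 2**16) else np.uint32
        tifffile.imwrite(dirpath / f"{mass}.tif", arr.astype(dtype))
    sidecar = {
        "masses": list(stack.masses),
        "shape": list(stack.shape),
        **stack.meta.to_dict(),
    }
    (dirpath / SIDECAR_NAME).write_text(json.dumps(sidecar, indent=2))


def read_stack(dirpath: str | Path) -> IonImageStack:
    """Read a stack directory written by :func:`write_stack` and validate it."""
    dirpath = Path(dirpath)
    sidecar_path = dirpath / SIDECAR_NAME
    if not sidecar_path.exists():
        raise StackIOError(f"missing sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    counts: dict[str, np.ndarray] = {}
    for mass in sidecar["masses"]:
        path = dirpath / f"{mass}.tif"
        if not path.exists():
            raise StackIOError(f"sidecar declares mass {mass} but {path.name} is absent")
        arr = tifffile.imread(path)
        if arr.ndim == 2:  # single-plane stacks read back as 2-D
            arr = arr[None]
        counts[mass] = np.asarray(arr)
    stack = IonImageStack(counts, meta=StackMeta.from_dict(sidecar))
    if "shape" in sidecar and tuple(sidecar["shape"]) != stack.shape:
        raise StackIOError(
            f"sidecar shape {tuple(sidecar['shape'])} != data shape {stack.shape}"
        )
    return stack


# ---------------------------------------------------------------------------
# ROI maps


def write_roi_map(roi: RoiMap, tiff_path: str | Path) -> None:
    """Write labels as a single-page int32 TIFF and classes as a JSON next to it."""
    tiff_path = Path(tiff_path)
    tiff_path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(tiff_path, roi.labels.astype(np.int32))
    meta = {"classes": {str(k): v for k, v in roi.classes.items()}, "warning": roi.warning}
    tiff_path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_roi_map(tiff_path: str | Path) -> RoiMap:
    tiff_path = Path(tiff_path)
    if not tiff_path.exists():
        raise StackIOError(f"missing ROI map {tiff_path}")
    labels = np.asarray(tifffile.imread(tiff_path))
    json_path = tiff_path.with_suffix(".json")
    if not json_path.exists():
        raise StackIOError(f"missing ROI class map {json_path}")
    meta = json.loads(json_path.read_text())
    classes = {int(k): v for k, v in meta["classes"].items()}
    return RoiMap(labels=labels, classes=classes, warning=meta.get("warning", ""))


# ---------------------------------------------------------------------------
# result tables

#: Identity columns every results CSV must carry.
RESULT_KEY_COLUMNS = ["sample_id", "roi_label"]


def results_to_frame(results: list) -> pd.DataFrame:
    """Flatten a list of per-coccolith results into the CSV schema.

    Accepts any objects exposing ``to_row() -> dict`` (see
    :class:`coccosims.quantify.LithResult`) or an already-flat DataFrame.
    """
    if isinstance(results, pd.DataFrame):
        return results
    rows = [r.to_row() if hasattr(r, "to_row") else dict(r) for r in results]
    if not rows:
        return pd.DataFrame(columns=RESULT_KEY_COLUMNS)
    return pd.DataFrame(rows)


def write_results(results, csv_path: str | Path) -> None:
    """Write per-coccolith results as comma-separated UTF-8 with ``.`` decimals."""
    frame = results_to_frame(results)
    csv_path = Path(csv_path)
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    # %.17g guarantees a lossless float64 round trip through the CSV
    frame.to_csv(csv_path, index=False, float_format="%.17g")


def read_results(csv_path: str | Path) -> pd.DataFrame:
    """Read a results CSV back, enforcing the identity columns."""
    csv_path = Path(csv_path)
    if not csv_path.exists():
        raise StackIOError(f"missing results table {csv_path}")
    frame = pd.read_csv(csv_path, float_precision="round_trip")
    missing = [c for c in RESULT_KEY_COLUMNS if c not in frame.columns]
    if missing:
        raise StackIOError(f"results table lacks required columns: {missing}")
    return frame
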