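"""Ground-truthed synthetic NanoSIMS-like image stacks.

The generator emulates the statistical structure the downstream analysis
assumes for imaging of coccoliths deposited on a polycarbonate filter:

* 3-5 um Ca-rich coccolith phantoms (annuli or discs) on a low-count filter
  background, with element/Ca count-rate ratios fixed per phantom (the ground
  truth the pipeline must recover);
* a Gaussian beam point-spread function of 350-500 nm FWHM;
* many acquisition planes (depth), with an optional multiplicative yield
  drift that relaxes exponentially as pre-sputtering equilibrates;
* salt/organic contaminant particles enriched in Na/Mg/K/Ba (never Sr) whose
  emission decays exponentially with depth as the particle is sputtered away;
* independent Poisson detection noise per pixel/plane/mass;
* a mass-88 dimer contribution drawn as an extra Poisson term with expectation
  ``delta *`` the local 44Ca rate, mimicking the unresolvable (44Ca)2+
  interference on 88Sr.

Counts are independent Poisson draws; no detector dead-time or QSA effects
are modelled.  Depth dependencies use a half-life parameterisation (the
simplest monotone model for particles gradually sputtering away).  Pixel
(0, 0) has its centre at (0.5, 0.5) pixel pitches; row index increases
downward; plane 0 is the shallowest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .stack_io import (
    CA_MASS,
    ELEMENT_TO_MASS,
    IonImageStack,
    MASS_TO_ELEMENT,
    StackMeta,
    SUPPORTED_MASSES,
)

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


class ScenarioError(KeyError):
    """Unknown scenario name."""


def _disc_mask(shape_hw: tuple[int, int], pitch_um: float, center_um, radius_um: float,
               inner_radius_um: float = 0.0) -> np.ndarray:
    """Boolean annulus/disc mask using pixel-centre coordinates."""
    h, w = shape_hw
    yy = (np.arange(h) + 0.5) * pitch_um
    xx = (np.arange(w) + 0.5) * pitch_um
    d2 = (yy[:, None] - center_um[0]) ** 2 + (xx[None, :] - center_um[1]) ** 2
    mask = d2 <= radius_um**2
    if inner_radius_um > 0:
        mask &= d2 > inner_radius_um**2
    return mask


@dataclass
class LithPhantom:
    """A coccolith phantom: a Ca-rich annulus (or disc when ``inner`` = 0).

    ``true_ratios`` maps element symbol -> true El/Ca ion-count ratio; this is
    the quantity the quantification stage must recover.
    """

    center_um: tuple[float, float]
    outer_radius_um: float
    inner_radius_um: float = 0.0
    ca_rate: float = 2.0  # mean 44Ca counts / pixel / plane inside the lith
    true_ratios: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.inner_radius_um < self.outer_radius_um):
            raise ValueError("need 0 <= inner radius < outer radius")
        if self.ca_rate < 0:
            raise ValueError("ca_rate must be >= 0")
        if any(v < 0 for v in self.true_ratios.values()):
            raise ValueError("true ratios must be >= 0")

    def mask(self, shape_hw: tuple[int, int], pitch_um: float) -> np.ndarray:
        """Pixel mask of the annulus itself."""
        return _disc_mask(shape_hw, pitch_um, self.center_um,
                          self.outer_radius_um, self.inner_radius_um)

    def disc_mask(self, shape_hw: tuple[int, int], pitch_um: float) -> np.ndarray:
        """Filled outer disc, central opening included (a hand-drawn-style ROI)."""
        return _disc_mask(shape_hw, pitch_um, self.center_um, self.outer_radius_um)

    def rate(self, element_or_ca: str) -> float:
        """Mean counts/pixel/plane of a mass inside the (unblurred) annulus."""
        if element_or_ca == "Ca":
            return self.ca_rate
        return self.ca_rate * self.true_ratios.get(element_or_ca, 0.0)


@dataclass
class ContaminantPhantom:
    """A salt/organic particle: Na/Mg/K/Ba-rich, Sr-free, sputters away.

    ``rates`` gives surface counts/pixel/plane at plane 0; emission decays as
    ``2**(-p / depletion_halflife_planes)``.
    """

    center_um: tuple[float, float]
    radius_um: float
    rates: dict[str, float] = field(default_factory=dict)
    depletion_halflife_planes: float = 80.0

    def __post_init__(self) -> None:
        if self.radius_um <= 0:
            raise ValueError("radius must be > 0")
        if self.rates.get("Sr", 0.0) != 0.0:
            raise ValueError("contaminants are Sr-free (rates['Sr'] must be 0)")
        if any(v < 0 for v in self.rates.values()):
            raise ValueError("contaminant rates must be >= 0")
        if self.depletion_halflife_planes <= 0:
            raise ValueError("depletion half-life must be > 0")

    def mask(self, shape_hw: tuple[int, int], pitch_um: float) -> np.ndarray:
        return _disc_mask(shape_hw, pitch_um, self.center_um, self.radius_um)

    def intersects_lith(self, lith: LithPhantom) -> bool:
        """True when the particle disc intersects the lith annulus."""
        d = float(np.hypot(self.center_um[0] - lith.center_um[0],
                           self.center_um[1] - lith.center_um[1]))
        return (d - self.radius_um < lith.outer_radius_um
                and d + self.radius_um > lith.inner_radius_um)


@dataclass
class StackTruth:
    """Complete description of a synthetic acquisition, including ground truth."""

    fov_um: float = 10.0
    shape: tuple[int, int, int] = (500, 128, 128)  # (P, H, W)
    masses: tuple[str, ...] = SUPPORTED_MASSES
    liths: list[LithPhantom] = field(default_factory=list)
    contaminants: list[ContaminantPhantom] = field(default_factory=list)
    background_rates: dict[str, float] = field(default_factory=dict)  # per mass
    drift_amplitude: dict[str, float] = field(default_factory=dict)  # a_m per mass
    drift_halflife_planes: float = 100.0
    psf_fwhm_um: float = 0.4
    dimer_delta: float = 0.0
    seed: int = 0
    sample_id: str = "synthetic"

    def __post_init__(self) -> None:
        p, h, w = self.shape
        if p < 10:
            raise ValueError("need at least 10 planes")
        if h < 1 or w < 1:
            raise ValueError("empty raster")
        bad = [m for m in self.masses if m not in SUPPORTED_MASSES]
        if bad:
            raise ValueError(f"unsupported masses: {bad}")
        if CA_MASS not in self.masses:
            raise ValueError("44Ca must be measured")
        if not (0.0 <= self.dimer_delta < 1.0):
            raise ValueError("dimer_delta must be in [0, 1)")
        if not (0.0 < self.psf_fwhm_um <= 1.0):
            raise ValueError("psf_fwhm_um outside the supported (0, 1] um range")
        for m, r in self.background_rates.items():
            if not np.isfinite(r) or r < 0:
                raise ValueError(f"background rate for {m} must be finite and >= 0")
        if self.drift_halflife_planes <= 0:
            raise ValueError("drift half-life must be > 0")

    @property
    def pitch_um(self) -> float:
        return self.fov_um / self.shape[2]

    def lith_mask(self, i: int) -> np.ndarray:
        return self.liths[i].mask(self.shape[1:], self.pitch_um)

    def lith_disc_mask(self, i: int) -> np.ndarray:
        return self.liths[i].disc_mask(self.shape[1:], self.pitch_um)

    def contaminant_mask(self, i: int) -> np.ndarray:
        return self.contaminants[i].mask(self.shape[1:], self.pitch_um)

    def expected_rate_field(self, mass: str) -> np.ndarray:
        """Blurred per-pixel rate at plane 0 with drift off (H x W floats).

        Background is uniform and left unblurred; lith and contaminant fields
        are convolved with the beam PSF.
        """
        p, h, w = self.shape
        el = MASS_TO_ELEMENT.get(mass)
        key = "Ca" if mass == CA_MASS else el
        lith_field = np.zeros((h, w))
        for lith in self.liths:
            lith_field[lith.mask((h, w), self.pitch_um)] += lith.rate(key)
        cont_field = np.zeros((h, w))
        for cont in self.contaminants:
            if key != "Ca":
                cont_field[cont.mask((h, w), self.pitch_um)] += cont.rates.get(key, 0.0)
        sigma_px = self.psf_fwhm_um * FWHM_TO_SIGMA / self.pitch_um
        blurred = gaussian_filter(lith_field + cont_field, sigma_px, mode="constant")
        return blurred + self.background_rates.get(mass, 0.0)


def _static_field(truth: StackTruth, mass: str) -> np.ndarray:
    """Depth-independent blurred rate field: liths (PSF-convolved) + background."""
    _, h, w = truth.shape
    pitch = truth.pitch_um
    key = "Ca" if mass == CA_MASS else MASS_TO_ELEMENT.get(mass)
    field_ = np.zeros((h, w))
    for lith in truth.liths:
        field_[lith.mask((h, w), pitch)] += lith.rate(key)
    sigma_px = truth.psf_fwhm_um * FWHM_TO_SIGMA / pitch
    field_ = gaussian_filter(field_, sigma_px, mode="constant")
    field_ += truth.background_rates.get(mass, 0.0)
    if not np.all(np.isfinite(field_)):
        raise ValueError(f"non-finite expected rates for mass {mass}")
    return field_


def _contaminant_terms(truth: StackTruth, mass: str):
    """Per-contaminant blurred footprints cropped to their support.

    Yields ``(row_slice, col_slice, field, halflife)``; the full rate of the
    term at plane p is ``field * 2**(-p / halflife)`` inside the crop.
    """
    if mass == CA_MASS:
        return
    _, h, w = truth.shape
    pitch = truth.pitch_um
    sigma_px = truth.psf_fwhm_um * FWHM_TO_SIGMA / pitch
    el = MASS_TO_ELEMENT[mass]
    for cont in truth.contaminants:
        rate = cont.rates.get(el, 0.0)
        if rate <= 0:
            continue
        foot = np.zeros((h, w))
        foot[cont.mask((h, w), pitch)] = rate
        foot = gaussian_filter(foot, sigma_px, mode="constant")
        if not np.all(np.isfinite(foot)):
            raise ValueError(f"non-finite contaminant rates for mass {mass}")
        rows, cols = np.nonzero(foot)
        if rows.size == 0:
            continue
        ys = slice(int(rows.min()), int(rows.max()) + 1)
        xs = slice(int(cols.min()), int(cols.max()) + 1)
        yield ys, xs, foot[ys, xs], cont.depletion_halflife_planes


def _draw_mass(rng: np.random.Generator, truth: StackTruth, mass: str,
               scale: float = 1.0) -> np.ndarray:
    """Poisson counts for one mass (the full lambda, scaled by ``scale``).

    Independent additive Poisson terms (static field, per-contaminant decay
    terms) are drawn separately and summed, which is distributionally
    identical to drawing from the summed rate.
    """
    p = truth.shape[0]
    planes = np.arange(p)
    a_m = truth.drift_amplitude.get(mass, 0.0)
    drift = 1.0 + a_m * np.exp2(-planes / truth.drift_halflife_planes)
    static = _static_field(truth, mass) * scale
    if a_m == 0.0:
        counts = rng.poisson(np.broadcast_to(static[None, :, :], truth.shape))
    else:
        counts = rng.poisson(np.multiply.outer(drift, static))
    for ys, xs, foot, halflife in _contaminant_terms(truth, mass):
        g = np.exp2(-planes / halflife) * drift
        lam = np.multiply.outer(g, foot * scale)
        counts[:, ys, xs] += rng.poisson(lam)
    return counts


def generate_stack(truth: StackTruth) -> IonImageStack:
    """Draw one synthetic acquisition.

    Counts for each mass are independent Poisson draws around the blurred rate
    field ``lambda = [background + liths + contaminants * 2**(-p/halflife)] *
    drift(m, p)``; mass 88 additionally receives an independent Poisson dimer
    term with expectation ``dimer_delta * lambda_Ca``.  Deterministic for a
    fixed ``truth.seed``.
    """
    rng = np.random.default_rng(truth.seed)
    counts: dict[str, np.ndarray] = {}
    for mass in truth.masses:
        counts[mass] = _draw_mass(rng, truth, mass)
    if "88Sr" in truth.masses and truth.dimer_delta > 0:
        dimer = _draw_mass(rng, truth, CA_MASS, scale=truth.dimer_delta)
        counts["88Sr"] = counts["88Sr"] + dimer
    counts = {m: c.astype(np.int32) for m, c in counts.items()}
    meta = StackMeta(fov_um=truth.fov_um, sample_id=truth.sample_id,
                     session_id=f"synthetic-seed-{truth.seed}")
    return IonImageStack(counts, meta=meta)


def inject_plane_shifts(stack: IonImageStack, offsets: np.ndarray) -> IonImageStack:
    """Mis-align a stack by rolling each plane by integer (dy, dx) offsets.

    Used to test registration: the aligner must recover ``-offsets``-free
    images, i.e. report exactly these offsets back.
    """
    offsets = np.asarray(offsets, dtype=int)
    if offsets.shape != (stack.planes, 2):
        raise ValueError("offsets must be (P, 2)")
    shifted = {}
    for mass, arr in stack.counts.items():
        out = np.empty_like(arr)
        for p in range(arr.shape[0]):
            out[p] = np.roll(arr[p], tuple(offsets[p]), axis=(0, 1))
        shifted[mass] = out
    return IonImageStack(shifted, meta=stack.meta)


# ---------------------------------------------------------------------------
# scenario registry

# Per-lith true ratios patterned on cultured E. huxleyi coccoliths: Na/Ca a few
# tenths, Mg/Ca a few percent, K/Ca ~0.1-0.4, Sr/Ca ~0.08, Ba/Ca ~1e-3.
_LITH_RATIOS = [
    {"Na": 0.437, "Mg": 0.0295, "K": 0.307, "Sr": 0.0842, "Ba": 0.00168},
    {"Na": 0.61, "Mg": 0.059, "K": 0.102, "Sr": 0.0781, "Ba": 0.00042},
    {"Na": 1.34, "Mg": 0.045, "K": 0.344, "Sr": 0.0784, "Ba": 0.00073},
]

# Very low-count filter background (counts/pixel/plane): of order one count per
# pixel over a full 500-1000 plane acquisition, as seen on blank filter areas.
_BACKGROUND = {
    "23Na": 5e-4, "24Mg": 2e-4, "39K": 5e-4,
    "44Ca": 2e-3, "88Sr": 5e-5, "138Ba": 5e-5,
}


def _clean_truth(seed: int) -> StackTruth:
    return StackTruth(
        fov_um=10.0,
        shape=(500, 128, 128),
        liths=[
            LithPhantom((3.0, 3.0), 1.75, 0.80, ca_rate=2.0, true_ratios=_LITH_RATIOS[0]),
            LithPhantom((7.2, 3.4), 1.60, 0.70, ca_rate=2.0, true_ratios=_LITH_RATIOS[1]),
            LithPhantom((4.9, 7.3), 1.90, 0.85, ca_rate=2.0, true_ratios=_LITH_RATIOS[2]),
        ],
        contaminants=[],
        background_rates=dict(_BACKGROUND),
        psf_fwhm_um=0.4,
        dimer_delta=0.005,
        seed=seed,
        sample_id="clean",
    )


def _salt_speckled_truth(seed: int) -> StackTruth:
    liths = [
        LithPhantom((3.2, 3.2), 1.75, 0.80, ca_rate=2.0, true_ratios=_LITH_RATIOS[0]),
        LithPhantom((6.8, 6.6), 1.70, 0.75, ca_rate=2.0, true_ratios=_LITH_RATIOS[2]),
    ]
    contaminants = [
        # salt particle lodged on the filter visible through the central
        # opening of lith 0 (particles sit atop, underneath or in between the
        # structural calcite elements); no Ca underneath, so Ca-gating is the
        # tool that removes it.
        ContaminantPhantom((3.2, 3.3), 0.35,
                           rates={"Na": 30.0, "Mg": 3.0, "K": 15.0, "Ba": 0.05},
                           depletion_halflife_planes=80.0),
        # second particle straddling the outer rim of lith 1: its disc
        # intersects the annulus (the "overlapping a lith" case).
        ContaminantPhantom((6.8, 8.2), 0.40,
                           rates={"Na": 20.0, "Mg": 5.0, "K": 8.0, "Ba": 0.03},
                           depletion_halflife_planes=60.0),
    ]
    truth = StackTruth(
        fov_um=10.0,
        shape=(500, 128, 128),
        liths=liths,
        contaminants=contaminants,
        background_rates=dict(_BACKGROUND),
        psf_fwhm_um=0.4,
        dimer_delta=0.005,
        seed=seed,
        sample_id="salt_speckled",
    )
    assert any(c.intersects_lith(l) for c in contaminants for l in liths)
    return truth


def _drifty_truth(seed: int) -> StackTruth:
    truth = _clean_truth(seed)
    truth.sample_id = "drifty"
    # secondary-ion yields of the alkali metals stabilise more slowly than Ca
    truth.drift_amplitude = {"23Na": 0.3, "24Mg": 0.3, "39K": 0.3}
    truth.drift_halflife_planes = 100.0
    return truth


def _tiny_clean_truth(seed: int) -> StackTruth:
    """Small single-lith variant for fast smoke tests and CLI examples."""
    return StackTruth(
        fov_um=5.0,
        shape=(100, 48, 48),
        liths=[LithPhantom((2.5, 2.5), 1.4, 0.6, ca_rate=2.0,
                           true_ratios=_LITH_RATIOS[0])],
        contaminants=[],
        background_rates=dict(_BACKGROUND),
        psf_fwhm_um=0.4,
        dimer_delta=0.005,
        seed=seed,
        sample_id="tiny_clean",
    )


SCENARIOS = {
    "clean": _clean_truth,
    "salt_speckled": _salt_speckled_truth,
    "drifty": _drifty_truth,
    "tiny_clean": _tiny_clean_truth,
}


def default_scenario(name: str, seed: int = 0) -> StackTruth:
    """Return a fully populated :class:`StackTruth` from the scenario registry."""
    try:
        factory = SCENARIOS[name]
    except KeyError:
        raise ScenarioError(
            f"unknown scenario {name!r}; known: {sorted(SCENARIOS)}"
        ) from None
    return factory(seed)
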