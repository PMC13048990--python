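# Methods

This note records the models, conventions and numerical choices behind
`coccosims`, and what its synthetic validation does and does not show.

## The measurement model

A NanoSIMS acquisition rasters a field of view (5–20 µm, here 5–10 µm) over
`P` planes (cycles), counting secondary ions per pixel per plane for up to
six masses (²³Na⁺, ²⁴Mg⁺, ³⁹K⁺, ⁴⁴Ca⁺, ⁸⁸Sr⁺, ¹³⁸Ba⁺). Ion detection is
treated as an inhomogeneous Poisson process: counts in different pixels,
planes and masses are independent Poisson draws around a rate field

```
lambda_m(x, p) = [ B_m + L_m(x) + sum_i C_im(x) * 2^(-p / h_i) ] * d_m(p)
```

* `B_m` — uniform filter background (counts px⁻¹ plane⁻¹). Defaults are of
  order 10⁻³–10⁻⁴, i.e. about one count per pixel over a full acquisition,
  as on blank filter areas.
* `L_m(x)` — coccolith phantoms: annuli (outer radius 1.6–1.9 µm, inner
  0.7–0.85 µm, matching 3–5 µm placoliths with an open centre) with a Ca
  rate of 2 counts px⁻¹ plane⁻¹ and element rates `ca_rate * R*_el`. The
  per-phantom `R*_el` are the ground truth to recover; defaults are
  patterned on cultured *E. huxleyi* values (Na/Ca ≈ 0.4–1.3,
  Mg/Ca ≈ 0.03–0.06, K/Ca ≈ 0.1–0.35, Sr/Ca ≈ 0.078–0.084,
  Ba/Ca ≈ 4·10⁻⁴–1.7·10⁻³).
* `C_im(x)` — contaminant particles (salt/organics): sub-µm discs with high
  surface rates for Na, Mg, K and Ba, *zero for Sr*, decaying exponentially
  with depth (half-life parameterisation — the simplest monotone model for
  a particle being sputtered away; half-lives of 60–80 planes).
* `d_m(p) = 1 + a_m · 2^(-p / h_drift)` — optional per-mass yield drift,
  emulating incomplete pre-sputter stabilisation.
* The spatial rate field (liths + contaminants, not the uniform background)
  is convolved with a Gaussian PSF of 0.4 µm FWHM (beam size 350–500 nm).
* Mass 88 receives an additional independent Poisson term with expectation
  `delta * lambda_Ca(x, p)` — the unresolvable ⁴⁴Ca₂⁺ dimer. It is additive
  (dimer detection does not remove monomer detections).

Not modelled: detector dead time, QSA, topography-dependent yields,
charging, physical sputtering (SRIM-like). Contaminants do not attenuate
the underlying calcite signal; the scenario geometry instead places the
particles where they occur in practice — on the filter, including the
filter visible through the placolith's central opening, and straddling a
rim — which reproduces the phenomenology that matters for the gating stage.

Pixel (0,0) has its centre at (0.5, 0.5) pixel pitches; rows grow downward;
plane 0 is shallowest. Per-mass draws use one `numpy` PCG64 generator
seeded from `truth.seed`; independent additive rate terms are drawn
separately and summed (distributionally identical to drawing the summed
rate, and much faster for localised terms).

## Processing conventions

**Alignment.** Integer shifts per block of 50 planes, estimated by
maximising the cross-correlation of the block's accumulated ⁴⁴Ca image
against the running aligned sum. Single planes are too sparse at ~2
counts px⁻¹ plane⁻¹ for per-plane registration, and integer shifts keep
counts integral. Output is cropped to the window valid under all shifts.

**Segmentation.** Coccolith ROIs are connected components of bright ⁴⁴Ca
pixels with ≥ 20 px. The default threshold is Otsu's method on the
accumulated ⁴⁴Ca image: a quantile-of-nonzero-pixels rule (available via
`ca_quantile`) is fragile when coccoliths occupy more than ~10 % of the
nonzero pixels, which is routine at 10 µm fields of view, whereas the
bimodal background/calcite histogram is exactly Otsu's use case; both rules
are scale-invariant. A contrast guard (foreground mean ≥ 5× the median
pixel) keeps structureless noise fields from producing ROIs; it assumes the
filter dominates the raster. Contaminant ROIs are components where the
3×3-mean-smoothed accumulated El/Ca ratio of Na, Mg, K or Ba exceeds 3× the
median ratio over coccolith pixels (≥ 5 px, smoothed counts ≥ 5 to guard
against low-count ratio noise). Sr is deliberately excluded from this test.
Pixels qualifying as both are classed contaminant — the conservative choice
where a particle overlaps a coccolith, flagged in the output. Hand-drawn
ROI maps can be supplied in place of segmentation.

**Depth QC.** Ratios are evaluated on blocks of 5 consecutive planes
(single-plane Ca counts are frequently zero). For a block series
`r(b) = n_el(b)/n_Ca(b)`:

* `CV_obs` = SD/mean over blocks (n−1 denominator, blocks unweighted);
* `CV_P = sqrt(mean_b(1/n_el + 1/n_Ca))` — the first-order relative SD of a
  ratio of independent Poisson sums, evaluated at the realised counts;
  blocks with `n_el = 0` contribute `1/max(n_el, 1)` (one count is the
  resolution floor); blocks with `n_Ca = 0` are dropped and counted;
* `CV_corr = sqrt(max(CV_obs² − CV_P², 0))` — the residual depth
  variability, reported as the measurement precision.

The correction is first-order: under a stationary null its unfloored
statistic `CV_obs² − CV_P²` is centred on zero up to an `O(1/λ²)` Poisson
term (about −4·10⁻⁴ at λ_el = 50 per block, verified by Monte Carlo), and
the floored `CV_corr` has a small positive mean (half-normal folding of
estimation noise, ≈ 0.016 against `CV_P ≈ 0.15` in the oracle setting).

**Window selection.** Exhaustive search over all contiguous block windows
covering ≥ 50 % of blocks (O(B²), B ≤ 200 — cheap and deterministic, no
changepoint heuristics): the longest window with `CV_corr ≤ 0.10` wins;
ties break on larger total Ca counts, then deeper start (surface
contamination and drift concentrate early). If none qualifies, the
minimum-CV window is used and the result flagged `unstable`. "Excluded
planes" means exactly that — planes are removed, never drift-corrected.

**Ca-gated accumulation.** Within the selected window, a (pixel, 5-plane
block) cell contributes only if it holds ≥ 1 detected ⁴⁴Ca ion
(`gate_min_ca = 1`; 0 bypasses the gate). The gate removes element counts
from cells with no calcite signal — contaminant particles on the bare
filter or in the placolith opening — without discarding a pixel for all
depths. Its cost is a small negative bias, `−exp(−λ_Ca·5)` relatively, in
cells where the gate can bind; at 2 Ca counts px⁻¹ plane⁻¹ this is ~4·10⁻⁵
in the lith interior and only matters in blur-edge cells. This is why
blocks of 5 planes are used rather than single planes.

**Dimer correction.** `corrected = max(raw₈₈ − δ·n_Ca, 0)` on the gated
sums, equivalently `R_Sr,corr = R_Sr,raw − δ` under the proportional model
(the equivalence is why the proportional form was chosen; count-level and
ratio-level formulations are then identical). δ is a config/session
constant; `estimate_delta` measures it from a Sr-free region but is never
auto-applied. The ¹³⁸Ba multimer interference is negligible and not
corrected.

**Calibration.** `M_el = a_el · R_el` (through the origin — an intercept is
not identifiable from the available pairs). Default slopes are fitted to
the shipped cohort table of 13 published per-sample mean (ion, molar)
pairs by through-origin least squares with 1/y² weights, i.e. minimising
relative residuals, which matches the multiplicative error structure of
ratio data; unweighted OLS would be dominated by the largest samples.
Fitted slopes: Na ≈ 25.5, Mg ≈ 144.6, Sr ≈ 31.6, Ba ≈ 14.6 mmol mol⁻¹ per
unit ion ratio. Slope accuracies are ±20 % (Na), ±21 % (Mg), ±5 % (Sr),
±4 % (Ba); reported molar uncertainties combine the per-lith residual CV
with the slope uncertainty in quadrature, and accuracy is never better than
the slope term. K/Ca has no standard and stays in ion-count units.

**Cohort statistics.** Ion-count ratios are right-skewed, so ANOVA,
Tukey HSD (Tukey–Kramer SE for unequal n, studentized-range reference
distribution) and correlations operate on natural-log ratios (the base
cancels in F, r and CV; natural log keeps growth rates in d⁻¹); zeros are
excluded with a reported count. Letters use insert-and-absorb compact
letter display; groups share a letter iff their adjusted p ≥ α. Per-lith
values are unweighted by their precision. Correlations map per-sample
covariates onto individual coccoliths, so replication is effectively at the
lith level — a documented caveat, and no multiple-testing adjustment is
applied. Per-sample summaries report raw-scale mean ± SE. ANOVA/Tukey run
per element, matching per-column letter displays.

## Scenario registry (the study conditions)

* `clean` — 128×128 px, 10 µm FOV, 500 planes, three annular liths
  (ca_rate 2), no contaminants, δ = 0.005.
* `salt_speckled` — as `clean` with two liths and two particles: one
  (r = 0.35 µm, Na 30, Mg 3, K 15, Ba 0.05 counts px⁻¹ plane⁻¹ at the
  surface, half-life 80 planes) on the filter in the first lith's central
  opening, its disc clear of the annulus; one (r = 0.4 µm, half-life 60)
  straddling the second lith's outer rim. Contaminant compositions are
  illustrative — no quantitative composition is available for real
  particles.
* `drifty` — as `clean` with `a_m = 0.3` on Na, Mg, K (alkali yields
  stabilise more slowly than Ca), half-life 100 planes.
* `tiny_clean` — 48×48 px, 100 planes, one lith; smoke tests and examples.

## Validation: problem sizes and what passing shows

The Monte-Carlo validation (`coccosims.benchmarks`, exercised by the test
suite and `scripts/acceptance.py`) uses: 2 000 replicate profiles of 200
blocks for the Poisson-CV oracle; 100 full-pipeline seeds of `clean`
(1 500 lith×element recovery cases, ≥ 95 % within 3× combined Poisson SE);
100 seeds of `salt_speckled` for gated-vs-ungated Na/Ca error (gating must
cut the median bias at least threefold; Sr/Ca must move by less than the
single-measurement counting SE); 200 seeds of a 64×64/100-plane dimer
stack (δ = 0.01 on true Sr/Ca = 0.080); 1 000 simulated null datasets for
the Tukey family-wise error. The gated-vs-ungated comparison uses a
hand-drawn-style ROI (the phantom's filled outer disc) over the full depth
range with no contaminant-pixel exclusion, because it isolates the gate;
the full pipeline (segmentation exclusion + windowing + gating) is
validated by the recovery benchmark.

What this does **not** show: the generator reproduces the statistical
structure the pipeline assumes (Poisson counts, proportional element/Ca
rates inside a lith, laterally homogeneous liths, exponential contaminant
decay) — not matrix effects between synthetic and biogenic calcite,
topography-driven yield variation, detector artefacts, or contaminants
that chemically mix with calcite. Passing on synthetic data validates the
estimators and their uncertainty accounting, not instrument accuracy;
absolute molar accuracy remains bounded by the calibration uncertainties
above.

## Degenerate inputs and tie-breaks

All-zero ⁴⁴Ca fails alignment with an explicit `max_shift_px=0` bypass
hint; a field with no coccolith-like contrast yields an empty ROI map with
a warning, not an exception; ratio-image pixels with zero smoothed Ca are
excluded from the enrichment test unless the element signal itself is
strong; window ties break deterministically (length, then Ca counts, then
depth); the dimer floor at zero counts is flagged when it binds; zero
ratios are dropped (and counted) before log transforms; groups with
identical values produce exact-separation letters with a warning rather
than a division by zero.
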