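"""Reproducibility benchmarks: the package's own end-to-end validation suite.

Each function recomputes, from scratch, one of the headline quantities the
pipeline is expected to deliver: the among-culture CVs of the published
cohort table, the Poisson-CV oracle agreement, parameter recovery on clean
synthetic stacks, the contamination robustness of Ca-gating, the (44Ca)2+
dimer correction, the validity of the Tukey statistics, and the consistency
of the proportional calibration with the published paired ion/molar means.

All randomness is derived from one base seed; child seeds stay below 2**31.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import cohort_stats, preprocess, quantify
from .depth_qc import DepthProfile, corrected_cv
from .synthetic_stack import StackTruth, LithPhantom, default_scenario, generate_stack


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % (2**31)


# ---------------------------------------------------------------------------
# worked examples from the published cohort table


def among_culture_cvs() -> dict[str, float]:
    """CV (n-1 SD / mean) of the six culture-mean ion-count ratios, per element."""
    table = quantify.load_reference_table()
    cultures = table[table["kind"] == "culture"]
    out = {}
    for el in ("Na", "Mg", "K", "Sr", "Ba"):
        vals = cultures[f"{el.lower()}_ion"].to_numpy(dtype=float)
        out[el] = float(vals.std(ddof=1) / vals.mean())
    return out


def _printed_ulp(text: str) -> float:
    """Resolution of a printed decimal: one unit in its last digit."""
    text = text.strip()
    if "." in text:
        return 10.0 ** -len(text.split(".")[1])
    return 1.0


def calibration_consistency() -> pd.DataFrame:
    """Through-origin slopes vs the published paired ion/molar means.

    One row per (element, sample): the predicted molar mean, the printed one,
    the relative error, and whether the prediction agrees within 2% or within
    the printed rounding resolution of the pair (whichever is larger —
    several molar means are printed with only 1-2 significant digits).
    """
    from importlib import resources

    calibration = quantify.default_calibration()
    table = quantify.load_reference_table()
    with resources.files("coccosims.data").joinpath("ehux_cohort_means.csv").open() as fh:
        printed = pd.read_csv(fh, dtype=str)
    rows = []
    for el in ("Na", "Mg", "Sr"):
        a = calibration.slopes[el]
        for (_, num), (_, txt) in zip(table.iterrows(), printed.iterrows()):
            x, y = num[f"{el.lower()}_ion"], num[f"{el.lower()}_molar"]
            if not (np.isfinite(x) and np.isfinite(y)):
                continue
            pred = a * x
            tol = max(0.02 * y,
                      0.5 * _printed_ulp(txt[f"{el.lower()}_molar"])
                      + a * 0.5 * _printed_ulp(txt[f"{el.lower()}_ion"]))
            rows.append({
                "element": el, "sample_id": num["sample_id"],
                "predicted": pred, "printed": y,
                "rel_err": abs(pred - y) / y,
                "within_tolerance": bool(abs(pred - y) <= tol),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Poisson-CV oracle


def poisson_cv_oracle(seed: int, reps: int = 2000, blocks: int = 200,
                      lam_el: float = 50.0, lam_ca: float = 500.0) -> dict:
    """Stationary Poisson block profiles: observed CV vs closed-form CV_P."""
    rng = np.random.default_rng(seed)
    nel = rng.poisson(lam_el, (reps, blocks))
    nca = rng.poisson(lam_ca, (reps, blocks))
    cv_obs, cv_p, cv_corr = [], [], []
    for i in range(reps):
        prof = DepthProfile(1, "Na", 5, nel[i], nca[i], np.arange(blocks))
        qc = corrected_cv(prof)
        cv_obs.append(qc.cv_obs)
        cv_p.append(qc.cv_poisson)
        cv_corr.append(qc.cv_corrected)
    cv_obs, cv_p, cv_corr = map(np.asarray, (cv_obs, cv_p, cv_corr))
    unfloored = cv_obs**2 - cv_p**2
    return {
        "mean_cv_obs": float(cv_obs.mean()),
        "mean_cv_poisson": float(cv_p.mean()),
        "rel_diff": float(abs(cv_obs.mean() - cv_p.mean()) / cv_p.mean()),
        "mean_cv_corrected": float(cv_corr.mean()),
        "mean_unfloored": float(unfloored.mean()),
        "mc_se_unfloored": float(unfloored.std(ddof=1) / np.sqrt(reps)),
        "n": reps,
    }


# ---------------------------------------------------------------------------
# parameter recovery on the clean scenario


def clean_recovery(seed: int, n_seeds: int = 100) -> dict:
    """Full pipeline on the clean scenario: fraction of (lith, element)
    cases whose recovered ratio lies within 3x its combined Poisson SE of
    the generator truth."""
    calibration = quantify.default_calibration()
    z_scores = []
    for s in _child_seeds(seed, n_seeds):
        truth = default_scenario("clean", seed=int(s))
        stack = generate_stack(truth)
        aligned, _ = preprocess.align_stack(stack)
        roi = preprocess.segment(preprocess.accumulate(aligned))
        results = quantify.quantify_all(aligned, roi, calibration,
                                        delta=truth.dimer_delta)
        for res in results:
            mask = roi.mask(res.roi_label)
            cy, cx = np.argwhere(mask).mean(axis=0) * truth.pitch_um
            i = int(np.argmin([(cy - l.center_um[0]) ** 2 + (cx - l.center_um[1]) ** 2
                               for l in truth.liths]))
            lith = truth.liths[i]
            for el, er in res.elements.items():
                se = er.poisson_rel_se * max(er.ion_ratio, 1e-12)
                z_scores.append((er.ion_ratio - lith.true_ratios[el]) / se)
    z = np.asarray(z_scores)
    return {
        "fraction_within_3se": float((np.abs(z) <= 3).mean()),
        "n_cases": int(z.size),
        "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------
# contamination robustness of the Ca gate


def contamination_gating(seed: int, n_seeds: int = 100) -> dict:
    """Gated vs ungated Na/Ca error on the contaminated lith of the
    salt-speckled scenario, measured on a hand-drawn-style ROI (the filled
    outer disc of the phantom) over the full depth range.

    Only the masses the measurement uses are generated; per-mass draws are
    independent, so this is distributionally identical to the full scenario.
    """
    gated_err, ungated_err, sr_gated_err, sr_ungated_err, sr_se = [], [], [], [], []
    for s in _child_seeds(seed, n_seeds):
        truth = default_scenario("salt_speckled", seed=int(s))
        truth = dataclasses.replace(truth, masses=("23Na", "44Ca", "88Sr"))
        stack = generate_stack(truth)
        lith = truth.liths[0]
        mask = truth.lith_disc_mask(0)
        for el, store_g, store_u in (("Na", gated_err, ungated_err),
                                     ("Sr", sr_gated_err, sr_ungated_err)):
            true = lith.true_ratios[el]
            g = quantify.gated_ratio(stack, mask, el, gate_min_ca=1)
            u = quantify.gated_ratio(stack, mask, el, gate_min_ca=0)
            rg, ru = g.ratio, u.ratio
            if el == "Sr":  # dimer removed in both arms
                rg -= truth.dimer_delta
                ru -= truth.dimer_delta
                sr_se.append(g.poisson_rel_se * rg)
            store_g.append(abs(rg - true))
            store_u.append(abs(ru - true))
    return {
        "median_gated_err_na": float(np.median(gated_err)),
        "median_ungated_err_na": float(np.median(ungated_err)),
        "error_ratio_na": float(np.median(gated_err) / np.median(ungated_err)),
        "median_gated_err_sr": float(np.median(sr_gated_err)),
        "median_ungated_err_sr": float(np.median(sr_ungated_err)),
        "sr_single_measurement_se": float(np.mean(sr_se)),
        "true_na": truth.liths[0].true_ratios["Na"],
        "true_sr": truth.liths[0].true_ratios["Sr"],
        "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------
# dimer correction


def dimer_benchmark(seed: int, n_seeds: int = 200, true_sr: float = 0.080,
                    delta: float = 0.01) -> dict:
    """Injected dimer yield: corrected ratios unbiased, raw biased by delta."""
    corrected, raw = [], []
    for s in _child_seeds(seed, n_seeds):
        truth = StackTruth(
            fov_um=6.0, shape=(100, 64, 64), masses=("44Ca", "88Sr"),
            liths=[LithPhantom((3.0, 3.0), 1.5, 0.0, ca_rate=2.0,
                               true_ratios={"Sr": true_sr})],
            background_rates={"44Ca": 2e-3, "88Sr": 5e-5},
            psf_fwhm_um=0.4, dimer_delta=delta, seed=int(s),
        )
        stack = generate_stack(truth)
        counts = quantify.gated_ratio(stack, truth.lith_mask(0), "Sr", gate_min_ca=0)
        raw.append(counts.ratio)
        n_sr, _ = quantify.dimer_correct(counts.n_el, counts.n_ca, delta)
        corrected.append(n_sr / counts.n_ca)
    corrected, raw = np.asarray(corrected), np.asarray(raw)
    return {
        "true_sr": true_sr,
        "delta": delta,
        "corrected_mean": float(corrected.mean()),
        "raw_mean": float(raw.mean()),
        "corrected_bias": float(corrected.mean() - true_sr),
        "raw_bias": float(raw.mean() - true_sr),
        "mc_se": float(corrected.std(ddof=1) / np.sqrt(n_seeds)),
        "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------
# Tukey family-wise error under the null


def tukey_null_fwer(seed: int, n_datasets: int = 1000, k: int = 4,
                    n_per_group: int = 10, alpha: float = 0.05) -> dict:
    """Simulated null (all groups one lognormal): fraction of datasets with
    any significant Tukey pair (the family-wise type-I error)."""
    rng = np.random.default_rng(seed)
    group_ids = np.repeat([f"g{i}" for i in range(k)], n_per_group)
    hits = 0
    for _ in range(n_datasets):
        table = pd.DataFrame({
            "sample_id": group_ids,
            "ratio_na": rng.lognormal(0.0, 0.5, k * n_per_group),
        })
        res = cohort_stats.anova_tukey(table, "Na", alpha=alpha)
        hits += int(res.pairs["significant"].any())
    fwer = hits / n_datasets
    return {
        "fwer": float(fwer),
        "alpha": alpha,
        "mc_se": float(np.sqrt(alpha * (1 - alpha) / n_datasets)),
        "n_datasets": n_datasets,
    }
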