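"""Poisson-corrected depth CV and stable-window selection."""

import numpy as np
import pytest

from coccosims.depth_qc import (
    DepthProfile,
    DepthQcError,
    build_profile,
    corrected_cv,
    poisson_cv,
    select_stable_window,
)
from coccosims.stack_io import IonImageStack, RoiMap


def _profile(n_el, n_ca, block_size=5):
    n_el = np.asarray(n_el)
    n_ca = np.asarray(n_ca)
    return DepthProfile(1, "Na", block_size, n_el, n_ca, np.arange(len(n_ca)))


def _roi_all(shape_hw):
    return RoiMap(np.ones(shape_hw, dtype=np.int32), {1: "coccolith"})


class TestBuildProfile:
    def test_block_count_arithmetic(self, rng):
        """1000 planes in blocks of 5 -> 200 blocks."""
        counts = {m: rng.poisson(lam, (1000, 4, 4)).astype(np.int32)
                  for m, lam in (("23Na", 0.5), ("44Ca", 2.0))}
        stack = IonImageStack(counts)
        prof = build_profile(stack, _roi_all((4, 4)), 1, "Na", block_size_planes=5)
        assert prof.n_blocks + prof.n_dropped == 200
        assert prof.n_dropped == 0  # lambda_Ca = 160/block: zero blocks absent

    def test_hand_built_two_block_fixture(self):
        """Counts listed per plane; block ratios equal hand division."""
        na = np.array([3, 1, 0, 2, 4, 0, 1, 1, 2, 1]).reshape(10, 1, 1)
        ca = np.array([10, 12, 8, 11, 9, 13, 10, 9, 8, 10]).reshape(10, 1, 1)
        stack = IonImageStack({"23Na": na, "44Ca": ca})
        prof = build_profile(stack, _roi_all((1, 1)), 1, "Na", block_size_planes=5)
        np.testing.assert_array_equal(prof.n_el, [10, 5])
        np.testing.assert_array_equal(prof.n_ca, [50, 50])
        np.testing.assert_allclose(prof.ratios, [0.2, 0.1])

    def test_ca_as_element_is_rejected(self, tiny_stack, tiny_roi):
        label = tiny_roi.labels_of_class("coccolith")[0]
        with pytest.raises(DepthQcError, match="44Ca"):
            build_profile(tiny_stack, tiny_roi, label, "Ca")

    def test_gated_profile_drops_ca_free_cells(self):
        """With the gate on, element counts in Ca-free cells are excluded."""
        na = np.zeros((5, 1, 2), dtype=int)
        ca = np.zeros((5, 1, 2), dtype=int)
        na[:, 0, 0] = [1, 1, 1, 1, 1]  # pixel 0: Na with Ca
        ca[:, 0, 0] = [2, 2, 2, 2, 2]
        na[:, 0, 1] = [7, 0, 0, 0, 0]  # pixel 1: Na but no Ca at all
        stack = IonImageStack({"23Na": na, "44Ca": ca})
        roi = _roi_all((1, 2))
        gated = build_profile(stack, roi, 1, "Na", block_size_planes=5, gate_min_ca=1)
        ungated = build_profile(stack, roi, 1, "Na", block_size_planes=5)
        assert gated.n_el.tolist() == [5] and gated.n_ca.tolist() == [10]
        assert ungated.n_el.tolist() == [12]


class TestPoissonCv:
    def test_closed_form(self):
        prof = _profile([100] * 10, [10000] * 10)
        assert poisson_cv(prof) == pytest.approx(np.sqrt(0.01 + 0.0001), abs=1e-12)

    def test_doubling_counts_scales_by_sqrt2(self):
        a = _profile([100] * 10, [10000] * 10)
        b = _profile([200] * 10, [20000] * 10)
        assert poisson_cv(a) / poisson_cv(b) == pytest.approx(np.sqrt(2), rel=1e-12)

    def test_monte_carlo_oracle(self, rng):
        """Observed CV of stationary Poisson block ratios matches CV_P."""
        reps, b = 400, 200
        nel = rng.poisson(50.0, (reps, b))
        nca = rng.poisson(500.0, (reps, b))
        obs, pois = [], []
        for i in range(reps):
            prof = _profile(nel[i], nca[i])
            obs.append(corrected_cv(prof).cv_obs)
            pois.append(poisson_cv(prof))
        assert abs(np.mean(obs) - np.mean(pois)) / np.mean(pois) < 0.02

    def test_needs_two_blocks(self):
        with pytest.raises(DepthQcError):
            poisson_cv(_profile([5], [50]))


class TestCorrectedCv:
    def test_floor_at_zero_when_obs_below_poisson(self):
        """Constant ratios: cv_obs = 0 < CV_P, so the residual CV floors at 0."""
        qc = corrected_cv(_profile([10, 10, 10], [100, 100, 100]))
        assert qc.cv_obs == pytest.approx(0.0, abs=1e-12)
        assert qc.cv_corrected == 0.0
        assert qc.cv_corrected <= qc.cv_obs + 1e-15

    def test_cv_is_order_free(self, rng):
        nel = rng.poisson(50.0, 80)
        nca = rng.poisson(500.0, 80)
        qc = corrected_cv(_profile(nel, nca))
        perm = rng.permutation(80)
        qc_shuffled = corrected_cv(_profile(nel[perm], nca[perm]))
        assert qc.cv_obs == pytest.approx(qc_shuffled.cv_obs, rel=1e-12)
        assert qc.cv_corrected == pytest.approx(qc_shuffled.cv_corrected, rel=1e-12)

    def test_stationary_profiles_stay_below_3pct(self):
        """Residual CV < 3% in >= 95% of stationary high-count profiles."""
        ok = 0
        seeds = 300
        for s in range(seeds):
            r = np.random.default_rng(50_000 + s)
            prof = _profile(r.poisson(500.0, 100), r.poisson(5000.0, 100))
            if corrected_cv(prof).cv_corrected < 0.03:
                ok += 1
        assert ok / seeds >= 0.95

    def test_drift_is_detected(self):
        """Yield drift of amplitude 0.3 pushes residual CV above 5%."""
        ok = 0
        seeds = 200
        p = np.arange(500)
        lam_el = 100.0 * (1 + 0.3 * np.exp2(-p / 100.0))
        block_lam = np.add.reduceat(lam_el, np.arange(0, 500, 5))
        for s in range(seeds):
            r = np.random.default_rng(60_000 + s)
            prof = _profile(r.poisson(block_lam), r.poisson(5000.0, 100))
            if corrected_cv(prof).cv_corrected > 0.05:
                ok += 1
        assert ok / seeds >= 0.95

    def test_correction_is_nearly_unbiased_under_the_null(self, rng):
        """Mean of cv_obs^2 - CV_P^2 ~ 0: the first-order correction leaves
        only a second-order Poisson residual of order 1/lambda^2."""
        reps, b = 1000, 200
        nel = rng.poisson(50.0, (reps, b))
        nca = rng.poisson(500.0, (reps, b))
        diffs = []
        for i in range(reps):
            qc = corrected_cv(_profile(nel[i], nca[i]))
            diffs.append(qc.cv_obs**2 - qc.cv_poisson**2)
        diffs = np.array(diffs)
        mc_se = diffs.std(ddof=1) / np.sqrt(reps)
        second_order = 2 * (1 / 50**2 + 1 / 500**2)
        assert abs(diffs.mean()) < max(3 * mc_se, second_order)


class TestWindowSelection:
    def test_stationary_profile_keeps_all_blocks(self):
        prof = _profile([100] * 20, [1000] * 20)
        window, qc = select_stable_window(prof)
        assert window == (0, 19)
        assert "unstable" not in qc.flags

    def test_tie_breaks_on_total_ca_then_depth(self):
        """Equal-CV candidates: the higher-Ca window wins."""
        prof = _profile([100, 100, 400, 400], [1000, 1000, 2000, 2000])
        window, qc = select_stable_window(prof, cv_target=0.10, min_fraction=0.5)
        assert window == (2, 3)
        # equal Ca everywhere: the deeper window wins
        prof2 = _profile([100, 100, 200, 200], [1000, 1000, 1000, 1000])
        window2, _ = select_stable_window(prof2, cv_target=0.10, min_fraction=0.5)
        assert window2 == (2, 3)

    def test_contaminated_early_blocks_are_excluded(self):
        """Surface contamination decaying over the first 16 of 100 blocks
        (amplitude and half-life patterned on the salt-speckled scenario)
        is excluded from the selected window in >= 80% of its blocks."""
        b = 100
        halflife_blocks = 16.0
        base_el, base_ca = 5450.0, 12500.0
        g = np.exp2(-np.arange(b) / halflife_blocks)
        contaminated = np.nonzero(g >= 0.5)[0]  # first 16 blocks
        excluded_frac = []
        for s in range(100):
            r = np.random.default_rng(70_000 + s)
            nel = r.poisson(base_el * (1 + 1.7 * g))
            nca = r.poisson(base_ca, b)
            prof = _profile(nel, nca)
            window, _ = select_stable_window(prof)
            excluded = np.sum((contaminated < window[0]) | (contaminated > window[1]))
            excluded_frac.append(excluded / len(contaminated))
        assert np.mean(excluded_frac) >= 0.8

    def test_unstable_flag_when_no_window_qualifies(self):
        prof = _profile([100, 400, 100, 400], [1000, 1000, 1000, 1000])
        window, qc = select_stable_window(prof, cv_target=0.01)
        assert "unstable" in qc.flags

    def test_reported_cv_is_of_the_window_not_full_profile(self):
        """Residual CV reported alongside the window describes that window."""
        nel = np.concatenate([[1000] * 10, [100] * 90])  # step at block 10
        nca = np.full(100, 1000)
        prof = _profile(nel, nca)
        window, qc = select_stable_window(prof)
        assert window[0] >= 10
        full = corrected_cv(prof)
        assert qc.cv_corrected < full.cv_corrected
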