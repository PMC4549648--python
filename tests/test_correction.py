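"""Tests for the ratiometric correction chain."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fretwaves.correction import (
    CellMask,
    CorrectionModel,
    compute_mask,
    compute_ratio,
    correct_fret,
    correct_photobleach,
    correct_shading_background,
    estimate_bleedthrough,
    run_correction_chain,
)
from fretwaves.stacks import ChannelStack
from fretwaves.synthetic import shading_field, simulate_scenario

from conftest import make_config, noise_free, ols_origin_slope


def stack(data, **kw):
    return ChannelStack(np.asarray(data, dtype=np.float64), **kw)


def full_mask(shape):
    return CellMask(mask=np.ones(shape, dtype=bool), thresholds=[None] * shape[0])


class TestShadingBackground:
    def test_identity(self):
        s = stack(np.random.default_rng(0).uniform(10, 100, (3, 8, 8)))
        out, prov = correct_shading_background(s, np.ones((8, 8)), background=0.0)
        np.testing.assert_allclose(out.data, s.data)
        assert prov["background"] == [0.0, 0.0, 0.0]

    def test_exact_inversion(self):
        cfg = make_config()
        shading = shading_field(cfg)
        c, bg = 500.0, 80.0
        s = stack((shading * c + bg)[None])
        out, _ = correct_shading_background(s, shading, background=bg)
        np.testing.assert_allclose(out.data[0], c, rtol=1e-9)

    def test_bowl_shading_flattens_uniform_frame(self):
        # post-correction spatial CV of a uniform-signal frame < 1%
        cfg = make_config()
        shading = shading_field(cfg)
        s = stack((shading * 1000.0 + 50.0)[None])
        out, _ = correct_shading_background(s, shading, background=50.0)
        frame = out.data[0]
        assert frame.std() / frame.mean() < 0.01

    def test_auto_background(self):
        rng = np.random.default_rng(0)
        frame = np.full((32, 32), 40.0)
        frame[8:24, 8:24] = 4000.0  # bright cell
        s = stack(frame[None] + rng.normal(0, 1, (1, 32, 32)) ** 2)
        out, prov = correct_shading_background(s, background="auto")
        assert prov["background"][0] == pytest.approx(40.0, abs=3.0)

    def test_nonpositive_flatfield_rejected(self):
        s = stack(np.ones((1, 4, 4)))
        flat = np.ones((4, 4))
        flat[0, 0] = 0.0
        with pytest.raises(ValueError, match="non-positive"):
            correct_shading_background(s, flat)


class TestPhotobleach:
    def test_constant_stack_identity(self):
        s = stack(np.full((10, 6, 6), 100.0))
        out, k = correct_photobleach(s, full_mask((10, 6, 6)))
        assert k == 0.0
        np.testing.assert_allclose(out.data, s.data)

    def test_noise_free_exact_recovery(self):
        k = 1e-3
        t = np.arange(50)
        data = 2000.0 * np.exp(-k * t)[:, None, None] * np.ones((50, 6, 6))
        out, k_fit = correct_photobleach(stack(data), full_mask(data.shape))
        assert k_fit == pytest.approx(k, abs=1e-6)
        means = out.data.mean(axis=(1, 2))
        np.testing.assert_allclose(means, means[0], rtol=1e-6)

    def test_noisy_recovery_within_10pct(self):
        # oracle: the seeded decay rate; spread over 20 seeds
        k, T = 5e-4, 900
        t = np.arange(T)
        errs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            lam = 2000.0 * np.exp(-k * t)[:, None, None] * np.ones((T, 24, 24))
            data = rng.poisson(lam * 0.5) / 0.5
            _, k_fit = correct_photobleach(stack(data), full_mask(data.shape))
            errs.append(abs(k_fit - k) / k)
        assert max(errs) < 0.10

    def test_empty_mask_rejected(self):
        s = stack(np.ones((6, 4, 4)))
        mask = full_mask((6, 4, 4))
        mask.mask[3] = False
        with pytest.raises(ValueError, match="frame 3"):
            correct_photobleach(s, mask)

    def test_too_few_frames_rejected(self):
        s = stack(np.ones((3, 4, 4)))
        with pytest.raises(ValueError, match="5 frames"):
            correct_photobleach(s, full_mask((3, 4, 4)))


class TestBleedthrough:
    def _pair(self, donor, acceptor):
        return stack(donor), stack(acceptor)

    def test_exact_slope(self):
        rng = np.random.default_rng(0)
        d = rng.uniform(100, 4000, (2, 40, 40))
        model = estimate_bleedthrough(self._pair(d, 0.6 * d))
        assert model.alpha == pytest.approx(0.6, abs=1e-12)

    def test_zero_spillover(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(100, 4000, (2, 40, 40))
        model = estimate_bleedthrough(None, self._pair(a, np.zeros_like(a)))
        assert model.alpha == 0.0
        assert model.beta == 0.0

    def test_matches_ols_oracle_with_noise(self):
        rng = np.random.default_rng(42)
        alpha = 0.35
        x = rng.uniform(200, 4000, (1, 100, 100))  # 1e4 pixels
        y = alpha * x * (1 + 0.01 * rng.standard_normal(x.shape))
        model = estimate_bleedthrough(self._pair(x, y))
        slope, se = ols_origin_slope(x.ravel(), y.ravel())
        assert model.alpha == pytest.approx(0.35, abs=0.01)
        assert abs(model.alpha - slope) <= max(se, model.alpha_se)

    def test_too_few_pixels_rejected(self):
        d = np.full((1, 5, 5), 1000.0)
        with pytest.raises(ValueError, match="too few"):
            estimate_bleedthrough(self._pair(d, d))

    def test_negative_slope_clipped_with_warning(self):
        # raw ndarray pairs are accepted (e.g. over-subtracted controls)
        rng = np.random.default_rng(0)
        x = rng.uniform(100, 4000, (1, 40, 40))
        with pytest.warns(UserWarning, match="clipped"):
            model = estimate_bleedthrough((x, -0.2 * x))
        assert model.alpha == 0.0


class TestCorrectFret:
    def test_arithmetic(self):
        raw = stack(np.full((1, 2, 2), 100.0))
        donor = stack(np.full((1, 2, 2), 50.0))
        direct = stack(np.full((1, 2, 2), 20.0))
        out = correct_fret(raw, donor, alpha=0.6, beta=0.5, acceptor_direct=direct)
        np.testing.assert_allclose(out.data, 60.0)

    def test_identity_when_zero_coefficients(self):
        raw = stack(np.random.default_rng(0).uniform(0, 100, (2, 4, 4)))
        donor = stack(np.ones((2, 4, 4)))
        out = correct_fret(raw, donor, alpha=0.0, beta=0.0)
        np.testing.assert_allclose(out.data, raw.data)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            correct_fret(stack(np.ones((1, 4, 4))), stack(np.ones((1, 5, 5))), 0.1)

    def test_estimated_alpha_recovers_true_fret(self):
        cfg = noise_free(n_frames=10, activity={"baseline": 1.2})
        donor, acceptor, truth = simulate_scenario(cfg)
        from fretwaves.synthetic import render_controls

        controls = render_controls(cfg)
        # controls rendered noise-free enter the fit shading/bg corrected
        flat = shading_field(cfg)
        ref, fr = controls["donor_only"]
        ref_c, _ = correct_shading_background(ref, flat, cfg.nuisance.background_donor)
        fr_c, _ = correct_shading_background(fr, flat, cfg.nuisance.background_acceptor)
        model = estimate_bleedthrough((ref_c, fr_c))
        assert model.alpha == pytest.approx(cfg.nuisance.alpha, abs=0.005)

        result = run_correction_chain(
            donor, acceptor, flatfield=flat,
            background=cfg.nuisance.background_donor,
            controls={"donor_only": (ref_c, fr_c)},
        )
        fret_true = cfg.nuisance.donor_brightness * truth.activity * truth.mask
        ok = truth.mask & (fret_true > 0)
        err = np.abs(result.fret.data[ok] - fret_true[ok]) / fret_true[ok]
        assert err.mean() < 0.02


class TestMask:
    def test_two_level_frame_exact(self):
        frame = np.full((32, 32), 10.0)
        frame[10:20, 12:22] = 1000.0
        mask = compute_mask(stack(frame[None]))
        expected = frame > 10.0
        np.testing.assert_array_equal(mask.mask[0], expected)
        assert not mask.degenerate[0]

    def test_constant_frame_degenerate(self):
        mask = compute_mask(stack(np.full((1, 16, 16), 7.0)))
        assert mask.degenerate[0]
        assert not mask.mask[0].any()

    def test_jaccard_vs_truth(self):
        cfg = make_config(n_frames=10)
        donor, _, truth = simulate_scenario(cfg)
        corrected, _ = correct_shading_background(
            donor, shading_field(cfg), cfg.nuisance.background_donor
        )
        mask = compute_mask(corrected)
        inter = (mask.mask & truth.mask).sum()
        union = (mask.mask | truth.mask).sum()
        assert inter / union >= 0.95

    @given(
        thr1=st.floats(0.1, 0.5),
        delta=st.floats(0.01, 0.4),
        seed=st.integers(0, 100),
    )
    @settings(max_examples=25, deadline=None)
    def test_threshold_monotonicity(self, thr1, delta, seed):
        # raising the threshold never grows the foreground
        frame = np.random.default_rng(seed).uniform(0, 1, (16, 16))
        lo = frame > thr1
        hi = frame > thr1 + delta
        assert not (hi & ~lo).any()


class TestRatio:
    def _mask(self, shape, inside):
        m = np.zeros(shape, dtype=bool)
        m[(slice(None),) + inside] = True
        return CellMask(mask=m, thresholds=[None] * shape[0])

    def test_ratio_one_inside_mask(self):
        shape = (2, 8, 8)
        inside = (slice(2, 6), slice(2, 6))
        donor = stack(np.full(shape, 200.0))
        mask = self._mask(shape, inside)
        ratio = compute_ratio(donor.with_data(donor.data.copy()), donor, mask)
        assert np.all(ratio.data[mask.mask] == pytest.approx(1.0))

    def test_outside_mask_undefined(self):
        shape = (1, 8, 8)
        donor = stack(np.full(shape, 200.0))
        mask = self._mask(shape, (slice(2, 6), slice(2, 6)))
        ratio = compute_ratio(donor, donor, mask)
        assert np.isnan(ratio.data[~mask.mask]).all()

    def test_epsilon_bounds(self):
        donor = stack(np.ones((1, 4, 4)))
        mask = full_mask((1, 4, 4))
        for eps in (0.0, 1.0, -0.2, 1.5):
            with pytest.raises(ValueError, match="epsilon"):
                compute_ratio(donor, donor, mask, epsilon=eps)

    def test_dim_pixels_undefined(self):
        shape = (1, 8, 8)
        donor_data = np.full(shape, 200.0)
        donor_data[0, 0, :] = 1.0  # below 5% of median
        donor = stack(donor_data)
        ratio = compute_ratio(donor, donor, full_mask(shape))
        assert np.isnan(ratio.data[0, 0]).all()

    def test_invariant_to_common_rescaling(self):
        cfg = noise_free(n_frames=6)
        donor, acceptor, _ = simulate_scenario(cfg)
        res1 = run_correction_chain(
            donor, acceptor, alpha=cfg.nuisance.alpha, background=100.0
        )
        donor2 = donor.with_data(donor.data * 3.0)
        acceptor2 = acceptor.with_data(acceptor.data * 3.0)
        res2 = run_correction_chain(
            donor2, acceptor2, alpha=cfg.nuisance.alpha, background=300.0
        )
        np.testing.assert_allclose(res1.ratio.data, res2.ratio.data, rtol=1e-5)


class TestModelValidation:
    def test_negative_alpha_rejected(self):
        with pytest.raises(ValueError):
            CorrectionModel(alpha=-0.1)

    def test_implausible_alpha_warns(self):
        with pytest.warns(UserWarning, match="implausible"):
            CorrectionModel(alpha=1.2)

    def test_chain_requires_alpha_source(self):
        cfg = noise_free(n_frames=4)
        donor, acceptor, _ = simulate_scenario(cfg)
        with pytest.raises(ValueError, match="bleedthrough"):
            run_correction_chain(donor, acceptor, background=100.0)

    def test_provenance_records_chain_order(self):
        cfg = noise_free(n_frames=6)
        donor, acceptor, _ = simulate_scenario(cfg)
        res = run_correction_chain(
            donor, acceptor, alpha=cfg.nuisance.alpha, background=100.0
        )
        assert res.provenance["chain_order"] == [
            "background_subtraction",
            "shading_division",
            "masking",
            "photobleach",
            "bleedthrough",
            "ratio",
        ]
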