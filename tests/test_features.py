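"""Pearson gate, LPC/LPCC and spider-web descriptor contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy import stats

from momofuse.errors import ParameterError
from momofuse.features import (
    LPCCConfig,
    SpiderWebConfig,
    ambient_gate,
    lpc_coefficients,
    lpcc,
    lpcc_window,
    pearson_correlation,
    slif_descriptor,
    spider_web_points,
)
from momofuse.skeleton import POINT_NAMES, SkeletonFrame

from .oracles import lpc_normal_equations, lpcc_brute_force, pearson_direct


class TestPearsonCorrelation:
    def test_self_correlation(self):
        assert pearson_correlation([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_anti_correlation(self):
        assert pearson_correlation([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_hand_oracle_value(self):
        assert pearson_correlation([1, 2, 3], [1, 2, 4]) == pytest.approx(
            pearson_direct([1, 2, 3], [1, 2, 4])
        )
        assert pearson_correlation([1, 2, 3], [1, 2, 4]) == pytest.approx(0.98198, abs=1e-5)

    def test_matches_direct_formula_on_random_pairs(self, rng):
        for _ in range(50):
            g, h = rng.normal(size=(2, 30))
            assert pearson_correlation(g, h) == pytest.approx(
                pearson_direct(list(g), list(h)), abs=1e-12
            )

    def test_scale_shift_invariance_and_symmetry(self, rng):
        g, h = rng.normal(size=(2, 40))
        r = pearson_correlation(g, h)
        assert pearson_correlation(h, g) == pytest.approx(r)
        assert pearson_correlation(3.2 * g + 1.0, h) == pytest.approx(r)
        assert pearson_correlation(-2.0 * g, h) == pytest.approx(-r)

    @settings(derandomize=True, max_examples=60)
    @given(
        g=arrays(np.float64, 25, elements=st.floats(-100, 100)),
        h=arrays(np.float64, 25, elements=st.floats(-100, 100)),
    )
    def test_always_bounded_by_one(self, g, h):
        r = pearson_correlation(g, h)
        assert -1 - 1e-12 <= r <= 1 + 1e-12

    def test_constant_input_degenerate_zero(self):
        assert pearson_correlation([5, 5, 5], [1, 2, 3]) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ParameterError):
            pearson_correlation([1, 2], [1, 2, 3])


class TestAmbientGate:
    def test_identical_channels_fire(self):
        x = np.sin(np.arange(40))[:, None]
        res = ambient_gate(np.hstack([x, x]))
        assert res.mean_abs_pc == pytest.approx(1.0)
        assert res.action_flag

    def test_constant_channels_do_not_fire(self):
        res = ambient_gate(np.ones((40, 3)))
        assert res.mean_abs_pc == 0.0 and not res.action_flag and res.degenerate

    def test_null_flag_rate_matches_theory(self, rng):
        """Two independent white-noise channels of length 100: the gate fires
        when |r| > 0.04, which under the null happens with p ~= 0.69."""
        fires = sum(
            ambient_gate(rng.normal(size=(100, 2))).action_flag for _ in range(1000)
        )
        expected = 2 * stats.norm.sf(0.04 * np.sqrt(99))
        assert fires / 1000 == pytest.approx(expected, abs=0.1)

    def test_feature_vector_layout(self):
        res = ambient_gate(np.random.default_rng(0).normal(size=(40, 4)))
        assert res.feature_vector.shape == (6 + 2,)
        assert res.feature_vector[-2] == pytest.approx(res.mean_abs_pc)

    def test_single_channel_falls_back_to_autocorrelation(self):
        res = ambient_gate(np.sin(np.arange(60) * 0.3)[:, None])
        assert res.pc_matrix.shape == (1, 1)
        assert res.action_flag  # smooth signal: strong lag-1 autocorrelation


class TestLPC:
    def test_ar1_coefficient_recovered(self, rng):
        x = np.zeros(4000)
        eps = rng.normal(size=4000)
        for i in range(1, 4000):
            x[i] = 0.8 * x[i - 1] + eps[i]
        a = lpc_coefficients(x, 1)
        assert a[0] == pytest.approx(0.8, abs=0.05)

    def test_white_noise_coefficients_near_zero(self, rng):
        a = lpc_coefficients(rng.normal(size=4000), 2)
        assert np.all(np.abs(a) < 0.1)

    def test_matches_normal_equations_oracle(self, rng):
        x = rng.normal(size=800)
        x = np.convolve(x, [1, 0.5, 0.2], mode="same")
        assert lpc_coefficients(x, 4) == pytest.approx(
            lpc_normal_equations(x, 4), abs=5e-2
        )

    def test_short_signal_rejected(self):
        with pytest.raises(ParameterError):
            lpc_coefficients(np.ones(8) + np.arange(8), 4)

    def test_constant_signal_rejected(self):
        with pytest.raises(ParameterError):
            lpc_coefficients(np.full(100, 3.0), 4)


class TestLPCC:
    def test_zero_propagation(self):
        assert np.all(lpcc(np.zeros(4), 4, 8) == 0)

    def test_closed_form_p1(self):
        c = lpcc(np.array([0.5]), 1, 2)
        assert c == pytest.approx([0.5, 0.125])  # c2 = (1/2) c1 a1

    def test_equals_brute_force_oracle(self, rng):
        for _ in range(200):
            p = int(rng.integers(1, 9))
            d = p + int(rng.integers(0, 6))
            a = rng.uniform(-0.9, 0.9, size=p) / p  # stable-ish filters
            assert np.max(np.abs(lpcc(a, p, d) - lpcc_brute_force(a, p, d))) <= 1e-12

    @settings(derandomize=True, max_examples=60)
    @given(
        a=arrays(np.float64, st.integers(1, 8),
                 elements=st.floats(-0.5, 0.5)),
        extra=st.integers(0, 5),
    )
    def test_recursion_equals_oracle_for_any_coefficients(self, a, extra):
        p = len(a)
        d = p + extra
        assert np.max(np.abs(lpcc(a, p, d) - lpcc_brute_force(a, p, d))) <= 1e-12

    def test_d_smaller_than_p_rejected(self):
        with pytest.raises(ParameterError):
            lpcc(np.ones(4), 4, 3)

    def test_window_feature_length_fixed(self, rng):
        cfg = LPCCConfig(p=6, d=8)
        x = rng.normal(size=(100, 3))
        x[:, 2] = 1.0  # flat channel cannot carry an LPC model -> zero block
        f = lpcc_window(x, cfg)
        assert f.shape == (3 * 8,)
        assert np.all(f[16:] == 0)


class TestSpiderWeb:
    def test_zero_angle_offset(self):
        pts = spider_web_points([0, 0], SpiderWebConfig(rings=(2.0,), spokes=4))
        assert pts[0, 0] == pytest.approx([2, 0])

    def test_quarter_turn_offset(self):
        pts = spider_web_points([0, 0], SpiderWebConfig(rings=(2.0,), spokes=4))
        assert pts[0, 1] == pytest.approx([0, 2], abs=1e-12)

    def test_unit_circle_table(self):
        pts = spider_web_points([0, 0], SpiderWebConfig(rings=(1.0,), spokes=8))
        expected = [(np.cos(2 * np.pi * z / 8), np.sin(2 * np.pi * z / 8))
                    for z in range(8)]
        assert pts[0] == pytest.approx(np.array(expected))

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ParameterError):
            SpiderWebConfig(rings=(4.0, 2.0))
        with pytest.raises(ParameterError):
            SpiderWebConfig(spokes=3)


class TestSlifDescriptor:
    def _skeleton(self, xy=(50.0, 50.0)):
        pts = np.tile(np.asarray(xy, dtype=float), (12, 1))
        return SkeletonFrame(points=pts, confidence=np.ones(12))

    def test_full_mask_all_ones(self):
        cfg = SpiderWebConfig(rings=(4.0, 8.0), spokes=8)
        d = slif_descriptor(np.ones((100, 100), bool), self._skeleton(), cfg)
        assert d.shape == (12 * (2 * 8 + 1),)
        assert np.all(d == 1.0)

    def test_empty_mask_all_zeros(self):
        d = slif_descriptor(np.zeros((100, 100), bool), self._skeleton())
        assert np.all(d == 0.0)

    def test_disk_containment(self):
        r = 16
        yy, xx = np.mgrid[0:100, 0:100]
        mask = (xx - 50) ** 2 + (yy - 50) ** 2 <= r**2
        cfg = SpiderWebConfig(rings=(r / 2, 2 * r), spokes=8,
                              anchors=("torso",))
        d = slif_descriptor(mask, self._skeleton(), cfg)
        inner, outer = d[:8], d[8:16]
        assert np.all(inner == 1.0) and np.all(outer == 0.0)

    def test_missing_anchor_zero_filled(self):
        sk = self._skeleton()
        sk.points[0] = np.nan
        cfg = SpiderWebConfig(rings=(4.0,), spokes=8, anchors=("head", "torso"))
        d = slif_descriptor(np.ones((100, 100), bool), sk, cfg)
        assert np.all(d[:9] == 0.0) and np.all(d[9:] == 1.0)

    def test_translation_equivariance(self, rng):
        mask = np.zeros((120, 120), bool)
        mask[30:70, 40:80] = True
        sk = self._skeleton((60.0, 50.0))
        cfg = SpiderWebConfig(rings=(5.0, 9.0), spokes=8)
        d1 = slif_descriptor(mask, sk, cfg)
        shifted = np.roll(np.roll(mask, 7, axis=0), 11, axis=1)
        sk2 = self._skeleton((71.0, 57.0))
        d2 = slif_descriptor(shifted, sk2, cfg)
        assert np.array_equal(d1, d2)
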