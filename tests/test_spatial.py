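"""Lattice geometry, angular tuning, sin/cos regression and decoding."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pherospace.spatial import (BilateralResponse, angular_error_deg,
                                angular_tuning, bilateral_contrast,
                                build_hex_lattice, cross_validate_decoder,
                                decode, fit_decoder, sincos_regression,
                                wrap_angle_deg)
from pherospace.synthetic import ForwardModelParams, generate_lattice_session


def brute_force_lattice(spacing, max_distance):
    """Independent enumeration of hexagonal-lattice points."""
    pts = set()
    k = int(np.ceil(max_distance / spacing)) + 2
    for i in range(-k, k + 1):
        for j in range(-k, k + 1):
            x = spacing * (i + j / 2)
            y = spacing * (j * np.sqrt(3) / 2)
            r = np.hypot(x, y)
            if 1e-9 < r <= max_distance + 1e-9:
                ang = np.degrees(np.arctan2(y, x))
                if abs(abs(((ang + 180) % 360) - 180) - 180) > 1e-6:
                    pts.add((round(x, 9), round(y, 9)))
    return pts


class TestHexLattice:
    def test_default_census(self, lattice):
        assert len(lattice) == 16
        assert len(lattice.unique_angles) == 11
        assert sorted(set(np.round(lattice.distances, 3))) == \
            pytest.approx([1.0, 1.732, 2.0])

    def test_two_points_removed_behind(self):
        # before excluding 180°, three rings of 6 points each would give
        # 18; the 1 mm and 2 mm rings each lose their rearmost point
        kept = brute_force_lattice(1.0, 2.0)
        assert len(kept) == 16

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(20):
            spacing = float(rng.uniform(0.5, 2.0))
            max_d = spacing * float(rng.uniform(1.0, 3.0))
            lat = build_hex_lattice(spacing, max_d)
            got = {(round(x, 9), round(y, 9)) for x, y in lat.positions}
            assert got == brute_force_lattice(spacing, max_d)

    def test_angle_convention(self, lattice):
        a = lattice.unique_angles
        assert 0.0 in a and 180.0 not in a and -180.0 not in a
        assert np.allclose(sorted(a), np.arange(-150, 151, 30))

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            build_hex_lattice(spacing=1.0, max_distance=0.5)


class TestBilateralContrast:
    def test_illustrative_decomposition(self):
        assert bilateral_contrast(0.6, 0.18) == pytest.approx(0.42)

    def test_equal_means_zero_and_sign(self):
        assert bilateral_contrast(0.5, 0.5) == 0.0
        assert bilateral_contrast(0.2, 0.5) < 0


def session(params=None, lattice=None, **kw):
    params = params or ForwardModelParams(noise_sd=0.0)
    lattice = lattice or build_hex_lattice()
    return generate_lattice_session(params, lattice, **kw)


class TestAngularTuning:
    def test_interpolation_arithmetic(self, lattice):
        # plant left responses: 1.0 on the 1 mm ring, 0.5 on the 2 mm ring
        resp = []
        for i, d in enumerate(lattice.distances):
            v = {1.0: 1.0, 2.0: 0.5}.get(round(float(d), 6), 0.7)
            resp.append(BilateralResponse(fly_id=0, trial=0, pos_index=i,
                                          left=v, right=v))
        tun = angular_tuning(resp, lattice)
        at0 = tun.left_mean[list(tun.angles).index(0.0)]
        assert at0 == pytest.approx((2 - np.sqrt(3)) * 1.0
                                    + (np.sqrt(3) - 1) * 0.5, abs=1e-12)
        assert at0 == pytest.approx(0.634, abs=1e-3)

    def test_direct_angles_pass_through(self, lattice):
        resp = []
        for i, d in enumerate(lattice.distances):
            v = 0.9 if abs(d - np.sqrt(3)) < 1e-6 else 0.1
            resp.append(BilateralResponse(fly_id=0, trial=0, pos_index=i,
                                          left=v, right=v))
        tun = angular_tuning(resp, lattice)
        direct = tun.provenance == "direct"
        assert direct.sum() == 6 and (~direct).sum() == 5
        assert np.allclose(tun.left_mean[direct], 0.9)

    def test_symmetric_model_gives_mirror_tuning(self, lattice):
        tun = angular_tuning(session(n_flies=2, n_trials=2, seed=0), lattice)
        for k, a in enumerate(tun.angles):
            j = list(tun.angles).index(-a)
            assert tun.left_mean[k] == pytest.approx(tun.right_mean[j],
                                                     abs=1e-12)


class TestSincosRegression:
    def test_pure_sine_recovered(self):
        ang = np.arange(-150, 151, 30)
        reg = sincos_regression(ang, 0.5 * np.sin(np.radians(ang)),
                                np.cos(np.radians(ang)))
        slope, _, r2 = reg["diff_vs_sin"]
        assert r2 == pytest.approx(1.0) and slope == pytest.approx(0.5)

    def test_noiseless_forward_model_gives_unit_r2(self, lattice):
        tun = angular_tuning(session(seed=0), lattice)
        reg = sincos_regression(tun.angles, tun.right_mean - tun.left_mean,
                                tun.right_mean + tun.left_mean)
        assert reg["diff_vs_sin"][2] == pytest.approx(1.0, abs=1e-12)
        assert reg["sum_vs_cos"][2] == pytest.approx(1.0, abs=1e-12)

    def test_antisymmetric_signal_orthogonal_to_cosine(self):
        ang = np.arange(-150, 151, 30)
        diff = 0.5 * np.sin(np.radians(ang))
        reg = sincos_regression(ang, diff, diff)
        assert reg["sum_vs_cos"][2] < 0.05


class TestDecoder:
    def test_identity_mapping_coefficients(self, lattice):
        # craft responses whose sum equals x and diff equals y exactly
        resp = []
        for i, (x, y) in enumerate(lattice.positions):
            resp.append(BilateralResponse(fly_id=0, trial=0, pos_index=i,
                                          left=(x - y) / 2, right=(x + y) / 2))
        model = fit_decoder(resp, lattice, target="position")
        assert model.coef_x == pytest.approx((0.0, 1.0, 0.0), abs=1e-9)
        assert model.coef_y == pytest.approx((1.0, 0.0, 0.0), abs=1e-9)

    def test_coefficients_match_normal_equations(self, lattice, rng):
        resp = [BilateralResponse(fly_id=0, trial=t, pos_index=i,
                                  left=float(rng.uniform(0, 1)),
                                  right=float(rng.uniform(0, 1)))
                for t in range(3) for i in range(len(lattice))]
        model = fit_decoder(resp, lattice)
        X = np.array([[r.diff, r.sum, 1.0] for r in resp])
        ang = np.radians(lattice.angles_deg)
        tx = np.cos(ang)[[r.pos_index for r in resp]]
        cx = np.linalg.solve(X.T @ X, X.T @ tx)
        assert model.coef_x == pytest.approx(tuple(cx), abs=1e-9)

    def test_constant_sum_shift_moves_only_intercepts(self, lattice):
        resp = session(n_flies=2, n_trials=1, seed=1)
        shifted = [BilateralResponse(fly_id=r.fly_id, trial=r.trial,
                                     pos_index=r.pos_index,
                                     left=r.left + 0.5, right=r.right + 0.5)
                   for r in resp]
        m0 = fit_decoder(resp, lattice)
        m1 = fit_decoder(shifted, lattice)
        assert m0.coef_x[:2] == pytest.approx(m1.coef_x[:2], abs=1e-9)
        assert m0.coef_y[:2] == pytest.approx(m1.coef_y[:2], abs=1e-9)

    def test_wraparound_error(self):
        assert angular_error_deg(170.0, -170.0) == pytest.approx(20.0)
        assert wrap_angle_deg(190.0) == pytest.approx(-170.0)

    def test_loo_exact_on_noiseless_data(self, lattice):
        res = cross_validate_decoder(session(seed=0), lattice,
                                     scheme="loo-trial")
        assert res.angular_error_deg.max() <= 1e-6

    def test_leftright_flip_negates_predicted_angles(self, lattice):
        # exact on noiseless data, where the fitted model is antisymmetric
        resp = session(params=ForwardModelParams(noise_sd=0.0), seed=4,
                       n_flies=2, n_trials=2)
        model = fit_decoder(resp, lattice)
        flipped = [BilateralResponse(fly_id=r.fly_id, trial=r.trial,
                                     pos_index=r.pos_index,
                                     left=r.right, right=r.left)
                   for r in resp]
        a = decode(model, resp, lattice).pred_angle_deg
        b = decode(model, flipped, lattice).pred_angle_deg
        assert np.allclose(wrap_angle_deg(a + b), 0.0, atol=1e-9)

    def test_sum_diff_transform_invertible(self, rng):
        L = rng.uniform(0, 1, 50)
        R = rng.uniform(0, 1, 50)
        s, d = L + R, R - L
        assert np.allclose((s - d) / 2, L) and np.allclose((s + d) / 2, R)

    def test_error_decreases_with_noise(self, lattice):
        meds = []
        for sd in (0.2, 0.05, 0.01):
            errs = []
            for seed in range(10):
                resp = session(params=ForwardModelParams(noise_sd=sd),
                               seed=seed)
                errs.append(cross_validate_decoder(
                    resp, lattice, scheme="loo-fly").median_angular_error)
            meds.append(np.median(errs))
        assert meds[0] > meds[1] > meds[2]


@settings(deadline=None, max_examples=25)
@given(st.integers(0, 2**31 - 1))
def test_wrap_angle_involution(seed):
    r = np.random.default_rng(seed)
    a = r.uniform(-1000, 1000, 20)
    w = wrap_angle_deg(a)
    assert np.all((w > -180.0 - 1e-12) & (w <= 180.0 + 1e-12))
    assert np.allclose(np.cos(np.radians(w)), np.cos(np.radians(a)))
    assert np.allclose(np.sin(np.radians(w)), np.sin(np.radians(a)))
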