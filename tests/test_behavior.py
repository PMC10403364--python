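"""Behavioral metrics: cleaning, OSP, turns, circular stats, treadmill."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pherospace.behavior import (CircularSample, TrackedPair, TreadmillTrial,
                                 circular_median, circular_median_test,
                                 classify_treadmill_trial, clean_tracks,
                                 displacement_permutation_test,
                                 lateral_displacement, osp_score,
                                 relative_orientation)
from pherospace.synthetic import generate_treadmill_trial


def static_pair(n=100, fs=30.0, rx=0.0, ry=0.0, rori=0.0, sx=3.0, sy=0.0):
    return TrackedPair(
        fs=fs,
        receiver_x=np.full(n, rx), receiver_y=np.full(n, ry),
        receiver_orientation=np.full(n, rori),
        stimulus_x=np.full(n, sx), stimulus_y=np.full(n, sy),
        stimulus_orientation=np.zeros(n))


class TestCleanTracks:
    def test_clean_track_unchanged(self):
        pair = static_pair()
        assert clean_tracks(pair).valid.all()

    def test_velocity_jump_removed(self):
        pair = static_pair()
        pair.receiver_x[50] = 2.0  # 2 mm in one 30 Hz frame = 60 mm/s
        out = clean_tracks(pair)
        assert not out.valid[50]

    def test_orientation_flip_removed(self):
        pair = static_pair()
        pair.receiver_orientation[50:] = 30.0  # 900 deg/s at the step
        out = clean_tracks(pair)
        assert not out.valid[50]


class TestOsp:
    def _pair_near(self, frac, n=1200, fs=30.0):
        """Receiver within 5 mm of the stimulus for `frac` of the time."""
        near = int(n * frac)
        x = np.r_[np.full(near, 3.0), np.full(n - near, -4.0)]
        return TrackedPair(fs=fs, receiver_x=x, receiver_y=np.zeros(n),
                           receiver_orientation=np.zeros(n),
                           stimulus_x=np.full(n, 4.0),
                           stimulus_y=np.zeros(n),
                           stimulus_orientation=np.zeros(n),
                           arena_radius=8.0)

    def test_score_arithmetic(self):
        res = osp_score(self._pair_near(0.5), self._pair_near(0.25))
        assert res.osp == pytest.approx(25.0)

    def test_identical_trajectories_zero(self):
        res = osp_score(self._pair_near(0.4), self._pair_near(0.4))
        assert res.osp == 0.0

    def test_antisymmetric_under_swap(self):
        a, b = self._pair_near(0.6), self._pair_near(0.2)
        assert osp_score(a, b).osp == pytest.approx(-osp_score(b, a).osp)

    def test_rim_frames_excluded(self):
        pair = self._pair_near(0.5)
        pair.receiver_x[:] = 7.0  # 1 mm from the wall, 3 mm from stimulus
        res = osp_score(pair, self._pair_near(0.0))
        assert res.osp == 0.0

    def test_discrete_profile_sums_to_cumulative(self):
        res = osp_score(self._pair_near(0.5), self._pair_near(0.2))
        total = sum(res.discrete_profile.values())
        largest = res.cumulative_profile[max(res.cumulative_profile)]
        assert total == pytest.approx(largest, abs=1e-9)


class TestRelativeOrientation:
    def test_stimulus_ahead_is_zero(self):
        assert relative_orientation(static_pair(rori=0.0, sx=3.0), 0) == \
            pytest.approx(0.0)

    def test_stimulus_due_right_is_plus_ninety(self):
        # receiver faces north (+y); stimulus to the east = its right
        pair = static_pair(rori=90.0, sx=3.0, sy=0.0)
        assert relative_orientation(pair, 0) == pytest.approx(90.0)

    def test_invariant_under_world_rotation(self, rng):
        for _ in range(20):
            rx, ry = rng.uniform(-3, 3, 2)
            sx, sy = rng.uniform(-3, 3, 2)
            if math.hypot(sx - rx, sy - ry) < 1e-3:
                continue
            ori = float(rng.uniform(-180, 180))
            base = relative_orientation(
                static_pair(rx=rx, ry=ry, rori=ori, sx=sx, sy=sy), 0)
            phi = float(rng.uniform(-180, 180))
            c, s = math.cos(math.radians(phi)), math.sin(math.radians(phi))
            rot = lambda x, y: (c * x - s * y, s * x + c * y)  # noqa: E731
            rrx, rry = rot(rx, ry)
            rsx, rsy = rot(sx, sy)
            rotated = relative_orientation(
                static_pair(rx=rrx, ry=rry, rori=ori + phi, sx=rsx, sy=rsy), 0)
            assert rotated == pytest.approx(base, abs=1e-6)

    def test_coincident_positions_rejected(self):
        with pytest.raises(ValueError):
            relative_orientation(static_pair(sx=0.0, sy=0.0), 0)


class TestCircularMedian:
    def test_simple_median(self):
        assert circular_median(np.array([10.0, 20.0, 30.0])) == \
            pytest.approx(20.0)

    def test_wraparound_midpoint(self):
        med = circular_median(np.array([350.0, 10.0]))
        assert abs(med) == pytest.approx(0.0, abs=1e-9)

    @settings(deadline=None, max_examples=60)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_exhaustive_minimization(self, seed):
        r = np.random.default_rng(seed)
        angles = r.uniform(0, 360, r.integers(3, 12))
        med = circular_median(angles)

        def total_dist(c):
            d = np.abs(angles - c) % 360
            return np.minimum(d, 360 - d).sum()

        grid = np.arange(0, 360, 0.05)
        best = min(total_dist(c) for c in grid)
        assert total_dist(med) <= best + 1e-6


class TestCircularMedianTest:
    def test_identical_samples_large_p(self):
        a = np.array([10.0, 25.0, 40.0, 55.0, 70.0, 85.0])
        rep = circular_median_test(a, a.copy())
        assert rep["p_value"] > 0.9

    def test_offset_groups_detected(self):
        rng = np.random.default_rng(0)
        for s in range(5):
            g1 = np.degrees(rng.vonmises(0, 5, 50))
            g2 = np.degrees(rng.vonmises(np.pi / 2, 5, 50))
            assert circular_median_test(g1, g2)["p_value"] < 0.01

    def test_insufficient_data_rejected(self):
        with pytest.raises(ValueError):
            circular_median_test([1.0, 2.0], [3.0, 4.0, 5.0, 6.0, 7.0])


class TestTreadmill:
    def test_all_zero_is_no_movement(self):
        t = TreadmillTrial(forward=np.zeros(400), lateral=np.zeros(400),
                           rotational=np.zeros(400))
        assert classify_treadmill_trial(t) == "no_movement"

    def test_constant_forward_is_constant_movement(self):
        t = TreadmillTrial(forward=np.ones(400), lateral=np.zeros(400),
                           rotational=np.zeros(400))
        assert classify_treadmill_trial(t) == "constant_movement"

    def test_burst_from_rest_is_valid(self):
        t = generate_treadmill_trial(noise_sd=0.0)
        assert classify_treadmill_trial(t) == "valid"

    def test_pure_lateral_one_second(self):
        t = generate_treadmill_trial(response_lateral=1.0,
                                     response_rotation=0.0, noise_sd=0.0)
        assert lateral_displacement(t) == pytest.approx(1.0, abs=0.05)

    def test_pure_forward_gives_zero_lateral(self):
        t = generate_treadmill_trial(response_lateral=0.0,
                                     response_rotation=0.0, noise_sd=0.0)
        assert lateral_displacement(t) == pytest.approx(0.0, abs=0.02)

    def test_rotation_then_forward_matches_fine_integration(self):
        # 90 deg/s rotation for 0.5 s, then 2 mm/s forward for 0.5 s
        fs = 50.0
        n = int(8 * fs) + 1
        t = np.arange(n) / fs
        rot = np.where((t >= 2.5) & (t < 3.0), 90.0, 0.0)
        fwd = np.where((t >= 3.0) & (t < 3.5), 2.0, 0.0)
        # keep the onset detectable: nonzero speed from 2.5 s onward
        trial = TreadmillTrial(forward=fwd, lateral=np.zeros(n),
                               rotational=rot, fs=fs, stim_side="right",
                               stim_window=(2.0, 5.0))
        got = lateral_displacement(trial)
        # fine-step oracle
        dt = 1e-4
        tt = np.arange(2.5, 3.5, dt)
        psi = np.cumsum(np.where(tt < 3.0, 90.0, 0.0) * dt)
        v = np.where(tt >= 3.0, 2.0, 0.0)
        expect = np.sum(v * np.sin(np.radians(psi)) * dt)
        assert got == pytest.approx(expect, abs=0.05)

    def test_left_presentation_flips_sign(self):
        tr = generate_treadmill_trial(stim_side="left", noise_sd=0.0)
        # response_lateral is toward the stimulus side, so the signed
        # displacement toward the stimulus is still positive
        assert lateral_displacement(tr) == pytest.approx(1.0, abs=0.05)


class TestPermutationTest:
    def test_identical_groups_large_p(self):
        a = [1.0, 2.0, 3.0, 4.0]
        rep = displacement_permutation_test(a, list(a))
        assert rep["p_value"] == pytest.approx(1.0)

    def test_shifted_groups_detected(self, rng):
        a = rng.normal(1.0, 0.2, 20)
        b = rng.normal(0.0, 0.2, 20)
        rep = displacement_permutation_test(a, b, n_perm=2000, seed=1)
        assert rep["p_value"] < 0.01

    def test_exact_enumeration_matches_monte_carlo(self, rng):
        a = rng.normal(0.3, 1.0, 4)
        b = rng.normal(0.0, 1.0, 4)
        exact = displacement_permutation_test(a, b)
        assert exact["method"] == "exact"
        mc = displacement_permutation_test(a, b, n_perm=20_000, seed=3,
                                           exact_limit=0)
        assert mc["p_value"] == pytest.approx(exact["p_value"], abs=0.01)

    def test_exact_p_matches_independent_enumeration(self, rng):
        a = list(rng.normal(0.5, 1.0, 4))
        b = list(rng.normal(0.0, 1.0, 4))
        rep = displacement_permutation_test(a, b)
        pooled = a + b
        obs = np.mean(a) - np.mean(b)
        count = total = 0
        for comb in itertools.combinations(range(8), 4):
            ga = [pooled[i] for i in comb]
            gb = [pooled[i] for i in range(8) if i not in comb]
            total += 1
            if abs(np.mean(ga) - np.mean(gb)) >= abs(obs) - 1e-12:
                count += 1
        assert rep["p_value"] == pytest.approx(count / total)
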