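"""NNSF data association: gates, ray likelihood, assignment, merge
prevention, track birth and death."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize_scalar

from flight3d.association import (
    AssignmentVector,
    GatingParams,
    area_gate,
    associate,
    closest_point_on_ray,
    feature_likelihood,
    mahalanobis_distance,
    pixel_gate,
    resolve_shared,
    retire_targets,
    spawn_targets,
)
from flight3d.ekf import ProcessModel, TargetModel, predict
from flight3d.features import FeaturePoint
from flight3d.geometry import Ray, project

PARAMS = GatingParams(max_pixel_dist=20.0, min_area=1.0)


def feat(u, v, alpha=5.0, beta=80.0):
    return FeaturePoint(u=u, v=v, alpha=alpha, beta=beta, theta=0.0, epsilon=0.0)


def make_target(pos, P=None, tid=0):
    P = np.eye(6) * 0.01 if P is None else P
    return TargetModel(id=tid, state=np.concatenate([pos, np.zeros(3)]), covariance=P)


class TestGates:
    def test_pixel_gate_inclusive_boundary(self):
        assert pixel_gate(feat(0, 0), (0, 0), PARAMS) == 1
        assert pixel_gate(feat(20.0, 0), (0, 0), PARAMS) == 1  # exactly at gate
        assert pixel_gate(feat(20.0 + 1e-9, 0), (0, 0), PARAMS) == 0

    def test_area_gate_strict(self):
        assert area_gate(feat(0, 0, alpha=1.0), PARAMS) == 0  # == threshold
        assert area_gate(feat(0, 0, alpha=2.0), PARAMS) == 1
        loose = GatingParams(min_area=1e-12)
        assert area_gate(feat(0, 0, alpha=0.5), loose) == 1


class TestClosestPointOnRay:
    def test_identity_cov_is_orthogonal_projection(self):
        ray = Ray(origin=[0, 0, 0], direction=[1, 0, 0])
        out = closest_point_on_ray(ray, [3.0, 4.0, 0.0], np.eye(3))
        assert np.allclose(out, [3, 0, 0])

    def test_mean_on_ray_returns_mean(self):
        ray = Ray(origin=[1, 1, 1], direction=[0, 0, 1])
        out = closest_point_on_ray(ray, [1, 1, 4.0], np.diag([2.0, 1.0, 0.5]))
        assert np.allclose(out, [1, 1, 4])
        assert mahalanobis_distance(out, [1, 1, 4], np.diag([2.0, 1.0, 0.5])) == 0

    def test_matches_numeric_minimization_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(30):
            ray = Ray(origin=rng.normal(size=3), direction=rng.normal(size=3))
            mean = rng.normal(size=3)
            A = rng.normal(size=(3, 3))
            cov = A @ A.T + 0.5 * np.eye(3)

            def d2(s):
                return mahalanobis_distance(ray.point_at(s), mean, cov) ** 2

            # independent 1-D numeric minimization oracle
            res = minimize_scalar(d2, bounds=(-100, 100), method="bounded",
                                  options={"xatol": 1e-10})
            expected = ray.point_at(res.x)
            assert np.allclose(closest_point_on_ray(ray, mean, cov), expected,
                               atol=1e-6)

    def test_singular_covariance_raises(self):
        ray = Ray(origin=[0, 0, 0], direction=[1, 0, 0])
        with pytest.raises(ValueError):
            closest_point_on_ray(ray, [1, 1, 1], np.zeros((3, 3)))

    coord = st.floats(-10, 10, allow_nan=False)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.tuples(coord, coord, coord), st.tuples(coord, coord, coord),
           st.tuples(st.floats(0.1, 5), st.floats(0.1, 5), st.floats(0.1, 5)),
           st.integers(0, 2))
    def test_minimizer_lies_on_ray_and_dominates_samples(self, origin, mean,
                                                         diag, axis):
        direction = np.eye(3)[axis]
        ray = Ray(origin=origin, direction=direction)
        cov = np.diag(diag)
        best = closest_point_on_ray(ray, mean, cov)
        # on the ray: displacement from origin parallel to direction
        disp = best - np.asarray(origin)
        assert np.linalg.norm(disp - (disp @ direction) * direction) < 1e-9
        d_best = mahalanobis_distance(best, mean, cov)
        for s in (-3.0, -0.5, 0.0, 0.7, 2.0):
            other = ray.point_at((disp @ direction) + s) if s else best
            assert d_best <= mahalanobis_distance(other, mean, cov) + 1e-9


class TestMahalanobis:
    def test_hand_examples(self):
        assert mahalanobis_distance([1, 2, 3], [1, 2, 3], np.eye(3)) == 0
        assert mahalanobis_distance([3, 4, 0], [0, 0, 0], np.eye(3)) == pytest.approx(5)
        assert mahalanobis_distance([2, 0, 0], [0, 0, 0],
                                    np.diag([4.0, 1, 1])) == pytest.approx(1.0)


class TestFeatureLikelihood:
    def test_out_of_gate_short_circuits_ray_term(self, small_rig):
        cam = small_rig[0]
        target = make_target([0, 0, 0.75])
        predicted = project(cam, target.position)
        far = feat(predicted[0] + 100.0, predicted[1])
        stats = {}
        assert feature_likelihood(far, target, cam, PARAMS, stats=stats) == 0.0
        assert stats.get("ray_terms", 0) == 0

    def test_small_area_short_circuits_ray_term(self, small_rig):
        cam = small_rig[0]
        target = make_target([0, 0, 0.75])
        predicted = project(cam, target.position)
        tiny = feat(*predicted, alpha=0.5)
        stats = {}
        assert feature_likelihood(tiny, target, cam, PARAMS, stats=stats) == 0.0
        assert stats.get("ray_terms", 0) == 0

    def test_ray_through_mean_is_maximal(self, small_rig):
        cam = small_rig[0]
        target = make_target([0.02, -0.04, 0.8])
        exact = feat(*project(cam, target.position))
        stats = {}
        score = feature_likelihood(exact, target, cam, PARAMS, stats=stats)
        assert score == pytest.approx(1.0, abs=1e-9)  # d_mahal = 0
        assert stats["ray_terms"] == 1

    def test_monotone_in_ray_distance(self, small_rig):
        cam = small_rig[0]
        target = make_target([0.0, 0.0, 0.8])
        predicted = project(cam, target.position)
        near = feat(predicted[0] + 2.0, predicted[1])
        far = feat(predicted[0] + 8.0, predicted[1])
        s_near = feature_likelihood(near, target, cam, PARAMS)
        s_far = feature_likelihood(far, target, cam, PARAMS)
        assert s_near > s_far > 0


class TestAssociate:
    def test_full_assignment_single_target(self, small_rig):
        target = make_target([0.0, 0.0, 0.8])
        features = [[feat(*project(c, target.position))] for c in small_rig]
        (av,) = associate([target], features, small_rig, PARAMS)
        assert av.entries == [0] * len(small_rig)

    def test_all_out_of_gate_yields_null_vector(self, small_rig):
        target = make_target([0.0, 0.0, 0.8])
        features = [[feat(project(c, target.position)[0] + 500.0, 10.0)]
                    for c in small_rig]
        (av,) = associate([target], features, small_rig, PARAMS)
        assert av.entries == [None] * len(small_rig)

    def test_matches_brute_force_argmax_oracle(self, small_rig):
        """Random small instances: the per-target per-camera choice equals an
        independent exhaustive argmax over features."""
        rng = np.random.default_rng(17)
        cams = small_rig[:4]
        for _ in range(200):
            n_targets = rng.integers(1, 4)
            targets = [
                make_target(rng.uniform([-0.1, -0.1, 0.3], [0.1, 0.1, 1.2]), tid=k)
                for k in range(n_targets)
            ]
            features = []
            for c in cams:
                m = rng.integers(0, 6)
                feats = []
                for _ in range(m):
                    base = project(c, targets[rng.integers(n_targets)].position)
                    feats.append(feat(base[0] + rng.normal(0, 15),
                                      base[1] + rng.normal(0, 15),
                                      alpha=rng.uniform(0.5, 10)))
                features.append(feats)
            got = associate(targets, features, cams, PARAMS)
            for k, target in enumerate(targets):
                for ci, cam in enumerate(cams):
                    best, best_score = None, 0.0
                    for fi, f in enumerate(features[ci]):
                        s = feature_likelihood(f, target, cam, PARAMS)
                        if s > best_score:
                            best, best_score = fi, s
                    assert got[k].entries[ci] == best

    def test_permutation_equivariance(self, small_rig):
        rng = np.random.default_rng(18)
        target = make_target([0.0, 0.0, 0.8])
        features = []
        for c in small_rig:
            base = project(c, target.position)
            features.append([feat(base[0] + rng.normal(0, 5), base[1] + rng.normal(0, 5))
                             for _ in range(4)])
        (av,) = associate([target], features, small_rig, PARAMS)
        perm = [2, 0, 3, 1]
        permuted = [[fl[p] for p in perm] for fl in features]
        (av_p,) = associate([target], permuted, small_rig, PARAMS)
        for ci in range(len(small_rig)):
            chosen = features[ci][av.entries[ci]]
            chosen_p = permuted[ci][av_p.entries[ci]]
            assert chosen is chosen_p


class TestResolveShared:
    def test_closest_prediction_keeps_shared_set(self, small_rig):
        pos = np.array([0.0, 0.0, 0.8])
        a = make_target(pos, tid=0)
        b = make_target(pos + [0.01, 0, 0], tid=1)
        features = [[feat(*project(c, pos))] for c in small_rig]
        assignments = associate([a, b], features, small_rig, PARAMS)
        assert assignments[0].claimed_set() == assignments[1].claimed_set()
        resolved = resolve_shared([a, b], assignments, small_rig, features)
        assert resolved[0].n_assigned == len(small_rig)  # A's prediction is exact
        assert resolved[1].entries == [None] * len(small_rig)

    def test_distinct_sets_unchanged(self, small_rig):
        a = make_target([0.0, 0.0, 0.5], tid=0)
        b = make_target([0.05, 0.05, 1.0], tid=1)
        features = [
            [feat(*project(c, a.position)), feat(*project(c, b.position))]
            for c in small_rig
        ]
        assignments = associate([a, b], features, small_rig, PARAMS)
        resolved = resolve_shared([a, b], assignments, small_rig, features)
        assert resolved == assignments

    def test_exact_tie_goes_to_lower_id(self, small_rig):
        pos = np.array([0.0, 0.0, 0.8])
        a = make_target(pos, tid=3)
        b = make_target(pos, tid=1)  # same prediction: distance tie
        features = [[feat(*project(c, pos))] for c in small_rig]
        assignments = associate([a, b], features, small_rig, PARAMS)
        resolved = resolve_shared([a, b], assignments, small_rig, features)
        # target id 1 (index 1) wins the tie
        assert resolved[1].n_assigned == len(small_rig)
        assert resolved[0].entries == [None] * len(small_rig)


class TestSpawn:
    def test_consistent_features_in_three_of_four_cameras(self, small_rig):
        cams = small_rig[:4]
        X = np.array([0.05, -0.03, 0.6])
        unclaimed = [[feat(*project(c, X))] for c in cams[:3]] + [[]]
        born = spawn_targets(unclaimed, cams, PARAMS, next_id=7)
        assert len(born) == 1
        t = born[0]
        assert t.id == 7
        assert np.allclose(t.position, X, atol=1e-6)
        assert np.array_equal(t.velocity, [0, 0, 0])
        assert np.trace(t.position_covariance) > 0.01  # deliberately uncertain

    def test_single_camera_features_cannot_spawn(self, small_rig):
        unclaimed = [[feat(10, 10), feat(50, 50)]] + [[] for _ in small_rig[1:]]
        assert spawn_targets(unclaimed, small_rig, PARAMS, next_id=0) == []

    def test_hypothesis_count_and_widest_combination_wins(self, small_rig):
        """n consistent single-feature cameras: 2^n - n - 1 hypotheses are
        enumerated and the n-camera one wins."""
        n = len(small_rig)
        X = np.array([0.0, 0.02, 0.9])
        unclaimed = [[feat(*project(c, X))] for c in small_rig]
        stats = {}
        born = spawn_targets(unclaimed, small_rig, PARAMS, next_id=0, stats=stats)
        assert stats["hypotheses"] == 2**n - n - 1
        assert len(born) == 1
        assert np.allclose(born[0].position, X, atol=1e-6)

    def test_combination_budget_caps_enumeration(self, small_rig):
        rng = np.random.default_rng(20)
        unclaimed = [[feat(rng.uniform(0, 640), rng.uniform(0, 480))
                      for _ in range(5)] for _ in small_rig]
        capped = GatingParams(max_birth_combinations=50)
        stats = {}
        spawn_targets(unclaimed, small_rig, capped, next_id=0, stats=stats)
        assert stats["hypotheses"] <= 50


class TestRetire:
    def test_trace_growth_crossing_matches_closed_form(self):
        """An unobserved target accumulates covariance through A P A^T + Q;
        the retirement frame equals the first crossing predicted by an
        independent block-recursion oracle."""
        process = ProcessModel(dt=0.01)
        params = GatingParams(max_covariance_trace_death=0.05,
                              max_frames_unobserved=10_000)
        P0 = np.diag([0.01] * 3 + [1.0] * 3)
        target = TargetModel(id=0, state=np.zeros(6), covariance=P0.copy())

        # oracle: iterate the positional/velocity block recursion directly
        dt = process.dt
        Pp, Ppv, Pv = P0[:3, :3].copy(), P0[:3, 3:].copy(), P0[3:, 3:].copy()
        crossing = None
        for k in range(1, 500):
            Pp = Pp + dt * (Ppv + Ppv.T) + dt**2 * Pv + 1e-4 * np.eye(3)
            Ppv = Ppv + dt * Pv
            Pv = Pv + 0.25 * np.eye(3)
            if np.trace(Pp) > params.max_covariance_trace_death:
                crossing = k
                break
        assert crossing is not None

        for k in range(1, crossing + 1):
            target = predict(target, process)
            kept, retired = retire_targets([target], params)
            if k < crossing:
                assert kept and not retired
            else:
                assert retired and not kept

    def test_observed_target_kept_and_infinite_threshold(self):
        params = GatingParams(max_covariance_trace_death=np.inf,
                              max_frames_unobserved=10_000)
        t = TargetModel(id=0, state=np.zeros(6), covariance=np.eye(6) * 1e9)
        kept, retired = retire_targets([t], params)
        assert kept == [t] and retired == []

    def test_unobserved_frame_limit(self):
        params = GatingParams(max_covariance_trace_death=np.inf,
                              max_frames_unobserved=3)
        t = TargetModel(id=0, state=np.zeros(6), covariance=np.eye(6) * 1e-6,
                        frames_since_observation=4)
        kept, retired = retire_targets([t], params)
        assert retired == [t]
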