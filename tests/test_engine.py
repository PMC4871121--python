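"""End-to-end registration: recovery, consistency, multistart, fusion."""

import numpy as np
import pytest

from igrtqa import (
    CouchCorrection,
    InitializationError,
    MetricSpec,
    OptimizerConfig,
    PhantomSpec,
    RigidTransform2D,
    compose,
    fuse_orthogonal,
    make_pair,
    multistart,
    register_pair,
    resample,
)


def fast_evo(seed=7, n=800):
    return OptimizerConfig(kind="evolutionary", seed=seed, evo_max_iter=n)


class TestRegisterPair:
    def test_recovers_planted_shift(self, small_phantom):
        fixed, moving, truth = small_phantom
        for opt in (OptimizerConfig(kind="gd"), fast_evo()):
            res = register_pair(fixed, moving, MetricSpec("ncc"), opt)
            t = res.transform
            assert abs(t.tx - truth.tx) <= 0.5
            assert abs(t.ty - truth.ty) <= 0.5
            assert abs(t.theta - truth.theta) <= 0.3

    def test_self_registration_stays_at_identity(self, clean_phantom):
        fixed, _, _ = clean_phantom
        res = register_pair(fixed, fixed, MetricSpec("ncc"),
                            OptimizerConfig(kind="gd"))
        t = res.transform
        assert max(abs(t.tx), abs(t.ty)) <= 0.02
        assert abs(t.theta) <= 0.02

    def test_optimizers_agree_on_clean_phantom(self, small_phantom):
        fixed, moving, truth = small_phantom
        gd = register_pair(fixed, moving, MetricSpec("ncc"),
                           OptimizerConfig(kind="gd")).transform
        evo = register_pair(fixed, moving, MetricSpec("ncc"), fast_evo()).transform
        assert abs(gd.tx - evo.tx) <= 0.1
        assert abs(gd.ty - evo.ty) <= 0.1
        assert abs(gd.theta - evo.theta) <= 0.15

    def test_degenerate_start_raises(self, small_phantom):
        fixed, moving, truth = small_phantom
        with pytest.raises(InitializationError, match="x0"):
            register_pair(fixed, moving, MetricSpec("ncc"), fast_evo(),
                          x0=RigidTransform2D(120.0, 0.0, 0.0))

    def test_deterministic_serialization(self, small_phantom):
        fixed, moving, _ = small_phantom
        a = register_pair(fixed, moving, MetricSpec("ncc"), fast_evo(seed=9))
        b = register_pair(fixed, moving, MetricSpec("ncc"), fast_evo(seed=9))
        assert a.to_json() == b.to_json()

    def test_self_consistency_random_transforms(self, rng):
        """Registering (fixed, resample(fixed, T)) recovers T for |t|<=20, |th|<=5."""
        spec = PhantomSpec(shape=(128, 128), gamma=1.0, contrast=1.0, offset=0.0,
                           noise_sigma=0.0, seed=0)
        fixed, _, _ = make_pair(spec)
        center = fixed.physical_center
        for kind in ("gd", "evolutionary"):
            for _ in range(3):
                t = RigidTransform2D(*rng.uniform(-20, 20, 2),
                                     rng.uniform(-5, 5), center)
                warped, _ = resample(fixed, t.inverse(), fixed)
                opt = OptimizerConfig(kind=kind, seed=11, evo_max_iter=1200)
                res = register_pair(fixed, warped, MetricSpec("ncc"), opt)
                assert abs(res.transform.tx - t.tx) <= 0.5
                assert abs(res.transform.ty - t.ty) <= 0.5
                assert abs(res.transform.theta - t.theta) <= 0.3

    def test_inverse_consistency(self, clean_phantom):
        fixed, moving, truth = clean_phantom
        fwd = register_pair(fixed, moving, MetricSpec("ncc"), fast_evo(1)).transform
        rev = register_pair(moving, fixed, MetricSpec("ncc"), fast_evo(2)).transform
        comp = compose(fwd, rev)
        assert max(abs(comp.tx), abs(comp.ty)) <= 1.0
        assert abs(comp.theta) <= 0.5

    def test_final_cost_matches_reevaluation(self, small_phantom):
        from igrtqa.metrics import PairCost

        fixed, moving, _ = small_phantom
        res = register_pair(fixed, moving, MetricSpec("ncc"), fast_evo())
        pc = PairCost(fixed, moving, MetricSpec("ncc"))
        assert pc(res.transform) == pytest.approx(res.final_cost, abs=1e-10)


class TestMultistart:
    def test_zero_radius_same_seed_identical(self, small_phantom):
        fixed, moving, _ = small_phantom
        r1, s1 = multistart(fixed, moving, MetricSpec("ncc"), fast_evo(), n_starts=2,
                            offset_radius=0.0, seed=4)
        assert r1[0].transform == r1[1].transform or (
            abs(r1[0].transform.tx - r1[1].transform.tx) < 1e-12)
        r2, s2 = multistart(fixed, moving, MetricSpec("ncc"), fast_evo(), n_starts=2,
                            offset_radius=0.0, seed=4)
        assert [x.to_json() for x in r1] == [x.to_json() for x in r2]

    def test_all_starts_converge_from_20mm(self, small_phantom):
        fixed, moving, truth = small_phantom
        results, summary = multistart(fixed, moving, MetricSpec("ncc"),
                                      fast_evo(n=1500), n_starts=6,
                                      offset_radius=20.0, seed=3, around=truth,
                                      mode="circle")
        for res in results:
            err = np.hypot(res.transform.tx - truth.tx, res.transform.ty - truth.ty)
            assert err <= 1.0
        assert summary.max_pairwise_translation_mm <= 1.0
        costs = np.array([r.final_cost for r in results])
        assert np.all(np.abs(costs - costs.mean()) <= 3 * costs.std(ddof=1) + 1e-12)

    def test_needs_two_starts(self, small_phantom):
        fixed, moving, _ = small_phantom
        with pytest.raises(ValueError):
            multistart(fixed, moving, n_starts=1)


class TestFuseOrthogonal:
    def test_identity_fuses_to_zero(self):
        ident = RigidTransform2D.identity()
        couch, diag = fuse_orthogonal(ident, ident)
        assert couch == CouchCorrection()
        assert diag == 0.0

    def test_stated_mapping(self):
        ap = RigidTransform2D(2.0, 1.0, 1.0)
        lat = RigidTransform2D(1.0, -3.0, 0.5)
        couch, diag = fuse_orthogonal(ap, lat)
        assert couch == CouchCorrection(vert=-3.0, lat=2.0, long=1.0,
                                        rotation=1.0, pitch=0.5)
        assert diag == 0.0

    def test_longitudinal_disagreement_diagnostic(self):
        ap = RigidTransform2D(0.0, 1.0, 0.0)
        lat = RigidTransform2D(2.0, 0.0, 0.0)
        couch, diag = fuse_orthogonal(ap, lat)
        assert couch.long == pytest.approx(1.5)
        assert diag == pytest.approx(1.0)
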