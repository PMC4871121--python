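"""Similarity metrics against brute-force oracles and bound/invariance properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from igrtqa import (
    DegenerateMetricError,
    MetricSpec,
    ProjectionImage,
    RigidTransform2D,
    evaluate,
    gradient_difference,
    mrsd,
    ncc,
)
from igrtqa.metrics import INVALID_COST, PairCost


def _ncc_bruteforce(a, b):
    """Direct-summation Pearson correlation, negated."""
    a = a.ravel()
    b = b.ravel()
    am, bm = a.mean(), b.mean()
    num = sum((x - am) * (y - bm) for x, y in zip(a, b))
    den = (sum((x - am) ** 2 for x in a) * sum((y - bm) ** 2 for y in b)) ** 0.5
    return -num / den


class TestNCC:
    def test_self_correlation(self, rng):
        a = rng.uniform(0, 1, (8, 8))
        assert ncc(a, a) == pytest.approx(-1.0, abs=1e-12)

    def test_positive_linear_map_gives_minus_one(self, rng):
        a = rng.uniform(0, 1, (8, 8))
        assert ncc(a, 2.0 * a + 5.0) == pytest.approx(-1.0, abs=1e-12)

    def test_3x3_brute_force_oracle(self):
        fixed = np.array([[0, 1, 2], [1, 2, 3], [2, 3, 4]], dtype=float)
        moving = np.array([[0, 0, 2], [1, 2, 3], [2, 3, 4]], dtype=float)
        assert ncc(fixed, moving) == pytest.approx(_ncc_bruteforce(fixed, moving), abs=1e-12)

    def test_linear_invariance_to_1e10(self, rng):
        a = rng.uniform(0, 1, (16, 16))
        b = rng.uniform(0, 1, (16, 16))
        base = ncc(a, b)
        for scale, offset in ((3.7, -2.0), (0.01, 100.0), (1e4, 0.0)):
            assert ncc(a, scale * b + offset) == pytest.approx(base, abs=1e-10)

    def test_constant_image_degenerate(self):
        with pytest.raises(DegenerateMetricError):
            ncc(np.ones((8, 8)), np.arange(64.0).reshape(8, 8))

    @settings(max_examples=30, deadline=None)
    @given(hnp.arrays(np.float64, (6, 6), elements=st.floats(0, 1)),
           hnp.arrays(np.float64, (6, 6), elements=st.floats(0, 1)))
    def test_bounds(self, a, b):
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            return
        assert -1.0 - 1e-12 <= ncc(a, b) <= 1.0 + 1e-12


class TestGradientDifference:
    def test_identical_images_zero(self, rng):
        a = rng.uniform(0, 1, (8, 8))
        assert gradient_difference(a, a) == 0.0

    def test_constant_offset_invisible(self, rng):
        a = rng.uniform(0, 1, (8, 8))
        assert gradient_difference(a, a + 3.0) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_central_difference_oracle(self):
        # 5x5 pair differing in one off-centre pixel; only the interior
        # pixel (2,2) survives border exclusion.
        fixed = np.zeros((5, 5))
        moving = np.zeros((5, 5))
        moving[2, 3] = 2.0
        # at (2,2): fixed gradients 0; moving col-gradient (m[2,3]-m[2,1])/2 = 1
        # cost = mean over the 9 interior pixels of squared differences
        interior = []
        for i in range(1, 4):
            for j in range(1, 4):
                gr = (moving[i + 1, j] - moving[i - 1, j]) / 2
                gc = (moving[i, j + 1] - moving[i, j - 1]) / 2
                interior.append(gr**2 + gc**2)
        expected = float(np.mean(interior))
        assert gradient_difference(fixed, moving) == pytest.approx(expected, abs=1e-12)

    def test_nonnegative_random(self, rng):
        for _ in range(20):
            a = rng.uniform(0, 1, (8, 8))
            b = rng.uniform(0, 1, (8, 8))
            assert gradient_difference(a, b) >= 0.0

    def test_normalized_variant_bounded(self, rng):
        a = rng.uniform(0, 1, (12, 12))
        b = rng.uniform(0, 1, (12, 12))
        v = gradient_difference(a, b, normalized=True)
        assert -2.0 <= v <= 0.0
        assert gradient_difference(a, a, normalized=True) == pytest.approx(-2.0)


class TestMRSD:
    def test_identical_is_minus_one(self, rng):
        a = rng.uniform(0, 1, (8, 8))
        assert mrsd(a, a) == -1.0

    def test_half_response_at_capture_radius(self, rng):
        a = rng.uniform(0, 1, (8, 8))
        lam = 0.1
        assert mrsd(a, a + lam, lambda_capture=lam) == pytest.approx(-0.5, abs=1e-12)

    def test_asymptote_for_huge_differences(self, rng):
        a = rng.uniform(0, 1, (8, 8))
        v = mrsd(a, a + 1e6, lambda_capture=0.1)
        assert -1e-9 < v <= 0.0

    @settings(max_examples=30, deadline=None)
    @given(hnp.arrays(np.float64, (6, 6), elements=st.floats(0, 1)),
           hnp.arrays(np.float64, (6, 6), elements=st.floats(0, 1)))
    def test_bounds(self, a, b):
        assert -1.0 <= mrsd(a, b) <= 0.0


class TestEvaluate:
    def test_identity_on_identical_pair(self, rng):
        img = ProjectionImage(rng.uniform(0, 1, (32, 32)))
        t = RigidTransform2D.identity(img.physical_center)
        assert evaluate(MetricSpec("ncc"), img, img, t, preprocess=False) == \
            pytest.approx(-1.0, abs=1e-12)
        assert evaluate(MetricSpec("mrsd"), img, img, t, preprocess=False) == \
            pytest.approx(-1.0, abs=1e-12)

    def test_truth_beats_large_offset(self, small_phantom):
        fixed, moving, truth = small_phantom
        pc = PairCost(fixed, moving, MetricSpec("ncc"))
        assert pc(truth) < pc(truth.replace(tx=truth.tx + 10.0))

    def test_degenerate_overlap_returns_sentinel(self, small_phantom):
        fixed, moving, truth = small_phantom
        pc = PairCost(fixed, moving, MetricSpec("ncc"))
        # 90% off-image: below the minimum-overlap fraction
        assert pc(RigidTransform2D(115.0, 0.0, 0.0, truth.center)) == INVALID_COST

    def test_roi_restricts_evaluation(self, rng):
        base = rng.uniform(0, 1, (32, 32))
        other = base.copy()
        other[:16] = rng.uniform(0, 1, (16, 32))  # corrupt top half
        fixed = ProjectionImage(base)
        moving = ProjectionImage(other)
        t = RigidTransform2D.identity(fixed.physical_center)
        spec_all = MetricSpec("ncc")
        spec_roi = MetricSpec("ncc", roi=(16, 32, 0, 32))  # clean bottom half
        full = PairCost(fixed, moving, spec_all, preprocess=False)(t)
        roi = PairCost(fixed, moving, spec_roi, preprocess=False)(t)
        assert roi == pytest.approx(-1.0, abs=1e-12)
        assert full > roi
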