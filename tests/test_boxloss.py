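"""Box geometry and the CIoU / inner-IoU / AICI loss family."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stenoskit.autodiff import Tensor
from stenoskit.boxloss import (AICIParams, Box, aici_loss, ciou_loss,
                               inner_iou, iou, rasterized_iou, upsilon_alpha)
from tests.conftest import random_box_pairs

# frozen oracle values (hand term-by-term evaluation; see each test)
WORKED_PRED = Box(1, 1, 2, 2)
WORKED_GT = Box(2, 2, 2, 2)


class TestIoU:
    def test_identical_boxes(self):
        assert iou(WORKED_PRED, WORKED_PRED) == pytest.approx(1.0)

    def test_disjoint_boxes(self):
        assert iou(Box(1, 1, 2, 2), Box(10, 10, 2, 2)) == 0.0

    def test_worked_example(self):
        # inter 1, union 4+4-1 = 7
        assert iou(WORKED_PRED, WORKED_GT) == pytest.approx(1 / 7, abs=1e-12)

    def test_symmetry(self, rng):
        a, b = random_box_pairs(rng, 200)
        np.testing.assert_allclose(iou(a, b), iou(b, a), atol=1e-12)

    def test_degenerate_box_has_zero_iou(self):
        assert iou(Box(0, 0, 0, 0), Box(0, 0, 2, 2)) == 0.0
        assert iou(Box(0, 0, 0, 0), Box(0, 0, 0, 0)) == 0.0

    def test_negative_size_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            Box(0, 0, -1, 1)
        with pytest.raises(ValueError, match="negative"):
            iou(np.array([0, 0, -1.0, 1]), np.array([0, 0, 1.0, 1]))

    def test_matches_rasterization_oracle(self, rng):
        a, b = random_box_pairs(rng, 100, scale=5.0)
        for i in range(100):
            ba, bb = Box(*a[i]), Box(*b[i])
            assert iou(ba, bb) == pytest.approx(
                rasterized_iou(ba, bb, cells=600), abs=1e-2)


class TestUpsilonAlpha:
    def test_shared_aspect_gives_zero(self):
        ups, alpha = upsilon_alpha(Box(0, 0, 4, 2), Box(5, 5, 2, 1), 0.3)
        assert ups == pytest.approx(0.0, abs=1e-15)
        assert alpha == pytest.approx(0.0, abs=1e-12)

    def test_worked_values(self):
        # (4/pi^2)(arctan(1/2) - arctan(2))^2 = 0.16782584...
        ups, _ = upsilon_alpha(Box(0, 0, 2, 1), Box(0, 0, 1, 2), 0.5)
        assert ups == pytest.approx(0.1678258460, abs=1e-9)
        _, alpha = upsilon_alpha(Box(0, 0, 2, 1), Box(0, 0, 1, 2), 0.5)
        assert alpha == pytest.approx(0.1678258460 / (0.5 + 0.1678258460),
                                      abs=1e-9)

    def test_zero_dimension_rejected(self):
        with pytest.raises(ValueError, match="degenerate aspect"):
            upsilon_alpha(Box(0, 0, 1, 0), Box(0, 0, 1, 1), 0.5)


class TestCIoU:
    def test_identity_is_zero(self):
        assert ciou_loss(WORKED_GT, WORKED_GT) == pytest.approx(0.0, abs=1e-12)

    def test_worked_example(self):
        # 1 - 1/7 + 2/18 + 0 = 61/63
        assert ciou_loss(WORKED_PRED, WORKED_GT) == pytest.approx(
            61 / 63, abs=1e-9)

    def test_terms_exposed(self):
        loss, terms = ciou_loss(WORKED_PRED, WORKED_GT, return_terms=True)
        assert terms["iou"] == pytest.approx(1 / 7)
        assert terms["distance"] == pytest.approx(2 / 18)
        assert terms["aspect"] == pytest.approx(0.0, abs=1e-12)
        assert loss == pytest.approx((1 - 1 / 7) + 2 / 18, abs=1e-12)

    def test_concentric_same_aspect_reduces_to_iou_loss(self):
        pred, gt = Box(3, 3, 2, 4), Box(3, 3, 4, 8)
        assert ciou_loss(pred, gt) == pytest.approx(1 - iou(pred, gt),
                                                    abs=1e-12)

    def test_nonnegative_and_finite(self, rng):
        a, b = random_box_pairs(rng, 500)
        losses = ciou_loss(a, b)
        assert np.all(np.isfinite(losses)) and np.all(losses >= 0)

    def test_zero_iff_equal(self, rng):
        a, _ = random_box_pairs(rng, 50)
        np.testing.assert_allclose(ciou_loss(a, a), 0.0, atol=1e-9)
        b = a.copy()
        b[:, 0] += 0.5
        assert np.all(ciou_loss(a, b) > 1e-6)


class TestInnerIoU:
    def test_ratio_one_equals_iou(self, rng):
        a, b = random_box_pairs(rng, 10_000)
        np.testing.assert_allclose(inner_iou(a, b, 1.0), iou(a, b), atol=1e-9)

    def test_identity(self):
        assert inner_iou(WORKED_GT, WORKED_GT, 1.7) == pytest.approx(1.0)

    def test_worked_example_ratio_12(self):
        # scaled dims 2.4: inter 1.4^2 = 1.96, union 2*5.76 - 1.96 = 9.56
        assert inner_iou(WORKED_PRED, WORKED_GT, 1.2) == pytest.approx(
            1.96 / 9.56, abs=1e-9)

    def test_matches_rasterization_on_scaled_boxes(self, rng):
        a, b = random_box_pairs(rng, 50, scale=5.0)
        for i in range(50):
            sa = Box(a[i, 0], a[i, 1], 1.2 * a[i, 2], 1.2 * a[i, 3])
            sb = Box(b[i, 0], b[i, 1], 1.2 * b[i, 2], 1.2 * b[i, 3])
            assert inner_iou(Box(*a[i]), Box(*b[i]), 1.2) == pytest.approx(
                rasterized_iou(sa, sb, cells=600), abs=1e-2)

    def test_invalid_ratio(self):
        with pytest.raises(ValueError, match="ratio"):
            inner_iou(WORKED_PRED, WORKED_GT, 0.0)
        with pytest.raises(ValueError, match="ratio"):
            inner_iou(WORKED_PRED, WORKED_GT, -1.1)

    def test_engages_on_disjoint_near_miss(self):
        # gap 0.2 between unit boxes: plain IoU is flat zero, a modest
        # auxiliary-scale factor recovers overlap (hence gradient)
        pred, gt = Box(0, 0, 1, 1), Box(1.2, 0, 1, 1)
        assert iou(pred, gt) == 0.0
        assert inner_iou(pred, gt, 1.5) > 0.0


class TestAICI:
    def test_reduces_to_ciou(self, rng):
        a, b = random_box_pairs(rng, 10_000)
        got = aici_loss(a, b, ratio=1.0, psi=1.0, tau=1.0)
        np.testing.assert_allclose(got, ciou_loss(a, b), atol=1e-9)

    def test_identity_is_zero(self):
        assert aici_loss(WORKED_GT, WORKED_GT) == pytest.approx(0.0, abs=1e-12)

    def test_worked_example_defaults(self):
        # ratio 1.1: inner = 1.2^2 / (2*4.84 - 1.44) = 1.44/8.24
        # loss = 1 - 1.44/8.24 + 0.5 * 2/18 + 0
        expect = 1 - 1.44 / 8.24 + 0.5 * (2 / 18)
        assert aici_loss(WORKED_PRED, WORKED_GT) == pytest.approx(
            expect, abs=1e-9)

    def test_alpha_switch(self, rng):
        a, b = random_box_pairs(rng, 100)
        with_inner = aici_loss(a, b, ratio=1.4)
        with_plain = aici_loss(a, b, ratio=1.4, alpha_from_inner=False)
        assert np.any(np.abs(with_inner - with_plain) > 1e-9)

    def test_param_validation(self):
        with pytest.raises(ValueError):
            AICIParams(ratio=-1.0)
        with pytest.raises(ValueError):
            AICIParams(psi=-0.1)

    def test_differentiable_with_finite_gradients(self):
        # tie-free geometries (equal coordinates sit on the max/min
        # subgradient kink where finite differences disagree by design)
        for pred, gt in [(WORKED_PRED, WORKED_GT),
                         (Box(0, 0, 1.2, 0.9), Box(3, 0.4, 1.0, 1.4))]:
            comps = tuple(Tensor(np.array([v], dtype=float),
                                 requires_grad=True)
                          for v in (pred.cx, pred.cy, pred.w, pred.h))
            tgt = tuple(np.array([v], dtype=float)
                        for v in (gt.cx, gt.cy, gt.w, gt.h))
            loss = aici_loss(comps, tgt)
            loss.sum().backward()
            grads = np.array([c.grad[0] for c in comps])
            assert np.all(np.isfinite(grads))
            # check against central differences
            eps = 1e-6
            for k in range(4):
                arr = np.array([pred.cx, pred.cy, pred.w, pred.h],
                               dtype=float)
                hi, lo = arr.copy(), arr.copy()
                hi[k] += eps
                lo[k] -= eps
                num = (aici_loss(tuple(np.array([v]) for v in hi), tgt)
                       - aici_loss(tuple(np.array([v]) for v in lo), tgt)) \
                    / (2 * eps)
                assert grads[k] == pytest.approx(num.item(), abs=1e-5)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(cx=st.floats(-5, 5), cy=st.floats(-5, 5),
       w=st.floats(0.1, 5), h=st.floats(0.1, 5),
       ratio=st.floats(0.5, 2.0))
def test_inner_iou_bounded(cx, cy, w, h, ratio):
    """Inner-IoU stays in [0, 1] across random geometry and ratios."""
    v = inner_iou(Box(cx, cy, w, h), Box(0, 0, 1, 2), ratio)
    assert 0.0 <= v <= 1.0 + 1e-12


def test_corner_form_roundtrip():
    b = Box(3.5, -1.25, 2.0, 0.5)
    assert Box.from_corners(b.left, b.top, b.right, b.bottom) == b
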