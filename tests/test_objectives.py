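"""Loss identities, bounds, the adaptive combination, and gradient sanity."""

import numpy as np
import pytest

from pdflow import (
    LossWeights,
    MagnitudeFlow,
    OrientationFlow,
    UncertaintyParams,
    adaptive_combine,
    loss_baseline,
    loss_explicit,
    loss_generalized,
    loss_implicit,
    mse,
    orientation_distance,
)
from pdflow.autograd import Tensor
from pdflow.errors import ConfigError, ShapeError, UndefinedLossError


def _orientation(units, valid=None):
    units = np.asarray(units, dtype=float)
    if valid is None:
        valid = np.ones(units.shape[:-1], dtype=bool)
    return OrientationFlow(units=units, valid_mask=valid)


class TestMse:
    def test_hand_value_and_symmetry(self):
        a, b = np.array([0.0, 0.0]), np.array([1.0, 1.0])
        assert mse(a, b) == 1.0
        assert mse(a, b) == mse(b, a)

    def test_zero_at_equality(self):
        x = np.random.default_rng(0).normal(size=(3, 4))
        assert mse(x, x) == 0.0

    def test_scaling_error_closed_form(self):
        p = np.random.default_rng(1).normal(size=(5, 6))
        c = 1.7
        assert np.isclose(mse(c * p, p), (c - 1) ** 2 * np.mean(p**2))

    def test_shape_mismatch(self):
        with pytest.raises(ShapeError):
            mse(np.ones(3), np.ones(4))


class TestOrientationDistance:
    def test_parallel_orthogonal_antiparallel(self):
        o = _orientation([[[1.0, 0, 0]]])
        assert orientation_distance(o, o) == 0.0
        assert orientation_distance(o, _orientation([[[0.0, 1, 0]]])) == 0.5
        assert orientation_distance(o, _orientation([[[-1.0, 0, 0]]])) == 1.0

    def test_invalid_targets_excluded_from_mean(self):
        units = np.array([[[1.0, 0, 0], [1.0, 0, 0]]])
        valid = np.array([[True, False]])
        o = _orientation(units, valid)
        o_hat = _orientation(np.array([[[1.0, 0, 0], [-1.0, 0, 0]]]))
        # the antiparallel entry is masked out, so the distance is 0
        assert orientation_distance(o, o_hat) == 0.0

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(2)
        u = rng.normal(size=(10, 5, 3))
        u /= np.linalg.norm(u, axis=-1, keepdims=True)
        v = rng.normal(size=(10, 5, 3))
        v /= np.linalg.norm(v, axis=-1, keepdims=True)
        d = orientation_distance(_orientation(u), _orientation(v))
        assert 0.0 <= d <= 1.0

    def test_no_valid_entries_errors(self):
        o = _orientation(np.zeros((1, 1, 3)), np.zeros((1, 1), dtype=bool))
        with pytest.raises(UndefinedLossError):
            orientation_distance(o, o)


class TestVariantLosses:
    def setup_method(self):
        rng = np.random.default_rng(3)
        self.alpha = np.abs(rng.normal(size=(4, 5)))
        units = rng.normal(size=(4, 5, 3))
        self.units = units / np.linalg.norm(units, axis=-1, keepdims=True)
        self.m = MagnitudeFlow(self.alpha)
        self.o = _orientation(self.units)
        self.p = rng.normal(size=(4, 15))

    def test_zero_at_perfect_reconstruction(self):
        # orientation self-distance carries ~1e-16 rounding from the unit norms
        assert abs(loss_explicit(self.m, self.o, self.alpha, self.o).total) < 1e-12
        bd = loss_implicit(self.m, self.o, self.alpha, self.o, self.p, self.p)
        assert abs(bd.total) < 1e-12
        bd = loss_generalized(self.m, self.o, self.alpha, self.o, self.p, self.p, self.p)
        assert abs(bd.total) < 1e-12
        assert loss_baseline(self.p, self.p, self.p).total == 0.0

    def test_weighted_sum_bookkeeping(self):
        w = LossWeights(w1=2.0, w2=0.5, w3=3.0, w4=0.25)
        rng = np.random.default_rng(4)
        bd = loss_generalized(
            self.m, self.o, self.alpha + 0.1, self.o,
            self.p + rng.normal(size=self.p.shape) * 0.1, self.p, self.p, w,
        )
        recomputed = sum(bd.weights[k] * bd.terms[k] for k in bd.terms)
        assert abs(bd.total - recomputed) < 1e-12
        assert set(bd.terms) == {"magnitude", "orientation", "pose_M", "pose_O"}

    def test_weight_zero_removes_term(self):
        flipped = _orientation(-self.units)
        w = LossWeights(w1=0.0, w2=1.0)
        bd = loss_explicit(self.m, self.o, self.alpha + 5.0, flipped, w)
        assert bd.total == 1.0  # only the (antiparallel) orientation term remains

    def test_constraint_term_scales_linearly(self):
        q = self.p + 1.0
        bd1 = loss_implicit(self.m, self.o, self.alpha, self.o, self.p, q,
                            LossWeights(w3=1.0))
        bd2 = loss_implicit(self.m, self.o, self.alpha, self.o, self.p, q,
                            LossWeights(w3=2.0))
        assert np.isclose(bd2.total - bd1.total, bd1.terms["constraint"])

    def test_baseline_total_is_mean_of_decoder_losses(self):
        a = self.p + 0.5
        bd = loss_baseline(self.p, a, self.p)
        assert np.isclose(bd.total, 0.5 * (bd.terms["pose_M"] + bd.terms["pose_O"]))


class TestAdaptiveCombine:
    def test_hand_value_at_unit_deltas(self):
        u = UncertaintyParams(s=np.zeros(2))
        assert np.isclose(adaptive_combine({"m": 0.4, "o": 0.2}, u), 0.3)

    def test_zero_losses_leave_half_sum_of_s(self):
        s = np.array([0.3, -0.1, 0.7])
        u = UncertaintyParams(s=s)
        assert np.isclose(adaptive_combine([0.0, 0.0, 0.0], u), 0.5 * s.sum())

    def test_frozen_s_zero_equals_half_unweighted_sum(self):
        u = UncertaintyParams(s=np.zeros(2))
        vals = [0.123, 0.456]
        assert np.isclose(adaptive_combine(vals, u), 0.5 * sum(vals))

    def test_optimal_s_satisfies_stationarity(self):
        # for fixed L, d/ds [e^{-s}L/2 + s/2] = 0 at s = log L
        losses = np.array([0.4, 0.2])
        s_opt = np.log(losses)
        u = UncertaintyParams(s=Tensor(s_opt.copy(), requires_grad=True))
        total = adaptive_combine([Tensor(v) for v in losses], u)
        total.backward()
        assert np.abs(u.s.grad).max() < 1e-12
        # and it is a minimum: perturbing s increases the objective
        for ds in (0.1, -0.1):
            perturbed = adaptive_combine(list(losses), UncertaintyParams(s=s_opt + ds))
            assert perturbed > float(total.data)

    def test_term_count_mismatch(self):
        with pytest.raises(ConfigError):
            adaptive_combine([1.0], UncertaintyParams(s=np.zeros(2)))


class TestGradientSanity:
    """Finite-difference vs. backprop gradients of each loss w.r.t. predictions."""

    @staticmethod
    def _check(build_loss, x0):
        t = Tensor(x0.copy(), requires_grad=True)
        build_loss(t).backward()
        num = np.zeros_like(x0)
        h = 1e-6
        flat_x, flat_g = x0.reshape(-1), num.reshape(-1)
        for i in range(flat_x.size):
            orig = flat_x[i]
            flat_x[i] = orig + h
            hi = float(build_loss(Tensor(x0)).data)
            flat_x[i] = orig - h
            lo = float(build_loss(Tensor(x0)).data)
            flat_x[i] = orig
            flat_g[i] = (hi - lo) / (2 * h)
        assert np.abs(t.grad - num).max() < 1e-4

    def test_mse_gradient(self):
        rng = np.random.default_rng(5)
        target = rng.normal(size=(2, 6))
        self._check(lambda t: mse(target, t), rng.normal(size=(2, 6)))

    def test_orientation_gradient(self):
        rng = np.random.default_rng(6)
        u = rng.normal(size=(2, 3, 3))
        u /= np.linalg.norm(u, axis=-1, keepdims=True)
        target = _orientation(u)

        def build(t):
            return orientation_distance(target, OrientationFlow(t, target.valid_mask))

        self._check(build, rng.normal(size=(2, 3, 3)))

    def test_explicit_loss_gradient_through_both_terms(self):
        rng = np.random.default_rng(7)
        alpha = np.abs(rng.normal(size=(2, 3)))
        u = rng.normal(size=(2, 3, 3))
        u /= np.linalg.norm(u, axis=-1, keepdims=True)
        m, o = MagnitudeFlow(alpha), _orientation(u)

        def build(t):
            m_hat = t[:, :, 0]
            o_hat = OrientationFlow(t, o.valid_mask)
            return loss_explicit(m, o, m_hat, o_hat).total

        self._check(build, rng.normal(size=(2, 3, 3)))

    def test_adaptive_gradient_wrt_s(self):
        losses = [0.4, 0.2]

        def build(t):
            return adaptive_combine(losses, UncertaintyParams(s=t))

        self._check(build, np.array([0.1, -0.2]))
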