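"""Exact/approximate DVH curves and the training losses."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hdaunet.autodiff import Tensor
from hdaunet.core import EmptyStructureError, StructureSet
from hdaunet.dvh import (
    DVHSpec,
    LossWeights,
    approx_dvh,
    approx_dvh_tensor,
    combined_loss,
    combined_loss_tensor,
    dvh_loss,
    exact_dvh,
)


def brute_force_dvh(dose, mask, thresholds):
    """Independent voxel-count oracle: explicit loop over thresholds/voxels."""
    vals = np.asarray(dose)[np.asarray(mask).astype(bool)]
    return np.array([(vals >= t).sum() / len(vals) for t in thresholds])


class TestExactDVH:
    def test_constant_dose_is_step_function(self):
        dose = np.full((4, 4, 4), 50.0)
        mask = np.ones((4, 4, 4))
        curve = exact_dvh(dose, mask)
        spec = DVHSpec()
        np.testing.assert_array_equal(curve, (spec.thresholds <= 50.0).astype(float))

    def test_half_volume_above_threshold(self):
        dose = np.zeros((4, 1, 1))
        dose[:, 0, 0] = [10, 20, 30, 40]
        mask = np.ones_like(dose)
        curve = exact_dvh(dose, mask, DVHSpec(thresholds=np.array([25.0])))
        assert curve[0] == 0.5

    def test_matches_brute_force_oracle(self, rng):
        spec = DVHSpec()
        for _ in range(10):
            dose = rng.random((8, 8, 8)) * 85
            mask = rng.random((8, 8, 8)) > 0.4
            np.testing.assert_array_equal(
                exact_dvh(dose, mask, spec), brute_force_dvh(dose, mask, spec.thresholds)
            )

    def test_empty_mask_rejected(self):
        with pytest.raises(EmptyStructureError):
            exact_dvh(np.ones((3, 3, 3)), np.zeros((3, 3, 3)))


class TestApproxDVH:
    def test_voxel_on_threshold_gives_half(self):
        dose = np.array([[[70.0]]])
        mask = np.ones((1, 1, 1))
        v = approx_dvh(dose, mask, DVHSpec(thresholds=np.array([70.0])))
        assert v[0] == pytest.approx(0.5)

    def test_single_voxel_closed_form(self):
        # one voxel at 71 Gy, threshold 70, m=1, beta=1 -> sigmoid(1)
        v = approx_dvh(np.array([[[71.0]]]), np.ones((1, 1, 1)),
                       DVHSpec(thresholds=np.array([70.0])))
        assert v[0] == pytest.approx(1 / (1 + np.exp(-1.0)), abs=1e-12)

    def test_converges_to_exact_for_steep_sigmoid(self, rng):
        spec = DVHSpec(steepness=1000.0)
        for _ in range(5):
            dose = rng.integers(0, 80, size=(6, 6, 6)) + 0.5  # off-threshold doses
            mask = rng.random((6, 6, 6)) > 0.3
            diff = np.abs(approx_dvh(dose, mask, spec) - exact_dvh(dose, mask, spec))
            assert diff.max() < 1e-3

    def test_values_in_open_unit_interval_and_monotone(self, rng):
        dose = rng.random((5, 5, 5)) * 80
        mask = np.ones((5, 5, 5))
        v = approx_dvh(dose, mask)
        assert np.all(v > 0) and np.all(v < 1)
        assert np.all(np.diff(v) <= 0)

    def test_tensor_path_matches_numpy_path(self, rng):
        dose = rng.random((4, 4, 4)) * 70
        mask = rng.random((4, 4, 4)) > 0.5
        t = approx_dvh_tensor(Tensor(dose), mask)
        np.testing.assert_allclose(t.data, approx_dvh(dose, mask), rtol=1e-12)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_exact_curve_monotone_nonincreasing_property(seed):
    rng = np.random.default_rng(seed)
    dose = rng.random((4, 4, 4)) * rng.uniform(1, 100)
    curve = exact_dvh(dose, np.ones((4, 4, 4)))
    assert np.all(np.diff(curve) <= 0)


def _two_structure_setup(rng):
    dose_a = rng.random((4, 4, 4)) * 70
    dose_b = rng.random((4, 4, 4)) * 70
    masks = {
        "A": (rng.random((4, 4, 4)) > 0.4).astype(np.uint8),
        "B": (rng.random((4, 4, 4)) > 0.6).astype(np.uint8),
    }
    return dose_a, dose_b, StructureSet(masks)


class TestDVHLoss:
    def test_zero_on_identical_doses(self, rng):
        dose, _, structs = _two_structure_setup(rng)
        assert dvh_loss(dose, dose.copy(), structs) == 0.0

    def test_symmetric_in_arguments(self, rng):
        da, db, structs = _two_structure_setup(rng)
        assert dvh_loss(da, db, structs) == pytest.approx(dvh_loss(db, da, structs), rel=1e-12)

    def test_matches_hand_expanded_sum(self, rng):
        """Independent oracle: expand the mean-over-structures-and-thresholds
        of squared sigmoid-curve differences with plain numpy loops."""
        da, db, structs = _two_structure_setup(rng)
        spec = DVHSpec()
        total = 0.0
        for name in ("A", "B"):
            mask = structs[name].astype(bool)
            va = np.array(
                [np.mean(1 / (1 + np.exp(-(da[mask] - t)))) for t in spec.thresholds]
            )
            vb = np.array(
                [np.mean(1 / (1 + np.exp(-(db[mask] - t)))) for t in spec.thresholds]
            )
            total += ((va - vb) ** 2).sum()
        expected = total / (2 * spec.n_thresholds)
        assert dvh_loss(da, db, structs, spec) == pytest.approx(expected, abs=1e-10)

    def test_invariant_under_structure_relabeling(self, rng):
        da, db, structs = _two_structure_setup(rng)
        swapped = StructureSet({"B": structs["A"], "A": structs["B"]})
        assert dvh_loss(da, db, structs) == pytest.approx(dvh_loss(da, db, swapped), rel=1e-12)

    def test_empty_structures_are_skipped(self, rng):
        da, db, structs = _two_structure_setup(rng)
        structs.masks["EMPTY"] = np.zeros((4, 4, 4), dtype=np.uint8)
        with_empty = dvh_loss(da, db, structs)
        without = dvh_loss(da, db, StructureSet({k: structs[k] for k in ("A", "B")}))
        assert with_empty == pytest.approx(without, rel=1e-12)

    def test_all_empty_rejected(self, rng):
        empty = StructureSet({"E": np.zeros((3, 3, 3), dtype=np.uint8)})
        with pytest.raises(ValueError):
            dvh_loss(np.ones((3, 3, 3)), np.zeros((3, 3, 3)), empty)


class TestCombinedLoss:
    def test_weighted_sum_of_components(self, rng):
        da, db, structs = _two_structure_setup(rng)
        w = LossWeights(1.0, 0.1)
        loss, mse, dvh = combined_loss_tensor(Tensor(da), Tensor(db), structs, weights=w)
        assert loss.item() == pytest.approx(1.0 * mse + 0.1 * dvh, rel=1e-12)
        # the stated arithmetic: components (0.5, 0.3) combine to 0.53
        assert 1.0 * 0.5 + 0.1 * 0.3 == pytest.approx(0.53)

    def test_zero_dvh_weight_reduces_to_mse(self, rng):
        da, db, structs = _two_structure_setup(rng)
        loss = combined_loss(da, db, structs, weights=LossWeights(1.0, 0.0))
        assert loss == pytest.approx(np.mean((da - db) ** 2), rel=1e-12)

    def test_gradient_matches_finite_differences(self, rng):
        from conftest import fd_gradient

        da = rng.random((4, 4, 4)) * 70
        db = rng.random((4, 4, 4)) * 70
        structs = StructureSet({"A": (rng.random((4, 4, 4)) > 0.5).astype(np.uint8)})
        pred = Tensor(db, requires_grad=True)
        loss, _, _ = combined_loss_tensor(Tensor(da), pred, structs)
        loss.backward()

        def value():
            l, _, _ = combined_loss_tensor(Tensor(da), Tensor(pred.data), structs)
            return l.item()

        idx = rng.choice(pred.size, size=12, replace=False)
        num = fd_gradient(value, pred, idx, eps=1e-5)
        np.testing.assert_allclose(pred.grad.reshape(-1)[idx], num, rtol=1e-4, atol=1e-9)

    def test_gradient_nonzero_at_masked_voxels_when_curves_differ(self, rng):
        da = np.full((3, 3, 3), 60.0)
        db = np.full((3, 3, 3), 40.0)
        mask = np.zeros((3, 3, 3), dtype=np.uint8)
        mask[1, 1, 1] = 1
        structs = StructureSet({"A": mask})
        pred = Tensor(db, requires_grad=True)
        loss, _, _ = combined_loss_tensor(Tensor(da), pred, structs, weights=LossWeights(0.0, 1.0))
        loss.backward()
        assert abs(pred.grad[1, 1, 1]) > 0
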