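"""Dosimetric metric identities and exhaustive-oracle equivalence."""

import numpy as np
import pytest
from scipy import stats

from hdaunet.core import DoseVolume, EmptyStructureError, StructureSet
from hdaunet.dvh import DVHSpec, exact_dvh
from hdaunet.metrics import (
    PrescriptionContext,
    compare_methods,
    conformity,
    coverage_and_max,
    dose_percentile,
    homogeneity,
    mean_dose_error,
    vxx,
)

CTX = PrescriptionContext(70.0, "PTV")


def _random_case(rng, n=6):
    dose = rng.random((n, n, n)) * 80
    ptv = (rng.random((n, n, n)) > 0.6).astype(np.uint8)
    ptv[n // 2, n // 2, n // 2] = 1  # never empty
    return dose, StructureSet({"PTV": ptv}, {"PTV": "target"})


class TestPercentiles:
    def test_uniform_dose_gives_prescription_everywhere(self):
        dose = np.full((4, 4, 4), 70.0)
        mask = np.ones((4, 4, 4))
        for p in (99, 98, 95, 50, 2):
            assert dose_percentile(dose, mask, p) == 70.0

    def test_ceil_rank_convention(self):
        # doses 10..100: D95 -> rank ceil(9.5) = 10 -> lowest value
        dose = np.arange(10.0, 101.0, 10.0).reshape(10, 1, 1)
        mask = np.ones_like(dose)
        assert dose_percentile(dose, mask, 95) == 10.0
        assert dose_percentile(dose, mask, 50) == 60.0

    def test_monotone_in_percentile(self, rng):
        dose, structs = _random_case(rng)
        m = structs["PTV"]
        d99, d98, d95, d50, d2 = (dose_percentile(dose, m, p) for p in (99, 98, 95, 50, 2))
        assert d99 <= d98 <= d95 <= d50 <= d2

    def test_matches_sorted_rank_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 40))
            vals = rng.random(n) * 80
            dose = vals.reshape(n, 1, 1)
            mask = np.ones_like(dose)
            for p in (99, 98, 95, 50, 2):
                srt = np.sort(vals)[::-1]
                expected = srt[int(np.ceil(p / 100 * n)) - 1]
                assert dose_percentile(dose, mask, p) == pytest.approx(expected, abs=1e-9)

    def test_empty_mask_rejected(self):
        with pytest.raises(EmptyStructureError):
            dose_percentile(np.ones((2, 2, 2)), np.zeros((2, 2, 2)), 95)


class TestCoverageAndMax:
    def test_single_hot_voxel_sets_dmax(self):
        dose = np.full((4, 4, 4), 70.0)
        dose[0, 0, 0] = 1.06 * 70
        structs = StructureSet({"PTV": np.ones((4, 4, 4), dtype=np.uint8)})
        out = coverage_and_max(dose, structs, CTX)
        assert out["Dmax"] == pytest.approx(1.06)
        assert out["D95"] == pytest.approx(1.0)

    def test_matches_exhaustive_scan(self, rng):
        dose, structs = _random_case(rng)
        out = coverage_and_max(dose, structs, CTX)
        assert out["Dmax"] == pytest.approx(dose.max() / 70.0, abs=1e-12)
        vals = np.sort(dose[structs["PTV"].astype(bool)])[::-1]
        expected = vals[int(np.ceil(0.95 * len(vals))) - 1] / 70.0
        assert out["D95"] == pytest.approx(expected, abs=1e-12)

    def test_tight_noise_free_phantom_has_unit_d95(self):
        from hdaunet.phantom import PhantomSpec, generate_anatomy, generate_reference_dose

        spec = PhantomSpec(grid_shape=(24, 24, 16), seed=2, noise_sd=0.0, oar_sparing=0.0,
                           falloff_tau=0.5, hotspot=1.0, n_oars=0,
                           ptv_radius_range=(5.0, 8.0))
        _, s = generate_anatomy(spec)
        dose = generate_reference_dose(s, spec)
        ctx = PrescriptionContext(spec.prescription, "PTV")
        assert coverage_and_max(dose, s, ctx)["D95"] == pytest.approx(1.0, abs=0.01)


class TestHomogeneity:
    def test_uniform_dose(self):
        structs = StructureSet({"PTV": np.ones((3, 3, 3), dtype=np.uint8)})
        h1, h2 = homogeneity(np.full((3, 3, 3), 70.0), structs, CTX)
        assert h1 == 0.0 and h2 == 1.0

    def test_linear_ramp_matches_percentile_oracle(self):
        vals = np.linspace(60, 70, 64)
        dose = vals.reshape(4, 4, 4)
        structs = StructureSet({"PTV": np.ones((4, 4, 4), dtype=np.uint8)})
        srt = np.sort(vals)[::-1]

        def dp(p):
            return srt[int(np.ceil(p / 100 * 64)) - 1]

        h1, h2 = homogeneity(dose, structs, CTX)
        assert h1 == pytest.approx((dp(2) - dp(98)) / dp(50), abs=1e-12)
        assert h2 == pytest.approx(dp(95) / dp(50), abs=1e-12)
        assert h1 >= 0.0


class TestConformity:
    def test_perfect_conformity(self):
        ptv = np.zeros((6, 6, 6), dtype=np.uint8)
        ptv[2:4, 2:4, 2:4] = 1
        dose = np.where(ptv, 70.0, 10.0)
        ci, vant = conformity(dose, StructureSet({"PTV": ptv}), CTX)
        assert ci == 1.0 and vant == 1.0

    def test_isodose_twice_target_volume(self):
        ptv = np.zeros((8, 8, 8), dtype=np.uint8)
        ptv[:2, :2, :2] = 1  # 8 voxels
        dose = np.full((8, 8, 8), 0.0)
        dose[:2, :2, :4] = 70.0  # 16 voxels covering the PTV
        ci, vant = conformity(dose, StructureSet({"PTV": ptv}), CTX)
        assert ci == 1.0 and vant == pytest.approx(0.5)

    def test_no_voxel_at_isodose_gives_zero(self):
        ptv = np.ones((3, 3, 3), dtype=np.uint8)
        ci, vant = conformity(np.full((3, 3, 3), 35.0), StructureSet({"PTV": ptv}), CTX)
        assert ci == 0.0 and vant == 0.0

    def test_matches_set_count_oracle_and_bound(self, rng):
        for _ in range(50):
            dose, structs = _random_case(rng)
            ci, vant = conformity(dose, structs, CTX)
            ptv = structs["PTV"].astype(bool)
            v100 = dose >= 70.0
            inter = int((ptv & v100).sum())
            assert ci == pytest.approx(inter / ptv.sum(), abs=1e-12)
            if v100.sum():
                assert vant == pytest.approx(inter**2 / (ptv.sum() * v100.sum()), abs=1e-12)
                sel = inter / v100.sum()
                assert vant <= min(ci, sel) + 1e-12
            assert vant <= ci + 1e-12


class TestMeanDoseError:
    def test_zero_for_identical_plans(self, rng):
        dose, structs = _random_case(rng)
        out = mean_dose_error(dose, dose.copy(), structs, CTX)
        assert out["PTV"] == 0.0

    def test_constant_offset_is_one_percent(self, rng):
        dose, structs = _random_case(rng)
        out = mean_dose_error(dose, dose + 0.7, structs, CTX)
        assert out["PTV"] == pytest.approx(1.0, rel=1e-12)

    def test_matches_voxel_loop_oracle(self, rng):
        dt, structs = _random_case(rng)
        dp = dt + rng.normal(size=dt.shape)
        dp = np.clip(dp, 0, None)
        out = mean_dose_error(dt, dp, structs, CTX)
        mask = structs["PTV"].astype(bool)
        acc = [abs(dt[i, j, k] - dp[i, j, k]) for i, j, k in zip(*np.nonzero(mask))]
        assert out["PTV"] == pytest.approx(np.mean(acc) / 70 * 100, abs=1e-10)


class TestVxx:
    def test_uniform_doses(self):
        mask = np.ones((3, 3, 3))
        assert vxx(np.full((3, 3, 3), 40.0), mask, 30) == 100.0
        assert vxx(np.full((3, 3, 3), 20.0), mask, 30) == 0.0

    def test_consistent_with_exact_dvh(self, rng):
        dose, structs = _random_case(rng)
        mask = structs["PTV"]
        for x in (10.0, 30.0, 55.0):
            curve = exact_dvh(dose, mask, DVHSpec(thresholds=np.array([x])))
            assert vxx(dose, mask, x) == pytest.approx(100 * curve[0], abs=1e-12)


class TestCompareMethods:
    def test_identical_samples_give_p_one(self):
        assert compare_methods([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)

    def test_textbook_case_matches_closed_form(self):
        a, b = [1.0, 2.0, 3.0], [2.0, 3.0, 4.0]
        # pooled variance 1, t = -1 / sqrt(2/3), df = 4
        t_stat = -1.0 / np.sqrt(2.0 / 3.0)
        expected = 2 * stats.t.sf(abs(t_stat), df=4)
        assert compare_methods(a, b) == pytest.approx(expected, rel=1e-12)

    def test_symmetric(self, rng):
        a, b = rng.normal(size=6), rng.normal(size=8)
        assert compare_methods(a, b) == pytest.approx(compare_methods(b, a), rel=1e-12)

    def test_zero_variance_equal_means_convention(self):
        assert compare_methods([2.0, 2.0], [2.0, 2.0]) == 1.0

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            compare_methods([1.0], [1.0, 2.0])
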