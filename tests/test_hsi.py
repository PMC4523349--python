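"""Core HSI model: curve interpolation, Beer-law light, geometric mean."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from savgsa import (
    CellEnvironment,
    SpeciesModel,
    SuitabilityCurve,
    compute_adbl,
    evaluate_cell,
    interpolate_si,
    select_adbl_curve,
    total_hsi,
)


def _random_curve(rng, n_pts):
    xs = np.sort(rng.uniform(-5, 40, n_pts))
    while np.any(np.diff(xs) <= 0):
        xs = np.sort(rng.uniform(-5, 40, n_pts))
    sis = rng.uniform(0, 1, n_pts)
    return SuitabilityCurve("salinity", tuple(zip(xs, sis)))


class TestSuitabilityCurve:
    @pytest.mark.parametrize(
        "breakpoints, x, expected",
        [
            ((((0, 1), (10, 0))), 5.0, 0.5),  # midpoint of a linear segment
            ((((0, 1), (10, 0))), -3.0, 1.0),  # clamp below the domain
            ((((0, 1), (10, 0))), 12.0, 0.0),  # clamp above the domain
            ((((0, 0), (5, 1), (20, 1), (30, 0))), 27.0, 0.3),  # 1-(27-20)/10
            ((((0, 0), (5, 1), (20, 1), (30, 0))), 10.0, 1.0),  # on a plateau
        ],
    )
    def test_interpolation_examples(self, breakpoints, x, expected):
        curve = SuitabilityCurve("salinity", breakpoints)
        assert interpolate_si(curve, x) == pytest.approx(expected)

    def test_nonfinite_x_rejected(self, ramp_curve):
        for bad in (float("nan"), float("inf")):
            with pytest.raises(ValueError):
                interpolate_si(ramp_curve, bad)

    @pytest.mark.parametrize(
        "breakpoints",
        [
            ((0, 1),),  # too few points
            ((0, 1), (0, 0)),  # non-increasing x
            ((0, 1.5), (10, 0)),  # si out of range
        ],
    )
    def test_invalid_curves_rejected(self, breakpoints):
        with pytest.raises(ValueError):
            SuitabilityCurve("salinity", breakpoints)

    def test_matches_dense_segment_oracle(self):
        """Agrees with a brute-force nearest-segment evaluation on random curves.

        The oracle finds the bracketing segment by linear scan and applies
        the two-point line formula directly.
        """
        rng = np.random.default_rng(42)
        for _ in range(25):
            curve = _random_curve(rng, rng.integers(2, 9))
            xs, sis = curve.x, curve.si
            for x in rng.uniform(-10, 45, 40):
                if x <= xs[0]:
                    expected = sis[0]
                elif x >= xs[-1]:
                    expected = sis[-1]
                else:
                    j = next(i for i in range(len(xs) - 1) if xs[i] <= x <= xs[i + 1])
                    w = (x - xs[j]) / (xs[j + 1] - xs[j])
                    expected = (1 - w) * sis[j] + w * sis[j + 1]
                assert interpolate_si(curve, x) == pytest.approx(expected, abs=1e-12)


class TestAdbl:
    def test_closed_form(self):
        env = CellEnvironment(salinity=20, temperature=25, depth=1.0, par=1000, k_light=0.85)
        assert compute_adbl(env, 0.9) == pytest.approx(900 * math.exp(-0.85), rel=1e-12)
        assert compute_adbl(env, 0.9) == pytest.approx(384.67, abs=0.01)

    def test_zero_depth_and_zero_par(self):
        surf = CellEnvironment(salinity=0, temperature=25, depth=0.0, par=1000, k_light=0.85)
        assert compute_adbl(surf, 0.9) == pytest.approx(900.0)
        dark = CellEnvironment(salinity=0, temperature=25, depth=3.0, par=0.0, k_light=0.85)
        assert compute_adbl(dark, 0.9) == 0.0

    @given(
        depth=st.floats(0.01, 10), k=st.floats(0.01, 3),
        d_inc=st.floats(0.01, 2), k_inc=st.floats(0.01, 1),
    )
    def test_strictly_decreasing_in_depth_and_k(self, depth, k, d_inc, k_inc):
        def adbl(d, kk):
            return compute_adbl(
                CellEnvironment(salinity=0, temperature=25, depth=d, par=500, k_light=kk)
            )

        assert adbl(depth + d_inc, k) < adbl(depth, k)
        assert adbl(depth, k + k_inc) < adbl(depth, k)


class TestAdblCurveSelection:
    def test_single_curve_species_ignores_salinity(self, toy_species):
        assert select_adbl_curve(toy_species, 30.0) is toy_species.adbl_curves[0]

    def test_threshold_rule(self, dual_adbl_species):
        assert select_adbl_curve(dual_adbl_species, 5.0) is dual_adbl_species.adbl_curves[0]
        # salinity exactly at the threshold selects the high-salinity curve
        assert select_adbl_curve(dual_adbl_species, 10.0) is dual_adbl_species.adbl_curves[1]
        assert select_adbl_curve(dual_adbl_species, 25.0) is dual_adbl_species.adbl_curves[1]

    def test_threshold_required_iff_two_curves(self, toy_species):
        with pytest.raises(ValueError):
            SpeciesModel(
                name="bad",
                salinity_curve=toy_species.salinity_curve,
                temperature_curve=toy_species.temperature_curve,
                adbl_curves=toy_species.adbl_curves,
                adbl_salinity_threshold=10.0,
            )


class TestTotalHsi:
    @pytest.mark.parametrize(
        "parts, expected",
        [
            ((1, 1, 1), 1.0),
            ((0, 0.9, 0.9), 0.0),  # limiting factor
            ((0.2, 0.4, 0.8), 0.4),  # cube root of 0.064
        ],
    )
    def test_examples(self, parts, expected):
        assert total_hsi(*parts) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            total_hsi(1.2, 0.5, 0.5)
        with pytest.raises(ValueError):
            total_hsi(0.5, -0.1, 0.5)

    @given(
        a=st.floats(0, 1), b=st.floats(0, 1), c=st.floats(0, 1),
    )
    def test_symmetric_and_bounded_by_min_max(self, a, b, c):
        h = total_hsi(a, b, c)
        assert h == pytest.approx(total_hsi(c, a, b), rel=1e-12, abs=1e-300)
        assert h == pytest.approx(total_hsi(b, c, a), rel=1e-12, abs=1e-300)
        assert min(a, b, c) - 1e-12 <= h <= max(a, b, c) + 1e-12

    @given(a=st.floats(0, 1))
    def test_idempotent_on_equal_inputs(self, a):
        assert total_hsi(a, a, a) == pytest.approx(a, abs=1e-12)


class TestEvaluateCell:
    def test_baseline_equals_deterministic_hsi(self, toy_species):
        """All multipliers 1 reproduces the plain (unperturbed) model."""
        env = CellEnvironment(salinity=12, temperature=24, depth=1.2, par=900, k_light=0.85)
        hsi, si_sal, si_temp, si_adbl = evaluate_cell(toy_species, env)
        assert si_sal == pytest.approx(1.0)  # on the plateau 5..20
        assert si_temp == pytest.approx(1.0)
        adbl = 0.9 * 900 * math.exp(-0.85 * 1.2)  # 292.1, on the rising limb
        assert si_adbl == pytest.approx(adbl / 400)
        assert hsi == pytest.approx(total_hsi(si_sal, si_temp, si_adbl))

    def test_full_suitability_plateau_gives_one(self, toy_species):
        env = CellEnvironment(salinity=10, temperature=25, depth=0.0, par=600, k_light=0.85)
        hsi, *_ = evaluate_cell(toy_species, env)
        assert hsi == pytest.approx(1.0)

    def test_limiting_factor_zero(self, toy_species):
        env = CellEnvironment(salinity=0.0, temperature=25, depth=0.0, par=600, k_light=0.85)
        hsi, si_sal, *_ = evaluate_cell(toy_species, env)
        assert si_sal == 0.0 and hsi == 0.0

    def test_hand_oracle_with_multipliers(self, dual_adbl_species):
        """Step-by-step hand computation of one perturbed evaluation."""
        env = CellEnvironment(salinity=12.0, temperature=22.0, depth=0.5, par=800, k_light=1.0)
        m = (1.1, 0.9, 1.2, 0.8)  # f.sal, f.temp, f.adbl, f.adbl2
        # hand computation:
        adbl = 0.9 * 800 * math.exp(-1.0 * 0.5)        # 436.70...
        si_sal = 1.1 * (1 - 12 / 15)                   # ramp 1->0 over 0..15
        si_temp = 0.9 * (1 - (22 - 20) / 15)           # descending limb 20->35
        si_adbl = 0.8 * (adbl / 600)                   # salinity 12 >= threshold 10 -> high curve
        expected = (si_sal * si_temp * si_adbl) ** (1 / 3)
        hsi, s1, s2, s3 = evaluate_cell(dual_adbl_species, env, m)
        assert (s1, s2, s3) == pytest.approx((si_sal, si_temp, si_adbl))
        assert hsi == pytest.approx(expected)

    def test_multiplier_truncation_to_unit_interval(self, toy_species):
        env = CellEnvironment(salinity=10, temperature=25, depth=0.0, par=600, k_light=0.85)
        hsi, si_sal, si_temp, si_adbl = evaluate_cell(toy_species, env, (1.2, 1.2, 1.2))
        assert (si_sal, si_temp, si_adbl) == (1.0, 1.0, 1.0)
        assert hsi == 1.0

    def test_wrong_multiplier_count_rejected(self, toy_species):
        env = CellEnvironment(salinity=10, temperature=25, depth=0.5, par=600, k_light=0.85)
        with pytest.raises(ValueError):
            evaluate_cell(toy_species, env, (1.0, 1.0))
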