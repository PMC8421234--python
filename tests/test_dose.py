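"""EQD2 conversion and dose-volume metrics against hand values and a
brute-force per-voxel oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thyntcp import (
    DoseGrid,
    DoseKind,
    FractionationScheme,
    RadiobiologyParams,
    StructureMask,
    convert_to_eqd2,
    cumulative_dvh,
    dose_metrics,
    eqd2_voxel,
)
from conftest import random_grid_and_mask


def brute_force_metrics(values, mask, levels):
    """Exhaustive per-voxel enumeration of Dmin/Dmax/Dmean and Vx."""
    doses = [float(values[idx]) for idx in np.ndindex(values.shape) if mask[idx]]
    n = len(doses)
    vx = {x: 100.0 * sum(1 for d in doses if d >= x) / n for x in levels}
    return min(doses), max(doses), sum(doses) / n, vx


def brute_force_dvh(values, mask, edges):
    doses = [float(values[idx]) for idx in np.ndindex(values.shape) if mask[idx]]
    return [100.0 * sum(1 for d in doses if d >= e) / len(doses) for e in edges]


def uniform_grid(dose, shape=(4, 4, 4), kind=DoseKind.PHYSICAL):
    return DoseGrid(np.full(shape, float(dose)), spacing=(1, 1, 1), dose_kind=kind)


class TestEQD2Voxel:
    @pytest.mark.parametrize(
        "D, d, ab, expected",
        [
            (50.0, 2.0, 3.0, 50.0),     # 2 Gy/fraction identity
            (0.0, 1.7, 3.0, 0.0),       # zero dose
            (60.0, 1.5, 3.0, 54.0),     # 60 * 4.5 / 5
            (46.2, 1.4, 3.0, 46.2 * 4.4 / 5.0),
        ],
    )
    def test_hand_values(self, D, d, ab, expected):
        assert eqd2_voxel(D, d, RadiobiologyParams(ab)) == pytest.approx(expected)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            eqd2_voxel(-1.0, 2.0)
        with pytest.raises(ValueError):
            eqd2_voxel(10.0, -0.5)
        with pytest.raises(ValueError):
            RadiobiologyParams(0.0)
        with pytest.raises(ValueError):
            RadiobiologyParams(-3.0)

    @settings(deadline=None, derandomize=True)
    @given(
        D=st.floats(0.0, 200.0),
        ab=st.floats(0.5, 20.0),
    )
    def test_identity_at_two_gray_per_fraction(self, D, ab):
        assert eqd2_voxel(D, 2.0, RadiobiologyParams(ab)) == pytest.approx(D)

    @settings(deadline=None, derandomize=True)
    @given(
        D=st.floats(0.1, 100.0),
        d=st.floats(0.1, 5.0),
        delta=st.floats(0.01, 10.0),
        ab=st.floats(0.5, 20.0),
    )
    def test_monotone_in_total_and_fraction_dose(self, D, d, delta, ab):
        p = RadiobiologyParams(ab)
        assert eqd2_voxel(D + delta, d, p) > eqd2_voxel(D, d, p)
        assert eqd2_voxel(D, d + delta, p) > eqd2_voxel(D, d, p)


class TestConvertGrid:
    def test_identity_fractionation(self):
        out = convert_to_eqd2(uniform_grid(44.0), FractionationScheme(22))
        assert out.dose_kind is DoseKind.EQD2
        np.testing.assert_allclose(out.values, 44.0)

    def test_hypofractionation_hand_value(self):
        # d = 44/33 Gy; EQD2 = 44 * (4/3 + 3) / 5 = 38.1333...
        out = convert_to_eqd2(uniform_grid(44.0), FractionationScheme(33))
        np.testing.assert_allclose(out.values, 44.0 * (44.0 / 33.0 + 3.0) / 5.0)
        np.testing.assert_allclose(out.values, 38.13333333, rtol=1e-8)

    def test_single_voxel_two_gray(self):
        g = DoseGrid(np.full((1, 1, 1), 70.0), spacing=(2, 2, 2))
        out = convert_to_eqd2(g, FractionationScheme(35))
        assert out.values[0, 0, 0] == pytest.approx(70.0)

    def test_double_conversion_refused(self):
        g = uniform_grid(44.0, kind=DoseKind.EQD2)
        with pytest.raises(ValueError, match="already EQD2"):
            convert_to_eqd2(g, FractionationScheme(22))

    def test_geometry_preserved(self, rng):
        values, _, spacing = random_grid_and_mask(rng)
        g = DoseGrid(values, spacing=spacing, origin=(1.0, -2.0, 3.5))
        out = convert_to_eqd2(g, FractionationScheme(30))
        assert out.spacing == g.spacing and out.origin == g.origin
        assert out.shape == g.shape


class TestDVH:
    def test_uniform_structure(self):
        g = uniform_grid(30.0)
        m = StructureMask(np.ones(g.shape, dtype=bool))
        curve = cumulative_dvh(g, m, bin_width=1.0)
        at_or_below = curve.dose_edges <= 30.0
        np.testing.assert_allclose(curve.cum_volume_pct[at_or_below], 100.0)
        np.testing.assert_allclose(curve.cum_volume_pct[~at_or_below], 0.0)

    def test_two_level_half_half(self):
        values = np.concatenate([np.full(32, 20.0), np.full(32, 40.0)]).reshape(4, 4, 4)
        g = DoseGrid(values, spacing=(1, 1, 1))
        m = StructureMask(np.ones(g.shape, dtype=bool))
        curve = cumulative_dvh(g, m, bin_width=1.0)
        idx30 = int(np.where(np.isclose(curve.dose_edges, 30.0))[0][0])
        assert curve.cum_volume_pct[idx30] == pytest.approx(50.0)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            values, mask, spacing = random_grid_and_mask(rng)
            g = DoseGrid(values, spacing=spacing)
            m = StructureMask(mask)
            curve = cumulative_dvh(g, m, bin_width=0.7)
            expected = brute_force_dvh(values, mask, curve.dose_edges)
            np.testing.assert_array_equal(curve.cum_volume_pct, expected)

    def test_invariants(self, rng):
        values, mask, spacing = random_grid_and_mask(rng)
        curve = cumulative_dvh(DoseGrid(values, spacing=spacing), StructureMask(mask))
        assert curve.cum_volume_pct[0] == 100.0
        assert np.all(np.diff(curve.cum_volume_pct) <= 0)
        assert np.all((curve.cum_volume_pct >= 0) & (curve.cum_volume_pct <= 100))
        assert np.all(np.diff(curve.dose_edges) > 0)

    def test_bad_inputs(self):
        g = uniform_grid(10.0)
        m = StructureMask(np.ones(g.shape, dtype=bool))
        with pytest.raises(ValueError):
            cumulative_dvh(g, m, bin_width=0.0)
        with pytest.raises(ValueError):
            StructureMask(np.zeros(g.shape, dtype=bool))  # empty mask
        with pytest.raises(ValueError):
            cumulative_dvh(g, StructureMask(np.ones((2, 2, 2), dtype=bool)))


class TestDoseMetrics:
    def test_uniform_eqd2(self):
        g = uniform_grid(45.0, kind=DoseKind.EQD2)
        m = StructureMask(np.ones(g.shape, dtype=bool))
        dm = dose_metrics(g, m)
        assert dm.d_min == dm.d_max == dm.d_mean == 45.0
        assert dm.v[45] == 100.0 and dm.v[50] == 0.0

    def test_two_level_hand_values(self):
        values = np.concatenate([np.full(32, 20.0), np.full(32, 40.0)]).reshape(4, 4, 4)
        m = StructureMask(np.ones((4, 4, 4), dtype=bool))
        dm = dose_metrics(DoseGrid(values, spacing=(1, 1, 1)), m)
        assert dm.d_mean == pytest.approx(30.0)
        assert dm.v[30] == 50.0 and dm.v[10] == 100.0 and dm.v[45] == 0.0

    def test_fractionated_dose_from_physical_grid(self):
        g = uniform_grid(46.2)
        m = StructureMask(np.ones(g.shape, dtype=bool))
        dm = dose_metrics(g, m, scheme=FractionationScheme(33))
        assert dm.fractionated_dose == pytest.approx(1.4)

    def test_fractionated_dose_needs_physical_mean_for_eqd2(self):
        g = uniform_grid(45.0, kind=DoseKind.EQD2)
        m = StructureMask(np.ones(g.shape, dtype=bool))
        assert dose_metrics(g, m, scheme=FractionationScheme(30)).fractionated_dose is None
        dm = dose_metrics(g, m, scheme=FractionationScheme(30), physical_d_mean=42.0)
        assert dm.fractionated_dose == pytest.approx(1.4)

    def test_volume_cc(self):
        g = DoseGrid(np.full((10, 10, 10), 5.0), spacing=(2.0, 2.0, 2.5))
        m = StructureMask(np.ones(g.shape, dtype=bool))
        # 1000 voxels * 10 mm^3 = 10 cc
        assert dose_metrics(g, m).volume_cc == pytest.approx(10.0)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            values, mask, spacing = random_grid_and_mask(rng)
            dm = dose_metrics(DoseGrid(values, spacing=spacing), StructureMask(mask))
            lo, hi, mean, vx = brute_force_metrics(values, mask, dm.v.keys())
            assert dm.d_min == lo and dm.d_max == hi
            assert dm.d_mean == pytest.approx(mean, rel=1e-12)
            assert dm.v == vx

    def test_order_invariants(self, rng):
        for _ in range(10):
            values, mask, spacing = random_grid_and_mask(rng)
            dm = dose_metrics(DoseGrid(values, spacing=spacing), StructureMask(mask))
            assert dm.d_min <= dm.d_mean <= dm.d_max
            levels = sorted(dm.v)
            assert all(dm.v[a] >= dm.v[b] for a, b in zip(levels, levels[1:]))
            assert all(0.0 <= v <= 100.0 for v in dm.v.values())


def test_grid_validation():
    with pytest.raises(ValueError):
        DoseGrid(np.full((2, 2, 2), -1.0), spacing=(1, 1, 1))
    with pytest.raises(ValueError):
        DoseGrid(np.full((2, 2), 1.0), spacing=(1, 1, 1))
    with pytest.raises(ValueError):
        DoseGrid(np.full((2, 2, 2), 1.0), spacing=(1, 0, 1))
    with pytest.raises(ValueError):
        DoseGrid(np.full((2, 2, 2), np.nan), spacing=(1, 1, 1))
    with pytest.raises(ValueError):
        FractionationScheme(0)
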