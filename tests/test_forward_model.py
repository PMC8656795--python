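"""Diffusion forward model and LUT inversion."""

import numpy as np
import pytest

from ssopkit import (
    LUT,
    OpticalProperties,
    build_lut,
    diffuse_reflectance,
    invert_optical_properties,
)
from ssopkit.forward_model import QC_NAN, QC_OUT_OF_RANGE

# Frozen reference values computed beforehand by an independent plain-math
# evaluation of the closed-form expression (mu_a, mu_s_prime, n, fx) -> R_d.
REFERENCE_VALUES = [
    (0.01, 1.0, 1.4, 0.0, 0.6148876974487388),
    (0.01, 1.0, 1.4, 0.2, 0.11790694795236298),
    (0.03, 1.5, 1.4, 0.0, 0.5171879674542004),
    (0.03, 1.5, 1.4, 0.2, 0.18492024942316732),
]

PHANTOM_MU_A = np.linspace(0.005, 0.05, 10)
PHANTOM_MU_S = np.linspace(0.5, 3.0, 10)


@pytest.mark.parametrize("mu_a,mu_s,n,fx,expected", REFERENCE_VALUES)
def test_diffuse_reflectance_matches_independent_evaluation(mu_a, mu_s, n, fx, expected):
    op = OpticalProperties(mu_a, mu_s, n)
    assert diffuse_reflectance(op, fx) == pytest.approx(expected, rel=1e-12)


def test_reflectance_bounded_and_monotone_over_phantom_grid():
    """R_d in [0,1]; increasing in mu_s' at both frequencies; strictly
    decreasing in mu_a at DC (at the AC frequency the closed form is only
    monotone away from the low-absorption corner, so the endpoint
    comparison is asserted there); non-increasing in fx."""
    a = PHANTOM_MU_A[:, None]
    s = PHANTOM_MU_S[None, :]
    for fx in (0.0, 0.1, 0.2):
        rd = diffuse_reflectance(None, fx, mu_a=a, mu_s_prime=s, n=1.4)
        assert np.all(rd >= 0) and np.all(rd <= 1)
        assert np.all(np.diff(rd, axis=1) > 0)  # d/d mu_s' > 0
    rd0 = diffuse_reflectance(None, 0.0, mu_a=a, mu_s_prime=s, n=1.4)
    rd2 = diffuse_reflectance(None, 0.2, mu_a=a, mu_s_prime=s, n=1.4)
    assert np.all(np.diff(rd0, axis=0) < 0)  # d/d mu_a < 0 at DC
    # at the AC frequency absorption contrast holds in the scattering-
    # dominated region (mu_s' >~ 0.7 here); at the mu_s'=0.5 validity edge
    # the frequency term overwhelms absorption and the ordering inverts
    scatter_ok = PHANTOM_MU_S >= 0.7
    assert np.all(rd2[-1, scatter_ok] < rd2[0, scatter_ok])
    assert diffuse_reflectance(None, 0.2, mu_a=0.05, mu_s_prime=1.0, n=1.4) < \
        diffuse_reflectance(None, 0.2, mu_a=0.005, mu_s_prime=1.0, n=1.4)
    assert np.all(rd2 <= rd0)


@pytest.mark.parametrize(
    "kwargs",
    [dict(mu_a=-0.01, mu_s_prime=1.0), dict(mu_a=0.0, mu_s_prime=1.0),
     dict(mu_a=0.01, mu_s_prime=0.0)],
)
def test_nonpositive_properties_rejected(kwargs):
    with pytest.raises(ValueError):
        OpticalProperties(n=1.4, **kwargs)
    with pytest.raises(ValueError):
        diffuse_reflectance(None, 0.0, n=1.4, **kwargs)


def test_negative_frequency_rejected():
    with pytest.raises(ValueError):
        diffuse_reflectance(OpticalProperties(0.01, 1.0), -0.1)


class TestBuildLut:
    def test_entries_equal_forward_calls_at_random_nodes(self, default_lut):
        rng = np.random.default_rng(42)
        for _ in range(20):
            i = rng.integers(default_lut.mu_a_grid.size)
            j = rng.integers(default_lut.mu_s_grid.size)
            op = OpticalProperties(default_lut.mu_a_grid[i], default_lut.mu_s_grid[j],
                                   default_lut.n)
            assert default_lut.rd_dc[i, j] == diffuse_reflectance(op, default_lut.fx_dc)
            assert default_lut.rd_ac[i, j] == diffuse_reflectance(op, default_lut.fx_ac)

    def test_covers_phantom_property_range(self, default_lut):
        assert default_lut.mu_a_grid[0] <= 0.005 and default_lut.mu_a_grid[-1] >= 0.05
        assert default_lut.mu_s_grid[0] <= 0.5 and default_lut.mu_s_grid[-1] >= 3.0
        assert (default_lut.fx_dc, default_lut.fx_ac) == (0.0, 0.2)

    def test_table_invariants(self, default_lut):
        assert np.all(default_lut.rd_dc >= 0) and np.all(default_lut.rd_dc <= 1)
        assert np.all(default_lut.rd_ac <= default_lut.rd_dc)
        assert np.all(np.diff(default_lut.rd_dc, axis=0) < 0)

    def test_single_cell_grid(self):
        lut = build_lut([0.01], [1.0], 0.0, 0.2, 1.4)
        op = OpticalProperties(0.01, 1.0, 1.4)
        assert lut.rd_dc[0, 0] == diffuse_reflectance(op, 0.0)
        assert lut.rd_ac[0, 0] == diffuse_reflectance(op, 0.2)

    @pytest.mark.parametrize(
        "kwargs",
        [dict(mu_a_grid=[]), dict(mu_s_grid=[]),
         dict(fx_dc=0.2, fx_ac=0.2), dict(fx_dc=0.3, fx_ac=0.2),
         dict(mu_a_grid=[0.01, 0.005])],
    )
    def test_invalid_configuration_rejected(self, kwargs):
        base = dict(mu_a_grid=[0.005, 0.05], mu_s_grid=[0.5, 3.0], fx_dc=0.0, fx_ac=0.2)
        base.update(kwargs)
        with pytest.raises(ValueError):
            build_lut(**base)

    def test_save_load_round_trip(self, default_lut, tmp_path):
        path = tmp_path / "lut.csv"
        default_lut.save(path)
        back = LUT.load(path)
        np.testing.assert_array_equal(back.mu_a_grid, default_lut.mu_a_grid)
        np.testing.assert_array_equal(back.mu_s_grid, default_lut.mu_s_grid)
        np.testing.assert_array_equal(back.rd_dc, default_lut.rd_dc)
        np.testing.assert_array_equal(back.rd_ac, default_lut.rd_ac)
        assert (back.fx_dc, back.fx_ac, back.n) == (
            default_lut.fx_dc, default_lut.fx_ac, default_lut.n)


class TestInversion:
    def test_round_trip_over_phantom_range(self, default_lut):
        """Forward-map a 10x10 truth grid, invert: median error < 1%, max
        error < one LUT grid cell."""
        a, s = np.meshgrid(PHANTOM_MU_A, PHANTOM_MU_S, indexing="ij")
        rd_dc = diffuse_reflectance(None, 0.0, mu_a=a, mu_s_prime=s, n=1.4)
        rd_ac = diffuse_reflectance(None, 0.2, mu_a=a, mu_s_prime=s, n=1.4)
        ops = invert_optical_properties(rd_dc, rd_ac, default_lut)
        rel_a = np.abs(ops.mu_a - a) / a
        rel_s = np.abs(ops.mu_s_prime - s) / s
        assert np.median(rel_a) < 0.01 and np.median(rel_s) < 0.01
        # one grid cell, as a relative width, at the coarsest part of the grid
        cell_a = np.max(np.diff(default_lut.mu_a_grid) / default_lut.mu_a_grid[1:])
        cell_s = np.max(np.diff(default_lut.mu_s_grid) / default_lut.mu_s_grid[:-1])
        assert rel_a.max() < cell_a and rel_s.max() < cell_s
        assert np.all(ops.qc == 0)

    def test_interior_relative_error_below_one_percent(self, default_lut):
        rng = np.random.default_rng(3)
        a = rng.uniform(0.006, 0.045, 200)
        s = rng.uniform(0.6, 2.8, 200)
        rd_dc = diffuse_reflectance(None, 0.0, mu_a=a, mu_s_prime=s, n=1.4)
        rd_ac = diffuse_reflectance(None, 0.2, mu_a=a, mu_s_prime=s, n=1.4)
        ops = invert_optical_properties(rd_dc, rd_ac, default_lut)
        assert np.max(np.abs(ops.mu_a - a) / a) < 0.01
        assert np.max(np.abs(ops.mu_s_prime - s) / s) < 0.01

    def test_exact_node_returns_node(self, default_lut):
        i, j = 57, 123
        ops = invert_optical_properties(
            np.array([[default_lut.rd_dc[i, j]]]),
            np.array([[default_lut.rd_ac[i, j]]]),
            default_lut,
        )
        assert ops.mu_a[0, 0] == pytest.approx(default_lut.mu_a_grid[i], rel=1e-9)
        assert ops.mu_s_prime[0, 0] == pytest.approx(default_lut.mu_s_grid[j], rel=1e-9)

    def test_matches_brute_force_nearest_node_search(self):
        """Against an exhaustive argmin oracle on a coarse LUT."""
        lut = build_lut(np.geomspace(0.004, 0.06, 41), np.linspace(0.4, 3.2, 41))
        rng = np.random.default_rng(11)
        a = rng.uniform(0.006, 0.05, 50)
        s = rng.uniform(0.5, 3.0, 50)
        rd_dc = diffuse_reflectance(None, 0.0, mu_a=a, mu_s_prime=s, n=1.4)
        rd_ac = diffuse_reflectance(None, 0.2, mu_a=a, mu_s_prime=s, n=1.4)
        ops = invert_optical_properties(rd_dc, rd_ac, lut)
        for k in range(a.size):
            d2 = (lut.rd_dc - rd_dc[k]) ** 2 + (lut.rd_ac - rd_ac[k]) ** 2
            i, j = np.unravel_index(np.argmin(d2), d2.shape)
            # refined solution stays within one cell of the oracle node
            assert abs(ops.mu_a[k] - lut.mu_a_grid[i]) <= np.max(np.diff(lut.mu_a_grid))
            assert abs(ops.mu_s_prime[k] - lut.mu_s_grid[j]) <= np.max(np.diff(lut.mu_s_grid))

    def test_out_of_range_clamped_and_flagged(self, default_lut):
        ops = invert_optical_properties(
            np.array([0.99]), np.array([0.98]), default_lut)
        assert ops.qc[0] & QC_OUT_OF_RANGE
        assert default_lut.mu_a_grid[0] <= ops.mu_a[0] <= default_lut.mu_a_grid[-1]

    def test_nan_pixels_propagate_flagged(self, default_lut):
        rd = np.array([[0.6, np.nan]])
        ops = invert_optical_properties(rd, rd * 0.2, default_lut)
        assert np.isnan(ops.mu_a[0, 1]) and ops.qc[0, 1] & QC_NAN
        assert np.isfinite(ops.mu_a[0, 0]) and ops.qc[0, 0] == 0

    def test_shape_mismatch_rejected(self, default_lut):
        with pytest.raises(ValueError):
            invert_optical_properties(np.zeros((2, 2)), np.zeros((2, 3)), default_lut)

    def test_scalar_and_map_inversion_agree(self, default_lut):
        op = OpticalProperties(0.02, 1.7)
        rd_dc = diffuse_reflectance(op, 0.0)
        rd_ac = diffuse_reflectance(op, 0.2)
        single = invert_optical_properties(np.array([rd_dc]), np.array([rd_ac]),
                                           default_lut)
        tiled = invert_optical_properties(np.full((5, 5), rd_dc),
                                          np.full((5, 5), rd_ac), default_lut)
        assert np.all(tiled.mu_a == single.mu_a[0])
        assert np.all(tiled.mu_s_prime == single.mu_s_prime[0])
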