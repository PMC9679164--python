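import numpy as np
import pytest

from conftest import random_display
from photoprf.calibration import (
    DisplayModel,
    ExcitationMatrix,
    build_excitation_matrix,
    michelson_contrast,
    receptor_excitation,
    solve_cone_isolating_pair,
    solve_rod_isolating_pair,
    validate_pair,
)
from photoprf.spectra import (
    ReceptorSet,
    SpectralCurve,
    gaussian_primary,
    standard_receptors,
)


def delta_spd(peak_nm, power, grid):
    v = np.zeros_like(grid)
    v[np.searchsorted(grid, peak_nm)] = power
    return SpectralCurve(grid, v)


@pytest.fixture(scope="module")
def mono_display(receptors):
    grid = receptors["L"].wavelength_nm
    return DisplayModel(
        primaries=(
            delta_spd(610.0, 2.0, grid),
            delta_spd(530.0, 1.5, grid),
            delta_spd(450.0, 1.0, grid),
        )
    )


class TestExcitationMatrix:
    def test_monochromatic_primaries_give_pointwise_products(
        self, mono_display, receptors
    ):
        # delta-like SPDs: entry (r, c) = power_c * S_r(peak_c) * dlambda
        m = build_excitation_matrix(mono_display, receptors).matrix
        peaks, powers = (610.0, 530.0, 450.0), (2.0, 1.5, 1.0)
        for r, name in enumerate(("L", "M", "S", "rod")):
            curve = receptors[name]
            for c in range(3):
                s = curve.value[np.searchsorted(curve.wavelength_nm, peaks[c])]
                assert np.isclose(m[r, c], powers[c] * s, rtol=1e-12)

    def test_zero_spds_give_zero_matrix(self, receptors):
        grid = receptors["L"].wavelength_nm
        zero = SpectralCurve(grid, np.zeros_like(grid))
        disp = DisplayModel(primaries=(zero, zero, zero))
        assert np.all(build_excitation_matrix(disp, receptors).matrix == 0)

    def test_linearity_in_spd_power(self, demo_display, receptors):
        m1 = build_excitation_matrix(demo_display, receptors).matrix
        doubled = DisplayModel(
            primaries=tuple(p.scaled(2.0) for p in demo_display.primaries),
            gamma=demo_display.gamma,
        )
        m2 = build_excitation_matrix(doubled, receptors).matrix
        assert np.allclose(m2, 2 * m1)

    def test_non_overlapping_ranges_error(self, receptors):
        grid = np.arange(900.0, 950.0)
        far = SpectralCurve(grid, np.ones_like(grid))
        disp = DisplayModel(primaries=(far, far, far))
        with pytest.raises(ValueError, match="non-overlapping"):
            build_excitation_matrix(disp, receptors)

    def test_riemann_sum_converges_under_grid_refinement(self, receptors):
        coarse = np.arange(390.0, 781.0, 2.0)
        fine = np.arange(390.0, 781.0, 0.5)
        mats = []
        for grid in (coarse, fine):
            disp = DisplayModel(
                primaries=(
                    gaussian_primary(610, grid=grid),
                    gaussian_primary(545, grid=grid),
                    gaussian_primary(465, grid=grid),
                )
            )
            mats.append(build_excitation_matrix(disp, receptors).matrix)
        # refinement changes every entry by < 0.1% of the matrix scale
        assert np.allclose(mats[0], mats[1], rtol=1e-3, atol=1e-3 * mats[1].max())


class TestReceptorExcitation:
    def test_zero_drive_gives_zero(self, demo_display, receptors):
        assert np.allclose(
            receptor_excitation(demo_display, receptors, np.zeros(3)), 0.0
        )

    def test_unit_red_with_linear_gamma_selects_first_column(self, receptors):
        disp = DisplayModel(
            primaries=(
                gaussian_primary(610), gaussian_primary(545), gaussian_primary(465),
            )
        )
        m = build_excitation_matrix(disp, receptors).matrix
        e = receptor_excitation(disp, receptors, np.array([1.0, 0.0, 0.0]))
        assert np.allclose(e, m[:, 0])

    def test_gamma_exponent_applied_per_channel(self, demo_display, receptors):
        m = build_excitation_matrix(demo_display, receptors).matrix
        e = receptor_excitation(demo_display, receptors, np.full(3, 0.5))
        assert np.allclose(e, m @ np.full(3, 0.5**2.2))

    def test_out_of_range_drive_errors(self, demo_display, receptors):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            receptor_excitation(demo_display, receptors, np.array([0.5, 1.2, 0.5]))


class TestMichelson:
    @pytest.mark.parametrize(
        "et,eb,expected", [(2.0, 1.0, 1 / 3), (5.0, 5.0, 0.0), (3.0, 1.0, 0.5)]
    )
    def test_known_values(self, et, eb, expected):
        assert np.isclose(michelson_contrast(et, eb), expected)

    def test_both_zero_errors(self):
        with pytest.raises(ValueError, match="undefined"):
            michelson_contrast(np.zeros(2), np.zeros(2))

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(0)
        a, b = rng.uniform(0, 10, 100), rng.uniform(1e-6, 10, 100)
        c = michelson_contrast(a, b)
        assert np.all((c >= 0) & (c <= 1))


TOY_MATRIX = ExcitationMatrix(
    np.array(
        [
            [2.0, 1.0, 0.0],  # L
            [1.0, 2.0, 0.0],  # M
            [0.0, 0.0, 1.0],  # S
            [1.0, 1.0, 1.0],  # rod
        ]
    )
)


@pytest.fixture(scope="module")
def linear_display(receptors):
    grid = receptors["L"].wavelength_nm
    ones = SpectralCurve(grid, np.ones_like(grid))
    return DisplayModel(primaries=(ones, ones, ones))  # linear gamma


class TestConeIsolatingPair:
    def test_zero_contrast_returns_background(self, demo_display, receptors):
        bg = np.array([0.5, 0.5, 0.5])
        pair = solve_cone_isolating_pair(demo_display, receptors, bg, 0.0)
        assert np.allclose(pair.target_drive, pair.background_drive)
        assert all(v == 0 for v in pair.receptor_contrasts.values())

    def test_toy_matrix_follows_rod_null_direction(self, linear_display, receptors):
        # rod row (1, 1, *): the rod-null direction in the R-G plane is (1, -1)
        bg = np.array([0.5, 0.5, 0.5])
        pair = solve_cone_isolating_pair(
            linear_display, receptors, bg, 0.1, matrix=TOY_MATRIX
        )
        delta = pair.target_drive - pair.background_drive
        assert np.isclose(delta[2], 0.0, atol=1e-15)
        assert np.isclose(delta[0], -delta[1], rtol=1e-9)
        lm = (pair.receptor_contrasts["L"] + pair.receptor_contrasts["M"]) / 2
        assert np.isclose(lm, 0.1, atol=1e-9)
        assert pair.receptor_contrasts["rod"] <= 1e-12

    def test_random_displays_silence_rods(self, receptors):
        rng = np.random.default_rng(11)
        for _ in range(5):
            disp = random_display(rng)
            bg = rng.uniform(0.4, 0.6, 3)
            pair = solve_cone_isolating_pair(disp, receptors, bg, 0.05)
            assert pair.receptor_contrasts["rod"] <= 1e-9
            assert pair.background_drive[2] == pair.target_drive[2]

    def test_contrast_roundtrip_matches_stored(self, demo_display, receptors):
        pair = solve_cone_isolating_pair(
            demo_display, receptors, np.array([0.5, 0.5, 0.5]), 0.08
        )
        re = pair.recompute_contrasts(demo_display, receptors)
        for k, v in pair.receptor_contrasts.items():
            assert np.isclose(re[k], v, atol=1e-12)

    def test_gamut_violation_names_channel(self, linear_display, receptors):
        bg = np.array([0.98, 0.02, 0.5])
        with pytest.raises(ValueError, match="limiting channel: [RG]"):
            solve_cone_isolating_pair(
                linear_display, receptors, bg, 0.9, matrix=TOY_MATRIX
            )

    def test_bidirectional_drive_deltas_scale_linearly(
        self, linear_display, receptors
    ):
        # with a linear-gamma display the bidirectional solve is exactly linear
        bg = np.array([0.5, 0.5, 0.5])
        p1 = solve_cone_isolating_pair(
            linear_display, receptors, bg, 0.05, bidirectional=True, matrix=TOY_MATRIX
        )
        p2 = solve_cone_isolating_pair(
            linear_display, receptors, bg, 0.10, bidirectional=True, matrix=TOY_MATRIX
        )
        d1 = p1.target_drive - p1.background_drive
        d2 = p2.target_drive - p2.background_drive
        assert np.allclose(d2, 2 * d1, rtol=1e-9)


class TestRodIsolatingPair:
    def test_zero_contrast_identical_drives(self, demo_display, receptors):
        pair = solve_rod_isolating_pair(
            demo_display, receptors, np.array([0.5, 0.5, 0.5]), 0.0
        )
        assert np.allclose(pair.target_drive, pair.background_drive)

    def test_toy_null_space_direction(self, linear_display, receptors):
        # L = e1, M = e2: the (L, M)-null space is the blue axis
        m = ExcitationMatrix(
            np.array([[1.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0], [0.5, 0.5, 1.0]])
        )
        pair = solve_rod_isolating_pair(
            linear_display, receptors, np.array([0.5, 0.5, 0.5]), 0.1, matrix=m
        )
        delta = pair.target_drive - pair.background_drive
        assert np.allclose(delta[:2], 0.0, atol=1e-15)
        assert abs(delta[2]) > 0
        assert np.isclose(pair.receptor_contrasts["rod"], 0.1, atol=1e-9)

    def test_silences_both_cone_classes(self, demo_display, receptors):
        pair = solve_rod_isolating_pair(
            demo_display, receptors, np.array([0.5, 0.5, 0.5]), 0.1
        )
        assert pair.receptor_contrasts["L"] <= 1e-9
        assert pair.receptor_contrasts["M"] <= 1e-9
        # S-cone contrast is reported but unconstrained
        assert "S" in pair.receptor_contrasts

    def test_degenerate_null_space_errors(self, linear_display, receptors):
        m = ExcitationMatrix(
            np.array([[1.0, 1, 1], [2.0, 2, 2], [0, 0, 1.0], [1.0, 0.5, 0.2]])
        )
        with pytest.raises(ValueError, match="null space"):
            solve_rod_isolating_pair(
                linear_display, receptors, np.array([0.5, 0.5, 0.5]), 0.1, matrix=m
            )


class TestValidatePair:
    def test_perfect_pair_passes(self, demo_display, receptors):
        pair = solve_cone_isolating_pair(
            demo_display, receptors, np.array([0.5, 0.5, 0.5]), 0.05
        )
        report = validate_pair(pair, demo_display, receptors, ["rod"], tol=1e-6)
        assert report["passed"]
        assert report["residuals"]["rod"] < 1e-9

    def test_miscalibrated_gamma_leaks_rod_contrast(self, receptors):
        solver_display = DisplayModel(
            primaries=(
                gaussian_primary(610), gaussian_primary(545), gaussian_primary(465),
            ),
            gamma=np.full(3, 2.2),
        )
        pair = solve_cone_isolating_pair(
            solver_display, receptors, np.array([0.5, 0.5, 0.5]), 0.2
        )
        # the physical screen has a slightly different (non-canonical) gamma
        true_display = DisplayModel(
            primaries=solver_display.primaries, gamma=np.array([2.4, 2.1, 2.2])
        )
        report = validate_pair(pair, true_display, receptors, ["rod"], tol=1e-6)
        assert not report["passed"]
        assert report["residuals"]["rod"] > 1e-6

    def test_empty_silenced_list_vacuous_pass(self, demo_display, receptors):
        pair = solve_cone_isolating_pair(
            demo_display, receptors, np.array([0.5, 0.5, 0.5]), 0.05
        )
        assert validate_pair(pair, demo_display, receptors, [], tol=0.0)["passed"]
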