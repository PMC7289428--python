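"""The hexagon colour model: captures, excitations, loci, hue sectors."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from beehex.spectra import MODEL_GRID, ReceptorSet, SpectralFunction, a1_template
from beehex.vision import (
    ACHROMATIC_EPS,
    SECTOR_NAMES,
    classify_sector,
    excitation,
    hexagon_coords,
    hue_and_contrast,
    locus_from_excitations,
    photon_capture,
    spectrum_to_locus,
    von_kries_coefficient,
)

SIN60 = math.sin(math.radians(60.0))


def flat(value, grid=MODEL_GRID):
    return SpectralFunction(grid, np.full(len(grid), float(value)))


class TestVonKries:
    def test_reciprocal_of_background_integral(self, illuminant):
        # engineered so ∫ S·I_B·D dλ = 2 exactly
        s = flat(1.0)
        bg = flat(1.0)
        d = flat(2.0 / (10.0 * MODEL_GRID.size))
        assert von_kries_coefficient(s, bg, d) == pytest.approx(0.5)

    def test_scaling_illuminant_scales_coefficient_inversely(
        self, background, illuminant, receptors
    ):
        r1 = von_kries_coefficient(receptors.b, background, illuminant)
        bright = SpectralFunction(illuminant.wavelengths_nm, 3.0 * illuminant.values)
        assert von_kries_coefficient(receptors.b, background, bright) == pytest.approx(
            r1 / 3.0
        )

    def test_degenerate_background_signalled(self, illuminant, receptors):
        with pytest.raises(ValueError, match="degenerate"):
            von_kries_coefficient(receptors.b, flat(0.0), illuminant)

    def test_agrees_with_trapezoid_oracle(self, background, illuminant, receptors):
        # Independent quadrature: trapezoid rule on the same grid differs
        # from the Riemann sum only by the half-weight endpoints.
        prod = (
            receptors.b.values * background.values * illuminant.values
        )
        trapezoid = 1.0 / np.trapezoid(prod, MODEL_GRID)
        riemann = von_kries_coefficient(receptors.b, background, illuminant)
        endpoint = 0.5 * (prod[0] + prod[-1]) * 10.0
        assert riemann == pytest.approx(1.0 / (1.0 / trapezoid + endpoint), rel=1e-12)
        assert riemann == pytest.approx(trapezoid, rel=0.02)


class TestPhotonCapture:
    def test_background_capture_is_unity(self, background, illuminant, receptors):
        for s in (receptors.uv, receptors.b, receptors.g):
            r = von_kries_coefficient(s, background, illuminant)
            assert photon_capture(s, background, illuminant, r) == pytest.approx(1.0)

    def test_zero_reflectance_zero_capture(self, background, illuminant, receptors):
        r = von_kries_coefficient(receptors.g, background, illuminant)
        assert photon_capture(receptors.g, flat(0.0), illuminant, r) == 0.0

    def test_linearity_in_stimulus(self, background, illuminant, receptors):
        r = von_kries_coefficient(receptors.uv, background, illuminant)
        doubled = SpectralFunction(
            background.wavelengths_nm, 2.0 * background.values
        )
        assert photon_capture(
            receptors.uv, doubled, illuminant, r
        ) == pytest.approx(2.0)


class TestExcitation:
    @pytest.mark.parametrize(
        "p,e", [(0.0, 0.0), (1.0, 0.5), (3.0, 0.75)]
    )
    def test_closed_form(self, p, e):
        assert excitation(p) == pytest.approx(e)

    def test_negative_capture_rejected(self):
        with pytest.raises(ValueError):
            excitation(-0.1)

    @given(st.floats(0.0, 1e6), st.floats(0.0, 1e6))
    def test_monotone_and_bounded(self, p1, p2):
        e1, e2 = excitation(p1), excitation(p2)
        assert 0.0 <= e1 < 1.0
        if p1 < p2:
            assert e1 <= e2


class TestHexagonGeometry:
    def test_adapted_background_at_centre(self):
        assert hexagon_coords(0.5, 0.5, 0.5) == (0.0, 0.0)

    def test_pure_vertices(self):
        assert hexagon_coords(0.0, 1.0, 0.0) == pytest.approx((0.0, 1.0))
        x, y = hexagon_coords(0.0, 0.0, 1.0)
        assert (x, y) == pytest.approx((SIN60, -0.5))
        x, y = hexagon_coords(1.0, 0.0, 0.0)
        assert (x, y) == pytest.approx((-SIN60, -0.5))

    def test_vertex_distances_exactly_one(self):
        for e in [(0.0, 1.0, 0.0), (1.0, 0.0, 0.0), (0.0, 0.0, 1.0)]:
            _, contrast = hue_and_contrast(*hexagon_coords(*e))
            assert contrast == pytest.approx(1.0, abs=1e-15)

    def test_hue_convention(self):
        assert hue_and_contrast(0.0, 1.0) == (pytest.approx(90.0), pytest.approx(1.0))
        # hand oracle: atan2(-0.5, √3/2) = -30° → 330°
        hue, contrast = hue_and_contrast(SIN60, -0.5)
        assert hue == pytest.approx(330.0)
        assert contrast == pytest.approx(1.0)

    def test_achromatic_point_has_undefined_hue(self):
        hue, contrast = hue_and_contrast(0.0, 0.0)
        assert hue is None and contrast == 0.0
        hue, _ = hue_and_contrast(ACHROMATIC_EPS / 10, 0.0)
        assert hue is None

    @given(
        st.floats(0.0, 1.0), st.floats(0.0, 1.0), st.floats(0.0, 1.0)
    )
    def test_physical_excitations_stay_in_hexagon(self, euv, eb, eg):
        _, contrast = hue_and_contrast(*hexagon_coords(euv, eb, eg))
        assert contrast <= 1.0 + 1e-12


class TestSectorClassification:
    @pytest.mark.parametrize(
        "hue,sector",
        [
            (90.0, "B"), (0.0, "BG"), (60.0, "B"), (330.0, "G"),
            (120.0, "UB"), (180.0, "U"), (240.0, "UG"), (300.0, "G"),
            (59.999, "BG"), (359.999, "G"),
        ],
    )
    def test_sector_convention(self, hue, sector):
        assert classify_sector(hue) == sector

    def test_undefined_hue_rejected(self):
        with pytest.raises(ValueError):
            classify_sector(None)

    @given(st.floats(0.0, 360.0, exclude_max=True))
    def test_partition_of_the_circle(self, hue):
        # total on [0, 360) and the six preimages tile it in 60° blocks
        sector = classify_sector(hue)
        assert sector in SECTOR_NAMES
        assert sector == SECTOR_NAMES[int(hue // 60)]


class TestFullPipeline:
    def test_background_neutrality(self, background):
        locus = spectrum_to_locus(background)
        assert abs(locus.x) < 1e-12 and abs(locus.y) < 1e-12
        assert locus.sector is None

    def test_flat_white_brighter_than_background_everywhere(self):
        locus = spectrum_to_locus(flat(1.0))
        assert min(locus.e_uv, locus.e_b, locus.e_g) > 0.5

    def test_illuminant_scale_invariance(self, background, illuminant):
        stim = flat(0.6)
        l1 = spectrum_to_locus(stim, background, illuminant)
        scaled = SpectralFunction(illuminant.wavelengths_nm, 7.3 * illuminant.values)
        l2 = spectrum_to_locus(stim, background, scaled)
        assert (l1.x, l1.y) == pytest.approx((l2.x, l2.y), abs=1e-12)

    def test_blue_reflectance_increase_moves_locus_up(self, background, illuminant):
        base = np.full(MODEL_GRID.size, 0.3)
        bump = base.copy()
        in_b = (MODEL_GRID >= 420) & (MODEL_GRID <= 470)
        bump[in_b] += 0.3
        l0 = spectrum_to_locus(SpectralFunction(MODEL_GRID, base), background, illuminant)
        l1 = spectrum_to_locus(SpectralFunction(MODEL_GRID, bump), background, illuminant)
        assert l1.y > l0.y

    def test_toy_grid_equivalence_with_hand_oracle(self):
        # Three wavelengths, every spectral value chosen by hand; the
        # expected locus is computed step by step with plain arithmetic.
        grid = np.array([400.0, 500.0, 600.0])
        dlam = 100.0
        sens = {
            "UV": np.array([1.0, 0.2, 0.0]),
            "B": np.array([0.3, 1.0, 0.1]),
            "G": np.array([0.0, 0.5, 1.0]),
        }
        stim_v = np.array([0.6, 0.1, 0.8])
        bg_v = np.array([0.2, 0.3, 0.4])
        d_v = np.array([1.0, 1.5, 0.9])

        exps = {}
        for name in ("UV", "B", "G"):
            r = 1.0 / float(np.sum(sens[name] * bg_v * d_v) * dlam)
            p = r * float(np.sum(sens[name] * stim_v * d_v) * dlam)
            exps[name] = p / (p + 1.0)
        ex = math.sin(math.radians(60.0)) * (exps["G"] - exps["UV"])
        ey = exps["B"] - 0.5 * (exps["G"] + exps["UV"])

        receptors = ReceptorSet(
            uv=SpectralFunction(grid, sens["UV"]),
            b=SpectralFunction(grid, sens["B"]),
            g=SpectralFunction(grid, sens["G"]),
            nominal_peaks=(400.0, 500.0, 600.0),
        )
        locus = spectrum_to_locus(
            SpectralFunction(grid, stim_v),
            SpectralFunction(grid, bg_v),
            SpectralFunction(grid, d_v),
            receptors,
        )
        assert locus.x == pytest.approx(ex, abs=1e-12)
        assert locus.y == pytest.approx(ey, abs=1e-12)

    def test_locus_from_excitations_consistency(self):
        locus = locus_from_excitations(0.2, 0.9, 0.4)
        assert locus.sector == classify_sector(locus.hue_deg)
        assert locus.contrast == pytest.approx(math.hypot(locus.x, locus.y))
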