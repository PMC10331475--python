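"""Ecosystem-function estimators: hand arithmetic, balances, monotonicity."""

import numpy as np
import pytest

from veqi.ecofunctions import (
    angstrom_prescott,
    biomass_to_npp_carbon,
    casa_npp,
    cover_factor,
    habitat_quality,
    ls_factor,
    rainfall_erosivity,
    soil_retention,
    water_conservation,
)
from veqi.errors import ConfigurationError, DomainError, ShapeError


def monthly(value, shape=(12, 2, 2)):
    return np.full(shape, float(value))


# ---------------------------------------------------------------------------
# CASA NPP
# ---------------------------------------------------------------------------

class TestCasaNpp:
    def test_hand_arithmetic_single_month(self):
        """SSR 100, FPAR 0.95, all stress scalars 1, eps_max 0.389
        -> 100 x 0.95 x 0.5 x 0.389 = 18.4775 g C m-2."""
        shape = (12, 1, 1)
        vi = np.zeros(shape)
        vi[0] = 0.95  # maps to FPAR cap
        ssr = np.zeros(shape)
        ssr[0] = 100.0
        npp = casa_npp(vi, monthly(15, shape), ssr, np.ones(shape),
                       eps_max=0.389, t1=1.0, t2=1.0)
        assert npp[0, 0, 0] == pytest.approx(18.4775, abs=1e-10)

    def test_bare_soil_limit(self):
        vi = monthly(0.05)  # at vi_min -> FPAR 0
        npp = casa_npp(vi, monthly(15), monthly(100), np.ones((12, 2, 2)))
        np.testing.assert_allclose(npp, 0.0)

    def test_linear_in_radiation(self):
        rng = np.random.default_rng(0)
        vi = rng.uniform(0.2, 0.8, (12, 3, 3))
        tem = rng.uniform(0, 25, (12, 3, 3))
        ssr = rng.uniform(200, 600, (12, 3, 3))
        w = rng.uniform(0.5, 1.0, (12, 3, 3))
        np.testing.assert_allclose(casa_npp(vi, tem, 2 * ssr, w), 2 * casa_npp(vi, tem, ssr, w), rtol=1e-12)

    def test_shape_and_domain_errors(self):
        with pytest.raises(ShapeError):
            casa_npp(monthly(0.5), monthly(10, (12, 3, 3)), monthly(100), np.ones((12, 2, 2)))
        with pytest.raises(DomainError):
            casa_npp(monthly(0.5), monthly(10), monthly(100), np.ones((12, 2, 2)), eps_max=0.0)

    def test_nonnegative_on_physical_inputs(self):
        rng = np.random.default_rng(3)
        npp = casa_npp(rng.uniform(-0.2, 1, (24, 4, 4)), rng.uniform(-10, 35, (24, 4, 4)),
                       rng.uniform(0, 700, (24, 4, 4)), rng.uniform(0, 1, (24, 4, 4)))
        assert np.all(npp >= 0)
        assert npp.shape == (2, 4, 4)


# ---------------------------------------------------------------------------
# Water conservation
# ---------------------------------------------------------------------------

class TestWaterConservation:
    landuse = np.array([[1, 1], [2, 2]])

    def test_hand_arithmetic(self):
        wc, floored = water_conservation(np.full((2, 2), 100.0), np.full((2, 2), 60.0),
                                         self.landuse, {1: 0.2, 2: 0.2})
        np.testing.assert_allclose(wc, 20.0)
        assert not floored.any()

    def test_floor_and_identity_cases(self):
        wc, floored = water_conservation(np.full((2, 2), 50.0), np.full((2, 2), 80.0),
                                         self.landuse, {1: 0.1, 2: 0.1})
        np.testing.assert_allclose(wc, 0.0)
        assert floored.all()
        wc, _ = water_conservation(np.full((2, 2), 123.0), np.zeros((2, 2)),
                                   self.landuse, {1: 0.0, 2: 0.0})
        np.testing.assert_allclose(wc, 123.0)

    def test_water_balance_closes(self, rng):
        pre = rng.uniform(200, 1500, (5, 6, 6))
        et = rng.uniform(100, 1200, (5, 6, 6))
        landuse = rng.integers(1, 4, (6, 6))
        coefs = {1: 0.1, 2: 0.25, 3: 0.4}
        wc, floored = water_conservation(pre, et, landuse, coefs)
        coef = np.vectorize(coefs.get)(landuse)
        deficit = np.where(floored, -(pre - et - pre * coef), 0.0)
        np.testing.assert_allclose(wc + pre * coef + et - deficit, pre, atol=1e-9)

    def test_missing_class_raises(self):
        with pytest.raises(ConfigurationError):
            water_conservation(np.ones((2, 2)), np.ones((2, 2)), self.landuse, {1: 0.2})


# ---------------------------------------------------------------------------
# Soil retention
# ---------------------------------------------------------------------------

class TestSoilRetention:
    pre = np.full((12, 5, 5), 80.0)
    dem_flat = np.full((5, 5), 1000.0)

    def dem_sloped(self, degrees=10.0, cell=500.0):
        rise = np.tan(np.radians(degrees)) * cell
        return 1000.0 + rise * np.arange(5)[:, None] * np.ones((5, 5))

    def test_full_cover_gives_maximum_retention(self):
        fvc = np.ones((1, 5, 5))
        sr = soil_retention(self.pre, self.dem_sloped(), fvc, 0.03)
        r = rainfall_erosivity(self.pre)
        ls = ls_factor(self.dem_sloped())
        np.testing.assert_allclose(sr, r * 0.03 * ls, rtol=1e-12)

    def test_bare_soil_retains_nothing(self):
        sr = soil_retention(self.pre, self.dem_sloped(), np.zeros((1, 5, 5)), 0.03)
        np.testing.assert_allclose(sr, 0.0, atol=1e-12)

    def test_slope_monotonicity(self):
        fvc = np.full((1, 5, 5), 0.7)
        flat = soil_retention(self.pre, self.dem_flat, fvc, 0.03)
        sloped = soil_retention(self.pre, self.dem_sloped(10.0), fvc, 0.03)
        interior = np.s_[:, 1:-1, 1:-1]
        assert np.all(sloped[interior] > flat[interior])

    def test_cover_factor_endpoints_and_monotone(self):
        assert cover_factor(0.0) == pytest.approx(1.0)
        assert cover_factor(1.0) == pytest.approx(0.0)
        f = np.linspace(0, 1, 50)
        assert np.all(np.diff(cover_factor(f)) < 0)

    def test_single_pixel_grid_rejected(self):
        with pytest.raises(DomainError):
            soil_retention(np.full((12, 1, 1), 80.0), np.ones((1, 1)), np.ones((1, 1, 1)), 0.03)


# ---------------------------------------------------------------------------
# Habitat quality
# ---------------------------------------------------------------------------

class TestHabitatQuality:
    def test_threat_free_limit(self):
        landuse = np.ones((4, 4), dtype=int)  # all forest, no threat pixels
        hq = habitat_quality(landuse, {4: {"weight": 1.0, "max_dist": 3.0}},
                             {1: {4: 0.8}}, {1: 0.9})
        np.testing.assert_allclose(hq, 0.9)

    def test_half_saturation_identity(self):
        """A threat source co-located with habitat of sensitivity 1 and
        weight k yields D = k, hence HQ = H / 2 on the source pixels."""
        landuse = np.full((3, 3), 3, dtype=int)  # all cropland (threat to itself)
        hq = habitat_quality(landuse, {3: {"weight": 0.5, "max_dist": 2.0}},
                             {3: {3: 1.0}}, {3: 0.8}, half_sat=0.5)
        np.testing.assert_allclose(hq, 0.4)

    @pytest.mark.parametrize("decay", ["linear", "exponential"])
    def test_moving_threat_farther_never_lowers_quality(self, decay):
        probe = (0, 0)
        values = []
        for col in range(1, 6):
            landuse = np.ones((1, 7), dtype=int)
            landuse[0, col] = 4  # urban source at increasing distance
            hq = habitat_quality(landuse, {4: {"weight": 1.0, "max_dist": 4.0, "decay": decay}},
                                 {1: {4: 0.8}, 4: {4: 0.0}}, {1: 1.0, 4: 0.05})
            values.append(hq[probe])
        assert np.all(np.diff(values) >= 0)

    def test_negative_weight_rejected(self):
        with pytest.raises(ConfigurationError):
            habitat_quality(np.ones((2, 2), dtype=int), {4: {"weight": -1.0, "max_dist": 2.0}},
                            {1: {4: 0.5}}, {1: 1.0})


# ---------------------------------------------------------------------------
# Utilities
# ---------------------------------------------------------------------------

class TestUtilities:
    def test_angstrom_prescott_cases(self):
        assert angstrom_prescott(12.0, 12.0, 40.0) == pytest.approx(30.0)
        assert angstrom_prescott(0.0, 12.0, 40.0) == pytest.approx(10.0)
        n = np.linspace(0, 12, 13)
        ssr = angstrom_prescott(n, 12.0, 40.0)
        assert np.all(np.diff(ssr) > 0)
        with pytest.raises(DomainError):
            angstrom_prescott(13.0, 12.0, 40.0)

    def test_biomass_carbon_hand_arithmetic(self):
        assert biomass_to_npp_carbon(0.0) == 0.0
        assert biomass_to_npp_carbon(100.0) == pytest.approx(219.3475, abs=1e-10)

    def test_biomass_carbon_linearity(self, rng):
        x = rng.uniform(0, 500, 20)
        np.testing.assert_allclose(biomass_to_npp_carbon(2 * x), 2 * biomass_to_npp_carbon(x), rtol=1e-12)
        with pytest.raises(DomainError):
            biomass_to_npp_carbon(-1.0)
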