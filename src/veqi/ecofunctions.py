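"""Annual ecosystem-function grids: NPP, water conservation, soil retention,
habitat quality, plus small field-data and radiation utilities.

Each estimator follows the canonical published form of its model family —
the CASA light-use-efficiency equation for net primary productivity, the
water-balance difference for conserved water, the RUSLE retention
difference for soil, and the InVEST threat-decay formulation for habitat
quality — with every coefficient exposed as a parameter so regional
calibrations can be swapped in.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, DomainError, ShapeError

__all__ = [
    "casa_npp",
    "casa_t1",
    "casa_t2",
    "water_scalar_from_sm",
    "water_conservation",
    "soil_retention",
    "rainfall_erosivity",
    "ls_factor",
    "cover_factor",
    "habitat_quality",
    "angstrom_prescott",
    "biomass_to_npp_carbon",
]


# ---------------------------------------------------------------------------
# Carbon sequestration: CASA light-use efficiency
# ---------------------------------------------------------------------------

def casa_t1(topt):
    """CASA temperature stress T1: a parabola in the optimal temperature,
    1.0 at 20 degC, penalising sites whose growing-season optimum is
    extreme. T1 = 0.8 + 0.02 Topt - 0.0005 Topt^2 (floored at 0)."""
    topt = np.asarray(topt, dtype=float)
    return np.clip(0.8 + 0.02 * topt - 0.0005 * topt**2, 0.0, None)


def casa_t2(topt, tem):
    """CASA temperature stress T2: double-logistic penalty for months whose
    temperature departs from the site optimum."""
    topt = np.asarray(topt, dtype=float)
    tem = np.asarray(tem, dtype=float)
    return 1.1814 / ((1.0 + np.exp(0.2 * (topt - 10.0 - tem)))
                     * (1.0 + np.exp(0.3 * (-topt - 10.0 + tem))))


def water_scalar_from_sm(sm: np.ndarray, floor: float = 0.5) -> np.ndarray:
    """Map soil moisture to the CASA water stress scalar W in [floor, 1]:
    W = floor + (1 - floor) * sm / max(sm), the common moisture-limited
    variant when regional evapotranspiration submodels are unavailable."""
    sm = np.asarray(sm, dtype=float)
    top = np.nanmax(sm)
    if not np.isfinite(top) or top <= 0:
        return np.full_like(sm, floor)
    return floor + (1.0 - floor) * sm / top


def casa_npp(vi, tem, ssr, water_scalar, eps_max: float = 0.389,
             vi_min: float = 0.05, vi_max: float = 0.95,
             fpar_max: float = 0.95, months_per_year: int = 12,
             topt=None, t1=None, t2=None) -> np.ndarray:
    """Annual NPP (g C m-2 yr-1) by the CASA light-use-efficiency model.

    Monthly NPP = APAR x eps with APAR = SSR x FPAR x 0.5 (half of incident
    shortwave is photosynthetically active) and eps = T1 x T2 x W x eps_max.
    FPAR is linear in the vegetation index between ``(vi_min, vi_max)`` and
    clipped to [0, fpar_max]. Annual NPP sums the 12 monthly values.

    Parameters
    ----------
    vi, tem, ssr, water_scalar
        (n_months, y, x) grids: vegetation index in [-0.2, 1], air
        temperature (degC), surface solar radiation (MJ m-2 month-1) and the
        water stress scalar W in [0, 1].
    eps_max
        Maximal light-use efficiency (g C MJ-1).
    topt
        Optimal temperature grid (y, x); derived per pixel as the
        temperature of the month with the greenest vegetation when omitted.
    t1, t2
        Optional overrides for the temperature stress scalars (broadcastable
        to the monthly grids); when given, ``topt`` is ignored for that term.
    """
    vi = np.asarray(vi, dtype=float)
    tem = np.asarray(tem, dtype=float)
    ssr = np.asarray(ssr, dtype=float)
    w = np.asarray(water_scalar, dtype=float)
    if not (vi.shape == tem.shape == ssr.shape):
        raise ShapeError("vi, tem and ssr must share a (month, y, x) shape")
    if w.shape != vi.shape and w.shape != vi.shape[1:]:
        raise ShapeError("water_scalar must match the monthly or spatial shape")
    if eps_max <= 0:
        raise DomainError("eps_max must be positive")
    if vi.shape[0] % months_per_year:
        raise ShapeError("time dimension must be a whole number of years")

    fpar = np.clip((vi - vi_min) / (vi_max - vi_min), 0.0, fpar_max)
    if t1 is None or t2 is None:
        if topt is None:
            greenest = np.argmax(vi, axis=0)
            topt = np.take_along_axis(tem, greenest[None], axis=0)[0]
        if t1 is None:
            t1 = casa_t1(topt)
        if t2 is None:
            t2 = casa_t2(topt, tem)
    eps = np.asarray(t1, dtype=float) * np.asarray(t2, dtype=float) * w * eps_max
    monthly = ssr * fpar * 0.5 * eps
    n_years = vi.shape[0] // months_per_year
    return monthly.reshape(n_years, months_per_year, *vi.shape[1:]).sum(axis=1)


# ---------------------------------------------------------------------------
# Water conservation: water balance
# ---------------------------------------------------------------------------

def water_conservation(pre, et, landuse, runoff_coef: dict) -> tuple[np.ndarray, np.ndarray]:
    """Annual conserved water WC = PRE - ET - PRE x runoff_coef (mm yr-1).

    Negative balances are floored at zero; the second return value flags
    floored pixels so the deficit can be reported (the water balance then
    closes as WC + PRE x c + ET + deficit = PRE).

    Parameters
    ----------
    pre, et
        Annual precipitation and evapotranspiration, (year, y, x) or (y, x).
    landuse
        Integer class grid (y, x).
    runoff_coef
        Mapping land-use code -> surface runoff coefficient in [0, 1].
    """
    pre = np.asarray(pre, dtype=float)
    et = np.asarray(et, dtype=float)
    landuse = np.asarray(landuse)
    if pre.shape != et.shape:
        raise ShapeError("pre and et must share a shape")
    present = np.unique(landuse)
    missing = [int(c) for c in present if c not in runoff_coef]
    if missing:
        raise ConfigurationError(f"no runoff coefficient for land-use classes {missing}")
    coef = np.zeros(landuse.shape, dtype=float)
    for code, c in runoff_coef.items():
        coef[landuse == code] = c
    raw = pre - et - pre * coef
    floored = raw < 0
    return np.clip(raw, 0.0, None), floored


# ---------------------------------------------------------------------------
# Soil retention: RUSLE difference form
# ---------------------------------------------------------------------------

def rainfall_erosivity(pre_monthly: np.ndarray, months_per_year: int = 12) -> np.ndarray:
    """Annual rainfall erosivity R by the Wischmeier monthly formula:
    R = sum_i 1.735 x 10^(1.5 log10(p_i^2 / P) - 0.8188), with p_i the
    monthly and P the annual precipitation (mm)."""
    p = np.asarray(pre_monthly, dtype=float)
    if p.shape[0] % months_per_year:
        raise ShapeError("time dimension must be a whole number of years")
    n_years = p.shape[0] // months_per_year
    p = p.reshape(n_years, months_per_year, *p.shape[1:])
    annual = p.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(annual > 0, p**2 / np.where(annual > 0, annual, 1.0), 0.0)
        term = np.where(ratio > 0, 1.735 * 10.0 ** (1.5 * np.log10(np.where(ratio > 0, ratio, 1.0)) - 0.8188), 0.0)
    return term.sum(axis=1)


def _horn_slope(dem: np.ndarray, cell_size: float) -> np.ndarray:
    """Slope (radians) by Horn 3x3 finite differences; borders replicated
    (one-sided differences at the grid edge)."""
    if dem.ndim != 2 or min(dem.shape) < 2:
        raise DomainError("slope needs a 2-D DEM with at least 2 pixels per axis")
    padded = np.pad(dem, 1, mode="edge")
    z = {(i, j): padded[1 + i:padded.shape[0] - 1 + i, 1 + j:padded.shape[1] - 1 + j]
         for i in (-1, 0, 1) for j in (-1, 0, 1)}
    dzdx = ((z[(-1, 1)] + 2 * z[(0, 1)] + z[(1, 1)])
            - (z[(-1, -1)] + 2 * z[(0, -1)] + z[(1, -1)])) / (8.0 * cell_size)
    dzdy = ((z[(1, -1)] + 2 * z[(1, 0)] + z[(1, 1)])
            - (z[(-1, -1)] + 2 * z[(-1, 0)] + z[(-1, 1)])) / (8.0 * cell_size)
    return np.arctan(np.hypot(dzdx, dzdy))


def ls_factor(dem: np.ndarray, cell_size: float = 500.0, slope_length: float = 100.0) -> np.ndarray:
    """Topographic LS factor from a DEM.

    L = (lambda / 22.13)^m with the slope-length exponent m stepped by slope
    class (0.2/0.3/0.4/0.5); S by the McCool steepness form
    (10.8 sin(theta) + 0.03 below 9% slope, 16.8 sin(theta) - 0.5 above).
    """
    theta = _horn_slope(np.asarray(dem, dtype=float), cell_size)
    sin_t = np.sin(theta)
    pct = np.tan(theta) * 100.0
    m = np.where(pct < 1.0, 0.2, np.where(pct < 3.5, 0.3, np.where(pct < 5.0, 0.4, 0.5)))
    l = (slope_length / 22.13) ** m
    s = np.where(pct < 9.0, 10.8 * sin_t + 0.03, 16.8 * sin_t - 0.5)
    return l * s


def cover_factor(fvc: np.ndarray, alpha: float = 2.0) -> np.ndarray:
    """Cover-management factor C as a decreasing function of fractional
    cover with fixed endpoints C(0) = 1 and C(1) = 0:
    C = (exp(-alpha f) - exp(-alpha)) / (1 - exp(-alpha))."""
    f = np.clip(np.asarray(fvc, dtype=float), 0.0, 1.0)
    e = np.exp(-alpha)
    return (np.exp(-alpha * f) - e) / (1.0 - e)


def soil_retention(pre_monthly, dem, fvc, k_factor, cell_size: float = 500.0,
                   slope_length: float = 100.0, c_alpha: float = 2.0,
                   months_per_year: int = 12) -> np.ndarray:
    """Annual soil retention SR = R x K x LS x (1 - C) (t ha-1 yr-1):
    the erosion prevented by vegetation relative to bare soil, with R the
    rainfall erosivity, K soil erodibility, LS the slope factor and C the
    cover factor (C -> 1 as cover vanishes, so bare soil retains nothing).

    ``fvc`` is (year, y, x) or (y, x); ``k_factor`` a grid or scalar.
    """
    dem = np.asarray(dem, dtype=float)
    if dem.ndim != 2 or min(dem.shape) < 2:
        raise DomainError("soil_retention needs a DEM of at least 2x2 pixels")
    r = rainfall_erosivity(pre_monthly, months_per_year)
    ls = ls_factor(dem, cell_size, slope_length)
    c = cover_factor(fvc, c_alpha)
    if c.ndim == 2:
        c = c[None, ...]
    k = np.asarray(k_factor, dtype=float)
    return r * k * ls * (1.0 - c)


# ---------------------------------------------------------------------------
# Biodiversity maintenance: InVEST-style habitat quality
# ---------------------------------------------------------------------------

def habitat_quality(landuse, threat_params: dict, sensitivity: dict,
                    suitability: dict, half_sat: float = 0.5,
                    z_exp: float = 2.5, cell_size: float = 1.0) -> np.ndarray:
    """Habitat quality in [0, 1] from land use, threats and sensitivities.

    Each threat class present on the grid degrades surrounding habitat with
    a distance decay (linear ``1 - d/d_max`` or exponential
    ``exp(-2.99 d / d_max)``, zero beyond d_max). The total degradation is

        D = sum_r  weight_r x decay_r(d) x sensitivity[habitat, r]

    and quality follows the half-saturation law
    ``HQ = H x (1 - D^z / (D^z + k^z))`` so that HQ = H with no threats and
    HQ = H/2 exactly at D = k.

    Parameters
    ----------
    threat_params
        threat land-use code -> dict(weight, max_dist, decay) with decay in
        {"linear", "exponential"}; max_dist in the units of ``cell_size``.
    sensitivity
        habitat land-use code -> {threat code -> sensitivity in [0, 1]}.
    suitability
        land-use code -> habitat suitability H in [0, 1].
    """
    landuse = np.asarray(landuse)
    if half_sat <= 0:
        raise ConfigurationError("half-saturation constant k must be positive")
    for code, p in threat_params.items():
        if p["weight"] < 0:
            raise ConfigurationError(f"negative weight for threat class {code}")
    present = np.unique(landuse)
    missing = [int(c) for c in present if c not in suitability]
    if missing:
        raise ConfigurationError(f"no habitat suitability for classes {missing}")

    d_total = np.zeros(landuse.shape, dtype=float)
    for threat_code, p in threat_params.items():
        sources = landuse == threat_code
        if not sources.any():
            continue
        dist = ndimage.distance_transform_edt(~sources) * cell_size
        if p.get("decay", "linear") == "exponential":
            decay = np.exp(-2.99 * dist / p["max_dist"])
        else:
            decay = 1.0 - dist / p["max_dist"]
        decay = np.where(dist <= p["max_dist"], np.clip(decay, 0.0, 1.0), 0.0)
        sens = np.zeros(landuse.shape, dtype=float)
        for habitat_code in present:
            s = sensitivity.get(int(habitat_code), {}).get(threat_code, 0.0)
            sens[landuse == habitat_code] = s
        d_total += p["weight"] * decay * sens

    h = np.zeros(landuse.shape, dtype=float)
    for code, suit in suitability.items():
        h[landuse == code] = suit
    dz = d_total**z_exp
    return h * (1.0 - dz / (dz + half_sat**z_exp))


# ---------------------------------------------------------------------------
# Utilities
# ---------------------------------------------------------------------------

def angstrom_prescott(sunshine_hours, day_length, extraterrestrial,
                      a: float = 0.25, b: float = 0.50):
    """Surface solar radiation from sunshine duration:
    SSR = (a + b n/N) Ra, the Angstrom-Prescott relation with the standard
    default coefficients a = 0.25, b = 0.50."""
    n = np.asarray(sunshine_hours, dtype=float)
    nn = np.asarray(day_length, dtype=float)
    ra = np.asarray(extraterrestrial, dtype=float)
    if np.any(n < 0) or np.any(n > nn):
        raise DomainError("sunshine hours must satisfy 0 <= n <= N")
    out = (a + b * n / nn) * ra
    return float(out) if out.ndim == 0 else out


def biomass_to_npp_carbon(agb_dry, root_crown_ratio: float = 4.25,
                          agb_c_coef: float = 0.3698, bgb_c_coef: float = 0.4291):
    """Convert above-ground dry biomass (g m-2) to total vegetation carbon.

    Below-ground biomass is AGB x root-to-crown ratio; the two pools convert
    to carbon with separate coefficients (defaults 36.98% above ground,
    42.91% below)."""
    agb = np.asarray(agb_dry, dtype=float)
    if np.any(agb < 0):
        raise DomainError("above-ground biomass must be nonnegative")
    out = agb * agb_c_coef + agb * root_crown_ratio * bgb_c_coef
    return float(out) if out.ndim == 0 else out
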