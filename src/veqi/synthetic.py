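"""Synthetic raster scenes with a known climate/human decomposition.

The generator emulates the kind of co-registered multi-year monthly stack a
vegetation-quality study works from: six climate variables (TEM, PRE, SSR,
WS, SM, ET) on one grid, a monthly EVI field that responds to climate
through a smooth known function, a set of rectangular patches carrying a
linear human-activity trend, a reserve-core region guaranteed free of the
human signal, plus static land-use and elevation grids.

Because the decomposition

    EVI(t, pixel) = g(climate(t, pixel)) + human(t, pixel) + noise

is stored exactly (:class:`SceneTruth`), the attribution pipeline can be
validated against per-pixel ground truth: the fraction of each pixel's
absolute trend that is human-caused is known by construction.

A separate exact fractional-Gaussian-noise generator (Davies-Harte
circulant embedding) provides 1-D series with known Hurst exponent for
calibrating the rescaled-range estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import xarray as xr

from .errors import ConfigurationError, DomainError
from .trends import theil_sen_grid

CLIMATE_VARS = ("tem", "pre", "ssr", "ws", "sm", "et")

LANDUSE_CLASSES = {0: "water", 1: "forest", 2: "grass", 3: "crop", 4: "urban"}
LANDUSE_CODES = {v: k for k, v in LANDUSE_CLASSES.items()}


@dataclass(frozen=True)
class ClimateVarParams:
    """Monthly generating model for one climate variable.

    value = mean + gradient * (y_norm - 1/2) + amplitude * seasonal(month)
            + trend_per_year * year + N(0, noise_sd); negative values are
    clipped to zero for variables that are physically nonnegative.
    """

    mean: float
    amplitude: float = 0.0
    trend_per_year: float = 0.0
    gradient: float = 0.0
    noise_sd: float = 0.0
    phase: float = 0.0
    nonnegative: bool = False


@dataclass(frozen=True)
class HumanPatch:
    """Rectangle [row0:row1, col0:col1) with a linear EVI trend (per year)."""

    row0: int
    row1: int
    col0: int
    col1: int
    trend_per_year: float


@dataclass(frozen=True)
class ResponseParams:
    """Smooth climate-to-EVI response: a baseline plus weighted logistic
    transforms of monthly temperature and precipitation. Temperature carries
    the larger weight by default, making it the dominant climate factor."""

    base: float = 0.12
    tem_weight: float = 0.45
    tem_center: float = 10.0
    tem_scale: float = 6.0
    pre_weight: float = 0.15
    pre_center: float = 60.0
    pre_scale: float = 40.0


@dataclass(frozen=True)
class LandusePatch:
    row0: int
    row1: int
    col0: int
    col1: int
    klass: str


def _default_climate_params() -> dict[str, ClimateVarParams]:
    # ET is derived from TEM and PRE (see _derive_et); its entry is unused
    # apart from existing so configs can be serialised symmetrically.
    return {
        "tem": ClimateVarParams(mean=12.0, amplitude=8.0, trend_per_year=0.04,
                                gradient=3.0, noise_sd=0.8),
        "pre": ClimateVarParams(mean=80.0, amplitude=60.0, trend_per_year=0.3,
                                gradient=20.0, noise_sd=10.0, nonnegative=True),
        "ssr": ClimateVarParams(mean=450.0, amplitude=150.0, trend_per_year=0.0,
                                gradient=30.0, noise_sd=15.0, nonnegative=True),
        "ws": ClimateVarParams(mean=2.5, amplitude=0.5, trend_per_year=0.0,
                               gradient=0.5, noise_sd=0.2, nonnegative=True),
        "sm": ClimateVarParams(mean=60.0, amplitude=20.0, trend_per_year=0.0,
                               gradient=10.0, noise_sd=4.0, nonnegative=True),
    }


def _default_human_patches() -> list[HumanPatch]:
    # one restoration-like (greening) and one degradation patch, both on the
    # opposite side of the grid from the reserve strip
    return [
        HumanPatch(5, 15, 25, 35, 0.008),
        HumanPatch(25, 35, 25, 35, -0.006),
    ]


def _default_landuse_patches() -> list[LandusePatch]:
    return [
        LandusePatch(0, 14, 0, 40, "grass"),
        LandusePatch(30, 36, 4, 12, "crop"),
        LandusePatch(36, 40, 14, 20, "urban"),
        LandusePatch(37, 40, 0, 5, "water"),
    ]


@dataclass(frozen=True)
class SceneConfig:
    """Full configuration of one synthetic scene.

    Defaults describe a 40 x 40 pixel, 20-year monthly scene with a modest
    warming trend (0.04 degC/yr), two human-trend patches (+0.008 and
    -0.006 EVI/yr) and a reserve strip holding 20% of the grid.
    """

    n_rows: int = 40
    n_cols: int = 40
    n_years: int = 20
    months_per_year: int = 12
    seed: int = 0
    climate_params: dict[str, ClimateVarParams] = field(default_factory=_default_climate_params)
    response_params: ResponseParams = field(default_factory=ResponseParams)
    human_params: tuple[HumanPatch, ...] = field(default_factory=lambda: tuple(_default_human_patches()))
    landuse_patches: tuple[LandusePatch, ...] = field(default_factory=lambda: tuple(_default_landuse_patches()))
    reserve_fraction: float = 0.2
    noise_sd: float = 0.02
    #: |trend| at or above which a human patch counts as a "strong" signal
    strong_human_trend: float = 0.004

    def __post_init__(self):
        if self.n_rows <= 0 or self.n_cols <= 0 or self.months_per_year <= 0:
            raise ConfigurationError("grid and month counts must be positive")
        if self.n_years < 3:
            raise ConfigurationError("need n_years >= 3")
        if not (0.0 < self.reserve_fraction < 1.0):
            raise ConfigurationError("reserve_fraction must lie in (0, 1)")
        mask = self.reserve_mask()
        for p in self.human_params:
            if not (0 <= p.row0 < p.row1 <= self.n_rows and 0 <= p.col0 < p.col1 <= self.n_cols):
                raise ConfigurationError(f"human patch {p} exceeds the grid")
            if mask[p.row0:p.row1, p.col0:p.col1].any():
                raise ConfigurationError(f"human patch {p} overlaps the reserve core")

    def reserve_mask(self) -> np.ndarray:
        """Left-edge strip whose width quantises reserve_fraction in columns."""
        width = max(1, round(self.reserve_fraction * self.n_cols))
        mask = np.zeros((self.n_rows, self.n_cols), dtype=bool)
        mask[:, :width] = True
        return mask

    @property
    def n_months(self) -> int:
        return self.n_years * self.months_per_year


@dataclass
class SceneTruth:
    """Exact decomposition of the emitted EVI.

    ``climate_monthly + human_monthly + noise_monthly`` reconstructs the
    emitted EVI to machine precision (any clipping of extreme EVI values is
    folded into the stored noise). Annual components are means over the
    months of each year; ``true_human_contribution`` is
    |Sen(human)| / (|Sen(climate)| + |Sen(human)|) on the annual component
    series, the scene's ground-truth analogue of the attribution pipeline's
    human contribution rate.
    """

    climate_monthly: np.ndarray
    human_monthly: np.ndarray
    noise_monthly: np.ndarray
    climate_component: np.ndarray
    human_component: np.ndarray
    true_human_contribution: np.ndarray
    strong_human_mask: np.ndarray
    human_mask: np.ndarray

    def regional_human_share(self, mask: np.ndarray) -> float:
        """Scene-truth regional human share (%) over ``mask``: the summed
        absolute Theil-Sen slope of the human component relative to the
        summed absolute slopes of both components."""
        s_c = np.abs(theil_sen_grid(self.climate_component))
        s_h = np.abs(theil_sen_grid(self.human_component))
        mask = np.asarray(mask, dtype=bool)
        denom = np.sum((s_c + s_h)[mask])
        return float(100.0 * np.sum(s_h[mask]) / denom) if denom > 0 else 0.0

    def to_dataset(self) -> xr.Dataset:
        return xr.Dataset(
            {
                "climate_monthly": (("time", "y", "x"), self.climate_monthly),
                "human_monthly": (("time", "y", "x"), self.human_monthly),
                "noise_monthly": (("time", "y", "x"), self.noise_monthly),
                "climate_component": (("year", "y", "x"), self.climate_component),
                "human_component": (("year", "y", "x"), self.human_component),
                "true_human_contribution": (("y", "x"), self.true_human_contribution),
                "strong_human_mask": (("y", "x"), self.strong_human_mask.astype("i1")),
                "human_mask": (("y", "x"), self.human_mask.astype("i1")),
            }
        )


@dataclass
class Scene:
    """One generated scene: climate + EVI + static grids + ground truth."""

    climate: xr.Dataset
    evi: xr.DataArray
    landuse: np.ndarray
    dem: np.ndarray
    reserve_mask: np.ndarray
    truth: SceneTruth
    config: SceneConfig

    def to_dataset(self) -> xr.Dataset:
        ds = self.climate.copy()
        ds["evi"] = self.evi
        ds["landuse"] = (("y", "x"), self.landuse.astype("i1"))
        ds["dem"] = (("y", "x"), self.dem)
        ds["reserve_mask"] = (("y", "x"), self.reserve_mask.astype("i1"))
        return ds


def _seasonal(month_of_year: np.ndarray, months_per_year: int, phase: float) -> np.ndarray:
    # peak mid-year (northern-hemisphere summer) for phase 0
    return np.sin(2.0 * np.pi * (month_of_year + 0.5) / months_per_year - np.pi / 2.0 + phase)


def _logistic(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def _derive_et(tem: np.ndarray, pre: np.ndarray) -> np.ndarray:
    """Monthly ET as a fixed monotone function of TEM and PRE.

    A fraction of precipitation evaporates, the fraction rising with
    temperature — so ET is collinear with both drivers, as in real stacks.
    """
    return 0.75 * pre * _logistic((tem - 8.0) / 6.0)


def generate_climate(config: SceneConfig, rng: np.random.Generator | None = None) -> xr.Dataset:
    """Generate the six monthly climate variable stacks for a scene.

    Each of TEM/PRE/SSR/WS/SM is spatial gradient + seasonal sinusoid +
    linear interannual trend + iid Gaussian noise; ET is then derived from
    TEM and PRE through a fixed monotone function.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    nt, ny, nx = config.n_months, config.n_rows, config.n_cols
    t = np.arange(nt)
    year = t // config.months_per_year
    month = t % config.months_per_year
    y_norm = (np.arange(ny) + 0.5) / ny

    data = {}
    for name in ("tem", "pre", "ssr", "ws", "sm"):
        p = config.climate_params[name]
        base = (
            p.mean
            + p.amplitude * _seasonal(month, config.months_per_year, p.phase)[:, None, None]
            + p.trend_per_year * year[:, None, None]
            + p.gradient * (y_norm[None, :, None] - 0.5)
        )
        noise = rng.normal(0.0, p.noise_sd, size=(nt, ny, nx)) if p.noise_sd > 0 else 0.0
        grid = np.broadcast_to(base, (nt, ny, nx)) + noise
        if p.nonnegative:
            grid = np.clip(grid, 0.0, None)
        data[name] = (("time", "y", "x"), np.ascontiguousarray(grid, dtype=float))
    et = _derive_et(data["tem"][1], data["pre"][1])
    data["et"] = (("time", "y", "x"), et)

    coords = {
        "time": t,
        "year": ("time", year),
        "month": ("time", month),
        "y": np.arange(ny),
        "x": np.arange(nx),
    }
    ds = xr.Dataset(data, coords=coords)
    ds.attrs["months_per_year"] = config.months_per_year
    ds.attrs["n_years"] = config.n_years
    return ds


def generate_scene(config: SceneConfig) -> Scene:
    """Generate a full scene with its exact climate/human/noise truth."""
    rng = np.random.default_rng(config.seed)
    climate = generate_climate(config, rng)
    nt, ny, nx = config.n_months, config.n_rows, config.n_cols
    r = config.response_params

    clim_evi = (
        r.base
        + r.tem_weight * _logistic((climate["tem"].values - r.tem_center) / r.tem_scale)
        + r.pre_weight * _logistic((climate["pre"].values - r.pre_center) / r.pre_scale)
    )

    reserve = config.reserve_mask()
    year = np.arange(nt) // config.months_per_year
    human = np.zeros((nt, ny, nx))
    human_mask = np.zeros((ny, nx), dtype=bool)
    strong = np.zeros((ny, nx), dtype=bool)
    for p in config.human_params:
        human[:, p.row0:p.row1, p.col0:p.col1] += p.trend_per_year * year[:, None, None]
        human_mask[p.row0:p.row1, p.col0:p.col1] = True
        if abs(p.trend_per_year) >= config.strong_human_trend:
            strong[p.row0:p.row1, p.col0:p.col1] = True
    human[:, reserve] = 0.0
    human_mask &= ~reserve
    strong &= ~reserve

    eps = rng.normal(0.0, config.noise_sd, size=(nt, ny, nx)) if config.noise_sd > 0 else np.zeros((nt, ny, nx))
    evi = np.clip(clim_evi + human + eps, -0.2, 1.0)
    noise = evi - clim_evi - human  # clipping folded into the stored noise

    mpy = config.months_per_year
    clim_annual = clim_evi.reshape(config.n_years, mpy, ny, nx).mean(axis=1)
    human_annual = human.reshape(config.n_years, mpy, ny, nx).mean(axis=1)

    s_c = np.abs(theil_sen_grid(clim_annual))
    s_h = np.abs(theil_sen_grid(human_annual))
    denom = s_c + s_h
    with np.errstate(invalid="ignore", divide="ignore"):
        contrib = np.where(denom > 0, s_h / np.where(denom > 0, denom, 1.0), 0.0)

    truth = SceneTruth(
        climate_monthly=clim_evi,
        human_monthly=human,
        noise_monthly=noise,
        climate_component=clim_annual,
        human_component=human_annual,
        true_human_contribution=contrib,
        strong_human_mask=strong,
        human_mask=human_mask,
    )

    landuse = np.full((ny, nx), LANDUSE_CODES["forest"], dtype=np.int8)
    for p in config.landuse_patches:
        landuse[p.row0:p.row1, p.col0:p.col1] = LANDUSE_CODES[p.klass]

    y_norm = (np.arange(ny) + 0.5) / ny
    x_norm = (np.arange(nx) + 0.5) / nx
    dem = 500.0 + 1500.0 * y_norm[:, None] + 300.0 * np.sin(np.pi * x_norm)[None, :]
    dem = np.broadcast_to(dem, (ny, nx)).copy()

    evi_da = xr.DataArray(evi, dims=("time", "y", "x"), coords=climate.coords, name="evi")
    return Scene(climate, evi_da, landuse, dem, reserve, truth, config)


def scene_from_config_dict(d: dict) -> SceneConfig:
    """Build a SceneConfig from a plain (YAML-loaded) mapping."""
    kwargs = dict(d)
    if "climate_params" in kwargs:
        cp = _default_climate_params()
        for name, sub in kwargs["climate_params"].items():
            cp[name] = replace(cp[name], **sub) if name in cp else ClimateVarParams(**sub)
        kwargs["climate_params"] = cp
    if "response_params" in kwargs:
        kwargs["response_params"] = ResponseParams(**kwargs["response_params"])
    if "human_params" in kwargs:
        kwargs["human_params"] = tuple(HumanPatch(**p) for p in kwargs["human_params"])
    if "landuse_patches" in kwargs:
        kwargs["landuse_patches"] = tuple(LandusePatch(**p) for p in kwargs["landuse_patches"])
    return SceneConfig(**kwargs)


# ---------------------------------------------------------------------------
# Fractional Gaussian noise (exact, circulant embedding)
# ---------------------------------------------------------------------------

def fgn_autocovariance(hurst: float, lags: np.ndarray, sd: float = 1.0) -> np.ndarray:
    """Closed-form fGn autocovariance
    gamma(k) = (sd^2 / 2) (|k+1|^2H - 2|k|^2H + |k-1|^2H)."""
    k = np.abs(np.asarray(lags, dtype=float))
    h2 = 2.0 * hurst
    return 0.5 * sd**2 * ((k + 1) ** h2 - 2 * k**h2 + np.abs(k - 1) ** h2)


def generate_fgn(hurst: float, n: int, sd: float = 1.0, seed: int = 0,
                 n_series: int = 1) -> np.ndarray:
    """Exact fractional Gaussian noise via Davies-Harte circulant embedding.

    Embeds the (n x n) Toeplitz covariance in a 2n-circulant whose
    eigenvalues are obtained by FFT; the returned series has exactly the
    target autocovariance for every lag. For fGn the circulant eigenvalues
    are nonnegative, so the method is exact (tiny negative values from
    floating-point roundoff are clipped).

    Returns shape (n,) for ``n_series == 1``, else (n_series, n).
    """
    if not (0.0 < hurst < 1.0):
        raise DomainError(f"Hurst exponent must lie in (0, 1), got {hurst}")
    if n < 8:
        raise DomainError(f"need n >= 8, got {n}")
    rng = np.random.default_rng(seed)

    gamma = fgn_autocovariance(hurst, np.arange(n + 1), sd)
    row = np.concatenate([gamma, gamma[-2:0:-1]])  # length 2n
    m = row.size
    lam = np.fft.fft(row).real
    lam = np.clip(lam, 0.0, None)

    u = rng.standard_normal((n_series, n + 1))
    v = rng.standard_normal((n_series, n - 1))
    a = np.zeros((n_series, m), dtype=complex)
    a[:, 0] = np.sqrt(lam[0]) * u[:, 0]
    a[:, n] = np.sqrt(lam[n]) * u[:, n]
    mid = np.sqrt(lam[1:n] / 2.0)
    a[:, 1:n] = mid * (u[:, 1:n] + 1j * v)
    a[:, n + 1:] = np.conj(a[:, n - 1:0:-1])
    series = np.fft.fft(a, axis=1).real[:, :n] / np.sqrt(m)
    return series[0] if n_series == 1 else series
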