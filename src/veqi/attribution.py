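"""Climate-vs-human attribution of VEQI change by residual analysis.

The design rests on one identifying assumption: vegetation inside the
reserve core is driven by climate alone. A gradient-boosted regression
model is trained on reserve pixel-years to predict VEQI from the six
annual climate factors (TEM, PRE, ET, WS, SM, SSR); applying it everywhere
yields the climate-only index VEQI_C, and the residual

    VEQI_H = VEQI - VEQI_C

is read as the human-activity component. Theil-Sen slopes of the total,
climate and human series then classify each pixel's influence degree
(seven ordinal levels from significantly inhibited to significantly
promoted), determine the driver (C, H, or C&H), and split the trend into
relative contribution rates that sum to 100%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.metrics import mean_squared_error, r2_score
from xgboost import XGBRegressor

from .errors import ConfigurationError, SampleSizeError, ShapeError, VeqiError
from .trends import Z_MODERATE, Z_SIGNIFICANT, mann_kendall_grid, theil_sen_grid

CLIMATE_FEATURES = ("tem", "pre", "et", "ws", "sm", "ssr")
#: features aggregated by annual total rather than annual mean
_SUM_FEATURES = {"pre", "et"}

DEFAULT_HYPERPARAMS = {"learning_rate": 0.3, "max_depth": 8, "n_estimators": 1000}

DRIVER_LABELS = {0: "none", 1: "C", 2: "H", 3: "C&H"}

INFLUENCE_LABELS = {
    -3: "significantly inhibited",
    -2: "moderately inhibited",
    -1: "slightly inhibited",
    0: "no effects",
    1: "slightly promoted",
    2: "moderately promoted",
    3: "significantly promoted",
}


@dataclass
class ClimateModelReport:
    """Held-out performance and feature importances of the climate model."""

    r2: float
    rmse: float
    importances: dict[str, float]
    hyperparameters: dict
    n_samples: int

    def as_dict(self) -> dict:
        return {
            "r2": self.r2,
            "rmse": self.rmse,
            "importances": self.importances,
            "hyperparameters": {k: v for k, v in self.hyperparameters.items()},
            "n_samples": self.n_samples,
        }


@dataclass
class AttributionResult:
    """Per-pixel attribution grids (see module docstring for semantics)."""

    veqi_c: np.ndarray
    veqi_h: np.ndarray
    sen_total: np.ndarray
    sen_c: np.ndarray
    sen_h: np.ndarray
    z_total: np.ndarray
    z_c: np.ndarray
    z_h: np.ndarray
    influence_climate: np.ndarray
    influence_human: np.ndarray
    driver: np.ndarray
    contrib_climate: np.ndarray
    contrib_human: np.ndarray
    table_gap: np.ndarray
    report: ClimateModelReport = field(repr=False)


# ---------------------------------------------------------------------------
# Climate model
# ---------------------------------------------------------------------------

def annual_climate_features(climate) -> dict[str, np.ndarray]:
    """Aggregate monthly climate stacks to annual feature grids.

    TEM/WS/SM/SSR are annual means; PRE/ET annual totals (they are fluxes
    whose yearly accumulation is the physically meaningful quantity).
    """
    mpy = int(climate.attrs.get("months_per_year", 12))
    out = {}
    for name in CLIMATE_FEATURES:
        arr = np.asarray(climate[name].values, dtype=float)
        n_years = arr.shape[0] // mpy
        blocks = arr.reshape(n_years, mpy, *arr.shape[1:])
        out[name] = blocks.sum(axis=1) if name in _SUM_FEATURES else blocks.mean(axis=1)
    return out


def build_training_table(veqi: np.ndarray, climate, reserve_mask: np.ndarray) -> pd.DataFrame:
    """One row per reserve pixel-year: six annual climate features + target.

    ``veqi`` is the annual index on the fractional [0, 1] scale,
    shape (year, y, x).
    """
    reserve_mask = np.asarray(reserve_mask, dtype=bool)
    if not reserve_mask.any():
        raise ConfigurationError("reserve mask is empty; the climate model has no training data")
    veqi = np.asarray(veqi, dtype=float)
    if veqi.shape[0] < 3:
        raise SampleSizeError("need at least 3 years of VEQI")
    feats = annual_climate_features(climate)
    if feats["tem"].shape != veqi.shape:
        raise ShapeError("climate and VEQI grids disagree in annual shape")
    cols = {name: feats[name][:, reserve_mask].ravel() for name in CLIMATE_FEATURES}
    cols["veqi"] = veqi[:, reserve_mask].ravel()
    table = pd.DataFrame(cols)
    return table.dropna().reset_index(drop=True)


def _split(n: int, split_fraction: float, seed: int) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(round(n * split_fraction))
    return order[:n_train], order[n_train:]


def fit_climate_model(table: pd.DataFrame, split_fraction: float = 0.5, seed: int = 0,
                      hyperparams: dict | None = None) -> tuple[XGBRegressor, ClimateModelReport]:
    """Fit the boosted-tree climate model on a random half of the table.

    Defaults are the tuned hyperparameters: learning rate 0.3, depth 8,
    1000 trees. The report carries held-out R2/RMSE and gain-based feature
    importances normalised to sum to one.
    """
    if len(table) < 50:
        raise SampleSizeError(f"need at least 50 rows, got {len(table)}")
    y = table["veqi"].to_numpy()
    if np.std(y) == 0:
        raise VeqiError("degenerate target: VEQI is constant over the reserve")
    x = table[list(CLIMATE_FEATURES)].to_numpy()
    hp = {**DEFAULT_HYPERPARAMS, **(hyperparams or {})}
    train, test = _split(len(table), split_fraction, seed)
    model = XGBRegressor(random_state=seed, n_jobs=1, tree_method="hist",
                         verbosity=0, **hp)
    model.fit(x[train], y[train])
    pred = model.predict(x[test])
    imp = np.asarray(model.feature_importances_, dtype=float)
    total = imp.sum()
    imp = imp / total if total > 0 else np.full_like(imp, 1.0 / len(imp))
    report = ClimateModelReport(
        r2=float(r2_score(y[test], pred)),
        rmse=float(np.sqrt(mean_squared_error(y[test], pred))),
        importances={name: float(imp[j]) for j, name in enumerate(CLIMATE_FEATURES)},
        hyperparameters=hp,
        n_samples=len(table),
    )
    return model, report


def predict_veqi_c(model, climate, valid_mask: np.ndarray) -> np.ndarray:
    """Predict the climate-only index for every valid pixel-year, clipped to
    the fractional [0, 1] range; NaN outside the mask."""
    feats = annual_climate_features(climate)
    names = getattr(model, "feature_names_in_", None)
    if names is not None and tuple(names) != CLIMATE_FEATURES:
        raise ShapeError(f"model expects features {tuple(names)}, not {CLIMATE_FEATURES}")
    valid_mask = np.asarray(valid_mask, dtype=bool)
    shape = feats["tem"].shape
    x = np.column_stack([feats[name][:, valid_mask].ravel() for name in CLIMATE_FEATURES])
    pred = np.clip(model.predict(x), 0.0, 1.0)
    out = np.full(shape, np.nan)
    out[:, valid_mask] = pred.reshape(shape[0], -1)
    return out


def residual_human(veqi: np.ndarray, veqi_c: np.ndarray) -> np.ndarray:
    """Human-activity component: the elementwise residual VEQI - VEQI_C."""
    veqi = np.asarray(veqi, dtype=float)
    veqi_c = np.asarray(veqi_c, dtype=float)
    if veqi.shape != veqi_c.shape:
        raise ShapeError("veqi and veqi_c must share a shape")
    return veqi - veqi_c


# ---------------------------------------------------------------------------
# Influence degrees and drivers
# ---------------------------------------------------------------------------

def classify_influence(sen_slope: float, mk_z: float) -> str:
    """Seven-level influence degree from a component's slope and |Z|.

    Positive slopes promote vegetation quality, negative inhibit; |Z| above
    1.96 is significant, between 1.645 and 1.96 moderate, below 1.645
    slight. A zero slope has no effect regardless of |Z|.
    """
    code = classify_influence_grid(np.asarray([sen_slope]), np.asarray([mk_z]))[0]
    return INFLUENCE_LABELS[int(code)]


def classify_influence_grid(sen_slope: np.ndarray, mk_z: np.ndarray,
                            z_significant: float = Z_SIGNIFICANT,
                            z_moderate: float = Z_MODERATE) -> np.ndarray:
    """Vectorised :func:`classify_influence` returning signed codes
    (-3..3, 0 = no effects); non-finite inputs give -9 (invalid)."""
    slope = np.asarray(sen_slope, dtype=float)
    az = np.abs(np.asarray(mk_z, dtype=float))
    valid = np.isfinite(slope) & np.isfinite(az)
    degree = np.where(az > z_significant, 3, np.where(az > z_moderate, 2, 1))
    code = np.sign(np.where(valid, slope, 0.0)).astype(int) * degree
    return np.where(valid, code, -9).astype(int)


def attribute_drivers(sen_total, sen_c, sen_h):
    """Driver and relative contribution rates from the three Sen slopes.

    For a changing pixel (sen_total != 0) whose components agree with the
    total's direction, both drivers act and the contribution rates split by
    the component ratio sen_c / (sen_c + sen_h); a component opposing the
    total concedes the full 100% to the other. Sign combinations outside
    that scheme (reachable because the Sen operator is not additive) fall
    back to the dominant-magnitude component at 100/0 and raise the
    table-gap flag. A pixel with no total trend has driver "none" and NaN
    contributions.

    Accepts scalars or arrays; returns (driver, contrib_climate %,
    contrib_human %, table_gap_flag) with driver as integer codes
    (see DRIVER_LABELS) for array input and as a label string for scalars.
    """
    st = np.asarray(sen_total, dtype=float)
    sc = np.asarray(sen_c, dtype=float)
    sh = np.asarray(sen_h, dtype=float)
    scalar = st.ndim == 0
    st, sc, sh = np.atleast_1d(st), np.atleast_1d(sc), np.atleast_1d(sh)

    driver = np.zeros(st.shape, dtype=int)
    cc = np.full(st.shape, np.nan)
    ch = np.full(st.shape, np.nan)
    gap = np.zeros(st.shape, dtype=bool)

    changing = st != 0
    same_dir = changing & (np.sign(sc) == np.sign(st)) & (np.sign(sh) == np.sign(st))
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = sc / (sc + sh)
    driver[same_dir] = 3
    cc[same_dir] = 100.0 * ratio[same_dir]
    ch[same_dir] = 100.0 - cc[same_dir]

    climate_only = changing & (np.sign(sc) == np.sign(st)) & (np.sign(sh) == -np.sign(st))
    driver[climate_only] = 1
    cc[climate_only], ch[climate_only] = 100.0, 0.0

    human_only = changing & (np.sign(sh) == np.sign(st)) & (np.sign(sc) == -np.sign(st))
    driver[human_only] = 2
    cc[human_only], ch[human_only] = 0.0, 100.0

    covered = same_dir | climate_only | human_only
    fallback = changing & ~covered
    both_zero = fallback & (sc == 0) & (sh == 0)
    gap[fallback] = True
    rest = fallback & ~both_zero
    c_dominates = rest & (np.abs(sc) >= np.abs(sh))
    driver[c_dominates] = 1
    cc[c_dominates], ch[c_dominates] = 100.0, 0.0
    h_dominates = rest & ~c_dominates
    driver[h_dominates] = 2
    cc[h_dominates], ch[h_dominates] = 0.0, 100.0

    nonfinite = ~(np.isfinite(st) & np.isfinite(sc) & np.isfinite(sh))
    driver[nonfinite] = 0
    cc[nonfinite] = np.nan
    ch[nonfinite] = np.nan
    gap[nonfinite] = False

    if scalar:
        return DRIVER_LABELS[int(driver[0])], float(cc[0]), float(ch[0]), bool(gap[0])
    return driver, cc, ch, gap


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def attribute_scene(veqi: np.ndarray, climate, reserve_mask: np.ndarray,
                    valid_mask: np.ndarray | None = None, seed: int = 0,
                    split_fraction: float = 0.5,
                    hyperparams: dict | None = None) -> AttributionResult:
    """Run the full residual-attribution chain on an annual VEQI stack.

    ``veqi`` is on the fractional [0, 1] scale, shape (year, y, x); slopes
    and classes are computed on the per-pixel annual series of the total,
    climate-predicted and residual components.
    """
    veqi = np.asarray(veqi, dtype=float)
    if valid_mask is None:
        valid_mask = np.all(np.isfinite(veqi), axis=0)
    table = build_training_table(veqi, climate, reserve_mask)
    model, report = fit_climate_model(table, split_fraction, seed, hyperparams)
    veqi_c = predict_veqi_c(model, climate, valid_mask)
    veqi_h = residual_human(np.where(valid_mask[None], veqi, np.nan), veqi_c)

    sen_total = theil_sen_grid(np.where(valid_mask[None], veqi, np.nan))
    sen_c = theil_sen_grid(veqi_c)
    sen_h = theil_sen_grid(veqi_h)
    _, z_total = mann_kendall_grid(np.where(valid_mask[None], veqi, np.nan))
    _, z_c = mann_kendall_grid(veqi_c)
    _, z_h = mann_kendall_grid(veqi_h)

    infl_c = classify_influence_grid(sen_c, z_c)
    infl_h = classify_influence_grid(sen_h, z_h)
    driver, cc, ch, gap = attribute_drivers(sen_total, sen_c, sen_h)
    return AttributionResult(veqi_c, veqi_h, sen_total, sen_c, sen_h,
                             z_total, z_c, z_h, infl_c, infl_h,
                             driver, cc, ch, gap, report)


CONTRIB_BINS = ((0, 20), (20, 40), (40, 60), (60, 80), (80, 100))


def regional_summary(result: AttributionResult, valid_mask: np.ndarray,
                     region_labels: np.ndarray) -> pd.DataFrame:
    """Per-region area shares by driver, influence class and human-
    contribution bin, plus mean contribution rates.

    Two aggregates of the human contribution are emitted: the mean over
    attributable pixels and the area-weighted share of the summed absolute
    component slopes (robust to pixels with near-zero total trend).
    """
    valid_mask = np.asarray(valid_mask, dtype=bool)
    labels = np.asarray(region_labels)
    if np.any(valid_mask & (labels == None)):  # noqa: E711 - object-array guard
        raise ConfigurationError("region labels must cover the valid mask")
    rows = []
    for region in np.unique(labels[valid_mask]):
        sel = valid_mask & (labels == region)
        n = int(sel.sum())
        row: dict = {"region": region, "n_pixels": n}
        for code, lab in DRIVER_LABELS.items():
            row[f"driver_{lab}_pct"] = 100.0 * np.sum(result.driver[sel] == code) / n
        for code, lab in INFLUENCE_LABELS.items():
            key = lab.replace(" ", "_")
            row[f"climate_{key}_pct"] = 100.0 * np.sum(result.influence_climate[sel] == code) / n
            row[f"human_{key}_pct"] = 100.0 * np.sum(result.influence_human[sel] == code) / n
        attributable = sel & (result.driver != 0)
        ch = result.contrib_human[attributable]
        for lo, hi in CONTRIB_BINS:
            frac = np.sum((ch >= lo) & (ch < hi) | ((hi == 100) & (ch == 100)))
            row[f"contrib_human_{lo}_{hi}_pct"] = 100.0 * frac / n if n else np.nan
        row["mean_contrib_human"] = float(np.nanmean(ch)) if ch.size else np.nan
        row["mean_contrib_climate"] = float(np.nanmean(result.contrib_climate[attributable])) if ch.size else np.nan
        abs_c = np.abs(result.sen_c[sel])
        abs_h = np.abs(result.sen_h[sel])
        denom = np.nansum(abs_c + abs_h)
        row["slope_weighted_contrib_human"] = float(100.0 * np.nansum(abs_h) / denom) if denom > 0 else np.nan
        row["table_gap_pct"] = 100.0 * np.sum(result.table_gap[sel]) / n
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Stepwise-linear baseline
# ---------------------------------------------------------------------------

def baseline_linear_model(table: pd.DataFrame, split_fraction: float = 0.5,
                          seed: int = 0) -> tuple[object, ClimateModelReport]:
    """Forward-stepwise OLS baseline on the same features and split.

    Features enter greedily by adjusted-R2 improvement on the training half;
    the report mirrors :func:`fit_climate_model` (importances are the
    normalised absolute standardised coefficients of the selected features,
    zero for the unselected).
    """
    if len(table) < 50:
        raise SampleSizeError(f"need at least 50 rows, got {len(table)}")
    y = table["veqi"].to_numpy()
    if np.std(y) == 0:
        raise VeqiError("degenerate target: VEQI is constant over the reserve")
    x = table[list(CLIMATE_FEATURES)].to_numpy()
    train, test = _split(len(table), split_fraction, seed)

    selected: list[int] = []
    remaining = list(range(x.shape[1]))
    best_adj = -np.inf
    while remaining:
        scores = []
        for j in remaining:
            cols = selected + [j]
            fit = sm.OLS(y[train], sm.add_constant(x[train][:, cols])).fit()
            scores.append((fit.rsquared_adj, j))
        adj, j = max(scores)
        if adj <= best_adj + 1e-12:
            break
        best_adj = adj
        selected.append(j)
        remaining.remove(j)

    fit = sm.OLS(y[train], sm.add_constant(x[train][:, selected])).fit()
    pred = fit.predict(sm.add_constant(x[test][:, selected], has_constant="add"))
    imp = np.zeros(x.shape[1])
    sd_x = x[train][:, selected].std(axis=0)
    imp[selected] = np.abs(fit.params[1:]) * sd_x
    total = imp.sum()
    imp = imp / total if total > 0 else np.full_like(imp, 1.0 / len(imp))
    report = ClimateModelReport(
        r2=float(r2_score(y[test], pred)),
        rmse=float(np.sqrt(mean_squared_error(y[test], pred))),
        importances={name: float(imp[j]) for j, name in enumerate(CLIMATE_FEATURES)},
        hyperparameters={"method": "forward-stepwise OLS",
                         "selected": [CLIMATE_FEATURES[j] for j in selected]},
        n_samples=len(table),
    )
    return fit, report
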