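"""Per-pixel trend statistics and the six-class future-trend typology.

Three classical nonparametric tools are applied to annual series (one value
per year) of the vegetation ecological quality index:

* Theil-Sen slope - median of all pairwise slopes, a robust trend magnitude;
* Mann-Kendall test - rank-based significance with the tie-corrected normal
  approximation;
* Hurst index - rescaled-range (R/S) long-memory exponent with the
  Anis-Lloyd small-sample expectation correction, used to judge whether the
  observed trend is expected to persist.

The three are combined into a six-class future-trend code: the significance
threshold splits trends into certain/uncertain, the Hurst index splits the
future into persistent (HI > 0.5) and anti-persistent (HI <= 0.5), and the
slope sign gives the direction.
"""

from __future__ import annotations

import contextlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .errors import DomainError, MissingDataError, SampleSizeError

#: two-sided 5% threshold on |Z|; frozen constant, overridable per call
Z_SIGNIFICANT = 1.96
#: two-sided 10% threshold, used by the influence-degree classifier
Z_MODERATE = 1.645

FUTURE_TREND_LABELS = {
    1: "uncertain",
    2: "decreasing to increasing",
    3: "increasing to decreasing",
    4: "persistently stable",
    5: "persistently decreasing",
    6: "persistently increasing",
}


# ---------------------------------------------------------------------------
# Theil-Sen
# ---------------------------------------------------------------------------

def theil_sen(series) -> float:
    """Theil-Sen slope: the median of all pairwise slopes.

    Parameters
    ----------
    series
        1-D sequence of at least 3 finite annual values, implicitly indexed
        by 0, 1, 2, ... (units of the result are input units per year).
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise DomainError("theil_sen expects a 1-D series")
    if x.size < 3:
        raise SampleSizeError(f"need at least 3 values, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise MissingDataError("series contains NaN/inf; mask before calling")
    return float(np.median(_pairwise_slopes(x[:, None])[:, 0]))


def _pairwise_slopes(arr: np.ndarray) -> np.ndarray:
    """All (j - i)-scaled forward differences of ``arr`` with shape (n, m)."""
    n = arr.shape[0]
    i, j = np.triu_indices(n, k=1)
    return (arr[j] - arr[i]) / (j - i)[:, None]


def theil_sen_grid(stack: np.ndarray) -> np.ndarray:
    """Vectorised Theil-Sen slope along axis 0 of a (time, ...) stack.

    NaN pixels (any NaN along time) yield NaN.
    """
    n = stack.shape[0]
    if n < 3:
        raise SampleSizeError(f"need at least 3 time steps, got {n}")
    flat = stack.reshape(n, -1)
    slopes = np.median(_pairwise_slopes(flat), axis=0)
    return slopes.reshape(stack.shape[1:])


# ---------------------------------------------------------------------------
# Mann-Kendall
# ---------------------------------------------------------------------------

def mann_kendall(series) -> tuple[int, float, float]:
    """Mann-Kendall trend test.

    Returns ``(S, var_s, Z)`` where ``S = sum_{i<j} sign(x_j - x_i)``,
    ``var_s`` is the tie-corrected variance
    ``[n(n-1)(2n+5) - sum_t t(t-1)(2t+5)] / 18`` over tie groups of size t,
    and Z is the continuity-corrected normal deviate. A fully tied series has
    zero variance and returns Z = 0 (callers may treat it as a tie flag).
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise DomainError("mann_kendall expects a 1-D series")
    if x.size < 4:
        raise SampleSizeError(f"need at least 4 values, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise MissingDataError("series contains NaN/inf; mask before calling")
    n = x.size
    diffs = np.sign(x[None, :] - x[:, None])
    s = int(np.triu(diffs, k=1).sum())
    _, counts = np.unique(x, return_counts=True)
    tie_term = float(np.sum(counts * (counts - 1) * (2 * counts + 5)))
    var_s = (n * (n - 1) * (2 * n + 5) - tie_term) / 18.0
    if var_s <= 0:
        return s, 0.0, 0.0
    if s > 0:
        z = (s - 1) / np.sqrt(var_s)
    elif s < 0:
        z = (s + 1) / np.sqrt(var_s)
    else:
        z = 0.0
    return s, float(var_s), float(z)


def mann_kendall_grid(stack: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised Mann-Kendall along axis 0. Returns (S, Z) grids."""
    n = stack.shape[0]
    if n < 4:
        raise SampleSizeError(f"need at least 4 time steps, got {n}")
    flat = stack.reshape(n, -1)
    i, j = np.triu_indices(n, k=1)
    s = np.sign(flat[j] - flat[i]).sum(axis=0)
    base = n * (n - 1) * (2 * n + 5)
    var_s = np.empty(flat.shape[1])
    for col in range(flat.shape[1]):
        v = flat[:, col]
        if np.any(np.isnan(v)):
            var_s[col] = np.nan
            continue
        _, counts = np.unique(v, return_counts=True)
        var_s[col] = (base - np.sum(counts * (counts - 1) * (2 * counts + 5))) / 18.0
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(s > 0, (s - 1) / np.sqrt(var_s), np.where(s < 0, (s + 1) / np.sqrt(var_s), 0.0))
    z = np.where(var_s <= 0, 0.0, z)
    z = np.where(np.isnan(var_s), np.nan, z)
    nanmask = np.any(np.isnan(flat), axis=0)
    s = np.where(nanmask, np.nan, s)
    return s.reshape(stack.shape[1:]), z.reshape(stack.shape[1:])


# ---------------------------------------------------------------------------
# Hurst index (rescaled range)
# ---------------------------------------------------------------------------

def _anis_lloyd_expectation(tau: np.ndarray) -> np.ndarray:
    """E[R/S] for iid Gaussian noise at window size tau (Anis-Lloyd with the
    (tau - 0.5)/tau finite-sample correction)."""
    out = np.empty(len(tau))
    for k, t in enumerate(tau):
        i = np.arange(1, t)
        ssum = np.sum(np.sqrt((t - i) / i))
        if t <= 340:
            front = np.exp(gammaln((t - 1) / 2.0) - gammaln(t / 2.0)) / np.sqrt(np.pi)
        else:
            front = 1.0 / np.sqrt(t * np.pi / 2.0)
        out[k] = (t - 0.5) / t * front * ssum
    return out


def _rs_window_sizes(n: int, min_window: int | None, max_window: int | None) -> np.ndarray:
    if min_window is None:
        # very small blocks carry the worst small-sample distortion, so the
        # smallest window grows (slowly) with the series length; short annual
        # series fall back to tiny windows so an estimate is still attempted
        min_window = max(8, n // 32) if n >= 16 else max(4, n // 4)
    if max_window is None:
        max_window = n // 2
    max_window = min(max_window, n // 2)
    if max_window < min_window:
        raise SampleSizeError(
            f"no usable R/S windows: n={n}, min_window={min_window}, max_window={max_window}"
        )
    sizes = np.unique(np.round(np.exp(np.linspace(np.log(min_window), np.log(max_window), 12))).astype(int))
    sizes = sizes[(sizes >= min_window) & (sizes <= max_window)]
    if len(sizes) < 2:  # degenerate range; widen downward so a fit exists
        sizes = np.unique([max(4, max_window // 2), max_window])
    return sizes


@contextlib.contextmanager
def _suppress_all_nan():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Mean of empty slice")
        yield


def _rs_values(flat: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """Mean R/S over non-overlapping blocks, per window size and per column.

    ``flat`` is (n, m); returns (len(sizes), m) with NaN where every block of
    a column has zero dispersion.
    """
    n, m = flat.shape
    rs = np.empty((len(sizes), m))
    for k, tau in enumerate(sizes):
        nblocks = n // tau
        blocks = flat[: nblocks * tau].reshape(nblocks, tau, m)
        dev = blocks - blocks.mean(axis=1, keepdims=True)
        cums = np.cumsum(dev, axis=1)
        r = cums.max(axis=1) - cums.min(axis=1)
        s = blocks.std(axis=1, ddof=1)  # sample-std convention of the Anis-Lloyd expectation
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where(s > 0, r / np.where(s > 0, s, 1.0), np.nan)
        if nblocks > 1:
            with np.errstate(invalid="ignore"), _suppress_all_nan():
                rs[k] = np.nanmean(ratio, axis=0)
        else:
            rs[k] = ratio[0]
    return rs


def hurst_rs(series, min_window: int | None = None, max_window: int | None = None) -> float:
    """Hurst index via classical rescaled-range analysis.

    For each window size tau in a log-spaced set between ``min_window`` and
    ``max_window`` (defaults: max(8, n // 32) and n // 2), the range of the cumulative deviations of
    each non-overlapping block is divided by the block standard deviation and
    averaged. The estimate is ``0.5 + slope`` of the OLS fit of
    ``log(R/S) - log(E[R/S])`` against ``log(tau)``, where E[R/S] is the
    Anis-Lloyd white-noise expectation — the small-sample bias correction
    that re-centres white noise at 0.5.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise DomainError("hurst_rs expects a 1-D series")
    if x.size < 16:
        raise SampleSizeError(f"need at least 16 values, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise MissingDataError("series contains NaN/inf; mask before calling")
    if np.ptp(x) == 0:
        raise DomainError("constant series has zero range; Hurst undefined")
    est = hurst_rs_grid(x[:, None], min_window=min_window, max_window=max_window)
    h = float(est[0])
    if np.isnan(h):
        raise DomainError("R/S undefined for this series (zero in-block dispersion)")
    return h


def hurst_rs_grid(stack: np.ndarray, min_window: int | None = None, max_window: int | None = None) -> np.ndarray:
    """Vectorised Hurst R/S estimate along axis 0; NaN where undefined."""
    n = stack.shape[0]
    flat = stack.reshape(n, -1).astype(float)
    sizes = _rs_window_sizes(n, min_window, max_window)
    if len(sizes) < 2:
        raise SampleSizeError("need at least two distinct window sizes for the log-log fit")
    rs = _rs_values(flat, sizes)
    expected = _anis_lloyd_expectation(sizes)
    logtau = np.log(sizes)
    logtau = logtau - logtau.mean()
    denom = np.sum(logtau**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        y = np.log(rs) - np.log(expected)[:, None]
    bad = np.any(~np.isfinite(y), axis=0)
    y = np.where(np.isfinite(y), y, 0.0)
    slope = (logtau[:, None] * (y - y.mean(axis=0))).sum(axis=0) / denom
    h = 0.5 + slope
    h[bad] = np.nan
    return h.reshape(stack.shape[1:])


# ---------------------------------------------------------------------------
# Future-trend typology
# ---------------------------------------------------------------------------

def classify_future_trend(sen_slope: float, mk_z: float, hurst: float,
                          z_threshold: float = Z_SIGNIFICANT) -> int:
    """Map (slope, |Z|, HI) to the six-class future-trend code.

    =========  =========  ========  ==========================  ====
    slope      \\|Z|        HI        meaning                     code
    =========  =========  ========  ==========================  ====
    any        <= 1.96    <= 0.5    uncertain                    1
    < 0        >  1.96    <= 0.5    decreasing to increasing     2
    > 0        >  1.96    <= 0.5    increasing to decreasing     3
    any        <= 1.96    >  0.5    persistently stable          4
    < 0        >  1.96    >  0.5    persistently decreasing      5
    > 0        >  1.96    >  0.5    persistently increasing      6
    =========  =========  ========  ==========================  ====

    A significant |Z| with an exactly zero slope has no row above; it is
    classed 1 (no evidence of direction). Grid callers receive a diagnostic
    flag for such pixels via :func:`classify_future_trend_grid`.
    """
    if not (np.isfinite(sen_slope) and np.isfinite(mk_z) and np.isfinite(hurst)):
        raise DomainError("classify_future_trend requires finite inputs")
    code, _ = _classify(np.asarray([sen_slope]), np.asarray([mk_z]), np.asarray([hurst]), z_threshold)
    return int(code[0])


def _classify(slope, z, hurst, z_threshold):
    az = np.abs(z)
    persistent = hurst > 0.5
    significant = az > z_threshold
    code = np.where(persistent, 4, 1)
    code = np.where(significant & (slope < 0), np.where(persistent, 5, 2), code)
    code = np.where(significant & (slope > 0), np.where(persistent, 6, 3), code)
    gap = significant & (slope == 0)
    code = np.where(gap, 1, code)
    return code.astype(int), gap


def classify_future_trend_grid(sen_slope: np.ndarray, mk_z: np.ndarray, hurst: np.ndarray,
                               z_threshold: float = Z_SIGNIFICANT) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised :func:`classify_future_trend`; returns (codes, gap_flags).

    Pixels with any non-finite input get code 0 (invalid) and no flag.
    """
    slope = np.asarray(sen_slope, dtype=float)
    z = np.asarray(mk_z, dtype=float)
    h = np.asarray(hurst, dtype=float)
    code, gap = _classify(slope, z, h, z_threshold)
    valid = np.isfinite(slope) & np.isfinite(z) & np.isfinite(h)
    return np.where(valid, code, 0), gap & valid


# ---------------------------------------------------------------------------
# Raster driver
# ---------------------------------------------------------------------------

@dataclass
class TrendResult:
    """Per-pixel trend grids plus an area summary.

    All grids share the (y, x) shape of the input stack; pixels outside the
    valid mask are NaN (or 0 for the integer code grid).
    """

    sen_slope: np.ndarray
    mk_s: np.ndarray
    mk_z: np.ndarray
    hurst: np.ndarray
    future_code: np.ndarray
    gap_flag: np.ndarray
    summary: pd.DataFrame = field(repr=False)


def trend_map(stack: np.ndarray, valid_mask: np.ndarray | None = None,
              min_years_for_hurst: int = 10, z_threshold: float = Z_SIGNIFICANT,
              min_window: int | None = None) -> TrendResult:
    """Apply the three trend estimators per pixel over an annual stack.

    Parameters
    ----------
    stack
        (year, y, x) array of annual values.
    valid_mask
        Boolean (y, x) mask of analysable pixels; defaults to all-finite
        pixels. Per-pixel failures (constant series for Hurst) become NaN,
        never abort the map.
    min_years_for_hurst
        Below this series length the Hurst index is not attempted and the
        future-trend code is left invalid (0).
    """
    n_years = stack.shape[0]
    finite = np.all(np.isfinite(stack), axis=0)
    mask = finite if valid_mask is None else (np.asarray(valid_mask, bool) & finite)

    work = np.where(mask[None, :, :], stack, np.nan)
    sen = theil_sen_grid(work)
    mk_s, mk_z = mann_kendall_grid(work)
    if n_years >= min_years_for_hurst:
        hurst = hurst_rs_grid(work, min_window=min_window)
    else:
        hurst = np.full(stack.shape[1:], np.nan)
    code, gap = classify_future_trend_grid(sen, mk_z, hurst, z_threshold)
    code = np.where(mask, code, 0)

    n_valid = int(mask.sum())
    rows = []
    for c, label in FUTURE_TREND_LABELS.items():
        pct = 100.0 * np.sum(code == c) / n_valid if n_valid else np.nan
        rows.append({"class": f"code_{c}", "label": label, "area_pct": pct})
    sig = np.abs(mk_z) > z_threshold
    for label, sel in [
        ("significant increase", mask & sig & (sen > 0)),
        ("nonsignificant increase", mask & ~sig & (sen > 0)),
        ("no trend", mask & (sen == 0)),
        ("nonsignificant decrease", mask & ~sig & (sen < 0)),
        ("significant decrease", mask & sig & (sen < 0)),
    ]:
        pct = 100.0 * np.sum(sel) / n_valid if n_valid else np.nan
        rows.append({"class": "slope_significance", "label": label, "area_pct": pct})
    summary = pd.DataFrame(rows)
    return TrendResult(sen, mk_s, mk_z, hurst, code, gap, summary)
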