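"""Composite vegetation ecological quality index (VEQI).

The index couples vegetation structure and function:

* each annual ecosystem-function grid is min-max normalised over its full
  space-time record;
* the four normalised functions are combined into the integrated
  ecological function EFc with objective CRITIC weights (an indicator's
  weight grows with its contrast — standard deviation — and its conflict
  — one minus its correlation with the other indicators);
* fractional vegetation cover FVC comes from the EVI by pixel dichotomy,
  with the bare-soil and full-vegetation endpoints taken as the 0.5th and
  99.5th percentiles of the study-area EVI record;
* VEQI = (FVC x f1 + EFc x f2) x 100%, the two weights again from CRITIC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    ConfigurationError,
    DegenerateIndicatorError,
    SampleSizeError,
    ShapeError,
)


@dataclass
class CriticWeights:
    """CRITIC weighting diagnostics for a set of indicators.

    ``information[j] = contrast[j] * conflict[j]`` with
    ``contrast = sigma_j`` (standard deviation over observations) and
    ``conflict = sum_k (1 - r_jk)`` over Pearson correlations; weights are
    the information contents normalised to sum to one.
    """

    names: tuple[str, ...]
    contrast: np.ndarray
    conflict: np.ndarray
    information: np.ndarray
    weights: np.ndarray

    def as_dict(self) -> dict:
        return {
            name: {
                "sigma": float(self.contrast[j]),
                "conflict": float(self.conflict[j]),
                "information": float(self.information[j]),
                "weight": float(self.weights[j]),
            }
            for j, name in enumerate(self.names)
        }


@dataclass
class VeqiStack:
    """Annual composite-index grids plus the weights that produced them."""

    veqi: np.ndarray          # percent, [0, 100]
    fvc: np.ndarray           # [0, 1]
    efc: np.ndarray           # [0, 1]
    normalized_functions: dict[str, np.ndarray]
    function_weights: CriticWeights
    coupling_weights: CriticWeights


def minmax_normalize(grid: np.ndarray) -> np.ndarray:
    """Normalise one indicator to [0, 1] by its global space-time min/max.

    The extent is deliberately the full record — per-pixel normalisation
    would erase spatial contrast between good and poor sites.
    """
    grid = np.asarray(grid, dtype=float)
    finite = grid[np.isfinite(grid)]
    if finite.size < 2:
        raise DegenerateIndicatorError("fewer than 2 finite values to normalise")
    lo, hi = finite.min(), finite.max()
    if hi <= lo:
        raise DegenerateIndicatorError("constant indicator carries no information")
    return (grid - lo) / (hi - lo)


def critic_weights(indicator_matrix: np.ndarray, names=None) -> CriticWeights:
    """Objective CRITIC weights from an observations x indicators matrix.

    C_j = sigma_j * sum_k (1 - r_jk); w_j = C_j / sum C. Standard deviations
    use the population convention (ddof 0); r is the Pearson correlation
    over the supplied observations.
    """
    x = np.asarray(indicator_matrix, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ConfigurationError("need a 2-D matrix with at least 2 indicator columns")
    if x.shape[0] < 3:
        raise SampleSizeError(f"need at least 3 observations, got {x.shape[0]}")
    if not np.all(np.isfinite(x)):
        x = x[np.all(np.isfinite(x), axis=1)]
        if x.shape[0] < 3:
            raise SampleSizeError("fewer than 3 complete observations after masking")
    sigma = x.std(axis=0)
    if np.any(sigma == 0):
        raise DegenerateIndicatorError("constant indicator column carries no information")
    r = np.corrcoef(x, rowvar=False)
    conflict = (1.0 - r).sum(axis=1)
    info = sigma * conflict
    weights = info / info.sum()
    if names is None:
        names = tuple(f"indicator_{j}" for j in range(x.shape[1]))
    return CriticWeights(tuple(names), sigma, conflict, info, weights)


def integrate_functions(normalized: dict[str, np.ndarray], weights: CriticWeights) -> np.ndarray:
    """Integrated ecological function EFc: the CRITIC-weighted sum of the
    normalised function grids, elementwise per pixel-year."""
    if set(normalized) != set(weights.names):
        raise ConfigurationError(
            f"weights cover {sorted(weights.names)} but grids are {sorted(normalized)}"
        )
    shapes = {g.shape for g in normalized.values()}
    if len(shapes) != 1:
        raise ShapeError(f"function grids disagree in shape: {shapes}")
    out = np.zeros(shapes.pop(), dtype=float)
    for j, name in enumerate(weights.names):
        out += weights.weights[j] * normalized[name]
    return out


def fvc_from_evi(evi_monthly: np.ndarray, lo_pct: float = 0.5, hi_pct: float = 99.5,
                 months_per_year: int = 12, valid_mask: np.ndarray | None = None) -> np.ndarray:
    """Annual fractional vegetation cover by pixel dichotomy.

    The bare-soil endpoint EVI_soil and full-vegetation endpoint EVI_veg are
    the ``lo_pct`` / ``hi_pct`` empirical percentiles of all valid EVI
    values in the record. Monthly cover fractions
    (EVI - EVI_soil) / (EVI_veg - EVI_soil) are clipped to [0, 1] and
    averaged within each year.
    """
    evi = np.asarray(evi_monthly, dtype=float)
    if evi.shape[0] < months_per_year or evi.shape[0] % months_per_year:
        raise ShapeError("need a whole number of years of monthly EVI")
    pool = evi if valid_mask is None else evi[:, valid_mask]
    pool = pool[np.isfinite(pool)]
    evi_soil, evi_veg = np.percentile(pool, [lo_pct, hi_pct])
    if evi_veg <= evi_soil:
        raise DegenerateIndicatorError("EVI percentile endpoints collapsed; scene has no contrast")
    fc = np.clip((evi - evi_soil) / (evi_veg - evi_soil), 0.0, 1.0)
    n_years = evi.shape[0] // months_per_year
    return fc.reshape(n_years, months_per_year, *evi.shape[1:]).mean(axis=1)


def compute_veqi(fvc: np.ndarray, efc: np.ndarray,
                 valid_mask: np.ndarray | None = None) -> tuple[np.ndarray, CriticWeights]:
    """Couple cover and function into VEQI = (FVC f1 + EFc f2) x 100%.

    The coupling weights (f1, f2) come from CRITIC over pooled pixel-year
    observations of (FVC, EFc); the returned grid is in percent, [0, 100].
    """
    fvc = np.asarray(fvc, dtype=float)
    efc = np.asarray(efc, dtype=float)
    if fvc.shape != efc.shape:
        raise ShapeError("fvc and efc must share a shape")
    if valid_mask is not None:
        rows = np.column_stack([fvc[:, valid_mask].ravel(), efc[:, valid_mask].ravel()])
    else:
        rows = np.column_stack([fvc.ravel(), efc.ravel()])
    w = critic_weights(rows, names=("fvc", "efc"))
    veqi = (fvc * w.weights[0] + efc * w.weights[1]) * 100.0
    return veqi, w
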