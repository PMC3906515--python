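"""Intensity-dependent dye-bias removal and between-array M scaling.

Two-color arrays show a curved M-vs-A trend caused by unequal dye
incorporation and scanner response.  Local intensity-dependent
normalization estimates that trend with a robust local regression of M on A
and subtracts it, leaving biologically meaningful log-ratios centered on
zero for unregulated probes.  A per-array robust scale step then equalizes
M magnitudes across arrays so their values are comparable.

The trend fit is a robust degree-1 local regression with tricube weights
(statsmodels lowess) at a fixed span, with robustifying reweighting
iterations that downweight large residuals so strongly regulated probes do
not drag the fit.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from dataclasses import dataclass
from statsmodels.nonparametric.smoothers_lowess import lowess

from .arrays import MASet
from .errors import ConfigurationError, InputError

logger = logging.getLogger(__name__)

MIN_PROBES_FOR_FIT = 50
MAD_TO_SD = 1.4826  # consistency factor: MAD of a normal sample → SD


@dataclass
class TrendFit:
    """A fitted M-vs-A bias curve, evaluable anywhere by interpolation."""

    array_id: str
    grid_a: np.ndarray
    grid_m: np.ndarray
    span: float
    robust_iterations: int

    def __call__(self, a: np.ndarray) -> np.ndarray:
        return np.interp(np.asarray(a, dtype=float), self.grid_a, self.grid_m)


def fit_intensity_trend(ma: MASet, span: float = 0.3,
                        robust_iterations: int = 3,
                        trim_mad: float = 3.0,
                        reject_sd: float = 2.0,
                        reject_iterations: int = 3,
                        reject_floor: float = 0.1) -> TrendFit:
    """Fit the intensity-dependent bias trend of one array.

    The fit is a robust local-linear regression of M on A, hardened against
    regulated probes in two ways beyond lowess's own reweighting.  First,
    globally extreme M values (further than ``trim_mad`` robust SDs from the
    array median) are excluded up front: dye bias is a sub-unit effect while
    regulation reaches several log2 units, and up-front trimming is immune
    to the local masking that residual-based weights suffer when regulated
    probes cluster in one intensity range — which is exactly what residual
    neuronal transcripts do at low A in co-culture arrays.  Second, the fit
    is re-estimated ``reject_iterations`` times after discarding probes whose
    residual exceeds ``reject_sd`` robust SDs, peeling off moderately
    regulated probes that survive the global trim.

    Parameters
    ----------
    ma
        M/A values of one array (typically raw, i.e. un-normalized).
    span
        Fraction of probes in each local window, in (0, 1].
    robust_iterations
        Lowess robustifying reweighting iterations per fit.
    trim_mad
        Global pre-trim threshold in MAD-based robust SDs.
    reject_sd
        Residual threshold for the trimmed refits, in robust SDs.
    reject_iterations
        Number of reject-and-refit passes.
    reject_floor
        Minimum rejection radius in log2 units.  Rejection exists to peel
        off regulation-scale outliers; residuals at dye-bias scale are never
        rejected, which keeps the refits stable on nearly noise-free data.
    """
    if not 0.0 < span <= 1.0:
        raise ConfigurationError(f"span must be in (0, 1], got {span}")
    if ma.table.shape[0] < MIN_PROBES_FOR_FIT:
        raise InputError(
            f"array {ma.array_id} has only {ma.table.shape[0]} probes; "
            f"at least {MIN_PROBES_FOR_FIT} are required for a trend fit — "
            "analyze raw M values instead")
    # sort by (A, probe_id) so ties in A are resolved reproducibly
    order = np.lexsort((ma.table["probe_id"].to_numpy(), ma.a))
    a, m = ma.a[order], ma.m[order]
    delta = 0.01 * (a[-1] - a[0])

    def smooth(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        fitted = lowess(m[mask], a[mask], frac=span, it=robust_iterations,
                        delta=delta, return_sorted=True)
        grid_a, idx = np.unique(fitted[:, 0], return_index=True)
        return grid_a, fitted[:, 1][idx]

    med = np.median(m)
    mad = np.median(np.abs(m - med)) * MAD_TO_SD
    # like the rejection radius, the trim radius never shrinks below
    # regulation scale: dye bias stays within ~1 log2 unit of the bulk
    trim_radius = max(trim_mad * mad, 10.0 * reject_floor)
    keep = np.abs(m - med) <= trim_radius if mad > 0 else np.ones(m.size, bool)
    grid_a, grid_m = smooth(keep)
    for _ in range(reject_iterations):
        resid = m - np.interp(a, grid_a, grid_m)
        rmed = np.median(resid)
        rmad = np.median(np.abs(resid - rmed)) * MAD_TO_SD
        if rmad <= 0:
            break
        radius = max(reject_sd * rmad, reject_floor)
        retained = keep & (np.abs(resid - rmed) <= radius)
        if retained.sum() < MIN_PROBES_FOR_FIT:
            break
        grid_a, grid_m = smooth(retained)
    if not np.all(np.isfinite(grid_m)):
        raise InputError(f"trend fit for array {ma.array_id} is not finite")
    return TrendFit(array_id=ma.array_id, grid_a=grid_a, grid_m=grid_m,
                    span=span, robust_iterations=robust_iterations)


def normalize_intensity(ma: MASet, fit: TrendFit) -> MASet:
    """Subtract the fitted bias trend: M' = M − trend(A); A is unchanged."""
    if fit.array_id != ma.array_id:
        raise InputError(
            f"trend fit is for array {fit.array_id}, not {ma.array_id}")
    m_prime = ma.m - fit(ma.a)
    return ma.with_m(m_prime, normalized=True)


def normalize_array(ma: MASet, span: float = 0.3,
                    robust_iterations: int = 3) -> tuple[MASet, TrendFit]:
    """Convenience: fit the trend and subtract it in one call."""
    fit = fit_intensity_trend(ma, span=span, robust_iterations=robust_iterations)
    return normalize_intensity(ma, fit), fit


def robust_scale(m: np.ndarray) -> float:
    """MAD-based scale estimate of an M vector (≈ SD under normality)."""
    m = np.asarray(m, dtype=float)
    return float(np.median(np.abs(m - np.median(m))) * MAD_TO_SD)


def scale_m_values(ma_sets: list[MASet]) -> list[MASet]:
    """Equalize robust M scales across arrays.

    Each array's M is divided by its MAD·1.4826 scale and multiplied by the
    geometric mean of all arrays' scales, so between-array magnitudes become
    comparable while the overall magnitude level is preserved.  Rank order
    within each array is unchanged; an array with zero scale is left
    untouched with a warning.
    """
    if not ma_sets:
        raise InputError("scale_m_values requires at least one MASet")
    scales = np.array([robust_scale(ma.m) for ma in ma_sets])
    usable = scales > 0
    if not usable.any():
        logger.warning("all arrays have zero robust M scale; nothing rescaled")
        return list(ma_sets)
    ref = float(np.exp(np.mean(np.log(scales[usable]))))
    out: list[MASet] = []
    for ma, s in zip(ma_sets, scales):
        if s <= 0:
            logger.warning("array %s has zero robust M scale; left unscaled",
                           ma.array_id)
            out.append(ma)
        else:
            out.append(ma.with_m(ma.m * (ref / s)))
    return out


def decile_means(ma: MASet, n_bins: int = 10) -> pd.DataFrame:
    """Mean M per A-decile — the QC table written before/after normalization."""
    a, m = ma.a, ma.m
    edges = np.quantile(a, np.linspace(0, 1, n_bins + 1))
    bins = np.clip(np.searchsorted(edges, a, side="right") - 1, 0, n_bins - 1)
    rows = [(b, float(m[bins == b].mean()), int((bins == b).sum()))
            for b in range(n_bins) if (bins == b).any()]
    return pd.DataFrame(rows, columns=["decile", "mean_M", "n_probes"])
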