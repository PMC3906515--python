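"""Cold-jet efficiency at the RNA level and replicate concordance.

The efficiency estimator mirrors the study's fluorescence arithmetic: for
neuron-enriched probes (the most cold-jet-depleted probes of the CC vs
CC-CJ comparison), take their fluorescence in CC and CC-CJ, subtract the
level present in astrocytes alone, and express the residual as a
percentage of the co-culture level:

    residual%  = 100 · (F_CCCJ − F_AA) / (F_CC − F_AA)
    removal%   = 100 − summary(residual%)

Because F_AA lives on different physical arrays (the Cy5 channel of the
regulation arrays) than F_CC / F_CCCJ, single-channel fluorescence is
first made comparable across arrays by 75th-percentile scaling over
unselected probes, optionally after per-probe dye-bias correction using
the normalization trend fits; replicate channels are then averaged per
sample.

Replicate concordance is Spearman's rho between same-sample channels of
replicate arrays, computed on raw (non-normalized) fluorescence restricted
to regulated probes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .arrays import (
    DESIGN_SAMPLES,
    ArrayScan,
    MASet,
    SAMPLE_AACJ,
    SAMPLE_CC,
    SAMPLE_CCCJ,
)
from .errors import InputError
from .normalize import TrendFit

logger = logging.getLogger(__name__)


@dataclass
class EfficiencyReport:
    """Per-probe residual neuronal signal and the summary removal percent."""

    probe_ids: list[str]
    residual_percent: pd.DataFrame   # probe_id, residual_percent
    removal_percent: float
    summary: str                     # "median" or "mean"
    n_skipped_denominator: int
    normalization_mode: str


@dataclass
class ConcordanceReport:
    """Spearman rho between replicate channels on a probe subset."""

    pairs: pd.DataFrame   # sample, array_a, array_b, rho, n_probes
    probe_subset_size: int


def neuron_enriched_probe_set(dep_ma_a: MASet, dep_ma_b: MASet | None = None,
                              n: int = 40) -> list[str]:
    """Top-n probes most depleted by the cold jet (highest M in CC vs CC-CJ).

    With both arrays given, probes are ranked by their mean depletion M; a
    single array ranks by that array alone (used by the cross-replicate
    efficiency estimator).
    """
    if n == 0:
        return []
    a = dep_ma_a.table.set_index("probe_id")["M"]
    if dep_ma_b is not None:
        b = dep_ma_b.table.set_index("probe_id")["M"]
        common = a.index.intersection(b.index)
        a = (a.loc[common] + b.loc[common]) / 2.0
    mean_m = a.sort_values(ascending=False)
    if n > len(mean_m):
        logger.warning("requested top %d probes but only %d available", n, len(mean_m))
        n = len(mean_m)
    return mean_m.index[:n].tolist()


def _corrected_channels(scan: ArrayScan, trend: TrendFit | None,
                        floor: float = 1.0) -> pd.DataFrame:
    """Red/green vectors of a scan, optionally dye-bias corrected.

    The normalization trend is defined on M (first-named over second-named
    sample); the correction is applied entirely to the red channel so that
    the corrected channels reproduce the normalized M values.
    """
    red = scan.probes["red"].to_numpy(dtype=float)
    green = scan.probes["green"].to_numpy(dtype=float)
    if trend is not None:
        a = 0.5 * np.log2(np.maximum(red, floor) * np.maximum(green, floor))
        t = trend(a)
        first, _ = DESIGN_SAMPLES[scan.design]
        red_is_numerator = scan.dye_map[first] == "red"
        red = red * np.exp2(-t if red_is_numerator else t)
    return pd.DataFrame({"red": red, "green": green},
                        index=scan.probes["probe_id"])


def _scaled_channels(scans: list[ArrayScan],
                     exclude_probes: set[str] | None,
                     trend_fits: dict[str, TrendFit] | None,
                     quantile: float) -> list[tuple[str, str, pd.Series]]:
    """Quantile-scaled (sample, array_id, fluorescence) channel triples."""
    if not scans:
        raise InputError("cross_array_channel_normalize requires scans")
    universe = set(scans[0].probes["probe_id"])
    for scan in scans[1:]:
        if set(scan.probes["probe_id"]) != universe:
            raise InputError(
                f"array {scan.array_id} has a different probe universe")
    exclude_probes = exclude_probes or set()
    trend_fits = trend_fits or {}

    channels: list[tuple[str, str, pd.Series]] = []
    for scan in scans:
        table = _corrected_channels(scan, trend_fits.get(scan.array_id))
        for sample, dye in scan.dye_map.items():
            channels.append((sample, scan.array_id, table[dye]))

    ref_mask = ~channels[0][2].index.isin(list(exclude_probes))
    quantiles = np.array([np.quantile(vec[ref_mask], quantile)
                          for _, _, vec in channels])
    if np.any(quantiles <= 0):
        raise InputError("non-positive reference quantile; cannot scale channels")
    target = float(np.exp(np.mean(np.log(quantiles))))
    return [(sample, aid, vec * (target / q))
            for (sample, aid, vec), q in zip(channels, quantiles)]


def cross_array_channel_normalize(scans: list[ArrayScan],
                                  exclude_probes: set[str] | None = None,
                                  trend_fits: dict[str, TrendFit] | None = None,
                                  quantile: float = 0.75,
                                  ) -> dict[str, pd.Series]:
    """Make single-channel fluorescence comparable across arrays.

    Each channel vector is scaled so that its `quantile` (default 75th
    percentile) over probes *not* in `exclude_probes` equals the geometric
    mean of those quantiles across all channels; replicate channels are then
    averaged per sample label.  Returns sample label → per-probe fluorescence.
    """
    channels = _scaled_channels(scans, exclude_probes, trend_fits, quantile)
    by_sample: dict[str, list[pd.Series]] = {}
    for sample, _, vec in channels:
        by_sample.setdefault(sample, []).append(vec)
    return {sample: pd.concat(vecs, axis=1).mean(axis=1)
            for sample, vecs in by_sample.items()}


def removal_efficiency(f_aa: pd.Series, f_cc: pd.Series, f_cccj: pd.Series,
                       probe_ids: list[str] | None = None,
                       summary: str = "median",
                       denominator_floor: float = 1e-9,
                       normalization_mode: str = "quantile75",
                       ) -> EfficiencyReport:
    """Estimate the percentage of neuronal RNA removed by the cold jet.

    Residuals are clipped to [0, 100] before summarizing (median by default)
    because noise can push individual probes outside the physical range;
    probes whose background-subtracted co-culture signal F_CC − F_AA is
    below `denominator_floor` are skipped and counted.
    """
    if summary not in ("median", "mean"):
        raise InputError(f"summary must be 'median' or 'mean', got {summary!r}")
    if probe_ids is not None:
        f_aa, f_cc, f_cccj = (v.loc[probe_ids] for v in (f_aa, f_cc, f_cccj))
    denom = f_cc - f_aa
    usable = denom > denominator_floor
    n_skipped = int((~usable).sum())
    if not usable.any():
        raise InputError("no probes with positive co-culture minus astrocyte "
                         "signal; cannot estimate removal efficiency")
    residual = 100.0 * (f_cccj[usable] - f_aa[usable]) / denom[usable]
    residual = residual.clip(0.0, 100.0)
    stat = float(residual.median() if summary == "median" else residual.mean())
    return EfficiencyReport(
        probe_ids=residual.index.tolist(),
        residual_percent=pd.DataFrame({"probe_id": residual.index,
                                       "residual_percent": residual.to_numpy()}
                                      ).reset_index(drop=True),
        removal_percent=100.0 - stat,
        summary=summary,
        n_skipped_denominator=n_skipped,
        normalization_mode=normalization_mode,
    )


def estimate_removal(scans: list[ArrayScan], dep_ma: tuple[MASet, MASet],
                     top_n: int = 40, summary: str = "median",
                     trend_fits: dict[str, TrendFit] | None = None,
                     cross_replicate: bool = True) -> EfficiencyReport:
    """End-to-end efficiency estimate from the four scans.

    Selects the top-n cold-jet-depleted probes, makes channels comparable
    across arrays (excluding those probes from the scaling reference), and
    evaluates the background-subtracted residual formula.

    With ``cross_replicate`` (default) the ranking and the measurement use
    different replicates: probes ranked on one CC vs CC-CJ array are
    measured on the other array's channels, and the two folds' per-probe
    residuals are pooled before summarizing.  Ranking probes by extremeness
    on the very channels entering the residual formula otherwise couples
    selection noise to measurement noise and deflates the residual
    (a winner's-curse effect visible at moderate removal rates).
    """
    if len(dep_ma) != 2:
        raise InputError("estimate_removal needs the two CC vs CC-CJ MA sets")
    dep_ids = {ma.array_id for ma in dep_ma}

    if cross_replicate:
        folds = [(neuron_enriched_probe_set(dep_ma[0], n=top_n), dep_ma[1].array_id),
                 (neuron_enriched_probe_set(dep_ma[1], n=top_n), dep_ma[0].array_id)]
    else:
        folds = [(neuron_enriched_probe_set(*dep_ma, n=top_n), None)]
    exclude = set().union(*(set(p) for p, _ in folds))
    channels = _scaled_channels(scans, exclude, trend_fits, quantile=0.75)

    def sample_mean(sample: str, use_dep_array: str | None) -> pd.Series:
        # for CC / CC-CJ channels on the depletion arrays, restrict to the
        # measurement replicate of the fold; other channels are independent
        vecs = [vec for s, aid, vec in channels
                if s == sample and (use_dep_array is None
                                    or aid not in dep_ids or aid == use_dep_array)]
        if not vecs:
            raise InputError(f"sample {sample} not present on any array")
        return pd.concat(vecs, axis=1).mean(axis=1)

    reports = []
    for probe_ids, measure_array in folds:
        reports.append(removal_efficiency(
            sample_mean(SAMPLE_AACJ, measure_array),
            sample_mean(SAMPLE_CC, measure_array),
            sample_mean(SAMPLE_CCCJ, measure_array),
            probe_ids=probe_ids, summary=summary))
    if len(reports) == 1:
        return reports[0]
    residual = pd.concat([r.residual_percent for r in reports],
                         ignore_index=True)
    vals = residual["residual_percent"]
    stat = float(vals.median() if summary == "median" else vals.mean())
    return EfficiencyReport(
        probe_ids=residual["probe_id"].tolist(),
        residual_percent=residual,
        removal_percent=100.0 - stat,
        summary=summary,
        n_skipped_denominator=sum(r.n_skipped_denominator for r in reports),
        normalization_mode="quantile75+cross_replicate",
    )


def replicate_concordance(scans: list[ArrayScan],
                          regulated_probe_ids: list[str]) -> ConcordanceReport:
    """Spearman rho between replicate channels, on regulated probes only.

    For every sample hybridized on more than one array, all pairs of its raw
    channel vectors are compared (average-rank tie handling).  Constant
    vectors yield an undefined rho, reported as NaN.
    """
    if len(regulated_probe_ids) < 2:
        raise InputError("need at least 2 probes for a rank correlation")
    by_sample: dict[str, list[tuple[str, pd.Series]]] = {}
    for scan in scans:
        table = scan.probes.set_index("probe_id")
        for sample, dye in scan.dye_map.items():
            vec = table[dye].reindex(regulated_probe_ids)
            if vec.isna().any():
                raise InputError(
                    f"array {scan.array_id} is missing regulated probes")
            by_sample.setdefault(sample, []).append((scan.array_id, vec))

    rows = []
    for sample, vecs in sorted(by_sample.items()):
        for i in range(len(vecs)):
            for j in range(i + 1, len(vecs)):
                (id_a, va), (id_b, vb) = vecs[i], vecs[j]
                if va.nunique() <= 1 or vb.nunique() <= 1:
                    rho = float("nan")
                    logger.warning("constant fluorescence vector for %s on "
                                   "%s/%s; rho undefined", sample, id_a, id_b)
                else:
                    rho = float(sps.spearmanr(va, vb).statistic)
                rows.append((sample, id_a, id_b, rho, len(va)))
    pairs = pd.DataFrame(rows, columns=["sample", "array_a", "array_b",
                                        "rho", "n_probes"])
    return ConcordanceReport(pairs=pairs,
                             probe_subset_size=len(regulated_probe_ids))
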