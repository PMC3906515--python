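"""Four-criterion selection of neuron-responsive astrocyte transcripts.

The selection operates on normalized M values of the two replicate
CC-CJ vs AA-CJ arrays, with the two CC vs CC-CJ arrays supplying the
neuronal-contamination check:

1. Per array, compute the mean and sample SD of all probes' M values and
   call a probe up/down when M ≥ mean + 2·SD or M ≤ mean − 2·SD
   (boundaries inclusive).
2. A probe must be called in the same direction on both replicate arrays.
3. Genes represented by multiple probes are kept only when their called
   probes agree in direction (configurable stricter variant: every sibling
   probe must itself pass the thresholds).
4. An up-called gene that is also extremely depleted by the cold jet
   (M ≥ mean + 2·SD on both CC vs CC-CJ arrays, oriented positive = higher
   in CC) is interpreted as residual neuronal RNA and removed.  Criterion 4
   never touches down-regulated candidates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .arrays import MASet
from .errors import InputError

logger = logging.getLogger(__name__)

DIR_UP = "up"
DIR_DOWN = "down"
DIR_NONE = "none"

#: criterion-3 variants: called probes must agree ("unanimity", default) or
#: every sibling probe must itself pass the thresholds ("all_probes_pass")
CONSISTENCY_RULES = ("unanimity", "all_probes_pass")

#: criterion-4 readings: "exclude_extreme" (default) removes up-candidates
#: whose cold-jet depletion reaches the +2SD extreme on both contamination
#: arrays; "require_extreme" is the literal alternate that keeps only those
CRITERION4_MODES = ("exclude_extreme", "require_extreme")


@dataclass
class ThresholdStats:
    """Per-array mean/SD of M and the mean ± 2·SD calling cutoffs."""

    array_id: str
    mean_m: float
    sd_m: float
    n_probes: int
    degenerate: bool = False

    @property
    def upper(self) -> float:
        return self.mean_m + 2.0 * self.sd_m

    @property
    def lower(self) -> float:
        return self.mean_m - 2.0 * self.sd_m


@dataclass
class ProbeCalls:
    """Per-probe direction calls on one array (or a replicate intersection)."""

    array_id: str
    table: pd.DataFrame  # columns probe_id, gene_id, M, direction [, discordant]

    @property
    def called(self) -> pd.DataFrame:
        return self.table[self.table["direction"] != DIR_NONE]


@dataclass
class GeneCalls:
    """Gene-level calls after probe collapsing (criterion 3)."""

    table: pd.DataFrame        # columns gene_id, direction, mean_M, n_probes
    inconsistent: list[str] = field(default_factory=list)

    def genes(self, direction: str) -> list[str]:
        return self.table.loc[self.table["direction"] == direction, "gene_id"].tolist()


@dataclass
class RegulatedSet:
    """Final up/down gene lists with per-stage provenance counts."""

    up: pd.DataFrame           # gene_id, mean_M
    down: pd.DataFrame
    removed_contamination: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    @property
    def up_genes(self) -> list[str]:
        return self.up["gene_id"].tolist()

    @property
    def down_genes(self) -> list[str]:
        return self.down["gene_id"].tolist()


def compute_thresholds(ma: MASet) -> ThresholdStats:
    """Mean and sample SD (n−1 denominator) of all retained probes' M."""
    m = ma.m
    if m.size < 2:
        raise InputError(
            f"array {ma.array_id} has {m.size} probes; need >= 2 for thresholds")
    sd = float(np.std(m, ddof=1))
    # a constant vector yields sd at float-epsilon scale, not exactly zero
    degenerate = sd <= 1e-12 * max(1.0, abs(float(np.mean(m))))
    stats = ThresholdStats(array_id=ma.array_id, mean_m=float(np.mean(m)),
                           sd_m=sd, n_probes=int(m.size), degenerate=degenerate)
    if stats.degenerate:
        logger.warning("array %s has zero M variance; no probes will be called",
                       ma.array_id)
    return stats


def select_by_threshold(ma: MASet, stats: ThresholdStats) -> ProbeCalls:
    """Call each probe up/down/none against the array's mean ± 2·SD cutoffs."""
    if stats.array_id != ma.array_id:
        raise InputError(
            f"thresholds are for array {stats.array_id}, not {ma.array_id}")
    m = ma.m
    direction = np.full(m.shape, DIR_NONE, dtype=object)
    if not stats.degenerate:
        direction[m >= stats.upper] = DIR_UP
        direction[m <= stats.lower] = DIR_DOWN
    table = ma.table[["probe_id", "gene_id", "M"]].copy()
    table["direction"] = direction
    n_up = int((direction == DIR_UP).sum())
    n_down = int((direction == DIR_DOWN).sum())
    logger.info("array %s: %d up, %d down of %d probes called",
                ma.array_id, n_up, n_down, m.size)
    return ProbeCalls(array_id=ma.array_id, table=table)


def intersect_replicates(calls_a: ProbeCalls, calls_b: ProbeCalls) -> ProbeCalls:
    """Criterion 2: keep a call only when both replicate arrays agree.

    The output carries every probe with direction up/down/none, the mean of
    the two arrays' M values, and a ``discordant`` flag for probes called in
    opposite directions.
    """
    a = calls_a.table.set_index("probe_id")
    b = calls_b.table.set_index("probe_id")
    common = a.index.intersection(b.index)
    if len(common) == 0:
        raise InputError("replicate arrays share no probes")
    if len(common) < len(a) or len(common) < len(b):
        logger.warning("replicate intersection drops %d / %d probes present on "
                       "only one array", len(a) - len(common), len(b) - len(common))
    a, b = a.loc[common], b.loc[common]
    same = (a["direction"] == b["direction"]) & (a["direction"] != DIR_NONE)
    both_called = (a["direction"] != DIR_NONE) & (b["direction"] != DIR_NONE)
    discordant = both_called & (a["direction"] != b["direction"])
    table = pd.DataFrame({
        "probe_id": common,
        "gene_id": a["gene_id"].to_numpy(),
        "M": (a["M"].to_numpy() + b["M"].to_numpy()) / 2.0,
        "direction": np.where(same, a["direction"], DIR_NONE),
        "discordant": discordant.to_numpy(),
    }).reset_index(drop=True)
    return ProbeCalls(array_id=f"{calls_a.array_id}+{calls_b.array_id}", table=table)


def collapse_probes(calls: ProbeCalls,
                    consistency_rule: str = "unanimity") -> GeneCalls:
    """Criterion 3: collapse probe calls to gene calls with a consistency check.

    A gene is retained when its called probes agree in direction; under
    ``all_probes_pass`` every probe of the gene must itself be called.  The
    gene M is the mean over all of the gene's probes.
    """
    if consistency_rule not in CONSISTENCY_RULES:
        raise InputError(f"consistency_rule must be one of {CONSISTENCY_RULES}")
    rows = []
    inconsistent: list[str] = []
    called_genes = calls.table.loc[calls.table["direction"] != DIR_NONE,
                                   "gene_id"].unique()
    subset = calls.table[calls.table["gene_id"].isin(called_genes)]
    for gene_id, grp in subset.groupby("gene_id", sort=True):
        dirs = set(grp.loc[grp["direction"] != DIR_NONE, "direction"])
        if not dirs:
            continue
        if len(dirs) > 1:
            inconsistent.append(gene_id)
            continue
        if consistency_rule == "all_probes_pass" and (grp["direction"] == DIR_NONE).any():
            inconsistent.append(gene_id)
            continue
        rows.append((gene_id, dirs.pop(), float(grp["M"].mean()), len(grp)))
    table = pd.DataFrame(rows, columns=["gene_id", "direction", "mean_M", "n_probes"])
    return GeneCalls(table=table, inconsistent=sorted(inconsistent))


def _gene_mean_m(ma: MASet) -> pd.Series:
    return ma.table.groupby("gene_id")["M"].mean()


def contamination_filter(up_genes: list[str], dep_ma_a: MASet, dep_ma_b: MASet,
                         stats_a: ThresholdStats, stats_b: ThresholdStats,
                         mode: str = "exclude_extreme",
                         require_both: bool = True,
                         ) -> tuple[list[str], pd.DataFrame]:
    """Criterion 4: drop up-candidates that look like residual neuronal RNA.

    A gene's depletion signal is its probe-mean M on each CC vs CC-CJ array
    (positive = higher in CC, i.e. removed by the cold jet).  Under the
    default ``exclude_extreme`` mode a candidate is removed when that signal
    reaches the array's mean + 2·SD cutoff on both contamination arrays
    (one array suffices with ``require_both=False``).  ``require_extreme``
    is the literal alternate reading, keeping only the extreme-depletion
    candidates.  Genes absent from the contamination arrays cannot be tested
    and are retained with a warning.  Returns the retained genes and a table
    of removals with their per-array depletion M.
    """
    if mode not in CRITERION4_MODES:
        raise InputError(f"mode must be one of {CRITERION4_MODES}")
    mean_a, mean_b = _gene_mean_m(dep_ma_a), _gene_mean_m(dep_ma_b)
    kept: list[str] = []
    removed_rows = []
    for gene in up_genes:
        if gene not in mean_a.index or gene not in mean_b.index:
            logger.warning("gene %s missing from contamination arrays; retained "
                           "untested", gene)
            kept.append(gene)
            continue
        extreme_a = mean_a[gene] >= stats_a.upper
        extreme_b = mean_b[gene] >= stats_b.upper
        extreme = (extreme_a and extreme_b) if require_both else (extreme_a or extreme_b)
        drop = extreme if mode == "exclude_extreme" else not extreme
        if drop:
            removed_rows.append((gene, float(mean_a[gene]), float(mean_b[gene])))
        else:
            kept.append(gene)
    removed = pd.DataFrame(removed_rows,
                           columns=["gene_id", "depletion_M_a", "depletion_M_b"])
    return kept, removed


def rank_top(gene_table: pd.DataFrame, n: int) -> pd.DataFrame:
    """Top-n genes by |mean M| (descending), ties broken by gene_id."""
    if n < 1:
        raise InputError(f"n must be >= 1, got {n}")
    df = gene_table.copy()
    df["_abs"] = df["mean_M"].abs()
    df = df.sort_values(["_abs", "gene_id"], ascending=[False, True])
    return df.drop(columns="_abs").head(n).reset_index(drop=True)


def select_regulated(reg_ma: tuple[MASet, MASet], dep_ma: tuple[MASet, MASet],
                     consistency_rule: str = "unanimity",
                     criterion4_mode: str = "exclude_extreme",
                     criterion4_both: bool = True) -> RegulatedSet:
    """Run criteria 1–4 end to end on normalized MA sets.

    `reg_ma` are the two CC-CJ vs AA-CJ arrays (regulation comparison) and
    `dep_ma` the two CC vs CC-CJ arrays (cold-jet depletion comparison).
    """
    stats = [compute_thresholds(ma) for ma in reg_ma]
    calls = [select_by_threshold(ma, st) for ma, st in zip(reg_ma, stats)]
    joint = intersect_replicates(*calls)
    genes = collapse_probes(joint, consistency_rule=consistency_rule)

    up_before = genes.table[genes.table["direction"] == DIR_UP]
    down = genes.table[genes.table["direction"] == DIR_DOWN]

    dep_stats = [compute_thresholds(ma) for ma in dep_ma]
    kept_up, removed = contamination_filter(
        up_before["gene_id"].tolist(), dep_ma[0], dep_ma[1],
        dep_stats[0], dep_stats[1], mode=criterion4_mode,
        require_both=criterion4_both)
    up = up_before[up_before["gene_id"].isin(kept_up)]

    provenance = {
        "thresholds": {st.array_id: {"mean": st.mean_m, "sd": st.sd_m,
                                     "upper": st.upper, "lower": st.lower}
                       for st in stats + dep_stats},
        "n_probes_called_each": [int(len(c.called)) for c in calls],
        "n_probes_concordant": int(len(joint.called)),
        "n_probes_discordant": int(joint.table["discordant"].sum()),
        "n_genes_inconsistent": len(genes.inconsistent),
        "n_up_before_contamination_filter": int(len(up_before)),
        "n_up_removed_contamination": int(len(removed)),
        "n_up": int(len(up)),
        "n_down": int(len(down)),
        "criterion4_mode": criterion4_mode,
        "consistency_rule": consistency_rule,
    }
    return RegulatedSet(
        up=up[["gene_id", "mean_M", "n_probes"]].reset_index(drop=True),
        down=down[["gene_id", "mean_M", "n_probes"]].reset_index(drop=True),
        removed_contamination=removed,
        provenance=provenance,
    )
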