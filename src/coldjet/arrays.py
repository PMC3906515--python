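"""Data model and I/O for two-channel array scans and their M/A representation.

A two-color hybridization compares two RNA samples labeled with Cy5 ("red")
and Cy3 ("green") on one physical array.  The experiment uses two designs:

* ``CCCJ_vs_AACJ`` — co-culture after cold jet (Cy3) against astrocytes alone
  after cold jet (Cy5); positive M means higher in the co-cultured astrocytes.
* ``CC_vs_CCCJ``  — untreated co-culture (Cy5) against co-culture after cold
  jet (Cy3); positive M means higher before the cold jet, i.e. depleted by it.

M is the per-probe log2 channel ratio oriented so that "up in the first-named
sample" is positive; A is the mean log2 intensity of the two channels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError, InputError

logger = logging.getLogger(__name__)

DESIGN_CCCJ_VS_AACJ = "CCCJ_vs_AACJ"
DESIGN_CC_VS_CCCJ = "CC_vs_CCCJ"

SAMPLE_AACJ = "AA-CJ"
SAMPLE_CC = "CC"
SAMPLE_CCCJ = "CC-CJ"

#: first-named (numerator) and second-named (denominator) sample per design
DESIGN_SAMPLES: dict[str, tuple[str, str]] = {
    DESIGN_CCCJ_VS_AACJ: (SAMPLE_CCCJ, SAMPLE_AACJ),
    DESIGN_CC_VS_CCCJ: (SAMPLE_CC, SAMPLE_CCCJ),
}

#: dye assignment used throughout the study: CC-CJ is Cy3 (green) in both designs
DEFAULT_DYE_MAPS: dict[str, dict[str, str]] = {
    DESIGN_CCCJ_VS_AACJ: {SAMPLE_CCCJ: "green", SAMPLE_AACJ: "red"},
    DESIGN_CC_VS_CCCJ: {SAMPLE_CC: "red", SAMPLE_CCCJ: "green"},
}

ARRAY_TABLE_COLUMNS = ["probe_id", "gene_id", "red", "green", "is_control"]


@dataclass
class ArrayScan:
    """One two-channel hybridization: per-probe red/green fluorescence."""

    array_id: str
    design: str
    probes: pd.DataFrame  # columns probe_id, gene_id, red, green
    dye_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.design not in DESIGN_SAMPLES:
            raise ConfigurationError(
                f"design must be one of {sorted(DESIGN_SAMPLES)}, got {self.design!r}"
            )
        if not self.dye_map:
            self.dye_map = dict(DEFAULT_DYE_MAPS[self.design])
        expected = set(DESIGN_SAMPLES[self.design])
        if set(self.dye_map) != expected:
            raise ConfigurationError(
                f"dye_map samples {sorted(self.dye_map)} do not match design "
                f"{self.design} samples {sorted(expected)}"
            )
        if self.probes["probe_id"].duplicated().any():
            dup = self.probes.loc[self.probes["probe_id"].duplicated(), "probe_id"].iloc[0]
            raise InputError(f"duplicate probe_id {dup!r} in array {self.array_id}")

    @property
    def n_probes(self) -> int:
        return len(self.probes)

    def channel(self, sample: str) -> np.ndarray:
        """Fluorescence vector of the channel carrying `sample`."""
        try:
            dye = self.dye_map[sample]
        except KeyError:
            raise InputError(f"sample {sample!r} not hybridized on array {self.array_id}")
        return self.probes[dye].to_numpy(dtype=float)


@dataclass
class MASet:
    """Per-probe M (oriented log2 ratio) and A (mean log2 intensity) values."""

    array_id: str
    design: str
    table: pd.DataFrame  # columns probe_id, gene_id, M, A
    normalized: bool = False
    n_low_intensity_dropped: int = 0

    @property
    def m(self) -> np.ndarray:
        return self.table["M"].to_numpy(dtype=float)

    @property
    def a(self) -> np.ndarray:
        return self.table["A"].to_numpy(dtype=float)

    def with_m(self, m: np.ndarray, *, normalized: bool | None = None) -> "MASet":
        table = self.table.copy()
        table["M"] = np.asarray(m, dtype=float)
        return replace(
            self,
            table=table,
            normalized=self.normalized if normalized is None else normalized,
        )

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def read_array_table(path, design: str, dye_map: dict[str, str] | None = None,
                     array_id: str | None = None) -> ArrayScan:
    """Load a tab-delimited probe table into an :class:`ArrayScan`.

    Control rows (``is_control != 0``) and rows with negative fluorescence are
    dropped; their counts are logged.  Missing columns raise
    :class:`~coldjet.errors.FormatError` naming the column.
    """
    df = pd.read_csv(path, sep="\t")
    for col in ARRAY_TABLE_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"array table {path} is missing column {col!r}")
    n_control = int((df["is_control"] != 0).sum())
    df = df[df["is_control"] == 0]
    bad = (df["red"] < 0) | (df["green"] < 0)
    if bad.any():
        logger.warning("%s: rejected %d rows with negative fluorescence", path, int(bad.sum()))
        df = df[~bad]
    if n_control:
        logger.info("%s: dropped %d control rows", path, n_control)
    probes = df[["probe_id", "gene_id", "red", "green"]].reset_index(drop=True)
    if array_id is None:
        import os

        array_id = os.path.splitext(os.path.basename(str(path)))[0]
    return ArrayScan(array_id=array_id, design=design, probes=probes,
                     dye_map=dye_map or {})


def ma_transform(scan: ArrayScan, floor: float = 1.0) -> MASet:
    """Compute oriented M and A values for every probe of a scan.

    The numerator channel is the design's first-named sample, so upregulation
    in that sample gives positive M.  Channels are floored at `floor` before
    taking logs; probes with *both* channels below the floor are dropped and
    counted in ``n_low_intensity_dropped``.
    """
    if floor <= 0:
        raise ConfigurationError(f"floor must be positive, got {floor}")
    first, second = DESIGN_SAMPLES[scan.design]
    num = scan.channel(first)
    den = scan.channel(second)
    both_low = (num < floor) & (den < floor)
    n_dropped = int(both_low.sum())
    keep = ~both_low
    num = np.maximum(num[keep], floor)
    den = np.maximum(den[keep], floor)
    m = np.log2(num / den)
    a = 0.5 * np.log2(num * den)
    table = scan.probes.loc[keep, ["probe_id", "gene_id"]].reset_index(drop=True)
    table["M"] = m
    table["A"] = a
    return MASet(array_id=scan.array_id, design=scan.design, table=table,
                 normalized=False, n_low_intensity_dropped=n_dropped)
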