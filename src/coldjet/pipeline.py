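"""End-to-end orchestration: read → MA → normalize → select → evaluate → enrich.

One :func:`run_pipeline` call reproduces the two analysis purposes of the
experiment — detection of neuron-induced astrocyte gene expression and
quantification of the cold jet's RNA-removal efficiency — from a directory
of array tables plus ontology/annotation files, writing all tabular outputs
and a JSON run report with per-stage counts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .arrays import (
    DESIGN_CC_VS_CCCJ,
    DESIGN_CCCJ_VS_AACJ,
    read_array_table,
    ma_transform,
)
from .errors import ConfigurationError, StageError
from .evaluate import estimate_removal, replicate_concordance
from .normalize import decile_means, normalize_array, scale_m_values
from .ontology import (
    fisher_enrichment,
    load_obo,
    propagate_annotations,
    read_annotations,
    report_tables,
)
from .select import select_regulated

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a reproducible pipeline run needs."""

    arrays_dir: str
    design_map: str              # TSV: array_id, design
    ontology: str
    annotations: str
    out_dir: str
    intensity_floor: float = 1.0
    span: float = 0.3
    robust_iterations: int = 3
    scale_between_arrays: bool = True
    consistency_rule: str = "unanimity"
    criterion4_mode: str = "exclude_extreme"
    criterion4_both: bool = True
    efficiency_top_n: int = 40
    efficiency_summary: str = "median"
    enrichment_cutoff: float = 0.005
    min_term_size: int = 3
    with_bh: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate_paths(self) -> None:
        for name in ("arrays_dir", "design_map", "ontology", "annotations"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise ConfigurationError(f"{name} path does not exist: {p}")


@dataclass
class RunReport:
    """Per-stage counts and results of one pipeline run."""

    config: dict
    version: str = __version__
    stages: dict = field(default_factory=dict)

    def check_consistency(self) -> None:
        """Counts must shrink monotonically through criteria 1 → 4."""
        sel = self.stages.get("selection", {})
        if sel:
            assert sel["n_up"] <= sel["n_up_before_contamination_filter"]
            assert sel["n_up"] + sel["n_up_removed_contamination"] == \
                sel["n_up_before_contamination_filter"]
            assert sel["n_probes_concordant"] <= min(sel["n_probes_called_each"])

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"version": self.version, "config": self.config,
                       "stages": self.stages}, fh, indent=2, default=str)


def _load_scans(config: RunConfig):
    design_map = pd.read_csv(config.design_map, sep="\t")
    scans = []
    for _, row in design_map.iterrows():
        path = Path(config.arrays_dir) / f"{row['array_id']}.tsv"
        scans.append(read_array_table(path, design=row["design"],
                                      array_id=row["array_id"]))
    return scans


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all stages in order; any failure aborts with the stage name."""
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=dataclasses.asdict(config))
    logger.info("effective config: %s", report.config)

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:  # noqa: BLE001 - re-raised with context
                raise StageError(name, exc) from exc
        return wrap

    scans = stage("read")(lambda: _load_scans(config))
    report.stages["read"] = {
        s.array_id: {"design": s.design, "n_probes": s.n_probes} for s in scans}

    def _normalize():
        ma_raw = [ma_transform(s, floor=config.intensity_floor) for s in scans]
        normalized, fits, qc = [], {}, {}
        for ma in ma_raw:
            pre = decile_means(ma)
            norm, fit = normalize_array(ma, span=config.span,
                                        robust_iterations=config.robust_iterations)
            post = decile_means(norm)
            qc[ma.array_id] = {"pre_decile_mean_M": pre["mean_M"].tolist(),
                               "post_decile_mean_M": post["mean_M"].tolist(),
                               "n_low_intensity_dropped": ma.n_low_intensity_dropped}
            fits[ma.array_id] = fit
            normalized.append(norm)
        if config.scale_between_arrays:
            normalized = scale_m_values(normalized)
        for ma in normalized:
            ma.write_tsv(out / f"ma_{ma.array_id}.tsv")
        return normalized, fits, qc

    normalized, fits, qc = stage("normalize")(_normalize)
    report.stages["normalize"] = qc

    def _select():
        reg = tuple(ma for ma in normalized if ma.design == DESIGN_CCCJ_VS_AACJ)
        dep = tuple(ma for ma in normalized if ma.design == DESIGN_CC_VS_CCCJ)
        if len(reg) != 2 or len(dep) != 2:
            raise ConfigurationError(
                f"expected 2 arrays per design, got {len(reg)} regulation and "
                f"{len(dep)} depletion arrays")
        regulated = select_regulated(
            reg, dep, consistency_rule=config.consistency_rule,
            criterion4_mode=config.criterion4_mode,
            criterion4_both=config.criterion4_both)
        regulated.up.to_csv(out / "regulated_up.tsv", sep="\t", index=False)
        regulated.down.to_csv(out / "regulated_down.tsv", sep="\t", index=False)
        regulated.removed_contamination.to_csv(
            out / "excluded_contamination.tsv", sep="\t", index=False)
        pd.DataFrame([
            {"array_id": aid, **vals}
            for aid, vals in regulated.provenance["thresholds"].items()
        ]).to_csv(out / "thresholds.tsv", sep="\t", index=False)
        return regulated, reg, dep

    regulated, reg_ma, dep_ma = stage("select")(_select)
    report.stages["selection"] = {k: v for k, v in regulated.provenance.items()
                                  if k != "thresholds"}

    def _evaluate():
        efficiency = estimate_removal(
            scans, dep_ma, top_n=config.efficiency_top_n,
            summary=config.efficiency_summary, trend_fits=fits)
        efficiency.residual_percent.to_csv(out / "efficiency_residuals.tsv",
                                           sep="\t", index=False)
        # concordance on regulated probes as indicated by the regulation arrays
        reg_genes = set(regulated.up_genes) | set(regulated.down_genes)
        probe_ids = reg_ma[0].table.loc[
            reg_ma[0].table["gene_id"].isin(reg_genes), "probe_id"].tolist()
        concordance = replicate_concordance(scans, probe_ids)
        concordance.pairs.to_csv(out / "concordance.tsv", sep="\t", index=False)
        return efficiency, concordance

    efficiency, concordance = stage("evaluate")(_evaluate)
    report.stages["efficiency"] = {
        "removal_percent": efficiency.removal_percent,
        "summary": efficiency.summary,
        "n_probes": len(efficiency.probe_ids),
        "n_skipped_denominator": efficiency.n_skipped_denominator,
    }
    report.stages["concordance"] = {
        "rho": {f"{r.sample}:{r.array_a}/{r.array_b}": r.rho
                for r in concordance.pairs.itertuples()},
        "n_probes": concordance.probe_subset_size,
    }

    def _enrich():
        dag = load_obo(config.ontology)
        annotations = propagate_annotations(read_annotations(config.annotations), dag)
        universe = set(reg_ma[0].table["gene_id"])
        lists = {
            "up": set(regulated.up_genes) & universe,
            "down": set(regulated.down_genes) & universe,
            "combined": (set(regulated.up_genes) | set(regulated.down_genes)) & universe,
        }
        results = {name: fisher_enrichment(genes, universe, annotations, dag,
                                           min_term_size=config.min_term_size)
                   for name, genes in lists.items()}
        tables = report_tables(results, out, p_cutoff=config.enrichment_cutoff,
                               with_bh=config.with_bh)
        return {name: {"n_significant": int(len(df)),
                       "top_terms": df["GO_ID"].head(5).tolist()}
                for name, df in tables.items()}

    report.stages["enrichment"] = stage("enrich")(_enrich)
    report.check_consistency()
    report.write(out / "run_report.json")
    return report
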