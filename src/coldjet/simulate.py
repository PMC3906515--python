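"""Synthetic co-culture microarray experiment with known ground truth.

The generator emulates the study layout: three RNA samples — astrocytes
cultured alone then cold-jetted (AA-CJ), neuron-astrocyte co-culture (CC),
and co-culture after cold-jet removal of neurons (CC-CJ) — hybridized on
four two-color arrays, two per design (CC-CJ vs AA-CJ; CC vs CC-CJ).

The mixture model: each gene g has an astrocyte abundance and a neuron
abundance.  Co-cultured astrocytes respond to neurons with a log2 effect
β(g) (zero except for the designated astro_up / astro_down genes).  The CC
sample is a mass mixture of astrocyte and neuron RNA with neuronal fraction
c; the cold jet removes a fraction r of the neuronal RNA:

    AA    = astro_alone
    CC    = (1 − c)·astro_cocultured + c·neuron
    CC-CJ = (1 − c)·astro_cocultured + c·(1 − r)·neuron

after which each sample is rescaled to equal total RNA mass, mimicking the
fixed RNA input of array labeling.  Neuron-enriched genes get astrocyte
abundance from the low tail (not zero) so background subtraction in the
efficiency estimator is exercised nontrivially.

Measurement model: per-probe lognormal affinities shared across arrays
(they cancel in M), lognormal channel noise, per-array channel gains, and a
polynomial intensity-dependent dye bias on the red (Cy5) channel — the
curved MA trend the normalization stage must remove.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .arrays import (
    DEFAULT_DYE_MAPS,
    DESIGN_CC_VS_CCCJ,
    DESIGN_CCCJ_VS_AACJ,
    DESIGN_SAMPLES,
    ArrayScan,
)
from .errors import ConfigurationError, InputError

LABEL_NULL = "null"
LABEL_NEURON = "neuron_enriched"
LABEL_ASTRO_UP = "astro_up"
LABEL_ASTRO_DOWN = "astro_down"
LABELS = (LABEL_NEURON, LABEL_ASTRO_UP, LABEL_ASTRO_DOWN, LABEL_NULL)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic co-culture experiment.

    Defaults are the desk-scale study conditions: 10k genes × 2 probes
    (a stand-in for a 4x44K chip), 3% neuron-enriched, 2% astrocyte-up,
    1% astrocyte-down genes, neuronal RNA fraction c = 0.4 in co-culture
    and cold-jet removal efficiency r = 0.9.
    """

    n_genes: int = 10_000
    probes_per_gene: int = 2
    frac_neuron_enriched: float = 0.03
    frac_astro_up: float = 0.02
    frac_astro_down: float = 0.01
    #: central magnitude of regulation effects; |β| ~ U(0.6, 1.4)·effect_size_log2
    effect_size_log2: float = 2.5
    contamination_c: float = 0.4
    removal_r: float = 0.9
    #: red-channel bias b(z) = c0 + c1·z + c2·z² ... on standardized A
    dye_bias_coeffs: tuple[float, ...] = (0.3, -0.15, -0.1)
    noise_sd_log2: float = 0.2
    probe_affinity_sd_log2: float = 0.25
    channel_gain_sd_log2: float = 0.15
    abundance_log2_mean: float = 8.0
    abundance_log2_sd: float = 1.5
    #: location shift (log2) of astrocyte abundance for neuron-enriched genes
    astro_low_tail_log2_offset: float = -3.75
    #: location shift (log2) of neuron abundance for non-enriched genes
    neuron_background_log2_offset: float = -4.0
    #: neuron/astrocyte enrichment ~ U(1.2, 2.2)·effect_size_log2
    total_mass: float | None = None
    n_control_probes: int = 20
    seed: int = 0

    def validate(self) -> None:
        for name in ("frac_neuron_enriched", "frac_astro_up", "frac_astro_down",
                     "contamination_c", "removal_r"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < self.contamination_c < 1.0 and self.contamination_c != 0.0:
            # c = 0 is allowed for degenerate tests; c = 1 (no astrocytes) is not
            raise ConfigurationError(
                f"contamination_c must be in [0, 1), got {self.contamination_c}")
        total = self.frac_neuron_enriched + self.frac_astro_up + self.frac_astro_down
        if total > 1.0 + 1e-12:
            raise ConfigurationError(
                f"frac_neuron_enriched + frac_astro_up + frac_astro_down must be "
                f"<= 1, got {total}")
        if self.n_genes < 1:
            raise ConfigurationError(f"n_genes must be >= 1, got {self.n_genes}")
        if self.probes_per_gene < 1:
            raise ConfigurationError(
                f"probes_per_gene must be >= 1, got {self.probes_per_gene}")
        for name in ("noise_sd_log2", "probe_affinity_sd_log2", "channel_gain_sd_log2"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.effect_size_log2 <= 0:
            raise ConfigurationError(
                f"effect_size_log2 must be positive, got {self.effect_size_log2}")

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class GroundTruth:
    """Simulator truth channel: labels, effects and nuisance factors."""

    gene_ids: np.ndarray
    labels: np.ndarray          # one of LABELS per gene
    log2_effects: np.ndarray    # 0 iff label == null
    contamination_c: float
    removal_r: float
    probe_ids: np.ndarray
    probe_gene_ids: np.ndarray
    probe_affinities: np.ndarray

    def genes_with_label(self, label: str) -> np.ndarray:
        return self.gene_ids[self.labels == label]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "gene_id": self.gene_ids,
            "label": self.labels,
            "log2_effect": self.log2_effects,
        })


@dataclass
class Profiles:
    """Per-gene abundance of the three biological populations."""

    gene_ids: np.ndarray
    astro_alone: np.ndarray
    astro_cocultured: np.ndarray
    neuron: np.ndarray


@dataclass
class Samples:
    """Mixed RNA samples, rescaled to equal total mass."""

    gene_ids: np.ndarray
    aa: np.ndarray      # astrocytes alone (after cold jet)
    cc: np.ndarray      # co-culture
    cccj: np.ndarray    # co-culture after cold jet
    total_mass: float


def _gene_ids(n: int) -> np.ndarray:
    width = max(6, len(str(n)))
    return np.array([f"G{i:0{width}d}" for i in range(1, n + 1)])


def generate_profiles(config: SimulationConfig) -> tuple[Profiles, GroundTruth]:
    """Draw astrocyte/neuron abundance profiles and the truth labels."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    gene_ids = _gene_ids(n)

    n_ne = int(round(config.frac_neuron_enriched * n))
    n_up = int(round(config.frac_astro_up * n))
    n_dn = int(round(config.frac_astro_down * n))
    labels = np.array([LABEL_NULL] * n, dtype=object)
    order = rng.permutation(n)
    idx_ne = order[:n_ne]
    idx_up = order[n_ne:n_ne + n_up]
    idx_dn = order[n_ne + n_up:n_ne + n_up + n_dn]
    labels[idx_ne] = LABEL_NEURON
    labels[idx_up] = LABEL_ASTRO_UP
    labels[idx_dn] = LABEL_ASTRO_DOWN

    mu, sd = config.abundance_log2_mean, config.abundance_log2_sd
    base = rng.normal(mu, sd, size=n)
    # astrocyte abundance: low tail for neuron-enriched genes (not exactly 0)
    astro_log2 = base.copy()
    astro_log2[idx_ne] = rng.normal(mu + config.astro_low_tail_log2_offset,
                                    sd / 2.0, size=n_ne)
    astro_alone = np.exp2(astro_log2)

    effects = np.zeros(n)
    es = config.effect_size_log2
    effects[idx_up] = es * rng.uniform(0.6, 1.4, size=n_up)
    effects[idx_dn] = -es * rng.uniform(0.6, 1.4, size=n_dn)
    # effects for neuron-enriched genes are filled in below; they do not alter
    # the astrocyte response (β = 0 for those genes)
    astro_cocultured = astro_alone * np.exp2(effects)

    neuron_log2 = rng.normal(mu + config.neuron_background_log2_offset, 1.0, size=n)
    enrich = es * rng.uniform(1.2, 2.2, size=n_ne)
    neuron_log2[idx_ne] = astro_log2[idx_ne] + enrich
    effects[idx_ne] = enrich
    neuron = np.exp2(neuron_log2)

    n_probes = n * config.probes_per_gene
    probe_gene_ids = np.repeat(gene_ids, config.probes_per_gene)
    probe_ids = np.array([
        f"{g}_p{j + 1}"
        for g in gene_ids
        for j in range(config.probes_per_gene)
    ])
    affinities = np.exp2(rng.normal(0.0, config.probe_affinity_sd_log2, size=n_probes))

    truth = GroundTruth(
        gene_ids=gene_ids,
        labels=labels,
        log2_effects=effects,
        contamination_c=config.contamination_c,
        removal_r=config.removal_r,
        probe_ids=probe_ids,
        probe_gene_ids=probe_gene_ids,
        probe_affinities=affinities,
    )
    profiles = Profiles(gene_ids=gene_ids, astro_alone=astro_alone,
                        astro_cocultured=astro_cocultured, neuron=neuron)
    return profiles, truth


def mix_samples(profiles: Profiles, truth: GroundTruth,
                config: SimulationConfig) -> Samples:
    """Mix the population profiles into AA, CC and CC-CJ samples by RNA mass.

    Each mixed sample is rescaled to a common total mass (the astrocyte-alone
    mass unless ``config.total_mass`` is set), mimicking equal-RNA labeling.
    """
    c, r = config.contamination_c, config.removal_r
    aa = profiles.astro_alone.astype(float)
    cc = (1.0 - c) * profiles.astro_cocultured + c * profiles.neuron
    cccj = (1.0 - c) * profiles.astro_cocultured + c * (1.0 - r) * profiles.neuron
    target = float(config.total_mass) if config.total_mass else float(aa.sum())
    aa = aa * (target / aa.sum())
    cc = cc * (target / cc.sum())
    cccj = cccj * (target / cccj.sum())
    return Samples(gene_ids=profiles.gene_ids, aa=aa, cc=cc, cccj=cccj,
                   total_mass=target)


def simulate_hybridization(sample_first: np.ndarray, sample_second: np.ndarray,
                           design: str, config: SimulationConfig,
                           truth: GroundTruth, rng: np.random.Generator,
                           array_id: str,
                           dye_map: dict[str, str] | None = None) -> ArrayScan:
    """Hybridize two samples on one two-channel array.

    `sample_first` / `sample_second` are the design's first- and second-named
    samples; the dye map assigns each to red or green.  Per probe, fluorescence
    is affinity·gain·abundance·2^noise, with the polynomial dye bias (in
    standardized noise-free A) applied multiplicatively to the red channel.
    """
    if len(sample_first) != len(sample_second) or len(sample_first) != len(truth.gene_ids):
        raise InputError("sample vectors and gene universe sizes do not match")
    dye_map = dye_map or DEFAULT_DYE_MAPS[design]
    first, second = DESIGN_SAMPLES[design]
    n_probes = len(truth.probe_ids)
    k = config.probes_per_gene
    aff = truth.probe_affinities

    x = np.repeat(sample_first, k) * aff     # first-named sample, per probe
    y = np.repeat(sample_second, k) * aff
    gains = np.exp2(rng.normal(0.0, config.channel_gain_sd_log2, size=2))
    by_dye = {"red": None, "green": None}
    by_dye[dye_map[first]] = x * gains[0]
    by_dye[dye_map[second]] = y * gains[1]
    red0, green0 = by_dye["red"], by_dye["green"]

    with np.errstate(divide="ignore"):
        a0 = 0.5 * np.log2(np.maximum(red0, 1e-300) * np.maximum(green0, 1e-300))
    sd_a = a0.std()
    z = (a0 - a0.mean()) / sd_a if sd_a > 0 else np.zeros_like(a0)
    bias = np.polynomial.polynomial.polyval(z, np.asarray(config.dye_bias_coeffs, float))

    noise = np.exp2(rng.normal(0.0, config.noise_sd_log2, size=(2, n_probes)))
    red = red0 * np.exp2(bias) * noise[0]
    green = green0 * noise[1]

    probes = pd.DataFrame({
        "probe_id": truth.probe_ids,
        "gene_id": truth.probe_gene_ids,
        "red": red,
        "green": green,
    })
    return ArrayScan(array_id=array_id, design=design, probes=probes,
                     dye_map=dict(dye_map))


@dataclass
class Experiment:
    """A complete simulated 4-array experiment plus its truth channel."""

    config: SimulationConfig
    profiles: Profiles
    samples: Samples
    truth: GroundTruth
    scans: list[ArrayScan] = field(default_factory=list)

    def scans_for(self, design: str) -> list[ArrayScan]:
        return [s for s in self.scans if s.design == design]


def simulate_experiment(config: SimulationConfig | None = None,
                        seed: int | None = None) -> Experiment:
    """Generate the full 2+2 array layout with independent per-array noise."""
    config = config or SimulationConfig()
    if seed is not None:
        config = config.replace(seed=seed)
    profiles, truth = generate_profiles(config)
    samples = mix_samples(profiles, truth, config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    scans = [
        simulate_hybridization(samples.cccj, samples.aa, DESIGN_CCCJ_VS_AACJ,
                               config, truth, rng, "array1"),
        simulate_hybridization(samples.cccj, samples.aa, DESIGN_CCCJ_VS_AACJ,
                               config, truth, rng, "array2"),
        simulate_hybridization(samples.cc, samples.cccj, DESIGN_CC_VS_CCCJ,
                               config, truth, rng, "array3"),
        simulate_hybridization(samples.cc, samples.cccj, DESIGN_CC_VS_CCCJ,
                               config, truth, rng, "array4"),
    ]
    return Experiment(config=config, profiles=profiles, samples=samples,
                      truth=truth, scans=scans)


# ---------------------------------------------------------------------------
# Synthetic GO fixture


def make_synthetic_ontology(truth: GroundTruth, rng: np.random.Generator,
                            ) -> tuple[str, pd.DataFrame, dict[str, str]]:
    """Build a small OBO ontology and a gene→term annotation table.

    The astro_up genes are concentrated in ``GO:S000011`` (response to
    neuronal contact), astro_down genes in ``GO:S000021`` (sterol metabolic
    process) and neuron-enriched genes in ``GO:S000031`` (synaptic signaling),
    so the enrichment stage has known positives.  One obsolete term is
    included to exercise the loader's filter.  Returns the OBO text, the
    annotation frame and a map of the designated enriched terms.
    """
    root = ("GO:S000001", "biological process", None)
    mids = [
        ("GO:S000002", "metabolic process", "GO:S000001"),
        ("GO:S000003", "cell communication", "GO:S000001"),
        ("GO:S000004", "transport", "GO:S000001"),
        ("GO:S000005", "developmental process", "GO:S000001"),
    ]
    leaves = [
        ("GO:S000011", "response to neuronal contact", "GO:S000003"),
        ("GO:S000021", "sterol metabolic process", "GO:S000002"),
        ("GO:S000031", "synaptic signaling", "GO:S000003"),
        ("GO:S000012", "cell-matrix adhesion", "GO:S000003"),
        ("GO:S000022", "lipid transport", "GO:S000004"),
        ("GO:S000023", "ion transport", "GO:S000004"),
        ("GO:S000041", "gliogenesis", "GO:S000005"),
        ("GO:S000042", "blood vessel maturation", "GO:S000005"),
        ("GO:S000024", "amino acid metabolic process", "GO:S000002"),
        ("GO:S000043", "response to nutrient levels", "GO:S000005"),
    ]
    lines = ["format-version: 1.2", "ontology: synthetic-go", ""]
    for tid, name, parent in [root, *mids, *leaves]:
        lines += ["[Term]", f"id: {tid}", f"name: {name}",
                  "namespace: biological_process"]
        if parent:
            lines.append(f"is_a: {parent}")
        lines.append("")
    lines += ["[Term]", "id: GO:S000099", "name: retired process",
              "namespace: biological_process", "is_obsolete: true", ""]
    obo_text = "\n".join(lines)

    genes = truth.gene_ids
    rows: list[tuple[str, str]] = []
    leaf_ids = [t[0] for t in leaves]
    background = {tid: rng.choice(genes, size=max(3, int(0.04 * len(genes))),
                                  replace=False)
                  for tid in leaf_ids}
    for tid, members in background.items():
        rows += [(g, tid) for g in members]
    enriched = {"astro_up": "GO:S000011", "astro_down": "GO:S000021",
                "neuron_enriched": "GO:S000031"}
    for label, tid in enriched.items():
        members = truth.genes_with_label(label)
        take = members[rng.random(len(members)) < 0.5]
        rows += [(g, tid) for g in take]
    ann = pd.DataFrame(rows, columns=["gene_id", "term_id"]).drop_duplicates()
    ann = ann.sort_values(["gene_id", "term_id"]).reset_index(drop=True)
    return obo_text, ann, enriched


# ---------------------------------------------------------------------------
# Fixture I/O

ARRAY_FILES = ("array1.tsv", "array2.tsv", "array3.tsv", "array4.tsv")


def write_experiment(out_dir, config: SimulationConfig | None = None,
                     experiment: Experiment | None = None) -> dict[str, Path]:
    """Write the four array tables, design map, truth and GO fixtures.

    Control probes (random fluorescence, ``is_control = 1``) are appended to
    each array file; readers drop them, so read-back reproduces the in-memory
    scans exactly.
    """
    out = Path(out_dir)
    if experiment is None:
        experiment = simulate_experiment(config)
    config = experiment.config
    (out / "arrays").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))

    paths: dict[str, Path] = {}
    for fname, scan in zip(ARRAY_FILES, experiment.scans):
        table = scan.probes.copy()
        table["is_control"] = 0
        if config.n_control_probes:
            ctrl = pd.DataFrame({
                "probe_id": [f"CTRL_{i:03d}" for i in range(config.n_control_probes)],
                "gene_id": "control",
                "red": rng.uniform(10, 1000, size=config.n_control_probes),
                "green": rng.uniform(10, 1000, size=config.n_control_probes),
                "is_control": 1,
            })
            table = pd.concat([table, ctrl], ignore_index=True)
        path = out / "arrays" / fname
        table.to_csv(path, sep="\t", index=False)
        paths[scan.array_id] = path

    design_map = pd.DataFrame({
        "array_id": [s.array_id for s in experiment.scans],
        "design": [s.design for s in experiment.scans],
    })
    paths["design_map"] = out / "design_map.tsv"
    design_map.to_csv(paths["design_map"], sep="\t", index=False)

    paths["truth"] = out / "truth.tsv"
    experiment.truth.to_frame().to_csv(paths["truth"], sep="\t", index=False)

    obo_text, ann, _ = make_synthetic_ontology(experiment.truth, rng)
    paths["ontology"] = out / "ontology.obo"
    paths["ontology"].write_text(obo_text)
    paths["annotations"] = out / "annotations.tsv"
    ann.to_csv(paths["annotations"], sep="\t", index=False)

    paths["config"] = out / "simulation_config.txt"
    with open(paths["config"], "w") as fh:
        for f in dataclasses.fields(config):
            v = getattr(config, f.name)
            if isinstance(v, tuple):
                v = ",".join(str(x) for x in v)
            fh.write(f"{f.name} = {v}\n")
    return paths


def read_simulation_config(path) -> SimulationConfig:
    """Parse a flat ``key = value`` config file into a SimulationConfig."""
    kwargs: dict[str, object] = {}
    fields = {f.name: f for f in dataclasses.fields(SimulationConfig)}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigurationError(f"cannot parse config line: {raw!r}")
        key, value = (s.strip() for s in line.split("=", 1))
        if key not in fields:
            raise ConfigurationError(f"unknown config field {key!r}")
        if key == "dye_bias_coeffs":
            kwargs[key] = tuple(float(x) for x in value.split(",") if x.strip())
        elif key in ("n_genes", "probes_per_gene", "seed", "n_control_probes"):
            kwargs[key] = int(value)
        elif key == "total_mass":
            kwargs[key] = None if value in ("None", "") else float(value)
        else:
            kwargs[key] = float(value)
    config = SimulationConfig(**kwargs)
    config.validate()
    return config
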