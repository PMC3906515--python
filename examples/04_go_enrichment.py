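"""GO biological-process overrepresentation of a regulated gene list.

Annotations are propagated up the is_a DAG (true-path rule) and each term
is scored with a one-sided Fisher exact test against the chip universe.
"""

import numpy as np

from coldjet import SimulationConfig, generate_profiles
from coldjet.ontology import (
    AnnotationMap,
    fisher_enrichment,
    load_obo,
    propagate_annotations,
    results_frame,
)
from coldjet.simulate import make_synthetic_ontology

config = SimulationConfig(n_genes=2000, seed=42)
profiles, truth = generate_profiles(config)
obo_text, annotations, enriched_terms = make_synthetic_ontology(
    truth, np.random.default_rng(0))

import tempfile, pathlib

with tempfile.TemporaryDirectory() as tmp:
    obo_path = pathlib.Path(tmp) / "go.obo"
    obo_path.write_text(obo_text)
    dag = load_obo(obo_path)

ann = propagate_annotations(
    AnnotationMap({g: set(grp["term_id"])
                   for g, grp in annotations.groupby("gene_id")}), dag)

universe = set(truth.gene_ids)
study = set(truth.genes_with_label("astro_up"))
results = fisher_enrichment(study, universe, ann, dag)
print(results_frame(results).head(5).to_string(index=False))
print(f"\nthe designated up-enriched term is {enriched_terms['astro_up']} — "
      "it should top the table with p far below the 0.005 screen")
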