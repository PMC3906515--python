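"""GO biological-process overrepresentation via one-sided Fisher's exact test.

The ontology is an ``is_a`` DAG; annotations follow the true-path rule
(a gene annotated to a term is annotated to all of its ancestors), so
annotation sets are propagated before testing.  Each term with enough
annotated genes in the universe gets a one-sided overrepresentation
p-value from the hypergeometric tail of its 2×2 table — classic per-term
Fisher scoring, without DAG-decorrelation heuristics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import obonet
import pandas as pd
from scipy.stats import hypergeom

from .errors import FormatError, InputError

logger = logging.getLogger(__name__)


@dataclass
class OntologyDAG:
    """Terms and is_a edges (child → parent) of an ontology subset."""

    graph: nx.DiGraph
    n_obsolete_dropped: int = 0

    @property
    def terms(self) -> list[str]:
        return sorted(self.graph.nodes)

    def name(self, term: str) -> str:
        return self.graph.nodes[term].get("name", term)

    def ancestors(self, term: str) -> set[str]:
        """All is_a ancestors of a term (excluding the term itself)."""
        if term not in self.graph:
            raise InputError(f"unknown term {term!r}")
        return set(nx.descendants(self.graph, term))


@dataclass
class AnnotationMap:
    """gene → set of term ids, optionally closed under the true-path rule."""

    gene_terms: dict[str, set[str]]
    propagated: bool = False

    def term_genes(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for gene, terms in self.gene_terms.items():
            for t in terms:
                out.setdefault(t, set()).add(gene)
        return out


@dataclass
class EnrichmentResult:
    term_id: str
    term_name: str
    annotated_in_universe: int
    annotated_in_study: int
    expected: float
    p_value: float


def load_obo(path) -> OntologyDAG:
    """Parse an OBO 1.2 file into an is_a DAG; obsolete terms are dropped."""
    full = obonet.read_obo(path, ignore_obsolete=False)
    obsolete = [n for n, d in full.nodes(data=True)
                if str(d.get("is_obsolete", "")).lower() == "true"]
    if obsolete:
        logger.info("dropping %d obsolete terms", len(obsolete))
    graph = nx.DiGraph()
    for node, data in full.nodes(data=True):
        if node in obsolete:
            continue
        graph.add_node(node, name=data.get("name", node),
                       namespace=data.get("namespace", ""))
    for child, parent, key in full.edges(keys=True):
        if key != "is_a" or child in obsolete or parent in obsolete:
            continue
        if parent not in graph:
            raise FormatError(f"is_a target {parent!r} is not a known term")
        graph.add_edge(child, parent)
    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        raise FormatError(f"ontology contains an is_a cycle: {cycle}")
    return OntologyDAG(graph=graph, n_obsolete_dropped=len(obsolete))


def read_annotations(path) -> AnnotationMap:
    """Read a two-column TSV (gene_id, term_id) into an unpropagated map."""
    df = pd.read_csv(path, sep="\t")
    for col in ("gene_id", "term_id"):
        if col not in df.columns:
            raise FormatError(f"annotation table {path} is missing column {col!r}")
    gene_terms: dict[str, set[str]] = {}
    for gene, term in zip(df["gene_id"], df["term_id"]):
        gene_terms.setdefault(str(gene), set()).add(str(term))
    return AnnotationMap(gene_terms=gene_terms, propagated=False)


def propagate_annotations(annotations: AnnotationMap,
                          dag: OntologyDAG) -> AnnotationMap:
    """Close each gene's term set under is_a ancestry (idempotent)."""
    # cache ancestor sets per term; annotation tables reuse few distinct terms
    ancestor_cache: dict[str, set[str]] = {}
    out: dict[str, set[str]] = {}
    for gene, terms in annotations.gene_terms.items():
        closed: set[str] = set()
        for t in terms:
            if t not in dag.graph:
                logger.warning("annotation of %s to unknown term %s dropped",
                               gene, t)
                continue
            if t not in ancestor_cache:
                ancestor_cache[t] = dag.ancestors(t) | {t}
            closed |= ancestor_cache[t]
        if closed:
            out[gene] = closed
    return AnnotationMap(gene_terms=out, propagated=True)


def fisher_enrichment(study: set[str], universe: set[str],
                      annotations: AnnotationMap,
                      dag: OntologyDAG | None = None,
                      min_term_size: int = 3) -> list[EnrichmentResult]:
    """Score each term's overrepresentation in the study set.

    The 2×2 table per term is (study∩term, study∖term, term∖study, rest);
    the one-sided p-value is the upper hypergeometric tail
    P(X ≥ observed overlap).  Terms with fewer than `min_term_size`
    annotated universe genes are skipped.  Results are sorted by p-value,
    ties broken by term id.
    """
    study, universe = set(study), set(universe)
    offenders = study - universe
    if offenders:
        raise InputError(
            f"study genes not in universe: {sorted(offenders)[:10]}"
            + (" ..." if len(offenders) > 10 else ""))
    if not annotations.propagated:
        logger.warning("annotation map is not propagated; term counts will "
                       "ignore the true-path rule")
    n_universe = len(universe)
    n_study = len(study)
    results: list[EnrichmentResult] = []
    for term, genes in annotations.term_genes().items():
        in_universe = genes & universe
        k_universe = len(in_universe)
        if k_universe < min_term_size:
            continue
        k_study = len(in_universe & study)
        p = float(hypergeom.sf(k_study - 1, n_universe, k_universe, n_study))
        results.append(EnrichmentResult(
            term_id=term,
            term_name=dag.name(term) if dag and term in dag.graph else term,
            annotated_in_universe=k_universe,
            annotated_in_study=k_study,
            expected=n_study * k_universe / n_universe,
            p_value=min(p, 1.0),
        ))
    results.sort(key=lambda r: (r.p_value, r.term_id))
    return results


def results_frame(results: list[EnrichmentResult],
                  with_bh: bool = False) -> pd.DataFrame:
    """Tabulate results as (GO_ID, GO_term, annotated, in_study, expected, p)."""
    df = pd.DataFrame([{
        "GO_ID": r.term_id,
        "GO_term": r.term_name,
        "annotated": r.annotated_in_universe,
        "in_study": r.annotated_in_study,
        "expected": r.expected,
        "p_value": r.p_value,
    } for r in results])
    if with_bh and len(df):
        from statsmodels.stats.multitest import multipletests

        # Benjamini-Hochberg column is an extra convenience, not part of the
        # screening rule (which uses raw p-values)
        df["bh_fdr"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df


def report_tables(results_by_list: dict[str, list[EnrichmentResult]],
                  out_dir, p_cutoff: float = 0.005,
                  with_bh: bool = False) -> dict[str, pd.DataFrame]:
    """Write one TSV per gene list with rows passing the raw-p screen."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables: dict[str, pd.DataFrame] = {}
    for name, results in results_by_list.items():
        df = results_frame(results, with_bh=with_bh)
        if len(df):
            df = df[df["p_value"] < p_cutoff].reset_index(drop=True)
        else:
            df = pd.DataFrame(columns=["GO_ID", "GO_term", "annotated",
                                       "in_study", "expected", "p_value"])
        df.to_csv(out / f"go_{name}.tsv", sep="\t", index=False)
        tables[name] = df
    return tables
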