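"""Hypergeometric GO-term enrichment with true-path annotation propagation.

Annotations are propagated up the is_a DAG (a gene annotated to a term is
annotated to every ancestor), terms with fewer than ``node_size_floor``
background-restricted genes are dropped (the topGO nodeSize convention),
and each remaining term is scored by the one-sided upper-tail
hypergeometric (Fisher) test of study hits against the background.  The
default mode is the classic Fisher test; an optional "elim" mode removes
the genes of significantly enriched terms from their ancestors before the
ancestors are tested, decorrelating nested terms.

The background for the dosage analysis is the *union* of genes passing the
detection filter in any of the three pairwise comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .dosage_classifier import DosageCallSet
from .errors import OntologyError, ParameterError, ValidationError

logger = logging.getLogger(__name__)

NODE_SIZE_FLOOR = 10
ELIM_P_CUTOFF = 0.01


@dataclass
class OntologyGraph:
    """An is_a DAG of terms with (direct or propagated) gene annotations.

    ``graph`` edges point child -> parent.  ``annotations`` maps term_id to
    the set of directly annotated genes; after :func:`propagate_annotations`
    each term also carries its descendants' genes.
    """

    graph: nx.DiGraph
    annotations: dict[str, set[str]]
    propagated: bool = False

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            raise OntologyError(f"ontology contains a cycle through edge {cycle[0]}")
        unknown = set(self.annotations) - set(self.graph.nodes)
        if unknown:
            raise OntologyError(f"annotated terms missing from graph: {sorted(unknown)[:5]}")

    @property
    def terms(self) -> list[str]:
        return list(self.graph.nodes)

    def term_name(self, term: str) -> str:
        return self.graph.nodes[term].get("name", term)

    @classmethod
    def from_obo(cls, obo_path: str, annotation_table: pd.DataFrame) -> "OntologyGraph":
        """Read an OBO file (is_a edges only) plus a (gene_id, term_id) table."""
        import obonet

        g = obonet.read_obo(obo_path)
        dag = nx.DiGraph()
        dag.add_nodes_from(
            (n, {"name": d.get("name", n), "namespace": d.get("namespace", "")})
            for n, d in g.nodes(data=True)
        )
        for child, parent, key in g.edges(keys=True):
            if key == "is_a":
                dag.add_edge(child, parent)
        ann: dict[str, set[str]] = {}
        for r in annotation_table.itertuples(index=False):
            gene, term = str(r[0]), str(r[1])
            if term not in dag.nodes:
                logger.warning("annotation to unknown term %s skipped", term)
                continue
            ann.setdefault(term, set()).add(gene)
        return cls(graph=dag, annotations=ann)


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-term Fisher enrichment of one study set against a background."""

    table: pd.DataFrame  # term_id, name, study_hits, study_size, term_background, background_size, odds_ratio, p_fisher, p_adjusted
    node_size_floor: int
    background_description: str


def propagate_annotations(graph: OntologyGraph) -> OntologyGraph:
    """True-path propagation: each term inherits its descendants' genes.

    Processing terms in topological order of the child->parent DAG pushes
    every gene up to all ancestors in one pass; the operation is idempotent.
    """
    ann = {t: set(g) for t, g in graph.annotations.items()}
    for node in nx.topological_sort(graph.graph):
        genes = ann.get(node)
        if not genes:
            continue
        for parent in graph.graph.successors(node):
            ann.setdefault(parent, set()).update(genes)
    return OntologyGraph(graph=graph.graph, annotations=ann, propagated=True)


def _hypergeom_upper(hits: int, study: int, term_bg: int, bg: int) -> float:
    # P(X >= hits) for X ~ Hypergeom(bg, term_bg, study)
    return float(stats.hypergeom.sf(hits - 1, bg, term_bg, study))


def _odds_ratio(hits: int, study: int, term_bg: int, bg: int) -> float:
    a = hits
    b = study - hits
    c = term_bg - hits
    d = bg - study - c
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return float((a * d) / (b * c))


def fisher_enrich(
    study: set[str],
    background: set[str],
    graph: OntologyGraph,
    node_size_floor: int = NODE_SIZE_FLOOR,
    mode: str = "classic",
    elim_p: float = ELIM_P_CUTOFF,
) -> EnrichmentResult:
    """Fisher (upper-tail hypergeometric) enrichment over ontology terms.

    Tests every term whose background-restricted annotation count reaches
    ``node_size_floor``; Bonferroni-adjusts over the tested terms.  In
    "elim" mode terms are visited leaves-first and the genes of terms with
    raw p below ``elim_p`` are excluded from their ancestors' tables.
    """
    if mode not in ("classic", "elim"):
        raise ParameterError(f"unknown enrichment mode {mode!r}")
    if node_size_floor < 1:
        raise ParameterError("node_size_floor must be >= 1")
    if not background:
        raise ValidationError("background set is empty")
    stray = set(study) - set(background)
    if stray:
        raise ValidationError(f"study genes absent from background: {sorted(stray)[:5]}")
    if not graph.propagated:
        graph = propagate_annotations(graph)

    study, background = set(study), set(background)
    bg_n, study_n = len(background), len(study)
    term_bg_genes = {
        t: graph.annotations.get(t, set()) & background for t in graph.terms
    }
    testable = [t for t in graph.terms if len(term_bg_genes[t]) >= node_size_floor]
    testable_set = set(testable)

    removed: dict[str, set[str]] = {t: set() for t in testable}
    order = (
        list(nx.topological_sort(graph.graph)) if mode == "elim" else testable
    )
    rows = []
    for term in order:
        if term not in testable_set:
            continue
        bg_genes = term_bg_genes[term] - removed.get(term, set())
        term_bg = len(bg_genes)
        if term_bg < node_size_floor:
            continue
        hits_genes = bg_genes & study
        p = _hypergeom_upper(len(hits_genes), study_n, term_bg, bg_n)
        rows.append(
            {
                "term_id": term,
                "name": graph.term_name(term),
                "study_hits": len(hits_genes),
                "study_size": study_n,
                "term_background": term_bg,
                "background_size": bg_n,
                "odds_ratio": _odds_ratio(len(hits_genes), study_n, term_bg, bg_n),
                "p_fisher": p,
            }
        )
        if mode == "elim" and p < elim_p:
            for anc in nx.descendants(graph.graph, term):  # ancestors in child->parent DAG
                removed.setdefault(anc, set()).update(bg_genes)

    df = pd.DataFrame(
        rows,
        columns=[
            "term_id", "name", "study_hits", "study_size", "term_background",
            "background_size", "odds_ratio", "p_fisher",
        ],
    )
    m = len(df)
    df["p_adjusted"] = np.minimum(1.0, df["p_fisher"] * m) if m else []
    df = df.sort_values(["p_fisher", "term_id"]).reset_index(drop=True)
    return EnrichmentResult(
        table=df,
        node_size_floor=node_size_floor,
        background_description=f"{bg_n} genes",
    )


def enrich_linear_sets(
    calls: DosageCallSet,
    background: set[str],
    graph: OntologyGraph,
    node_size_floor: int = NODE_SIZE_FLOOR,
    mode: str = "classic",
) -> tuple[EnrichmentResult, EnrichmentResult]:
    """Enrich the linear-up and linear-down gene sets separately.

    Both sets are tested against the same background — the union of genes
    analyzable in any of the three pairwise comparisons.
    """
    results = []
    for call in ("linear_up", "linear_down"):
        genes = set(calls.genes_with_call(call))
        if not genes:
            logger.warning("no %s genes; enrichment result is empty", call)
            empty = pd.DataFrame(
                columns=[
                    "term_id", "name", "study_hits", "study_size", "term_background",
                    "background_size", "odds_ratio", "p_fisher", "p_adjusted",
                ]
            )
            results.append(
                EnrichmentResult(
                    table=empty,
                    node_size_floor=node_size_floor,
                    background_description=f"{len(background)} genes",
                )
            )
            continue
        results.append(
            fisher_enrich(genes, background, graph, node_size_floor, mode=mode)
        )
    return results[0], results[1]
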