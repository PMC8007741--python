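"""Minimal gene-ontology support: OBO subset parsing, descendant closures,
GO gene filters, and Fisher-exact enrichment with BH correction.

Only ``is_a`` edges are honored.  A GO filter for a target term collects
every transcript annotated to the term or to any of its descendant
(child) terms — the same closure logic used to build e.g. an "oogenesis"
or "RNA metabolic process" transcript set from an annotated reference.

Enrichment is the classic one-sided (over-representation) per-term Fisher
exact test against a GO-annotated universe, BH-corrected across terms.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import obonet
import pandas as pd
from scipy.stats import hypergeom

from .de import bh_adjust


@dataclass
class OntologyGraph:
    """is_a DAG of terms. Edges run child -> parent (obonet convention)."""

    graph: nx.DiGraph

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    def name(self, term: str) -> str:
        return self.graph.nodes[term].get("name", term)

    def __contains__(self, term: str) -> bool:
        return term in self.graph


AnnotationMap = Mapping[str, frozenset]


def parse_obo(path: str | Path, strict: bool = True) -> OntologyGraph:
    """Parse an OBO subset ([Term], id, name, is_a stanzas).

    strict=True raises on is_a references to undeclared terms; otherwise
    they are auto-declared (nameless).  Cycles always raise.
    """
    path = Path(path)
    if path.stat().st_size == 0 or not path.read_text().strip():
        import warnings

        warnings.warn(f"empty ontology file: {path}")
        return OntologyGraph(nx.DiGraph())
    multigraph = obonet.read_obo(path, ignore_obsolete=True)
    graph = nx.DiGraph()
    graph.add_nodes_from(multigraph.nodes(data=True))
    declared = {n for n, d in multigraph.nodes(data=True) if "name" in d or True}
    for child, parent, key in multigraph.edges(keys=True):
        if key != "is_a":
            continue
        if strict and parent not in declared:
            raise ValueError(f"is_a references undeclared term: {parent}")
        graph.add_edge(child, parent)
    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        raise ValueError(f"ontology contains a cycle: {cycle}")
    return OntologyGraph(graph)


def write_obo(graph: OntologyGraph, path: str | Path) -> None:
    lines = ["format-version: 1.2", "ontology: go-subset", ""]
    for term in sorted(graph.graph.nodes):
        lines.append("[Term]")
        lines.append(f"id: {term}")
        name = graph.graph.nodes[term].get("name")
        if name:
            lines.append(f"name: {name}")
        for _, parent in sorted(graph.graph.out_edges(term)):
            lines.append(f"is_a: {parent} ! {graph.graph.nodes[parent].get('name', '')}")
        lines.append("")
    Path(path).write_text("\n".join(lines))


def descendant_closure(graph: OntologyGraph, term: str) -> frozenset:
    """The term plus all terms reachable against is_a edges (its children,
    transitively)."""
    if term not in graph:
        raise KeyError(f"unknown term: {term}")
    # edges run child -> parent, so descendants are nx 'ancestors'
    return frozenset(nx.ancestors(graph.graph, term)) | {term}


def go_filter_transcripts(
    annotation: AnnotationMap, graph: OntologyGraph, term: str
) -> frozenset:
    """Transcripts annotated to the term or any descendant term."""
    closure = descendant_closure(graph, term)
    return frozenset(t for t, terms in annotation.items() if terms & closure)


def propagate_annotations(
    annotation: AnnotationMap, graph: OntologyGraph
) -> dict[str, frozenset]:
    """Extend each transcript's terms with all ancestors (standard GO
    true-path convention)."""
    anc_cache: dict[str, frozenset] = {}

    def ancestors(term: str) -> frozenset:
        if term not in anc_cache:
            if term in graph:
                anc_cache[term] = frozenset(nx.descendants(graph.graph, term)) | {term}
            else:
                anc_cache[term] = frozenset({term})
        return anc_cache[term]

    return {
        t: frozenset().union(*(ancestors(term) for term in terms)) if terms else frozenset()
        for t, terms in annotation.items()
    }


def fisher_enrichment(
    study_set: Iterable[str],
    universe: Iterable[str],
    annotation: AnnotationMap,
    graph: OntologyGraph,
    alpha: float = 0.05,
    propagate: bool = True,
) -> pd.DataFrame:
    """Per-term over-representation test of the study set within the universe.

    One-sided hypergeometric upper-tail p for the 2x2 table
    (study∩term, study∖term, universe∩term∖study, rest), BH-adjusted across
    all terms with >=1 universe annotation.  ``enriched`` flags adjusted
    p <= alpha.  This is the classic per-term Fisher test; results are
    labeled classic-Fisher (no decorrelation across the DAG).
    """
    study = set(study_set)
    univ = set(universe)
    if not univ:
        raise ValueError("empty universe")
    if not study <= univ:
        raise ValueError("study set must be contained in the universe")

    ann = {t: annotation.get(t, frozenset()) for t in univ}
    if propagate:
        ann = propagate_annotations(ann, graph)

    term_to_universe: dict[str, int] = {}
    term_to_study: dict[str, int] = {}
    for t, terms in ann.items():
        in_study = t in study
        for term in terms:
            term_to_universe[term] = term_to_universe.get(term, 0) + 1
            if in_study:
                term_to_study[term] = term_to_study.get(term, 0) + 1

    rows = []
    n_univ, n_study = len(univ), len(study)
    for term in sorted(term_to_universe):
        k_univ = term_to_universe[term]
        k_study = term_to_study.get(term, 0)
        # P(X >= k_study), X ~ Hypergeom(N=n_univ, K=k_univ, n=n_study)
        p = float(hypergeom.sf(k_study - 1, n_univ, k_univ, n_study))
        rows.append((term, graph.name(term) if term in graph else term, k_study, k_univ, min(p, 1.0)))
    table = pd.DataFrame(
        rows, columns=["term", "name", "study_count", "universe_count", "p"]
    ).set_index("term")
    table["fdr"] = bh_adjust(table["p"].to_numpy())
    table["enriched"] = table["fdr"] <= alpha
    table.attrs["method"] = "classic-Fisher"
    return table


def write_enrichment(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index_label="term")


def write_transcript_list(ids: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(ids)) + "\n")
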