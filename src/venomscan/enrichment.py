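"""GO-term enrichment of the venom set against the transcriptome background.

Annotations are first propagated up the is_a DAG (true-path rule: a gene
annotated to a term is implicitly annotated to every ancestor). Each term is
then tested for over-representation in the venom (test) set against the whole
transcriptome (reference) with a one-sided Fisher's exact test, the p-values
are Benjamini-Hochberg adjusted, and the significant terms are reduced to the
most specific ones by discarding any enriched term that is a proper ancestor
of another enriched term.

Ontologies are held as networkx DiGraphs with child -> parent ``is_a`` edges
(the orientation obonet produces); only ``is_a`` semantics are interpreted.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import obonet
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_ALPHA = 0.05


class EnrichmentError(ValueError):
    pass


def load_ontology(path: str | Path) -> nx.DiGraph:
    """Read an OBO file, keeping only is_a edges (child -> parent)."""
    multi = obonet.read_obo(str(path))
    g = nx.DiGraph()
    g.add_nodes_from((n, d) for n, d in multi.nodes(data=True))
    for u, v, key in multi.edges(keys=True):
        if key == "is_a":
            g.add_edge(u, v)
    if not nx.is_directed_acyclic_graph(g):
        raise EnrichmentError("ontology is_a graph is cyclic")
    return g


def term_ancestors(ontology: nx.DiGraph, term: str) -> set[str]:
    """Proper ancestors of a term along is_a (child -> parent reachability)."""
    return nx.descendants(ontology, term)


def term_depth(ontology: nx.DiGraph, term: str) -> int:
    """Longest is_a path from the term up to a root."""
    depth = 0
    frontier = {term}
    while True:
        nxt = {p for t in frontier for p in ontology.successors(t)}
        if not nxt:
            return depth
        depth += 1
        frontier = nxt


def propagate_annotations(
    ontology: nx.DiGraph, direct: Mapping[str, Iterable[str]]
) -> dict[str, set[str]]:
    """True-path closure: annotate each gene to all ancestors of its terms."""
    unknown = sorted(
        {t for terms in direct.values() for t in terms if t not in ontology}
    )
    if unknown:
        raise EnrichmentError(f"unknown ontology terms: {unknown}")
    cache: dict[str, set[str]] = {}

    def closure(term: str) -> set[str]:
        if term not in cache:
            cache[term] = {term} | term_ancestors(ontology, term)
        return cache[term]

    return {
        gene: set().union(*(closure(t) for t in terms)) if terms else set()
        for gene, terms in direct.items()
    }


def fisher_enrichment(
    test_genes: Iterable[str],
    reference_genes: Iterable[str],
    term: str,
    annotations: Mapping[str, set[str]],
) -> float:
    """One-sided (over-representation) Fisher's exact p for one term.

    The 2x2 table splits the reference set into the test set and the rest:
    (test with term, test without, rest with term, rest without). Requires
    test to be a subset of reference.
    """
    test = set(test_genes)
    reference = set(reference_genes)
    if not test <= reference:
        raise EnrichmentError("test set must be a subset of the reference set")
    k = sum(1 for g in test if term in annotations.get(g, ()))
    K = sum(1 for g in reference if term in annotations.get(g, ()))
    # hypergeometric upper tail: P(X >= k) drawing len(test) from the reference
    return float(stats.hypergeom.sf(k - 1, len(reference), K, len(test)))


def bh_fdr(p_values: Iterable[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted values (monotone, capped at 1)."""
    p = list(p_values)
    if not p:
        return []
    if any(not (0 < x <= 1) for x in p):
        raise EnrichmentError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


def reduce_to_most_specific(
    terms: Iterable[str], ontology: nx.DiGraph
) -> set[str]:
    """Drop every term that is a proper ancestor of another term in the set."""
    terms = set(terms)
    ancestors_of_any = set()
    for t in terms:
        ancestors_of_any |= term_ancestors(ontology, t)
    return terms - ancestors_of_any


def enrich(
    test_genes: Iterable[str],
    reference_genes: Iterable[str],
    direct_annotations: Mapping[str, Iterable[str]],
    ontology: nx.DiGraph,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Term-by-term enrichment table with BH-FDR and most-specific reduction.

    Every term annotated (after propagation) to at least one test gene is
    tested. Columns: term, name, depth, n_test_with, n_test, n_ref_with,
    n_ref, p_value, fdr, enriched (fdr < alpha), most_specific (enriched and
    not an ancestor of another enriched term).
    """
    test = sorted(set(test_genes))
    reference = sorted(set(reference_genes))
    annotations = propagate_annotations(
        ontology, {g: set(direct_annotations.get(g, ())) for g in reference}
    )
    terms = sorted({t for g in test for t in annotations.get(g, ())})
    rows = []
    for term in terms:
        p = fisher_enrichment(test, reference, term, annotations)
        rows.append(
            {
                "term": term,
                "name": ontology.nodes[term].get("name", ""),
                "depth": term_depth(ontology, term),
                "n_test_with": sum(1 for g in test if term in annotations[g]),
                "n_test": len(test),
                "n_ref_with": sum(1 for g in reference if term in annotations[g]),
                "n_ref": len(reference),
                "p_value": p,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "term", "name", "depth", "n_test_with", "n_test",
            "n_ref_with", "n_ref", "p_value",
        ],
    )
    if df.empty:
        df["fdr"] = []
        df["enriched"] = []
        df["most_specific"] = []
        return df
    df["fdr"] = bh_fdr(df["p_value"])
    df["enriched"] = df["fdr"] < alpha
    specific = reduce_to_most_specific(df.loc[df["enriched"], "term"], ontology)
    df["most_specific"] = df["term"].isin(specific) & df["enriched"]
    return df.sort_values(["fdr", "term"], kind="mergesort").reset_index(drop=True)
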