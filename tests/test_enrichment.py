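"""Annotation propagation, Fisher enrichment, BH-FDR, term reduction."""

import math

import networkx as nx
import numpy as np
import pytest

from venomscan import (
    bh_fdr,
    enrich,
    fisher_enrichment,
    propagate_annotations,
    reduce_to_most_specific,
)
from venomscan.enrichment import EnrichmentError, load_ontology, term_depth
from venomscan.synthetic import ontology_to_obo, synthetic_ontology


def _chain():
    g = nx.DiGraph()
    g.add_edge("child", "parent")
    g.add_edge("parent", "root")
    return g


def _diamond():
    g = _chain()
    g.add_edge("child", "parent2")
    g.add_edge("parent2", "root")
    return g


def test_propagation_closure():
    full = propagate_annotations(_chain(), {"g1": {"child"}, "g2": {"root"}})
    assert full["g1"] == {"child", "parent", "root"}
    assert full["g2"] == {"root"}


def test_propagation_diamond_counts_shared_ancestor_once():
    full = propagate_annotations(_diamond(), {"g": {"child"}})
    assert full["g"] == {"child", "parent", "parent2", "root"}


def test_propagation_rejects_unknown_terms():
    with pytest.raises(EnrichmentError, match="bogus"):
        propagate_annotations(_chain(), {"g": {"bogus"}})


def _hypergeom_tail(k, N, K, n):
    """Independent oracle: exact upper-tail sum via binomial coefficients."""
    total = math.comb(N, n)
    return sum(
        math.comb(K, x) * math.comb(N - K, n - x)
        for x in range(k, min(K, n) + 1)
        if n - x <= N - K
    ) / total


def test_fisher_trivial_cases():
    g = _chain()
    annotations = {f"g{i}": set() for i in range(10)}
    test = [f"g{i}" for i in range(3)]
    # term absent everywhere -> p = 1
    assert fisher_enrichment(test, list(annotations), "child", annotations) == 1.0
    # test == reference -> p = 1 for any term
    annotations["g0"] = {"child"}
    ids = list(annotations)
    assert fisher_enrichment(ids, ids, "child", annotations) == pytest.approx(1.0)
    with pytest.raises(EnrichmentError):
        fisher_enrichment(["zz"], ids, "child", annotations)


def test_fisher_matches_exhaustive_hypergeometric():
    for N in (5, 8, 12):
        for n in range(1, N + 1):
            for K in range(0, N + 1):
                for k in range(0, min(n, K) + 1):
                    annotations = {}
                    with_term = [f"t{i}" for i in range(k)] + [
                        f"r{i}" for i in range(K - k)
                    ]
                    test = [f"t{i}" for i in range(k)] + [
                        f"u{i}" for i in range(n - k)
                    ]
                    rest = [f"r{i}" for i in range(K - k)] + [
                        f"v{i}" for i in range(N - n - (K - k))
                    ]
                    if len(rest) + len(test) != N:
                        continue
                    reference = test + rest
                    annotations = {g: {"T"} if g in with_term else set() for g in reference}
                    p = fisher_enrichment(test, reference, "T", annotations)
                    assert p == pytest.approx(_hypergeom_tail(k, N, K, n), rel=1e-9)


def test_bh_adjustment():
    assert bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])
    assert bh_fdr([0.04]) == pytest.approx([0.04])
    assert bh_fdr([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])
    out = bh_fdr(list(np.random.default_rng(0).uniform(0.001, 1, size=50)))
    ordered = sorted(out)
    assert all(b <= 1 for b in out)
    assert ordered == sorted(ordered)
    with pytest.raises(EnrichmentError):
        bh_fdr([0.0, 0.5])
    assert bh_fdr([]) == []


def test_reduce_to_most_specific():
    g = _chain()
    assert reduce_to_most_specific({"parent", "child"}, g) == {"child"}
    assert reduce_to_most_specific({"parent", "root", "child"}, g) == {"child"}
    g2 = _diamond()
    assert reduce_to_most_specific({"parent", "parent2"}, g2) == {"parent", "parent2"}
    # output is always an antichain
    out = reduce_to_most_specific({"child", "parent2", "root"}, g2)
    for a in out:
        for b in out:
            assert a == b or b not in nx.descendants(g2, a)


def test_planted_term_detected_in_most_seeds():
    """A term at 5x frequency in a 50-gene test set vs a 1000-gene background
    reaches FDR < 0.05 in at least 9 of 10 seeds."""
    g = _chain()
    hits = 0
    for seed in range(10):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(1000)]
        test = genes[:50]
        direct = {}
        for gene in genes:
            p = 0.5 if gene in test else 0.1
            direct[gene] = {"child"} if rng.random() < p else {"root"}
        df = enrich(test, genes, direct, g, alpha=0.05)
        row = df[df["term"] == "child"]
        if len(row) and bool(row["enriched"].iloc[0]):
            hits += 1
    assert hits >= 9


def test_obo_round_trip_and_depth():
    onto = synthetic_ontology()
    obo_text = ontology_to_obo(onto)
    import tempfile, pathlib

    with tempfile.TemporaryDirectory() as d:
        path = pathlib.Path(d) / "mini.obo"
        path.write_text(obo_text)
        loaded = load_ontology(path)
    assert set(loaded.nodes) == set(onto.nodes)
    assert set(loaded.edges) == set(onto.edges)
    assert term_depth(loaded, "GO:0000007") == 4
    assert term_depth(loaded, "GO:0000001") == 0
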