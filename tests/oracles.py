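"""Independent brute-force oracles used to freeze expected values.

These deliberately avoid the code paths they check: the tail oracle
enumerates the full hypergeometric pmf in exact rational arithmetic, and
the ancestor oracle walks an explicitly materialized graph.
"""

from fractions import Fraction
from math import comb

import networkx as nx


def hypergeom_tail_oracle(n: int, a: int, s: int, m: int) -> float:
    """P(X >= m) by full pmf enumeration with exact rationals."""
    total = comb(n, s)
    pmf = {k: Fraction(comb(a, k) * comb(n - a, s - k), total)
           for k in range(max(0, s - (n - a)), min(a, s) + 1)}
    assert sum(pmf.values()) == 1
    return float(sum(p for k, p in pmf.items() if k >= m))


def ancestors_oracle(terminology, descriptor_id: str) -> frozenset[str]:
    """Ancestors via explicit graph traversal.

    The hierarchy lives on tree numbers, not descriptors: each tree number
    links to its immediate resolvable parent (its longest proper prefix
    present in the index), and a descriptor's ancestors are the owners of
    the tree numbers reachable upward from any of its own tree numbers.
    """
    graph = nx.DiGraph()
    index = terminology.tree_index
    for tn in index:
        graph.add_node(tn)
        segments = tn.split(".")
        for i in range(len(segments) - 1, 0, -1):
            parent = ".".join(segments[:i])
            if parent in index:
                graph.add_edge(parent, tn)
                break
    out = set()
    for tn in terminology[descriptor_id].tree_numbers:
        out.update(index[anc] for anc in nx.ancestors(graph, tn))
    return frozenset(out)


def aggregated_sets_oracle(corpus, terminology):
    """a(t) by explicit descendant enumeration: for every term, union the
    raw article sets of every descriptor having the term as an ancestor."""
    raw = {}
    for article, descriptor, _ in corpus.records:
        raw.setdefault(descriptor, set()).add(article)
    out = {}
    for term in raw:
        out.setdefault(term, set()).update(raw[term])
    for descriptor in terminology:
        did = descriptor.descriptor_id
        if did not in raw:
            continue
        for anc in ancestors_oracle(terminology, did):
            out.setdefault(anc, set()).update(raw[did])
    return {t: frozenset(a) for t, a in out.items()}
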