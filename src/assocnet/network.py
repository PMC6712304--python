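"""Bipartite association networks.

Vertices are the molecular and microbial features incident to at least one
retained association; edges carry the test result (statistic, P, sign,
BH q).  Connected components of this bipartite graph are the network's
modules — groups of molecules and microbes linked through shared
cooccurrence — which is where biotransformation stories (one microbe tied
positively to products and negatively to precursors) show up.
"""

from __future__ import annotations

import networkx as nx

MOLECULE = "molecule"
MICROBE = "microbe"


def build_network(edges, threshold: float | None = None) -> nx.Graph:
    """Assemble the bipartite graph from scan edges.

    Nodes are exactly the features incident to >= 1 edge; molecule nodes
    carry m/z when known.  Bipartiteness is asserted on every build.
    """
    g = nx.Graph()
    g.graph["threshold"] = "" if threshold is None else threshold
    for e in edges:
        mol = f"mol::{e.molecule_id}"
        mic = f"mic::{e.microbe_id}"
        g.add_node(mol, kind=MOLECULE, feature_id=e.molecule_id, bipartite=0)
        if e.mz is not None:
            g.nodes[mol]["mz"] = float(e.mz)
        g.add_node(mic, kind=MICROBE, feature_id=e.microbe_id, bipartite=1)
        attrs = {"test": e.test, "statistic": float(e.statistic), "sign": e.sign}
        if e.p_value is not None:
            attrs["p_value"] = float(e.p_value)
        if e.q_value is not None:
            attrs["q_value"] = float(e.q_value)
        g.add_edge(mol, mic, **attrs)
    _assert_bipartite(g)
    return g


def _assert_bipartite(g: nx.Graph) -> None:
    for u, v in g.edges:
        ku, kv = g.nodes[u]["kind"], g.nodes[v]["kind"]
        if {ku, kv} != {MOLECULE, MICROBE}:
            raise ValueError(f"edge {u}--{v} is not molecule--microbe")


def connected_modules(g: nx.Graph, min_size: int = 2) -> list:
    """Connected components with >= min_size nodes, largest first.

    Size ties break on the sorted node names so the order is deterministic.
    """
    comps = [set(c) for c in nx.connected_components(g) if len(c) >= min_size]
    comps.sort(key=lambda c: (-len(c), sorted(c)))
    return comps


def export_network(g: nx.Graph, path, format: str = "graphml") -> None:
    """Write GraphML (typed attributes) or a flat TSV edge list."""
    if format == "graphml":
        nx.write_graphml(g, path)
    elif format == "edge_tsv":
        comp_of = {}
        for idx, comp in enumerate(connected_modules(g, min_size=1)):
            for node in comp:
                comp_of[node] = idx
        with open(path, "w") as fh:
            fh.write(
                "molecule_id\tmicrobe_id\tmz\ttest\tstatistic\tp_value\tsign"
                "\tq_value\tcomponent\n"
            )
            rows = []
            for u, v, attrs in g.edges(data=True):
                if g.nodes[u]["kind"] != MOLECULE:
                    u, v = v, u
                rows.append((
                    g.nodes[u]["feature_id"], g.nodes[v]["feature_id"],
                    g.nodes[u].get("mz", ""), attrs["test"], attrs["statistic"],
                    attrs.get("p_value", ""), attrs["sign"],
                    attrs.get("q_value", ""), comp_of[u],
                ))
            for row in sorted(rows, key=lambda r: (r[0], r[1])):
                fh.write("\t".join(str(x) for x in row) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def load_network(path) -> nx.Graph:
    """Read a GraphML file written by :func:`export_network`."""
    g = nx.read_graphml(path)
    g = nx.relabel_nodes(g, {n: str(n) for n in g.nodes})
    _assert_bipartite(g)
    return g


def collapse_by_taxonomy(g: nx.Graph, level: int) -> nx.Graph:
    """Merge microbe nodes sharing a taxonomy prefix of ``level`` ranks.

    Optional coarse-graining for display (e.g. family level = 5 ranks of a
    k__;p__;c__;o__;f__;g__;s__ string); molecule nodes are untouched and
    parallel edges keep the smallest P value.
    """
    mapping = {}
    for node, attrs in g.nodes(data=True):
        if attrs["kind"] == MICROBE and attrs.get("taxonomy"):
            prefix = ";".join(attrs["taxonomy"].split(";")[:level]).strip()
            if prefix:
                mapping[node] = f"mic::{prefix}"
    out = nx.Graph(**g.graph)
    for node, attrs in g.nodes(data=True):
        out.add_node(mapping.get(node, node), **attrs)
        if node in mapping:
            out.nodes[mapping[node]]["feature_id"] = mapping[node][5:]
    for u, v, attrs in g.edges(data=True):
        u2, v2 = mapping.get(u, u), mapping.get(v, v)
        if out.has_edge(u2, v2):
            if attrs.get("p_value", 1.0) < out.edges[u2, v2].get("p_value", 1.0):
                out.edges[u2, v2].update(attrs)
        else:
            out.add_edge(u2, v2, **attrs)
    _assert_bipartite(out)
    return out
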