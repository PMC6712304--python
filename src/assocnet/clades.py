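"""Assigning molecules to phylogenetic clades.

A molecule that is positively associated with several related microbes is
more parsimoniously explained by the clade those microbes form than by any
one of them.  Given a rooted tree over the microbial feature ids, the tree
is pruned to the microbes with at least one positive association; for each
molecule the leaves matching its positive partners are marked, and the
molecule is assigned to the minimal clade (fewest leaves) that contains at
least P percent (default 80) of its marked leaves — provided that clade is a
proper subtree, i.e. not the whole pruned tree.

Candidate clades are internal nodes only: a single leaf is a species, not a
clade, so single-leaf evidence maps to the leaf's parent cherry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy

logger = logging.getLogger(__name__)

DEFAULT_PERCENT = 80.0


@dataclass
class CladeAssignment:
    """A molecule mapped to one clade of the pruned tree."""

    molecule_id: str | None
    clade_label: str          # smallest leaf label + leaf count, e.g. "otu3|n=4"
    postorder_index: int
    node_name: str | None
    n_marked_total: int
    n_marked_in_clade: int
    n_leaves_in_clade: int
    clade_leaves: frozenset = frozenset()

    @property
    def fraction(self) -> float:
        return self.n_marked_in_clade / self.n_marked_total


def load_tree(source: str, is_path: bool = True) -> dendropy.Tree:
    """Read a Newick tree, keeping underscores in labels verbatim.

    A basal polytomy (the usual encoding of an unrooted tree) is
    midpoint-rooted with a warning so that clades are well defined.
    """
    kwargs = dict(schema="newick", preserve_underscores=True)
    if is_path:
        tree = dendropy.Tree.get(path=source, **kwargs)
    else:
        tree = dendropy.Tree.get(data=source, **kwargs)
    root = tree.seed_node
    if len(root.child_nodes()) > 2:
        logger.warning("input tree looks unrooted (basal polytomy); midpoint rooting")
        tree.reroot_at_midpoint(update_bipartitions=False)
    tree.is_rooted = True
    return tree


def leaf_labels(tree: dendropy.Tree) -> set:
    return {leaf.taxon.label for leaf in tree.leaf_node_iter()}


def prune_tree(tree: dendropy.Tree, keep: set) -> dendropy.Tree:
    """Smallest topology-preserving tree on the kept leaves.

    Unary internal nodes created by pruning are suppressed with their branch
    lengths summed, so root-to-leaf path lengths are preserved.
    """
    present = leaf_labels(tree) & set(keep)
    if not present:
        raise ValueError("none of the requested leaves occur in the tree")
    pruned = tree.extract_tree_with_taxa_labels(labels=present)
    pruned.purge_taxon_namespace()
    return pruned


def _annotate(tree: dendropy.Tree):
    """Post-order pass: per node leaf count, leaf set handle, and depth."""
    info = []
    for idx, node in enumerate(tree.postorder_node_iter()):
        node._po_index = idx
        if node.is_leaf():
            node._leaves = frozenset({node.taxon.label})
        else:
            node._leaves = frozenset().union(*(c._leaves for c in node.child_nodes()))
        info.append(node)
    depth = {}
    for node in tree.preorder_node_iter():
        depth[id(node)] = 0 if node.parent_node is None else depth[id(node.parent_node)] + 1
    return info, depth


def _clade_label(node) -> str:
    return f"{min(node._leaves)}|n={len(node._leaves)}"


def assign_clade(
    tree: dendropy.Tree,
    marked: set,
    percent: float = DEFAULT_PERCENT,
    molecule_id: str | None = None,
) -> CladeAssignment | None:
    """Minimal proper clade containing >= percent% of the marked leaves.

    Among internal, non-root nodes whose subtree covers at least ``percent``
    percent of all marked leaves, returns the one with the fewest leaves
    (ties: greater depth, then post-order index).  Returns None when only
    the whole tree qualifies, or when nothing is marked.
    """
    if not 0 < percent <= 100:
        raise ValueError("percent must be in (0, 100]")
    marked = set(marked)
    labels = leaf_labels(tree)
    if not marked:
        logger.debug("no marked leaves for %s; no assignment", molecule_id)
        return None
    if not marked <= labels:
        raise ValueError(f"marked leaves not in the tree: {sorted(marked - labels)[:5]}")

    nodes, depth = _annotate(tree)
    total = len(marked)
    best = None
    best_key = None
    for node in nodes:
        if node.is_leaf() or node.parent_node is None:
            continue  # leaves are not clades; the root is the whole tree
        covered = len(node._leaves & marked)
        if covered * 100 >= percent * total:
            key = (len(node._leaves), -depth[id(node)], node._po_index)
            if best_key is None or key < best_key:
                best, best_key = node, key
    if best is None:
        return None
    return CladeAssignment(
        molecule_id=molecule_id,
        clade_label=_clade_label(best),
        postorder_index=best._po_index,
        node_name=getattr(best, "label", None),
        n_marked_total=total,
        n_marked_in_clade=len(best._leaves & marked),
        n_leaves_in_clade=len(best._leaves),
        clade_leaves=best._leaves,
    )


def assign_all(
    tree: dendropy.Tree, edges, percent: float = DEFAULT_PERCENT
) -> list:
    """Assign every molecule with positive associations to a clade.

    The tree is pruned once to the union of all positively associated
    microbes that occur as leaves; each molecule's positive partners within
    the pruned tree are its marked set.  Output is sorted by molecule id.
    """
    positive = [e for e in edges if e.sign == "positive"]
    partners: dict[str, set] = {}
    for e in positive:
        partners.setdefault(e.molecule_id, set()).add(e.microbe_id)
    present = leaf_labels(tree)
    associated = set().union(*partners.values()) if partners else set()
    keep = associated & present
    if not keep:
        logger.warning("no positively associated microbe occurs in the tree")
        return []
    pruned = prune_tree(tree, keep)
    out = []
    for mol in sorted(partners):
        marked = partners[mol] & keep
        if not marked:
            continue
        assignment = assign_clade(pruned, marked, percent, molecule_id=mol)
        if assignment is not None:
            out.append(assignment)
    return out


def assignments_to_tsv(assignments, edges, path) -> None:
    """Write the assignment table with each molecule's best in-clade P.

    The reported P is the minimal P value among the molecule's positive
    edges into microbes of its assigned clade (the -log10 of this value is
    the natural heat for clade-by-molecule displays).
    """
    best_p: dict[tuple, float] = {}
    for e in edges:
        if e.sign != "positive" or e.p_value is None:
            continue
        key = (e.molecule_id, e.microbe_id)
        best_p[key] = min(best_p.get(key, 1.0), e.p_value)
    with open(path, "w") as fh:
        fh.write(
            "molecule_id\tclade\tn_leaves\tn_marked\tn_marked_total\tfraction"
            "\tmin_p\n"
        )
        for a in assignments:
            pvals = [
                p
                for (mol, mic), p in best_p.items()
                if mol == a.molecule_id and mic in a.clade_leaves
            ]
            min_p = min(pvals) if pvals else ""
            fh.write(
                f"{a.molecule_id}\t{a.clade_label}\t{a.n_leaves_in_clade}"
                f"\t{a.n_marked_in_clade}\t{a.n_marked_total}"
                f"\t{a.fraction:.4f}\t{min_p}\n"
            )
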