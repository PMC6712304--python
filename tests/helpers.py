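"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: the Fisher oracle
enumerates the hypergeometric support in exact integer/rational arithmetic,
the BH oracle is the step-up definition written out literally, and the clade
oracle enumerates every subtree's leaf set explicitly.
"""

from fractions import Fraction
from math import comb

import dendropy
import numpy as np

_fisher_cache = {}


def fisher_oracle(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher P by exhaustive enumeration, exact rational result."""
    # the P value is invariant under row swap, column swap and transpose
    key = min(
        (a, b, c, d), (b, a, d, c), (c, d, a, b), (d, c, b, a),
        (a, c, b, d), (c, a, d, b), (b, d, a, c), (d, b, c, a),
    )
    if key in _fisher_cache:
        return _fisher_cache[key]
    a, b, c, d = key
    m, k, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, m + k - n), min(m, k)
    w_obs = comb(m, a) * comb(n - m, k - a)
    total = comb(n, k)
    if total == 0:
        return Fraction(1)
    s = sum(
        w
        for x in range(lo, hi + 1)
        if (w := comb(m, x) * comb(n - m, k - x)) <= w_obs
    )
    p = Fraction(s, total)
    _fisher_cache[key] = p
    return p


def bh_oracle(p_values) -> np.ndarray:
    """BH step-up by definition: sort, q_i = min_{j>=i} p_j * m / j."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, p[order[rank - 1]] * m / rank)
        q_sorted[rank - 1] = min(running, 1.0)
    out = np.empty(m)
    out[order] = q_sorted
    return out


def random_binary_tree(labels, rng) -> str:
    """A uniform-ish random rooted binary topology as a Newick string."""
    labels = list(labels)
    rng.shuffle(labels)

    def build(ls):
        if len(ls) == 1:
            return ls[0]
        split = int(rng.integers(1, len(ls)))
        return f"({build(ls[:split])},{build(ls[split:])})"

    return build(labels) + ";"


def _subtree_leaves(node) -> frozenset:
    if node.is_leaf():
        return frozenset({node.taxon.label})
    out = set()
    for child in node.child_nodes():
        out |= _subtree_leaves(child)
    return frozenset(out)


def brute_force_clade(tree: dendropy.Tree, marked, percent) -> frozenset | None:
    """Enumerate every internal non-root subtree and apply the rule directly.

    Returns the chosen clade's leaf set (minimal leaf count covering at
    least ``percent`` % of the marked leaves; ties: deeper node, then
    post-order index), or None.
    """
    marked = set(marked)
    total = len(marked)
    if total == 0:
        return None
    depth = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        depth[id(node)] = 0 if parent is None else depth[id(parent)] + 1
    best, best_key = None, None
    for idx, node in enumerate(tree.postorder_node_iter()):
        if node.is_leaf() or node.parent_node is None:
            continue
        leaves = _subtree_leaves(node)
        if len(leaves & marked) * 100 >= percent * total:
            key = (len(leaves), -depth[id(node)], idx)
            if best_key is None or key < best_key:
                best, best_key = leaves, key
    return best
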