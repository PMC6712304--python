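"""Deduplication of redundant LC-MS molecular features.

Feature extractors report the same molecule as several features at nearly
identical m/z.  Two features are putative duplicates when their m/z values
agree within an absolute tolerance (default 0.01 Th) AND their presence
patterns cooccur significantly (Fisher's exact P <= 1e-5, the same test the
association scan uses, applied molecule-vs-molecule).  Duplicate groups are
the connected components of the resulting graph; each group is replaced by a
consensus feature with the mean m/z and the union presence set.

Candidate pairs are generated with a sliding window over m/z-sorted
features, so only the m/z-compatible fraction of the O(n^2) pairs is ever
tested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx

from .assoc import POSITIVE, ContingencyTable, fisher_pvalue, sign_of_association
from .feature_io import MOLECULAR, BinaryFeature

logger = logging.getLogger(__name__)

DEFAULT_MZ_TOL = 0.01
DEFAULT_P_THRESHOLD = 1e-5


@dataclass
class DuplicateGroup:
    """A connected component of the duplicate graph, with its consensus."""

    member_ids: frozenset
    consensus_id: str
    consensus_mz: float
    consensus_sample_set: frozenset


def duplicate_pairs(
    molecules,
    mz_tol: float = DEFAULT_MZ_TOL,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    n_samples: int | None = None,
) -> list:
    """All unordered pairs passing both the m/z and the cooccurrence gate.

    Returns ``(id_i, id_j, p_value)`` triples with |mz_i - mz_j| <= mz_tol,
    positive cooccurrence, and Fisher P <= p_threshold over the
    ``n_samples``-sample universe.
    """
    if mz_tol <= 0:
        raise ValueError("mz_tol must be > 0")
    if not 0 < p_threshold <= 1:
        raise ValueError("p_threshold must be in (0, 1]")
    if n_samples is None:
        raise ValueError("n_samples (the universe size) is required")
    for f in molecules:
        if f.mz is None:
            raise ValueError(f"{f.feature_id}: molecular feature without mz")

    order = sorted(molecules, key=lambda f: (f.mz, f.feature_id))
    pairs = []
    for i, fi in enumerate(order):
        for fj in order[i + 1:]:
            if fj.mz - fi.mz > mz_tol:
                break
            a = len(fi.sample_set & fj.sample_set)
            t = ContingencyTable(
                a=a,
                b=len(fi.sample_set) - a,
                c=len(fj.sample_set) - a,
                d=n_samples - len(fi.sample_set) - len(fj.sample_set) + a,
            )
            # duplicates of one molecule cooccur; a significant two-sided P
            # with co-presence BELOW expectation is avoidance, not redundancy
            if sign_of_association(t) != POSITIVE:
                continue
            p = fisher_pvalue(t)
            if p <= p_threshold:
                x, y = sorted((fi.feature_id, fj.feature_id))
                pairs.append((x, y, p))
    pairs.sort()
    return pairs


def deduplicate(
    molecules,
    mz_tol: float = DEFAULT_MZ_TOL,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    n_samples: int | None = None,
) -> list:
    """Partition molecules into duplicate groups (connected components).

    Singleton components pass through unchanged (the consensus is the
    feature itself); multi-member components get a ``dedup:`` consensus id
    derived from the lexicographically smallest member, the members' mean
    m/z, and the union of their sample sets.
    """
    by_id = {f.feature_id: f for f in molecules}
    if len(by_id) != len(molecules):
        raise ValueError("duplicate molecular feature ids")
    graph = nx.Graph()
    graph.add_nodes_from(by_id)
    graph.add_edges_from(
        (i, j) for i, j, _ in duplicate_pairs(molecules, mz_tol, p_threshold, n_samples)
    )
    groups = []
    for component in nx.connected_components(graph):
        members = sorted(component)
        feats = [by_id[m] for m in members]
        cid = members[0] if len(members) == 1 else f"dedup:{members[0]}"
        union = frozenset().union(*(f.sample_set for f in feats))
        groups.append(
            DuplicateGroup(
                member_ids=frozenset(members),
                consensus_id=cid,
                consensus_mz=sum(f.mz for f in feats) / len(feats),
                consensus_sample_set=union,
            )
        )
    groups.sort(key=lambda g: g.consensus_id)
    n_merged = sum(1 for g in groups if len(g.member_ids) > 1)
    if n_merged:
        logger.info(
            "deduplication: %d features -> %d consensus features (%d merged groups)",
            len(molecules), len(groups), n_merged,
        )
    return groups


def groups_to_features(groups) -> list:
    """Materialise consensus features for downstream scans."""
    return [
        BinaryFeature(
            feature_id=g.consensus_id,
            sample_set=g.consensus_sample_set,
            kind=MOLECULAR,
            mz=g.consensus_mz,
        )
        for g in groups
    ]
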