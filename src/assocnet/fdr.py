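"""False-discovery-rate control: target-decoy estimation and Benjamini-Hochberg.

The target-decoy approach (TDA) builds, for every molecular feature, a decoy
feature whose presence set is a uniformly random subset of the sample
universe of the same size.  Decoys are null by construction, so the ratio
|decoy associations| / |target associations| passing a threshold estimates
the FDR of the target set at that threshold.  Multiple decoys per target
(``n_per_target``) reduce the variance of the estimate; the decoy count is
then normalised by ``n_per_target``.

BH adjustment over the full molecule x microbe family of P values is the
parametric alternative; for mutual information (which carries no P value)
TDA is the only route.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .assoc import AssociationEdge, association_scan
from .feature_io import DECOY, BinaryDataset, BinaryFeature

logger = logging.getLogger(__name__)


@dataclass
class DecoySet:
    """Size-matched random decoy molecules."""

    decoys: list
    source_map: dict
    rng_seed: int
    n_per_target: int = 1


@dataclass
class FdrEstimate:
    """TDA and BH estimates at one threshold."""

    threshold: float
    n_real: int
    n_decoy: int
    fdr_tda: float
    fdr_bh: np.ndarray | None = None  # BH-adjusted P per real edge, input order


def make_decoys(molecules, samples, seed: int, n_per_target: int = 1) -> DecoySet:
    """Draw ``n_per_target`` size-matched random decoys per molecular feature.

    Each decoy's presence set is a uniform subset (without replacement) of
    the universe with exactly the target's prevalence; reproducible from
    ``seed``.
    """
    if n_per_target < 1:
        raise ValueError("n_per_target must be >= 1")
    rng = np.random.default_rng(seed)
    universe = np.asarray(list(samples), dtype=object)
    decoys, source_map = [], {}
    for target in molecules:
        size = len(target.sample_set)
        if size > len(universe):
            raise ValueError(f"{target.feature_id}: presence set exceeds universe")
        for j in range(n_per_target):
            chosen = rng.choice(universe, size=size, replace=False)
            did = f"decoy{j}:{target.feature_id}"
            decoys.append(
                BinaryFeature(
                    feature_id=did,
                    sample_set=frozenset(chosen),
                    kind=DECOY,
                    mz=target.mz,
                )
            )
            source_map[did] = target.feature_id
    return DecoySet(decoys=decoys, source_map=source_map, rng_seed=seed,
                    n_per_target=n_per_target)


def scan_with_decoys(
    dataset: BinaryDataset,
    *,
    test: str = "fisher",
    threshold: float | None = None,
    seed: int = 0,
    n_per_target: int = 1,
):
    """Run the target scan and the matched decoy scan.

    The decoy scan reuses the same microbial features, sample universe, test
    and threshold by construction, which is what makes the decoy/target
    ratio a valid FDR estimate.
    """
    real = association_scan(dataset, test=test, threshold=threshold)
    decoy_set = make_decoys(dataset.molecules, dataset.samples, seed, n_per_target)
    decoy_ds = BinaryDataset(
        samples=dataset.samples, molecules=decoy_set.decoys, microbes=dataset.microbes
    )
    decoy = association_scan(decoy_ds, test=test, threshold=threshold)
    return real, decoy, decoy_set


def _check_same_test(real_edges, decoy_edges) -> str:
    tests = {e.test for e in real_edges} | {e.test for e in decoy_edges}
    if len(tests) > 1:
        raise ValueError(f"mixed tests in edge sets: {sorted(tests)}")
    return tests.pop() if tests else "fisher"


def _passes(edges, test: str, threshold: float) -> np.ndarray:
    score = np.array([e.score for e in edges], dtype=float)
    if test == "mutual_information":
        return score >= threshold
    return score < threshold


def tda_fdr(
    real_edges, decoy_edges, threshold: float, n_per_target: int = 1
) -> FdrEstimate:
    """Estimate the FDR at one threshold as n_decoy / (n_per_target * n_real).

    The ratio is capped at 1 and defined as 1 when no real association
    passes.  BH-adjusted values for the real edges ride along when the test
    produces P values.
    """
    test = _check_same_test(real_edges, decoy_edges)
    n_real = int(_passes(real_edges, test, threshold).sum())
    n_decoy = int(_passes(decoy_edges, test, threshold).sum())
    if n_real == 0:
        fdr = 1.0
    else:
        fdr = min(1.0, n_decoy / (n_per_target * n_real))
    bh = None
    if test != "mutual_information" and real_edges:
        bh = bh_adjust([e.p_value for e in real_edges])
    return FdrEstimate(threshold=threshold, n_real=n_real, n_decoy=n_decoy,
                       fdr_tda=fdr, fdr_bh=bh)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if not (np.isfinite(p).all() and (p >= 0).all() and (p <= 1).all()):
        raise ValueError("P values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def attach_bh(edges) -> list:
    """Fill each edge's q_value with its BH-adjusted P (family = all edges)."""
    pvals = [e.p_value for e in edges]
    if any(p is None for p in pvals):
        raise ValueError("BH needs P values on every edge")
    q = bh_adjust(pvals)
    for e, qi in zip(edges, q):
        e.q_value = float(qi)
    return edges


def fdr_curve(real_edges, decoy_edges, thresholds, n_per_target: int = 1) -> pd.DataFrame:
    """Tabulate TDA and BH discovery counts over a threshold grid.

    One row per threshold: counts of passing real and decoy edges, the TDA
    ratio, and (for P-value tests) how many real edges have BH-adjusted
    value <= the threshold.
    """
    test = _check_same_test(real_edges, decoy_edges)
    thresholds = list(thresholds)
    if sorted(thresholds) != thresholds and sorted(thresholds, reverse=True) != thresholds:
        raise ValueError("thresholds must be sorted")
    bh = None
    if test != "mutual_information" and real_edges:
        bh = bh_adjust([e.p_value for e in real_edges])
    rows = []
    for t in thresholds:
        est = tda_fdr(real_edges, decoy_edges, t, n_per_target)
        n_bh = np.nan if bh is None else int((bh <= t).sum())
        rows.append(
            {"threshold": t, "n_real": est.n_real, "n_decoy": est.n_decoy,
             "fdr_tda": est.fdr_tda, "n_pass_bh": n_bh}
        )
    return pd.DataFrame(rows)


def select_at_fdr(real_edges, decoy_edges, q: float, n_per_target: int = 1):
    """Largest set of real edges whose TDA-estimated FDR is <= q.

    Walks the real edges from strongest to weakest score; at the k strongest
    the estimate is (decoys at least as strong) / (n_per_target * k).  The
    largest k satisfying the target is kept (ties in score are kept
    together).  Returns ``(selected_edges, score_threshold)``; an empty
    selection returns ``([], None)``.
    """
    if not real_edges:
        return [], None
    test = _check_same_test(real_edges, decoy_edges)
    bigger_is_better = test == "mutual_information"
    real = sorted(real_edges, key=lambda e: e.score, reverse=bigger_is_better)
    scores = np.array([e.score for e in real], dtype=float)
    dscores = np.sort(np.array([e.score for e in decoy_edges], dtype=float))
    if bigger_is_better:
        # decoys with score >= s
        n_decoy = len(dscores) - np.searchsorted(dscores, scores, side="left")
    else:
        n_decoy = np.searchsorted(dscores, scores, side="right")
    k = np.arange(1, len(real) + 1)
    fdr = n_decoy / (n_per_target * k)
    ok = np.nonzero(fdr <= q)[0]
    if ok.size == 0:
        return [], None
    kstar = int(ok[-1])
    cutoff = scores[kstar]
    if bigger_is_better:
        selected = [e for e in real if e.score >= cutoff]
    else:
        selected = [e for e in real if e.score <= cutoff]
    selected.sort(key=lambda e: (e.molecule_id, e.microbe_id))
    return selected, float(cutoff)
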