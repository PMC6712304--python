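"""Pairwise molecule-microbe association tests.

The central test is Fisher's exact test on the 2x2 presence/absence
contingency table of a (molecule, microbe) pair over the sample universe:
under the null, the two presence events are independent and the table's
co-presence cell follows a hypergeometric distribution with fixed margins.
Pearson, Spearman (on raw abundances) and the plug-in mutual information of
the presence indicators are provided as alternative association measures.

The two-sided exact P is the sum of the point probabilities of all tables
(with the observed margins) no more probable than the observed one.  It is
computed from the hypergeometric pmf over the whole support, cached per
margin pair, which makes all-pairs scans cheap: a scan touches at most
``n_molecules x n_microbes`` distinct margin pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .feature_io import BinaryDataset, BinaryFeature, FeatureTable

logger = logging.getLogger(__name__)

TESTS = ("fisher", "pearson", "spearman", "mutual_information")
#: tests whose score is a P value (smaller = stronger); MI is the exception
P_VALUE_TESTS = ("fisher", "pearson", "spearman")

POSITIVE = "positive"
NEGATIVE = "negative"

# relative slack when comparing floating-point pmf values for the two-sided
# sum; point probabilities that are exactly equal as rationals can differ in
# the last float bits
_PMF_SLACK = 1.0 + 1e-7


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 presence table: a = both, b = molecule only, c = microbe only."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be >= 0")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class AssociationEdge:
    """One (molecule, microbe) association with its test result."""

    molecule_id: str
    microbe_id: str
    test: str
    statistic: float
    p_value: float | None
    sign: str
    q_value: float | None = None
    mz: float | None = None
    table: ContingencyTable | None = field(default=None, repr=False)

    @property
    def score(self) -> float:
        """Ranking score: the P value, or the MI statistic for MI edges."""
        return self.statistic if self.p_value is None else self.p_value


def contingency(x: BinaryFeature, y: BinaryFeature, samples) -> ContingencyTable:
    """Cross-tabulate two presence sets over the sample universe."""
    universe = set(samples)
    sx, sy = set(x.sample_set), set(y.sample_set)
    if not (sx <= universe and sy <= universe):
        raise ValueError("sample sets must lie within the universe")
    a = len(sx & sy)
    return ContingencyTable(a=a, b=len(sx) - a, c=len(sy) - a,
                            d=len(universe) - len(sx) - len(sy) + a)


@lru_cache(maxsize=200_000)
def _two_sided_table(m: int, k: int, n: int):
    """Two-sided Fisher P for every co-presence count a with margins (m, k, n).

    Returns ``(lo, p)`` where ``p[a - lo]`` is the P value for a table with
    ``a`` in the hypergeometric support ``[lo, min(m, k)]``.
    """
    if n == 0:
        return 0, np.array([1.0])  # empty universe: nothing to test
    lo = max(0, m + k - n)
    hi = min(m, k)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, m, k)
    p = (pmf[None, :] * (pmf[None, :] <= pmf[:, None] * _PMF_SLACK)).sum(axis=1)
    return lo, np.minimum(p, 1.0)


def fisher_pvalue(t: ContingencyTable) -> float:
    """Two-sided exact P under the fixed-margins hypergeometric null."""
    lo, p = _two_sided_table(t.a + t.b, t.a + t.c, t.n)
    return float(p[t.a - lo])


def fisher_exact(t: ContingencyTable) -> tuple[float, float]:
    """Sample odds ratio and two-sided exact P.

    Degenerate margins (a row or column of zeros) leave a single admissible
    table, so P = 1.  The odds ratio is ``inf`` when only the off-diagonal is
    empty and ``nan`` when both diagonals vanish.
    """
    num, den = t.a * t.d, t.b * t.c
    if den > 0:
        odds = num / den
    else:
        odds = np.inf if num > 0 else np.nan
    return odds, fisher_pvalue(t)


def sign_of_association(t: ContingencyTable) -> str:
    """Positive iff co-presence exceeds its independence expectation.

    Compares a*n with (a+b)(a+c), which is well defined even when a cell is
    zero; exact equality is called positive by convention (and logged).
    """
    lhs = t.a * t.n
    rhs = (t.a + t.b) * (t.a + t.c)
    if lhs == rhs:
        logger.debug("sign tie (observed == expected); calling it positive")
        return POSITIVE
    return POSITIVE if lhs > rhs else NEGATIVE


def _pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    n = len(x)
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    r = float(np.clip((xc * yc).sum() / denom, -1.0, 1.0))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return r, float(2.0 * stats.t.sf(abs(t), n - 2))


def pearson_test(x_values, y_values) -> tuple[float, float]:
    """Sample Pearson r with a two-sided P from the t(n-2) distribution.

    Constant input makes r undefined; the pair is reported as (nan, nan) and
    skipped by scans rather than raising.
    """
    x = np.asarray(x_values, dtype=float)
    y = np.asarray(y_values, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.debug("constant vector: correlation undefined, skipping")
        return np.nan, np.nan
    return _pearson_with_p(x, y)


def spearman_test(x_values, y_values) -> tuple[float, float]:
    """Spearman rho (Pearson r of mid-ranks) with the t-approximation P."""
    x = np.asarray(x_values, dtype=float)
    y = np.asarray(y_values, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.debug("constant vector: correlation undefined, skipping")
        return np.nan, np.nan
    return _pearson_with_p(stats.rankdata(x), stats.rankdata(y))


def _mi_bits(a, m, k, n):
    """Plug-in mutual information (bits) of two presence indicators.

    Vectorized over co-presence counts ``a`` with margins ``m``, ``k``; uses
    the 0*log(0) = 0 convention.
    """
    a = np.asarray(a, dtype=float)
    cells = np.stack([a, m - a, k - a, n - m - k + a])
    px = np.stack([m, m, n - m, n - m], dtype=float)
    py = np.stack([k, n - k, k, n - k], dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = cells / n * np.log2(cells * n / (px * py))
    mi = np.where(cells > 0, term, 0.0).sum(axis=0)
    return np.maximum(mi, 0.0)


def mutual_information(x: BinaryFeature, y: BinaryFeature, samples) -> float:
    """MI (bits) between the presence indicators of two features."""
    t = contingency(x, y, samples)
    return float(_mi_bits(t.a, t.a + t.b, t.a + t.c, t.n))


def _presence_matrix(features, samples) -> np.ndarray:
    index = {s: j for j, s in enumerate(samples)}
    mat = np.zeros((len(features), len(samples)), dtype=np.int64)
    for i, f in enumerate(features):
        for s in f.sample_set:
            mat[i, index[s]] = 1
    return mat


def _binary_scan(molecules, microbes, samples, test, threshold):
    n = len(samples)
    X = _presence_matrix(molecules, samples)
    Y = _presence_matrix(microbes, samples)
    A = X @ Y.T
    m = X.sum(axis=1)
    k = Y.sum(axis=1)

    if test == "fisher":
        score = np.empty(A.shape, dtype=float)
        for i in range(len(molecules)):
            for j in range(len(microbes)):
                lo, p = _two_sided_table(int(m[i]), int(k[j]), n)
                score[i, j] = p[A[i, j] - lo]
        passing = np.ones_like(A, bool) if threshold is None else score < threshold
    else:  # mutual information: larger is stronger
        score = _mi_bits(A, m[:, None], k[None, :], n)
        passing = np.ones_like(A, bool) if threshold is None else score >= threshold

    edges = []
    for i, j in zip(*np.nonzero(passing)):
        t = ContingencyTable(
            a=int(A[i, j]), b=int(m[i] - A[i, j]), c=int(k[j] - A[i, j]),
            d=int(n - m[i] - k[j] + A[i, j]),
        )
        if test == "fisher":
            odds, p = fisher_exact(t)
            stat, pval = odds, float(score[i, j])
        else:
            stat, pval = float(score[i, j]), None
        edges.append(
            AssociationEdge(
                molecule_id=molecules[i].feature_id,
                microbe_id=microbes[j].feature_id,
                test=test,
                statistic=stat,
                p_value=pval,
                sign=sign_of_association(t),
                mz=molecules[i].mz,
                table=t,
            )
        )
    return edges


def _continuous_scan(molecular, microbial, test, threshold, log_transform):
    if set(molecular.sample_ids) != set(microbial.sample_ids):
        raise ValueError("tables must share one sample universe (align first)")
    X = molecular.data.loc[:, microbial.sample_ids].to_numpy(dtype=float)
    Y = microbial.data.to_numpy(dtype=float)
    if log_transform:
        X = np.log10(1.0 + X)
        Y = np.log10(1.0 + Y)
    n = X.shape[1]
    if n < 3:
        raise ValueError("continuous tests need at least 3 shared samples")
    if test == "spearman":
        X = stats.rankdata(X, axis=1)
        Y = stats.rankdata(Y, axis=1)

    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    xn = np.sqrt((Xc**2).sum(axis=1))
    yn = np.sqrt((Yc**2).sum(axis=1))
    const_x, const_y = xn == 0, yn == 0
    if const_x.any() or const_y.any():
        logger.info(
            "skipping %d constant molecular and %d constant microbial features",
            int(const_x.sum()), int(const_y.sum()),
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        R = np.clip((Xc @ Yc.T) / np.outer(xn, yn), -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = R * np.sqrt((n - 2) / (1.0 - R**2))
    P = 2.0 * stats.t.sf(np.abs(tstat), n - 2)
    P[np.abs(R) == 1.0] = 0.0
    P[const_x, :] = np.nan
    P[:, const_y] = np.nan

    passing = np.isfinite(P) if threshold is None else np.isfinite(P) & (P < threshold)
    mz = molecular.meta["mz"] if "mz" in molecular.meta.columns else None
    mol_ids = molecular.feature_ids
    mic_ids = microbial.feature_ids
    edges = []
    for i, j in zip(*np.nonzero(passing)):
        r = float(R[i, j])
        edges.append(
            AssociationEdge(
                molecule_id=str(mol_ids[i]),
                microbe_id=str(mic_ids[j]),
                test=test,
                statistic=r,
                p_value=float(P[i, j]),
                sign=POSITIVE if r >= 0 else NEGATIVE,
                mz=float(mz.loc[mol_ids[i]]) if mz is not None else None,
            )
        )
    return edges


def association_scan(
    dataset: BinaryDataset | None = None,
    *,
    test: str = "fisher",
    threshold: float | None = 1e-10,
    molecular_table: FeatureTable | None = None,
    microbial_table: FeatureTable | None = None,
    log_transform: bool = False,
) -> list:
    """Evaluate every (molecule, microbe) pair and keep the passing edges.

    Fisher and mutual information run on a :class:`BinaryDataset`; Pearson
    and Spearman run on the paired abundance tables.  P-value tests keep
    pairs with ``p < threshold`` (strict); MI keeps ``mi >= threshold``.
    ``threshold=None`` keeps every evaluated pair, which is what the FDR
    machinery wants.  Output is sorted by (molecule id, microbe id) and is
    deterministic.
    """
    if test not in TESTS:
        raise ValueError(f"unknown test {test!r}; choose from {TESTS}")
    if test in ("fisher", "mutual_information"):
        if dataset is None:
            raise ValueError(f"{test} requires a BinaryDataset")
        edges = _binary_scan(
            dataset.molecules, dataset.microbes, dataset.samples, test, threshold
        )
    else:
        if molecular_table is None or microbial_table is None:
            raise ValueError(f"{test} requires molecular_table and microbial_table")
        edges = _continuous_scan(
            molecular_table, microbial_table, test, threshold, log_transform
        )
    edges.sort(key=lambda e: (e.molecule_id, e.microbe_id))
    return edges


_EDGE_COLUMNS = [
    "molecule_id", "microbe_id", "mz", "test", "statistic", "p_value",
    "sign", "q_value",
]


def edges_to_frame(edges) -> pd.DataFrame:
    """Flatten edges to the canonical TSV layout."""
    rows = [
        {
            "molecule_id": e.molecule_id,
            "microbe_id": e.microbe_id,
            "mz": e.mz,
            "test": e.test,
            "statistic": e.statistic,
            "p_value": e.p_value,
            "sign": e.sign,
            "q_value": e.q_value,
        }
        for e in edges
    ]
    return pd.DataFrame(rows, columns=_EDGE_COLUMNS)


def frame_to_edges(frame: pd.DataFrame) -> list:
    edges = []
    for row in frame.itertuples(index=False):
        p = getattr(row, "p_value", None)
        q = getattr(row, "q_value", None)
        mz = getattr(row, "mz", None)
        edges.append(
            AssociationEdge(
                molecule_id=str(row.molecule_id),
                microbe_id=str(row.microbe_id),
                test=str(row.test),
                statistic=float(row.statistic),
                p_value=None if p is None or pd.isna(p) else float(p),
                sign=str(row.sign),
                q_value=None if q is None or pd.isna(q) else float(q),
                mz=None if mz is None or pd.isna(mz) else float(mz),
            )
        )
    return edges


def write_edges(edges, path) -> None:
    edges_to_frame(edges).to_csv(path, sep="\t", index=False)


def read_edges(path) -> list:
    return frame_to_edges(pd.read_csv(path, sep="\t"))
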