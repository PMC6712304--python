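"""Benchmark harness: discoveries versus FDR across feature sets and tests.

Different molecular feature sets (feature extractors, binarization
thresholds) and association tests are compared by the number of
associations — and of distinct microbial features involved — discovered at
given FDR levels, under both target-decoy and BH control.  More discoveries
at matched FDR means more usable signal.  Binarization thresholds default
to the decade grid 10, 10^2, ..., 10^6.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assoc import P_VALUE_TESTS, association_scan
from .fdr import attach_bh, make_decoys, select_at_fdr
from .feature_io import BinaryDataset, FeatureTable, binarize, filter_prevalence

logger = logging.getLogger(__name__)

BINARIZATION_GRID = tuple(10.0**k for k in range(1, 7))


@dataclass
class BenchmarkDataset:
    """One molecular feature set to benchmark.

    ``mode`` is "binary" (Fisher / mutual information on presence sets) or
    "continuous" (Pearson / Spearman on intensities).
    """

    name: str
    molecular: FeatureTable
    mode: str = "binary"
    min_intensity: float = 0.0
    min_molecule_samples: int = 2


def _binary_dataset(ds: BenchmarkDataset, microbes, samples) -> BinaryDataset:
    molecules = filter_prevalence(
        binarize(ds.molecular, ds.min_intensity), ds.min_molecule_samples
    )
    return BinaryDataset(samples=samples, molecules=molecules, microbes=microbes)


def benchmark_methods(
    datasets,
    microbes,
    samples,
    microbial_table: FeatureTable | None = None,
    tests=("fisher",),
    fdr_levels=(0.01, 0.05, 0.2),
    seed: int = 0,
    n_per_target: int = 10,
) -> pd.DataFrame:
    """Count discoveries at each FDR level for every dataset x test.

    For each combination, all pairs are scored, a matched decoy scan is run,
    and edges are selected at each level by TDA; for P-value tests the BH
    route is tabulated alongside.  Returns one row per (dataset, test,
    fdr_method, fdr_level).
    """
    rows = []
    for ds in datasets:
        for test in tests:
            if test in ("fisher", "mutual_information"):
                data = _binary_dataset(ds, microbes, samples)
                real = association_scan(data, test=test, threshold=None)
                decoy_set = make_decoys(data.molecules, samples, seed, n_per_target)
                decoy_ds = BinaryDataset(
                    samples=samples, molecules=decoy_set.decoys, microbes=microbes
                )
                decoy = association_scan(decoy_ds, test=test, threshold=None)
            else:
                if microbial_table is None:
                    raise ValueError(f"{test} needs the continuous microbial table")
                real = association_scan(
                    test=test, threshold=None,
                    molecular_table=ds.molecular, microbial_table=microbial_table,
                )
                # decoys for continuous tests: permute each molecule's values
                rng = np.random.default_rng(seed)
                perm = ds.molecular.data.copy()
                decoy_frames = []
                for j in range(n_per_target):
                    shuffled = perm.to_numpy().copy()
                    for r in range(shuffled.shape[0]):
                        rng.shuffle(shuffled[r])
                    df = pd.DataFrame(
                        shuffled,
                        index=[f"decoy{j}:{i}" for i in perm.index],
                        columns=perm.columns,
                    )
                    decoy_frames.append(df)
                decoy_table = FeatureTable(
                    data=pd.concat(decoy_frames),
                    kind=ds.molecular.kind,
                    meta=pd.DataFrame(
                        {"mz": np.tile(ds.molecular.meta["mz"].to_numpy(), n_per_target)},
                        index=pd.concat(decoy_frames).index,
                    ),
                )
                decoy = association_scan(
                    test=test, threshold=None,
                    molecular_table=decoy_table, microbial_table=microbial_table,
                )
            if test in P_VALUE_TESTS and real:
                attach_bh(real)
            for level in sorted(fdr_levels):
                selected, _ = select_at_fdr(real, decoy, level, n_per_target)
                rows.append(_row(ds.name, test, "tda", level, selected))
                if test in P_VALUE_TESTS:
                    bh_sel = [e for e in real if e.q_value is not None and e.q_value <= level]
                    rows.append(_row(ds.name, test, "bh", level, bh_sel))
    return pd.DataFrame(rows)


def _row(name, test, method, level, edges) -> dict:
    return {
        "dataset": name,
        "test": test,
        "fdr_method": method,
        "fdr_level": level,
        "n_associations": len(edges),
        "n_unique_microbes": len({e.microbe_id for e in edges}),
    }


def plot_benchmark(table: pd.DataFrame, path) -> None:
    """Discoveries-vs-FDR curves, one line per (dataset, test, method)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharex=True)
    for (name, test, method), grp in table.groupby(["dataset", "test", "fdr_method"]):
        grp = grp.sort_values("fdr_level")
        label = f"{name}/{test}/{method}"
        axes[0].plot(grp["fdr_level"], grp["n_associations"], marker="o", label=label)
        axes[1].plot(grp["fdr_level"], grp["n_unique_microbes"], marker="o", label=label)
    axes[0].set_xlabel("FDR level")
    axes[0].set_ylabel("associations discovered")
    axes[1].set_xlabel("FDR level")
    axes[1].set_ylabel("unique microbial features")
    axes[0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
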