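"""Synthetic paired microbiome/metabolome data with known ground truth.

The generator emulates the statistical structure the association test
assumes: independent Bernoulli presence for background features, a
configurable number of planted (molecule, microbe) pairs whose molecule
presence depends on the microbe through two conditional probabilities, and
clusters of "duplicate" molecular features that share one latent presence
set (with independent dropout) and sit within an m/z jitter of a shared
centre.  Abundances are zero when absent and log-normal when present,
mimicking LC-MS zero inflation; binarizing with threshold 0 recovers the
underlying presence process exactly.

Defaults reflect a modest cohort: 200 samples, 100 molecules x 50 microbes,
30% background prevalence, planted conditionals (0.9 given the microbe,
0.02 given its absence).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .feature_io import MICROBIAL, MOLECULAR, FeatureTable

MZ_RANGE = (100.0, 1500.0)


@dataclass
class SimulationConfig:
    n_samples: int = 200
    n_molecules: int = 100
    n_microbes: int = 50
    background_presence: float = 0.3
    n_planted_pairs: int = 0
    planted_prob_present: float = 0.9   # P(molecule | microbe present)
    planted_prob_absent: float = 0.02   # P(molecule | microbe absent)
    n_duplicate_clusters: int = 0
    duplicate_cluster_size: int = 3
    duplicate_dropout: float = 0.05     # per-member, per-sample loss from the latent set
    mz_jitter: float = 0.004            # within-cluster m/z half-width, Thomson
    intensity_log_mean: float = 9.0     # log intensity when present (~8e3 median)
    intensity_log_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        probs = (
            self.background_presence, self.planted_prob_present,
            self.planted_prob_absent, self.duplicate_dropout,
        )
        if not all(0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.n_planted_pairs > min(self.n_molecules, self.n_microbes):
            raise ValueError("more planted pairs than features on one side")
        if self.mz_jitter < 0 or self.n_samples < 1:
            raise ValueError("inconsistent configuration")


@dataclass
class SimulationTruth:
    """Ground truth: planted pairs and duplicate-cluster memberships."""

    planted_pairs: list = field(default_factory=list)   # (molecule_id, microbe_id)
    duplicate_clusters: list = field(default_factory=list)  # list of id lists

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"kind": "planted", "molecule_id": m, "microbe_id": a, "cluster": ""}
            for m, a in self.planted_pairs
        ]
        rows += [
            {"kind": "duplicate", "molecule_id": mid, "microbe_id": "", "cluster": i}
            for i, cluster in enumerate(self.duplicate_clusters)
            for mid in cluster
        ]
        return pd.DataFrame(rows, columns=["kind", "molecule_id", "microbe_id", "cluster"])


def _intensities(presence: np.ndarray, rng, cfg: SimulationConfig) -> np.ndarray:
    vals = rng.lognormal(cfg.intensity_log_mean, cfg.intensity_log_sd, presence.shape)
    return np.where(presence, vals, 0.0)


def simulate(config: SimulationConfig) -> tuple[FeatureTable, FeatureTable, SimulationTruth]:
    """Draw one paired dataset; bit-reproducible from ``config.seed``."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    samples = [f"s{i:04d}" for i in range(cfg.n_samples)]
    mic_ids = [f"otu{i:04d}" for i in range(cfg.n_microbes)]
    mol_ids = [f"mol{i:04d}" for i in range(cfg.n_molecules)]

    mic_presence = rng.random((cfg.n_microbes, cfg.n_samples)) < cfg.background_presence
    mol_presence = rng.random((cfg.n_molecules, cfg.n_samples)) < cfg.background_presence

    truth = SimulationTruth()
    for i in range(cfg.n_planted_pairs):
        cond = np.where(mic_presence[i], cfg.planted_prob_present, cfg.planted_prob_absent)
        mol_presence[i] = rng.random(cfg.n_samples) < cond
        truth.planted_pairs.append((mol_ids[i], mic_ids[i]))

    mz = rng.uniform(*MZ_RANGE, cfg.n_molecules)

    dup_ids, dup_presence, dup_mz = [], [], []
    for c in range(cfg.n_duplicate_clusters):
        latent = rng.random(cfg.n_samples) < cfg.background_presence
        centre = rng.uniform(*MZ_RANGE)
        members = []
        for j in range(cfg.duplicate_cluster_size):
            kept = latent & (rng.random(cfg.n_samples) >= cfg.duplicate_dropout)
            fid = f"dup{c:03d}_{j}"
            members.append(fid)
            dup_ids.append(fid)
            dup_presence.append(kept)
            dup_mz.append(centre + rng.uniform(-cfg.mz_jitter, cfg.mz_jitter))
        truth.duplicate_clusters.append(members)

    mol_presence_all = (
        np.vstack([mol_presence] + [np.asarray(dup_presence)])
        if dup_ids else mol_presence
    )
    mol_ids_all = mol_ids + dup_ids
    mz_all = np.concatenate([mz, np.asarray(dup_mz)]) if dup_ids else mz

    microbial = FeatureTable(
        data=pd.DataFrame(
            _intensities(mic_presence, rng, cfg), index=mic_ids, columns=samples
        ).round(1),
        kind=MICROBIAL,
    )
    molecular = FeatureTable(
        data=pd.DataFrame(
            _intensities(mol_presence_all, rng, cfg), index=mol_ids_all, columns=samples
        ).round(1),
        kind=MOLECULAR,
        meta=pd.DataFrame({"mz": np.round(mz_all, 4)}, index=mol_ids_all),
    )
    return microbial, molecular, truth


def evaluate(edges, truth: SimulationTruth) -> tuple[float, float]:
    """(recall, empirical FDR) of an edge set against the planted pairs.

    Recall is the fraction of planted pairs present among the edges;
    empirical FDR the fraction of edges that are not planted.  An empty edge
    set has empirical FDR 0 by convention.  With no planted pairs recall
    is 1 vacuously.
    """
    planted = set(truth.planted_pairs)
    found = {(e.molecule_id, e.microbe_id) for e in edges}
    recall = 1.0 if not planted else len(planted & found) / len(planted)
    efdr = 0.0 if not found else len(found - planted) / len(found)
    return recall, efdr
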