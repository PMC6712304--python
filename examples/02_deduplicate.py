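"""Merge redundant LC-MS features into consensus features.

Feature extractors report one molecule as several features at nearly
identical m/z.  Here 5 planted triplets of duplicates (same latent presence
set, m/z jitter < 0.01 Th) are merged back by the m/z + cooccurrence graph.
"""

from assocnet import SimulationConfig, binarize, deduplicate, simulate

cfg = SimulationConfig(
    n_samples=200, n_molecules=60, n_microbes=5,
    n_duplicate_clusters=5, duplicate_cluster_size=3, seed=7,
)
_, molecular, truth = simulate(cfg)
features = binarize(molecular, 0)

groups = deduplicate(features, mz_tol=0.01, p_threshold=1e-5, n_samples=cfg.n_samples)
merged = [g for g in groups if len(g.member_ids) > 1]
print(f"{len(features)} molecular features -> {len(groups)} consensus features")
print(f"merged groups: {len(merged)} (planted duplicate clusters: "
      f"{len(truth.duplicate_clusters)})")
for g in merged:
    print(f"  {g.consensus_id}: members={sorted(g.member_ids)}, "
          f"consensus m/z={g.consensus_mz:.4f}, "
          f"present in {len(g.consensus_sample_set)} samples")
print("\neach consensus feature carries the mean m/z and the union of its "
      "members' presence sets")
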