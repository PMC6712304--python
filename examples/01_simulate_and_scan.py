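"""Generate a paired microbiome/metabolome cohort and scan for associations.

Plants 8 dependent (molecule, microbe) pairs in an otherwise independent
background, binarizes both tables, and runs the all-pairs Fisher scan at a
stringent P threshold.
"""

from assocnet import SimulationConfig, association_scan, evaluate, make_binary_dataset, simulate

cfg = SimulationConfig(
    n_samples=200, n_molecules=100, n_microbes=50, n_planted_pairs=8, seed=42
)
microbial, molecular, truth = simulate(cfg)
print(f"simulated {cfg.n_samples} samples, "
      f"{molecular.n_features} molecular x {microbial.n_features} microbial features")

# presence = abundance strictly above the threshold (MinCount / MinIntensity = 0);
# molecular features seen in < 2 samples are dropped
dataset = make_binary_dataset(microbial, molecular, min_count=0, min_intensity=0)

edges = association_scan(dataset, test="fisher", threshold=1e-10)
recall, efdr = evaluate(edges, truth)
print(f"\nedges with two-sided Fisher P < 1e-10: {len(edges)}")
for e in edges[:3]:
    print(f"  {e.molecule_id} -- {e.microbe_id}: P = {e.p_value:.3g}, sign = {e.sign}")
print(f"\nrecall of the 8 planted pairs: {recall:.2f}; "
      f"fraction of reported edges that are spurious: {efdr:.2f}")
print("(a recall of 1 with no spurious edges means the scan found exactly "
      "the planted dependencies)")
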