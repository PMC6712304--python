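# Methods

This note records the statistical model behind `assocnet`, the parameters
that matter, the numerical choices, and what the synthetic-data tests do and
do not demonstrate.

## Presence model and the association test

All association statistics operate on presence sets. A feature X is present
in sample S when its abundance strictly exceeds a threshold: `MinCount` for
microbial count tables (default 0, so a zero count is absent) and
`MinIntensity` for LC-MS intensity tables (default 0; typical real-data
values are 10³–10⁶ and a decade grid of them is what the benchmark harness
sweeps). Molecular features present in fewer than two samples are removed —
a feature seen once can never produce a meaningful 2×2 table — and rare
BGC-family features are conventionally filtered at ten samples.

For molecule X and microbe A over n paired samples, the table
(a, b, c, d) = (both, X only, A only, neither) is tested against the null
that the two presence events are independent. The two-sided exact P is the
sum of hypergeometric point probabilities (margins fixed) not exceeding the
observed one. Implementation: the full pmf support for a margin pair
(|Samples_X|, |Samples_A|, n) is computed once with `scipy.stats.hypergeom`
and cached, so an all-pairs scan costs one pmf vector per distinct margin
pair rather than one exact-test call per pair. Floating-point pmf ties are
compared with a relative slack of 10⁻⁷; for n ≤ 30 the smallest nonzero
relative gap between distinct point probabilities is ~10⁻³, so the slack
captures exact rational ties and nothing else (verified against an
integer-arithmetic enumeration oracle in the tests).

The test is two-sided because both directions are scientifically
meaningful: positive edges suggest production, negative edges suggest
consumption or transformation of a precursor. The sign is recovered
separately by comparing observed co-presence with its independence
expectation, a·n vs (a+b)(a+c) — well defined even with empty cells, unlike
an odds ratio. Exact equality is called positive and logged.

Pearson and Spearman run on raw intensities (no transform by default; a
log10(1+x) option exists because zero-inflated intensities span decades),
with the usual t(n−2) two-sided P. Constant vectors are skipped with a
logged reason rather than raised, since all-pairs scans routinely meet
degenerate features. Mutual information is the plug-in estimate on the two
presence indicators, in bits, with 0·log 0 = 0; it carries no P value, so
the target-decoy route is its only FDR control.

## Target-decoy FDR

For every molecule X a decoy X_d receives a uniformly random sample subset
of the same size — null by construction while preserving the prevalence
distribution. After scanning decoys against the identical microbial
features, the FDR at a threshold is estimated as
`n_decoy / (n_per_target · n_real)`, capped at 1 and defined as 1 when no
real association passes.

Selection at a target q walks the real edges from strongest to weakest
score and keeps the largest prefix whose estimate is ≤ q (ties in score are
kept together). The package defaults to, and its own analyses use,
**n_per_target = 10** decoys per target. With a single decoy the
zero-correction ratio is anticonservative at small counts: under the null
the k strongest combined scores are all targets with probability ~2^(−k),
so tiny all-target prefixes with estimated FDR 0 are routinely selected.
Ten decoys per target shrink that probability to ~11^(−k) and reduce the
variance of the estimate roughly tenfold at negligible cost (the decoy scan
is vectorised over cached margins). Calibration is verified empirically: on
twenty pure-null cohorts the across-seed mean false-discovery proportion of
sets selected at q ∈ {0.05, 0.2} stays below q + 3 binomial standard
errors, while planted near-deterministic pairs are still recovered
essentially completely at q = 0.01.

For continuous tests the presence-set decoy construction does not apply;
the benchmark harness instead permutes each molecular feature's intensity
vector across samples, which preserves the marginal and breaks the pairing.

BH adjustment (statsmodels' step-up implementation, verified against the
by-definition computation) is applied over the full molecule × microbe
family — that is the family actually searched, so per-molecule adjustment
would understate multiplicity.

## Deduplication

Two molecular features are putative duplicates when |Δm/z| ≤ 0.01 Th
(absolute, not ppm), their cooccurrence is significant (Fisher P ≤ 10⁻⁵,
fixed cutoff, deliberately not multiplicity-corrected — it is a redundancy
heuristic, not an inference), and the cooccurrence is *positive*. The sign
gate matters: a two-sided P alone would merge perfectly anti-correlated
features, which are two different molecules, not one reported twice.
Duplicate groups are connected components of the pair graph; transitive
chaining can merge features whose pairwise Δm/z exceeds the tolerance,
which is accepted as part of the component definition. Each group's
consensus carries the unweighted mean m/z and the union sample set; the
consensus id is `dedup:` plus the lexicographically smallest member id
(singletons pass through unchanged). Candidate pairs come from a sliding
window over m/z-sorted features, so only m/z-compatible pairs are ever
tested — necessary at 10⁴–10⁵ features.

## Network and clades

The association network is strictly bipartite (asserted on every build);
nodes are exactly the features incident to at least one retained edge.
"Modules" are plain connected components — no community-detection method is
imposed — with a deterministic size-then-name ordering. GraphML export
round-trips attributes exactly.

Clade assignment reads the P-percent rule as *coverage*: the chosen clade
must contain ≥ P% (default 80) of **all** the molecule's positively
associated leaves. The alternative reading (≥ P% of the clade's leaves are
marked) makes any single marked leaf trivially optimal and is rejected.
"Minimal" means fewest leaves; ties break toward the deeper node, then
post-order index, so the result is deterministic. Candidates are internal
non-root nodes only — a single leaf is a species, not a clade, so
single-leaf evidence maps to the parent cherry — and an assignment is
reported only when the winning clade is a proper subtree of the pruned
tree. Counting marked leaves is one post-order pass; the tests check it
against exhaustive subtree enumeration on hundreds of random trees.
Newick input is handled by dendropy with underscores preserved; trees with
a basal polytomy are midpoint-rooted with a warning, and parsed trees are
always treated as rooted.

## Synthetic data

The generator emulates exactly the structure the Fisher null assumes, plus
the two violations the pipeline must handle:

* independent Bernoulli presence for background features (default
  prevalence 0.3 — mid-range for common gut taxa and detectable
  metabolites, and the regime where the 2×2 test is most informative);
* planted pairs where P(molecule | microbe present) = 0.9 and
  P(molecule | microbe absent) = 0.02 — "near-deterministic" dependence
  whose P values sit tens of orders of magnitude below the null minimum;
* duplicate clusters sharing one latent presence set with 5% per-member
  dropout and ±0.004 Th m/z jitter around a shared centre (inside the
  0.01 Th tolerance by construction);
* intensities that are log-normal (median ~8×10³) when present and exactly
  0 when absent, mimicking LC-MS zero inflation; binarizing at 0 recovers
  the presence process.

Default problem sizes (200 samples, 100 molecules × 50 microbes, 20 seeds
for calibration runs, 10 for benchmark comparisons) were chosen so every
property — null calibration, planted recovery, duplicate merging — is
measured on thousands to tens of thousands of pairwise tests while a full
verification run stays in the minutes range on one core.

What passing these tests shows: the statistics, the decoy machinery, the
graph operations and the clade rule are implemented correctly and are
calibrated under their own model. What it does not show: robustness to
compositionality, sequencing-depth and batch effects, correlated taxa, or
confounding by host covariates — real cohorts violate feature independence,
and the decoy estimate can be optimistic there. A correlated-background
stress option (shared latent factor) is a natural extension hook; partial
correlations and compositionality-aware measures are out of scope.

## Known limitations

* Fisher P values on sparse features are discrete and conservative;
  extremely prevalent or rare features carry little information either way.
* The TDA ratio is an estimate, not a guarantee; at very small discovery
  counts it remains noisy even with ten decoys per target.
* Deduplication is not isotope/adduct-aware and ignores retention time.
* Mutual information is thresholded on the statistic itself; comparisons
  across sample sizes should use TDA-matched levels, not raw bits.
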