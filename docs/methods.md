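# Methods

## Model

A biallelic SNP assay yields per-sample probe intensities
(v_A, v_B) ≥ 0 in arbitrary MFI units. The working variable is the
normalized intensity φ = v_A/(v_A + v_B); the summed intensity
v_A + v_B carries no genotype information but measures signal quality
and is used for the threshold filter and as the plot's log axis. The
method assumes that, within one SNP, samples of the same genotype form
a unimodal cluster in φ and that with ≥ 30 clustered samples the
within-cluster φ distribution is adequately approximated as normal
(central-limit reasoning); below 30 samples calls are still produced
but flagged `small_sample`, since both the cut-offs and the interval
coverage lose their justification.

Genotype assignment is purely interval-based: no mixture model or EM
is fitted. A cluster's interval is mean ± U_{1−α/2}·σ with σ the
*sample* standard deviation (ddof = 1; a choice this package makes —
standard for interval construction) and deliberately **without** the
1/√n factor: the interval must cover the cluster's members, not
estimate its mean. Samples outside every interval become `NA` rather
than being forced into the nearest cluster; the design premise is that
experimental variation the model cannot capture should surface as
no-calls, never as wrong calls.

## Cut-offs

Three methods produce the (CoD, CoU) pair that seeds the three
candidate groups (intervals [0; CoD[, [CoD; CoU[, [CoU; 1], half-open
exactly so):

* **arbitrary** — (0.3, 0.7), appropriate when clusters sit at their
  mathematical positions, and the recommended choice for monoallelic
  SNPs where the data-driven formula is skewed;
* **experimental** (default) — CoU = max(v_A)/(max(v_A)+m),
  CoD = m/(max(v_B)+m), m = min[max(v_A), max(v_B), pooled mean of all
  v_A and v_B]. With symmetric maxima and pooled mean r·M this gives
  CoU = 1/(1+r): anchor values (r, CoU) = (1/2, 2/3), (1/3, 3/4),
  (2/3, 3/5), (1, 1/2), frozen as regression tests. The functional
  form was reconstructed from those anchor values; it is the unique
  simple ratio form reproducing all of them. At r = 1 the raw pair
  degenerates to CoD = CoU = 1/2 (provably CoD ≤ CoU always, equality
  iff max(v_A) = max(v_B) = pooled mean), which is why `CutoffPair`
  admits equality for raw pairs; the clamp control restores strict
  ordering.
* **manual** — a per-SNP file entry (CoD < CoU strictly, both in
  (0,1)). A manual entry overrides any configured method and is exempt
  from clamping: the user override wins.

## Quality controls

1. **Threshold** — total intensity < threshold (default 300) ⇒ `THR`,
   excluded from cut-off computation and clustering. A zero-total
   sample has undefined φ and is `THR` under any positive threshold
   (reason `zero_total` when the threshold is 0).
2. **Clamp** — computed CoU is raised to ≥ 0.6 and CoD lowered to
   ≤ 0.4 so three clusters stay representable; idempotent, flags
   recorded.
3. **Dominant-cluster recheck** — when one group holds strictly more
   than 80% of threshold-passing samples (the fraction is computed
   over non-THR samples, since THR samples never enter clustering),
   experimental cut-offs are recomputed from that group alone and its
   members re-partitioned. If they stay in one group the first round
   is validated; if they split, the second-round (clamped) pair is
   adopted and *all* samples re-partitioned before boundaries are
   computed. One second round only, and only under the experimental
   method — the recomputation is meaningless for the arbitrary
   constants and must not override a manual file. Note a sensitivity:
   because the recomputed CoU sits at max(v_A)/(max(v_A)+max(v_B))
   within the dominant group, a noisy but genuinely single cluster
   whose φ values straddle that point can trigger the adopted branch;
   the control is intentionally aggressive in flagging dominance, and
   the rerun is always recorded (`dominant_cluster_rerun`) so such
   assays can be inspected.
4. **Overlap resolution** — adjacent intervals that overlap are made
   flanking by moving both boundaries to the midpoint of the two old
   boundary values; pairs are processed low↔mid then mid↔high.
   Idempotent, and the union of intervals is unchanged (the midpoint
   splits it), which is what makes the no-call count provably
   monotone in interval width and hence in decreasing α. A φ exactly
   on a shared boundary goes to the upper cluster, consistent with the
   half-open cut-off convention. In the pathological containment case
   where resolution would invert an interval, the interval collapses
   to a point and the assay is flagged `interval_collapsed`.
5. **Silhouette** — mean silhouette width over called points with
   distances = |Δφ| (1-D; φ is the clustering variable, so the
   log-total axis is excluded from distances). Per point
   s = (b−a)/max(a,b); singleton-cluster members score 0; fewer than
   two populated clusters ⇒ not applicable. Bands: accept > 0.65,
   fail < 0.25, inspect in [0.25, 0.65]. The implementation is a
   brute-force O(n²) pairwise computation; tests cross-check it
   against a general-purpose library implementation to 1e-9.
6. **HWE** — Pearson χ² of observed genotype counts against
   p̂²/2p̂q̂/q̂² with p̂ = (2·n_AA + n_AB)/2n, 1 df, upper-tail p-value.
   Informational only (ascertainment can bias it legitimately); never
   rejects an assay; not computed for multi-allelic sub-assays, whose
   membership is probe-ranked rather than population-sampled.

Cluster-interval membership is closed at both endpoints (the
cut-off intervals' half-open convention is not carried over), so a
degenerate σ = 0 cluster still calls its own members; endpoint ties
between adjacent intervals go to the upper cluster. Singleton groups
get a point interval plus a `singleton_cluster` warning.

## Multi-allelic decomposition

For k ≥ 3 probes each sample is routed to the biallelic sub-assay of
its two brightest probes (at most k(k−1)/2 sub-assays). A tie between
the 2nd and 3rd brightest probes breaks the background-noise premise,
so such samples are called `NA` with reason `ambiguous_probe_rank`
rather than routed arbitrarily. Sub-assays below 30 members are called
with the small-sample warning rather than skipped — the warning, not
suppression, is the mechanism for communicating unreliability. Each
sub-assay computes its own cut-offs; merged labels are the sorted
allele pair (`AT`, `GG`).

## Synthetic data generator

`simulate.SimulationParams` emulates the structure of plate-style MFI
data: genotypes drawn from HWE proportions at a given allele
frequency; "on" probes lognormal with mean 2000 and CV 0.08; "off"
probes lognormal with mean 60 and CV 0.3; heterozygotes split the
signal mean per `het_balance` (default 0.5); `imbalance` multiplies
the A probe everywhere; `threshold_fail_fraction` scales a random
subset of samples by 0.05 so they land under the default threshold.
Defaults were chosen as a realistic clean assay: cluster means near
0.97/0.50/0.03 in φ, heterozygote φ spread ≈ 0.35·CV ≈ 0.03, totals
≈ 2060 (≈ 7× the threshold). Lognormal noise is a structural choice —
fluorescence is positive and right-skewed — not a claim of
distributional fidelity to bead chemistry; the generator also omits
plate spatial effects, bead-count variation, cross-hybridisation and
probe-sequence effects. Passing tests therefore demonstrate that the
algorithm recovers truth when its own model assumptions (separable,
roughly normal φ clusters) hold, not that it survives every real-world
pathology; the QC warnings are the designed channel for the latter.

With the default generator at α = 0.05, the expected no-call rate is
essentially the interval miss rate: ≈ α for the two-sided heterozygote
interval and ≈ α/2 for each clamped homozygote interval, ≈ 3.5–5%
overall, which is why a clean assay still shows a few percent `NA`.

## Problem sizes and numerics

The test suite and the acceptance script use 20 seeded assays of
n = 300 for accuracy/no-call measurement, 10,000 multinomial draws at
n = 200 for HWE type-I calibration, 100 random labelled datasets for
the silhouette cross-check and one 600-sample 3-allele assay for
multi-allelic recovery — sizes at which the measured rates' Monte
Carlo error is well inside the tolerances asserted, while the whole
suite runs in seconds. Normal quantiles come from `scipy.stats.norm`;
tests verify them against the standard library's independent
`statistics.NormalDist`. All randomness flows through
`numpy.random.default_rng` seeds; the acceptance script derives
per-component streams from a single `SeedSequence`.

## Known limitations

* The interval method has no notion of cluster shape beyond mean ± U·σ
  in φ; heavy-tailed or skewed clusters inflate the no-call rate.
* The dominant-cluster recheck can adopt second-round cut-offs for a
  noisy single cluster (see above); inspect assays with the
  `dominant_cluster_rerun` warning.
* Experimental cut-offs are undefined when a probe is entirely dark;
  the arbitrary method is the documented fallback for monoallelic
  SNPs.
* One intensity per (sample, allele) is assumed; replicate wells must
  be aggregated upstream.
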