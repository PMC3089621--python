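"""The quality controls in isolation: clamp, overlap, silhouette, HWE.

Each block feeds a small constructed input to one control and prints
what it does: the 0.6/0.4 clamp repairing a degenerate cut-off pair,
overlap resolution moving two colliding cluster boundaries to their
midpoint, the silhouette score separating a clean from a smeared
assay, and the Hardy-Weinberg chi-square test on genotype counts.
"""

import numpy as np

from beadcall.data import ClusterInterval, ClusterModel, CutoffPair
from beadcall.qc import (
    clamp_cutoffs,
    hwe_test,
    resolve_overlap,
    silhouette_band,
    silhouette_width,
)

# --- cut-off clamping: CoU is lifted to >= 0.6, CoD pushed to <= 0.4
raw = CutoffPair(cod=0.48, cou=0.52, method="experimental")
clamped = clamp_cutoffs(raw)
print(f"clamp: ({raw.cod}, {raw.cou}) -> ({clamped.cod}, {clamped.cou})")

# --- overlap resolution: boundaries meet at the midpoint 0.60
model = ClusterModel(
    intervals={
        "homB": None,
        "het": ClusterInterval(40, 0.50, 0.06, 0.35, 0.62),
        "homA": ClusterInterval(30, 0.95, 0.02, 0.58, 1.0),
    },
    alpha=0.05, u_quantile=1.959964,
)
resolved = resolve_overlap(model)
print(f"overlap: het hi 0.62 / homA lo 0.58 -> breakpoint "
      f"{resolved.intervals['het'].hi:.2f}; phi=0.60 calls as "
      f"{resolved.genotype_of(0.60)}")

# --- silhouette: tight separated clusters score near 1, smeared ones low
rng = np.random.default_rng(0)
for sd, desc in ((0.01, "tight"), (0.15, "smeared")):
    phis = np.concatenate([rng.normal(0.1, sd, 50), rng.normal(0.5, sd, 50),
                           rng.normal(0.9, sd, 50)]).clip(0, 1)
    labels = ["homB"] * 50 + ["het"] * 50 + ["homA"] * 50
    score = silhouette_width(phis, labels)
    print(f"silhouette ({desc} clusters, sd={sd}): {score:.3f} "
          f"[{silhouette_band(score)}]")

# --- HWE: exact proportions give chi2 = 0; a het deficit is flagged
for counts in ((25, 50, 25), (40, 20, 40)):
    result = hwe_test(*counts)
    print(f"HWE {counts}: chi2={result.chi2:.2f}, p={result.p:.3g} "
          "(informational only)")
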