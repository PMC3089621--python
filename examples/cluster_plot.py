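"""Render the diagnostic cluster plot for a simulated 91-sample assay.

The plot shows each sample at (phi, log10 of summed intensity), colour
coded by call (A-homozygote blue, heterozygote black, B-homozygote
green, no-calls red), with bracket marks at the cluster
confidence-interval boundaries and the silhouette score and HWE
p-value annotated.  Output lands in scratch/ as PNG and SVG.
"""

from pathlib import Path

from beadcall import call_assay
from beadcall.plot import render_cluster_plot
from beadcall.simulate import SimulationParams, simulate_assay

assay, _ = simulate_assay(SimulationParams(n_samples=91, seed=6))
result = call_assay(assay)

outdir = Path(__file__).resolve().parent.parent / "scratch"
outdir.mkdir(exist_ok=True)
for suffix in (".png", ".svg"):
    path = render_cluster_plot(result, outdir / f"clusters{suffix}")
    print(f"wrote {path}")
print(f"calls: {result.call_counts}")
print(f"silhouette = {result.qc.silhouette:.3f}, HWE p = {result.qc.hwe_p:.3f}")
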