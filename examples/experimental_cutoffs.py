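"""How the experimental cut-offs track the mean-to-max intensity ratio.

With symmetric probe maxima M and a pooled intensity mean of r*M, the
upper cut-off is CoU = 1/(1+r): a well-behaved assay (r near 1/2)
lands near the theoretical 0.7/0.3 pair, while skewed intensity
distributions move the pair with the data.  The printed values are the
formula's anchor points; the last one (ratio 1) collapses to 1/2 and
is what the 0.6/0.4 clamp quality control exists to repair.
"""

from beadcall import cutoffs_experimental
from beadcall.qc import clamp_cutoffs

M = 1000.0
cases = {
    "1/2": ([M, 0.0], [0.0, M]),
    "1/3": ([M, 0.0, 0.0], [0.0, M, 0.0]),
    "2/3": ([M, M, 0.0], [M, M, 0.0]),
    "1":   ([M, M], [M, M]),
}
for ratio, (va, vb) in cases.items():
    pair = cutoffs_experimental(va, vb)
    clamped = clamp_cutoffs(pair)
    note = ""
    if clamped.cou_clamped or clamped.cod_clamped:
        note = f"  -> clamped to CoD={clamped.cod:.3f}, CoU={clamped.cou:.3f}"
    print(f"mean-max ratio {ratio:>3}: CoD={pair.cod:.4f}, CoU={pair.cou:.4f}{note}")
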