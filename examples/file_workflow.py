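"""The file-based workflow: MFI table in, calls CSV and QC report out.

Writes a simulated assay to the canonical long format (one row per
sample/SNP/allele measurement), reads it back, calls it, and writes
the per-sample calls CSV plus the JSON QC sidecar — the same artifacts
the `beadcall call` command produces.
"""

import json
from pathlib import Path

from beadcall import call_assay
from beadcall.io import read_long_table, write_calls, write_long_table
from beadcall.simulate import SimulationParams, simulate_assay

outdir = Path(__file__).resolve().parent.parent / "scratch"
outdir.mkdir(exist_ok=True)

assay, _ = simulate_assay(SimulationParams(n_samples=60, seed=9))
mfi_path = outdir / "assay.csv"
write_long_table(mfi_path, [assay])
print(f"wrote {assay.n_samples * assay.n_alleles} measurements -> {mfi_path}")

for loaded in read_long_table(mfi_path):
    result = call_assay(loaded)
    calls_path = outdir / f"{loaded.snp_id}.calls.csv"
    write_calls(calls_path, result)
    report = json.loads(
        (outdir / f"{loaded.snp_id}.calls.csv.qc.json").read_text()
    )
    print(f"{loaded.snp_id}: wrote {calls_path}")
    print(f"  calls: {result.call_counts}")
    print(f"  QC report: silhouette {report['silhouette']['score']:.3f} "
          f"({report['silhouette']['band']}), warnings {report['warnings']}")
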