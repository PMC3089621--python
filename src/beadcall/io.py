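"""Readers and writers for the tabular artifacts of a calling run.

Canonical input is a long-format delimited text file with one row per
(sample, SNP, allele) measurement::

    sample,snp,allele,mfi
    s001,rs2267437,A,1890.5
    s001,rs2267437,B,95.0

A secondary plate-style wide reader accepts one column pair per SNP
(``<snp>_<allele>`` headers, sample ids in the first column), the shape
fluorescence readers typically export.  MFI values are taken as
already-summarized per-well means/medians; no bead-level aggregation
happens here.

Outputs are a per-sample calls CSV and a JSON quality-control sidecar
per run (cut-offs used, cluster intervals, silhouette, HWE, warnings).
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data import (
    AssayData,
    GenotypeCall,
    InputError,
    ManualCutoffEntry,
)

#: Column order of the calls CSV.  ``call`` always holds the label
#: (genotype, NA or THR); ``genotype`` is empty for NA/THR rows.
CALL_COLUMNS = ("sample", "snp", "call", "genotype", "phi", "total", "reason")

_DEFAULT_COLUMNS = ("sample", "snp", "allele", "mfi")


def _validate_mfi_column(df: pd.DataFrame, mfi_col: str, path) -> pd.Series:
    mfi = pd.to_numeric(df[mfi_col], errors="coerce")
    bad = mfi.isna() | (mfi < 0) | ~np.isfinite(mfi)
    if bad.any():
        line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
        raise InputError(
            f"{path}: invalid MFI value {df[mfi_col][bad.idxmax()]!r} "
            f"at line {line} (must be a non-negative number)"
        )
    return mfi.astype(float)


def read_long_table(
    path,
    *,
    delimiter: str = ",",
    columns: Sequence[str] = _DEFAULT_COLUMNS,
) -> list[AssayData]:
    """Read a long-format MFI table into one AssayData per SNP.

    ``columns`` names the (sample, snp, allele, mfi) headers in order,
    for exports with different labels.  Assays are returned sorted by
    SNP id; alleles are ordered lexicographically and samples by first
    appearance.  Duplicate (sample, snp, allele) rows, non-numeric or
    negative intensities, and missing probe cells raise
    :class:`InputError` naming the offending row.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"input file not found: {path}")
    sample_col, snp_col, allele_col, mfi_col = columns
    df = pd.read_csv(path, sep=delimiter, skipinitialspace=True, dtype=str)
    df.columns = [c.strip() for c in df.columns]
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise InputError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
        )
    if df.empty:
        return []
    for col in (sample_col, snp_col, allele_col):
        df[col] = df[col].astype(str).str.strip()
    mfi = _validate_mfi_column(df, mfi_col, path)

    dup = df.duplicated(subset=[sample_col, snp_col, allele_col], keep="first")
    if dup.any():
        line = int(dup.idxmax()) + 2
        row = df.loc[dup.idxmax()]
        raise InputError(
            f"{path}: duplicate measurement for sample {row[sample_col]!r}, "
            f"SNP {row[snp_col]!r}, allele {row[allele_col]!r} at line {line}"
        )

    assays = []
    for snp_id in sorted(df[snp_col].unique()):
        sub = df[df[snp_col] == snp_id]
        alleles = tuple(sorted(sub[allele_col].unique()))
        samples = tuple(dict.fromkeys(sub[sample_col]))  # first appearance
        matrix = np.full((len(samples), len(alleles)), np.nan)
        sample_index = {s: i for i, s in enumerate(samples)}
        allele_index = {a: j for j, a in enumerate(alleles)}
        for idx in sub.index:
            matrix[sample_index[sub.at[idx, sample_col]],
                   allele_index[sub.at[idx, allele_col]]] = mfi[idx]
        holes = np.argwhere(np.isnan(matrix))
        if holes.size:
            i, j = holes[0]
            raise InputError(
                f"{path}: SNP {snp_id!r} is missing the {alleles[j]!r} probe "
                f"for sample {samples[i]!r}"
            )
        assays.append(AssayData(snp_id=snp_id, alleles=alleles,
                                samples=samples, mfi=matrix))
    return assays


def write_long_table(path, assays: Iterable[AssayData], *, delimiter: str = ",") -> None:
    """Write assays back to the canonical long format (full precision)."""
    rows = []
    for assay in assays:
        for record in assay.records():
            rows.append((record.sample_id, record.snp_id, record.allele,
                         repr(record.mfi)))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(delimiter.join(_DEFAULT_COLUMNS) + "\n")
        for row in rows:
            fh.write(delimiter.join(row) + "\n")


def read_wide_table(path, *, delimiter: str = ",") -> list[AssayData]:
    """Read a plate-style wide export: one ``<snp>_<allele>`` column pair per SNP.

    The first column holds sample ids; every other header must contain
    an underscore separating the SNP id from the allele label (the last
    underscore splits, so SNP ids may themselves contain underscores).
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"input file not found: {path}")
    df = pd.read_csv(path, sep=delimiter, skipinitialspace=True, dtype=str)
    df.columns = [c.strip() for c in df.columns]
    if df.shape[1] < 3:
        raise InputError(
            f"{path}: wide format needs a sample column plus at least one "
            "probe column pair"
        )
    sample_col = df.columns[0]
    long_rows = []
    for col in df.columns[1:]:
        if "_" not in col:
            raise InputError(
                f"{path}: probe column {col!r} is not of the form <snp>_<allele>"
            )
        snp_id, allele = col.rsplit("_", 1)
        for idx in df.index:
            long_rows.append((str(df.at[idx, sample_col]).strip(), snp_id,
                              allele, df.at[idx, col]))
    long_df = pd.DataFrame(long_rows, columns=_DEFAULT_COLUMNS)
    mfi = _validate_mfi_column(long_df, "mfi", path)
    long_df["mfi"] = mfi

    assays = []
    for snp_id in sorted(long_df["snp"].unique()):
        sub = long_df[long_df["snp"] == snp_id]
        pivot = sub.pivot(index="sample", columns="allele", values="mfi")
        pivot = pivot.loc[list(dict.fromkeys(sub["sample"])),
                          sorted(pivot.columns)]
        assays.append(AssayData(
            snp_id=snp_id,
            alleles=tuple(pivot.columns),
            samples=tuple(pivot.index),
            mfi=pivot.to_numpy(dtype=float),
        ))
    return assays


def read_manual_cutoffs(path, *, delimiter: str = ",") -> dict[str, ManualCutoffEntry]:
    """Read a manual cut-off file: one ``snp, CoD, CoU`` row per SNP.

    Blank lines and ``#`` comments are skipped; an empty file yields an
    empty mapping.  Each entry is validated (both values in (0, 1),
    CoD < CoU) and manual pairs are exempt from the 0.6/0.4 clamp.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"manual cut-off file not found: {path}")
    entries: dict[str, ManualCutoffEntry] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = [f.strip() for f in line.split(delimiter)]
            if len(fields) != 3:
                raise InputError(
                    f"{path}: line {lineno}: expected 'snp{delimiter} CoD"
                    f"{delimiter} CoU', got {line!r}"
                )
            snp_id = fields[0]
            try:
                cod, cou = float(fields[1]), float(fields[2])
            except ValueError as exc:
                raise InputError(
                    f"{path}: line {lineno}: non-numeric cut-off in {line!r}"
                ) from exc
            if snp_id in entries:
                raise InputError(
                    f"{path}: line {lineno}: duplicate entry for SNP {snp_id!r}"
                )
            entries[snp_id] = ManualCutoffEntry(snp_id=snp_id, cod=cod, cou=cou)
    return entries


def _fmt(value: float | None) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return ""
    return repr(float(value))


def write_calls(path, result, *, delimiter: str = ",", report_path=None) -> None:
    """Write one run's calls CSV plus its JSON QC sidecar report.

    ``result`` is an :class:`beadcall.calling.AssayResult`.  The calls
    file has columns :data:`CALL_COLUMNS`; the sidecar (default:
    calls path with a ``.qc.json`` suffix) carries the cut-offs used,
    the cluster intervals, silhouette score and band, the HWE test and
    all warnings.
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(delimiter.join(CALL_COLUMNS) + "\n")
        for call in result.calls:
            genotype = call.label if call.is_genotype else ""
            fh.write(delimiter.join((
                call.sample_id, result.snp_id, call.label, genotype,
                _fmt(call.phi), _fmt(call.total), call.reason or "",
            )) + "\n")
    if report_path is None:
        report_path = path.with_suffix(path.suffix + ".qc.json")
    with open(report_path, "w", encoding="utf-8") as fh:
        json.dump(qc_report_dict(result), fh, indent=2)
        fh.write("\n")


def qc_report_dict(result) -> dict:
    """Serializable QC summary of one AssayResult."""
    model = result.model
    intervals = {}
    for genotype, interval in model.intervals.items():
        if interval is None:
            intervals[genotype] = None
        else:
            intervals[genotype] = {
                "n": interval.n, "mean": interval.mean, "sd": interval.sd,
                "lo": interval.lo, "hi": interval.hi,
                "singleton": interval.singleton,
            }
    qc = result.qc
    return {
        "snp": result.snp_id,
        "alpha": model.alpha,
        "cutoffs": {
            "cod": result.cutoffs.cod,
            "cou": result.cutoffs.cou,
            "method": result.cutoffs.method,
            "cod_clamped": result.cutoffs.cod_clamped,
            "cou_clamped": result.cutoffs.cou_clamped,
        },
        "intervals": intervals,
        "call_counts": result.call_counts,
        "silhouette": {"score": qc.silhouette, "band": qc.silhouette_band},
        "hwe": {"chi2": qc.hwe_chi2, "p": qc.hwe_p, "df": qc.hwe_df},
        "dominant_cluster_recheck": result.rerun_flag,
        "warnings": qc.warnings,
    }


def read_calls(path, *, delimiter: str = ",") -> list[GenotypeCall]:
    """Parse a calls CSV back into GenotypeCall objects (round-trip)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"calls file not found: {path}")
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    missing = [c for c in CALL_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing call column(s) {missing}")
    calls = []
    for _, row in df.iterrows():
        phi = float(row["phi"]) if row["phi"] else math.nan
        total = float(row["total"]) if row["total"] else math.nan
        calls.append(GenotypeCall(
            sample_id=row["sample"], label=row["call"], phi=phi, total=total,
            reason=row["reason"] or None,
        ))
    return calls


__all__ = [
    "CALL_COLUMNS",
    "read_long_table",
    "write_long_table",
    "read_wide_table",
    "read_manual_cutoffs",
    "write_calls",
    "read_calls",
    "qc_report_dict",
]
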