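"""Core data containers shared across the calling pipeline.

A Luminex xMAP genotyping assay reports one mean fluorescence intensity
(MFI, arbitrary units) per sample and per allele-specific probe.  For a
biallelic SNP with alleles A and B the two intensities ``vA`` and ``vB``
are normalized to ``phi = vA / (vA + vB)``: homozygous A samples cluster
near ``phi = 1``, heterozygotes near ``0.5`` and homozygous B samples
near ``0``.  The containers below carry the raw intensities, the cut-off
pair that splits the ``phi`` range into three candidate intervals, the
per-genotype confidence-interval cluster model, and the resulting calls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

#: Genotype labels ordered by increasing phi.
GENOTYPES = ("homB", "het", "homA")

#: Label for a sample whose phi falls outside every cluster interval.
NO_CALL = "NA"

#: Label for a sample whose summed intensity is below the minimum threshold.
THRESHOLD_CALL = "THR"

CUTOFF_METHODS = ("arbitrary", "experimental", "manual")


class BeadcallError(Exception):
    """Base class for errors raised by this package."""


class InputError(BeadcallError):
    """Malformed or invalid input data."""


@dataclass(frozen=True)
class IntensityRecord:
    """One (sample, SNP, allele) fluorescence measurement."""

    sample_id: str
    snp_id: str
    allele: str
    mfi: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.mfi) or self.mfi < 0:
            raise InputError(
                f"MFI must be a finite non-negative number, got {self.mfi!r} "
                f"for sample {self.sample_id!r}, SNP {self.snp_id!r}, "
                f"allele {self.allele!r}"
            )


@dataclass
class AssayData:
    """All per-sample, per-allele MFI values for one SNP on one plate.

    Parameters
    ----------
    snp_id : str
        SNP identifier (opaque, e.g. an rs number).
    alleles : sequence of str
        Probe/allele labels, deterministically ordered (lexicographic by
        default in the readers).
    samples : sequence of str
        Sample identifiers, one per matrix row.
    mfi : ndarray of shape (n_samples, n_alleles)
        Non-negative mean fluorescence intensities; no missing cells.
    """

    snp_id: str
    alleles: tuple[str, ...]
    samples: tuple[str, ...]
    mfi: np.ndarray

    def __post_init__(self) -> None:
        self.alleles = tuple(self.alleles)
        self.samples = tuple(self.samples)
        self.mfi = np.asarray(self.mfi, dtype=float)
        if len(self.alleles) < 2:
            raise InputError(
                f"SNP {self.snp_id!r}: at least two alleles required, "
                f"got {self.alleles}"
            )
        if len(set(self.alleles)) != len(self.alleles):
            raise InputError(f"SNP {self.snp_id!r}: duplicate allele labels")
        if len(set(self.samples)) != len(self.samples):
            raise InputError(f"SNP {self.snp_id!r}: duplicate sample ids")
        if self.mfi.shape != (len(self.samples), len(self.alleles)):
            raise InputError(
                f"SNP {self.snp_id!r}: intensity matrix shape {self.mfi.shape} "
                f"does not match {len(self.samples)} samples x "
                f"{len(self.alleles)} alleles"
            )
        if np.isnan(self.mfi).any():
            raise InputError(
                f"SNP {self.snp_id!r}: missing probe intensities (NaN cells)"
            )
        if (self.mfi < 0).any():
            raise InputError(f"SNP {self.snp_id!r}: negative MFI values")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_alleles(self) -> int:
        return len(self.alleles)

    def probe(self, allele: str) -> np.ndarray:
        """Intensity column for one allele's probe."""
        return self.mfi[:, self.alleles.index(allele)]

    def records(self) -> Iterable[IntensityRecord]:
        """Iterate the matrix as long-format records (samples outer)."""
        for i, sample in enumerate(self.samples):
            for j, allele in enumerate(self.alleles):
                yield IntensityRecord(sample, self.snp_id, allele, float(self.mfi[i, j]))


@dataclass(frozen=True)
class ManualCutoffEntry:
    """User-supplied cut-off pair for one SNP (CoD < CoU, both in (0,1))."""

    snp_id: str
    cod: float
    cou: float

    def __post_init__(self) -> None:
        if not (0.0 < self.cod < 1.0 and 0.0 < self.cou < 1.0):
            raise InputError(
                f"SNP {self.snp_id!r}: manual cut-offs must lie in (0, 1), "
                f"got CoD={self.cod}, CoU={self.cou}"
            )
        if self.cod >= self.cou:
            raise InputError(
                f"SNP {self.snp_id!r}: manual CoD ({self.cod}) must be "
                f"strictly below CoU ({self.cou})"
            )


@dataclass(frozen=True)
class CutoffPair:
    """The (CoD, CoU) pair splitting phi's range into three intervals.

    The intervals are half-open following the convention
    ``[0; CoD[``, ``[CoD; CoU[``, ``[CoU; 1]`` — low values are candidate
    homB, intermediate values candidate het, high values candidate homA.

    ``cod <= cou`` always; equality can occur for a *raw* experimental
    pair on degenerate (e.g. monoallelic) data where the pooled mean
    equals both probe maxima, and is removed by the 0.6/0.4 clamp.
    """

    cod: float
    cou: float
    method: str
    cod_clamped: bool = False
    cou_clamped: bool = False

    def __post_init__(self) -> None:
        if self.method not in CUTOFF_METHODS:
            raise ValueError(f"unknown cut-off method {self.method!r}")
        if not (0.0 < self.cod < 1.0 and 0.0 < self.cou < 1.0):
            raise ValueError(
                f"cut-offs must lie in (0, 1), got CoD={self.cod}, CoU={self.cou}"
            )
        if self.cod > self.cou:
            raise ValueError(
                f"CoD ({self.cod}) must not exceed CoU ({self.cou})"
            )


@dataclass(frozen=True)
class NormalizedPoint:
    """One sample's normalized intensity.

    ``phi`` is ``vA/(vA+vB)`` and is NaN when the total intensity is
    zero (flagged undefined); ``log_total`` is ``log10(vA+vB)``, the
    plot's Y axis, NaN for zero totals.
    """

    sample_id: str
    phi: float
    total: float
    log_total: float

    @property
    def defined(self) -> bool:
        return not math.isnan(self.phi)

    @property
    def va(self) -> float:
        """Reconstructed first-probe intensity (phi * total)."""
        return self.phi * self.total if self.defined else 0.0

    @property
    def vb(self) -> float:
        """Reconstructed second-probe intensity ((1-phi) * total)."""
        return (1.0 - self.phi) * self.total if self.defined else 0.0


@dataclass(frozen=True)
class ClusterInterval:
    """Confidence interval of one genotype cluster on the phi axis."""

    n: int
    mean: float
    sd: float
    lo: float
    hi: float
    singleton: bool = False

    def contains(self, phi: float) -> bool:
        return self.lo <= phi <= self.hi


@dataclass
class ClusterModel:
    """Per-genotype phi-intervals plus the confidence settings behind them.

    ``intervals`` maps each genotype in :data:`GENOTYPES` to a
    :class:`ClusterInterval` or ``None`` when the genotype's group is
    empty.  ``u_quantile`` is the standard-normal quantile
    ``U_{1-alpha/2}`` used for the half-width ``U * sigma`` (the sample
    size term is removed, so intervals describe the cluster spread, not
    the mean's uncertainty).
    """

    intervals: dict[str, ClusterInterval | None]
    alpha: float
    u_quantile: float
    small_sample_warning: bool = False
    overlap_resolved: bool = False
    collapsed: bool = False

    def genotype_of(self, phi: float) -> str | None:
        """Genotype whose interval contains phi; ties go to the upper cluster."""
        for genotype in reversed(GENOTYPES):  # homA first: shared endpoints go up
            interval = self.intervals.get(genotype)
            if interval is not None and interval.contains(phi):
                return genotype
        return None


@dataclass(frozen=True)
class GenotypeCall:
    """Final per-sample call with the evidence behind it."""

    sample_id: str
    label: str
    phi: float
    total: float
    reason: str | None = None

    @property
    def is_genotype(self) -> bool:
        return self.label not in (NO_CALL, THRESHOLD_CALL)


@dataclass
class QCReport:
    """Per-assay quality summary.

    ``silhouette`` is the mean silhouette width over called points in
    1-D phi space (None when fewer than two clusters are populated);
    ``silhouette_band`` is ``accept`` (> 0.65), ``inspect`` ([0.25,
    0.65]), ``fail`` (< 0.25) or ``not_applicable``.  The HWE chi-square
    test (1 df) is reported for information only and never rejects an
    assay.
    """

    silhouette: float | None
    silhouette_band: str
    hwe_chi2: float | None
    hwe_p: float | None
    hwe_df: int | None
    warnings: list[str] = field(default_factory=list)


def make_points(assay: AssayData, a_index: int = 0, b_index: int = 1) -> list[NormalizedPoint]:
    """Normalize a biallelic assay into per-sample phi points."""
    from .calling import normalize  # local import avoids a cycle

    points = []
    for i, sample in enumerate(assay.samples):
        va = float(assay.mfi[i, a_index])
        vb = float(assay.mfi[i, b_index])
        total = va + vb
        phi = normalize(va, vb)
        log_total = math.log10(total) if total > 0 else math.nan
        points.append(NormalizedPoint(sample, phi, total, log_total))
    return points


__all__ = [
    "GENOTYPES",
    "NO_CALL",
    "THRESHOLD_CALL",
    "CUTOFF_METHODS",
    "BeadcallError",
    "InputError",
    "IntensityRecord",
    "AssayData",
    "ManualCutoffEntry",
    "CutoffPair",
    "NormalizedPoint",
    "ClusterInterval",
    "ClusterModel",
    "GenotypeCall",
    "QCReport",
    "make_points",
]
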