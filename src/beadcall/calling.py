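"""Core genotype-calling algorithm for two-probe fluorescence assays.

The pipeline for one biallelic SNP:

1. **Threshold pre-filter** — samples whose summed probe intensity
   ``vA + vB`` falls below a minimum fluorescence threshold (default
   300) are excluded from clustering and called ``THR``.
2. **Normalization** — each remaining sample is reduced to
   ``phi = vA / (vA + vB)`` in [0, 1].
3. **Cut-offs** — a (CoD, CoU) pair splits phi's range into three
   candidate intervals ``[0; CoD[``, ``[CoD; CoU[``, ``[CoU; 1]``.
   Either the arbitrary pair (0.3, 0.7), an experimental pair derived
   from the probe maxima and the pooled intensity mean, or a manual
   per-SNP pair from a user file.
4. **Cluster boundaries** — within each candidate group a confidence
   interval ``mean ± U_{1-alpha/2} * sd`` (sample-size term removed) is
   clamped to [0, 1]; the low cluster's lower bound is 0 and the high
   cluster's upper bound is 1 by the natural limits of phi.
5. **Quality controls** — cut-off clamping to CoU >= 0.6 / CoD <= 0.4,
   the >80% dominant-cluster recheck, and overlap resolution between
   adjacent intervals (see :mod:`beadcall.qc`).
6. **Assignment** — each sample gets exactly one call: ``THR`` below
   threshold, a genotype when phi lies in exactly one interval
   (endpoint ties go to the upper cluster), otherwise ``NA``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import norm

from .data import (
    GENOTYPES,
    NO_CALL,
    THRESHOLD_CALL,
    AssayData,
    BeadcallError,
    ClusterInterval,
    ClusterModel,
    CutoffPair,
    GenotypeCall,
    ManualCutoffEntry,
    NormalizedPoint,
    QCReport,
    make_points,
)

#: Minimum number of clustered samples for the normal approximation
#: behind the confidence intervals to be trusted.
MIN_SAMPLES_FOR_NORMALITY = 30


@dataclass
class CallConfig:
    """Run configuration for :func:`call_assay`.

    alpha : type-I error rate of the cluster confidence intervals
        (default 0.05; lowering it widens intervals and reduces
        no-calls).
    threshold : minimum summed fluorescence for a sample to enter the
        analysis (default 300, arbitrary MFI units).
    cutoff_method : "arbitrary" (0.3/0.7), "experimental" (default) or
        "manual" (requires an entry in ``manual_cutoffs``).
    manual_cutoffs : optional mapping snp_id -> ManualCutoffEntry; an
        entry for the assay's SNP always overrides the computed pair.
    """

    alpha: float = 0.05
    threshold: float = 300.0
    cutoff_method: str = "experimental"
    manual_cutoffs: Mapping[str, ManualCutoffEntry] | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.threshold < 0:
            raise ValueError(f"threshold must be >= 0, got {self.threshold}")
        if self.cutoff_method not in ("arbitrary", "experimental", "manual"):
            raise ValueError(f"unknown cutoff_method {self.cutoff_method!r}")


@dataclass
class AssayResult:
    """Everything :func:`call_assay` produces for one SNP."""

    snp_id: str
    calls: list[GenotypeCall]
    model: ClusterModel
    cutoffs: CutoffPair
    qc: QCReport
    points: list[NormalizedPoint] = field(default_factory=list)
    rerun_flag: str = "not_triggered"

    @property
    def call_counts(self) -> dict[str, int]:
        counts = {g: 0 for g in (*GENOTYPES, NO_CALL, THRESHOLD_CALL)}
        for call in self.calls:
            counts[call.label] = counts.get(call.label, 0) + 1
        return counts


def normalize(va: float, vb: float) -> float:
    """Normalized intensity ``phi = vA / (vA + vB)``.

    Returns NaN (flagged undefined) when both intensities are zero;
    downstream such a sample is called THR under any positive threshold.
    """
    if va < 0 or vb < 0:
        raise ValueError(f"intensities must be non-negative, got ({va}, {vb})")
    total = va + vb
    if total == 0:
        return math.nan
    return va / total


def cutoffs_arbitrary() -> CutoffPair:
    """The fixed theoretical pair CoD = 0.3, CoU = 0.7.

    Appropriate when clusters sit at their mathematical positions
    (phi near 0, 0.5 and 1), e.g. for monoallelic SNPs where the
    data-driven method is skewed.
    """
    return CutoffPair(cod=0.3, cou=0.7, method="arbitrary")


def cutoffs_experimental(
    va_values: Sequence[float], vb_values: Sequence[float]
) -> CutoffPair:
    """Data-driven cut-offs from the probe maxima and the pooled mean.

    With ``m = min[max(vA), max(vB), mean(all vA and vB pooled)]``:

    ``CoU = max(vA) / (max(vA) + m)`` and ``CoD = m / (max(vB) + m)``.

    When both probes reach similar maxima the pair tracks the
    mean-to-max ratio ``r`` as ``CoU = 1/(1+r)``: r = 1/2 gives the
    familiar 2/3 and 1/3, while probe imbalance shifts the pair to
    follow the skewed clusters.  Returned unclamped; the 0.6/0.4
    limits are a separate quality control (:func:`beadcall.qc.clamp_cutoffs`).
    """
    va = np.asarray(va_values, dtype=float)
    vb = np.asarray(vb_values, dtype=float)
    if va.size == 0 or vb.size == 0:
        raise ValueError("experimental cut-offs require non-empty intensity lists")
    if va.size != vb.size:
        raise ValueError(
            f"probe intensity lists differ in length ({va.size} vs {vb.size})"
        )
    if (va < 0).any() or (vb < 0).any():
        raise ValueError("negative intensities")
    max_a = float(va.max())
    max_b = float(vb.max())
    pooled_mean = float(np.concatenate([va, vb]).mean())
    m = min(max_a, max_b, pooled_mean)
    if m == 0 or max_a == 0 or max_b == 0:
        raise BeadcallError(
            "experimental cut-offs undefined: a probe has no signal "
            "(all-zero intensities)"
        )
    cou = max_a / (max_a + m)
    cod = m / (max_b + m)
    return CutoffPair(cod=cod, cou=cou, method="experimental")


def partition(
    points: Sequence[NormalizedPoint], cutoffs: CutoffPair
) -> dict[str, list[NormalizedPoint]]:
    """Split points into low / mid / high groups by the half-open rule.

    Low is ``[0; CoD[``, mid ``[CoD; CoU[``, high ``[CoU; 1]`` — a phi
    exactly at CoD belongs to mid, exactly at CoU to high.  Points with
    undefined phi are ignored.
    """
    groups: dict[str, list[NormalizedPoint]] = {"low": [], "mid": [], "high": []}
    for point in points:
        if not point.defined:
            continue
        if point.phi < cutoffs.cod:
            groups["low"].append(point)
        elif point.phi < cutoffs.cou:
            groups["mid"].append(point)
        else:
            groups["high"].append(point)
    return groups


def cluster_boundaries(
    group: Sequence[float],
    alpha: float,
    side: str = "both",
) -> ClusterInterval | None:
    """Confidence interval ``mean ± U_{1-alpha/2} * sd`` for one cluster.

    The sample-size term is deliberately removed: the interval should
    cover the cluster's member spread, not the uncertainty of its mean.
    ``side`` fixes one bound at the natural phi limit: ``upper_only``
    (low/homB cluster, lower bound 0), ``lower_only`` (high/homA
    cluster, upper bound 1) or ``both`` (het).  Endpoints are clamped
    to [0, 1].  Empty groups yield ``None`` (genotype absent); a
    singleton group gets a point interval (sd treated as 0) and is
    flagged.
    """
    phis = np.asarray(group, dtype=float)
    if phis.size == 0:
        return None
    if side not in ("both", "upper_only", "lower_only"):
        raise ValueError(f"unknown side {side!r}")
    u = float(norm.ppf(1.0 - alpha / 2.0))
    mean = float(phis.mean())
    singleton = phis.size == 1
    sd = 0.0 if singleton else float(phis.std(ddof=1))
    lo = max(0.0, mean - u * sd)
    hi = min(1.0, mean + u * sd)
    if side == "upper_only":
        lo = 0.0
    elif side == "lower_only":
        hi = 1.0
    return ClusterInterval(n=int(phis.size), mean=mean, sd=sd, lo=lo, hi=hi,
                           singleton=singleton)


def build_cluster_model(
    groups: Mapping[str, Sequence[NormalizedPoint]], alpha: float
) -> ClusterModel:
    """Turn the three cut-off groups into per-genotype intervals.

    low -> homB (lower bound pinned at 0), mid -> het, high -> homA
    (upper bound pinned at 1).
    """
    sides = {"low": "upper_only", "mid": "both", "high": "lower_only"}
    genotype_for = {"low": "homB", "mid": "het", "high": "homA"}
    intervals: dict[str, ClusterInterval | None] = {}
    n_total = 0
    for group_name, side in sides.items():
        members = groups.get(group_name, [])
        phis = [p.phi for p in members]
        intervals[genotype_for[group_name]] = cluster_boundaries(phis, alpha, side)
        n_total += len(phis)
    return ClusterModel(
        intervals=intervals,
        alpha=alpha,
        u_quantile=float(norm.ppf(1.0 - alpha / 2.0)),
        small_sample_warning=n_total < MIN_SAMPLES_FOR_NORMALITY,
    )


def assign_calls(
    points: Sequence[NormalizedPoint],
    model: ClusterModel,
    threshold: float,
) -> list[GenotypeCall]:
    """Give every sample exactly one call.

    Precedence: (1) summed intensity below the threshold -> THR;
    (2) phi inside a cluster interval -> that genotype, with shared
    endpoints resolved to the upper cluster; (3) otherwise -> NA.
    """
    calls = []
    for point in points:
        if point.total == 0:
            reason = "below_threshold" if threshold > 0 else "zero_total"
            calls.append(GenotypeCall(point.sample_id, THRESHOLD_CALL,
                                      math.nan, point.total, reason))
            continue
        if point.total < threshold:
            calls.append(GenotypeCall(point.sample_id, THRESHOLD_CALL,
                                      point.phi, point.total, "below_threshold"))
            continue
        genotype = model.genotype_of(point.phi)
        if genotype is None:
            calls.append(GenotypeCall(point.sample_id, NO_CALL, point.phi,
                                      point.total, "outside_all_intervals"))
        else:
            calls.append(GenotypeCall(point.sample_id, genotype, point.phi,
                                      point.total, None))
    return calls


def _select_cutoffs(
    assay: AssayData,
    passing: Sequence[NormalizedPoint],
    config: CallConfig,
    warnings: list[str],
) -> CutoffPair:
    from . import qc as qc_mod

    manual = (config.manual_cutoffs or {}).get(assay.snp_id)
    if manual is not None:
        return CutoffPair(cod=manual.cod, cou=manual.cou, method="manual")
    if config.cutoff_method == "manual":
        raise BeadcallError(
            f"cutoff_method='manual' but no manual cut-offs supplied for "
            f"SNP {assay.snp_id!r}"
        )
    if config.cutoff_method == "arbitrary":
        raw = cutoffs_arbitrary()
    else:
        raw = cutoffs_experimental(
            [p.va for p in passing], [p.vb for p in passing]
        )
    clamped = qc_mod.clamp_cutoffs(raw)
    if clamped.cou_clamped:
        warnings.append("cou_clamped")
    if clamped.cod_clamped:
        warnings.append("cod_clamped")
    return clamped


def call_assay(
    assay: AssayData,
    config: CallConfig | None = None,
    *,
    hwe: bool = True,
) -> AssayResult:
    """Run the full calling pipeline on one biallelic assay.

    The first listed allele plays the "A" role (phi near 1 for its
    homozygote).  Multi-allelic assays must go through
    :func:`beadcall.multiallelic.call_multiallelic` first.

    Set ``hwe=False`` to suppress the Hardy-Weinberg test (used for
    multi-allelic sub-assays, where the sub-group is not a random
    population sample).
    """
    from . import qc as qc_mod

    if config is None:
        config = CallConfig()
    if assay.n_alleles != 2:
        raise BeadcallError(
            f"SNP {assay.snp_id!r} has {assay.n_alleles} alleles; use "
            "beadcall.multiallelic.call_multiallelic for multi-allelic assays"
        )

    points = make_points(assay)
    passing = [p for p in points if p.defined and p.total >= config.threshold
               and p.total > 0]
    warnings: list[str] = []

    if not passing:
        # every sample is below threshold: no clustering possible
        model = ClusterModel(
            intervals={g: None for g in GENOTYPES},
            alpha=config.alpha,
            u_quantile=float(norm.ppf(1.0 - config.alpha / 2.0)),
            small_sample_warning=True,
        )
        calls = assign_calls(points, model, config.threshold)
        qc = QCReport(
            silhouette=None, silhouette_band="not_applicable",
            hwe_chi2=None, hwe_p=None, hwe_df=None,
            warnings=["no_samples_above_threshold", "small_sample"],
        )
        cutoffs = cutoffs_arbitrary()  # placeholder pair; nothing clustered
        return AssayResult(assay.snp_id, calls, model, cutoffs, qc, points)

    cutoffs = _select_cutoffs(assay, passing, config, warnings)
    groups = partition(passing, cutoffs)

    rerun_flag = "not_triggered"
    if cutoffs.method == "experimental":
        cutoffs, rerun_flag = qc_mod.dominant_cluster_recheck(
            passing, cutoffs, config
        )
        if rerun_flag == "rerun_adopted":
            warnings.append("dominant_cluster_rerun")
            groups = partition(passing, cutoffs)

    model = build_cluster_model(groups, config.alpha)
    model = qc_mod.resolve_overlap(model)
    if model.overlap_resolved:
        warnings.append("overlap_resolved")
    if model.collapsed:
        warnings.append("interval_collapsed")
    if model.small_sample_warning:
        warnings.append("small_sample")
    if any(iv is not None and iv.singleton for iv in model.intervals.values()):
        warnings.append("singleton_cluster")

    calls = assign_calls(points, model, config.threshold)

    called = [c for c in calls if c.is_genotype]
    score = qc_mod.silhouette_width(
        [c.phi for c in called], [c.label for c in called]
    )
    counts = {g: sum(1 for c in called if c.label == g) for g in GENOTYPES}
    if hwe and called:
        hwe_result = qc_mod.hwe_test(counts["homA"], counts["het"], counts["homB"])
        hwe_chi2 = hwe_result.chi2 if hwe_result.applicable else None
        hwe_p = hwe_result.p if hwe_result.applicable else None
        hwe_df = hwe_result.df if hwe_result.applicable else None
    else:
        hwe_chi2 = hwe_p = hwe_df = None

    qc = QCReport(
        silhouette=score,
        silhouette_band=qc_mod.silhouette_band(score),
        hwe_chi2=hwe_chi2,
        hwe_p=hwe_p,
        hwe_df=hwe_df,
        warnings=warnings,
    )
    return AssayResult(assay.snp_id, calls, model, cutoffs, qc, points,
                       rerun_flag)


__all__ = [
    "MIN_SAMPLES_FOR_NORMALITY",
    "CallConfig",
    "AssayResult",
    "normalize",
    "cutoffs_arbitrary",
    "cutoffs_experimental",
    "partition",
    "cluster_boundaries",
    "build_cluster_model",
    "assign_calls",
    "call_assay",
]
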