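"""Quality controls applied around the core calling step.

Six controls guard each assay: (1) the minimum-fluorescence threshold
(applied in :func:`beadcall.calling.assign_calls`); (2) a second-round
cut-off computation when one cluster holds more than 80% of samples;
(3) resolution of overlapping cluster intervals at the midpoint of the
old boundaries; (4) clamping of computed cut-offs to CoU >= 0.6 and
CoD <= 0.4 so three clusters stay representable; (5) a silhouette
cluster-quality score with accept/inspect/fail bands at 0.65 and 0.25;
(6) a Hardy-Weinberg equilibrium chi-square test, reported for
information only.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import chi2 as chi2_dist

from .data import (
    GENOTYPES,
    BeadcallError,
    ClusterInterval,
    ClusterModel,
    CutoffPair,
    NormalizedPoint,
)

#: Silhouette decision bands: accept above, fail below.
SILHOUETTE_ACCEPT = 0.65
SILHOUETTE_FAIL = 0.25

#: CoU may not fall below / CoD rise above these values after clamping.
COU_FLOOR = 0.6
COD_CEILING = 0.4

#: Fraction of samples in one cluster that triggers the second-round
#: cut-off computation (strictly more than).
DOMINANCE_FRACTION = 0.8


def clamp_cutoffs(raw: CutoffPair) -> CutoffPair:
    """Limit computed cut-offs so all three clusters remain representable.

    CoU is raised to at least 0.6 and CoD lowered to at most 0.4 when a
    computed pair deviates further; flags record which bound moved.
    Manual pairs are exempt — a user override wins.  Idempotent.
    """
    if raw.method == "manual":
        return raw
    cou = max(raw.cou, COU_FLOOR)
    cod = min(raw.cod, COD_CEILING)
    if cod >= cou:
        # cannot happen: clamping only pushes the bounds apart
        raise BeadcallError(
            f"clamping produced invalid cut-offs CoD={cod}, CoU={cou}"
        )
    return CutoffPair(
        cod=cod,
        cou=cou,
        method=raw.method,
        cod_clamped=raw.cod_clamped or cod != raw.cod,
        cou_clamped=raw.cou_clamped or cou != raw.cou,
    )


def dominant_cluster_recheck(
    points: Sequence[NormalizedPoint],
    cutoffs: CutoffPair,
    config,
) -> tuple[CutoffPair, str]:
    """Second-round cut-off computation against merged clusters.

    Triggered only when one cut-off group holds strictly more than 80%
    of the threshold-passing samples — the signature of probe imbalance
    having pulled two true clusters into one interval.  Experimental
    cut-offs are recomputed from the dominant group's members alone and
    those members re-partitioned:

    * still one group -> the first-round cut-offs were correct
      (``"validated"``);
    * they split -> the second-round pair is adopted
      (``"rerun_adopted"``) and the caller re-partitions *all* samples
      with it before computing boundaries.

    Returns ``(final_cutoffs, flag)`` with flag in
    ``{"not_triggered", "validated", "rerun_adopted"}``.
    """
    from .calling import cutoffs_experimental, partition

    groups = partition(points, cutoffs)
    n = sum(len(g) for g in groups.values())
    if n == 0:
        return cutoffs, "not_triggered"
    dominant = max(groups.values(), key=len)
    if len(dominant) <= DOMINANCE_FRACTION * n:
        return cutoffs, "not_triggered"

    try:
        second = cutoffs_experimental(
            [p.va for p in dominant], [p.vb for p in dominant]
        )
    except BeadcallError:
        # degenerate dominant group (a probe fully dark): keep round one
        return cutoffs, "validated"
    second = clamp_cutoffs(second)
    regrouped = partition(dominant, second)
    populated = sum(1 for g in regrouped.values() if g)
    if populated <= 1:
        return cutoffs, "validated"
    return second, "rerun_adopted"


def resolve_overlap(model: ClusterModel) -> ClusterModel:
    """Move overlapping adjacent interval boundaries to their midpoint.

    An overlap would put one phi in two genotypes; instead both
    boundaries are moved to the point equidistant from the two old
    (overlapping) boundary values, yielding flanking disjoint
    intervals.  Pairs are resolved low<->mid then mid<->high; the
    operation is idempotent and never grows total coverage.  A phi
    landing exactly on a shared boundary is assigned to the upper
    cluster by :meth:`ClusterModel.genotype_of`.
    """
    intervals = dict(model.intervals)
    changed = False
    collapsed = model.collapsed
    for lower_name, upper_name in (("homB", "het"), ("het", "homA")):
        lower = intervals.get(lower_name)
        upper = intervals.get(upper_name)
        if lower is None or upper is None:
            continue
        if upper.lo < lower.hi:  # strict overlap
            breakpoint_ = 0.5 * (lower.hi + upper.lo)
            intervals[lower_name] = dataclasses.replace(lower, hi=breakpoint_)
            intervals[upper_name] = dataclasses.replace(upper, lo=breakpoint_)
            changed = True
    # guard against pathological containment leaving lo > hi
    for name, interval in intervals.items():
        if interval is not None and interval.lo > interval.hi:
            mid = 0.5 * (interval.lo + interval.hi)
            intervals[name] = dataclasses.replace(interval, lo=mid, hi=mid)
            collapsed = True
    if not changed and collapsed == model.collapsed:
        return model
    return ClusterModel(
        intervals=intervals,
        alpha=model.alpha,
        u_quantile=model.u_quantile,
        small_sample_warning=model.small_sample_warning,
        overlap_resolved=model.overlap_resolved or changed,
        collapsed=collapsed,
    )


def silhouette_width(
    phis: Sequence[float], labels: Sequence[str]
) -> float | None:
    """Mean silhouette width of the called points in 1-D phi space.

    Distances are absolute phi differences.  Per point,
    ``s = (b - a) / max(a, b)`` with ``a`` the mean distance to the
    other members of its own cluster and ``b`` the smallest mean
    distance to any other cluster; members of singleton clusters score
    0, as do points where both means vanish.  Returns ``None`` when
    fewer than two clusters are populated (score not applicable).
    """
    phis = np.asarray(phis, dtype=float)
    labels = np.asarray(labels, dtype=object)
    if phis.shape != labels.shape:
        raise ValueError("phis and labels must have equal length")
    unique = np.unique(labels)
    if phis.size == 0 or unique.size < 2:
        return None
    distances = np.abs(phis[:, None] - phis[None, :])
    masks = {lab: labels == lab for lab in unique}
    scores = np.zeros(phis.size)
    for i in range(phis.size):
        own = masks[labels[i]]
        n_own = int(own.sum())
        if n_own == 1:
            scores[i] = 0.0
            continue
        a = (distances[i, own].sum()) / (n_own - 1)  # excludes self (d=0)
        b = min(
            distances[i, mask].mean()
            for lab, mask in masks.items()
            if lab != labels[i]
        )
        denom = max(a, b)
        scores[i] = (b - a) / denom if denom > 0 else 0.0
    return float(scores.mean())


def silhouette_band(score: float | None) -> str:
    """accept (> 0.65) / inspect ([0.25, 0.65]) / fail (< 0.25)."""
    if score is None:
        return "not_applicable"
    if score > SILHOUETTE_ACCEPT:
        return "accept"
    if score < SILHOUETTE_FAIL:
        return "fail"
    return "inspect"


@dataclass(frozen=True)
class HweResult:
    """Pearson chi-square test of Hardy-Weinberg proportions (1 df)."""

    chi2: float
    p: float
    df: int
    applicable: bool


def hwe_test(n_hom_a: int, n_het: int, n_hom_b: int) -> HweResult:
    """Test observed genotype counts against Hardy-Weinberg proportions.

    The allele frequency ``p = (2*n_homA + n_het) / 2n`` gives expected
    counts ``(p^2 n, 2p(1-p) n, (1-p)^2 n)``; the Pearson chi-square
    statistic has one degree of freedom (three classes, one estimated
    frequency).  Monomorphic data (p in {0, 1}) make the test
    inapplicable.  The result is informational only: a deviation may
    reflect sample ascertainment rather than a failed assay, so no
    automatic rejection is derived from it.
    """
    counts = np.array([n_hom_a, n_het, n_hom_b], dtype=float)
    if (counts < 0).any():
        raise ValueError(f"genotype counts must be non-negative, got {counts}")
    n = counts.sum()
    if n == 0:
        raise ValueError("genotype counts sum to zero")
    p = (2 * counts[0] + counts[1]) / (2 * n)
    if p in (0.0, 1.0):
        return HweResult(chi2=math.nan, p=math.nan, df=1, applicable=False)
    expected = n * np.array([p**2, 2 * p * (1 - p), (1 - p) ** 2])
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    p_value = float(chi2_dist.sf(chi2, df=1))
    return HweResult(chi2=chi2, p=p_value, df=1, applicable=True)


__all__ = [
    "SILHOUETTE_ACCEPT",
    "SILHOUETTE_FAIL",
    "COU_FLOOR",
    "COD_CEILING",
    "DOMINANCE_FRACTION",
    "clamp_cutoffs",
    "dominant_cluster_recheck",
    "resolve_overlap",
    "silhouette_width",
    "silhouette_band",
    "HweResult",
    "hwe_test",
]
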