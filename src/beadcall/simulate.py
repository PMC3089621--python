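"""Synthetic assay generator with known genotype truth.

Emulates the structure of two-probe (or k-probe) bead-array MFI data:
genotypes drawn from Hardy-Weinberg proportions, an "on" probe emitting
a bright lognormal signal, "off" probes emitting dim lognormal
background, heterozygotes splitting the signal between their two "on"
probes.  Lognormal intensities were chosen because fluorescence is
positive and right-skewed; the claim is structural (three separable phi
clusters over a log-total axis), not distributional fidelity to any
particular bead chemistry.

Knobs map one-to-one onto the failure modes the caller must survive:
``imbalance`` multiplies one probe's output everywhere (skewing all
clusters toward that allele), ``het_balance`` skews only the
heterozygote split, ``threshold_fail_fraction`` scales a random subset
of samples down so they land under the minimum-fluorescence threshold,
and ``signal_cv`` controls cluster tightness in phi.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .data import AssayData, GenotypeCall

#: Default probe labels for simulated alleles.
_ALLELE_LETTERS = "ABCDEFGH"


@dataclass(frozen=True)
class SimulationParams:
    """Generator settings for one synthetic assay.

    n_samples : number of individuals.
    allele_freq : frequency of allele A for the biallelic generator;
        genotypes are drawn from HWE proportions (p^2, 2pq, q^2).
    signal_mean, signal_cv : lognormal mean and coefficient of
        variation of an "on" probe's MFI (arbitrary units).  The
        default CV of 0.08 puts the heterozygote cluster's phi spread
        near 0.03, a tight, well-behaved assay.
    background_mean, background_cv : same for "off" probes.
    imbalance : multiplicative factor applied to the allele-A probe
        everywhere (probe intensity imbalance); 1 = balanced.
    het_balance : expected fraction of a heterozygote's signal routed
        to the allele-A probe (0.5 = symmetric).
    threshold_fail_fraction : fraction of samples whose intensities are
        globally scaled by ``fail_scale`` to fall under the default 300
        threshold.
    seed : RNG seed; fixed seeds are bit-reproducible.
    """

    n_samples: int = 300
    allele_freq: float = 0.5
    signal_mean: float = 2000.0
    signal_cv: float = 0.08
    background_mean: float = 60.0
    background_cv: float = 0.3
    imbalance: float = 1.0
    het_balance: float = 0.5
    threshold_fail_fraction: float = 0.0
    fail_scale: float = 0.05
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if not (0.0 <= self.allele_freq <= 1.0):
            raise ValueError("allele_freq must lie in [0, 1]")
        for name in ("signal_mean", "background_mean", "imbalance"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("signal_cv", "background_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 < self.het_balance < 1.0):
            raise ValueError("het_balance must lie in (0, 1)")
        if not (0.0 <= self.threshold_fail_fraction <= 1.0):
            raise ValueError("threshold_fail_fraction must lie in [0, 1]")
        if not (0.0 < self.fail_scale < 1.0):
            raise ValueError("fail_scale must lie in (0, 1)")


def _lognormal(rng: np.random.Generator, mean: float, cv: float, size: int) -> np.ndarray:
    """Lognormal draws parameterized by arithmetic mean and CV."""
    if cv == 0:
        return np.full(size, mean)
    sigma2 = math.log1p(cv**2)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=size)


def _apply_threshold_failures(
    rng: np.random.Generator, mfi: np.ndarray, params: SimulationParams
) -> np.ndarray:
    n_fail = int(round(params.threshold_fail_fraction * mfi.shape[0]))
    if n_fail:
        rows = rng.choice(mfi.shape[0], size=n_fail, replace=False)
        mfi[rows] *= params.fail_scale
    return mfi


def simulate_assay(
    params: SimulationParams, snp_id: str = "snp_sim"
) -> tuple[AssayData, dict[str, str]]:
    """Generate one biallelic assay and its genotype truth.

    Returns the assay (alleles ``A``, ``B``) and a mapping sample id ->
    true label in ``{"homA", "het", "homB"}``.  Homozygotes emit signal
    on one probe and background on the other; heterozygotes split the
    signal per ``het_balance``; ``imbalance`` scales the A probe last,
    so with imbalance ``w`` the heterozygote cluster sits near
    ``phi = w*h / (w*h + (1-h))``.
    """
    rng = np.random.default_rng(params.seed)
    p = params.allele_freq
    probs = [p**2, 2 * p * (1 - p), (1 - p) ** 2]
    labels = ("homA", "het", "homB")
    n = params.n_samples
    genotype_idx = rng.choice(3, size=n, p=probs)

    va = np.empty(n)
    vb = np.empty(n)
    for g, label in enumerate(labels):
        rows = np.flatnonzero(genotype_idx == g)
        k = rows.size
        if not k:
            continue
        if label == "homA":
            va[rows] = _lognormal(rng, params.signal_mean, params.signal_cv, k)
            vb[rows] = _lognormal(rng, params.background_mean, params.background_cv, k)
        elif label == "homB":
            va[rows] = _lognormal(rng, params.background_mean, params.background_cv, k)
            vb[rows] = _lognormal(rng, params.signal_mean, params.signal_cv, k)
        else:
            h = params.het_balance
            va[rows] = _lognormal(rng, h * params.signal_mean, params.signal_cv, k)
            vb[rows] = _lognormal(rng, (1 - h) * params.signal_mean, params.signal_cv, k)
    va *= params.imbalance

    mfi = _apply_threshold_failures(rng, np.column_stack([va, vb]), params)
    samples = tuple(f"s{i:04d}" for i in range(n))
    assay = AssayData(snp_id=snp_id, alleles=("A", "B"), samples=samples, mfi=mfi)
    truth = {samples[i]: labels[genotype_idx[i]] for i in range(n)}
    return assay, truth


def simulate_multiallelic(
    params: SimulationParams,
    k: int = 3,
    allele_freqs: Sequence[float] | None = None,
    snp_id: str = "snp_sim_multi",
) -> tuple[AssayData, dict[str, str]]:
    """Generate a k-allele assay (k >= 3) and its genotype truth.

    Each sample's genotype is two independent allele draws from
    ``allele_freqs`` (HWE), giving truth labels like ``AB`` or ``CC``
    (lexicographically ordered).  Homozygotes light one probe,
    heterozygotes split the signal across their two probes per
    ``het_balance`` (lexicographically first allele gets the
    ``het_balance`` share); all other probes emit background.
    ``imbalance`` scales the first probe's column.
    """
    if k < 3:
        raise ValueError("simulate_multiallelic requires k >= 3 alleles")
    if k > len(_ALLELE_LETTERS):
        raise ValueError(f"at most {len(_ALLELE_LETTERS)} alleles supported")
    if allele_freqs is None:
        allele_freqs = [1.0 / k] * k
    freqs = np.asarray(allele_freqs, dtype=float)
    if freqs.size != k or (freqs < 0).any() or not math.isclose(freqs.sum(), 1.0):
        raise ValueError("allele_freqs must be k non-negative values summing to 1")

    rng = np.random.default_rng(params.seed)
    alleles = tuple(_ALLELE_LETTERS[:k])
    n = params.n_samples
    draws = rng.choice(k, size=(n, 2), p=freqs)
    draws.sort(axis=1)  # (i, j) with i <= j: lexicographic genotype

    mfi = np.empty((n, k))
    for j in range(k):
        mfi[:, j] = _lognormal(rng, params.background_mean, params.background_cv, n)
    truth = {}
    samples = tuple(f"s{i:04d}" for i in range(n))
    signal = _lognormal(rng, params.signal_mean, params.signal_cv, n)
    split = _lognormal(rng, params.het_balance * params.signal_mean,
                       params.signal_cv, n)
    split_other = _lognormal(rng, (1 - params.het_balance) * params.signal_mean,
                             params.signal_cv, n)
    for i in range(n):
        a, b = draws[i]
        if a == b:
            mfi[i, a] = signal[i]
        else:
            mfi[i, a] = split[i]
            mfi[i, b] = split_other[i]
        truth[samples[i]] = alleles[a] + alleles[b]
    mfi[:, 0] *= params.imbalance

    mfi = _apply_threshold_failures(rng, mfi, params)
    assay = AssayData(snp_id=snp_id, alleles=alleles, samples=samples, mfi=mfi)
    return assay, truth


def concordance(
    calls: Sequence[GenotypeCall],
    truth: dict[str, str],
    *,
    include_no_calls: bool = False,
) -> float:
    """Fraction of calls agreeing with the simulated truth.

    By default only genotype calls enter the denominator (NA and THR
    are excluded), matching how genotyping accuracy is conventionally
    reported on called genotypes; with ``include_no_calls=True`` every
    sample counts and NA/THR are automatically discordant.
    """
    considered = [c for c in calls if include_no_calls or c.is_genotype]
    if not considered:
        return math.nan
    agree = sum(1 for c in considered if c.is_genotype and truth[c.sample_id] == c.label)
    return agree / len(considered)


__all__ = [
    "SimulationParams",
    "simulate_assay",
    "simulate_multiallelic",
    "concordance",
]
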