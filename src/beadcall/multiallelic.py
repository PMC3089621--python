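"""Multi-allelic SNP calling by top-two-probe decomposition.

A sample carries at most two alleles, so for a SNP with k >= 3 probes
every probe beyond a sample's two most fluorescent ones is background
noise.  Each sample is therefore routed to the biallelic sub-assay of
its top-two probes (e.g. a three-allele A/T/G SNP yields up to three
independent procedures: A vs T, A vs G, G vs T), each sub-assay is
called with the standard biallelic pipeline, and the calls are merged
back using explicit two-allele genotype labels (``AT``, ``GG``, ...).

The Hardy-Weinberg test is suppressed for sub-assays: a sub-group
selected by probe ranking is not a random draw from the population, so
HWE proportions are not expected to hold within it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .calling import AssayResult, CallConfig, call_assay
from .data import (
    NO_CALL,
    THRESHOLD_CALL,
    AssayData,
    BeadcallError,
    GenotypeCall,
)


@dataclass
class SubAssay:
    """One biallelic sub-problem: the samples whose top-two probes match."""

    allele_pair: tuple[str, str]  # lexicographically ordered
    assay: AssayData              # restricted to the pair's two probe columns


@dataclass
class MultiallelicResult:
    """Merged calls plus the per-sub-assay evidence."""

    snp_id: str
    calls: list[GenotypeCall]                       # input sample order
    sub_results: dict[tuple[str, str], AssayResult]
    ambiguous_samples: list[str] = field(default_factory=list)


def split_by_top_two(assay: AssayData) -> tuple[list[SubAssay], list[str]]:
    """Assign each sample to the sub-assay of its two brightest probes.

    Returns the populated sub-assays (at most k*(k-1)/2, ordered by
    allele pair) and the list of samples whose 2nd and 3rd brightest
    probes tie — for them the background-noise premise fails, so they
    receive no sub-assay and are later called NA.
    """
    if assay.n_alleles < 3:
        raise BeadcallError(
            f"SNP {assay.snp_id!r} has {assay.n_alleles} alleles; "
            "split_by_top_two requires at least 3"
        )
    members: dict[tuple[str, str], list[int]] = {}
    ambiguous: list[str] = []
    for i, sample in enumerate(assay.samples):
        row = assay.mfi[i]
        order = np.argsort(row, kind="stable")[::-1]  # brightest first
        second, third = row[order[1]], row[order[2]]
        if second == third:
            ambiguous.append(sample)
            continue
        pair = tuple(sorted((assay.alleles[order[0]], assay.alleles[order[1]])))
        members.setdefault(pair, []).append(i)

    sub_assays = []
    for pair in sorted(members):
        rows = members[pair]
        cols = [assay.alleles.index(a) for a in pair]
        sub = AssayData(
            snp_id=f"{assay.snp_id}:{pair[0]}/{pair[1]}",
            alleles=pair,
            samples=tuple(assay.samples[i] for i in rows),
            mfi=assay.mfi[np.ix_(rows, cols)],
        )
        sub_assays.append(SubAssay(allele_pair=pair, assay=sub))
    return sub_assays, ambiguous


def _pair_label(genotype: str, pair: tuple[str, str]) -> str:
    """Map a biallelic call to an explicit two-allele label.

    Within a sub-assay the lexicographically first allele plays the
    "A" role (phi near 1 for its homozygote).
    """
    a, b = pair
    joiner = "" if len(a) == 1 and len(b) == 1 else "/"
    return {
        "homA": joiner.join((a, a)),
        "het": joiner.join((a, b)),
        "homB": joiner.join((b, b)),
    }[genotype]


def call_multiallelic(
    assay: AssayData, config: CallConfig | None = None
) -> MultiallelicResult:
    """Call a k-allele assay (k >= 3) through biallelic sub-assays.

    Every sub-assay gets its own independently computed cut-off pair
    and cluster model; sub-assays below the 30-sample normality guard
    are still called but carry the small-sample warning.  Every input
    sample appears exactly once in the merged output.
    """
    if config is None:
        config = CallConfig()
    if assay.n_alleles == 2:
        raise BeadcallError(
            f"SNP {assay.snp_id!r} is biallelic; use beadcall.calling.call_assay"
        )
    sub_assays, ambiguous = split_by_top_two(assay)

    merged: dict[str, GenotypeCall] = {}
    sub_results: dict[tuple[str, str], AssayResult] = {}
    for sub in sub_assays:
        result = call_assay(sub.assay, config, hwe=False)
        sub_results[sub.allele_pair] = result
        for call in result.calls:
            if call.label in (NO_CALL, THRESHOLD_CALL):
                label = call.label
            else:
                label = _pair_label(call.label, sub.allele_pair)
            merged[call.sample_id] = GenotypeCall(
                call.sample_id, label, call.phi, call.total, call.reason
            )

    for i, sample in enumerate(assay.samples):
        if sample in merged:
            continue
        # ambiguous probe ranking: top-two premise violated
        total = float(assay.mfi[i].sum())
        merged[sample] = GenotypeCall(
            sample, NO_CALL, math.nan, total, "ambiguous_probe_rank"
        )

    calls = [merged[sample] for sample in assay.samples]
    return MultiallelicResult(
        snp_id=assay.snp_id,
        calls=calls,
        sub_results=sub_results,
        ambiguous_samples=ambiguous,
    )


__all__ = ["SubAssay", "MultiallelicResult", "split_by_top_two", "call_multiallelic"]
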