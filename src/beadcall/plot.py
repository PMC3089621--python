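"""Cluster plot: log total intensity against normalized intensity phi.

The standard diagnostic view of a two-probe genotyping assay: each
sample is a point at (phi, log10(vA + vB)); the three genotype clusters
appear as vertical bands, colour-coded, with no-calls in red and
below-threshold samples in grey.  Bracket marks on the phi axis show
the cluster confidence-interval boundaries, and the silhouette score
and HWE p-value of the run are annotated.
"""

from __future__ import annotations

import math
from pathlib import Path

import matplotlib

matplotlib.use("Agg")  # headless backend; plots are always written to files

import matplotlib.pyplot as plt

from .calling import AssayResult
from .data import GENOTYPES, NO_CALL, THRESHOLD_CALL

#: Genotype colours in the conventional scheme: A-homozygote blue,
#: heterozygote black, B-homozygote green, no-call red.
CALL_COLORS = {
    "homA": "tab:blue",
    "het": "black",
    "homB": "tab:green",
    NO_CALL: "red",
    THRESHOLD_CALL: "0.6",
}

_BRACKET_COLOR = {"homB": "tab:green", "het": "black", "homA": "tab:blue"}


def render_cluster_plot(result: AssayResult, path, *, dpi: int = 120) -> Path:
    """Render the cluster plot for one called assay to ``path``.

    The output format follows the file suffix (``.png`` or ``.svg``).
    SVG output is written without a creation date so identical runs
    produce identical files.
    """
    path = Path(path)
    fig, ax = plt.subplots(figsize=(7, 5))

    by_label: dict[str, tuple[list[float], list[float]]] = {}
    for call in result.calls:
        if math.isnan(call.phi) or call.total <= 0:
            continue  # zero-total samples have no position on either axis
        xs, ys = by_label.setdefault(call.label, ([], []))
        xs.append(call.phi)
        ys.append(math.log10(call.total))
    for label in (*GENOTYPES, NO_CALL, THRESHOLD_CALL):
        if label not in by_label:
            continue
        xs, ys = by_label[label]
        ax.scatter(xs, ys, s=18, color=CALL_COLORS[label], label=f"{label} ({len(xs)})",
                   alpha=0.85, linewidths=0)

    # bracket marks at the confidence-interval boundaries
    for genotype in GENOTYPES:
        interval = result.model.intervals.get(genotype)
        if interval is None:
            continue
        color = _BRACKET_COLOR[genotype]
        for x, mark in ((interval.lo, "["), (interval.hi, "]")):
            ax.axvline(x, color=color, linestyle=":", linewidth=0.8, alpha=0.6)
            ax.text(x, 0.02, mark, color=color, fontsize=11,
                    ha="center", va="bottom", transform=ax.get_xaxis_transform())

    qc = result.qc
    sil = "n/a" if qc.silhouette is None else f"{qc.silhouette:.3f}"
    hwe = "n/a" if qc.hwe_p is None else f"{qc.hwe_p:.3f}"
    ax.text(0.02, 0.98,
            f"silhouette = {sil} ({qc.silhouette_band})\nHWE p = {hwe}",
            transform=ax.transAxes, va="top", fontsize=9,
            bbox=dict(boxstyle="round", facecolor="white", alpha=0.8))

    ax.set_xlim(-0.02, 1.02)
    ax.set_xlabel(r"normalized intensity $\phi = v_A / (v_A + v_B)$")
    ax.set_ylabel(r"$\log_{10}(v_A + v_B)$")
    ax.set_title(
        f"{result.snp_id}  (CoD={result.cutoffs.cod:.2f}, "
        f"CoU={result.cutoffs.cou:.2f}, {result.cutoffs.method})"
    )
    ax.legend(loc="center left", fontsize=8, framealpha=0.8)
    fig.tight_layout()
    if path.suffix.lower() == ".svg":
        # fixed hashsalt + no date: identical runs give identical files
        with matplotlib.rc_context({"svg.hashsalt": "beadcall"}):
            fig.savefig(path, dpi=dpi, metadata={"Date": None})
    else:
        fig.savefig(path, dpi=dpi)
    plt.close(fig)
    return path


__all__ = ["CALL_COLORS", "render_cluster_plot"]
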