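"""Unit tests for normalization, cut-offs, boundaries and assignment."""

import math
import statistics

import numpy as np
import pytest

from beadcall.calling import (
    CallConfig,
    assign_calls,
    build_cluster_model,
    call_assay,
    cluster_boundaries,
    cutoffs_arbitrary,
    cutoffs_experimental,
    normalize,
    partition,
)
from beadcall.data import (
    AssayData,
    BeadcallError,
    ClusterInterval,
    ClusterModel,
    CutoffPair,
    ManualCutoffEntry,
    NormalizedPoint,
)
from beadcall.simulate import SimulationParams, simulate_assay


def _point(phi, total=1000.0, sample="s"):
    log_total = math.log10(total) if total > 0 else math.nan
    return NormalizedPoint(sample, phi, total, log_total)


class TestNormalize:
    @pytest.mark.parametrize(
        "va, vb, expected",
        [(100, 0, 1.0), (250, 250, 0.5), (300, 100, 0.75), (0, 80, 0.0)],
    )
    def test_ratio(self, va, vb, expected):
        assert normalize(va, vb) == pytest.approx(expected)

    def test_zero_total_is_undefined(self):
        assert math.isnan(normalize(0.0, 0.0))

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            normalize(-1.0, 10.0)


class TestCutoffs:
    def test_arbitrary_pair(self):
        pair = cutoffs_arbitrary()
        assert (pair.cod, pair.cou) == (0.3, 0.7)
        assert pair.method == "arbitrary"

    # symmetric probe maxima M with a pooled mean of r*M give
    # CoU = 1/(1+r): the formula's anchor points.
    @pytest.mark.parametrize(
        "va, vb, cod, cou",
        [
            ([1000, 0], [0, 1000], 1 / 3, 2 / 3),          # mean-max ratio 1/2
            ([900, 0, 0], [0, 900, 0], None, 3 / 4),       # ratio 1/3
            ([600, 600, 0], [600, 600, 0], None, 3 / 5),   # ratio 2/3
            ([500, 500], [500, 500], 1 / 2, 1 / 2),        # ratio 1 (degenerate)
        ],
    )
    def test_mean_max_ratio_anchor_points(self, va, vb, cod, cou):
        pair = cutoffs_experimental(va, vb)
        assert pair.cou == pytest.approx(cou)
        if cod is not None:
            assert pair.cod == pytest.approx(cod)
        assert pair.method == "experimental"

    def test_all_zero_intensities_error(self):
        with pytest.raises(BeadcallError):
            cutoffs_experimental([0.0, 0.0], [0.0, 0.0])

    def test_empty_or_mismatched_lists_error(self):
        with pytest.raises(ValueError):
            cutoffs_experimental([], [])
        with pytest.raises(ValueError):
            cutoffs_experimental([1.0], [1.0, 2.0])


class TestPartition:
    def test_one_point_per_group(self):
        pair = cutoffs_arbitrary()
        groups = partition([_point(0.1), _point(0.5), _point(0.9)], pair)
        assert [len(groups[g]) for g in ("low", "mid", "high")] == [1, 1, 1]

    def test_half_open_boundaries(self):
        # [0; CoD[ , [CoD; CoU[ , [CoU; 1]: CoD belongs to mid, CoU to high
        pair = cutoffs_arbitrary()
        assert partition([_point(0.29)], pair)["low"]
        assert partition([_point(0.3)], pair)["mid"]
        assert partition([_point(0.7)], pair)["high"]

    def test_conservation_on_uniform_grid(self):
        points = [_point(phi) for phi in np.linspace(0, 1, 1000)]
        groups = partition(points, cutoffs_arbitrary())
        assert sum(len(g) for g in groups.values()) == 1000

    def test_undefined_phi_is_skipped(self):
        groups = partition([_point(math.nan, total=0.0)], cutoffs_arbitrary())
        assert sum(len(g) for g in groups.values()) == 0


class TestClusterBoundaries:
    def test_degenerate_group_gives_point_interval(self):
        interval = cluster_boundaries([0.5, 0.5, 0.5], alpha=0.05)
        assert (interval.lo, interval.hi) == (0.5, 0.5)
        assert interval.sd == 0.0

    def test_half_width_is_u_times_sigma(self):
        # group chosen so mean = 0.9, sample sd = 0.1 exactly; the upper
        # bound clamps to 1 and the lower sits at mean - U_{0.975} * sd.
        group = [0.8, 0.9, 1.0]
        u = statistics.NormalDist().inv_cdf(0.975)  # independent quantile oracle
        interval = cluster_boundaries(group, alpha=0.05, side="lower_only")
        assert interval.hi == 1.0
        assert interval.lo == pytest.approx(0.9 - u * 0.1)
        assert interval.lo == pytest.approx(0.704, abs=5e-4)

    def test_lower_alpha_widens_interval(self):
        group = [0.45, 0.5, 0.55]
        narrow = cluster_boundaries(group, alpha=0.05)
        wide = cluster_boundaries(group, alpha=0.0001)
        assert wide.lo < narrow.lo and wide.hi > narrow.hi

    def test_empty_group_means_absent_genotype(self):
        assert cluster_boundaries([], alpha=0.05) is None

    def test_singleton_group_flagged(self):
        interval = cluster_boundaries([0.5], alpha=0.05)
        assert interval.singleton and interval.lo == interval.hi == 0.5

    def test_natural_limits_pinned(self):
        low = cluster_boundaries([0.02, 0.05, 0.08], 0.05, side="upper_only")
        high = cluster_boundaries([0.92, 0.95, 0.98], 0.05, side="lower_only")
        assert low.lo == 0.0 and high.hi == 1.0


class TestAssignCalls:
    def _model(self):
        intervals = {
            "homB": ClusterInterval(10, 0.03, 0.01, 0.0, 0.1),
            "het": ClusterInterval(10, 0.5, 0.02, 0.4, 0.6),
            "homA": ClusterInterval(10, 0.97, 0.01, 0.9, 1.0),
        }
        return ClusterModel(intervals=intervals, alpha=0.05, u_quantile=1.96)

    def test_threshold_beats_everything(self):
        calls = assign_calls([_point(0.5, total=250.0)], self._model(), 300.0)
        assert calls[0].label == "THR"
        assert calls[0].reason == "below_threshold"

    def test_gap_between_intervals_is_no_call(self):
        calls = assign_calls([_point(0.75)], self._model(), 300.0)
        assert calls[0].label == "NA"
        assert calls[0].reason == "outside_all_intervals"

    def test_inside_intervals_called(self):
        calls = assign_calls(
            [_point(0.05), _point(0.5), _point(0.95)], self._model(), 300.0
        )
        assert [c.label for c in calls] == ["homB", "het", "homA"]

    def test_zero_total_thr_even_with_zero_threshold(self):
        calls = assign_calls([_point(math.nan, total=0.0)], self._model(), 0.0)
        assert calls[0].label == "THR"
        assert calls[0].reason == "zero_total"

    def test_shared_endpoint_goes_to_upper_cluster(self):
        intervals = {
            "homB": ClusterInterval(5, 0.05, 0.02, 0.0, 0.3),
            "het": ClusterInterval(5, 0.5, 0.05, 0.3, 0.6),
            "homA": None,
        }
        model = ClusterModel(intervals=intervals, alpha=0.05, u_quantile=1.96)
        calls = assign_calls([_point(0.3)], model, 300.0)
        assert calls[0].label == "het"


class TestCallAssay:
    def test_clean_assay_calls_three_groups(self, tight_assay, tight_result):
        counts = tight_result.call_counts
        assert all(counts[g] > 0 for g in ("homA", "het", "homB"))
        assert tight_result.qc.warnings == []
        assert counts["THR"] == 0

    def test_call_count_conservation(self, tight_assay, tight_result):
        assay, _ = tight_assay
        assert sum(tight_result.call_counts.values()) == assay.n_samples

    def test_small_assay_warns_but_calls(self):
        assay, _ = simulate_assay(SimulationParams(n_samples=20, seed=5))
        result = call_assay(assay)
        assert "small_sample" in result.qc.warnings
        assert len(result.calls) == 20
        assert result.model.small_sample_warning

    def test_monoallelic_with_arbitrary_cutoffs(self):
        assay, _ = simulate_assay(
            SimulationParams(n_samples=60, allele_freq=1.0, seed=2)
        )
        result = call_assay(assay, CallConfig(cutoff_method="arbitrary"))
        genotyped = [c for c in result.calls if c.is_genotype]
        assert genotyped and all(c.label == "homA" for c in genotyped)

    def test_multiallelic_assay_rejected(self):
        assay = AssayData("snpX", ("A", "B", "C"), ("s1",), [[1.0, 2.0, 3.0]])
        with pytest.raises(BeadcallError, match="multiallelic"):
            call_assay(assay)

    def test_manual_cutoffs_override_method(self, tight_assay):
        assay, _ = tight_assay
        manual = {assay.snp_id: ManualCutoffEntry(assay.snp_id, 0.4, 0.9)}
        result = call_assay(
            assay, CallConfig(cutoff_method="experimental", manual_cutoffs=manual)
        )
        assert result.cutoffs.method == "manual"
        assert (result.cutoffs.cod, result.cutoffs.cou) == (0.4, 0.9)

    def test_manual_method_without_entry_errors(self, tight_assay):
        assay, _ = tight_assay
        with pytest.raises(BeadcallError, match="manual"):
            call_assay(assay, CallConfig(cutoff_method="manual"))

    def test_all_below_threshold_gives_all_thr(self):
        assay = AssayData(
            "snpY", ("A", "B"), ("s1", "s2"), [[10.0, 20.0], [5.0, 1.0]]
        )
        result = call_assay(assay)
        assert [c.label for c in result.calls] == ["THR", "THR"]
        assert result.qc.silhouette_band == "not_applicable"

    def test_relaxing_alpha_never_adds_no_calls(self, tight_assay):
        assay, _ = tight_assay
        na_default = call_assay(assay, CallConfig(alpha=0.05)).call_counts["NA"]
        na_strict = call_assay(assay, CallConfig(alpha=0.0001)).call_counts["NA"]
        assert na_strict <= na_default


def test_cutoff_pair_validation():
    with pytest.raises(ValueError):
        CutoffPair(cod=0.8, cou=0.4, method="arbitrary")
    with pytest.raises(ValueError):
        CutoffPair(cod=0.0, cou=0.7, method="arbitrary")
    with pytest.raises(ValueError):
        CutoffPair(cod=0.3, cou=0.7, method="bogus")


def test_build_cluster_model_maps_groups_to_genotypes():
    groups = {
        "low": [_point(0.05), _point(0.06)],
        "mid": [_point(0.5)],
        "high": [],
    }
    model = build_cluster_model(groups, alpha=0.05)
    assert model.intervals["homB"].lo == 0.0
    assert model.intervals["het"].singleton
    assert model.intervals["homA"] is None
    assert model.small_sample_warning
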