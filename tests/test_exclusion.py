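"""Exclusion thresholds, sample filtering, success rates, contamination."""

import numpy as np
import pytest
from sklearn.base import clone

from katharoseq import (
    CompositionPoint,
    ExclusionDecision,
    FeatureTable,
    HillFit,
    ReadCountFilter,
    SampleRecord,
    SimulationParams,
    StudyDesign,
    apply_exclusion,
    contamination_report,
    generate_study,
    gel_comparison,
    success_rate,
    threshold_fit_half_max,
    threshold_max_input_median,
)
from katharoseq.errors import (
    ComputationError,
    MissingControlsError,
    UnreachableHalfMaxError,
    ValidationError,
)


def _fit(ymax=1.0, k=683.0, h=1.2, converged=True):
    return HillFit(
        ymax=ymax,
        k_half=k,
        h=h,
        r_squared=0.9,
        n_points=10,
        x_variable="reads",
        converged=converged,
    )


def _point(sid, depth, cells):
    return CompositionPoint(
        sample_id=sid, depth=depth, target_fraction=0.5, input_cells=cells
    )


class TestThresholds:
    def test_half_max_equals_k_half_at_unit_plateau(self):
        assert threshold_fit_half_max(_fit(k=683.0)) == 683

    def test_half_max_rounds_up(self):
        assert threshold_fit_half_max(_fit(k=10.2, h=1.0)) == 11

    def test_half_max_unreachable_plateau(self):
        with pytest.raises(UnreachableHalfMaxError):
            threshold_fit_half_max(_fit(ymax=0.4))

    def test_half_max_requires_convergence(self):
        with pytest.raises(ComputationError):
            threshold_fit_half_max(_fit(converged=False))

    def test_max_input_median_odd(self):
        pts = [
            _point("a", 1500, 5000),
            _point("b", 1696, 5000),
            _point("c", 2200, 5000),
            _point("d", 90, 50),  # lower level ignored
        ]
        assert threshold_max_input_median(pts) == 1696

    def test_max_input_median_single_control(self):
        assert threshold_max_input_median([_point("a", 2015, 5000)]) == 2015

    def test_max_input_median_even_takes_lower_central(self):
        pts = [_point("a", 10, 5000), _point("b", 20, 5000)]
        assert threshold_max_input_median(pts) == 10

    def test_max_input_median_duplication_invariant(self):
        pts = [_point(f"a{i}", d, 5000) for i, d in enumerate((1500, 1696, 2200))]
        doubled = pts + [
            _point(f"b{i}", p.depth, p.input_cells) for i, p in enumerate(pts)
        ]
        assert threshold_max_input_median(pts) == threshold_max_input_median(doubled)

    def test_max_input_median_requires_positives(self):
        with pytest.raises(MissingControlsError):
            threshold_max_input_median([])


def _depth_table(depths: dict):
    sids = tuple(depths)
    counts = np.array([[depths[s] for s in sids]])
    return FeatureTable(("f1",), sids, counts)


def _plain_design(sids):
    return StudyDesign(
        records={s: SampleRecord(sample_id=s, control_class="sample") for s in sids}
    )


class TestApplyExclusion:
    def test_boundary_inclusive_retention(self):
        table = _depth_table({"lo": 100, "at": 683, "hi": 5000})
        decisions, filtered = apply_exclusion(
            table, _plain_design(table.sample_ids), 683
        )
        verdicts = {d.sample_id: d.retained for d in decisions}
        assert verdicts == {"lo": False, "at": True, "hi": True}
        assert filtered.sample_ids == ("at", "hi")

    def test_threshold_one_keeps_all_nonzero(self):
        table = _depth_table({"a": 1, "b": 0, "c": 50})
        decisions, filtered = apply_exclusion(
            table, _plain_design(table.sample_ids), 1
        )
        assert set(filtered.sample_ids) == {"a", "c"}

    def test_decisions_partition_and_counts_conserved(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 200, size=(4, 6))
        table = FeatureTable(
            tuple(f"f{i}" for i in range(4)),
            tuple(f"s{i}" for i in range(6)),
            counts,
        )
        decisions, filtered = apply_exclusion(
            table, _plain_design(table.sample_ids), 300
        )
        assert len(decisions) == 6
        assert sum(d.retained for d in decisions) + sum(
            not d.retained for d in decisions
        ) == 6
        for sid in filtered.sample_ids:
            assert (
                filtered.sample_counts(sid) == table.sample_counts(sid)
            ).all()

    def test_retention_is_monotone_in_depth(self):
        table = _depth_table({f"s{i}": d for i, d in enumerate(range(0, 2000, 97))})
        decisions, _ = apply_exclusion(table, _plain_design(table.sample_ids), 777)
        by_depth = sorted(decisions, key=lambda d: d.depth)
        flags = [d.retained for d in by_depth]
        assert flags == sorted(flags)  # once retained, deeper stays retained

    def test_positive_threshold_required(self):
        table = _depth_table({"a": 5})
        with pytest.raises(ValidationError):
            apply_exclusion(table, _plain_design(("a",)), 0)


def _decisions(n_retained, n_total, prefix="lib"):
    out = []
    for i in range(n_total):
        retained = i < n_retained
        out.append(
            ExclusionDecision(
                sample_id=f"{prefix}{i}",
                depth=1000 if retained else 10,
                threshold=683.0,
                retained=retained,
                strategy="fixed",
            )
        )
    return out


class TestRates:
    def test_success_rate_simple(self):
        decisions = _decisions(9, 10)
        assert success_rate(decisions, [d.sample_id for d in decisions]) == 0.9

    def test_success_rate_all_excluded(self):
        decisions = _decisions(0, 5)
        assert success_rate(decisions, [d.sample_id for d in decisions]) == 0.0

    def test_success_rate_16_of_18(self):
        decisions = _decisions(16, 18)
        assert success_rate(decisions, [d.sample_id for d in decisions]) == (
            pytest.approx(16 / 18)
        )

    def test_success_rate_empty_subset(self):
        with pytest.raises(ValidationError):
            success_rate(_decisions(1, 2), [])

    def test_gel_false_negativity_from_printed_counts(self):
        """26 banded among 37 read-retained libraries -> 11/37 ≈ 30%."""
        decisions = _decisions(37, 72)
        bands = {d.sample_id: False for d in decisions}
        for d in decisions[:26]:  # banded libraries are all read-retained
            bands[d.sample_id] = True
        rate = gel_comparison(bands, decisions)
        assert rate == pytest.approx(11 / 37)
        assert round(100 * rate) == 30

    def test_gel_all_banded_and_none_banded(self):
        decisions = _decisions(4, 6)
        assert gel_comparison(
            {d.sample_id: d.retained for d in decisions}, decisions
        ) == 0.0
        assert gel_comparison({d.sample_id: False for d in decisions}, decisions) == 1.0

    def test_gel_requires_full_coverage_and_retained(self):
        decisions = _decisions(2, 3)
        with pytest.raises(ValidationError):
            gel_comparison({}, decisions)
        none_retained = _decisions(0, 3)
        with pytest.raises(ComputationError):
            gel_comparison({d.sample_id: True for d in none_retained}, none_retained)


class TestContamination:
    def test_background_cells_is_the_fitted_k_half(self, default_titration):
        table, design = default_titration
        fit = HillFit(
            ymax=1.0, k_half=96.88, h=1.377, r_squared=0.92, n_points=72,
            x_variable="cells",
        )
        report = contamination_report(table, design, "g__Bacillus", fit)
        assert report.background_cells == 96.88
        assert report.target_in_negatives is not None

    def test_no_leakage_means_no_target_in_samples(self):
        params = SimulationParams(leakage_rate=0.0, n_samples=20)
        table, design = generate_study(params, seed=5)
        fit = HillFit(
            ymax=1.0, k_half=96.88, h=1.377, r_squared=0.9, n_points=10,
            x_variable="cells",
        )
        report = contamination_report(table, design, "g__Bacillus", fit)
        assert report.target_in_samples["max"] == 0.0
        assert report.flagged_samples == []

    def test_one_percent_leakage_recovered(self):
        params = SimulationParams(leakage_rate=0.01, n_samples=200)
        table, design = generate_study(params, seed=6)
        fit = HillFit(
            ymax=1.0, k_half=96.88, h=1.377, r_squared=0.9, n_points=10,
            x_variable="cells",
        )
        report = contamination_report(table, design, "g__Bacillus", fit)
        assert report.target_in_samples["median"] == pytest.approx(0.01, abs=0.005)


class TestReadCountFilter:
    def test_learns_median_threshold_and_filters(self, default_titration):
        table, design = default_titration
        filt = ReadCountFilter(strategy="max_input_median")
        filtered = filt.fit_transform(table, design)
        points = [
            p
            for p in _titration_points(table, design)
            if p.input_cells == 5000.0
        ]
        assert filt.threshold_ == threshold_max_input_median(points)
        assert len(filt.decisions_) == table.n_samples
        assert set(filtered.sample_ids) == {
            d.sample_id for d in filt.decisions_ if d.retained
        }

    def test_fit_half_max_strategy(self, default_titration):
        table, design = default_titration
        filt = ReadCountFilter(strategy="fit_half_max", ymax_mode="fixed_1")
        filt.fit(table, design)
        assert filt.reads_fit_.x_variable == "reads"
        assert filt.threshold_ > 0

    def test_missing_controls_raise(self, default_titration):
        table, _ = default_titration
        design = _plain_design(table.sample_ids)
        with pytest.raises(MissingControlsError):
            ReadCountFilter(strategy="max_input_median").fit(table, design)

    def test_sklearn_clone(self):
        filt = ReadCountFilter(strategy="fixed", threshold=683)
        assert clone(filt).get_params() == filt.get_params()


def _titration_points(table, design):
    from katharoseq import composition_points

    points, _ = composition_points(table, design, {"extraction_positive"})
    return points
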