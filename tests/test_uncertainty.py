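"""DVH computation, DVH metrics, ensemble statistics, cohort summary."""

from __future__ import annotations

import numpy as np
import pytest

from redose_uq import (
    GridGeometry,
    MappedDose,
    StructureMask,
    VolumeGrid,
    build_report,
    compute_dvh,
    dose_at_volume,
    dvh_metric,
    metric_stats,
    organ_mean_dose,
    summarise_cohort,
    voxelwise_sd,
)
from redose_uq.plausibility import PlausibilityRecord
from redose_uq.uncertainty import OARUncertaintyReport

GEOM = GridGeometry((0.0, 0.0, 0.0), (1.0, 1.0, 1.0), (20, 20, 20))


def mapped(values, geom=GEOM, valid=None, label="cfg"):
    values = np.asarray(values, dtype=float)
    if valid is None:
        valid = np.ones(values.shape, dtype=bool)
    return MappedDose(label, VolumeGrid(geom, values), valid)


def full_mask(geom=GEOM, organ_class="parallel", name="oar"):
    return StructureMask(name, organ_class, VolumeGrid(geom, np.ones(geom.size)))


def box_mask(sl, geom=GEOM, organ_class="parallel", name="oar"):
    vals = np.zeros(geom.size)
    vals[sl] = 1.0
    return StructureMask(name, organ_class, VolumeGrid(geom, vals))


class TestDVH:
    def test_uniform_dose_is_a_step(self):
        curve = compute_dvh(mapped(np.full(GEOM.size, 30.0)), full_mask(), 0.1)
        assert curve.rel_volume[0] == 1.0
        inside = curve.bin_edges_gy <= 30.0
        assert np.all(curve.rel_volume[inside] == 1.0)
        assert np.all(curve.rel_volume[~inside] == 0.0)

    def test_linear_ramp_matches_uniform_cdf(self):
        """Doses uniform on (0, 60): V(d) = 1 - d/60 within one bin."""
        vals = np.linspace(0.0, 60.0, np.prod(GEOM.size)).reshape(GEOM.size)
        curve = compute_dvh(mapped(vals), full_mask(), bin_width_gy=0.1)
        expected = np.clip(1.0 - curve.bin_edges_gy / 60.0, 0.0, 1.0)
        assert np.max(np.abs(curve.rel_volume - expected)) < 0.1 / 60.0 + 1e-6

    def test_single_voxel_steps_at_its_bin(self):
        vals = np.zeros(GEOM.size)
        vals[3, 4, 5] = 12.34
        m = box_mask((3, 4, 5))
        curve = compute_dvh(mapped(vals), m, 0.1)
        assert curve.volume_at_dose(12.3) == 1.0
        assert curve.volume_at_dose(12.5) == 0.0

    def test_monotone_non_increasing_and_anchored(self, rng):
        vals = rng.uniform(0, 70, GEOM.size)
        curve = compute_dvh(mapped(vals), full_mask(), 0.5)
        assert curve.rel_volume[0] == 1.0
        assert np.all(np.diff(curve.rel_volume) <= 1e-12)
        assert curve.rel_volume[-1] == 0.0

    def test_invalid_voxels_excluded(self):
        vals = np.full(GEOM.size, 40.0)
        valid = np.ones(GEOM.size, bool)
        valid[:10] = False
        vals[:10] = 0.0  # stored zeros must not enter the DVH
        curve = compute_dvh(mapped(vals, valid=valid), full_mask(), 0.1)
        assert curve.volume_at_dose(39.9) == 1.0

    def test_no_valid_voxels_rejected(self):
        with pytest.raises(ValueError):
            compute_dvh(mapped(np.zeros(GEOM.size), valid=np.zeros(GEOM.size, bool)),
                        full_mask(), 0.1)


class TestDoseAtVolume:
    def test_uniform_dose_any_volume(self):
        md = mapped(np.full(GEOM.size, 50.0))
        assert dose_at_volume(md, full_mask(), 0.1) == 50.0
        assert dose_at_volume(md, full_mask(), 3.0) == 50.0

    def test_full_volume_returns_minimum(self, rng):
        vals = rng.uniform(10, 60, GEOM.size)
        md = mapped(vals)
        total_cc = np.prod(GEOM.size) * GEOM.voxel_volume_mm3 / 1000.0
        assert dose_at_volume(md, full_mask(), total_cc) == pytest.approx(vals.min())

    def test_sorted_walk_with_interpolation(self):
        """1000 voxels of 0.1 cm3 with doses 1..1000 Gy:
        D(0.1 cm3) = 1000 Gy, D(0.25 cm3) = 998.5 Gy (hand enumeration)."""
        geom = GridGeometry((0, 0, 0), (10.0, 10.0, 1.0), (10, 10, 10))
        vals = np.arange(1.0, 1001.0).reshape(10, 10, 10)
        md = mapped(vals, geom=geom)
        mask = StructureMask("o", "serial", VolumeGrid(geom, np.ones(geom.size)))
        assert dose_at_volume(md, mask, 0.1) == pytest.approx(1000.0)
        assert dose_at_volume(md, mask, 0.25) == pytest.approx(998.5)

    def test_volume_beyond_organ_rejected(self):
        md = mapped(np.full(GEOM.size, 50.0))
        with pytest.raises(ValueError):
            dose_at_volume(md, full_mask(), 1e6)
        with pytest.raises(ValueError):
            dose_at_volume(md, full_mask(), 0.0)

    def test_hot_spot_dominates_mean_dominates_min(self, rng):
        """For any single dose grid: D0.1cm3 >= organ mean >= organ min."""
        for _ in range(10):
            vals = rng.gamma(3.0, 5.0, GEOM.size)
            md = mapped(vals)
            mask = full_mask()
            d01 = dose_at_volume(md, mask, 0.1)
            mean = organ_mean_dose(md, mask)
            assert d01 >= mean >= vals.min()

    def test_dvh_and_dose_at_volume_mutually_consistent(self, rng):
        """Reading dose off the DVH at relative volume v agrees with
        dose_at_volume(v * organ volume) within one bin width."""
        vals = rng.uniform(0, 60, GEOM.size)
        md = mapped(vals)
        mask = full_mask()
        bw = 0.2
        curve = compute_dvh(md, mask, bw)
        total_cc = np.prod(GEOM.size) * GEOM.voxel_volume_mm3 / 1000.0
        for v in (0.9, 0.5, 0.1):
            dose = dose_at_volume(md, mask, v * total_cc)
            # invert the curve at v
            idx = np.searchsorted(-curve.rel_volume, -v)
            dvh_dose = curve.bin_edges_gy[min(idx, len(curve.bin_edges_gy) - 1)]
            assert abs(dvh_dose - dose) <= bw + 1e-9


class TestMetricStats:
    def test_identical_members_have_zero_sd_exactly(self):
        doses = [mapped(np.full(GEOM.size, 30.0), label=f"c{i}") for i in range(4)]
        stats = metric_stats(doses, full_mask())
        assert stats.sd_gy == 0.0 and stats.mean_gy == 30.0

    def test_two_member_sample_sd_is_delta_over_sqrt2(self):
        doses = [mapped(np.full(GEOM.size, 10.0)), mapped(np.full(GEOM.size, 12.0))]
        stats = metric_stats(doses, full_mask())
        assert stats.mean_gy == pytest.approx(11.0)
        assert stats.sd_gy == pytest.approx(2.0 / np.sqrt(2.0))
        assert stats.sd_gy == pytest.approx(1.4142, abs=5e-5)

    def test_single_member_sd_undefined_not_zero(self):
        stats = metric_stats([mapped(np.full(GEOM.size, 20.0))], full_mask())
        assert stats.mean_gy == 20.0 and stats.sd_gy is None and not stats.sd_defined

    def test_empty_ensemble_flagged(self):
        stats = metric_stats([], full_mask())
        assert stats.n == 0 and stats.mean_gy is None

    def test_serial_organ_uses_hot_spot_metric(self, rng):
        vals = rng.uniform(0, 60, GEOM.size)
        md = mapped(vals)
        serial = full_mask(organ_class="serial")
        assert dvh_metric(md, serial) == dose_at_volume(md, serial, 0.1)
        parallel = full_mask(organ_class="parallel")
        assert dvh_metric(md, parallel) == organ_mean_dose(md, parallel)


class TestVoxelwiseSD:
    def test_identical_members_give_exactly_zero_map(self, rng):
        base = rng.uniform(0, 50, GEOM.size)
        doses = [mapped(base.copy(), label=f"c{i}") for i in range(5)]
        out = voxelwise_sd(doses, full_mask())
        assert np.all(out.sd.values == 0.0)

    def test_single_voxel_difference(self):
        a = np.full(GEOM.size, 10.0)
        b = a.copy()
        b[5, 5, 5] += 3.0
        out = voxelwise_sd([mapped(a), mapped(b)], full_mask())
        assert out.sd.values[5, 5, 5] == pytest.approx(3.0 / np.sqrt(2.0))
        assert out.sd.values[5, 5, 5] == pytest.approx(2.1213, abs=5e-5)
        assert np.all(np.delete(out.sd.values, 5 * 400 + 5 * 20 + 5) == 0.0)

    def test_matches_two_pass_oracle_exactly(self, rng):
        """Seeded per-config perturbations: the map equals a brute-force
        two-pass SD over the stacked values."""
        base = rng.uniform(0, 50, GEOM.size)
        doses = [mapped(base + rng.normal(0, 2.0, GEOM.size), label=f"c{k}") for k in range(6)]
        mask = box_mask((slice(4, 16), slice(4, 16), slice(4, 16)))
        out = voxelwise_sd(doses, mask)
        stack = np.stack([d.dose.values for d in doses])
        oracle = np.std(stack, axis=0, ddof=1)
        inside = mask.indicator
        np.testing.assert_array_equal(out.sd.values[inside], oracle[inside])
        assert np.all(out.sd.values[~inside] == 0.0)

    def test_voxels_valid_in_fewer_than_two_members_flagged(self):
        a = mapped(np.full(GEOM.size, 10.0))
        valid = np.ones(GEOM.size, bool)
        valid[0, 0, 0] = False
        b = mapped(np.full(GEOM.size, 12.0), valid=valid)
        out = voxelwise_sd([a, b], full_mask())
        assert not out.defined[0, 0, 0]
        assert out.sd.values[0, 0, 0] == 0.0

    def test_fewer_than_two_members_rejected(self):
        with pytest.raises(ValueError):
            voxelwise_sd([mapped(np.zeros(GEOM.size))], full_mask())

    def test_plausible_spread_with_flat_dose_gives_zero_dose_sd(self):
        """Geometric spread does not imply dose uncertainty: divergent
        fields sampling a zero-gradient dose region produce identical
        mapped doses, hence a zero SD map."""
        flat = np.full(GEOM.size, 20.0)
        doses = [mapped(flat.copy(), label=f"c{i}") for i in range(3)]
        out = voxelwise_sd(doses, full_mask())
        assert np.all(out.sd.values == 0.0)


def simple_records(labels, oar, plausible):
    return [
        PlausibilityRecord(lbl, oar, 0.05 if lbl in plausible else 0.8, lbl in plausible)
        for lbl in labels
    ]


class TestReportAndCohort:
    labels = ["CC1", "CC3", "CC5", "MI1", "MI3", "MI5"]

    def test_report_structure_consistent(self):
        mask = full_mask(name="oar")
        doses = [mapped(np.full(GEOM.size, 30.0 + i), label=lbl)
                 for i, lbl in enumerate(self.labels)]
        rep = build_report("case", "oar", simple_records(self.labels, "oar", set(self.labels)),
                           doses, mask)
        assert rep.n_configs == 6 and rep.n_plausible == 6
        assert len(rep.dvh_ensemble) == rep.n_plausible
        assert rep.metric.sd_defined and rep.voxel_sd is not None
        assert rep.invalid_voxel_fraction == 0.0
        assert rep.mappable

    def test_zero_plausible_report_carries_flag_without_numbers(self):
        mask = full_mask(name="oar")
        rep = build_report("case", "oar", simple_records(self.labels, "oar", set()), [], mask)
        assert not rep.mappable and rep.metric is None and rep.dvh_ensemble == []

    def test_mismatched_mapped_count_rejected(self):
        mask = full_mask(name="oar")
        with pytest.raises(ValueError):
            build_report("case", "oar", simple_records(self.labels, "oar", {"CC1"}), [], mask)

    def _report(self, case, oar, n_pl, n_cfg, sd):
        return OARUncertaintyReport(
            case_id=case, oar_name=oar, organ_class="parallel",
            n_configs=n_cfg, n_plausible=n_pl,
            metric=None if sd is None else type(
                "M", (), {"sd_gy": sd, "metric_kind": "mean_dose"}
            )(),
        )

    def test_five_of_six_is_83_percent(self):
        summary = summarise_cohort([self._report("c1", "o1", 5, 6, 0.2)])
        assert summary.percent_plausible_overall == pytest.approx(83.3, abs=0.05)

    def test_all_plausible_is_100_percent(self):
        summary = summarise_cohort([self._report("c1", "o1", 6, 6, 0.1),
                                    self._report("c2", "o1", 6, 6, 0.3)])
        assert summary.percent_plausible_overall == 100.0

    def test_split_cohort_percentages(self):
        summary = summarise_cohort([self._report("c1", "o1", 6, 6, 0.1),
                                    self._report("c2", "o1", 0, 6, None)])
        assert summary.percent_plausible_overall == 50.0
        assert summary.percent_plausible_per_case["c1"] == 100.0
        assert summary.percent_plausible_per_case["c2"] == 0.0

    def test_sd_distribution_uses_iqr_outlier_rule(self):
        sds = [0.1, 0.11, 0.12, 0.13, 5.0]
        reports = [self._report(f"c{i}", "o1", 6, 6, s) for i, s in enumerate(sds)]
        summary = summarise_cohort(reports)
        row = summary.sd_distribution_per_oar.loc["o1"]
        assert row["outliers"] == [5.0]
        assert row["min"] == 0.1 and row["max"] == 5.0
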