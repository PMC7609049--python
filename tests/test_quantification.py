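"""Per-well aggregation, CV, linearity, edge effects, brightfield size."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from orgscreen.plate_io import WellImageSet
from orgscreen.quantification import (
    SYNTHETIC_NUCLEUS_GATE,
    WellSummary,
    batch_cv,
    dilution_linearity,
    edge_effect_report,
    quantify_filamentous_marker,
    quantify_nuclear_marker,
    size_from_brightfield,
    sox2_negative_fraction,
)
from orgscreen.synthetic_data import (
    AcquisitionModel,
    OrganoidPhenotype,
    generate_organoid_stack,
)


class TestNuclearQuantification:
    def test_totals_equal_per_plane_breakdown(self, small_organoid):
        stack, _ = small_organoid
        s = quantify_nuclear_marker(WellImageSet("A1", [stack]), "Sox2",
                                    SYNTHETIC_NUCLEUS_GATE)
        assert s.n_objects == sum(row[2] for row in s.per_plane)
        assert s.total_brightness_abu == pytest.approx(
            sum(row[3] for row in s.per_plane))
        assert s.aggregate_area_um2 == pytest.approx(
            sum(row[4] for row in s.per_plane))

    def test_planted_count_recovered_within_10_percent(self):
        """Every planted nucleus appears on exactly one plane, so summing
        per-plane counts recovers the planted total."""
        phen = OrganoidPhenotype(radius_um=110.0, n_nuclei=1200,
                                 zone_fractions={}, filament_density={})
        stack, gt = generate_organoid_stack(phen, AcquisitionModel(), seed=21,
                                            grid_shape=(256, 256), n_planes=14)
        s = quantify_nuclear_marker(WellImageSet("A1", [stack]), "DAPI",
                                    SYNTHETIC_NUCLEUS_GATE)
        assert s.n_objects == pytest.approx(1200, rel=0.10)

    def test_zero_marker_well_counts_zero(self):
        phen = OrganoidPhenotype(radius_um=50.0, n_nuclei=150,
                                 zone_fractions={"Sox2": (0.0,)}, filament_density={})
        stack, _ = generate_organoid_stack(phen, AcquisitionModel(), seed=22,
                                           grid_shape=(144, 144), n_planes=4)
        s = quantify_nuclear_marker(WellImageSet("A1", [stack]), "Sox2",
                                    SYNTHETIC_NUCLEUS_GATE)
        assert s.n_objects == 0

    def test_per_plane_counts_follow_sphere_profile(self):
        """Accepted nucleus counts peak at the equatorial planes and fall
        toward the poles (largest aggregate diameter = most nuclei)."""
        phen = OrganoidPhenotype(radius_um=70.0, n_nuclei=700, zone_fractions={},
                                 filament_density={})
        stack, _ = generate_organoid_stack(phen, AcquisitionModel(), seed=23,
                                           grid_shape=(192, 192), n_planes=8)
        s = quantify_nuclear_marker(WellImageSet("A1", [stack]), "DAPI",
                                    SYNTHETIC_NUCLEUS_GATE)
        counts = [row[2] for row in s.per_plane]
        mid = int(np.argmax(counts))
        assert 2 <= mid <= 5
        assert counts[mid] > counts[0] and counts[mid] > counts[-1]

    def test_qc_failed_well_refused_without_override(self, small_organoid):
        stack, _ = small_organoid
        well = WellImageSet("A1", [stack])
        with pytest.raises(ValueError, match="QC"):
            quantify_nuclear_marker(well, "Sox2", SYNTHETIC_NUCLEUS_GATE, qc_pass=False)
        s = quantify_nuclear_marker(well, "Sox2", SYNTHETIC_NUCLEUS_GATE,
                                    qc_pass=False, override_qc=True)
        assert not s.qc_pass


class TestFilamentousQuantification:
    def test_constant_intensity_sums_plane_means(self):
        """Constant 100 abu inside the mask over 10 planes sums to 1000."""
        from orgscreen.plate_io import ChannelSpec, ImageStack

        yy, xx = np.ogrid[:128, :128]
        disc = (yy - 64) ** 2 + (xx - 64) ** 2 <= 45**2
        plane = np.where(disc, 100.0, 0.0)
        voxels = np.stack([np.stack([plane] * 10)] * 2)
        stack = ImageStack(voxels, 1.0, 10.0,
                           [ChannelSpec("DAPI", "nuclear"),
                            ChannelSpec("Map2", "filamentous")])
        s = quantify_filamentous_marker(WellImageSet("A1", [stack]), "Map2")
        assert s.filament_intensity_abu == pytest.approx(1000.0, rel=1e-6)

    def test_no_aggregate_planes_give_zero(self, rng):
        from orgscreen.plate_io import ChannelSpec, ImageStack

        voxels = rng.normal(5, 1, size=(1, 4, 96, 96)).clip(0)
        stack = ImageStack(voxels, 1.0, 10.0, [ChannelSpec("Map2", "filamentous")])
        s = quantify_filamentous_marker(WellImageSet("A1", [stack]), "Map2")
        assert s.filament_intensity_abu == 0.0

    def test_metric_monotone_in_filament_density(self):
        values = []
        for density in (40.0, 80.0):
            phen = OrganoidPhenotype(radius_um=45.0, n_nuclei=80, zone_fractions={},
                                     filament_density={"Map2": density})
            stack, _ = generate_organoid_stack(phen, AcquisitionModel(), seed=24,
                                               grid_shape=(128, 128), n_planes=4)
            s = quantify_filamentous_marker(WellImageSet("A1", [stack]), "Map2")
            values.append(s.filament_intensity_abu)
        assert values[1] > values[0]


class TestMatureFraction:
    def _summary(self, n):
        return WellSummary("A1", "x", n_objects=n)

    @pytest.mark.parametrize("sox2,dapi,expected", [(30, 100, 0.70), (0, 50, 1.0),
                                                    (100, 100, 0.0), (120, 100, 0.0)])
    def test_formula(self, sox2, dapi, expected):
        assert sox2_negative_fraction(self._summary(sox2), self._summary(dapi)) == \
            pytest.approx(expected)

    def test_zero_total_count_rejected(self):
        with pytest.raises(ZeroDivisionError):
            sox2_negative_fraction(self._summary(5), self._summary(0))

    def test_planted_mature_fraction_recovered(self):
        """The marker-negative fraction of a synthetic organoid matches
        the planted composition within 5 percentage points."""
        phen = OrganoidPhenotype(radius_um=80.0, n_nuclei=500,
                                 zone_fractions={"Sox2": (0.25,)}, filament_density={})
        stack, gt = generate_organoid_stack(phen, AcquisitionModel(), seed=25,
                                            grid_shape=(208, 208), n_planes=10)
        well = WellImageSet("A1", [stack])
        s_sox2 = quantify_nuclear_marker(well, "Sox2", SYNTHETIC_NUCLEUS_GATE)
        s_dapi = quantify_nuclear_marker(well, "DAPI", SYNTHETIC_NUCLEUS_GATE)
        measured = sox2_negative_fraction(s_sox2, s_dapi)
        planted = 1.0 - gt.n_labeled("Sox2") / gt.n_nuclei
        assert measured == pytest.approx(planted, abs=0.05)


class TestBatchCV:
    def test_known_values(self):
        stats = batch_cv([1.0, 2.0, 3.0])
        assert stats.sd == pytest.approx(1.0)  # sample sd, n-1
        assert stats.cv == pytest.approx(0.5)
        assert batch_cv([2.0, 2.0, 2.0]).cv == 0.0

    @given(st.floats(0.1, 100.0))
    @settings(deadline=None, derandomize=True, max_examples=30)
    def test_scale_invariance(self, factor):
        base = [3.0, 4.0, 5.0, 6.0]
        assert batch_cv([factor * v for v in base]).cv == pytest.approx(
            batch_cv(base).cv, rel=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            batch_cv([1.0])
        with pytest.raises(ZeroDivisionError):
            batch_cv([-1.0, 1.0])


class TestEdgeEffect:
    def _summaries(self, edge_value, inside_value, jitter=0.0, seed=0):
        from orgscreen.plate_io import PlateLayout, classify_well_position

        rng = np.random.default_rng(seed)
        layout = PlateLayout()
        out = []
        for well in layout.well_ids():
            pos = classify_well_position(well, layout)
            value = edge_value if pos == "edge" else inside_value
            value *= 1 + jitter * rng.standard_normal()
            s = WellSummary(well, "Map2", filament_intensity_abu=value,
                            position_class=pos)
            out.append(s)
        return out

    def test_identical_wells_give_exactly_zero_difference(self):
        report = edge_effect_report(self._summaries(100.0, 100.0), "Map2")
        assert report["relative_difference"] == 0.0

    def test_planted_reduction_recovered_with_ci_excluding_zero(self):
        report = edge_effect_report(self._summaries(100.0, 90.0, jitter=0.03), "Map2",
                                    seed=1)
        assert report["relative_difference"] == pytest.approx(-0.10, abs=0.03)
        assert report["ci_high"] < 0.0

    def test_null_effect_ci_contains_zero(self):
        report = edge_effect_report(self._summaries(100.0, 100.0, jitter=0.05), "Map2",
                                    seed=2)
        assert report["ci_low"] < 0.0 < report["ci_high"]

    def test_too_few_wells_rejected(self):
        with pytest.raises(ValueError):
            edge_effect_report(self._summaries(100.0, 90.0)[:4], "Map2")


class TestDilutionLinearity:
    def test_collinear_points_give_r2_of_one(self):
        fractions = [0.0125, 0.025, 0.05, 0.1]
        values = [10 * f + 1 for f in fractions]
        assert dilution_linearity(fractions, values)["r_squared"] == pytest.approx(1.0)

    def test_shuffled_values_destroy_linearity(self, rng):
        """Permutation oracle: breaking the pairing collapses R²."""
        fractions = np.repeat([0.0125, 0.025, 0.05, 0.1, 0.2, 0.4], 3)
        values = 1000 * fractions * (1 + 0.02 * rng.standard_normal(fractions.size))
        good = dilution_linearity(fractions, values)["r_squared"]
        r2_shuffled = [
            dilution_linearity(fractions, rng.permutation(values))["r_squared"]
            for _ in range(20)
        ]
        assert good > 0.99
        assert np.mean(r2_shuffled) < 0.2

    def test_needs_three_distinct_fractions(self):
        with pytest.raises(ValueError):
            dilution_linearity([0.1, 0.1, 0.2], [1, 2, 3])


class TestBrightfieldSize:
    def _disc_image(self, radius, shape=(400, 400), extra=None):
        yy, xx = np.ogrid[: shape[0], : shape[1]]
        img = np.full(shape, 200.0)
        img[(yy - shape[0] / 2) ** 2 + (xx - shape[1] / 2) ** 2 <= radius**2] = 50.0
        if extra:
            cy, cx, r = extra
            img[(yy - cy) ** 2 + (xx - cx) ** 2 <= r**2] = 50.0
        return img

    def test_disc_area_within_3_percent(self):
        out = size_from_brightfield(self._disc_image(150), 1.0)
        assert out["area_um2"] == pytest.approx(np.pi * 150**2, rel=0.03)

    def test_largest_component_wins_over_debris(self):
        out = size_from_brightfield(self._disc_image(120, extra=(40, 40, 20)), 1.0)
        assert out["area_um2"] == pytest.approx(np.pi * 120**2, rel=0.03)

    def test_blank_image_rejected(self):
        with pytest.raises(ValueError):
            size_from_brightfield(np.full((64, 64), 100.0), 1.0)
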