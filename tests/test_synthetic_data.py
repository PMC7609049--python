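"""Generator contracts: determinism, label statistics, signal content."""

import numpy as np
import pytest

from orgscreen.synthetic_data import (
    AcquisitionModel,
    OrganoidPhenotype,
    generate_calcium_traces,
    generate_dilution_series,
    generate_field_potential,
    generate_organoid_stack,
    generate_toxin_plate,
    planted_calcium_events,
)


class TestOrganoidStack:
    def test_empty_organoid_contains_only_haze_and_noise(self):
        phen = OrganoidPhenotype(radius_um=40.0, n_nuclei=0, zone_fractions={},
                                 filament_density={})
        acq = AcquisitionModel(haze_amplitude=50.0, noise_sd=5.0)
        stack, gt = generate_organoid_stack(phen, acq, seed=1, grid_shape=(96, 96),
                                            n_planes=4)
        assert gt.n_nuclei == 0
        # no blob can push intensities anywhere near the nuclear gain
        assert stack.channel("DAPI").max() < 0.5 * acq.abu_per_fluorophore

    def test_no_attenuation_no_noise_gives_equal_peak_blobs(self, clean_acquisition):
        phen = OrganoidPhenotype(radius_um=40.0, n_nuclei=30, zone_fractions={},
                                 filament_density={}, nucleus_radius_um=(3.5, 0.0))
        stack, gt = generate_organoid_stack(phen, clean_acquisition, seed=2,
                                            grid_shape=(128, 128), n_planes=4)
        dapi = stack.channel("DAPI")
        peaks = []
        for i in range(gt.n_nuclei):
            p = gt.plane_index[i]
            r, c = (gt.centers_um[i, 1:] / stack.pixel_size_um).astype(int)
            peaks.append(dapi[p, r - 2 : r + 3, c - 2 : c + 3].max())
        # brightness jitter is per-nucleus but attenuation-free peaks are
        # all the same scale; with jitter sd 10 % the spread stays tight
        assert np.std(peaks) / np.mean(peaks) < 0.25
        assert min(peaks) > 0.3 * clean_acquisition.abu_per_fluorophore

    def test_fixed_seed_reproduces_stack_exactly(self):
        phen = OrganoidPhenotype(radius_um=40.0, n_nuclei=100, filament_density={"Map2": 40.0})
        a, _ = generate_organoid_stack(phen, seed=33, grid_shape=(96, 96), n_planes=4)
        b, _ = generate_organoid_stack(phen, seed=33, grid_shape=(96, 96), n_planes=4)
        np.testing.assert_array_equal(a.voxels, b.voxels)
        c, _ = generate_organoid_stack(phen, seed=34, grid_shape=(96, 96), n_planes=4)
        assert not np.array_equal(a.voxels, c.voxels)

    def test_sphere_must_fit_grid(self):
        phen = OrganoidPhenotype(radius_um=80.0, n_nuclei=10, zone_fractions={})
        with pytest.raises(ValueError, match="exceeds"):
            generate_organoid_stack(phen, seed=1, grid_shape=(96, 96))

    def test_centers_inside_sphere_and_one_plane_each(self, small_organoid):
        stack, gt = small_organoid
        center = np.array([stack.n_planes * stack.plane_spacing_um / 2, 80.0, 80.0])
        d = np.linalg.norm(gt.centers_um - center, axis=1)
        assert np.all(d <= 60.0 + 1e-9)
        assert gt.plane_index.min() >= 0 and gt.plane_index.max() < stack.n_planes

    def test_zone_fractions_shape_marker_distribution(self):
        """A core-enriched marker is more frequent among inner nuclei."""
        phen = OrganoidPhenotype(radius_um=60.0, n_nuclei=600,
                                 zone_fractions={"Sox2": (0.9, 0.5, 0.1)},
                                 filament_density={})
        stack, gt = generate_organoid_stack(phen, seed=4, grid_shape=(160, 160), n_planes=6)
        center = np.array([stack.n_planes * stack.plane_spacing_um / 2, 80.0, 80.0])
        r = np.linalg.norm(gt.centers_um - center, axis=1) / 60.0
        core = gt.labels["Sox2"][r < 1 / 3].mean()
        rim = gt.labels["Sox2"][r > 2 / 3].mean()
        assert core > 0.75 and rim < 0.25


class TestDilutionSeries:
    def test_paper_fraction_list_gives_six_wells_per_replicate(self):
        fractions = (0.0125, 0.025, 0.05, 0.1, 0.2, 0.4)
        records = generate_dilution_series(fractions, 200, seed=5, replicates=2,
                                           radius_um=50.0, grid_shape=(128, 128),
                                           n_planes=4)
        assert len(records) == 12
        assert sorted({r["fraction"] for r in records}) == sorted(fractions)

    @pytest.mark.parametrize("fraction,expected", [(0.0, 0), (1.0, 400)])
    def test_degenerate_fractions(self, fraction, expected):
        records = generate_dilution_series([fraction], 400, seed=6, replicates=1,
                                           radius_um=60.0, grid_shape=(160, 160),
                                           n_planes=4)
        assert records[0]["ground_truth"].n_labeled("Tracker") == expected

    def test_realized_fraction_follows_binomial_law(self):
        """Labelled counts land within 3 binomial standard deviations of
        the requested fraction."""
        n, frac = 600, 0.2
        records = generate_dilution_series([frac], n, seed=7, replicates=3,
                                           radius_um=70.0, grid_shape=(192, 192),
                                           n_planes=4)
        sd = np.sqrt(n * frac * (1 - frac))
        for rec in records:
            assert abs(rec["ground_truth"].n_labeled("Tracker") - n * frac) <= 3 * sd

    def test_empty_fraction_list_rejected(self):
        with pytest.raises(ValueError):
            generate_dilution_series([], 100, seed=1)

    def test_labeled_signal_proportional_to_labeled_count(self, clean_acquisition):
        """In a noiseless, attenuation-free render the planted tracker
        signal is proportional to the labelled-nucleus count — the
        premise behind dilution-series linearity."""
        totals, counts = [], []
        for frac in (0.1, 0.2, 0.4):
            phen = OrganoidPhenotype(radius_um=60.0, n_nuclei=400, zone_fractions={},
                                     filament_density={}, labeled_fraction=frac,
                                     nucleus_radius_um=(3.5, 0.0))
            stack, gt = generate_organoid_stack(phen, clean_acquisition, seed=8,
                                                grid_shape=(160, 160), n_planes=8)
            totals.append(stack.channel("Tracker").sum())
            counts.append(gt.n_labeled("Tracker"))
        ratio = np.array(totals) / np.array(counts)
        assert np.std(ratio) / np.mean(ratio) < 0.05


class TestToxinPlate:
    def test_dose_zero_spares_everyone(self):
        records = generate_toxin_plate([0.0, 100.0], {"TH": [0.0, 0.5]}, seed=9,
                                       replicates=1, grid_shape=(128, 128),
                                       phenotype=OrganoidPhenotype(
                                           radius_um=50.0, n_nuclei=200,
                                           zone_fractions={}, filament_density={}))
        control = records[0]["ground_truth"]
        assert control.ablation == {"TH": 0.0}
        assert control.n_labeled("TH") == round(0.35 * 200)

    def test_specific_kill_reduces_target_only(self):
        phen = OrganoidPhenotype(radius_um=60.0, n_nuclei=300, zone_fractions={},
                                 filament_density={})
        records = generate_toxin_plate([0.0, 500.0], {"TH": [0.0, 0.9]}, seed=10,
                                       replicates=2, phenotype=phen,
                                       grid_shape=(160, 160))
        th0 = np.mean([r["ground_truth"].n_labeled("TH")
                       for r in records if r["dose"] == 0.0])
        th1 = np.mean([r["ground_truth"].n_labeled("TH")
                       for r in records if r["dose"] == 500.0])
        map0 = np.mean([r["ground_truth"].n_labeled("Map2")
                        for r in records if r["dose"] == 0.0])
        map1 = np.mean([r["ground_truth"].n_labeled("Map2")
                        for r in records if r["dose"] == 500.0])
        assert th1 / th0 == pytest.approx(0.1, abs=0.08)
        assert map1 == map0

    def test_non_monotone_curve_rejected_unless_overridden(self):
        with pytest.raises(ValueError, match="monotone"):
            generate_toxin_plate([0.0, 10.0, 20.0], {"TH": [0.0, 0.5, 0.3]}, seed=1)
        records = generate_toxin_plate(
            [0.0, 10.0, 20.0], {"TH": [0.0, 0.5, 0.3]}, seed=1, replicates=1,
            allow_non_monotone=True, grid_shape=(128, 128),
            phenotype=OrganoidPhenotype(radius_um=50.0, n_nuclei=100,
                                        zone_fractions={}, filament_density={}))
        assert len(records) == 3

    def test_fixed_seed_reproduces_plate(self):
        kwargs = dict(replicates=1, grid_shape=(128, 128),
                      phenotype=OrganoidPhenotype(radius_um=50.0, n_nuclei=100,
                                                  zone_fractions={}, filament_density={}))
        a = generate_toxin_plate([0.0, 100.0], {"TH": [0.0, 0.5]}, seed=12, **kwargs)
        b = generate_toxin_plate([0.0, 100.0], {"TH": [0.0, 0.5]}, seed=12, **kwargs)
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra["stack"].voxels, rb["stack"].voxels)


class TestTraceGenerators:
    def test_ten_hz_four_minutes_gives_2400_samples(self):
        ts = generate_calcium_traces(rate_hz=10.0, duration_s=240.0, seed=1)
        assert ts.traces.shape[1] == 2400

    def test_period_30_duration_240_plants_8_events(self):
        assert len(planted_calcium_events(30.0, 240.0)) == 8

    def test_zero_amplitude_gives_flat_noisy_traces(self):
        ts = generate_calcium_traces(spike_amplitude=0.0, noise_sd=1.0, seed=2,
                                     duration_s=60.0)
        assert np.ptp(ts.traces) < 10.0

    def test_frequency_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            generate_field_potential([(600.0, 1.0)], rate_hz=1000.0)

    def test_noiseless_field_potential_is_exact_sinusoid_sum(self):
        ts = generate_field_potential([(5.0, 2.0)], rate_hz=200.0, duration_s=2.0,
                                      noise_sd=0.0, seed=3)
        # all electrodes identical (phase-locked), amplitude exactly 2
        np.testing.assert_array_equal(ts.traces[0], ts.traces[1])
        assert ts.traces[0].max() == pytest.approx(2.0, abs=0.01)

    def test_empty_components_is_pure_noise(self):
        ts = generate_field_potential([], rate_hz=100.0, duration_s=2.0,
                                      noise_sd=1.0, seed=4)
        assert abs(ts.traces.mean()) < 0.2
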