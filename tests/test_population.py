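"""Synthetic generators: populations, phantoms and MEA traces."""

import numpy as np
import pandas as pd
import pytest

from arborsim.geometry import GeometryError
from arborsim.morphometry import percent_change
from arborsim.synth.mea import MEATraceSpec, generate_mea_traces
from arborsim.synth.phantom import (
    PhantomSpec,
    branch_truth,
    generate_neuron_phantom,
    place_off_neuron_puncta,
)
from arborsim.synth.population import (
    ImagingPopulationSpec,
    PopulationSpec,
    generate_population,
    sample_phantom_population,
    stochastic_round,
)
from tests.conftest import straight_branch

VS = (1.0, 0.25, 0.25)


class TestPhantomGenerator:
    def test_empty_arbor_renders_only_the_soma(self):
        spec = PhantomSpec(shape=(9, 120, 120),
                           soma_center_um=np.array([4.0, 15.0, 15.0]),
                           noise_sd=5.0, seed=0)
        vols, truth = generate_neuron_phantom(spec)
        assert truth.length_um.sum() == 0
        assert truth.crossings.sum() == 0
        assert truth.tube_voxels.sum() > 0  # the soma blob
        r = np.linalg.norm(
            (np.argwhere(truth.tube_voxels) * np.array(VS))
            - spec.soma_center_um, axis=1)
        assert r.max() <= spec.soma_radius_um + 1.5

    def test_straight_dendrite_bookkeeping(self):
        center = np.array([4.0, 40.0, 40.0])
        branch = straight_branch(center, 6.2, 31.2)
        spec = PhantomSpec(shape=(9, 320, 320), soma_center_um=center,
                           branches=[branch], seed=1)
        _, truth = generate_neuron_phantom(spec)
        np.testing.assert_array_equal(truth.crossings[1:5], [1, 1, 1, 1])
        assert truth.crossings[5:].sum() == 0
        # spans annuli 1-4: total true length 4 x 6.25 um, within one
        # voxel diagonal of the polyline discretization
        assert truth.length_um[1:].sum() == pytest.approx(25.0, abs=1.2)

    def test_on_and_off_neuron_flags(self):
        center = np.array([4.0, 30.0, 30.0])
        branch = straight_branch(center, 5.0, 20.0)
        puncta = pd.DataFrame([
            {"z_um": 4.0, "y_um": 30.0, "x_um": 40.0, "channel": "VGlut1",
             "afu": 1.0, "on_neuron": True},
            {"z_um": 4.0, "y_um": 10.0, "x_um": 10.0, "channel": "VGlut1",
             "afu": 1.0, "on_neuron": False},
        ])
        spec = PhantomSpec(shape=(9, 240, 240), soma_center_um=center,
                           branches=[branch], puncta=puncta, seed=2)
        _, truth = generate_neuron_phantom(spec)
        flags = truth.puncta.sort_values("x_um", ascending=False)[
            "on_rendered_neuron"].tolist()
        assert flags == [True, False]

    def test_branch_outside_volume_rejected(self):
        center = np.array([4.0, 10.0, 10.0])
        branch = straight_branch(center, 5.0, 50.0)
        spec = PhantomSpec(shape=(9, 80, 80), soma_center_um=center,
                           branches=[branch], seed=0)
        with pytest.raises(GeometryError):
            generate_neuron_phantom(spec)

    def test_deterministic_per_seed(self):
        center = np.array([4.0, 20.0, 20.0])
        b = straight_branch(center, 5.0, 15.0)
        mk = lambda: generate_neuron_phantom(
            PhantomSpec(shape=(9, 160, 160), soma_center_um=center,
                        branches=[b], seed=5)
        )[0]["GFP"].voxels
        np.testing.assert_array_equal(mk(), mk())

    def test_off_neuron_placement_clears_the_tube(self):
        rng = np.random.default_rng(0)
        tube = np.zeros((9, 80, 80), dtype=bool)
        tube[4, 30:50, 30:50] = True
        df = place_off_neuron_puncta(rng, (9, 80, 80), VS, tube, 10)
        for _, row in df.iterrows():
            vox = np.round(np.array([row.z_um, row.y_um, row.x_um])
                           / np.array(VS)).astype(int)
            assert not tube[tuple(vox)]


class TestBranchTruthConsistency:
    def test_annulus_sums_equal_total_polyline_length(self):
        rng = np.random.default_rng(3)
        pop = ImagingPopulationSpec()
        from arborsim.synth.population import sample_phantom_spec

        spec = sample_phantom_spec(rng, pop, treated=True, seed=1)
        length, _ = branch_truth(spec.branches, spec.soma_center_um)
        poly_total = sum(
            np.linalg.norm(np.diff(np.asarray(b), axis=0), axis=1).sum()
            for b in spec.branches
        )
        # one voxel diagonal per branch of slack
        slack = len(spec.branches) * np.linalg.norm(VS)
        assert abs(length.sum() - poly_total) <= slack


class TestPopulationGenerator:
    def test_null_multipliers_give_no_effect(self):
        spec = PopulationSpec(n_per_group=20, seed=0, length_mult=1.0,
                              crossings_mult=1.0, count_mult=1.0,
                              i_intensity_mult=1.0)
        diffs = []
        for s in range(100):
            spec.seed = s
            a, b = generate_population(spec)
            diffs.append(percent_change(
                np.mean([n.total_length_um for n in b]),
                np.mean([n.total_length_um for n in a])))
        assert abs(np.mean(diffs)) < 2.5

    def test_multiplier_recovered_without_bias(self):
        # |bias| < 2 Monte-Carlo SEs over many replicates
        spec = PopulationSpec(n_per_group=63, length_mult=1.24,
                              crossings_mult=1.0, count_mult=1.0)
        diffs = []
        for s in range(300):
            spec.seed = s
            a, b = generate_population(spec)
            diffs.append(percent_change(
                np.mean([n.total_length_um for n in b]),
                np.mean([n.total_length_um for n in a])))
        se = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
        assert abs(np.mean(diffs) - 24.0) < 2 * se + 0.3

    def test_vgat_intensity_shift(self):
        spec = PopulationSpec(n_per_group=40, seed=5, length_mult=1.0,
                              crossings_mult=1.0, count_mult=1.0,
                              i_intensity_mult=1.5)
        a, b = generate_population(spec)
        from arborsim.profiles import CONDUCTANCE_LEVELS

        def mean_i_afu(group):
            hist = np.sum([n.i_hist for n in group], axis=(0, 1))
            return (hist * CONDUCTANCE_LEVELS).sum() / hist.sum()

        assert mean_i_afu(b) > 1.2 * mean_i_afu(a)

    def test_deterministic_per_seed(self):
        spec = PopulationSpec(n_per_group=4, seed=11)
        a1, b1 = generate_population(spec)
        a2, b2 = generate_population(spec)
        for x, y in zip(a1 + b1, a2 + b2):
            np.testing.assert_array_equal(x.e_hist, y.e_hist)
            np.testing.assert_allclose(x.length_um, y.length_um)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            PopulationSpec(length_mult=0.0).validate()
        with pytest.raises(ValueError):
            PopulationSpec(n_per_group=1).validate()

    def test_stochastic_round_is_unbiased(self):
        rng = np.random.default_rng(0)
        x = np.full(20000, 2.3)
        assert stochastic_round(rng, x).mean() == pytest.approx(2.3, abs=0.02)

    def test_phantom_population_deterministic(self):
        pop = ImagingPopulationSpec(n_per_group=2, seed=4)
        a1, _ = sample_phantom_population(pop)
        a2, _ = sample_phantom_population(pop)
        for (_, s1), (_, s2) in zip(a1, a2):
            assert s1.seed == s2.seed
            np.testing.assert_allclose(
                np.vstack(s1.branches), np.vstack(s2.branches)
            )


class TestMEAGenerator:
    def test_zero_rate_gives_noise_only(self):
        spec = MEATraceSpec(n_electrodes=2, epoch_rates_hz=(0.0,),
                            epoch_labels=("baseline",), epoch_duration_s=5.0,
                            seed=0)
        ts = generate_mea_traces(spec)
        assert len(ts.true_spikes) == 0
        v = ts.trace(0, 0)
        assert np.abs(v).max() < 6 * spec.noise_sd

    def test_poisson_mean_spike_count(self):
        spec = MEATraceSpec(n_electrodes=1, epoch_rates_hz=(10.0,),
                            epoch_labels=("baseline",), epoch_duration_s=60.0,
                            seed=1)
        ts = generate_mea_traces(spec)
        n = len(ts.true_spikes)
        assert abs(n - 600) < 4 * np.sqrt(600)

    def test_rate_ratio_bookkeeping(self):
        spec = MEATraceSpec(n_electrodes=16, epoch_rates_hz=(2.0, 4.04, 12.68),
                            epoch_duration_s=30.0, seed=2)
        ts = generate_mea_traces(spec)
        ratio = ts.true_rate_ratio(2)
        n_base = (ts.true_spikes["epoch"] == "baseline").sum()
        se = 6.34 * np.sqrt(1 / n_base + 1 / (6.34 * n_base))
        assert abs(ratio - 6.34) < 3 * se

    def test_waveform_longer_than_epoch_rejected(self):
        with pytest.raises(ValueError):
            MEATraceSpec(epoch_duration_s=0.001).validate()

    def test_traces_deterministic(self):
        spec = MEATraceSpec(n_electrodes=1, epoch_rates_hz=(5.0,),
                            epoch_labels=("baseline",), epoch_duration_s=3.0,
                            seed=9)
        a = generate_mea_traces(spec).trace(0, 0)
        b = generate_mea_traces(spec).trace(0, 0)
        np.testing.assert_array_equal(a, b)
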