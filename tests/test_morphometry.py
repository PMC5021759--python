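import numpy as np
import pandas as pd
import pytest
from scipy import stats

from arborsim.geometry import N_ANNULI
from arborsim.morphometry import (
    bin_annuli,
    compare_groups,
    ei_balance_fit,
    group_summary,
    percent_change,
)
from arborsim.profiles import (
    NeuronMorphology,
    frame_to_profiles,
    profiles_to_frame,
)
from arborsim.segmentation import NeuronMask, ShollResult
from arborsim.synth.population import PopulationSpec, generate_population

VS = (1.0, 0.25, 0.25)


def make_inputs(puncta_rows):
    mask = NeuronMask(np.zeros((4, 40, 40), dtype=bool), VS)
    mask.mask[2, 20, 20:30] = True
    sholl = ShollResult(
        length_um=np.zeros(N_ANNULI), crossings=np.zeros(N_ANNULI, int),
        skeleton=mask.mask,
    )
    dmap = np.zeros((4, 40, 40), dtype=np.float32)
    tab = pd.DataFrame(
        puncta_rows,
        columns=["channel", "dist_um", "afu", "colocalized"],
    )
    return mask, sholl, tab, dmap


class TestBinAnnuli:
    def test_floor_rule_assigns_10p5_to_annulus_1(self):
        mask, sholl, tab, dmap = make_inputs(
            [("VGlut1", 10.5, 1.0, True)]
        )
        m = bin_annuli(mask, sholl, tab, dmap, VS)
        assert m.e_counts[1] == 1
        assert m.total_e == 1

    def test_empty_punctae_all_zero(self):
        mask, sholl, tab, dmap = make_inputs([])
        m = bin_annuli(mask, sholl, tab, dmap, VS)
        assert m.total_e == m.total_i == 0

    def test_distal_punctum_clipped_into_last_annulus_with_warning(self):
        mask, sholl, tab, dmap = make_inputs([("VGAT", 70.0, 1.0, True)])
        with pytest.warns(UserWarning):
            m = bin_annuli(mask, sholl, tab, dmap, VS)
        assert m.i_counts[8] == 1

    def test_non_colocalized_punctae_excluded(self):
        mask, sholl, tab, dmap = make_inputs(
            [("VGlut1", 3.0, 1.0, False), ("VGlut1", 3.0, 1.0, True)]
        )
        m = bin_annuli(mask, sholl, tab, dmap, VS)
        assert m.total_e == 1

    def test_totals_equal_annulus_sums(self, profile_pair):
        for m in profile_pair[0]:
            assert m.total_e == m.e_counts.sum()
            assert m.total_i == m.i_counts.sum()
            assert m.total_crossings == m.crossings[1:].sum()

    def test_fill_volume_binned_from_mask(self):
        mask, sholl, tab, dmap = make_inputs([])
        m = bin_annuli(mask, sholl, tab, dmap, VS)
        # all mask voxels sit at distance 0 -> annulus 0 holds everything
        assert m.volume_um3[0] == pytest.approx(
            mask.mask.sum() * np.prod(VS)
        )
        assert m.volume_um3[1:].sum() == 0


class TestProfileRoundTrip:
    def test_tsv_frame_round_trip(self, profile_pair):
        neurons = profile_pair[0][:3]
        df = profiles_to_frame(neurons)
        back = frame_to_profiles(df)
        for a, b in zip(neurons, back):
            np.testing.assert_allclose(a.length_um, b.length_um)
            np.testing.assert_array_equal(a.e_hist, b.e_hist)
            np.testing.assert_array_equal(a.i_hist, b.i_hist)


class TestEIBalance:
    def _neurons(self, e_totals, i_totals):
        out = []
        for j, (e, i) in enumerate(zip(e_totals, i_totals)):
            m = NeuronMorphology(neuron_id=f"n{j}")
            m.e_hist[1, 3] = e
            m.i_hist[1, 3] = i
            out.append(m)
        return out

    def test_exact_line_through_origin(self):
        e = np.array([100, 200, 300, 400])
        ns = self._neurons(e, (0.3 * e).astype(int))
        slope, intercept, r = ei_balance_fit(ns)
        assert slope == pytest.approx(0.3)
        assert intercept == pytest.approx(0.0, abs=1e-9)

    def test_scale_invariance_of_slope(self):
        e = np.array([100, 150, 220, 330])
        i = np.array([30, 50, 61, 105])
        s1, _, _ = ei_balance_fit(self._neurons(e, i))
        s2, _, _ = ei_balance_fit(self._neurons(3 * e, 3 * i))
        assert s2 == pytest.approx(s1)

    def test_degenerate_constant_e_rejected(self):
        with pytest.raises(ValueError):
            ei_balance_fit(self._neurons([5, 5, 5], [1, 2, 3]))

    def test_recovers_generator_slope_within_two_ses(self):
        spec = PopulationSpec(n_per_group=63, seed=8)
        a, _ = generate_population(spec)
        slope, _, _ = ei_balance_fit(a)
        e = np.array([n.total_e for n in a], float)
        i = np.array([n.total_i for n in a], float)
        se = stats.linregress(e, i).stderr
        expected = spec.i_density_per_um / spec.e_density_per_um
        assert abs(slope - expected) < 2 * se + 0.02

    def test_balanced_count_multiplier_leaves_slope_unchanged(self):
        spec = PopulationSpec(n_per_group=63, seed=9, count_mult=1.5,
                              length_mult=1.0, crossings_mult=1.0)
        a, b = generate_population(spec)
        sa, _, _ = ei_balance_fit(a)
        sb, _, _ = ei_balance_fit(b)
        assert sb == pytest.approx(sa, abs=0.06)


class TestCompareGroups:
    def test_identical_samples_do_not_reject(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        r = compare_groups(x, x)
        assert r.pvalue > 0.9
        assert r.statistic == pytest.approx(0.0, abs=1e-9)

    def test_normal_samples_select_t_test(self):
        rng = np.random.default_rng(1)
        r = compare_groups(rng.normal(0, 1, 40), rng.normal(0.2, 1, 40))
        assert r.test.startswith("t")

    def test_heavy_tailed_samples_select_rank_test(self):
        rng = np.random.default_rng(2)
        a = rng.standard_cauchy(60)
        b = rng.standard_cauchy(60) + 1
        r = compare_groups(a, b)
        assert r.test == "mann-whitney"
        r2 = compare_groups(a, b, paired=True)
        assert r2.test == "wilcoxon signed-rank"

    def test_power_matches_noncentral_t(self):
        # n = 63 per group, shift d in SD units: empirical rejection rate
        # of the screened test vs the closed-form noncentral-t power
        rng = np.random.default_rng(3)
        n, d, alpha = 63, 0.5, 0.05
        reps = 400
        rej = 0
        for _ in range(reps):
            r = compare_groups(rng.normal(0, 1, n), rng.normal(d, 1, n))
            rej += r.pvalue < alpha
        df = 2 * n - 2
        nc = d * np.sqrt(n / 2)
        tcrit = stats.t.ppf(1 - alpha / 2, df)
        power = 1 - stats.nct.cdf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc)
        se = np.sqrt(power * (1 - power) / reps)
        assert abs(rej / reps - power) < 4 * se

    def test_type_i_error_calibrated(self):
        rng = np.random.default_rng(4)
        reps, rej = 500, 0
        for _ in range(reps):
            r = compare_groups(rng.normal(0, 1, 20), rng.normal(0, 1, 20))
            rej += r.pvalue < 0.05
        assert 0.025 <= rej / reps <= 0.085

    def test_paired_unequal_sizes_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1, 2, 3], [1, 2, 3, 4], paired=True)


class TestPercentChange:
    def test_arithmetic(self):
        assert percent_change(12.4, 10.0) == pytest.approx(24.0)
        assert percent_change(10.0, 10.0) == 0.0

    def test_zero_baseline_undefined(self):
        with pytest.raises(ZeroDivisionError):
            percent_change(5.0, 0.0)

    def test_generator_multiplier_recovered(self):
        # crossings multiplier 1.30 -> ~30% complexity change
        diffs = []
        for seed in range(60):
            a, b = generate_population(
                PopulationSpec(n_per_group=63, seed=seed, length_mult=1.0,
                               crossings_mult=1.30, count_mult=1.0)
            )
            ca = np.mean([n.total_crossings for n in a])
            cb = np.mean([n.total_crossings for n in b])
            diffs.append(percent_change(cb, ca))
        assert np.mean(diffs) == pytest.approx(30.0, abs=1.5)


class TestGroupSummary:
    def test_summary_reports_configured_contrasts(self, profile_pair):
        a, b = profile_pair
        s = group_summary(a, b)
        assert set(s["tests"]) == {
            "total_length_um", "total_crossings", "total_e", "total_i"
        }
        sem_rows = s["annulus_means"]
        assert (sem_rows["n"] == len(a)).all()
        # SEM = SD / sqrt(n) spot check
        row = sem_rows[(sem_rows["group"] == "-BDNF")
                       & (sem_rows["annulus"] == 2)
                       & (sem_rows["metric"] == "length_um")].iloc[0]
        vals = np.array([n.length_um[2] for n in a])
        assert row["sem"] == pytest.approx(vals.std(ddof=1) / np.sqrt(len(a)))
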