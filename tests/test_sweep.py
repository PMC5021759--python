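import numpy as np
import pandas as pd
import pytest

from arborsim.cable import BiophysicsConfig
from arborsim.geometry import N_ANNULI
from arborsim.sweep import (
    SweepConfig,
    SweepResult,
    expected_combo_count,
    group_average,
    percent_difference_map,
    rank_models,
    run_sweep,
    substitute_and_run,
    substitute_profile,
)
from arborsim.synth.population import PopulationSpec, generate_population

BIO = BiophysicsConfig()


def tiny_config(n_strengths=1):
    """1 combo per strength: every parameter list collapsed to its middle."""
    strengths = (0.2, 0.6, 1.0)[:n_strengths]
    return SweepConfig(
        strengths=strengths,
        apical_lengths_um=(250.0,),
        tau_decay_e_ms=(3.0,),
        tau_decay_i_ms=(8.0,),
        windows_ms=(100.0,),
        excitabilities=(1.0,),
    )


class TestComboAccounting:
    def test_default_scheme_yields_105_combos(self):
        cfg = SweepConfig()
        assert cfg.n_combos() == 105
        assert expected_combo_count(5, 5, 5) == 105

    def test_63_models_per_group_give_6615_runs(self):
        # counted, not simulated
        assert 63 * SweepConfig().n_combos() == 6615

    def test_full_grid_count(self):
        cfg = SweepConfig(
            apical_lengths_um=(1.0, 2.0, 3.0),
            tau_decay_e_ms=(1.0,),
            tau_decay_i_ms=(1.0,),
            windows_ms=(100.0,),
            excitabilities=(1.0,),
            strengths=(0.5, 1.0),
            scheme="full-grid",
        )
        assert cfg.n_combos() == expected_combo_count(1, 3, 2, "full-grid") * 1

    def test_even_length_list_rejected(self):
        with pytest.raises(ValueError):
            SweepConfig(apical_lengths_um=(1.0, 2.0)).validate()

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            SweepConfig(strengths=()).validate()


class TestRunSweep:
    def test_single_combo_three_models_three_rows_per_group(self, profile_pair):
        a, b = profile_pair
        res = run_sweep(a[:3], b[:1], tiny_config(), BIO)
        assert len(res.table) == 4
        assert res.table.groupby("group").size().to_dict() == {"-BDNF": 3, "+BDNF": 1}

    def test_identical_populations_shared_seeds_agree_exactly(self, profile_pair):
        a, _ = profile_pair
        res = run_sweep(a[:2], a[:2], tiny_config(), BIO)
        means = res.combo_group_means()
        np.testing.assert_allclose(means.iloc[:, 0], means.iloc[:, 1])

    def test_deterministic_per_config_seed(self, profile_pair):
        a, b = profile_pair
        r1 = run_sweep(a[:2], b[:2], tiny_config(), BIO)
        r2 = run_sweep(a[:2], b[:2], tiny_config(), BIO)
        pd.testing.assert_frame_equal(r1.table, r2.table)


def synthetic_result(rates_by_model, combo_ids=("c0",), group="-BDNF"):
    rows = []
    for combo in combo_ids:
        for mid, rate in rates_by_model.items():
            rows.append(
                {"model_id": mid, "group": group, "combo_id": combo,
                 "seed": 0, "strength": 1.0, "window_ms": 100.0,
                 "ap_count": int(rate), "rate_hz": float(rate)}
            )
    return rows


class TestRanking:
    def test_descending_by_mean_rate(self):
        res = SweepResult(
            pd.DataFrame(synthetic_result({"a": 2, "b": 9, "c": 5})), 1,
            {"-BDNF": 3},
        )
        assert rank_models(res) == ["b", "c", "a"]

    def test_ties_broken_by_id(self):
        res = SweepResult(
            pd.DataFrame(synthetic_result({"b": 4, "a": 4, "c": 4})), 1,
            {"-BDNF": 3},
        )
        assert rank_models(res) == ["a", "b", "c"]

    def test_row_permutation_invariance(self):
        rows = synthetic_result({"a": 2, "b": 9, "c": 5}, ("c0", "c1"))
        res1 = SweepResult(pd.DataFrame(rows), 2, {"-BDNF": 3})
        res2 = SweepResult(
            pd.DataFrame(rows).sample(frac=1, random_state=0), 2, {"-BDNF": 3}
        )
        assert rank_models(res1) == rank_models(res2)


class TestPercentDifferenceMap:
    def _result(self, scale_b=1.0, zeros_in_a=0):
        rows = []
        for g, scale in (("-BDNF", 1.0), ("+BDNF", scale_b)):
            for m in range(6):
                rate = 0.0 if (g == "-BDNF" and m < zeros_in_a) else (
                    10.0 + m
                ) * scale
                rows += synthetic_result({f"{g}{m}": rate}, group=g)
        return SweepResult(pd.DataFrame(rows), 1, {"-BDNF": 6, "+BDNF": 6})

    def test_identical_groups_zero_percent(self):
        per_combo, _ = percent_difference_map(self._result(1.0))
        assert per_combo["pct_difference"].iloc[0] == pytest.approx(0.0)
        assert per_combo["flag"].iloc[0] == "ok"

    def test_scaled_groups_plus_ten_percent(self):
        per_combo, pairs = percent_difference_map(self._result(1.1))
        assert per_combo["pct_difference"].iloc[0] == pytest.approx(10.0)
        # rank-matched pairs also report +10% each
        assert pairs["pct_difference"].dropna().to_numpy() == pytest.approx(
            np.full(6, 10.0)
        )

    def test_combo_with_under_half_firing_flagged(self):
        per_combo, _ = percent_difference_map(self._result(1.0, zeros_in_a=6))
        # 6 of 12 models silent -> exactly half fire; push below half
        res = self._result(1.0, zeros_in_a=6)
        res.table.loc[
            (res.table["group"] == "+BDNF") & (res.table["model_id"] == "+BDNF0"),
            ["rate_hz", "ap_count"],
        ] = 0
        per_combo, _ = percent_difference_map(res)
        assert per_combo["flag"].iloc[0] == "not_compared"
        assert np.isnan(per_combo["pct_difference"].iloc[0])


class TestSubstitution:
    @pytest.fixture(scope="class")
    def groups(self):
        return generate_population(PopulationSpec(n_per_group=8, seed=21))

    def test_exactly_one_parameter_changes(self, groups):
        a, b = groups
        donor = group_average(a)
        p = b[0]
        checks = {
            "dendrite_counts": lambda m: m.crossings[1:],
            "total_synapses": lambda m: m.e_counts + m.i_counts,
            "e_intensity": lambda m: m.e_hist,
            "i_intensity": lambda m: m.i_hist,
            "fill_volume": lambda m: m.volume_um3,
        }
        for param in checks:
            sub = substitute_profile(p, donor, param)
            # the non-substituted marginals are preserved exactly
            if param != "dendrite_counts":
                np.testing.assert_array_equal(sub.crossings, p.crossings)
            if param not in ("total_synapses", "e_intensity", "i_intensity"):
                np.testing.assert_array_equal(sub.e_hist, p.e_hist)
                np.testing.assert_array_equal(sub.i_hist, p.i_hist)
            if param in ("e_intensity", "i_intensity"):
                np.testing.assert_array_equal(
                    sub.e_counts + sub.i_counts, p.e_counts + p.i_counts
                )
            if param != "fill_volume":
                np.testing.assert_allclose(sub.volume_um3, p.volume_um3)

    def test_total_synapse_substitution_hits_donor_average(self, groups):
        a, b = groups
        donor = group_average(a)
        for p in b[:4]:
            sub = substitute_profile(p, donor, "total_synapses")
            for k in range(N_ANNULI):
                assert sub.e_counts[k] + sub.i_counts[k] == int(
                    round(donor.synapse_totals[k])
                )

    def test_ei_ratio_substitution_preserves_totals(self, groups):
        a, b = groups
        donor = group_average(a)
        for p in b[:4]:
            sub = substitute_profile(p, donor, "ei_ratio")
            np.testing.assert_array_equal(
                sub.e_counts + sub.i_counts, p.e_counts + p.i_counts
            )

    def test_self_substitution_leaves_rates_statistically_unchanged(self, groups):
        _, b = groups
        table, tests = substitute_and_run(
            b[:6], b, "total_synapses", BIO, strengths=(0.6,), seed=1
        )
        row = tests.iloc[0]
        rel = abs(row["mean_hybrid"] - row["mean_original"]) / max(
            row["mean_original"], 1e-9
        )
        assert rel < 0.15

    def test_fewer_donor_synapses_decrease_rate(self):
        # donors have ~25% fewer synapses at identical morphology
        a, b = generate_population(
            PopulationSpec(n_per_group=12, seed=22, cv=0.1,
                           length_mult=1.0, crossings_mult=1.0,
                           count_mult=1.33, i_intensity_mult=1.0)
        )
        table, tests = substitute_and_run(
            b, a, "total_synapses", BIO, strengths=(0.4,), seed=2, n_repeats=4
        )
        row = tests.iloc[0]
        assert row["mean_hybrid"] < row["mean_original"]

    def test_fewer_donor_dendrites_increase_rate(self):
        # donors have fewer dendrites; synapse counts match recipients
        a, b = generate_population(
            PopulationSpec(n_per_group=12, seed=23, cv=0.1,
                           length_mult=1.0, crossings_mult=1.35,
                           count_mult=1.0, i_intensity_mult=1.0)
        )
        table, tests = substitute_and_run(
            b, a, "dendrite_counts", BIO, strengths=(0.4,), seed=3, n_repeats=4
        )
        row = tests.iloc[0]
        assert row["mean_hybrid"] > row["mean_original"]

    def test_unknown_parameter_rejected(self, groups):
        a, b = groups
        with pytest.raises(ValueError):
            substitute_profile(b[0], group_average(a), "soma_size")
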