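"""Operating-characteristics simulation and the accuracy index."""

import numpy as np
import pytest

import crmkit as ck
from crmkit.escalation import STOPPED_TOXIC


class TestPlateauCurves:
    def test_printed_rows(self):
        curves = ck.plateau_curves()
        assert curves[0].true_probs == (0.35, 0.52, 0.52, 0.52, 0.52)
        assert curves[2].true_probs == (0.21, 0.21, 0.35, 0.52, 0.52)
        assert curves[4].true_probs == (0.21, 0.21, 0.21, 0.21, 0.35)
        assert [c.true_mtd_level for c in curves] == [1, 2, 3, 4, 5]

    def test_unsupported_target_rejected(self):
        with pytest.raises(ck.ValidationError):
            ck.plateau_curves(theta=0.25)


class TestAccuracyIndex:
    def test_all_mass_on_target_level_gives_one(self):
        sc = ck.plateau_curves()[2]
        assert ck.accuracy_index((0, 0, 1, 0, 0), sc, 0.35) == pytest.approx(1.0)

    def test_uniform_selection_gives_zero(self):
        sc = ck.plateau_curves()[2]
        assert ck.accuracy_index((0.2,) * 5, sc, 0.35) == pytest.approx(0.0, abs=1e-12)

    def test_worked_example(self):
        sc = ck.plateau_curves()[2]
        got = ck.accuracy_index((0.0, 0.5, 0.3, 0.2, 0.0), sc, 0.35)
        # 1 - 5*(0.5*0.14 + 0.2*0.17)/0.62
        assert got == pytest.approx(1 - 5 * (0.5 * 0.14 + 0.2 * 0.17) / 0.62, abs=1e-12)

    def test_unmultiplied_variant_scales_the_penalty(self):
        sc = ck.plateau_curves()[2]
        rho = (0.0, 0.5, 0.3, 0.2, 0.0)
        a_k = ck.accuracy_index(rho, sc, 0.35, k_multiplied=True)
        a_1 = ck.accuracy_index(rho, sc, 0.35, k_multiplied=False)
        assert 1 - a_k == pytest.approx(5 * (1 - a_1))

    def test_degenerate_curve_rejected(self):
        sc = ck.Scenario(true_probs=(0.35, 0.35001), true_mtd_level=1)
        flat = ck.Scenario(true_probs=(0.35, 0.35), true_mtd_level=1)
        ck.accuracy_index((1, 0), sc, 0.35)  # fine
        with pytest.raises(ck.ValidationError):
            ck.accuracy_index((1, 0), flat, 0.35)


class TestSimulateTrial:
    def test_nontoxic_scenario_never_stops_toxic(self, design):
        sc = ck.Scenario(true_probs=(0.001,) * 5, true_mtd_level=5)
        rng = np.random.default_rng(1)
        for _ in range(30):
            rec = ck.simulate_trial(sc, design, rng)
            assert rec.state != STOPPED_TOXIC
            levels = [r.dose_level for r in rec.history.records]
            # no-skip along the realised path
            high = design.start_level
            for c in range(0, len(levels), 3):
                assert levels[c] <= high + 1
                high = max(high, levels[c])

    def test_fully_toxic_scenario_stops_within_two_cohorts(self, design):
        sc = ck.Scenario(true_probs=(0.999,) * 5, true_mtd_level=1)
        rng = np.random.default_rng(2)
        for _ in range(30):
            rec = ck.simulate_trial(sc, design, rng)
            assert rec.state == STOPPED_TOXIC
            assert rec.history.n_patients <= 2 * design.cohort_size

    def test_fixed_stream_replays_identically(self, design):
        sc = ck.plateau_curves()[1]
        ss = np.random.SeedSequence(42)
        a = ck.simulate_trial(sc, design, np.random.default_rng(ss))
        b = ck.simulate_trial(sc, design, np.random.default_rng(np.random.SeedSequence(42)))
        assert a == b


@pytest.fixture(scope="module")
def oc3(design):
    return ck.simulate_oc(ck.plateau_curves()[2], design, n_reps=400, seed=11)


class TestSimulateOC:
    def test_selection_distribution_normalised(self, oc3):
        assert sum(oc3.selection_probs) + oc3.prob_no_selection == pytest.approx(
            1.0, abs=1e-9
        )

    def test_pcs_bounded_by_within_one_selection_mass(self, oc3):
        tm = 3
        near = sum(oc3.selection_probs[tm - 2 : tm + 1])
        assert oc3.pcs <= near + 1e-12

    def test_patient_counts_are_cohort_multiples(self, design, oc3):
        assert oc3.mean_n_treated <= design.max_n
        rng = np.random.default_rng(9)
        for _ in range(10):
            rec = ck.simulate_trial(ck.plateau_curves()[2], design, rng)
            assert rec.history.n_patients % design.cohort_size == 0

    def test_no_overdose_when_mtd_is_top_level(self, design):
        oc = ck.simulate_oc(ck.plateau_curves()[4], design, n_reps=200, seed=3)
        assert oc.mean_prop_overdose == 0.0

    def test_seed_reproducibility(self, design):
        sc = ck.plateau_curves()[3]
        a = ck.simulate_oc(sc, design, n_reps=200, seed=5)
        b = ck.simulate_oc(sc, design, n_reps=200, seed=5)
        assert a == b
        c = ck.simulate_oc(sc, design, n_reps=200, seed=6)
        assert a.selection_probs != c.selection_probs

    def test_stopping_disabled_treats_max_n_exactly(self, design):
        spec = design.with_(stop_prob_threshold=0.999999, consecutive_cohorts=100)
        oc = ck.simulate_oc(ck.plateau_curves()[2], spec, n_reps=100, seed=4)
        assert oc.mean_n_treated == pytest.approx(21.0)


class TestDeltaGrid:
    def test_single_delta_reduces_to_per_curve_oc(self, design):
        df = ck.delta_grid_evaluation([0.06], n_reps=100, seed=13)
        assert sorted(df["curve"].unique()) == [0, 1, 2, 3, 4, 5]
        assert df["sigma_li"].iloc[0] == pytest.approx(0.265, abs=5e-4)
        summary = df[df["curve"] == 0].iloc[0]
        per = df[df["curve"].isin([2, 3, 4, 5])]
        assert summary["pcs"] == pytest.approx(per["pcs"].mean())
        assert summary["sd_accuracy_index"] == pytest.approx(
            per["accuracy_index"].std(ddof=1)
        )
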