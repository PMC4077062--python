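"""Uptake kinetics: initial rates, saturation and competition fits,
Cheng-Prusoff conversion, censoring and wild-type normalization."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import grid_search_michaelis_menten, profile_ic50
from ureakit.containers import CensoredValue, UptakeDataset
from ureakit.datasets import kinetic_truth_for, load_allele_table
from ureakit.kinetics import (
    CompetitionModel,
    MichaelisMentenModel,
    cheng_prusoff,
    fit_ic50,
    fit_michaelis_menten,
    initial_rate,
    relative_uptake,
)
from ureakit.synthetic import (
    KineticTruth,
    gen_competition,
    gen_saturation,
    gen_timecourse,
)


def _timecourse(points, reps=1):
    rows = []
    for rep in range(1, reps + 1):
        for t, y in points:
            rows.append({"x": t, "replicate": rep, "signal": y})
    return UptakeDataset(kind="timecourse", condition="x", data=pd.DataFrame(rows))


class TestInitialRate:
    def test_exact_line_recovered(self):
        est = initial_rate(_timecourse([(0, 0), (1, 5), (2, 10)]))
        assert est.value == pytest.approx(5.0)

    def test_flat_trace_gives_zero(self):
        est = initial_rate(_timecourse([(0, 3), (1, 3), (2, 3)]))
        assert est.value == pytest.approx(0.0)

    def test_points_outside_window_ignored(self):
        est = initial_rate(_timecourse([(0, 0), (1, 5), (2, 10), (10, 12)]), window=2.0)
        assert est.value == pytest.approx(5.0)

    def test_single_point_in_window_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            initial_rate(_timecourse([(0, 0), (5, 10)]), window=2.0)

    def test_mean_estimate_tracks_generating_rate(self):
        truth = KineticTruth(Km=26.0, Vmax=100.0, noise_cv=0.15)
        v_true = 100.0 * 1.0 / 27.0
        est = [
            initial_rate(gen_timecourse(truth.with_seed(s), S=1.0)).value
            for s in range(200)
        ]
        assert np.mean(est) == pytest.approx(v_true, rel=0.02)


class TestRelativeUptake:
    def test_arithmetic(self):
        assert float(relative_uptake(16, 102, 2)) == pytest.approx(14.0)

    def test_mutant_at_background_reports_below_resolution(self):
        v = relative_uptake(2.0, 102.0, 2.0)
        assert float(v) == 0.0
        assert str(v) == "<2"

    def test_wt_against_itself_is_100(self):
        assert float(relative_uptake(102, 102, 2)) == pytest.approx(100.0)

    def test_below_background_floored_at_zero(self):
        assert float(relative_uptake(1.0, 102.0, 2.0)) == 0.0

    def test_invalid_assay_rejected(self):
        with pytest.raises(ValueError, match="background"):
            relative_uptake(10, 2, 2)


class TestMichaelisMentenFit:
    def test_noiseless_recovery_for_every_allele_row(self):
        table = load_allele_table()
        for allele in table.index:
            try:
                truth = kinetic_truth_for(allele, noise_cv=0.0)
            except ValueError:
                continue  # rows without measurable kinetics
            res = fit_michaelis_menten(gen_saturation(truth))
            assert res.Km == pytest.approx(truth.Km, rel=1e-6), allele
            assert res.Vmax == pytest.approx(truth.Vmax, rel=1e-6), allele
            assert res.converged and res.reliable

    def test_noisy_mean_km_within_printed_wt_interval(self):
        kms = [
            fit_michaelis_menten(gen_saturation(kinetic_truth_for("wt", seed=s))).Km
            for s in range(60)
        ]
        assert 24.0 <= np.mean(kms) <= 28.0

    def test_matches_grid_search_oracle(self):
        truth = kinetic_truth_for("wt", noise_cv=0.15, seed=5)
        ds = gen_saturation(truth)
        res = fit_michaelis_menten(ds)
        km_grid = np.linspace(res.Km * 0.8, res.Km * 1.2, 81)
        vmax_grid = np.linspace(res.Vmax * 0.8, res.Vmax * 1.2, 81)
        km_o, vmax_o = grid_search_michaelis_menten(
            ds.data["x"].to_numpy(), ds.data["signal"].to_numpy(), km_grid, vmax_grid
        )
        assert res.Km == pytest.approx(km_o, rel=0.01)
        assert res.Vmax == pytest.approx(vmax_o, rel=0.01)

    def test_too_few_concentrations_rejected(self):
        truth = KineticTruth(Km=26, Vmax=100, noise_cv=0)
        ds = gen_saturation(truth, conc_grid=[1.0, 10.0, 50.0])
        with pytest.raises(ValueError, match=">=4"):
            MichaelisMentenModel(ds)

    def test_estimator_bias_shrinks_with_replicates(self):
        biases = []
        for reps in (3, 10, 30):
            kms = [
                fit_michaelis_menten(
                    gen_saturation(kinetic_truth_for("wt", seed=s), reps=reps)
                ).Km
                for s in range(40)
            ]
            biases.append(abs(np.mean(kms) - 26.0))
        assert biases[-1] <= biases[0] + 0.5  # tighter data, no worse bias

    def test_summary_reports_estimates(self):
        res = fit_michaelis_menten(gen_saturation(kinetic_truth_for("wt", noise_cv=0.0)))
        text = res.summary()
        assert "Km" in text and "Vmax" in text and "converged" in text


class TestIC50Fit:
    def test_noiseless_ic50_recovered_exactly(self):
        truth = kinetic_truth_for("wt", noise_cv=0.0)
        ds = gen_competition(truth, "acetamide")
        res = fit_ic50(ds)
        expected = 237.0 * (1 + 1.0 / 26.0)
        assert res.IC50 == pytest.approx(expected, rel=1e-6)
        assert not res.censored

    def test_flat_response_censored_at_max_concentration(self):
        grid = [0.0, 0.5, 10.0, 300.0, 3000.0]
        rows = [
            {"x": x, "replicate": r, "signal": 3.7}
            for x in grid for r in (1, 2, 3)
        ]
        ds = UptakeDataset(
            kind="competition", condition="guanidine",
            data=pd.DataFrame(rows), tracer_conc=1.0,
        )
        res = fit_ic50(ds)
        assert res.censored
        assert str(res.IC50) == ">3000"
        ki = res.ki(26.0)
        assert isinstance(ki, CensoredValue) and str(ki) == ">3000"

    def test_matches_profile_likelihood_oracle(self):
        truth = kinetic_truth_for("wt", seed=9)
        ds = gen_competition(truth, "acetamide")
        res = fit_ic50(ds)
        grid = np.geomspace(res.IC50 * 0.7, res.IC50 * 1.4, 400)
        oracle = profile_ic50(ds.data["x"].to_numpy(), ds.data["signal"].to_numpy(), grid)
        assert res.IC50 == pytest.approx(oracle, rel=0.01)

    def test_missing_anchor_rejected(self):
        truth = kinetic_truth_for("wt", noise_cv=0.0)
        ds = gen_competition(truth, "acetamide", inhibitor_grid=[0.5, 10, 300, 3000])
        with pytest.raises(ValueError, match="I=0"):
            CompetitionModel(ds)

    def test_free_slope_diagnostic_near_unity_on_unit_slope_data(self):
        truth = kinetic_truth_for("wt", noise_cv=0.0)
        res = fit_ic50(gen_competition(truth, "acetamide"), free_slope=True)
        assert res.hill_slope == pytest.approx(1.0, abs=1e-3)


class TestChengPrusoff:
    def test_worked_identity(self):
        assert cheng_prusoff(27.0, 1.0, 26.0) == pytest.approx(26.0)

    def test_zero_tracer_is_identity(self):
        assert cheng_prusoff(150.0, 0.0, 26.0) == pytest.approx(150.0)

    def test_tracer_at_km_halves(self):
        assert cheng_prusoff(100.0, 26.0, 26.0) == pytest.approx(50.0)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            cheng_prusoff(-1.0, 1.0, 26.0)
        with pytest.raises(ValueError):
            cheng_prusoff(10.0, 1.0, 0.0)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        ic50=st.floats(1e-3, 1e4),
        l1=st.floats(0.0, 100.0),
        l2=st.floats(0.0, 100.0),
        km=st.floats(1e-2, 1e3),
    )
    def test_monotone_in_ic50_and_antitone_in_tracer(self, ic50, l1, l2, km):
        # Ki increases with IC50 at fixed L, decreases with L at fixed Km
        assert cheng_prusoff(ic50 * 2, l1, km) >= cheng_prusoff(ic50, l1, km)
        lo, hi = sorted((l1, l2))
        assert cheng_prusoff(ic50, hi, km) <= cheng_prusoff(ic50, lo, km)


class TestGenerateFitConsistency:
    """Generator and fitter are mutually consistent on noiseless data."""

    def test_ic50_equals_ki_times_competition_factor(self):
        table = load_allele_table()
        for allele in ("wt", "Y106F", "Y437F", "A110G", "N275Q"):
            truth = kinetic_truth_for(allele, noise_cv=0.0)
            ki_true = truth.Ki_map["acetamide"]
            res = fit_ic50(gen_competition(truth, "acetamide"))
            assert res.IC50 == pytest.approx(
                ki_true * (1 + truth.L / truth.Km), rel=1e-6
            ), allele
            assert res.ki(truth.Km) == pytest.approx(ki_true, rel=1e-6)

    def test_vpercent_identities(self):
        assert float(relative_uptake(50.0, 50.0, 4.0)) == 100.0
        assert float(relative_uptake(4.0, 50.0, 4.0)) == 0.0
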