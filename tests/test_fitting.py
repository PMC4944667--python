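"""Naive averaging, weighted-LS fitting, selection, tuning, CV operations."""

import numpy as np
import pandas as pd
import pytest

import dmtpk
from dmtpk import (
    DosingRegimen,
    ModelStructure,
    PKParameters,
    cv_reduction,
    fit_compartment_model,
    naive_average,
    predict_plasma,
    select_model,
    simulate,
    tune_effect_site,
)
from dmtpk.fitting import FitDataset


def _cohort_frame(rows):
    return pd.DataFrame(rows, columns=["subject_id", "dose_mg_per_kg", "weight_kg",
                                       "time_min", "conc_ng_ml"])


class TestNaiveAverage:
    def test_hand_example(self):
        """Two subjects at 10 and 30: mean 20, SD 14.142, CV 70.71%."""
        rows = [("a", 0.4, 75, 2.75, 10.0), ("b", 0.4, 75, 2.75, 30.0),
                ("a", 0.4, 75, 5.75, 10.0), ("b", 0.4, 75, 5.75, 10.0)]
        mean_series, cvs = naive_average(_cohort_frame(rows))
        row = cvs.table.iloc[0]
        assert row["mean_ng_ml"] == 20.0
        assert row["sd_ng_ml"] == pytest.approx(14.142, abs=1e-3)
        assert row["cv_pct"] == pytest.approx(70.71, abs=0.01)
        # identical subjects at the second time: CV exactly 0
        assert cvs.table.iloc[1]["cv_pct"] == 0.0
        assert cvs.window_cv_pct == pytest.approx((70.71 + 0.0) / 2, abs=0.01)

    def test_zero_mean_flagged(self):
        rows = [("a", 0.4, 75, 0.0, 0.0), ("b", 0.4, 75, 0.0, 0.0),
                ("a", 0.4, 75, 2.75, 10.0), ("b", 0.4, 75, 2.75, 20.0)]
        _, cvs = naive_average(_cohort_frame(rows))
        assert np.isnan(cvs.table.iloc[0]["cv_pct"])
        assert any("undefined" in f for f in cvs.flags)

    def test_requires_two_subjects(self):
        rows = [("a", 0.4, 75, 2.75, 10.0)]
        with pytest.raises(ValueError, match="at least 2"):
            naive_average(_cohort_frame(rows))

    def test_rejects_mixed_dose_groups(self):
        rows = [("a", 0.4, 75, 2.75, 10.0), ("b", 0.2, 75, 2.75, 30.0)]
        with pytest.raises(ValueError, match="dose group"):
            naive_average(_cohort_frame(rows))


class TestFit:
    def test_noiseless_recovery(self, params04, bolus04, sampling_times):
        """A noiseless mean curve from the saturable two-compartment model
        is recovered to well under 1% on all five parameters."""
        conc = predict_plasma(params04, bolus04, sampling_times)
        ds = FitDataset(times=sampling_times, conc=conc, regimen=bolus04)
        res = fit_compartment_model(ds, ModelStructure(2, "mm"), n_starts=8, seed=11)
        for name in res.structure.param_names:
            assert res.estimates[name] == pytest.approx(getattr(params04, name),
                                                        rel=0.01)
        assert res.objective < 1e-10

    def test_correctly_specified_linear_recovery(self, sampling_times):
        truth = PKParameters(Vc=100.0, Vp=1.0, Q12=0.0, CL=6.0, n_peripheral=0)
        reg = DosingRegimen.bolus(30.0)
        conc = predict_plasma(truth, reg, sampling_times)
        ds = FitDataset(times=sampling_times, conc=conc, regimen=reg)
        res = fit_compartment_model(ds, ModelStructure(1, "linear"), n_starts=4, seed=0)
        assert res.objective < 1e-12  # residuals at solver noise level

    def test_infeasible_bounds_fail_cleanly(self, params04, bolus04, sampling_times):
        conc = predict_plasma(params04, bolus04, sampling_times)
        ds = FitDataset(times=sampling_times, conc=conc, regimen=bolus04)
        with pytest.raises(ValueError, match="infeasible bounds"):
            fit_compartment_model(ds, ModelStructure(2, "mm"),
                                  bounds={"Vc": (10.0, 1.0)})

    def test_underdetermined_rejected(self, params04, bolus04):
        times = np.array([2.75, 5.75])
        conc = predict_plasma(params04, bolus04, times)
        ds = FitDataset(times=times, conc=conc, regimen=bolus04)
        with pytest.raises(ValueError, match="identify"):
            fit_compartment_model(ds, ModelStructure(2, "mm"))

    def test_multistart_objective_never_worse(self, params04, bolus04, sampling_times):
        """Start sets nest with the seed held fixed, so the best objective
        cannot increase with more starts."""
        rng = np.random.default_rng(4)
        conc = predict_plasma(params04, bolus04, sampling_times)
        conc = conc * np.exp(rng.normal(0, 0.1, conc.size))
        ds = FitDataset(times=sampling_times, conc=conc, regimen=bolus04)
        few = fit_compartment_model(ds, ModelStructure(2, "mm"), n_starts=2, seed=5,
                                    ls_tol=1e-8, solver_rtol=1e-6)
        many = fit_compartment_model(ds, ModelStructure(2, "mm"), n_starts=6, seed=5,
                                     ls_tol=1e-8, solver_rtol=1e-6)
        assert many.objective <= few.objective + 1e-12


@pytest.fixture(scope="module")
def joint_datasets(params04):
    times = 0.75 + np.array([2.0, 5.0, 10.0, 15.0, 30.0, 60.0])
    out = []
    for dose in (0.2, 0.4):
        reg = DosingRegimen.per_kg_bolus(dose, 75.0)
        out.append(FitDataset(times=times,
                              conc=predict_plasma(params04, reg, times),
                              regimen=reg))
    return out


class TestSelect:
    def test_single_candidate_returns_itself(self, joint_datasets):
        sel = select_model(joint_datasets, candidates=[ModelStructure(2, "mm")],
                           n_starts=3, seed=0, ls_tol=1e-8, solver_rtol=1e-6)
        assert sel.best.label == "2C-MM" and len(sel.ranked) == 1

    def test_saturation_unidentifiable_prefers_linear(self, sampling_times):
        """Data generated far below Km carry no saturation signal, so a
        linear-clearance candidate wins the parsimony tie-break."""
        km = 1e6
        truth = PKParameters(Vc=93.0, Vp=340.0, Q12=56.0, Vm=2.0 * km, Km=km)
        datasets = []
        for dose in (0.2, 0.4):
            reg = DosingRegimen.per_kg_bolus(dose, 75.0)
            datasets.append(FitDataset(times=sampling_times,
                                       conc=predict_plasma(truth, reg, sampling_times),
                                       regimen=reg))
        sel = select_model(datasets,
                           candidates=[ModelStructure(2, "mm"),
                                       ModelStructure(2, "linear")],
                           n_starts=4, seed=2, ls_tol=1e-8, solver_rtol=1e-6)
        assert sel.best.label == "2C-linear"

    def test_permutation_invariant(self, joint_datasets):
        cands = [ModelStructure(2, "mm"), ModelStructure(1, "linear"),
                 ModelStructure(2, "linear")]
        a = select_model(joint_datasets, candidates=cands, n_starts=2, seed=1,
                         ls_tol=1e-8, solver_rtol=1e-6)
        b = select_model(joint_datasets, candidates=cands[::-1], n_starts=2, seed=1,
                         ls_tol=1e-8, solver_rtol=1e-6)
        assert [f.label for f in a.ranked] == [f.label for f in b.ranked]

    def test_overparameterized_candidate_gets_infinite_aicc(self, params04, bolus04,
                                                            sampling_times):
        """On a single 6-point curve the small-sample correction is
        undefined for the 5-parameter candidate."""
        conc = predict_plasma(params04, bolus04, sampling_times)
        ds = FitDataset(times=sampling_times, conc=conc, regimen=bolus04)
        res = fit_compartment_model(ds, ModelStructure(2, "mm"), n_starts=2, seed=0,
                                    ls_tol=1e-8, solver_rtol=1e-6)
        assert np.isinf(res.aicc) and np.isfinite(res.bic)


class TestTuneEffectSite:
    def test_peak_at_three_minutes(self, params04, tuned_effect, bolus04):
        res = simulate(params04, tuned_effect, bolus04, 20.0)
        t_pk, ce_pk = dmtpk.peak(res, "Ce")
        assert t_pk == pytest.approx(3.0, abs=0.05)
        assert ce_pk == pytest.approx(res.cc_at(t_pk)[0], rel=0.01)
        assert tuned_effect.k1e == tuned_effect.ke0

    def test_peak_time_decreasing_in_k(self, params04, bolus04):
        """A stiffer link tracks plasma faster — the bracketing property
        the root finder relies on."""
        times = []
        for k in (0.1, 0.3, 1.0, 3.0):
            res = simulate(params04, dmtpk.EffectSiteParams.linked(k), bolus04, 30.0,
                           rtol=1e-7, atol=1e-9)
            times.append(dmtpk.peak(res, "Ce")[0])
        assert all(a > b for a, b in zip(times, times[1:]))

    def test_target_before_plasma_peak_infeasible(self, params04):
        with pytest.raises(ValueError, match="plasma peak"):
            tune_effect_site(params04, t_target=0.3)


class TestCVReduction:
    @pytest.mark.parametrize(
        "subj, conc, expected",
        [
            ((50.0, 50.0), (50.0, 50.0), 0),
            ((50.0, 50.0), (100.0, 100.0), 50),
            ((46.0, 32.0), (83.0, 58.0), 45),
        ],
    )
    def test_values(self, subj, conc, expected):
        assert cv_reduction(subj, conc) == expected

    def test_scale_invariant(self):
        base = cv_reduction((46.0, 32.0), (83.0, 58.0))
        for s in (0.1, 3.0, 17.5):
            assert cv_reduction((46 * s, 32 * s), (83 * s, 58 * s)) == base

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            cv_reduction((0.0, 10.0), (50.0, 50.0))
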