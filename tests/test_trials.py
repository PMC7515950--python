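"""Virtual-trial engine: paired design, statistics, PSA, scenarios."""

import numpy as np
import pytest

import fedrapbpk as f
from fedrapbpk.trials import (
    TrialDesign,
    dose_reescalation_scenario,
    prediction_error,
    psa,
    run_trials,
    set_param,
)

from conftest import zero_cv_spec


def koz_design(**over):
    kw = dict(
        victim="fedratinib",
        victim_entry=f.DosingEntry(
            compound="fedratinib", dose_mg=300.0, schedule="single", start_h=48.0
        ),
        perpetrator_entries=[
            f.DosingEntry(
                compound="ketoconazole", dose_mg=200.0, schedule="bid", start_h=0.0, n_doses=21
            )
        ],
        n_trials=1,
        n_subjects_per_trial=4,
        metric="auc_inf",
        sampling_duration_h=216.0,
        seed=5,
    )
    kw.update(over)
    return TrialDesign(**kw)


class TestPredictionError:
    def test_printed_example(self):
        assert prediction_error(3.17, 3.06) == pytest.approx(3.59, abs=0.05)

    def test_zero_for_equal(self):
        assert prediction_error(2.5, 2.5) == 0.0

    def test_direct_arithmetic(self):
        assert prediction_error(529.0, 440.0) == pytest.approx(20.2, abs=0.05)

    def test_zero_observation_rejected(self):
        with pytest.raises(ValueError):
            prediction_error(1.0, 0.0)


class TestRunTrials:
    def test_zero_perpetrator_dose_gives_unit_ratios(self, library):
        design = koz_design(n_subjects_per_trial=2)
        design.perpetrator_entries[0].dose_mg = 0.0
        summ = run_trials(design, library)
        assert summ.ratio_auc[0] == pytest.approx(1.0, abs=1e-9)
        assert summ.ratio_cmax[0] == pytest.approx(1.0, abs=1e-9)

    def test_zero_cv_population_gives_zero_ci_width(self, library):
        design = koz_design(population=zero_cv_spec(), n_subjects_per_trial=3)
        summ = run_trials(design, library)
        gm, lo, hi = summ.ratio_auc
        assert lo == pytest.approx(gm) and hi == pytest.approx(gm)

    def test_arm_gm_ratio_equals_gm_of_paired_ratios(self, library):
        summ = run_trials(koz_design(), library)
        per = summ.per_subject
        gm_of_ratios = np.exp(np.mean(np.log(per["auc_combo"] / per["auc_alone"])))
        ratio_of_gms = summ.combo.gm_auc / summ.alone.gm_auc
        assert gm_of_ratios == pytest.approx(ratio_of_gms, rel=1e-12)
        assert summ.ratio_auc[1] <= summ.ratio_auc[0] <= summ.ratio_auc[2]

    def test_seed_reproducibility(self, library):
        a = run_trials(koz_design(n_subjects_per_trial=2), library)
        b = run_trials(koz_design(n_subjects_per_trial=2), library)
        assert a.ratio_auc == b.ratio_auc


class TestPSA:
    def test_single_baseline_value_matches_baseline_run(self, library):
        design = koz_design(n_subjects_per_trial=2)
        baseline = run_trials(design, library)
        ki = library["ketoconazole"].interactions[f.EnzymeId.CYP3A4_liver].ki_reversible
        table = psa(design, library, "ketoconazole",
                    "interactions.CYP3A4_liver.ki_reversible", [ki])
        assert table.loc[0, "auc_ratio"] == pytest.approx(baseline.ratio_auc[0], rel=1e-9)

    def test_monotone_in_victim_fm_cyp3a4(self, library):
        """Raising the victim's CYP3A4 intrinsic clearance (hence fm_CYP3A4)
        raises the inhibitor DDI ratio, strictly."""
        design = koz_design(population=zero_cv_spec(), n_subjects_per_trial=1)
        base = library["fedratinib"].enzyme_clearances[f.EnzymeId.CYP3A4_liver].value
        table = psa(design, library, "fedratinib",
                    "enzyme_clearances.CYP3A4_liver.value",
                    [0.3 * base, base, 3.0 * base])
        r = table["auc_ratio"].values
        assert r[0] < r[1] < r[2]

    def test_insensitive_to_cyp2c9_ki_20fold(self, library):
        """Warfarin AUC ratio moves <1% over a 20-fold fedratinib Ki(CYP2C9)
        sweep (the inhibition is negligible at clinical exposure)."""
        design = TrialDesign(
            victim="warfarin",
            victim_entry=f.DosingEntry(
                compound="warfarin", dose_mg=15.0, schedule="single", start_h=96.0
            ),
            perpetrator_entries=[
                f.DosingEntry(compound="fedratinib", dose_mg=400.0, schedule="qd", n_doses=12)
            ],
            n_trials=1, n_subjects_per_trial=1, population=zero_cv_spec(),
            metric="auc_inf", sampling_duration_h=192.0, seed=3,
        )
        ki = library["fedratinib"].interactions[f.EnzymeId.CYP2C9].ki_reversible
        table = psa(design, library, "fedratinib",
                    "interactions.CYP2C9.ki_reversible", [ki / 4.5, ki, ki * 4.5])
        r = table["auc_ratio"].values
        assert np.all(np.abs(r / r[1] - 1) < 0.01)

    def test_non_numeric_path_rejected(self, library):
        with pytest.raises(TypeError):
            set_param(library["fedratinib"], "provenance", 3.0)


class TestOrderings:
    def test_inducer_below_one_inhibitor_above_one(self, library):
        """Pure-CYP3A4 victim: inducer ratios < 1 < inhibitor ratios."""
        def mdz_ratio(perp, dose):
            design = TrialDesign(
                victim="midazolam",
                victim_entry=f.DosingEntry(
                    compound="midazolam", dose_mg=2.0, schedule="single", start_h=168.0
                ),
                perpetrator_entries=[
                    f.DosingEntry(compound=perp, dose_mg=dose, schedule="qd", n_doses=9)
                ],
                n_trials=1, n_subjects_per_trial=1, population=zero_cv_spec(),
                metric="auc_inf", sampling_duration_h=47.0, seed=2,
            )
            return run_trials(design, library).ratio_auc[0]

        assert mdz_ratio("rifampin", 600.0) < 1.0
        assert mdz_ratio("ketoconazole", 200.0) > 1.0

    def test_victim_ddi_magnitude_lower_in_cancer_population(self, library):
        """Reduced hepatic CYP3A4 abundance in the cancer population lowers
        fedratinib's fm_CYP3A4 and hence the inhibitor DDI magnitude."""
        def koz_ratio(pop):
            design = koz_design(population=pop, n_subjects_per_trial=1)
            return run_trials(design, library).ratio_auc[0]

        healthy = zero_cv_spec()
        cancer = f.cancer_modifiers(healthy)
        assert koz_ratio(cancer) < koz_ratio(healthy)


@pytest.fixture(scope="module")
def scenario(library):
    return dose_reescalation_scenario(library, population=zero_cv_spec())


class TestDoseReescalation:
    def test_phase3_matches_unperturbed_400qd(self, library, scenario):
        """Post-recovery 400 mg QD exposure within 5% of a standalone run."""
        from fedrapbpk.calibration import measure_racc  # noqa: F401  (same machinery)
        from fedrapbpk.engine import Regimen, simulate
        from fedrapbpk.calibration import nca

        res, phases = scenario
        subject = f.central_subject(zero_cv_spec())
        n = 21
        reg = Regimen(entries=[Regimen.qd("fedratinib", 400.0, n)])
        fine = np.arange(0.0, 24.5, 0.5)
        t_last = (n - 1) * 24.0
        tout = np.unique(np.concatenate([np.arange(0.0, t_last, 2.0), t_last + fine]))
        ref = simulate(subject, [library["fedratinib"]], reg, n * 24.0, output_times=tout)
        m = ref.times >= t_last
        standalone = nca(ref.times[m] - t_last, ref.conc["fedratinib"][m], tau=24.0).auc_tau
        assert phases[2].auc_tau == pytest.approx(standalone, rel=0.05)

    def test_phase1_reduced_dose_with_inhibitor_near_full_dose_exposure(self, scenario):
        """200 mg + strong inhibitor lands in the same exposure range as the
        unperturbed full dose (the label's intent): within ~2-fold."""
        res, phases = scenario
        assert 0.5 < phases[0].auc_tau / phases[2].auc_tau < 2.0

    def test_enzyme_recovery_trajectory_exported(self, scenario):
        res, phases = scenario
        E = res.enzyme_fractions[f.EnzymeId.CYP3A4_liver]
        t = res.times
        # suppressed under inhibitor+auto, recovering after washout
        during = E[np.searchsorted(t, 14 * 24.0 - 1)]
        later = E[np.searchsorted(t, 20 * 24.0)]
        assert later > during

    def test_overlapping_phases_rejected(self, library):
        with pytest.raises(ValueError, match="phase"):
            dose_reescalation_scenario(library, phase_days=(0, 14, 14))


class TestLabelRules:
    def test_strong_inhibitor_magnitude_reduces_dose(self):
        assert f.recommend_dose(2.0).recommended_dose_mg == 200  # tie -> reduce

    def test_moderate_keeps_400(self):
        assert f.recommend_dose(1.19).recommended_dose_mg == 400

    def test_intermediate_band(self):
        assert f.recommend_dose(1.5).recommended_dose_mg == 300

    def test_missing_ratio_errors(self):
        with pytest.raises(ValueError):
            f.recommend_dose(0.0)

    def test_classifier_bands(self):
        assert f.classify_inhibitor(6.0) == "strong"
        assert f.classify_inhibitor(3.0) == "moderate"
        assert f.classify_inhibitor(1.5) == "weak"
        assert f.classify_inhibitor(0.3) == "inducer"
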