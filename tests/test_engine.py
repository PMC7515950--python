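"""ODE engine: closed-form oracles, interaction contracts, invariants."""

import numpy as np
import pytest

import fedrapbpk as f
from fedrapbpk.compound import KDEG_PER_H, EnzymeId
from fedrapbpk.engine import EngineError, Regimen, simulate

from conftest import one_compartment_compound


def bateman(t, dose, ka, ke, v):
    return dose * ka / (v * (ka - ke)) * (np.exp(-ke * t) - np.exp(-ka * t))


@pytest.fixture(scope="module")
def one_cpt_result(fast_liver_subject):
    comp = one_compartment_compound(cl_renal=10.0, ka=1.0)
    reg = Regimen(entries=[Regimen.single("probe1c", 100.0)])
    tout = np.arange(0.0, 96.0 + 1e-9, 0.05)
    return comp, simulate(fast_liver_subject, [comp], reg, 96.0, output_times=tout)


class TestClosedFormOracles:
    def test_one_compartment_auc_inf(self, one_cpt_result):
        """AUCinf = F·D/CL = 10 mg·h/L for D=100 mg, CL=10 L/h, F=1."""
        comp, res = one_cpt_result
        m = f.nca(res.times, res.conc["probe1c"])
        assert m.auc_inf == pytest.approx(10_000.0, rel=5e-3)  # ng·h/mL

    def test_one_compartment_cmax_tmax_bateman(self, one_cpt_result):
        comp, res = one_cpt_result
        ka, ke, v = 1.0, 0.1, 100.0
        tmax = np.log(ka / ke) / (ka - ke)
        cmax = bateman(tmax, 100.0, ka, ke, v) * 1000.0
        m = f.nca(res.times, res.conc["probe1c"])
        assert m.cmax == pytest.approx(cmax, rel=1e-3)
        assert m.tmax == pytest.approx(tmax, abs=0.06)

    def test_full_profile_matches_bateman(self, one_cpt_result):
        comp, res = one_cpt_result
        t = res.times[res.times > 0.5]
        pred = bateman(t, 100.0, 1.0, 0.1, 100.0) * 1000.0
        obs = res.conc["probe1c"][res.times > 0.5]
        assert np.allclose(obs, pred, rtol=2e-3)


def make_victim(fm_3a4=1.0, cl_total_u=50.0):
    """Hepatically cleared victim with a given CYP3A4 share of CLint."""
    ec = {}
    if fm_3a4 > 0:
        ec[EnzymeId.CYP3A4_liver] = {
            "value": cl_total_u * fm_3a4 / 542.52, "unit": "uL/min/pmol"}
    if fm_3a4 < 1:
        ec[EnzymeId.HLM_additional] = {
            "value": cl_total_u * (1 - fm_3a4) / 3.96, "unit": "uL/min/mg"}
    return f.CompoundModel(
        name="victim", mol_weight=400.0, fu_plasma=0.1, blood_plasma_ratio=1.0,
        ka=1.0, fa=1.0, fg_model="fixed_fg", fixed_fg=1.0,
        vss=1.4, v_sac=0.0, q_sac=0.0, enzyme_clearances=ec,
        provenance="test construct",
    )


def make_constant_inhibitor(iu_over_ki, ki=1.0, mechanisms=None, name="inhib"):
    """Huge-volume, negligible-clearance perpetrator: its unbound liver
    concentration stays ~constant at iu_over_ki * ki for days."""
    mw, fu, vss_l_kg = 400.0, 0.5, 100.0
    target_iu = iu_over_ki * ki  # µM
    conc_mg_l = target_iu * mw / 1000.0 / fu
    dose = conc_mg_l * vss_l_kg * 70.0
    inter = mechanisms or {EnzymeId.CYP3A4_liver: {"ki_reversible": ki, "provenance": "t"}}
    return f.CompoundModel(
        name=name, mol_weight=mw, fu_plasma=fu, blood_plasma_ratio=1.0,
        ka=20.0, fa=1.0, fg_model="fixed_fg", fixed_fg=1.0,
        vss=vss_l_kg, v_sac=0.0, q_sac=0.0, cl_renal=0.01,
        interactions=inter, provenance="test construct",
    ), dose


def oral_auc(subject, compounds, entries, t_end, victim="victim"):
    tout = np.unique(np.concatenate([np.arange(0.0, 48.0, 0.1),
                                     np.arange(48.0, t_end + 1e-9, 1.0)]))
    res = simulate(subject, compounds, Regimen(entries=entries), t_end, output_times=tout)
    m = f.nca(res.times, res.conc[victim])
    return m.auc_inf, m, res


class TestInteractionContracts:
    def test_competitive_inhibition_at_ki_halves_clearance(self, subject):
        """fm_CYP3A4 = 1 victim, constant unbound inhibitor at I = Ki:
        effective CLint halves, so oral AUC doubles."""
        victim = make_victim(fm_3a4=1.0)
        inhib, dose = make_constant_inhibitor(iu_over_ki=1.0)
        base, *_ = oral_auc(subject, [victim], [Regimen.single("victim", 10.0)], 240.0)
        entries = [Regimen.single("inhib", dose), Regimen.single("victim", 10.0)]
        inh, *_ = oral_auc(subject, [victim, inhib], entries, 240.0)
        assert inh / base == pytest.approx(2.0, rel=0.02)

    @pytest.mark.parametrize("fm,iu_over_ki", [(0.6, 2.0), (0.9, 5.0), (1.0, 0.5)])
    def test_static_rowland_matin_limit(self, subject, fm, iu_over_ki):
        """AUC ratio -> 1/(fm/(1+Iu/Ki) + (1-fm)) within 2% for a constant
        competitive inhibitor, fg = 1."""
        victim = make_victim(fm_3a4=fm)
        inhib, dose = make_constant_inhibitor(iu_over_ki=iu_over_ki)
        base, *_ = oral_auc(subject, [victim], [Regimen.single("victim", 10.0)], 240.0)
        entries = [Regimen.single("inhib", dose), Regimen.single("victim", 10.0)]
        inh, *_ = oral_auc(subject, [victim, inhib], entries, 240.0)
        expected = 1.0 / (fm / (1 + iu_over_ki) + (1 - fm))
        assert inh / base == pytest.approx(expected, rel=0.02)

    def test_no_perpetrator_equivalence(self, subject):
        """Victim-alone profiles identical whether interaction fields exist
        or not, when the victim has no auto-interaction."""
        victim = make_victim(fm_3a4=0.7)
        with_fields = victim.model_copy(deep=True)
        with_fields.interactions = {
            EnzymeId.CYP2C9: f.InteractionKinetics(ki_reversible=1e9, provenance="t")
        }
        tout = np.arange(0.0, 48.0, 0.25)
        a = simulate(subject, [victim], Regimen(entries=[Regimen.single("victim", 10.0)]),
                     48.0, output_times=tout)
        b = simulate(subject, [with_fields], Regimen(entries=[Regimen.single("victim", 10.0)]),
                     48.0, output_times=tout)
        assert np.allclose(a.conc["victim"], b.conc["victim"], rtol=1e-9, atol=1e-12)

    def test_enzyme_fractions_stay_one_without_turnover_perpetrator(self, subject):
        victim = make_victim(fm_3a4=0.7)
        res = simulate(subject, [victim], Regimen(entries=[Regimen.single("victim", 10.0)]), 48.0)
        assert res.enzyme_fractions == {}  # no dynamic pools at all

    def test_enzyme_recovery_exponential_with_kdeg(self, subject):
        """After perpetrator washout E(t) -> 1 at rate kdeg (closed form)."""
        tdi = {EnzymeId.CYP3A4_liver: {"kinact": 2.0, "ki_app": 0.5, "provenance": "t"}}
        perp = f.CompoundModel(
            name="tdi", mol_weight=400.0, fu_plasma=0.5, blood_plasma_ratio=1.0,
            ka=2.0, fa=1.0, fg_model="fixed_fg", fixed_fg=1.0,
            vss=0.5, v_sac=0.0, q_sac=0.0, cl_renal=35.0,  # t1/2 ~ 0.7 h: fast washout
            interactions=tdi, provenance="test construct")
        tout = np.arange(0.0, 400.0, 0.5)
        res = simulate(subject, [perp], Regimen(entries=[Regimen.single("tdi", 500.0)]),
                       400.0, output_times=tout)
        E = res.enzyme_fractions[EnzymeId.CYP3A4_liver]
        kdeg = KDEG_PER_H[EnzymeId.CYP3A4_liver]
        t0_idx = np.searchsorted(res.times, 24.0)  # perpetrator long gone
        e0 = E[t0_idx]
        expected = 1 - (1 - e0) * np.exp(-kdeg * (res.times[t0_idx:] - 24.0))
        assert np.allclose(E[t0_idx:], expected, atol=0.01)
        assert E[-1] > 0.95


class TestInvariantsAndProperties:
    def test_mass_conservation_multidose_multicompound(self, subject, library):
        reg = Regimen(entries=[
            Regimen.qd("fedratinib", 400.0, 3),
            Regimen.bid("ketoconazole", 200.0, 6),
        ])
        res = simulate(subject, [library["fedratinib"], library["ketoconazole"]], reg, 96.0)
        assert res.mass_balance_error("fedratinib") < 1e-3
        assert res.mass_balance_error("ketoconazole") < 1e-3

    def test_auc_insensitive_to_grid_refinement(self, subject, fedratinib):
        reg = Regimen(entries=[Regimen.single("fedratinib", 300.0)])
        aucs = []
        for dt in (0.5, 0.25):
            tout = np.arange(0.0, 168.0 + 1e-9, dt)
            res = simulate(subject, [fedratinib], reg, 168.0, output_times=tout)
            aucs.append(f.nca(res.times, res.conc["fedratinib"]).auc_last)
        assert abs(aucs[0] / aucs[1] - 1) < 0.005

    def test_monotone_in_inhibitor_and_inducer_dose(self, subject, library):
        """Victim AUC ratio non-decreasing in inhibitor dose, non-increasing
        in inducer dose."""
        victim = make_victim(fm_3a4=0.9)

        def ratio(perp_name, dose, n_doses=8):
            base, *_ = oral_auc(
                subject, [victim], [Regimen.single("victim", 10.0, start_h=48.0)], 216.0)
            entries = [Regimen.qd(perp_name, dose, n_doses),
                       Regimen.single("victim", 10.0, start_h=48.0)]
            inh, *_ = oral_auc(subject, [victim, library[perp_name]], entries, 216.0)
            return inh / base

        kratios = [ratio("ketoconazole", d) for d in (50.0, 200.0, 600.0)]
        assert kratios[0] < kratios[1] < kratios[2]
        assert all(r > 1 for r in kratios)
        rratios = [ratio("rifampin", d) for d in (100.0, 600.0)]
        assert rratios[0] > rratios[1]
        assert all(r < 1 for r in rratios)

    def test_t_end_before_last_dose_rejected(self, subject, fedratinib):
        reg = Regimen(entries=[Regimen.qd("fedratinib", 400.0, 10)])
        with pytest.raises(ValueError, match="t_end"):
            simulate(subject, [fedratinib], reg, 48.0)

    def test_unknown_compound_in_regimen_rejected(self, subject, fedratinib):
        reg = Regimen(entries=[Regimen.single("nope", 100.0)])
        with pytest.raises(ValueError, match="unknown compounds"):
            simulate(subject, [fedratinib], reg, 48.0)

    def test_times_strictly_increasing_required(self, subject, fedratinib):
        reg = Regimen(entries=[Regimen.single("fedratinib", 300.0)])
        with pytest.raises(ValueError):
            simulate(subject, [fedratinib], reg, 48.0, output_times=np.array([0.0, 1.0, 1.0]))


class TestFmFePartition:
    def test_single_pathway_is_unity(self, one_cpt_result):
        comp, res = one_cpt_result
        fm = f.fm_fe_partition(res, (0.0, 24.0))
        assert fm["renal"] == pytest.approx(1.0)

    def test_fractions_sum_to_one(self, subject, fedratinib):
        reg = Regimen(entries=[Regimen.qd("fedratinib", 400.0, 2)])
        res = simulate(subject, [fedratinib], reg, 48.0)
        fm = f.fm_fe_partition(res, (0.0, 24.0))
        assert sum(fm.values()) == pytest.approx(1.0, abs=1e-6)

    def test_zero_elimination_window_errors(self, subject, fedratinib):
        reg = Regimen(entries=[Regimen.single("fedratinib", 300.0, start_h=40.0)])
        res = simulate(subject, [fedratinib], reg, 96.0)
        with pytest.raises(ValueError, match="no elimination"):
            f.fm_fe_partition(res, (0.0, 30.0))

    def test_window_outside_range_errors(self, one_cpt_result):
        comp, res = one_cpt_result
        with pytest.raises(ValueError, match="window"):
            f.fm_fe_partition(res, (0.0, 1e4))

    def test_gut_first_pass_excluded_by_default(self, subject, library):
        reg = Regimen(entries=[Regimen.single("midazolam", 2.0)])
        res = simulate(subject, [library["midazolam"]], reg, 24.0)
        fm = f.fm_fe_partition(res, (0.0, 12.0))
        assert "gut_first_pass" not in fm
        fm_fp = f.fm_fe_partition(res, (0.0, 12.0), include_first_pass=True)
        assert fm_fp["gut_first_pass"] > 0.1  # midazolam loses real mass in the gut wall
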