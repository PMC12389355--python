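"""Dynamic engine: closed-form PK checks, turnover oracles, well-stirred
clearance limits, and whole-pipeline invariants."""

import math

import numpy as np
import pydantic
import pytest

from cypind.errors import ValidationError
from cypind.library import list_designs, load_compound, load_design
from cypind.pbpk import (
    CompoundModel,
    CompoundPK,
    DDIDesign,
    DosingRegimen,
    EnzymeSettings,
    PerpetratorExposure,
    enzyme_dynamics,
    run_ddi,
    sensitivity_scan,
    simulate_perpetrator,
    victim_clearance,
)
from cypind.static import EnzymeInduction, FmMap, StaticInput, fold_cl_change, net_auc_ratio

FAST_SETTINGS = EnzymeSettings(kdeg_per_h={"CYP3A4": 0.1, "CYP2C9": 0.1})


def _perp(emax=4.0, ec50=0.5, enzyme="CYP3A4", **pk_kw):
    pk = dict(
        mw_g_mol=500.0, ka_per_h=1.0, fa=1.0, v_L=50.0, cl_L_h=5.0, fu_plasma=0.1
    )
    pk.update(pk_kw)
    return CompoundModel(
        "perp",
        "perpetrator",
        CompoundPK(**pk),
        induction={enzyme: EnzymeInduction(ec50_uM=ec50, emax_fold=emax)},
    )


def _victim(fm=None, **pk_kw):
    pk = dict(
        mw_g_mol=300.0, ka_per_h=1.5, fa=0.9, v_L=40.0, cl_L_h=4.0, fu_plasma=0.05
    )
    pk.update(pk_kw)
    return CompoundModel(
        "vic",
        "victim",
        CompoundPK(**pk),
        fm=FmMap("vic", fm or {"CYP3A4": 0.8}),
    )


def _design(perp_doses=3, victim_start=72.0, perp_dose=200.0, victim_dose=10.0):
    return DDIDesign(
        perpetrator=DosingRegimen(dose_mg=perp_dose, interval_h=24, n_doses=perp_doses),
        victim=DosingRegimen(dose_mg=victim_dose, n_doses=1, start_h=victim_start),
    )


# ---------------------------------------------------------------------------
# perpetrator closed-form kinetics
# ---------------------------------------------------------------------------


def test_iv_bolus_limit_matches_monoexponential():
    """With very fast absorption the oral profile collapses onto
    D/V * exp(-k t) (within 0.5% once absorption is complete)."""
    pk = CompoundPK(
        mw_g_mol=400.0, ka_per_h=200.0, fa=1.0, v_L=50.0, cl_L_h=5.0, fu_plasma=0.1
    )
    reg = DosingRegimen(dose_mg=100.0, n_doses=1)
    exp_obj = PerpetratorExposure(pk, reg)
    t = np.linspace(0.5, 24.0, 48)
    d_umol = pk.dose_umol(100.0)
    ref = d_umol / pk.v_L * np.exp(-0.1 * t)
    assert np.allclose(exp_obj.conc_total(t), ref, rtol=5e-3)


def test_zero_dose_profile_is_identically_zero():
    pk = CompoundPK(
        mw_g_mol=400.0, ka_per_h=1.0, fa=1.0, v_L=50.0, cl_L_h=5.0, fu_plasma=0.1
    )
    exp_obj = PerpetratorExposure(pk, DosingRegimen(dose_mg=0.0, n_doses=3))
    t = np.linspace(0, 72, 100)
    assert np.all(exp_obj.conc_total(t) == 0.0)
    assert np.all(exp_obj.conc_inlet_unbound(t) == 0.0)


def test_multiple_dose_superposition():
    """The n-dose profile equals the sum of time-shifted single-dose
    profiles (linear PK)."""
    pk = CompoundPK(
        mw_g_mol=400.0, ka_per_h=0.8, fa=0.9, v_L=60.0, cl_L_h=6.0, fu_plasma=0.2
    )
    multi = PerpetratorExposure(pk, DosingRegimen(dose_mg=150.0, interval_h=24, n_doses=4))
    t = np.linspace(0, 120, 241)
    summed = np.zeros_like(t)
    for k in range(4):
        single = PerpetratorExposure(
            pk, DosingRegimen(dose_mg=150.0, n_doses=1, start_h=24.0 * k)
        )
        summed += single.conc_total(t)
    assert np.allclose(multi.conc_total(t), summed, rtol=1e-12, atol=1e-15)


def test_absorption_mass_balance_for_all_packaged_designs():
    """Cumulative absorbed drug converges to Fa * total dose within 0.5% for
    every vendored dosing design."""
    for victim in list_designs():
        design = load_design(victim)
        pk = load_compound("rifampicin").pk
        exp_obj = PerpetratorExposure(pk, design.perpetrator)
        reg = design.perpetrator
        expected = pk.fa * pk.dose_umol(reg.dose_mg) * reg.n_doses
        got = exp_obj.cumulative_absorbed_umol(reg.dose_times[-1] + 24.0)
        assert got == pytest.approx(expected, rel=5e-3)


def test_rifampicin_steady_state_auc_within_bioequivalence_of_literature():
    """Day-5 AUC over a dosing interval for the packaged 600 mg qd fixture
    falls within 0.8-1.25-fold of the literature steady-state exposure
    (~45 ug*h/mL)."""
    rif = load_compound("rifampicin")
    frame, exp_obj = simulate_perpetrator(
        rif.pk, DosingRegimen(dose_mg=600, interval_h=24, n_doses=5), t_end=120.0
    )
    t = np.arange(96.0, 120.0001, 0.05)
    auc_um_h = np.trapezoid(exp_obj.conc_total(t), t)
    auc_ug_h_ml = auc_um_h * rif.pk.mw_g_mol / 1000.0
    assert 0.8 <= auc_ug_h_ml / 45.0 <= 1.25
    assert {"conc_total_uM", "conc_inlet_unbound_uM"} <= set(frame.columns)


def test_inlet_exceeds_systemic_unbound_during_absorption():
    pk = load_compound("rifampicin").pk
    exp_obj = PerpetratorExposure(pk, DosingRegimen(dose_mg=600, n_doses=1))
    t = np.linspace(0.1, 12, 50)
    assert np.all(exp_obj.conc_inlet_unbound(t) > exp_obj.conc_unbound(t))


# ---------------------------------------------------------------------------
# enzyme turnover oracles
# ---------------------------------------------------------------------------


def test_no_induction_keeps_enzyme_at_baseline():
    e = enzyme_dynamics(lambda t: 5.0, 1.0, 0.5, 0.1, (0.0, 100.0))
    assert np.all(e(np.linspace(0, 100, 50)) == 1.0)


def test_constant_driver_steady_state_and_approach():
    """Cu = EC50 and Emax = 5 give E_ss = 3 approached as 3 - 2 e^{-kdeg t}."""
    kdeg = 0.1
    e = enzyme_dynamics(lambda t: 0.5, 5.0, 0.5, kdeg, (0.0, 120.0))
    t = np.linspace(0.0, 120.0, 60)
    expected = 3.0 - 2.0 * np.exp(-kdeg * t)
    assert np.allclose(e(t), expected, rtol=1e-3)
    assert e(np.array([120.0]))[0] == pytest.approx(3.0, rel=1e-3)


def test_washout_half_life_of_return():
    """After the driver is removed, (E - 1) halves every ln2/kdeg and the
    trajectory returns to baseline within 0.1% after seven half-lives (small
    perturbations)."""
    kdeg = 0.1
    t_half = math.log(2.0) / kdeg
    t0 = 120.0

    def make(emax):
        driver = lambda t: 100.0 if t < t0 else 0.0  # noqa: E731
        return enzyme_dynamics(driver, emax, 0.5, kdeg, (0.0, 400.0))

    e = make(3.0)
    e0 = float(e(np.array([t0]))[0])
    half = float(e(np.array([t0 + t_half]))[0])
    assert half == pytest.approx(1.0 + (e0 - 1.0) / 2.0, rel=1e-2)
    # generic 2^-7 decay of the excess abundance
    e7 = float(e(np.array([t0 + 7 * t_half]))[0])
    assert e7 - 1.0 == pytest.approx((e0 - 1.0) * 2.0**-7, abs=5e-4)
    # small perturbation: absolute return to 1 within 0.1%
    e_small = make(1.12)
    back = float(e_small(np.array([t0 + 7 * t_half]))[0])
    assert back == pytest.approx(1.0, abs=1e-3)


def test_enzyme_trajectory_bounded(rifampicin, settings):
    exp_obj = PerpetratorExposure(
        rifampicin.pk, DosingRegimen(dose_mg=600, interval_h=24, n_doses=5), settings
    )
    params = rifampicin.induction["CYP3A4"]
    e = enzyme_dynamics(
        lambda t: exp_obj.hepatic_driver(t),
        params.emax_fold,
        params.ec50_uM,
        settings.kdeg_per_h["CYP3A4"],
        (0.0, 240.0),
    )
    traj = e(np.linspace(0, 240, 200))
    assert np.all(traj >= 1.0) and np.all(traj <= params.emax_fold)


def test_enzyme_dynamics_validates_inputs():
    with pytest.raises(ValidationError):
        enzyme_dynamics(lambda t: 1.0, 2.0, 0.5, 0.0, (0, 10))
    with pytest.raises(ValidationError):
        enzyme_dynamics(lambda t: 1.0, 2.0, -1.0, 0.1, (0, 10))


# ---------------------------------------------------------------------------
# well-stirred clearance
# ---------------------------------------------------------------------------


def test_clearance_baseline_unchanged():
    fm = FmMap("v", {"CYP3A4": 0.8})
    cl_int, cl_h, f_h = victim_clearance(fm, {"CYP3A4": 1.0}, 100.0, 0.05)
    assert cl_int == pytest.approx(100.0)
    assert cl_h < 97.0 and 0 < f_h < 1


def test_low_extraction_clearance_doubles_with_abundance():
    fm = FmMap("v", {"CYP3A4": 1.0})
    _, base, _ = victim_clearance(fm, {"CYP3A4": 1.0}, 10.0, 0.01)
    _, doubled, _ = victim_clearance(fm, {"CYP3A4": 2.0}, 10.0, 0.01)
    assert doubled / base == pytest.approx(2.0, rel=5e-2)


def test_flow_limited_clearance_insensitive_to_induction():
    fm = FmMap("v", {"CYP3A4": 1.0})
    _, base, _ = victim_clearance(fm, {"CYP3A4": 1.0}, 1e6, 1.0)
    _, induced, _ = victim_clearance(fm, {"CYP3A4": 5.0}, 1e6, 1.0)
    assert base == pytest.approx(97.0, rel=1e-3)
    assert induced == pytest.approx(base, rel=1e-3)
    assert induced < 97.0


# ---------------------------------------------------------------------------
# run_ddi invariants
# ---------------------------------------------------------------------------


def test_zero_perpetrator_dose_gives_exact_unity_aucr():
    out = run_ddi(
        _perp(), _victim(), _design(perp_dose=0.0), settings=FAST_SETTINGS, window_h=48.0
    )
    assert out.aucr == 1.0
    assert out.percent_reduction == 0.0


def test_fm_on_uninduced_enzyme_gives_exact_unity_aucr():
    out = run_ddi(
        _perp(enzyme="CYP3A4"),
        _victim(fm={"CYP2C9": 0.9}),
        _design(),
        settings=FAST_SETTINGS,
        window_h=48.0,
    )
    assert out.aucr == 1.0


def test_victim_dose_linearity():
    a = run_ddi(
        _perp(), _victim(), _design(victim_dose=10.0), settings=FAST_SETTINGS, window_h=48.0
    )
    b = run_ddi(
        _perp(), _victim(), _design(victim_dose=20.0), settings=FAST_SETTINGS, window_h=48.0
    )
    assert b.aucr == pytest.approx(a.aucr, rel=1e-8)
    assert b.auc_alone_uM_h == pytest.approx(2.0 * a.auc_alone_uM_h, rel=1e-8)


def test_percent_reduction_identity():
    out = run_ddi(_perp(), _victim(), _design(), settings=FAST_SETTINGS, window_h=48.0)
    assert out.percent_reduction == 100.0 * (1.0 - out.aucr)
    assert out.auc_with_uM_h < out.auc_alone_uM_h


def test_dynamic_static_concordance_under_constant_exposure():
    """A constant-rate perpetrator infusion at steady state reproduces the
    static fm-weighted ratio within 2% for a low-extraction victim."""
    settings = EnzymeSettings(kdeg_per_h={"CYP3A4": 0.1}, driver="systemic")
    perp = _perp(emax=4.0, ec50=0.5)
    vic = _victim(fm={"CYP3A4": 0.8}, cl_L_h=2.0, fu_plasma=0.05)
    reg = DosingRegimen(
        dose_mg=5000.0, interval_h=600.0, n_doses=1, route="infusion", duration_h=600.0
    )
    design = DDIDesign(perpetrator=reg, victim=DosingRegimen(dose_mg=10.0, start_h=200.0))
    out = run_ddi(perp, vic, design, settings=settings, window_h=150.0)
    rate_umol_h = perp.pk.dose_umol(5000.0) / 600.0
    cstar_u = perp.pk.fu_plasma * rate_umol_h / perp.pk.cl_L_h
    si = StaticInput(induction=perp.induction, imax_u_uM=cstar_u, input_multiplier=1.0)
    static_aucr = net_auc_ratio(
        FmMap("vic", {"CYP3A4": 0.8}), {"CYP3A4": fold_cl_change(si, "CYP3A4")}
    )
    assert abs(out.aucr - static_aucr) / static_aucr < 0.02


def test_solver_tolerance_robustness():
    """Halving rtol/atol moves the reported AUCR by far less than 0.5%."""
    base = run_ddi(_perp(), _victim(), _design(), settings=FAST_SETTINGS, window_h=48.0)
    import dataclasses

    tight = dataclasses.replace(FAST_SETTINGS, rtol=5e-9, atol=5e-11)
    redo = run_ddi(_perp(), _victim(), _design(), settings=tight, window_h=48.0)
    assert abs(redo.aucr - base.aucr) / base.aucr < 5e-3


def test_gut_pool_deepens_cyp3a4_interaction():
    """Adding gut-wall extraction (fg0 < 1) to a CYP3A4 victim lowers the
    AUCR relative to the hepatic-only case."""
    no_gut = run_ddi(_perp(), _victim(), _design(), settings=FAST_SETTINGS, window_h=48.0)
    with_gut = run_ddi(
        _perp(), _victim(fg0=0.5), _design(), settings=FAST_SETTINGS, window_h=48.0
    )
    assert with_gut.aucr < no_gut.aucr


# ---------------------------------------------------------------------------
# sensitivity scans
# ---------------------------------------------------------------------------


def test_sensitivity_factor_one_is_bit_identical():
    base = run_ddi(_perp(), _victim(), _design(), settings=FAST_SETTINGS, window_h=48.0)
    tab = sensitivity_scan(
        _perp(), _victim(), _design(), "Emax", [1.0], settings=FAST_SETTINGS, window_h=48.0
    )
    assert tab.loc[0, "aucr"] == base.aucr


def test_sensitivity_monotone_in_emax_and_ec50():
    tab_e = sensitivity_scan(
        _perp(), _victim(), _design(), "Emax", [1.0, 1.5, 2.0],
        settings=FAST_SETTINGS, window_h=48.0,
    )
    assert np.all(np.diff(tab_e["aucr"]) < 0)
    tab_c = sensitivity_scan(
        _perp(), _victim(), _design(), "EC50", [0.5, 1.0, 2.0],
        settings=FAST_SETTINGS, window_h=48.0,
    )
    assert np.all(np.diff(tab_c["aucr"]) > 0)


def test_joint_emax_up_ec50_down_strictly_below_base():
    tab = sensitivity_scan(
        _perp(), _victim(), _design(), ("Emax", "EC50"), [(1.0, 1.0), (2.0, 0.5)],
        settings=FAST_SETTINGS, window_h=48.0,
    )
    assert tab.loc[1, "aucr"] < tab.loc[0, "aucr"]


def test_clint_scan_matches_direct_reruns():
    factors = [0.5, 1.0, 2.0]
    tab = sensitivity_scan(
        _perp(), _victim(), _design(), "CL_int", factors,
        settings=FAST_SETTINGS, window_h=48.0,
    )
    for i, f in enumerate(factors):
        direct = run_ddi(
            _perp(), _victim(), _design(), settings=FAST_SETTINGS,
            window_h=48.0, clint_factor=f,
        )
        assert tab.loc[i, "aucr"] == pytest.approx(direct.aucr, rel=1e-12)


# ---------------------------------------------------------------------------
# configuration validation
# ---------------------------------------------------------------------------


def test_pk_validation_rejects_nonpositive_parameters():
    with pytest.raises(pydantic.ValidationError):
        CompoundPK(
            mw_g_mol=400.0, ka_per_h=-1.0, fa=1.0, v_L=50.0, cl_L_h=5.0, fu_plasma=0.1
        )
    with pytest.raises(pydantic.ValidationError):
        CompoundPK(
            mw_g_mol=400.0, ka_per_h=1.0, fa=1.5, v_L=50.0, cl_L_h=5.0, fu_plasma=0.1
        )
    with pytest.raises(pydantic.ValidationError):
        DosingRegimen(dose_mg=-5.0)
    with pytest.raises(pydantic.ValidationError):
        DosingRegimen(dose_mg=5.0, route="infusion")  # missing duration


def test_enzyme_settings_validation():
    with pytest.raises(ValidationError):
        EnzymeSettings(kdeg_per_h={"CYP3A4": -0.1})
    with pytest.raises(ValidationError):
        EnzymeSettings(kdeg_per_h={"CYP3A4": 0.1}, driver="bogus")
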