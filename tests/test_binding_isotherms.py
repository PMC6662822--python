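"""Single-site binding: exact bound fraction, isotherm fits, free-energy
conversions and melting-curve analysis."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import thermolead as tl
from thermolead.binding_isotherms import (
    NoTransitionError,
    TitrationSeries,
    dg_from_kd,
    ds_from_dg_dh,
    extract_tm,
    fit_isotherm,
    fraction_bound,
    kd_from_dg,
    sigma_dg_from_kd,
    signal_at,
    thermo_state,
)
from thermolead import synthetic_data as synth
from conftest import titration_series_from_table

from oracles import bisect_fraction_bound


def test_fraction_bound_limits():
    assert fraction_bound(2.5e-6, 0.0, 1e-3) == 0.0
    # weak-binding limit: receptor << Kd, ligand = Kd -> half saturation
    assert fraction_bound(1e-9, 3.5e-4, 3.5e-4) == pytest.approx(0.5, abs=1e-3)


def test_fraction_bound_matches_bisection_oracle_at_study_conditions():
    got = fraction_bound(2.5e-6, 1e-3, 0.35e-3)
    assert got == pytest.approx(bisect_fraction_bound(2.5e-6, 1e-3, 0.35e-3), abs=1e-12)


@settings(derandomize=True, max_examples=60)
@given(
    st.floats(1e-9, 1e-3), st.floats(1e-9, 1e-2), st.floats(1e-9, 1e-1),
    st.floats(1.01, 10.0),
)
def test_fraction_bound_monotonicity(receptor, ligand, kd, factor):
    base = fraction_bound(receptor, ligand, kd)
    assert fraction_bound(receptor, ligand * factor, kd) >= base - 1e-12
    assert fraction_bound(receptor, ligand, kd * factor) <= base + 1e-12


@pytest.mark.parametrize("kd", [1e-9, 0.35e-3, 0.06e-6, 1.0])
def test_dg_kd_roundtrip(kd):
    assert kd_from_dg(dg_from_kd(kd)) == pytest.approx(kd, rel=1e-12)


@pytest.mark.parametrize(
    "kd, expected, decimals",
    [(0.35e-3, -19.73, 2), (1.0, 0.0, 2), (0.10e-6, -40.0, 1)],
)
def test_dg_reproduces_published_values(kd, expected, decimals):
    assert round(dg_from_kd(kd, 298.15), decimals) == expected


def test_entropy_from_enthalpy_and_free_energy():
    assert ds_from_dg_dh(-20.0, -20.0)[0] == 0.0
    ds1, _ = ds_from_dg_dh(-40.0, -17.7, 298.15)
    assert ds1 == pytest.approx(74.8, abs=0.05)
    assert abs(ds1 - 70.0) < 11.0  # consistent with the reported ternary value
    ds2, _ = ds_from_dg_dh(-41.3, -25.1, 298.15)
    assert ds2 == pytest.approx(54.3, abs=0.05)
    assert abs(ds2 - 47.0) < 8.0


def test_error_propagation_scales():
    # sigma_dG = R*T*sigma_Kd/Kd: relative Kd error of 10% -> ~0.25 kJ/mol
    assert sigma_dg_from_kd(1e-3, 1e-4) == pytest.approx(8.314 * 298.15 * 0.1 / 1000)
    state = thermo_state(0.06e-6, 0.03e-6, dh=-25.1, sigma_dh=1.2)
    assert state.ds == pytest.approx((state.dh - state.dg) * 1000 / 298.15)
    assert state.sigma_ds > 0


def test_noiseless_isotherm_fit_recovers_kd_exactly():
    kd, receptor = 2.0e-4, 5e-8
    conc = np.logspace(-7, -2, 16)
    signal = 800.0 - 60.0 * fraction_bound(receptor, conc, kd)
    fit = fit_isotherm(TitrationSeries(conc, signal, receptor))
    assert fit.kd == pytest.approx(kd, rel=1e-6)
    assert fit.amplitude == pytest.approx(-60.0, rel=1e-6)


def test_mst_fit_recovers_published_kd_within_ci():
    data = synth.generate(synth.preset("mst/KESEEE-NH2", seed=5))
    fit = fit_isotherm(titration_series_from_table(data.table, data.truth["receptor_M"]))
    lo, hi = fit.kd_ci95
    assert lo <= 0.39e-3 <= hi


def test_reference_peptide_binds_weaker_than_selected_leader():
    lead = synth.generate(synth.preset("mst/KESEEE-NH2", seed=9))
    ref = synth.generate(synth.preset("mst/RRRDDDSDDD", seed=9))
    fit_lead = fit_isotherm(titration_series_from_table(lead.table, lead.truth["receptor_M"]))
    fit_ref = fit_isotherm(titration_series_from_table(ref.table, ref.truth["receptor_M"]))
    assert fit_ref.kd > fit_lead.kd


def test_exclude_above_drops_unfolding_points():
    kd, receptor = 2.0e-4, 5e-8
    conc = np.logspace(-7, -2, 16)
    signal = 800.0 - 60.0 * fraction_bound(receptor, conc, kd)
    signal[conc >= 1e-3] += 50.0  # unfolding artefact at high concentration
    fit = fit_isotherm(TitrationSeries(conc, signal, receptor), exclude_above=1e-3)
    assert fit.kd == pytest.approx(kd, rel=1e-6)


def test_tm_extraction_from_two_state_sigmoid():
    temps = np.arange(20.0, 80.0, 0.25)
    tm_true = 45.0
    ratio = 0.8 + 0.15 / (1.0 + np.exp((tm_true - temps) / 1.5))
    assert extract_tm(temps, ratio) == pytest.approx(tm_true, abs=0.2)


def test_flat_curve_has_no_transition():
    temps = np.arange(20.0, 80.0, 0.25)
    with pytest.raises(NoTransitionError):
        extract_tm(temps, np.full_like(temps, 0.8))
    with pytest.raises(NoTransitionError):
        extract_tm(temps, 0.5 + 0.001 * temps)  # monotone baseline drift only


def test_melting_temperature_decreases_with_peptide_concentration():
    data = synth.generate(synth.preset("dsf/KESEEE-NH2", seed=2))
    concs, tms = [], []
    for key, melt in data.tables.items():
        concs.append(float(key.split("_")[1]))
        tms.append(extract_tm(melt["temp_C"].to_numpy(), melt["ratio"].to_numpy()))
    order = np.argsort(concs)
    tms = np.asarray(tms)[order]
    assert tms[-1] < tms[0] - 2.0  # clear destabilization at high peptide
    # extracted Tm tracks the generator truth
    truth = data.truth["tm_by_conc"]
    for conc, tm in zip(np.asarray(concs)[order], tms):
        assert tm == pytest.approx(truth[f"{conc:.4e}"], abs=0.5)


def test_native_and_unfolded_states_have_distinct_affinities():
    # signal slices at 25 C (native) and 75 C (unfolded) yield different Kd
    data = synth.generate(synth.preset("dsf/KESEEE-NH2", seed=4))
    concs, s25, s75 = [], [], []
    for key, melt in data.tables.items():
        concs.append(float(key.split("_")[1]))
        t, r = melt["temp_C"].to_numpy(), melt["ratio"].to_numpy()
        s25.append(signal_at(t, r, 25.0))
        s75.append(signal_at(t, r, 75.0))
    order = np.argsort(concs)
    concs = np.asarray(concs)[order]
    receptor = data.truth["receptor_M"]
    fit25 = fit_isotherm(
        TitrationSeries(concs, np.asarray(s25)[order], receptor, assay="nanoDSF-ratio")
    )
    fit75 = fit_isotherm(
        TitrationSeries(concs, np.asarray(s75)[order], receptor, assay="nanoDSF-ratio")
    )
    assert fit75.kd > fit25.kd  # weaker binding to the unfolded state
    assert fit25.kd == pytest.approx(data.truth["kd_native"], rel=0.3)
    assert fit75.kd == pytest.approx(data.truth["kd_unfolded"], rel=0.5)
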