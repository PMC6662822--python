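"""Two-exponential relaxation decays: simulation, global fitting, ranking."""

import numpy as np
import pytest

import thermolead as tl
from thermolead.relaxation_fit import (
    BiExpParams,
    RegionAmplitudes,
    RelaxationError,
    RelaxationSeries,
    fit_biexp_global,
    rank_peptides,
    simulate_decay,
)
from thermolead.synthetic_data import NMR_DELAYS_S, RELAXATION_RATES
from conftest import relaxation_series_from_table
from thermolead import synthetic_data as synth


def _params(r2f, r2s, a1, a2, y0=0.0):
    return BiExpParams(r2f=r2f, r2s=r2s, regions={"r": RegionAmplitudes(a1, a2, y0)})


def test_simulated_decay_limits():
    pure_slow = _params(2.5, 2.5, 0.0, 1.0)
    series = simulate_decay(pure_slow, [0.0, 0.1, 5.0])
    y = series.intensities["r"]
    assert y[0] == pytest.approx(1.0)
    assert y[-1] == pytest.approx(0.0, abs=2e-5)  # asymptote is y0 = 0


def test_simulated_decay_matches_hand_formula_for_strongest_binder():
    r2f, r2s = RELAXATION_RATES["KESEEE-NH2"]
    series = simulate_decay(_params(r2f, r2s, 0.4, 0.6, 0.05), NMR_DELAYS_S)
    t = 0.1
    expected = 0.4 * np.exp(-r2f * t) + 0.6 * np.exp(-r2s * t) + 0.05
    i = list(NMR_DELAYS_S).index(t)
    assert series.intensities["r"][i] == pytest.approx(expected, rel=1e-12)


def test_negative_rates_rejected():
    with pytest.raises(RelaxationError):
        _params(-1.0, 0.5, 1.0, 1.0)
    with pytest.raises(RelaxationError):
        simulate_decay(_params(5.0, 1.0, 1.0, 1.0), [0.0, 0.1], noise_sd=-0.1)


def test_noiseless_global_fit_recovers_parameters_exactly():
    truth = BiExpParams(
        r2f=31.3,
        r2s=2.5,
        regions={
            "a": RegionAmplitudes(0.4, 0.8, 0.03),
            "b": RegionAmplitudes(0.2, 0.5, 0.01),
        },
    )
    fit = fit_biexp_global(simulate_decay(truth, NMR_DELAYS_S))
    assert fit.r2f == pytest.approx(31.3, rel=1e-6)
    assert fit.r2s == pytest.approx(2.5, rel=1e-6)
    for key in truth.regions:
        assert fit.regions[key].a1 == pytest.approx(truth.regions[key].a1, rel=1e-5)


def test_monoexponential_degenerate_submodel():
    truth = _params(10.0, 2.5, 0.0, 1.0)
    fit = fit_biexp_global(simulate_decay(truth, NMR_DELAYS_S))
    assert fit.r2s == pytest.approx(2.5, rel=1e-4)
    assert fit.regions["r"].a1 == pytest.approx(0.0, abs=1e-6)


def test_fitter_canonicalizes_component_exchange():
    # swapping (A1, R2f) <-> (A2, R2s) in the generator leaves the curve
    # unchanged; the fit must still report R2f >= R2s
    a = simulate_decay(_params(20.0, 3.0, 0.3, 0.7), NMR_DELAYS_S)
    b = simulate_decay(_params(3.0, 3.0, 0.7, 0.3), NMR_DELAYS_S)  # same slow part
    np.testing.assert_allclose(
        _curve(0.3, 0.7, 20.0, 3.0), _curve(0.7, 0.3, 3.0, 20.0)
    )
    fit = fit_biexp_global(a)
    assert fit.r2f >= fit.r2s


def _curve(a1, a2, rf, rs):
    t = NMR_DELAYS_S
    return a1 * np.exp(-rf * t) + a2 * np.exp(-rs * t)


def test_too_few_delays_rejected():
    series = RelaxationSeries(np.array([0, 0.01, 0.02, 0.05, 0.1]), {"r": np.ones(5)})
    with pytest.raises(RelaxationError):
        fit_biexp_global(series)


def test_recovery_from_noisy_published_rate_pair():
    data = synth.generate(synth.preset("nmr/KESEEE-NH2", seed=7))
    fit = fit_biexp_global(relaxation_series_from_table(data.table))
    assert fit.converged
    lo, hi = fit.r2f_ci95
    assert lo <= 31.3 <= hi


def test_weaker_binder_has_lower_fitted_fast_rate():
    strong = synth.generate(synth.preset("nmr/KESEEE-NH2", seed=11))
    weak = synth.generate(synth.preset("nmr/DDTDDD-NH2", seed=11))
    f_strong = fit_biexp_global(relaxation_series_from_table(strong.table))
    f_weak = fit_biexp_global(relaxation_series_from_table(weak.table))
    assert f_weak.r2f < f_strong.r2f


def test_increasing_true_fast_rate_increases_fitted_rate_in_expectation():
    def median_fit(r2f_true, n=10):
        out = []
        for seed in range(n):
            cfg = synth.ScenarioConfig(
                "nmr", {"r2f": r2f_true, "r2s": 2.5}, noise_sd=0.02, seed=seed
            )
            fit = fit_biexp_global(relaxation_series_from_table(synth.generate(cfg).table))
            out.append(fit.r2f)
        return np.median(out)

    assert median_fit(10.0) < median_fit(20.0) < median_fit(40.0)


def test_ranking_of_published_rates_puts_strongest_first_weakest_last():
    fits = {
        pep: BiExpParams(r2f=r2f, r2s=r2s, regions={})
        for pep, (r2f, r2s) in RELAXATION_RATES.items()
    }
    ranking = rank_peptides(fits)
    assert ranking.iloc[0]["peptide"] == "KESEEE-NH2"
    assert ranking.iloc[-1]["peptide"] == "DDTDDD-NH2"
    assert len(ranking) == len(RELAXATION_RATES)


def test_single_entry_ranking():
    ranking = rank_peptides({"only": BiExpParams(5.0, 1.0, {})})
    assert list(ranking["peptide"]) == ["only"]
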