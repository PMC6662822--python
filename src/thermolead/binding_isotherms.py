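"""Single-site binding isotherms, thermodynamic conversions and melting-curve
analysis.

The central model is 1:1 receptor-ligand equilibrium solved exactly from the
mass balance (no weak-binding approximation), so titrations where receptor
and Kd are comparable are handled correctly.  Signals (nanoDSF 350/330 nm
fluorescence ratio at a fixed temperature, MST thermophoresis amplitude) are
modeled as linear interpolations between free and bound end states.

Free energies use the 1 M reference state: dG = R*T*ln(Kd / 1 M), with
R = 8.314 J/mol/K; errors propagate as sigma_dG = R*T*sigma_Kd/Kd.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import lmfit
from scipy.signal import savgol_filter
from scipy import stats

__all__ = [
    "GAS_CONSTANT",
    "TitrationSeries",
    "BindingFit",
    "ThermoState",
    "FitError",
    "NoTransitionError",
    "fraction_bound",
    "fit_isotherm",
    "dg_from_kd",
    "kd_from_dg",
    "sigma_dg_from_kd",
    "ds_from_dg_dh",
    "thermo_state",
    "extract_tm",
    "signal_at",
]

#: gas constant, J/(mol K)
GAS_CONSTANT = 8.314


class FitError(RuntimeError):
    """Raised when a fit cannot be set up or is fundamentally unidentifiable."""


class NoTransitionError(RuntimeError):
    """Raised when a melting curve shows no detectable unfolding transition."""


def fraction_bound(receptor_total, ligand_total, kd):
    """Fraction of receptor bound at equilibrium for 1:1 binding.

    Solves the mass-balance quadratic exactly, using the numerically stable
    root form 2*R*L / (b + sqrt(b^2 - 4*R*L)) with b = R + L + Kd, which
    avoids catastrophic cancellation when Kd << R + L.
    """
    receptor_total = np.asarray(receptor_total, dtype=float)
    ligand_total = np.asarray(ligand_total, dtype=float)
    if np.any(receptor_total < 0) or np.any(ligand_total < 0):
        raise ValueError("total concentrations must be non-negative")
    if np.any(np.asarray(kd) <= 0):
        raise ValueError("Kd must be positive")
    b = receptor_total + ligand_total + kd
    disc = b * b - 4.0 * receptor_total * ligand_total
    complex_conc = np.where(
        receptor_total * ligand_total > 0,
        2.0 * receptor_total * ligand_total / (b + np.sqrt(np.maximum(disc, 0.0))),
        0.0,
    )
    frac = np.where(receptor_total > 0, complex_conc / np.where(receptor_total > 0, receptor_total, 1.0), 0.0)
    return float(frac) if frac.ndim == 0 else frac


@dataclass
class TitrationSeries:
    """One titration: varying total ligand against fixed total receptor."""

    ligand_total: np.ndarray  # M
    signal: np.ndarray  # a.u.
    receptor_total: float  # M
    assay: str = "MST"
    temperature: float = 298.15  # K
    replicate: int | str = 0

    def __post_init__(self) -> None:
        self.ligand_total = np.asarray(self.ligand_total, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.ligand_total.shape != self.signal.shape:
            raise ValueError("ligand_total and signal must have equal length")
        if np.any(self.ligand_total <= 0):
            raise ValueError("ligand concentrations must be positive")
        if self.receptor_total <= 0:
            raise ValueError("receptor concentration must be positive")


@dataclass
class BindingFit:
    """Result of a single-site isotherm fit."""

    kd: float  # M
    sigma_kd: float  # M
    kd_ci95: tuple[float, float]  # M, from the log-scale standard error
    amplitude: float  # S_bound - S_free, a.u.
    s_free: dict  # per-replicate free-state baseline
    model: str = "single-site"
    success: bool = True
    result: lmfit.minimizer.MinimizerResult | None = field(default=None, repr=False)

    @property
    def s_bound(self) -> dict:
        return {k: v + self.amplitude for k, v in self.s_free.items()}


def _isotherm_residual(params, series_list):
    res = []
    kd = 10.0 ** params["log10_kd"].value
    amp = params["amplitude"].value
    for i, s in enumerate(series_list):
        fb = fraction_bound(s.receptor_total, s.ligand_total, kd)
        model = params[f"s_free_{i}"].value + amp * fb
        res.append(s.signal - model)
    return np.concatenate(res)


def fit_isotherm(
    series: TitrationSeries | Sequence[TitrationSeries],
    kd_bounds: tuple[float, float] = (1e-12, 1.0),
    n_starts: int = 5,
    exclude_above: float | None = None,
) -> BindingFit:
    """Least-squares single-site fit, global across replicate titrations.

    Kd is optimized on a log10 scale within ``kd_bounds``; the fit is
    restarted from ``n_starts`` initial Kd values spread over the sampled
    concentration range and the best minimum is kept.  The free-state
    baseline is per replicate (instrument baselines jitter between runs)
    while the binding amplitude and Kd are shared.  ``exclude_above`` drops
    ligand concentrations at or above a cutoff, e.g. where high peptide
    concentrations unfold the receptor and distort the raw signal.
    """
    series_list = [series] if isinstance(series, TitrationSeries) else list(series)
    if not series_list:
        raise FitError("no titration series given")
    if exclude_above is not None:
        trimmed = []
        for s in series_list:
            keep = s.ligand_total < exclude_above
            trimmed.append(
                TitrationSeries(
                    s.ligand_total[keep], s.signal[keep], s.receptor_total,
                    s.assay, s.temperature, s.replicate,
                )
            )
        series_list = trimmed
    n_points = sum(len(s.ligand_total) for s in series_list)
    if n_points < 3 + len(series_list):
        raise FitError("not enough points for Kd, amplitude and baselines")

    logc = np.log10(np.concatenate([s.ligand_total for s in series_list]))
    lo, hi = math.log10(kd_bounds[0]), math.log10(kd_bounds[1])
    starts = np.clip(np.linspace(logc.min(), logc.max(), n_starts), lo + 0.01, hi - 0.01)

    best = None
    for start in starts:
        params = lmfit.Parameters()
        params.add("log10_kd", value=float(start), min=lo, max=hi)
        sig_all = np.concatenate([s.signal for s in series_list])
        params.add("amplitude", value=float(sig_all[-1] - sig_all[0]) or 1.0)
        for i, s in enumerate(series_list):
            params.add(f"s_free_{i}", value=float(s.signal[0]))
        out = lmfit.minimize(_isotherm_residual, params, args=(series_list,))
        if best is None or out.chisqr < best.chisqr:
            best = out

    p = best.params
    kd = 10.0 ** p["log10_kd"].value
    stderr_log = p["log10_kd"].stderr
    success = bool(best.success) and stderr_log is not None and np.isfinite(stderr_log)
    at_bound = (
        p["log10_kd"].value <= lo + 1e-6 or p["log10_kd"].value >= hi - 1e-6
    )
    if at_bound:
        success = False
    if stderr_log is None or not np.isfinite(stderr_log):
        stderr_log = np.nan
    tcrit = stats.t.ppf(0.975, max(best.nfree, 1))
    ci = (10.0 ** (p["log10_kd"].value - tcrit * stderr_log),
          10.0 ** (p["log10_kd"].value + tcrit * stderr_log))
    return BindingFit(
        kd=kd,
        sigma_kd=math.log(10) * kd * stderr_log,
        kd_ci95=ci,
        amplitude=p["amplitude"].value,
        s_free={s.replicate: p[f"s_free_{i}"].value for i, s in enumerate(series_list)},
        success=success,
        result=best,
    )


def dg_from_kd(kd: float, temperature: float = 298.15) -> float:
    """Binding free energy in kJ/mol from Kd (M), 1 M reference state."""
    if kd <= 0:
        raise ValueError("Kd must be positive")
    return GAS_CONSTANT * temperature * math.log(kd) / 1000.0


def kd_from_dg(dg_kj: float, temperature: float = 298.15) -> float:
    """Inverse of :func:`dg_from_kd`."""
    return math.exp(dg_kj * 1000.0 / (GAS_CONSTANT * temperature))


def sigma_dg_from_kd(kd: float, sigma_kd: float, temperature: float = 298.15) -> float:
    """Propagated free-energy error, kJ/mol: R*T*sigma_Kd/Kd."""
    return GAS_CONSTANT * temperature * sigma_kd / kd / 1000.0


def ds_from_dg_dh(
    dg_kj: float,
    dh_kj: float,
    temperature: float = 298.15,
    sigma_dg: float = 0.0,
    sigma_dh: float = 0.0,
) -> tuple[float, float]:
    """Binding entropy (J/mol/K) and its propagated error from dG and dH."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    ds = (dh_kj - dg_kj) * 1000.0 / temperature
    sigma = math.hypot(sigma_dg, sigma_dh) * 1000.0 / temperature
    return ds, sigma


@dataclass
class ThermoState:
    """Complete thermodynamic characterization of one binding equilibrium."""

    kd: float  # M
    sigma_kd: float  # M
    dg: float  # kJ/mol
    sigma_dg: float
    dh: float | None = None  # kJ/mol
    sigma_dh: float | None = None
    ds: float | None = None  # J/mol/K
    sigma_ds: float | None = None
    temperature: float = 298.15  # K


def thermo_state(
    kd: float,
    sigma_kd: float = 0.0,
    dh: float | None = None,
    sigma_dh: float = 0.0,
    temperature: float = 298.15,
) -> ThermoState:
    """Build a :class:`ThermoState` from Kd (and optionally dH)."""
    dg = dg_from_kd(kd, temperature)
    sdg = sigma_dg_from_kd(kd, sigma_kd, temperature)
    if dh is None:
        return ThermoState(kd, sigma_kd, dg, sdg, temperature=temperature)
    ds, sds = ds_from_dg_dh(dg, dh, temperature, sdg, sigma_dh)
    return ThermoState(kd, sigma_kd, dg, sdg, dh, sigma_dh, ds, sds, temperature)


def signal_at(temps, values, at_temp: float) -> float:
    """Linear interpolation of a thermal profile at one temperature."""
    temps = np.asarray(temps, dtype=float)
    values = np.asarray(values, dtype=float)
    if not (temps.min() <= at_temp <= temps.max()):
        raise ValueError("requested temperature outside the ramp")
    return float(np.interp(at_temp, temps, values))


def extract_tm(temps, ratios, window: int = 11, polyorder: int = 3) -> float:
    """Melting temperature from a 350/330 nm fluorescence-ratio thermal ramp.

    The curve is Savitzky-Golay smoothed, the first derivative with respect
    to temperature is taken, and Tm is the location of the derivative
    extremum refined by parabolic interpolation over the neighbouring grid
    points.  A curve without a clear transition (derivative extremum not
    standing out of the baseline slope) raises :class:`NoTransitionError`.
    """
    temps = np.asarray(temps, dtype=float)
    ratios = np.asarray(ratios, dtype=float)
    if temps.size < window:
        raise ValueError("melting curve too short for the smoothing window")
    if np.any(np.diff(temps) <= 0):
        raise ValueError("temperatures must be strictly increasing")
    smooth = savgol_filter(ratios, window_length=window, polyorder=polyorder)
    deriv = np.gradient(smooth, temps)
    mag = np.abs(deriv)
    # ignore edge artefacts of the smoother
    inner = slice(window // 2, len(mag) - window // 2)
    idx = int(np.argmax(mag[inner])) + window // 2
    peak, baseline = mag[idx], float(np.median(mag))
    scale = float(np.max(np.abs(smooth))) or 1.0
    if peak < 1e-9 * scale or (baseline > 0 and peak < 3.0 * baseline):
        raise NoTransitionError("no unfolding transition detected")
    if 0 < idx < len(mag) - 1:
        y0, y1, y2 = mag[idx - 1], mag[idx], mag[idx + 1]
        denom = y0 - 2 * y1 + y2
        shift = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
        step = temps[idx + 1] - temps[idx]
        return float(temps[idx] + np.clip(shift, -1, 1) * step)
    return float(temps[idx])
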