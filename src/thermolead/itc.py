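"""One-site isothermal titration calorimetry: forward simulation and fitting.

The experimental design mirrored here is a reverse titration: the low-mass
ligand sits in the perfusion cell and the protein is injected from the
syringe (a small pre-injection followed by a series of equal injections).
Each injection displaces an equal volume of pre-injection cell content out
of the active volume; concentrations are then updated and the heat of the
injection is the binding enthalpy times the change in complex inside the
active volume,

    Q_i = dH * V_cell * ( [C]_i - [C]_{i-1} * (1 - dV_i/V_cell) ).

The equilibrium complex concentration is the exact single-site quadratic
with apparent stoichiometry n (binding sites per cell-species molecule).
Because the pair is treated symmetrically, which species is the "titrant"
does not affect Kd.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import lmfit
from scipy import stats

from .binding_isotherms import ThermoState, thermo_state

__all__ = [
    "ITCExperiment",
    "ITCFit",
    "ITCError",
    "paper_schedule",
    "simulate_itc",
    "itc_heats",
    "fit_itc",
]


class ITCError(ValueError):
    """Invalid ITC design or data."""


def paper_schedule() -> np.ndarray:
    """Injection volumes (µl): one 4 µl pre-injection then 12 x 20 µl."""
    return np.array([4.0] + [20.0] * 12)


@dataclass
class ITCExperiment:
    """Design (and optionally measured heats) of one ITC titration."""

    cell_conc: float  # M, species loaded in the cell
    syringe_conc: float  # M, titrant
    injection_volumes_ul: np.ndarray = field(default_factory=paper_schedule)
    cell_volume_ul: float = 950.0
    heats_uJ: np.ndarray | None = None  # per injection, pre-injection first
    temperature: float = 298.15  # K

    def __post_init__(self) -> None:
        self.injection_volumes_ul = np.asarray(self.injection_volumes_ul, dtype=float)
        if self.cell_volume_ul <= 0 or np.any(self.injection_volumes_ul <= 0):
            raise ITCError("volumes must be positive")
        if self.cell_conc < 0 or self.syringe_conc < 0:
            raise ITCError("concentrations must be non-negative")
        if self.heats_uJ is not None:
            self.heats_uJ = np.asarray(self.heats_uJ, dtype=float)
            if self.heats_uJ.shape != self.injection_volumes_ul.shape:
                raise ITCError("heats and injection volumes must align")


@dataclass
class ITCFit:
    """Fitted one-site parameters of an ITC titration."""

    kd: float  # M
    sigma_kd: float  # M
    kd_ci95: tuple[float, float]
    dh: float  # kJ/mol
    sigma_dh: float
    n: float  # apparent stoichiometry (sites per cell-species molecule)
    sigma_n: float
    baseline_uJ: float  # constant per-injection dilution heat
    c_value: float  # n * cell_conc / Kd
    success: bool = True
    warnings: list[str] = field(default_factory=list)
    result: lmfit.minimizer.MinimizerResult | None = field(default=None, repr=False)


def _complex_quadratic(sites: float, titrant: float, kd: float) -> float:
    """Stable root of C^2 - C(S + P + Kd) + S*P = 0 on [0, min(S, P)]."""
    b = sites + titrant + kd
    prod = sites * titrant
    if prod <= 0:
        return 0.0
    return 2.0 * prod / (b + math.sqrt(max(b * b - 4.0 * prod, 0.0)))


def itc_heats(
    kd: float,
    dh_kj: float,
    n: float,
    design: ITCExperiment,
    baseline_uJ: float = 0.0,
) -> np.ndarray:
    """Noiseless per-injection heats (µJ) of the one-site forward model."""
    if kd <= 0 or n <= 0:
        raise ITCError("Kd and stoichiometry must be positive")
    v_cell = design.cell_volume_ul * 1e-6  # l
    cell = design.cell_conc  # M, diluted as injections proceed
    titrant = 0.0  # M, accumulates
    complex_prev = 0.0
    heats = np.empty(design.injection_volumes_ul.size)
    for i, dv_ul in enumerate(design.injection_volumes_ul):
        f = dv_ul * 1e-6 / v_cell
        cell *= 1.0 - f
        titrant = titrant * (1.0 - f) + design.syringe_conc * f
        complex_new = _complex_quadratic(n * cell, titrant, kd)
        dq_mol = complex_new - complex_prev * (1.0 - f)  # M
        heats[i] = dh_kj * 1e3 * v_cell * dq_mol * 1e6 + baseline_uJ
        complex_prev = complex_new
    return heats


def simulate_itc(
    kd: float,
    dh_kj: float,
    n: float,
    design: ITCExperiment,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> ITCExperiment:
    """Forward-simulate an ITC run; returns the design with heats filled in.

    ``noise_sd`` is a Gaussian standard deviation expressed as a fraction of
    the largest injection heat magnitude.
    """
    if noise_sd < 0:
        raise ITCError("noise_sd must be non-negative")
    heats = itc_heats(kd, dh_kj, n, design)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        scale = noise_sd * (np.max(np.abs(heats)) or 1.0)
        heats = heats + rng.normal(0.0, scale, size=heats.shape)
    return replace(design, heats_uJ=heats)


def fit_itc(
    experiments: ITCExperiment | Sequence[ITCExperiment],
    exclude_pre_injection: bool = True,
    kd_log10_starts: Sequence[float] = (-9.0, -8.0, -7.0, -6.0, -5.0),
) -> tuple[ITCFit, ThermoState]:
    """Least-squares one-site fit of (Kd, dH, n, baseline), jointly over runs.

    The pre-injection (first, reduced-volume injection) is excluded from the
    residuals by default, as its heat is corrupted by diffusion across the
    syringe tip.  Kd is optimized as log10(Kd) with restarts over
    ``kd_log10_starts``.  A c-value (n * cell_conc / Kd) outside [1, 1000]
    triggers a warning: outside that window the isotherm shape constrains Kd
    poorly.  dG and dS are derived from the fit via the 1 M reference state.
    """
    exp_list = [experiments] if isinstance(experiments, ITCExperiment) else list(experiments)
    if not exp_list:
        raise ITCError("no experiments given")
    for e in exp_list:
        if e.heats_uJ is None:
            raise ITCError("experiment has no measured heats")
        usable = e.heats_uJ.size - (1 if exclude_pre_injection else 0)
        if usable < 8:
            raise ITCError("need at least 8 usable injections")

    start = 0 if not exclude_pre_injection else 1
    # tight-binding guess: first usable heat over moles of titrant injected
    e0 = exp_list[0]
    injected_mol = e0.syringe_conc * e0.injection_volumes_ul[start] * 1e-6
    dh0 = float(e0.heats_uJ[start]) * 1e-6 / injected_mol / 1e3 if injected_mol > 0 else -20.0
    if not np.isfinite(dh0) or dh0 == 0:
        dh0 = -20.0

    def residual(p):
        kd = 10.0 ** p["log10_kd"].value
        out = []
        for e in exp_list:
            model = itc_heats(kd, p["dh"].value, p["n"].value, e, p["baseline"].value)
            out.append(e.heats_uJ[start:] - model[start:])
        return np.concatenate(out)

    best = None
    for s in kd_log10_starts:
        params = lmfit.Parameters()
        params.add("log10_kd", value=float(s), min=-12.0, max=0.0)
        params.add("dh", value=dh0)
        params.add("n", value=1.0, min=0.05, max=10.0)
        params.add("baseline", value=0.0)
        out = lmfit.minimize(residual, params)
        if best is None or out.chisqr < best.chisqr:
            best = out

    p = best.params
    kd = 10.0 ** p["log10_kd"].value
    stderr_log = p["log10_kd"].stderr
    ok = bool(best.success) and stderr_log is not None and np.isfinite(stderr_log)
    if stderr_log is None or not np.isfinite(stderr_log):
        stderr_log = np.nan
    tcrit = stats.t.ppf(0.975, max(best.nfree, 1))
    ci = (10.0 ** (p["log10_kd"].value - tcrit * stderr_log),
          10.0 ** (p["log10_kd"].value + tcrit * stderr_log))
    c_value = p["n"].value * exp_list[0].cell_conc / kd
    warns = []
    if not 1.0 <= c_value <= 1000.0:
        msg = f"c-value {c_value:.3g} outside [1, 1000]: Kd poorly determined"
        warns.append(msg)
        warnings.warn(msg, stacklevel=2)
    fit = ITCFit(
        kd=kd,
        sigma_kd=math.log(10) * kd * stderr_log,
        kd_ci95=ci,
        dh=p["dh"].value,
        sigma_dh=p["dh"].stderr if p["dh"].stderr is not None else np.nan,
        n=p["n"].value,
        sigma_n=p["n"].stderr if p["n"].stderr is not None else np.nan,
        baseline_uJ=p["baseline"].value,
        c_value=c_value,
        success=ok,
        warnings=warns,
        result=best,
    )
    state = thermo_state(
        kd=kd,
        sigma_kd=fit.sigma_kd,
        dh=fit.dh,
        sigma_dh=fit.sigma_dh if np.isfinite(fit.sigma_dh) else 0.0,
        temperature=exp_list[0].temperature,
    )
    return fit, state
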