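"""Sigmoidal IC50 analysis of kinase-inhibition dose-response data.

The ADP-Glo style readout is luminescence proportional to residual kinase
activity, so the response falls with inhibitor concentration.  The model is
the four-parameter logistic (4PL)

    y(c) = bottom + (top - bottom) / (1 + (c / IC50)^hill),

fit globally across replicate series in log10-concentration space.  Potency
comparisons between a parent compound and its conjugate are expressed as a
fold-enhancement ratio with quotient error propagation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import lmfit
from scipy import stats

from .binding_isotherms import FitError

__all__ = [
    "DoseResponseSeries",
    "DoseResponseFit",
    "UnidentifiableFitError",
    "four_param_logistic",
    "fit_ic50",
    "fold_enhancement",
]


class UnidentifiableFitError(FitError):
    """The response range is too small relative to noise to define an IC50."""


@dataclass
class DoseResponseSeries:
    """One replicate of an inhibition assay: concentration vs. signal."""

    conc: np.ndarray  # M
    response: np.ndarray  # a.u. (luminescence)
    replicate: int | str = 0

    def __post_init__(self) -> None:
        self.conc = np.asarray(self.conc, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.conc.shape != self.response.shape:
            raise ValueError("conc and response must have equal length")
        if np.any(self.conc <= 0):
            raise ValueError("concentrations must be positive")


@dataclass
class DoseResponseFit:
    ic50: float  # M
    sigma_ic50: float  # M
    ic50_ci95: tuple[float, float]
    hill: float
    top: float
    bottom: float
    success: bool = True
    result: lmfit.minimizer.MinimizerResult | None = field(default=None, repr=False)


def four_param_logistic(conc, ic50, hill, top, bottom):
    """Descending 4PL response (inhibition: top at low dose)."""
    conc = np.asarray(conc, dtype=float)
    return bottom + (top - bottom) / (1.0 + (conc / ic50) ** hill)


def _identifiability_check(series_list):
    """Reject data whose dynamic range is buried in replicate noise."""
    pooled: dict[float, list[float]] = {}
    for s in series_list:
        for c, r in zip(s.conc, s.response):
            pooled.setdefault(float(c), []).append(float(r))
    means = np.array([np.mean(v) for v in pooled.values()])
    spread = float(means.max() - means.min())
    sds = [np.std(v, ddof=1) for v in pooled.values() if len(v) > 1]
    noise = float(np.mean(sds)) if sds else 0.0
    if spread == 0 or (noise > 0 and spread < 3.0 * noise):
        raise UnidentifiableFitError(
            f"response range {spread:.3g} below 3x replicate noise {noise:.3g}"
        )


def fit_ic50(
    series: DoseResponseSeries | Sequence[DoseResponseSeries],
    hill_bounds: tuple[float, float] = (0.3, 4.0),
    fix_plateaus: tuple[float, float] | None = None,
    n_starts: int = 3,
) -> DoseResponseFit:
    """Global 4PL fit over replicates; IC50 optimized on the log10 scale.

    ``fix_plateaus`` optionally pins (top, bottom) instead of fitting them.
    At least 5 distinct concentrations are required; a response window
    smaller than three times the replicate noise raises
    :class:`UnidentifiableFitError` before any fitting is attempted.
    """
    series_list = [series] if isinstance(series, DoseResponseSeries) else list(series)
    if not series_list:
        raise FitError("no dose-response series given")
    all_conc = np.concatenate([s.conc for s in series_list])
    if np.unique(all_conc).size < 5:
        raise FitError("need at least 5 distinct concentrations")
    _identifiability_check(series_list)

    logc = np.log10(all_conc)
    resp = np.concatenate([s.response for s in series_list])
    starts = np.quantile(logc, np.linspace(0.25, 0.75, n_starts))

    def residual(p):
        model = four_param_logistic(
            all_conc, 10.0 ** p["log10_ic50"].value, p["hill"].value,
            p["top"].value, p["bottom"].value,
        )
        return resp - model

    best = None
    for s0 in starts:
        params = lmfit.Parameters()
        params.add("log10_ic50", value=float(s0), min=logc.min() - 3, max=logc.max() + 3)
        params.add("hill", value=1.0, min=hill_bounds[0], max=hill_bounds[1])
        if fix_plateaus is None:
            params.add("top", value=float(resp.max()))
            params.add("bottom", value=float(resp.min()))
        else:
            params.add("top", value=fix_plateaus[0], vary=False)
            params.add("bottom", value=fix_plateaus[1], vary=False)
        out = lmfit.minimize(residual, params)
        if best is None or out.chisqr < best.chisqr:
            best = out

    p = best.params
    ic50 = 10.0 ** p["log10_ic50"].value
    stderr_log = p["log10_ic50"].stderr
    ok = bool(best.success) and stderr_log is not None and np.isfinite(stderr_log)
    if stderr_log is None or not np.isfinite(stderr_log):
        stderr_log = np.nan
    tcrit = stats.t.ppf(0.975, max(best.nfree, 1))
    ci = (10.0 ** (p["log10_ic50"].value - tcrit * stderr_log),
          10.0 ** (p["log10_ic50"].value + tcrit * stderr_log))
    if p["top"].value <= p["bottom"].value:
        ok = False
    return DoseResponseFit(
        ic50=ic50,
        sigma_ic50=math.log(10) * ic50 * stderr_log,
        ic50_ci95=ci,
        hill=p["hill"].value,
        top=p["top"].value,
        bottom=p["bottom"].value,
        success=ok,
        result=best,
    )


def fold_enhancement(
    ic50_parent: float,
    ic50_derived: float,
    sigma_parent: float = 0.0,
    sigma_derived: float = 0.0,
) -> tuple[float, float]:
    """Potency gain parent/derived with quotient error propagation."""
    if ic50_parent <= 0 or ic50_derived <= 0:
        raise ValueError("IC50 values must be positive")
    ratio = ic50_parent / ic50_derived
    sigma = ratio * math.hypot(sigma_parent / ic50_parent, sigma_derived / ic50_derived)
    return ratio, sigma
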