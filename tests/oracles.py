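"""Independent brute-force oracles used to validate the closed-form and
fitted computations.  These deliberately avoid the package's own solution
paths: equilibria are solved by interval bisection on the mass balance and
masses are summed from atomic masses by hand."""

from __future__ import annotations

import numpy as np

# atomic monoisotopic masses, Da (CODATA/IUPAC values)
ATOMIC_MONO = {"H": 1.0078250319, "C": 12.0, "N": 14.0030740052, "O": 15.9949146221, "S": 31.97207069}


def formula_mass(formula: dict[str, int]) -> float:
    """Sum atomic masses of an elemental formula given as {element: count}."""
    return sum(ATOMIC_MONO[el] * cnt for el, cnt in formula.items())


def bisect_complex(sites: float, titrant: float, kd: float, iters: int = 200) -> float:
    """Equilibrium complex concentration by bisection on the mass balance
    (S - C)(P - C) = Kd * C over C in [0, min(S, P)]."""
    lo, hi = 0.0, min(sites, titrant)
    if hi == 0.0:
        return 0.0

    def f(c):
        return (sites - c) * (titrant - c) - kd * c

    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def bisect_fraction_bound(receptor: float, ligand: float, kd: float) -> float:
    """Receptor bound fraction via the bisection equilibrium solver."""
    if receptor == 0:
        return 0.0
    return bisect_complex(receptor, ligand, kd) / receptor


def itc_heats_oracle(kd, dh_kj, n, cell_conc, syringe_conc, cell_volume_ul, injections_ul):
    """Per-injection ITC heats (µJ) with moles-based bookkeeping and a
    bisection equilibrium solve at every injection.

    Uses the same physical convention as the simulator (displaced volume
    leaves at pre-injection concentrations) but an entirely separate code
    path: state is tracked in moles, equilibrium is solved by bisection, and
    heats follow from the complex increment corrected for displacement.
    """
    v = cell_volume_ul * 1e-6  # l
    mol_cell = cell_conc * v
    mol_titrant = 0.0
    c_prev = 0.0
    heats = []
    for dv_ul in injections_ul:
        dv = dv_ul * 1e-6
        f = dv / v
        mol_cell -= (mol_cell / v) * dv
        mol_titrant = mol_titrant - (mol_titrant / v) * dv + syringe_conc * dv
        c_new = bisect_complex(n * mol_cell / v, mol_titrant / v, kd)
        dq = dh_kj * 1e3 * v * (c_new - c_prev * (1.0 - f))  # J
        heats.append(dq * 1e6)
        c_prev = c_new
    return np.array(heats)
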