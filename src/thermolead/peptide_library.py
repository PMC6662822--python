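"""Combinatorial peptide libraries: enumeration, masses, isobaric classes,
MS peak assignment and pull-down enrichment scoring.

Positional libraries are written as an ordered list of residue sets, e.g.
``["KGDE", "DE", "ST", "DE", "DE", "DE"]`` with an amidated C-terminus.
Enumeration is the Cartesian product of the position sets; each member is a
:class:`Peptide` carrying its elemental composition and neutral
monoisotopic/average masses.  Because the residue pairs Thr+Asp and Glu+Ser
share the elemental composition C8H12N2O5, distinct sequences can be exactly
isobaric; :func:`isobaric_classes` groups them so that MS peaks are assigned
to ensembles rather than to single sequences.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from pyteomics import mass as _pmass

__all__ = [
    "LibraryError",
    "LibrarySpec",
    "Peptide",
    "IsobaricClass",
    "MassPeak",
    "PeakAssignment",
    "enumerate_library",
    "peptide_mass",
    "isobaric_classes",
    "assign_peaks",
    "enrichment_score",
]

#: mass of a proton, Da (monoisotopic convention)
PROTON_MONO = 1.007276
#: proton mass used with average masses, Da
PROTON_AVG = 1.008

STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")
CTERM_STATES = ("free-acid", "amide")


class LibraryError(ValueError):
    """Invalid library specification or residue code."""


def _validate_cterm(cterm: str) -> str:
    if cterm not in CTERM_STATES:
        raise LibraryError(f"cterm must be one of {CTERM_STATES}, got {cterm!r}")
    return cterm


@dataclass(frozen=True)
class LibrarySpec:
    """Positional residue-set grammar of a combinatorial peptide library."""

    positions: tuple[str, ...]
    cterm: str = "amide"
    name: str = ""

    def __post_init__(self) -> None:
        _validate_cterm(self.cterm)
        object.__setattr__(self, "positions", tuple(self.positions))
        if not self.positions:
            raise LibraryError("library needs at least one position")
        for i, pos in enumerate(self.positions):
            if not pos:
                raise LibraryError(f"position {i} has an empty residue set")
            bad = set(pos) - STANDARD_RESIDUES
            if bad:
                raise LibraryError(f"position {i}: unknown residue codes {sorted(bad)}")

    @property
    def size(self) -> int:
        """Number of distinct sequences (product of position-set sizes)."""
        out = 1
        for pos in self.positions:
            out *= len(set(pos))
        return out


@dataclass(frozen=True)
class Peptide:
    """A single peptide sequence with a defined C-terminal state."""

    sequence: str
    cterm: str = "free-acid"

    def __post_init__(self) -> None:
        _validate_cterm(self.cterm)
        bad = set(self.sequence) - STANDARD_RESIDUES
        if bad:
            raise LibraryError(f"unknown residue codes {sorted(bad)} in {self.sequence!r}")

    @property
    def composition(self) -> _pmass.Composition:
        """Elemental composition of the neutral molecule."""
        comp = _pmass.Composition(sequence=self.sequence)
        if self.cterm == "amide":
            # C-terminal OH -> NH2
            comp["O"] -= 1
            comp["H"] += 1
            comp["N"] += 1
        return comp

    @property
    def residue_counts(self) -> Counter:
        return Counter(self.sequence)

    @property
    def mono_mass(self) -> float:
        """Neutral monoisotopic mass, Da."""
        return _pmass.calculate_mass(composition=self.composition)

    @property
    def avg_mass(self) -> float:
        """Neutral average mass, Da."""
        return _pmass.calculate_mass(composition=self.composition, average=True)

    @property
    def label(self) -> str:
        return self.sequence + ("-NH2" if self.cterm == "amide" else "")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


def enumerate_library(spec: LibrarySpec) -> list[Peptide]:
    """Enumerate the full Cartesian product of a positional library.

    Returns one :class:`Peptide` per distinct sequence; the count equals the
    product of the position-set sizes.
    """
    position_sets = [sorted(set(pos)) for pos in spec.positions]
    return [
        Peptide("".join(combo), cterm=spec.cterm)
        for combo in itertools.product(*position_sets)
    ]


def peptide_mass(
    peptide: Peptide,
    kind: str = "mono",
    adduct: str = "neutral",
    nominal: bool = False,
) -> float:
    """Mass of a peptide under an explicit convention.

    Parameters
    ----------
    kind : {"mono", "avg"}
        Monoisotopic or average mass.
    adduct : {"neutral", "protonated"}
        ``protonated`` returns the singly protonated ion mass [M+H]+.
    nominal : bool
        Round to the nearest integer (the "750 Da" style of reporting used
        for unit-resolution ESI-MS peak lists).
    """
    if kind == "mono":
        m = peptide.mono_mass
        if adduct == "protonated":
            m += PROTON_MONO
        elif adduct != "neutral":
            raise LibraryError(f"unknown adduct {adduct!r}")
    elif kind == "avg":
        m = peptide.avg_mass
        if adduct == "protonated":
            m += PROTON_AVG
        elif adduct != "neutral":
            raise LibraryError(f"unknown adduct {adduct!r}")
    else:
        raise LibraryError(f"kind must be 'mono' or 'avg', got {kind!r}")
    return float(round(m)) if nominal else float(m)


@dataclass
class IsobaricClass:
    """A set of peptides indistinguishable by mass under a stated policy."""

    key: tuple
    members: list[Peptide] = field(default_factory=list)

    @property
    def mono_mass(self) -> float:
        return self.members[0].mono_mass

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def labels(self) -> list[str]:
        return [p.label for p in self.members]


def _composition_key(p: Peptide) -> tuple:
    return tuple(sorted(p.composition.items()))


def isobaric_classes(
    peptides: Sequence[Peptide],
    policy: str = "exact-composition",
    tolerance: float | None = None,
) -> list[IsobaricClass]:
    """Partition a peptide list into isobaric classes.

    ``exact-composition`` groups by identical elemental composition (an
    equivalence relation; captures the T+D = E+S degeneracy exactly).
    ``mass-tolerance`` chains peptides whose neutral monoisotopic masses lie
    within ``tolerance`` Da of the previous member after sorting, so every
    exact-composition class is contained in a tolerance class for any
    tolerance > 0.
    """
    if not peptides:
        raise LibraryError("cannot partition an empty peptide list")
    if policy == "exact-composition":
        groups: dict[tuple, IsobaricClass] = {}
        for p in peptides:
            key = _composition_key(p)
            groups.setdefault(key, IsobaricClass(key=key)).members.append(p)
        classes = list(groups.values())
    elif policy == "mass-tolerance":
        if tolerance is None or tolerance < 0:
            raise LibraryError("mass-tolerance policy needs tolerance >= 0")
        ordered = sorted(peptides, key=lambda p: p.mono_mass)
        classes = []
        for p in ordered:
            if classes and p.mono_mass - classes[-1].members[-1].mono_mass <= tolerance:
                classes[-1].members.append(p)
            else:
                classes.append(IsobaricClass(key=(round(p.mono_mass, 6),), members=[p]))
    else:
        raise LibraryError(f"unknown policy {policy!r}")
    return sorted(classes, key=lambda c: c.mono_mass)


@dataclass(frozen=True)
class MassPeak:
    """A centroided MS peak from one LC-MS run."""

    mz: float
    intensity: float
    run: str = "library"

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise LibraryError("peak m/z must be positive")
        if self.intensity < 0:
            raise LibraryError("peak intensity must be non-negative")


@dataclass
class PeakAssignment:
    """Association of an observed peak with candidate isobaric classes."""

    peak: MassPeak
    classes: list[IsobaricClass]
    adduct: str
    mass_error: float | None

    @property
    def assigned(self) -> bool:
        return bool(self.classes)

    @property
    def candidates(self) -> list[Peptide]:
        return [p for c in self.classes for p in c.members]


def assign_peaks(
    peaks: Iterable[MassPeak],
    classes: Sequence[IsobaricClass],
    tolerance: float = 0.5,
    kind: str = "mono",
    adduct: str = "protonated",
) -> list[PeakAssignment]:
    """Match observed peaks against class masses within an m/z tolerance.

    Default convention: singly protonated monoisotopic ions at 0.5 Da
    (unit-resolution) tolerance.  Unmatched peaks are reported with an empty
    candidate list, never dropped.
    """
    if tolerance <= 0:
        raise LibraryError("tolerance must be positive")
    ref = np.array([peptide_mass(c.members[0], kind=kind, adduct=adduct) for c in classes])
    out = []
    for peak in peaks:
        err = np.abs(ref - peak.mz)
        hit = np.flatnonzero(err <= tolerance)
        out.append(
            PeakAssignment(
                peak=peak,
                classes=[classes[i] for i in hit],
                adduct=adduct,
                mass_error=float(err[hit].min()) if hit.size else None,
            )
        )
    return out


def _class_intensities(
    peaks: Sequence[MassPeak],
    classes: Sequence[IsobaricClass],
    tolerance: float,
) -> np.ndarray:
    """Per-class intensity, normalized to the run's total ion intensity."""
    total = sum(p.intensity for p in peaks)
    acc = np.zeros(len(classes))
    for assignment in assign_peaks(peaks, classes, tolerance=tolerance):
        for cls in assignment.classes:
            acc[classes.index(cls)] += assignment.peak.intensity
    return acc / total if total > 0 else acc


def enrichment_score(
    peaks_library: Sequence[MassPeak],
    peaks_eluent: Sequence[MassPeak],
    peaks_control: Sequence[MassPeak],
    classes: Sequence[IsobaricClass],
    tolerance: float = 0.5,
    control_threshold: float = 1.5,
) -> pd.DataFrame:
    """Score pull-down enrichment per isobaric class.

    Intensities in each run are total-ion normalized; the enrichment of a
    class is its eluent/library share ratio.  Classes whose control-run ratio
    (no protein on the column) exceeds ``control_threshold`` are flagged
    unspecific and excluded from the ranking, mirroring the exclusion of
    resin binders in the pull-down analysis.  Classes absent from the library
    run get an undefined (NaN) ratio and are flagged.
    """
    lib = _class_intensities(peaks_library, classes, tolerance)
    elu = _class_intensities(peaks_eluent, classes, tolerance)
    ctl = _class_intensities(peaks_control, classes, tolerance)
    with np.errstate(divide="ignore", invalid="ignore"):
        enrich = np.where(lib > 0, elu / lib, np.nan)
        ctl_ratio = np.where(lib > 0, ctl / lib, np.nan)
    frame = pd.DataFrame(
        {
            "class_mass_mh": [
                peptide_mass(c.members[0], adduct="protonated") for c in classes
            ],
            "members": [";".join(c.labels) for c in classes],
            "n_members": [c.size for c in classes],
            "library_share": lib,
            "eluent_share": elu,
            "control_share": ctl,
            "enrichment": enrich,
            "control_ratio": ctl_ratio,
        }
    )
    frame["undefined"] = ~np.isfinite(enrich)
    frame["unspecific"] = np.nan_to_num(ctl_ratio) > control_threshold
    frame["excluded"] = frame["undefined"] | frame["unspecific"]
    frame["rank"] = (
        frame["enrichment"].where(~frame["excluded"]).rank(ascending=False)
    )
    return frame.sort_values("rank").reset_index(drop=True)
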