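"""Shared CSV/JSON readers and writers plus config loading and logging.

All concentrations are serialized in molar with explicit unit suffixes in
the column headers (``conc_M``, ``heat_uJ``, ``delay_s``, ...); energies in
kJ/mol; temperatures in kelvin internally.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .binding_isotherms import TitrationSeries
from .dose_response import DoseResponseSeries
from .itc import ITCExperiment
from .peptide_library import LibrarySpec, MassPeak
from .relaxation_fit import RelaxationSeries

__all__ = [
    "setup_logging",
    "load_config",
    "json_dump",
    "read_table",
    "write_table",
    "read_relaxation_csv",
    "read_titration_csv",
    "read_melting_csv",
    "read_itc_csv",
    "read_dose_response_csv",
    "read_peaks_csv",
    "library_spec_from_config",
]

log = logging.getLogger("thermolead")


def setup_logging(level: str = "INFO") -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("thermolead")
    root.handlers[:] = [handler]
    root.setLevel(level.upper())


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg


class _Encoder(json.JSONEncoder):
    def default(self, o: Any):
        if isinstance(o, np.bool_):
            return bool(o)
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            d = dataclasses.asdict(o)
            d.pop("result", None)  # fit machinery is not serializable
            return d
        if isinstance(o, pd.DataFrame):
            return o.to_dict(orient="records")
        return super().default(o)


def json_dump(obj: Any, path: str | Path | None = None, **kwargs) -> str:
    text = json.dumps(obj, cls=_Encoder, indent=2, **kwargs)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_table(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, index=False)


def _require(frame: pd.DataFrame, cols: tuple[str, ...], what: str) -> None:
    missing = set(cols) - set(frame.columns)
    if missing:
        raise ValueError(f"{what}: missing columns {sorted(missing)}")


def read_relaxation_csv(path: str | Path) -> RelaxationSeries:
    """Read a ``delay_s,region,intensity`` table into a RelaxationSeries."""
    frame = read_table(path)
    _require(frame, ("delay_s", "region", "intensity"), "relaxation table")
    pivot = frame.pivot_table(index="delay_s", columns="region", values="intensity")
    pivot = pivot.sort_index()
    return RelaxationSeries(
        delays=pivot.index.to_numpy(),
        intensities={str(c): pivot[c].to_numpy() for c in pivot.columns},
    )


def read_titration_csv(
    path: str | Path, receptor_total: float, assay: str = "MST"
) -> list[TitrationSeries]:
    """Read a ``conc_M,signal[,replicate]`` table into per-replicate series."""
    frame = read_table(path)
    _require(frame, ("conc_M", "signal"), "titration table")
    if "replicate" not in frame.columns:
        frame = frame.assign(replicate=0)
    return [
        TitrationSeries(
            grp["conc_M"].to_numpy(), grp["signal"].to_numpy(),
            receptor_total=receptor_total, assay=assay, replicate=rep,
        )
        for rep, grp in frame.groupby("replicate")
    ]


def read_melting_csv(path: str | Path) -> pd.DataFrame:
    frame = read_table(path)
    _require(frame, ("temp_C", "ratio"), "melting curve")
    return frame.sort_values("temp_C").reset_index(drop=True)


def read_itc_csv(
    path: str | Path,
    cell_conc: float,
    syringe_conc: float,
    cell_volume_ul: float = 950.0,
) -> ITCExperiment:
    """Read an ``injection_ul,heat_uJ`` table (pre-injection first)."""
    frame = read_table(path)
    _require(frame, ("injection_ul", "heat_uJ"), "ITC table")
    return ITCExperiment(
        cell_conc=cell_conc,
        syringe_conc=syringe_conc,
        cell_volume_ul=cell_volume_ul,
        injection_volumes_ul=frame["injection_ul"].to_numpy(),
        heats_uJ=frame["heat_uJ"].to_numpy(),
    )


def read_dose_response_csv(path: str | Path) -> list[DoseResponseSeries]:
    frame = read_table(path)
    _require(frame, ("conc_M", "response"), "dose-response table")
    if "replicate" not in frame.columns:
        frame = frame.assign(replicate=0)
    return [
        DoseResponseSeries(grp["conc_M"].to_numpy(), grp["response"].to_numpy(), rep)
        for rep, grp in frame.groupby("replicate")
    ]


def read_peaks_csv(path: str | Path) -> dict[str, list[MassPeak]]:
    """Read an ``mz,intensity,run`` peak list grouped by run label."""
    frame = read_table(path)
    _require(frame, ("mz", "intensity"), "peak list")
    if "run" not in frame.columns:
        frame = frame.assign(run="library")
    return {
        str(run): [MassPeak(r.mz, r.intensity, str(run)) for r in grp.itertuples()]
        for run, grp in frame.groupby("run")
    }


def library_spec_from_config(cfg: dict) -> LibrarySpec:
    """Build a LibrarySpec from ``{"positions": [...], "cterm": ..., "name": ...}``."""
    known = {"positions", "cterm", "name"}
    unknown = set(cfg) - known
    if unknown:
        raise ValueError(f"unknown library config keys {sorted(unknown)}")
    return LibrarySpec(
        positions=tuple(cfg["positions"]),
        cterm=cfg.get("cterm", "amide"),
        name=cfg.get("name", ""),
    )
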