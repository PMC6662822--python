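"""End-to-end screening pipeline on synthetic presets.

Runs the stages in the order of the experimental workflow — pull-down
enrichment, relaxation-filtered ranking, binding isotherms (MST and nanoDSF),
ternary cross-dependency tests, and dose-response potency — and collects a
single report: ranked peptides, a Kd/dG table, independence verdicts and the
fold-enhancement of the assembled bi-substrate inhibitor.  A stage failure
marks the stage and skips everything downstream instead of raising.
"""

from __future__ import annotations

import logging
from typing import Any

import numpy as np

from . import synthetic_data as synth
from .binding_isotherms import (
    dg_from_kd,
    extract_tm,
    fit_isotherm,
    sigma_dg_from_kd,
    signal_at,
    TitrationSeries,
)
from .dose_response import DoseResponseSeries, fit_ic50, fold_enhancement
from .itc import ITCExperiment, fit_itc
from .peptide_library import enrichment_score, enumerate_library, isobaric_classes, MassPeak
from .relaxation_fit import fit_biexp_global, rank_peptides
from .io import read_relaxation_csv  # noqa: F401  (re-exported for CLI use)

__all__ = ["run_pipeline"]

log = logging.getLogger("thermolead.pipeline")


def _peaks_from_frame(frame) -> list[MassPeak]:
    return [MassPeak(r.mz, r.intensity, r.run) for r in frame.itertuples()]


def _stage_screening(seed: int) -> dict[str, Any]:
    data = synth.generate(synth.preset("peaks/pulldown", seed))
    classes = isobaric_classes(enumerate_library(synth.HEXA_LIBRARY))
    table = enrichment_score(
        _peaks_from_frame(data.tables["library"]),
        _peaks_from_frame(data.tables["eluent"]),
        _peaks_from_frame(data.tables["control"]),
        classes,
    )
    kept = table[~table["excluded"]]
    return {
        "n_classes": len(classes),
        "top_classes": kept.head(3)["members"].tolist(),
        "n_excluded_unspecific": int(table["unspecific"].sum()),
    }


def _stage_nmr(seed: int) -> dict[str, Any]:
    rng = np.random.default_rng(seed)
    fits = {}
    for pep in synth.RELAXATION_RATES:
        data = synth.generate(synth.preset(f"nmr/{pep}", int(rng.integers(2**31))))
        frame = data.table
        pivot = frame.pivot_table(index="delay_s", columns="region", values="intensity")
        from .relaxation_fit import RelaxationSeries

        series = RelaxationSeries(
            pivot.index.to_numpy(),
            {str(c): pivot[c].to_numpy() for c in pivot.columns},
        )
        fits[pep] = fit_biexp_global(series)
    ranking = rank_peptides(fits)
    return {
        "ranking": ranking.reset_index().to_dict(orient="records"),
        "top_peptide": ranking.iloc[0]["peptide"],
    }


def _mst_fit(name: str, seed: int) -> dict[str, Any]:
    data = synth.generate(synth.preset(f"mst/{name}", seed))
    frame = data.table
    series = [
        TitrationSeries(
            g["conc_M"].to_numpy(), g["signal"].to_numpy(),
            receptor_total=data.truth["receptor_M"], assay="MST", replicate=r,
        )
        for r, g in frame.groupby("replicate")
    ]
    fit = fit_isotherm(series)
    return {
        "kd_M": fit.kd,
        "sigma_kd_M": fit.sigma_kd,
        "dg_kJ_mol": dg_from_kd(fit.kd),
        "sigma_dg_kJ_mol": sigma_dg_from_kd(fit.kd, fit.sigma_kd),
        "true_kd_M": data.truth["kd"],
    }


def _stage_binding(seed: int) -> dict[str, Any]:
    rng = np.random.default_rng(seed)
    out: dict[str, Any] = {"mst": {}, "dsf": {}}
    for name in ("KESEEE-NH2", "RRRDDDSDDD", "KESEEE-NH2+TBBt"):
        out["mst"][name] = _mst_fit(name, int(rng.integers(2**31)))
    # nanoDSF: melting-temperature trend and a 25 C signal-slice isotherm
    data = synth.generate(synth.preset("dsf/KESEEE-NH2", int(rng.integers(2**31))))
    concs, signals, tms = [], [], []
    for key, melt in data.tables.items():
        conc = float(key.split("_")[1])
        concs.append(conc)
        tms.append(extract_tm(melt["temp_C"], melt["ratio"]))
        signals.append(signal_at(melt["temp_C"], melt["ratio"], 25.0))
    order = np.argsort(concs)
    concs = np.asarray(concs)[order]
    series = TitrationSeries(
        concs, np.asarray(signals)[order],
        receptor_total=data.truth["receptor_M"], assay="nanoDSF-ratio",
    )
    fit = fit_isotherm(series)
    out["dsf"]["KESEEE-NH2"] = {
        "kd_M": fit.kd,
        "sigma_kd_M": fit.sigma_kd,
        "dg_kJ_mol": dg_from_kd(fit.kd),
        "tm_range_C": [float(min(tms)), float(max(tms))],
        "tm_decreases_with_conc": bool(tms[order[-1]] < tms[order[0]]),
        "true_kd_M": data.truth["kd_native"],
    }
    return out


def _itc_fit(name: str, seed: int) -> dict[str, Any]:
    data = synth.generate(synth.preset(f"itc/{name}", seed))
    exps = []
    for (key, frame), dsg in zip(data.tables.items(), data.truth["designs"]):
        exps.append(
            ITCExperiment(
                cell_conc=dsg["cell_M"],
                syringe_conc=dsg["syringe_M"],
                cell_volume_ul=dsg["cell_volume_ul"],
                injection_volumes_ul=frame["injection_ul"].to_numpy(),
                heats_uJ=frame["heat_uJ"].to_numpy(),
            )
        )
    fit, state = fit_itc(exps)
    return {
        "kd_M": fit.kd,
        "sigma_kd_M": fit.sigma_kd,
        "dh_kJ_mol": fit.dh,
        "n": fit.n,
        "dg_kJ_mol": state.dg,
        "ds_J_mol_K": state.ds,
        "true_kd_M": data.truth["kd"],
    }


def _stage_ternary(seed: int, binding: dict[str, Any]) -> dict[str, Any]:
    from .ternary import test_independence

    rng = np.random.default_rng(seed)
    out: dict[str, Any] = {}
    mst_apo = binding["mst"]["KESEEE-NH2"]
    mst_tern = binding["mst"]["KESEEE-NH2+TBBt"]
    res = test_independence(
        mst_apo["kd_M"], mst_apo["sigma_kd_M"],
        mst_tern["kd_M"], mst_tern["sigma_kd_M"],
    )
    out["peptide_vs_TBBt_complex"] = {
        "method": "MST", "z": res.z, "verdict": res.verdict,
        "coupling_dg_kJ_mol": res.coupling_dg,
    }
    itc_apo = _itc_fit("TBBt", int(rng.integers(2**31)))
    itc_tern = _itc_fit("TBBt+KESEEE-NH2", int(rng.integers(2**31)))
    res2 = test_independence(
        itc_apo["kd_M"], abs(itc_apo["sigma_kd_M"]),
        itc_tern["kd_M"], abs(itc_tern["sigma_kd_M"]),
    )
    out["TBBt_vs_peptide_complex"] = {
        "method": "ITC", "z": res2.z, "verdict": res2.verdict,
        "coupling_dg_kJ_mol": res2.coupling_dg,
    }
    out["itc_fits"] = {"TBBt": itc_apo, "TBBt+KESEEE-NH2": itc_tern}
    return out


def _stage_potency(seed: int) -> dict[str, Any]:
    rng = np.random.default_rng(seed)
    fits = {}
    for name in synth.IC50_TRUTH:
        data = synth.generate(synth.preset(f"ic50/{name}", int(rng.integers(2**31))))
        frame = data.table
        series = [
            DoseResponseSeries(g["conc_M"].to_numpy(), g["response"].to_numpy(), r)
            for r, g in frame.groupby("replicate")
        ]
        fit = fit_ic50(series)
        fits[name] = {
            "ic50_M": fit.ic50, "sigma_ic50_M": fit.sigma_ic50, "hill": fit.hill,
            "true_ic50_M": data.truth["ic50"],
        }
    ratio, sigma = fold_enhancement(
        fits["7-COOH-Br3Bt"]["ic50_M"], fits["bisubstrate"]["ic50_M"],
        abs(fits["7-COOH-Br3Bt"]["sigma_ic50_M"]), abs(fits["bisubstrate"]["sigma_ic50_M"]),
    )
    return {"fits": fits, "fold_enhancement": ratio, "sigma_fold": sigma}


_STAGES = (
    ("screening", lambda seed, rep: _stage_screening(seed)),
    ("nmr_ranking", lambda seed, rep: _stage_nmr(seed)),
    ("binding", lambda seed, rep: _stage_binding(seed)),
    ("ternary", lambda seed, rep: _stage_ternary(seed, rep["binding"])),
    ("potency", lambda seed, rep: _stage_potency(seed)),
)


def run_pipeline(seed: int = 0) -> dict[str, Any]:
    """Execute all stages on the preset scenarios; never raises on stage failure."""
    rng = np.random.default_rng(seed)
    report: dict[str, Any] = {"seed": seed, "stages": []}
    failed = False
    for name, stage in _STAGES:
        stage_seed = int(rng.integers(2**31))
        if failed:
            report["stages"].append({"stage": name, "status": "skipped"})
            continue
        try:
            result = stage(stage_seed, report)
            report[name] = result
            report["stages"].append({"stage": name, "status": "ok"})
            log.info("stage %s done", name)
        except Exception as exc:  # stage isolation is the contract here
            log.error("stage %s failed: %s", name, exc)
            report["stages"].append({"stage": name, "status": "failed", "error": str(exc)})
            failed = True
    return report
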