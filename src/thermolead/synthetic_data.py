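"""Seeded synthetic-data generators emulating every assay in the screening
workflow.

Each generator reproduces the corresponding experimental design — the
18-delay relaxation filter, the 16-point MST pseudo-titration in triplicate,
the 20-80 C nanoDSF ramp, the 4 µl + 12 x 20 µl reverse ITC schedule, and
the 7-concentration inhibition assay in triplicate — and uses the published
fitted parameters (relaxation rates, dissociation constants, enthalpies,
IC50 values) as ground truth, so every pipeline stage can be exercised and
validated end to end without instrument data.

Noise is Gaussian and scaled to each curve's dynamic range; identical
configurations produce identical tables, and changing only the seed changes
the noise realization but never the design.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable

import numpy as np
import pandas as pd

from . import relaxation_fit as rf
from .binding_isotherms import fraction_bound
from .itc import ITCExperiment, simulate_itc
from .dose_response import four_param_logistic
from .peptide_library import (
    LibrarySpec,
    enumerate_library,
    isobaric_classes,
    peptide_mass,
)

__all__ = [
    "ScenarioConfig",
    "GeneratedData",
    "PRESETS",
    "RELAXATION_RATES",
    "NMR_DELAYS_S",
    "NMR_REGIONS",
    "HEXA_LIBRARY",
    "HEPTA_LIBRARIES",
    "preset",
    "generate",
]

# ---------------------------------------------------------------------------
# study conditions: designs and published fitted parameters used as truth

#: relaxation-filter delays, s (18 values, 0-200 ms)
NMR_DELAYS_S = np.array(
    [0, 1, 2, 3, 4, 5, 10, 15, 20, 25, 30, 35, 40, 45, 50, 100, 150, 200]
) / 1000.0

#: representative 1H resonance regions monitored per peptide
NMR_REGIONS = (
    "Glu-Hg 2.3ppm",
    "Asp-Hb 2.8ppm",
    "Ser-Hb 3.8ppm",
    "Thr-CH3 1.1ppm",
    "Lys-He 2.9ppm",
    "amide 8.2-8.9ppm",
)

#: globally fitted (R2f, R2s) in 1/s per peptide, amidated C-terminus
RELAXATION_RATES: dict[str, tuple[float, float]] = {
    "KESEEE-NH2": (31.3, 2.5),
    "EETEEE-NH2": (18.5, 3.1),
    "EESEEE-NH2": (17.5, 2.3),
    "KETEEE-NH2": (15.9, 2.6),
    "EETEED-NH2": (16.1, 2.2),
    "EETDEE-NH2": (15.4, 2.3),
    "DETEEE-NH2": (10.4, 2.2),
    "EDTEEE-NH2": (14.9, 1.5),
    "EETEDE-NH2": (17.2, 3.7),
    "DDTDDD-NH2": (7.1, 1.0),
}

#: MST dissociation constants (M) per titrant/condition
MST_KD: dict[str, float] = {
    "KESEEE-NH2": 0.39e-3,
    "RRRDDDSDDD": 2.1e-3,
    "KESEEE-NH2+TBBt": 0.36e-3,
    "TBBt": 96e-9,
    "TBBt+KESEEE-NH2": 86e-9,
}

#: nanoDSF-derived native-state Kd (M) at 25 C
DSF_KD: dict[str, float] = {
    "KESEEE-NH2": 0.35e-3,
    "EESEEE-NH2": 1.58e-3,
    "KETEEE-NH2": 0.95e-3,
    "EETEEE-NH2": 0.96e-3,
    "KESEEE-NH2+TBBt": 0.45e-3,
}

#: ITC truth (Kd in M, dH in kJ/mol) for the reverse titrations
ITC_TRUTH: dict[str, tuple[float, float]] = {
    "TBBt": (0.06e-6, -25.1),
    "TBBt+KESEEE-NH2": (0.10e-6, -17.7),
}

#: IC50 truth (M) for the inhibition assay
IC50_TRUTH: dict[str, float] = {
    "bisubstrate": 0.67e-6,
    "TBBt": 0.62e-6,
    "7-COOH-Br3Bt": 8.0e-6,
}

#: hexapeptide library from the kinase consensus sequence
HEXA_LIBRARY = LibrarySpec(
    positions=("KGDE", "DE", "ST", "DE", "DE", "DE"), cterm="amide", name="hexa"
)
#: heptapeptide sub-libraries (Ser- and Thr-fixed acceptor position)
HEPTA_LIBRARIES = (
    LibrarySpec(("KGDE", "DE", "S", "DE", "DE", "DE", "DE"), "amide", "hepta-S"),
    LibrarySpec(("KGDE", "DE", "T", "DE", "DE", "DE", "DE"), "amide", "hepta-T"),
)

#: classes enhanced in the eluent run of the synthetic pull-down, keyed by a
#: member sequence, with the eluent enrichment factor (library-normalized)
PULLDOWN_ENRICHED: dict[str, float] = {
    "EETEED": 3.0,  # the 750 Da six-member ensemble
    "KETEEE": 2.5,
    "EETEEE": 2.2,
}
#: a resin-sticky class (enhanced in the no-protein control run)
PULLDOWN_STICKY: dict[str, float] = {"GDTDDD": 4.0}


@dataclass
class ScenarioConfig:
    """Fully specifies one synthetic dataset: assay, truth, design, noise, seed."""

    assay: str  # nmr | mst | dsf | itc | ic50 | peaks
    params: dict[str, Any] = field(default_factory=dict)
    design: dict[str, Any] = field(default_factory=dict)
    noise_sd: float = 0.02
    seed: int = 0
    replicates: int = 1


@dataclass
class GeneratedData:
    """A generated dataset plus the ground-truth record used to produce it."""

    tables: dict[str, pd.DataFrame]
    truth: dict[str, Any]

    @property
    def table(self) -> pd.DataFrame:
        if len(self.tables) != 1:
            raise ValueError("scenario produced multiple tables; access .tables")
        return next(iter(self.tables.values()))


# ---------------------------------------------------------------------------
# per-assay generators


def _gen_nmr(cfg: ScenarioConfig, rng: np.random.Generator) -> GeneratedData:
    r2f = cfg.params["r2f"]
    r2s = cfg.params["r2s"]
    delays = np.asarray(cfg.design.get("delays_s", NMR_DELAYS_S), dtype=float)
    region_names = cfg.design.get("regions", NMR_REGIONS)
    bound_frac = cfg.params.get("bound_fraction", 0.3)
    regions = {}
    for name in region_names:
        scale = rng.uniform(0.5, 1.5)  # region intensities differ
        regions[name] = rf.RegionAmplitudes(
            a1=bound_frac * scale, a2=(1.0 - bound_frac) * scale, y0=0.02 * scale
        )
    truth_params = rf.BiExpParams(r2f=r2f, r2s=r2s, regions=regions)
    series = rf.simulate_decay(
        truth_params, delays, noise_sd=cfg.noise_sd,
        seed=int(rng.integers(2**31)),
    )
    rows = [
        {"delay_s": t, "region": region, "intensity": y[i]}
        for region, y in series.intensities.items()
        for i, t in enumerate(series.delays)
    ]
    return GeneratedData(
        tables={"decay": pd.DataFrame(rows)},
        truth={"r2f": r2f, "r2s": r2s, "regions": {k: vars(v) for k, v in regions.items()}},
    )


def _gen_mst(cfg: ScenarioConfig, rng: np.random.Generator) -> GeneratedData:
    kd = cfg.params["kd"]
    receptor = cfg.design.get("receptor_M", 50e-9)
    conc = np.asarray(
        cfg.design.get("ligand_M", np.logspace(-7, -2, 16)), dtype=float
    )
    s_free = cfg.params.get("s_free", 800.0)
    amplitude = cfg.params.get("amplitude", -60.0)
    jitter_sd = cfg.design.get("baseline_jitter", 0.05) * abs(amplitude)
    rows = []
    for rep in range(cfg.replicates):
        base = s_free + rng.normal(0.0, jitter_sd)
        signal = base + amplitude * fraction_bound(receptor, conc, kd)
        signal = signal + rng.normal(0.0, cfg.noise_sd * abs(amplitude), size=conc.shape)
        rows.append(pd.DataFrame({"conc_M": conc, "signal": signal, "replicate": rep}))
    return GeneratedData(
        tables={"titration": pd.concat(rows, ignore_index=True)},
        truth={
            "kd": kd, "receptor_M": receptor, "s_free": s_free,
            "amplitude": amplitude,
        },
    )


def _dsf_ratio_curve(temps, tm, params):
    """Two-state 350/330 ratio profile with sloping baselines."""
    f_unfolded = 1.0 / (1.0 + np.exp((tm - temps) / params["width"]))
    native = params["native_level"] + params["native_slope"] * (temps - 25.0)
    unfolded = params["unfolded_level"] + params["unfolded_slope"] * (temps - 75.0)
    return native * (1 - f_unfolded) + unfolded * f_unfolded


def _gen_dsf(cfg: ScenarioConfig, rng: np.random.Generator) -> GeneratedData:
    kd_native = cfg.params["kd_native"]
    kd_unfolded = cfg.params.get("kd_unfolded", 1.0e-3)
    tm0 = cfg.params.get("tm0_C", 52.0)
    dtm = cfg.params.get("max_destabilization_C", 8.0)
    receptor = cfg.design.get("receptor_M", 2.5e-6)
    concs = np.asarray(
        cfg.design.get("peptide_M", np.logspace(np.log10(300e-9), -2, 12)),
        dtype=float,
    )
    temps = np.arange(20.0, 80.0 + 1e-9, cfg.design.get("step_C", 0.25))
    shape = {
        "width": 1.5,
        "native_level": 0.80,
        "native_slope": 0.0008,
        "unfolded_level": 0.95,
        "unfolded_slope": 0.0004,
    }
    amp_native = cfg.params.get("native_amplitude", -0.06)
    amp_unfolded = cfg.params.get("unfolded_amplitude", -0.02)
    tables = {}
    tms = {}
    for conc in concs:
        fb_n = fraction_bound(receptor, conc, kd_native)
        fb_u = fraction_bound(receptor, conc, kd_unfolded)
        tm = tm0 - dtm * fb_n  # peptide-concentration-dependent destabilization
        local = dict(shape)
        local["native_level"] += amp_native * fb_n
        local["unfolded_level"] += amp_unfolded * fb_u
        ratio = _dsf_ratio_curve(temps, tm, local)
        if cfg.noise_sd > 0:
            span = float(ratio.max() - ratio.min())
            ratio = ratio + rng.normal(0.0, cfg.noise_sd * span, size=ratio.shape)
        key = f"{conc:.4e}"
        tables[f"melt_{key}"] = pd.DataFrame({"temp_C": temps, "ratio": ratio})
        tms[key] = float(tm)
    return GeneratedData(
        tables=tables,
        truth={
            "kd_native": kd_native, "kd_unfolded": kd_unfolded, "tm0_C": tm0,
            "tm_by_conc": tms, "receptor_M": receptor,
            "native_amplitude": amp_native, "unfolded_amplitude": amp_unfolded,
        },
    )


def _gen_itc(cfg: ScenarioConfig, rng: np.random.Generator) -> GeneratedData:
    kd, dh = cfg.params["kd"], cfg.params["dh"]
    n = cfg.params.get("n", 1.0)
    tables = {}
    designs = []
    for rep in range(cfg.replicates):
        design = ITCExperiment(
            cell_conc=cfg.design.get("cell_M", 5e-6) * (1.0 + 0.2 * rep),
            syringe_conc=cfg.design.get("syringe_M", 40e-6) * (1.0 + 0.2 * rep),
            cell_volume_ul=cfg.design.get("cell_volume_ul", 950.0),
            injection_volumes_ul=cfg.design.get(
                "injection_volumes_ul", [4.0] + [20.0] * 12
            ),
        )
        sim = simulate_itc(
            kd, dh, n, design, noise_sd=cfg.noise_sd, seed=int(rng.integers(2**31))
        )
        designs.append(sim)
        tables[f"run{rep}"] = pd.DataFrame(
            {
                "injection_ul": sim.injection_volumes_ul,
                "heat_uJ": sim.heats_uJ,
            }
        )
    return GeneratedData(
        tables=tables,
        truth={
            "kd": kd, "dh": dh, "n": n,
            "designs": [
                {"cell_M": d.cell_conc, "syringe_M": d.syringe_conc,
                 "cell_volume_ul": d.cell_volume_ul}
                for d in designs
            ],
        },
    )


def _gen_ic50(cfg: ScenarioConfig, rng: np.random.Generator) -> GeneratedData:
    ic50 = cfg.params["ic50"]
    hill = cfg.params.get("hill", 1.0)
    top = cfg.params.get("top", 100.0)
    bottom = cfg.params.get("bottom", 5.0)
    conc = np.asarray(cfg.design.get("conc_M", np.logspace(-9, -3, 7)), dtype=float)
    rows = []
    for rep in range(cfg.replicates):
        resp = four_param_logistic(conc, ic50, hill, top, bottom)
        resp = resp + rng.normal(0.0, cfg.noise_sd * (top - bottom), size=conc.shape)
        rows.append(pd.DataFrame({"conc_M": conc, "response": resp, "replicate": rep}))
    return GeneratedData(
        tables={"dose_response": pd.concat(rows, ignore_index=True)},
        truth={"ic50": ic50, "hill": hill, "top": top, "bottom": bottom},
    )


def _gen_peaks(cfg: ScenarioConfig, rng: np.random.Generator) -> GeneratedData:
    spec = cfg.params.get("library", HEXA_LIBRARY)
    enriched = cfg.params.get("enriched", PULLDOWN_ENRICHED)
    sticky = cfg.params.get("sticky", PULLDOWN_STICKY)
    classes = isobaric_classes(enumerate_library(spec))
    seq_to_class = {p.sequence: i for i, c in enumerate(classes) for p in c.members}
    base = rng.uniform(0.8, 1.2, size=len(classes)) * np.array([c.size for c in classes])
    mz_err = cfg.design.get("mz_error_da", 0.05)

    def run_table(factors: dict[str, float], run: str) -> pd.DataFrame:
        weights = base.copy()
        for seq, factor in factors.items():
            if seq in seq_to_class:
                weights[seq_to_class[seq]] *= factor
        intens = weights * (1.0 + rng.normal(0.0, cfg.noise_sd, size=weights.shape))
        mz = np.array(
            [peptide_mass(c.members[0], adduct="protonated") for c in classes]
        )
        if cfg.noise_sd > 0:
            mz = mz + rng.normal(0.0, mz_err, size=len(classes))
        return pd.DataFrame(
            {"mz": mz, "intensity": np.maximum(intens, 0.0), "run": run}
        )

    tables = {
        "library": run_table({}, "library"),
        "eluent": run_table(enriched, "eluent"),
        "control": run_table(sticky, "control"),
    }
    return GeneratedData(
        tables=tables,
        truth={
            "library": spec.name,
            "enriched": dict(enriched),
            "sticky": dict(sticky),
            "n_classes": len(classes),
        },
    )


_GENERATORS: dict[str, Callable[[ScenarioConfig, np.random.Generator], GeneratedData]] = {
    "nmr": _gen_nmr,
    "mst": _gen_mst,
    "dsf": _gen_dsf,
    "itc": _gen_itc,
    "ic50": _gen_ic50,
    "peaks": _gen_peaks,
}


def generate(config: ScenarioConfig) -> GeneratedData:
    """Produce the raw tables and truth record for one scenario."""
    if config.assay not in _GENERATORS:
        raise ValueError(
            f"unknown assay {config.assay!r}; choose from {sorted(_GENERATORS)}"
        )
    if config.noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(config.seed)
    return _GENERATORS[config.assay](config, rng)


# ---------------------------------------------------------------------------
# named presets: the published parameter sets as ground truth


def _preset_factories() -> dict[str, Callable[[int], ScenarioConfig]]:
    out: dict[str, Callable[[int], ScenarioConfig]] = {}
    for pep, (r2f, r2s) in RELAXATION_RATES.items():
        out[f"nmr/{pep}"] = (
            lambda seed, r2f=r2f, r2s=r2s: ScenarioConfig(
                "nmr", {"r2f": r2f, "r2s": r2s}, noise_sd=0.02, seed=seed
            )
        )
    for name, kd in MST_KD.items():
        out[f"mst/{name}"] = (
            lambda seed, kd=kd: ScenarioConfig(
                "mst", {"kd": kd}, noise_sd=0.03, seed=seed, replicates=3
            )
        )
    for name, kd in DSF_KD.items():
        out[f"dsf/{name}"] = (
            lambda seed, kd=kd: ScenarioConfig(
                "dsf", {"kd_native": kd}, noise_sd=0.005, seed=seed
            )
        )
    for name, (kd, dh) in ITC_TRUTH.items():
        # noise calibrated so the fitted Kd uncertainty matches the reported
        # error scale (roughly half the Kd) at this high-c titration design
        out[f"itc/{name}"] = (
            lambda seed, kd=kd, dh=dh: ScenarioConfig(
                "itc", {"kd": kd, "dh": dh, "n": 1.0}, noise_sd=0.08,
                seed=seed, replicates=2,
            )
        )
    for name, ic50 in IC50_TRUTH.items():
        out[f"ic50/{name}"] = (
            lambda seed, ic50=ic50: ScenarioConfig(
                "ic50", {"ic50": ic50}, noise_sd=0.05, seed=seed, replicates=3
            )
        )
    out["peaks/pulldown"] = lambda seed: ScenarioConfig(
        "peaks", noise_sd=0.05, seed=seed
    )
    return out


PRESETS: dict[str, Callable[[int], ScenarioConfig]] = _preset_factories()


def preset(name: str, seed: int = 0) -> ScenarioConfig:
    """Look up a named scenario with the published parameters as truth."""
    try:
        return PRESETS[name](seed)
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}") from None
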