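"""End-to-end pipeline: simulate -> trace analysis -> Hill fits -> Woodhull.

Subtype presets encode the study conditions for each receptor variant:
blocking-site depth (fractional electrical distance), zero-voltage IC50,
1- vs 2-site stoichiometry and the direction of rectification.  The
pipeline generates a synthetic cohort from a preset (or explicit truth
parameters), applies the quality filter, measures fraction-remaining from
every ramp pair, fits per-voltage Hill curves, regresses the Woodhull
relation per cell and aggregates delta across cells, writing tidy CSV/JSON
summaries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import DEFAULT_TEMPERATURE
from .kinetics import (BlockParams, GatingParams, Rectification, KineticScheme,
                       build_block_scheme)
from .synth import (RecordingConfig, SyntheticCohort, generate_cohort,
                    DEFAULT_VOLTAGE_GRID)
from .traces import (ramp_fraction_remaining, average_fraction_curves,
                     quality_filter)
from .hillfit import ic50_voltage_table, infer_stoichiometry
from .woodhull import fit_woodhull, aggregate_delta

__all__ = ["SubtypePreset", "PRESETS", "RunConfig", "run_pipeline",
           "cohort_dose_table", "recover_delta"]


@dataclass(frozen=True)
class SubtypePreset:
    """Ground-truth generator settings for one receptor variant."""

    name: str
    n_sites: int
    delta: float
    ic50_0_uM: float          # apparent zero-voltage IC50 of the one-site fit
    rectification: str        # 'outward' | 'inward' | 'none'
    glycine_uM: float = 30.0
    ec50_gate_uM: float = 40.0
    desensitization_rate: float = 0.0
    cooperativity: float = 1.0

    def block_params(self) -> BlockParams:
        return BlockParams(n_sites=self.n_sites, kd0=self.ic50_0_uM,
                           delta=self.delta, cooperativity=self.cooperativity)

    def gating_params(self, open_saturated: bool = False) -> GatingParams:
        rect = None
        if self.rectification != "none":
            rect = Rectification(direction=self.rectification)
        closing = 1e-4 if open_saturated else 50.0
        return GatingParams(opening_rate0=300.0, closing_rate=closing,
                            ec50_gate=self.ec50_gate_uM,
                            rectification=rect,
                            desensitization_rate=self.desensitization_rate)

    def scheme(self, T: float = DEFAULT_TEMPERATURE,
               open_saturated: bool = False) -> KineticScheme:
        return build_block_scheme(self.n_sites, self.gating_params(open_saturated),
                                  self.block_params(), T=T)


# Depths and zero-voltage IC50s follow the per-subtype summary tables at
# 30 uM glycine; alpha1 is the two-site variant (nH ~ 1.5), alpha2 and the
# alpha3-like preset single-site.  The G254A pore mutant sits between the
# wild types in both depth and potency.
PRESETS: dict[str, SubtypePreset] = {
    "alpha1": SubtypePreset("alpha1", n_sites=2, delta=0.16, ic50_0_uM=280.0,
                            rectification="outward", cooperativity=25.0),
    "alpha2": SubtypePreset("alpha2", n_sites=1, delta=0.65, ic50_0_uM=40.0,
                            rectification="inward"),
    "alpha3": SubtypePreset("alpha3", n_sites=1, delta=0.60, ic50_0_uM=40.0,
                            rectification="outward", glycine_uM=100.0,
                            ec50_gate_uM=100.0, desensitization_rate=1.0),
    "g254a": SubtypePreset("g254a", n_sites=1, delta=0.37, ic50_0_uM=120.0,
                           rectification="outward", ec50_gate_uM=34.0),
    "heteromer": SubtypePreset("heteromer", n_sites=2, delta=0.16, ic50_0_uM=300.0,
                               rectification="outward", cooperativity=25.0),
}


@dataclass
class RunConfig:
    """Parameters of one pipeline run (seed, preset, cohort size, output)."""

    preset: str = "alpha2"
    n_cells: int = 8
    conc_grid_uM: tuple = (3.0, 10.0, 30.0, 100.0, 300.0, 1000.0)
    voltages_mV: tuple = DEFAULT_VOLTAGE_GRID
    seed: int = 1
    noise_cv: float = 0.05
    noise_sd_pA: float = 2.0
    temperature_K: float = DEFAULT_TEMPERATURE
    out_dir: str | None = None
    include_long: bool = False

    def recording_config(self) -> RecordingConfig:
        return RecordingConfig(noise_sd=self.noise_sd_pA, noise_cv=self.noise_cv,
                               seed=self.seed)


def cohort_dose_table(cohort: SyntheticCohort,
                      vgrid=None, apply_quality: bool = True) -> pd.DataFrame:
    """Tidy (cell, V, conc, fraction) table from every ramp pair of a cohort.

    Up- and down-ramp fraction-remaining curves of the same pair are
    averaged; cells failing the quality filter are dropped.
    """
    if vgrid is None:
        vgrid = cohort.voltages
    rows = []
    for cell in cohort.cells:
        if apply_quality:
            keep, _ = quality_filter({"rin_mohm": cell.rin_mohm,
                                      "run_down": cell.run_down})
            if not keep:
                continue
        by_conc: dict[float, list] = {}
        for sweep in cell.ramp_sweeps:
            curve = ramp_fraction_remaining(sweep["control"], sweep["drug"],
                                            vgrid=vgrid)
            by_conc.setdefault(sweep["conc"], []).append(curve)
        for conc, curves in by_conc.items():
            avg = average_fraction_curves(curves)
            for v, f in zip(avg.voltage_mV, avg.fraction):
                rows.append({"cell": cell.cell_id, "voltage_mV": v,
                             "nfa_uM": conc, "fraction": f})
    if not rows:
        raise ValueError("no usable cells after quality filtering")
    return pd.DataFrame(rows)


def recover_delta(cohort: SyntheticCohort, T: float = DEFAULT_TEMPERATURE,
                  vgrid=None) -> dict:
    """Full recovery chain: ramp pairs -> per-voltage Hill fits per cell ->
    per-cell Woodhull regression -> mean +/- SEM of delta across cells."""
    table = cohort_dose_table(cohort, vgrid=vgrid)
    fits = ic50_voltage_table(table, vgrid=vgrid or cohort.voltages)
    per_cell_delta = {}
    per_cell_ic50_0 = {}
    for cell, g in fits[fits["cell"] != "pooled"].groupby("cell"):
        g = g[g["converged"]]
        if len(g) < 2:
            continue
        fit = fit_woodhull(list(zip(g["voltage_mV"], g["ic50_uM"])), T=T)
        per_cell_delta[cell] = fit.delta
        per_cell_ic50_0[cell] = fit.ic50_0_uM
    agg = aggregate_delta(list(per_cell_delta.values()))
    pooled_g = fits[(fits["cell"] == "pooled") & fits["converged"]]
    pooled = fit_woodhull(list(zip(pooled_g["voltage_mV"], pooled_g["ic50_uM"])),
                          T=T, pooled=True)
    nh_means = fits[fits["cell"] != "pooled"].groupby("voltage_mV")["nh"].mean()
    stoich = infer_stoichiometry(nh_means.to_numpy())
    return {"delta_mean": agg["mean"], "delta_sem": agg["sem"], "n_cells": agg["n"],
            "per_cell_delta": per_cell_delta, "per_cell_ic50_0": per_cell_ic50_0,
            "pooled_delta": pooled.delta, "pooled_ic50_0": pooled.ic50_0_uM,
            "nh_by_voltage": {float(v): float(x) for v, x in nh_means.items()},
            "stoichiometry": stoich, "fits": fits}


def run_pipeline(config: RunConfig) -> dict:
    """Execute simulate -> analyze -> fit -> aggregate, optionally writing
    a summary JSON plus Woodhull/Hill tables under ``config.out_dir``."""
    if config.preset not in PRESETS:
        raise ValueError(f"unknown preset {config.preset!r}; "
                         f"available: {sorted(PRESETS)}")
    if config.out_dir is not None:
        out = Path(config.out_dir)
        if not out.parent.exists():
            raise FileNotFoundError(f"output location {out.parent} does not exist")
    preset = PRESETS[config.preset]
    scheme = preset.scheme(T=config.temperature_K)
    cohort = generate_cohort(config.n_cells, scheme, config.conc_grid_uM,
                             config.recording_config(),
                             voltages=config.voltages_mV,
                             glycine_uM=preset.glycine_uM,
                             include_long=config.include_long)
    rec = recover_delta(cohort, T=config.temperature_K)
    fits = rec.pop("fits")
    summary = {
        "preset": preset.name,
        "truth": {"delta": preset.delta, "ic50_0_uM": preset.ic50_0_uM,
                  "n_sites": preset.n_sites},
        "config": {k: v for k, v in asdict(config).items() if k != "out_dir"},
        "recovered": rec,
    }
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        fits.to_csv(out / f"hill_fits_{preset.name}.csv", index=False)
        woodhull_rows = pd.DataFrame(
            [{"subtype": preset.name, "glycine_uM": preset.glycine_uM,
              "delta_mean": rec["delta_mean"], "delta_sem": rec["delta_sem"],
              "n": rec["n_cells"]}])
        woodhull_rows.to_csv(out / f"woodhull_{preset.name}.csv", index=False)
        (out / f"summary_{preset.name}.json").write_text(
            json.dumps(summary, indent=1, sort_keys=True, default=str))
        (out / f"manifest_{preset.name}.json").write_text(cohort.manifest())
    return summary
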