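"""Generate synthetic whole-cell cohorts for the three receptor variants.

Writes one cohort manifest per subtype preset (alpha1, alpha2, G254A-alpha1)
plus a few example ramp sweeps as CSV traces under results/cohorts/.  The
ground truth (blocking-site depth delta, zero-voltage IC50, stoichiometry)
is stored alongside the data so downstream scripts can compare recovered
against generating values.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "cohorts"

from glyrblock import PRESETS, RunConfig, generate_cohort
from glyrblock.io import write_trace

SEED = 1


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    for name in ("alpha1", "alpha2", "g254a"):
        preset = PRESETS[name]
        cfg = RunConfig(preset=name, n_cells=8, seed=SEED)
        cohort = generate_cohort(cfg.n_cells, preset.scheme(), cfg.conc_grid_uM,
                                 cfg.recording_config(), voltages=cfg.voltages_mV,
                                 glycine_uM=preset.glycine_uM)
        (OUT / f"{name}_manifest.json").write_text(cohort.manifest())
        # a representative ramp pair from the first cell, decimated 20x so
        # the stored example stays small (full-rate data regenerate from the
        # manifest seed)
        sweep = cohort.cells[0].ramp_sweeps[2]
        for tag in ("control", "drug"):
            tr = sweep[tag]
            thin = type(tr)(time_s=tr.time_s[::20], current_pA=tr.current_pA[::20],
                            voltage_mV=tr.voltage_mV[::20], meta=dict(tr.meta))
            write_trace(thin, OUT / f"{name}_example_{tag}.csv")
        print(f"{name}: {len(cohort.cells)} cells, truth delta={preset.delta}, "
              f"IC50(0)={preset.ic50_0_uM} uM, {preset.n_sites} site(s)")
    print(f"wrote manifests and example sweeps to {OUT}")


if __name__ == "__main__":
    main()
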