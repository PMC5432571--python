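# glyrblock

Voltage-dependent open-channel block of glycine receptor (GlyR) channels,
end to end: a tested implementation of the analysis chain used to localize
a charged pore blocker — niflumic acid (NFA), an anionic fenamate — inside
the pore of α1, α2 and mutant GlyRs, together with a constrained
Monte-Carlo docking layer that rationalizes the electrophysiology
structurally.

## Who this is for

Ion-channel electrophysiologists and modellers who want a reproducible
reference implementation of the classic blocker-localization workflow:
dose-inhibition Hill fits, Woodhull voltage-dependence analysis,
single-channel flicker-burst quantification, and pore-docking energy
profiles — plus a synthetic patch-clamp data generator with exact ground
truth for validating every stage.

## The model

A blocker that enters the open pore and binds at a site that senses a
fraction δ of the transmembrane field has a voltage-dependent dissociation
constant (Woodhull model; V = inside − outside):

    IC50(V) = IC50(0) · exp(−δ·F·V / R·T)

so a regression of ln IC50 on V yields δ, the *fractional electrical
distance* of the binding site from the external membrane surface.
Dose-inhibition curves at each potential are fitted with the Hill
equation

    I = Imax / (1 + ([B]/IC50)^nH),

whose coefficient nH reports apparent stoichiometry (nH near 2 → two
blocking molecules; near 1 → one).  The generator realizes these
equations mechanistically as a continuous-time Markov scheme
C ⇌ O ⇌ OB (⇌ OB2) with agonist-dependent opening, Woodhull-factored
blocking rates, rectification, desensitization, cell-to-cell amplitude
scatter and recording noise — so every analysis stage can be checked
against an analytic equilibrium oracle.

The structural layer builds the anionic NFA conformer from internal
coordinates (planar, intramolecular N–H···O hydrogen bond, 2-fold
aryl-carboxylate torsion with a 3 kcal/mol barrier and minima at ±90°)
and an idealized pentamer of pore-lining TM2 helices with the canonical
prime-level rings (−2′ Pro, 0′ Arg, 2′ Gly/Ala, 6′ Thr, 9′ Leu, 13′ Thr …
20′).  The ligand is pulled along the pore axis in 0.5 Å steps under
plane / flat-bottom radial / Cα-pin restraints, Monte-Carlo
energy-minimizing at each level until 100 consecutive minimizations fail
to improve the best energy.

## Worked example

```python
from glyrblock import RunConfig, run_pipeline

summary = run_pipeline(RunConfig(preset="alpha2", n_cells=8, seed=1))
r = summary["recovered"]
print(f"delta = {r['delta_mean']:.3f} +/- {r['delta_sem']:.3f} "
      f"(truth {summary['truth']['delta']})")
print(f"mean nH = {r['stoichiometry']['mean_nh']:.2f} -> "
      f"{r['stoichiometry']['n_sites']} site(s)")
```

prints

```
delta = 0.651 +/- 0.000 (truth 0.65)
mean nH = 0.99 -> 1 site(s)
```

i.e. an 8-cell synthetic α2-like cohort (one-site block generated with
δ = 0.65, 5 % amplitude noise) analyzed blind through ramp-pair fraction
remaining → per-voltage Hill fits → per-cell Woodhull regression →
aggregation recovers the generating depth to three decimals, and the unit
Hill coefficient correctly reports single-molecule block.  The α1-like
preset (two cooperating sites, shallow δ = 0.16) instead returns
mean nH ≈ 1.7 → 2 sites.

The numbered scripts under `analysis/` run the full study: cohort
generation (01), per-voltage IC50/nH tables (02), the Woodhull δ summary
(03), single-channel flicker-block quantification (04), and the
α1-vs-α2 pore energy profiles with two-ligand docking (05).  Each writes
tidy CSV/TSV/JSON under `results/`.

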