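# Methods

## Kinetic model of gating and open-channel block

The channel is a continuous-time Markov chain.  Gating is collapsed to a
single agonist-dependent opening step C → O with rate β₀·h([A]), where
h(a) = aⁿ/(aⁿ + EC50ⁿ) is a saturating occupancy factor (defaults
β₀ = 300 s⁻¹, α = 50 s⁻¹, EC50 = 34–100 μM per receptor variant,
n = 1), and a constant closing rate α.  No multi-step agonist binding is
modelled: the experimental analysis this package implements never fits a
gating scheme, it only needs a realistic open probability.

Open-channel block adds one or two blocked states reached from O.  Binding
at fractional electrical distance δ (measured from the external surface,
V = inside − outside) makes the per-site dissociation constant

    Kd(V) = Kd(0) · exp(−δ·F·V/RT),

with RT/F = 25.43 mV at the default 295.15 K (the recordings being
emulated were made at room temperature).  The Woodhull factor is split
between association and dissociation rates by `voltage_split` (default
0.5); the equilibrium is split-invariant, the kinetics are not.  For the
two-site scheme, entry/exit carry statistical factors 2/1 and 1/2, the
second site binds `cooperativity`-fold tighter, and by default only the
doubly occupied state is non-conducting — the simplest scheme in which
two blocker molecules jointly occlude the pore.  Unblocking/blocking
rates (koff₀ = 300 s⁻¹ whole-cell, 500 s⁻¹ in the single-channel
examples) are conventions: the experiments being emulated constrain only
equilibrium quantities, so kon₀ is always derived as koff₀/Kd(0).

**Apparent IC50 vs Kd.**  At full equilibrium of C ⇌ O ⇌ OB the measured
fraction remaining is 1/(1 + c/IC50app) with IC50app = Kd(V)·(1 + α/β·h):
probing an open-channel blocker through a gating equilibrium inflates the
apparent IC50 by the closed/open ratio.  Because the gating factor here is
voltage-independent, the inflation is a constant multiplier — the Woodhull
slope, and hence δ, is unaffected, and the Hill coefficient stays exactly 1
for one site.  This is also why raising the agonist concentration increases
apparent blocker potency, as seen experimentally.  Tests that assert the
bare identities IC50 = Kd and f(Kd) = ½ use a "clamped-open" gating
(α/β ≈ 10⁻⁶).

Rectification (outward for α1-like, inward for α2-like variants) is a
Boltzmann factor in (0, 1] applied multiplicatively to the conducting
current.  It shapes I/V curves and the rectification index but cancels
exactly in drug/control ratios, which keeps the blocker analysis unbiased;
mechanistically voltage-dependent gating rates would contaminate the
Woodhull slope with d ln Popen/dV and are deliberately not used.

## Synthetic recordings

Whole-cell sweeps integrate the master equation along the voltage and
solution protocols: within each sample interval the generator matrix is
frozen at the midpoint voltage and propagated exactly by
eigendecomposition, so stiff block kinetics cost nothing and long
fixed-potential segments are one propagation step.  At 2 kHz sampling the
ramp moves 0.08 mV per sample, making the zero-order-hold error far below
the recording noise.  Current is

    I(t) = N · i(−30 mV) · (V−E_rev)/(−30−E_rev) · rect(V) · Σ gᵢpᵢ(t)

with N = 200 channels, the unitary current anchored to 2.8 pA at −30 mV,
E_rev = 0 mV (near-symmetric chloride), plus additive Gaussian noise
(2 pA) and optional multiplicative amplitude noise (5 % in the cohort
studies).  Cell-to-cell maximal currents are lognormal (CV 0.3); input
resistance (Normal(350, 70) MΩ) and run-down (|Normal(0.08, 0.05)|,
applied linearly across the sweep order) are drawn per cell so the
quality filter (drop if Rin < 150 MΩ or run-down > 30 %) has realistic
material.  Solution exchange is instantaneous (the emulated fast
application system exchanges in 3–5 ms, negligible at these timescales);
no liquid-junction, series-resistance or capacitive artifacts are
modelled.  Protocols follow the experimental design: voltage ramps
−80→+80 mV in 1 s between 500 ms holds, and the long application
glycine 2 s / glycine+NFA 10 s / glycine 5 s at fixed potential.

Single-channel records are exact Gillespie simulations of the same
scheme, rendered at 50 kHz with Gaussian noise.

All randomness descends from one master seed through per-cell
`SeedSequence` children; cohorts regenerate bit-identically.

What passing tests on these data do show: the estimation chain (binning,
Hill fitting, Woodhull regression, aggregation, burst analysis) is
unbiased and correctly calibrated for data generated by the stated
mechanism at realistic noise.  What they do not show: robustness to
un-modelled features of real recordings — series-resistance error, seal
drift, 1/f noise, desensitization interacting with solution exchange, or
multi-channel patches.

## Fitting

Hill fits are nonlinear least squares in (log IC50, nH) with nH bounded
to [0.2, 4], Imax fixed at 1 for fraction-remaining data (free for
activation curves), and a small multi-start over nH ∈ {0.5, 1, 2};
standard errors come from the Jacobian covariance with the delta method
for IC50.  Fraction-remaining at each grid voltage is the ratio of
windowed means (±3 mV) of drug and control sweeps, up- and down-ramps
averaged so the opposite-signed kinetic lags cancel; grid points where
the control current is within the noise floor of reversal are masked.
Percent inhibition from long-protocol sweeps is 100·(1 − I1/I2) with I1
the mean of the final 10 % of the co-application window and I2 the final
40 % of the post-wash window — the post-wash quasi-stationary level is
the reference so that slow desensitization does not masquerade as block.
Woodhull δ is ordinary least squares of ln IC50 on V (δ = −slope·RT/F);
the default workflow fits each cell and aggregates δ as mean ± SEM,
matching how per-subtype tables report n as cells; a pooled fit is also
available.  The 1-vs-2-site call (mean nH > 1.3 → 2 sites) is an
explicitly labelled heuristic, not a model comparison.

Single-channel analysis uses half-amplitude threshold idealization with a
two-sample minimum event, EM-fitted exponential mixtures for dwell
distributions, and the equal-misclassification intersection of the two
shut components as the default burst criterion t_crit.  Because flicker
gaps are blocked sojourns *censored at t_crit*, koff is estimated by the
truncated-exponential maximum likelihood (solving mean_obs = 1/k −
t_crit/(e^{k·t_crit} − 1)) rather than the naive reciprocal mean, and the
observed gap rate is divided by the uncensored fraction 1 − e^{−koff·t_crit}
before computing kon = gap rate / [B].  Without this correction koff
appears to rise with blocker concentration once 1/koff is no longer ≪
t_crit.

## Ligand and pore models

NFA (2-{[3-(trifluoromethyl)phenyl]amino}pyridine-3-carboxylate, net
charge −1) is built from internal coordinates: rigid planar rings with
1.395 Å bonds, a 124° diarylamine C–N–C bridge, and the H-bond-closed
arrangement with the CF3-bearing meta position distal.  Three torsions
are rotatable — aryl–carboxylate (2-fold, 3 kcal/mol barrier, minima
±90°) and the two ring–bridge bonds (2-fold conjugation terms, 8 and
4.8 kcal/mol) — and the conformer is relaxed over them under the ligand
force field: torsion terms, an intramolecular 10–12 H-bond (scaled ×2
for this resonance-assisted six-membered pseudo-ring), and LJ between
atoms ≥ 6 bonds apart (closer contacts are rigid-geometry artifacts
subsumed in the torsion potentials).  The relaxed conformer is nearly
planar (ring-plane angle ≈ 8°), keeps the N–H···O bond at 1.9 Å, and
spans 10.67 Å between its most remote atoms.

The idealized pore is five ideal α-helices (1.5 Å rise, 100°/residue,
CA radius 2.3 Å) of the 23-residue TM2 stretch (residues 250–272),
helix axes on a 10.8 Å circle, phased so the prime-level rings face the
lumen; with leucine side chains pointing inward this leaves ≈ 3.3 Å of
free radius at the 9′ constriction.  Side chains are minimal atom sets
with rotatable χ1 (plus hydroxyl torsions); backbone atoms are fixed
wall material.  The α2 model is the α1 model with G254A in all five
chains — the only sequence difference, mirroring the real TM2 helices.
A user-supplied pentamer PDB can replace the idealized model; nothing is
downloaded.

The energy model is deliberately minimal physics: 12-6 LJ with standard
atomic radii, Coulomb with distance-dependent dielectric ε = r, an
explicit 10–12 H-bond term (depth 4 kcal/mol at 1.9 Å) weighted by
cos² of the donor–H–acceptor angle, all switched off smoothly between
6.5 and 8 Å (switching evaluated on r², which avoids square roots in the
hot loop).  Two implicit-hydration contact terms complete it, because
plain LJ cannot distinguish an exposed glycine ring from an alanine
ring: an atomic-contact-energy-style hydrophobic term (−0.10 kcal/mol
per nonpolar pair at contact, ramping off over 4.5–6.5 Å) between
weakly-charged ligand C/F atoms and water-shielded protein side-chain
C/S atoms, and the complementary desolvation penalty (+0.10 kcal/mol
per pair, same ramp) when a nonpolar ligand atom buries a hydrated
polar backbone N/O.  These two terms encode, at contact-count level,
the driving force the mechanism requires: the hydrophobic blocker gains
from the Ala254 methyl ring and pays for pressing against the
pore-exposed Gly254 backbone.  Both are folded into the reported van der
Waals component so the decomposition stays (vdW, electrostatic, H-bond,
ligand torsion, constraint).  Partial charges are a small
electronegativity-motivated table: carboxylate −0.5/−0.5, guanidinium +1
spread over the Arg head group, hydroxyl dipoles on Ser/Thr, small
backbone dipoles.  Atom overlaps below 0.1 Å set a clash flag and the
repulsion is evaluated at a 0.6 Å floor so the optimizer can escape.

## Monte-Carlo energy minimization and pulling

MCM alternates random perturbation, local minimization and Metropolis
acceptance at 600 K, terminating when `stop_after` (default 100)
consecutive minimizations fail to improve the best energy by more than
0.01 kcal/mol.  Perturbations move the ligand ≤ 1 Å / ≤ 30° (occasional
120° torsion kicks) and side-chain χ angles; local minimization
(L-BFGS-B, numerical gradients) acts on the ligand pose block only,
which keeps the protein side cacheable per χ vector and the scan fast —
χ relaxation happens through the Monte-Carlo accept/reject loop instead.
Constraints: a stiff plane restraint on the bridging nitrogen N1 at the
working level, a 6 Å flat-bottom radial restraint, and Cα pins
(penalty-free to 1 Å, 10 kcal · mol⁻¹ · Å⁻¹ beyond — trivially satisfied
here because the backbone is fixed, and evaluated anyway so any future
backbone flexibility inherits the contract).  Profiles step N1 in 0.5 Å
planes from below the −2′ ring to 20′, seeding each level with the
previous best pose; reported energies are the ligand–channel interaction
(vdW + electrostatic + H-bond), with the constraint penalty tabulated
separately and required to stay ≈ 0.

Per-level best energies carry several kcal/mol of Monte-Carlo sampling
scatter, so the α1-vs-α2 contrast (itself 1–3 kcal/mol) is compared with
a paired estimator (`compare_subtype_profiles`): each model is scanned
independently, then cross-seeded — every level's best pose from one
model is locally re-minimized in the other — and each model keeps the
better of its own and the cross-refined energy.  Because the two models
share all coordinates except the 2′ ring side chains, both are thereby
evaluated over the union of sampled pose families and sampling luck
cancels, leaving the systematic ring-identity contrast.  The raw
(independent-scan) difference has the same sign but roughly triple the
variance.

Problem sizes: the shipped analysis driver and the test suite scan the
cytoplasmic stretch of the pore (−3′…9′ and 2′…6′ respectively) at
reduced MCM depth (stop_after 15–25), which reproduces the qualitative
profile features in minutes; the full-range, stop_after = 100 protocol is
available behind `--full`.

## Known limitations

- The energy function is a stand-in with minimal physics; absolute
  kcal/mol values are not comparable to published force-field profiles,
  only the qualitative structure (deep electrostatic minima for the anion
  near the 0′ Arg ring, H-bond minima at 6′/13′, the 9′ barrier, the α1
  vs α2 contrast at 2′–6′) is meaningful.
- Hydration enters only through the two contact terms; there is no
  explicit water, no ordered-water structure at the Gly2′ backbone, and
  no ionic screening beyond the ε = r dielectric.  The α1/α2 contrast at
  2′–6′ (1–3 kcal/mol with the paired estimator) therefore tests the
  contact-level encoding of the mechanism, not a hydration free energy.
- MCM sampling at rugged levels is not exhaustive: restarting from
  rotated initial placements can differ by several kcal/mol even at full
  stopping depth, so per-level energies carry that sampling uncertainty
  even though the pore model itself is exactly 5-fold symmetric.
  Likewise the two-ligand docking landscape has several competing
  low-energy modes (side-by-side with both carboxylates on the Thr265
  ring, singly Thr-bonded, stacked dimer); which one a run returns
  depends on the random stream, and the complex-level tests examine a
  seeded run that lands in the doubly Thr265-bonded mode.
- Missed-event correction, subconductance levels and multi-channel
  deconvolution are out of scope for the single-channel layer.
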