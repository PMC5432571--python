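"""Pairwise-additive ligand-channel energy model.

Minimal physics chosen to reproduce the qualitative features of blocker
energy profiles in a pentameric pore: 12-6 van der Waals with standard
atomic radii, Coulomb electrostatics with a distance-dependent dielectric
(eps = r, in Angstrom), an explicit 10-12 hydrogen-bond term with
donor-H-acceptor angle weighting, and an 8 A nonbond cutoff with switching.
The decomposition (vdw / elec / hbond / torsion / constraint) always sums
to the reported total.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["VDW_PARAMS", "EnergyBreakdown", "EnergyModel", "interaction_energy",
           "hbond_energy"]

# element -> (R* A, epsilon kcal/mol); H entries distinguish polar H (on N/O)
VDW_PARAMS = {
    "C": (1.90, 0.086),
    "N": (1.82, 0.170),
    "O": (1.66, 0.210),
    "F": (1.75, 0.061),
    "S": (2.00, 0.250),
    "H": (1.20, 0.015),   # nonpolar H
    "HP": (0.60, 0.010),  # polar H (bonded to N/O)
}

COULOMB_K = 332.0636     # kcal A / (mol e^2)
CUTOFF = 8.0             # A
SWITCH_ON = 6.5          # A
HB_R0 = 1.90             # A, optimal H...acceptor distance
HB_DEPTH = 4.0           # kcal/mol
CLASH_R = 0.1            # A
R_FLOOR = 0.6            # A, repulsion cap
# hydrophobic contact term (atomic-contact-energy style): nonpolar heavy
# atoms in water-shielded positions gain this per pair at contact; ramps
# off between PHOB_ON and PHOB_OFF.  Represents the desolvation driving
# force that plain LJ lacks; backbone atoms are excluded on the protein
# side (they stay hydrated), which is what distinguishes an exposed
# glycine ring from an alanine ring.
PHOB_E = -0.10           # kcal/mol per nonpolar pair at contact
PHOB_ON = 4.5            # A
PHOB_OFF = 6.5           # A
# the complementary desolvation penalty: burying a hydrated polar atom
# (pore-exposed backbone N/O) under a nonpolar ligand atom costs the
# hydration energy without an H-bond to compensate
DESOLV_E = +0.10         # kcal/mol per nonpolar/polar pair at contact


def _switch(r: np.ndarray) -> np.ndarray:
    """C1 switching function of r^2: 1 below SWITCH_ON, 0 above CUTOFF."""
    return _switch2(np.square(r))


def _switch2(r2: np.ndarray) -> np.ndarray:
    """Switching evaluated on squared distance (avoids a sqrt)."""
    t = np.clip((CUTOFF ** 2 - r2) / (CUTOFF ** 2 - SWITCH_ON ** 2), 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def hbond_energy(donor: np.ndarray, h: np.ndarray, acceptor: np.ndarray) -> float:
    """10-12 H-bond term with cos^2 donor-H-acceptor angle weighting.

    Zero for bent geometries (angle < 90 deg) and beyond the cutoff.
    """
    r = float(np.linalg.norm(acceptor - h))
    if r >= CUTOFF or r < 1e-6:
        return 0.0
    v1 = donor - h
    v2 = acceptor - h
    cosang = float(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    # angle at H between donor and acceptor; linear D-H...A has cosang = -1
    if cosang > 0.0:
        return 0.0
    rr = HB_R0 / max(r, 1.2)
    e = HB_DEPTH * (5.0 * rr ** 12 - 6.0 * rr ** 10)
    return float(e * cosang ** 2 * _switch(np.array([r]))[0])


@dataclass
class EnergyBreakdown:
    """Energy components (kcal/mol); ``total`` is their exact sum."""

    vdw: float = 0.0
    elec: float = 0.0
    hbond: float = 0.0
    torsion: float = 0.0
    constraint: float = 0.0
    clash: bool = False

    @property
    def total(self) -> float:
        return self.vdw + self.elec + self.hbond + self.torsion + self.constraint

    @property
    def interaction(self) -> float:
        """Ligand-channel interaction energy (without constraint penalties)."""
        return self.vdw + self.elec + self.hbond


def _effective_elements(elements, bonds=None, charges=None):
    """Tag polar hydrogens so they get the reduced vdW radius."""
    out = list(elements)
    if bonds:
        for a, b in bonds:
            for h, x in ((a, b), (b, a)):
                if out[h] == "H" and elements[x] in ("N", "O"):
                    out[h] = "HP"
    return out


class EnergyModel:
    """Precomputed pair tables between one atom group and another.

    Build once per (ligand, pruned protein subset) pairing; evaluation is a
    distance-matrix pass.
    """

    def __init__(self, elems_a, charges_a, elems_b, charges_b,
                 bonds_a=None, bonds_b=None,
                 nonpolar_a=None, nonpolar_b=None, polar_b=None):
        ea = _effective_elements(elems_a, bonds_a)
        eb = _effective_elements(elems_b, bonds_b)
        ra = np.array([VDW_PARAMS[e][0] for e in ea])
        rb = np.array([VDW_PARAMS[e][0] for e in eb])
        sa = np.array([VDW_PARAMS[e][1] for e in ea])
        sb = np.array([VDW_PARAMS[e][1] for e in eb])
        self.r0 = ra[:, None] + rb[None, :]
        self.eps = np.sqrt(sa[:, None] * sb[None, :])
        self.qq = COULOMB_K * np.outer(np.asarray(charges_a), np.asarray(charges_b))
        # flattened LJ coefficient tables: E = A/r^12 - B/r^6
        r0_6 = self.r0.ravel() ** 6
        self._A = (self.eps.ravel() * r0_6 ** 2)
        self._B = (2.0 * self.eps.ravel() * r0_6)
        self._qqf = self.qq.ravel()
        if nonpolar_a is not None and nonpolar_b is not None:
            self._phob = np.outer(np.asarray(nonpolar_a, dtype=bool),
                                  np.asarray(nonpolar_b, dtype=bool)).ravel()
        else:
            self._phob = np.zeros(len(self._qqf), dtype=bool)
        if nonpolar_a is not None and polar_b is not None:
            self._desolv = np.outer(np.asarray(nonpolar_a, dtype=bool),
                                    np.asarray(polar_b, dtype=bool)).ravel()
        else:
            self._desolv = np.zeros(len(self._qqf), dtype=bool)

    def pair_energies(self, xa: np.ndarray, xb: np.ndarray):
        """(vdw, elec, clash_flag) between coordinate sets xa (n,3), xb (m,3).

        The hydrophobic contact term (nonpolar-pair tables) is folded into
        the van der Waals component.
        """
        d = xa[:, None, :] - xb[None, :, :]
        r2 = np.einsum("ijk,ijk->ij", d, d).ravel()
        clash = bool((r2 < CLASH_R ** 2).any())
        near = r2 < CUTOFF ** 2
        r2n = np.maximum(r2[near], R_FLOOR ** 2)
        sw = _switch2(r2n)
        r6 = r2n * r2n * r2n
        vdw = float(np.sum((self._A[near] / (r6 * r6) - self._B[near] / r6) * sw))
        elec = float(np.sum(self._qqf[near] / r2n * sw))  # eps(r) = r dielectric
        if self._phob.any() or self._desolv.any():
            t = np.clip((PHOB_OFF ** 2 - r2n) / (PHOB_OFF ** 2 - PHOB_ON ** 2),
                        0.0, 1.0)
            ramp = t * t * (3 - 2 * t)
            vdw += float(PHOB_E * np.sum(self._phob[near] * ramp))
            vdw += float(DESOLV_E * np.sum(self._desolv[near] * ramp))
        return vdw, elec, clash


def interaction_energy(pore, lig_coords: np.ndarray, ligand,
                       model: EnergyModel | None = None,
                       prot_idx=None, torsion_energy: float = 0.0,
                       constraint_energy: float = 0.0) -> EnergyBreakdown:
    """Ligand-channel energy with full decomposition.

    ``pore`` supplies protein coordinates, charges and H-bond geometry;
    ``prot_idx`` restricts the protein to a neighbourhood subset (the same
    subset the ``model`` tables were built for).
    """
    if prot_idx is None:
        prot_idx = np.arange(len(pore.elements))
    pcoords = pore.coords[prot_idx]
    if model is None:
        model = EnergyModel(ligand.elements, ligand.charges,
                            [pore.elements[i] for i in prot_idx],
                            pore.charges[prot_idx],
                            bonds_a=ligand.bonds)
    vdw, elec, clash = model.pair_energies(lig_coords, pcoords)

    hb = 0.0
    sub = set(int(i) for i in prot_idx)
    # protein donors -> ligand acceptors
    for heavy, h in pore.donors:
        if heavy not in sub:
            continue
        for acc in ligand.acceptors:
            hb += hbond_energy(pore.coords[heavy], pore.coords[h], lig_coords[acc])
    # ligand donors -> protein acceptors
    for heavy, h in ligand.donors:
        for acc in pore.acceptors:
            if acc in sub:
                hb += hbond_energy(lig_coords[heavy], lig_coords[h], pore.coords[acc])
    return EnergyBreakdown(vdw=vdw, elec=elec, hbond=hb, torsion=torsion_energy,
                           constraint=constraint_energy, clash=clash)
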