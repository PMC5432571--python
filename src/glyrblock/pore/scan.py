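"""Pulling the blocker through the pore and two-ligand docking.

The pulling protocol reproduces the classic constrained-MCM scan: the
ligand's bridging nitrogen (N1) is confined to a plane normal to the pore
axis, stepped in 0.5 A increments from below the -2' level to the 20'
level; a 6 A flat-bottom radial restraint keeps the ligand from escaping
the pore; pin restraints (penalty-free up to 1 A, 10 kcal/mol/A beyond)
tie the alpha-carbons to the template.  At each level the energy is
MC-minimized until ``stop_after`` consecutive minimizations fail to improve
the best energy, seeding each level from the previous one's best pose.

Degrees of freedom: per ligand a rigid-body block (translation of N1 +
rotation about N1) plus its rotatable torsions; side-chain chi angles of
residues near the working level.  Local minimization moves the ligand
blocks only (numerical gradients over a handful of dofs); chi angles are
sampled by the Monte-Carlo moves and accepted through the Metropolis step,
which keeps the protein side cacheable and the scan fast.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .energy import (EnergyBreakdown, EnergyModel, CUTOFF, HB_R0, HB_DEPTH,
                     _switch)
from .ligand import LigandConformer, _rotation_matrix
from .mcm import mc_minimize, MCMResult
from .poremodel import PoreModel, RISE

__all__ = ["Constraint", "plane_constraint", "radial_constraint", "pin_constraint",
           "z_window_constraint", "PoseProblem", "EnergyProfile", "pull_profile",
           "compare_subtype_profiles", "dock_two_ligands", "hbond_inventory"]


@dataclass(frozen=True)
class Constraint:
    """Restraint with a flat bottom and parabolic or linear walls."""

    kind: str               # 'plane' | 'radial' | 'pin' | 'z_window'
    params: dict

    def energy(self, n1_positions, pore: PoreModel) -> float:
        p = self.params
        if self.kind == "plane":
            return sum(p["k"] * (x[2] - p["z0"]) ** 2 for x in n1_positions)
        if self.kind == "radial":
            e = 0.0
            for x in n1_positions:
                r = np.hypot(x[0], x[1])
                if r > p["r0"]:
                    e += p["k"] * (r - p["r0"]) ** 2
            return e
        if self.kind == "z_window":
            e = 0.0
            for x in n1_positions:
                if x[2] < p["z_lo"]:
                    e += p["k"] * (p["z_lo"] - x[2]) ** 2
                elif x[2] > p["z_hi"]:
                    e += p["k"] * (x[2] - p["z_hi"]) ** 2
            return e
        if self.kind == "pin":
            dev = pore.ca_deviation()
            return float(np.sum(p["k"] * np.clip(dev - p["flat"], 0.0, None)))
        raise ValueError(f"unknown constraint kind {self.kind!r}")


def plane_constraint(z0: float, k: float = 5000.0) -> Constraint:
    """Confine atom N1 to the plane normal to the pore axis at height z0."""
    return Constraint("plane", {"z0": z0, "k": k})


def radial_constraint(r0: float = 6.0, k: float = 50.0) -> Constraint:
    """Flat-bottom: N1 may wander up to r0 from the axis penalty-free."""
    return Constraint("radial", {"r0": r0, "k": k})


def z_window_constraint(z_lo: float, z_hi: float, k: float = 5000.0) -> Constraint:
    return Constraint("z_window", {"z_lo": z_lo, "z_hi": z_hi, "k": k})


def pin_constraint(k: float = 10.0, flat: float = 1.0) -> Constraint:
    """Alpha-carbon pins: free up to ``flat`` A, then ``k`` kcal/mol/A."""
    return Constraint("pin", {"k": k, "flat": flat})


def _vec_hbond(d_pos, h_pos, a_pos) -> float:
    """Vectorized 10-12 H-bond sum with cos^2 angle weighting."""
    if len(d_pos) == 0 or len(a_pos) == 0:
        return 0.0
    dv = a_pos[None, :, :] - h_pos[:, None, :]
    r = np.sqrt((dv ** 2).sum(-1))
    dh = d_pos - h_pos
    num = np.einsum("ij,ikj->ik", dh, dv)
    den = np.linalg.norm(dh, axis=1)[:, None] * np.clip(r, 1e-9, None)
    cosang = num / den
    rr = HB_R0 / np.clip(r, 1.2, None)
    e = HB_DEPTH * (5.0 * rr ** 12 - 6.0 * rr ** 10)
    mask = (cosang < 0.0) & (r < CUTOFF)
    return float(np.sum(e * cosang ** 2 * _switch(r) * mask))


class _LigandBlock:
    """Precomputed fast transform for one ligand's dof block."""

    def __init__(self, lig: LigandConformer):
        self.lig = lig
        self.base = lig.coords.copy()
        self.n1 = lig.n1_index
        self.torsions = lig.torsions
        self.base_dihedrals = np.array([lig.dihedral(*t[1]) for t in lig.torsions])
        self.acceptors = np.array(lig.acceptors, dtype=int)
        self.donor_heavy = np.array([d for d, _ in lig.donors], dtype=int)
        self.donor_h = np.array([h for _, h in lig.donors], dtype=int)
        self.n_dof = 6 + len(lig.torsions)

    def coords(self, part: np.ndarray) -> np.ndarray:
        X = self.base.copy()
        # torsions first (moving sets are nested outermost-first in build order)
        for k, (name, (a, b, c, d), moving, _pot) in enumerate(self.torsions):
            delta = float(part[6 + k]) - self.base_dihedrals[k]
            if abs(delta) > 1e-12:
                axis = X[c] - X[b]
                axis /= np.linalg.norm(axis)
                R = _rotation_matrix(axis, delta)
                X[moving] = (X[moving] - X[c]) @ R.T + X[c]
        pivot = X[self.n1].copy()
        rv = part[3:6]
        ang = np.linalg.norm(rv)
        if ang > 1e-12:
            R = _rotation_matrix(rv / ang, ang)
            X = (X - pivot) @ R.T + pivot
        return X + part[:3]

    def torsion_energy(self, part: np.ndarray) -> float:
        return float(sum(pot(float(part[6 + k]))
                         for k, (_n, _q, _m, pot) in enumerate(self.torsions)))


class PoseProblem:
    """Maps a degree-of-freedom vector to coordinates and energy.

    dof layout: per ligand [tx, ty, tz, rx, ry, rz (rotation vector about
    N1), torsion angles...] followed by the selected side-chain chi angles.
    """

    def __init__(self, pore: PoreModel, ligands, constraints,
                 z_center: float, subset_margin: float = 11.0,
                 chi_margin: float = 8.0):
        self.pore = pore
        self.constraints = list(constraints)
        self.blocks = [_LigandBlock(lig.copy()) for lig in ligands]
        self.ligands = [b.lig for b in self.blocks]
        self.sub = pore.subset_near_z(z_center, subset_margin)
        sub_set = set(int(i) for i in self.sub)
        self._sub_pos = {int(g): i for i, g in enumerate(self.sub)}
        # hydrophobic (water-shielded nonpolar) atoms: side-chain C/S on the
        # protein side (backbone stays hydrated), weakly charged C/F on the
        # ligand side
        def lig_nonpolar(lig):
            return [(e in ("C", "F")) and abs(q) < 0.25
                    for e, q in zip(lig.elements, lig.charges)]

        pore_np = [(pore.names[i] not in ("N", "CA", "C", "O"))
                   and (pore.elements[i] in ("C", "S"))
                   and abs(pore.charges[i]) < 0.25
                   for i in self.sub]
        # hydrated polar atoms: pore-exposed backbone N/O (burying them
        # under a nonpolar ligand atom costs their hydration)
        pore_pol = [(pore.names[i] in ("N", "O")) for i in self.sub]
        self.models = [EnergyModel(b.lig.elements, b.lig.charges,
                                   [pore.elements[i] for i in self.sub],
                                   pore.charges[self.sub], bonds_a=b.lig.bonds,
                                   nonpolar_a=lig_nonpolar(b.lig),
                                   nonpolar_b=pore_np, polar_b=pore_pol)
                       for b in self.blocks]
        self.model_ll = None
        if len(self.blocks) == 2:
            a, b = self.ligands
            self.model_ll = EnergyModel(a.elements, a.charges, b.elements,
                                        b.charges, bonds_a=a.bonds, bonds_b=b.bonds,
                                        nonpolar_a=lig_nonpolar(a),
                                        nonpolar_b=lig_nonpolar(b))
        # side-chain chi torsions near the working level
        self.chi = [(label, a, b, np.array(moving, dtype=int))
                    for label, a, b, moving in pore.chi_torsions
                    if abs(pore.coords[b][2] - z_center) <= chi_margin]
        self.n_dof = sum(b.n_dof for b in self.blocks) + len(self.chi)
        self._lig_dof = sum(b.n_dof for b in self.blocks)
        # protein H-bond partners inside the subset (positions in sub order)
        self.p_donors = [(d, h) for d, h in pore.donors
                         if d in sub_set and h in sub_set]
        self._pd_heavy = np.array([self._sub_pos[d] for d, _ in self.p_donors], dtype=int)
        self._pd_h = np.array([self._sub_pos[h] for _, h in self.p_donors], dtype=int)
        self._p_acc = np.array([self._sub_pos[a] for a in pore.acceptors
                                if a in sub_set], dtype=int)
        self._chi_cache: tuple[bytes, np.ndarray] | None = None

    # --- dof handling -----------------------------------------------------
    def split(self, x: np.ndarray):
        parts = []
        off = 0
        for b in self.blocks:
            parts.append(np.asarray(x[off:off + b.n_dof], dtype=float))
            off += b.n_dof
        return parts, np.asarray(x[off:], dtype=float)

    def minimize_indices(self) -> np.ndarray:
        """The ligand dof block (gradient-minimized subset)."""
        return np.arange(self._lig_dof)

    def ligand_coords(self, x: np.ndarray):
        parts, _ = self.split(x)
        return [b.coords(p) for b, p in zip(self.blocks, parts)]

    def pore_sub_coords(self, x: np.ndarray) -> np.ndarray:
        _, chis = self.split(x)
        if len(self.chi) == 0:
            return self.pore.coords[self.sub]
        key = chis.tobytes()
        if self._chi_cache is not None and self._chi_cache[0] == key:
            return self._chi_cache[1]
        coords = self.pore.coords.copy()
        for (label, a, b, moving), ang in zip(self.chi, chis):
            if abs(float(ang)) < 1e-12:
                continue
            axis = coords[b] - coords[a]
            axis /= np.linalg.norm(axis)
            R = _rotation_matrix(axis, float(ang))
            coords[moving] = (coords[moving] - coords[b]) @ R.T + coords[b]
        out = coords[self.sub]
        self._chi_cache = (key, out)
        return out

    # --- energies ---------------------------------------------------------
    def breakdown(self, x: np.ndarray) -> EnergyBreakdown:
        x = np.asarray(x, dtype=float)
        parts, _ = self.split(x)
        psub = self.pore_sub_coords(x)
        lig_coords = [b.coords(p) for b, p in zip(self.blocks, parts)]
        vdw = elec = hb = tor = 0.0
        clash = False
        pd = psub[self._pd_heavy] if len(self._pd_heavy) else np.zeros((0, 3))
        ph = psub[self._pd_h] if len(self._pd_h) else np.zeros((0, 3))
        pa = psub[self._p_acc] if len(self._p_acc) else np.zeros((0, 3))
        for blk, model, lc, part in zip(self.blocks, self.models, lig_coords, parts):
            v, e, cl = model.pair_energies(lc, psub)
            vdw += v
            elec += e
            clash = clash or cl
            tor += blk.torsion_energy(part)
            hb += _vec_hbond(pd, ph, lc[blk.acceptors])
            hb += _vec_hbond(lc[blk.donor_heavy], lc[blk.donor_h], pa)
        if self.model_ll is not None:
            v, e, cl = self.model_ll.pair_energies(lig_coords[0], lig_coords[1])
            vdw += v
            elec += e
            clash = clash or cl
            a, b = self.blocks
            hb += _vec_hbond(lig_coords[0][a.donor_heavy], lig_coords[0][a.donor_h],
                             lig_coords[1][b.acceptors])
            hb += _vec_hbond(lig_coords[1][b.donor_heavy], lig_coords[1][b.donor_h],
                             lig_coords[0][a.acceptors])
        n1s = [lc[blk.n1] for blk, lc in zip(self.blocks, lig_coords)]
        con = sum(c.energy(n1s, self.pore) for c in self.constraints)
        return EnergyBreakdown(vdw=vdw, elec=elec, hbond=hb, torsion=tor,
                               constraint=con, clash=clash)

    def energy(self, x: np.ndarray) -> float:
        return self.breakdown(x).total

    # --- initialization and moves ----------------------------------------
    def initial_dof(self) -> np.ndarray:
        return np.zeros(self.n_dof)

    def carry_dof(self, x_prev: np.ndarray, problem_prev: "PoseProblem") -> np.ndarray:
        """Transfer a previous level's best dof onto this problem's layout."""
        x = np.zeros(self.n_dof)
        n = min(self._lig_dof, problem_prev._lig_dof)
        x[:n] = np.asarray(x_prev[:n], dtype=float)
        _, chis_prev = problem_prev.split(np.asarray(x_prev, dtype=float))
        prev = {lab: ang for (lab, *_), ang in zip(problem_prev.chi, chis_prev)}
        for i, (lab, *_) in enumerate(self.chi):
            x[self._lig_dof + i] = prev.get(lab, 0.0)
        return x

    def place_n1(self, x: np.ndarray, target: np.ndarray | None = None,
                 z0: float | None = None, block: int = 0) -> np.ndarray:
        """Shift one ligand block's translation so N1 lands on target/z0."""
        x = np.asarray(x, dtype=float).copy()
        off = sum(b.n_dof for b in self.blocks[:block])
        lc = self.blocks[block].coords(x[off:off + self.blocks[block].n_dof])
        n1 = lc[self.blocks[block].n1]
        if target is not None:
            x[off:off + 3] += np.asarray(target) - n1
        elif z0 is not None:
            x[off + 2] += z0 - n1[2]
        return x

    def perturb(self, x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        y = np.asarray(x, dtype=float).copy()
        off = 0
        for blk in self.blocks:
            y[off:off + 3] += rng.uniform(-1.0, 1.0, 3)          # <= 1 A translation
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            y[off + 3:off + 6] += axis * rng.uniform(0, np.radians(30))
            for k in range(len(blk.torsions)):
                if rng.random() < 0.4:
                    step = np.radians(120.0 if rng.random() < 0.25 else 30.0)
                    y[off + 6 + k] += rng.uniform(-step, step)
            off += blk.n_dof
        for i in range(len(self.chi)):
            if rng.random() < 0.35:
                step = np.radians(90.0 if rng.random() < 0.3 else 30.0)
                y[off + i] += rng.uniform(-step, step)
        return y


@dataclass
class EnergyProfile:
    """Best MC-minimized energies along the pore axis, one entry per step."""

    z: np.ndarray
    prime: np.ndarray
    e_total: np.ndarray          # interaction energy (vdw+elec+hbond)
    e_vdw: np.ndarray
    e_elec: np.ndarray
    e_hbond: np.ndarray
    e_torsion: np.ndarray
    e_constraint: np.ndarray
    poses: list = field(default_factory=list)
    dofs: list = field(default_factory=list)
    subtype: str = ""

    def to_tsv(self, path) -> Path:
        import pandas as pd
        df = pd.DataFrame({"z_A": self.z, "prime_level": self.prime,
                           "E_total": self.e_total, "E_vdw": self.e_vdw,
                           "E_elec": self.e_elec, "E_hbond": self.e_hbond,
                           "E_torsion": self.e_torsion,
                           "E_constraint": self.e_constraint})
        df.to_csv(path, sep="\t", index=False)
        return Path(path)

    def mean_between_primes(self, lo: float, hi: float) -> float:
        m = (self.prime >= lo) & (self.prime <= hi)
        return float(self.e_total[m].mean())


def _long_axis_upright(lig: LigandConformer) -> LigandConformer:
    """Rotate the conformer so its longest axis lies along +z (pore axis)."""
    work = lig.copy()
    c = work.coords - work.coords.mean(axis=0)
    _, _, vt = np.linalg.svd(c)
    R = np.zeros((3, 3))
    R[2] = vt[0]
    R[0] = vt[1]
    R[1] = np.cross(R[2], R[0])
    work.coords = c @ R.T
    work.coords -= work.coords[work.n1_index]
    return work


def pull_profile(pore: PoreModel, ligand: LigandConformer,
                 z_from: float | None = None, z_to: float | None = None,
                 step: float = 0.5, seed: int = 0, stop_after: int = 100,
                 radial_limit: float = 6.0,
                 minimizer_options: dict | None = None,
                 max_minimizations: int = 2000) -> EnergyProfile:
    """Constrained MCM pulling scan from the cytoplasmic to the
    extracellular end of the pore (0.5 A steps, both ends included)."""
    if z_from is None:
        z_from = pore.z_of_prime(-3)   # one residue step below the -2' ring
    if z_to is None:
        z_to = pore.z_of_prime(20)
    n_steps = int(round((z_to - z_from) / step))
    levels = z_from + step * np.arange(n_steps + 1)
    lig0 = _long_axis_upright(ligand)
    rng = np.random.default_rng(seed)

    rows, poses, dofs = [], [], []
    carry = None
    prob_prev = None
    for z0 in levels:
        cons = [plane_constraint(z0), radial_constraint(radial_limit),
                pin_constraint()]
        prob = PoseProblem(pore, [lig0], cons, z_center=z0)
        if carry is None:
            x0 = prob.initial_dof()
        else:
            x0 = prob.carry_dof(carry, prob_prev)
        x0 = prob.place_n1(x0, z0=z0)
        res = mc_minimize(prob.energy, x0, prob.perturb,
                          seed=int(rng.integers(2**31)), stop_after=stop_after,
                          minimizer_options=minimizer_options,
                          max_minimizations=max_minimizations,
                          minimize_indices=prob.minimize_indices())
        bd = prob.breakdown(res.best_x)
        rows.append((z0, bd))
        poses.append(prob.ligand_coords(res.best_x)[0])
        dofs.append(res.best_x.copy())
        carry, prob_prev = res.best_x, prob
    return EnergyProfile(
        z=np.array([z for z, _ in rows]),
        prime=np.array([z / RISE - 2.0 for z, _ in rows]),
        e_total=np.array([b.interaction for _, b in rows]),
        e_vdw=np.array([b.vdw for _, b in rows]),
        e_elec=np.array([b.elec for _, b in rows]),
        e_hbond=np.array([b.hbond for _, b in rows]),
        e_torsion=np.array([b.torsion for _, b in rows]),
        e_constraint=np.array([b.constraint for _, b in rows]),
        poses=poses, dofs=dofs, subtype=pore.subtype)


def _refine_dof_on(pore: PoreModel, ligand: LigandConformer, z0: float,
                   x_start: np.ndarray, prob_src: PoseProblem,
                   radial_limit: float = 6.0,
                   minimizer_options: dict | None = None):
    """Local re-minimization of a pose (taken from another model's scan)
    in ``pore`` at level z0; returns (breakdown, problem, dof)."""
    from scipy.optimize import minimize as _sp_minimize
    cons = [plane_constraint(z0), radial_constraint(radial_limit),
            pin_constraint()]
    prob = PoseProblem(pore, [ligand], cons, z_center=z0)
    x0 = prob.carry_dof(x_start, prob_src)
    opts = {"maxiter": 60, "maxfun": 2000, "eps": 1e-3}
    if minimizer_options:
        opts.update(minimizer_options)
    idx = prob.minimize_indices()

    def sub_energy(xi):
        y = x0.copy()
        y[idx] = xi
        return prob.energy(y)

    res = _sp_minimize(sub_energy, x0[idx], method="L-BFGS-B", options=opts)
    out = x0.copy()
    out[idx] = res.x
    return prob.breakdown(out), prob, out


def compare_subtype_profiles(pore_a: PoreModel, pore_b: PoreModel,
                             ligand: LigandConformer,
                             z_from: float, z_to: float, step: float = 0.5,
                             seed: int = 0, stop_after: int = 15,
                             minimizer_options: dict | None = None) -> dict:
    """Paired best-energy comparison of two pore models over a z range.

    Each model is scanned independently, then cross-seeded: at every level
    the other model's best pose is locally re-minimized in this model and
    the better of (own scan, cross-refined) is kept.  Because the two
    models share all coordinates except the 2' ring side chains, the
    cross-seeding evaluates both on the union of sampled pose families,
    cancelling Monte-Carlo sampling luck and leaving the systematic
    subtype contrast.
    """
    lig0 = _long_axis_upright(ligand)
    profs = {}
    for pore in (pore_a, pore_b):
        profs[pore.subtype] = pull_profile(pore, ligand, z_from=z_from,
                                           z_to=z_to, step=step, seed=seed,
                                           stop_after=stop_after,
                                           minimizer_options=minimizer_options)
    pa, pb = profs[pore_a.subtype], profs[pore_b.subtype]
    best = {pore_a.subtype: pa.e_total.copy(), pore_b.subtype: pb.e_total.copy()}
    for i, z0 in enumerate(pa.z):
        # rebuild the source problems to translate the stored dofs
        cons = [plane_constraint(z0), radial_constraint(), pin_constraint()]
        prob_a = PoseProblem(pore_a, [lig0], cons, z_center=z0)
        prob_b = PoseProblem(pore_b, [lig0], cons, z_center=z0)
        bd_ab, *_ = _refine_dof_on(pore_b, lig0, z0, pa.dofs[i], prob_a,
                                   minimizer_options=minimizer_options)
        bd_ba, *_ = _refine_dof_on(pore_a, lig0, z0, pb.dofs[i], prob_b,
                                   minimizer_options=minimizer_options)
        if bd_ab.constraint < 0.5:
            best[pore_b.subtype][i] = min(best[pore_b.subtype][i], bd_ab.interaction)
        if bd_ba.constraint < 0.5:
            best[pore_a.subtype][i] = min(best[pore_a.subtype][i], bd_ba.interaction)
    return {"profiles": profs, "best": best, "z": pa.z, "prime": pa.prime}


def hbond_inventory(prob: PoseProblem, x: np.ndarray,
                    max_h_a: float = 2.6) -> list[dict]:
    """Formed hydrogen bonds (pore donor residue -> ligand acceptor atom)."""
    out = []
    psub = prob.pore_sub_coords(x)
    lig_coords = prob.ligand_coords(x)
    for li, (blk, lc) in enumerate(zip(prob.blocks, lig_coords)):
        for (d, h), hp in zip(prob.p_donors, prob._pd_h):
            for acc in blk.acceptors:
                r = float(np.linalg.norm(lc[acc] - psub[hp]))
                if r <= max_h_a:
                    out.append({"ligand": li,
                                "donor": f"{prob.pore.res_name[d]}"
                                         f"{int(prob.pore.res_id[d])}."
                                         f"{int(prob.pore.chain[d])}",
                                "acceptor_atom": blk.lig.names[int(acc)],
                                "h_a_distance_A": r})
    return out


def dock_two_ligands(pore: PoreModel, ligand: LigandConformer | None = None,
                     seed: int = 0, stop_after: int = 100,
                     minimizer_options: dict | None = None,
                     max_minimizations: int = 1500) -> dict:
    """Dock a second blocker onto the single-ligand complex at level 13'.

    Both bridging nitrogens are confined above the 9' constriction (z
    window between 9'+0.5 A and 17').  Returns poses, the energy
    breakdown, the ligand-ligand van der Waals energy and the H-bond
    inventory.
    """
    from .ligand import build_nfa
    if ligand is None:
        ligand = build_nfa()
    lig0 = _long_axis_upright(ligand)
    z13 = pore.z_of_prime(13)
    rng = np.random.default_rng(seed)

    # stage 1: single-ligand complex at 13'
    cons1 = [plane_constraint(z13), radial_constraint(), pin_constraint()]
    prob1 = PoseProblem(pore, [lig0], cons1, z_center=z13)
    x0 = prob1.place_n1(prob1.initial_dof(), z0=z13)
    res1 = mc_minimize(prob1.energy, x0, prob1.perturb,
                       seed=int(rng.integers(2**31)), stop_after=stop_after,
                       minimizer_options=minimizer_options,
                       max_minimizations=max_minimizations,
                       minimize_indices=prob1.minimize_indices())

    # stage 2: both ligands, N1 confined above the 9' ring around level 13'
    z_lo = pore.z_of_prime(9) + 0.5
    z_hi = pore.z_of_prime(15)
    cons2 = [z_window_constraint(z_lo, z_hi), radial_constraint(), pin_constraint()]
    prob2 = PoseProblem(pore, [lig0, lig0], cons2, z_center=z13)
    x2 = prob2.carry_dof(res1.best_x, prob1)
    first_n1 = prob1.ligand_coords(res1.best_x)[0][lig0.n1_index]
    x2 = prob2.place_n1(x2, target=np.array([-first_n1[0], -first_n1[1],
                                             first_n1[2] + 1.0]), block=1)
    res2 = mc_minimize(prob2.energy, x2, prob2.perturb,
                       seed=int(rng.integers(2**31)), stop_after=stop_after,
                       minimizer_options=minimizer_options,
                       max_minimizations=max_minimizations,
                       minimize_indices=prob2.minimize_indices())
    bd = prob2.breakdown(res2.best_x)
    lig_coords = prob2.ligand_coords(res2.best_x)
    ll_vdw, ll_elec, _ = prob2.model_ll.pair_energies(lig_coords[0], lig_coords[1])
    return {"problem": prob2, "dof": res2.best_x, "breakdown": bd,
            "poses": lig_coords, "interligand_vdw": ll_vdw,
            "interligand_elec": ll_elec,
            "hbonds": hbond_inventory(prob2, res2.best_x),
            "single_result": res1, "mcm_result": res2}
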