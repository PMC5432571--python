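"""Pentameric TM2 pore models (idealized or from a PDB file).

The ion pore of the receptor is lined by five TM2 helices whose pore-facing
residues form rings indexed by "prime" numbers from the cytoplasmic (-2')
to the extracellular (20') end: -2' Pro250, 0' Arg252, 2' Gly254 (alpha1) /
Ala254 (alpha2), 6' Thr258, 9' Leu261 (the open-pore constriction), 13'
Thr265, 17' Gly269, 20' Ala272.  The idealized builder places five ideal
alpha-helices (1.5 A rise, 100 deg/residue, CA radius 2.3 A) on a circle
around the pore axis (+z toward the extracellular side), phased so the ring
residues face the lumen, with minimal side-chain atom sets and rotatable
chi torsions.  The alpha1 and alpha2 models differ only at level 2'
(G254A in all five chains).

A user-supplied PDB file of a pentameric pore can be used instead; nothing
needs to be downloaded for the idealized default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["PoreModel", "build_pore", "TM2_ALPHA1", "PRIME_LEVELS"]

# residues 250..272 of the alpha1 subunit (mature numbering)
TM2_ALPHA1 = "PARVGLGITTVLTMTTQSSGSRA"
TM2_START = 250
# prime level of residue number n is n - 252
PRIME_LEVELS = {-2: "PRO", 0: "ARG", 2: "GLY", 6: "THR", 9: "LEU",
                13: "THR", 17: "GLY", 20: "ALA"}

RISE = 1.5            # A per residue
TWIST = 100.0         # deg per residue
R_CA = 2.3            # A, CA helix radius
R_AXIS = 10.8         # A, helix axis distance from the pore axis
PHASE_OFFSET = -50.0  # deg, centers the pore-facing stripe on the lumen

AA3 = {"P": "PRO", "A": "ALA", "R": "ARG", "V": "VAL", "G": "GLY", "L": "LEU",
       "I": "ILE", "T": "THR", "M": "MET", "Q": "GLN", "S": "SER", "K": "LYS"}

# side-chain recipes: (atom name, element, parent atom, bond length,
# placement: 'ext' along the growth direction, 'b+'/'b-' branches, 'h' hydroxyl H)
SIDE_CHAINS = {
    "GLY": [],
    "ALA": [("CB", "C", "CA", 1.53, "ext")],
    "VAL": [("CB", "C", "CA", 1.53, "ext"), ("CG1", "C", "CB", 1.52, "b+"),
            ("CG2", "C", "CB", 1.52, "b-")],
    "LEU": [("CB", "C", "CA", 1.53, "ext"), ("CG", "C", "CB", 1.52, "ext"),
            ("CD1", "C", "CG", 1.52, "b+"), ("CD2", "C", "CG", 1.52, "b-")],
    "ILE": [("CB", "C", "CA", 1.53, "ext"), ("CG1", "C", "CB", 1.52, "ext"),
            ("CG2", "C", "CB", 1.52, "b-"), ("CD1", "C", "CG1", 1.52, "ext")],
    "THR": [("CB", "C", "CA", 1.53, "ext"), ("OG1", "O", "CB", 1.43, "b+"),
            ("CG2", "C", "CB", 1.52, "b-"), ("HG1", "H", "OG1", 0.96, "h")],
    "SER": [("CB", "C", "CA", 1.53, "ext"), ("OG", "O", "CB", 1.43, "ext"),
            ("HG", "H", "OG", 0.96, "h")],
    "MET": [("CB", "C", "CA", 1.53, "ext"), ("CG", "C", "CB", 1.52, "ext"),
            ("SD", "S", "CG", 1.80, "ext"), ("CE", "C", "SD", 1.79, "ext")],
    "GLN": [("CB", "C", "CA", 1.53, "ext"), ("CG", "C", "CB", 1.52, "ext"),
            ("CD", "C", "CG", 1.52, "ext"), ("OE1", "O", "CD", 1.23, "b+"),
            ("NE2", "N", "CD", 1.33, "b-")],
    "PRO": [("CB", "C", "CA", 1.53, "ext"), ("CG", "C", "CB", 1.52, "b+"),
            ("CD", "C", "CG", 1.52, "b-")],
    "ARG": [("CB", "C", "CA", 1.53, "ext"), ("CG", "C", "CB", 1.52, "ext"),
            ("CD", "C", "CG", 1.52, "ext"), ("NE", "N", "CD", 1.46, "ext"),
            ("CZ", "C", "NE", 1.33, "ext"), ("NH1", "N", "CZ", 1.33, "b+"),
            ("NH2", "N", "CZ", 1.33, "b-")],
    "LYS": [("CB", "C", "CA", 1.53, "ext"), ("CG", "C", "CB", 1.52, "ext"),
            ("CD", "C", "CG", 1.52, "ext"), ("CE", "C", "CD", 1.52, "ext"),
            ("NZ", "N", "CE", 1.47, "ext")],
}

# guanidinium +1 for Arg, ammonium +1 for Lys, small polar charges elsewhere
SIDE_CHARGES = {
    "ARG": {"NE": 0.0, "CZ": 0.4, "NH1": 0.3, "NH2": 0.3},
    "LYS": {"NZ": 1.0},
    "THR": {"OG1": -0.40, "HG1": 0.30, "CB": 0.10},
    "SER": {"OG": -0.40, "HG": 0.30, "CB": 0.10},
    "GLN": {"OE1": -0.38, "NE2": -0.30, "CD": 0.68},
}
BACKBONE_CHARGES = {"N": -0.30, "CA": 0.30, "C": 0.30, "O": -0.30}


@dataclass
class PoreModel:
    """Atom-level pentamer with prime-level map and chi torsions."""

    subtype: str
    names: list[str]
    elements: list[str]
    coords: np.ndarray
    charges: np.ndarray
    res_id: np.ndarray            # residue number (250..272)
    res_name: list[str]
    chain: np.ndarray             # 0..4
    ca_indices: np.ndarray
    template_ca: np.ndarray       # pin targets
    donors: list[tuple[int, int]] = field(default_factory=list)
    acceptors: list[int] = field(default_factory=list)
    chi_torsions: list[tuple] = field(default_factory=list)  # (label, a, b, moving)
    axis_origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    axis_direction: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    @property
    def level_map(self) -> dict:
        """prime level -> (z along the axis, residue name)."""
        out = {}
        for p, rn in PRIME_LEVELS.items():
            resnum = p + 252
            m = self.res_id == resnum
            if not m.any():
                continue
            ca = [i for i in np.where(m)[0] if self.names[i] == "CA"]
            zs = self.coords[ca] - self.axis_origin
            z = float(np.mean(zs @ self.axis_direction))
            name = self.res_name[int(np.where(m)[0][0])]
            out[p] = (z, name)
        return out

    def z_of_prime(self, prime: float) -> float:
        """Axial coordinate of a (possibly fractional) prime level."""
        return RISE * (prime + 2.0)

    def subset_near_z(self, z: float, margin: float = 12.0) -> np.ndarray:
        rel = (self.coords - self.axis_origin) @ self.axis_direction
        return np.where(np.abs(rel - z) <= margin)[0]

    def ca_deviation(self) -> np.ndarray:
        """Per-CA distance from the pin template (A)."""
        return np.linalg.norm(self.coords[self.ca_indices] - self.template_ca, axis=1)

    def sequence(self, chain: int = 0) -> str:
        inv = {v: k for k, v in AA3.items()}
        seen = {}
        for i in np.where(self.chain == chain)[0]:
            seen[int(self.res_id[i])] = self.res_name[i]
        return "".join(inv[seen[r]] for r in sorted(seen))

    def write_pdb(self, path) -> Path:
        import biotite.structure as struc
        import biotite.structure.io.pdb as pdb
        n = len(self.names)
        arr = struc.AtomArray(n)
        arr.coord = self.coords.astype(np.float32)
        arr.atom_name = np.array(self.names)
        arr.element = np.array(self.elements)
        arr.res_id = self.res_id.astype(int)
        arr.res_name = np.array(self.res_name)
        arr.chain_id = np.array([chr(ord("A") + c) for c in self.chain])
        arr.hetero = np.zeros(n, dtype=bool)
        f = pdb.PDBFile()
        f.set_structure(arr)
        f.write(str(path))
        return Path(path)


def _tm2_sequence(subtype: str) -> str:
    if subtype in ("alpha1", "a1"):
        return TM2_ALPHA1
    if subtype in ("alpha2", "a2", "g254a"):
        # alpha2 (and the G254A mutant) carry Ala at level 2'
        i = 254 - TM2_START
        return TM2_ALPHA1[:i] + "A" + TM2_ALPHA1[i + 1:]
    raise ValueError(f"unknown subtype {subtype!r}; use 'alpha1' or 'alpha2'")


def _build_idealized(subtype: str) -> PoreModel:
    seq = _tm2_sequence(subtype)
    names, elements, res_id, res_name, chain_col = [], [], [], [], []
    coords, charges = [], []
    chi = []
    zhat = np.array([0.0, 0.0, 1.0])

    for k in range(5):
        theta_helix = np.radians(72.0 * k)
        helix_center = R_AXIS * np.array([np.cos(theta_helix), np.sin(theta_helix), 0.0])
        phase0 = np.degrees(theta_helix) + 180.0 + PHASE_OFFSET
        for i, aa in enumerate(seq):
            rn = AA3[aa]
            resnum = TM2_START + i
            z = RISE * i
            phi = np.radians(phase0 + TWIST * i)
            radial = np.array([np.cos(phi), np.sin(phi), 0.0])
            ca = helix_center + R_CA * radial + z * zhat
            # approximate backbone placement (wall bulk, not H-bonding)
            phi_n = np.radians(phase0 + TWIST * i - 27.0)
            phi_c = np.radians(phase0 + TWIST * i + 26.0)
            npos = helix_center + 1.55 * np.array([np.cos(phi_n), np.sin(phi_n), 0]) + (z - 0.9) * zhat
            cpos = helix_center + 1.67 * np.array([np.cos(phi_c), np.sin(phi_c), 0]) + (z + 0.55) * zhat
            opos = cpos + 1.23 * (0.35 * np.array([np.cos(phi_c), np.sin(phi_c), 0]) + 0.94 * zhat)
            atom_pos = {"N": npos, "CA": ca, "C": cpos, "O": opos}
            # side-chain local frame: u points away from the helix axis (for
            # lumen-phased residues that is toward the pore axis)
            u = radial.copy()
            w = zhat
            v = np.cross(w, u)
            for (an, el, parent, blen, mode) in SIDE_CHAINS[rn]:
                p = atom_pos[parent]
                if mode == "ext":
                    d = u if parent in ("CA",) else _norm(p - atom_pos.get("CA", ca)) * 0.7 + 0.3 * u
                    d = _norm(0.9 * _norm(d) + 0.25 * w * ((-1) ** len(atom_pos)))
                elif mode == "b+":
                    d = _norm(0.62 * u + 0.79 * v)
                elif mode == "b-":
                    d = _norm(0.62 * u - 0.79 * v)
                else:  # hydroxyl H: continue outward
                    d = _norm(p - atom_pos["CB"])
                atom_pos[an] = p + blen * d

            base = len(names)
            order = ["N", "CA", "C", "O"] + [sc[0] for sc in SIDE_CHAINS[rn]]
            for an in order:
                names.append(an)
                elements.append(SIDE_CHAINS[rn][[sc[0] for sc in SIDE_CHAINS[rn]].index(an)][1]
                               if an not in ("N", "CA", "C", "O") else
                               {"N": "N", "CA": "C", "C": "C", "O": "O"}[an])
                coords.append(atom_pos[an])
                q = BACKBONE_CHARGES.get(an, 0.0) if an in ("N", "CA", "C", "O") \
                    else SIDE_CHARGES.get(rn, {}).get(an, 0.0)
                charges.append(q)
                res_id.append(resnum)
                res_name.append(rn)
                chain_col.append(k)
            # chi1: rotate side atoms beyond CB about CA->CB
            side_names = [sc[0] for sc in SIDE_CHAINS[rn]]
            if len(side_names) >= 2:
                ca_i = base + order.index("CA")
                cb_i = base + order.index("CB")
                moving = [base + order.index(n) for n in side_names if n != "CB"]
                chi.append((f"{rn}{resnum}.{k}.chi1", ca_i, cb_i, moving))
            if rn in ("THR", "SER"):
                og = "OG1" if rn == "THR" else "OG"
                hg = "HG1" if rn == "THR" else "HG"
                cb_i = base + order.index("CB")
                og_i = base + order.index(og)
                chi.append((f"{rn}{resnum}.{k}.chiOH", cb_i, og_i, [base + order.index(hg)]))

    coords = np.array(coords)
    charges = np.array(charges)
    res_id = np.array(res_id)
    chain_col = np.array(chain_col)
    ca_idx = np.array([i for i, n in enumerate(names) if n == "CA"])

    donors, acceptors = [], []
    for i, (n, rn) in enumerate(zip(names, res_name)):
        if n in ("HG1", "HG"):
            heavy = i - 1  # OG follows CB, HG follows OG in the recipes
            donors.append((heavy, i))
        if n in ("OG1", "OG", "OE1", "O"):
            acceptors.append(i)

    return PoreModel(subtype=subtype, names=names, elements=elements,
                     coords=coords, charges=charges, res_id=res_id,
                     res_name=res_name, chain=chain_col, ca_indices=ca_idx,
                     template_ca=coords[ca_idx].copy(), donors=donors,
                     acceptors=acceptors, chi_torsions=chi)


def _norm(v):
    return v / np.linalg.norm(v)


def _build_from_pdb(subtype: str, pdb_path) -> PoreModel:
    """Pore model from a user-supplied pentamer PDB (e.g. 3JAE-derived).

    Requires exactly five chains containing the TM2 stretch; only the atoms
    of the internal side-chain vocabulary are kept.  The pore axis is the
    principal axis of the CA cloud, oriented so residue numbers increase
    with z.
    """
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb
    f = pdb.PDBFile.read(str(pdb_path))
    arr = f.get_structure(model=1)
    arr = arr[~arr.hetero]
    chains = sorted(set(arr.chain_id))
    if len(chains) != 5:
        raise ValueError(f"{pdb_path}: need exactly 5 chains, found {len(chains)}")
    seq = _tm2_sequence(subtype)
    keep_names = {"N", "CA", "C", "O"} | {sc[0] for rn in SIDE_CHAINS.values() for sc in rn}

    names, elements, res_id, res_name, chain_col, coords, charges = [], [], [], [], [], [], []
    for k, ch in enumerate(chains):
        sub = arr[arr.chain_id == ch]
        resnums = sorted(set(int(r) for r in sub.res_id))
        if not all((TM2_START + i) in resnums for i in range(len(seq))):
            raise ValueError(f"{pdb_path}: chain {ch} lacks TM2 residues "
                             f"{TM2_START}..{TM2_START + len(seq) - 1}")
        for i, aa in enumerate(seq):
            resnum = TM2_START + i
            res_atoms = sub[sub.res_id == resnum]
            rn = str(res_atoms.res_name[0])
            for j in range(len(res_atoms)):
                an = str(res_atoms.atom_name[j])
                if an not in keep_names:
                    continue
                names.append(an)
                elements.append(str(res_atoms.element[j]).capitalize()
                                if len(str(res_atoms.element[j])) else an[0])
                coords.append(np.asarray(res_atoms.coord[j], dtype=float))
                q = BACKBONE_CHARGES.get(an, 0.0) if an in ("N", "CA", "C", "O") \
                    else SIDE_CHARGES.get(rn, {}).get(an, 0.0)
                charges.append(q)
                res_id.append(resnum)
                res_name.append(rn)
                chain_col.append(k)
    coords = np.array(coords)
    # orient: principal axis of CA cloud -> +z, numbering increasing with z
    ca_idx = np.array([i for i, n in enumerate(names) if n == "CA"])
    ca = coords[ca_idx]
    center = ca.mean(axis=0)
    _, _, vt = np.linalg.svd(ca - center)
    axis = vt[0]
    zvals = (ca - center) @ axis
    rid = np.array(res_id)[ca_idx]
    if np.corrcoef(zvals, rid)[0, 1] < 0:
        axis = -axis
    # rotate axis onto z and shift so level -2' sits at its idealized height
    R = _rotation_onto_z(axis)
    coords = (coords - center) @ R.T
    ca_z = coords[ca_idx][:, 2]
    z_m2 = float(np.mean(ca_z[rid == 250]))
    coords[:, 2] += RISE * 0.0 - z_m2
    model = PoreModel(subtype=subtype, names=names, elements=elements,
                      coords=coords, charges=np.array(charges),
                      res_id=np.array(res_id), res_name=res_name,
                      chain=np.array(chain_col), ca_indices=ca_idx,
                      template_ca=coords[ca_idx].copy())
    # donors/acceptors and chi torsions from the generic vocabulary
    for i, n in enumerate(model.names):
        if n in ("OG1", "OG", "OE1", "O"):
            model.acceptors.append(i)
    return model


def _rotation_onto_z(axis: np.ndarray) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, z)
    s = np.linalg.norm(v)
    if s < 1e-12:
        return np.eye(3) if axis @ z > 0 else np.diag([1.0, -1.0, -1.0])
    c = float(axis @ z)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)


def build_pore(subtype: str = "alpha1", source: str = "idealized",
               pdb_path=None) -> PoreModel:
    """Build the alpha1 or alpha2 pore model.

    ``source='idealized'`` needs no input; ``source='pdb'`` reads a
    user-supplied pentamer coordinate file.
    """
    if source == "idealized":
        return _build_idealized(subtype)
    if source == "pdb":
        if pdb_path is None:
            raise ValueError("source='pdb' requires pdb_path")
        return _build_from_pdb(subtype, pdb_path)
    raise ValueError(f"unknown source {source!r}")
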