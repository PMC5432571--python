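"""Niflumic acid (NFA) 3D model built from internal coordinates.

NFA is 2-{[3-(trifluoromethyl)phenyl]amino}pyridine-3-carboxylic acid: a
pyridine ring carrying a carboxylate, bridged through a secondary amine
nitrogen (flagged N1 here) to a phenyl ring bearing a CF3 group.  At
physiological pH the molecule is anionic (net charge -1 on the
carboxylate).  The builder places both rings planar with standard bond
lengths and 120-degree ring geometry, a 124-degree diarylamine C-N-C bridge
angle, and closes the intramolecular N-H...O hydrogen bond that keeps the
free molecule nearly planar.  The carboxylate twist follows a 2-fold
torsional potential with a 3 kcal/mol barrier and minima at +/-90 degrees
(benzoic-acid-type), and the conformer is relaxed over its rotatable
torsions under the ligand force-field terms (torsion potentials,
intramolecular H-bond, intramolecular van der Waals).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations

import numpy as np
from scipy.optimize import minimize

__all__ = ["LigandConformer", "build_nfa", "ph_coo_torsion_energy"]

RING_BOND = 1.395
PH_COO_BARRIER = 3.0        # kcal/mol, 2-fold, minima at +/-90 deg
CONJUGATION_BARRIER = 8.0   # kcal/mol, 2-fold, minima at 0/180 (aryl-amine planarity)
BRIDGE_ANGLE = 124.0        # deg, diarylamine C-N-C
HB_INTRA_SCALE = 2.0        # resonance-assisted intramolecular H-bond (~8 kcal/mol)


@dataclass
class LigandConformer:
    """Atom-level ligand model with rotatable torsions.

    ``torsions`` holds (name, (a, b, c, d), moving-atom indices, potential)
    where rotation is about the b-c bond and ``potential`` maps a dihedral
    in radians to kcal/mol.
    """

    names: list[str]
    elements: list[str]
    coords: np.ndarray
    charges: np.ndarray
    bonds: list[tuple[int, int]]
    torsions: list[tuple]
    n1_index: int
    donors: list[tuple[int, int]]       # (heavy, H)
    acceptors: list[int]
    net_charge: float = -1.0

    def index(self, name: str) -> int:
        return self.names.index(name)

    def copy(self) -> "LigandConformer":
        return replace(self, coords=self.coords.copy())

    def max_interatomic_distance(self) -> float:
        d = self.coords[:, None, :] - self.coords[None, :, :]
        return float(np.sqrt((d ** 2).sum(-1)).max())

    def dihedral(self, a: int, b: int, c: int, d: int) -> float:
        """Signed dihedral angle in radians."""
        return _dihedral(self.coords[a], self.coords[b], self.coords[c], self.coords[d])

    def set_torsion(self, tor_idx: int, angle_rad: float) -> None:
        """Rotate the moving set so the named dihedral equals ``angle_rad``."""
        name, (a, b, c, d), moving, _pot = self.torsions[tor_idx]
        cur = self.dihedral(a, b, c, d)
        self.rotate_about_bond(b, c, moving, angle_rad - cur)

    def rotate_about_bond(self, b: int, c: int, moving, angle_rad: float) -> None:
        axis = self.coords[c] - self.coords[b]
        axis = axis / np.linalg.norm(axis)
        R = _rotation_matrix(axis, angle_rad)
        origin = self.coords[c]
        self.coords[moving] = (self.coords[moving] - origin) @ R.T + origin

    def ring_plane_angle_deg(self) -> float:
        """Angle between the pyridine and phenyl ring planes."""
        py = [self.index(n) for n in ("C2", "Npy", "C6", "C5", "C4", "C3")]
        ph = [self.index(n) for n in ("CP1", "CP2", "CP3", "CP4", "CP5", "CP6")]
        n1 = _plane_normal(self.coords[py])
        n2 = _plane_normal(self.coords[ph])
        c = abs(float(n1 @ n2))
        return float(np.degrees(np.arccos(min(1.0, c))))

    def hbond_h_to_o_distance(self) -> float:
        """Distance from the bridge N-H hydrogen to the nearer carboxylate O."""
        h = self.coords[self.index("HN1")]
        return float(min(np.linalg.norm(h - self.coords[self.index("O1c")]),
                         np.linalg.norm(h - self.coords[self.index("O2c")])))


def _rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    x, y, z = axis
    c, s = np.cos(angle), np.sin(angle)
    C = 1.0 - c
    return np.array([
        [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
        [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
        [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
    ])


def _dihedral(p0, p1, p2, p3) -> float:
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - (b0 @ b1) * b1
    w = b2 - (b2 @ b1) * b1
    return float(np.arctan2(np.cross(v, w) @ b1, v @ w))


def _plane_normal(pts: np.ndarray) -> np.ndarray:
    q = pts - pts.mean(axis=0)
    return np.linalg.svd(q)[2][2]


def ph_coo_torsion_energy(phi_rad: float) -> float:
    """Aryl-carboxylate 2-fold torsion: 3 kcal/mol barrier, minima at +/-90."""
    return 0.5 * PH_COO_BARRIER * (1.0 + np.cos(2.0 * phi_rad))


def _conjugation_energy(barrier):
    def pot(phi):
        return 0.5 * barrier * (1.0 - np.cos(2.0 * phi))
    return pot


def _build_geometry() -> tuple[list[str], list[str], np.ndarray]:
    """Planar H-bond-closed NFA skeleton from standard internal coordinates."""
    def hexagon(center, start_deg):
        ang = np.radians(start_deg) + np.arange(6) * np.pi / 3
        return center + RING_BOND * np.stack(
            [np.cos(ang), np.sin(ang), np.zeros(6)], axis=1)

    def rotz(deg):
        t = np.radians(deg)
        return np.array([[np.cos(t), -np.sin(t), 0.0],
                         [np.sin(t), np.cos(t), 0.0],
                         [0.0, 0.0, 1.0]])

    cen1 = np.zeros(3)
    py = hexagon(cen1, 0.0)  # order: C2, Npy, C6, C5, C4, C3

    def exo(ring, i, cen):
        v = ring[i] - cen
        return v / np.linalg.norm(v)

    n1 = py[0] + 1.40 * exo(py, 0, cen1)
    d = exo(py, 0, cen1)
    d10 = rotz(180.0 - BRIDGE_ANGLE) @ d
    cp1 = n1 + 1.41 * d10
    cen2 = cp1 + RING_BOND * d10
    a0 = np.degrees(np.arctan2(-d10[1], -d10[0]))
    ph = hexagon(cen2, a0)  # order: CP1, CP2, CP3, CP4, CP5, CP6 (CP3 bears CF3)

    ct = ph[2] + 1.50 * exo(ph, 2, cen2)
    ax = exo(ph, 2, cen2)
    perp1 = np.array([0.0, 0.0, 1.0])
    perp2 = np.cross(ax, perp1)
    th = np.radians(180.0 - 111.5)
    fs = [ct + 1.34 * (np.cos(th) * ax
                       + np.sin(th) * (np.cos(p) * perp1 + np.sin(p) * perp2))
          for p in np.radians([90.0, 210.0, 330.0])]

    cc = py[5] + 1.50 * exo(py, 5, cen1)
    dC = exo(py, 5, cen1)
    o_syn = cc + 1.25 * (rotz(180.0 - 117.0) @ dC)    # points toward the N-H
    o_anti = cc + 1.25 * (rotz(-(180.0 - 117.0)) @ dC)

    hs, hnames = [], []
    for ring, cen, keep, tags in ((py, cen1, (2, 3, 4), ("H6", "H5", "H4")),
                                  (ph, cen2, (1, 3, 4, 5), ("HP2", "HP4", "HP5", "HP6"))):
        for i, tag in zip(keep, tags):
            hs.append(ring[i] + 1.082 * exo(ring, i, cen))
            hnames.append(tag)
    bis = (py[0] - n1) / 1.40 + (cp1 - n1) / 1.41
    hn1 = n1 - 1.011 * bis / np.linalg.norm(bis)

    names = (["O1c", "O2c", "CC"]
             + ["C2", "Npy", "C6", "C5", "C4", "C3"]
             + ["N1", "HN1"]
             + ["CP1", "CP2", "CP3", "CP4", "CP5", "CP6"]
             + ["CT", "F1", "F2", "F3"]
             + hnames)
    elements = (["O", "O", "C"] + ["C", "N", "C", "C", "C", "C"]
                + ["N", "H"] + ["C"] * 6 + ["C", "F", "F", "F"]
                + ["H"] * len(hnames))
    coords = np.array([o_syn, o_anti, cc, *py, n1, hn1, *ph, ct, *fs, *hs])
    return names, elements, coords


# simple electronegativity-motivated charge table; the carboxylate formal
# charge is split over both oxygens and any residual is spread over ring
# carbons so the net charge is exactly -1
_CHARGES = {"O1c": -0.50, "O2c": -0.50, "CC": 0.30,
            "Npy": -0.30, "C2": 0.20, "N1": -0.40, "HN1": 0.35,
            "CT": 0.40, "F1": -0.15, "F2": -0.15, "F3": -0.15,
            "CP1": 0.10}


def _bonds(names: list[str]) -> list[tuple[int, int]]:
    ix = {n: i for i, n in enumerate(names)}
    ring1 = ["C2", "Npy", "C6", "C5", "C4", "C3"]
    ring2 = ["CP1", "CP2", "CP3", "CP4", "CP5", "CP6"]
    pairs = [(ring1[i], ring1[(i + 1) % 6]) for i in range(6)]
    pairs += [(ring2[i], ring2[(i + 1) % 6]) for i in range(6)]
    pairs += [("C3", "CC"), ("CC", "O1c"), ("CC", "O2c"),
              ("C2", "N1"), ("N1", "HN1"), ("N1", "CP1"),
              ("CP3", "CT"), ("CT", "F1"), ("CT", "F2"), ("CT", "F3"),
              ("C6", "H6"), ("C5", "H5"), ("C4", "H4"),
              ("CP2", "HP2"), ("CP4", "HP4"), ("CP5", "HP5"), ("CP6", "HP6")]
    return [(ix[a], ix[b]) for a, b in pairs]


def _bond_path_lengths(n: int, bonds) -> np.ndarray:
    """All-pairs bond-graph distances (small n, BFS per atom)."""
    adj = [[] for _ in range(n)]
    for a, b in bonds:
        adj[a].append(b)
        adj[b].append(a)
    D = np.full((n, n), 99, dtype=int)
    for s in range(n):
        D[s, s] = 0
        queue = [s]
        while queue:
            nxt = []
            for u in queue:
                for v in adj[u]:
                    if D[s, v] > D[s, u] + 1:
                        D[s, v] = D[s, u] + 1
                        nxt.append(v)
            queue = nxt
    return D


def _internal_energy(lig: LigandConformer, pair_idx, pair_r0, pair_eps) -> float:
    """Ligand-internal force field: torsions + intramolecular H-bond + vdW."""
    e = 0.0
    for name, (a, b, c, d), _moving, pot in lig.torsions:
        e += pot(lig.dihedral(a, b, c, d))
    # intramolecular H-bond, donor N1-H: resonance-assisted (conjugated
    # six-membered pseudo-ring), hence deeper than a generic H-bond
    from .energy import hbond_energy
    for acc in lig.acceptors:
        e += (HB_INTRA_SCALE
              * hbond_energy(lig.coords[lig.index("N1")], lig.coords[lig.index("HN1")],
                             lig.coords[acc]))
    if len(pair_idx[0]):
        dvec = lig.coords[pair_idx[0]] - lig.coords[pair_idx[1]]
        r = np.sqrt((dvec ** 2).sum(-1))
        r = np.clip(r, 0.6, None)
        ratio = pair_r0 / r
        e += float(np.sum(pair_eps * (ratio ** 12 - 2.0 * ratio ** 6)))
    return e


def build_nfa(minimize_conformer: bool = True) -> LigandConformer:
    """Construct and relax the anionic NFA conformer; atom N1 is flagged."""
    names, elements, coords = _build_geometry()
    ix = {n: i for i, n in enumerate(names)}
    charges = np.array([_CHARGES.get(n, 0.0) for n in names])
    ring_c = [ix[n] for n in ("C6", "C5", "C4", "C3", "CP2", "CP3", "CP4", "CP5", "CP6")]
    residual = -1.0 - charges.sum()
    charges[ring_c] += residual / len(ring_c)
    bonds = _bonds(names)

    phenyl_group = [ix[n] for n in ("CP1", "CP2", "CP3", "CP4", "CP5", "CP6",
                                    "CT", "F1", "F2", "F3",
                                    "HP2", "HP4", "HP5", "HP6")]
    torsions = [
        ("ph_coo", (ix["C4"], ix["C3"], ix["CC"], ix["O1c"]),
         [ix["O1c"], ix["O2c"]], lambda p: ph_coo_torsion_energy(p)),
        ("py_n1", (ix["Npy"], ix["C2"], ix["N1"], ix["CP1"]),
         [ix["HN1"]] + phenyl_group, _conjugation_energy(CONJUGATION_BARRIER)),
        ("n1_ph", (ix["C2"], ix["N1"], ix["CP1"], ix["CP2"]),
         [i for i in phenyl_group if i != ix["CP1"]],
         _conjugation_energy(0.6 * CONJUGATION_BARRIER)),
    ]
    lig = LigandConformer(names=names, elements=elements, coords=coords,
                          charges=charges, bonds=bonds, torsions=torsions,
                          n1_index=ix["N1"],
                          donors=[(ix["N1"], ix["HN1"])],
                          acceptors=[ix["O1c"], ix["O2c"], ix["Npy"]])
    if minimize_conformer:
        _relax_torsions(lig)
    return lig


def _relax_torsions(lig: LigandConformer) -> None:
    """Relax the rotatable torsions under the ligand force field."""
    from .energy import VDW_PARAMS
    # bonds, angles and rings are rigid here, so short-bond-path contacts
    # (including the 1-5 ortho contacts that real geometries relieve by
    # in-plane bending) are subsumed in the torsion potentials; plain LJ
    # applies only across >= 6 bonds
    D = _bond_path_lengths(len(lig.names), lig.bonds)
    ii, jj = np.where(np.triu(D, 1) >= 6)
    # exclude the H-bond pair itself from vdW (it has its own term)
    keep = []
    hb = {(lig.index("HN1"), lig.index("O1c")), (lig.index("HN1"), lig.index("O2c")),
          (lig.index("HN1"), lig.index("Npy"))}
    for a, b in zip(ii, jj):
        if (a, b) in hb or (b, a) in hb:
            continue
        keep.append((a, b))
    pi = np.array([k[0] for k in keep]), np.array([k[1] for k in keep])
    r0 = np.array([VDW_PARAMS[lig.elements[a]][0] + VDW_PARAMS[lig.elements[b]][0]
                   for a, b in keep])
    eps = np.array([np.sqrt(VDW_PARAMS[lig.elements[a]][1] * VDW_PARAMS[lig.elements[b]][1])
                    for a, b in keep])
    x0 = np.array([lig.dihedral(*t[1]) for t in lig.torsions])

    def objective(x):
        for k, ang in enumerate(x):
            lig.set_torsion(k, ang)
        return _internal_energy(lig, pi, r0, eps)

    res = minimize(objective, x0, method="Nelder-Mead",
                   options={"xatol": 1e-4, "fatol": 1e-8, "maxiter": 2000})
    objective(res.x)
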