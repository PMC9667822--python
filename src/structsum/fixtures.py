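"""Deterministic synthetic PDB files with known ground truth.

Peptides are built by sequential internal-coordinate placement (NeRF)
at ideal main-chain geometry, so requested (phi, psi, omega) torsions
round-trip within 0.5 degrees and unperturbed fixtures pass the
stereochemical geometry checks cleanly. The same ideal bond lengths and
angles are used here and in the geometry-validation reference set; that
coupling is deliberate and itself under test.

All generators are bit-reproducible for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from structsum.geometry import rotation_matrix
from structsum.pdb_io import AA_ONE_TO_THREE

# ideal main-chain internal coordinates (angstroms / degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_CA_CB = 1.530
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
ANGLE_N_CA_CB = 110.4
# improper C-N-CA-CB torsion giving the L-configuration at CA
IMPROPER_CB = -122.6


@dataclass
class PeptideSpec:
    """Sequence plus one (phi, psi, omega) triple per residue.

    phi of the first residue and psi/omega of terminal residues are
    still consumed by the builder (they orient the chain ends) even
    though they are undefined on recomputation.
    """

    sequence: str
    torsions: list[tuple[float, float, float]] = field(default_factory=list)

    def __post_init__(self):
        if not self.torsions:
            self.torsions = [(-139.0, 135.0, 180.0)] * len(self.sequence)
        if len(self.torsions) != len(self.sequence):
            raise ValueError("torsion list length must equal sequence length")
        for aa in self.sequence:
            if aa not in AA_ONE_TO_THREE:
                raise ValueError(f"invalid residue letter {aa!r}")


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, ang_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF placement: position D given A-B-C, |CD|, angle BCD, torsion ABCD."""
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    ang = np.radians(ang_deg)
    tor = np.radians(torsion_deg)
    d_local = np.array(
        [-bond * np.cos(ang),
         bond * np.sin(ang) * np.cos(tor),
         -bond * np.sin(ang) * np.sin(tor)]
    )
    rot = np.column_stack([bc, m, n])
    return c + rot @ d_local


def build_backbone(spec: PeptideSpec) -> list[dict[str, np.ndarray]]:
    """Per-residue dict of backbone atom coordinates (N, CA, C, O, CB)."""
    n_res = len(spec.sequence)
    residues: list[dict[str, np.ndarray]] = [dict() for _ in range(n_res)]

    residues[0]["N"] = np.zeros(3)
    residues[0]["CA"] = np.array([BOND_N_CA, 0.0, 0.0])
    ang = np.radians(ANGLE_N_CA_C)
    residues[0]["C"] = residues[0]["CA"] + BOND_CA_C * np.array(
        [-np.cos(ang), np.sin(ang), 0.0]
    )

    for i in range(1, n_res):
        phi_i = spec.torsions[i][0]
        psi_prev = spec.torsions[i - 1][1]
        omega_i = spec.torsions[i][2]
        prev = residues[i - 1]
        cur = residues[i]
        cur["N"] = place_atom(prev["N"], prev["CA"], prev["C"],
                              BOND_C_N, ANGLE_CA_C_N, psi_prev)
        cur["CA"] = place_atom(prev["CA"], prev["C"], cur["N"],
                               BOND_N_CA, ANGLE_C_N_CA, omega_i)
        cur["C"] = place_atom(prev["C"], cur["N"], cur["CA"],
                              BOND_CA_C, ANGLE_N_CA_C, phi_i)

    # carbonyl O: trans to the next N across the peptide plane (psi + 180)
    for i in range(n_res):
        psi_i = spec.torsions[i][1]
        r = residues[i]
        r["O"] = place_atom(r["N"], r["CA"], r["C"], BOND_C_O, ANGLE_CA_C_O,
                            psi_i + 180.0)
        if spec.sequence[i] != "G":
            r["CB"] = place_atom(r["C"], r["N"], r["CA"], BOND_CA_CB,
                                 ANGLE_N_CA_CB, IMPROPER_CB)
    return residues


# ---------------------------------------------------------------------------
# PDB serialisation helpers

_ELEMENT_OF = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}
_ATOM_ORDER = ["N", "CA", "C", "O", "CB"]


def _pdb_atom_line(serial: int, name: str, resname: str, chain: str,
                   resseq: int, xyz: np.ndarray, element: str,
                   het: bool = False, occ: float = 1.0, b: float = 10.0) -> str:
    rec = "HETATM" if het else "ATOM  "
    fname = name if len(name) == 4 else f" {name:<3s}"
    return (
        f"{rec}{serial:5d} {fname:<4.4s} {resname:>3s} {chain:1.1s}{resseq:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{occ:6.2f}{b:6.2f}          {element:>2.2s}"
    )


def _serialise_peptide(spec: PeptideSpec, residues: list[dict[str, np.ndarray]],
                       chain: str = "A", start_resseq: int = 1,
                       start_serial: int = 1) -> tuple[list[str], int]:
    lines = []
    serial = start_serial
    for i, coords in enumerate(residues):
        resname = AA_ONE_TO_THREE[spec.sequence[i]]
        for atom_name in _ATOM_ORDER:
            if atom_name not in coords:
                continue
            lines.append(
                _pdb_atom_line(serial, atom_name, resname, chain,
                               start_resseq + i, coords[atom_name],
                               _ELEMENT_OF[atom_name])
            )
            serial += 1
    return lines, serial


def transform_coords(residues: list[dict[str, np.ndarray]],
                     rot: np.ndarray = None, shift: np.ndarray = None):
    out = []
    for coords in residues:
        d = {}
        for k, v in coords.items():
            w = v.copy()
            if rot is not None:
                w = rot @ w
            if shift is not None:
                w = w + shift
            d[k] = w
        out.append(d)
    return out


# ---------------------------------------------------------------------------
# public generators

def make_peptide(spec: PeptideSpec, seed: int = 0, chain: str = "A") -> str:
    """Single-chain peptide PDB text built at the requested torsions."""
    del seed  # construction is fully deterministic; accepted for API symmetry
    residues = build_backbone(spec)
    lines, _ = _serialise_peptide(spec, residues, chain=chain)
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def make_ideal_helix(n_res: int = 12, seed: int = 0) -> str:
    """Poly-alanine alpha helix at (phi, psi) = (-57, -47)."""
    spec = PeptideSpec("A" * n_res, [(-57.0, -47.0, 180.0)] * n_res)
    return make_peptide(spec, seed=seed)


# Strand torsions refined numerically (Powell search over the ten
# strand (phi, psi) pairs, turn held at the type-I' ideals) so that the
# two strands register into an antiparallel ladder with main-chain
# amide energies below the -0.5 kcal/mol assignment threshold at the
# three rungs 3-10, 4-9, 5-8 and no steric clash.
HAIRPIN_TORSIONS = [
    (-120.0, 130.0, 180.0),
    (-120.0, 129.0, 180.0),
    (-119.9, 130.0, 180.0),
    (-100.0, 112.5, 180.0),
    (-103.2, 129.1, 180.0),
    (60.0, 30.0, 180.0),    # turn i+1 (type I')
    (90.0, 0.0, 180.0),     # turn i+2
    (-127.2, 105.5, 180.0),
    (-87.1, 132.3, 180.0),
    (-120.0, 130.0, 180.0),
    (-120.0, 130.0, 180.0),
    (-120.0, 130.0, 180.0),
]


def make_beta_hairpin(seed: int = 0) -> str:
    """Two antiparallel 5-residue strands joined by a type-I' turn.

    The strand torsions are slightly tightened relative to the ideal
    antiparallel sheet so the two strands register with cross-strand
    N...O distances near 2.9 A.
    """
    spec = PeptideSpec("A" * 12, list(HAIRPIN_TORSIONS))
    return make_peptide(spec, seed=seed)


def make_two_helix_dimer(separation: float = 9.0, seed: int = 0) -> str:
    """Two parallel poly-ALA helices (chains A, B) *separation* A apart."""
    spec = PeptideSpec("A" * 10, [(-57.0, -47.0, 180.0)] * 10)
    res_a = build_backbone(spec)
    # align helix axis with x: the raw NeRF helix axis must be measured
    ca = np.array([r["CA"] for r in res_a])
    axis = _principal_axis(ca)
    rot = _rotation_onto(axis, np.array([1.0, 0.0, 0.0]))
    res_a = transform_coords(res_a, rot=rot)
    res_b = transform_coords(res_a, shift=np.array([0.0, separation, 0.0]))
    lines_a, serial = _serialise_peptide(spec, res_a, chain="A")
    lines_b, _ = _serialise_peptide(spec, res_b, chain="B", start_serial=serial)
    return "\n".join(lines_a + ["TER"] + lines_b + ["TER", "END"]) + "\n"


def _principal_axis(points: np.ndarray) -> np.ndarray:
    c = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(c)
    axis = vt[0]
    # orient from first to last point
    if np.dot(points[-1] - points[0], axis) < 0:
        axis = -axis
    return axis


def _rotation_onto(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix sending unit vector a onto unit vector b."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    s = np.linalg.norm(v)
    if s < 1e-12:
        return np.eye(3) if np.dot(a, b) > 0 else -np.eye(3)
    c = np.dot(a, b)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)


# toy-complex construction constants, found by a grid search over
# helix separations and carbonyl anchor residues so that the contact
# criteria report exactly two protein-ligand hydrogen bonds
_TOY_SEPARATION = 10.5   # inter-helix axis distance, A
_TOY_ANCHOR_A = 5        # 0-based residue of chain A whose O accepts from ligand N1
_TOY_ANCHOR_B = 2        # 0-based residue of chain B whose O accepts from ligand O1
_TOY_HB_DIST = 2.9       # anchor hydrogen-bond length, A
_TOY_BOND = 1.5          # ligand skeleton bond length, A


def make_toy_complex(seed: int = 0) -> str:
    """A 20-residue helical pocket around a 6-atom ligand (resname LIG).

    Two 10-residue poly-ALA helices (chains A, B) face each other
    across a gap; the ligand bridges the gap with its two polar atoms
    each placed 2.9 A radially out from one backbone carbonyl oxygen,
    so the contact criteria find exactly two protein-ligand hydrogen
    bonds (N1 -> O of A, O1 -> O of B) plus several non-bonded
    contacts, and no steric clash.
    """
    del seed
    spec = PeptideSpec("A" * 10, [(-57.0, -47.0, 180.0)] * 10)
    res = build_backbone(spec)
    ca = np.array([r["CA"] for r in res])
    rot = _rotation_onto(_principal_axis(ca), np.array([1.0, 0.0, 0.0]))
    res_a = transform_coords(res, rot=rot)
    centre = np.mean([r["CA"] for r in res_a], axis=0)
    res_a = transform_coords(res_a, shift=-centre)
    res_b = transform_coords(res_a, rot=rotation_matrix([1.0, 0.0, 0.0], 180.0))
    res_b = transform_coords(res_b, shift=np.array([0.0, _TOY_SEPARATION, 0.0]))

    lines_a, serial = _serialise_peptide(spec, res_a, chain="A")
    lines_b, serial = _serialise_peptide(spec, res_b, chain="B", start_serial=serial)

    lig_lines = []
    for name, elem, xyz in _ligand_coords(res_a, res_b):
        lig_lines.append(
            _pdb_atom_line(serial, name, "LIG", "L", 1, xyz, elem, het=True)
        )
        serial += 1
    return "\n".join(lines_a + ["TER"] + lines_b + ["TER"] + lig_lines + ["END"]) + "\n"


def _radial_anchor(residues, j: int, axis_y: float, d: float) -> np.ndarray:
    """Point *d* angstroms radially out from the carbonyl O of residue j.

    The helix axis is the line y = axis_y, z = 0 (helices are built
    aligned with x), so 'radially' means away from that line.
    """
    o = residues[j]["O"]
    axis_pt = np.array([o[0], axis_y, 0.0])
    rad = o - axis_pt
    rad /= np.linalg.norm(rad)
    return o + d * rad


def _ligand_coords(res_a, res_b) -> list[tuple[str, str, np.ndarray]]:
    """Six-atom ligand: O1-C1-C2-C3-C4-N1 arc between the two anchors.

    The four carbons lie on a circular-arc bulge of the O1-N1 chord,
    with the bulge height solved so every skeleton bond is 1.5 A.
    """
    from scipy.optimize import brentq

    n1 = _radial_anchor(res_a, _TOY_ANCHOR_A, 0.0, _TOY_HB_DIST)
    o1 = _radial_anchor(res_b, _TOY_ANCHOR_B, _TOY_SEPARATION, _TOY_HB_DIST)
    seg = n1 - o1
    u = seg / np.linalg.norm(seg)
    perp = np.array([0.0, 0.0, 1.0])
    perp -= np.dot(perp, u) * u
    perp /= np.linalg.norm(perp)

    def mean_bond(bulge: float) -> float:
        ts = np.linspace(0.0, 1.0, 6)
        pts = [o1 + seg * t + bulge * np.sin(np.pi * t) * perp for t in ts]
        return sum(np.linalg.norm(pts[k + 1] - pts[k]) for k in range(5)) / 5

    bulge = brentq(lambda b: mean_bond(b) - _TOY_BOND, 0.0, 6.0)
    ts = np.linspace(0.0, 1.0, 6)
    carbons = [o1 + seg * t + bulge * np.sin(np.pi * t) * perp for t in ts][1:5]
    return [
        ("C1", "C", carbons[0]),
        ("C2", "C", carbons[1]),
        ("C3", "C", carbons[2]),
        ("C4", "C", carbons[3]),
        ("O1", "O", o1),
        ("N1", "N", n1),
    ]


def make_cavity_cage(edge: float = 8.0, seed: int = 0, sealed: bool = True) -> str:
    """Carbon cage enclosing an empty cubic cavity, for cleft tests.

    With ``sealed`` (default) the cube surface is a full lattice of
    carbons spaced ~4 A (corners, edge midpoints, face centres at edge
    8), tight enough that no gap sphere of the default minimum radius
    passes through a wall: the interior cavity is then a single
    connected component separate from outside space. With
    ``sealed=False`` only the 8 corner atoms are emitted (an open cage
    whose gap-sphere field leaks through the faces).
    """
    del seed
    if edge <= 2 * 1.70:
        raise ValueError("edge must exceed twice the carbon vdW radius")
    half = edge / 2.0
    if sealed:
        n_ticks = max(3, int(round(edge / 4.0)) + 1)
        ticks = np.linspace(-half, half, n_ticks)
        coords = [
            np.array([x, y, z])
            for x in ticks for y in ticks for z in ticks
            if any(abs(abs(v) - half) < 1e-9 for v in (x, y, z))
        ]
    else:
        coords = [
            np.array([sx * half, sy * half, sz * half])
            for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)
        ]
    lines = []
    for i, xyz in enumerate(coords, 1):
        lines.append(_pdb_atom_line(i, "C", "CAG", "A", i, xyz, "C", het=True))
    lines.append("END")
    return "\n".join(lines) + "\n"
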