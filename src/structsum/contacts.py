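"""Detection of hydrogen bonds, non-bonded contacts, salt bridges,
disulphides, and metal coordination.

Hydrogen bonds use heavy-atom geometric criteria with explicit polar
hydrogens placed at idealised positions: a donor-acceptor pair
qualifies iff D-A <= 3.9 A and, when a hydrogen can be constructed,
H-A <= 2.5 A and the D-H...A angle >= 90 degrees. Donors whose
antecedent atoms are missing are tested on distance only. Rotatable
donors (Ser/Thr/Tyr hydroxyls, Lys NZ, Cys SG) orient their hydrogen
on the rotor cone toward each candidate acceptor, i.e. the geometry
test uses the most favourable rotamer.

Pair searches run on a k-d tree; tests hold the results equal to an
exhaustive O(n^2) scan.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
from scipy.spatial import cKDTree

from structsum.config import ContactCriteria
from structsum.geometry import angle, rotation_matrix
from structsum.pdb_io import METAL_ELEMENTS, Atom, Residue, Structure

MAINCHAIN_ATOMS = {"N", "CA", "C", "O", "OXT"}

COVALENT_RADII = {"C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05, "P": 1.07,
                  "H": 0.31, "SE": 1.20}
DEFAULT_COVALENT = 0.76
COVALENT_MARGIN = 0.45

# side-chain donors: atom -> (hybridisation, antecedent, plane-reference, n_H, rotatable)
SIDECHAIN_DONORS = {
    ("SER", "OG"): ("sp3", "CB", None, 1, True),
    ("THR", "OG1"): ("sp3", "CB", None, 1, True),
    ("TYR", "OH"): ("sp2", "CZ", "CE1", 1, True),
    ("CYS", "SG"): ("sp3", "CB", None, 1, True),
    ("LYS", "NZ"): ("sp3", "CE", None, 3, True),
    ("ARG", "NE"): ("sp2", None, None, 1, False),   # bisector of CD, CZ
    ("ARG", "NH1"): ("sp2", "CZ", "NE", 2, False),
    ("ARG", "NH2"): ("sp2", "CZ", "NE", 2, False),
    ("ASN", "ND2"): ("sp2", "CG", "OD1", 2, False),
    ("GLN", "NE2"): ("sp2", "CD", "OE1", 2, False),
    ("HIS", "ND1"): ("sp2", None, None, 1, False),  # ring bisector
    ("HIS", "NE2"): ("sp2", None, None, 1, False),
    ("TRP", "NE1"): ("sp2", None, None, 1, False),
}
# ring donors handled by the bisector of their two ring neighbours
RING_NEIGHBOURS = {
    ("ARG", "NE"): ("CD", "CZ"),
    ("HIS", "ND1"): ("CG", "CE1"),
    ("HIS", "NE2"): ("CD2", "CE1"),
    ("TRP", "NE1"): ("CD1", "CE2"),
}

SIDECHAIN_ACCEPTORS = {
    ("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2"),
    ("ASN", "OD1"), ("GLN", "OE1"), ("SER", "OG"), ("THR", "OG1"),
    ("TYR", "OH"), ("HIS", "ND1"), ("HIS", "NE2"), ("MET", "SD"),
    ("CYS", "SG"),
}

BASIC_ATOMS = {("LYS", "NZ"), ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"),
               ("HIS", "ND1"), ("HIS", "NE2")}
ACIDIC_ATOMS = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}


@dataclass
class AtomRef:
    residue: Residue
    atom: Atom

    @property
    def key(self):
        return (self.residue.chain_id, self.residue.resseq, self.residue.icode,
                self.atom.name)

    def __repr__(self):
        return f"{self.residue.label}:{self.atom.name}"


@dataclass
class HBond:
    donor: AtomRef
    acceptor: AtomRef
    d_a: float
    h_pos: Optional[np.ndarray] = None
    h_a: Optional[float] = None
    dha_angle: Optional[float] = None
    category: str = ""

    @property
    def pair_key(self):
        return frozenset((self.donor.key, self.acceptor.key))


@dataclass
class Contact:
    atom_a: AtomRef
    atom_b: AtomRef
    dist: float

    @property
    def pair_key(self):
        return frozenset((self.atom_a.key, self.atom_b.key))


@dataclass
class SaltBridge:
    basic_atom: AtomRef
    acidic_atom: AtomRef
    dist: float


# ---------------------------------------------------------------------------
# donor/acceptor resolution

def is_donor(res: Residue, atom: Atom) -> bool:
    if atom.is_hydrogen:
        return False
    if res.category == "amino":
        if atom.name == "N":
            return res.resname != "PRO"
        return (res.resname, atom.name) in SIDECHAIN_DONORS
    if res.category == "water":
        return atom.element == "O"
    # HET groups / nucleotides: polar elements, distance-only criteria
    return atom.element in ("N", "O")


def is_acceptor(res: Residue, atom: Atom) -> bool:
    if atom.is_hydrogen:
        return False
    if res.category == "amino":
        if atom.name in ("O", "OXT"):
            return True
        return (res.resname, atom.name) in SIDECHAIN_ACCEPTORS
    if res.category == "water":
        return atom.element == "O"
    return atom.element in ("O", "N", "S")


# ---------------------------------------------------------------------------
# covalent connectivity (for excluding bonded / 1-3 pairs)

def covalent_adjacency(s: Structure) -> dict[tuple, set]:
    """Atom-key -> set of directly bonded atom-keys.

    Intra-residue bonds are inferred from covalent radii (+0.45 A
    margin); inter-residue peptide (C-N) and phosphodiester (O3'-P)
    links plus disulphides (SG-SG <= 2.5 A) are added explicitly.
    """
    adj: dict[tuple, set] = {}

    def link(ka, kb):
        adj.setdefault(ka, set()).add(kb)
        adj.setdefault(kb, set()).add(ka)

    sg_refs = []
    for chain in s.chains:
        prev: Optional[Residue] = None
        for res in chain.residues:
            heavies = res.heavy_atoms()
            for i, a in enumerate(heavies):
                ra = COVALENT_RADII.get(a.element, DEFAULT_COVALENT)
                for b in heavies[i + 1:]:
                    rb = COVALENT_RADII.get(b.element, DEFAULT_COVALENT)
                    if np.linalg.norm(a.xyz - b.xyz) <= ra + rb + COVALENT_MARGIN:
                        link(_akey(res, a), _akey(res, b))
            if res.resname == "CYS":
                sg = res.atom("SG")
                if sg is not None:
                    sg_refs.append((res, sg))
            if prev is not None:
                _link_polymer(prev, res, link)
            prev = res if res.category in ("amino", "nucleotide") else None

    for i, (res_a, sg_a) in enumerate(sg_refs):
        for res_b, sg_b in sg_refs[i + 1:]:
            if np.linalg.norm(sg_a.xyz - sg_b.xyz) <= 2.5:
                link(_akey(res_a, sg_a), _akey(res_b, sg_b))
    return adj


def _akey(res: Residue, atom: Atom):
    return (res.chain_id, res.resseq, res.icode, atom.name)


def _link_polymer(prev: Residue, res: Residue, link) -> None:
    if prev.category == "amino" and res.category == "amino":
        c, n = prev.atom("C"), res.atom("N")
        if c is not None and n is not None and np.linalg.norm(c.xyz - n.xyz) < 1.8:
            link(_akey(prev, c), _akey(res, n))
    elif prev.category == "nucleotide" and res.category == "nucleotide":
        o3, p = prev.atom("O3'"), res.atom("P")
        if o3 is not None and p is not None and np.linalg.norm(o3.xyz - p.xyz) < 2.0:
            link(_akey(prev, o3), _akey(res, p))


def _within_two_bonds(adj, ka, kb) -> bool:
    na = adj.get(ka, ())
    if kb in na:
        return True
    nb = adj.get(kb, set())
    return any(k in nb for k in na)


# ---------------------------------------------------------------------------
# polar hydrogen placement

def place_polar_hydrogens(s: Structure) -> dict[tuple, list[np.ndarray]]:
    """Donor atom-key -> list of idealised H positions (1.00 A bonds).

    Rotatable donors are returned with an empty list here; their H is
    constructed per-acceptor on the rotor cone by `rotamer_h`.
    Donors with missing antecedents are absent from the mapping and
    fall back to distance-only criteria.
    """
    out: dict[tuple, list[np.ndarray]] = {}
    for chain in s.chains:
        prev: Optional[Residue] = None
        for res in chain.residues:
            if res.category == "amino":
                n = res.atom("N")
                ca = res.atom("CA")
                if (n is not None and ca is not None and res.resname != "PRO"
                        and prev is not None and prev.atom("C") is not None):
                    c_prev = prev.atom("C")
                    d = _unit(n.xyz - c_prev.xyz) + _unit(n.xyz - ca.xyz)
                    out[_akey(res, n)] = [n.xyz + _unit(d)]
                for (rn, an), (hyb, ante, ref, n_h, rot) in SIDECHAIN_DONORS.items():
                    if rn != res.resname:
                        continue
                    donor = res.atom(an)
                    if donor is None:
                        continue
                    if rot:
                        out[_akey(res, donor)] = []   # cone donor
                        continue
                    hs = _fixed_hydrogens(res, donor, ante, ref, n_h)
                    if hs is not None:
                        out[_akey(res, donor)] = hs
            prev = res if res.category == "amino" else None
    return out


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _fixed_hydrogens(res: Residue, donor: Atom, ante: Optional[str],
                     ref: Optional[str], n_h: int) -> Optional[list[np.ndarray]]:
    key = (res.resname, donor.name)
    if key in RING_NEIGHBOURS:
        n1, n2 = RING_NEIGHBOURS[key]
        a1, a2 = res.atom(n1), res.atom(n2)
        if a1 is None or a2 is None:
            return None
        d = _unit(donor.xyz - a1.xyz) + _unit(donor.xyz - a2.xyz)
        return [donor.xyz + _unit(d)]
    a1 = res.atom(ante) if ante else None
    a2 = res.atom(ref) if ref else None
    if a1 is None or a2 is None:
        return None
    # sp2: two H in the a2-a1-donor plane at +-120 deg from the a1 bond
    normal = np.cross(a1.xyz - a2.xyz, donor.xyz - a1.xyz)
    if np.linalg.norm(normal) < 1e-8:
        return None
    normal = _unit(normal)
    u = _unit(donor.xyz - a1.xyz)
    hs = []
    for sign in (1.0, -1.0):
        rot = rotation_matrix(normal, sign * 120.0)
        hs.append(donor.xyz + rot @ u)
        if len(hs) == n_h:
            break
    return hs


def rotamer_h(res: Residue, donor: Atom, acceptor_xyz: np.ndarray) -> Optional[np.ndarray]:
    """Optimal H on the rotor cone of a rotatable donor, toward acceptor."""
    info = SIDECHAIN_DONORS.get((res.resname, donor.name))
    if info is None:
        return None
    hyb, ante, _, _, rot = info
    a1 = res.atom(ante) if ante else None
    if a1 is None:
        return None
    beta = 109.5 if hyb == "sp3" else 120.0
    u = _unit(donor.xyz - a1.xyz)  # rotor axis, pointing away from antecedent
    v = acceptor_xyz - donor.xyz
    v_perp = v - np.dot(v, u) * u
    norm = np.linalg.norm(v_perp)
    if norm < 1e-8:
        # acceptor on the axis: any cone position; pick a deterministic one
        w = _unit(np.cross(u, [1.0, 0.0, 0.0]) if abs(u[0]) < 0.9
                  else np.cross(u, [0.0, 1.0, 0.0]))
    else:
        w = v_perp / norm
    ang = np.radians(180.0 - beta)
    h_dir = np.cos(ang) * u + np.sin(ang) * w
    return donor.xyz + h_dir


# ---------------------------------------------------------------------------
# pair categorisation

def _is_mainchain_atom(res: Residue, atom_name: str) -> bool:
    return res.category == "amino" and atom_name in MAINCHAIN_ATOMS


def categorise_pair(donor_res: Residue, donor_atom: str,
                    acceptor_res: Residue, acceptor_atom: str) -> str:
    cats = {donor_res.category, acceptor_res.category}
    if "ligand" in cats or "metal" in cats:
        return "protein-ligand"
    if "nucleotide" in cats:
        return "protein-dna"
    if donor_res.chain_id != acceptor_res.chain_id:
        return "interchain"
    dm = _is_mainchain_atom(donor_res, donor_atom)
    am = _is_mainchain_atom(acceptor_res, acceptor_atom)
    if dm and am:
        return "mainchain-mainchain"
    if dm or am:
        return "mainchain-sidechain"
    return "sidechain-sidechain"


# ---------------------------------------------------------------------------
# searches

def _atom_table(s: Structure, heavy_only: bool = True):
    refs, coords = [], []
    for res, atom in s.atoms():
        if heavy_only and atom.is_hydrogen:
            continue
        refs.append(AtomRef(res, atom))
        coords.append(atom.xyz)
    return refs, (np.array(coords) if coords else np.zeros((0, 3)))


def find_hbonds(s: Structure, criteria: ContactCriteria = None,
                adjacency=None, hydrogens=None) -> list[HBond]:
    crit = criteria or ContactCriteria()
    adj = adjacency if adjacency is not None else covalent_adjacency(s)
    hpos = hydrogens if hydrogens is not None else place_polar_hydrogens(s)

    donors: list[AtomRef] = []
    acceptors: list[AtomRef] = []
    for res, atom in s.atoms():
        if atom.is_hydrogen:
            continue
        ref = AtomRef(res, atom)
        if is_donor(res, atom):
            donors.append(ref)
        if is_acceptor(res, atom):
            acceptors.append(ref)
    if not donors or not acceptors:
        return []

    acc_coords = np.array([a.atom.xyz for a in acceptors])
    tree = cKDTree(acc_coords)
    out: list[HBond] = []
    for dref in donors:
        dkey = dref.key
        for j in tree.query_ball_point(dref.atom.xyz, crit.d_a_max):
            aref = acceptors[j]
            if aref.residue is dref.residue:
                continue
            akey = aref.key
            if dkey == akey or _within_two_bonds(adj, dkey, akey):
                continue
            d_a = float(np.linalg.norm(dref.atom.xyz - aref.atom.xyz))
            if d_a > crit.d_a_max:
                continue
            hb = _evaluate_geometry(dref, aref, d_a, hpos, crit)
            if hb is not None:
                out.append(hb)
    out.sort(key=lambda h: (h.donor.residue.chain_id, h.donor.residue.resseq,
                            h.donor.residue.icode, h.donor.atom.name,
                            h.acceptor.key))
    return out


def _evaluate_geometry(dref: AtomRef, aref: AtomRef, d_a: float,
                       hpos, crit: ContactCriteria) -> Optional[HBond]:
    dkey = dref.key
    category = categorise_pair(dref.residue, dref.atom.name,
                               aref.residue, aref.atom.name)
    if dkey not in hpos:
        # no constructible H: distance-only criterion
        return HBond(dref, aref, d_a, category=category)
    candidates = hpos[dkey]
    if not candidates:  # rotatable donor: build optimal cone H
        h = rotamer_h(dref.residue, dref.atom, aref.atom.xyz)
        candidates = [h] if h is not None else []
        if not candidates:
            return HBond(dref, aref, d_a, category=category)
    best = None
    for h in candidates:
        h_a = float(np.linalg.norm(h - aref.atom.xyz))
        dha = angle(dref.atom.xyz, h, aref.atom.xyz)
        if h_a <= crit.h_a_max and dha >= crit.dha_min:
            if best is None or h_a < best[0]:
                best = (h_a, dha, h)
    if best is None:
        return None
    return HBond(dref, aref, d_a, h_pos=best[2], h_a=best[0],
                 dha_angle=best[1], category=category)


def find_nonbonded(s: Structure, cutoff: float = None,
                   criteria: ContactCriteria = None,
                   hbonds: Iterable[HBond] = (),
                   adjacency=None) -> list[Contact]:
    crit = criteria or ContactCriteria()
    cut = cutoff if cutoff is not None else crit.nonbonded_max
    adj = adjacency if adjacency is not None else covalent_adjacency(s)
    hb_keys = {hb.pair_key for hb in hbonds}

    refs, coords = _atom_table(s)
    if len(refs) < 2:
        return []
    tree = cKDTree(coords)
    out: list[Contact] = []
    for i, j in tree.query_pairs(cut):
        ra, rb = refs[i], refs[j]
        if ra.residue is rb.residue:
            continue
        if _within_two_bonds(adj, ra.key, rb.key):
            continue
        if frozenset((ra.key, rb.key)) in hb_keys:
            continue
        if ra.key > rb.key:
            ra, rb = rb, ra
        out.append(Contact(ra, rb, float(np.linalg.norm(ra.atom.xyz - rb.atom.xyz))))
    out.sort(key=lambda c: (c.atom_a.key, c.atom_b.key))
    return out


def find_salt_bridges(s: Structure, cutoff: float = None,
                      criteria: ContactCriteria = None) -> list[SaltBridge]:
    crit = criteria or ContactCriteria()
    cut = cutoff if cutoff is not None else crit.salt_bridge_max
    basics, acidics = [], []
    for res, atom in s.atoms():
        if (res.resname, atom.name) in BASIC_ATOMS:
            basics.append(AtomRef(res, atom))
        elif (res.resname, atom.name) in ACIDIC_ATOMS:
            acidics.append(AtomRef(res, atom))
    best: dict[tuple, SaltBridge] = {}
    for b in basics:
        for a in acidics:
            d = float(np.linalg.norm(b.atom.xyz - a.atom.xyz))
            if d <= cut:
                rp = (b.residue.key, a.residue.key)
                if rp not in best or d < best[rp].dist:
                    best[rp] = SaltBridge(b, a, d)
    return sorted(best.values(), key=lambda sb: (sb.basic_atom.key, sb.acidic_atom.key))


def find_metal_contacts(s: Structure, cutoff: float = None,
                        criteria: ContactCriteria = None) -> list[Contact]:
    crit = criteria or ContactCriteria()
    cut = cutoff if cutoff is not None else crit.metal_max
    metals = [AtomRef(res, atom) for res, atom in s.atoms()
              if atom.element in METAL_ELEMENTS]
    out = []
    for m in metals:
        for res, atom in s.atoms():
            if atom is m.atom or atom.element not in ("N", "O", "S"):
                continue
            d = float(np.linalg.norm(m.atom.xyz - atom.xyz))
            if d <= cut:
                out.append(Contact(m, AtomRef(res, atom), d))
    out.sort(key=lambda c: (c.atom_a.key, c.atom_b.key))
    return out


def find_disulphides(s: Structure, criteria: ContactCriteria = None) -> list[Contact]:
    crit = criteria or ContactCriteria()
    sgs = [AtomRef(res, res.atom("SG")) for res in s.residues()
           if res.resname == "CYS" and res.atom("SG") is not None]
    out = []
    for i, a in enumerate(sgs):
        for b in sgs[i + 1:]:
            d = float(np.linalg.norm(a.atom.xyz - b.atom.xyz))
            if d <= crit.ss_bond_max:
                out.append(Contact(a, b, d))
    return out


# ---------------------------------------------------------------------------
# one-shot bundle used by the pipeline

@dataclass
class ContactSet:
    hbonds: list[HBond]
    nonbonded: list[Contact]
    salt_bridges: list[SaltBridge]
    metals: list[Contact]
    disulphides: list[Contact]


def analyse_contacts(s: Structure, criteria: ContactCriteria = None) -> ContactSet:
    crit = criteria or ContactCriteria()
    adj = covalent_adjacency(s)
    hyd = place_polar_hydrogens(s)
    hbonds = find_hbonds(s, crit, adjacency=adj, hydrogens=hyd)
    nonbonded = find_nonbonded(s, criteria=crit, hbonds=hbonds, adjacency=adj)
    return ContactSet(
        hbonds=hbonds,
        nonbonded=nonbonded,
        salt_bridges=find_salt_bridges(s, criteria=crit),
        metals=find_metal_contacts(s, criteria=crit),
        disulphides=find_disulphides(s, crit),
    )


# ---------------------------------------------------------------------------
# tabular output

def _ref_fields(ref: AtomRef) -> list[str]:
    r = ref.residue
    return [r.chain_id, str(r.resseq), r.icode.strip() or "-", r.resname, ref.atom.name]

_PAIR_HEADER = ["chain1", "resseq1", "icode1", "resname1", "atom1",
                "chain2", "resseq2", "icode2", "resname2", "atom2",
                "dist", "angle", "category"]


def hbonds_table(hbonds: list[HBond]) -> str:
    rows = ["\t".join(_PAIR_HEADER)]
    for hb in hbonds:
        ang = f"{hb.dha_angle:.1f}" if hb.dha_angle is not None else "-"
        rows.append("\t".join(_ref_fields(hb.donor) + _ref_fields(hb.acceptor)
                              + [f"{hb.d_a:.2f}", ang, hb.category]))
    return "\n".join(rows) + "\n"


def contacts_table(contacts: list[Contact], category: str = "nonbonded") -> str:
    rows = ["\t".join(_PAIR_HEADER)]
    for c in contacts:
        rows.append("\t".join(_ref_fields(c.atom_a) + _ref_fields(c.atom_b)
                              + [f"{c.dist:.2f}", "-", category]))
    return "\n".join(rows) + "\n"


def salt_bridges_table(bridges: list[SaltBridge]) -> str:
    rows = ["\t".join(_PAIR_HEADER)]
    for sb in bridges:
        rows.append("\t".join(_ref_fields(sb.basic_atom) + _ref_fields(sb.acidic_atom)
                              + [f"{sb.dist:.2f}", "-", "salt-bridge"]))
    return "\n".join(rows) + "\n"
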