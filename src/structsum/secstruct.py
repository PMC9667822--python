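"""Secondary-structure assignment and motif detection.

Assignment follows the Kabsch-Sander hydrogen-bond pattern scheme: the
main-chain amide energy

    E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)  kcal/mol

identifies an N-H...O=C hydrogen bond when E < -0.5, with the amide H
reconstructed from backbone geometry (1.0 A from N, anti to the
preceding carbonyl) even when the file contains hydrogens. n-turn and
bridge patterns then yield helices (H/G/I), strands (E), isolated
bridges (B), turns (T) and bends (S). Sheets are the transitive
closure of ladder links, labelled A, B, ... by size then order.

Motif detectors cover beta turns (Hutchinson-Thornton classes), gamma
turns, hairpins, bulges, beta-alpha-beta units, psi-loops and
helix-helix packing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from structsum.geometry import DihedralUndefined, angle, dihedral
from structsum.pdb_io import Residue, Structure

HB_ENERGY_CUTOFF = -0.5   # kcal/mol
Q_FACTOR = 0.084 * 332.0  # electrostatic prefactor of the amide energy

HELICAL_STATES = {"H", "G", "I"}

# Hutchinson-Thornton ideal central torsions per beta-turn class:
# class -> ((phi_i+1, psi_i+1), (phi_i+2, psi_i+2), requires cis-Pro at i+2)
TURN_CLASS_TABLE: dict[str, tuple[tuple[float, float], tuple[float, float], bool]] = {
    "I":    ((-60.0, -30.0), (-90.0, 0.0), False),
    "I'":   ((60.0, 30.0), (90.0, 0.0), False),
    "II":   ((-60.0, 120.0), (80.0, 0.0), False),
    "II'":  ((60.0, -120.0), (-80.0, 0.0), False),
    "VIII": ((-60.0, -30.0), (-120.0, 120.0), False),
    "VIa1": ((-60.0, 120.0), (-90.0, 0.0), True),
    "VIa2": ((-120.0, 120.0), (-60.0, 0.0), True),
    "VIb":  ((-135.0, 135.0), (-75.0, 160.0), True),
}
TURN_CLASS_ORDER = ["I", "I'", "II", "II'", "VIII", "VIa1", "VIa2", "VIb"]

GAMMA_CLASSIC_IDEAL = (75.0, -64.0)
GAMMA_INVERSE_IDEAL = (-79.0, 69.0)
GAMMA_TOL = 40.0


# ---------------------------------------------------------------------------
# backbone bookkeeping

@dataclass
class BackboneResidue:
    """A protein residue with complete backbone, in global order."""

    index: int
    residue: Residue
    n: np.ndarray
    ca: np.ndarray
    c: np.ndarray
    o: np.ndarray
    h: Optional[np.ndarray] = None     # reconstructed amide H
    chain_break_before: bool = False

    @property
    def key(self):
        return self.residue.key


def backbone_table(s: Structure) -> list[BackboneResidue]:
    out: list[BackboneResidue] = []
    idx = 0
    for chain in s.chains:
        prev: Optional[BackboneResidue] = None
        for res in chain.residues:
            if res.category != "amino":
                prev = None
                continue
            atoms = {nm: res.atom(nm) for nm in ("N", "CA", "C", "O")}
            if any(a is None for a in atoms.values()):
                prev = None
                continue
            bb = BackboneResidue(
                index=idx, residue=res,
                n=atoms["N"].xyz, ca=atoms["CA"].xyz,
                c=atoms["C"].xyz, o=atoms["O"].xyz,
            )
            linked = (
                prev is not None
                and np.linalg.norm(prev.c - bb.n) < 2.5
            )
            bb.chain_break_before = not linked
            if linked and res.resname != "PRO":
                co = prev.c - prev.o
                bb.h = bb.n + co / np.linalg.norm(co)
            out.append(bb)
            prev = bb
            idx += 1
    return out


def mainchain_hbond_energy(donor: BackboneResidue, acceptor: BackboneResidue) -> Optional[float]:
    """Kabsch-Sander amide energy of N-H(donor) ... O=C(acceptor), kcal/mol.

    None when the donor has no amide hydrogen (Pro, segment start).
    """
    if donor.h is None:
        return None
    r_on = np.linalg.norm(acceptor.o - donor.n)
    r_ch = np.linalg.norm(acceptor.c - donor.h)
    r_oh = np.linalg.norm(acceptor.o - donor.h)
    r_cn = np.linalg.norm(acceptor.c - donor.n)
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:
        return None  # colliding atoms: meaningless
    return Q_FACTOR * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def _hbond_matrix(bb: list[BackboneResidue]) -> np.ndarray:
    """hb[i, j] true iff NH(i) donates to CO(j) with E < -0.5, |i-j| >= 2."""
    n = len(bb)
    hb = np.zeros((n, n), dtype=bool)
    if n == 0:
        return hb
    coords = np.array([r.ca for r in bb])
    from scipy.spatial import cKDTree

    tree = cKDTree(coords)
    pairs = tree.query_pairs(9.0)  # CA-CA prefilter; amide bonds are < 5.2 A
    for i, j in pairs:
        for a, b in ((i, j), (j, i)):
            if abs(bb[a].index - bb[b].index) < 2:
                continue
            e = mainchain_hbond_energy(bb[a], bb[b])
            if e is not None and e < HB_ENERGY_CUTOFF:
                hb[a, b] = True
    return hb


# ---------------------------------------------------------------------------
# assignment result containers

@dataclass
class Strand:
    strand_id: int
    keys: list
    sheet_id: str = ""
    chain_id: str = ""


@dataclass
class Helix:
    helix_id: str
    keys: list
    chain_id: str = ""
    kind: str = "H"


@dataclass
class Ladder:
    strand_a: int
    strand_b: int
    kind: str                      # parallel | antiparallel
    bridges: list = field(default_factory=list)  # (index_a, index_b) pairs


@dataclass
class SSAssignment:
    backbone: list[BackboneResidue]
    state: dict
    helix_id: dict
    strand_id: dict
    sheet_id: dict
    helices: list[Helix]
    strands: list[Strand]
    ladders: list[Ladder]
    hb: np.ndarray

    def state_of(self, res: Residue) -> str:
        return self.state.get(res.key, "-")

    def states_in_order(self) -> list[tuple]:
        return [(bb.key, self.state.get(bb.key, "-")) for bb in self.backbone]


def assign_secondary_structure(s: Structure) -> SSAssignment:
    bb = backbone_table(s)
    n = len(bb)
    hb = _hbond_matrix(bb)
    state = {r.key: "-" for r in bb}

    def linked(i, j):
        """Residues i..j are one unbroken segment of one chain."""
        return all(not bb[k].chain_break_before for k in range(i + 1, j + 1))

    # n-turns: NH(i+k) -> CO(i)
    turns: dict[int, set[int]] = {3: set(), 4: set(), 5: set()}
    for k in (3, 4, 5):
        for i in range(n - k):
            if hb[i + k, i] and linked(i, i + k):
                turns[k].add(i)

    raw = [" "] * n
    # helices from two consecutive n-turns (minimal DSSP patterns)
    for kind, k in (("H", 4), ("G", 3), ("I", 5)):
        for i in range(1, n - k):
            if i - 1 in turns[k] and i in turns[k]:
                for m in range(i, i + k):
                    if raw[m] == " " or raw[m] == kind:
                        raw[m] = kind

    # bridges (Kabsch-Sander patterns); Hbond(a, b) = CO(a)...HN(b) = hb[b, a]
    def hbond(a, b):
        return 0 <= a < n and 0 <= b < n and hb[b, a]

    bridges: dict[tuple[int, int], str] = {}
    for i in range(1, n - 1):
        for j in range(i + 3, n - 1):
            para = (hbond(i - 1, j) and hbond(j, i + 1)) or (
                hbond(j - 1, i) and hbond(i, j + 1)
            )
            anti = (hbond(i, j) and hbond(j, i)) or (
                hbond(i - 1, j + 1) and hbond(j - 1, i + 1)
            )
            if para:
                bridges[(i, j)] = "parallel"
            elif anti:
                bridges[(i, j)] = "antiparallel"

    # ladders: consecutive bridges of one type
    ladder_of: dict[tuple[int, int], int] = {}
    ladders: list[Ladder] = []
    for (i, j), kind in sorted(bridges.items()):
        placed = False
        for lid, lad in enumerate(ladders):
            if lad.kind != kind:
                continue
            li, lj = lad.bridges[-1]
            step_ok = (
                (kind == "parallel" and i - li == 1 and j - lj == 1)
                or (kind == "antiparallel" and i - li == 1 and lj - j == 1)
            )
            if step_ok:
                lad.bridges.append((i, j))
                ladder_of[(i, j)] = lid
                placed = True
                break
        if not placed:
            ladders.append(Ladder(strand_a=-1, strand_b=-1, kind=kind, bridges=[(i, j)]))
            ladder_of[(i, j)] = len(ladders) - 1

    bridge_residues = sorted({i for ij in bridges for i in ij})
    extended = {i for lad in ladders if len(lad.bridges) >= 2 for ij in lad.bridges for i in ij}
    for i in bridge_residues:
        mark = "E" if i in extended else "B"
        if raw[i] in (" ", "B", "E", "T", "S"):
            raw[i] = mark
        elif raw[i] in ("G", "I"):   # extended pattern outranks 3/5-turn helix
            raw[i] = mark

    # turns (T) and bends (S) on whatever is left
    for k in (3, 4, 5):
        for i in turns[k]:
            for m in range(i + 1, i + k):
                if raw[m] == " ":
                    raw[m] = "T"
    for i in range(2, n - 2):
        if raw[i] == " " and linked(i - 2, i + 2):
            kappa = angle(bb[i - 2].ca, bb[i].ca, bb[i + 2].ca)
            if 180.0 - kappa > 70.0:
                raw[i] = "S"

    for i, r in enumerate(bb):
        state[r.key] = raw[i] if raw[i] != " " else "-"

    # --- strands and sheets -------------------------------------------------
    strands: list[Strand] = []
    strand_of_res: dict[int, int] = {}
    i = 0
    while i < n:
        if raw[i] == "E":
            j = i
            while j + 1 < n and raw[j + 1] == "E" and not bb[j + 1].chain_break_before:
                j += 1
            sid = len(strands)
            strands.append(Strand(strand_id=sid,
                                  keys=[bb[m].key for m in range(i, j + 1)],
                                  chain_id=bb[i].residue.chain_id))
            for m in range(i, j + 1):
                strand_of_res[m] = sid
            i = j + 1
        else:
            i += 1

    for lad in ladders:
        ia, ja = lad.bridges[0]
        lad.strand_a = strand_of_res.get(ia, -1)
        lad.strand_b = strand_of_res.get(ja, -1)

    # sheets: union-find over strands linked by ladders
    parent = list(range(len(strands)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for lad in ladders:
        if lad.strand_a >= 0 and lad.strand_b >= 0:
            ra, rb = find(lad.strand_a), find(lad.strand_b)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)

    groups: dict[int, list[int]] = {}
    for sid in range(len(strands)):
        groups.setdefault(find(sid), []).append(sid)
    # label sheets by residue count (desc), ties by first strand index
    ordered = sorted(groups.values(),
                     key=lambda g: (-sum(len(strands[s].keys) for s in g), min(g)))
    for gi, group in enumerate(ordered):
        label = _sheet_label(gi)
        for sid in group:
            strands[sid].sheet_id = label

    sheet_id = {}
    strand_id = {}
    for st in strands:
        for key in st.keys:
            strand_id[key] = st.strand_id
            sheet_id[key] = st.sheet_id

    # --- helices ------------------------------------------------------------
    helices: list[Helix] = []
    helix_id: dict = {}
    count = 0
    i = 0
    while i < n:
        if raw[i] == "H":
            j = i
            while j + 1 < n and raw[j + 1] == "H" and not bb[j + 1].chain_break_before:
                j += 1
            if j - i + 1 >= 4:
                count += 1
                hid = f"H{count}"
                keys = [bb[m].key for m in range(i, j + 1)]
                helices.append(Helix(helix_id=hid, keys=keys,
                                     chain_id=bb[i].residue.chain_id))
                for key in keys:
                    helix_id[key] = hid
            i = j + 1
        else:
            i += 1

    return SSAssignment(backbone=bb, state=state, helix_id=helix_id,
                        strand_id=strand_id, sheet_id=sheet_id,
                        helices=helices, strands=strands, ladders=ladders, hb=hb)


def _sheet_label(i: int) -> str:
    label = ""
    i += 1
    while i > 0:
        i, rem = divmod(i - 1, 26)
        label = chr(ord("A") + rem) + label
    return label


# ---------------------------------------------------------------------------
# beta turns

@dataclass
class BetaTurn:
    keys: list                      # residues i..i+3
    turn_class: str
    phi_psi: tuple                  # (phi1, psi1, phi2, psi2)
    chain_id: str


def _ang_diff(a: float, b: float) -> float:
    d = (a - b) % 360.0
    return min(d, 360.0 - d)


def classify_beta_turn(phi1: float, psi1: float, phi2: float, psi2: float,
                       cis_pro_2: bool = False) -> str:
    """Assign the Hutchinson-Thornton class of a beta turn.

    A class matches when all four central torsions are within 30 deg of
    its ideals, except that a single torsion may deviate up to 45 deg.
    cis-Pro classes (VIa1/VIa2/VIb) additionally require a cis proline
    at position i+2. Anything else is class IV.
    """
    values = (phi1, psi1, phi2, psi2)
    for name in TURN_CLASS_ORDER:
        (p1, s1), (p2, s2), needs_cis = TURN_CLASS_TABLE[name]
        if needs_cis and not cis_pro_2:
            continue
        devs = [_ang_diff(v, ideal) for v, ideal in zip(values, (p1, s1, p2, s2))]
        over30 = [d for d in devs if d > 30.0]
        if not over30 or (len(over30) == 1 and over30[0] <= 45.0):
            return name
    return "IV"


def find_beta_turns(s: Structure, ss: SSAssignment) -> list[BetaTurn]:
    """All i..i+3 windows with CA(i)-CA(i+3) < 7 A whose central pair is
    not fully helical, classified by their central torsions."""
    bb = ss.backbone
    out: list[BetaTurn] = []
    for i in range(len(bb) - 3):
        window = bb[i:i + 4]
        if any(w.chain_break_before for w in window[1:]):
            continue
        if np.linalg.norm(window[0].ca - window[3].ca) >= 7.0:
            continue
        s1 = ss.state.get(window[1].key, "-")
        s2 = ss.state.get(window[2].key, "-")
        if s1 in HELICAL_STATES and s2 in HELICAL_STATES:
            continue
        try:
            phi1 = dihedral(window[0].c, window[1].n, window[1].ca, window[1].c)
            psi1 = dihedral(window[1].n, window[1].ca, window[1].c, window[2].n)
            phi2 = dihedral(window[1].c, window[2].n, window[2].ca, window[2].c)
            psi2 = dihedral(window[2].n, window[2].ca, window[2].c, window[3].n)
        except DihedralUndefined:
            continue
        cis_pro = False
        if window[2].residue.resname == "PRO":
            try:
                omega = dihedral(window[1].ca, window[1].c, window[2].n, window[2].ca)
                cis_pro = abs(omega) < 30.0
            except DihedralUndefined:
                pass
        out.append(BetaTurn(
            keys=[w.key for w in window],
            turn_class=classify_beta_turn(phi1, psi1, phi2, psi2, cis_pro),
            phi_psi=(phi1, psi1, phi2, psi2),
            chain_id=window[0].residue.chain_id,
        ))
    out.sort(key=lambda t: (t.chain_id, t.keys[0][1], t.keys[0][2]))
    return out


# ---------------------------------------------------------------------------
# gamma turns

@dataclass
class GammaTurn:
    keys: list         # residues i..i+2
    subtype: str       # classic | inverse
    phi_psi: tuple


def find_gamma_turns(s: Structure, ss: SSAssignment, hbonds) -> list[GammaTurn]:
    """i..i+2 windows closed by a CO(i)...NH(i+2) hydrogen bond, with
    the central torsions in the classic or inverse window (+-40 deg)."""
    donor_acceptor = set()
    for hbond in hbonds:
        donor_acceptor.add((hbond.donor.residue.key, hbond.donor.atom.name,
                            hbond.acceptor.residue.key, hbond.acceptor.atom.name))
    bb = ss.backbone
    out = []
    for i in range(len(bb) - 2):
        w = bb[i:i + 3]
        if any(x.chain_break_before for x in w[1:]):
            continue
        if (w[2].key, "N", w[0].key, "O") not in donor_acceptor:
            continue
        try:
            phi = dihedral(w[0].c, w[1].n, w[1].ca, w[1].c)
            psi = dihedral(w[1].n, w[1].ca, w[1].c, w[2].n)
        except DihedralUndefined:
            continue
        if _ang_diff(phi, GAMMA_CLASSIC_IDEAL[0]) <= GAMMA_TOL and \
           _ang_diff(psi, GAMMA_CLASSIC_IDEAL[1]) <= GAMMA_TOL:
            subtype = "classic"
        elif _ang_diff(phi, GAMMA_INVERSE_IDEAL[0]) <= GAMMA_TOL and \
             _ang_diff(psi, GAMMA_INVERSE_IDEAL[1]) <= GAMMA_TOL:
            subtype = "inverse"
        else:
            continue
        out.append(GammaTurn(keys=[x.key for x in w], subtype=subtype,
                             phi_psi=(phi, psi)))
    return out


# ---------------------------------------------------------------------------
# sheet motifs

@dataclass
class Hairpin:
    strand_a: int
    strand_b: int
    loop_keys: list


@dataclass
class Bulge:
    ladder_kind: str
    long_side: list    # 2 residue keys on the bulged strand
    short_side: list   # 1 residue key opposite


@dataclass
class BetaAlphaBeta:
    strand_a: int
    strand_b: int
    helix_ids: list


@dataclass
class PsiLoop:
    strand_a: int
    strand_b: int


@dataclass
class HelixPacking:
    helix_a: str
    helix_b: str
    omega: float       # signed interhelix packing angle, degrees
    distance: float    # closest approach of the axis segments, A


def _strand_span(ss: SSAssignment, sid: int) -> tuple[int, int]:
    idx = [bb.index for bb in ss.backbone if ss.strand_id.get(bb.key) == sid]
    return min(idx), max(idx)


def find_hairpins(ss: SSAssignment) -> list[Hairpin]:
    """Consecutive antiparallel strands of one sheet and their loop."""
    out = []
    for lad in ss.ladders:
        if lad.kind != "antiparallel" or lad.strand_a < 0 or lad.strand_b < 0:
            continue
        sa, sb = sorted((lad.strand_a, lad.strand_b))
        if sb != sa + 1:
            continue
        st_a, st_b = ss.strands[sa], ss.strands[sb]
        if st_a.sheet_id != st_b.sheet_id or st_a.chain_id != st_b.chain_id:
            continue
        _, end_a = _strand_span(ss, sa)
        start_b, _ = _strand_span(ss, sb)
        loop = [ss.backbone[m].key for m in range(end_a + 1, start_b)]
        out.append(Hairpin(strand_a=sa, strand_b=sb, loop_keys=loop))
    return out


def find_bulges(ss: SSAssignment, hbonds=None) -> list[Bulge]:
    """Ladder positions where one strand contributes two residues
    against one on the partner strand (irregular rung step)."""
    out = []
    for lad in ss.ladders:
        for (i1, j1), (i2, j2) in zip(lad.bridges, lad.bridges[1:]):
            di = i2 - i1
            dj = (j2 - j1) if lad.kind == "parallel" else (j1 - j2)
            if di == 1 and dj == 1:
                continue
            if di == 2 and dj == 1:
                out.append(Bulge(lad.kind,
                                 [ss.backbone[i1].key, ss.backbone[i2].key],
                                 [ss.backbone[j1].key]))
            elif di == 1 and dj == 2:
                out.append(Bulge(lad.kind,
                                 [ss.backbone[j1].key, ss.backbone[j2].key],
                                 [ss.backbone[i1].key]))
    return out


def find_beta_alpha_beta(ss: SSAssignment) -> list[BetaAlphaBeta]:
    """Parallel strand pairs of one sheet with >= 1 helix between them."""
    out = []
    seen = set()
    for lad in ss.ladders:
        if lad.kind != "parallel" or lad.strand_a < 0 or lad.strand_b < 0:
            continue
        sa, sb = sorted((lad.strand_a, lad.strand_b))
        if (sa, sb) in seen:
            continue
        seen.add((sa, sb))
        st_a, st_b = ss.strands[sa], ss.strands[sb]
        if st_a.sheet_id != st_b.sheet_id or st_a.chain_id != st_b.chain_id:
            continue
        _, end_a = _strand_span(ss, sa)
        start_b, _ = _strand_span(ss, sb)
        between = [h.helix_id for h in ss.helices
                   if h.keys and _helix_between(ss, h, end_a, start_b)]
        if between:
            out.append(BetaAlphaBeta(strand_a=sa, strand_b=sb, helix_ids=between))
    return out


def _helix_between(ss: SSAssignment, helix: Helix, lo: int, hi: int) -> bool:
    idx = [bb.index for bb in ss.backbone if ss.helix_id.get(bb.key) == helix.helix_id]
    return bool(idx) and min(idx) > lo and max(idx) < hi


def find_psi_loops(ss: SSAssignment) -> list[PsiLoop]:
    """Antiparallel strand pairs adjacent in the sheet but far apart in
    sequence (> 10 residues) with an intervening strand in sequence."""
    out = []
    for lad in ss.ladders:
        if lad.kind != "antiparallel" or lad.strand_a < 0 or lad.strand_b < 0:
            continue
        sa, sb = sorted((lad.strand_a, lad.strand_b))
        st_a, st_b = ss.strands[sa], ss.strands[sb]
        if st_a.chain_id != st_b.chain_id:
            continue
        _, end_a = _strand_span(ss, sa)
        start_b, _ = _strand_span(ss, sb)
        if start_b - end_a <= 10:
            continue
        if any(sa < mid < sb for mid in range(len(ss.strands))
               if ss.strands[mid].chain_id == st_a.chain_id):
            out.append(PsiLoop(strand_a=sa, strand_b=sb))
    return out


# ---------------------------------------------------------------------------
# helix packing

def _helix_axis(ss: SSAssignment, helix: Helix):
    cas = np.array([bb.ca for bb in ss.backbone if bb.key in set(helix.keys)])
    centroid = cas.mean(axis=0)
    _, _, vt = np.linalg.svd(cas - centroid)
    axis = vt[0]
    if np.dot(cas[-1] - cas[0], axis) < 0:
        axis = -axis
    ts = (cas - centroid) @ axis
    return centroid, axis, ts.min(), ts.max()


def _segment_closest(p1, d1, t1lo, t1hi, p2, d2, t2lo, t2hi):
    """Closest points of two finite axis segments."""
    # parametric closest approach of the infinite lines, clamped
    w0 = p1 - p2
    a = np.dot(d1, d1)
    b = np.dot(d1, d2)
    c = np.dot(d2, d2)
    d = np.dot(d1, w0)
    e = np.dot(d2, w0)
    denom = a * c - b * b
    if abs(denom) < 1e-10:
        s = 0.0
        t = e / c if c > 0 else 0.0
    else:
        s = (b * e - c * d) / denom
        t = (a * e - b * d) / denom
    s = float(np.clip(s, t1lo, t1hi))
    t = float(np.clip(t, t2lo, t2hi))
    q1 = p1 + s * d1
    q2 = p2 + t * d2
    return q1, q2, float(np.linalg.norm(q1 - q2))


def find_helix_interactions(s: Structure, ss: SSAssignment,
                            cutoff: float = 10.0) -> list[HelixPacking]:
    """Helix pairs whose axes approach within *cutoff* angstroms.

    Omega is the signed torsion angle between the two axis vectors
    about their closest-approach vector, in (-180, 180]; positive for
    right-handed packing. Near 0: parallel; near +-180: antiparallel.
    """
    out = []
    axes = []
    for h in ss.helices:
        if len(h.keys) >= 4:
            axes.append((h, *_helix_axis(ss, h)))
    for ai in range(len(axes)):
        for bi in range(ai + 1, len(axes)):
            ha, pa, da, alo, ahi = axes[ai]
            hb_, pb, db, blo, bhi = axes[bi]
            q1, q2, dist = _segment_closest(pa, da, alo, ahi, pb, db, blo, bhi)
            if dist > cutoff:
                continue
            u = q2 - q1
            nu = np.linalg.norm(u)
            if nu < 1e-6:
                omega = float(np.degrees(np.arccos(np.clip(np.dot(da, db), -1, 1))))
            else:
                u = u / nu
                x = np.dot(da, db) - np.dot(da, u) * np.dot(db, u)
                y = np.dot(np.cross(da, db), u)
                omega = float(np.degrees(np.arctan2(y, x)))
            out.append(HelixPacking(helix_a=ha.helix_id, helix_b=hb_.helix_id,
                                    omega=omega, distance=dist))
    return out


# ---------------------------------------------------------------------------
# tables and wiring-diagram data

def secstruct_table(ss: SSAssignment) -> str:
    rows = ["chain\tresseq\ticode\tresname\tstate\thelix\tstrand\tsheet"]
    for bb in ss.backbone:
        key = bb.key
        rows.append("\t".join([
            bb.residue.chain_id, str(bb.residue.resseq),
            bb.residue.icode.strip() or "-", bb.residue.resname,
            ss.state.get(key, "-"),
            ss.helix_id.get(key, "-"),
            str(ss.strand_id[key]) if key in ss.strand_id else "-",
            ss.sheet_id.get(key, "-"),
        ]))
    return "\n".join(rows) + "\n"


def turns_table(turns: list[BetaTurn]) -> str:
    rows = ["chain\tstart\tend\tclass\tphi1\tpsi1\tphi2\tpsi2"]
    for t in turns:
        rows.append("\t".join([
            t.chain_id, str(t.keys[0][1]), str(t.keys[3][1]), t.turn_class,
            *(f"{v:.1f}" for v in t.phi_psi),
        ]))
    return "\n".join(rows) + "\n"


def wiring_diagram_data(s: Structure, ss: SSAssignment,
                        turns: list[BetaTurn],
                        gammas: list[GammaTurn],
                        ligand_contact_keys: Iterable = ()) -> dict:
    """JSON-serialisable data behind the sequence/secondary-structure
    wiring diagram: per-residue state with helix/sheet labels plus turn
    and ligand-contact markers."""
    lig_keys = {tuple(k) for k in ligand_contact_keys}
    per_chain: dict[str, list[dict]] = {}
    for bb in ss.backbone:
        key = bb.key
        per_chain.setdefault(bb.residue.chain_id, []).append({
            "resseq": bb.residue.resseq,
            "icode": bb.residue.icode.strip(),
            "resname": bb.residue.resname,
            "state": ss.state.get(key, "-"),
            "helix": ss.helix_id.get(key),
            "sheet": ss.sheet_id.get(key),
            "ligand_contact": key in lig_keys,
        })
    return {
        "chains": per_chain,
        "beta_turns": [
            {"chain": t.chain_id, "start": t.keys[0][1], "end": t.keys[3][1],
             "class": t.turn_class}
            for t in turns
        ],
        "gamma_turns": [
            {"chain": g.keys[0][0], "start": g.keys[0][1], "end": g.keys[2][1],
             "subtype": g.subtype}
            for g in gammas
        ],
    }
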