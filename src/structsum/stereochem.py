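"""Stereochemical quality analysis.

Covers main-chain and side-chain torsions, Ramachandran region
classification, bond-length/angle/planarity deviations from ideal
geometry, log-odds G-factors, and the per-residue property profile.

The Ramachandran region grid (10 x 10 degree cells, four categories,
separate general/Gly/Pro variants) and the reference torsion
histograms behind the G-factors are generated from smooth circular
Gaussian mixtures centred on the canonical conformational basins and
thresholded at fixed area fractions. They are data, versioned by this
module, and swappable; no claim of cell-for-cell identity with any
other program's grids is made.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from structsum.geometry import DihedralUndefined, angle, best_fit_plane, dihedral
from structsum.pdb_io import Residue, Structure
from structsum.config import StereoThresholds

# --- Engh-Huber ideal main-chain geometry ----------------------------------
IDEAL_BONDS = {
    ("N", "CA"): 1.458,
    ("CA", "C"): 1.525,
    ("C", "O"): 1.231,
    ("CA", "CB"): 1.530,
}
IDEAL_PEPTIDE_BOND = 1.329   # C(i)-N(i+1)
IDEAL_ANGLES = {
    ("N", "CA", "C"): 111.2,
    ("CA", "C", "O"): 120.8,
    ("N", "CA", "CB"): 110.4,
    ("CB", "CA", "C"): 110.1,
}
IDEAL_PEPTIDE_ANGLES = {
    ("CA", "C", "N+"): 116.2,
    ("O", "C", "N+"): 123.0,
    ("C-", "N", "CA"): 121.7,
}

ZETA_IDEAL = 33.9   # CA-N-C-CB virtual torsion of an L-residue

# side-chain chi atom quadruples
CHI_ATOMS: dict[str, list[tuple[str, str, str, str]]] = {
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "CYS": [("N", "CA", "CB", "SG")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "PRO": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")],
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "VAL": [("N", "CA", "CB", "CG1")],
}

# planar side-chain groups: residue -> (atom names, is_ring)
PLANAR_GROUPS: dict[str, tuple[list[str], bool]] = {
    "PHE": (["CG", "CD1", "CD2", "CE1", "CE2", "CZ"], True),
    "TYR": (["CG", "CD1", "CD2", "CE1", "CE2", "CZ"], True),
    "TRP": (["CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"], True),
    "HIS": (["CG", "ND1", "CD2", "CE1", "NE2"], True),
    "ARG": (["CD", "NE", "CZ", "NH1", "NH2"], False),
    "ASP": (["CB", "CG", "OD1", "OD2"], False),
    "GLU": (["CG", "CD", "OE1", "OE2"], False),
    "ASN": (["CB", "CG", "OD1", "ND2"], False),
    "GLN": (["CG", "CD", "OE1", "NE2"], False),
}


@dataclass
class TorsionSet:
    key: tuple                      # (chain, resseq, icode)
    resname: str
    phi: Optional[float] = None
    psi: Optional[float] = None
    omega: Optional[float] = None
    chi: list = field(default_factory=list)   # chi1..chi4 (present entries only)
    zeta: Optional[float] = None

    @property
    def chi1(self) -> Optional[float]:
        return self.chi[0] if self.chi else None


def _safe_dihedral(*pts) -> Optional[float]:
    try:
        return dihedral(*pts)
    except DihedralUndefined:
        return None


def compute_torsions(chain_residues: Iterable[Residue]) -> list[TorsionSet]:
    """Backbone and side-chain torsions for one chain's amino residues.

    A torsion whose defining atoms are missing is left undefined,
    never zeroed. Omega of residue i uses CA(i-1)-C(i-1)-N(i)-CA(i).
    """
    residues = [r for r in chain_residues if r.category == "amino"]
    out: list[TorsionSet] = []
    for i, res in enumerate(residues):
        ts = TorsionSet(key=res.key, resname=res.resname)
        n, ca, c, cb = (res.atom(x) for x in ("N", "CA", "C", "CB"))
        prev = residues[i - 1] if i > 0 else None
        nxt = residues[i + 1] if i + 1 < len(residues) else None
        if prev is not None and not _peptide_linked(prev, res):
            prev = None
        if nxt is not None and not _peptide_linked(res, nxt):
            nxt = None
        if prev is not None and all(x is not None for x in (n, ca, c)):
            pc = prev.atom("C")
            pca = prev.atom("CA")
            if pc is not None:
                ts.phi = _safe_dihedral(pc.xyz, n.xyz, ca.xyz, c.xyz)
                if pca is not None:
                    ts.omega = _safe_dihedral(pca.xyz, pc.xyz, n.xyz, ca.xyz)
        if nxt is not None and all(x is not None for x in (n, ca, c)):
            nn = nxt.atom("N")
            if nn is not None:
                ts.psi = _safe_dihedral(n.xyz, ca.xyz, c.xyz, nn.xyz)
        if all(x is not None for x in (n, ca, c, cb)):
            ts.zeta = _safe_dihedral(ca.xyz, n.xyz, c.xyz, cb.xyz)
        for quad in CHI_ATOMS.get(res.resname, []):
            atoms = [res.atom(nm) for nm in quad]
            if any(a is None for a in atoms):
                break
            chi = _safe_dihedral(*(a.xyz for a in atoms))
            if chi is None:
                break
            ts.chi.append(chi)
        out.append(ts)
    return out


def compute_structure_torsions(s: Structure) -> list[TorsionSet]:
    out = []
    for chain in s.chains:
        out.extend(compute_torsions(chain.residues))
    return out


def _peptide_linked(prev: Residue, res: Residue) -> bool:
    c, n = prev.atom("C"), res.atom("N")
    return c is not None and n is not None and float(np.linalg.norm(c.xyz - n.xyz)) < 2.5


# ---------------------------------------------------------------------------
# Ramachandran region grid

GRID_STEP = 10
GRID_N = 36
REGIONS = ("core", "allowed", "generous", "disallowed")
# cumulative area fractions: top 12% of cells by density are core, the
# next 18% allowed, the next 25% generous, the remaining 45% disallowed
_AREA_FRACTIONS = (0.12, 0.30, 0.55)

# circular Gaussian mixture components per residue class:
# (weight, phi0, psi0, sigma_phi, sigma_psi)
_MIXTURES = {
    "general": [
        (0.42, -63.0, -43.0, 24.0, 24.0),    # alpha
        (0.12, -90.0, -10.0, 25.0, 30.0),    # alpha basin shoulder
        (0.30, -120.0, 130.0, 28.0, 32.0),   # beta
        (0.10, -65.0, 145.0, 22.0, 25.0),    # polyproline II
        (0.06, 55.0, 40.0, 18.0, 18.0),      # left-handed alpha
    ],
    "gly": [
        (0.23, -63.0, -43.0, 26.0, 26.0),
        (0.23, 63.0, 43.0, 26.0, 26.0),
        (0.17, -120.0, 130.0, 30.0, 34.0),
        (0.17, 120.0, -130.0, 30.0, 34.0),
        (0.10, -85.0, 170.0, 25.0, 30.0),
        (0.10, 85.0, -170.0, 25.0, 30.0),
    ],
    "pro": [
        (0.50, -63.0, -35.0, 14.0, 22.0),
        (0.50, -63.0, 145.0, 14.0, 25.0),
    ],
}


def _wrap_delta(a: np.ndarray, b: float) -> np.ndarray:
    d = (a - b + 180.0) % 360.0 - 180.0
    return d


def _density_grid(resclass: str) -> np.ndarray:
    centers = np.arange(-175.0, 180.0, GRID_STEP)
    phi, psi = np.meshgrid(centers, centers, indexing="ij")
    dens = np.zeros_like(phi)
    for w, p0, s0, sp, ss_ in _MIXTURES[resclass]:
        dp = _wrap_delta(phi, p0)
        ds = _wrap_delta(psi, s0)
        dens += w * np.exp(-0.5 * ((dp / sp) ** 2 + (ds / ss_) ** 2))
    return dens


def _region_grid(resclass: str) -> np.ndarray:
    """36x36 int grid: 0 core, 1 allowed, 2 generous, 3 disallowed."""
    dens = _density_grid(resclass)
    flat = np.sort(dens.ravel())[::-1]
    ncells = flat.size
    thresholds = [flat[int(f * ncells) - 1] for f in _AREA_FRACTIONS]
    grid = np.full(dens.shape, 3, dtype=int)
    grid[dens >= thresholds[2]] = 2
    grid[dens >= thresholds[1]] = 1
    grid[dens >= thresholds[0]] = 0
    return grid


_REGION_CACHE: dict[str, np.ndarray] = {}
_DENSITY_CACHE: dict[str, np.ndarray] = {}


def region_grid(resclass: str) -> np.ndarray:
    if resclass not in _REGION_CACHE:
        _REGION_CACHE[resclass] = _region_grid(resclass)
    return _REGION_CACHE[resclass]


def _density(resclass: str) -> np.ndarray:
    if resclass not in _DENSITY_CACHE:
        _DENSITY_CACHE[resclass] = _density_grid(resclass)
    return _DENSITY_CACHE[resclass]


def res_class(resname: str) -> str:
    if resname == "GLY":
        return "gly"
    if resname == "PRO":
        return "pro"
    return "general"


def _cell(value: float) -> int:
    # half-open [lo, hi) cells over [-180, 180)
    v = value
    if v >= 180.0:
        v -= 360.0
    if v < -180.0:
        v += 360.0
    idx = int(math.floor((v + 180.0) / GRID_STEP))
    return min(max(idx, 0), GRID_N - 1)


def ramachandran_region(phi: float, psi: float, resclass: str = "general") -> str:
    """Region of the (phi, psi) cell: core/allowed/generous/disallowed."""
    grid = region_grid(resclass)
    return REGIONS[grid[_cell(phi), _cell(psi)]]


def ramachandran_counts(torsions: Iterable[TorsionSet]) -> dict[str, int]:
    counts = {r: 0 for r in REGIONS}
    for ts in torsions:
        if ts.phi is None or ts.psi is None:
            continue
        counts[ramachandran_region(ts.phi, ts.psi, res_class(ts.resname))] += 1
    return counts


# ---------------------------------------------------------------------------
# geometry deviations

@dataclass
class GeometryDeviation:
    kind: str                 # bond-length | bond-angle | planarity
    key: tuple
    resname: str
    atoms: tuple
    actual: float
    ideal: float
    threshold: float


def check_geometry(s: Structure, thresholds: StereoThresholds = None) -> list[GeometryDeviation]:
    """Main-chain bond lengths and angles versus the ideal-geometry
    reference set; a record is emitted when |actual - ideal| exceeds
    the bond (0.05 A) or angle (10 deg) threshold."""
    thr = thresholds or StereoThresholds()
    out: list[GeometryDeviation] = []
    for chain in s.chains:
        aminos = [r for r in chain.residues if r.category == "amino"]
        for i, res in enumerate(aminos):
            atoms = {nm: res.atom(nm) for nm in ("N", "CA", "C", "O", "CB")}
            for (a, b), ideal in IDEAL_BONDS.items():
                if atoms.get(a) is not None and atoms.get(b) is not None:
                    d = float(np.linalg.norm(atoms[a].xyz - atoms[b].xyz))
                    if abs(d - ideal) > thr.bond_length_tol:
                        out.append(GeometryDeviation("bond-length", res.key,
                                                     res.resname, (a, b), d,
                                                     ideal, thr.bond_length_tol))
            for (a, b, c), ideal in IDEAL_ANGLES.items():
                if all(atoms.get(x) is not None for x in (a, b, c)):
                    ang = angle(atoms[a].xyz, atoms[b].xyz, atoms[c].xyz)
                    if abs(ang - ideal) > thr.bond_angle_tol:
                        out.append(GeometryDeviation("bond-angle", res.key,
                                                     res.resname, (a, b, c),
                                                     ang, ideal, thr.bond_angle_tol))
            nxt = aminos[i + 1] if i + 1 < len(aminos) else None
            if nxt is not None and _peptide_linked(res, nxt):
                c, n_next = res.atom("C"), nxt.atom("N")
                d = float(np.linalg.norm(c.xyz - n_next.xyz))
                if abs(d - IDEAL_PEPTIDE_BOND) > thr.bond_length_tol:
                    out.append(GeometryDeviation("bond-length", res.key,
                                                 res.resname, ("C", "N+"), d,
                                                 IDEAL_PEPTIDE_BOND, thr.bond_length_tol))
                ca, o = res.atom("CA"), res.atom("O")
                if ca is not None:
                    ang = angle(ca.xyz, c.xyz, n_next.xyz)
                    if abs(ang - IDEAL_PEPTIDE_ANGLES[("CA", "C", "N+")]) > thr.bond_angle_tol:
                        out.append(GeometryDeviation("bond-angle", res.key, res.resname,
                                                     ("CA", "C", "N+"), ang,
                                                     IDEAL_PEPTIDE_ANGLES[("CA", "C", "N+")],
                                                     thr.bond_angle_tol))
                if o is not None:
                    ang = angle(o.xyz, c.xyz, n_next.xyz)
                    if abs(ang - IDEAL_PEPTIDE_ANGLES[("O", "C", "N+")]) > thr.bond_angle_tol:
                        out.append(GeometryDeviation("bond-angle", res.key, res.resname,
                                                     ("O", "C", "N+"), ang,
                                                     IDEAL_PEPTIDE_ANGLES[("O", "C", "N+")],
                                                     thr.bond_angle_tol))
                nca = nxt.atom("CA")
                if nca is not None:
                    ang = angle(c.xyz, n_next.xyz, nca.xyz)
                    if abs(ang - IDEAL_PEPTIDE_ANGLES[("C-", "N", "CA")]) > thr.bond_angle_tol:
                        out.append(GeometryDeviation("bond-angle", nxt.key, nxt.resname,
                                                     ("C-", "N", "CA"), ang,
                                                     IDEAL_PEPTIDE_ANGLES[("C-", "N", "CA")],
                                                     thr.bond_angle_tol))
    return out


def check_planarity(s: Structure, thresholds: StereoThresholds = None) -> list[GeometryDeviation]:
    """RMS out-of-plane deviation of ring / carboxy-amide / guanidinium
    groups; flagged above 0.03 A (rings) or 0.02 A (others)."""
    thr = thresholds or StereoThresholds()
    out = []
    for res in s.residues():
        group = PLANAR_GROUPS.get(res.resname)
        if group is None or res.category != "amino":
            continue
        names, is_ring = group
        pts = [res.atom(nm) for nm in names]
        pts = [a.xyz for a in pts if a is not None]
        if len(pts) < 4:
            continue
        pts = np.array(pts)
        centroid, normal = best_fit_plane(pts)
        rms = float(np.sqrt(np.mean(((pts - centroid) @ normal) ** 2)))
        limit = thr.planarity_rms_ring if is_ring else thr.planarity_rms_other
        if rms > limit:
            out.append(GeometryDeviation("planarity", res.key, res.resname,
                                         tuple(names), rms, 0.0, limit))
    return out


# ---------------------------------------------------------------------------
# G-factors

@dataclass
class GFactors:
    phi_psi: Optional[float] = None
    chi1_chi2: Optional[float] = None
    chi1_only: Optional[float] = None
    omega: Optional[float] = None

    @property
    def overall(self) -> Optional[float]:
        parts = [v for v in (self.phi_psi, self.chi1_chi2, self.chi1_only, self.omega)
                 if v is not None]
        return sum(parts) / len(parts) if parts else None


_HIST_FLOOR = 1e-4

_CHI_MIX_1D = [(1 / 3, -60.0, 15.0), (1 / 3, 60.0, 15.0), (1 / 3, 180.0, 15.0)]
_OMEGA_SIGMA = 6.0


def _hist_1d(mix) -> np.ndarray:
    centers = np.arange(-175.0, 180.0, GRID_STEP)
    h = np.zeros_like(centers)
    for w, mu, sig in mix:
        h += w * np.exp(-0.5 * (_wrap_delta(centers, mu) / sig) ** 2)
    h = h + _HIST_FLOOR
    return h / h.mean()


def _hist_2d(resclass: str) -> np.ndarray:
    h = _density(resclass) + _HIST_FLOOR
    return h / h.mean()


_chi1_hist = None
_chi12_hist = None
_omega_hist = None


def _reference_histograms():
    global _chi1_hist, _chi12_hist, _omega_hist
    if _chi1_hist is None:
        _chi1_hist = _hist_1d(_CHI_MIX_1D)
        h2 = np.outer(_chi1_hist, _chi1_hist)
        _chi12_hist = h2 / h2.mean()
        _omega_hist = _hist_1d([(1.0, 180.0, _OMEGA_SIGMA)])
    return _chi1_hist, _chi12_hist, _omega_hist


def log_odds_phi_psi(phi: float, psi: float, resclass: str) -> float:
    h = _hist_2d(resclass)
    return float(np.log10(h[_cell(phi), _cell(psi)]))


def compute_g_factors(torsions: Iterable[TorsionSet]) -> GFactors:
    """Mean log10 normalised frequency of each residue's torsion cells.

    Components with no contributing residues are undefined and excluded
    from the overall mean."""
    chi1h, chi12h, omegah = _reference_histograms()
    pp, c12, c1, om = [], [], [], []
    for ts in torsions:
        if ts.phi is not None and ts.psi is not None:
            pp.append(log_odds_phi_psi(ts.phi, ts.psi, res_class(ts.resname)))
        if len(ts.chi) >= 2:
            c12.append(float(np.log10(chi12h[_cell(ts.chi[0]), _cell(ts.chi[1])])))
        elif len(ts.chi) == 1:
            c1.append(float(np.log10(chi1h[_cell(ts.chi[0])])))
        if ts.omega is not None:
            om.append(float(np.log10(omegah[_cell(ts.omega)])))
    return GFactors(
        phi_psi=float(np.mean(pp)) if pp else None,
        chi1_chi2=float(np.mean(c12)) if c12 else None,
        chi1_only=float(np.mean(c1)) if c1 else None,
        omega=float(np.mean(om)) if om else None,
    )


# ---------------------------------------------------------------------------
# residue property profile

CHI1_ROTAMER_MEANS = (-60.0, 60.0, 180.0)


@dataclass
class ResidueProperties:
    key: tuple
    resname: str
    dchi1: Optional[float]       # |deviation| from nearest rotamer mean
    domega: Optional[float]      # |deviation| from nearer of 180 (trans) / 0 (cis)
    is_cis: bool
    dzeta: Optional[float]       # |deviation| from +33.9
    ss_state: str
    rel_accessibility: Optional[float]
    rama_region: Optional[str]
    max_deviation: float         # largest normalised deviation
    g_factor: Optional[float]    # per-residue phi-psi log-odds


def residue_property_profile(s: Structure, torsions: list[TorsionSet],
                             ss=None, sasa=None,
                             thresholds: StereoThresholds = None) -> list[ResidueProperties]:
    thr = thresholds or StereoThresholds()
    ss_state = {}
    if ss is not None:
        ss_state = dict(ss.states_in_order())
    rel_acc = {}
    if sasa is not None:
        rel_acc = sasa.relative_by_residue
    out = []
    for ts in torsions:
        dchi1 = None
        if ts.chi:
            dchi1 = min(abs(_sdiff(ts.chi[0], m)) for m in CHI1_ROTAMER_MEANS)
        domega = None
        is_cis = False
        if ts.omega is not None:
            d_trans = abs(_sdiff(ts.omega, 180.0))
            d_cis = abs(_sdiff(ts.omega, 0.0))
            is_cis = d_cis < d_trans
            domega = min(d_trans, d_cis)
        dzeta = abs(_sdiff(ts.zeta, thr.zeta_ideal)) if ts.zeta is not None else None
        region = None
        g = None
        if ts.phi is not None and ts.psi is not None:
            rc = res_class(ts.resname)
            region = ramachandran_region(ts.phi, ts.psi, rc)
            g = log_odds_phi_psi(ts.phi, ts.psi, rc)
        devs = []
        if dchi1 is not None:
            devs.append(dchi1 / 15.0)
        if domega is not None:
            devs.append(domega / _OMEGA_SIGMA)
        if dzeta is not None:
            devs.append(dzeta / thr.zeta_tol)
        out.append(ResidueProperties(
            key=ts.key, resname=ts.resname, dchi1=dchi1, domega=domega,
            is_cis=is_cis, dzeta=dzeta,
            ss_state=ss_state.get(ts.key, "-"),
            rel_accessibility=rel_acc.get(ts.key),
            rama_region=region,
            max_deviation=max(devs) if devs else 0.0,
            g_factor=g,
        ))
    return out


def _sdiff(a: float, b: float) -> float:
    return (a - b + 180.0) % 360.0 - 180.0


# ---------------------------------------------------------------------------
# reports

def procheck_summary(torsions: list[TorsionSet], gfactors: GFactors,
                     deviations: list[GeometryDeviation]) -> str:
    counts = ramachandran_counts(torsions)
    total = sum(counts.values()) or 1
    lines = ["Stereochemical quality summary", ""]
    lines.append("Ramachandran regions (residues with defined phi, psi):")
    for region in REGIONS:
        c = counts[region]
        lines.append(f"  {region:<12s} {c:5d}  ({100.0 * c / total:5.1f}%)")
    lines.append("")
    lines.append("G-factors (log-odds; less negative is more typical):")
    for name, v in (("phi-psi", gfactors.phi_psi),
                    ("chi1-chi2", gfactors.chi1_chi2),
                    ("chi1 only", gfactors.chi1_only),
                    ("omega", gfactors.omega),
                    ("OVERALL", gfactors.overall)):
        lines.append(f"  {name:<10s} {'-' if v is None else format(v, '6.2f')}")
    lines.append("")
    nb = sum(1 for d in deviations if d.kind == "bond-length")
    na = sum(1 for d in deviations if d.kind == "bond-angle")
    npl = sum(1 for d in deviations if d.kind == "planarity")
    lines.append(f"Distorted geometry: {nb} bond lengths, {na} bond angles, "
                 f"{npl} planar groups flagged")
    return "\n".join(lines) + "\n"


def deviations_table(deviations: list[GeometryDeviation]) -> str:
    rows = ["kind\tchain\tresseq\ticode\tresname\tatoms\tactual\tideal\tthreshold"]
    for d in deviations:
        rows.append("\t".join([
            d.kind, d.key[0], str(d.key[1]), d.key[2].strip() or "-", d.resname,
            "-".join(d.atoms), f"{d.actual:.3f}", f"{d.ideal:.3f}", f"{d.threshold:.3f}",
        ]))
    return "\n".join(rows) + "\n"


def properties_table(props: list[ResidueProperties]) -> str:
    rows = ["chain\tresseq\ticode\tresname\tdchi1\tdomega\tcis\tdzeta\tss"
            "\trel_acc\tregion\tmax_dev\tgfactor"]
    for p in props:
        def fmt(v, spec=".1f"):
            return "-" if v is None else format(v, spec)
        rows.append("\t".join([
            p.key[0], str(p.key[1]), p.key[2].strip() or "-", p.resname,
            fmt(p.dchi1), fmt(p.domega), "cis" if p.is_cis else "trans",
            fmt(p.dzeta), p.ss_state, fmt(p.rel_accessibility, ".2f"),
            p.rama_region or "-", f"{p.max_deviation:.2f}", fmt(p.g_factor, ".2f"),
        ]))
    return "\n".join(rows) + "\n"


def ramachandran_svg(torsions: list[TorsionSet], title: str = "") -> str:
    """Scatter of (phi, psi) over the general region grid as SVG text."""
    size, margin = 400, 40
    scale = size / 360.0
    grid = region_grid("general")
    colours = {0: "#cc3333", 1: "#cc8844", 2: "#ccbb55", 3: "#f4eecb"}
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" '
        f'width="{size + 2 * margin}" height="{size + 2 * margin}">',
        f'<text x="{margin + size / 2:.0f}" y="20" text-anchor="middle" '
        f'font-family="sans-serif" font-size="14">Ramachandran plot {title}</text>',
        f'<g transform="translate({margin},{margin})">',
    ]
    for i in range(GRID_N):
        for j in range(GRID_N):
            x = i * GRID_STEP * scale
            y = size - (j + 1) * GRID_STEP * scale
            parts.append(
                f'<rect x="{x:.1f}" y="{y:.1f}" width="{GRID_STEP * scale:.1f}" '
                f'height="{GRID_STEP * scale:.1f}" fill="{colours[grid[i, j]]}"/>'
            )
    for ts in torsions:
        if ts.phi is None or ts.psi is None:
            continue
        x = (ts.phi + 180.0) * scale
        y = size - (ts.psi + 180.0) * scale
        rc = res_class(ts.resname)
        region = ramachandran_region(ts.phi, ts.psi, rc)
        fill = "#cc0000" if region == "disallowed" else "#2222aa"
        parts.append(f'<rect x="{x - 3:.1f}" y="{y - 3:.1f}" width="6" height="6" '
                     f'fill="{fill}"/>')
        if region == "disallowed":
            parts.append(
                f'<text x="{x + 5:.1f}" y="{y:.1f}" font-size="9" '
                f'font-family="sans-serif">{ts.resname}{ts.key[1]}({ts.key[0]})</text>'
            )
    parts.append(
        f'<rect x="0" y="0" width="{size}" height="{size}" fill="none" stroke="black"/>'
    )
    parts.append(f'</g></svg>')
    return "\n".join(parts) + "\n"
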