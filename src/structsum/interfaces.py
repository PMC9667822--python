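"""Chain-chain interface analysis: interaction counts, interface
residues, and buried solvent-accessible surface area (SASA).

SASA uses Shrake-Rupley sphere-point counting with a deterministic
golden-section spiral point set, so results are bit-reproducible.
Buried area of a chain is SASA(chain alone) minus SASA(chain in the
pair complex), always >= 0 up to quadrature error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
from scipy.spatial import cKDTree

from structsum.config import SasaParams
from structsum.contacts import ContactSet
from structsum.pdb_io import Residue, Structure, VDW_RADII, DEFAULT_VDW

# maximum accessible areas of X in an extended Gly-X-Gly tripeptide
# (theoretical values of Tien et al.), used for relative accessibility
GXG_REFERENCE = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
    "MSE": 224.0,
}


def sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-section spiral of *n* points on the unit sphere."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * k
    return np.column_stack([
        np.cos(theta) * np.sin(phi),
        np.sin(theta) * np.sin(phi),
        np.cos(phi),
    ])


@dataclass
class SasaResult:
    atom_areas: dict            # atom key -> accessible area, A^2
    residue_areas: dict         # residue key -> summed area
    relative_by_residue: dict   # residue key -> area / GXG reference (protein only)

    @property
    def total(self) -> float:
        return float(sum(self.atom_areas.values()))


def _collect_atoms(s: Structure, chain_ids: Optional[set] = None):
    refs, coords, radii = [], [], []
    for chain in s.chains:
        if chain_ids is not None and chain.chain_id not in chain_ids:
            continue
        for res in chain.residues:
            if res.category == "water":
                continue
            for a in res.heavy_atoms():
                refs.append((res, a))
                coords.append(a.xyz)
                radii.append(a.vdw_radius)
    return refs, np.array(coords) if coords else np.zeros((0, 3)), np.array(radii)


def sasa(s: Structure, probe: float = 1.4, n_points: int = 960,
         chain_ids: Optional[Iterable[str]] = None) -> SasaResult:
    """Shrake-Rupley accessible surface area of the non-water heavy atoms.

    chain_ids restricts the computation (and the occluding context) to
    those chains; default is the whole structure.
    """
    subset = set(chain_ids) if chain_ids is not None else None
    refs, coords, radii = _collect_atoms(s, subset)
    n = len(refs)
    atom_areas: dict = {}
    if n == 0:
        return SasaResult({}, {}, {})
    pts = sphere_points(n_points)
    ext = radii + probe
    tree = cKDTree(coords)
    max_r = ext.max()
    for i in range(n):
        centre = coords[i]
        r_i = ext[i]
        neigh = [j for j in tree.query_ball_point(centre, r_i + max_r) if j != i]
        test = centre + pts * r_i
        if neigh:
            ncoords = coords[neigh]
            nradii = ext[neigh]
            d2 = ((test[:, None, :] - ncoords[None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (nradii ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        res, atom = refs[i]
        key = (res.chain_id, res.resseq, res.icode, atom.name)
        atom_areas[key] = float(frac * 4.0 * np.pi * r_i ** 2)

    residue_areas: dict = {}
    relative: dict = {}
    for (res, atom) in refs:
        key = (res.chain_id, res.resseq, res.icode, atom.name)
        rkey = res.key
        residue_areas[rkey] = residue_areas.get(rkey, 0.0) + atom_areas[key]
    for chain in s.chains:
        if subset is not None and chain.chain_id not in subset:
            continue
        for res in chain.residues:
            ref = GXG_REFERENCE.get(res.resname)
            if ref and res.key in residue_areas:
                relative[res.key] = residue_areas[res.key] / ref
    return SasaResult(atom_areas, residue_areas, relative)


def interface_area(s: Structure, chain_a: str, chain_b: str,
                   params: SasaParams = None) -> tuple[float, float]:
    """Buried area (A^2) of each chain upon forming the a-b pair complex."""
    if chain_a == chain_b:
        raise ValueError("interface requires two distinct chains")
    p = params or SasaParams()
    alone_a = sasa(s, p.probe, p.n_points, chain_ids=[chain_a]).total
    alone_b = sasa(s, p.probe, p.n_points, chain_ids=[chain_b]).total
    pair = sasa(s, p.probe, p.n_points, chain_ids=[chain_a, chain_b])
    in_complex_a = sum(v for k, v in pair.atom_areas.items() if k[0] == chain_a)
    in_complex_b = sum(v for k, v in pair.atom_areas.items() if k[0] == chain_b)
    return (max(alone_a - in_complex_a, 0.0), max(alone_b - in_complex_b, 0.0))


@dataclass
class InterfaceSummary:
    chain_a: str
    chain_b: str
    n_salt_bridges: int = 0
    n_hbonds: int = 0
    n_nonbonded: int = 0
    n_disulphides: int = 0
    residues_a: list = field(default_factory=list)
    residues_b: list = field(default_factory=list)
    buried_area_a: float = 0.0
    buried_area_b: float = 0.0
    sasa_alone_a: float = 0.0
    sasa_alone_b: float = 0.0
    records: list = field(default_factory=list)   # (type, ref_a, ref_b, dist)

    @property
    def wedge_percent_a(self) -> float:
        return 100.0 * self.buried_area_a / self.sasa_alone_a if self.sasa_alone_a else 0.0

    @property
    def wedge_percent_b(self) -> float:
        return 100.0 * self.buried_area_b / self.sasa_alone_b if self.sasa_alone_b else 0.0


def _between(ref_a, ref_b, chain_a, chain_b):
    ca, cb = ref_a.residue.chain_id, ref_b.residue.chain_id
    if (ca, cb) == (chain_a, chain_b):
        return ref_a, ref_b
    if (ca, cb) == (chain_b, chain_a):
        return ref_b, ref_a
    return None


def analyze_interface(s: Structure, chain_a: str, chain_b: str,
                      contacts: ContactSet, params: SasaParams = None,
                      compute_area: bool = True) -> InterfaceSummary:
    """Assemble the chain-pair interface summary from whole-structure
    contact results: counts are symmetric in (a, b); residue lists are
    ordered by residue number."""
    out = InterfaceSummary(chain_a=chain_a, chain_b=chain_b)
    res_a, res_b = set(), set()

    for hb in contacts.hbonds:
        pair = _between(hb.donor, hb.acceptor, chain_a, chain_b)
        if pair:
            out.n_hbonds += 1
            out.records.append(("hbond", pair[0], pair[1], hb.d_a))
            res_a.add(pair[0].residue.key)
            res_b.add(pair[1].residue.key)
    for c in contacts.nonbonded:
        pair = _between(c.atom_a, c.atom_b, chain_a, chain_b)
        if pair:
            out.n_nonbonded += 1
            out.records.append(("nonbonded", pair[0], pair[1], c.dist))
            res_a.add(pair[0].residue.key)
            res_b.add(pair[1].residue.key)
    for sb in contacts.salt_bridges:
        pair = _between(sb.basic_atom, sb.acidic_atom, chain_a, chain_b)
        if pair:
            out.n_salt_bridges += 1
            out.records.append(("salt-bridge", pair[0], pair[1], sb.dist))
            res_a.add(pair[0].residue.key)
            res_b.add(pair[1].residue.key)
    for ds in contacts.disulphides:
        pair = _between(ds.atom_a, ds.atom_b, chain_a, chain_b)
        if pair:
            out.n_disulphides += 1
            out.records.append(("disulphide", pair[0], pair[1], ds.dist))
            res_a.add(pair[0].residue.key)
            res_b.add(pair[1].residue.key)

    out.residues_a = sorted(res_a, key=lambda k: (k[1], k[2]))
    out.residues_b = sorted(res_b, key=lambda k: (k[1], k[2]))

    if compute_area:
        p = params or SasaParams()
        out.buried_area_a, out.buried_area_b = interface_area(s, chain_a, chain_b, p)
        out.sasa_alone_a = sasa(s, p.probe, p.n_points, chain_ids=[chain_a]).total
        out.sasa_alone_b = sasa(s, p.probe, p.n_points, chain_ids=[chain_b]).total
    return out


# ---------------------------------------------------------------------------
# tables

def interface_table(summary: InterfaceSummary) -> str:
    rows = ["type\tchain1\tresseq1\tresname1\tatom1\tchain2\tresseq2\tresname2\tatom2\tdist"]
    for kind, ra, rb, dist in summary.records:
        rows.append("\t".join([
            kind,
            ra.residue.chain_id, str(ra.residue.resseq), ra.residue.resname, ra.atom.name,
            rb.residue.chain_id, str(rb.residue.resseq), rb.residue.resname, rb.atom.name,
            f"{dist:.2f}",
        ]))
    return "\n".join(rows) + "\n"


def interface_summary_table(summaries: list[InterfaceSummary]) -> str:
    rows = ["chain_a\tchain_b\tsalt_bridges\thbonds\tnonbonded\tdisulphides"
            "\tburied_a\tburied_b\twedge_a_pct\twedge_b_pct\tn_res_a\tn_res_b"]
    for sm in summaries:
        rows.append("\t".join([
            sm.chain_a, sm.chain_b, str(sm.n_salt_bridges), str(sm.n_hbonds),
            str(sm.n_nonbonded), str(sm.n_disulphides),
            f"{sm.buried_area_a:.1f}", f"{sm.buried_area_b:.1f}",
            f"{sm.wedge_percent_a:.1f}", f"{sm.wedge_percent_b:.1f}",
            str(len(sm.residues_a)), str(len(sm.residues_b)),
        ]))
    return "\n".join(rows) + "\n"


def interface_diagram_data(summary: InterfaceSummary) -> dict:
    """JSON-serialisable data behind the interface schematic."""
    def reslabel(k):
        return {"chain": k[0], "resseq": k[1], "icode": k[2].strip()}
    return {
        "chain_a": summary.chain_a,
        "chain_b": summary.chain_b,
        "counts": {
            "salt_bridges": summary.n_salt_bridges,
            "hbonds": summary.n_hbonds,
            "nonbonded": summary.n_nonbonded,
            "disulphides": summary.n_disulphides,
        },
        "buried_area": {summary.chain_a: round(summary.buried_area_a, 1),
                        summary.chain_b: round(summary.buried_area_b, 1)},
        "wedge_percent": {summary.chain_a: round(summary.wedge_percent_a, 1),
                          summary.chain_b: round(summary.wedge_percent_b, 1)},
        "residues_a": [reslabel(k) for k in summary.residues_a],
        "residues_b": [reslabel(k) for k in summary.residues_b],
        "interactions": [
            {"type": kind,
             "a": {"chain": ra.residue.chain_id, "resseq": ra.residue.resseq,
                   "atom": ra.atom.name},
             "b": {"chain": rb.residue.chain_id, "resseq": rb.residue.resseq,
                   "atom": rb.atom.name},
             "dist": round(dist, 2)}
            for kind, ra, rb, dist in summary.records
        ],
    }
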