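"""Flattened 2D schematics of protein-ligand interactions.

The interaction graph holds the ligand's atoms and distance-inferred
covalent bonds, its hydrogen bonds to protein residues, and the
"eyelash" residues that only make non-bonded contacts. The layout
projects the 3D coordinates onto the ligand's best-fit plane and then
iteratively pushes label boxes apart (springs on covalent bonds,
H-bond partners tethered near their ligand atom) until no two label
boxes overlap. Hydrogen-bond edge labels always carry the 3D
donor-acceptor distance; the 2D geometry is schematic only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from structsum.contacts import ContactSet, COVALENT_RADII, DEFAULT_COVALENT, COVALENT_MARGIN
from structsum.geometry import best_fit_plane
from structsum.pdb_io import Residue, Structure


@dataclass
class LigandNode:
    name: str
    element: str
    xyz: np.ndarray


@dataclass
class HBondEdge:
    ligand_atom: str
    residue_key: tuple
    residue_label: str
    partner_atom: str
    partner_xyz: np.ndarray
    dist3d: float


@dataclass
class EyelashResidue:
    residue_key: tuple
    residue_label: str
    contacted_atoms: list
    centroid: np.ndarray


@dataclass
class InteractionGraph:
    ligand_label: str
    nodes: list[LigandNode]
    covalent: list[tuple[str, str]]
    hbonds: list[HBondEdge]
    eyelashes: list[EyelashResidue]

    def node(self, name: str) -> Optional[LigandNode]:
        for n in self.nodes:
            if n.name == name:
                return n
        return None


class LigandNotFound(KeyError):
    pass


def build_interaction_graph(s: Structure, ligand: Residue | tuple,
                            contacts: ContactSet) -> InteractionGraph:
    """Assemble the 2D-diagram graph for one HET group.

    A residue that both hydrogen-bonds and contacts the ligand appears
    as an H-bond partner only (H-bonds take precedence over eyelashes).
    """
    if not isinstance(ligand, Residue):
        key = tuple(ligand)
        found = None
        for r in s.residues():
            if r.key == key:
                found = r
                break
        if found is None:
            available = ", ".join(r.label for r in s.het_groups()) or "none"
            raise LigandNotFound(
                f"no residue {key} in structure {s.code}; HET groups present: {available}")
        ligand = found

    nodes = [LigandNode(a.name, a.element, a.xyz) for a in ligand.heavy_atoms()]
    covalent = []
    for i, a in enumerate(ligand.heavy_atoms()):
        ra = COVALENT_RADII.get(a.element, DEFAULT_COVALENT)
        for b in ligand.heavy_atoms()[i + 1:]:
            rb = COVALENT_RADII.get(b.element, DEFAULT_COVALENT)
            if np.linalg.norm(a.xyz - b.xyz) < ra + rb + COVALENT_MARGIN:
                covalent.append((a.name, b.name))

    hedges: list[HBondEdge] = []
    hbond_residues = set()
    for hb in contacts.hbonds:
        if hb.donor.residue is ligand and hb.acceptor.residue is not ligand:
            lig_atom, partner = hb.donor.atom, hb.acceptor
        elif hb.acceptor.residue is ligand and hb.donor.residue is not ligand:
            lig_atom, partner = hb.acceptor.atom, hb.donor
        else:
            continue
        hedges.append(HBondEdge(
            ligand_atom=lig_atom.name,
            residue_key=partner.residue.key,
            residue_label=partner.residue.label,
            partner_atom=partner.atom.name,
            partner_xyz=partner.atom.xyz,
            dist3d=hb.d_a,
        ))
        hbond_residues.add(partner.residue.key)

    eyelash: dict[tuple, EyelashResidue] = {}
    for c in contacts.nonbonded:
        if c.atom_a.residue is ligand and c.atom_b.residue is not ligand:
            lig_atom, partner = c.atom_a.atom, c.atom_b
        elif c.atom_b.residue is ligand and c.atom_a.residue is not ligand:
            lig_atom, partner = c.atom_b.atom, c.atom_a
        else:
            continue
        key = partner.residue.key
        if key in hbond_residues:
            continue
        if key not in eyelash:
            eyelash[key] = EyelashResidue(key, partner.residue.label, [],
                                          np.zeros(3))
        if lig_atom.name not in eyelash[key].contacted_atoms:
            eyelash[key].contacted_atoms.append(lig_atom.name)

    node_by_name = {n.name: n for n in nodes}
    for e in eyelash.values():
        pts = [node_by_name[nm].xyz for nm in e.contacted_atoms if nm in node_by_name]
        e.centroid = np.mean(pts, axis=0) if pts else np.zeros(3)

    return InteractionGraph(
        ligand_label=ligand.label,
        nodes=nodes,
        covalent=covalent,
        hbonds=hedges,
        eyelashes=sorted(eyelash.values(), key=lambda e: e.residue_key),
    )


# ---------------------------------------------------------------------------
# layout

TARGET_BOND = 1.5       # plot units per covalent bond
ATOM_BOX = (0.9, 0.6)   # label box of a ligand atom
RES_BOX = (2.4, 0.9)    # label box of a residue


@dataclass
class Layout2D:
    coords: dict               # node id -> np.array([x, y])
    boxes: dict                # node id -> (w, h)
    overlap_count: int
    iterations: int
    converged: bool


def _project_plane(points: np.ndarray) -> np.ndarray:
    centroid, normal = best_fit_plane(points)
    # build in-plane basis deterministically
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, normal)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(normal, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    rel = points - centroid
    return np.column_stack([rel @ e1, rel @ e2])


def _boxes_overlap(c1, b1, c2, b2) -> bool:
    return (abs(c1[0] - c2[0]) < (b1[0] + b2[0]) / 2.0
            and abs(c1[1] - c2[1]) < (b1[1] + b2[1]) / 2.0)


def _count_overlaps(ids, coords, boxes) -> int:
    n = 0
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if _boxes_overlap(coords[ids[i]], boxes[ids[i]],
                              coords[ids[j]], boxes[ids[j]]):
                n += 1
    return n


def flatten_layout(g: InteractionGraph, seed: int = 0,
                   max_iter: int = 2000) -> Layout2D:
    """Deterministic seeded refinement of the projected coordinates.

    The overlap count never increases from one accepted iteration to
    the next; refinement stops at zero overlaps or *max_iter*.
    """
    if not g.nodes:
        raise ValueError("empty interaction graph")
    rng = np.random.default_rng(seed)

    pts3d = np.array([n.xyz for n in g.nodes])
    all3d = [n.xyz for n in g.nodes]
    ids = [f"atom:{n.name}" for n in g.nodes]
    boxes = {f"atom:{n.name}": ATOM_BOX for n in g.nodes}
    for e in g.hbonds:
        all3d.append(e.partner_xyz)
        rid = f"res:{e.residue_key}"
        if rid not in boxes:
            ids.append(rid)
            boxes[rid] = RES_BOX
    for e in g.eyelashes:
        all3d.append(e.centroid)
        rid = f"res:{e.residue_key}"
        if rid not in boxes:
            ids.append(rid)
            boxes[rid] = RES_BOX

    plane = _project_plane(np.array(all3d))
    # scale so the mean covalent bond is TARGET_BOND
    atom2d = {f"atom:{n.name}": plane[i] for i, n in enumerate(g.nodes)}
    if g.covalent:
        lens = [np.linalg.norm(atom2d[f"atom:{a}"] - atom2d[f"atom:{b}"])
                for a, b in g.covalent]
        mean_len = float(np.mean(lens))
        scale = TARGET_BOND / mean_len if mean_len > 1e-6 else 1.0
    else:
        scale = 1.0
    plane = plane * scale

    coords = {}
    k = 0
    for n in g.nodes:
        coords[f"atom:{n.name}"] = plane[k].copy()
        k += 1
    seen = set(coords)
    for e in g.hbonds:
        rid = f"res:{e.residue_key}"
        p = plane[k].copy()
        k += 1
        if rid not in seen:
            coords[rid] = p
            seen.add(rid)
    for e in g.eyelashes:
        rid = f"res:{e.residue_key}"
        p = plane[k].copy()
        k += 1
        if rid not in seen:
            coords[rid] = p
            seen.add(rid)

    # tiny deterministic jitter separates exactly coincident points
    for nid in ids:
        coords[nid] = coords[nid] + rng.normal(0.0, 1e-3, size=2)

    anchors = {}
    for e in g.hbonds:
        anchors.setdefault(f"res:{e.residue_key}", f"atom:{e.ligand_atom}")
    for e in g.eyelashes:
        if e.contacted_atoms:
            anchors.setdefault(f"res:{e.residue_key}", f"atom:{e.contacted_atoms[0]}")

    best = {nid: c.copy() for nid, c in coords.items()}
    best_overlaps = _count_overlaps(ids, coords, boxes)
    step = 0.25
    iterations = 0
    while best_overlaps > 0 and iterations < max_iter:
        iterations += 1
        forces = {nid: np.zeros(2) for nid in ids}
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                a, b = ids[i], ids[j]
                if _boxes_overlap(coords[a], boxes[a], coords[b], boxes[b]):
                    d = coords[a] - coords[b]
                    norm = np.linalg.norm(d)
                    if norm < 1e-9:
                        d = rng.normal(0, 1.0, size=2)
                        norm = np.linalg.norm(d)
                    push = d / norm
                    forces[a] += push
                    forces[b] -= push
        for a, b in g.covalent:
            na, nb = f"atom:{a}", f"atom:{b}"
            d = coords[na] - coords[nb]
            norm = np.linalg.norm(d) or 1e-9
            stretch = (norm - TARGET_BOND) / TARGET_BOND
            pull = -stretch * d / norm
            forces[na] += 0.8 * pull
            forces[nb] -= 0.8 * pull
        for rid, aid in anchors.items():
            d = coords[rid] - coords[aid]
            norm = np.linalg.norm(d) or 1e-9
            ideal = 2.2
            stretch = (norm - ideal) / ideal
            forces[rid] += -0.5 * stretch * d / norm

        trial = {nid: coords[nid] + step * forces[nid] for nid in ids}
        trial_overlaps = _count_overlaps(ids, trial, boxes)
        if trial_overlaps <= best_overlaps:
            coords = trial
            if trial_overlaps < best_overlaps:
                best_overlaps = trial_overlaps
                best = {nid: c.copy() for nid, c in coords.items()}
            step = min(step * 1.05, 0.5)
        else:
            step *= 0.6
            coords = {nid: coords[nid] + step * forces[nid] for nid in ids}
            new_o = _count_overlaps(ids, coords, boxes)
            if new_o <= best_overlaps:
                if new_o < best_overlaps:
                    best_overlaps = new_o
                    best = {nid: c.copy() for nid, c in coords.items()}
            else:
                coords = {nid: c.copy() for nid, c in best.items()}

    return Layout2D(coords=best, boxes=boxes, overlap_count=best_overlaps,
                    iterations=iterations, converged=best_overlaps == 0)


# ---------------------------------------------------------------------------
# SVG rendering

ELEMENT_COLOURS = {"C": "#222222", "N": "#2244cc", "O": "#cc2222",
                   "S": "#b8a000", "P": "#cc7722"}


def render_svg(g: InteractionGraph, layout: Layout2D) -> str:
    """Render the diagram: solid covalent bonds, dashed green H-bonds
    labelled with the 3D distance (A, 2 dp), orange eyelash arcs."""
    coords = layout.coords
    pts = np.array(list(coords.values()))
    lo = pts.min(axis=0) - 2.0
    hi = pts.max(axis=0) + 2.0
    span = np.maximum(hi - lo, 1e-6)
    size = 520
    pad = 40
    scale = (size - 2 * pad) / max(span)

    def xy(p):
        q = (p - lo) * scale + pad
        return q[0], size - q[1]

    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{size}" height="{size}">',
        f'<title>LIGPLOT-style diagram of {g.ligand_label}</title>',
        f'<text x="{size / 2:.0f}" y="24" text-anchor="middle" '
        f'font-family="sans-serif" font-size="16">{g.ligand_label}</text>',
    ]
    for a, b in g.covalent:
        x1, y1 = xy(coords[f"atom:{a}"])
        x2, y2 = xy(coords[f"atom:{b}"])
        parts.append(f'<line x1="{x1:.1f}" y1="{y1:.1f}" x2="{x2:.1f}" y2="{y2:.1f}" '
                     f'stroke="#444444" stroke-width="2"/>')
    for e in g.hbonds:
        x1, y1 = xy(coords[f"atom:{e.ligand_atom}"])
        x2, y2 = xy(coords[f"res:{e.residue_key}"])
        parts.append(f'<line x1="{x1:.1f}" y1="{y1:.1f}" x2="{x2:.1f}" y2="{y2:.1f}" '
                     f'stroke="#118811" stroke-width="1.5" stroke-dasharray="5,4"/>')
        mx, my = (x1 + x2) / 2, (y1 + y2) / 2
        parts.append(f'<text x="{mx:.1f}" y="{my - 4:.1f}" font-size="11" '
                     f'font-family="sans-serif" fill="#118811" '
                     f'text-anchor="middle">{e.dist3d:.2f}</text>')
    for e in g.eyelashes:
        rid = f"res:{e.residue_key}"
        x, y = xy(coords[rid])
        # eyelash glyph: small arc with radiating lashes
        parts.append(f'<g class="eyelash">')
        parts.append(f'<path d="M {x - 12:.1f} {y + 6:.1f} A 14 14 0 0 1 '
                     f'{x + 12:.1f} {y + 6:.1f}" fill="none" stroke="#dd7700" '
                     f'stroke-width="2"/>')
        for t in (-0.8, -0.4, 0.0, 0.4, 0.8):
            lx = x + 14 * np.sin(t)
            ly = y + 6 - 14 * np.cos(t) * 0.4
            parts.append(f'<line x1="{lx:.1f}" y1="{ly:.1f}" '
                         f'x2="{lx + 5 * np.sin(t):.1f}" y2="{ly - 5:.1f}" '
                         f'stroke="#dd7700" stroke-width="1.2"/>')
        parts.append('</g>')
        parts.append(f'<text x="{x:.1f}" y="{y + 20:.1f}" font-size="11" '
                     f'font-family="sans-serif" text-anchor="middle" '
                     f'fill="#aa5500">{e.residue_label}</text>')
    for n in g.nodes:
        x, y = xy(coords[f"atom:{n.name}"])
        colour = ELEMENT_COLOURS.get(n.element, "#222222")
        parts.append(f'<circle cx="{x:.1f}" cy="{y:.1f}" r="6" fill="white" '
                     f'stroke="{colour}" stroke-width="1.5"/>')
        parts.append(f'<text x="{x:.1f}" y="{y - 8:.1f}" font-size="10" '
                     f'font-family="sans-serif" text-anchor="middle" '
                     f'fill="{colour}">{n.name}</text>')
    for e in g.hbonds:
        rid = f"res:{e.residue_key}"
        x, y = xy(coords[rid])
        parts.append(f'<rect x="{x - 30:.1f}" y="{y - 9:.1f}" width="60" height="16" '
                     f'fill="#eef4ee" stroke="#118811"/>')
        parts.append(f'<text x="{x:.1f}" y="{y + 3:.1f}" font-size="10" '
                     f'font-family="sans-serif" text-anchor="middle">'
                     f'{e.residue_label}</text>')
    parts.append("</svg>")
    return "\n".join(parts) + "\n"


def interactions_table(g: InteractionGraph) -> str:
    rows = ["type\tligand_atom\tchain\tresseq\tresname_or_atom\tdist"]
    for e in g.hbonds:
        rows.append(f"hbond\t{e.ligand_atom}\t{e.residue_key[0]}\t{e.residue_key[1]}"
                    f"\t{e.partner_atom}\t{e.dist3d:.2f}")
    for e in g.eyelashes:
        rows.append(f"nonbonded\t{','.join(e.contacted_atoms)}\t{e.residue_key[0]}"
                    f"\t{e.residue_key[1]}\t{e.residue_label}\t-")
    return "\n".join(rows) + "\n"
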