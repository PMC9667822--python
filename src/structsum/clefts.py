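"""Surface-cleft and interior-cavity detection, ranked by volume.

Gap spheres are fitted between pairs of nearby atoms: a sphere is
centred in the middle of the inter-surface gap and shrunk until no
atom's van-der-Waals sphere penetrates it; spheres that stay above a
minimum radius are splatted onto a voxel grid, and the 26-connected
components of the occupied voxels form the clefts. Volumes are voxel
counts times the voxel volume; clefts are ranked largest first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from structsum.config import CleftParams
from structsum.pdb_io import Structure

import logging

logger = logging.getLogger(__name__)


@dataclass
class GapSphere:
    center: np.ndarray
    radius: float


@dataclass
class DensityGrid:
    origin: np.ndarray
    spacing: float
    dims: tuple
    values: np.ndarray


@dataclass
class Cleft:
    rank: int
    volume: float
    voxels: np.ndarray            # (n, 3) voxel centre coordinates
    lining_residues: list = field(default_factory=list)


def gap_sphere(center_a: np.ndarray, radius_a: float,
               center_b: np.ndarray, radius_b: float,
               neighbour_coords: np.ndarray, neighbour_radii: np.ndarray,
               r_min: float = 1.0, r_max: float = 4.0) -> Optional[GapSphere]:
    """Largest sphere centred midway in the a-b surface gap that touches
    no atom, or None when it would fall below *r_min*."""
    d = float(np.linalg.norm(center_b - center_a))
    gap = d - radius_a - radius_b
    if gap <= 2.0 * r_min or d < 1e-9:
        return None
    u = (center_b - center_a) / d
    centre = center_a + u * (radius_a + gap / 2.0)
    radius = min(gap / 2.0, r_max)
    if len(neighbour_coords):
        dists = np.linalg.norm(neighbour_coords - centre, axis=1) - neighbour_radii
        radius = min(radius, float(dists.min()))
    if radius < r_min:
        return None
    return GapSphere(center=centre, radius=radius)


def _heavy_atoms(s: Structure):
    coords, radii, refs = [], [], []
    for res in s.residues():
        if res.category == "water":
            continue
        for a in res.heavy_atoms():
            coords.append(a.xyz)
            radii.append(a.vdw_radius)
            refs.append(res)
    return np.array(coords), np.array(radii), refs


def find_gap_spheres(s: Structure, params: CleftParams = None) -> list[GapSphere]:
    p = params or CleftParams()
    coords, radii, _ = _heavy_atoms(s)
    n = len(coords)
    if n < 2:
        return []
    max_vdw = float(radii.max())
    pair_cut = 2.0 * p.r_max + 2.0 * max_vdw
    tree = cKDTree(coords)
    spheres: list[GapSphere] = []
    for i, j in sorted(tree.query_pairs(pair_cut)):
        centre_guess = 0.5 * (coords[i] + coords[j])
        neigh = tree.query_ball_point(centre_guess, p.r_max + max_vdw + 2.0)
        neigh = [k for k in neigh if k not in (i, j)]
        sp = gap_sphere(coords[i], radii[i], coords[j], radii[j],
                        coords[neigh] if neigh else np.zeros((0, 3)),
                        radii[neigh] if neigh else np.zeros(0),
                        r_min=p.r_min, r_max=p.r_max)
        if sp is not None:
            spheres.append(sp)
    return spheres


def compute_clefts(s: Structure, spacing: float = None,
                   params: CleftParams = None) -> tuple[list[Cleft], Optional[DensityGrid]]:
    """Detect clefts: fit gap spheres, splat them on a voxel grid, take
    26-connected components, drop tiny ones, rank by volume."""
    p = params or CleftParams()
    if spacing is not None:
        p = CleftParams(r_min=p.r_min, r_max=p.r_max, spacing=spacing,
                        min_volume=p.min_volume, lining_cutoff=p.lining_cutoff)
    coords, radii, refs = _heavy_atoms(s)
    if len(coords) < 2:
        return [], None
    spread = coords - coords.mean(axis=0)
    if len(coords) >= 3:
        svals = np.linalg.svd(spread, compute_uv=False)
        if svals[1] < 1e-6:
            logger.warning("degenerate (collinear) structure: no cleft search")
            return [], None

    spheres = find_gap_spheres(s, p)
    if not spheres:
        return [], None

    centres = np.array([sp.center for sp in spheres])
    rads = np.array([sp.radius for sp in spheres])
    lo = (centres - rads[:, None]).min(axis=0) - p.spacing
    hi = (centres + rads[:, None]).max(axis=0) + p.spacing
    # snap the origin to the global voxel lattice for stability
    origin = np.floor(lo / p.spacing) * p.spacing
    dims = tuple(int(x) for x in np.ceil((hi - origin) / p.spacing).astype(int) + 1)
    values = np.zeros(dims, dtype=np.float32)

    for sp in spheres:
        lo_idx = np.floor((sp.center - sp.radius - origin) / p.spacing).astype(int)
        hi_idx = np.ceil((sp.center + sp.radius - origin) / p.spacing).astype(int)
        lo_idx = np.maximum(lo_idx, 0)
        hi_idx = np.minimum(hi_idx, np.array(dims) - 1)
        ix = np.arange(lo_idx[0], hi_idx[0] + 1)
        iy = np.arange(lo_idx[1], hi_idx[1] + 1)
        iz = np.arange(lo_idx[2], hi_idx[2] + 1)
        gx, gy, gz = np.meshgrid(ix, iy, iz, indexing="ij")
        centres_xyz = origin + np.stack([gx, gy, gz], axis=-1) * p.spacing
        inside = ((centres_xyz - sp.center) ** 2).sum(axis=-1) <= sp.radius ** 2
        sub = values[lo_idx[0]:hi_idx[0] + 1, lo_idx[1]:hi_idx[1] + 1,
                     lo_idx[2]:hi_idx[2] + 1]
        sub[inside] = 1.0

    grid = DensityGrid(origin=origin, spacing=p.spacing, dims=dims, values=values)

    labels, n_comp = ndimage.label(values > 0, structure=np.ones((3, 3, 3), dtype=int))
    clefts: list[Cleft] = []
    tree = cKDTree(coords)
    voxel_volume = p.spacing ** 3
    comps = []
    for comp in range(1, n_comp + 1):
        idx = np.argwhere(labels == comp)
        vol = len(idx) * voxel_volume
        if vol < p.min_volume:
            continue
        comps.append((vol, idx))
    comps.sort(key=lambda t: (-t[0], t[1][0].tolist()))
    for rank, (vol, idx) in enumerate(comps, start=1):
        vox_xyz = origin + idx * p.spacing
        lining = set()
        near = tree.query_ball_point(vox_xyz, p.lining_cutoff)
        for lst in near:
            for k in lst:
                lining.add(refs[k].key)
        clefts.append(Cleft(rank=rank, volume=vol, voxels=vox_xyz,
                            lining_residues=sorted(lining)))
    return clefts, grid


# ---------------------------------------------------------------------------
# outputs

CLEFT_COLOURS = ["red", "orange", "yellow", "green", "cyan", "blue", "purple"]


def clefts_table(clefts: list[Cleft]) -> str:
    rows = ["rank\tvolume_A3\tn_voxels\tlining_residues"]
    for c in clefts:
        lining = ";".join(f"{k[0]}{k[1]}{k[2].strip()}" for k in c.lining_residues)
        rows.append(f"{c.rank}\t{c.volume:.1f}\t{len(c.voxels)}\t{lining}")
    return "\n".join(rows) + "\n"


def cleft_pseudo_pdb(cleft: Cleft) -> str:
    """Voxel centres of one cleft as HETATM pseudo-atoms.

    Each voxel gets its own residue number so the file survives a
    round trip through the parser's altloc/uniqueness rules."""
    lines = []
    chain_cycle = "ZYXWVUTSRQ"
    for i, xyz in enumerate(cleft.voxels):
        serial = (i + 1) % 100000
        resseq = i % 10000
        chain = chain_cycle[(i // 10000) % len(chain_cycle)]
        lines.append(
            f"HETATM{serial:5d}  O   CLF {chain}{resseq:4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00           O"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_cleft_outputs(clefts: list[Cleft], out_dir, structure_file: str = "structure.pdb"):
    """Write per-cleft pseudo-atom files plus RasMol/PyMOL viewer
    scripts (cleft 1 coloured red). Paths inside scripts are relative."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for c in clefts:
        fname = f"cleft_{c.rank}.pdb"
        (out / fname).write_text(cleft_pseudo_pdb(c))
        written.append(fname)

    spt = [f"load {structure_file}", "wireframe off", "cartoon on", "color chain"]
    pml = [f"load {structure_file}, molecule", "hide everything, molecule",
           "show cartoon, molecule", "util.cbc('molecule')"]
    for c in clefts:
        colour = CLEFT_COLOURS[(c.rank - 1) % len(CLEFT_COLOURS)]
        spt.append(f"# cleft {c.rank}: volume {c.volume:.1f} A^3 -> {colour}")
        pml.append(f"load cleft_{c.rank}.pdb, cleft{c.rank}")
        pml.append(f"show spheres, cleft{c.rank}")
        pml.append(f"set sphere_scale, 0.4, cleft{c.rank}")
        pml.append(f"color {colour}, cleft{c.rank}")
    (out / "clefts.spt").write_text("\n".join(spt) + "\n")
    (out / "clefts.pml").write_text("\n".join(pml) + "\n")
    return written
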