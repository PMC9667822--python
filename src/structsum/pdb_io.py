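"""PDB-format input/output, molecule classification, and entry codes.

Coordinates are parsed with gemmi; a fixed-column pre-validation pass
first drops (and counts) ATOM/HETATM records whose numeric fields do
not parse, because downstream analyses must never see silently
zero-filled coordinates. Only the first MODEL is retained and each
alternate-location group is reduced to its highest-occupancy conformer
(ties broken by the lowest altloc character), so every retained atom is
uniquely addressed by (chain, resseq, icode, name).
"""

from __future__ import annotations

import io
import logging
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

STANDARD_AMINO = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}
DNA_RESIDUES = {"DA", "DC", "DG", "DT", "DI"}
RNA_RESIDUES = {"A", "C", "G", "U", "I"}
WATER_RESIDUES = {"HOH", "WAT", "DOD", "H2O"}
METAL_ELEMENTS = {"ZN", "FE", "MG", "MN", "CA", "NA", "K", "CU", "NI", "CO", "CD", "HG"}

VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "H": 1.20}
DEFAULT_VDW = 1.70

AA_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V", "MSE": "M",
}
AA_ONE_TO_THREE = {v: k for k, v in AA_THREE_TO_ONE.items() if k != "MSE"}


class PdbParseError(ValueError):
    """Hard parse failure: no usable coordinate records."""


@dataclass
class Atom:
    serial: int
    name: str
    altloc: str          # blank after resolution unless kept conformer had one
    element: str         # upper-case symbol, never empty after inference
    xyz: np.ndarray      # shape (3,), angstroms
    occupancy: float
    bfactor: float
    is_het: bool

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")

    @property
    def vdw_radius(self) -> float:
        return VDW_RADII.get(self.element, DEFAULT_VDW)


@dataclass
class Residue:
    resname: str
    resseq: int
    icode: str
    atoms: list[Atom] = field(default_factory=list)
    category: str = "ligand"   # amino | nucleotide | water | ligand | metal
    chain_id: str = ""

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.resseq, self.icode)

    @property
    def label(self) -> str:
        ic = self.icode.strip()
        return f"{self.resname}{self.resseq}{ic}({self.chain_id})"

    @property
    def is_amino(self) -> bool:
        return self.category == "amino"

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def residue(self, resseq: int, icode: str = " ") -> Optional[Residue]:
        for r in self.residues:
            if r.resseq == resseq and r.icode == icode:
                return r
        return None


@dataclass
class HeaderInfo:
    title: str = ""
    compound: str = ""
    method: str = ""


@dataclass
class Structure:
    code: str
    chains: list[Chain] = field(default_factory=list)
    header: HeaderInfo = field(default_factory=HeaderInfo)
    seqres: dict[str, int] = field(default_factory=dict)   # chain id -> declared residue count
    n_malformed: int = 0
    source: str = ""

    def chain(self, chain_id: str) -> Optional[Chain]:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        return None

    def residues(self) -> Iterable[Residue]:
        for c in self.chains:
            yield from c.residues

    def atoms(self) -> Iterable[tuple[Residue, Atom]]:
        for r in self.residues():
            for a in r.atoms:
                yield r, a

    def het_groups(self) -> list[Residue]:
        """Non-water, non-polymer residues (ligands and metals)."""
        return [r for r in self.residues() if r.category in ("ligand", "metal")]


# ---------------------------------------------------------------------------
# parsing

def _coordinate_line_ok(line: str) -> bool:
    """Validate the numeric fixed columns of an ATOM/HETATM record."""
    if len(line) < 54:
        return False
    try:
        float(line[30:38])
        float(line[38:46])
        float(line[46:54])
        if line[22:26].strip():
            int(line[22:26])
        if len(line) >= 60 and line[54:60].strip():
            float(line[54:60])
        if len(line) >= 66 and line[60:66].strip():
            float(line[60:66])
    except ValueError:
        return False
    return True


def _residue_category(resname: str, any_het: bool, atoms: list[Atom]) -> str:
    name = resname.strip().upper()
    if name in WATER_RESIDUES:
        return "water"
    if name == "MSE" or name in STANDARD_AMINO:
        return "amino"
    if name in DNA_RESIDUES or name in RNA_RESIDUES:
        return "nucleotide"
    heavies = [a for a in atoms if not a.is_hydrogen]
    if len(heavies) == 1 and heavies[0].element in METAL_ELEMENTS:
        return "metal"
    if not any_het:
        # non-standard residue in ATOM records: treat as amino acid
        return "amino"
    return "ligand"


def _resolve_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep one conformer per atom name: highest occupancy, ties by altloc."""
    groups: dict[str, list[Atom]] = {}
    order: list[str] = []
    for a in atoms:
        if a.name not in groups:
            groups[a.name] = []
            order.append(a.name)
        groups[a.name].append(a)
    kept = []
    for name in order:
        group = groups[name]
        best = min(group, key=lambda a: (-a.occupancy, a.altloc or "~"))
        kept.append(best)
    return kept


def parse_pdb(source, code: str = "xxxx", name: str = "<stream>") -> Structure:
    """Parse PDB-format text (string, bytes, or file-like) into a Structure.

    Raises PdbParseError when the input has no valid coordinate record.
    Malformed ATOM/HETATM records are skipped, logged, and counted in
    ``Structure.n_malformed``.
    """
    if isinstance(source, (str, bytes)):
        text = source.decode() if isinstance(source, bytes) else source
    else:
        text = source.read()
        if isinstance(text, bytes):
            text = text.decode()

    kept_lines: list[str] = []
    n_malformed = 0
    title_parts: list[str] = []
    compound_parts: list[str] = []
    method = ""
    seqres: dict[str, int] = {}

    for line in text.splitlines():
        rec = line[:6]
        if rec in ("ATOM  ", "HETATM"):
            if _coordinate_line_ok(line):
                kept_lines.append(line)
            else:
                n_malformed += 1
                logger.warning("%s: skipping malformed record: %r", name, line[:30])
        elif rec in ("MODEL ", "ENDMDL", "TER   ", "END   ", "CONECT", "SSBOND"):
            kept_lines.append(line)
        elif rec == "TITLE ":
            title_parts.append(line[10:80].strip())
        elif rec == "COMPND":
            compound_parts.append(line[10:80].strip())
        elif rec == "EXPDTA":
            method = method or line[10:80].strip()
        elif rec == "SEQRES":
            ch = line[11] if len(line) > 11 else " "
            try:
                seqres[ch] = int(line[13:17])
            except ValueError:
                n_malformed += 1

    st = gemmi.read_pdb_string("\n".join(kept_lines) + "\n")
    if len(st) == 0 or st[0].count_atom_sites() == 0:
        raise PdbParseError(f"{name}: no valid ATOM/HETATM coordinate records")

    model = st[0]  # first MODEL only
    structure = Structure(code=code, source=name, n_malformed=n_malformed)
    structure.header = HeaderInfo(
        title=" ".join(p for p in title_parts if p),
        compound=" ".join(p for p in compound_parts if p),
        method=method,
    )
    structure.seqres = seqres

    chain_index: dict[str, Chain] = {}
    for gchain in model:
        cid = gchain.name.strip() or " "
        # fragments with a repeated chain id (e.g. after intervening
        # chains) are merged into the first occurrence
        chain = chain_index.get(cid) or Chain(chain_id=cid)
        for gres in gchain:
            any_het = gres.het_flag == "H"
            atoms = []
            for ga in gres:
                elem = ga.element.name.upper()
                if not elem or elem == "X":
                    elem = _infer_element(ga.name, gres.name)
                atoms.append(
                    Atom(
                        serial=ga.serial,
                        name=ga.name,
                        altloc=ga.altloc if ga.altloc != "\x00" else "",
                        element=elem,
                        xyz=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                        occupancy=ga.occ,
                        bfactor=ga.b_iso,
                        is_het=any_het,
                    )
                )
            atoms = _resolve_altlocs(atoms)
            if not atoms:
                continue
            res = Residue(
                resname=gres.name.strip(),
                resseq=gres.seqid.num,
                icode=gres.seqid.icode if gres.seqid.icode.strip() else " ",
                atoms=atoms,
                chain_id=chain.chain_id,
            )
            res.category = _residue_category(res.resname, any_het, atoms)
            chain.residues.append(res)
        if chain.residues and chain.chain_id not in chain_index:
            chain_index[chain.chain_id] = chain
            structure.chains.append(chain)
    return structure


def _infer_element(atom_name: str, resname: str) -> str:
    """Best-effort element from the atom-name columns (legacy files)."""
    stripped = atom_name.strip()
    if not stripped:
        return "C"
    if stripped[0].isdigit():
        stripped = stripped.lstrip(string.digits)
    two = stripped[:2].upper()
    if two in METAL_ELEMENTS or two in ("CL", "BR", "SE"):
        return two
    return stripped[0].upper()


def parse_pdb_file(path: str | Path, code: Optional[str] = None) -> Structure:
    path = Path(path)
    inferred = code or (path.name[3:7] if _is_pdbxxxx_name(path.name) else "xxxx")
    with open(path) as fh:
        return parse_pdb(fh, code=inferred, name=str(path))


# ---------------------------------------------------------------------------
# writing (round-trip subset)

def write_pdb(s: Structure) -> str:
    """Serialise the retained atoms back to fixed-column PDB text."""
    lines = []
    serial = 0
    for chain in s.chains:
        for res in chain.residues:
            for a in res.atoms:
                serial += 1
                rec = "HETATM" if a.is_het else "ATOM  "
                name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
                lines.append(
                    f"{rec}{serial:5d} {name:<4.4s}{(a.altloc or ' '):1.1s}{res.resname:>3s} "
                    f"{chain.chain_id:1.1s}{res.resseq:4d}{res.icode:1.1s}   "
                    f"{a.xyz[0]:8.3f}{a.xyz[1]:8.3f}{a.xyz[2]:8.3f}"
                    f"{a.occupancy:6.2f}{a.bfactor:6.2f}          {a.element:>2.2s}"
                )
        lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# entry codes

def _is_pdbxxxx_name(filename: str) -> bool:
    return (
        len(filename) == 11
        and filename.lower().startswith("pdb")
        and filename.lower().endswith(".ent")
    )


def assign_pdb_code(filename: str | Path, user_code: Optional[str] = None,
                    registry: Iterable[str] = ()) -> str:
    """Pick the 4-character entry code for a run.

    Precedence: explicit user code > ``pdbXXXX.ent`` filename pattern >
    auto-generated codes a001, a002, ... skipping codes already in the
    registry. An explicit code that is not 4 characters, or that clashes
    with the registry, is an error.
    """
    used = set(registry)
    if user_code is not None:
        if len(user_code) != 4:
            raise ValueError(f"entry code must be exactly 4 characters, got {user_code!r}")
        if user_code in used:
            raise ValueError(f"entry code {user_code!r} already present in the run registry")
        return user_code
    fname = Path(filename).name
    if _is_pdbxxxx_name(fname):
        code = fname[3:7].lower()
        if code not in used:
            return code
        # fall through to auto-generation when the filename code was used before
    i = 0
    while True:
        i += 1
        code = f"a{i:03d}"
        if code not in used:
            return code


# ---------------------------------------------------------------------------
# classification and coverage

def classify_chains(s: Structure) -> dict[str, str]:
    """Chain id -> one of protein, dna, rna, ligand-only, water-only, mixed."""
    out: dict[str, str] = {}
    for chain in s.chains:
        has_protein = any(
            r.category == "amino" and r.atom("CA") is not None for r in chain.residues
        )
        has_dna = any(r.resname in DNA_RESIDUES for r in chain.residues)
        has_rna = any(
            r.resname in RNA_RESIDUES and r.category == "nucleotide" for r in chain.residues
        )
        n_polymer_kinds = sum((has_protein, has_dna or has_rna))
        if n_polymer_kinds > 1 or (has_dna and has_rna):
            out[chain.chain_id] = "mixed"
        elif has_protein:
            out[chain.chain_id] = "protein"
        elif has_dna:
            out[chain.chain_id] = "dna"
        elif has_rna:
            out[chain.chain_id] = "rna"
        elif all(r.category == "water" for r in chain.residues):
            out[chain.chain_id] = "water-only"
        else:
            out[chain.chain_id] = "ligand-only"
    return out


def coverage_count(s: Structure, chain_id: str) -> tuple[int, int]:
    """(observed, declared) residue counts for a protein chain.

    observed counts residues with at least one non-hydrogen atom;
    declared is the SEQRES count when present, else equals observed.
    """
    chain = s.chain(chain_id)
    if chain is None:
        raise KeyError(f"no chain {chain_id!r} in structure {s.code}")
    observed = sum(
        1 for r in chain.residues if r.category == "amino" and r.heavy_atoms()
    )
    declared = s.seqres.get(chain_id, observed)
    return observed, declared
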