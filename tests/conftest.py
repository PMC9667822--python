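"""Shared fixtures: parsed synthetic structures and brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

from structsum import fixtures as fx
from structsum.config import ContactCriteria
from structsum.contacts import (analyse_contacts, covalent_adjacency,
                                is_acceptor, is_donor, place_polar_hydrogens,
                                rotamer_h, _within_two_bonds)
from structsum.geometry import angle
from structsum.pdb_io import parse_pdb


@pytest.fixture(scope="session")
def helix():
    return parse_pdb(fx.make_ideal_helix(12), code="helx")


@pytest.fixture(scope="session")
def hairpin():
    return parse_pdb(fx.make_beta_hairpin(), code="hpin")


@pytest.fixture(scope="session")
def toy_complex():
    return parse_pdb(fx.make_toy_complex(), code="toyc")


@pytest.fixture(scope="session")
def cavity_cage():
    return parse_pdb(fx.make_cavity_cage(8.0), code="cage")


@pytest.fixture(scope="session")
def dimer():
    return parse_pdb(fx.make_two_helix_dimer(9.0), code="dime")


@pytest.fixture(scope="session")
def toy_contacts(toy_complex):
    return analyse_contacts(toy_complex)


@pytest.fixture(scope="session")
def hairpin_contacts(hairpin):
    return analyse_contacts(hairpin)


# ---------------------------------------------------------------------------
# brute-force oracles (independent of the k-d tree search path)

def brute_force_hbonds(s, crit: ContactCriteria = None) -> set:
    """Exhaustive donor x acceptor scan under the same geometric criteria."""
    crit = crit or ContactCriteria()
    adj = covalent_adjacency(s)
    hpos = place_polar_hydrogens(s)
    pairs = set()
    atoms = list(s.atoms())
    for res_d, atom_d in atoms:
        if atom_d.is_hydrogen or not is_donor(res_d, atom_d):
            continue
        dkey = (res_d.chain_id, res_d.resseq, res_d.icode, atom_d.name)
        for res_a, atom_a in atoms:
            if atom_a.is_hydrogen or not is_acceptor(res_a, atom_a):
                continue
            if res_a is res_d:
                continue
            akey = (res_a.chain_id, res_a.resseq, res_a.icode, atom_a.name)
            if dkey == akey or _within_two_bonds(adj, dkey, akey):
                continue
            d_a = float(np.linalg.norm(atom_d.xyz - atom_a.xyz))
            if d_a > crit.d_a_max:
                continue
            if dkey in hpos:
                hs = hpos[dkey]
                if not hs:
                    h = rotamer_h(res_d, atom_d, atom_a.xyz)
                    hs = [h] if h is not None else []
                if hs:
                    ok = False
                    for h in hs:
                        h_a = float(np.linalg.norm(h - atom_a.xyz))
                        if h_a <= crit.h_a_max and \
                                angle(atom_d.xyz, h, atom_a.xyz) >= crit.dha_min:
                            ok = True
                            break
                    if not ok:
                        continue
            pairs.add((dkey, akey))
    return pairs


def brute_force_nonbonded(s, crit: ContactCriteria = None,
                          hbond_pairs: set = frozenset()) -> set:
    crit = crit or ContactCriteria()
    adj = covalent_adjacency(s)
    hb_unordered = {frozenset(p) for p in hbond_pairs}
    atoms = [(r, a) for r, a in s.atoms() if not a.is_hydrogen]
    pairs = set()
    for i, (res_a, atom_a) in enumerate(atoms):
        ka = (res_a.chain_id, res_a.resseq, res_a.icode, atom_a.name)
        for res_b, atom_b in atoms[i + 1:]:
            if res_b is res_a:
                continue
            kb = (res_b.chain_id, res_b.resseq, res_b.icode, atom_b.name)
            if float(np.linalg.norm(atom_a.xyz - atom_b.xyz)) > crit.nonbonded_max:
                continue
            if _within_two_bonds(adj, ka, kb):
                continue
            if frozenset((ka, kb)) in hb_unordered:
                continue
            pairs.add(frozenset((ka, kb)))
    return pairs


def brute_force_salt_bridges(s, cutoff: float = 4.0) -> set:
    from structsum.contacts import ACIDIC_ATOMS, BASIC_ATOMS

    basics, acidics = [], []
    for r, a in s.atoms():
        if (r.resname, a.name) in BASIC_ATOMS:
            basics.append((r, a))
        elif (r.resname, a.name) in ACIDIC_ATOMS:
            acidics.append((r, a))
    best = {}
    for rb, ab in basics:
        for ra, aa in acidics:
            d = float(np.linalg.norm(ab.xyz - aa.xyz))
            if d <= cutoff:
                key = (rb.key, ra.key)
                if key not in best or d < best[key][0]:
                    best[key] = (d, ab.name, aa.name)
    return {(k[0], v[1], k[1], v[2]) for k, v in best.items()}


def random_cluster_pdb(rng: np.random.Generator, n_res: int = 5) -> str:
    """Random short peptide plus a few random polar HET atoms: a small
    structure with donors, acceptors, and charged groups at random
    geometry, for search-vs-brute-force equality tests."""
    from structsum.fixtures import PeptideSpec, make_peptide, _pdb_atom_line

    torsions = [
        (float(rng.uniform(-180, 180)), float(rng.uniform(-180, 180)), 180.0)
        for _ in range(n_res)
    ]
    seq = "".join(rng.choice(list("AG"), size=n_res))
    text = make_peptide(PeptideSpec(seq, torsions))
    lines = [ln for ln in text.splitlines() if ln.startswith("ATOM")]
    serial = len(lines) + 1
    centre = rng.uniform(-3, 6, size=3)
    for k in range(int(rng.integers(2, 6))):
        elem = rng.choice(["O", "N", "C"])
        xyz = centre + rng.uniform(-4, 4, size=3)
        lines.append(_pdb_atom_line(serial, f"{elem}{k + 1}", "RND", "X",
                                    k + 1, xyz, str(elem), het=True))
        serial += 1
    return "\n".join(lines) + "\nEND\n"


def hbond_pairs_of(hbonds) -> set:
    return {(hb.donor.key, hb.acceptor.key) for hb in hbonds}
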