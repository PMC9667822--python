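"""Hydrogen bonds, non-bonded contacts, salt bridges, metals:
examples, brute-force set equality, and rigid-motion invariance."""

import numpy as np
import pytest

from structsum.config import ContactCriteria
from structsum.contacts import (analyse_contacts, find_hbonds, find_metal_contacts,
                                find_nonbonded, find_salt_bridges,
                                place_polar_hydrogens)
from structsum.fixtures import _pdb_atom_line, make_beta_hairpin
from structsum.geometry import rotation_matrix
from structsum.pdb_io import parse_pdb

from conftest import (brute_force_hbonds, brute_force_nonbonded,
                      brute_force_salt_bridges, hbond_pairs_of,
                      random_cluster_pdb)


def _mini(lines):
    return parse_pdb("\n".join(lines) + "\nEND\n", code="mini")


def _atom(serial, name, res, ch, num, xyz, el, het=False):
    return _pdb_atom_line(serial, name, res, ch, num, np.asarray(xyz, float), el, het=het)


# --- hydrogen placement ----------------------------------------------------

def test_backbone_nh_in_peptide_plane(helix):
    hpos = place_polar_hydrogens(helix)
    res2 = helix.chains[0].residues[1]
    key = ("A", 2, " ", "N")
    assert key in hpos and len(hpos[key]) == 1
    h = hpos[key][0]
    n = res2.atom("N").xyz
    assert np.linalg.norm(h - n) == pytest.approx(1.0, abs=1e-9)
    c_prev = helix.chains[0].residues[0].atom("C").xyz
    ca = res2.atom("CA").xyz
    normal = np.cross(c_prev - n, ca - n)
    normal /= np.linalg.norm(normal)
    assert abs(np.dot(h - n, normal)) < 1e-9  # in the C(prev)-N-CA plane


def test_proline_nitrogen_has_no_amide_h():
    lines = [
        _atom(1, "N", "ALA", "A", 1, (0, 0, 0), "N"),
        _atom(2, "CA", "ALA", "A", 1, (1.46, 0, 0), "C"),
        _atom(3, "C", "ALA", "A", 1, (2.0, 1.4, 0), "C"),
        _atom(4, "O", "ALA", "A", 1, (1.4, 2.4, 0), "O"),
        _atom(5, "N", "PRO", "A", 2, (3.3, 1.5, 0), "N"),
        _atom(6, "CA", "PRO", "A", 2, (4.2, 2.6, 0), "C"),
        _atom(7, "C", "PRO", "A", 2, (5.6, 2.0, 0), "C"),
    ]
    hpos = place_polar_hydrogens(_mini(lines))
    assert ("A", 2, " ", "N") not in hpos


def test_arginine_nh2_gets_two_hydrogens():
    # planar guanidinium fragment
    lines = [
        _atom(1, "N", "ARG", "A", 1, (0, 0, 0), "N"),
        _atom(2, "CA", "ARG", "A", 1, (1.46, 0, 0), "C"),
        _atom(3, "C", "ARG", "A", 1, (2.0, 1.4, 0), "C"),
        _atom(4, "NE", "ARG", "A", 1, (4.0, 4.0, 0), "N"),
        _atom(5, "CZ", "ARG", "A", 1, (5.0, 4.8, 0), "C"),
        _atom(6, "NH1", "ARG", "A", 1, (6.2, 4.4, 0), "N"),
        _atom(7, "NH2", "ARG", "A", 1, (4.8, 6.1, 0), "N"),
    ]
    hpos = place_polar_hydrogens(_mini(lines))
    assert len(hpos[("A", 1, " ", "NH2")]) == 2
    assert len(hpos[("A", 1, " ", "NH1")]) == 2


# --- hydrogen bonds ---------------------------------------------------------

def _nh_pair(d_a):
    """Donor N (with antecedents) and acceptor backbone O at distance d_a,
    arranged nearly linear through the reconstructed H."""
    lines = [
        _atom(1, "N", "GLY", "A", 1, (0, 0, 0), "N"),
        _atom(2, "CA", "GLY", "A", 1, (1.46, 0, 0), "C"),
        _atom(3, "C", "GLY", "A", 1, (2.0, 1.4, 0), "C"),
        _atom(4, "O", "GLY", "A", 1, (1.35, 2.45, 0), "O"),
        _atom(5, "N", "GLY", "A", 2, (3.33, 1.5, 0), "N"),
        _atom(6, "CA", "GLY", "A", 2, (4.25, 2.6, 0), "C"),
        _atom(7, "C", "GLY", "A", 2, (5.65, 2.0, 0), "C"),
        _atom(8, "O", "GLY", "A", 2, (6.65, 2.7, 0), "O"),
    ]
    s0 = _mini(lines)
    hpos = place_polar_hydrogens(s0)
    h = hpos[("A", 2, " ", "N")][0]
    n = s0.chains[0].residues[1].atom("N").xyz
    direction = (h - n) / np.linalg.norm(h - n)
    acceptor = n + direction * d_a
    lines.append(_atom(9, "O", "HOH", "W", 1, acceptor, "O"))
    return _mini(lines)


def test_hbond_inside_all_cutoffs_reported():
    s = _nh_pair(2.9)
    hbonds = find_hbonds(s)
    pairs = hbond_pairs_of(hbonds)
    assert (("A", 2, " ", "N"), ("W", 1, " ", "O")) in pairs
    hb = [x for x in hbonds if x.donor.key == ("A", 2, " ", "N")
          and x.acceptor.key == ("W", 1, " ", "O")][0]
    assert hb.dha_angle > 150.0


def test_hbond_distance_failure_not_reported():
    s = _nh_pair(4.5)
    pairs = hbond_pairs_of(find_hbonds(s))
    assert (("A", 2, " ", "N"), ("W", 1, " ", "O")) not in pairs


def test_hairpin_hbonds_equal_brute_force(hairpin):
    fast = hbond_pairs_of(find_hbonds(hairpin))
    assert fast == brute_force_hbonds(hairpin)


def test_randomised_clusters_hbond_and_contact_sets_match_oracle():
    rng = np.random.default_rng(2024)
    for _ in range(25):
        s = parse_pdb(random_cluster_pdb(rng), code="rand")
        hbonds = find_hbonds(s)
        fast_hb = hbond_pairs_of(hbonds)
        assert fast_hb == brute_force_hbonds(s)
        fast_nb = {frozenset((c.atom_a.key, c.atom_b.key))
                   for c in find_nonbonded(s, hbonds=hbonds)}
        assert fast_nb == brute_force_nonbonded(s, hbond_pairs=fast_hb)


# --- non-bonded contacts -----------------------------------------------------

def test_nonbonded_distance_cutoff():
    base = [
        _atom(1, "CB", "ALA", "A", 1, (0, 0, 0), "C"),
        _atom(2, "CB", "ALA", "A", 2, (3.5, 0, 0), "C"),
        _atom(3, "CB", "ALA", "B", 3, (0, 50, 0), "C"),
        _atom(4, "CB", "ALA", "B", 4, (4.0, 50, 0), "C"),
    ]
    contacts = find_nonbonded(_mini(base))
    dists = sorted(round(c.dist, 2) for c in contacts)
    assert dists == [3.50]  # the 4.0 A pair is outside the 3.9 cutoff


def test_hbond_pairs_excluded_from_nonbonded(hairpin, hairpin_contacts):
    hb_pairs = {hb.pair_key for hb in hairpin_contacts.hbonds}
    nb_pairs = {c.pair_key for c in hairpin_contacts.nonbonded}
    assert not hb_pairs & nb_pairs


def test_hbonds_satisfy_contact_distance_criterion(hairpin_contacts):
    crit = ContactCriteria()
    for hb in hairpin_contacts.hbonds:
        assert hb.d_a <= crit.nonbonded_max


# --- salt bridges ------------------------------------------------------------

def _charged_pair(acid_res, acid_atom, dist):
    return [
        _atom(1, "NZ", "LYS", "A", 1, (0, 0, 0), "N"),
        _atom(2, acid_atom, acid_res, "B", 2, (dist, 0, 0),
              "O" if acid_atom.startswith("O") else "N"),
    ]


def test_salt_bridge_detected_and_chemistry_checked():
    s = _mini(_charged_pair("ASP", "OD1", 3.2))
    assert len(find_salt_bridges(s)) == 1
    s2 = _mini([
        _atom(1, "NZ", "LYS", "A", 1, (0, 0, 0), "N"),
        _atom(2, "OG", "SER", "B", 2, (3.2, 0, 0), "O"),
    ])
    assert find_salt_bridges(s2) == []


def test_salt_bridge_count_invariant_under_chain_swap():
    lines = _charged_pair("GLU", "OE2", 3.5)
    swapped = [ln.replace(" A ", " X ").replace(" B ", " A ").replace(" X ", " B ")
               for ln in lines]
    assert len(find_salt_bridges(_mini(lines))) == \
           len(find_salt_bridges(_mini(swapped)))


def test_salt_bridges_match_brute_force_on_random_charged_clusters():
    rng = np.random.default_rng(77)
    for _ in range(20):
        lines = []
        serial = 1
        for k in range(int(rng.integers(2, 6))):
            res, atom = [("LYS", "NZ"), ("ARG", "NH1"), ("ASP", "OD1"),
                         ("GLU", "OE1"), ("HIS", "NE2")][int(rng.integers(5))]
            xyz = rng.uniform(-5, 5, size=3)
            lines.append(_atom(serial, atom, res, "A", serial, xyz,
                               "O" if atom.startswith("O") else "N"))
            serial += 1
        s = _mini(lines)
        fast = {(sb.basic_atom.residue.key, sb.basic_atom.atom.name,
                 sb.acidic_atom.residue.key, sb.acidic_atom.atom.name)
                for sb in find_salt_bridges(s)}
        assert fast == brute_force_salt_bridges(s)


# --- metals ------------------------------------------------------------------

def test_metal_coordination_rules():
    lines = [
        _atom(1, "ZN", "ZN", "M", 1, (0, 0, 0), "ZN", het=True),
        _atom(2, "NE2", "HIS", "A", 2, (2.1, 0, 0), "N"),
        _atom(3, "CB", "ALA", "A", 3, (0, 2.1, 0), "C"),
    ]
    contacts = find_metal_contacts(_mini(lines))
    partners = {c.atom_b.atom.name for c in contacts}
    assert partners == {"NE2"}  # carbon excluded


def test_no_metals_empty(helix):
    assert find_metal_contacts(helix) == []


# --- invariances ---------------------------------------------------------------

def test_contact_results_invariant_under_rigid_motion():
    rng = np.random.default_rng(55)
    text = make_beta_hairpin()
    s = parse_pdb(text, code="ref")
    ref = analyse_contacts(s)
    rot = rotation_matrix(rng.normal(size=3), 73.0)
    shift = np.array([11.0, -6.0, 4.0])
    s2 = parse_pdb(text, code="mov")
    for _, a in s2.atoms():
        a.xyz = rot @ a.xyz + shift
    moved = analyse_contacts(s2)
    assert hbond_pairs_of(ref.hbonds) == hbond_pairs_of(moved.hbonds)
    ref_nb = sorted((c.pair_key, round(c.dist, 6)) for c in ref.nonbonded)
    mov_nb = sorted((c.pair_key, round(c.dist, 6)) for c in moved.nonbonded)
    for (ka, da), (kb, db) in zip(ref_nb, mov_nb):
        assert ka == kb and abs(da - db) < 1e-6
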