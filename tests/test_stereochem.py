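"""Torsions, Ramachandran regions, geometry checks, G-factors, profile."""

import numpy as np
import pytest

from structsum.fixtures import (ANGLE_N_CA_C, BOND_CA_C, BOND_CA_CB, BOND_N_CA,
                                IMPROPER_CB, ANGLE_N_CA_CB, PeptideSpec,
                                make_ideal_helix, make_peptide, place_atom)
from structsum.geometry import dihedral
from structsum.pdb_io import parse_pdb
from structsum.stereochem import (GeometryDeviation, check_geometry,
                                  check_planarity, compute_g_factors,
                                  compute_structure_torsions, log_odds_phi_psi,
                                  ramachandran_counts, ramachandran_region,
                                  region_grid, res_class,
                                  residue_property_profile, ramachandran_svg,
                                  REGIONS, _cell, GRID_N)


# --- torsions -----------------------------------------------------------------

def test_constructed_torsions_recovered(helix):
    torsions = compute_structure_torsions(helix)
    for ts in torsions[1:-1]:
        assert ts.phi == pytest.approx(-57.0, abs=0.5)
        assert ts.psi == pytest.approx(-47.0, abs=0.5)
        assert abs(abs(ts.omega) - 180.0) < 0.5


def test_terminal_torsions_undefined(helix):
    torsions = compute_structure_torsions(helix)
    assert torsions[0].phi is None and torsions[0].omega is None
    assert torsions[-1].psi is None


def test_zeta_from_ideal_internal_coordinates():
    """Rebuild an ideal L-residue from internal coordinates and verify
    the CA-N-C-CB virtual torsion independently of the fixture path."""
    n = np.zeros(3)
    ca = np.array([BOND_N_CA, 0.0, 0.0])
    ang = np.radians(ANGLE_N_CA_C)
    c = ca + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    cb = place_atom(c, n, ca, BOND_CA_CB, ANGLE_N_CA_CB, IMPROPER_CB)
    zeta = dihedral(ca, n, c, cb)
    assert zeta == pytest.approx(33.9, abs=0.5)

    helix = parse_pdb(make_ideal_helix(6), code="z")
    ts = compute_structure_torsions(helix)[2]
    assert ts.zeta == pytest.approx(zeta, abs=0.5)


# --- Ramachandran regions -------------------------------------------------------

@pytest.mark.parametrize("phi,psi,expected", [
    (-60.0, -45.0, "core"),      # canonical alpha
    (-120.0, 130.0, "core"),     # canonical beta
])
def test_canonical_points_are_core(phi, psi, expected):
    assert ramachandran_region(phi, psi, "general") == expected


def test_region_counts_match_per_residue_lookup():
    rng = np.random.default_rng(21)
    from structsum.stereochem import TorsionSet

    torsions = []
    for i in range(200):
        resname = rng.choice(["ALA", "GLY", "PRO", "LEU"])
        ts = TorsionSet(key=("A", i, " "), resname=str(resname),
                        phi=float(rng.uniform(-180, 180)),
                        psi=float(rng.uniform(-180, 180)))
        torsions.append(ts)
    counts = ramachandran_counts(torsions)
    oracle = {r: 0 for r in REGIONS}
    for ts in torsions:
        grid = region_grid(res_class(ts.resname))
        oracle[REGIONS[grid[_cell(ts.phi), _cell(ts.psi)]]] += 1
    assert counts == oracle
    assert sum(counts.values()) == 200  # full partition


def test_region_fractions_partition_and_monotone():
    for rc in ("general", "gly", "pro"):
        grid = region_grid(rc)
        fracs = [(grid == k).mean() for k in range(4)]
        assert sum(fracs) == pytest.approx(1.0)
        assert fracs[0] < fracs[0] + fracs[1]  # core < allowed-or-better


def test_undefined_torsions_excluded_from_counts(helix):
    torsions = compute_structure_torsions(helix)
    counts = ramachandran_counts(torsions)
    defined = sum(1 for ts in torsions if ts.phi is not None and ts.psi is not None)
    assert sum(counts.values()) == defined == 10


# --- geometry deviations ----------------------------------------------------------

def test_ideal_fixture_produces_no_deviation(helix):
    assert check_geometry(helix) == []


def test_injected_angle_distortion_flagged_once():
    spec = PeptideSpec("AAA", [(-57.0, -47.0, 180.0)] * 3)
    text = make_peptide(spec)
    s = parse_pdb(text, code="bad")
    res = s.chains[0].residues[1]
    # rotate C about CA so N-CA-C opens by +15 degrees
    n, ca, c = res.atom("N"), res.atom("CA"), res.atom("C")
    axis = np.cross(n.xyz - ca.xyz, c.xyz - ca.xyz)
    from structsum.geometry import rotation_matrix, angle

    rot = rotation_matrix(axis, 15.0)
    c.xyz = ca.xyz + rot @ (c.xyz - ca.xyz)
    devs = [d for d in check_geometry(s) if d.kind == "bond-angle"
            and d.atoms == ("N", "CA", "C")]
    assert len(devs) == 1
    assert devs[0].actual == pytest.approx(111.2 + 15.0, abs=0.1)


def test_bond_length_distortion_flagged():
    spec = PeptideSpec("AA", [(-57.0, -47.0, 180.0)] * 2)
    s = parse_pdb(make_peptide(spec), code="bad")
    res = s.chains[0].residues[0]
    ca, c = res.atom("CA"), res.atom("C")
    u = (c.xyz - ca.xyz) / np.linalg.norm(c.xyz - ca.xyz)
    c.xyz = c.xyz + 0.10 * u   # stretch CA-C by 0.10 A
    kinds = [(d.kind, d.atoms) for d in check_geometry(s)]
    assert ("bond-length", ("CA", "C")) in kinds


# --- planarity ---------------------------------------------------------------------

def _ring_structure(displacement=0.0):
    """PHE ring as a perfect hexagon, optionally one atom displaced
    perpendicular to the ring plane."""
    from structsum.fixtures import _pdb_atom_line

    names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
    lines = [
        _pdb_atom_line(1, "N", "PHE", "A", 1, np.array([-3.0, 0, 0]), "N"),
        _pdb_atom_line(2, "CA", "PHE", "A", 1, np.array([-2.0, 0.8, 0]), "C"),
        _pdb_atom_line(3, "C", "PHE", "A", 1, np.array([-2.2, 2.2, 0]), "C"),
    ]
    r = 1.39
    for k, name in enumerate(names):
        theta = np.pi / 3 * k
        xyz = np.array([r * np.cos(theta), r * np.sin(theta), 0.0])
        if k == 3:
            xyz[2] += displacement
        lines.append(_pdb_atom_line(4 + k, name, "PHE", "A", 1, xyz, "C"))
    return parse_pdb("\n".join(lines) + "\nEND\n", code="ring")


def test_coplanar_ring_not_flagged():
    assert check_planarity(_ring_structure(0.0)) == []


def test_displaced_ring_atom_flagged_with_analytic_rms():
    disp = 0.12
    flagged = check_planarity(_ring_structure(disp))
    assert len(flagged) == 1
    # closed form for one vertex of a regular hexagon displaced d
    # perpendicular to the ring: the best-fit plane shifts by d/6 and
    # tilts about the perpendicular in-plane axis, leaving residuals
    # (d/2, d/6, 0, 0, -d/3, -d/3) whose rms is d/(2*sqrt(3))
    expected = disp / (2.0 * np.sqrt(3.0))
    assert flagged[0].actual == pytest.approx(expected, abs=2e-4)


def test_partial_ring_skipped():
    s = _ring_structure(0.5)
    ring = s.chains[0].residues[0]
    ring.atoms = [a for a in ring.atoms if a.name in ("N", "CA", "C", "CG", "CD1", "CE1")]
    assert check_planarity(s) == []  # only 3 ring atoms remain


# --- G-factors ------------------------------------------------------------------------

def test_modal_cell_gives_maximum_g():
    from structsum.stereochem import TorsionSet, _hist_2d

    h = _hist_2d("general")
    imax = np.unravel_index(np.argmax(h), h.shape)
    phi = -180.0 + (imax[0] + 0.5) * 10.0
    psi = -180.0 + (imax[1] + 0.5) * 10.0
    torsions = [TorsionSet(key=("A", i, " "), resname="ALA", phi=phi, psi=psi)
                for i in range(5)]
    gf = compute_g_factors(torsions)
    assert gf.phi_psi == pytest.approx(float(np.log10(h.max())), abs=1e-9)


def test_uniform_sample_matches_direct_average():
    from structsum.stereochem import TorsionSet

    rng = np.random.default_rng(33)
    torsions = [TorsionSet(key=("A", i, " "), resname="ALA",
                           phi=float(rng.uniform(-180, 180)),
                           psi=float(rng.uniform(-180, 180)))
                for i in range(400)]
    gf = compute_g_factors(torsions)
    direct = np.mean([log_odds_phi_psi(ts.phi, ts.psi, "general")
                      for ts in torsions])
    assert gf.phi_psi == pytest.approx(float(direct), abs=1e-12)


def test_g_factors_permutation_invariant(helix):
    torsions = compute_structure_torsions(helix)
    gf1 = compute_g_factors(torsions)
    gf2 = compute_g_factors(list(reversed(torsions)))
    assert gf1.phi_psi == pytest.approx(gf2.phi_psi)
    assert gf1.overall == pytest.approx(gf2.overall)


def test_missing_chi_components_excluded(helix):
    torsions = compute_structure_torsions(helix)  # poly-ALA: no chi
    gf = compute_g_factors(torsions)
    assert gf.chi1_chi2 is None and gf.chi1_only is None
    assert gf.overall == pytest.approx((gf.phi_psi + gf.omega) / 2)


# --- property profile --------------------------------------------------------------------

def test_trans_peptide_omega_deviation_small(helix):
    torsions = compute_structure_torsions(helix)
    props = residue_property_profile(helix, torsions)
    for p in props:
        if p.domega is not None:
            assert p.domega < 1.0
            assert not p.is_cis


def test_omega_150_gives_30_deviation():
    from structsum.stereochem import TorsionSet

    ts = TorsionSet(key=("A", 1, " "), resname="ALA", omega=150.0)
    p = residue_property_profile.__wrapped__ if hasattr(
        residue_property_profile, "__wrapped__") else None
    props = residue_property_profile(None, [ts])
    assert props[0].domega == pytest.approx(30.0)
    assert not props[0].is_cis


def test_cis_proline_reported_as_cis():
    from structsum.stereochem import TorsionSet

    ts = TorsionSet(key=("A", 1, " "), resname="PRO", omega=5.0)
    props = residue_property_profile(None, [ts])
    assert props[0].is_cis and props[0].domega == pytest.approx(5.0)


def test_ramachandran_svg_well_formed(helix):
    import xml.etree.ElementTree as ET

    torsions = compute_structure_torsions(helix)
    svg = ramachandran_svg(torsions, "helx")
    root = ET.fromstring(svg)
    assert root.tag.endswith("svg")
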