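"""PDB parsing, entry codes, chain classification, coverage."""

import numpy as np
import pytest

from structsum.fixtures import make_toy_complex
from structsum.pdb_io import (PdbParseError, assign_pdb_code, classify_chains,
                              coverage_count, parse_pdb, write_pdb)

ATOM = "ATOM  {serial:5d} {name:<4s}{alt:1s}{res:>3s} {ch:1s}{num:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {el:>2s}"


def line(serial=1, name=" N  ", alt=" ", res="ALA", ch="A", num=1,
         x=0.0, y=0.0, z=0.0, occ=1.0, b=10.0, el="N"):
    return ATOM.format(serial=serial, name=name, alt=alt, res=res, ch=ch,
                       num=num, x=x, y=y, z=z, occ=occ, b=b, el=el)


def test_minimal_single_atom_parse():
    s = parse_pdb(line() + "\nEND\n", code="test")
    assert len(s.chains) == 1
    assert len(s.chains[0].residues) == 1
    assert len(s.chains[0].residues[0].atoms) == 1
    atom = s.chains[0].residues[0].atoms[0]
    assert atom.name == "N" and atom.element == "N"
    assert np.allclose(atom.xyz, [0, 0, 0])


def test_first_model_only():
    text = "\n".join([
        "MODEL        1",
        line(1, " N  ", num=1), line(2, " CA ", num=1, x=1.5, el="C"),
        line(3, " C  ", num=1, x=2.5, el="C"),
        "ENDMDL",
        "MODEL        2",
        line(4, " N  ", num=1, y=9), line(5, " CA ", num=1, x=1.5, y=9, el="C"),
        line(6, " C  ", num=1, x=2.5, y=9, el="C"),
        "ENDMDL", "END",
    ])
    s = parse_pdb(text, code="test")
    atoms = [a for _, a in s.atoms()]
    assert len(atoms) == 3
    assert all(a.xyz[1] == 0 for a in atoms)  # model-1 coordinates retained


def test_altloc_highest_occupancy_ties_by_character():
    text = "\n".join([
        line(1, " CA ", alt="B", num=1, x=1.0, occ=0.4, el="C"),
        line(2, " CA ", alt="A", num=1, x=2.0, occ=0.6, el="C"),
        line(3, " CB ", alt="B", num=1, x=3.0, occ=0.5, el="C"),
        line(4, " CB ", alt="A", num=1, x=4.0, occ=0.5, el="C"),
        "END",
    ])
    s = parse_pdb(text, code="test")
    res = s.chains[0].residues[0]
    assert len(res.atoms) == 2
    assert res.atom("CA").xyz[0] == pytest.approx(2.0)   # higher occupancy
    assert res.atom("CB").xyz[0] == pytest.approx(4.0)   # tie: altloc 'A'


def test_malformed_records_skipped_and_counted():
    good = line(1, " N  ")
    bad = good.replace("   0.000", " abc.000", 1)
    s = parse_pdb("\n".join([good, bad, "END"]), code="test")
    assert s.n_malformed == 1
    assert sum(1 for _ in s.atoms()) == 1


def test_no_coordinates_is_hard_error():
    with pytest.raises(PdbParseError):
        parse_pdb("HEADER    EMPTY\nEND\n", code="test", name="empty.pdb")


def test_round_trip_field_by_field(toy_complex):
    text = write_pdb(toy_complex)
    again = parse_pdb(text, code=toy_complex.code)
    res_a = list(toy_complex.residues())
    res_b = list(again.residues())
    assert len(res_a) == len(res_b)
    for ra, rb in zip(res_a, res_b):
        assert (ra.resname, ra.resseq, ra.icode, ra.category) == \
               (rb.resname, rb.resseq, rb.icode, rb.category)
        assert len(ra.atoms) == len(rb.atoms)
        for aa, ab in zip(ra.atoms, rb.atoms):
            assert aa.name == ab.name and aa.element == ab.element
            assert aa.is_het == ab.is_het
            assert np.allclose(aa.xyz, ab.xyz, atol=1e-3)


def test_classification_invariant_under_residue_order(toy_complex):
    text = make_toy_complex()
    lines = [ln for ln in text.splitlines() if ln[:6] in ("ATOM  ", "HETATM")]
    rng = np.random.default_rng(4)
    by_res = {}
    for ln in lines:
        by_res.setdefault((ln[21], ln[22:26]), []).append(ln)
    keys = list(by_res)
    rng.shuffle(keys)
    shuffled = "\n".join(ln for k in keys for ln in by_res[k]) + "\nEND\n"
    assert classify_chains(parse_pdb(shuffled, code="x")) == classify_chains(toy_complex)


# --- entry codes -----------------------------------------------------------

def test_code_from_pdbxxxx_filename():
    assert assign_pdb_code("pdb18gs.ent") == "18gs"


def test_code_user_supplied_wins():
    assert assign_pdb_code("model.pdb", "ab12") == "ab12"


def test_code_auto_generated_sequence():
    assert assign_pdb_code("model.pdb") == "a001"
    assert assign_pdb_code("model.pdb", registry={"a001", "a002"}) == "a003"


def test_code_validation_errors():
    with pytest.raises(ValueError):
        assign_pdb_code("model.pdb", "toolong")
    with pytest.raises(ValueError):
        assign_pdb_code("model.pdb", "ab12", registry={"ab12"})


# --- classification and coverage -------------------------------------------

def _poly(res, n, ch="A", el_map=None):
    lines = []
    serial = 1
    for i in range(1, n + 1):
        for name, el in (el_map or [(" N  ", "N"), (" CA ", "C"), (" C  ", "C"), (" O  ", "O")]):
            lines.append(line(serial, name, res=res, ch=ch, num=i,
                              x=serial * 2.0, el=el))
            serial += 1
    return lines


def test_classify_protein_water_dna():
    prot = "\n".join(_poly("ALA", 5, "A") + ["TER"])
    wat = "\n".join(
        line(100 + i, " O  ", res="HOH", ch="W", num=i, x=50 + i * 3.0, el="O")
        for i in range(1, 4))
    dna = "\n".join(
        line(200 + i * 4 + j, name, res=res, ch="D", num=i, x=80 + (i * 4 + j) * 2.0, el=el)
        for i, res in enumerate(["DA", "DT", "DG", "DC"], start=1)
        for j, (name, el) in enumerate([(" P  ", "P"), (" C1'", "C"), (" N1 ", "N"), (" O3'", "O")])
    )
    s = parse_pdb("\n".join([prot, wat, dna, "END"]), code="mix")
    kinds = classify_chains(s)
    assert kinds == {"A": "protein", "W": "water-only", "D": "dna"}


def test_coverage_with_and_without_seqres():
    seqres = "SEQRES   1 A   10  ALA ALA ALA ALA ALA ALA ALA ALA ALA ALA"
    body = "\n".join(_poly("ALA", 8, "A"))
    s = parse_pdb(seqres + "\n" + body + "\nEND\n", code="cov")
    assert coverage_count(s, "A") == (8, 10)
    s2 = parse_pdb(body + "\nEND\n", code="cov")
    assert coverage_count(s2, "A") == (8, 8)
    with pytest.raises(KeyError):
        coverage_count(s2, "Z")


def test_element_inference_without_element_column():
    raw = line(1, " CA ", el="C")[:66]  # truncate the element columns
    s = parse_pdb(raw + "\nEND\n", code="test")
    assert s.chains[0].residues[0].atoms[0].element == "C"


def test_mse_is_amino_even_as_hetatm():
    l = line(1, " CA ", res="MSE", el="C").replace("ATOM  ", "HETATM")
    s = parse_pdb(l + "\nEND\n", code="test")
    assert s.chains[0].residues[0].category == "amino"
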