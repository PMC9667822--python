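"""Secondary-structure assignment and beta-turn classification.

Assigns hydrogen-bond-pattern states to the hairpin fixture and
classifies its turns. Expected: two 3-residue strands (E) in one
sheet 'A' joined by a type-I' turn at residues 5-8.
"""

from structsum.fixtures import make_beta_hairpin
from structsum.pdb_io import parse_pdb
from structsum.secstruct import (assign_secondary_structure, find_beta_turns,
                                 find_hairpins)

structure = parse_pdb(make_beta_hairpin(), code="hpin")
ss = assign_secondary_structure(structure)

states = "".join(state for _, state in ss.states_in_order())
print(f"states:  {states}   (E strand, T turn, '-' coil)")
for strand in ss.strands:
    resseqs = [k[1] for k in strand.keys]
    print(f"strand {strand.strand_id}: residues {min(resseqs)}-{max(resseqs)}, "
          f"sheet {strand.sheet_id}")

for turn in find_beta_turns(structure, ss):
    print(f"beta turn {turn.keys[0][1]}-{turn.keys[3][1]}: class {turn.turn_class} "
          f"(central torsions {', '.join(f'{v:.0f}' for v in turn.phi_psi)})")

for hp in find_hairpins(ss):
    print(f"hairpin: strands {hp.strand_a}+{hp.strand_b}, "
          f"loop residues {[k[1] for k in hp.loop_keys]}")
print("A type-I' turn is the canonical tight connector of a 2:2 beta hairpin.")
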