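"""Stereochemical quality: torsions, Ramachandran regions, distortions.

Computes the quality summary for an ideal helix (everything core, no
flags), then bends one backbone angle by 15 degrees and shows the
check catching exactly that distortion.
"""

import numpy as np

from structsum.fixtures import make_ideal_helix
from structsum.geometry import rotation_matrix
from structsum.pdb_io import parse_pdb
from structsum.stereochem import (check_geometry, compute_g_factors,
                                  compute_structure_torsions, procheck_summary)

structure = parse_pdb(make_ideal_helix(12), code="helx")
torsions = compute_structure_torsions(structure)
gfactors = compute_g_factors(torsions)
deviations = check_geometry(structure)
print(procheck_summary(torsions, gfactors, deviations))

# bend N-CA-C of residue 6 by +15 degrees
res = structure.chains[0].residues[5]
n, ca, c = (res.atom(x) for x in ("N", "CA", "C"))
axis = np.cross(n.xyz - ca.xyz, c.xyz - ca.xyz)
delta = ca.xyz + rotation_matrix(axis, 15.0) @ (c.xyz - ca.xyz) - c.xyz
c.xyz = c.xyz + delta
res.atom("O").xyz = res.atom("O").xyz + delta

print("after distorting residue 6:")
for d in check_geometry(structure):
    print(f"  {d.kind:12s} {d.resname}{d.key[1]}({d.key[0]}) "
          f"{'-'.join(d.atoms):10s} actual {d.actual:7.2f} ideal {d.ideal:7.2f}")
print("Flags appear only where the deviation from the ideal-geometry "
      "reference exceeds 0.05 A (bonds) or 10 degrees (angles).")
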