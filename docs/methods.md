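# Methods

This note records the models, parameter choices and numerical
decisions behind each analysis, what the synthetic test structures do
and do not emulate, and the known limitations.

## Coordinate model

PDB fixed-column text is parsed with gemmi after a light
pre-validation pass that drops (and counts) ATOM/HETATM records whose
numeric fields do not parse — gemmi would otherwise zero-fill them
silently, which is worse than losing the record. Only the first MODEL
of an ensemble is kept: every analysis here treats a single
conformer. Alternate locations are reduced per atom name to the
highest-occupancy conformer, ties broken by the lower altloc
character, so each retained atom is uniquely addressed by
(chain, resseq, icode, name). Author residue numbering and insertion
codes are reported unchanged. Residues are categorised as amino,
nucleotide, water, metal or ligand from the residue name and record
type; non-standard residues in ATOM records count as amino acids
(MSE always does). Chain fragments that reappear under the same
identifier later in a file are merged. Elements missing from the
element columns are inferred from the atom-name columns.

## Contacts

A donor/acceptor table covers the backbone (N donor except proline,
O/OXT acceptor) and the polar side chains of S, T, Y, C, K, R, H, W,
N, Q, D, E, M. Water oxygens and HET-group N/O are both donor and
acceptor with distance-only criteria (no hydrogen can be placed
reliably). Polar hydrogens are constructed at 1.00 Å: sp2 donors in
the plane of their antecedents (backbone N–H on the bisector of
C(prev) and CA; amide and guanidinium H at ±120° in the group plane;
ring N–H on the ring bisector), while rotatable donors (Ser/Thr/Tyr
hydroxyl, Lys NZ, Cys SG) place their hydrogen on the rotor cone at
the position most favourable to each candidate acceptor — i.e. the
angle test uses the best rotamer, matching how a distance-plus-angle
criterion is normally applied when hydroxyl orientations are unknown.

A donor–acceptor pair is a hydrogen bond iff D–A ≤ 3.9 Å and, when an
H exists, H–A ≤ 2.5 Å and ∠D–H⋯A ≥ 90°. These are the published
defaults of the HBPLUS lineage; all are in the configuration file.
Non-bonded contacts are all other inter-residue heavy-atom pairs
within 3.9 Å. Pairs within two covalent bonds are excluded from both
searches; connectivity is inferred from covalent radii (+0.45 Å)
inside residues plus explicit peptide/phosphodiester links and the
S–S ≤ 2.5 Å disulphide test, which gives the same exclusion set as a
residue template table on standard residues and extends uniformly to
arbitrary HET groups. Salt bridges pair Lys NZ / Arg NE,NH1,NH2 /
His ND1,NE2 with Asp/Glu carboxylate oxygens at ≤ 4.0 Å, one record
(minimum distance) per residue pair; metals coordinate N/O/S within
2.8 Å. Pair searches use a k-d tree; the tests hold the result sets
equal to exhaustive O(n²) scans on randomised structures, so the
acceleration is purely an implementation detail.

Water-mediated bridges are not computed; π/aromatic and halogen
interactions are out of scope.

## Secondary structure and motifs

Assignment follows the Kabsch–Sander scheme. The amide hydrogen is
always reconstructed from backbone geometry (1.0 Å from N along the
previous C=O direction), even when the file contains hydrogens, for
uniformity. The energy E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH −
1/r_CN) kcal/mol marks a hydrogen bond when E < −0.5; adjacent
residues are never paired. Two consecutive n-turns make a helix
(4→H, 3→G, 5→I; minimum length 4 for H); parallel/antiparallel
bridge patterns make ladders, ladders of length ≥ 2 make strands (E;
isolated bridges are B), and sheets are the union-find closure of
ladder links, labelled A, B, … by residue count then first
occurrence. Remaining turn residues get T; bends (S) mark CA-trace
kinks above 70°. Helix ids H1, H2, … run over the whole structure in
(chain, residue) order.

Beta turns are all four-residue windows with CA(i)–CA(i+3) < 7 Å
whose two central residues are not both helical, classified against
the Hutchinson–Thornton ideal table (I, I′, II, II′, VIII, and the
cis-proline classes VIa1, VIa2, VIb) with the standard tolerance:
every central torsion within ±30° of the class ideal, except that a
single torsion may stray to ±45°; IV is the catch-all. Gamma turns
require the CO(i)⋯NH(i+2) hydrogen bond and a central (φ, ψ) within
±40° of (75, −64) (classic) or (−79, 69) (inverse).

Sheet motifs are defined over strands and ladders: hairpins are
sequence-adjacent antiparallel strand pairs of one sheet; bulges are
irregular rung steps where one strand advances two residues against
one; β-α-β units are parallel strand pairs of one sheet with at
least one helix strictly between them in sequence; ψ-loops are
antiparallel pairs adjacent in the sheet but separated by more than
ten residues with an intervening strand. The bulge and ψ-loop
definitions are declared here (they vary between programs) and are
deliberately simple; they are not asserted to match any specific
historical implementation.

Helix packing reports pairs whose principal-component axis segments
approach within 10 Å. The packing angle Ω is the signed torsion
between the two axis vectors (oriented N→C) about the
closest-approach vector, in (−180°, 180°], positive for right-handed
packing: parallel pairs sit near 0°, antiparallel near ±180°. A
folded ±90° range would collapse the parallel/antiparallel
distinction, so the full range is kept.

## Stereochemical quality

Backbone torsions use the standard atom quadruples (ω of residue i
is CA(i−1)-C(i−1)-N(i)-CA(i)); χ1–χ4 come from the usual side-chain
tables; ζ is the CA-N-C-CB virtual torsion whose ideal value +33.9°
encodes L-chirality at CA (deviations beyond 15° are flagged, which
catches D-residues and distorted CAs). Any torsion with missing
atoms is undefined, never zero.

Bond lengths and angles are compared with the Engh–Huber ideal set
(N-CA 1.458, CA-C 1.525, C-N 1.329, C=O 1.231, CA-CB 1.530 Å; N-CA-C
111.2°, CA-C-N 116.2°, C-N-CA 121.7°, CA-C-O 120.8°, O-C-N 123.0°,
N-CA-CB 110.4°, CB-CA-C 110.1°); records are emitted above 0.05 Å /
10.0°, the classic "distorted geometry" thresholds. The same
constants drive the synthetic-structure builder, so unperturbed
fixtures pass cleanly by construction — that coupling is itself under
test. Planar groups (aromatic rings, His, Arg guanidinium,
carboxylates and amides) are flagged when the RMS distance from the
total-least-squares plane exceeds 0.03 Å (rings) or 0.02 Å (others);
groups with fewer than four present atoms are skipped.

The Ramachandran region grid (10°×10°, half-open cells, separate
general/Gly/Pro variants) is generated from smooth circular Gaussian
mixtures centred on the canonical basins (α at (−63, −43), β at
(−120, 130), polyproline II, left-handed α; mirrored basins for Gly;
φ-restricted basins for Pro) and thresholded at fixed area
fractions: the densest 12% of the plot is core, the next 18%
allowed, the next 25% generous, the rest disallowed. The canonical
α and β points fall in core by construction. The grid is data
generated by one versioned function — swappable, and not claimed to
be cell-for-cell identical to any published grid. The same mixture
densities, floored and normalised to mean 1, serve as the reference
histograms for the G-factors: a residue's G is log10 of its cell's
normalised frequency, components (φψ, χ1χ2, χ1-only, ω) are averaged
over residues, and the overall G-factor is the mean of defined
components. Because these reference histograms are generated rather
than fitted to a survey of structures, G-factor values are
property-tested (modal-cell maximum, permutation invariance,
direct-averaging agreement) rather than compared with published
numbers.

The per-residue profile mirrors the classic quality plot: |Δχ1| from
the nearest rotamer mean (−60/60/180), |Δω| from the nearer of 180°
(trans) and 0° (cis, reported separately), |Δζ| from +33.9°, the
secondary-structure state, mean relative accessibility, Ramachandran
region, the maximum normalised deviation, and the per-residue φψ
G-factor.

## Surface area and interfaces

SASA is Shrake–Rupley sphere-point counting with 960 points per atom
placed on a golden-section spiral — fully deterministic, so outputs
are bit-reproducible (quadrature error on an isolated atom is well
under 1%). Radii: C 1.70, N 1.55, O 1.52, S/P 1.80, default 1.70 Å;
probe 1.4 Å; waters and hydrogens excluded. Relative accessibility
divides a residue's area by its extended Gly-X-Gly reference value
(theoretical maxima of Tien et al.). Buried interface area of chain
X in pair (A, B) is SASA(X alone) − SASA(X in the A∪B complex),
computed in the pair context so third chains do not contaminate the
difference; the "wedge" percentage is buried/solo × 100. Interface
summaries count the contact records filtered to the chain pair, so
counts are symmetric by construction.

## Clefts

For every atom pair within 2·r_max + 2·r_vdw a gap sphere is centred
midway between the two van-der-Waals surfaces and shrunk until no
atom penetrates; spheres with radius ≥ r_min = 1.0 Å (cap
r_max = 4.0 Å) are kept and splatted as binary occupancy onto a 1.0 Å
voxel grid whose origin snaps to a global lattice (stability under
re-runs and translations). 26-connected components above 10 Å³ are
the clefts, ranked by volume (ties by lowest voxel index), each with
the residues within 4 Å of any voxel as lining. The binary splat is
simpler than a contoured Gaussian density and volume-faithful; it is
a declared divergence from the original contouring approach. Surface
clefts and enclosed cavities are reported together. Outputs include
per-cleft pseudo-atom PDB files (one residue per voxel, so they
re-parse losslessly) and RasMol/PyMOL scripts colouring the largest
cleft red.

## 2D ligand diagrams

The interaction graph takes ligand covalent bonds from covalent-radii
distances (+0.45 Å), hydrogen-bond edges from the contact results,
and "eyelash" residues as those with non-bonded contacts but no
hydrogen bond (H-bonds take precedence). Layout starts from the
projection onto the ligand's best-fit plane, scaled so the mean bond
is one target unit, then refines with box repulsion, bond springs and
partner tethers; moves that would raise the overlap count shrink the
step and fall back to the best layout seen, so the overlap count is
non-increasing and the result is deterministic per seed. Refinement
stops at zero overlaps or 2000 iterations (non-convergence is
flagged, never hidden). H-bond edge labels always carry the 3D
donor–acceptor distance; the 2D geometry is schematic.

## Pipeline and outputs

The controlling pipeline runs parse → contacts → secondary structure
→ stereochemistry → SASA → interfaces (all protein chain pairs) →
clefts → ligand diagrams (each HET group with ≥ 2 heavy atoms, plus
metals) → pages, per structure. A failed stage is logged, noted on
the entry's page, and does not abort the run; an unreadable input
produces an error record and the run index says so. All data files
and images are pre-generated; the HTML is static string-template
markup with no runtime dependency. Entry codes come from an explicit
argument, a `pdbXXXX.ent` filename, or the auto-sequence a001, a002,
… skipping registry entries; a source file already in the registry
keeps its code, so deleting one entry's directory and re-running
regenerates exactly that entry. `runs.tsv` is append-only. Outputs
are byte-identical across re-runs except for the files that embed
timestamps (registry, index pages, run.log). Viewer scripts use
relative paths only and provide named scenes for each beta turn
(residues coloured red/brown/green/blue in turn order) and for the
clefts (rank 1 red). Thumbnails are orthographic CA-trace SVGs
coloured by chain — a deliberately dependency-free stand-in for
interactive 3D viewers.

## Synthetic structures: what they cover, what they do not

The builder places backbones by sequential internal-coordinate (NeRF)
construction at the ideal geometry above, so requested (φ, ψ, ω)
round-trip within 0.5° and unperturbed fixtures carry no geometry
flags. The hairpin's strand torsions were refined once (Powell
search, turn residues held at the type-I′ ideals) so the two strands
register into a real antiparallel ladder with three rungs below the
−0.5 kcal/mol threshold; the values are frozen as constants. The toy
complex places a 6-atom ligand between two helices with its two polar
atoms 2.9 Å radially out from one backbone carbonyl each — a
geometry found by a one-time grid search so that the default criteria
report exactly two protein–ligand hydrogen bonds and ≥ 5 non-bonded
contacts. The cavity cage is a sealed ~4 Å surface lattice of
carbons: an open 8-corner cube admits gap spheres through its faces
that merge interior and exterior into one component, so no separate
interior cavity exists for that shape; sealing the walls makes the
cavity a single component whose volume tracks the Monte-Carlo
interstitial estimate (ratio ≈ 1.2 at edge 8 Å). The open cage
remains available (`sealed=False`).

These fixtures have no side chains beyond CB, no waters, no
alternate conformations, no experimental noise, and idealised
geometry throughout. Passing tests therefore demonstrate algorithmic
correctness against constructed ground truth and internal oracles —
not agreement with experimental structures or with the historical
programs' exact outputs on real entries. The worked-example module
computes the published reference quantities (chain coverage,
bond-angle and planarity flags, third beta turn) for users who supply
the reference PDB entry locally; those depend on matching the
declared default thresholds and are compatibility checks, not unit
tests.

## Known limitations

- Protonation states are not inferred; His is donor and acceptor at
  both ring nitrogens, and distance-only criteria apply wherever a
  hydrogen cannot be constructed.
- The Ramachandran grid and G-factor histograms are generated
  reference data, suitable for ranking and regression testing; they
  are not a substitute for survey-derived tables when absolute
  percentages matter.
- Cleft detection does not distinguish buried cavities from open
  clefts topologically, and the binary splat slightly overestimates
  volumes where spheres bulge into wall gaps.
- mmCIF input, NUCPLOT-style protein–DNA schematics, Pfam/UniProt
  annotation retrieval and ray-traced imagery are out of scope;
  protein–DNA contacts still appear in the contact tables.
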