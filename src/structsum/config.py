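"""Run configuration: every geometric cutoff used by the analyses.

Defaults follow the published parameterisations of the original tools
(HBPLUS distance/angle criteria, PROCHECK distortion thresholds,
SURFNET sphere radii); all are overridable from a ``key = value`` text
file or CLI flags so users can match other parameter sets.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path


@dataclass
class ContactCriteria:
    """HBPLUS-style hydrogen-bond and contact cutoffs."""

    d_a_max: float = 3.9          # donor-acceptor heavy-atom distance, A
    h_a_max: float = 2.5          # hydrogen-acceptor distance, A
    dha_min: float = 90.0         # D-H...A angle, degrees
    nonbonded_max: float = 3.9    # generic non-bonded contact cutoff, A
    salt_bridge_max: float = 4.0  # charged N...O cutoff, A
    metal_max: float = 2.8        # metal...N/O/S coordination cutoff, A
    ss_bond_max: float = 2.5      # disulphide S-S covalent test, A


@dataclass
class StereoThresholds:
    """PROCHECK-style distorted-geometry thresholds."""

    bond_length_tol: float = 0.05   # |actual - ideal|, A
    bond_angle_tol: float = 10.0    # degrees
    planarity_rms_ring: float = 0.03   # A, aromatic rings
    planarity_rms_other: float = 0.02  # A, carboxy/amide/guanidinium
    zeta_ideal: float = 33.9        # CA chirality virtual torsion, degrees
    zeta_tol: float = 15.0          # |zeta - ideal| flag threshold


@dataclass
class CleftParams:
    """SURFNET-style gap-sphere and grid parameters."""

    r_min: float = 1.0       # smallest acceptable gap sphere radius, A
    r_max: float = 4.0       # largest initial gap sphere radius, A
    spacing: float = 1.0     # voxel edge, A
    min_volume: float = 10.0  # smallest reportable cleft, A^3
    lining_cutoff: float = 4.0  # residue-to-voxel distance for lining, A


@dataclass
class SasaParams:
    probe: float = 1.4
    n_points: int = 960


@dataclass
class Config:
    contacts: ContactCriteria = field(default_factory=ContactCriteria)
    stereo: StereoThresholds = field(default_factory=StereoThresholds)
    clefts: CleftParams = field(default_factory=CleftParams)
    sasa: SasaParams = field(default_factory=SasaParams)
    helix_pack_cutoff: float = 10.0  # closest-approach cutoff, A
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "Config":
        """Read ``section.key = value`` lines; unknown keys are an error."""
        cfg = cls()
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
            key, value = (part.strip() for part in line.split("=", 1))
            cfg._set_dotted(key, value, where=f"{path}:{lineno}")
        return cfg

    def _set_dotted(self, key: str, value: str, where: str = "") -> None:
        parts = key.split(".")
        target = self
        for part in parts[:-1]:
            if not hasattr(target, part):
                raise ValueError(f"{where}: unknown config section {part!r}")
            target = getattr(target, part)
        leaf = parts[-1]
        if not hasattr(target, leaf):
            raise ValueError(f"{where}: unknown config key {key!r}")
        current = getattr(target, leaf)
        setattr(target, leaf, type(current)(float(value)) if isinstance(current, (int, float)) else value)

    def to_text(self) -> str:
        lines = []
        for sect_name in ("contacts", "stereo", "clefts", "sasa"):
            sect = getattr(self, sect_name)
            for f in dataclasses.fields(sect):
                lines.append(f"{sect_name}.{f.name} = {getattr(sect, f.name)}")
        lines.append(f"helix_pack_cutoff = {self.helix_pack_cutoff}")
        lines.append(f"seed = {self.seed}")
        return "\n".join(lines) + "\n"
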