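"""Shared configuration: physical constants, atom classification tables and
validation thresholds.

Everything here is a convention, not a result: gyromagnetic ratios and
effective bond lengths for RDC normalization, van der Waals radii and
reference maximum accessibilities for SASA, the nucleus-class map used by
the chemical-shift path, and the threshold set used by the red/orange/green
roll-up.  All of it can be overridden per run by constructing a
:class:`ValidationConfig` (or loading one from a JSON file with
:func:`load_config`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

# --- RDC bond table -------------------------------------------------------
# Gyromagnetic ratios in 10^6 rad s^-1 T^-1 (sign retained: gamma(15N) < 0)
# and effective internuclear distances in Angstrom.  Used to rescale any RDC
# type onto the N-HN scale.

GAMMA = {
    "1H": 267.522,
    "13C": 67.2828,
    "15N": -27.1262,
}

#: rdc type label -> (gamma of atom 1, gamma of atom 2, effective bond length in A)
DEFAULT_BOND_TABLE: dict[str, tuple[float, float, float]] = {
    "N-HN": (GAMMA["15N"], GAMMA["1H"], 1.02),
    "CA-HA": (GAMMA["13C"], GAMMA["1H"], 1.09),
    "N-C'": (GAMMA["15N"], GAMMA["13C"], 1.329),
    "CA-C'": (GAMMA["13C"], GAMMA["13C"], 1.525),
}

# --- SASA -----------------------------------------------------------------

#: van der Waals radii (A) by element; hydrogens are excluded from SASA.
VDW_RADII = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
}

#: Gly-X-Gly maximum accessible surface areas (A^2), theoretical values
#: (Tien et al. 2013), used to turn absolute per-residue ASA into a
#: relative accessibility in [0, 1].
MAX_ASA_GXG = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

# --- nucleus classes ------------------------------------------------------

#: ring carbons per aromatic residue type, also used for the ring-proximity cue
AROMATIC_RING_ATOMS = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
    "TRP": ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
}

AROMATIC_RING_CARBONS = {
    res: tuple(a for a in atoms if a.startswith("C"))
    for res, atoms in AROMATIC_RING_ATOMS.items()
}

NUCLEUS_CLASSES = ("1H", "15N", "13C_aliphatic", "13C_aromatic", "13C'")


def nucleus_class(resname: str, atom_name: str) -> str | None:
    """Map an atom name to its nucleus class.

    ``C`` (the backbone carbonyl) is 13C'; ring carbons of PHE/TYR/TRP/HIS
    are 13C_aromatic; every other carbon is 13C_aliphatic.  Returns None for
    elements outside 1H/13C/15N (e.g. O, S).
    """
    name = atom_name.upper()
    if name.startswith("H") or (name[:1].isdigit() and "H" in name):
        return "1H"
    if name.startswith("N"):
        return "15N"
    if name.startswith("C"):
        if name == "C":
            return "13C'"
        if name in AROMATIC_RING_CARBONS.get(resname.upper(), ()):
            return "13C_aromatic"
        return "13C_aliphatic"
    return None


# --- thresholds -----------------------------------------------------------

@dataclass
class RogThresholds:
    """Trigger levels for the red/orange/green per-residue roll-up."""

    red_dist_A: float = 0.5
    red_dih_deg: float = 20.0
    orange_dist_A: float = 0.3
    orange_dih_deg: float = 10.0
    red_z: float = 5.0
    orange_z: float = 3.0
    model_fraction: float = 0.5  # violation must occur in >= this fraction of models


@dataclass
class ValidationConfig:
    """Tunable parameters for a validation run."""

    rmsd_cluster_cutoff_A: float = 2.0
    sasa_probe_radius_A: float = 1.4
    sasa_n_points: int = 256
    buried_threshold: float = 0.20
    min_atoms_for_offset: int = 10
    min_reference_count: int = 10
    outlier_z: float = 3.0
    aromatic_proximity_A: float = 5.0
    q_normalization: str = "rms_obs"  # or "da_rhombicity" for Da*sqrt(4+3R^2)
    rog: RogThresholds = field(default_factory=RogThresholds)
    bond_table: dict = field(default_factory=lambda: dict(DEFAULT_BOND_TABLE))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["bond_table"] = {k: list(v) for k, v in self.bond_table.items()}
        return d


def load_config(path: str | Path) -> ValidationConfig:
    """Load a :class:`ValidationConfig` from JSON; absent keys keep defaults."""
    raw = json.loads(Path(path).read_text())
    rog = RogThresholds(**raw.pop("rog", {}))
    bond = {k: tuple(v) for k, v in raw.pop("bond_table", {}).items()} or dict(
        DEFAULT_BOND_TABLE
    )
    return ValidationConfig(rog=rog, bond_table=bond, **raw)
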