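"""Deterministic synthetic fixtures: toy ensembles with matching restraint,
RDC and chemical-shift data of known ground truth.

The generator builds a poly-alanine backbone from ideal helix internal
coordinates (phi = -57, psi = -47, standard bond lengths and angles, NeRF
chain extension), optionally with one PHE for the aromatic-proximity cue,
then derives every other data type from that geometry:

* models = base conformer + per-model Gaussian coordinate jitter, with an
  optional hinge rotation of the C-terminal half in half of the models
  (plants a two-conformation split for clustering tests);
* distance constraints bracket true distances with [d - 0.5, d + 0.5]
  bounds; a planted violation tightens one upper bound below the true
  distance by a stated amount;
* dihedral constraints are [true - 20, true + 20] arcs, with planted
  violations shifting the arc so the true angle sits a stated distance
  outside it;
* RDCs are generated from a known traceless Saupe tensor (raw or
  pre-scaled units);
* chemical shifts are drawn around an environment-conditioned reference
  table, with per-nucleus-class offsets and +k*sd outliers planted.

Everything is reproducible: one ``numpy`` generator seeded from the spec,
and seeds recorded as comments in the emitted files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .config import ValidationConfig, nucleus_class
from .ensemble_analysis import cluster_and_represent, compute_backbone_dihedrals
from .model_io import (ChemicalShiftRecord, DihedralConstraint,
                       DistanceConstraint, Ensemble, Model, RdcConstraint,
                       ShiftReferenceTable, format_atom_ref, write_ensemble)
from .rdc_analysis import design_row, normalization_factor
from .shift_validation import residue_environments

# ideal backbone geometry (A, degrees)
_BOND = {"N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329, "C-O": 1.231,
         "CA-CB": 1.521, "N-H": 1.02, "CA-HA": 1.09}
_ANGLE = {"C-N-CA": 121.7, "N-CA-C": 111.2, "CA-C-N": 116.2,
          "CA-C-O": 120.5, "C-CA-CB": 110.1, "C-N-H": 119.0,
          "C-CA-HA": 109.0}
_OMEGA = 180.0

HELIX_PHI = -57.0
HELIX_PSI = -47.0


@dataclass
class FixtureSpec:
    """Study conditions for one synthetic dataset."""

    n_residues: int = 20
    n_models: int = 10
    noise_sigma_A: float = 0.05
    seed: int = 0
    chain_id: str = "A"
    phi_deg: float = HELIX_PHI
    psi_deg: float = HELIX_PSI
    hinge_split_deg: float = 0.0          # 0 disables the two-conformation split
    aromatic_at: int | None = None        # residue number of a planted PHE
    # restraints
    n_long_range: int = 12
    planted_distance_violation_A: float = 0.0
    planted_dihedral_violation_deg: float = 0.0
    # RDCs
    rdc_types: tuple[str, ...] = ("N-HN",)
    rdc_noise_hz: float = 0.0
    rdc_prescaled: bool = False
    rdc_da_hz: float = 10.0
    rdc_rhombicity: float = 0.3
    # shifts
    shift_offsets_ppm: dict = field(default_factory=dict)
    shift_noise_scale: float = 1.0
    n_shift_outliers: int = 0
    outlier_sd_multiple: float = 6.0

    def __post_init__(self):
        if self.n_residues < 5:
            raise ValueError("need at least 5 residues")


@dataclass
class FixtureData:
    """A generated dataset plus its ground truth."""

    spec: FixtureSpec
    ensemble: Ensemble
    base_model: Model
    distance_constraints: list = field(default_factory=list)
    dihedral_constraints: list = field(default_factory=list)
    rdc_constraints: list = field(default_factory=list)
    shifts: list = field(default_factory=list)
    reference_table: ShiftReferenceTable | None = None
    planted_distance_id: str | None = None
    planted_dihedral_id: str | None = None
    planted_outlier_atoms: list = field(default_factory=list)
    saupe_tensor: np.ndarray | None = None
    representative_model_id: int | None = None


# --------------------------------------------------------------------------
# geometry
# --------------------------------------------------------------------------

def _place(a, b, c, bond: float, angle_deg: float, torsion_deg: float):
    """NeRF: position of atom d bonded to c, given internal coordinates
    relative to the chain a-b-c."""
    angle = np.radians(angle_deg)
    torsion = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array([-np.cos(angle),
                               np.sin(angle) * np.cos(torsion),
                               np.sin(angle) * np.sin(torsion)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


_PHE_RING = [
    # (atom, (a, b, c), bond, angle, torsion) reference atoms are same-residue
    ("CG", ("N", "CA", "CB"), 1.50, 113.8, 180.0),
    ("CD1", ("CA", "CB", "CG"), 1.39, 120.0, 90.0),
    ("CD2", ("CA", "CB", "CG"), 1.39, 120.0, -90.0),
    ("CE1", ("CB", "CG", "CD1"), 1.39, 120.0, 180.0),
    ("CE2", ("CB", "CG", "CD2"), 1.39, 120.0, 180.0),
    ("CZ", ("CG", "CD1", "CE1"), 1.39, 120.0, 0.0),
]


def build_backbone(n_residues: int, phi: float = HELIX_PHI,
                   psi: float = HELIX_PSI, chain_id: str = "A",
                   aromatic_at: int | None = None):
    """Ideal poly-alanine backbone (N, H, CA, HA, CB, C, O per residue,
    PHE ring at ``aromatic_at`` if requested).

    Returns ``(atoms, sequence)``: an atom-key -> position dict and the
    chain sequence as a list of (resnum, resname).
    """
    atoms: dict = {}
    seq = []
    n_prev = ca_prev = c_prev = None
    for i in range(1, n_residues + 1):
        resname = "PHE" if i == aromatic_at else "ALA"
        seq.append((i, resname))
        if i == 1:
            n = np.array([0.0, 0.0, 0.0])
            ca = np.array([_BOND["N-CA"], 0.0, 0.0])
            ang = np.radians(_ANGLE["N-CA-C"])
            c = ca + _BOND["CA-C"] * np.array([-np.cos(ang), np.sin(ang), 0.0])
        else:
            n = _place(n_prev, ca_prev, c_prev, _BOND["C-N"],
                       _ANGLE["CA-C-N"], psi)
            ca = _place(ca_prev, c_prev, n, _BOND["N-CA"],
                        _ANGLE["C-N-CA"], _OMEGA)
            c = _place(c_prev, n, ca, _BOND["CA-C"], _ANGLE["N-CA-C"], phi)
            atoms[(chain_id, i, "H")] = _place(ca_prev, c_prev, n,
                                               _BOND["N-H"], _ANGLE["C-N-H"],
                                               0.0)
        atoms[(chain_id, i, "N")] = n
        atoms[(chain_id, i, "CA")] = ca
        atoms[(chain_id, i, "C")] = c
        # O anti to the next N: torsion N-CA-C-O = psi + 180
        atoms[(chain_id, i, "O")] = _place(n, ca, c, _BOND["C-O"],
                                           _ANGLE["CA-C-O"], psi + 180.0)
        atoms[(chain_id, i, "CB")] = _place(n, c, ca, _BOND["CA-CB"],
                                            _ANGLE["C-CA-CB"], 122.6)
        atoms[(chain_id, i, "HA")] = _place(n, c, ca, _BOND["CA-HA"],
                                            _ANGLE["C-CA-HA"], -116.0)
        if resname == "PHE":
            for name, refs, bond, angle, torsion in _PHE_RING:
                ra, rb, rc = (atoms[(chain_id, i, r)] for r in refs)
                atoms[(chain_id, i, name)] = _place(ra, rb, rc, bond, angle,
                                                    torsion)
        n_prev, ca_prev, c_prev = n, ca, c
    return atoms, seq


def _rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    a = np.radians(angle_deg)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * (K @ K)


def make_ensemble(spec: FixtureSpec) -> FixtureData:
    """Build the ensemble for a spec: base conformer + per-model jitter and
    the optional hinge split (second conformation in the last half of the
    models)."""
    rng = np.random.default_rng(spec.seed)
    atoms, seq = build_backbone(spec.n_residues, spec.phi_deg, spec.psi_deg,
                                spec.chain_id, spec.aromatic_at)
    base = Model(model_id=0, atoms={k: v.copy() for k, v in atoms.items()})

    hinge_res = spec.n_residues // 2
    hinge_rot = None
    if spec.hinge_split_deg:
        pivot = atoms[(spec.chain_id, hinge_res, "CA")]
        # bend about an axis perpendicular to the chain direction so the
        # C-terminal half swings like a lever (large RMSD between conformers)
        direction = atoms[(spec.chain_id, spec.n_residues, "CA")] - pivot
        axis = np.cross(direction, np.array([0.0, 0.0, 1.0]))
        if np.linalg.norm(axis) < 1e-6:
            axis = np.cross(direction, np.array([0.0, 1.0, 0.0]))
        hinge_rot = (_rotation_about_axis(axis, spec.hinge_split_deg), pivot)

    models = []
    for m in range(spec.n_models):
        coords = {}
        flipped = hinge_rot is not None and m >= spec.n_models // 2
        for key, pos in atoms.items():
            p = pos.copy()
            if flipped and key[1] > hinge_res:
                R, pivot = hinge_rot
                p = R @ (p - pivot) + pivot
            if spec.noise_sigma_A > 0:
                p = p + rng.normal(0.0, spec.noise_sigma_A, size=3)
            coords[key] = p
        models.append(Model(model_id=m + 1, atoms=coords))
    ensemble = Ensemble(models=models,
                        sequence={spec.chain_id: seq},
                        polymer_type={spec.chain_id: "protein"})
    return FixtureData(spec=spec, ensemble=ensemble, base_model=base)


# --------------------------------------------------------------------------
# restraints
# --------------------------------------------------------------------------

def derive_restraints(data: FixtureData) -> FixtureData:
    """Derive distance and dihedral constraints from the base conformer.

    Local heavy-atom contacts below 5 A get [d - 0.5, d + 0.5] bounds; an
    extra set of long-range CB-CB constraints (>= 5 residues apart) is
    added with the same bracket so the long-range bookkeeping has data.
    Requested violations are planted by tightening one long-range upper
    bound (distance) or shifting one psi arc (dihedral).
    """
    spec = data.spec
    rng = np.random.default_rng(spec.seed + 1)
    chain = spec.chain_id
    base = data.base_model
    heavy = [k for k in base.atoms
             if not k[2].startswith("H") and k[2] != "HA"]

    constraints = []
    counter = 0
    for i, a in enumerate(heavy):
        for b in heavy[i + 1:]:
            if a[1] == b[1]:
                continue  # intra-residue pairs are covalent geometry, skip
            d = float(np.linalg.norm(base.atoms[a] - base.atoms[b]))
            if d >= 5.0:
                continue
            # skip directly bonded backbone neighbours (C-N peptide bond)
            if {a[2], b[2]} == {"C", "N"} and abs(a[1] - b[1]) == 1:
                continue
            counter += 1
            constraints.append(DistanceConstraint(
                id=f"dist{counter:04d}", members=[(a, b)],
                lower=max(0.0, d - 0.5), upper=d + 0.5))

    # long-range CB-CB constraints
    pairs = [(i, j) for i in range(1, spec.n_residues + 1)
             for j in range(i + 5, spec.n_residues + 1)]
    rng.shuffle(pairs)
    long_cons = []
    for i, j in pairs[:spec.n_long_range]:
        a, b = (chain, i, "CB"), (chain, j, "CB")
        d = float(np.linalg.norm(base.atoms[a] - base.atoms[b]))
        counter += 1
        con = DistanceConstraint(id=f"dist{counter:04d}", members=[(a, b)],
                                 lower=max(0.0, d - 0.5), upper=d + 0.5)
        constraints.append(con)
        long_cons.append(con)

    # one ambiguous constraint (two member pairs), bounds bracket d_eff
    if spec.n_residues >= 8:
        m1 = ((chain, 2, "CB"), (chain, 5, "CB"))
        m2 = ((chain, 2, "CB"), (chain, 6, "CB"))
        dists = [float(np.linalg.norm(base.atoms[a] - base.atoms[b]))
                 for a, b in (m1, m2)]
        d_eff = float(np.sum(np.asarray(dists) ** -6.0) ** (-1 / 6))
        counter += 1
        constraints.append(DistanceConstraint(
            id=f"dist{counter:04d}", members=[m1, m2],
            lower=max(0.0, d_eff - 0.5), upper=d_eff + 0.5))

    if spec.planted_distance_violation_A > 0:
        victim = long_cons[0]
        a, b = victim.members[0]
        d = float(np.linalg.norm(base.atoms[a] - base.atoms[b]))
        victim.lower = 0.0
        victim.upper = d - spec.planted_distance_violation_A
        data.planted_distance_id = victim.id

    # dihedral constraints: phi and psi arcs of +/- 20 deg around truth
    dset = compute_backbone_dihedrals(
        Ensemble(models=[Model(model_id=1, atoms=base.atoms)],
                 sequence=data.ensemble.sequence,
                 polymer_type=data.ensemble.polymer_type))
    dihedrals = []
    dcounter = 0
    for resnum in range(1, spec.n_residues + 1):
        for angle in ("phi", "psi"):
            values = dset.residue_angles(chain, resnum).get(angle)
            if not values or values[0] is None:
                continue
            true = values[0]
            dcounter += 1
            dihedrals.append(DihedralConstraint(
                id=f"dih{dcounter:04d}", chain=chain, resnum=resnum,
                angle=angle, lower=_wrap(true - 20.0), upper=_wrap(true + 20.0)))

    if spec.planted_dihedral_violation_deg > 0:
        # shift one interior psi arc so truth sits outside by the stated gap
        victim = next(d for d in dihedrals
                      if d.resnum == 3 and d.angle == "psi")
        values = dset.residue_angles(chain, 3)["psi"]
        true = values[0]
        off = spec.planted_dihedral_violation_deg
        victim.lower = _wrap(true + off)
        victim.upper = _wrap(true + off + 40.0)
        data.planted_dihedral_id = victim.id

    data.distance_constraints = constraints
    data.dihedral_constraints = dihedrals
    return data


def _wrap(angle: float) -> float:
    a = (angle + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


# --------------------------------------------------------------------------
# RDCs
# --------------------------------------------------------------------------

def make_saupe_matrix(da_hz: float, rhombicity: float,
                      seed: int = 0) -> np.ndarray:
    """Traceless symmetric tensor with the requested Da and rhombicity, in a
    seeded random orientation (so off-diagonal elements are exercised)."""
    l3 = 2.0 * da_hz
    diff = 1.5 * rhombicity * l3          # l1 - l2
    l1 = (-l3 + diff) / 2.0
    l2 = (-l3 - diff) / 2.0
    diag = np.diag([l1, l2, l3])
    rng = np.random.default_rng(seed)
    M = rng.normal(size=(3, 3))
    Q, _ = np.linalg.qr(M)
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q @ diag @ Q.T


_RDC_ATOMS = {"N-HN": ("N", "H"), "CA-HA": ("CA", "HA"), "N-C'": ("N", "C"),
              "CA-C'": ("CA", "C")}


def simulate_rdcs(data: FixtureData, medium: str = "m1") -> FixtureData:
    """Generate RDC observations from a known tensor against the base
    conformer, in raw or pre-scaled units per the spec."""
    spec = data.spec
    rng = np.random.default_rng(spec.seed + 2)
    tensor = make_saupe_matrix(spec.rdc_da_hz, spec.rdc_rhombicity,
                               seed=spec.seed + 3)
    s = np.array([tensor[0, 0], tensor[1, 1], tensor[0, 1], tensor[0, 2],
                  tensor[1, 2]])
    base = data.base_model
    chain = spec.chain_id
    rdcs = []
    counter = 0
    for rdc_type in spec.rdc_types:
        a_name, b_name = _RDC_ATOMS[rdc_type]
        scale = normalization_factor(rdc_type)
        for resnum in range(1, spec.n_residues + 1):
            ka, kb = (chain, resnum, a_name), (chain, resnum, b_name)
            if ka not in base.atoms or kb not in base.atoms:
                continue
            v = base.atoms[kb] - base.atoms[ka]
            v /= np.linalg.norm(v)
            d_norm = float(design_row(v) @ s)
            if spec.rdc_noise_hz > 0:
                d_norm += rng.normal(0.0, spec.rdc_noise_hz)
            observed = d_norm if spec.rdc_prescaled else d_norm / scale
            counter += 1
            rdcs.append(RdcConstraint(id=f"rdc{counter:04d}", atom1=ka,
                                      atom2=kb, rdc_type=rdc_type,
                                      medium=medium, observed_hz=observed))
    data.rdc_constraints = rdcs
    data.saupe_tensor = tensor
    return data


# --------------------------------------------------------------------------
# shifts
# --------------------------------------------------------------------------

#: rough random-coil means and spreads (ppm) for the residue types the
#: generator emits
_SHIFT_BASE = {
    ("ALA", "N"): (123.2, 3.5), ("ALA", "H"): (8.19, 0.60),
    ("ALA", "CA"): (53.1, 2.0), ("ALA", "HA"): (4.26, 0.44),
    ("ALA", "CB"): (19.0, 1.8), ("ALA", "C"): (177.8, 2.1),
    ("PHE", "N"): (120.3, 4.0), ("PHE", "H"): (8.34, 0.72),
    ("PHE", "CA"): (58.1, 2.6), ("PHE", "HA"): (4.62, 0.57),
    ("PHE", "CB"): (39.9, 2.0), ("PHE", "C"): (175.5, 2.0),
    ("PHE", "CD1"): (131.5, 1.2), ("PHE", "CE1"): (130.6, 1.2),
    ("PHE", "CZ"): (129.2, 1.4),
}

_SS_DELTA = {"H": 0.3, "E": -0.3, "C": 0.0}   # in units of sd
_BIN_DELTA = {"buried": 0.2, "exposed": 0.0}


def make_reference_table() -> ShiftReferenceTable:
    """Reference statistics for every (residue, atom, ss, bin) combination
    the generator can emit; synthetic stand-in for a curated shift corpus."""
    table = ShiftReferenceTable()
    for (resname, atom), (mean, sd) in _SHIFT_BASE.items():
        for ss, dss in _SS_DELTA.items():
            for acc_bin, dbin in _BIN_DELTA.items():
                table.add(resname, atom, ss, acc_bin,
                          mean + sd * (dss + dbin), sd, 250)
    return table


def simulate_shifts(data: FixtureData,
                    config: ValidationConfig | None = None) -> FixtureData:
    """Draw chemical shifts around the reference table on the representative
    model's environments, planting per-class offsets and +k*sd outliers."""
    spec = data.spec
    config = config or ValidationConfig()
    rng = np.random.default_rng(spec.seed + 4)
    table = make_reference_table()
    rep = cluster_and_represent(
        data.ensemble, rmsd_cutoff_A=config.rmsd_cluster_cutoff_A
    ).overall_representative
    data.representative_model_id = rep
    envs = residue_environments(data.ensemble, rep, config)

    candidates = []
    for chain, resnum, resname in data.ensemble.residues():
        for atom in ("N", "H", "CA", "HA", "CB", "C"):
            if (resname, atom) not in _SHIFT_BASE:
                continue
            if (chain, resnum, atom) not in data.base_model.atoms:
                continue
            candidates.append((chain, resnum, resname, atom))

    outlier_idx = set()
    if spec.n_shift_outliers:
        outlier_idx = set(rng.choice(len(candidates),
                                     size=spec.n_shift_outliers,
                                     replace=False).tolist())
    shifts = []
    planted = []
    for idx, (chain, resnum, resname, atom) in enumerate(candidates):
        env = envs[(chain, resnum)]
        mean, sd, _count = table.lookup(resname, atom, env.ss, env.acc_bin)
        nc = nucleus_class(resname, atom)
        offset = spec.shift_offsets_ppm.get(nc, 0.0)
        if idx in outlier_idx:
            value = mean + offset + spec.outlier_sd_multiple * sd
            planted.append((chain, resnum, atom))
        else:
            value = mean + offset + sd * spec.shift_noise_scale * rng.normal()
        shifts.append(ChemicalShiftRecord(chain=chain, resnum=resnum,
                                          resname=resname, atom=atom,
                                          nucleus_class=nc,
                                          value_ppm=float(value)))
    data.shifts = shifts
    data.reference_table = table
    data.planted_outlier_atoms = planted
    return data


# --------------------------------------------------------------------------
# presets and file output
# --------------------------------------------------------------------------

PRESETS = ("basic", "clustered", "violations", "rdc", "shifts")


def preset_spec(preset: str, seed: int = 0) -> FixtureSpec:
    """Canonical study conditions for each named preset."""
    if preset == "basic":
        return FixtureSpec(seed=seed)
    if preset == "clustered":
        return FixtureSpec(seed=seed, n_models=20, hinge_split_deg=90.0,
                           noise_sigma_A=0.05)
    if preset == "violations":
        return FixtureSpec(seed=seed, n_residues=20, n_models=10,
                           noise_sigma_A=0.02,
                           planted_distance_violation_A=1.0,
                           planted_dihedral_violation_deg=20.0)
    if preset == "rdc":
        return FixtureSpec(seed=seed, n_models=4, noise_sigma_A=0.0,
                           rdc_types=("N-HN", "CA-HA"))
    if preset == "shifts":
        return FixtureSpec(seed=seed, noise_sigma_A=0.02, aromatic_at=10,
                           shift_offsets_ppm={"13C_aliphatic": 1.7},
                           n_shift_outliers=5)
    raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")


def generate(spec: FixtureSpec) -> FixtureData:
    """Run the full generator pipeline for a spec."""
    data = make_ensemble(spec)
    derive_restraints(data)
    simulate_rdcs(data)
    simulate_shifts(data)
    return data


def _write_tsv(path: Path, header: list[str], rows, seed: int):
    lines = [f"# generated by nmrval synthetic_fixtures (seed={seed})",
             "\t".join(header)]
    lines.extend("\t".join(str(x) for x in row) for row in rows)
    path.write_text("\n".join(lines) + "\n")


def write_fixture_dir(data: FixtureData, out_dir: str | Path) -> dict[str, Path]:
    """Write all generated inputs as files (PDB + TSVs + ground truth JSON).

    Returns the path of each file keyed by role.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = data.spec
    paths = {}

    paths["coordinates"] = out / "ensemble.pdb"
    write_ensemble(data.ensemble, paths["coordinates"],
                   remarks=[f"nmrval synthetic fixture seed={spec.seed}"])

    paths["distance"] = out / "distance.tsv"
    _write_tsv(paths["distance"], ["id", "members", "lower_A", "upper_A"],
               [[c.id,
                 "|".join(f"{format_atom_ref(a)}-{format_atom_ref(b)}"
                          for a, b in c.members),
                 f"{c.lower:.4f}", f"{c.upper:.4f}"]
                for c in data.distance_constraints], spec.seed)

    paths["dihedral"] = out / "dihedral.tsv"
    _write_tsv(paths["dihedral"],
               ["id", "chain", "resnum", "angle", "lower_deg", "upper_deg"],
               [[c.id, c.chain, c.resnum, c.angle, f"{c.lower:.4f}",
                 f"{c.upper:.4f}"] for c in data.dihedral_constraints],
               spec.seed)

    paths["rdc"] = out / "rdc.tsv"
    _write_tsv(paths["rdc"],
               ["id", "atom1", "atom2", "type", "medium", "observed_hz"],
               [[c.id, format_atom_ref(c.atom1), format_atom_ref(c.atom2),
                 c.rdc_type, c.medium, f"{c.observed_hz:.6f}"]
                for c in data.rdc_constraints], spec.seed)

    paths["shifts"] = out / "shifts.tsv"
    _write_tsv(paths["shifts"],
               ["chain", "resnum", "resname", "atom", "nucleus_class",
                "shift_ppm"],
               [[s.chain, s.resnum, s.resname, s.atom, s.nucleus_class,
                 f"{s.value_ppm:.4f}"] for s in data.shifts], spec.seed)

    paths["shift_reference"] = out / "shift_reference.tsv"
    _write_tsv(paths["shift_reference"],
               ["resname", "atom", "ss", "acc_bin", "mean_ppm", "sd_ppm", "n"],
               [[k[0], k[1], k[2], k[3], f"{v[0]:.4f}", f"{v[1]:.4f}", v[2]]
                for k, v in sorted(data.reference_table.entries.items())],
               spec.seed)

    truth = {
        "spec": asdict(spec),
        "planted_distance_id": data.planted_distance_id,
        "planted_dihedral_id": data.planted_dihedral_id,
        "planted_outlier_atoms": [list(a) for a in data.planted_outlier_atoms],
        "saupe_tensor": data.saupe_tensor.tolist()
        if data.saupe_tensor is not None else None,
    }
    paths["ground_truth"] = out / "ground_truth.json"
    paths["ground_truth"].write_text(json.dumps(truth, indent=1,
                                                sort_keys=True) + "\n")
    return paths
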