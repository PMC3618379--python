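"""Chemical-shift validation: re-referencing offsets and environment-
conditioned Z-score outlier detection.

The procedure has two steps.  First, a per-nucleus-class referencing offset
(1H, 15N, 13C_aliphatic, 13C_aromatic, 13C') is estimated as the median of
(observed - expected mean) over all atoms of the class that have a
reference entry — a robust guard against systematically mis-referenced
shift lists.  Second, each shift with an adequately populated reference
entry gets

    z = (observed - offset - mean) / sd

where mean/sd come from a reference table conditioned on residue type, atom
name, secondary-structure class (H/E/C from the representative model's
phi/psi) and solvent-accessibility bin (buried/exposed from Shrake-Rupley
relative accessibility).  |z| > 3 flags an outlier; the display color ramps
smoothly green -> yellow -> red over |z| in [2, 5].

Aromatic ring currents are not modeled; instead residues near an aromatic
ring centroid are marked so their outliers can be discounted by the reader.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .config import (AROMATIC_RING_ATOMS, MAX_ASA_GXG, VDW_RADII,
                     ValidationConfig)
from .ensemble_analysis import DihedralSet
from .model_io import (ChemicalShiftRecord, Ensemble, Model,
                       ShiftReferenceTable)

logger = logging.getLogger(__name__)

SS_CLASSES = ("H", "E", "C")
ACC_BINS = ("buried", "exposed")


@dataclass
class ResidueEnvironment:
    ss: str                  # H | E | C
    acc_bin: str             # buried | exposed
    rel_accessibility: float


@dataclass
class ShiftValidationRecord:
    chain: str
    resnum: int
    resname: str
    atom: str
    nucleus_class: str
    observed_ppm: float
    offset_ppm: float
    expected_mean_ppm: float | None
    expected_sd_ppm: float | None
    z: float | None
    outlier: bool
    color: tuple[int, int, int] | None
    near_aromatic: bool = False


# --------------------------------------------------------------------------
# secondary structure and accessibility
# --------------------------------------------------------------------------

def ss_from_phi_psi(phi: float | None, psi: float | None) -> str:
    """Coarse secondary-structure class from backbone dihedrals.

    H when phi in (-100, -30) and psi in (-80, -5); E when phi in
    (-180, -45) and psi in (90, 180] or (-180, -150); otherwise C.
    Termini (missing phi or psi) are C.
    """
    if phi is None or psi is None:
        return "C"
    if -100.0 < phi < -30.0 and -80.0 < psi < -5.0:
        return "H"
    if -180.0 < phi < -45.0 and (90.0 < psi <= 180.0 or -180.0 < psi < -150.0):
        return "E"
    return "C"


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5 ** 0.5) * i
    return np.column_stack([np.cos(theta) * np.sin(phi),
                            np.sin(theta) * np.sin(phi),
                            np.cos(phi)])


def _element_of(atom_name: str) -> str | None:
    for ch in atom_name:
        if ch.isalpha():
            return ch.upper()
    return None


def shrake_rupley_asa(model: Model, probe_radius: float = 1.4,
                      n_points: int = 256) -> dict[tuple[str, int], float]:
    """Per-residue solvent-accessible surface area (A^2), Shrake-Rupley.

    Heavy atoms only (hydrogens are neither occluders nor contribute area);
    each atom's sphere of radius vdW + probe is sampled at ``n_points``
    quasi-uniform points and the accessible fraction scaled to the sphere
    area.
    """
    keys, centers, radii = [], [], []
    for (chain, resnum, atom), pos in model.atoms.items():
        elem = _element_of(atom)
        if elem == "H" or elem not in VDW_RADII:
            continue
        keys.append((chain, resnum))
        centers.append(pos)
        radii.append(VDW_RADII[elem] + probe_radius)
    centers = np.asarray(centers)
    radii = np.asarray(radii)
    sphere = _sphere_points(n_points)
    asa: dict[tuple[str, int], float] = {}
    for i in range(len(keys)):
        pts = centers[i] + radii[i] * sphere
        # neighbors whose expanded sphere can reach this one
        d = np.linalg.norm(centers - centers[i], axis=1)
        neigh = np.where((d < radii + radii[i]) & (d > 0))[0]
        accessible = np.ones(n_points, dtype=bool)
        for j in neigh:
            accessible &= (np.linalg.norm(pts - centers[j], axis=1) >= radii[j])
            if not accessible.any():
                break
        area = 4.0 * np.pi * radii[i] ** 2 * accessible.sum() / n_points
        asa[keys[i]] = asa.get(keys[i], 0.0) + area
    return asa


def residue_environment(ensemble: Ensemble, representative_model_id: int,
                        chain: str, resnum: int,
                        config: ValidationConfig | None = None,
                        dset: DihedralSet | None = None,
                        _asa_cache: dict | None = None) -> ResidueEnvironment:
    """Environment (ss class, accessibility bin) of one residue, judged on
    the representative model."""
    envs = residue_environments(ensemble, representative_model_id, config, dset,
                                _asa_cache)
    try:
        return envs[(chain, resnum)]
    except KeyError:
        raise KeyError(f"residue {chain}/{resnum} not in ensemble") from None


def residue_environments(ensemble: Ensemble, representative_model_id: int,
                         config: ValidationConfig | None = None,
                         dset: DihedralSet | None = None,
                         asa: dict | None = None
                         ) -> dict[tuple[str, int], ResidueEnvironment]:
    """Environments for every residue (single SASA pass over the
    representative model)."""
    from .ensemble_analysis import compute_backbone_dihedrals

    config = config or ValidationConfig()
    model = next(m for m in ensemble.models
                 if m.model_id == representative_model_id)
    if dset is None:
        dset = compute_backbone_dihedrals(ensemble)
    if asa is None:
        asa = shrake_rupley_asa(model, config.sasa_probe_radius_A,
                                config.sasa_n_points)
    midx = representative_model_id - 1
    envs = {}
    for chain, resnum, resname in ensemble.residues():
        angles = dset.residue_angles(chain, resnum)
        phi_list = angles.get("phi")
        psi_list = angles.get("psi")
        phi = phi_list[midx] if phi_list else None
        psi = psi_list[midx] if psi_list else None
        if ensemble.polymer_type.get(chain) != "protein":
            ss = "C"
        else:
            ss = ss_from_phi_psi(phi, psi)
        max_asa = MAX_ASA_GXG.get(resname.upper())
        if max_asa is None:
            logger.warning("no reference max ASA for residue type %s; treating "
                           "%s/%d as exposed", resname, chain, resnum)
            rel = 1.0
        else:
            rel = min(asa.get((chain, resnum), 0.0) / max_asa, 1.0)
        acc_bin = "buried" if rel < config.buried_threshold else "exposed"
        envs[(chain, resnum)] = ResidueEnvironment(ss=ss, acc_bin=acc_bin,
                                                   rel_accessibility=float(rel))
    return envs


# --------------------------------------------------------------------------
# offsets and Z-scores
# --------------------------------------------------------------------------

def _reference_for(shift: ChemicalShiftRecord, table: ShiftReferenceTable,
                   environments) -> tuple[float, float, int] | None:
    env = environments.get((shift.chain, shift.resnum))
    if env is None:
        return None
    return table.lookup(shift.resname, shift.atom, env.ss, env.acc_bin)


def referencing_offset(shifts: list[ChemicalShiftRecord],
                       table: ShiftReferenceTable, environments,
                       nucleus_class: str,
                       config: ValidationConfig | None = None) -> float:
    """Median re-referencing offset (ppm) for one nucleus class.

    Classes with fewer than ``config.min_atoms_for_offset`` matched atoms
    get offset 0 with a warning (too little data to re-reference).
    """
    config = config or ValidationConfig()
    deltas = []
    for s in shifts:
        if s.nucleus_class != nucleus_class:
            continue
        ref = _reference_for(s, table, environments)
        if ref is not None:
            deltas.append(s.value_ppm - ref[0])
    if len(deltas) < config.min_atoms_for_offset:
        logger.warning("nucleus class %s: only %d matched atoms (< %d); "
                       "offset set to 0", nucleus_class, len(deltas),
                       config.min_atoms_for_offset)
        return 0.0
    return float(np.median(deltas))


def all_offsets(shifts, table, environments,
                config: ValidationConfig | None = None) -> dict[str, float]:
    classes = sorted({s.nucleus_class for s in shifts})
    return {nc: referencing_offset(shifts, table, environments, nc, config)
            for nc in classes}


def shift_zscores(shifts: list[ChemicalShiftRecord],
                  table: ShiftReferenceTable, environments,
                  offsets: dict[str, float],
                  config: ValidationConfig | None = None,
                  near_aromatic: set | None = None
                  ) -> list[ShiftValidationRecord]:
    """Z-score every shift against its environment-matched reference entry.

    Entries with reference count below ``config.min_reference_count`` (or no
    reference at all) yield a record with null z; |z| > config.outlier_z
    (default 3, strict) flags an outlier.
    """
    config = config or ValidationConfig()
    near_aromatic = near_aromatic or set()
    records = []
    for s in shifts:
        offset = offsets.get(s.nucleus_class, 0.0)
        ref = _reference_for(s, table, environments)
        z = mean = sd = None
        if ref is not None:
            mean, sd, count = ref
            if sd <= 0:
                logger.warning("reference entry for %s/%s has sd <= 0; skipped",
                               s.resname, s.atom)
                mean = sd = None
            elif count < config.min_reference_count:
                mean = sd = None  # too few similar atoms: no z-score
            else:
                z = (s.value_ppm - offset - mean) / sd
        outlier = z is not None and abs(z) > config.outlier_z
        records.append(ShiftValidationRecord(
            chain=s.chain, resnum=s.resnum, resname=s.resname, atom=s.atom,
            nucleus_class=s.nucleus_class, observed_ppm=s.value_ppm,
            offset_ppm=offset, expected_mean_ppm=mean, expected_sd_ppm=sd,
            z=None if z is None else float(z), outlier=outlier,
            color=None if z is None else zscore_color(z),
            near_aromatic=(s.chain, s.resnum) in near_aromatic))
    return records


def zscore_color(z: float) -> tuple[int, int, int]:
    """RGB display color for a Z-score: green (|z| <= 2) through yellow
    (|z| = 3.5) to red (|z| >= 5), linear in |z| on each leg."""
    a = abs(z)
    if a <= 2.0:
        return (0, 255, 0)
    if a >= 5.0:
        return (255, 0, 0)
    if a <= 3.5:
        f = (a - 2.0) / 1.5           # green -> yellow
        return (round(255 * f), 255, 0)
    f = (a - 3.5) / 1.5               # yellow -> red
    return (255, round(255 * (1.0 - f)), 0)


# --------------------------------------------------------------------------
# aromatic proximity cue
# --------------------------------------------------------------------------

def aromatic_proximity(ensemble: Ensemble, model_id: int,
                       cutoff_A: float = 5.0) -> set[tuple[str, int]]:
    """Residues with any atom within ``cutoff_A`` of an aromatic ring
    centroid (PHE/TYR/TRP/HIS rings) in the given model."""
    model = next(m for m in ensemble.models if m.model_id == model_id)
    centroids = []
    for chain, resnum, resname in ensemble.residues():
        ring = AROMATIC_RING_ATOMS.get(resname.upper())
        if not ring:
            continue
        coords = [model.atoms[(chain, resnum, a)] for a in ring
                  if (chain, resnum, a) in model.atoms]
        if len(coords) >= 3:
            centroids.append(np.mean(coords, axis=0))
    if not centroids:
        return set()
    centroids = np.asarray(centroids)
    near = set()
    for (chain, resnum, _atom), pos in model.atoms.items():
        if (chain, resnum) in near:
            continue
        if np.min(np.linalg.norm(centroids - pos, axis=1)) <= cutoff_A:
            near.add((chain, resnum))
    return near
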