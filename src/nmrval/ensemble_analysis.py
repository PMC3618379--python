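"""Ensemble homogeneity: backbone dihedrals, the circular order parameter,
Kabsch superposition, RMSD clustering and representative-model selection.

The central quantity is a per-residue dihedral order parameter

    S2 = (1/M) * sum_i [ (mean_j cos g_ij)^2 + (mean_j sin g_ij)^2 ]

where g_ij is backbone dihedral angle type i (phi/psi for proteins,
alpha..zeta for nucleic acids) in conformer j, M is the number of angle
types defined for the residue and N the number of conformers.  S2 is 1 when
every conformer shows the same angles and approaches 0 for uniformly
scattered angles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from .model_io import Ensemble, Model

logger = logging.getLogger(__name__)

#: default atom selections for superposition, by polymer type
BACKBONE_SELECTION = {
    "protein": ("N", "CA", "C", "O"),
    "nucleic": ("P", "O5'", "C5'", "C4'", "C3'", "O3'"),
}

# (angle name, list of (residue offset, atom name)) defining each dihedral
_PROTEIN_DEFS = [
    ("phi", [(-1, "C"), (0, "N"), (0, "CA"), (0, "C")]),
    ("psi", [(0, "N"), (0, "CA"), (0, "C"), (+1, "N")]),
]
_NUCLEIC_DEFS = [
    ("alpha", [(-1, "O3'"), (0, "P"), (0, "O5'"), (0, "C5'")]),
    ("beta", [(0, "P"), (0, "O5'"), (0, "C5'"), (0, "C4'")]),
    ("gamma", [(0, "O5'"), (0, "C5'"), (0, "C4'"), (0, "C3'")]),
    ("delta", [(0, "C5'"), (0, "C4'"), (0, "C3'"), (0, "O3'")]),
    ("epsilon", [(0, "C4'"), (0, "C3'"), (0, "O3'"), (+1, "P")]),
    ("zeta", [(0, "C3'"), (0, "O3'"), (+1, "P"), (+1, "O5'")]),
]

_COLLINEAR_TOL = 1e-10


@dataclass
class DihedralSet:
    """Backbone dihedrals per residue across all models.

    ``angles[(chain, resnum)][angle_name]`` is a list of length N (model
    count) holding degrees in (-180, 180], with None where the angle is
    undefined in that model.
    """

    n_models: int
    angles: dict[tuple[str, int], dict[str, list[float | None]]] = field(
        default_factory=dict)

    def residue_angles(self, chain: str, resnum: int) -> dict[str, list]:
        return self.angles.get((chain, resnum), {})


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # proper 3x3
    translation: np.ndarray
    rmsd: float


@dataclass
class ClusterResult:
    clusters: list[list[int]]          # partition of model ids
    representatives: list[int]         # medoid per cluster (parallel list)
    overall_representative: int
    rmsd_matrix: np.ndarray            # pairwise post-superposition RMSD (A)


def dihedral_angle(p0, p1, p2, p3) -> float | None:
    """Torsion angle p0-p1-p2-p3 in degrees in (-180, 180].

    Returns None for degenerate (collinear) geometry.
    """
    b0 = np.asarray(p1, dtype=float) - np.asarray(p0, dtype=float)
    b1 = np.asarray(p2, dtype=float) - np.asarray(p1, dtype=float)
    b2 = np.asarray(p3, dtype=float) - np.asarray(p2, dtype=float)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    if np.dot(n1, n1) < _COLLINEAR_TOL or np.dot(n2, n2) < _COLLINEAR_TOL:
        return None
    b1n = b1 / np.linalg.norm(b1)
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b1n)
    ang = float(np.degrees(np.arctan2(y, x)))
    if ang <= -180.0:
        ang += 360.0
    return ang


def compute_backbone_dihedrals(ensemble: Ensemble) -> DihedralSet:
    """Compute phi/psi (proteins) or alpha..zeta (nucleic acids) for every
    residue in every model.

    Terminal residues lacking a flanking atom omit the affected angle
    entirely; a missing or degenerate mid-chain atom records None for that
    model with a warning.
    """
    dset = DihedralSet(n_models=ensemble.n_models)
    for chain, seq in ensemble.sequence.items():
        defs = (_PROTEIN_DEFS if ensemble.polymer_type.get(chain) == "protein"
                else _NUCLEIC_DEFS)
        index = {num: i for i, (num, _) in enumerate(seq)}
        for resnum, _resname in seq:
            per_res: dict[str, list] = {}
            for angle_name, spec in defs:
                keys = []
                ok = True
                for offset, atom in spec:
                    i = index[resnum] + offset
                    if i < 0 or i >= len(seq):
                        ok = False  # terminal residue: angle undefined by topology
                        break
                    keys.append((chain, seq[i][0], atom))
                if not ok:
                    continue
                values: list[float | None] = []
                any_defined = False
                for model in ensemble.models:
                    try:
                        pts = [model.atoms[k] for k in keys]
                    except KeyError:
                        logger.warning("model %d: missing backbone atom for %s of "
                                       "%s/%d", model.model_id, angle_name, chain,
                                       resnum)
                        values.append(None)
                        continue
                    ang = dihedral_angle(*pts)
                    if ang is None:
                        logger.warning("model %d: degenerate geometry for %s of "
                                       "%s/%d", model.model_id, angle_name, chain,
                                       resnum)
                    else:
                        any_defined = True
                    values.append(ang)
                if any_defined:
                    per_res[angle_name] = values
            if per_res:
                dset.angles[(chain, resnum)] = per_res
    return dset


def angular_order_parameter(dset: DihedralSet, chain: str,
                            resnum: int) -> float | None:
    """Circular order parameter S2 for one residue, in [0, 1].

    Only angle types defined in every model contribute; returns None when no
    angle type is complete.  A single-conformer ensemble returns 1.0 (with a
    warning: dispersion is unmeasurable from one model).
    """
    per_res = dset.residue_angles(chain, resnum)
    s_values = []
    for values in per_res.values():
        if any(v is None for v in values):
            continue
        rad = np.radians(np.asarray(values, dtype=float))
        s = float(np.mean(np.cos(rad)) ** 2 + np.mean(np.sin(rad)) ** 2)
        s_values.append(min(s, 1.0))
    if not s_values:
        return None
    if dset.n_models == 1:
        logger.warning("S2 for %s/%d computed from a single conformer", chain,
                       resnum)
        return 1.0
    return float(np.mean(s_values))


def order_parameters(ensemble: Ensemble,
                     dset: DihedralSet | None = None) -> dict[tuple[str, int], float | None]:
    """S2 for every residue of the ensemble."""
    if dset is None:
        dset = compute_backbone_dihedrals(ensemble)
    return {(c, r): angular_order_parameter(dset, c, r)
            for c, r, _ in ensemble.residues()}


# --------------------------------------------------------------------------
# superposition and clustering
# --------------------------------------------------------------------------

def kabsch_superpose(coords_a: np.ndarray, coords_b: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid-body superposition of B onto A (Kabsch).

    Returns the proper rotation R and translation t such that
    ``R @ b + t`` best matches A in the least-squares sense, together with
    the post-fit RMSD.  Reflections are corrected by flipping the sign of
    the smallest singular vector when det < 0.
    """
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError("coordinate arrays must be matching (n, 3)")
    n = A.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points for superposition")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    A0, B0 = A - ca, B - cb
    H = B0.T @ A0
    U, S, Vt = np.linalg.svd(H)
    # rank check: at least two non-negligible singular values (non-collinear)
    if S[1] < 1e-9 * max(S[0], 1.0):
        raise ValueError("degenerate (collinear) point set")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ca - R @ cb
    diff = (B0 @ R.T) - A0
    rmsd = float(np.sqrt(np.mean(np.sum(diff ** 2, axis=1))))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd)


def _selection_coords(ensemble: Ensemble, model: Model,
                      atom_selection: dict[str, tuple[str, ...]]) -> np.ndarray:
    keys = []
    for chain, resnum, _ in ensemble.residues():
        names = atom_selection.get(ensemble.polymer_type.get(chain, "protein"), ())
        for name in names:
            key = (chain, resnum, name)
            if key in model.atoms:
                keys.append(key)
    return np.array([model.atoms[k] for k in keys])


def pairwise_rmsd_matrix(ensemble: Ensemble,
                         atom_selection: dict[str, tuple[str, ...]] | None = None
                         ) -> np.ndarray:
    """Symmetric matrix of post-superposition backbone RMSDs (A)."""
    sel = atom_selection or BACKBONE_SELECTION
    coords = [_selection_coords(ensemble, m, sel) for m in ensemble.models]
    if coords[0].shape[0] == 0:
        raise ValueError("atom selection matches no atoms")
    n = len(coords)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            r = kabsch_superpose(coords[i], coords[j]).rmsd
            mat[i, j] = mat[j, i] = r
    return mat


def cluster_and_represent(ensemble: Ensemble,
                          atom_selection: dict[str, tuple[str, ...]] | None = None,
                          rmsd_cutoff_A: float = 2.0) -> ClusterResult:
    """Average-linkage clustering of the ensemble on pairwise backbone RMSD.

    The dendrogram is cut at ``rmsd_cutoff_A``; each cluster's
    representative is its medoid (minimum summed RMSD to cluster members)
    and the overall representative is the medoid of the largest cluster.
    Ties break toward the lower model id.
    """
    n = ensemble.n_models
    if n == 1:
        only = ensemble.models[0].model_id
        return ClusterResult(clusters=[[only]], representatives=[only],
                             overall_representative=only,
                             rmsd_matrix=np.zeros((1, 1)))
    mat = pairwise_rmsd_matrix(ensemble, atom_selection)
    labels = fcluster(average(squareform(mat, checks=False)), t=rmsd_cutoff_A,
                      criterion="distance")
    model_ids = [m.model_id for m in ensemble.models]
    clusters: list[list[int]] = []
    reps: list[int] = []
    for lab in sorted(set(labels)):
        idx = [i for i, l in enumerate(labels) if l == lab]
        members = [model_ids[i] for i in idx]
        sums = mat[np.ix_(idx, idx)].sum(axis=1)
        medoid = members[int(np.lexsort((members, sums))[0])]
        clusters.append(members)
        reps.append(medoid)
    # largest cluster; size ties -> the one containing the lowest model id
    order = sorted(range(len(clusters)),
                   key=lambda k: (-len(clusters[k]), min(clusters[k])))
    best = order[0]
    return ClusterResult(clusters=clusters, representatives=reps,
                         overall_representative=reps[best], rmsd_matrix=mat)
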