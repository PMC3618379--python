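"""Residual dipolar coupling analysis: Saupe alignment-tensor fitting and
goodness-of-fit metrics.

An RDC measured for an internuclear unit vector u = (x, y, z) in a
partially aligned molecule is, in the N-HN-normalized convention,

    D = u^T S u

with S the traceless symmetric 3x3 alignment (Saupe order) tensor in Hz.
Expanding with Szz = -Sxx - Syy gives a linear model in five unknowns

    D = Sxx (x^2 - z^2) + Syy (y^2 - z^2) + 2 Sxy xy + 2 Sxz xz + 2 Syz yz

fitted per model per alignment medium by SVD least squares (>= 5 couplings
required).  From the eigenvalues ordered |l1| <= |l2| <= |l3| the tensor
magnitude is Da = l3 / 2 and the rhombicity R = 2 (l1 - l2) / (3 l3), with
R in [0, 2/3].  Fit quality is summarized by the RMS deviation (Hz), the
Pearson correlation and the Cornilescu Q value rms(obs - calc) / rms(obs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .config import DEFAULT_BOND_TABLE
from .model_io import Model, RdcConstraint, format_atom_ref

logger = logging.getLogger(__name__)

CONDITION_WARN = 1e6
MIN_RDCS = 5


@dataclass
class SaupeTensor:
    """Traceless symmetric alignment tensor with derived quantities."""

    matrix: np.ndarray                 # 3x3, Hz
    eigenvalues: np.ndarray            # ordered |l1| <= |l2| <= |l3|
    axes: np.ndarray                   # unit eigenvectors as columns, same order
    da_hz: float                       # l3 / 2
    rhombicity: float                  # 2 (l1 - l2) / (3 l3)

    @classmethod
    def from_elements(cls, sxx, syy, sxy, sxz, syz) -> "SaupeTensor":
        m = np.array([[sxx, sxy, sxz],
                      [sxy, syy, syz],
                      [sxz, syz, -sxx - syy]], dtype=float)
        return cls.from_matrix(m)

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "SaupeTensor":
        m = np.asarray(m, dtype=float)
        if m.shape != (3, 3) or not np.allclose(m, m.T, atol=1e-9):
            raise ValueError("Saupe tensor must be symmetric 3x3")
        if abs(np.trace(m)) > 1e-9 * max(1.0, np.linalg.norm(m)):
            raise ValueError("Saupe tensor must be traceless")
        vals, vecs = np.linalg.eigh(m)
        order = np.argsort(np.abs(vals))
        vals = vals[order]
        vecs = vecs[:, order]
        l3 = vals[2]
        da = l3 / 2.0
        rhomb = 2.0 * (vals[0] - vals[1]) / (3.0 * l3) if l3 != 0 else 0.0
        return cls(matrix=m, eigenvalues=vals, axes=vecs, da_hz=float(da),
                   rhombicity=float(rhomb))


@dataclass
class RdcFit:
    model_id: int
    medium: str
    tensor: SaupeTensor
    constraint_ids: list[str]
    observed_hz: np.ndarray            # normalized observed values used in the fit
    calculated_hz: np.ndarray
    rmsd_hz: float
    pearson_r: float | None
    q_value: float | None
    n_constraints: int
    condition_number: float
    degenerate: bool = False
    extras: dict = field(default_factory=dict)


def normalization_factor(rdc_type: str, bond_table=None) -> float:
    """Scale putting an RDC type on the N-HN scale:
    (gN gH / r_NH^3) / (gA gB / r_AB^3).  Exactly 1 for N-HN."""
    table = bond_table or DEFAULT_BOND_TABLE
    if rdc_type not in table:
        raise ValueError(f"unknown RDC type {rdc_type!r}; known: "
                         f"{sorted(table)}")
    g_n, g_h, r_nh = table["N-HN"]
    g_a, g_b, r_ab = table[rdc_type]
    return (g_n * g_h / r_nh ** 3) / (g_a * g_b / r_ab ** 3)


def normalize_rdc(constraint: RdcConstraint, bond_table=None) -> float:
    """Observed value rescaled to the N-HN normalization (Hz)."""
    return constraint.observed_hz * normalization_factor(constraint.rdc_type,
                                                         bond_table)


def design_row(unit_vector: np.ndarray) -> np.ndarray:
    x, y, z = unit_vector
    return np.array([x * x - z * z, y * y - z * z, 2 * x * y, 2 * x * z,
                     2 * y * z])


def _unit_vector(model: Model, con: RdcConstraint) -> np.ndarray:
    for key in (con.atom1, con.atom2):
        if key not in model.atoms:
            raise ValueError(f"RDC {con.id}: atom {format_atom_ref(key)} not in "
                             f"model {model.model_id}")
    v = model.atoms[con.atom2] - model.atoms[con.atom1]
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError(f"RDC {con.id}: coincident atoms")
    return v / n


def goodness_of_fit(observed, calculated):
    """(rmsd_hz, pearson_r, q_value) between observed and calculated RDCs.

    Pearson is None for zero observed variance; Q (rms deviation over rms of
    observed values) is None when all observed values are zero.
    """
    obs = np.asarray(observed, dtype=float)
    calc = np.asarray(calculated, dtype=float)
    if obs.shape != calc.shape or obs.size < 2:
        raise ValueError("need two equal-length lists of >= 2 values")
    rmsd = float(np.sqrt(np.mean((obs - calc) ** 2)))
    pearson = None
    if np.std(obs) > 0 and np.std(calc) > 0:
        pearson = float(np.corrcoef(obs, calc)[0, 1])
    rms_obs = float(np.sqrt(np.mean(obs ** 2)))
    q = rmsd / rms_obs if rms_obs > 0 else None
    return rmsd, pearson, q


def fit_alignment_tensor(rdcs: list[RdcConstraint], model: Model,
                         bond_table=None, prescaled: bool = False) -> RdcFit:
    """Fit one Saupe tensor to the RDCs of a single alignment medium against
    one model's coordinates.

    Observed values are first put on the N-HN scale unless ``prescaled``
    (already deposited in normalized units).  The five tensor elements are
    solved by SVD pseudo-inverse least squares; an ill-conditioned design
    (condition number > 1e6, e.g. near-parallel bond vectors) is returned
    with ``degenerate=True`` rather than an error.
    """
    if len(rdcs) < MIN_RDCS:
        raise ValueError(f"need >= {MIN_RDCS} RDCs to fit a tensor, got "
                         f"{len(rdcs)}")
    media = {c.medium for c in rdcs}
    if len(media) != 1:
        raise ValueError(f"RDCs span several media: {sorted(media)}")
    obs = np.array([c.observed_hz if prescaled else normalize_rdc(c, bond_table)
                    for c in rdcs])
    A = np.vstack([design_row(_unit_vector(model, c)) for c in rdcs])
    s_vals = np.linalg.svd(A, compute_uv=False)
    cond = float(s_vals[0] / s_vals[-1]) if s_vals[-1] > 0 else np.inf
    degenerate = cond > CONDITION_WARN
    if degenerate:
        logger.warning("model %d medium %s: ill-conditioned RDC design matrix "
                       "(cond=%.3g)", model.model_id, rdcs[0].medium, cond)
    sol = np.linalg.pinv(A, rcond=1e-10) @ obs
    tensor = SaupeTensor.from_elements(*sol)
    calc = A @ sol
    rmsd, pearson, q = goodness_of_fit(obs, calc)
    return RdcFit(model_id=model.model_id, medium=rdcs[0].medium, tensor=tensor,
                  constraint_ids=[c.id for c in rdcs], observed_hz=obs,
                  calculated_hz=calc, rmsd_hz=rmsd, pearson_r=pearson,
                  q_value=q, n_constraints=len(rdcs), condition_number=cond,
                  degenerate=degenerate)


def q_value_da_normalized(fit: RdcFit) -> float | None:
    """Alternative Q normalization: rmsd / (|Da| sqrt(4 + 3 R^2))."""
    da, r = fit.tensor.da_hz, fit.tensor.rhombicity
    denom = abs(da) * np.sqrt(4.0 + 3.0 * r * r)
    return fit.rmsd_hz / denom if denom > 0 else None


def detect_rdc_unit_convention(rdcs: list[RdcConstraint], model: Model,
                               bond_table=None):
    """Decide whether a medium's RDCs were deposited raw or pre-scaled.

    With a single RDC type the two fits are indistinguishable (the scale is
    absorbed by the tensor), so ``raw`` is returned by convention.  With
    several types the convention giving the lower Q wins; both Q values are
    reported.
    """
    types = {c.rdc_type for c in rdcs}
    if len(types) < 2:
        return "raw", {"q_raw": None, "q_prescaled": None}
    fit_raw = fit_alignment_tensor(rdcs, model, bond_table, prescaled=False)
    fit_pre = fit_alignment_tensor(rdcs, model, bond_table, prescaled=True)
    qs = {"q_raw": fit_raw.q_value, "q_prescaled": fit_pre.q_value}
    if fit_pre.q_value is not None and (fit_raw.q_value is None
                                        or fit_pre.q_value < fit_raw.q_value):
        return "prescaled", qs
    return "raw", qs


def fit_ensemble(rdcs_by_medium: dict[str, list[RdcConstraint]], ensemble,
                 bond_table=None, prescaled_by_medium=None) -> dict[str, list[RdcFit]]:
    """Fit one tensor per model per medium over a whole ensemble."""
    prescaled_by_medium = prescaled_by_medium or {}
    fits: dict[str, list[RdcFit]] = {}
    for medium, rdcs in rdcs_by_medium.items():
        pres = prescaled_by_medium.get(medium, False)
        fits[medium] = [fit_alignment_tensor(rdcs, m, bond_table, prescaled=pres)
                        for m in ensemble.models]
    return fits


def ensemble_rdc_stats(fits: list[RdcFit]):
    """Across-model statistics of calculated RDCs per constraint, plus mean
    fit metrics for the medium.

    Returns ``(per_constraint, summary)``: per_constraint maps constraint id
    to (mean, sd, min, max) of the calculated value over models (sd = 0 for
    a single model); summary averages rmsd/|pearson-defined| metrics.
    """
    if not fits:
        raise ValueError("need at least one fit")
    ids = fits[0].constraint_ids
    calc = np.vstack([f.calculated_hz for f in fits])  # models x constraints
    per_constraint = {}
    for j, cid in enumerate(ids):
        col = calc[:, j]
        per_constraint[cid] = {
            "mean": float(col.mean()),
            "sd": float(col.std(ddof=0)) if len(col) > 1 else 0.0,
            "min": float(col.min()),
            "max": float(col.max()),
        }
    pearsons = [f.pearson_r for f in fits if f.pearson_r is not None]
    qs = [f.q_value for f in fits if f.q_value is not None]
    summary = {
        "mean_rmsd_hz": float(np.mean([f.rmsd_hz for f in fits])),
        "mean_pearson_r": float(np.mean(pearsons)) if pearsons else None,
        "mean_q": float(np.mean(qs)) if qs else None,
        "mean_da_hz": float(np.mean([f.tensor.da_hz for f in fits])),
        "mean_rhombicity": float(np.mean([f.tensor.rhombicity for f in fits])),
        "n_models": len(fits),
    }
    return per_constraint, summary
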