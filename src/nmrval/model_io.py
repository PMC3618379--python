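"""Input/output layer: coordinate ensembles, restraint tables, reports.

Coordinate files (PDB with MODEL/ENDMDL records, or mmCIF) are read through
gemmi into a plain :class:`Ensemble` container that addresses every atom by
``(chain id, author residue number, atom name)``.  Restraints, RDCs and
chemical shifts arrive in small tab-separated tables whose dialects are
defined here (see the ``*_COLUMNS`` constants); validation results leave as
a deterministic JSON report.

Conventions enforced on reading:

* every model must contain exactly the same atom keys (hard error otherwise);
* alternate locations other than blank/'A' are dropped;
* insertion codes are rejected — author numbering must be plain integers;
* hydrogens are kept (they carry RDC vectors and shift assignments).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

AtomKey = tuple[str, int, str]  # (chain id, residue number, atom name)

PROTEIN_ANGLES = ("phi", "psi")
NUCLEIC_ANGLES = ("alpha", "beta", "gamma", "delta", "epsilon", "zeta")

_NUCLEIC_RESNAMES = {
    "A", "C", "G", "U", "T", "DA", "DC", "DG", "DT", "DU",
    "RA", "RC", "RG", "RU",
}


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class Model:
    """One conformer: a map from atom key to Cartesian position in Angstrom."""

    model_id: int
    atoms: dict[AtomKey, np.ndarray]

    def position(self, key: AtomKey) -> np.ndarray:
        try:
            return self.atoms[key]
        except KeyError:
            raise KeyError(f"atom {key[0]}/{key[1]}/{key[2]} not present in model "
                           f"{self.model_id}") from None


@dataclass
class Ensemble:
    """An ordered multi-model ensemble of identical topology.

    ``sequence`` maps each chain id to its ordered list of
    ``(residue number, residue name)``; ``polymer_type`` labels each chain
    ``"protein"`` or ``"nucleic"``.
    """

    models: list[Model]
    sequence: dict[str, list[tuple[int, str]]]
    polymer_type: dict[str, str]

    @property
    def n_models(self) -> int:
        return len(self.models)

    def residues(self):
        """Yield (chain, resnum, resname) over all chains in order."""
        for chain, seq in self.sequence.items():
            for resnum, resname in seq:
                yield chain, resnum, resname

    def residue_name(self, chain: str, resnum: int) -> str:
        for num, name in self.sequence.get(chain, ()):
            if num == resnum:
                return name
        raise KeyError(f"residue {chain}/{resnum} not in ensemble")


@dataclass
class DistanceConstraint:
    """A (possibly ambiguous) distance bound between atom pairs.

    ``members`` is a non-empty list of candidate pairs; ambiguous members are
    combined at evaluation time by r^-6 sum averaging.
    """

    id: str
    members: list[tuple[AtomKey, AtomKey]]
    lower: float
    upper: float

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"constraint {self.id}: members must be non-empty")
        if self.lower < 0 or self.upper < self.lower:
            raise ValueError(
                f"constraint {self.id}: need 0 <= lower <= upper, got "
                f"[{self.lower}, {self.upper}]")


@dataclass
class DihedralConstraint:
    """Allowed arc for one backbone dihedral, traversed counter-clockwise
    from ``lower`` to ``upper`` (wrap through 180/-180 permitted)."""

    id: str
    chain: str
    resnum: int
    angle: str
    lower: float
    upper: float

    def __post_init__(self):
        for v in (self.lower, self.upper):
            if not (-180.0 < v <= 180.0):
                raise ValueError(
                    f"constraint {self.id}: angle bound {v} outside (-180, 180]")


@dataclass
class RdcConstraint:
    """One residual dipolar coupling observation (Hz) for an atom pair."""

    id: str
    atom1: AtomKey
    atom2: AtomKey
    rdc_type: str
    medium: str
    observed_hz: float

    def __post_init__(self):
        if self.atom1 == self.atom2:
            raise ValueError(f"constraint {self.id}: atoms must be distinct")


@dataclass
class ChemicalShiftRecord:
    chain: str
    resnum: int
    resname: str
    atom: str
    nucleus_class: str
    value_ppm: float


@dataclass
class ShiftReferenceTable:
    """Expected shift statistics keyed by
    (residue name, atom name, ss class, accessibility bin)."""

    entries: dict[tuple[str, str, str, str], tuple[float, float, int]] = field(
        default_factory=dict)

    def add(self, resname, atom, ss, acc_bin, mean, sd, count):
        key = (resname, atom, ss, acc_bin)
        if key in self.entries:
            raise ValueError(f"duplicate reference key {key}")
        if sd <= 0:
            raise ValueError(f"reference entry {key}: sd must be > 0, got {sd}")
        if count < 1:
            raise ValueError(f"reference entry {key}: count must be >= 1")
        self.entries[key] = (float(mean), float(sd), int(count))

    def lookup(self, resname, atom, ss, acc_bin):
        """Return (mean, sd, count) or None if no entry exists."""
        return self.entries.get((resname, atom, ss, acc_bin))


# --------------------------------------------------------------------------
# coordinate input
# --------------------------------------------------------------------------

def _polymer_type_of(atom_names: set[str], resnames: set[str]) -> str:
    if resnames & _NUCLEIC_RESNAMES or "O5'" in atom_names or "O3'" in atom_names:
        return "nucleic"
    return "protein"


def read_ensemble(path: str | Path, fmt: str | None = None) -> Ensemble:
    """Read a multi-model PDB or mmCIF file into an :class:`Ensemble`.

    ``fmt`` may be ``"pdb"`` or ``"mmcif"``; when None the format is
    detected from the file.  Raises ValueError for zero models, insertion
    codes, duplicate atoms or atom-key sets that differ between models.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        st = gemmi.read_structure(str(path))
    else:
        cf = {"pdb": gemmi.CoorFormat.Pdb, "mmcif": gemmi.CoorFormat.Mmcif}
        if fmt not in cf:
            raise ValueError(f"unknown coordinate format {fmt!r}")
        st = gemmi.read_structure(str(path), format=cf[fmt])

    models: list[Model] = []
    for gm in st:
        atoms: dict[AtomKey, np.ndarray] = {}
        for chain in gm:
            for res in chain:
                if res.seqid.icode not in (" ", "\x00", ""):
                    raise ValueError(
                        f"insertion code {res.seqid.icode!r} at "
                        f"{chain.name}/{res.seqid.num} is not supported")
                for atom in res:
                    if atom.altloc not in ("", "\x00", "A"):
                        continue
                    key = (chain.name, res.seqid.num, atom.name)
                    if key in atoms:
                        raise ValueError(
                            f"duplicate atom {key} in model {gm.num}")
                    pos = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                    if not np.all(np.isfinite(pos)):
                        raise ValueError(f"non-finite coordinates for {key}")
                    atoms[key] = pos
        if atoms:
            models.append(Model(model_id=len(models) + 1, atoms=atoms))

    if not models:
        raise ValueError(f"{path}: no models found")

    ref_keys = set(models[0].atoms)
    for m in models[1:]:
        keys = set(m.atoms)
        if keys != ref_keys:
            missing = sorted(ref_keys - keys)[:10]
            extra = sorted(keys - ref_keys)[:10]
            raise ValueError(
                f"model {m.model_id} atom set differs from model 1; "
                f"missing={missing} extra={extra}")

    # sequence + polymer type from the first gemmi model (preserves order)
    sequence: dict[str, list[tuple[int, str]]] = {}
    resnames_by_chain: dict[str, set[str]] = {}
    atomnames_by_chain: dict[str, set[str]] = {}
    for chain in st[0]:
        seq = sequence.setdefault(chain.name, [])
        rn = resnames_by_chain.setdefault(chain.name, set())
        an = atomnames_by_chain.setdefault(chain.name, set())
        for res in chain:
            if not seq or seq[-1][0] != res.seqid.num:
                seq.append((res.seqid.num, res.name))
            rn.add(res.name)
            an.update(a.name for a in res)
    polymer_type = {
        c: _polymer_type_of(atomnames_by_chain[c], resnames_by_chain[c])
        for c in sequence
    }
    return Ensemble(models=models, sequence=sequence, polymer_type=polymer_type)


_ELEMENT_FROM_NAME = {"SE": "Se", "CL": "Cl", "BR": "Br"}


def _guess_element(atom_name: str) -> str:
    name = atom_name.strip()
    if name[:2].upper() in _ELEMENT_FROM_NAME:
        return _ELEMENT_FROM_NAME[name[:2].upper()]
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return "X"


def write_ensemble(ensemble: Ensemble, path: str | Path,
                   remarks: list[str] | None = None) -> None:
    """Write an ensemble as a multi-model PDB file (via gemmi).

    ``remarks`` are prepended as ``REMARK 999`` lines (used by the fixture
    generator to record seeds).
    """
    st = gemmi.Structure()
    st.name = "nmrval"
    for model in ensemble.models:
        gm = gemmi.Model(model.model_id)
        for chain_id, seq in ensemble.sequence.items():
            gc = gemmi.Chain(chain_id)
            for resnum, resname in seq:
                gr = gemmi.Residue()
                gr.name = resname
                gr.seqid = gemmi.SeqId(resnum, " ")
                for (c, r, a), pos in model.atoms.items():
                    if c == chain_id and r == resnum:
                        ga = gemmi.Atom()
                        ga.name = a
                        ga.pos = gemmi.Position(*pos)
                        ga.element = gemmi.Element(_guess_element(a))
                        ga.occ = 1.0
                        gr.add_atom(ga)
                gc.add_residue(gr)
            gm.add_chain(gc)
        st.add_model(gm)
    st.setup_entities()
    path = Path(path)
    st.write_pdb(str(path))
    if remarks:
        body = path.read_text()
        header = "".join(f"REMARK 999 {r}\n" for r in remarks)
        path.write_text(header + body)


# --------------------------------------------------------------------------
# TSV tables
# --------------------------------------------------------------------------

DISTANCE_COLUMNS = ["id", "members", "lower_A", "upper_A"]
DIHEDRAL_COLUMNS = ["id", "chain", "resnum", "angle", "lower_deg", "upper_deg"]
RDC_COLUMNS = ["id", "atom1", "atom2", "type", "medium", "observed_hz"]
SHIFT_COLUMNS = ["chain", "resnum", "resname", "atom", "nucleus_class", "shift_ppm"]
REFERENCE_COLUMNS = ["resname", "atom", "ss", "acc_bin", "mean_ppm", "sd_ppm", "n"]

_HEADERS = {
    "distance": DISTANCE_COLUMNS,
    "dihedral": DIHEDRAL_COLUMNS,
    "rdc": RDC_COLUMNS,
    "shift": SHIFT_COLUMNS,
}


def parse_atom_ref(text: str) -> AtomKey:
    """Parse ``chain/resnum/atom`` into an atom key."""
    parts = text.strip().split("/")
    if len(parts) != 3:
        raise ValueError(f"bad atom reference {text!r}; expected chain/resnum/atom")
    chain, resnum, atom = parts
    try:
        num = int(resnum)
    except ValueError:
        raise ValueError(f"bad residue number in atom reference {text!r}") from None
    return (chain, num, atom)


def format_atom_ref(key: AtomKey) -> str:
    return f"{key[0]}/{key[1]}/{key[2]}"


def _float(text: str, line_no: int, col: str) -> float:
    try:
        v = float(text)
    except ValueError:
        raise ValueError(f"line {line_no}: non-numeric {col} value {text!r}") from None
    if math.isnan(v) or math.isinf(v):
        raise ValueError(f"line {line_no}: non-finite {col} value {text!r}")
    return v


def _iter_rows(path: Path, expected_header: list[str]):
    lines = path.read_text().splitlines()
    header = None
    for line_no, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if header is None:
            header = [f.strip() for f in fields]
            if header != expected_header:
                raise ValueError(
                    f"{path}: header {header} does not match expected "
                    f"{expected_header}")
            continue
        if len(fields) != len(expected_header):
            raise ValueError(
                f"{path} line {line_no}: expected {len(expected_header)} "
                f"columns, got {len(fields)}")
        yield line_no, [f.strip() for f in fields]
    if header is None:
        raise ValueError(f"{path}: missing header row")


def read_constraint_table(path: str | Path, kind: str):
    """Read a restraint/shift TSV.  ``kind`` selects the dialect:
    ``distance`` | ``dihedral`` | ``rdc`` | ``shift``."""
    path = Path(path)
    if kind not in _HEADERS:
        raise ValueError(f"unknown table kind {kind!r}")
    records = []
    for line_no, f in _iter_rows(path, _HEADERS[kind]):
        if kind == "distance":
            members = []
            for pair_text in f[1].split("|"):
                halves = pair_text.split("-")
                if len(halves) != 2:
                    raise ValueError(
                        f"{path} line {line_no}: bad member pair {pair_text!r}")
                members.append((parse_atom_ref(halves[0]),
                                parse_atom_ref(halves[1])))
            records.append(DistanceConstraint(
                id=f[0], members=members,
                lower=_float(f[2], line_no, "lower_A"),
                upper=_float(f[3], line_no, "upper_A")))
        elif kind == "dihedral":
            records.append(DihedralConstraint(
                id=f[0], chain=f[1], resnum=int(f[2]), angle=f[3],
                lower=_float(f[4], line_no, "lower_deg"),
                upper=_float(f[5], line_no, "upper_deg")))
        elif kind == "rdc":
            records.append(RdcConstraint(
                id=f[0], atom1=parse_atom_ref(f[1]), atom2=parse_atom_ref(f[2]),
                rdc_type=f[3], medium=f[4],
                observed_hz=_float(f[5], line_no, "observed_hz")))
        elif kind == "shift":
            records.append(ChemicalShiftRecord(
                chain=f[0], resnum=int(f[1]), resname=f[2], atom=f[3],
                nucleus_class=f[4],
                value_ppm=_float(f[5], line_no, "shift_ppm")))
    return records


def read_shift_reference(path: str | Path) -> ShiftReferenceTable:
    """Read the shift reference-statistics TSV into a lookup table."""
    table = ShiftReferenceTable()
    for line_no, f in _iter_rows(Path(path), REFERENCE_COLUMNS):
        mean = _float(f[4], line_no, "mean_ppm")
        sd = _float(f[5], line_no, "sd_ppm")
        count = int(f[6])
        table.add(f[0], f[1], f[2], f[3], mean, sd, count)
    return table


# --------------------------------------------------------------------------
# reports
# --------------------------------------------------------------------------

REPORT_SECTIONS = ("entry", "ensemble", "residues", "distance_constraints",
                   "dihedral_constraints", "rdc", "shifts", "rog")


def _sanitize(obj):
    """Replace NaN/inf floats by None and numpy scalars by Python ones."""
    if isinstance(obj, dict):
        return {k: _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if math.isfinite(v) else None
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _sanitize(obj.tolist())
    return obj


def write_report(report: dict, path: str | Path) -> None:
    """Serialize a validation report to strict, deterministic JSON.

    Keys are sorted, floats are finite (NaN/inf become null), encoding is
    UTF-8 with a trailing newline; identical reports serialize to identical
    bytes.
    """
    clean = _sanitize(report)
    try:
        text = json.dumps(clean, indent=1, sort_keys=True, allow_nan=False,
                          ensure_ascii=False)
    except TypeError as exc:
        raise TypeError(f"report is not JSON-serializable: {exc}") from exc
    Path(path).write_text(text + "\n", encoding="utf-8")


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))


def validate_report(report: dict) -> list[str]:
    """Structural check of a report against the shipped schema.

    Returns a list of problems (empty when the report conforms).  This is a
    lightweight in-package validator; the authoritative schema document is
    shipped at ``nmrval/data/report_schema.json``.
    """
    problems = []
    for key in REPORT_SECTIONS:
        if key not in report:
            problems.append(f"missing top-level section {key!r}")
    for key in ("residues", "distance_constraints", "dihedral_constraints",
                "rdc", "shifts", "rog"):
        if key in report and not isinstance(report[key], list):
            problems.append(f"section {key!r} must be a list")
    for key in ("entry", "ensemble"):
        if key in report and not isinstance(report[key], dict):
            problems.append(f"section {key!r} must be an object")
    if isinstance(report.get("residues"), list):
        seen = set()
        for rec in report["residues"]:
            if not isinstance(rec, dict):
                problems.append("residues[] entries must be objects")
                break
            for fld in ("chain", "resnum", "rog"):
                if fld not in rec:
                    problems.append(f"residue record missing field {fld!r}")
            key = (rec.get("chain"), rec.get("resnum"))
            if key in seen:
                problems.append(f"residue {key} appears more than once")
            seen.add(key)
            if rec.get("rog") not in ("red", "orange", "green"):
                problems.append(f"residue {key}: bad rog value {rec.get('rog')!r}")
    return problems
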