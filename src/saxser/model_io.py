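"""Core value types and file I/O for the refinement pipeline.

Coordinates are in Å throughout; momentum transfer q = 4π sin(θ)/λ is in
Å⁻¹.  Conformer models are reduced bead/CA representations: one scattering
point per bead with a constant form-factor weight.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "construct_length",
    "ConformerModel",
    "ScatteringCurve",
    "PeakList",
    "RnaSequence",
    "read_pdb",
    "write_pdb",
    "read_saxs_dat",
    "write_saxs_dat",
    "read_peak_list",
    "read_fasta",
]


class ModelIOError(ValueError):
    """Raised for malformed or inconsistent input files."""


def construct_length(first_residue: int, last_residue: int) -> int:
    """Residue count of a construct given 1-based inclusive boundaries.

    E.g. a domain spanning residues 56-144 comprises 89 residues.
    """
    if last_residue < first_residue:
        raise ModelIOError("last residue precedes first residue")
    return last_residue - first_residue + 1


@dataclass
class ConformerModel:
    """A labelled 3D point set with per-point scattering weights.

    Parameters
    ----------
    id : str
        Identifier for the conformer.
    points : (N, 3) array
        Bead coordinates in Å.
    weights : (N,) array, optional
        Non-negative scattering weights f_i, default 1.0 per point.
    labels : list of (chain, resseq, resname), optional
        Per-point residue metadata.
    """

    id: str
    points: np.ndarray
    weights: np.ndarray | None = None
    labels: list[tuple[str, int, str]] | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ModelIOError("points must be an (N, 3) array")
        if self.points.shape[0] == 0:
            raise ModelIOError("empty model: no points")
        if not np.all(np.isfinite(self.points)):
            raise ModelIOError("non-finite coordinates")
        if self.weights is None:
            self.weights = np.ones(len(self.points))
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.points),):
            raise ModelIOError("weights length must match points")
        if np.any(self.weights < 0) or not np.all(np.isfinite(self.weights)):
            raise ModelIOError("weights must be finite and non-negative")
        if self.labels is not None and len(self.labels) != len(self.points):
            raise ModelIOError("labels length must match points")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class ScatteringCurve:
    """A scattering profile (q, I[, σ]) on a strictly increasing q grid."""

    q: np.ndarray
    I: np.ndarray
    sigma: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        if self.q.ndim != 1 or self.q.shape != self.I.shape:
            raise ModelIOError("q and I must be 1-D arrays of equal length")
        if np.any(np.diff(self.q) <= 0):
            raise ModelIOError("q grid must be strictly increasing")
        if np.any(self.q < 0):
            raise ModelIOError("q values must be non-negative")
        if not np.all(np.isfinite(self.I)):
            raise ModelIOError("non-finite intensities")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.q.shape:
                raise ModelIOError("sigma length must match q")
            if np.any(self.sigma <= 0) or not np.all(np.isfinite(self.sigma)):
                raise ModelIOError("sigma values must be finite and positive")

    def __len__(self) -> int:
        return len(self.q)


@dataclass
class PeakList:
    """An HSQC peak list: (residue number, residue name, δH ppm, δN ppm)."""

    entries: list[tuple[int, str, float, float]]
    prolines: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        residues = [e[0] for e in self.entries]
        if len(set(residues)) != len(residues):
            dupes = sorted({r for r in residues if residues.count(r) > 1})
            raise ModelIOError(f"duplicate residue numbers in peak list: {dupes}")
        for res, _name, dh, dn in self.entries:
            if not (np.isfinite(dh) and np.isfinite(dn)):
                raise ModelIOError(f"non-finite chemical shift for residue {res}")

    def as_dict(self) -> dict[int, tuple[float, float]]:
        return {res: (dh, dn) for res, _name, dh, dn in self.entries}

    def residues(self) -> set[int]:
        return {e[0] for e in self.entries}


_RNA_ALPHABET = set("ACGU")


@dataclass
class RnaSequence:
    """An RNA sequence over {A, C, G, U}; T is normalized to U on input."""

    id: str
    bases: str

    def __post_init__(self) -> None:
        if not self.bases:
            raise ModelIOError("empty RNA sequence")
        normalized = self.bases.upper().replace("T", "U")
        if normalized != self.bases:
            logger.info("sequence %s: normalized to uppercase RNA alphabet", self.id)
        self.bases = normalized
        bad = set(self.bases) - _RNA_ALPHABET
        if bad:
            raise ModelIOError(
                f"sequence {self.id}: characters outside ACGU(T): {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.bases)


# ---------------------------------------------------------------------------
# PDB bead/CA models


def _model_from_biopdb(bio_model, model_id: str, ca_only: bool, origin: str) -> ConformerModel:
    points: list[tuple[float, float, float]] = []
    labels: list[tuple[str, int, str]] = []
    for chain in bio_model:
        for residue in chain:
            hetflag, resseq, _icode = residue.id
            for atom in residue:
                if atom.is_disordered():
                    atom = atom.disordered_get_list()[0]  # first altloc
                if ca_only and (atom.get_name() != "CA" or hetflag != " "):
                    continue
                x, y, z = atom.get_coord()
                points.append((float(x), float(y), float(z)))
                labels.append((chain.id.strip() or "A", resseq, residue.get_resname().strip()))
    if not points:
        raise ModelIOError(f"{origin}: no atoms after filtering (ca_only={ca_only})")
    return ConformerModel(id=model_id, points=np.array(points), labels=labels)


def read_pdb(path: str | Path, ca_only: bool = False) -> ConformerModel:
    """Read ATOM/HETATM records from a PDB file as a bead model.

    Keeps the first alternate location; occupancy and B-factor are ignored.
    With ``ca_only`` only CA atoms from standard residues are kept.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionException

    path = Path(path)
    try:
        structure = PDBParser(PERMISSIVE=False, QUIET=True).get_structure(path.stem, str(path))
    except (PDBConstructionException, ValueError) as exc:
        raise ModelIOError(f"{path.name}: malformed PDB record ({exc})") from exc
    bio_model = next(iter(structure))
    return _model_from_biopdb(bio_model, path.stem, ca_only, path.name)


def write_pdb(model: ConformerModel, path: str | Path) -> None:
    """Write a bead model as fixed-width ATOM records (CA atoms, 3 decimals)."""
    path = Path(path)
    lines = _atom_lines(model) + ["END"]
    path.write_text("\n".join(lines) + "\n")


def _atom_lines(model: ConformerModel) -> list[str]:
    if np.any(np.abs(model.points) >= 10000.0):
        raise ModelIOError("coordinate exceeds PDB fixed-width field (|x| >= 1e4 Å)")
    labels = model.labels
    if labels is None:
        labels = [("A", i + 1, "ALA") for i in range(len(model))]
    return [
        f"ATOM  {i % 100000:5d}  CA  {resname:<3s} {chain:1s}{resseq:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        for i, ((x, y, z), (chain, resseq, resname)) in enumerate(
            zip(model.points, labels), start=1
        )
    ]


def write_multi_model_pdb(models: Sequence[ConformerModel], path: str | Path) -> None:
    """Write several conformers as MODEL/ENDMDL blocks of one PDB file."""
    path = Path(path)
    lines: list[str] = []
    for n, model in enumerate(models, start=1):
        lines.append(f"MODEL     {n:4d}")
        lines.extend(_atom_lines(model))
        lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def read_multi_model_pdb(path: str | Path, ca_only: bool = False) -> list[ConformerModel]:
    """Read MODEL/ENDMDL blocks as separate conformers."""
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionException

    path = Path(path)
    try:
        structure = PDBParser(PERMISSIVE=False, QUIET=True).get_structure(path.stem, str(path))
    except (PDBConstructionException, ValueError) as exc:
        raise ModelIOError(f"{path.name}: malformed PDB record ({exc})") from exc
    models = [
        _model_from_biopdb(m, f"{path.stem}_{i}", ca_only, path.name)
        for i, m in enumerate(structure, start=1)
    ]
    if len(models) == 1:
        models[0].id = path.stem
    return models


# ---------------------------------------------------------------------------
# SAXS ASCII curves

_NM_PER_ANGSTROM = 0.1


def read_saxs_dat(path: str | Path, q_unit: str = "angstrom") -> ScatteringCurve:
    """Read a 2- or 3-column whitespace SAXS ASCII file (q, I[, σ]).

    Lines starting with '#' and non-numeric header lines are skipped.
    ``q_unit`` may be "angstrom" (Å⁻¹, default) or "nm" (nm⁻¹, converted).
    """
    if q_unit not in ("angstrom", "nm"):
        raise ValueError("q_unit must be 'angstrom' or 'nm'")
    path = Path(path)
    rows: list[list[float]] = []
    for line in path.read_text().splitlines():
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        parts = stripped.split()
        try:
            vals = [float(p) for p in parts]
        except ValueError:
            if rows:
                raise ModelIOError(f"{path.name}: non-numeric line after data: {line!r}")
            continue  # header line
        if len(vals) not in (2, 3):
            raise ModelIOError(f"{path.name}: expected 2 or 3 columns, got {len(vals)}")
        rows.append(vals)
    if not rows:
        raise ModelIOError(f"{path.name}: no data rows")
    ncol = len(rows[0])
    if any(len(r) != ncol for r in rows):
        raise ModelIOError(f"{path.name}: inconsistent column count")
    arr = np.array(rows)
    q = arr[:, 0]
    if q_unit == "nm":
        q = q * _NM_PER_ANGSTROM
    sigma = arr[:, 2] if ncol == 3 else None
    return ScatteringCurve(q=q, I=arr[:, 1], sigma=sigma)


def write_saxs_dat(curve: ScatteringCurve, path: str | Path, header: str = "") -> None:
    """Write a curve as 3 (or 2) columns with '%.8e' formatting."""
    path = Path(path)
    lines = [f"# {h}" for h in header.splitlines()] if header else []
    lines.append("# q(A^-1) I(q)" + (" sigma" if curve.sigma is not None else ""))
    for k in range(len(curve)):
        row = f"{curve.q[k]:.8e} {curve.I[k]:.8e}"
        if curve.sigma is not None:
            row += f" {curve.sigma[k]:.8e}"
        lines.append(row)
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Peak lists and RNA sequences

_PEAK_HEADER = ("residue", "name", "dH_ppm", "dN_ppm")


def read_peak_list(path: str | Path) -> PeakList:
    """Read a TSV peak list with header 'residue\\tname\\tdH_ppm\\tdN_ppm'."""
    path = Path(path)
    entries: list[tuple[int, str, float, float]] = []
    prolines: set[int] = set()
    lines = path.read_text().splitlines()
    if not lines:
        raise ModelIOError(f"{path.name}: empty file")
    start = 0
    first = tuple(c.strip() for c in lines[0].split("\t"))
    if first[: len(_PEAK_HEADER)] == _PEAK_HEADER:
        start = 1
    for lineno, line in enumerate(lines[start:], start=start + 1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 4:
            raise ModelIOError(f"{path.name}:{lineno}: expected 4 tab-separated columns")
        try:
            res = int(cols[0])
            dh = float(cols[2])
            dn = float(cols[3])
        except ValueError as exc:
            raise ModelIOError(f"{path.name}:{lineno}: malformed peak row") from exc
        name = cols[1].strip()
        if name.upper() in ("PRO", "P"):
            prolines.add(res)
        entries.append((res, name, dh, dn))
    return PeakList(entries=entries, prolines=frozenset(prolines))


def write_peak_list(peaks: PeakList, path: str | Path) -> None:
    path = Path(path)
    lines = ["\t".join(_PEAK_HEADER)]
    for res, name, dh, dn in peaks.entries:
        lines.append(f"{res}\t{name}\t{dh:.4f}\t{dn:.4f}")
    path.write_text("\n".join(lines) + "\n")


def read_fasta(path: str | Path) -> list[RnaSequence]:
    """Read FASTA records as RNA sequences (DNA T normalized to U)."""
    from Bio import SeqIO

    path = Path(path)
    seqs = [
        RnaSequence(id=rec.id or "unnamed", bases=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not seqs:
        raise ModelIOError(f"{path.name}: no FASTA records")
    return seqs
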