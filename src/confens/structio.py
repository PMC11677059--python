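"""Structure, ensemble and energy-log I/O plus simple structure editing.

Reads and writes fixed-column PDB files (v3.3 columns, single- and
multi-model), parses two-column time/energy text tables in the XVG dialect
(``#``/``@`` comment and directive lines), performs alanine substitution and
C-terminal truncation, and detects covalent disulfide bridges from Sγ–Sγ
distances.

Length unit is Å throughout (PDB convention); energies are kJ/mol.
Residues are always identified by the author-assigned ``(chain_id, res_seq)``
pair, never by a sequential index, so residue numbers from the literature
(e.g. Cys-262/Cys-310) are usable verbatim.
"""

from __future__ import annotations

import gzip
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Atom",
    "StructureModel",
    "Ensemble",
    "EnergyLog",
    "DisulfideBond",
    "PDBParseError",
    "MultiModelError",
    "EnsembleMismatchError",
    "EnergyLogError",
    "ResidueNotFoundError",
    "UnsupportedMutationError",
    "read_pdb",
    "read_ensemble_pdb",
    "write_pdb",
    "write_ensemble_pdb",
    "read_energy_log",
    "mutate_to_alanine",
    "delete_cterminal",
    "detect_disulfides",
]


class PDBParseError(ValueError):
    """Malformed ATOM/HETATM record; message carries the 1-based line number."""


class MultiModelError(ValueError):
    """Single-model reader given a multi-model file (use read_ensemble_pdb)."""


class EnsembleMismatchError(ValueError):
    """Atom count/name mismatch between models of a multi-model file."""


class EnergyLogError(ValueError):
    """Empty or malformed energy log."""


class ResidueNotFoundError(KeyError):
    """Requested (chain_id, res_seq) residue does not exist."""


class UnsupportedMutationError(ValueError):
    """Mutation target cannot be converted (e.g. GLY to ALA)."""


# Heavy/H atoms retained by an alanine substitution: backbone plus CB.
_ALA_KEEP = {"N", "CA", "C", "O", "CB", "OXT", "H", "HA", "H1", "H2", "H3"}

STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


@dataclass(frozen=True)
class Atom:
    serial: int
    name: str
    element: str
    res_seq: int
    res_name: str
    chain_id: str
    coords: np.ndarray  # shape (3,), Å

    def __post_init__(self):
        c = np.asarray(self.coords, dtype=float)
        if c.shape != (3,) or not np.all(np.isfinite(c)):
            raise ValueError(f"atom {self.name}: coords must be a finite 3-vector")
        object.__setattr__(self, "coords", c)


@dataclass
class StructureModel:
    """An ordered collection of atoms with author residue numbering."""

    atoms: list[Atom] = field(default_factory=list)

    @property
    def residues(self) -> list[tuple[str, int, str]]:
        seen: dict[tuple[str, int], str] = {}
        order: list[tuple[str, int, str]] = []
        for a in self.atoms:
            key = (a.chain_id, a.res_seq)
            if key not in seen:
                seen[key] = a.res_name
                order.append((a.chain_id, a.res_seq, a.res_name))
        return order

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray) -> "StructureModel":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape does not match atom count")
        return StructureModel(
            [replace(a, coords=coords[i]) for i, a in enumerate(self.atoms)]
        )

    def atom_index(self, chain_id: str, res_seq: int, name: str) -> int:
        for i, a in enumerate(self.atoms):
            if a.chain_id == chain_id and a.res_seq == res_seq and a.name == name:
                return i
        raise ResidueNotFoundError((chain_id, res_seq, name))

    def get_atom(self, chain_id: str, res_seq: int, name: str) -> Atom:
        return self.atoms[self.atom_index(chain_id, res_seq, name)]

    def residue_atoms(self, chain_id: str, res_seq: int) -> list[Atom]:
        out = [a for a in self.atoms
               if a.chain_id == chain_id and a.res_seq == res_seq]
        if not out:
            raise ResidueNotFoundError((chain_id, res_seq))
        return out


@dataclass
class Ensemble:
    """Coordinate frames sharing one topology, with optional per-frame energies."""

    topology: StructureModel
    frames: list[np.ndarray]
    frame_times: list[float] | None = None  # ps
    energies: list[float] | None = None  # kJ/mol

    def __post_init__(self):
        n_atoms = len(self.topology.atoms)
        self.frames = [np.asarray(f, dtype=float) for f in self.frames]
        for i, f in enumerate(self.frames):
            if f.shape != (n_atoms, 3):
                raise EnsembleMismatchError(
                    f"frame {i}: expected {n_atoms} atom coordinates, got {f.shape}"
                )
        if self.energies is not None and len(self.energies) != len(self.frames):
            raise EnsembleMismatchError(
                "energies length does not match frame count"
            )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def frame_model(self, i: int) -> StructureModel:
        return self.topology.with_coords(self.frames[i])


@dataclass
class EnergyLog:
    times: list[float]  # ps
    values: list[float]  # kJ/mol
    label: str = ""

    def __post_init__(self):
        if len(self.times) != len(self.values):
            raise EnergyLogError("times and values must have equal length")
        if any(b < a for a, b in zip(self.times, self.times[1:])):
            raise EnergyLogError("times must be non-decreasing")


@dataclass(frozen=True)
class DisulfideBond:
    cys_a: tuple[str, int]
    cys_b: tuple[str, int]
    sg_distance: float  # Å


def _open_text(path):
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _parse_atom_line(line: str, lineno: int) -> tuple[Atom, str, float, str]:
    """Parse one ATOM/HETATM record -> (atom, altloc, occupancy, icode)."""
    if len(line.rstrip("\n")) < 54:
        raise PDBParseError(
            f"line {lineno}: ATOM record too short for coordinate columns"
        )
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        altloc = line[16]
        res_name = line[17:20].strip()
        chain_id = line[21]
        res_seq = int(line[22:26])
        icode = line[26]
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError as exc:
        raise PDBParseError(f"line {lineno}: malformed ATOM record ({exc})") from None
    occ_field = line[54:60].strip()
    occupancy = float(occ_field) if occ_field else 1.0
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        # PDB column disambiguation: strip leading digits of the name field,
        # then take the leading alphabetic run ("1HG1" -> H, "CA" -> C...).
        stripped = name.lstrip("0123456789")
        element = stripped[:1].upper() if stripped else "X"
        if stripped[:2].upper() in ("CL", "BR", "FE", "ZN", "MG", "NA", "MN"):
            element = stripped[:2].capitalize()
    atom = Atom(serial, name, element, res_seq, res_name, chain_id,
                np.array([x, y, z]))
    return atom, altloc, occupancy, icode


def _resolve_altlocs(records: list[tuple[Atom, str, float]]) -> list[Atom]:
    """Keep the highest-occupancy conformer per (chain, res_seq, name); tie -> first."""
    best: dict[tuple[str, int, str], tuple[float, int, Atom]] = {}
    order: list[tuple[str, int, str]] = []
    for i, (atom, altloc, occ) in enumerate(records):
        key = (atom.chain_id, atom.res_seq, atom.name)
        if key not in best:
            best[key] = (occ, i, atom)
            order.append(key)
        elif occ > best[key][0]:
            best[key] = (occ, i, atom)
    return [best[k][2] for k in order]


def _read_pdb_models(path) -> list[list[tuple[Atom, str, float]]]:
    models: list[list[tuple[Atom, str, float]]] = []
    current: list[tuple[Atom, str, float]] = []
    in_model = False
    saw_model_record = False
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                saw_model_record = True
                in_model = True
                current = []
            elif rec == "ENDMDL":
                in_model = False
                models.append(current)
                current = []
            elif rec in ("ATOM  ", "HETATM"):
                atom, altloc, occ, icode = _parse_atom_line(line, lineno)
                if icode != " ":
                    raise PDBParseError(
                        f"line {lineno}: insertion codes are not supported"
                    )
                current.append((atom, altloc, occ))
    if current:
        models.append(current)
    if not models or all(not m for m in models):
        raise PDBParseError("no ATOM/HETATM records found")
    if not saw_model_record:
        models = [m for m in models if m]
    return models


def read_pdb(path) -> StructureModel:
    """Read a single-model PDB file (plain or gzipped).

    Alternate locations are resolved to the highest-occupancy conformer
    (ties keep the first). Files with more than one MODEL block raise
    :class:`MultiModelError` directing the caller to
    :func:`read_ensemble_pdb`.
    """
    models = _read_pdb_models(path)
    if len(models) > 1:
        raise MultiModelError(
            f"{path} contains {len(models)} models; use read_ensemble_pdb"
        )
    return StructureModel(_resolve_altlocs(models[0]))


def read_ensemble_pdb(path) -> Ensemble:
    """Read a multi-model PDB as an Ensemble (topology = first model)."""
    models = _read_pdb_models(path)
    resolved = [_resolve_altlocs(m) for m in models]
    top = StructureModel(resolved[0])
    ref_names = [(a.chain_id, a.res_seq, a.name) for a in top.atoms]
    frames = []
    for idx, atoms in enumerate(resolved):
        names = [(a.chain_id, a.res_seq, a.name) for a in atoms]
        if names != ref_names:
            raise EnsembleMismatchError(
                f"model {idx + 1}: atom set differs from model 1"
            )
        frames.append(np.array([a.coords for a in atoms]))
    return Ensemble(topology=top, frames=frames)


def _format_atom_line(a: Atom, serial: int) -> str:
    name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
    return (
        f"ATOM  {serial:5d} {name:<4.4s} {a.res_name:<3s} {a.chain_id}"
        f"{a.res_seq:4d}    {a.coords[0]:8.3f}{a.coords[1]:8.3f}"
        f"{a.coords[2]:8.3f}{1.0:6.2f}{0.0:6.2f}          "
        f"{a.element:>2.2s}\n"
    )


def write_pdb(model: StructureModel, path) -> None:
    with open(path, "w") as fh:
        for i, a in enumerate(model.atoms, start=1):
            fh.write(_format_atom_line(a, i))
        fh.write("END\n")


def write_ensemble_pdb(ens: Ensemble, path) -> None:
    with open(path, "w") as fh:
        for m, frame in enumerate(ens.frames, start=1):
            fh.write(f"MODEL     {m:4d}\n")
            for i, a in enumerate(ens.topology.atoms, start=1):
                fh.write(_format_atom_line(replace(a, coords=frame[i - 1]), i))
            fh.write("ENDMDL\n")
        fh.write("END\n")


def read_energy_log(path) -> EnergyLog:
    """Read a two-column time/energy table in the XVG dialect.

    Lines starting with ``#`` or ``@`` are comments/directives and are
    skipped, except ``@ s0 legend "..."`` which sets the log label. Data
    rows must have at least two whitespace-separated numeric columns;
    extra columns are ignored.
    """
    times: list[float] = []
    values: list[float] = []
    label = ""
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("#"):
                continue
            if stripped.startswith("@"):
                if stripped.startswith("@ s0 legend"):
                    part = stripped[len("@ s0 legend"):].strip()
                    label = part.strip('"')
                continue
            cols = stripped.split()
            if len(cols) < 2:
                raise EnergyLogError(
                    f"line {lineno}: expected at least 2 columns, got {len(cols)}"
                )
            try:
                t, v = float(cols[0]), float(cols[1])
            except ValueError:
                raise EnergyLogError(
                    f"line {lineno}: non-numeric value in data row"
                ) from None
            times.append(t)
            values.append(v)
    if not times:
        raise EnergyLogError(f"{path}: no numeric data rows")
    return EnergyLog(times=times, values=values, label=label)


def write_energy_log(log: EnergyLog, path) -> None:
    with open(path, "w") as fh:
        fh.write("@    title \"Potential energy\"\n")
        fh.write("@    xaxis  label \"Time (ps)\"\n")
        fh.write("@    yaxis  label \"(kJ/mol)\"\n")
        if log.label:
            fh.write(f"@ s0 legend \"{log.label}\"\n")
        for t, v in zip(log.times, log.values):
            fh.write(f"{t:12.4f} {v:14.4f}\n")


def mutate_to_alanine(model: StructureModel, chain_id: str,
                      res_seq: int) -> StructureModel:
    """Replace a residue by alanine, truncating the side chain at CB.

    Coordinates of retained atoms are unchanged; rotamer optimization is
    deliberately out of scope. Glycine (no CB) cannot be converted.
    """
    target = model.residue_atoms(chain_id, res_seq)
    res_name = target[0].res_name
    if res_name == "GLY":
        raise UnsupportedMutationError("cannot mutate GLY to ALA (no CB atom)")
    if res_name not in STANDARD_AA:
        raise UnsupportedMutationError(f"{res_name} is not a standard amino acid")
    if res_name == "ALA":
        return StructureModel(list(model.atoms))
    new_atoms = []
    for a in model.atoms:
        if a.chain_id == chain_id and a.res_seq == res_seq:
            if a.name not in _ALA_KEEP:
                continue
            a = replace(a, res_name="ALA")
        new_atoms.append(a)
    return StructureModel(new_atoms)


def delete_cterminal(model: StructureModel, first_deleted_res: int) -> StructureModel:
    """Remove every residue with res_seq >= first_deleted_res.

    Emulates C-terminal truncation constructs (e.g. removing residues
    305-313 of a 313-residue chain). Refuses to leave fewer than 3
    residues, below which backbone torsions are undefined.
    """
    kept = [a for a in model.atoms if a.res_seq < first_deleted_res]
    n_kept_res = len({(a.chain_id, a.res_seq) for a in kept})
    if len(kept) == len(model.atoms):
        return StructureModel(list(model.atoms))
    if n_kept_res < 3:
        raise ValueError(
            f"deletion from residue {first_deleted_res} would leave "
            f"{n_kept_res} residues; at least 3 required"
        )
    return StructureModel(kept)


def detect_disulfides(model: StructureModel, cutoff: float = 2.3
                      ) -> list[DisulfideBond]:
    """Detect disulfide bridges from cysteine Sγ–Sγ distances.

    All CYS SG pairs within ``cutoff`` (default 2.3 Å: a typical S–S bond
    of ~2.05 Å plus tolerance) are candidates; each cysteine joins at most
    one bond — when several partners are in range the shortest wins and a
    warning is emitted.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    sgs = [a for a in model.atoms if a.res_name == "CYS" and a.name == "SG"]
    pairs = []
    for i in range(len(sgs)):
        for j in range(i + 1, len(sgs)):
            a, b = sgs[i], sgs[j]
            if (a.chain_id, a.res_seq) == (b.chain_id, b.res_seq):
                continue
            d = float(np.linalg.norm(a.coords - b.coords))
            if d <= cutoff:
                pairs.append((d, a, b))
    pairs.sort(key=lambda p: p[0])
    used: set[tuple[str, int]] = set()
    bonds = []
    conflict = False
    for d, a, b in pairs:
        ka, kb = (a.chain_id, a.res_seq), (b.chain_id, b.res_seq)
        if ka in used or kb in used:
            conflict = True
            continue
        used.update((ka, kb))
        key_a, key_b = sorted([ka, kb], key=lambda k: (k[0], k[1]))
        bonds.append(DisulfideBond(cys_a=key_a, cys_b=key_b, sg_distance=d))
    if conflict:
        warnings.warn(
            "cysteine with multiple disulfide partners within cutoff; "
            "kept the shortest bond", stacklevel=2,
        )
    bonds.sort(key=lambda b: (b.cys_a[1], b.cys_b[1]))
    return bonds
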