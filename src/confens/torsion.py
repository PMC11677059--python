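"""Dihedral angles and torsion-record extraction from ensembles.

The backbone torsions φ, ψ, ω describe the peptide-chain conformation; the
side-chain torsions χ₁–χ₄ describe rotamer states. Two angle collections are
used downstream: Set I (φ/ψ/ω only, backbone conformation) and Set II
(Set I plus all χₙ, the full molecular conformation). ω(i) is assigned to
the residue C-terminal to the peptide bond, i.e. ω(i) uses
CA(i−1)-C(i−1)-N(i)-CA(i); conventions differ, so this is stated explicitly.

Dihedrals follow the IUPAC sign convention (cis = 0°, trans = 180°) with
values in (−180°, +180°].
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .structio import Ensemble, StructureModel

__all__ = [
    "TorsionRecord",
    "AngleSet",
    "UndefinedDihedralError",
    "dihedral",
    "extract_torsions",
    "chi_table",
    "SYMMETRIC_CHI",
]

BACKBONE_ANGLES = ("phi", "psi", "omega")

#: χ angles whose terminal group is 2-fold symmetric; by default these are
#: folded into (−90°, +90°] so that chemically identical states are not
#: counted as distinct conformers (this matters for entropy estimates).
SYMMETRIC_CHI = {
    ("ASP", "chi2"),
    ("GLU", "chi3"),
    ("PHE", "chi2"),
    ("TYR", "chi2"),
}

# Peptide-bond C–N distance beyond which two consecutive residues are
# treated as not covalently connected (chain break).
CHAIN_BREAK_CUTOFF = 2.5


class UndefinedDihedralError(ValueError):
    """Dihedral undefined because three consecutive points are collinear."""


@dataclass
class TorsionRecord:
    """One named dihedral time series, keyed by residue and angle name."""

    key: tuple[str, int, str]  # (chain_id, res_seq, angle_name)
    values: np.ndarray  # degrees, one per frame

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)

    @property
    def angle_name(self) -> str:
        return self.key[2]


@dataclass
class AngleSet:
    set_id: str  # "I" or "II"
    records: list[tuple[str, int, str]]


@lru_cache(maxsize=1)
def chi_table() -> dict[tuple[str, str], tuple[str, str, str, str]]:
    """Packaged χ-definition table: (res_name, angle) -> 4 atom names."""
    table: dict[tuple[str, str], tuple[str, str, str, str]] = {}
    ref = importlib.resources.files("confens").joinpath("data/chi_atoms.tsv")
    for line in ref.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        res, angle, a1, a2, a3, a4 = line.split("\t")
        table[(res, angle)] = (a1, a2, a3, a4)
    return table


def _dihedral_arrays(p1, p2, p3, p4):
    """Vectorized signed dihedral (degrees) for (..., 3) point arrays."""
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2, axis=-1)
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(np.cross(n1, n2) * b2, axis=-1) / np.where(b2n == 0, 1.0, b2n)
    ang = np.degrees(np.arctan2(y, x))
    # map −180 to +180 so the range is (−180, +180]
    return np.where(ang <= -180.0, ang + 360.0, ang)


def dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle of four points, IUPAC convention, degrees.

    cis = 0°, trans = 180°, range (−180°, +180°]. Swapping p1↔p4 and
    p2↔p3 flips the sign (except at exactly 180°). Raises
    :class:`UndefinedDihedralError` when p1p2p3 or p2p3p4 are collinear.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    if np.linalg.norm(b2) < 1e-12:
        raise UndefinedDihedralError("p2 and p3 coincide")
    scale = max(np.linalg.norm(b1), np.linalg.norm(b2), np.linalg.norm(b3))
    if (np.linalg.norm(np.cross(b1, b2)) < 1e-9 * scale**2
            or np.linalg.norm(np.cross(b2, b3)) < 1e-9 * scale**2):
        raise UndefinedDihedralError("collinear points: dihedral undefined")
    return float(_dihedral_arrays(p1, p2, p3, p4))


def fold_symmetric(values: np.ndarray) -> np.ndarray:
    """Fold a 2-fold-symmetric dihedral into (−90°, +90°]."""
    v = np.asarray(values, dtype=float) % 180.0
    return np.where(v > 90.0, v - 180.0, v)


def _stack_frames(ens: Ensemble) -> np.ndarray:
    return np.stack(ens.frames)  # (F, n_atoms, 3)


def extract_torsions(ens: Ensemble, set_id: str = "I",
                     fold_symmetric_chi: bool = True) -> list[TorsionRecord]:
    """Extract per-frame backbone (and optionally side-chain) torsions.

    Set "I" yields φ/ψ/ω records; Set "II" adds χₙ records per the packaged
    χ table. Chain-terminal angles whose defining quadruple does not exist
    are omitted (never padded); a missing backbone atom in a non-terminal
    residue omits the affected records with a warning. Consecutive residues
    whose C–N distance exceeds 2.5 Å in the topology are treated as a chain
    break (no φ/ψ/ω across the break).
    """
    if set_id not in ("I", "II"):
        raise ValueError("set_id must be 'I' or 'II'")
    top = ens.topology
    frames = _stack_frames(ens)
    residues = top.residues

    # atom index lookup per residue
    index: dict[tuple[str, int], dict[str, int]] = {}
    for i, a in enumerate(top.atoms):
        index.setdefault((a.chain_id, a.res_seq), {})[a.name] = i

    def idx(chain, res, name):
        return index.get((chain, res), {}).get(name)

    def bonded(chain, res_prev, res_next):
        ci = idx(chain, res_prev, "C")
        ni = idx(chain, res_next, "N")
        if ci is None or ni is None:
            return False
        d = np.linalg.norm(top.atoms[ci].coords - top.atoms[ni].coords)
        return d <= CHAIN_BREAK_CUTOFF

    records: list[TorsionRecord] = []
    missing_backbone: list[tuple[str, int]] = []

    by_chain: dict[str, list[tuple[int, str]]] = {}
    for chain, res_seq, res_name in residues:
        by_chain.setdefault(chain, []).append((res_seq, res_name))

    def quad_values(i1, i2, i3, i4):
        return _dihedral_arrays(frames[:, i1], frames[:, i2],
                                frames[:, i3], frames[:, i4])

    for chain, res_list in by_chain.items():
        for k, (res, res_name) in enumerate(res_list):
            n_i = idx(chain, res, "N")
            ca_i = idx(chain, res, "CA")
            c_i = idx(chain, res, "C")
            if n_i is None or ca_i is None or c_i is None:
                is_terminal = k == 0 or k == len(res_list) - 1
                if not is_terminal:
                    missing_backbone.append((chain, res))
                continue
            prev_res = res_list[k - 1][0] if k > 0 else None
            next_res = res_list[k + 1][0] if k < len(res_list) - 1 else None
            prev_ok = prev_res is not None and bonded(chain, prev_res, res)
            next_ok = next_res is not None and bonded(chain, res, next_res)

            if prev_ok:
                c_prev = idx(chain, prev_res, "C")
                ca_prev = idx(chain, prev_res, "CA")
                if c_prev is not None:
                    records.append(TorsionRecord(
                        (chain, res, "phi"),
                        quad_values(c_prev, n_i, ca_i, c_i)))
                if c_prev is not None and ca_prev is not None:
                    records.append(TorsionRecord(
                        (chain, res, "omega"),
                        quad_values(ca_prev, c_prev, n_i, ca_i)))
            if next_ok:
                n_next = idx(chain, next_res, "N")
                if n_next is not None:
                    records.append(TorsionRecord(
                        (chain, res, "psi"),
                        quad_values(n_i, ca_i, c_i, n_next)))

            if set_id == "II":
                for n_chi in range(1, 5):
                    angle = f"chi{n_chi}"
                    quad = chi_table().get((res_name, angle))
                    if quad is None:
                        continue
                    ids = [idx(chain, res, nm) for nm in quad]
                    if any(i is None for i in ids):
                        continue  # incomplete side chain: skip silently
                    vals = quad_values(*ids)
                    if fold_symmetric_chi and (res_name, angle) in SYMMETRIC_CHI:
                        vals = fold_symmetric(vals)
                    records.append(TorsionRecord((chain, res, angle), vals))

    if missing_backbone:
        warnings.warn(
            f"missing backbone atoms in non-terminal residues "
            f"{missing_backbone}; their torsion records were omitted",
            stacklevel=2,
        )
    return records


def angle_set(records: list[TorsionRecord], set_id: str) -> AngleSet:
    """Collect the record keys belonging to Set I or Set II."""
    if set_id == "I":
        keys = [r.key for r in records if r.angle_name in BACKBONE_ANGLES]
    elif set_id == "II":
        keys = [r.key for r in records]
    else:
        raise ValueError("set_id must be 'I' or 'II'")
    return AngleSet(set_id=set_id, records=keys)
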