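"""Structural-feature detection with trajectory occupancies.

Covers the machinery needed to characterize a region of a protein model
over an ensemble: geometric hydrogen-bond detection, a DSSP-style
secondary-structure assignment built on the Kabsch–Sander electrostatic
H-bond energy, geometric β-turn detection with type classification and
stability labels, and aromatic ring-stacking contacts.

Two distinct hydrogen-bond criteria coexist deliberately: a geometric
distance/angle rule (3.5 Å, 30° linearity tolerance) for site analysis,
and the Kabsch–Sander energetic rule used only inside secondary-structure
assignment. Occupancies are exact rational counts (frames present / total
frames).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .structio import Ensemble, StructureModel
from .torsion import CHAIN_BREAK_CUTOFF, _dihedral_arrays

__all__ = [
    "HBond",
    "SSAssignment",
    "BetaTurn",
    "StackingContact",
    "detect_hbonds",
    "hbond_occupancy",
    "assign_secondary_structure",
    "assign_ss_ensemble",
    "detect_beta_turns",
    "detect_stacking",
]

DEFAULT_HB_DIST = 3.5  # Å, donor-acceptor heavy-atom distance
DEFAULT_HB_ANGLE_TOL = 30.0  # degrees of deviation from linear D-H...A
KS_ENERGY_CUTOFF = -0.5  # kcal/mol, Kabsch-Sander bond threshold
DEFAULT_STACK_DIST = 5.5  # Å between ring centroids
STABLE_OCCUPANCY = 0.5

RING_ATOMS = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}

# canonical (phi_i+1, psi_i+1, phi_i+2, psi_i+2) per β-turn type
TURN_TYPES = {
    "I": (-60.0, -30.0, -90.0, 0.0),
    "I'": (60.0, 30.0, 90.0, 0.0),
    "II": (-60.0, 120.0, 80.0, 0.0),
    "II'": (60.0, -120.0, -80.0, 0.0),
    "VIII": (-60.0, -30.0, -120.0, 120.0),
}
TURN_CA_CUTOFF = 7.0  # Å between CA(i) and CA(i+3)
TURN_TOLERANCE = 30.0  # per angle, with one 45° allowance
TURN_TOLERANCE_LOOSE = 45.0


@dataclass(frozen=True)
class HBond:
    donor: tuple[tuple[str, int], str]  # ((chain, res_seq), heavy-atom name)
    acceptor: tuple[tuple[str, int], str]
    distance: float  # Å, donor-acceptor
    angle: float  # degrees D-H...A (nan in heavy-atom mode)
    occupancy: float | None = None
    n_present: int = 0
    n_frames: int = 0

    @property
    def stable(self) -> bool | None:
        if self.occupancy is None:
            return None
        return self.occupancy >= STABLE_OCCUPANCY


@dataclass
class SSAssignment:
    """Per-frame, per-residue secondary-structure codes (H/G/I/E/B/T/S/-)."""

    residue_keys: list[tuple[str, int]]
    codes: list[str]  # one string per frame, one char per residue

    def fraction(self, code: str, frame: int = 0) -> float:
        return self.codes[frame].count(code) / len(self.residue_keys)


@dataclass(frozen=True)
class BetaTurn:
    start_res: tuple[str, int]  # residue i of the i..i+3 window
    turn_type: str  # I, I', II, II', VIII, other
    occupancy: float
    stability: str  # "stable" | "unstable"
    n_present: int = 0
    n_frames: int = 0


@dataclass(frozen=True)
class StackingContact:
    res_a: tuple[str, int]
    res_b: tuple[str, int]
    centroid_distance: float  # Å, mean over frames present
    interplanar_angle: float  # degrees, mean over frames present
    geometry: str  # "parallel" | "t-shaped"
    occupancy: float = 1.0
    n_present: int = 0
    n_frames: int = 0


# ---------------------------------------------------------------------------
# residue bookkeeping


class _Residues:
    """Indexes backbone atoms per residue and chain connectivity."""

    def __init__(self, topology: StructureModel, coords: np.ndarray):
        self.coords = coords
        self.keys: list[tuple[str, int]] = []
        self.names: list[str] = []
        index: dict[tuple[str, int], dict[str, int]] = {}
        for i, a in enumerate(topology.atoms):
            key = (a.chain_id, a.res_seq)
            if key not in index:
                index[key] = {}
                self.keys.append(key)
                self.names.append(a.res_name)
            index[key][a.name] = i
        self.index = index
        self.n = len(self.keys)

    def atom(self, i: int, name: str) -> np.ndarray | None:
        j = self.index[self.keys[i]].get(name)
        return None if j is None else self.coords[j]

    def has_backbone(self, i: int) -> bool:
        names = self.index[self.keys[i]]
        return all(n in names for n in ("N", "CA", "C", "O"))

    def connected(self, i: int, j: int) -> bool:
        """j == i+1 in the same chain with a real peptide bond."""
        if j != i + 1 or j >= self.n:
            return False
        if self.keys[i][0] != self.keys[j][0]:
            return False
        c, n = self.atom(i, "C"), self.atom(j, "N")
        if c is None or n is None:
            return False
        return float(np.linalg.norm(c - n)) <= CHAIN_BREAK_CUTOFF

    def contiguous(self, lo: int, hi: int) -> bool:
        return all(self.connected(i, i + 1) for i in range(lo, hi))

    def amide_h(self, i: int) -> np.ndarray | None:
        """Explicit amide H, else reconstructed 1.0 Å from N opposite the
        preceding carbonyl; None for chain starts without an explicit H."""
        h = self.atom(i, "H")
        if h is not None:
            return h
        if self.names[i] == "PRO":
            return None
        if i == 0 or not self.connected(i - 1, i):
            return None
        n = self.atom(i, "N")
        c_prev, o_prev = self.atom(i - 1, "C"), self.atom(i - 1, "O")
        if n is None or c_prev is None or o_prev is None:
            return None
        d = c_prev - o_prev
        norm = np.linalg.norm(d)
        if norm < 1e-9:
            return None
        return n + d / norm


def _frame_coords(obj, frame) -> tuple[StructureModel, np.ndarray]:
    if isinstance(obj, Ensemble):
        return obj.topology, np.asarray(obj.frames[frame])
    if frame is None:
        return obj, obj.coords
    return obj, np.asarray(frame)


# ---------------------------------------------------------------------------
# geometric hydrogen bonds


def _attached_hydrogens(topology: StructureModel, coords: np.ndarray,
                        heavy_idx: int) -> list[int]:
    heavy = coords[heavy_idx]
    out = []
    a0 = topology.atoms[heavy_idx]
    for i, a in enumerate(topology.atoms):
        if a.element != "H":
            continue
        if (a.chain_id, a.res_seq) != (a0.chain_id, a0.res_seq):
            continue
        if np.linalg.norm(coords[i] - heavy) <= 1.25:
            out.append(i)
    return out


def detect_hbonds(frame, topology: StructureModel | None = None,
                  d_cut: float = DEFAULT_HB_DIST,
                  a_cut: float = DEFAULT_HB_ANGLE_TOL) -> list[HBond]:
    """Geometric hydrogen-bond detection in one frame.

    Donors and acceptors are N/O heavy atoms. With hydrogens present, a
    bond requires donor–acceptor distance ≤ d_cut and D–H···A angle ≥
    180° − a_cut; without hydrogens, the distance criterion alone is used.
    Pairs within the same residue and the trivially close peptide-bond
    pair N(i+1)···O(i) are excluded. ``frame`` may be a StructureModel or
    a coordinate array paired with ``topology``.
    """
    if isinstance(frame, StructureModel):
        topology, coords = frame, frame.coords
    else:
        if topology is None:
            raise ValueError("topology required when frame is a coordinate array")
        coords = np.asarray(frame, dtype=float)
    res = _Residues(topology, coords)
    have_h = any(a.element == "H" for a in topology.atoms)

    polar = [i for i, a in enumerate(topology.atoms) if a.element in ("N", "O")]
    res_of = {i: (topology.atoms[i].chain_id, topology.atoms[i].res_seq)
              for i in polar}
    res_pos = {k: p for p, k in enumerate(res.keys)}

    bonds = []
    for di in polar:
        d_atom = topology.atoms[di]
        if have_h:
            h_idx = _attached_hydrogens(topology, coords, di)
            if not h_idx:
                continue
        for ai in polar:
            if ai == di:
                continue
            if not have_h and ai < di:
                continue  # heavy-atom mode is directionless: pair once
            a_atom = topology.atoms[ai]
            if res_of[di] == res_of[ai]:
                continue
            # peptide-bond adjacency: amide N is 2 covalent bonds from the
            # preceding carbonyl O; never a hydrogen bond
            pd, pa = res_pos[res_of[di]], res_pos[res_of[ai]]
            if (d_atom.name == "N" and a_atom.name == "O"
                    and pa == pd - 1 and res.connected(pa, pd)):
                continue
            dist = float(np.linalg.norm(coords[di] - coords[ai]))
            if dist > d_cut:
                continue
            if have_h:
                best = None
                for hi in h_idx:
                    v1 = coords[di] - coords[hi]
                    v2 = coords[ai] - coords[hi]
                    cosang = np.dot(v1, v2) / (
                        np.linalg.norm(v1) * np.linalg.norm(v2))
                    ang = float(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
                    if best is None or ang > best:
                        best = ang
                if best is None or best < 180.0 - a_cut:
                    continue
                angle = best
            else:
                angle = float("nan")
            bonds.append(HBond(
                donor=(res_of[di], d_atom.name),
                acceptor=(res_of[ai], a_atom.name),
                distance=dist, angle=angle,
            ))
    bonds.sort(key=lambda b: (b.donor[0][0], b.donor[0][1], b.donor[1],
                              b.acceptor[0][1], b.acceptor[1]))
    return bonds


def hbond_occupancy(ens: Ensemble, d_cut: float = DEFAULT_HB_DIST,
                    a_cut: float = DEFAULT_HB_ANGLE_TOL,
                    stable_threshold: float = STABLE_OCCUPANCY
                    ) -> list[HBond]:
    """Union of per-frame H-bonds with per-bond occupancy fractions."""
    if ens.n_frames < 2:
        raise ValueError("occupancy requires at least 2 frames")
    seen: dict[tuple, list[HBond]] = {}
    for f in range(ens.n_frames):
        for b in detect_hbonds(ens.frames[f], ens.topology, d_cut, a_cut):
            seen.setdefault((b.donor, b.acceptor), []).append(b)
    out = []
    for (donor, acceptor), hits in seen.items():
        occ = len(hits) / ens.n_frames
        out.append(HBond(
            donor=donor, acceptor=acceptor,
            distance=float(np.mean([b.distance for b in hits])),
            angle=float(np.mean([b.angle for b in hits])),
            occupancy=occ, n_present=len(hits), n_frames=ens.n_frames,
        ))
    out.sort(key=lambda b: (b.donor[0][0], b.donor[0][1], b.donor[1],
                            b.acceptor[0][1], b.acceptor[1]))
    return out


# ---------------------------------------------------------------------------
# DSSP-style secondary structure


def _ks_hbond_matrix(res: _Residues) -> np.ndarray:
    """hb[d, a]: Kabsch–Sander bond from donor d's amide to acceptor a's
    carbonyl; E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol,
    bond iff E < −0.5."""
    n = res.n
    hb = np.zeros((n, n), dtype=bool)
    ca = np.array([
        res.atom(i, "CA") if res.atom(i, "CA") is not None else [1e6] * 3
        for i in range(n)
    ])
    for d in range(n):
        nd = res.atom(d, "N")
        hd = res.amide_h(d)
        if nd is None or hd is None:
            continue
        for a in range(n):
            if a == d or a == d - 1:
                continue
            if np.linalg.norm(ca[d] - ca[a]) > 9.0:
                continue
            c, o = res.atom(a, "C"), res.atom(a, "O")
            if c is None or o is None:
                continue
            r_on = np.linalg.norm(o - nd)
            r_ch = np.linalg.norm(c - hd)
            r_oh = np.linalg.norm(o - hd)
            r_cn = np.linalg.norm(c - nd)
            if min(r_on, r_ch, r_oh, r_cn) < 0.5:
                continue  # clash: treat as no bond
            e = 0.084 * 332.0 * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn)
            if e < KS_ENERGY_CUTOFF:
                hb[d, a] = True
    return hb


def assign_secondary_structure(frame, topology: StructureModel | None = None
                               ) -> SSAssignment:
    """DSSP-style secondary-structure codes for one frame.

    Implements the Kabsch–Sander core: electrostatic H-bond energy,
    n-turns (3/4/5 → G/H/I), bridge/ladder detection (B/E), H-bonded
    turns (T) and bends (S), with assignment priority
    H > E > G > I > B > T > S > '-'. Residues with missing backbone atoms
    are assigned '-' with a warning. Amide hydrogens are reconstructed
    geometrically when absent.
    """
    if isinstance(frame, StructureModel):
        topology, coords = frame, frame.coords
    else:
        if topology is None:
            raise ValueError("topology required when frame is a coordinate array")
        coords = np.asarray(frame, dtype=float)
    res = _Residues(topology, coords)
    n = res.n
    incomplete = [i for i in range(n) if not res.has_backbone(i)]
    if incomplete:
        warnings.warn(
            f"residues {[res.keys[i] for i in incomplete]} missing backbone "
            "atoms; assigned '-'", stacklevel=2,
        )
    hb = _ks_hbond_matrix(res)

    def hbond(acc: int, don: int) -> bool:
        # Kabsch–Sander notation Hbond(i, j): CO of i accepts from NH of j
        return hb[don, acc]

    turns = {k: np.zeros(n, dtype=bool) for k in (3, 4, 5)}
    for k in (3, 4, 5):
        for i in range(n - k):
            if res.contiguous(i, i + k) and hbond(i, i + k):
                turns[k][i] = True

    helix = {"H": np.zeros(n, bool), "G": np.zeros(n, bool),
             "I": np.zeros(n, bool)}
    for code, k in (("G", 3), ("H", 4), ("I", 5)):
        for i in range(1, n - k):
            if turns[k][i - 1] and turns[k][i]:
                helix[code][i:i + k] = True

    # bridges
    bridges: list[tuple[int, int, str]] = []
    for i in range(1, n - 1):
        if not (res.connected(i - 1, i) and res.connected(i, i + 1)):
            continue
        for j in range(i + 3, n - 1):
            if not (res.connected(j - 1, j) and res.connected(j, j + 1)):
                continue
            para = ((hbond(i - 1, j) and hbond(j, i + 1))
                    or (hbond(j - 1, i) and hbond(i, j + 1)))
            anti = ((hbond(i, j) and hbond(j, i))
                    or (hbond(i - 1, j + 1) and hbond(j - 1, i + 1)))
            if para:
                bridges.append((i, j, "P"))
            elif anti:
                bridges.append((i, j, "A"))

    in_ladder = np.zeros(n, bool)
    lone_bridge = np.zeros(n, bool)
    bridge_set = set(bridges)
    for i, j, t in bridges:
        step = 1 if t == "P" else -1
        extends = ((i + 1, j + step, t) in bridge_set
                   or (i - 1, j - step, t) in bridge_set)
        if extends:
            in_ladder[i] = in_ladder[j] = True
        else:
            lone_bridge[i] = lone_bridge[j] = True

    turn_t = np.zeros(n, bool)
    for k in (3, 4, 5):
        for i in np.flatnonzero(turns[k]):
            turn_t[i + 1:i + k] = True

    bend = np.zeros(n, bool)
    for i in range(2, n - 2):
        if not res.contiguous(i - 2, i + 2):
            continue
        ca = [res.atom(j, "CA") for j in (i - 2, i, i + 2)]
        if any(c is None for c in ca):
            continue
        v1 = ca[1] - ca[0]
        v2 = ca[2] - ca[1]
        cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        if np.degrees(np.arccos(np.clip(cosang, -1, 1))) > 70.0:
            bend[i] = True

    codes = []
    for i in range(n):
        if i in incomplete:
            codes.append("-")
        elif helix["H"][i]:
            codes.append("H")
        elif in_ladder[i]:
            codes.append("E")
        elif helix["G"][i]:
            codes.append("G")
        elif helix["I"][i]:
            codes.append("I")
        elif lone_bridge[i]:
            codes.append("B")
        elif turn_t[i]:
            codes.append("T")
        elif bend[i]:
            codes.append("S")
        else:
            codes.append("-")
    return SSAssignment(residue_keys=res.keys, codes=["".join(codes)])


def assign_ss_ensemble(ens: Ensemble) -> SSAssignment:
    """Per-frame secondary-structure strings for an ensemble."""
    per_frame = []
    keys = None
    with warnings.catch_warnings():
        warnings.simplefilter("once")
        for f in range(ens.n_frames):
            ss = assign_secondary_structure(ens.frames[f], ens.topology)
            per_frame.append(ss.codes[0])
            keys = ss.residue_keys
    return SSAssignment(residue_keys=keys, codes=per_frame)


# ---------------------------------------------------------------------------
# β-turns


def _circular_diff(a: float, b: float) -> float:
    return abs((a - b + 180.0) % 360.0 - 180.0)


def _classify_turn(phi1, psi1, phi2, psi2) -> str:
    for name, (c1, c2, c3, c4) in TURN_TYPES.items():
        diffs = [
            _circular_diff(phi1, c1), _circular_diff(psi1, c2),
            _circular_diff(phi2, c3), _circular_diff(psi2, c4),
        ]
        n_loose = sum(d > TURN_TOLERANCE for d in diffs)
        if max(diffs) <= TURN_TOLERANCE_LOOSE and n_loose <= 1:
            return name
    return "other"


def detect_beta_turns(ens: Ensemble,
                      stable_threshold: float = STABLE_OCCUPANCY
                      ) -> list[BetaTurn]:
    """Four-residue chain reversals with type classification and occupancy.

    Per frame, residues i..i+3 form a turn iff Cα(i)–Cα(i+3) ≤ 7 Å and
    residues i+1, i+2 are not both helical (H/G/I). Types are assigned
    from the central residues' (φ, ψ) against canonical values (±30° with
    one 45° allowance), otherwise "other". A turn is stable iff its
    occupancy over frames is ≥ ``stable_threshold``.
    """
    top = ens.topology
    n_frames = ens.n_frames
    ss = assign_ss_ensemble(ens)
    res0 = _Residues(top, np.asarray(ens.frames[0]))
    n = res0.n

    frames = np.stack(ens.frames)

    def phi_psi(frame_coords, res: _Residues, i):
        c_prev = res.atom(i - 1, "C")
        ni, cai, ci = res.atom(i, "N"), res.atom(i, "CA"), res.atom(i, "C")
        n_next = res.atom(i + 1, "N")
        if any(x is None for x in (c_prev, ni, cai, ci, n_next)):
            return None
        phi = float(_dihedral_arrays(c_prev, ni, cai, ci))
        psi = float(_dihedral_arrays(ni, cai, ci, n_next))
        return phi, psi

    results = []
    for i in range(n - 3):
        if not res0.contiguous(i, i + 3):
            continue
        present = 0
        types: Counter = Counter()
        for f in range(n_frames):
            res = _Residues(top, frames[f])
            ca_i, ca_i3 = res.atom(i, "CA"), res.atom(i + 3, "CA")
            if ca_i is None or ca_i3 is None:
                continue
            if np.linalg.norm(ca_i - ca_i3) > TURN_CA_CUTOFF:
                continue
            s = ss.codes[f]
            if s[i + 1] in "HGI" and s[i + 2] in "HGI":
                continue
            present += 1
            pp1 = phi_psi(frames[f], res, i + 1)
            pp2 = phi_psi(frames[f], res, i + 2)
            if pp1 is None or pp2 is None:
                types["other"] += 1
            else:
                types[_classify_turn(pp1[0], pp1[1], pp2[0], pp2[1])] += 1
        if present == 0:
            continue
        occ = present / n_frames
        results.append(BetaTurn(
            start_res=res0.keys[i],
            turn_type=types.most_common(1)[0][0],
            occupancy=occ,
            stability="stable" if occ >= stable_threshold else "unstable",
            n_present=present, n_frames=n_frames,
        ))
    return results


# ---------------------------------------------------------------------------
# aromatic stacking


def detect_stacking(ens: Ensemble, d_cut: float = DEFAULT_STACK_DIST
                    ) -> list[StackingContact]:
    """Aromatic ring-stacking contacts with occupancy over frames.

    A contact exists in a frame when the ring-centroid distance is ≤
    ``d_cut`` and the interplanar angle is ≤ 30° (parallel stacking) or
    ≥ 60° (T-shaped). The reported geometry class is the majority class
    over the frames in which the contact is present.
    """
    top = ens.topology
    res0 = _Residues(top, np.asarray(ens.frames[0]))
    aromatic = [i for i in range(res0.n) if res0.names[i] in RING_ATOMS]

    def ring(res: _Residues, i):
        atoms = [res.atom(i, nm) for nm in RING_ATOMS[res.names[i]]]
        if any(a is None for a in atoms):
            return None
        pts = np.array(atoms)
        centroid = pts.mean(axis=0)
        _, _, vt = np.linalg.svd(pts - centroid)
        return centroid, vt[2]  # plane normal = smallest singular vector

    hits: dict[tuple, list[tuple[float, float, str]]] = {}
    for f in range(ens.n_frames):
        res = _Residues(top, np.asarray(ens.frames[f]))
        rings = {i: ring(res, i) for i in aromatic}
        for ii in range(len(aromatic)):
            for jj in range(ii + 1, len(aromatic)):
                a, b = aromatic[ii], aromatic[jj]
                ra, rb = rings[a], rings[b]
                if ra is None or rb is None:
                    continue
                dist = float(np.linalg.norm(ra[0] - rb[0]))
                if dist > d_cut:
                    continue
                cosang = abs(float(np.dot(ra[1], rb[1])))
                angle = float(np.degrees(np.arccos(np.clip(cosang, 0, 1))))
                if angle <= 30.0:
                    cls = "parallel"
                elif angle >= 60.0:
                    cls = "t-shaped"
                else:
                    continue
                hits.setdefault((res0.keys[a], res0.keys[b]), []).append(
                    (dist, angle, cls))
    out = []
    for (ka, kb), obs in hits.items():
        cls = Counter(o[2] for o in obs).most_common(1)[0][0]
        out.append(StackingContact(
            res_a=ka, res_b=kb,
            centroid_distance=float(np.mean([o[0] for o in obs])),
            interplanar_angle=float(np.mean([o[1] for o in obs])),
            geometry=cls,
            occupancy=len(obs) / ens.n_frames,
            n_present=len(obs), n_frames=ens.n_frames,
        ))
    out.sort(key=lambda c: (c.res_a[0], c.res_a[1], c.res_b[1]))
    return out
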