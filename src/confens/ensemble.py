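"""Superposition, RMSF profiles, mobility-region calling and clustering.

RMSF (root-mean-square fluctuation) of Cα atoms around the ensemble-mean
structure is the per-residue mobility measure; comparative calling finds
contiguous residue runs where a mutant ensemble's RMSF reproducibly exceeds
a reference (e.g. a wild-type protein vs. a C-terminal deletion construct).
Conformational clustering follows the GROMOS most-neighbors rule: the frame
with the most neighbors within an RMSD cutoff repeatedly becomes a cluster
center, and it and its neighbors are removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structio import Ensemble

__all__ = [
    "RMSFProfile",
    "MobilityCall",
    "MobilityParams",
    "ClusterResult",
    "DegenerateSuperpositionError",
    "kabsch_superpose",
    "apply_transform",
    "rmsf",
    "call_mobility_regions",
    "cluster_gromos",
]


class DegenerateSuperpositionError(ValueError):
    """Fewer than 3 points, or all points collinear."""


@dataclass
class RMSFProfile:
    residue_keys: list[tuple[str, int]]
    values: np.ndarray  # Å, one per residue with a CA atom
    replica_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.residue_keys) != self.values.size:
            raise ValueError("one RMSF value per residue key required")
        if np.any(self.values < 0):
            raise ValueError("RMSF values must be non-negative")


@dataclass(frozen=True)
class MobilityCall:
    start_res: int
    end_res: int  # inclusive
    delta: float  # mean RMSF excess over the run, Å
    reproducibility: float  # fraction of (ref, alt) replica pairs supporting


@dataclass(frozen=True)
class MobilityParams:
    """Thresholds for comparative mobility calling.

    A residue is "elevated" when the mean RMSF excess of the alternative
    condition exceeds max(abs_floor, k × pooled inter-replica SD); elevated
    residues are merged into runs tolerating ``gap_tol`` interruptions, and
    runs shorter than ``min_len`` residues are dropped. Defaults are sized
    so that ~10–20-residue mobility regions of a few tenths of an Å stand
    out against replica noise. One-sided (increases only) unless
    ``two_sided``.
    """

    abs_floor: float = 0.2  # Å
    k: float = 1.0
    min_len: int = 4
    gap_tol: int = 1
    two_sided: bool = False


@dataclass
class ClusterResult:
    assignments: np.ndarray  # frame -> cluster id (0-based, by size)
    centers: list[int]  # frame index of each cluster's center
    cutoff: float  # Å
    sizes: list[int] = field(default_factory=list)


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray,
                     weights: np.ndarray | None = None
                     ) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares optimal rigid superposition (Kabsch, SVD form).

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best fits ``reference``. The
    rotation is proper (determinant +1; the reflection branch of the SVD is
    corrected). ``rmsd`` is the post-fit value.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must both be (N, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise DegenerateSuperpositionError("need at least 3 points")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        w = w / w.sum()
    mc = (w[:, None] * mobile).sum(axis=0)
    rc = (w[:, None] * reference).sum(axis=0)
    m0 = mobile - mc
    r0 = reference - rc
    sv_m = np.linalg.svd(m0 * np.sqrt(w)[:, None], compute_uv=False)
    if sv_m[1] < 1e-9 * max(sv_m[0], 1.0):
        raise DegenerateSuperpositionError("points are collinear")
    h = (w[:, None] * m0).T @ r0
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = rc - rot @ mc
    fitted = m0 @ rot.T + rc
    rmsd = float(np.sqrt((w * ((fitted - reference) ** 2).sum(axis=1)).sum()))
    return rot, trans, rmsd


def apply_transform(coords: np.ndarray, rotation: np.ndarray,
                    translation: np.ndarray) -> np.ndarray:
    return np.asarray(coords) @ rotation.T + translation


def _ca_indices(ens: Ensemble, selection: str = "CA"
                ) -> tuple[list[int], list[tuple[str, int]]]:
    idx, keys = [], []
    for i, a in enumerate(ens.topology.atoms):
        if a.name == selection:
            idx.append(i)
            keys.append((a.chain_id, a.res_seq))
    if not idx:
        raise ValueError(f"no '{selection}' atoms in topology")
    return idx, keys


def _mean_superposed(frames: np.ndarray, sel: list[int],
                     n_iter: int = 2) -> np.ndarray:
    """Superpose frames (on the selection) and return them fitted.

    Reference is the ensemble mean, refined iteratively: fit everything to
    frame 0, take the mean, then re-fit to the mean (``n_iter`` rounds).
    """
    fitted = frames.copy()
    reference = frames[0][sel]
    for _ in range(n_iter):
        for f in range(fitted.shape[0]):
            rot, trans, _ = kabsch_superpose(fitted[f][sel], reference)
            fitted[f] = apply_transform(fitted[f], rot, trans)
        reference = fitted[:, sel].mean(axis=0)
    return fitted


def rmsf(ens: Ensemble, selection: str = "CA", replica_id: str = ""
         ) -> RMSFProfile:
    """Per-residue RMSF of the selection after mean-structure superposition.

    RMSF(i) = sqrt(mean over frames of |x_i − ⟨x_i⟩|²), computed after each
    frame is rigid-body fitted (Kabsch on the selection) onto the
    iteratively refined ensemble-mean structure.
    """
    if ens.n_frames < 2:
        raise ValueError("RMSF undefined for fewer than 2 frames")
    sel, keys = _ca_indices(ens, selection)
    frames = np.stack(ens.frames)
    fitted = _mean_superposed(frames, sel)
    x = fitted[:, sel]  # (F, R, 3)
    mean = x.mean(axis=0)
    vals = np.sqrt(((x - mean) ** 2).sum(axis=2).mean(axis=0))
    return RMSFProfile(residue_keys=keys, values=vals, replica_id=replica_id)


def _profile_matrix(profiles: list[RMSFProfile],
                    keys: list[tuple[str, int]]) -> np.ndarray:
    rows = []
    for p in profiles:
        lookup = dict(zip(p.residue_keys, p.values))
        rows.append([lookup[k] for k in keys])
    return np.array(rows)


def call_mobility_regions(ref_profiles: list[RMSFProfile],
                          alt_profiles: list[RMSFProfile],
                          params: MobilityParams = MobilityParams()
                          ) -> list[MobilityCall]:
    """Call contiguous residue regions with reproducibly elevated mobility.

    Per residue, Δ(i) = mean_alt RMSF − mean_ref RMSF. A residue is
    elevated when Δ(i) > max(abs_floor, k × pooled inter-replica SD at i)
    (absolute value when ``two_sided``). Elevated residues are merged into
    maximal runs allowing ≤ gap_tol non-elevated residues; runs shorter
    than min_len are dropped. Reproducibility of a call is the fraction of
    (ref, alt) replica pairs in which the run-mean Δ is positive.

    Profiles are compared on the intersection of their residue keys, so a
    C-terminally truncated mutant is handled naturally.
    """
    if not ref_profiles or not alt_profiles:
        raise ValueError("need at least one profile per condition")
    shared = set(ref_profiles[0].residue_keys)
    for p in ref_profiles[1:] + alt_profiles:
        shared &= set(p.residue_keys)
    if not shared:
        raise ValueError("profiles have disjoint residue ranges")
    keys = [k for k in ref_profiles[0].residue_keys if k in shared]

    ref = _profile_matrix(ref_profiles, keys)  # (n_ref, R)
    alt = _profile_matrix(alt_profiles, keys)
    delta = alt.mean(axis=0) - ref.mean(axis=0)

    ddof = 1
    var_ref = ref.var(axis=0, ddof=ddof) if ref.shape[0] > 1 else np.zeros(len(keys))
    var_alt = alt.var(axis=0, ddof=ddof) if alt.shape[0] > 1 else np.zeros(len(keys))
    pooled_sd = np.sqrt((var_ref + var_alt) / 2.0)
    threshold = np.maximum(params.abs_floor, params.k * pooled_sd)
    excess = np.abs(delta) if params.two_sided else delta
    elevated = excess > threshold

    calls: list[MobilityCall] = []
    runs = _merge_runs(elevated, params.gap_tol)
    for lo, hi in runs:
        if hi - lo + 1 < params.min_len:
            continue
        run_idx = np.arange(lo, hi + 1)
        run_delta = float(delta[run_idx].mean())
        n_pairs = supported = 0
        for i in range(ref.shape[0]):
            for j in range(alt.shape[0]):
                n_pairs += 1
                if (alt[j, run_idx] - ref[i, run_idx]).mean() > 0:
                    supported += 1
        calls.append(MobilityCall(
            start_res=keys[lo][1], end_res=keys[hi][1],
            delta=run_delta, reproducibility=supported / n_pairs,
        ))
    return calls


def _merge_runs(mask: np.ndarray, gap_tol: int) -> list[tuple[int, int]]:
    """Maximal runs of True allowing gaps of at most gap_tol Falses."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    runs = []
    lo = prev = idx[0]
    for i in idx[1:]:
        if i - prev <= gap_tol + 1:
            prev = i
        else:
            runs.append((int(lo), int(prev)))
            lo = prev = i
    runs.append((int(lo), int(prev)))
    return runs


def pairwise_rmsd_matrix(ens: Ensemble, selection: str = "CA") -> np.ndarray:
    """All-pairs post-fit (Kabsch) RMSD matrix on the selection."""
    sel, _ = _ca_indices(ens, selection)
    frames = [f[sel] for f in ens.frames]
    n = len(frames)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, _, d = kabsch_superpose(frames[j], frames[i])
            mat[i, j] = mat[j, i] = d
    return mat


def cluster_gromos(ens: Ensemble, cutoff: float, selection: str = "CA",
                   rmsd_matrix: np.ndarray | None = None) -> ClusterResult:
    """GROMOS most-neighbors conformational clustering.

    Iteratively, the frame with the most neighbors within ``cutoff``
    (post-fit RMSD) becomes a center; it and its neighbors form a cluster
    and are removed. Neighbor-count ties go to the lowest frame index.
    Cluster ids are relabelled by decreasing size (ties: formation order).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    n = ens.n_frames
    mat = pairwise_rmsd_matrix(ens, selection) if rmsd_matrix is None else rmsd_matrix
    neighbors = mat <= cutoff
    np.fill_diagonal(neighbors, False)

    remaining = np.ones(n, dtype=bool)
    assignments = np.full(n, -1, dtype=int)
    clusters: list[tuple[int, np.ndarray]] = []
    while remaining.any():
        counts = (neighbors & remaining[None, :] & remaining[:, None]).sum(axis=1)
        counts[~remaining] = -1
        center = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.flatnonzero(remaining & (neighbors[center] | (np.arange(n) == center)))
        clusters.append((center, members))
        remaining[members] = False

    order = sorted(range(len(clusters)),
                   key=lambda c: (-len(clusters[c][1]), c))
    centers, sizes = [], []
    for new_id, old_id in enumerate(order):
        center, members = clusters[old_id]
        assignments[members] = new_id
        centers.append(center)
        sizes.append(len(members))
    return ClusterResult(assignments=assignments, centers=centers,
                         cutoff=cutoff, sizes=sizes)
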