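"""Synthetic fixtures with known ground truth for every pipeline stage.

Stands in for cluster-scale molecular-dynamics trajectories: every
generator is seeded (NumPy PCG64), returns its ground truth as a sidecar
dict, and emulates exactly one property the analysis must recover —
symbol streams of known entropy, harmonic ensembles of known per-residue
fluctuation amplitude, canonical secondary-structure geometries, matched
ensemble pairs with planted extra mobility, matched ordered/disordered
ensemble pairs with energy logs, and ensembles with a hydrogen bond
toggled in a known fraction of frames.

Peptide geometry is built by sequential internal-coordinate (NeRF-style)
atom placement with ideal bond lengths and angles (N–CA 1.458 Å,
CA–C 1.525 Å, C–N 1.329 Å), poly-alanine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .scoring import SymbolStream
from .structio import Atom, EnergyLog, Ensemble, StructureModel

__all__ = [
    "GeneratorSpec",
    "gen_symbol_stream",
    "gen_harmonic_ensemble",
    "gen_mobility_pair",
    "gen_ranking_pair",
    "gen_canonical_ss",
    "gen_hbond_toggle",
    "build_backbone",
    "CANONICAL_ANGLES",
]

# ideal backbone internal coordinates, Å and degrees
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_CA_CB = 1.521
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
ANGLE_C_CA_CB = 110.1

#: canonical backbone dihedrals (φ, ψ) per conformation
CANONICAL_ANGLES = {
    "helix": (-57.0, -47.0),
    "strand": (-139.0, 135.0),
}
TURN_I_ANGLES = ((-60.0, -30.0), (-90.0, 0.0))  # (i+1), (i+2)


@dataclass(frozen=True)
class GeneratorSpec:
    """Declarative description of one synthetic fixture."""

    kind: str  # symbol_stream | harmonic_ensemble | canonical_ss |
    #            mobility_pair | ranking_pair | hbond_toggle
    seed: int
    params: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# geometry construction


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom d with |cd| = bond, ∠(b,c,d) = angle and dihedral
    (a,b,c,d) = torsion (degrees)."""
    ang = math.radians(angle)
    tor = math.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array([
        -bond * math.cos(ang),
        bond * math.sin(ang) * math.cos(tor),
        bond * math.sin(ang) * math.sin(tor),
    ])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def build_backbone(phis, psis, omegas=None, res_names=None, chain_id="A",
                   first_res_seq: int = 1, with_cb: bool = True
                   ) -> StructureModel:
    """Build a peptide backbone from dihedrals with ideal geometry.

    ``phis``, ``psis`` (and optional ``omegas``, default all-trans) are
    per-residue lists; phi of the first and psi beyond the O-placement of
    the last residue are geometrically inert. Atoms per residue:
    N, CA, C, O (+ CB unless glycine or ``with_cb=False``).
    """
    n_res = len(phis)
    if len(psis) != n_res:
        raise ValueError("phis and psis must have equal length")
    omegas = [180.0] * n_res if omegas is None else list(omegas)
    res_names = ["ALA"] * n_res if res_names is None else list(res_names)

    ang = math.radians(ANGLE_N_CA_C)
    n_xyz = [np.array([0.0, 0.0, 0.0])]
    ca_xyz = [np.array([BOND_N_CA, 0.0, 0.0])]
    c_xyz = [ca_xyz[0] + BOND_CA_C * np.array(
        [-math.cos(ang), math.sin(ang), 0.0])]
    for i in range(1, n_res):
        n_xyz.append(place_atom(n_xyz[-1], ca_xyz[-1], c_xyz[-1],
                                BOND_C_N, ANGLE_CA_C_N, psis[i - 1]))
        ca_xyz.append(place_atom(ca_xyz[-1], c_xyz[-1], n_xyz[-1],
                                 BOND_N_CA, ANGLE_C_N_CA, omegas[i]))
        c_xyz.append(place_atom(c_xyz[-1], n_xyz[-1], ca_xyz[-1],
                                BOND_CA_C, ANGLE_N_CA_C, phis[i]))

    atoms: list[Atom] = []
    serial = 1

    def add(name, element, res_i, coords):
        nonlocal serial
        atoms.append(Atom(serial, name, element, first_res_seq + res_i,
                          res_names[res_i], chain_id, coords))
        serial += 1

    for i in range(n_res):
        add("N", "N", i, n_xyz[i])
        add("CA", "C", i, ca_xyz[i])
        add("C", "C", i, c_xyz[i])
        if i < n_res - 1:
            o = place_atom(n_xyz[i + 1], ca_xyz[i], c_xyz[i],
                           BOND_C_O, ANGLE_CA_C_O, 180.0)
        else:
            o = place_atom(n_xyz[i], ca_xyz[i], c_xyz[i],
                           BOND_C_O, ANGLE_CA_C_O, psis[i] + 180.0)
        add("O", "O", i, o)
        if with_cb and res_names[i] != "GLY":
            cb = place_atom(n_xyz[i], c_xyz[i], ca_xyz[i],
                            BOND_CA_CB, ANGLE_C_CA_CB, 122.6)
            add("CB", "C", i, cb)
    return StructureModel(atoms)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


# ---------------------------------------------------------------------------
# symbol streams


def _mixture_probs(n_bins: int, target_bits: float) -> np.ndarray:
    """Point-mass/uniform mixture with exactly the requested entropy.

    Support size k = ceil(2^H) (the smallest uniform support whose entropy
    reaches the target, keeping the distribution minimally skewed); the
    point mass sits on symbol 0 and its weight is solved by bisection.
    """
    max_bits = math.log2(n_bins)
    if not 0.0 <= target_bits <= max_bits + 1e-12:
        raise ValueError(
            f"entropy {target_bits} infeasible for {n_bins} bins "
            f"(max {max_bits:.4f})"
        )
    k = min(n_bins, max(1, math.ceil(2 ** target_bits - 1e-9)))

    def entropy(w):
        p0 = w + (1 - w) / k
        h = -p0 * math.log2(p0)
        if k > 1:
            p = (1 - w) / k
            if p > 0:
                h -= (k - 1) * p * math.log2(p)
        return h

    lo, hi = 0.0, 1.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if entropy(mid) > target_bits:
            lo = mid
        else:
            hi = mid
    w = 0.5 * (lo + hi)
    probs = np.zeros(n_bins)
    probs[:k] = (1 - w) / k
    probs[0] += w
    return probs


def gen_symbol_stream(n_bins: int, true_entropy_bits: float, n: int,
                      seed: int) -> tuple[SymbolStream, dict]:
    """I.i.d. symbol stream with exactly the requested Shannon entropy."""
    probs = _mixture_probs(n_bins, true_entropy_bits)
    rng = np.random.default_rng(seed)
    symbols = rng.choice(n_bins, size=n, p=probs)
    truth = {
        "kind": "symbol_stream",
        "true_entropy_bits": float(true_entropy_bits),
        "n_bins": n_bins, "n": n, "seed": seed,
        "probs": probs.tolist(),
    }
    return SymbolStream(symbols=symbols, n_bins=n_bins), truth


# ---------------------------------------------------------------------------
# harmonic ensembles and mobility pairs


def _sigma_array(reference: StructureModel, sigma_profile) -> np.ndarray:
    residues = reference.residues
    if np.isscalar(sigma_profile):
        return np.full(len(residues), float(sigma_profile))
    if isinstance(sigma_profile, dict):
        return np.array([sigma_profile[(c, r)] for c, r, _ in residues])
    arr = np.asarray(sigma_profile, dtype=float)
    if arr.size != len(residues):
        raise ValueError("sigma_profile must cover all residues")
    return arr


def gen_harmonic_ensemble(reference: StructureModel, sigma_profile,
                          n_frames: int, seed: int,
                          rigid_motion: bool = True) -> tuple[Ensemble, dict]:
    """Frames = reference + per-residue isotropic Gaussian displacement.

    Every atom of residue i receives i.i.d. Gaussian noise of that
    residue's σ per coordinate, so the expected RMSF is σ(i)·√3. A random
    global rigid-body motion is applied per frame (on by default) so that
    downstream superposition is actually exercised.
    """
    sigma = _sigma_array(reference, sigma_profile)
    if np.any(sigma < 0):
        raise ValueError("sigma values must be non-negative")
    res_keys = [(c, r) for c, r, _ in reference.residues]
    res_pos = {k: i for i, k in enumerate(res_keys)}
    atom_sigma = np.array([
        sigma[res_pos[(a.chain_id, a.res_seq)]] for a in reference.atoms
    ])
    ref = reference.coords
    rng = np.random.default_rng(seed)
    frames = []
    for _ in range(n_frames):
        noisy = ref + rng.normal(size=ref.shape) * atom_sigma[:, None]
        if rigid_motion:
            rot = _random_rotation(rng)
            trans = rng.uniform(-20.0, 20.0, size=3)
            noisy = noisy @ rot.T + trans
        frames.append(noisy)
    truth = {
        "kind": "harmonic_ensemble", "seed": seed, "n_frames": n_frames,
        "residue_keys": res_keys,
        "sigma": sigma.tolist(),
        "expected_rmsf": (sigma * math.sqrt(3.0)).tolist(),
        "rigid_motion": rigid_motion,
    }
    return Ensemble(topology=reference, frames=frames), truth


def gen_mobility_pair(reference: StructureModel, base_sigma: float,
                      planted_range: tuple[int, int], delta_sigma: float,
                      n_replicas: int, n_frames: int, seed: int
                      ) -> tuple[list[Ensemble], list[Ensemble], dict]:
    """Matched replicate ensembles with planted extra mobility.

    Reference replicas fluctuate at ``base_sigma`` everywhere; alternative
    replicas add ``delta_sigma`` inside ``planted_range`` (inclusive
    res_seq bounds). Each replica uses a distinct seed derived by
    SeedSequence spawning.
    """
    residues = reference.residues
    res_seqs = [r for _, r, _ in residues]
    lo, hi = planted_range
    if lo > hi or lo not in res_seqs or hi not in res_seqs:
        raise ValueError(
            f"planted range {planted_range} outside reference residues"
        )
    base = np.full(len(residues), float(base_sigma))
    alt = base.copy()
    mask = np.array([lo <= r <= hi for r in res_seqs])
    alt[mask] += delta_sigma
    children = np.random.SeedSequence(seed).spawn(2 * n_replicas)
    seeds = [int(c.generate_state(1)[0] % (2 ** 31)) for c in children]
    ref_ens = [gen_harmonic_ensemble(reference, base, n_frames, seeds[i])[0]
               for i in range(n_replicas)]
    alt_ens = [gen_harmonic_ensemble(reference, alt, n_frames,
                                     seeds[n_replicas + i])[0]
               for i in range(n_replicas)]
    truth = {
        "kind": "mobility_pair", "seed": seed,
        "planted_range": [lo, hi], "base_sigma": base_sigma,
        "delta_sigma": delta_sigma, "n_replicas": n_replicas,
        "n_frames": n_frames,
        "true_region": [] if delta_sigma == 0 else list(range(lo, hi + 1)),
    }
    return ref_ens, alt_ens, truth


# ---------------------------------------------------------------------------
# ordered/disordered ranking pairs


def _wrapped(angles: np.ndarray) -> np.ndarray:
    return (angles + 180.0) % 360.0 - 180.0


def _dihedral_sampled_ensemble(n_res: int, n_frames: int, angular_sigma: float,
                               rng: np.random.Generator) -> Ensemble:
    """Rebuild a poly-ALA chain per frame from noisy helix dihedrals."""
    phi0, psi0 = CANONICAL_ANGLES["helix"]
    topology = build_backbone([phi0] * n_res, [psi0] * n_res)
    frames = []
    for _ in range(n_frames):
        phis = _wrapped(phi0 + rng.normal(scale=angular_sigma, size=n_res))
        psis = _wrapped(psi0 + rng.normal(scale=angular_sigma, size=n_res))
        frames.append(build_backbone(phis, psis).coords)
    return Ensemble(topology=topology, frames=frames)


def gen_ranking_pair(seed: int, n_res: int = 20, n_frames: int = 1200,
                     sigma_ordered: float = 4.0,
                     sigma_disordered: float = 40.0,
                     e_ordered: float = -15000.0,
                     e_disordered: float = -14000.0,
                     e_sigma: float = 100.0,
                     ) -> tuple[dict, dict]:
    """Matched (Ensemble, EnergyLog) pairs emulating a model comparison.

    The "ordered" member samples backbone dihedrals from narrow wells
    (σ = 4°) and draws energies around a lower mean; the "disordered"
    member uses wide wells (σ = 40°) and a higher mean energy. Ground
    truth: the ordered member has both lower torsion entropy and lower
    energy, so it should be uniquely Pareto-dominant.
    """
    rng = np.random.default_rng(seed)
    members = {}
    for name, ang_sigma, e_mean in (
            ("ordered", sigma_ordered, e_ordered),
            ("disordered", sigma_disordered, e_disordered)):
        ens = _dihedral_sampled_ensemble(n_res, n_frames, ang_sigma, rng)
        energies = e_mean + rng.normal(scale=e_sigma, size=n_frames)
        log = EnergyLog(times=[10.0 * i for i in range(n_frames)],
                        values=energies.tolist(), label=name)
        members[name] = (ens, log)
    truth = {
        "kind": "ranking_pair", "seed": seed, "best": "ordered",
        "n_res": n_res, "n_frames": n_frames,
        "sigma_ordered": sigma_ordered, "sigma_disordered": sigma_disordered,
        "e_ordered": e_ordered, "e_disordered": e_disordered,
    }
    return members, truth


# ---------------------------------------------------------------------------
# canonical secondary-structure fixtures


def _hairpin_model(strand_len: int) -> StructureModel:
    """Two ideal antiparallel strands related by a dyad about the sheet
    normal, with spacing and registration picked by a deterministic scan
    that maximizes inter-strand Kabsch–Sander H-bonds subject to a steric
    clash filter. Fully extended flat strands (φ = ψ = 180°) are used:
    twisted strand geometries cannot be paired by a rigid dyad copy over
    a useful length."""
    from dataclasses import replace

    L = strand_len
    strand = build_backbone([180.0] * L, [180.0] * L)
    coords_a = strand.coords

    def sel(nm):
        return np.array([a.coords for a in strand.atoms if a.name == nm])

    n_at, ca, c_at, o_at = sel("N"), sel("CA"), sel("C"), sel("O")
    h_at = np.full_like(n_at, np.nan)
    for i in range(1, L):
        d0 = c_at[i - 1] - o_at[i - 1]
        h_at[i] = n_at[i] + d0 / np.linalg.norm(d0)
    heavy = np.vstack([n_at, ca, c_at, o_at, sel("CB")])

    centroid = ca.mean(axis=0)
    u = ca[-1] - ca[0]
    u /= np.linalg.norm(u)
    _, _, vt = np.linalg.svd(coords_a - coords_a.mean(axis=0))
    n_hat = vt[2]  # sheet normal: smallest principal axis
    v = np.cross(n_hat, u)
    v /= np.linalg.norm(v)
    rot = 2.0 * np.outer(n_hat, n_hat) - np.eye(3)  # 180° about n_hat
    t0 = (np.eye(3) - rot) @ centroid

    def transform(x, d, s):
        # dyad through centroid + d·v + s·u; in-plane offsets double
        return x @ rot.T + t0 + 2 * d * v + 2 * s * u

    def ks_count(d, s):
        hv = transform(heavy, d, s)
        dmin = np.sqrt(((heavy[:, None, :] - hv[None, :, :]) ** 2
                        ).sum(-1)).min()
        if dmin < 2.6:  # steric clash
            return -1
        nb, cb, ob, hb = (transform(x, d, s)
                          for x in (n_at, c_at, o_at, h_at))
        total = 0
        for don_n, don_h, acc_c, acc_o in ((n_at, h_at, cb, ob),
                                           (nb, hb, c_at, o_at)):
            for i in range(L):
                if np.isnan(don_h[i]).any():
                    continue
                r_on = np.linalg.norm(acc_o - don_n[i], axis=1)
                r_ch = np.linalg.norm(acc_c - don_h[i], axis=1)
                r_oh = np.linalg.norm(acc_o - don_h[i], axis=1)
                r_cn = np.linalg.norm(acc_c - don_n[i], axis=1)
                e = 0.084 * 332.0 * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn)
                total += int((e < -0.5).sum())
        return total

    best = None
    for d in np.arange(1.8, 3.4, 0.05):
        for s in np.arange(-5.0, 5.0, 0.1):
            count = ks_count(float(d), float(s))
            if best is None or count > best[0]:
                best = (count, float(d), float(s))
    _, d, s = best
    coords_b = transform(coords_a, d, s)
    atoms = list(strand.atoms)
    serial = len(atoms)
    for i, a in enumerate(strand.atoms):
        serial += 1
        atoms.append(replace(a, serial=serial, res_seq=a.res_seq + L + 10,
                             coords=coords_b[i]))
    return StructureModel(atoms)


def gen_canonical_ss(kind: str, length: int = 20, seed: int = 0
                     ) -> tuple[StructureModel, dict]:
    """Poly-ALA fixtures with canonical backbone geometry.

    kinds: "helix" (φ=−57°, ψ=−47°), "extended" (φ=−139°, ψ=135°,
    isolated strand), "hairpin" (two H-bond-registered antiparallel
    strands of ``length`` residues each), "turn_typeI" (4 residues with
    canonical type-I turn dihedrals).
    """
    if kind == "helix":
        phi, psi = CANONICAL_ANGLES["helix"]
        model = build_backbone([phi] * length, [psi] * length)
        truth = {"expected_interior_code": "H"}
    elif kind == "extended":
        phi, psi = CANONICAL_ANGLES["strand"]
        model = build_backbone([phi] * length, [psi] * length)
        truth = {"expected_interior_code": "-", "note": "no bridge partner"}
    elif kind == "hairpin":
        model = _hairpin_model(length)
        truth = {"expected_interior_code": "E", "strand_len": length}
    elif kind == "turn_typeI":
        if length != 4:
            raise ValueError("turn_typeI fixture is 4 residues")
        (p1, s1), (p2, s2) = TURN_I_ANGLES
        model = build_backbone([-120.0, p1, p2, -120.0],
                               [120.0, s1, s2, 120.0])
        truth = {"expected_turn_type": "I"}
    else:
        raise ValueError(f"unknown canonical kind {kind!r}")
    truth.update({"kind": kind, "length": length, "seed": seed})
    return model, truth


# ---------------------------------------------------------------------------
# hydrogen-bond toggling


def gen_hbond_toggle(fraction: float, n_frames: int, seed: int
                     ) -> tuple[Ensemble, dict]:
    """Ensemble in which one planted N–H···O=C bond is present in a known
    fraction of frames (the acceptor carbonyl swings away otherwise)."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    # acceptor residue 1 (C=O), donor residue 10 (N-H), 2.9 Å, linear
    atoms = [
        Atom(1, "CA", "C", 1, "ALA", "A", np.array([-1.1, 1.0, 0.0])),
        Atom(2, "C", "C", 1, "ALA", "A", np.array([-1.23, 0.0, 0.0])),
        Atom(3, "O", "O", 1, "ALA", "A", np.array([0.0, 0.0, 0.0])),
        Atom(4, "N", "N", 10, "ALA", "A", np.array([2.9, 0.0, 0.0])),
        Atom(5, "H", "H", 10, "ALA", "A", np.array([1.9, 0.0, 0.0])),
        Atom(6, "CA", "C", 10, "ALA", "A", np.array([3.6, 1.2, 0.0])),
    ]
    top = StructureModel(atoms)
    ref = top.coords
    broken = ref.copy()
    broken[3:] += np.array([4.0, 3.0, 0.0])  # move donor group away
    n_on = round(fraction * n_frames)
    rng = np.random.default_rng(seed)
    on_frames = set(rng.permutation(n_frames)[:n_on].tolist())
    frames = [ref.copy() if f in on_frames else broken.copy()
              for f in range(n_frames)]
    truth = {
        "kind": "hbond_toggle", "seed": seed, "fraction": fraction,
        "n_frames": n_frames, "n_on": n_on,
        "planted_fraction": n_on / n_frames,
        "donor": [["A", 10], "N"], "acceptor": [["A", 1], "O"],
    }
    return Ensemble(topology=top, frames=frames), truth


# ---------------------------------------------------------------------------
# dispatch


def generate(spec: GeneratorSpec):
    """Dispatch a GeneratorSpec to its generator; returns (object, truth)."""
    fns = {
        "symbol_stream": lambda p: gen_symbol_stream(seed=spec.seed, **p),
        "harmonic_ensemble": lambda p: gen_harmonic_ensemble(
            seed=spec.seed, **p),
        "mobility_pair": lambda p: gen_mobility_pair(seed=spec.seed, **p),
        "ranking_pair": lambda p: gen_ranking_pair(seed=spec.seed, **p),
        "canonical_ss": lambda p: gen_canonical_ss(seed=spec.seed, **p),
        "hbond_toggle": lambda p: gen_hbond_toggle(seed=spec.seed, **p),
    }
    if spec.kind not in fns:
        raise ValueError(f"unknown generator kind {spec.kind!r}")
    return fns[spec.kind](dict(spec.params))
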