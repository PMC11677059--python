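"""Superposition, RMSF, mobility calls and GROMOS clustering."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from confens import synthetic
from confens.ensemble import (DegenerateSuperpositionError, MobilityParams,
                              apply_transform, call_mobility_regions,
                              cluster_gromos, kabsch_superpose,
                              pairwise_rmsd_matrix, rmsf)
from confens.structio import Ensemble
from conftest import random_rigid_motion


def kabsch_oracle_rmsd(mobile, reference):
    """Independent minimum-RMSD via numeric optimization over rotation
    vectors (translation removed by centering)."""
    m = mobile - mobile.mean(axis=0)
    r = reference - reference.mean(axis=0)

    def cost(rotvec):
        rot = Rotation.from_rotvec(rotvec).as_matrix()
        return np.sqrt(((m @ rot.T - r) ** 2).sum(axis=1).mean())

    best = np.inf
    for x0 in ([0.0, 0.0, 0.0], [1.5, 0, 0], [0, 1.5, 0], [0, 0, 1.5],
               [2.2, 2.2, 0.0], [-1.5, 0.5, 1.0]):
        res = minimize(cost, x0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12,
                                "maxiter": 5000})
        best = min(best, res.fun)
    return best


class TestKabsch:
    def test_exact_recovery_of_rigid_motion(self, helix20):
        coords = helix20.coords
        theta = np.radians(37.0)
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
        moved = coords @ rot.T + np.array([1.0, 2.0, 3.0])
        _, _, rmsd = kabsch_superpose(moved, coords)
        assert rmsd < 1e-6

    def test_single_displaced_atom_analytic(self):
        rng = np.random.default_rng(2)
        ref = rng.normal(size=(100, 3)) * 10
        mob = ref.copy()
        mob[0] += [1.0, 0, 0]
        # displacing one atom of 100 by 1 Å: naive rmsd sqrt(1/100) = 0.1;
        # the optimal fit can only reduce it, and negligibly so for n=100
        _, _, rmsd = kabsch_superpose(mob, ref)
        assert rmsd == pytest.approx(0.1, rel=0.02)

    def test_matches_numeric_optimizer(self):
        rng = np.random.default_rng(31)
        for _ in range(5):
            a = rng.normal(size=(10, 3)) * 5
            b = rng.normal(size=(10, 3)) * 5
            _, _, rmsd = kabsch_superpose(a, b)
            assert rmsd == pytest.approx(kabsch_oracle_rmsd(a, b), abs=1e-4)

    def test_proper_rotation_only(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=(50, 3))
        b = -a  # a mirror image tempts the reflection branch
        rot, _, _ = kabsch_superpose(a, b)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_inputs_rejected(self):
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]],
                        dtype=float)
        with pytest.raises(DegenerateSuperpositionError):
            kabsch_superpose(line, line + 1.0)
        with pytest.raises(DegenerateSuperpositionError):
            kabsch_superpose(line[:2, :], line[:2, :])


class TestRMSF:
    def test_analytic_recovery_sigma_sqrt3(self):
        ref, _ = synthetic.gen_canonical_ss("helix", 100)
        ens, _ = synthetic.gen_harmonic_ensemble(ref, 0.5, 2000, seed=42)
        prof = rmsf(ens)
        interior = prof.values[5:-5]
        assert interior.mean() == pytest.approx(0.5 * np.sqrt(3), rel=0.03)

    def test_identical_frames_zero(self, helix20):
        ens = Ensemble(topology=helix20, frames=[helix20.coords] * 5)
        assert np.allclose(rmsf(ens).values, 0.0, atol=1e-9)

    def test_single_frame_rejected(self, helix20):
        ens = Ensemble(topology=helix20, frames=[helix20.coords])
        with pytest.raises(ValueError, match="2 frames"):
            rmsf(ens)

    def test_step_profile_recovered(self):
        ref, _ = synthetic.gen_canonical_ss("helix", 60)
        sigma = np.array([0.2] * 30 + [0.8] * 30)
        ens, truth = synthetic.gen_harmonic_ensemble(ref, sigma, 3000, seed=9)
        prof = rmsf(ens)
        lo = prof.values[5:25].mean()
        hi = prof.values[35:55].mean()
        assert lo == pytest.approx(0.2 * np.sqrt(3), rel=0.05)
        assert hi == pytest.approx(0.8 * np.sqrt(3), rel=0.05)

    def test_invariant_under_global_rigid_motion(self, helix30):
        rng = np.random.default_rng(6)
        frames = [helix30.coords + rng.normal(scale=0.3,
                                              size=(len(helix30.atoms), 3))
                  for _ in range(50)]
        ens = Ensemble(topology=helix30, frames=frames)
        base = rmsf(ens).values
        rot, trans = random_rigid_motion(rng)
        moved = Ensemble(topology=helix30,
                         frames=[apply_transform(f, rot, trans)
                                 for f in frames])
        np.testing.assert_allclose(rmsf(moved).values, base, atol=1e-9)


@pytest.fixture(scope="module")
def planted_pair():
    ref, _ = synthetic.gen_canonical_ss("helix", 80)
    return synthetic.gen_mobility_pair(ref, 0.3, (40, 50), 0.4,
                                       n_replicas=3, n_frames=300, seed=7)


class TestMobilityCalls:

    def test_planted_region_recovered(self, planted_pair):
        ref_ens, alt_ens, truth = planted_pair
        rp = [rmsf(e, replica_id=f"r{i}") for i, e in enumerate(ref_ens)]
        ap = [rmsf(e, replica_id=f"a{i}") for i, e in enumerate(alt_ens)]
        calls = call_mobility_regions(rp, ap)
        assert len(calls) == 1
        call = calls[0]
        called = set(range(call.start_res, call.end_res + 1))
        true = set(truth["true_region"])
        jaccard = len(called & true) / len(called | true)
        assert jaccard >= 0.7
        assert call.reproducibility == 1.0
        assert call.delta > 0

    def test_null_pair_no_calls(self):
        ref, _ = synthetic.gen_canonical_ss("helix", 80)
        r, a, _ = synthetic.gen_mobility_pair(ref, 0.3, (40, 50), 0.0,
                                              n_replicas=3, n_frames=300,
                                              seed=100)
        rp = [rmsf(e) for e in r]
        ap = [rmsf(e) for e in a]
        assert call_mobility_regions(rp, ap) == []

    def test_decrease_not_called_one_sided(self):
        ref, _ = synthetic.gen_canonical_ss("helix", 80)
        r, a, _ = synthetic.gen_mobility_pair(ref, 0.3, (40, 50), 0.4,
                                              n_replicas=2, n_frames=200,
                                              seed=13)
        # swap conditions: alt is now *less* mobile in the planted range
        rp = [rmsf(e) for e in a]
        ap = [rmsf(e) for e in r]
        assert call_mobility_regions(rp, ap) == []

    def test_disjoint_ranges_rejected(self):
        ref, _ = synthetic.gen_canonical_ss("helix", 10)
        ens, _ = synthetic.gen_harmonic_ensemble(ref, 0.3, 10, seed=1)
        p1 = rmsf(ens)
        p2 = rmsf(ens)
        p2.residue_keys = [("B", k[1] + 100) for k in p2.residue_keys]
        with pytest.raises(ValueError, match="disjoint"):
            call_mobility_regions([p1], [p2])


def gromos_bruteforce(mat, cutoff):
    """Independent exhaustive implementation of the most-neighbors rule."""
    n = mat.shape[0]
    remaining = set(range(n))
    clusters = []
    while remaining:
        best_frame, best_neigh = None, None
        for f in sorted(remaining):
            neigh = {g for g in remaining
                     if g != f and mat[f, g] <= cutoff}
            if best_neigh is None or len(neigh) > len(best_neigh):
                best_frame, best_neigh = f, neigh
        members = best_neigh | {best_frame}
        clusters.append((best_frame, members))
        remaining -= members
    order = sorted(range(len(clusters)),
                   key=lambda c: (-len(clusters[c][1]), c))
    assignments = np.empty(n, dtype=int)
    for new_id, old_id in enumerate(order):
        for m in clusters[old_id][1]:
            assignments[m] = new_id
    return assignments, [clusters[o][0] for o in order]


class TestGromosClustering:
    def _random_ensemble(self, seed, n_frames=8):
        ref, _ = synthetic.gen_canonical_ss("helix", 10)
        rng = np.random.default_rng(seed)
        frames = [ref.coords + rng.normal(scale=rng.uniform(0.2, 2.0),
                                          size=(len(ref.atoms), 3))
                  for _ in range(n_frames)]
        return Ensemble(topology=ref, frames=frames)

    def test_two_tight_triplets(self):
        ref, _ = synthetic.gen_canonical_ss("helix", 12)
        rng = np.random.default_rng(0)
        conf_a = ref.coords
        conf_b = ref.coords + rng.normal(scale=3.0, size=conf_a.shape)
        frames = []
        for base in (conf_a, conf_b):
            for _ in range(3):
                frames.append(base + rng.normal(scale=0.05, size=base.shape))
        ens = Ensemble(topology=ref, frames=frames)
        result = cluster_gromos(ens, cutoff=1.0)
        assert result.sizes == [3, 3]
        assert len(set(result.assignments[:3])) == 1
        assert len(set(result.assignments[3:])) == 1

    def test_everything_one_cluster_tie_to_frame0(self):
        ens = self._random_ensemble(1)
        result = cluster_gromos(ens, cutoff=1e6)
        assert result.sizes == [ens.n_frames]
        assert result.centers == [0]

    def test_matches_bruteforce_over_cutoffs(self):
        for seed in range(5):
            ens = self._random_ensemble(seed)
            mat = pairwise_rmsd_matrix(ens)
            cutoffs = np.unique(np.round(mat[mat > 0], 3))
            picks = cutoffs[:: max(1, len(cutoffs) // 6)]
            for cutoff in np.concatenate(([0.01], picks, [mat.max() + 1])):
                res = cluster_gromos(ens, float(cutoff), rmsd_matrix=mat)
                exp_assign, exp_centers = gromos_bruteforce(mat, cutoff)
                np.testing.assert_array_equal(res.assignments, exp_assign)
                assert res.centers == exp_centers

    def test_sizes_sum_to_frames_and_greedy_consistency(self):
        ens = self._random_ensemble(3)
        mat = pairwise_rmsd_matrix(ens)
        res = cluster_gromos(ens, 1.5, rmsd_matrix=mat)
        assert sum(res.sizes) == ens.n_frames
        # removing the largest cluster reproduces the remaining clusters
        keep = np.flatnonzero(res.assignments != 0)
        sub = Ensemble(topology=ens.topology,
                       frames=[ens.frames[i] for i in keep])
        sub_res = cluster_gromos(sub, 1.5,
                                 rmsd_matrix=mat[np.ix_(keep, keep)])
        relabel = {i: res.assignments[k] for i, k in enumerate(keep)}
        got = [relabel[i] for i in range(len(keep))]
        expect_groups = {}
        for i, c in enumerate(sub_res.assignments):
            expect_groups.setdefault(c, []).append(i)
        got_groups = {}
        for i, c in enumerate(got):
            got_groups.setdefault(c, []).append(i)
        assert sorted(map(sorted, expect_groups.values())) == \
            sorted(map(sorted, got_groups.values()))
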