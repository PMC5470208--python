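import numpy as np
import pytest

from tadfuse.boundaries import ContactMatrix
from tadfuse.model3d import (CONNECTIVITY, EXCLUDED, HARMONIC, EnsembleResult,
                             Model3D, RestraintSet, build_restraints,
                             cluster_mirror, kabsch_rmsd, optimize_model,
                             run_ensemble, virtual_hic)

from conftest import make_profile


def simple_restraints(pairs, targets, kinds=None, n=None):
    pairs = np.asarray(pairs)
    n = n if n is not None else int(pairs.max()) + 1
    m = pairs.shape[0]
    return RestraintSet(
        n_particles=n, pairs=pairs,
        targets=np.asarray(targets, dtype=float),
        kinds=np.asarray(kinds if kinds else [HARMONIC] * m, dtype=object),
        k=np.ones(m), d_min=1.0, d_max=50.0)


class TestBuildRestraints:
    def _profiles(self):
        # 12 bins of 100 bp; one end per 50 bp fragment
        raw = np.array([0, 0, 5, 9, 30, 0, 30, 9, 5, 2, 1, 1,
                        1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1], dtype=float)
        prof = make_profile(raw, ends=np.arange(24) * 50, frag_len=50,
                            viewpoint_pos=250)
        prof.smoothed = prof.raw.copy()
        prof.z = np.where(raw > 1, 1.0, -1.0)
        return [prof]

    def test_strongest_bin_gets_dmin_and_targets_bounded(self):
        rs = build_restraints(self._profiles(), region=(0, 1200),
                              bin_size=100, d_min=1.0, d_max=40.0)
        harm = rs.kinds == HARMONIC
        t = rs.targets[harm]
        assert t.min() == pytest.approx(1.0)   # strongest signal -> d_min
        assert t.max() <= 40.0                 # inverse map clipped at d_max

    def test_signal_monotone_decreasing_map(self):
        rs = build_restraints(self._profiles(), region=(0, 1200), bin_size=100)
        prof = self._profiles()[0]
        from tadfuse.model3d import bin_profile
        sig, _ = bin_profile(prof, 0, 1200, 100)
        harm = rs.kinds == HARMONIC
        vp_bin = 2
        targets = {j: t for (i, j), t in zip(rs.pairs[harm], rs.targets[harm])}
        bins = sorted(targets)
        for a in bins:
            for b in bins:
                if sig[a] > sig[b]:
                    assert targets[a] <= targets[b]

    def test_affine_endpoints(self):
        rs = build_restraints(self._profiles(), region=(0, 1200),
                              bin_size=100, d_min=2.0, d_max=20.0,
                              mapping="affine")
        harm = rs.kinds == HARMONIC
        assert rs.targets[harm].min() == pytest.approx(2.0)
        assert rs.targets[harm].max() == pytest.approx(20.0)

    def test_connectivity_chain_present(self):
        rs = build_restraints(self._profiles(), region=(0, 1200), bin_size=100)
        conn = {tuple(p) for p, k in zip(rs.pairs, rs.kinds)
                if k == CONNECTIVITY}
        assert conn == {(b, b + 1) for b in range(11)}

    def test_region_too_small(self):
        with pytest.raises(ValueError):
            build_restraints(self._profiles(), region=(0, 200), bin_size=100)


class TestOptimize:
    def test_two_particle_harmonic(self):
        rs = simple_restraints([[0, 1]], [10.0])
        model = optimize_model(rs, seed=1)
        d = np.linalg.norm(model.coords[0] - model.coords[1])
        assert d == pytest.approx(10.0, abs=1e-3)

    def test_determinism_bit_identical(self):
        rs = simple_restraints([[0, 1], [1, 2], [0, 2]], [5.0, 5.0, 10.0])
        a = optimize_model(rs, seed=42)
        b = optimize_model(rs, seed=42)
        assert np.array_equal(a.coords, b.coords)
        assert a.score == b.score

    def test_collinear_geometry_satisfied(self):
        rs = simple_restraints([[0, 1], [1, 2], [0, 2]], [5.0, 5.0, 10.0])
        model = optimize_model(rs, seed=3)
        d01 = np.linalg.norm(model.coords[0] - model.coords[1])
        d12 = np.linalg.norm(model.coords[1] - model.coords[2])
        d02 = np.linalg.norm(model.coords[0] - model.coords[2])
        assert model.score == pytest.approx(0.0, abs=1e-4)
        assert [d01, d12, d02] == pytest.approx([5, 5, 10], abs=1e-2)

    def test_never_worse_than_start(self):
        rs = simple_restraints([[0, 1]], [3.0])
        rng = np.random.default_rng(1)
        n = rs.n_particles
        side = rs.d_max * n ** (1 / 3)
        x0 = rng.uniform(-side / 2, side / 2, size=n * 3)
        from tadfuse.model3d import _energy_grad
        e0, _ = _energy_grad(x0, rs, rs.kinds != EXCLUDED)
        model = optimize_model(rs, seed=1)
        assert model.score <= e0


class TestEnsemble:
    def test_keep_all(self):
        rs = simple_restraints([[0, 1]], [4.0])
        er = run_ensemble(rs, n_models=10, n_keep=10, base_seed=0, max_iter=50)
        assert sorted(er.selected) == list(range(10))

    def test_selection_is_lowest_scores(self):
        rs = simple_restraints([[0, 1], [1, 2], [0, 2]], [5.0, 5.0, 30.0])
        er = run_ensemble(rs, n_models=12, n_keep=4, base_seed=0, max_iter=50)
        kept = {er.models[i].score for i in er.selected}
        others = [er.models[i].score for i in range(12) if i not in er.selected]
        assert max(kept) <= min(others) + 1e-12

    def test_n_keep_exceeds_models(self):
        rs = simple_restraints([[0, 1]], [4.0])
        with pytest.raises(ValueError):
            run_ensemble(rs, n_models=2, n_keep=3)


def _helix(n=12, seed=0):
    t = np.linspace(0, 3 * np.pi, n)
    coords = np.stack([np.cos(t) * 3, np.sin(t) * 3, t], axis=1)
    rng = np.random.default_rng(seed)
    return coords + rng.normal(0, 0.0, coords.shape)


def _ensemble_of(structures):
    models = [Model3D(coords=c, score=float(i), seed=i)
              for i, c in enumerate(structures)]
    return EnsembleResult(models=models, selected=list(range(len(models))))


class TestMirrorClustering:
    def test_rmsd_self_zero(self):
        S = _helix()
        rng = np.random.default_rng(0)
        # random proper rotation + translation
        from scipy.spatial.transform import Rotation
        R = Rotation.random(rng=0).as_matrix()
        assert kabsch_rmsd(S, S @ R.T + 5.0) == pytest.approx(0.0, abs=1e-9)

    def test_enantiomers_split_into_two_clusters(self):
        S = _helix()
        S_ref = S * np.array([1.0, 1.0, -1.0])
        er = _ensemble_of([S] * 5 + [S_ref] * 5)
        er = cluster_mirror(er)
        sizes = sorted(len(v) for v in er.clusters.values())
        assert sizes == [5, 5]
        assert er.mirror_checked

    def test_reflected_superposition_rmsd_near_zero(self):
        S = _helix()
        S_ref = S * np.array([1.0, 1.0, -1.0])
        assert kabsch_rmsd(S, S_ref) > 1.0           # proper rotation cannot align
        assert kabsch_rmsd(S * np.array([1.0, 1.0, -1.0]), S_ref) < 1e-9

    def test_majority_cluster_kept(self):
        S = _helix()
        S_ref = S * np.array([1.0, 1.0, -1.0])
        er = cluster_mirror(_ensemble_of([S] * 7 + [S_ref] * 3))
        assert len(er.clusters[er.kept_cluster]) == 7

    def test_identical_models_single_cluster(self):
        S = _helix()
        er = cluster_mirror(_ensemble_of([S] * 4))
        assert len(er.clusters) == 1


class TestVirtualHiC:
    def test_single_model_equals_own_distances(self):
        S = _helix()
        er = _ensemble_of([S])
        er.clusters = {0: [0]}
        er.kept_cluster = 0
        vh = virtual_hic(er, mode="distance")
        diff = S[:, None, :] - S[None, :, :]
        assert np.allclose(vh.values, np.sqrt((diff ** 2).sum(axis=2)))

    def test_distance_mode_symmetric_zero_diagonal(self):
        S = _helix()
        er = cluster_mirror(_ensemble_of([S] * 3 + [S * [1, 1, -1]] * 2))
        vh = virtual_hic(er, mode="distance")
        assert np.allclose(vh.values, vh.values.T)
        assert np.allclose(np.diagonal(vh.values), 0.0)

    def test_contact_mode_inverts_distance_ranking(self):
        S = _helix()
        er = _ensemble_of([S])
        er.clusters = {0: [0]}
        er.kept_cluster = 0
        dmat = virtual_hic(er, mode="distance").values
        cmat = virtual_hic(er, mode="contact").values
        iu = np.triu_indices_from(dmat, k=1)
        assert np.allclose(cmat[iu], 1.0 / dmat[iu])
        assert np.allclose(np.diagonal(cmat), cmat[iu].max())

    def test_rigid_motion_invariance(self):
        from scipy.spatial.transform import Rotation
        S = _helix()
        R = Rotation.random(rng=1).as_matrix()
        er1 = _ensemble_of([S, S + 1.0])
        er1.clusters = {0: [0, 1]}
        er1.kept_cluster = 0
        er2 = _ensemble_of([S @ R.T + 7.0, (S + 1.0) @ R.T + 7.0])
        er2.clusters = {0: [0, 1]}
        er2.kept_cluster = 0
        assert np.allclose(virtual_hic(er1, mode="distance").values,
                           virtual_hic(er2, mode="distance").values,
                           atol=1e-9)

    def test_requires_kept_cluster(self):
        er = _ensemble_of([_helix()])
        with pytest.raises(ValueError):
            virtual_hic(er)
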