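"""Rigid superposition (Kabsch) and conserved-water matching."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from gqwaters.structure_model import Atom, Residue, Structure
from gqwaters.superpose import (
    DegenerateFitError,
    ResidueCorrespondence,
    fit_quartets,
    kabsch,
    match_conserved_waters,
)
from gqwaters.synthetic import (
    SceneSpec,
    derive_native_copy,
    generate_scene,
    random_rotation,
)


def brute_force_mutual_pairs(coords_a, labels_a, coords_b, labels_b, threshold):
    """Oracle: exhaustive greedy mutual-nearest matching on the full matrix."""
    cands = []
    for i, pa in enumerate(coords_a):
        for j, pb in enumerate(coords_b):
            d = float(np.linalg.norm(pa - pb))
            if d <= threshold:
                cands.append((d, labels_a[i], labels_b[j]))
    cands.sort()
    used_a, used_b, out = set(), set(), set()
    for d, la, lb in cands:
        if la in used_a or lb in used_b:
            continue
        out.add((la, lb))
        used_a.add(la)
        used_b.add(lb)
    return out


def _waters_structure(coords, start_seq=1):
    residues = [
        Residue("HOH", start_seq + i, "W", "water",
                [Atom("O", "O", np.asarray(c, float))])
        for i, c in enumerate(coords)
    ]
    return Structure("waters", residues)


class TestKabsch:
    def test_identity_on_self(self, rng):
        pts = rng.normal(size=(10, 3))
        res = kabsch(pts, pts)
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(res.translation, 0, atol=1e-12)
        assert res.rmsd < 1e-12

    def test_recovers_known_transform(self, rng):
        pts = rng.normal(size=(20, 3)) * 4
        rot = random_rotation(rng)
        trans = np.array([3.0, -7.0, 1.5])
        res = kabsch(pts, pts @ rot.T + trans)
        np.testing.assert_allclose(res.rotation, rot, atol=1e-9)
        np.testing.assert_allclose(res.translation, trans, atol=1e-8)
        assert res.rmsd < 1e-6

    def test_matches_scipy_align_vectors(self, rng):
        # independent oracle: scipy's rotational alignment on centered clouds
        a = rng.normal(size=(15, 3))
        b = rng.normal(size=(15, 3))
        res = kabsch(a, b)
        r_scipy, _ = Rotation.align_vectors(b - b.mean(0), a - a.mean(0))
        np.testing.assert_allclose(res.rotation, r_scipy.as_matrix(), atol=1e-8)

    def test_proper_rotation(self, rng):
        # a reflected cloud must still yield det=+1
        a = rng.normal(size=(12, 3))
        b = a.copy()
        b[:, 0] = -b[:, 0]
        res = kabsch(a, b)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0)

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateFitError):
            kabsch(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], float)
        with pytest.raises(DegenerateFitError):
            kabsch(line, line)

    def test_rmsd_invariant_under_pre_transform(self, rng):
        a = rng.normal(size=(18, 3))
        b = a + rng.normal(scale=0.3, size=a.shape)
        base = kabsch(a, b).rmsd
        rot = random_rotation(rng)
        moved = a @ rot.T + np.array([5.0, 5.0, -2.0])
        assert kabsch(moved, b).rmsd == pytest.approx(base, abs=1e-9)


class TestFitQuartets:
    @staticmethod
    def _corr(structure):
        pairs = [(("A", r.seq_number), ("A", r.seq_number))
                 for r in structure.residues if r.category == "nucleotide"]
        return ResidueCorrespondence(pairs)

    def test_self_fit_is_identity(self):
        spec = SceneSpec(n_bridges=0, n_decoy_waters=0, seed=4)
        structure, _ = generate_scene(spec)
        res = fit_quartets(structure, structure, self._corr(structure))
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-9)
        assert res.rmsd < 1e-9

    def test_recovers_scene_transform(self, rng):
        rot, trans = random_rotation(rng), np.array([2.0, 8.0, -4.0])
        spec = SceneSpec(n_bridges=2, n_decoy_waters=4, seed=6,
                         rigid_transform=(rot, trans), conserved_fraction=1.0)
        structure, truth = generate_scene(spec)
        native, _ = derive_native_copy(structure, truth, spec)
        res = fit_quartets(structure, native, self._corr(structure))
        np.testing.assert_allclose(res.rotation, rot, atol=1e-8)
        assert res.rmsd < 1e-6

    def test_rmsd_tracks_jitter_level(self):
        # B = rigid copy of A with one-sided per-coordinate Gaussian jitter
        # sd sigma: expected fit RMSD ~ sigma * sqrt(3) (3 coordinates),
        # verified as a Monte-Carlo average over seeds at n >= 36 atoms
        sigma = 0.25
        rmsds = []
        for seed in range(8):
            rng = np.random.default_rng(seed)
            pts = rng.normal(size=(48, 3)) * 5
            rot = random_rotation(rng)
            noisy = (pts + rng.normal(scale=sigma, size=pts.shape)) @ rot.T
            rmsds.append(kabsch(pts, noisy).rmsd)
        mean_rmsd = float(np.mean(rmsds))
        assert mean_rmsd == pytest.approx(sigma * np.sqrt(3), rel=0.2)


class TestConservedWaters:
    def test_identical_sets_pair_at_zero(self, rng):
        coords = rng.normal(size=(8, 3)) * 6
        a = _waters_structure(coords, start_seq=1)
        b = _waters_structure(coords, start_seq=101)
        identity = kabsch(coords, coords)
        pairs = match_conserved_waters(a, b, identity, threshold=1.0)
        assert len(pairs) == 8
        assert all(p.distance == pytest.approx(0.0, abs=1e-12) for p in pairs)

    def test_planted_conserved_plus_extras(self, rng):
        base = rng.uniform(-10, 10, size=(10, 3))
        jitter = rng.normal(scale=0.1, size=base.shape)
        jitter = np.clip(jitter, -0.17, 0.17)  # keep every pair within 0.3 A
        extras_a = base.mean(0) + np.array([40.0, 0, 0]) + rng.uniform(-2, 2, (3, 3))
        extras_b = base.mean(0) + np.array([-40.0, 0, 0]) + rng.uniform(-2, 2, (3, 3))
        a = _waters_structure(np.vstack([base, extras_a]), start_seq=1)
        b = _waters_structure(np.vstack([base + jitter, extras_b]), start_seq=101)
        identity = kabsch(base, base)
        pairs = match_conserved_waters(a, b, identity, threshold=1.0)
        assert len(pairs) == 10
        got = {(p.water_a, p.water_b) for p in pairs}
        want = {(f"W{1 + i}", f"W{101 + i}") for i in range(10)}
        assert got == want

    def test_equals_brute_force_oracle(self, rng):
        identity = kabsch(np.eye(3) * 5, np.eye(3) * 5)
        for trial in range(5):
            na, nb = rng.integers(5, 25), rng.integers(5, 25)
            ca = rng.uniform(-6, 6, size=(na, 3))
            cb = rng.uniform(-6, 6, size=(nb, 3))
            a = _waters_structure(ca, start_seq=1)
            b = _waters_structure(cb, start_seq=201)
            pairs = match_conserved_waters(a, b, identity, threshold=2.0)
            got = {(p.water_a, p.water_b) for p in pairs}
            labels_a = [r.label for r in a.waters]
            labels_b = [r.label for r in b.waters]
            assert got == brute_force_mutual_pairs(ca, labels_a, cb, labels_b, 2.0)

    def test_each_water_in_at_most_one_pair(self, rng):
        ca = rng.uniform(-3, 3, size=(15, 3))
        cb = rng.uniform(-3, 3, size=(12, 3))
        a = _waters_structure(ca)
        b = _waters_structure(cb, start_seq=101)
        identity = kabsch(np.eye(3) * 5, np.eye(3) * 5)
        pairs = match_conserved_waters(a, b, identity, threshold=3.0)
        assert len({p.water_a for p in pairs}) == len(pairs)
        assert len({p.water_b for p in pairs}) == len(pairs)

    def test_pair_count_monotone_in_threshold(self, rng):
        ca = rng.uniform(-5, 5, size=(20, 3))
        cb = ca + rng.normal(scale=0.5, size=ca.shape)
        a = _waters_structure(ca)
        b = _waters_structure(cb, start_seq=101)
        identity = kabsch(np.eye(3) * 5, np.eye(3) * 5)
        counts = [
            len(match_conserved_waters(a, b, identity, threshold=t))
            for t in (0.25, 0.5, 1.0, 2.0)
        ]
        assert counts == sorted(counts)

    def test_optimal_assignment_option(self, rng):
        ca = rng.uniform(-5, 5, size=(10, 3))
        a = _waters_structure(ca)
        b = _waters_structure(ca, start_seq=101)
        identity = kabsch(np.eye(3) * 5, np.eye(3) * 5)
        mutual = match_conserved_waters(a, b, identity, 1.0, method="mutual")
        optimal = match_conserved_waters(a, b, identity, 1.0, method="optimal")
        assert {(p.water_a, p.water_b) for p in mutual} == \
               {(p.water_a, p.water_b) for p in optimal}
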