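import itertools
import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from pharmscreen import featurize
from pharmscreen.core import FeatureSet, PharmacophoreFeature, RigidTransform
from pharmscreen.libbuild import ConformerLibrary, LibraryEntry, compute_properties
from pharmscreen.pharma_search import (Correspondence, enumerate_correspondences,
                                       kabsch_align, match_conformer,
                                       search_pharmacophore, verify_match)

from conftest import embed


def feat(kind, center, radius=1.0, **kw):
    return PharmacophoreFeature(kind=kind, center=center, radius=radius, **kw)


def brute_force_matches(query_feats, conf_fs, angle_cutoff=45.0):
    """Exhaustive no-pruning oracle: try every injective kind-compatible
    mapping, align, verify; return {correspondence: rmsd}."""
    feats = list(conf_fs)
    nq = len(query_feats)
    accepted = {}
    for perm in itertools.permutations(range(len(feats)), nq):
        if any(query_feats[qi].kind != feats[fj].kind
               for qi, fj in enumerate(perm)):
            continue
        if any(query_feats[qi].kind == "Hydrophobic"
               and query_feats[qi].minsize is not None
               and (feats[fj].minsize or 0) < query_feats[qi].minsize
               for qi, fj in enumerate(perm)):
            continue
        corr = Correspondence(tuple((qi, fj) for qi, fj in enumerate(perm)))
        q_pts = np.array([query_feats[qi].center for qi, _ in corr.pairs])
        c_pts = np.array([feats[fj].center for _, fj in corr.pairs])
        tfm, rmsd = kabsch_align(q_pts, c_pts)
        if verify_match(query_feats, conf_fs, corr, tfm, angle_cutoff):
            accepted[corr.pairs] = rmsd
    return accepted


def random_featureset(rng, n, kinds=("HydrogenDonor", "HydrogenAcceptor",
                                     "Aromatic", "Hydrophobic")):
    feats = [feat(kinds[rng.integers(len(kinds))],
                  rng.uniform(-4, 4, 3), radius=float(rng.uniform(0.6, 1.4)))
             for _ in range(n)]
    return FeatureSet(feats)


class TestKabsch:
    def test_identical_points_zero_rmsd(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 2, 0], [0, 0, 3.0]])
        tfm, rmsd = kabsch_align(pts, pts)
        assert rmsd <= 1e-9
        assert np.allclose(tfm.rotation, np.eye(3), atol=1e-9)

    def test_rigid_copy_recovers_inverse_rotation(self):
        rng = np.random.default_rng(11)
        pts = rng.uniform(-5, 5, (6, 3))
        rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved = pts @ rot.T + np.array([1.0, 2.0, 3.0])
        tfm, rmsd = kabsch_align(pts, moved)
        assert rmsd <= 1e-9
        assert np.abs(tfm.rotation - rot.T).max() <= 1e-6

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_beats_random_rigid_placements(self, seed):
        rng = np.random.default_rng(seed)
        q = rng.uniform(-5, 5, (5, 3))
        c = rng.uniform(-5, 5, (5, 3))
        _, best = kabsch_align(q, c)
        for k in range(1000):
            rot = Rotation.random(
                random_state=np.random.RandomState(seed * 1000 + k)).as_matrix()
            trial = c @ rot.T + rng.uniform(-5, 5, 3)
            rmsd = math.sqrt(np.mean(np.sum((trial - q) ** 2, axis=1)))
            assert best <= rmsd + 1e-9

    def test_agrees_with_scipy_align_vectors(self):
        rng = np.random.default_rng(3)
        q = rng.uniform(-5, 5, (8, 3))
        c = rng.uniform(-5, 5, (8, 3))
        tfm, rmsd = kabsch_align(q, c)
        rot, rssd = Rotation.align_vectors(q - q.mean(0), c - c.mean(0))
        assert np.abs(tfm.rotation - rot.as_matrix()).max() <= 1e-6
        assert rmsd == pytest.approx(rssd / math.sqrt(len(q)), abs=1e-8)

    def test_degenerate_collinear_still_minimizes(self):
        q = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0.0]])
        c = np.array([[0, 0, 0], [0, 1, 0], [0, 2, 0.0]])
        tfm, rmsd = kabsch_align(q, c)
        assert rmsd <= 1e-9
        assert abs(np.linalg.det(tfm.rotation) - 1) <= 1e-6


class TestEnumerate:
    def test_exact_geometry_contains_identity(self):
        q = [feat("HydrogenDonor", (0, 0, 0)), feat("Aromatic", (3, 0, 0)),
             feat("HydrogenAcceptor", (0, 4, 0))]
        conf = FeatureSet([feat(f.kind, f.center) for f in q])
        corrs = enumerate_correspondences(q, conf)
        assert ((0, 0), (1, 1), (2, 2)) in {c.pairs for c in corrs}

    def test_distance_pruning_rejects(self):
        q = [feat("HydrogenDonor", (0, 0, 0)), feat("HydrogenDonor", (8, 0, 0))]
        conf = FeatureSet([feat("HydrogenDonor", (0, 0, 0)),
                           feat("HydrogenDonor", (2, 0, 0))])
        assert enumerate_correspondences(q, conf) == []

    def test_empty_query_is_error(self):
        with pytest.raises(ValueError, match="unsearchable"):
            enumerate_correspondences([], FeatureSet([feat("Aromatic", (0, 0, 0))]))

    @pytest.mark.parametrize("seed", range(8))
    def test_pruning_soundness_vs_exhaustive(self, seed):
        """Pruned enumeration + verification accepts exactly the matches the
        no-pruning oracle accepts, with equal RMSDs."""
        rng = np.random.default_rng(seed)
        q = list(random_featureset(rng, 4))
        conf = random_featureset(rng, int(rng.integers(4, 8)))
        oracle = brute_force_matches(q, conf)
        mine = {}
        for corr in enumerate_correspondences(q, conf):
            if len(corr.pairs) != len(q):
                continue
            q_pts = np.array([q[qi].center for qi, _ in corr.pairs])
            c_pts = np.array([list(conf)[fj].center for _, fj in corr.pairs])
            tfm, rmsd = kabsch_align(q_pts, c_pts)
            if verify_match(q, conf, corr, tfm):
                mine[corr.pairs] = rmsd
        assert set(mine) == set(oracle)
        for key in mine:
            assert mine[key] == pytest.approx(oracle[key], abs=1e-6)


class TestVerify:
    def test_centers_on_sphere_centers(self):
        q = [feat("Aromatic", (0, 0, 0)), feat("Aromatic", (3, 0, 0))]
        conf = FeatureSet([feat("Aromatic", (0, 0, 0)),
                           feat("Aromatic", (3, 0, 0))])
        corr = Correspondence(((0, 0), (1, 1)))
        assert verify_match(q, conf, corr, RigidTransform.identity())

    def test_center_just_outside_radius(self):
        q = [feat("Aromatic", (0, 0, 0), radius=1.0)]
        conf = FeatureSet([feat("Aromatic", (1.01, 0, 0))])
        corr = Correspondence(((0, 0),))
        assert not verify_match(q, conf, corr, RigidTransform.identity())

    def test_aromatic_direction_sign_symmetric(self):
        q = [feat("Aromatic", (0, 0, 0), direction=(0, 0, 1.0))]
        conf = FeatureSet([feat("Aromatic", (0, 0, 0), direction=(0, 0, -1.0))])
        corr = Correspondence(((0, 0),))
        assert verify_match(q, conf, corr, RigidTransform.identity())

    def test_donor_direction_not_sign_symmetric(self):
        q = [feat("HydrogenDonor", (0, 0, 0), direction=(0, 0, 1.0))]
        conf = FeatureSet([feat("HydrogenDonor", (0, 0, 0),
                                direction=(0, 0, -1.0))])
        corr = Correspondence(((0, 0),))
        assert not verify_match(q, conf, corr, RigidTransform.identity())


def tiny_library(mols):
    entries = []
    for i, m in enumerate(mols):
        entries.append(LibraryEntry(
            molecule_id=f"m{i:06d}", name=m.name, canonical=None,
            conformers=[m], properties=compute_properties(m)))
    return ConformerLibrary(entries=entries)


class TestSearch:
    def test_self_retrieval_rmsd_zero(self, template):
        fs = featurize.detect_features(template)
        lib = tiny_library([template, embed("CCCCC", "decoy", seed=8)])
        hits = search_pharmacophore(list(fs), lib)
        assert hits and hits[0].molecule_id == "m000000"
        assert hits[0].rmsd < 1e-6

    def test_results_sorted_by_rmsd(self, planted):
        lib, query = planted
        hits = search_pharmacophore(query, lib)
        rmsds = [h.rmsd for h in hits]
        assert rmsds == sorted(rmsds)

    def test_enlarging_radii_never_removes_hits(self, planted):
        lib, query = planted
        base = {(h.molecule_id, h.conformer_id)
                for h in search_pharmacophore(query, lib)}
        import dataclasses
        for scale in (1.5, 2.5):
            bigger = [dataclasses.replace(f, radius=f.radius * scale)
                      for f in query.features]
            grown = {(h.molecule_id, h.conformer_id)
                     for h in search_pharmacophore(bigger, lib)}
            assert base <= grown
            base = grown

    def test_matches_exhaustive_matcher_on_library(self, planted):
        lib, query = planted
        hits = {(h.molecule_id, h.conformer_id): h.rmsd
                for h in search_pharmacophore(query, lib)}
        oracle = {}
        for entry in lib.entries:
            for ci in range(len(entry.conformers)):
                fs = lib.features_for(entry, ci)
                accepted = brute_force_matches(list(query.features), fs)
                if accepted:
                    oracle[(entry.molecule_id, ci)] = min(accepted.values())
        assert set(hits) == set(oracle)
        for key in hits:
            assert hits[key] == pytest.approx(oracle[key], abs=1e-6)
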