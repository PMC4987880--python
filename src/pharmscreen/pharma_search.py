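"""Pharmacophore matching: correspondence enumeration, Kabsch superposition,
tolerance/direction verification, and pharmacophore-first library search.

A compound conformer matches a query when some injective, kind-compatible
assignment of its features to the query's tolerance spheres admits a proper
rigid motion placing every assigned feature inside its sphere.  The search
enumerates assignments with pairwise-distance pruning — a pair (i,j) of query
features at distance d_q can only host conformer features at distance d_c
with |d_q - d_c| <= r_i + r_j, a sound bound by the triangle inequality — and
then verifies each surviving assignment after a least-squares (Kabsch)
superposition of the matched feature centers.  Directions never enter the
superposition objective; they are checked post-alignment against an angle
cutoff (both normal signs accepted for aromatics).
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .core import (DEFAULT_DIRECTION_ANGLE, FeatureSet, Molecule,
                   PharmacophoreFeature, QueryDocument, RigidTransform,
                   angle_deg, logger)

__all__ = [
    "Correspondence", "RigidTransform", "AlignedHit",
    "enumerate_correspondences", "kabsch_align", "verify_match",
    "match_conformer", "search_pharmacophore",
]


@dataclass(frozen=True)
class Correspondence:
    """Injective pairing (query feature index, conformer feature index)."""

    pairs: Tuple[Tuple[int, int], ...]

    def __post_init__(self):
        qs = [p[0] for p in self.pairs]
        cs = [p[1] for p in self.pairs]
        if len(set(qs)) != len(qs) or len(set(cs)) != len(cs):
            raise ValueError("correspondence must be injective on both sides")


@dataclass
class AlignedHit:
    """A query-aligned conformer pose with its score(s)."""

    molecule_id: str
    conformer_id: int
    transform: RigidTransform
    rmsd: Optional[float] = None
    shape_similarity: Optional[float] = None
    correspondence: Optional[Correspondence] = None
    name: str = ""

    def __post_init__(self):
        if self.rmsd is not None and self.rmsd < -1e-12:
            raise ValueError("rmsd must be non-negative")
        if self.shape_similarity is not None and not (
                -1e-9 <= self.shape_similarity <= 1 + 1e-9):
            raise ValueError("shape similarity must lie in [0, 1]")


def _compatible(q: PharmacophoreFeature, f: PharmacophoreFeature) -> bool:
    if q.kind != f.kind:
        return False
    if q.kind == "Hydrophobic" and q.minsize is not None:
        return (f.minsize or 0) >= q.minsize
    return True


def enumerate_correspondences(query_features: Sequence[PharmacophoreFeature],
                              conf_features: FeatureSet) -> List[Correspondence]:
    """All kind-compatible injective assignments surviving pairwise pruning.

    Exhaustively complete under the pruning rule: any assignment admitting a
    rigid motion that puts each feature in its sphere satisfies
    |d_query(i,j) - d_conf(i,j)| <= r_i + r_j for every pair, so no verifiable
    match is lost.
    """
    query_features = list(query_features)
    if not query_features:
        raise ValueError("unsearchable query: no enabled features")
    feats = list(conf_features)
    candidates = [
        [j for j, f in enumerate(feats) if _compatible(q, f)]
        for q in query_features
    ]
    if any(not c for c in candidates):
        return []
    q_centers = np.asarray([q.center for q in query_features])
    f_centers = np.asarray([f.center for f in feats])
    qd = np.linalg.norm(q_centers[:, None] - q_centers[None, :], axis=2)
    fd = np.linalg.norm(f_centers[:, None] - f_centers[None, :], axis=2)
    radii = np.asarray([q.radius for q in query_features])

    # fill query slots in order of fewest candidates; report in query order
    order = sorted(range(len(query_features)), key=lambda i: len(candidates[i]))
    results: List[Correspondence] = []
    assign: List[Tuple[int, int]] = []
    used = set()

    def backtrack(pos: int):
        if pos == len(order):
            results.append(Correspondence(tuple(sorted(assign))))
            return
        qi = order[pos]
        for fj in candidates[qi]:
            if fj in used:
                continue
            ok = True
            for (qk, fk) in assign:
                if abs(qd[qi, qk] - fd[fj, fk]) > radii[qi] + radii[qk]:
                    ok = False
                    break
            if not ok:
                continue
            used.add(fj)
            assign.append((qi, fj))
            backtrack(pos + 1)
            assign.pop()
            used.discard(fj)

    backtrack(0)
    return results


def kabsch_align(query_pts: np.ndarray, conf_pts: np.ndarray
                 ) -> Tuple[RigidTransform, float]:
    """Proper rigid motion of *conf_pts* minimizing RMSD to *query_pts*.

    Classic Kabsch: centroids superposed, rotation from the SVD of the
    cross-covariance with a determinant correction so no reflection sneaks
    in.  Degenerate (collinear/coincident) point sets still return a
    minimizer; it is simply not unique.
    """
    q = np.asarray(query_pts, dtype=float).reshape(-1, 3)
    c = np.asarray(conf_pts, dtype=float).reshape(-1, 3)
    if q.shape != c.shape or len(q) == 0:
        raise ValueError("point lists must be equal-length and non-empty")
    qc, cc = q.mean(axis=0), c.mean(axis=0)
    h = (c - cc).T @ (q - qc)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = qc - rot @ cc
    tfm = RigidTransform(rot, trans)
    rmsd = float(np.sqrt(np.mean(np.sum((tfm.apply(c) - q) ** 2, axis=1))))
    return tfm, rmsd


def verify_match(query_features: Sequence[PharmacophoreFeature],
                 conf_features: FeatureSet,
                 correspondence: Correspondence,
                 transform: RigidTransform,
                 angle_cutoff: float = DEFAULT_DIRECTION_ANGLE) -> bool:
    """True iff every matched feature lands inside its tolerance sphere and
    every directional query feature agrees within *angle_cutoff* degrees
    (aromatic normals are sign-symmetric)."""
    feats = list(conf_features)
    for qi, fj in correspondence.pairs:
        q, f = query_features[qi], feats[fj]
        moved = f.moved(transform)
        if np.linalg.norm(moved.center - q.center) > q.radius + 1e-9:
            return False
        if q.direction is not None and moved.direction is not None:
            ang = angle_deg(q.direction, moved.direction)
            if q.kind == "Aromatic":
                ang = min(ang, 180.0 - ang)
            if ang > angle_cutoff + 1e-9:
                return False
    return True


def _degenerate_minimizer_candidates(query_features, feats, corr,
                                     q_pts, c_pts):
    """Alternative center-RMSD minimizers for degenerate point sets.

    When the matched centers are coincident, collinear or planar the Kabsch
    minimizer is not unique, and the SVD's arbitrary choice can point
    directional features the wrong way.  Among the minimizers we prefer one
    agreeing with the directions: the superposition is re-run with pseudo
    points at center + direction for every pair where both sides carry a
    direction (aromatic normals contribute both signs).  The returned
    transforms still minimize the centers-only RMSD up to numerical noise.
    """
    dir_pairs = []
    for qi, fj in corr.pairs:
        q, f = query_features[qi], feats[fj]
        if q.direction is not None and f.direction is not None:
            dir_pairs.append((q, f, q.kind == "Aromatic"))
    if not dir_pairs:
        return []
    sym_idx = [i for i, (_, _, sym) in enumerate(dir_pairs) if sym][:3]
    candidates = []
    for combo in itertools.product((1.0, -1.0), repeat=len(sym_idx)):
        signs = [1.0] * len(dir_pairs)
        for s, i in zip(combo, sym_idx):
            signs[i] = s
        q_aug = np.vstack([q_pts] + [[q.center + q.direction]
                                     for q, _, _ in dir_pairs])
        c_aug = np.vstack([c_pts] + [[f.center + s * f.direction]
                                     for (_, f, _), s in zip(dir_pairs, signs)])
        tfm, _ = kabsch_align(q_aug, c_aug)
        rmsd = float(np.sqrt(np.mean(
            np.sum((tfm.apply(c_pts) - q_pts) ** 2, axis=1))))
        candidates.append((rmsd, tfm))
    return candidates


def _rank_deficient(pts: np.ndarray) -> bool:
    if len(pts) < 3:
        return True
    svals = np.linalg.svd(pts - pts.mean(axis=0), compute_uv=False)
    return bool(svals[2] < 1e-8 * max(svals[0], 1.0))


def match_conformer(query_features: Sequence[PharmacophoreFeature],
                    conf_features: FeatureSet,
                    angle_cutoff: float = DEFAULT_DIRECTION_ANGLE,
                    max_poses: int = 1
                    ) -> List[Tuple[float, RigidTransform, Correspondence]]:
    """Verified poses for one conformer, best (lowest feature-RMSD) first."""
    query_features = list(query_features)
    q_centers = np.asarray([q.center for q in query_features])
    feats = list(conf_features)
    poses = []
    for corr in enumerate_correspondences(query_features, conf_features):
        c_pts = np.asarray([feats[fj].center for _, fj in corr.pairs])
        q_pts = np.asarray([q_centers[qi] for qi, _ in corr.pairs])
        tfm, rmsd = kabsch_align(q_pts, c_pts)
        if verify_match(query_features, conf_features, corr, tfm, angle_cutoff):
            poses.append((rmsd, tfm, corr))
        elif _rank_deficient(c_pts):
            for rmsd2, tfm2 in _degenerate_minimizer_candidates(
                    query_features, feats, corr, q_pts, c_pts):
                if rmsd2 <= rmsd + 1e-6 and verify_match(
                        query_features, conf_features, corr, tfm2, angle_cutoff):
                    poses.append((rmsd2, tfm2, corr))
                    break
    poses.sort(key=lambda p: p[0])
    return poses[:max_poses] if max_poses is not None else poses


def search_pharmacophore(query, library, shape_constraints=None,
                         angle_cutoff: float = DEFAULT_DIRECTION_ANGLE,
                         max_poses: int = 1) -> List[AlignedHit]:
    """Pharmacophore-first search over a conformer library.

    For every conformer the best verified correspondence (lowest RMSD over
    matched feature centers) becomes a hit; the optional shape constraints
    then filter the aligned pose on heavy-atom centers only.  Hits sort by
    ascending RMSD, ties broken by (molecule_id, conformer_id).
    """
    from .shape import check_constraints_filter

    if isinstance(query, QueryDocument):
        query_features = query.enabled_features()
    else:
        query_features = [f for f in query if f.enabled]
    if not query_features:
        raise ValueError("unsearchable query: no enabled features")

    hits: List[AlignedHit] = []
    for entry in library.entries:
        for ci, conf in enumerate(entry.conformers):
            if conf.is_2d:
                continue
            conf_fs = library.features_for(entry, ci)
            poses = match_conformer(query_features, conf_fs,
                                    angle_cutoff=angle_cutoff,
                                    max_poses=max_poses)
            for rmsd, tfm, corr in poses:
                if shape_constraints is not None and not shape_constraints.is_empty():
                    aligned = conf.transformed(tfm)
                    if not check_constraints_filter(aligned, shape_constraints):
                        continue
                hits.append(AlignedHit(
                    molecule_id=entry.molecule_id, conformer_id=ci,
                    transform=tfm, rmsd=rmsd, correspondence=corr,
                    name=entry.name))
    hits.sort(key=lambda h: (h.rmsd, h.molecule_id, h.conformer_id))
    return hits
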