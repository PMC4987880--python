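"""Pharmacophore feature detection and receptor-interaction elucidation.

Six feature kinds are recognized: hydrogen-bond donors and acceptors,
positive and negative ionizable groups, aromatic rings, and hydrophobic
clusters.  Donor/acceptor/ion typing is SMARTS-driven from an editable table
shipped with the package (``data/pharmacophore_smarts.tsv``); aromatic rings
come from ring perception (5- and 6-membered aromatic rings) and hydrophobic
features from connected clusters of apolar carbons/halogens.

Feature centers: the heteroatom for donors/acceptors, the charged-group
centroid for ions, the ring centroid for aromatics, the cluster centroid for
hydrophobes.  Directions: donor = heteroatom->H (bond-vector fallback when no
explicit hydrogen is present), acceptor = approximate lone-pair direction
(negated bond-vector sum), aromatic = ring normal (either sign accepted by the
matcher).
"""
from __future__ import annotations

import importlib.resources as resources
from typing import Dict, List, Optional, Tuple

import numpy as np

from .core import (COMPLEMENT, DEFAULT_INTERACTION_CUTOFFS, DEFAULT_RADII,
                   FEATURE_KINDS, FeatureSet, Molecule, PharmacophoreFeature,
                   unit)

__all__ = [
    "PharmacophoreFeature", "FeatureSet", "load_feature_definitions",
    "detect_features", "interacting_subset",
]

_HALOGENS = {"F", "Cl", "Br", "I"}
_definitions_cache: Optional[list] = None


def load_feature_definitions(path=None) -> list:
    """Load (kind, SMARTS, center-mode) rows; the shipped table by default."""
    global _definitions_cache
    if path is None and _definitions_cache is not None:
        return _definitions_cache
    if path is None:
        text = (resources.files("pharmscreen") / "data" /
                "pharmacophore_smarts.tsv").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    rows = []
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"feature table line {lineno}: expected 3 columns")
        kind, smarts, center = parts
        if kind not in FEATURE_KINDS:
            raise ValueError(f"feature table line {lineno}: unknown kind {kind!r}")
        if center not in ("first", "all"):
            raise ValueError(f"feature table line {lineno}: bad center mode")
        rows.append((kind, smarts, center))
    if path is None:
        _definitions_cache = rows
    return rows


def _smarts_matches(rdmol, definitions) -> Dict[str, List[Tuple[int, ...]]]:
    """Matched atom-index groups per kind, deduplicated.

    Within a kind, a match whose atoms are a subset of another match is
    dropped (e.g. the bare ``[O-]`` of a carboxylate in favor of the whole
    group), and duplicate centers collapse to one feature.
    """
    from rdkit import Chem

    by_kind: Dict[str, List[Tuple[int, ...]]] = {}
    for kind, smarts, center in definitions:
        patt = Chem.MolFromSmarts(smarts)
        if patt is None:
            raise ValueError(f"invalid SMARTS in feature table: {smarts!r}")
        for match in rdmol.GetSubstructMatches(patt, uniquify=True):
            group = (match[0],) if center == "first" else tuple(sorted(match))
            by_kind.setdefault(kind, []).append(group)
    deduped: Dict[str, List[Tuple[int, ...]]] = {}
    for kind, groups in by_kind.items():
        groups = sorted(set(groups), key=lambda g: (-len(g), g))
        kept: List[Tuple[int, ...]] = []
        for g in groups:
            if any(set(g) <= set(k) for k in kept):
                continue
            kept.append(g)
        deduped[kind] = sorted(kept)
    return deduped


def _donor_direction(rdmol, coords, idx) -> Optional[np.ndarray]:
    atom = rdmol.GetAtomWithIdx(int(idx))
    h_vecs = [coords[n.GetIdx()] - coords[idx] for n in atom.GetNeighbors()
              if n.GetSymbol() == "H"]
    if h_vecs:
        return unit(np.sum(h_vecs, axis=0))
    heavy = [coords[n.GetIdx()] - coords[idx] for n in atom.GetNeighbors()]
    if not heavy:
        return None
    return unit(-np.sum(heavy, axis=0))


def _acceptor_direction(rdmol, coords, idx) -> Optional[np.ndarray]:
    atom = rdmol.GetAtomWithIdx(int(idx))
    vecs = [coords[n.GetIdx()] - coords[idx] for n in atom.GetNeighbors()]
    if not vecs:
        return None
    return unit(-np.sum(vecs, axis=0))


def _ring_normal(coords, ring) -> Optional[np.ndarray]:
    pts = coords[list(ring)]
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    return unit(vt[2])


def _hydrophobic_clusters(rdmol) -> List[Tuple[int, ...]]:
    """Connected clusters (size >= 2) of apolar carbons and halogens.

    An atom qualifies if it is C or halogen, carries no formal charge, and has
    no charged neighbor nor a direct bond to N/O/S (keeps e.g. benzene rings
    and alkyl chains, rejects carbinol/carbonyl carbons).
    """
    candidates = set()
    for atom in rdmol.GetAtoms():
        sym = atom.GetSymbol()
        if sym != "C" and sym not in _HALOGENS:
            continue
        if atom.GetFormalCharge() != 0:
            continue
        ok = True
        for n in atom.GetNeighbors():
            if n.GetFormalCharge() != 0 or n.GetSymbol() in ("N", "O", "S"):
                ok = False
                break
        if ok:
            candidates.add(atom.GetIdx())
    clusters, seen = [], set()
    for start in sorted(candidates):
        if start in seen:
            continue
        comp, stack = [], [start]
        seen.add(start)
        while stack:
            i = stack.pop()
            comp.append(i)
            for n in rdmol.GetAtomWithIdx(i).GetNeighbors():
                j = n.GetIdx()
                if j in candidates and j not in seen:
                    seen.add(j)
                    stack.append(j)
        if len(comp) >= 2:
            clusters.append(tuple(sorted(comp)))
    return clusters


def detect_features(mol: Molecule, definitions=None, radii=None,
                    source: str = "ligand") -> FeatureSet:
    """Detect all pharmacophore features on a 3D molecule."""
    if mol.is_2d:
        raise ValueError("feature detection requires 3D coordinates")
    if definitions is None:
        definitions = load_feature_definitions()
    radii = {**DEFAULT_RADII, **(radii or {})}
    rdmol = mol.to_rdkit()
    coords = mol.coords

    features: List[PharmacophoreFeature] = []
    for kind, groups in _smarts_matches(rdmol, definitions).items():
        for group in groups:
            center = coords[list(group)].mean(axis=0)
            direction = None
            if kind == "HydrogenDonor":
                direction = _donor_direction(rdmol, coords, group[0])
            elif kind == "HydrogenAcceptor":
                direction = _acceptor_direction(rdmol, coords, group[0])
            features.append(PharmacophoreFeature(
                kind=kind, center=center, radius=radii[kind],
                direction=direction, member_atoms=group))

    ri = rdmol.GetRingInfo()
    for ring in ri.AtomRings():
        if len(ring) not in (5, 6):
            continue
        if not all(rdmol.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
            continue
        center = coords[list(ring)].mean(axis=0)
        features.append(PharmacophoreFeature(
            kind="Aromatic", center=center, radius=radii["Aromatic"],
            direction=_ring_normal(coords, ring), member_atoms=tuple(sorted(ring))))

    for cluster in _hydrophobic_clusters(rdmol):
        center = coords[list(cluster)].mean(axis=0)
        features.append(PharmacophoreFeature(
            kind="Hydrophobic", center=center, radius=radii["Hydrophobic"],
            minsize=len(cluster), member_atoms=cluster))

    features.sort(key=lambda f: (FEATURE_KINDS.index(f.kind), f.member_atoms))
    return FeatureSet(features=features, source=source)


def interacting_subset(ligand_fs: FeatureSet, receptor_fs: FeatureSet,
                       cutoffs=None) -> FeatureSet:
    """Enable the ligand features that interact with the receptor.

    A ligand feature is enabled iff a complementary receptor feature
    (donor<->acceptor, +<->-, aromatic<->aromatic, hydrophobic<->hydrophobic)
    lies within the kind's center-distance cutoff.  All features are returned
    so disabled ones can be re-enabled interactively.
    """
    cutoffs = {**DEFAULT_INTERACTION_CUTOFFS, **(cutoffs or {})}
    rec_centers: Dict[str, np.ndarray] = {}
    for kind in FEATURE_KINDS:
        pts = [f.center for f in receptor_fs.by_kind(kind)]
        rec_centers[kind] = np.asarray(pts).reshape(-1, 3)
    out = []
    for f in ligand_fs:
        partner = rec_centers[COMPLEMENT[f.kind]]
        enabled = False
        if partner.size:
            d = np.linalg.norm(partner - f.center, axis=1)
            enabled = bool((d <= cutoffs[f.kind]).any())
        out.append(PharmacophoreFeature(
            kind=f.kind, center=f.center, radius=f.radius, direction=f.direction,
            minsize=f.minsize, enabled=enabled, member_atoms=f.member_atoms))
    return FeatureSet(features=out, source="ligand")
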