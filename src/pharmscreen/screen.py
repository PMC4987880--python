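"""End-to-end screening: modality dispatch, filters, caps, metrics, export.

Two modalities exist.  ``pharmacophore_first`` aligns conformers to minimize
feature RMSD and optionally filters the aligned poses with heavy-atom-center
shape constraints; ``shape_first`` matches inertia-canonical voxel shapes
under strict containment/avoidance semantics and optionally filters poses by
feature-sphere containment.  Either way, drug-likeness property ranges prune
entries before the structural search, and hit caps (poses per conformer,
conformers per molecule, total) prune the ranked results afterwards.

Benchmark metrics mirror common virtual-screening practice: when library
names carry an "active" keyword, the enrichment factor EF = (a/n)/(A/N) and
the F1 score of retrieval are reported over distinct molecules.
"""
from __future__ import annotations

import gzip
import io
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import QueryDocument, Molecule, logger
from . import featurize, pharma_search, shape as shape_mod
from .libbuild import ConformerLibrary, LibraryEntry
from .pharma_search import AlignedHit

__all__ = [
    "ScreenConfig", "ScreenResult", "apply_property_filter", "apply_caps",
    "enrichment_metrics", "run_screen", "export_hits_sdf",
    "external_minimizer_hook",
]

_SORT_KEYS = ("rmsd", "similarity", "molweight", "rotatable_bonds")


@dataclass
class ScreenConfig:
    modality: str = "pharmacophore_first"  # or "shape_first"
    prop_ranges: Dict[str, Tuple[Optional[float], Optional[float]]] = field(
        default_factory=dict)
    max_poses_per_conformer: Optional[int] = None
    max_confs_per_molecule: Optional[int] = None
    max_total_hits: Optional[int] = None
    sort_key: Optional[str] = None  # default depends on modality
    sort_ascending: Optional[bool] = None
    resolution: float = 0.5
    probe: float = 1.4
    active_keyword: str = "active"
    f1_mode: str = "harmonic"  # or "geometric"

    def __post_init__(self):
        if self.modality not in ("pharmacophore_first", "shape_first"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.sort_key is not None and self.sort_key not in _SORT_KEYS:
            raise ValueError(f"unknown sort key {self.sort_key!r}")
        for cap in (self.max_poses_per_conformer, self.max_confs_per_molecule):
            if cap is not None and cap < 1:
                raise ValueError("per-conformer/per-molecule caps must be >= 1")
        if self.max_total_hits is not None and self.max_total_hits < 0:
            raise ValueError("max_total_hits must be >= 0")
        for prop, (lo, hi) in self.prop_ranges.items():
            if lo is not None and hi is not None and lo > hi:
                raise ValueError(f"range for {prop!r} has min > max")


@dataclass
class ScreenResult:
    hits: List[AlignedHit]
    n_molecules_searched: int
    n_conformers_searched: int
    metrics: Optional[dict] = None


def apply_property_filter(entries: Sequence[LibraryEntry],
                          prop_ranges) -> List[LibraryEntry]:
    """Keep entries whose every specified property lies in its closed range."""
    if not prop_ranges:
        return list(entries)
    out = []
    for e in entries:
        props = e.properties.as_dict()
        ok = True
        for key, (lo, hi) in prop_ranges.items():
            if key not in props:
                raise KeyError(f"unknown property {key!r}")
            v = props[key]
            if (lo is not None and v < lo) or (hi is not None and v > hi):
                ok = False
                break
        if ok:
            out.append(e)
    return out


def apply_caps(hits: Sequence[AlignedHit], config: ScreenConfig
               ) -> List[AlignedHit]:
    """Cap hits (already sorted by the active key): best poses per conformer,
    then best conformers per molecule, then total; stable."""
    out = list(hits)
    if config.max_poses_per_conformer is not None:
        counts: Dict[Tuple[str, int], int] = {}
        kept = []
        for h in out:
            key = (h.molecule_id, h.conformer_id)
            if counts.get(key, 0) < config.max_poses_per_conformer:
                counts[key] = counts.get(key, 0) + 1
                kept.append(h)
        out = kept
    if config.max_confs_per_molecule is not None:
        conf_seen: Dict[str, set] = {}
        kept = []
        for h in out:
            seen = conf_seen.setdefault(h.molecule_id, set())
            if h.conformer_id in seen or len(seen) < config.max_confs_per_molecule:
                seen.add(h.conformer_id)
                kept.append(h)
        out = kept
    if config.max_total_hits is not None:
        out = out[:config.max_total_hits]
    return out


def enrichment_metrics(hits: Sequence[AlignedHit], library: ConformerLibrary,
                       active_keyword: str = "active",
                       f1_mode: str = "harmonic") -> dict:
    """EF and F1 of a screen against a library whose active compounds carry
    *active_keyword* (case-insensitive substring) in their names.

    Counting is over distinct molecules: with A actives of N library
    molecules and a actives among the n distinct hit molecules,
    EF = (a/n)/(A/N), recall = a/A, precision = a/n and F1 combines the two
    (harmonic mean by default, geometric under ``f1_mode="geometric"``).
    """
    kw = active_keyword.lower()
    names = {e.molecule_id: e.name for e in library.entries}
    active_ids = {mid for mid, nm in names.items() if kw in nm.lower()}
    n_total = len(library.entries)
    n_actives = len(active_ids)
    if n_actives == 0:
        raise ValueError("no actives in library")
    hit_ids = {h.molecule_id for h in hits}
    n = len(hit_ids)
    a = len(hit_ids & active_ids)
    if n == 0:
        return {"ef": None, "f1": None, "recall": None, "precision": None,
                "n_actives_in_hits": 0, "n_hit_molecules": 0,
                "n_actives": n_actives, "n_molecules": n_total}
    precision = a / n
    recall = a / n_actives
    ef = precision / (n_actives / n_total)
    if precision + recall == 0:
        f1 = 0.0
    elif f1_mode == "geometric":
        f1 = math.sqrt(precision * recall)
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return {"ef": ef, "f1": f1, "recall": recall, "precision": precision,
            "n_actives_in_hits": a, "n_hit_molecules": n,
            "n_actives": n_actives, "n_molecules": n_total}


def _sort_hits(hits: List[AlignedHit], library: ConformerLibrary,
               config: ScreenConfig) -> List[AlignedHit]:
    key = config.sort_key
    if key is None:
        key = "rmsd" if config.modality == "pharmacophore_first" else "similarity"
    ascending = config.sort_ascending
    if ascending is None:
        ascending = key in ("rmsd", "molweight", "rotatable_bonds")
    props = {e.molecule_id: e.properties for e in library.entries}

    def value(h: AlignedHit):
        if key == "rmsd":
            return h.rmsd if h.rmsd is not None else math.inf
        if key == "similarity":
            return h.shape_similarity if h.shape_similarity is not None else -math.inf
        return getattr(props[h.molecule_id], key)

    return sorted(hits, key=lambda h: ((value(h) if ascending else -value(h)),
                                       h.molecule_id, h.conformer_id))


def _shape_constraints_from_query(query: QueryDocument,
                                  config: ScreenConfig,
                                  exclusive_grid=None,
                                  inclusive_grid=None,
                                  inclusive_tolerance: float = 0.0,
                                  exclusive_tolerance: float = 0.0):
    inc = inclusive_grid
    exc = exclusive_grid
    if inc is None and query.inclusive_spheres:
        inc = shape_mod.rasterize_spheres(query.inclusive_spheres,
                                          config.resolution)
    if exc is None and query.exclusive_spheres:
        exc = shape_mod.rasterize_spheres(query.exclusive_spheres,
                                          config.resolution)
    if inc is None and exc is None:
        return None
    return shape_mod.ShapeConstraints(
        inclusive=inc, exclusive=exc,
        inclusive_tolerance=inclusive_tolerance,
        exclusive_tolerance=exclusive_tolerance)


def run_screen(query: QueryDocument, library: ConformerLibrary,
               config: Optional[ScreenConfig] = None,
               query_ligand: Optional[Molecule] = None,
               exclusive_grid=None, inclusive_grid=None,
               inclusive_tolerance: float = 0.0,
               exclusive_tolerance: float = 0.0) -> ScreenResult:
    """Run one screen end to end and return ranked, capped, annotated hits.

    *query_ligand* supplies the reference shape (and its inertia-canonical
    frame) for the shape-first modality; manual spheres or explicit grids may
    stand in for it.  Metrics are attached when any library name contains the
    active keyword.
    """
    config = config or ScreenConfig()
    entries = apply_property_filter(library.entries, config.prop_ranges)
    filtered = ConformerLibrary(entries=entries)
    # share lazily-computed shapes/features with the parent library
    filtered._shape_cache = library._shape_cache
    logger.info("screen: %d/%d entries pass property filters",
                len(entries), len(library.entries))

    constraints = _shape_constraints_from_query(
        query, config, exclusive_grid=exclusive_grid,
        inclusive_grid=inclusive_grid,
        inclusive_tolerance=inclusive_tolerance,
        exclusive_tolerance=exclusive_tolerance)

    if config.modality == "pharmacophore_first":
        hits = pharma_search.search_pharmacophore(
            query, filtered, shape_constraints=constraints,
            max_poses=config.max_poses_per_conformer or 1)
    else:
        query_shape = None
        canon = None
        if query_ligand is not None:
            canon = shape_mod.inertia_canonicalize(query_ligand)
            query_shape = shape_mod.voxelize_sev(
                query_ligand.transformed(canon), resolution=config.resolution,
                probe=config.probe)
        pharma_filter = None
        feats = query.enabled_features()
        if feats:
            if canon is not None:
                pharma_filter = [f.moved(canon) for f in feats]
            else:
                pharma_filter = feats
        if constraints is None:
            constraints = shape_mod.ShapeConstraints()
        hits = shape_mod.search_shape(
            constraints, filtered, query_shape=query_shape,
            pharma_filter=pharma_filter, resolution=config.resolution,
            probe=config.probe)

    hits = _sort_hits(hits, library, config)
    hits = apply_caps(hits, config)
    logger.info("screen: %d hits after caps", len(hits))

    kw = config.active_keyword.lower()
    metrics = None
    if any(kw in e.name.lower() for e in library.entries):
        metrics = enrichment_metrics(hits, library,
                                     active_keyword=config.active_keyword,
                                     f1_mode=config.f1_mode)
    return ScreenResult(hits=hits,
                        n_molecules_searched=len(entries),
                        n_conformers_searched=sum(len(e.conformers)
                                                  for e in entries),
                        metrics=metrics)


def export_hits_sdf(result_or_hits, library: ConformerLibrary, path) -> None:
    """Write query-aligned hit poses as a (gzipped) SDF with score SD tags."""
    from rdkit import Chem

    hits = result_or_hits.hits if isinstance(result_or_hits, ScreenResult) \
        else list(result_or_hits)
    buf = io.StringIO()
    writer = Chem.SDWriter(buf)
    writer.SetKekulize(False)
    for h in hits:
        entry = library.entry_by_id(h.molecule_id)
        conf = entry.conformers[h.conformer_id].transformed(h.transform)
        rd = conf.to_rdkit()
        rd.SetProp("_Name", entry.name)
        rd.SetProp("molecule_id", h.molecule_id)
        rd.SetProp("conformer_id", str(h.conformer_id))
        if h.rmsd is not None:
            rd.SetProp("ps_rmsd", f"{h.rmsd:.6f}")
        if h.shape_similarity is not None:
            rd.SetProp("ps_similarity", f"{h.shape_similarity:.6f}")
        writer.write(rd)
    writer.close()
    if str(path).endswith(".gz"):
        # fixed mtime/name keep byte-identical exports across runs
        with open(path, "wb") as raw:
            with gzip.GzipFile(fileobj=raw, mode="wb", filename="", mtime=0) as fh:
                fh.write(buf.getvalue().encode())
    else:
        with open(path, "w") as fh:
            fh.write(buf.getvalue())


def external_minimizer_hook(hits: Sequence[AlignedHit], score_fn,
                            max_mrmsd: Optional[float] = None,
                            max_affinity: Optional[float] = None
                            ) -> List[AlignedHit]:
    """Adapter hook for an external pose minimizer/scorer.

    *score_fn* maps an AlignedHit to (affinity kcal/mol, mrmsd angstrom) —
    typically by shelling out to an external minimization tool; no scoring
    function is implemented here.  Hits are re-sorted by ascending affinity
    and optionally filtered on affinity/mrmsd bounds.
    """
    scored = []
    for h in hits:
        affinity, mrmsd = score_fn(h)
        if max_affinity is not None and affinity > max_affinity:
            continue
        if max_mrmsd is not None and mrmsd > max_mrmsd:
            continue
        scored.append((affinity, mrmsd, h))
    scored.sort(key=lambda t: (t[0], t[1], t[2].molecule_id))
    return [h for _, _, h in scored]
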