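"""Voxelized molecular shapes and shape-first search.

Molecular volumes are solvent-excluded volumes (SEV) rasterized on a fixed
0.5 A grid: the union of heavy-atom van der Waals spheres morphologically
closed with a probe-radius ball (dilate then erode), a standard grid
approximation of the surface traced by a rolling solvent probe.  Grid origins
are snapped to the resolution lattice so grids built in the same frame share a
global voxel indexing and set operations (Tanimoto, containment) are exact.

Shape-first matching follows the strict semantics: the entire inclusive
constraint must lie inside the molecular shape and the shape must not touch
the exclusive constraint, with molecules compared in inertia-canonical frames
and ranked by voxel Tanimoto similarity to the query ligand shape.  When the
shape query instead filters a pharmacophore-aligned pose, only heavy-atom
centers are tested against the constraint grids.
"""
from __future__ import annotations

import importlib.resources as resources
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .core import FeatureSet, Molecule, RigidTransform, Sphere, logger

__all__ = [
    "ShapeGrid", "ShapeConstraints", "voxelize_sev", "rasterize_spheres",
    "grow_shrink", "inertia_canonicalize", "shape_tanimoto",
    "check_constraints_strict", "check_constraints_filter", "search_shape",
    "AXIS_FLIPS",
]

DEFAULT_RESOLUTION = 0.5  # angstrom per voxel
DEFAULT_PROBE = 1.4       # water-probe radius, angstrom

#: The four proper sign choices of a principal-axis frame.
AXIS_FLIPS = tuple(
    np.diag(s) for s in
    [(1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)]
)

_vdw_cache: Optional[Dict[str, float]] = None


def vdw_radius(element: str) -> float:
    global _vdw_cache
    if _vdw_cache is None:
        text = (resources.files("pharmscreen") / "data" / "vdw_radii.tsv").read_text()
        _vdw_cache = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            el, r = line.split("\t")
            _vdw_cache[el] = float(r)
    return _vdw_cache.get(element, 1.7)


@dataclass
class ShapeGrid:
    """Voxel occupancy on a lattice anchored at multiples of *resolution*."""

    origin: np.ndarray
    resolution: float
    occupancy: np.ndarray  # bool array, shape dims

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.occupancy = np.asarray(self.occupancy, dtype=bool)
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")

    @property
    def dims(self) -> Tuple[int, int, int]:
        return tuple(self.occupancy.shape)

    @property
    def occupied(self) -> set:
        """Occupied voxel indices (local to this grid)."""
        return set(map(tuple, np.argwhere(self.occupancy)))

    @property
    def count(self) -> int:
        return int(self.occupancy.sum())

    @property
    def volume(self) -> float:
        return self.count * self.resolution ** 3

    def voxel_center(self, idx) -> np.ndarray:
        return self.origin + (np.asarray(idx, dtype=float) + 0.5) * self.resolution

    def global_indices(self) -> set:
        """Occupied voxels as indices on the shared resolution lattice."""
        base = np.round(self.origin / self.resolution).astype(int)
        occ = np.argwhere(self.occupancy)
        return set(map(tuple, occ + base))

    def contains_points(self, pts: np.ndarray) -> np.ndarray:
        """Boolean mask: which points fall in an occupied voxel."""
        pts = np.asarray(pts, dtype=float).reshape(-1, 3)
        idx = np.floor((pts - self.origin) / self.resolution).astype(int)
        ok = np.all((idx >= 0) & (idx < np.array(self.dims)), axis=1)
        out = np.zeros(len(pts), dtype=bool)
        if ok.any():
            sel = idx[ok]
            out[ok] = self.occupancy[sel[:, 0], sel[:, 1], sel[:, 2]]
        return out

    def is_empty(self) -> bool:
        return not self.occupancy.any()


def _ball(radius_vox: int) -> np.ndarray:
    if radius_vox <= 0:
        return np.ones((1, 1, 1), dtype=bool)
    r = radius_vox
    ax = np.arange(-r, r + 1)
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    return x * x + y * y + z * z <= r * r


def _snap(v: np.ndarray, resolution: float) -> np.ndarray:
    return np.floor(v / resolution) * resolution


def voxelize_sev(mol: Molecule, resolution: float = DEFAULT_RESOLUTION,
                 probe: float = DEFAULT_PROBE) -> ShapeGrid:
    """Solvent-excluded volume of the heavy atoms on a voxel grid."""
    if mol.is_2d:
        raise ValueError("shape computation requires 3D coordinates")
    heavy = mol.heavy_indices
    coords = mol.coords[heavy]
    radii = np.array([vdw_radius(mol.atoms[i].element) for i in heavy])
    pad = 2.0 * (radii.max() + probe)
    origin = _snap(coords.min(axis=0) - pad, resolution)
    upper = coords.max(axis=0) + pad
    dims = np.ceil((upper - origin) / resolution).astype(int)
    occ = np.zeros(tuple(dims), dtype=bool)
    for pos, r in zip(coords, radii):
        lo = np.maximum(np.floor((pos - r - origin) / resolution).astype(int), 0)
        hi = np.minimum(np.ceil((pos + r - origin) / resolution).astype(int) + 1, dims)
        if np.any(lo >= hi):
            continue
        ax = [np.arange(lo[k], hi[k]) for k in range(3)]
        centers = [origin[k] + (ax[k] + 0.5) * resolution for k in range(3)]
        dx = (centers[0] - pos[0])[:, None, None] ** 2
        dy = (centers[1] - pos[1])[None, :, None] ** 2
        dz = (centers[2] - pos[2])[None, None, :] ** 2
        occ[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= (dx + dy + dz) <= r * r
    probe_vox = int(round(probe / resolution))
    if probe_vox > 0:
        ball = _ball(probe_vox)
        occ = ndimage.binary_erosion(ndimage.binary_dilation(occ, ball), ball)
    return ShapeGrid(origin=origin, resolution=resolution, occupancy=occ)


def rasterize_spheres(spheres: Sequence[Sphere],
                      resolution: float = DEFAULT_RESOLUTION) -> ShapeGrid:
    """Rasterize manual inclusion/exclusion spheres onto a grid."""
    if not spheres:
        raise ValueError("no spheres to rasterize")
    centers = np.array([s.center for s in spheres], dtype=float)
    radii = np.array([s.radius for s in spheres], dtype=float)
    pad = radii.max() + resolution
    origin = _snap(centers.min(axis=0) - pad, resolution)
    upper = centers.max(axis=0) + pad
    dims = np.ceil((upper - origin) / resolution).astype(int)
    occ = np.zeros(tuple(dims), dtype=bool)
    grid = ShapeGrid(origin=origin, resolution=resolution, occupancy=occ)
    for pos, r in zip(centers, radii):
        lo = np.maximum(np.floor((pos - r - origin) / resolution).astype(int), 0)
        hi = np.minimum(np.ceil((pos + r - origin) / resolution).astype(int) + 1, dims)
        ax = [np.arange(lo[k], hi[k]) for k in range(3)]
        cc = [origin[k] + (ax[k] + 0.5) * resolution for k in range(3)]
        dx = (cc[0] - pos[0])[:, None, None] ** 2
        dy = (cc[1] - pos[1])[None, :, None] ** 2
        dz = (cc[2] - pos[2])[None, None, :] ** 2
        occ[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= (dx + dy + dz) <= r * r
    return grid


def grow_shrink(grid: ShapeGrid, delta: float) -> ShapeGrid:
    """Dilate (delta > 0) or erode (delta < 0) by round(|delta|/resolution)
    voxel shells with a Euclidean-ball structuring element."""
    n = int(round(abs(delta) / grid.resolution))
    if n == 0:
        return ShapeGrid(grid.origin.copy(), grid.resolution, grid.occupancy.copy())
    ball = _ball(n)
    if delta > 0:
        # pad so dilation cannot run off the array
        occ = np.pad(grid.occupancy, n)
        occ = ndimage.binary_dilation(occ, ball)
        origin = grid.origin - n * grid.resolution
    else:
        occ = ndimage.binary_erosion(grid.occupancy, ball)
        origin = grid.origin.copy()
    return ShapeGrid(origin=origin, resolution=grid.resolution, occupancy=occ)


@dataclass
class ShapeConstraints:
    """Inclusive/exclusive shape constraints with grow/shrink tolerances.

    A positive tolerance shrinks (erodes) the stored constraint volume, making
    the constraint more permissive; a negative one grows it.
    """

    inclusive: Optional[ShapeGrid] = None
    exclusive: Optional[ShapeGrid] = None
    inclusive_tolerance: float = 0.0
    exclusive_tolerance: float = 0.0

    @classmethod
    def from_spheres(cls, inclusive: Sequence[Sphere] = (),
                     exclusive: Sequence[Sphere] = (),
                     resolution: float = DEFAULT_RESOLUTION,
                     **kw) -> "ShapeConstraints":
        inc = rasterize_spheres(inclusive, resolution) if inclusive else None
        exc = rasterize_spheres(exclusive, resolution) if exclusive else None
        return cls(inclusive=inc, exclusive=exc, **kw)

    def effective(self) -> Tuple[Optional[ShapeGrid], Optional[ShapeGrid]]:
        inc, exc = self.inclusive, self.exclusive
        if inc is not None and self.inclusive_tolerance != 0.0:
            inc = grow_shrink(inc, -self.inclusive_tolerance)
        if exc is not None and self.exclusive_tolerance != 0.0:
            exc = grow_shrink(exc, -self.exclusive_tolerance)
        return inc, exc

    def is_empty(self) -> bool:
        return self.inclusive is None and self.exclusive is None


def inertia_canonicalize(mol: Molecule, return_info: bool = False):
    """Transform mapping the molecule into its inertia-canonical frame.

    The heavy-atom centroid goes to the origin and the principal axes of the
    unit-mass second-moment (gyration) tensor align with x, y, z in order of
    decreasing eigenvalue.  Of the four proper sign choices, the canonical one
    makes the third moments along x and y non-negative (z sign follows from
    det=+1).  Near-degenerate eigenvalue spectra or vanishing third moments
    are flagged in the optional info dict; downstream shape search evaluates
    all four proper flips anyway, so the convention only affects ranking
    determinism, not correctness.
    """
    heavy = mol.heavy_coords
    if len(heavy) < 3:
        raise ValueError("inertia frame needs at least 3 heavy atoms")
    centroid = heavy.mean(axis=0)
    centered = heavy - centroid
    cov = centered.T @ centered / len(centered)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    axes = evecs[:, order].T  # rows = principal axes
    if np.linalg.det(axes) < 0:
        axes[2] = -axes[2]
    local = centered @ axes.T
    m3 = (local ** 3).sum(axis=0)
    degenerate_spectrum = bool(
        np.min(np.abs(np.diff(evals))) < 1e-4 * max(evals.max(), 1.0))
    ambiguous_sign = bool(min(abs(m3[0]), abs(m3[1])) < 1e-6 * max(1.0, np.abs(m3).max()))
    s0 = 1.0 if m3[0] >= 0 else -1.0
    s1 = 1.0 if m3[1] >= 0 else -1.0
    flip = np.diag([s0, s1, s0 * s1])
    rotation = flip @ axes
    tfm = RigidTransform(rotation, -rotation @ centroid)
    if return_info:
        return tfm, {"eigenvalues": evals, "degenerate": degenerate_spectrum,
                     "ambiguous_sign": ambiguous_sign}
    return tfm


def shape_tanimoto(a: ShapeGrid, b: ShapeGrid) -> float:
    """Intersection-over-union of occupied voxels (grids in a common frame)."""
    if abs(a.resolution - b.resolution) > 1e-9:
        raise ValueError("shape grids must share a resolution")
    sa, sb = a.global_indices(), b.global_indices()
    union = len(sa | sb)
    if union == 0:
        return 0.0
    return len(sa & sb) / union


def check_constraints_strict(mol_shape: ShapeGrid,
                             constraints: ShapeConstraints) -> bool:
    """Strict (shape-first) semantics: the whole inclusive constraint lies
    inside the molecular shape; no molecular voxel touches the exclusive."""
    inc, exc = constraints.effective()
    mol_set = mol_shape.global_indices()
    if inc is not None and not inc.global_indices() <= mol_set:
        return False
    if exc is not None and mol_set & exc.global_indices():
        return False
    return True


def check_constraints_filter(aligned_mol: Molecule,
                             constraints: ShapeConstraints) -> bool:
    """Filter (pharmacophore-first) semantics on heavy-atom centers: at least
    one center inside the inclusive volume, none inside the exclusive."""
    inc, exc = constraints.effective()
    pts = aligned_mol.heavy_coords
    if inc is not None and not inc.is_empty():
        if not inc.contains_points(pts).any():
            return False
    if exc is not None and exc.contains_points(pts).any():
        return False
    return True


def _feature_filter_in_pose(query_features, conf_fs: FeatureSet) -> bool:
    """Every enabled query sphere must contain a same-kind conformer feature
    in the already-aligned pose (no re-alignment)."""
    for q in query_features:
        ok = False
        for f in conf_fs.by_kind(q.kind):
            if np.linalg.norm(f.center - q.center) <= q.radius:
                if q.minsize is not None and (f.minsize or 0) < q.minsize:
                    continue
                ok = True
                break
        if not ok:
            return False
    return True


def search_shape(constraints: ShapeConstraints, library,
                 query_shape: Optional[ShapeGrid] = None,
                 pharma_filter=None,
                 resolution: float = DEFAULT_RESOLUTION,
                 probe: float = DEFAULT_PROBE) -> list:
    """Shape-first search over a conformer library.

    Each conformer is placed in its inertia-canonical frame; all four proper
    axis flips are tested against the strict constraint semantics and the best
    passing flip (highest Tanimoto vs *query_shape*) is kept.  Results sort by
    descending shape similarity.  *pharma_filter* (enabled query features, in
    the same canonical frame) prunes poses whose features miss the tolerance
    spheres; it never re-aligns.
    """
    from .pharma_search import AlignedHit  # local import to avoid a cycle

    if query_shape is None and (constraints.inclusive is None):
        raise ValueError("shape search needs a query ligand shape or an "
                         "inclusive constraint")
    reference = query_shape if query_shape is not None else constraints.effective()[0]
    qfeats = list(pharma_filter) if pharma_filter is not None else None

    hits = []
    for entry in library.entries:
        for ci, conf in enumerate(entry.conformers):
            if conf.is_2d:
                continue
            try:
                canon = inertia_canonicalize(conf)
            except ValueError:
                continue
            best = None
            for flip in AXIS_FLIPS:
                tfm = RigidTransform(flip @ canon.rotation, flip @ canon.translation)
                posed = conf.transformed(tfm)
                grid = voxelize_sev(posed, resolution=resolution, probe=probe)
                if not check_constraints_strict(grid, constraints):
                    continue
                if qfeats is not None:
                    conf_fs = library.features_for(entry, ci).moved(tfm)
                    if not _feature_filter_in_pose(qfeats, conf_fs):
                        continue
                sim = shape_tanimoto(grid, reference)
                if best is None or sim > best[0]:
                    best = (sim, tfm)
            if best is not None:
                hits.append(AlignedHit(
                    molecule_id=entry.molecule_id, conformer_id=ci,
                    transform=best[1], rmsd=None, shape_similarity=best[0]))
    hits.sort(key=lambda h: (-h.shape_similarity, h.molecule_id, h.conformer_id))
    return hits
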