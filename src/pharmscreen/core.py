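"""Shared dataclasses and constants used across the screening pipeline.

Coordinates are Cartesian angstroms everywhere; no unit conversion happens
inside the package.  A :class:`Molecule` is a single conformer; multi-conformer
compounds are represented by the library layer as lists of molecules sharing a
topology.
"""
from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple, Optional, Sequence

import numpy as np

logger = logging.getLogger("pharmscreen")

#: The six supported pharmacophore feature kinds.
FEATURE_KINDS = (
    "HydrogenAcceptor",
    "HydrogenDonor",
    "NegativeIon",
    "PositiveIon",
    "Aromatic",
    "Hydrophobic",
)

#: Default tolerance-sphere radii per kind (angstrom).
DEFAULT_RADII = {
    "HydrogenAcceptor": 1.0,
    "HydrogenDonor": 1.0,
    "NegativeIon": 1.0,
    "PositiveIon": 1.0,
    "Aromatic": 1.1,
    "Hydrophobic": 1.1,
}

#: Complementary kind on the receptor side for ligand-receptor interaction
#: elucidation.
COMPLEMENT = {
    "HydrogenDonor": "HydrogenAcceptor",
    "HydrogenAcceptor": "HydrogenDonor",
    "NegativeIon": "PositiveIon",
    "PositiveIon": "NegativeIon",
    "Aromatic": "Aromatic",
    "Hydrophobic": "Hydrophobic",
}

#: Default ligand-receptor feature-center distance cutoffs (angstrom), keyed by
#: the ligand-side kind.
DEFAULT_INTERACTION_CUTOFFS = {
    "HydrogenDonor": 4.0,
    "HydrogenAcceptor": 4.0,
    "NegativeIon": 5.0,
    "PositiveIon": 5.0,
    "Aromatic": 5.0,
    "Hydrophobic": 5.0,
}

#: Angle cutoff (degrees) used when verifying directional features.
DEFAULT_DIRECTION_ANGLE = 45.0


class Atom(NamedTuple):
    element: str
    position: tuple  # (x, y, z) in angstrom
    formal_charge: int = 0


class Bond(NamedTuple):
    i: int
    j: int
    order: float  # 1, 2, 3 or 1.5 for aromatic


@dataclass
class Molecule:
    """One conformer of one compound: elements, coordinates, bonds, charges."""

    name: str = ""
    atoms: list = field(default_factory=list)  # list[Atom]
    bonds: list = field(default_factory=list)  # list[Bond]
    source_id: Optional[str] = None
    is_2d: bool = False
    _rdmol: object = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if not self.atoms:
            raise ValueError("a molecule needs at least one atom")
        coords = np.asarray([a.position for a in self.atoms], dtype=float)
        if not np.isfinite(coords).all():
            raise ValueError("non-finite atom coordinates")
        n = len(self.atoms)
        for b in self.bonds:
            if not (0 <= b.i < n and 0 <= b.j < n and b.i != b.j):
                raise ValueError(f"bond {b} has invalid atom indices")

    # -- geometry -----------------------------------------------------------
    @property
    def coords(self) -> np.ndarray:
        return np.asarray([a.position for a in self.atoms], dtype=float)

    @property
    def elements(self) -> list:
        return [a.element for a in self.atoms]

    @property
    def heavy_indices(self) -> np.ndarray:
        return np.asarray(
            [i for i, a in enumerate(self.atoms) if a.element != "H"], dtype=int
        )

    @property
    def heavy_coords(self) -> np.ndarray:
        return self.coords[self.heavy_indices]

    def num_atoms(self) -> int:
        return len(self.atoms)

    def with_coords(self, coords: np.ndarray, name: Optional[str] = None) -> "Molecule":
        coords = np.asarray(coords, dtype=float)
        atoms = [
            Atom(a.element, tuple(c), a.formal_charge)
            for a, c in zip(self.atoms, coords)
        ]
        return Molecule(
            name=self.name if name is None else name,
            atoms=atoms,
            bonds=list(self.bonds),
            source_id=self.source_id,
            is_2d=self.is_2d,
            _rdmol=self._rdmol,
        )

    def transformed(self, tfm: "RigidTransform") -> "Molecule":
        return self.with_coords(tfm.apply(self.coords))

    # -- RDKit bridge -------------------------------------------------------
    @classmethod
    def from_rdkit(cls, rdmol, conf_id: int = -1, name: Optional[str] = None,
                   source_id: Optional[str] = None, is_2d: bool = False) -> "Molecule":
        from rdkit import Chem

        if name is None:
            name = rdmol.GetProp("_Name") if rdmol.HasProp("_Name") else ""
        if is_2d or rdmol.GetNumConformers() == 0:
            coords = np.zeros((rdmol.GetNumAtoms(), 3))
            is_2d = True
        else:
            coords = rdmol.GetConformer(conf_id).GetPositions()
        atoms = [
            Atom(a.GetSymbol(), tuple(coords[a.GetIdx()]), a.GetFormalCharge())
            for a in rdmol.GetAtoms()
        ]
        order_map = {
            Chem.BondType.SINGLE: 1.0,
            Chem.BondType.DOUBLE: 2.0,
            Chem.BondType.TRIPLE: 3.0,
            Chem.BondType.AROMATIC: 1.5,
        }
        bonds = [
            Bond(b.GetBeginAtomIdx(), b.GetEndAtomIdx(),
                 order_map.get(b.GetBondType(), 1.0))
            for b in rdmol.GetBonds()
        ]
        return cls(name=name, atoms=atoms, bonds=bonds, source_id=source_id,
                   is_2d=is_2d, _rdmol=rdmol)

    def to_rdkit(self):
        """An RDKit mol with this conformer's coordinates (cached)."""
        from rdkit import Chem
        from rdkit.Chem import AllChem

        if self._rdmol is not None:
            rd = self._rdmol
            if rd.GetNumAtoms() == self.num_atoms():
                rd = Chem.Mol(rd)
                if not self.is_2d:
                    conf = Chem.Conformer(rd.GetNumAtoms())
                    for i, p in enumerate(self.coords):
                        conf.SetAtomPosition(i, p.tolist())
                    rd.RemoveAllConformers()
                    rd.AddConformer(conf, assignId=True)
                return rd
        rw = Chem.RWMol()
        for a in self.atoms:
            at = Chem.Atom(a.element)
            at.SetFormalCharge(a.formal_charge)
            rw.AddAtom(at)
        order_map = {1.0: Chem.BondType.SINGLE, 2.0: Chem.BondType.DOUBLE,
                     3.0: Chem.BondType.TRIPLE, 1.5: Chem.BondType.AROMATIC}
        for b in self.bonds:
            rw.AddBond(b.i, b.j, order_map.get(b.order, Chem.BondType.SINGLE))
        mol = rw.GetMol()
        Chem.SanitizeMol(mol)
        if not self.is_2d:
            conf = Chem.Conformer(mol.GetNumAtoms())
            for i, p in enumerate(self.coords):
                conf.SetAtomPosition(i, p.tolist())
            mol.AddConformer(conf, assignId=True)
        if self.name:
            mol.SetProp("_Name", self.name)
        object.__setattr__(self, "_rdmol", mol)
        return mol


@dataclass
class RigidTransform:
    """Proper rigid motion x -> R x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-6:
            raise ValueError("rotation must be proper (det=+1)")
        if not np.allclose(self.rotation.T @ self.rotation, np.eye(3), atol=1e-6):
            raise ValueError("rotation must be orthogonal")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return pts @ self.rotation.T + self.translation

    def apply_vector(self, v: np.ndarray) -> np.ndarray:
        return np.asarray(v, dtype=float) @ self.rotation.T

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: (self∘other)(x) = self(other(x))."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


@dataclass
class PharmacophoreFeature:
    """A typed tolerance sphere, optionally directional or sized."""

    kind: str
    center: np.ndarray
    radius: float
    direction: Optional[np.ndarray] = None
    minsize: Optional[int] = None
    enabled: bool = True
    member_atoms: tuple = ()

    def __post_init__(self):
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind: {self.kind!r}")
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        if not self.radius > 0:
            raise ValueError("tolerance radius must be > 0")
        if self.direction is not None:
            d = np.asarray(self.direction, dtype=float).reshape(3)
            n = np.linalg.norm(d)
            if n < 1e-9:
                self.direction = None
            else:
                self.direction = d / n
        if self.direction is not None and self.kind not in (
                "HydrogenAcceptor", "HydrogenDonor", "Aromatic"):
            raise ValueError(f"{self.kind} features cannot carry a direction")
        if self.minsize is not None and self.kind != "Hydrophobic":
            raise ValueError("minsize is only meaningful for Hydrophobic features")
        self.member_atoms = tuple(int(i) for i in self.member_atoms)

    def moved(self, tfm: RigidTransform) -> "PharmacophoreFeature":
        return replace(
            self,
            center=tfm.apply(self.center[None, :])[0],
            direction=None if self.direction is None else tfm.apply_vector(self.direction),
        )


@dataclass
class FeatureSet:
    features: list  # list[PharmacophoreFeature]
    source: str = "ligand"  # "ligand" | "receptor"

    def __iter__(self):
        return iter(self.features)

    def __len__(self):
        return len(self.features)

    def enabled(self) -> list:
        return [f for f in self.features if f.enabled]

    def by_kind(self, kind: str) -> list:
        return [f for f in self.features if f.kind == kind]

    def centers(self) -> np.ndarray:
        return np.asarray([f.center for f in self.features]).reshape(-1, 3)

    def moved(self, tfm: RigidTransform) -> "FeatureSet":
        return FeatureSet([f.moved(tfm) for f in self.features], self.source)


class Sphere(NamedTuple):
    center: tuple
    radius: float


@dataclass
class QueryDocument:
    """An on-disk pharmacophore/shape query: typed tolerance spheres plus
    optional manual inclusive/exclusive spheres."""

    features: list = field(default_factory=list)  # list[PharmacophoreFeature]
    inclusive_spheres: list = field(default_factory=list)  # list[Sphere]
    exclusive_spheres: list = field(default_factory=list)  # list[Sphere]
    receptor_ref: Optional[str] = None
    ligand_ref: Optional[str] = None

    def enabled_features(self) -> list:
        return [f for f in self.features if f.enabled]


def unit(v: np.ndarray) -> Optional[np.ndarray]:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n < 1e-9:
        return None
    return v / n


def angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    c = float(np.clip(np.dot(unit(u), unit(v)), -1.0, 1.0))
    return math.degrees(math.acos(c))
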