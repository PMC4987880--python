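"""Synthetic inputs with planted structure: libraries whose actives realize a
known pharmacophore and whose decoys provably cannot, plus a toy
receptor-ligand complex with a known interacting-feature set.

The planted-library construction gives ground truth by construction rather
than by running the matcher: active molecules are rigidly moved (and
noise-perturbed, with per-atom displacements clipped well below the tolerance
radii) copies of a template compound whose features define the query, so they
must match; decoys are purely aliphatic molecules containing no aromatic
ring, so a query that includes an aromatic feature can never be mapped onto
them.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, NamedTuple, Optional, Tuple

import numpy as np

from .core import (Atom, FeatureSet, Molecule, PharmacophoreFeature,
                   QueryDocument, RigidTransform, unit)
from . import featurize
from .libbuild import (ConformerLibrary, LibraryEntry, compute_properties,
                       entry_from_rdkit, _embed_conformers, _mix_seed)

__all__ = [
    "FixtureSpec", "ToyComplex", "make_template_ligand", "make_planted_library",
    "make_toy_complex", "fixture_ligands",
]

#: Rigid-ish template whose features define the default planted query:
#: an aromatic ring, a phenolic donor and a carbonyl acceptor.
TEMPLATE_SMILES = "NC(=O)c1ccc(O)cc1"  # 4-hydroxybenzamide

#: Feature-rich aromatic compounds for self-retrieval fixtures.
LIGAND_CATALOG = [
    "Oc1ccccc1", "NC(=O)c1ccccc1", "NC(=N)c1ccccc1", "Nc1ccccc1",
    "OC(=O)c1ccccc1", "Oc1ccc(Cl)cc1", "COc1ccccc1", "Cc1ccc(O)cc1",
    "NCc1ccccc1", "OCc1ccccc1", "Oc1ccc(C=O)cc1", "NC(=O)c1ccc(O)cc1",
    "c1ccc2[nH]ccc2c1", "Oc1cccc2ccccc12", "NC(=O)Cc1ccccc1",
    "OC(=O)Cc1ccccc1", "Nc1ccc(O)cc1", "Clc1ccc(CO)cc1",
    "Cc1cccc(N)c1", "COc1ccc(CN)cc1", "Oc1ccc(CCO)cc1", "NC(=O)c1cccnc1",
    "Oc1ccccn1", "NCc1ccc(O)cc1",
]


@dataclass
class FixtureSpec:
    n_decoys: int = 90
    n_planted: int = 10
    query_template: Optional[QueryDocument] = None
    geometric_noise: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_decoys < 0 or self.n_planted < 0:
            raise ValueError("counts must be non-negative")
        if self.geometric_noise < 0:
            raise ValueError("noise must be non-negative")


def _embed_smiles(smiles: str, name: str, seed: int, max_confs: int = 1):
    from rdkit import Chem

    rd = Chem.MolFromSmiles(smiles)
    embedded = _embed_conformers(rd, max_confs, seed)
    if embedded is None:
        raise RuntimeError(f"embedding failed for {smiles}")
    embedded.SetProp("_Name", name)
    return embedded


def make_template_ligand(seed: int = 0) -> Molecule:
    """The embedded template compound in its as-embedded frame."""
    rd = _embed_smiles(TEMPLATE_SMILES, "template", _mix_seed(seed, 9001))
    return Molecule.from_rdkit(rd, name="template")


def _default_query(template: Molecule) -> QueryDocument:
    """Aromatic + phenol donor + carbonyl acceptor, read off the template."""
    fs = featurize.detect_features(template)
    rd = template.to_rdkit()

    def is_phenol_o(idx):
        a = rd.GetAtomWithIdx(int(idx))
        return a.GetSymbol() == "O" and any(
            n.GetIsAromatic() for n in a.GetNeighbors())

    def is_carbonyl_o(idx):
        a = rd.GetAtomWithIdx(int(idx))
        heavy = [n for n in a.GetNeighbors() if n.GetSymbol() != "H"]
        n_h = a.GetTotalNumHs(includeNeighbors=True)
        return a.GetSymbol() == "O" and n_h == 0 and len(heavy) == 1

    chosen = []
    for f in fs:
        if f.kind == "Aromatic" and not any(c.kind == "Aromatic" for c in chosen):
            chosen.append(f)
        elif f.kind == "HydrogenDonor" and is_phenol_o(f.member_atoms[0]):
            chosen.append(f)
        elif f.kind == "HydrogenAcceptor" and is_carbonyl_o(f.member_atoms[0]):
            chosen.append(f)
    if len(chosen) != 3:
        raise RuntimeError("template did not yield the expected three features")
    # only the aromatic normal is directional: it is stable under the
    # clipped coordinate noise, unlike single-bond O-H/C=O vectors whose
    # angle can swing past the cutoff at sub-radius displacements
    feats = [PharmacophoreFeature(
        kind=f.kind, center=f.center, radius=f.radius,
        direction=(f.direction if f.kind == "Aromatic" else None),
        minsize=None, enabled=True, member_atoms=())
        for f in chosen]
    return QueryDocument(features=feats)


def _decoy_smiles(n: int) -> List[str]:
    """n distinct aliphatic SMILES (no aromatic ring anywhere)."""
    from rdkit import Chem

    suffixes = ["", "O", "N", "OC", "S", "(C)C", "(C)O", "N(C)C", "C(=O)OC",
                "OCC", "CC(C)O", "C(C)N"]
    out, seen = [], set()
    for length in range(2, 16):
        for suf in suffixes:
            smi = "C" * length + suf
            rd = Chem.MolFromSmiles(smi)
            if rd is None:
                continue
            if any(a.GetIsAromatic() for a in rd.GetAtoms()):
                continue
            canon = Chem.MolToSmiles(rd)
            if canon in seen:
                continue
            seen.add(canon)
            out.append(smi)
            if len(out) >= n:
                return out
    raise ValueError(f"decoy catalog exhausted (asked for {n})")


def _clipped_noise(rng: np.random.Generator, shape, sigma: float,
                   max_norm: float) -> np.ndarray:
    noise = rng.normal(0.0, sigma, size=shape) if sigma > 0 else np.zeros(shape)
    norms = np.linalg.norm(noise, axis=1, keepdims=True)
    factor = np.minimum(1.0, max_norm / np.maximum(norms, 1e-12))
    return noise * factor


def _random_rigid(rng: np.random.Generator) -> RigidTransform:
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(random_state=np.random.RandomState(
        rng.integers(2 ** 31))).as_matrix()
    trans = rng.uniform(-10.0, 10.0, size=3)
    return RigidTransform(rot, trans)


def make_planted_library(spec: FixtureSpec
                         ) -> Tuple[ConformerLibrary, QueryDocument]:
    """A library of n_planted matching actives and n_decoys non-matchers.

    Actives are rigidly displaced copies of the template with per-atom noise
    clipped at min(3*sigma, 0.4) A, far inside the 1.0/1.1 A tolerance radii,
    so every active matches the query.  Decoys carry no aromatic ring (checked
    at generation time on the molecular graph) and therefore cannot map the
    query's aromatic feature.
    """
    from rdkit import Chem

    rng = np.random.default_rng(spec.seed)
    template = make_template_ligand(spec.seed)
    query = spec.query_template or _default_query(template)

    entries: List[LibraryEntry] = []
    tmpl_props = compute_properties(template)
    tmpl_canon = Chem.MolToSmiles(Chem.RemoveHs(template.to_rdkit()))
    clip = min(3.0 * spec.geometric_noise, 0.4)
    for i in range(spec.n_planted):
        tfm = _random_rigid(rng)
        coords = tfm.apply(template.coords)
        coords = coords + _clipped_noise(rng, coords.shape,
                                         spec.geometric_noise, clip)
        name = f"active_{i:03d}"
        mol = template.with_coords(coords, name=name)
        entries.append(LibraryEntry(
            molecule_id=f"m{len(entries):06d}", name=name,
            canonical=tmpl_canon, conformers=[mol], properties=tmpl_props))

    for i, smi in enumerate(_decoy_smiles(spec.n_decoys)):
        name = f"decoy_{i:03d}"
        rd = _embed_smiles(smi, name, _mix_seed(spec.seed, 100 + i))
        if any(a.GetIsAromatic() for a in rd.GetAtoms()):
            raise RuntimeError("decoy construction produced an aromatic ring")
        entries.append(entry_from_rdkit(rd, f"m{len(entries):06d}", name))

    return ConformerLibrary(entries=entries), query


# ---------------------------------------------------------------------------
# toy receptor-ligand complex
# ---------------------------------------------------------------------------

class ToyComplex(NamedTuple):
    pdb_text: str
    ligand_resname: str
    ligand: Molecule                # the ligand with proper bond orders
    expected_enabled_kinds: dict    # kind -> count of enabled ligand features
    expected_feature_counts: dict   # kind -> total ligand features


# residue templates: (atom name, element, position); backbone geometry is
# approximate — bond assignment in readers is template/proximity based.
_BACKBONE = [("N", "N", (-1.458, 0.0, 0.0)), ("CA", "C", (0.0, 0.0, 0.0)),
             ("C", "C", (0.551, 1.420, 0.0)), ("O", "O", (-0.251, 2.390, 0.0))]
_SER = _BACKBONE + [("CB", "C", (0.540, -0.760, -1.230)),
                    ("OG", "O", (0.040, -2.080, -1.280))]
_PHE = _BACKBONE + [("CB", "C", (0.540, -0.760, -1.230)),
                    ("CG", "C", (0.180, -2.210, -1.260)),
                    ("CD1", "C", (1.010, -3.120, -0.620)),
                    ("CD2", "C", (-0.960, -2.680, -1.920)),
                    ("CE1", "C", (0.700, -4.470, -0.640)),
                    ("CE2", "C", (-1.270, -4.030, -1.950)),
                    ("CZ", "C", (-0.440, -4.930, -1.310))]
_GLY = list(_BACKBONE)
_PHE_RING = ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal proper rotation taking unit vector a to unit vector b."""
    a, b = unit(a), unit(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-9:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate 180 deg about any perpendicular axis
        perp = unit(np.cross(a, [1.0, 0.0, 0.0]))
        if perp is None:
            perp = unit(np.cross(a, [0.0, 1.0, 0.0]))
        return -np.eye(3) + 2.0 * np.outer(perp, perp)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / (np.linalg.norm(v) ** 2))


def _place_residue(template, key_point: np.ndarray, target: np.ndarray,
                   toward: np.ndarray):
    """Rigidly place a residue template: *key_point* (template frame) lands on
    *target* with the backbone pointing away from the *toward* direction."""
    names = [t[0] for t in template]
    elements = [t[1] for t in template]
    coords = np.array([t[2] for t in template], dtype=float)
    backbone = coords[:4].mean(axis=0)
    rot = _rotation_between(key_point - backbone, toward)
    placed = (coords - key_point) @ rot.T + target
    return list(zip(names, elements, placed))


def _pdb_atom_line(serial, name, resname, chain, resseq, pos, element,
                   hetatm=False) -> str:
    rec = "HETATM" if hetatm else "ATOM"
    if len(name) < 4 and len(element) == 1:
        name = " " + name
    return (f"{rec:<6}{serial:>5} {name:<4} {resname:>3} {chain:1}{resseq:>4}"
            f"    {pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}  1.00  0.00"
            f"          {element:>2}")


def make_toy_complex(seed: int = 0) -> ToyComplex:
    """A small synthetic complex with a known interacting-feature set.

    The ligand (template compound) sits at the origin; a serine hydroxyl is
    placed 2.8 A outside its phenol oxygen (enabling the phenol donor and
    acceptor), a phenylalanine ring 3.8 A above the ligand ring (enabling the
    aromatic and hydrophobic features), and a glycine plus two waters far
    away.  The ligand's amide donor and carbonyl acceptor have no
    complementary partner within any cutoff and stay disabled.
    """
    template = make_template_ligand(seed)
    from .shape import inertia_canonicalize

    ligand = template.transformed(inertia_canonicalize(template))
    fs = featurize.detect_features(ligand)
    rd = ligand.to_rdkit()

    ring = next(f for f in fs if f.kind == "Aromatic")
    phenol = next(f for f in fs if f.kind == "HydrogenDonor"
                  and rd.GetAtomWithIdx(f.member_atoms[0]).GetSymbol() == "O")
    amide_n = next(f for f in fs if f.kind == "HydrogenDonor"
                   and rd.GetAtomWithIdx(f.member_atoms[0]).GetSymbol() == "N")
    carbonyl = next(
        f for f in fs if f.kind == "HydrogenAcceptor"
        and rd.GetAtomWithIdx(f.member_atoms[0]).GetTotalNumHs(
            includeNeighbors=True) == 0
        and len([n for n in rd.GetAtomWithIdx(f.member_atoms[0]).GetNeighbors()
                 if n.GetSymbol() != "H"]) == 1)

    out_dir = unit(phenol.center - ring.center)
    normal = unit(ring.direction)
    ser_target = phenol.center + 2.8 * out_dir
    ser = _place_residue(_SER, np.array(_SER[5][2]), ser_target, -out_dir)
    phe_key = np.array([_PHE[i][2] for i, t in enumerate(_PHE)
                        if t[0] in _PHE_RING]).mean(axis=0)
    phe_target = ring.center + 3.8 * normal
    phe = _place_residue(_PHE, phe_key, phe_target, -normal)
    far = ring.center + 25.0 * out_dir
    gly = _place_residue(_GLY, np.array(_GLY[1][2]), far, out_dir)

    # construction check: the deliberately non-interacting ligand features
    # must be clear of every receptor polar atom by more than any cutoff
    rec_polar = [pos for (nm, el, pos) in ser + phe + gly if el in ("N", "O")]
    for feat in (amide_n, carbonyl):
        dmin = min(np.linalg.norm(np.asarray(p) - feat.center)
                   for p in rec_polar)
        if dmin <= 5.5:
            raise RuntimeError(
                f"toy-complex geometry violated: {feat.kind} at {dmin:.2f} A "
                "from a receptor polar atom")

    lines, serial = [], 1
    for resseq, (resname, atoms) in enumerate(
            [("GLY", gly), ("SER", ser), ("PHE", phe)], start=1):
        for nm, el, pos in atoms:
            lines.append(_pdb_atom_line(serial, nm, resname, "A", resseq, pos, el))
            serial += 1
    heavy = ligand.heavy_indices
    counters: dict = {}
    for i in heavy:
        el = ligand.atoms[i].element
        counters[el] = counters.get(el, 0) + 1
        nm = f"{el}{counters[el]}"
        lines.append(_pdb_atom_line(serial, nm, "LIG", "B", 1,
                                    ligand.coords[i], el, hetatm=True))
        serial += 1
    for wi, direction in enumerate((out_dir, -normal), start=1):
        pos = ring.center + 14.0 * np.asarray(direction) + np.array([0, 0, 3.0 * wi])
        lines.append(_pdb_atom_line(serial, "O", "HOH", "W", wi, pos, "O",
                                    hetatm=True))
        serial += 1
    lines.append("END")

    expected_counts = {"HydrogenDonor": 2, "HydrogenAcceptor": 2,
                       "Aromatic": 1, "Hydrophobic": 1}
    expected_enabled = {"HydrogenDonor": 1, "HydrogenAcceptor": 1,
                        "Aromatic": 1, "Hydrophobic": 1}
    return ToyComplex(pdb_text="\n".join(lines) + "\n",
                      ligand_resname="LIG", ligand=ligand,
                      expected_enabled_kinds=expected_enabled,
                      expected_feature_counts=expected_counts)


def fixture_ligands(n: int = 20, seed: int = 0) -> List[Molecule]:
    """n embedded, feature-rich single-conformer ligands for retrieval tests."""
    if n > len(LIGAND_CATALOG):
        raise ValueError(f"at most {len(LIGAND_CATALOG)} fixture ligands")
    out = []
    for i, smi in enumerate(LIGAND_CATALOG[:n]):
        rd = _embed_smiles(smi, f"lig_{i:02d}", _mix_seed(seed, 500 + i))
        out.append(Molecule.from_rdkit(rd, name=f"lig_{i:02d}"))
    return out
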