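"""Building searchable conformer libraries from SMILES or 3D SDF input.

From SMILES, each record runs through: parse -> keep largest covalent
component (salt stripping) -> canonicalize and drop duplicate canonical
SMILES (first occurrence wins) -> rule-based protonation at pH 7.4 ->
distance-geometry embedding with UFF relaxation for up to ``max_confs``
conformers, pruned for diversity at 0.5 A heavy-atom RMSD.  From SDF, the
provided coordinates are trusted as conformers; consecutive records sharing a
name and topology are grouped as conformers of one entry, and acidic protons
are normalized.

Each entry carries precomputed drug-likeness properties and per-conformer
pharmacophore features; voxelized shapes are computed on demand and cached.
"""
from __future__ import annotations

import gzip
import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import FeatureSet, Molecule, logger
from . import chem_io, featurize

__all__ = [
    "PropertyRecord", "LibraryEntry", "ConformerLibrary",
    "build_from_smiles", "build_from_sdf", "compute_properties",
    "write_library", "read_library",
]

PROPERTY_COLUMNS = ["id", "name", "molweight", "rotatable_bonds", "logp",
                    "tpsa", "aromatic_groups", "hba", "hbd"]


@dataclass
class PropertyRecord:
    molweight: float
    rotatable_bonds: int
    logp: float
    tpsa: float
    aromatic_groups: int
    hba: int
    hbd: int

    def __post_init__(self):
        if min(self.rotatable_bonds, self.aromatic_groups, self.hba,
               self.hbd) < 0 or self.tpsa < 0:
            raise ValueError("counts and TPSA must be non-negative")

    def as_dict(self) -> dict:
        return {"molweight": self.molweight,
                "rotatable_bonds": self.rotatable_bonds, "logp": self.logp,
                "tpsa": self.tpsa, "aromatic_groups": self.aromatic_groups,
                "hba": self.hba, "hbd": self.hbd}


@dataclass
class LibraryEntry:
    molecule_id: str
    name: str
    canonical: Optional[str]
    conformers: List[Molecule]
    properties: PropertyRecord
    flagged_2d: bool = False
    _features: list = field(default_factory=list, repr=False)

    def __post_init__(self):
        if not self.conformers:
            raise ValueError("an entry needs at least one conformer")


@dataclass
class ConformerLibrary:
    entries: List[LibraryEntry] = field(default_factory=list)
    _shape_cache: dict = field(default_factory=dict, repr=False)

    def __len__(self):
        return len(self.entries)

    @property
    def n_conformers(self) -> int:
        return sum(len(e.conformers) for e in self.entries)

    def entry_by_id(self, molecule_id: str) -> LibraryEntry:
        for e in self.entries:
            if e.molecule_id == molecule_id:
                return e
        raise KeyError(molecule_id)

    def features_for(self, entry: LibraryEntry, conf_id: int) -> FeatureSet:
        if not entry._features:
            entry._features = [featurize.detect_features(c)
                               for c in entry.conformers]
        return entry._features[conf_id]

    def shape_for(self, entry: LibraryEntry, conf_id: int, resolution=0.5,
                  probe=1.4):
        from . import shape as shape_mod

        key = (entry.molecule_id, conf_id, resolution, probe)
        if key not in self._shape_cache:
            self._shape_cache[key] = shape_mod.voxelize_sev(
                entry.conformers[conf_id], resolution=resolution, probe=probe)
        return self._shape_cache[key]


# ---------------------------------------------------------------------------
# protonation at pH 7.4 (rule-based)
# ---------------------------------------------------------------------------

# (SMARTS, atom position in match, charge delta); hydrogens follow the charge.
_DEPROTONATE = [
    ("[CX3](=O)[OX2H1]", 2),          # carboxylic acid
    ("[SX4](=O)(=O)[OX2H1]", 3),      # sulfonic acid
    ("[PX4](=O)[OX2H1]", 2),          # phosph(on)ate OH
]
_PROTONATE = [
    ("[NX3;H2,H1,H0;+0;!$(N-a);!$(N-*=[O,N,S]);!$(N~[!#6;!#1])]", 0),  # aliphatic amine
    ("[NX2;+0]=[CX3]-[NX3;+0]", 0),   # amidine / guanidine imine N
]


def protonate_ph74(rdmol):
    """Apply fixed-pH 7.4 protonation rules (returns a new sanitized mol)."""
    from rdkit import Chem

    rw = Chem.RWMol(rdmol)
    for smarts, pos in _DEPROTONATE:
        patt = Chem.MolFromSmarts(smarts)
        for match in rw.GetMol().GetSubstructMatches(patt):
            a = rw.GetAtomWithIdx(match[pos])
            if a.GetFormalCharge() == 0 and a.GetTotalNumHs() >= 1:
                a.SetFormalCharge(-1)
                a.SetNumExplicitHs(max(0, a.GetNumExplicitHs() - 1)
                                   if a.GetNumExplicitHs() else 0)
                a.SetNoImplicit(True)
    for smarts, pos in _PROTONATE:
        patt = Chem.MolFromSmarts(smarts)
        for match in rw.GetMol().GetSubstructMatches(patt):
            a = rw.GetAtomWithIdx(match[pos])
            if a.GetFormalCharge() == 0:
                a.SetFormalCharge(1)
                a.SetNumExplicitHs(a.GetTotalNumHs() + 1)
                a.SetNoImplicit(True)
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    return mol


def _largest_component(rdmol):
    from rdkit import Chem

    frags = Chem.GetMolFrags(rdmol, asMols=True, sanitizeFrags=True)
    return max(frags, key=lambda f: f.GetNumHeavyAtoms())


def _embed_conformers(rdmol, max_confs: int, seed: int):
    """Distance-geometry embedding + UFF relaxation + 0.5 A diversity prune."""
    from rdkit import Chem
    from rdkit.Chem import AllChem, rdMolAlign

    mol = Chem.AddHs(rdmol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) % (2 ** 31)
    n_try = max(max_confs * 2, max_confs + 2)
    ids = list(AllChem.EmbedMultipleConfs(mol, numConfs=n_try, params=params))
    if not ids:
        params.useRandomCoords = True
        ids = list(AllChem.EmbedMultipleConfs(mol, numConfs=n_try, params=params))
    if not ids:
        return None
    results = AllChem.UFFOptimizeMoleculeConfs(mol, maxIters=500)
    energies = [e for (_conv, e) in results]
    order = sorted(range(len(ids)), key=lambda k: energies[k])
    heavy = Chem.RemoveHs(Chem.Mol(mol))
    kept: List[int] = []
    for k in order:
        cid = ids[k]
        diverse = True
        for kc in kept:
            rms = rdMolAlign.GetBestRMS(heavy, heavy, prbId=cid, refId=kc)
            if rms < 0.5:
                diverse = False
                break
        if diverse:
            kept.append(cid)
        if len(kept) >= max_confs:
            break
    if not kept:
        kept = [ids[order[0]]]
    out = Chem.Mol(mol)
    out.RemoveAllConformers()
    for cid in kept:
        conf = Chem.Conformer(mol.GetConformer(cid))
        out.AddConformer(conf, assignId=True)
    return out


def compute_properties(mol) -> PropertyRecord:
    """Drug-likeness properties for a molecule (2D input is fine).

    Rotatable bonds: non-ring single bonds between heavy atoms that each have
    another heavy neighbor, amide C-N excluded.  HBA/HBD counts reuse the
    pharmacophore SMARTS definitions so filters and features agree.
    """
    from rdkit import Chem
    from rdkit.Chem import Descriptors, rdMolDescriptors

    from rdkit import Chem

    rdmol = mol.to_rdkit() if isinstance(mol, Molecule) else mol
    rdmol = Chem.RemoveHs(Chem.Mol(rdmol))  # descriptors assume implicit H
    defs = featurize.load_feature_definitions()
    matches = featurize._smarts_matches(rdmol, defs)
    return PropertyRecord(
        molweight=float(Descriptors.MolWt(rdmol)),
        rotatable_bonds=int(rdMolDescriptors.CalcNumRotatableBonds(rdmol)),
        logp=float(Descriptors.MolLogP(rdmol)),
        tpsa=float(Descriptors.TPSA(rdmol)),
        aromatic_groups=int(rdMolDescriptors.CalcNumAromaticRings(rdmol)),
        hba=len(matches.get("HydrogenAcceptor", [])),
        hbd=len(matches.get("HydrogenDonor", [])),
    )


def _mix_seed(seed: int, idx: int) -> int:
    return (int(seed) * 1000003 + idx * 7919 + 17) % (2 ** 31)


def entry_from_rdkit(rdmol, molecule_id: str, name: str,
                     canonical: Optional[str] = None) -> LibraryEntry:
    """Wrap a multi-conformer RDKit mol as one library entry."""
    from rdkit import Chem

    confs = [Molecule.from_rdkit(rdmol, conf_id=c.GetId(), name=name)
             for c in rdmol.GetConformers()]
    if canonical is None:
        canonical = Chem.MolToSmiles(Chem.RemoveHs(rdmol))
    return LibraryEntry(molecule_id=molecule_id, name=name,
                        canonical=canonical, conformers=confs,
                        properties=compute_properties(confs[0]))


def build_from_smiles(records: Sequence[Tuple[str, str]], max_confs: int = 10,
                      seed: int = 0) -> ConformerLibrary:
    """Build a library from (smiles, name) records; deterministic under seed."""
    from rdkit import Chem

    if max_confs < 1:
        raise ValueError("max_confs must be >= 1")
    seen: Dict[str, str] = {}
    entries: List[LibraryEntry] = []
    n_skipped = 0
    for idx, (smi, name) in enumerate(records):
        rd = Chem.MolFromSmiles(smi)
        if rd is None:
            n_skipped += 1
            logger.warning("record %d (%r): unparseable SMILES, skipped", idx, name)
            continue
        rd = _largest_component(rd)
        canonical = Chem.MolToSmiles(rd)
        if canonical in seen:
            logger.info("record %d (%r): duplicate of %s, dropped", idx, name,
                        seen[canonical])
            continue
        seen[canonical] = name
        try:
            rd = protonate_ph74(rd)
        except Exception as exc:  # noqa: BLE001 - record-level resilience
            n_skipped += 1
            logger.warning("record %d (%r): protonation failed (%s), skipped",
                           idx, name, exc)
            continue
        embedded = _embed_conformers(rd, max_confs, _mix_seed(seed, idx))
        if embedded is None:
            n_skipped += 1
            logger.warning("record %d (%r): 3D embedding failed, skipped", idx, name)
            continue
        mid = f"m{len(entries):06d}"
        entries.append(entry_from_rdkit(embedded, mid, name or mid,
                                        canonical=canonical))
    if not entries:
        raise ValueError(f"no usable records ({n_skipped} skipped)")
    logger.info("library: %d entries, %d conformers (%d records skipped)",
                len(entries), sum(len(e.conformers) for e in entries), n_skipped)
    return ConformerLibrary(entries=entries)


def build_from_sdf(path, max_confs: int = 10) -> ConformerLibrary:
    """Build a library from a 3D SDF; coordinates are used as-is.

    Consecutive records with identical name and canonical topology become
    conformers of one entry.  Flat geometries (all z ~ 0 on >3 heavy atoms)
    are flagged as suspect 2D input.
    """
    from rdkit import Chem

    mols = chem_io.read_molecules(path, fmt="sdf")
    entries: List[LibraryEntry] = []
    current: Optional[LibraryEntry] = None
    current_key = None
    for mol in mols:
        rd = mol.to_rdkit()
        try:
            rd_norm = protonate_ph74(Chem.Mol(rd))
            canonical = Chem.MolToSmiles(Chem.RemoveHs(rd_norm))
        except Exception:
            canonical = Chem.MolToSmiles(Chem.RemoveHs(rd))
        key = (mol.name, canonical)
        flat = (len(mol.heavy_indices) > 3
                and bool(np.all(np.abs(mol.heavy_coords[:, 2]) < 1e-3)))
        if flat:
            logger.warning("entry %r: coordinates look 2D (flat z)", mol.name)
        if current is not None and key == current_key:
            if len(current.conformers) < max_confs:
                current.conformers.append(mol)
            current.flagged_2d = current.flagged_2d or flat
        else:
            mid = f"m{len(entries):06d}"
            current = LibraryEntry(
                molecule_id=mid, name=mol.name or mid, canonical=canonical,
                conformers=[mol], properties=compute_properties(mol),
                flagged_2d=flat)
            current_key = key
            entries.append(current)
    return ConformerLibrary(entries=entries)


# ---------------------------------------------------------------------------
# persistence: manifest JSON + gzipped SDF shard + property table (TSV)
# ---------------------------------------------------------------------------

def write_library(library: ConformerLibrary, dirpath) -> None:
    os.makedirs(dirpath, exist_ok=True)
    sdf_path = os.path.join(dirpath, "shard000.sdf.gz")
    from rdkit import Chem
    import io

    buf = io.StringIO()
    writer = Chem.SDWriter(buf)
    writer.SetKekulize(False)
    for entry in library.entries:
        for ci, conf in enumerate(entry.conformers):
            rd = conf.to_rdkit()
            rd.SetProp("_Name", entry.name)
            rd.SetProp("molecule_id", entry.molecule_id)
            rd.SetProp("conformer_id", str(ci))
            writer.write(rd)
    writer.close()
    with gzip.open(sdf_path, "wt") as fh:
        fh.write(buf.getvalue())

    rows = [{"id": e.molecule_id, "name": e.name, **e.properties.as_dict()}
            for e in library.entries]
    pd.DataFrame(rows, columns=PROPERTY_COLUMNS).to_csv(
        os.path.join(dirpath, "properties.tsv"), sep="\t", index=False)
    manifest = {
        "format": "pharmscreen-library/1",
        "entries": [
            {"id": e.molecule_id, "name": e.name, "canonical": e.canonical,
             "n_conformers": len(e.conformers), "flagged_2d": e.flagged_2d}
            for e in library.entries
        ],
        "shards": ["shard000.sdf.gz"],
    }
    with open(os.path.join(dirpath, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)


def read_library(dirpath) -> ConformerLibrary:
    with open(os.path.join(dirpath, "manifest.json")) as fh:
        manifest = json.load(fh)
    props = pd.read_csv(os.path.join(dirpath, "properties.tsv"), sep="\t")
    props = props.set_index("id")
    mols: List[Molecule] = []
    tags: List[Tuple[str, int]] = []
    from rdkit import Chem

    for shard in manifest["shards"]:
        with gzip.open(os.path.join(dirpath, shard), "rb") as fh:
            for rd in Chem.ForwardSDMolSupplier(fh, removeHs=False, sanitize=True):
                if rd is None:
                    continue
                mols.append(Molecule.from_rdkit(rd))
                tags.append((rd.GetProp("molecule_id"),
                             int(rd.GetProp("conformer_id"))))
    by_id: Dict[str, List[Molecule]] = {}
    for mol, (mid, ci) in zip(mols, tags):
        by_id.setdefault(mid, []).append(mol)
    entries = []
    for meta in manifest["entries"]:
        mid = meta["id"]
        row = props.loc[mid]
        record = PropertyRecord(
            molweight=float(row["molweight"]),
            rotatable_bonds=int(row["rotatable_bonds"]), logp=float(row["logp"]),
            tpsa=float(row["tpsa"]), aromatic_groups=int(row["aromatic_groups"]),
            hba=int(row["hba"]), hbd=int(row["hbd"]))
        entries.append(LibraryEntry(
            molecule_id=mid, name=meta["name"], canonical=meta["canonical"],
            conformers=by_id[mid], properties=record,
            flagged_2d=bool(meta.get("flagged_2d", False))))
    return ConformerLibrary(entries=entries)
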