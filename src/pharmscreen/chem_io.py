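"""Reading and writing chemical file formats and the pharmacophore query JSON.

Supported formats: SDF (V2000), PDB, SMILES (one per line, optional name after
whitespace) and a JSON query dialect of typed tolerance spheres.  Gzip is
handled transparently for any path ending in ``.gz``.  No chemistry beyond
parsing/sanitization happens here.
"""
from __future__ import annotations

import gzip
import io
import json
import os
from typing import List, Optional, Tuple

import numpy as np

from .core import (FEATURE_KINDS, Atom, FeatureSet, Molecule,
                   PharmacophoreFeature, QueryDocument, Sphere, logger)

__all__ = [
    "Molecule", "QueryDocument", "read_molecules", "write_molecules",
    "split_complex", "read_query", "write_query",
]

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


def _open_text(path, mode="rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _resolve_format(path, fmt: str) -> str:
    if fmt != "auto":
        return fmt
    base = str(path)
    if base.endswith(".gz"):
        base = base[:-3]
    ext = os.path.splitext(base)[1].lower().lstrip(".")
    mapping = {"sdf": "sdf", "sd": "sdf", "mol": "sdf", "pdb": "pdb",
               "ent": "pdb", "smi": "smiles", "smiles": "smiles", "ism": "smiles"}
    if ext not in mapping:
        raise ValueError(f"cannot resolve format from extension {ext!r}")
    return mapping[ext]


def read_molecules(path, fmt: str = "auto") -> List[Molecule]:
    """Read all records from *path*; unparseable records are logged and
    skipped, but zero valid records is an error.

    SMILES records carry no coordinates and are flagged 2D; every 3D operation
    downstream rejects them (only the library builder accepts 2D input).
    """
    from rdkit import Chem

    fmt = _resolve_format(path, fmt)
    mols: List[Molecule] = []
    n_bad = 0
    if fmt == "sdf":
        with _open_text(path, "rb") as fh:
            suppl = Chem.ForwardSDMolSupplier(fh, removeHs=False, sanitize=True)
            for idx, rd in enumerate(suppl):
                if rd is None:
                    n_bad += 1
                    logger.warning("%s: record %d unparseable, skipped", path, idx)
                    continue
                mols.append(Molecule.from_rdkit(rd, source_id=str(idx)))
    elif fmt == "pdb":
        with _open_text(path) as fh:
            block = fh.read()
        rd = Chem.MolFromPDBBlock(block, removeHs=False, sanitize=True)
        if rd is None:
            rd = Chem.MolFromPDBBlock(block, removeHs=False, sanitize=False)
        if rd is not None:
            mols.append(Molecule.from_rdkit(rd, source_id="0",
                                            name=os.path.basename(str(path))))
        else:
            n_bad += 1
    elif fmt == "smiles":
        with _open_text(path) as fh:
            for idx, line in enumerate(fh):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split(None, 1)
                smi, name = parts[0], (parts[1].strip() if len(parts) > 1 else "")
                rd = Chem.MolFromSmiles(smi)
                if rd is None:
                    n_bad += 1
                    logger.warning("%s: line %d not valid SMILES, skipped", path, idx + 1)
                    continue
                mols.append(Molecule.from_rdkit(rd, name=name, source_id=str(idx),
                                                is_2d=True))
    else:  # pragma: no cover - _resolve_format guards this
        raise ValueError(f"unsupported format {fmt!r}")
    if not mols:
        raise ValueError(f"{path}: no valid records (skipped {n_bad})")
    return mols


def write_molecules(mols, path) -> None:
    """Write molecules as an SDF (V2000); gzipped when path ends in .gz."""
    from rdkit import Chem

    buf = io.StringIO()
    writer = Chem.SDWriter(buf)
    writer.SetKekulize(False)
    for m in mols:
        writer.write(m.to_rdkit())
    writer.close()
    mode = "wt"
    with _open_text(path, mode) as fh:
        fh.write(buf.getvalue())


# ---------------------------------------------------------------------------
# receptor/ligand splitting
# ---------------------------------------------------------------------------

def _dedupe_altloc(residue):
    """Keep one atom per name: highest occupancy, first on ties."""
    best = {}
    order = []
    for atom in residue:
        key = atom.name
        if key not in best:
            best[key] = atom
            order.append(key)
        elif atom.occ > best[key].occ:
            best[key] = atom
    return [best[k] for k in order]


def _atoms_to_pdb_lines(entries) -> str:
    lines = []
    serial = 1
    for rec, resname, chain, resseq, atom in entries:
        el = atom.element.name if atom.element else ""
        name = atom.name
        # PDB atom-name column convention: element right-aligned in cols 13-14
        if len(name) < 4 and len(el) == 1:
            name = " " + name
        lines.append(
            f"{rec:<6}{serial:>5} {name:<4}{'':1}{resname:>3} {chain:1}"
            f"{resseq:>4}{'':1}   {atom.pos.x:8.3f}{atom.pos.y:8.3f}{atom.pos.z:8.3f}"
            f"{atom.occ:6.2f}{atom.b_iso:6.2f}          {el:>2}"
        )
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def _pdb_lines_to_molecule(block: str, name: str) -> Molecule:
    from rdkit import Chem

    rd = Chem.MolFromPDBBlock(block, removeHs=False, sanitize=True)
    if rd is None:
        rd = Chem.MolFromPDBBlock(block, removeHs=False, sanitize=False)
    if rd is None:
        raise ValueError(f"could not rebuild molecule {name!r} from PDB atoms")
    return Molecule.from_rdkit(rd, name=name)


def split_complex(pdb_path, ligand_resname: str, water_mode: str = "ignore",
                  ligand_index: int = 0) -> Tuple[Molecule, Molecule]:
    """Split a complex into (receptor, ligand) by HETATM residue name.

    Model 1 only; alternate locations resolved to the highest-occupancy copy.
    *water_mode* routes waters: ``ignore`` drops them, ``receptor`` or
    ``ligand`` appends them to that side.  When several copies of the named
    residue exist, *ligand_index* selects one in chain/residue order.
    """
    import gemmi

    if water_mode not in ("ignore", "receptor", "ligand"):
        raise ValueError(f"unknown water_mode {water_mode!r}")
    st = gemmi.read_structure(str(pdb_path))
    st.setup_entities()
    model = st[0]

    receptor_entries, water_entries, ligand_groups = [], [], []
    het_names = set()
    for chain in model:
        for residue in chain:
            atoms = _dedupe_altloc(residue)
            resname = residue.name
            seqid = residue.seqid.num
            is_het = residue.het_flag == "H"
            if resname in _WATER_NAMES:
                water_entries.extend(
                    ("HETATM", resname, chain.name, seqid, a) for a in atoms)
                continue
            if is_het:
                het_names.add(resname)
                if resname == ligand_resname:
                    ligand_groups.append(
                        [("HETATM", resname, chain.name, seqid, a) for a in atoms])
            else:
                receptor_entries.extend(
                    ("ATOM", resname, chain.name, seqid, a) for a in atoms)

    if not ligand_groups:
        avail = ", ".join(sorted(het_names)) or "(none)"
        raise ValueError(
            f"no HETATM residue named {ligand_resname!r}; available: {avail}")
    if not (0 <= ligand_index < len(ligand_groups)):
        raise ValueError(
            f"ligand_index {ligand_index} out of range (found {len(ligand_groups)} "
            f"copies of {ligand_resname!r})")
    ligand_entries = list(ligand_groups[ligand_index])

    if water_mode == "receptor":
        receptor_entries = receptor_entries + water_entries
    elif water_mode == "ligand":
        ligand_entries = ligand_entries + water_entries

    if not receptor_entries:
        raise ValueError("no polymer atoms found for the receptor")
    receptor = _pdb_lines_to_molecule(_atoms_to_pdb_lines(receptor_entries),
                                      name="receptor")
    ligand = _pdb_lines_to_molecule(_atoms_to_pdb_lines(ligand_entries),
                                    name=ligand_resname)
    return receptor, ligand


# ---------------------------------------------------------------------------
# query JSON dialect
# ---------------------------------------------------------------------------

def read_query(path) -> QueryDocument:
    """Read a pharmacophore query document (JSON dialect).

    Top level: ``points`` (typed tolerance spheres), optional ``inspheres`` /
    ``exspheres`` arrays and ``receptor`` / ``ligand`` references.
    """
    with _open_text(path) as fh:
        doc = json.load(fh)
    features = []
    for p in doc.get("points", []):
        kind = p.get("name")
        if kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {kind!r}")
        direction = None
        if "svector" in p and p["svector"] is not None:
            sv = p["svector"]
            direction = np.array([sv["x"], sv["y"], sv["z"]], dtype=float)
        features.append(PharmacophoreFeature(
            kind=kind,
            center=np.array([p["x"], p["y"], p["z"]], dtype=float),
            radius=float(p["radius"]),
            enabled=bool(p.get("enabled", True)),
            direction=direction,
            minsize=(int(p["size"]) if p.get("size") not in (None, "") else None),
        ))
    def spheres(key):
        return [Sphere((s["x"], s["y"], s["z"]), float(s["radius"]))
                for s in doc.get(key, [])]
    return QueryDocument(
        features=features,
        inclusive_spheres=spheres("inspheres"),
        exclusive_spheres=spheres("exspheres"),
        receptor_ref=doc.get("receptor"),
        ligand_ref=doc.get("ligand"),
    )


def write_query(doc: QueryDocument, path) -> None:
    points = []
    for f in doc.features:
        p = {"name": f.kind, "x": float(f.center[0]), "y": float(f.center[1]),
             "z": float(f.center[2]), "radius": float(f.radius),
             "enabled": bool(f.enabled)}
        if f.direction is not None:
            p["svector"] = {"x": float(f.direction[0]), "y": float(f.direction[1]),
                            "z": float(f.direction[2])}
        if f.minsize is not None:
            p["size"] = int(f.minsize)
        points.append(p)
    out = {"points": points}
    for key, spheres in (("inspheres", doc.inclusive_spheres),
                         ("exspheres", doc.exclusive_spheres)):
        if spheres:
            out[key] = [{"x": s.center[0], "y": s.center[1], "z": s.center[2],
                         "radius": s.radius} for s in spheres]
    if doc.receptor_ref:
        out["receptor"] = doc.receptor_ref
    if doc.ligand_ref:
        out["ligand"] = doc.ligand_ref
    with _open_text(path, "wt") as fh:
        json.dump(out, fh, indent=1)
        fh.write("\n")
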