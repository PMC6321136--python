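"""Structure input: SDF conformer records and SMILES with embedded
conformer generation (capped at 10 conformers per compound)."""

from __future__ import annotations

import csv
from pathlib import Path

from pharmfish.errors import SchemaError, StructureError
from pharmfish.pharmacophore import MAX_CONFORMERS, Conformer


def conformer_from_rdkit(mol, compound_id: str, conformer_index: int = 0,
                         conf_id: int = -1) -> Conformer:
    """Extract a Conformer from a sanitized RDKit Mol with 3D coordinates.

    The molecule is kekulized on a copy so bond orders serialize as 1/2/3.
    """
    from rdkit import Chem

    kek = Chem.Mol(mol)
    Chem.Kekulize(kek, clearAromaticFlags=True)
    conf = kek.GetConformer(conf_id)
    atoms = []
    charges = []
    for atom in kek.GetAtoms():
        pos = conf.GetAtomPosition(atom.GetIdx())
        atoms.append((atom.GetSymbol(), pos.x, pos.y, pos.z))
        charges.append(atom.GetFormalCharge())
    order_map = {Chem.BondType.SINGLE: 1, Chem.BondType.DOUBLE: 2,
                 Chem.BondType.TRIPLE: 3}
    bonds = []
    for bond in kek.GetBonds():
        order = order_map.get(bond.GetBondType())
        if order is None:
            raise StructureError(compound_id,
                                 f"unsupported bond type {bond.GetBondType()}")
        bonds.append((bond.GetBeginAtomIdx(), bond.GetEndAtomIdx(), order))
    return Conformer(compound_id, tuple(atoms), tuple(bonds),
                     conformer_index=conformer_index, charges=tuple(charges))


def read_sdf_conformers(path) -> dict:
    """Group a multi-record SDF by title into per-compound conformer lists.

    Records sharing a title are treated as conformers of one compound,
    keeping at most the first 10 in file order.  Untitled records get
    positional ids.
    """
    from rdkit import Chem

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    grouped: dict = {}
    supplier = Chem.SDMolSupplier(str(path), removeHs=False)
    for record_index, mol in enumerate(supplier):
        if mol is None:
            raise StructureError(f"record#{record_index}",
                                 f"unparseable SDF record in {path}")
        compound_id = (mol.GetProp("_Name").strip()
                       if mol.HasProp("_Name") and mol.GetProp("_Name").strip()
                       else f"record{record_index}")
        conformers = grouped.setdefault(compound_id, [])
        if len(conformers) >= MAX_CONFORMERS:
            continue
        conformers.append(
            conformer_from_rdkit(mol, compound_id, conformer_index=len(conformers)))
    return grouped


def read_smiles_conformers(path, seed: int = 0,
                           n_conformers: int = MAX_CONFORMERS) -> dict:
    """Read `compound_id<TAB>smiles` and embed up to 10 3D conformers each."""
    from rdkit import Chem
    from rdkit.Chem import AllChem

    grouped: dict = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or len(header) < 2:
            raise SchemaError(f"{path}: expected header compound_id<TAB>smiles")
        for lineno, row in enumerate(reader, start=2):
            if not row or not row[0].strip():
                continue
            compound_id, smiles = row[0].strip(), row[1].strip()
            if compound_id in grouped:
                raise SchemaError(f"{path}:{lineno}: duplicate compound_id "
                                  f"{compound_id!r}")
            mol = Chem.MolFromSmiles(smiles)
            if mol is None:
                raise StructureError(compound_id,
                                     f"invalid SMILES at {path}:{lineno}")
            mol = Chem.AddHs(mol)
            params = AllChem.ETKDGv3()
            params.randomSeed = seed
            conf_ids = AllChem.EmbedMultipleConfs(
                mol, numConfs=min(n_conformers, MAX_CONFORMERS), params=params)
            if not conf_ids:
                raise StructureError(compound_id, "conformer embedding failed")
            mol = Chem.RemoveHs(mol)
            grouped[compound_id] = [
                conformer_from_rdkit(mol, compound_id, conformer_index=i,
                                     conf_id=conf_id)
                for i, conf_id in enumerate(conf_ids)
            ]
    return grouped
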