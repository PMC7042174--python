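"""Reading and writing the molecule and tabular formats the pipeline touches.

Supported formats:

* ``.smi`` — whitespace-separated SMILES-then-identifier, one record per
  line, ``#`` comment lines ignored (the shape DUD-E and most screening
  libraries use);
* SDF (V2000/V3000) with 3D coordinates; the molecule title supplies the
  molecule identifier unless a property name is configured.  Conformer
  records carry charges / logP contributions / energies from the SDF
  properties ``CHARGES``, ``LOGP_CONTRIBS`` and ``ENERGY_KCAL_MOL`` when
  present;
* the descriptor table — a CSV with header
  ``mol_id,conf_id,method,m01,...,m15`` (USR rows leave m13–m15 empty) that
  round-trips descriptors bit-compatibly at 12 significant digits;
* a JSON dataset manifest ``{target_id, actives: [...], decoys: [...]}``.

Unparseable molecules are skipped with a logged warning rather than aborting
the run — screening libraries routinely contain a few bad entries — but an
input that yields zero records is treated as a format error.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from rdkit import Chem

from .records import ConformerRecord, Label, MoleculeRecord, ShapeDescriptor, TargetDataset

logger = logging.getLogger(__name__)

DESCRIPTOR_COLUMNS = ["mol_id", "conf_id", "method"] + [f"m{i:02d}" for i in range(1, 16)]
_METHOD_LENGTH = {"usr": 12, "es4d": 15, "es5d": 15}


def read_smiles_file(path: str | Path) -> List[MoleculeRecord]:
    """Parse a .smi file into molecule records (file order preserved).

    Lines are ``SMILES<whitespace>identifier``; blank and ``#`` lines are
    ignored.  Invalid SMILES are skipped with a warning; a file with no
    parseable record at all is a format error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: List[MoleculeRecord] = []
    n_skipped = 0
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 2:
            logger.warning("%s:%d: expected 'SMILES id', got %r", path, lineno, raw)
            n_skipped += 1
            continue
        smiles, mol_id = parts[0], parts[1]
        if Chem.MolFromSmiles(smiles) is None:
            logger.warning("%s:%d: unparseable SMILES %r (skipped)", path, lineno, smiles)
            n_skipped += 1
            continue
        records.append(MoleculeRecord(mol_id=mol_id, smiles=smiles))
    if not records:
        raise ValueError(f"no parseable SMILES records in {path}")
    if n_skipped:
        logger.warning("%s: skipped %d unparseable lines", path, n_skipped)
    return records


def _float_list_prop(mol: Chem.Mol, name: str) -> Optional[np.ndarray]:
    if not mol.HasProp(name):
        return None
    return np.array([float(x) for x in mol.GetProp(name).split()])


def read_sdf(path: str | Path, id_property: Optional[str] = None) -> List[ConformerRecord]:
    """Read an SDF into conformer records.

    ``conf_id`` is assigned sequentially per molecule identifier, starting at
    0, in file order.  Entries whose atoms all sit at z = 0 are emitted but
    flagged as "2D suspect"; corrupt entries are skipped with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
    records: List[ConformerRecord] = []
    counters: Dict[str, int] = {}
    for i, mol in enumerate(supplier):
        if mol is None:
            logger.warning("%s: entry %d is corrupt (skipped)", path, i)
            continue
        if id_property and mol.HasProp(id_property):
            mol_id = mol.GetProp(id_property)
        elif mol.HasProp("_Name") and mol.GetProp("_Name"):
            mol_id = mol.GetProp("_Name")
        else:
            mol_id = f"entry{i}"
        if mol.GetNumConformers() == 0:
            logger.warning("%s: entry %d (%s) has no coordinates (skipped)", path, i, mol_id)
            continue
        coords = np.asarray(mol.GetConformer().GetPositions(), dtype=float)
        if np.allclose(coords[:, 2], 0.0):
            logger.warning("%s: entry %d (%s) is 2D suspect (all z = 0)", path, i, mol_id)
        conf_id = counters.get(mol_id, 0)
        counters[mol_id] = conf_id + 1
        energy = float(mol.GetProp("ENERGY_KCAL_MOL")) if mol.HasProp("ENERGY_KCAL_MOL") else 0.0
        records.append(
            ConformerRecord(
                mol_id=mol_id,
                conf_id=conf_id,
                coords=coords,
                charges=_float_list_prop(mol, "CHARGES"),
                logp_contribs=_float_list_prop(mol, "LOGP_CONTRIBS"),
                energy=energy,
                is_hydrogen=np.array([a.GetAtomicNum() == 1 for a in mol.GetAtoms()]),
            )
        )
    return records


def write_sdf(
    path: str | Path,
    mols: Sequence[Tuple[Chem.Mol, str]],
) -> None:
    """Write (mol, mol_id) pairs to an SDF, one entry per conformer, carrying
    the pipeline's standard properties."""
    writer = Chem.SDWriter(str(path))
    try:
        for mol, mol_id in mols:
            mol.SetProp("_Name", mol_id)
            for conf in mol.GetConformers():
                writer.write(mol, confId=conf.GetId())
    finally:
        writer.close()


def write_descriptor_table(
    descriptors: Sequence[ShapeDescriptor], path: str | Path
) -> None:
    """Persist descriptors as delimited text (header ``mol_id,conf_id,method,
    m01..m15``); USR rows leave the trailing three columns empty.

    All descriptors in one table must share a method tag.  Values are written
    with 17 significant digits so a read of the written table reproduces the
    vectors to well beyond 12 significant digits.
    """
    descriptors = list(descriptors)
    methods = {d.method for d in descriptors}
    if len(methods) > 1:
        raise ValueError(f"mixed method tags in one table: {sorted(methods)}")
    rows = []
    for d in descriptors:
        padded = list(d.values) + [""] * (15 - len(d.values))
        rows.append([d.mol_id, d.conf_id, d.method, *padded])
    frame = pd.DataFrame(rows, columns=DESCRIPTOR_COLUMNS)
    frame.to_csv(path, index=False, float_format="%.17g")


def read_descriptor_table(path: str | Path) -> List[ShapeDescriptor]:
    """Read a descriptor table written by :func:`write_descriptor_table`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, dtype={"mol_id": str})
    if list(frame.columns) != DESCRIPTOR_COLUMNS:
        raise ValueError(
            f"descriptor table header mismatch in {path}: {list(frame.columns)}"
        )
    out: List[ShapeDescriptor] = []
    for row in frame.itertuples(index=False):
        method = row.method
        if method not in _METHOD_LENGTH:
            raise ValueError(f"unknown method tag {method!r} in {path}")
        length = _METHOD_LENGTH[method]
        values = [getattr(row, f"m{i:02d}") for i in range(1, 16)]
        tail = values[length:]
        if any(pd.notna(v) for v in tail):
            raise ValueError(
                f"row for {row.mol_id}/{row.conf_id}: method {method!r} admits "
                f"{length} values but trailing columns are populated"
            )
        out.append(
            ShapeDescriptor(
                mol_id=row.mol_id,
                conf_id=int(row.conf_id),
                method=method,
                values=np.array(values[:length], dtype=float),
            )
        )
    return out


def descriptor_frame(
    descriptors: Sequence[ShapeDescriptor],
    labels: Optional[Dict[str, Label]] = None,
) -> pd.DataFrame:
    """Arrange descriptors as the tidy frame the ML layer consumes
    (columns mol_id, conf_id, label, m01..)."""
    descriptors = list(descriptors)
    if not descriptors:
        raise ValueError("no descriptors")
    methods = {d.method for d in descriptors}
    if len(methods) > 1:
        raise ValueError(f"mixed method tags: {sorted(methods)}")
    labels = labels or {}
    dim = descriptors[0].values.shape[0]
    cols = [f"m{i:02d}" for i in range(1, dim + 1)]
    rows = [
        (
            d.mol_id,
            d.conf_id,
            Label(labels.get(d.mol_id, Label.UNKNOWN)).value,
            *d.values,
        )
        for d in descriptors
    ]
    return pd.DataFrame(rows, columns=["mol_id", "conf_id", "label", *cols])


def write_dataset_manifest(dataset: TargetDataset, path: str | Path) -> None:
    payload = {
        "target_id": dataset.target_id,
        "actives": [m.mol_id for m in dataset.actives],
        "decoys": [m.mol_id for m in dataset.decoys],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_dataset_manifest(path: str | Path) -> Dict[str, object]:
    payload = json.loads(Path(path).read_text())
    for key in ("target_id", "actives", "decoys"):
        if key not in payload:
            raise ValueError(f"manifest {path} missing key {key!r}")
    return payload


def assemble_target_dataset(
    actives_path: str | Path,
    decoys_path: str | Path,
    conformer_paths: Iterable[str | Path] = (),
    target_id: str = "target",
) -> TargetDataset:
    """Build a target dataset from active/decoy .smi files plus conformer SDFs.

    Labels come from file membership; conformers are attached by mol_id.
    Molecules without conformers are retained (and counted in a warning); a
    mol_id present in both the actives and decoys files is a fatal
    consistency error.
    """
    actives = [
        MoleculeRecord(m.mol_id, m.smiles, Label.ACTIVE)
        for m in read_smiles_file(actives_path)
    ]
    decoys = [
        MoleculeRecord(m.mol_id, m.smiles, Label.DECOY)
        for m in read_smiles_file(decoys_path)
    ]
    conformers: Dict[str, List[ConformerRecord]] = {}
    for p in conformer_paths:
        for rec in read_sdf(p):
            conformers.setdefault(rec.mol_id, []).append(rec)
    known = {m.mol_id for m in actives} | {m.mol_id for m in decoys}
    unknown = set(conformers) - known
    for mol_id in unknown:
        logger.warning("conformers for unknown molecule %s dropped", mol_id)
        del conformers[mol_id]
    dataset = TargetDataset(
        target_id=target_id, actives=actives, decoys=decoys, conformers=conformers
    )
    missing = [m.mol_id for m in dataset.molecules if m.mol_id not in conformers]
    if missing:
        logger.warning(
            "%d molecules have no conformers: %s%s",
            len(missing),
            ", ".join(missing[:5]),
            "..." if len(missing) > 5 else "",
        )
    return dataset
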