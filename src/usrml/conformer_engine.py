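"""Conformer generation, energy filtering and LEC selection.

Molecules are standardised (structure normalisation + largest fragment, via
RDKit's MolStandardize), embedded with ETKDG — whose torsion knowledge
produces geometries that are already close to energy-minimised, so no
post-embedding minimisation is applied — and assigned a single-point MMFF94
energy.  Conformers whose energy exceeds that of the lowest-energy conformer
(LEC) by the energy window (default 5 kcal/mol) or more are discarded.

Partial charges (MMFF94 by default, Gasteiger selectable) and Crippen-type
per-atom logP contributions are attached at generation time, so descriptor
computation downstream never needs molecular perception.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, Crippen
from rdkit.Chem.MolStandardize import rdMolStandardize

from .records import ConformerRecord, MoleculeRecord

logger = logging.getLogger(__name__)


@dataclass
class ConformerFilterConfig:
    """Knobs of the conformer protocol.

    ``energy_window`` is the keep-threshold relative to the LEC in kcal/mol
    (a conformer is kept iff its energy is *less than* LEC + window);
    ``max_conformers`` caps the embedding request per molecule.
    """

    energy_window: float = 5.0
    max_conformers: int = 200
    rng_seed: int = 42
    charge_model: str = "mmff94"  # or "gasteiger"
    embed_retries: int = 3

    def __post_init__(self) -> None:
        if self.energy_window <= 0:
            raise ValueError("energy_window must be > 0")
        if self.max_conformers < 1:
            raise ValueError("max_conformers must be >= 1")
        if self.charge_model not in ("mmff94", "gasteiger"):
            raise ValueError("charge_model must be 'mmff94' or 'gasteiger'")


def standardize_molecule(record: MoleculeRecord) -> MoleculeRecord:
    """Normalise a molecule and keep its largest fragment.

    Delegates to RDKit's MolStandardize (cleanup then fragment parent), the
    same rule set as the MolVS standardiser it absorbed.  The operation is
    idempotent; failures raise ``ValueError`` so callers can exclude and
    count the molecule.
    """
    if record.smiles is None:
        raise ValueError(f"molecule {record.mol_id} has no SMILES to standardize")
    mol = Chem.MolFromSmiles(record.smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES for {record.mol_id}: {record.smiles!r}")
    try:
        mol = rdMolStandardize.Cleanup(mol)
        mol = rdMolStandardize.FragmentParent(mol)
    except Exception as exc:  # RDKit raises various internal types
        raise ValueError(f"standardization failed for {record.mol_id}: {exc}") from exc
    return MoleculeRecord(
        mol_id=record.mol_id, smiles=Chem.MolToSmiles(mol), label=record.label
    )


def _partial_charges(mol: Chem.Mol, config: ConformerFilterConfig) -> np.ndarray:
    if config.charge_model == "mmff94":
        props = AllChem.MMFFGetMoleculeProperties(mol)
        if props is not None:
            return np.array(
                [props.GetMMFFPartialCharge(i) for i in range(mol.GetNumAtoms())]
            )
        logger.warning("MMFF94 parameters unavailable; falling back to Gasteiger")
    AllChem.ComputeGasteigerCharges(mol)
    return np.array(
        [float(a.GetProp("_GasteigerCharge")) for a in mol.GetAtoms()]
    )


def _logp_contribs(mol: Chem.Mol) -> np.ndarray:
    contribs = Crippen.rdMolDescriptors._CalcCrippenContribs(mol)
    return np.array([c[0] for c in contribs])


def conformers_from_mol(
    mol: Chem.Mol, mol_id: str, config: Optional[ConformerFilterConfig] = None
) -> List[ConformerRecord]:
    """Extract ConformerRecords (with charges, logP, MMFF energies) from an
    embedded RDKit molecule."""
    config = config or ConformerFilterConfig()
    charges = _partial_charges(mol, config)
    logp = _logp_contribs(mol)
    is_h = np.array([a.GetAtomicNum() == 1 for a in mol.GetAtoms()])
    mmff_props = AllChem.MMFFGetMoleculeProperties(mol)
    out: List[ConformerRecord] = []
    for i, conf in enumerate(mol.GetConformers()):
        coords = conf.GetPositions()
        energy = 0.0
        if mmff_props is not None:
            ff = AllChem.MMFFGetMoleculeForceField(mol, mmff_props, confId=conf.GetId())
            if ff is not None:
                energy = float(ff.CalcEnergy())
        out.append(
            ConformerRecord(
                mol_id=mol_id,
                conf_id=i,
                coords=np.asarray(coords, dtype=float),
                charges=charges,
                logp_contribs=logp,
                energy=energy,
                is_hydrogen=is_h,
            )
        )
    return out


def generate_conformers(
    record: MoleculeRecord, config: Optional[ConformerFilterConfig] = None
) -> List[ConformerRecord]:
    """Embed up to ``max_conformers`` ETKDG conformers for a molecule.

    Hydrogens are added before embedding; each conformer receives a
    single-point MMFF94 energy (no minimisation — ETKDG geometries are
    treated as already relaxed), partial charges and per-atom logP
    contributions.  Fully reproducible given ``rng_seed``; embedding failure
    after the configured retries returns an empty list with a warning.
    """
    config = config or ConformerFilterConfig()
    if record.smiles is None:
        raise ValueError(f"molecule {record.mol_id} has no SMILES")
    mol = Chem.MolFromSmiles(record.smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES for {record.mol_id}")
    if mol.GetNumHeavyAtoms() < 1:
        raise ValueError(f"molecule {record.mol_id} has no heavy atoms")
    mol = Chem.AddHs(mol)
    for attempt in range(config.embed_retries):
        params = AllChem.ETKDGv2()
        params.randomSeed = int(config.rng_seed + attempt) % (2**31)
        conf_ids = AllChem.EmbedMultipleConfs(mol, numConfs=config.max_conformers, params=params)
        if len(conf_ids) > 0:
            return conformers_from_mol(mol, record.mol_id, config)
    logger.warning("embedding failed for %s after %d retries", record.mol_id, config.embed_retries)
    return []


def filter_by_energy_window(
    conformers: Sequence[ConformerRecord], window: float = 5.0
) -> List[ConformerRecord]:
    """Keep conformers with energy strictly below LEC energy + window.

    The boundary is exclusive on the keep side — a conformer higher than the
    LEC by exactly the window (or more) is removed.  Order is preserved and
    the LEC itself is always retained; an empty input yields an empty output.
    """
    confs = list(conformers)
    if not confs:
        return []
    if len({c.mol_id for c in confs}) > 1:
        raise ValueError("all conformers must share one mol_id")
    e_min = min(c.energy for c in confs)
    return [c for c in confs if c.energy - e_min < window]


def select_lec(conformers: Sequence[ConformerRecord]) -> ConformerRecord:
    """Return the lowest-energy conformer; ties broken by lowest conf_id."""
    confs = list(conformers)
    if not confs:
        raise ValueError("select_lec requires a non-empty conformer list")
    if len({c.mol_id for c in confs}) > 1:
        raise ValueError("all conformers must share one mol_id")
    return min(confs, key=lambda c: (c.energy, c.conf_id))
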