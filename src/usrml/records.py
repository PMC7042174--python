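"""Core data records shared across the screening pipeline.

The pipeline passes molecules through three representations:

* :class:`MoleculeRecord` — a 2D molecule (SMILES + identifier + activity label),
* :class:`ConformerRecord` — one 3D geometry of a molecule, carrying the
  per-atom quantities (partial charges, atomic logP contributions) that the
  augmented descriptor spaces need,
* :class:`ShapeDescriptor` — the rotation/translation-invariant moment vector
  computed from a conformer (12 values for USR, 15 for ElectroShape 4D/5D).

A :class:`TargetDataset` bundles the actives and decoys of one protein target
with their conformers; a :class:`ScoredMolecule` is the unit of ranking that
the evaluation metrics consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np


class Label(str, Enum):
    """Activity label of a molecule in a retrospective screening benchmark."""

    ACTIVE = "active"
    DECOY = "decoy"
    UNKNOWN = "unknown"


@dataclass
class MoleculeRecord:
    """A molecule identified by ``mol_id``, optionally with SMILES and label."""

    mol_id: str
    smiles: Optional[str] = None
    label: Label = Label.UNKNOWN

    def __post_init__(self) -> None:
        if not self.mol_id:
            raise ValueError("mol_id must be non-empty")
        self.label = Label(self.label)


@dataclass
class ConformerRecord:
    """One 3D conformer of a molecule.

    Attributes
    ----------
    coords : (n, 3) float array
        Cartesian coordinates in Angstrom.
    charges : (n,) float array or None
        Per-atom partial charges in elementary-charge units.
    logp_contribs : (n,) float array or None
        Per-atom lipophilicity (ALogP-type atomic) contributions.
    energy : float
        Force-field energy in kcal/mol (single-point evaluation).
    """

    mol_id: str
    conf_id: int
    coords: np.ndarray
    charges: Optional[np.ndarray] = None
    logp_contribs: Optional[np.ndarray] = None
    energy: float = 0.0
    is_hydrogen: Optional[np.ndarray] = None  # boolean mask, for H filtering

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be an (n, 3) array")
        if self.coords.shape[0] < 1:
            raise ValueError("conformer must contain at least one atom")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords must be finite")
        if self.conf_id < 0:
            raise ValueError("conf_id must be non-negative")
        n = self.coords.shape[0]
        for name in ("charges", "logp_contribs"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.shape != (n,):
                    raise ValueError(f"{name} must have length {n}")
                setattr(self, name, arr)
        if self.is_hydrogen is not None:
            mask = np.asarray(self.is_hydrogen, dtype=bool)
            if mask.shape != (n,):
                raise ValueError(f"is_hydrogen must have length {n}")
            self.is_hydrogen = mask

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]


@dataclass
class ShapeDescriptor:
    """Moment-vector descriptor of one conformer.

    ``values`` has length 12 for ``method='usr'`` (3 moments x 4 reference
    points) and 15 for ``method='es4d'``/``'es5d'`` (3 moments x 5 reference
    points).
    """

    mol_id: str
    conf_id: int
    method: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = {"usr": 12, "es4d": 15, "es5d": 15}
        if self.method not in expected:
            raise ValueError(f"unknown descriptor method: {self.method!r}")
        if self.values.shape != (expected[self.method],):
            raise ValueError(
                f"method {self.method!r} requires {expected[self.method]} values, "
                f"got {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("descriptor values must be finite")


@dataclass
class ScoredMolecule:
    """A molecule with its aggregated screening score — the unit of ranking."""

    mol_id: str
    score: float
    label: Label = Label.UNKNOWN

    def __post_init__(self) -> None:
        if not np.isfinite(self.score):
            raise ValueError("score must be finite")
        self.label = Label(self.label)


@dataclass
class TargetDataset:
    """Actives, decoys and conformers for one protein target."""

    target_id: str
    actives: list = field(default_factory=list)
    decoys: list = field(default_factory=list)
    conformers: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        active_ids = {m.mol_id for m in self.actives}
        decoy_ids = {m.mol_id for m in self.decoys}
        overlap = active_ids & decoy_ids
        if overlap:
            raise ValueError(
                f"molecules present in both actives and decoys: {sorted(overlap)}"
            )
        known = active_ids | decoy_ids
        orphans = set(self.conformers) - known
        if orphans:
            raise ValueError(
                f"conformers reference unknown molecules: {sorted(orphans)}"
            )

    @property
    def molecules(self) -> list:
        return list(self.actives) + list(self.decoys)

    @property
    def n_molecules(self) -> int:
        return len(self.actives) + len(self.decoys)
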