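"""Classical USR/ElectroShape screening by inverse-Manhattan similarity.

The similarity between a query descriptor M^q and a library descriptor M^i is

    S = ( 1 + (1/L) * sum_l |M_l^q - M_l^i| )^(-1)

with L the descriptor length (12 for USR, 15 for ElectroShape), so S lies in
(0, 1] and equals 1 exactly when the descriptors coincide.  Molecule-level
similarity is the maximum over all conformer pairs; a library is ranked
against a set of active templates by the maximum over templates.  Screening
can use the full conformer ensemble of each template ("full" mode) or only
each template's lowest-energy conformer ("lec" mode).
"""

from __future__ import annotations

from typing import Dict, List, Sequence

import numpy as np

from .records import Label, ScoredMolecule, ShapeDescriptor


def similarity(q: ShapeDescriptor, i: ShapeDescriptor) -> float:
    """Inverse-Manhattan similarity between two descriptors of one method."""
    if q.method != i.method:
        raise ValueError(f"method mismatch: {q.method!r} vs {i.method!r}")
    L = q.values.shape[0]
    return 1.0 / (1.0 + np.abs(q.values - i.values).sum() / L)


def molecule_similarity(
    query_confs: Sequence[ShapeDescriptor], lib_confs: Sequence[ShapeDescriptor]
) -> float:
    """Similarity between two molecules: max over all conformer pairs."""
    if not query_confs or not lib_confs:
        raise ValueError("conformer descriptor lists must be non-empty")
    methods = {d.method for d in query_confs} | {d.method for d in lib_confs}
    if len(methods) > 1:
        raise ValueError(f"mixed descriptor methods: {sorted(methods)}")
    Q = np.vstack([d.values for d in query_confs])
    X = np.vstack([d.values for d in lib_confs])
    L = Q.shape[1]
    # pairwise L1 distances, vectorised over both conformer sets
    dists = np.abs(Q[:, None, :] - X[None, :, :]).sum(axis=2)
    return float((1.0 / (1.0 + dists / L)).max())


def screen(
    templates: Sequence[Sequence[ShapeDescriptor]],
    library: Dict[str, Sequence[ShapeDescriptor]],
    mode: str = "full",
    labels: Dict[str, Label] | None = None,
) -> List[ScoredMolecule]:
    """Rank a library against active templates.

    Parameters
    ----------
    templates : sequence of per-molecule descriptor lists
        In ``lec`` mode every template must hold exactly one descriptor
        (its lowest-energy conformer).
    library : mapping mol_id -> descriptor list
    labels : optional mapping mol_id -> Label for annotating the ranking.

    Returns the library sorted by descending score; ties are broken by
    lexicographic mol_id so rankings are bit-reproducible.
    """
    if mode not in ("full", "lec"):
        raise ValueError(f"unknown mode {mode!r}")
    if not templates or not library:
        raise ValueError("templates and library must be non-empty")
    if mode == "lec":
        for t in templates:
            if len(t) != 1:
                raise ValueError("lec mode requires exactly one descriptor per template")
    labels = labels or {}
    scored = [
        ScoredMolecule(
            mol_id=mol_id,
            score=max(molecule_similarity(t, confs) for t in templates),
            label=labels.get(mol_id, Label.UNKNOWN),
        )
        for mol_id, confs in library.items()
    ]
    scored.sort(key=lambda m: (-m.score, m.mol_id))
    return scored
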