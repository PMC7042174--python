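"""USR and ElectroShape moment descriptors.

Ultrafast Shape Recognition (USR) encodes the shape of a conformer as the
first three moments of the distributions of atomic distances to four
reference points:

* ``ctd`` — the molecular centroid (mean of atom positions),
* ``cst`` — the atom closest to ``ctd``,
* ``fct`` — the atom furthest from ``ctd``,
* ``ftf`` — the atom furthest from ``fct``.

Each distance distribution is condensed into a :class:`MomentTriple`
``(m1, m2, m3)``: the mean, the square root of the population second central
moment, and the signed cube root of the population third central moment.  The
root normalisation puts all three moments on a length scale comparable to the
mean; the signed cube root preserves the direction of the asymmetry.
Concatenating the four triples yields a 12-element vector that is invariant
to rigid motion (and, deliberately, to mirror reflection — enantiomers map to
identical USR descriptors).

ElectroShape extends this by appending a fourth coordinate, the partial
charge of each atom scaled by ``Q`` (Angstrom per elementary charge) to make
its magnitude comparable to the spatial dimensions, and — in the 5D variant —
a fifth coordinate, the per-atom ALogP lipophilicity contribution scaled
analogously.  Five reference points are used in the augmented space
(``c1``–``c5``; the last two are chirality-sensitive, built from the cross
product of the spatial parts of ``c2 - c1`` and ``c3 - c1``), giving a
15-element descriptor.  Distances are Euclidean in the full augmented space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, List

import numpy as np

from .records import ConformerRecord, ShapeDescriptor

logger = logging.getLogger(__name__)

#: reference-point count per descriptor method
_N_REFPOINTS = {"usr": 4, "es4d": 5, "es5d": 5}
#: augmented-space dimensionality per descriptor method
_DIMS = {"usr": 3, "es4d": 4, "es5d": 5}


@dataclass
class DescriptorScheme:
    """Configuration of a descriptor computation.

    Parameters
    ----------
    method : {'usr', 'es4d', 'es5d'}
    charge_scale : float
        Q, in Angstrom per elementary charge; scales the 4th dimension.
    logp_scale : float
        Scale for the 5th (lipophilicity) dimension, per ALogP unit.
    include_hydrogens : bool
        Whether hydrogen atoms participate in the point cloud.
    """

    method: str = "usr"
    charge_scale: float = 25.0
    logp_scale: float = 25.0
    include_hydrogens: bool = True

    def __post_init__(self) -> None:
        if self.method not in _DIMS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.charge_scale <= 0 or self.logp_scale <= 0:
            raise ValueError("scales must be positive")

    @property
    def dim(self) -> int:
        return _DIMS[self.method]

    @property
    def n_refpoints(self) -> int:
        return _N_REFPOINTS[self.method]

    @property
    def n_values(self) -> int:
        return 3 * self.n_refpoints


@dataclass
class AugmentedPointCloud:
    """Atom positions embedded in the (possibly augmented) descriptor space."""

    points: np.ndarray  # (n, d), d in {3, 4, 5}

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] not in (3, 4, 5):
            raise ValueError("points must be (n, d) with d in {3, 4, 5}")
        if self.points.shape[0] < 1:
            raise ValueError("cloud must contain at least one point")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("points must be finite")

    @property
    def dim(self) -> int:
        return self.points.shape[1]


@dataclass
class ReferencePointSet:
    """The k reference points (k=4 for USR, k=5 for ElectroShape)."""

    points: np.ndarray  # (k, d)


def augment_points(
    conformer: ConformerRecord, scheme: DescriptorScheme
) -> AugmentedPointCloud:
    """Embed a conformer into the scheme's descriptor space.

    For USR the cloud is the raw coordinates; ElectroShape 4D appends
    ``charge_scale * charge`` per atom, and 5D additionally appends
    ``logp_scale * logp_contrib``.
    """
    if not scheme.include_hydrogens and conformer.is_hydrogen is not None:
        keep = ~conformer.is_hydrogen
        if not np.any(keep):
            raise ValueError("cloud would be empty after hydrogen removal")
        conformer = ConformerRecord(
            mol_id=conformer.mol_id,
            conf_id=conformer.conf_id,
            coords=conformer.coords[keep],
            charges=None if conformer.charges is None else conformer.charges[keep],
            logp_contribs=(
                None
                if conformer.logp_contribs is None
                else conformer.logp_contribs[keep]
            ),
            energy=conformer.energy,
        )
    cols = [conformer.coords]
    if scheme.dim >= 4:
        if conformer.charges is None:
            raise ValueError(
                f"scheme {scheme.method!r} requires partial charges on "
                f"conformer {conformer.mol_id}/{conformer.conf_id}"
            )
        cols.append(scheme.charge_scale * conformer.charges[:, None])
    if scheme.dim == 5:
        if conformer.logp_contribs is None:
            raise ValueError(
                f"scheme {scheme.method!r} requires logP contributions on "
                f"conformer {conformer.mol_id}/{conformer.conf_id}"
            )
        cols.append(scheme.logp_scale * conformer.logp_contribs[:, None])
    return AugmentedPointCloud(np.hstack(cols))


def usr_reference_points(cloud: AugmentedPointCloud) -> ReferencePointSet:
    """Compute the four USR reference points ctd, cst, fct, ftf.

    Ties between candidate atoms are broken by lowest atom index, making the
    selection deterministic and stable under input order.
    """
    if cloud.dim != 3:
        raise ValueError("USR reference points require a 3D cloud")
    pts = cloud.points
    ctd = pts.mean(axis=0)
    d_ctd = np.linalg.norm(pts - ctd, axis=1)
    cst = pts[int(np.argmin(d_ctd))]
    fct = pts[int(np.argmax(d_ctd))]
    d_fct = np.linalg.norm(pts - fct, axis=1)
    ftf = pts[int(np.argmax(d_fct))]
    return ReferencePointSet(np.vstack([ctd, cst, fct, ftf]))


def electroshape_reference_points(
    cloud: AugmentedPointCloud, scheme: DescriptorScheme | None = None
) -> ReferencePointSet:
    """Compute the five ElectroShape reference points c1..c5.

    ``c1`` is the centroid of the augmented cloud, ``c2`` the point furthest
    from ``c1`` and ``c3`` the point furthest from ``c2`` (augmented-space
    distances, lowest-index tie-break).  ``c4`` and ``c5`` are
    chirality-sensitive: with ``a = c2 - c1`` and ``b = c3 - c1``, their
    shared spatial part is displaced from ``c1`` along the cross product of
    the spatial parts of ``a`` and ``b`` by ``|a_xyz| / 2``; their 4th
    coordinates are the maximum and minimum scaled charge in the cloud
    respectively, and (in 5D) both inherit the 5th coordinate of ``c1``.
    When the spatial parts are collinear the cross product is degenerate and
    ``c4 = c5 = c1``.
    """
    if cloud.dim not in (4, 5):
        raise ValueError("ElectroShape reference points require a 4D/5D cloud")
    pts = cloud.points
    c1 = pts.mean(axis=0)
    d1 = np.linalg.norm(pts - c1, axis=1)
    c2 = pts[int(np.argmax(d1))]
    d2 = np.linalg.norm(pts - c2, axis=1)
    c3 = pts[int(np.argmax(d2))]

    a = c2 - c1
    b = c3 - c1
    cross = np.cross(a[:3], b[:3])
    norm_cross = np.linalg.norm(cross)
    if norm_cross < 1e-12:
        logger.debug("degenerate cross product; c4 = c5 = c1")
        c4 = c1.copy()
        c5 = c1.copy()
    else:
        spatial = c1[:3] + (np.linalg.norm(a[:3]) / (2.0 * norm_cross)) * cross
        c4 = np.concatenate([spatial, [pts[:, 3].max()], c1[4:]])
        c5 = np.concatenate([spatial, [pts[:, 3].min()], c1[4:]])
    return ReferencePointSet(np.vstack([c1, c2, c3, c4, c5]))


def moment_triple(distances: np.ndarray) -> np.ndarray:
    """Condense a distance distribution into its normalised moment triple.

    Returns ``(m1, m2, m3)`` where ``m1`` is the mean, ``m2`` the square root
    of the population variance and ``m3`` the signed cube root of the
    population third central moment.  A single observation yields
    ``(d, 0, 0)``.
    """
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise ValueError("moment_triple requires at least one distance")
    m1 = d.mean()
    centred = d - m1
    mu2 = np.mean(centred**2)
    mu3 = np.mean(centred**3)
    m2 = np.sqrt(mu2)
    m3 = np.sign(mu3) * np.abs(mu3) ** (1.0 / 3.0)
    return np.array([m1, m2, m3])


def compute_descriptor(
    conformer: ConformerRecord, scheme: DescriptorScheme
) -> ShapeDescriptor:
    """Compute the full moment-vector descriptor of one conformer.

    The descriptor is the concatenation, over reference points in their fixed
    order, of the moment triple of the distances from every cloud point to
    that reference point.  Distances are Euclidean in the scheme's full
    (augmented) space.
    """
    cloud = augment_points(conformer, scheme)
    if scheme.method == "usr":
        refs = usr_reference_points(cloud)
    else:
        refs = electroshape_reference_points(cloud, scheme)
    blocks = []
    for ref in refs.points:
        dists = np.linalg.norm(cloud.points - ref, axis=1)
        blocks.append(moment_triple(dists))
    return ShapeDescriptor(
        mol_id=conformer.mol_id,
        conf_id=conformer.conf_id,
        method=scheme.method,
        values=np.concatenate(blocks),
    )


def batch_descriptors(
    conformers: Iterable[ConformerRecord], scheme: DescriptorScheme
) -> List[ShapeDescriptor]:
    """Order-preserving descriptor computation over many conformers.

    Conformers that fail (e.g. missing charges under an ElectroShape scheme)
    are skipped with a logged warning; if every input fails, a ``ValueError``
    is raised.
    """
    out: List[ShapeDescriptor] = []
    n_failed = 0
    n_total = 0
    for conf in conformers:
        n_total += 1
        try:
            out.append(compute_descriptor(conf, scheme))
        except ValueError as exc:
            n_failed += 1
            logger.warning(
                "skipping conformer %s/%s: %s", conf.mol_id, conf.conf_id, exc
            )
    if n_total > 0 and not out:
        raise ValueError(f"all {n_total} conformers failed descriptor computation")
    if n_failed:
        logger.warning("descriptor batch: %d of %d conformers skipped", n_failed, n_total)
    return out
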