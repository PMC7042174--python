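"""Synthetic inputs for exercising every pipeline stage without downloads.

Two families of generators are provided:

* **point-cloud "molecules"** (:func:`random_point_cloud`, :func:`mirror`,
  :func:`rigid_transform`) — exercise the descriptor geometry: invariance
  under rigid motion, enantiomer degeneracy, permutation stability;

* **descriptor-space scenarios** (:func:`sample_descriptor_population`,
  :func:`make_screening_scenario`) — exercise the learning and evaluation
  machinery.  A scenario draws active-conformer descriptors from one or more
  Gaussian clusters (emulating the distinct shape clusters that arise from a
  target's binding modes) and decoy descriptors from a broader background
  Gaussian centred away from the active clusters, with a tunable
  centre-to-centre separation that controls screening difficulty.

All generators are pure functions of their configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .records import ConformerRecord, Label, ShapeDescriptor


@dataclass
class ScenarioConfig:
    """Controls a synthetic descriptor-space screening scenario.

    Parameters
    ----------
    n_actives, n_decoys : int
        Molecule counts for each class.
    n_conformers_per_mol : int
        Descriptor draws per molecule (each emulating one conformer).
    active_modes : int
        Number of active clusters — one per emulated binding mode.
    separation : float
        Distance (descriptor units) between every active-cluster centre and
        the decoy background centre, and between active centres themselves.
    noise_sd : float
        Within-cluster standard deviation of active descriptors.
    decoy_spread_factor : float
        Decoy background standard deviation as a multiple of ``noise_sd``.
        The default of 3 emulates the greater shape diversity of a decoy
        library; set to 1 (with ``separation=0``) for a fully exchangeable
        null scenario.
    descriptor_dim : int
        12 (USR-shaped) or 15 (ElectroShape-shaped).
    """

    n_actives: int = 20
    n_decoys: int = 1000
    n_conformers_per_mol: int = 5
    active_modes: int = 1
    separation: float = 8.0
    noise_sd: float = 1.0
    decoy_spread_factor: float = 3.0
    descriptor_dim: int = 12
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_actives, self.n_decoys, self.n_conformers_per_mol) < 1:
            raise ValueError("counts must be >= 1")
        if self.active_modes < 1:
            raise ValueError("active_modes must be >= 1")
        if self.separation < 0:
            raise ValueError("separation must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.descriptor_dim not in (12, 15):
            raise ValueError("descriptor_dim must be 12 or 15")


@dataclass
class ScreeningScenario:
    """A labelled descriptor population ready for screening experiments.

    ``descriptors`` is a tidy frame with columns ``mol_id``, ``conf_id``,
    ``label`` and the feature columns ``m01..m{dim}``; ``active_centers``
    holds the ground-truth cluster centres.
    """

    config: ScenarioConfig
    descriptors: pd.DataFrame
    active_centers: np.ndarray
    feature_columns: List[str] = field(default_factory=list)

    @property
    def features(self) -> np.ndarray:
        return self.descriptors[self.feature_columns].to_numpy()


def random_point_cloud(n_atoms: int, seed: int) -> ConformerRecord:
    """Draw a random labelled point cloud standing in for a conformer.

    Coordinates are uniform in a 10 Angstrom box; charges and per-atom logP
    contributions are uniform in [-0.5, 0.5]; energy is zero.
    """
    if n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    rng = np.random.default_rng(seed)
    return ConformerRecord(
        mol_id=f"synth-{seed}",
        conf_id=0,
        coords=rng.uniform(0.0, 10.0, size=(n_atoms, 3)),
        charges=rng.uniform(-0.5, 0.5, size=n_atoms),
        logp_contribs=rng.uniform(-0.5, 0.5, size=n_atoms),
        energy=0.0,
    )


def mirror(conformer: ConformerRecord) -> ConformerRecord:
    """Reflect a conformer through the yz plane (negate x).

    Produces the enantiomer of a chiral point cloud; charges and logP are
    untouched.  Applying twice returns the original.
    """
    coords = conformer.coords.copy()
    coords[:, 0] *= -1.0
    return ConformerRecord(
        mol_id=conformer.mol_id,
        conf_id=conformer.conf_id,
        coords=coords,
        charges=conformer.charges,
        logp_contribs=conformer.logp_contribs,
        energy=conformer.energy,
        is_hydrogen=conformer.is_hydrogen,
    )


def rigid_transform(conformer: ConformerRecord, seed: int) -> ConformerRecord:
    """Apply a uniformly random rotation plus translation to the coordinates."""
    rng = np.random.default_rng(seed)
    rot = Rotation.random(rng=rng).as_matrix()
    shift = rng.uniform(-20.0, 20.0, size=3)
    return ConformerRecord(
        mol_id=conformer.mol_id,
        conf_id=conformer.conf_id,
        coords=conformer.coords @ rot.T + shift,
        charges=conformer.charges,
        logp_contribs=conformer.logp_contribs,
        energy=conformer.energy,
        is_hydrogen=conformer.is_hydrogen,
    )


def sample_descriptor_population(
    weights: Sequence[float],
    means: Sequence[np.ndarray],
    covariances: Sequence[np.ndarray],
    n: int,
    seed: int,
    method: Optional[str] = None,
) -> List[ShapeDescriptor]:
    """Draw n i.i.d. descriptors from a known Gaussian mixture.

    Used as ground truth in mixture-model parameter-recovery tests.  The
    component of each draw is sampled from ``weights``; descriptors are
    tagged with synthetic molecule/conformer identifiers in draw order.
    """
    weights = np.asarray(weights, dtype=float)
    if weights.ndim != 1 or np.any(weights < 0) or abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("weights must be non-negative and sum to 1")
    means = [np.asarray(m, dtype=float) for m in means]
    covariances = [np.asarray(c, dtype=float) for c in covariances]
    if not (len(weights) == len(means) == len(covariances)):
        raise ValueError("weights, means, covariances must have equal length")
    d = means[0].shape[0]
    for c in covariances:
        if c.shape != (d, d):
            raise ValueError("covariance shape mismatch")
        if np.any(np.linalg.eigvalsh((c + c.T) / 2) <= 0):
            raise ValueError("covariances must be positive definite")
    if method is None:
        method = {12: "usr", 15: "es5d"}.get(d)
        if method is None:
            raise ValueError("descriptor dimension must be 12 or 15")
    rng = np.random.default_rng(seed)
    comps = rng.choice(len(weights), size=n, p=weights)
    return [
        ShapeDescriptor(f"pop-{i}", 0, method, rng.multivariate_normal(means[k], covariances[k]))
        for i, k in enumerate(comps)
    ]


def _mode_centers(config: ScenarioConfig, rng: np.random.Generator) -> np.ndarray:
    """Place active-mode centres pairwise >= separation apart and at distance
    ``separation`` from the decoy centre (the origin)."""
    d = config.descriptor_dim
    if config.active_modes > d:
        raise ValueError(
            f"cannot place {config.active_modes} mutually separated modes "
            f"in {d} dimensions"
        )
    # Orthogonal unit directions scaled to the requested separation: centres
    # are then sqrt(2)*separation apart from each other and exactly
    # `separation` from the origin.
    basis = np.eye(d)[: config.active_modes]
    perm = rng.permutation(d)
    return config.separation * basis[:, perm]


def make_screening_scenario(config: ScenarioConfig) -> ScreeningScenario:
    """Generate a labelled active/decoy descriptor population.

    Active molecules are assigned round-robin to ``active_modes`` Gaussian
    clusters of spread ``noise_sd``; all conformer draws of one molecule come
    from its own cluster.  Decoys are drawn from a single broad Gaussian
    (``decoy_spread_factor * noise_sd``) centred at the origin, which lies at
    distance ``separation`` from every active centre.
    """
    rng = np.random.default_rng(config.rng_seed)
    d = config.descriptor_dim
    centers = _mode_centers(config, rng)
    feature_cols = [f"m{i + 1:02d}" for i in range(d)]

    rows = []
    for i in range(config.n_actives):
        center = centers[i % config.active_modes]
        for c in range(config.n_conformers_per_mol):
            x = center + config.noise_sd * rng.standard_normal(d)
            rows.append((f"act{i:04d}", c, Label.ACTIVE.value, *x))
    decoy_sd = config.decoy_spread_factor * config.noise_sd
    for i in range(config.n_decoys):
        for c in range(config.n_conformers_per_mol):
            x = decoy_sd * rng.standard_normal(d)
            rows.append((f"dec{i:04d}", c, Label.DECOY.value, *x))

    frame = pd.DataFrame(rows, columns=["mol_id", "conf_id", "label", *feature_cols])
    return ScreeningScenario(
        config=config,
        descriptors=frame,
        active_centers=centers,
        feature_columns=feature_cols,
    )
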