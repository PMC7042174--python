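"""Machine-learning scoring models over shape descriptors.

Instead of ranking a library by inverse-Manhattan similarity to individual
templates, the descriptors of the known actives are assimilated into a single
per-target scoring model:

* **Gaussian mixture model** (one-class) — fitted by expectation-maximisation
  to active-conformer descriptors; a library descriptor is scored by the log
  of the mixture density, so descriptors falling near the shape clusters of
  the actives (their binding modes) score high.
* **Isolation forest** (one-class) — fitted to active-conformer descriptors;
  scores are the negated anomaly score, so inliers of the active distribution
  score high.
* **Single-hidden-layer neural network** (supervised) — a regressor with ReLU
  hidden activation and a linear output trained on active=1 / decoy=0 labels
  under squared-error loss; the raw output ranks the library.  Optionally the
  active rows are oversampled to balance the typically ~1:50 active:decoy
  ratio.

All three families share one convention: higher score = more active-like.
A molecule's score is the maximum over its conformer scores, mirroring the
max-over-conformer-pairs rule of classical template screening.

The training protocol is the same for every family: hold out 20% of the
molecules as a test set, select hyperparameters by 5-fold cross-validated
grid search on the remaining 80%, refit on the full 80% with the winning
hyperparameters, and evaluate on the untouched test set.  Splits are always
at molecule level — the conformers of one molecule are near-duplicates and
conformer-level splits would leak.  The one-class families never see a decoy
descriptor during fitting; decoys enter only through validation scoring.

:class:`ScreeningModel` / :class:`ScreeningResults` wrap the protocol in a
fit/results object pair; the module-level functions expose the individual
steps.
"""

from __future__ import annotations

import contextlib
import logging
from dataclasses import dataclass, field
from typing import Any, Dict, Iterator, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.ensemble import IsolationForest
from sklearn.mixture import GaussianMixture
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neural_network import MLPRegressor

from . import evaluation
from .records import Label, ScoredMolecule

logger = logging.getLogger(__name__)

FAMILIES = ("gmm", "iforest", "ann")
ONE_CLASS_FAMILIES = ("gmm", "iforest")

#: default hyperparameter grids per model family
DEFAULT_GRIDS: Dict[str, List[Dict[str, Any]]] = {
    "gmm": [{"n_components": m} for m in (1, 2, 4, 8, 16)],
    "iforest": [{"n_trees": t} for t in (100, 200)],
    "ann": [{"hidden_size": h} for h in (100, 500)],
}

# --- one-class fit audit -----------------------------------------------------
# When a recording context is active, every GMM / isolation-forest fit logs
# the labels of the rows it received, so tests can prove that no decoy
# descriptor ever reaches one-class training.
_FIT_AUDIT: Optional[List[Dict[str, Any]]] = None


@contextlib.contextmanager
def record_fits() -> Iterator[List[Dict[str, Any]]]:
    """Context manager collecting an audit entry per one-class model fit."""
    global _FIT_AUDIT
    prev, _FIT_AUDIT = _FIT_AUDIT, []
    try:
        yield _FIT_AUDIT
    finally:
        _FIT_AUDIT = prev


def _audit(family: str, X: np.ndarray, labels: Optional[Sequence[str]]) -> None:
    if _FIT_AUDIT is not None:
        _FIT_AUDIT.append(
            {
                "family": family,
                "n_rows": int(X.shape[0]),
                "labels": None if labels is None else list(labels),
            }
        )


# --- configuration -----------------------------------------------------------


@dataclass
class TrainingProtocolConfig:
    """The shared train/validate/test protocol.

    20% of molecules are held out as the final test set; hyperparameters are
    chosen by ``cv_folds``-fold cross-validated grid search on the remainder,
    scored by ``selection_metric`` ('roc_auc', the default, or 'ef1').
    ``balance_by_oversampling`` applies to the supervised ANN only.
    """

    test_fraction: float = 0.20
    cv_folds: int = 5
    grids: Dict[str, List[Dict[str, Any]]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_GRIDS.items()}
    )
    selection_metric: str = "roc_auc"
    rng_seed: int = 0
    balance_by_oversampling: bool = False
    gmm_reg_covar: float = 1e-6
    iforest_subsample: int = 256
    ann_max_iter: int = 300

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.selection_metric not in ("roc_auc", "ef1"):
            raise ValueError("selection_metric must be 'roc_auc' or 'ef1'")


@dataclass
class FractionSweepConfig:
    """The training-set-size sweep: 8 sizes x 2 conformer modes = 16 cells."""

    fractions: Tuple[float, ...] = (1.0, 0.8, 0.6, 0.5, 0.3, 0.1, 0.05)
    absolute_counts: Tuple[int, ...] = (10,)
    modes: Tuple[str, ...] = ("full", "lec")
    ef_percent: float = 1.0

    def __post_init__(self) -> None:
        for f in self.fractions:
            if not 0 < f <= 1:
                raise ValueError("fractions must be in (0, 1]")
        for c in self.absolute_counts:
            if c < 1:
                raise ValueError("absolute counts must be >= 1")


# --- fitted-model containers -------------------------------------------------


@dataclass
class GmmModel:
    """Fitted Gaussian mixture (EM), delegating to scikit-learn."""

    n_components: int
    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    sk_model: GaussianMixture


@dataclass
class IsolationForestModel:
    n_trees: int
    subsample_size: int
    sk_model: IsolationForest


@dataclass
class AnnModel:
    hidden_size: int
    sk_model: MLPRegressor


@dataclass
class TrainedScreenModel:
    """A fitted scoring model plus the metadata of its training run."""

    family: str
    hyperparams: Dict[str, Any]
    model: Any
    mode: str
    selection_metric: str
    rng_seed: int
    cv_table: Optional[pd.DataFrame] = None

    def score(self, X: np.ndarray) -> np.ndarray:
        return score_descriptors(self.family, self.model, X)


# --- fitting and scoring primitives -----------------------------------------


def fit_gmm(
    X: np.ndarray,
    n_components: int,
    config: TrainingProtocolConfig,
    labels: Optional[Sequence[str]] = None,
) -> GmmModel:
    """Fit an M-component full-covariance Gaussian mixture by EM.

    ``X`` must hold active-conformer descriptors only; a small diagonal
    regulariser keeps covariances positive definite.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < n_components:
        raise ValueError(
            f"need at least {n_components} samples to fit {n_components} components"
        )
    _audit("gmm", X, labels)
    sk = GaussianMixture(
        n_components=n_components,
        covariance_type="full",
        reg_covar=config.gmm_reg_covar,
        max_iter=500,
        n_init=1,
        random_state=config.rng_seed % (2**31),
    )
    sk.fit(X)
    if not np.all(np.isfinite(sk.weights_)):
        raise ValueError("GMM fit produced non-finite weights")
    return GmmModel(
        n_components=n_components,
        weights=sk.weights_,
        means=sk.means_,
        covariances=sk.covariances_,
        sk_model=sk,
    )


def gmm_score(model: GmmModel, X: np.ndarray) -> np.ndarray:
    """Log mixture density of each row; higher = more active-like."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.means.shape[1]:
        raise ValueError(
            f"dimension mismatch: model is {model.means.shape[1]}-d, "
            f"input is {X.shape[1]}-d"
        )
    return model.sk_model.score_samples(X)


def fit_isolation_forest(
    X: np.ndarray,
    config: TrainingProtocolConfig,
    n_trees: int = 100,
    labels: Optional[Sequence[str]] = None,
) -> IsolationForestModel:
    """Fit an isolation forest to active-conformer descriptors."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("isolation forest requires at least 2 samples")
    _audit("iforest", X, labels)
    subsample = min(config.iforest_subsample, X.shape[0])
    sk = IsolationForest(
        n_estimators=n_trees,
        max_samples=subsample,
        random_state=config.rng_seed % (2**31),
    )
    sk.fit(X)
    return IsolationForestModel(n_trees=n_trees, subsample_size=subsample, sk_model=sk)


def if_score(model: IsolationForestModel, X: np.ndarray) -> np.ndarray:
    """Negated anomaly score (normality); higher = more active-like."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return model.sk_model.score_samples(X)


def oversample_actives(
    X: np.ndarray, y: np.ndarray, seed: int
) -> Tuple[np.ndarray, np.ndarray]:
    """Duplicate active rows until the active:decoy row counts balance.

    Whole copies are taken first; any remainder is drawn without replacement
    so the final active count equals the decoy count exactly.
    """
    y = np.asarray(y)
    act_idx = np.flatnonzero(y == 1)
    dec_idx = np.flatnonzero(y == 0)
    n_act, n_dec = act_idx.size, dec_idx.size
    if n_act == 0 or n_dec == 0 or n_act >= n_dec:
        return X, y
    reps, rem = divmod(n_dec, n_act)
    rng = np.random.default_rng(seed)
    extra = rng.choice(act_idx, size=rem, replace=False)
    all_idx = np.concatenate([dec_idx] + [act_idx] * reps + [extra])
    return X[all_idx], y[all_idx]


def fit_ann(
    X: np.ndarray,
    y: np.ndarray,
    config: TrainingProtocolConfig,
    hidden_size: int = 100,
) -> AnnModel:
    """Train the single-hidden-layer regressor (ReLU hidden, linear output).

    Labels are active=1 / decoy=0 and the network is trained as a regression
    under squared-error loss; ranking uses the raw (unbounded) output.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(set(y.tolist())) < 2:
        raise ValueError("ANN training requires both active and decoy rows")
    if config.balance_by_oversampling:
        X, y = oversample_actives(X, (y > 0.5).astype(int), config.rng_seed)
        y = y.astype(float)
    sk = MLPRegressor(
        hidden_layer_sizes=(hidden_size,),
        activation="relu",
        solver="adam",
        max_iter=config.ann_max_iter,
        early_stopping=True,
        n_iter_no_change=10,
        random_state=config.rng_seed % (2**31),
    )
    sk.fit(X, y)
    return AnnModel(hidden_size=hidden_size, sk_model=sk)


def ann_score(model: AnnModel, X: np.ndarray) -> np.ndarray:
    """Raw linear output of the network; higher = more active-like."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return model.sk_model.predict(X)


def score_descriptors(family: str, model: Any, X: np.ndarray) -> np.ndarray:
    if family == "gmm":
        return gmm_score(model, X)
    if family == "iforest":
        return if_score(model, X)
    if family == "ann":
        return ann_score(model, X)
    raise ValueError(f"unknown model family {family!r}")


def molecule_score(scores: Sequence[float]) -> float:
    """Aggregate per-conformer scores to one molecule score (max rule)."""
    scores = list(scores)
    if not scores:
        raise ValueError("molecule_score requires at least one conformer score")
    return float(max(scores))


# --- protocol steps ----------------------------------------------------------


def _molecule_table(frame: pd.DataFrame) -> pd.DataFrame:
    mols = frame[["mol_id", "label"]].drop_duplicates("mol_id")
    return mols.sort_values("mol_id").reset_index(drop=True)


def split_train_test(
    frame: pd.DataFrame, config: TrainingProtocolConfig
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Molecule-level stratified 80/20 split of a descriptor frame.

    Every conformer of a molecule lands on the same side, and the two sides
    are disjoint in mol_id by construction.
    """
    if frame.empty:
        raise ValueError("descriptor frame is empty")
    mols = _molecule_table(frame)
    counts = mols["label"].value_counts()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(f"cannot stratify: label classes with < 2 molecules: {bad}")
    train_ids, test_ids = train_test_split(
        mols["mol_id"],
        test_size=config.test_fraction,
        stratify=mols["label"],
        random_state=config.rng_seed % (2**31),
    )
    train = frame[frame["mol_id"].isin(set(train_ids))].reset_index(drop=True)
    test = frame[frame["mol_id"].isin(set(test_ids))].reset_index(drop=True)
    return train, test


def select_lec_rows(frame: pd.DataFrame) -> pd.DataFrame:
    """Reduce a descriptor frame to one conformer per molecule.

    The lowest-energy conformer is kept when an ``energy`` column is present;
    otherwise the lowest ``conf_id`` stands in (ties by conf_id).
    """
    by = ["energy", "conf_id"] if "energy" in frame.columns else ["conf_id"]
    idx = frame.sort_values(["mol_id"] + by, kind="mergesort").groupby("mol_id").head(1)
    return idx.reset_index(drop=True)


def _rank_molecules(
    frame: pd.DataFrame, feature_columns: Sequence[str], family: str, model: Any
) -> List[ScoredMolecule]:
    scores = score_descriptors(family, model, frame[feature_columns].to_numpy())
    agg = (
        frame.assign(_score=scores)
        .groupby("mol_id")
        .agg(score=("_score", "max"), label=("label", "first"))
        .reset_index()
    )
    scored = [
        ScoredMolecule(r.mol_id, float(r.score), Label(r.label))
        for r in agg.itertuples()
    ]
    scored.sort(key=lambda m: (-m.score, m.mol_id))
    return scored


def _fit_family(
    family: str,
    train: pd.DataFrame,
    feature_columns: Sequence[str],
    params: Dict[str, Any],
    config: TrainingProtocolConfig,
) -> Any:
    """Fit one model; one-class families receive active rows only."""
    if family in ONE_CLASS_FAMILIES:
        act = train[train["label"] == Label.ACTIVE.value]
        X = act[feature_columns].to_numpy()
        labels = act["label"].tolist()
        if family == "gmm":
            return fit_gmm(X, params["n_components"], config, labels=labels)
        return fit_isolation_forest(
            X, config, n_trees=params["n_trees"], labels=labels
        )
    X = train[feature_columns].to_numpy()
    y = (train["label"] == Label.ACTIVE.value).astype(float).to_numpy()
    return fit_ann(X, y, config, hidden_size=params["hidden_size"])


def _validation_metric(
    ranked: List[ScoredMolecule], metric: str, ef_percent: float = 1.0
) -> float:
    if metric == "roc_auc":
        return evaluation.roc_auc(ranked)
    return evaluation.enrichment_factor(ranked, ef_percent).ef


def cv_grid_search(
    train: pd.DataFrame,
    feature_columns: Sequence[str],
    family: str,
    config: TrainingProtocolConfig,
) -> Tuple[Dict[str, Any], pd.DataFrame]:
    """Molecule-level k-fold cross-validated grid search.

    One-class families fit on the active conformers of the training folds and
    are scored on the actives *and* decoys of the held-out fold; the ANN fits
    on both classes.  Returns the winning grid point (first in grid order on
    ties) and the per-point mean-score table.
    """
    grid = config.grids.get(family, DEFAULT_GRIDS[family])
    if not grid:
        raise ValueError(f"empty hyperparameter grid for family {family!r}")
    mols = _molecule_table(train)
    class_counts = mols["label"].value_counts()
    n_folds = int(min(config.cv_folds, class_counts.min()))
    if len(grid) == 1:
        return grid[0], pd.DataFrame([{**grid[0], "mean_score": np.nan}])
    # below 3 molecules per class a fold's training side can drop to a single
    # molecule; cross-validation is meaningless there, so fall back
    if n_folds < 2 or class_counts.min() < 3:
        logger.warning(
            "too few molecules per class for cross-validation; "
            "using first grid point %s",
            grid[0],
        )
        return grid[0], pd.DataFrame([{**grid[0], "mean_score": np.nan}])

    skf = StratifiedKFold(
        n_splits=n_folds, shuffle=True, random_state=config.rng_seed % (2**31)
    )
    folds = list(skf.split(mols["mol_id"], mols["label"]))
    rows = []
    best: Optional[Tuple[float, int]] = None
    for gi, params in enumerate(grid):
        fold_scores = []
        try:
            for tr_idx, va_idx in folds:
                tr_ids = set(mols["mol_id"].iloc[tr_idx])
                va_ids = set(mols["mol_id"].iloc[va_idx])
                fold_train = train[train["mol_id"].isin(tr_ids)]
                fold_val = train[train["mol_id"].isin(va_ids)]
                model = _fit_family(family, fold_train, feature_columns, params, config)
                ranked = _rank_molecules(fold_val, feature_columns, family, model)
                fold_scores.append(
                    _validation_metric(ranked, config.selection_metric)
                )
            mean_score = float(np.mean(fold_scores))
        except ValueError as exc:
            logger.warning("grid point %s failed: %s", params, exc)
            mean_score = -np.inf
        rows.append({**params, "mean_score": mean_score})
        if np.isfinite(mean_score) and (best is None or mean_score > best[0]):
            best = (mean_score, gi)
    if best is None:
        raise ValueError(f"all grid points failed for family {family!r}")
    return grid[best[1]], pd.DataFrame(rows)


def train_and_screen(
    frame: pd.DataFrame,
    feature_columns: Sequence[str],
    family: str,
    config: TrainingProtocolConfig,
    mode: str = "full",
) -> Tuple[TrainedScreenModel, List[ScoredMolecule]]:
    """Run the full protocol and rank the held-out test molecules.

    split -> grid search -> final fit on the training portion -> score and
    rank the test molecules (descending score, mol_id tie-break).  In ``lec``
    mode the frame is first reduced to one conformer per molecule.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown model family {family!r}")
    if mode not in ("full", "lec"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "lec":
        frame = select_lec_rows(frame)
    train, test = split_train_test(frame, config)
    params, cv_table = cv_grid_search(train, feature_columns, family, config)
    model = _fit_family(family, train, feature_columns, params, config)
    trained = TrainedScreenModel(
        family=family,
        hyperparams=params,
        model=model,
        mode=mode,
        selection_metric=config.selection_metric,
        rng_seed=config.rng_seed,
        cv_table=cv_table,
    )
    ranking = _rank_molecules(test, feature_columns, family, model)
    return trained, ranking


def fraction_sweep(
    frame: pd.DataFrame,
    feature_columns: Sequence[str],
    family: str,
    sweep: FractionSweepConfig,
    config: TrainingProtocolConfig,
) -> pd.DataFrame:
    """Retrain at successively smaller active training sets.

    For each of the configured dataset sizes (7 fractions plus the absolute
    counts, 8 by default) and each conformer mode, the *training* actives are
    subsampled at random (for the supervised ANN the decoys are subsampled
    proportionally; one-class models never see decoys), the model is
    retrained per protocol, and the untouched test set is re-evaluated.
    Returns one row per (size, mode) cell — 16 by default — with EF and AUC;
    cells whose subsample cannot support training are marked unavailable
    (NaN metrics) rather than fatal.
    """
    sizes: List[Tuple[str, Optional[float], Optional[int]]] = [
        (f"{f:g}", f, None) for f in sweep.fractions
    ] + [(f"n={c}", None, c) for c in sweep.absolute_counts]

    rows = []
    for mode in sweep.modes:
        mode_frame = select_lec_rows(frame) if mode == "lec" else frame
        train, test = split_train_test(mode_frame, config)
        train_mols = _molecule_table(train)
        act_ids = train_mols.loc[
            train_mols["label"] == Label.ACTIVE.value, "mol_id"
        ].to_numpy()
        dec_ids = train_mols.loc[
            train_mols["label"] == Label.DECOY.value, "mol_id"
        ].to_numpy()
        for si, (size_label, fraction, count) in enumerate(sizes):
            mode_offset = {"full": 0, "lec": 1}.get(mode, 2)
            cell_seed = (config.rng_seed * 10007 + si * 101 + mode_offset * 97) % (2**31)
            rng = np.random.default_rng(cell_seed)
            n_keep = (
                count if count is not None else int(round(fraction * act_ids.size))
            )
            n_keep = min(n_keep, act_ids.size)
            row: Dict[str, Any] = {
                "fraction": size_label,
                "mode": mode,
                "n_actives_train": n_keep,
            }
            if n_keep == 0:
                row.update(ef=np.nan, roc_auc=np.nan, available=False)
                rows.append(row)
                continue
            keep_act = set(rng.choice(act_ids, size=n_keep, replace=False))
            keep = keep_act
            if family == "ann":
                frac_kept = n_keep / act_ids.size
                n_dec = max(1, int(round(frac_kept * dec_ids.size)))
                keep = keep_act | set(rng.choice(dec_ids, size=n_dec, replace=False))
            else:
                keep = keep_act | set(dec_ids)  # decoys only reach CV validation
            sub_train = train[train["mol_id"].isin(keep)]
            cell_config = TrainingProtocolConfig(
                test_fraction=config.test_fraction,
                cv_folds=config.cv_folds,
                grids=config.grids,
                selection_metric=config.selection_metric,
                rng_seed=cell_seed,
                balance_by_oversampling=config.balance_by_oversampling,
                gmm_reg_covar=config.gmm_reg_covar,
                iforest_subsample=config.iforest_subsample,
                ann_max_iter=config.ann_max_iter,
            )
            try:
                params, _ = cv_grid_search(
                    sub_train, feature_columns, family, cell_config
                )
                model = _fit_family(
                    family, sub_train, feature_columns, params, cell_config
                )
                ranked = _rank_molecules(test, feature_columns, family, model)
                row.update(
                    ef=evaluation.enrichment_factor(ranked, sweep.ef_percent).ef,
                    roc_auc=evaluation.roc_auc(ranked),
                    available=True,
                    hyperparams=str(params),
                )
            except ValueError as exc:
                logger.warning("sweep cell (%s, %s) unavailable: %s", size_label, mode, exc)
                row.update(ef=np.nan, roc_auc=np.nan, available=False)
            rows.append(row)
    return pd.DataFrame(rows)


# --- model-object interface --------------------------------------------------


class ScreeningModel:
    """Statsmodels-style front end to the training protocol.

    Construct from a tidy descriptor frame (columns ``mol_id``, ``conf_id``,
    ``label`` plus feature columns) or from a
    :class:`~usrml.synthetic_fixtures.ScreeningScenario`, choose a model
    family and protocol, then call :meth:`fit`.
    """

    def __init__(
        self,
        frame: pd.DataFrame,
        feature_columns: Sequence[str],
        family: str = "gmm",
        config: Optional[TrainingProtocolConfig] = None,
        mode: str = "full",
    ) -> None:
        required = {"mol_id", "conf_id", "label"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"descriptor frame missing columns: {sorted(missing)}")
        if family not in FAMILIES:
            raise ValueError(f"unknown model family {family!r}")
        self.frame = frame
        self.feature_columns = list(feature_columns)
        self.family = family
        self.config = config or TrainingProtocolConfig()
        self.mode = mode

    @classmethod
    def from_scenario(
        cls,
        scenario: "Any",
        family: str = "gmm",
        config: Optional[TrainingProtocolConfig] = None,
        mode: str = "full",
    ) -> "ScreeningModel":
        return cls(
            scenario.descriptors,
            scenario.feature_columns,
            family=family,
            config=config,
            mode=mode,
        )

    def fit(self) -> "ScreeningResults":
        trained, ranking = train_and_screen(
            self.frame, self.feature_columns, self.family, self.config, self.mode
        )
        return ScreeningResults(self, trained, ranking)

    def fraction_sweep(
        self, sweep: Optional[FractionSweepConfig] = None
    ) -> pd.DataFrame:
        return fraction_sweep(
            self.frame,
            self.feature_columns,
            self.family,
            sweep or FractionSweepConfig(),
            self.config,
        )


class ScreeningResults:
    """Held-out ranking and metrics produced by :meth:`ScreeningModel.fit`."""

    def __init__(
        self,
        model: ScreeningModel,
        trained: TrainedScreenModel,
        ranking: List[ScoredMolecule],
    ) -> None:
        self.model = model
        self.trained = trained
        self.ranking = ranking

    def ef(self, x_percent: float = 1.0) -> float:
        return evaluation.enrichment_factor(self.ranking, x_percent).ef

    @property
    def roc_auc(self) -> float:
        return evaluation.roc_auc(self.ranking)

    def report(
        self,
        ef_percentages: Sequence[float] = (1.0, 0.25),
        baseline: Optional[Sequence[ScoredMolecule]] = None,
        baseline_name: Optional[str] = None,
    ) -> evaluation.EvaluationReport:
        return evaluation.summarize(
            self.ranking, ef_percentages, baseline=baseline, baseline_name=baseline_name
        )

    def summary(self) -> str:
        n_act = sum(1 for m in self.ranking if m.label == Label.ACTIVE)
        lines = [
            "Virtual screening results",
            "=" * 56,
            f"model family:      {self.trained.family}",
            f"conformer mode:    {self.trained.mode}",
            f"hyperparameters:   {self.trained.hyperparams}",
            f"selection metric:  {self.trained.selection_metric}",
            f"test molecules:    {len(self.ranking)} ({n_act} active)",
            f"EF 1%:             {self.ef(1.0):.3f}",
            f"ROC AUC:           {self.roc_auc:.4f}",
        ]
        if self.trained.cv_table is not None and len(self.trained.cv_table) > 1:
            lines.append("cross-validation grid:")
            lines.append(self.trained.cv_table.to_string(index=False))
        return "\n".join(lines)
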