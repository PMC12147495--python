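"""Sub-dataset ensemble: resampling, model selection, nested CV.

The variability machinery: from a dataset whose materials each carry
1..k repeated response measurements, draw N sub-datasets by selecting
one measurement per material uniformly at random (features unchanged).
For each sub-dataset, candidate regressors compete by inner-CV r^2 on
standardised features and the winner is refitted; predictive estimates
come from double (nested) cross-validation, so every material receives
one out-of-fold estimate per sub-dataset — an N-vector per material
whose spread is the predicted variability.

Method selection runs inside each outer training fold (proper nested
CV), so the inner selection never sees held-out rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.base import clone
from sklearn.metrics import r2_score
from sklearn.model_selection import KFold
from sklearn.preprocessing import StandardScaler

from .data import FeatureTable, MaterialDataset, MethodCombo, assemble_feature_matrix
from .features import BandList, impute_missing

__all__ = [
    "SubDataset",
    "ModelZoo",
    "EnsemblePrediction",
    "default_zoo",
    "fast_zoo",
    "generate_subdatasets",
    "select_and_fit",
    "double_cross_validate",
    "predict_ensemble",
]


class FoldError(ValueError):
    """Too few materials for the requested fold counts."""


class DegenerateTargetError(ValueError):
    """Responses in a training set have zero variance."""


@dataclass
class SubDataset:
    """One resampled copy: shared features, one response per material."""

    feature_table: FeatureTable
    responses: np.ndarray
    chosen_index: np.ndarray

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=float)
        self.chosen_index = np.asarray(self.chosen_index, dtype=int)
        n = len(self.feature_table.material_ids)
        if self.responses.shape != (n,) or self.chosen_index.shape != (n,):
            raise ValueError("responses/chosen_index must have one entry per material")


@dataclass
class ModelZoo:
    """Candidate regressors with small hyperparameter grids.

    ``methods`` maps method name -> list of (estimator factory, params)
    pairs; each factory takes a random_state-like seed and returns an
    unfitted sklearn-compatible estimator.
    """

    methods: dict[str, list[Callable[[int], object]]]

    def __post_init__(self) -> None:
        if not self.methods:
            raise ValueError("zoo must contain at least one method")

    @property
    def names(self) -> list[str]:
        return list(self.methods)

    def candidates(self, seed: int):
        """Yield (method_name, unfitted estimator) over the whole grid."""
        for name, factories in self.methods.items():
            for factory in factories:
                yield name, factory(seed)


def default_zoo(max_pls_components: int = 10) -> ModelZoo:
    """The full 13-method zoo: 6 linear + 7 nonlinear regressors.

    Grids are small, conventional ones (log-spaced regularisation for
    ridge/lasso/elastic net, C/gamma log grids for SVR, shallow-to-deep
    trees, ~100-tree forests and boosters); they live here rather than
    in the methods themselves so runs can shrink or extend them.
    """
    from sklearn.cross_decomposition import PLSRegression
    from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
    from sklearn.gaussian_process import GaussianProcessRegressor
    from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel
    from sklearn.linear_model import ElasticNet, Lasso, LinearRegression, Ridge
    from sklearn.svm import SVR, LinearSVR
    from sklearn.tree import DecisionTreeRegressor

    methods: dict[str, list] = {}
    methods["ols"] = [lambda seed: LinearRegression()]
    methods["pls"] = [
        (lambda seed, k=k: PLSRegression(n_components=k))
        for k in range(1, max_pls_components + 1)
    ]
    methods["ridge"] = [
        (lambda seed, a=a: Ridge(alpha=a)) for a in np.logspace(-3, 3, 7)
    ]
    methods["lasso"] = [
        (lambda seed, a=a: Lasso(alpha=a, max_iter=5000)) for a in np.logspace(-4, 1, 6)
    ]
    methods["elastic-net"] = [
        (lambda seed, a=a, l1=l1: ElasticNet(alpha=a, l1_ratio=l1, max_iter=5000))
        for a in np.logspace(-4, 1, 4)
        for l1 in (0.3, 0.7)
    ]
    methods["linear-svr"] = [
        (lambda seed, c=c: LinearSVR(C=c, max_iter=10000, dual="auto"))
        for c in (0.1, 1.0, 10.0)
    ]
    methods["gpr"] = [
        lambda seed: GaussianProcessRegressor(
            kernel=ConstantKernel() * RBF() + WhiteKernel(),
            normalize_y=True,
            random_state=seed,
        )
    ]
    methods["nonlinear-svr"] = [
        (lambda seed, c=c, g=g: SVR(C=c, gamma=g))
        for c in (1.0, 10.0, 100.0)
        for g in ("scale", 0.01)
    ]
    methods["decision-tree"] = [
        (lambda seed, d=d: DecisionTreeRegressor(max_depth=d, random_state=seed))
        for d in (3, 5, None)
    ]
    methods["random-forest"] = [
        (lambda seed, mf=mf: RandomForestRegressor(
            n_estimators=100, max_features=mf, random_state=seed, n_jobs=1
        ))
        for mf in ("sqrt", 1.0)
    ]
    methods["gbdt"] = [
        lambda seed: GradientBoostingRegressor(n_estimators=100, random_state=seed)
    ]
    methods["xgb"] = [lambda seed: _make_xgb(seed)]
    methods["lgbm"] = [lambda seed: _make_lgbm(seed)]
    return ModelZoo(methods)


def _make_xgb(seed: int):
    from xgboost import XGBRegressor

    return XGBRegressor(
        n_estimators=100, max_depth=3, learning_rate=0.1, random_state=seed, verbosity=0
    )


def _make_lgbm(seed: int):
    from lightgbm import LGBMRegressor

    return LGBMRegressor(
        n_estimators=100, max_depth=3, random_state=seed, verbose=-1, min_child_samples=5
    )


def fast_zoo(names: Sequence[str] = ("ridge", "random-forest")) -> ModelZoo:
    """A reduced zoo for quick runs: tiny grids, 50-tree forests."""
    from sklearn.cross_decomposition import PLSRegression
    from sklearn.ensemble import RandomForestRegressor
    from sklearn.linear_model import LinearRegression, Ridge
    from sklearn.tree import DecisionTreeRegressor

    catalogue: dict[str, list] = {
        "ols": [lambda seed: LinearRegression()],
        "ridge": [(lambda seed, a=a: Ridge(alpha=a)) for a in (0.01, 0.1, 1.0, 10.0)],
        "pls": [(lambda seed, k=k: PLSRegression(n_components=k)) for k in (1, 2, 3)],
        "decision-tree": [
            (lambda seed, d=d: DecisionTreeRegressor(max_depth=d, random_state=seed))
            for d in (3, None)
        ],
        "random-forest": [
            lambda seed: RandomForestRegressor(n_estimators=50, random_state=seed, n_jobs=1)
        ],
    }
    unknown = set(names) - set(catalogue)
    if unknown:
        raise ValueError(f"unknown fast-zoo methods: {sorted(unknown)}")
    return ModelZoo({n: catalogue[n] for n in names})


def zoo_from_names(names: Sequence[str]) -> ModelZoo:
    """Subset of the full default zoo by method name."""
    full = default_zoo()
    unknown = set(names) - set(full.methods)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}; choose from {full.names}")
    return ModelZoo({n: full.methods[n] for n in names})


def generate_subdatasets(
    dataset: MaterialDataset,
    feature_table: FeatureTable,
    n_subdatasets: int,
    seed: int = 0,
) -> list[SubDataset]:
    """Draw N sub-datasets, one uniformly chosen measurement per material."""
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    if n_subdatasets < 1:
        raise ValueError("n_subdatasets must be >= 1")
    rng = np.random.default_rng(seed)
    counts = np.array([s.n_measurements for s in dataset.samples])
    meas = dataset.measurements_list()
    subs = []
    for _ in range(n_subdatasets):
        idx = rng.integers(0, counts)  # uniform over each material's measurements
        responses = np.array([meas[i][idx[i]] for i in range(len(meas))])
        subs.append(SubDataset(feature_table=feature_table, responses=responses, chosen_index=idx))
    return subs


@dataclass
class _FittedModel:
    method: str
    scaler: StandardScaler
    estimator: object
    inner_cv_r2: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self.estimator.predict(self.scaler.transform(X))).ravel()


def _inner_cv_score(est, folds) -> float:
    scores = []
    for (Xtr, ytr), (Xva, yva) in folds:
        m = clone(est)
        m.fit(Xtr, ytr)
        scores.append(r2_score(yva, np.asarray(m.predict(Xva)).ravel()))
    return float(np.mean(scores))


def select_and_fit(
    X: np.ndarray,
    y: np.ndarray,
    zoo: ModelZoo,
    inner_folds: int = 5,
    seed: int = 0,
) -> _FittedModel:
    """Pick the best method/grid point by mean inner-CV r^2 and refit.

    Features are standardised with statistics of each inner training
    fold (and of the full training set for the final refit). Ties break
    toward the earlier candidate in zoo order.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(y) < inner_folds:
        raise FoldError(f"{len(y)} rows < inner_folds={inner_folds}")
    if np.var(y) == 0:
        raise DegenerateTargetError("training responses have zero variance")

    kf = KFold(n_splits=inner_folds, shuffle=True, random_state=seed % (2**32 - 1))
    # Pre-scale once per fold; shared by every candidate for speed and fairness.
    folds = []
    for tr, va in kf.split(X):
        sc = StandardScaler().fit(X[tr])
        folds.append(((sc.transform(X[tr]), y[tr]), (sc.transform(X[va]), y[va])))

    best = None
    for name, est in zoo.candidates(seed):
        score = _inner_cv_score(est, folds)
        if best is None or score > best[0]:
            best = (score, name, est)

    score, name, est = best
    scaler = StandardScaler().fit(X)
    final = clone(est)
    final.fit(scaler.transform(X), y)
    return _FittedModel(method=name, scaler=scaler, estimator=final, inner_cv_r2=score)


def double_cross_validate(
    sub: SubDataset,
    zoo: ModelZoo,
    inner_folds: int = 5,
    outer_folds: int = 10,
    seed: int = 0,
) -> tuple[np.ndarray, list[str]]:
    """Nested CV over one sub-dataset.

    Materials are split into shuffled outer folds; within each outer
    training set, :func:`select_and_fit` chooses and fits a model which
    then predicts the held-out materials. Returns (one out-of-fold
    estimate per material, chosen method name per outer fold).
    """
    X = sub.feature_table.matrix
    y = sub.responses
    n = len(y)
    if n < outer_folds:
        raise FoldError(f"{n} materials < outer_folds={outer_folds}")
    estimates = np.full(n, np.nan)
    chosen: list[str] = []
    kf = KFold(n_splits=outer_folds, shuffle=True, random_state=seed % (2**32 - 1))
    for k, (tr, te) in enumerate(kf.split(X)):
        model = select_and_fit(X[tr], y[tr], zoo, inner_folds=inner_folds, seed=seed + 1000 * (k + 1))
        estimates[te] = model.predict(X[te])
        chosen.append(model.method)
    assert not np.isnan(estimates).any()
    return estimates, chosen


@dataclass
class EnsemblePrediction:
    """Per-material vectors of out-of-fold estimates across sub-datasets."""

    material_ids: list[str]
    matrix: np.ndarray  # rows = materials, columns = sub-datasets
    chosen_methods: list[list[str]]  # per sub-dataset, per outer fold
    n_models_fitted: int

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[0] != len(self.material_ids):
            raise ValueError("one estimate row per material required")

    @property
    def n_subdatasets(self) -> int:
        return self.matrix.shape[1]

    @property
    def estimates(self) -> dict[str, np.ndarray]:
        return {m: self.matrix[i] for i, m in enumerate(self.material_ids)}

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.matrix,
            index=self.material_ids,
            columns=[f"sub_{j}" for j in range(self.n_subdatasets)],
        )


def predict_ensemble(
    dataset: MaterialDataset,
    combo: MethodCombo | str,
    zoo: ModelZoo,
    n_subdatasets: int = 100,
    inner_folds: int = 5,
    outer_folds: int = 10,
    seed: int = 0,
    ftir_bands: BandList | None = None,
    xrd_bands: BandList | None = None,
    lbp_normalize: bool = True,
    impute_components: int = 1,
) -> EnsemblePrediction:
    """Full pipeline: featurize, resample, nested-CV per sub-dataset.

    The feature matrix is assembled once (identical X across
    sub-datasets); NaN cells from missing image blocks are imputed
    before modelling. Per-sub-dataset seeds derive from ``seed`` so the
    fold shuffles differ across sub-datasets but the whole run is
    reproducible from the one root seed.
    """
    table = assemble_feature_matrix(
        dataset, combo, ftir_bands=ftir_bands, xrd_bands=xrd_bands, lbp_normalize=lbp_normalize
    )
    if table.has_missing:
        table = impute_missing(table, n_components=impute_components, seed=seed)
    subs = generate_subdatasets(dataset, table, n_subdatasets, seed=seed)
    rows = np.empty((len(dataset), n_subdatasets))
    methods: list[list[str]] = []
    for j, sub in enumerate(subs):
        est, chosen = double_cross_validate(
            sub, zoo, inner_folds=inner_folds, outer_folds=outer_folds, seed=seed + j + 1
        )
        rows[:, j] = est
        methods.append(chosen)
    return EnsemblePrediction(
        material_ids=list(dataset.material_ids),
        matrix=rows,
        chosen_methods=methods,
        n_models_fitted=n_subdatasets * outer_folds,
    )
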