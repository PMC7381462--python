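"""Random-forest panel selection for clinical-lipid prediction.

Discovery-stage procedure: split the cohort 70:30 into training and test
sets, fit a random-forest regression of the clinical lipid on *all* lipids in
the training set, rank lipids by importance, then grow a panel by forward
addition in rank order — refitting at each size — until the panel model's
test-set correlation comes within a tolerance of the all-lipid model's. The
result is an ordered lipid panel with its training mean square of residuals
(MSR) and test-set Pearson r/p.

:class:`PanelGrower` is the scikit-learn estimator that runs the whole
procedure in ``fit``; the module functions (``split_cohort``,
``rank_all_lipids``, ``grow_panel``, ``evaluate``) expose the individual
stages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance

__all__ = [
    "RFConfig",
    "SplitSpec",
    "PanelModel",
    "PanelGrower",
    "split_cohort",
    "rank_all_lipids",
    "grow_panel",
    "evaluate",
]


@dataclass
class RFConfig:
    """Random-forest hyperparameters.

    Defaults follow the classic regression-forest conventions: 500 trees and
    p/3 candidate features per split. ``importance`` is "permutation"
    (importance measured by test-free permutation on the training set) or
    "impurity" (faster, slightly biased toward high-cardinality features —
    immaterial here since all features are continuous).
    """

    n_estimators: int = 500
    max_features: float | str = 1.0 / 3.0
    seed: int = 0
    importance: str = "permutation"
    n_permutation_repeats: int = 5
    n_jobs: int = 1

    def make_forest(self) -> RandomForestRegressor:
        return RandomForestRegressor(
            n_estimators=self.n_estimators,
            max_features=self.max_features,
            random_state=self.seed,
            n_jobs=self.n_jobs,
        )


@dataclass
class SplitSpec:
    """Train/test split: 70:30 by default, seeded, optionally quartile-stratified."""

    train_fraction: float = 0.70
    seed: int = 0
    stratified: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass
class PanelModel:
    """A grown lipid panel and its performance record."""

    target: str
    panel: list[str]
    training_msr: float
    test_r: float | None
    test_p: float | None
    all_lipid_test_r: float | None
    rf_config: RFConfig
    split: SplitSpec
    used_all_lipids: bool = False
    ranking: list[str] = field(default_factory=list)
    growth_trace: list[dict] = field(default_factory=list)

    def summary(self) -> dict:
        return {
            "target": self.target,
            "panel_size": len(self.panel),
            "panel": list(self.panel),
            "training_msr": self.training_msr,
            "test_r": self.test_r,
            "test_p": self.test_p,
            "all_lipid_test_r": self.all_lipid_test_r,
            "used_all_lipids": self.used_all_lipids,
        }


def split_cohort(n: int, spec: SplitSpec, y: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Seeded 70:30 (by default) split into train/test index arrays.

    |train| = round(train_fraction * n). With ``stratified=True`` (and y
    given) sampling is proportional within quartiles of y.
    """
    if n < 10:
        raise ValueError("need at least 10 samples to split")
    n_train = int(round(spec.train_fraction * n))
    if n_train == 0 or n_train == n:
        raise ValueError("split leaves one set empty")
    rng = np.random.default_rng(spec.seed)
    if spec.stratified and y is not None:
        order = np.argsort(np.argsort(y, kind="stable"), kind="stable")
        quart = order * 4 // n
        train_parts = []
        for q in range(4):
            idx = np.flatnonzero(quart == q)
            k = int(round(spec.train_fraction * idx.size))
            train_parts.append(rng.choice(idx, size=k, replace=False))
        train = np.sort(np.concatenate(train_parts))
        # pad/trim to exactly n_train for the global ratio
        rest = np.setdiff1d(np.arange(n), train)
        if train.size < n_train:
            extra = rng.choice(rest, size=n_train - train.size, replace=False)
            train = np.sort(np.concatenate([train, extra]))
        elif train.size > n_train:
            drop = rng.choice(train, size=train.size - n_train, replace=False)
            train = np.setdiff1d(train, drop)
    else:
        perm = rng.permutation(n)
        train = np.sort(perm[:n_train])
    test = np.setdiff1d(np.arange(n), train)
    return train, test


def evaluate(
    predicted: np.ndarray, measured: np.ndarray
) -> tuple[float | None, float | None, float]:
    """Test-set performance: Pearson r, its two-sided p, and the MSR.

    p comes from the t transform t = r sqrt(n-2)/sqrt(1-r^2) with n-2 df.
    Zero variance in either vector leaves r/p undefined (None) with a warning.
    """
    predicted = np.asarray(predicted, dtype=float)
    measured = np.asarray(measured, dtype=float)
    if predicted.size < 3:
        raise ValueError("need at least 3 points to evaluate")
    msr = float(np.mean((predicted - measured) ** 2))
    if np.std(predicted) == 0 or np.std(measured) == 0:
        warnings.warn("zero variance: correlation undefined", stacklevel=2)
        return None, None, msr
    r = float(np.corrcoef(predicted, measured)[0, 1])
    n = predicted.size
    if abs(r) >= 1.0:
        return float(np.sign(r)), 0.0, msr
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return r, p, msr


def rank_all_lipids(
    X_train: pd.DataFrame, y_train: np.ndarray, rf_config: RFConfig | None = None
) -> tuple[list[str], RandomForestRegressor]:
    """Fit the all-lipid forest on training data and rank lipids by importance."""
    rf_config = rf_config or RFConfig()
    y_train = np.asarray(y_train, dtype=float)
    if np.std(y_train) == 0:
        raise ValueError("constant response: cannot rank lipids")
    if X_train.isna().any().any():
        raise ValueError("feature matrix contains missing cells")
    forest = rf_config.make_forest().fit(X_train, y_train)
    if rf_config.importance == "permutation":
        imp = permutation_importance(
            forest,
            X_train,
            y_train,
            n_repeats=rf_config.n_permutation_repeats,
            random_state=rf_config.seed,
            n_jobs=rf_config.n_jobs,
        ).importances_mean
    else:
        imp = forest.feature_importances_
    order = np.lexsort((np.arange(len(imp)), -imp))  # stable on ties
    return [X_train.columns[i] for i in order], forest


def grow_panel(
    ranking: list[str],
    X_train: pd.DataFrame,
    X_test: pd.DataFrame,
    y_train: np.ndarray,
    y_test: np.ndarray,
    tolerance: float = 0.01,
    rf_config: RFConfig | None = None,
    all_lipid_test_r: float | None = None,
    all_lipid_forest: RandomForestRegressor | None = None,
    target: str = "y",
    split: SplitSpec | None = None,
    max_panel: int | None = None,
    criterion: str = "r",
) -> PanelModel:
    """Forward panel growth in ranking order until test r matches the all-lipid model.

    Returns the smallest panel whose test-set Pearson r is >=
    ``all_lipid_test_r - tolerance``; if no proper subset qualifies, the panel
    is all lipids (flagged ``used_all_lipids``). ``criterion="msr"`` stops
    instead when the panel's test-set MSR is <= the all-lipid model's MSR
    plus ``tolerance`` (in squared mmol/L).
    """
    if not ranking:
        raise ValueError("empty ranking")
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    if criterion not in ("r", "msr"):
        raise ValueError("criterion must be 'r' or 'msr'")
    rf_config = rf_config or RFConfig()
    all_msr = None
    if all_lipid_test_r is None or criterion == "msr":
        if all_lipid_forest is None:
            all_lipid_forest = rf_config.make_forest().fit(X_train, y_train)
        pred = all_lipid_forest.predict(X_test)
        all_lipid_test_r, _, all_msr = evaluate(pred, y_test)
    goal = (all_lipid_test_r if all_lipid_test_r is not None else 0.0) - tolerance

    trace = []
    limit = len(ranking) if max_panel is None else min(max_panel, len(ranking))
    for k in range(1, limit + 1):
        cols = ranking[:k]
        forest = rf_config.make_forest().fit(X_train[cols], y_train)
        train_msr = float(np.mean((forest.predict(X_train[cols]) - y_train) ** 2))
        r, p, test_msr = evaluate(forest.predict(X_test[cols]), y_test)
        trace.append({"k": k, "test_r": r, "training_msr": train_msr})
        if criterion == "msr":
            hit = all_msr is not None and test_msr <= all_msr + tolerance
        else:
            hit = r is not None and r >= goal
        if hit:
            return PanelModel(
                target=target,
                panel=cols,
                training_msr=train_msr,
                test_r=r,
                test_p=p,
                all_lipid_test_r=all_lipid_test_r,
                rf_config=rf_config,
                split=split or SplitSpec(),
                ranking=list(ranking),
                growth_trace=trace,
            )
    # no proper subset qualified: fall back to the full lipid set
    cols = list(ranking)
    forest = rf_config.make_forest().fit(X_train[cols], y_train)
    train_msr = float(np.mean((forest.predict(X_train[cols]) - y_train) ** 2))
    r, p, _ = evaluate(forest.predict(X_test[cols]), y_test)
    return PanelModel(
        target=target,
        panel=cols,
        training_msr=train_msr,
        test_r=r,
        test_p=p,
        all_lipid_test_r=all_lipid_test_r,
        rf_config=rf_config,
        split=split or SplitSpec(),
        used_all_lipids=True,
        ranking=list(ranking),
        growth_trace=trace,
    )


class PanelGrower(BaseEstimator, RegressorMixin):
    """Two-stage discovery estimator: rank all lipids, then grow a minimal panel.

    Parameters
    ----------
    tolerance : float
        How close (in absolute test-set Pearson r) the panel model must come
        to the all-lipid model before growth stops.
    split : SplitSpec
        70:30 train/test split specification; the split is fixed before
        ranking, ranking and growth use training data only.
    stop_on : str
        "test" evaluates candidate panels on the held-out test set (the
        reported workflow); "inner" uses a leakage-safe inner validation
        split carved from the training set, and re-reports final performance
        on the untouched test set.
    max_panel : int or None
        Optional cap on panel growth; when hit, the all-lipid fallback is
        used.

    Fitted attributes: ``panel_``, ``ranking_``, ``model_`` (the panel
    forest), ``panel_model_`` (the full :class:`PanelModel` record),
    ``train_idx_``/``test_idx_``.
    """

    def __init__(
        self,
        tolerance: float = 0.01,
        split: SplitSpec | None = None,
        rf_config: RFConfig | None = None,
        stop_on: str = "test",
        max_panel: int | None = None,
        target_name: str = "y",
        criterion: str = "r",
    ):
        self.tolerance = tolerance
        self.split = split
        self.rf_config = rf_config
        self.stop_on = stop_on
        self.max_panel = max_panel
        self.target_name = target_name
        self.criterion = criterion

    def fit(self, X: pd.DataFrame, y) -> "PanelGrower":
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X))
            X.columns = [f"x{j}" for j in range(X.shape[1])]
        y = np.asarray(y, dtype=float)
        if X.shape[0] != y.size:
            raise ValueError("X and y lengths differ")
        if X.shape[0] < 30:
            raise ValueError("need at least 30 samples for panel discovery")
        if self.stop_on not in ("test", "inner"):
            raise ValueError("stop_on must be 'test' or 'inner'")
        split = self.split or SplitSpec()
        rf_config = self.rf_config or RFConfig()

        train, test = split_cohort(X.shape[0], split, y)
        X_tr, X_te = X.iloc[train], X.iloc[test]
        y_tr, y_te = y[train], y[test]

        ranking, all_forest = rank_all_lipids(X_tr, y_tr, rf_config)
        all_r, _, _ = evaluate(all_forest.predict(X_te), y_te)

        if self.stop_on == "inner":
            inner_split = SplitSpec(split.train_fraction, split.seed + 1, split.stratified)
            itr, ival = split_cohort(len(train), inner_split, y_tr)
            inner_all = rf_config.make_forest().fit(X_tr.iloc[itr], y_tr[itr])
            inner_all_r, _, _ = evaluate(inner_all.predict(X_tr.iloc[ival]), y_tr[ival])
            pm = grow_panel(
                ranking,
                X_tr.iloc[itr],
                X_tr.iloc[ival],
                y_tr[itr],
                y_tr[ival],
                tolerance=self.tolerance,
                rf_config=rf_config,
                all_lipid_test_r=inner_all_r,
                target=self.target_name,
                split=split,
                max_panel=self.max_panel,
                criterion=self.criterion,
            )
            # refit the chosen panel on the full training set; report on test
            forest = rf_config.make_forest().fit(X_tr[pm.panel], y_tr)
            r, p, _ = evaluate(forest.predict(X_te[pm.panel]), y_te)
            pm.training_msr = float(np.mean((forest.predict(X_tr[pm.panel]) - y_tr) ** 2))
            pm.test_r, pm.test_p, pm.all_lipid_test_r = r, p, all_r
            self.model_ = forest
        else:
            pm = grow_panel(
                ranking,
                X_tr,
                X_te,
                y_tr,
                y_te,
                tolerance=self.tolerance,
                rf_config=rf_config,
                all_lipid_test_r=all_r,
                target=self.target_name,
                split=split,
                max_panel=self.max_panel,
                criterion=self.criterion,
            )
            self.model_ = rf_config.make_forest().fit(X_tr[pm.panel], y_tr)

        self.panel_model_ = pm
        self.panel_ = list(pm.panel)
        self.ranking_ = list(ranking)
        self.all_lipid_test_r_ = all_r
        self.training_msr_ = pm.training_msr
        self.test_r_ = pm.test_r
        self.test_p_ = pm.test_p
        self.train_idx_, self.test_idx_ = train, test
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise AttributeError("PanelGrower is not fitted")
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X), columns=self.feature_names_in_)
        return self.model_.predict(X[self.panel_])
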