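"""Random-forest models with recursive feature elimination.

Three model recipes over the engineered features, all fitted on the
training split only:

* motif model: z-scored ratio matrix -> t-test filter -> PCA (30
  components) -> RF-RFE over the components -> random forest;
* protein model: RF-RFE over the ten markers (nine measured + PGR) ->
  random forest;
* combined model: the motif branch's 30 components joined with the ten
  markers, RF-RFE over the union -> random forest.

RF-RFE eliminates the lowest-importance feature one step at a time and
scores every candidate subset size by mean stratified 10-fold CV AUC; the
chosen size is the argmax, ties broken toward the smaller subset.  Folds
are shared across subset sizes (one fold seed per run) so scores are
comparable.  Selected-feature counts are outcomes of the data, never
forced; the counts the original study arrived at (16 components, 8
proteins, 20 components + 6 proteins) are carried as reference metadata
only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .evaluate import auc
from .features import DeterministicPCA, DifferentialTTestSelector, component_frame
from .motifs import MotifZScaler

#: selected-feature counts the original screening study reported, kept as
#: reference metadata for report annotation only — never enforced
PUBLISHED_FEATURE_COUNTS = {
    "motif": {"n_selected": 16},
    "protein": {"n_selected": 8},
    "combined": {"n_components": 20, "n_proteins": 6},
}

PROTEIN_FEATURES = (
    "AFP",
    "CA19-9",
    "CA24-2",
    "CA72-4",
    "CEA",
    "Cyfra21-1",
    "SCC",
    "PG I",
    "PG II",
    "PGR",
)


def _forest(n_trees: int, seed: int) -> RandomForestClassifier:
    # common forest practice: sqrt(p) variables per split, unlimited depth
    return RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        random_state=seed,
        n_jobs=1,
    )


def _cv_auc(X: pd.DataFrame, y: np.ndarray, folds, n_trees: int, seed: int) -> float:
    scores = []
    for train_idx, test_idx in folds:
        rf = _forest(n_trees, seed).fit(X.iloc[train_idx], y[train_idx])
        prob = rf.predict_proba(X.iloc[test_idx])[:, 1]
        scores.append(auc(prob, y[test_idx]))
    return float(np.mean(scores))


@dataclass
class RFEResult:
    """Outcome of one RF-RFE run."""

    ranking: list  # best feature first (survivors, then reverse elimination)
    cv_scores: dict  # subset size -> mean CV AUC
    chosen: list  # selected feature subset
    metric: str
    seed: int
    n_folds: int


def rfe_select(
    X: pd.DataFrame,
    y,
    n_folds: int = 10,
    step: int = 1,
    seed: int = 0,
    n_trees: int = 500,
) -> RFEResult:
    """Recursive feature elimination with random-forest importances.

    At each subset size the mean stratified CV AUC is recorded, then the
    ``step`` lowest-importance features (by a forest fitted on the full
    training rows) are dropped.  The chosen subset maximises the CV score;
    ties go to the smaller subset.
    """
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("labels are single-class")
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    # canonical column order makes the run invariant to the caller's
    # feature ordering (forest feature subsampling is index-based)
    X = X[sorted(map(str, X.columns))]
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    remaining = list(X.columns)
    eliminated: list = []  # first-eliminated first
    cv_scores: dict[int, float] = {}
    subsets: dict[int, list] = {}
    while remaining:
        size = len(remaining)
        cv_scores[size] = _cv_auc(X[remaining], y, folds, n_trees, seed)
        subsets[size] = list(remaining)
        if size == 1:
            break
        rf = _forest(n_trees, seed).fit(X[remaining], y)
        order = np.argsort(rf.feature_importances_, kind="stable")
        n_drop = min(step, size - 1)
        dropped = [remaining[i] for i in order[:n_drop].tolist()]
        eliminated.extend(dropped)  # increasing-importance order
        remaining = [f for f in remaining if f not in set(dropped)]
    best_size = None
    best_score = -np.inf
    for size in sorted(cv_scores):  # ascending: ties keep the smaller size
        if cv_scores[size] > best_score:
            best_score = cv_scores[size]
            best_size = size
    ranking = list(remaining) + list(reversed(eliminated))
    return RFEResult(
        ranking=ranking,
        cv_scores=cv_scores,
        chosen=subsets[best_size],
        metric="mean_cv_auc",
        seed=seed,
        n_folds=n_folds,
    )


@dataclass
class ForestFit:
    model: RandomForestClassifier
    cv_scores: dict  # hyper point -> mean CV AUC
    best_params: dict
    fold_scores: list
    seed: int


def fit_random_forest(
    X: pd.DataFrame,
    y,
    hyper_grid: list[dict] | None = None,
    n_folds: int = 10,
    seed: int = 0,
    n_trees: int = 500,
) -> ForestFit:
    """Grid-searched random forest scored by mean stratified CV AUC.

    The default grid is the single configured forest; the best grid point
    is refit on all rows.  Deterministic under ``seed``.
    """
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("labels are single-class")
    grid = hyper_grid or [{"n_estimators": n_trees}]
    if not grid:
        raise ValueError("empty hyperparameter grid")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    cv_scores = {}
    best_params, best_score = None, -np.inf
    best_fold_scores: list = []
    for params in grid:
        base = _forest(params.get("n_estimators", n_trees), seed)
        base.set_params(**{k: v for k, v in params.items() if k != "n_estimators"})
        fold_scores = []
        for train_idx, test_idx in folds:
            rf = clone(base).fit(X.iloc[train_idx], y[train_idx])
            prob = rf.predict_proba(X.iloc[test_idx])[:, 1]
            fold_scores.append(auc(prob, y[test_idx]))
        mean_score = float(np.mean(fold_scores))
        cv_scores[tuple(sorted(params.items()))] = mean_score
        if mean_score > best_score:
            best_score, best_params = mean_score, params
            best_fold_scores = fold_scores
    final = _forest(best_params.get("n_estimators", n_trees), seed)
    final.set_params(**{k: v for k, v in best_params.items() if k != "n_estimators"})
    final.fit(X, y)
    return ForestFit(
        model=final,
        cv_scores=cv_scores,
        best_params=best_params,
        fold_scores=best_fold_scores,
        seed=seed,
    )


class _RecipeBase(BaseEstimator, ClassifierMixin):
    """Shared fit/predict machinery for the three screening recipes."""

    recipe: str = ""

    def __init__(
        self,
        alpha: float = 0.05,
        n_components: int = 30,
        n_folds: int = 10,
        n_trees: int = 500,
        rfe_step: int = 1,
        hyper_grid: list | None = None,
        seed: int = 0,
    ):
        self.alpha = alpha
        self.n_components = n_components
        self.n_folds = n_folds
        self.n_trees = n_trees
        self.rfe_step = rfe_step
        self.hyper_grid = hyper_grid
        self.seed = seed

    # engineered feature table from raw inputs (frozen state applied)
    def _engineer(self, X: pd.DataFrame, fit: bool, y=None) -> pd.DataFrame:
        raise NotImplementedError

    def fit(self, X: pd.DataFrame, y):
        y = np.asarray(y).astype(int)
        features = self._engineer(X, fit=True, y=y)
        self.rfe_ = rfe_select(
            features,
            y,
            n_folds=self.n_folds,
            step=self.rfe_step,
            seed=self.seed,
            n_trees=self.n_trees,
        )
        self.selected_features_ = list(self.rfe_.chosen)
        self.forest_fit_ = fit_random_forest(
            features[self.selected_features_],
            y,
            hyper_grid=self.hyper_grid,
            n_folds=self.n_folds,
            seed=self.seed,
            n_trees=self.n_trees,
        )
        imp = self.forest_fit_.model.feature_importances_
        total = imp.sum()
        self.feature_importances_ = pd.Series(
            imp / total if total > 0 else imp, index=self.selected_features_
        ).sort_values(ascending=False)
        self.classes_ = np.array([0, 1])
        self.published_counts_ = PUBLISHED_FEATURE_COUNTS.get(self.recipe, {})
        return self

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "forest_fit_")
        features = self._engineer(X, fit=False)
        return self.forest_fit_.model.predict_proba(features[self.selected_features_])

    def predict_scores(self, X: pd.DataFrame) -> np.ndarray:
        """Per-sample case-class probability (fraction of trees voting
        case), in [0, 1]."""
        return self.predict_proba(X)[:, 1]

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return (self.predict_scores(X) >= 0.5).astype(int)


class _MotifBranchMixin:
    """Z-scale -> t-filter -> PCA feature branch shared by the motif and
    combined recipes.  All three stages are fitted on training rows only."""

    def _fit_motif_branch(self, ratios: pd.DataFrame, y: np.ndarray) -> pd.DataFrame:
        self.scaler_ = MotifZScaler().fit(ratios)
        z = self.scaler_.transform(ratios)
        self.selector_ = DifferentialTTestSelector(alpha=self.alpha).fit(z, y)
        selected = self.selector_.transform(z)
        if selected.shape[1] == 0:
            raise ValueError("no motifs passed the differential filter")
        n_comp = min(self.n_components, selected.shape[1], len(selected) - 1)
        self.pca_ = DeterministicPCA(n_components=n_comp).fit(selected)
        return component_frame(self.pca_.transform(selected), index=ratios.index)

    def _apply_motif_branch(self, ratios: pd.DataFrame) -> pd.DataFrame:
        z = self.scaler_.transform(ratios)
        selected = self.selector_.transform(z)
        return component_frame(self.pca_.transform(selected), index=ratios.index)


class MotifModel(_MotifBranchMixin, _RecipeBase):
    """cfDNA end-motif recipe: principal components of the differential
    motifs feed RF-RFE and a random forest.  ``X`` is the samples x 256
    ratio matrix."""

    recipe = "motif"

    def _engineer(self, X, fit, y=None):
        if fit:
            return self._fit_motif_branch(X, y)
        return self._apply_motif_branch(X)


class ProteinModel(_RecipeBase):
    """Protein recipe: RF-RFE over the ten markers (nine measured + the
    pepsinogen ratio PGR), then a random forest.  ``X`` is the protein
    table; markers enter untransformed (forests are monotone-invariant)."""

    recipe = "protein"

    def _engineer(self, X, fit, y=None):
        missing = [m for m in PROTEIN_FEATURES if m not in X.columns]
        if missing:
            raise ValueError(f"missing protein marker columns: {missing}")
        return X.loc[:, list(PROTEIN_FEATURES)]


class CombinedModel(_MotifBranchMixin, _RecipeBase):
    """Combined recipe: motif-branch components joined with the ten
    protein markers; RF-RFE runs over the union.  ``X`` must carry the 256
    motif ratio columns and the ten marker columns."""

    recipe = "combined"

    def _split_input(self, X):
        from .motifs import MOTIFS_4MER

        missing_m = [c for c in MOTIFS_4MER if c not in X.columns]
        missing_p = [m for m in PROTEIN_FEATURES if m not in X.columns]
        if missing_m or missing_p:
            raise ValueError(
                "combined recipe needs both omic layers: "
                f"{len(missing_m)} motif and {len(missing_p)} protein columns missing"
            )
        return X.loc[:, list(MOTIFS_4MER)], X.loc[:, list(PROTEIN_FEATURES)]

    def _engineer(self, X, fit, y=None):
        ratios, proteins = self._split_input(X)
        if fit:
            comps = self._fit_motif_branch(ratios, y)
        else:
            comps = self._apply_motif_branch(ratios)
        return pd.concat([comps, proteins], axis=1)


RECIPES = {"motif": MotifModel, "protein": ProteinModel, "combined": CombinedModel}


def build_recipe(
    recipe: str,
    X: pd.DataFrame,
    y,
    **params,
) -> _RecipeBase:
    """Fit one of the three model recipes on training data.

    ``X`` carries the layer(s) the recipe needs: the 256-column ratio
    matrix (motif), the protein table (protein), or their column union
    (combined).
    """
    if recipe not in RECIPES:
        raise ValueError(f"unknown recipe {recipe!r}; choose from {sorted(RECIPES)}")
    return RECIPES[recipe](**params).fit(X, y)


def predict_scores(model: _RecipeBase, X: pd.DataFrame) -> np.ndarray:
    """Risk scores in [0, 1] from a fitted recipe (frozen upstream state)."""
    return model.predict_scores(X)
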