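"""Differential feature selection and dimensionality reduction.

Fitted on the training split only:

* per-feature two-sample t-tests of cases (ESCC + precancerous) against
  controls, selecting features at raw p < alpha with up/down direction
  bookkeeping — no multiplicity correction by default, optional
  Benjamini-Hochberg;
* PCA of the selected motif features to a fixed number of components
  (default 30), with a deterministic sign convention so repeated fits give
  identical loadings.

Both steps are scikit-learn transformers and compose in a Pipeline; frozen
training state (selection mask, means, loadings) is applied unchanged to
validation/test rows.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted


def ttest_differential(
    X: pd.DataFrame,
    y,
    alpha: float = 0.05,
    equal_var: bool = True,
    fdr: bool = False,
) -> pd.DataFrame:
    """Per-feature two-sample t-test, cases (y=1) vs controls (y=0).

    Returns a frame indexed by feature with columns ``t``, ``p``,
    ``mean_diff`` (case - control), ``direction`` (up/down by the sign of
    the mean difference) and ``selected`` (p below ``alpha``; adjusted p if
    ``fdr``).  Features constant in both classes have undefined t; they are
    reported with t=0, p=1, flagged ``degenerate`` and never selected.
    """
    y = np.asarray(y).astype(int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if len(y) != len(X):
        raise ValueError("labels must cover all rows")
    cases = X.loc[y == 1]
    controls = X.loc[y == 0]
    if len(cases) < 2 or len(controls) < 2:
        raise ValueError("need >= 2 samples per class")
    import warnings

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # zero-variance features trigger a harmless precision warning; they
        # are handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(cases, controls, equal_var=equal_var, axis=0)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    mean_diff = cases.mean(axis=0).to_numpy() - controls.mean(axis=0).to_numpy()
    # nan arises only when both classes are constant with equal means:
    # the test is undefined there and the feature is never selected
    degenerate = np.isnan(t)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)
    p_crit = p.copy()
    if fdr:
        from statsmodels.stats.multitest import multipletests

        p_crit = multipletests(p, method="fdr_bh")[1]
    result = pd.DataFrame(
        {
            "t": t,
            "p": p,
            "mean_diff": mean_diff,
            "direction": np.where(mean_diff > 0, "up", "down"),
            "selected": (p_crit < alpha) & ~degenerate,
            "degenerate": degenerate,
        },
        index=X.columns,
    )
    result.attrs["alpha"] = alpha
    result.attrs["equal_var"] = equal_var
    result.attrs["fdr"] = fdr
    return result


class DifferentialTTestSelector(BaseEstimator, TransformerMixin):
    """Select features differential between cases and controls at p < alpha.

    Parameters
    ----------
    alpha : float, default 0.05
        Raw two-sided significance cut-off.
    equal_var : bool, default True
        Student's pooled-variance test; False gives Welch.
    fdr : bool, default False
        Apply Benjamini-Hochberg before thresholding.

    Attributes
    ----------
    result_ : DataFrame with t, p, direction per feature
    support_ : boolean mask of selected features
    selected_features_ : list of selected feature names
    n_up_, n_down_ : selected counts by direction
    """

    def __init__(self, alpha: float = 0.05, equal_var: bool = True, fdr: bool = False):
        self.alpha = alpha
        self.equal_var = equal_var
        self.fdr = fdr

    def fit(self, X: pd.DataFrame, y) -> "DifferentialTTestSelector":
        self.result_ = ttest_differential(
            X, y, alpha=self.alpha, equal_var=self.equal_var, fdr=self.fdr
        )
        self.support_ = self.result_["selected"].to_numpy()
        self.feature_names_in_ = np.asarray(X.columns)
        self.selected_features_ = list(self.result_.index[self.support_])
        sel = self.result_[self.result_["selected"]]
        self.n_up_ = int((sel["direction"] == "up").sum())
        self.n_down_ = int((sel["direction"] == "down").sum())
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "support_")
        if list(X.columns) != list(self.feature_names_in_):
            raise ValueError("feature axis mismatch with fitted selector")
        return X.loc[:, self.selected_features_]


class DeterministicPCA(PCA):
    """PCA with a fixed sign convention on every component.

    ``sklearn`` eigenvector signs are arbitrary up to numerical detail;
    here each loading vector is flipped so its largest-magnitude entry is
    positive, making repeated fits (and serialised models) identical.
    Uses the full SVD solver, so results carry no solver randomness.
    """

    def __init__(self, n_components=30):
        super().__init__(n_components=n_components, svd_solver="full")

    def fit(self, X, y=None):
        super().fit(np.asarray(X, dtype=float))
        flip = np.sign(
            self.components_[
                np.arange(self.components_.shape[0]),
                np.argmax(np.abs(self.components_), axis=1),
            ]
        )
        flip[flip == 0] = 1.0
        self.components_ = self.components_ * flip[:, None]
        return self

    def fit_transform(self, X, y=None):
        # fit then transform, so the sign convention is always applied
        self.fit(X, y)
        return self.transform(np.asarray(X, dtype=float))

    def transform(self, X):
        return super().transform(np.asarray(X, dtype=float))


def pca_fit(X: pd.DataFrame, n_components: int = 30) -> DeterministicPCA:
    """Fit sign-fixed PCA on the training rows of the selected motifs."""
    n_samples, n_features = np.asarray(X).shape
    if n_components > min(n_samples - 1, n_features):
        raise ValueError(
            f"n_components={n_components} exceeds min(n_train-1, n_selected)"
            f"={min(n_samples - 1, n_features)}"
        )
    if n_samples < 2:
        raise ValueError("need >= 2 training samples")
    return DeterministicPCA(n_components=n_components).fit(X)


def pca_transform(X, model: DeterministicPCA) -> np.ndarray:
    """Project rows onto the fitted components (training means subtracted)."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.components_.shape[1]:
        raise ValueError("feature axis mismatch with fitted PCA model")
    return model.transform(X)


def component_frame(scores: np.ndarray, index=None) -> pd.DataFrame:
    """Label component scores PC1..PCk for reporting."""
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return pd.DataFrame(scores, index=index, columns=cols)
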