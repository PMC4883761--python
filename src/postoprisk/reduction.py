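"""Dimensionality-reduction arms: univariate screen, LASSO, and PCA.

Three alternatives for taming the post-encoding feature space before model
fitting, always fitted on the training fold and applied to validation:

* ``univariate_screen`` keeps features whose single-covariate logistic Wald
  p-value falls below ``alpha`` (default 0.2, a deliberately permissive
  screen meant to discard only clearly uninformative predictors);
* ``lasso_select`` keeps the nonzero-coefficient support of an L1-penalized
  logistic regression with the penalty chosen by cross-validated deviance;
* ``pca_extract`` replaces the features with the top principal components
  (default 5) of the standardized (correlation-scale) feature matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegressionCV
from sklearn.preprocessing import StandardScaler


@dataclass
class ReductionResult:
    """Fitted reduction transform: selected columns or component loadings."""

    arm: str  # none | screen | lasso | pca
    selected: list[str] = field(default_factory=list)
    loadings: np.ndarray | None = None  # (n_features, n_components), orthonormal
    means: np.ndarray | None = None
    scales: np.ndarray | None = None
    feature_names: list[str] = field(default_factory=list)

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if self.arm == "pca":
            Z = (X[self.feature_names].to_numpy(dtype=float) - self.means) / self.scales
            scores = Z @ self.loadings
            cols = [f"pc{i + 1}" for i in range(scores.shape[1])]
            return pd.DataFrame(scores, columns=cols, index=X.index)
        if self.arm == "none":
            return X
        return X[self.selected]


def univariate_screen(
    X: pd.DataFrame, outcome: np.ndarray, alpha: float = 0.2
) -> ReductionResult:
    """Keep features with single-covariate logistic Wald p-value < alpha.

    Constant features are excluded with a warning (their p-value is
    undefined); a fit that fails to converge is likewise dropped.
    """
    y = np.asarray(outcome)
    selected: list[str] = []
    for col in X.columns:
        x = X[col].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            warnings.warn(f"feature {col!r} is constant; excluded from screen")
            continue
        design = sm.add_constant((x - x.mean()) / x.std())
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(y, design).fit(disp=0, maxiter=100)
            p = float(res.pvalues[1])
        except Exception:
            warnings.warn(f"univariate fit failed for {col!r}; excluded")
            continue
        if np.isfinite(p) and p < alpha:
            selected.append(col)
    return ReductionResult(arm="screen", selected=selected, feature_names=list(X.columns))


def lasso_select(
    X: pd.DataFrame,
    outcome: np.ndarray,
    Cs: int | np.ndarray = 20,
    cv: int = 5,
    seed: int = 0,
) -> ReductionResult:
    """L1-penalized logistic selection with CV-chosen penalty.

    Features are standardized internally; ``selected`` is the set of columns
    with nonzero coefficients at the cross-validated optimum.
    """
    y = np.asarray(outcome)
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate outcome")
    scaler = StandardScaler().fit(X.to_numpy(dtype=float))
    Z = scaler.transform(X.to_numpy(dtype=float))
    model = LogisticRegressionCV(
        Cs=Cs,
        cv=cv,
        penalty="l1",
        solver="liblinear",
        scoring="neg_log_loss",
        random_state=seed,
        max_iter=2000,
    ).fit(Z, y)
    mask = np.abs(model.coef_.ravel()) > 1e-10
    selected = [c for c, m in zip(X.columns, mask) if m]
    return ReductionResult(arm="lasso", selected=selected, feature_names=list(X.columns))


def lasso_path_support(
    X: pd.DataFrame, outcome: np.ndarray, Cs: np.ndarray
) -> list[list[str]]:
    """Support along an explicit penalty path (small C = strong penalty)."""
    from sklearn.linear_model import LogisticRegression

    y = np.asarray(outcome)
    Z = StandardScaler().fit_transform(X.to_numpy(dtype=float))
    supports = []
    for C in Cs:
        lr = LogisticRegression(
            penalty="l1", C=float(C), solver="liblinear", max_iter=2000
        ).fit(Z, y)
        mask = np.abs(lr.coef_.ravel()) > 1e-10
        supports.append([c for c, m in zip(X.columns, mask) if m])
    return supports


def pca_extract(
    X: pd.DataFrame, n_components: int = 5
) -> tuple[ReductionResult, pd.DataFrame]:
    """Top principal components of the standardized feature matrix.

    Standardization makes this the correlation-matrix PCA, appropriate for
    mixed-unit clinical features. Loadings are orthonormal and the returned
    scores are empirically uncorrelated.
    """
    if n_components > X.shape[1]:
        raise ValueError("n_components exceeds feature count")
    A = X.to_numpy(dtype=float)
    means = A.mean(axis=0)
    scales = A.std(axis=0)
    scales[scales == 0] = 1.0
    Z = (A - means) / scales
    pca = PCA(n_components=n_components, svd_solver="full").fit(Z)
    result = ReductionResult(
        arm="pca",
        loadings=pca.components_.T,
        means=means,
        scales=scales,
        feature_names=list(X.columns),
    )
    return result, result.transform(X)


def rare_binary_composite(
    X: pd.DataFrame,
    binary_cols: list[str],
    threshold: float = 0.02,
    composite_name: str = "comorbidity_index",
) -> tuple[pd.DataFrame, list[str]]:
    """Replace low-prevalence binary indicators by a composite count.

    Comorbidities rarer than ``threshold`` contribute to a single summed
    index instead of entering individually (the Charlson-style composite
    used when sparse indicators would be unstable).
    """
    rare = [c for c in binary_cols if X[c].mean() < threshold]
    if not rare:
        return X, []
    out = X.drop(columns=rare).copy()
    out[composite_name] = X[rare].sum(axis=1)
    return out, rare
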