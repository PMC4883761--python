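"""The four risk models: logistic regression, spline GAM, naive Bayes, SVM.

All models consume a numeric feature matrix (continuous labs, binary
indicators, log-ratio-encoded categoricals) and a binary outcome, and expose
``predict_risk``: probabilities for the probabilistic models, decision
scores for the (uncalibrated) SVM.

The GAM is the centrepiece: logit P(E=1|x) = alpha + sum_i f_i(x_i), with
cubic B-spline smooths for designated continuous features and linear terms
for the rest. Per-term smoothing penalties are chosen by minimizing AICc
over a penalty grid; after fitting, smooth terms whose effective degrees of
freedom fall below a threshold (default 1.5, i.e. "close to linear") are
demoted to plain linear terms and the model is refit — so the final model
partitions predictors into a linear set and a genuinely nonlinear set.

Models serialize to plain dictionaries (JSON-ready) carrying everything
needed for exact re-scoring: coefficients, spline knots and weights, NB
frequency tables, SVM support vectors and kernel parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.spatial.distance import pdist
from scipy.special import expit
from sklearn.svm import SVC
from statsmodels.gam.api import GLMGam, BSplines

# ---------------------------------------------------------------------------
# Logistic regression (IRLS maximum likelihood)
# ---------------------------------------------------------------------------


@dataclass
class LogisticModel:
    kind: str
    feature_names: list[str]
    params: np.ndarray  # intercept first
    probabilistic: bool = True

    def predict_risk(self, X: pd.DataFrame) -> np.ndarray:
        if list(X.columns) != self.feature_names and not set(self.feature_names) <= set(
            X.columns
        ):
            raise ValueError("feature schema mismatch")
        A = X[self.feature_names].to_numpy(dtype=float)
        eta = self.params[0] + A @ self.params[1:]
        return expit(eta)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "feature_names": self.feature_names,
            "params": np.asarray(self.params).tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LogisticModel":
        return cls(
            kind=d["kind"],
            feature_names=list(d["feature_names"]),
            params=np.asarray(d["params"], dtype=float),
        )


def fit_logistic(X: pd.DataFrame, y: np.ndarray) -> LogisticModel:
    """Maximum-likelihood logistic regression via IRLS.

    Perfect separation falls back to a lightly ridge-penalized fit with a
    warning rather than failing.
    """
    y = np.asarray(y)
    design = sm.add_constant(X.to_numpy(dtype=float), has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, design, family=sm.families.Binomial()).fit()
        params = np.asarray(res.params)
        if not np.all(np.isfinite(params)) or np.abs(params).max() > 1e6:
            raise ValueError("diverged")
    except Exception:
        warnings.warn("logistic fit unstable (separation?); using ridge fallback")
        from sklearn.linear_model import LogisticRegression

        lr = LogisticRegression(C=1e4, max_iter=5000).fit(X.to_numpy(dtype=float), y)
        params = np.concatenate([lr.intercept_, lr.coef_.ravel()])
    return LogisticModel(kind="logistic", feature_names=list(X.columns), params=params)


def logistic_standard_errors(X: pd.DataFrame, y: np.ndarray) -> np.ndarray:
    """Wald standard errors (intercept first) for the IRLS logistic fit."""
    design = sm.add_constant(X.to_numpy(dtype=float), has_constant="add")
    res = sm.GLM(np.asarray(y), design, family=sm.families.Binomial()).fit()
    return np.asarray(res.bse)


# ---------------------------------------------------------------------------
# Generalized additive model
# ---------------------------------------------------------------------------


@dataclass
class GamFitDiagnostics:
    edf: dict[str, float]  # per smoothed-candidate feature
    linearized: list[str]  # candidates demoted to linear terms
    alphas: dict[str, float]  # selected penalty weight per retained smooth


@dataclass
class GamModel:
    kind: str
    linear_features: list[str]
    smooth_features: list[str]
    params: np.ndarray  # [const, linear coefs..., spline coefs...]
    knots: dict[str, np.ndarray]
    spline_df: int
    spline_degree: int
    probabilistic: bool = True
    _smoother: BSplines | None = field(default=None, repr=False, compare=False)

    @property
    def feature_names(self) -> list[str]:
        return self.linear_features + self.smooth_features

    def _clip(self, xs: np.ndarray) -> np.ndarray:
        # constant extrapolation beyond the training range: new points are
        # clamped just inside the outermost knots
        xs = xs.copy()
        for k, f in enumerate(self.smooth_features):
            kn = self.knots[f]
            lo, hi = kn.min(), kn.max()
            span = (hi - lo) or 1.0
            xs[:, k] = np.clip(xs[:, k], lo + 1e-9 * span, hi - 1e-9 * span)
        return xs

    def _basis(self, X: pd.DataFrame) -> np.ndarray | None:
        if not self.smooth_features:
            return None
        xs = self._clip(X[self.smooth_features].to_numpy(dtype=float))
        if self._smoother is None:
            self._smoother = BSplines(
                xs,
                df=[self.spline_df] * len(self.smooth_features),
                degree=[self.spline_degree] * len(self.smooth_features),
                knot_kwds=[{"all_knots": self.knots[f]} for f in self.smooth_features],
            )
        return self._smoother.transform(xs)

    def design(self, X: pd.DataFrame) -> np.ndarray:
        cols = [np.ones(len(X))]
        if self.linear_features:
            cols.append(X[self.linear_features].to_numpy(dtype=float))
        basis = self._basis(X)
        if basis is not None:
            cols.append(basis)
        return np.column_stack(cols)

    def predict_risk(self, X: pd.DataFrame) -> np.ndarray:
        missing = set(self.feature_names) - set(X.columns)
        if missing:
            raise ValueError(f"feature schema mismatch: missing {sorted(missing)}")
        return expit(self.design(X) @ self.params)

    def partial_effect(self, feature: str, grid: np.ndarray) -> np.ndarray:
        """Centred additive contribution f(feature) over a grid."""
        grid = np.asarray(grid, dtype=float)
        if feature in self.smooth_features:
            j = self.smooth_features.index(feature)
            xs = np.zeros((len(grid), len(self.smooth_features)))
            for k, f in enumerate(self.smooth_features):
                xs[:, k] = grid if k == j else np.median(self.knots[f])
            xs = self._clip(xs)
            sm_obj = BSplines(
                xs,
                df=[self.spline_df] * len(self.smooth_features),
                degree=[self.spline_degree] * len(self.smooth_features),
                knot_kwds=[{"all_knots": self.knots[f]} for f in self.smooth_features],
            )
            basis = sm_obj.transform(xs)
            dims = [s.dim_basis for s in sm_obj.smoothers]
            offset = 1 + len(self.linear_features)
            start = offset + sum(dims[:j])
            coefs = self.params[start : start + dims[j]]
            eff = basis[:, sum(dims[:j]) : sum(dims[: j + 1])] @ coefs
        elif feature in self.linear_features:
            beta = self.params[1 + self.linear_features.index(feature)]
            eff = beta * grid
        else:
            raise ValueError(f"feature {feature!r} not in model")
        return eff - eff.mean()

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "linear_features": self.linear_features,
            "smooth_features": self.smooth_features,
            "params": np.asarray(self.params).tolist(),
            "knots": {k: np.asarray(v).tolist() for k, v in self.knots.items()},
            "spline_df": self.spline_df,
            "spline_degree": self.spline_degree,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GamModel":
        return cls(
            kind=d["kind"],
            linear_features=list(d["linear_features"]),
            smooth_features=list(d["smooth_features"]),
            params=np.asarray(d["params"], dtype=float),
            knots={k: np.asarray(v, dtype=float) for k, v in d["knots"].items()},
            spline_df=d["spline_df"],
            spline_degree=d["spline_degree"],
        )


def _aicc(res, n: int) -> float:
    edf = float(res.edf.sum())
    return float(res.deviance) + 2 * edf + 2 * edf * (edf + 1) / max(n - edf - 1, 1.0)


def _gam_fit_once(y, exog, smoother, alphas):
    model = GLMGam(
        y, exog=exog, smoother=smoother, family=sm.families.Binomial(), alpha=list(alphas)
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return model.fit()


def _term_edf(res, k_exog: int, dim_basis: Sequence[int]) -> list[float]:
    edf = np.asarray(res.edf)
    out, k = [], k_exog
    for d in dim_basis:
        out.append(float(edf[k : k + d].sum()))
        k += d
    return out


def fit_gam(
    X: pd.DataFrame,
    y: np.ndarray,
    smooth_features: Sequence[str],
    edf_linear_threshold: float = 1.5,
    spline_df: int = 10,
    spline_degree: int = 3,
    alpha_grid: Sequence[float] | None = None,
    search: str = "refine",
) -> tuple[GamModel, GamFitDiagnostics]:
    """Penalized cubic-spline additive logistic model with term linearization.

    ``search`` controls the penalty-weight selection: ``"shared"`` minimizes
    AICc over a single weight common to all smooth terms; ``"refine"``
    additionally optimizes each term's weight coordinate-wise starting from
    the shared optimum. Smoothed candidates with fewer than 10 distinct
    values, or whose fitted effective degrees of freedom fall below
    ``edf_linear_threshold``, enter (or re-enter) the model as linear terms.
    """
    y = np.asarray(y)
    n = len(y)
    if alpha_grid is None:
        alpha_grid = [10.0**k for k in range(-2, 8)]

    smooth = []
    demoted: list[str] = []
    for f in smooth_features:
        if f not in X.columns:
            raise ValueError(f"smooth feature {f!r} not in design")
        if X[f].nunique() < 10:
            warnings.warn(f"{f!r} has <10 distinct values; demoted to linear term")
            demoted.append(f)
        else:
            smooth.append(f)
    linear = [c for c in X.columns if c not in smooth]

    diagnostics = GamFitDiagnostics(edf={}, linearized=list(demoted), alphas={})

    def build(smooth_cols: list[str], alphas: Sequence[float]):
        lin_cols = [c for c in X.columns if c not in smooth_cols]
        exog = np.column_stack([np.ones(n)] + (
            [X[lin_cols].to_numpy(dtype=float)] if lin_cols else []
        ))
        bs = BSplines(
            X[smooth_cols].to_numpy(dtype=float),
            df=[spline_df] * len(smooth_cols),
            degree=[spline_degree] * len(smooth_cols),
        )
        res = _gam_fit_once(y, exog, bs, alphas)
        return lin_cols, exog, bs, res

    if not smooth:
        lr = fit_logistic(X, y)
        model = GamModel(
            kind="gam",
            linear_features=list(X.columns),
            smooth_features=[],
            params=lr.params,
            knots={},
            spline_df=spline_df,
            spline_degree=spline_degree,
        )
        return model, diagnostics

    # penalty selection by AICc over the grid
    best_alpha, best_crit = None, np.inf
    for a in alpha_grid:
        _, _, _, res = build(smooth, [a] * len(smooth))
        crit = _aicc(res, n)
        if crit < best_crit:
            best_alpha, best_crit = a, crit
    alphas = [best_alpha] * len(smooth)
    if search == "refine":
        for t in range(len(smooth)):
            for a in alpha_grid:
                if a == alphas[t]:
                    continue
                trial = list(alphas)
                trial[t] = a
                _, _, _, res = build(smooth, trial)
                crit = _aicc(res, n)
                if crit < best_crit:
                    alphas, best_crit = trial, crit
    elif search != "shared":
        raise ValueError("search must be 'shared' or 'refine'")

    lin_cols, exog, bs, res = build(smooth, alphas)
    edfs = _term_edf(res, exog.shape[1], [s.dim_basis for s in bs.smoothers])
    for f, e in zip(smooth, edfs):
        diagnostics.edf[f] = e

    keep = [f for f, e in zip(smooth, edfs) if e >= edf_linear_threshold]
    drop = [f for f in smooth if f not in keep]
    if drop:
        diagnostics.linearized.extend(drop)
        if keep:
            alphas = [a for f, a in zip(smooth, alphas) if f in keep]
            lin_cols, exog, bs, res = build(keep, alphas)
        else:
            lr = fit_logistic(X, y)
            model = GamModel(
                kind="gam",
                linear_features=list(X.columns),
                smooth_features=[],
                params=lr.params,
                knots={},
                spline_df=spline_df,
                spline_degree=spline_degree,
            )
            return model, diagnostics
    smooth = keep if drop else smooth

    diagnostics.alphas = {f: float(a) for f, a in zip(smooth, alphas)}
    knots = {f: np.asarray(s.knots) for f, s in zip(smooth, bs.smoothers)}
    model = GamModel(
        kind="gam",
        linear_features=lin_cols,
        smooth_features=smooth,
        params=np.asarray(res.params),
        knots=knots,
        spline_df=spline_df,
        spline_degree=spline_degree,
        _smoother=None,
    )
    return model, diagnostics


# ---------------------------------------------------------------------------
# Naive Bayes with mixed feature types
# ---------------------------------------------------------------------------


@dataclass
class NaiveBayesModel:
    kind: str
    feature_names: list[str]
    priors: np.ndarray  # P(E=0), P(E=1)
    gaussian: dict[str, tuple[tuple[float, float], tuple[float, float]]]
    tables: dict[str, tuple[dict[float, float], dict[float, float], int]]
    class_counts: tuple[int, int] = (0, 0)
    probabilistic: bool = True

    def predict_risk(self, X: pd.DataFrame) -> np.ndarray:
        missing = set(self.feature_names) - set(X.columns)
        if missing:
            raise ValueError(f"feature schema mismatch: missing {sorted(missing)}")
        n = len(X)
        logp = np.tile(np.log(self.priors), (n, 1))
        for f in self.feature_names:
            x = X[f].to_numpy(dtype=float)
            if f in self.gaussian:
                for c in (0, 1):
                    mu, var = self.gaussian[f][c]
                    logp[:, c] += -0.5 * (np.log(2 * np.pi * var) + (x - mu) ** 2 / var)
            else:
                t0, t1, k = self.tables[f]
                n0, n1 = self.class_counts
                for c, tab, nc in ((0, t0, n0), (1, t1, n1)):
                    counts = np.array([tab.get(v, 0.0) for v in x])
                    logp[:, c] += np.log((counts + 1.0) / (nc + k))
        m = logp.max(axis=1, keepdims=True)
        p = np.exp(logp - m)
        return p[:, 1] / p.sum(axis=1)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "feature_names": self.feature_names,
            "priors": self.priors.tolist(),
            "gaussian": self.gaussian,
            "tables": {
                f: [
                    {str(k): v for k, v in t0.items()},
                    {str(k): v for k, v in t1.items()},
                    k_,
                ]
                for f, (t0, t1, k_) in self.tables.items()
            },
            "class_counts": list(self.class_counts),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NaiveBayesModel":
        tables = {
            f: (
                {float(k): v for k, v in t0.items()},
                {float(k): v for k, v in t1.items()},
                int(k_),
            )
            for f, (t0, t1, k_) in d["tables"].items()
        }
        gaussian = {
            f: (tuple(v[0]), tuple(v[1])) for f, v in d["gaussian"].items()
        }
        return cls(
            kind=d["kind"],
            feature_names=list(d["feature_names"]),
            priors=np.asarray(d["priors"], dtype=float),
            gaussian=gaussian,
            tables=tables,
            class_counts=tuple(d["class_counts"]),
        )


def fit_naive_bayes(
    X: pd.DataFrame,
    y: np.ndarray,
    categorical_features: Sequence[str] | None = None,
    max_table_cardinality: int = 20,
    var_floor: float = 1e-9,
) -> NaiveBayesModel:
    """Naive Bayes with Gaussian continuous and Laplace-smoothed discrete terms.

    Class priors come from outcome frequencies. Features listed in
    ``categorical_features`` (or, by default, features with at most
    ``max_table_cardinality`` distinct values) use per-class frequency tables
    with Laplace pseudo-count 1; all others use per-class Gaussians. The
    returned posterior is normalized over both classes.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate outcome")
    n1 = int(y.sum())
    n0 = len(y) - n1
    priors = np.array([n0, n1], dtype=float) / len(y)
    if categorical_features is None:
        categorical_features = [
            c for c in X.columns if X[c].nunique() <= max_table_cardinality
        ]
    gaussian: dict = {}
    tables: dict = {}
    for f in X.columns:
        x = X[f].to_numpy(dtype=float)
        if f in categorical_features:
            k = len(np.unique(x))
            t0 = pd.Series(x[y == 0]).value_counts().to_dict()
            t1 = pd.Series(x[y == 1]).value_counts().to_dict()
            tables[f] = (
                {float(k_): float(v) for k_, v in t0.items()},
                {float(k_): float(v) for k_, v in t1.items()},
                int(k),
            )
        else:
            entry = []
            for c in (0, 1):
                xc = x[y == c]
                mu, var = float(xc.mean()), float(xc.var())
                if var < var_floor:
                    warnings.warn(f"zero variance for {f!r} in class {c}; floored")
                    var = var_floor
                entry.append((mu, var))
            gaussian[f] = (entry[0], entry[1])
    return NaiveBayesModel(
        kind="naive_bayes",
        feature_names=list(X.columns),
        priors=priors,
        gaussian=gaussian,
        tables=tables,
        class_counts=(n0, n1),
    )


# ---------------------------------------------------------------------------
# Support vector machine
# ---------------------------------------------------------------------------


@dataclass
class SvmModel:
    kind: str
    feature_names: list[str]
    means: np.ndarray
    scales: np.ndarray
    svc: SVC
    probabilistic: bool = False

    def _standardize(self, X: pd.DataFrame) -> np.ndarray:
        missing = set(self.feature_names) - set(X.columns)
        if missing:
            raise ValueError(f"feature schema mismatch: missing {sorted(missing)}")
        A = X[self.feature_names].to_numpy(dtype=float)
        return (A - self.means) / self.scales

    def predict_risk(self, X: pd.DataFrame) -> np.ndarray:
        Z = self._standardize(X)
        if self.probabilistic:
            return self.svc.predict_proba(Z)[:, 1]
        return self.svc.decision_function(Z)

    def to_dict(self) -> dict:
        svc = self.svc
        return {
            "kind": self.kind,
            "feature_names": self.feature_names,
            "means": self.means.tolist(),
            "scales": self.scales.tolist(),
            "kernel": svc.kernel,
            "gamma": float(svc._gamma) if svc.kernel == "rbf" else None,
            "support_vectors": svc.support_vectors_.tolist(),
            "dual_coef": svc.dual_coef_.tolist(),
            "intercept": svc.intercept_.tolist(),
        }


def median_heuristic_gamma(Z: np.ndarray, max_rows: int = 1000, seed: int = 0) -> float:
    """RBF bandwidth from the median pairwise distance of a subsample."""
    rng = np.random.default_rng(seed)
    if len(Z) > max_rows:
        Z = Z[rng.choice(len(Z), max_rows, replace=False)]
    med = float(np.median(pdist(Z)))
    if med == 0:
        return 1.0
    return 1.0 / (2.0 * med**2)


def fit_svm(
    X: pd.DataFrame,
    y: np.ndarray,
    kernel: str = "rbf",
    C: float = 1.0,
    gamma: float | str = "median",
    class_weight: str | dict | None = "balanced",
    platt: bool = False,
    seed: int = 0,
) -> SvmModel:
    """Soft-margin SVM on internally standardized features.

    Default kernel is RBF with the median-heuristic bandwidth; classes are
    inverse-prevalence weighted so the rare (5%-prevalence) outcome is not
    ignored. Decision scores are the raw margin w.x - b; with ``platt=True``
    the model instead exposes Platt-calibrated probabilities.
    """
    y = np.asarray(y)
    A = X.to_numpy(dtype=float)
    means = A.mean(axis=0)
    scales = A.std(axis=0)
    scales[scales == 0] = 1.0
    Z = (A - means) / scales
    if kernel == "rbf" and gamma == "median":
        gamma = median_heuristic_gamma(Z, seed=seed)
    kwargs = {"probability": True} if platt else {}
    svc = SVC(
        kernel=kernel,
        C=C,
        gamma=gamma if kernel == "rbf" else "scale",
        class_weight=class_weight,
        random_state=seed,
        cache_size=500,
        **kwargs,
    )
    svc.fit(Z, y)
    return SvmModel(
        kind="svm",
        feature_names=list(X.columns),
        means=means,
        scales=scales,
        svc=svc,
        probabilistic=platt,
    )


# ---------------------------------------------------------------------------
# Common surface
# ---------------------------------------------------------------------------

RiskModel = LogisticModel | GamModel | NaiveBayesModel | SvmModel


def predict_risk(model: RiskModel, X: pd.DataFrame) -> np.ndarray:
    """Score a feature table: probabilities, or decision scores for SVM."""
    return model.predict_risk(X)
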