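"""Repeated stratified hold-out evaluation with bootstrap CIs and calibration.

The harness mirrors a standard internal-validation design: the cohort is
split 70/30 with per-class (stratified) allocation so outcome prevalence is
preserved in both partitions, every data-dependent preprocessing step
(cleaning statistics, categorical encodings, code aggregation, reduction
transforms) is fitted on the training fold and applied to validation, models
are fitted and scored, and the whole process is repeated (default 50 times).

Discrimination is summarized by the Mann-Whitney AUC, classification by
accuracy and positive predictive value at a probability threshold, and
calibration by the Hosmer-Lemeshow decile-of-risk statistic. Confidence
intervals are reported two ways — percentile bootstrap over validation
patients within a split, and the spread of the metric across repetitions —
because the two answer different questions (sampling noise of one
validation set vs. split-to-split variability).

``paper_mode=True`` instead fits all preprocessing on the whole cohort
before splitting; this reproduces the common (optimistic) practice of
encoding before cross-validation and is provided for comparison, labelled
as such.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2, rankdata, wilcoxon

from .cleaning import Cleaner
from .codes import aggregate_codes, apply_grouping, build_prefix_tree
from .encoding import apply_encoder, fit_encoder
from .models import (
    GamModel,
    fit_gam,
    fit_logistic,
    fit_naive_bayes,
    fit_svm,
)
from .reduction import lasso_select, pca_extract, univariate_screen
from .synthetic import Cohort

PAPER_SMOOTH_FEATURES = ("age", "egfr", "hematocrit", "hemoglobin")


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------


@dataclass
class SplitPlan:
    rep: int
    train_idx: np.ndarray
    val_idx: np.ndarray
    seed: int


def stratified_split(
    y: np.ndarray, train_fraction: float = 0.7, seed: int = 0, rep: int = 0
) -> SplitPlan:
    """Per-class random allocation at the training fraction.

    Guarantees disjoint exhaustive partitions whose class prevalences match
    the cohort's up to integer rounding.
    """
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    train_parts, val_parts = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if len(idx) < 2:
            raise ValueError(f"class {cls} has fewer than 2 members")
        idx = rng.permutation(idx)
        k = int(round(train_fraction * len(idx)))
        k = min(max(k, 1), len(idx) - 1)
        train_parts.append(idx[:k])
        val_parts.append(idx[k:])
    return SplitPlan(
        rep=rep,
        train_idx=np.sort(np.concatenate(train_parts)),
        val_idx=np.sort(np.concatenate(val_parts)),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC: P(random positive outranks random negative), ties half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes required to compute AUC")
    r = rankdata(scores)
    return float((r[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def auc_standard_error(a: float, n1: int, n0: int) -> float:
    """Hanley-McNeil standard error of an AUC estimate."""
    q1 = a / (2 - a)
    q2 = 2 * a**2 / (1 + a)
    var = (a * (1 - a) + (n1 - 1) * (q1 - a**2) + (n0 - 1) * (q2 - a**2)) / (n1 * n0)
    return float(np.sqrt(max(var, 0.0)))


def accuracy_ppv(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> tuple[float, float]:
    """Fraction correctly classified and positive predictive value.

    PPV is undefined (returned as NaN) when no patient is predicted positive.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pred = scores > threshold
    accuracy = float((pred == (labels == 1)).mean())
    if pred.sum() == 0:
        return accuracy, float("nan")
    ppv = float(labels[pred].mean())
    return accuracy, ppv


def bootstrap_ci(
    metric: Callable[[np.ndarray, np.ndarray], float],
    scores: np.ndarray,
    labels: np.ndarray,
    B: int = 2000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Percentile bootstrap over resampled validation patients.

    Returns (observed metric, lower, upper). Resamples on which the metric is
    undefined (e.g. a single-class draw) are skipped.
    """
    if B < 100:
        raise ValueError("B must be at least 100")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n = len(scores)
    rng = np.random.default_rng(seed)
    point = metric(scores, labels)
    vals = []
    for _ in range(B):
        idx = rng.integers(0, n, n)
        try:
            v = metric(scores[idx], labels[idx])
        except ValueError:
            continue
        if np.isfinite(v):
            vals.append(v)
    lo, hi = np.quantile(vals, [(1 - level) / 2, 1 - (1 - level) / 2])
    return float(point), float(lo), float(hi)


def hosmer_lemeshow(
    probabilities: np.ndarray, labels: np.ndarray, groups: int = 10
) -> tuple[float, float]:
    """Decile-of-risk calibration chi-square with groups-2 degrees of freedom.

    Patients are split into equal-size risk-ordered groups; within each,
    observed events O are compared with expected E = sum of predicted
    probabilities via sum (O-E)^2 / (n_g pbar (1-pbar)). Groups with
    degenerate expected counts are merged with their neighbour.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0,1]")
    order = np.argsort(p, kind="mergesort")
    chunks = [c for c in np.array_split(order, groups) if len(c)]
    # merge groups whose expected events (or non-events) are ~zero
    merged: list[np.ndarray] = []
    for c in chunks:
        if merged and (p[c].sum() < 1e-9 or (1 - p[c]).sum() < 1e-9):
            warnings.warn("Hosmer-Lemeshow group with zero expected count merged")
            merged[-1] = np.concatenate([merged[-1], c])
        else:
            merged.append(c)
    stat = 0.0
    for c in merged:
        n_g = len(c)
        O = float(y[c].sum())
        E = float(p[c].sum())
        pbar = E / n_g
        denom = n_g * pbar * (1 - pbar)
        if denom <= 0:
            continue
        stat += (O - E) ** 2 / denom
    df = max(len(merged) - 2, 1)
    return float(stat), float(chi2.sf(stat, df))


def compare_models(aucs_a: Sequence[float], aucs_b: Sequence[float]) -> float:
    """Two-sided Wilcoxon signed-rank p for paired per-repetition AUCs."""
    a = np.asarray(aucs_a, dtype=float)
    b = np.asarray(aucs_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("AUC sequences must be paired by repetition")
    d = a - b
    if np.allclose(d, 0):
        return 1.0
    return float(wilcoxon(a, b, alternative="two-sided").pvalue)


# ---------------------------------------------------------------------------
# Risk-function curves
# ---------------------------------------------------------------------------


def risk_function_curves(
    gam_model: GamModel,
    logistic_model,
    feature: str,
    grid: np.ndarray,
    edf: float | None = None,
    out_csv: str | Path | None = None,
    out_png: str | Path | None = None,
) -> pd.DataFrame:
    """Partial-effect curves of one smoothed feature under GAM vs logistic.

    Both curves are centred logit-scale contributions with the other
    features held at reference values; one row per grid point.
    """
    grid = np.asarray(grid, dtype=float)
    if feature not in gam_model.feature_names:
        raise ValueError(f"{feature!r} not in the GAM")
    if feature not in logistic_model.feature_names:
        raise ValueError(f"{feature!r} not in the logistic model")
    gam_eff = gam_model.partial_effect(feature, grid)
    beta = logistic_model.params[1 + logistic_model.feature_names.index(feature)]
    lr_eff = beta * grid
    lr_eff = lr_eff - lr_eff.mean()
    table = pd.DataFrame(
        {feature: grid, "gam_effect": gam_eff, "logistic_effect": lr_eff}
    )
    table.attrs["edf"] = edf
    if out_csv is not None:
        table.to_csv(out_csv, index=False, float_format="%.8g")
    if out_png is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        ax.plot(grid, gam_eff, label=f"GAM (edf={edf:.2f})" if edf else "GAM")
        ax.plot(grid, lr_eff, "--", label="logistic")
        ax.set_xlabel(feature)
        ax.set_ylabel("centred logit contribution")
        ax.legend()
        fig.tight_layout()
        fig.savefig(out_png, dpi=120)
        plt.close(fig)
    return table


# ---------------------------------------------------------------------------
# Full factorial experiment
# ---------------------------------------------------------------------------


@dataclass
class ExperimentConfig:
    models: tuple[str, ...] = ("logistic", "gam", "naive_bayes", "svm")
    arms: tuple[str, ...] = ("none",)
    outcomes: tuple[str, ...] = ("aki", "sepsis")
    repetitions: int = 50
    train_fraction: float = 0.7
    paper_mode: bool = False
    seed: int = 0
    bootstrap_B: int = 2000
    screen_alpha: float = 0.2
    n_components: int = 5
    min_count: int = 100
    n_clusters: int = 5
    smoothing: float = 0.5
    threshold: float = 0.5
    gam_search: str = "shared"
    svm_max_train: int | None = None
    smooth_features: tuple[str, ...] | None = None


@dataclass
class EvalReport:
    table: pd.DataFrame
    per_rep_auc: dict[tuple[str, str, str], np.ndarray]
    pairwise_p: pd.DataFrame

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False, float_format="%.6f")

    def to_json(self, path: str | Path) -> None:
        import json

        payload = {
            "table": self.table.to_dict(orient="records"),
            "per_rep_auc": {
                "|".join(k): v.tolist() for k, v in self.per_rep_auc.items()
            },
            "pairwise_p": self.pairwise_p.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=1, default=float))


def _encode_features(
    cohort: Cohort,
    y: np.ndarray,
    fit_idx: np.ndarray,
    cfg: ExperimentConfig,
    seed: int,
) -> pd.DataFrame:
    """Clean and numerically encode every feature, fitting on ``fit_idx`` rows."""
    fit_view = Cohort(
        cohort.X.iloc[fit_idx].reset_index(drop=True),
        cohort.outcomes.iloc[fit_idx].reset_index(drop=True),
        dict(cohort.meta),
    )
    cleaner = Cleaner().fit(fit_view)
    cleaned, _ = cleaner.transform(cohort)
    out: dict[str, np.ndarray] = {}
    for col in cleaned.columns_of_type("continuous", "binary"):
        out[col] = cleaned.X[col].to_numpy(dtype=float)
    y_fit = y[fit_idx]
    for col in cleaned.columns_of_type("nominal"):
        enc = fit_encoder(
            cleaned.X[col].iloc[fit_idx],
            y_fit,
            min_count=cfg.min_count,
            n_clusters=cfg.n_clusters,
            smoothing=cfg.smoothing,
            seed=seed,
        )
        out[col] = apply_encoder(enc, cleaned.X[col])
    for col in cleaned.columns_of_type("code"):
        tree = build_prefix_tree(cleaned.X[col].iloc[fit_idx])
        grouping = aggregate_codes(tree, min_count=cfg.min_count)
        labels_all = apply_grouping(grouping, cleaned.X[col])
        enc = fit_encoder(
            labels_all[fit_idx], y_fit, min_count=1, smoothing=cfg.smoothing, seed=seed
        )
        out[col] = apply_encoder(enc, labels_all)
    return pd.DataFrame(out, index=cohort.X.index)


def _fit_one(
    name: str,
    X_tr: pd.DataFrame,
    y_tr: np.ndarray,
    cfg: ExperimentConfig,
    smooth: list[str],
    seed: int,
    categorical: list[str] | None = None,
):
    if name == "logistic":
        return fit_logistic(X_tr, y_tr)
    if name == "gam":
        model, _ = fit_gam(X_tr, y_tr, smooth_features=smooth, search=cfg.gam_search)
        return model
    if name == "naive_bayes":
        cats = [c for c in (categorical or []) if c in X_tr.columns]
        return fit_naive_bayes(X_tr, y_tr, categorical_features=cats or None)
    if name == "svm":
        if cfg.svm_max_train is not None and len(X_tr) > cfg.svm_max_train:
            rng = np.random.default_rng(seed)
            idx = np.sort(rng.choice(len(X_tr), cfg.svm_max_train, replace=False))
            X_tr, y_tr = X_tr.iloc[idx], y_tr[idx]
        return fit_svm(X_tr, y_tr, seed=seed)
    raise ValueError(f"unknown model {name!r}")


def run_experiment(
    cohort: Cohort, cfg: ExperimentConfig | None = None
) -> EvalReport:
    """Full factorial (model x reduction arm x outcome) repeated evaluation."""
    cfg = cfg or ExperimentConfig()
    ss = np.random.SeedSequence(cfg.seed)
    results: dict[tuple[str, str, str], dict] = {}
    per_rep: dict[tuple[str, str, str], list[float]] = {}

    for oi, outcome in enumerate(cfg.outcomes):
        if outcome not in cohort.outcomes.columns:
            raise ValueError(f"outcome {outcome!r} not present in cohort")
        y = cohort.outcomes[outcome].to_numpy()
        o_ss = np.random.SeedSequence((cfg.seed, oi))
        rep_seeds = o_ss.generate_state(3 * cfg.repetitions) % (2**31)
        X_paper = None
        if cfg.paper_mode:
            X_paper = _encode_features(
                cohort, y, np.arange(cohort.n), cfg, int(rep_seeds[0])
            )
        for rep in range(cfg.repetitions):
            s_split, s_prep, s_fit = (int(s) for s in rep_seeds[3 * rep : 3 * rep + 3])
            plan = stratified_split(y, cfg.train_fraction, seed=s_split, rep=rep)
            tr, va = plan.train_idx, plan.val_idx
            X_all = X_paper if cfg.paper_mode else _encode_features(
                cohort, y, tr, cfg, s_prep
            )
            X_tr, X_va = X_all.iloc[tr], X_all.iloc[va]
            y_tr, y_va = y[tr], y[va]

            smooth_candidates = (
                list(cfg.smooth_features)
                if cfg.smooth_features is not None
                else [
                    c
                    for c in cohort.columns_of_type("continuous")
                    if c in PAPER_SMOOTH_FEATURES
                ]
                or cohort.columns_of_type("continuous")
            )

            for arm in cfg.arms:
                if arm == "none":
                    Xa_tr, Xa_va = X_tr, X_va
                    smooth = [c for c in smooth_candidates if c in Xa_tr.columns]
                elif arm == "screen":
                    red = univariate_screen(X_tr, y_tr, alpha=cfg.screen_alpha)
                    Xa_tr, Xa_va = red.transform(X_tr), red.transform(X_va)
                    smooth = [c for c in smooth_candidates if c in Xa_tr.columns]
                elif arm == "lasso":
                    red = lasso_select(X_tr, y_tr, seed=s_fit)
                    Xa_tr, Xa_va = red.transform(X_tr), red.transform(X_va)
                    smooth = [c for c in smooth_candidates if c in Xa_tr.columns]
                elif arm == "pca":
                    red, Xa_tr = pca_extract(X_tr, n_components=cfg.n_components)
                    Xa_va = red.transform(X_va)
                    smooth = list(Xa_tr.columns)
                else:
                    raise ValueError(f"unknown reduction arm {arm!r}")

                # binary indicators and log-ratio-encoded categoricals use
                # frequency-table conditionals in naive Bayes; PCA scores are
                # continuous by construction
                categorical = (
                    []
                    if arm == "pca"
                    else cohort.columns_of_type("binary", "nominal", "code")
                )
                for mname in cfg.models:
                    key = (mname, arm, outcome)
                    model = _fit_one(
                        mname, Xa_tr, y_tr, cfg, smooth, s_fit, categorical
                    )
                    scores = model.predict_risk(Xa_va)
                    thr = cfg.threshold if model.probabilistic else 0.0
                    a = auc(scores, y_va)
                    acc, ppv = accuracy_ppv(scores, y_va, threshold=thr)
                    per_rep.setdefault(key, []).append(a)
                    slot = results.setdefault(
                        key, {"acc": [], "ppv": [], "first": None}
                    )
                    slot["acc"].append(acc)
                    slot["ppv"].append(ppv)
                    if rep == 0:
                        slot["first"] = (scores, y_va, model.probabilistic)

    rows = []
    for key in sorted(results):
        mname, arm, outcome = key
        aucs = np.array(per_rep[key])
        accs = np.array(results[key]["acc"], dtype=float)
        ppvs = np.array(results[key]["ppv"], dtype=float)
        scores, y_va, probabilistic = results[key]["first"]
        pt, blo, bhi = bootstrap_ci(
            auc, scores, y_va, B=cfg.bootstrap_B, seed=cfg.seed
        )
        if probabilistic:
            hl_stat, hl_p = hosmer_lemeshow(scores, y_va)
        else:
            hl_stat, hl_p = float("nan"), float("nan")
        row = {
            "model": mname,
            "arm": arm,
            "outcome": outcome,
            "auc_mean": aucs.mean(),
            "auc_rep_lo": np.quantile(aucs, 0.025) if len(aucs) > 1 else aucs[0],
            "auc_rep_hi": np.quantile(aucs, 0.975) if len(aucs) > 1 else aucs[0],
            "auc_boot": pt,
            "auc_boot_lo": blo,
            "auc_boot_hi": bhi,
            "accuracy_mean": float(np.nanmean(accs)),
            "ppv_mean": float(np.nanmean(ppvs)) if np.isfinite(ppvs).any() else float("nan"),
            "hl_stat": hl_stat,
            "hl_p": hl_p,
        }
        rows.append(row)
    table = pd.DataFrame(rows)

    pair_rows = []
    for outcome in cfg.outcomes:
        for arm in cfg.arms:
            names = [m for m in cfg.models]
            for i in range(len(names)):
                for j in range(i + 1, len(names)):
                    ka = (names[i], arm, outcome)
                    kb = (names[j], arm, outcome)
                    if ka in per_rep and kb in per_rep and len(per_rep[ka]) >= 2:
                        p = compare_models(per_rep[ka], per_rep[kb])
                    else:
                        p = float("nan")
                    pair_rows.append(
                        {
                            "outcome": outcome,
                            "arm": arm,
                            "model_a": names[i],
                            "model_b": names[j],
                            "p_value": p,
                        }
                    )
    pairwise = pd.DataFrame(pair_rows)
    return EvalReport(
        table=table,
        per_rep_auc={k: np.array(v) for k, v in per_rep.items()},
        pairwise_p=pairwise,
    )
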