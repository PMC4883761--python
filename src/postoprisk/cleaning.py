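"""Automatic data-cleaning rules: percentile outlier removal and imputation.

Continuous features: observations in the top and bottom 1% of the empirical
distribution are treated as outliers, removed, and then imputed together
with originally-missing entries using the feature mean computed on the
retained values. Nominal/code features: missing entries become a reserved
``__missing__`` level, which downstream encoders treat as an ordinary level.

The cleaner follows the fit/transform idiom: quantile cut-offs and
imputation means are estimated once (``fit``) and can then be applied to
any cohort with the same schema — in honest evaluation they are fitted on
the training fold only, while paper-mode fits them on the whole cohort
before splitting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import Cohort, MISSING_NOMINAL


@dataclass
class CleaningReport:
    """Per-feature audit of what the cleaner did."""

    outliers_flagged: dict[str, int] = field(default_factory=dict)
    values_imputed: dict[str, int] = field(default_factory=dict)
    imputation_constants: dict[str, float] = field(default_factory=dict)
    missing_category_created: dict[str, bool] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1, default=float))


def flag_outliers(
    values: np.ndarray, lower_q: float = 0.01, upper_q: float = 0.99
) -> np.ndarray:
    """Boolean mask of entries strictly outside the [lower_q, upper_q] quantiles.

    Quantiles are linear-interpolation empirical quantiles of the non-missing
    values; missing entries are never flagged. Requires at least 10
    non-missing values.
    """
    values = np.asarray(values, dtype=float)
    finite = values[~np.isnan(values)]
    if finite.size == 0:
        raise ValueError("all-missing column cannot be outlier-flagged")
    if finite.size < 10:
        raise ValueError("need at least 10 non-missing values to estimate quantiles")
    lo = np.quantile(finite, lower_q)
    hi = np.quantile(finite, upper_q)
    with np.errstate(invalid="ignore"):
        mask = (values < lo) | (values > hi)
    mask[np.isnan(values)] = False
    return mask


def impute_continuous(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Replace masked entries by the mean of unmasked, non-missing entries."""
    values = np.asarray(values, dtype=float).copy()
    mask = np.asarray(mask, dtype=bool) | np.isnan(values)
    retained = values[~mask]
    if retained.size == 0:
        raise ValueError("no retained values to impute from")
    values[mask] = retained.mean()
    return values


def impute_nominal(levels: pd.Series | np.ndarray) -> np.ndarray:
    """Map missing entries to the reserved ``__missing__`` level."""
    arr = pd.Series(levels, dtype=object)
    observed = set(arr.dropna().unique())
    if MISSING_NOMINAL in observed:
        raise ValueError(
            f"observed level collides with reserved marker {MISSING_NOMINAL!r}"
        )
    return arr.fillna(MISSING_NOMINAL).to_numpy(dtype=object)


@dataclass
class Cleaner:
    """Fitted cleaning statistics: quantile cut-offs and imputation means."""

    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    means: dict[str, float] = field(default_factory=dict)
    lower_q: float = 0.01
    upper_q: float = 0.99
    flag_outliers: bool = True

    def fit(self, cohort: Cohort) -> "Cleaner":
        for col in cohort.columns_of_type("continuous", "binary"):
            vals = cohort.X[col].to_numpy(dtype=float)
            if self.flag_outliers and cohort.meta[col] == "continuous":
                mask = flag_outliers(vals, self.lower_q, self.upper_q)
                self.bounds[col] = tuple(
                    np.quantile(vals[~np.isnan(vals)], [self.lower_q, self.upper_q])
                )
            else:
                mask = np.zeros(len(vals), dtype=bool)
            keep = ~(mask | np.isnan(vals))
            if not keep.any():
                raise ValueError(f"column {col!r} has no retainable values")
            self.means[col] = float(vals[keep].mean())
        return self

    def transform(self, cohort: Cohort) -> tuple[Cohort, CleaningReport]:
        out = cohort.copy()
        report = CleaningReport()
        for col in cohort.columns_of_type("continuous", "binary"):
            vals = out.X[col].to_numpy(dtype=float)
            n_missing = int(np.isnan(vals).sum())
            if col in self.bounds:
                lo, hi = self.bounds[col]
                with np.errstate(invalid="ignore"):
                    mask = (vals < lo) | (vals > hi)
                mask[np.isnan(vals)] = False
            else:
                mask = np.zeros(len(vals), dtype=bool)
            n_flagged = int(mask.sum())
            filled = np.asarray(vals, dtype=float).copy()
            filled[mask | np.isnan(vals)] = self.means[col]
            out.X[col] = filled
            report.outliers_flagged[col] = n_flagged
            report.values_imputed[col] = n_flagged + n_missing
            report.imputation_constants[col] = self.means[col]
        for col in cohort.columns_of_type("nominal", "code"):
            had_missing = bool(out.X[col].isna().any())
            if had_missing:
                out.X[col] = impute_nominal(out.X[col])
            report.missing_category_created[col] = had_missing
        return out, report


def clean_cohort(
    cohort: Cohort,
    lower_q: float = 0.01,
    upper_q: float = 0.99,
    flag: bool = True,
) -> tuple[Cohort, CleaningReport]:
    """Fit cleaning statistics on ``cohort`` and apply them to it.

    With ``flag=False`` no quantile re-flagging is performed (only
    imputation), which makes repeated cleaning exactly idempotent.
    """
    cleaner = Cleaner(lower_q=lower_q, upper_q=upper_q, flag_outliers=flag).fit(cohort)
    return cleaner.transform(cohort)
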