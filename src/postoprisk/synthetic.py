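"""Synthetic perioperative cohorts with known ground-truth risk.

The study population this package targets — adult inpatient surgical
admissions with preoperative labs, comorbidity indicators, high-cardinality
nominal features (attending surgeon, residence area) and hierarchical
4-digit procedure codes — is institutional and cannot be redistributed.
This module generates cohorts with the same statistical structure and a
fully known additive risk model on the logit scale, so that every
downstream stage (cleaning, encoding, code aggregation, model fitting,
evaluation) can be tested against ground truth.

Two binary outcomes are simulated independently given the covariates: an
AKI-like outcome with ~36% prevalence and a severe-sepsis-like outcome
with ~5% prevalence. Intercepts are calibrated by root finding so the
expected prevalence matches the target exactly (to 1e-4) before outcome
sampling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

MISSING_NOMINAL = "__missing__"

# ---------------------------------------------------------------------------
# Specification dataclasses
# ---------------------------------------------------------------------------


@dataclass
class ContinuousFeature:
    """One continuous covariate: sampling distribution and true effect.

    ``effect`` is ("linear", {"beta": b}) or ("quadratic", {"a": a, "b": b}),
    both evaluated on the standardized scale z = (x - loc) / scale, giving
    f(z) = b*z  or  f(z) = a*(z**2 - 1) + b*z  (the quadratic is centred so
    that E[f(Z)] = 0 for standard-normal Z).
    """

    name: str
    dist: str = "normal"  # normal | lognormal
    loc: float = 0.0
    scale: float = 1.0
    corr_with: tuple[str, float] | None = None  # (other feature, rho)


@dataclass
class NominalFeature:
    """High-cardinality nominal covariate with Zipf-like level frequencies.

    ``linked_to_code=True`` assigns each level (e.g. a surgeon) to one
    procedure top class and draws the level from the patient's own class
    pool — surgeons specialize, so surgeon identity co-varies with the
    procedure feature instead of being independent case-mix.
    """

    name: str
    n_levels: int = 100
    zipf_exponent: float = 1.2
    effect_sd: float = 0.3
    linked_to_code: bool = False


@dataclass
class CodeFeature:
    """Hierarchical 4-digit procedure-code feature.

    Codes live on a prefix tree: 2-digit top classes, 3-digit subclasses,
    4-digit leaves. Leaf frequencies are Zipf-like; true effects are drawn
    independently at every tree depth so that risk signal can exist at any
    granularity. ``age_tilt_sd > 0`` draws a per-class loading that tilts
    each patient's top-class probabilities by their (standardized) age, so
    procedure mix depends on demographics as it does in real cohorts.
    """

    name: str = "proc_code"
    n_top_classes: int = 18
    n_mid_per_top: int = 5
    n_leaf_per_mid: int = 6
    zipf_exponent: float = 1.3
    effect_sd: tuple[float, float, float] = (0.25, 0.15, 0.10)  # depth 2, 3, 4
    age_tilt_sd: float = 0.6
    tilt_feature: str = "age"


@dataclass
class CohortSpec:
    n_patients: int = 20_000
    prevalence_targets: dict[str, float] = field(
        default_factory=lambda: {"aki": 0.36, "sepsis": 0.05}
    )
    continuous_features: list[ContinuousFeature] = field(default_factory=list)
    binary_rates: dict[str, float] = field(default_factory=dict)
    # comorbidities co-vary with age/labs in real cohorts: optional latent-
    # normal coupling of a binary feature to a continuous driver
    binary_corr: dict[str, tuple[str, float]] = field(default_factory=dict)
    nominal_features: list[NominalFeature] = field(default_factory=list)
    code_feature: CodeFeature | None = None
    missingness_rate: float = 0.0
    outlier_rate: float = 0.0
    outlier_magnitude: float = 8.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        for name, p in self.prevalence_targets.items():
            if not 0.0 < p < 1.0:
                raise ValueError(f"prevalence target for {name!r} must be in (0,1)")
        for b, r in self.binary_rates.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"Bernoulli rate for {b!r} outside [0,1]")
        for nf in self.nominal_features:
            if nf.n_levels < 2:
                raise ValueError(f"nominal feature {nf.name!r} needs >= 2 levels")
        if not 0.0 <= self.missingness_rate < 1.0:
            raise ValueError("missingness_rate must be in [0,1)")
        if not 0.0 <= self.outlier_rate <= 1.0:
            raise ValueError("outlier_rate must be in [0,1]")

    @property
    def feature_names(self) -> list[str]:
        names = [c.name for c in self.continuous_features]
        names += list(self.binary_rates)
        names += [nf.name for nf in self.nominal_features]
        if self.code_feature is not None:
            names.append(self.code_feature.name)
        return names


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------


@dataclass
class OutcomeEffects:
    """Additive logit-scale effects for one outcome."""

    intercept: float = 0.0
    linear: dict[str, float] = field(default_factory=dict)
    nonlinear: dict[str, tuple[str, dict[str, float]]] = field(default_factory=dict)
    nominal: dict[str, dict[str, float]] = field(default_factory=dict)
    code_nodes: dict[str, float] = field(default_factory=dict)


@dataclass
class TrueModel:
    """The generative counterpart of the additive risk model.

    logit P(E=1 | X) = alpha + sum_i f_i(x_i), with f_i linear, quadratic,
    a per-level nominal effect, or a sum of prefix-node effects for the
    hierarchical code feature. Continuous effects are parameterised on the
    standardized scale recorded in ``standardizers``.
    """

    outcomes: dict[str, OutcomeEffects]
    standardizers: dict[str, tuple[float, float]] = field(default_factory=dict)

    def feature_effect(self, outcome: str, name: str, values: pd.Series) -> np.ndarray:
        eff = self.outcomes[outcome]
        if name in eff.nonlinear:
            kind, par = eff.nonlinear[name]
            loc, scale = self.standardizers[name]
            z = (values.to_numpy(dtype=float) - loc) / scale
            if kind == "linear":
                return par["beta"] * z
            if kind == "quadratic":
                return par["a"] * (z**2 - 1.0) + par.get("b", 0.0) * z
            raise ValueError(f"unknown nonlinear kind {kind!r}")
        if name in eff.linear:
            if name in self.standardizers:
                loc, scale = self.standardizers[name]
                z = (values.to_numpy(dtype=float) - loc) / scale
            else:
                z = values.to_numpy(dtype=float)
            return eff.linear[name] * z
        if name in eff.nominal:
            table = eff.nominal[name]
            return np.array([table.get(v, 0.0) for v in values], dtype=float)
        if eff.code_nodes and values.dtype == object:
            out = np.zeros(len(values))
            for i, code in enumerate(values):
                s = 0.0
                for d in (2, 3, 4):
                    s += eff.code_nodes.get(str(code)[:d], 0.0)
                out[i] = s
            return out
        return np.zeros(len(values))

    def linear_predictor(
        self, X: pd.DataFrame, outcome: str, include_intercept: bool = True
    ) -> np.ndarray:
        eff = self.outcomes[outcome]
        eta = np.full(len(X), eff.intercept if include_intercept else 0.0)
        code_cols = [
            c for c in X.columns if X[c].dtype == object and c not in eff.nominal
        ]
        for col in X.columns:
            if col in eff.nonlinear or col in eff.linear or col in eff.nominal:
                eta = eta + self.feature_effect(outcome, col, X[col])
            elif col in code_cols and eff.code_nodes:
                eta = eta + self.feature_effect(outcome, col, X[col])
        return eta

    def to_dict(self) -> dict:
        return {
            "outcomes": {k: asdict(v) for k, v in self.outcomes.items()},
            "standardizers": {k: list(v) for k, v in self.standardizers.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrueModel":
        outcomes = {
            k: OutcomeEffects(
                intercept=v["intercept"],
                linear=dict(v["linear"]),
                nonlinear={f: (kk, dict(pp)) for f, (kk, pp) in v["nonlinear"].items()},
                nominal={f: dict(t) for f, t in v["nominal"].items()},
                code_nodes=dict(v["code_nodes"]),
            )
            for k, v in d["outcomes"].items()
        }
        stand = {k: (float(a), float(b)) for k, (a, b) in d["standardizers"].items()}
        return cls(outcomes=outcomes, standardizers=stand)


# ---------------------------------------------------------------------------
# Cohort container
# ---------------------------------------------------------------------------


@dataclass
class Cohort:
    """Patient-by-feature table with typed columns and binary outcomes.

    ``meta`` maps each feature column to one of ``continuous``, ``binary``,
    ``nominal``, ``code``. Outcomes never contain missing values; nominal
    columns store level identifiers (strings), never encoded scores.
    """

    X: pd.DataFrame
    outcomes: pd.DataFrame
    meta: dict[str, str]

    def __post_init__(self) -> None:
        if self.outcomes.isna().any().any():
            raise ValueError("outcome columns must not contain missing values")
        unknown = set(self.meta.values()) - {"continuous", "binary", "nominal", "code"}
        if unknown:
            raise ValueError(f"unknown column types: {unknown}")

    @property
    def n(self) -> int:
        return len(self.X)

    def columns_of_type(self, *types: str) -> list[str]:
        return [c for c, t in self.meta.items() if t in types]

    def copy(self) -> "Cohort":
        return Cohort(self.X.copy(), self.outcomes.copy(), dict(self.meta))

    # -- plain-text persistence (CSV + JSON sidecar) ------------------------

    def to_dir(self, path: str | Path, true_model: TrueModel | None = None) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        table = pd.concat([self.X, self.outcomes], axis=1)
        table.to_csv(path / "cohort.csv", index=False, float_format="%.10g")
        sidecar = {
            "columns": self.meta,
            "outcomes": list(self.outcomes.columns),
            "true_model": true_model.to_dict() if true_model is not None else None,
        }
        (path / "cohort.json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_dir(cls, path: str | Path) -> tuple["Cohort", TrueModel | None]:
        path = Path(path)
        sidecar = json.loads((path / "cohort.json").read_text())
        meta = sidecar["columns"]
        dtypes = {c: (object if t in ("nominal", "code") else float) for c, t in meta.items()}
        table = pd.read_csv(path / "cohort.csv", dtype=dtypes, keep_default_na=True)
        out_cols = sidecar["outcomes"]
        cohort = cls(
            X=table[list(meta)],
            outcomes=table[out_cols].astype(int),
            meta=meta,
        )
        tm = sidecar.get("true_model")
        return cohort, (TrueModel.from_dict(tm) if tm else None)


# ---------------------------------------------------------------------------
# Default study conditions
# ---------------------------------------------------------------------------


def default_cohort_spec(n_patients: int = 20_000, seed: int = 0) -> CohortSpec:
    """Cohort emulating the target study population.

    Continuous labs/demographics with realistic locations and scales; the
    haematological pair (hematocrit, hemoglobin) strongly correlated;
    ten binary comorbidity/medication indicators; a surgeon-like nominal
    feature with 500 levels and an area-code feature with 70 levels, both
    Zipf-distributed; a hierarchical procedure-code feature with 18 top
    classes. Hematocrit, hemoglobin and eGFR carry U-shaped true effects.
    """
    continuous = [
        ContinuousFeature("age", "normal", 56.0, 16.0),
        ContinuousFeature("ref_creatinine", "lognormal", -0.16, 0.35),
        ContinuousFeature("egfr", "normal", 90.0, 25.0, corr_with=("ref_creatinine", -0.85)),
        ContinuousFeature("hematocrit", "normal", 34.3, 6.0),
        ContinuousFeature("hemoglobin", "normal", 11.7, 2.2, corr_with=("hematocrit", 0.9)),
    ]
    binary = {
        "diabetes": 0.17,
        "chf": 0.08,
        "mi": 0.065,
        "copd": 0.16,
        "pvd": 0.12,
        "cvd": 0.08,
        "liver_disease": 0.05,
        "cancer": 0.20,
        "med_diuretics": 0.12,
        "med_pressors": 0.057,
    }
    binary_corr = {
        "diabetes": ("age", 0.40),
        "chf": ("age", 0.50),
        "mi": ("age", 0.40),
        "copd": ("age", 0.30),
        "pvd": ("age", 0.40),
        "cvd": ("age", 0.40),
        "cancer": ("age", 0.30),
        "med_diuretics": ("age", 0.35),
    }
    nominal = [
        NominalFeature(
            "surgeon_id", n_levels=500, zipf_exponent=1.15, effect_sd=0.35,
            linked_to_code=True,
        ),
        NominalFeature("area_code", n_levels=70, zipf_exponent=1.1, effect_sd=0.20),
    ]
    return CohortSpec(
        n_patients=n_patients,
        continuous_features=continuous,
        binary_rates=binary,
        binary_corr=binary_corr,
        nominal_features=nominal,
        code_feature=CodeFeature(),
        seed=seed,
    )


def _default_effects(spec: CohortSpec, rng: np.random.Generator, outcome: str) -> OutcomeEffects:
    """Draw one outcome's true effects given the cohort spec.

    Known lab features get fixed clinically-motivated shapes (U-shaped
    hematocrit/hemoglobin/eGFR); everything else gets effects drawn from the
    stage RNG, so the full effect set is deterministic given the master seed.
    """
    eff = OutcomeEffects()
    # curvature kept modest relative to the linear trends: nonlinear models
    # should gain measurably but not dramatically over a linear logit
    shaped = {
        "age": ("linear", {"beta": 0.35}),
        "hematocrit": ("quadratic", {"a": 0.12, "b": -0.25}),
        "hemoglobin": ("quadratic", {"a": 0.05, "b": -0.15}),
        "egfr": ("quadratic", {"a": 0.05, "b": -0.35}),
    }
    for cf in spec.continuous_features:
        if cf.name in shaped:
            eff.nonlinear[cf.name] = shaped[cf.name]
        else:
            eff.nonlinear[cf.name] = ("linear", {"beta": float(rng.normal(0.3, 0.1))})
    for b in spec.binary_rates:
        eff.linear[b] = float(rng.normal(0.25, 0.2))
    for nf in spec.nominal_features:
        levels = [f"{nf.name}_L{i:03d}" for i in range(nf.n_levels)]
        eff.nominal[nf.name] = {
            lv: float(v) for lv, v in zip(levels, rng.normal(0.0, nf.effect_sd, nf.n_levels))
        }
    return eff


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _zipf_probs(k: int, s: float) -> np.ndarray:
    w = np.arange(1, k + 1, dtype=float) ** (-s)
    return w / w.sum()


def _build_code_universe(
    cf: CodeFeature, rng: np.random.Generator
) -> tuple[list[list[str]], np.ndarray, list[np.ndarray]]:
    """Random prefix-tree universe: per-class leaves, class probabilities,
    and within-class leaf probabilities (both Zipf-like, shuffled)."""
    tops = sorted(rng.choice(100, size=cf.n_top_classes, replace=False))
    class_leaves: list[list[str]] = []
    for t in tops:
        leaves = [
            f"{t:02d}{m:d}{l:d}"
            for m in range((cf.n_mid_per_top))
            for l in range(cf.n_leaf_per_mid)
        ]
        class_leaves.append(leaves)
    class_probs = _zipf_probs(cf.n_top_classes, 1.0)
    rng.shuffle(class_probs)
    leaf_probs = []
    for leaves in class_leaves:
        p = _zipf_probs(len(leaves), cf.zipf_exponent)
        rng.shuffle(p)
        leaf_probs.append(p)
    return class_leaves, class_probs, leaf_probs


def calibrate_intercept(
    eta_no_intercept: np.ndarray, prevalence_target: float
) -> float:
    """Intercept alpha with mean(sigmoid(eta + alpha)) == target, to 1e-4.

    The expected prevalence is strictly increasing in alpha, so a bracketed
    root find always succeeds for targets strictly inside (0, 1).
    """
    if not 0.0 < prevalence_target < 1.0:
        raise ValueError("prevalence target must be strictly inside (0, 1)")

    def gap(a: float) -> float:
        return float(expit(eta_no_intercept + a).mean() - prevalence_target)

    lo, hi = -40.0, 40.0
    return float(brentq(gap, lo, hi, xtol=1e-8))


def generate_cohort(
    spec: CohortSpec, true_model: TrueModel | None = None
) -> tuple[Cohort, TrueModel]:
    """Sample a complete cohort (no missingness/outliers) and its ground truth.

    Covariates are sampled first; each outcome's intercept is then calibrated
    so the expected prevalence hits the spec's target, and outcomes are drawn
    Bernoulli from the true risk. Identical (spec, seed) give bitwise-identical
    cohorts: every stage uses its own child of the master seed.
    """
    spec.validate()
    ss = np.random.SeedSequence(spec.seed)
    keys = ["continuous", "binary", "nominal", "code", "effects", "outcome"]
    rngs = {k: np.random.default_rng(child) for k, child in zip(keys, ss.spawn(len(keys)))}

    n = spec.n_patients
    cols: dict[str, np.ndarray] = {}
    meta: dict[str, str] = {}
    standardizers: dict[str, tuple[float, float]] = {}

    rng = rngs["continuous"]
    z_cache: dict[str, np.ndarray] = {}
    for cf in spec.continuous_features:
        if cf.corr_with is not None:
            other, rho = cf.corr_with
            if other not in z_cache:
                raise ValueError(f"{cf.name}: correlate {other!r} must be generated first")
            z = rho * z_cache[other] + np.sqrt(1 - rho**2) * rng.standard_normal(n)
        else:
            z = rng.standard_normal(n)
        z_cache[cf.name] = z
        if cf.dist == "normal":
            x = cf.loc + cf.scale * z
        elif cf.dist == "lognormal":
            x = np.exp(cf.loc + cf.scale * z)
        else:
            raise ValueError(f"unknown distribution {cf.dist!r}")
        cols[cf.name] = x
        meta[cf.name] = "continuous"
        standardizers[cf.name] = (cf.loc, cf.scale)

    rng = rngs["binary"]
    from scipy.stats import norm

    for bname, rate in spec.binary_rates.items():
        if bname in spec.binary_corr:
            driver, rho = spec.binary_corr[bname]
            if driver not in z_cache:
                raise ValueError(f"{bname}: driver {driver!r} is not a continuous feature")
            latent = rho * z_cache[driver] + np.sqrt(1 - rho**2) * rng.standard_normal(n)
            cols[bname] = (latent > norm.ppf(1 - rate)).astype(float)
        else:
            cols[bname] = (rng.random(n) < rate).astype(float)
        meta[bname] = "binary"

    # procedure codes come before nominals so linked features (surgeons)
    # can condition on the patient's procedure class
    code_leaves: list[str] = []
    patient_class: np.ndarray | None = None
    class_probs: np.ndarray | None = None
    if spec.code_feature is not None:
        cf = spec.code_feature
        rng = rngs["code"]
        class_leaves, class_probs, leaf_probs = _build_code_universe(cf, rng)
        code_leaves = [lf for leaves in class_leaves for lf in leaves]
        if cf.age_tilt_sd > 0 and cf.tilt_feature in z_cache:
            gamma = rng.normal(0.0, cf.age_tilt_sd, cf.n_top_classes)
            logits = np.log(class_probs)[None, :] + np.outer(
                z_cache[cf.tilt_feature], gamma
            )
            P = np.exp(logits - logits.max(axis=1, keepdims=True))
            P /= P.sum(axis=1, keepdims=True)
            u = rng.random(n)
            patient_class = (P.cumsum(axis=1) > u[:, None]).argmax(axis=1)
        else:
            patient_class = rng.choice(cf.n_top_classes, size=n, p=class_probs)
        codes = np.empty(n, dtype=object)
        for ci in range(cf.n_top_classes):
            m = patient_class == ci
            if m.any():
                codes[m] = rng.choice(
                    np.array(class_leaves[ci]), size=int(m.sum()), p=leaf_probs[ci]
                )
        cols[cf.name] = codes
        meta[cf.name] = "code"

    rng = rngs["nominal"]
    for nf in spec.nominal_features:
        levels = np.array([f"{nf.name}_L{i:03d}" for i in range(nf.n_levels)])
        if nf.linked_to_code and patient_class is not None:
            # partition levels into per-class pools sized by class share
            k = spec.code_feature.n_top_classes
            sizes = np.maximum(1, np.round(class_probs * nf.n_levels).astype(int))
            while sizes.sum() > nf.n_levels:
                sizes[np.argmax(sizes)] -= 1
            while sizes.sum() < nf.n_levels:
                sizes[np.argmin(sizes)] += 1
            pools, start = [], 0
            for ci in range(k):
                pools.append(levels[start : start + sizes[ci]])
                start += sizes[ci]
            vals = np.empty(n, dtype=object)
            for ci in range(k):
                m = patient_class == ci
                if m.any():
                    p = _zipf_probs(len(pools[ci]), nf.zipf_exponent)
                    vals[m] = rng.choice(pools[ci], size=int(m.sum()), p=p)
            cols[nf.name] = vals
        else:
            probs = _zipf_probs(nf.n_levels, nf.zipf_exponent)
            cols[nf.name] = rng.choice(levels, size=n, p=probs)
        meta[nf.name] = "nominal"

    X = pd.DataFrame(cols)

    if true_model is None:
        rng = rngs["effects"]
        outcomes_eff: dict[str, OutcomeEffects] = {}
        for oname in spec.prevalence_targets:
            eff = _default_effects(spec, rng, oname)
            if spec.code_feature is not None:
                sd2, sd3, sd4 = spec.code_feature.effect_sd
                nodes: dict[str, float] = {}
                for leaf in code_leaves:
                    for d, sd in ((2, sd2), (3, sd3), (4, sd4)):
                        pref = leaf[:d]
                        if pref not in nodes:
                            nodes[pref] = float(rng.normal(0.0, sd))
                eff.code_nodes = nodes
            outcomes_eff[oname] = eff
        true_model = TrueModel(outcomes=outcomes_eff, standardizers=standardizers)
    else:
        true_model.standardizers = dict(standardizers)

    rng = rngs["outcome"]
    out_cols = {}
    for oname, target in spec.prevalence_targets.items():
        eta0 = true_model.linear_predictor(X, oname, include_intercept=False)
        alpha = calibrate_intercept(eta0, target)
        true_model.outcomes[oname].intercept = alpha
        out_cols[oname] = rng.binomial(1, expit(eta0 + alpha))
    outcomes = pd.DataFrame(out_cols)

    return Cohort(X=X, outcomes=outcomes, meta=meta), true_model


def make_gaussian_cohort(
    n_patients: int,
    linear: dict[str, float] | None = None,
    quadratic: dict[str, tuple[float, float]] | None = None,
    binary: dict[str, tuple[float, float]] | None = None,
    prevalence: float = 0.36,
    outcome: str = "y",
    seed: int = 0,
) -> tuple[Cohort, TrueModel]:
    """Small fully-specified cohort: standard-normal features, known effects.

    ``linear`` maps feature name -> beta; ``quadratic`` maps name -> (a, b)
    for f(z) = a(z^2-1) + bz; ``binary`` maps name -> (rate, beta). Handy for
    parameter- and risk-function-recovery studies where the truth must be
    exactly known and the design well-specified.
    """
    linear = linear or {}
    quadratic = quadratic or {}
    binary = binary or {}
    spec = CohortSpec(
        n_patients=n_patients,
        prevalence_targets={outcome: prevalence},
        continuous_features=[
            ContinuousFeature(name, "normal", 0.0, 1.0)
            for name in list(linear) + list(quadratic)
        ],
        binary_rates={name: rate for name, (rate, _) in binary.items()},
        seed=seed,
    )
    eff = OutcomeEffects(
        nonlinear={
            **{name: ("linear", {"beta": b}) for name, b in linear.items()},
            **{name: ("quadratic", {"a": a, "b": b}) for name, (a, b) in quadratic.items()},
        },
        linear={name: b for name, (_, b) in binary.items()},
    )
    tm = TrueModel(outcomes={outcome: eff})
    return generate_cohort(spec, true_model=tm)


# ---------------------------------------------------------------------------
# Corruption: MCAR missingness and injected outliers
# ---------------------------------------------------------------------------


def inject_missingness(
    cohort: Cohort, rates: float | dict[str, float], seed: int
) -> Cohort:
    """Apply a missing-completely-at-random mask to feature columns.

    Outcome columns are never masked. ``rates`` may be a scalar (applied to
    every feature column) or a per-feature dict; rates must lie in [0, 1).
    """
    out = cohort.copy()
    rng = np.random.default_rng(seed)
    if np.isscalar(rates):
        rates = {c: float(rates) for c in out.X.columns}
    for col, rate in rates.items():
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"missingness rate for {col!r} must be in [0,1)")
        if rate == 0.0:
            continue
        mask = rng.random(out.n) < rate
        if out.meta[col] in ("nominal", "code"):
            vals = out.X[col].astype(object).to_numpy()
            vals[mask] = np.nan
            out.X[col] = vals
        else:
            vals = out.X[col].to_numpy(dtype=float).copy()
            vals[mask] = np.nan
            out.X[col] = vals
    return out


def inject_outliers(
    cohort: Cohort,
    rate: float | dict[str, float],
    magnitude: float,
    seed: int,
) -> tuple[Cohort, dict[str, np.ndarray]]:
    """Replace a fraction of continuous entries with far-out values.

    Replacements are pushed beyond ``magnitude`` scale units from the
    feature's location (random sign), so with a large magnitude they land
    outside the clean 1st-99th percentile band. Returns the corrupted cohort
    and, per feature, the injected row indices — the oracle for outlier-
    detection tests.
    """
    if magnitude <= 1.0:
        raise ValueError("outlier magnitude must exceed 1")
    out = cohort.copy()
    rng = np.random.default_rng(seed)
    cont = cohort.columns_of_type("continuous")
    if np.isscalar(rate):
        rate = {c: float(rate) for c in cont}
    record: dict[str, np.ndarray] = {}
    for col, r in rate.items():
        k = int(round(r * out.n))
        idx = rng.choice(out.n, size=k, replace=False)
        record[col] = np.sort(idx)
        if k == 0:
            continue
        vals = out.X[col].to_numpy(dtype=float).copy()
        finite = vals[np.isfinite(vals)]
        loc, scale = float(np.mean(finite)), float(np.std(finite))
        sign = rng.choice([-1.0, 1.0], size=k)
        excess = np.abs(rng.normal(0.0, 0.25, size=k))
        vals[idx] = loc + sign * scale * magnitude * (1.0 + excess)
        out.X[col] = vals
    return out, record


# ---------------------------------------------------------------------------
# Oracle ceiling
# ---------------------------------------------------------------------------


def theoretical_auc(true_model: TrueModel, cohort: Cohort, outcome: str) -> float:
    """AUC of the true risk score against the realized outcomes.

    This is the Bayes-optimal discrimination attainable on this cohort; no
    fitted model should beat it beyond sampling noise.
    """
    from .evaluation import auc  # local import avoids a cycle at module load

    y = cohort.outcomes[outcome].to_numpy()
    if y.min() == y.max():
        raise ValueError("degenerate outcome: only one class present")
    eta = true_model.linear_predictor(cohort.X, outcome)
    return auc(eta, y)
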