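"""Standardisation, univariable screening and the three logistic models.

The modelling stage mirrors a published neonatal encephalopathy analysis:
positively skewed HRV features are log10-transformed, all HRV features are
z-scored, candidate predictors are screened univariably (eligible at
p < 0.25, correlated pairs pruned keeping the higher univariable AUROC) and
three multivariable logistic models are fitted on complete cases: an
HRV-only model, a clinical-only model and their combination. The printed
coefficient equations of the original report are also available as
transcribed models for scoring new subjects without refitting.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .exceptions import (
    DegenerateOutcomeError,
    MissingTermError,
    SeparationWarning,
    TransformError,
)
from .metrics import ModelEvaluation, auroc, evaluate_scores

__all__ = [
    "LOG10_FEATURES",
    "StandardizationRecipe",
    "LogisticModel",
    "ScreeningResult",
    "StudyConfig",
    "StudyResult",
    "standardize",
    "fit_logistic",
    "univariable_screen",
    "published_model",
    "predict_prob",
    "run_study",
]

# HRV features treated as positively skewed (log10 before z-scoring);
# the remaining features (mean NN and the MSE summaries, which may be
# negative) are z-scored on their original scale.
LOG10_FEATURES = (
    "sdnn_ms",
    "vlf_power_ms2",
    "lf_power_ms2",
    "hf_power_ms2",
    "lf_hf_ratio",
    "tinn_ms",
)


@dataclass
class StandardizationRecipe:
    """Per-feature transform (identity or log10) plus z-scoring constants."""

    transforms: dict[str, str]  # feature -> "identity" | "log10"
    means: dict[str, float]
    sds: dict[str, float]

    @classmethod
    def fit(
        cls,
        table: pd.DataFrame,
        features: list[str],
        log10_features: tuple[str, ...] = LOG10_FEATURES,
    ) -> "StandardizationRecipe":
        transforms, means, sds = {}, {}, {}
        for f in features:
            col = table[f].astype(float)
            tag = "log10" if f in log10_features else "identity"
            if tag == "log10":
                if (col.dropna() <= 0).any():
                    raise TransformError(
                        f"feature {f!r} has non-positive values; cannot log10-transform"
                    )
                col = np.log10(col)
            mu = float(col.mean())
            sd = float(col.std(ddof=1))
            if not sd > 0:
                raise TransformError(f"feature {f!r} has zero variance on the fitting cohort")
            transforms[f], means[f], sds[f] = tag, mu, sd
        return cls(transforms, means, sds)

    def apply(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        for f, tag in self.transforms.items():
            col = out[f].astype(float)
            if tag == "log10":
                if (col.dropna() <= 0).any():
                    raise TransformError(
                        f"feature {f!r} has non-positive values; cannot log10-transform"
                    )
                col = np.log10(col)
            out[f] = (col - self.means[f]) / self.sds[f]
        return out

    def to_dict(self) -> dict:
        return {"transforms": self.transforms, "means": self.means, "sds": self.sds}

    @classmethod
    def from_dict(cls, d: dict) -> "StandardizationRecipe":
        return cls(dict(d["transforms"]), dict(d["means"]), dict(d["sds"]))


def standardize(
    table: pd.DataFrame,
    features: list[str],
    recipe: StandardizationRecipe | None = None,
    log10_features: tuple[str, ...] = LOG10_FEATURES,
) -> tuple[pd.DataFrame, StandardizationRecipe]:
    """Transform and z-score ``features``; fit a recipe unless one is given."""
    if recipe is None:
        recipe = StandardizationRecipe.fit(table, features, log10_features)
    return recipe.apply(table), recipe


@dataclass
class LogisticModel:
    """A logistic model for moderate-severe outcome (coded 1).

    ``provenance`` is ``"fitted"`` for maximum-likelihood fits on data and
    ``"transcribed-from-paper"`` for models entered from printed equations,
    whose coefficients carry two-decimal rounding into every derived
    quantity. Transcribed models expect standardized HRV inputs (the recipe
    must be fitted on the user's cohort) and raw clinical values: binary
    flags 0/1, gestational age in weeks, Apgar at 5 min as an integer score.
    """

    terms: list[str]
    intercept: float
    coefficients: dict[str, float]
    provenance: str = "fitted"
    recipe: StandardizationRecipe | None = None
    se: dict[str, float] = field(default_factory=dict)
    pvalues: dict[str, float] = field(default_factory=dict)
    printed_or: dict[str, float] = field(default_factory=dict)
    n_used: int | None = None
    n_dropped: int | None = None

    def __post_init__(self) -> None:
        if set(self.terms) != set(self.coefficients):
            raise ValueError("term list and coefficient keys disagree")

    def linear_predictor(self, row: Mapping[str, float] | pd.DataFrame) -> np.ndarray | float:
        if isinstance(row, pd.DataFrame):
            for t in self.terms:
                if t not in row.columns:
                    raise MissingTermError(f"model term {t!r} missing from input")
            eta = self.intercept + sum(
                self.coefficients[t] * row[t].to_numpy(dtype=float) for t in self.terms
            )
            return np.asarray(eta, dtype=float)
        for t in self.terms:
            if t not in row or row[t] is None or (
                isinstance(row[t], float) and math.isnan(row[t])
            ):
                raise MissingTermError(f"model term {t!r} missing from input")
        return float(self.intercept + sum(self.coefficients[t] * float(row[t]) for t in self.terms))

    def or_table(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2)
        rows = []
        for t in self.terms:
            b = self.coefficients[t]
            se = self.se.get(t, math.nan)
            rows.append(
                {
                    "term": t,
                    "coef": b,
                    "or": _safe_exp(b),
                    "or_ci_low": _safe_exp(b - z * se) if np.isfinite(se) else math.nan,
                    "or_ci_high": _safe_exp(b + z * se) if np.isfinite(se) else math.nan,
                    "p": self.pvalues.get(t, math.nan),
                }
            )
        return pd.DataFrame(rows).set_index("term")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "terms": self.terms,
            "intercept": self.intercept,
            "coefficients": self.coefficients,
            "provenance": self.provenance,
            "recipe": self.recipe.to_dict() if self.recipe else None,
            "se": self.se,
            "pvalues": self.pvalues,
            "printed_or": self.printed_or,
            "n_used": self.n_used,
            "n_dropped": self.n_dropped,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "LogisticModel":
        text = str(source)
        if isinstance(source, Path) or (len(text) < 4096 and "\n" not in text and Path(text).exists()):
            text = Path(source).read_text()
        d = json.loads(text)
        return cls(
            terms=list(d["terms"]),
            intercept=float(d["intercept"]),
            coefficients={k: float(v) for k, v in d["coefficients"].items()},
            provenance=d.get("provenance", "fitted"),
            recipe=StandardizationRecipe.from_dict(d["recipe"]) if d.get("recipe") else None,
            se={k: float(v) for k, v in d.get("se", {}).items()},
            pvalues={k: float(v) for k, v in d.get("pvalues", {}).items()},
            printed_or={k: float(v) for k, v in d.get("printed_or", {}).items()},
            n_used=d.get("n_used"),
            n_dropped=d.get("n_dropped"),
        )


def predict_prob(model: LogisticModel, row: Mapping[str, float] | pd.DataFrame):
    """Inverse-logit of the model's linear predictor; scalar or array."""
    from scipy.special import expit

    eta = model.linear_predictor(row)
    if isinstance(eta, np.ndarray):
        return expit(eta)
    return float(expit(eta))


def fit_logistic(
    design: pd.DataFrame,
    outcome: np.ndarray | pd.Series,
    maxiter: int = 100,
    tol: float = 1e-8,
    recipe: StandardizationRecipe | None = None,
) -> LogisticModel:
    """Maximum-likelihood logistic fit (Newton-Raphson via statsmodels).

    Rows with any missing term or outcome are dropped (complete-case) and
    counted in ``n_dropped``. Quasi-complete separation triggers a
    :class:`SeparationWarning`; the fit then falls back to IRLS, whose
    drifting estimates are returned as-is.
    """
    y = pd.Series(np.asarray(outcome, dtype=float), index=design.index)
    data = design.astype(float).copy()
    data["_y"] = y
    complete = data.dropna()
    n_dropped = len(data) - len(complete)
    yv = complete["_y"].to_numpy()
    X = complete.drop(columns="_y")
    if np.unique(yv).size < 2:
        raise DegenerateOutcomeError("outcome is constant on complete cases")
    Xc = sm.add_constant(X, has_constant="add")
    separation = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = sm.Logit(yv, Xc).fit(method="newton", maxiter=maxiter, tol=tol, disp=0)
        except Exception as exc:
            separation = "eparation" in str(exc) or isinstance(exc, np.linalg.LinAlgError)
            res = sm.Logit(yv, Xc).fit(method="bfgs", maxiter=2 * maxiter, disp=0)
    separation |= any("eparation" in str(w.message) for w in caught)
    params = pd.Series(np.asarray(res.params), index=Xc.columns)
    with np.errstate(all="ignore"):
        bse = pd.Series(np.asarray(res.bse), index=Xc.columns)
    coef_max = float(np.max(np.abs(params.drop("const").to_numpy()), initial=0.0))
    bse_arr = bse.to_numpy()
    bse_max = float(np.max(bse_arr[np.isfinite(bse_arr)], initial=0.0))
    if separation or coef_max > 20 or bse_max > 100 or not np.all(np.isfinite(bse_arr)):
        warnings.warn(
            "quasi-complete separation suspected; coefficients may be unstable",
            SeparationWarning,
            stacklevel=2,
        )
    pvals = pd.Series(res.pvalues, index=Xc.columns)
    terms = [c for c in Xc.columns if c != "const"]
    return LogisticModel(
        terms=terms,
        intercept=float(params["const"]),
        coefficients={t: float(params[t]) for t in terms},
        provenance="fitted",
        recipe=recipe,
        se={t: float(bse[t]) for t in terms},
        pvalues={t: float(pvals[t]) for t in terms},
        n_used=len(complete),
        n_dropped=n_dropped,
    )


def _safe_exp(x: float) -> float:
    """exp() that saturates to inf/0 instead of overflowing."""
    if not np.isfinite(x):
        return math.nan if math.isnan(x) else (math.inf if x > 0 else 0.0)
    return math.exp(x) if x < 709 else math.inf


@dataclass
class ScreeningResult:
    """Univariable screen: one row per candidate variable."""

    table: pd.DataFrame  # or, ci, p, auroc, eligible, kept, pruned_by
    p_threshold: float
    corr_threshold: float

    @property
    def kept(self) -> list[str]:
        return list(self.table.index[self.table["kept"]])


def univariable_screen(
    data: pd.DataFrame,
    outcome: str,
    candidates: list[str],
    p_threshold: float = 0.25,
    corr_threshold: float = 0.8,
) -> ScreeningResult:
    """Single-predictor logistic fits with eligibility and correlation pruning.

    Each candidate is fitted on its own complete cases. Variables with
    Wald p below ``p_threshold`` are eligible; among eligible pairs with
    |Pearson r| above ``corr_threshold`` only the variable with the higher
    univariable AUROC is kept (greedy, in decreasing AUROC order).
    """
    rows = {}
    for var in candidates:
        sub = data[[var, outcome]].dropna()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", SeparationWarning)
                m = fit_logistic(sub[[var]], sub[outcome])
            b = m.coefficients[var]
            se = m.se[var]
            p = m.pvalues[var]
            probs = predict_prob(m, sub[[var]])
            auc, _ = auroc(np.asarray(probs), sub[outcome].to_numpy())
        except DegenerateOutcomeError:
            b, se, p, auc = math.nan, math.nan, 1.0, 0.5
        z = 1.959963984540054
        rows[var] = {
            "n": len(sub),
            "coef": b,
            "or": _safe_exp(b),
            "or_ci_low": _safe_exp(b - z * se) if np.isfinite(se) else math.nan,
            "or_ci_high": _safe_exp(b + z * se) if np.isfinite(se) else math.nan,
            "p": p,
            "auroc": auc,
            "eligible": bool(p < p_threshold),
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "variable"
    table["kept"] = False
    table["pruned_by"] = ""

    eligible = table.index[table["eligible"]].tolist()
    order = sorted(eligible, key=lambda v: table.loc[v, "auroc"], reverse=True)
    kept: list[str] = []
    for var in order:
        clash = None
        for other in kept:
            pair = data[[var, other]].dropna()
            if len(pair) >= 3:
                r = pair[var].corr(pair[other])
                if np.isfinite(r) and abs(r) > corr_threshold:
                    clash = other
                    break
        if clash is None:
            kept.append(var)
            table.loc[var, "kept"] = True
        else:
            table.loc[var, "pruned_by"] = clash
    return ScreeningResult(table=table, p_threshold=p_threshold, corr_threshold=corr_threshold)


# ---------------------------------------------------------------------------
# Transcribed (published) models. Coefficients are stored exactly as printed
# (two decimals); derived odds ratios inherit that rounding. HRV terms expect
# standardized inputs (log10 first where tagged in the recipe below).
# ---------------------------------------------------------------------------

_PUBLISHED_TRANSFORMS = {
    "mean_nn_ms": "identity",
    "hf_power_ms2": "log10",
    "lf_hf_ratio": "log10",
    "tinn_ms": "log10",
    "mse_complexity_index": "identity",
    "mse_short_slope": "identity",
}

_PUBLISHED = {
    "hrv": {
        "intercept": 0.49,
        "coefficients": {
            "mean_nn_ms": 1.00,
            "hf_power_ms2": 0.37,
            "lf_hf_ratio": 0.40,
            "tinn_ms": -0.50,
            "mse_complexity_index": -0.51,
            "mse_short_slope": -1.16,
        },
        "printed_or": {
            "mean_nn_ms": 2.73,
            "hf_power_ms2": 1.45,
            "lf_hf_ratio": 1.48,
            "tinn_ms": 0.61,
            "mse_complexity_index": 0.60,
            "mse_short_slope": 0.31,
        },
    },
    "clinical": {
        "intercept": 9.71,
        "coefficients": {
            "foetal_distress": -1.26,
            "ga_weeks": -0.25,
            "emergency_delivery": -0.32,
            "apgar5": -0.07,
            "ventilation_10min": 2.70,
        },
        "printed_or": {
            "foetal_distress": 0.28,
            "ga_weeks": 0.78,
            "emergency_delivery": 0.73,
            "apgar5": 0.93,
            "ventilation_10min": 14.92,
        },
    },
    "combined": {
        "intercept": 11.49,
        "coefficients": {
            "mean_nn_ms": 0.85,
            "hf_power_ms2": 0.66,
            "lf_hf_ratio": 0.42,
            "tinn_ms": -0.35,
            "mse_complexity_index": -0.18,
            "mse_short_slope": -1.04,
            "foetal_distress": -1.20,
            "ga_weeks": -0.28,
            "emergency_delivery": -0.46,
            "apgar5": -0.06,
            "ventilation_10min": 2.19,
        },
        "printed_or": {
            "mean_nn_ms": 2.34,
            "hf_power_ms2": 1.94,
            "lf_hf_ratio": 1.51,
            "tinn_ms": 0.70,
            "mse_complexity_index": 0.84,
            "mse_short_slope": 0.35,
            "foetal_distress": 0.30,
            "ga_weeks": 0.76,
            "emergency_delivery": 0.63,
            "apgar5": 0.94,
            "ventilation_10min": 8.94,
        },
    },
}


def published_model(name: str) -> LogisticModel:
    """Return one of the transcribed multivariable models.

    ``name`` is ``"hrv"``, ``"clinical"`` or ``"combined"``. HRV terms take
    standardized values (z-scores of the feature, after a log10 transform
    for HF power, LF/HF ratio and TINN); clinical terms take raw encodings:
    yes/no flags as 1/0, gestational age in weeks, Apgar-5 as the integer
    score.
    """
    if name not in _PUBLISHED:
        raise KeyError(f"unknown published model {name!r}; choose from {sorted(_PUBLISHED)}")
    spec = _PUBLISHED[name]
    return LogisticModel(
        terms=list(spec["coefficients"]),
        intercept=spec["intercept"],
        coefficients=dict(spec["coefficients"]),
        provenance="transcribed-from-paper",
        printed_or=dict(spec["printed_or"]),
    )


# ---------------------------------------------------------------------------
# Full study pipeline
# ---------------------------------------------------------------------------

HRV_CANDIDATES = [
    "mean_nn_ms",
    "sdnn_ms",
    "tinn_ms",
    "vlf_power_ms2",
    "lf_power_ms2",
    "hf_power_ms2",
    "lf_hf_ratio",
    "mse_complexity_index",
    "mse_max",
    "mse_short_slope",
    "mse_long_slope",
]

CLINICAL_CANDIDATES = [
    "intrapartum_complications",
    "foetal_distress",
    "ga_weeks",
    "emergency_delivery",
    "male",
    "bw_per_100g",
    "apgar1",
    "apgar5",
    "ventilation_10min",
]

BLOOD_GAS_CANDIDATES = ["ph_per_001", "lactate", "base_deficit"]


@dataclass
class StudyConfig:
    """Knobs of the screening/modelling pipeline."""

    outcome: str = "moderate_severe"
    p_threshold: float = 0.25
    corr_threshold: float = 0.8
    log10_features: tuple[str, ...] = LOG10_FEATURES
    hrv_candidates: list[str] = field(default_factory=lambda: list(HRV_CANDIDATES))
    clinical_candidates: list[str] = field(default_factory=lambda: list(CLINICAL_CANDIDATES))
    subgroup: str | None = None  # None | "cooled" | "no_asm"
    include_blood_gas: bool | None = None  # default: only in subgroup analyses
    hl_groups: int = 10
    ci_method: str = "delong"


@dataclass
class StudyResult:
    """Screen, fitted models and evaluations for one cohort run."""

    screening: ScreeningResult
    models: dict[str, LogisticModel]
    evaluations: dict[str, ModelEvaluation]
    recipe: StandardizationRecipe
    n_total: int
    n_complete: int
    config: StudyConfig

    def report(self) -> str:
        lines = [
            f"subjects: {self.n_total} total, {self.n_complete} complete-case",
            f"screen: kept {', '.join(self.screening.kept) or '(none)'}",
        ]
        for name, ev in self.evaluations.items():
            lines.append(
                f"{name:9s} AUROC {ev.auroc:.3f} "
                f"(95% CI {ev.auroc_ci[0]:.3f}-{ev.auroc_ci[1]:.3f}), "
                f"cutoff {ev.optimal_cutoff:.2f}, sens {ev.sensitivity:.1%}, "
                f"spec {ev.specificity:.1%}, PPV {ev.ppv:.1%}, NPV {ev.npv:.1%}, "
                f"HL p {ev.hl_p:.3f}"
            )
        return "\n".join(lines)


def _encode_clinical(clinical: pd.DataFrame) -> pd.DataFrame:
    """Add the per-unit encodings used for screening and model fits."""
    out = clinical.copy()
    if "bw_g" in out.columns:
        out["bw_per_100g"] = out["bw_g"] / 100.0  # OR per 100 g
    if "ph" in out.columns:
        out["ph_per_001"] = out["ph"] * 100.0  # OR per 0.01 pH unit
    return out


def run_study(
    features: pd.DataFrame,
    clinical: pd.DataFrame,
    config: StudyConfig | None = None,
) -> StudyResult:
    """Run the full screening + multivariable modelling pipeline.

    ``features`` holds one row of HRV features per subject, ``clinical``
    the covariates and the binary outcome column; both are joined on their
    index. Multivariable fits use the complete-case subset for the union of
    screened terms, and the three models (HRV / clinical / combined) are
    fitted and evaluated on that same subset.
    """
    config = config or StudyConfig()
    data = features.join(clinical, how="inner")
    if config.subgroup == "cooled":
        data = data[data["cooled"] == 1]
    elif config.subgroup == "no_asm":
        data = data[data["any_asm"] == 0]
    elif config.subgroup is not None:
        raise ValueError(f"unknown subgroup {config.subgroup!r}")
    include_gas = (
        config.include_blood_gas
        if config.include_blood_gas is not None
        else config.subgroup is not None
    )
    data = _encode_clinical(data)

    hrv_feats = [f for f in config.hrv_candidates if f in data.columns]
    data, recipe = standardize(data, hrv_feats, log10_features=config.log10_features)

    clin_cands = [c for c in config.clinical_candidates if c in data.columns]
    if include_gas:
        clin_cands += [c for c in BLOOD_GAS_CANDIDATES if c in data.columns]

    screen = univariable_screen(
        data,
        config.outcome,
        hrv_feats + clin_cands,
        p_threshold=config.p_threshold,
        corr_threshold=config.corr_threshold,
    )
    kept_hrv = [v for v in screen.kept if v in hrv_feats]
    kept_clin = [v for v in screen.kept if v in clin_cands]

    model_terms = {
        "hrv": kept_hrv,
        "clinical": kept_clin,
        "combined": kept_hrv + kept_clin,
    }
    all_terms = model_terms["combined"]
    complete = data.dropna(subset=all_terms + [config.outcome]) if all_terms else data
    models: dict[str, LogisticModel] = {}
    evals: dict[str, ModelEvaluation] = {}
    for name, terms in model_terms.items():
        if terms:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", SeparationWarning)
                m = fit_logistic(complete[terms], complete[config.outcome], recipe=recipe)
            probs = np.asarray(predict_prob(m, complete[terms]))
        else:  # nothing survived the screen: intercept-only null model
            prev = float(complete[config.outcome].mean())
            m = LogisticModel(
                terms=[],
                intercept=math.log(prev / (1 - prev)) if 0 < prev < 1 else 0.0,
                coefficients={},
                provenance="fitted",
                recipe=recipe,
                n_used=len(complete),
                n_dropped=0,
            )
            probs = np.full(len(complete), prev)
        models[name] = m
        evals[name] = evaluate_scores(
            probs,
            complete[config.outcome].to_numpy(),
            hl_groups=config.hl_groups,
            ci_method=config.ci_method,
        )
    return StudyResult(
        screening=screen,
        models=models,
        evaluations=evals,
        recipe=recipe,
        n_total=len(data),
        n_complete=len(complete),
        config=config,
    )
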