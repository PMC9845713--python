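"""Discrimination and calibration metrics for binary risk models.

AUROC is the Mann-Whitney statistic (ties counted 1/2) with a DeLong
covariance-based confidence interval by default; the Hanley-McNeil variance
is available as an alternative. The operating point is chosen by Youden's
index over observed score values, and calibration is assessed with the
Hosmer-Lemeshow deciles-of-risk test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import CalibrationWarning, ConfigurationError, DegenerateOutcomeError

__all__ = ["ModelEvaluation", "auroc", "youden_cutoff", "hosmer_lemeshow", "evaluate_scores"]


@dataclass
class ModelEvaluation:
    """AUROC with CI, Youden operating point and Hosmer-Lemeshow fit."""

    auroc: float
    auroc_ci: tuple[float, float]
    optimal_cutoff: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    hl_statistic: float
    hl_df: int
    hl_p: float
    n: int

    def as_dict(self) -> dict[str, float]:
        d = {
            "auroc": self.auroc,
            "auroc_ci_low": self.auroc_ci[0],
            "auroc_ci_high": self.auroc_ci[1],
            "optimal_cutoff": self.optimal_cutoff,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "hl_statistic": self.hl_statistic,
            "hl_df": self.hl_df,
            "hl_p": self.hl_p,
            "n": self.n,
        }
        return d


def _check_binary(labels: np.ndarray) -> np.ndarray:
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2 or not set(classes).issubset({0, 1}):
        raise DegenerateOutcomeError("labels must contain both classes coded 0/1")
    return y.astype(int)


def auroc(
    scores: np.ndarray,
    labels: np.ndarray,
    ci_method: str = "delong",
    alpha: float = 0.05,
) -> tuple[float, tuple[float, float]]:
    """AUROC and a normal-approximation confidence interval.

    The point estimate is U/(n1*n0) from midranks, exact on small inputs.
    ``ci_method`` is ``"delong"`` (placement-value variance) or
    ``"hanley-mcneil"``.
    """
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    ranks = stats.rankdata(s)
    n1 = int(y.sum())
    n0 = y.size - n1
    auc = (ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)

    if ci_method == "delong":
        # placement values: v10_i = P(neg < pos_i) + 0.5 P(neg == pos_i)
        r_pos = stats.rankdata(s[y == 1])
        r_neg = stats.rankdata(s[y == 0])
        v10 = (ranks[y == 1] - r_pos) / n0
        v01 = 1.0 - (ranks[y == 0] - r_neg) / n1
        var = (np.var(v10, ddof=1) / n1 if n1 > 1 else np.nan) + (
            np.var(v01, ddof=1) / n0 if n0 > 1 else np.nan
        )
    elif ci_method == "hanley-mcneil":
        q1 = auc / (2 - auc)
        q2 = 2 * auc**2 / (1 + auc)
        var = (
            auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n0 - 1) * (q2 - auc**2)
        ) / (n1 * n0)
    else:
        raise ConfigurationError(f"unknown ci_method {ci_method!r}")
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * math.sqrt(var) if np.isfinite(var) else math.nan
    ci = (max(0.0, auc - half), min(1.0, auc + half))
    return float(auc), ci


def youden_cutoff(scores: np.ndarray, labels: np.ndarray) -> dict[str, float]:
    """Operating point maximising sensitivity + specificity - 1.

    A subject is predicted positive when its score is >= the cutoff; the
    cutoff is searched over observed score values and ties on the Youden
    index are broken toward higher specificity (the larger cutoff).
    """
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    n1 = int(y.sum())
    n0 = y.size - n1
    cutoffs = np.unique(s)[::-1]  # descending: increasing sensitivity
    tp = np.array([(y[s >= c] == 1).sum() for c in cutoffs])
    fp = np.array([(y[s >= c] == 0).sum() for c in cutoffs])
    sens = tp / n1
    spec = 1 - fp / n0
    j = sens + spec - 1
    best = np.flatnonzero(j == j.max())
    pick = best[np.argmax(spec[best])]
    c = float(cutoffs[pick])
    tp_, fp_ = int(tp[pick]), int(fp[pick])
    fn_, tn_ = n1 - tp_, n0 - fp_
    return {
        "optimal_cutoff": c,
        "sensitivity": tp_ / n1,
        "specificity": tn_ / n0,
        "ppv": tp_ / (tp_ + fp_) if tp_ + fp_ else math.nan,
        "npv": tn_ / (tn_ + fn_) if tn_ + fn_ else math.nan,
        "youden": float(j[pick]),
    }


def hosmer_lemeshow(
    probs: np.ndarray,
    labels: np.ndarray,
    g: int = 10,
) -> tuple[float, int, float]:
    """Hosmer-Lemeshow goodness-of-fit test over deciles of risk.

    chi2 = sum_g (O_g - E_g)^2 / (E_g (1 - E_g/n_g)), compared against a
    chi-square with ``groups - 2`` degrees of freedom. Quantile ties can
    collapse groups; zero-variance groups are merged with a neighbour and a
    :class:`CalibrationWarning` is emitted. If fewer than three groups
    survive, the statistic is returned with a NaN p-value.
    """
    if g < 3:
        raise ConfigurationError("Hosmer-Lemeshow requires g >= 3 (df = g - 2 >= 1)")
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels, dtype=float)
    if p.size < 2 * g:
        raise ConfigurationError(f"need at least {2 * g} observations for g={g}")
    edges = np.quantile(p, np.linspace(0, 1, g + 1))
    edges = np.unique(edges)
    if edges.size - 1 < g:
        warnings.warn("tied probabilities collapsed risk groups", CalibrationWarning)
    grp = np.clip(np.searchsorted(edges, p, side="right") - 1, 0, edges.size - 2)

    obs, exp, cnt = [], [], []
    for k in range(edges.size - 1):
        sel = grp == k
        if not sel.any():
            continue
        obs.append(y[sel].sum())
        exp.append(p[sel].sum())
        cnt.append(int(sel.sum()))

    # merge groups whose binomial variance vanishes
    i = 0
    merged = False
    while i < len(obs):
        denom = exp[i] * (1 - exp[i] / cnt[i])
        if denom <= 0 and len(obs) > 1:
            j = i - 1 if i > 0 else i + 1
            obs[j] += obs.pop(i)
            exp[j] += exp.pop(i)
            cnt[j] += cnt.pop(i)
            merged = True
            i = 0
        else:
            i += 1
    if merged:
        warnings.warn("merged risk groups with zero expected variance", CalibrationWarning)

    stat = 0.0
    for o, e, n_g in zip(obs, exp, cnt):
        denom = e * (1 - e / n_g)
        if denom > 0:
            stat += (o - e) ** 2 / denom
    df = len(obs) - 2
    if df < 1:
        warnings.warn("fewer than 3 risk groups; p-value undefined", CalibrationWarning)
        return float(stat), df, math.nan
    return float(stat), df, float(stats.chi2.sf(stat, df))


def evaluate_scores(
    probs: np.ndarray,
    labels: np.ndarray,
    hl_groups: int = 10,
    ci_method: str = "delong",
) -> ModelEvaluation:
    """Full evaluation of predicted probabilities against binary labels."""
    p = np.asarray(probs, dtype=float)
    y = _check_binary(labels)
    auc, ci = auroc(p, y, ci_method=ci_method)
    op = youden_cutoff(p, y)
    g = min(hl_groups, max(3, p.size // 5))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", CalibrationWarning)
        stat, df, pval = hosmer_lemeshow(p, y, g=g)
    return ModelEvaluation(
        auroc=auc,
        auroc_ci=ci,
        optimal_cutoff=op["optimal_cutoff"],
        sensitivity=op["sensitivity"],
        specificity=op["specificity"],
        ppv=op["ppv"],
        npv=op["npv"],
        hl_statistic=stat,
        hl_df=df,
        hl_p=pval,
        n=int(p.size),
    )
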