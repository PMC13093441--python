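"""Test-cohort evaluation: exact binomial inference, paired comparisons,
the abnormal-deflection screening rule and the Spiegelhalter-Knill-Jones
ECG scoring model.

All confusion-matrix metrics carry Clopper-Pearson exact 95% confidence
intervals; paired MCG-vs-ECG classifications are compared with the exact
binomial McNemar test; nonparametric group contrasts are summarised by the
effect size r = |Z| / sqrt(N) of the Mann-Whitney statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "clopper_pearson",
    "MetricWithCI",
    "DiagnosticReport",
    "confusion_metrics",
    "mcnemar_exact",
    "bonferroni",
    "effect_size_r",
    "calibrate_deflection",
    "deflection_rule",
    "SKJModel",
    "SKJResults",
    "skj_fit",
    "skj_score",
]


def clopper_pearson(x: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval by beta-quantile inversion.

    Boundary cases are closed-form: lower = 0 at x = 0, upper = 1 at x = n
    (and there lower = (alpha/2)^(1/n)).
    """
    if not (0 <= x <= n) or n < 1 or int(x) != x or int(n) != n:
        raise ValueError(f"invalid binomial count x={x}, n={n}")
    alpha = 1.0 - conf
    lower = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2.0, x, n - x + 1))
    upper = 1.0 if x == n else float(stats.beta.ppf(1.0 - alpha / 2.0, x + 1, n - x))
    return lower, upper


@dataclass(frozen=True)
class MetricWithCI:
    """A proportion with its exact CI; undefined when the denominator is 0."""

    numerator: int
    denominator: int
    conf: float = 0.95

    @property
    def defined(self) -> bool:
        return self.denominator > 0

    @property
    def value(self) -> float:
        return self.numerator / self.denominator if self.defined else float("nan")

    @property
    def ci(self) -> tuple[float, float]:
        if not self.defined:
            return (float("nan"), float("nan"))
        return clopper_pearson(self.numerator, self.denominator, self.conf)

    def __str__(self) -> str:
        if not self.defined:
            return "undefined"
        lo, hi = self.ci
        return f"{100 * self.value:.1f}% ({100 * lo:.1f}%-{100 * hi:.1f}%)"


@dataclass
class DiagnosticReport:
    """Confusion counts and derived metrics with exact CIs."""

    tp: int
    fp: int
    tn: int
    fn: int
    auc: Optional[float] = None
    auc_ci: Optional[tuple[float, float]] = None

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> MetricWithCI:
        return MetricWithCI(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> MetricWithCI:
        return MetricWithCI(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> MetricWithCI:
        return MetricWithCI(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> MetricWithCI:
        return MetricWithCI(self.tn, self.tn + self.fn)

    @property
    def accuracy(self) -> MetricWithCI:
        return MetricWithCI(self.tp + self.tn, self.n)

    def summary(self) -> str:
        lines = [
            f"confusion: TP={self.tp} FP={self.fp} TN={self.tn} FN={self.fn} (n={self.n})",
            f"Sen {self.sensitivity}   Spe {self.specificity}",
            f"PPV {self.ppv}   NPV {self.npv}   Acc {self.accuracy}",
        ]
        if self.auc is not None:
            ci = f" ({self.auc_ci[0]:.3f}-{self.auc_ci[1]:.3f})" if self.auc_ci else ""
            lines.append(f"AUC {self.auc:.3f}{ci}")
        return "\n".join(lines)

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
            m: MetricWithCI = getattr(self, name)
            lo, hi = m.ci
            rows.append(
                {
                    "metric": name,
                    "numerator": m.numerator,
                    "denominator": m.denominator,
                    "value_pct": round(100 * m.value, 1) if m.defined else float("nan"),
                    "ci_lower_pct": round(100 * lo, 1) if m.defined else float("nan"),
                    "ci_upper_pct": round(100 * hi, 1) if m.defined else float("nan"),
                }
            )
        return pd.DataFrame(rows)


def confusion_metrics(
    predictions: Sequence[int] | np.ndarray, labels: Sequence[int] | np.ndarray
) -> DiagnosticReport:
    """Confusion counts and Se/Sp/PPV/NPV/Acc with Clopper-Pearson CIs."""
    pred = np.asarray(predictions, dtype=int)
    lab = np.asarray(labels, dtype=int)
    if pred.shape != lab.shape:
        raise ValueError("predictions and labels must align")
    if len(np.unique(lab)) < 2:
        raise ValueError("labels must contain both classes")
    tp = int(((pred == 1) & (lab == 1)).sum())
    fp = int(((pred == 1) & (lab == 0)).sum())
    tn = int(((pred == 0) & (lab == 0)).sum())
    fn = int(((pred == 0) & (lab == 1)).sum())
    return DiagnosticReport(tp=tp, fp=fp, tn=tn, fn=fn)


def mcnemar_exact(b: int, c: int) -> float:
    """Exact two-sided McNemar p from the discordant-pair counts b and c.

    Under the null the smaller discordant count is Binomial(b + c, 1/2);
    p = min(1, 2 P(X <= min(b, c))).  b = c = 0 returns 1 by convention.
    """
    if b < 0 or c < 0 or int(b) != b or int(c) != c:
        raise ValueError("discordant counts must be non-negative integers")
    n = b + c
    if n == 0:
        return 1.0
    k = min(b, c)
    return float(min(1.0, 2.0 * stats.binom.cdf(k, n, 0.5)))


def bonferroni(p_values: Sequence[float]) -> list[float]:
    """Bonferroni-adjusted p-values: min(1, m * p)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return [float(min(1.0, len(p) * v)) for v in p]


def effect_size_r(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """Mann-Whitney effect size r = |Z| / sqrt(N), tie-corrected.

    Z is the normal approximation of the U statistic (without continuity
    correction); identical pooled values give r = 0.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    mean_u = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
    var_u = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var_u <= 0:
        return 0.0
    z = (u - mean_u) / math.sqrt(var_u)
    return float(abs(z) / math.sqrt(n))


# ---------------------------------------------------------------------------
# abnormal-deflection screening rule
# ---------------------------------------------------------------------------


def calibrate_deflection(hc_ca_r: Sequence[float], percentile: float = 97.5) -> float:
    """Abnormality threshold: the given percentile of healthy-control CA_R."""
    vals = np.asarray(hc_ca_r, dtype=float)
    if len(vals) < 20:
        raise ValueError("need at least 20 healthy controls to calibrate")
    return float(np.percentile(vals, percentile))


def deflection_rule(ca_r: float | np.ndarray, threshold_deg: float = 62.0):
    """Abnormal R-peak current deflection: CA_R strictly greater than threshold."""
    arr = np.asarray(ca_r, dtype=float)
    if np.any(np.isnan(arr)):
        raise ValueError("CA_R missing")
    flag = arr > threshold_deg
    if np.ndim(ca_r) == 0:
        return bool(flag)
    return flag


# ---------------------------------------------------------------------------
# Spiegelhalter-Knill-Jones ECG scoring
# ---------------------------------------------------------------------------


@dataclass
class SKJModel:
    """Additive log-likelihood-ratio scoring model over binary findings.

    Each finding contributes ln LR(present) when present and ln LR(absent)
    when absent (add-1/2 smoothed); the subject score is the prior log-odds
    plus the shrunken sum of weights.
    """

    weights_present: dict[str, float]
    weights_absent: dict[str, float]
    prior_log_odds: float
    shrinkage: float
    threshold: float
    flagged: list[str] = field(default_factory=list)

    def score(self, findings: pd.DataFrame) -> np.ndarray:
        s = np.full(len(findings), self.prior_log_odds, dtype=float)
        for name, w_p in self.weights_present.items():
            w_a = self.weights_absent[name]
            x = findings[name].to_numpy(dtype=float)
            s += self.shrinkage * (x * w_p + (1 - x) * w_a)
        return s

    def classify(self, findings: pd.DataFrame) -> np.ndarray:
        return (self.score(findings) >= self.threshold).astype(int)

    def summary(self) -> str:
        lines = [
            "Spiegelhalter-Knill-Jones ECG score",
            f"prior log-odds = {self.prior_log_odds:.3f}  shrinkage = {self.shrinkage:.3f}  "
            f"threshold = {self.threshold:.3f}",
            f"{'finding':<24}{'w(present)':>12}{'w(absent)':>12}",
        ]
        for name in self.weights_present:
            lines.append(
                f"{name:<24}{self.weights_present[name]:>12.3f}{self.weights_absent[name]:>12.3f}"
            )
        if self.flagged:
            lines.append("smoothed one-class findings: " + ", ".join(self.flagged))
        return "\n".join(lines)


#: alias kept for symmetry with the model module's results naming
SKJResults = SKJModel


def skj_fit(
    findings: pd.DataFrame,
    labels: Sequence[int] | np.ndarray,
    finding_cols: Optional[list[str]] = None,
) -> SKJModel:
    """Fit an SKJ scoring model from binary findings and class labels.

    Weights are natural logs of add-1/2-smoothed likelihood ratios; the
    shrinkage factor is the logistic-calibration slope of the raw score
    (clipped to [0, 1]); the operating threshold maximises the Youden index
    of the shrunken score on the training data.
    """
    from .model import fit_logistic, youden_cutoff

    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required to fit an SKJ model")
    if finding_cols is None:
        finding_cols = [c for c in findings.columns if c not in ("id", "label")]
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    weights_present: dict[str, float] = {}
    weights_absent: dict[str, float] = {}
    flagged: list[str] = []
    for name in finding_cols:
        x = findings[name].to_numpy(dtype=float)
        a = float(((x == 1) & (y == 1)).sum())  # present in cases
        b = float(((x == 1) & (y == 0)).sum())  # present in controls
        if a == 0 or b == 0 or a == n_pos or b == n_neg:
            flagged.append(name)
        p_pres_case = (a + 0.5) / (n_pos + 1.0)
        p_pres_ctrl = (b + 0.5) / (n_neg + 1.0)
        weights_present[name] = math.log(p_pres_case / p_pres_ctrl)
        weights_absent[name] = math.log((1.0 - p_pres_case) / (1.0 - p_pres_ctrl))
    prior = math.log(n_pos / n_neg)

    raw = np.full(len(findings), prior, dtype=float)
    for name in finding_cols:
        x = findings[name].to_numpy(dtype=float)
        raw += x * weights_present[name] + (1 - x) * weights_absent[name]
    # logistic calibration of the raw score; slope in [0, 1] is the shrinkage
    spread = np.ptp(raw)
    if spread < 1e-12:
        shrinkage = 1.0
    else:
        cal = fit_logistic(raw[:, None], y)
        shrinkage = float(np.clip(cal.params.iloc[1], 0.0, 1.0))

    model = SKJModel(
        weights_present=weights_present,
        weights_absent=weights_absent,
        prior_log_odds=prior,
        shrinkage=shrinkage,
        threshold=0.0,
        flagged=flagged,
    )
    scores = model.score(findings)
    if np.ptp(scores) < 1e-12:
        model.threshold = float(scores[0])
    else:
        model.threshold, _ = youden_cutoff(scores, y)
    return model


def skj_score(model: SKJModel, findings: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Scores and binary classifications of a findings table under a model."""
    s = model.score(findings)
    return s, (s >= model.threshold).astype(int)
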