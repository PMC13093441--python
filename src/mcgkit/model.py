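"""Diagnostic-model development: forced-covariate forward-stepwise logistic
regression with Youden cutoff, bootstrap optimism correction and calibration.

The workflow mirrors standard clinical-prediction-model practice: screen the
candidate markers for multicollinearity (VIF), force the confounders (age,
sex) into a binary logistic model, add markers one at a time by the
likelihood-ratio test until none reaches the entry alpha, pick the operating
cutoff that maximises the Youden index on the training data, and estimate the
in-sample optimism of AUC / sensitivity / specificity by Harrell's bootstrap
(the entire selection procedure re-run inside each resample).

The module follows the model / results split: build a :class:`StepwiseLogit`
from a subject table, ``fit()`` it, and interrogate the returned
:class:`StepwiseLogitResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .containers import FEATURE_NAMES

__all__ = [
    "LogitFit",
    "fit_logistic",
    "vif",
    "StepwiseConfig",
    "StepwiseLogit",
    "StepwiseLogitResults",
    "OptimismResult",
    "youden_cutoff",
    "auc_mann_whitney",
    "hosmer_lemeshow",
    "bootstrap_optimism",
    "calibration_curve",
    "PerfectSeparationWarning",
]


class PerfectSeparationWarning(UserWarning):
    """The likelihood is monotone; coefficients reported at the iteration cap."""


# ---------------------------------------------------------------------------
# maximum-likelihood logistic fit (IRLS)
# ---------------------------------------------------------------------------


@dataclass
class LogitFit:
    """Maximum-likelihood logistic-regression fit.

    ``params`` includes the intercept under the name "const"; ``llf`` is the
    log-likelihood, so the deviance (-2 log L) is ``-2 * llf``.
    """

    terms: list[str]
    params: pd.Series
    bse: pd.Series
    llf: float
    n_iter: int
    converged: bool

    @property
    def deviance(self) -> float:
        return -2.0 * self.llf

    @property
    def zvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(2.0 * stats.norm.sf(np.abs(self.zvalues)), index=self.params.index)

    @property
    def odds_ratios(self) -> pd.Series:
        return np.exp(self.params)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {"lower": self.params - z * self.bse, "upper": self.params + z * self.bse}
        )

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Event probabilities for a design frame containing ``terms``."""
        eta = self.params["const"] + X[self.terms].to_numpy(float) @ self.params[self.terms].to_numpy()
        return expit(eta)


def _design(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return np.column_stack([np.ones(X.shape[0]), X])


def fit_logistic(
    X: pd.DataFrame | np.ndarray,
    y: Sequence[int] | np.ndarray,
    terms: Optional[list[str]] = None,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> LogitFit:
    """Fit a binary logistic model by iteratively reweighted least squares.

    Converges when the largest score (gradient) component falls below ``tol``.
    Perfect separation is flagged with :class:`PerfectSeparationWarning` and
    the finite-iteration estimates are returned.
    """
    if isinstance(X, pd.DataFrame):
        terms = terms if terms is not None else list(X.columns)
        Xmat = X[terms].to_numpy(dtype=float)
    else:
        Xmat = np.asarray(X, dtype=float)
        if Xmat.ndim == 1:
            Xmat = Xmat[:, None]
        terms = terms if terms is not None else [f"x{i}" for i in range(Xmat.shape[1])]
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("labels must be binary 0/1")
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("need at least one event and one non-event")
    if not np.all(np.isfinite(Xmat)):
        raise ValueError("missing or non-finite values in design matrix")

    D = _design(Xmat)
    n, p = D.shape
    beta = np.zeros(p)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = D @ beta
        mu = expit(eta)
        w = mu * (1.0 - mu)
        score = D.T @ (y - mu)
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        XtWX = (D * w[:, None]).T @ D
        try:
            step = np.linalg.solve(XtWX, score)
        except np.linalg.LinAlgError as exc:
            raise ValueError("singular design matrix in logistic fit") from exc
        # damped Newton: halve until the likelihood does not decrease
        llf_old = np.sum(y * eta - np.logaddexp(0.0, eta))
        lam = 1.0
        for _ in range(30):
            cand = beta + lam * step
            eta_c = D @ cand
            llf_new = np.sum(y * eta_c - np.logaddexp(0.0, eta_c))
            if llf_new >= llf_old - 1e-12:
                break
            lam /= 2.0
        beta = beta + lam * step

    eta = D @ beta
    mu = expit(eta)
    llf = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    separated = np.all(mu[y == 1] > 1 - 1e-6) and np.all(mu[y == 0] < 1e-6)
    if separated or (not converged and np.max(np.abs(beta)) > 50):
        warnings.warn(
            "perfect or quasi-perfect separation detected; coefficients are not "
            "finite maximum-likelihood estimates",
            PerfectSeparationWarning,
        )
    w = mu * (1.0 - mu)
    XtWX = (D * w[:, None]).T @ D
    try:
        cov = np.linalg.inv(XtWX)
        diag = np.diag(cov)
        bse = np.where(diag > 0, np.sqrt(np.abs(diag)), np.nan)
    except np.linalg.LinAlgError:
        bse = np.full(p, np.nan)
    index = ["const", *terms]
    return LogitFit(
        terms=list(terms),
        params=pd.Series(beta, index=index),
        bse=pd.Series(bse, index=index),
        llf=llf,
        n_iter=it,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# multicollinearity screen
# ---------------------------------------------------------------------------


def vif(table: pd.DataFrame, terms: Sequence[str]) -> pd.Series:
    """Variance inflation factor per term: VIF_j = 1 / (1 - R^2_j).

    R^2_j comes from the least-squares regression of term j on the remaining
    terms (with intercept).  Exact collinearity yields +inf.
    """
    terms = list(terms)
    if len(table) <= len(terms) + 1:
        raise ValueError("need n > number of terms + 1 for a VIF screen")
    X = table[terms].to_numpy(dtype=float)
    out = {}
    for j, name in enumerate(terms):
        yj = X[:, j]
        others = np.delete(X, j, axis=1)
        D = _design(others)
        coef, *_ = np.linalg.lstsq(D, yj, rcond=None)
        resid = yj - D @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((yj - yj.mean()) ** 2).sum())
        if ss_tot == 0:
            out[name] = np.inf
            continue
        r2 = 1.0 - ss_res / ss_tot
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


# ---------------------------------------------------------------------------
# score-level utilities
# ---------------------------------------------------------------------------


def auc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> float:
    """ROC AUC via the Mann-Whitney identity, ties counted half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes required for AUC")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def youden_cutoff(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Cutoff maximising J = Se + Sp - 1 over the observed score thresholds.

    A subject is classified positive when score >= cutoff.  Ties in J break
    toward the lowest cutoff.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes required for a Youden cutoff")
    thresholds = np.unique(scores)
    best_j, best_cut = -np.inf, thresholds[0]
    for cut in thresholds:
        pred = scores >= cut
        se = (pred & (labels == 1)).sum() / n_pos
        sp = (~pred & (labels == 0)).sum() / n_neg
        j = se + sp - 1.0
        if j > best_j + 1e-12:
            best_j, best_cut = j, cut
    return float(best_cut), float(best_j)


def hosmer_lemeshow(
    probs: np.ndarray, labels: np.ndarray, g: int = 10
) -> tuple[float, int, float, int]:
    """Hosmer-Lemeshow goodness-of-fit test on ``g`` quantile groups.

    Returns (chi2, df, p, n_groups_used); df = g - 2 with the groups actually
    used (empty quantile groups are merged and counted).
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(probs) < g:
        raise ValueError("need at least g observations")
    if np.any((probs <= 0) | (probs >= 1)):
        probs = np.clip(probs, 1e-10, 1 - 1e-10)
    order = np.argsort(probs, kind="mergesort")
    edges = np.array_split(order, g)
    groups = [e for e in edges if len(e) > 0]
    chi2 = 0.0
    for idx in groups:
        p_bar = probs[idx].mean()
        n_g = len(idx)
        o = labels[idx].sum()
        e = n_g * p_bar
        denom = e * (1.0 - p_bar)
        if denom <= 0:
            continue
        chi2 += (o - e) ** 2 / denom
    df = len(groups) - 2
    p = float(stats.chi2.sf(chi2, df))
    return float(chi2), df, p, len(groups)


def calibration_curve(
    probs: np.ndarray, labels: np.ndarray, bins: int = 5
) -> pd.DataFrame:
    """Quantile-binned calibration table with exact per-bin binomial CIs.

    Columns: bin, n, mean_predicted, observed_rate, ci_lower, ci_upper.
    Degenerate probability vectors (fewer unique values than bins) collapse to
    the achievable number of bins.
    """
    from .evaluate import clopper_pearson

    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(probs) < bins:
        raise ValueError("need at least `bins` observations")
    order = np.argsort(probs, kind="mergesort")
    if len(np.unique(probs)) < bins:
        parts = [order]  # single effective bin fallback
    else:
        parts = np.array_split(order, bins)
    rows = []
    for i, idx in enumerate(parts):
        x = int(labels[idx].sum())
        n = len(idx)
        lo, hi = clopper_pearson(x, n)
        rows.append(
            {
                "bin": i,
                "n": n,
                "mean_predicted": float(probs[idx].mean()),
                "observed_rate": x / n,
                "ci_lower": lo,
                "ci_upper": hi,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# stepwise model / results
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StepwiseConfig:
    """Configuration of the stepwise development workflow.

    ``scale_rules`` maps a term to a multiplicative factor applied before
    fitting (e.g. CA_R per 10 degrees -> factor 0.1), so its coefficient is
    reported on the clinically convenient scale.
    """

    forced_terms: tuple[str, ...] = ("age", "sex")
    candidate_terms: tuple[str, ...] = tuple(FEATURE_NAMES)
    entry_alpha: float = 0.05
    max_steps: int = 9
    vif_limit: float = 5.0
    scale_rules: dict[str, float] = field(default_factory=lambda: {"CA_R": 0.1})

    def __post_init__(self) -> None:
        if set(self.forced_terms) & set(self.candidate_terms):
            raise ValueError("forced and candidate terms must be disjoint")
        if not 0.0 < self.entry_alpha < 1.0:
            raise ValueError("entry_alpha must lie in (0, 1)")


def _prepare_table(table: pd.DataFrame, config: StepwiseConfig, label_col: str) -> tuple[pd.DataFrame, np.ndarray | None]:
    df = table.copy()
    if "sex" in df.columns and df["sex"].dtype == object:
        df["sex"] = (df["sex"].astype(str).str.lower() == "male").astype(float)
    for term, factor in config.scale_rules.items():
        if term in df.columns:
            df[term] = df[term].astype(float) * factor
    if label_col not in df.columns:
        return df, None
    if df[label_col].dtype == object:
        y = (df[label_col].astype(str).str.upper() == "PH").astype(int).to_numpy()
    else:
        y = df[label_col].astype(int).to_numpy()
    return df, y


def _collinearity_prune(
    df: pd.DataFrame, y: np.ndarray, candidates: list[str], config: StepwiseConfig
) -> list[str]:
    """Drop candidates until every VIF is below the limit.

    Among the offending terms, the one whose forced-covariate-adjusted
    univariable model has the highest deviance (worst fit) is dropped first —
    the conventional resolution that keeps the better-fitting member of a
    collinear pair.
    """
    kept = list(candidates)
    dropped: list[str] = []
    while len(kept) >= 2:
        v = vif(df, kept)
        offenders = [t for t in kept if v[t] > config.vif_limit]
        if not offenders:
            break
        deviances = {}
        for t in offenders:
            try:
                deviances[t] = fit_logistic(df, y, terms=list(config.forced_terms) + [t]).deviance
            except ValueError:
                deviances[t] = np.inf
        worst = max(offenders, key=lambda t: deviances[t])
        kept.remove(worst)
        dropped.append(worst)
    return dropped


def _stepwise_fit(
    df: pd.DataFrame, y: np.ndarray, config: StepwiseConfig
) -> tuple[list[str], LogitFit, list[dict]]:
    """Forward likelihood-ratio selection from forced terms; returns the trail."""
    selected = list(config.forced_terms)
    trail: list[dict] = []
    with warnings.catch_warnings():
        # candidate-scan fits may hit separation transiently; only the final
        # model's warning (re-raised by the fit below) is informative
        warnings.simplefilter("ignore", PerfectSeparationWarning)
        current = fit_logistic(df, y, terms=selected)
        remaining = [t for t in config.candidate_terms if t in df.columns]
        for _ in range(config.max_steps):
            best = None
            for cand in remaining:
                try:
                    fit = fit_logistic(df, y, terms=selected + [cand])
                except ValueError:
                    continue
                lr = max(current.deviance - fit.deviance, 0.0)
                p = float(stats.chi2.sf(lr, 1))
                if best is None or p < best[1] - 1e-12:  # ties keep candidate order
                    best = (cand, p, fit)
            if best is None or best[1] >= config.entry_alpha:
                break
            cand, p, fit = best
            trail.append({"term": cand, "lr_p": p, "deviance": fit.deviance})
            selected.append(cand)
            remaining.remove(cand)
            current = fit
    current = fit_logistic(df, y, terms=selected)
    return selected, current, trail


@dataclass
class OptimismResult:
    """Harrell bootstrap optimism estimate for one or more metrics."""

    apparent: dict[str, float]
    optimism: dict[str, float]
    corrected: dict[str, float]
    n_resamples: int
    n_redrawn: int
    per_resample: pd.DataFrame


class StepwiseLogitResults:
    """Fitted stepwise diagnostic model: estimates, cutoff, diagnostics."""

    def __init__(
        self,
        model: "StepwiseLogit",
        selected_terms: list[str],
        fit: LogitFit,
        trail: list[dict],
        vif_table: pd.Series,
        train_probs: np.ndarray,
        y: np.ndarray,
    ) -> None:
        self.model = model
        self.selected_terms = selected_terms
        self.fit = fit
        self.selection_trail = trail
        self.vif_table = vif_table
        self.train_probs = train_probs
        self._y = y
        self.dropped_terms: list[str] = []
        self.cutoff, self.youden_j = youden_cutoff(train_probs, y)
        self.apparent_auc = auc_mann_whitney(train_probs, y)

    # -- estimates ---------------------------------------------------------
    @property
    def params(self) -> pd.Series:
        return self.fit.params

    @property
    def odds_ratios(self) -> pd.Series:
        return self.fit.odds_ratios

    @property
    def deviance(self) -> float:
        return self.fit.deviance

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        df, _ = _prepare_table(table, self.model.config, self.model.label_col)
        return self.fit.predict(df)

    def classify(self, table: pd.DataFrame) -> np.ndarray:
        """Binary prediction at the training Youden cutoff (>= cutoff -> PH)."""
        return (self.predict_proba(table) >= self.cutoff).astype(int)

    # -- diagnostics -------------------------------------------------------
    def hosmer_lemeshow(self, g: int = 10) -> tuple[float, int, float, int]:
        return hosmer_lemeshow(self.train_probs, self._y, g=g)

    def calibration(self, bins: int = 5, table: Optional[pd.DataFrame] = None) -> pd.DataFrame:
        if table is None:
            return calibration_curve(self.train_probs, self._y, bins=bins)
        df, y = _prepare_table(table, self.model.config, self.model.label_col)
        return calibration_curve(self.fit.predict(df), y, bins=bins)

    def validate(self, B: int = 2000, seed: int = 0) -> OptimismResult:
        """Bootstrap optimism correction re-running the full selection per resample."""
        return bootstrap_optimism(
            self.model.table, self.model.config, B=B, seed=seed, label_col=self.model.label_col
        )

    # -- presentation ------------------------------------------------------
    def summary(self) -> str:
        ci = self.fit.conf_int()
        or_ci_low = np.exp(ci["lower"])
        or_ci_high = np.exp(ci["upper"])
        lines = [
            "Stepwise logistic diagnostic model",
            "=" * 66,
            f"n = {len(self._y)}   events = {int(self._y.sum())}   "
            f"-2 log L = {self.deviance:.3f}",
            f"selected terms: {', '.join(self.selected_terms)}",
            f"apparent AUC = {self.apparent_auc:.3f}   "
            f"Youden cutoff = {self.cutoff:.3f} (J = {self.youden_j:.3f})",
            "-" * 66,
            f"{'term':<10}{'B':>9}{'SE':>9}{'OR':>9}{'OR 95% CI':>19}{'p':>9}",
        ]
        for name in self.fit.params.index:
            p = self.fit.pvalues[name]
            lines.append(
                f"{name:<10}{self.fit.params[name]:>9.3f}{self.fit.bse[name]:>9.3f}"
                f"{self.fit.odds_ratios[name]:>9.3f}"
                f"{or_ci_low[name]:>9.3f}-{or_ci_high[name]:<9.3f}"
                f"{p:>8.3g}"
            )
        scale = self.model.config.scale_rules
        if scale:
            notes = ", ".join(f"{t} scaled by {f}" for t, f in scale.items())
            lines.append(f"note: {notes}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        """Serializable description (terms, coefficients, cutoff, config)."""
        return {
            "selected_terms": list(self.selected_terms),
            "coefficients": {k: float(v) for k, v in self.fit.params.items()},
            "odds_ratios": {k: float(v) for k, v in self.fit.odds_ratios.items()},
            "cutoff": float(self.cutoff),
            "apparent_auc": float(self.apparent_auc),
            "deviance": float(self.deviance),
            "scale_rules": dict(self.model.config.scale_rules),
            "forced_terms": list(self.model.config.forced_terms),
        }


class StepwiseLogit:
    """Diagnostic-model builder over a subject feature table.

    Parameters
    ----------
    table : DataFrame
        One row per subject with the label column, forced covariates and
        candidate markers.  ``sex`` may be "female"/"male" strings.
    config : StepwiseConfig
    label_col : str
        Column with the class label; "PH" (or 1) is the event.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        config: Optional[StepwiseConfig] = None,
        label_col: str = "label",
    ) -> None:
        self.table = table.reset_index(drop=True)
        self.config = config or StepwiseConfig()
        self.label_col = label_col

    @classmethod
    def from_records(cls, records, config: Optional[StepwiseConfig] = None) -> "StepwiseLogit":
        from .io import records_to_frame

        return cls(records_to_frame(records), config=config)

    def screen_vif(self) -> pd.Series:
        df, _ = _prepare_table(self.table, self.config, self.label_col)
        terms = [t for t in self.config.candidate_terms if t in df.columns]
        return vif(df, terms)

    def fit(self) -> StepwiseLogitResults:
        df, y = _prepare_table(self.table, self.config, self.label_col)
        vif_table = self.screen_vif()
        candidates = [t for t in self.config.candidate_terms if t in df.columns]
        dropped = _collinearity_prune(df, y, candidates, self.config)
        config = self.config
        if dropped:
            config = StepwiseConfig(
                forced_terms=config.forced_terms,
                candidate_terms=tuple(t for t in candidates if t not in dropped),
                entry_alpha=config.entry_alpha,
                max_steps=config.max_steps,
                vif_limit=config.vif_limit,
                scale_rules=config.scale_rules,
            )
        selected, final_fit, trail = _stepwise_fit(df, y, config)
        probs = final_fit.predict(df)
        results = StepwiseLogitResults(self, selected, final_fit, trail, vif_table, probs, y)
        results.dropped_terms = dropped
        return results


def stepwise_forward_lr(
    table: pd.DataFrame, config: Optional[StepwiseConfig] = None, label_col: str = "label"
) -> StepwiseLogitResults:
    """Functional wrapper: build and fit a :class:`StepwiseLogit`."""
    return StepwiseLogit(table, config=config, label_col=label_col).fit()


def bootstrap_optimism(
    table: pd.DataFrame,
    config: Optional[StepwiseConfig] = None,
    B: int = 2000,
    seed: int = 0,
    label_col: str = "label",
    refit_selection: bool = True,
) -> OptimismResult:
    """Harrell's bootstrap optimism correction of AUC, Se and Sp.

    For each resample the entire modelling process (stepwise selection
    included, unless ``refit_selection=False``) is re-run on the bootstrap
    sample; optimism is the bootstrap-sample performance minus the original-
    sample performance of the bootstrap model, averaged over resamples.
    Resamples containing a single class are redrawn (counted in the result).
    """
    if B < 1:
        raise ValueError("need at least one resample")
    config = config or StepwiseConfig()
    df, y = _prepare_table(table, config, label_col)
    selected, fit0, _ = _stepwise_fit(df, y, config)
    probs0 = fit0.predict(df)
    cut0, _ = youden_cutoff(probs0, y)

    def _metrics(probs: np.ndarray, yy: np.ndarray, cut: float) -> dict[str, float]:
        pred = probs >= cut
        se = (pred & (yy == 1)).sum() / max((yy == 1).sum(), 1)
        sp = (~pred & (yy == 0)).sum() / max((yy == 0).sum(), 1)
        return {"auc": auc_mann_whitney(probs, yy), "se": float(se), "sp": float(sp)}

    apparent = _metrics(probs0, y, cut0)
    rng = np.random.default_rng(seed)
    n = len(y)
    rows = []
    n_redrawn = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PerfectSeparationWarning)
        for b in range(B):
            while True:
                idx = rng.integers(0, n, size=n)
                yb = y[idx]
                if 0 < yb.sum() < n:
                    break
                n_redrawn += 1
            dfb = df.iloc[idx].reset_index(drop=True)
            try:
                if refit_selection:
                    cands_b = [t for t in config.candidate_terms if t in dfb.columns]
                    dropped_b = _collinearity_prune(dfb, yb, cands_b, config)
                    cfg_b = config
                    if dropped_b:
                        cfg_b = StepwiseConfig(
                            forced_terms=config.forced_terms,
                            candidate_terms=tuple(t for t in cands_b if t not in dropped_b),
                            entry_alpha=config.entry_alpha,
                            max_steps=config.max_steps,
                            vif_limit=config.vif_limit,
                            scale_rules=config.scale_rules,
                        )
                    _, fit_b, _ = _stepwise_fit(dfb, yb, cfg_b)
                else:
                    fit_b = fit_logistic(dfb, yb, terms=selected)
            except ValueError:
                n_redrawn += 1
                continue
            probs_bb = fit_b.predict(dfb)
            cut_b, _ = youden_cutoff(probs_bb, yb)
            m_boot = _metrics(probs_bb, yb, cut_b)
            probs_orig = fit_b.predict(df)
            m_orig = _metrics(probs_orig, y, cut_b)
            rows.append(
                {"resample": b, **{f"boot_{k}": v for k, v in m_boot.items()},
                 **{f"orig_{k}": v for k, v in m_orig.items()}}
            )
    per = pd.DataFrame(rows)
    optimism = {k: float((per[f"boot_{k}"] - per[f"orig_{k}"]).mean()) for k in ("auc", "se", "sp")}
    corrected = {k: apparent[k] - optimism[k] for k in apparent}
    return OptimismResult(
        apparent=apparent,
        optimism=optimism,
        corrected=corrected,
        n_resamples=len(per),
        n_redrawn=n_redrawn,
        per_resample=per,
    )
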