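"""Diagnostic and epidemiological evaluation statistics.

Everything needed to judge a binary VTE-risk test against observed outcomes:
2x2 confusion tables and their derived metrics (sensitivity, specificity,
PPV, NPV, Youden index), odds ratios with Woolf log-normal confidence
intervals (optionally Haldane-Anscombe corrected for sparse tables),
chi-square and Student t group comparisons, ROC curves with Youden-optimal
cutoff selection, and maximum-likelihood logistic regression for multivariate
risk-factor analysis.

Conventions: the Youden index is stored as sensitivity + specificity - 1 in
[-1, 1] and displayed x100, matching the clinical-literature habit of
printing e.g. "6.1" next to percentages; odds ratios are exposure-by-outcome
cross-product ratios with the exposed/event cell first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import stats

from .cohort import ConfusionTable

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


# ---------------------------------------------------------------------------
# Confusion table and derived metrics


def confusion(predictions: Sequence[bool], outcomes: Sequence[bool]) -> ConfusionTable:
    """Cross-tabulate test positives against true outcomes.

    ``predictions[i]`` is True when the test calls patient *i* high risk;
    ``outcomes[i]`` is True when the patient actually developed the event.
    """
    if len(predictions) != len(outcomes):
        raise ValueError(
            f"length mismatch: {len(predictions)} predictions vs "
            f"{len(outcomes)} outcomes"
        )
    if len(outcomes) == 0:
        raise ValueError("empty cohort")
    tp = fp = fn = tn = 0
    for pred, out in zip(predictions, outcomes):
        if pred and out:
            tp += 1
        elif pred and not out:
            fp += 1
        elif not pred and out:
            fn += 1
        else:
            tn += 1
    return ConfusionTable(tp=tp, fp=fp, fn=fn, tn=tn)


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Proportion-scale metrics; a denominator of zero leaves a field None."""

    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]

    @property
    def youden_index(self) -> Optional[float]:
        if self.sensitivity is None or self.specificity is None:
            return None
        return self.sensitivity + self.specificity - 1.0

    @property
    def undefined(self) -> tuple[str, ...]:
        out = [
            name
            for name in ("sensitivity", "specificity", "ppv", "npv")
            if getattr(self, name) is None
        ]
        if self.youden_index is None:
            out.append("youden_index")
        return tuple(out)

    def as_percentages(self) -> dict[str, Optional[float]]:
        """Display form: proportions x100, Youden x100, rounded to 1 dp."""
        def pct(x):
            return None if x is None else round(100.0 * x, 1)

        return {
            "sensitivity": pct(self.sensitivity),
            "ppv": pct(self.ppv),
            "specificity": pct(self.specificity),
            "npv": pct(self.npv),
            "youden_index": pct(self.youden_index),
        }


def metrics(ct: ConfusionTable) -> DiagnosticMetrics:
    """Sensitivity, specificity, PPV and NPV of a confusion table."""
    if ct.n == 0:
        raise ValueError("empty confusion table")

    def ratio(num, den):
        return None if den == 0 else num / den

    return DiagnosticMetrics(
        sensitivity=ratio(ct.tp, ct.tp + ct.fn),
        specificity=ratio(ct.tn, ct.tn + ct.fp),
        ppv=ratio(ct.tp, ct.tp + ct.fp),
        npv=ratio(ct.tn, ct.tn + ct.fn),
    )


# ---------------------------------------------------------------------------
# Odds ratios


@dataclass(frozen=True)
class OddsRatioResult:
    or_value: float
    ci_low: float
    ci_high: float
    p_value: Optional[float]
    method: Literal["woolf", "woolf-haldane"]


def odds_ratio(
    a: int,
    b: int,
    c: int,
    d: int,
    method: Literal["woolf", "woolf-haldane"] = "woolf",
) -> OddsRatioResult:
    """Odds ratio of a 2x2 exposure-by-outcome table with a Woolf 95% CI.

    Cell layout: ``a`` exposed events, ``b`` unexposed events, ``c`` exposed
    non-events, ``d`` unexposed non-events, so OR = (a*d)/(b*c).  The Woolf
    interval is exp(ln OR +/- 1.96 * sqrt(1/a + 1/b + 1/c + 1/d)).  With
    ``method="woolf-haldane"`` the Haldane-Anscombe 0.5 is added to every
    cell iff any cell is zero; with plain ``"woolf"`` a zero cell is an
    error, since the OR is then undefined.

    The accompanying p-value is Fisher's exact when any expected cell count
    is below 5 (the sparse-table convention), else the Pearson chi-square.
    """
    cells = (a, b, c, d)
    if any(x < 0 for x in cells):
        raise ValueError("all cells must be non-negative")
    if method == "woolf" and 0 in cells:
        raise ValueError(
            "odds ratio undefined with a zero cell; use method='woolf-haldane'"
        )
    if method == "woolf-haldane" and 0 in cells:
        aa, bb, cc, dd = (x + 0.5 for x in cells)
    else:
        aa, bb, cc, dd = (float(x) for x in cells)

    orv = (aa * dd) / (bb * cc)
    se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    ci_low = math.exp(math.log(orv) - Z_95 * se)
    ci_high = math.exp(math.log(orv) + Z_95 * se)

    table = np.array([[a, c], [b, d]], dtype=float)
    p_value: Optional[float]
    if table.sum() == 0 or (table.sum(0) == 0).any() or (table.sum(1) == 0).any():
        p_value = None
    else:
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        if (expected < 5).any():
            p_value = float(stats.fisher_exact(table)[1])
        else:
            p_value = float(stats.chi2_contingency(table, correction=False)[1])
    return OddsRatioResult(orv, ci_low, ci_high, p_value, method)


def odds_ratio_from_confusion(ct: ConfusionTable, **kw) -> OddsRatioResult:
    """OR of test positivity for the event (a=TP, b=FN, c=FP, d=TN)."""
    return odds_ratio(ct.tp, ct.fn, ct.fp, ct.tn, **kw)


# ---------------------------------------------------------------------------
# Group comparisons


def chi_square_test(
    table: Sequence[Sequence[float]],
    correction: Literal["none", "yates", "auto"] = "auto",
) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, optionally Yates-corrected.

    ``correction="auto"`` applies the Yates continuity correction whenever
    any expected cell count is below 5 (the small-sample convention of
    mainstream clinical statistics software); "yates" forces it, "none"
    disables it.  Returns ``(statistic, p_value)`` with p from chi-square(1).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if t.sum() == 0 or (t.sum(0) == 0).any() or (t.sum(1) == 0).any():
        raise ValueError("degenerate margins: chi-square undefined")
    if correction == "auto":
        expected = np.outer(t.sum(1), t.sum(0)) / t.sum()
        use_yates = bool((expected < 5).any())
    else:
        use_yates = correction == "yates"
    stat, p, _, _ = stats.chi2_contingency(t, correction=use_yates)
    return float(stat), float(p)


def two_sample_t(
    group_a: Sequence[float],
    group_b: Sequence[float],
    equal_var: bool = True,
) -> tuple[float, float]:
    """Two-sided two-sample t-test (pooled variance by default; Welch by flag)."""
    xa = np.asarray(group_a, dtype=float)
    xb = np.asarray(group_b, dtype=float)
    if len(xa) < 2 or len(xb) < 2:
        raise ValueError("each group needs at least two observations")
    if xa.std() == 0 and xb.std() == 0:
        raise ValueError("zero variance in both groups: t undefined")
    res = stats.ttest_ind(xa, xb, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# ROC / AUC and Youden-optimal cutoffs


@dataclass(frozen=True)
class RocCurve:
    """ROC curve of a marker where higher values indicate the event.

    ``thresholds`` are candidate "positive iff marker > threshold" cutpoints:
    midpoints between consecutive distinct observed values plus -inf/+inf
    sentinels, ordered so that (fpr, tpr) sweeps from (0,0) to (1,1).
    """

    thresholds: np.ndarray
    tpr: np.ndarray  # sensitivity at each threshold
    fpr: np.ndarray  # 1 - specificity
    auc: float
    optimal_cutoff: float

    @property
    def youden(self) -> np.ndarray:
        return self.tpr - self.fpr


def roc(values: Sequence[float], outcomes: Sequence[bool]) -> RocCurve:
    """ROC analysis of a continuous marker against a binary outcome.

    The AUC is the Mann-Whitney two-sample statistic normalised to [0, 1]:
    the probability that a random event case outranks a random non-case,
    ties counting one half.  The optimal cutoff maximises the Youden index
    over the threshold grid; ties are broken toward the higher cutoff
    (higher specificity — the conservative screening choice).
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(outcomes, dtype=bool)
    if len(x) != len(y):
        raise ValueError("length mismatch between marker values and outcomes")
    n1 = int(y.sum())
    n0 = int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("ROC needs both outcome classes present")

    # AUC via midranks (Mann-Whitney with tie correction)
    ranks = stats.rankdata(x)
    auc = (ranks[y].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)

    distinct = np.unique(x)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    thresholds = np.concatenate(([np.inf], mids[::-1], [-np.inf]))
    tpr = np.array([(x[y] > t).mean() for t in thresholds])
    fpr = np.array([(x[~y] > t).mean() for t in thresholds])

    j = tpr - fpr
    # argmax returns the first maximiser; thresholds are in decreasing order,
    # so the first tie is the highest cutoff (most specific)
    best = int(np.argmax(j))
    return RocCurve(
        thresholds=thresholds,
        tpr=tpr,
        fpr=fpr,
        auc=float(auc),
        optimal_cutoff=float(thresholds[best]),
    )


# ---------------------------------------------------------------------------
# Logistic regression


@dataclass(frozen=True)
class LogisticFit:
    """Per-covariate maximum-likelihood logistic estimates.

    ``wald`` is the squared z-ratio (B/SE)^2, chi-square(1) distributed under
    the null, as clinical multivariate tables print it.
    """

    names: tuple[str, ...]
    coef: np.ndarray  # B
    se: np.ndarray
    wald: np.ndarray
    p_values: np.ndarray
    converged: bool

    @property
    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.coef)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "B": self.coef,
                "SE": self.se,
                "Wald": self.wald,
                "p": self.p_values,
                "OR": self.odds_ratios,
            },
            index=list(self.names),
        )


def fit_logistic(
    design,
    outcomes: Sequence[bool],
    add_intercept: bool = True,
    tol: float = 1e-8,
) -> LogisticFit:
    """Maximum-likelihood logistic regression (Newton-Raphson / IRLS).

    ``design`` is a 2-D array or DataFrame of covariates (one column per
    covariate); an intercept column is prepended unless ``add_intercept``
    is False.  Standard errors come from the observed information at the
    optimum.  Perfect separation or non-convergence raises with a
    diagnostic message rather than returning silently absurd estimates.
    """
    import pandas as pd
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    if isinstance(design, pd.DataFrame):
        names = list(design.columns)
        X = design.to_numpy(dtype=float)
    else:
        X = np.asarray(design, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = [f"x{i}" for i in range(X.shape[1])]
    y = np.asarray(outcomes, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcomes must be binary")
    if X.shape[0] <= X.shape[1] + int(add_intercept):
        raise ValueError("need more observations than covariates")
    if add_intercept:
        X = np.column_stack([np.ones(len(y)), X])
        names = ["intercept"] + names

    with np.errstate(all="ignore"):
        try:
            res = sm.Logit(y, X).fit(disp=0, method="newton", tol=tol, maxiter=200)
        except (PerfectSeparationError, np.linalg.LinAlgError) as e:
            raise RuntimeError(f"logistic fit failed: {e}") from e
    if not res.mle_retvals.get("converged", False):
        raise RuntimeError("logistic fit did not converge")
    if not np.all(np.isfinite(res.bse)):
        raise RuntimeError(
            "logistic fit produced non-finite standard errors "
            "(likely perfect separation)"
        )
    coef = np.asarray(res.params)
    se = np.asarray(res.bse)
    wald = (coef / se) ** 2
    p = stats.chi2.sf(wald, df=1)
    return LogisticFit(
        names=tuple(names), coef=coef, se=se, wald=wald, p_values=p, converged=True
    )
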