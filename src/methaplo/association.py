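"""Dichotomization and case-control association statistics.

Continuous methylation measures are dichotomized at the Youden-index
cutoff (J = sensitivity + specificity - 1, cases positive, ">= cutoff"
test-positive). Association is estimated from the 2x2 table with the
cross-product odds ratio and Woolf log-normal 95% CI (z = 1.96, no
continuity correction), Pearson chi-square without Yates correction, and
by maximum-likelihood logistic regression (IRLS) with optional covariate
adjustment. Subgroup p-values can be Bonferroni-adjusted.

Table orientation: with a = case_low, b = case_high, c = control_low,
d = control_high, the high-vs-low odds ratio is (b*c)/(a*d).
"""

from __future__ import annotations

import warnings
from collections import namedtuple
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

Z_95 = 1.959963984540054  # exact normal 97.5% quantile
Z_REPORT = 1.96           # conventional value used in printed tables

YoudenResult = namedtuple("YoudenResult", ["cutoff", "j"])


@dataclass(frozen=True)
class TwoByTwo:
    """Case/control x low/high (hypo/hyper) contingency table."""

    a: int  # case, low  (hypo)
    b: int  # case, high (hyper)
    c: int  # control, low
    d: int  # control, high

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if v < 0:
                raise ValidationError(f"cell {name} = {v} < 0")
        if self.total == 0:
            raise ValidationError("empty table")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def swap_groups(self) -> "TwoByTwo":
        return TwoByTwo(self.c, self.d, self.a, self.b)


@dataclass
class AssociationResult:
    or_point: float
    ci_low: float
    ci_high: float
    chi2: float | None
    p_value: float
    method: str          # "woolf_2x2" | "logistic_wald"
    orientation: str
    n_used: int
    converged: bool = True
    coef: float | None = None
    se: float | None = None


# ---------------------------------------------------------------------------
# Youden dichotomization
# ---------------------------------------------------------------------------

def youden_cutoff(values, labels) -> YoudenResult:
    """Cutoff maximizing J over midpoints of consecutive distinct values.

    Cases are treated as test-positive when value >= cutoff. Ties on J
    resolve to the smallest cutoff.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=object)
    if values.shape != labels.shape:
        raise ValidationError("values and labels differ in length")
    case = values[labels == "case"]
    ctrl = values[labels == "control"]
    if case.size == 0 or ctrl.size == 0:
        raise ValidationError("both case and control labels required")
    distinct = np.unique(values)
    if distinct.size < 2:
        raise ValidationError("all values identical; no cutoff exists")
    candidates = (distinct[:-1] + distinct[1:]) / 2.0
    best = YoudenResult(cutoff=np.nan, j=-np.inf)
    for c in candidates:
        sens = np.mean(case >= c)
        spec = np.mean(ctrl < c)
        j = sens + spec - 1.0
        if j > best.j:
            best = YoudenResult(cutoff=float(c), j=float(j))
    return best


def dichotomize(values, cutoff: float):
    """Map values to 'hyper' (>= cutoff) / 'hypo'; NaN entries excluded.

    Returns (labels, n_excluded). For a pandas Series input the returned
    labels keep the surviving index.
    """
    if not np.isfinite(cutoff):
        raise ValidationError("cutoff must be finite")
    if isinstance(values, pd.Series):
        mask = values.notna()
        n_excluded = int((~mask).sum())
        out = pd.Series(
            np.where(values[mask] >= cutoff, "hyper", "hypo"),
            index=values.index[mask], dtype=object,
        )
        return out, n_excluded
    arr = np.asarray(values, dtype=float)
    mask = ~np.isnan(arr)
    labels = np.where(arr[mask] >= cutoff, "hyper", "hypo").astype(object)
    return labels, int((~mask).sum())


def crosstab(exposure_labels: pd.Series, status: pd.Series) -> TwoByTwo:
    """Build a TwoByTwo from aligned exposure (hypo/hyper) and status series."""
    joined = pd.concat([exposure_labels.rename("exp"), status.rename("st")],
                       axis=1, join="inner").dropna()
    return TwoByTwo(
        a=int(((joined["st"] == "case") & (joined["exp"] == "hypo")).sum()),
        b=int(((joined["st"] == "case") & (joined["exp"] == "hyper")).sum()),
        c=int(((joined["st"] == "control") & (joined["exp"] == "hypo")).sum()),
        d=int(((joined["st"] == "control") & (joined["exp"] == "hyper")).sum()),
    )


# ---------------------------------------------------------------------------
# Closed-form 2x2 statistics
# ---------------------------------------------------------------------------

def odds_ratio_2x2(t: TwoByTwo, haldane: bool = False) -> AssociationResult:
    """Cross-product OR (high vs low) with Woolf 95% CI.

    Zero cells yield a degenerate (infinite or zero) OR flagged via
    ``converged=False`` unless ``haldane=True`` adds 0.5 to every cell.
    """
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    if haldane and 0.0 in (a, b, c, d):
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    chi2, p_chi2 = (None, np.nan)
    try:
        chi2, p_chi2 = pearson_chi2(t)
    except ValidationError:
        pass
    if 0.0 in (a, b, c, d):
        if b * c == 0 and a * d == 0:
            or_point = np.nan
        else:
            or_point = np.inf if a * d == 0 else 0.0
        return AssociationResult(
            or_point=or_point, ci_low=0.0, ci_high=np.inf,
            chi2=chi2, p_value=p_chi2 if chi2 is not None else np.nan,
            method="woolf_2x2", orientation="high_vs_low",
            n_used=t.total, converged=False,
        )
    or_point = (b * c) / (a * d)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = np.log(or_point)
    ci_low = float(np.exp(log_or - Z_REPORT * se))
    ci_high = float(np.exp(log_or + Z_REPORT * se))
    p_wald = float(2 * stats.norm.sf(abs(log_or) / se))
    return AssociationResult(
        or_point=float(or_point), ci_low=ci_low, ci_high=ci_high,
        chi2=chi2, p_value=p_wald,
        method="woolf_2x2", orientation="high_vs_low",
        n_used=t.total, coef=float(log_or), se=float(se),
    )


def pearson_chi2(t: TwoByTwo) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) and its p-value."""
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    n = a + b + c + d
    margins = (a + b) * (c + d) * (a + c) * (b + d)
    if margins == 0:
        raise ValidationError("zero margin; chi-square undefined")
    chi2 = n * (a * d - b * c) ** 2 / margins
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


# ---------------------------------------------------------------------------
# Logistic regression
# ---------------------------------------------------------------------------

def _irls_logistic(X: np.ndarray, y: np.ndarray, tol: float = 1e-8,
                   max_iter: int = 100) -> tuple[np.ndarray, np.ndarray, bool]:
    """IRLS fit; returns (coefs, standard errors, converged)."""
    n, p = X.shape
    beta = np.zeros(p)
    dev_old = np.inf
    converged = False
    cov = np.full((p, p), np.nan)
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        mu = np.clip(mu, 1e-10, 1 - 1e-10)
        w = mu * (1 - mu)
        z = eta + (y - mu) / w
        WX = X * w[:, None]
        try:
            beta_new = np.linalg.solve(X.T @ WX, X.T @ (w * z))
        except np.linalg.LinAlgError:
            break
        beta = beta_new
        dev = -2.0 * np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu))
        if abs(dev_old - dev) < tol:
            converged = True
            break
        dev_old = dev
    eta = X @ beta
    mu = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-10, 1 - 1e-10)
    w = mu * (1 - mu)
    try:
        cov = np.linalg.inv(X.T @ (X * w[:, None]))
    except np.linalg.LinAlgError:
        converged = False
    se = np.sqrt(np.diag(cov))
    return beta, se, converged


def logistic_fit(
    outcome,
    exposure,
    covariates: pd.DataFrame | None = None,
    exposure_name: str = "exposure",
) -> dict[str, AssociationResult]:
    """ML logistic regression of case status on exposure (+ covariates).

    *outcome* is a case/control label sequence (or 0/1); *exposure* is
    binary ('hypo'/'hyper', 0/1) or continuous. Returns one
    AssociationResult per non-intercept term with OR = exp(coef) and Wald
    95% CI. Coefficients with |coef| > 15 flag separation
    (``converged=False``).
    """
    y = np.asarray(
        [1 if v in (1, "case", True) else 0 for v in np.asarray(outcome)],
        dtype=float,
    )
    exp_arr = np.asarray(exposure)
    if exp_arr.dtype.kind in "OUS":
        exp_num = np.asarray(
            [1.0 if v in ("hyper", "high", 1, "1") else 0.0 for v in exp_arr]
        )
    else:
        exp_num = exp_arr.astype(float)

    cols = {exposure_name: exp_num}
    if covariates is not None:
        for name in covariates.columns:
            cols[str(name)] = covariates[name].to_numpy(dtype=float)
    design = pd.DataFrame(cols)
    design.insert(0, "intercept", 1.0)
    X = design.to_numpy(dtype=float)
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValidationError("missing values in design matrix or outcome")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns by greedy rank check
        bad = []
        kept_idx: list[int] = []
        for j in range(X.shape[1]):
            trial = X[:, kept_idx + [j]]
            if np.linalg.matrix_rank(trial) == len(kept_idx) + 1:
                kept_idx.append(j)
            else:
                bad.append(design.columns[j])
        raise ValidationError(f"design matrix rank deficient; columns {bad}")

    beta, se, ok = _irls_logistic(X, y)
    separated = np.any(np.abs(beta) > 15)
    if separated:
        warnings.warn("possible separation: |coefficient| > 15", stacklevel=2)
    results: dict[str, AssociationResult] = {}
    for j, name in enumerate(design.columns):
        if name == "intercept":
            continue
        coef, s = float(beta[j]), float(se[j])
        p = float(2 * stats.norm.sf(abs(coef) / s)) if s > 0 else np.nan
        with np.errstate(over="ignore"):
            or_point = float(np.exp(coef))
            ci_lo = float(np.exp(coef - Z_REPORT * s))
            ci_hi = float(np.exp(coef + Z_REPORT * s))
        results[name] = AssociationResult(
            or_point=or_point,
            ci_low=ci_lo,
            ci_high=ci_hi,
            chi2=None,
            p_value=p,
            method="logistic_wald",
            orientation=f"{name} (unit increase / high vs low)",
            n_used=int(y.size),
            converged=bool(ok and not separated),
            coef=coef,
            se=s,
        )
    return results


def bonferroni(p_values, m: int) -> np.ndarray:
    """Bonferroni adjustment p_adj = min(1, m * p)."""
    p = np.asarray(p_values, dtype=float)
    if m < p.size:
        raise ValidationError(f"m = {m} < number of tests ({p.size})")
    return np.minimum(1.0, m * p)
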