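"""Prognostic-evaluation machinery: ROC/AUC with DeLong inference,
optimal-cutpoint search, Kaplan–Meier, log-rank, Cox proportional hazards,
Cohen's kappa and sensitivity/specificity.

Conventions
-----------
* A *score* is a continuous marker (e.g. SDmax); higher = worse prognosis.
* Dichotomization uses ``score > cutoff`` as the high-risk rule.
* The ROC outcome is the observed event indicator over full follow-up by
  default; a fixed-horizon variant (event observed by ``horizon`` months) is
  available since censoring is otherwise ignored by the ROC — a documented
  limitation, not a bug.
* The maximally-selected log-rank cutpoint search inflates type-I error
  (minimum-p selection); its naive p-value is reported as such and a
  permutation-adjusted p-value is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats
from sklearn.metrics import cohen_kappa_score
from statsmodels.duration.hazard_regression import PHReg

__all__ = [
    "KMEstimate",
    "CoxFit",
    "AUCResult",
    "MaxstatResult",
    "km_estimate",
    "logrank_test",
    "cox_ph",
    "cox_score_test",
    "roc_auc",
    "delong_compare",
    "youden_cutoff",
    "maxstat_cutoff",
    "optimal_cutoff",
    "binary_agreement_kappa",
    "sens_spec",
    "event_by_horizon",
]


# ---------------------------------------------------------------------------
# Kaplan–Meier
# ---------------------------------------------------------------------------

@dataclass
class KMEstimate:
    """Product-limit survival estimate with a plain Greenwood 95% band."""

    times: np.ndarray        # distinct event times, ascending
    survival: np.ndarray     # S(t) just after each event time
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray

    def at(self, t: float) -> float:
        """S(t): right-continuous step-function lookup (S(0) = 1)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(time, event, alpha: float = 0.05) -> KMEstimate:
    """Kaplan–Meier estimator with a Greenwood-variance normal-scale CI.

    The band is clipped to [0, 1]; at S=0 or S=1 the Greenwood variance is 0
    and the band collapses onto the estimate.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise ValueError("at least one record is required")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    # restrict to distinct observed event times
    table = kmf.event_table[kmf.event_table["observed"] > 0]
    times = table.index.to_numpy(dtype=float)
    d = table["observed"].to_numpy(dtype=float)
    n = table["at_risk"].to_numpy(dtype=float)
    surv = np.array([float(kmf.predict(t)) for t in times])
    with np.errstate(divide="ignore", invalid="ignore"):
        greenwood = np.cumsum(np.where(n > d, d / (n * (n - d)), 0.0))
    se = surv * np.sqrt(greenwood)
    z = stats.norm.ppf(1 - alpha / 2)
    return KMEstimate(
        times=times,
        survival=surv,
        ci_lower=np.clip(surv - z * se, 0.0, 1.0),
        ci_upper=np.clip(surv + z * se, 0.0, 1.0),
        n_at_risk=n.astype(int),
        n_events=d.astype(int),
    )


# ---------------------------------------------------------------------------
# Log-rank
# ---------------------------------------------------------------------------

def _logrank_chi2(time: np.ndarray, event: np.ndarray, group: np.ndarray) -> float:
    """Vectorized two-group log-rank chi2 (hypergeometric variance).

    O(n log n): sorts once and accumulates observed-minus-expected and the
    variance over the distinct event times.
    """
    order = np.argsort(time, kind="stable")
    t, e, g = time[order], event[order], group[order]
    n = len(t)
    # at-risk counts just before each distinct time
    uniq, start = np.unique(t, return_index=True)
    n_at_risk = n - start                       # total at risk at each distinct time
    g_cum = np.concatenate([[0], np.cumsum(g)])
    n1_at_risk = g.sum() - g_cum[start]         # group-1 at risk
    # events at each distinct time (total and group 1)
    d_tot = np.add.reduceat(e, start)
    d1 = np.add.reduceat(e * g, start)
    has_event = d_tot > 0
    nn, n1 = n_at_risk[has_event].astype(float), n1_at_risk[has_event].astype(float)
    d = d_tot[has_event].astype(float)
    o_minus_e = float((d1[has_event] - d * n1 / nn).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.where(nn > 1, d * (n1 / nn) * (1 - n1 / nn) * (nn - d) / (nn - 1), 0.0)
    var = float(v.sum())
    if var <= 0:
        return 0.0
    return o_minus_e * o_minus_e / var


def logrank_test(time_a, event_a, time_b, event_b) -> tuple[float, float]:
    """Two-group 1-df log-rank test; returns (chi2, p).

    When neither group has any event the statistic is 0 and p = 1 by
    convention (there is nothing to compare).
    """
    time_a = np.asarray(time_a, dtype=float)
    time_b = np.asarray(time_b, dtype=float)
    event_a = np.asarray(event_a, dtype=int)
    event_b = np.asarray(event_b, dtype=int)
    if time_a.size == 0 or time_b.size == 0:
        raise ValueError("both groups must be non-empty")
    if event_a.sum() == 0 and event_b.sum() == 0:
        return 0.0, 1.0
    chi2 = _logrank_chi2(
        np.concatenate([time_a, time_b]),
        np.concatenate([event_a, event_b]),
        np.concatenate([np.zeros(time_a.size), np.ones(time_b.size)]),
    )
    return chi2, float(stats.chi2.sf(chi2, df=1)) if chi2 > 0 else 1.0


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

@dataclass
class CoxFit:
    """Fitted Cox model: per-covariate HR with Wald 95% CI and p-value."""

    covariates: list[str]
    coef: np.ndarray            # beta-hat
    se: np.ndarray
    hr: np.ndarray              # exp(beta)
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    p: np.ndarray               # two-sided Wald
    log_likelihood: float
    converged: bool
    ties: str

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef, "se": self.se, "hr": self.hr,
                "hr_ci_lower": self.ci_lower, "hr_ci_upper": self.ci_upper,
                "p": self.p,
            },
            index=self.covariates,
        )


def cox_ph(
    df: pd.DataFrame,
    duration_col: str,
    event_col: str,
    covariates: list[str],
    ties: str = "efron",
) -> CoxFit:
    """Fit a Cox PH model by Newton–Raphson partial-likelihood maximization.

    Efron tie handling by default (monthly-scale times produce ties;
    Efron is less biased than Breslow). Monotone likelihood (complete
    separation) is flagged as non-convergence with a warning rather than
    reported silently.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    if df[event_col].sum() == 0:
        raise ValueError("no events: Cox model is not identifiable")
    X = df[covariates].to_numpy(dtype=float)
    if np.unique(X, axis=0).shape[0] < 2:
        raise ValueError("need at least 2 distinct covariate patterns")
    model = PHReg(
        df[duration_col].to_numpy(dtype=float),
        X,
        status=df[event_col].to_numpy(dtype=int),
        ties=ties,
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        res = model.fit(disp=False)
        fit_warned = any("converge" in str(w.message).lower() for w in caught)
    coef = np.asarray(res.params, dtype=float)
    se = np.asarray(res.bse, dtype=float)
    converged = bool(
        np.all(np.isfinite(coef)) and np.all(np.isfinite(se))
        and np.all(np.abs(coef) < 15) and not fit_warned
    )
    if not converged:
        warnings.warn(
            "Cox fit did not converge (possible monotone likelihood / "
            "complete separation); estimates are unreliable",
            stacklevel=2,
        )
    z = coef / se
    with np.errstate(over="ignore"):  # divergent fits overflow exp; already flagged
        hr = np.exp(coef)
        ci_lo = np.exp(coef - 1.96 * se)
        ci_hi = np.exp(coef + 1.96 * se)
    return CoxFit(
        covariates=list(covariates),
        coef=coef,
        se=se,
        hr=hr,
        ci_lower=ci_lo,
        ci_upper=ci_hi,
        p=2 * stats.norm.sf(np.abs(z)),
        log_likelihood=float(res.llf),
        converged=converged,
        ties=ties,
    )


def cox_score_test(time, event, x) -> tuple[float, float]:
    """Cox partial-likelihood score test at beta = 0 for one covariate.

    Returns (chi2, p). On tie-free data with a binary covariate this is
    algebraically identical to the log-rank statistic — used as a
    cross-check between the two routes.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    x = np.asarray(x, dtype=float)
    u = 0.0
    info = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        xr = x[at_risk]
        d = int(((time == t) & (event == 1)).sum())
        sum_x_events = x[(time == t) & (event == 1)].sum()
        xbar = xr.mean()
        u += sum_x_events - d * xbar
        info += d * xr.var()  # population variance over the risk set
    if info <= 0:
        return 0.0, 1.0
    chi2 = u * u / info
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


# ---------------------------------------------------------------------------
# ROC / AUC with DeLong inference
# ---------------------------------------------------------------------------

@dataclass
class AUCResult:
    auc: float
    variance: float
    ci_lower: float
    ci_upper: float
    n_pos: int
    n_neg: int


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    """DeLong structural components V10 (per positive) and V01 (per negative)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    # psi(X, Y) = 1 if X > Y, 0.5 if tie, 0 otherwise
    cmp = (pos[:, None] > neg[None, :]).astype(float)
    cmp += 0.5 * (pos[:, None] == neg[None, :])
    v10 = cmp.mean(axis=1)   # length m
    v01 = cmp.mean(axis=0)   # length n
    return v10, v01


def roc_auc(scores, events, alpha: float = 0.05) -> AUCResult:
    """AUC (Mann–Whitney with ties counted 1/2) and its DeLong variance."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(events, dtype=int)
    v10, v01 = _delong_components(scores, labels)
    auc = float(v10.mean())
    m, n = len(v10), len(v01)
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01, ddof=1) / n if n > 1 else 0.0
    )
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(var)
    return AUCResult(
        auc=auc,
        variance=float(var),
        ci_lower=max(0.0, auc - half),
        ci_upper=min(1.0, auc + half),
        n_pos=m,
        n_neg=n,
    )


def delong_compare(scores_a, scores_b, events) -> tuple[float, float]:
    """Paired DeLong test for the difference of two AUCs on the same patients.

    Returns (z, two-sided p). When the variance of the difference is zero and
    the AUCs coincide (e.g. identical scores) p = 1.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(events, dtype=int)
    if scores_a.shape != scores_b.shape or scores_a.shape != labels.shape:
        raise ValueError("paired scores must share the patients' shape")
    va10, va01 = _delong_components(scores_a, labels)
    vb10, vb01 = _delong_components(scores_b, labels)
    auc_a, auc_b = va10.mean(), vb10.mean()
    m, n = len(va10), len(va01)
    s10 = np.cov(np.vstack([va10, vb10]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([va01, vb01]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var_diff <= 0:
        return 0.0, 1.0 if np.isclose(auc_a, auc_b) else 0.0
    z = float((auc_a - auc_b) / np.sqrt(var_diff))
    return z, float(2 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# Cutoff optimization
# ---------------------------------------------------------------------------

def sens_spec(scores, cutoff: float, events) -> tuple[float, float]:
    """Sensitivity and specificity of the rule score > cutoff for the event."""
    scores = np.asarray(scores, dtype=float)
    events = np.asarray(events, dtype=int)
    pos = events == 1
    neg = ~pos
    se = float((scores[pos] > cutoff).mean()) if pos.any() else float("nan")
    sp = float((scores[neg] <= cutoff).mean()) if neg.any() else float("nan")
    return se, sp


def youden_cutoff(scores, events) -> float:
    """Cutoff maximizing Youden's J = Se + Sp - 1 on the event indicator.

    Candidates are midpoints between consecutive unique scores (plus one
    below the minimum); ties resolve to the lowest cutoff.
    """
    scores = np.asarray(scores, dtype=float)
    events = np.asarray(events, dtype=int)
    uniq = np.unique(scores)
    if uniq.size < 2:
        raise ValueError("degenerate scores: all values equal")
    cands = np.concatenate([[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0])
    best_c, best_j = cands[0], -np.inf
    for c in cands:
        se, sp = sens_spec(scores, c, events)
        j = se + sp - 1
        if j > best_j + 1e-12:
            best_j, best_c = j, c
    return float(best_c)


@dataclass
class MaxstatResult:
    cutoff: float
    chi2: float
    naive_p: float                 # anti-conservative: maximum over cutoffs
    perm_p: float | None = None    # permutation-adjusted, if requested


def maxstat_cutoff(
    scores,
    time,
    event,
    lower_quantile: float = 0.10,
    upper_quantile: float = 0.90,
    n_permutations: int = 0,
    rng: np.random.Generator | int | None = None,
) -> MaxstatResult:
    """Maximally selected log-rank cutpoint (an X-tile-style search).

    Scans the unique score values between the 10th and 90th percentiles and
    keeps the cutoff maximizing the log-rank chi2 of the induced high/low
    split (ties -> lower cutoff). The naive p-value of the maximized chi2 is
    anti-conservative; with ``n_permutations > 0`` a permutation-adjusted
    p-value (scores permuted against (time, event)) is also computed.
    """
    scores = np.asarray(scores, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if np.unique(scores).size < 2:
        raise ValueError("degenerate scores: all values equal")

    def _scan(sc: np.ndarray) -> tuple[float, float]:
        lo, hi = np.quantile(sc, [lower_quantile, upper_quantile])
        cands = np.unique(sc)
        cands = cands[(cands >= lo) & (cands <= hi)]
        best_c, best_chi2 = float("nan"), -np.inf
        for c in cands:
            high = sc > c
            if high.sum() == 0 or (~high).sum() == 0:
                continue
            chi2, _ = logrank_test(time[~high], event[~high], time[high], event[high])
            if chi2 > best_chi2 + 1e-12:
                best_chi2, best_c = chi2, float(c)
        if not np.isfinite(best_chi2):
            raise ValueError("no admissible cutoff splits the cohort")
        return best_c, best_chi2

    cutoff, chi2 = _scan(scores)
    naive_p = float(stats.chi2.sf(chi2, df=1))
    perm_p = None
    if n_permutations > 0:
        rng = np.random.default_rng(rng)
        exceed = 0
        for _ in range(n_permutations):
            _, chi2_perm = _scan(rng.permutation(scores))
            if chi2_perm >= chi2:
                exceed += 1
        perm_p = (exceed + 1) / (n_permutations + 1)
    return MaxstatResult(cutoff=cutoff, chi2=float(chi2), naive_p=naive_p, perm_p=perm_p)


def optimal_cutoff(
    scores,
    time,
    event,
    method: str = "maxstat",
    **kwargs,
) -> float:
    """Optimal dichotomization cutoff by 'youden' (ROC) or 'maxstat' (log-rank)."""
    if len(np.asarray(scores)) < 10:
        raise ValueError("at least 10 records are required for cutoff search")
    if method == "youden":
        return youden_cutoff(scores, event)
    if method == "maxstat":
        return maxstat_cutoff(scores, time, event, **kwargs).cutoff
    raise ValueError(f"unknown cutoff method {method!r}")


# ---------------------------------------------------------------------------
# Agreement and misc
# ---------------------------------------------------------------------------

def binary_agreement_kappa(groups_a, groups_b) -> float:
    """Cohen's kappa between two binary classifications of the same patients."""
    a = np.asarray(groups_a, dtype=int)
    b = np.asarray(groups_b, dtype=int)
    if a.shape != b.shape:
        raise ValueError("classifications must have equal length")
    if np.array_equal(a, b):
        return 1.0
    return float(cohen_kappa_score(a, b))


def event_by_horizon(time, event, horizon_months: float) -> np.ndarray:
    """Fixed-horizon outcome: 1 if an event is observed by the horizon.

    Patients censored before the horizon without an event keep outcome 0;
    this is the simple (not inverse-probability-weighted) variant.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    return ((event == 1) & (time <= horizon_months)).astype(int)
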