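"""Clinical validation statistics: expression categories, Kaplan-Meier,
log-rank, age-adjusted Cox regression, Kruskal-Wallis and Fisher's exact.

Overall survival is measured from initial pathologic diagnosis: subjects
recorded dead contribute days-to-death as an event, subjects alive are
censored at days-to-last-follow-up.  Because the expression distribution
is strongly right-skewed, patients are grouped by absolute expression
cutpoints rather than percentiles — initial categories <=1, >1-5, >5-10
and >10 — and the upper categories are combined into a single
high-expression group (>1) for the survival contrast.

All estimators and tests here are computed from first principles:
product-limit survival curves, the log-rank test with hypergeometric
variance, Cox partial-likelihood Newton-Raphson with Breslow (or Efron)
tie handling, tie-corrected Kruskal-Wallis with small-sample exact
enumeration, and Fisher's exact test by hypergeometric enumeration.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _sps
from scipy.stats import rankdata

from .genotype import InputError

INITIAL_CATEGORIES = ("<=1", ">1-5", ">5-10", ">10-83")
KW_EXACT_N_MAX = 10


class ConvergenceError(RuntimeError):
    """Raised when the Cox partial likelihood cannot be maximized."""


# --------------------------------------------------------------------------
# expression categorization and cohort exclusions
# --------------------------------------------------------------------------

def categorize_expression(expression: float) -> tuple[str, str]:
    """(initial category, binary group) for one expression value.

    Initial categories are <=1, >1-5, >5-10 and >10-83 (the last is
    open-ended above 10); the binary analysis covariate is low (<=1,
    boundary inclusive) versus high (>1).
    """
    if not (np.isfinite(expression) and expression >= 0):
        raise InputError(f"expression must be finite and >= 0, got {expression}")
    if expression <= 1.0:
        return INITIAL_CATEGORIES[0], "low"
    if expression <= 5.0:
        return INITIAL_CATEGORIES[1], "high"
    if expression <= 10.0:
        return INITIAL_CATEGORIES[2], "high"
    return INITIAL_CATEGORIES[3], "high"


def survival_time_event(records: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Extract (time, event) arrays: days-to-death for the dead,
    days-to-last-follow-up (censored) for the living."""
    dead = records["vital_status"].astype(str).str.lower() == "dead"
    time = np.where(dead, records["days_to_death"],
                    records["days_to_last_followup"]).astype(float)
    if np.any(~np.isfinite(time)) or np.any(time < 0):
        raise InputError("every record needs a non-negative survival time")
    return time, dead.to_numpy()


def apply_exclusions(records: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Drop records with follow-up time 0 or pathologic stage 'NA'.

    Returns (analysis cohort, report with counts by reason).
    """
    time, _ = survival_time_event(records)
    zero_fu = time == 0
    stage_na = records["ajcc_stage"].astype(str).isin(["NA", "nan", ""]) \
        | records["ajcc_stage"].isna()
    keep = ~(zero_fu | stage_na)
    report = {
        "n_input": int(len(records)),
        "n_excluded_zero_followup": int(zero_fu.sum()),
        "n_excluded_stage_na": int((stage_na & ~zero_fu).sum()),
        "n_excluded": int((~keep).sum()),
        "n_retained": int(keep.sum()),
    }
    return records[keep].reset_index(drop=True), report


# --------------------------------------------------------------------------
# Kaplan-Meier
# --------------------------------------------------------------------------

@dataclass
class SurvivalCurve:
    """Product-limit estimate for one group."""

    group: str
    table: pd.DataFrame = field(repr=False)  # time, n_at_risk, n_events, survival

    def survival_at(self, t: float) -> float:
        tab = self.table[self.table["time"] <= t]
        return 1.0 if tab.empty else float(tab["survival"].iloc[-1])


def km_estimate(times, events, groups=None) -> dict[str, SurvivalCurve]:
    """Kaplan-Meier product-limit curves, one per group label.

    At tied times, events are processed before censorings (a subject
    censored at t is still at risk for an event at t).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if np.any(times < 0) or np.any(~np.isfinite(times)):
        raise InputError("times must be finite and >= 0")
    if groups is None:
        groups = np.full(times.shape, "all")
    groups = np.asarray(groups)

    curves = {}
    for g in pd.unique(groups):
        sel = groups == g
        if not sel.any():
            raise InputError(f"group {g} is empty")
        t, e = times[sel], events[sel]
        order = np.argsort(t, kind="stable")
        t, e = t[order], e[order]
        n_at_risk = len(t)
        s = 1.0
        rows = []
        for ut in np.unique(t):
            here = t == ut
            d = int(e[here].sum())
            if d > 0:
                s *= 1.0 - d / n_at_risk
                rows.append((float(ut), n_at_risk, d, s))
            n_at_risk -= int(here.sum())
        curves[str(g)] = SurvivalCurve(
            group=str(g),
            table=pd.DataFrame(rows, columns=["time", "n_at_risk", "n_events",
                                              "survival"]),
        )
    return curves


# --------------------------------------------------------------------------
# log-rank test
# --------------------------------------------------------------------------

def logrank_test(times, events, groups) -> tuple[float, float]:
    """Two-group log-rank test: (chi-square statistic df=1, two-sided p).

    At each event time the observed events in group 1 are compared with
    their hypergeometric expectation given the risk sets; the squared
    standardized sum is referred to chi-square with 1 df.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise InputError(f"log-rank needs exactly 2 groups, got {list(labels)}")
    g1 = groups == labels[0]
    if not events.any():
        warnings.warn("no events in either group; log-rank p = 1", stacklevel=2)
        return 0.0, 1.0

    o_minus_e = 0.0
    var = 0.0
    for ut in np.unique(times[events]):
        at_risk = times >= ut
        n = int(at_risk.sum())
        n1 = int((at_risk & g1).sum())
        d = int((events & (times == ut)).sum())
        d1 = int((events & (times == ut) & g1).sum())
        e1 = d * n1 / n
        o_minus_e += d1 - e1
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e ** 2 / var
    return float(chi2), float(_sps.chi2.sf(chi2, 1))


# --------------------------------------------------------------------------
# Cox proportional hazards
# --------------------------------------------------------------------------

@dataclass
class CoxFit:
    coef: pd.Series
    hazard_ratio: pd.Series
    se: pd.Series
    wald_p: pd.Series
    loglik: float
    n_iter: int
    ties: str
    score_test_chi2: float  # global score test evaluated at beta = 0
    score_test_p: float


def _cox_derivatives(beta, times, events, X, ties):
    """Partial log-likelihood, score vector and information matrix."""
    n, p = X.shape
    eta = X @ beta
    w = np.exp(eta)
    order = np.argsort(-times, kind="stable")  # descending time
    ll = 0.0
    score = np.zeros(p)
    info = np.zeros((p, p))
    s0 = 0.0
    s1 = np.zeros(p)
    s2 = np.zeros((p, p))
    i = 0
    while i < n:
        t = times[order[i]]
        block = []
        while i < n and times[order[i]] == t:
            block.append(order[i])
            i += 1
        for j in block:  # everyone at this time enters the risk set
            s0 += w[j]
            s1 += w[j] * X[j]
            s2 += w[j] * np.outer(X[j], X[j])
        ev = [j for j in block if events[j]]
        d = len(ev)
        if d == 0:
            continue
        xsum = X[ev].sum(axis=0)
        ll += float(eta[ev].sum())
        if ties == "breslow" or d == 1:
            ll -= d * math.log(s0)
            score += xsum - d * s1 / s0
            info += d * (s2 / s0 - np.outer(s1 / s0, s1 / s0))
        else:  # efron
            w_ev = w[ev].sum()
            s1_ev = (w[ev, None] * X[ev]).sum(axis=0)
            s2_ev = (w[ev, None, None] * X[ev, :, None] * X[ev, None, :]).sum(axis=0)
            for k in range(d):
                f = k / d
                a0 = s0 - f * w_ev
                a1 = s1 - f * s1_ev
                a2 = s2 - f * s2_ev
                ll -= math.log(a0)
                score += xsum / d - a1 / a0
                info += a2 / a0 - np.outer(a1 / a0, a1 / a0)
    return ll, score, info


def cox_fit(times, events, covariates: pd.DataFrame,
            ties: str = "breslow", max_iter: int = 50,
            tol: float = 1e-8) -> CoxFit:
    """Fit a Cox proportional-hazards model by Newton-Raphson.

    ``covariates`` is an n x p DataFrame (e.g. high-expression indicator
    and age).  Convergence requires max |score| < ``tol``; monotone
    likelihood (complete separation) is reported as a diagnostic error.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    X = covariates.to_numpy(dtype=float)
    if events.sum() < 2:
        raise InputError("Cox regression needs at least 2 events")
    if np.any(~np.isfinite(X)):
        raise InputError("covariates must be finite")
    if ties not in ("breslow", "efron"):
        raise InputError("ties must be 'breslow' or 'efron'")
    names = list(covariates.columns)
    p = X.shape[1]

    # center covariates for numerical stability; slopes are unchanged
    center = X.mean(axis=0)
    Xc = X - center

    beta = np.zeros(p)
    ll0, score0, info0 = _cox_derivatives(beta, times, events, Xc, ties)
    try:
        score_chi2 = float(score0 @ np.linalg.solve(info0, score0))
    except np.linalg.LinAlgError:
        score_chi2 = float("nan")
    ll, score, info = ll0, score0, info0
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        if np.max(np.abs(score)) < tol:
            break
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError("singular information matrix") from exc
        if np.max(np.abs(step)) < 1e-10:  # stalled at float precision
            break
        new_beta = beta + step
        new_ll, new_score, new_info = _cox_derivatives(
            new_beta, times, events, Xc, ties)
        halvings = 0
        while new_ll < ll - 1e-12 and halvings < 30:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_score, new_info = _cox_derivatives(
                new_beta, times, events, Xc, ties)
            halvings += 1
        beta, ll, score, info = new_beta, new_ll, new_score, new_info
        if np.max(np.abs(beta)) > 50:
            raise ConvergenceError(
                "monotone likelihood (complete separation?) — "
                f"coefficients diverging: {dict(zip(names, beta))}")
    else:
        # the gradient of the partial likelihood cannot be driven below
        # float rounding of the log-likelihood sum; accept a stalled score
        # that is merely precision-limited, diagnose anything larger
        if np.max(np.abs(score)) > 1e-6 * max(1.0, abs(ll)):
            raise ConvergenceError(
                f"Newton-Raphson did not converge in {max_iter} iterations "
                f"(max |score| = {np.max(np.abs(score)):.3g})")

    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    wald = beta / se
    return CoxFit(
        coef=pd.Series(beta, index=names),
        hazard_ratio=pd.Series(np.exp(beta), index=names),
        se=pd.Series(se, index=names),
        wald_p=pd.Series(2.0 * _sps.norm.sf(np.abs(wald)), index=names),
        loglik=float(ll),
        n_iter=n_iter,
        ties=ties,
        score_test_chi2=score_chi2,
        score_test_p=float(_sps.chi2.sf(score_chi2, p)),
    )


# --------------------------------------------------------------------------
# Kruskal-Wallis
# --------------------------------------------------------------------------

def _kw_statistic(ranks: np.ndarray, group_idx: list[np.ndarray],
                  tie_factor: float, n: int) -> float:
    h = 0.0
    for idx in group_idx:
        h += ranks[idx].sum() ** 2 / len(idx)
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    return h / tie_factor if tie_factor > 0 else 0.0


def kruskal_wallis(values, labels) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H test: (H, p).

    p comes from chi-square with k-1 df, or from exact enumeration of
    all group assignments when total n <= 10.  If all values are equal
    the statistic is defined as 0 and p = 1.
    """
    values = np.asarray(list(values), dtype=float)
    labels = np.asarray(list(labels))
    uniq = pd.unique(labels)
    if len(uniq) < 2:
        raise InputError("Kruskal-Wallis needs at least 2 groups")
    group_idx = [np.flatnonzero(labels == g) for g in uniq]
    if any(len(idx) == 0 for idx in group_idx):
        raise InputError("every group must be non-empty")
    n = len(values)
    ranks = rankdata(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_factor = 1.0 - float(np.sum(tie_counts ** 3 - tie_counts)) / (n ** 3 - n)
    if tie_factor <= 0:  # all values identical
        return 0.0, 1.0
    h_obs = _kw_statistic(ranks, group_idx, tie_factor, n)
    k = len(uniq)

    if n <= KW_EXACT_N_MAX:
        sizes = [len(idx) for idx in group_idx]
        count = total = 0
        for assignment in _partitions(n, sizes):
            h = _kw_statistic(ranks, assignment, tie_factor, n)
            total += 1
            if h >= h_obs - 1e-9:
                count += 1
        return float(h_obs), count / total
    return float(h_obs), float(_sps.chi2.sf(h_obs, k - 1))


def _partitions(n: int, sizes: list[int]):
    """Yield all ways to split range(n) into ordered groups of the sizes."""
    def rec(remaining: tuple[int, ...], sizes_left: list[int], acc):
        if not sizes_left:
            yield [np.asarray(g) for g in acc]
            return
        if len(sizes_left) == 1:
            yield [np.asarray(g) for g in acc] + [np.asarray(remaining)]
            return
        s = sizes_left[0]
        for combo in itertools.combinations(remaining, s):
            rest = tuple(i for i in remaining if i not in combo)
            yield from rec(rest, sizes_left[1:], acc + [combo])
    yield from rec(tuple(range(n)), sizes, [])


# --------------------------------------------------------------------------
# Fisher's exact test
# --------------------------------------------------------------------------

def fisher_exact(table) -> tuple[float, float]:
    """Fisher's exact test on a 2x2 table: (two-sided p, odds ratio).

    The two-sided p-value sums the hypergeometric probabilities of all
    tables (with the observed margins) no more likely than the observed
    one.  The odds ratio is the sample odds ratio ad/bc.
    """
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise InputError("fisher_exact needs a 2x2 table")
    if np.any(arr < 0) or np.any(arr != np.floor(arr)):
        raise InputError("counts must be non-negative integers")
    a, b = arr[0]
    c, d = arr[1]
    r1, c1, n = a + b, a + c, arr.sum()
    if n == 0:
        return 1.0, float("nan")
    dist = _sps.hypergeom(int(n), int(r1), int(c1))
    k_lo = int(max(0, c1 - (n - r1)))
    k_hi = int(min(r1, c1))
    ks = np.arange(k_lo, k_hi + 1)
    pmf = dist.pmf(ks)
    p_obs = dist.pmf(int(a))
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        odds = (a * d) / (b * c) if b * c > 0 else math.inf if a * d > 0 \
            else float("nan")
    return min(p, 1.0), odds


# --------------------------------------------------------------------------
# stage summaries
# --------------------------------------------------------------------------

_AJCC_COLLAPSE = {
    "I": "I", "IA": "I", "IB": "I",
    "II": "II", "IIA": "II", "IIB": "II",
    "III": "III", "IIIA": "III", "IIIB": "III", "IIIC": "III",
    "IV": "IV",
}
_T_COLLAPSE = {
    "T1": "T1", "T1A": "T1", "T1B": "T1", "T1C": "T1",
    "T2": "T2", "T2B": "T2",
    "T3": "T3",
    "T4": "T4", "T4B": "T4", "T4D": "T4",
}


def collapse_stage(label: str, kind: str = "ajcc") -> str:
    """Collapse stage sub-labels (IA/IB -> I, T1a/b/c -> T1, ...)."""
    s = str(label).upper().replace("STAGE", "").strip()
    table = _AJCC_COLLAPSE if kind == "ajcc" else _T_COLLAPSE
    return table.get(s, "NA")


def stagewise_summary(cohort: pd.DataFrame,
                      expression_col: str = "expression") -> dict:
    """Per-stage expression summaries with a Kruskal-Wallis test.

    For each grouping (AJCC stage and tumor-size T stage) the summary
    reports n, median, quartiles (linear-interpolation convention),
    mean and SD per stage, plus the tie-corrected Kruskal-Wallis p
    across stages.  Records with stage 'NA' are excluded per grouping.
    """
    out = {}
    for kind, col, order in (
        ("ajcc", "ajcc_stage", ["I", "II", "III", "IV"]),
        ("tsize", "t_stage", ["T1", "T2", "T3", "T4"]),
    ):
        stages = cohort[col].map(lambda s: collapse_stage(s, kind))
        keep = stages != "NA"
        sub = cohort[keep]
        st = stages[keep]
        rows = []
        for stage in order:
            vals = sub.loc[st == stage, expression_col]
            if len(vals) == 0:
                continue
            rows.append((
                stage, len(vals), float(vals.median()),
                float(vals.quantile(0.25)), float(vals.quantile(0.75)),
                float(vals.mean()),
                float(vals.std(ddof=1)) if len(vals) > 1 else float("nan"),
            ))
        table = pd.DataFrame(rows, columns=[
            "stage", "n", "median", "q1", "q3", "mean", "sd"])
        present = [s for s in order if (st == s).any()]
        if len(present) >= 2:
            h, p = kruskal_wallis(sub[expression_col], st)
        else:
            h, p = float("nan"), float("nan")
        out[kind] = {"table": table, "kw_h": h, "kw_p": p}
    return out


# --------------------------------------------------------------------------
# cohort-level analysis
# --------------------------------------------------------------------------

def analyze_survival(records: pd.DataFrame, cutpoint: float = 1.0) -> dict:
    """Full clinical analysis of a cohort table.

    Applies exclusions, categorizes expression at the cutpoint, and runs
    Kaplan-Meier + log-rank for low vs high expression, the age-adjusted
    Cox model and the stage-wise summaries.
    """
    cohort, exclusions = apply_exclusions(records)
    group = np.where(cohort["expression"] > cutpoint, "high", "low")
    time, event = survival_time_event(cohort)
    out: dict = {"exclusions": exclusions,
                 "n_high": int((group == "high").sum()),
                 "n_low": int((group == "low").sum())}
    out["km"] = km_estimate(time, event, group)
    chi2, p = logrank_test(time, event, group)
    out["logrank"] = {"chi2": chi2, "p": p}
    covars = pd.DataFrame({
        "high_expression": (group == "high").astype(float),
        "age": cohort["age"].to_numpy(dtype=float),
    })
    fit = cox_fit(time, event, covars)
    out["cox"] = fit
    out["stagewise"] = stagewise_summary(cohort)
    return out
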