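"""RNA in situ hybridization (RNAscope) scoring and rank-based comparison.

Chromogenic ISH yields countable dots per cell.  Specimens are scored
semi-quantitatively on a 0/1/2 scale:

* 0 — no staining or fewer than 1 dot per 10 cells (< 0.1 dots/cell),
* 1 — 1-10 dots per cell with few dot clusters,
* 2 — more than 10 dots per cell AND more than 10% of dots in clusters.

Specimens failing control-probe QC (positive control POLR2 scored 0,
i.e. degraded RNA, or negative control dapB scored 2, i.e. background
failure) are excluded before analysis.  Group comparisons use the
Wilcoxon rank-sum (unpaired) and signed-rank (paired) tests with
mid-ranks for ties, a tie-corrected normal approximation at large n and
exact permutation enumeration at small n.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps
from scipy.stats import rankdata

from .genotype import InputError

EXACT_N_MAX = 12  # total sample size at or below which the null is enumerated


# --------------------------------------------------------------------------
# scoring
# --------------------------------------------------------------------------

def score_specimen(dots_per_cell: float, cluster_fraction: float) -> int:
    """Apply the 0/1/2 dot-count rubric to one specimen.

    Score 2 requires both >10 dots/cell and >10% of dots in clusters;
    specimens above 10 dots/cell without the clustering are scored 1
    (the conservative reading of the rubric).
    """
    if not (np.isfinite(dots_per_cell) and dots_per_cell >= 0):
        raise InputError(f"dots_per_cell must be finite and >= 0, got {dots_per_cell}")
    if not (np.isfinite(cluster_fraction) and 0.0 <= cluster_fraction <= 1.0):
        raise InputError(
            f"cluster_fraction must lie in [0, 1], got {cluster_fraction}")
    if dots_per_cell < 0.1:
        return 0
    if dots_per_cell > 10.0 and cluster_fraction > 0.10:
        return 2
    return 1


ADJUDICATE = -1  # sentinel for two-observer disagreement of 2 levels


def consensus_score(observer_a: int, observer_b: int) -> int:
    """Combine two independent observer scores.

    Equal scores stand; a one-level disagreement takes the lower
    (conservative) score; a two-level disagreement is flagged for
    adjudication (returns the ADJUDICATE sentinel) and the specimen is
    excluded from analysis.
    """
    for s in (observer_a, observer_b):
        if s not in (0, 1, 2):
            raise InputError(f"observer score must be 0, 1 or 2, got {s!r}")
    gap = abs(observer_a - observer_b)
    if gap == 2:
        return ADJUDICATE
    return min(observer_a, observer_b)


def qc_filter(specimens: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Exclude specimens failing control-probe QC.

    POLR2 (positive control) scored 0 indicates RNA degradation; dapB
    (negative control) scored 2 indicates background failure.  Returns
    (retained table, report with counts by reason).
    """
    for col in ("polr2_score", "dapb_score"):
        if col not in specimens.columns:
            raise InputError(f"specimen table is missing control column {col}")
        if specimens[col].isna().any():
            raise InputError(f"missing {col} for some specimens")
    degraded = specimens["polr2_score"] == 0
    background = specimens["dapb_score"] == 2
    retained = specimens[~(degraded | background)].reset_index(drop=True)
    report = {
        "n_input": int(len(specimens)),
        "n_excluded_degraded": int(degraded.sum()),
        "n_excluded_background": int((background & ~degraded).sum()),
        "n_retained": int(len(retained)),
    }
    return retained, report


def positivity_rate(scores) -> tuple[int, int, int]:
    """(n_positive, n_total, percent) of specimens with score >= 1.

    The percent is rounded to the nearest integer, matching how such
    rates are conventionally reported.
    """
    scores = list(scores)
    if not scores:
        raise InputError("positivity_rate needs a non-empty score list")
    n_pos = sum(1 for s in scores if s >= 1)
    n_tot = len(scores)
    return n_pos, n_tot, int(round(100.0 * n_pos / n_tot))


def score_table(specimens: pd.DataFrame) -> pd.DataFrame:
    """Score a specimen table, using two-observer consensus when present.

    Adds a ``score`` column; adjudication-flagged specimens are dropped.
    """
    df = specimens.copy()
    if {"obs_a", "obs_b"}.issubset(df.columns):
        df["score"] = [consensus_score(int(a), int(b))
                       for a, b in zip(df["obs_a"], df["obs_b"])]
        df = df[df["score"] != ADJUDICATE].reset_index(drop=True)
    else:
        df["score"] = [score_specimen(d, c) for d, c in
                       zip(df["dots_per_cell"], df["cluster_fraction"])]
    return df


# --------------------------------------------------------------------------
# rank tests
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RankTestResult:
    statistic: float
    p: float
    method: str
    n1: int | None = None
    n2: int | None = None
    n_pairs: int | None = None


def rank_sum_test(scores_a, scores_b) -> RankTestResult:
    """Two-sample Wilcoxon rank-sum test with mid-ranks for ties.

    The statistic is the rank sum W of the first group.  For total
    n <= 12 the two-sided p-value is computed exactly by enumerating all
    group assignments of the pooled values; otherwise a tie-corrected
    normal approximation with continuity correction is used.
    """
    a = np.asarray(list(scores_a), dtype=float)
    b = np.asarray(list(scores_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise InputError("both groups must be non-empty")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    w = float(ranks[:n1].sum())
    mean_w = n1 * (n1 + n2 + 1) / 2.0

    if n1 + n2 <= EXACT_N_MAX:
        dev = abs(w - mean_w)
        count = total = 0
        for combo in itertools.combinations(range(n1 + n2), n1):
            ws = ranks[list(combo)].sum()
            total += 1
            if abs(ws - mean_w) >= dev - 1e-9:
                count += 1
        return RankTestResult(w, count / total, "exact_permutation", n1=n1, n2=n2)

    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts)) / (n * (n - 1))
    var_w = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var_w == 0:
        return RankTestResult(w, 1.0, "rank_sum_normal_tie_corrected", n1=n1, n2=n2)
    z = (abs(w - mean_w) - 0.5) / math.sqrt(var_w)
    p = min(1.0, 2.0 * _sps.norm.sf(max(z, 0.0)))
    return RankTestResult(w, p, "rank_sum_normal_tie_corrected", n1=n1, n2=n2)


def signed_rank_test(differences, drop_zeros: bool = True) -> RankTestResult:
    """Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped (classical treatment); mid-ranks are
    used on |d|.  With at most 12 nonzero pairs the null is enumerated
    exactly over all 2^m sign assignments; otherwise a tie-corrected
    normal approximation with continuity correction is used.
    """
    d = np.asarray(list(differences), dtype=float)
    if drop_zeros:
        d = d[d != 0]
    if d.size == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return RankTestResult(0.0, 1.0, "signed_rank_degenerate", n_pairs=0)
    m = d.size
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mean_w = ranks.sum() / 2.0

    if m <= EXACT_N_MAX:
        dev = abs(w_plus - mean_w)
        count = 0
        for signs in itertools.product((0, 1), repeat=m):
            ws = float(np.dot(signs, ranks))
            if abs(ws - mean_w) >= dev - 1e-9:
                count += 1
        return RankTestResult(w_plus, count / 2 ** m, "exact_permutation",
                              n_pairs=m)

    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    var_w = (m * (m + 1) * (2 * m + 1)
             - 0.5 * float(np.sum(tie_counts ** 3 - tie_counts))) / 24.0
    if var_w == 0:
        return RankTestResult(w_plus, 1.0, "signed_rank_normal", n_pairs=m)
    z = (abs(w_plus - mean_w) - 0.5) / math.sqrt(var_w)
    p = min(1.0, 2.0 * _sps.norm.sf(max(z, 0.0)))
    return RankTestResult(w_plus, p, "signed_rank_normal", n_pairs=m)


# --------------------------------------------------------------------------
# cohort-level summary
# --------------------------------------------------------------------------

def analyze_ish(specimens: pd.DataFrame) -> dict:
    """Score, QC-filter and compare an ISH specimen table.

    Returns a summary with positivity by group, the unpaired tumor vs
    normal rank-sum test and, when matched pairs exist, the paired
    signed-rank test.
    """
    retained, qc_report = qc_filter(specimens)
    scored = score_table(retained)
    tumor = scored[scored["group"] == "tumor"]
    normal = scored[scored["group"] == "normal"]
    out: dict = {"qc": qc_report}
    for name, grp in (("tumor", tumor), ("normal", normal)):
        if len(grp):
            n_pos, n_tot, pct = positivity_rate(grp["score"])
            out[f"{name}_positivity"] = {
                "n_positive": n_pos, "n_total": n_tot, "percent": pct}
    if len(tumor) and len(normal):
        res = rank_sum_test(tumor["score"], normal["score"])
        out["rank_sum"] = res.__dict__
    paired = scored[scored["pair_id"].astype(str).str.len() > 0] \
        if "pair_id" in scored.columns else scored.iloc[0:0]
    if len(paired):
        wide = paired.pivot_table(index="pair_id", columns="group",
                                  values="score", aggfunc="first")
        wide = wide.dropna()
        if {"tumor", "normal"}.issubset(wide.columns) and len(wide):
            res = signed_rank_test(wide["tumor"] - wide["normal"])
            out["signed_rank"] = res.__dict__
    return out
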