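"""Concordance between two knockdown treatments' expression responses.

Two shRNA constructs targeting the same transcript should perturb an
overlapping set of downstream genes with correlated fold changes; strong
concordance argues against off-target effects.  Given per-gene log2 fold
changes and p-values for each treatment versus a common control, this
module filters to significant genes (p < 0.001 by default), counts the
overlap, rank-correlates the overlapping genes' fold changes (Spearman's
rho, with rho^2 reported alongside since squared correlations are the
convention for such concordance plots) and computes pathway-set overlap
percentages.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats as _sps
from scipy.stats import rankdata

from .genotype import InputError

SPEARMAN_EXACT_N_MAX = 8


def de_filter(stats: pd.DataFrame, p_max: float = 0.001) -> set[str]:
    """Genes with p strictly below p_max."""
    if not {"gene_id", "p"}.issubset(stats.columns):
        raise InputError("gene stats need columns gene_id and p")
    return set(stats.loc[stats["p"] < p_max, "gene_id"])


def overlap_sets(set_a, set_b) -> tuple[int, float, float, float]:
    """(n_overlap, pct of A, pct of B, min pct) for two identifier sets."""
    a, b = set(set_a), set(set_b)
    if not a or not b:
        raise InputError("overlap percentage undefined for an empty set")
    n = len(a & b)
    pct_a = 100.0 * n / len(a)
    pct_b = 100.0 * n / len(b)
    return n, pct_a, pct_b, min(pct_a, pct_b)


def spearman_rho(x, y) -> tuple[float, float, float]:
    """Spearman rank correlation: (rho, rho^2, two-sided p).

    Computed as the Pearson correlation of mid-ranks (handles ties).
    The p-value uses the t approximation with n-2 df, or exact
    permutation enumeration when n <= 8.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size != y.size or x.size < 3:
        raise InputError("spearman_rho needs >= 3 paired values")
    rx, ry = rankdata(x), rankdata(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        raise InputError("correlation undefined for a constant vector")

    def pearson(u, v):
        u = u - u.mean()
        v = v - v.mean()
        return float(u @ v / math.sqrt((u @ u) * (v @ v)))

    rho = pearson(rx, ry)
    n = x.size
    if n <= SPEARMAN_EXACT_N_MAX:
        count = total = 0
        for perm in itertools.permutations(range(n)):
            r = pearson(rx, ry[list(perm)])
            total += 1
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
        return rho, rho * rho, count / total
    if abs(rho) >= 1.0:
        return rho, rho * rho, 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * _sps.t.sf(abs(t), n - 2)
    return rho, rho * rho, p


@dataclass
class ConcordanceReport:
    n_sig_a: int
    n_sig_b: int
    n_overlap: int
    spearman_rho: float
    spearman_rho2: float
    spearman_p: float
    pathway_overlap: dict | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def concordance_report(
    stats_a: pd.DataFrame,
    stats_b: pd.DataFrame,
    p_max: float = 0.001,
    pathways_a=None,
    pathways_b=None,
) -> tuple[ConcordanceReport, pd.DataFrame]:
    """Full concordance analysis of two treatments against a common control.

    Returns the report plus a table of overlapping significant genes with
    both log2 fold changes.
    """
    sig_a = de_filter(stats_a, p_max)
    sig_b = de_filter(stats_b, p_max)
    shared = sorted(sig_a & sig_b)
    lfc_a = stats_a.set_index("gene_id")["log2fc"]
    lfc_b = stats_b.set_index("gene_id")["log2fc"]
    overlap_table = pd.DataFrame({
        "gene_id": shared,
        "log2fc_a": lfc_a.reindex(shared).to_numpy(),
        "log2fc_b": lfc_b.reindex(shared).to_numpy(),
    })
    if len(shared) >= 3:
        rho, rho2, p = spearman_rho(overlap_table["log2fc_a"],
                                    overlap_table["log2fc_b"])
    else:
        rho = rho2 = p = float("nan")
    pathway = None
    if pathways_a is not None and pathways_b is not None:
        n, pa, pb, mn = overlap_sets(pathways_a, pathways_b)
        pathway = {"n_overlap": n, "pct_of_a": pa, "pct_of_b": pb,
                   "min_pct": mn}
    report = ConcordanceReport(
        n_sig_a=len(sig_a), n_sig_b=len(sig_b), n_overlap=len(shared),
        spearman_rho=rho, spearman_rho2=rho2, spearman_p=p,
        pathway_overlap=pathway,
    )
    return report, overlap_table
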