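"""Paired differential expression with an empirical-Bayes moderated t-test.

For each marker the per-pair difference ``d_i = log2(tumor) - log2(normal)``
is summarized by its mean (the log2 fold change) and sample variance s^2.
The marker-wise variances are shrunk toward a common prior: under the
hierarchical model

    s^2 | sigma^2  ~  sigma^2 * chi^2_df / df,
    1 / sigma^2    ~  (1 / (d0 * s0^2)) * chi^2_d0 / d0,

the marginal distribution of s^2 is a scaled F, and the hyperparameters
(d0, s0^2) are estimated by matching the mean and variance of log s^2
through digamma/trigamma moment equations.  The posterior variance

    s~^2 = (d0 * s0^2 + df * s^2) / (d0 + df)

yields the moderated t statistic ``t = log2FC / sqrt(s~^2 / n)`` with
``d0 + df`` degrees of freedom.  d0 = 0 recovers the ordinary paired t;
d0 = infinity pools all variance information (normal reference).

Candidate markers pass the joint filter p < 0.005, FDR < 0.15 and
|log2FC| > 1 (all strict), and are then aggregated to intergenic loci by
genomic containment; a locus whose passing markers disagree in sign is
flagged discordant and excluded from the up/down tallies.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import special, stats

from .genotype import ExpressionMatrix, InputError


# --------------------------------------------------------------------------
# paired design
# --------------------------------------------------------------------------

def make_design(pairs: pd.DataFrame) -> pd.DataFrame:
    """Build a paired design (normal_sample, tumor_sample, pair_id) table."""
    design = pairs[["normal_sample", "tumor_sample", "pair_id"]].copy()
    validate_design(design)
    return design


def validate_design(design: pd.DataFrame) -> None:
    required = {"normal_sample", "tumor_sample", "pair_id"}
    if not required.issubset(design.columns):
        raise InputError(f"design must have columns {sorted(required)}")
    samples = pd.concat([design["normal_sample"], design["tumor_sample"]])
    if samples.duplicated().any():
        dup = samples[samples.duplicated()].iloc[0]
        raise InputError(f"sample {dup} appears more than once in the design")
    if len(design) < 2:
        raise InputError("a paired analysis needs at least 2 pairs")


# --------------------------------------------------------------------------
# per-marker paired statistics
# --------------------------------------------------------------------------

def paired_differences(expr: ExpressionMatrix | pd.DataFrame,
                       design: pd.DataFrame) -> pd.DataFrame:
    """Markers x pairs matrix of per-pair log2 differences (tumor - normal)."""
    validate_design(design)
    v = expr.values if isinstance(expr, ExpressionMatrix) else expr
    missing = [s for s in pd.concat([design["normal_sample"],
                                     design["tumor_sample"]])
               if s not in v.columns]
    if missing:
        raise InputError(f"design samples absent from expression matrix: {missing}")
    d = {row["pair_id"]: v[row["tumor_sample"]] - v[row["normal_sample"]]
         for _, row in design.iterrows()}
    return pd.DataFrame(d, index=v.index)


def paired_stats(expr: ExpressionMatrix | pd.DataFrame,
                 design: pd.DataFrame) -> pd.DataFrame:
    """Per-marker paired summary: log2FC (mean difference), s2, n.

    Markers lose only the pairs in which either member is missing
    (complete-pairs analysis); markers left with fewer than 2 complete
    pairs are dropped with a warning.
    """
    d = paired_differences(expr, design)
    arr = d.to_numpy(dtype=float)
    n = np.sum(np.isfinite(arr), axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        lfc = np.nanmean(arr, axis=1)
        s2 = np.nanvar(arr, axis=1, ddof=1)
    out = pd.DataFrame({"log2fc": lfc, "s2": s2, "n": n}, index=d.index)
    dropped = out.index[n < 2]
    if len(dropped):
        warnings.warn(
            f"dropping {len(dropped)} markers with <2 complete pairs",
            stacklevel=2,
        )
        out = out.drop(index=dropped)
    return out


# --------------------------------------------------------------------------
# empirical-Bayes prior
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class EBayesPrior:
    """Hyperparameters of the inverse-chi-square variance prior."""

    d0: float     # prior degrees of freedom; math.inf allowed
    s0_2: float   # prior variance


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(75):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_prior(s2: np.ndarray, df: float | np.ndarray) -> EBayesPrior:
    """Estimate (d0, s0^2) by moment matching on log s^2.

    Under the scaled-F marginal, E[log s^2] and Var[log s^2] are linear in
    digamma/trigamma terms of df/2 and d0/2; the trigamma equation is
    inverted numerically.  When the observed dispersion of log s^2 does not
    exceed what sampling alone (df) explains, d0 is infinite and s0^2 is
    the bias-corrected geometric mean of s^2.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    pos = s2 > 0
    if not pos.any():
        raise InputError(
            "all marker variances are zero; check that noise is simulated "
            "or that replicate arrays are not duplicated"
        )
    if pos.sum() < 10:
        raise InputError("need >= 10 markers with positive s2 to fit the prior")
    z = np.log(s2[pos])
    dfp = df[pos]
    # center each log s2 by its sampling-expectation offset digamma(df/2)-log(df/2)
    e_offset = special.digamma(dfp / 2.0) - np.log(dfp / 2.0)
    z_centered = z - e_offset
    mean_z = float(np.mean(z_centered))
    var_z = float(np.var(z_centered, ddof=1))
    excess = var_z - float(np.mean(special.polygamma(1, dfp / 2.0)))
    if excess <= 0:
        return EBayesPrior(d0=math.inf, s0_2=float(np.exp(mean_z)))
    d0 = 2.0 * _trigamma_inverse(excess)
    log_s0_2 = mean_z + special.digamma(d0 / 2.0) - math.log(d0 / 2.0)
    return EBayesPrior(d0=float(d0), s0_2=float(np.exp(log_s0_2)))


# --------------------------------------------------------------------------
# moderated t
# --------------------------------------------------------------------------

def moderated_t(stats_df: pd.DataFrame, prior: EBayesPrior) -> pd.DataFrame:
    """Moderated t statistics and two-sided p-values for paired_stats output.

    Adds columns s2_post, df_total, t_mod, p.  d0 = 0 gives the classical
    paired t; d0 = infinity gives a z-test against the pooled prior
    variance.
    """
    lfc = stats_df["log2fc"].to_numpy(dtype=float)
    s2 = stats_df["s2"].to_numpy(dtype=float)
    n = stats_df["n"].to_numpy(dtype=float)
    df = n - 1.0
    d0, s0_2 = prior.d0, prior.s0_2
    if math.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = np.full_like(s2, np.inf)
    else:
        s2_post = (d0 * s0_2 + df * s2) / (d0 + df)
        df_total = d0 + df

    out = stats_df.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(s2_post / n)
        t = lfc / se
    degenerate = s2_post == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} markers have zero posterior variance; "
            "their p-values are set to 0", stacklevel=2,
        )
        t[degenerate] = np.sign(lfc[degenerate]) * np.inf
    if math.isinf(d0):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p[degenerate] = 0.0
    out["s2_post"] = s2_post
    out["df_total"] = df_total
    out["t_mod"] = t
    out["p"] = p
    return out


# --------------------------------------------------------------------------
# Benjamini-Hochberg
# --------------------------------------------------------------------------

def bh_adjust(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    arr = np.asarray(p, dtype=float)
    if arr.ndim != 1:
        raise InputError("p must be one-dimensional")
    if np.any(~np.isfinite(arr)) or np.any(arr < 0) or np.any(arr > 1):
        raise InputError("p-values must lie in [0, 1]")
    m = arr.size
    order = np.argsort(arr, kind="stable")
    ranked = arr[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


# --------------------------------------------------------------------------
# candidate filter and locus aggregation
# --------------------------------------------------------------------------

def select_candidates(
    results: pd.DataFrame,
    p_max: float = 0.005,
    fdr_max: float = 0.15,
    min_abs_log2fc: float = 1.0,
) -> pd.DataFrame:
    """Markers passing p < p_max, fdr < fdr_max, |log2FC| > min_abs_log2fc.

    All three inequalities are strict; boundary values are rejected.
    """
    keep = (
        (results["p"] < p_max)
        & (results["fdr"] < fdr_max)
        & (results["log2fc"].abs() > min_abs_log2fc)
    )
    return results[keep]


class AmbiguousLocusError(InputError):
    """A marker falls inside more than one annotated locus."""


def map_markers_to_loci(marker_map: pd.DataFrame,
                        loci: pd.DataFrame) -> pd.Series:
    """Map each marker to the locus containing it (half-open intervals).

    Marker positions are 1-based; locus intervals are BED 0-based
    half-open, so marker pos p lies in [start, end) iff start < p <= end.
    Markers outside every locus map to NA; a marker inside two loci raises.
    """
    trees: dict[str, IntervalTree] = {}
    for _, row in loci.iterrows():
        trees.setdefault(row["chrom"], IntervalTree()).addi(
            int(row["start"]), int(row["end"]), row["locus_id"])
    assigned = {}
    for _, row in marker_map.iterrows():
        tree = trees.get(row["chrom"])
        hits = sorted(iv.data for iv in tree.at(int(row["pos"]) - 1)) if tree else []
        if len(hits) > 1:
            raise AmbiguousLocusError(
                f"marker {row['marker_id']} maps to overlapping loci: {hits}")
        assigned[row["marker_id"]] = hits[0] if hits else pd.NA
    return pd.Series(assigned, name="locus_id")


def aggregate_to_loci(
    candidates: pd.DataFrame,
    marker_map: pd.DataFrame,
    loci: pd.DataFrame,
) -> tuple[pd.DataFrame, dict]:
    """Roll passing markers up to locus calls with direction and support.

    Returns (locus table, summary).  The locus table has one row per locus
    with at least one passing marker: direction in {up, down, discordant},
    supporting-marker count and the member list.  Discordant loci (passing
    markers of both signs) are excluded from the up/down tallies.
    """
    locus_of = map_markers_to_loci(marker_map, loci)
    rows = []
    cand = candidates.copy()
    cand["locus_id"] = locus_of.reindex(cand.index)
    for locus_id, grp in cand.dropna(subset=["locus_id"]).groupby("locus_id"):
        signs = set(np.sign(grp["log2fc"]))
        direction = "up" if signs == {1.0} else "down" if signs == {-1.0} \
            else "discordant"
        rows.append((locus_id, direction, len(grp), sorted(grp.index)))
    table = pd.DataFrame(
        rows, columns=["locus_id", "direction", "n_markers_support", "markers"]
    )
    summary = {
        "n_up_loci": int((table["direction"] == "up").sum()),
        "n_up_markers": int(table.loc[table["direction"] == "up",
                                      "n_markers_support"].sum()),
        "n_down_loci": int((table["direction"] == "down").sum()),
        "n_down_markers": int(table.loc[table["direction"] == "down",
                                        "n_markers_support"].sum()),
        "n_discordant_loci": int((table["direction"] == "discordant").sum()),
        "n_candidate_markers": int(len(cand)),
        "n_candidate_markers_outside_loci":
            int(cand["locus_id"].isna().sum()),
    }
    return table, summary


# --------------------------------------------------------------------------
# one-call pipeline
# --------------------------------------------------------------------------

def run_de(
    expr: ExpressionMatrix | pd.DataFrame,
    design: pd.DataFrame,
    p_max: float = 0.005,
    fdr_max: float = 0.15,
    min_abs_log2fc: float = 1.0,
) -> pd.DataFrame:
    """Full marker-level analysis: paired stats, EB moderation, BH FDR."""
    st = paired_stats(expr, design)
    prior = estimate_prior(st["s2"].to_numpy(), st["n"].to_numpy() - 1.0)
    res = moderated_t(st, prior)
    res["fdr"] = bh_adjust(res["p"].to_numpy())
    res.attrs["prior"] = prior
    return res
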