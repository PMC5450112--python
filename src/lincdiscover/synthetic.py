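"""Synthetic cohort generators with known ground truth.

Every downstream stage of the pipeline (genotype calling, expression
quantification, paired differential expression, ISH scoring, survival
analysis, knockdown concordance) can be exercised on data produced here,
with the planted truth returned alongside so that recovery can be measured.

The array generator emulates a paired tumor/normal two-channel SNP-array
experiment: one germline gDNA hybridization per subject, one ds-cDNA
hybridization per sample (normal and tumor of each pair) plus technical
replicates for designated samples.  Genotypes are drawn under
Hardy-Weinberg equilibrium at each marker's minor-allele frequency; gDNA
channel intensities cluster by genotype (AA high-X/low-Y, AB balanced,
BB low-X/high-Y); cDNA total intensity is proportional to the expression
level of the containing locus and is split across the X/Y channels by the
genotype's allele balance.  Noise is multiplicative log-normal per channel,
parameterized by a coefficient of variation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats


class ConfigError(ValueError):
    """Raised when a simulation configuration is invalid."""


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SimConfig:
    """Parameters of the paired-cohort array simulation.

    Defaults mirror the design of the motivating experiment: seven
    tumor/normal pairs plus two technical replicates, with two pairs
    degraded so that they fail genotyping QC.
    """

    n_pairs: int = 7
    n_tech_replicates: int = 2
    n_markers: int = 400
    n_loci: int = 60
    markers_per_locus: tuple[int, int] = (1, 3)
    frac_true_up: float = 0.10
    frac_true_down: float = 0.10
    planted_log2fc: float = 2.0
    intensity_scale: float = 1000.0
    noise_cv: float = 0.15
    maf_range: tuple[float, float] = (0.10, 0.50)
    seed: int = 0
    # pairs whose gDNA is partially degraded, and the marker call rate
    # degradation leaves them with
    n_degraded_pairs: int = 2
    degraded_call_rate: float = 0.80

    def validate(self) -> None:
        counts = {
            "n_pairs": self.n_pairs,
            "n_markers": self.n_markers,
            "n_loci": self.n_loci,
        }
        for name, v in counts.items():
            if not (isinstance(v, (int, np.integer)) and v >= 1):
                raise ConfigError(f"{name} must be a count >= 1, got {v!r}")
        if self.n_tech_replicates < 0:
            raise ConfigError("n_tech_replicates must be >= 0")
        if self.n_degraded_pairs < 0 or self.n_degraded_pairs > self.n_pairs:
            raise ConfigError("n_degraded_pairs must be in [0, n_pairs]")
        for name in ("frac_true_up", "frac_true_down", "degraded_call_rate"):
            v = getattr(self, name)
            if not (np.isfinite(v) and 0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be a proportion in [0, 1]")
        if self.frac_true_up + self.frac_true_down > 1.0:
            raise ConfigError("frac_true_up + frac_true_down must be <= 1")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigError("maf_range must be contained in (0, 0.5]")
        mlo, mhi = self.markers_per_locus
        if not (1 <= mlo <= mhi):
            raise ConfigError("markers_per_locus must satisfy 1 <= lo <= hi")
        for name in ("planted_log2fc", "intensity_scale", "noise_cv"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ConfigError(f"{name} must be finite, got {v!r}")
        if self.intensity_scale <= 0:
            raise ConfigError("intensity_scale must be positive")
        if self.noise_cv < 0:
            raise ConfigError("noise_cv must be >= 0")


@dataclass
class CohortData:
    """Bundle of all simulated pipeline inputs plus the planted truth."""

    gdna: pd.DataFrame          # marker_id + <subject>.X / <subject>.Y
    cdna: pd.DataFrame          # marker_id + <sample>.X / <sample>.Y
    marker_map: pd.DataFrame    # marker_id, chrom, pos (1-based)
    loci: pd.DataFrame          # chrom, start, end, locus_id (BED, 0-based)
    truth: pd.DataFrame         # locus_id, direction, true_log2fc
    pairs: pd.DataFrame         # pair_id, subject_id, normal_sample, tumor_sample
    config: SimConfig

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.gdna.to_csv(outdir / "gdna.tsv", sep="\t", index=False)
        self.cdna.to_csv(outdir / "cdna.tsv", sep="\t", index=False)
        self.marker_map.to_csv(outdir / "markers.tsv", sep="\t", index=False)
        self.loci.to_csv(outdir / "loci.bed", sep="\t", index=False, header=False)
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        self.pairs.to_csv(outdir / "pairs.tsv", sep="\t", index=False)


def _lognormal_noise(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Multiplicative noise factors with unit mean and the given CV."""
    if cv == 0:
        return np.ones(shape)
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=shape)


# --------------------------------------------------------------------------
# paired-cohort array simulation
# --------------------------------------------------------------------------

def simulate_cohort(config: SimConfig) -> CohortData:
    """Simulate gDNA and ds-cDNA two-channel intensities for a paired cohort.

    Returns intensity tables, the marker map, the locus annotation (BED)
    and the per-locus ground truth (direction and true log2 fold change).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    # --- genome layout: loci with their markers, plus inter-locus markers
    mlo, mhi = config.markers_per_locus
    per_locus = rng.integers(mlo, mhi + 1, size=config.n_loci)
    if per_locus.sum() > config.n_markers:
        raise ConfigError(
            f"n_markers={config.n_markers} too small for "
            f"{per_locus.sum()} locus markers; increase n_markers"
        )
    n_outside = config.n_markers - int(per_locus.sum())

    marker_rows = []   # (marker_id, chrom, pos 1-based, locus_idx or -1)
    locus_rows = []    # (chrom, start, end, locus_id) 0-based half-open
    pos = 10_000       # running 0-based coordinate
    gap = 5_000
    for j in range(config.n_loci):
        m = int(per_locus[j])
        start = pos
        end = start + 1_000 * m
        locus_rows.append(("chr1", start, end, f"LOC{j + 1:04d}"))
        offsets = np.sort(rng.choice(np.arange(end - start), size=m, replace=False))
        for k, off in enumerate(offsets):
            marker_rows.append((None, "chr1", start + int(off) + 1, j))
        pos = end + gap
    for k in range(n_outside):
        marker_rows.append((None, "chr1", pos + 1, -1))
        pos += gap
    # stable marker ids in genome order
    marker_rows.sort(key=lambda r: r[2])
    marker_rows = [
        (f"rsS{i + 1:06d}", chrom, p, j)
        for i, (_, chrom, p, j) in enumerate(marker_rows)
    ]
    marker_map = pd.DataFrame(
        [(m, c, p) for m, c, p, _ in marker_rows],
        columns=["marker_id", "chrom", "pos"],
    )
    loci = pd.DataFrame(locus_rows, columns=["chrom", "start", "end", "locus_id"])
    locus_of_marker = np.array([j for _, _, _, j in marker_rows])

    # --- planted truth
    n_up = int(round(config.frac_true_up * config.n_loci))
    n_down = int(round(config.frac_true_down * config.n_loci))
    order = rng.permutation(config.n_loci)
    direction = np.full(config.n_loci, "null", dtype=object)
    direction[order[:n_up]] = "up"
    direction[order[n_up:n_up + n_down]] = "down"
    true_lfc = np.where(
        direction == "up", config.planted_log2fc,
        np.where(direction == "down", -config.planted_log2fc, 0.0),
    )
    truth = pd.DataFrame({
        "locus_id": loci["locus_id"],
        "direction": direction,
        "true_log2fc": true_lfc,
    })

    # --- cohort structure
    subjects = [f"S{i + 1}" for i in range(config.n_pairs)]
    pairs = pd.DataFrame({
        "pair_id": [f"P{i + 1}" for i in range(config.n_pairs)],
        "subject_id": subjects,
        "normal_sample": [f"{s}_N" for s in subjects],
        "tumor_sample": [f"{s}_T" for s in subjects],
    })
    degraded_subjects = set(subjects[: config.n_degraded_pairs])

    # --- genotypes under Hardy-Weinberg (B-allele count per subject)
    maf = rng.uniform(*config.maf_range, size=config.n_markers)
    nb = rng.binomial(2, maf[:, None], size=(config.n_markers, config.n_pairs))

    # --- per-marker expression levels (right-skewed), shared within a locus
    locus_expr = rng.lognormal(
        mean=math.log(config.intensity_scale), sigma=0.5, size=config.n_loci
    )
    outside_expr = rng.lognormal(
        mean=math.log(config.intensity_scale), sigma=0.5, size=config.n_markers
    )
    base_expr = np.where(locus_of_marker >= 0,
                         locus_expr[np.clip(locus_of_marker, 0, None)],
                         outside_expr)
    marker_lfc = np.where(locus_of_marker >= 0,
                          true_lfc[np.clip(locus_of_marker, 0, None)], 0.0)
    tumor_expr = base_expr * np.exp2(marker_lfc)

    # --- gDNA intensities: genotype clusters + noise
    bg = 0.02 * config.intensity_scale
    scale = config.intensity_scale
    gdna_cols: dict[str, np.ndarray] = {"marker_id": marker_map["marker_id"]}
    for i, subj in enumerate(subjects):
        g = nb[:, i]
        x = np.where(g == 0, scale, np.where(g == 1, scale / 2, bg)).astype(float)
        y = np.where(g == 2, scale, np.where(g == 1, scale / 2, bg)).astype(float)
        x = x * _lognormal_noise(rng, config.noise_cv, config.n_markers)
        y = y * _lognormal_noise(rng, config.noise_cv, config.n_markers)
        if subj in degraded_subjects:
            n_fail = int(round((1 - config.degraded_call_rate) * config.n_markers))
            fail = rng.choice(config.n_markers, size=n_fail, replace=False)
            x[fail] = 0.0
            y[fail] = 0.0
        gdna_cols[f"{subj}.X"] = x
        gdna_cols[f"{subj}.Y"] = y
    gdna = pd.DataFrame(gdna_cols)

    # --- ds-cDNA intensities: total tracks expression, split by allele balance
    def cdna_channels(total: np.ndarray, g: np.ndarray):
        frac_x = np.where(g == 0, 1.0, np.where(g == 1, 0.5, 0.0))
        x = total * frac_x
        y = total * (1.0 - frac_x)
        x = x * _lognormal_noise(rng, config.noise_cv, total.shape)
        y = y * _lognormal_noise(rng, config.noise_cv, total.shape)
        return x, y

    rep_samples = [pairs["tumor_sample"].iloc[i % config.n_pairs]
                   for i in range(config.n_tech_replicates)]
    cdna_cols: dict[str, np.ndarray] = {"marker_id": marker_map["marker_id"]}
    for i, subj in enumerate(subjects):
        g = nb[:, i]
        for sample, total in ((f"{subj}_N", base_expr), (f"{subj}_T", tumor_expr)):
            x, y = cdna_channels(total, g)
            cdna_cols[f"{sample}.X"] = x
            cdna_cols[f"{sample}.Y"] = y
            n_extra = rep_samples.count(sample)
            for r in range(n_extra):
                x, y = cdna_channels(total, g)
                cdna_cols[f"{sample}.rep{r + 2}.X"] = x
                cdna_cols[f"{sample}.rep{r + 2}.Y"] = y
    cdna = pd.DataFrame(cdna_cols)

    return CohortData(gdna=gdna, cdna=cdna, marker_map=marker_map, loci=loci,
                      truth=truth, pairs=pairs, config=config)


# --------------------------------------------------------------------------
# ISH specimen table
# --------------------------------------------------------------------------

def simulate_ish_table(
    n_tumor: int,
    n_normal: int,
    degraded_frac: float,
    effect: float,
    seed: int,
    normal_mean_dots: float = 0.15,
    gamma_shape: float = 0.3,
) -> pd.DataFrame:
    """Simulate a specimen-level RNA-ISH dot-count table.

    Dots per cell are gamma distributed; the tumor mean is the normal mean
    multiplied by ``exp(effect)``, so ``effect=0`` plants a null.  Each of
    the first ``min(n_normal, n_tumor)`` tumors is paired with a normal
    specimen.  Specimens flagged degraded (independently with probability
    ``degraded_frac``) receive a POLR2 positive-control score of 0; the
    truth flag is recorded in the ``degraded_truth`` column, which the
    QC filter must not consult.
    """
    if n_tumor < 0 or n_normal < 0:
        raise ConfigError("specimen counts must be >= 0")
    if not (np.isfinite(degraded_frac) and 0.0 <= degraded_frac <= 1.0):
        raise ConfigError("degraded_frac must be in [0, 1]")
    if not np.isfinite(effect):
        raise ConfigError("effect must be finite")
    rng = np.random.default_rng(seed)

    rows = []
    n_paired = min(n_normal, n_tumor)
    groups = ["tumor"] * n_tumor + ["normal"] * n_normal
    for i, group in enumerate(groups):
        idx = i if group == "tumor" else i - n_tumor
        specimen = f"{'T' if group == 'tumor' else 'N'}{idx + 1:03d}"
        pair = f"PR{idx + 1:03d}" if idx < n_paired else ""
        mean = normal_mean_dots * (math.exp(effect) if group == "tumor" else 1.0)
        dots = rng.gamma(gamma_shape, mean / gamma_shape)
        cf_center = dots / (dots + 15.0)
        cluster = float(np.clip(rng.normal(cf_center, 0.05), 0.0, 1.0))
        degraded = bool(rng.random() < degraded_frac)
        polr2 = 0 if degraded else int(rng.choice([1, 2], p=[0.3, 0.7]))
        dapb = int(rng.choice([0, 1], p=[0.95, 0.05]))
        rows.append((specimen, group, pair, dots, cluster, polr2, dapb, degraded))
    df = pd.DataFrame(rows, columns=[
        "specimen_id", "group", "pair_id", "dots_per_cell", "cluster_fraction",
        "polr2_score", "dapb_score", "degraded_truth",
    ])

    # two-observer scores: observer A applies the rubric; observer B
    # occasionally deviates by one level
    from .ish import score_specimen  # local import to avoid a cycle
    obs_a = [score_specimen(d, c) for d, c in
             zip(df["dots_per_cell"], df["cluster_fraction"])]
    jitter = rng.choice([-1, 0, 1], size=len(df), p=[0.05, 0.90, 0.05])
    obs_b = np.clip(np.asarray(obs_a) + jitter, 0, 2)
    df["obs_a"] = obs_a
    df["obs_b"] = obs_b
    return df


# --------------------------------------------------------------------------
# survival cohort
# --------------------------------------------------------------------------

@dataclass
class SurvivalSim:
    records: pd.DataFrame
    truth: dict = field(default_factory=dict)


_AJCC_PROBS = {"I": 0.17, "II": 0.585, "III": 0.225, "IV": 0.02}
_AJCC_EXPR_MULT = {"I": 0.7, "II": 1.0, "III": 1.25, "IV": 2.5}
_T_PROBS = {"T1": 0.265, "T2": 0.59, "T3": 0.107, "T4": 0.038}


def simulate_survival_cohort(
    n: int,
    frac_high: float,
    hr_high: float,
    hr_age_per_year: float,
    censor_rate: float,
    seed: int,
    frac_zero_followup: float = 0.0,
    frac_stage_na: float = 0.0,
    expr_sigma: float = 1.5,
    baseline_median_days: float = 2500.0,
) -> SurvivalSim:
    """Simulate a TCGA-style clinical table under proportional hazards.

    Expression is log-normal (right-skewed) with the cutpoint 1.0 placed at
    approximately the ``1 - frac_high`` quantile; stage labels multiply
    expression so that later stages run higher.  Event times are
    exponential with hazard scaled by ``hr_high`` for the high-expression
    group and ``hr_age_per_year`` per year of age above 60; censoring is
    independent exponential.  A configurable fraction of records receives
    follow-up time 0 or stage "NA" to exercise cohort exclusions.
    """
    if n < 2:
        raise ConfigError("n must be >= 2")
    if hr_high <= 0 or hr_age_per_year <= 0:
        raise ConfigError("hazard ratios must be > 0")
    for name, v in (("frac_high", frac_high), ("censor_rate", censor_rate),
                    ("frac_zero_followup", frac_zero_followup),
                    ("frac_stage_na", frac_stage_na)):
        if not (np.isfinite(v) and 0.0 <= v <= 1.0):
            raise ConfigError(f"{name} must be a proportion in [0, 1]")
    rng = np.random.default_rng(seed)

    stages = rng.choice(list(_AJCC_PROBS), size=n, p=list(_AJCC_PROBS.values()))
    t_stages = rng.choice(list(_T_PROBS), size=n, p=list(_T_PROBS.values()))
    mult = np.array([_AJCC_EXPR_MULT[s] for s in stages])
    mu = expr_sigma * stats.norm.ppf(frac_high)
    expression = np.exp(rng.normal(mu, expr_sigma, size=n)) * mult
    high = expression > 1.0
    age = rng.uniform(35.0, 80.0, size=n)

    h0 = math.log(2.0) / baseline_median_days
    hazard = h0 * np.where(high, hr_high, 1.0) * hr_age_per_year ** (age - 60.0)
    event_time = rng.exponential(1.0 / hazard)
    if censor_rate > 0:
        hc = h0 * censor_rate / (1.0 - censor_rate) if censor_rate < 1 else np.inf
        censor_time = rng.exponential(1.0 / hc, size=n)
    else:
        censor_time = np.full(n, np.inf)
    time = np.minimum(event_time, censor_time)
    event = event_time <= censor_time
    time = np.maximum(np.round(time), 1.0)

    zero_fu = rng.random(n) < frac_zero_followup
    stage_na = rng.random(n) < frac_stage_na
    # zero-follow-up records are recorded alive at time 0
    event = np.where(zero_fu, False, event)
    time = np.where(zero_fu, 0.0, time)
    stages = np.where(stage_na, "NA", stages)

    records = pd.DataFrame({
        "patient_id": [f"PT{i + 1:04d}" for i in range(n)],
        "expression": expression,
        "vital_status": np.where(event, "dead", "alive"),
        "days_to_death": np.where(event, time, np.nan),
        "days_to_last_followup": np.where(event, np.nan, time),
        "age": age,
        "ajcc_stage": stages,
        "t_stage": t_stages,
    })
    truth = {
        "log_hr_high": math.log(hr_high),
        "log_hr_age": math.log(hr_age_per_year),
        "n_high": int(high.sum()),
        "n_zero_followup": int(zero_fu.sum()),
        "n_stage_na": int((stage_na & ~zero_fu).sum()),
        "n_excluded": int((zero_fu | stage_na).sum()),
    }
    return SurvivalSim(records=records, truth=truth)


# --------------------------------------------------------------------------
# knockdown gene statistics
# --------------------------------------------------------------------------

def simulate_knockdown_stats(
    n_genes: int,
    n_shared: int,
    n_only_a: int,
    n_only_b: int,
    effect: float,
    seed: int,
    se: float = 0.25,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate per-gene log2FC/p tables for two knockdown treatments.

    Shared true targets carry the same signed effect (drawn around
    ``effect``) in both treatments; treatment-specific targets carry it in
    one.  Observed log2FC adds normal noise with standard error ``se`` and
    the p-value is the corresponding two-sided z-test, so null genes have
    uniform p-values.  Returns (stats_a, stats_b, truth).
    """
    if n_shared + n_only_a + n_only_b > n_genes:
        raise ConfigError("true-target counts exceed n_genes")
    if not np.isfinite(effect) or se <= 0:
        raise ConfigError("effect must be finite and se > 0")
    rng = np.random.default_rng(seed)
    genes = np.array([f"GENE{i + 1:05d}" for i in range(n_genes)])
    kind = np.array(["null"] * n_genes, dtype=object)
    kind[:n_shared] = "shared"
    kind[n_shared:n_shared + n_only_a] = "only_a"
    kind[n_shared + n_only_a:n_shared + n_only_a + n_only_b] = "only_b"
    sign = rng.choice([-1.0, 1.0], size=n_genes)
    magnitude = np.abs(rng.normal(effect, 0.3 * abs(effect) if effect else 0.1,
                                  size=n_genes))
    delta = sign * magnitude

    def observe(active: np.ndarray) -> pd.DataFrame:
        true = np.where(active, delta, 0.0)
        lfc = true + rng.normal(0.0, se, size=n_genes)
        p = 2.0 * stats.norm.sf(np.abs(lfc) / se)
        return pd.DataFrame({"gene_id": genes, "log2fc": lfc, "p": p})

    stats_a = observe((kind == "shared") | (kind == "only_a"))
    stats_b = observe((kind == "shared") | (kind == "only_b"))
    truth = pd.DataFrame({
        "gene_id": genes,
        "kind": kind,
        "true_log2fc": np.where(kind == "null", 0.0, delta),
    })
    return stats_a, stats_b, truth
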