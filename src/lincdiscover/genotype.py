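"""Genotype calling, sample QC and genotype-aware expression quantification.

A two-channel SNP array reports X and Y fluorescence intensities per marker:
X tracks the A allele, Y the B allele.  Genotypes are called from the gDNA
hybridization with a fixed-threshold rule on the allele contrast
``theta = X / (X + Y)``; total expression per marker is then computed from
the ds-cDNA hybridization with the genotype-aware assignment:

* heterozygous (AB) markers: expression = X + Y (both alleles transcribed),
* homozygous AA: expression = X (the Y channel carries only cross-talk),
* homozygous BB: expression = Y,
* NoCall: the cell is missing.

Pairs whose genotyping call rate falls below a threshold are excluded
before differential expression.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

AA, AB, BB, NOCALL = "AA", "AB", "BB", "NoCall"

_REP_RE = re.compile(r"^(?P<sample>.+)\.rep\d+$")


class InputError(ValueError):
    """Raised on malformed or inconsistent input tables."""


# --------------------------------------------------------------------------
# intensity table I/O
# --------------------------------------------------------------------------

def read_intensity_tsv(path: str | Path) -> pd.DataFrame:
    """Read a wide intensity TSV: marker_id then <sample>.X / <sample>.Y."""
    df = pd.read_csv(path, sep="\t")
    if "marker_id" not in df.columns:
        raise InputError(f"{path}: missing marker_id column")
    return df


def intensity_samples(table: pd.DataFrame) -> list[str]:
    """Sample names present in a wide intensity table (order preserved)."""
    names = []
    for col in table.columns:
        if col.endswith(".X"):
            names.append(col[:-2])
    return names


def _channels(table: pd.DataFrame, sample: str) -> tuple[np.ndarray, np.ndarray]:
    x = table[f"{sample}.X"].to_numpy(dtype=float)
    y = table[f"{sample}.Y"].to_numpy(dtype=float)
    return x, y


def _check_nonnegative(table: pd.DataFrame, sample: str) -> None:
    x, y = _channels(table, sample)
    bad = ~(np.isfinite(x) & np.isfinite(y)) | (x < 0) | (y < 0)
    if bad.any():
        marker = table["marker_id"].iloc[int(np.flatnonzero(bad)[0])]
        raise InputError(
            f"negative or non-finite intensity at marker {marker}, sample {sample}"
        )


def average_replicates(table: pd.DataFrame) -> pd.DataFrame:
    """Average technical replicates into their base sample, raw scale.

    Replicate columns are named ``<sample>.repK.X/Y``; the replicate and the
    base sample array are averaged channel-wise before any quantification.
    """
    groups: dict[str, list[str]] = {}
    for s in intensity_samples(table):
        m = _REP_RE.match(s)
        groups.setdefault(m.group("sample") if m else s, []).append(s)
    out = pd.DataFrame({"marker_id": table["marker_id"]})
    for base, members in groups.items():
        xs = np.mean([_channels(table, s)[0] for s in members], axis=0)
        ys = np.mean([_channels(table, s)[1] for s in members], axis=0)
        out[f"{base}.X"] = xs
        out[f"{base}.Y"] = ys
    return out


# --------------------------------------------------------------------------
# genotype calling
# --------------------------------------------------------------------------

@dataclass
class GenotypeCalls:
    """Per-marker, per-subject genotype calls and allele contrasts."""

    calls: pd.DataFrame   # markers x subjects, values in {AA, AB, BB, NoCall}
    theta: pd.DataFrame   # markers x subjects, X/(X+Y), NaN where undefined
    intensity_floor: float

    def call_rate(self) -> pd.Series:
        return (self.calls != NOCALL).mean(axis=0)


def call_genotypes(
    gdna: pd.DataFrame,
    theta_hom_hi: float = 0.75,
    theta_hom_lo: float = 0.25,
    ab_band: tuple[float, float] = (0.35, 0.65),
    intensity_floor: float | None = None,
) -> GenotypeCalls:
    """Call diploid genotypes from gDNA X/Y intensities.

    The allele contrast theta = X/(X+Y) maps genotypes to clusters near
    1 (AA), 0.5 (AB) and 0 (BB).  Fixed thresholds assign theta >=
    ``theta_hom_hi`` to AA, theta <= ``theta_hom_lo`` to BB and theta
    inside ``ab_band`` to AB; anything between bands, or any marker whose
    total intensity X+Y is below the floor, is NoCall.  The default floor
    is 5% of the grand median total intensity.
    """
    if not (0.0 < theta_hom_lo < theta_hom_hi < 1.0):
        raise InputError("thresholds must satisfy 0 < lo < hi < 1")
    subjects = intensity_samples(gdna)
    if not subjects:
        raise InputError("no sample columns found in gDNA table")
    for s in subjects:
        _check_nonnegative(gdna, s)

    totals = np.column_stack([np.sum(_channels(gdna, s), axis=0) for s in subjects])
    if intensity_floor is None:
        intensity_floor = 0.05 * float(np.median(totals))

    call_cols, theta_cols = {}, {}
    lo_band, hi_band = ab_band
    for j, s in enumerate(subjects):
        x, y = _channels(gdna, s)
        total = x + y
        with np.errstate(invalid="ignore", divide="ignore"):
            theta = np.where(total > 0, x / np.where(total > 0, total, 1.0), np.nan)
        call = np.full(len(x), NOCALL, dtype=object)
        ok = total >= intensity_floor
        call[ok & (theta >= theta_hom_hi)] = AA
        call[ok & (theta <= theta_hom_lo)] = BB
        call[ok & (theta >= lo_band) & (theta <= hi_band)] = AB
        call_cols[s] = call
        theta_cols[s] = theta
    idx = pd.Index(gdna["marker_id"], name="marker_id")
    return GenotypeCalls(
        calls=pd.DataFrame(call_cols, index=idx),
        theta=pd.DataFrame(theta_cols, index=idx),
        intensity_floor=float(intensity_floor),
    )


# --------------------------------------------------------------------------
# pair-level QC
# --------------------------------------------------------------------------

def qc_exclude_pairs(
    calls: GenotypeCalls,
    pairs: pd.DataFrame,
    min_call_rate: float = 0.95,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exclude pairs whose subject fails the genotyping call-rate threshold.

    A subject fails if its fraction of non-NoCall markers is below
    ``min_call_rate``; a pair is excluded if any subject belonging to it
    fails.  Returns (retained pairs, report) where the report lists every
    pair with its call rate and exclusion reason.
    """
    required = {"pair_id", "subject_id"}
    if not required.issubset(pairs.columns):
        raise InputError(f"pairs table must have columns {sorted(required)}")
    rates = calls.call_rate()
    missing = set(pairs["subject_id"]) - set(rates.index)
    if missing:
        raise InputError(f"no genotype calls for subjects: {sorted(missing)}")

    rows = []
    for pair_id, grp in pairs.groupby("pair_id", sort=False):
        subject_rates = rates[grp["subject_id"]]
        failed = subject_rates[subject_rates < min_call_rate]
        reason = (
            "" if failed.empty else
            "call rate below threshold: " + ", ".join(
                f"{s}={r:.3f}" for s, r in failed.items())
        )
        rows.append((pair_id, float(subject_rates.min()), failed.empty, reason))
    report = pd.DataFrame(
        rows, columns=["pair_id", "min_subject_call_rate", "retained", "reason"]
    )
    retained = pairs[pairs["pair_id"].isin(report.loc[report["retained"], "pair_id"])]
    return retained.reset_index(drop=True), report


# --------------------------------------------------------------------------
# expression quantification
# --------------------------------------------------------------------------

HET_SUM, HOM_X, HOM_Y, MISSING = "het-sum", "hom-X", "hom-Y", "missing"


@dataclass
class ExpressionMatrix:
    """Markers x samples total expression with per-cell provenance."""

    values: pd.DataFrame      # float, NaN = missing
    provenance: pd.DataFrame  # strings in {het-sum, hom-X, hom-Y, missing}
    log2: bool = False

    def provenance_counts(self) -> dict[str, int]:
        flat = self.provenance.to_numpy().ravel()
        return {k: int((flat == k).sum()) for k in (HET_SUM, HOM_X, HOM_Y, MISSING)}

    def write(self, path: str | Path) -> None:
        path = Path(path)
        self.values.to_csv(path, sep="\t")
        sidecar = path.with_suffix(path.suffix + ".provenance.json")
        sidecar.write_text(json.dumps(self.provenance_counts(), indent=2) + "\n")


def quantify_expression(
    cdna: pd.DataFrame,
    calls: GenotypeCalls,
    pairs: pd.DataFrame,
) -> ExpressionMatrix:
    """Compute genotype-aware total expression from ds-cDNA intensities.

    Every cDNA sample is mapped to its subject through the pairs table so
    that the subject's germline genotype selects the channel rule:
    AB -> X+Y, AA -> X, BB -> Y, NoCall -> missing.
    """
    sample_to_subject: dict[str, str] = {}
    for _, row in pairs.iterrows():
        sample_to_subject[row["normal_sample"]] = row["subject_id"]
        sample_to_subject[row["tumor_sample"]] = row["subject_id"]

    samples = intensity_samples(cdna)
    if not samples:
        raise InputError("no sample columns found in cDNA table")
    cdna = cdna.set_index("marker_id") if "marker_id" in cdna.columns else cdna
    idx = cdna.index

    missing_markers = idx.difference(calls.calls.index)
    if len(missing_markers):
        raise InputError(
            f"cDNA markers without genotype calls: {list(missing_markers[:5])}"
        )

    values, prov = {}, {}
    for s in samples:
        m = _REP_RE.match(s)
        subject = sample_to_subject.get(m.group("sample") if m else s)
        if subject is None:
            raise InputError(f"cDNA sample {s} has no subject in the pairs table")
        x = cdna[f"{s}.X"].to_numpy(dtype=float)
        y = cdna[f"{s}.Y"].to_numpy(dtype=float)
        bad = ~(np.isfinite(x) & np.isfinite(y)) | (x < 0) | (y < 0)
        if bad.any():
            m = idx[int(np.flatnonzero(bad)[0])]
            raise InputError(
                f"negative or non-finite intensity at marker {m}, sample {s}")
        g = calls.calls.loc[idx, subject].to_numpy()
        e = np.where(g == AB, x + y, np.where(g == AA, x, np.where(g == BB, y, np.nan)))
        p = np.where(g == AB, HET_SUM,
                     np.where(g == AA, HOM_X, np.where(g == BB, HOM_Y, MISSING)))
        values[s] = e
        prov[s] = p
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=idx),
        provenance=pd.DataFrame(prov, index=idx),
    )


def normalize_and_log(expr: ExpressionMatrix, scale: bool = True) -> ExpressionMatrix:
    """Median-scale each array to the grand median, then log2(e + 1).

    With ``scale=False`` the median scaling is skipped (pass-through mode)
    and only the log transform is applied.  Missing cells propagate.
    """
    v = expr.values
    if (v.to_numpy() < 0).any():
        raise InputError("expression matrix has negative entries")
    if scale:
        medians = v.median(axis=0, skipna=True)
        if (medians <= 0).any():
            bad = medians.index[medians <= 0].tolist()
            raise InputError(f"array median is zero for samples: {bad}")
        grand = float(np.nanmedian(v.to_numpy()))
        v = v * (grand / medians)
    out = np.log2(v + 1.0)
    return ExpressionMatrix(values=out, provenance=expr.provenance.copy(), log2=True)
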