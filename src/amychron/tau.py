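"""Longitudinal tau change versus A+ chronicity.

Relates NFT-stage (Braak-composite) flortaucipir SUVRs to chronological age,
amyloid burden and A+ chronicity: Pearson correlations with Fisher-z CIs,
annualized percent change for participants with two tau scans, chronicity-bin
summaries (mean annualized % change with t-based 95% CIs) and Cohen's d effect
sizes between baseline and follow-up SUVR.

Stage composites are volume-weighted means over FreeSurfer regions; the
default region→stage map follows the commonly used Braak-stage composites
(entorhinal for stage I through occipital/sensorimotor for stage VI) and can
be overridden by the caller.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import N_STAGES, STAGE_COLUMNS
from .errors import InputError

logger = logging.getLogger(__name__)

__all__ = [
    "BIN_LABELS",
    "BIN_EDGES",
    "assign_chronicity_bin",
    "annualized_change",
    "cohens_d_with_ci",
    "pearson_with_ci",
    "summarize_bin",
    "BinSummary",
    "aggregate_nft_stage_suvr",
    "DEFAULT_STAGE_MAP",
    "run_tau_analysis",
]

# left-closed, right-open chronicity bins (years)
BIN_EDGES = (-np.inf, 0.0, 2.5, 5.0, 10.0, np.inf)
BIN_LABELS = ("<0", "0–2.5", "2.5–5", "5–10", ">10")

# Braak-composite FreeSurfer regions per NFT stage (a documented default;
# pass your own map for a different ROI scheme)
DEFAULT_STAGE_MAP: dict[str, int] = {
    "entorhinal": 1,
    "hippocampus": 2,
    "parahippocampal": 3, "fusiform": 3, "lingual": 3, "amygdala": 3,
    "middletemporal": 4, "caudalanteriorcingulate": 4,
    "rostralanteriorcingulate": 4, "posteriorcingulate": 4,
    "isthmuscingulate": 4, "insula": 4, "inferiortemporal": 4,
    "temporalpole": 4,
    "superiorfrontal": 5, "lateralorbitofrontal": 5, "medialorbitofrontal": 5,
    "frontalpole": 5, "caudalmiddlefrontal": 5, "rostralmiddlefrontal": 5,
    "parsopercularis": 5, "parsorbitalis": 5, "parstriangularis": 5,
    "lateraloccipital": 5, "supramarginal": 5, "inferiorparietal": 5,
    "superiortemporal": 5, "superiorparietal": 5, "precuneus": 5,
    "bankssts": 5, "transversetemporal": 5,
    "pericalcarine": 6, "postcentral": 6, "cuneus": 6, "precentral": 6,
    "paracentral": 6,
}


def assign_chronicity_bin(chronicity) -> np.ndarray | str:
    """Map chronicity (years) to its bin label.

    Bins are left-closed/right-open: (−∞, 0), [0, 2.5), [2.5, 5), [5, 10),
    [10, ∞) — so 2.5 falls in "2.5–5" and 10 falls in ">10".
    """
    arr = np.asarray(chronicity, float)
    if not np.all(np.isfinite(arr)):
        raise InputError("chronicity must be finite")
    idx = np.searchsorted(BIN_EDGES[1:-1], arr, side="right")
    labels = np.asarray(BIN_LABELS, dtype=object)[idx]
    return str(labels) if arr.ndim == 0 else labels


def annualized_change(baseline: float, followup: float, dt: float) -> tuple[float, float]:
    """Annualized absolute (SUVR/yr) and percent (%/yr, relative to baseline)
    change between two scans ``dt`` years apart."""
    if not (np.isfinite(baseline) and np.isfinite(followup) and np.isfinite(dt)):
        raise InputError("annualized_change requires finite inputs")
    if dt <= 0:
        raise InputError("dt must be positive")
    if baseline <= 0:
        raise InputError("baseline SUVR must be positive")
    rate = (followup - baseline) / dt
    pct_rate = 100.0 * (followup - baseline) / (baseline * dt)
    return rate, pct_rate


def cohens_d_with_ci(baseline, followup, alpha: float = 0.05):
    """Independent-groups Cohen's d (follow-up minus baseline, pooled SD) with
    a normal-approximation CI: se = √(2/n + d²/(4(2n−2))).

    Positive d means the follow-up mean exceeds the baseline mean.  Returns
    ``(nan, nan, nan)`` when the pooled SD is zero (undefined effect).
    """
    b = np.asarray(baseline, float)
    f = np.asarray(followup, float)
    if b.size != f.size or b.size < 2:
        raise InputError("cohens_d_with_ci needs two equal-length samples, n >= 2")
    n = b.size
    sp2 = ((n - 1) * b.var(ddof=1) + (n - 1) * f.var(ddof=1)) / (2 * n - 2)
    if sp2 <= 0:
        logger.warning("zero pooled SD; Cohen's d undefined")
        return np.nan, np.nan, np.nan
    d = (f.mean() - b.mean()) / np.sqrt(sp2)
    z = stats.norm.ppf(1 - alpha / 2)
    se = np.sqrt(2.0 / n + d**2 / (4.0 * (2 * n - 2)))
    return float(d), float(d - z * se), float(d + z * se)


def pearson_with_ci(x, y, alpha: float = 0.05):
    """Pearson r with a Fisher-z 95% CI: tanh(atanh(r) ± z/√(n−3))."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 4:
        raise InputError("pearson_with_ci needs two equal-length samples, n >= 4")
    if np.std(x) == 0 or np.std(y) == 0:
        raise InputError("correlation undefined for constant input")
    r = float(stats.pearsonr(x, y).statistic)
    if abs(r) >= 1.0 - 1e-12:  # degenerate: perfectly linear data
        return r, r, r
    z = stats.norm.ppf(1 - alpha / 2)
    zr = np.arctanh(r)
    half = z / np.sqrt(x.size - 3)
    return r, float(np.tanh(zr - half)), float(np.tanh(zr + half))


@dataclass
class BinSummary:
    """Per-bin, per-stage summary of longitudinal tau change."""

    chronicity_bin: str
    n: int
    mean_burden_cl: float
    mean_pct_rate: np.ndarray  # %/yr, one per NFT stage
    pct_ci_low: np.ndarray
    pct_ci_high: np.ndarray
    cohens_d: np.ndarray
    d_ci_low: np.ndarray
    d_ci_high: np.ndarray

    def __post_init__(self) -> None:
        for name in ("mean_pct_rate", "pct_ci_low", "pct_ci_high",
                     "cohens_d", "d_ci_low", "d_ci_high"):
            setattr(self, name, np.asarray(getattr(self, name), float))
        ok = (self.pct_ci_low <= self.mean_pct_rate + 1e-12) & (
            self.mean_pct_rate <= self.pct_ci_high + 1e-12
        )
        if not np.all(ok | np.isnan(self.mean_pct_rate)):
            raise InputError("CI bounds must bracket the mean for every stage")

    def to_rows(self) -> list[dict]:
        rows = []
        for k in range(N_STAGES):
            rows.append(
                {
                    "chronicity_bin": self.chronicity_bin,
                    "n": self.n,
                    "mean_burden_cl": self.mean_burden_cl,
                    "stage": k + 1,
                    "mean_pct_rate": self.mean_pct_rate[k],
                    "pct_ci_low": self.pct_ci_low[k],
                    "pct_ci_high": self.pct_ci_high[k],
                    "cohens_d": self.cohens_d[k],
                    "d_ci_low": self.d_ci_low[k],
                    "d_ci_high": self.d_ci_high[k],
                }
            )
        return rows


def _t_interval(values: np.ndarray, alpha: float = 0.05) -> tuple[float, float, float]:
    """Mean with a t-distribution CI; a single value gives a NaN interval."""
    m = float(values.mean())
    n = values.size
    if n < 2:
        return m, np.nan, np.nan
    sd = float(values.std(ddof=1))
    half = stats.t.ppf(1 - alpha / 2, n - 1) * sd / np.sqrt(n)
    return m, m - half, m + half


def summarize_bin(records: pd.DataFrame) -> BinSummary:
    """Summarize the change records of one chronicity bin.

    ``records`` is long-format with one row per subject × stage and columns
    ``subject_id, stage, baseline_suvr, followup_suvr, pct_rate,
    chronicity_bin, baseline_cl``.
    """
    if len(records) == 0:
        raise InputError("cannot summarize an empty bin")
    label = str(records["chronicity_bin"].iloc[0])
    subjects = records["subject_id"].unique()
    n = subjects.size
    per_subj = records.drop_duplicates("subject_id")
    mean_cl = float(per_subj["baseline_cl"].mean()) if "baseline_cl" in records else np.nan

    mean_pct = np.full(N_STAGES, np.nan)
    lo = np.full(N_STAGES, np.nan)
    hi = np.full(N_STAGES, np.nan)
    d = np.full(N_STAGES, np.nan)
    d_lo = np.full(N_STAGES, np.nan)
    d_hi = np.full(N_STAGES, np.nan)
    for k in range(N_STAGES):
        grp = records[records["stage"] == k + 1]
        if len(grp) == 0:
            continue
        mean_pct[k], lo[k], hi[k] = _t_interval(grp["pct_rate"].to_numpy(float))
        if len(grp) >= 2:
            d[k], d_lo[k], d_hi[k] = cohens_d_with_ci(
                grp["baseline_suvr"].to_numpy(float),
                grp["followup_suvr"].to_numpy(float),
            )
    # a single-record bin has an NA interval; treat it as bracketing its mean
    lo_chk = np.where(np.isnan(lo), mean_pct, lo)
    hi_chk = np.where(np.isnan(hi), mean_pct, hi)
    return BinSummary(
        chronicity_bin=label, n=int(n), mean_burden_cl=mean_cl,
        mean_pct_rate=mean_pct, pct_ci_low=lo_chk, pct_ci_high=hi_chk,
        cohens_d=d, d_ci_low=d_lo, d_ci_high=d_hi,
    )


def aggregate_nft_stage_suvr(
    region_table: pd.DataFrame, stage_map: dict[str, int] | None = None
) -> np.ndarray:
    """Volume-weighted stage-composite SUVRs from per-region values.

    ``region_table`` has columns ``region, suvr, volume``; regions absent from
    the map are ignored.  Raises if any of the six stages ends up with no
    member region.
    """
    stage_map = DEFAULT_STAGE_MAP if stage_map is None else stage_map
    if (region_table["volume"] <= 0).any():
        raise InputError("region volumes must be positive")
    out = np.full(N_STAGES, np.nan)
    mapped = region_table[region_table["region"].isin(stage_map)]
    stages = mapped["region"].map(stage_map)
    for k in range(1, N_STAGES + 1):
        grp = mapped[stages == k]
        if len(grp) == 0:
            raise InputError(f"NFT stage {k} has no member region in the table")
        w = grp["volume"].to_numpy(float)
        out[k - 1] = float(np.average(grp["suvr"].to_numpy(float), weights=w))
    return out


def _subject_chronicity(estimates: pd.DataFrame) -> dict[str, tuple[float, float]]:
    """subject_id → (reference_age, chronicity at reference)."""
    return {
        str(r.subject_id): (float(r.reference_age), float(r.chronicity))
        for r in estimates.itertuples()
    }


def _nearest_amyloid(visits: pd.DataFrame, sid: str, age: float,
                     tolerance: float = 0.5):
    """Amyloid scan co-scheduled (same day) with a tau scan; None if absent."""
    amy = visits[(visits["subject_id"] == sid) & (visits["modality"] == "amyloid")]
    if len(amy) == 0:
        return None
    diffs = (amy["age"] - age).abs()
    i = diffs.idxmin()
    if diffs.loc[i] > tolerance:
        return None
    return amy.loc[i]


def run_tau_analysis(
    visits: pd.DataFrame, estimates: pd.DataFrame
) -> dict[str, pd.DataFrame]:
    """Full tau-versus-chronicity analysis.

    Returns a dict with three tables:

    ``correlations`` — per stage, Pearson r (with Fisher-z CI) of baseline tau
    SUVR against chronological age, amyloid load and A+ chronicity.

    ``changes`` — long-format annualized change records (one row per
    subject × stage) for participants with two tau scans, with the chronicity
    bin of the baseline tau scan.

    ``bin_summaries`` — per bin × stage mean annualized % change with 95% CI
    and Cohen's d (baseline vs. follow-up) with 95% CI.
    """
    tau = visits[visits["modality"] == "tau"].sort_values(["subject_id", "age"])
    chron_map = _subject_chronicity(estimates)

    # cross-sectional table: first (baseline) tau scan per subject
    xs_rows = []
    for sid, grp in tau.groupby("subject_id", sort=True):
        if sid not in chron_map:
            continue
        row = grp.iloc[0]
        ref_age, ref_chron = chron_map[sid]
        chron = ref_chron + (float(row["age"]) - ref_age)
        amy = _nearest_amyloid(visits, sid, float(row["age"]))
        rec = {
            "subject_id": sid,
            "age": float(row["age"]),
            "chronicity": chron,
            "abl": float(amy["abl"]) if amy is not None else np.nan,
            "cl": float(amy["cl"]) if amy is not None and "cl" in amy else np.nan,
        }
        for col in STAGE_COLUMNS:
            rec[col] = float(row[col])
        xs_rows.append(rec)
    xs = pd.DataFrame(xs_rows)

    corr_rows = []
    if len(xs) >= 4:
        for pred in ("age", "abl", "chronicity"):
            sub = xs.dropna(subset=[pred])
            for k, col in enumerate(STAGE_COLUMNS, start=1):
                if len(sub) < 4 or sub[pred].nunique() <= 1 or sub[col].nunique() <= 1:
                    continue
                r, lo, hi = pearson_with_ci(sub[pred], sub[col])
                corr_rows.append(
                    {"predictor": pred, "stage": k, "r": r,
                     "ci_low": lo, "ci_high": hi, "n": len(sub)}
                )
    correlations = pd.DataFrame(
        corr_rows, columns=["predictor", "stage", "r", "ci_low", "ci_high", "n"]
    )

    # longitudinal change records: first vs. last tau scan
    change_rows = []
    for sid, grp in tau.groupby("subject_id", sort=True):
        if len(grp) < 2 or sid not in chron_map:
            continue
        b_row, f_row = grp.iloc[0], grp.iloc[-1]
        dt = float(f_row["age"]) - float(b_row["age"])
        if dt <= 0:
            raise InputError(f"non-positive tau follow-up interval for {sid}")
        ref_age, ref_chron = chron_map[sid]
        chron_baseline = ref_chron + (float(b_row["age"]) - ref_age)
        bin_label = assign_chronicity_bin(chron_baseline)
        amy = _nearest_amyloid(visits, sid, float(b_row["age"]))
        baseline_cl = float(amy["cl"]) if amy is not None and "cl" in amy else np.nan
        for k, col in enumerate(STAGE_COLUMNS, start=1):
            b, f = float(b_row[col]), float(f_row[col])
            rate, pct = annualized_change(b, f, dt)
            change_rows.append(
                {
                    "subject_id": sid, "stage": k,
                    "baseline_suvr": b, "followup_suvr": f, "dt": dt,
                    "rate": rate, "pct_rate": pct,
                    "chronicity_baseline": chron_baseline,
                    "chronicity_bin": bin_label, "baseline_cl": baseline_cl,
                }
            )
    changes = pd.DataFrame(
        change_rows,
        columns=["subject_id", "stage", "baseline_suvr", "followup_suvr", "dt",
                 "rate", "pct_rate", "chronicity_baseline", "chronicity_bin",
                 "baseline_cl"],
    )
    if len(changes) == 0:
        logger.warning("no participant has two tau scans; longitudinal stage skipped")

    summary_rows = []
    for label in BIN_LABELS:
        grp = changes[changes["chronicity_bin"] == label] if len(changes) else changes
        if len(grp) == 0:
            continue
        summary_rows.extend(summarize_bin(grp).to_rows())
    bin_summaries = pd.DataFrame(
        summary_rows,
        columns=["chronicity_bin", "n", "mean_burden_cl", "stage",
                 "mean_pct_rate", "pct_ci_low", "pct_ci_high",
                 "cohens_d", "d_ci_low", "d_ci_high"],
    )
    return {"correlations": correlations, "changes": changes,
            "bin_summaries": bin_summaries}
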