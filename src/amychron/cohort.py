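"""Synthetic longitudinal amyloid/tau PET cohort generator.

Emulates an adult Down-syndrome cohort of the kind studied in the
Alzheimer's Biomarker Consortium–Down Syndrome (ABC-DS): 177 participants,
PiB amyloid scans every 2–3 years with a fixed distribution of scan counts
(1–5 scans), flortaucipir tau scans co-scheduled with a subset of the amyloid
visits, cohort age roughly 39 ± 8.5 years, and heterogeneous A+ onset ages
spanning roughly 30–60 years.

The latent amyloid process is an ODE in burden: the accumulation rate is a
sigmoid function of current burden that rises from a small pre-onset drift and
plateaus at a maximal rate (the cohort shows a plateau in the *rate* of
accumulation, not in burden itself).  Each subject's latent trajectory is
anchored so it crosses the A+ cutoff (13.3 Aβ_L) exactly at the subject's
onset age.  Tau SUVR in each neurofibrillary-tangle (NFT) stage composite
follows a hinge-linear function of A+ chronicity with stage-ordered lags
(earlier Braak stages rise first).  Measurement noise is additive Gaussian on
both scales.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.special import expit
from scipy.stats import truncnorm

from .burden import abl_to_cl, CONSTANTS
from .errors import ConfigError, InputError, SchemaError

__all__ = [
    "CohortConfig",
    "N_STAGES",
    "STAGE_COLUMNS",
    "COHORT_COLUMNS",
    "simulate_amyloid_trajectory",
    "simulate_tau_profile",
    "generate_cohort",
    "write_cohort_csv",
    "read_cohort_csv",
    "validate_cohort_schema",
]

N_STAGES = 6
STAGE_COLUMNS = tuple(f"nft{i}" for i in range(1, N_STAGES + 1))
COHORT_COLUMNS = (
    "subject_id",
    "age",
    "modality",
    "abl",
    "cl",
    *STAGE_COLUMNS,
    "true_onset_age",
)

# onset ages are truncated to the study's age-eligibility range
_ONSET_TRUNCATION = (25.0, 70.0)


@dataclass
class CohortConfig:
    """All knobs of the synthetic cohort.

    Defaults reproduce the study conditions: n = 177 with the published
    amyloid/tau scan-count distributions, visits every 2–3 years, a rate field
    plateauing at 3.73 Aβ_L/yr, and onset ages centred near 41 years so that
    truncation to [25, 70] yields the reported ~30–60-year onset spread.
    """

    n_subjects: int = 177
    onset_age_mean: float = 41.0   # years
    onset_age_sd: float = 7.0      # years
    pre_onset_rate: float = 0.2    # Aβ_L/yr drift below the cutoff
    rate_max: float = 3.73         # Aβ_L/yr plateau of the rate field
    rate_midpoint: float = 30.0    # Aβ_L at half-maximal rate
    rate_slope: float = 8.0        # Aβ_L sigmoid width
    noise_sd_abl: float = 1.5      # Aβ_L measurement noise
    visit_interval_range: tuple[float, float] = (2.0, 3.0)  # years
    scan_count_distribution: Mapping[int, int] = field(
        default_factory=lambda: {1: 58, 2: 64, 3: 15, 4: 30, 5: 10}
    )
    tau_subset_distribution: Mapping[int, int] = field(
        default_factory=lambda: {1: 75, 2: 92}
    )
    tau_base: tuple[float, ...] = (1.10, 1.15, 1.08, 1.05, 1.02, 1.00)   # SUVR
    tau_lag: tuple[float, ...] = (0.0, 0.0, 1.0, 3.0, 4.0, 5.0)          # years
    tau_slope: tuple[float, ...] = (0.030, 0.028, 0.025, 0.020, 0.018, 0.012)  # SUVR/yr
    noise_sd_suvr: float = 0.05
    first_visit_age_mean: float = 35.0  # years; cohort all-scan mean lands near 39.2
    first_visit_age_sd: float = 8.5     # years
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        for name in ("pre_onset_rate", "rate_max", "rate_slope",
                     "noise_sd_abl", "noise_sd_suvr"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.pre_onset_rate <= 0 or self.rate_max <= 0 or self.rate_slope <= 0:
            raise ConfigError("rate parameters must be strictly positive")
        total = sum(self.scan_count_distribution.values())
        if total != self.n_subjects:
            raise ConfigError(
                f"scan_count_distribution sums to {total}, expected {self.n_subjects}"
            )
        if any(k < 1 for k in self.scan_count_distribution):
            raise ConfigError("scan counts must be >= 1")
        tau_total = sum(self.tau_subset_distribution.values())
        if tau_total > self.n_subjects:
            raise ConfigError("tau_subset_distribution exceeds n_subjects")
        for tup in (self.tau_base, self.tau_lag, self.tau_slope):
            if len(tup) != N_STAGES:
                raise ConfigError("tau stage parameters must have six entries")
        lags = np.asarray(self.tau_lag, float)
        if np.any(np.diff(lags) < 0):
            raise ConfigError("tau_lag must be non-decreasing across stages I→VI")
        lo, hi = self.visit_interval_range
        if not (0 < lo <= hi):
            raise ConfigError("visit_interval_range must satisfy 0 < lo <= hi")

    def rate_law(self, abl):
        """Latent accumulation rate dA/dt as a function of burden A (Aβ_L/yr)."""
        a = np.asarray(abl, dtype=float)
        return self.pre_onset_rate + (self.rate_max - self.pre_onset_rate) * expit(
            (a - self.rate_midpoint) / self.rate_slope
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scan_count_distribution"] = {int(k): int(v) for k, v in
                                        self.scan_count_distribution.items()}
        d["tau_subset_distribution"] = {int(k): int(v) for k, v in
                                        self.tau_subset_distribution.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortConfig":
        d = dict(d)
        for key in ("scan_count_distribution", "tau_subset_distribution"):
            if key in d:
                d[key] = {int(k): int(v) for k, v in d[key].items()}
        for key in ("visit_interval_range", "tau_base", "tau_lag", "tau_slope"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def simulate_amyloid_trajectory(
    config: CohortConfig, onset_age: float, eval_ages: Sequence[float]
) -> np.ndarray:
    """Noise-free latent amyloid burden at the given ages.

    Integrates ``dA/dt = rate_law(A)`` with the anchor ``A(onset_age) = 13.3``
    (the A+ cutoff), forward and backward in age as needed.  The rate law is
    strictly positive, so the latent burden is strictly increasing in age.
    """
    ages = np.asarray(eval_ages, dtype=float)
    if ages.ndim != 1 or ages.size == 0:
        raise InputError("eval_ages must be a non-empty 1-D sequence")
    if np.any(np.diff(ages) <= 0):
        raise InputError("eval_ages must be strictly increasing")

    anchor = CONSTANTS.cutoff_abl
    out = np.empty_like(ages)
    rhs = lambda t, y: config.rate_law(y)  # noqa: E731 - autonomous ODE

    at_anchor = np.isclose(ages, onset_age, rtol=0, atol=1e-12)
    out[at_anchor] = anchor
    for direction in (+1, -1):
        sel = (ages > onset_age) if direction > 0 else (ages < onset_age)
        sel &= ~at_anchor
        if not sel.any():
            continue
        t_eval = ages[sel] if direction > 0 else ages[sel][::-1]
        span = (onset_age, t_eval[-1])
        sol = solve_ivp(rhs, span, [anchor], t_eval=t_eval,
                        rtol=1e-9, atol=1e-9, method="RK45")
        vals = sol.y[0] if direction > 0 else sol.y[0][::-1]
        out[sel] = vals
    return out


def simulate_tau_profile(chronicity: float, config: CohortConfig) -> np.ndarray:
    """Noise-free NFT-stage SUVR profile at a given A+ chronicity.

    Hinge-linear: stage k sits at its base SUVR until ``chronicity`` passes the
    stage lag, then rises linearly at the stage slope.  Chronicity may be
    negative (pre-onset scans).
    """
    base = np.asarray(config.tau_base, float)
    lag = np.asarray(config.tau_lag, float)
    slope = np.asarray(config.tau_slope, float)
    return base + slope * np.maximum(0.0, chronicity - lag)


def _truncnorm_rvs(mean, sd, lo, hi, size, rng):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate the long-format visit table (one row per scan).

    Deterministic given ``config.seed``.  Amyloid scan counts match
    ``scan_count_distribution`` exactly; tau visits are co-scheduled with
    amyloid visits (baseline, and for two-scan tau subjects the final amyloid
    visit); every row carries the subject's ground-truth onset age.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects

    counts = np.repeat(
        list(config.scan_count_distribution.keys()),
        list(config.scan_count_distribution.values()),
    )
    rng.shuffle(counts)

    # tau scan counts: two-scan tau subjects need >= 2 amyloid visits to
    # co-schedule with, so assign those first among eligible subjects
    tau_counts = np.zeros(n, dtype=int)
    n_tau2 = int(config.tau_subset_distribution.get(2, 0))
    n_tau1 = int(config.tau_subset_distribution.get(1, 0))
    multi = np.flatnonzero(counts >= 2)
    if n_tau2 > multi.size:
        raise ConfigError(
            "not enough multi-scan subjects to host two co-scheduled tau visits"
        )
    tau2_idx = rng.choice(multi, size=n_tau2, replace=False)
    tau_counts[tau2_idx] = 2
    remaining = np.flatnonzero(tau_counts == 0)
    tau1_idx = rng.choice(remaining, size=n_tau1, replace=False)
    tau_counts[tau1_idx] = 1

    lo, hi = _ONSET_TRUNCATION
    onset_ages = _truncnorm_rvs(
        config.onset_age_mean, config.onset_age_sd, lo, hi, n, rng
    )
    first_ages = _truncnorm_rvs(
        config.first_visit_age_mean, config.first_visit_age_sd, lo, hi, n, rng
    )

    rows = []
    gap_lo, gap_hi = config.visit_interval_range
    width = len(str(n))
    for i in range(n):
        sid = f"S{i + 1:0{width}d}"
        k = int(counts[i])
        gaps = rng.uniform(gap_lo, gap_hi, size=k - 1)
        ages = first_ages[i] + np.concatenate([[0.0], np.cumsum(gaps)])
        latent = simulate_amyloid_trajectory(config, onset_ages[i], ages)
        observed = latent + rng.normal(0.0, config.noise_sd_abl, size=k)
        for age, abl in zip(ages, observed):
            rows.append(
                {
                    "subject_id": sid,
                    "age": age,
                    "modality": "amyloid",
                    "abl": abl,
                    "cl": abl_to_cl(abl),
                    "true_onset_age": onset_ages[i],
                }
            )
        n_tau = int(tau_counts[i])
        tau_ages = []
        if n_tau >= 1:
            tau_ages.append(ages[0])
        if n_tau == 2:
            tau_ages.append(ages[-1])
        for age in tau_ages:
            chron = age - onset_ages[i]
            suvr = simulate_tau_profile(chron, config)
            suvr = suvr + rng.normal(0.0, config.noise_sd_suvr, size=N_STAGES)
            suvr = np.maximum(suvr, 1e-3)  # SUVR is a ratio; keep it positive
            row = {
                "subject_id": sid,
                "age": age,
                "modality": "tau",
                "true_onset_age": onset_ages[i],
            }
            row.update({col: v for col, v in zip(STAGE_COLUMNS, suvr)})
            rows.append(row)

    df = pd.DataFrame(rows).reindex(columns=list(COHORT_COLUMNS))
    df = df.sort_values(["subject_id", "age", "modality"], kind="mergesort")
    return df.reset_index(drop=True)


def validate_cohort_schema(df: pd.DataFrame) -> pd.DataFrame:
    """Check the visit-table schema, raising :class:`SchemaError` with the
    offending column or rows named."""
    missing = [c for c in ("subject_id", "age", "modality", "abl")
               if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort table missing required columns: {missing}")
    bad_modality = ~df["modality"].isin(["amyloid", "tau"])
    if bad_modality.any():
        raise SchemaError(
            f"unknown modality at rows {df.index[bad_modality].tolist()[:5]}"
        )
    if not np.all(np.isfinite(df["age"].to_numpy(float))):
        raise SchemaError("non-finite ages in cohort table")
    if (df["age"] <= 0).any():
        raise SchemaError("ages must be positive")
    amyloid = df[df["modality"] == "amyloid"]
    if amyloid["abl"].isna().any():
        bad = amyloid.index[amyloid["abl"].isna()].tolist()[:5]
        raise SchemaError(f"amyloid rows missing abl at rows {bad}")
    return df


def write_cohort_csv(df: pd.DataFrame, path, config: CohortConfig | None = None,
                     header_comment: str | None = None) -> None:
    """Write the visit table, optionally with a provenance header comment and a
    JSON sidecar echoing the generating config."""
    path = Path(path)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False)
    if config is not None:
        sidecar = path.with_suffix(path.suffix + ".json")
        with open(sidecar, "w") as fh:
            json.dump({"config": config.to_dict()}, fh, indent=2)


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    return validate_cohort_schema(df)
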