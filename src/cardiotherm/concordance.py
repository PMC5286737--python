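"""Lesion-size concordance statistics for the in-vivo ablation series.

Ships the record of 12 ventricular RF ablations performed in 3 sheep
(power, duration, energy, peak temperature, and the 2D lesion
dimensions measured on the real-time thermal-dose maps and on
post-ablation T1-weighted images) and computes the outcome statistics:
RF energy summaries, Pearson correlation and linear regression between
the paired TD-map and T1-w dimensions, and Bland-Altman limits of
agreement.

Pairing convention: each lesion contributes its two printed dimensions,
matched positionally (first with first, second with second), giving
N = 2 x 12 = 24 pairs; an optional flag re-sorts each pair descending
before matching.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AblationRecord",
    "EnergySummary",
    "AgreementStats",
    "load_table1",
    "energy_summary",
    "paired_dimensions",
    "pearson",
    "linear_fit",
    "bland_altman",
    "concordance_analysis",
]

_FIXTURE = "table1_ablations.csv"
_FIXTURE_SHA256 = "9c65e9afe9f182864e69f8a0f027cf70c236bfbf5c2a8ef54d1bb67f232d03f3"


@dataclass(frozen=True)
class AblationRecord:
    """One RF delivery and its measured lesion dimensions."""

    sheep_id: int
    rfa_id: int
    power_w: float
    duration_s: float
    energy_j: float
    temp_max_degc: float
    td_dims_mm: tuple[float, float]
    t1w_dims_mm: tuple[float, float]


def load_table1() -> list[AblationRecord]:
    """Load the packaged 12-ablation record.

    Validates the fixture checksum and the exact identity
    energy = power x duration on every row.
    """
    ref = resources.files("cardiotherm.data") / _FIXTURE
    raw = ref.read_bytes()
    if hashlib.sha256(raw).hexdigest() != _FIXTURE_SHA256:
        raise ValueError("ablation fixture is corrupted (checksum mismatch)")
    df = pd.read_csv(ref.open("r"))
    records = []
    for row in df.itertuples(index=False):
        if row.energy_j != row.power_w * row.duration_s:
            raise ValueError(
                f"energy != power x duration for sheep {row.sheep_id} "
                f"RFA {row.rfa_id}"
            )
        if min(row.td_d1_mm, row.td_d2_mm, row.t1w_d1_mm, row.t1w_d2_mm) <= 0:
            raise ValueError("non-positive lesion dimension in fixture")
        records.append(
            AblationRecord(
                int(row.sheep_id),
                int(row.rfa_id),
                float(row.power_w),
                float(row.duration_s),
                float(row.energy_j),
                float(row.temp_max_degc),
                (float(row.td_d1_mm), float(row.td_d2_mm)),
                (float(row.t1w_d1_mm), float(row.t1w_d2_mm)),
            )
        )
    return records


@dataclass
class EnergySummary:
    """Sample statistics (ddof=1) of the RF deliveries."""

    power_mean_w: float
    power_sd_w: float
    duration_mean_s: float
    duration_sd_s: float
    energy_mean_kj: float
    energy_sd_kj: float
    energy_min_kj: float
    energy_max_kj: float


def energy_summary(records: list[AblationRecord]) -> EnergySummary:
    """Mean/sd power and duration, mean/sd/min/max delivered energy."""
    if len(records) < 2:
        raise ValueError("need at least 2 records")
    P = np.array([r.power_w for r in records])
    D = np.array([r.duration_s for r in records])
    E = np.array([r.energy_j for r in records]) / 1000.0  # kJ
    return EnergySummary(
        float(P.mean()), float(P.std(ddof=1)),
        float(D.mean()), float(D.std(ddof=1)),
        float(E.mean()), float(E.std(ddof=1)),
        float(E.min()), float(E.max()),
    )


def paired_dimensions(
    records: list[AblationRecord], sort_descending: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Paired lesion dimensions: (TD-map, T1-w), 2 per lesion.

    Returns arrays (x, y) with x the TD-map dimensions and y the T1-w
    dimensions, matched positionally within each record (or after
    sorting each pair descending when ``sort_descending``).
    """
    td, t1w = [], []
    for r in records:
        a, b = r.td_dims_mm, r.t1w_dims_mm
        if sort_descending:
            a, b = sorted(a, reverse=True), sorted(b, reverse=True)
        td.extend(a)
        t1w.extend(b)
    return np.array(td, dtype=float), np.array(t1w, dtype=float)


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation; errors on constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(stats.pearsonr(x, y).statistic)


def linear_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Ordinary least squares of y on x: returns (slope, intercept).

    For the lesion analysis the TD-map dimensions are regressed on the
    T1-w dimensions (call as ``linear_fit(t1w, td)``); swap arguments
    for the other orientation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("x and y must be 1D of equal length >= 2")
    if np.ptp(x) == 0:
        raise ValueError("regression undefined for a constant regressor")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept)


@dataclass
class AgreementStats:
    """Pearson/regression/Bland-Altman agreement of paired measurements."""

    r: float
    slope: float
    intercept: float
    bias_mm: float
    sd_diff_mm: float
    loa_low_mm: float
    loa_high_mm: float
    n: int


def bland_altman(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """Bias, SD of differences and 95% limits of agreement for d = x - y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D of equal length")
    if len(x) < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, sd, bias - 1.96 * sd, bias + 1.96 * sd


def concordance_analysis(
    records: list[AblationRecord] | None = None, sort_descending: bool = False
) -> AgreementStats:
    """Full TD-vs-T1w agreement analysis on the 24 paired dimensions."""
    if records is None:
        records = load_table1()
    td, t1w = paired_dimensions(records, sort_descending=sort_descending)
    slope, intercept = linear_fit(t1w, td)
    bias, sd, lo, hi = bland_altman(td, t1w)
    return AgreementStats(
        r=pearson(td, t1w),
        slope=slope,
        intercept=intercept,
        bias_mm=bias,
        sd_diff_mm=sd,
        loa_low_mm=lo,
        loa_high_mm=hi,
        n=len(td),
    )
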