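"""Survey completeness: Chao2 richness, accumulation-curve slope, tiers.

Three metrics score how completely a survey (all records in one grid cell
and time period) inventories its species assemblage:

1. ``n`` — the number of occurrence records;
2. the Chao2 completeness index ``C = S_obs / S_hat``, where ``S_hat`` is
   the bias-corrected Chao2 estimate of true richness from incidence
   frequencies (each record treated as one sampling unit);
3. the final (right-side) slope of the species accumulation curve, the
   expected number of new species added by the last record, which has the
   closed form ``Q1 / n``.

A cell is *well-surveyed* at a threshold tier iff all three criteria hold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln


def _counts_array(counts) -> np.ndarray:
    if hasattr(counts, "counts"):  # SurveyInventory
        counts = list(counts.counts.values())
    c = np.asarray(counts, dtype=np.int64)
    if c.size == 0 or c.sum() < 1:
        raise ValueError("inventory is empty")
    if (c < 1).any():
        raise ValueError("species record counts must be >= 1")
    return c


def chao2_richness(counts, bias_corrected: bool = True) -> float:
    """Chao2 estimate of true species richness from record counts.

    ``counts`` is the per-species record-count vector of one survey (or a
    SurveyInventory).  Each record is one incidence sampling unit, so the
    number of units ``m`` equals the number of records ``n`` and Qk is the
    number of species with exactly k records.

    The default is the bias-corrected form, finite even when Q2 = 0::

        S_hat = S_obs + ((m - 1) / m) * Q1 * (Q1 - 1) / (2 * (Q2 + 1))

    ``bias_corrected=False`` selects the classic form
    ``S_obs + Q1^2 / (2 Q2)`` (infinite when Q2 = 0 and Q1 > 0), kept for
    comparison only.
    """
    c = _counts_array(counts)
    s_obs = c.size
    m = int(c.sum())
    q1 = int((c == 1).sum())
    q2 = int((c == 2).sum())
    if bias_corrected:
        if m == 0:
            return float(s_obs)
        return s_obs + (m - 1) / m * q1 * (q1 - 1) / (2.0 * (q2 + 1))
    if q2 == 0:
        return float("inf") if q1 > 0 else float(s_obs)
    return s_obs + q1 * q1 / (2.0 * q2)


def completeness_index(counts) -> float:
    """Observed / Chao2-estimated richness, in (0, 1]."""
    c = _counts_array(counts)
    return c.size / chao2_richness(c)


def sac_expected_richness(counts, m: int) -> float:
    """Exact expected richness after ``m`` of the ``n`` records.

    Analytic rarefaction over equiprobable record orderings::

        E[S(m)] = S_obs - sum_i C(n - n_i, m) / C(n, m)

    with ``C(a, b) = 0`` when ``a < b``.  Binomial coefficients are taken in
    log space so surveys with thousands of records do not overflow.
    """
    c = _counts_array(counts)
    n = int(c.sum())
    if not 0 <= m <= n:
        raise ValueError(f"subsample size m={m} outside [0, {n}]")
    if m == 0:
        return 0.0
    feasible = (n - c) >= m
    if not feasible.any():
        return float(c.size)
    a = (n - c[feasible]).astype(float)
    log_ratio = (
        gammaln(a + 1)
        - gammaln(a - m + 1)
        - (gammaln(n + 1) - gammaln(n - m + 1))
    )
    return float(c.size - np.exp(log_ratio).sum())


def sac_final_slope(counts) -> float:
    """Final slope of the species accumulation curve: ``Q1 / n``.

    Equals ``E[S(n)] - E[S(n - 1)]`` exactly — the expected number of
    species contributed by the last record over all orderings.  A slope near
    zero means the curve has flattened (the inventory is near asymptote);
    for a single record the slope is 1.
    """
    c = _counts_array(counts)
    n = int(c.sum())
    return float((c == 1).sum()) / n


@dataclass(frozen=True)
class Tier:
    min_records: int
    min_completeness: float
    max_slope: float


@dataclass(frozen=True)
class ThresholdSet:
    """Low / moderate / high well-surveyed thresholds (all inclusive).

    Defaults: low >=10 records, C >= 0.6, slope <= 0.15; moderate >=25,
    >=0.7, <=0.10; high >=50, >=0.8, <=0.05.  Tiers must nest: each tier's
    thresholds are at least as strict as the one below.
    """

    low: Tier = Tier(10, 0.6, 0.15)
    moderate: Tier = Tier(25, 0.7, 0.10)
    high: Tier = Tier(50, 0.8, 0.05)

    def __post_init__(self) -> None:
        t = [self.low, self.moderate, self.high]
        for a, b in zip(t, t[1:]):
            if not (
                a.min_records <= b.min_records
                and a.min_completeness <= b.min_completeness
                and a.max_slope >= b.max_slope
            ):
                raise ValueError("tiers must be monotone low <= moderate <= high")

    def items(self):
        return [("low", self.low), ("moderate", self.moderate), ("high", self.high)]


DEFAULT_THRESHOLDS = ThresholdSet()


def compute_metrics(stats: pd.DataFrame) -> pd.DataFrame:
    """Vectorized completeness metrics for a table of survey stats.

    ``stats`` has one row per survey with columns n, s_obs, q1, q2 (from
    :func:`surveygap.ingest.inventory_stats`).  Adds chao2_s_hat,
    completeness and final_slope columns.
    """
    out = stats.copy()
    n = out["n"].to_numpy(dtype=float)
    s_obs = out["s_obs"].to_numpy(dtype=float)
    q1 = out["q1"].to_numpy(dtype=float)
    q2 = out["q2"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        s_hat = s_obs + (n - 1) / n * q1 * (q1 - 1) / (2.0 * (q2 + 1))
    out["chao2_s_hat"] = s_hat
    out["completeness"] = s_obs / s_hat
    out["final_slope"] = q1 / n
    return out


def classify_cells(
    metrics: pd.DataFrame, thresholds: ThresholdSet = DEFAULT_THRESHOLDS
) -> pd.DataFrame:
    """Flag each survey against the three tiers (conjunction of criteria).

    A survey passes a tier iff records >= min_records AND completeness >=
    min_completeness AND final slope <= max_slope, all comparisons
    inclusive.  Tier nesting (high => moderate => low) follows from the
    threshold monotonicity enforced by :class:`ThresholdSet`.
    """
    out = metrics.copy()
    for name, tier in thresholds.items():
        out[f"pass_{name}"] = (
            (out["n"] >= tier.min_records)
            & (out["completeness"] >= tier.min_completeness)
            & (out["final_slope"] <= tier.max_slope)
        )
    return out


def completeness_summary(
    classified: pd.DataFrame, n_background: int
) -> pd.DataFrame:
    """Dataset x period summary of surveyed and well-surveyed cell counts.

    Per (dataset, period): number of surveyed cells with its percentage of
    all background cells, and per tier the number of well-surveyed cells
    with its percentage of *surveyed* cells.
    """
    if n_background <= 0:
        raise ValueError("background cell count must be positive")
    rows = []
    if classified.empty:
        return pd.DataFrame(
            columns=["dataset", "period", "n_surveyed", "pct_surveyed"]
            + [f"{p}_{t}" for t in ("low", "moderate", "high") for p in ("n", "pct")]
        )
    for (dataset, period), g in classified.groupby(["dataset", "period"], sort=True):
        n_surv = len(g)
        row = {
            "dataset": dataset,
            "period": period,
            "n_surveyed": n_surv,
            "pct_surveyed": 100.0 * n_surv / n_background,
        }
        for tier in ("low", "moderate", "high"):
            n_pass = int(g[f"pass_{tier}"].sum())
            row[f"n_{tier}"] = n_pass
            row[f"pct_{tier}"] = 100.0 * n_pass / n_surv if n_surv else 0.0
        rows.append(row)
    return pd.DataFrame(rows)
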