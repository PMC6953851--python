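"""Most-probable-number (MPN) population estimation and summary arithmetic.

The MPN model: a sample containing ``lambda`` viable cells per gram is
serially diluted; a vial inoculated with ``m`` grams of original material
turns positive iff it receives at least one cell, which under Poisson
sampling happens with probability ``1 - exp(-lambda * m)``.  Given ``g_i``
positives out of ``n_i`` vials at amounts ``m_i``, the maximum-likelihood
estimate of ``lambda`` solves the score equation

    sum_i g_i * m_i * exp(-lambda*m_i) / (1 - exp(-lambda*m_i))
        = sum_i (n_i - g_i) * m_i

An approximate 95% interval comes from the observed-information standard
error of ``ln(lambda)``.  Summary arithmetic reproduces the study's survey
table: per-sample totals are sums of per-medium display MPNs; per-medium
means average over all nine samples including zeros; per-soil means
average the three sample totals per soil.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from scipy.optimize import brentq

from .model import DilutionSeries, Medium, Soil, Source

#: display scale used throughout the survey table (MPN x 10^4 cells/g)
DISPLAY_SCALE = 1e4

_Z95 = 1.959963984540054


@dataclass(frozen=True)
class MpnEstimate:
    """MPN maximum-likelihood estimate for one dilution series."""

    sample_id: str
    lambda_hat: float  # cells/g; 0 if all negative; +inf if unbounded
    ci_low: float
    ci_high: float
    unbounded: bool = False

    @property
    def display_value(self) -> float:
        """MPN on the survey-table scale (x 10^4), 2 decimals."""
        return round(self.lambda_hat / DISPLAY_SCALE, 2)


def _score(lam: float, amounts, n_vials, n_positive) -> float:
    s = 0.0
    for m, n, g in zip(amounts, n_vials, n_positive):
        if g > 0:
            em = math.exp(-lam * m)
            s += g * m * em / (1.0 - em)
        s -= (n - g) * m
    return s


def _observed_information(lam: float, amounts, n_positive) -> float:
    # J(lambda) = sum_i g_i m_i^2 e^{-lam m_i} / (1 - e^{-lam m_i})^2
    j = 0.0
    for m, g in zip(amounts, n_positive):
        if g > 0:
            em = math.exp(-lam * m)
            j += g * m * m * em / (1.0 - em) ** 2
    return j


def estimate_mpn(series: DilutionSeries) -> MpnEstimate:
    """Maximum-likelihood MPN for one dilution series.

    All-negative series give ``lambda_hat = 0`` with an exact-binomial
    upper bound; all-positive series are flagged unbounded (the likelihood
    increases in lambda) and carry only a lower bound.
    """
    amounts, n_vials, n_positive = series.amounts, series.n_vials, series.n_positive
    total_pos = sum(n_positive)
    total_mass = sum(n * m for n, m in zip(n_vials, amounts))

    if total_pos == 0:
        # upper bound: largest lambda with P(all negative) >= 0.05
        return MpnEstimate(series.sample_id, 0.0, 0.0, math.log(20.0) / total_mass)

    if all(g == n for g, n in zip(n_positive, n_vials)):
        # likelihood increasing in lambda: report lower bound only
        def log_p_all_pos(lam: float) -> float:
            return sum(n * math.log1p(-math.exp(-lam * m))
                       for n, m in zip(n_vials, amounts)) - math.log(0.05)

        lo, hi = 1e-12, 1.0 / min(amounts)
        while log_p_all_pos(hi) < 0:
            hi *= 10.0
        ci_low = brentq(log_p_all_pos, lo, hi, rtol=1e-10)
        return MpnEstimate(series.sample_id, math.inf, ci_low, math.inf, unbounded=True)

    lo, hi = 1e-3, 1e12
    f = lambda lam: _score(lam, amounts, n_vials, n_positive)
    while f(lo) < 0 and lo > 1e-300:
        lo /= 10.0
    while f(hi) > 0 and hi < 1e300:
        hi *= 10.0
    lam = brentq(f, lo, hi, rtol=1e-10)

    info = _observed_information(lam, amounts, n_positive)
    se_loglam = 1.0 / (lam * math.sqrt(info)) if info > 0 else math.inf
    ci_low = lam * math.exp(-_Z95 * se_loglam)
    ci_high = lam * math.exp(_Z95 * se_loglam)
    return MpnEstimate(series.sample_id, lam, ci_low, ci_high)


# ---------------------------------------------------------------------------
# Survey-table arithmetic (display MPN values keyed by source/soil/medium)

MEDIA_ORDER = [m.value for m in Medium]
SOIL_ORDER = [s.value for s in Soil]
SOURCE_ORDER = [s.value for s in Source]


def build_mpn_table(rows) -> pd.DataFrame:
    """Assemble the survey MPN table from (source, soil, medium, n, mpn) rows.

    ``mpn`` is on the display scale (x 10^4 cells/g).  Missing combinations
    are allowed and treated as 0 in downstream means and totals.
    """
    df = pd.DataFrame(rows, columns=["source", "soil", "medium", "n", "mpn"])
    df["source"] = df["source"].map(lambda s: Source(s).value)
    df["soil"] = df["soil"].map(lambda s: Soil(s).value)
    df["medium"] = df["medium"].map(lambda m: Medium(m).value)
    if (df["mpn"] < 0).any() or (df["n"] < 0).any():
        raise ValueError("MPN values and isolate counts must be non-negative")
    if df.duplicated(["source", "soil", "medium"]).any():
        raise ValueError("duplicate (source, soil, medium) cell in MPN table")
    return df


def total_mpn(group: pd.DataFrame) -> float:
    """Sample total: sum of per-medium display MPNs, rounded to 2 decimals.

    Includes media with MPN growth but no retrieved isolates (n = 0); an
    empty group totals 0.
    """
    if len(group) == 0:
        return 0.0
    return round(float(group["mpn"].sum()), 2)


def sample_totals(table: pd.DataFrame) -> pd.DataFrame:
    """Per-(source, soil) totals with isolate counts, in canonical order."""
    recs = []
    for source in SOURCE_ORDER:
        for soil in SOIL_ORDER:
            grp = table[(table["source"] == source) & (table["soil"] == soil)]
            if len(grp) == 0:
                continue
            recs.append(
                {"source": source, "soil": soil,
                 "n": int(grp["n"].sum()), "total_mpn": total_mpn(grp)}
            )
    return pd.DataFrame(recs)


def summarize_mpn(table: pd.DataFrame) -> dict:
    """Per-medium means across the 9 samples and per-soil means of totals.

    A sample missing a medium contributes 0 to that medium's mean (the
    divisor is always the number of samples), reproducing the survey's
    printed per-medium arithmetic.
    """
    totals = sample_totals(table)
    n_samples = max(len(totals), 1)

    medium_means = {}
    for medium in MEDIA_ORDER:
        vals = table.loc[table["medium"] == medium, "mpn"]
        medium_means[medium] = round(float(vals.sum()) / n_samples, 2)

    soil_means = {}
    for soil in SOIL_ORDER:
        t = totals.loc[totals["soil"] == soil, "total_mpn"]
        if len(t):
            soil_means[soil] = round(float(t.mean()), 2)

    medium_counts = {
        medium: int(table.loc[table["medium"] == medium, "n"].sum())
        for medium in MEDIA_ORDER
    }
    return {
        "medium_means": medium_means,
        "soil_means": soil_means,
        "medium_isolate_totals": medium_counts,
        "total_isolates": int(table["n"].sum()),
        "sample_totals": totals,
    }


def mpn_table_from_estimates(entries) -> pd.DataFrame:
    """Build the survey table from per-sample-medium MPN estimates.

    ``entries``: iterable of (source, soil, medium, n_isolates, MpnEstimate).
    """
    rows = []
    for source, soil, medium, n, est in entries:
        mpn = 0.0 if est.unbounded else est.display_value
        rows.append((source, soil, medium, n, mpn))
    return build_mpn_table(rows)
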