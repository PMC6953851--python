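"""One-way ANOVA, Scott-Knott clustering of means, and Pearson correlation.

The Scott-Knott procedure partitions sorted treatment means into
non-overlapping groups by recursive binary splitting.  At each node the
split of the k sorted means maximizing the between-group sum of squares

    B0 = T1^2/k1 + T2^2/k2 - (T1+T2)^2/(k1+k2)

is tested with the likelihood-ratio-type statistic

    lambda = pi / (2*(pi - 2)) * B0 / sigma0^2,
    sigma0^2 = (sum_i (ybar_i - ybar)^2 + nu * s2_ybar) / (k + nu),

where ``s2_ybar = MSE / r`` is the estimated variance of a treatment mean
and ``nu`` the ANOVA error degrees of freedom.  The split is accepted when
lambda exceeds the chi-square quantile at 1 - alpha with nu0 = k/(pi - 2)
(non-integer) degrees of freedom, and the procedure recurses on both
halves.  Groups are labelled a, b, c, ... from the highest mean down.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from statistics import harmonic_mean
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

from .model import BiomassObservation, Species


@dataclass
class AnovaResult:
    k: int
    r: float  # replicates per group (harmonic mean when unbalanced)
    f: float
    mse: float
    df_error: int
    means: dict[str, float]  # treatment -> mean
    balanced: bool = True

    @property
    def p_value(self) -> float:
        return float(sps.f.sf(self.f, self.k - 1, self.df_error))


def one_way_anova(obs: Iterable[BiomassObservation], species: Species | str,
                  response: str) -> AnovaResult:
    """Textbook one-way ANOVA of a biomass response for one species.

    ``response`` is ``"rdw"`` or ``"sdw"``.  Requires >= 2 treatments with
    >= 2 replicates each.
    """
    species = Species(species)
    if response not in ("rdw", "sdw"):
        raise ValueError("response must be 'rdw' or 'sdw'")
    groups: dict[str, list[float]] = {}
    for o in obs:
        if o.species == species:
            groups.setdefault(o.treatment, []).append(getattr(o, response))
    if len(groups) < 2:
        raise ValueError("need at least 2 treatment groups")
    for t, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"treatment {t!r} has fewer than 2 replicates")

    sizes = [len(v) for v in groups.values()]
    all_vals = np.concatenate([np.asarray(v) for v in groups.values()])
    grand = all_vals.mean()
    ss_between = sum(len(v) * (np.mean(v) - grand) ** 2 for v in groups.values())
    ss_within = sum(((np.asarray(v) - np.mean(v)) ** 2).sum() for v in groups.values())
    k = len(groups)
    df_error = len(all_vals) - k
    mse = ss_within / df_error
    ms_between = ss_between / (k - 1)
    f = ms_between / mse if mse > 0 else (0.0 if ss_between == 0 else math.inf)
    return AnovaResult(
        k=k,
        r=float(harmonic_mean(sizes)),
        f=float(f),
        mse=float(mse),
        df_error=df_error,
        means={t: float(np.mean(v)) for t, v in groups.items()},
        balanced=len(set(sizes)) == 1,
    )


@dataclass
class MeansGrouping:
    """Partition of treatments into Scott-Knott groups.

    ``clusters`` lists treatments grouped together, ordered by descending
    group mean; labels run a, b, c, ... from the highest mean down.
    """

    clusters: list[list[str]]
    means: dict[str, float]
    labels: dict[str, str] = field(init=False)

    def __post_init__(self) -> None:
        self.labels = {}
        for idx, cluster in enumerate(self.clusters):
            label = _letter(idx)
            for t in cluster:
                self.labels[t] = label

    def cluster_index(self, treatment: str) -> int:
        """0-based rank of the treatment's cluster (0 = highest mean)."""
        for idx, cluster in enumerate(self.clusters):
            if treatment in cluster:
                return idx
        raise KeyError(treatment)


def _letter(idx: int) -> str:
    out = ""
    idx += 1
    while idx:
        idx, rem = divmod(idx - 1, 26)
        out = chr(ord("a") + rem) + out
    return out


_PI_FACTOR = math.pi / (2.0 * (math.pi - 2.0))


def _sk_split(means: Sequence[float]) -> tuple[float, int]:
    """Best contiguous split of sorted means: returns (max B0, split index)."""
    k = len(means)
    total = sum(means)
    best_b0, best_idx = -math.inf, 1
    t1 = 0.0
    for i in range(1, k):
        t1 += means[i - 1]
        t2 = total - t1
        b0 = t1 * t1 / i + t2 * t2 / (k - i) - total * total / k
        if b0 > best_b0:
            best_b0, best_idx = b0, i
    return best_b0, best_idx


def scott_knott(anova: AnovaResult, alpha: float = 0.05) -> MeansGrouping:
    """Scott-Knott clustering of the ANOVA treatment means at level alpha."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    order = sorted(anova.means, key=lambda t: (-anova.means[t], t))
    s2_ybar = anova.mse / anova.r
    nu = anova.df_error

    clusters: list[list[str]] = []

    def recurse(treatments: list[str]) -> None:
        k = len(treatments)
        if k == 1:
            clusters.append(treatments)
            return
        means = [anova.means[t] for t in treatments]
        b0, idx = _sk_split(means)
        ybar = sum(means) / k
        sigma0_sq = (sum((m - ybar) ** 2 for m in means) + nu * s2_ybar) / (k + nu)
        if sigma0_sq <= 0:
            clusters.append(treatments)
            return
        lam = _PI_FACTOR * b0 / sigma0_sq
        nu0 = k / (math.pi - 2.0)
        if lam > sps.chi2.ppf(1.0 - alpha, nu0):
            recurse(treatments[:idx])
            recurse(treatments[idx:])
        else:
            clusters.append(treatments)

    recurse(order)
    return MeansGrouping(clusters=clusters, means=dict(anova.means))


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Product-moment correlation with two-sided p from the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)
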