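"""Separability statistics: Wilcoxon signed-ranks screening and Fisher ranking.

Per texture parameter, paired observations from two arms (two ROI kinds at a
fixed sequence and thickness, or two thicknesses within one ROI kind) are
compared with a two-sided Wilcoxon signed-ranks test; the share of the 264
parameters with p < alpha is the separability measure.  Feature selection
for classification uses the Fisher coefficient F = D / V (between-classes
variance over within-classes variance).  No multiple-testing correction is
applied: the proportion of raw p-values below alpha *is* the statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .features.names import FEATURE_NAMES

__all__ = [
    "WilcoxonResult",
    "wilcoxon_signed_rank",
    "SeparabilityReport",
    "separability",
    "FisherRanking",
    "fisher_rank",
]


@dataclass(frozen=True)
class WilcoxonResult:
    p_value: float
    statistic: float  # W+ = sum of ranks of positive differences
    n_nonzero: int    # sample size after zero-difference removal
    all_zero: bool = False
    exact: bool = True


def _exact_two_sided_p(double_ranks: np.ndarray, w_plus_doubled: int) -> float:
    """Exact two-sided p by enumeration of the signed-rank null.

    Equivalent to enumerating all 2^n equiprobable sign assignments: the
    distribution of the (doubled, hence integer) positive-rank sum is built
    by dynamic programming, and p = 2 * min(P(W+ <= w), P(W+ >= w)), capped
    at 1.  Mid-ranks (ties) are supported because doubling makes them
    integers.
    """
    total = int(double_ranks.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in double_ranks:
        r = int(r)
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[:-r] if r > 0 else dist
        dist = dist + shifted
    dist /= dist.sum()
    cdf = float(dist[: w_plus_doubled + 1].sum())
    sf = float(dist[w_plus_doubled:].sum())
    return min(1.0, 2.0 * min(cdf, sf))


def wilcoxon_signed_rank(differences, exact_max_n: int = 25) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-ranks test on paired differences.

    Zero differences are removed (Wilcoxon's original treatment); ties in
    |difference| receive mid-ranks.  Up to ``exact_max_n`` remaining
    differences the p-value is exact (full enumeration of the sign-flip
    null); beyond that a normal approximation with tie and continuity
    corrections is used.  All differences zero yields p = 1 with a flag.
    """
    d = np.asarray(differences, dtype=np.float64)
    if d.ndim != 1 or d.size == 0:
        raise ValueError("differences must be a non-empty 1D array")
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        return WilcoxonResult(p_value=1.0, statistic=0.0, n_nonzero=0, all_zero=True)
    ranks = sps.rankdata(np.abs(d))  # mid-ranks
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        double_ranks = np.rint(2.0 * ranks).astype(np.int64)
        w2 = int(np.rint(2.0 * w_plus))
        p = _exact_two_sided_p(double_ranks, w2)
        return WilcoxonResult(p_value=p, statistic=w_plus, n_nonzero=n, exact=True)
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, counts = np.unique(ranks, return_counts=True)
    var -= float(((counts ** 3 - counts).sum())) / 48.0
    if var <= 0:
        return WilcoxonResult(p_value=1.0, statistic=w_plus, n_nonzero=n, exact=False)
    delta = w_plus - mean
    z = (delta - 0.5 * np.sign(delta)) / np.sqrt(var)  # continuity correction
    p = min(1.0, 2.0 * float(sps.norm.sf(abs(z))))
    return WilcoxonResult(p_value=p, statistic=w_plus, n_nonzero=n, exact=False)


# ---------------------------------------------------------------------------
# separability screening over a feature table
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class SeparabilityReport:
    contrast: tuple[dict, dict]
    p_values: pd.Series            # per feature (NaN = excluded)
    alpha: float
    n_pairs: int
    n_tested: int
    n_excluded_features: int
    percent_significant: float
    dropped_units: list = field(default_factory=list)


def _select_arm(table: pd.DataFrame, selector: dict, pairing: tuple[str, ...]) -> pd.DataFrame:
    sub = table
    for col, val in selector.items():
        sub = sub[sub[col] == val]
    if sub.empty:
        raise ValueError(f"no rows match arm selector {selector}")
    sub = sub.set_index(list(pairing))
    if sub.index.has_duplicates:
        raise ValueError(f"arm {selector} has multiple rows per pairing unit")
    return sub


def separability(
    table: pd.DataFrame,
    arm_a: dict,
    arm_b: dict,
    pairing: tuple[str, ...] = ("subject", "level"),
    alpha: float = 0.05,
    feature_columns: list[str] | None = None,
) -> SeparabilityReport:
    """Paired per-feature Wilcoxon screening between two arms of a feature table.

    ``arm_a`` / ``arm_b`` are column -> value selectors, e.g.
    ``{"roi_kind": "WM", "sequence": "T1", "thickness": "1mm"}``.  Pairing
    units (default subject x level) missing from either arm are dropped with
    a warning; features whose pairwise-complete sample is empty are excluded
    and counted.
    """
    feats = list(feature_columns) if feature_columns is not None else [
        f for f in FEATURE_NAMES if f in table.columns
    ]
    a = _select_arm(table, arm_a, pairing)
    b = _select_arm(table, arm_b, pairing)
    units = a.index.intersection(b.index).sort_values()
    dropped = list(a.index.symmetric_difference(b.index))
    if dropped:
        warnings.warn(
            f"{len(dropped)} pairing unit(s) missing one arm were excluded: "
            f"{dropped[:5]}{'...' if len(dropped) > 5 else ''}",
            stacklevel=2,
        )
    if len(units) == 0:
        raise ValueError("no pairing unit present in both arms")
    diffs = a.loc[units, feats].to_numpy(dtype=float) - b.loc[units, feats].to_numpy(dtype=float)
    p_values = {}
    n_sig = n_tested = n_excluded = 0
    for k, f in enumerate(feats):
        d = diffs[:, k]
        d = d[~np.isnan(d)]
        if d.size == 0:
            p_values[f] = float("nan")
            n_excluded += 1
            continue
        res = wilcoxon_signed_rank(d)
        p_values[f] = res.p_value
        n_tested += 1
        if res.p_value < alpha:
            n_sig += 1
    percent = 100.0 * n_sig / n_tested if n_tested else float("nan")
    return SeparabilityReport(
        contrast=(arm_a, arm_b),
        p_values=pd.Series(p_values),
        alpha=alpha,
        n_pairs=len(units),
        n_tested=n_tested,
        n_excluded_features=n_excluded,
        percent_significant=percent,
        dropped_units=dropped,
    )


# ---------------------------------------------------------------------------
# Fisher-coefficient feature ranking
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class FisherRanking:
    f_values: pd.Series      # per feature; +inf marks V = 0 with D > 0
    top_k: list[str]
    excluded: list[str]      # undefined or 0/0 features


def fisher_rank(
    features: pd.DataFrame,
    labels,
    top_k: int = 3,
) -> FisherRanking:
    """Rank features by the Fisher coefficient F = D / V for a two-class problem.

    D is the population variance of the two class means about their
    unweighted grand mean, V the unweighted mean of the two within-class
    population variances.  V = 0 with D > 0 yields +inf (ranked above every
    finite value); V = D = 0 and features containing undefined values are
    excluded.  Ties are broken lexicographically by feature name.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(f"fisher_rank needs exactly two classes, got {classes!r}")
    x = features.to_numpy(dtype=float)
    masks = [labels == c for c in classes]
    if min(m.sum() for m in masks) < 2:
        raise ValueError("each class needs at least 2 observations")
    names = list(features.columns)
    undefined = np.isnan(x).any(axis=0)
    m0 = x[masks[0]].mean(axis=0)
    m1 = x[masks[1]].mean(axis=0)
    v0 = x[masks[0]].var(axis=0)  # population
    v1 = x[masks[1]].var(axis=0)
    d_between = 0.25 * (m0 - m1) ** 2  # variance of the two means about their mean
    v_within = 0.5 * (v0 + v1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(v_within > 0.0, d_between / v_within, np.inf)
    f[(v_within == 0.0) & (d_between == 0.0)] = np.nan  # 0/0: excluded
    f[undefined] = np.nan
    series = pd.Series(f, index=names)
    excluded = [n for n, bad in zip(names, np.isnan(f)) if bad]
    ranked = sorted(
        (n for n in names if not np.isnan(series[n])),
        key=lambda n: (-series[n], n),
    )
    return FisherRanking(f_values=series, top_k=ranked[:top_k], excluded=excluded)
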