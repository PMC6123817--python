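"""Matched-pair replication stage and power analysis.

Carriers of a rare variant are matched to non-carrier controls on sex,
year of birth, and serum-sample year (within one year); the paired
difference in assay values (triplicate means) is tested with a
Wilcoxon signed-rank test (exact for small n, normal approximation with
continuity correction otherwise) and with a paired t-test on log
values.  Discovery and replication p-values are combined with Fisher's
method.  The power functions use the standard normal approximation for
an additive dosage with variance 2*maf*(1-maf) against a unit-variance
trait.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError

__all__ = [
    "MatchedPairSet",
    "ReplicationResult",
    "CombinedResult",
    "triplicate_mean",
    "match_controls",
    "wilcoxon_signed_rank",
    "paired_log_t",
    "fold_summary",
    "fisher_combine",
    "min_detectable_effect",
    "power_at",
    "replication_report",
]

ASSAY_RANGE = (2.5, 200.0)  # reported range of the ELISA, IU/L


@dataclass
class MatchedPair:
    carrier: str
    control: str
    carrier_value: float
    control_value: float
    sex: int
    carrier_birth_year: int
    control_birth_year: int
    sample_year_diff: int


@dataclass
class MatchedPairSet:
    pairs: list[MatchedPair]
    unmatched: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def carrier_values(self) -> np.ndarray:
        return np.array([p.carrier_value for p in self.pairs])

    @property
    def control_values(self) -> np.ndarray:
        return np.array([p.control_value for p in self.pairs])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(p) for p in self.pairs])


@dataclass
class ReplicationResult:
    n_pairs: int
    carrier_median: float
    control_median: float
    ratio_of_medians: float
    median_of_ratios: float
    wilcoxon_p: float
    paired_log_t_p: float


@dataclass
class CombinedResult:
    p_values: list[float]
    statistic: float
    df: int
    combined_p: float


def triplicate_mean(replicates, assay_range=ASSAY_RANGE) -> tuple[float, bool]:
    """Arithmetic mean of replicate assay values (normally 3).

    Returns ``(mean, flagged)``; flagged when fewer than 3 replicates
    were supplied or any replicate falls outside the assay's reported
    range.  Out-of-range replicates are still averaged.
    """
    vals = np.asarray(list(replicates), dtype=float)
    if vals.size == 0:
        raise ValueError("need at least one replicate")
    flagged = vals.size != 3 or bool(
        ((vals < assay_range[0]) | (vals > assay_range[1])).any()
    )
    return float(vals.mean()), flagged


def match_controls(carriers: list[str], pool: list[str],
                   metadata: pd.DataFrame,
                   values: pd.Series | None = None,
                   max_sample_year_diff: int = 1) -> MatchedPairSet:
    """Greedy deterministic matching of carriers to pool controls.

    Carriers are processed sorted by id; each receives the available
    control of the same sex with minimal |year-of-birth difference|
    among those with |sample-year difference| <= 1, ties broken by
    smaller control id.  No control is reused; carriers with no
    eligible control are reported unmatched.

    ``metadata`` is indexed by id with columns sex, birth_year,
    sample_year; ``values`` (assay means, by id) fill the pair values
    when given.
    """
    if set(carriers) & set(pool):
        raise ValueError("carrier and control pools must be disjoint")
    meta = metadata
    pairs: list[MatchedPair] = []
    unmatched: list[str] = []
    available = set(pool)
    for car in sorted(carriers):
        crow = meta.loc[car]
        best = None
        for ctl in sorted(available):
            prow = meta.loc[ctl]
            if int(prow["sex"]) != int(crow["sex"]):
                continue
            sy = abs(int(prow["sample_year"]) - int(crow["sample_year"]))
            if sy > max_sample_year_diff:
                continue
            by = abs(int(prow["birth_year"]) - int(crow["birth_year"]))
            key = (by, ctl)
            if best is None or key < best[0]:
                best = (key, ctl, sy)
        if best is None:
            unmatched.append(car)
            continue
        _, ctl, sy = best
        available.discard(ctl)
        cv = float(values.loc[car]) if values is not None else float("nan")
        pv = float(values.loc[ctl]) if values is not None else float("nan")
        pairs.append(
            MatchedPair(
                carrier=car, control=ctl, carrier_value=cv, control_value=pv,
                sex=int(crow["sex"]),
                carrier_birth_year=int(crow["birth_year"]),
                control_birth_year=int(meta.loc[ctl, "birth_year"]),
                sample_year_diff=sy,
            )
        )
    return MatchedPairSet(pairs=pairs, unmatched=unmatched)


# ---------------------------------------------------------------------------
# Paired tests
# ---------------------------------------------------------------------------

def _wilcoxon_exact_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p by dynamic programming over the 2^n sign
    assignments.  Ranks may be half-integral (average ranks under ties);
    doubling makes all sums integral."""
    r2 = np.round(2 * ranks).astype(int)
    total = int(r2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        nxt = dist.copy()
        nxt[r:] += dist[: total + 1 - r]
        dist = nxt
    dist /= dist.sum()
    w2 = int(round(2 * w_plus))
    lower = dist[: w2 + 1].sum()
    upper = dist[w2:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


def wilcoxon_signed_rank(pairs: MatchedPairSet | np.ndarray,
                         exact_limit: int = 25,
                         continuity: bool = True) -> float:
    """Two-sided Wilcoxon signed-rank p for paired differences.

    Zero differences are dropped; tied absolute differences share the
    average rank.  Up to ``exact_limit`` nonzero differences the exact
    null distribution is enumerated; beyond that the normal
    approximation (with tie-corrected variance and optional continuity
    correction) is used.  All differences zero returns p = 1.
    """
    if isinstance(pairs, MatchedPairSet):
        d = pairs.carrier_values - pairs.control_values
    else:
        d = np.asarray(pairs, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    ranks = stats.rankdata(np.abs(d), method="average")
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_limit:
        return _wilcoxon_exact_p(ranks, w_plus)
    mean = n * (n + 1) / 4.0
    # variance with tie correction
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
    dev = w_plus - mean
    if continuity:
        dev = np.sign(dev) * max(abs(dev) - 0.5, 0.0)
    z = dev / math.sqrt(var)
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def paired_log_t(pairs: MatchedPairSet) -> float:
    """Two-sided paired t-test on log-transformed values, df = n - 1."""
    cv, tv = pairs.carrier_values, pairs.control_values
    if len(pairs) < 2:
        raise ValueError("need at least 2 pairs")
    if (cv <= 0).any() or (tv <= 0).any():
        raise ValueError("log-scale paired t requires positive values")
    d = np.log(cv) - np.log(tv)
    if np.ptp(d) < 1e-12 * max(1.0, np.abs(d).max()):
        if abs(d[0]) < 1e-300:
            return 1.0
        return float(np.finfo(float).tiny)  # zero variance, nonzero shift
    t = stats.ttest_rel(np.log(cv), np.log(tv))
    return float(t.pvalue)


def fold_summary(pairs: MatchedPairSet) -> ReplicationResult:
    """Median-based fold summaries plus both paired tests.

    Reports both the ratio of group medians and the median of the
    per-pair carrier/control ratios; the two conventions differ in
    general.  Pairs with a zero control value are excluded from the
    ratio-based summary.
    """
    cv, tv = pairs.carrier_values, pairs.control_values
    if len(pairs) == 0:
        raise ValueError("no pairs")
    cm, tm = float(np.median(cv)), float(np.median(tv))
    ok = tv != 0
    med_ratio = float(np.median(cv[ok] / tv[ok])) if ok.any() else float("nan")
    return ReplicationResult(
        n_pairs=len(pairs),
        carrier_median=cm,
        control_median=tm,
        ratio_of_medians=cm / tm if tm != 0 else float("nan"),
        median_of_ratios=med_ratio,
        wilcoxon_p=wilcoxon_signed_rank(pairs),
        paired_log_t_p=paired_log_t(pairs) if len(pairs) >= 2 else float("nan"),
    )


replication_report = fold_summary


def fisher_combine(p_values) -> CombinedResult:
    """Fisher's combined probability test: X = -2 sum ln p_i, compared
    to chi-square with 2k degrees of freedom."""
    ps = [float(p) for p in p_values]
    if not ps:
        raise ValueError("need at least one p-value")
    for p in ps:
        if p <= 0:
            raise ValueError("p = 0 is invalid for Fisher's method")
        if p > 1:
            raise ValueError("p-values must be <= 1")
    x = -2.0 * sum(math.log(p) for p in ps)
    df = 2 * len(ps)
    return CombinedResult(p_values=ps, statistic=x, df=df,
                          combined_p=float(stats.chi2.sf(x, df)))


# ---------------------------------------------------------------------------
# Power
# ---------------------------------------------------------------------------

def _check_power_args(n: int, maf: float, alpha: float) -> float:
    if n <= 0:
        raise ConfigurationError("N must be positive")
    if not (0 < maf < 1):
        raise ConfigurationError("maf must be in (0, 1)")
    if not (0 < alpha < 1):
        raise ConfigurationError("alpha must be in (0, 1)")
    v = n * 2.0 * maf * (1.0 - maf)
    if v <= 0:
        raise ConfigurationError("no information: N * 2 maf (1-maf) = 0")
    return v


def min_detectable_effect(n: int, maf: float, alpha: float = 0.05,
                          power: float = 0.80) -> float:
    """Smallest per-allele effect (SD units) detectable at the given
    two-sided alpha and power:
    (z_{1-alpha/2} + z_{power}) / sqrt(N * 2 maf (1-maf))."""
    v = _check_power_args(n, maf, alpha)
    if power <= alpha:
        raise ConfigurationError("power must exceed alpha")
    return float((stats.norm.ppf(1 - alpha / 2) + stats.norm.ppf(power)) / math.sqrt(v))


def power_at(n: int, maf: float, effect: float, alpha: float = 0.05) -> float:
    """Power of the two-sided test at the given effect (the negligible
    opposite tail is dropped):
    1 - CDF(z_{1-alpha/2} - |effect| sqrt(N * 2 maf (1-maf)))."""
    v = _check_power_args(n, maf, alpha)
    return float(stats.norm.sf(stats.norm.ppf(1 - alpha / 2)
                               - abs(effect) * math.sqrt(v)))
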