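"""Scan calibration: LD scores, LD-score-regression intercept
correction, and annotation-class-weighted genome-wide significance.

The weighted Bonferroni scheme assigns each annotation class c (with
N_c variants and relative weight w_c) the per-test threshold

    alpha_c = w_c * FWER / sum_d N_d * w_d

so that sum_c N_c * alpha_c equals the family-wise error rate and the
thresholds stand in the ratio of the weights.  A raw p-value is
reported as corrected p = p * FWER / alpha_class, so genome-wide
significance is corrected p < FWER regardless of class.

The LD-score regression fits chi-square statistics against per-variant
LD scores by OLS; the intercept measures confounding inflation and is
applied as a divisor of the chi-square statistics only when it exceeds
1 (a deflated scan is never inflated into significance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError

__all__ = [
    "ThresholdScheme",
    "LdscFit",
    "DEFAULT_CLASS_WEIGHTS",
    "STUDY_CLASS_COUNTS",
    "ld_scores",
    "ldsc_intercept",
    "weighted_thresholds",
    "solve_missing_threshold",
    "corrected_p",
    "apply_correction",
]

# Relative class weights back-derived from the ratios of published
# per-class genome-wide thresholds (high : moderate : low : DHS : other);
# the absolute scale is irrelevant, only ratios matter.
DEFAULT_CLASS_WEIGHTS = {
    "high": 2.6e-7 / 7.9e-10,
    "moderate": 5.1e-8 / 7.9e-10,
    "low": 4.6e-9 / 7.9e-10,
    "DHS": 2.3e-9 / 7.9e-10,
    "other": 1.0,
}

# Published per-class variant counts for a ~32.5M-variant scan.
STUDY_CLASS_COUNTS = {
    "high": 8_464,
    "moderate": 149_983,
    "low": 2_283_889,
    "DHS": 3_913_058,
    "other": 26_108_038,
}


@dataclass
class ThresholdScheme:
    """Per-class significance thresholds controlling the FWER."""

    classes: list[str]
    counts: dict[str, int]
    weights: dict[str, float]
    thresholds: dict[str, float]
    fwer: float = 0.05

    def alpha(self, cls: str) -> float:
        try:
            return self.thresholds[cls]
        except KeyError:
            raise KeyError(f"unknown annotation class {cls!r}") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class": self.classes,
                "count": [self.counts[c] for c in self.classes],
                "weight": [self.weights[c] for c in self.classes],
                "threshold": [self.thresholds[c] for c in self.classes],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, fwer: float = 0.05) -> "ThresholdScheme":
        return cls(
            classes=df["class"].tolist(),
            counts=dict(zip(df["class"], df["count"].astype(int))),
            weights=dict(zip(df["class"], df["weight"].astype(float))),
            thresholds=dict(zip(df["class"], df["threshold"].astype(float))),
            fwer=fwer,
        )


@dataclass
class LdscFit:
    intercept: float
    slope: float
    n_variants: int
    flagged: bool = False

    @property
    def correction_factor(self) -> float:
        """The factor actually applied: max(intercept, 1)."""
        return max(self.intercept, 1.0)


def ld_scores(panel: np.ndarray | pd.DataFrame, window: int = 50) -> np.ndarray:
    """Windowed LD score per variant.

    score_j = 1 + sum over k != j within ``window`` positions of the
    bias-adjusted squared correlation r2_adj = r2 - (1 - r2)/(n - 2),
    floored at 0 per pair.  Monomorphic variants contribute 0 to their
    neighbours and receive score 1 (flagged NaN-free).
    """
    X = np.asarray(panel, dtype=float)
    n, m = X.shape
    if m < 2:
        raise ValueError("need at least 2 variants")
    if window < 1:
        raise ValueError("window must be >= 1")
    sd = X.std(axis=0)
    poly = sd > 0
    Z = np.zeros_like(X)
    Z[:, poly] = (X[:, poly] - X[:, poly].mean(axis=0)) / sd[poly]
    scores = np.ones(m)
    for j in range(m):
        lo, hi = max(0, j - window), min(m, j + window + 1)
        if not poly[j]:
            continue
        r = Z[:, lo:hi].T @ Z[:, j] / n
        r2 = r**2
        r2adj = np.maximum(r2 - (1.0 - r2) / max(n - 2, 1), 0.0)
        r2adj[j - lo] = 0.0  # self
        r2adj[~poly[lo:hi]] = 0.0
        scores[j] += r2adj.sum()
    return scores


def ldsc_intercept(chi2: np.ndarray, scores: np.ndarray,
                   min_variants: int = 100) -> LdscFit:
    """OLS regression of per-variant chi-square on LD score."""
    chi2 = np.asarray(chi2, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if chi2.size != scores.size:
        raise ValueError("chi2 and scores length mismatch")
    if chi2.size < min_variants:
        raise ValueError(f"need at least {min_variants} variants")
    if np.ptp(scores) == 0:
        return LdscFit(intercept=float(chi2.mean()), slope=float("nan"),
                       n_variants=chi2.size, flagged=True)
    slope, intercept = np.polyfit(scores, chi2, 1)
    return LdscFit(intercept=float(intercept), slope=float(slope),
                   n_variants=chi2.size)


def apply_correction(chi2: np.ndarray, fit: LdscFit) -> tuple[np.ndarray, np.ndarray]:
    """Divide chi-square statistics by the applied factor (>= 1) and
    recompute 1-df p-values."""
    factor = fit.correction_factor
    corr = np.asarray(chi2, dtype=float) / factor
    return corr, stats.chi2.sf(corr, df=1)


def weighted_thresholds(counts: dict[str, int], weights: dict[str, float],
                        fwer: float = 0.05) -> ThresholdScheme:
    """Weighted Bonferroni: alpha_c = w_c * fwer / sum_d N_d * w_d."""
    if set(counts) != set(weights):
        raise ConfigurationError("counts and weights must cover the same classes")
    if fwer <= 0 or fwer >= 1:
        raise ConfigurationError("fwer must be in (0, 1)")
    for c in counts:
        if counts[c] <= 0:
            raise ConfigurationError(f"count for class {c!r} must be positive")
        if weights[c] <= 0:
            raise ConfigurationError(f"weight for class {c!r} must be positive")
    denom = sum(counts[c] * weights[c] for c in counts)
    thresholds = {c: weights[c] * fwer / denom for c in counts}
    return ThresholdScheme(
        classes=list(counts), counts=dict(counts), weights=dict(weights),
        thresholds=thresholds, fwer=fwer,
    )


def study_threshold_scheme(fwer: float = 0.05) -> ThresholdScheme:
    """The packaged default scheme: published class counts with the
    back-derived weight ratios."""
    return weighted_thresholds(STUDY_CLASS_COUNTS, DEFAULT_CLASS_WEIGHTS, fwer)


def solve_missing_threshold(known: list[tuple[int, float]], n_missing: int,
                            fwer: float = 0.05) -> float:
    """Threshold for one unlisted class so the scheme exhausts the FWER:
    alpha = (fwer - sum N_c * alpha_c) / N_missing."""
    if n_missing <= 0:
        raise ConfigurationError("n_missing must be positive")
    spent = sum(n * a for n, a in known)
    numer = fwer - spent
    if numer <= 0:
        raise ConfigurationError(
            f"known classes already spend {spent:g} >= fwer {fwer:g}"
        )
    return numer / n_missing


def corrected_p(p: float, cls: str, scheme: ThresholdScheme) -> float:
    """Class-weighted corrected p-value: min(1, p * fwer / alpha_class).

    Significant iff raw p < alpha_class iff corrected p < fwer.
    """
    if not (0 < p <= 1):
        raise ValueError("p must be in (0, 1]")
    alpha = scheme.alpha(cls)
    return min(1.0, p * scheme.fwer / alpha)


def annotate_scan(results: pd.DataFrame, scheme: ThresholdScheme,
                  class_col: str = "annotation", p_col: str = "p") -> pd.DataFrame:
    """Add corrected_p and significant columns to scan results."""
    out = results.copy()
    out["corrected_p"] = [
        corrected_p(p, c, scheme) if np.isfinite(p) else np.nan
        for p, c in zip(out[p_col], out[class_col])
    ]
    out["significant"] = out["corrected_p"] < scheme.fwer
    return out
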