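"""Raw measurements to analysis-ready standardized phenotypes.

The discovery-phase pipeline is: collapse repeated measurements to one
value per individual (arithmetic mean on the raw scale), residualize on
sex and year of birth by OLS, then rank inverse-normal transform so the
final phenotype is standard normal.  A separate stratified path
(per sex x laboratory inverse-normal plus a smooth age adjustment)
mirrors how large multi-laboratory blood measurements are standardized.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import interpolate, stats

from .errors import DegenerateInputError

logger = logging.getLogger(__name__)

__all__ = [
    "PhenotypeVector",
    "collapse_repeats",
    "residualize",
    "inverse_normal",
    "standardize_stratified",
]


@dataclass
class PhenotypeVector:
    """Standardized (unitless, target standard-normal) phenotype."""

    ids: list[str]
    values: np.ndarray
    n_measurements: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.ids) != self.values.size:
            raise ValueError("ids and values length mismatch")

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=pd.Index(self.ids, name="iid"),
                         name="phenotype")


def collapse_repeats(measurements: pd.DataFrame) -> pd.DataFrame:
    """One row per individual: arithmetic mean of raw-scale values.

    Expects columns iid, value and carries sex / birth_year (and any
    other constant-per-individual columns present) through.  Individuals
    with no finite measurement are dropped and logged.
    """
    df = measurements.copy()
    df = df[np.isfinite(df["value"])]
    dropped = set(measurements["iid"]) - set(df["iid"])
    if dropped:
        logger.warning("excluded %d individuals with no usable measurement", len(dropped))
    keep_cols = [c for c in ("sex", "birth_year", "lab", "measurement_year")
                 if c in df.columns]
    named = {
        "value": pd.NamedAgg("value", "mean"),
        "n_measurements": pd.NamedAgg("value", "size"),
        **{c: pd.NamedAgg(c, "first") for c in keep_cols},
    }
    out = df.groupby("iid", sort=True).agg(**named)
    return out.reset_index()


def residualize(values: pd.Series, covariates: pd.DataFrame) -> pd.Series:
    """OLS residuals of value on an intercept plus the covariate columns.

    Constant covariate columns are dropped with a warning.  Residuals
    sum to zero (intercept always included).
    """
    y = values.to_numpy(dtype=float)
    cols = []
    names = []
    for c in covariates.columns:
        x = covariates[c].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            warnings.warn(f"covariate {c!r} is constant; dropped", stacklevel=2)
            continue
        cols.append(x)
        names.append(c)
    X = np.column_stack([np.ones_like(y)] + cols)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return pd.Series(resid, index=values.index, name="residual")


def inverse_normal(values: pd.Series | np.ndarray,
                   offset: float = 0.5) -> np.ndarray:
    """Rank-based inverse-normal transform: Probit((rank - offset) / n).

    Ties receive the average rank, making the transform deterministic
    and invariant under any strictly monotone transformation of the
    input.  ``offset`` = 0.5 by default; 3/8 with denominator n + 1/4
    (Blom) is available via ``offset="blom"``.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("inverse_normal needs at least 3 values")
    if np.ptp(x) == 0:
        raise DegenerateInputError("all values identical; transform undefined")
    ranks = stats.rankdata(x, method="average")
    if offset == "blom":
        q = (ranks - 3.0 / 8.0) / (n + 0.25)
    else:
        q = (ranks - float(offset)) / n
    return stats.norm.ppf(q)


def prepare_phenotype(measurements: pd.DataFrame,
                      covariate_scale: str = "log") -> PhenotypeVector:
    """Full discovery-phase pipeline: collapse, residualize on sex and
    year of birth, inverse-normal transform.

    For a positive, right-skewed trait the covariate correction is done
    on the log scale by default: covariate effects on such traits are
    multiplicative, and an additive fit on the raw scale perturbs the
    ranks that the inverse-normal step consumes, attenuating genetic
    effects.  ``covariate_scale="linear"`` fits the raw values instead.
    """
    per_ind = collapse_repeats(measurements)
    vals = per_ind["value"]
    if covariate_scale == "log":
        if (vals <= 0).any():
            raise ValueError("log-scale correction requires positive values")
        vals = np.log(vals)
    elif covariate_scale != "linear":
        raise ValueError("covariate_scale must be 'log' or 'linear'")
    resid = residualize(vals, per_ind[["sex", "birth_year"]].astype(float))
    z = inverse_normal(resid)
    return PhenotypeVector(
        ids=per_ind["iid"].tolist(),
        values=z,
        n_measurements=per_ind["n_measurements"].to_numpy(),
    )


def _smooth_age_trend(age: np.ndarray, z: np.ndarray) -> np.ndarray:
    """GCV-penalized cubic smoothing spline fit of z on age, evaluated at
    each input age.  Duplicate ages are averaged before fitting."""
    order = np.argsort(age, kind="stable")
    a_sorted = age[order]
    z_sorted = z[order]
    uniq, inverse = np.unique(a_sorted, return_inverse=True)
    if uniq.size < 4:
        # too few distinct ages for a cubic spline: use the stratum mean
        return np.full_like(z, z.mean())
    zbar = np.bincount(inverse, weights=z_sorted) / np.bincount(inverse)
    spline = interpolate.make_smoothing_spline(uniq, zbar)
    return np.asarray(spline(age), dtype=float)


def standardize_stratified(
    measurements: pd.DataFrame,
    strata: list[str] = ("sex", "lab"),
    age_col: str = "age",
    min_stratum: int = 30,
) -> pd.DataFrame:
    """Per-stratum inverse-normal standardization with smooth age
    adjustment.

    Within each sex x laboratory stratum the collapsed values are
    inverse-normal transformed, a penalized cubic spline age trend
    (smoothing chosen by generalized cross-validation) is subtracted,
    and the result re-standardized; strata are then pooled.  Strata
    smaller than ``min_stratum`` are merged into the largest stratum of
    the same sex (or overall) with a warning.
    """
    per_ind = collapse_repeats(measurements)
    if age_col not in per_ind.columns:
        if "measurement_year" in per_ind.columns and "birth_year" in per_ind.columns:
            per_ind[age_col] = per_ind["measurement_year"] - per_ind["birth_year"]
        else:
            raise ValueError(f"no {age_col!r} column and cannot derive one")

    strata = list(strata)
    key = per_ind[strata].astype(str).agg("|".join, axis=1)
    sizes = key.value_counts()
    small = sizes[sizes < min_stratum].index
    if len(small) > 0:
        biggest = sizes.idxmax()
        warnings.warn(
            f"{len(small)} strata below {min_stratum} individuals merged into {biggest!r}",
            stacklevel=2,
        )
        key = key.where(~key.isin(small), biggest)

    out = per_ind[["iid"]].copy()
    out["stratum"] = key.values
    out["phenotype"] = np.nan
    for s, idx in per_ind.groupby(key.values).groups.items():
        sub = per_ind.loc[idx]
        z = inverse_normal(sub["value"])
        trend = _smooth_age_trend(sub[age_col].to_numpy(dtype=float), z)
        adj = z - trend
        sd = adj.std(ddof=0)
        if sd > 0:
            adj = (adj - adj.mean()) / sd
        out.loc[idx, "phenotype"] = adj
    out["n_measurements"] = per_ind["n_measurements"].values
    return out
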