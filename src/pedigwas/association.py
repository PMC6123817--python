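"""Kinship-covariance association models and the filtered genome scan.

The quantitative-trait model is

    y ~ N(alpha + beta * g, 2 * sigma^2 * Phi)

with g the expected minor-allele count and Phi the genealogical kinship
matrix (diagonal 1/2, off-diagonal twice the kinship coefficient).
Fitting decorrelates by the Cholesky factor of 2*Phi and solves the
resulting OLS problem; sigma^2 is the maximum-likelihood estimate, the
headline test is the 1-df likelihood-ratio chi-square of beta = 0, and
the Wald standard error provides the 95% CI.  Binary traits use
logistic regression with a likelihood-ratio test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .pedigree import KinshipMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationResult",
    "ModelSpec",
    "gls_fit",
    "logistic_lrt",
    "genome_scan",
    "ols_fit",
]

_RIDGE = 1e-10


@dataclass
class AssociationResult:
    variant_id: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    chi2: float
    p: float
    n: int
    maf: float = float("nan")
    info: float = float("nan")
    status: str = "ok"  # "ok" | "degenerate" | "separation"

    @classmethod
    def degenerate(cls, variant_id: str, n: int, **kw) -> "AssociationResult":
        return cls(variant_id, 0.0, float("nan"), float("nan"), float("nan"),
                   0.0, 1.0, n, status="degenerate", **kw)

    def to_dict(self) -> dict:
        return {
            "variant_id": self.variant_id, "beta": self.beta, "se": self.se,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "chi2": self.chi2, "p": self.p, "n": self.n,
            "maf": self.maf, "info": self.info, "status": self.status,
        }


@dataclass
class ModelSpec:
    """Inputs of one quantitative-trait fit, on a shared id ordering."""

    ids: list[str]
    y: np.ndarray
    g: np.ndarray
    phi: KinshipMatrix | np.ndarray
    covariates: np.ndarray | None = None

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        n = len(self.ids)
        if self.y.shape != (n,) or self.g.shape != (n,):
            raise ValueError("y and g must match the id list length")
        phi = self.phi.phi if isinstance(self.phi, KinshipMatrix) else np.asarray(self.phi)
        if phi.shape != (n, n):
            raise ValueError("phi must be n x n")
        if isinstance(self.phi, KinshipMatrix) and self.phi.ids != list(self.ids):
            raise ValueError("phi id ordering differs from the model id ordering")
        self._phi_arr = phi


def _chol_2phi(phi: np.ndarray, ridge: float = _RIDGE) -> np.ndarray:
    a = 2.0 * phi
    for r in (0.0, ridge, 1e-8):
        try:
            return np.linalg.cholesky(a if r == 0 else a + r * np.eye(a.shape[0]))
        except np.linalg.LinAlgError:
            continue
    raise np.linalg.LinAlgError(
        "2*Phi is not positive definite even after a 1e-8 ridge"
    )


def _loglik(n: int, rss: float, logdet_2phi: float) -> float:
    sigma2 = rss / n
    return -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet_2phi + n)


def gls_fit(spec: ModelSpec, variant_id: str = "variant",
            chol: np.ndarray | None = None) -> AssociationResult:
    """ML fit of y ~ N(alpha + beta*g [+ C*gamma], 2*sigma^2*Phi).

    Pass ``chol`` (the Cholesky factor of 2*Phi) to amortize the
    decomposition across variants sharing one kinship matrix.
    """
    n = len(spec.ids)
    k_cov = 0 if spec.covariates is None else spec.covariates.shape[1]
    if n <= k_cov + 2:
        raise ValueError("need n > number of fixed effects + 1")
    if chol is None:
        chol = _chol_2phi(spec._phi_arr)
    z = linalg.solve_triangular(chol, spec.y, lower=True)
    ones = linalg.solve_triangular(chol, np.ones(n), lower=True)
    w_g = linalg.solve_triangular(chol, spec.g, lower=True)
    if spec.covariates is not None:
        w_cov = linalg.solve_triangular(chol, spec.covariates, lower=True)
        X0 = np.column_stack([ones, w_cov])
    else:
        X0 = ones[:, None]
    X1 = np.column_stack([X0, w_g])

    # degenerate variant: no variation after decorrelation / monomorphic
    if np.ptp(spec.g) == 0 or np.linalg.matrix_rank(X1) < X1.shape[1]:
        return AssociationResult.degenerate(variant_id, n)

    beta0, res0, *_ = np.linalg.lstsq(X0, z, rcond=None)
    rss0 = float(((z - X0 @ beta0) ** 2).sum())
    beta1, res1, *_ = np.linalg.lstsq(X1, z, rcond=None)
    rss1 = float(((z - X1 @ beta1) ** 2).sum())

    chi2 = max(0.0, n * np.log(rss0 / rss1))
    p = float(stats.chi2.sf(chi2, df=1))
    sigma2 = rss1 / n
    xtx_inv = np.linalg.inv(X1.T @ X1)
    se = float(np.sqrt(sigma2 * xtx_inv[-1, -1]))
    b = float(beta1[-1])
    return AssociationResult(
        variant_id, b, se, b - 1.96 * se, b + 1.96 * se, chi2, p, n,
    )


def ols_fit(ids: list[str], y: np.ndarray, g: np.ndarray,
            variant_id: str = "variant") -> AssociationResult:
    """Kinship-ignorant fit: identical model with Phi = I/2 (so the
    covariance is sigma^2 * I).  Used to demonstrate the inflation the
    kinship model removes."""
    n = len(ids)
    spec = ModelSpec(ids, y, g, 0.5 * np.eye(n))
    return gls_fit(spec, variant_id=variant_id, chol=np.eye(n))


def loglik_at(spec: ModelSpec, alpha: float, beta: float, sigma2: float) -> float:
    """Exact multivariate-normal log-likelihood at given parameters; the
    independent check that gls_fit sits at the maximum."""
    phi = spec._phi_arr
    n = len(spec.ids)
    cov = 2.0 * sigma2 * phi
    resid = spec.y - alpha - beta * spec.g
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0:
        return -np.inf
    return float(-0.5 * (n * np.log(2 * np.pi) + logdet
                         + resid @ np.linalg.solve(cov, resid)))


# ---------------------------------------------------------------------------
# Logistic regression for binary traits
# ---------------------------------------------------------------------------

def _firth_logistic(X: np.ndarray, y: np.ndarray, max_iter: int = 50,
                    tol: float = 1e-10) -> tuple[np.ndarray, float]:
    """Jeffreys-prior penalized logistic fit (Firth); returns
    (coefficients, penalized log-likelihood).  Used when ML fails to
    converge under complete separation."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu)
        XtW = X.T * w
        info = XtW @ X
        info_inv = np.linalg.pinv(info)
        h = np.einsum("ij,jk,ik->i", X, info_inv, X) * w  # hat diagonal
        u = X.T @ (y - mu + h * (0.5 - mu))
        step = info_inv @ u
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    ll = float(y @ np.log(mu + 1e-300) + (1 - y) @ np.log(1 - mu + 1e-300))
    sign, logdet = np.linalg.slogdet(X.T * (mu * (1 - mu)) @ X)
    return beta, ll + 0.5 * logdet


def logistic_lrt(status: np.ndarray, g: np.ndarray,
                 nuisance: np.ndarray | None = None,
                 variant_id: str = "variant") -> AssociationResult:
    """1-df likelihood-ratio test of the dosage term in a logistic model.

    The effect is reported on the log-odds-per-allele scale.  Complete
    separation triggers a Firth (profile-penalized likelihood) fallback,
    flagged in ``status``.
    """
    import statsmodels.api as sm

    y = np.asarray(status, dtype=float)
    g = np.asarray(g, dtype=float)
    n = y.size
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("status must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("need both cases and controls")
    X0 = np.ones((n, 1))
    if nuisance is not None:
        nuis = np.asarray(nuisance, dtype=float)
        keep = [j for j in range(nuis.shape[1]) if np.ptp(nuis[:, j]) > 0]
        if len(keep) < nuis.shape[1]:
            logger.warning("dropped %d constant nuisance columns",
                           nuis.shape[1] - len(keep))
        nuis = nuis[:, keep]
        # drop collinear columns by rank-revealing QR on the augmented design
        X0 = np.column_stack([X0, nuis])
        q, r = np.linalg.qr(X0)
        keep = np.abs(np.diag(r)) > 1e-9 * np.abs(r[0, 0])
        X0 = X0[:, keep]
    if np.ptp(g) == 0:
        return AssociationResult.degenerate(variant_id, n)
    X1 = np.column_stack([X0, g])

    with np.errstate(all="ignore"):
        m0 = sm.GLM(y, X0, family=sm.families.Binomial()).fit()
        m1 = sm.GLM(y, X1, family=sm.families.Binomial()).fit()
    beta = float(m1.params[-1])
    separated = not np.isfinite(m1.bse[-1]) or abs(beta) > 15
    if separated:
        b0, ll0 = _firth_logistic(X0, y)
        b1, ll1 = _firth_logistic(X1, y)
        chi2 = max(0.0, 2.0 * (ll1 - ll0))
        p = float(stats.chi2.sf(chi2, df=1))
        return AssociationResult(variant_id, float(b1[-1]), float("nan"),
                                 float("nan"), float("nan"), chi2, p, n,
                                 status="separation")
    chi2 = max(0.0, 2.0 * float(m1.llf - m0.llf))
    p = float(stats.chi2.sf(chi2, df=1))
    se = float(m1.bse[-1])
    return AssociationResult(variant_id, beta, se, beta - 1.96 * se,
                             beta + 1.96 * se, chi2, p, n)


# ---------------------------------------------------------------------------
# Genome scan
# ---------------------------------------------------------------------------

def genome_scan(
    phenotype: pd.Series,
    dosages: pd.DataFrame,
    phi: KinshipMatrix,
    variants: pd.DataFrame | None = None,
    info_cutoff: float = 0.8,
    maf_cutoff: float = 0.0001,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Filtered scan of every variant column in ``dosages``.

    Variants with imputation info <= ``info_cutoff`` or MAF <=
    ``maf_cutoff`` are excluded *before* testing and recorded in the
    filter ledger.  Returns ``(results, ledger)``; together they
    partition the input panel exactly.
    """
    ids = list(phenotype.index)
    if list(dosages.index) != ids:
        dosages = dosages.loc[ids]
    sub = phi.subset(ids) if phi.ids != ids else phi
    y = phenotype.to_numpy(dtype=float)
    n = len(ids)
    chol = _chol_2phi(sub.phi)

    meta = {}
    if variants is not None:
        meta = variants.set_index("variant_id").to_dict("index")

    # decorrelate once for all variants
    z = linalg.solve_triangular(chol, y, lower=True)
    ones = linalg.solve_triangular(chol, np.ones(n), lower=True)
    G = linalg.solve_triangular(chol, dosages.to_numpy(dtype=float), lower=True)

    X0 = ones[:, None]
    b0, *_ = np.linalg.lstsq(X0, z, rcond=None)
    rss0 = float(((z - X0 @ b0) ** 2).sum())

    results = []
    ledger = []
    for j, vid in enumerate(dosages.columns):
        d = dosages[vid].to_numpy(dtype=float)
        maf = float(d.mean() / 2.0)
        maf = min(maf, 1.0 - maf)
        info = meta.get(vid, {}).get("info")
        if info is None:
            from .pedigree import imputation_info
            info = imputation_info(d)
        if info <= info_cutoff:
            ledger.append({"variant_id": vid, "reason": "info"})
            continue
        if maf <= maf_cutoff:
            ledger.append({"variant_id": vid, "reason": "maf"})
            continue
        w = G[:, j]
        X1 = np.column_stack([ones, w])
        if np.ptp(d) == 0:
            res = AssociationResult.degenerate(vid, n, maf=maf, info=float(info))
        else:
            b1, *_ = np.linalg.lstsq(X1, z, rcond=None)
            rss1 = float(((z - X1 @ b1) ** 2).sum())
            chi2 = max(0.0, n * np.log(rss0 / rss1))
            p = float(stats.chi2.sf(chi2, df=1))
            sigma2 = rss1 / n
            xtx_inv = np.linalg.inv(X1.T @ X1)
            se = float(np.sqrt(sigma2 * xtx_inv[-1, -1]))
            b = float(b1[-1])
            res = AssociationResult(vid, b, se, b - 1.96 * se, b + 1.96 * se,
                                    chi2, p, n, maf=maf, info=float(info))
        row = res.to_dict()
        if vid in meta:
            for key in ("chrom", "pos", "annotation"):
                if key in meta[vid]:
                    row[key] = meta[vid][key]
        results.append(row)
    res_df = pd.DataFrame(results)
    ledger_df = pd.DataFrame(ledger, columns=["variant_id", "reason"])
    return res_df, ledger_df
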