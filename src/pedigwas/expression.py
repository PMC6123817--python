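"""Whole-blood expression analysis at desk scale: RNA library QC,
rank-transformed expression association, and allele-balance testing."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .association import AssociationResult, ModelSpec, gls_fit
from .pedigree import KinshipMatrix
from .phenotypes import inverse_normal

__all__ = [
    "RnaLibraryStats",
    "filter_rna_libraries",
    "rank_expression_assoc",
    "allele_balance_test",
]

MIN_MAPPED_READS = 10_000_000
MIN_MAPPED_PAIRS = 1_000_000
MIN_RELATIVE_RATE = 0.8


@dataclass(frozen=True)
class RnaLibraryStats:
    library_id: str
    mapped_reads: int
    mapped_pairs: int
    mapping_rate_end1: float
    mapping_rate_end2: float

    def __post_init__(self):
        if self.mapped_reads < 0 or self.mapped_pairs < 0:
            raise ValueError("read counts must be nonnegative")
        for r in (self.mapping_rate_end1, self.mapping_rate_end2):
            if not (0 <= r <= 1):
                raise ValueError("mapping rates must be in [0, 1]")


def filter_rna_libraries(
    libraries: list[RnaLibraryStats],
) -> tuple[list[RnaLibraryStats], list[tuple[RnaLibraryStats, list[str]]]]:
    """QC partition of RNA libraries.

    A library is excluded if mapped reads < 1e7, or mapped read pairs
    < 1e6, or the lower of the two read-end mapping rates falls below
    80% of the higher one.  Returns ``(kept, excluded)`` where each
    exclusion carries the list of triggered rules.
    """
    kept, excluded = [], []
    for lib in libraries:
        reasons = []
        if lib.mapped_reads < MIN_MAPPED_READS:
            reasons.append("mapped reads")
        if lib.mapped_pairs < MIN_MAPPED_PAIRS:
            reasons.append("mapped pairs")
        r1, r2 = lib.mapping_rate_end1, lib.mapping_rate_end2
        hi = max(r1, r2)
        if hi == 0 or min(r1, r2) / hi < MIN_RELATIVE_RATE:
            reasons.append("relative mapping rate")
        if reasons:
            excluded.append((lib, reasons))
        else:
            kept.append(lib)
    return kept, excluded


def rank_expression_assoc(
    expression: pd.Series,
    dosage: pd.Series,
    nuisance: pd.DataFrame | None = None,
    phi: KinshipMatrix | None = None,
    gene_id: str = "gene",
) -> AssociationResult:
    """Association of one gene's expression with a variant dosage.

    Expression values are rank-inverse-normal transformed, then
    regressed on the dosage plus any nuisance covariates (fragment
    length, exonic rate, genes detected, prep method, read length ...).
    With a kinship matrix the fit uses the 2*sigma^2*Phi covariance
    model; without one it is ordinary least squares.  The effect is in
    SD units per allele.
    """
    ids = list(expression.index)
    if len(ids) < 30:
        raise ValueError("need at least 30 individuals")
    y = inverse_normal(expression)
    g = dosage.loc[ids].to_numpy(dtype=float)
    cov = None
    if nuisance is not None:
        nuis = nuisance.loc[ids]
        cols = []
        for c in nuis.columns:
            x = nuis[c].to_numpy(dtype=float)
            if np.ptp(x) == 0:
                warnings.warn(f"nuisance column {c!r} constant; dropped", stacklevel=2)
                continue
            cols.append(x)
        if cols:
            cov = np.column_stack(cols)
            # drop collinear columns
            q, r = np.linalg.qr(np.column_stack([np.ones(len(ids)), cov]))
            keep = np.abs(np.diag(r))[1:] > 1e-9 * abs(r[0, 0])
            if not keep.all():
                warnings.warn("dropped collinear nuisance columns", stacklevel=2)
                cov = cov[:, keep]
    phi_arr = phi.subset(ids) if phi is not None else 0.5 * np.eye(len(ids))
    spec = ModelSpec(ids, y, g, phi_arr, covariates=cov)
    chol = None if phi is not None else np.eye(len(ids))
    return gls_fit(spec, variant_id=gene_id, chol=chol)


def allele_balance_test(alt_reads: int, total_reads: int) -> float:
    """Exact two-sided binomial test of allelic balance against 1:1.

    Two-sided by summing the probabilities of all outcomes no more
    likely than the observed one under Binomial(total, 1/2).
    """
    if total_reads < 1:
        raise ValueError("total_reads must be >= 1")
    if not (0 <= alt_reads <= total_reads):
        raise ValueError("alt_reads must be within [0, total_reads]")
    return float(stats.binomtest(alt_reads, total_reads, 0.5).pvalue)
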