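"""Pedigree container, kinship matrices, relationship degrees, and
single-locus genotype-probability inference for untyped relatives.

The kinship coefficient k_ij is the probability that one allele sampled
from i and one from j are identical by descent.  The association model
uses the kinship matrix Phi with Phi_ii = 1/2 and Phi_ij = k_ij off the
diagonal, so that 2*Phi is the standard additive (numerator)
relationship matrix A — expected allele sharing, e.g. 1/2 for
parent-child and 1/16 for half first cousins — and the trait covariance
2*sigma^2*Phi collapses to sigma^2 * I for unrelated individuals.
(Definitions placing 2*k_ij off the diagonal while keeping the diagonal
at 1/2 appear in print but are not positive semidefinite for any family
with two or more children, so they cannot parameterize a covariance.)

Genotype probabilities for untyped individuals are exact single-locus
posteriors obtained by variable elimination over the family graph
(founder priors Hardy-Weinberg, 3x3x3 Mendelian transmission factors),
with a conditioned gene-dropping Monte-Carlo fallback for very large
families.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .errors import (
    MendelianInconsistencyError,
    PedigreeStructureError,
    UnknownIndividualError,
)

__all__ = [
    "Individual",
    "Pedigree",
    "KinshipMatrix",
    "DosageDistribution",
    "kinship_matrix",
    "kinship_coefficient",
    "relationship_degree",
    "expected_dosage",
    "imputation_info",
]

# P(child count | father count, mother count): each parent transmits the
# minor allele with probability (own count)/2, independently.
_TRANSMISSION = np.zeros((3, 3, 3))
for _f in range(3):
    for _m in range(3):
        pf, pm = _f / 2.0, _m / 2.0
        _TRANSMISSION[_f, _m, 0] = (1 - pf) * (1 - pm)
        _TRANSMISSION[_f, _m, 1] = pf * (1 - pm) + (1 - pf) * pm
        _TRANSMISSION[_f, _m, 2] = pf * pm


@dataclass(frozen=True)
class Individual:
    iid: str
    father: str | None
    mother: str | None
    sex: int  # 1 = male, 2 = female, 0 = unknown
    birth_year: int | None = None


class Pedigree:
    """Directed acyclic pedigree; every member has 0 or 2 recorded parents."""

    def __init__(self, individuals: list[Individual]):
        self._members: dict[str, Individual] = {}
        for ind in individuals:
            if ind.iid in self._members:
                raise PedigreeStructureError(f"duplicate individual id {ind.iid!r}")
            if (ind.father is None) != (ind.mother is None):
                raise PedigreeStructureError(
                    f"{ind.iid!r} has exactly one recorded parent; must be 0 or 2"
                )
            self._members[ind.iid] = ind
        for ind in individuals:
            for p in (ind.father, ind.mother):
                if p is not None and p not in self._members:
                    raise PedigreeStructureError(
                        f"parent {p!r} of {ind.iid!r} not in pedigree"
                    )
        g = nx.DiGraph()
        g.add_nodes_from(self._members)
        for ind in individuals:
            if ind.father is not None:
                g.add_edge(ind.father, ind.iid)
                g.add_edge(ind.mother, ind.iid)
        try:
            self._topo: list[str] = list(nx.topological_sort(g))
        except nx.NetworkXUnfeasible as exc:
            raise PedigreeStructureError("pedigree contains a parent-link cycle") from exc
        self._graph = g
        self._children: dict[str, list[str]] = {i: sorted(g.successors(i)) for i in g}

    # -- basic accessors -------------------------------------------------
    def __len__(self) -> int:
        return len(self._members)

    def __contains__(self, iid: str) -> bool:
        return iid in self._members

    def __iter__(self):
        return iter(self._topo)

    @property
    def ids(self) -> list[str]:
        return list(self._members)

    @property
    def topological_order(self) -> list[str]:
        return list(self._topo)

    def member(self, iid: str) -> Individual:
        try:
            return self._members[iid]
        except KeyError:
            raise UnknownIndividualError(f"unknown individual {iid!r}") from None

    def parents(self, iid: str) -> tuple[str, str] | None:
        ind = self.member(iid)
        if ind.father is None:
            return None
        return (ind.father, ind.mother)

    def children(self, iid: str) -> list[str]:
        self.member(iid)
        return list(self._children[iid])

    def is_founder(self, iid: str) -> bool:
        return self.member(iid).father is None

    @property
    def founders(self) -> list[str]:
        return [i for i in self._topo if self._members[i].father is None]

    def family_component(self, iid: str) -> set[str]:
        """All individuals connected to ``iid`` through parent-child links."""
        self.member(iid)
        return set(nx.node_connected_component(self._graph.to_undirected(as_view=True), iid))

    # -- I/O -------------------------------------------------------------
    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "Pedigree":
        inds = []
        for row in df.itertuples(index=False):
            father = None if str(row.father) in ("0", "nan", ".", "None") else str(row.father)
            mother = None if str(row.mother) in ("0", "nan", ".", "None") else str(row.mother)
            year = getattr(row, "birth_year", None)
            inds.append(
                Individual(
                    iid=str(row.iid),
                    father=father,
                    mother=mother,
                    sex=int(row.sex),
                    birth_year=None if year is None or pd.isna(year) else int(year),
                )
            )
        return cls(inds)

    def to_dataframe(self, family_id: str = "FAM1") -> pd.DataFrame:
        rows = [
            {
                "family": family_id,
                "iid": ind.iid,
                "father": ind.father or "0",
                "mother": ind.mother or "0",
                "sex": ind.sex,
                "birth_year": ind.birth_year if ind.birth_year is not None else 0,
            }
            for ind in (self._members[i] for i in self._topo)
        ]
        return pd.DataFrame(rows)


@dataclass
class KinshipMatrix:
    """Phi matrix: diagonal 1/2, off-diagonal k_ij, indexed by ``ids``.

    2*Phi is the additive relationship matrix; the model covariance is
    2*sigma^2*Phi.
    """

    ids: list[str]
    phi: np.ndarray

    def __post_init__(self):
        self.phi = np.asarray(self.phi, dtype=float)
        n = len(self.ids)
        if self.phi.shape != (n, n):
            raise ValueError("phi shape does not match ids")
        self._index = {iid: k for k, iid in enumerate(self.ids)}

    def value(self, i: str, j: str) -> float:
        return float(self.phi[self._index[i], self._index[j]])

    def subset(self, subjects: list[str]) -> "KinshipMatrix":
        try:
            idx = [self._index[s] for s in subjects]
        except KeyError as exc:
            raise UnknownIndividualError(f"unknown subject {exc.args[0]!r}") from None
        return KinshipMatrix(list(subjects), self.phi[np.ix_(idx, idx)])

    def to_sparse_frame(self) -> pd.DataFrame:
        """Upper triangle (incl. diagonal) of nonzero entries as long TSV rows."""
        iu, ju = np.triu_indices(len(self.ids))
        vals = self.phi[iu, ju]
        keep = vals != 0
        return pd.DataFrame(
            {
                "id_i": [self.ids[k] for k in iu[keep]],
                "id_j": [self.ids[k] for k in ju[keep]],
                "phi": vals[keep],
            }
        )


@dataclass
class DosageDistribution:
    """Posterior over one individual's genotype at a biallelic locus."""

    iid: str
    probabilities: np.ndarray  # P(G=0), P(G=1), P(G=2)
    method: str = "exact"

    def __post_init__(self):
        p = np.asarray(self.probabilities, dtype=float)
        if p.shape != (3,) or (p < -1e-12).any():
            raise ValueError("probabilities must be 3 nonnegative numbers")
        s = p.sum()
        if not np.isfinite(s) or s <= 0:
            raise ValueError("probabilities sum to zero")
        self.probabilities = np.clip(p / s, 0.0, 1.0)

    @property
    def expected_count(self) -> float:
        return float(self.probabilities[1] + 2.0 * self.probabilities[2])


# ---------------------------------------------------------------------------
# Kinship
# ---------------------------------------------------------------------------

def kinship_matrix(pedigree: Pedigree, subjects: list[str] | None = None) -> KinshipMatrix:
    """Phi over ``subjects`` (default: all members, topological order).

    k_ij follows the standard recursion over a topological order:
    founders are unrelated to non-descendants, and for a non-founder i
    with parents (f, m) and any earlier individual j,
    k_ij = (k_fj + k_mj) / 2.  The diagonal of Phi is fixed at 1/2
    regardless of inbreeding (for inbred pedigrees this truncation can
    cost positive semidefiniteness; the synthetic pedigrees here are
    non-inbred).
    """
    order = pedigree.topological_order
    pos = {iid: k for k, iid in enumerate(order)}
    n = len(order)
    K = np.zeros((n, n))
    for t, iid in enumerate(order):
        par = pedigree.parents(iid)
        if par is None:
            K[t, t] = 0.5
        else:
            f, m = pos[par[0]], pos[par[1]]
            if t > 0:
                K[t, :t] = 0.5 * (K[f, :t] + K[m, :t])
                K[:t, t] = K[t, :t]
            K[t, t] = 0.5 + 0.5 * K[f, m]
    phi = K
    np.fill_diagonal(phi, 0.5)
    full = KinshipMatrix(order, phi)
    if subjects is None:
        return full
    for s in subjects:
        if s not in pedigree:
            raise UnknownIndividualError(f"unknown subject {s!r}")
    return full.subset(list(subjects))


def kinship_coefficient(pedigree: Pedigree, i: str, j: str,
                        _memo: dict | None = None) -> float:
    """Recursive kinship coefficient k_ij for a single pair."""
    memo = {} if _memo is None else _memo
    pos = {iid: k for k, iid in enumerate(pedigree.topological_order)}

    def k(a: str, b: str) -> float:
        if pos[a] < pos[b]:
            a, b = b, a
        key = (a, b)
        if key in memo:
            return memo[key]
        if a == b:
            par = pedigree.parents(a)
            val = 0.5 if par is None else 0.5 + 0.5 * k(par[0], par[1])
        else:
            par = pedigree.parents(a)  # a is the later individual; b not its descendant
            val = 0.0 if par is None else 0.5 * (k(par[0], b) + k(par[1], b))
        memo[key] = val
        return val

    pedigree.member(i), pedigree.member(j)
    return k(i, j)


def relationship_degree(pedigree: Pedigree, i: str, j: str) -> str:
    """Classify the pair as self / 1st / 2nd / 3rd+ / unrelated.

    1st degree: parent-offspring or full siblings.  2nd degree:
    grandparent-grandchild, half siblings, or avuncular.  Any other pair
    with positive kinship is 3rd+.
    """
    a, b = pedigree.member(i), pedigree.member(j)
    if i == j:
        return "self"
    pa, pb = pedigree.parents(i), pedigree.parents(j)
    if (pa is not None and j in pa) or (pb is not None and i in pb):
        return "1st"
    if pa is not None and pb is not None:
        shared = len(set(pa) & set(pb))
        if shared == 2:
            return "1st"
        if shared == 1:
            return "2nd"

    def grandparents(iid):
        gp = set()
        par = pedigree.parents(iid)
        if par:
            for p in par:
                pp = pedigree.parents(p)
                if pp:
                    gp.update(pp)
        return gp

    if i in grandparents(j) or j in grandparents(i):
        return "2nd"

    def full_sibs(iid):
        par = pedigree.parents(iid)
        if par is None:
            return set()
        return {
            c
            for c in pedigree.children(par[0])
            if c != iid and pedigree.parents(c) is not None
            and set(pedigree.parents(c)) == set(par)
        }

    # avuncular: i is a full sibling of one of j's parents (or vice versa)
    for x, y in ((i, j), (j, i)):
        py = pedigree.parents(y)
        if py and any(x in full_sibs(p) for p in py):
            return "2nd"
    if kinship_coefficient(pedigree, i, j) > 0:
        return "3rd+"
    return "unrelated"


# ---------------------------------------------------------------------------
# Genotype-probability inference
# ---------------------------------------------------------------------------

def _check_typed_trios(pedigree: Pedigree, typed: dict[str, int]) -> None:
    for c, g in typed.items():
        par = pedigree.parents(c)
        if par is None:
            continue
        f, m = par
        if f in typed and m in typed:
            if _TRANSMISSION[typed[f], typed[m], g] == 0:
                raise MendelianInconsistencyError(
                    f"genotypes of trio child={c} father={f} mother={m} "
                    f"({typed[f]}x{typed[m]} -> {g}) are Mendelianly impossible",
                    trio=(c, f, m),
                )


def _prune_component(pedigree: Pedigree, component: set[str],
                     typed: dict[str, int], target: str) -> set[str]:
    """Drop untyped childless individuals (other than the target); they
    marginalize out of the single-locus likelihood exactly."""
    keep = set(component)
    changed = True
    while changed:
        changed = False
        for iid in list(keep):
            if iid == target or iid in typed:
                continue
            if not any(c in keep for c in pedigree.children(iid)):
                keep.discard(iid)
                changed = True
    return keep


class _Factor:
    __slots__ = ("vars", "table")

    def __init__(self, vars: tuple[str, ...], table: np.ndarray):
        self.vars = vars
        self.table = table


def _multiply_and_marginalize(factors: list[_Factor], out: str) -> _Factor:
    """Product of factors, then sum out variable ``out``."""
    all_vars: list[str] = []
    for f in factors:
        for v in f.vars:
            if v not in all_vars:
                all_vars.append(v)
    axis = {v: k for k, v in enumerate(all_vars)}
    prod = np.ones((1,) * len(all_vars))
    for f in factors:
        shape = [1] * len(all_vars)
        src = f.table
        # transpose factor axes into global order
        order = sorted(range(len(f.vars)), key=lambda a: axis[f.vars[a]])
        src = np.transpose(src, order)
        for v in f.vars:
            shape[axis[v]] = 3
        prod = prod * src.reshape(shape)
    summed = prod.sum(axis=axis[out])
    rem = tuple(v for v in all_vars if v != out)
    return _Factor(rem, summed)


def _eliminate(factors: list[_Factor], keep: str) -> np.ndarray:
    """Variable elimination down to the marginal of ``keep`` (unnormalized)."""
    factors = list(factors)
    while True:
        vars_present: dict[str, int] = {}
        for f in factors:
            for v in f.vars:
                if v != keep:
                    vars_present[v] = vars_present.get(v, 0) + 1
        if not vars_present:
            break
        # min-degree heuristic: eliminate the variable whose product factor is smallest
        def cost(v: str) -> int:
            s = set()
            for f in factors:
                if v in f.vars:
                    s.update(f.vars)
            return len(s)

        v = min(sorted(vars_present), key=cost)
        touching = [f for f in factors if v in f.vars]
        rest = [f for f in factors if v not in f.vars]
        rest.append(_multiply_and_marginalize(touching, v))
        factors = rest
    result = np.ones(3)
    for f in factors:
        if f.vars == (keep,):
            result = result * f.table
        elif f.vars == ():
            result = result * float(f.table)
        else:  # pragma: no cover - keep is the only variable left by construction
            raise AssertionError("elimination left an unexpected factor")
    return result


def _build_factors(pedigree: Pedigree, members: set[str],
                   typed: dict[str, int], maf: float) -> list[_Factor]:
    hw = np.array([(1 - maf) ** 2, 2 * maf * (1 - maf), maf**2])
    factors: list[_Factor] = []

    def reduce_obs(vars_: list[str], table: np.ndarray) -> _Factor:
        for v in list(vars_):
            if v in typed:
                ax = vars_.index(v)
                table = np.take(table, typed[v], axis=ax)
                vars_.pop(ax)
        return _Factor(tuple(vars_), table)

    for iid in members:
        par = pedigree.parents(iid)
        if par is None or par[0] not in members:
            # founder of the (pruned) family graph: Hardy-Weinberg prior
            factors.append(reduce_obs([iid], hw.copy()))
        else:
            factors.append(reduce_obs([par[0], par[1], iid], _TRANSMISSION.copy()))
    return factors


def expected_dosage(
    pedigree: Pedigree,
    typed: dict[str, int],
    maf: float,
    target: str,
    *,
    max_exact_untyped: int = 20,
    mc_drops: int = 100_000,
    seed: int = 0,
) -> DosageDistribution:
    """Posterior genotype distribution of an untyped ``target``.

    Exact variable elimination over the target's family component
    (after pruning untyped childless members, which do not affect the
    single-locus likelihood).  Components with more than
    ``max_exact_untyped`` untyped members fall back to conditioned
    gene-dropping Monte Carlo with ``mc_drops`` seeded drops.
    """
    if not (0 < maf <= 0.5):
        raise ValueError("maf must be in (0, 0.5]")
    pedigree.member(target)
    if target in typed:
        raise ValueError(f"target {target!r} is already typed")
    for iid, g in typed.items():
        pedigree.member(iid)
        if g not in (0, 1, 2):
            raise ValueError(f"typed genotype of {iid!r} must be 0, 1 or 2")
    _check_typed_trios(pedigree, typed)

    component = pedigree.family_component(target)
    typed_local = {i: g for i, g in typed.items() if i in component}
    members = _prune_component(pedigree, component, typed_local, target)
    typed_local = {i: g for i, g in typed_local.items() if i in members}
    n_untyped = sum(1 for m in members if m not in typed_local)

    if n_untyped <= max_exact_untyped:
        factors = _build_factors(pedigree, members, typed_local, maf)
        marginal = _eliminate(factors, target)
        if marginal.sum() <= 0:
            raise MendelianInconsistencyError(
                "typed genotypes have zero likelihood in the family of "
                f"{target!r} (no violating trio is fully typed)"
            )
        return DosageDistribution(target, marginal, method="exact")
    return _mc_dosage(pedigree, members, typed_local, maf, target, mc_drops, seed)


def _mc_dosage(pedigree: Pedigree, members: set[str], typed: dict[str, int],
               maf: float, target: str, n_drops: int, seed: int) -> DosageDistribution:
    rng = np.random.default_rng(seed)
    order = [i for i in pedigree.topological_order if i in members]
    geno = {}
    for iid in order:
        par = pedigree.parents(iid)
        if par is None or par[0] not in members:
            geno[iid] = rng.binomial(2, maf, size=n_drops)
        else:
            tf = rng.binomial(1, geno[par[0]] / 2.0)
            tm = rng.binomial(1, geno[par[1]] / 2.0)
            geno[iid] = tf + tm
    ok = np.ones(n_drops, dtype=bool)
    for iid, g in typed.items():
        ok &= geno[iid] == g
    if not ok.any():
        raise MendelianInconsistencyError(
            f"no gene-dropping configuration matched the typed genotypes "
            f"around {target!r} in {n_drops} drops"
        )
    counts = np.bincount(geno[target][ok], minlength=3).astype(float)
    return DosageDistribution(target, counts, method="monte-carlo")


def brute_force_dosage(pedigree: Pedigree, typed: dict[str, int],
                       maf: float, target: str) -> DosageDistribution:
    """Exhaustive enumeration over all untyped-member genotype
    configurations of the target's family component.  Exponential; for
    validation on small families only."""
    component = sorted(pedigree.family_component(target))
    untyped = [i for i in component if i not in typed]
    hw = np.array([(1 - maf) ** 2, 2 * maf * (1 - maf), maf**2])
    marginal = np.zeros(3)
    for combo in itertools.product(range(3), repeat=len(untyped)):
        g = dict(zip(untyped, combo))
        g.update({i: typed[i] for i in component if i in typed})
        lik = 1.0
        for iid in component:
            par = pedigree.parents(iid)
            if par is None:
                lik *= hw[g[iid]]
            else:
                lik *= _TRANSMISSION[g[par[0]], g[par[1]], g[iid]]
            if lik == 0.0:
                break
        marginal[g[target]] += lik
    if marginal.sum() <= 0:
        raise MendelianInconsistencyError("zero likelihood in enumeration")
    return DosageDistribution(target, marginal, method="enumeration")


def imputation_info(dosages: np.ndarray, maf_hat: float | None = None) -> float:
    """MACH/IMPUTE-style r-hat-squared: Var(dosage) / (2 p (1-p)).

    Equals 1 for hard genotypes in Hardy-Weinberg proportions and 0 for
    pure-prior dosages.  Clipped to [0, 1.05] to tolerate sampling noise;
    degenerate allele frequencies (0 or 1) return 1.
    """
    d = np.asarray(dosages, dtype=float)
    if d.size == 0:
        raise ValueError("dosages must be nonempty")
    p = float(d.mean() / 2.0) if maf_hat is None else float(maf_hat)
    if p <= 0.0 or p >= 1.0:
        return 1.0
    info = float(d.var() / (2.0 * p * (1.0 - p)))
    return float(np.clip(info, 0.0, 1.05))
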