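"""Synthetic cohort generator.

Emulates the data structure of a genealogy-based rare-variant study of a
skewed serum biomarker: a multi-generation pedigree with a chip-typed
subset, a rare biallelic variant gene-dropped through the pedigree at
very low frequency, a panel of common variants in LD blocks, and a
positively skewed trait with sex and birth-year covariate effects plus a
per-allele effect in SD units on the latent (standard-normal) scale.

Everything is a pure function of its configuration and seed; identical
inputs reproduce identical outputs bit for bit.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .pedigree import Individual, Pedigree, kinship_matrix

__all__ = [
    "SimConfig",
    "simulate_pedigree",
    "gene_drop",
    "simulate_trait",
    "simulate_variant_panel",
    "assign_typing_status",
    "ANNOTATION_CLASSES",
    "ANNOTATION_PROPORTIONS",
]

ANNOTATION_CLASSES = ("high", "moderate", "low", "DHS", "other")
# Proportions follow the relative sizes of the five functional-impact
# classes among ~32.5M tested variants (high impact rarest, unannotated
# variants dominating).
ANNOTATION_PROPORTIONS = (0.00026, 0.00462, 0.07035, 0.12054, 0.80423)


@dataclass(frozen=True)
class SimConfig:
    """Study-condition knobs for the synthetic cohort.

    Defaults target a discovery cohort of roughly 4200 phenotyped
    individuals carrying a rare variant at MAF 0.09% with a per-allele
    effect of 1.47 SD on the latent trait scale, a trait median of
    13.3 IU/L on the raw scale, and ~70% of the pedigree chip-typed.
    """

    n_founders: int = 730
    n_generations: int = 3
    mean_offspring: float = 2.5
    max_offspring: int = 8
    rare_maf: float = 0.0009
    rare_effect_sd: float = 1.47
    n_common_variants: int = 500
    ld_block_size: int = 10
    ld_copy_prob: float = 0.9
    chip_typed_fraction: float = 0.715
    # trait model
    sex_effect: float = 0.2
    birth_year_effect: float = 0.01  # latent units per year
    polygenic_var: float = 0.3  # fraction of residual latent variance with 2*Phi covariance
    repeat_prob: float = 0.4  # P(second measurement); mean measurements 1.4
    repeat_noise_sd: float = 0.1
    raw_scale: float = 0.5
    raw_median: float = 13.3  # IU/L
    seed: int = 0

    def __post_init__(self):
        if self.n_founders < 2:
            raise ConfigurationError("n_founders must be >= 2")
        if self.n_generations < 1:
            raise ConfigurationError("n_generations must be >= 1")
        if self.mean_offspring <= 0:
            raise ConfigurationError("mean_offspring must be positive")
        if not (0 < self.rare_maf <= 0.5):
            raise ConfigurationError("rare_maf must be in (0, 0.5]")
        if not (0 <= self.chip_typed_fraction <= 1):
            raise ConfigurationError("chip_typed_fraction must be in [0, 1]")
        if not (0 <= self.polygenic_var < 1):
            raise ConfigurationError("polygenic_var must be in [0, 1)")
        if self.n_common_variants < self.ld_block_size:
            raise ConfigurationError("n_common_variants must be >= ld_block_size")

    def to_dict(self) -> dict:
        return asdict(self)


def _rng(config: SimConfig, stream: str, seed: int | None = None) -> np.random.Generator:
    base = config.seed if seed is None else seed
    tag = zlib.crc32(stream.encode()) % (2**31)
    return np.random.default_rng(np.random.SeedSequence([base, tag]))


def simulate_pedigree(config: SimConfig, seed: int | None = None) -> Pedigree:
    """Multi-generation pedigree by random monogamous pairing.

    Within each generation, males and females are randomly paired;
    couples sharing any ancestor are disallowed, so the pedigree is
    non-inbred and the kinship matrix with diagonal 1/2 is a proper
    covariance.  Each couple has a Poisson (``mean_offspring``) number
    of children, truncated at ``max_offspring``.  Children's birth
    years exceed both parents'.
    """
    rng = _rng(config, "pedigree", seed)
    inds: list[Individual] = []
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"I{counter:06d}"

    current: list[Individual] = []
    for _ in range(config.n_founders):
        ind = Individual(new_id(), None, None, int(rng.integers(1, 3)),
                         int(np.round(rng.normal(1920, 5))))
        current.append(ind)
    inds.extend(current)

    ancestors: dict[str, frozenset[str]] = {i.iid: frozenset([i.iid]) for i in current}
    for _gen in range(config.n_generations):
        males = [i for i in current if i.sex == 1]
        females = [i for i in current if i.sex == 2]
        rng.shuffle(males)
        rng.shuffle(females)
        next_gen: list[Individual] = []
        used_females: set[str] = set()
        for m in males:
            mate = None
            for f in females:
                if f.iid in used_females:
                    continue
                if ancestors[m.iid] & ancestors[f.iid]:  # consanguineous
                    continue
                mate = f
                break
            if mate is None:
                continue
            used_females.add(mate.iid)
            n_kids = min(int(rng.poisson(config.mean_offspring)), config.max_offspring)
            base_year = max(y for y in (m.birth_year, mate.birth_year) if y is not None)
            for _ in range(n_kids):
                child = Individual(
                    new_id(), m.iid, mate.iid, int(rng.integers(1, 3)),
                    base_year + int(rng.integers(20, 36)),
                )
                next_gen.append(child)
                ancestors[child.iid] = (
                    frozenset([child.iid]) | ancestors[m.iid] | ancestors[mate.iid]
                )
        inds.extend(next_gen)
        current = next_gen
        if not current:
            break
    return Pedigree(inds)


def gene_drop(pedigree: Pedigree, maf: float, seed: int,
              n_drops: int = 1) -> pd.DataFrame:
    """Drop a biallelic variant through the pedigree.

    Founder alleles are i.i.d. Bernoulli(maf); every child inherits one
    allele from each parent uniformly at random.  Returns a DataFrame
    indexed by individual id with one column per drop holding
    minor-allele counts in {0, 1, 2}.
    """
    if not (0 <= maf <= 0.5):
        raise ValueError("maf must be in [0, 0.5]")
    rng = np.random.default_rng(seed)
    order = pedigree.topological_order
    geno: dict[str, np.ndarray] = {}
    for iid in order:
        par = pedigree.parents(iid)
        if par is None:
            geno[iid] = rng.binomial(2, maf, size=n_drops)
        else:
            tf = rng.binomial(1, geno[par[0]] / 2.0)
            tm = rng.binomial(1, geno[par[1]] / 2.0)
            geno[iid] = tf + tm
    out = pd.DataFrame(
        {f"drop{k}": [geno[i][k] for i in order] for k in range(n_drops)},
        index=pd.Index(order, name="iid"),
    )
    return out


def simulate_trait(
    pedigree: Pedigree,
    genotypes: pd.Series,
    effect_sd: float,
    config: SimConfig,
    seed: int | None = None,
    trait: str = "EPO",
    chol_2phi: np.ndarray | None = None,
) -> pd.DataFrame:
    """Skewed raw measurements with a planted per-allele latent effect.

    latent = sex_effect*1[male] + birth_year_effect*(year - mean year)
             + effect_sd * allele count + family + noise,
    where (family + noise) has unit variance, the family part has
    covariance ``polygenic_var * 2*Phi`` (pass ``chol_2phi`` to reuse a
    precomputed Cholesky factor), and the reported measurement is
    exp(raw_scale * latent + log raw_median) with 1-2 repeats per
    individual.
    """
    rng = _rng(config, f"trait:{trait}", seed)
    ids = pedigree.topological_order
    missing = [i for i in ids if i not in genotypes.index]
    if missing:
        raise ValueError(f"genotypes missing for {len(missing)} pedigree members")
    g = genotypes.loc[ids].to_numpy(dtype=float)
    n = len(ids)

    sex = np.array([pedigree.member(i).sex for i in ids])
    year = np.array([pedigree.member(i).birth_year or 0 for i in ids], dtype=float)
    year_c = year - year.mean()

    noise = rng.standard_normal(n) * np.sqrt(1.0 - config.polygenic_var)
    if config.polygenic_var > 0:
        if chol_2phi is None:
            from .association import _chol_2phi

            phi = kinship_matrix(pedigree).subset(ids).phi
            chol_2phi = _chol_2phi(phi)
        family = np.sqrt(config.polygenic_var) * (chol_2phi @ rng.standard_normal(n))
    else:
        family = np.zeros(n)

    latent = (
        config.sex_effect * (sex == 1)
        + config.birth_year_effect * year_c
        + effect_sd * g
        + family
        + noise
    )

    n_meas = 1 + rng.binomial(1, config.repeat_prob, size=n)
    rows = []
    for i, iid in enumerate(ids):
        for rep in range(n_meas[i]):
            lat = latent[i] + rng.normal(0.0, config.repeat_noise_sd)
            value = float(np.exp(config.raw_scale * lat + np.log(config.raw_median)))
            rows.append(
                {
                    "iid": iid,
                    "trait": trait,
                    "value": value,
                    "sex": int(sex[i]),
                    "birth_year": int(year[i]),
                    "measurement_year": 1994 + int(rng.integers(0, 22)),
                    "lab": f"lab{1 + int(rng.integers(0, 4))}",
                }
            )
    return pd.DataFrame(rows)


def simulate_variant_panel(
    config: SimConfig, pedigree: Pedigree, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Common-variant dosage panel in LD blocks, plus variant metadata.

    Founder haplotypes are built blockwise: the first variant of a block
    is Bernoulli(p_j) with p_j ~ Uniform(0.05, 0.5); each subsequent
    variant copies the previous variant's allele on the same haplotype
    with probability ``ld_copy_prob``, else redraws.  Blocks are
    transmitted without internal recombination (one parental haplotype
    chosen per block per meiosis), preserving within-block LD.  Each
    variant gets one of the five annotation classes.

    Returns ``(dosages, variants)``: dosages is individuals x variants
    (hard genotype counts), variants carries id, block, class, maf, info.
    """
    rng = _rng(config, "panel", seed)
    m = config.n_common_variants
    bs = config.ld_block_size
    n_blocks = int(np.ceil(m / bs))
    founders = pedigree.founders
    order = pedigree.topological_order
    nf = len(founders)

    mafs = rng.uniform(0.05, 0.5, size=m)
    # haplotypes: blocks x (2 per founder) x variants-in-block
    hap: dict[str, np.ndarray] = {}  # iid -> (2, m) alleles
    fh = np.zeros((2 * nf, m), dtype=np.int8)
    for b in range(n_blocks):
        lo, hi = b * bs, min((b + 1) * bs, m)
        fh[:, lo] = rng.binomial(1, mafs[lo], size=2 * nf)
        for j in range(lo + 1, hi):
            copy = rng.random(2 * nf) < config.ld_copy_prob
            fresh = rng.binomial(1, mafs[j], size=2 * nf)
            fh[:, j] = np.where(copy, fh[:, j - 1], fresh)
    for k, iid in enumerate(founders):
        hap[iid] = fh[2 * k : 2 * k + 2]

    block_of = np.arange(m) // bs
    for iid in order:
        par = pedigree.parents(iid)
        if par is None:
            continue
        child = np.zeros((2, m), dtype=np.int8)
        for w, p in enumerate(par):
            pick = rng.integers(0, 2, size=n_blocks)  # one haplotype per block
            child[w] = hap[p][pick[block_of], np.arange(m)]
        hap[iid] = child

    dos = np.vstack([hap[i].sum(axis=0) for i in order]).astype(float)
    classes = rng.choice(ANNOTATION_CLASSES, size=m, p=ANNOTATION_PROPORTIONS)
    emp_maf = dos.mean(axis=0) / 2.0
    emp_maf = np.minimum(emp_maf, 1 - emp_maf)
    variants = pd.DataFrame(
        {
            "variant_id": [f"var{j:05d}" for j in range(m)],
            "chrom": "1",
            "pos": 10_000 + 100 * np.arange(m),
            "block": block_of,
            "annotation": classes,
            "maf": emp_maf,
            "info": 1.0,
        }
    )
    dosages = pd.DataFrame(dos, index=pd.Index(order, name="iid"),
                           columns=variants["variant_id"])
    return dosages, variants


def assign_typing_status(
    pedigree: Pedigree, fraction: float, seed: int
) -> tuple[pd.Series, list[str]]:
    """Label each individual chip-typed or not, and report the untyped
    individuals having at least one typed first- or second-degree
    relative (the set whose genotypes can be inferred through the
    genealogy)."""
    if not (0 <= fraction <= 1):
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    ids = pedigree.topological_order
    typed = pd.Series(rng.random(len(ids)) < fraction, index=pd.Index(ids, name="iid"))
    if fraction in (0.0, 1.0):
        typed[:] = bool(fraction)
    typed_set = set(typed.index[typed])
    inferable = []
    for iid in ids:
        if iid in typed_set:
            continue
        rels = _close_relatives(pedigree, iid)
        if rels & typed_set:
            inferable.append(iid)
    return typed, inferable


def _close_relatives(pedigree: Pedigree, iid: str) -> set[str]:
    """First- and second-degree relatives via pedigree links.

    1st: parents, children, full siblings.  2nd: grandparents,
    grandchildren, half siblings, and avuncular pairs through a full
    sibling (half-avuncular pairs are 3rd degree and excluded).
    """
    rels: set[str] = set()
    par = pedigree.parents(iid) or ()
    rels.update(par)
    rels.update(pedigree.children(iid))

    def full_sibs(x: str) -> set[str]:
        p = pedigree.parents(x)
        if p is None:
            return set()
        return {
            s for s in pedigree.children(p[0])
            if s != x and pedigree.parents(s) is not None
            and set(pedigree.parents(s)) == set(p)
        }

    for p in par:
        rels.update(pedigree.parents(p) or ())  # grandparents
        for s in pedigree.children(p):  # full and half sibs (1st / 2nd)
            if s != iid:
                rels.add(s)
        rels.update(full_sibs(p))  # aunts/uncles through a full sibling
    for c in pedigree.children(iid):
        rels.update(pedigree.children(c))  # grandchildren
    for s in full_sibs(iid):
        rels.update(pedigree.children(s))  # nieces/nephews
    rels.discard(iid)
    return rels
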