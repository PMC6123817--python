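"""Carrier-count and allele-frequency arithmetic for rare variants.

For a rare biallelic variant essentially all carriers are heterozygous,
so the carrier frequency is approximately twice the minor allele
frequency; these helpers convert between carrier counts, MAF, and the
cohort sizes needed to observe a given number of carriers.
"""

from __future__ import annotations

__all__ = [
    "maf_from_carriers",
    "carrier_frequency",
    "random_sample_size_for_carriers",
    "rarity_ratio",
    "maf_from_allele_count",
]


def maf_from_carriers(n_carriers: int, n_genotyped: int) -> float:
    """MAF implied by a carrier count, treating carriers as heterozygous."""
    if n_genotyped <= 0:
        raise ValueError("n_genotyped must be positive")
    if not (0 <= n_carriers <= n_genotyped):
        raise ValueError("n_carriers must be within [0, n_genotyped]")
    return n_carriers / (2.0 * n_genotyped)


def maf_from_allele_count(n_alleles: int, n_genomes: int) -> float:
    """MAF from an observed minor-allele count among diploid genomes."""
    if n_genomes <= 0:
        raise ValueError("n_genomes must be positive")
    return n_alleles / (2.0 * n_genomes)


def carrier_frequency(maf: float) -> float:
    """P(carry >= 1 minor allele) under Hardy-Weinberg: 1 - (1-maf)^2."""
    if not (0 <= maf <= 1):
        raise ValueError("maf must be in [0, 1]")
    return 1.0 - (1.0 - maf) ** 2


def random_sample_size_for_carriers(n_carriers: int, carrier_freq: float) -> float:
    """Expected random-sample size needed to contain ``n_carriers``
    carriers at the given population carrier frequency."""
    if carrier_freq <= 0:
        raise ValueError("carrier_freq must be positive")
    return n_carriers / carrier_freq


def rarity_ratio(maf_a: float, maf_b: float) -> float:
    """How many times rarer the variant is in population b than a."""
    if maf_b <= 0:
        raise ValueError("maf_b must be positive")
    return maf_a / maf_b
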