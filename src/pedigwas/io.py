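"""Interchange formats: FAM-like pedigree TSV, VCF 4.2 dosages,
phenotype and kinship TSVs, and the pipeline configuration.

All tabular files are tab-separated with a header row, UTF-8, and '.'
for missing values.  VCF coordinates are 1-based inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError
from .pedigree import KinshipMatrix, Pedigree

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "read_pedigree_tsv",
    "write_pedigree_tsv",
    "read_vcf_dosages",
    "write_vcf_dosages",
    "read_phenotype_tsv",
    "write_phenotype_tsv",
    "read_kinship_tsv",
    "write_kinship_tsv",
]

_TSV = dict(sep="\t", na_rep=".")


@dataclass
class PipelineConfig:
    """Thresholds, toggles and paths for the end-to-end pipeline."""

    seed: int = 0
    out_dir: str = "pedigwas_out"
    info_cutoff: float = 0.8
    maf_cutoff: float = 0.0001
    fwer: float = 0.05
    ld_window: int = 50
    run_replication: bool = True
    n_replication_pairs: int = 34
    class_weights: dict = field(default_factory=dict)
    sim: dict = field(default_factory=dict)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(vars(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


# -- pedigree ---------------------------------------------------------------

def write_pedigree_tsv(pedigree: Pedigree, path: str | Path,
                       family_id: str = "FAM1") -> None:
    pedigree.to_dataframe(family_id).to_csv(path, index=False, **_TSV)


def read_pedigree_tsv(path: str | Path) -> Pedigree:
    df = pd.read_csv(path, sep="\t", dtype={"iid": str, "father": str, "mother": str})
    return Pedigree.from_dataframe(df)


# -- phenotypes -------------------------------------------------------------

def write_phenotype_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, **_TSV)


def read_phenotype_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"iid": str}, na_values=["."])


# -- kinship ----------------------------------------------------------------

def write_kinship_tsv(kin: KinshipMatrix, path: str | Path) -> None:
    kin.to_sparse_frame().to_csv(path, index=False, **_TSV)


def read_kinship_tsv(path: str | Path, ids: list[str] | None = None) -> KinshipMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"id_i": str, "id_j": str})
    if ids is None:
        ids = sorted(set(df["id_i"]) | set(df["id_j"]))
    index = {iid: k for k, iid in enumerate(ids)}
    phi = np.zeros((len(ids), len(ids)))
    for i, j, v in zip(df["id_i"], df["id_j"], df["phi"]):
        a, b = index[i], index[j]
        phi[a, b] = phi[b, a] = v
    return KinshipMatrix(list(ids), phi)


# -- VCF --------------------------------------------------------------------

def write_vcf_dosages(
    dosages: pd.DataFrame,
    variants: pd.DataFrame,
    path: str | Path,
    genotypes: pd.DataFrame | None = None,
    ref: str = "G",
    alt: str = "A",
) -> None:
    """Minimal VCF 4.2 with per-sample DS (dosage) and optional GT.

    ``dosages``: individuals x variants; ``variants`` needs variant_id,
    chrom, pos (1-based) and optionally annotation (written to INFO).
    """
    samples = list(dosages.index)
    fmt = "GT:DS" if genotypes is not None else "DS"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Expected alternate allele dosage">\n')
        fh.write('##INFO=<ID=ANN,Number=1,Type=String,Description="Annotation class">\n')
        for chrom in dict.fromkeys(str(c) for c in variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\t" + "FORMAT\t"
                 + "\t".join(samples) + "\n")
        for row in variants.itertuples(index=False):
            vid = row.variant_id
            info = f"ANN={row.annotation}" if hasattr(row, "annotation") else "."
            ds = dosages[vid]
            fields = [str(row.chrom), str(row.pos), vid, ref, alt, ".", "PASS",
                      info, fmt]
            for s in samples:
                d = ds.loc[s]
                if genotypes is not None:
                    g = genotypes[vid].loc[s]
                    gt = {0: "0/0", 1: "0/1", 2: "1/1"}.get(int(g), "./.")
                    fields.append(f"{gt}:{d:g}")
                else:
                    fields.append(f"{d:g}")
            fh.write("\t".join(fields) + "\n")


def read_vcf_dosages(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read dosages (DS if present, else GT allele count) from a VCF.

    Returns ``(dosages, variants)`` mirroring :func:`write_vcf_dosages`.
    Missing genotypes are excluded from the per-variant MAF.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    dosage_cols: dict[str, np.ndarray] = {}
    meta = []
    for k, rec in enumerate(vcf):
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}"
        try:
            ds = np.asarray(rec.format("DS"), dtype=float).ravel()
        except (KeyError, TypeError):
            ds = None
        if ds is None:
            gts = np.asarray(rec.genotype.array())[:, :2]
            ds = np.where((gts < 0).any(axis=1), np.nan,
                          (gts > 0).sum(axis=1)).astype(float)
        maf_vals = ds[np.isfinite(ds)]
        maf = float(maf_vals.mean() / 2) if maf_vals.size else float("nan")
        maf = min(maf, 1 - maf)
        ann = dict(rec.INFO).get("ANN", ".")
        meta.append({"variant_id": vid, "chrom": rec.CHROM, "pos": rec.POS,
                     "annotation": ann, "maf": maf})
        dosage_cols[vid] = ds
    variants = pd.DataFrame(meta)
    dosages = pd.DataFrame(dosage_cols, index=pd.Index(samples, name="iid"))
    return dosages, variants
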