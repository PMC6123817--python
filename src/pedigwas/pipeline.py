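"""End-to-end orchestration: simulate -> kinship -> phenotype prep ->
genome scan -> calibration -> replication -> report.

The discovery cohort mirrors the genealogy-driven study design: it is
the union of chip-typed individuals (whose true genotypes are observed)
and untyped individuals with at least one typed first- or second-degree
relative, whose dosages are posterior expected allele counts inferred
through the pedigree.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import calibration, replication
from .association import genome_scan
from .io import PipelineConfig, write_pedigree_tsv, write_phenotype_tsv
from .pedigree import (
    Individual,
    KinshipMatrix,
    Pedigree,
    expected_dosage,
    imputation_info,
    kinship_matrix,
)
from .phenotypes import prepare_phenotype
from .simulate import (
    SimConfig,
    assign_typing_status,
    gene_drop,
    simulate_pedigree,
    simulate_trait,
    simulate_variant_panel,
    _close_relatives,
)

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "infer_cohort_dosages", "PipelineReport"]


@dataclass
class PipelineReport:
    config: dict
    n_pedigree: int
    n_cohort: int
    n_typed: int
    n_inferred: int
    scan: pd.DataFrame
    ledger: pd.DataFrame
    ldsc: calibration.LdscFit
    scheme: calibration.ThresholdScheme
    top_variant: dict
    replication: replication.ReplicationResult | None = None
    combined_p: float | None = None

    def summary(self) -> dict:
        out = {
            "n_pedigree": self.n_pedigree,
            "n_cohort": self.n_cohort,
            "n_typed": self.n_typed,
            "n_inferred": self.n_inferred,
            "n_tested": int(len(self.scan)),
            "n_filtered": int(len(self.ledger)),
            "ldsc_intercept": self.ldsc.intercept,
            "ldsc_factor_applied": self.ldsc.correction_factor,
            "top_variant": self.top_variant,
        }
        if self.replication is not None:
            out["replication"] = vars(self.replication)
            out["combined_p"] = self.combined_p
        return out


def _local_subpedigree(pedigree: Pedigree, target: str) -> Pedigree:
    """Pedigree restricted to the target's first/second-degree
    neighbourhood; parents outside the set become founders with
    Hardy-Weinberg priors.  Keeps exact inference local and fast."""
    keep = {target} | _close_relatives(pedigree, target)
    # include both parents of any kept individual when one is kept
    for iid in list(keep):
        par = pedigree.parents(iid)
        if par and (par[0] in keep or par[1] in keep):
            keep.update(par)
    inds = []
    for iid in keep:
        m = pedigree.member(iid)
        inside = m.father in keep and m.mother in keep
        inds.append(
            Individual(iid, m.father if inside else None,
                       m.mother if inside else None, m.sex, m.birth_year)
        )
    return Pedigree(inds)


def infer_cohort_dosages(
    pedigree: Pedigree,
    true_genotypes: pd.Series,
    typed: pd.Series,
    maf: float,
    targets: list[str],
    seed: int = 0,
) -> pd.Series:
    """Expected allele counts for untyped ``targets`` through the
    genealogy, conditioning on typed genotypes in each target's local
    first/second-degree family."""
    out = {}
    typed_ids = set(typed.index[typed])
    for t in targets:
        sub = _local_subpedigree(pedigree, t)
        obs = {i: int(true_genotypes.loc[i]) for i in sub.ids if i in typed_ids}
        dist = expected_dosage(sub, obs, maf, t, seed=seed)
        out[t] = dist.expected_count
    return pd.Series(out, name="dosage")


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> PipelineReport:
    """Execute every stage on a synthetic cohort and return the report.

    With ``out_dir`` set, writes the pedigree, phenotypes, scan results,
    filter ledger, threshold scheme and a JSON summary.
    """
    sim = SimConfig(**{**config.sim, "seed": config.seed})
    logger.info("simulating pedigree (seed=%d)", config.seed)
    ped = simulate_pedigree(sim)
    rare = gene_drop(ped, sim.rare_maf, seed=config.seed + 1)["drop0"]
    panel, variants = simulate_variant_panel(sim, ped)
    measurements = simulate_trait(ped, rare, sim.rare_effect_sd, sim)
    typed, inferable = assign_typing_status(ped, sim.chip_typed_fraction,
                                            seed=config.seed + 2)

    cohort = [i for i in ped.topological_order
              if typed.loc[i] or i in set(inferable)]
    logger.info("cohort: %d of %d pedigree members (%d typed, %d inferred)",
                len(cohort), len(ped), int(typed.loc[cohort].sum()),
                len(cohort) - int(typed.loc[cohort].sum()))

    # rare-variant dosages: observed for typed, inferred for the rest
    inferred_targets = [i for i in cohort if not typed.loc[i]]
    inferred = infer_cohort_dosages(ped, rare, typed, sim.rare_maf,
                                    inferred_targets, seed=config.seed + 3)
    rare_dosage = rare.loc[cohort].astype(float)
    rare_dosage.loc[inferred.index] = inferred

    pheno = prepare_phenotype(measurements[measurements["iid"].isin(cohort)])
    y = pheno.to_series()
    cohort = list(y.index)

    logger.info("kinship matrix over %d subjects", len(cohort))
    phi = kinship_matrix(ped, cohort)

    dosages = panel.loc[cohort].copy()
    rare_info = imputation_info(rare_dosage.loc[cohort].to_numpy())
    dosages["rare1"] = rare_dosage.loc[cohort]
    rare_maf_hat = float(dosages["rare1"].mean() / 2)
    variants = pd.concat(
        [variants,
         pd.DataFrame([{"variant_id": "rare1", "chrom": "19", "pos": 11_383_104,
                        "block": -1, "annotation": "high",
                        "maf": min(rare_maf_hat, 1 - rare_maf_hat),
                        "info": rare_info}])],
        ignore_index=True,
    )

    logger.info("genome scan: %d variants (info > %g, MAF > %g)",
                dosages.shape[1], config.info_cutoff, config.maf_cutoff)
    scan, ledger = genome_scan(y, dosages, phi, variants,
                               info_cutoff=config.info_cutoff,
                               maf_cutoff=config.maf_cutoff)

    # LDSC correction from the common-variant panel
    common_mask = scan["variant_id"] != "rare1"
    scores = calibration.ld_scores(panel.loc[cohort].to_numpy(), window=config.ld_window)
    score_map = dict(zip(panel.columns, scores))
    chis = scan.loc[common_mask, "chi2"].to_numpy()
    ld = np.array([score_map[v] for v in scan.loc[common_mask, "variant_id"]])
    ldsc = calibration.ldsc_intercept(chis, ld, min_variants=min(100, len(chis)))
    corr_chi2, corr_p = calibration.apply_correction(scan["chi2"].to_numpy(), ldsc)
    scan["chi2"], scan["p"] = corr_chi2, corr_p

    weights = config.class_weights or calibration.DEFAULT_CLASS_WEIGHTS
    counts = scan["annotation"].value_counts().to_dict()
    weights = {c: weights[c] for c in counts}
    scheme = calibration.weighted_thresholds(counts, weights, fwer=config.fwer)
    scan = calibration.annotate_scan(scan, scheme)

    top = scan.sort_values("corrected_p").iloc[0].to_dict()

    rep = None
    comb = None
    if config.run_replication:
        rep, comb = _replication_stage(ped, rare, sim, typed, cohort,
                                       config, top)

    report = PipelineReport(
        config=vars(config), n_pedigree=len(ped), n_cohort=len(cohort),
        n_typed=int(typed.loc[cohort].sum()),
        n_inferred=len(cohort) - int(typed.loc[cohort].sum()),
        scan=scan, ledger=ledger, ldsc=ldsc, scheme=scheme,
        top_variant=top, replication=rep, combined_p=comb,
    )
    if out_dir is not None:
        _write_bundle(report, ped, pheno, out_dir)
    return report


def _replication_stage(ped, rare, sim, typed, discovery_cohort, config, top):
    """Measure fresh assay values for carriers outside the discovery
    cohort and matched non-carrier controls, then run the paired tests
    and Fisher's combination with the discovery p-value."""
    rng = np.random.default_rng(config.seed + 7)
    outside = [i for i in ped.topological_order if i not in set(discovery_cohort)]
    carriers = [i for i in outside if rare.loc[i] > 0]
    controls = [i for i in outside if rare.loc[i] == 0]
    if not carriers:
        logger.warning("no carriers outside the discovery cohort; replication skipped")
        return None, None
    carriers = carriers[: config.n_replication_pairs]

    meta = {}
    values = {}
    for iid in carriers + controls:
        m = ped.member(iid)
        meta[iid] = {"sex": m.sex, "birth_year": m.birth_year or 0,
                     "sample_year": int(rng.integers(2015, 2018))}
        latent = (sim.sex_effect * (m.sex == 1)
                  + sim.rare_effect_sd * float(rare.loc[iid])
                  + rng.standard_normal())
        base = float(np.exp(sim.raw_scale * latent + np.log(sim.raw_median)))
        reps = base * np.exp(rng.normal(0, sim.repeat_noise_sd, size=3))
        values[iid], _ = replication.triplicate_mean(reps)
    meta_df = pd.DataFrame(meta).T
    vals = pd.Series(values)
    pairs = replication.match_controls(carriers, controls, meta_df, vals)
    if len(pairs) < 2:
        return None, None
    rep = replication.fold_summary(pairs)
    comb = replication.fisher_combine([top["p"], rep.wilcoxon_p]).combined_p
    return rep, comb


def _write_bundle(report: PipelineReport, ped, pheno, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_pedigree_tsv(ped, out / "pedigree.tsv")
    write_phenotype_tsv(
        pd.DataFrame({"iid": pheno.ids, "phenotype": pheno.values,
                      "n_measurements": pheno.n_measurements}),
        out / "phenotypes.tsv",
    )
    report.scan.to_csv(out / "scan.tsv", sep="\t", index=False, na_rep=".")
    report.ledger.to_csv(out / "filter_ledger.tsv", sep="\t", index=False)
    report.scheme.to_frame().to_csv(out / "thresholds.tsv", sep="\t", index=False)
    with open(out / "summary.json", "w") as fh:
        json.dump(report.summary(), fh, indent=2, default=float)
    logger.info("report bundle written to %s", out)
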