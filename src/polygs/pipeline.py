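"""End-to-end orchestration: simulate -> QC -> parentage -> kinship ->
model fits -> cross-validation -> gains, producing a comparison table of
heritabilities, type-B correlations, accuracies, PA/PACC and expected
gains for the ABLUP-partial, ABLUP-full and GBLUP analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import crossval, gains, kinship, parentage, remlfit, simpop, snpqc
from .datatypes import GenotypeMatrix, PedigreeTable, TraitTable

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    config: simpop.SimConfig
    genotypes: GenotypeMatrix
    true_pedigree: simpop.TruePedigree
    traits: TraitTable
    qc_report: snpqc.QCReport
    parentage_table: pd.DataFrame
    recovered_pedigree: PedigreeTable
    fits: dict[tuple[str, str], remlfit.FitResult]  # (trait, model) -> fit
    cv_results: dict[tuple[str, str], crossval.CVResult]
    gain_reports: dict[str, gains.GainReport]
    comparison: pd.DataFrame = field(default=None)

    def summary_table(self) -> pd.DataFrame:
        rows = []
        for (trait, model), fit in self.fits.items():
            cv = self.cv_results.get((trait, model))
            rows.append(
                {
                    "trait": trait,
                    "model": model,
                    "h2": fit.params.h2,
                    "h2_se": fit.params.h2_se,
                    "r_B": fit.params.r_b,
                    "PA": cv.pa if cv else np.nan,
                    "PACC": cv.pacc if cv else np.nan,
                    "gain_pct": self.gain_reports[trait].gain_pct
                    if model == "GBLUP" and trait in self.gain_reports
                    else np.nan,
                }
            )
        return pd.DataFrame(rows)


def run_polycross_pipeline(
    config: simpop.SimConfig,
    traits_to_fit: list[str] | None = None,
    cv_reps: int = 3,
    cv_folds: int = 10,
    refit_cv_variances: bool = False,
    selection_fraction: float = 0.05,
    years: float = gains.YEARS_POLYCROSS,
) -> PipelineResult:
    """Run the full polycross analysis on one simulated realisation.

    The parentage stage sees only what a real analysis would: parent
    genotypes, offspring genotypes, and the crossing records (expected
    mothers).  The recovered full pedigree then feeds the ABLUP-full fit,
    while ABLUP-partial uses mothers only and GBLUP the marker matrix.
    """
    parents = simpop.simulate_parents(config)
    offspring, true_ped = simpop.simulate_polycross(parents, config)
    arch = simpop.build_architecture(offspring, config)
    traits = simpop.simulate_phenotypes(offspring, arch, config, pedigree=true_ped)
    trait_names = traits_to_fit or [t.name for t in config.trait_specs]

    # --- SNP QC + imputation ---------------------------------------------
    stats = snpqc.compute_snp_stats(offspring)
    qc = snpqc.filter_snps(stats)
    offspring_qc = offspring.subset(snp_ids=qc.retained)
    parents_qc = parents.subset(snp_ids=qc.retained)
    imputed, imp_accuracy = snpqc.impute_knn(offspring_qc, n_mask=min(2000, offspring_qc.calls.size // 10), seed=config.seed)
    log.info("QC retained %d/%d SNPs; imputation accuracy %.3f",
             len(qc.retained), offspring.n_snps, imp_accuracy)

    # --- parentage recovery ----------------------------------------------
    expected = {o: true_ped.dam[o] for o in offspring.ids}
    mothers_g = parents_qc.subset(ids=config.mother_ids)
    fathers_g = parents_qc.subset(ids=config.father_ids)
    mverify = parentage.verify_mothers(
        offspring_qc, mothers_g, expected, error_rate=0.02
    )
    dam_assign = {
        r.id: r.assigned_dam
        for r in mverify.table.itertuples()
        if r.assigned_dam is not None
    }
    freqs = np.nan_to_num(offspring_qc.allele_freqs(), nan=0.5)
    thr = parentage.estimate_delta_threshold(
        fathers_g, freqs, n_simulated=2000, error_rate=0.02,
        sampled_fraction=1.0, seed=config.seed + 1,
    )
    passign = parentage.assign_paternity(
        offspring_qc, fathers_g, dam_assign, mothers_g, thr, allele_freqs=freqs
    )
    g_all = kinship.build_G(snpqc.mode_impute(offspring_qc))
    unassigned = [r.id for r in passign.table.itertuples() if r.assigned_sire is None]
    clusters = parentage.cluster_unassigned_sires(
        unassigned, g_all, mother_of=dam_assign
    )
    flags = parentage.flag_contaminants(clusters)
    ptable = passign.table.merge(
        flags.table[["id", "cluster", "cluster_size", "status"]],
        on="id", how="left", suffixes=("", "_cluster"),
    )
    contaminants = set(flags.table.loc[flags.table["status"] == "contaminant", "id"])

    # recovered pedigree: assigned sires, cluster labels for unknown fathers
    cluster_of = {
        oid: label for label, members in clusters.items() for oid in members
    }
    recs = [(p, None, None) for p in parents.ids]
    recs += [
        (label, None, None)
        for label, members in clusters.items()
        if len(members) >= 7
    ]
    keep_ids = []
    for r in passign.table.itertuples():
        if r.id in contaminants:
            continue
        dam = dam_assign.get(r.id)
        if dam is None:
            continue  # mirrors discarding offspring with unverified mothers
        sire = r.assigned_sire or cluster_of.get(r.id)
        recs.append((r.id, dam, sire))
        keep_ids.append(r.id)
    recovered = PedigreeTable.from_tuples(recs)
    traits_kept = traits.subset(keep_ids)
    geno_kept = imputed.subset(ids=keep_ids)

    # --- relationship matrices -------------------------------------------
    a_full = kinship.build_A(recovered, mode="full")
    a_partial = kinship.build_A(recovered, mode="partial")
    g = kinship.build_G(geno_kept)

    models = {
        "ABLUP_partial": (a_partial, "A_partial"),
        "ABLUP_full": (a_full, "A_full"),
        "GBLUP": (g, "G"),
    }
    fits: dict[tuple[str, str], remlfit.FitResult] = {}
    cv_results: dict[tuple[str, str], crossval.CVResult] = {}
    gain_reports: dict[str, gains.GainReport] = {}
    fam_key = {i: recovered.parents_of(i)[0] or "_" for i in keep_ids}
    for trait in trait_names:
        for model, (kern, tag) in models.items():
            spec = remlfit.ModelSpec(trait=trait, kernel_kind=tag)
            fits[(trait, model)] = remlfit.fit_reml(traits_kept, kern, spec)
        h2_ref = fits[(trait, "GBLUP")].params.h2
        for model, (kern, tag) in models.items():
            spec = remlfit.ModelSpec(trait=trait, kernel_kind=tag)
            cv_results[(trait, model)] = crossval.run_cv(
                traits_kept, kern, spec, k=cv_folds, reps=cv_reps,
                h2_reference=h2_ref, family_key=fam_key,
                refit_variances=refit_cv_variances,
                reference_fit=fits[(trait, model)],
                seed=config.seed + 7, model_label=model,
            )
        # gains from GBLUP CV predictions
        spec = remlfit.ModelSpec(trait=trait, kernel_kind="G")
        gebv_reps = [
            crossval.cv_predictions(
                traits_kept, g, spec, k=cv_folds, family_key=fam_key,
                reference_fit=fits[(trait, "GBLUP")], seed=config.seed + 100 + rep,
            )
            for rep in range(cv_reps)
        ]
        pheno_mean = float(traits_kept.data[trait].mean())
        gain_reports[trait] = gains.expected_gain(
            gebv_reps, pheno_mean, cv_results[(trait, "GBLUP")].pacc,
            years=years, fraction=selection_fraction, trait=trait,
            relationships=a_full,
        )

    result = PipelineResult(
        config=config,
        genotypes=offspring,
        true_pedigree=true_ped,
        traits=traits,
        qc_report=qc,
        parentage_table=ptable,
        recovered_pedigree=recovered,
        fits=fits,
        cv_results=cv_results,
        gain_reports=gain_reports,
    )
    result.comparison = result.summary_table()
    return result
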