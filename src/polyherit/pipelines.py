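"""High-level experiment drivers combining the pipeline stages.

These functions wire the synthetic generators into the analysis modules to
run the study designs the package is built around: compartment-partitioned
GREML recovery on ascertained case-control cohorts, compartment-restricted
PRS threshold sweeps with a shared discovery/validation architecture, and
the matched-null overlap permutation experiment on a large synthetic
universe.  They are used by the test suite and the acceptance script alike.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import synthetic as syn
from .annotation import overlap_marks
from .datatypes import COMPARTMENTS, CohortData, CompartmentAssignment
from .enrichment import (
    MatchCriteria,
    annotate_universe,
    null_overlap_counts,
    permutation_overlap_test,
    sample_matched_nulls,
)
from .heritability import LiabilityScaleParams, compute_grm, reml_fit
from .polygenic import PRSConfig, compartment_sweeps
from .association import scan


def proportional_assignment(
    snp_table: pd.DataFrame,
    fractions: dict[str, float],
    rng: np.random.Generator,
    window_kb: float = 10.0,
) -> CompartmentAssignment:
    """Random compartment assignment with exact SNP-count fractions.

    Used for designs that fix the compartment split directly (e.g. 5% /
    45% / 50%) rather than deriving it from gene geometry.
    """
    m = len(snp_table)
    counts = {c: int(round(fractions.get(c, 0.0) * m)) for c in COMPARTMENTS}
    # absorb rounding into the largest compartment
    largest = max(counts, key=counts.get)
    counts[largest] += m - sum(counts.values())
    labels = np.concatenate([[c] * k for c, k in counts.items()])
    rng.shuffle(labels)
    return CompartmentAssignment(
        labels=pd.Series(labels, index=snp_table["snp"].to_numpy()), window_kb=window_kb
    )


@dataclass
class RemlRecoveryResult:
    """Per-seed liability-scale estimates, SEs and truth for each compartment."""

    estimates: pd.DataFrame  # rows: seeds; columns: compartments
    ses: pd.DataFrame
    truth: dict[str, float]

    def within_2se(self) -> pd.DataFrame:
        err = self.estimates - pd.Series(self.truth)
        return err.abs() <= 2.0 * self.ses


def compartment_reml_recovery(
    n_individuals: int = 4000,
    n_snps: int = 3000,
    split: dict[str, float] | None = None,
    h2: dict[str, float] | None = None,
    prevalence: float = 0.06,
    case_fraction: float = 0.5,
    seeds: range | list[int] = range(10),
    within_block_rho: float = 0.0,
) -> RemlRecoveryResult:
    """Three-component GREML parameter recovery on ascertained cohorts.

    For each seed: simulate a liability-threshold disease with the given
    per-compartment liability h2 over a fixed compartment split, ascertain a
    case-enriched cohort, build one GRM per compartment, fit the joint
    three-component REML, and convert estimates to the liability scale with
    the prevalence/case-proportion multiplier.
    """
    split = split or {"genic_coding": 0.05, "genic_noncoding": 0.45, "intergenic": 0.50}
    h2 = h2 or {"genic_coding": 0.10, "genic_noncoding": 0.25, "intergenic": 0.07}
    est_rows, se_rows = [], []
    for seed in seeds:
        cfg = syn.SimulationConfig(
            n_individuals=n_individuals,
            n_snps=n_snps,
            within_block_rho=within_block_rho,
            prevalence=prevalence,
            sample_case_fraction=case_fraction,
            h2_by_compartment=h2,
            seed=int(seed),
        )
        rng = np.random.default_rng(cfg.seed)
        snp_table = syn.draw_snp_table(cfg, rng)
        assignment = proportional_assignment(snp_table, split, rng)
        effects = syn.draw_effects(snp_table, assignment, cfg, rng)
        labels = assignment.labels.to_numpy()
        effects = syn._calibrate_scales(effects, labels, snp_table, cfg, rng)
        cohort = syn.simulate_case_control(cfg, snp_table, effects, rng)
        grms = [
            compute_grm(cohort, np.flatnonzero(labels == c)) for c in COMPARTMENTS
        ]
        fit = reml_fit(cohort.phenotype, cohort.covariates, grms)
        lp = LiabilityScaleParams(prevalence, float(cohort.phenotype.mean()))
        est_rows.append(dict(zip(COMPARTMENTS, fit.ratios * lp.multiplier)))
        se_rows.append(dict(zip(COMPARTMENTS, fit.se_ratios * lp.multiplier)))
    idx = list(seeds)
    return RemlRecoveryResult(
        estimates=pd.DataFrame(est_rows, index=idx),
        ses=pd.DataFrame(se_rows, index=idx),
        truth=h2,
    )


def prs_compartment_experiment(
    n_discovery: int = 4000,
    n_validation: int = 2000,
    n_snps: int = 2000,
    h2: dict[str, float] | None = None,
    split: dict[str, float] | None = None,
    prevalence: float = 0.06,
    case_fraction: float = 0.5,
    seed: int = 0,
    thresholds: tuple[float, ...] | None = None,
) -> dict[str, pd.DataFrame]:
    """Compartment-restricted PRS sweeps with a shared genetic architecture.

    Discovery and validation cohorts are independent ascertained samples from
    the same liability model; the discovery cohort is scanned to produce
    summary statistics and each compartment's SNPs are scored in the
    validation cohort across the threshold grid.
    """
    h2 = h2 or {"genic_coding": 0.03, "genic_noncoding": 0.30, "intergenic": 0.03}
    split = split or {"genic_coding": 0.10, "genic_noncoding": 0.45, "intergenic": 0.45}
    rng = np.random.default_rng(seed)
    cfg = syn.SimulationConfig(
        n_individuals=n_discovery,
        n_snps=n_snps,
        within_block_rho=0.0,
        prevalence=prevalence,
        sample_case_fraction=case_fraction,
        h2_by_compartment=h2,
        seed=seed,
    )
    snp_table = syn.draw_snp_table(cfg, rng)
    assignment = proportional_assignment(snp_table, split, rng)
    effects = syn.draw_effects(snp_table, assignment, cfg, rng)
    effects = syn._calibrate_scales(effects, assignment.labels.to_numpy(), snp_table, cfg, rng)
    discovery_cohort = syn.simulate_case_control(cfg, snp_table, effects, rng)
    cfg_val = syn.SimulationConfig(**{**cfg.__dict__, "n_individuals": n_validation})
    validation_cohort = syn.simulate_case_control(cfg_val, snp_table, effects, rng)
    stats = scan(discovery_cohort)
    prs_cfg = PRSConfig() if thresholds is None else PRSConfig(thresholds=thresholds)
    return compartment_sweeps(stats, validation_cohort, assignment, prs_cfg)


@dataclass
class OverlapExperimentResult:
    observed: int
    n_queries: int
    n_dropped: int
    result: object  # PermutationTestResult


def matched_null_overlap_experiment(
    n_universe_snps: int = 100_000,
    n_individuals: int = 400,
    n_queries: int = 45,
    n_sets: int = 10_000,
    seed: int = 0,
    mark_biased_queries: float = 0.8,
    n_genes: int | None = None,
) -> OverlapExperimentResult:
    """Full matched-null permutation run on a large synthetic universe.

    Builds a universe cohort with block LD, annotates it (MAF, LD buddies,
    gene distance/density), picks query SNPs enriched for histone-mark
    overlap (fraction ``mark_biased_queries`` drawn from mark-resident SNPs),
    draws matched null sets and computes the empirical overlap p.
    """
    cfg = syn.SimulationConfig(
        n_individuals=n_individuals,
        n_snps=n_universe_snps,
        within_block_rho=0.6,
        n_cell_types=6,
        peak_density=0.15,
        peak_sharing=0.4,
        seed=seed,
    )
    rng = np.random.default_rng(seed)
    snp_table = syn.draw_snp_table(cfg, rng)
    fixture = syn.simulate_annotations(cfg, n_genes=n_genes, rng=rng)
    dosages = syn.dosage_matrix(snp_table["freq"].to_numpy(), cfg, n_individuals, rng)
    cohort = CohortData(dosages=dosages, snp_table=snp_table)
    universe = annotate_universe(cohort, fixture.gene_models)
    membership = overlap_marks(snp_table, fixture.peak_tracks)
    in_any_mark = membership.any(axis=1)

    marked = snp_table["snp"].to_numpy()[in_any_mark.to_numpy()]
    unmarked = snp_table["snp"].to_numpy()[~in_any_mark.to_numpy()]
    n_marked = int(round(mark_biased_queries * n_queries))
    queries = list(rng.choice(marked, n_marked, replace=False)) + list(
        rng.choice(unmarked, n_queries - n_marked, replace=False)
    )
    criteria = MatchCriteria(n_sets=n_sets, seed=seed)
    collection = sample_matched_nulls(queries, universe, criteria)
    observed, null_counts = null_overlap_counts(collection, in_any_mark)
    res = permutation_overlap_test(observed, null_counts)
    # every emitted null must satisfy all four criteria vs its query
    _assert_nulls_match(collection, universe, criteria)
    return OverlapExperimentResult(
        observed=observed,
        n_queries=len(collection.queries),
        n_dropped=len(collection.dropped_queries),
        result=res,
    )


def _assert_nulls_match(collection, universe: pd.DataFrame, criteria: MatchCriteria) -> None:
    """Verify the matched-null invariant on a sample of emitted sets."""
    uni = universe.reset_index(drop=True)
    by_snp = uni.set_index("snp")
    check_sets = collection.sets[:: max(1, collection.n_sets // 50)]
    for s in check_sets:
        for j, q in enumerate(collection.queries):
            row_q = by_snp.loc[q]
            row_n = uni.iloc[s[j]]
            assert abs(row_n["maf"] - row_q["maf"]) <= criteria.maf_tolerance + 1e-12
            assert (
                abs(row_n["ld_buddies"] - row_q["ld_buddies"])
                <= criteria.ld_buddy_tolerance * row_q["ld_buddies"] + 1e-12
            )
            assert (
                abs(row_n["gene_distance"] - row_q["gene_distance"])
                <= criteria.gene_distance_tolerance * row_q["gene_distance"] + 1e-9
            )
            assert (
                abs(row_n["gene_density"] - row_q["gene_density"])
                <= criteria.gene_density_tolerance * row_q["gene_density"] + 1e-12
            )
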