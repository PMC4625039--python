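"""Synthetic cohorts with known genetic architecture.

Generates every input the pipeline consumes: block-LD genotype dosages, a
liability-threshold binary disease whose heritability is concentrated in
configurable genomic compartments, gene models with coding subintervals,
per-(mark, cell type) regulatory peak tracks with tunable sharing, a
scale-free protein-interaction graph and per-SNP conservation scores.

Genotypes are produced by thresholding latent Gaussian haplotypes with
exchangeable within-block correlation, so the inter-SNP r2 inside a block is
tunable through a single parameter while per-SNP allele frequencies are
honoured exactly in expectation.

Disease liability follows the classical threshold model: standardized
genotypes weighted by per-SNP effects (Gaussian within compartment, zero in
compartments configured with zero heritability) plus a standard normal
residual; an individual is a case iff liability exceeds the quantile implied
by the population prevalence K.  Case-enriched sampling (ascertainment) is
available to emulate case-control GWAS designs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import COMPARTMENTS, CohortData, CompartmentAssignment, GeneModel, GenomeFixture

DEFAULT_MARKS = ("H3K27ac", "H3K4me3", "H3K9ac")

#: average SNP spacing (bp) used to derive an implicit genome length
BP_PER_SNP = 1000


@dataclass
class SimulationConfig:
    """Ground-truth parameters of a synthetic case-control study.

    ``h2_by_compartment`` holds liability-scale variance fractions; their sum
    must lie in [0, 1].  ``prevalence`` is the population prevalence K of the
    liability-threshold disease (default 0.06); ``sample_case_fraction`` P, if
    set, requests a case-enriched (ascertained) sample.
    """

    n_individuals: int = 2000
    n_snps: int = 2000
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 20
    within_block_rho: float = 0.0
    prevalence: float = 0.06
    sample_case_fraction: float | None = None
    h2_by_compartment: dict[str, float] = field(
        default_factory=lambda: {"genic_coding": 0.10, "genic_noncoding": 0.25, "intergenic": 0.07}
    )
    n_cell_types: int = 8
    peak_density: float = 0.15
    peak_sharing: float = 0.5
    n_covariates: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals <= 0 or self.n_snps <= 0:
            raise ValueError("n_individuals and n_snps must be positive")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie in (0, 0.5]")
        if not (0 <= self.within_block_rho < 1):
            raise ValueError("within_block_rho must lie in [0, 1)")
        if self.ld_block_size <= 0:
            raise ValueError("ld_block_size must be positive")
        if not (0 < self.prevalence < 1):
            raise ValueError("prevalence must lie in (0, 1)")
        h2_sum = sum(self.h2_by_compartment.values())
        if not (0 <= h2_sum <= 1):
            raise ValueError(f"sum of h2_by_compartment is {h2_sum}, must be in [0, 1]")
        if any(v < 0 for v in self.h2_by_compartment.values()):
            raise ValueError("h2 fractions must be non-negative")
        if self.sample_case_fraction is not None and not (
            self.prevalence <= self.sample_case_fraction < 1
        ):
            raise ValueError("sample_case_fraction must lie in [prevalence, 1)")

    @property
    def genome_length(self) -> int:
        return self.n_snps * BP_PER_SNP

    @property
    def h2_total(self) -> float:
        return float(sum(self.h2_by_compartment.values()))


# ---------------------------------------------------------------------------
# genotypes


def _distinct_sorted_positions(n: int, genome_length: int, rng: np.random.Generator) -> np.ndarray:
    """n distinct 1-based positions, sorted increasing."""
    if n > genome_length:
        raise ValueError("genome too short for the requested number of SNPs")
    pos: np.ndarray = np.unique(rng.integers(1, genome_length + 1, size=int(n * 1.2) + 16))
    while pos.size < n:
        extra = rng.integers(1, genome_length + 1, size=n)
        pos = np.unique(np.concatenate([pos, extra]))
    return np.sort(rng.choice(pos, size=n, replace=False))


def draw_snp_table(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Per-SNP metadata: id, chromosome, position, alleles, MAF, info score."""
    mafs = rng.uniform(config.maf_range[0], config.maf_range[1], config.n_snps)
    positions = _distinct_sorted_positions(config.n_snps, config.genome_length, rng)
    return pd.DataFrame(
        {
            "snp": [f"rs{i}" for i in range(config.n_snps)],
            "chrom": "1",
            "pos": positions,
            "a1": "A",
            "a2": "G",
            "freq": mafs,
            "info": rng.uniform(0.7, 1.0, config.n_snps),
        }
    )


def _dosage_block(
    mafs: np.ndarray, rho: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Diploid dosages for one LD block via a thresholded exchangeable latent."""
    m = len(mafs)
    thresh = stats.norm.ppf(mafs)
    out = np.zeros((n, m))
    for _ in range(2):  # two haplotypes
        shared = rng.standard_normal((n, 1))
        latent = math.sqrt(rho) * shared + math.sqrt(1.0 - rho) * rng.standard_normal((n, m))
        out += latent < thresh
    return out


def dosage_matrix(
    mafs: np.ndarray, config: SimulationConfig, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Dosages for ``n`` individuals at the given SNP frequencies."""
    m = len(mafs)
    block = config.ld_block_size
    cols = []
    for start in range(0, m, block):
        cols.append(_dosage_block(mafs[start : start + block], config.within_block_rho, n, rng))
    return np.concatenate(cols, axis=1)


def simulate_genotypes(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> CohortData:
    """Cohort of block-correlated dosages (no phenotype yet).

    Deterministic under a fixed ``config.seed`` when ``rng`` is not supplied.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    snp_table = draw_snp_table(config, rng)
    dosages = dosage_matrix(snp_table["freq"].to_numpy(), config, config.n_individuals, rng)
    covs = rng.standard_normal((config.n_individuals, config.n_covariates))
    return CohortData(dosages=dosages, snp_table=snp_table, covariates=covs)


# ---------------------------------------------------------------------------
# genome fixture


def _merge_intervals(iv: np.ndarray) -> np.ndarray:
    if len(iv) == 0:
        return iv.reshape(0, 2).astype(int)
    iv = iv[np.argsort(iv[:, 0])]
    merged = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.array(merged, dtype=int)


def _place_genes(
    genome_length: int, n_genes: int, rng: np.random.Generator
) -> list[GeneModel]:
    lengths = rng.integers(5_000, 50_001, n_genes)
    slack = genome_length - int(lengths.sum())
    if slack < 0:
        raise ValueError(
            f"cannot place {n_genes} non-overlapping genes totalling "
            f"{int(lengths.sum())} bp in a {genome_length} bp genome"
        )
    gaps = np.floor(rng.dirichlet(np.ones(n_genes + 1)) * slack).astype(int)
    genes = []
    cursor = 0
    for i in range(n_genes):
        start = cursor + int(gaps[i])
        end = start + int(lengths[i])
        n_exons = int(rng.integers(1, 5))
        inner = np.sort(rng.choice(np.arange(start + 1, end), 2 * n_exons, replace=False))
        coding = [(int(inner[2 * k]), int(inner[2 * k + 1])) for k in range(n_exons)]
        coding = [(s, e) for s, e in coding if s < e]
        if not coding:  # degenerate draw: use the middle third
            coding = [(start + (end - start) // 3, end - (end - start) // 3)]
        genes.append(
            GeneModel(
                gene_id=f"gene{i}",
                chrom="1",
                start=start,
                end=end,
                strand="+" if rng.random() < 0.5 else "-",
                coding=coding,
            )
        )
        cursor = end
    return genes


def _sample_in_territory(
    territory: np.ndarray, genome_length: int, k: int, rng: np.random.Generator, bias: float
) -> np.ndarray:
    """Peak centres, a fraction ``bias`` drawn inside the territory."""
    if len(territory) == 0 or bias <= 0:
        return rng.integers(0, genome_length, k)
    lens = territory[:, 1] - territory[:, 0]
    cum = np.concatenate([[0], np.cumsum(lens)])
    inside = rng.random(k) < bias
    offs = rng.integers(0, cum[-1], k)
    seg = np.searchsorted(cum, offs, side="right") - 1
    centres = territory[seg, 0] + (offs - cum[seg])
    uniform = rng.integers(0, genome_length, k)
    return np.where(inside, centres, uniform)


def _peaks_from_centres(
    centres: np.ndarray, genome_length: int, rng: np.random.Generator
) -> np.ndarray:
    widths = np.clip(rng.normal(1500, 300, len(centres)), 500, 3000).astype(int)
    starts = np.clip(centres - widths // 2, 0, genome_length - 1)
    ends = np.clip(centres + widths // 2, starts + 1, genome_length)
    return np.column_stack([starts, ends])


def simulate_annotations(
    config: SimulationConfig,
    genome_length: int | None = None,
    n_genes: int | None = None,
    rng: np.random.Generator | None = None,
    window_kb: float = 10.0,
    genic_bias: float = 0.9,
    marks: tuple[str, ...] = DEFAULT_MARKS,
) -> GenomeFixture:
    """Gene models, peak tracks, PPI graph and conservation scores.

    Peaks are placed preferentially (fraction ``genic_bias``) inside genic
    territory (gene body plus ``window_kb``); a fraction ``peak_sharing`` of
    each mark's peaks is common to every cell type, the rest are placed
    independently per cell type.  Conservation scores follow a two-component
    Gaussian mixture so that a "< 5" cutoff separates a conserved minority.
    """
    import networkx as nx

    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    if genome_length is None:
        genome_length = config.genome_length
    if n_genes is None:
        n_genes = max(1, genome_length // 200_000)

    genes = _place_genes(genome_length, n_genes, rng) if n_genes > 0 else []
    w = int(window_kb * 1000)
    territory = _merge_intervals(
        np.array([[max(0, g.start - w), min(genome_length, g.end + w)] for g in genes])
        if genes
        else np.empty((0, 2))
    )
    terr_len = int((territory[:, 1] - territory[:, 0]).sum()) if len(territory) else genome_length
    mean_width = 1500
    n_peaks = max(1, round(config.peak_density * terr_len / mean_width))

    peak_tracks: dict[str, dict[str, np.ndarray]] = {}
    cell_types = [f"celltype{i}" for i in range(config.n_cell_types)]
    for mark in marks:
        n_shared = rng.binomial(n_peaks, config.peak_sharing)
        shared = _peaks_from_centres(
            _sample_in_territory(territory, genome_length, n_shared, rng, genic_bias),
            genome_length,
            rng,
        )
        peak_tracks[mark] = {}
        for ct in cell_types:
            private = _peaks_from_centres(
                _sample_in_territory(
                    territory, genome_length, n_peaks - n_shared, rng, genic_bias
                ),
                genome_length,
                rng,
            )
            peak_tracks[mark][ct] = _merge_intervals(np.vstack([shared, private]))

    if n_genes >= 3:
        g = nx.barabasi_albert_graph(n_genes, m=2, seed=int(rng.integers(2**31)))
        ppi = [(f"gene{a}", f"gene{b}") for a, b in g.edges()]
    else:
        ppi = []

    conserved = rng.random(config.n_snps) < 0.15
    conservation = np.where(conserved, rng.normal(7.0, 1.5, config.n_snps), rng.normal(0.0, 2.0, config.n_snps))
    return GenomeFixture(
        gene_models=genes,
        peak_tracks=peak_tracks,
        ppi_edges=ppi,
        conservation=conservation,
        genome_length=genome_length,
    )


# ---------------------------------------------------------------------------
# phenotypes


@dataclass
class PhenotypeSimulation:
    """True per-SNP effects (standardized-genotype scale), liabilities and status."""

    effects: np.ndarray
    liability: np.ndarray
    phenotype: np.ndarray
    threshold: float

    @property
    def case_fraction(self) -> float:
        return float(self.phenotype.mean())


def draw_effects(
    snp_table: pd.DataFrame,
    assignment: CompartmentAssignment,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-SNP liability effects: N(0, h2_c / M_c) within compartment c.

    SNPs in compartments with configured h2 of zero get exactly zero effect.
    """
    labels = assignment.labels.reindex(snp_table["snp"])
    if labels.isna().any():
        raise ValueError("compartment assignment does not cover every SNP")
    effects = np.zeros(len(snp_table))
    for comp in COMPARTMENTS:
        h2 = config.h2_by_compartment.get(comp, 0.0)
        mask = (labels == comp).to_numpy()
        m_c = int(mask.sum())
        if h2 > 0 and m_c > 0:
            effects[mask] = rng.normal(0.0, math.sqrt(h2 / m_c), m_c)
    return effects


def _standardize(dosages: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    sd = np.sqrt(2.0 * freqs * (1.0 - freqs))
    return (dosages - 2.0 * freqs) / sd


def _calibrate_scales(
    effects: np.ndarray,
    labels: np.ndarray,
    snp_table: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
    n_ref: int = 4000,
) -> np.ndarray:
    """Rescale effects so each compartment contributes its exact h2 fraction.

    Uses a reference population draw to measure the realized genetic variance
    per compartment (which differs from the target by effect-sampling and LD
    noise) and divides it out.
    """
    freqs = snp_table["freq"].to_numpy()
    ref = dosage_matrix(freqs, config, n_ref, rng)
    z = _standardize(ref, freqs)
    scaled = effects.copy()
    for comp in COMPARTMENTS:
        h2 = config.h2_by_compartment.get(comp, 0.0)
        mask = labels == comp
        if h2 > 0 and mask.any():
            g_c = z[:, mask] @ effects[mask]
            v = g_c.var()
            if v > 0:
                scaled[mask] = effects[mask] * math.sqrt(h2 / v)
    return scaled


def simulate_phenotypes(
    cohort: CohortData,
    assignment: CompartmentAssignment,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    calibrate: bool = True,
) -> PhenotypeSimulation:
    """Liability-threshold phenotypes for an existing cohort.

    Liability = standardized-genotype score + N(0, 1 - h2) residual; an
    individual is a case iff liability > Phi^-1(1 - K).  Sets
    ``cohort.phenotype`` in place and returns the ground truth.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    h2 = config.h2_total
    effects = draw_effects(cohort.snp_table, assignment, config, rng)
    labels = assignment.labels.reindex(cohort.snp_table["snp"]).to_numpy()
    if calibrate and h2 > 0:
        effects = _calibrate_scales(effects, labels, cohort.snp_table, config, rng)
    freqs = cohort.snp_table["freq"].to_numpy()
    g = _standardize(cohort.dosages, freqs) @ effects
    liability = g + rng.standard_normal(cohort.n_individuals) * math.sqrt(max(0.0, 1.0 - h2))
    threshold = stats.norm.ppf(1.0 - config.prevalence)
    phenotype = (liability > threshold).astype(int)
    cohort.phenotype = phenotype
    return PhenotypeSimulation(effects=effects, liability=liability, phenotype=phenotype, threshold=threshold)


def simulate_case_control(
    config: SimulationConfig,
    snp_table: pd.DataFrame,
    effects: np.ndarray,
    rng: np.random.Generator,
    chunk: int = 5000,
    max_population_factor: float = 80.0,
) -> CohortData:
    """Ascertained case-control cohort by rejection sampling from the population.

    Individuals are simulated in chunks; cases are retained until the case
    quota (``n * P``) fills, controls until the control quota fills.
    """
    p_target = config.sample_case_fraction
    if p_target is None:
        raise ValueError("config.sample_case_fraction must be set for ascertained sampling")
    n = config.n_individuals
    n_cases = int(round(n * p_target))
    n_controls = n - n_cases
    freqs = snp_table["freq"].to_numpy()
    threshold = stats.norm.ppf(1.0 - config.prevalence)
    resid_sd = math.sqrt(max(0.0, 1.0 - config.h2_total))

    kept_dos: list[np.ndarray] = []
    kept_phen: list[np.ndarray] = []
    got_cases = got_controls = 0
    drawn = 0
    limit = max_population_factor * n / config.prevalence
    while got_cases < n_cases or got_controls < n_controls:
        if drawn > limit:
            raise RuntimeError("ascertainment could not fill quotas; prevalence too low?")
        dos = dosage_matrix(freqs, config, chunk, rng)
        drawn += chunk
        g = _standardize(dos, freqs) @ effects
        liab = g + rng.standard_normal(chunk) * resid_sd
        is_case = liab > threshold
        take_case = np.flatnonzero(is_case)[: n_cases - got_cases]
        take_ctrl = np.flatnonzero(~is_case)[: n_controls - got_controls]
        take = np.concatenate([take_case, take_ctrl])
        kept_dos.append(dos[take])
        kept_phen.append(is_case[take].astype(int))
        got_cases += len(take_case)
        got_controls += len(take_ctrl)

    dosages = np.concatenate(kept_dos)[:n]
    phenotype = np.concatenate(kept_phen)[:n]
    order = rng.permutation(n)
    covs = rng.standard_normal((n, config.n_covariates))
    return CohortData(
        dosages=dosages[order],
        snp_table=snp_table,
        phenotype=phenotype[order],
        covariates=covs,
    )


@dataclass
class StudyData:
    """A complete synthetic study: cohort, genome fixture, compartments, truth."""

    cohort: CohortData
    fixture: GenomeFixture
    assignment: CompartmentAssignment
    effects: np.ndarray
    config: SimulationConfig


def simulate_study(
    config: SimulationConfig,
    n_genes: int | None = None,
    window_kb: float = 10.0,
    rng: np.random.Generator | None = None,
) -> StudyData:
    """End-to-end synthetic study with known ground truth.

    Builds the SNP table and genome fixture, classifies compartments, draws
    and calibrates effects, and produces either a population cohort or (when
    ``config.sample_case_fraction`` is set) an ascertained case-control
    cohort.
    """
    from .annotation import classify_compartments

    if rng is None:
        rng = np.random.default_rng(config.seed)
    snp_table = draw_snp_table(config, rng)
    fixture = simulate_annotations(config, n_genes=n_genes, rng=rng, window_kb=window_kb)
    assignment = classify_compartments(snp_table, fixture.gene_models, window_kb=window_kb)
    effects = draw_effects(snp_table, assignment, config, rng)
    if config.h2_total > 0:
        labels = assignment.labels.reindex(snp_table["snp"]).to_numpy()
        effects = _calibrate_scales(effects, labels, snp_table, config, rng)

    if config.sample_case_fraction is not None:
        cohort = simulate_case_control(config, snp_table, effects, rng)
    else:
        dosages = dosage_matrix(snp_table["freq"].to_numpy(), config, config.n_individuals, rng)
        covs = rng.standard_normal((config.n_individuals, config.n_covariates))
        cohort = CohortData(dosages=dosages, snp_table=snp_table, covariates=covs)
        threshold = stats.norm.ppf(1.0 - config.prevalence)
        g = _standardize(dosages, snp_table["freq"].to_numpy()) @ effects
        resid = rng.standard_normal(config.n_individuals) * math.sqrt(max(0.0, 1.0 - config.h2_total))
        cohort.phenotype = ((g + resid) > threshold).astype(int)
    return StudyData(cohort=cohort, fixture=fixture, assignment=assignment, effects=effects, config=config)
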