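"""Annotation-restricted polygenic risk scores across discovery P thresholds.

The score for individual i is ``sum_j beta_j * d_ij`` over SNPs passing the
discovery p-value cutoff, with each beta oriented to the risk allele
(beta > 0) and the dosage flipped accordingly.  Association of the score
with disease in the validation cohort uses a logistic Wald test; variance
explained is Nagelkerke's R2 against a covariates-only null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .datatypes import COMPARTMENTS, CohortData, CompartmentAssignment

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = (
    5e-8, 5e-7, 5e-6, 5e-5, 5e-4, 0.005, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 1.0,
)


@dataclass
class PRSConfig:
    """Threshold grid, SNP-set restriction and optional exclusion regions."""

    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    snp_set: set[str] | None = None
    exclusion_regions: list[tuple[str, int, int]] | None = None  # (chrom, lo, hi) 1-based inclusive

    def __post_init__(self) -> None:
        t = np.asarray(self.thresholds, dtype=float)
        if not ((t > 0).all() and (t <= 1).all() and (np.diff(t) > 0).all()):
            raise ValueError("thresholds must lie in (0, 1] and be strictly increasing")


def exclusion_around_leads(
    leads: list[str], snp_table: pd.DataFrame, flank_mb: float = 1.0
) -> list[tuple[str, int, int]]:
    """±flank_mb regions around lead SNPs (1-based inclusive bounds)."""
    flank = int(flank_mb * 1_000_000)
    rows = snp_table.set_index("snp").loc[leads]
    return [
        (str(r["chrom"]), max(1, int(r["pos"]) - flank), int(r["pos"]) + flank)
        for _, r in rows.iterrows()
    ]


def _region_mask(snp_table: pd.DataFrame, regions) -> np.ndarray:
    """True for SNPs inside any exclusion region."""
    mask = np.zeros(len(snp_table), dtype=bool)
    chrom = snp_table["chrom"].to_numpy()
    pos = snp_table["pos"].to_numpy()
    for c, lo, hi in regions:
        mask |= (chrom == c) & (pos >= lo) & (pos <= hi)
    return mask


def _eligible(
    discovery: pd.DataFrame,
    validation: CohortData,
    config: PRSConfig,
) -> pd.DataFrame:
    """Discovery rows usable for scoring: present in validation, alleles
    reconciled (sign-flipping beta for swapped alleles), restrictions applied.
    """
    val = validation.snp_table[["snp", "a1", "a2"]].rename(
        columns={"a1": "v_a1", "a2": "v_a2"}
    )
    merged = discovery.merge(val, on="snp", how="inner")
    if merged.empty:
        raise ValueError("no SNPs shared between discovery and validation")
    same = (merged["a1"] == merged["v_a1"]) & (merged["a2"] == merged["v_a2"])
    flipped = (merged["a1"] == merged["v_a2"]) & (merged["a2"] == merged["v_a1"])
    mismatched = ~(same | flipped)
    if mismatched.any():
        logger.warning("%d SNPs dropped for irreconcilable alleles", int(mismatched.sum()))
    merged = merged[~mismatched].copy()
    merged.loc[flipped[~mismatched], "beta"] *= -1.0
    if config.snp_set is not None:
        merged = merged[merged["snp"].isin(config.snp_set)]
    if config.exclusion_regions:
        keep = ~_region_mask(merged, config.exclusion_regions)
        merged = merged[keep]
    merged = merged[np.isfinite(merged["beta"]) & np.isfinite(merged["p"])]
    return merged


def build_prs(
    discovery: pd.DataFrame,
    validation: CohortData,
    config: PRSConfig,
    threshold: float,
) -> tuple[np.ndarray, int]:
    """Per-individual risk score at one discovery threshold.

    Betas are oriented so the scored allele is the risk allele (beta > 0);
    dosages are flipped to 2 - d for originally protective alleles.  SNPs
    with beta exactly zero carry no risk allele and are excluded.  Raises if
    no SNP qualifies.
    """
    elig = _eligible(discovery, validation, config)
    use = elig[(elig["p"] < threshold) & (elig["beta"] != 0.0)]
    if use.empty:
        raise ValueError(f"no scoring SNPs at threshold {threshold}")
    idx = validation.snp_indices(use["snp"])
    dos = validation.dosages[:, idx]
    beta = use["beta"].to_numpy()
    flip = beta < 0
    dos = np.where(flip[None, :], 2.0 - dos, dos)
    score = dos @ np.abs(beta)
    return score, len(use)


def evaluate_prs(
    score: np.ndarray,
    phenotype: np.ndarray,
    covariates: np.ndarray | None = None,
) -> tuple[float, float]:
    """Wald p and Nagelkerke R2 of the score in a logistic model.

    The null model contains intercept and covariates only, so the R2
    isolates the score's contribution:
    R2 = [1 - exp((2/n)(l0 - l1))] / [1 - exp((2/n) l0)].
    Perfect separation is flagged by returning (nan, nan).
    """
    score = np.asarray(score, dtype=float)
    if not np.isfinite(score).all():
        raise ValueError("score contains non-finite values")
    y = np.asarray(phenotype, dtype=float)
    n = len(y)
    base = [np.ones(n)]
    if covariates is not None:
        base.append(np.atleast_2d(np.asarray(covariates, dtype=float)).reshape(n, -1))
    X0 = np.column_stack(base)
    X1 = np.column_stack(base + [score])
    try:
        null = sm.Logit(y, X0).fit(disp=0)
        full = sm.Logit(y, X1).fit(disp=0)
        if not (np.isfinite(full.bse).all() and np.abs(full.params).max() < 1e3):
            return float("nan"), float("nan")
    except Exception:
        return float("nan"), float("nan")
    wald_p = float(full.pvalues[-1])
    l0, l1 = null.llf, full.llf
    r2 = (1.0 - np.exp((2.0 / n) * (l0 - l1))) / (1.0 - np.exp((2.0 / n) * l0))
    return wald_p, float(r2)


def threshold_sweep(
    discovery: pd.DataFrame,
    validation: CohortData,
    config: PRSConfig | None = None,
    covariates: np.ndarray | None = None,
) -> pd.DataFrame:
    """PRS evaluation over the whole threshold grid.

    Returns one row per threshold: number of scoring SNPs, validation Wald p,
    Nagelkerke R2 and the per-SNP-normalized R2.  Thresholds with no scoring
    SNP produce an all-missing row.
    """
    config = config or PRSConfig()
    if covariates is None:
        covariates = validation.covariates
    rows = []
    for t in config.thresholds:
        try:
            score, n_snps = build_prs(discovery, validation, config, t)
            wald_p, r2 = evaluate_prs(score, validation.phenotype, covariates)
        except ValueError:
            rows.append({"threshold": t, "n_snps": 0, "wald_p": np.nan,
                         "nagelkerke_r2": np.nan, "r2_per_snp": np.nan})
            continue
        rows.append(
            {
                "threshold": t,
                "n_snps": n_snps,
                "wald_p": wald_p,
                "nagelkerke_r2": r2,
                "r2_per_snp": r2 / n_snps if n_snps else np.nan,
            }
        )
    return pd.DataFrame(rows)


def compartment_sweeps(
    discovery: pd.DataFrame,
    validation: CohortData,
    assignment: CompartmentAssignment,
    config: PRSConfig | None = None,
    covariates: np.ndarray | None = None,
) -> dict[str, pd.DataFrame]:
    """One threshold sweep per genomic compartment.

    When the config carries exclusion regions, an additional
    ``<compartment>:excluded`` sweep is emitted with those regions removed.
    """
    config = config or PRSConfig()
    out: dict[str, pd.DataFrame] = {}
    for comp in COMPARTMENTS:
        snps = set(assignment.snps_in(comp))
        base = PRSConfig(thresholds=config.thresholds, snp_set=snps)
        out[comp] = threshold_sweep(discovery, validation, base, covariates)
        if config.exclusion_regions:
            excl = PRSConfig(
                thresholds=config.thresholds,
                snp_set=snps,
                exclusion_regions=config.exclusion_regions,
            )
            out[f"{comp}:excluded"] = threshold_sweep(discovery, validation, excl, covariates)
    return out
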