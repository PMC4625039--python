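"""QC filtering and per-SNP case-control association scans.

The scan is an additive-dosage logistic regression per SNP (Wald test),
solved by Newton-Raphson.  A lean dedicated solver is used because desk-scale
experiments scan thousands of SNPs across many seeds; it is cross-checked
against statsmodels in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import CohortData


@dataclass
class QCThresholds:
    """Exclusion thresholds applied before association analysis."""

    hwe_p_min: float = 1e-6
    maf_min_genotyped: float = 0.01
    maf_min_imputed: float = 0.005
    snp_call_rate_min: float = 0.98
    sample_call_rate_min: float = 0.95
    info_min: float = 0.5

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if not (0 < v < 1):
                raise ValueError(f"{name} must lie in (0, 1), got {v}")


def hwe_pvalues(dosages: np.ndarray) -> np.ndarray:
    """Hardy-Weinberg chi-square (1 df) p-values from rounded genotype calls."""
    geno = np.rint(dosages)
    out = np.ones(dosages.shape[1])
    for j in range(dosages.shape[1]):
        g = geno[:, j]
        g = g[~np.isnan(g)]
        n = len(g)
        if n == 0:
            continue
        counts = np.array([(g == k).sum() for k in (0, 1, 2)], dtype=float)
        p = (counts[1] + 2 * counts[2]) / (2 * n)
        if p in (0.0, 1.0):
            continue
        exp = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
        chi2 = float((np.square(counts - exp) / exp).sum())
        out[j] = stats.chi2.sf(chi2, df=1)
    return out


@dataclass
class QCReport:
    """Exclusion counts per criterion plus the surviving dimensions."""

    n_samples_removed: int
    n_snps_removed: dict[str, int]
    removed_snps: dict[str, list[str]] = field(default_factory=dict)


def qc_filter(
    cohort: CohortData, thresholds: QCThresholds | None = None
) -> tuple[CohortData, QCReport]:
    """Remove individuals/SNPs failing call-rate, MAF, HWE and info thresholds.

    Sample call rate is applied first; SNP criteria are then evaluated on the
    surviving individuals.  The MAF floor is ``maf_min_imputed`` for SNPs
    flagged imputed (boolean ``imputed`` column in the SNP table) and
    ``maf_min_genotyped`` otherwise.  Raises if every SNP is removed.
    """
    thr = thresholds or QCThresholds()
    dos = cohort.dosages
    sample_cr = 1.0 - np.isnan(dos).mean(axis=1)
    keep_ind = sample_cr >= thr.sample_call_rate_min
    cohort = cohort.subset_individuals(keep_ind)
    dos = cohort.dosages

    snp = cohort.snp_table
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        freq = np.nanmean(dos, axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    call_rate = 1.0 - np.isnan(dos).mean(axis=0)
    hwe_p = hwe_pvalues(dos)
    info = snp["info"].to_numpy() if "info" in snp.columns else np.ones(len(snp))
    imputed = (
        snp["imputed"].to_numpy().astype(bool)
        if "imputed" in snp.columns
        else np.zeros(len(snp), dtype=bool)
    )
    maf_floor = np.where(imputed, thr.maf_min_imputed, thr.maf_min_genotyped)

    fails = {
        "maf": maf < maf_floor,
        "hwe": hwe_p < thr.hwe_p_min,
        "call_rate": call_rate < thr.snp_call_rate_min,
        "info": info < thr.info_min,
    }
    any_fail = np.zeros(len(snp), dtype=bool)
    counts, removed = {}, {}
    for name, mask in fails.items():
        counts[name] = int(mask.sum())
        removed[name] = list(snp["snp"].to_numpy()[mask])
        any_fail |= mask
    if any_fail.all():
        raise ValueError("QC removed every SNP")
    filtered = cohort.subset_snps(~any_fail)
    report = QCReport(
        n_samples_removed=int((~keep_ind).sum()),
        n_snps_removed=counts,
        removed_snps=removed,
    )
    return filtered, report


# ---------------------------------------------------------------------------
# association scan


def _newton_logistic(X: np.ndarray, y: np.ndarray, max_iter: int = 30, tol: float = 1e-10):
    """Newton-Raphson logistic fit; returns (beta, se, loglik, converged)."""
    n, k = X.shape
    beta = np.zeros(k)
    beta[0] = np.log(y.mean() / (1 - y.mean())) if 0 < y.mean() < 1 else 0.0
    ll_old = -np.inf
    cov = None
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        if not np.isfinite(mu).all() or w.max() < 1e-12:
            return beta, None, ll_old, False
        grad = X.T @ (y - mu)
        hess = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            return beta, None, ll_old, False
        beta = beta + step
        ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
        if abs(ll - ll_old) < tol:
            try:
                cov = np.linalg.inv(hess)
            except np.linalg.LinAlgError:
                return beta, None, ll, False
            # flag quasi-separation: exploding coefficients
            if np.abs(beta).max() > 30:
                return beta, None, ll, False
            return beta, np.sqrt(np.diag(cov)), ll, True
        ll_old = ll
    return beta, None, ll_old, False


def scan(
    cohort: CohortData,
    covariates: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-SNP additive logistic regression of phenotype on dosage.

    Returns summary statistics with one row per SNP: effect size ``beta``
    (log-odds per copy of allele ``a1``), its Wald SE and p, allele frequency
    and a ``converged`` flag.  Monomorphic or separated SNPs get missing
    beta/se/p and ``converged=False``.
    """
    if cohort.phenotype is None:
        raise ValueError("cohort has no phenotype")
    y = np.asarray(cohort.phenotype, dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("phenotype must be binary 0/1")
    if covariates is None:
        covariates = cohort.covariates
    n = cohort.n_individuals
    base = [np.ones(n)]
    if covariates is not None:
        base.append(np.atleast_2d(np.asarray(covariates, dtype=float)).reshape(n, -1))
    C = np.column_stack(base)

    m = cohort.n_snps
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    pval = np.full(m, np.nan)
    conv = np.zeros(m, dtype=bool)
    X = np.column_stack([C, np.zeros(n)])
    for j in range(m):
        x = cohort.dosages[:, j]
        if np.nanstd(x) == 0 or np.isnan(x).any():
            continue
        X[:, -1] = x
        b, s, _, ok = _newton_logistic(X, y)
        if ok:
            beta[j], se[j] = b[-1], s[-1]
            z = b[-1] / s[-1]
            pval[j] = 2.0 * stats.norm.sf(abs(z))
            conv[j] = True

    snp = cohort.snp_table
    freq = cohort.dosages.mean(axis=0) / 2.0
    return pd.DataFrame(
        {
            "snp": snp["snp"].to_numpy(),
            "chrom": snp["chrom"].to_numpy(),
            "pos": snp["pos"].to_numpy(),
            "a1": snp["a1"].to_numpy(),
            "a2": snp["a2"].to_numpy(),
            "af": freq,
            "beta": beta,
            "se": se,
            "p": pval,
            "info": snp["info"].to_numpy() if "info" in snp.columns else 1.0,
            "converged": conv,
        }
    )


def compare_signal(
    p_set: np.ndarray, p_baseline: np.ndarray
) -> tuple[float, float, str]:
    """Two-sided Mann-Whitney rank-sum comparison of association strength.

    Operates on -log10(p) so larger values mean stronger signal.  Returns
    (U statistic, two-sided p, direction) where direction reports which
    sample has the larger median signal.
    """
    a = -np.log10(np.asarray(p_set, dtype=float))
    b = -np.log10(np.asarray(p_baseline, dtype=float))
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    if np.unique(np.concatenate([a, b])).size == 1:
        warnings.warn("degenerate all-tied input; p set to 1")
        return float(len(a) * len(b) / 2.0), 1.0, "tied"
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    direction = "set_stronger" if np.median(a) > np.median(b) else "baseline_stronger"
    return float(res.statistic), float(res.pvalue), direction
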