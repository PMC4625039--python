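"""Multi-component GREML variance partitioning for a binary trait.

The model is y = Xb + sum_c g_c + e with g_c ~ N(0, A_c * sigma2_c), where
each A_c is a genomic relationship matrix built from the SNPs of one
annotation component.  Variance components are estimated by restricted
maximum likelihood with average-information (AI) updates and
expectation-maximization fallback steps, non-negativity constraints, and a
likelihood-ratio test per component using the 0.5*chi2_0 + 0.5*chi2_1
boundary mixture.  Observed-scale estimates for an (ascertained)
case-control sample are converted to the liability scale with the
prevalence/ascertainment-corrected multiplier
K^2 (1-K)^2 / (z^2 P (1-P)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg, stats

from .datatypes import CohortData


@dataclass
class GRM:
    """Genomic relationship matrix over one SNP component."""

    matrix: np.ndarray
    n_snps: int
    ids: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("GRM must be square")
        if not np.isfinite(self.matrix).all():
            raise ValueError("GRM contains non-finite entries")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def compute_grm(cohort: CohortData, snp_subset=None) -> GRM:
    """GCTA-style GRM: A_jk = (1/M) sum_i (x_ij - 2p_i)(x_ik - 2p_i) / (2 p_i (1-p_i)).

    ``p_i`` is the sample allele frequency.  Monomorphic SNPs in the subset
    are dropped with a warning (they would divide by zero).
    """
    sub = cohort if snp_subset is None else cohort.subset_snps(np.asarray(snp_subset))
    if sub.n_snps == 0:
        raise ValueError("empty SNP subset")
    x = sub.dosages
    p = x.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.all():
        warnings.warn(f"{int((~poly).sum())} monomorphic SNPs dropped from GRM")
        x, p = x[:, poly], p[poly]
    if x.shape[1] == 0:
        raise ValueError("no polymorphic SNPs left for GRM")
    z = (x - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    a = (z @ z.T) / x.shape[1]
    return GRM(matrix=a, n_snps=x.shape[1], ids=sub.sample_ids.copy())


def prune_related(grm: GRM, cutoff: float = 0.05) -> np.ndarray:
    """Greedy relatedness pruning: drop one member of each pair above cutoff.

    Individuals participating in the most over-cutoff pairs are removed first
    until no pair remains; returns the kept individual ids.
    """
    a = grm.matrix.copy()
    np.fill_diagonal(a, -np.inf)
    active = np.ones(grm.n, dtype=bool)
    while True:
        over = (a > cutoff) & active[:, None] & active[None, :]
        counts = over.sum(axis=1)
        if counts.max() == 0:
            break
        active[int(np.argmax(counts))] = False
    return grm.ids[active]


@dataclass
class VarianceComponentsFit:
    """REML fit: per-component variances, ratios and SEs, plus diagnostics."""

    variances: np.ndarray          # per-component sigma2 (genetic components)
    residual_variance: float
    se_variances: np.ndarray
    ratios: np.ndarray             # V_c / Vp
    se_ratios: np.ndarray
    loglik: float
    n_iterations: int
    converged: bool
    covariance: np.ndarray         # covariance of [sigma2_1..C, sigma2_e]
    ai_singular: bool = False

    @property
    def phenotypic_variance(self) -> float:
        return float(self.variances.sum() + self.residual_variance)

    @property
    def total_ratio(self) -> float:
        return float(self.ratios.sum())

    @property
    def se_total_ratio(self) -> float:
        # delta method on h2 = sum(sigma_c) / Vp
        th = np.append(self.variances, self.residual_variance)
        vp = th.sum()
        h2 = self.variances.sum() / vp
        grad = np.append(np.full(len(self.variances), (1.0 - h2) / vp), -h2 / vp)
        return float(np.sqrt(grad @ self.covariance @ grad))


def _haseman_elston_init(y, X, A, vp0, floor):
    """Haseman-Elston starting values: regress off-diagonal phenotype
    cross-products on the GRM entries (method-of-moments); cheap and close
    enough to cut several REML iterations."""
    n = len(y)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    e = y - X @ beta
    iu = np.triu_indices(n, k=1)
    cp = np.outer(e, e)[iu]
    design = np.column_stack([a[iu] for a in A] + [np.ones(len(cp))])
    gram = design.T @ design
    rhs = design.T @ cp
    try:
        coef = np.linalg.solve(gram, rhs)
    except np.linalg.LinAlgError:
        return np.full(len(A) + 1, vp0 / (len(A) + 1))
    theta = np.empty(len(A) + 1)
    theta[:-1] = coef[:-1]
    theta[-1] = vp0 - theta[:-1].sum()
    theta = np.clip(theta, 10 * floor, vp0)
    if not np.isfinite(theta).all():
        return np.full(len(A) + 1, vp0 / (len(A) + 1))
    return theta


def _project(vinv_b, vx, xtvx_cf, xt_vinv_b):
    """Apply P = Vinv - Vinv X (X'VinvX)^-1 X'Vinv to a vector, given pieces."""
    return vinv_b - vx @ linalg.cho_solve(xtvx_cf, xt_vinv_b)


def reml_fit(
    phenotype: np.ndarray,
    covariates: np.ndarray | None,
    grms: list[GRM],
    tol: float = 1e-6,
    max_iter: int = 100,
    constrain: bool = True,
) -> VarianceComponentsFit:
    """AI-REML over one or more GRMs with EM fallback and non-negativity.

    Convergence when the restricted log-likelihood changes by less than
    ``tol`` between iterations (deterministic given the data).  A singular AI
    matrix triggers EM-only updates and is flagged on the fit.
    """
    if not grms:
        raise ValueError("at least one GRM required")
    n = grms[0].n
    for g in grms:
        if g.n != n:
            raise ValueError("all GRMs must cover the same individuals")
    y = np.asarray(phenotype, dtype=float)
    if len(y) != n:
        raise ValueError("phenotype length does not match GRMs")
    X = [np.ones(n)]
    if covariates is not None:
        X.append(np.atleast_2d(np.asarray(covariates, dtype=float)).reshape(n, -1))
    X = np.column_stack(X)

    A = [g.matrix for g in grms]
    C = len(A)
    vp0 = y.var(ddof=1)
    floor = 1e-6 * vp0
    theta = _haseman_elston_init(y, X, A, vp0, floor)

    I_n = np.eye(n)
    ll_old = -np.inf
    ai_singular = False
    converged = False
    theta_prev = theta.copy()
    it = 0
    for it in range(1, max_iter + 1):
        V = theta[-1] * I_n
        for c in range(C):
            V += theta[c] * A[c]
        try:
            cf = linalg.cho_factor(V, lower=True, check_finite=False)
        except linalg.LinAlgError:
            theta = theta_prev.copy()
            break
        vinv = linalg.cho_solve(cf, I_n, check_finite=False)
        logdet_v = 2.0 * np.log(np.diag(cf[0])).sum()
        vx = vinv @ X
        xtvx = X.T @ vx
        xtvx_cf = linalg.cho_factor(xtvx)
        logdet_x = 2.0 * np.log(np.diag(xtvx_cf[0])).sum()
        vy = vinv @ y
        py = _project(vy, vx, xtvx_cf, X.T @ vy)
        ypy = float(y @ py)
        ll = -0.5 * (logdet_v + logdet_x + ypy)

        if abs(ll - ll_old) < tol and it > 1:
            ll_old = ll
            converged = True
            break
        ll_old = ll
        theta_prev = theta.copy()

        # first derivatives need tr(P A_c); correct tr(Vinv A_c) for the
        # fixed-effect projection
        tr_pa = np.empty(C + 1)
        u = np.empty((C + 1, n))  # u_c = A_c @ Py
        for c in range(C + 1):
            a_c = A[c] if c < C else None
            if a_c is None:
                tr_vinv_a = float(np.trace(vinv))
                avx = vx
                u[c] = py
            else:
                tr_vinv_a = float((vinv * a_c).sum())
                avx = a_c @ vx
                u[c] = a_c @ py
            corr = float(np.trace(linalg.cho_solve(xtvx_cf, vx.T @ avx)))
            tr_pa[c] = tr_vinv_a - corr

        score = np.empty(C + 1)
        pu = np.empty((C + 1, n))
        for c in range(C + 1):
            vinv_u = linalg.cho_solve(cf, u[c], check_finite=False)
            pu[c] = _project(vinv_u, vx, xtvx_cf, X.T @ vinv_u)
            score[c] = -0.5 * (tr_pa[c] - float(py @ u[c]))
        ai = 0.5 * (u @ pu.T)
        ai = 0.5 * (ai + ai.T)

        use_em = it == 1 or ai_singular
        if not use_em:
            try:
                if np.linalg.cond(ai) > 1e12:
                    raise np.linalg.LinAlgError
                delta = np.linalg.solve(ai, score)
                if not np.isfinite(delta).all():
                    raise np.linalg.LinAlgError
            except np.linalg.LinAlgError:
                ai_singular = True
                use_em = True
        if use_em:
            if ai_singular and it > 1:
                warnings.warn("singular AI matrix; falling back to EM updates")
            delta = np.array(
                [theta[c] ** 2 * (float(py @ u[c]) - tr_pa[c]) / n for c in range(C + 1)]
            )
        theta = theta + delta
        if constrain:
            theta = np.maximum(theta, floor)
        else:
            theta[-1] = max(theta[-1], floor)

    # covariance of estimates from the final AI matrix
    V = theta[-1] * I_n
    for c in range(C):
        V += theta[c] * A[c]
    cf = linalg.cho_factor(V, lower=True, check_finite=False)
    vinv = linalg.cho_solve(cf, I_n, check_finite=False)
    vx = vinv @ X
    xtvx_cf = linalg.cho_factor(X.T @ vx)
    vy = vinv @ y
    py = _project(vy, vx, xtvx_cf, X.T @ vy)
    u = np.empty((C + 1, n))
    for c in range(C + 1):
        u[c] = A[c] @ py if c < C else py
    pu = np.empty((C + 1, n))
    for c in range(C + 1):
        vinv_u = linalg.cho_solve(cf, u[c], check_finite=False)
        pu[c] = _project(vinv_u, vx, xtvx_cf, X.T @ vinv_u)
    ai = 0.5 * (u @ pu.T)
    ai = 0.5 * (ai + ai.T)
    try:
        cov = np.linalg.inv(ai)
    except np.linalg.LinAlgError:
        ai_singular = True
        cov = np.linalg.pinv(ai)
    logdet_v = 2.0 * np.log(np.diag(cf[0])).sum()
    logdet_x = 2.0 * np.log(np.diag(xtvx_cf[0])).sum()
    ll = -0.5 * (logdet_v + logdet_x + float(y @ py))

    vp = theta.sum()
    ratios = theta[:C] / vp
    se_var = np.sqrt(np.maximum(np.diag(cov), 0.0))
    # delta method for ratios r_c = theta_c / sum(theta)
    se_ratios = np.empty(C)
    for c in range(C):
        grad = np.full(C + 1, -theta[c] / vp**2)
        grad[c] += 1.0 / vp
        se_ratios[c] = np.sqrt(max(0.0, grad @ cov @ grad))

    return VarianceComponentsFit(
        variances=theta[:C].copy(),
        residual_variance=float(theta[-1]),
        se_variances=se_var[:C].copy(),
        ratios=ratios,
        se_ratios=se_ratios,
        loglik=float(ll),
        n_iterations=it,
        converged=converged,
        covariance=cov,
        ai_singular=ai_singular,
    )


def residual_only_fit(
    phenotype: np.ndarray, covariates: np.ndarray | None = None
) -> VarianceComponentsFit:
    """Closed-form REML fit of the no-genetic-component model y = Xb + e.

    Serves as the reduced model when testing a single variance component:
    sigma2_e = RSS/(n - p) and the restricted log-likelihood follows in
    closed form.
    """
    y = np.asarray(phenotype, dtype=float)
    n = len(y)
    X = [np.ones(n)]
    if covariates is not None:
        X.append(np.atleast_2d(np.asarray(covariates, dtype=float)).reshape(n, -1))
    X = np.column_stack(X)
    p = X.shape[1]
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.square(y - X @ beta).sum())
    sigma2 = rss / (n - p)
    _, logdet_xx = np.linalg.slogdet(X.T @ X)
    ll = -0.5 * ((n - p) * np.log(sigma2) + logdet_xx + (n - p))
    return VarianceComponentsFit(
        variances=np.empty(0),
        residual_variance=sigma2,
        se_variances=np.empty(0),
        ratios=np.empty(0),
        se_ratios=np.empty(0),
        loglik=float(ll),
        n_iterations=0,
        converged=True,
        covariance=np.array([[2.0 * sigma2**2 / (n - p)]]),
    )


def lrt_component(full: VarianceComponentsFit, reduced: VarianceComponentsFit,
                  tol: float = 1e-3) -> float:
    """Boundary-mixture LRT p for dropping one variance component.

    p = 0.5 * Pr(chi2_1 > 2*(l_full - l_reduced)); the other half of the
    mixture mass sits at zero because the component is constrained
    non-negative.  Raises if the full likelihood falls below the reduced
    one beyond tolerance (optimizer failure).
    """
    if len(reduced.variances) != len(full.variances) - 1:
        raise ValueError("reduced model must drop exactly one component")
    lrt = 2.0 * (full.loglik - reduced.loglik)
    if lrt < -tol:
        raise RuntimeError(
            f"full log-likelihood below reduced ({full.loglik:.6f} < {reduced.loglik:.6f})"
        )
    lrt = max(0.0, lrt)
    return float(0.5 * stats.chi2.sf(lrt, df=1))


@dataclass
class LiabilityScaleParams:
    """Population prevalence K and sample case proportion P."""

    prevalence: float
    case_proportion: float

    def __post_init__(self) -> None:
        if not (0 < self.prevalence < 1) or not (0 < self.case_proportion < 1):
            raise ValueError("K and P must lie strictly in (0, 1)")

    @property
    def threshold(self) -> float:
        return float(stats.norm.ppf(1.0 - self.prevalence))

    @property
    def density_at_threshold(self) -> float:
        return float(stats.norm.pdf(self.threshold))

    @property
    def multiplier(self) -> float:
        k, p, z = self.prevalence, self.case_proportion, self.density_at_threshold
        return k**2 * (1.0 - k) ** 2 / (z**2 * p * (1.0 - p))


def to_liability(h2_observed: float, params: LiabilityScaleParams) -> float:
    """Observed-scale (0/1, possibly ascertained) h2 -> liability scale.

    h2_l = h2_o * K^2 (1-K)^2 / (z^2 P (1-P)); linear in h2_o, so SEs
    transform by the same multiplier.
    """
    if h2_observed < 0:
        raise ValueError("h2_observed must be non-negative")
    return float(h2_observed * params.multiplier)


def enrichment_of_variance(
    v_component: float, v_total: float, m_component: int, m_total: int
) -> float:
    """Fold enrichment: (% variance of total) / (% SNPs of total)."""
    if v_total <= 0 or m_total <= 0:
        raise ValueError("totals must be positive")
    if m_component == 0:
        raise ValueError("fold enrichment undefined for an empty component")
    return (v_component / v_total) / (m_component / m_total)


def deviation_test(
    v_observed: float, se_observed: float, v_total: float, snp_fraction: float
) -> tuple[float, float]:
    """z-test of observed component variance against its size-proportional
    expectation ``v_total * snp_fraction``; returns (expected, two-sided p)."""
    if se_observed <= 0:
        raise ValueError("se_observed must be positive")
    v_expected = v_total * snp_fraction
    z = (v_observed - v_expected) / se_observed
    return float(v_expected), float(2.0 * stats.norm.sf(abs(z)))


def ivw_meta(estimates, ses) -> tuple[float, float]:
    """Fixed-effect inverse-variance-weighted meta-analysis."""
    est = np.asarray(estimates, dtype=float)
    se = np.asarray(ses, dtype=float)
    if (se <= 0).any():
        raise ValueError("all SEs must be positive")
    if len(est) == 1:
        return float(est[0]), float(se[0])
    w = 1.0 / se**2
    return float((w * est).sum() / w.sum()), float(1.0 / np.sqrt(w.sum()))
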