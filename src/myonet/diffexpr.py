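"""Module-level differential expression: subject-blocked generalised least
squares on eigengenes with empirical-Bayes moderated contrasts.

Each eigengene is fitted with a group-means parameterisation of the
age-group x condition design. Correlation between repeated samples from the
same subject is handled by a single consensus within-subject correlation
(estimated across modules, Fisher-transform trimmed mean) entering the GLS
covariance sigma^2 [(1-rho) I + rho B], B the same-subject block indicator.
Moderated t-statistics shrink per-module residual variances towards a pooled
prior estimated by matching moments of log s^2 (digamma/trigamma relations);
all module x contrast p-values form one global Benjamini-Hochberg family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cholesky, solve_triangular
from scipy.special import digamma, polygamma
from scipy.stats import t as t_dist, trim_mean
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "BlockCorrelation",
    "ModuleFits",
    "estimate_within_subject_correlation",
    "fit_module_models",
    "default_contrasts",
    "moderated_contrasts",
    "differential_analysis",
]

AGE_GROUPS = ("young", "older")
CONDITIONS = ("BL", "ECC", "CON")


def _check_design(design: pd.DataFrame) -> pd.DataFrame:
    for col in ("subject", "age_group", "condition"):
        if col not in design.columns:
            raise ValueError(f"design is missing column '{col}'")
    per_subj = design.groupby("subject")["age_group"].nunique()
    if (per_subj > 1).any():
        bad = per_subj.index[per_subj > 1].tolist()
        raise ValueError(f"subjects in more than one age group: {bad}")
    return design


def group_factor(design: pd.DataFrame) -> pd.Series:
    """Combined age x condition group, e.g. 'young:BL' (6 levels)."""
    return design["age_group"].astype(str) + ":" + design["condition"].astype(str)


def _group_design_matrix(design: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    groups = group_factor(design)
    levels = [f"{a}:{c}" for a in AGE_GROUPS for c in CONDITIONS if f"{a}:{c}" in set(groups)]
    extra = [g for g in pd.unique(groups) if g not in levels]
    levels += sorted(extra)
    X = np.column_stack([(groups == lv).to_numpy(float) for lv in levels])
    return X, levels


@dataclass
class BlockCorrelation:
    """Consensus within-subject residual correlation across modules."""

    consensus_rho: float
    per_module_rho: pd.Series


def estimate_within_subject_correlation(
    eigengenes: pd.DataFrame, design: pd.DataFrame, trim: float = 0.1
) -> BlockCorrelation:
    """Estimate the within-subject correlation shared by all modules.

    Per module, the group-means model is fitted by OLS and rho is the mean
    product of residual pairs from the same subject divided by the residual
    variance. The consensus is the inverse Fisher transform of the
    ``trim``-trimmed mean of the per-module Fisher z values, clamped to
    (-0.99, 0.99).
    """
    design = _check_design(design)
    X, _ = _group_design_matrix(design)
    n, p = X.shape
    subj = design["subject"].to_numpy()
    pairs = [
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if subj[i] == subj[j]
    ]
    if not pairs:
        logger.warning("no repeated subjects; consensus correlation set to 0")
        return BlockCorrelation(0.0, pd.Series(dtype=float))
    ii = np.array([a for a, _ in pairs])
    jj = np.array([b for _, b in pairs])
    H = X @ np.linalg.solve(X.T @ X, X.T)
    M = np.eye(n) - H
    # moment correction: residual products are attenuated by the projection,
    # E[e_i e_j] = sigma^2[(1-rho) M_ij + rho (MBM)_ij] and
    # E[s^2] = sigma^2[(1-rho) + rho tr(BM)/(n-p)]; invert the linear map so
    # the estimator recovers rho without bias from the lost degrees of freedom
    B = (subj[:, None] == subj[None, :]).astype(float)
    MBM = M @ B @ M
    a_coef = float(np.mean(M[ii, jj]))
    b_coef = float(np.mean(MBM[ii, jj]))
    d_coef = float(np.trace(B @ M)) / (n - p)
    rhos = {}
    for mod, y in eigengenes.iterrows():
        e = M @ y.to_numpy(dtype=float)
        s2 = float(e @ e) / (n - p)
        if s2 <= 0:
            continue
        ratio = float(np.mean(e[ii] * e[jj]) / s2)
        denom = ratio + b_coef - a_coef - ratio * d_coef
        rho = (ratio - a_coef) / denom if abs(denom) > 1e-12 else 0.0
        rhos[mod] = float(np.clip(rho, -0.99, 0.99))
    per_module = pd.Series(rhos, name="rho")
    if per_module.empty:
        return BlockCorrelation(0.0, per_module)
    z = np.arctanh(per_module.to_numpy())
    consensus = float(np.tanh(trim_mean(z, trim)))
    consensus = float(np.clip(consensus, -0.99, 0.99))
    return BlockCorrelation(consensus, per_module)


@dataclass
class ModuleFits:
    """Per-module GLS fits under the consensus block covariance."""

    coefficients: pd.DataFrame  # modules x group levels
    sigma2: pd.Series  # residual variance per module
    df_residual: float
    cov_unscaled: np.ndarray  # (X' Sigma^-1 X)^-1
    group_levels: list[str]
    rho: float


def fit_module_models(
    eigengenes: pd.DataFrame, design: pd.DataFrame, rho: float = 0.0
) -> ModuleFits:
    """Generalised least squares of each eigengene on the group-means design.

    The error covariance is sigma^2 [(1-rho) I + rho B] with B the
    same-subject block indicator; rho = 0 reduces exactly to OLS.
    """
    design = _check_design(design)
    X, levels = _group_design_matrix(design)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        # identify aliased columns by QR pivoting
        _, r = np.linalg.qr(X)
        aliased = [levels[j] for j in range(p) if abs(r[j, j]) < 1e-10]
        raise ValueError(f"design matrix is rank deficient; aliased groups: {aliased}")
    subj = design["subject"].to_numpy()
    B = (subj[:, None] == subj[None, :]).astype(float)
    sigma = (1.0 - rho) * np.eye(n) + rho * B
    L = cholesky(sigma, lower=True)
    Xw = solve_triangular(L, X, lower=True)
    xtx = Xw.T @ Xw
    cov_unscaled = np.linalg.inv(xtx)
    coefs, s2 = {}, {}
    for mod, y in eigengenes.iterrows():
        yw = solve_triangular(L, y.to_numpy(dtype=float), lower=True)
        beta = cov_unscaled @ (Xw.T @ yw)
        resid = yw - Xw @ beta
        coefs[mod] = beta
        s2[mod] = float(resid @ resid) / (n - p)
    coefficients = pd.DataFrame(coefs, index=levels).T
    return ModuleFits(coefficients, pd.Series(s2), float(n - p), cov_unscaled, levels, rho)


def default_contrasts(levels: list[str]) -> pd.DataFrame:
    """All condition pairs within each age group plus between-age comparisons
    at each condition (columns = contrast names, rows = group levels)."""
    cols = {}
    by_age = {a: [lv for lv in levels if lv.startswith(a + ":")] for a in AGE_GROUPS}
    for a in AGE_GROUPS:
        lvs = by_age[a]
        for i in range(len(lvs)):
            for j in range(i + 1, len(lvs)):
                name = f"{lvs[j]}-vs-{lvs[i]}"
                v = np.zeros(len(levels))
                v[levels.index(lvs[j])] = 1.0
                v[levels.index(lvs[i])] = -1.0
                cols[name] = v
    conds = sorted({lv.split(":", 1)[1] for lv in levels})
    for c in conds:
        a0, a1 = f"{AGE_GROUPS[1]}:{c}", f"{AGE_GROUPS[0]}:{c}"
        if a0 in levels and a1 in levels:
            v = np.zeros(len(levels))
            v[levels.index(a0)] = 1.0
            v[levels.index(a1)] = -1.0
            cols[f"{a0}-vs-{a1}"] = v
    return pd.DataFrame(cols, index=levels)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_variance_prior(sigma2: np.ndarray, df: float) -> tuple[float, float]:
    """Empirical-Bayes prior (d0, s0^2) for the residual variances.

    Moment-matches z = log(s^2): E[z] and Var[z] relate to digamma/trigamma
    of the degrees of freedom for scaled chi^2 variances. Returns
    d0 = np.inf (complete shrinkage) when the observed spread of log s^2 does
    not exceed what the residual degrees of freedom alone imply.
    """
    s2 = np.maximum(np.asarray(sigma2, dtype=float), 1e-300)
    if s2.size < 4:
        raise ValueError("need >= 4 modules to estimate the variance prior")
    z = np.log(s2)
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    ebar = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(polygamma(1, df / 2.0))
    if evar <= 0:
        logger.info("variance prior: no excess dispersion; d0 = inf (full shrinkage)")
        return np.inf, float(np.exp(ebar))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0_sq = float(np.exp(ebar + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def moderated_contrasts(
    fits: ModuleFits,
    contrasts: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Empirical-Bayes moderated t-tests of the given contrasts.

    Returns one row per module x contrast with the estimate, moderated t,
    total degrees of freedom (d0 + d), raw p and globally BH-adjusted p.
    """
    if contrasts is None:
        contrasts = default_contrasts(fits.group_levels)
    C = contrasts.reindex(fits.group_levels).to_numpy(dtype=float)
    if np.isnan(C).any():
        raise ValueError("contrast matrix rows must match the design group levels")
    d = fits.df_residual
    s2 = fits.sigma2.to_numpy()
    if len(s2) < 4:
        logger.warning("fewer than 4 modules: no variance moderation applied")
        d0, s0_sq = 0.0, float(np.mean(s2))
    else:
        d0, s0_sq = estimate_variance_prior(s2, d)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + d * s2) / (d0 + d)
        df_total = d0 + d
    se_factor = np.sqrt(np.einsum("ij,jk,ki->i", C.T, fits.cov_unscaled, C))
    est = fits.coefficients.to_numpy() @ C  # modules x contrasts
    tstat = est / (np.sqrt(s2_post)[:, None] * se_factor[None, :])
    pval = 2.0 * t_dist.sf(np.abs(tstat), df_total)
    rows = []
    for mi, mod in enumerate(fits.coefficients.index):
        for ci, cname in enumerate(contrasts.columns):
            rows.append((mod, cname, est[mi, ci], tstat[mi, ci], pval[mi, ci]))
    out = pd.DataFrame(rows, columns=["module", "contrast", "estimate", "moderated_t", "p"])
    out["df_total"] = df_total
    _, p_adj, _, _ = multipletests(out["p"].to_numpy(), method="fdr_bh")
    out["p_adj"] = p_adj
    out["significant"] = out["p_adj"] < alpha
    return out


def differential_analysis(
    eigengenes: pd.DataFrame,
    design: pd.DataFrame,
    contrasts: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, BlockCorrelation]:
    """Consensus correlation -> GLS fits -> moderated global-BH contrasts."""
    block = estimate_within_subject_correlation(eigengenes, design)
    fits = fit_module_models(eigengenes, design, rho=block.consensus_rho)
    results = moderated_contrasts(fits, contrasts, alpha=alpha)
    return results, block
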