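"""Signed weighted co-expression network construction.

Pearson correlation -> signed adjacency Adj = (0.5 * (1 + Corr))^beta ->
topological overlap matrix (TOM) -> dissimilarity 1 - TOM. The soft-threshold
power beta is selected as the smallest candidate whose connectivity
distribution satisfies the scale-free topology fit criterion
(signed R^2 >= 0.85 with a negative log-log slope).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ScaleFreeFit",
    "CoexpressionNetwork",
    "pairwise_correlation",
    "signed_adjacency",
    "connectivity",
    "scale_free_fit",
    "fit_power_law",
    "select_beta",
    "topological_overlap",
    "dissimilarity",
    "build_network",
]

_SYM_TOL = 1e-10


@dataclass
class ScaleFreeFit:
    """Scale-free topology scan across candidate soft-threshold powers.

    ``r2_signed`` is -sign(slope) * R^2 of the regression of log10(bin
    frequency) on log10(mean bin connectivity); a high positive value with a
    negative slope indicates an approximately scale-free (power-law)
    connectivity distribution.
    """

    beta_candidates: list[int]
    r2_signed: np.ndarray
    slope: np.ndarray
    chosen_beta: int
    threshold: float
    met_threshold: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"beta": self.beta_candidates, "r2_signed": self.r2_signed, "slope": self.slope}
        )


@dataclass
class CoexpressionNetwork:
    gene_ids: list[str]
    corr: np.ndarray
    beta: int
    adjacency: np.ndarray
    tom: np.ndarray
    fit: ScaleFreeFit | None = None

    @property
    def disstom(self) -> np.ndarray:
        return dissimilarity(self.tom)


def pairwise_correlation(expr: pd.DataFrame) -> np.ndarray:
    """Gene x gene Pearson correlation across samples (rows = genes)."""
    if expr.shape[1] < 3:
        raise ValueError("pairwise correlation requires at least 3 samples")
    vals = expr.to_numpy(dtype=float)
    sd = vals.std(axis=1)
    if (sd == 0).any():
        bad = expr.index[sd == 0].tolist()
        raise ValueError(f"zero-variance genes (pre-filter them): {bad[:10]}")
    corr = np.corrcoef(vals)
    corr = np.clip(corr, -1.0, 1.0)
    corr = (corr + corr.T) / 2.0
    np.fill_diagonal(corr, 1.0)
    return corr


def signed_adjacency(corr: np.ndarray, beta: int) -> np.ndarray:
    """Signed connection strengths Adj = (0.5 * (1 + Corr))^beta in [0, 1].

    The half-shift maps corr -1 -> 0 and +1 -> 1, so negatively correlated
    (repressed) gene pairs receive near-zero weight rather than a strong one.
    """
    if beta < 1:
        raise ValueError(f"beta must be >= 1, got {beta}")
    adj = (0.5 * (1.0 + corr)) ** beta
    np.fill_diagonal(adj, 1.0)
    return adj


def connectivity(adjacency: np.ndarray) -> np.ndarray:
    """Whole-network connectivity k_i = sum_{j != i} Adj_ij."""
    return adjacency.sum(axis=1) - np.diag(adjacency)


def scale_free_fit(adjacency: np.ndarray, n_bins: int = 10) -> tuple[float, float, bool]:
    """Scale-free topology fit of the adjacency's connectivity distribution.

    Returns ``(r2_signed, slope, degenerate)``; see :func:`fit_power_law`.
    """
    return fit_power_law(connectivity(adjacency), n_bins=n_bins)


def fit_power_law(k: np.ndarray, n_bins: int = 10) -> tuple[float, float, bool]:
    """Power-law fit index of a connectivity vector.

    Bins connectivity into ``n_bins`` equal-width bins, regresses
    log10(frequency) on log10(mean connectivity) over non-empty bins and
    returns ``(r2_signed, slope, degenerate)`` with
    r2_signed = -sign(slope) * R^2.
    """
    k = np.asarray(k, dtype=float)
    if np.ptp(k) == 0:
        return 0.0, 0.0, True
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    mean_k, freq = [], []
    for b in range(n_bins):
        mask = idx == b
        if mask.sum() == 0:
            continue
        mk = k[mask].mean()
        if mk <= 0:
            continue
        mean_k.append(mk)
        freq.append(mask.mean())
    if len(mean_k) < 2:
        return 0.0, 0.0, True
    res = stats.linregress(np.log10(mean_k), np.log10(freq))
    r2 = res.rvalue**2
    return float(-np.sign(res.slope) * r2), float(res.slope), False


def select_beta(
    expr: pd.DataFrame,
    candidates: list[int] | range = range(1, 31),
    r2_threshold: float = 0.85,
    n_bins: int = 10,
    corr: np.ndarray | None = None,
) -> ScaleFreeFit:
    """Scan candidate powers and pick the smallest achieving the fit criterion.

    The chosen beta is the smallest candidate with signed R^2 >= threshold and
    negative slope; if none qualifies, the candidate with maximal signed R^2
    is chosen and a warning is logged.
    """
    candidates = sorted(int(b) for b in candidates)
    if not candidates:
        raise ValueError("empty candidate list")
    if corr is None:
        corr = pairwise_correlation(expr)
    r2s, slopes = [], []
    for beta in candidates:
        r2, slope, _ = scale_free_fit(signed_adjacency(corr, beta), n_bins=n_bins)
        r2s.append(r2)
        slopes.append(slope)
    r2s = np.array(r2s)
    slopes = np.array(slopes)
    ok = (r2s >= r2_threshold) & (slopes < 0)
    if ok.any():
        chosen = candidates[int(np.argmax(ok))]
        met = True
    else:
        chosen = candidates[int(np.argmax(r2s))]
        met = False
        logger.warning(
            "select_beta: no candidate reached signed R^2 >= %g; using beta=%d (R^2=%.3f)",
            r2_threshold, chosen, r2s.max(),
        )
    return ScaleFreeFit(candidates, r2s, slopes, chosen, r2_threshold, met)


def _check_adjacency(adjacency: np.ndarray) -> None:
    if adjacency.ndim != 2 or adjacency.shape[0] != adjacency.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(adjacency, adjacency.T, atol=_SYM_TOL):
        raise ValueError("adjacency must be symmetric")
    if adjacency.min() < -_SYM_TOL or adjacency.max() > 1 + _SYM_TOL:
        raise ValueError("adjacency entries must lie in [0, 1]")
    if not np.allclose(np.diag(adjacency), 1.0, atol=_SYM_TOL):
        raise ValueError("adjacency must have unit diagonal")


def topological_overlap(adjacency: np.ndarray, block_size: int = 2000) -> np.ndarray:
    """Topological overlap matrix.

    TOM_ij = (L_ij + Adj_ij) / (min(k_i, k_j) + 1 - Adj_ij) for i != j, where
    L_ij = sum_{u != i,j} Adj_iu * Adj_uj counts shared-neighbour agreement and
    k is connectivity; TOM_ii = 1. Computed in row blocks of ``block_size`` to
    bound working memory on large gene sets.
    """
    _check_adjacency(adjacency)
    a = adjacency.astype(float).copy()
    np.fill_diagonal(a, 0.0)
    n = a.shape[0]
    k = a.sum(axis=1)
    tom = np.empty_like(a)
    for start in range(0, n, block_size):
        stop = min(start + block_size, n)
        block = a[start:stop]
        l_block = block @ a  # zero diagonal of `a` excludes u == i and u == j terms
        min_k = np.minimum.outer(k[start:stop], k)
        denom = min_k + 1.0 - block
        tom[start:stop] = (l_block + block) / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return tom


def dissimilarity(tom: np.ndarray) -> np.ndarray:
    """dissTOM = 1 - TOM; zero diagonal."""
    d = 1.0 - tom
    np.fill_diagonal(d, 0.0)
    return d


def build_network(
    expr: pd.DataFrame,
    beta: int | None = None,
    candidates: list[int] | range = range(1, 31),
    r2_threshold: float = 0.85,
    n_bins: int = 10,
) -> CoexpressionNetwork:
    """Correlation, soft-threshold selection (unless ``beta`` given), adjacency
    and TOM in one call."""
    corr = pairwise_correlation(expr)
    fit = None
    if beta is None:
        fit = select_beta(expr, candidates, r2_threshold, n_bins, corr=corr)
        beta = fit.chosen_beta
    adj = signed_adjacency(corr, beta)
    tom = topological_overlap(adj)
    return CoexpressionNetwork(list(expr.index), corr, beta, adj, tom, fit)
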