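"""Module detection on the TOM dissimilarity: average-linkage clustering,
adaptive (dynamic) branch cutting, module eigengenes, and eigengene-based
module merging.

The dynamic cut is the hybrid adaptive branch-cutting scheme, implemented as
bottom-up branch tracking along the dendrogram merges (without the optional
medoid refinement stage): a branch is accepted as a module when it is large
enough, internally tight (low core scatter) and well separated from the
height at which it merges with the rest of the tree. Genes in no accepted
branch receive label 0 (the unassigned module, M0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

__all__ = [
    "Eigengenes",
    "ModuleDetection",
    "hierarchical_cluster",
    "dynamic_tree_cut",
    "module_eigengene",
    "merge_similar_modules",
    "relabel_modules",
    "detect_modules",
]

# deepSplit sensitivity -> maximum allowed (normalised) core scatter; the
# minimum branch gap is tied to it. Higher sensitivity tolerates looser cores,
# splitting the tree into more, smaller modules.
_MAX_CORE_SCATTER = {0: 0.64, 1: 0.73, 2: 0.82, 3: 0.91, 4: 0.95}


def hierarchical_cluster(disstom: np.ndarray) -> np.ndarray:
    """Average-linkage (UPGMA) tree on the TOM dissimilarity.

    Returns a SciPy linkage matrix (n-1 merges, heights non-decreasing).
    """
    d = np.asarray(disstom, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("dissimilarity must be square")
    if d.shape[0] < 2:
        raise ValueError("clustering requires at least 2 genes")
    return linkage(squareform(d, checks=False), method="average")


class _Branch:
    __slots__ = ("members", "frozen", "clusters")

    def __init__(self, members: list[int]):
        self.members = members
        self.frozen = False
        self.clusters: list[list[int]] = []


def dynamic_tree_cut(
    Z: np.ndarray,
    disstom: np.ndarray,
    deep_split: int = 2,
    min_cluster_size: int = 15,
    cut_height: float | None = None,
) -> np.ndarray:
    """Adaptive branch cutting of the dendrogram into modules.

    Merges are scanned bottom-up below the static cut height (default: 5th
    percentile + 0.99 x range of the joining heights). A growing branch
    qualifies as a module once (i) it has >= ``min_cluster_size`` members,
    (ii) the mean pairwise dissimilarity of its core (its
    ``min_cluster_size`` lowest-merging leaves) is at most the deep-split
    dependent maxCoreScatter, and (iii) the gap between its merging height
    and its core scatter is at least minGap (heights normalised to [0, 1]).
    When two qualifying branches meet, both are fixed as modules; an
    unqualified branch meeting a qualifying one is absorbed. Finally each
    module is trimmed: members whose mean dissimilarity to the module core
    exceeds maxCoreScatter are returned to the unassigned label 0.
    """
    if deep_split not in _MAX_CORE_SCATTER:
        raise ValueError(f"deep_split must be in 0..4, got {deep_split}")
    if min_cluster_size < 2:
        raise ValueError("min_cluster_size must be >= 2")
    n = Z.shape[0] + 1
    labels = np.zeros(n, dtype=int)
    if min_cluster_size > n:
        logger.warning("dynamic_tree_cut: min_cluster_size %d exceeds %d genes; all unassigned",
                       min_cluster_size, n)
        return labels

    heights = Z[:, 2]
    hmin, hmax = float(heights.min()), float(heights.max())
    if hmax == hmin:  # degenerate flat tree: everything equally similar
        return np.ones(n, dtype=int)
    q05 = float(np.quantile(heights, 0.05))
    if cut_height is None:
        cut_height = q05 + 0.99 * (hmax - q05)

    # scatter/gap thresholds are expressed on the scale anchored at the 5th
    # percentile of joining heights and the cut height
    span = cut_height - q05
    if span <= 0:
        return np.ones(n, dtype=int)
    dnorm = np.clip((np.asarray(disstom, dtype=float) - q05) / span, 0.0, None)
    max_scatter = _MAX_CORE_SCATTER[deep_split]
    min_gap = (1.0 - max_scatter) * 3.0 / 4.0

    # attach height of a leaf = height of its first merge
    leaf_attach = np.empty(n)
    for i in range(n - 1):
        for child in (int(Z[i, 0]), int(Z[i, 1])):
            if child < n:
                leaf_attach[child] = heights[i]

    def core_scatter(members: list[int]) -> float:
        order = sorted(members, key=lambda l: (leaf_attach[l], l))
        core = order[: min(len(order), min_cluster_size)]
        if len(core) < 2:
            return 0.0
        sub = dnorm[np.ix_(core, core)]
        m = len(core)
        return float(sub.sum() / (m * (m - 1)))

    def qualifies(branch: _Branch, merge_h: float) -> bool:
        if len(branch.members) < min_cluster_size:
            return False
        scatter = core_scatter(branch.members)
        gap = max(0.0, (merge_h - q05) / span) - scatter
        return scatter <= max_scatter and gap >= min_gap

    node_branch: dict[int, _Branch] = {}

    def get_branch(node: int) -> _Branch:
        if node < n:
            return _Branch([node])
        return node_branch.pop(node)

    final_clusters: list[list[int]] = []
    for i in range(n - 1):
        h = float(heights[i])
        if h > cut_height:
            break
        bu = get_branch(int(Z[i, 0]))
        bv = get_branch(int(Z[i, 1]))
        qu = bu.frozen or qualifies(bu, h)
        qv = bv.frozen or qualifies(bv, h)
        if qu and qv:
            merged = _Branch(bu.members + bv.members)
            merged.frozen = True
            for b in (bu, bv):
                if b.frozen:
                    merged.clusters.extend(b.clusters)
                else:
                    merged.clusters.append(b.members)
        elif qu or qv:
            good, other = (bu, bv) if qu else (bv, bu)
            if good.frozen:
                # leaves joining an already-fixed composite stay unassigned
                merged = good
                merged.members = good.members + other.members
            else:
                merged = _Branch(good.members + other.members)
        else:
            merged = _Branch(bu.members + bv.members)
        node_branch[n + i] = merged
    # finalize branches not consumed by a processed merge
    for branch in node_branch.values():
        if branch.frozen:
            final_clusters.extend(branch.clusters)
        elif qualifies(branch, cut_height):
            final_clusters.append(branch.members)

    # attachment trim: a member stays only if its mean dissimilarity to the
    # branch core is closer to the core scatter than to the cut height
    label = 0
    for members in final_clusters:
        order = sorted(members, key=lambda l: (leaf_attach[l], l))
        core = set(order[: min(len(order), min_cluster_size)])
        core_idx = np.array(sorted(core))
        scatter = core_scatter(members)
        trim_at = scatter + 0.5 * (1.0 - scatter)  # 1.0 = the cut on this scale
        keep = []
        for m in members:
            if m in core:
                keep.append(m)
                continue
            mean_d = float(dnorm[m, core_idx].mean())
            if mean_d <= trim_at:
                keep.append(m)
        if len(keep) >= min_cluster_size:
            label += 1
            labels[keep] = label
    logger.info("dynamic_tree_cut: %d modules, %d/%d genes unassigned",
                label, int((labels == 0).sum()), n)
    return labels


@dataclass
class Eigengenes:
    """Module eigengenes: first principal component of each module's
    standardised expression, sign-aligned to correlate positively (on
    average) with the member genes; unit norm over samples."""

    values: pd.DataFrame  # modules x samples
    variance_explained: pd.Series

    @property
    def module_ids(self) -> list[int]:
        return list(self.values.index)


def module_eigengene(expr: pd.DataFrame, labels: pd.Series) -> Eigengenes:
    """First right singular vector of each module's gene-standardised
    submatrix; ``variance_explained`` is the leading squared singular value
    over the total."""
    labels = labels.reindex(expr.index)
    rows, ve = {}, {}
    for mod in sorted(int(m) for m in labels.unique() if m != 0):
        sub = expr.loc[labels == mod].to_numpy(dtype=float)
        if sub.shape[0] < 2:
            raise ValueError(f"module {mod} has fewer than 2 genes")
        mu = sub.mean(axis=1, keepdims=True)
        sd = sub.std(axis=1, ddof=1, keepdims=True)
        if (sd == 0).any():
            bad = expr.index[labels == mod][(sd == 0).ravel()].tolist()
            raise ValueError(f"zero-variance genes in module {mod}: {bad[:10]}")
        std = (sub - mu) / sd
        u, s, vt = np.linalg.svd(std, full_matrices=False)
        v = vt[0]
        # sign convention: mean correlation with member genes >= 0
        norms = np.linalg.norm(std, axis=1)
        if float(np.sum(std @ v / norms)) < 0:
            v = -v
        rows[mod] = v
        ve[mod] = float(s[0] ** 2 / np.sum(s**2))
    values = pd.DataFrame(rows, index=expr.columns).T
    values.index.name = "module"
    return Eigengenes(values, pd.Series(ve, name="variance_explained"))


def merge_similar_modules(
    expr: pd.DataFrame,
    labels: pd.Series,
    merge_cut: float = 0.9,
    max_iter: int = 100,
) -> tuple[pd.Series, Eigengenes]:
    """Merge modules whose eigengenes correlate at least ``merge_cut``.

    Eigengenes are clustered by average linkage on 1 - correlation; all
    modules joined at or below 1 - merge_cut collapse into one, eigengenes
    are recomputed and the procedure repeats until the maximum off-diagonal
    eigengene correlation is below the cut. Label 0 never merges.
    """
    labels = labels.copy()
    eig = module_eigengene(expr, labels)
    for _ in range(max_iter):
        mods = eig.module_ids
        if len(mods) < 2:
            break
        corr = np.corrcoef(eig.values.to_numpy())
        off = corr[~np.eye(len(mods), dtype=bool)]
        if off.max() < merge_cut:
            break
        d = np.clip(1.0 - corr, 0.0, None)
        np.fill_diagonal(d, 0.0)
        Z = linkage(squareform(d, checks=False), method="average")
        groups = fcluster(Z, t=1.0 - merge_cut, criterion="distance")
        mapping = {}
        for g in np.unique(groups):
            grp = [mods[j] for j in np.flatnonzero(groups == g)]
            target = min(grp)
            for m in grp:
                mapping[m] = target
        if all(k == v for k, v in mapping.items()):
            break
        labels = labels.map(lambda m: mapping.get(int(m), int(m))).astype(int)
        logger.info("merge_similar_modules: %d -> %d modules", len(mods),
                    len(set(mapping.values())))
        eig = module_eigengene(expr, labels)
    return labels, eig


def relabel_modules(labels: pd.Series) -> pd.Series:
    """Renumber modules 1..K by decreasing size (ties broken by the smallest
    member gene ID); 0 is preserved."""
    sizes = labels[labels != 0].value_counts()
    keyed = sorted(
        sizes.index,
        key=lambda m: (-sizes[m], min(str(g) for g in labels.index[labels == m])),
    )
    mapping = {int(old): new for new, old in enumerate(keyed, start=1)}
    mapping[0] = 0
    return labels.map(lambda m: mapping[int(m)]).astype(int)


@dataclass
class ModuleDetection:
    labels: pd.Series
    eigengenes: Eigengenes
    linkage: np.ndarray


def detect_modules(
    expr: pd.DataFrame,
    disstom: np.ndarray,
    deep_split: int = 2,
    min_cluster_size: int = 15,
    merge_cut: float = 0.9,
    cut_height: float | None = None,
) -> ModuleDetection:
    """Cluster, cut, merge and canonically relabel in one call."""
    Z = hierarchical_cluster(disstom)
    raw = dynamic_tree_cut(Z, disstom, deep_split, min_cluster_size, cut_height)
    labels = pd.Series(raw, index=expr.index, name="module")
    if (labels != 0).any():
        labels, _ = merge_similar_modules(expr, labels, merge_cut=merge_cut)
        labels = relabel_modules(labels)
        eig = module_eigengene(expr, labels)
    else:
        eig = Eigengenes(pd.DataFrame(columns=expr.columns), pd.Series(dtype=float))
    return ModuleDetection(labels, eig, Z)
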