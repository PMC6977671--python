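"""Hub-gene identification and trait-based prioritisation.

A gene's intramodular connectivity (kIM) is its summed adjacency to the other
genes of its own module; dividing by the module maximum gives scaled kIM, and
genes with scaled kIM >= 0.7 are hubs. Hubs of trait-relevant modules are
further prioritised when their gene significance (|correlation| with the
trait, computed under the same scheme as the module-level association) falls
in the upper quartile of the module's GS distribution.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .trait import partial_correlation, repeated_measures_correlation, _pearson

logger = logging.getLogger(__name__)

__all__ = [
    "intramodular_connectivity",
    "scale_and_flag_hubs",
    "gene_significance",
    "prioritize_hubs",
]


def intramodular_connectivity(
    adjacency: np.ndarray, labels: pd.Series
) -> pd.Series:
    """kIM_i = sum of adjacency to same-module genes (unassigned genes are
    excluded)."""
    lab = labels.to_numpy()
    genes = labels.index
    kim = pd.Series(np.nan, index=genes, name="kIM")
    for mod in np.unique(lab):
        if mod == 0:
            continue
        idx = np.flatnonzero(lab == mod)
        sub = adjacency[np.ix_(idx, idx)]
        kim.iloc[idx] = sub.sum(axis=1) - np.diag(sub)
    return kim.dropna()


def scale_and_flag_hubs(
    kim: pd.Series, labels: pd.Series, threshold: float = 0.7
) -> pd.DataFrame:
    """Scale kIM by the module maximum and flag hubs (scaled kIM >= threshold)."""
    labels = labels.reindex(kim.index)
    out = pd.DataFrame({"module": labels.astype(int), "kIM": kim})
    scaled = np.full(len(out), 0.0)
    for mod, grp in out.groupby("module"):
        mx = grp["kIM"].max()
        if mx <= 0:
            logger.warning("module %s has max kIM = 0; scaled values set to 0", mod)
            continue
        scaled[out.index.get_indexer(grp.index)] = grp["kIM"] / mx
    out["kIM_scaled"] = scaled
    out["is_hub"] = out["kIM_scaled"] >= threshold
    return out


def gene_significance(
    expr: pd.DataFrame,
    trait: pd.Series,
    scheme: str,
    design: pd.DataFrame | None = None,
    group: str | None = None,
    covariate: np.ndarray | pd.Series | None = None,
    subject: pd.Series | None = None,
) -> pd.Series:
    """Gene significance GS = |r| between each gene's expression and a trait,
    using the same correlation machinery as the module-level scheme.

    ``expr`` columns must align with the observations of ``trait`` (one trait
    value per expression column). Schemes: 'pearson', 'per_group' (restrict
    to ``group`` via design age_group), 'partial' (needs ``covariate``),
    'rmcorr' (needs ``subject``).
    """
    y = np.asarray(trait, dtype=float)
    X = expr.to_numpy(dtype=float)
    if scheme in ("pearson", "per_group"):
        if scheme == "per_group":
            if design is None or group is None:
                raise ValueError("per_group GS needs design and group")
            mask = (design["age_group"] == group).to_numpy()
            X, y = X[:, mask], y[mask]
        xc = X - X.mean(axis=1, keepdims=True)
        yc = y - y.mean()
        denom = np.sqrt((xc**2).sum(axis=1) * (yc @ yc))
        if (denom == 0).any():
            raise ValueError("zero variance in GS input")
        r = xc @ yc / denom
        return pd.Series(np.abs(np.clip(r, -1, 1)), index=expr.index, name="GS")
    if scheme == "partial":
        if covariate is None:
            raise ValueError("partial GS needs a covariate")
        gs = {
            g: abs(partial_correlation(X[i], y, np.asarray(covariate, float)).r)
            for i, g in enumerate(expr.index)
        }
        return pd.Series(gs, name="GS")
    if scheme == "rmcorr":
        if subject is None:
            raise ValueError("rmcorr GS needs subject identifiers")
        gs = {
            g: abs(repeated_measures_correlation(X[i], y, subject).r)
            for i, g in enumerate(expr.index)
        }
        return pd.Series(gs, name="GS")
    raise ValueError(f"unknown GS scheme '{scheme}'")


def prioritize_hubs(hub_table: pd.DataFrame, gs: pd.Series) -> pd.DataFrame:
    """Mark hubs whose GS reaches the 75th percentile (linear interpolation)
    of GS over all genes of the same module; prioritized implies hub."""
    out = hub_table.copy()
    out["GS"] = gs.reindex(out.index)
    out["prioritized"] = False
    for mod, grp in out.groupby("module"):
        vals = grp["GS"].dropna()
        if vals.empty:
            continue
        q75 = float(np.percentile(vals, 75))
        sel = grp.index[(grp["is_hub"]) & (grp["GS"] >= q75)]
        out.loc[sel, "prioritized"] = True
    return out
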