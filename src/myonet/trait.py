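"""Module-trait association under the age-(in)dependent decision scheme.

Baseline: for each module, an OLS interaction screen (trait ~ eigengene + age
+ eigengene x age) routes the analysis — a significant interaction yields
per-age-group Pearson correlations (age-dependent), otherwise a single
partial correlation controlling for age (age-independent). Post-exercise:
contraction-responsive modules are correlated with % MVC decline using plain
Pearson (single contraction mode) or repeated-measures correlation (pooled
ECC+CON observations per subject). Significance everywhere: |r| > 0.5 and
p < 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "TraitAssociation",
    "interaction_screen",
    "group_correlation",
    "partial_correlation",
    "repeated_measures_correlation",
    "baseline_mvc",
    "classify_module_trait",
]


@dataclass
class TraitAssociation:
    module: int | str | None
    scheme: str  # 'interaction' | 'per_group' | 'partial' | 'rmcorr' | 'pearson'
    r: float
    p: float
    n: int
    group: str | None = None
    measure: str | None = None  # e.g. 'baseline', 'post_abs', 'post_delta'
    significant: bool = False

    def flag(self, r_min: float = 0.5, alpha: float = 0.05) -> "TraitAssociation":
        self.significant = bool(abs(self.r) > r_min and self.p < alpha)
        return self


def _as_array(x) -> np.ndarray:
    return np.asarray(x, dtype=float)


def _pearson(x: np.ndarray, y: np.ndarray, df: int | None = None) -> tuple[float, float]:
    n = len(x)
    if df is None:
        df = n - 2
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        raise ValueError("zero variance in correlation input")
    r = float(np.clip(xc @ yc / denom, -1.0, 1.0))
    if df <= 0 or abs(r) == 1.0:
        return r, 0.0 if abs(r) == 1.0 else 1.0
    t = r * np.sqrt(df / (1.0 - r * r))
    return r, float(2.0 * stats.t.sf(abs(t), df))


def interaction_screen(eigengene, trait, age_group) -> float:
    """Two-sided p-value of the eigengene x age interaction in
    trait ~ eigengene + age + eigengene:age (OLS)."""
    x, y = _as_array(eigengene), _as_array(trait)
    age = pd.Series(age_group).astype(str).to_numpy()
    groups = np.unique(age)
    if len(groups) < 2:
        raise ValueError("interaction screen requires both age groups")
    if len(x) < 6:
        raise ValueError("interaction screen requires n >= 6")
    a = (age == groups[1]).astype(float)
    X = np.column_stack([np.ones_like(x), x, a, x * a])
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise ValueError("interaction design is rank deficient")
    resid = y - X @ beta
    df = len(y) - X.shape[1]
    s2 = resid @ resid / df
    scale = float(np.mean(y * y)) or 1.0
    if s2 / scale < 1e-24:  # perfect fit: no residual evidence either way
        return 1.0 if abs(beta[3]) < 1e-10 * np.sqrt(scale) else 0.0
    cov = s2 * np.linalg.inv(X.T @ X)
    t = beta[3] / np.sqrt(cov[3, 3])
    return float(2.0 * stats.t.sf(abs(t), df))


def group_correlation(eigengene, trait, age_group) -> dict[str, TraitAssociation]:
    """Pearson r and two-sided p separately within each age group."""
    x, y = _as_array(eigengene), _as_array(trait)
    age = pd.Series(age_group).astype(str).to_numpy()
    out = {}
    for g in np.unique(age):
        mask = age == g
        if mask.sum() < 3:
            raise ValueError(f"group '{g}' has fewer than 3 samples")
        r, p = _pearson(x[mask], y[mask])
        out[g] = TraitAssociation(None, "per_group", r, p, int(mask.sum()), group=g).flag()
    return out


def _residualize(v: np.ndarray, covariate: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones_like(covariate), covariate])
    beta, _, rank, _ = np.linalg.lstsq(X, v, rcond=None)
    if rank < 2:
        raise ValueError("covariate is collinear with the intercept")
    return v - X @ beta


def partial_correlation(eigengene, trait, covariate) -> TraitAssociation:
    """Pearson correlation of the two variables after residualising both on
    the covariate (with intercept); p from t with n - 3 df."""
    x, y, z = _as_array(eigengene), _as_array(trait), _as_array(covariate)
    n = len(x)
    if n < 4:
        raise ValueError("partial correlation requires n >= 4")
    rx = _residualize(x, z)
    ry = _residualize(y, z)
    if np.allclose(ry, 0) or np.allclose(rx, 0):
        logger.warning("partial correlation: degenerate residual (variable ~ covariate)")
        return TraitAssociation(None, "partial", 0.0, 1.0, n).flag()
    r, p = _pearson(rx, ry, df=n - 3)
    return TraitAssociation(None, "partial", r, p, n).flag()


def repeated_measures_correlation(x, y, subject) -> TraitAssociation:
    """Common within-subject correlation (ANCOVA with subject factor).

    r_rm = sign(b) * sqrt(SS_x / (SS_x + SS_error)) where b is the common
    slope after removing subject means; df = N - n_subjects - 1.
    """
    x, y = _as_array(x), _as_array(y)
    subj = pd.Series(subject).astype(str)
    counts = subj.value_counts()
    usable = counts.index[counts >= 2]
    dropped = counts.index[counts < 2].tolist()
    if dropped:
        logger.warning("rmcorr: dropping subjects with < 2 observations: %s", dropped)
    mask = subj.isin(usable).to_numpy()
    x, y, subj = x[mask], y[mask], subj[mask].to_numpy()
    groups = pd.unique(subj)
    if len(groups) < 2:
        raise ValueError("rmcorr requires >= 2 subjects with >= 2 observations")
    xc = x.copy()
    yc = y.copy()
    for g in groups:
        m = subj == g
        xc[m] -= x[m].mean()
        yc[m] -= y[m].mean()
    sxx = float(xc @ xc)
    if sxx == 0:
        raise ValueError("rmcorr: no within-subject variation in x")
    b = float(xc @ yc) / sxx
    ss_x = b * b * sxx
    resid = yc - b * xc
    ss_err = float(resid @ resid)
    n_obs, n_subj = len(x), len(groups)
    df = n_obs - n_subj - 1
    r = float(np.sign(b) * np.sqrt(ss_x / (ss_x + ss_err))) if (ss_x + ss_err) > 0 else 0.0
    if df <= 0 or abs(r) >= 1.0:
        p = 0.0 if abs(r) >= 1.0 else 1.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df))
    return TraitAssociation(None, "rmcorr", r, p, n_obs).flag()


def baseline_mvc(traits: pd.DataFrame) -> pd.Series:
    """Per-subject baseline MVC: the average of the two legs when left/right
    columns are present, otherwise the single ``baseline_mvc`` column."""
    if {"baseline_mvc_left", "baseline_mvc_right"} <= set(traits.columns):
        return (traits["baseline_mvc_left"] + traits["baseline_mvc_right"]) / 2.0
    if "baseline_mvc" in traits.columns:
        return traits["baseline_mvc"]
    raise ValueError("trait table lacks baseline MVC columns")


def classify_module_trait(
    eigengenes: pd.DataFrame,
    traits: pd.DataFrame,
    design: pd.DataFrame,
    responsive: dict[int, set[str]] | None = None,
    alpha: float = 0.05,
    r_min: float = 0.5,
) -> list[TraitAssociation]:
    """Run the full module-trait decision scheme.

    Baseline (all modules): interaction screen on baseline samples routes to
    per-age-group Pearson (age-dependent) or age-partial correlation
    (age-independent). Post-exercise (modules listed in ``responsive``,
    mapping module -> set of contraction modes from {'ECC','CON'}): absolute
    and delta (post - subject baseline) eigengene values are correlated with
    the matching % MVC decline — Pearson for a single mode, repeated-measures
    correlation when both modes pool per subject.
    """
    results: list[TraitAssociation] = []
    mvc = baseline_mvc(traits)
    bl_mask = design["condition"] == "BL"
    bl_samples = design.index[bl_mask]
    bl_subjects = design.loc[bl_mask, "subject"]
    bl_age = design.loc[bl_mask, "age_group"]
    age_numeric = (bl_age == bl_age.unique()[1]).astype(float)
    y = mvc.reindex(bl_subjects).to_numpy(dtype=float)

    for mod, eg in eigengenes.iterrows():
        x = eg.reindex(bl_samples).to_numpy(dtype=float)
        p_int = interaction_screen(x, y, bl_age)
        results.append(
            TraitAssociation(mod, "interaction", np.nan, p_int, len(x), measure="baseline")
        )
        if p_int < alpha:  # age-dependent: report each age group separately
            for g, assoc in group_correlation(x, y, bl_age).items():
                assoc.module = mod
                assoc.measure = "baseline"
                assoc.flag(r_min, alpha)
                results.append(assoc)
        else:  # age-independent: partial correlation with age as covariate
            assoc = partial_correlation(x, y, age_numeric.to_numpy())
            assoc.module = mod
            assoc.measure = "baseline"
            assoc.flag(r_min, alpha)
            results.append(assoc)

    if responsive:
        results.extend(
            _post_exercise_associations(eigengenes, traits, design, responsive, alpha, r_min)
        )
    return results


def _post_exercise_associations(
    eigengenes: pd.DataFrame,
    traits: pd.DataFrame,
    design: pd.DataFrame,
    responsive: dict[int, set[str]],
    alpha: float,
    r_min: float,
) -> list[TraitAssociation]:
    out: list[TraitAssociation] = []
    decline_col = {"ECC": "pct_decline_ecc", "CON": "pct_decline_con"}
    bl = design.index[design["condition"] == "BL"]
    for mod, modes in responsive.items():
        if mod not in eigengenes.index:
            continue
        eg = eigengenes.loc[mod]
        bl_by_subject = pd.Series(
            eg.reindex(bl).to_numpy(), index=design.loc[bl, "subject"]
        )
        rows = []  # (subject, mode, post_value, delta, decline)
        for cond in sorted(modes):
            samp = design.index[design["condition"] == cond]
            for s in samp:
                subj = design.loc[s, "subject"]
                if subj not in bl_by_subject.index:
                    continue
                decline = traits.loc[subj, decline_col[cond]] if subj in traits.index else np.nan
                if np.isnan(decline):
                    continue
                post = float(eg[s])
                rows.append((subj, cond, post, post - float(bl_by_subject[subj]), decline))
        if len(rows) < 4:
            continue
        df = pd.DataFrame(rows, columns=["subject", "mode", "post", "delta", "decline"])
        pooled = len(modes) > 1
        for measure in ("post", "delta"):
            if pooled:
                assoc = repeated_measures_correlation(
                    df[measure].to_numpy(), df["decline"].to_numpy(), df["subject"]
                )
            else:
                r, p = _pearson(df[measure].to_numpy(), df["decline"].to_numpy())
                assoc = TraitAssociation(None, "pearson", r, p, len(df))
            assoc.module = mod
            assoc.measure = f"post_{'delta' if measure == 'delta' else 'abs'}"
            assoc.flag(r_min, alpha)
            out.append(assoc)
    return out
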