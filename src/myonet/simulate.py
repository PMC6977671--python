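"""Synthetic data with the statistical structure the pipeline assumes.

Emulates the study design: two age groups of subjects, each sampled at
baseline (BL) and 5 h after eccentric (ECC) and concentric (CON) leg
exercise. Each planted module m follows a single-factor model: its factor
f_m(sample) = design effect + subject random intercept + standard-normal
innovation, and member genes are x_gs = mu_g + a_g * f_m(s) + noise with
loadings a_g spanning weak-to-hub genes. Background genes are pure noise.
Muscle-strength traits are linear in selected module factors, annotation
terms coincide with planted modules (plus decoys), and one TF per selected
module has an elevated binding-site hit rate. Optionally, counts are
synthesised by inverting the RPKM/log transform and Poisson sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .enrich import AnnotationSet

__all__ = ["SimulationConfig", "SyntheticTruth", "SyntheticDataset",
           "generate_dataset", "evaluate_recovery", "RecoveryMetrics"]

# effect map: module label -> {(age_group | None, condition | None): shift}
# applied to the module factor for every matching sample (None = all).
_DEFAULT_EFFECTS = {
    1: {("older", None): 1.2},      # age-shifted module
    2: {(None, "ECC"): 1.5},        # ECC-responsive in both ages
    3: {("older", "CON"): -1.5},    # CON-suppressed in older muscle only
}

# trait couplings: (module, kind); baseline MVC couples to module 4 with a
# common slope across ages and to module 5 with age-crossover slopes; the
# post-exercise % MVC declines track the responsive modules' post factors.
_DEFAULT_TRAIT = {
    "baseline_common": {"module": 4, "slope": 18.0},
    "baseline_age_dependent": {"module": 5, "slope_young": 18.0, "slope_older": -18.0},
    "decline_ecc": {"module": 2, "slope": 6.0},
    "decline_con": {"module": 3, "slope": 6.0},
}


@dataclass
class SimulationConfig:
    n_subjects_per_group: int = 8
    age_groups: tuple[str, ...] = ("young", "older")
    conditions: tuple[str, ...] = ("BL", "ECC", "CON")
    module_sizes: tuple[int, ...] = (200, 120, 80, 50, 30)
    n_background: int = 300
    loading_range: tuple[float, float] = (0.4, 0.95)
    noise_sd: float = 1.0
    subject_sd: float = 0.5
    mean_range: tuple[float, float] = (2.0, 8.0)
    effects: dict = field(default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_EFFECTS.items()})
    trait_couplings: dict = field(default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_TRAIT.items()})
    trait_noise_sd: float = 4.0
    baseline_mvc_mean: dict = field(default_factory=lambda: {"young": 220.0, "older": 160.0})
    decline_mean: float = 20.0
    n_decoy_terms: int = 20
    n_null_tfs: int = 15
    region_length_bp: int = 10_000
    tf_null_rate: float = 5.0      # expected hits per gene region
    tf_enriched_rate: float = 15.0
    counts: bool = False
    library_size: float = 2e7

    def validate(self) -> None:
        if self.n_subjects_per_group < 2:
            raise ValueError("need at least 2 subjects per age group")
        if any(s < 2 for s in self.module_sizes):
            raise ValueError("module sizes must be >= 2")
        lo, hi = self.loading_range
        if not (0 < lo <= hi):
            raise ValueError("invalid loading range")
        for m in self.effects:
            if not 1 <= m <= len(self.module_sizes):
                raise ValueError(f"effect map refers to unknown module {m}")


@dataclass
class SyntheticTruth:
    labels: pd.Series            # gene -> planted module (0 = background)
    factors: pd.DataFrame        # modules x samples
    loadings: pd.Series          # gene -> loading (0 for background)
    effects: dict
    trait_couplings: dict


@dataclass
class SyntheticDataset:
    expr: pd.DataFrame           # genes x samples, log2(RPKM+1)-like scale
    counts: pd.DataFrame | None
    gene_lengths: pd.Series
    design: pd.DataFrame         # sample -> subject, age_group, condition
    traits: pd.DataFrame         # subject -> MVC columns
    annotation: AnnotationSet
    tfbs_hits: pd.DataFrame      # long: tf_id, gene_id, occurrences
    tfbs_lengths: pd.Series
    truth: SyntheticTruth


def _make_design(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for ai, age in enumerate(config.age_groups):
        prefix = age[0]
        for s in range(1, config.n_subjects_per_group + 1):
            subj = f"{prefix}{s:02d}"
            for cond in config.conditions:
                rows.append((f"{subj}_{cond}", subj, age, cond))
    design = pd.DataFrame(rows, columns=["sample_id", "subject", "age_group", "condition"])
    return design.set_index("sample_id")


def _effect_for(effects: dict, module: int, age: str, cond: str) -> float:
    total = 0.0
    for (a, c), delta in effects.get(module, {}).items():
        if (a is None or a == age) and (c is None or c == cond):
            total += delta
    return total


def generate_dataset(config: SimulationConfig | None = None, seed: int = 0) -> SyntheticDataset:
    """Draw one complete synthetic dataset. Identical config + seed gives
    byte-identical outputs."""
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    design = _make_design(config)
    samples = design.index
    n_samples = len(samples)
    n_modules = len(config.module_sizes)
    subjects = pd.unique(design["subject"])

    # module factors: design effects + subject intercept + innovation
    factors = np.zeros((n_modules, n_samples))
    for m in range(1, n_modules + 1):
        intercepts = dict(zip(subjects, rng.normal(0, config.subject_sd, len(subjects))))
        for j, samp in enumerate(samples):
            row = design.loc[samp]
            factors[m - 1, j] = (
                _effect_for(config.effects, m, row["age_group"], row["condition"])
                + intercepts[row["subject"]]
                + rng.normal()
            )

    sizes = list(config.module_sizes)
    n_genes = sum(sizes) + config.n_background
    width = len(str(n_genes))
    gene_ids = [f"G{i:0{width}d}" for i in range(1, n_genes + 1)]
    labels = np.concatenate(
        [np.full(s, m + 1) for m, s in enumerate(sizes)] + [np.zeros(config.n_background)]
    ).astype(int)
    lo, hi = config.loading_range
    loadings = np.where(labels > 0, rng.uniform(lo, hi, n_genes), 0.0)
    mu = rng.uniform(*config.mean_range, n_genes)
    expr = mu[:, None] + rng.normal(0, config.noise_sd, (n_genes, n_samples))
    for g in range(n_genes):
        if labels[g] > 0:
            expr[g] += loadings[g] * factors[labels[g] - 1]
    # values live on a log2(RPKM+1)-like scale; the mean range keeps them
    # essentially positive without truncating the factor model
    expr_df = pd.DataFrame(expr, index=gene_ids, columns=samples)

    traits = _make_traits(config, design, factors, rng)
    annotation = _make_annotation(config, gene_ids, labels, rng)
    tfbs_hits, tfbs_lengths = _make_tfbs(config, gene_ids, labels, rng)

    gene_lengths = pd.Series(
        rng.integers(200, 10_001, n_genes), index=gene_ids, name="length_bp"
    )
    counts = None
    if config.counts:
        rpkm = np.maximum(2.0**expr - 1.0, 0.0)
        lam = rpkm * gene_lengths.to_numpy()[:, None] * config.library_size / 1e9
        counts = pd.DataFrame(rng.poisson(lam), index=gene_ids, columns=samples)

    truth = SyntheticTruth(
        labels=pd.Series(labels, index=gene_ids, name="module"),
        factors=pd.DataFrame(factors, index=range(1, n_modules + 1), columns=samples),
        loadings=pd.Series(loadings, index=gene_ids, name="loading"),
        effects=config.effects,
        trait_couplings=config.trait_couplings,
    )
    return SyntheticDataset(
        expr_df, counts, gene_lengths, design, traits, annotation,
        tfbs_hits, tfbs_lengths, truth,
    )


def _make_traits(config, design, factors, rng) -> pd.DataFrame:
    subjects = pd.unique(design["subject"])
    n_modules = factors.shape[0]
    cp = config.trait_couplings

    def subj_mean(module: int, condition: str) -> pd.Series:
        if not 1 <= module <= n_modules:
            raise ValueError(f"trait coupling refers to unknown module {module}")
        mask = design["condition"] == condition
        vals = pd.Series(factors[module - 1][mask.to_numpy()],
                         index=design.loc[mask, "subject"])
        return vals.groupby(level=0).mean().reindex(subjects)

    rows = {}
    base = pd.Series([config.baseline_mvc_mean[design.loc[design["subject"] == s].iloc[0]["age_group"]]
                      for s in subjects], index=subjects)
    mvc = base.astype(float)
    if "baseline_common" in cp:
        c = cp["baseline_common"]
        mvc = mvc + c["slope"] * subj_mean(c["module"], "BL")
    if "baseline_age_dependent" in cp:
        c = cp["baseline_age_dependent"]
        f = subj_mean(c["module"], "BL")
        age = design.drop_duplicates("subject").set_index("subject")["age_group"].reindex(subjects)
        slope = np.where(age == "young", c["slope_young"], c["slope_older"])
        mvc = mvc + slope * f
    noise_l = rng.normal(0, config.trait_noise_sd, len(subjects))
    noise_r = rng.normal(0, config.trait_noise_sd, len(subjects))
    rows["baseline_mvc_left"] = mvc + noise_l
    rows["baseline_mvc_right"] = mvc + noise_r
    for mode, key in (("ecc", "decline_ecc"), ("con", "decline_con")):
        decline = pd.Series(config.decline_mean, index=subjects, dtype=float)
        if key in cp:
            c = cp[key]
            decline = decline + c["slope"] * subj_mean(c["module"], mode.upper())
        rows[f"pct_decline_{mode}"] = decline + rng.normal(0, config.trait_noise_sd, len(subjects))
    traits = pd.DataFrame(rows, index=pd.Index(subjects, name="subject_id"))
    return traits


def _make_annotation(config, gene_ids, labels, rng) -> AnnotationSet:
    terms, names, categories = {}, {}, {}
    gene_arr = np.asarray(gene_ids)
    for m in range(1, len(config.module_sizes) + 1):
        members = gene_arr[labels == m]
        take = max(2, int(round(0.8 * len(members))))
        chosen = rng.choice(members, size=take, replace=False)
        tid = f"TERM_M{m}"
        terms[tid] = set(chosen.tolist())
        names[tid] = f"planted process of module {m}"
        categories[tid] = "BP"
    for d in range(1, config.n_decoy_terms + 1):
        size = min(int(rng.integers(30, 101)), len(gene_arr))
        tid = f"DECOY_{d:02d}"
        terms[tid] = set(rng.choice(gene_arr, size=size, replace=False).tolist())
        names[tid] = f"decoy term {d}"
        categories[tid] = "BP"
    return AnnotationSet(terms, names, categories)


def _make_tfbs(config, gene_ids, labels, rng) -> tuple[pd.DataFrame, pd.Series]:
    gene_arr = np.asarray(gene_ids)
    lengths = pd.Series(config.region_length_bp, index=gene_ids, name="region_length_bp")
    rows = []
    for m in range(1, len(config.module_sizes) + 1):
        tf = f"TF_M{m}"
        lam = np.where(labels == m, config.tf_enriched_rate, config.tf_null_rate)
        occ = rng.poisson(lam)
        for g, o in zip(gene_arr, occ):
            if o > 0:
                rows.append((tf, g, int(o)))
    for t in range(1, config.n_null_tfs + 1):
        tf = f"TF_NULL_{t:02d}"
        occ = rng.poisson(config.tf_null_rate, len(gene_arr))
        for g, o in zip(gene_arr, occ):
            if o > 0:
                rows.append((tf, g, int(o)))
    hits = pd.DataFrame(rows, columns=["tf_id", "gene_id", "occurrences"])
    return hits, lengths


@dataclass
class RecoveryMetrics:
    ari: float
    jaccard: dict[int, float]              # planted module -> best Jaccard
    matched: dict[int, int]                # planted module -> detected label
    eigengene_factor_corr: dict[int, float]
    background_unassigned_fraction: float


def evaluate_recovery(
    truth: SyntheticTruth,
    labels: pd.Series,
    eigengenes: pd.DataFrame | None = None,
) -> RecoveryMetrics:
    """Planted-module recovery metrics.

    The adjusted Rand index is computed over genes the detection assigned to
    a module (detected label > 0) against the planted labels (planted
    background counts as its own class), so background genes absorbed into
    modules are penalised. Each planted module is matched to the detected
    module of maximal Jaccard overlap; for genuinely matched pairs (Jaccard
    >= 0.5) the |correlation| between the detected eigengene and the planted
    factor is reported when eigengenes are supplied.
    """
    labels = labels.reindex(truth.labels.index).fillna(0).astype(int)
    assigned = labels > 0
    if assigned.sum() == 0:
        ari = 0.0
    else:
        ari = float(adjusted_rand_score(truth.labels[assigned], labels[assigned]))
    jaccard, matched, corr = {}, {}, {}
    detected_ids = [int(m) for m in labels.unique() if m != 0]
    for m in sorted(int(x) for x in truth.labels.unique() if x != 0):
        planted = set(truth.labels.index[truth.labels == m])
        best, best_j = 0, 0.0
        for d in detected_ids:
            det = set(labels.index[labels == d])
            j = len(planted & det) / len(planted | det)
            if j > best_j:
                best, best_j = d, j
        jaccard[m] = best_j
        matched[m] = best
        if best_j >= 0.5 and eigengenes is not None and best in eigengenes.index:
            f = truth.factors.loc[m].reindex(eigengenes.columns).to_numpy(dtype=float)
            e = eigengenes.loc[best].to_numpy(dtype=float)
            corr[m] = float(abs(np.corrcoef(e, f)[0, 1]))
    bg = truth.labels == 0
    bg_frac = float((labels[bg] == 0).mean()) if bg.any() else 1.0
    return RecoveryMetrics(ari, jaccard, matched, corr, bg_frac)
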