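"""Over-representation analysis of module gene sets and TFBS enrichment.

Annotation enrichment uses the one-sided hypergeometric (Fisher) tail or its
conservative EASE variant (one subtracted from the overlap), BH-corrected
within each annotation category. TFBS enrichment scores each transcription
factor by (i) a per-nucleotide binomial Z-score of binding-site occurrence
rate in the module versus the network background and (ii) a Fisher score
(-ln one-sided Fisher p of the gene-level hit proportions); a TF is enriched
in a module when both scores reach mean + 1.5 SD of that module's score
distributions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationSet",
    "overrepresentation",
    "representative_gene_set",
    "tfbs_enrichment",
]


@dataclass
class AnnotationSet:
    """Term -> gene sets with optional per-term name/category metadata."""

    terms: dict[str, set[str]]
    names: dict[str, str] = field(default_factory=dict)
    categories: dict[str, str] = field(default_factory=dict)

    def category(self, term: str) -> str:
        return self.categories.get(term, "custom")


def _fisher_tail(overlap: int, module_n: int, term_n: int, background_n: int) -> float:
    """One-sided enrichment p = P(X >= overlap), X hypergeometric."""
    if overlap <= 0:
        return 1.0
    return float(hypergeom.sf(overlap - 1, background_n, term_n, module_n))


def overrepresentation(
    module_genes: set[str] | list[str],
    background: set[str] | list[str],
    annotation: AnnotationSet,
    method: str = "ease",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided enrichment of every annotation term in the module gene set.

    ``method='fisher'`` is the exact hypergeometric tail;
    ``method='ease'`` (the modified Fisher test) subtracts one from the
    overlap, giving a strictly more conservative p for non-empty overlaps.
    BH correction is applied within each annotation category.
    """
    if method not in ("fisher", "ease"):
        raise ValueError(f"method must be 'fisher' or 'ease', got {method}")
    background = set(background)
    module = set(module_genes) & background
    if set(module_genes) - background:
        raise ValueError("module genes must be a subset of the background")
    rows = []
    for term, genes in annotation.terms.items():
        term_bg = genes & background
        overlap = len(module & term_bg)
        degenerate = len(module) == 0 or len(term_bg) == 0
        k = overlap if method == "fisher" else overlap - 1
        p = 1.0 if degenerate else _fisher_tail(k, len(module), len(term_bg), len(background))
        rows.append(
            (term, annotation.category(term), overlap, len(term_bg), p, degenerate)
        )
    out = pd.DataFrame(
        rows, columns=["term", "category", "overlap", "term_size", "p", "degenerate"]
    )
    out["p_adj"] = np.nan
    for cat, grp in out.groupby("category"):
        _, p_adj, _, _ = multipletests(grp["p"].to_numpy(), method="fdr_bh")
        out.loc[grp.index, "p_adj"] = p_adj
    out["enriched"] = out["p_adj"] < alpha
    return out.sort_values("p_adj", kind="stable").reset_index(drop=True)


def representative_gene_set(
    module_genes: list[str], kim: pd.Series, max_size: int = 500
) -> list[str]:
    """For modules larger than ``max_size``, the ceil(size/3) most connected
    genes (by kIM, ties by gene ID) represent the module; smaller modules are
    returned unchanged."""
    genes = list(module_genes)
    if len(genes) <= max_size:
        return genes
    n_keep = math.ceil(len(genes) / 3)
    ranked = sorted(genes, key=lambda g: (-float(kim[g]), str(g)))
    return ranked[:n_keep]


def tfbs_enrichment(
    module_genes: set[str] | list[str],
    background: set[str] | list[str],
    hits: pd.DataFrame,
    region_lengths: pd.Series,
    sd_multiplier: float = 1.5,
) -> pd.DataFrame:
    """Score each TF's binding-site over-representation in a module.

    ``hits`` is a long table with columns (tf_id, gene_id, occurrences);
    ``region_lengths`` gives the searched region length (bp) per gene (e.g.
    the 5 kb up/downstream convention around the TSS). Per TF:
    Z = (x - n p) / sqrt(n p (1 - p)) with p the background per-nucleotide
    occurrence rate, n the module's searched length and x its occurrences;
    Fisher score = -ln of the one-sided Fisher p comparing the proportion of
    genes with >= 1 hit in the module versus the rest of the background.
    A TF is enriched when both scores are >= mean + ``sd_multiplier`` SD of
    the module's respective score distributions (>= mean when an SD is 0).
    """
    background = sorted(set(background))
    module = sorted(set(module_genes))
    if set(module) - set(background):
        raise ValueError("module genes must be a subset of the background")
    lengths = region_lengths.reindex(background)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("every background gene needs a positive searched-region length")
    wide = (
        hits.pivot_table(index="tf_id", columns="gene_id", values="occurrences",
                         aggfunc="sum", fill_value=0)
        .reindex(columns=background, fill_value=0)
    )
    total_len = float(lengths.sum())
    mod_mask = np.isin(background, module)
    mod_len = float(lengths.to_numpy()[mod_mask].sum())
    n_mod, n_rest = len(module), len(background) - len(module)
    rows = []
    for tf, occ in wide.iterrows():
        occ_v = occ.to_numpy(dtype=float)
        total_occ = occ_v.sum()
        p_hat = total_occ / total_len
        x = occ_v[mod_mask].sum()
        if p_hat <= 0 or p_hat >= 1:
            z = 0.0
        else:
            z = (x - mod_len * p_hat) / math.sqrt(mod_len * p_hat * (1.0 - p_hat))
        hit_genes = occ_v >= 1
        k = int(hit_genes[mod_mask].sum())
        total_hit = int(hit_genes.sum())
        p_fisher = _fisher_tail(k, n_mod, total_hit, n_mod + n_rest)
        fisher_score = -math.log(max(p_fisher, 1e-300))
        rows.append((tf, x, z, p_fisher, fisher_score))
    out = pd.DataFrame(rows, columns=["tf", "module_occurrences", "z", "fisher_p", "fisher_score"])
    for col, flagcol in (("z", "_z_ok"), ("fisher_score", "_f_ok")):
        vals = out[col].to_numpy()
        mu, sd = float(vals.mean()), float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        if sd == 0 or not np.isfinite(sd):
            logger.warning("tfbs_enrichment: degenerate %s distribution; threshold = mean", col)
            thr = mu
        else:
            thr = mu + sd_multiplier * sd
        out[flagcol] = vals >= thr
    out["enriched"] = out.pop("_z_ok") & out.pop("_f_ok")
    return out.sort_values("z", ascending=False, kind="stable").reset_index(drop=True)
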