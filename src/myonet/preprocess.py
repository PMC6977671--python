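"""Count-matrix preprocessing: low-expression filtering, RPKM, log transform,
and iterative inter-sample-correlation (ISC) outlier removal.

The pipeline input is a gene x sample read-count matrix (``pandas.DataFrame``
with gene IDs as index, sample IDs as columns) plus a per-gene length table in
base pairs. Output is a log2(RPKM + 1) expression matrix cleaned of outlier
samples, the common currency of every downstream stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "OutlierReport",
    "filter_low_expression",
    "rpkm_normalize",
    "log_transform",
    "remove_outlier_samples",
    "preprocess_counts",
]


@dataclass
class OutlierReport:
    """Record of iterative ISC-based sample exclusion.

    ``mean_isc_per_sample`` holds each original sample's mean Pearson
    correlation with all other samples at the first iteration.
    ``thresholds`` lists the exclusion cutoff (mean ISC - multiplier * SD)
    applied at each removal round, in order.
    """

    removed_sample_ids: list[str] = field(default_factory=list)
    mean_isc_per_sample: pd.Series | None = None
    thresholds: list[float] = field(default_factory=list)
    iterations: int = 0
    degenerate: bool = False

    def to_frame(self) -> pd.DataFrame:
        isc = self.mean_isc_per_sample
        out = pd.DataFrame({"mean_isc": isc if isc is not None else []})
        out.index.name = "sample_id"
        out["removed"] = out.index.isin(self.removed_sample_ids)
        return out


def _check_count_matrix(counts: pd.DataFrame) -> None:
    if counts.empty:
        raise ValueError("count matrix is empty")
    if counts.index.duplicated().any():
        dup = counts.index[counts.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene IDs: {dup}")
    if counts.columns.duplicated().any():
        dup = counts.columns[counts.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample IDs: {dup}")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")


def filter_low_expression(
    counts: pd.DataFrame, min_count: int = 10, min_fraction: float = 0.8
) -> pd.DataFrame:
    """Drop genes with consistently low read counts.

    A gene is removed iff the fraction of samples in which its count is
    strictly below ``min_count`` is at least ``min_fraction`` (default: count
    < 10 in at least 80% of samples). Sample set and gene order are preserved.
    """
    _check_count_matrix(counts)
    if not 0 < min_fraction <= 1:
        raise ValueError(f"min_fraction must be in (0, 1], got {min_fraction}")
    frac_low = (counts.to_numpy() < min_count).mean(axis=1)
    keep = frac_low < min_fraction
    out = counts.loc[keep]
    logger.info(
        "filter_low_expression: %d/%d genes retained (min_count=%d, min_fraction=%g)",
        keep.sum(), len(counts), min_count, min_fraction,
    )
    return out


def rpkm_normalize(
    counts: pd.DataFrame,
    gene_lengths: pd.Series,
    library_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """Reads per kilobase per million mapped reads.

    RPKM_gs = 1e9 * count_gs / (length_g * libsize_s). By default the library
    size of a sample is the column sum of the (already filtered) counts;
    externally determined mapped-read totals can be supplied instead.
    """
    _check_count_matrix(counts)
    missing = counts.index.difference(gene_lengths.index)
    if len(missing):
        raise ValueError(f"genes without a length: {missing.tolist()[:10]}")
    lengths = gene_lengths.reindex(counts.index).astype(float)
    if (lengths <= 0).any():
        bad = lengths.index[lengths <= 0].tolist()
        raise ValueError(f"non-positive gene lengths: {bad[:10]}")
    if library_sizes is None:
        libsize = counts.sum(axis=0).astype(float)
    else:
        libsize = library_sizes.reindex(counts.columns).astype(float)
        if libsize.isna().any():
            raise ValueError("library_sizes missing for some samples")
    zero = libsize.index[libsize == 0].tolist()
    if zero:
        raise ValueError(f"zero library size for sample(s): {zero}")
    rpkm = 1e9 * counts.to_numpy(dtype=float) / np.outer(lengths.to_numpy(), libsize.to_numpy())
    return pd.DataFrame(rpkm, index=counts.index, columns=counts.columns)


def log_transform(rpkm: pd.DataFrame) -> pd.DataFrame:
    """log2(RPKM + 1); maps 0 to 0 and is monotone."""
    vals = rpkm.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("negative values passed to log_transform")
    return pd.DataFrame(np.log2(vals + 1.0), index=rpkm.index, columns=rpkm.columns)


def _mean_isc(values: np.ndarray) -> np.ndarray:
    # values: genes x samples; ISC_i = mean Pearson corr of sample i with others
    c = np.corrcoef(values.T)
    n = c.shape[0]
    return (c.sum(axis=1) - 1.0) / (n - 1)


def remove_outlier_samples(
    expr: pd.DataFrame, sd_multiplier: float = 2.5
) -> tuple[pd.DataFrame, OutlierReport]:
    """Iteratively drop samples whose mean inter-sample correlation falls more
    than ``sd_multiplier`` standard deviations below the dataset mean ISC.

    ISC is recomputed after each removal round until no sample fails. Ties at
    the threshold are retained (strict <). At least 3 samples are always kept.
    """
    if expr.shape[1] < 4:
        raise ValueError("outlier removal requires at least 4 samples")
    report = OutlierReport()
    kept = expr
    while True:
        isc = _mean_isc(kept.to_numpy(dtype=float))
        isc_s = pd.Series(isc, index=kept.columns)
        if report.mean_isc_per_sample is None:
            report.mean_isc_per_sample = isc_s
        sd = float(np.std(isc, ddof=1))
        if sd == 0 or not np.isfinite(sd):
            report.degenerate = True
            logger.info("remove_outlier_samples: degenerate ISC dispersion, no removals")
            break
        threshold = float(np.mean(isc) - sd_multiplier * sd)
        failing = isc_s.index[isc_s < threshold]
        if len(failing) == 0:
            break
        report.iterations += 1
        report.thresholds.append(threshold)
        # never go below 3 retained samples; drop worst-ISC first
        n_removable = max(0, kept.shape[1] - 3)
        failing = list(isc_s.loc[failing].sort_values().index[:n_removable])
        if not failing:
            break
        report.removed_sample_ids.extend(failing)
        logger.info(
            "remove_outlier_samples: round %d removed %s (threshold %.4f)",
            report.iterations, failing, threshold,
        )
        kept = kept.drop(columns=failing)
    return kept, report


def preprocess_counts(
    counts: pd.DataFrame,
    gene_lengths: pd.Series,
    min_count: int = 10,
    min_fraction: float = 0.8,
    sd_multiplier: float = 2.5,
    library_sizes: pd.Series | None = None,
) -> tuple[pd.DataFrame, OutlierReport]:
    """Full preprocessing chain: filter, RPKM, log2(x+1), outlier removal."""
    filtered = filter_low_expression(counts, min_count=min_count, min_fraction=min_fraction)
    expr = log_transform(rpkm_normalize(filtered, gene_lengths, library_sizes=library_sizes))
    return remove_outlier_samples(expr, sd_multiplier=sd_multiplier)
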