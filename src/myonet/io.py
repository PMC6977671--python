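"""File formats, configuration and the run manifest.

Everything tabular is TSV with explicit headers; gene sets are GMT
(term <TAB> description <TAB> gene...). Gene and sample identifiers are
opaque strings; cross-file ID consistency is validated at load time.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .enrich import AnnotationSet

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "read_counts",
    "read_gene_lengths",
    "read_design",
    "read_traits",
    "read_gmt",
    "write_gmt",
    "read_tfbs_hits",
    "read_region_lengths",
    "write_matrix",
    "read_matrix",
    "validate_inputs",
]


@dataclass
class PipelineConfig:
    """All stage parameters, defaulting to the published analysis choices."""

    min_count: int = 10
    min_fraction: float = 0.8
    isc_sd_multiplier: float = 2.5
    beta: int | None = None
    beta_candidates: tuple[int, int] = (1, 30)
    r2_threshold: float = 0.85
    n_bins: int = 10
    deep_split: int = 2
    min_cluster_size: int = 15
    merge_cut: float = 0.9
    hub_threshold: float = 0.7
    alpha: float = 0.05
    r_min: float = 0.5
    tfbs_sd_multiplier: float = 1.5
    representative_max_size: int = 500
    enrich_method: str = "ease"
    seed: int = 0

    def validate(self) -> None:
        checks = [
            (self.min_count >= 0, "min_count must be >= 0"),
            (0 < self.min_fraction <= 1, "min_fraction must be in (0, 1]"),
            (self.isc_sd_multiplier > 0, "isc_sd_multiplier must be > 0"),
            (self.beta is None or self.beta >= 1, "beta must be >= 1"),
            (1 <= self.beta_candidates[0] <= self.beta_candidates[1], "bad beta candidate range"),
            (0 < self.r2_threshold <= 1, "r2_threshold must be in (0, 1]"),
            (self.n_bins >= 2, "n_bins must be >= 2"),
            (self.deep_split in range(5), "deep_split must be in 0..4"),
            (self.min_cluster_size >= 2, "min_cluster_size must be >= 2"),
            (0 < self.merge_cut <= 1, "merge_cut must be in (0, 1]"),
            (0 < self.hub_threshold <= 1, "hub_threshold must be in (0, 1]"),
            (0 < self.alpha < 1, "alpha must be in (0, 1)"),
            (0 <= self.r_min < 1, "r_min must be in [0, 1)"),
            (self.tfbs_sd_multiplier > 0, "tfbs_sd_multiplier must be > 0"),
            (self.representative_max_size >= 1, "representative_max_size must be >= 1"),
            (self.enrich_method in ("ease", "fisher"), "enrich_method must be ease|fisher"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(msg)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys in {path}: {sorted(unknown)}")
        if "beta_candidates" in raw:
            raw["beta_candidates"] = tuple(raw["beta_candidates"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    input_checksums: dict[str, str] = field(default_factory=dict)
    stage_counts: dict[str, dict] = field(default_factory=dict)
    stages_completed: list[str] = field(default_factory=list)
    started: float = field(default_factory=time.time)

    def record(self, stage: str, **counts) -> None:
        self.stages_completed.append(stage)
        self.stage_counts[stage] = counts

    def write(self, path: str | Path) -> None:
        payload = {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "input_checksums": self.input_checksums,
            "stages_completed": self.stages_completed,
            "stage_counts": self.stage_counts,
            "started": self.started,
            "finished": time.time(),
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def file_checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def read_matrix(path: str | Path, index_name: str = "gene_id") -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = index_name
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate row IDs {dup[:5]}")
    if df.columns.duplicated().any():
        raise ValueError(f"{path}: duplicate column IDs")
    return df


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t")


def read_counts(path: str | Path) -> pd.DataFrame:
    counts = read_matrix(path)
    if (counts.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative counts")
    return counts


def read_gene_lengths(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (gene_id, length_bp)")
    s = df.set_index(df.columns[0])[df.columns[1]]
    if s.index.duplicated().any():
        raise ValueError(f"{path}: duplicate gene IDs")
    return s


def read_design(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    need = {"subject", "age_group", "condition"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing design columns {sorted(missing)}")
    return df


def read_traits(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_gmt(path: str | Path, category: str = "custom") -> AnnotationSet:
    """Parse a GMT file (term, description, genes...); malformed lines raise
    errors naming the file and line number."""
    terms, names, categories = {}, {}, {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has {len(fields)} fields (need >= 3)")
            term, desc, *genes = fields
            if term in terms:
                raise ValueError(f"{path}:{lineno}: duplicate term '{term}'")
            terms[term] = set(g for g in genes if g)
            names[term] = desc
            categories[term] = category
    return AnnotationSet(terms, names, categories)


def write_gmt(annotation: AnnotationSet, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for term in sorted(annotation.terms):
            genes = sorted(annotation.terms[term])
            desc = annotation.names.get(term, "")
            fh.write("\t".join([term, desc, *genes]) + "\n")


def read_tfbs_hits(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"tf_id", "gene_id", "occurrences"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing TFBS columns {sorted(missing)}")
    if (df["occurrences"] < 0).any():
        raise ValueError(f"{path}: negative occurrence counts")
    return df


def read_region_lengths(path: str | Path) -> pd.Series:
    s = read_gene_lengths(path)
    if (s <= 0).any():
        raise ValueError(f"{path}: region lengths must be positive")
    return s


def validate_inputs(
    counts: pd.DataFrame,
    gene_lengths: pd.Series,
    design: pd.DataFrame | None = None,
    traits: pd.DataFrame | None = None,
) -> None:
    """Cross-file consistency: every gene has a length; design samples are
    matrix columns; trait subjects appear in the design."""
    missing = counts.index.difference(gene_lengths.index)
    if len(missing):
        raise ValueError(f"genes without lengths: {missing.tolist()[:5]}")
    if design is not None:
        extra = design.index.difference(counts.columns)
        if len(extra):
            raise ValueError(f"design samples absent from the matrix: {extra.tolist()[:5]}")
        if traits is not None:
            unknown = traits.index.difference(design["subject"].unique())
            if len(unknown):
                raise ValueError(f"trait subjects absent from the design: {unknown.tolist()[:5]}")
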