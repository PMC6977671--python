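"""Stage-wise pipeline orchestration over serialized TSV inputs/outputs.

Each stage can be run standalone from the previous stage's files; ``run_all``
chains preprocess -> network -> modules -> diff -> trait -> hubs -> enrich
and emits a run manifest. All outputs are deterministic given inputs and the
configured seed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import diffexpr, enrich, hubs, modules_detect, network, preprocess, trait
from .io import (
    PipelineConfig,
    RunManifest,
    file_checksum,
    read_counts,
    read_design,
    read_gene_lengths,
    read_gmt,
    read_matrix,
    read_region_lengths,
    read_tfbs_hits,
    read_traits,
    validate_inputs,
    write_matrix,
)

logger = logging.getLogger(__name__)

STAGES = ("preprocess", "network", "modules", "diff", "trait", "hubs", "enrich")


def _eig_index_to_str(values: pd.DataFrame) -> pd.DataFrame:
    out = values.copy()
    out.index = [f"M{m}" for m in out.index]
    out.index.name = "module"
    return out


def _eig_index_to_int(values: pd.DataFrame) -> pd.DataFrame:
    out = values.copy()
    out.index = [int(str(m).lstrip("M")) for m in out.index]
    out.index.name = "module"
    return out


def stage_preprocess(indir: Path, outdir: Path, config: PipelineConfig) -> dict:
    counts = read_counts(indir / "counts.tsv")
    lengths = read_gene_lengths(indir / "gene_lengths.tsv")
    validate_inputs(counts, lengths)
    expr, report = preprocess.preprocess_counts(
        counts, lengths,
        min_count=config.min_count, min_fraction=config.min_fraction,
        sd_multiplier=config.isc_sd_multiplier,
    )
    write_matrix(expr, outdir / "expression.tsv")
    write_matrix(report.to_frame(), outdir / "outliers.tsv")
    return {"genes": expr.shape[0], "samples": expr.shape[1],
            "outliers_removed": len(report.removed_sample_ids)}


def stage_network(outdir: Path, config: PipelineConfig) -> tuple[network.CoexpressionNetwork, pd.DataFrame, dict]:
    expr = read_matrix(outdir / "expression.tsv")
    lo, hi = config.beta_candidates
    net = network.build_network(
        expr, beta=config.beta, candidates=range(lo, hi + 1),
        r2_threshold=config.r2_threshold, n_bins=config.n_bins,
    )
    if net.fit is not None:
        write_matrix(net.fit.to_frame().set_index("beta"), outdir / "scale_free_fit.tsv")
        params = {"beta": net.beta, "r2_signed": float(net.fit.r2_signed[net.fit.beta_candidates.index(net.beta)]),
                  "met_threshold": net.fit.met_threshold}
    else:
        params = {"beta": net.beta, "r2_signed": None, "met_threshold": None}
    (outdir / "network_params.json").write_text(json.dumps(params, indent=2) + "\n")
    return net, expr, {"genes": len(net.gene_ids), "beta": net.beta}


def stage_modules(outdir: Path, config: PipelineConfig,
                  net: network.CoexpressionNetwork | None = None,
                  expr: pd.DataFrame | None = None) -> dict:
    if net is None or expr is None:
        expr = read_matrix(outdir / "expression.tsv")
        params = json.loads((outdir / "network_params.json").read_text())
        net = network.build_network(expr, beta=params["beta"])
    det = modules_detect.detect_modules(
        expr, net.disstom,
        deep_split=config.deep_split, min_cluster_size=config.min_cluster_size,
        merge_cut=config.merge_cut,
    )
    assign = det.labels.to_frame()
    assign.index.name = "gene_id"
    write_matrix(assign, outdir / "module_assignment.tsv")
    write_matrix(_eig_index_to_str(det.eigengenes.values), outdir / "eigengenes.tsv")
    n_mod = int((det.labels.unique() != 0).sum())
    return {"modules": n_mod, "unassigned": int((det.labels == 0).sum())}


def _load_labels_eigengenes(outdir: Path) -> tuple[pd.Series, pd.DataFrame]:
    labels = read_matrix(outdir / "module_assignment.tsv")["module"].astype(int)
    eig = _eig_index_to_int(read_matrix(outdir / "eigengenes.tsv", index_name="module"))
    return labels, eig


def stage_diff(indir: Path, outdir: Path, config: PipelineConfig) -> dict:
    design = read_design(indir / "design.tsv")
    _, eig = _load_labels_eigengenes(outdir)
    design = design.loc[design.index.intersection(eig.columns)]
    results, block = diffexpr.differential_analysis(eig[design.index], design, alpha=config.alpha)
    results.to_csv(outdir / "diff_results.tsv", sep="\t", index=False)
    return {"tests": len(results), "significant": int(results["significant"].sum()),
            "consensus_rho": round(block.consensus_rho, 4)}


def responsive_modules(diff_results: pd.DataFrame) -> dict[int, set[str]]:
    """Contraction-responsive modules and their modes: modules with a
    BH-significant post-vs-baseline contrast, mapped to the mode(s)
    involved."""
    out: dict[int, set[str]] = {}
    sig = diff_results[diff_results["significant"]]
    for _, row in sig.iterrows():
        name = str(row["contrast"])  # e.g. 'young:ECC-vs-young:BL'
        try:
            lhs, rhs = name.split("-vs-")
            cond_l = lhs.split(":", 1)[1]
            cond_r = rhs.split(":", 1)[1]
        except (ValueError, IndexError):
            continue
        conds = {cond_l, cond_r}
        if "BL" in conds:
            mode = (conds - {"BL"}).pop()
            if mode in ("ECC", "CON"):
                out.setdefault(int(row["module"]), set()).add(mode)
    return out


def stage_trait(indir: Path, outdir: Path, config: PipelineConfig) -> dict:
    design = read_design(indir / "design.tsv")
    traits = read_traits(indir / "traits.tsv")
    _, eig = _load_labels_eigengenes(outdir)
    design = design.loc[design.index.intersection(eig.columns)]
    validate_inputs(eig, pd.Series(1, index=eig.index), design=None)
    diff_path = outdir / "diff_results.tsv"
    responsive = None
    if diff_path.exists():
        responsive = responsive_modules(pd.read_csv(diff_path, sep="\t"))
    assocs = trait.classify_module_trait(
        eig[design.index], traits, design, responsive=responsive,
        alpha=config.alpha, r_min=config.r_min,
    )
    rows = [
        (a.module, a.scheme, a.group or "", a.measure or "", a.r, a.p, a.n, a.significant)
        for a in assocs
    ]
    df = pd.DataFrame(rows, columns=["module", "scheme", "group", "measure", "r", "p", "n", "significant"])
    df.to_csv(outdir / "trait_associations.tsv", sep="\t", index=False)
    return {"associations": len(df), "significant": int(df["significant"].sum())}


def stage_hubs(indir: Path, outdir: Path, config: PipelineConfig,
               net: network.CoexpressionNetwork | None = None,
               expr: pd.DataFrame | None = None) -> dict:
    if net is None or expr is None:
        expr = read_matrix(outdir / "expression.tsv")
        params = json.loads((outdir / "network_params.json").read_text())
        net = network.build_network(expr, beta=params["beta"])
    labels, _ = _load_labels_eigengenes(outdir)
    design = read_design(indir / "design.tsv")
    traits = read_traits(indir / "traits.tsv")
    design = design.loc[design.index.intersection(expr.columns)]
    kim = hubs.intramodular_connectivity(net.adjacency, labels)
    table = hubs.scale_and_flag_hubs(kim, labels, threshold=config.hub_threshold)
    # gene significance to baseline MVC (age as covariate), mirroring the
    # age-independent module-level scheme
    bl = design.index[design["condition"] == "BL"]
    mvc = trait.baseline_mvc(traits).reindex(design.loc[bl, "subject"]).to_numpy(float)
    age = (design.loc[bl, "age_group"] == "older").to_numpy(float)
    gs = hubs.gene_significance(expr.loc[table.index, bl], pd.Series(mvc), "partial", covariate=age)
    table = hubs.prioritize_hubs(table, gs)
    table.index.name = "gene_id"
    write_matrix(table, outdir / "hub_table.tsv")
    return {"module_genes": len(table), "hubs": int(table["is_hub"].sum()),
            "prioritized": int(table["prioritized"].sum())}


def stage_enrich(indir: Path, outdir: Path, config: PipelineConfig) -> dict:
    labels, _ = _load_labels_eigengenes(outdir)
    annotation = read_gmt(indir / "annotation.gmt", category="BP")
    hits = read_tfbs_hits(indir / "tfbs_hits.tsv")
    region_lengths = read_region_lengths(indir / "tfbs_region_lengths.tsv")
    hub_table = read_matrix(outdir / "hub_table.tsv")
    background = [str(g) for g in labels.index]
    ann_frames, tf_frames = [], []
    for mod in sorted(int(m) for m in labels.unique() if m != 0):
        genes = [str(g) for g in labels.index[labels == mod]]
        res = enrich.overrepresentation(genes, background, annotation,
                                        method=config.enrich_method, alpha=config.alpha)
        res.insert(0, "module", mod)
        ann_frames.append(res)
        kim = hub_table.loc[hub_table["module"] == mod, "kIM"]
        rep = enrich.representative_gene_set(genes, kim, max_size=config.representative_max_size)
        tf = enrich.tfbs_enrichment(rep, background, hits, region_lengths,
                                    sd_multiplier=config.tfbs_sd_multiplier)
        tf.insert(0, "module", mod)
        tf_frames.append(tf)
    pd.concat(ann_frames).to_csv(outdir / "annotation_enrichment.tsv", sep="\t", index=False)
    pd.concat(tf_frames).to_csv(outdir / "tfbs_enrichment.tsv", sep="\t", index=False)
    n_terms = int(sum(f["enriched"].sum() for f in ann_frames))
    n_tfs = int(sum(f["enriched"].sum() for f in tf_frames))
    return {"enriched_terms": n_terms, "enriched_tfs": n_tfs}


def run_all(indir: str | Path, outdir: str | Path, config: PipelineConfig | None = None,
            stop_after: str | None = None) -> RunManifest:
    """Execute the full pipeline; stage failure halts with the stage named."""
    indir, outdir = Path(indir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = config or PipelineConfig()
    config.validate()
    if stop_after is not None and stop_after not in STAGES:
        raise ValueError(f"unknown stage '{stop_after}'")
    manifest = RunManifest(config_hash=config.config_hash(), seed=config.seed)
    for name in ("counts.tsv", "gene_lengths.tsv", "design.tsv", "traits.tsv",
                 "annotation.gmt", "tfbs_hits.tsv", "tfbs_region_lengths.tsv"):
        p = indir / name
        if p.exists():
            manifest.input_checksums[name] = file_checksum(p)
    net = expr = None
    try:
        for stage in STAGES:
            try:
                if stage == "preprocess":
                    manifest.record(stage, **stage_preprocess(indir, outdir, config))
                elif stage == "network":
                    net, expr, info = stage_network(outdir, config)
                    manifest.record(stage, **info)
                elif stage == "modules":
                    manifest.record(stage, **stage_modules(outdir, config, net, expr))
                elif stage == "diff":
                    manifest.record(stage, **stage_diff(indir, outdir, config))
                elif stage == "trait":
                    manifest.record(stage, **stage_trait(indir, outdir, config))
                elif stage == "hubs":
                    manifest.record(stage, **stage_hubs(indir, outdir, config, net, expr))
                elif stage == "enrich":
                    manifest.record(stage, **stage_enrich(indir, outdir, config))
            except Exception as exc:
                raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc
            logger.info("stage %s done: %s", stage, manifest.stage_counts[stage])
            if stage == stop_after:
                break
    finally:
        manifest.write(outdir / "manifest.json")
    return manifest


def write_simulated_inputs(dataset, indir: str | Path) -> None:
    """Serialize a synthetic dataset in the formats the pipeline reads."""
    from .io import write_gmt
    indir = Path(indir)
    indir.mkdir(parents=True, exist_ok=True)
    if dataset.counts is not None:
        counts = dataset.counts.copy()
        counts.index.name = "gene_id"
        write_matrix(counts, indir / "counts.tsv")
    expr = dataset.expr.copy()
    expr.index.name = "gene_id"
    write_matrix(expr, indir / "expression.tsv")
    lengths = dataset.gene_lengths.to_frame()
    lengths.index.name = "gene_id"
    write_matrix(lengths, indir / "gene_lengths.tsv")
    design = dataset.design.copy()
    design.index.name = "sample_id"
    write_matrix(design, indir / "design.tsv")
    write_matrix(dataset.traits, indir / "traits.tsv")
    write_gmt(dataset.annotation, indir / "annotation.gmt")
    dataset.tfbs_hits.to_csv(indir / "tfbs_hits.tsv", sep="\t", index=False)
    rl = dataset.tfbs_lengths.to_frame()
    rl.index.name = "gene_id"
    write_matrix(rl, indir / "tfbs_region_lengths.tsv")
    truth = dataset.truth.labels.to_frame()
    truth.index.name = "gene_id"
    write_matrix(truth, indir / "truth_modules.tsv")
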