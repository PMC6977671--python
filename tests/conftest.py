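"""Shared fixtures: synthetic datasets and cached multi-seed pipeline runs."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest

import myonet
from myonet.hubs import intramodular_connectivity, scale_and_flag_hubs

RECOVERY_SEEDS = tuple(range(10))


@dataclass
class PipelineRun:
    seed: int
    dataset: myonet.SyntheticDataset
    beta: int
    r2_at_beta: float
    met_threshold: bool
    labels: pd.Series
    eigengenes: pd.DataFrame
    recovery: myonet.RecoveryMetrics
    hub_table: pd.DataFrame


def _run_seed(seed: int) -> PipelineRun:
    ds = myonet.generate_dataset(seed=seed)
    net = myonet.build_network(ds.expr)
    det = myonet.detect_modules(ds.expr, net.disstom)
    rec = myonet.evaluate_recovery(ds.truth, det.labels, det.eigengenes.values)
    kim = intramodular_connectivity(net.adjacency, det.labels)
    hub_table = scale_and_flag_hubs(kim, det.labels)
    idx = net.fit.beta_candidates.index(net.beta)
    return PipelineRun(
        seed=seed,
        dataset=ds,
        beta=net.beta,
        r2_at_beta=float(net.fit.r2_signed[idx]),
        met_threshold=net.fit.met_threshold,
        labels=det.labels,
        eigengenes=det.eigengenes.values,
        recovery=rec,
        hub_table=hub_table,
    )


@pytest.fixture(scope="session")
def pipeline_runs() -> list[PipelineRun]:
    """Full network + module-detection pipeline on the default generator for
    ten fixed seeds; reused by the recovery, hub, enrichment and determinism
    checks."""
    return [_run_seed(s) for s in RECOVERY_SEEDS]


@pytest.fixture(scope="session")
def default_dataset() -> myonet.SyntheticDataset:
    return myonet.generate_dataset(seed=1)


@pytest.fixture(scope="session")
def small_dataset() -> myonet.SyntheticDataset:
    """Reduced dataset for fast I/O and CLI round trips."""
    cfg = myonet.SimulationConfig(
        n_subjects_per_group=4,
        module_sizes=(30, 20),
        n_background=50,
        n_decoy_terms=5,
        n_null_tfs=5,
        counts=True,
        effects={1: {("older", None): 1.2}, 2: {(None, "ECC"): 1.5}},
        trait_couplings={
            "baseline_common": {"module": 1, "slope": 18.0},
            "decline_ecc": {"module": 2, "slope": 6.0},
        },
    )
    return myonet.generate_dataset(cfg, seed=7)


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)


def random_adjacency(n: int, generator: np.random.Generator) -> np.ndarray:
    """Random valid signed-adjacency-like matrix: symmetric, [0,1], unit diag."""
    corr = generator.uniform(-1, 1, (n, n))
    corr = (corr + corr.T) / 2
    np.fill_diagonal(corr, 1.0)
    return (0.5 * (1 + corr)) ** int(generator.integers(1, 8))
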