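"""Shared fixtures and independent oracle implementations.

The oracles here deliberately re-derive quantities by exhaustive or naive
means (full running-sum enumeration, quadratic step-up scan) so the tests
check the package against something that shares none of its code paths.
"""

from __future__ import annotations

import numpy as np
import pytest

from geroscreen import (
    GeneSpace,
    PertType,
    Perturbagen,
    SignatureSet,
    SimulationParams,
    simulate_signature_universe,
)


def brute_force_es(z_ranked: np.ndarray, hits: np.ndarray, weighted: bool) -> float:
    """Tabulate all N partial sums of the KS walk and take the extremum.

    ``z_ranked`` are z-scores in ranked order, ``hits`` a boolean mask of
    query genes in that order.
    """
    z_ranked = np.asarray(z_ranked, dtype=float)
    hits = np.asarray(hits, dtype=bool)
    n, k = hits.size, int(hits.sum())
    if weighted:
        w = np.abs(z_ranked) * hits
        if w.sum() == 0.0:
            return 0.0
        inc = w / w.sum()
    else:
        inc = hits / k
    walk = np.cumsum(inc - (~hits) / (n - k))
    hi, lo = walk.max(), walk.min()
    # same positive-preferring tie rule as the package, to 1e-12
    return float(hi) if abs(hi) >= abs(lo) - 1e-12 else float(lo)


def hand_step_up(pvals) -> list[float]:
    """Quadratic, formula-literal BH: adj_i = min_{j>=i} p_(j) * m / j."""
    p = list(map(float, pvals))
    m = len(p)
    order = sorted(range(m), key=lambda i: (p[i], i))
    adj = [0.0] * m
    for pos, i in enumerate(order):
        adj[i] = min(
            min(p[order[j]] * m / (j + 1) for j in range(pos, m)), 1.0
        )
    return adj


@pytest.fixture
def brute_es():
    return brute_force_es


@pytest.fixture
def bh_oracle():
    return hand_step_up


def make_sigset(values, gene_ids=None, pert_ids=None, cell_line="default",
                pert_types=None, target_genes=None) -> SignatureSet:
    """Assemble a small SignatureSet from a plain matrix."""
    values = np.asarray(values, dtype=float)
    n_genes, n_perts = values.shape
    gene_ids = gene_ids or [f"g{i + 1}" for i in range(n_genes)]
    pert_ids = pert_ids or [f"c{j + 1}" for j in range(n_perts)]
    pert_types = pert_types or [PertType.COMPOUND] * n_perts
    target_genes = target_genes or [None] * n_perts
    lines = [cell_line] * n_perts if isinstance(cell_line, str) else list(cell_line)
    perts = tuple(
        Perturbagen(pid, pt, cell_line=cl, target_gene=tg)
        for pid, pt, cl, tg in zip(pert_ids, pert_types, lines, target_genes)
    )
    return SignatureSet(
        gene_space=GeneSpace(tuple(gene_ids)), perturbagens=perts, values=values
    )


@pytest.fixture
def sigset_factory():
    return make_sigset


SMALL_PARAMS = SimulationParams(
    n_genes=80,
    n_background_compounds=20,
    n_interventions=3,
    cell_lines=("PC3", "MCF7"),
    query_size=5,
)


@pytest.fixture(scope="session")
def small_universe():
    """A desk-scale planted universe reused across screen tests (seed 11)."""
    return simulate_signature_universe(SMALL_PARAMS, seed=11)
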