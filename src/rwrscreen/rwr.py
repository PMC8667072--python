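"""Random walk with restart (RWR) over a weighted PPI network.

The walker starts on the seed genes (probability 1/k each), moves along
edges with probability 1 - r per step, and restarts at the seeds with
probability r:

    p_{t+1} = (1 - r) W p_t + r p_0

with W the column-stochastic transition operator.  Iteration stops at the
first iterate whose L1 change from its predecessor falls below the
tolerance; the fixed point scores every node's proximity to the seed set.
Non-seed nodes whose converged probability exceeds the candidate cutoff
become raw candidate genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ConvergenceError, ValidationError
from .network import SeedSet, TransitionOperator, WeightedNetwork

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RwrConfig:
    """Walk parameters.

    restart_probability
        Teleport probability r in (0, 1]; the default 0.8 keeps most mass
        near the seeds.
    convergence_tol
        L1 threshold on successive iterates (default 1e-6).
    max_iterations
        Iteration budget; exceeding it raises :class:`ConvergenceError`.
    candidate_cutoff
        Minimum converged probability (strict) for a non-seed node to be
        reported as a raw candidate (default 1e-5).
    """

    restart_probability: float = 0.8
    convergence_tol: float = 1e-6
    max_iterations: int = 10000
    candidate_cutoff: float = 1e-5

    def __post_init__(self):
        if not (0.0 < self.restart_probability <= 1.0):
            raise ValidationError(f"restart_probability must be in (0, 1], got {self.restart_probability}")
        if self.convergence_tol <= 0:
            raise ValidationError("convergence_tol must be > 0")
        if self.max_iterations < 1:
            raise ValidationError("max_iterations must be >= 1")
        if self.candidate_cutoff < 0:
            raise ValidationError("candidate_cutoff must be >= 0")


def make_seed_vector(network: WeightedNetwork, seeds: SeedSet) -> np.ndarray:
    """Initial distribution p_0: probability 1/k on each of the k seeds."""
    missing = [g for g in seeds if g not in network]
    if missing:
        raise ValidationError(f"seed gene(s) not in network: {', '.join(missing)}")
    p0 = np.zeros(network.n_nodes)
    idx = [network.node_index(g) for g in seeds]
    p0[idx] = 1.0 / len(idx)
    p0 /= p0.sum()  # exact unit mass regardless of rounding in 1/k
    return p0


def _iterate(matrix, p0: np.ndarray, config: RwrConfig) -> tuple[np.ndarray, int]:
    """Shared iteration core; p0 may be a vector or an (n, m) batch of columns."""
    r = config.restart_probability
    restart = r * p0
    p = p0
    for iteration in range(1, config.max_iterations + 1):
        p_next = (1.0 - r) * (matrix @ p) + restart
        change = np.abs(p_next - p).sum(axis=0)
        p = p_next
        if np.max(change) < config.convergence_tol:
            return p, iteration
    raise ConvergenceError(
        f"RWR did not converge within {config.max_iterations} iterations "
        f"(last L1 change {float(np.max(change)):.3e})",
        last_change=float(np.max(change)),
    )


def run_rwr(operator: TransitionOperator, p0: np.ndarray, config: RwrConfig | None = None) -> np.ndarray:
    """Iterate the walk to its fixed point and return the converged vector."""
    config = config or RwrConfig()
    p0 = np.asarray(p0, dtype=float)
    if p0.shape[0] != operator.n_nodes:
        raise ValidationError(
            f"probability vector length {p0.shape[0]} does not match network size {operator.n_nodes}"
        )
    p, n_iter = _iterate(operator.matrix, p0, config)
    log.debug("RWR converged in %d iterations", n_iter)
    return p


def run_rwr_batch(operator: TransitionOperator, p0_columns: np.ndarray,
                  config: RwrConfig | None = None) -> np.ndarray:
    """Run many walks at once; column j of the result is the fixed point of column j."""
    config = config or RwrConfig()
    p0_columns = np.asarray(p0_columns, dtype=float)
    if p0_columns.ndim != 2 or p0_columns.shape[0] != operator.n_nodes:
        raise ValidationError("p0_columns must be an (n_nodes, n_walks) array")
    p, _ = _iterate(operator.matrix, p0_columns, config)
    return p


def select_raw_candidates(
    probabilities: np.ndarray,
    network: WeightedNetwork,
    seeds: SeedSet,
    cutoff: float = 1e-5,
    include_seeds: bool = False,
) -> list[tuple[str, float]]:
    """Non-seed genes with probability strictly above the cutoff.

    Returned sorted by probability descending, ties broken lexicographically
    on the gene identifier.  ``include_seeds=True`` keeps seed genes in the
    list for diagnostics.
    """
    if cutoff < 0:
        raise ValidationError("cutoff must be >= 0")
    out = []
    for gene, p in zip(network.nodes, probabilities):
        if not include_seeds and gene in seeds:
            continue
        if p > cutoff:
            out.append((gene, float(p)))
    out.sort(key=lambda t: (-t[1], t[0]))
    if not out:
        log.info("no raw candidates above cutoff %g", cutoff)
    return out


def write_probability_tsv(network: WeightedNetwork, probabilities: np.ndarray, path: str | Path) -> None:
    """Export a probability vector as TSV (gene_id, probability; 10 significant digits)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\tprobability\n")
        for gene, p in zip(network.nodes, probabilities):
            fh.write(f"{gene}\t{float(p):.10g}\n")
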