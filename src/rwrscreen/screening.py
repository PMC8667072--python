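"""Three-stage screening of raw RWR candidates.

Stage 1 (permutation test): the observed probability of each candidate is
compared against the probabilities it receives when the walk is restarted
from random seed sets of the same size; the standardized difference is a
Z-score and candidates with Z > 1.96 survive.

Stage 2 (association test): a candidate's maximum association score (MAS)
is its largest edge confidence to any validated disease gene; MAS >= 900
(STRING's highest-confidence tier) survives.

Stage 3 (function test): the maximum function score (MFS, computed in
:mod:`rwrscreen.enrichment`) is thresholded at a disease-specific cutoff.

Null seed sets are drawn uniformly without replacement from all network
nodes.  A candidate's null mean and standard deviation are estimated from
the permutations in which the candidate itself was *not* drawn as a seed:
a candidate is by construction a non-seed in the observed walk, and the
restart mass r/k it receives in the few draws that do include it would
otherwise dominate the null standard deviation and swamp any real signal.
The unconditional statistics remain available via
``exclude_candidate_draws=False``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import ValidationError
from .network import SeedSet, TransitionOperator, WeightedNetwork
from .rwr import RwrConfig, run_rwr_batch

log = logging.getLogger(__name__)

STAGES = ("rwr", "permutation", "association", "function")


def z_score(observed: float, null_mean: float, null_std: float) -> float:
    """Standardized deviation (observed - mean) / std.

    Degenerate null_std = 0: +inf when observed exceeds the mean, -inf when
    below, 0.0 when equal (logged).
    """
    if null_std < 0:
        raise ValidationError("null_std must be >= 0")
    if null_std == 0:
        log.warning("degenerate null (std = 0) for observed=%g mean=%g", observed, null_mean)
        if observed > null_mean:
            return math.inf
        if observed < null_mean:
            return -math.inf
        return 0.0
    return (observed - null_mean) / null_std


@dataclass(frozen=True)
class PermutationResult:
    gene: str
    observed_probability: float
    null_mean: float
    null_std: float
    z_score: float
    n_permutations: int


def draw_null_seed_indices(n_nodes: int, k: int, n_draws: int, rng_seed: int) -> np.ndarray:
    """(n_draws, k) node indices, each row uniform without replacement.

    Row i is generated from an independent stream keyed by (rng_seed, i),
    so any permutation is reproducible in isolation.
    """
    if k > n_nodes:
        raise ValidationError(f"cannot draw {k} seeds from {n_nodes} nodes")
    out = np.empty((n_draws, k), dtype=np.int64)
    for i in range(n_draws):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=rng_seed, spawn_key=(i,)))
        out[i] = rng.choice(n_nodes, size=k, replace=False)
    return out


def null_probability_matrix(
    operator: TransitionOperator,
    seed_indices: np.ndarray,
    config: RwrConfig | None = None,
    chunk: int = 256,
) -> np.ndarray:
    """Converged RWR probabilities for each null seed set.

    Returns an (n_nodes, n_draws) matrix; column i is the fixed point of
    the walk restarted from row i of ``seed_indices``.  Walks are solved in
    batches for speed; results equal one-at-a-time runs.
    """
    config = config or RwrConfig()
    n_draws, k = seed_indices.shape
    n = operator.n_nodes
    probs = np.empty((n, n_draws))
    for start in range(0, n_draws, chunk):
        stop = min(start + chunk, n_draws)
        p0 = np.zeros((n, stop - start))
        for j, row in enumerate(seed_indices[start:stop]):
            p0[row, j] = 1.0 / k
            p0[:, j] /= p0[:, j].sum()
        probs[:, start:stop] = run_rwr_batch(operator, p0, config)
    return probs


def permutation_test(
    operator: TransitionOperator,
    network: WeightedNetwork,
    seeds: SeedSet,
    candidates: Sequence[tuple[str, float]],
    n_permutations: int = 1000,
    rng_seed: int = 0,
    config: RwrConfig | None = None,
    exclude_candidate_draws: bool = True,
    ddof: int = 0,
) -> list[PermutationResult]:
    """Permutation null and Z-score for every raw candidate.

    ``ddof=0`` (population standard deviation) is the default; with 1,000
    permutations the sample/population difference is negligible.
    """
    if n_permutations < 2:
        raise ValidationError("n_permutations must be >= 2 to estimate a standard deviation")
    if len(seeds) > network.n_nodes:
        raise ValidationError("more seeds than network nodes")
    seed_indices = draw_null_seed_indices(network.n_nodes, len(seeds), n_permutations, rng_seed)
    probs = null_probability_matrix(operator, seed_indices, config)
    member = np.zeros((network.n_nodes, n_permutations), dtype=bool)
    for i, row in enumerate(seed_indices):
        member[row, i] = True

    results = []
    for gene, observed in candidates:
        idx = network.node_index(gene)
        values = probs[idx]
        if exclude_candidate_draws:
            keep = ~member[idx]
            if keep.sum() < 2:
                log.warning("%s seeded in nearly every permutation; using unconditional null", gene)
                keep = np.ones(n_permutations, dtype=bool)
            values = values[keep]
        mean = float(values.mean())
        std = float(values.std(ddof=ddof))
        results.append(
            PermutationResult(
                gene=gene,
                observed_probability=float(observed),
                null_mean=mean,
                null_std=std,
                z_score=z_score(float(observed), mean, std),
                n_permutations=int(values.size),
            )
        )
    return results


def null_z_exceedance(
    operator: TransitionOperator,
    k: int,
    n_null: int = 1000,
    n_draws: int = 2000,
    rng_seed: int = 0,
    z_cutoff: float = 1.96,
    config: RwrConfig | None = None,
    exclude_candidate_draws: bool = True,
) -> float:
    """Empirical type-I rate of the Z filter under a null-on-null design.

    Estimates each gene's null from ``n_null`` random seed sets, then draws
    ``n_draws`` further random seed sets; for each draw, every gene that is
    not itself a seed of that draw plays the role of a candidate and its
    Z-score is computed exactly as :func:`permutation_test` would.  Returns
    the fraction of (gene, draw) pairs with Z above ``z_cutoff``.

    On sparse networks the per-gene null is right-skewed (a random seed
    landing on or next to a gene inflates it), so the returned rate
    typically exceeds the nominal normal tail probability.
    """
    n = operator.n_nodes
    base_idx = draw_null_seed_indices(n, k, n_null, rng_seed)
    draw_idx = draw_null_seed_indices(n, k, n_draws, rng_seed + 1)
    base = null_probability_matrix(operator, base_idx, config)
    draws = null_probability_matrix(operator, draw_idx, config)
    base_member = np.zeros((n, n_null), dtype=bool)
    for i, row in enumerate(base_idx):
        base_member[row, i] = True
    draw_member = np.zeros((n, n_draws), dtype=bool)
    for i, row in enumerate(draw_idx):
        draw_member[row, i] = True

    exceed = 0
    total = 0
    for g in range(n):
        values = base[g][~base_member[g]] if exclude_candidate_draws else base[g]
        std = values.std()
        if std == 0:
            continue
        mean = values.mean()
        observed = draws[g][~draw_member[g]]
        exceed += int(((observed - mean) / std > z_cutoff).sum())
        total += observed.size
    if total == 0:
        raise ValidationError("no usable (gene, draw) pairs in calibration experiment")
    return exceed / total


def max_association_score(network: WeightedNetwork, candidate: str, validated: SeedSet | Iterable[str]) -> int:
    """Largest edge confidence from the candidate to any validated gene (0 if none)."""
    network.node_index(candidate)
    return max((network.confidence(candidate, g) for g in validated if g in network), default=0)


@dataclass(frozen=True)
class ScreeningThresholds:
    """Stage cutoffs: Z strictly greater; MAS and MFS inclusive (>=)."""

    z_cutoff: float = 1.96
    mas_cutoff: int = 900
    mfs_cutoff: float = 0.9

    def __post_init__(self):
        if not (1 <= self.mas_cutoff <= 999):
            raise ValidationError(f"mas_cutoff must be in [1, 999], got {self.mas_cutoff}")
        if not (0.0 <= self.mfs_cutoff <= 1.0):
            raise ValidationError(f"mfs_cutoff must be in [0, 1], got {self.mfs_cutoff}")


@dataclass
class CandidateRecord:
    """One candidate gene's scores across the cascade (table row schema)."""

    gene: str
    probability: float
    z_score: float | None = None
    mas: int | None = None
    mfs: float | None = None
    stage_passed: str = "rwr"


@dataclass(frozen=True)
class StageCounts:
    """Surviving-gene counts after each filtration step."""

    rwr: int
    permutation: int
    association: int
    function: int

    def __post_init__(self):
        if not (self.rwr >= self.permutation >= self.association >= self.function >= 0):
            raise ValidationError(f"stage counts must be monotone non-increasing: {self}")

    def as_dict(self) -> dict[str, int]:
        return {s: getattr(self, s) for s in STAGES}


def apply_thresholds(
    records: Iterable[CandidateRecord],
    thresholds: ScreeningThresholds | None = None,
) -> tuple[list[CandidateRecord], StageCounts]:
    """Run the cascade over scored records.

    Each record's ``stage_passed`` is set to the deepest stage it survives;
    a record that reaches a stage must carry that stage's score (records
    that failed an earlier stage may leave later fields unset).  Returns the
    fully surviving records sorted by MFS descending (ties lexicographic)
    together with the per-stage counts.
    """
    thresholds = thresholds or ScreeningThresholds()
    records = list(records)
    survivors = []
    n_perm = n_assoc = n_func = 0
    for rec in records:
        rec.stage_passed = "rwr"
        if rec.z_score is None:
            raise ValidationError(f"record {rec.gene} reached the permutation stage without a z_score")
        if not rec.z_score > thresholds.z_cutoff:
            continue
        rec.stage_passed = "permutation"
        n_perm += 1
        if rec.mas is None:
            raise ValidationError(f"record {rec.gene} reached the association stage without a MAS")
        if not rec.mas >= thresholds.mas_cutoff:
            continue
        rec.stage_passed = "association"
        n_assoc += 1
        if rec.mfs is None:
            raise ValidationError(f"record {rec.gene} reached the function stage without an MFS")
        if not rec.mfs >= thresholds.mfs_cutoff:
            continue
        rec.stage_passed = "function"
        n_func += 1
        survivors.append(rec)
    survivors.sort(key=lambda r: (-r.mfs, r.gene))
    counts = StageCounts(rwr=len(records), permutation=n_perm, association=n_assoc, function=n_func)
    return survivors, counts
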