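# Methods

## Model and procedure

`rwrscreen` scores every gene in a weighted PPI network by its proximity to
a set of validated disease genes and filters the high-scoring ones through
three guilt-by-association tests.

**Network and walk operator.** The network is undirected over gene
identifiers with integer edge confidences in [1, 999] (the STRING
convention). The walk operator is the column-normalized weighted adjacency
matrix, `W[i,j] = Q(i,j) / weighted-degree(j)`. This operator is
column-stochastic, so applying it to a probability vector conserves unit
mass; nodes left isolated by confidence filtering receive a unit
self-transition (they can hold mass only if seeded). A commonly written
alternative applies the transpose of a column-normalized matrix; for
weighted graphs that composite is not mass-conserving, so this package uses
the conservative convention throughout. Node order is lexicographic, making
every vector and exported table byte-reproducible.

**Random walk with restart.**
`p(t+1) = (1 − r) W p(t) + r p0`, with `p0` uniform over the `k` seeds and
restart probability `r = 0.8` by default — a high restart keeps mass near
the seeds, so scores reflect local network context rather than global
centrality. Iteration stops at the first iterate whose L1 change from its
predecessor is below `1e-6` (default); hitting the iteration budget
(10,000) is an error, not a warning. Because the iteration is a contraction
with factor `(1 − r)`, the converged iterate sits within about
`tol · (1 − r)/r` of the exact fixed point `r (I − (1 − r) W)⁻¹ p0`; tests
that compare against the closed form therefore run the solver at
`tol = 1e-12`, which is a solver setting in those tests, not a changed
default. Non-seed genes with probability strictly above `1e-5` become raw
candidates; seeds are excluded from the candidate list by default (they are
already validated), with an `include_seeds` diagnostic flag.

**Permutation test.** 1,000 random seed sets of size `k` are drawn
uniformly without replacement from all network nodes (overlap with the true
seeds is permitted), the walk is re-run from each, and every candidate's
observed probability is standardized:
`Z(g) = (P(g) − PM(g)) / PSTD(g)`. `PM` and `PSTD` are, by default, the
mean and population standard deviation of the candidate's probabilities
over the permutations in which the candidate was **not** itself drawn as a
seed. The conditioning matters: a candidate is by construction a non-seed
in the observed run, whereas in roughly `k/N` of unrestricted permutations
the gene receives the restart mass `r/k` directly. That spike is one to two
orders of magnitude above any probability a non-seed gene can attain, so an
unconditional `PSTD` is dominated by it and the test loses essentially all
power (on the planted-module benchmark below, no latent gene reaches
`Z > 1.96` unconditionally, while published per-gene probability/Z pairs
from studies of this design are only arithmetically consistent with the
conditional null). The unconditional estimator remains available via
`exclude_candidate_draws=False`, and the sample-standard-deviation
convention via `ddof=1`; with 1,000 permutations the ddof choice is
negligible. Each permutation's seed set is drawn from an independent
counter-keyed stream `(rng_seed, i)`, so results are reproducible
permutation-by-permutation. Z uses a strict `>` at the 1.96 cutoff;
degenerate `PSTD = 0` yields ±infinity (or 0 on exact equality) and is
logged.

*Calibration caveat.* On sparse networks a gene's null distribution is
right-skewed even after conditioning — the dominant variance contribution
is the discrete event "a random seed landed on or next to the gene" — so
the normal-quantile cutoff 1.96 is anti-conservative: the measured
null-on-null firing rate on a 300-node synthetic network with seed sets of
10 is ≈ 0.055–0.058 rather than the nominal 0.025, and stays in the
0.05–0.08 range for seed-set sizes 10–72. The Z filter should be read as a
fixed operating point of the protocol, not as a calibrated 2.5% type-I
test; `scripts/acceptance.py` reports the measured rate. In the full
cascade this looseness only admits extra candidates into the association
test, which the `MAS ≥ 900` requirement then removes unless they have a
highest-confidence edge to a validated gene.

**Association test.** `MAS(g)` is the maximum edge confidence from the
candidate to any validated gene, 0 when there is none. The cutoff 900 is
inclusive (`≥`), matching the lower bound of STRING's highest-confidence
tier.

**Function test.** A gene's neighborhood is itself plus its direct
interactors at any confidence. For each functional term, the
−log10 one-sided upper-tail hypergeometric p-value of the
neighborhood/term overlap (universe = all network nodes by default,
configurable) forms one entry of the enrichment vector `V(g)`. Tails are
computed in log space from log-gamma probability masses combined with
logsumexp, so arbitrarily small p-values never underflow; −log10 p is
capped at 300. `Λ(g, g′)` is the cosine of two vectors — in [0, 1] since
entries are nonnegative, defined as 0 if either vector is all-zero — and
`MFS(g)` is the maximum `Λ` over validated genes, thresholded inclusively
(default 0.9; disease-specific values such as 0.96 are supported).

**Over-representation.** Putative genes are tested per term with the same
one-sided hypergeometric, uncorrected `p < 0.001`, reported by namespace
(BP/CC/MF) sorted by p. This is the "classic" per-term test: no GO-graph
decorrelation (elim/weight-style algorithms) and no ancestor propagation —
the corpus is taken as annotated. Results on real GO corpora will
therefore differ from decorrelated analyses, intentionally so.

## Synthetic benchmark

The generator emulates the statistical shape of the real inputs, not their
content:

- **Background interactome** — preferential attachment
  (`attachment_parameter = 2` edges per node), reproducing the heavy-tailed
  degree distribution of PPI networks; edge confidences uniform integers in
  150–700.
- **Planted disease module** — `module_size = 20` genes wired as a
  near-clique (path backbone plus each remaining pair with probability
  0.9) at confidences 900–999, attached to the background by 1–2
  low-confidence bridges per member. `seed_fraction = 0.5` of the module
  (ceiling) is designated as known seeds; the rest are the latent targets
  the pipeline should recover.
- **Annotation corpus** — `n_terms = 50` terms, namespaces cycling
  BP/CC/MF. A fraction `term_module_bias = 0.8` of terms is module-biased:
  each draws at least half the module and strictly fewer background genes
  than module genes, so module members share high-signal coordinates in
  their enrichment vectors. The remaining terms annotate 8–25 uniformly
  sampled genes.

Defaults (500 background genes + the 20-gene module) are the benchmark's
study conditions; the frozen 60-node study used in the tests scales the
same structure down (50 + 10, 30 terms, generator seed 2021) and its stage
counts were pinned when the fixture was frozen. All generation is
deterministic in `rng_seed`, with separate sub-streams for the network and
the corpus.

What the generator does **not** emulate: STRING's score calibration and
subscore channels, GO's DAG structure and annotation depth bias,
database-specific gene-identifier namespaces, and the size of real
interactomes (~19k nodes). Passing the recovery benchmark shows the
cascade's machinery is sound under its own assumptions — a clean module
wired at high confidence with biased annotations — not that any particular
recall holds on real disease data.

## Numerical and design choices

- Transition operator stored sparse (CSR); permutation walks are solved in
  batches of 256 start vectors at once, which is algebraically identical to
  one-at-a-time runs (the convergence criterion is the max column-wise L1
  change, so a batched column never stops earlier than it would alone).
- All exported floats use 10 significant digits; MAS is printed as an
  integer; candidate tables mark unset stage fields `NA`.
- Duplicate edges keep the maximum confidence (logged); self-loops are
  dropped; the node universe after confidence filtering is the endpoints of
  the surviving edges.
- Ties: raw candidates sort by probability descending then gene ID;
  surviving records by MFS descending then gene ID; term output by p then
  term ID.
- Degenerate inputs: empty candidate list after the cutoff is allowed (later
  stages run empty without error); an empty putative set skips
  over-representation; an empty confidence matrix keeps its headers.

## Limitations

- The permutation null samples seed sets from all network nodes; real
  disease genes are not degree-uniform, so the null may understate the
  scores of hub-adjacent genes. A degree-matched null would be a natural
  extension.
- The `Z > 1.96` stage is anti-conservative on skewed graph-score nulls
  (see calibration caveat); interpret it as a screening heuristic.
- Enrichment vectors treat terms as independent coordinates; correlated GO
  terms inflate cosine similarity between any two well-annotated genes.
- Identifier mapping across namespaces (Ensembl peptide/gene/symbol) is out
  of scope; inputs must share one namespace.
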