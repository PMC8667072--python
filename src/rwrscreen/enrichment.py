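"""Functional-term enrichment: vectors, cosine similarity, MFS, and GO over-representation.

A gene's enrichment vector V(g) has one entry per functional term: the
-log10 one-sided hypergeometric p-value for over-representation of the
term's annotation set in the gene's network neighborhood (the gene plus its
direct interactors).  Functional similarity between two genes is the cosine
of their enrichment vectors,

    Lambda(g, g') = V(g) . V(g') / (||V(g)|| ||V(g')||),

which lies in [0, 1] because entries are nonnegative; a candidate's maximum
function score (MFS) is its largest Lambda to any validated disease gene.

Tail probabilities are evaluated in log space via log-gamma (summed with
logsumexp) so tiny p-values never underflow; -log10 p is capped at 300.
The final over-representation step applies the same one-sided test to the
putative-gene set per term, reporting uncorrected p-values below a cutoff
grouped by GO namespace.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
from scipy import stats
from scipy.special import logsumexp

from .errors import ValidationError
from .network import SeedSet, WeightedNetwork, validate_gene_id

log = logging.getLogger(__name__)

NAMESPACES = ("BP", "CC", "MF", "KEGG")
NEGLOG10_CAP = 300.0
_LN10 = math.log(10.0)


class AnnotationCorpus:
    """Map from functional-term IDs to annotated gene sets, with namespaces.

    Term order is fixed (lexicographic on term ID) so enrichment vectors
    from the same corpus are always comparable.
    """

    def __init__(self, terms: Mapping[str, Iterable[str]], namespaces: Mapping[str, str],
                 descriptions: Mapping[str, str] | None = None):
        self._terms: dict[str, frozenset[str]] = {}
        self._namespaces: dict[str, str] = {}
        self._descriptions: dict[str, str] = {}
        for term, genes in terms.items():
            gene_set = frozenset(validate_gene_id(g) for g in genes)
            if not gene_set:
                raise ValidationError(f"term {term!r} annotates no genes")
            ns = namespaces.get(term)
            if ns not in NAMESPACES:
                raise ValidationError(f"term {term!r} has invalid namespace {ns!r}")
            self._terms[term] = gene_set
            self._namespaces[term] = ns
            self._descriptions[term] = (descriptions or {}).get(term, "")
        if not self._terms:
            raise ValidationError("annotation corpus is empty")
        self.term_order: tuple[str, ...] = tuple(sorted(self._terms))

    def __len__(self) -> int:
        return len(self._terms)

    def __iter__(self) -> Iterator[str]:
        return iter(self.term_order)

    def genes_for(self, term: str) -> frozenset[str]:
        return self._terms[term]

    def namespace(self, term: str) -> str:
        return self._namespaces[term]

    def description(self, term: str) -> str:
        return self._descriptions[term]

    # GMT: term_id <TAB> namespace|description <TAB> gene1 <TAB> gene2 ...
    @classmethod
    def from_gmt(cls, path: str | Path) -> "AnnotationCorpus":
        terms: dict[str, list[str]] = {}
        namespaces: dict[str, str] = {}
        descriptions: dict[str, str] = {}
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ValidationError(f"{path}:{lineno}: GMT line needs term, description, >=1 gene")
                term, desc = fields[0], fields[1]
                ns, _, rest = desc.partition("|")
                ns = ns.strip()
                if ns not in NAMESPACES:
                    raise ValidationError(
                        f"{path}:{lineno}: description must start with a namespace tag "
                        f"{'/'.join(NAMESPACES)}, got {desc!r}"
                    )
                terms[term] = [g for g in fields[2:] if g]
                namespaces[term] = ns
                descriptions[term] = rest
        return cls(terms, namespaces, descriptions)

    def to_gmt(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for term in self.term_order:
                desc = f"{self._namespaces[term]}|{self._descriptions[term]}"
                genes = "\t".join(sorted(self._terms[term]))
                fh.write(f"{term}\t{desc}\t{genes}\n")


def neighborhood_gene_set(network: WeightedNetwork, gene: str) -> frozenset[str]:
    """The gene together with its direct interactors (any confidence)."""
    return frozenset((gene,)) | frozenset(network.neighbors(gene))


def _log_hypergeom_tail(overlap: int, universe: int, term: int, draw: int) -> float:
    """Natural-log upper-tail P(X >= overlap), X ~ Hypergeom(universe, term, draw)."""
    lo = max(0, draw + term - universe)
    hi = min(term, draw)
    if overlap <= lo:
        return 0.0  # tail covers the whole support: p = 1
    support = np.arange(overlap, hi + 1)
    if support.size == 0:
        return -math.inf
    return float(logsumexp(stats.hypergeom.logpmf(support, universe, term, draw)))


def hypergeometric_association(
    neighborhood: Iterable[str], term_set: Iterable[str], universe: Iterable[str]
) -> float:
    """-log10 over-representation p of the term set within the neighborhood.

    One-sided upper tail P(X >= observed overlap) under
    Hypergeom(|universe|, |term_set|, |neighborhood|); capped at 300.
    Empty neighborhood or term set yields 0 with a warning.
    """
    universe = frozenset(universe)
    neighborhood = frozenset(neighborhood)
    term_set = frozenset(term_set)
    if not universe:
        raise ValidationError("universe is empty")
    if not neighborhood <= universe or not term_set <= universe:
        raise ValidationError("neighborhood and term set must be subsets of the universe")
    if not neighborhood or not term_set:
        log.warning("empty neighborhood or term set; association set to 0")
        return 0.0
    overlap = len(neighborhood & term_set)
    logp = _log_hypergeom_tail(overlap, len(universe), len(term_set), len(neighborhood))
    return min(-logp / _LN10, NEGLOG10_CAP)


def enrichment_vector(
    network: WeightedNetwork,
    gene: str,
    corpus: AnnotationCorpus,
    universe: Iterable[str] | None = None,
) -> np.ndarray:
    """V(g): per-term -log10 hypergeometric p of the gene's neighborhood.

    Entries follow the corpus's fixed term order.  The universe defaults to
    all network nodes; term annotations outside the universe are ignored.
    """
    universe = frozenset(universe) if universe is not None else frozenset(network.nodes)
    neighborhood = neighborhood_gene_set(network, gene) & universe
    vec = np.empty(len(corpus))
    for i, term in enumerate(corpus.term_order):
        vec[i] = hypergeometric_association(neighborhood, corpus.genes_for(term) & universe, universe)
    return vec


def functional_similarity(v1: np.ndarray, v2: np.ndarray) -> float:
    """Cosine similarity Lambda of two enrichment vectors; 0 if either is all-zero."""
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    if v1.shape != v2.shape:
        raise ValidationError(f"enrichment vectors have mismatched shapes {v1.shape} vs {v2.shape}")
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 == 0.0 or n2 == 0.0:
        return 0.0
    return float(np.clip(v1 @ v2 / (n1 * n2), 0.0, 1.0))


def max_function_score(
    candidate: str, validated: SeedSet | Iterable[str], vectors: Mapping[str, np.ndarray]
) -> float:
    """MFS: the candidate's largest Lambda to any validated gene."""
    if candidate not in vectors:
        raise ValidationError(f"no enrichment vector for candidate {candidate!r}")
    scores = []
    for g in validated:
        if g not in vectors:
            raise ValidationError(f"no enrichment vector for validated gene {g!r}")
        scores.append(functional_similarity(vectors[candidate], vectors[g]))
    if not scores:
        raise ValidationError("validated set is empty")
    return max(scores)


@dataclass(frozen=True)
class EnrichedTerm:
    term: str
    namespace: str
    p_value: float
    overlap_count: int
    term_size: int


def go_overrepresentation(
    genes: Iterable[str],
    corpus: AnnotationCorpus,
    universe: Iterable[str],
    p_cutoff: float = 0.001,
) -> list[EnrichedTerm]:
    """Classic per-term one-sided hypergeometric over-representation.

    Uncorrected p-values; terms with p < p_cutoff returned sorted by p
    ascending (ties lexicographic on term ID).  No parent-term propagation
    or graph decorrelation is applied: each term is tested as annotated.
    """
    genes = frozenset(genes)
    universe = frozenset(universe)
    if not genes:
        raise ValidationError("gene set for over-representation is empty")
    if not genes <= universe:
        raise ValidationError("gene set must be a subset of the universe")
    out = []
    for term in corpus.term_order:
        term_set = corpus.genes_for(term) & universe
        if not term_set:
            continue
        overlap = len(genes & term_set)
        logp = _log_hypergeom_tail(overlap, len(universe), len(term_set), len(genes))
        p = float(math.exp(logp))
        if p < p_cutoff:
            out.append(EnrichedTerm(term=term, namespace=corpus.namespace(term),
                                    p_value=p, overlap_count=overlap, term_size=len(term_set)))
    out.sort(key=lambda t: (t.p_value, t.term))
    return out


def namespace_counts(terms: Iterable[EnrichedTerm]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for t in terms:
        counts[t.namespace] = counts.get(t.namespace, 0) + 1
    return counts


def write_enriched_terms_tsv(terms: Iterable[EnrichedTerm], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("term\tnamespace\tp_value\toverlap\tterm_size\n")
        for t in terms:
            fh.write(f"{t.term}\t{t.namespace}\t{t.p_value:.10g}\t{t.overlap_count}\t{t.term_size}\n")
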