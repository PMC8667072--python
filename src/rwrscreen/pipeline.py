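"""End-to-end orchestration: load -> RWR -> screening cascade -> GO enrichment.

The pipeline mirrors the published protocol: seed genes are propagated over
the weighted PPI network by random walk with restart, non-seed genes above
the probability cutoff become raw candidates, and three sequential filters
(permutation Z-score, maximum association score, maximum function score)
reduce them to putative disease genes, which are finally tested for GO
term over-representation.  All outputs are plain TSV; floats are printed
with 10 significant digits so runs are byte-comparable.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .enrichment import (
    AnnotationCorpus,
    EnrichedTerm,
    enrichment_vector,
    go_overrepresentation,
    max_function_score,
    namespace_counts,
    write_enriched_terms_tsv,
)
from .errors import ValidationError
from .network import (
    SeedSet,
    WeightedNetwork,
    build_transition_operator,
    load_gene_list,
    load_string_links,
)
from .rwr import RwrConfig, make_seed_vector, run_rwr, select_raw_candidates, write_probability_tsv
from .screening import (
    CandidateRecord,
    ScreeningThresholds,
    StageCounts,
    apply_thresholds,
    max_association_score,
    permutation_test,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Paths plus every stage's parameters; defaults are the study values."""

    edges_path: str
    seeds_path: str
    gmt_path: str
    output_dir: str = "rwrscreen_output"
    min_confidence: int = 1
    rwr: RwrConfig = field(default_factory=RwrConfig)
    thresholds: ScreeningThresholds = field(default_factory=ScreeningThresholds)
    n_permutations: int = 1000
    go_p_cutoff: float = 0.001
    rng_seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "edges_path": self.edges_path,
            "seeds_path": self.seeds_path,
            "gmt_path": self.gmt_path,
            "output_dir": self.output_dir,
            "min_confidence": self.min_confidence,
            "restart_probability": self.rwr.restart_probability,
            "convergence_tol": self.rwr.convergence_tol,
            "max_iterations": self.rwr.max_iterations,
            "candidate_cutoff": self.rwr.candidate_cutoff,
            "z_cutoff": self.thresholds.z_cutoff,
            "mas_cutoff": self.thresholds.mas_cutoff,
            "mfs_cutoff": self.thresholds.mfs_cutoff,
            "n_permutations": self.n_permutations,
            "go_p_cutoff": self.go_p_cutoff,
            "rng_seed": self.rng_seed,
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise ValidationError(f"config file not found: {path}")
        payload = yaml.safe_load(path.read_text(encoding="utf-8"))
        if not isinstance(payload, dict):
            raise ValidationError(f"{path}: config must be a mapping")
        try:
            return cls(
                edges_path=payload["edges_path"],
                seeds_path=payload["seeds_path"],
                gmt_path=payload["gmt_path"],
                output_dir=payload.get("output_dir", "rwrscreen_output"),
                min_confidence=int(payload.get("min_confidence", 1)),
                rwr=RwrConfig(
                    restart_probability=float(payload.get("restart_probability", 0.8)),
                    convergence_tol=float(payload.get("convergence_tol", 1e-6)),
                    max_iterations=int(payload.get("max_iterations", 10000)),
                    candidate_cutoff=float(payload.get("candidate_cutoff", 1e-5)),
                ),
                thresholds=ScreeningThresholds(
                    z_cutoff=float(payload.get("z_cutoff", 1.96)),
                    mas_cutoff=int(payload.get("mas_cutoff", 900)),
                    mfs_cutoff=float(payload.get("mfs_cutoff", 0.9)),
                ),
                n_permutations=int(payload.get("n_permutations", 1000)),
                go_p_cutoff=float(payload.get("go_p_cutoff", 0.001)),
                rng_seed=int(payload.get("rng_seed", 0)),
            )
        except KeyError as exc:
            raise ValidationError(f"{path}: missing required config key {exc}") from None


@dataclass
class PipelineResult:
    stage_counts: StageCounts
    records: list[CandidateRecord]
    putative: list[CandidateRecord]
    enriched_terms: list[EnrichedTerm]
    confidence_matrix: pd.DataFrame
    probabilities: np.ndarray
    network: WeightedNetwork
    seeds: SeedSet

    @property
    def putative_genes(self) -> frozenset[str]:
        return frozenset(r.gene for r in self.putative)


def _stage(name: str, start: float, count: int) -> float:
    now = time.perf_counter()
    log.info("stage %-12s: %6d gene(s) [%.2fs]", name, count, now - start)
    return now


def run_analysis(
    network: WeightedNetwork,
    seeds: SeedSet,
    corpus: AnnotationCorpus,
    rwr_config: RwrConfig | None = None,
    thresholds: ScreeningThresholds | None = None,
    n_permutations: int = 1000,
    go_p_cutoff: float = 0.001,
    rng_seed: int = 0,
    universe: Iterable[str] | None = None,
) -> PipelineResult:
    """Run the full screening cascade on in-memory objects."""
    rwr_config = rwr_config or RwrConfig()
    thresholds = thresholds or ScreeningThresholds()
    universe = frozenset(universe) if universe is not None else frozenset(network.nodes)

    t = time.perf_counter()
    operator = build_transition_operator(network)
    p = run_rwr(operator, make_seed_vector(network, seeds), rwr_config)
    candidates = select_raw_candidates(p, network, seeds, cutoff=rwr_config.candidate_cutoff)
    t = _stage("rwr", t, len(candidates))

    perm = permutation_test(
        operator, network, seeds, candidates,
        n_permutations=n_permutations, rng_seed=rng_seed, config=rwr_config,
    )
    records = [
        CandidateRecord(gene=res.gene, probability=res.observed_probability, z_score=res.z_score)
        for res in perm
    ]
    z_passers = [r for r in records if r.z_score > thresholds.z_cutoff]
    t = _stage("permutation", t, len(z_passers))

    for rec in z_passers:
        rec.mas = max_association_score(network, rec.gene, seeds)
    mas_passers = [r for r in z_passers if r.mas >= thresholds.mas_cutoff]
    t = _stage("association", t, len(mas_passers))

    if mas_passers:
        vectors = {g: enrichment_vector(network, g, corpus, universe)
                   for g in sorted({r.gene for r in mas_passers} | seeds.genes)}
        for rec in mas_passers:
            rec.mfs = max_function_score(rec.gene, seeds, vectors)
    putative, counts = apply_thresholds(records, thresholds)
    t = _stage("function", t, counts.function)

    enriched: list[EnrichedTerm] = []
    if putative:
        enriched = go_overrepresentation(
            (r.gene for r in putative), corpus, universe, p_cutoff=go_p_cutoff
        )
        log.info("enriched terms at p < %g: %d %s", go_p_cutoff, len(enriched),
                 namespace_counts(enriched))
    else:
        log.info("no putative genes; skipping over-representation")

    matrix = export_confidence_matrix(network, (r.gene for r in putative), seeds)
    return PipelineResult(
        stage_counts=counts,
        records=records,
        putative=putative,
        enriched_terms=enriched,
        confidence_matrix=matrix,
        probabilities=p,
        network=network,
        seeds=seeds,
    )


def export_confidence_matrix(
    network: WeightedNetwork, putative: Iterable[str], validated: SeedSet | Iterable[str]
) -> pd.DataFrame:
    """Putative x validated matrix of edge confidences (0 where not adjacent).

    The matrix backs the association heat maps: rows are putative genes,
    columns validated ones.  An empty putative set yields an empty matrix
    that keeps its column headers.
    """
    rows = sorted(set(putative))
    cols = sorted(set(validated.genes if isinstance(validated, SeedSet) else validated))
    data = [[network.confidence(r, c) for c in cols] for r in rows]
    return pd.DataFrame(data, index=rows, columns=cols, dtype=int)


def shared_genes(result_a: "PipelineResult | Iterable[str]", result_b: "PipelineResult | Iterable[str]") -> frozenset[str]:
    """Putative genes common to two analyses (e.g., two disease phenotypes)."""
    def genes(x):
        return x.putative_genes if isinstance(x, PipelineResult) else frozenset(x)
    return genes(result_a) & genes(result_b)


def _format_field(value, as_int: bool = False) -> str:
    if value is None:
        return "NA"
    if as_int:
        return str(int(value))
    return f"{float(value):.10g}"


def write_candidate_table(records: Iterable[CandidateRecord], path: str | Path) -> None:
    """TSV mirroring the putative-gene tables: probability / Z / MAS / MFS / stage."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\tprobability\tz_score\tmas\tmfs\tstage_passed\n")
        for r in records:
            fh.write(
                f"{r.gene}\t{_format_field(r.probability)}\t{_format_field(r.z_score)}\t"
                f"{_format_field(r.mas, as_int=True)}\t{_format_field(r.mfs)}\t{r.stage_passed}\n"
            )


def read_candidate_table(path: str | Path) -> list[CandidateRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str).replace({"NA": None})
    required = {"gene_id", "probability", "z_score", "mas", "mfs"}
    if not required <= set(df.columns):
        raise ValidationError(f"{path}: candidate table must have columns {sorted(required)}")
    records = []
    for row in df.itertuples(index=False):
        records.append(CandidateRecord(
            gene=row.gene_id,
            probability=float(row.probability),
            z_score=None if row.z_score is None else float(row.z_score),
            mas=None if row.mas is None else int(row.mas),
            mfs=None if row.mfs is None else float(row.mfs),
        ))
    return records


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """File-driven pipeline: load inputs, run the cascade, write all exports."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    network = load_string_links(config.edges_path, min_confidence=config.min_confidence)
    seeds = load_gene_list(config.seeds_path, network)
    corpus = AnnotationCorpus.from_gmt(config.gmt_path)
    log.info("loaded network: %d nodes, %d edges; %d seed(s); %d term(s)",
             network.n_nodes, network.n_edges, len(seeds), len(corpus))

    result = run_analysis(
        network, seeds, corpus,
        rwr_config=config.rwr,
        thresholds=config.thresholds,
        n_permutations=config.n_permutations,
        go_p_cutoff=config.go_p_cutoff,
        rng_seed=config.rng_seed,
    )

    write_probability_tsv(network, result.probabilities, out_dir / "probabilities.tsv")
    write_candidate_table(result.records, out_dir / "candidates.tsv")
    write_candidate_table(result.putative, out_dir / "putative.tsv")
    write_enriched_terms_tsv(result.enriched_terms, out_dir / "enriched_terms.tsv")
    result.confidence_matrix.to_csv(out_dir / "confidence_matrix.tsv", sep="\t", index_label="gene_id")
    with open(out_dir / "stage_counts.tsv", "w", encoding="utf-8") as fh:
        fh.write("stage\tcount\n")
        for stage, count in result.stage_counts.as_dict().items():
            fh.write(f"{stage}\t{count}\n")
    config.to_yaml(out_dir / "config.yaml")
    return result
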