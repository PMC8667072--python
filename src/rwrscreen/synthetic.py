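"""Synthetic benchmark data with the structure the screening cascade assumes.

Real inputs to the pipeline are a STRING-style weighted PPI network, a
disease seed-gene list, and a GO/KEGG annotation corpus.  The generator
emulates their statistical shape so every stage is testable offline:

* a background interactome grown by preferential attachment (heavy-tailed
  degree distribution, as in PPI networks) with mid-range confidences;
* a planted disease module — a near-clique wired at STRING's
  highest-confidence tier (>= 900) and sparsely bridged to the background —
  of which a fixed fraction is designated as known seeds and the remainder
  as latent targets the pipeline should recover;
* an annotation corpus in which a fraction of terms preferentially annotate
  module members, giving module genes similar enrichment vectors.

Everything is deterministic for a fixed ``rng_seed``; the network and the
corpus use independent sub-streams so neither depends on generation order.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from .enrichment import AnnotationCorpus
from .errors import ValidationError
from .network import SeedSet, WeightedNetwork, write_gene_list, write_string_links

log = logging.getLogger(__name__)

_NS_CYCLE = ("BP", "CC", "MF")


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator parameters.

    n_background
        Background interactome size (preferential-attachment graph).
    module_size
        Planted disease-module size (>= 2).
    seed_fraction
        Fraction of module members designated as known seeds (ceil); the
        rest are latent targets.
    intra_module_confidence / background_confidence
        Inclusive integer confidence ranges for module and background
        edges; defaults put the module in STRING's highest-confidence tier
        (900-999) and the background well below it (150-700).
    attachment_parameter
        Edges added per node during preferential attachment.
    module_edge_density
        Probability of each intra-module pair beyond a connectivity
        backbone (near-clique at the default 0.9).
    module_bridges
        Inclusive range of background attachments per module member
        (sparse coupling).
    n_terms / term_module_bias
        Corpus size and the fraction of terms that draw most of their
        genes from the module.
    """

    n_background: int = 500
    module_size: int = 20
    seed_fraction: float = 0.5
    intra_module_confidence: tuple[int, int] = (900, 999)
    background_confidence: tuple[int, int] = (150, 700)
    attachment_parameter: int = 2
    module_edge_density: float = 0.9
    module_bridges: tuple[int, int] = (1, 2)
    n_terms: int = 50
    term_module_bias: float = 0.8
    rng_seed: int = 0

    def __post_init__(self):
        if self.module_size < 2:
            raise ValidationError("module_size must be >= 2")
        if self.n_background < 3:
            raise ValidationError("n_background must be >= 3")
        if not (0.0 < self.seed_fraction < 1.0):
            raise ValidationError("seed_fraction must be in (0, 1)")
        for name in ("intra_module_confidence", "background_confidence"):
            lo, hi = getattr(self, name)
            if not (1 <= lo <= hi <= 999):
                raise ValidationError(f"{name} range must satisfy 1 <= lo <= hi <= 999")
        if self.attachment_parameter < 1:
            raise ValidationError("attachment_parameter must be >= 1")
        if self.attachment_parameter >= self.n_background:
            raise ValidationError("attachment_parameter must be < n_background")
        if not (0.0 <= self.module_edge_density <= 1.0):
            raise ValidationError("module_edge_density must be in [0, 1]")
        lo, hi = self.module_bridges
        if not (1 <= lo <= hi):
            raise ValidationError("module_bridges must satisfy 1 <= lo <= hi")
        if self.n_terms < 1:
            raise ValidationError("n_terms must be >= 1")
        if not (0.0 <= self.term_module_bias <= 1.0):
            raise ValidationError("term_module_bias must be in [0, 1]")
        n_seeds = math.ceil(self.seed_fraction * self.module_size)
        if n_seeds >= self.module_size:
            raise ValidationError("seed_fraction leaves no latent targets in the module")


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted ground truth: module membership and the seed/latent split."""

    module_members: frozenset[str]
    seeds: SeedSet
    latent_targets: frozenset[str]

    def __post_init__(self):
        if not self.seeds.genes < self.module_members:
            raise ValidationError("seeds must be a proper subset of the module")
        if not self.latent_targets:
            raise ValidationError("latent target set is empty")


def _rng(spec: SyntheticSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=spec.rng_seed, spawn_key=(stream,)))


def _background_name(i: int) -> str:
    return f"B{i:05d}"


def _module_name(i: int) -> str:
    return f"M{i:04d}"


def generate_network(spec: SyntheticSpec) -> tuple[WeightedNetwork, SyntheticTruth]:
    """Background interactome plus planted disease module; deterministic."""
    rng = _rng(spec, 0)
    lo_b, hi_b = spec.background_confidence
    lo_m, hi_m = spec.intra_module_confidence

    bg = nx.barabasi_albert_graph(
        spec.n_background, spec.attachment_parameter, seed=int(rng.integers(2**31 - 1))
    )
    edges: list[tuple[str, str, int]] = [
        (_background_name(u), _background_name(v), int(rng.integers(lo_b, hi_b + 1)))
        for u, v in sorted(bg.edges())
    ]

    module = [_module_name(i) for i in range(spec.module_size)]
    # connectivity backbone (a path), then the remaining pairs at the density
    for i in range(spec.module_size - 1):
        edges.append((module[i], module[i + 1], int(rng.integers(lo_m, hi_m + 1))))
    for i in range(spec.module_size):
        for j in range(i + 2, spec.module_size):
            if rng.random() < spec.module_edge_density:
                edges.append((module[i], module[j], int(rng.integers(lo_m, hi_m + 1))))
    # sparse bridges into the background
    blo, bhi = spec.module_bridges
    for m in module:
        n_bridge = int(rng.integers(blo, bhi + 1))
        targets = rng.choice(spec.n_background, size=n_bridge, replace=False)
        for t in sorted(targets):
            edges.append((m, _background_name(int(t)), int(rng.integers(lo_b, hi_b + 1))))

    graph = nx.Graph()
    graph.add_edges_from((u, v) for u, v, _ in edges)
    if not nx.is_connected(graph):  # BA background + bridged module is connected by construction
        components = sorted(nx.connected_components(graph), key=lambda c: (len(c), sorted(c)))
        anchor = sorted(components[-1])[0]
        for comp in components[:-1]:
            other = sorted(comp)[0]
            edges.append((anchor, other, int(rng.integers(lo_b, hi_b + 1))))
            log.info("added bridge %s-%s to connect the graph", anchor, other)

    n_seeds = math.ceil(spec.seed_fraction * spec.module_size)
    seed_genes = frozenset(rng.choice(module, size=n_seeds, replace=False).tolist())
    truth = SyntheticTruth(
        module_members=frozenset(module),
        seeds=SeedSet(genes=seed_genes),
        latent_targets=frozenset(module) - seed_genes,
    )
    return WeightedNetwork(edges), truth


def generate_annotations(
    network: WeightedNetwork, truth: SyntheticTruth, spec: SyntheticSpec
) -> AnnotationCorpus:
    """Annotation corpus whose biased terms preferentially cover the module.

    A biased term draws most of its members from the module (at least half
    the module, always more module genes than background fillers), so module
    genes share high-signal coordinates in their enrichment vectors; the
    remaining terms annotate uniformly sampled genes.  Namespaces cycle
    BP/CC/MF.
    """
    rng = _rng(spec, 1)
    module = sorted(truth.module_members)
    background = sorted(set(network.nodes) - truth.module_members)
    all_nodes = list(network.nodes)
    n_biased = round(spec.term_module_bias * spec.n_terms)

    terms: dict[str, list[str]] = {}
    namespaces: dict[str, str] = {}
    descriptions: dict[str, str] = {}
    for t in range(spec.n_terms):
        term = f"T{t:04d}"
        namespaces[term] = _NS_CYCLE[t % len(_NS_CYCLE)]
        if t < n_biased and background:
            n_mod = int(rng.integers(math.ceil(len(module) / 2), len(module) + 1))
            n_bg = int(rng.integers(1, n_mod)) if n_mod > 1 else 1
            n_bg = min(n_bg, len(background), n_mod - 1) if n_mod > 1 else min(1, len(background))
            members = rng.choice(module, size=n_mod, replace=False).tolist()
            if n_bg:
                members += rng.choice(background, size=n_bg, replace=False).tolist()
            descriptions[term] = f"synthetic module-biased term {t}"
        else:
            size = int(rng.integers(8, min(26, len(all_nodes) + 1)))
            members = rng.choice(all_nodes, size=size, replace=False).tolist()
            descriptions[term] = f"synthetic uniform term {t}"
        terms[term] = members
    return AnnotationCorpus(terms, namespaces, descriptions)


def write_truth_json(truth: SyntheticTruth, path: str | Path) -> None:
    payload = {
        "module_members": sorted(truth.module_members),
        "seeds": sorted(truth.seeds.genes),
        "latent_targets": sorted(truth.latent_targets),
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def load_truth_json(path: str | Path) -> SyntheticTruth:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    return SyntheticTruth(
        module_members=frozenset(payload["module_members"]),
        seeds=SeedSet(genes=frozenset(payload["seeds"])),
        latent_targets=frozenset(payload["latent_targets"]),
    )


def write_dataset(spec: SyntheticSpec, out_dir: str | Path) -> dict[str, Path]:
    """Emit a complete synthetic study: edges, seed list, GMT corpus, truth JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    network, truth = generate_network(spec)
    corpus = generate_annotations(network, truth, spec)
    paths = {
        "edges": out_dir / "edges.txt",
        "seeds": out_dir / "seeds.txt",
        "gmt": out_dir / "annotations.gmt",
        "truth": out_dir / "truth.json",
    }
    write_string_links(network, paths["edges"])
    write_gene_list(truth.seeds.genes, paths["seeds"])
    corpus.to_gmt(paths["gmt"])
    write_truth_json(truth, paths["truth"])
    return paths
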