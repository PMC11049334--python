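"""Seedable synthetic multiscale benchmarks with planted positive compounds.

The generator emulates the structure of the real inputs without any
downloads: a connected scale-free protein–protein layer (preferential
attachment), a rooted biological-function DAG, protein→function annotations
drawn with network locality (proteins near an anchor share its functions),
a disease module grown by snowball sampling so it is connected and
network-localized, and a compound library in which planted positives draw
their targets from within a configurable hop distance of the disease module
while negatives draw targets uniformly. Positives and negatives share one
target-count distribution so recovery cannot be a set-size artifact.

All randomness flows through a single numpy PCG64 generator seeded once per
benchmark; identical config + seed reproduce byte-identical output files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .network import MultiscaleNetwork, Node, TypedEdge, build_network
from .scoring import CompoundRecord, DiseaseSignature

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SyntheticConfig:
    """Benchmark shape and planting parameters.

    Defaults define the standard benchmark: 500 proteins, 150 functions,
    40 compounds of which 8 are planted positives, 3–25 targets per
    compound, positives planted within 1 PPI hop of a 20-protein disease
    module with a 10% noise fraction of uniformly drawn targets.
    """

    n_proteins: int = 500
    ppi_attachment: int = 2  # preferential-attachment edges per new protein
    n_functions: int = 150
    dag_max_parents: int = 3
    annotations_per_protein: float = 2.0
    disease_module_size: int = 20
    n_compounds: int = 40
    n_planted_positives: int = 8
    targets_min: int = 3
    targets_max: int = 25
    planting_locality: int = 1  # max PPI hops from the disease module
    noise: float = 0.1  # fraction of positive targets drawn uniformly
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_proteins": self.n_proteins,
            "n_functions": self.n_functions,
            "disease_module_size": self.disease_module_size,
            "n_compounds": self.n_compounds,
            "targets_min": self.targets_min,
            "targets_max": self.targets_max,
            "ppi_attachment": self.ppi_attachment,
            "dag_max_parents": self.dag_max_parents,
        }
        for name, v in counts.items():
            if v < 1:
                raise ValueError(f"{name} must be positive, got {v}")
        if self.n_planted_positives >= self.n_compounds:
            raise ValueError("planted positives must be fewer than compounds")
        if self.planting_locality < 0:
            raise ValueError("planting locality must be >= 0")
        if not (0.0 <= self.noise <= 1.0):
            raise ValueError("noise must lie in [0, 1]")
        if self.targets_max < self.targets_min:
            raise ValueError("targets_max must be >= targets_min")
        if self.ppi_attachment >= self.n_proteins:
            raise ValueError("ppi_attachment must be < n_proteins")
        if self.disease_module_size > self.n_proteins:
            raise ValueError("disease module cannot exceed the protein count")
        if self.targets_max > self.n_proteins:
            raise ValueError("targets_max cannot exceed the protein count")


@dataclass
class SyntheticBenchmark:
    """A generated network, disease, compound library and truth labels."""

    network: MultiscaleNetwork
    disease: DiseaseSignature
    compounds: list[CompoundRecord]
    labels: dict[str, int]  # compound id -> 1 (planted positive) / 0
    config: SyntheticConfig
    provenance: dict = field(default_factory=dict)


def _protein_id(i: int) -> str:
    return f"P{i:05d}"


def _function_id(i: int) -> str:
    return f"F{i:05d}"


def _compound_id(i: int) -> str:
    return f"C{i:04d}"


def generate_network(cfg: SyntheticConfig, rng: np.random.Generator | None = None) -> MultiscaleNetwork:
    """Scale-free PPI layer + rooted function DAG + localized annotations."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)

    ba_seed = int(rng.integers(2**31))
    ppi = nx.barabasi_albert_graph(cfg.n_proteins, cfg.ppi_attachment, seed=ba_seed)

    nodes = [Node(_protein_id(i), "protein", f"protein {i}") for i in range(cfg.n_proteins)]
    nodes += [Node(_function_id(i), "function", f"function {i}") for i in range(cfg.n_functions)]
    edges = [
        TypedEdge(_protein_id(a), _protein_id(b), "ppi") for a, b in sorted(ppi.edges())
    ]

    # rooted DAG: node i > 0 links child→parent to 1..dag_max_parents earlier nodes
    for i in range(1, cfg.n_functions):
        n_par = int(rng.integers(1, cfg.dag_max_parents + 1))
        parents = rng.choice(i, size=min(n_par, i), replace=False)
        for p in sorted(int(x) for x in parents):
            edges.append(TypedEdge(_function_id(i), _function_id(p), "hierarchy"))

    # localized annotations: each function annotates proteins in the closed
    # PPI neighborhood of a random anchor
    total_annotations = cfg.annotations_per_protein * cfg.n_proteins
    per_function = total_annotations / cfg.n_functions
    seen_ann: set[tuple[str, str]] = set()
    for i in range(cfg.n_functions):
        anchor = int(rng.integers(cfg.n_proteins))
        ball = [anchor] + sorted(ppi.neighbors(anchor))
        quota = min(max(1, int(rng.poisson(per_function))), len(ball))
        chosen = rng.choice(len(ball), size=quota, replace=False)
        for c in sorted(int(x) for x in chosen):
            key = (_protein_id(ball[c]), _function_id(i))
            if key not in seen_ann:
                seen_ann.add(key)
                edges.append(TypedEdge(key[0], key[1], "annotation"))

    return build_network(nodes, edges)


def generate_disease(
    net: MultiscaleNetwork, cfg: SyntheticConfig, rng: np.random.Generator | None = None
) -> DiseaseSignature:
    """Snowball-sample a connected protein module from a random anchor."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    ppi = net.ppi_graph()
    proteins = sorted(ppi.nodes)
    anchor = proteins[int(rng.integers(len(proteins)))]
    module = {anchor}
    boundary = sorted(set(ppi.neighbors(anchor)))
    while len(module) < cfg.disease_module_size and boundary:
        pick = boundary[int(rng.integers(len(boundary)))]
        module.add(pick)
        boundary = sorted(
            {nb for m in module for nb in ppi.neighbors(m)} - module
        )
    if len(module) < cfg.disease_module_size:
        logger.warning(
            "disease module truncated at %d proteins (component exhausted)", len(module)
        )
    return DiseaseSignature(name="synthetic-disease", proteins=frozenset(module))


def _hop_neighborhood(ppi: nx.Graph, seeds: set[str], hops: int) -> list[str]:
    reach = set(seeds)
    frontier = set(seeds)
    for _ in range(hops):
        frontier = {nb for nid in frontier for nb in ppi.neighbors(nid)} - reach
        reach |= frontier
    return sorted(reach)


def generate_compounds(
    net: MultiscaleNetwork,
    disease: DiseaseSignature,
    cfg: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[CompoundRecord], dict[str, int]]:
    """Compound library with planted positives near the disease module.

    Target counts follow one long-tailed (geometric, range-clipped)
    distribution for positives and negatives alike. Positive targets come
    from within ``planting_locality`` PPI hops of the disease module except
    for a ``noise`` fraction drawn uniformly; negative targets are uniform.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    ppi = net.ppi_graph()
    all_proteins = sorted(ppi.nodes)
    pool = _hop_neighborhood(ppi, set(disease.proteins), cfg.planting_locality)

    # one shared long-tailed count distribution, clipped to the configured range
    span = cfg.targets_max - cfg.targets_min
    counts = cfg.targets_min + np.minimum(rng.geometric(p=0.18, size=cfg.n_compounds) - 1, span)

    pos_idx = set(
        int(i) for i in rng.choice(cfg.n_compounds, size=cfg.n_planted_positives, replace=False)
    )
    compounds: list[CompoundRecord] = []
    labels: dict[str, int] = {}
    for i in range(cfg.n_compounds):
        cid = _compound_id(i)
        n_t = int(counts[i])
        if i in pos_idx:
            targets: set[str] = set()
            while len(targets) < n_t:
                if rng.random() < cfg.noise or len(pool) <= len(targets & set(pool)):
                    targets.add(all_proteins[int(rng.integers(len(all_proteins)))])
                else:
                    targets.add(pool[int(rng.integers(len(pool)))])
            label = 1
        else:
            chosen = rng.choice(len(all_proteins), size=n_t, replace=False)
            targets = {all_proteins[int(c)] for c in chosen}
            label = 0
        compounds.append(
            CompoundRecord(
                id=cid,
                name=f"compound-{i}",
                targets=frozenset(targets),
                pubchem_cid=str(100000 + i),
            )
        )
        labels[cid] = label
    return compounds, labels


def generate_benchmark(
    cfg: SyntheticConfig | None = None, outdir: str | Path | None = None
) -> SyntheticBenchmark:
    """Compose network, disease and compounds; optionally write the TSV inputs.

    When ``outdir`` is given, writes ``nodes.tsv``, ``edges.tsv``,
    ``compounds.tsv``, ``disease_proteins.txt``, ``truth_labels.tsv`` and a
    ``provenance.json`` recording config, seed and generator algorithm.
    Truth labels live only in the truth file, never in the standard inputs.
    """
    from . import io as mio

    cfg = cfg or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    net = generate_network(cfg, rng)
    disease = generate_disease(net, cfg, rng)
    compounds, labels = generate_compounds(net, disease, cfg, rng)
    provenance = {
        "config": asdict(cfg),
        "rng": "numpy PCG64 (default_rng), single stream, draw order: "
               "network, disease, compounds",
    }
    bench = SyntheticBenchmark(
        network=net, disease=disease, compounds=compounds,
        labels=labels, config=cfg, provenance=provenance,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        mio.write_node_table(net, outdir / "nodes.tsv")
        mio.write_edge_table(net, outdir / "edges.tsv")
        mio.write_compound_table(compounds, outdir / "compounds.tsv")
        mio.write_disease_list(disease, outdir / "disease_proteins.txt")
        mio.write_truth_labels(labels, outdir / "truth_labels.tsv")
        with open(outdir / "provenance.json", "w") as fh:
            json.dump(provenance, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return bench
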