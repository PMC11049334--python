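"""Top-k mechanism subnetwork extraction and export.

The mechanism of a predicted compound–disease association is summarized by
the induced subgraph over: the k most-visited nodes of the compound profile,
the k most-visited nodes of the disease profile, the compound's targets and
the disease proteins. Compound-target nodes with no link to any
disease-associated node or selected biological function are omitted; the
highest-visited node of the compound profile is flagged as the primary
mechanism candidate. Default k is 20.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .diffusion import DiffusionProfile
from .network import MultiscaleNetwork, TypedEdge
from .scoring import CompoundRecord, DiseaseSignature

logger = logging.getLogger(__name__)

DEFAULT_TOP_K = 20

ORIGIN_TOP_COMPOUND = "top-k-of-compound"
ORIGIN_TOP_DISEASE = "top-k-of-disease"
ORIGIN_COMPOUND_TARGET = "compound-target"
ORIGIN_DISEASE_PROTEIN = "disease-protein"

_DISEASE_SIDE = {ORIGIN_TOP_DISEASE, ORIGIN_DISEASE_PROTEIN}


class EmptySubnetworkError(ValueError):
    """The selection is empty after the compound-target link filter."""


@dataclass
class MechanismSubnetwork:
    """Selected nodes (with origin tags and profile values) and induced edges."""

    compound_id: str
    disease_name: str
    origins: dict[str, set[str]]  # node id -> origin tags
    r_c: dict[str, float]
    r_d: dict[str, float]
    kinds: dict[str, str]
    edges: list[TypedEdge]
    primary: str  # highest-visited node of the compound profile

    @property
    def node_ids(self) -> list[str]:
        return sorted(self.origins)


def top_k_nodes(
    r: DiffusionProfile, k: int = DEFAULT_TOP_K, exclude: set[str] | None = None
) -> list[str]:
    """The k highest-probability node ids, descending, ties broken by id."""
    if k < 1:
        raise ValueError("k must be >= 1")
    exclude = exclude or set()
    pairs = [
        (nid, p) for nid, p in zip(r.ids, r.r) if nid not in exclude
    ]
    pairs.sort(key=lambda t: (-t[1], t[0]))
    return [nid for nid, _ in pairs[:k]]


def extract_mechanism(
    net: MultiscaleNetwork,
    r_c: DiffusionProfile,
    r_d: DiffusionProfile,
    compound: CompoundRecord,
    disease: DiseaseSignature,
    k: int = DEFAULT_TOP_K,
    max_hops: int = 1,
) -> MechanismSubnetwork:
    """Build the top-k mechanism subnetwork for one compound–disease pair.

    Selection = top-k(compound profile) ∪ top-k(disease profile) ∪ in-network
    compound targets ∪ in-network disease proteins. A node whose only role is
    compound-side (a compound target, possibly also compound-top-k) is dropped
    unless it reaches a disease-associated node or a selected biological
    function within ``max_hops`` edges of the induced subgraph.
    """
    if r_c.ids != list(net.ids) or r_d.ids != list(net.ids):
        raise ValueError("profiles must be computed on this network's node index")
    node_ids = set(net.index)
    targets = compound.targets & node_ids
    disease_prot = disease.proteins & node_ids

    origins: dict[str, set[str]] = {}

    def tag(ids, origin):
        for nid in ids:
            origins.setdefault(nid, set()).add(origin)

    tag(top_k_nodes(r_c, k), ORIGIN_TOP_COMPOUND)
    tag(top_k_nodes(r_d, k), ORIGIN_TOP_DISEASE)
    tag(targets, ORIGIN_COMPOUND_TARGET)
    tag(disease_prot, ORIGIN_DISEASE_PROTEIN)

    g = net.graph().subgraph(origins).copy()

    # omission rule: a compound target with no induced link (within max_hops)
    # to disease-associated nodes or selected functions is dropped
    anchors = {
        nid for nid, tags in origins.items()
        if tags & _DISEASE_SIDE or net.nodes[nid].kind == "function"
    }
    reachable: set[str] = set(anchors)
    frontier = set(anchors)
    for _ in range(max_hops):
        frontier = {nb for nid in frontier for nb in g.neighbors(nid)} - reachable
        reachable |= frontier
    for nid in sorted(origins):
        tags = origins[nid]
        if ORIGIN_COMPOUND_TARGET in tags and not tags & _DISEASE_SIDE:
            if nid not in reachable:
                logger.info(
                    "compound %s: target %s not linked to disease-associated "
                    "nodes or functions; omitted", compound.id, nid,
                )
                del origins[nid]
    if not origins:
        raise EmptySubnetworkError(
            f"compound {compound.id!r} is disconnected from the disease context"
        )

    selected = set(origins)
    edges = sorted(
        (e for e in net.edges if e.source in selected and e.target in selected),
        key=lambda e: (e.kind, e.source, e.target),
    )
    primary = top_k_nodes(r_c, 1)[0]
    idx = net.index
    return MechanismSubnetwork(
        compound_id=compound.id,
        disease_name=disease.name,
        origins=origins,
        r_c={nid: float(r_c.r[idx[nid]]) for nid in selected},
        r_d={nid: float(r_d.r[idx[nid]]) for nid in selected},
        kinds={nid: net.nodes[nid].kind for nid in selected},
        edges=edges,
        primary=primary,
    )


def export_subnetwork(sub: MechanismSubnetwork, path: str | Path, fmt: str = "sif") -> Path:
    """Write the subnetwork as SIF or GraphML, plus a node-attribute TSV.

    Output is deterministic: rows are sorted by (kind, source, target). The
    companion ``<path stem>.nodes.tsv`` carries kind, origin tags, both
    profile values and the primary-candidate flag.
    """
    if not sub.origins:
        raise EmptySubnetworkError("refusing to export an empty subnetwork")
    path = Path(path)
    if fmt == "sif":
        with open(path, "w") as fh:
            for e in sub.edges:
                fh.write(f"{e.source}\t{e.kind}\t{e.target}\n")
    elif fmt == "graphml":
        g = nx.Graph()
        for nid in sub.node_ids:
            g.add_node(
                nid,
                kind=sub.kinds[nid],
                origins=";".join(sorted(sub.origins[nid])),
                r_c=sub.r_c[nid],
                r_d=sub.r_d[nid],
                primary=nid == sub.primary,
            )
        for e in sub.edges:
            g.add_edge(e.source, e.target, kind=e.kind)
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unsupported export format {fmt!r} (use 'sif' or 'graphml')")

    attr_path = path.with_suffix(".nodes.tsv")
    rows = [
        {
            "id": nid,
            "kind": sub.kinds[nid],
            "origins": ";".join(sorted(sub.origins[nid])),
            "r_c": f"{sub.r_c[nid]:.10e}",
            "r_d": f"{sub.r_d[nid]:.10e}",
            "primary": int(nid == sub.primary),
        }
        for nid in sub.node_ids
    ]
    pd.DataFrame(rows).to_csv(attr_path, sep="\t", index=False)
    return path
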