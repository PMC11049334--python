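"""Pipeline configuration, manifest, and the end-to-end driver.

``run_pipeline`` wires the stages together: read and validate inputs, build
the biased transition matrix, compute the disease profile once, score and
rank all eligible compounds, run hypergeometric overlap tests, optional
gene-set enrichment and known-positive evaluation, and export mechanism
subnetworks for the top-ranked compounds. Every run leaves a manifest with
the config snapshot, input checksums and per-stage counts; identical config
and inputs reproduce byte-identical outputs (timestamps excluded).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import shutil
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from . import io as mio
from .diffusion import DiffusionParams
from .mechanism import DEFAULT_TOP_K, EmptySubnetworkError, extract_mechanism, export_subnetwork
from .network import EdgeWeightScheme, build_transition_matrix
from .scoring import DEFAULT_MIN_TARGETS, compound_profile, disease_profile, rank_compounds
from .stats import evaluate_known_positives, enrich_gene_sets, overlap_test

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """All inputs and parameters for one pipeline run.

    ``epsilon`` (1e-6), ``k`` (20) and ``min_targets`` (3) default to the
    method's standard settings; ``alpha`` and the edge-class weights have no
    canonical published values and default to 0.85 and uniform 1.0 — both
    are deliberate configuration choices.
    """

    nodes: str = "nodes.tsv"
    edges: str = "edges.tsv"
    compounds: str = "compounds.tsv"
    disease: str = "disease_proteins.txt"
    gene_sets: str | None = None
    positives: str | None = None
    outdir: str = "multidiff_out"
    alpha: float = 0.85
    epsilon: float = 1e-6
    max_iter: int = 10000
    weights: dict = field(default_factory=lambda: dict(EdgeWeightScheme().as_dict()))
    k: int = DEFAULT_TOP_K
    min_targets: int = DEFAULT_MIN_TARGETS
    universe: str = "network-proteins"  # or "union" of targets+disease
    mechanism_top: int = 3
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def diffusion_params(self) -> DiffusionParams:
        return DiffusionParams(alpha=self.alpha, epsilon=self.epsilon, max_iter=self.max_iter)

    def weight_scheme(self) -> EdgeWeightScheme:
        return EdgeWeightScheme(**self.weights)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def read_inputs(cfg: PipelineConfig):
    """Load and validate all configured inputs."""
    net = mio.read_network(cfg.nodes, cfg.edges)
    compounds = mio.read_compound_table(cfg.compounds)
    disease = mio.read_disease_list(cfg.disease)
    gene_sets = mio.read_gmt(cfg.gene_sets) if cfg.gene_sets else None
    positives = mio.read_positive_list(cfg.positives) if cfg.positives else None
    return net, compounds, disease, gene_sets, positives


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run every stage and write outputs plus a manifest to ``cfg.outdir``.

    On a stage failure, partial outputs are moved to a ``_failed`` quarantine
    subdirectory and a :class:`StageError` naming the stage is raised.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    started = datetime.now(timezone.utc).isoformat()
    stage = "read_inputs"
    counts: dict[str, int] = {}
    try:
        net, compounds, disease, gene_sets, positives = read_inputs(cfg)
        counts["nodes"] = net.n_nodes
        counts["edges"] = net.n_edges
        counts["compounds_in"] = len(compounds)
        logger.info("read %d nodes, %d edges, %d compounds", net.n_nodes, net.n_edges, len(compounds))

        stage = "transition_matrix"
        T = build_transition_matrix(net, cfg.weight_scheme())
        params = cfg.diffusion_params()

        stage = "rank"
        st = rank_compounds(compounds, disease, net, T, params, cfg.min_targets)
        st.metadata["weights"] = cfg.weights
        counts["compounds_scored"] = len(st.table)
        mio.write_score_table(st, outdir / "scores.tsv")

        stage = "overlap"
        protein_set = set(net.protein_ids())
        if cfg.universe == "network-proteins":
            universe = protein_set
        elif cfg.universe == "union":
            universe = (set().union(*(c.targets for c in compounds)) | set(disease.proteins)) & protein_set
        else:
            raise ValueError(f"unknown universe choice {cfg.universe!r}")
        by_id = {c.id: c for c in compounds}
        overlap_rows = []
        for cid in st.table["compound_id"]:
            c = by_id[cid]
            try:
                ot = overlap_test(c.targets, disease.proteins, universe)
            except ValueError:
                continue
            overlap_rows.append(
                {"compound_id": cid, "k": ot.k, "n": ot.n, "K": ot.K, "N": ot.N,
                 "p_value": f"{ot.p_value:.6e}"}
            )
        pd.DataFrame(overlap_rows).to_csv(outdir / "overlap_tests.tsv", sep="\t", index=False)
        counts["overlap_tests"] = len(overlap_rows)

        if gene_sets:
            stage = "enrich"
            all_targets = set().union(*(by_id[c].targets for c in st.table["compound_id"]))
            rows = enrich_gene_sets(all_targets & protein_set, gene_sets, protein_set)
            pd.DataFrame(
                [{"set_name": r.set_name, "overlap": r.overlap, "set_size": r.set_size,
                  "p_value": f"{r.p_value:.6e}", "adjusted_p": f"{r.adjusted_p:.6e}"}
                 for r in rows]
            ).to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
            counts["enriched_sets"] = len(rows)

        if positives:
            stage = "evaluate"
            ev = evaluate_known_positives(st, positives)
            report = {
                "auroc": ev.auroc, "aupr": ev.aupr,
                "n_positive": ev.n_positive, "n_total": ev.n_total,
            }
            with open(outdir / "evaluation.json", "w") as fh:
                json.dump(report, fh, indent=2, sort_keys=True)
                fh.write("\n")
            ev.roc_points.to_csv(outdir / "roc_points.tsv", sep="\t", index=False,
                                 float_format="%.6f")
            ev.pr_points.to_csv(outdir / "pr_points.tsv", sep="\t", index=False,
                                float_format="%.6f")

        stage = "mechanism"
        r_d = disease_profile(disease, net, T, params)
        n_mech = 0
        for cid in st.table["compound_id"].head(cfg.mechanism_top):
            c = by_id[cid]
            r_c = compound_profile(c, net, T, params)
            try:
                sub = extract_mechanism(net, r_c, r_d, c, disease, k=cfg.k)
            except EmptySubnetworkError as exc:
                logger.warning("mechanism for %s skipped: %s", cid, exc)
                continue
            export_subnetwork(sub, outdir / f"mechanism_{cid}.sif", fmt="sif")
            n_mech += 1
        counts["mechanism_subnetworks"] = n_mech

        stage = "manifest"
        input_paths = {
            "nodes": cfg.nodes, "edges": cfg.edges,
            "compounds": cfg.compounds, "disease": cfg.disease,
        }
        if cfg.gene_sets:
            input_paths["gene_sets"] = cfg.gene_sets
        if cfg.positives:
            input_paths["positives"] = cfg.positives
        manifest = {
            "config": dataclasses.asdict(cfg),
            "inputs_sha256": {k: _sha256(Path(v)) for k, v in input_paths.items()},
            "version": __version__,
            "started": started,
            "finished": datetime.now(timezone.utc).isoformat(),
            "stage_counts": counts,
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return outdir
    except StageError:
        raise
    except Exception as exc:
        quarantine = outdir / "_failed"
        quarantine.mkdir(exist_ok=True)
        for item in sorted(outdir.iterdir()):
            if item.name != "_failed":
                shutil.move(str(item), quarantine / item.name)
        raise StageError(stage, exc) from exc
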