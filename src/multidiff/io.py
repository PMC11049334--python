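"""Readers and writers for the pipeline's plain-text formats.

Dialects
--------
* node table TSV: columns ``id``, ``kind``, ``label`` (header required)
* edge table TSV: columns ``source``, ``target``, ``kind``
* compound table TSV: ``compound_id``, ``name``, ``pubchem_cid``,
  ``targets`` (semicolon-separated protein ids)
* disease protein list: one id per line; ``#`` comments allowed
* gene sets: GMT (name, description, members, tab-separated)
* diffusion profile: two-column TSV plus a JSON sidecar with walk metadata
* score table: TSV preceded by a ``#``-prefixed metadata block

Edge/node kinds are case-folded on input (logged); malformed rows are
reported with their line numbers.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from .diffusion import DiffusionProfile
from .network import EDGE_KINDS, NODE_KINDS, MultiscaleNetwork, build_network
from .scoring import CompoundRecord, DiseaseSignature, ScoreTable

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Malformed input file (missing columns, bad kinds, duplicates...)."""


def _require_columns(df: pd.DataFrame, needed: list[str], path) -> None:
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")


def _fold_kind(value: str, allowed: tuple[str, ...], path, line: int) -> str:
    folded = str(value).strip().lower()
    if folded not in allowed:
        raise FormatError(f"{path}:{line}: unknown kind {value!r} (allowed: {allowed})")
    if folded != value:
        logger.info("%s:%d: kind %r case-folded to %r", path, line, value, folded)
    return folded


def read_node_table(path: str | Path) -> list[dict]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.empty:
        raise FormatError(f"{path}: empty node table")
    _require_columns(df, ["id", "kind"], path)
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        records.append(
            {
                "id": row.id,
                "kind": _fold_kind(row.kind, NODE_KINDS, path, i),
                "label": getattr(row, "label", ""),
            }
        )
    return records


def read_edge_table(path: str | Path) -> list[dict]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.empty:
        raise FormatError(f"{path}: empty edge table")
    _require_columns(df, ["source", "target", "kind"], path)
    return [
        {
            "source": row.source,
            "target": row.target,
            "kind": _fold_kind(row.kind, EDGE_KINDS, path, i),
        }
        for i, row in enumerate(df.itertuples(index=False), start=2)
    ]


def read_network(nodes_path: str | Path, edges_path: str | Path) -> MultiscaleNetwork:
    return build_network(read_node_table(nodes_path), read_edge_table(edges_path))


def write_node_table(net: MultiscaleNetwork, path: str | Path) -> None:
    rows = [
        {"id": nid, "kind": net.nodes[nid].kind, "label": net.nodes[nid].label}
        for nid in net.ids
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_edge_table(net: MultiscaleNetwork, path: str | Path) -> None:
    rows = [
        {"source": e.source, "target": e.target, "kind": e.kind} for e in net.edges
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_compound_table(path: str | Path) -> list[CompoundRecord]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.empty:
        raise FormatError(f"{path}: empty compound table")
    _require_columns(df, ["compound_id", "name", "targets"], path)
    seen: set[str] = set()
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        cid = row.compound_id
        if cid in seen:
            raise FormatError(f"{path}:{i}: duplicated compound id {cid!r}")
        seen.add(cid)
        targets = frozenset(t for t in str(row.targets).split(";") if t)
        if not targets:
            raise FormatError(f"{path}:{i}: compound {cid!r} lists no targets")
        cid_pc = getattr(row, "pubchem_cid", "") or None
        out.append(CompoundRecord(id=cid, name=row.name, targets=targets, pubchem_cid=cid_pc))
    return out


def write_compound_table(compounds: list[CompoundRecord], path: str | Path) -> None:
    rows = [
        {
            "compound_id": c.id,
            "name": c.name,
            "pubchem_cid": c.pubchem_cid or "",
            "targets": ";".join(sorted(c.targets)),
        }
        for c in sorted(compounds, key=lambda c: c.id)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_disease_list(path: str | Path, name: str | None = None) -> DiseaseSignature:
    path = Path(path)
    proteins = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            proteins.append(line)
    if not proteins:
        raise FormatError(f"{path}: empty disease protein list")
    return DiseaseSignature(name=name or path.stem, proteins=frozenset(proteins))


def write_disease_list(disease: DiseaseSignature, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# disease: {disease.name}\n")
        for pid in sorted(disease.proteins):
            fh.write(pid + "\n")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT gene sets: name <tab> description <tab> member ids."""
    path = Path(path)
    sets: dict[str, set[str]] = {}
    for i, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}:{i}: GMT rows need name, description, >=1 member")
        name = parts[0]
        if name in sets:
            raise FormatError(f"{path}:{i}: duplicated gene-set name {name!r}")
        sets[name] = {m for m in parts[2:] if m}
    if not sets:
        raise FormatError(f"{path}: empty GMT file")
    return sets


def read_positive_list(path: str | Path) -> set[str]:
    path = Path(path)
    ids = {
        line.strip()
        for line in path.read_text().splitlines()
        if line.strip() and not line.startswith("#")
    }
    if not ids:
        raise FormatError(f"{path}: empty known-positive list")
    return ids


def read_truth_labels(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", dtype={"compound_id": str, "label": int})
    _require_columns(df, ["compound_id", "label"], path)
    return dict(zip(df["compound_id"], df["label"]))


def write_truth_labels(labels: dict[str, int], path: str | Path) -> None:
    rows = [{"compound_id": cid, "label": labels[cid]} for cid in sorted(labels)]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_profile(profile: DiffusionProfile, path: str | Path, params=None) -> None:
    """Two-column TSV plus a JSON sidecar with walk metadata."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("node_id\tprobability\n")
        for nid, p in zip(profile.ids, profile.r):
            fh.write(f"{nid}\t{p:.10e}\n")
    sidecar = {
        "iterations_used": profile.iterations_used,
        "converged": profile.converged,
    }
    if params is not None:
        sidecar.update({"alpha": params.alpha, "epsilon": params.epsilon})
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_profile(path: str | Path) -> DiffusionProfile:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"node_id": str})
    _require_columns(df, ["node_id", "probability"], path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    meta = {}
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
    return DiffusionProfile(
        r=df["probability"].to_numpy(),
        ids=df["node_id"].tolist(),
        iterations_used=int(meta.get("iterations_used", 0)),
        converged=bool(meta.get("converged", True)),
    )


def write_score_table(st: ScoreTable, path: str | Path) -> None:
    """Score TSV with a ``#`` metadata header block; scores to 6 decimals."""
    path = Path(path)
    df = st.table.copy()
    df["score"] = df["score"].map(lambda v: f"{v:.6f}")
    with open(path, "w") as fh:
        for key in sorted(st.metadata):
            if key == "excluded":
                for row in st.metadata[key]:
                    fh.write(f"# excluded\t{row['compound_id']}\t{row['reason']}\n")
            else:
                fh.write(f"# {key}\t{st.metadata[key]}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_score_table(path: str | Path) -> ScoreTable:
    path = Path(path)
    meta: dict = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    excluded = []
    for i, line in enumerate(lines):
        if not line.startswith("#"):
            body_start = i
            break
        parts = line[1:].strip().split("\t")
        if parts[0] == "excluded":
            excluded.append({"compound_id": parts[1], "reason": parts[2]})
        else:
            meta[parts[0]] = parts[1] if len(parts) > 1 else ""
    if excluded:
        meta["excluded"] = excluded
    from io import StringIO

    df = pd.read_csv(
        StringIO("".join(lines[body_start:])), sep="\t",
        dtype={"compound_id": str, "name": str},
    )
    return ScoreTable(table=df, metadata=meta)
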