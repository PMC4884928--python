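"""Readers and writers for the pipeline's plain-text interchange formats.

Everything is TSV/CSV/JSON so inputs and outputs stay diffable:

* expression matrix TSV (rows = genes, columns = sample ids) with a
  companion metadata TSV (sample_id, drug, day, dose) and an optional
  detection-p TSV of identical shape;
* PPI edge list TSV (node_a, node_b, confidence);
* drug-target TSV (drug, target, confidence);
* fingerprints TSV (drug, n_bits, hex-packed bits);
* screen CSV (drug, dose, pct_differentiated, live_cells);
* ground-truth JSON for synthetic scenarios.

The same expression reader handles matrices exported from public
repositories, provided they are reshaped to this layout.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .datasets import ExpressionDataset, GroundTruth


# -- expression ------------------------------------------------------------

def write_expression(data: ExpressionDataset, outdir, prefix: str = "expression") -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "values": outdir / f"{prefix}.tsv",
        "meta": outdir / f"{prefix}_meta.tsv",
    }
    data.values.to_csv(paths["values"], sep="\t", index_label="gene")
    data.meta.to_csv(paths["meta"], sep="\t", index_label="sample_id")
    if data.detection is not None:
        paths["detection"] = outdir / f"{prefix}_detection.tsv"
        data.detection.to_csv(paths["detection"], sep="\t", index_label="gene")
    return paths


def read_expression(values_path, meta_path, detection_path=None) -> ExpressionDataset:
    values = pd.read_csv(values_path, sep="\t", index_col="gene")
    values.index.name = None  # label is a file artifact, not part of the data
    meta = pd.read_csv(meta_path, sep="\t", index_col="sample_id")
    detection = None
    if detection_path is not None:
        detection = pd.read_csv(detection_path, sep="\t", index_col="gene")
        detection.index.name = None
    return ExpressionDataset(values, meta, detection)


# -- networks and targets ---------------------------------------------------

def write_ppi(net: nx.Graph, path) -> None:
    rows = [
        (u, v, d.get("confidence", 1.0))
        for u, v, d in sorted(net.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["node_a", "node_b", "confidence"]).to_csv(
        path, sep="\t", index=False
    )


def read_ppi(path) -> nx.Graph:
    frame = pd.read_csv(path, sep="\t")
    g = nx.Graph()
    for row in frame.itertuples(index=False):
        g.add_edge(row.node_a, row.node_b, confidence=float(row.confidence))
    return g


def write_targets(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_targets(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# -- fingerprints ------------------------------------------------------------

def write_fingerprints(fps: dict[str, np.ndarray], path) -> None:
    rows = []
    for drug, bits in fps.items():
        bits = np.asarray(bits, dtype=bool)
        rows.append((drug, bits.size, np.packbits(bits).tobytes().hex()))
    pd.DataFrame(rows, columns=["drug", "n_bits", "fingerprint_hex"]).to_csv(
        path, sep="\t", index=False
    )


def read_fingerprints(path) -> dict[str, np.ndarray]:
    frame = pd.read_csv(path, sep="\t")
    out = {}
    for row in frame.itertuples(index=False):
        packed = np.frombuffer(bytes.fromhex(row.fingerprint_hex), dtype=np.uint8)
        out[row.drug] = np.unpackbits(packed)[: row.n_bits].astype(bool)
    return out


# -- screen ------------------------------------------------------------------

def write_screen(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_screen(path) -> pd.DataFrame:
    return pd.read_csv(path)


# -- ground truth -------------------------------------------------------------

def write_ground_truth(truth: GroundTruth, path) -> None:
    payload = {
        "gene_categories": (
            truth.gene_categories.to_dict() if truth.gene_categories is not None else None
        ),
        "undetected_genes": sorted(truth.undetected_genes),
        "effective_drugs": sorted(truth.effective_drugs),
        "backbone_edges": sorted(list(e) for e in truth.backbone_edges),
        "entry_edges": {d: list(e) for d, e in truth.entry_edges.items()},
        "drug_targets": {d: list(t) for d, t in truth.drug_targets.items()},
        "entry_node": truth.entry_node,
        "deg_node": truth.deg_node,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_ground_truth(path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    cats = payload.get("gene_categories")
    return GroundTruth(
        gene_categories=pd.Series(cats, name="category") if cats else None,
        undetected_genes=frozenset(payload.get("undetected_genes", [])),
        effective_drugs=frozenset(payload.get("effective_drugs", [])),
        backbone_edges=frozenset(tuple(e) for e in payload.get("backbone_edges", [])),
        entry_edges={d: tuple(e) for d, e in payload.get("entry_edges", {}).items()},
        drug_targets={d: tuple(t) for d, t in payload.get("drug_targets", {}).items()},
        entry_node=payload.get("entry_node"),
        deg_node=payload.get("deg_node"),
    )


# -- CAP-Net outputs -----------------------------------------------------------

def write_capnet(cap, outdir, prefix: str = "capnet") -> dict:
    """Edge TSV + SIF + GraphML, plus the node table when annotated."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frame = cap.to_frame()
    paths = {"edges": outdir / f"{prefix}_edges.tsv"}
    frame.to_csv(paths["edges"], sep="\t", index=False)

    paths["sif"] = outdir / f"{prefix}.sif"
    with open(paths["sif"], "w") as fh:
        for row in frame.itertuples(index=False):
            fh.write(f"{row.node_a}\tpp\t{row.node_b}\n")

    g = nx.Graph()
    for row in frame.itertuples(index=False):
        g.add_edge(
            row.node_a,
            row.node_b,
            support=int(row.support),
            p_value=float(row.p_value) if not pd.isna(row.p_value) else -1.0,
        )
    paths["graphml"] = outdir / f"{prefix}.graphml"
    nx.write_graphml(g, paths["graphml"])

    if cap.node_annotations is not None:
        paths["nodes"] = outdir / f"{prefix}_nodes.tsv"
        cap.node_annotations.to_csv(paths["nodes"], sep="\t", index=False)
    return paths
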