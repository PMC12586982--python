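"""Readers and writers for the pipeline's plain-text formats.

All genomic coordinates are 0-based half-open in memory. On disk, SEG-like
tables are 1-based inclusive and BEDPE is 0-based half-open; conversions
happen here and nowhere else.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd

from .concordance import PileupPanel
from .cnv import ImproperPairRecord, Segment
from .methylome import BetaMatrix

__all__ = [
    "read_pileups", "write_pileups",
    "read_seg", "write_seg",
    "read_bedpe", "write_bedpe",
    "read_beta_matrix", "write_beta_matrix",
    "read_sample_sheet", "write_amplicon_graph",
]

_PILEUP_COLS = ["sample_id", "chrom", "pos", "nA", "nC", "nG", "nT"]


def read_pileups(path) -> list[PileupPanel]:
    """Read a pileup TSV (one row per sample x site, 1-based positions)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(_PILEUP_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"pileup file lacks columns {sorted(missing)}")
    panels = []
    sites = (df[["chrom", "pos"]].drop_duplicates().reset_index(drop=True))
    sites["variant_class"] = "single"
    for sample_id, sub in df.groupby("sample_id", sort=True):
        sub = sub.sort_values(["chrom", "pos"])
        panels.append(PileupPanel(
            sample_id=str(sample_id), sites=sites,
            counts=sub[["nA", "nC", "nG", "nT"]].to_numpy()))
    return panels


def write_pileups(panels: list[PileupPanel], path) -> None:
    rows = []
    for p in panels:
        block = p.sites[["chrom", "pos"]].copy()
        block.insert(0, "sample_id", p.sample_id)
        block[["nA", "nC", "nG", "nT"]] = p.counts
        rows.append(block)
    pd.concat(rows).to_csv(path, sep="\t", index=False)


def read_seg(path) -> dict[str, list[Segment]]:
    """Read a SEG-like TSV (1-based inclusive) into per-sample segment lists."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, list[Segment]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["sample"]), []).append(Segment(
            chromosome=str(row["chrom"]), start=int(row["start"]) - 1,
            end=int(row["end"]), log_ratio=float(row["log_ratio"]),
            n_markers=int(row.get("n_markers", 0))))
    return out


def write_seg(segments_by_sample: dict[str, list[Segment]], path) -> None:
    rows = []
    for sample, segs in segments_by_sample.items():
        for s in segs:
            rows.append({"sample": sample, "chrom": s.chromosome,
                         "start": s.start + 1, "end": s.end,
                         "n_markers": s.n_markers, "log_ratio": s.log_ratio,
                         "integer_cn": s.integer_cn})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_bedpe(path) -> list[ImproperPairRecord]:
    """Read BEDPE (0-based half-open) with n_pairs / n_split extra columns."""
    df = pd.read_csv(path, sep="\t")
    recs = []
    for _, row in df.iterrows():
        recs.append(ImproperPairRecord(
            chrom1=str(row["chrom1"]), start1=int(row["start1"]), end1=int(row["end1"]),
            chrom2=str(row["chrom2"]), start2=int(row["start2"]), end2=int(row["end2"]),
            orientation=str(row["strand1"]) + str(row["strand2"]),
            n_pairs=int(row["n_pairs"]), n_split=int(row.get("n_split", 0))))
    return recs


def write_bedpe(records: list[ImproperPairRecord], path) -> None:
    rows = []
    for i, r in enumerate(records):
        rows.append({"chrom1": r.chrom1, "start1": r.start1, "end1": r.end1,
                     "chrom2": r.chrom2, "start2": r.start2, "end2": r.end2,
                     "name": f"pair{i}", "score": r.n_pairs,
                     "strand1": r.orientation[0], "strand2": r.orientation[1],
                     "n_pairs": r.n_pairs, "n_split": r.n_split})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_beta_matrix(values_path, annotations_path) -> BetaMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    annotations = pd.read_csv(annotations_path, sep="\t", index_col=0)
    return BetaMatrix(values=values, annotations=annotations)


def write_beta_matrix(matrix: BetaMatrix, values_path, annotations_path) -> None:
    matrix.values.to_csv(values_path, sep="\t")
    matrix.annotations.to_csv(annotations_path, sep="\t")


def read_sample_sheet(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_amplicon_graph(graph: nx.Graph, path) -> None:
    """Serialize an amplicon graph as JSON (nodes with copies/chrom/seed)."""
    payload = {
        "nodes": [{"id": list(n), **graph.nodes[n]} for n in graph.nodes],
        "edges": [{"source": list(u), "target": list(v),
                   "n_bridging_pairs": d["n_bridging_pairs"]}
                  for u, v, d in graph.edges(data=True)],
    }
    Path(path).write_text(json.dumps(payload, indent=2))
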