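"""Purity/ploidy-aware integer copy number, focal deletions, amplicon graphs
and rearrangement calls from segmented log ratios and discordant read pairs.

The central model treats the observed log2 ratio of a genomic segment as a
mixture of tumor and normal cells:

    R = log2( (C_T * p + C_N * (1 - p)) / (P_T * p + P_N * (1 - p)) )

where ``p`` is tumor purity, ``C_T`` / ``C_N`` the segment copy number in
tumor / normal cells, and ``P_T`` / ``P_N`` the average tumor / normal ploidy.
Integer copy number is recovered by inverting this relationship and rounding
to the nearest integer (ties away from zero, clipped at zero).

Downstream calls follow fixed evidence rules:

* focal deletions: segments < 3 Mb with integer copy number 0 (homozygous) or
  1 (hemizygous); flagged supported ("+") when >= 2 improper read pairs with
  deletion-type orientation fall within a flank window of the segment ends;
* amplicon seeds: segments with copy number strictly greater than 2.5x the
  average tumor ploidy;
* amplicon links: low-copy gains (>= 1.5x ploidy) joined to a seed's graph
  component when >= 2 read pairs bridge the two segments;
* rearrangements: >= 2 improper pairs and >= 1 split read, minus any event
  whose both breakends overlap a matched-normal event.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "CopyNumberContext",
    "Segment",
    "ImproperPairRecord",
    "DeletionCall",
    "expected_logr",
    "integer_copy_number",
    "normalize_logr",
    "assign_integer_cn",
    "filter_samples",
    "call_focal_deletions",
    "seed_amplicons",
    "link_amplicons",
    "call_rearrangements",
    "FOCAL_DELETION_MAX_BP",
    "DELETION_FLANK_BP",
    "NORMAL_OVERLAP_BP",
]

FOCAL_DELETION_MAX_BP = 3_000_000
#: breakends within this window outside a segment end count as consistent
#: with its deletion (config default; not a published constant)
DELETION_FLANK_BP = 10_000
#: rearrangements whose breakends both fall within this distance of a
#: matched-normal event are treated as germline/artifact and excluded
NORMAL_OVERLAP_BP = 1_000


@dataclass(frozen=True)
class CopyNumberContext:
    """Purity/ploidy context shared by all segments of one sample."""

    purity: float
    tumor_ploidy: float
    normal_ploidy: float = 2.0
    normal_copies: float = 2.0

    def __post_init__(self) -> None:
        if not (0.0 < self.purity <= 1.0):
            raise ValueError(f"purity must be in (0, 1], got {self.purity}")
        if self.tumor_ploidy < 0 or self.normal_ploidy < 0 or self.normal_copies < 0:
            raise ValueError("ploidies and normal copies must be non-negative")


@dataclass
class Segment:
    """One segment of piecewise-constant copy number.

    Coordinates are 0-based half-open in memory; SEG-like files on disk are
    1-based inclusive and converted at the I/O boundary.
    """

    chromosome: str
    start: int
    end: int
    log_ratio: float
    integer_cn: int | None = None
    n_markers: int = 0

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"end must exceed start: {self.start}..{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ImproperPairRecord:
    """Discordant read-pair / split-read evidence joining two breakend intervals."""

    chrom1: str
    start1: int
    end1: int
    chrom2: str
    start2: int
    end2: int
    orientation: str = "+-"
    n_pairs: int = 1
    n_split: int = 0


@dataclass
class DeletionCall:
    segment: Segment
    zygosity: str  # "homozygous" (CN 0) or "hemizygous" (CN 1)
    supported: bool  # ">= 2 consistent improper pairs" -> the "+" flag


def expected_logr(c_t: float, ctx: CopyNumberContext) -> float:
    """Expected log2 ratio of a segment with ``c_t`` tumor copies.

    Returns ``-inf`` when the numerator is zero (homozygous deletion in a
    pure tumor), which round-trips correctly through
    :func:`integer_copy_number`.
    """
    p = ctx.purity
    denom = ctx.tumor_ploidy * p + ctx.normal_ploidy * (1.0 - p)
    if denom <= 0:
        raise ValueError("non-positive ploidy mixture denominator")
    num = c_t * p + ctx.normal_copies * (1.0 - p)
    if num < 0:
        raise ValueError("negative copy mixture numerator")
    if num == 0:
        return float("-inf")
    return math.log2(num / denom)


def _round_half_away(x: float) -> int:
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def integer_copy_number(log_ratio: float, ctx: CopyNumberContext) -> int:
    """Invert the mixture model: nearest integer C_T, clipped at zero."""
    p = ctx.purity
    denom = ctx.tumor_ploidy * p + ctx.normal_ploidy * (1.0 - p)
    if denom <= 0:
        raise ValueError("non-positive ploidy mixture denominator")
    c_t = (2.0**log_ratio * denom - ctx.normal_copies * (1.0 - p)) / p
    return max(0, _round_half_away(c_t))


def normalize_logr(tumor: pd.DataFrame, matched_normal: pd.DataFrame) -> pd.DataFrame:
    """Subtract matched-normal log ratios from tumor log ratios.

    Both tables must carry chrom/start/end/log_ratio on the same segment
    grid; technical biases and germline copy events cancel in the
    difference.
    """
    key = ["chrom", "start", "end"]
    for df, name in ((tumor, "tumor"), (matched_normal, "normal")):
        missing = set(key + ["log_ratio"]) - set(df.columns)
        if missing:
            raise ValueError(f"{name} table missing columns {sorted(missing)}")
    t = tumor.reset_index(drop=True)
    n = matched_normal.reset_index(drop=True)
    if len(t) != len(n) or not t[key].equals(n[key]):
        raise ValueError("tumor and normal tables are on different segment grids")
    out = t.copy()
    out["log_ratio"] = t["log_ratio"].to_numpy() - n["log_ratio"].to_numpy()
    return out


def assign_integer_cn(segments: list[Segment], ctx: CopyNumberContext) -> list[Segment]:
    """Set ``integer_cn`` on every segment from its log ratio (in place)."""
    for seg in segments:
        seg.integer_cn = integer_copy_number(seg.log_ratio, ctx)
    return segments


def filter_samples(sheet: pd.DataFrame, purity_max_excluded: float = 0.20,
                   cellularity_max_excluded: float = 20.0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a sample sheet into retained and excluded samples.

    Excluded when purity is missing (could not be estimated), purity is at or
    below 0.20, or tumor cellularity is at or below 20%. The excluded table
    carries a ``reason`` column.
    """
    reasons = []
    for _, row in sheet.iterrows():
        purity = row.get("purity", np.nan)
        cellularity = row.get("cellularity", np.nan)
        if pd.isna(purity):
            reasons.append("purity_missing")
        elif purity <= purity_max_excluded:
            reasons.append("purity_low")
        elif not pd.isna(cellularity) and cellularity <= cellularity_max_excluded:
            reasons.append("cellularity_low")
        else:
            reasons.append("")
    reasons = pd.Series(reasons, index=sheet.index, name="reason")
    retained = sheet[reasons == ""].copy()
    excluded = sheet[reasons != ""].copy()
    excluded["reason"] = reasons[reasons != ""]
    return retained, excluded


def _pairs_supporting_deletion(segment: Segment, pairs: list[ImproperPairRecord],
                               flank: int = DELETION_FLANK_BP) -> int:
    """Count improper pairs consistent with deletion of ``segment``.

    Consistent means deletion-type orientation (ends pointing inward, "+-")
    with one breakend within ``flank`` of each segment end, on the segment's
    chromosome.
    """
    n = 0
    for rec in pairs:
        if rec.chrom1 != segment.chromosome or rec.chrom2 != segment.chromosome:
            continue
        if rec.orientation != "+-":
            continue
        left_ok = abs(rec.start1 - segment.start) <= flank or abs(rec.end1 - segment.start) <= flank
        right_ok = abs(rec.start2 - segment.end) <= flank or abs(rec.end2 - segment.end) <= flank
        if left_ok and right_ok:
            n += rec.n_pairs
    return n


def call_focal_deletions(segments: list[Segment], pairs: list[ImproperPairRecord],
                         max_length: int = FOCAL_DELETION_MAX_BP,
                         flank: int = DELETION_FLANK_BP) -> list[DeletionCall]:
    """Call focal deletions: segments < 3 Mb with integer copy number 0 or 1.

    ``supported`` is True (the "+" designation, e.g. homozygous+) when two
    or more improper read pairs have alignments consistent with the
    deletion.
    """
    calls = []
    for seg in segments:
        if seg.integer_cn is None:
            raise ValueError("integer_cn must be assigned before deletion calling")
        if seg.length >= max_length or seg.integer_cn not in (0, 1):
            continue
        zygosity = "homozygous" if seg.integer_cn == 0 else "hemizygous"
        supported = _pairs_supporting_deletion(seg, pairs, flank) >= 2
        calls.append(DeletionCall(segment=seg, zygosity=zygosity, supported=supported))
    return calls


def seed_amplicons(segments: list[Segment], ctx: CopyNumberContext) -> list[Segment]:
    """High-copy focal amplifications: copy number strictly > 2.5x average ploidy."""
    out = []
    for seg in segments:
        if seg.integer_cn is None:
            raise ValueError("integer_cn must be assigned before amplicon seeding")
        if seg.integer_cn > 2.5 * ctx.tumor_ploidy:
            out.append(seg)
    return out


def _seg_key(seg: Segment) -> tuple[str, int, int]:
    return (seg.chromosome, seg.start, seg.end)


def _breakend_in(chrom: str, start: int, end: int, seg: Segment) -> bool:
    return chrom == seg.chromosome and start < seg.end and end > seg.start


def _bridging_pairs(a: Segment, b: Segment, pairs: list[ImproperPairRecord]) -> int:
    n = 0
    for rec in pairs:
        fwd = (_breakend_in(rec.chrom1, rec.start1, rec.end1, a)
               and _breakend_in(rec.chrom2, rec.start2, rec.end2, b))
        rev = (_breakend_in(rec.chrom1, rec.start1, rec.end1, b)
               and _breakend_in(rec.chrom2, rec.start2, rec.end2, a))
        if fwd or rev:
            n += rec.n_pairs
    return n


def link_amplicons(seeds: list[Segment], segments: list[Segment],
                   pairs: list[ImproperPairRecord], ctx: CopyNumberContext) -> nx.Graph:
    """Build the linked-amplicon graph.

    Nodes are seed segments plus low-copy gains (copy number >= 1.5x average
    ploidy) that are bridged by >= 2 improper read pairs into a seed's
    component, directly or through other linked candidates. Candidates
    without a path to any seed are dropped. Node attributes: ``copies``,
    ``chrom``, ``seed``; edge attribute: ``n_bridging_pairs``.
    """
    seed_keys = {_seg_key(s) for s in seeds}
    candidates = [
        seg for seg in segments
        if _seg_key(seg) not in seed_keys
        and seg.integer_cn is not None
        and seg.integer_cn >= 1.5 * ctx.tumor_ploidy
    ]
    graph = nx.Graph()
    members = list(seeds) + candidates
    for seg in members:
        graph.add_node(_seg_key(seg), copies=seg.integer_cn, chrom=seg.chromosome,
                       seed=_seg_key(seg) in seed_keys)
    for i, a in enumerate(members):
        for b in members[i + 1:]:
            n = _bridging_pairs(a, b, pairs)
            if n >= 2:
                graph.add_edge(_seg_key(a), _seg_key(b), n_bridging_pairs=n)
    # keep only components that contain a seed; drop unconnected candidates
    keep: set[tuple[str, int, int]] = set()
    for comp in nx.connected_components(graph):
        if any(graph.nodes[n]["seed"] for n in comp):
            keep |= comp
    graph.remove_nodes_from([n for n in graph.nodes if n not in keep])
    _check_amplicon_invariants(graph)
    return graph


def _check_amplicon_invariants(graph: nx.Graph) -> None:
    for _, _, data in graph.edges(data=True):
        if data["n_bridging_pairs"] < 2:
            raise AssertionError("amplicon edge with < 2 bridging pairs")
    for comp in nx.connected_components(graph):
        if not any(graph.nodes[n]["seed"] for n in comp):
            raise AssertionError("amplicon component without a seed")


def _breakends_overlap(a: ImproperPairRecord, b: ImproperPairRecord,
                       window: int = NORMAL_OVERLAP_BP) -> bool:
    def near(c1, s1, e1, c2, s2, e2):
        return c1 == c2 and s1 < e2 + window and e1 > s2 - window

    fwd = (near(a.chrom1, a.start1, a.end1, b.chrom1, b.start1, b.end1)
           and near(a.chrom2, a.start2, a.end2, b.chrom2, b.start2, b.end2))
    rev = (near(a.chrom1, a.start1, a.end1, b.chrom2, b.start2, b.end2)
           and near(a.chrom2, a.start2, a.end2, b.chrom1, b.start1, b.end1))
    return fwd or rev


def call_rearrangements(tumor_pairs: list[ImproperPairRecord],
                        normal_pairs: list[ImproperPairRecord],
                        window: int = NORMAL_OVERLAP_BP) -> list[ImproperPairRecord]:
    """Call rearrangements: >= 2 improper pairs and >= 1 split read.

    Events whose both breakends overlap (within ``window``) an event seen in
    the matched normal are excluded as germline or artifact.
    """
    calls = []
    for rec in tumor_pairs:
        if rec.n_pairs < 2 or rec.n_split < 1:
            continue
        if any(_breakends_overlap(rec, nrm, window) for nrm in normal_pairs):
            continue
        calls.append(rec)
    return calls
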