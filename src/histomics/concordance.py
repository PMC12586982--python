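"""Sample matching by genotype concordance at sampled SNP sites.

When several tissue samples exist per patient, sample swaps and labeling
errors are detected by comparing consensus genotypes at a shared panel of
biallelic SNP positions. A site is evaluable in a sample when it has at
least ``min_depth`` qualified reads and at least ``min_fraction`` of them
support one base; a pair's concordance is the fraction of jointly evaluable
sites whose consensus bases agree. Pairs drawn at random between unrelated
samples give a null distribution; a pair is genotype-matched when its
concordance is an outlier above Q3 + 1.5*IQR of that null.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PileupPanel",
    "ConcordanceResult",
    "NullSummary",
    "select_snp_sites",
    "site_consensus",
    "panel_consensus",
    "pair_concordance",
    "all_pair_concordances",
    "concordance_null",
    "match_samples",
]

BASES = np.array(["A", "C", "G", "T"])


@dataclass
class PileupPanel:
    """Base counts for one sample at the shared SNP site panel.

    ``counts`` is an (n_sites, 4) array of qualified-read counts in A,C,G,T
    order; ``sites`` is the shared panel table (chrom, pos, 1-based).
    """

    sample_id: str
    sites: pd.DataFrame
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.sites), 4):
            raise ValueError("counts must be (n_sites, 4)")
        if (self.counts < 0).any():
            raise ValueError("negative read counts")


@dataclass(frozen=True)
class ConcordanceResult:
    sample_a: str
    sample_b: str
    n_evaluated: int
    n_matched: int

    @property
    def concordance(self) -> float:
        if self.n_evaluated == 0:
            return float("nan")

        return self.n_matched / self.n_evaluated

    @property
    def comparable(self) -> bool:
        return self.n_evaluated > 0


@dataclass(frozen=True)
class NullSummary:
    """Quartile summary of the unrelated-pair concordance null."""

    q1: float
    q3: float
    n_pairs: int
    quartile_method: str = "linear"

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1

    @property
    def threshold(self) -> float:
        return self.q3 + 1.5 * self.iqr


def select_snp_sites(catalog: pd.DataFrame, n: int = 10_000, seed: int = 0,
                     class_column: str = "variant_class",
                     substitution_class: str = "single") -> pd.DataFrame:
    """Retain single-base substitution sites and sample ``n`` without replacement."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if class_column not in catalog.columns:
        raise ValueError(f"catalog lacks a {class_column!r} column")
    eligible = catalog[catalog[class_column] == substitution_class]
    if len(eligible) < n:
        raise ValueError(f"only {len(eligible)} eligible sites for n={n}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(eligible), size=n, replace=False)
    return eligible.iloc[np.sort(idx)].reset_index(drop=True)


def site_consensus(counts: np.ndarray, min_depth: int = 20,
                   min_fraction: float = 0.95) -> str | None:
    """Consensus base at one site, or None when not evaluable.

    Evaluable iff depth >= min_depth and the majority base holds at least
    ``min_fraction`` of reads (boundary inclusive).
    """
    counts = np.asarray(counts)
    depth = counts.sum()
    if depth < min_depth:
        return None
    top = counts.max()
    if top / depth < min_fraction:
        return None
    return str(BASES[int(counts.argmax())])


def panel_consensus(panel: PileupPanel, min_depth: int = 20,
                    min_fraction: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized consensus for every site of a panel.

    Returns ``(consensus, evaluable)``: consensus is an int8 array of base
    indices (A=0..T=3, meaningful only where evaluable is True).
    """
    depth = panel.counts.sum(axis=1)
    top = panel.counts.max(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(depth > 0, top / np.maximum(depth, 1), 0.0)
    evaluable = (depth >= min_depth) & (frac >= min_fraction)
    consensus = panel.counts.argmax(axis=1).astype(np.int8)
    return consensus, evaluable


def pair_concordance(a: PileupPanel, b: PileupPanel, min_depth: int = 20,
                     min_fraction: float = 0.95) -> ConcordanceResult:
    """Concordance of two panels over their jointly evaluable sites."""
    if len(a.sites) != len(b.sites):
        raise ValueError("panels are on different site panels")
    ca, ea = panel_consensus(a, min_depth, min_fraction)
    cb, eb = panel_consensus(b, min_depth, min_fraction)
    joint = ea & eb
    matched = int((joint & (ca == cb)).sum())
    return ConcordanceResult(a.sample_id, b.sample_id, int(joint.sum()), matched)


def all_pair_concordances(panels: list[PileupPanel], min_depth: int = 20,
                          min_fraction: float = 0.95) -> list[ConcordanceResult]:
    """All unordered pairwise concordances, computed with one matrix pass.

    Equivalent to calling :func:`pair_concordance` on every pair but O(k)
    matrix products instead of O(m^2) site loops.
    """
    m = len(panels)
    cons = np.empty((m, len(panels[0].sites)), dtype=np.int8)
    evalu = np.empty_like(cons, dtype=bool)
    for i, p in enumerate(panels):
        cons[i], evalu[i] = panel_consensus(p, min_depth, min_fraction)
    n_eval = evalu.astype(np.float32) @ evalu.astype(np.float32).T
    n_match = np.zeros((m, m), dtype=np.float32)
    for base in range(4):
        hot = (evalu & (cons == base)).astype(np.float32)
        n_match += hot @ hot.T
    out = []
    for i, j in itertools.combinations(range(m), 2):
        out.append(ConcordanceResult(panels[i].sample_id, panels[j].sample_id,
                                     int(round(n_eval[i, j])), int(round(n_match[i, j]))))
    return out


def concordance_null(results: list[ConcordanceResult], n_pairs: int = 1_000,
                     seed: int = 0,
                     exclude: set[frozenset[str]] | None = None) -> NullSummary:
    """Quartile summary of concordance over randomly sampled unrelated pairs.

    ``exclude`` lists known/annotated pairs (as frozensets of two sample
    ids) that must not enter the null; including true pairs would inflate
    the upper quartile and the outlier threshold.
    """
    if n_pairs < 10:
        raise ValueError("n_pairs must be >= 10")
    exclude = exclude or set()
    pool = [r for r in results
            if r.comparable and frozenset((r.sample_a, r.sample_b)) not in exclude]
    if len(pool) < 2:
        raise ValueError("too few distinct comparable pairs for a null")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(pool), size=n_pairs)
    values = np.array([pool[i].concordance for i in idx])
    q1, q3 = np.percentile(values, [25, 75], method="linear")
    return NullSummary(q1=float(q1), q3=float(q3), n_pairs=n_pairs)


def match_samples(results: list[ConcordanceResult], null: NullSummary,
                  annotations: pd.DataFrame,
                  ambiguity_margin: float | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Genotype-match samples against the null threshold.

    ``annotations`` must carry sample_id, patient_id and tumor_type columns.
    Returns ``(matches, exclusions)``:

    * a pair is genotype-matched when its concordance strictly exceeds the
      null threshold and each sample is the other's best above-threshold
      partner; the genotype match overrides annotation;
    * a sample whose runner-up partner comes within ``ambiguity_margin`` of
      its best partner (default 1.5x the null IQR, the same dispersion
      scale as the outlier rule) is ambiguous and excluded — with many
      thousands of unrelated pairs a few necessarily straggle over the
      threshold, and only competitors indistinguishable within the null's
      dispersion genuinely confound the pairing;
    * matched pairs whose annotated tumor types differ are both excluded;
    * samples with no genotype match are excluded.
    """
    required = {"sample_id", "patient_id", "tumor_type"}
    if not required <= set(annotations.columns):
        raise ValueError(f"annotations must carry columns {sorted(required)}")
    ann = annotations.set_index("sample_id")
    thr = null.threshold
    if ambiguity_margin is None:
        ambiguity_margin = 1.5 * null.iqr

    partners: dict[str, list[tuple[str, float]]] = {s: [] for s in ann.index}
    for r in results:
        if not r.comparable or r.concordance <= thr:
            continue
        partners.setdefault(r.sample_a, []).append((r.sample_b, r.concordance))
        partners.setdefault(r.sample_b, []).append((r.sample_a, r.concordance))
    for s in partners:
        partners[s].sort(key=lambda pc: -pc[1])

    def best(s: str) -> str | None:
        return partners[s][0][0] if partners.get(s) else None

    match_rows, excl_rows = [], []
    ambiguous = {
        s for s, ps in partners.items()
        if len(ps) > 1 and ps[1][1] >= ps[0][1] - ambiguity_margin
    }
    for s in sorted(ambiguous):
        excl_rows.append({"sample_id": s, "reason": "ambiguous_multiple_matches"})

    seen_pairs: set[frozenset[str]] = set()
    for s, ps in sorted(partners.items()):
        if s in ambiguous:
            continue
        if not ps:
            excl_rows.append({"sample_id": s, "reason": "no_genotype_match"})
            continue
        partner, conc = ps[0]
        if partner in ambiguous:
            excl_rows.append({"sample_id": s, "reason": "partner_ambiguous"})
            continue
        if best(partner) != s:
            excl_rows.append({"sample_id": s, "reason": "no_reciprocal_match"})
            continue
        pair = frozenset((s, partner))
        if pair in seen_pairs:
            continue
        seen_pairs.add(pair)
        type_a = ann.loc[s, "tumor_type"] if s in ann.index else None
        type_b = ann.loc[partner, "tumor_type"] if partner in ann.index else None
        if type_a is not None and type_b is not None and type_a != type_b:
            excl_rows.append({"sample_id": s, "reason": "tumor_type_mismatch"})
            excl_rows.append({"sample_id": partner, "reason": "tumor_type_mismatch"})
            continue
        annotated = (s in ann.index and partner in ann.index
                     and ann.loc[s, "patient_id"] == ann.loc[partner, "patient_id"])
        match_rows.append({"sample_a": s, "sample_b": partner,
                           "concordance": conc, "annotation_agrees": annotated})

    matches = pd.DataFrame(match_rows, columns=["sample_a", "sample_b",
                                                "concordance", "annotation_agrees"])
    exclusions = pd.DataFrame(excl_rows, columns=["sample_id", "reason"])
    return matches, exclusions
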