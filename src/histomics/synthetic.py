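"""Synthetic cohorts with known ground truth for every pipeline stage.

Each generator forward-simulates the data model its downstream stage
assumes, so recovery can be checked exactly:

* pileup panels — biallelic SNP sites with allele frequency ~ U(0.05, 0.5),
  Hardy-Weinberg genotypes per individual, Poisson read depth and a
  per-read error rate; duplicated individuals yield two panels from the
  same genotypes (the "matched tumor/normal" a swap check must find);
* copy-number cohorts — piecewise-constant integer copy states mixed with
  normal cells at a stated purity, Gaussian log-ratio noise, and discordant
  read-pair records supporting the deletions and amplicon links;
* alteration matrices — per-group Bernoulli gene alterations at stated
  theta, with a fraction of samples inflated past the hypermutator
  threshold;
* beta matrices — three-class methylation profiles with an informative
  probe block shifted per class and annotation columns for probe filters;
* survival tables — exponential event times under a group hazard ratio
  with independent exponential censoring.

A single integer seed drives everything through named substreams
(:mod:`histomics._rng`), so identical arguments reproduce byte-identical
cohorts and adding a new generator never perturbs existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import substream
from .concordance import PileupPanel
from .cnv import CopyNumberContext, ImproperPairRecord, Segment, expected_logr
from .methylome import BetaMatrix
from .prevalence import GeneAlterationMatrix, flag_hypermutators

__all__ = [
    "CohortTruth",
    "PileupCohort",
    "CnCohort",
    "make_pileup_cohort",
    "make_cn_cohort",
    "make_alteration_cohort",
    "make_beta_cohort",
    "make_survival_cohort",
    "make_sv_fixture",
]


@dataclass
class CohortTruth:
    """Ground truth emitted alongside each synthetic cohort."""

    pair_map: dict[str, str] = field(default_factory=dict)  # tumor id -> normal id
    cn_truth: list[tuple[tuple[str, int, int], int]] = field(default_factory=list)
    theta_truth: pd.DataFrame | None = None  # gene x group alteration probability
    class_labels: pd.Series | None = None  # sample -> tissue class
    hazard_ratio: float | None = None

    def __post_init__(self) -> None:
        if self.theta_truth is not None:
            v = self.theta_truth.to_numpy()
            if ((v < 0) | (v > 1)).any():
                raise ValueError("theta_truth values must lie in [0, 1]")
        if self.hazard_ratio is not None and self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be positive")


@dataclass
class PileupCohort:
    panels: list[PileupPanel]
    sample_sheet: pd.DataFrame
    catalog: pd.DataFrame  # SNP site catalog incl. variant_class column
    truth: CohortTruth


@dataclass
class CnCohort:
    segments: list[Segment]
    bedpe: list[ImproperPairRecord]
    ctx: CopyNumberContext
    truth: CohortTruth


def make_pileup_cohort(n_individuals: int, n_sites: int = 10_000,
                       depth_mean: float = 50.0, error_rate: float = 0.01,
                       n_duplicated: int = 0, seed: int = 0) -> PileupCohort:
    """Simulate pileup panels at a shared biallelic SNP panel.

    The first ``n_duplicated`` individuals contribute two panels each
    (suffixes ``_T`` and ``_N``) drawn independently from the same
    genotypes; all other individuals contribute one panel. Reads are
    Poisson(``depth_mean``) per site and carry the wrong base with
    probability ``error_rate`` (uniform over the three other bases).
    """
    if n_individuals < 1 or n_sites < 1:
        raise ValueError("counts must be positive")
    if not 0 <= error_rate < 0.5:
        raise ValueError("error_rate must lie in [0, 0.5)")
    if n_duplicated > n_individuals:
        raise ValueError("n_duplicated cannot exceed n_individuals")
    rng = substream(seed, "pileup")

    # site catalog: biallelic substitutions with AF ~ U(0.05, 0.5)
    af = rng.uniform(0.05, 0.5, size=n_sites)
    ref = rng.integers(0, 4, size=n_sites)
    alt = (ref + rng.integers(1, 4, size=n_sites)) % 4
    sites = pd.DataFrame({
        "chrom": "chr1",
        "pos": np.arange(1, n_sites + 1) * 1_000,
        "variant_class": "single",
    })

    # HWE genotypes: number of alt alleles per individual per site
    geno = rng.binomial(2, af[None, :], size=(n_individuals, n_sites))

    panels: list[PileupPanel] = []
    sheet_rows = []
    pair_map: dict[str, str] = {}

    def draw_panel(sample_id: str, g: np.ndarray) -> PileupPanel:
        depth = rng.poisson(depth_mean, size=n_sites)
        p_alt = g / 2.0
        pvals = np.full((n_sites, 4), error_rate / 3.0)
        rows = np.arange(n_sites)
        pvals[rows, ref] = (1 - p_alt) * (1 - error_rate) + p_alt * error_rate / 3.0
        pvals[rows, alt] = p_alt * (1 - error_rate) + (1 - p_alt) * error_rate / 3.0
        pvals /= pvals.sum(axis=1, keepdims=True)
        counts = rng.multinomial(depth, pvals)
        return PileupPanel(sample_id=sample_id, sites=sites, counts=counts)

    for i in range(n_individuals):
        patient = f"PT{i:04d}"
        tumor_id = f"{patient}_T"
        panels.append(draw_panel(tumor_id, geno[i]))
        sheet_rows.append({"sample_id": tumor_id, "patient_id": patient,
                           "tumor_type": "carcinoma"})
        if i < n_duplicated:
            normal_id = f"{patient}_N"
            panels.append(draw_panel(normal_id, geno[i]))
            sheet_rows.append({"sample_id": normal_id, "patient_id": patient,
                               "tumor_type": "carcinoma"})
            pair_map[tumor_id] = normal_id

    return PileupCohort(
        panels=panels,
        sample_sheet=pd.DataFrame(sheet_rows),
        catalog=sites,
        truth=CohortTruth(pair_map=pair_map),
    )


def make_cn_cohort(n_segments: int = 12, purity: float = 0.6,
                   tumor_ploidy: float = 2.0, copy_states=(0, 1, 2, 3, 4, 6),
                   noise_sd: float = 0.05, sv_support: int = 2,
                   seed: int = 0) -> CnCohort:
    """Simulate one sample's segment table and supporting BEDPE records.

    Segment copy states cycle through ``copy_states``. Deletion states (0/1)
    get focal segments (< 3 Mb); all others get broad segments, except
    amplifications beyond 2.5x ploidy, which are focal as well. Every
    deletion receives ``sv_support`` inward-facing improper pairs at its
    ends, and every low-copy gain (>= 1.5x ploidy, not a seed) is bridged to
    the first seed by ``sv_support`` pairs.
    """
    if not 0 < purity <= 1:
        raise ValueError("purity must lie in (0, 1]")
    if any(c < 0 for c in copy_states):
        raise ValueError("copy states must be non-negative")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = substream(seed, "cn")
    ctx = CopyNumberContext(purity=purity, tumor_ploidy=tumor_ploidy)

    states = [copy_states[i % len(copy_states)] for i in range(n_segments)]
    segments: list[Segment] = []
    pos = 0
    gap = 100_000
    for i, c in enumerate(states):
        focal = c in (0, 1) or c > 2.5 * tumor_ploidy
        length = int(rng.uniform(1e6, 2.5e6)) if focal else int(rng.uniform(5e6, 1e7))
        r = expected_logr(c, ctx)
        if np.isfinite(r):
            r += rng.normal(0, noise_sd) if noise_sd > 0 else 0.0
        segments.append(Segment(chromosome="chr1", start=pos, end=pos + length,
                                log_ratio=r, n_markers=max(10, length // 50_000)))
        pos += length + gap

    bedpe: list[ImproperPairRecord] = []
    for seg, c in zip(segments, states):
        if c in (0, 1) and seg.length < 3_000_000 and sv_support > 0:
            bedpe.append(ImproperPairRecord(
                chrom1=seg.chromosome, start1=seg.start - 200, end1=seg.start,
                chrom2=seg.chromosome, start2=seg.end, end2=seg.end + 200,
                orientation="+-", n_pairs=sv_support, n_split=1))
    seeds = [s for s, c in zip(segments, states) if c > 2.5 * tumor_ploidy]
    if seeds and sv_support > 0:
        anchor = seeds[0]
        for seg, c in zip(segments, states):
            if seg is anchor or c <= 1.5 * tumor_ploidy or c > 2.5 * tumor_ploidy:
                continue
            bedpe.append(ImproperPairRecord(
                chrom1=anchor.chromosome, start1=anchor.start + 100,
                end1=anchor.start + 300,
                chrom2=seg.chromosome, start2=seg.start + 100, end2=seg.start + 300,
                orientation="++", n_pairs=sv_support, n_split=1))

    truth = CohortTruth(cn_truth=[((s.chromosome, s.start, s.end), int(c))
                                  for s, c in zip(segments, states)])
    return CnCohort(segments=segments, bedpe=bedpe, ctx=ctx, truth=truth)


def make_alteration_cohort(theta_by_group: pd.DataFrame, n_per_group: dict[str, int],
                           hypermutator_fraction: float = 0.0,
                           seed: int = 0) -> tuple[GeneAlterationMatrix, CohortTruth]:
    """Simulate a binary gene x sample alteration matrix for two groups.

    ``theta_by_group`` is genes x groups (exactly two columns; the first is
    the reference group, dummy 0). Each entry of the matrix is
    Bernoulli(theta[gene, group]). A ``hypermutator_fraction`` of each
    group's samples gets a per-exome mutation count inflated past the
    hypermutator threshold; the rest sit near the cohort's typical burden.
    """
    v = theta_by_group.to_numpy()
    if ((v < 0) | (v > 1)).any():
        raise ValueError("theta values must lie in [0, 1]")
    if theta_by_group.shape[1] != 2:
        raise ValueError("theta_by_group must have exactly two group columns")
    if any(n < 1 for n in n_per_group.values()):
        raise ValueError("each group needs at least one sample")
    rng = substream(seed, "alteration")

    cols, groups = [], []
    blocks = []
    for dummy, group in enumerate(theta_by_group.columns):
        n = n_per_group[group]
        theta = theta_by_group[group].to_numpy()[:, None]
        blocks.append(rng.random((len(theta_by_group), n)) < theta)
        cols += [f"{group}_{i:03d}" for i in range(n)]
        groups += [dummy] * n
    data = pd.DataFrame(np.concatenate(blocks, axis=1).astype(np.int8),
                        index=theta_by_group.index, columns=cols)

    # typical exome burden ~ 54 mutations; hypermutators are inflated well
    # past the 500-mutation threshold (MMR/POLE-like), theta untouched
    counts = rng.poisson(54, size=len(cols)).astype(int)
    n_hyper = int(round(hypermutator_fraction * len(cols)))
    if n_hyper:
        hyper_idx = rng.choice(len(cols), size=n_hyper, replace=False)
        counts[hyper_idx] = 501 + rng.poisson(2_000, size=n_hyper)
    counts = pd.Series(counts, index=cols, name="mutation_count")

    matrix = GeneAlterationMatrix(
        data=data, groups=pd.Series(groups, index=cols, name="group"),
        mutation_counts=counts, hypermutator=flag_hypermutators(counts),
    )
    return matrix, CohortTruth(theta_truth=theta_by_group)


def make_beta_cohort(classes, n_per_class: dict[str, int], n_probes: int = 2_000,
                     n_informative: int = 500, effect: float = 0.3,
                     seed: int = 0) -> tuple[BetaMatrix, pd.Series, CohortTruth]:
    """Simulate a three-class (or k-class) methylation beta matrix.

    Uninformative probes share one Beta distribution across classes; each
    informative probe is assigned a marker class whose samples have the
    probe's mean shifted by ``effect`` (clipped into (0, 1)). Probe
    annotations (autosomal chromosome, zero SNP MAF, small detection p) pass
    the standard probe filters.
    """
    if n_informative > n_probes:
        raise ValueError("n_informative cannot exceed n_probes")
    classes = list(classes)
    rng = substream(seed, "beta")
    concentration = 20.0

    base_mean = rng.uniform(0.15, 0.85, size=n_probes)
    marker_class = rng.integers(0, len(classes), size=n_informative)

    sample_ids, labels = [], []
    for c in classes:
        n = n_per_class[c]
        sample_ids += [f"{c}_{i:03d}" for i in range(n)]
        labels += [c] * n
    labels = pd.Series(labels, index=sample_ids, name="tissue_class")

    values = np.empty((n_probes, len(sample_ids)))
    for j, c in enumerate(labels):
        mean = base_mean.copy()
        ci = classes.index(c)
        shift_dir = np.where(base_mean[:n_informative] < 0.5, 1.0, -1.0)
        mean[:n_informative] = np.where(
            marker_class == ci,
            np.clip(base_mean[:n_informative] + effect * shift_dir, 0.02, 0.98),
            base_mean[:n_informative])
        a = mean * concentration
        b = (1 - mean) * concentration
        values[:, j] = rng.beta(a, b)

    probe_ids = [f"cg{i:07d}" for i in range(n_probes)]
    annotations = pd.DataFrame({
        "chrom": [f"chr{1 + i % 22}" for i in range(n_probes)],
        "maf": 0.0,
        "detection_p": rng.uniform(0, 0.01, size=n_probes),
    }, index=pd.Index(probe_ids, name="probe_id"))
    matrix = BetaMatrix(values=pd.DataFrame(values, index=probe_ids, columns=sample_ids),
                        annotations=annotations)
    return matrix, labels, CohortTruth(class_labels=labels)


def make_sv_fixture() -> dict:
    """A deterministic 12-segment / 9-pair-record structural-variant fixture.

    Every copy-number, size, orientation and evidence threshold of the
    calling rules is exercised at least once, and the exact expected call
    set is enumerated by hand in ``truth``:

    ======= ========== ====== ==========================================
    segment coordinates copies role
    ======= ========== ====== ==========================================
    A       chr1 1-3 Mb   0   focal homozygous deletion, 2 pairs -> "+"
    B       chr1 3.1-4.2  1   focal hemizygous deletion, 1 pair only
    C       chr1 5-8.5    1   3.5 Mb: too large, no deletion call
    D       chr1 9-10     0   focal homozygous deletion, no pairs
    E       chr1 11-12    2   neutral
    F       chr1 13-14    6   amplicon seed (6 > 2.5 x 2)
    G       chr1 15-16    5   not a seed (5 is not > 5); linked gain
    H       chr1 17-18    4   gain with only 1 bridging pair: dropped
    I       chr1 19-20    3   gain linked transitively through G
    J       chr1 21-22    7   isolated seed, singleton component
    K       chr1 23-24    2   neutral
    L       chr2 1-2      1   hemizygous; 2 pairs but wrong orientation
    ======= ========== ====== ==========================================

    The tumor pair records also cover the rearrangement rules (>= 2 pairs
    and >= 1 split read, matched-normal overlap exclusion).
    """
    ctx = CopyNumberContext(purity=1.0, tumor_ploidy=2.0)
    layout = [
        ("A", "chr1", 1_000_000, 3_000_000, 0),
        ("B", "chr1", 3_100_000, 4_200_000, 1),
        ("C", "chr1", 5_000_000, 8_500_000, 1),
        ("D", "chr1", 9_000_000, 10_000_000, 0),
        ("E", "chr1", 11_000_000, 12_000_000, 2),
        ("F", "chr1", 13_000_000, 14_000_000, 6),
        ("G", "chr1", 15_000_000, 16_000_000, 5),
        ("H", "chr1", 17_000_000, 18_000_000, 4),
        ("I", "chr1", 19_000_000, 20_000_000, 3),
        ("J", "chr1", 21_000_000, 22_000_000, 7),
        ("K", "chr1", 23_000_000, 24_000_000, 2),
        ("L", "chr2", 1_000_000, 2_000_000, 1),
    ]
    segments = {name: Segment(chromosome=chrom, start=s, end=e,
                              log_ratio=expected_logr(c, ctx))
                for name, chrom, s, e, c in layout}
    P = ImproperPairRecord
    tumor_pairs = [
        # deletion support for A (2 inward pairs + split): also a rearrangement
        P("chr1", 999_800, 1_000_000, "chr1", 3_000_000, 3_000_200, "+-", 2, 1),
        # B: a single pair is below the support threshold
        P("chr1", 3_099_900, 3_100_000, "chr1", 4_200_000, 4_200_100, "+-", 1, 0),
        # L: enough pairs but not deletion-type orientation; still a rearrangement
        P("chr2", 999_900, 1_000_000, "chr2", 2_000_000, 2_000_100, "++", 2, 1),
        # F-G amplicon bridge (2 pairs, no split: not a rearrangement)
        P("chr1", 13_100_000, 13_100_500, "chr1", 15_100_000, 15_100_500, "++", 2, 0),
        # F-H bridge with only 1 pair: H stays unlinked
        P("chr1", 13_200_000, 13_200_500, "chr1", 17_100_000, 17_100_500, "++", 1, 0),
        # G-I bridge: links I transitively to seed F; also a rearrangement
        P("chr1", 15_200_000, 15_200_500, "chr1", 19_100_000, 19_100_500, "++", 2, 1),
        # rearrangement between neutral segments
        P("chr1", 11_100_000, 11_100_500, "chr1", 23_100_000, 23_100_500, "++", 2, 1),
        # rearrangement that also appears in the matched normal: excluded
        P("chr1", 30_000_000, 30_000_500, "chr1", 40_000_000, 40_000_500, "++", 2, 1),
        # enough pairs but no split read: not called
        P("chr1", 50_000_000, 50_000_500, "chr1", 60_000_000, 60_000_500, "++", 3, 0),
    ]
    normal_pairs = [
        P("chr1", 30_000_100, 30_000_400, "chr1", 40_000_100, 40_000_400, "++", 5, 2),
    ]
    truth = {
        "integer_cn": {name: c for name, _, _, _, c in layout},
        "deletions": {  # segment -> (zygosity, supported)
            "A": ("homozygous", True),
            "B": ("hemizygous", False),
            "D": ("homozygous", False),
            "L": ("hemizygous", False),
        },
        "seeds": {"F", "J"},
        "graph_nodes": {"F", "G", "I", "J"},
        "graph_edges": {frozenset(("F", "G")): 2, frozenset(("G", "I")): 2},
        "rearrangement_indices": [0, 2, 5, 6],  # into tumor_pairs
    }
    return {"segments": segments, "tumor_pairs": tumor_pairs,
            "normal_pairs": normal_pairs, "ctx": ctx, "truth": truth}


def make_survival_cohort(n: int = 100, baseline_rate: float = 1.0 / 1000,
                         hazard_ratio: float = 1.0, censor_rate: float = 1.0 / 2000,
                         seed: int = 0) -> pd.DataFrame:
    """Simulate exponential survival with a binary group hazard ratio.

    Group 1 ("altered") has event rate ``baseline_rate * hazard_ratio``.
    Censoring times are exponential at ``censor_rate``; a rate of exactly 0
    means administrative follow-up never ends (no censoring).
    """
    if baseline_rate <= 0 or hazard_ratio <= 0:
        raise ValueError("rates and hazard ratio must be positive")
    if censor_rate < 0:
        raise ValueError("censor_rate must be non-negative")
    rng = substream(seed, "survival")
    group = rng.integers(0, 2, size=n)
    rate = baseline_rate * hazard_ratio**group
    t_event = rng.exponential(1.0 / rate)
    t_censor = (rng.exponential(1.0 / censor_rate, size=n) if censor_rate > 0
                else np.full(n, np.inf))
    time = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)
    return pd.DataFrame({
        "sample_id": [f"S{i:04d}" for i in range(n)],
        "time": time,
        "event": event,
        "group": np.where(group == 1, "altered", "unaltered"),
    })
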