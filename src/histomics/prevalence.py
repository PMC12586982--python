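"""Gene-level alteration integration and Bayesian prevalence comparison.

Sequence and structural alterations (mutations, focal deletions, amplicon
membership, rearrangement breakends) are integrated into a binary gene x
sample matrix. For each driver gene altered in at least 10% of the combined
cohort, the difference in alteration prevalence between two histology groups
is modeled as

    y_j ~ Binomial(theta_j, n_j),    logit(theta_j) = alpha0 + alpha1 * x_j

with priors alpha0 ~ Normal(0, sd=10) and alpha1 ~ Laplace(0, scale=1),
where x_j is 0 for the reference group and 1 for the comparator. The log
odds ratio (LOR) is reported as log-odds(reference) - log-odds(comparator),
i.e. -alpha1, so a positive LOR means the alteration is more prevalent in
the reference (first-named) group. 90% credible intervals are the 5th and
95th posterior percentiles. A gene is significantly different when that
interval excludes zero.

Two posterior routes are provided: an adaptive random-walk Metropolis
sampler (:func:`fit_prevalence`) and a deterministic 2-D trapezoidal
quadrature (:func:`quadrature_posterior`) that serves as its oracle.

A Monte-Carlo null converts the *number* of significant genes into a
multiplicity-aware p-value: binarize a reps x P matrix of Uniform(0,1)
deviates at alpha and count rows with at least the observed number of hits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "PrevalenceCounts",
    "PosteriorFit",
    "GeneAlterationMatrix",
    "HYPERMUTATOR_THRESHOLD",
    "filter_candidate_mutations",
    "flag_hypermutators",
    "build_alteration_matrix",
    "select_comparison_genes",
    "fit_prevalence",
    "quadrature_posterior",
    "count_significance_null",
    "flag_significant_genes",
    "proportion_ci",
]

#: more than this many mutations per exome marks a hypermutator
HYPERMUTATOR_THRESHOLD = 500


@dataclass(frozen=True)
class PrevalenceCounts:
    """Altered / total sample counts for the two groups (0 = reference)."""

    y0: int
    n0: int
    y1: int
    n1: int

    def __post_init__(self) -> None:
        if not (0 <= self.y0 <= self.n0 and 0 <= self.y1 <= self.n1):
            raise ValueError("require 0 <= y_j <= n_j")
        if self.n0 == 0 or self.n1 == 0:
            raise ValueError("both groups need at least one sample")


@dataclass
class PosteriorFit:
    """Posterior summaries of the prevalence model.

    ``lor_*`` quantities are on the reference-minus-comparator scale
    (-alpha1); positive means more prevalent in the reference group.
    """

    lor_mean: float
    lor_q05: float
    lor_q95: float
    theta0_mean: float
    theta1_mean: float
    n_effective: float
    method: str
    draws: np.ndarray | None = None  # (n, 2) columns (alpha0, alpha1)
    lor_sign_convention: str = "log-odds(reference) - log-odds(comparator)"

    @property
    def significant(self) -> bool:
        """True when the 90% credible interval strictly excludes zero."""
        return self.lor_q05 > 0 or self.lor_q95 < 0


@dataclass
class GeneAlterationMatrix:
    """Binary gene x sample alteration matrix with per-sample metadata."""

    data: pd.DataFrame  # genes x samples, values in {0, 1}
    groups: pd.Series  # sample -> 0/1 dummy (0 = reference)
    mutation_counts: pd.Series  # sample -> total mutations per exome
    hypermutator: pd.Series  # sample -> bool

    def __post_init__(self) -> None:
        vals = self.data.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("alteration entries must be 0/1")
        if not np.isin(self.groups.to_numpy(), (0, 1)).all():
            raise ValueError("group dummies must be 0/1")

    def counts_for_gene(self, gene: str, exclude_hypermutators: bool = True) -> PrevalenceCounts:
        keep = self.data.columns
        if exclude_hypermutators:
            keep = [s for s in keep if not bool(self.hypermutator.get(s, False))]
        row = self.data.loc[gene, keep]
        grp = self.groups[keep]
        return PrevalenceCounts(
            y0=int(row[grp == 0].sum()), n0=int((grp == 0).sum()),
            y1=int(row[grp == 1].sum()), n1=int((grp == 1).sum()),
        )


def filter_candidate_mutations(records: pd.DataFrame, assay: str) -> pd.DataFrame:
    """Post-caller read-support filters for candidate somatic mutations.

    Targeted panels keep mutations altered in > 10% of distinct reads. WES
    additionally requires >= 5 altered reads in at least one sample carrying
    the mutation (grouped by gene, position, ref and alt).
    """
    if assay not in ("targeted", "WES"):
        raise ValueError(f"assay must be 'targeted' or 'WES', got {assay!r}")
    for col in ("altered_reads", "distinct_reads"):
        if col not in records.columns:
            raise ValueError(f"mutation table lacks column {col!r}")
    frac = records["altered_reads"] / records["distinct_reads"]
    kept = records[frac > 0.10].copy()
    if assay == "WES" and len(kept):
        key = [c for c in ("gene", "chrom", "pos", "ref", "alt") if c in kept.columns]
        ok = kept.groupby(key)["altered_reads"].transform("max") >= 5
        kept = kept[ok]
    return kept.reset_index(drop=True)


def flag_hypermutators(per_sample_counts: pd.Series,
                       threshold: int = HYPERMUTATOR_THRESHOLD) -> pd.Series:
    """Flag samples with more than ``threshold`` mutations per exome."""
    counts = per_sample_counts.astype(float)
    if (counts < 0).any():
        raise ValueError("mutation counts must be non-negative")
    return counts > threshold


def _interval_overlaps_gene(chrom, start, end, genes: pd.DataFrame) -> list[str]:
    hit = genes[(genes["chrom"] == chrom) & (genes["start"] < end) & (genes["end"] > start)]
    return list(hit["gene"])


def build_alteration_matrix(mutations: pd.DataFrame, deletions, amplicon_nodes,
                            rearrangements, gene_intervals: pd.DataFrame,
                            samples: pd.DataFrame) -> GeneAlterationMatrix:
    """Integrate sequence and structural changes into one binary matrix.

    ``samples`` carries sample_id, group (0/1) and total mutation count per
    sample. ``deletions``/``amplicon_nodes``/``rearrangements`` are
    per-sample dicts mapping sample_id to lists of (chrom, start, end)
    intervals (deletion segments, amplicon node segments, rearrangement
    breakends). A gene is altered in a sample when any kept mutation names
    it or any structural interval overlaps its coordinates.
    """
    genes = list(gene_intervals["gene"])
    ids = list(samples["sample_id"])
    mat = pd.DataFrame(0, index=genes, columns=ids, dtype=np.int8)

    known = set(genes)
    for _, rec in mutations.iterrows():
        if rec["gene"] not in known:
            warnings.warn(f"unknown gene {rec['gene']!r} in mutation table; skipped",
                          stacklevel=2)
            continue
        if rec["sample_id"] in mat.columns:
            mat.loc[rec["gene"], rec["sample_id"]] = 1

    for source in (deletions or {}, amplicon_nodes or {}, rearrangements or {}):
        for sample_id, intervals in source.items():
            if sample_id not in mat.columns:
                continue
            for chrom, start, end in intervals:
                for g in _interval_overlaps_gene(chrom, start, end, gene_intervals):
                    mat.loc[g, sample_id] = 1

    counts = samples.set_index("sample_id")["mutation_count"] \
        if "mutation_count" in samples.columns else pd.Series(0, index=ids)
    return GeneAlterationMatrix(
        data=mat,
        groups=samples.set_index("sample_id")["group"],
        mutation_counts=counts,
        hypermutator=flag_hypermutators(counts),
    )


def select_comparison_genes(matrix: GeneAlterationMatrix, drivers: list[str],
                            min_freq: float = 0.10) -> list[str]:
    """Driver genes altered in at least ``min_freq`` of the combined cohort.

    Hypermutator samples are excluded from the frequency denominator, as
    they are from model fitting.
    """
    if not drivers:
        raise ValueError("driver gene list is empty")
    out = []
    for gene in drivers:
        if gene not in matrix.data.index:
            continue
        c = matrix.counts_for_gene(gene)
        if (c.y0 + c.y1) / (c.n0 + c.n1) >= min_freq:
            out.append(gene)
    return out


def _log_posterior(alpha0, alpha1, counts: PrevalenceCounts):
    """Unnormalized log posterior; broadcasts over alpha grids."""
    t0 = special.expit(alpha0)
    t1 = special.expit(alpha0 + alpha1)
    loglik = (counts.y0 * np.log(t0) + (counts.n0 - counts.y0) * np.log1p(-t0)
              + counts.y1 * np.log(t1) + (counts.n1 - counts.y1) * np.log1p(-t1))
    logprior = -0.5 * (alpha0 / 10.0) ** 2 - np.abs(alpha1)
    return loglik + logprior


def fit_prevalence(counts: PrevalenceCounts, n_draws: int = 50_000, seed: int = 0,
                   n_chains: int = 4, burn_in: int = 5_000) -> PosteriorFit:
    """Posterior of the prevalence model by adaptive random-walk Metropolis.

    ``n_draws`` kept draws are pooled over ``n_chains`` chains after
    discarding ``burn_in`` per chain; the proposal scale adapts toward a
    ~35% acceptance rate during burn-in only.
    """
    if n_draws < 2_000:
        raise ValueError("n_draws must be >= 2000")
    rng = np.random.default_rng(seed)
    per_chain = int(np.ceil(n_draws / n_chains))

    # crude empirical-logit start, jittered per chain
    p0 = (counts.y0 + 0.5) / (counts.n0 + 1.0)
    p1 = (counts.y1 + 0.5) / (counts.n1 + 1.0)
    state = np.column_stack([
        np.full(n_chains, special.logit(p0)),
        np.full(n_chains, special.logit(p1) - special.logit(p0)),
    ]) + rng.normal(0, 0.1, size=(n_chains, 2))
    logp = _log_posterior(state[:, 0], state[:, 1], counts)
    scale = np.full(n_chains, 0.5)

    kept = np.empty((n_chains, per_chain, 2))
    accept_window = np.zeros(n_chains)
    for it in range(burn_in + per_chain):
        prop = state + rng.normal(size=(n_chains, 2)) * scale[:, None]
        logp_prop = _log_posterior(prop[:, 0], prop[:, 1], counts)
        accept = np.log(rng.random(n_chains)) < logp_prop - logp
        state[accept] = prop[accept]
        logp[accept] = logp_prop[accept]
        if it < burn_in:
            accept_window += accept
            if (it + 1) % 100 == 0:
                rate = accept_window / 100.0
                scale *= np.exp(0.5 * (rate - 0.35))
                accept_window[:] = 0.0
        else:
            kept[:, it - burn_in] = state
    draws = kept.reshape(-1, 2)[:n_draws]
    ess = float(sum(_ess(-chain[:, 1]) for chain in kept))
    return _summarize_draws(draws, method="metropolis", n_effective=ess)


def _ess(x: np.ndarray) -> float:
    """Effective sample size by initial-positive-sequence autocorrelation."""
    n = len(x)
    x = x - x.mean()
    var = x.var()
    if var == 0:
        return float(n)
    acf = np.correlate(x, x, mode="full")[n - 1:] / (var * n)
    s = 1.0
    for k in range(1, min(n, 1000)):
        if acf[k] <= 0:
            break
        s += 2 * acf[k]
    return float(n / s)


def _summarize_draws(draws: np.ndarray, method: str,
                     n_effective: float | None = None) -> PosteriorFit:
    lor = -draws[:, 1]
    q05, q95 = np.percentile(lor, [5, 95])
    theta0 = special.expit(draws[:, 0]).mean()
    theta1 = special.expit(draws[:, 0] + draws[:, 1]).mean()
    return PosteriorFit(
        lor_mean=float(lor.mean()), lor_q05=float(q05), lor_q95=float(q95),
        theta0_mean=float(theta0), theta1_mean=float(theta1),
        n_effective=_ess(lor) if n_effective is None else n_effective,
        method=method, draws=draws,
    )


def quadrature_posterior(counts: PrevalenceCounts, bound: float = 12.0,
                         step: float = 0.01) -> PosteriorFit:
    """Deterministic oracle: 2-D trapezoidal integration of the posterior.

    The grid spans alpha0, alpha1 in [-bound, bound] at spacing ``step``.
    LOR summaries come from the marginal of -alpha1.
    """
    if step > 0.05:
        warnings.warn("quadrature grid coarser than 0.05; summaries may be imprecise",
                      stacklevel=2)
    a0 = np.arange(-bound, bound + step / 2, step)
    a1 = np.arange(-bound, bound + step / 2, step)
    logp = _log_posterior(a0[:, None], a1[None, :], counts)
    post = np.exp(logp - logp.max())

    # trapezoid weights per axis
    w0 = np.full(len(a0), step); w0[[0, -1]] = step / 2
    w1 = np.full(len(a1), step); w1[[0, -1]] = step / 2
    weighted = post * w0[:, None] * w1[None, :]
    z = weighted.sum()

    marg1 = weighted.sum(axis=0) / z  # marginal mass on the alpha1 grid
    lor_grid = -a1
    order = np.argsort(lor_grid)
    lor_sorted, mass = lor_grid[order], marg1[order]
    cdf = np.cumsum(mass)
    cdf /= cdf[-1]
    q05 = float(np.interp(0.05, cdf, lor_sorted))
    q95 = float(np.interp(0.95, cdf, lor_sorted))
    lor_mean = float((lor_grid * marg1).sum())

    t0 = special.expit(a0)[:, None]
    t1 = special.expit(a0[:, None] + a1[None, :])
    theta0 = float((t0 * weighted).sum() / z)
    theta1 = float((t1 * weighted).sum() / z)
    return PosteriorFit(
        lor_mean=lor_mean, lor_q05=q05, lor_q95=q95,
        theta0_mean=theta0, theta1_mean=theta1,
        n_effective=float("inf"), method="quadrature", draws=None,
    )


def count_significance_null(n_genes: int, observed: int, alpha: float = 0.1,
                            reps: int = 1_000, seed: int = 0) -> float:
    """Monte-Carlo p-value for observing >= ``observed`` significant genes.

    Under the null that all P genes have equal prevalence in both groups,
    each gene is independently "significant" with probability alpha; the
    null count distribution is simulated from a reps x P uniform matrix.
    """
    if not 0 <= observed <= n_genes:
        raise ValueError("observed must be in [0, n_genes]")
    rng = np.random.default_rng(seed)
    hits = (rng.random((reps, n_genes)) < alpha).sum(axis=1)
    return float((hits >= observed).mean())


def flag_significant_genes(fits: dict[str, PosteriorFit]) -> list[str]:
    """Genes whose 90% credible interval strictly excludes zero."""
    return [g for g, f in fits.items() if f.significant]


def proportion_ci(y: int, n: int, level: float = 0.95,
                  method: str = "beta") -> tuple[float, float]:
    """Binomial proportion confidence interval (method selectable).

    ``method`` is passed to statsmodels ``proportion_confint`` ("beta" is
    Clopper-Pearson, "jeffreys", "wilson", ...).
    """
    from statsmodels.stats.proportion import proportion_confint

    lo, hi = proportion_confint(y, n, alpha=1 - level, method=method)
    return float(lo), float(hi)
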