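"""Methylation probe filtering and PCA->LDA tissue-of-origin projection.

Beta values (methylated / total signal, in [0, 1]) at CpG probes are first
filtered (sex chromosomes, failed detection, SNP-overlapping probes), then a
reference cohort with known tissue labels is summarized by the 1,000 most
variable probes, reduced to five principal components, and a linear
discriminant model with pooled within-class covariance is fit on the PC
scores. Query samples are projected through the frozen probe set, centering
means, PC loadings and LD axes, yielding LD coordinates and Gaussian class
probabilities; per-class 95% ellipses are level sets of the fitted
bivariate normal at the chi-square(2) quantile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

__all__ = [
    "BetaMatrix",
    "ProjectionModel",
    "filter_probes",
    "methylated_fraction",
    "intersect_probes",
    "fit_projection",
    "project_samples",
    "class_ellipse",
]


@dataclass
class BetaMatrix:
    """Probes x samples matrix of beta values plus probe annotations.

    ``annotations`` is indexed by probe id with columns chrom, maf (dbSNP
    minor-allele frequency) and detection_p.
    """

    values: pd.DataFrame
    annotations: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values.to_numpy()
        if ((v < 0) | (v > 1)).any():
            raise ValueError("beta values must lie in [0, 1]")
        missing = set(self.values.index) - set(self.annotations.index)
        if missing:
            raise ValueError(f"{len(missing)} probes lack annotations")

    @property
    def probes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


@dataclass
class ProjectionModel:
    """Everything needed to project new samples without refitting."""

    probe_ids: pd.Index  # selected most-variable probes, fixed order
    probe_means: np.ndarray  # centering means on the reference cohort
    pc_loadings: np.ndarray  # (n_probes, n_pc), orthonormal columns
    ld_axes: np.ndarray  # (n_pc, k-1) discriminant directions
    classes: list[str]
    class_means_ld: np.ndarray  # (k, k-1)
    within_cov_ld: np.ndarray  # pooled within-class covariance in LD space
    class_priors: np.ndarray  # uniform by default
    reference_coords: pd.DataFrame  # LD coordinates of the reference samples


def filter_probes(matrix: BetaMatrix, det_p_max: float = 0.5,
                  maf_max: float = 0.10,
                  sex_chroms: tuple[str, ...] = ("chrX", "chrY", "X", "Y")) -> BetaMatrix:
    """Drop sex-chromosome probes, failed probes and SNP-overlapping probes.

    Detection p and MAF thresholds are strict: a probe is dropped only when
    its value exceeds the threshold.
    """
    ann = matrix.annotations.loc[matrix.probes]
    keep = (~ann["chrom"].isin(sex_chroms)
            & ~(ann["detection_p"] > det_p_max)
            & ~(ann["maf"].fillna(0.0) > maf_max))
    kept = matrix.probes[keep.to_numpy()]
    return BetaMatrix(values=matrix.values.loc[kept],
                      annotations=matrix.annotations.loc[kept])


def methylated_fraction(matrix: BetaMatrix, threshold: float = 0.3) -> pd.Series:
    """Per-sample fraction of probes with beta strictly above ``threshold``."""
    if len(matrix.probes) == 0:
        raise ValueError("no probes left to summarize")
    return (matrix.values > threshold).mean(axis=0)


def intersect_probes(reference: BetaMatrix, query: BetaMatrix) -> pd.Index:
    """Probe ids present on both platforms, in reference order."""
    common = reference.probes.intersection(query.probes)
    if len(common) == 0:
        raise ValueError("no probes in common between reference and query")
    return reference.probes[reference.probes.isin(common)]


def _fix_axis_signs(axes: np.ndarray) -> np.ndarray:
    """Orient each column so its largest-magnitude loading is positive."""
    idx = np.abs(axes).argmax(axis=0)
    signs = np.sign(axes[idx, np.arange(axes.shape[1])])
    signs[signs == 0] = 1.0
    return axes * signs


def fit_projection(reference: BetaMatrix, labels: pd.Series, n_top: int = 1_000,
                   n_pc: int = 5) -> ProjectionModel:
    """Fit the tissue-of-origin model on a labeled reference cohort.

    Probe selection (top ``n_top`` by sample variance), PCA centering means
    and loadings, and LD axes are all estimated on the reference only, so
    query data can never leak into the model.
    """
    labels = labels.reindex(reference.samples)
    classes = sorted(labels.unique())
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    if n_top > len(reference.probes):
        raise ValueError("n_top exceeds the number of probes")
    counts = labels.value_counts()
    if (counts < 2).any():
        raise ValueError("every class needs at least two reference samples")
    if len(reference.samples) <= n_pc:
        raise ValueError("need more reference samples than principal components")

    variances = reference.values.var(axis=1, ddof=1)
    top = variances.sort_values(ascending=False, kind="stable").index[:n_top]
    top = reference.probes[reference.probes.isin(top)]  # genome order, stable

    x = reference.values.loc[top].to_numpy().T  # samples x probes
    means = x.mean(axis=0)
    xc = x - means
    _, _, vt = np.linalg.svd(xc, full_matrices=False)
    loadings = _fix_axis_signs(vt[:n_pc].T)  # probes x n_pc
    scores = xc @ loadings

    y = labels.to_numpy()
    grand = scores.mean(axis=0)
    sw = np.zeros((n_pc, n_pc))
    sb = np.zeros((n_pc, n_pc))
    class_means_pc = np.empty((len(classes), n_pc))
    for i, c in enumerate(classes):
        sc = scores[y == c]
        class_means_pc[i] = sc.mean(axis=0)
        dev = sc - class_means_pc[i]
        sw += dev.T @ dev
        diff = (class_means_pc[i] - grand)[:, None]
        sb += len(sc) * (diff @ diff.T)
    sw /= len(scores) - len(classes)

    eigvals, eigvecs = linalg.eigh(sb, sw)
    order = np.argsort(eigvals)[::-1][: len(classes) - 1]
    axes = _fix_axis_signs(eigvecs[:, order])

    ld = scores @ axes
    class_means_ld = class_means_pc @ axes
    within = np.zeros((axes.shape[1], axes.shape[1]))
    for i, c in enumerate(classes):
        dev = ld[y == c] - class_means_ld[i]
        within += dev.T @ dev
    within /= len(ld) - len(classes)

    coords = pd.DataFrame(ld, index=reference.samples,
                          columns=[f"LD{i + 1}" for i in range(axes.shape[1])])
    return ProjectionModel(
        probe_ids=top, probe_means=means, pc_loadings=loadings, ld_axes=axes,
        classes=classes, class_means_ld=class_means_ld, within_cov_ld=within,
        class_priors=np.full(len(classes), 1.0 / len(classes)),
        reference_coords=coords,
    )


def project_samples(model: ProjectionModel, query: BetaMatrix,
                    max_missing: float = 0.05) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Project query samples onto the LD axes and score class membership.

    Probes absent from the query are imputed at the reference mean, up to a
    fraction ``max_missing`` of the model's probes. Returns ``(coords,
    probabilities)``, both indexed by query sample.
    """
    present = model.probe_ids.isin(query.probes)
    n_missing = int((~present).sum())
    if n_missing > max_missing * len(model.probe_ids):
        raise ValueError(
            f"{n_missing} of {len(model.probe_ids)} model probes missing from query "
            f"(> {max_missing:.0%} allowed)")
    x = np.tile(model.probe_means, (len(query.samples), 1))
    x[:, present] = query.values.loc[model.probe_ids[present]].to_numpy().T
    ld = (x - model.probe_means) @ model.pc_loadings @ model.ld_axes

    prec = np.linalg.inv(model.within_cov_ld)
    logp = np.empty((len(ld), len(model.classes)))
    for i in range(len(model.classes)):
        dev = ld - model.class_means_ld[i]
        logp[:, i] = -0.5 * np.einsum("ij,jk,ik->i", dev, prec, dev) \
            + np.log(model.class_priors[i])
    logp -= logp.max(axis=1, keepdims=True)
    prob = np.exp(logp)
    prob /= prob.sum(axis=1, keepdims=True)

    coords = pd.DataFrame(ld, index=query.samples,
                          columns=model.reference_coords.columns)
    probs = pd.DataFrame(prob, index=query.samples, columns=model.classes)
    return coords, probs


def class_ellipse(model: ProjectionModel, class_label: str,
                  level: float = 0.95) -> dict:
    """Level-set ellipse of a class Gaussian in the first two LD dimensions.

    Returns center, semi-axis lengths and rotation angle (radians); the
    squared Mahalanobis radius is the chi-square(2) quantile at ``level``.
    """
    if model.ld_axes.shape[1] < 2:
        raise ValueError("ellipses require a 2-D LD space")
    i = model.classes.index(class_label)
    center = model.class_means_ld[i, :2]
    cov = model.within_cov_ld[:2, :2]
    if np.linalg.matrix_rank(cov) < 2:
        raise np.linalg.LinAlgError("singular within-class covariance")
    r2 = stats.chi2.ppf(level, df=2) if level > 0 else 0.0
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    return {
        "class": class_label,
        "center": (float(center[0]), float(center[1])),
        "semi_axes": (float(np.sqrt(eigvals[0] * r2)), float(np.sqrt(eigvals[1] * r2))),
        "angle_rad": float(np.arctan2(eigvecs[1, 0], eigvecs[0, 0])),
        "level": level,
    }
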