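"""Expression and qPCR preprocessing upstream of the correlation screen.

Covers quantile normalization of the log2 intensity matrix, a deterministic
per-gene location-scale batch adjustment, qPCR quantities (dCt, ddCt, RQ),
Kruskal-Wallis group comparison, the lentiviral titration formula and a PCA
quality-control summary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .sequence_io import ExpressionMatrix, SampleMetadata

CT_RANGE = (0.0, 45.0)


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample (column) onto the common rank-wise mean distribution.

    Ties within a column receive the average of the target values their ranks
    span.  On tie-free (continuous) data the procedure is exactly idempotent;
    tie-averaged entries can shift marginally on reapplication.
    """
    df = matrix.data
    if df.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    values = df.to_numpy(float)
    order = np.sort(values, axis=0)
    target = order.mean(axis=1)  # rank-wise mean of sorted columns
    out = np.empty_like(values)
    for c in range(values.shape[1]):
        ranks = stats.rankdata(values[:, c], method="average")  # 1-based, ties averaged
        # Fractional ranks interpolate between adjacent target quantiles.
        out[:, c] = np.interp(ranks, np.arange(1, len(target) + 1), target)
    return ExpressionMatrix(pd.DataFrame(out, index=df.index, columns=df.columns))


def batch_adjust(
    matrix: ExpressionMatrix,
    meta: SampleMetadata,
    allow_single_batch: bool = False,
) -> ExpressionMatrix:
    """Per-gene location-scale batch adjustment.

    For each gene, each batch is centred, rescaled to the pooled (all-sample)
    standard deviation of that gene, and shifted back to the pooled mean.
    Within-batch rank order per gene is preserved.  A batch perfectly
    confounded with genotype is warned about but processed.
    """
    df = matrix.data
    m = meta.for_samples(df.columns)
    batches = m["batch"]
    unique_batches = batches.unique()
    if len(unique_batches) < 2:
        if allow_single_batch:
            return ExpressionMatrix(df.copy())
        raise ValueError("batch adjustment needs >= 2 batches (or allow_single_batch)")
    counts = batches.value_counts()
    if (counts < 2).any():
        raise ValueError("every batch needs >= 2 samples")
    for b in unique_batches:
        genos = m.loc[batches == b, "genotype"].unique()
        if len(genos) == 1:
            warnings.warn(
                f"batch {b!r} is confounded with genotype {genos[0]!r}; proceeding"
            )

    values = df.to_numpy(float)
    pooled_mean = values.mean(axis=1, keepdims=True)
    pooled_sd = values.std(axis=1, ddof=1, keepdims=True)
    out = np.empty_like(values)
    for b in unique_batches:
        cols = np.asarray(batches == b)
        block = values[:, cols]
        mu = block.mean(axis=1, keepdims=True)
        sd = block.std(axis=1, ddof=1, keepdims=True)
        scale = np.divide(pooled_sd, sd, out=np.ones_like(sd), where=sd > 0)
        out[:, cols] = (block - mu) * scale + pooled_mean
    return ExpressionMatrix(pd.DataFrame(out, index=df.index, columns=df.columns))


@dataclass
class MiRNAMeasurement:
    """One qPCR measurement of a miRNA in one sample, with its reference."""

    sample_id: str
    mirna_id: str
    ct_target: float
    ct_reference: float

    def __post_init__(self) -> None:
        for label, ct in (("target", self.ct_target), ("reference", self.ct_reference)):
            if not CT_RANGE[0] < ct < CT_RANGE[1]:
                raise ValueError(
                    f"{self.sample_id}/{self.mirna_id}: {label} Ct {ct} outside (0, 45)"
                )

    @property
    def delta_ct(self) -> float:
        return self.ct_target - self.ct_reference


def delta_ct(ct_target: float, ct_reference: float) -> float:
    """dCt = target Ct - reference Ct (e.g. RNU6B); both must lie in (0, 45)."""
    for label, ct in (("target", ct_target), ("reference", ct_reference)):
        if not CT_RANGE[0] < ct < CT_RANGE[1]:
            raise ValueError(f"{label} Ct {ct} outside (0, 45)")
    return ct_target - ct_reference


def relative_quantity(
    delta_cts: pd.Series, calibrator_samples: list[str]
) -> pd.Series:
    """RQ = 2^-(dCt - mean dCt of the calibrator group), per sample.

    The calibrator group mean therefore has RQ exactly 1.
    """
    if not calibrator_samples:
        raise ValueError("calibrator group is empty")
    missing = [s for s in calibrator_samples if s not in delta_cts.index]
    if missing:
        raise ValueError(f"calibrator sample {missing[0]!r} has no dCt")
    ddct = delta_cts - delta_cts.loc[calibrator_samples].mean()
    return np.exp2(-ddct).rename("rq")


def group_compare(
    values: pd.Series, groups: pd.Series
) -> tuple[float, float]:
    """Kruskal-Wallis H and p across the named groups (>=2 groups, each >=2)."""
    aligned = pd.DataFrame({"value": values, "group": groups}).dropna()
    by_group = [g["value"].to_numpy() for _, g in aligned.groupby("group")]
    if len(by_group) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 2 for g in by_group):
        raise ValueError("every group needs at least 2 samples")
    h, p = stats.kruskal(*by_group)
    return float(h), float(p)


def lentiviral_titer(concentration_g: float, bp: float) -> float:
    """Transducing-unit equivalents: M = (C * 6.02e23) / (660 * bp)."""
    if concentration_g <= 0 or bp <= 0:
        raise ValueError("concentration and plasmid size must be positive")
    return (concentration_g * 6.02e23) / (660.0 * bp)


@dataclass
class PCAReport:
    """Sample scores on the first two principal components, with QC flags."""

    scores: pd.DataFrame  # samples x (PC1, PC2)
    variance_fractions: tuple[float, float]
    genotype_distance: float
    treatment_distance: float
    degenerate: bool

    @property
    def genotype_separates_first(self) -> bool:
        return self.genotype_distance > self.treatment_distance


def pca_qc(matrix: ExpressionMatrix, meta: SampleMetadata) -> PCAReport:
    """Centered PCA of samples; compares genotype vs treatment centroid spread.

    In the sponge cohort the segmental-dosage effect dominates, so genotype
    centroids should separate more than treatment centroids on PC1-2.
    """
    df = matrix.data
    if df.shape[1] < 3:
        raise ValueError("PCA QC needs at least 3 samples")
    X = df.to_numpy(float).T  # samples x genes
    X = X - X.mean(axis=0, keepdims=True)
    total_var = float((X**2).sum())
    if total_var == 0:
        scores = pd.DataFrame(
            np.zeros((X.shape[0], 2)), index=df.columns, columns=["PC1", "PC2"]
        )
        return PCAReport(scores, (0.0, 0.0), 0.0, 0.0, degenerate=True)
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    pcs = X @ vt[:2].T
    scores = pd.DataFrame(pcs, index=df.columns, columns=["PC1", "PC2"])
    varfrac = (float(s[0] ** 2 / total_var), float(s[1] ** 2 / total_var) if len(s) > 1 else 0.0)

    m = meta.for_samples(df.columns)

    def centroid_distance(label: str) -> float:
        cents = scores.groupby(m[label].to_numpy()).mean()
        if len(cents) < 2:
            return 0.0
        diffs = [
            np.linalg.norm(cents.iloc[i] - cents.iloc[j])
            for i in range(len(cents))
            for j in range(i + 1, len(cents))
        ]
        return float(np.mean(diffs))

    return PCAReport(
        scores,
        varfrac,
        genotype_distance=centroid_distance("genotype"),
        treatment_distance=centroid_distance("treatment"),
        degenerate=False,
    )
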