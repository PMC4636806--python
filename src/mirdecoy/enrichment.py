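"""Enrichment, genomic topology and cross-study concordance summaries.

GSEA-style enrichment of predicted-target sets in a correlation-ranked gene
list (classic weighted Kolmogorov-Smirnov running sum with a gene-label
permutation null), 1-Mb binning of significant negative pairs along the
genome, and direction-concordance / normalization fractions between two
fold-change profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .sequence_io import GeneLocus


@dataclass
class EnrichmentResult:
    """Enrichment score of a gene set in a ranked list, with permutation p."""

    set_name: str
    es: float
    nperm: int = 0
    p_perm: float = float("nan")
    leading_edge: list[str] = field(default_factory=list)


def _ranked_series(ranked_metric: Mapping[str, float] | pd.Series) -> pd.Series:
    s = pd.Series(dict(ranked_metric)) if not isinstance(ranked_metric, pd.Series) else ranked_metric
    # Descending metric; gene id breaks ties deterministically.
    return s.iloc[np.lexsort((s.index.to_numpy(), -s.to_numpy()))]


def _running_es(metric: np.ndarray, is_hit: np.ndarray, p: float) -> tuple[float, np.ndarray, int]:
    weights = np.abs(metric) ** p
    hit_total = weights[is_hit].sum()
    n, n_hits = len(metric), int(is_hit.sum())
    if n_hits == n:
        return 1.0, np.ones(n), n - 1
    steps = np.where(
        is_hit,
        (weights / hit_total) if hit_total > 0 else (1.0 / n_hits),
        -1.0 / (n - n_hits),
    )
    running = np.cumsum(steps)
    peak = int(np.argmax(np.abs(running)))
    return float(running[peak]), running, peak


def gsea_es(
    ranked_metric: Mapping[str, float] | pd.Series,
    gene_set: Iterable[str],
    weight: float = 1.0,
    set_name: str = "gene_set",
) -> EnrichmentResult:
    """Classic weighted KS enrichment score of ``gene_set`` in the ranked list.

    Genes are ordered by metric, descending.  At a set member the running sum
    rises by |metric|^weight normalized by the set total; elsewhere it falls
    by 1/(N - Nh).  The score is the extreme deviation of the running sum.
    """
    s = _ranked_series(ranked_metric)
    genes = s.index.to_numpy()
    members = set(gene_set)
    is_hit = np.isin(genes, list(members))
    if not is_hit.any():
        raise ValueError("gene set does not intersect the ranked list")
    es, running, peak = _running_es(s.to_numpy(float), is_hit, weight)
    if es >= 0:
        leading = [g for g, h in zip(genes[: peak + 1], is_hit[: peak + 1]) if h]
    else:
        leading = [g for g, h in zip(genes[peak:], is_hit[peak:]) if h]
    return EnrichmentResult(set_name=set_name, es=es, leading_edge=leading)


def gsea_permutation_p(
    ranked_metric: Mapping[str, float] | pd.Series,
    gene_set: Iterable[str],
    nperm: int = 1000,
    seed: int | np.random.Generator | None = 0,
    weight: float = 1.0,
    set_name: str = "gene_set",
) -> EnrichmentResult:
    """Gene-label permutation p-value for the enrichment score.

    Random gene sets of the observed size are drawn from the ranked universe;
    p = (1 + #{|es_perm| >= |es_obs|}) / (nperm + 1).
    """
    if nperm < 100:
        raise ValueError("nperm must be >= 100")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    s = _ranked_series(ranked_metric)
    genes = s.index.to_numpy()
    metric = s.to_numpy(float)
    observed = gsea_es(s, gene_set, weight=weight, set_name=set_name)
    members = set(gene_set) & set(genes)
    k = len(members)
    count = 0
    for _ in range(nperm):
        idx = rng.choice(len(genes), size=k, replace=False)
        is_hit = np.zeros(len(genes), dtype=bool)
        is_hit[idx] = True
        es_perm, _, _ = _running_es(metric, is_hit, weight)
        if abs(es_perm) >= abs(observed.es):
            count += 1
    observed.nperm = nperm
    observed.p_perm = (1 + count) / (nperm + 1)
    return observed


def bin_pairs(
    candidates: pd.DataFrame,
    loci: Iterable[GeneLocus],
    bin_size: int = 1_000_000,
) -> tuple[pd.DataFrame, int]:
    """Count significant negative pairs per genomic bin of ``bin_size`` nt.

    A pair falls in the bin containing its gene's locus start (0-based,
    half-open tiling).  Returns (bins, n_unlocated); total binned pairs plus
    unlocated pairs equals the input pair count.
    """
    locus_by_gene = {}
    for loc in loci:
        locus_by_gene.setdefault(loc.gene_id, loc)
    rows = []
    n_unlocated = 0
    for row in candidates.itertuples(index=False):
        loc = locus_by_gene.get(row.gene)
        if loc is None:
            n_unlocated += 1
            continue
        rows.append(
            {
                "chromosome": loc.chromosome,
                "start": (loc.start // bin_size) * bin_size,
                "mirna": row.mirna,
                "r": row.r,
            }
        )
    if not rows:
        return (
            pd.DataFrame(columns=["chromosome", "start", "end", "mirna", "n_pairs", "mean_r"]),
            n_unlocated,
        )
    df = pd.DataFrame(rows)
    bins = (
        df.groupby(["chromosome", "start", "mirna"])
        .agg(n_pairs=("r", "size"), mean_r=("r", "mean"))
        .reset_index()
    )
    bins.insert(2, "end", bins["start"] + bin_size)
    bins = bins.sort_values(["chromosome", "start", "mirna"]).reset_index(drop=True)
    return bins, n_unlocated


@dataclass
class ConcordanceResult:
    """Agreement between two gene-wise fold-change profiles."""

    n_common: int
    fraction_same_direction: float = float("nan")
    fraction_down: float = float("nan")
    fraction_normalized: float = float("nan")


def direction_concordance(
    fc_a: Mapping[str, float] | pd.Series,
    fc_b: Mapping[str, float] | pd.Series,
    min_abs: float = 0.0,
) -> ConcordanceResult:
    """Share of shared genes whose log2 fold-changes agree in sign.

    Genes with |fc| < ``min_abs`` in either profile, or with a zero
    fold-change, are excluded.  Symmetric in its arguments.
    """
    a = pd.Series(dict(fc_a)) if not isinstance(fc_a, pd.Series) else fc_a
    b = pd.Series(dict(fc_b)) if not isinstance(fc_b, pd.Series) else fc_b
    common = a.index.intersection(b.index)
    if len(common) == 0:
        raise ValueError("no common genes between the two profiles")
    av, bv = a.loc[common], b.loc[common]
    keep = (av.abs() >= min_abs) & (bv.abs() >= min_abs) & (av != 0) & (bv != 0)
    if keep.sum() == 0:
        raise ValueError("no common genes pass the fold-change threshold")
    same = (np.sign(av[keep]) == np.sign(bv[keep])).mean()
    return ConcordanceResult(n_common=int(keep.sum()), fraction_same_direction=float(same))


def normalization_fractions(
    fc_trisomic: Mapping[str, float] | pd.Series,
    fc_silenced: Mapping[str, float] | pd.Series,
    candidate_genes: Iterable[str],
    tol: float = 0.5,
) -> ConcordanceResult:
    """Down-regulation and normalization fractions over a candidate set.

    Both profiles are log2 fold-changes versus the euploid reference:
    ``fc_trisomic`` for the trisomic state and ``fc_silenced`` after silencing
    the extra chromosomal copy.  ``fraction_down`` is the share of candidates
    down in trisomy; ``fraction_normalized`` the share whose silenced
    fold-change shrinks below both its trisomic magnitude and ``tol``.
    """
    a = pd.Series(dict(fc_trisomic)) if not isinstance(fc_trisomic, pd.Series) else fc_trisomic
    b = pd.Series(dict(fc_silenced)) if not isinstance(fc_silenced, pd.Series) else fc_silenced
    genes = [g for g in candidate_genes if g in a.index and g in b.index]
    if not genes:
        raise ValueError("no candidate gene present in both profiles")
    av, bv = a.loc[genes], b.loc[genes]
    down = av < 0
    normalized = (bv.abs() < av.abs()) & (bv.abs() < tol)
    return ConcordanceResult(
        n_common=len(genes),
        fraction_down=float(down.mean()),
        fraction_normalized=float(normalized.mean()),
    )
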