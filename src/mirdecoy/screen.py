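"""miRNA-target screen: expression-miRNA anticorrelation meets site predictions.

The screen follows the miRComb recipe: Pearson correlation between every
gene's (normalized) expression and each miRNA's abundance across all samples
pooled over genotype and treatment, then the filter

    r < 0  and  p < alpha (default 0.05, uncorrected)  and  >= 1 predicted site,

and a candidate ranking by predicted site count (descending) then correlation
(most negative first).  ``TargetScreen`` is the model object;
``TargetScreen.fit()`` returns a :class:`TargetScreenResults` carrying the
per-pair table, the ranked candidates, stratification and a summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sequence_io import ExpressionMatrix, PredictionRecord, predictions_frame

PAIR_COLUMNS = ["mirna", "gene", "r", "p", "n", "total", "conserved"]


def pair_correlations(
    expr: ExpressionMatrix, mirna_abundance: pd.Series, mirna_id: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson r and two-sided p for every gene against one miRNA's abundance.

    p comes from t = r*sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom.
    Returns (pairs, skipped); constant genes are skipped with a reason.
    """
    shared = [s for s in expr.sample_ids if s in mirna_abundance.index]
    if len(shared) < 4:
        raise ValueError("need at least 4 shared samples")
    x = mirna_abundance.loc[shared].to_numpy(float)
    if np.ptp(x) == 0:
        raise ValueError("miRNA abundance is constant across samples")
    Y = expr.data[shared].to_numpy(float)
    n = len(shared)

    xc = x - x.mean()
    yc = Y - Y.mean(axis=1, keepdims=True)
    x_ss = float(xc @ xc)
    y_ss = (yc**2).sum(axis=1)
    constant = y_ss == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (yc @ xc) / np.sqrt(y_ss * x_ss)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isfinite(t), p, 0.0)  # |r| == 1

    genes = np.asarray(expr.gene_ids)
    pairs = pd.DataFrame(
        {
            "mirna": mirna_id,
            "gene": genes[~constant],
            "r": r[~constant],
            "p": p[~constant],
            "n": n,
        }
    )
    skipped = pd.DataFrame(
        {"mirna": mirna_id, "gene": genes[constant], "reason": "constant expression"}
    )
    return pairs, skipped


def attach_site_counts(
    pairs: pd.DataFrame, predictions: Iterable[PredictionRecord] | pd.DataFrame
) -> pd.DataFrame:
    """Join predicted site counts onto the pair table (0 where unpredicted)."""
    pred = (
        predictions
        if isinstance(predictions, pd.DataFrame)
        else predictions_frame(list(predictions))
    )
    merged = pairs.merge(
        pred[["mirna", "gene", "total", "conserved"]], on=["mirna", "gene"], how="left"
    )
    merged[["total", "conserved"]] = merged[["total", "conserved"]].fillna(0).astype(int)
    return merged


def apply_filter(
    pairs: pd.DataFrame, alpha: float = 0.05, use_bh: bool = False
) -> pd.DataFrame:
    """Keep pairs with negative, significant correlation and >= 1 predicted site."""
    p = pairs["p"].to_numpy()
    if use_bh:
        order = np.argsort(p)
        m = len(p)
        adj = np.empty(m)
        adj[order] = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
        p = adj
    keep = (pairs["r"] < 0) & (p < alpha) & (pairs["total"] >= 1)
    return pairs.loc[keep].reset_index(drop=True)


def rank_candidates(filtered: pd.DataFrame, top_k: int | None = None) -> pd.DataFrame:
    """Order candidates by site count (desc), then r (most negative), then gene id."""
    ranked = filtered.sort_values(
        ["total", "r", "gene"], ascending=[False, True, True], kind="mergesort"
    ).reset_index(drop=True)
    ranked.insert(0, "rank", np.arange(1, len(ranked) + 1))
    return ranked.head(top_k) if top_k is not None else ranked


def stratify_by_sites(
    pairs: pd.DataFrame, max_group: int = 3
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Distribution of r by predicted-site-count group (0, 1, ..., max_group+).

    Each positive group is rank-sum tested (two-sided Mann-Whitney) against
    the 0-site group; absent comparison groups are omitted with a note.
    """
    labels = np.where(
        pairs["total"] >= max_group, f"{max_group}+", pairs["total"].astype(str)
    )
    grouped = pairs.assign(site_group=labels).groupby("site_group")["r"]
    summary = grouped.agg(
        n="size", mean_r="mean", q25=lambda s: s.quantile(0.25),
        median_r="median", q75=lambda s: s.quantile(0.75),
    ).reset_index()
    order = [str(k) for k in range(max_group)] + [f"{max_group}+"]
    summary["site_group"] = pd.Categorical(summary["site_group"], order, ordered=True)
    summary = summary.sort_values("site_group").reset_index(drop=True)

    if (summary["n"] > 0).sum() < 2:
        raise ValueError("stratification needs at least 2 non-empty groups")

    tests = []
    zero = pairs.loc[labels == "0", "r"].to_numpy()
    for g in order[1:]:
        vals = pairs.loc[labels == g, "r"].to_numpy()
        if len(zero) == 0 or len(vals) == 0:
            tests.append({"site_group": g, "u": np.nan, "p": np.nan, "note": "group empty"})
            continue
        u, p = stats.mannwhitneyu(vals, zero, alternative="two-sided")
        tests.append({"site_group": g, "u": float(u), "p": float(p), "note": ""})
    return summary, pd.DataFrame(tests)


def intersect_predictions(
    list_a: Iterable[str], list_b: Iterable[str]
) -> tuple[int, int, int, list[str]]:
    """Venn counts and the sorted overlap of two predicted-target gene sets."""
    a, b = set(list_a), set(list_b)
    overlap = sorted(a & b)
    return len(a), len(b), len(overlap), overlap


class TargetScreen:
    """Anticorrelation screen model over an expression matrix and miRNA levels.

    Parameters
    ----------
    expr : ExpressionMatrix
        Normalized log2 expression, genes x samples.
    mirna_abundance : DataFrame (samples x miRNAs) or mapping miRNA -> Series
        Per-sample miRNA abundance proxy.  By convention this is -dCt so that
        target repression shows up as negative gene-miRNA correlation; pass
        raw dCt only if you want the sign flipped.
    predictions : iterable of PredictionRecord or DataFrame
        Predicted site counts per miRNA-gene pair.
    """

    def __init__(
        self,
        expr: ExpressionMatrix,
        mirna_abundance: pd.DataFrame | Mapping[str, pd.Series],
        predictions: Iterable[PredictionRecord] | pd.DataFrame,
        alpha: float = 0.05,
        use_bh: bool = False,
    ) -> None:
        self.expr = expr
        if isinstance(mirna_abundance, pd.DataFrame):
            self.mirna_abundance = {c: mirna_abundance[c] for c in mirna_abundance.columns}
        else:
            self.mirna_abundance = dict(mirna_abundance)
        self.predictions = (
            predictions
            if isinstance(predictions, pd.DataFrame)
            else predictions_frame(list(predictions))
        )
        self.alpha = alpha
        self.use_bh = use_bh

    @classmethod
    def from_delta_ct(
        cls,
        expr: ExpressionMatrix,
        delta_ct: pd.DataFrame,
        predictions,
        correlate_raw_dct: bool = False,
        **kwargs,
    ) -> "TargetScreen":
        """Build from a (samples x miRNAs) dCt table; uses -dCt unless told not to."""
        abundance = delta_ct if correlate_raw_dct else -delta_ct
        return cls(expr, abundance, predictions, **kwargs)

    def fit(self) -> "TargetScreenResults":
        all_pairs, all_skipped = [], []
        for mirna_id, abundance in self.mirna_abundance.items():
            pairs, skipped = pair_correlations(self.expr, abundance, mirna_id)
            all_pairs.append(attach_site_counts(pairs, self.predictions))
            all_skipped.append(skipped)
        pairs = pd.concat(all_pairs, ignore_index=True)
        skipped = pd.concat(all_skipped, ignore_index=True)
        candidates = rank_candidates(apply_filter(pairs, self.alpha, self.use_bh))
        return TargetScreenResults(
            model=self, pairs=pairs, candidates=candidates, skipped=skipped
        )


@dataclass
class TargetScreenResults:
    """Fitted screen: per-pair statistics and the filtered candidate ranking."""

    model: TargetScreen
    pairs: pd.DataFrame
    candidates: pd.DataFrame
    skipped: pd.DataFrame = field(default_factory=pd.DataFrame)

    def top(self, k: int, mirna_id: str | None = None) -> pd.DataFrame:
        cand = self.candidates
        if mirna_id is not None:
            cand = cand[cand["mirna"] == mirna_id]
        return cand.head(k)

    def stratify_by_sites(self, mirna_id: str | None = None, max_group: int = 3):
        pairs = self.pairs
        if mirna_id is not None:
            pairs = pairs[pairs["mirna"] == mirna_id]
        return stratify_by_sites(pairs, max_group=max_group)

    def summary(self) -> str:
        lines = [
            "miRNA target anticorrelation screen",
            f"  samples per pair: {int(self.pairs['n'].iloc[0]) if len(self.pairs) else 0}",
            f"  alpha: {self.model.alpha}"
            + (" (Benjamini-Hochberg adjusted)" if self.model.use_bh else " (unadjusted)"),
        ]
        for mirna_id in self.model.mirna_abundance:
            sub = self.pairs[self.pairs["mirna"] == mirna_id]
            cand = self.candidates[self.candidates["mirna"] == mirna_id]
            neg = (sub["r"] < 0).sum()
            lines.append(
                f"  {mirna_id}: {len(sub)} genes tested, {neg} negatively correlated, "
                f"{len(cand)} candidates pass the filter"
            )
            for row in cand.head(5).itertuples(index=False):
                lines.append(
                    f"    {row.gene:<12} sites={row.total} r={row.r:+.3f} p={row.p:.2e}"
                )
        if len(self.skipped):
            lines.append(f"  skipped: {len(self.skipped)} constant gene(s)")
        return "\n".join(lines)
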