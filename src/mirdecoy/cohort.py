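"""Synthetic sponge-cohort generator with ground truth.

Emulates the statistical structure of a 2-genotype (euploid EU / trisomic TS)
x 2-treatment (control / sponge lentivirus) hippocampal expression study: a
segmental 1.5x dosage gain on a contiguous block of genes, two resident
miRNAs overexpressed with the dosage and renormalized by the sponge,
per-site multiplicative repression of their targets, gene-wise Gaussian
noise, an additive batch effect, and qPCR dCt readouts of the miRNAs.  Every
table the real pipeline consumes is emitted, together with the ground truth
needed to score recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .sequence_io import (
    ExpressionMatrix,
    GeneLocus,
    PredictionRecord,
    SampleMetadata,
)

#: log2 abundance is read out as dCt = DELTA_CT_CONSTANT - log2(abundance);
#: the constant is arbitrary and cancels in ddCt.
DELTA_CT_CONSTANT = 20.0


@dataclass
class CohortConfig:
    """Knobs of the simulated cohort; defaults are the study-like conditions."""

    n_per_group: int = 5
    n_genes: int = 2000
    n_trisomic_genes: int = 150
    n_targets_per_mirna: int = 100
    n_decoy_predictions: int = 200  # predicted sites but no repression
    site_count_distribution: dict[int, float] = field(
        default_factory=lambda: {1: 0.10, 2: 0.30, 3: 0.30, 4: 0.30}
    )
    dosage_fc: float = 1.5
    mirna_overexpression_fc: float = 1.5
    repression_beta: float = 0.4  # log2 units per site per unit relative miRNA excess
    noise_sd: float = 0.25
    batch_shift: float = 0.3
    sponge_efficacy: float = 1.0
    mirna_ids: tuple[str, str] = ("mmu-miR-155", "mmu-miR-802")
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_per_group": self.n_per_group,
            "n_genes": self.n_genes,
            "n_trisomic_genes": self.n_trisomic_genes,
            "n_targets_per_mirna": self.n_targets_per_mirna,
        }
        for name, v in counts.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_decoy_predictions < 0:
            raise ValueError("n_decoy_predictions must be non-negative")
        if self.dosage_fc <= 1:
            raise ValueError("dosage_fc must exceed 1")
        if not 0 <= self.sponge_efficacy <= 1:
            raise ValueError("sponge_efficacy must lie in [0, 1]")
        if abs(sum(self.site_count_distribution.values()) - 1) > 1e-9:
            raise ValueError("site_count_distribution must sum to 1")
        n_special = len(self.mirna_ids) * (
            self.n_targets_per_mirna + self.n_decoy_predictions
        ) + self.n_trisomic_genes
        if n_special > self.n_genes:
            raise ValueError("n_genes too small for targets + decoys + trisomic block")


@dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort.

    ``genes`` has one row per gene: is_trisomic plus, per miRNA,
    is_target_<id> and n_sites_<id> (decoy predictions carry sites but are
    not targets).  ``mirna_abundance`` is samples x miRNAs on the linear
    scale used to drive repression and dCt.
    """

    genes: pd.DataFrame
    mirna_abundance: pd.DataFrame
    config: CohortConfig

    def target_genes(self, mirna_id: str) -> list[str]:
        col = f"is_target_{mirna_id}"
        return list(self.genes.index[self.genes[col]])


class CohortData(NamedTuple):
    expression: ExpressionMatrix
    metadata: SampleMetadata
    mirna_measurements: pd.DataFrame
    predictions: list[PredictionRecord]
    loci: list[GeneLocus]
    truth: SyntheticTruth


def generate_cohort(cfg: CohortConfig | None = None) -> CohortData:
    """Simulate one cohort under ``cfg`` (byte-reproducible under its seed)."""
    cfg = cfg or CohortConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    # --- samples: EU/TS x control/sponge, n per group, alternating batches ---
    rows = []
    for genotype in ("EU", "TS"):
        for treatment in ("control", "sponge"):
            for k in range(cfg.n_per_group):
                rows.append(
                    {
                        "sample_id": f"{genotype}_{treatment}_{k + 1}",
                        "genotype": genotype,
                        "treatment": treatment,
                        "batch": "A" if k % 2 == 0 else "B",
                    }
                )
    meta = SampleMetadata(pd.DataFrame(rows))
    samples = meta.data["sample_id"].to_numpy()
    genotype = meta.data["genotype"].to_numpy()
    treatment = meta.data["treatment"].to_numpy()
    in_batch_b = (meta.data["batch"] == "B").to_numpy()
    n_samples = len(samples)

    # --- gene roles: contiguous trisomic block, disjoint target/decoy sets ---
    genes = np.array([f"gene{g + 1:05d}" for g in range(cfg.n_genes)])
    trisomic = np.zeros(cfg.n_genes, dtype=bool)
    trisomic[: cfg.n_trisomic_genes] = True
    pool = np.arange(cfg.n_trisomic_genes, cfg.n_genes)
    pool = rng.permutation(pool)
    role: dict[str, np.ndarray] = {}
    offset = 0
    for mirna_id in cfg.mirna_ids:
        role[f"target_{mirna_id}"] = pool[offset : offset + cfg.n_targets_per_mirna]
        offset += cfg.n_targets_per_mirna
        role[f"decoy_{mirna_id}"] = pool[offset : offset + cfg.n_decoy_predictions]
        offset += cfg.n_decoy_predictions

    site_values = np.array(sorted(cfg.site_count_distribution))
    site_probs = np.array([cfg.site_count_distribution[v] for v in site_values], float)
    n_sites = {m: np.zeros(cfg.n_genes, dtype=int) for m in cfg.mirna_ids}
    is_target = {m: np.zeros(cfg.n_genes, dtype=bool) for m in cfg.mirna_ids}
    predictions: list[PredictionRecord] = []
    for mirna_id in cfg.mirna_ids:
        for kind in ("target", "decoy"):
            idx = role[f"{kind}_{mirna_id}"]
            counts = rng.choice(site_values, size=len(idx), p=site_probs)
            n_sites[mirna_id][idx] = counts
            if kind == "target":
                is_target[mirna_id][idx] = True
            for g, total in zip(idx, counts):
                conserved = int(rng.integers(0, total + 1))
                predictions.append(
                    PredictionRecord(mirna_id, genes[g], conserved, int(total - conserved))
                )

    # --- miRNA abundance per sample (linear scale, euploid mean m0) ---
    m0 = 100.0
    fc = cfg.mirna_overexpression_fc
    abundance = np.full(n_samples, m0)
    ts = genotype == "TS"
    abundance[ts & (treatment == "control")] = m0 * fc
    abundance[ts & (treatment == "sponge")] = m0 * (
        1 + (fc - 1) * (1 - cfg.sponge_efficacy)
    )
    mirna_abundance = pd.DataFrame(
        {m: abundance for m in cfg.mirna_ids}, index=samples
    )

    # --- expression: baseline + dosage + repression + noise + batch ---
    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_genes)
    expr = np.tile(baseline[:, None], (1, n_samples))
    expr[trisomic[:, None] & ts[None, :]] += np.log2(cfg.dosage_fc)
    excess = abundance / m0 - 1.0
    for mirna_id in cfg.mirna_ids:
        expr -= cfg.repression_beta * n_sites[mirna_id][:, None] * excess[None, :] * is_target[
            mirna_id
        ][:, None]
    expr += rng.normal(0.0, cfg.noise_sd, size=expr.shape)
    expr[:, in_batch_b] += cfg.batch_shift
    expression = ExpressionMatrix(pd.DataFrame(expr, index=genes, columns=samples))

    # --- qPCR readout of the miRNAs ---
    ct_reference = DELTA_CT_CONSTANT / 2
    meas_rows = []
    for mirna_id in cfg.mirna_ids:
        dct = DELTA_CT_CONSTANT - np.log2(mirna_abundance[mirna_id].to_numpy())
        for s, d in zip(samples, dct):
            meas_rows.append(
                {
                    "sample_id": s,
                    "mirna_id": mirna_id,
                    "ct_target": ct_reference + d,
                    "ct_reference": ct_reference,
                    "delta_ct": d,
                }
            )
    measurements = pd.DataFrame(meas_rows)

    # --- loci: trisomic block contiguous on chr16, the rest uniform ---
    loci: list[GeneLocus] = []
    gene_span = 100_000
    for g in range(cfg.n_genes):
        if trisomic[g]:
            start = 10_000_000 + g * gene_span
            loci.append(GeneLocus(genes[g], "chr16", start, start + gene_span // 2))
        else:
            chrom = f"chr{rng.integers(1, 16)}"
            start = int(rng.integers(0, 150_000_000))
            loci.append(GeneLocus(genes[g], chrom, start, start + gene_span // 2))

    truth_genes = pd.DataFrame({"is_trisomic": trisomic}, index=pd.Index(genes, name="gene_id"))
    for mirna_id in cfg.mirna_ids:
        truth_genes[f"is_target_{mirna_id}"] = is_target[mirna_id]
        truth_genes[f"n_sites_{mirna_id}"] = n_sites[mirna_id]
    truth = SyntheticTruth(truth_genes, mirna_abundance, cfg)

    return CohortData(expression, meta, measurements, predictions, loci, truth)


def truth_eval(
    ranked: pd.DataFrame, truth: SyntheticTruth, k: int
) -> tuple[float, float]:
    """Sensitivity and false-discovery proportion of the top-k ranked pairs.

    A ranked row is a true positive when its gene is a ground-truth target of
    its miRNA.  Sensitivity is relative to the total number of true
    (miRNA, target) pairs in the truth table.
    """
    if k > len(ranked):
        raise ValueError(f"k={k} exceeds ranked list length {len(ranked)}")
    mirnas = truth.config.mirna_ids
    truth_pairs = {
        (m, g) for m in mirnas for g in truth.target_genes(m)
    }
    top = ranked.head(k)
    hits = sum((row.mirna, row.gene) in truth_pairs for row in top.itertuples(index=False))
    sensitivity = hits / len(truth_pairs) if truth_pairs else float("nan")
    fdr = (len(top) - hits) / len(top) if len(top) else 0.0
    return float(sensitivity), float(fdr)
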