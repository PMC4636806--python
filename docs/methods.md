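# Methods

## Decoy (sponge) site design

A mature miRNA (19–25 nt, 5'→3') recognizes targets primarily through its
seed, positions 2–8.  A *perfect* decoy site is the exact reverse complement
of the mature sequence; Argonaute 2 cleaves such duplexes, which shortens
the decoy's useful life.  A *bulged* site therefore keeps the seed-pairing
3' region intact and replaces the complement of the miRNA's central
positions (default window 9–12, 4 nt) with 3 nucleotides chosen to pair
neither Watson–Crick nor wobble with the bases they face.  From a 23-nt
miRNA the default design yields a 22-nt site with exactly 3 mismatched
nucleotides — the architecture of the published miR155T/miR802T cassettes,
which the cassette builder reproduces verbatim from the same motif, spacer
and flank components (4 sites, 4-nt spacers, restriction half-site flanks).

The designer's only free choice is the identity of the 3 inserted bases;
they are drawn from an explicit seeded RNG (no global state), and site
validation checks seed-match presence, mismatch count and length rather
than exact string equality, because many base choices satisfy the design
rule equally well.

`mmu-miR-802`'s mature sequence is reconstructed by inverting the design
rule on the published miR802T oligo (21-nt site ⇒ 22-nt mature); it is
labelled a reconstruction in `mirdecoy.constructs`.

## Hybridization energy model

`duplex_mfe` minimizes free energy over all *intermolecular* secondary
structures of two RNA strands: a single duplex of stacked pairs interrupted
by bulges and interior loops, no intramolecular pairs, no pseudoknots —
the model class of the RNAhybrid family.  The energy of a structure is

    E = duplex_initiation + Σ stacks + Σ loop penalties + terminal penalties

* **Stacks** — nearest-neighbor ΔG37 values from the published Turner-2004
  tables, including G·U wobble pairs (36 ordered doublet entries).
* **Loops** — affine penalties: `interior(s1,s2) = 0.55 + 0.27·(s1+s2) +
  0.60·|s1−s2|`, `bulge(n) = 3.50 + 0.35·n`, both capped at 15 unpaired nt
  per strand.  The line was fit to the Turner loop-initiation curve; the
  intercept is versioned against the published engineered-site energies
  (below).
* **Ends** — unpaired strand ends dangle free; an AU/GU closing penalty of
  0.45 kcal/mol applies at the two outermost pairs.  `duplex_initiation` is
  0.0: the tool the study used reports hybridization energies without the
  bimolecular initiation term (tools that include it, e.g. RNAduplex, read
  ~+4.1 kcal/mol higher on the same duplex).

All parameters live in the bundled, versioned text file
`data/rna_nn_params_v1.tsv`; reported energies are only comparable within a
parameter version.  Because the original study does not state its parameter
vintage, the v1 interior-loop intercept was fixed (within the band the
Turner tables bracket: a pure affine fit to large loops gives 0.30,
Turner-priced small 2×1 loops imply ≈1.1) such that the two engineered
bulged duplexes reproduce the study's published [−35, −30] kcal/mol window
(−34.94 and −30.04).  This calibration is recorded here deliberately: the
parameter file, not the code, carries it.

The DP is exact over the model class; `brute_force_mfe` enumerates all
monotone pairings on small inputs (≤64 cell products) with an independent
scorer and is used as the test oracle.  Ties are broken toward structures
with more pairs, then lexicographically, so tracebacks are deterministic.

Null site categories mirror the published comparison: 100 uniform random
22-mers, and 100 random 22-mers with the 7-mer seed match implanted at the
canonical position (ending one nucleotide short of the site 3' end).

## Expression preprocessing

* **Quantile normalization** maps every sample column onto the rank-wise
  mean of the sorted columns; within-column ties receive the average of the
  target values their ranks span.  On tie-free data the operation is
  exactly idempotent.
* **Batch adjustment** is a deterministic per-gene location–scale
  correction: each batch is centred, rescaled to the gene's pooled standard
  deviation, and shifted back to the pooled mean.  This is a simplification
  of empirical-Bayes ComBat — intentionally, since the original study's
  batch structure and priors are unavailable; it removes additive and
  multiplicative batch effects exactly and preserves within-batch rank
  order, but does not shrink gene-wise estimates across genes.
* **qPCR** — ΔCt = Ct_target − Ct_reference (both required in (0, 45));
  RQ = 2^−ΔΔCt relative to a calibrator group whose mean RQ is exactly 1.
  Group comparisons use Kruskal–Wallis.  The lentiviral titration formula
  M = (C·6.02·10²³)/(660·bp) is implemented as printed; C is plasmid mass
  (g) per reaction volume and M molecule count per the same volume.
* **PCA QC** reports sample scores on the first two principal components
  and whether genotype centroids separate more than treatment centroids —
  in this design the segmental dosage effect should dominate the sponge
  effect.

## The anticorrelation screen

`TargetScreen` correlates every gene with each miRNA's abundance across all
samples pooled over genotype and treatment (the variation *between* groups
is the signal).  The abundance proxy is −ΔCt, so repression appears as
negative correlation; a flag restores raw ΔCt for sign-convention
comparisons.  p-values come from t = r·√((n−2)/(1−r²)) on n−2 df,
two-sided.  The filter keeps pairs with r < 0, p < 0.05 (uncorrected, as in
the original analysis; Benjamini–Hochberg available by flag) and at least
one predicted target site; candidates are ranked by total predicted sites
(descending), then r (ascending), then gene id.  Genes without predictions
enter the 0-site stratification group but can never become candidates.

Stratification compares correlation distributions across 0/1/2/3+ predicted
site groups with two-sided rank-sum tests against the 0-site group (the
original figure does not name its test; the choice is flagged in output).

Enrichment uses the classic weighted Kolmogorov–Smirnov running sum
(weight p = 1, genes ranked by correlation with the miRNA) and a gene-label
permutation null — gene-label rather than phenotype permutation because the
groups are small; p = (1 + #{|ES_perm| ≥ |ES_obs|})/(nperm + 1).  Only ES
and the permutation p are reported (no NES).  Genomic topology counts
filtered pairs per 1-Mb bin keyed by the gene's 0-based locus start.
Cross-study concordance is operationalized as the share of shared genes
whose log2 fold-changes agree in sign, and "normalization" as a silenced
fold-change smaller than both the trisomic magnitude and 0.5 log2 units —
explicit stand-ins, since the compared study reports no formula.

## Synthetic cohort generator

The generator emulates the study design: 2 genotypes × 2 treatments ×
n_per_group (default 5) samples; 2000 genes with baseline log2 expression
~ N(8, 1.5²); a contiguous block of 150 trisomic genes gaining log2(1.5)
in trisomic samples; two miRNAs with disjoint target sets (100 each) and
additional decoy predictions (200 each — genes carrying predicted sites but
no repression, as sequence-based predictions often do); per-target
repression of β·n_sites·(m_s/m_0 − 1) log2 units (β = 0.4), where m_s is
the sample's miRNA abundance (euploid m_0, trisomic-control 1.5·m_0,
trisomic-sponge renormalized by sponge efficacy, default 1.0); N(0, 0.25²)
noise per cell; +0.3 log2 on a balanced half of samples as batch B; miRNA
ΔCt emitted as 20 − log2(abundance) (the constant cancels in ΔΔCt); loci
placing the trisomic block contiguously on chr16.

Per-target site counts are drawn from {1: 0.10, 2: 0.30, 3: 0.30, 4: 0.30}.
The distribution was fixed by a design-time power analysis: at the study's
effect and noise scales a single-site target (0.2 log2 repression against
0.25 noise over 20 samples) sits at the detection boundary, and the screen's
positive class — like the candidates the original study validated — is
dominated by multi-site genes.  Under these defaults the screen recovers
82–87% of planted targets (seeds 1–5) with <10% false discoveries, and
sensitivity collapses to chance when β = 0.

What the generator does *not* emulate: probe-level array artifacts,
correlated gene modules, miRNA measurement noise in ΔCt, shared targets
between the two miRNAs, and expression-dependent variance.  Passing tests
therefore demonstrate correctness of the statistical machinery under the
assumed generative model, not performance on real microarray data.

## Numerical and degenerate-input conventions

Constant genes are skipped (with reason) rather than given r = 0; |r| = 1
maps to p = 0.  DP tie-breaks favor more pairs, then lexicographic order.
Quantile normalization rejects single-sample matrices; batch adjustment
requires ≥2 batches of ≥2 samples and warns on genotype-confounded batches.
BED coordinates are 0-based half-open throughout; bin membership is by
integer division of the locus start.  All stochastic operations take an
explicit seed; the same seed reproduces outputs byte-identically.

## Known limitations

* The energy model's affine loop penalties flatten Turner's tabulated
  small-loop structure; energies are comparable within the bundled
  parameter version only, and no partition function (ensemble) quantities
  are computed.
* The batch adjustment is not empirical-Bayes; with very few samples per
  batch its per-gene scale estimates are noisy.
* The screen uses marginal Pearson correlations; co-regulated gene modules
  or shared miRNA targets would inflate apparent hits.
* miR-802's mature sequence is a reconstruction from the published sponge
  oligo, not a literature import.
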