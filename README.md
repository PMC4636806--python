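# mirdecoy

Tools for the computational arm of a lentiviral miRNA-sponge screen in a
trisomic (Down-syndrome model) mouse brain.  The Ts65Dn mouse carries a third
copy of a chromosome-16 segment harboring two miRNAs, miR-155 and miR-802;
both are overexpressed (~1.5x) and repress their mRNA targets more strongly
than in euploid littermates.  A *sponge* (decoy) transcript carrying several
bulged miRNA binding sites sequesters the excess miRNA and renormalizes
target expression; comparing expression across euploid/trisomic x
control/sponge groups then exposes the miRNA dosage-sensitive genes.

The package covers both halves of that experiment:

* **Decoy design and scoring** — construct perfect and bulged sponge sites
  and multi-site cassettes from a mature miRNA; score miRNA:site
  hybridization with an exact intermolecular minimum-free-energy (MFE)
  dynamic program over nearest-neighbor stacking energies (Turner-style,
  G·U wobbles, affine bulge/interior-loop penalties, no intramolecular
  pairs), against four null site categories: perfect, bulged, fully random,
  and random with the seed match fixed.
* **Target identification** — quantile normalization, location-scale batch
  adjustment, qPCR quantities (ΔCt, ΔΔCt, RQ = 2^-ΔΔCt), then a
  `TargetScreen` model computing per-pair Pearson correlations between gene
  expression and miRNA abundance across all samples, the filter
  *r < 0 ∧ p < 0.05 ∧ ≥1 predicted site*, candidate ranking by predicted
  site count and correlation strength, site-count stratification, GSEA-style
  enrichment with a permutation null, 1-Mb genomic binning, and cross-study
  fold-change concordance.
* **Synthetic cohorts** — a generator that emulates the 2x2 study design
  with segmental 1.5x dosage, sponge-renormalized miRNA overexpression,
  per-site multiplicative repression, noise and batch structure, together
  with ground truth, so the whole pipeline is testable end to end.

## Worked example

```python
from mirdecoy import MatureMiRNA, bulged_site, duplex_mfe, load_default_parameters
from mirdecoy.cohort import CohortConfig, generate_cohort, truth_eval
from mirdecoy.pipeline import screen_cohort

mir155 = MatureMiRNA("mmu-miR-155", "UUAAUGCUAAUUGUGAUAGGGGU")
site = bulged_site(mir155, seed_rng=7)          # 22-nt site, 3-nt central bulge
print(site.site_sequence)                       # ACCCCUAUCACUUGAGCAUUAA
print(duplex_mfe(mir155, site, load_default_parameters()).mfe)  # -31.16 kcal/mol

data = generate_cohort(CohortConfig(seed=1))    # 2000 genes x 20 samples + truth
results = screen_cohort(data)                   # qnorm + batch adjust + screen
print(results.summary())
```

```
miRNA target anticorrelation screen
  samples per pair: 20
  alpha: 0.05 (unadjusted)
  mmu-miR-155: 2000 genes tested, 899 negatively correlated, 91 candidates pass the filter
    gene01562    sites=4 r=-0.943 p=4.58e-10
    ...
  mmu-miR-802: 2000 genes tested, 899 negatively correlated, 90 candidates pass the filter
```

The bulged site binds its miRNA at -31.2 kcal/mol — weaker than the perfect
duplex (-40.5) but far stronger than seed-only or random 22-mers, which is
the design point: stable binding without Ago2-mediated cleavage.  Scoring
the ranked candidates against the generator's truth:

```python
k = min(200, len(results.candidates))
print(truth_eval(results.candidates, data.truth, k))   # (0.87, 0.039)
```

87% of the 200 planted targets are recovered in the top of the ranking with
a 3.9% false-discovery proportion.

A full pipeline run (`simulate → preprocess → correlate → enrich →
topology`) is available from the shell:

```sh
mirdecoy run --seed 1 -o runs/demo
mirdecoy design --mirna-fasta mirnas.fa --seed 7 -o cassette.fasta
mirdecoy energy --mirna-fasta mirnas.fa --nulls 100 --seed 7 -o fig_report.tsv
```

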