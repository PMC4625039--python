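# polyherit

Partitioning the polygenic signal and SNP-heritability of a binary disease
across genomic compartments and cell-type regulatory annotations.

Complex diseases such as coronary artery disease are driven by thousands of
common variants of small effect, and a central question is *where* in the
genome that risk resides: in protein-coding sequence, in the noncoding
territory flanking genes, in intergenic space, or in the regulatory elements
(histone-mark peaks, enhancer states) of particular cell types.  `polyherit`
implements the full analysis stack used to answer that question with
genome-wide association data, exercised end-to-end on synthetic cohorts with
known ground truth:

- **Synthetic cohorts** — block-LD genotype dosages, a liability-threshold
  disease with annotation-concentrated heritability
  (case iff liability > Φ⁻¹(1−K), default prevalence K = 0.06), case-enriched
  ascertainment, gene models, per-(mark, cell type) peak tracks, a
  scale-free PPI graph.
- **Annotation** — exclusive genic-coding / genic-noncoding / intergenic
  compartments at ±10/20/50 kb windows; SNP × (mark, cell type) overlap;
  LD expansion of lead SNPs at r² ≥ 0.8; locus-to-gene regulatory windows
  (TSS − 110 kb to TES + 40 kb, strand-aware).
- **Association** — GWAS QC (call rate, MAF, HWE, imputation info) and an
  additive logistic dosage scan producing summary statistics; Mann–Whitney
  comparison of association strength between variant sets.
- **Polygenic scores** — PRSᵢ = Σⱼ βⱼ dᵢⱼ over SNPs passing a discovery
  P threshold, risk-allele oriented (β > 0), evaluated by logistic Wald test
  and Nagelkerke R² across a 13-point threshold grid, per compartment, with
  optional ±1 Mb known-locus exclusion.
- **Heritability** — GCTA-style GRMs, relatedness pruning (cutoff 0.05),
  multi-component average-information REML with per-component
  boundary-mixture likelihood-ratio tests, liability-scale transformation
  h²_l = h²_o·K²(1−K)²/(z²P(1−P)), enrichment of variance
  (%variance / %SNPs), deviation-from-expected z-test, inverse-variance
  meta-analysis.
- **Enrichment** — proportion enrichment with exact 2×2 tests, matched-null
  SNP sampling (MAF ±0.05, LD buddies / gene distance / gene density ±10%),
  empirical permutation overlap p, fold enrichment with Bonferroni
  correction, locus × cell-type overlap matrices with complete-linkage
  clustering and breadth summaries.
- **Network** — direct PPI connectivity among locus genes with a
  degree-binned 1,000-permutation empirical p.

## Worked example

```python
import polyherit as ph
from polyherit.heritability import LiabilityScaleParams
import numpy as np

cfg = ph.SimulationConfig(
    n_individuals=2000, n_snps=1500, prevalence=0.06,
    sample_case_fraction=0.5,
    h2_by_compartment={"genic_coding": 0.10, "genic_noncoding": 0.25,
                       "intergenic": 0.07},
    seed=7,
)
study = ph.simulate_study(cfg, n_genes=15)

labels = study.assignment.labels.to_numpy()
grms = [ph.compute_grm(study.cohort, np.flatnonzero(labels == c))
        for c in ph.COMPARTMENTS]
fit = ph.reml_fit(study.cohort.phenotype, study.cohort.covariates, grms)
lp = LiabilityScaleParams(0.06, study.cohort.phenotype.mean())
for comp, ratio, se in zip(ph.COMPARTMENTS, fit.ratios, fit.se_ratios):
    print(f"{comp:16s} h2_liability = {ratio * lp.multiplier:.3f}"
          f" (se {se * lp.multiplier:.3f})")
```

prints (seed 7):

```
genic_coding     h2_liability = 0.073 (se 0.014)
genic_noncoding  h2_liability = 0.241 (se 0.021)
intergenic       h2_liability = 0.046 (se 0.018)
```

i.e. the three variance components jointly fitted on an ascertained
case-control cohort of 2,000, converted to the liability scale with
K = 0.06 and the observed 50% case proportion.  The genic-noncoding
compartment's concentration of heritability (simulated 0.25 vs 0.10 /
0.07) is clearly resolved.  Estimates on ascertained binary data sit
systematically a little below the simulated truth — the known attenuation
of REML's liability transform under strong ascertainment, quantified in
`docs/methods.md`.

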