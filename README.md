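# cpghm — somatic CpG hypermutation discovery in cancer cohorts

Some tumours accumulate an extreme load of C>T mutations at CpG
dinucleotides — the spectrum of spontaneous 5-methylcytosine deamination
left unrepaired, most often under MutSα (MSH2/MSH6) mismatch-repair
deficiency. This "CpG hypermutator" phenotype matters clinically: it is
concentrated in colorectal cancer and paediatric malignancies, converges
on TP53 hotspot driver mutations, and is associated with response to
immune checkpoint inhibitors (ICI). `cpghm` is a library + CLI for
discovering and characterising the phenotype in somatic mutation
catalogues, for analysts working with MAF-like cohort data.

## What it computes

**Classification.** A sample is a hypermutator (HM) when its mutation
count n exceeds the upper Tukey fence of its cohort (study × histology ×
sequencing method),

    n > Q3 + 1.5·IQR,

and its TMB exceeds the cohort-median floor. HM samples whose CpG>TpG
proportion — C>T SNVs at Np[C>T]pG contexts over classified SNVs —
exceeds a cohort-wide Tukey fence are **HM_CpG-Hi** (CpG hypermutators);
the rest are HM_CpG-Lo. On large pan-cancer cohorts this proportion fence
evaluates to Q3 + 1.5·IQR = 0.305 + 1.5·0.193 ≈ 0.60.

**Characterisation.** SBS96 spectra and cosine matching against a
signature reference (SBS1-like identity is the expected signature of the
phenotype); P-MACD-style motif enrichment with nCg/rCg models, Fisher
confirmation and minimum motif-specific mutation loads; per-cancer-type
exact binomial prevalence tests; TP53 CpG-convergence summaries (fold
enrichment over sequence expectation, ≥1% hotspot sites, per-stratum
C>T-at-CpG rates); expression z-score silencing flags; a simplified
trinucleotide-aware dN/dS scan with calibrated profile-likelihood tests;
and TMB/CpG-stratified ICI survival analysis (Kaplan–Meier, log-rank,
unadjusted and TMB-adjusted Cox models).

**Synthetic cohorts.** A fully self-contained generator (reference genome
with tunable CpG density, exome BED, in-frame genes with TP53-like CpG
hotspots, signature-structured catalogues with planted hypermutators,
MMR genotypes, expression, and survival) with truth labels, so every
stage is testable end to end. See `docs/methods.md` for the model and its
limits.

## Worked example

```python
import cpghm
from cpghm.simulate import SyntheticConfig, generate_catalog

cohort = generate_catalog(SyntheticConfig(seed=0))          # 2000 samples
catalog = cpghm.annotate_context(cohort.catalog, cohort.reference.genome)
model = cpghm.CpGHypermutatorModel(
    catalog, cohort.meta,
    regions=cohort.reference.regions,
    config=cpghm.ClassifierConfig(rng_seed=0),
)
results = model.fit()
print(results.summary())
```

```
CpG hypermutator classification
===============================================
cohorts (study|histology|method): 4
samples classified:               2043
TMB floor (median, mut/Mb):       800
global CpG>TpG threshold:         0.4254

label counts        sample  patient
  non-HM              1832     1792
  HM_CpG-Lo            202      199
  HM_CpG-Hi              9        9
```

The fitted thresholds are estimated from the data: the TMB floor is the
cohort median (the synthetic genome is desk-scale, so mut/Mb values are
uniformly inflated — every classifier rule is scale-free), and the
global CpG>TpG fence (0.425 here) is the Tukey fence of the per-sample
proportion distribution. All 9 planted CpG hypermutators are recovered
(`cohort.truth` carries the planted labels). Survival stratification on a
synthetic ICI cohort:

```python
from cpghm.simulate import generate_ici_cohort
from cpghm.survival import IciSurvivalModel

clinical, hazards = generate_ici_cohort(seed=0)   # 1661 patients
print(IciSurvivalModel(clinical).fit().summary())
```

```
ICI survival stratification
===============================================
stratum sizes: TMB-Lo=1173, TMB-Hi_CpG-Lo=469, TMB-Hi_CpG-Hi=19
CpG>TpG cut-off: 0.6
log-rank chi2 = 62.82, p = 2.29e-14

Cox PH (reference TMB-Lo), unadjusted:
                 hr  ci_low  ci_high  p_value
covariate
TMB-Hi_CpG-Lo 0.607   0.529    0.696 8.66e-13
TMB-Hi_CpG-Hi 0.274    0.13    0.576 0.000648
```

The estimated hazard ratios (0.61 for TMB-high, 0.27 for CpG
hypermutators, both vs TMB-low) recover the generator's planted hazards
and reproduce the magnitude of the survival benefit reported for CpG
hypermutators under ICI therapy.

The same pipeline runs from the shell:

```bash
cpghm simulate --seed 0 --out simdir/
cpghm ingest   --maf simdir/catalog.tsv --ref simdir/reference.fa \
               --bed simdir/exome.bed --out catalog.tsv
cpghm classify --catalog catalog.tsv --meta simdir/meta.tsv \
               --bed simdir/exome.bed --out calls.tsv
cpghm enrich   --catalog catalog.tsv --ref simdir/reference.fa --out enrich.tsv
cpghm survival --clinical simdir/clinical.tsv --out surv/
```

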