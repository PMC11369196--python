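# Methods

`cpghm` implements a pipeline for discovering somatic CpG hypermutation —
tumours whose mutation catalogue is dominated by C>T transitions at CpG
dinucleotides, the spectrum produced when spontaneous 5-methylcytosine
deamination goes unrepaired (typically under MutSα/MMR deficiency) — and
for quantifying its downstream consequences: signature identity, motif
enrichment, cohort prevalence, convergence on TP53 hotspots, selection
pressure, and survival under immune checkpoint inhibition (ICI).

## Mutation representation

Catalogues are MAF-like tables (1-based positions); target regions are BED
(0-based half-open); all coordinate conversions happen at the I/O
boundary. BED `[start, end)` covers 1-based positions `start+1 .. end`.
Every SNV is represented on the pyrimidine strand: a substitution with an
A/G reference allele is reverse-complemented together with its
trinucleotide context, so each SNV maps to one of the 96 channels in the
conventional COSMIC order (C>A, C>G, C>T, T>A, T>C, T>G blocks; 5' then 3'
base cycling A, C, G, T). Indels are retained in catalogues and counted in
discovery-mode TMB but never receive a 96-channel context; the CpG>TpG
proportion denominator is therefore classified SNVs only, and that
denominator choice is visible in the outputs.

A mismatch between a catalogue reference allele and the genome aborts with
a report rather than silently re-complementing: silent fixes hide genome
build mismatches, which are the usual cause.

## Hypermutator classification

A sample is a hypermutator (HM) when

1. its (region-restricted) mutation count exceeds the upper Tukey fence
   Q3 + 1.5·IQR of its cohort, where a cohort is one (study, histology,
   sequencing method) group; and
2. its TMB exceeds a cohort-wide floor, the median TMB over representative
   samples (guards against cohorts whose whole distribution is low).

HM samples whose CpG>TpG proportion exceeds a single cohort-wide Tukey
fence over per-sample proportions (samples with >10 mutations) are
HM_CpG-Hi — the CpG hypermutator phenotype; the rest are HM_CpG-Lo.
One representative sample per patient enters threshold estimation
(primaries preferred; ties broken by a seeded, order-invariant
per-patient stream; patients with only metastasis/relapse samples are
excluded from threshold estimation but still classified). Cohorts with
fewer than 20 representative samples are dropped.

Quantiles use linear interpolation between order statistics (the numpy
default). Tukey fences depend on the quantile convention, so it is fixed,
documented, and recorded in the run manifest. The CpG threshold can be
frozen (e.g. to 0.60, the value this rule yields on large pan-cancer
cohorts) for replication runs; the default recomputes it from the data,
because the fence is cohort-specific.

For ICI cohorts the strata are: TMB-Lo (coding TMB < 10 mut/Mb, the FDA
treatment threshold; coding TMB counts non-synonymous SNVs with VAF > 5%),
TMB-Hi_CpG-Lo, and TMB-Hi_CpG-Hi (TMB ≥ 10 and CpG>TpG proportion > 0.6).
A median-split mode for the CpG cut is available because both rules appear
in practice; the fixed 0.6 threshold is the default as it is the rule tied
to the phenotype definition.

## Signature matching

Per-sample spectra are normalised, the per-channel median across samples
is taken, and the median vector is renormalised (normalise → median →
renormalise; the alternative orderings differ only in degenerate cases).
Matching against a signature reference uses cosine similarity with the
conventional ≥ 0.9 match threshold, ties broken by column order. The
bundled reference is synthetic (four columns: an SBS1-like profile with
90% of mass evenly on the four N[C>T]G channels, a flat profile, a
non-CpG C>T profile, and a UV-like dipyrimidine C>T profile); users supply
the real COSMIC TSV for production work.

## Motif enrichment (P-MACD-style)

For each sample, C>T mutations are compared with motif availability in
±20 nt windows around each mutated position (both strands counted via
pyrimidine normalisation; overlapping windows counted once per mutation
window; windows truncated at contig ends with a warning):

    enrichment = (m_motif · n_base) / (m_base · n_motif)
    min_load   = m_motif · max(0, (enrichment − 1)/enrichment)

with a one-sided Fisher exact test on [[m_motif, m_base−m_motif],
[n_motif, n_base−n_motif]]. Two motif models: nCg (any Np[C>T]pG) and rCg,
which restricts the 5' base to purines (A/G). The rCg definition exists to
exclude the dipyrimidine contexts (Cp[C>T]pG, Tp[C>T]pG) that overlap the
UV photoproduct signature; a source describing this model prints
"R = C or T", which contradicts its own stated purpose (those are the
pyrimidines being excluded) and the IUPAC meaning of R. We treat that as a
typo and use purines, but ship the literal pyrimidine reading as a third
selectable model (`rCg_yCg`) so the choice is auditable.

## Cohort statistics

Per-cancer-type prevalence uses the one-sided exact binomial tail
P(X ≥ x | n, p0) with p0 the cohort-wide frequency of CpG-hypermutated
samples (sample-level counts by default; BH q-values reported alongside
raw p). Two-by-two contrasts use Fisher's exact test (two-sided p by
hypergeometric summation of tables no more probable than observed) with
the sample odds ratio; zero off-diagonal cells give an infinite OR, or a
0.5-continuity-corrected OR on request.

Gene-level CpG convergence: the expected probability that a uniformly
random coding SNV is a C>T at CpG is 2·(#CG dinucleotides)/(3·L) — each CG
contributes a CpG cytosine on both strands, one qualifying alternative
allele each, out of 3L possible substitutions. Fold enrichment is
observed/expected. Hotspots are sites carrying ≥ 1% (inclusive boundary)
of the gene's mutations. The expression silencing flag z-scales each
gene's expression across the cohort and flags z < −2, requiring ≥ 10
observations and non-zero variance.

## Simplified dN/dS

Selection is quantified per gene and globally as w = dN/dS under a
trinucleotide-aware opportunity model: every coding site contributes three
possible substitutions, each labelled synonymous/missense/nonsense by the
genetic code and assigned a pyrimidine-strand channel from its genomic
context. Per-channel neutral rates are anchored on synonymous counts
pooled across genes.

The test of w = 1 is a profile likelihood ratio: counts per channel are
Poisson with free per-channel rates, the target class scaled by w; for
fixed w the rate MLE is (s_c+m_c)/(a_c + w·b_c), giving the 1-D profile
log-likelihood l(w) = M·log w − Σ n_c·log(a_c + w·b_c). Profiling the
rates (rather than conditioning on synonymous-only estimates) keeps the
LRT calibrated — the alternative treats the neutral rate as known and is
badly anti-conservative. Confidence intervals invert the profile deviance
at the χ²(1) 95% point; gene-level p combines the missense and nonsense
deviances on 2 df; q-values are Benjamini–Hochberg. Channels with no
synonymous opportunity carry no information about w (their free rate
absorbs the scale) and are excluded; w_hat is reported as infinite in the
degenerate case where no synonymous anchor overlaps the target channels.

This is a deliberate simplification of full driver-discovery frameworks:
no negative-binomial gene-level rate dispersion, no covariates, no indel
model. It flags strong selection signals and calibrates correctly under
neutrality (LRT p-values are uniform in simulation), but per-gene results
on real cohorts would be noisier than a full model's.

## Survival analysis

Kaplan–Meier estimation, log-rank tests and Cox proportional-hazards
regression are delegated to lifelines (Efron tie handling; Wald CIs).
Strata enter the Cox model as treatment dummies against the TMB-Lo
reference; both an unadjusted model and one adjusted for continuous TMB
are reported, since the CpG stratum's effect should survive adjustment for
raw burden if it carries independent information. Strata without events
are reported with an infinite HR and a warning rather than dropped.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes, at
desk scale, with truth labels for every planted feature. Defaults (the
study conditions for all tests):

- **Reference**: 100 kb single-contig genome, CpG dinucleotide density
  adjusted to 0.05, exome tiling covering ~60%, five in-frame genes
  written into exome intervals including a TP53-like gene with ≥ 5
  designated CpG (arginine-codon) hotspot sites and MSH2/MSH6-like genes.
- **Cohort layout**: 2 studies × 2 histologies × 500 samples (2000 total),
  plus ~2% extra metastasis samples and ~1% metastasis-only patients to
  exercise representative selection.
- **Burden**: bulk samples draw log-normal burden (median 1.5 mut/Mb,
  σ = 0.8) over a virtual 30-Mb exome territory; counts are placed in the
  small genome, so TMB against the desk-scale BED is uniformly inflated —
  harmless, because every TMB rule in the classifier is scale-free
  (median floor, within-cohort fences). Hypermutators (6% of samples; 4%
  of those CpG-Hi) scale the cohort median burden by a log-normal factor
  (median 15×, σ = 0.4) truncated below at 8×. The truncation guarantees
  that a planted hypermutator is a realised burden outlier (≥ 12 mut/Mb
  against fences around 4–6), so truth labels always describe the planted
  phenotype; without it, a low base draw can cancel the factor and plant a
  "hypermutator" inside the bulk.
- **Spectra**: per-sample channel distributions are signature mixtures.
  CpG hypermutators put uniform(0.8, 0.98) weight on the SBS1-like column;
  other classes draw Beta-distributed SBS1-like weight (mean ≈ 0.15,
  matching the ~0.185 median CpG proportion of real pan-cancer cohorts)
  that is further diluted as relative burden grows (`clock_dilution`):
  high bulk burden comes from non-CpG processes, so a bulk draw cannot sit
  above both the burden and CpG fences simultaneously. Placement is exact
  indexed sampling — every exome position is pre-indexed by pyrimidine
  triplet and each sampled channel draws a position from the matching pool
  — which is exact and cannot fail, unlike capped rejection sampling.
- **Genetics**: MutSα-mutant genotypes at baseline rate 0.02 with odds
  ratio 48 in CpG hypermutators; TP53-like mutations added with
  probability 0.3 per sample, placed at a CpG hotspot site with
  probability 0.75 (CpG-Hi) vs 0.25 (others).
- **Survival**: the ICI cohort defaults to 1661 patients with stratum
  sizes 1173/469/19 and exponential monthly hazards 0.063/0.0365/0.017
  (hazard ratios ≈ 0.58 and 0.27 vs TMB-Lo) under uniform censoring.

All randomness flows from one seed through named substreams (reference,
labels, burdens, placement, genotypes, metadata), so components can be
regenerated independently and the same seed reproduces every output
byte-for-byte.

**What the generator does not emulate**: real per-cancer-type burden
distributions, subclonal structure/VAF biology (VAFs are Beta(8,8) noise),
linked germline variants, copy number, MSI status, panel sequencing
artefacts, or genome-scale context heterogeneity (CpG islands are a
density adjustment, not annotated features). Passing tests therefore show
that the algorithms recover planted structure under the stated model —
not that the pipeline's thresholds transfer unchanged to any real cohort.

## Problem sizes and numerical choices

Test and acceptance runs use the 2000-sample cohort (~250k mutations),
10⁴-mutation neutral dN/dS simulations with 1000 replicates of 300
mutations for calibration checks, 1000 patients per arm for hazard-ratio
recovery, and 5000 placements for the motif null. Degenerate inputs are
handled explicitly: empty spectra and zero-mutation samples yield NaN
proportions and are excluded from proportion analyses; constant
distributions give degenerate fences with a warning; zero-variance
expression yields no flags; tables with empty margins and Cox fits
without events raise.
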