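"""Self-contained synthetic cohorts for the CpG-hypermutation pipeline.

The generator emulates the statistical structure the pipeline assumes in
real pan-cancer catalogues, at desk scale:

- a random reference genome with tunable CpG dinucleotide density, an
  exome region set and in-frame genes, including a TP53-like gene with
  designated CpG hotspot codons;
- per-sample mutation burdens that are log-normal (median ~1.5 mut/Mb over
  a virtual 30-Mb exome territory) with a heavy right tail;
- mutation spectra drawn from mixtures of bundled synthetic signatures,
  with planted hypermutators in CpG-high (SBS1-like weight >= 0.8) and
  CpG-low flavours;
- MutSalpha (MSH2/MSH6-like) genotypes enriched in CpG hypermutators at a
  configurable odds ratio;
- TP53-like mutations placed preferentially at CpG hotspot sites in CpG
  hypermutators;
- expression matrices with planted silenced outliers, and ICI survival
  cohorts with stratum-specific exponential hazards.

Every sample carries a truth label so downstream tests can score
parameter recovery.  All randomness flows from one seed through named
substreams; the same seed reproduces every output byte-for-byte.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import RegionSet
from .dnds import build_coding_model, CodingModel
from .spectrum import CHANNELS, revcomp, synthetic_signatures

LABELS = ("non-HM", "HM_CpG-Lo", "HM_CpG-Hi")

_STOP_CODONS = {"TAA", "TAG", "TGA"}
_HOTSPOT_CODONS = ("CGA", "CGG", "CGC", "CGT")  # arginine, CpG at codon pos 1-2


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic cohort generator."""

    seed: int = 0
    # cohort layout
    n_studies: int = 2
    histologies: tuple = ("HIST-A", "HIST-B")
    samples_per_cohort: int = 500
    method: str = "WES"
    extra_metastasis_fraction: float = 0.02
    metastasis_only_fraction: float = 0.01
    # burden model (mut/Mb over a virtual exome territory)
    burden_median: float = 1.5
    burden_sigma: float = 0.8
    territory_mb: float = 30.0
    hm_burden_factor_median: float = 15.0
    hm_burden_factor_sigma: float = 0.4
    hm_min_burden_factor: float = 8.0  # guarantees planted HM are outliers
    clock_dilution: float = 3.0  # SBS1-like weight shrinks with burden
    # class mix
    hm_fraction: float = 0.06
    cpg_hm_fraction_of_hm: float = 0.04
    # spectra (signature mixture weights on the SBS1-like column)
    sbs1_weight_cpg_hm: tuple = (0.8, 0.98)  # uniform range, mean ~0.89
    sbs1_beta_non_hm: tuple = (3.0, 17.0)  # Beta params, mean 0.15
    sbs1_beta_hm_lo: tuple = (2.0, 18.0)  # mean 0.10
    indel_rate: float = 0.02
    # genetics
    mmr_baseline_rate: float = 0.02
    mmr_or: float = 48.0
    tp53_mutation_prob: float = 0.3
    tp53_cpg_site_prob: tuple = (0.25, 0.75)  # (non-CpG-HM, CpG-HM)
    # reference
    genome_length: int = 100_000
    cpg_density: float = 0.05
    exome_fraction: float = 0.6

    def __post_init__(self):
        for f in (self.hm_fraction, self.cpg_hm_fraction_of_hm, self.cpg_density,
                  self.exome_fraction, self.mmr_baseline_rate, *self.tp53_cpg_site_prob):
            if not 0 <= f <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if self.genome_length < 10_000:
            raise ValueError("genome_length must be at least 10 kb")


def _stream(seed: int, name: str) -> np.random.Generator:
    """Named RNG substream so components can be regenerated independently."""
    return np.random.default_rng([seed, zlib.crc32(name.encode())])


# ---------------------------------------------------------------------------
# reference genome


@dataclass
class Reference:
    """Synthetic reference: genome, exome regions, genes, hotspot sites."""

    genome: dict[str, str]
    regions: RegionSet
    genes: pd.DataFrame  # gene, chrom, start, end, strand
    tp53_hotspots: list[int]  # 1-based genomic positions of hotspot CpG cytosines
    seed: int

    def write(self, outdir) -> None:
        """Write FASTA (+ .fai via pyfaidx on first read), BED and gene TSV."""
        import pathlib

        outdir = pathlib.Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "reference.fa", "w") as fh:
            for chrom, seq in self.genome.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
        self.regions.to_bed(outdir / "exome.bed")
        self.genes.to_csv(outdir / "genes.tsv", sep="\t", index=False)


def _random_orf(rng: np.random.Generator, n_codons: int,
                hotspot_every: int | None = None) -> tuple[str, list[int]]:
    """ATG + random non-stop codons + TAA; optionally plant CpG (arginine)
    hotspot codons every ``hotspot_every`` codons.  Returns the sequence and
    the 0-based in-CDS offsets of the hotspot cytosines."""
    codons = ["ATG"]
    hotspot_offsets = []
    all_codons = ["".join(c) for c in itertools.product("ACGT", repeat=3)]
    safe = [c for c in all_codons if c not in _STOP_CODONS and c != "ATG"]
    for i in range(1, n_codons - 1):
        if hotspot_every and i % hotspot_every == 0:
            codon = _HOTSPOT_CODONS[rng.integers(len(_HOTSPOT_CODONS))]
            hotspot_offsets.append(3 * i)  # offset of the C of the CpG
        else:
            codon = safe[rng.integers(len(safe))]
        codons.append(codon)
    codons.append("TAA")
    return "".join(codons), hotspot_offsets


def _adjust_cpg_density(seq: np.ndarray, target_density: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Add or remove CG dinucleotides until the CpG density matches."""
    n = len(seq)
    target = int(round(target_density * (n - 1)))
    for _ in range(50):
        is_cg = (seq[:-1] == "C") & (seq[1:] == "G")
        starts = np.flatnonzero(is_cg)
        excess = len(starts) - target
        if excess == 0:
            break
        if excess > 0:
            kill = rng.choice(starts, size=excess, replace=False)
            seq[kill + 1] = rng.choice(np.array(["A", "T"]), size=excess)
        else:
            spots = rng.integers(0, n - 1, size=-excess)
            seq[spots] = "C"
            seq[spots + 1] = "G"
    return seq


def generate_reference(config: SyntheticConfig) -> Reference:
    """Generate the synthetic genome, exome BED and gene models."""
    rng = _stream(config.seed, "reference")
    n = config.genome_length
    seq = rng.choice(np.array(list("ACGT")), size=n)
    seq = _adjust_cpg_density(seq, config.cpg_density, rng)

    # exome tiling: alternate target/gap blocks to reach the exome fraction
    block = 3000
    gap = int(block * (1 - config.exome_fraction) / max(config.exome_fraction, 1e-9))
    intervals = []
    pos = 500
    while pos + block < n - 500:
        intervals.append(("chr1", pos, pos + block))
        pos += block + gap
    regions = RegionSet(pd.DataFrame(intervals, columns=["chrom", "start", "end"]))

    # genes written into the first exome intervals
    gene_specs = [("TP53", 150, 20), ("MSH2", 120, None), ("MSH6", 120, None),
                  ("GENE1", 100, None), ("GENE2", 100, None)]
    genes = []
    tp53_hotspots: list[int] = []
    for (name, n_codons, hotspot_every), (chrom, istart, iend) in zip(gene_specs, intervals):
        orf, hotspot_offsets = _random_orf(rng, n_codons, hotspot_every)
        start = istart + 50
        end = start + len(orf)
        if end > iend:
            raise ValueError("gene does not fit its exome interval")
        seq[start:end] = list(orf)
        genes.append((name, chrom, start, end, "+"))
        if name == "TP53":
            tp53_hotspots = [start + off + 1 for off in hotspot_offsets]  # 1-based C
    genome = {"chr1": "".join(seq)}
    gene_df = pd.DataFrame(genes, columns=["gene", "chrom", "start", "end", "strand"])
    return Reference(genome=genome, regions=regions, genes=gene_df,
                     tp53_hotspots=tp53_hotspots, seed=config.seed)


# ---------------------------------------------------------------------------
# placement index


def _context_index(reference: Reference) -> dict[str, np.ndarray]:
    """Map each pyrimidine triplet to the exome positions (1-based) whose
    reference context matches it."""
    seq = reference.genome["chr1"]
    pools: dict[str, list[int]] = {}
    for _, row in reference.regions.intervals.iterrows():
        for p0 in range(max(row["start"], 1), min(row["end"], len(seq) - 1)):
            triplet = seq[p0 - 1 : p0 + 2]
            if triplet[1] not in "CT":
                triplet = revcomp(triplet)
            pools.setdefault(triplet, []).append(p0 + 1)
    return {k: np.asarray(v) for k, v in pools.items()}


_CHANNEL_TRIPLET_ALT = []
for _lab in CHANNELS:
    _five, _rest = _lab[0], _lab[2:]
    _ref, _alt, _three = _rest[0], _rest[2], _rest[4]
    _CHANNEL_TRIPLET_ALT.append((_five + _ref + _three, _alt))


# ---------------------------------------------------------------------------
# cohort generation


@dataclass
class SyntheticCohort:
    """Generated catalogue with metadata and planted truth."""

    catalog: pd.DataFrame
    meta: pd.DataFrame
    truth: pd.DataFrame
    reference: Reference
    config: SyntheticConfig
    coding_model: CodingModel = field(repr=False, default=None)

    def write(self, outdir) -> None:
        import pathlib

        outdir = pathlib.Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.reference.write(outdir)
        header = f"# seed={self.config.seed}\n"
        for name, df in (("catalog", self.catalog), ("meta", self.meta),
                         ("truth", self.truth)):
            path = outdir / f"{name}.tsv"
            with open(path, "w") as fh:
                fh.write(header)
                df.to_csv(fh, sep="\t", index=False)


def _draw_weights(label: str, cfg: SyntheticConfig, rng, burden_rel: float = 1.0
                  ) -> np.ndarray:
    """Signature mixture weights (SBS1like, SBSflat, CTother, UVlike).

    Outside the CpG-hypermutator class the clock-like (SBS1-like) weight
    is diluted as the relative burden grows: extra mutation load comes
    from other mutational processes, as in real tumours where only
    MMR-deficient hypermutation concentrates on CpG sites.
    """
    if label == "HM_CpG-Hi":
        lo, hi = cfg.sbs1_weight_cpg_hm
        w1 = rng.uniform(lo, hi)
        rest = rng.dirichlet([1.0, 1.0, 0.5])
    elif label == "HM_CpG-Lo":
        a, b = cfg.sbs1_beta_hm_lo
        w1 = rng.beta(a, b + cfg.clock_dilution * max(burden_rel - 1.0, 0.0))
        rest = rng.dirichlet([1.0, 4.0, 1.0])  # CTother-dominated
    else:
        a, b = cfg.sbs1_beta_non_hm
        w1 = rng.beta(a, b + cfg.clock_dilution * max(burden_rel - 1.0, 0.0))
        rest = rng.dirichlet([2.0, 2.0, 1.0])
    w = np.empty(4)
    w[0] = w1
    w[1:] = (1 - w1) * rest
    return w


def generate_catalog(config: SyntheticConfig, reference: Reference | None = None
                     ) -> SyntheticCohort:
    """Generate the full synthetic cohort.

    Mutations are placed by exact indexed sampling: every exome position is
    pre-indexed by its pyrimidine triplet and each sampled SBS96 channel
    draws a position from the matching pool, so the reference allele always
    matches the genome.  Channels whose triplet is absent from the exome
    are renormalised away (none at default CpG density).
    """
    if reference is None:
        reference = generate_reference(config)
    cfg = config
    sigs = synthetic_signatures().to_numpy()  # 96 x 4
    pools = _context_index(reference)
    coding = build_coding_model(reference.genome, reference.genes)
    subs = coding.substitutions
    cons_lookup = {
        (c, p, a): (g, q)
        for c, p, a, g, q in zip(subs["chrom"], subs["pos"], subs["alt"],
                                 subs["gene"], subs["consequence"])
    }
    genome = reference.genome["chr1"]
    _cpg_ct = (
        subs["context3"].str.get(1).eq("C")
        & subs["context3"].str.get(2).eq("G")
        & (
            (subs["ref"].eq("C") & subs["alt"].eq("T"))
            | (subs["ref"].eq("G") & subs["alt"].eq("A"))
        )
    )
    tp53_noncpg_pool = subs[
        subs["gene"].eq("TP53")
        & subs["consequence"].isin(("missense", "nonsense"))
        & ~_cpg_ct
    ].reset_index(drop=True)

    rng_label = _stream(cfg.seed, "labels")
    rng_burden = _stream(cfg.seed, "burdens")
    rng_place = _stream(cfg.seed, "placement")
    rng_gt = _stream(cfg.seed, "genotypes")
    rng_meta = _stream(cfg.seed, "metadata")

    available = np.array([t in pools for t, _ in _CHANNEL_TRIPLET_ALT])

    cat_rows = []
    meta_rows = []
    truth_rows = []
    sample_no = 0
    for study_i in range(cfg.n_studies):
        study = f"STUDY{study_i + 1}"
        for hist in cfg.histologies:
            for _ in range(cfg.samples_per_cohort):
                sample_no += 1
                sid = f"S{sample_no:05d}"
                pid = f"P{sample_no:05d}"

                u = rng_label.random()
                if u < cfg.hm_fraction * cfg.cpg_hm_fraction_of_hm:
                    label = "HM_CpG-Hi"
                elif u < cfg.hm_fraction:
                    label = "HM_CpG-Lo"
                else:
                    label = "non-HM"

                if label == "non-HM":
                    burden = cfg.burden_median * np.exp(
                        rng_burden.normal(0.0, cfg.burden_sigma)
                    )
                else:
                    # planted hypermutators scale the cohort median by a
                    # heavy-tailed factor with a floor, so the planted label
                    # always corresponds to a realised burden outlier
                    factor = 0.0
                    while factor < cfg.hm_min_burden_factor:
                        factor = cfg.hm_burden_factor_median * np.exp(
                            rng_burden.normal(0.0, cfg.hm_burden_factor_sigma)
                        )
                    burden = cfg.burden_median * factor
                n_mut = int(rng_burden.poisson(burden * cfg.territory_mb))

                weights = _draw_weights(label, cfg, rng_burden,
                                        burden_rel=burden / cfg.burden_median)
                p96 = sigs @ weights
                p96 = np.where(available, p96, 0.0)
                p96 = p96 / p96.sum()
                channel_counts = rng_place.multinomial(n_mut, p96)
                for ch, m in enumerate(channel_counts):
                    if m == 0:
                        continue
                    triplet, alt_pyr = _CHANNEL_TRIPLET_ALT[ch]
                    positions = rng_place.choice(pools[triplet], size=m, replace=True)
                    for pos in positions:
                        gref = genome[pos - 1]
                        if gref in "CT":
                            alt = alt_pyr
                        else:
                            alt = revcomp(alt_pyr)
                        gene, cons = cons_lookup.get(("chr1", pos, alt), (pd.NA, "noncoding"))
                        cat_rows.append((sid, "chr1", pos, gref, alt, gene, cons,
                                         round(rng_place.beta(8, 8), 3)))

                # a small indel load (no 96-channel context)
                for _ in range(rng_place.poisson(cfg.indel_rate * max(n_mut, 1))):
                    iv = reference.regions.intervals.iloc[
                        rng_place.integers(len(reference.regions.intervals))
                    ]
                    pos = int(rng_place.integers(iv["start"] + 1, iv["end"] + 1))
                    cat_rows.append((sid, "chr1", pos, genome[pos - 1], "-",
                                     pd.NA, "indel", round(rng_place.beta(8, 8), 3)))

                # TP53-like convergence mutation
                tp53_at_cpg = pd.NA
                if rng_gt.random() < cfg.tp53_mutation_prob:
                    p_cpg = cfg.tp53_cpg_site_prob[label == "HM_CpG-Hi"]
                    if rng_gt.random() < p_cpg:
                        pos = int(reference.tp53_hotspots[
                            rng_gt.integers(len(reference.tp53_hotspots))
                        ])
                        gref, alt = "C", "T"
                        tp53_at_cpg = True
                    else:
                        pick = tp53_noncpg_pool.iloc[
                            int(rng_gt.integers(len(tp53_noncpg_pool)))
                        ]
                        pos, gref, alt = int(pick["pos"]), pick["ref"], pick["alt"]
                        tp53_at_cpg = False
                    gene, cons = cons_lookup.get(("chr1", pos, alt), ("TP53", "missense"))
                    cat_rows.append((sid, "chr1", pos, gref, alt, gene, cons,
                                     round(rng_gt.beta(8, 8), 3)))

                # MutSalpha genotype at the configured odds ratio
                p0 = cfg.mmr_baseline_rate
                odds1 = cfg.mmr_or * p0 / (1 - p0)
                p_mmr = odds1 / (1 + odds1) if label == "HM_CpG-Hi" else p0
                mmr = bool(rng_gt.random() < p_mmr)

                timing = "primary"
                meta_rows.append((sid, pid, study, hist, cfg.method, timing, "adult"))
                truth_rows.append((sid, label, float(weights[0]), float(burden),
                                   mmr, tp53_at_cpg))

                # occasional extra metastasis sample for the same patient
                if rng_meta.random() < cfg.extra_metastasis_fraction:
                    sample_no += 1
                    sid2 = f"S{sample_no:05d}"
                    meta_rows.append((sid2, pid, study, hist, cfg.method,
                                      "metastasis", "adult"))
                    truth_rows.append((sid2, label, float(weights[0]),
                                       float(burden), mmr, pd.NA))
                    # a light catalogue for the metastasis sample
                    m2 = max(1, n_mut // 2)
                    ch2 = rng_place.multinomial(m2, p96)
                    for ch, m in enumerate(ch2):
                        triplet, alt_pyr = _CHANNEL_TRIPLET_ALT[ch]
                        for pos in rng_place.choice(pools[triplet], size=m, replace=True):
                            gref = genome[pos - 1]
                            alt = alt_pyr if gref in "CT" else revcomp(alt_pyr)
                            gene, cons = cons_lookup.get(("chr1", pos, alt),
                                                         (pd.NA, "noncoding"))
                            cat_rows.append((sid2, "chr1", pos, gref, alt, gene,
                                             cons, round(rng_place.beta(8, 8), 3)))

    catalog = pd.DataFrame(
        cat_rows,
        columns=["sample_id", "chrom", "pos", "ref", "alt", "gene", "consequence", "vaf"],
    )
    catalog = catalog.drop_duplicates(
        subset=["sample_id", "chrom", "pos", "ref", "alt"]
    ).reset_index(drop=True)
    catalog["context3"] = pd.NA
    catalog = catalog[["sample_id", "chrom", "pos", "ref", "alt", "gene",
                       "consequence", "context3", "vaf"]]
    meta = pd.DataFrame(
        meta_rows,
        columns=["sample_id", "patient_id", "study_id", "histology", "method",
                 "timing", "age_group"],
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["sample_id", "true_label", "sbs1_weight", "burden_mut_per_mb",
                 "mmr_mutant", "tp53_at_cpg"],
    )
    return SyntheticCohort(catalog=catalog, meta=meta, truth=truth,
                           reference=reference, config=cfg, coding_model=coding)


# ---------------------------------------------------------------------------
# expression and survival


def generate_expression(samples, flagged_samples, genes=("MSH2", "MSH6", "MLH1", "PMS2"),
                        seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expression matrix (genes x samples) with planted silenced outliers.

    ``flagged_samples`` maps gene -> iterable of sample ids whose
    expression is planted 4 cohort-SDs below the gene mean.  Returns the
    matrix and a truth frame (gene, sample_id).
    """
    rng = _stream(seed, "expression")
    samples = list(samples)
    data = {}
    truth = []
    for gene in genes:
        mu, sd = rng.uniform(8, 12), rng.uniform(0.5, 1.5)
        vals = pd.Series(rng.normal(mu, sd, size=len(samples)), index=samples)
        for sid in flagged_samples.get(gene, ()):
            vals[sid] = mu - 4 * sd
            truth.append((gene, sid))
        data[gene] = vals
    expr = pd.DataFrame(data).T
    return expr, pd.DataFrame(truth, columns=["gene", "sample_id"])


def generate_ici_cohort(seed: int = 0, n: int = 1661,
                        stratum_fractions=(1173 / 1661, 469 / 1661, 19 / 1661),
                        monthly_hazards=(0.063, 0.0365, 0.017),
                        censor_max_months: float = 60.0) -> tuple[pd.DataFrame, dict]:
    """Synthetic ICI-treated clinical cohort with stratum-specific hazards.

    Stratum sizes default to the observed proportions of a large ICI
    cohort (TMB-Lo, TMB-Hi_CpG-Lo, TMB-Hi_CpG-Hi); survival times are
    exponential with the given monthly hazards (hazard ratios ~0.58 and
    ~0.27 vs TMB-Lo) under uniform censoring.  TMB and CpG proportions are
    drawn consistently with each stratum's definition.
    Returns (clinical frame, truth dict of hazards).
    """
    rng = _stream(seed, "ici")
    strata = ("TMB-Lo", "TMB-Hi_CpG-Lo", "TMB-Hi_CpG-Hi")
    counts = np.round(np.asarray(stratum_fractions) * n).astype(int)
    counts[0] = n - counts[1:].sum()
    rows = []
    k = 0
    for stratum, cnt, hz in zip(strata, counts, monthly_hazards):
        for _ in range(cnt):
            k += 1
            if stratum == "TMB-Lo":
                tmb = min(9.9, float(np.exp(rng.normal(np.log(3), 0.7))))
                prop = min(0.59, float(rng.beta(2, 9)))
            else:
                tmb = 10.0 + float(np.exp(rng.normal(np.log(15), 0.8)))
                if stratum == "TMB-Hi_CpG-Hi":
                    tmb = 10.0 + float(np.exp(rng.normal(np.log(32), 0.5)))
                    prop = 0.6 + 0.38 * float(rng.beta(2, 2))
                else:
                    prop = min(0.59, float(rng.beta(2, 9)))
            t_event = rng.exponential(1.0 / hz)
            t_cens = rng.uniform(1.0, censor_max_months)
            time = max(min(t_event, t_cens), 1e-3)
            rows.append((f"ICI{k:05d}", time, t_event <= t_cens, tmb, prop, stratum))
    clinical = pd.DataFrame(
        rows, columns=["sample_id", "time", "event", "tmb", "cpg_proportion",
                       "true_stratum"],
    )
    truth = dict(zip(strata, monthly_hazards))
    return clinical, truth


def simulate_two_arm_survival(n_per_arm: int, hazard_ratio: float, seed: int = 0,
                              baseline_hazard: float = 0.07,
                              censor_max: float = 60.0) -> pd.DataFrame:
    """Two-arm exponential survival simulation for HR-recovery checks."""
    rng = _stream(seed, "two-arm")
    rows = []
    for arm, hz in (("control", baseline_hazard),
                    ("treated", baseline_hazard * hazard_ratio)):
        t_event = rng.exponential(1.0 / hz, size=n_per_arm)
        t_cens = rng.uniform(1.0, censor_max, size=n_per_arm)
        time = np.minimum(t_event, t_cens)
        rows.append(pd.DataFrame({
            "time": np.maximum(time, 1e-3),
            "event": t_event <= t_cens,
            "stratum": arm,
            "tmb": np.nan,
        }))
    return pd.concat(rows, ignore_index=True)
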