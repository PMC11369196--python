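"""Dual Tukey-fence classification of somatic CpG hypermutators.

A sample is called a hypermutator (HM) when its somatic mutation count is
an upper Tukey outlier within its cohort (study x histology x sequencing
method) AND its tumour mutation burden exceeds a cohort-wide floor (the
median TMB over representative samples).  HM samples whose fraction of
C>T mutations at NpCpG contexts exceeds a single cohort-wide Tukey fence
are labelled HM_CpG-Hi (the CpG hypermutator phenotype); the remaining HM
samples are HM_CpG-Lo.

Quantiles use linear interpolation between order statistics (the numpy
default).  Tukey fences depend on the quantile convention, so it is fixed
here and recorded in the run manifest.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import spectrum as sp
from .catalog import RegionSet, compute_tmb, restrict_to_regions

log = logging.getLogger(__name__)

LABELS = ("non-HM", "HM_CpG-Lo", "HM_CpG-Hi")


@dataclass(frozen=True)
class TukeyFence:
    """Upper Tukey fence: upper = Q3 + multiplier * IQR."""

    q3: float
    iqr: float
    multiplier: float = 1.5

    @property
    def upper(self) -> float:
        return self.q3 + self.multiplier * self.iqr

    @classmethod
    def from_quartiles(cls, q3: float, iqr: float, multiplier: float = 1.5) -> "TukeyFence":
        if iqr < 0:
            raise ValueError("IQR must be non-negative")
        return cls(q3=q3, iqr=iqr, multiplier=multiplier)


def tukey_upper_fence(values, multiplier: float = 1.5) -> TukeyFence:
    """Upper outlier fence of a distribution of values.

    Q1/Q3 are linear-interpolation quantiles; requires at least two finite
    values.  With constant input the IQR is zero and the fence degenerates
    to the constant.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise ValueError("tukey_upper_fence requires at least 2 finite values")
    q1, q3 = np.quantile(x, [0.25, 0.75])
    iqr = q3 - q1
    if iqr == 0:
        log.warning("degenerate Tukey fence: IQR = 0, fence equals Q3 = %g", q3)
    return TukeyFence(q3=float(q3), iqr=float(iqr), multiplier=multiplier)


@dataclass
class ClassifierConfig:
    """Tunable thresholds of the CpG hypermutator classifier."""

    fence_multiplier: float = 1.5
    min_cohort_size: int = 20
    min_mutations_for_proportion: int = 10
    cpg_threshold: float | None = None  # None => recompute cohort-wide fence
    tmb_floor: float | None = None  # None => median TMB of representatives
    rng_seed: int = 0

    def __post_init__(self):
        if self.fence_multiplier <= 0 or self.min_cohort_size <= 0:
            raise ValueError("thresholds must be positive")


def _patient_rng(seed: int, patient_id: str) -> np.random.Generator:
    # order-invariant per-patient stream: same choice whatever the row order
    return np.random.default_rng([seed, zlib.crc32(str(patient_id).encode())])


def select_representative(meta: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Choose at most one representative sample per patient.

    Primary samples are preferred; among several primaries (or, failing
    any, among unknown-timing samples) one is drawn uniformly with a seeded
    per-patient stream.  Patients represented only by metastasis/relapse
    samples get no representative: they are excluded from threshold
    estimation but their samples are still classified.
    Returns the metadata with added boolean columns ``is_representative``
    and ``excluded_from_thresholds``.
    """
    out = meta.copy()
    out["is_representative"] = False
    out["excluded_from_thresholds"] = False
    for patient, grp in out.groupby("patient_id", sort=False):
        timing = grp["timing"]
        for pool_label in ("primary", "unknown"):
            pool = grp.index[timing == pool_label]
            if len(pool):
                chosen = sorted(pool, key=lambda i: str(out.at[i, "sample_id"]))
                pick = _patient_rng(seed, patient).integers(len(chosen))
                out.at[chosen[pick], "is_representative"] = True
                break
        else:
            out.loc[grp.index, "excluded_from_thresholds"] = True
    return out


def group_cohorts(meta: pd.DataFrame, min_cohort_size: int = 20) -> pd.DataFrame:
    """Assign cohort keys (study, histology, method) and drop small cohorts.

    Cohort size is counted over representative samples (call
    :func:`select_representative` first).  Samples in dropped cohorts are
    excluded from classification entirely; removals are logged.
    """
    out = meta.copy()
    out["cohort"] = (
        out["study_id"].astype(str)
        + "|"
        + out["histology"].astype(str)
        + "|"
        + out["method"].astype(str)
    )
    rep_counts = out[out["is_representative"]].groupby("cohort").size()
    keep = rep_counts[rep_counts >= min_cohort_size].index
    dropped = sorted(set(out["cohort"]) - set(keep))
    if dropped:
        log.info("dropping %d cohorts below %d representative samples: %s",
                 len(dropped), min_cohort_size, dropped)
    return out[out["cohort"].isin(keep)].reset_index(drop=True)


def global_cpg_threshold(
    proportions: pd.Series,
    n_mutations: pd.Series,
    min_mutations: int = 10,
    multiplier: float = 1.5,
) -> TukeyFence:
    """Cohort-wide CpG hypermutation threshold.

    Upper Tukey fence of the per-sample CpG>TpG proportion over samples
    with more than ``min_mutations`` (region-restricted) mutations.
    """
    eligible = proportions[(n_mutations.reindex(proportions.index) > min_mutations)]
    eligible = eligible.dropna()
    if len(eligible) < 2:
        raise ValueError("fewer than 2 samples eligible for the CpG threshold")
    return tukey_upper_fence(eligible.to_numpy(), multiplier=multiplier)


def ici_classify(tmb_coding, cpg_proportion, tmb_cut: float = 10.0, cpg_cut: float = 0.6):
    """Stratify ICI-treated samples by coding TMB and CpG>TpG proportion.

    TMB-Lo when coding TMB < ``tmb_cut`` (the FDA treatment threshold of 10
    coding mut/Mb); otherwise TMB-Hi_CpG-Hi when the CpG>TpG proportion
    exceeds ``cpg_cut`` (default 0.6) else TMB-Hi_CpG-Lo.  Accepts scalars
    or array-likes.
    """
    tmb = np.asarray(tmb_coding, dtype=float)
    prop = np.asarray(cpg_proportion, dtype=float)
    out = np.where(
        tmb < tmb_cut,
        "TMB-Lo",
        np.where(prop > cpg_cut, "TMB-Hi_CpG-Hi", "TMB-Hi_CpG-Lo"),
    )
    if out.ndim == 0:
        return out.item()
    return out


# ---------------------------------------------------------------------------
# model / results


class CpGHypermutatorModel:
    """Dual-outlier CpG hypermutator classifier for one discovery cohort.

    Parameters
    ----------
    catalog : DataFrame
        Annotated mutation catalogue (``context3`` set; see
        :func:`cpghm.catalog.annotate_context`).
    meta : DataFrame
        Sample metadata (sample_id, patient_id, study_id, histology,
        method, timing).
    regions : RegionSet, optional
        Uniform TMB territory.  When given, mutation counts and TMB are
        restricted to these regions; otherwise raw counts are used with a
        1-Mb nominal territory.
    config : ClassifierConfig, optional

    ``fit()`` estimates every threshold from the data (per-cohort burden
    fences, the cohort-wide CpG fence, the median-TMB floor) and returns a
    :class:`HypermutatorResults`.
    """

    def __init__(self, catalog, meta, regions: RegionSet | None = None,
                 config: ClassifierConfig | None = None):
        self.catalog = catalog
        self.meta = meta
        self.regions = regions
        self.config = config or ClassifierConfig()

    @classmethod
    def from_files(cls, catalog_path, meta_path, bed_path=None, config=None):
        from .catalog import read_catalog, read_sample_metadata

        regions = RegionSet.from_bed(bed_path) if bed_path else None
        return cls(read_catalog(catalog_path), read_sample_metadata(meta_path),
                   regions=regions, config=config)

    def fit(self) -> "HypermutatorResults":
        cfg = self.config
        cat = self.catalog
        if self.regions is not None:
            cat = restrict_to_regions(cat, self.regions)
            total_mb = self.regions.total_mb
        else:
            total_mb = 1.0

        meta = select_representative(self.meta, seed=cfg.rng_seed)
        meta = group_cohorts(meta, cfg.min_cohort_size)
        samples = meta["sample_id"]

        n_mut = cat.groupby("sample_id").size().reindex(samples, fill_value=0)
        n_mut.index = samples.index
        tmb = n_mut / total_mb
        props = pd.Series(
            {i: sp.cpg_ct_proportion(g) for i, g in cat.groupby("sample_id")}
        ).reindex(samples).set_axis(samples.index)

        calls = meta.copy()
        calls["n_mutations"] = n_mut.astype(int)
        calls["tmb"] = tmb
        calls["cpg_proportion"] = props

        rep = calls["is_representative"]
        # cohort-wide thresholds over representative samples
        if cfg.tmb_floor is not None:
            tmb_floor = float(cfg.tmb_floor)
        else:
            tmb_floor = float(calls.loc[rep, "tmb"].median())
        if cfg.cpg_threshold is not None:
            cpg_fence = TukeyFence(q3=float("nan"), iqr=float("nan"),
                                   multiplier=cfg.fence_multiplier)
            cpg_threshold = float(cfg.cpg_threshold)
        else:
            cpg_fence = global_cpg_threshold(
                calls.loc[rep, "cpg_proportion"],
                calls.loc[rep, "n_mutations"],
                min_mutations=cfg.min_mutations_for_proportion,
                multiplier=cfg.fence_multiplier,
            )
            cpg_threshold = cpg_fence.upper

        # per-cohort burden fences (representative samples define the fence,
        # every sample in the cohort is classified against it)
        fences = {}
        for cohort, grp in calls.groupby("cohort", sort=False):
            fences[cohort] = tukey_upper_fence(
                grp.loc[grp["is_representative"], "n_mutations"].to_numpy(),
                multiplier=cfg.fence_multiplier,
            )
        calls["burden_fence_upper"] = calls["cohort"].map(
            {k: f.upper for k, f in fences.items()}
        )

        is_hm = (calls["n_mutations"] > calls["burden_fence_upper"]) & (
            calls["tmb"] > tmb_floor
        )
        is_hi = is_hm & (calls["cpg_proportion"] > cpg_threshold)
        calls["label"] = np.where(is_hi, "HM_CpG-Hi", np.where(is_hm, "HM_CpG-Lo", "non-HM"))
        calls["global_cpg_threshold"] = cpg_threshold
        calls["tmb_floor"] = tmb_floor

        return HypermutatorResults(
            calls=calls,
            group_fences=fences,
            cpg_fence=cpg_fence,
            cpg_threshold=cpg_threshold,
            tmb_floor=tmb_floor,
            config=cfg,
        )


@dataclass
class HypermutatorResults:
    """Fitted thresholds and per-sample hypermutator calls."""

    calls: pd.DataFrame
    group_fences: dict[str, TukeyFence]
    cpg_fence: TukeyFence
    cpg_threshold: float
    tmb_floor: float
    config: ClassifierConfig

    @property
    def labels(self) -> pd.Series:
        return self.calls.set_index("sample_id")["label"]

    def counts(self, by: str = "sample") -> pd.Series:
        """Label tallies per sample or per patient (a patient counts as
        HM_CpG-Hi if any of its tumours does, then HM_CpG-Lo, else non-HM)."""
        if by == "sample":
            return self.calls["label"].value_counts().reindex(LABELS, fill_value=0)
        if by == "patient":
            rank = {lab: i for i, lab in enumerate(LABELS)}
            best = (
                self.calls.assign(rank=self.calls["label"].map(rank))
                .groupby("patient_id")["rank"]
                .max()
                .map({v: k for k, v in rank.items()})
            )
            return best.value_counts().reindex(LABELS, fill_value=0)
        raise ValueError("by must be 'sample' or 'patient'")

    def manifest(self) -> dict:
        """Run manifest: thresholds, seed and configuration."""
        return {
            "config": asdict(self.config),
            "quantile_convention": "linear interpolation between order statistics",
            "tmb_floor": self.tmb_floor,
            "global_cpg_threshold": self.cpg_threshold,
            "cpg_fence_q3": self.cpg_fence.q3,
            "cpg_fence_iqr": self.cpg_fence.iqr,
            "n_cohorts": len(self.group_fences),
        }

    def summary(self) -> str:
        lines = [
            "CpG hypermutator classification",
            "=" * 47,
            f"cohorts (study|histology|method): {len(self.group_fences)}",
            f"samples classified:               {len(self.calls)}",
            f"TMB floor (median, mut/Mb):       {self.tmb_floor:.4g}",
            f"global CpG>TpG threshold:         {self.cpg_threshold:.4f}",
            "",
            "label counts        sample  patient",
        ]
        cs, cp = self.counts("sample"), self.counts("patient")
        for lab in LABELS:
            lines.append(f"  {lab:<16} {cs[lab]:>7} {cp[lab]:>8}")
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.calls.to_csv(path, sep="\t", index=False)
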