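"""Somatic mutation catalogue I/O, context annotation and TMB.

The in-memory catalogue is a pandas DataFrame with one row per somatic
variant and columns::

    sample_id  chrom  pos  ref  alt  gene  consequence  context3  vaf

``pos`` is 1-based (MAF convention); BED regions are 0-based half-open and
all conversions happen at the I/O boundary.  ``context3`` is the
pyrimidine-normalised reference triplet, set by :func:`annotate_context`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectrum import revcomp

log = logging.getLogger(__name__)

CONSEQUENCES = (
    "synonymous",
    "missense",
    "nonsense",
    "splice",
    "noncoding",
    "indel",
    "other",
)

CATALOG_COLUMNS = [
    "sample_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "consequence",
    "context3",
    "vaf",
]

#: default MAF header -> catalogue column mapping
DEFAULT_MAF_COLUMNS = {
    "sample_id": "Tumor_Sample_Barcode",
    "chrom": "Chromosome",
    "pos": "Start_Position",
    "ref": "Reference_Allele",
    "alt": "Tumor_Seq_Allele2",
    "gene": "Hugo_Symbol",
    "consequence": "Variant_Classification",
    "vaf": "VAF",
}

#: MAF Variant_Classification -> consequence enum
MAF_CONSEQUENCE_MAP = {
    "Silent": "synonymous",
    "Missense_Mutation": "missense",
    "Nonsense_Mutation": "nonsense",
    "Nonstop_Mutation": "missense",
    "Splice_Site": "splice",
    "Splice_Region": "splice",
    "Frame_Shift_Del": "indel",
    "Frame_Shift_Ins": "indel",
    "In_Frame_Del": "indel",
    "In_Frame_Ins": "indel",
    "3'UTR": "noncoding",
    "5'UTR": "noncoding",
    "3'Flank": "noncoding",
    "5'Flank": "noncoding",
    "Intron": "noncoding",
    "IGR": "noncoding",
    "RNA": "noncoding",
}

_VALID_BASES = frozenset("ACGT")


def _is_snv(ref: str, alt: str) -> bool:
    return (
        isinstance(ref, str)
        and isinstance(alt, str)
        and len(ref) == 1
        and len(alt) == 1
        and ref in _VALID_BASES
        and alt in _VALID_BASES
    )


def read_maf(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read a MAF-like tab-separated somatic mutation file.

    ``column_map`` maps catalogue column names to file header names; the
    defaults follow the MAF standard.  Rows failing validation (unparseable
    position, ref == alt, non-ACGT SNV alleles) are dropped and reported
    with their line numbers; duplicate (sample, chrom, pos, ref, alt) rows
    are deduplicated with a logged count.
    """
    cmap = dict(DEFAULT_MAF_COLUMNS)
    if column_map:
        cmap.update(column_map)
    raw = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    # accept catalogue-standard names where the mapped MAF header is absent
    for col in list(cmap):
        if cmap[col] not in raw.columns and col in raw.columns:
            cmap[col] = col
    for col in ("sample_id", "chrom", "pos", "ref", "alt"):
        if cmap[col] not in raw.columns:
            raise ValueError(
                f"mandatory column {cmap[col]!r} (for {col}) missing from {path}"
            )
    df = pd.DataFrame(
        {
            "sample_id": raw[cmap["sample_id"]],
            "chrom": raw[cmap["chrom"]],
            "pos": pd.to_numeric(raw[cmap["pos"]], errors="coerce"),
            "ref": raw[cmap["ref"]].str.upper(),
            "alt": raw[cmap["alt"]].str.upper(),
        }
    )
    df["gene"] = raw[cmap["gene"]] if cmap["gene"] in raw.columns else pd.NA
    if cmap["consequence"] in raw.columns:
        df["consequence"] = (
            raw[cmap["consequence"]]
            .map(lambda v: MAF_CONSEQUENCE_MAP.get(v, v if v in CONSEQUENCES else "other"))
            .fillna("other")
        )
    else:
        df["consequence"] = "other"
    if cmap.get("vaf") in raw.columns:
        df["vaf"] = pd.to_numeric(raw[cmap["vaf"]], errors="coerce")
    else:
        df["vaf"] = np.nan
    df["context3"] = pd.NA

    # row-level validation (line numbers are 1-based incl. header)
    bad_pos = df["pos"].isna() | (df["pos"] < 1)
    snv_like = df["ref"].str.len().eq(1) & df["alt"].str.len().eq(1) & ~df["alt"].eq("-") & ~df["ref"].eq("-")
    bad_allele = snv_like & (
        ~df["ref"].isin(_VALID_BASES) | ~df["alt"].isin(_VALID_BASES)
    )
    same = df["ref"].eq(df["alt"])
    invalid = bad_pos | bad_allele | same
    if invalid.any():
        lines = (df.index[invalid] + 2).tolist()
        log.warning("%s: dropped %d invalid rows (file lines %s)", path, invalid.sum(), lines)
        df = df[~invalid]
    df["pos"] = df["pos"].astype(np.int64)

    n0 = len(df)
    df = df.drop_duplicates(subset=["sample_id", "chrom", "pos", "ref", "alt"])
    if len(df) < n0:
        log.warning("%s: removed %d duplicate rows", path, n0 - len(df))
    # flag indels so downstream filters never need to re-parse alleles
    if len(df):
        is_snv = (
            df["ref"].str.len().eq(1)
            & df["alt"].str.len().eq(1)
            & df["ref"].isin(_VALID_BASES)
            & df["alt"].isin(_VALID_BASES)
        )
        df.loc[~is_snv, "consequence"] = "indel"
    return df.reset_index(drop=True)[CATALOG_COLUMNS]


def write_catalog(catalog: pd.DataFrame, path) -> None:
    """Write an annotated catalogue as TSV (lossless round trip)."""
    catalog.to_csv(path, sep="\t", index=False)


def read_catalog(path) -> pd.DataFrame:
    """Read a catalogue written by :func:`write_catalog`."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample_id": str},
                     comment="#")
    df["context3"] = df["context3"].where(df["context3"].notna(), pd.NA)
    df["gene"] = df["gene"].where(df["gene"].notna(), pd.NA)
    return df[CATALOG_COLUMNS]


def read_sample_metadata(path) -> pd.DataFrame:
    """Read the sample metadata TSV.

    Expected columns: sample_id, patient_id, study_id, histology, method
    (WGS/WES), timing (primary/metastasis/relapse/unknown), and either
    age_group or an ``age`` column (age < 18 years marks paediatric).
    """
    meta = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = ["sample_id", "patient_id", "study_id", "histology", "method"]
    missing = [c for c in required if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing columns: {missing}")
    if "timing" not in meta.columns:
        meta["timing"] = "unknown"
    meta["timing"] = meta["timing"].fillna("unknown")
    if "age_group" not in meta.columns:
        if "age" in meta.columns:
            age = pd.to_numeric(meta["age"], errors="coerce")
            meta["age_group"] = np.where(
                age.isna(), "unknown", np.where(age < 18, "paediatric", "adult")
            )
        else:
            meta["age_group"] = "unknown"
    return meta


# ---------------------------------------------------------------------------
# regions


@dataclass
class RegionSet:
    """Normalised genomic intervals (0-based half-open) with Mb total."""

    intervals: pd.DataFrame  # columns chrom, start, end

    def __post_init__(self):
        df = self.intervals[["chrom", "start", "end"]].copy()
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if (df["end"] <= df["start"]).any():
            raise ValueError("intervals must satisfy start < end")
        df = df.sort_values(["chrom", "start"]).reset_index(drop=True)
        # merge overlapping/adjacent intervals per chromosome
        merged = []
        for chrom, grp in df.groupby("chrom", sort=False):
            cur_s = cur_e = None
            for s, e in zip(grp["start"], grp["end"]):
                if cur_s is None:
                    cur_s, cur_e = s, e
                elif s <= cur_e:
                    cur_e = max(cur_e, e)
                else:
                    merged.append((chrom, cur_s, cur_e))
                    cur_s, cur_e = s, e
            merged.append((chrom, cur_s, cur_e))
        self.intervals = pd.DataFrame(merged, columns=["chrom", "start", "end"])
        if self.total_mb <= 0:
            raise ValueError("RegionSet covers zero territory")

    @property
    def total_mb(self) -> float:
        return float((self.intervals["end"] - self.intervals["start"]).sum() / 1e6)

    @classmethod
    def from_bed(cls, path) -> "RegionSet":
        bed = pd.read_csv(
            path, sep="\t", header=None, usecols=[0, 1, 2], names=["chrom", "start", "end"],
            dtype={0: str}, comment="#",
        )
        return cls(bed)

    def to_bed(self, path) -> None:
        self.intervals.to_csv(path, sep="\t", header=False, index=False)

    def contains(self, chrom, pos_1based) -> np.ndarray:
        """Vectorised membership test for 1-based positions."""
        chrom = np.asarray(chrom)
        pos0 = np.asarray(pos_1based, dtype=np.int64) - 1
        out = np.zeros(len(pos0), dtype=bool)
        for c, grp in self.intervals.groupby("chrom", sort=False):
            mask = chrom == c
            if not mask.any():
                continue
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            idx = np.searchsorted(starts, pos0[mask], side="right") - 1
            ok = (idx >= 0) & (pos0[mask] < ends[np.clip(idx, 0, len(ends) - 1)])
            out[np.flatnonzero(mask)] = ok
        return out


def restrict_to_regions(catalog: pd.DataFrame, regions: RegionSet) -> pd.DataFrame:
    """Keep only records whose 1-based position falls inside the regions."""
    if regions is None or len(regions.intervals) == 0:
        raise ValueError("empty RegionSet")
    keep = regions.contains(catalog["chrom"].to_numpy(), catalog["pos"].to_numpy())
    if not keep.any() and len(catalog):
        log.warning("restrict_to_regions removed every record")
    return catalog[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# reference access and context annotation


def _fetch(reference, chrom: str, start0: int, end0: int) -> str:
    """Fetch reference sequence [start0, end0) from a pyfaidx.Fasta, a
    mapping of chrom -> sequence string, or a path to a FASTA file."""
    if isinstance(reference, dict):
        return reference[chrom][start0:end0].upper()
    if isinstance(reference, (str, bytes)) or hasattr(reference, "__fspath__"):
        import pyfaidx

        reference = pyfaidx.Fasta(str(reference))
    return str(reference[chrom][start0:end0]).upper()


def _contig_length(reference, chrom: str) -> int:
    if isinstance(reference, dict):
        return len(reference[chrom])
    return len(reference[chrom])


def open_reference(reference):
    """Normalise a reference argument to an indexable object."""
    if isinstance(reference, dict):
        return reference
    if isinstance(reference, (str, bytes)) or hasattr(reference, "__fspath__"):
        import pyfaidx

        return pyfaidx.Fasta(str(reference))
    return reference


def annotate_context(catalog: pd.DataFrame, reference) -> pd.DataFrame:
    """Set the pyrimidine-normalised reference triplet ``context3`` for SNVs.

    For a C/T reference allele the triplet is the reference window
    ``[pos-1, pos+1]``; for A/G it is the reverse complement of that window
    (substitutions are stored on the pyrimidine strand downstream).  SNVs at
    a contig boundary stay unannotated (unclassifiable).  A mismatch between
    the catalogue ref allele and the reference genome aborts with a report
    listing the offending records: silent re-complementing hides genome
    build mismatches.
    """
    ref_obj = open_reference(reference)
    out = catalog.copy()
    contexts = []
    mismatches = []
    lengths: dict[str, int] = {}
    for i, row in out.iterrows():
        r, a = row["ref"], row["alt"]
        if not _is_snv(r, a):
            contexts.append(pd.NA)
            continue
        chrom, pos = row["chrom"], int(row["pos"])
        n = lengths.setdefault(chrom, _contig_length(ref_obj, chrom))
        if pos < 2 or pos > n - 1:
            contexts.append(pd.NA)  # no flanking base: unclassifiable
            continue
        triplet = _fetch(ref_obj, chrom, pos - 2, pos + 1)
        if triplet[1] != r:
            mismatches.append((row["sample_id"], chrom, pos, r, triplet[1]))
            contexts.append(pd.NA)
            continue
        if "N" in triplet:
            contexts.append(pd.NA)
            continue
        contexts.append(triplet if r in "CT" else revcomp(triplet))
    if mismatches:
        head = ", ".join(f"{s}:{c}:{p} {r}!={g}" for s, c, p, r, g in mismatches[:10])
        raise ValueError(
            f"{len(mismatches)} catalogue ref alleles mismatch the reference genome: {head}"
        )
    out["context3"] = contexts
    return out


# ---------------------------------------------------------------------------
# tumour mutation burden


NONSYNONYMOUS = ("missense", "nonsense")


def compute_tmb(
    catalog: pd.DataFrame,
    regions: RegionSet,
    mode: str = "discovery",
    vaf_min: float = 0.05,
    samples=None,
) -> pd.Series:
    """Per-sample tumour mutation burden (mutations per Mb).

    discovery mode counts all somatic SNVs and indels; ICI mode counts
    non-synonymous coding SNVs with VAF above ``vaf_min`` (records without a
    VAF are retained — absence of the annotation is not evidence of a low
    VAF).  ``samples`` optionally fixes the output index so samples with
    zero qualifying mutations appear with TMB 0.
    """
    if regions.total_mb == 0:
        raise ValueError("regions cover zero Mb")
    df = catalog
    if mode == "ici":
        snv = df.apply(lambda r: _is_snv(r["ref"], r["alt"]), axis=1) if len(df) else pd.Series(dtype=bool)
        keep = snv & df["consequence"].isin(NONSYNONYMOUS)
        keep &= df["vaf"].isna() | (df["vaf"] > vaf_min)
        df = df[keep]
    elif mode != "discovery":
        raise ValueError(f"unknown TMB mode {mode!r}")
    counts = df.groupby("sample_id").size()
    if samples is not None:
        counts = counts.reindex(samples, fill_value=0)
    return counts / regions.total_mb
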