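"""Cohort-level enrichment statistics and TP53 CpG-convergence analysis.

Implements the per-cancer-type exact binomial enrichment test, two-by-two
Fisher/odds-ratio contrasts, gene-level C>T-at-CpG summaries with
hotspot detection and fold enrichment against the coding-sequence
expectation, per-stratum CpG mutation rates, and the expression z-score
silencing flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .catalog import NONSYNONYMOUS, _is_snv

log = logging.getLogger(__name__)


def binom_enrichment(x: int, n: int, p0: float) -> float:
    """One-sided (greater) exact binomial tail P(X >= x | n, p0).

    The null success probability is typically the cohort-wide frequency of
    CpG-hypermutated samples.
    """
    if not 0 < p0 < 1:
        raise ValueError("p0 must be in (0, 1)")
    if x < 0 or x > n:
        raise ValueError("require 0 <= x <= n")
    return float(sps.binom.sf(x - 1, n, p0))


def binom_enrichment_table(counts: pd.DataFrame, p0: float) -> pd.DataFrame:
    """Per-group exact binomial enrichment with BH correction.

    ``counts`` needs columns ``group``, ``x`` (CpG-hypermutated samples)
    and ``n`` (cohort size).  Raw p-values are reported alongside BH
    q-values.
    """
    out = counts.copy()
    out["p0"] = p0
    out["p_value"] = [binom_enrichment(x, n, p0) for x, n in zip(out["x"], out["n"])]
    out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out


@dataclass
class TableTest:
    """Two-by-two exact test result."""

    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p_value: float
    sidedness: str


def fisher_or(a: int, b: int, c: int, d: int, sidedness: str = "two-sided",
              continuity: bool = False) -> TableTest:
    """Fisher exact test on [[a, b], [c, d]] with the sample odds ratio.

    Two-sided p sums hypergeometric tables no more probable than the
    observed one.  With a zero off-diagonal cell the sample odds ratio is
    infinite; ``continuity=True`` instead reports the 0.5-corrected
    (a+.5)(d+.5)/((b+.5)(c+.5)).
    """
    cells = (a, b, c, d)
    if any(v < 0 for v in cells):
        raise ValueError("negative contingency cell")
    if a + b + c + d == 0 or ((a + b == 0 or c + d == 0) and (a + c == 0 or b + d == 0)):
        raise ValueError("degenerate table margin")
    alt = {"two-sided": "two-sided", "greater": "greater", "less": "less"}[sidedness]
    p = float(sps.fisher_exact([[a, b], [c, d]], alternative=alt)[1])
    if continuity:
        orat = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
    elif b * c == 0:
        orat = float("inf") if a * d > 0 else float("nan")
    else:
        orat = a * d / (b * c)
    return TableTest(a=a, b=b, c=c, d=d, odds_ratio=float(orat), p_value=p, sidedness=sidedness)


# ---------------------------------------------------------------------------
# gene-level CpG convergence


def _is_cpg_ct(ref, alt, context3) -> bool:
    """C>T at a CpG dinucleotide, on the pyrimidine strand."""
    if not isinstance(context3, str) or len(context3) != 3:
        return False
    sub_ok = (ref == "C" and alt == "T") or (ref == "G" and alt == "A")
    return sub_ok and context3[1] == "C" and context3[2] == "G"


def cpg_ct_mask(records: pd.DataFrame) -> pd.Series:
    return pd.Series(
        [_is_cpg_ct(r, a, c) for r, a, c in
         zip(records["ref"], records["alt"], records["context3"])],
        index=records.index, dtype=bool,
    )


@dataclass
class GeneCpGSummary:
    """Gene-level C>T-at-CpG convergence summary."""

    gene: str
    n_mutations: int
    n_ct_at_cpg: int
    proportion: float
    expectation: float
    fold_enrichment: float
    hotspots: pd.DataFrame  # columns pos, count, fraction, is_cpg_ct


def cpg_ct_expectation(coding_seq: str) -> float:
    """Probability that a uniformly random SNV in a coding sequence is a
    C>T at CpG, under equal per-site substitution rates.

    Every CG dinucleotide contributes two CpG cytosines (one per strand),
    each with one qualifying alternative allele out of the 3 * L possible
    substitutions.
    """
    seq = coding_seq.upper()
    n_cpg_cytosines = 2 * seq.count("CG")
    return n_cpg_cytosines / (3 * len(seq))


def gene_cpg_summary(records: pd.DataFrame, coding_seq: str,
                     hotspot_fraction: float = 0.01) -> GeneCpGSummary:
    """Summarise C>T-at-CpG convergence for one gene's mutations.

    Hotspots are sites carrying at least ``hotspot_fraction`` (default 1%)
    of the gene's mutations.  Fold enrichment compares the observed
    C>T-at-CpG proportion with the sequence-composition expectation.
    """
    n = len(records)
    gene = str(records["gene"].iloc[0]) if n else ""
    if n == 0:
        return GeneCpGSummary(gene=gene, n_mutations=0, n_ct_at_cpg=0,
                              proportion=float("nan"), expectation=float("nan"),
                              fold_enrichment=float("nan"),
                              hotspots=pd.DataFrame(columns=["pos", "count", "fraction", "cpg_ct_fraction"]))
    is_cpg = cpg_ct_mask(records)
    n_cpg = int(is_cpg.sum())
    prop = n_cpg / n
    expectation = cpg_ct_expectation(coding_seq)
    fold = prop / expectation if expectation > 0 else float("nan")
    per_site = records.assign(is_cpg=is_cpg).groupby("pos").agg(
        count=("pos", "size"), cpg_ct_fraction=("is_cpg", "mean")
    )
    per_site["fraction"] = per_site["count"] / n
    hotspots = (
        per_site[per_site["fraction"] >= hotspot_fraction]
        .reset_index()[["pos", "count", "fraction", "cpg_ct_fraction"]]
        .sort_values("count", ascending=False)
        .reset_index(drop=True)
    )
    return GeneCpGSummary(gene=gene, n_mutations=n, n_ct_at_cpg=n_cpg,
                          proportion=prop, expectation=expectation,
                          fold_enrichment=fold, hotspots=hotspots)


def strata_cpg_rate(gene_records: pd.DataFrame, calls: pd.DataFrame,
                    strata=("HM_CpG-Hi",)) -> pd.DataFrame:
    """Per-stratum proportion of non-synonymous gene mutations that are
    C>T at CpG, plus the ratio of each stratum to the pooled complement.

    ``calls`` must carry sample_id and label columns (classifier output).
    """
    labels = calls.set_index("sample_id")["label"]
    recs = gene_records[gene_records["consequence"].isin(NONSYNONYMOUS)].copy()
    recs["stratum"] = recs["sample_id"].map(labels)
    recs = recs[recs["stratum"].notna()]
    recs["grp"] = np.where(recs["stratum"].isin(strata), "focal", "rest")
    rows = []
    for grp_name in ("focal", "rest"):
        sub = recs[recs["grp"] == grp_name]
        k = int(cpg_ct_mask(sub).sum()) if len(sub) else 0
        n = len(sub)
        rows.append({"stratum": grp_name, "n_ct_at_cpg": k, "n_mutations": n,
                     "proportion": k / n if n else float("nan")})
    out = pd.DataFrame(rows).set_index("stratum")
    out["ratio_vs_rest"] = out["proportion"] / out.loc["rest", "proportion"]
    return out


def low_expression_flag(expression: pd.DataFrame, z_cut: float = -2.0,
                        min_samples: int = 10) -> pd.DataFrame:
    """Flag silenced genes by z-scaled expression.

    ``expression`` is genes x samples.  Per gene, z = (x - mean)/sd across
    the cohort; entries with z below ``z_cut`` are flagged.  Genes with
    fewer than ``min_samples`` observations or zero variance yield no
    flags (warning logged for the latter).
    Returns a boolean genes x samples frame.
    """
    flags = pd.DataFrame(False, index=expression.index, columns=expression.columns)
    for gene, row in expression.iterrows():
        vals = row.dropna()
        if len(vals) < min_samples:
            continue
        sd = vals.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            log.warning("gene %s has zero expression variance; no flags", gene)
            continue
        z = (vals - vals.mean()) / sd
        flags.loc[gene, z.index[z < z_cut]] = True
    return flags
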