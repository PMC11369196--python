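"""Motif-enrichment confirmation of CpG mutagenesis (P-MACD-style).

For each sample the mutated-cytosine load is compared with the local
availability of the motif context in +/- ``window_halfwidth`` nt windows
around each mutation.  Two motif models are provided:

- ``nCg``: C>T at any NpCpG context;
- ``rCg``: C>T at RpCpG with the 5' base restricted to purines (A/G),
  excluding the dipyrimidine CpCpG and TpCpG contexts that overlap the
  UV photoproduct signature.  (A ``pyrimidine_5p`` restriction is also
  selectable for audit.)

Enrichment = (m_motif * n_base) / (m_base * n_motif) where m_* count
mutations and n_* count cytosine contexts in the windows, both strands'
pyrimidine representations.  The minimum motif-specific mutation load is
m_motif * max(0, (E - 1)/E).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import open_reference, _fetch, _contig_length, _is_snv

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class MotifModel:
    """A C>T mutation-motif model for enrichment analysis."""

    name: str
    five_prime: frozenset | None = None  # None = any base (nCg)
    window_halfwidth: int = 20

    def __post_init__(self):
        if self.window_halfwidth < 1:
            raise ValueError("window_halfwidth must be >= 1")

    def matches_context(self, context3: str) -> bool:
        """Does a pyrimidine-normalised triplet match the motif?"""
        if not isinstance(context3, str) or len(context3) != 3:
            return False
        if context3[1] != "C" or context3[2] != "G":
            return False
        return self.five_prime is None or context3[0] in self.five_prime


NCG = MotifModel(name="nCg")
RCG = MotifModel(name="rCg", five_prime=frozenset("AG"))
#: the paper-text literal reading of the rCg 5' set, selectable for audit
RCG_PYRIMIDINE = MotifModel(name="rCg_yCg", five_prime=frozenset("CT"))

MODELS = {"nCg": NCG, "rCg": RCG, "rCg_yCg": RCG_PYRIMIDINE}


def count_window_contexts(records: pd.DataFrame, reference, model: MotifModel) -> tuple[int, int]:
    """Motif and cytosine context counts in windows around each mutation.

    Windows extend ``model.window_halfwidth`` nt either side of each
    mutated position and are truncated (with a warning) at contig ends.
    Overlapping windows are counted once per mutation window, following the
    established convention for this statistic.
    """
    ref_obj = open_reference(reference)
    hw = model.window_halfwidth
    n_motif = n_base = 0
    lengths: dict[str, int] = {}
    truncated = 0
    for chrom, pos in zip(records["chrom"], records["pos"]):
        n = lengths.setdefault(chrom, _contig_length(ref_obj, chrom))
        start = int(pos) - 1 - hw
        end = int(pos) + hw
        if start < 0 or end > n:
            truncated += 1
            start, end = max(start, 0), min(end, n)
        # one extra flank base each side so edge Cs keep their neighbours
        s0, e0 = max(start - 1, 0), min(end + 1, n)
        seq = _fetch(ref_obj, chrom, s0, e0)
        lo, hi = start - s0, start - s0 + (end - start)
        m, b = _window_counts_flanked(seq, lo, hi, model)
        n_motif += m
        n_base += b
    if truncated:
        log.warning("%d windows truncated at contig boundaries", truncated)
    return n_motif, n_base


def _window_counts_flanked(seq: str, lo: int, hi: int, model: MotifModel) -> tuple[int, int]:
    """Count contexts for positions [lo, hi) of ``seq`` using neighbours
    from the full string (which may include one flanking base each side)."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    n_motif = n_base = 0
    for i in range(lo, hi):
        b = seq[i]
        if b == "C":
            n_base += 1
            three = seq[i + 1] if i + 1 < len(seq) else None
            five = seq[i - 1] if i >= 1 else None
        elif b == "G":
            n_base += 1
            three = comp.get(seq[i - 1]) if i >= 1 else None
            five = comp.get(seq[i + 1]) if i + 1 < len(seq) else None
        else:
            continue
        if three == "G" and (model.five_prime is None or (five is not None and five in model.five_prime)):
            n_motif += 1
    return n_motif, n_base


def motif_enrichment(m_motif: int, m_base: int, n_motif: int, n_base: int) -> float:
    """Fold enrichment of motif mutations over motif context availability."""
    if m_base <= 0 or n_motif <= 0 or n_base <= 0:
        return float("nan")
    return (m_motif * n_base) / (m_base * n_motif)


def enrichment_fisher(m_motif: int, m_base: int, n_motif: int, n_base: int) -> float:
    """One-sided (greater) Fisher exact p for motif enrichment.

    Table: [[m_motif, m_base - m_motif], [n_motif, n_base - n_motif]].
    """
    cells = (m_motif, m_base - m_motif, n_motif, n_base - n_motif)
    if any(c < 0 for c in cells):
        raise ValueError(f"negative contingency cell in {cells}")
    table = [[cells[0], cells[1]], [cells[2], cells[3]]]
    return float(stats.fisher_exact(table, alternative="greater")[1])


def min_mutation_load(m_motif: int, enrichment: float) -> float:
    """Minimum estimate of the motif-specific mutation load.

    The fraction (E - 1)/E of the observed motif mutations cannot be
    explained by context availability alone; floored at zero.
    """
    if m_motif == 0 or not np.isfinite(enrichment) or enrichment <= 0:
        return 0.0
    return float(m_motif * max(0.0, (enrichment - 1.0) / enrichment))


@dataclass
class EnrichmentResult:
    """Per-sample motif-enrichment statistics for one motif model."""

    sample_id: str
    model: str
    m_motif: int
    m_base: int
    n_motif: int
    n_base: int
    enrichment: float
    fisher_p: float
    min_load: float


def sample_enrichment(
    catalog: pd.DataFrame, reference, models=("nCg", "rCg")
) -> pd.DataFrame:
    """Motif-enrichment statistics per sample and motif model.

    Requires annotated contexts.  The mutation class tested is C>T on the
    pyrimidine strand; m_base counts all such mutations, m_motif the subset
    in motif context.
    """
    resolved = [MODELS[m] if isinstance(m, str) else m for m in models]
    rows = []
    for sample, grp in catalog.groupby("sample_id", sort=True):
        snv = grp[[_is_snv(r, a) for r, a in zip(grp["ref"], grp["alt"])]]
        ct = snv[
            snv["context3"].notna()
            & snv["context3"].astype(str).str.get(1).eq("C")
            & (
                (snv["ref"].eq("C") & snv["alt"].eq("T"))
                | (snv["ref"].eq("G") & snv["alt"].eq("A"))
            )
        ]
        for model in resolved:
            m_base = len(ct)
            m_motif = int(ct["context3"].astype(str).map(model.matches_context).sum()) if m_base else 0
            n_motif, n_base = count_window_contexts(ct, reference, model) if m_base else (0, 0)
            enr = motif_enrichment(m_motif, m_base, n_motif, n_base)
            p = (
                enrichment_fisher(m_motif, m_base, n_motif, n_base)
                if np.isfinite(enr)
                else float("nan")
            )
            rows.append(
                EnrichmentResult(
                    sample_id=sample, model=model.name, m_motif=m_motif,
                    m_base=m_base, n_motif=n_motif, n_base=n_base,
                    enrichment=enr, fisher_p=p,
                    min_load=min_mutation_load(m_motif, enr),
                )
            )
    return pd.DataFrame([vars(r) for r in rows])
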