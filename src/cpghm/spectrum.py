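"""SBS96 trinucleotide mutation spectra and signature matching.

Every single-base substitution is represented on the pyrimidine strand
(reference C or T); a substitution with a purine reference allele is
reverse-complemented together with its trinucleotide context.  The 96
channels follow the conventional COSMIC ordering: six substitution classes
(C>A, C>G, C>T, T>A, T>C, T>G), within each the 5' base cycles A,C,G,T and
within that the 3' base cycles A,C,G,T.  Channel labels are written
``"A[C>T]G"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BASES = "ACGT"
PYRIMIDINES = frozenset("CT")
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved, N allowed)."""
    return seq.translate(_COMPLEMENT)[::-1]


def channel_labels() -> list[str]:
    """The 96 channel labels in canonical COSMIC order."""
    labels = []
    for sub in SUBSTITUTIONS:
        for five in BASES:
            for three in BASES:
                labels.append(f"{five}[{sub}]{three}")
    return labels


CHANNELS = channel_labels()
_CHANNEL_INDEX = {lab: i for i, lab in enumerate(CHANNELS)}

#: indices of the four N[C>T]G channels (CpG>TpG)
CPG_CT_CHANNELS = tuple(
    _CHANNEL_INDEX[f"{five}[C>T]G"] for five in BASES
)


def classify_substitution(ref: str, alt: str, context3: str) -> int:
    """Map one SNV to its SBS96 channel index.

    ``context3`` is the pyrimidine-normalised reference triplet (middle base
    C or T).  A purine ``ref`` is reverse-complemented onto that strand.
    Returns -1 for unclassifiable input (ambiguous base, missing context).
    """
    if not isinstance(context3, str) or len(context3) != 3:
        return -1
    ref = ref.upper()
    alt = alt.upper()
    context3 = context3.upper()
    if ref not in BASES or alt not in BASES or ref == alt:
        return -1
    if ref not in PYRIMIDINES:
        ref = revcomp(ref)
        alt = revcomp(alt)
    if context3[1] != ref or any(b not in BASES for b in context3):
        return -1
    label = f"{context3[0]}[{ref}>{alt}]{context3[2]}"
    return _CHANNEL_INDEX.get(label, -1)


def channel_indices(catalog: pd.DataFrame) -> pd.Series:
    """Per-row SBS96 channel index for a mutation catalogue (-1 where
    unclassifiable: indels, missing context, ambiguous bases)."""
    return pd.Series(
        [
            classify_substitution(r, a, c)
            if isinstance(r, str) and isinstance(a, str) and len(r) == 1 and len(a) == 1
            else -1
            for r, a, c in zip(catalog["ref"], catalog["alt"], catalog["context3"])
        ],
        index=catalog.index,
        dtype=int,
    )


@dataclass
class Spectrum96:
    """Counts over the 96 trinucleotide substitution channels."""

    counts: np.ndarray
    n_classified: int = field(default=None)  # type: ignore[assignment]
    n_excluded: int = 0

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (96,):
            raise ValueError("Spectrum96 requires exactly 96 channel counts")
        if (self.counts < 0).any():
            raise ValueError("negative channel counts")
        total = int(self.counts.sum())
        if self.n_classified is None:
            self.n_classified = total
        elif self.n_classified != total:
            raise ValueError("n_classified must equal the channel count sum")

    def relative(self) -> np.ndarray:
        """Relative channel frequencies (zeros if the spectrum is empty)."""
        if self.n_classified == 0:
            return np.zeros(96)
        return self.counts / self.n_classified

    def cpg_ct_proportion(self) -> float:
        """Fraction of classified SNVs in the four N[C>T]G channels."""
        if self.n_classified == 0:
            return float("nan")
        return float(self.counts[list(CPG_CT_CHANNELS)].sum() / self.n_classified)


def build_spectrum(records: pd.DataFrame) -> Spectrum96:
    """SBS96 spectrum for one sample's annotated records.

    Indels and records without a classifiable context are excluded from the
    channel counts and tallied in ``n_excluded``.
    """
    counts = np.zeros(96)
    if len(records):
        idx = channel_indices(records)
        ok = idx >= 0
        counts = np.bincount(idx[ok], minlength=96).astype(float)
        n_excluded = int((~ok).sum())
    else:
        n_excluded = 0
    return Spectrum96(counts=counts, n_excluded=n_excluded)


def cpg_ct_proportion(records: pd.DataFrame) -> float:
    """Proportion of classified SNVs that are C>T at a CpG dinucleotide.

    The denominator is classified SNVs only (indels carry no 96-channel
    context); NaN when no SNV is classifiable, in which case the sample is
    excluded from proportion-based analyses.
    """
    return build_spectrum(records).cpg_ct_proportion()


def cosine_similarity(a, b) -> float:
    """Cosine similarity of two non-negative 96-vectors; scale invariant."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(a, b) / (na * nb))


def median_spectrum(spectra: list[Spectrum96]) -> np.ndarray:
    """Per-channel median of per-sample relative frequencies, renormalised.

    Each spectrum is normalised to relative frequencies first, the
    elementwise median is taken across samples, and the median vector is
    rescaled to sum to one.
    """
    rel = [s.relative() for s in spectra if s.n_classified > 0]
    if not rel:
        raise ValueError("median_spectrum requires at least one non-empty spectrum")
    med = np.median(np.vstack(rel), axis=0)
    total = med.sum()
    if total == 0:
        raise ValueError("median spectrum is identically zero")
    return med / total


# ---------------------------------------------------------------------------
# signature matrices


def validate_signature_matrix(matrix: pd.DataFrame, atol: float = 1e-6) -> pd.DataFrame:
    """Check a 96 x K signature matrix (rows = channel labels, columns sum 1)."""
    if list(matrix.index) != CHANNELS:
        try:
            matrix = matrix.loc[CHANNELS]
        except KeyError as exc:
            raise ValueError("signature matrix must be indexed by the 96 channel labels") from exc
    if (matrix.values < 0).any():
        raise ValueError("signature profiles must be non-negative")
    sums = matrix.sum(axis=0)
    if not np.allclose(sums, 1.0, atol=atol):
        bad = sums[~np.isclose(sums, 1.0, atol=atol)].index.tolist()
        raise ValueError(f"signature columns must sum to 1: {bad}")
    return matrix


def read_signature_matrix(path) -> pd.DataFrame:
    """Read a signature reference TSV (channel label column + one column per
    signature), e.g. the COSMIC SBS download."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return validate_signature_matrix(df.astype(float))


def synthetic_signatures() -> pd.DataFrame:
    """Bundled synthetic signature reference (not COSMIC).

    Four profiles capturing the shapes the pipeline distinguishes:

    - ``SBS1like``  : 90% of mass evenly on the four N[C>T]G channels
      (spontaneous 5mC deamination shape), remainder flat.
    - ``SBSflat``   : uniform over all 96 channels.
    - ``CTother``   : C>T concentrated outside CpG contexts.
    - ``UVlike``    : C>T at 5'-pyrimidine dipyrimidine contexts.
    """
    mats = {}
    sbs1 = np.full(96, 0.1 / 92)
    for c in CPG_CT_CHANNELS:
        sbs1[c] = 0.9 / 4
    mats["SBS1like"] = sbs1

    mats["SBSflat"] = np.full(96, 1 / 96)

    ct_non_cpg = [
        i
        for i, lab in enumerate(CHANNELS)
        if "[C>T]" in lab and lab[-1] != "G"
    ]
    ct = np.full(96, 0.15 / (96 - len(ct_non_cpg)))
    ct[ct_non_cpg] = 0.85 / len(ct_non_cpg)
    mats["CTother"] = ct

    uv_idx = [
        i
        for i, lab in enumerate(CHANNELS)
        if "[C>T]" in lab and lab[0] in "CT"
    ]
    uv = np.full(96, 0.1 / (96 - len(uv_idx)))
    uv[uv_idx] = 0.9 / len(uv_idx)
    mats["UVlike"] = uv

    df = pd.DataFrame(mats, index=CHANNELS)
    return validate_signature_matrix(df)


def best_signature_match(
    spectrum, matrix: pd.DataFrame, match_threshold: float = 0.9
) -> tuple[str, float, bool]:
    """Best cosine match of a spectrum against a signature matrix.

    A score of at least ``match_threshold`` (default 0.9) counts as a
    signature match.  Ties break on first column order.
    Returns ``(name, score, matched)``.
    """
    if matrix.shape[1] == 0:
        raise ValueError("empty signature matrix")
    vec = spectrum.relative() if isinstance(spectrum, Spectrum96) else np.asarray(spectrum, float)
    scores = np.array([cosine_similarity(vec, matrix[c].values) for c in matrix.columns])
    k = int(np.argmax(scores))  # argmax returns the first maximum: tie-break
    name = matrix.columns[k]
    score = float(scores[k])
    return name, score, score >= match_threshold
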