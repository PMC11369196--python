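"""Trinucleotide-aware dN/dS estimation for driver-gene scanning.

A deliberately simplified selection model: per-channel neutral mutation
rates are fitted from synonymous counts against synonymous opportunities
pooled across genes, expected missense/nonsense counts per gene follow
from each gene's opportunity spectrum, and dN/dS (w) is observed/expected
with a Poisson likelihood-ratio test of w = 1, profile-likelihood 95%
confidence intervals and Benjamini-Hochberg q-values across genes.

There is no negative-binomial gene-level rate dispersion, no covariate
model and no indel model; this scan flags strong selection signals and is
not a substitute for a full driver-discovery framework.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import optimize
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .catalog import open_reference, _fetch
from .spectrum import classify_substitution, revcomp

log = logging.getLogger(__name__)

CLASSES = ("synonymous", "missense", "nonsense")
_BASES = "ACGT"


@dataclass
class CodingModel:
    """Enumerated single-base substitutions over a set of coding genes.

    ``substitutions`` has one row per possible substitution (3 per coding
    site): gene, chrom, pos (1-based genomic), ref, alt (genome strand),
    context3 (pyrimidine-normalised), channel, consequence.
    ``opportunities[gene]`` is a (96, 3) count matrix over channels x
    (synonymous, missense, nonsense).
    """

    substitutions: pd.DataFrame
    opportunities: dict[str, np.ndarray]

    @property
    def genes(self) -> list[str]:
        return sorted(self.opportunities)

    def pooled_opportunities(self, genes=None) -> np.ndarray:
        genes = self.genes if genes is None else genes
        out = np.zeros((96, 3))
        for g in genes:
            out += self.opportunities[g]
        return out


def build_coding_model(reference, gene_table: pd.DataFrame) -> CodingModel:
    """Enumerate coding substitutions for genes on a reference.

    ``gene_table`` columns: gene, chrom, start (0-based), end, strand.
    Each CDS must be in frame (length divisible by 3), start-to-stop, with
    no internal stop codon.  Trinucleotide contexts come from the genomic
    flanks, so every coding site contributes exactly three substitutions
    with a channel label on the pyrimidine strand.
    """
    ref_obj = open_reference(reference)
    rows = []
    for _, g in gene_table.iterrows():
        name, chrom = g["gene"], g["chrom"]
        start, end, strand = int(g["start"]), int(g["end"]), g.get("strand", "+")
        window = _fetch(ref_obj, chrom, start - 1, end + 1)
        genomic = window[1:-1]
        cds = genomic if strand == "+" else revcomp(genomic)
        if len(cds) % 3:
            raise ValueError(f"gene {name}: CDS length {len(cds)} not divisible by 3")
        aa = str(Seq(cds).translate())
        if "*" in aa[:-1]:
            raise ValueError(f"gene {name}: internal stop codon")
        for j, ref_base_cds in enumerate(cds):
            codon_i, off = divmod(j, 3)
            codon = cds[3 * codon_i : 3 * codon_i + 3]
            ref_aa = aa[codon_i]
            if strand == "+":
                pos0 = start + j
                genome_ref = ref_base_cds
            else:
                pos0 = end - 1 - j
                genome_ref = revcomp(ref_base_cds)
            # triplet on the genome with one flank either side
            widx = pos0 - (start - 1)
            triplet = window[widx - 1 : widx + 2]
            for alt_cds in _BASES:
                if alt_cds == ref_base_cds:
                    continue
                new_codon = codon[:off] + alt_cds + codon[off + 1 :]
                new_aa = str(Seq(new_codon).translate())
                if new_aa == ref_aa:
                    cons = "synonymous"
                elif new_aa == "*":
                    cons = "nonsense"
                else:
                    cons = "missense"
                genome_alt = alt_cds if strand == "+" else revcomp(alt_cds)
                ctx = triplet if genome_ref in "CT" else revcomp(triplet)
                chan = classify_substitution(genome_ref, genome_alt, ctx)
                rows.append((name, chrom, pos0 + 1, genome_ref, genome_alt, ctx, chan, cons))
    subs = pd.DataFrame(
        rows,
        columns=["gene", "chrom", "pos", "ref", "alt", "context3", "channel", "consequence"],
    )
    opps = {}
    cls_idx = {c: i for i, c in enumerate(CLASSES)}
    for name, grp in subs.groupby("gene"):
        m = np.zeros((96, 3))
        np.add.at(m, (grp["channel"].to_numpy(), grp["consequence"].map(cls_idx).to_numpy()), 1)
        opps[name] = m
    return CodingModel(substitutions=subs, opportunities=opps)


# ---------------------------------------------------------------------------
# estimation


class _WProfile:
    """Profile likelihood for a selection coefficient w.

    Counts per channel: synonymous s_c with opportunity a_c (the neutral
    anchor, pooled across genes) and target-class m_c with opportunity b_c
    (one gene, or pooled).  Model: counts are Poisson with per-channel rate
    r_c, the target class scaled by w.  For fixed w the rate MLE is
    r_c = (s_c + m_c)/(a_c + w b_c), giving the profile log-likelihood
    (up to w-free constants)

        l(w) = M log w - sum_c n_c log(a_c + w b_c),   n_c = s_c + m_c.

    Profiling the rates keeps the likelihood-ratio test of w = 1
    calibrated: the noise of the neutral-rate estimate is accounted for
    rather than conditioned away.
    """

    def __init__(self, s, a, m, b):
        # channels without synonymous opportunity are uninformative for w:
        # their free rate absorbs the scale, so the profile is flat in w
        keep = np.asarray(a) > 0
        self.s = np.asarray(s, float)[keep]
        self.a = np.asarray(a, float)[keep]
        self.m = np.asarray(m, float)[keep]
        self.b = np.asarray(b, float)[keep]
        self.n = self.s + self.m
        self.M = float(self.m.sum())

    def loglik(self, w: float) -> float:
        lam = self.a + w * self.b
        ok = lam > 0
        out = -float(np.sum(self.n[ok] * np.log(lam[ok])))
        if self.M > 0:
            if w <= 0:
                return -np.inf
            out += self.M * np.log(w)
        return out

    def _score_root(self) -> float:
        # dl/dw = M/w - sum n_c b_c/(a_c + w b_c) = 0
        def score(w):
            return self.M / w - float(np.sum(self.n * self.b / (self.a + w * self.b)))

        if self.M == 0:
            return 0.0
        if float(self.s[self.b > 0].sum()) == 0:
            # no synonymous anchor in the target channels: w unbounded
            return float("inf")
        lo, hi = 1e-9, 1.0
        while score(hi) > 0 and hi < 1e12:
            hi *= 2
        while score(lo) < 0 and lo > 1e-15:
            lo /= 2
        return float(optimize.brentq(score, lo, hi))

    def fit(self, level: float = 0.95):
        """Return (w_hat, p_value, ci_low, ci_high, lrt_stat)."""
        if self.b.sum() == 0 or self.n.sum() == 0:
            nan = float("nan")
            return nan, nan, nan, nan, nan
        w_hat = self._score_root()
        if not np.isfinite(w_hat):
            # supremum as w -> inf (only when s = 0 on every target channel)
            bpos = self.b > 0
            ll_hat = -float(
                np.sum(self.n[bpos] * np.log(self.b[bpos]))
                + np.sum(self.n[~bpos & (self.a > 0)] * np.log(self.a[~bpos & (self.a > 0)]))
            )
            stat = 2.0 * (ll_hat - self.loglik(1.0))
            return w_hat, float(sps.chi2.sf(max(stat, 0.0), df=1)), 0.0, float("inf"), float(stat)
        ll_hat = self.loglik(w_hat) if w_hat > 0 else self.loglik(1e-300)
        if self.M == 0:
            # l(w) = -sum n log(a + w b): supremum at w -> 0
            ll_hat = -float(np.sum(self.n[self.a > 0] * np.log(self.a[self.a > 0])))
        stat = 2.0 * (ll_hat - self.loglik(1.0))
        p = float(sps.chi2.sf(max(stat, 0.0), df=1))
        crit = float(sps.chi2.ppf(level, df=1))

        def dev(w):
            lam = self.a + w * self.b
            if np.any(lam <= 0):
                return np.inf
            ll = -float(np.sum(self.n * np.log(lam)))
            if self.M > 0:
                ll += self.M * np.log(w) if w > 0 else -np.inf
            return 2.0 * (ll_hat - ll) - crit

        hi = max(w_hat, 1e-6)
        while dev(hi * 2) < 0 and hi < 1e9:
            hi *= 2
        upper = float(optimize.brentq(dev, max(w_hat, 1e-6), hi * 2))
        if self.M == 0 or w_hat == 0:
            lower = 0.0
        else:
            lo = w_hat
            while dev(lo / 2) < 0 and lo > 1e-12:
                lo /= 2
            lower = float(optimize.brentq(dev, lo / 2, w_hat)) if dev(lo / 2) >= 0 else 0.0
        return float(w_hat), p, lower, upper, float(stat)


@dataclass
class DnDsResults:
    """Per-gene and global dN/dS estimates."""

    table: pd.DataFrame  # per-gene results
    global_: pd.Series  # pooled results
    rates: np.ndarray  # fitted per-channel neutral rates
    n_mutations: int

    def summary(self) -> str:
        g = self.global_
        lines = [
            "dN/dS selection scan (simplified trinucleotide model)",
            "=" * 55,
            f"mutations used: {self.n_mutations}   genes: {len(self.table)}",
            f"global w_mis = {g['w_mis']:.3f} [{g['ci_mis_low']:.3f}, {g['ci_mis_high']:.3f}]",
            f"global w_non = {g['w_non']:.3f} [{g['ci_non_low']:.3f}, {g['ci_non_high']:.3f}]",
            "",
        ]
        cols = ["gene", "n_syn", "n_mis", "n_non", "w_mis", "w_non", "p_value", "q_value"]
        lines.append(self.table[cols].to_string(index=False, float_format=lambda v: f"{v:.3g}"))
        return "\n".join(lines)


class DnDsModel:
    """Fit per-gene and global dN/dS from a mutation catalogue.

    Parameters
    ----------
    catalog : DataFrame
        Annotated catalogue; only SNVs in the model's genes with
        consequence synonymous/missense/nonsense are used.
    model : CodingModel
    samples : iterable, optional
        Restrict to these sample ids (e.g. one hypermutator stratum).
    """

    def __init__(self, catalog: pd.DataFrame, model: CodingModel, samples=None):
        cat = catalog
        if samples is not None:
            cat = cat[cat["sample_id"].isin(set(samples))]
        cat = cat[cat["gene"].isin(model.opportunities) & cat["consequence"].isin(CLASSES)]
        self.catalog = cat.copy()
        self.model = model

    def _observed(self) -> dict[str, np.ndarray]:
        """Per-gene (96, 3) observed count matrices."""
        from .spectrum import channel_indices

        cat = self.catalog
        chan = channel_indices(cat)
        ok = chan >= 0
        cat = cat[ok]
        chan = chan[ok]
        cls_idx = {c: i for i, c in enumerate(CLASSES)}
        out = {g: np.zeros((96, 3)) for g in self.model.opportunities}
        for g, ch, cons in zip(cat["gene"], chan, cat["consequence"]):
            out[g][ch, cls_idx[cons]] += 1
        return out

    def fit(self) -> DnDsResults:
        obs = self._observed()
        opp = self.model.opportunities
        pooled_obs = sum(obs.values())
        pooled_opp = self.model.pooled_opportunities()
        syn_opp = pooled_opp[:, 0]
        syn_obs = pooled_obs[:, 0]
        if syn_obs.sum() == 0:
            raise ValueError("no synonymous mutations: neutral rates not estimable")
        with np.errstate(invalid="ignore", divide="ignore"):
            rates = np.where(syn_opp > 0, syn_obs / np.maximum(syn_opp, 1), 0.0)

        def one_scope(o, e) -> dict:
            out = {}
            stat_sum, df = 0.0, 0
            for k, cls in ((1, "mis"), (2, "non")):
                if e[:, k].sum() == 0:
                    out.update({f"w_{cls}": float("nan"), f"obs_{cls}": 0.0,
                                f"exp_{cls}": 0.0, f"ci_{cls}_low": float("nan"),
                                f"ci_{cls}_high": float("nan"), f"p_{cls}": float("nan")})
                    continue
                prof = _WProfile(syn_obs, syn_opp, o[:, k], e[:, k])
                w, p, lo, hi, stat = prof.fit()
                out.update({f"w_{cls}": w, f"obs_{cls}": float(o[:, k].sum()),
                            f"exp_{cls}": float((rates * e[:, k]).sum()),
                            f"ci_{cls}_low": lo, f"ci_{cls}_high": hi,
                            f"p_{cls}": p})
                if np.isfinite(stat):
                    stat_sum += stat
                    df += 1
            out["p_value"] = float(sps.chi2.sf(stat_sum, df=df)) if df else float("nan")
            return out

        rows = []
        for gene in self.model.genes:
            o, e = obs[gene], opp[gene]
            if e[:, 1].sum() == 0 or e[:, 2].sum() == 0:
                log.warning("gene %s lacks opportunities of some class", gene)
            row = {"gene": gene,
                   "n_syn": int(o[:, 0].sum()),
                   "n_mis": int(o[:, 1].sum()),
                   "n_non": int(o[:, 2].sum())}
            row.update(one_scope(o, e))
            rows.append(row)
        table = pd.DataFrame(rows)
        ok = table["p_value"].notna()
        table["q_value"] = np.nan
        table.loc[ok, "q_value"] = multipletests(table.loc[ok, "p_value"], method="fdr_bh")[1]

        glob = pd.Series(one_scope(pooled_obs, pooled_opp))
        return DnDsResults(table=table, global_=glob, rates=rates,
                           n_mutations=len(self.catalog))


def estimate_dnds(catalog: pd.DataFrame, model: CodingModel, samples=None) -> DnDsResults:
    """Functional wrapper around :class:`DnDsModel`."""
    return DnDsModel(catalog, model, samples=samples).fit()


def simulate_neutral_mutations(model: CodingModel, n: int, rng,
                               channel_intensity=None, sample_id: str = "SIM") -> pd.DataFrame:
    """Draw coding mutations with no selection.

    Each enumerated substitution is sampled with probability proportional
    to the intensity of its trinucleotide channel (uniform by default), so
    observed/expected ratios are 1 in expectation for every consequence
    class.  Returns catalogue-shaped rows.
    """
    subs = model.substitutions
    if channel_intensity is None:
        w = np.ones(len(subs))
    else:
        channel_intensity = np.asarray(channel_intensity, dtype=float)
        w = channel_intensity[subs["channel"].to_numpy()]
    p = w / w.sum()
    idx = rng.choice(len(subs), size=n, replace=True, p=p)
    out = subs.iloc[idx].copy().reset_index(drop=True)
    out["sample_id"] = sample_id
    out["vaf"] = 0.5
    return out[["sample_id", "chrom", "pos", "ref", "alt", "gene", "consequence", "context3", "vaf"]]
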