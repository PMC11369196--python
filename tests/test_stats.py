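import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cpghm.stats import (
    binom_enrichment,
    binom_enrichment_table,
    cpg_ct_expectation,
    fisher_or,
    gene_cpg_summary,
    low_expression_flag,
    strata_cpg_rate,
)


def brute_fisher_two_sided(a, b, c, d):
    """Oracle: exact-fraction hypergeometric summation of all tables with
    probability not exceeding the observed table's."""
    n1, n2, k = a + b, c + d, a + c
    total = math.comb(n1 + n2, k)
    p_obs = Fraction(math.comb(n1, a) * math.comb(n2, c), total)
    acc = Fraction(0)
    for x in range(max(0, k - n2), min(k, n1) + 1):
        p = Fraction(math.comb(n1, x) * math.comb(n2, k - x), total)
        if p <= p_obs:
            acc += p
    return float(acc)


class TestBinomialEnrichment:
    def test_zero_successes_full_tail(self):
        assert binom_enrichment(0, 100, 0.01) == 1.0

    def test_matches_pmf_summation_oracle(self):
        for x, n, p0 in [(18, 1660, 76 / 30950), (15, 291, 76 / 30950), (3, 50, 0.02)]:
            oracle = float(sps.binom.pmf(np.arange(x, n + 1), n, p0).sum())
            assert binom_enrichment(x, n, p0) == pytest.approx(oracle, rel=1e-9)

    def test_monotone_nonincreasing_in_x(self):
        ps = [binom_enrichment(x, 200, 0.05) for x in range(0, 40)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            binom_enrichment(5, 4, 0.1)
        with pytest.raises(ValueError):
            binom_enrichment(1, 4, 0.0)

    def test_table_adds_bh_qvalues(self):
        counts = pd.DataFrame({"group": ["A", "B"], "x": [10, 1], "n": [100, 100]})
        out = binom_enrichment_table(counts, p0=0.01)
        assert (out["q_value"] >= out["p_value"]).all()


class TestFisherOr:
    def test_null_table(self):
        res = fisher_or(5, 5, 5, 5)
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_perfect_association(self):
        res = fisher_or(10, 0, 0, 10)
        assert math.isinf(res.odds_ratio)
        assert res.p_value == pytest.approx(2 / math.comb(20, 10))

    def test_continuity_corrected_odds_ratio(self):
        res = fisher_or(10, 0, 0, 10, continuity=True)
        assert res.odds_ratio == pytest.approx(10.5 * 10.5 / 0.25)

    def test_matches_brute_force_hypergeometric(self, rng):
        for _ in range(80):
            a, b, c, d = rng.integers(0, 26, size=4)
            if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
                continue
            got = fisher_or(int(a), int(b), int(c), int(d)).p_value
            assert got == pytest.approx(brute_fisher_two_sided(a, b, c, d), rel=1e-7)

    def test_degenerate_margin_raises(self):
        with pytest.raises(ValueError):
            fisher_or(0, 0, 0, 0)


class TestGeneCpG:
    def _gene_records(self, positions, refs, alts, contexts, consequence="missense"):
        return pd.DataFrame({
            "sample_id": [f"S{i}" for i in range(len(positions))],
            "chrom": "chr1", "pos": positions, "ref": refs, "alt": alts,
            "gene": "TP53", "consequence": consequence,
            "context3": contexts, "vaf": np.nan,
        })

    def test_hotspot_threshold_rule(self):
        # 200 mutations, one site with 3 (1.5% >= 1%) is a hotspot
        positions = list(range(1, 198)) + [500, 500, 500]
        n = len(positions)
        recs = self._gene_records(positions, ["C"] * n, ["T"] * n, ["ACA"] * n)
        out = gene_cpg_summary(recs, coding_seq="ATG" + "CGA" * 10 + "TAA")
        assert 500 in out.hotspots["pos"].tolist()
        assert (out.hotspots["fraction"] >= 0.01).all()

    def test_fold_enrichment_arithmetic(self):
        # observed 1/3 at CpG vs an expectation of ~0.0202 -> ~16.5-fold
        seq = "ATG" + "AAA" * 160 + "CGT" * 5 + "TAA"
        exp = cpg_ct_expectation(seq)
        recs = self._gene_records(
            [1, 2, 3], ["C", "C", "C"], ["T", "A", "A"], ["ACG", "ACA", "ACA"])
        out = gene_cpg_summary(recs, seq)
        assert out.proportion == pytest.approx(1 / 3)
        assert out.fold_enrichment == pytest.approx((1 / 3) / exp)

    def test_expectation_counts_both_strands(self):
        # one CG in 6 bases: 2 CpG cytosines / 18 substitutions
        assert cpg_ct_expectation("AACGAA") == pytest.approx(2 / 18)

    def test_uniform_placement_fold_is_one(self, rng):
        seq = "ATG" + "".join(rng.choice(["CGA", "ACT", "GTA", "CTG"], size=200)) + "TAA"
        exp = cpg_ct_expectation(seq)
        # simulate uniformly random substitutions over all sites/alts
        n = 6000
        sites = rng.integers(0, len(seq), size=n)
        rows = []
        for i, s in enumerate(sites):
            ref = seq[s]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            ctx = seq[max(s - 1, 0):s + 2]
            if len(ctx) != 3:
                continue
            if ref in "AG":
                from cpghm.spectrum import revcomp

                ctx = revcomp(ctx)
            rows.append((f"S{i}", "chr1", s + 1, ref, alt, "G", "missense", ctx, np.nan))
        recs = pd.DataFrame(rows, columns=["sample_id", "chrom", "pos", "ref",
                                           "alt", "gene", "consequence",
                                           "context3", "vaf"])
        out = gene_cpg_summary(recs, seq, hotspot_fraction=1.1)
        se = math.sqrt(exp * (1 - exp) / len(recs)) / exp
        assert out.fold_enrichment == pytest.approx(1.0, abs=5 * se)

    def test_empty_gene_undefined(self):
        out = gene_cpg_summary(self._gene_records([], [], [], []), "ATGTAA")
        assert math.isnan(out.proportion)


class TestStrataRate:
    def _mk(self, n_focal, k_focal, n_rest, k_rest):
        rows = []
        calls = []
        for i in range(n_focal):
            cpg = i < k_focal
            rows.append((f"F{i}", "chr1", 10, "C", "T", "TP53", "missense",
                         "ACG" if cpg else "ACA", np.nan))
            calls.append((f"F{i}", "HM_CpG-Hi"))
        for i in range(n_rest):
            cpg = i < k_rest
            rows.append((f"R{i}", "chr1", 20, "C", "T", "TP53", "missense",
                         "ACG" if cpg else "ACA", np.nan))
            calls.append((f"R{i}", "non-HM"))
        recs = pd.DataFrame(rows, columns=["sample_id", "chrom", "pos", "ref",
                                           "alt", "gene", "consequence",
                                           "context3", "vaf"])
        return recs, pd.DataFrame(calls, columns=["sample_id", "label"])

    def test_printed_proportions(self):
        recs, calls = self._mk(44, 33, 806, 203)
        out = strata_cpg_rate(recs, calls)
        assert out.loc["focal", "proportion"] == pytest.approx(33 / 44)
        assert out.loc["rest", "proportion"] == pytest.approx(203 / 806, abs=1e-9)
        assert out.loc["focal", "ratio_vs_rest"] == pytest.approx((33 / 44) / (203 / 806))

    def test_generator_probabilities_recovered(self, rng):
        # stratum-specific CpG placement (0.25, 0.75) recovered at n=500/stratum
        k_focal = rng.binomial(500, 0.75)
        k_rest = rng.binomial(500, 0.25)
        recs, calls = self._mk(500, k_focal, 500, k_rest)
        out = strata_cpg_rate(recs, calls)
        assert out.loc["focal", "proportion"] == pytest.approx(0.75, abs=0.05)
        assert out.loc["rest", "proportion"] == pytest.approx(0.25, abs=0.05)


class TestExpressionFlag:
    def test_three_sd_outlier_flagged(self):
        vals = [10.0] * 6 + [8.0] * 5 + [12.0] * 5 + [4.0]
        expr = pd.DataFrame([vals], index=["MSH2"],
                            columns=[f"S{i}" for i in range(len(vals))])
        flags = low_expression_flag(expr, z_cut=-2)
        assert flags.loc["MSH2"].sum() == 1
        assert flags.loc["MSH2", f"S{len(vals) - 1}"]

    def test_constant_expression_no_flags(self, caplog):
        expr = pd.DataFrame([[5.0] * 12], index=["MSH6"],
                            columns=[f"S{i}" for i in range(12)])
        with caplog.at_level("WARNING"):
            flags = low_expression_flag(expr)
        assert not flags.values.any()

    def test_planted_outliers_recovered(self):
        from cpghm.simulate import generate_expression

        samples = [f"S{i}" for i in range(60)]
        expr, truth = generate_expression(
            samples, {"MSH2": ["S1", "S7"], "MSH6": ["S3"]}, seed=5)
        flags = low_expression_flag(expr, z_cut=-2)
        for _, row in truth.iterrows():
            assert flags.loc[row["gene"], row["sample_id"]]
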