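"""Binomial mutation calling, stratified rates and subtype-specific sites."""

from __future__ import annotations

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from shoremeth import mutation as mut
from shoremeth.regions import BinIndex

from _oracles import binom_tail_exact, subtype_specific_rule
from conftest import make_sheet


def obs_frame(rows):
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "sample", "coverage", "mismatches", "rms"]
    )


class TestCaller:
    def test_no_mismatches_never_called(self):
        out = mut.call_mutations(obs_frame([("chr1", 10, "s1", 30, 0, 0.5)]))
        assert out.loc[0, "p_error"] == 1.0
        assert not out.loc[0, "is_mutated"]

    def test_heterozygous_signal_called(self):
        out = mut.call_mutations(obs_frame([("chr1", 10, "s1", 30, 15, 0.5)]))
        assert out.loc[0, "p_error"] < 1e-20
        assert out.loc[0, "is_mutated"]

    def test_low_coverage_excluded_regardless_of_mismatches(self):
        out = mut.call_mutations(
            obs_frame([("chr1", 10, "s1", 5, 5, 0.5)]), min_coverage=10
        )
        assert not out.loc[0, "eligible"]
        assert not out.loc[0, "is_mutated"]

    def test_coverage_cap_subsamples_mismatches_proportionally(self):
        out = mut.call_mutations(
            obs_frame([("chr1", 10, "s1", 500, 250, 0.5)]), max_reads=250
        )
        assert out.loc[0, "coverage"] == 250
        assert out.loc[0, "mismatches"] == 125

    def test_mismatches_exceeding_coverage_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            mut.call_mutations(obs_frame([("chr1", 10, "s1", 5, 6, 0.5)]))

    def test_tail_matches_exact_rational_oracle(self):
        """scipy binomial tails agree with Fraction arithmetic to 1e-12."""
        rng = np.random.default_rng(0)
        rows = []
        for i in range(100):
            cov = int(rng.integers(10, 250))
            mm = int(rng.integers(0, min(cov, 20) + 1))
            rows.append(("chr1", i, "s1", cov, mm, 0.5))
        out = mut.call_mutations(obs_frame(rows))
        err = Fraction(1, 500)  # 0.002 exactly
        for i, (_, _, _, cov, mm, _) in enumerate(rows):
            exact = float(binom_tail_exact(cov, mm, err))
            assert abs(out.loc[i, "p_error"] - exact) <= 1e-12

    def test_false_positive_rate_under_null(self):
        """Pure sequencing error over 2e4 site-samples: no calls at alpha 1e-6."""
        rng = np.random.default_rng(1)
        n = 20_000
        cov = rng.poisson(30, n).clip(10, 250)
        mm = rng.binomial(cov, 0.002)
        rows = obs_frame(
            [("chr1", i, "s1", int(c), int(m), 0.5) for i, (c, m) in enumerate(zip(cov, mm))]
        )
        out = mut.call_mutations(rows)
        fp = out["is_mutated"].mean()
        assert fp <= 1e-6 + 3 * np.sqrt(1e-6 / n)


class TestRateTable:
    def calls_for(self, n, n_mut, rms=0.3, subtype_sample="Lu01"):
        rows = []
        for i in range(n):
            mm = 15 if i < n_mut else 0
            rows.append(("chr1", i, subtype_sample, 30, mm, rms))
        return mut.call_mutations(obs_frame(rows))

    def test_rate_is_mutated_over_eligible(self):
        sheet = make_sheet(2)
        calls = self.calls_for(100, 5)
        out = mut.mutation_rate_by_methylation(calls, sheet, 0.05)
        row = out[(out["subtype"] == "luminal") & (out["stratum_lo"] == 0.3)]
        assert row["n_sites"].item() == 100
        assert row["rate"].item() == pytest.approx(0.05)

    def test_empty_stratum_is_na_not_zero(self):
        sheet = make_sheet(2)
        out = mut.mutation_rate_by_methylation(self.calls_for(10, 0), sheet, 0.05)
        empty = out[(out["subtype"] == "luminal") & (out["stratum_lo"] == 0.9)]
        assert np.isnan(empty["rate"].item())

    def test_top_stratum_closed_at_one(self):
        sheet = make_sheet(2)
        calls = self.calls_for(10, 2, rms=1.0)
        out = mut.mutation_rate_by_methylation(calls, sheet, 0.05)
        top = out[(out["subtype"] == "luminal") & (out["stratum_hi"] == 1.0)]
        assert top["n_sites"].item() == 10

    def test_stratum_totals_conserve_call_count(self, default_dataset):
        ds = default_dataset
        calls = mut.call_mutations(ds.sites)
        out = mut.mutation_rate_by_methylation(calls, ds.samples, 0.05)
        subtype_of = dict(zip(ds.samples["sample"], ds.samples["subtype"]))
        eligible = calls[calls["eligible"]]
        for st in ("luminal", "basalA", "basalB"):
            members = [s for s, t in subtype_of.items() if t == st]
            total = int(eligible[eligible["sample"].isin(members)]["is_mutated"].sum())
            assert out[out["subtype"] == st]["n_mutated"].sum() == total


class TestStratumAnova:
    def make_rates(self, rng, n_strata=5, shift=None):
        sheet = make_sheet(10)
        vals = rng.normal(0.02, 0.004, (n_strata, 30)).clip(0)
        if shift is not None:
            strata, delta = shift
            mask = (sheet["subtype"] == "basalA").to_numpy()
            vals[np.ix_(strata, np.flatnonzero(mask))] += delta
        return pd.DataFrame(vals, columns=sheet["sample"]), sheet

    def test_null_rates_rarely_significant(self):
        rng = np.random.default_rng(2)
        hits = 0
        for _ in range(40):
            rates, sheet = self.make_rates(rng)
            out = mut.stratum_anova(rates, sheet, 0.2)
            hits += bool((out["p_adj"] < 0.05).any())
        assert hits / 40 <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 40)

    def test_single_stratum_bonferroni_is_identity(self):
        rng = np.random.default_rng(3)
        rates, sheet = self.make_rates(rng, n_strata=1)
        out = mut.stratum_anova(rates.iloc[:1], sheet, 1.0)
        assert out["p_adj"].iloc[0] == pytest.approx(out["p"].iloc[0])

    def test_shifted_strata_flagged_selectively(self):
        rng = np.random.default_rng(4)
        rates, sheet = self.make_rates(rng, n_strata=5, shift=([0, 1], 0.04))
        out = mut.stratum_anova(rates, sheet, 0.2)
        assert (out.loc[[0, 1], "p_adj"] < 0.05).all()
        assert (out.loc[[2, 3, 4], "p_adj"] > 0.05).all()


class TestClassifySpecific:
    def calls_with_fractions(self, grids, n_per=10):
        """One site per (a, b, c) carrier-count triple over 10/10/10 samples."""
        sheet = make_sheet(n_per)
        rows = []
        for i, (ka, kb, kc) in enumerate(grids):
            counts = {"luminal": ka, "basalA": kb, "basalB": kc}
            done = {"luminal": 0, "basalA": 0, "basalB": 0}
            for r in sheet.itertuples(index=False):
                mutated = done[r.subtype] < counts[r.subtype]
                done[r.subtype] += mutated
                rows.append(("chr1", i, r.sample, 30, 15 if mutated else 0, 0.5))
        return mut.call_mutations(obs_frame(rows)), sheet

    def test_example_rule_applications(self):
        calls, sheet = self.calls_with_fractions([(0, 4, 0), (0, 4, 2)])
        out = mut.classify_subtype_specific(calls, sheet)
        assert len(out) == 1
        assert out.iloc[0]["pos"] == 0 and out.iloc[0]["assigned_subtype"] == "basalA"

    def test_misconfigured_thresholds_rejected(self):
        calls, sheet = self.calls_with_fractions([(0, 4, 0)])
        with pytest.raises(ValueError, match="min_in"):
            mut.classify_subtype_specific(calls, sheet, min_in=0.1, max_out=0.2)

    def test_full_enumeration_matches_rule_oracle(self):
        """All 11^3 carrier-count combinations at n=10/10/10, exactly."""
        grids = [(a, b, c) for a in range(11) for b in range(11) for c in range(11)]
        calls, sheet = self.calls_with_fractions(grids)
        out = mut.classify_subtype_specific(calls, sheet)
        got = dict(zip(out["pos"], out["assigned_subtype"]))
        for i, (a, b, c) in enumerate(grids):
            expect = subtype_specific_rule(
                {"luminal": a / 10, "basalA": b / 10, "basalB": c / 10}
            )
            assert got.get(i) == expect, (a, b, c)

    def test_permutation_equivariance_under_relabeling(self):
        calls, sheet = self.calls_with_fractions([(4, 0, 0), (0, 4, 0), (0, 0, 4)])
        out1 = mut.classify_subtype_specific(calls, sheet)
        swap = {"luminal": "basalB", "basalB": "luminal", "basalA": "basalA"}
        sheet2 = sheet.assign(subtype=sheet["subtype"].map(swap))
        out2 = mut.classify_subtype_specific(calls, sheet2)
        m1 = dict(zip(out1["pos"], out1["assigned_subtype"]))
        m2 = dict(zip(out2["pos"], out2["assigned_subtype"]))
        assert m2 == {pos: swap[st] for pos, st in m1.items()}


class TestRegionalCounts:
    def test_empty_specific_set_gives_empty_tables(self):
        sheet = make_sheet(2)
        calls = mut.call_mutations(obs_frame([("chr1", 1, "Lu01", 30, 0, 0.5)]))
        spec = mut.classify_subtype_specific(calls, sheet)
        bi = BinIndex({"chr1": 1000}, 100)
        counts, anova = mut.regional_mutation_counts(
            spec, calls, bi, [set() for _ in range(10)], sheet
        )
        assert counts.empty and anova.empty

    def test_planted_regional_bias_recovered(self, default_dataset):
        """Basal A specific sites dominate island-related regions, basal B introns."""
        ds = default_dataset
        calls = mut.call_mutations(ds.sites)
        spec = mut.classify_subtype_specific(calls, ds.samples)
        counts, anova = mut.regional_mutation_counts(
            spec, calls, ds.genome.bin_index, ds.genome.bin_labels, ds.samples
        )
        c = counts.set_index("region")
        for region in ("CpGI", "shore", "shelf"):
            assert c.loc[region, "basalA"] == c.loc[region].max()
        assert c.loc["intron", "basalB"] == c.loc["intron"].max()
        sig = anova.set_index("region")["p_adj"]
        assert sig["intron"] < 0.05 and sig["shore"] < 0.05
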