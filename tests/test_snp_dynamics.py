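"""Variant calling, shared-SNP fractions and turnover regression."""

import datetime

import numpy as np
import pandas as pd
import pytest

from phageome.snp_dynamics import (
    InputError,
    SNPProfile,
    call_snps,
    classify_substitution,
    fit_turnover_rate,
    select_genomes_for_snp,
    shared_snp_fraction,
    similarity_series,
    similarity_vs_lag,
)
from phageome.synthetic_data import SimTruth, generate_snp_series


class TestGenomeSelection:
    def run(self, coverages):
        cov = pd.DataFrame([coverages], index=["g"], columns=[f"s{i}" for i in range(len(coverages))])
        return select_genomes_for_snp(cov, {"A2": list(cov.columns)})["A2"]

    def test_all_samples_deep_enough(self):
        assert self.run([12.0, 15.0, 11.0]) == ["g"]

    def test_one_shallow_sample_disqualifies(self):
        assert self.run([12.0, 9.0, 11.0]) == []

    def test_boundary_inclusive(self):
        assert self.run([10.0, 10.0, 10.0]) == ["g"]

    def test_missing_sample_counts_zero(self):
        cov = pd.DataFrame([[20.0]], index=["g"], columns=["s0"])
        assert select_genomes_for_snp(cov, {"A2": ["s0", "s_absent"]})["A2"] == []


def pileup(rows):
    return pd.DataFrame(rows, columns=["position", "ref_base", "base", "count", "mean_qual"])


class TestCallSnps:
    def test_three_alt_reads_below_count_rule(self):
        p = pileup([(100, "A", "A", 97, 37.0), (100, "A", "T", 3, 37.0)])
        assert call_snps(p, "g", "d").variants == set()

    def test_five_alt_reads_called_with_frequency(self):
        p = pileup([(100, "A", "A", 95, 37.0), (100, "A", "T", 5, 37.0)])
        vs = call_snps(p, "g", "d").variants
        assert vs == {(100, "A", "T", 0.05)}

    def test_frequency_rule_strict(self):
        # 9 of 1000 reads is 0.9% -- below the >1% rule despite 9 reads
        p = pileup([(50, "C", "C", 991, 37.0), (50, "C", "G", 9, 37.0)])
        assert call_snps(p, "g", "d").variants == set()

    def test_low_quality_calls_excluded(self):
        p = pileup([(10, "A", "A", 90, 37.0), (10, "A", "G", 10, 25.0)])
        assert call_snps(p, "g", "d").variants == set()

    def test_multi_allelic_site_independent_records(self):
        p = pileup(
            [(7, "A", "A", 80, 37.0), (7, "A", "T", 10, 37.0), (7, "A", "G", 10, 37.0)]
        )
        vs = call_snps(p, "g", "d").variant_keys()
        assert vs == {(7, "T"), (7, "G")}

    def test_matches_per_site_filter_oracle(self):
        rng = np.random.default_rng(17)
        rows = []
        for pos in range(1, 60):
            depth = int(rng.integers(5, 200))
            alt = int(rng.integers(0, depth // 2 + 1))
            qual = float(rng.choice([25.0, 37.0]))
            rows.append((pos, "A", "A", depth - alt, 37.0))
            rows.append((pos, "A", "C", alt, qual))
        p = pileup(rows)
        got = call_snps(p, "g", "d").variant_keys()
        expected = set()
        for pos, _r, base, count, qual in rows:
            if base == "A":
                continue
            depth = sum(c for pp, _rr, _b, c, _q in rows if pp == pos)
            if qual > 30 and count >= 4 and count / depth > 0.01:
                expected.add((pos, base))
        assert got == expected


class TestSharedFraction:
    def prof(self, keys, date=1):
        return SNPProfile("g", date, {(pos, "A", alt, 0.1) for pos, alt in keys})

    def test_half_shared(self):
        earlier = self.prof([(100, "T"), (200, "G")], 1)
        later = self.prof([(100, "T"), (300, "A")], 2)
        assert shared_snp_fraction(earlier, later) == 0.5

    def test_identical_sets(self):
        assert shared_snp_fraction(self.prof([(1, "T")], 1), self.prof([(1, "T")], 2)) == 1.0

    def test_disjoint_sets(self):
        assert shared_snp_fraction(self.prof([(1, "T")], 1), self.prof([(2, "C")], 2)) == 0.0

    def test_empty_earlier_flagged(self):
        with pytest.warns(UserWarning):
            assert np.isnan(shared_snp_fraction(self.prof([], 1), self.prof([(1, "T")], 2)))

    def test_genome_mismatch_rejected(self):
        with pytest.raises(InputError):
            shared_snp_fraction(SNPProfile("g1", 1), SNPProfile("g2", 2))

    def test_monotone_under_removal_of_shared_variants(self):
        earlier = self.prof([(1, "T"), (2, "G"), (3, "C")], 1)
        later = self.prof([(1, "T"), (2, "G")], 2)
        f_full = shared_snp_fraction(earlier, later)
        later_smaller = self.prof([(1, "T")], 2)
        assert shared_snp_fraction(earlier, later_smaller) <= f_full


class TestClassifySubstitution:
    # gene on the forward strand at positions 1-9: GCT GAT AAA
    SEQ = "GCTGATAAA" + "TTTT"
    GENES = [(1, 9, "+")]

    def test_synonymous(self):
        # GCT -> GCC is Ala -> Ala
        assert classify_substitution(self.SEQ, self.GENES, 11, 3, "T", "C") == ["synonymous"]

    def test_non_synonymous(self):
        # GCT -> GTT is Ala -> Val
        assert classify_substitution(self.SEQ, self.GENES, 11, 2, "C", "T") == ["non-synonymous"]

    def test_intergenic(self):
        assert classify_substitution(self.SEQ, self.GENES, 11, 11, "T", "A") == ["intergenic"]

    def test_reverse_strand_gene(self):
        # gene is the reverse complement: read TTTATCAGC backwards
        seq = "GCTGATAAA"
        genes = [(1, 9, "-")]
        # genome position 9 (A) is the first base of the minus-strand gene (T)
        # A->G at pos 9 makes the codon TTT -> CTT: Phe -> Leu
        assert classify_substitution(seq, genes, 11, 9, "A", "G") == ["non-synonymous"]

    def test_recoded_stop_codon_honored(self):
        # TAG is a stop under code 11 but Gln under code 15: CAG -> TAG is
        # non-synonymous either way, but TAG -> TAA differs by code
        seq = "TAGGATAAA"
        genes = [(1, 9, "+")]
        # code 15: TAG=Q, TAA=* -> non-synonymous; code 91: TAG=*, TAA=Q
        assert classify_substitution(seq, genes, 15, 3, "G", "A") == ["non-synonymous"]

    def test_ref_mismatch_rejected(self):
        with pytest.raises(InputError):
            classify_substitution(self.SEQ, self.GENES, 11, 1, "T", "C")


def series_from_turnover(rho_v, rho_t, seed, n_dates=8, sites=20, n_pops=4):
    truth = SimTruth()
    genomes = {}
    rng = np.random.default_rng(seed)
    for i in range(n_pops):
        pop = f"P{i}"
        truth.pop_lifestyle[pop] = "virulent" if i % 2 == 0 else "temperate"
        gid = f"g{i}"
        truth.representative[pop] = gid
        genomes[gid] = "".join(rng.choice(list("ACGT"), size=2000))
    pile = generate_snp_series(
        truth, genomes, n_dates=n_dates, sites_per_genome=sites,
        turnover_virulent=rho_v, turnover_temperate=rho_t, depth=50, seed=seed,
    )
    profiles = []
    for (gid, date), grp in pile.groupby(["genome_id", "sample_id"]):
        prof = call_snps(grp, gid, datetime.date.fromisoformat(date))
        profiles.append(prof)
    lifestyle_of_genome = {
        truth.representative[p]: ls for p, ls in truth.pop_lifestyle.items()
    }
    frames = [
        similarity_series([p for p in profiles if lifestyle_of_genome[p.genome_id] == ls], ls)
        for ls in ("virulent", "temperate")
    ]
    return pd.concat(frames, ignore_index=True)


class TestSimilarityVsLag:
    def test_zero_turnover_limit(self):
        series = series_from_turnover(0.0, 0.0, seed=2)
        assert (series["shared_fraction"] == 1.0).all()
        fits, _cmp = similarity_vs_lag(series)
        assert (fits["slope"] == 0.0).all()
        assert fits["adj_r2"].isna().all()

    def test_geometric_decay_matches_closed_form(self):
        """Mean shared fraction at lag t tracks (1-rho)^t."""
        series = series_from_turnover(0.3, 0.3, seed=3, n_dates=10, sites=40, n_pops=6)
        means = series.groupby("lag_days")["shared_fraction"].mean()
        for lag in (1, 2, 3):
            assert means[lag] == pytest.approx(0.7**lag, abs=0.08)

    def test_virulent_turnover_steeper_negative_slope(self):
        series = series_from_turnover(0.3, 0.1, seed=4, n_dates=10, sites=30, n_pops=6)
        fits, cmp_df = similarity_vs_lag(series)
        assert fits.loc["virulent", "slope"] < fits.loc["temperate", "slope"] < 0
        # virulent fractions lower at every early lag
        early = cmp_df[cmp_df["lag_days"] <= 5]
        assert (early["mean_temperate"] > early["mean_virulent"]).all()

    def test_fit_turnover_recovers_rate(self):
        series = series_from_turnover(0.3, 0.1, seed=5, n_dates=10, sites=40, n_pops=8)
        rates = fit_turnover_rate(series)
        assert rates["virulent"] == pytest.approx(0.3, abs=0.06)
        assert rates["temperate"] == pytest.approx(0.1, abs=0.06)
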