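"""Spacer / homology host prediction and interaction statistics."""

import numpy as np
import pandas as pd
import pytest

from phageome._codes import reverse_complement
from phageome.host_linkage import (
    HostLink,
    defense_burden,
    host_and_phage_range,
    match_genome_homology,
    match_spacers,
    phage_host_correlation,
)
from phageome.io_formats import AlignmentHit
from phageome.synthetic_data import generate_hosts


def ident_maps(genomes):
    return {g: g for g in genomes}


class TestMatchSpacers:
    GENOME = "A" * 100 + "ACGTACGTGGCCTTAAGGCCACGTACGTGGAA" + "T" * 100
    SPACER = "ACGTACGTGGCCTTAAGGCCACGTACGTGGAA"

    def run(self, spacer_seq):
        return match_spacers(
            [("sp1", "h1", spacer_seq)],
            {"g1": self.GENOME},
            {"g1": "pop1"},
            {"h1": "prok1"},
        )

    def test_exact_substring_links(self):
        links = self.run(self.SPACER)
        assert links == [HostLink("pop1", "prok1", "spacer", links[0].detail)]

    def test_one_mismatch_no_link(self):
        mutated = "T" + self.SPACER[1:]
        assert self.run(mutated) == []

    def test_reverse_complement_links(self):
        assert len(self.run(reverse_complement(self.SPACER))) == 1

    def test_non_acgt_spacer_skipped_with_warning(self):
        with pytest.warns(UserWarning):
            assert self.run("ACGTNNACGTACGTACGTACGTACGT") == []

    def test_short_spacer_skipped(self):
        with pytest.warns(UserWarning):
            assert self.run("ACGTACGTACGT") == []

    def test_agrees_with_all_positions_scan(self):
        """Matcher equals a brute-force scan over every position and strand."""
        rng = np.random.default_rng(9)
        bases = np.array(list("ACGT"))
        genomes = {
            f"g{i}": "".join(rng.choice(bases, size=400)) for i in range(4)
        }
        spacers = []
        for k in range(12):
            gid = f"g{k % 4}"
            start = int(rng.integers(0, 360))
            seq = genomes[gid][start : start + 30]
            if rng.random() < 0.5:
                seq = reverse_complement(seq)
            if rng.random() < 0.3:  # plant some mismatching spacers
                seq = "".join(rng.choice(bases, size=30))
            spacers.append((f"sp{k}", "h1", seq))
        links = match_spacers(spacers, genomes, ident_maps(genomes), {"h1": "h1"})
        # oracle: position-by-position comparison on both strands
        expected = set()
        for sid, _h, seq in spacers:
            rc = reverse_complement(seq)
            for gid, gseq in genomes.items():
                hitting = any(
                    gseq[i : i + len(seq)] in (seq, rc)
                    for i in range(len(gseq) - len(seq) + 1)
                )
                if hitting:
                    expected.add((gid, "h1"))
        assert {(l.phage_pop_id, l.prok_pop_id) for l in links} == expected

    def test_planted_spacers_full_recall_no_false_links(self, community_with_hosts):
        genomes, _gt, truth, hosts = community_with_hosts
        links = match_spacers(
            hosts.spacers,
            genomes,
            truth.votu_of,
            {h: h for h in hosts.genomes},
        )
        found = {(l.phage_pop_id, l.prok_pop_id) for l in links}
        planted = {(pop, host) for _sid, host, pop in truth.spacers}
        assert found == planted  # 100% recall, zero false links


def hom_hit(length, ident, evalue=1e-20, bits=500):
    return AlignmentHit("p1", "h1", ident, length, 0, 0, 1, length, 1, length, evalue, bits)


class TestHomology:
    MAPS = ({"p1": "pop1"}, {"h1": "prok1"})

    @pytest.mark.parametrize(
        "length,ident,evalue,bits,linked",
        [
            (1200, 97.0, 1e-20, 800, True),
            (900, 99.0, 1e-30, 800, False),          # alignment below 1 kb
            (1000, 96.0, 1e-3, 50, True),            # every boundary inclusive
            (1500, 95.9, 1e-20, 800, False),         # identity below 96
            (1500, 97.0, 1e-2, 800, False),          # e-value above 1e-3
            (1500, 97.0, 1e-20, 49.9, False),        # bit score below 50
        ],
    )
    def test_four_part_criterion(self, length, ident, evalue, bits, linked):
        links = match_genome_homology([hom_hit(length, ident, evalue, bits)], *self.MAPS)
        assert (len(links) == 1) is linked

    def test_links_revalidate_against_thresholds(self):
        rng = np.random.default_rng(13)
        hits = [
            hom_hit(
                int(rng.integers(200, 3000)),
                float(rng.uniform(90, 100)),
                float(10.0 ** rng.uniform(-30, 0)),
                float(rng.uniform(10, 900)),
            )
            for _ in range(100)
        ]
        links = match_genome_homology(hits, *self.MAPS)
        for l in links:
            matching = [
                h
                for h in hits
                if h.evalue <= 1e-3 and h.bit_score >= 50 and h.aln_length >= 1000 and h.pct_identity >= 96
            ]
            assert matching, "link emitted without a qualifying hit"


class TestRanges:
    LIFESTYLES = {"P1": "virulent", "P2": "temperate", "P3": "temperate"}

    def test_host_and_phage_range_counts(self):
        links = [
            HostLink("P1", "H1", "spacer"),
            HostLink("P1", "H2", "homology"),
            HostLink("P2", "H1", "spacer"),
            HostLink("P3", "H1", "spacer"),
            HostLink("P1", "H1", "homology"),  # duplicate pair, distinct evidence
        ]
        host_range, phage_range = host_and_phage_range(links, self.LIFESTYLES)
        assert host_range.loc["P1", "host_range"] == 2
        # phage range is reported per lifestyle: H1 hosts 1 virulent + 2 temperate
        h1 = phage_range.loc["H1"].set_index("lifestyle")["phage_range"]
        assert h1["virulent"] == 1 and h1["temperate"] == 2
        assert h1.sum() == 3

    def test_no_links_empty_tables(self):
        host_range, phage_range = host_and_phage_range([], self.LIFESTYLES)
        assert host_range.empty and phage_range.empty


class TestCorrelation:
    def frame(self, rows, index):
        return pd.DataFrame(rows, index=index, columns=[f"s{i}" for i in range(6)])

    def test_identical_series_r_one(self):
        x = [1.0, 2, 3, 4, 5, 6]
        out = phage_host_correlation(
            self.frame([x], ["P"]), self.frame([x], ["H"]),
            [HostLink("P", "H", "spacer")], {"P": "virulent"},
        )
        assert out["r"].iloc[0] == pytest.approx(1.0)

    def test_negated_series_r_minus_one(self):
        x = np.array([1.0, 2, 3, 4, 5, 6])
        out = phage_host_correlation(
            self.frame([x], ["P"]), self.frame([10 - x], ["H"]),
            [HostLink("P", "H", "spacer")], {"P": "virulent"},
        )
        assert out["r"].iloc[0] == pytest.approx(-1.0)

    def test_zero_variance_excluded_with_warning(self):
        out_args = (
            self.frame([[1.0] * 6], ["P"]), self.frame([[1, 2, 3, 4, 5, 6]], ["H"]),
            [HostLink("P", "H", "spacer")], {"P": "virulent"},
        )
        with pytest.warns(UserWarning):
            out = phage_host_correlation(*out_args)
        assert out.empty

    def test_planted_shared_multiplier_strong_correlation(self):
        """A host tracking its phage's abundance with sigma=0.1 lognormal
        noise (the piggyback-the-winner plant) correlates at r > 0.8."""
        rng = np.random.default_rng(21)
        phage = rng.lognormal(3, 1.0, size=12)
        host = phage * rng.lognormal(0, 0.1, size=12)
        cols = [f"s{i}" for i in range(12)]
        out = phage_host_correlation(
            pd.DataFrame([phage], index=["P"], columns=cols),
            pd.DataFrame([host], index=["H"], columns=cols),
            [HostLink("P", "H", "spacer")],
            {"P": "temperate"},
        )
        assert out["r"].iloc[0] > 0.8


class TestDefenseBurden:
    TABLE = pd.DataFrame(
        {
            "prok_genome_id": ["h1", "h1", "h2", "h3"],
            "system_name": ["RM", "CRISPR-Cas", "RM", "RM"],
            "count": [2, 1, 1, 4],
        }
    )

    def test_per_genome_total_counts_instances(self):
        out = defense_burden(self.TABLE, {"g": {"h1"}})
        assert out.loc["g", "mean_systems"] == 3.0

    def test_empty_group_flagged(self):
        with pytest.warns(UserWarning):
            out = defense_burden(self.TABLE, {"empty": set()})
        assert np.isnan(out.loc["empty", "mean_systems"])

    def test_missing_genome_counts_zero(self):
        with pytest.warns(UserWarning):
            out = defense_burden(self.TABLE, {"g": {"h1", "ghost"}})
        assert out.loc["g", "mean_systems"] == pytest.approx(1.5)

    def test_planted_group_difference_sign_recovered(self):
        rng = np.random.default_rng(8)
        rows = []
        vir_group, tem_group = set(), set()
        for i in range(30):
            g = f"v{i}"
            vir_group.add(g)
            rows.append((g, "RM", int(rng.poisson(4))))
        for i in range(30):
            g = f"t{i}"
            tem_group.add(g)
            rows.append((g, "RM", int(rng.poisson(1.5))))
        table = pd.DataFrame(rows, columns=["prok_genome_id", "system_name", "count"])
        out = defense_burden(table, {"virulent": vir_group, "temperate": tem_group})
        assert out.loc["virulent", "mean_systems"] > out.loc["temperate", "mean_systems"]
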