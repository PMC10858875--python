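"""Protein clustering and gene-sharing (HGT proxy) statistics."""

import numpy as np
import pandas as pd
import pytest
from Bio.Align import substitution_matrices

from phageome.gene_sharing import (
    InputError,
    ProteinCluster,
    ProteinRecord,
    cluster_proteins,
    host_vs_nonhost_sharing,
    screen_ta_and_correlate,
    shared_pc_ratio,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def prot(pid, seq, origin="virulent", genome=None, pop=None):
    return ProteinRecord(pid, seq, origin, genome or pid, pop or (genome or pid))


def random_protein(rng, n):
    return "".join(rng.choice(list(AA), size=n))


def mutate_protein(rng, seq, n_subs):
    s = list(seq)
    for i in rng.choice(len(s), size=n_subs, replace=False):
        s[i] = rng.choice([a for a in AA if a != s[i]])
    return "".join(s)


class TestClusterProteins:
    def test_identical_sequences_one_cluster(self):
        rng = np.random.default_rng(0)
        seq = random_protein(rng, 80)
        pcs = cluster_proteins([prot("a", seq), prot("b", seq)])
        assert len(pcs) == 1 and len(pcs[0].members) == 2

    def test_near_identical_join_unrelated_separate(self):
        rng = np.random.default_rng(1)
        seq = random_protein(rng, 100)
        near = mutate_protein(rng, seq, 5)  # 95% identity
        other = random_protein(rng, 100)
        pcs = cluster_proteins([prot("a", seq), prot("b", near), prot("c", other)])
        assert len(pcs) == 2
        sizes = sorted(len(pc.members) for pc in pcs)
        assert sizes == [1, 2]

    def test_non_amino_acid_rejected(self):
        with pytest.raises(InputError):
            cluster_proteins([prot("a", "ACDEF*GHIK")])

    def test_matches_exact_dp_oracle(self):
        """The greedy partition equals one driven by an independently
        implemented Smith-Waterman (BLOSUM62, gap 11/1) with the same
        ordering and best-cluster rule."""
        rng = np.random.default_rng(5)
        proteins = []
        k = 0
        for fam in range(6):
            base = random_protein(rng, int(rng.integers(40, 70)))
            for _ in range(int(rng.integers(1, 4))):
                n_subs = int(rng.integers(0, max(1, len(base) // 10)))
                proteins.append(prot(f"p{k:02d}", mutate_protein(rng, base, n_subs)))
                k += 1
        while k < 30:
            proteins.append(prot(f"p{k:02d}", random_protein(rng, int(rng.integers(40, 70)))))
            k += 1
        pcs = cluster_proteins(proteins)
        got = {}
        for pc in pcs:
            for m in pc.members:
                got[m.protein_id] = pc.pc_id
        expected = oracle_partition(proteins)
        # compare as partitions
        by_got, by_exp = {}, {}
        for pid in got:
            by_got.setdefault(got[pid], set()).add(pid)
            by_exp.setdefault(expected[pid], set()).add(pid)
        assert sorted(map(sorted, by_got.values())) == sorted(map(sorted, by_exp.values()))


def smith_waterman(a, b):
    """Affine-gap local alignment returning (identity, coverage of shorter)."""
    blosum = substitution_matrices.load("BLOSUM62")
    n, m = len(a), len(b)
    NEG = -1e9
    M = np.full((n + 1, m + 1), 0.0)
    X = np.full((n + 1, m + 1), NEG)  # gap in b (vertical)
    Y = np.full((n + 1, m + 1), NEG)  # gap in a (horizontal)
    ptrM = np.zeros((n + 1, m + 1), dtype=int)
    best, bi, bj = 0.0, 0, 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            X[i, j] = max(M[i - 1, j] - 11, X[i - 1, j] - 1)
            Y[i, j] = max(M[i, j - 1] - 11, Y[i, j - 1] - 1)
            s = blosum[a[i - 1], b[j - 1]]
            cand = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            M[i, j] = max(0.0, cand + s)
            if M[i, j] > best:
                best, bi, bj = M[i, j], i, j
    if best <= 0:
        return 0.0, 0.0
    # traceback from (bi, bj) through the M/X/Y lattice
    i, j, state = bi, bj, "M"
    cols = ident = a_res = b_res = 0
    while i > 0 and j > 0:
        if state == "M":
            if M[i, j] == 0:
                break
            cols += 1
            a_res += 1
            b_res += 1
            if a[i - 1] == b[j - 1]:
                ident += 1
            s = blosum[a[i - 1], b[j - 1]]
            prev = M[i, j] - s
            if abs(prev - M[i - 1, j - 1]) < 1e-6 or abs(prev) < 1e-6:
                state = "M"
            elif abs(prev - X[i - 1, j - 1]) < 1e-6:
                state = "X"
            else:
                state = "Y"
            i, j = i - 1, j - 1
            if prev <= 1e-6:
                break
        elif state == "X":
            cols += 1
            a_res += 1
            if abs(X[i, j] - (M[i - 1, j] - 11)) < 1e-6:
                state = "M"
            i -= 1
        else:
            cols += 1
            b_res += 1
            if abs(Y[i, j] - (M[i, j - 1] - 11)) < 1e-6:
                state = "M"
            j -= 1
    short_res = a_res if len(a) <= len(b) else b_res
    return ident / cols, short_res / min(len(a), len(b))


def oracle_partition(proteins, identity=0.60, cov_short=0.80):
    order = sorted(proteins, key=lambda p: (-len(p.seq), p.protein_id))
    clusters, reps = [], []
    assign = {}
    for p in order:
        best_idx, best_ident = None, -1.0
        for idx, rep in enumerate(reps):
            ident, cov = smith_waterman(rep, p.seq)
            if ident >= identity and cov >= cov_short and ident > best_ident:
                best_idx, best_ident = idx, ident
        if best_idx is None:
            clusters.append(len(clusters))
            reps.append(p.seq)
            assign[p.protein_id] = len(clusters) - 1
        else:
            assign[p.protein_id] = best_idx
    return assign


def make_pc(pc_id, members):
    pc = ProteinCluster(pc_id, members[0].protein_id)
    pc.members = list(members)
    return pc


class TestSharedRatio:
    def test_ratio_counts_distinct_pcs(self):
        pcs = [
            make_pc("pc1", [prot("a1", "AAAA", "virulent", "g1"), prot("h1", "AAAA", "prokaryote", "p1")]),
            make_pc("pc2", [prot("a2", "CCCC", "virulent", "g1")]),
            make_pc("pc3", [prot("a3", "DDDD", "virulent", "g1")]),
            make_pc("pc4", [prot("a4", "EEEE", "virulent", "g1")]),
            make_pc("pc5", [prot("a5", "FFFF", "virulent", "g1")]),
        ]
        ratios = shared_pc_ratio(pcs)
        assert ratios["g1"] == pytest.approx(1 / 5)

    def test_no_shared_zero_and_all_shared_one(self):
        unshared = [make_pc("pc1", [prot("a", "AAAA", "virulent", "g1")])]
        assert shared_pc_ratio(unshared)["g1"] == 0.0
        shared = [
            make_pc("pc1", [prot("a", "AAAA", "virulent", "g1"), prot("h", "AAAA", "prokaryote", "p1")])
        ]
        assert shared_pc_ratio(shared)["g1"] == 1.0

    def test_duplicate_protein_does_not_move_ratio(self):
        pcs = [
            make_pc("pc1", [prot("a1", "AAAA", "virulent", "g1"), prot("h1", "AAAA", "prokaryote", "p1")]),
            make_pc("pc2", [prot("a2", "CCCC", "virulent", "g1")]),
        ]
        before = shared_pc_ratio(pcs)["g1"]
        pcs[0].members.append(prot("a1b", "AAAA", "virulent", "g1"))
        assert shared_pc_ratio(pcs)["g1"] == before

    def test_shared_flag_audit(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            origins = rng.choice(["virulent", "temperate", "prokaryote"], size=rng.integers(1, 5))
            pc = make_pc("pc", [prot(f"x{i}", "AAAA", o, f"g{i}") for i, o in enumerate(origins)])
            has_phage = any(o in ("virulent", "temperate") for o in origins)
            has_prok = "prokaryote" in origins
            assert pc.shared == (has_phage and has_prok)


class TestHostVsNonhost:
    def build_pcs(self):
        # phage pops P1, P2 each with 2 PCs; prokaryotes A-family a1,a2,a3
        pcs = [
            make_pc("pc1", [prot("p1a", "AAAA", "virulent", "P1", "P1"),
                            prot("a1x", "AAAA", "prokaryote", "a1", "a1")]),
            make_pc("pc2", [prot("p1b", "CCCC", "virulent", "P1", "P1")]),
            make_pc("pc3", [prot("p2a", "DDDD", "virulent", "P2", "P2")]),
            make_pc("pc4", [prot("p2b", "EEEE", "virulent", "P2", "P2")]),
        ]
        return pcs

    FAMS = {"a1": "A", "a2": "A", "a3": "A"}

    def test_subsample_matches_host_pair_count(self):
        pcs = self.build_pcs()
        out = host_vs_nonhost_sharing(pcs, [("P1", "a1")], self.FAMS, seed=0)
        assert out.loc["A", "n_pairs"] == 1
        # host proportion: P1 has 2 PCs, 1 shared with a1
        assert out.loc["A", "host_mean"] == pytest.approx(0.5)
        assert out.loc["A", "nonhost_mean"] == 0.0

    def test_same_seed_same_subsample(self):
        pcs = self.build_pcs()
        a = host_vs_nonhost_sharing(pcs, [("P1", "a1")], self.FAMS, seed=3)
        b = host_vs_nonhost_sharing(pcs, [("P1", "a1")], self.FAMS, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_planted_hgt_host_exceeds_nonhost_every_family(self):
        """With host-specific gene copies planted, host pairs share strictly
        more PCs than family-matched nonhost pairs in every family."""
        from phageome.synthetic_data import extract_proteins, generate_community, generate_hosts

        genomes, gene_table, truth = generate_community(
            n_votus=6, members_per_votu=1, genome_len=10_000, seed=31, genes_per_genome=4
        )
        # 8 hosts over a 4-family pool -> two prokaryotes per family, so
        # every family has nonhost candidates to subsample
        hosts = generate_hosts(
            genomes, truth, phage_gene_table=gene_table,
            n_hosts=8, shared_genes_per_pair=2, background_shared_genes=0,
            seed=32, genes_per_host=4,
        )
        proteins = extract_proteins(genomes, gene_table, truth.lifestyle_of, truth.votu_of)
        proteins += extract_proteins(
            hosts.genomes, hosts.gene_table,
            {h: "prokaryote" for h in hosts.genomes}, {h: h for h in hosts.genomes},
        )
        pcs = cluster_proteins(proteins)
        fam_of = dict(zip(hosts.families["prok_pop_id"], hosts.families["family"]))
        out = host_vs_nonhost_sharing(
            pcs, sorted(truth.host_of.items()), fam_of, seed=33
        )
        valid = out.dropna(subset=["nonhost_mean"])
        assert not valid.empty
        assert (valid["host_mean"] > valid["nonhost_mean"]).all()


class TestTACorrelation:
    def test_proportional_abundance_r_one_vs_leaf(self):
        leaf = np.array([0.1, 0.3, 0.5, 0.7, 0.9, 0.2])
        samples = [f"s{i}" for i in range(6)]
        pc_mat = pd.DataFrame([leaf * 7.0], index=["pc1"], columns=samples)
        diet = pd.DataFrame({"leaf": leaf, "fruit": 1 - leaf}, index=samples)
        out = screen_ta_and_correlate({"pc1": "PemK"}, pc_mat, diet)
        r_leaf = out.loc[out["axis"] == "leaf", "r"].iloc[0]
        assert r_leaf == pytest.approx(1.0)

    def test_constant_pc_excluded(self):
        samples = [f"s{i}" for i in range(5)]
        pc_mat = pd.DataFrame([[2.0] * 5], index=["pc1"], columns=samples)
        diet = pd.DataFrame({"leaf": np.linspace(0, 1, 5), "fruit": np.linspace(1, 0, 5)}, index=samples)
        with pytest.warns(UserWarning):
            out = screen_ta_and_correlate({"pc1": "HicB"}, pc_mat, diet)
        assert out.empty

    def test_missing_pc_skipped_with_warning(self):
        samples = ["s0", "s1", "s2"]
        pc_mat = pd.DataFrame([[1.0, 2.0, 3.0]], index=["pc1"], columns=samples)
        diet = pd.DataFrame({"leaf": [0.1, 0.2, 0.3], "fruit": [0.9, 0.8, 0.7]}, index=samples)
        with pytest.warns(UserWarning):
            out = screen_ta_and_correlate({"ghost": "YoeB"}, pc_mat, diet)
        assert out.empty
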