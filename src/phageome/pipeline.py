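"""Pipeline orchestration: chain the analysis stages over files on disk.

Every stage reads and writes the canonical tabular formats in a working
directory, so stages can be run individually (via the CLI) or chained
end to end with :func:`run_pipeline`.  A manifest either points at an
input directory containing the stage inputs or requests synthetic
generation with planted truth.  Runs are pure functions of (config,
manifest): the same seed produces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import abundance as ab
from . import diet_response as diet
from . import gene_sharing as gs
from . import host_linkage as hl
from . import screening as scr
from . import snp_dynamics as snp
from . import stats_core as stats
from . import synthetic_data as sim
from . import votu
from .io_formats import (
    ManifestError,
    RunConfig,
    read_alignment_table,
    read_fasta,
    read_tsv,
    write_fasta,
    write_tsv,
)

INPUT_FILES = {
    "screen": [
        "phage_genomes.fasta",
        "screening_summaries.tsv",
        "coding_scores.tsv",
        "lifestyle_inputs.tsv",
    ],
    "cluster": ["phage_ani_hits.tsv"],
    "abundance": ["depth_profiles.tsv", "sample_metadata.tsv"],
    "diet": ["feeding_bouts.tsv"],
    "hosts": [
        "spacers.tsv",
        "host_genomes.fasta",
        "families.tsv",
        "defense.tsv",
        "prok_abundance.tsv",
    ],
    "genes": ["phage_genes.tsv", "host_genes.tsv"],
    "snps": ["pileups.tsv"],
}

STAGE_ORDER = [
    "screen",
    "cluster",
    "abundance",
    "diet",
    "hosts",
    "genes",
    "respond",
    "snps",
    "stats",
]


def check_manifest(indir: Path) -> None:
    for stage, files in INPUT_FILES.items():
        for fname in files:
            if not (indir / fname).exists():
                raise ManifestError(f"{stage} stage: missing input {fname}")


# ---------------------------------------------------------------------------
# Synthetic input generation


def simulate_inputs(outdir: str | Path, config: RunConfig, **params) -> Path:
    """Write a full synthetic input set (with truth tables) into *outdir*."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    n_votus = params.get("n_votus", 20)
    members = params.get("members_per_votu", 3)
    genome_len = params.get("genome_len", 15_000)

    genomes, gene_table, truth = sim.generate_community(
        n_votus=n_votus,
        members_per_votu=members,
        genome_len=genome_len,
        intra_div=params.get("intra_div", 0.02),
        inter_div=params.get("inter_div", 0.15),
        frac_temperate=params.get("frac_temperate", 0.5),
        seed=seed,
        genes_per_genome=params.get("genes_per_genome", 5),
    )
    ts = sim.generate_timeseries(
        truth,
        n_dates_per_season=params.get("n_dates_per_season", 6),
        effect_multiplier=params.get("effect_multiplier", 10.0),
        noise_sigma=params.get("noise_sigma", 0.3),
        n_responsive=params.get("n_responsive", 6),
        individuals=params.get("individuals", ("A2",)),
        seed=seed + 1,
        genome_lengths={g: len(s) for g, s in genomes.items()},
    )
    hosts = sim.generate_hosts(
        genomes,
        truth,
        phage_gene_table=gene_table,
        n_hosts=params.get("n_hosts", 6),
        spacers_per_host=params.get("spacers_per_host", 2),
        shared_genes_per_pair=params.get("shared_genes_per_pair", 1),
        background_shared_genes=params.get("background_shared_genes", 0),
        seed=seed + 2,
    )
    summaries, coding, lifestyles, sources, seqs = sim.generate_screening_inputs(
        genomes, truth, n_decoys=params.get("n_decoys", 4), seed=seed + 3
    )
    pileups = sim.generate_snp_series(
        truth,
        genomes,
        n_dates=params.get("snp_dates", 8),
        sites_per_genome=params.get("sites_per_genome", 20),
        turnover_virulent=params.get("turnover_virulent", 0.3),
        turnover_temperate=params.get("turnover_temperate", 0.1),
        depth=params.get("snp_depth", 50),
        seed=seed + 4,
    )

    write_fasta(outdir / "phage_genomes.fasta", sorted(seqs.items()))
    write_tsv(outdir / "phage_genes.tsv", gene_table)
    write_tsv(
        outdir / "screening_summaries.tsv",
        pd.DataFrame([dataclasses.asdict(s) for s in summaries]),
    )
    write_tsv(
        outdir / "coding_scores.tsv",
        pd.DataFrame(
            [
                {"contig_id": cid, "code": code, "score": score}
                for cid, table in sorted(coding.items())
                for code, score in sorted(table.scores.items())
            ]
        ),
    )
    write_tsv(
        outdir / "lifestyle_inputs.tsv",
        pd.DataFrame(
            [
                {
                    "contig_id": cid,
                    "is_prophage": int(flag),
                    "episomal_label": label or "absent",
                    "source": sources[cid],
                }
                for cid, (flag, label) in sorted(lifestyles.items())
            ]
        ),
    )
    from .io_formats import write_alignment_table

    write_alignment_table(
        outdir / "phage_ani_hits.tsv", sim.all_pairs_alignment_hits(genomes)
    )
    write_tsv(outdir / "depth_profiles.tsv", ts.depth_table)
    write_tsv(outdir / "sample_metadata.tsv", ts.metadata)
    write_tsv(outdir / "feeding_bouts.tsv", ts.bouts)
    write_tsv(
        outdir / "spacers.tsv",
        pd.DataFrame(hosts.spacers, columns=["spacer_id", "prok_genome_id", "seq"]),
    )
    write_fasta(outdir / "host_genomes.fasta", sorted(hosts.genomes.items()))
    write_tsv(outdir / "host_genes.tsv", hosts.gene_table)
    write_tsv(outdir / "families.tsv", hosts.families)
    write_tsv(outdir / "defense.tsv", hosts.defense)
    prok = sim.prokaryote_abundance(truth, ts.abundance, seed=seed + 5)
    prok_ab = prok.reset_index().rename(columns={"index": "population"})
    write_tsv(outdir / "prok_abundance.tsv", prok_ab)
    write_tsv(outdir / "pileups.tsv", pileups)
    # no genome-homology input at toy scale: the spacer route carries the links
    write_alignment_table(outdir / "phage_prok_hits.tsv", [])

    # truth tables
    write_tsv(
        outdir / "truth_genomes.tsv",
        pd.DataFrame(
            [
                {
                    "genome_id": g,
                    "votu": truth.votu_of[g],
                    "lifestyle": truth.lifestyle_of[g],
                    "source": truth.source_of[g],
                }
                for g in sorted(truth.votu_of)
            ]
        ),
    )
    write_tsv(
        outdir / "truth_populations.tsv",
        pd.DataFrame(
            [
                {
                    "population": p,
                    "lifestyle": truth.pop_lifestyle[p],
                    "representative": truth.representative.get(p, ""),
                    "host": truth.host_of.get(p, ""),
                    "effect_multiplier": truth.effect_multiplier.get(p, 1.0),
                }
                for p in truth.populations
            ]
        ),
    )
    write_tsv(
        outdir / "truth_seasons.tsv",
        pd.DataFrame(
            sorted(truth.season_of_date.items()), columns=["date", "season"]
        ),
    )
    return outdir


# ---------------------------------------------------------------------------
# Stages


def stage_screen(indir: Path, outdir: Path, config: RunConfig, log: list) -> None:
    seqs = dict(read_fasta(indir / "phage_genomes.fasta"))
    summaries_df = read_tsv(indir / "screening_summaries.tsv")
    summaries = [
        scr.GeneCountSummary(
            contig_id=r.contig_id,
            viral_genes=int(r.viral_genes),
            host_genes=int(r.host_genes),
            hallmark_genes=int(r.hallmark_genes),
            length=int(r.length),
            gc=float(r.gc),
        )
        for r in summaries_df.itertuples()
    ]
    scores_df = read_tsv(indir / "coding_scores.tsv")
    coding = {
        cid: scr.CodingScoreTable(cid, dict(zip(grp["code"].astype(int), grp["score"])))
        for cid, grp in scores_df.groupby("contig_id")
    }
    ls_df = read_tsv(indir / "lifestyle_inputs.tsv")
    lifestyle_inputs = {
        r.contig_id: (
            bool(r.is_prophage),
            None if r.episomal_label == "absent" else r.episomal_label,
        )
        for r in ls_df.itertuples()
    }
    sources = dict(zip(ls_df["contig_id"], ls_df["source"]))
    gene_table = read_tsv(indir / "phage_genes.tsv")
    genes = {
        gid: [tuple(row) for row in grp[["start", "end", "strand", "category"]].itertuples(index=False)]
        for gid, grp in gene_table.groupby("genome_id")
    }
    records = scr.screen_contigs(
        summaries, coding, lifestyle_inputs, seqs, sources, genes=genes
    )
    out = pd.DataFrame(
        [
            {
                "genome_id": r.id,
                "source": r.source,
                "lifestyle": r.lifestyle,
                "is_prophage": int(r.is_prophage),
                "genetic_code": r.genetic_code,
                "length": len(r.sequence),
            }
            for r in records
        ]
    ).sort_values("genome_id")
    write_tsv(outdir / "screened_genomes.tsv", out)
    write_fasta(
        outdir / "screened_genomes.fasta",
        [(r.id, r.sequence) for r in sorted(records, key=lambda r: r.id)],
    )
    log.append(f"screen\tin={len(summaries)}\tout={len(records)}")


def stage_cluster(indir: Path, outdir: Path, config: RunConfig, log: list) -> None:
    screened = read_tsv(outdir / "screened_genomes.tsv")
    lengths = dict(zip(screened["genome_id"], screened["length"].astype(int)))
    lifestyles = dict(zip(screened["genome_id"], screened["lifestyle"]))
    sources = dict(zip(screened["genome_id"], screened["source"]))
    hits = read_alignment_table(indir / "phage_ani_hits.tsv")
    by_pair: dict[tuple[str, str], list] = {}
    for h in hits:
        if h.query_id in lengths and h.subject_id in lengths:
            by_pair.setdefault((h.query_id, h.subject_id), []).append(h)
    records = [
        votu.compute_ani_af(pair_hits, lengths[a], lengths[b], a, b)
        for (a, b), pair_hits in sorted(by_pair.items())
    ]
    clusters = votu.cluster_votus(lengths, records, config.ani_min, config.af_min)
    rows = []
    for c in clusters:
        c.lifestyle = {m: lifestyles[m] for m in c.members}
        c.source = {m: sources[m] for m in c.members}
        for m in c.members:
            rows.append(
                {
                    "votu_id": c.votu_id,
                    "member_id": m,
                    "is_representative": int(m == c.representative),
                    "source": sources[m],
                    "lifestyle": lifestyles[m],
                }
            )
    write_tsv(outdir / "votus.tsv", pd.DataFrame(rows))
    write_tsv(
        outdir / "ani.tsv",
        pd.DataFrame(
            [dataclasses.asdict(r) for r in records]
        ),
    )
    log.append(f"cluster\tin={len(lengths)}\tout={len(clusters)}")


def _votu_tables(outdir: Path):
    vt = read_tsv(outdir / "votus.tsv")
    reps = vt[vt["is_representative"] == 1]
    rep_to_votu = dict(zip(reps["member_id"], reps["votu_id"]))
    votu_lifestyle = (
        vt.groupby("votu_id")["lifestyle"].agg(lambda s: s.mode().iloc[0]).to_dict()
    )
    return vt, rep_to_votu, votu_lifestyle


def stage_abundance(indir: Path, outdir: Path, config: RunConfig, log: list) -> None:
    depth = read_tsv(indir / "depth_profiles.tsv")
    meta = read_tsv(indir / "sample_metadata.tsv").set_index("sample_id")
    screened = read_tsv(outdir / "screened_genomes.tsv")
    lengths = dict(zip(screened["genome_id"], screened["length"].astype(int)))
    _, rep_to_votu, _ = _votu_tables(outdir)
    rep_lengths = {g: lengths[g] for g in rep_to_votu if g in lengths}
    depth = depth[depth["genome_id"].isin(rep_lengths)]
    mat = ab.coverage_matrix(depth, rep_lengths, config.trim_frac)
    mat.values.index = [rep_to_votu[g] for g in mat.values.index]
    mat.metadata = meta
    write_tsv(
        outdir / "abundance.tsv",
        mat.values.reset_index().rename(columns={"index": "population"}),
    )
    hel = ab.hellinger_transform(mat)
    write_tsv(
        outdir / "hellinger.tsv",
        hel.values.reset_index().rename(columns={"index": "population"}),
    )
    log.append(f"abundance\tin={len(depth)}\tout={mat.values.shape[0]}x{mat.values.shape[1]}")


def stage_diet(indir: Path, outdir: Path, config: RunConfig, log: list) -> None:
    bouts_df = read_tsv(indir / "feeding_bouts.tsv")
    profiles = []
    for (ind, date), grp in bouts_df.groupby(["individual", "date"]):
        bouts = [
            diet.FeedingBout(ind, date, r.food_type, float(r.start_min), float(r.end_min))
            for r in grp.itertuples()
        ]
        profiles.append(diet.diet_composition(bouts))
    seasons = diet.assign_seasons(profiles)
    write_tsv(
        outdir / "diet_profiles.tsv",
        pd.DataFrame(
            [
                {"individual": p.individual, "date": p.date, "season": p.season,
                 **{t: p.proportions[t] for t in diet.FOOD_TYPES}}
                for p in profiles
            ]
        ),
    )
    write_tsv(
        outdir / "seasons.tsv",
        pd.DataFrame(
            [{"individual": k[0], "date": k[1], "season": v} for k, v in sorted(seasons.items())]
        ),
    )
    log.append(f"diet\tin={len(bouts_df)}\tout={len(profiles)}")


def stage_respond(indir: Path, outdir: Path, config: RunConfig, log: list) -> None:
    mat = read_tsv(outdir / "abundance.tsv").set_index("population")
    meta = read_tsv(indir / "sample_metadata.tsv")
    seasons_df = read_tsv(outdir / "seasons.tsv")
    season_of = {(r.individual, r.date): r.season for r in seasons_df.itertuples()}
    _, _, votu_lifestyle = _votu_tables(outdir)
    family_map = {}
    links_path = outdir / "links.tsv"
    if links_path.exists():
        links_df = read_tsv(links_path)
        fam_df = read_tsv(indir / "families.tsv")
        fam_of_prok = dict(zip(fam_df["prok_pop_id"], fam_df["family"]))
        for r in links_df.itertuples():
            family_map.setdefault(r.phage_pop_id, fam_of_prok.get(r.prok_pop_id))
    out_frames = []
    for ind, ind_meta in meta.groupby("individual"):
        sample_season = pd.Series(
            [season_of[(ind, d)] for d in ind_meta["date"]],
            index=ind_meta["sample_id"],
        )
        for lifestyle in ("virulent", "temperate"):
            pops = [p for p in mat.index if votu_lifestyle.get(p) == lifestyle]
            if not pops:
                continue
            sub = mat.loc[pops, ind_meta["sample_id"]]
            res = diet.test_diet_responsive(sub, sample_season, config.fdr_alpha)
            per_pop, _fam = diet.abundance_variation(sub, sample_season, family_map)
            res["delta"] = per_pop["delta"]
            res["host_family"] = per_pop["host_family"]
            res["individual"] = ind
            res["lifestyle"] = lifestyle
            out_frames.append(res.reset_index())
    out = pd.concat(out_frames, ignore_index=True)
    write_tsv(outdir / "response.tsv", out)
    log.append(f"respond\tin={mat.shape[0]}\tout={int(out['responsive'].sum())}")


def stage_hosts(indir: Path, outdir: Path, config: RunConfig, log: list) -> None:
    vt, _, votu_lifestyle = _votu_tables(outdir)
    pop_of_genome = dict(zip(vt["member_id"], vt["votu_id"]))
    phage_seqs = dict(read_fasta(outdir / "screened_genomes.fasta"))
    spacers_df = read_tsv(indir / "spacers.tsv")
    spacers = list(spacers_df.itertuples(index=False, name=None))
    prok_pop_of = {g: g for g in read_tsv(indir / "families.tsv")["prok_pop_id"]}
    links = hl.match_spacers(
        spacers, phage_seqs, pop_of_genome, prok_pop_of
    )
    hom_path = indir / "phage_prok_hits.tsv"
    if hom_path.exists():
        hom_hits = read_alignment_table(hom_path)
        links += hl.match_genome_homology(
            hom_hits,
            pop_of_genome,
            prok_pop_of,
            config.homology_evalue,
            config.homology_bitscore,
            config.homology_min_len,
            config.homology_min_ident,
        )
    write_tsv(
        outdir / "links.tsv",
        pd.DataFrame([dataclasses.asdict(l) for l in links]),
    )
    host_range, phage_range = hl.host_and_phage_range(links, votu_lifestyle)
    write_tsv(outdir / "host_range.tsv", host_range.reset_index())
    write_tsv(outdir / "phage_range.tsv", phage_range.reset_index())

    defense = read_tsv(indir / "defense.tsv")
    groups: dict[str, set[str]] = {"virulent": set(), "temperate": set()}
    for l in links:
        ls = votu_lifestyle.get(l.phage_pop_id)
        if ls in groups:
            groups[ls].add(l.prok_pop_id)
    burden = hl.defense_burden(defense, groups)
    write_tsv(outdir / "defense_burden.tsv", burden.reset_index())

    phage_mat = read_tsv(outdir / "abundance.tsv").set_index("population")
    prok_mat = read_tsv(indir / "prok_abundance.tsv").set_index("population")
    corr = hl.phage_host_correlation(phage_mat, prok_mat, links, votu_lifestyle)
    write_tsv(outdir / "phage_host_correlation.tsv", corr)
    log.append(f"hosts\tin={len(spacers)}\tout={len(links)}")


def stage_genes(indir: Path, outdir: Path, config: RunConfig, log: list) -> None:
    vt, _, votu_lifestyle = _votu_tables(outdir)
    pop_of_genome = dict(zip(vt["member_id"], vt["votu_id"]))
    lifestyle_of_genome = dict(zip(vt["member_id"], vt["lifestyle"]))
    phage_seqs = dict(read_fasta(outdir / "screened_genomes.fasta"))
    phage_genes = read_tsv(indir / "phage_genes.tsv")
    phage_genes = phage_genes[phage_genes["genome_id"].isin(phage_seqs)]
    host_seqs = dict(read_fasta(indir / "host_genomes.fasta"))
    host_genes = read_tsv(indir / "host_genes.tsv")

    proteins = sim.extract_proteins(
        phage_seqs, phage_genes, lifestyle_of_genome, pop_of_genome
    )
    proteins += sim.extract_proteins(
        host_seqs,
        host_genes,
        {g: "prokaryote" for g in host_seqs},
        {g: g for g in host_seqs},
    )
    categories = {
        f"{row.genome_id}_g{idx}": row.category
        for idx, row in pd.concat([phage_genes, host_genes]).iterrows()
    }
    pcs = gs.cluster_proteins(proteins, config.pc_identity, config.pc_cov_short)
    rows = []
    for pc in pcs:
        for m in pc.members:
            rows.append(
                {
                    "pc_id": pc.pc_id,
                    "protein_id": m.protein_id,
                    "origin": m.origin,
                    "genome_id": m.genome_id,
                    "population_id": m.population_id,
                    "shared": int(pc.shared),
                }
            )
    write_tsv(outdir / "pcs.tsv", pd.DataFrame(rows))
    ratios = gs.shared_pc_ratio(pcs)
    write_tsv(outdir / "shared_pc_ratio.tsv", ratios.reset_index().rename(columns={"index": "genome_id"}))

    links_df = read_tsv(outdir / "links.tsv")
    fam_df = read_tsv(indir / "families.tsv")
    family_of = dict(zip(fam_df["prok_pop_id"], fam_df["family"]))
    host_pairs = list(zip(links_df["phage_pop_id"], links_df["prok_pop_id"]))
    sharing = gs.host_vs_nonhost_sharing(pcs, host_pairs, family_of, seed=config.seed)
    write_tsv(outdir / "host_nonhost_sharing.tsv", sharing.reset_index())

    # TA screen: a PC is TA-annotated when any member gene carries the TA label
    ta_annotations = {}
    pc_lifestyles = {}
    pc_pops: dict[str, set[str]] = {}
    for pc in pcs:
        pc_lifestyles[pc.pc_id] = pc.lifestyles
        for m in pc.members:
            if categories.get(m.protein_id) == "TA":
                ta_annotations[pc.pc_id] = "TA"
            if m.origin in gs.PHAGE_ORIGINS:
                pc_pops.setdefault(pc.pc_id, set()).add(m.population_id)
    phage_mat = read_tsv(outdir / "abundance.tsv").set_index("population")
    pc_mat = ab.pc_abundance(
        {k: v for k, v in pc_pops.items()}, ab.AbundanceMatrix(phage_mat)
    )
    diet_df = read_tsv(outdir / "diet_profiles.tsv")
    meta = read_tsv(indir / "sample_metadata.tsv")
    diet_axes = (
        meta.merge(diet_df, on=["individual", "date"])
        .set_index("sample_id")[["leaf", "fruit"]]
    )
    ta = gs.screen_ta_and_correlate(ta_annotations, pc_mat.values, diet_axes, pc_lifestyles)
    write_tsv(outdir / "ta_correlations.tsv", ta)
    log.append(f"genes\tin={len(proteins)}\tout={len(pcs)}")


def stage_snps(indir: Path, outdir: Path, config: RunConfig, log: list) -> None:
    pileups = read_tsv(indir / "pileups.tsv")
    vt, rep_to_votu, votu_lifestyle = _votu_tables(outdir)
    meta = read_tsv(indir / "sample_metadata.tsv")
    mat = read_tsv(outdir / "abundance.tsv").set_index("population")
    votu_to_rep = {v: g for g, v in rep_to_votu.items()}
    coverage = mat.rename(index=votu_to_rep)
    eligible = snp.select_genomes_for_snp(
        coverage,
        {ind: list(grp["sample_id"]) for ind, grp in meta.groupby("individual")},
        config.snp_min_depth,
    )
    eligible_genomes = sorted(set().union(*eligible.values())) if eligible else []
    profiles = []
    var_rows = []
    for (gid, date), grp in pileups.groupby(["genome_id", "sample_id"]):
        if gid not in eligible_genomes:
            continue
        prof = snp.call_snps(
            grp, gid, date, config.snp_qual, config.snp_min_alt_reads, config.snp_min_alt_freq
        )
        profiles.append(prof)
        for pos, ref, alt, freq in sorted(prof.variants):
            var_rows.append({"genome_id": gid, "date": date, "pos": pos, "ref": ref, "alt": alt, "freq": freq})
    write_tsv(outdir / "snps.tsv", pd.DataFrame(var_rows))

    import datetime as _dt

    frames = []
    for lifestyle in ("virulent", "temperate"):
        sub = [
            p
            for p in profiles
            if votu_lifestyle.get(rep_to_votu.get(p.genome_id)) == lifestyle
        ]
        for p in sub:
            p.date = _dt.date.fromisoformat(p.date) if isinstance(p.date, str) else p.date
        if sub:
            frames.append(snp.similarity_series(sub, lifestyle))
    series = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    write_tsv(outdir / "snp_similarity.tsv", series)
    if not series.empty:
        fits, comparison = snp.similarity_vs_lag(series)
        write_tsv(outdir / "snp_fits.tsv", fits.reset_index())
        write_tsv(outdir / "snp_lag_comparison.tsv", comparison)
    log.append(f"snps\tin={len(pileups)}\tout={len(var_rows)}")


def stage_stats(indir: Path, outdir: Path, config: RunConfig, log: list) -> None:
    hel = read_tsv(outdir / "hellinger.tsv").set_index("population")
    meta = read_tsv(indir / "sample_metadata.tsv").set_index("sample_id")
    seasons_df = read_tsv(outdir / "seasons.tsv")
    season_of = {(r.individual, r.date): r.season for r in seasons_df.itertuples()}
    groups = [
        season_of[(meta.loc[s, "individual"], meta.loc[s, "date"])] for s in hel.columns
    ]
    dist = stats.bray_curtis(hel)
    coords, eigvals = stats.pcoa(dist)
    write_tsv(outdir / "pcoa.tsv", coords.reset_index().rename(columns={"index": "sample_id"}))
    res = stats.permanova(dist, groups, config.n_perm, seed=config.seed)
    prok_mat = read_tsv(indir / "prok_abundance.tsv").set_index("population")
    prok_hel = ab.hellinger_transform(ab.AbundanceMatrix(prok_mat[hel.columns]))
    mantel_res = stats.mantel(
        dist, stats.bray_curtis(prok_hel.values), config.n_perm, seed=config.seed
    )
    write_tsv(
        outdir / "stats_summary.tsv",
        pd.DataFrame(
            [
                {"test": "permanova_season", **res},
                {"test": "mantel_phage_vs_prok", **mantel_res},
            ]
        ),
    )
    log.append(f"stats\tin={hel.shape[1]}\tout=2")


STAGES = {
    "screen": stage_screen,
    "cluster": stage_cluster,
    "abundance": stage_abundance,
    "diet": stage_diet,
    "hosts": stage_hosts,
    "genes": stage_genes,
    "respond": stage_respond,
    "snps": stage_snps,
    "stats": stage_stats,
}


def run_pipeline(config: RunConfig, manifest: dict, outdir: str | Path) -> dict:
    """Run the full pipeline.

    *manifest* either contains ``{"synthetic": {...params...}}`` to
    generate inputs with planted truth, or ``{"indir": path}`` pointing
    at a directory with all stage inputs.  Outputs (one tabular file
    per result, plus a run log with seed, thresholds and per-stage
    record counts) land in *outdir*.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if "synthetic" in manifest:
        indir = simulate_inputs(outdir / "inputs", config, **(manifest["synthetic"] or {}))
    elif "indir" in manifest:
        indir = Path(manifest["indir"])
    else:
        raise ManifestError("manifest must provide 'synthetic' params or 'indir'")
    check_manifest(indir)
    log: list[str] = [
        f"phageome\t{__version__}",
        f"seed\t{config.seed}",
        "config\t" + ",".join(
            f"{f.name}={getattr(config, f.name)}" for f in dataclasses.fields(config)
        ),
    ]
    for stage in STAGE_ORDER:
        STAGES[stage](indir, outdir, config, log)
    (outdir / "log.txt").write_text("\n".join(log) + "\n")
    return {"outdir": outdir, "log": log}
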