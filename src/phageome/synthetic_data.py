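"""Synthetic gut-phageome inputs with planted ground truth.

Every pipeline stage is testable offline against data generated here: a
phage community with known population (vOTU) structure and lifestyles,
prokaryotic hosts carrying CRISPR spacers copied from their phages and
horizontally shared genes, a two-season abundance time series with
planted diet-responsive populations and matching feeding-bout records,
and per-site variant series with lifestyle-dependent turnover.

The substitution model is i.i.d. uniform replacement over the three
alternative bases with no indels, which makes the expected ANI between
two members mutated at rate ``d`` from one ancestor analytically
``(1-d)^2 + d^2/3``.  Abundance noise is multiplicative lognormal, and
per-base read depth is Poisson around the population's abundance.  All
generators are pure functions of their arguments and the seed.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._codes import reverse_complement, translate
from .gene_sharing import ProteinRecord
from .io_formats import AlignmentHit
from .screening import CodingScoreTable, GeneCountSummary

BASES = np.frombuffer(b"ACGT", dtype="S1")
SENSE_AA = "ACDEFGHIKLMNPQRSTVWY"

FAMILY_POOL = (
    "Lachnospiraceae",
    "Bacteroidaceae",
    "Oscillospiraceae",
    "Rikenellaceae",
    "Ruminococcaceae",
    "Muribaculaceae",
)


class ConfigError(ValueError):
    pass


@dataclass
class SimTruth:
    """Planted ground truth, queryable by ID."""

    votu_of: dict[str, str] = field(default_factory=dict)  # genome -> vOTU
    lifestyle_of: dict[str, str] = field(default_factory=dict)  # genome -> lifestyle
    source_of: dict[str, str] = field(default_factory=dict)  # genome -> VM | MM
    pop_lifestyle: dict[str, str] = field(default_factory=dict)  # vOTU -> lifestyle
    representative: dict[str, str] = field(default_factory=dict)  # vOTU -> genome
    host_of: dict[str, str] = field(default_factory=dict)  # vOTU -> prokaryote pop
    family_of: dict[str, str] = field(default_factory=dict)  # prokaryote pop -> family
    spacers: list[tuple[str, str, str]] = field(default_factory=list)  # (spacer, host, vOTU)
    shared_genes: list[tuple[str, str]] = field(default_factory=list)  # (vOTU, host) host-specific
    background_shared: list[tuple[str, str]] = field(default_factory=list)
    effect_multiplier: dict[str, float] = field(default_factory=dict)  # vOTU -> HL/HF ratio
    season_of_date: dict[str, str] = field(default_factory=dict)  # date -> HF | HL
    variants: dict[tuple[str, str], set] = field(default_factory=dict)  # (genome, date) -> {(pos, alt)}

    @property
    def populations(self) -> list[str]:
        return sorted(self.pop_lifestyle)

    @property
    def responsive(self) -> set[str]:
        return {p for p, m in self.effect_multiplier.items() if m != 1.0}


def minimal_truth(n_pops: int, frac_temperate: float = 0.5) -> SimTruth:
    """A sequence-free truth skeleton (populations and lifestyles only).

    Useful for abundance-level simulations that do not need genomes:
    population IDs double as their own representatives.
    """
    truth = SimTruth()
    n_temperate = round(frac_temperate * n_pops)
    for i in range(n_pops):
        pop = f"sim_vOTU_{i + 1:03d}"
        truth.pop_lifestyle[pop] = "temperate" if i < n_temperate else "virulent"
        truth.representative[pop] = pop
    return truth


def _random_genome(rng: np.random.Generator, length: int) -> np.ndarray:
    return BASES[rng.integers(0, 4, size=length)]


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float) -> np.ndarray:
    """i.i.d. substitution at *rate*; each hit base moves to one of the 3 others."""
    out = seq.copy()
    hits = np.flatnonzero(rng.random(seq.size) < rate)
    if hits.size:
        shift = rng.integers(1, 4, size=hits.size)
        idx = np.searchsorted(BASES, out[hits])
        out[hits] = BASES[(idx + shift) % 4]
    return out


def _stop_free_gene(rng: np.random.Generator, n_codons: int, code_aa: str = SENSE_AA) -> str:
    """A random open reading frame free of stop codons under code 11."""
    codons_by_aa = {}
    for b1 in "ACGT":
        for b2 in "ACGT":
            for b3 in "ACGT":
                codon = b1 + b2 + b3
                aa = translate(codon, 11)
                if aa != "*":
                    codons_by_aa.setdefault(aa, []).append(codon)
    all_codons = [c for aas in codons_by_aa.values() for c in aas]
    picks = rng.integers(0, len(all_codons), size=n_codons)
    return "".join(all_codons[i] for i in picks)


def _seq_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode()


GENE_CATEGORIES = ("hallmark", "viral", "viral", "host", "TA")


def generate_community(
    n_votus: int = 20,
    members_per_votu: int = 3,
    genome_len: int = 15_000,
    intra_div: float = 0.02,
    inter_div: float = 0.15,
    frac_temperate: float = 0.5,
    seed: int = 0,
    genes_per_genome: int = 5,
    gene_len: int = 300,
) -> tuple[dict[str, str], pd.DataFrame, SimTruth]:
    """Generate a phage community with known population structure.

    Members of one population derive from a shared ancestor by i.i.d.
    substitution at rate *intra_div*; ancestors are mutually independent
    random sequences (pairwise divergence ~75%, far above *inter_div*).
    Gene coordinates are tiled identically across members, with
    stop-free coding sequence planted in the ancestor so translated
    proteins are well-formed.  Lifestyle is assigned per population:
    the first ``round(frac_temperate * n_votus)`` populations are
    temperate, the rest virulent.
    """
    if not intra_div < 0.05 < inter_div:
        raise ConfigError(
            f"need intra_div < 0.05 < inter_div, got {intra_div} / {inter_div}"
        )
    if genome_len < 10_000:
        raise ConfigError("genome_len must be >= 10 kb (minimum contig size)")
    rng = np.random.default_rng(seed)
    genomes: dict[str, str] = {}
    gene_rows = []
    truth = SimTruth()
    n_temperate = round(frac_temperate * n_votus)
    gene_gap = max(gene_len, (genome_len - 200) // max(genes_per_genome, 1) )
    for v in range(n_votus):
        votu = f"sim_vOTU_{v + 1:03d}"
        lifestyle = "temperate" if v < n_temperate else "virulent"
        truth.pop_lifestyle[votu] = lifestyle
        ancestor = _random_genome(rng, genome_len)
        # plant stop-free ORFs at fixed coordinates
        coords = []
        for g in range(genes_per_genome):
            start = 100 + g * gene_gap  # 0-based
            end = start + gene_len
            if end > genome_len:
                break
            orf = _stop_free_gene(rng, gene_len // 3)
            ancestor[start:end] = np.frombuffer(orf.encode(), dtype="S1")
            strand = "-" if g % 3 == 2 else "+"
            coords.append((start + 1, end, strand, GENE_CATEGORIES[g % len(GENE_CATEGORIES)]))
        for m in range(members_per_votu):
            gid = f"{votu}_m{m + 1}"
            member = _mutate(rng, ancestor, intra_div) if intra_div > 0 else ancestor.copy()
            genomes[gid] = _seq_str(member)
            truth.votu_of[gid] = votu
            truth.lifestyle_of[gid] = lifestyle
            truth.source_of[gid] = "VM" if m % 2 == 0 else "MM"
            if m == 0:
                truth.representative[votu] = gid
            for start, end, strand, category in coords:
                gene_rows.append((gid, start, end, strand, category, float(rng.uniform(50, 150))))
    gene_table = pd.DataFrame(
        gene_rows,
        columns=["genome_id", "start", "end", "strand", "category", "coding_score"],
    )
    return genomes, gene_table, truth


def pairwise_identity(a: str, b: str) -> float:
    """Percent identity of two equal-length ungapped genomes (brute force)."""
    x = np.frombuffer(a.encode(), dtype="S1")
    y = np.frombuffer(b.encode(), dtype="S1")
    n = min(x.size, y.size)
    if n == 0:
        return 0.0
    return 100.0 * float((x[:n] == y[:n]).mean())


def all_pairs_alignment_hits(genomes: Mapping[str, str]) -> list[AlignmentHit]:
    """Full-length alignment hits for every genome pair.

    The substitution-only model aligns genomes end to end without gaps,
    so each ordered pair yields one fragment covering both genomes with
    identity equal to the ungapped percent identity.
    """
    ids = sorted(genomes)
    hits = []
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            ident = pairwise_identity(genomes[a], genomes[b])
            L = min(len(genomes[a]), len(genomes[b]))
            n_mismatch = round(L * (100.0 - ident) / 100.0)
            hits.append(
                AlignmentHit(
                    query_id=a,
                    subject_id=b,
                    pct_identity=ident,
                    aln_length=L,
                    mismatches=n_mismatch,
                    gap_opens=0,
                    q_start=1,
                    q_end=L,
                    s_start=1,
                    s_end=L,
                    evalue=0.0,
                    bit_score=2.0 * L * ident / 100.0,
                )
            )
    return hits


# ---------------------------------------------------------------------------
# Hosts


@dataclass
class HostData:
    genomes: dict[str, str]
    spacers: list[tuple[str, str, str]]  # (spacer_id, host_genome_id, sequence)
    families: pd.DataFrame  # prok_pop_id, family
    defense: pd.DataFrame  # prok_genome_id, system_name, count
    gene_table: pd.DataFrame  # genome_id, start, end, strand, category, coding_score


def generate_hosts(
    genomes: Mapping[str, str],
    truth: SimTruth,
    phage_gene_table: pd.DataFrame | None = None,
    n_hosts: int = 6,
    spacers_per_host: int = 2,
    shared_genes_per_pair: int = 1,
    background_shared_genes: int = 0,
    seed: int = 0,
    host_len: int = 30_000,
    genes_per_host: int = 6,
    gene_len: int = 300,
    spacer_revcomp_prob: float = 0.5,
    defense_mean_virulent: float = 4.0,
    defense_mean_temperate: float = 1.5,
) -> HostData:
    """Generate prokaryotic host genomes linked to the phage community.

    Each phage population is assigned one host (round-robin).  Spacers
    are verbatim 25-45 nt substrings of a member genome of an assigned
    population, inserted in forward or reverse-complement orientation.
    Host-specific shared genes are copied verbatim from the phage
    representative into the host genome (the HGT plant); background
    shared genes are copied into *random* hosts irrespective of the
    host assignment, so sharing carries no host signal.  Hosts assigned
    at least one virulent population receive a higher mean anti-phage
    defense burden.  Host families come from a fixed pool, with the
    hosts of planted responsive virulent / temperate populations
    labelled Lachnospiraceae / Bacteroidaceae respectively.
    """
    rng = np.random.default_rng(seed)
    pops = truth.populations
    if not pops:
        raise ConfigError("community truth has no populations")
    hosts = [f"prok_{h + 1:02d}" for h in range(n_hosts)]
    for i, pop in enumerate(pops):
        truth.host_of[pop] = hosts[i % n_hosts]
    assigned: dict[str, list[str]] = {h: [] for h in hosts}
    for pop, h in truth.host_of.items():
        assigned[h].append(pop)

    host_genomes: dict[str, str] = {}
    gene_rows = []
    spacers = []
    spacer_n = 0
    for h in hosts:
        arr = _random_genome(rng, host_len)
        # own stop-free genes at the front
        for g in range(genes_per_host):
            start = 100 + g * (gene_len + 60)
            end = start + gene_len
            orf = _stop_free_gene(rng, gene_len // 3)
            arr[start:end] = np.frombuffer(orf.encode(), dtype="S1")
            gene_rows.append((h, start + 1, end, "+", "host", float(rng.uniform(50, 150))))
        host_genomes[h] = _seq_str(arr)

    # spacers: exact copies from member genomes of assigned populations
    for h in hosts:
        pool = sorted(assigned[h])
        if not pool:
            continue
        for k in range(spacers_per_host):
            pop = pool[k % len(pool)]
            members = sorted(g for g, v in truth.votu_of.items() if v == pop)
            gid = members[int(rng.integers(0, len(members)))]
            seq = genomes[gid]
            length = int(rng.integers(25, 46))
            if len(seq) <= length:
                raise ConfigError("phage genome shorter than requested spacer")
            start = int(rng.integers(0, len(seq) - length))
            spacer = seq[start : start + length]
            if rng.random() < spacer_revcomp_prob:
                spacer = reverse_complement(spacer)
            spacer_n += 1
            sid = f"spacer_{spacer_n:03d}"
            spacers.append((sid, h, spacer))
            truth.spacers.append((sid, h, pop))

    # shared genes (HGT): copy an annotated phage gene into the host genome,
    # verbatim at the nucleotide level, so the same protein sits on both sides
    def _copy_gene(pop: str, host: str, record: list):
        if phage_gene_table is None or phage_gene_table.empty:
            raise ConfigError("shared genes requested but no phage gene table given")
        rep = truth.representative[pop]
        rep_genes = phage_gene_table[phage_gene_table["genome_id"] == rep]
        if rep_genes.empty:
            raise ConfigError(f"representative {rep} has no annotated genes")
        row = rep_genes.iloc[int(rng.integers(0, len(rep_genes)))]
        fragment = genomes[rep][int(row["start"]) - 1 : int(row["end"])]
        old = host_genomes[host]
        gene_rows.append(
            (host, len(old) + 1, len(old) + len(fragment), row["strand"], "shared", 100.0)
        )
        host_genomes[host] = old + fragment
        record.append((pop, host))

    for pop in pops:
        for _ in range(shared_genes_per_pair):
            _copy_gene(pop, truth.host_of[pop], truth.shared_genes)
    for _ in range(background_shared_genes):
        pop = pops[int(rng.integers(0, len(pops)))]
        host = hosts[int(rng.integers(0, len(hosts)))]
        _copy_gene(pop, host, truth.background_shared)

    # families
    responsive_vir = sorted(
        p for p in truth.responsive if truth.pop_lifestyle[p] == "virulent"
    )
    responsive_tem = sorted(
        p for p in truth.responsive if truth.pop_lifestyle[p] == "temperate"
    )
    fam_cycle = [f for f in FAMILY_POOL if f not in ("Lachnospiraceae", "Bacteroidaceae")]
    for i, h in enumerate(hosts):
        if any(truth.host_of[p] == h for p in responsive_vir):
            truth.family_of[h] = "Lachnospiraceae"
        elif any(truth.host_of[p] == h for p in responsive_tem):
            truth.family_of[h] = "Bacteroidaceae"
        else:
            truth.family_of[h] = fam_cycle[i % len(fam_cycle)]
    families = pd.DataFrame(
        sorted(truth.family_of.items()), columns=["prok_pop_id", "family"]
    )

    # anti-phage defense systems: heavier burden on hosts of virulent phages
    defense_rows = []
    for h in hosts:
        virulent_assigned = any(
            truth.pop_lifestyle[p] == "virulent" for p in assigned[h]
        )
        mean = defense_mean_virulent if virulent_assigned else defense_mean_temperate
        for system in ("RM", "CRISPR-Cas", "AbiE"):
            defense_rows.append((h, system, int(rng.poisson(mean / 3.0))))
    defense = pd.DataFrame(defense_rows, columns=["prok_genome_id", "system_name", "count"])

    gene_table = pd.DataFrame(
        gene_rows, columns=["genome_id", "start", "end", "strand", "category", "coding_score"]
    )
    return HostData(host_genomes, spacers, families, defense, gene_table)


# ---------------------------------------------------------------------------
# Abundance time series and feeding bouts


@dataclass
class TimeSeriesData:
    abundance: pd.DataFrame  # populations x samples (planted expected coverage)
    prok_abundance: pd.DataFrame  # prokaryote pops x samples (empty if no hosts)
    depth_table: pd.DataFrame  # genome_id, sample_id, position, depth (may be empty)
    bouts: pd.DataFrame  # individual, date, food_type, start_min, end_min
    metadata: pd.DataFrame  # sample_id, individual, date, season


def _season_dates(n_per_season: int) -> tuple[list[str], list[str]]:
    hf0 = datetime.date(2018, 1, 1)
    hl0 = datetime.date(2018, 7, 1)
    hf = [(hf0 + datetime.timedelta(days=7 * i)).isoformat() for i in range(n_per_season)]
    hl = [(hl0 + datetime.timedelta(days=7 * i)).isoformat() for i in range(n_per_season)]
    return hf, hl


def generate_timeseries(
    truth: SimTruth,
    n_dates_per_season: int = 6,
    base_mu: float = 3.0,
    base_sigma: float = 0.7,
    effect_multiplier: float = 10.0,
    noise_sigma: float = 0.3,
    n_responsive: int = 6,
    individuals: Sequence[str] = ("A2",),
    seed: int = 0,
    genome_lengths: Mapping[str, int] | None = None,
    make_depth: bool = True,
) -> TimeSeriesData:
    """Two-season abundance series with planted responsive populations.

    Population base abundance is lognormal(mu, sigma); in high-leaf
    (HL) season a responsive population's abundance is multiplied by
    its planted effect (virulent responders go up by
    *effect_multiplier*, temperate responders down by its inverse,
    mirroring the directionality of interest); all samples get
    multiplicative lognormal noise of scale *noise_sigma*.  Feeding
    bouts are drawn so that fruit occupies > 70% of feeding time on HF
    dates and leaf > 70% on HL dates.  With *make_depth*, per-base
    depths of each population representative are Poisson around the
    sample abundance (requires *genome_lengths*).
    """
    import warnings as _warnings

    if n_dates_per_season < 3:
        _warnings.warn("fewer than 3 dates per season: tests will be under-powered")
    rng = np.random.default_rng(seed)
    pops = truth.populations
    hf_dates, hl_dates = _season_dates(n_dates_per_season)
    for d in hf_dates:
        truth.season_of_date[d] = "HF"
    for d in hl_dates:
        truth.season_of_date[d] = "HL"

    # plant effects: first responders among virulent go up in HL, temperate down
    if not truth.effect_multiplier:
        vir = [p for p in pops if truth.pop_lifestyle[p] == "virulent"]
        tem = [p for p in pops if truth.pop_lifestyle[p] == "temperate"]
        n_vir = min(len(vir), (n_responsive + 1) // 2)
        n_tem = min(len(tem), n_responsive - n_vir)
        for p in pops:
            truth.effect_multiplier[p] = 1.0
        for p in vir[:n_vir]:
            truth.effect_multiplier[p] = effect_multiplier
        for p in tem[:n_tem]:
            truth.effect_multiplier[p] = 1.0 / effect_multiplier

    samples = []
    for ind in individuals:
        for d in hf_dates + hl_dates:
            samples.append((f"{ind}_{d}", ind, d, truth.season_of_date[d]))
    metadata = pd.DataFrame(samples, columns=["sample_id", "individual", "date", "season"])

    base = {
        (p, ind): float(np.exp(rng.normal(base_mu, base_sigma)))
        for p in pops
        for ind in individuals
    }
    abundance = pd.DataFrame(0.0, index=pops, columns=metadata["sample_id"])
    for _, row in metadata.iterrows():
        for p in pops:
            mult = truth.effect_multiplier.get(p, 1.0) if row["season"] == "HL" else 1.0
            noise = float(np.exp(rng.normal(0.0, noise_sigma)))
            abundance.loc[p, row["sample_id"]] = base[(p, row["individual"])] * mult * noise

    # prokaryote abundance follows the phage assignments when already known
    prok = (
        prokaryote_abundance(truth, abundance, seed=seed + 101)
        if truth.host_of
        else pd.DataFrame()
    )

    # per-base depth profiles for representatives
    depth_rows: list[pd.DataFrame] = []
    if make_depth:
        if genome_lengths is None:
            raise ConfigError("make_depth=True requires genome_lengths")
        for p in pops:
            rep = truth.representative.get(p, p)
            L = genome_lengths[rep]
            for s in abundance.columns:
                depths = rng.poisson(abundance.loc[p, s], size=L)
                depth_rows.append(
                    pd.DataFrame(
                        {
                            "genome_id": rep,
                            "sample_id": s,
                            "position": np.arange(1, L + 1),
                            "depth": depths,
                        }
                    )
                )
    depth_table = (
        pd.concat(depth_rows, ignore_index=True)
        if depth_rows
        else pd.DataFrame(columns=["genome_id", "sample_id", "position", "depth"])
    )

    bouts = _feeding_bouts(rng, metadata)
    return TimeSeriesData(abundance, prok, depth_table, bouts, metadata)


def prokaryote_abundance(
    truth: SimTruth,
    phage_abundance: pd.DataFrame,
    seed: int = 0,
    jitter_sigma: float = 0.1,
) -> pd.DataFrame:
    """Host abundance tracking the summed abundance of its assigned phages.

    Emulates tight phage-host covariation (the piggyback-the-winner
    regime): each prokaryote population's abundance is the sum over its
    assigned phage populations times small multiplicative lognormal
    noise, giving planted phage-host Pearson correlations near 1.
    """
    if not truth.host_of:
        raise ConfigError("no host assignments in truth")
    rng = np.random.default_rng(seed)
    hosts = sorted(set(truth.host_of.values()))
    prok = pd.DataFrame(0.0, index=hosts, columns=phage_abundance.columns)
    for h in hosts:
        its = [p for p, hh in truth.host_of.items() if hh == h]
        series = phage_abundance.loc[its].sum(axis=0)
        jitter = np.exp(rng.normal(0.0, jitter_sigma, size=len(series)))
        prok.loc[h] = series.to_numpy() * jitter
    return prok


def _feeding_bouts(rng: np.random.Generator, metadata: pd.DataFrame) -> pd.DataFrame:
    """Full-day bout records whose dominant food matches the season."""
    rows = []
    for _, row in metadata.iterrows():
        dominant = "fruit" if row["season"] == "HF" else "leaf"
        secondary = "leaf" if dominant == "fruit" else "fruit"
        dom_frac = float(rng.uniform(0.72, 0.88))
        sec_frac = float(rng.uniform(0.05, 0.9)) * (1 - dom_frac) * 0.6
        flower_frac = (1 - dom_frac - sec_frac) * float(rng.uniform(0.3, 0.7))
        other_frac = 1 - dom_frac - sec_frac - flower_frac
        total = float(rng.uniform(240, 360))
        t = 480.0
        for food, frac in (
            (dominant, dom_frac),
            (secondary, sec_frac),
            ("flower", flower_frac),
            ("other", other_frac),
        ):
            dur = total * frac
            if dur <= 0.5:
                continue
            # split each food's time into two bouts to look like scans
            for part in (0.6, 0.4):
                d = dur * part
                rows.append((row["individual"], row["date"], food, round(t, 2), round(t + d, 2)))
                t += d + float(rng.uniform(3, 15))
    return pd.DataFrame(rows, columns=["individual", "date", "food_type", "start_min", "end_min"])


# ---------------------------------------------------------------------------
# SNP time series


def generate_snp_series(
    truth: SimTruth,
    genomes: Mapping[str, str],
    n_dates: int = 10,
    sites_per_genome: int = 20,
    turnover_virulent: float = 0.3,
    turnover_temperate: float = 0.1,
    depth: int = 50,
    seed: int = 0,
    populations: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-site pileups over consecutive dates with geometric SNP loss.

    Each population representative starts with *sites_per_genome*
    variant sites.  From one date to the next, every variant survives
    with probability ``1 - turnover`` for its lifestyle and lost
    variants are replaced at fresh positions, keeping the site count
    constant.  Pileups encode each variant with an alternative-read
    count derived from a frequency in [0.1, 0.5] (always >= 4 reads at
    the default 50x depth) and base quality above the calling
    threshold.  Truth records the variant set per genome and date.
    """
    if depth < 10:
        raise ConfigError("depth must be >= 10 (genome-selection rule)")
    if turnover_virulent < turnover_temperate:
        raise ConfigError("turnover_virulent must be >= turnover_temperate")
    rng = np.random.default_rng(seed)
    base_date = datetime.date(2018, 3, 1)
    dates = [(base_date + datetime.timedelta(days=d)).isoformat() for d in range(n_dates)]
    pops = list(populations) if populations is not None else truth.populations
    rows = []
    for pop in pops:
        rep = truth.representative[pop]
        seq = genomes[rep]
        L = len(seq)
        rho = (
            turnover_virulent
            if truth.pop_lifestyle[pop] == "virulent"
            else turnover_temperate
        )
        positions = rng.choice(np.arange(1, L + 1), size=sites_per_genome, replace=False)
        current: set[tuple[int, str]] = set()
        for pos in positions:
            ref = seq[pos - 1]
            alt = _other_base(rng, ref)
            current.add((int(pos), alt))
        for date in dates:
            truth.variants[(rep, date)] = set(current)
            for pos, alt in sorted(current):
                ref = seq[pos - 1]
                freq = float(rng.uniform(0.1, 0.5))
                alt_count = max(4, int(round(freq * depth)))
                rows.append((rep, date, pos, ref, alt, alt_count, 37.0))
                rows.append((rep, date, pos, ref, ref, depth - alt_count, 37.0))
            # evolve to the next date (sorted iteration: rng draws must not
            # depend on set order, which varies with hash randomization)
            survivors = {v for v in sorted(current) if rng.random() > rho}
            lost = len(current) - len(survivors)
            occupied = {p for p, _ in survivors}
            while lost > 0:
                pos = int(rng.integers(1, L + 1))
                if pos in occupied:
                    continue
                alt = _other_base(rng, seq[pos - 1])
                survivors.add((pos, alt))
                occupied.add(pos)
                lost -= 1
            current = survivors
    return pd.DataFrame(
        rows,
        columns=["genome_id", "sample_id", "position", "ref_base", "base", "count", "mean_qual"],
    )


def _other_base(rng: np.random.Generator, ref: str) -> str:
    choices = [b for b in "ACGT" if b != ref]
    return choices[int(rng.integers(0, 3))]


# ---------------------------------------------------------------------------
# Screening inputs and protein extraction


def generate_screening_inputs(
    genomes: Mapping[str, str],
    truth: SimTruth,
    n_decoys: int = 4,
    seed: int = 0,
) -> tuple[
    list[GeneCountSummary],
    dict[str, CodingScoreTable],
    dict[str, tuple[bool, str | None]],
    dict[str, str],
    dict[str, str],
]:
    """Annotation summaries that let the screening stage run on the
    synthetic community.

    True phage contigs get >= 1 viral gene so the candidate filter
    keeps them; *n_decoys* non-phage contigs (no viral gene, host genes
    present, few hallmarks) are appended and must be screened out.
    The first member of each temperate population is marked as a
    prophage; other temperate members carry an episomal temperate
    label.  Returns (summaries, coding scores, lifestyle inputs,
    sources, sequences-including-decoys).
    """
    rng = np.random.default_rng(seed)
    summaries = []
    coding: dict[str, CodingScoreTable] = {}
    lifestyle_inputs: dict[str, tuple[bool, str | None]] = {}
    sources: dict[str, str] = {}
    seqs: dict[str, str] = {}
    for gid, seq in sorted(genomes.items()):
        gc = 100.0 * (seq.count("G") + seq.count("C")) / len(seq)
        summaries.append(
            GeneCountSummary(
                contig_id=gid,
                viral_genes=int(rng.integers(2, 7)),
                host_genes=int(rng.integers(0, 3)),
                hallmark_genes=int(rng.integers(1, 4)),
                length=len(seq),
                gc=gc,
            )
        )
        coding[gid] = CodingScoreTable(gid, {11: 100.0})
        lifestyle = truth.lifestyle_of[gid]
        is_prophage = lifestyle == "temperate" and gid.endswith("_m1")
        lifestyle_inputs[gid] = (is_prophage, None if is_prophage else lifestyle)
        sources[gid] = truth.source_of[gid]
        seqs[gid] = seq
    for d in range(n_decoys):
        did = f"decoy_{d + 1:02d}"
        seq = _seq_str(_random_genome(rng, 12_000))
        summaries.append(
            GeneCountSummary(
                contig_id=did,
                viral_genes=0,
                host_genes=int(rng.integers(1, 6)),
                hallmark_genes=int(rng.integers(0, 3)),
                length=len(seq),
                gc=50.0,
            )
        )
        coding[did] = CodingScoreTable(did, {11: 100.0})
        lifestyle_inputs[did] = (False, "virulent")
        sources[did] = "MM"
        seqs[did] = seq
    return summaries, coding, lifestyle_inputs, sources, seqs


def extract_proteins(
    genomes: Mapping[str, str],
    gene_table: pd.DataFrame,
    origin_of_genome: Mapping[str, str],
    pop_of_genome: Mapping[str, str],
    code_of_genome: Mapping[str, int] | None = None,
) -> list[ProteinRecord]:
    """Translate planted genes into protein records for clustering.

    Substitutions in member genomes occasionally create stop codons
    inside a planted ORF; since these sequences are synthetic stand-ins
    rather than real ORFs, internal stops are replaced by alanine so
    the amino-acid alphabet stays valid while near-identity between
    members is preserved.
    """
    code_of_genome = code_of_genome or {}
    proteins = []
    for idx, row in gene_table.iterrows():
        gid = row["genome_id"]
        seq = genomes[gid][int(row["start"]) - 1 : int(row["end"])]
        if row["strand"] == "-":
            seq = reverse_complement(seq)
        aa = translate(seq, code_of_genome.get(gid, 11)).replace("*", "A").replace("X", "A")
        proteins.append(
            ProteinRecord(
                protein_id=f"{gid}_g{idx}",
                seq=aa,
                origin=origin_of_genome[gid],
                genome_id=gid,
                population_id=pop_of_genome[gid],
            )
        )
    return proteins
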