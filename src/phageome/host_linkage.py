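"""Phage-host linkage via CRISPR spacers and genome homology, and the
interaction statistics built on the links: host range, phage range,
phage-host abundance correlation, and anti-phage defense burden.

A spacer links a prokaryote to a phage only on an exact, full-length,
zero-mismatch match (either strand).  A genome-homology link requires
all four of: E-value <= 1e-3, bit score >= 50, alignment >= 1 kb and
identity >= 96%.  Genome-level evidence is aggregated to the population
level by the union rule: a population pair is linked when any member
genome pair is.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from ._codes import reverse_complement
from .io_formats import AlignmentHit
from .stats_core import bh_adjust


@dataclass(frozen=True)
class HostLink:
    phage_pop_id: str
    prok_pop_id: str
    evidence: str  # "spacer" | "homology"
    detail: str = ""


def match_spacers(
    spacers: Sequence[tuple[str, str, str]],  # (spacer_id, prok_genome_id, sequence)
    phage_genomes: Mapping[str, str],
    phage_pop_of: Mapping[str, str],
    prok_pop_of: Mapping[str, str],
    min_length: int = 20,
) -> list[HostLink]:
    """Link prokaryote populations to phage populations by exact spacer hits.

    A link requires the whole spacer (>= *min_length* nt, ACGT only) to
    occur with zero mismatches in a phage genome, on either strand.
    """
    links: dict[tuple[str, str], str] = {}
    for spacer_id, prok_genome, seq in spacers:
        seq = seq.upper()
        if set(seq) - set("ACGT"):
            warnings.warn(f"spacer {spacer_id} skipped: non-ACGT symbols")
            continue
        if len(seq) < min_length:
            warnings.warn(f"spacer {spacer_id} skipped: shorter than {min_length} nt")
            continue
        rc = reverse_complement(seq)
        for genome_id, genome_seq in phage_genomes.items():
            if seq in genome_seq or rc in genome_seq:
                key = (phage_pop_of[genome_id], prok_pop_of[prok_genome])
                links.setdefault(key, f"spacer={spacer_id},genome={genome_id}")
    return [
        HostLink(phage, prok, "spacer", detail)
        for (phage, prok), detail in sorted(links.items())
    ]


def match_genome_homology(
    hits: Sequence[AlignmentHit],
    phage_pop_of: Mapping[str, str],
    prok_pop_of: Mapping[str, str],
    max_evalue: float = 1e-3,
    min_bitscore: float = 50.0,
    min_length: int = 1000,
    min_identity: float = 96.0,
) -> list[HostLink]:
    """Link populations by phage-vs-prokaryote genome alignment.

    Hits are oriented phage = query.  All four thresholds are inclusive
    at the boundary.
    """
    links: dict[tuple[str, str], str] = {}
    for h in hits:
        if (
            h.evalue <= max_evalue
            and h.bit_score >= min_bitscore
            and h.aln_length >= min_length
            and h.pct_identity >= min_identity
        ):
            key = (phage_pop_of[h.query_id], prok_pop_of[h.subject_id])
            links.setdefault(key, f"{h.query_id}~{h.subject_id}:{h.aln_length}bp@{h.pct_identity}%")
    return [
        HostLink(phage, prok, "homology", detail)
        for (phage, prok), detail in sorted(links.items())
    ]


def host_and_phage_range(
    links: Iterable[HostLink],
    lifestyle_of_pop: Mapping[str, str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Distinct-partner counts per phage population and per prokaryote.

    Host range = number of prokaryote populations linked to a phage
    population; phage range = number of phage populations linked to a
    prokaryote population, split by phage lifestyle.  A prokaryote
    linked to both lifestyles appears in both lifestyle groups.
    """
    pairs = {(l.phage_pop_id, l.prok_pop_id) for l in links}
    if not pairs:
        empty_h = pd.DataFrame(columns=["lifestyle", "host_range"])
        empty_p = pd.DataFrame(columns=["lifestyle", "phage_range"])
        return empty_h, empty_p
    df = pd.DataFrame(sorted(pairs), columns=["phage_pop", "prok_pop"])
    df["lifestyle"] = df["phage_pop"].map(lifestyle_of_pop)
    host_range = (
        df.groupby(["phage_pop", "lifestyle"])["prok_pop"].nunique().rename("host_range").reset_index()
    ).set_index("phage_pop")
    phage_range = (
        df.groupby(["prok_pop", "lifestyle"])["phage_pop"].nunique().rename("phage_range").reset_index()
    ).set_index("prok_pop")
    return host_range, phage_range


def phage_host_correlation(
    phage_matrix: pd.DataFrame,
    prok_matrix: pd.DataFrame,
    links: Iterable[HostLink],
    lifestyle_of_pop: Mapping[str, str],
    min_samples: int = 5,
) -> pd.DataFrame:
    """Pearson correlation of each linked phage-host abundance pair.

    Correlations use the samples shared by both matrices; pairs with a
    zero-variance series are excluded with a warning.  q is BH across
    the evaluated links.
    """
    shared = [s for s in phage_matrix.columns if s in prok_matrix.columns]
    if len(shared) < min_samples:
        raise ValueError(f"only {len(shared)} shared samples (< {min_samples})")
    rows = []
    for l in sorted({(l.phage_pop_id, l.prok_pop_id) for l in links}):
        phage_pop, prok_pop = l
        if phage_pop not in phage_matrix.index or prok_pop not in prok_matrix.index:
            continue
        x = phage_matrix.loc[phage_pop, shared].to_numpy(float)
        y = prok_matrix.loc[prok_pop, shared].to_numpy(float)
        if np.std(x) == 0 or np.std(y) == 0:
            warnings.warn(f"zero-variance series for {phage_pop}~{prok_pop}: excluded")
            continue
        r, p = pearsonr(x, y)
        rows.append((phage_pop, prok_pop, lifestyle_of_pop.get(phage_pop), float(r), float(p)))
    out = pd.DataFrame(rows, columns=["phage_pop", "prok_pop", "lifestyle", "r", "p"])
    if not out.empty:
        out["q"] = bh_adjust(out["p"].to_numpy())
    else:
        out["q"] = []
    return out


def defense_burden(
    defense_table: pd.DataFrame,  # columns: prok_genome_id, system_name, count
    group_assignments: Mapping[str, set[str]],  # group label -> prokaryote genome ids
) -> pd.DataFrame:
    """Mean +/- sd of anti-phage system counts per prokaryote group.

    The per-genome burden counts system *instances* (summing counts
    over systems).  Genomes absent from the defense table count 0, with
    a warning.  An empty group is flagged with NaN summaries.
    """
    per_genome = defense_table.groupby("prok_genome_id")["count"].sum()
    rows = []
    for group, genomes in group_assignments.items():
        genomes = sorted(genomes)
        if not genomes:
            warnings.warn(f"group {group!r} empty: summary undefined")
            rows.append((group, 0, np.nan, np.nan))
            continue
        missing = [g for g in genomes if g not in per_genome.index]
        if missing:
            warnings.warn(f"{len(missing)} genome(s) absent from defense table: counted 0")
        counts = np.array([per_genome.get(g, 0) for g in genomes], dtype=float)
        rows.append((group, len(genomes), float(counts.mean()), float(counts.std(ddof=1)) if len(counts) > 1 else np.nan))
    return pd.DataFrame(rows, columns=["group", "n_genomes", "mean_systems", "sd_systems"]).set_index("group")
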