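"""Protein clustering and phage-prokaryote gene sharing, a proxy for
horizontal gene transfer (HGT).

Proteins are clustered greedily in decreasing length order: a sequence
joins the best existing cluster whose representative aligns at >= 60%
identity with the alignment covering >= 80% of the shorter sequence,
otherwise it founds a new cluster.  Identity is computed by exact local
alignment (BLOSUM62, gap open 11 / extend 1) as matches over alignment
columns; no seeding heuristics are used, only the threshold semantics.
A protein cluster (PC) containing both phage- and prokaryote-origin
proteins is a *shared* PC.  Prokaryote proteins encoded on
prophage-flagged contigs must be excluded by the caller before
clustering so prophage genes do not masquerade as HGT.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.stats import pearsonr

from .stats_core import bh_adjust


class InputError(ValueError):
    pass


PHAGE_ORIGINS = ("virulent", "temperate")
_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class ProteinRecord:
    protein_id: str
    seq: str
    origin: str  # "virulent" | "temperate" | "prokaryote"
    genome_id: str
    population_id: str


@dataclass
class ProteinCluster:
    pc_id: str
    representative: str
    members: list[ProteinRecord] = field(default_factory=list)

    @property
    def shared(self) -> bool:
        origins = {m.origin for m in self.members}
        return bool(origins & set(PHAGE_ORIGINS)) and "prokaryote" in origins

    @property
    def lifestyles(self) -> set[str]:
        return {m.origin for m in self.members if m.origin in PHAGE_ORIGINS}


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "local"
    return aligner


def _identity_and_coverage(aligner, rep: str, seq: str) -> tuple[float, float]:
    """Best local alignment of *seq* against *rep*: (identity, coverage of shorter).

    Identity = identical columns / alignment columns (gaps included);
    coverage = aligned residues of the shorter sequence / its length.
    """
    if rep == seq:
        return 1.0, 1.0
    alns = aligner.align(rep, seq)
    if len(alns) == 0:
        return 0.0, 0.0
    aln = alns[0]
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    if columns == 0:
        return 0.0, 0.0
    identity = counts.identities / columns
    short_len = min(len(rep), len(seq))
    which = 0 if len(rep) <= len(seq) else 1
    aligned_residues = sum(end - start for start, end in aln.aligned[which])
    return identity, aligned_residues / short_len


def cluster_proteins(
    proteins: Sequence[ProteinRecord],
    identity: float = 0.60,
    cov_short: float = 0.80,
) -> list[ProteinCluster]:
    """Greedy incremental protein clustering.

    Sequences are processed longest first (ID as tie-break); each joins
    the *best* qualifying cluster (highest identity to its
    representative, earliest cluster on ties), matching the
    best-cluster assignment convention of greedy clusterers.
    """
    for p in proteins:
        if set(p.seq.upper()) - _AA:
            raise InputError(f"{p.protein_id}: non-amino-acid symbols")
        if len(p.seq) < 1:
            raise InputError(f"{p.protein_id}: empty sequence")
    aligner = _make_aligner()
    order = sorted(proteins, key=lambda p: (-len(p.seq), p.protein_id))
    clusters: list[ProteinCluster] = []
    reps: list[str] = []
    for p in order:
        best_idx, best_ident = None, -1.0
        for idx, rep_seq in enumerate(reps):
            ident, cov = _identity_and_coverage(aligner, rep_seq, p.seq)
            if ident >= identity and cov >= cov_short and ident > best_ident:
                best_idx, best_ident = idx, ident
        if best_idx is None:
            clusters.append(
                ProteinCluster(pc_id=f"PC_{len(clusters) + 1:05d}", representative=p.protein_id, members=[p])
            )
            reps.append(p.seq)
        else:
            clusters[best_idx].members.append(p)
    return clusters


def pc_sets_by_genome(pcs: Sequence[ProteinCluster]) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    for pc in pcs:
        for m in pc.members:
            out.setdefault(m.genome_id, set()).add(pc.pc_id)
    return out


def pc_sets_by_population(
    pcs: Sequence[ProteinCluster], origins: Iterable[str] | None = None
) -> dict[str, set[str]]:
    wanted = set(origins) if origins is not None else None
    out: dict[str, set[str]] = {}
    for pc in pcs:
        for m in pc.members:
            if wanted is None or m.origin in wanted:
                out.setdefault(m.population_id, set()).add(pc.pc_id)
    return out


def shared_pc_ratio(pcs: Sequence[ProteinCluster]) -> pd.Series:
    """Per phage genome: fraction of its PCs that are shared with prokaryotes.

    Counts distinct PCs, so duplicating a protein already represented
    in a PC does not move the ratio.  Genomes with no phage-origin
    proteins are excluded with a warning.
    """
    shared_ids = {pc.pc_id for pc in pcs if pc.shared}
    genome_pcs: dict[str, set[str]] = {}
    for pc in pcs:
        for m in pc.members:
            if m.origin in PHAGE_ORIGINS:
                genome_pcs.setdefault(m.genome_id, set()).add(pc.pc_id)
    ratios = {}
    for genome, ids in sorted(genome_pcs.items()):
        if not ids:
            warnings.warn(f"{genome}: no PCs, excluded")
            continue
        ratios[genome] = len(ids & shared_ids) / len(ids)
    return pd.Series(ratios, name="shared_pc_ratio", dtype=float)


def host_vs_nonhost_sharing(
    pcs: Sequence[ProteinCluster],
    host_pairs: Iterable[tuple[str, str]],  # (phage_pop, prok_pop)
    family_of_prok: Mapping[str, str],
    seed: int = 0,
) -> pd.DataFrame:
    """Compare per-pair shared-PC proportion between hosts and nonhosts.

    For one phage-prokaryote pair the proportion is the number of the
    phage population's PCs also found in that prokaryote population,
    over the phage population's total PCs.  For each prokaryotic family
    the nonhost pairs (same phages, non-linked prokaryotes of the
    family) are subsampled without replacement to the family's host
    pair count; families with fewer nonhost than host pairs use all
    nonhost pairs with a warning.
    """
    rng = np.random.default_rng(seed)
    phage_pcs = pc_sets_by_population(pcs, origins=PHAGE_ORIGINS)
    prok_pcs = pc_sets_by_population(pcs, origins=("prokaryote",))
    host_pairs = sorted(set(host_pairs))
    proks = sorted(family_of_prok)

    def proportion(phage_pop: str, prok_pop: str) -> float | None:
        ppcs = phage_pcs.get(phage_pop)
        if not ppcs:
            return None
        return len(ppcs & prok_pcs.get(prok_pop, set())) / len(ppcs)

    rows = []
    families = sorted({family_of_prok[p] for _, p in host_pairs if p in family_of_prok})
    for fam in families:
        fam_hosts = [(ph, pr) for ph, pr in host_pairs if family_of_prok.get(pr) == fam]
        if not fam_hosts:
            continue
        linked = set(host_pairs)
        fam_proks = [p for p in proks if family_of_prok[p] == fam]
        candidates = [
            (ph, pr)
            for ph, _ in fam_hosts
            for pr in fam_proks
            if (ph, pr) not in linked
        ]
        candidates = sorted(set(candidates))
        n_host = len(fam_hosts)
        if len(candidates) < n_host:
            warnings.warn(f"family {fam}: fewer nonhost than host pairs, using all")
            chosen = candidates
        else:
            idx = rng.choice(len(candidates), size=n_host, replace=False)
            chosen = [candidates[i] for i in sorted(idx)]
        host_props = [v for v in (proportion(*p) for p in fam_hosts) if v is not None]
        nonhost_props = [v for v in (proportion(*p) for p in chosen) if v is not None]
        rows.append(
            (
                fam,
                n_host,
                float(np.mean(host_props)) if host_props else np.nan,
                float(np.std(host_props, ddof=1)) if len(host_props) > 1 else np.nan,
                float(np.mean(nonhost_props)) if nonhost_props else np.nan,
                float(np.std(nonhost_props, ddof=1)) if len(nonhost_props) > 1 else np.nan,
            )
        )
    return pd.DataFrame(
        rows,
        columns=["family", "n_pairs", "host_mean", "host_sd", "nonhost_mean", "nonhost_sd"],
    ).set_index("family")


def screen_ta_and_correlate(
    ta_annotations: Mapping[str, str],  # pc_id -> TA family name (PemK, HicB, ...)
    pc_matrix: pd.DataFrame,  # PC x sample abundance
    diet_axes: pd.DataFrame,  # sample x {"leaf", "fruit"} proportions
    pc_lifestyles: Mapping[str, set[str]] | None = None,
) -> pd.DataFrame:
    """Correlate toxin-antitoxin PC abundances with diet proportions.

    For every TA-annotated PC found in the abundance matrix and every
    diet axis, the Pearson correlation is computed over the samples;
    q-values are BH-adjusted across all tested PC x axis pairs.
    Constant-abundance PCs are excluded (zero variance).
    """
    samples = [s for s in pc_matrix.columns if s in diet_axes.index]
    rows = []
    for pc_id in sorted(ta_annotations):
        if pc_id not in pc_matrix.index:
            warnings.warn(f"{pc_id}: absent from abundance matrix, skipped")
            continue
        x = pc_matrix.loc[pc_id, samples].to_numpy(float)
        if np.std(x) == 0:
            warnings.warn(f"{pc_id}: constant abundance, excluded")
            continue
        lifestyles = ",".join(sorted((pc_lifestyles or {}).get(pc_id, set())))
        for axis in diet_axes.columns:
            y = diet_axes.loc[samples, axis].to_numpy(float)
            r, p = pearsonr(x, y)
            rows.append((pc_id, ta_annotations[pc_id], lifestyles, axis, float(r), float(p)))
    out = pd.DataFrame(rows, columns=["pc_id", "ta_name", "lifestyles", "axis", "r", "p"])
    out["q"] = bh_adjust(out["p"].to_numpy()) if not out.empty else []
    return out
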