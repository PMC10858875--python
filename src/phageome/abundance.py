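"""Coverage-derived abundance matrices and ecological transforms.

A population's abundance in a sample is the trimmed mean of the
per-base read depth over its representative genome ("tpmean": the
lowest and highest 5% of positions by depth are discarded before
averaging), computed from read alignments kept at >= 95% identity over
>= 75% of the read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import AlignmentHit


class InputError(ValueError):
    pass


@dataclass
class AbundanceMatrix:
    """Populations x samples abundance with per-sample metadata.

    ``state`` tracks the normalization applied: "raw", "relative" or
    "hellinger".  ``metadata`` is indexed by sample id and carries at
    least individual, date and season columns when known.
    """

    values: pd.DataFrame  # rows = populations, columns = samples
    state: str = "raw"
    metadata: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise InputError("negative abundance values")


def filter_read_alignments(
    hits: Sequence[AlignmentHit],
    read_lengths: Mapping[str, int],
    min_identity: float = 95.0,
    min_aligned_frac: float = 0.75,
) -> list[AlignmentHit]:
    """Keep read-to-genome hits at >= min_identity over >= min_aligned_frac of the read."""
    kept = []
    for h in hits:
        rlen = read_lengths[h.query_id]
        if rlen <= 0:
            raise InputError(f"read {h.query_id} has non-positive length")
        if h.pct_identity >= min_identity and h.aln_length / rlen >= min_aligned_frac:
            kept.append(h)
    return kept


def tpmean_coverage(depths: Sequence[float] | np.ndarray, trim_frac: float = 0.05) -> float:
    """Trimmed-mean coverage of one genome in one sample.

    Discards the ``floor(trim_frac * L)`` lowest-depth and highest-depth
    positions (rank-based, not contiguous windows) and averages the
    rest.  With ``trim_frac=0`` this is the plain mean.
    """
    depths = np.asarray(depths, dtype=float)
    if depths.size == 0:
        raise InputError("empty depth profile")
    k = int(np.floor(trim_frac * depths.size))
    if k == 0:
        return float(depths.mean())
    ordered = np.sort(depths)
    return float(ordered[k : depths.size - k].mean())


def coverage_matrix(
    depth_table: pd.DataFrame,
    genome_lengths: Mapping[str, int],
    trim_frac: float = 0.05,
) -> AbundanceMatrix:
    """Build a raw population x sample matrix of tpmean coverages.

    ``depth_table`` has columns genome_id, sample_id, position, depth;
    positions absent from the table are depth 0.
    """
    samples = sorted(depth_table["sample_id"].unique())
    genomes = sorted(genome_lengths)
    out = pd.DataFrame(0.0, index=genomes, columns=samples)
    for (gid, sid), grp in depth_table.groupby(["genome_id", "sample_id"], sort=False):
        L = genome_lengths[gid]
        depths = np.zeros(L)
        pos = grp["position"].to_numpy(dtype=int) - 1  # 1-based in files
        depths[pos] = grp["depth"].to_numpy(dtype=float)
        out.loc[gid, sid] = tpmean_coverage(depths, trim_frac)
    return AbundanceMatrix(out, state="raw")


def normalize_by_sample_total(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Divide each sample by its total coverage (library-size proxy)."""
    vals = matrix.values.copy()
    totals = vals.sum(axis=0)
    nonzero = totals > 0
    vals.loc[:, nonzero] = vals.loc[:, nonzero] / totals[nonzero]
    return AbundanceMatrix(vals, state="relative", metadata=matrix.metadata)


def hellinger_transform(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Hellinger standardization: sqrt of per-sample relative abundance.

    Each transformed sample has unit sum of squares (all-zero samples
    stay all-zero, with a warning).
    """
    vals = matrix.values.to_numpy(dtype=float)
    if (vals < 0).any():
        raise InputError("negative values in abundance matrix")
    totals = vals.sum(axis=0)
    if (totals == 0).any():
        warnings.warn("all-zero sample(s) left untransformed")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.sqrt(np.where(totals > 0, vals / np.where(totals > 0, totals, 1.0), 0.0))
    frame = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return AbundanceMatrix(frame, state="hellinger", metadata=matrix.metadata)


def pc_abundance(
    pc_membership: Mapping[str, set[str] | Sequence[str]],
    pop_matrix: AbundanceMatrix,
) -> AbundanceMatrix:
    """Abundance of each protein cluster: total abundance of the distinct
    phage populations encoding a protein in that PC.

    A population contributing several proteins to one PC is counted
    once; member populations absent from the matrix contribute zero.
    """
    rows = {}
    for pc_id, pops in pc_membership.items():
        pops = set(pops)
        missing = pops - set(pop_matrix.values.index)
        if missing:
            warnings.warn(f"{pc_id}: {len(missing)} member population(s) not in matrix")
        present = sorted(pops & set(pop_matrix.values.index))
        if not present:
            warnings.warn(f"{pc_id}: empty PC row")
            rows[pc_id] = pd.Series(0.0, index=pop_matrix.values.columns)
        else:
            rows[pc_id] = pop_matrix.values.loc[present].sum(axis=0)
    frame = pd.DataFrame(rows).T
    frame = frame.reindex(index=list(pc_membership))
    return AbundanceMatrix(frame, state=pop_matrix.state, metadata=pop_matrix.metadata)


def prevalence_and_mean_abundance(
    matrix: AbundanceMatrix, populations: Sequence[str] | None = None
) -> pd.DataFrame:
    """Per-population prevalence (%) and mean relative abundance (%).

    Prevalence is the percentage of samples where the population is
    detected (> 0).  Relative abundance is computed per sample
    (value / sample total x 100) and then averaged over *all* samples,
    zeros included.
    """
    vals = matrix.values
    if populations is not None:
        vals = vals.loc[list(populations)]
    if vals.empty:
        return pd.DataFrame(columns=["prevalence_pct", "mean_rel_abundance_pct"])
    totals = matrix.values.sum(axis=0)
    rel = vals.divide(totals.where(totals > 0, np.nan), axis=1).fillna(0.0) * 100.0
    return pd.DataFrame(
        {
            "prevalence_pct": (vals > 0).mean(axis=1) * 100.0,
            "mean_rel_abundance_pct": rel.mean(axis=1),
        }
    )
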