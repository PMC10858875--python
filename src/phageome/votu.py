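"""Pairwise ANI/AF computation and greedy centroid clustering of phage
genomes into populations (vOTUs), plus source/lifestyle sub-population
splitting.

ANI is the alignment-length-weighted mean identity over local-alignment
fragments after resolving query-interval overlaps; AF is the fraction
of a genome covered by the merged fragments.  Two genomes belong to one
population when ANI >= 95% with >= 85% of the shorter genome aligned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io_formats import AlignmentHit


class InputError(ValueError):
    pass


@dataclass
class ANIRecord:
    genome_a: str
    genome_b: str
    ani: float
    af_a: float
    af_b: float

    def af_of(self, genome: str) -> float:
        if genome == self.genome_a:
            return self.af_a
        if genome == self.genome_b:
            return self.af_b
        raise KeyError(genome)


@dataclass
class VOTUCluster:
    votu_id: str
    representative: str
    members: list[str]
    # attribute maps filled by the caller (genome -> "VM"/"MM", "virulent"/"temperate")
    source: dict[str, str] = field(default_factory=dict)
    lifestyle: dict[str, str] = field(default_factory=dict)


def _interval_union_length(intervals: Iterable[tuple[int, int]]) -> int:
    total, last_end = 0, None
    for start, end in sorted(intervals):
        if last_end is None or start >= last_end:
            total += end - start
            last_end = end
        elif end > last_end:
            total += end - last_end
            last_end = end
    return total


def _novel_length(interval: tuple[int, int], covered: list[tuple[int, int]]) -> int:
    """Bases of *interval* not already inside any interval of *covered*."""
    start, end = interval
    overlaps = [
        (max(start, cs), min(end, ce)) for cs, ce in covered if min(end, ce) > max(start, cs)
    ]
    return (end - start) - _interval_union_length(overlaps)


def compute_ani_af(
    hits: Sequence[AlignmentHit], len_a: int, len_b: int,
    genome_a: str | None = None, genome_b: str | None = None,
) -> ANIRecord:
    """Aggregate local-alignment fragments of one genome pair into ANI/AF.

    Fragments are taken in decreasing bit-score order; a fragment
    contributes only where it covers at least one query base not yet
    covered by a better fragment, and its identity is weighted by that
    novel length.  AF of each genome is the merged covered length over
    genome length, in percent.  A pair with no hits gets ANI 0 / AF 0.
    """
    if genome_a is None:
        genome_a = hits[0].query_id if hits else "a"
    if genome_b is None:
        genome_b = hits[0].subject_id if hits else "b"
    if not hits:
        return ANIRecord(genome_a, genome_b, 0.0, 0.0, 0.0)

    covered_q: list[tuple[int, int]] = []
    kept_q_intervals: list[tuple[int, int]] = []
    kept_s_intervals: list[tuple[int, int]] = []
    weighted = 0.0
    total_novel = 0
    order = sorted(hits, key=lambda h: (-h.bit_score, h.query_interval()))
    for h in order:
        q_iv = h.query_interval()
        novel = _novel_length(q_iv, covered_q)
        if novel >= 1:
            weighted += h.pct_identity * novel
            total_novel += novel
            covered_q.append(q_iv)
            kept_q_intervals.append(q_iv)
            kept_s_intervals.append(h.subject_interval())
    if total_novel == 0:
        return ANIRecord(genome_a, genome_b, 0.0, 0.0, 0.0)
    ani = weighted / total_novel
    af_a = 100.0 * _interval_union_length(kept_q_intervals) / len_a
    af_b = 100.0 * _interval_union_length(kept_s_intervals) / len_b
    return ANIRecord(genome_a, genome_b, ani, min(af_a, 100.0), min(af_b, 100.0))


def cluster_votus(
    genome_lengths: Mapping[str, int],
    ani_records: Iterable[ANIRecord],
    ani_min: float = 95.0,
    af_min: float = 85.0,
) -> list[VOTUCluster]:
    """Greedy centroid clustering of genomes into populations.

    Genomes are visited in decreasing length (ties broken by ID).  A
    genome joins the first established seed it matches at ANI >=
    *ani_min* with the aligned fraction of the shorter genome of the
    pair >= *af_min*; otherwise it founds a new cluster.  The result is
    a partition: every genome lands in exactly one cluster, and each
    cluster's representative is its longest member (the seed).
    """
    if not isinstance(genome_lengths, Mapping):
        pairs = list(genome_lengths)
        ids = [g for g, _ in pairs]
        if len(ids) != len(set(ids)):
            raise InputError("duplicate genome IDs")
        genome_lengths = dict(pairs)
    ids = list(genome_lengths)
    lookup: dict[tuple[str, str], ANIRecord] = {}
    for rec in ani_records:
        lookup[(rec.genome_a, rec.genome_b)] = rec
        lookup[(rec.genome_b, rec.genome_a)] = rec

    order = sorted(ids, key=lambda g: (-genome_lengths[g], g))
    seeds: list[str] = []
    members: dict[str, list[str]] = {}
    for g in order:
        assigned = None
        for seed in seeds:
            rec = lookup.get((g, seed))
            if rec is None or rec.ani < ani_min:
                continue
            shorter = min((g, seed), key=lambda x: (genome_lengths[x], x))
            if rec.af_of(shorter) >= af_min:
                assigned = seed
                break
        if assigned is None:
            seeds.append(g)
            members[g] = [g]
        else:
            members[assigned].append(g)

    clusters = []
    for i, seed in enumerate(seeds):
        clusters.append(
            VOTUCluster(votu_id=f"vOTU_{i + 1:04d}", representative=seed, members=members[seed])
        )
    return clusters


def split_votu(cluster: VOTUCluster, attribute: str) -> dict[str, list[str]]:
    """Split one cluster into sub-populations by *attribute*.

    ``attribute`` is ``"source"`` (VM/MM) or ``"lifestyle"``
    (virulent/temperate).  Returns a map attribute-value -> member ids;
    a cluster whose members carry both values yields two sub-populations
    sharing the cluster's votu_id.
    """
    attr_map = getattr(cluster, attribute, None)
    if not isinstance(attr_map, dict):
        raise InputError(f"unknown attribute {attribute!r}")
    out: dict[str, list[str]] = {}
    for m in cluster.members:
        if m not in attr_map:
            raise InputError(f"member {m} missing attribute {attribute!r}")
        out.setdefault(attr_map[m], []).append(m)
    return out


def subpopulation_counts(clusters: Sequence[VOTUCluster], attribute: str) -> dict[str, int]:
    """Count sub-populations per attribute value, plus dual clusters.

    Satisfies the inclusion-exclusion identity
    ``sum(per-value counts) - dual = len(clusters)`` for a two-valued
    attribute.
    """
    counts: dict[str, int] = {}
    dual = 0
    for c in clusters:
        split = split_votu(c, attribute)
        if len(split) > 1:
            dual += 1
        for value in split:
            counts[value] = counts.get(value, 0) + 1
    counts["_dual"] = dual
    return counts


def inclusion_exclusion_total(count_a: int, count_b: int, dual: int) -> int:
    """Total clusters implied by two sub-population counts and their overlap."""
    return count_a + count_b - dual


def select_representatives(
    clusters: Sequence[VOTUCluster],
    attribute: str,
    genome_lengths: Mapping[str, int],
) -> dict[tuple[str, str], str]:
    """Pick a representative genome for every (votu, attribute value).

    Longest member wins; length ties break toward the lexicographically
    smaller ID so repeated runs are identical.
    """
    reps: dict[tuple[str, str], str] = {}
    for c in clusters:
        for value, ids in split_votu(c, attribute).items():
            if not ids:
                raise RuntimeError("empty sub-population")
            reps[(c.votu_id, value)] = min(ids, key=lambda g: (-genome_lengths[g], g))
    return reps
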