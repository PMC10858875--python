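"""Phage-candidate screening, alternative genetic-code selection and
lifestyle resolution.

The inputs here are summaries produced by upstream annotation (per-contig
viral/host/hallmark gene counts, per-code total coding scores, prophage
flags and episomal lifestyle labels); this module applies the decision
rules that turn them into a screened set of phage genome records.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

from ._codes import SUPPORTED_CODES


class InputError(ValueError):
    pass


ALTERNATIVE_CODES = tuple(c for c in SUPPORTED_CODES if c != 11)


@dataclass
class GeneCountSummary:
    """Per-contig gene-category counts used by the candidate filter."""

    contig_id: str
    viral_genes: int
    host_genes: int
    hallmark_genes: int
    length: int
    gc: float

    def __post_init__(self) -> None:
        if min(self.viral_genes, self.host_genes, self.hallmark_genes) < 0:
            raise InputError(f"{self.contig_id}: negative gene count")


@dataclass
class CodingScoreTable:
    """Total coding score of a contig under each candidate genetic code."""

    contig_id: str
    scores: dict[int, float]

    def __post_init__(self) -> None:
        if 11 not in self.scores:
            raise InputError(f"{self.contig_id}: missing standard-code (11) score")


@dataclass
class PhageGenomeRecord:
    """A screened phage genome with its source, lifestyle and genes."""

    id: str
    sequence: str
    source: str  # "VM" | "MM"
    lifestyle: str  # "virulent" | "temperate"
    is_prophage: bool
    genetic_code: int = 11
    genes: list = field(default_factory=list)  # (start, end, strand, category, annotations)

    def __post_init__(self) -> None:
        if self.source not in ("VM", "MM"):
            raise InputError(f"{self.id}: source must be VM or MM")
        if self.lifestyle not in ("virulent", "temperate"):
            raise InputError(f"{self.id}: bad lifestyle {self.lifestyle!r}")
        if self.is_prophage and self.lifestyle != "temperate":
            raise InputError(f"{self.id}: a prophage is temperate by definition")
        if self.genetic_code not in SUPPORTED_CODES:
            raise InputError(f"{self.id}: unsupported genetic code {self.genetic_code}")


def screen_phage_candidate(summary: GeneCountSummary) -> bool:
    """Candidate filter on annotation counts.

    Keep a contig iff it has at least one viral gene, or it has no viral
    gene and either no host gene or more than two hallmark genes.  The
    rule is monotone in viral and hallmark counts: adding viral or
    hallmark evidence can only retain a contig.
    """
    if summary.viral_genes >= 1:
        return True
    return summary.host_genes == 0 or summary.hallmark_genes > 2


def select_genetic_code(
    scores: CodingScoreTable,
    length: int,
    gc: float,
    *,
    min_length: int = 10_000,
    max_gc: float = 50.0,
    margin: float = 1.10,
) -> int:
    """Pick the genetic code for a contig from per-code coding scores.

    Stop-codon reassignment is only considered for long (> *min_length*)
    low-GC (< *max_gc* %) contigs, where it is biologically plausible.
    An alternative code wins only when its score is the unique maximum
    over all codes and at least ``margin`` times the standard-code
    score; ties and near-misses fall back to code 11.
    """
    if length <= min_length or gc >= max_gc:
        return 11
    std = scores.scores[11]
    best_code, best_score = 11, std
    for code in sorted(scores.scores):
        if code == 11:
            continue
        s = scores.scores[code]
        if s > best_score:  # strict: equal scores keep the earlier (11-first) choice
            best_code, best_score = code, s
    if best_code != 11 and best_score >= margin * std:
        return best_code
    return 11


def validate_recoded_contig(
    phage_hit_flags: list[bool],
    hallmark_flags: list[bool],
    *,
    min_phage_fraction: float = 0.5,
) -> bool:
    """Keep a recoded contig only if its annotation still looks phage-like.

    Requires at least one hallmark protein, or at least half of the
    annotated genes hitting a phage reference.  With zero annotated
    genes the fraction is undefined and the contig is dropped.
    """
    if sum(hallmark_flags) >= 1:
        return True
    if not phage_hit_flags:
        warnings.warn("recoded contig with zero annotated genes dropped")
        return False
    return sum(phage_hit_flags) / len(phage_hit_flags) >= min_phage_fraction


def resolve_lifestyle(is_prophage: bool, episomal_label: str | None) -> str:
    """Resolve a genome's lifestyle.

    Prophages are temperate by definition; episomal genomes take the
    lifestyle label assigned by the upstream classifier.
    """
    if is_prophage:
        if episomal_label is not None:
            raise InputError("episomal label supplied for a prophage")
        return "temperate"
    if episomal_label not in ("virulent", "temperate"):
        raise InputError(f"invalid episomal label {episomal_label!r}")
    return episomal_label


def screen_contigs(
    summaries: list[GeneCountSummary],
    coding_scores: dict[str, CodingScoreTable],
    lifestyle_inputs: dict[str, tuple[bool, str | None]],
    sequences: dict[str, str],
    sources: dict[str, str],
    genes: dict[str, list] | None = None,
    recoded_validation: dict[str, tuple[list[bool], list[bool]]] | None = None,
) -> list[PhageGenomeRecord]:
    """Apply the full screening stage to a batch of contigs.

    ``lifestyle_inputs`` maps contig -> (is_prophage, episomal_label);
    ``recoded_validation`` maps contig -> (phage_hit_flags,
    hallmark_flags) for contigs that end up recoded.
    """
    genes = genes or {}
    recoded_validation = recoded_validation or {}
    kept: list[PhageGenomeRecord] = []
    for summary in summaries:
        if not screen_phage_candidate(summary):
            continue
        cid = summary.contig_id
        table = coding_scores.get(cid, CodingScoreTable(cid, {11: 0.0}))
        code = select_genetic_code(table, summary.length, summary.gc)
        if code != 11:
            flags = recoded_validation.get(cid, ([], []))
            if not validate_recoded_contig(*flags):
                continue
        is_prophage, episomal = lifestyle_inputs[cid]
        lifestyle = resolve_lifestyle(is_prophage, episomal)
        kept.append(
            PhageGenomeRecord(
                id=cid,
                sequence=sequences[cid],
                source=sources[cid],
                lifestyle=lifestyle,
                is_prophage=is_prophage,
                genetic_code=code,
                genes=genes.get(cid, []),
            )
        )
    return kept
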