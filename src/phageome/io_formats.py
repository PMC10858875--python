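"""External file formats, run configuration and pipeline entry point.

All genomic coordinates at file boundaries are 1-based inclusive (the
BLAST tabular convention); internal code converts to 0-based half-open
intervals where it needs arithmetic.  Tabular outputs are plain TSV so
that a run is diffable and byte-reproducible under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml
from Bio import SeqIO


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class ManifestError(ValueError):
    """A pipeline manifest is missing an input required by a stage."""


class ConfigError(ValueError):
    """A configuration value is outside its stated domain."""


# ---------------------------------------------------------------------------
# Domain types


@dataclass
class AlignmentHit:
    """One row of a 12-column BLAST-style tabular alignment file."""

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bit_score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_identity <= 100.0:
            raise FormatError(
                f"pct_identity {self.pct_identity} outside [0, 100] "
                f"for {self.query_id} vs {self.subject_id}"
            )
        if self.aln_length < 1:
            raise FormatError(f"aln_length {self.aln_length} < 1")
        if self.evalue < 0:
            raise FormatError(f"negative evalue {self.evalue}")

    def query_interval(self) -> tuple[int, int]:
        """Query span as a 0-based half-open interval (orientation normalized)."""
        lo, hi = sorted((self.q_start, self.q_end))
        return lo - 1, hi

    def subject_interval(self) -> tuple[int, int]:
        lo, hi = sorted((self.s_start, self.s_end))
        return lo - 1, hi


@dataclass
class RunConfig:
    """Every stage threshold of the pipeline, with its default value.

    Defaults are the operating points of the analysis: 95% ANI / 85%
    aligned fraction for population (vOTU) clustering, exact full-length
    spacer matching (the recorded E-value is provenance only), the
    four-part genome-homology host criterion, the read-filter and
    trimmed-mean settings used for coverage, cd-hit-style protein
    clustering thresholds, the SNP filters, BH alpha and 999
    permutations for permutation tests.
    """

    ani_min: float = 95.0
    af_min: float = 85.0
    spacer_evalue: float = 1e-10
    homology_evalue: float = 1e-3
    homology_bitscore: float = 50.0
    homology_min_len: int = 1000
    homology_min_ident: float = 96.0
    read_min_ident: float = 95.0
    read_min_aligned_frac: float = 0.75
    trim_frac: float = 0.05
    pc_identity: float = 0.60
    pc_cov_short: float = 0.80
    snp_qual: float = 30.0
    snp_min_alt_reads: int = 4
    snp_min_alt_freq: float = 0.01
    snp_min_depth: float = 10.0
    fdr_alpha: float = 0.05
    n_perm: int = 999
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("ani_min", "af_min", "homology_min_ident", "read_min_ident"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ConfigError(f"{name}={v} outside [0, 100]")
        for name in (
            "read_min_aligned_frac",
            "trim_frac",
            "pc_identity",
            "pc_cov_short",
            "snp_min_alt_freq",
            "fdr_alpha",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if self.trim_frac >= 0.5:
            raise ConfigError("trim_frac must be < 0.5")
        if self.n_perm < 1:
            raise ConfigError("n_perm must be >= 1")
        if self.snp_min_alt_reads < 1:
            raise ConfigError("snp_min_alt_reads must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(data) - known
        if extra:
            raise ConfigError(f"unknown config keys: {sorted(extra)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(id, SEQUENCE), ...]`` preserving order.

    Sequences are uppercased.  Duplicate IDs and empty records are
    format errors: downstream stages key everything by sequence ID.
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"empty FASTA record {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append((rec.id, seq))
    return records


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BLAST tabular (outfmt 6)

_HIT_COLUMNS = [
    ("query_id", str),
    ("subject_id", str),
    ("pct_identity", float),
    ("aln_length", int),
    ("mismatches", int),
    ("gap_opens", int),
    ("q_start", int),
    ("q_end", int),
    ("s_start", int),
    ("s_end", int),
    ("evalue", float),
    ("bit_score", float),
]


def read_alignment_table(path: str | Path) -> list[AlignmentHit]:
    """Parse a 12-column tab-separated local-alignment table."""
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise FormatError(
                    f"{path}:{lineno}: expected 12 columns, found {len(fields)}"
                )
            kwargs = {}
            for (name, typ), raw in zip(_HIT_COLUMNS, fields):
                try:
                    kwargs[name] = typ(raw)
                except ValueError as exc:
                    raise FormatError(
                        f"{path}:{lineno}: field {name!r}: {exc}"
                    ) from None
            hits.append(AlignmentHit(**kwargs))
    return hits


def write_alignment_table(path: str | Path, hits: Iterable[AlignmentHit]) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.subject_id,
                        _fmt(h.pct_identity),
                        str(h.aln_length),
                        str(h.mismatches),
                        str(h.gap_opens),
                        str(h.q_start),
                        str(h.q_end),
                        str(h.s_start),
                        str(h.s_end),
                        _fmt(h.evalue),
                        _fmt(h.bit_score),
                    ]
                )
                + "\n"
            )


def _fmt(x: float) -> str:
    """Format a real to 12 significant digits (round-trip safe in text)."""
    if isinstance(x, float) and (math.isnan(x) or math.isinf(x)):
        return str(x)
    return format(x, ".12g")


# ---------------------------------------------------------------------------
# Generic TSV helpers


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_tsv(path: str | Path, frame: pd.DataFrame) -> None:
    """Write a DataFrame as TSV, reals at 12 significant digits."""
    frame.to_csv(path, sep="\t", index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# Pipeline entry point (implementation in phageome.pipeline)


def run_pipeline(config: RunConfig, manifest: dict, outdir: str | Path) -> dict:
    """Run every pipeline stage described by *manifest*; see phageome.pipeline."""
    from . import pipeline

    return pipeline.run_pipeline(config, manifest, outdir)
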