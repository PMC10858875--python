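"""Within-population variant calling from pileups and SNP turnover over
time.

A variant is an (position, alternative base) pair passing the filters:
base quality > 30, >= 4 supporting reads, alternative-allele frequency
> 1%.  Genome similarity between two dates is the fraction of the
earlier date's variants still present at the later date; its decline
with time lag measures intrapopulation variant turnover, which is
compared between virulent and temperate phages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import linregress, mannwhitneyu

from ._codes import reverse_complement, translate


class InputError(ValueError):
    pass


@dataclass
class SNPProfile:
    genome_id: str
    date: object  # sortable date (datetime.date or ISO string)
    variants: set = field(default_factory=set)  # {(pos_1based, ref, alt, freq)}

    def variant_keys(self) -> set[tuple[int, str]]:
        """Identity of a SNP is (position, alt base); frequency is ignored."""
        return {(pos, alt) for pos, _ref, alt, _f in self.variants}


def select_genomes_for_snp(
    coverage: pd.DataFrame,  # genomes x samples tpmean coverage
    samples_by_individual: Mapping[str, Sequence[str]],
    min_depth: float = 10.0,
) -> dict[str, list[str]]:
    """Genomes deep enough for SNP calling, per individual.

    A genome is eligible for an individual iff its coverage is >=
    *min_depth* (inclusive) in every sample of that individual; a
    genome missing from a sample counts as coverage 0.
    """
    out: dict[str, list[str]] = {}
    for individual, samples in samples_by_individual.items():
        eligible = []
        for genome in coverage.index:
            depths = [
                float(coverage.loc[genome, s]) if s in coverage.columns else 0.0
                for s in samples
            ]
            if depths and min(depths) >= min_depth:
                eligible.append(genome)
        out[individual] = eligible
    return out


def call_snps(
    pileup: pd.DataFrame,  # columns: position, ref_base, base, count, mean_qual
    genome_id: str,
    date,
    qual_min: float = 30.0,
    min_alt_reads: int = 4,
    min_alt_freq: float = 0.01,
) -> SNPProfile:
    """Call variants for one genome on one date from per-site base counts.

    Site depth is the total count over all bases at the site.  Each
    alternative base with quality > *qual_min*, count >= *min_alt_reads*
    and frequency > *min_alt_freq* (strict, as the thresholds are
    printed) is an independent variant record; multi-allelic sites thus
    yield several records.  Zero-depth sites are skipped.
    """
    variants = set()
    for pos, site in pileup.groupby("position"):
        depth = site["count"].sum()
        if depth <= 0:
            continue
        refs = site["ref_base"].unique()
        ref = refs[0]
        for _, row in site.iterrows():
            base = row["base"]
            if base == ref:
                continue
            if row["mean_qual"] <= qual_min:
                continue
            count = row["count"]
            freq = count / depth
            if count >= min_alt_reads and freq > min_alt_freq:
                variants.add((int(pos), str(ref), str(base), float(freq)))
    return SNPProfile(genome_id=genome_id, date=date, variants=variants)


def shared_snp_fraction(earlier: SNPProfile, later: SNPProfile) -> float:
    """Fraction of the earlier date's SNPs still present at the later date.

    Undefined (NaN, with a warning) when the earlier profile is empty.
    """
    if earlier.genome_id != later.genome_id:
        raise InputError(
            f"profiles are for different genomes: {earlier.genome_id} vs {later.genome_id}"
        )
    a, b = earlier.variant_keys(), later.variant_keys()
    if not a:
        warnings.warn(f"{earlier.genome_id}@{earlier.date}: no SNPs, fraction undefined")
        return float("nan")
    return len(a & b) / len(a)


def classify_substitution(
    genome_seq: str,
    genes: Sequence[tuple[int, int, str]],  # (start_1based, end_1based_incl, strand)
    genetic_code: int,
    position: int,  # 1-based
    ref_base: str,
    alt_base: str,
) -> list[str]:
    """Substitution effect of a variant, per overlapping gene.

    Translates the reference and alternative codon with the genome's
    assigned genetic code (stop-recoded codes honored).  Returns one
    label per gene containing the position ("synonymous" /
    "non-synonymous"), or ["intergenic"] when no gene covers it.
    """
    if genome_seq[position - 1] != ref_base:
        raise InputError(
            f"reference base mismatch at {position}: genome has "
            f"{genome_seq[position - 1]}, variant says {ref_base}"
        )
    labels = []
    for start, end, strand in genes:
        if not start <= position <= end:
            continue
        gene_seq = genome_seq[start - 1 : end]
        offset = position - start
        if strand == "-":
            gene_seq = reverse_complement(gene_seq)
            offset = (end - start) - offset
            sub = reverse_complement(alt_base)
        else:
            sub = alt_base
        codon_idx = offset // 3
        within = offset % 3
        codon = gene_seq[codon_idx * 3 : codon_idx * 3 + 3]
        if len(codon) < 3:
            continue  # trailing partial codon
        alt_codon = codon[:within] + sub + codon[within + 1 :]
        ref_aa = translate(codon, genetic_code)
        alt_aa = translate(alt_codon, genetic_code)
        labels.append("synonymous" if ref_aa == alt_aa else "non-synonymous")
    return labels or ["intergenic"]


def similarity_series(
    profiles: Sequence[SNPProfile],
    lifestyle: str,
    day_of: Mapping[object, int] | None = None,
) -> pd.DataFrame:
    """All (reference date, later date) shared-SNP fractions for one genome set.

    Each date's profile is compared with every subsequent date of the
    same genome.  ``day_of`` converts dates to integer days; by default
    dates must already be integers or date objects with subtraction.
    """
    rows = []
    by_genome: dict[str, list[SNPProfile]] = {}
    for p in profiles:
        by_genome.setdefault(p.genome_id, []).append(p)
    for genome, plist in sorted(by_genome.items()):
        plist = sorted(plist, key=lambda p: p.date)
        for i, earlier in enumerate(plist):
            for later in plist[i + 1 :]:
                if day_of is not None:
                    lag = day_of[later.date] - day_of[earlier.date]
                else:
                    delta = later.date - earlier.date
                    lag = delta.days if hasattr(delta, "days") else int(delta)
                frac = shared_snp_fraction(earlier, later)
                rows.append((genome, lifestyle, earlier.date, lag, frac))
    return pd.DataFrame(
        rows, columns=["genome_id", "lifestyle", "reference_date", "lag_days", "shared_fraction"]
    )


def similarity_vs_lag(series: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """OLS of shared-SNP fraction on time lag, per lifestyle, plus a
    per-lag Wilcoxon comparison between lifestyles.

    The fit pools genome x reference-date fraction pairs within each
    lifestyle.  All-identical fractions give slope 0 with an undefined
    R^2 (flagged as NaN).
    """
    fits = []
    clean = series.dropna(subset=["shared_fraction"])
    for lifestyle, grp in clean.groupby("lifestyle"):
        x = grp["lag_days"].to_numpy(float)
        y = grp["shared_fraction"].to_numpy(float)
        if len(np.unique(x)) < 3:
            raise InputError(f"{lifestyle}: need >= 3 distinct lag points")
        if np.allclose(y, y[0]):
            fits.append((lifestyle, 0.0, float(y[0]), np.nan, len(y)))
            continue
        res = linregress(x, y)
        n = len(y)
        r2 = res.rvalue**2
        adj_r2 = 1 - (1 - r2) * (n - 1) / (n - 2) if n > 2 else np.nan
        fits.append((lifestyle, float(res.slope), float(res.intercept), float(adj_r2), n))
    fit_df = pd.DataFrame(
        fits, columns=["lifestyle", "slope", "intercept", "adj_r2", "n"]
    ).set_index("lifestyle")

    comparisons = []
    lifestyles = sorted(clean["lifestyle"].unique())
    if len(lifestyles) == 2:
        a, b = lifestyles
        for lag, grp in clean.groupby("lag_days"):
            xa = grp.loc[grp["lifestyle"] == a, "shared_fraction"].to_numpy(float)
            xb = grp.loc[grp["lifestyle"] == b, "shared_fraction"].to_numpy(float)
            if len(xa) == 0 or len(xb) == 0:
                continue
            pooled = np.concatenate([xa, xb])
            if np.all(pooled == pooled[0]):
                p = 1.0
            else:
                p = float(mannwhitneyu(xa, xb, alternative="two-sided").pvalue)
            comparisons.append((int(lag), float(np.mean(xa)), float(np.mean(xb)), p))
    cmp_df = pd.DataFrame(comparisons, columns=["lag_days", f"mean_{lifestyles[0] if len(lifestyles)==2 else 'a'}", f"mean_{lifestyles[1] if len(lifestyles)==2 else 'b'}", "p"])
    return fit_df, cmp_df


def fit_turnover_rate(series: pd.DataFrame) -> pd.Series:
    """Per-lifestyle daily variant loss rate from geometric decay.

    Under a constant per-day loss probability rho, the expected shared
    fraction at lag t is (1 - rho)^t.  The fit regresses
    log(mean fraction at lag) on lag through the origin and returns
    rho = 1 - exp(slope).  Lags whose mean fraction is 0 are dropped
    (log undefined).
    """
    out = {}
    clean = series.dropna(subset=["shared_fraction"])
    for lifestyle, grp in clean.groupby("lifestyle"):
        means = grp.groupby("lag_days")["shared_fraction"].mean()
        means = means[means > 0]
        if means.empty:
            out[lifestyle] = np.nan
            continue
        t = means.index.to_numpy(float)
        y = np.log(means.to_numpy(float))
        slope = (t * y).sum() / (t * t).sum()
        out[lifestyle] = 1.0 - float(np.exp(slope))
    return pd.Series(out, name="turnover_rate")
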