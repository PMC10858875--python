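"""Diet composition, feeding-season assignment and diet-responsive
population detection.

Daily diet profiles (proportion of full-day feeding time per food type)
are clustered into two feeding seasons -- high-fruit (HF) and high-leaf
(HL) -- and each phage population is tested for an abundance shift
between the seasons with an unpaired two-sided Wilcoxon rank-sum test,
BH-adjusted within one individual and lifestyle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import mannwhitneyu

from .stats_core import bh_adjust

FOOD_TYPES = ("fruit", "leaf", "flower", "animal", "other")


class InputError(ValueError):
    pass


@dataclass
class FeedingBout:
    individual: str
    date: str
    food_type: str
    start_min: float
    end_min: float

    def __post_init__(self) -> None:
        if self.food_type not in FOOD_TYPES:
            raise InputError(f"unknown food type {self.food_type!r}")
        if self.end_min <= self.start_min:
            raise InputError(
                f"{self.individual} {self.date}: bout end {self.end_min} "
                f"not after start {self.start_min}"
            )

    @property
    def duration(self) -> float:
        return self.end_min - self.start_min


@dataclass
class DietProfile:
    individual: str
    date: str
    proportions: dict[str, float]  # keys FOOD_TYPES, sum to 1
    season: str | None = None  # "HF" | "HL" once assigned

    def vector(self) -> np.ndarray:
        return np.array([self.proportions.get(t, 0.0) for t in FOOD_TYPES])


def diet_composition(bouts: list[FeedingBout]) -> DietProfile:
    """Fold one individual-day of feeding bouts into a diet profile.

    The proportion of a food type is its summed bout duration divided
    by the total feeding time of the day.  Bouts of one individual-day
    must not overlap.
    """
    if not bouts:
        raise InputError("no feeding bouts")
    keys = {(b.individual, b.date) for b in bouts}
    if len(keys) != 1:
        raise InputError("bouts span multiple individual-days")
    ordered = sorted(bouts, key=lambda b: b.start_min)
    for prev, cur in zip(ordered, ordered[1:]):
        if cur.start_min < prev.end_min:
            raise InputError(
                f"overlapping bouts at {prev.individual} {prev.date}: "
                f"[{prev.start_min}, {prev.end_min}) and [{cur.start_min}, {cur.end_min})"
            )
    total = sum(b.duration for b in bouts)
    if total <= 0:
        raise InputError("zero total feeding time")
    props = {t: 0.0 for t in FOOD_TYPES}
    for b in bouts:
        props[b.food_type] += b.duration / total
    individual, date = next(iter(keys))
    return DietProfile(individual, date, props)


def assign_seasons(
    profiles: list[DietProfile],
    method: str = "ward",
    metric: str = "euclidean",
) -> dict[tuple[str, str], str]:
    """Label each individual-date profile HF or HL by hierarchical clustering.

    Agglomerative clustering (Ward linkage on Euclidean distances by
    default) of the diet-proportion vectors, cut at two clusters; the
    cluster with the higher mean fruit proportion is the high-fruit
    (HF) season, the other high-leaf (HL).
    """
    if len(profiles) < 4:
        raise InputError("need at least 4 profiles to assign seasons")
    X = np.vstack([p.vector() for p in profiles])
    if np.allclose(X, X[0]):
        warnings.warn("all diet profiles identical: single season")
        return {(p.individual, p.date): "HF" for p in profiles}
    Z = linkage(X, method=method, metric=metric)
    labels = fcluster(Z, t=2, criterion="maxclust")
    fruit = X[:, FOOD_TYPES.index("fruit")]
    mean1 = fruit[labels == 1].mean()
    mean2 = fruit[labels == 2].mean() if (labels == 2).any() else -np.inf
    hf_label = 1 if mean1 >= mean2 else 2
    out = {}
    for p, lab in zip(profiles, labels):
        p.season = "HF" if lab == hf_label else "HL"
        out[(p.individual, p.date)] = p.season
    return out


def _rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided unpaired Wilcoxon rank-sum p-value.

    Exact null distribution when both groups are small and tie-free,
    otherwise normal approximation with continuity and tie correction.
    Degenerate input (all values identical across both groups, e.g. a
    never-detected population) returns p = 1 by convention.
    """
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    return float(mannwhitneyu(x, y, alternative="two-sided", method="auto").pvalue)


def test_diet_responsive(
    pop_matrix: pd.DataFrame,
    seasons: pd.Series,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Test every population for an abundance shift between HF and HL.

    ``pop_matrix`` is populations x samples for one individual and one
    lifestyle; ``seasons`` maps sample id -> "HF"/"HL".  The BH family
    is the set of populations tested here.  Returns a table with p, q
    and the responsive flag (q < alpha).
    """
    seasons = seasons.reindex(pop_matrix.columns)
    if seasons.isna().any():
        raise InputError("season label missing for some samples")
    hf = pop_matrix.columns[seasons == "HF"]
    hl = pop_matrix.columns[seasons == "HL"]
    if len(hf) == 0 or len(hl) == 0:
        raise InputError("a season has no samples")
    if min(len(hf), len(hl)) < 3:
        warnings.warn("fewer than 3 samples in a season: test under-powered")
    pvals = [
        _rank_sum_p(pop_matrix.loc[pop, hf].to_numpy(float), pop_matrix.loc[pop, hl].to_numpy(float))
        for pop in pop_matrix.index
    ]
    q = bh_adjust(pvals)
    return pd.DataFrame(
        {
            "population": pop_matrix.index,
            "p": pvals,
            "q": q,
            "responsive": q < alpha,
        }
    ).set_index("population")


def abundance_variation(
    pop_matrix: pd.DataFrame,
    seasons: pd.Series,
    host_family: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Seasonal abundance change per population and per host family.

    delta = mean abundance in HL minus mean abundance in HF.  The family
    aggregate sums the deltas of populations linked to that family;
    populations without a host link stay in the per-population table but
    are excluded from the aggregate.
    """
    seasons = seasons.reindex(pop_matrix.columns)
    hf = pop_matrix.columns[seasons == "HF"]
    hl = pop_matrix.columns[seasons == "HL"]
    if len(hf) == 0 or len(hl) == 0:
        raise InputError("both seasons must be represented")
    delta = pop_matrix[hl].mean(axis=1) - pop_matrix[hf].mean(axis=1)
    per_pop = pd.DataFrame({"delta": delta})
    host_family = host_family or {}
    per_pop["host_family"] = [host_family.get(p) for p in per_pop.index]
    fam = per_pop.dropna(subset=["host_family"]).groupby("host_family")["delta"].sum()
    return per_pop, fam
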