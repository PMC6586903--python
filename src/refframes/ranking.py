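"""Differential ranking: ordering taxa by their relative differentials.

A fitted clr differential is known only up to an additive bias constant
log K = log(N_A/N_B) set by the unobserved total microbial loads, so its
*value* cannot say whether a taxon changed.  Its *rank* among all taxa is
invariant to K, and the *difference* between two taxa's differentials is the
load-free log-fold change of their ratio.  This module exposes exactly
those bias-free quantities — ranks, rank-plot data, and pairwise log-ratio
differences — and deliberately never classifies a taxon as "unchanged".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import DifferentialSet, FeatureTable

__all__ = [
    "RankResult",
    "rank_taxa",
    "rank_difference_to_logratio",
    "suggest_references",
    "export_rank_plot_data",
]

BIAS_CAVEAT = ("differentials are known only up to an additive bias constant "
               "log K; ranks and differences are bias-free, values are not")


@dataclass(frozen=True)
class RankResult:
    """Taxa ordered ascending by clr differential for one covariate.

    ``entries`` is a list of (taxon_id, clr_differential, rank) with rank 1
    for the most-decreasing taxon; exact ties are broken by taxon_id.  The
    ``caveat`` field restates that values carry the unknown load bias.
    """

    covariate: str
    entries: tuple[tuple[str, float, int], ...]
    tie_policy: str = "stable sort, ties broken by taxon_id"
    caveat: str = BIAS_CAVEAT

    def __post_init__(self):
        ranks = [e[2] for e in self.entries]
        if sorted(ranks) != list(range(1, len(self.entries) + 1)):
            raise ValueError("ranks must be a permutation of 1..D")
        vals = [e[1] for e in self.entries]
        if any(b < a for a, b in zip(vals, vals[1:])):
            raise ValueError("entries must be sorted ascending by differential")
        object.__setattr__(self, "entries", tuple(self.entries))

    @property
    def taxon_order(self) -> tuple[str, ...]:
        return tuple(e[0] for e in self.entries)

    def rank_of(self, taxon_id: str) -> int:
        for tid, _, r in self.entries:
            if tid == taxon_id:
                return r
        raise KeyError(f"taxon {taxon_id!r} not in rank result")


def _clr_column(diffs: DifferentialSet, covariate: str) -> pd.Series:
    if covariate not in diffs.covariate_names:
        raise KeyError(
            f"unknown covariate {covariate!r}; available: "
            f"{list(diffs.covariate_names)}")
    return diffs.clr_dataframe()[covariate]


def rank_taxa(diffs: DifferentialSet, covariate: str) -> RankResult:
    """Rank all taxa by their clr differential for one covariate.

    Rank 1 is the taxon decreasing the most relative to the others; rank D
    the one increasing the most.  Extremes at either end are the candidates
    for log-ratio numerators and denominators.
    """
    col = _clr_column(diffs, covariate)
    order = sorted(col.items(), key=lambda kv: (kv[1], kv[0]))
    entries = tuple((tid, float(v), i + 1) for i, (tid, v) in enumerate(order))
    return RankResult(covariate, entries)


def rank_difference_to_logratio(
    diffs: DifferentialSet, covariate: str, taxon_i: str, taxon_j: str
) -> float:
    """Log-fold change of the ratio taxon_i : taxon_j per unit covariate.

    clr_i - clr_j: the additive bias constant cancels, so this equals the
    same difference in any alr coordinate system and is directly
    interpretable on absolute abundances.
    """
    col = _clr_column(diffs, covariate)
    for t in (taxon_i, taxon_j):
        if t not in col.index:
            raise KeyError(f"taxon {t!r} not in differentials")
    return float(col[taxon_i] - col[taxon_j])


def suggest_references(
    table: FeatureTable,
    ranks: RankResult,
    prevalence_threshold: float = 0.9,
    band: float | None = None,
) -> pd.DataFrame:
    """Candidate reference taxa: prevalent, and mid-ranked.

    An ideal reference is present in most samples (so log-ratios rarely hit
    zeros) and sits away from the rank extremes (so it is plausibly stable
    across conditions).  Returns taxa with sample prevalence >=
    ``prevalence_threshold``, ordered by distance of rank from the median
    rank, ties by taxon_id.  ``band`` optionally restricts the output to
    the central quantile band of ranks of that width (e.g. 0.5 keeps the
    middle half).  An empty result is valid.
    """
    if not 0 < prevalence_threshold <= 1:
        raise ValueError("prevalence_threshold must be in (0, 1]")
    shared = set(table.taxon_ids) & set(ranks.taxon_order)
    prevalence = (table.counts > 0).mean(axis=0)
    prev = dict(zip(table.taxon_ids, prevalence))
    D = len(ranks.entries)
    median_rank = (D + 1) / 2.0
    rows = []
    for tid, _, r in ranks.entries:
        if tid not in shared or prev[tid] < prevalence_threshold:
            continue
        if band is not None:
            lo = median_rank - band * D / 2.0
            hi = median_rank + band * D / 2.0
            if not lo <= r <= hi:
                continue
        rows.append((tid, float(prev[tid]), r, abs(r - median_rank)))
    rows.sort(key=lambda row: (row[3], row[0]))
    return pd.DataFrame(rows, columns=["taxon_id", "prevalence", "rank",
                                       "distance_to_median_rank"])


def export_rank_plot_data(
    ranks: RankResult, highlight: set[str] | None = None
) -> pd.DataFrame:
    """Tabulate a rank plot: one row per taxon, sorted by differential.

    Columns: rank, clr_differential, taxon_id, highlighted.  Unknown
    highlight taxa trigger a warning and are ignored.
    """
    highlight = set() if highlight is None else set(highlight)
    known = set(ranks.taxon_order)
    unknown = sorted(highlight - known)
    if unknown:
        warnings.warn(f"highlight taxa not in rank result (ignored): {unknown}",
                      UserWarning, stacklevel=2)
    rows = [(r, v, tid, tid in highlight and tid in known)
            for tid, v, r in ranks.entries]
    return pd.DataFrame(rows, columns=["rank", "clr_differential", "taxon_id",
                                       "highlighted"])
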