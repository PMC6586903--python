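"""Reference-frame hypothesis tests on per-sample log-ratios.

The total microbial load N of a sample multiplies every taxon's abundance,
so it cancels from any within-sample ratio: log(a_i/a_j) computed from raw
counts, proportions, or flow-cytometry-scaled absolute abundances is the
same number.  Statistics built on such log-ratios — paired t-tests between
conditions, correlations with a clinical covariate — are therefore
scale-invariant and agree exactly between relative and absolute data.
Per-taxon tests on proportions do not have this property and are provided
here only as the explicitly labelled naive baseline.

Zeros make a log-ratio infinite; following the drop-as-missing policy, any
sample with a zero in the numerator or denominator set is removed from that
ratio and reported in ``dropped_sample_ids``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import FeatureTable

__all__ = [
    "LogRatioResult",
    "PairedTestResult",
    "AbsoluteAbundanceProfile",
    "compute_log_ratio",
    "paired_ttest",
    "correlate_with_covariate",
    "absolute_from_relative",
    "per_taxon_naive_tests",
]


@dataclass(frozen=True)
class LogRatioResult:
    """Per-sample log-ratios for one numerator/denominator taxon pair of sets."""

    sample_ids: tuple[str, ...]
    values: np.ndarray
    dropped_sample_ids: tuple[str, ...]
    numerator_ids: tuple[str, ...]
    denominator_ids: tuple[str, ...]
    aggregation: str = "geometric mean within each set"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError("log-ratio values must be finite")
        if v.size != len(self.sample_ids):
            raise ValueError("values must align with sample_ids")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "dropped_sample_ids",
                           tuple(str(s) for s in self.dropped_sample_ids))

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.sample_ids), name="log_ratio")


@dataclass(frozen=True)
class PairedTestResult:
    t_statistic: float
    p_value: float
    n_pairs: int
    mean_difference: float

    def __post_init__(self):
        if self.n_pairs < 2:
            raise ValueError("a paired t-test needs at least 2 pairs")
        if not 0 <= self.p_value <= 1:
            raise ValueError("p_value must be in [0, 1]")


@dataclass(frozen=True)
class AbsoluteAbundanceProfile:
    """Load-scaled (copy-number-corrected) abundances; rows sum to the load."""

    values: np.ndarray
    sample_ids: tuple[str, ...]
    taxon_ids: tuple[str, ...]
    load: np.ndarray = field(default=None)  # type: ignore[assignment]
    copy_numbers: np.ndarray | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or np.any(v < 0):
            raise ValueError("values must be a non-negative samples x taxa matrix")
        load = np.asarray(self.load, dtype=float)
        if load.shape != (v.shape[0],) or np.any(load <= 0):
            raise ValueError("load must be positive, one value per sample")
        if np.abs(v.sum(axis=1) - load).max() > 1e-8 * max(1.0, load.max()):
            raise ValueError("row sums must equal the per-sample load")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "load", load)
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "taxon_ids", tuple(str(t) for t in self.taxon_ids))


def _as_matrix(table) -> tuple[np.ndarray, list[str], list[str]]:
    if isinstance(table, FeatureTable):
        return table.counts.astype(float), list(table.sample_ids), list(table.taxon_ids)
    if isinstance(table, AbsoluteAbundanceProfile):
        return table.values, list(table.sample_ids), list(table.taxon_ids)
    raise TypeError("expected a FeatureTable or AbsoluteAbundanceProfile")


def compute_log_ratio(
    table: FeatureTable | AbsoluteAbundanceProfile,
    numerator: Sequence[str],
    denominator: Sequence[str],
) -> LogRatioResult:
    """Per-sample log(gm(numerator) / gm(denominator)), zeros dropped.

    ``gm`` is the geometric mean over the set's entries in that sample.  A
    sample with any zero entry in either set is dropped (the ratio would be
    +/- infinity) and recorded.  The result is identical whether the input
    holds counts, proportions, or absolute abundances of the same samples:
    the per-sample scale cancels.
    """
    num = [str(t) for t in numerator]
    den = [str(t) for t in denominator]
    if not num or not den:
        raise ValueError("numerator and denominator sets must be non-empty")
    overlap = sorted(set(num) & set(den))
    if overlap:
        raise ValueError(f"numerator and denominator overlap: {overlap}")
    mat, samples, taxa = _as_matrix(table)
    pos = {t: i for i, t in enumerate(taxa)}
    unknown = sorted((set(num) | set(den)) - set(pos))
    if unknown:
        raise KeyError(f"taxa not in table: {unknown}")
    ni = [pos[t] for t in num]
    di = [pos[t] for t in den]
    sub = mat[:, ni + di]
    ok = np.all(sub > 0, axis=1)
    if not ok.any():
        raise ValueError(
            "all samples dropped: numerator/denominator sets have zero "
            "coverage in every sample")
    with np.errstate(divide="ignore"):
        vals = (np.log(mat[ok][:, ni]).mean(axis=1)
                - np.log(mat[ok][:, di]).mean(axis=1))
    kept = [s for s, k in zip(samples, ok) if k]
    dropped = [s for s, k in zip(samples, ok) if not k]
    return LogRatioResult(tuple(kept), vals, tuple(dropped), tuple(num), tuple(den))


def _paired_differences(
    before: LogRatioResult,
    after: LogRatioResult,
    pairing: Mapping[str, str],
) -> np.ndarray:
    b = before.to_series()
    a = after.to_series()
    diffs = []
    for sb, sa in pairing.items():
        sb, sa = str(sb), str(sa)
        if sb in b.index and sa in a.index:
            diffs.append(a[sa] - b[sb])
    return np.asarray(diffs, dtype=float)


def paired_ttest(
    before: LogRatioResult,
    after: LogRatioResult,
    pairing: Mapping[str, str],
) -> PairedTestResult:
    """Two-sided paired t-test on after-minus-before log-ratio differences.

    ``pairing`` maps each before-sample id to its after-sample id (e.g. both
    sides of one subject).  Pairs where either side was dropped for zeros
    are excluded.
    """
    d = _paired_differences(before, after, pairing)
    if d.size < 2:
        raise ValueError(f"need >= 2 complete pairs, got {d.size}")
    if np.allclose(d, d[0]):
        raise ValueError("degenerate test: paired differences have zero variance")
    t, p = stats.ttest_1samp(d, 0.0)
    return PairedTestResult(float(t), float(p), int(d.size), float(d.mean()))


def correlate_with_covariate(
    ratios: LogRatioResult,
    covariate: Mapping[str, float] | pd.Series,
    method: str = "pearson",
) -> tuple[float, float]:
    """Correlate per-sample log-ratios with a continuous covariate.

    Only retained (non-dropped) samples with covariate values enter.
    Returns (r, p_value) from the Pearson or Spearman test.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    cov = pd.Series(covariate)
    cov.index = cov.index.astype(str)
    s = ratios.to_series()
    common = [sid for sid in s.index if sid in cov.index]
    if len(common) < 3:
        raise ValueError("need >= 3 retained samples with covariate values")
    x = s[common].to_numpy()
    y = cov[common].astype(float).to_numpy()
    if np.allclose(y, y[0]):
        raise ValueError("constant covariate: correlation undefined")
    if np.allclose(x, x[0]):
        raise ValueError("constant log-ratios: correlation undefined")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    else:
        r, p = stats.spearmanr(x, y)
    return float(r), float(p)


def absolute_from_relative(
    table: FeatureTable,
    load: Mapping[str, float] | pd.Series | np.ndarray,
    copy_numbers: Mapping[str, float] | pd.Series | np.ndarray | None = None,
) -> AbsoluteAbundanceProfile:
    """Reconstruct absolute abundances: load x copy-corrected proportions.

    Counts are divided elementwise by per-taxon copy numbers (when given),
    re-closed to proportions within each sample, and multiplied by that
    sample's externally measured total load (e.g. flow-cytometry cell
    counts).  Row sums equal the load by construction.
    """
    counts = table.counts.astype(float)
    if isinstance(load, (pd.Series, Mapping)):
        load_s = pd.Series(load)
        load_s.index = load_s.index.astype(str)
        missing = [s for s in table.sample_ids if s not in load_s.index]
        if missing:
            raise KeyError(f"samples missing from load: {missing}")
        load_v = load_s[list(table.sample_ids)].astype(float).to_numpy()
    else:
        load_v = np.asarray(load, dtype=float)
        if load_v.shape != (table.n_samples,):
            raise ValueError("load must have one value per sample")
    if np.any(load_v <= 0):
        raise ValueError("load values must be positive")

    cn_v = None
    if copy_numbers is not None:
        if isinstance(copy_numbers, (pd.Series, Mapping)):
            cn_s = pd.Series(copy_numbers)
            cn_s.index = cn_s.index.astype(str)
            missing = [t for t in table.taxon_ids if t not in cn_s.index]
            if missing:
                raise KeyError(f"taxa missing from copy_numbers: {missing}")
            cn_v = cn_s[list(table.taxon_ids)].astype(float).to_numpy()
        else:
            cn_v = np.asarray(copy_numbers, dtype=float)
            if cn_v.shape != (table.n_taxa,):
                raise ValueError("copy_numbers must have one value per taxon")
        if np.any(cn_v <= 0):
            raise ValueError("copy numbers must be positive")
        counts = counts / cn_v

    totals = counts.sum(axis=1)
    if np.any(totals <= 0):
        raise ValueError("zero-total sample after copy-number correction")
    values = counts / totals[:, None] * load_v[:, None]
    return AbsoluteAbundanceProfile(values, table.sample_ids, table.taxon_ids,
                                    load_v, cn_v)


def per_taxon_naive_tests(
    table_before: FeatureTable | AbsoluteAbundanceProfile,
    table_after: FeatureTable | AbsoluteAbundanceProfile,
    pairing: Mapping[str, str],
    fdr: bool = False,
) -> pd.DataFrame:
    """Naive per-taxon paired t-tests on closed proportions (or absolutes).

    One two-sided paired t-test per taxon on its per-sample proportion
    (FeatureTable input) or absolute value (AbsoluteAbundanceProfile
    input).  On relative data these tests are biased by the unobserved
    total load — the output carries the column ``reference_frame`` set to
    ``"none (biased by total load)"`` to make that explicit.  Taxa with
    fewer than 2 complete pairs or zero-variance differences are flagged in
    the ``flag`` column and given NaN statistics.  ``fdr=True`` adds
    Benjamini-Hochberg-adjusted q-values.
    """
    mb, sb, tb = _as_matrix(table_before)
    ma, sa, ta = _as_matrix(table_after)
    if tb != ta:
        raise ValueError("before/after tables must share taxon order")
    if isinstance(table_before, FeatureTable):
        mb = mb / mb.sum(axis=1, keepdims=True)
        ma = ma / ma.sum(axis=1, keepdims=True)
    bi = {s: i for i, s in enumerate(sb)}
    ai = {s: i for i, s in enumerate(sa)}
    pairs = [(bi[str(x)], ai[str(y)]) for x, y in pairing.items()
             if str(x) in bi and str(y) in ai]
    if not pairs:
        raise ValueError("no complete pairs between the two tables")
    rows_b = [p[0] for p in pairs]
    rows_a = [p[1] for p in pairs]
    diffs = ma[rows_a] - mb[rows_b]  # pairs x taxa

    out = []
    for j, taxon in enumerate(tb):
        d = diffs[:, j]
        if d.size < 2:
            out.append((taxon, np.nan, np.nan, d.size, "insufficient pairs"))
        elif np.allclose(d, d[0]):
            # identical before/after values: t = 0 when the shared value is 0
            if np.allclose(d, 0):
                out.append((taxon, 0.0, 1.0, d.size, "zero differences"))
            else:
                out.append((taxon, np.nan, np.nan, d.size, "zero variance"))
        else:
            t, p = stats.ttest_1samp(d, 0.0)
            out.append((taxon, float(t), float(p), d.size, ""))
    df = pd.DataFrame(out, columns=["taxon_id", "t_statistic", "p_value",
                                    "n_pairs", "flag"])
    df["reference_frame"] = "none (biased by total load)"
    if fdr:
        mask = df["p_value"].notna()
        q = np.full(len(df), np.nan)
        if mask.any():
            q[mask.to_numpy()] = stats.false_discovery_control(
                df.loc[mask, "p_value"].to_numpy())
        df["q_value"] = q
    return df
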