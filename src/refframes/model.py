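"""MAP multinomial regression for relative differentials.

The generative model for a count vector Y_i at covariates X_i is

    beta_jk ~ Normal(0, prior_scale)
    eta_i   = alr_inverse(X_i beta)
    Y_i     ~ Multinomial(N_i, eta_i)

where beta is a (D-1) x k matrix of coefficients in alr coordinates.  The
fitted non-intercept columns of beta are *relative differentials*: per-unit
log-fold changes of each taxon relative to the alr reference, known only up
to the unobserved total-load bias constant log K.  Their clr view (center
the alr vector after prepending a zero for the reference) re-expresses the
same differentials against the "average microbe", and their ranking is
invariant to K.

Estimation is maximum a posteriori via mini-batch stochastic gradient
descent on the (1/n-scaled) negative log posterior; the multinomial
normalization constant is dropped since it does not depend on beta.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .transforms import alr_inverse, clr_from_alr

__all__ = [
    "FeatureTable",
    "DesignMatrix",
    "FitConfig",
    "DifferentialSet",
    "build_design_matrix",
    "negative_log_posterior",
    "fit_map",
    "predict_proportions",
]


@dataclass(frozen=True)
class FeatureTable:
    """A samples x taxa matrix of non-negative integer counts."""

    counts: np.ndarray
    sample_ids: tuple[str, ...]
    taxon_ids: tuple[str, ...]

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.ndim != 2:
            raise ValueError("counts must be a 2-d samples x taxa matrix")
        if not np.issubdtype(c.dtype, np.integer):
            if np.any(c != np.round(c)):
                raise ValueError("counts must be integral")
            c = c.astype(np.int64)
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        sids = tuple(str(s) for s in self.sample_ids)
        tids = tuple(str(t) for t in self.taxon_ids)
        if len(sids) != c.shape[0] or len(tids) != c.shape[1]:
            raise ValueError("identifier lengths must match the count matrix")
        if len(set(sids)) != len(sids):
            raise ValueError("sample_ids must be unique")
        if len(set(tids)) != len(tids):
            raise ValueError("taxon_ids must be unique")
        if np.any(c.sum(axis=1) < 1):
            empty = [sids[i] for i in np.nonzero(c.sum(axis=1) < 1)[0]]
            raise ValueError(f"samples with zero total count: {empty}")
        object.__setattr__(self, "counts", c)
        object.__setattr__(self, "sample_ids", sids)
        object.__setattr__(self, "taxon_ids", tids)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    def filter_taxa(self, min_samples: int) -> "FeatureTable":
        """Keep taxa present (count > 0) in at least ``min_samples`` samples."""
        keep = (self.counts > 0).sum(axis=0) >= min_samples
        if not keep.any():
            raise ValueError("min_samples filter removed every taxon")
        return FeatureTable(
            self.counts[:, keep],
            self.sample_ids,
            tuple(t for t, k in zip(self.taxon_ids, keep) if k),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.sample_ids),
                            columns=list(self.taxon_ids))


@dataclass(frozen=True)
class DesignMatrix:
    """Encoded covariates, one row per sample, intercept first."""

    matrix: np.ndarray
    column_names: tuple[str, ...]
    sample_ids: tuple[str, ...]
    encoding_map: dict = field(default_factory=dict)

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2:
            raise ValueError("design matrix must be 2-d")
        if not np.allclose(m[:, 0], 1.0):
            raise ValueError("first design column must be the intercept (all ones)")
        if len(self.column_names) != m.shape[1]:
            raise ValueError("column_names must match matrix width")
        if len(self.sample_ids) != m.shape[0]:
            raise ValueError("sample_ids must match matrix height")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "column_names", tuple(self.column_names))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        if np.linalg.matrix_rank(m) < m.shape[1]:
            warnings.warn("design matrix is rank deficient; the prior will "
                          "regularize the fit", UserWarning, stacklevel=2)

    @property
    def n_covariates(self) -> int:
        return self.matrix.shape[1]


@dataclass(frozen=True)
class FitConfig:
    """Optimizer settings for the MAP fit.

    prior_scale is the standard deviation of the zero-centered normal prior
    on every coefficient.  batch_size defaults to min(n, 32) at fit time
    when left as None.
    """

    prior_scale: float = 1.0
    learning_rate: float = 1e-3
    batch_size: int | None = None
    epochs: int = 1000
    seed: int = 0
    convergence_tol: float = 1e-6

    def __post_init__(self):
        if self.prior_scale <= 0:
            raise ValueError("prior_scale must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size is not None and self.batch_size < 1:
            raise ValueError("batch_size must be a positive integer")
        if self.epochs < 1:
            raise ValueError("epochs must be a positive integer")
        if self.convergence_tol < 0:
            raise ValueError("convergence_tol must be non-negative")


@dataclass(frozen=True)
class DifferentialSet:
    """Fitted coefficients beta in alr coordinates, with clr/ilr views."""

    alr_coefficients: np.ndarray  # (D-1) x k
    reference_taxon: str
    covariate_names: tuple[str, ...]
    taxon_ids: tuple[str, ...]
    fit_diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        b = np.asarray(self.alr_coefficients, dtype=float)
        if b.ndim != 2:
            raise ValueError("alr_coefficients must be (D-1) x k")
        if b.shape[0] != len(self.taxon_ids) - 1:
            raise ValueError("coefficient rows must be D-1 for D taxa")
        if b.shape[1] != len(self.covariate_names):
            raise ValueError("coefficient columns must match covariate_names")
        if self.reference_taxon not in self.taxon_ids:
            raise ValueError("reference_taxon must be one of taxon_ids")
        object.__setattr__(self, "alr_coefficients", b)
        object.__setattr__(self, "covariate_names", tuple(self.covariate_names))
        object.__setattr__(self, "taxon_ids", tuple(self.taxon_ids))

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    def clr_coefficients(self) -> np.ndarray:
        """D x k matrix of clr differentials, rows ordered as taxon_ids.

        The alr reference occupies its original position; each column sums
        to zero.
        """
        ref = self.taxon_ids.index(self.reference_taxon)
        out = np.empty((self.n_taxa, len(self.covariate_names)))
        for k in range(out.shape[1]):
            c = clr_from_alr(self.alr_coefficients[:, k]).values
            # clr_from_alr puts the reference first; restore table order
            col = np.empty(self.n_taxa)
            col[ref] = c[0]
            col[np.arange(self.n_taxa) != ref] = c[1:]
            out[:, k] = col
        return out

    def clr_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.clr_coefficients(), index=list(self.taxon_ids),
                            columns=list(self.covariate_names))


def build_design_matrix(
    metadata: pd.DataFrame,
    covariates: Sequence[tuple[str, str]] | Sequence[str],
    sample_ids: Sequence[str] | None = None,
    center_continuous: bool = False,
) -> DesignMatrix:
    """Encode declared covariates into a design matrix with an intercept.

    Parameters
    ----------
    metadata
        Sample-indexed table of covariates.
    covariates
        Ordered ``(name, kind)`` pairs with kind in {"categorical",
        "continuous"}; bare names infer kind from the column dtype.
        Each categorical covariate with L levels yields L-1 indicator
        columns against a reference level, the first level in order of
        appearance.
    sample_ids
        Sample order to encode (default: metadata order).  Every id must be
        present in the metadata.
    center_continuous
        Subtract the mean from continuous covariates.
    """
    if sample_ids is None:
        sample_ids = list(metadata.index.astype(str))
    else:
        sample_ids = [str(s) for s in sample_ids]
        missing = [s for s in sample_ids if s not in metadata.index.astype(str)]
        if missing:
            raise KeyError(f"samples missing from metadata: {missing}")
    md = metadata.copy()
    md.index = md.index.astype(str)
    md = md.loc[sample_ids]

    declared: list[tuple[str, str]] = []
    for cov in covariates:
        if isinstance(cov, str):
            if cov not in md.columns:
                raise KeyError(f"covariate {cov!r} not in metadata columns "
                               f"{list(md.columns)}")
            kind = "continuous" if pd.api.types.is_numeric_dtype(md[cov]) else "categorical"
            declared.append((cov, kind))
        else:
            name, kind = cov
            if name not in md.columns:
                raise KeyError(f"covariate {name!r} not in metadata columns "
                               f"{list(md.columns)}")
            if kind not in ("categorical", "continuous"):
                raise ValueError(f"covariate kind must be categorical or continuous, "
                                 f"got {kind!r}")
            declared.append((name, kind))

    cols = [np.ones(len(md))]
    names = ["Intercept"]
    encoding: dict = {}
    for name, kind in declared:
        series = md[name]
        if series.isna().any():
            bad = list(series.index[series.isna()])
            raise ValueError(f"covariate {name!r} has missing values for samples {bad}")
        if kind == "continuous":
            vals = series.astype(float).to_numpy()
            if center_continuous:
                vals = vals - vals.mean()
            cols.append(vals)
            names.append(name)
        else:
            levels = list(pd.unique(series.astype(str)))
            if len(levels) < 2:
                raise ValueError(f"categorical covariate {name!r} has a single "
                                 f"level {levels!r}")
            reference, rest = levels[0], levels[1:]
            encoding[name] = {"reference": reference,
                              "columns": {lv: f"{name}[{lv}]" for lv in rest}}
            for lv in rest:
                cols.append((series.astype(str) == lv).astype(float).to_numpy())
                names.append(f"{name}[{lv}]")
    return DesignMatrix(np.column_stack(cols), tuple(names), tuple(sample_ids), encoding)


def _eta(beta: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Row-wise alr_inverse(X beta): n x D matrix of proportions."""
    z = X @ beta.T  # n x (D-1)
    z = np.concatenate([np.zeros((z.shape[0], 1)), z], axis=1)
    z -= z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def negative_log_posterior(
    beta: np.ndarray,
    design: DesignMatrix | np.ndarray,
    table: FeatureTable | np.ndarray,
    prior_scale: float,
) -> float:
    """Unnormalized negative log posterior of the multinomial model.

    Sum over samples of -sum_j Y_ij log eta_ij plus the Gaussian penalty
    sum beta^2 / (2 prior_scale^2); the multinomial coefficient is omitted
    as an additive constant.  The count matrix is taken in alr order: column
    0 is the reference taxon.
    """
    X = design.matrix if isinstance(design, DesignMatrix) else np.asarray(design, float)
    Y = table.counts if isinstance(table, FeatureTable) else np.asarray(table, float)
    beta = np.asarray(beta, dtype=float)
    if not np.all(np.isfinite(beta)):
        raise ValueError("beta must be finite")
    if np.any(Y.sum(axis=1) < 1):
        raise ValueError("every sample must have total count >= 1")
    if beta.shape != (Y.shape[1] - 1, X.shape[1]):
        raise ValueError(
            f"beta must be (D-1) x k = {(Y.shape[1]-1, X.shape[1])}, got {beta.shape}")
    eta = _eta(beta, X)
    nll = -float(np.sum(Y * np.log(eta)))
    prior = float(np.sum(beta**2)) / (2.0 * prior_scale**2)
    return nll + prior


def fit_map(
    table: FeatureTable,
    design: DesignMatrix,
    config: FitConfig = FitConfig(),
    reference_taxon: str | None = None,
) -> DifferentialSet:
    """MAP-fit the multinomial regression by mini-batch gradient descent.

    The optimizer minimizes the negative log posterior scaled by 1/n (a
    per-sample mean likelihood plus prior/n), whose argmin equals the MAP;
    the scaling keeps the fixed learning rate stable across sample sizes.
    Batches are sampled without replacement each epoch; beta starts at the
    prior mode (zero); convergence is declared when the relative change of
    the full objective over a 10-epoch window drops below
    ``config.convergence_tol``.  Bit-for-bit reproducible from the config.
    """
    if tuple(design.sample_ids) != tuple(table.sample_ids):
        raise ValueError("design matrix and feature table sample order differ")
    n, D = table.counts.shape
    k = design.n_covariates
    if n < k:
        raise ValueError(f"need at least as many samples ({n}) as covariates ({k})")

    if reference_taxon is None:
        ref_idx = 0
    else:
        if reference_taxon not in table.taxon_ids:
            raise KeyError(f"reference taxon {reference_taxon!r} not in table")
        ref_idx = table.taxon_ids.index(reference_taxon)
    order = [ref_idx] + [j for j in range(D) if j != ref_idx]
    Y = table.counts[:, order].astype(float)
    X = design.matrix
    sigma2 = config.prior_scale**2
    batch = min(n, 32) if config.batch_size is None else min(config.batch_size, n)
    lr = config.learning_rate

    rng = np.random.default_rng(config.seed)
    beta = np.zeros((D - 1, k))
    trace = []
    obj = negative_log_posterior(beta, X, Y, config.prior_scale) / n
    trace.append(obj)
    epochs_run = 0
    converged = False
    for epoch in range(config.epochs):
        perm = rng.permutation(n)
        for start in range(0, n, batch):
            idx = perm[start:start + batch]
            Xb, Yb = X[idx], Y[idx]
            eta = _eta(beta, Xb)
            Nb = Yb.sum(axis=1, keepdims=True)
            # gradient step on the mean NLL, then an exact (proximal)
            # shrink for the quadratic prior — stable for any prior_scale
            resid = Nb * eta[:, 1:] - Yb[:, 1:]  # batch x (D-1)
            beta = (beta - lr * resid.T @ Xb / idx.size) \
                / (1.0 + lr / (sigma2 * n))
        if not np.all(np.isfinite(beta)):
            raise FloatingPointError(
                "optimization diverged (non-finite coefficients); "
                "try a smaller learning_rate")
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            obj = negative_log_posterior(beta, X, Y, config.prior_scale) / n
        if not np.isfinite(obj):
            raise FloatingPointError(
                "optimization diverged (non-finite objective); "
                "try a smaller learning_rate")
        trace.append(obj)
        epochs_run = epoch + 1
        if epoch >= 10:
            prev, cur = trace[-11], trace[-1]
            denom = max(abs(prev), 1e-12)
            if abs(prev - cur) / denom < config.convergence_tol:
                converged = True
                break

    taxa = [table.taxon_ids[j] for j in order]
    diagnostics = {
        "final_objective": trace[-1] * n,
        "objective_trace": np.asarray(trace) * n,
        "epochs_run": epochs_run,
        "converged": converged,
        "seed": config.seed,
        "batch_size": batch,
    }
    return DifferentialSet(beta, table.taxon_ids[ref_idx], design.column_names,
                           tuple(taxa), diagnostics)


def predict_proportions(diffs: DifferentialSet, design_row: Sequence[float]):
    """Predicted composition alr_inverse(x beta) for one covariate row."""
    x = np.asarray(design_row, dtype=float)
    if x.shape != (len(diffs.covariate_names),):
        raise ValueError(
            f"design_row must have length {len(diffs.covariate_names)}, "
            f"got {x.shape}")
    return alr_inverse(diffs.alr_coefficients @ x, labels=diffs.taxon_ids)
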