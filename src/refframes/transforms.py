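"""Log-ratio coordinate transforms for compositional data.

Relative-abundance data live on the simplex: only ratios between parts are
informative, because the total microbial load of a sample is lost during
sequencing.  The additive log-ratio (alr) transform maps a D-part
composition to unconstrained Euclidean coordinates by taking logs against a
designated reference part; its inverse is a softmax with a zero prepended
for the reference.  The centered log-ratio (clr) divides by the geometric
mean instead, giving a symmetric, zero-sum view; the isometric log-ratio
(ilr) projects clr coordinates onto an orthonormal contrast basis so that
Euclidean geometry in the coordinates matches Aitchison geometry on the
simplex.

Everything here is pure and rejects zeros outright: sampling zeros are a
modelling concern (the multinomial likelihood handles them natively, the
log-ratio tests drop affected samples) and do not belong in the math layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Composition",
    "LogRatioCoordinates",
    "OrthonormalBasis",
    "closure",
    "alr",
    "alr_inverse",
    "clr",
    "clr_from_alr",
    "build_orthonormal_basis",
    "ilr",
]

_ATOL = 1e-10


def _default_labels(n: int, prefix: str = "t") -> tuple[str, ...]:
    return tuple(f"{prefix}{i}" for i in range(n))


@dataclass(frozen=True)
class Composition:
    """A point on the simplex: strictly positive parts summing to one.

    Parameters
    ----------
    values
        Strictly positive proportions, length >= 2, summing to 1.
    labels
        Taxon identifiers aligned to ``values``; generated if omitted.
    """

    values: np.ndarray
    labels: tuple[str, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("a composition needs at least 2 parts")
        if not np.all(np.isfinite(v)):
            raise ValueError("composition values must be finite")
        bad = np.nonzero(v <= 0)[0]
        if bad.size:
            raise ValueError(
                f"composition parts must be strictly positive; "
                f"offending indices: {bad[:5].tolist()}"
            )
        if abs(v.sum() - 1.0) > _ATOL:
            raise ValueError(f"composition must sum to 1 (got {v.sum()!r})")
        object.__setattr__(self, "values", v)
        labels = self.labels
        if labels is None:
            labels = _default_labels(v.size)
        labels = tuple(str(x) for x in labels)
        if len(labels) != v.size:
            raise ValueError("labels must align with values")
        object.__setattr__(self, "labels", labels)

    @property
    def size(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class LogRatioCoordinates:
    """Real-valued coordinates of a composition in a log-ratio system.

    ``coordinate_system`` is one of ``{"alr", "clr", "ilr"}``.  alr
    coordinates record the reference taxon; ilr coordinates record the
    identifier of the basis used.
    """

    values: np.ndarray
    coordinate_system: str
    reference_label: str | None = None
    basis_id: str | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if self.coordinate_system not in ("alr", "clr", "ilr"):
            raise ValueError(f"unknown coordinate system {self.coordinate_system!r}")
        if not np.all(np.isfinite(v)):
            raise ValueError("log-ratio coordinates must be finite")
        if self.coordinate_system == "clr" and abs(v.sum()) > 1e-8:
            raise ValueError("clr coordinates must sum to 0")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class OrthonormalBasis:
    """A (D-1) x D orthonormal contrast matrix Psi.

    Rows are unit norm, mutually orthogonal, and orthogonal to the ones
    vector, so ``Psi @ clr(x)`` yields ilr coordinates (balances).
    """

    matrix: np.ndarray
    taxon_labels: tuple[str, ...]
    basis_id: str = "sbp-balanced"

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1] - 1:
            raise ValueError("basis must be (D-1) x D")
        d = m.shape[1]
        if np.abs(m @ m.T - np.eye(d - 1)).max() > _ATOL:
            raise ValueError("basis rows must be orthonormal")
        if np.abs(m @ np.ones(d)).max() > _ATOL:
            raise ValueError("basis rows must be orthogonal to the ones vector")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "taxon_labels", tuple(str(x) for x in self.taxon_labels))
        if len(self.taxon_labels) != d:
            raise ValueError("taxon_labels must have D entries")


def closure(x: Sequence[float] | np.ndarray, labels: Sequence[str] | None = None) -> Composition:
    """Project a strictly positive vector onto the simplex (divide by sum)."""
    v = np.asarray(x, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("closure requires a 1-d vector of length >= 2")
    if not np.all(np.isfinite(v)):
        raise ValueError("closure requires finite input")
    bad = np.nonzero(v <= 0)[0]
    if bad.size:
        raise ValueError(
            f"closure requires strictly positive entries; "
            f"offending indices: {bad[:5].tolist()}"
        )
    return Composition(v / v.sum(), None if labels is None else tuple(labels))


def alr(p: Composition, reference: int | str = 0) -> LogRatioCoordinates:
    """Additive log-ratio transform against a designated reference part.

    Returns log(x_j / x_ref) for every non-reference part j, in table order
    with the reference removed.  Default reference: the first part.
    """
    if isinstance(reference, str):
        try:
            ref_idx = p.labels.index(reference)
        except ValueError:
            raise KeyError(f"reference taxon {reference!r} not in composition") from None
    else:
        ref_idx = int(reference)
        if not 0 <= ref_idx < p.size:
            raise IndexError(f"reference index {ref_idx} out of range for D={p.size}")
    v = p.values
    logv = np.log(v)
    coords = np.delete(logv - logv[ref_idx], ref_idx)
    return LogRatioCoordinates(coords, "alr", reference_label=p.labels[ref_idx])


def alr_inverse(
    coords: LogRatioCoordinates | np.ndarray,
    labels: Sequence[str] | None = None,
) -> Composition:
    """Inverse alr: the degenerate softmax C[exp(0, x_1, ..., x_{D-1})].

    The first output part corresponds to the reference.
    """
    v = coords.values if isinstance(coords, LogRatioCoordinates) else np.asarray(coords, float)
    if v.ndim != 1:
        raise ValueError("alr coordinates must be a 1-d vector")
    if not np.all(np.isfinite(v)):
        raise ValueError("alr coordinates must be finite")
    z = np.concatenate(([0.0], v))
    z -= z.max()  # overflow guard; closure is shift-invariant
    e = np.exp(z)
    return Composition(e / e.sum(), None if labels is None else tuple(labels))


def clr(p: Composition) -> LogRatioCoordinates:
    """Centered log-ratio transform: log parts over their geometric mean."""
    logv = np.log(p.values)
    return LogRatioCoordinates(logv - logv.mean(), "clr")


def clr_from_alr(coords: LogRatioCoordinates | np.ndarray) -> LogRatioCoordinates:
    """Re-express alr coordinates in clr form: clr(alr_inverse(x)).

    Algebraically this prepends a zero and centers, but it is computed via
    the definition to keep the two transforms independently testable.
    """
    return clr(alr_inverse(coords))


def build_orthonormal_basis(D: int, labels: Sequence[str] | None = None) -> OrthonormalBasis:
    """Deterministic default orthonormal contrast basis for D parts.

    Uses the sequential binary partition of a balanced bifurcation of the
    parts in table order: each internal split contrasts its left block
    against its right block with the standard balance weights
    ``+sqrt(s/(r(r+s)))`` on the r left parts and ``-sqrt(r/(s(r+s)))`` on
    the s right parts.  Such rows are orthonormal by construction.
    """
    D = int(D)
    if D < 2:
        raise ValueError("an orthonormal basis requires D >= 2")
    rows = []

    def split(lo: int, hi: int):
        # balanced bifurcation over parts [lo, hi)
        n = hi - lo
        if n < 2:
            return
        mid = lo + (n + 1) // 2
        r, s = mid - lo, hi - mid
        row = np.zeros(D)
        row[lo:mid] = np.sqrt(s / (r * (r + s)))
        row[mid:hi] = -np.sqrt(r / (s * (r + s)))
        rows.append(row)
        split(lo, mid)
        split(mid, hi)

    split(0, D)
    psi = np.array(rows)
    if labels is None:
        labels = _default_labels(D)
    return OrthonormalBasis(psi, tuple(labels))


def ilr(
    coords: LogRatioCoordinates | np.ndarray,
    basis: OrthonormalBasis,
) -> LogRatioCoordinates:
    """Isometric log-ratio coordinates: Psi @ clr_from_alr(alr coords)."""
    c = clr_from_alr(coords)
    if c.values.size != basis.matrix.shape[1]:
        raise ValueError(
            f"dimension mismatch: alr coordinates imply D={c.values.size} "
            f"but basis has D={basis.matrix.shape[1]} columns"
        )
    return LogRatioCoordinates(basis.matrix @ c.values, "ilr", basis_id=basis.basis_id)
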