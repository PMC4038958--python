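"""Ordered cumulative score processes.

Observations are sorted by an auxiliary variable V (continuous, ordinal, or
categorical) and the casewise scores are accumulated into the decorrelated
empirical fluctuation process

    B(t) = Ihat^{-1/2} n^{-1/2} sum_{i <= floor(nt)} s(theta_hat; x_(i)),

whose rows (t = 0, 1/n, ..., 1) approximate a k-dimensional Brownian bridge
under parameter stability.  Decorrelation always uses the full k x k
information; testing a parameter subset selects columns *after*
decorrelation, mirroring the semantics of testing part of a jointly
estimated model.

For ordinal/categorical V the tie structure is recorded: level counts,
cumulative proportions ``t_l`` and boundary indices ``i_l = floor(n t_l)``.
Statistics that only read the boundary rows are exactly invariant to
reordering observations within a level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

__all__ = [
    "AuxiliaryOrdering",
    "OrdinalGrouping",
    "CumulativeProcess",
    "RankDeficiencyError",
    "order_observations",
    "matrix_inverse_sqrt",
    "empirical_process",
]


class RankDeficiencyError(np.linalg.LinAlgError):
    """Information matrix is (numerically) singular."""


@dataclass(frozen=True)
class OrdinalGrouping:
    """Tie structure of an ordinal/categorical auxiliary variable."""

    m: int
    counts: np.ndarray          # length m, per-level counts
    t: np.ndarray               # length m-1, cumulative proportions
    i: np.ndarray               # length m-1, boundary indices floor(n * t_l)
    n: int

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("need at least one level")
        if self.counts.sum() != self.n:
            raise ValueError("level counts do not sum to n")
        if self.m > 1 and not (np.all(np.diff(self.i) > 0) and 0 < self.i[0] and self.i[-1] < self.n):
            raise ValueError("boundary indices must be strictly increasing inside (0, n)")


@dataclass(frozen=True)
class AuxiliaryOrdering:
    """A sort of the observations by the auxiliary variable, with tie blocks."""

    treatment: str              # continuous | ordinal | categorical
    perm: np.ndarray            # permutation of 0..n-1 (stable within ties)
    bounds: np.ndarray          # cumulative block boundaries, [0, ..., n]
    levels: np.ndarray          # block labels (unique values, in block order)

    @property
    def n(self) -> int:
        return len(self.perm)

    @property
    def has_ties(self) -> bool:
        return bool(np.any(np.diff(self.bounds) > 1))

    def grouping(self) -> OrdinalGrouping:
        counts = np.diff(self.bounds)
        n = self.n
        t = self.bounds[1:-1] / n
        # i_l = floor(n t_l) computed exactly: t_l is the rational cum-count/n
        i = self.bounds[1:-1].astype(int)
        return OrdinalGrouping(m=len(counts), counts=counts, t=t, i=i, n=n)


def order_observations(V, treatment: str = "ordinal") -> AuxiliaryOrdering:
    """Sort observations by the auxiliary variable.

    ``continuous`` uses a stable sort (ties keep input order — an arbitrary
    choice that downstream continuous statistics depend on); ``ordinal``
    sorts by level and records tie blocks; ``categorical`` forms blocks in
    level order (the order of blocks is immaterial to the unordered LM
    statistic).  Ordered pandas Categoricals keep their declared order.
    """
    if treatment not in ("continuous", "ordinal", "categorical"):
        raise ValueError(f"unknown treatment {treatment!r}")
    if isinstance(V, pd.Series) and isinstance(V.dtype, pd.CategoricalDtype):
        codes = V.cat.codes.to_numpy()
        if (codes < 0).any():
            raise ValueError("auxiliary variable contains missing values")
        present = np.unique(codes)
        levels = np.asarray(V.cat.categories, dtype=object)[present]
        keys = np.searchsorted(present, codes)
    else:
        arr = pd.Series(V).to_numpy()
        if pd.isna(arr).any():
            raise ValueError("auxiliary variable contains missing values")
        if treatment == "continuous" and not np.issubdtype(arr.dtype, np.number):
            raise ValueError("continuous treatment requires a numeric auxiliary variable")
        levels, keys = np.unique(arr, return_inverse=True)
        levels = np.asarray(levels, dtype=object)
    perm = np.argsort(keys, kind="stable")
    sorted_keys = keys[perm]
    # block boundaries from runs of equal values
    change = np.flatnonzero(np.diff(sorted_keys)) + 1
    bounds = np.concatenate(([0], change, [len(perm)]))
    return AuxiliaryOrdering(treatment=treatment, perm=perm, bounds=bounds,
                             levels=levels)


def matrix_inverse_sqrt(M: np.ndarray, tol: float = 1e-10,
                        labels=None) -> np.ndarray:
    """Symmetric inverse square root R with R M R = I.

    Raises :class:`RankDeficiencyError` when any eigenvalue falls below
    ``tol`` times the largest, naming the parameters with the heaviest
    weight in the offending eigenvectors.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("M must be square")
    if not np.allclose(M, M.T, atol=1e-8):
        raise ValueError("M must be symmetric (within 1e-8)")
    lam, V = linalg.eigh(M)
    lmax = lam.max() if lam.size else 0.0
    bad = lam < tol * max(lmax, np.finfo(float).tiny)
    if bad.any():
        culprits = []
        for idx in np.flatnonzero(bad):
            j = int(np.argmax(np.abs(V[:, idx])))
            culprits.append(labels[j] if labels is not None else f"parameter {j}")
        raise RankDeficiencyError(
            "information matrix is rank deficient; offending directions load on: "
            + ", ".join(sorted(set(culprits))))
    return (V / np.sqrt(lam)) @ V.T


@dataclass(frozen=True)
class CumulativeProcess:
    """The (n+1) x k decorrelated cumulative score process (row 0 = 0)."""

    B: np.ndarray
    labels: tuple[str, ...]
    ordering: AuxiliaryOrdering

    @property
    def n(self) -> int:
        return self.B.shape[0] - 1

    @property
    def k(self) -> int:
        return self.B.shape[1]

    def subset(self, idx: np.ndarray) -> "CumulativeProcess":
        """Restrict to the tested columns (after full-information decorrelation)."""
        idx = np.asarray(idx, dtype=int)
        if idx.size == 0:
            raise ValueError("empty parameter subset")
        return CumulativeProcess(B=self.B[:, idx],
                                 labels=tuple(self.labels[i] for i in idx),
                                 ordering=self.ordering)


def empirical_process(scores: np.ndarray, info: np.ndarray,
                      ordering: AuxiliaryOrdering,
                      labels=None, tol: float = 1e-10) -> CumulativeProcess:
    """Build the decorrelated cumulative score process from scores and information."""
    S = np.asarray(scores, dtype=float)
    n, k = S.shape
    if len(ordering.perm) != n:
        raise ValueError("ordering length does not match score matrix")
    R = matrix_inverse_sqrt(np.asarray(info, dtype=float), tol=tol, labels=labels)
    cs = np.empty((n + 1, k))
    cs[0] = 0.0
    np.cumsum(S[ordering.perm], axis=0, out=cs[1:])
    B = (cs / np.sqrt(n)) @ R
    if labels is None:
        labels = tuple(f"theta{j + 1}" for j in range(k))
    return CumulativeProcess(B=B, labels=tuple(labels), ordering=ordering)
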