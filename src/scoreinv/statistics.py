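"""Test statistics for parameter instability, and the ``sctest`` driver.

All statistics are pure functions of a :class:`~scoreinv.fluctuation.CumulativeProcess`
restricted to the tested columns.  For a process with rows ``B_i`` (i = 0..n):

- ``DM``     max_{i,j} |B_ij|                                  (continuous V)
- ``CvM``    n^{-1} sum_i sum_j B_ij^2                          (continuous V)
- ``maxLM``  max_{i in trim window} {i/n (1-i/n)}^{-1} sum_j B_ij^2
- ``WDMo``   max over tie points i_l of {i_l/n (1-i_l/n)}^{-1/2} max_j |B_{i_l j}|
- ``maxLMo`` max over tie points of {i_l/n (1-i_l/n)}^{-1} sum_j B_{i_l j}^2
- ``LMuo``   sum over level blocks of (dt_l)^{-1} sum_j (B_{i_l j}-B_{i_{l-1} j})^2,
  the unordered Lagrange-multiplier form, asymptotically equivalent to the
  multi-group likelihood-ratio statistic.

p-values are delegated entirely to :mod:`scoreinv.nulldist`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nulldist
from .fit import FittedCFA, information_matrix, score_matrix
from .fluctuation import (
    AuxiliaryOrdering,
    CumulativeProcess,
    OrdinalGrouping,
    empirical_process,
    order_observations,
)

__all__ = [
    "TrimSpec",
    "TestResult",
    "dm_stat",
    "cvm_stat",
    "maxlm_stat",
    "wdmo_stat",
    "maxlmo_stat",
    "lmuo_stat",
    "sctest",
    "FUNCTIONALS",
]

FUNCTIONALS = ("DM", "CvM", "maxLM", "WDMo", "maxLMo", "LMuo")
_ORDINAL = ("WDMo", "maxLMo")


@dataclass(frozen=True)
class TrimSpec:
    """Trimming window for the maxLM maximization, as fractions of n."""

    lower: float = 0.1
    upper: float = 0.9

    def __post_init__(self) -> None:
        if not 0.0 < self.lower < self.upper < 1.0:
            raise ValueError("require 0 < lower < upper < 1")


def _check(process: CumulativeProcess) -> np.ndarray:
    B = process.B
    if B.shape[1] == 0:
        raise ValueError("empty column subset")
    if B.shape[0] < 3:
        raise ValueError("need n >= 2 observations")
    return B


def dm_stat(process: CumulativeProcess) -> float:
    """Double-maximum statistic: largest absolute process value."""
    B = _check(process)
    return float(np.abs(B[1:]).max())


def cvm_stat(process: CumulativeProcess) -> float:
    """Cramer-von Mises statistic: average squared process size."""
    B = _check(process)
    n = process.n
    return float((B[1:] ** 2).sum() / n)


def maxlm_stat(process: CumulativeProcess, trim: TrimSpec = TrimSpec()) -> float:
    """Maximum Lagrange-multiplier statistic over the trimmed window."""
    B = _check(process)
    n = process.n
    lo = int(np.ceil(n * trim.lower))
    hi = int(np.floor(n * trim.upper))
    hi = min(hi, n - 1)
    lo = max(lo, 1)
    if hi < lo:
        raise ValueError("trim window contains no index")
    i = np.arange(lo, hi + 1)
    frac = i / n
    w = 1.0 / (frac * (1.0 - frac))
    ssq = (B[lo:hi + 1] ** 2).sum(axis=1)
    return float((w * ssq).max())


def _boundary_rows(B: np.ndarray, grouping: OrdinalGrouping):
    i = grouping.i
    frac = i / grouping.n
    return B[i], frac


def wdmo_stat(process: CumulativeProcess, grouping: OrdinalGrouping) -> float:
    """Weighted double-max over ordinal tie points."""
    B = _check(process)
    if grouping.m < 2:
        raise ValueError("need m >= 2 levels")
    rows, frac = _boundary_rows(B, grouping)
    w = 1.0 / np.sqrt(frac * (1.0 - frac))
    return float((w * np.abs(rows).max(axis=1)).max())


def maxlmo_stat(process: CumulativeProcess, grouping: OrdinalGrouping) -> float:
    """Maximum LM over ordinal tie points."""
    B = _check(process)
    if grouping.m < 2:
        raise ValueError("need m >= 2 levels")
    rows, frac = _boundary_rows(B, grouping)
    w = 1.0 / (frac * (1.0 - frac))
    return float((w * (rows ** 2).sum(axis=1)).max())


def lmuo_stat(process: CumulativeProcess, grouping: OrdinalGrouping) -> float:
    """Unordered LM statistic from weighted squared block increments."""
    B = _check(process)
    n = grouping.n
    idx = np.concatenate(([0], grouping.i, [n]))
    dt = np.diff(idx) / n
    if np.any(dt <= 0):
        raise ValueError("degenerate level blocks")
    inc = np.diff(B[idx], axis=0)
    return float(((inc ** 2).sum(axis=1) / dt).sum())


@dataclass
class TestResult:
    """Outcome of a score-based instability test."""

    functional: str
    statistic: float
    pvalue: float | None
    labels: tuple[str, ...]
    k: int
    n: int
    m: int | None = None
    provenance: dict = field(default_factory=dict)
    process: CumulativeProcess | None = None
    grouping: OrdinalGrouping | None = None

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        p = "n/a" if self.pvalue is None else f"{self.pvalue:.5g}"
        return (f"{self.functional} test: f(efp) = {self.statistic:.4g}, "
                f"p-value = {p} (k = {self.k}, n = {self.n}"
                + (f", m = {self.m}" if self.m is not None else "") + ")")


def _resolve_treatment(functional: str, treatment: str | None) -> str:
    if treatment is not None:
        return treatment
    if functional in _ORDINAL:
        return "ordinal"
    if functional == "LMuo":
        return "categorical"
    return "continuous"


def sctest(
    fitted: FittedCFA,
    order_by,
    *,
    functional: str = "maxLMo",
    parm=None,
    vcov: str = "observed",
    treatment: str | None = None,
    trim: TrimSpec | tuple = TrimSpec(),
    nrep: int | None = None,
    seed: int = 0,
    critvals: "nulldist.CriticalValueTable | None" = None,
    compute_pvalue: bool = True,
) -> TestResult:
    """Score-based test of parameter instability along an auxiliary variable.

    Orchestrates scores -> information -> ordering -> cumulative process ->
    statistic -> p-value.  ``order_by`` is a column name of the fitted data
    or an array aligned with its rows; ``parm`` selects the tested parameters
    (labels, 1-based positions, or ``"1:4"``).  ``critvals`` supplies a
    pre-simulated table for maxLMo (validated against the data's tie
    proportions).
    """
    if functional not in FUNCTIONALS:
        raise ValueError(f"functional must be one of {FUNCTIONALS}, got {functional!r}")
    treatment = _resolve_treatment(functional, treatment)
    if functional in _ORDINAL and treatment == "continuous":
        raise ValueError(
            f"{functional} requires an ordinal or categorical auxiliary variable; "
            "use DM/CvM/maxLM for continuous orderings")
    if isinstance(order_by, str):
        if order_by not in fitted.data.columns:
            raise ValueError(f"column {order_by!r} not in the fitted data")
        V = fitted.data[order_by]
    else:
        V = order_by
        if len(V) != fitted.n:
            raise ValueError("order_by length does not match the fitted sample")

    ordering = order_observations(V, treatment=treatment)
    if treatment == "continuous" and ordering.has_ties:
        warnings.warn(
            "continuous treatment of a tied auxiliary variable: results depend "
            "on the (arbitrary) within-tie input order; consider the ordinal "
            "functionals", stacklevel=2)

    grouping = ordering.grouping() if treatment in ("ordinal", "categorical") else None
    if functional in _ORDINAL + ("LMuo",) and grouping is not None and grouping.m == fitted.n:
        raise ValueError(
            "auxiliary variable has all-unique values; ordinal/categorical "
            "functionals need ties — use the continuous functionals instead")

    info = information_matrix(fitted, kind=vcov)
    S = score_matrix(fitted).matrix
    process_full = empirical_process(S, info.matrix, ordering,
                                     labels=fitted.table.free_labels)
    idx = fitted.table.resolve_parm(parm)
    process = process_full.subset(idx)
    k = process.k
    if not isinstance(trim, TrimSpec):
        trim = TrimSpec(*trim)

    provenance: dict = {"vcov": info.kind, "treatment": treatment}
    if functional == "DM":
        stat = dm_stat(process)
        pval = nulldist.p_dm(stat, k) if compute_pvalue else None
        provenance["critical_values"] = "analytic"
    elif functional == "CvM":
        stat = cvm_stat(process)
        pval = None
        if compute_pvalue:
            nr = nrep or 20000
            pval = nulldist.p_cvm(stat, k, nrep=nr, seed=seed)
            provenance["critical_values"] = f"simulated(seed={seed}, nrep={nr})"
    elif functional == "maxLM":
        stat = maxlm_stat(process, trim)
        pval = None
        if compute_pvalue:
            nr = nrep or 20000
            pval = nulldist.p_maxlm(stat, k, (trim.lower, trim.upper),
                                    nrep=nr, seed=seed)
            provenance["critical_values"] = f"simulated(seed={seed}, nrep={nr})"
    elif functional == "WDMo":
        stat = wdmo_stat(process, grouping)
        pval = nulldist.p_wdmo(stat, k, grouping.t) if compute_pvalue else None
        provenance["critical_values"] = "analytic"
    elif functional == "maxLMo":
        stat = maxlmo_stat(process, grouping)
        pval = None
        if compute_pvalue:
            if critvals is not None:
                critvals.require_match(grouping.t)
                table = critvals
            else:
                nr = nrep or 50000
                table = nulldist.ord_l2bb_critvals(grouping.t, k_range=(k,),
                                                   nrep=nr, seed=seed)
            pval = table.pvalue(stat, k)
            provenance["critical_values"] = (
                f"simulated(seed={table.seed}, nrep={table.nrep})")
    else:  # LMuo
        stat = lmuo_stat(process, grouping)
        pval = nulldist.p_lmuo(stat, k, grouping.m) if compute_pvalue else None
        provenance["critical_values"] = "chi2"

    return TestResult(
        functional=functional, statistic=stat, pvalue=pval,
        labels=process.labels, k=k, n=fitted.n,
        m=None if grouping is None else grouping.m,
        provenance=provenance, process=process, grouping=grouping,
    )
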