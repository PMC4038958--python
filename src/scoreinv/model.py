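"""Confirmatory factor analysis model specification and parameter bookkeeping.

A model is described by a small text syntax (``factor =~ ind1 + ind2 + ...``),
expanded into a :class:`ParameterTable` that enumerates every loading,
intercept, unique variance and factor (co)variance per group, records which
entries are free, and assigns each free parameter a contiguous index
``0..k-1``.  Cross-group equality constraints collapse entries onto a shared
free index.  The table order is deterministic: loadings first, then
intercepts, unique variances, factor variances and factor covariances, each
block iterating groups in order — so for a constrained-loadings multi-group
model the free loadings occupy the leading indices (the convention the
positional ``parm`` addressing relies on).

Two identification conventions are supported:

``marker``
    first loading per factor fixed to 1, factor variances free
    (the multi-group tutorial convention);
``variance``
    factor variances fixed to 1, all loadings free (needed when individual
    loadings themselves are to be tested for instability).

Factor means are fixed to 0 in every group.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CFAModelSpec",
    "ParameterTable",
    "ModelSyntaxError",
    "parse_model_syntax",
    "build_parameter_table",
    "model_df",
    "CFAModel",
]

ROLE_LOADING = "loading"
ROLE_INTERCEPT = "intercept"
ROLE_UNIQUE = "unique_variance"
ROLE_FVAR = "factor_variance"
ROLE_FCOV = "factor_covariance"

#: roles whose free parameters are variances (log-transformed during optimization)
VARIANCE_ROLES = frozenset({ROLE_UNIQUE, ROLE_FVAR})

# lavaan-style keywords accepted by the ``equal`` argument
_EQUAL_KEYWORDS = {
    "loadings": ROLE_LOADING,
    "intercepts": ROLE_INTERCEPT,
    "residuals": ROLE_UNIQUE,
    "lv.variances": ROLE_FVAR,
    "lv.covariances": ROLE_FCOV,
}


class ModelSyntaxError(ValueError):
    """Raised when the model-syntax text cannot be parsed."""


class IdentificationError(ValueError):
    """Raised when the model is not identified (e.g. a single-indicator factor)."""


@dataclass(frozen=True)
class CFAModelSpec:
    """Structural description of a confirmatory factor model.

    Parameters
    ----------
    factors : tuple of str
        Factor names in declaration order.
    loadings : mapping factor -> tuple of indicator names (declaration order).
    mean_structure : bool
        Whether intercepts are modeled (default True).
    group_var : str or None
        Name of the grouping column for multi-group fits.
    identification : {"marker", "variance"}
    """

    factors: tuple[str, ...]
    loadings: Mapping[str, tuple[str, ...]]
    mean_structure: bool = True
    group_var: str | None = None
    identification: str = "marker"

    def __post_init__(self) -> None:
        if self.identification not in ("marker", "variance"):
            raise ValueError(
                f"identification must be 'marker' or 'variance', got {self.identification!r}"
            )
        for f in self.factors:
            if f not in self.loadings or len(self.loadings[f]) == 0:
                raise ModelSyntaxError(f"factor {f!r} has no indicators")

    @property
    def indicators(self) -> tuple[str, ...]:
        """All indicators, in first-appearance order."""
        seen: dict[str, None] = {}
        for f in self.factors:
            for ind in self.loadings[f]:
                seen.setdefault(ind)
        return tuple(seen)

    @property
    def n_indicators(self) -> int:
        return len(self.indicators)

    @property
    def n_factors(self) -> int:
        return len(self.factors)


_LINE_RE = re.compile(r"^\s*(?P<lhs>[\w.]+)\s*=~\s*(?P<rhs>.+?)\s*$")


def parse_model_syntax(text: str) -> CFAModelSpec:
    """Parse ``factor =~ ind1 + ind2 + ...`` lines into a :class:`CFAModelSpec`.

    Lines may be separated by newlines or semicolons; blank lines and
    ``#`` comments are ignored.  The first indicator of each factor is the
    marker under the default identification.
    """
    if not isinstance(text, str) or not text.strip():
        raise ModelSyntaxError("empty model syntax")
    factors: list[str] = []
    loadings: dict[str, tuple[str, ...]] = {}
    raw_lines = [piece for chunk in text.splitlines() for piece in chunk.split(";")]
    for lineno, line in enumerate(raw_lines, start=1):
        stripped = line.split("#", 1)[0].strip()
        if not stripped:
            continue
        m = _LINE_RE.match(stripped)
        if m is None:
            raise ModelSyntaxError(f"cannot parse line {lineno}: {line.strip()!r}")
        factor = m.group("lhs")
        inds = [s.strip() for s in m.group("rhs").split("+")]
        if any(not re.fullmatch(r"[\w.]+", s or "") for s in inds):
            raise ModelSyntaxError(f"malformed indicator list on line {lineno}: {line.strip()!r}")
        if factor in loadings:
            raise ModelSyntaxError(f"duplicate factor name {factor!r} on line {lineno}")
        if len(set(inds)) != len(inds):
            raise ModelSyntaxError(f"duplicate indicator within factor {factor!r} on line {lineno}")
        factors.append(factor)
        loadings[factor] = tuple(inds)
    if not factors:
        raise ModelSyntaxError("no factor definitions found")
    return CFAModelSpec(factors=tuple(factors), loadings=loadings)


def _label(role: str, spec: CFAModelSpec, f: str | None, ind: str | None,
           f2: str | None = None) -> str:
    if role == ROLE_LOADING:
        return f"{f}=~{ind}"
    if role == ROLE_INTERCEPT:
        return f"{ind}~1"
    if role == ROLE_UNIQUE:
        return f"{ind}~~{ind}"
    if role == ROLE_FVAR:
        return f"{f}~~{f}"
    return f"{f}~~{f2}"


@dataclass
class ParameterTable:
    """Row-per-parameter bookkeeping for a (possibly multi-group) CFA model.

    ``df`` has one row per model parameter per group with columns:

    - ``label``: full label, with ``.g<g>`` suffix when there are >1 groups
    - ``base_label``: label without the group suffix
    - ``role``: one of loading / intercept / unique_variance /
      factor_variance / factor_covariance
    - ``group``: 0-based group index
    - ``i``, ``j``: matrix coordinates (indicator/factor positions)
    - ``free``: bool; ``value``: fixed value (NaN for free rows)
    - ``free_index``: 0..k-1 for free rows (shared under equality), -1 otherwise
    """

    spec: CFAModelSpec
    n_groups: int
    df: pd.DataFrame
    k: int = field(init=False)
    free_labels: list[str] = field(init=False)

    def __post_init__(self) -> None:
        self.k = int(self.df.loc[self.df.free, "free_index"].max()) + 1 if self.df.free.any() else 0
        labels: list[str] = [""] * self.k
        counts = np.zeros(self.k, dtype=int)
        for row in self.df.itertuples():
            if row.free and not labels[row.free_index]:
                labels[row.free_index] = row.label
            if row.free:
                counts[row.free_index] += 1
        # shared across all groups -> report the group-free base label
        for row in self.df.itertuples():
            if row.free and counts[row.free_index] == self.n_groups and self.n_groups > 1:
                labels[row.free_index] = row.base_label
        self.free_labels = labels

    @property
    def variance_mask(self) -> np.ndarray:
        """Boolean length-k mask of free parameters that are variances."""
        mask = np.zeros(self.k, dtype=bool)
        sub = self.df[self.df.free]
        for role, fi in zip(sub.role, sub.free_index):
            if role in VARIANCE_ROLES:
                mask[fi] = True
        return mask

    def resolve_parm(self, parm) -> np.ndarray:
        """Resolve a parameter-subset request to 0-based free indices.

        Accepts ``None`` (all parameters), a string like ``"1:4"`` (1-based
        inclusive range), an iterable of 1-based integers, or an iterable of
        labels (free labels or full row labels).
        """
        if parm is None:
            return np.arange(self.k)
        if isinstance(parm, str):
            s = parm.strip()
            m = re.fullmatch(r"(\d+):(\d+)", s)
            if m:
                lo, hi = int(m.group(1)), int(m.group(2))
                parm = list(range(lo, hi + 1))
            elif "," in s:
                parm = [p.strip() for p in s.split(",")]
            else:
                parm = [s]
        idx: list[int] = []
        by_label = {lab: i for i, lab in enumerate(self.free_labels)}
        full = {row.label: row.free_index for row in self.df.itertuples() if row.free}
        base = {}
        for row in self.df.itertuples():
            if row.free:
                base.setdefault(row.base_label, row.free_index)
        for p in parm:
            if isinstance(p, (int, np.integer)):
                if not 1 <= p <= self.k:
                    raise ValueError(f"parameter index {p} out of range 1..{self.k}")
                idx.append(int(p) - 1)
            elif isinstance(p, str) and re.fullmatch(r"\d+", p):
                idx.append(self.resolve_parm([int(p)])[0])
            elif p in by_label:
                idx.append(by_label[p])
            elif p in full:
                idx.append(full[p])
            elif p in base:
                idx.append(base[p])
            else:
                raise ValueError(f"unknown parameter {p!r}")
        out = np.array(sorted(dict.fromkeys(idx)), dtype=int)
        if out.size == 0:
            raise ValueError("empty parameter subset")
        return out


def build_parameter_table(
    spec: CFAModelSpec,
    n_groups: int = 1,
    equal: Iterable[str] = (),
) -> ParameterTable:
    """Expand a model spec into its full parameter table.

    ``equal`` lists cross-group equality constraints, either role keywords
    (``"loadings"``, ``"intercepts"``, ``"residuals"``, ``"lv.variances"``,
    ``"lv.covariances"``) or explicit base labels (e.g. ``"f1=~y2"``).
    """
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    equal = list(equal)
    equal_roles: set[str] = set()
    equal_labels: set[str] = set()
    for e in equal:
        if e in _EQUAL_KEYWORDS:
            equal_roles.add(_EQUAL_KEYWORDS[e])
        else:
            equal_labels.add(e)

    indicators = spec.indicators
    ind_pos = {ind: i for i, ind in enumerate(indicators)}
    fac_pos = {f: i for i, f in enumerate(spec.factors)}

    rows: list[dict] = []

    def add(role, group, i, j, free, value, f=None, ind=None, f2=None):
        base = _label(role, spec, f, ind, f2)
        lab = base if n_groups == 1 else f"{base}.g{group + 1}"
        rows.append(dict(label=lab, base_label=base, role=role, group=group,
                         i=i, j=j, free=free, value=value))

    for g in range(n_groups):
        for f in spec.factors:
            for pos, ind in enumerate(spec.loadings[f]):
                fixed = spec.identification == "marker" and pos == 0
                add(ROLE_LOADING, g, ind_pos[ind], fac_pos[f],
                    not fixed, 1.0 if fixed else np.nan, f=f, ind=ind)
    if spec.mean_structure:
        for g in range(n_groups):
            for ind in indicators:
                add(ROLE_INTERCEPT, g, ind_pos[ind], -1, True, np.nan, ind=ind)
    for g in range(n_groups):
        for ind in indicators:
            add(ROLE_UNIQUE, g, ind_pos[ind], -1, True, np.nan, ind=ind)
    for g in range(n_groups):
        for f in spec.factors:
            fixed = spec.identification == "variance"
            add(ROLE_FVAR, g, fac_pos[f], fac_pos[f],
                not fixed, 1.0 if fixed else np.nan, f=f)
    for g in range(n_groups):
        for fa, fb in combinations(spec.factors, 2):
            add(ROLE_FCOV, g, fac_pos[fa], fac_pos[fb], True, np.nan, f=fa, f2=fb)

    df = pd.DataFrame(rows)

    known_bases = set(df.base_label)
    for lab in equal_labels:
        if lab not in known_bases:
            raise ValueError(f"equality constraint references unknown parameter {lab!r}")

    free_index = np.full(len(df), -1, dtype=int)
    assigned: dict[str, int] = {}
    nxt = 0
    for r in range(len(df)):
        if not df.free.iloc[r]:
            continue
        base = df.base_label.iloc[r]
        role = df.role.iloc[r]
        constrained = role in equal_roles or base in equal_labels
        key = base if constrained else df.label.iloc[r]
        if key in assigned:
            free_index[r] = assigned[key]
        else:
            assigned[key] = nxt
            free_index[r] = nxt
            nxt += 1
    df["free_index"] = free_index
    return ParameterTable(spec=spec, n_groups=n_groups, df=df)


def model_df(spec: CFAModelSpec, n_groups: int = 1, equal: Iterable[str] = ()) -> int:
    """Model degrees of freedom: sample moments minus free parameters.

    With a mean structure each group contributes ``p(p+3)/2`` moments
    (p means plus p(p+1)/2 covariances); without, ``p(p+1)/2``.
    """
    table = build_parameter_table(spec, n_groups, equal)
    p = spec.n_indicators
    per_group = p * (p + 3) // 2 if spec.mean_structure else p * (p + 1) // 2
    return n_groups * per_group - table.k


class CFAModel:
    """Numeric assembly of model matrices from a parameter vector.

    Precomputes index arrays so that building ``(nu, Lambda, Theta, Phi)``
    for all groups from a length-k free-parameter vector is vectorized.
    """

    def __init__(self, table: ParameterTable):
        self.table = table
        self.spec = table.spec
        self.G = table.n_groups
        self.p = self.spec.n_indicators
        self.q = self.spec.n_factors
        self.k = table.k
        df = table.df
        self._by_role = {}
        for role in (ROLE_LOADING, ROLE_INTERCEPT, ROLE_UNIQUE, ROLE_FVAR, ROLE_FCOV):
            sub = df[df.role == role]
            self._by_role[role] = (
                sub.group.to_numpy(int),
                sub.i.to_numpy(int),
                sub.j.to_numpy(int),
                sub.free_index.to_numpy(int),
                sub.value.to_numpy(float),
            )

    def _values(self, role: str, theta: np.ndarray):
        g, i, j, fi, val = self._by_role[role]
        v = np.where(fi >= 0, theta[np.clip(fi, 0, None)], val)
        return g, i, j, v

    def matrices(self, theta: np.ndarray):
        """Return (nu (G,p), Lam (G,p,q), th (G,p), Phi (G,q,q)) at theta."""
        theta = np.asarray(theta, dtype=float)
        G, p, q = self.G, self.p, self.q
        nu = np.zeros((G, p))
        Lam = np.zeros((G, p, q))
        th = np.zeros((G, p))
        Phi = np.zeros((G, q, q))
        g, i, j, v = self._values(ROLE_LOADING, theta)
        Lam[g, i, j] = v
        if self.spec.mean_structure:
            g, i, _, v = self._values(ROLE_INTERCEPT, theta)
            nu[g, i] = v
        g, i, _, v = self._values(ROLE_UNIQUE, theta)
        th[g, i] = v
        g, i, j, v = self._values(ROLE_FVAR, theta)
        Phi[g, i, j] = v
        g, i, j, v = self._values(ROLE_FCOV, theta)
        Phi[g, i, j] = v
        Phi[g, j, i] = v
        return nu, Lam, th, Phi

    def implied_moments(self, theta: np.ndarray):
        """Model-implied (mu (G,p), Sigma (G,p,p)) at theta."""
        nu, Lam, th, Phi = self.matrices(theta)
        Sigma = np.einsum("gpq,gqr,gsr->gps", Lam, Phi, Lam)
        idx = np.arange(self.p)
        Sigma[:, idx, idx] += th
        return nu, Sigma
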