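"""Null distributions, p-values and critical values for the test statistics.

Under parameter stability the decorrelated cumulative score process converges
to k independent standard Brownian bridges, so every functional's null law is
a functional of the bridge:

- ``DM``: analytic, via the boundary-crossing series
  P(sup|BB| <= c) = 1 - 2 sum_{i>=1} (-1)^{i+1} exp(-2 i^2 c^2);
- ``WDMo``: exact finite-dimensional law — a multivariate-normal rectangle
  probability over the tie points, computed here by deterministic density
  propagation along the bridge's Markov chain;
- ``maxLMo``: simulated from the exact tie-point law (only m-1 Gaussian
  draws per bridge are needed, not a path grid);
- ``LMuo``: chi-square with k(m-1) degrees of freedom;
- ``CvM`` / ``maxLM``: simulated from Brownian-bridge paths on a grid.

Simulated tables record their seed and replication count and reproduce
bit-identically from them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats

__all__ = [
    "CriticalValueTable",
    "p_dm",
    "p_wdmo",
    "p_lmuo",
    "p_maxlm",
    "p_cvm",
    "simulate_bb_functionals",
    "ord_l2bb_critvals",
    "bridge_rectangle_prob",
]

_ORDINAL_FUNCTIONALS = ("WDMo", "maxLMo", "LMuo")
_CONTINUOUS_FUNCTIONALS = ("DM", "CvM", "maxLM")


def p_dm(statistic: float, k: int) -> float:
    """Analytic double-max p-value: 1 - P(sup|BB| <= c)^k.

    Uses the alternating boundary-crossing series for a single standard
    Brownian bridge, truncated at relative 1e-12; the decorrelated
    components are independent, hence the k-th power.
    """
    c = float(statistic)
    if c <= 0:
        return 1.0
    s = 0.0
    i = 1
    while True:
        term = (-1) ** (i + 1) * np.exp(-2.0 * i * i * c * c)
        s += term
        if abs(term) < 1e-12 * max(abs(s), 1e-300) or i > 1000:
            break
        i += 1
    F = min(max(1.0 - 2.0 * s, 0.0), 1.0)
    return float(1.0 - F ** k)


def bridge_rectangle_prob(t: np.ndarray, a: np.ndarray, grid: int = 401) -> float:
    """P(|BB(t_l)| <= a_l for all l) for a standard Brownian bridge.

    The bridge evaluated at the ordered tie points is a Gaussian Markov
    chain — BB(t_b) | BB(t_a) = x ~ N(x (1-t_b)/(1-t_a), (t_b-t_a)(1-t_b)/(1-t_a))
    — so the rectangle probability is computed by propagating the joint
    density across levels with trapezoidal quadrature.  Deterministic, unlike
    QMC multivariate-normal integration.
    """
    t = np.asarray(t, dtype=float)
    a = np.asarray(a, dtype=float)
    if t.ndim != 1 or np.any(np.diff(t) <= 0) or t[0] <= 0 or t[-1] >= 1:
        raise ValueError("tie proportions must be strictly increasing in (0, 1)")
    if np.any(a <= 0):
        return 0.0
    # marginal at t_1
    sd1 = np.sqrt(t[0] * (1.0 - t[0]))
    x = np.linspace(-a[0], a[0], grid)
    f = stats.norm.pdf(x, scale=sd1)
    w = np.full(grid, (2.0 * a[0]) / (grid - 1))
    w[0] = w[-1] = w[0] / 2.0
    for l in range(1, len(t)):
        shrink = (1.0 - t[l]) / (1.0 - t[l - 1])
        sd = np.sqrt((t[l] - t[l - 1]) * (1.0 - t[l]) / (1.0 - t[l - 1]))
        y = np.linspace(-a[l], a[l], grid)
        K = stats.norm.pdf(y[:, None], loc=shrink * x[None, :], scale=sd)
        f = K @ (w * f)
        x = y
        w = np.full(grid, (2.0 * a[l]) / (grid - 1))
        w[0] = w[-1] = w[0] / 2.0
    return float(np.clip(np.sum(w * f), 0.0, 1.0))


def p_wdmo(statistic: float, k: int, t: np.ndarray) -> float:
    """Weighted ordinal double-max p-value from the exact tie-point law."""
    t = np.asarray(t, dtype=float)
    if len(t) < 1:
        raise ValueError("need at least one tie point (m >= 2)")
    c = float(statistic)
    if c <= 0:
        return 1.0
    a = c * np.sqrt(t * (1.0 - t))
    R = bridge_rectangle_prob(t, a)
    return float(1.0 - R ** k)


def p_lmuo(statistic: float, k: int, m: int) -> float:
    """Unordered LM p-value: chi-square upper tail with k(m-1) df."""
    if m < 2:
        raise ValueError("need m >= 2 levels")
    return float(stats.chi2.sf(statistic, k * (m - 1)))


@dataclass
class CriticalValueTable:
    """Empirical null distribution of a functional, simulated once and reusable.

    Reuse is valid only for the identical tie-proportion vector (ordinal
    functionals); :meth:`require_match` enforces this.
    """

    functional: str
    nrep: int
    seed: int
    samples: dict[int, np.ndarray]          # k -> sorted null statistics
    t: np.ndarray | None = None             # tie proportions (ordinal) or None
    grid: int | None = None                 # path grid (continuous) or None
    trim: tuple[float, float] | None = None
    warning: str | None = None

    @property
    def k_range(self) -> tuple[int, ...]:
        return tuple(sorted(self.samples))

    def _get(self, k: int) -> np.ndarray:
        if k not in self.samples:
            raise KeyError(
                f"table covers k in {self.k_range}; regenerate with a k_range "
                f"including {k}")
        return self.samples[k]

    def pvalue(self, statistic: float, k: int) -> float:
        s = self._get(k)
        ge = len(s) - np.searchsorted(s, statistic, side="left")
        return float((1.0 + ge) / (self.nrep + 1.0))

    def critical_value(self, alpha: float, k: int) -> float:
        return float(np.quantile(self._get(k), 1.0 - alpha))

    def require_match(self, t: np.ndarray) -> None:
        if self.t is None:
            raise ValueError("table was not simulated for an ordinal functional")
        t = np.asarray(t, dtype=float)
        if len(t) != len(self.t) or not np.allclose(t, self.t, atol=1e-8):
            raise ValueError(
                "critical-value table was simulated for different tie proportions; "
                "tables must be resimulated for new data")


def _bridge_tie_draws(rng, t: np.ndarray, nrep: int, k: int) -> np.ndarray:
    """Draw BB values at tie points: (nrep, m-1, k), exact joint law."""
    m1 = len(t)
    C = np.minimum.outer(t, t) * (1.0 - np.maximum.outer(t, t))
    L = linalg.cholesky(C, lower=True)
    Z = rng.standard_normal((nrep, m1, k))
    return np.einsum("ab,rbk->rak", L, Z)


def simulate_bb_functionals(
    functional: str,
    k: int,
    *,
    nrep: int = 20000,
    seed: int = 0,
    grid: int = 1000,
    t: np.ndarray | None = None,
    trim: tuple[float, float] = (0.1, 0.9),
    chunk: int = 2000,
) -> CriticalValueTable:
    """Simulate the null distribution of a functional of k Brownian bridges.

    Continuous functionals (DM, CvM, maxLM) use Gaussian-increment paths on a
    ``grid``; ordinal functionals (WDMo, maxLMo, LMuo) use the exact
    finite-dimensional law at the tie proportions ``t``.
    """
    if nrep < 1:
        raise ValueError("nrep must be >= 1")
    warning = None
    if nrep < 1000:
        warning = f"nrep={nrep} is small; p-values and quantiles will be noisy"
        warnings.warn(warning)
    rng = np.random.default_rng(seed)
    vals = np.empty(nrep)
    pos = 0
    if functional in _ORDINAL_FUNCTIONALS:
        if t is None or len(t) < 1:
            raise ValueError(f"{functional} requires tie proportions t")
        t = np.asarray(t, dtype=float)
        tfull = np.concatenate(([0.0], t, [1.0]))
        dt = np.diff(tfull)
        while pos < nrep:
            c = min(chunk, nrep - pos)
            B = _bridge_tie_draws(rng, t, c, k)
            if functional == "WDMo":
                w = 1.0 / np.sqrt(t * (1.0 - t))
                vals[pos:pos + c] = (w[None, :] * np.abs(B).max(axis=2)).max(axis=1)
            elif functional == "maxLMo":
                w = 1.0 / (t * (1.0 - t))
                vals[pos:pos + c] = (w[None, :] * (B ** 2).sum(axis=2)).max(axis=1)
            else:  # LMuo
                Bfull = np.concatenate(
                    [np.zeros((c, 1, k)), B, np.zeros((c, 1, k))], axis=1)
                inc = np.diff(Bfull, axis=1)
                vals[pos:pos + c] = ((inc ** 2).sum(axis=2) / dt[None, :]).sum(axis=1)
            pos += c
        return CriticalValueTable(functional=functional, nrep=nrep, seed=seed,
                                  samples={k: np.sort(vals)}, t=t, warning=warning)
    if functional not in _CONTINUOUS_FUNCTIONALS:
        raise ValueError(f"unknown functional {functional!r}")
    tg = np.arange(1, grid + 1) / grid
    if functional == "maxLM":
        lo, hi = trim
        mask = (tg >= lo) & (tg <= hi) & (tg < 1.0)
        wlm = 1.0 / (tg[mask] * (1.0 - tg[mask]))
    while pos < nrep:
        c = min(chunk, nrep - pos)
        Z = rng.standard_normal((c, k, grid)) / np.sqrt(grid)
        W = np.cumsum(Z, axis=2)
        B = W - tg[None, None, :] * W[:, :, -1:]
        if functional == "DM":
            vals[pos:pos + c] = np.abs(B).max(axis=(1, 2))
        elif functional == "CvM":
            vals[pos:pos + c] = (B ** 2).sum(axis=1).mean(axis=1)
        else:
            ssq = (B[:, :, mask] ** 2).sum(axis=1)
            vals[pos:pos + c] = (wlm[None, :] * ssq).max(axis=1)
        pos += c
    return CriticalValueTable(functional=functional, nrep=nrep, seed=seed,
                              samples={k: np.sort(vals)}, grid=grid,
                              trim=trim if functional == "maxLM" else None,
                              warning=warning)


def ord_l2bb_critvals(
    t: np.ndarray,
    k_range=range(1, 21),
    nrep: int = 50000,
    seed: int = 0,
    chunk: int = 5000,
) -> CriticalValueTable:
    """Simulate the maxLMo null for a range of process dimensions at once.

    One table per dataset's tie proportions; covers ``k_range`` (default
    1-20 tested parameters) by accumulating squared bridge components, so a
    single sweep of Gaussian draws serves every k.
    """
    t = np.asarray(t, dtype=float)
    ks = sorted(set(int(k) for k in k_range))
    if ks[0] < 1:
        raise ValueError("k_range must contain positive integers")
    kmax = ks[-1]
    rng = np.random.default_rng(seed)
    w = 1.0 / (t * (1.0 - t))
    out = {k: np.empty(nrep) for k in ks}
    pos = 0
    while pos < nrep:
        c = min(chunk, nrep - pos)
        B = _bridge_tie_draws(rng, t, c, kmax)
        cum = np.cumsum(B ** 2, axis=2)             # (c, m-1, kmax)
        stat = (w[None, :, None] * cum).max(axis=1)  # (c, kmax)
        for k in ks:
            out[k][pos:pos + c] = stat[:, k - 1]
        pos += c
    return CriticalValueTable(functional="maxLMo", nrep=nrep, seed=seed,
                              samples={k: np.sort(v) for k, v in out.items()}, t=t)


def p_maxlm(statistic: float, k: int, trim=(0.1, 0.9), *, nrep: int = 20000,
            seed: int = 0, grid: int = 1000,
            table: CriticalValueTable | None = None) -> float:
    """Simulated p-value for the trimmed maximum-LM functional."""
    if table is None:
        table = simulate_bb_functionals("maxLM", k, nrep=nrep, seed=seed,
                                        grid=grid, trim=tuple(trim))
    return table.pvalue(statistic, k)


def p_cvm(statistic: float, k: int, *, nrep: int = 20000, seed: int = 0,
          grid: int = 1000, table: CriticalValueTable | None = None) -> float:
    """Simulated p-value for the Cramer-von Mises functional."""
    if table is None:
        table = simulate_bb_functionals("CvM", k, nrep=nrep, seed=seed, grid=grid)
    return table.pvalue(statistic, k)
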