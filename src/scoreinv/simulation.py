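"""Monte-Carlo machinery: data-generating processes, instability injection,
power/Type-I-error studies, and the synthetic tutorial fixture.

The default DGP is a two-factor model with three indicators per factor,
identified by unit factor variances (all six loadings free).  True values:
loadings 1, intercepts 0, unique variances 1, factor covariance 0.5; an
optional unmodeled cross-loading (factor 2 -> indicator 1) of 0.5 creates
the misspecification design.

An instability of magnitude ``d`` shifts one parameter for every individual
below the changepoint level ``1 + m/2`` of the ordinal variable by
``d`` times that parameter's asymptotic standard error at the simulated n
(SE_n = SE_1 / sqrt(n), so d is comparable across sample sizes).  Subgroup
sizes are balanced (largest-remainder allocation when m does not divide n).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import linalg, stats

from . import nulldist
from .fit import (
    CFAModel,
    ConvergenceError,
    FitOptions,
    expected_information_at,
    fit_ml,
)
from .model import CFAModelSpec, build_parameter_table
from .statistics import lmuo_stat, maxlmo_stat, sctest, wdmo_stat

__all__ = [
    "DGPSpec",
    "ViolationSpec",
    "PowerTable",
    "two_factor_dgp",
    "asymptotic_se",
    "generate_dataset",
    "run_power_study",
    "make_fixture",
]

_ITEMS = ("y1", "y2", "y3", "y4", "y5", "y6")
EXTRA_LOADING_LABEL = "f2=~y1"


@dataclass(frozen=True)
class DGPSpec:
    """A data-generating CFA model with true parameter values."""

    spec: CFAModelSpec
    theta: np.ndarray
    table: object = None
    model: CFAModel = None

    def with_values(self, **values: float) -> "DGPSpec":
        """Return a copy with named true parameters replaced (label -> value)."""
        theta = self.theta.copy()
        labels = list(self.table.free_labels)
        for lab, v in values.items():
            theta[labels.index(lab)] = v
        return replace(self, theta=theta)


def two_factor_dgp(extra_loading: float | None = None, **overrides) -> DGPSpec:
    """The default simulation DGP (optionally with the unmodeled cross-loading).

    ``extra_loading`` adds a loading of indicator y1 on factor f2 to the
    generating model; the *fitted* model in misspecification studies omits it.
    """
    loadings = {"f1": ("y1", "y2", "y3"),
                "f2": ("y4", "y5", "y6") if extra_loading is None
                else ("y4", "y5", "y6", "y1")}
    spec = CFAModelSpec(factors=("f1", "f2"), loadings=loadings,
                        mean_structure=True, identification="variance")
    table = build_parameter_table(spec, n_groups=1)
    model = CFAModel(table)
    theta = np.zeros(table.k)
    for i, lab in enumerate(table.free_labels):
        if "=~" in lab:
            theta[i] = 1.0
        elif lab.endswith("~1"):
            theta[i] = 0.0
        elif lab == "f1~~f2":
            theta[i] = 0.5
        elif "~~" in lab:
            theta[i] = 1.0
    if extra_loading is not None:
        theta[table.free_labels.index(EXTRA_LOADING_LABEL)] = float(extra_loading)
    dgp = DGPSpec(spec=spec, theta=theta, table=table, model=model)
    if overrides:
        dgp = dgp.with_values(**overrides)
    return dgp


@dataclass(frozen=True)
class ViolationSpec:
    """Which parameter drifts, and by how many asymptotic standard errors."""

    parameter: str
    d: float

    def __post_init__(self) -> None:
        if self.d < 0:
            raise ValueError("violation magnitude d must be >= 0")


def changepoint_level(m: int) -> int:
    """First stable level: individuals below level 1 + m/2 carry the deviation."""
    return 1 + m // 2


def asymptotic_se(dgp: DGPSpec, n: int, parameter: str) -> float:
    """Asymptotic SE of a DGP parameter at sample size n.

    Square root of the parameter's diagonal entry of the inverse expected
    information of the generating model at the true values, divided by n.
    """
    I = expected_information_at(dgp.model, dgp.theta)
    try:
        cov = linalg.inv(I)
    except linalg.LinAlgError as e:
        raise ValueError("expected information at the true values is singular") from e
    idx = dgp.table.free_labels.index(parameter)
    se = np.sqrt(cov[idx, idx] / n)
    if not np.isfinite(se) or se <= 0:
        raise ValueError(f"non-positive asymptotic variance for {parameter!r}")
    return float(se)


def _allocate(n: int, m: int) -> np.ndarray:
    """Balanced largest-remainder allocation of n individuals to m levels."""
    base = np.full(m, n // m)
    rem = n - base.sum()
    base[:rem] += 1
    return base


def generate_dataset(
    dgp: DGPSpec,
    violation: ViolationSpec | None,
    n: int,
    m: int,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Draw a dataset with an ordinal auxiliary column ``level`` (1..m).

    Individuals at levels below the changepoint ``1 + m/2`` are generated
    from the deviated parameter vector; the rest from the baseline.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = _allocate(n, m)
    theta_dev = dgp.theta
    if violation is not None and violation.d > 0:
        delta = violation.d * asymptotic_se(dgp, n, violation.parameter)
        theta_dev = dgp.theta.copy()
        theta_dev[dgp.table.free_labels.index(violation.parameter)] += delta
    cp = changepoint_level(m)

    def moments(theta):
        mu, Sigma = dgp.model.implied_moments(theta)
        try:
            L = linalg.cholesky(Sigma[0], lower=True)
        except linalg.LinAlgError as e:
            raise ValueError(
                f"deviated parameters give a non-positive-definite covariance "
                f"(parameter {violation.parameter!r}, d={violation.d})") from e
        return mu[0], L

    mu_base, L_base = moments(dgp.theta)
    mu_dev, L_dev = moments(theta_dev) if violation is not None and violation.d > 0 \
        else (mu_base, L_base)
    p = dgp.model.p
    blocks = []
    levels = []
    for lvl, ng in enumerate(counts, start=1):
        mu, L = (mu_dev, L_dev) if lvl < cp else (mu_base, L_base)
        Z = rng.standard_normal((ng, p))
        blocks.append(mu + Z @ L.T)
        levels.append(np.full(ng, lvl))
    X = np.vstack(blocks)
    items = dgp.spec.indicators
    df = pd.DataFrame(X, columns=list(items))
    df["level"] = np.concatenate(levels)
    return df


@dataclass
class PowerTable:
    """Rejection proportions per simulation cell, with MC standard errors."""

    df: pd.DataFrame
    alpha: float
    seed: int

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    def to_json(self, path) -> None:
        self.df.to_json(path, orient="records", indent=1)


def _critical_value(functional: str, k: int, grouping, alpha: float,
                    tables: dict, nrep: int, seed: int) -> float:
    """5%-level (or alpha-level) critical value for an ordinal functional."""
    key = (functional, k, tuple(np.round(grouping.t, 12)))
    if key in tables:
        return tables[key]
    if functional == "LMuo":
        cv = float(stats.chi2.ppf(1 - alpha, k * (grouping.m - 1)))
    elif functional == "WDMo":
        # invert the analytic tie-point rectangle probability
        from scipy.optimize import brentq
        cv = float(brentq(lambda c: nulldist.p_wdmo(c, k, grouping.t) - alpha,
                          1e-6, 50.0, xtol=1e-8))
    elif functional == "maxLMo":
        tab = nulldist.ord_l2bb_critvals(grouping.t, k_range=(k,), nrep=nrep,
                                         seed=seed)
        cv = tab.critical_value(alpha, k)
    else:
        raise ValueError(f"power study supports ordinal functionals, got {functional!r}")
    tables[key] = cv
    return cv


def run_power_study(
    dgp: DGPSpec,
    fit_spec: CFAModelSpec,
    *,
    ns=(480,),
    ms=(8,),
    ds=(0.0, 2.0, 4.0),
    violating: str = "f1=~y1",
    tested: dict[str, list] | None = None,
    functionals=("maxLMo", "WDMo", "LMuo"),
    nrep: int = 500,
    alpha: float = 0.05,
    seed: int = 0,
    vcov: str = "observed",
    critval_nrep: int = 50000,
) -> PowerTable:
    """Monte-Carlo rejection rates over an (n, m, d) grid.

    Each replication generates a dataset, fits ``fit_spec`` (pooled, ignoring
    the ordinal variable), and evaluates every functional on every tested
    parameter subset against alpha-level critical values.  Non-converged
    replications are dropped and counted; a cell with more than 5%
    non-convergence is flagged.  Reproducible from ``seed`` (one spawned
    stream per cell).
    """
    tested = tested or {violating: [violating]}
    fit_table = build_parameter_table(fit_spec, n_groups=1)
    cv_cache: dict = {}
    rows = []
    root = np.random.SeedSequence(seed)
    cell_idx = 0
    for n in ns:
        for m in ms:
            for d in ds:
                ss = np.random.SeedSequence(entropy=root.entropy,
                                            spawn_key=(cell_idx,))
                cell_idx += 1
                rng = np.random.default_rng(ss)
                viol = ViolationSpec(parameter=violating, d=float(d))
                rej = {(f, name): 0 for f in functionals for name in tested}
                used = 0
                failed = 0
                for _ in range(nrep):
                    data = generate_dataset(dgp, viol, n, m, seed=rng)
                    try:
                        fitted = fit_ml(data, fit_spec, table=fit_table,
                                        options=FitOptions(restarts=2))
                    except (ConvergenceError, ValueError):
                        failed += 1
                        continue
                    used += 1
                    base = sctest(fitted, "level", functional="LMuo",
                                  parm=None, vcov=vcov, compute_pvalue=False)
                    proc, grouping = base.process, base.grouping
                    for name, parm in tested.items():
                        idx = fitted.table.resolve_parm(parm)
                        sub = proc.subset(idx)
                        for f in functionals:
                            statfn = {"maxLMo": maxlmo_stat, "WDMo": wdmo_stat,
                                      "LMuo": lmuo_stat}[f]
                            stat = statfn(sub, grouping)
                            cv = _critical_value(f, sub.k, grouping, alpha,
                                                 cv_cache, critval_nrep, seed)
                            if stat > cv:
                                rej[(f, name)] += 1
                for (f, name), r in rej.items():
                    prop = r / used if used else np.nan
                    mc_se = np.sqrt(prop * (1 - prop) / used) if used else np.nan
                    rows.append(dict(functional=f, tested_set=name,
                                     violating_param=violating, n=n, m=m, d=d,
                                     nrep=used, rejections=r, proportion=prop,
                                     mc_se=mc_se, nonconverged=failed,
                                     flagged=failed > 0.05 * nrep))
    return PowerTable(df=pd.DataFrame(rows), alpha=alpha, seed=seed)


def make_fixture(n: int = 300, seed: int = 0) -> pd.DataFrame:
    """Synthetic five-item Likert questionnaire with six ordered age groups.

    Emulates the shape of a youth gratitude survey: one latent factor, five
    seven-point items, and six age groups of near-equal size (sizes differ by
    at most one).  Group membership is independent of the responses, so the
    fixture satisfies measurement invariance by construction.
    """
    if n < 60:
        raise ValueError("need n >= 60 for a sensible six-group fixture")
    rng = np.random.default_rng(seed)
    lam = np.array([1.0, 0.9, 0.8, 1.1, 0.95])
    mu = np.array([5.8, 5.6, 6.0, 5.4, 5.7])
    psi = np.array([0.9, 1.1, 0.8, 1.2, 1.0])
    eta = rng.standard_normal(n)
    eps = rng.standard_normal((n, 5)) * np.sqrt(psi)
    cont = mu + np.outer(eta, lam) + eps
    items = np.clip(np.rint(cont), 1, 7).astype(int)
    df = pd.DataFrame(items, columns=[f"item{i + 1}" for i in range(5)])
    counts = _allocate(n, 6)
    groups = np.concatenate([np.full(c, g + 1) for g, c in enumerate(counts)])
    df["agegroup"] = rng.permutation(groups)
    return df


def fixture_model_spec(group: bool = True) -> CFAModelSpec:
    """One-factor model for the fixture items (marker identification)."""
    return CFAModelSpec(
        factors=("f1",),
        loadings={"f1": tuple(f"item{i + 1}" for i in range(5))},
        mean_structure=True,
        group_var="agegroup" if group else None,
        identification="marker",
    )
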