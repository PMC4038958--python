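"""The six instability statistics against brute-force enumeration, and sctest."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scoreinv.fluctuation import AuxiliaryOrdering, CumulativeProcess, OrdinalGrouping, \
    order_observations
from scoreinv.statistics import (
    TrimSpec,
    cvm_stat,
    dm_stat,
    lmuo_stat,
    maxlm_stat,
    maxlmo_stat,
    sctest,
    wdmo_stat,
)


def _process(B: np.ndarray) -> CumulativeProcess:
    n = B.shape[0] - 1
    o = order_observations(np.arange(float(n)), treatment="continuous")
    return CumulativeProcess(B=B, labels=tuple(f"p{j}" for j in range(B.shape[1])),
                             ordering=o)


def _grouping(n: int, counts) -> OrdinalGrouping:
    counts = np.asarray(counts)
    cum = np.cumsum(counts)[:-1]
    return OrdinalGrouping(m=len(counts), counts=counts, t=cum / n, i=cum, n=n)


def _random_process(seed: int, n: int = 10, k: int = 3) -> CumulativeProcess:
    rng = np.random.default_rng(seed)
    B = np.vstack([np.zeros((1, k)), rng.normal(size=(n, k))])
    B[-1] = 0.0
    return _process(B)


def brute_force(name: str, B: np.ndarray, grouping=None, trim=(0.1, 0.9)):
    """Direct enumeration over (i, j) from the definitions."""
    n = B.shape[0] - 1
    if name == "DM":
        return max(abs(B[i, j]) for i in range(1, n + 1) for j in range(B.shape[1]))
    if name == "CvM":
        return sum(B[i, j] ** 2 for i in range(1, n + 1)
                   for j in range(B.shape[1])) / n
    if name == "maxLM":
        lo = int(np.ceil(n * trim[0])); hi = min(int(np.floor(n * trim[1])), n - 1)
        return max(sum(B[i, j] ** 2 for j in range(B.shape[1]))
                   / ((i / n) * (1 - i / n)) for i in range(lo, hi + 1))
    if name == "WDMo":
        return max(max(abs(B[i, j]) for j in range(B.shape[1]))
                   / np.sqrt((i / n) * (1 - i / n)) for i in grouping.i)
    if name == "maxLMo":
        return max(sum(B[i, j] ** 2 for j in range(B.shape[1]))
                   / ((i / n) * (1 - i / n)) for i in grouping.i)
    if name == "LMuo":
        idx = [0] + list(grouping.i) + [n]
        out = 0.0
        for a, b in zip(idx[:-1], idx[1:]):
            dt = (b - a) / n
            out += sum((B[b, j] - B[a, j]) ** 2 for j in range(B.shape[1])) / dt
        return out
    raise ValueError(name)


CONTINUOUS = [("DM", dm_stat), ("CvM", cvm_stat),
              ("maxLM", lambda p: maxlm_stat(p, TrimSpec()))]
ORDINAL = [("WDMo", wdmo_stat), ("maxLMo", maxlmo_stat), ("LMuo", lmuo_stat)]


@pytest.mark.parametrize("seed", range(5))
@pytest.mark.parametrize("name,fn", CONTINUOUS)
def test_continuous_statistics_equal_brute_force(name, fn, seed):
    proc = _random_process(seed)
    assert fn(proc) == pytest.approx(brute_force(name, proc.B), rel=1e-12)


@pytest.mark.parametrize("seed", range(5))
@pytest.mark.parametrize("name,fn", ORDINAL)
def test_ordinal_statistics_equal_brute_force(name, fn, seed):
    proc = _random_process(seed)
    g = _grouping(10, [3, 4, 3])
    assert fn(proc, g) == pytest.approx(brute_force(name, proc.B, g), rel=1e-12)


def test_zero_process_gives_zero_statistics():
    proc = _process(np.zeros((11, 2)))
    g = _grouping(10, [5, 5])
    for _, fn in CONTINUOUS:
        assert fn(proc) == 0.0
    for _, fn in ORDINAL:
        assert fn(proc, g) == 0.0


def test_dm_invariant_to_sign_flips():
    proc = _random_process(3)
    flipped = _process(proc.B * np.array([1.0, -1.0, 1.0]))
    assert dm_stat(proc) == dm_stat(flipped)


def test_cvm_additive_over_disjoint_column_subsets():
    proc = _random_process(4)
    total = cvm_stat(proc)
    parts = cvm_stat(proc.subset([0])) + cvm_stat(proc.subset([1, 2]))
    assert total == pytest.approx(parts, rel=1e-12)


def test_wider_trim_window_never_decreases_maxlm():
    proc = _random_process(6, n=40)
    narrow = maxlm_stat(proc, TrimSpec(0.2, 0.8))
    wide = maxlm_stat(proc, TrimSpec(0.05, 0.95))
    assert wide >= narrow


def test_single_parameter_maxlmo_is_squared_wdmo():
    """With one tested parameter the two ordinal statistics are equivalent."""
    proc = _random_process(7).subset([1])
    g = _grouping(10, [3, 3, 4])
    assert maxlmo_stat(proc, g) == pytest.approx(wdmo_stat(proc, g) ** 2, rel=1e-12)


def test_empty_subset_rejected():
    proc = _random_process(8)
    with pytest.raises(ValueError):
        proc.subset([])


@settings(max_examples=30, derandomize=True, deadline=None)
@given(st.integers(0, 10 ** 6), st.integers(2, 5), st.integers(1, 4))
def test_statistics_match_brute_force_property(seed, m, k):
    """Property: every functional equals its direct enumeration on random input."""
    rng = np.random.default_rng(seed)
    n = 12
    B = np.vstack([np.zeros((1, k)), rng.normal(size=(n, k))])
    B[-1] = 0.0
    proc = _process(B)
    counts = rng.multinomial(n - m, np.ones(m) / m) + 1
    g = _grouping(n, counts)
    for name, fn in CONTINUOUS:
        assert fn(proc) == pytest.approx(brute_force(name, B), rel=1e-10)
    for name, fn in ORDINAL:
        assert fn(proc, g) == pytest.approx(brute_force(name, B, g), rel=1e-10)


class TestSctest:
    def test_full_pipeline_on_fixture_all_functionals(self, fixture_fit):
        """Tutorial-style chain: restricted fit, then every functional."""
        for functional in ("DM", "CvM", "maxLM", "WDMo", "maxLMo", "LMuo"):
            with np.errstate(all="ignore"):
                import warnings
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = sctest(fixture_fit, "agegroup", functional=functional,
                                 parm="1:4", seed=1, nrep=5000)
            assert res.statistic >= 0
            assert 0.0 <= res.pvalue <= 1.0
            assert res.k == 4
            assert res.labels == ("f1=~item2", "f1=~item3", "f1=~item4", "f1=~item5")

    def test_lmuo_pvalue_is_chi_square_tail(self, fixture_fit):
        from scipy import stats as sps
        res = sctest(fixture_fit, "agegroup", functional="LMuo", parm="1:4")
        assert res.m == 6
        assert res.pvalue == pytest.approx(sps.chi2.sf(res.statistic, 4 * 5))

    def test_single_parameter_wdmo_maxlmo_agree_in_pvalue(self, fixture_fit):
        """k=1: the ordinal statistics are monotone transforms with matching decisions."""
        r1 = sctest(fixture_fit, "agegroup", functional="WDMo", parm=[1])
        r2 = sctest(fixture_fit, "agegroup", functional="maxLMo", parm=[1],
                    nrep=50000, seed=5)
        assert r2.statistic == pytest.approx(r1.statistic ** 2, rel=1e-10)
        assert abs(r1.pvalue - r2.pvalue) < 0.01

    def test_deterministic_given_seed(self, fixture_fit):
        a = sctest(fixture_fit, "agegroup", functional="maxLMo", parm="1:4",
                   seed=7, nrep=2000)
        b = sctest(fixture_fit, "agegroup", functional="maxLMo", parm="1:4",
                   seed=7, nrep=2000)
        assert a.statistic == b.statistic and a.pvalue == b.pvalue

    def test_ordinal_functional_needs_ties(self, sim_fit, rng):
        V = rng.normal(size=sim_fit.n)
        with pytest.raises(ValueError, match="continuous"):
            sctest(sim_fit, V, functional="maxLMo", treatment="ordinal")

    def test_continuous_treatment_of_tied_variable_warns(self, fixture_fit):
        with pytest.warns(UserWarning, match="within-tie"):
            sctest(fixture_fit, "agegroup", functional="DM", treatment="continuous")

    def test_unknown_functional_lists_options(self, sim_fit):
        with pytest.raises(ValueError, match="DM"):
            sctest(sim_fit, "level", functional="superLM")

    def test_critvals_table_reuse_and_mismatch(self, fixture_fit):
        from scoreinv.nulldist import ord_l2bb_critvals
        res0 = sctest(fixture_fit, "agegroup", functional="maxLMo", parm="1:4",
                      compute_pvalue=False)
        table = ord_l2bb_critvals(res0.grouping.t, k_range=(4,), nrep=20000, seed=3)
        res = sctest(fixture_fit, "agegroup", functional="maxLMo", parm="1:4",
                     critvals=table)
        assert res.provenance["critical_values"] == "simulated(seed=3, nrep=20000)"
        wrong = ord_l2bb_critvals(np.array([0.5]), k_range=(4,), nrep=2000, seed=3)
        with pytest.raises(ValueError, match="resimulated"):
            sctest(fixture_fit, "agegroup", functional="maxLMo", parm="1:4",
                   critvals=wrong)
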