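"""Simulation-study harness: type-I error, power, and post hoc equivalence.

Rejection probabilities are estimated with the bias-adjusted
``(r+1)/(n+1)`` estimator, which never reports 0% or 100% and matches the
estimator used for the published calibration results.  Every replicate is
individually reproducible: replicate i uses ``SeedSequence((master_seed, i))``,
so studies can be re-run or parallelised without changing results.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .assoc_tests import (
    bin_test,
    burden_test,
    cluster_burden,
    reference_position_tests,
)
from .core_data import CASE, CONTROL, GeneDataset
from .simulator import SimulatedDataset, SimulationScenario, simulate_gene

__all__ = [
    "PowerResult",
    "PosthocPower",
    "TEST_REGISTRY",
    "estimate_exceedance_rate",
    "null_pvalue_table",
    "run_power_study",
    "check_p_independence",
    "posthoc_multiplier",
]


def _p_bin(ds: GeneDataset) -> float:
    return bin_test(ds).p


def _p_burden(ds: GeneDataset) -> float:
    return burden_test(ds)


def _p_clusterburden(ds: GeneDataset) -> float:
    return cluster_burden(ds).p_combined


def _p_ad(ds: GeneDataset) -> float:
    return reference_position_tests(ds.positions(CASE), ds.positions(CONTROL))[0]


def _p_ks(ds: GeneDataset) -> float:
    return reference_position_tests(ds.positions(CASE), ds.positions(CONTROL))[1]


#: Named per-gene tests usable in power studies and from the CLI.
TEST_REGISTRY: dict[str, Callable[[GeneDataset], float]] = {
    "bin": _p_bin,
    "burden": _p_burden,
    "clusterburden": _p_clusterburden,
    "ad": _p_ad,
    "ks": _p_ks,
}


@dataclass
class PowerResult:
    """Monte-Carlo rejection-rate estimate for one test and scenario."""

    test_name: str
    scenario: str
    n_reps: int
    alpha: float
    rejections: int
    estimate: float
    mc_se: float


@dataclass
class PosthocPower:
    """Sample-size multiplier equating burden-only power to combined power.

    Each observed p-value is inverted to a chi-squared statistic (1 df for
    the burden test, 4 df for the Fisher combination), treated as a
    non-centrality parameter that scales linearly with sample size; the
    multiplier c solves power(c * ncp_burden, 1 df) = power(ncp_combined, 4 df)
    at the given alpha.
    """

    p_burden: float
    p_combined: float
    alpha: float
    ncp_burden: float
    ncp_combined: float
    multiplier: float
    percent_increase: float
    unbounded: bool = False


def estimate_exceedance_rate(r: int, n: int) -> float:
    """The (r+1)/(n+1) estimator of a rejection probability."""
    if n < 1 or not 0 <= r <= n:
        raise ValueError(f"need 0 <= r <= n with n >= 1, got r={r}, n={n}")
    return (r + 1) / (n + 1)


def _replicate_seed(master_seed: int, index: int) -> np.random.SeedSequence:
    """Documented splitting scheme: replicate i gets SeedSequence((seed, i))."""
    return np.random.SeedSequence((master_seed, index))


def iter_replicates(
    scenario: SimulationScenario, n_reps: int, seed: int
):
    """Yield ``n_reps`` independently seeded simulated datasets."""
    for i in range(n_reps):
        yield simulate_gene(scenario, seed=_replicate_seed(seed, i))


def null_pvalue_table(
    scenario: SimulationScenario,
    n_reps: int,
    seed: int,
    tests: Sequence[str] = ("burden", "bin", "clusterburden"),
) -> pd.DataFrame:
    """p-values of several tests on the same simulated replicates.

    One row per replicate, one column per test name.  Sharing replicates
    across tests is what the p-value independence diagnostic requires,
    and it also halves the cost of joint calibration studies.
    """
    rows = []
    for sim in iter_replicates(scenario, n_reps, seed):
        rows.append({t: TEST_REGISTRY[t](sim.dataset) for t in tests})
    return pd.DataFrame(rows)


def run_power_study(
    test: str | Callable[[GeneDataset], float],
    scenario: SimulationScenario,
    n_reps: int,
    alpha: float = 0.05,
    seed: int = 0,
) -> PowerResult:
    """Estimate the rejection rate of one test under one scenario."""
    if isinstance(test, str):
        test_name, test_fn = test, TEST_REGISTRY[test]
    else:
        test_name, test_fn = getattr(test, "__name__", "custom"), test
    r = 0
    for sim in iter_replicates(scenario, n_reps, seed):
        if test_fn(sim.dataset) < alpha:
            r += 1
    est = estimate_exceedance_rate(r, n_reps)
    mc_se = math.sqrt(est * (1.0 - est) / n_reps)
    return PowerResult(
        test_name=test_name, scenario=scenario.name, n_reps=n_reps, alpha=alpha,
        rejections=r, estimate=est, mc_se=mc_se,
    )


def check_p_independence(
    scenario: SimulationScenario, n_reps: int, seed: int = 0
) -> tuple[float, float]:
    """Spearman correlation between burden and BIN-test p-values.

    Fisher's method assumes the combined p-values are independent; under a
    null scenario the correlation should be ~0 (under a disease scenario a
    positive correlation is expected, since both tests gain power with the
    number of observed variants).
    """
    table = null_pvalue_table(scenario, n_reps, seed, tests=("burden", "bin"))
    rho, p = stats.spearmanr(table["burden"], table["bin"])
    return float(rho), float(p)


def _ncx2_power(ncp: float, df: int, alpha: float) -> float:
    crit = stats.chi2.isf(alpha, df)
    return float(stats.ncx2.sf(crit, df, ncp)) if ncp > 0 else float(alpha)


def posthoc_multiplier(
    p_burden: float, p_combined: float, alpha: float = 0.05
) -> PosthocPower:
    """Sample-size increase needed for burden-only to match combined power."""
    for p in (p_burden, p_combined):
        if not 0.0 < p < 1.0:
            raise ValueError(f"p-values must lie in (0, 1), got {p}")
    ncp_b = float(stats.chi2.isf(p_burden, 1))
    ncp_c = float(stats.chi2.isf(p_combined, 4))
    power_c = _ncx2_power(ncp_c, 4, alpha)
    power_b = _ncx2_power(ncp_b, 1, alpha)

    if p_burden <= p_combined or power_b >= power_c:
        # the burden test alone is already at least as strong
        mult, unbounded = 1.0, False
    else:
        f = lambda c: _ncx2_power(c * ncp_b, 1, alpha) - power_c
        hi = 1e4
        if f(hi) < 0:
            mult, unbounded = hi, True
        else:
            mult = float(optimize.brentq(f, 1.0, hi, xtol=1e-10, rtol=1e-12))
            unbounded = False
    return PosthocPower(
        p_burden=p_burden, p_combined=p_combined, alpha=alpha,
        ncp_burden=ncp_b, ncp_combined=ncp_c,
        multiplier=mult, percent_increase=100.0 * (mult - 1.0),
        unbounded=unbounded,
    )
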