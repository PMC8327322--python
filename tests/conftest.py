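"""Shared fixtures: simulated replicate tables and synthetic GAM frames.

The expensive Monte-Carlo artefacts (null replicate p-values, clustered
power tables, GAM calibration sweeps) are session-scoped so the module
tests and the calibration suite share one computation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from cbkit.core_data import CASE, CONTROL, GeneDataset, VariantRecord
from cbkit.evaluation import TEST_REGISTRY, iter_replicates
from cbkit.hotspot_gam import GamFrame, fit_hotspot, predict_log_or
from cbkit.simulator import SimulationScenario

settings.register_profile(
    "suite", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("suite")

#: Master seeds for the deterministic Monte-Carlo fixtures.
NULL_SEED = 1234
POWER_SEED = 7

N_NULL_REPS = 1000
N_POWER_REPS = 500


def make_dataset(
    case_positions,
    control_positions,
    L=100,
    n_cases=100,
    n_controls=1000,
    gene="TOY",
    coverage_case=None,
    coverage_control=None,
):
    """GeneDataset from plain position lists (one carrier per variant)."""
    variants = [
        VariantRecord(gene=gene, residue_position=int(p), cohort=CASE)
        for p in case_positions
    ] + [
        VariantRecord(gene=gene, residue_position=int(p), cohort=CONTROL)
        for p in control_positions
    ]
    return GeneDataset(
        gene=gene, protein_length=L, n_cases=n_cases, n_controls=n_controls,
        variants=variants, coverage_case=coverage_case,
        coverage_control=coverage_control,
    )


def make_carrier_frame(
    rng,
    n_car=150,
    L=500,
    n_cases=500,
    n_controls=5000,
    or_fn=None,
    scores_effect=None,
):
    """GamFrame drawn from an explicit logistic carrier model.

    Carrier positions are uniform on [1, L]; carrier case status is
    Bernoulli with odds ``(n_cases/n_controls) * OR(position) *
    exp(gamma * score)``.  Returns (frame, positions, scores).
    """
    pos = rng.integers(1, L + 1, size=n_car)
    base_odds = n_cases / n_controls
    orx = np.array([or_fn(p) for p in pos]) if or_fn else np.ones(n_car)
    scores = rng.standard_normal(n_car)
    gamma = scores_effect if scores_effect is not None else 0.0
    odds = base_odds * orx * np.exp(gamma * scores)
    y = rng.binomial(1, odds / (1 + odds)).astype(float)
    n_case_car = int(y.sum())
    frame = GamFrame(
        is_case=np.concatenate([y, [1.0, 0.0]]),
        carrier=np.concatenate([np.ones(n_car), [0.0, 0.0]]),
        position=np.concatenate([pos.astype(float), [0.0, 0.0]]),
        weight=np.concatenate(
            [np.ones(n_car), [n_cases - n_case_car, n_controls - (n_car - n_case_car)]]
        ),
        gene="SYN", L=L,
    )
    return frame, pos, scores


@pytest.fixture(scope="session")
def null_ptable() -> pd.DataFrame:
    """Burden / BIN / ClusterBurden p-values on 1000 shared null replicates."""
    scenario = SimulationScenario(name="null", L=500, n_cases=500, n_controls=5000)
    tests = ("burden", "bin", "clusterburden")
    rows = []
    for sim in iter_replicates(scenario, N_NULL_REPS, NULL_SEED):
        rows.append({t: TEST_REGISTRY[t](sim.dataset) for t in tests})
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def clustered_ptables() -> dict[str, pd.DataFrame]:
    """All five tests on 500 shared replicates per clustered scenario."""
    tests = ("bin", "burden", "clusterburden", "ad", "ks")
    out = {}
    for name in ("single_cluster", "multi_cluster"):
        scenario = SimulationScenario(name=name, L=500, n_cases=500, n_controls=5000)
        rows = []
        for sim in iter_replicates(scenario, N_POWER_REPS, POWER_SEED):
            rows.append({t: TEST_REGISTRY[t](sim.dataset) for t in tests})
        out[name] = pd.DataFrame(rows)
    return out


@pytest.fixture(scope="session")
def gam_null_coverage() -> np.ndarray:
    """Per-seed fraction of positions whose 95% CI covers OR=1 (null truth).

    100 synthetic null genes (no positional or burden effect among
    carriers beyond the cohort base rate).
    """
    fracs = []
    for seed in range(100):
        rng = np.random.default_rng(seed)
        frame, _, _ = make_carrier_frame(rng)
        model = fit_hotspot(frame)
        log_or, se = predict_log_or(model, np.arange(1, frame.L + 1))
        covered = (log_or - 1.96 * se <= 0.0) & (0.0 <= log_or + 1.96 * se)
        fracs.append(covered.mean())
    return np.asarray(fracs)


@pytest.fixture(scope="session")
def gamma_recovery() -> tuple[int, int]:
    """(n_covered, n_seeds) for recovery of a unit feature effect.

    Data are simulated with a true per-carrier score coefficient of 1.0;
    each seed's hotspot+ fit is checked for |gamma_hat - 1| < 2 SE.
    """
    from cbkit.hotspot_plus import FeatureMatrix, fit_hotspot_plus

    n_seeds, covered = 100, 0
    for seed in range(n_seeds):
        rng = np.random.default_rng(seed)
        frame, _, scores = make_carrier_frame(rng, n_car=300, scores_effect=1.0)
        X = FeatureMatrix(names=("f0",), values=scores[:, None])
        model = fit_hotspot_plus(frame, X, ["f0"])
        gamma_hat = model.beta[-1]
        se = np.sqrt(model.cov[-1, -1])
        if abs(gamma_hat - 1.0) < 2.0 * se:
            covered += 1
    return covered, n_seeds
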