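"""Synthetic case-control generator for rare missense variants.

The generator emulates a gene in which discrete exonic windows carry
pathogenic missense variation while a benign background of ultra-rare
variants is spread uniformly along the protein:

* **benign background** — a fixed panel of candidate benign sites, each
  with a true population allele frequency drawn from a log-uniform
  ultra-rare spectrum (10^U, U ~ Uniform(-6.5, -3.5), producing the
  realistic excess of singletons); carriers in each cohort are binomial in
  the cohort size, so under the null the two cohorts are exchangeable
  apart from size.
* **pathogenic variants** — positions drawn uniformly inside the scenario's
  cluster windows (or over the whole protein for the burden-only
  "uniform" scenario); carriage is incompletely penetrant: the case:control
  carriage odds ratio equals ``penetrance_or``, so pathogenic variants do
  appear in controls.  Pathogenic variants are absent from the reference
  population (missing popmax AF).
* **rarity filter** — the standard popmax AF < 1e-4 filter is applied to
  the realized variants, exactly as for real data.

Scenario names: ``null`` (benign only), ``uniform`` (burden without
clustering), ``single_cluster`` and ``multi_cluster``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .core_data import CASE, CONTROL, GeneDataset, VariantRecord, filter_rare

__all__ = [
    "SimulationScenario",
    "SimulatedDataset",
    "simulate_gene",
    "default_scenarios",
    "single_cluster_windows",
    "multi_cluster_windows",
]

SCENARIO_NAMES = ("null", "uniform", "single_cluster", "multi_cluster")

#: Log10 range of the benign population allele-frequency spectrum.
AF_LOG10_RANGE = (-6.5, -3.5)

#: Full-scale study conditions (cases / controls).
FULL_SCALE = (5000, 125_000)
#: Desk-scale conditions preserving the 1:25 case:control ratio.
DESK_SCALE = (500, 5000)


#: Fraction of the protein covered by one pathogenic window; exon-sized
#: (about 30 residues at L=500), matching the premise of discrete exonic
#: regions of elevated pathogenic potential.
WINDOW_FRACTION = 0.06


def single_cluster_windows(L: int) -> tuple[tuple[int, int], ...]:
    """One exon-sized pathogenic window starting at 0.20 L."""
    return ((max(1, round(0.20 * L)), round((0.20 + WINDOW_FRACTION) * L)),)


def multi_cluster_windows(L: int) -> tuple[tuple[int, int], ...]:
    """Three exon-sized pathogenic windows starting at 0.10, 0.50 and 0.80 of L."""
    return tuple(
        (max(1, round(s * L)), round((s + WINDOW_FRACTION) * L))
        for s in (0.10, 0.50, 0.80)
    )


@dataclass(frozen=True)
class SimulationScenario:
    """Generative parameters for one synthetic case-control experiment.

    ``benign_carrier_rate`` is the expected number of benign rare-variant
    carriage events per individual; ``pathogenic_carrier_rate_cases`` is
    the fraction of cases carrying a pathogenic variant; ``penetrance_or``
    is the case:control carriage odds ratio of pathogenic variants.
    Defaults are calibrated so that at desk scale (500/5000) the burden
    signal in a disease gene is overwhelming while the positional tests
    sit in a discriminating mid-to-high power range — the regime in which
    clustering information adds value over burden alone.
    """

    name: str
    L: int = 500
    n_cases: int = DESK_SCALE[0]
    n_controls: int = DESK_SCALE[1]
    cluster_windows: tuple[tuple[int, int], ...] = ()
    benign_carrier_rate: float = 0.06
    pathogenic_carrier_rate_cases: float = 0.045
    penetrance_or: float = 50.0
    maf_threshold: float = 1e-4
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.name not in SCENARIO_NAMES:
            raise ValueError(f"unknown scenario name {self.name!r}")
        windows = tuple(tuple(w) for w in self.cluster_windows)
        if self.name in ("null", "uniform"):
            if windows:
                raise ValueError(f"{self.name} scenario takes no cluster windows")
        else:
            if not windows:
                windows = (
                    single_cluster_windows(self.L)
                    if self.name == "single_cluster"
                    else multi_cluster_windows(self.L)
                )
            prev_end = 0
            for lo, hi in sorted(windows):
                if not (1 <= lo <= hi <= self.L):
                    raise ValueError(f"window ({lo}, {hi}) outside [1, {self.L}]")
                if lo <= prev_end:
                    raise ValueError("cluster windows must not overlap")
                prev_end = hi
        object.__setattr__(self, "cluster_windows", windows)

    @property
    def scale_label(self) -> str:
        return "full" if (self.n_cases, self.n_controls) == FULL_SCALE else "desk"


@dataclass
class SimulatedDataset:
    """A simulated :class:`GeneDataset` plus per-variant ground truth.

    ``truth_pathogenic`` and ``truth_or`` align index-wise with
    ``dataset.variants``.
    """

    dataset: GeneDataset
    truth_pathogenic: np.ndarray
    truth_or: np.ndarray
    scenario: SimulationScenario

    def __post_init__(self) -> None:
        n = len(self.dataset.variants)
        self.truth_pathogenic = np.asarray(self.truth_pathogenic, dtype=bool)
        self.truth_or = np.asarray(self.truth_or, dtype=float)
        if self.truth_pathogenic.shape != (n,) or self.truth_or.shape != (n,):
            raise ValueError("truth vectors must align with dataset.variants")


def _mean_benign_af() -> float:
    """Analytic mean of the log-uniform AF spectrum 10^U, U~U(lo, hi)."""
    lo, hi = AF_LOG10_RANGE
    return (10.0 ** hi - 10.0 ** lo) / ((hi - lo) * math.log(10.0))


def _draw_window_positions(
    rng: np.random.Generator, windows: Sequence[tuple[int, int]], size: int
) -> np.ndarray:
    lengths = np.array([hi - lo + 1 for lo, hi in windows], dtype=float)
    which = rng.choice(len(windows), size=size, p=lengths / lengths.sum())
    lows = np.array([lo for lo, _ in windows])
    highs = np.array([hi for _, hi in windows])
    return rng.integers(lows[which], highs[which] + 1)


def simulate_gene(
    scenario: SimulationScenario,
    seed: int | np.random.SeedSequence | None = None,
    gene: str = "SIM",
) -> SimulatedDataset:
    """Generate one synthetic case-control dataset under ``scenario``.

    The explicit ``seed`` overrides ``scenario.seed``; equal seeds give
    bit-identical datasets.
    """
    if seed is None:
        seed = scenario.seed
    rng = np.random.default_rng(seed)
    L, n_cases, n_controls = scenario.L, scenario.n_cases, scenario.n_controls

    records: list[VariantRecord] = []
    pathogenic: list[bool] = []
    true_or: list[float] = []

    # --- benign background ------------------------------------------------
    n_sites = max(1, round(scenario.benign_carrier_rate / (2.0 * _mean_benign_af())))
    site_pos = rng.integers(1, L + 1, size=n_sites)
    lo, hi = AF_LOG10_RANGE
    site_af = 10.0 ** rng.uniform(lo, hi, size=n_sites)
    carrier_prob = np.minimum(1.0, 2.0 * site_af)  # diploid carriage
    case_counts = rng.binomial(n_cases, carrier_prob)
    ctrl_counts = rng.binomial(n_controls, carrier_prob)
    for pos, af, c_case, c_ctrl in zip(site_pos, site_af, case_counts, ctrl_counts):
        for cohort, count in ((CASE, c_case), (CONTROL, c_ctrl)):
            if count > 0:
                records.append(
                    VariantRecord(
                        gene=gene, residue_position=int(pos), cohort=cohort,
                        carrier_count=int(count), popmax_af=float(af),
                    )
                )
                pathogenic.append(False)
                true_or.append(1.0)

    # --- pathogenic variants ---------------------------------------------
    if scenario.name != "null":
        p_case = scenario.pathogenic_carrier_rate_cases
        if p_case >= 1.0:
            raise ValueError("pathogenic case-carrier rate must be < 1")
        odds_case = p_case / (1.0 - p_case)
        odds_ctrl = odds_case / scenario.penetrance_or
        p_ctrl = odds_ctrl / (1.0 + odds_ctrl)
        n_path_case = rng.binomial(n_cases, p_case)
        n_path_ctrl = rng.binomial(n_controls, p_ctrl)
        windows = scenario.cluster_windows or ((1, L),)
        for cohort, count in ((CASE, n_path_case), (CONTROL, n_path_ctrl)):
            positions = _draw_window_positions(rng, windows, count)
            for pos in positions:
                # each carriage event is its own ultra-rare variant,
                # unseen in the reference population
                records.append(
                    VariantRecord(
                        gene=gene, residue_position=int(pos), cohort=cohort,
                        carrier_count=1, popmax_af=None,
                    )
                )
                pathogenic.append(True)
                true_or.append(scenario.penetrance_or)

    # --- rarity filter ----------------------------------------------------
    kept = filter_rare(records, scenario.maf_threshold)
    kept_ids = {id(v) for v in kept}
    keep_mask = np.array([id(v) in kept_ids for v in records], dtype=bool)

    # sanity: carriage must fit in the cohorts
    for cohort, size in ((CASE, n_cases), (CONTROL, n_controls)):
        total = sum(v.carrier_count for v in kept if v.cohort == cohort)
        if total > size:
            raise ValueError(
                f"simulated {cohort} carriers ({total}) exceed cohort size ({size}); "
                "lower the carrier rates"
            )

    ds = GeneDataset(
        gene=gene, protein_length=L, n_cases=n_cases, n_controls=n_controls,
        variants=kept,
    )
    return SimulatedDataset(
        dataset=ds,
        truth_pathogenic=np.asarray(pathogenic)[keep_mask],
        truth_or=np.asarray(true_or)[keep_mask],
        scenario=scenario,
    )


def default_scenarios() -> list[SimulationScenario]:
    """The standard scenario grid.

    Full scale (5000 cases / 125 000 controls) and desk scale (500 / 5000,
    same 1:25 ratio) crossed with protein lengths 500 and 1000 and the
    four scenario kinds: one null plus three alternatives (uniform,
    single_cluster, multi_cluster) per length and scale.
    """
    out: list[SimulationScenario] = []
    for n_cases, n_controls in (FULL_SCALE, DESK_SCALE):
        for L in (500, 1000):
            for name in SCENARIO_NAMES:
                out.append(
                    SimulationScenario(
                        name=name, L=L, n_cases=n_cases, n_controls=n_controls
                    )
                )
    return out
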