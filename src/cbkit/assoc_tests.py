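"""Association tests for rare missense variants in protein coordinates.

Three complementary tests operate on a :class:`~cbkit.core_data.GeneDataset`:

* the **BIN-test** — a chi-squared two-sample test on a k x 2 contingency
  table of binned residue positions, sensitive to *differential clustering*
  of case versus control variants along the protein;
* a **one-sided burden test** — Fisher's exact test (hypergeometric upper
  tail) for an excess of rare-variant carriers in cases;
* **ClusterBurden** — Fisher's method combination of the two p-values,
  testing the joint hypothesis of excess burden *and* differential
  clustering.  The combination is valid because under the null the two
  component p-values are independent (the burden test conditions on carrier
  totals; the BIN-test compares positions given those totals).

Uneven sequencing depth between cohorts is handled by coverage adjustment:
binned counts are divided by the mean 10x-coverage proportion in each bin
(per cohort), and the burden test shrinks cohort sizes by the gene-wide
mean coverage.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

from .core_data import CASE, CONTROL, BinTable, GeneDataset, carrier_summary

__all__ = [
    "BinTestResult",
    "TestResult",
    "PanelScan",
    "choose_bin_count",
    "bin_positions",
    "bin_edges",
    "adjust_bin_counts",
    "binned_chi2",
    "build_bin_table",
    "bin_test",
    "burden_test",
    "fishers_method",
    "cluster_burden",
    "reference_position_tests",
    "scan_panel",
]

#: p-values are floored here before taking logs in Fisher's method.
P_FLOOR = 1e-300


class BinTestResult(NamedTuple):
    statistic: float
    df: int
    p: float
    k: int
    degenerate: bool = False


@dataclass
class TestResult:
    """Per-gene result of the burden, BIN and combined tests."""

    gene: str
    p_burden: float
    p_cluster: float | None
    p_combined: float
    statistic_cluster: float | None
    df_cluster: int
    n_case_variants: int
    n_control_variants: int
    cluster_degenerate: bool = False


@dataclass
class PanelScan:
    """Multi-gene scan with a Bonferroni-adjusted family threshold.

    ``n_tests`` counts every test performed (three per gene), and
    ``alpha_per_test = alpha_family / n_tests``; ``flags`` maps each gene
    to {test: "significant" | "nominal" | "ns" | "undefined"}.
    """

    results: list[TestResult]
    alpha_family: float = 0.05
    n_tests: int = 0
    alpha_per_test: float = field(init=False)
    flags: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_tests == 0:
            self.n_tests = 3 * len(self.results)
        self.alpha_per_test = self.alpha_family / self.n_tests


def choose_bin_count(n_total_variants: int) -> int:
    """Bin-count heuristic k ~ n^(2/5), round-half-up, floored at 2.

    ``n_total_variants`` is the combined case+control count of observed
    variant positions (carrier-expanded by default upstream).
    """
    if n_total_variants < 0:
        raise ValueError("variant count must be non-negative")
    k = math.floor(n_total_variants ** 0.4 + 0.5)  # round half up
    return max(2, k)


def bin_edges(L: int, k: int) -> np.ndarray:
    """k+1 equal-length bin boundaries over residues [1, L].

    Edges sit at half-integers so bin j covers residues ((j-1)L/k, jL/k],
    consistent with :func:`bin_positions`.
    """
    return np.linspace(0.5, L + 0.5, k + 1)


def bin_positions(positions: Sequence[int] | np.ndarray, L: int, k: int) -> np.ndarray:
    """Count residue positions into k equal-length bins.

    The bin index of residue r is ``min(k, ceil(r*k/L))`` so that bin j
    covers residues ((j-1)L/k, jL/k] and the counts sum to the number of
    positions.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    pos = np.asarray(positions, dtype=int)
    counts = np.zeros(k, dtype=float)
    if pos.size == 0:
        return counts
    if np.any(pos < 1) or np.any(pos > L):
        bad = pos[(pos < 1) | (pos > L)]
        raise ValueError(f"positions out of range [1, {L}]: {bad.tolist()}")
    idx = np.minimum(k, np.ceil(pos * k / L).astype(int)) - 1
    np.add.at(counts, idx, 1.0)
    return counts


def _bin_residue_slices(L: int, k: int) -> list[np.ndarray]:
    """Residues (0-based indices into a coverage vector) in each bin."""
    r = np.arange(1, L + 1)
    idx = np.minimum(k, np.ceil(r * k / L).astype(int)) - 1
    return [np.flatnonzero(idx == j) for j in range(k)]


def adjust_bin_counts(
    counts: np.ndarray, coverage: np.ndarray, L: int | None = None, k: int | None = None
) -> np.ndarray:
    """Divide each bin count by the mean 10x coverage across that bin.

    Low coverage inflates the adjusted count, compensating for variants
    missed by shallow sequencing.  Adjusted counts are real-valued.
    """
    counts = np.asarray(counts, dtype=float)
    coverage = np.asarray(coverage, dtype=float)
    if np.any(coverage <= 0) or np.any(coverage > 1):
        raise ValueError("coverage values must lie in (0, 1]")
    if k is None:
        k = len(counts)
    if L is None:
        L = len(coverage)
    out = np.empty_like(counts)
    for j, residues in enumerate(_bin_residue_slices(L, k)):
        mean_cov = coverage[residues].mean() if residues.size else 1.0
        if mean_cov <= 0:
            raise ValueError(f"mean coverage in bin {j} is zero")
        out[j] = counts[j] / mean_cov
    return out


def binned_chi2(counts_case: np.ndarray, counts_control: np.ndarray) -> BinTestResult:
    """Chi-squared two-sample test on a k x 2 table of binned counts.

    Bins with zero combined count are dropped with a matching reduction in
    the degrees of freedom (df = retained bins - 1).  No continuity
    correction is applied; counts may be real-valued (coverage-adjusted).
    """
    a = np.asarray(counts_case, dtype=float)
    b = np.asarray(counts_control, dtype=float)
    k = len(a)
    keep = (a + b) > 0
    a, b = a[keep], b[keep]
    kept = int(keep.sum())
    if kept < 2:
        return BinTestResult(statistic=0.0, df=0, p=1.0, k=k, degenerate=True)
    table = np.column_stack([a, b])
    total = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    stat = float(((table - expected) ** 2 / expected).sum())
    df = kept - 1
    p = float(stats.chi2.sf(stat, df))
    return BinTestResult(statistic=stat, df=df, p=max(p, P_FLOOR), k=k, degenerate=False)


def build_bin_table(
    ds: GeneDataset,
    use_coverage: bool = False,
    expand_carriers: bool = True,
    k: int | None = None,
) -> BinTable:
    """Assemble the k x 2 (optionally coverage-adjusted) positional table."""
    pos_case = ds.positions(CASE, expand_carriers=expand_carriers)
    pos_ctrl = ds.positions(CONTROL, expand_carriers=expand_carriers)
    n_total = pos_case.size + pos_ctrl.size
    if k is None:
        k = choose_bin_count(n_total)
    L = ds.protein_length
    counts_case = bin_positions(pos_case, L, k)
    counts_ctrl = bin_positions(pos_ctrl, L, k)
    adjusted = False
    if use_coverage:
        if ds.coverage_case is not None:
            counts_case = adjust_bin_counts(counts_case, ds.coverage_case, L, k)
            adjusted = True
        if ds.coverage_control is not None:
            counts_ctrl = adjust_bin_counts(counts_ctrl, ds.coverage_control, L, k)
            adjusted = True
    return BinTable(
        k=k, edges=bin_edges(L, k),
        counts_case=counts_case, counts_control=counts_ctrl,
        adjusted=adjusted,
    )


def bin_test(
    ds: GeneDataset,
    use_coverage: bool = False,
    expand_carriers: bool = True,
) -> BinTestResult:
    """The BIN-test: binned chi-squared comparison of positional distributions.

    Requires at least one variant in each cohort.  When fewer than two bins
    retain counts, the result is flagged degenerate with p = 1.
    """
    if not ds.cohort_variants(CASE) or not ds.cohort_variants(CONTROL):
        raise ValueError(f"{ds.gene}: BIN-test needs >= 1 variant in each cohort")
    table = build_bin_table(ds, use_coverage=use_coverage, expand_carriers=expand_carriers)
    return binned_chi2(table.counts_case, table.counts_control)


def burden_test(ds: GeneDataset, use_coverage: bool = False) -> float:
    """One-sided Fisher's exact test for carrier excess in cases.

    The p-value is the hypergeometric upper tail P(X >= case_carriers) on
    the 2x2 carriers/non-carriers table — only enrichment in cases counts
    as evidence.  With ``use_coverage`` the cohort sizes are first shrunk
    by the gene-wide mean 10x coverage.
    """
    case_car, ctrl_car, _, _ = carrier_summary(ds)
    n_cases, n_controls = ds.n_cases, ds.n_controls
    if use_coverage:
        if ds.coverage_case is not None:
            n_cases = int(round(ds.n_cases * float(np.mean(ds.coverage_case))))
        if ds.coverage_control is not None:
            n_controls = int(round(ds.n_controls * float(np.mean(ds.coverage_control))))
    if case_car > n_cases or ctrl_car > n_controls:
        raise ValueError(
            f"{ds.gene}: carriers exceed effective cohort size "
            f"({case_car}/{n_cases} cases, {ctrl_car}/{n_controls} controls)"
        )
    M = n_cases + n_controls          # population size
    K = case_car + ctrl_car           # total carriers
    p = float(stats.hypergeom.sf(case_car - 1, M, K, n_cases))
    return min(max(p, P_FLOOR), 1.0)


def fishers_method(p1: float, p2: float) -> float:
    """Combine two independent p-values with Fisher's method.

    X = -2(ln p1 + ln p2) is chi-squared with 4 df under the null; the
    upper tail has the closed form exp(-X/2) * (1 + X/2).
    """
    for p in (p1, p2):
        if not 0.0 < p <= 1.0:
            raise ValueError(f"p-values must lie in (0, 1], got {p}")
    p1 = max(p1, P_FLOOR)
    p2 = max(p2, P_FLOOR)
    x = -2.0 * (math.log(p1) + math.log(p2))
    return math.exp(-x / 2.0) * (1.0 + x / 2.0)


def cluster_burden(
    ds: GeneDataset,
    use_coverage: bool = False,
    expand_carriers: bool = True,
) -> TestResult:
    """ClusterBurden: burden and BIN-test p-values combined by Fisher's method.

    If the BIN-test is degenerate (fewer than two populated bins) the
    combined p-value falls back to the burden p-value with a flag.
    """
    p_burden = burden_test(ds, use_coverage=use_coverage)
    bin_res = bin_test(ds, use_coverage=use_coverage, expand_carriers=expand_carriers)
    if bin_res.degenerate:
        p_combined = p_burden
    else:
        p_combined = fishers_method(p_burden, bin_res.p)
    return TestResult(
        gene=ds.gene,
        p_burden=p_burden,
        p_cluster=bin_res.p,
        p_combined=p_combined,
        statistic_cluster=bin_res.statistic,
        df_cluster=bin_res.df,
        n_case_variants=len(ds.cohort_variants(CASE)),
        n_control_variants=len(ds.cohort_variants(CONTROL)),
        cluster_degenerate=bin_res.degenerate,
    )


def reference_position_tests(
    case_positions: Sequence[int] | np.ndarray,
    control_positions: Sequence[int] | np.ndarray,
) -> tuple[float, float]:
    """Comparator two-sample tests on raw position multisets.

    Returns ``(p_AD, p_KS)`` from the k-sample Anderson-Darling test and
    the two-sample Kolmogorov-Smirnov test, with no binning or coverage
    adjustment.  scipy clamps the AD p-value to [0.001, 0.25].
    """
    x = np.asarray(case_positions, dtype=float)
    y = np.asarray(control_positions, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both cohorts need at least one position")
    if np.array_equal(np.sort(x), np.sort(y)):
        # identical multisets: no evidence of any distributional difference
        return 0.25, 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ad = stats.anderson_ksamp([x, y])
        p_ad = float(ad.significance_level)
    ks = stats.ks_2samp(x, y, method="asymp")
    return p_ad, float(min(ks.pvalue, 1.0))


def scan_panel(
    datasets: Sequence[GeneDataset],
    alpha_family: float = 0.05,
    use_coverage: bool = False,
) -> PanelScan:
    """Run burden, BIN and ClusterBurden over a gene panel.

    Each p-value is flagged against the Bonferroni per-test threshold
    ``alpha_family / (3 * n_genes)`` ("significant"), the nominal 0.05
    ("nominal") or neither ("ns").  Genes with an empty cohort get
    "undefined" flags.
    """
    n_tests = 3 * len(datasets)
    results: list[TestResult] = []
    flags: dict[str, dict[str, str]] = {}
    alpha_per_test = alpha_family / n_tests

    def flag(p: float | None) -> str:
        if p is None:
            return "undefined"
        if p < alpha_per_test:
            return "significant"
        if p < 0.05:
            return "nominal"
        return "ns"

    for ds in datasets:
        try:
            res = cluster_burden(ds, use_coverage=use_coverage)
        except ValueError:
            res = TestResult(
                gene=ds.gene, p_burden=burden_test(ds, use_coverage=use_coverage),
                p_cluster=None, p_combined=float("nan"), statistic_cluster=None,
                df_cluster=0,
                n_case_variants=len(ds.cohort_variants(CASE)),
                n_control_variants=len(ds.cohort_variants(CONTROL)),
                cluster_degenerate=True,
            ) if ds.variants else TestResult(
                gene=ds.gene, p_burden=float("nan"), p_cluster=None,
                p_combined=float("nan"), statistic_cluster=None, df_cluster=0,
                n_case_variants=0, n_control_variants=0, cluster_degenerate=True,
            )
        results.append(res)
        flags[ds.gene] = {
            "burden": flag(res.p_burden if not math.isnan(res.p_burden) else None),
            "cluster": flag(res.p_cluster),
            "combined": flag(
                res.p_combined if not math.isnan(res.p_combined) else None
            ),
        }
    scan = PanelScan(results=results, alpha_family=alpha_family, n_tests=n_tests)
    scan.flags = flags
    return scan
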