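"""Core domain containers for rare-missense case-control data.

A gene's data are represented in protein coordinates: every variant is an
amino-acid residue position (1-based) plus a cohort label and a carrier
count.  Cases and controls are kept as separate records even when they hit
the same residue, because carrier counts are cohort-specific.  Rarity is
judged on the population-maximum allele frequency (popmax AF) from a large
reference panel; a variant absent from the reference has a missing popmax
AF and is treated as maximally rare.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "CASE",
    "CONTROL",
    "COHORTS",
    "VariantRecord",
    "GeneDataset",
    "BinTable",
    "filter_rare",
    "carrier_summary",
]

CASE = "case"
CONTROL = "control"
COHORTS = (CASE, CONTROL)

#: Default popmax allele-frequency cutoff for "ultra-rare" missense variants.
RARE_AF_THRESHOLD = 1e-4

#: Expert five-tier classification labels (plus "unknown") carried through
#: for reporting; never used by the statistics.
ACMG_LABELS = (
    "benign",
    "likely_benign",
    "VUS",
    "likely_pathogenic",
    "pathogenic",
    "unknown",
)


@dataclass
class VariantRecord:
    """One observed rare missense variant in one cohort.

    Parameters
    ----------
    gene : str
        Gene symbol.
    residue_position : int
        1-based amino-acid index in the protein.
    cohort : str
        ``"case"`` or ``"control"``.
    carrier_count : int
        Number of carriers (allele count) observed in that cohort; >= 1.
    popmax_af : float or None
        Population-maximum allele frequency in the reference panel.
        ``None`` means the variant was not seen in the reference at all.
    scores : dict or None
        Optional in-silico predictor scores keyed by feature name.
    label : str or None
        Optional expert classification (one of :data:`ACMG_LABELS`).
    """

    gene: str
    residue_position: int
    cohort: str
    carrier_count: int = 1
    popmax_af: float | None = None
    scores: dict[str, float] | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        if self.cohort not in COHORTS:
            raise ValueError(f"cohort must be one of {COHORTS}, got {self.cohort!r}")
        if self.residue_position < 1:
            raise ValueError(f"residue_position must be >= 1, got {self.residue_position}")
        if self.carrier_count < 1:
            raise ValueError(f"carrier_count must be >= 1, got {self.carrier_count}")
        if self.popmax_af is not None:
            if isinstance(self.popmax_af, float) and math.isnan(self.popmax_af):
                self.popmax_af = None
            elif not 0.0 <= self.popmax_af <= 1.0:
                raise ValueError(f"popmax_af must lie in [0, 1], got {self.popmax_af}")
        if self.label is not None and self.label not in ACMG_LABELS:
            raise ValueError(f"unknown label {self.label!r}")


@dataclass
class GeneDataset:
    """All case/control rare variants for one gene plus cohort metadata.

    ``coverage_case`` / ``coverage_control`` are optional per-residue vectors
    of the mean proportion of samples sequenced to at least 10x depth,
    values in (0, 1].  When absent, coverage is assumed complete.
    """

    gene: str
    protein_length: int
    n_cases: int
    n_controls: int
    variants: list[VariantRecord] = field(default_factory=list)
    coverage_case: np.ndarray | None = None
    coverage_control: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.protein_length < 1:
            raise ValueError("protein_length must be positive")
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("cohort sizes must be positive")
        for cov_name in ("coverage_case", "coverage_control"):
            cov = getattr(self, cov_name)
            if cov is None:
                continue
            cov = np.asarray(cov, dtype=float)
            if cov.shape != (self.protein_length,):
                raise ValueError(
                    f"{cov_name} must have length {self.protein_length}, got {cov.shape}"
                )
            if np.any(cov <= 0) or np.any(cov > 1):
                raise ValueError(f"{cov_name} values must lie in (0, 1]")
            setattr(self, cov_name, cov)
        for v in self.variants:
            if v.residue_position > self.protein_length:
                raise ValueError(
                    f"variant at residue {v.residue_position} exceeds protein "
                    f"length {self.protein_length} for {self.gene}"
                )
        case_c, ctrl_c, _, _ = carrier_summary(self)
        del case_c, ctrl_c  # raises if carriers exceed cohort sizes

    # -- convenience accessors -------------------------------------------

    def cohort_variants(self, cohort: str) -> list[VariantRecord]:
        return [v for v in self.variants if v.cohort == cohort]

    def positions(self, cohort: str, expand_carriers: bool = True) -> np.ndarray:
        """Residue positions for one cohort.

        With ``expand_carriers`` each variant contributes ``carrier_count``
        copies of its position (the default convention for the positional
        tests, mirroring allele counts); otherwise one copy per distinct
        variant record.
        """
        pos: list[int] = []
        for v in self.cohort_variants(cohort):
            reps = v.carrier_count if expand_carriers else 1
            pos.extend([v.residue_position] * reps)
        return np.asarray(pos, dtype=int)

    def coverage(self, cohort: str) -> np.ndarray | None:
        return self.coverage_case if cohort == CASE else self.coverage_control


@dataclass
class BinTable:
    """A k x 2 table of binned positional variant counts.

    ``edges`` are the k+1 bin boundaries over [1, L]; bins are half-open
    [lo, hi) except the last, which is closed.  Counts are real-valued when
    coverage-adjusted, integer otherwise.
    """

    k: int
    edges: np.ndarray
    counts_case: np.ndarray
    counts_control: np.ndarray
    adjusted: bool = False

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.counts_case = np.asarray(self.counts_case, dtype=float)
        self.counts_control = np.asarray(self.counts_control, dtype=float)
        if self.k < 2:
            raise ValueError("need at least 2 bins")
        if self.edges.shape != (self.k + 1,) or np.any(np.diff(self.edges) <= 0):
            raise ValueError("edges must be k+1 strictly increasing boundaries")
        if self.counts_case.shape != (self.k,) or self.counts_control.shape != (self.k,):
            raise ValueError("count vectors must have length k")
        if np.any(self.counts_case < 0) or np.any(self.counts_control < 0):
            raise ValueError("counts must be non-negative")

    def as_array(self) -> np.ndarray:
        """The k x 2 table, cases in column 0."""
        return np.column_stack([self.counts_case, self.counts_control])


def filter_rare(
    variants: Iterable[VariantRecord], af_threshold: float = RARE_AF_THRESHOLD
) -> list[VariantRecord]:
    """Keep variants with popmax AF strictly below ``af_threshold``.

    Variants with a missing popmax AF are retained: absence from the
    reference population is the strongest evidence of rarity.  Input
    order is preserved and the operation is idempotent.
    """
    if not 0.0 < af_threshold < 1.0:
        raise ValueError(f"af_threshold must lie in (0, 1), got {af_threshold}")
    return [v for v in variants if v.popmax_af is None or v.popmax_af < af_threshold]


def carrier_summary(ds: GeneDataset) -> tuple[int, int, int, int]:
    """Carrier / non-carrier bookkeeping for the 2x2 burden table.

    Returns ``(case_carriers, control_carriers, case_noncarriers,
    control_noncarriers)``.  Raises if carriers exceed a cohort size.
    """
    case_carriers = sum(v.carrier_count for v in ds.variants if v.cohort == CASE)
    control_carriers = sum(v.carrier_count for v in ds.variants if v.cohort == CONTROL)
    case_non = ds.n_cases - case_carriers
    control_non = ds.n_controls - control_carriers
    if case_non < 0:
        raise ValueError(
            f"{ds.gene}: case carriers ({case_carriers}) exceed n_cases ({ds.n_cases})"
        )
    if control_non < 0:
        raise ValueError(
            f"{ds.gene}: control carriers ({control_carriers}) exceed "
            f"n_controls ({ds.n_controls})"
        )
    return case_carriers, control_carriers, case_non, control_non
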