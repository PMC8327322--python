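"""Tab-separated readers/writers and run configuration.

The native dialect is TSV in protein coordinates (the unit of analysis is
the amino-acid residue, so genomic formats are deliberately out of scope).

Variant tables carry the header columns ``gene``, ``protein_position``,
``cohort``, ``carrier_count``, ``popmax_af`` plus any number of extra
numeric columns, which are preserved as per-variant scores, and an
optional ``acmg_class`` label column.  Coverage tables carry ``gene``,
``position``, ``cohort``, ``prop_10x`` with values in (0, 1]; residues
missing from a profile default to full coverage (1.0).
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core_data import CASE, COHORTS, CONTROL, GeneDataset, VariantRecord

__all__ = [
    "RunConfig",
    "read_variant_table",
    "write_variant_table",
    "read_coverage",
    "read_protein_lengths",
]

logger = logging.getLogger("cbkit")

REQUIRED_COLUMNS = ("gene", "protein_position", "cohort", "carrier_count")
RESERVED_COLUMNS = set(REQUIRED_COLUMNS) | {"popmax_af", "acmg_class"}


@dataclass
class RunConfig:
    """Plain-text-serializable knobs shared by the CLI subcommands."""

    af_threshold: float = 1e-4
    alpha_family: float = 0.05
    bin_floor: int = 2
    basis_dim: int = 10
    smoothing: str = "REML"
    coverage_window: int = 15
    benign_carrier_rate: float = 0.06
    pathogenic_carrier_rate_cases: float = 0.045
    penetrance_or: float = 50.0
    seed: int = 0
    out_dir: str = "."

    def __post_init__(self) -> None:
        if not 0 < self.af_threshold < 1:
            raise ValueError("af_threshold must lie in (0, 1)")
        if not 0 < self.alpha_family < 1:
            raise ValueError("alpha_family must lie in (0, 1)")
        if self.basis_dim < 4:
            raise ValueError("basis_dim must be >= 4")

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def read_protein_lengths(path) -> dict[str, int]:
    """Two-column TSV gene<TAB>length -> dict."""
    df = pd.read_csv(path, sep="\t", comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    if not {"gene", "length"} <= set(df.columns):
        raise ValueError("protein-length table needs columns: gene, length")
    return dict(zip(df["gene"].astype(str), df["length"].astype(int)))


def read_variant_table(
    path,
    protein_lengths: dict[str, int] | None = None,
    n_cases: int = 1,
    n_controls: int = 1,
    coverage: dict[tuple[str, str], np.ndarray] | None = None,
) -> list[GeneDataset]:
    """Read a variant TSV into one :class:`GeneDataset` per gene.

    ``protein_lengths`` supplies L per gene (or a ``protein_length``
    column in the file does); without either, L defaults to the maximum
    observed position, with a warning.  Unknown numeric columns become
    per-variant scores.  Cohort sizes are study metadata and must be
    passed by the caller.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"variant table is missing required column '{col}'")
    bad = df[~df["protein_position"].astype(str).str.fullmatch(r"\d+")]
    if len(bad):
        line = int(bad.index[0]) + 2  # header is line 1
        raise ValueError(f"non-integer protein_position at line {line}")
    df["protein_position"] = df["protein_position"].astype(int)
    score_cols = [c for c in df.columns if c not in RESERVED_COLUMNS
                  and c != "protein_length"]

    datasets: list[GeneDataset] = []
    for gene, sub in df.groupby("gene", sort=True):
        if protein_lengths and gene in protein_lengths:
            L = protein_lengths[gene]
        elif "protein_length" in sub.columns:
            L = int(sub["protein_length"].iloc[0])
        else:
            L = int(sub["protein_position"].max())
            logger.warning(
                "%s: no protein length supplied; using max observed position %d",
                gene, L,
            )
        variants = []
        for _, row in sub.iterrows():
            af = row.get("popmax_af")
            af = None if af is None or pd.isna(af) else float(af)
            scores = {
                c: float(row[c]) for c in score_cols if not pd.isna(row[c])
            } or None
            label = row.get("acmg_class")
            label = None if label is None or pd.isna(label) else str(label)
            variants.append(
                VariantRecord(
                    gene=str(gene), residue_position=int(row["protein_position"]),
                    cohort=str(row["cohort"]), carrier_count=int(row["carrier_count"]),
                    popmax_af=af, scores=scores, label=label,
                )
            )
        cov_case = cov_ctrl = None
        if coverage:
            cov_case = coverage.get((str(gene), CASE))
            cov_ctrl = coverage.get((str(gene), CONTROL))
        datasets.append(
            GeneDataset(
                gene=str(gene), protein_length=L, n_cases=n_cases,
                n_controls=n_controls, variants=variants,
                coverage_case=cov_case, coverage_control=cov_ctrl,
            )
        )
    return datasets


def write_variant_table(datasets, path, header_comments: list[str] | None = None) -> None:
    """Write GeneDatasets back to the TSV dialect (round-trip safe)."""
    rows = []
    score_names: list[str] = []
    for ds in datasets:
        for v in ds.variants:
            row = {
                "gene": v.gene,
                "protein_position": v.residue_position,
                "cohort": v.cohort,
                "carrier_count": v.carrier_count,
                "popmax_af": v.popmax_af if v.popmax_af is not None else np.nan,
                "protein_length": ds.protein_length,
                "acmg_class": v.label if v.label is not None else np.nan,
            }
            if v.scores:
                for k, val in v.scores.items():
                    if k not in score_names:
                        score_names.append(k)
                    row[k] = val
            rows.append(row)
    cols = ["gene", "protein_position", "cohort", "carrier_count", "popmax_af",
            "protein_length", "acmg_class", *score_names]
    df = pd.DataFrame(rows, columns=cols)
    with open(path, "w") as fh:
        for line in header_comments or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_coverage(
    path, protein_lengths: dict[str, int]
) -> dict[tuple[str, str], np.ndarray]:
    """Read per-residue 10x-coverage profiles keyed by (gene, cohort).

    Unlisted residues default to 1.0 (full coverage) with a logged
    warning; duplicate (gene, position, cohort) rows and values outside
    (0, 1] are errors.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    needed = {"gene", "position", "cohort", "prop_10x"}
    if not needed <= set(df.columns):
        raise ValueError(f"coverage table needs columns {sorted(needed)}")
    if df.duplicated(subset=["gene", "position", "cohort"]).any():
        raise ValueError("duplicate (gene, position, cohort) rows in coverage table")
    if ((df["prop_10x"] <= 0) | (df["prop_10x"] > 1)).any():
        raise ValueError("prop_10x values must lie in (0, 1]")
    out: dict[tuple[str, str], np.ndarray] = {}
    for (gene, cohort), sub in df.groupby(["gene", "cohort"]):
        gene, cohort = str(gene), str(cohort)
        if cohort not in COHORTS:
            raise ValueError(f"unknown cohort {cohort!r} in coverage table")
        if gene not in protein_lengths:
            raise ValueError(f"no protein length known for {gene}")
        L = protein_lengths[gene]
        vec = np.ones(L)
        pos = sub["position"].astype(int).to_numpy()
        if pos.min() < 1 or pos.max() > L:
            raise ValueError(f"{gene}: coverage positions outside [1, {L}]")
        vec[pos - 1] = sub["prop_10x"].to_numpy()
        if len(pos) < L:
            logger.warning(
                "%s/%s: %d of %d residues missing from coverage profile; "
                "defaulting to 1.0", gene, cohort, L - len(pos), L,
            )
        out[(gene, cohort)] = vec
    return out
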