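"""Reading, peptide aggregation, quantification filtering, imputation, QC.

Mirrors the processing chain applied to TMT reporter-ion tables before any
comparison: unique-peptide aggregation, removal of under-quantified and
IgG-only proteins, replacement of missing values by the lowest detected
value, and the core-component quality gate on each bait IP.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._types import AbundanceMatrix, Design, ValidationError
from .catalog import ComplexCatalog

__all__ = [
    "read_abundance",
    "aggregate_unique_peptides",
    "apply_quant_filter",
    "impute_lowest_detected",
    "qc_bait_ip",
    "DropReport",
    "QCReport",
]


def _read_table(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep, index_col=index_col)


def read_abundance(table_path: str | Path, design_path: str | Path) -> AbundanceMatrix:
    """Load an abundance TSV/CSV (rows = proteins) against a design table."""
    design = Design.from_tsv(design_path)
    frame = _read_table(table_path)
    bad: list[str] = []
    for col in frame.columns:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        newly_bad = coerced.isna() & frame[col].notna()
        if newly_bad.any():
            for row in frame.index[newly_bad]:
                bad.append(f"row {row!r}, column {col!r}: {frame.at[row, col]!r}")
        frame[col] = coerced
    if bad:
        raise ValidationError("unparseable numeric value(s): " + "; ".join(bad))
    return AbundanceMatrix(frame, design, provenance="raw")


def aggregate_unique_peptides(
    peptides: pd.DataFrame,
    protein_col: str = "protein",
    unique_col: str = "unique",
) -> tuple[pd.DataFrame, list[str]]:
    """Sum unique-peptide abundances per protein and sample.

    Shared peptides are excluded from quantification. Proteins for which
    no unique peptide exists are dropped and returned in the drop report.

    Parameters
    ----------
    peptides:
        One row per peptide with a protein assignment column, a boolean
        uniqueness flag column, and one numeric column per sample.

    Returns
    -------
    (values, dropped):
        Protein x sample abundance frame and the list of proteins that had
        only shared peptides.
    """
    for col in (protein_col, unique_col):
        if col not in peptides.columns:
            raise ValidationError(f"peptide table missing column {col!r}")
    sample_cols = [c for c in peptides.columns if c not in (protein_col, unique_col)]
    flags = peptides[unique_col].astype(bool)
    unique_rows = peptides[flags]
    values = (
        unique_rows.groupby(protein_col)[sample_cols].sum(min_count=1).sort_index()
    )
    all_proteins = set(peptides[protein_col])
    dropped = sorted(all_proteins - set(values.index))
    return values, dropped


@dataclass
class DropReport:
    """Per-reason protein exclusions from the quantification filter."""

    below_min_quantified: list[str] = field(default_factory=list)
    control_only: list[str] = field(default_factory=list)

    @property
    def n_below_min_quantified(self) -> int:
        return len(self.below_min_quantified)

    @property
    def n_control_only(self) -> int:
        return len(self.control_only)


def apply_quant_filter(
    matrix: AbundanceMatrix,
    min_quantified_samples: int = 1,
    drop_control_only: bool = True,
) -> tuple[AbundanceMatrix, DropReport]:
    """Drop under-quantified proteins and proteins seen only in IgG controls."""
    n_samples = len(matrix.design.sample_ids)
    if min_quantified_samples > n_samples:
        raise ValidationError(
            f"min_quantified_samples={min_quantified_samples} exceeds "
            f"sample count {n_samples}"
        )
    observed = matrix.values.notna()
    n_quantified = observed.sum(axis=1)
    low = n_quantified < min_quantified_samples
    report = DropReport(below_min_quantified=sorted(matrix.values.index[low]))
    keep = ~low
    if drop_control_only:
        control_cols = matrix.design.control_samples()
        ip_cols = [c for c in matrix.values.columns if c not in set(control_cols)]
        control_only = observed[control_cols].any(axis=1) & ~observed[ip_cols].any(axis=1)
        control_only &= keep  # report each protein under one reason only
        report.control_only = sorted(matrix.values.index[control_only])
        keep &= ~control_only
    filtered = matrix.with_values(matrix.values[keep])
    return filtered, report


def impute_lowest_detected(
    matrix: AbundanceMatrix, per_sample: bool = False
) -> AbundanceMatrix:
    """Replace missing values with the lowest detected abundance.

    Default is the global matrix minimum (single scalar); ``per_sample``
    switches to each sample column's own observed minimum.
    """
    values = matrix.values
    if values.notna().to_numpy().sum() == 0:
        raise ValidationError("cannot impute an all-missing matrix")
    if per_sample:
        filled = values.apply(lambda col: col.fillna(col.min()))
        if filled.isna().any().any():
            # a fully missing column falls back to the global minimum
            filled = filled.fillna(values.min().min())
    else:
        filled = values.fillna(values.min().min())
    return matrix.with_values(filled, provenance="imputed")


@dataclass
class BaitQC:
    ip_target: str
    cell_context: str
    replicate_scores: dict[str, float]  # sample_id -> mean core enrichment vs IgG
    n_failing: int
    passed: bool
    core_genes_used: list[str]


@dataclass
class QCReport:
    core_enrichment_min: float
    max_failing_replicates: int
    results: list[BaitQC]

    def passed(self, ip_target: str, cell_context: str) -> bool:
        for r in self.results:
            if (r.ip_target, r.cell_context) == (ip_target, cell_context):
                return r.passed
        raise KeyError(f"no QC result for {ip_target}:{cell_context}")

    def failing_ips(self) -> list[tuple[str, str]]:
        return [(r.ip_target, r.cell_context) for r in self.results if not r.passed]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            for sample, score in r.replicate_scores.items():
                rows.append(
                    {
                        "ip_target": r.ip_target,
                        "cell_context": r.cell_context,
                        "sample_id": sample,
                        "core_enrichment": score,
                        "below_threshold": score < self.core_enrichment_min,
                        "ip_passed": r.passed,
                    }
                )
        return pd.DataFrame(rows)


def qc_bait_ip(
    matrix: AbundanceMatrix,
    catalog: ComplexCatalog,
    core_enrichment_min: float = 1.5,
    max_failing_replicates: int = 1,
) -> QCReport:
    """Gate each bait IP on mean core-component enrichment over IgG.

    Per replicate, the score is the mean over detected core components of
    the replicate abundance divided by the protein's mean abundance across
    the matched-context IgG replicates. The IP fails when more than
    ``max_failing_replicates`` replicates score below the threshold.
    """
    mapping = catalog.match_genes(matrix.proteins)
    core = catalog.core_genes()
    core_rows = [sym for sym, gene in mapping.items() if gene in core]
    if not core_rows:
        raise ValidationError("no core components present in the matrix")
    results = []
    for target, context in matrix.design.ips():
        igg_cols = matrix.design.igg_samples(context)
        igg_mean = matrix.values.loc[core_rows, igg_cols].mean(axis=1)
        scores: dict[str, float] = {}
        for sample in matrix.design.samples_for(target, context):
            ratio = matrix.values.loc[core_rows, sample] / igg_mean
            scores[sample] = float(ratio.mean())
        n_failing = sum(score < core_enrichment_min for score in scores.values())
        results.append(
            BaitQC(
                ip_target=target,
                cell_context=context,
                replicate_scores=scores,
                n_failing=n_failing,
                passed=n_failing <= max_failing_replicates,
                core_genes_used=sorted(core_rows),
            )
        )
    return QCReport(core_enrichment_min, max_failing_replicates, results)
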