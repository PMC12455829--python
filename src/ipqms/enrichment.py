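"""IgG filtering, bait normalization, and differential IP enrichment.

The comparison statistic reproduces the analysis chain used for TMT IP
data: per-protein fold change as the ratio of group means of
bait-normalized abundances, a two-sided Welch t-test across replicates,
Benjamini-Hochberg adjustment across the comparison, and a significance
call requiring fold change above the threshold on the enriched side plus
a raw p-value below alpha.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._types import AbundanceMatrix, ValidationError

__all__ = [
    "Thresholds",
    "ComparisonSpec",
    "igg_filter",
    "intersect_for_comparison",
    "bait_normalize",
    "differential_enrichment",
    "significant_counts",
    "run_comparison",
]


@dataclass(frozen=True)
class Thresholds:
    igg_fc_min: float = 1.5
    comparison_fc_min: float = 1.2
    alpha: float = 0.05
    log_scale: bool = False  # Welch test on log2 abundances instead of linear

    def __post_init__(self) -> None:
        if self.igg_fc_min <= 0 or self.comparison_fc_min <= 0:
            raise ValidationError("fold-change thresholds must be positive")
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError("alpha must be in (0, 1)")


@dataclass(frozen=True)
class ComparisonSpec:
    side_a: tuple[str, str]  # (ip_target, cell_context)
    side_b: tuple[str, str]
    label: str = ""

    def __post_init__(self) -> None:
        if self.side_a == self.side_b:
            raise ValidationError("comparison sides must differ")
        if not self.label:
            object.__setattr__(
                self,
                "label",
                f"{self.side_a[0]}-{self.side_a[1]}_vs_{self.side_b[0]}-{self.side_b[1]}",
            )


def igg_filter(
    matrix: AbundanceMatrix,
    ip: tuple[str, str],
    igg_fc_min: float = 1.5,
) -> tuple[set[str], pd.Series]:
    """Retain proteins at or above the fold-change cutoff versus IgG.

    Fold change is the mean over the IP's replicates divided by the mean
    over the matched-context IgG replicates. Proteins strictly below the
    cutoff are removed (a protein exactly at the cutoff is kept).
    """
    target, context = ip
    ip_cols = matrix.design.samples_for(target, context)
    igg_cols = matrix.design.igg_samples(context)
    fc = matrix.values[ip_cols].mean(axis=1) / matrix.values[igg_cols].mean(axis=1)
    fc = fc.rename("fold_change_vs_igg")
    retained = set(fc.index[fc >= igg_fc_min])
    return retained, fc


def intersect_for_comparison(retained_a: set[str], retained_b: set[str]) -> set[str]:
    """Proteins passing the IgG filter on both sides of a comparison."""
    common = set(retained_a) & set(retained_b)
    if not common:
        raise ValidationError("empty intersection between the two retained sets")
    return common


def bait_normalize(
    matrix: AbundanceMatrix, bait: str, samples: list[str] | None = None
) -> AbundanceMatrix:
    """Divide every abundance by the bait abundance in its own sample.

    After normalization the bait row is exactly 1 in every normalized
    column. Columns not listed in ``samples`` (default: all) pass through
    unchanged.
    """
    if bait not in matrix.values.index:
        raise ValidationError(f"bait {bait!r} absent from the matrix")
    cols = list(matrix.values.columns) if samples is None else list(samples)
    bait_row = matrix.values.loc[bait, cols]
    bad = [c for c in cols if not np.isfinite(bait_row[c]) or bait_row[c] <= 0]
    if bad:
        raise ValidationError(
            f"bait {bait!r} abundance missing or non-positive in sample(s): {bad}"
        )
    values = matrix.values.copy()
    values[cols] = values[cols] / bait_row
    return matrix.with_values(values, provenance="normalized")


def welch_test(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise two-sided Welch t-test; returns (t, p) arrays."""
    res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    return np.asarray(res.statistic), np.asarray(res.pvalue)


def differential_enrichment(
    norm_a: pd.DataFrame,
    norm_b: pd.DataFrame,
    thresholds: Thresholds = Thresholds(),
) -> pd.DataFrame:
    """Differential enrichment between two replicate blocks.

    Parameters
    ----------
    norm_a, norm_b:
        Bait-normalized abundance blocks, rows = proteins (identical
        index), columns = replicates of each side.

    Returns
    -------
    DataFrame with columns ``mean_a``, ``mean_b``, ``fold_change``,
    ``p_value``, ``fdr``, ``significant_in`` ("a" / "b" / "none") and
    ``degenerate`` (zero variance on both sides).
    """
    if not norm_a.index.equals(norm_b.index):
        raise ValidationError("the two sides must share the same protein index")
    if norm_a.shape[1] < 2 or norm_b.shape[1] < 2:
        raise ValidationError("need >= 2 replicates on each side")
    a = norm_a.to_numpy(dtype=float)
    b = norm_b.to_numpy(dtype=float)
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(mean_b > 0, mean_a / np.where(mean_b > 0, mean_b, 1.0), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # constant rows (e.g. the bait at exactly 1) are flagged below
        warnings.simplefilter("ignore", RuntimeWarning)
        if thresholds.log_scale:
            _, p = welch_test(np.log2(a), np.log2(b))
        else:
            _, p = welch_test(a, b)
    var_a = a.var(axis=1, ddof=1)
    var_b = b.var(axis=1, ddof=1)
    degenerate = (var_a == 0) & (var_b == 0)
    p = np.where(degenerate & (mean_a == mean_b), 1.0, p)
    p = np.where(np.isnan(p) & degenerate, 1.0, p)
    valid = ~np.isnan(p)
    fdr = np.full_like(p, np.nan)
    if valid.any():
        fdr[valid] = multipletests(p[valid], method="fdr_bh")[1]
    table = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "fold_change": fold,
            "p_value": p,
            "fdr": fdr,
            "degenerate": degenerate,
        },
        index=norm_a.index,
    )
    sig = np.full(len(table), "none", dtype=object)
    ok = valid & np.isfinite(fold)
    enriched_a = ok & (fold > thresholds.comparison_fc_min) & (p < thresholds.alpha)
    with np.errstate(divide="ignore"):
        inv = np.where(fold > 0, 1.0 / np.where(fold > 0, fold, 1.0), np.inf)
    enriched_b = ok & (inv > thresholds.comparison_fc_min) & (p < thresholds.alpha)
    sig[enriched_a] = "a"
    sig[enriched_b] = "b"
    table["significant_in"] = sig
    table.index.name = "protein"
    return table


def significant_counts(
    table: pd.DataFrame, bait: str | None = None
) -> tuple[int, int]:
    """Counts of proteins significant on each side, excluding the bait."""
    t = table if bait is None else table.drop(index=bait, errors="ignore")
    n_a = int((t["significant_in"] == "a").sum())
    n_b = int((t["significant_in"] == "b").sum())
    return n_a, n_b


@dataclass
class ComparisonResult:
    spec: ComparisonSpec
    retained_a: set[str]
    retained_b: set[str]
    compared: set[str]
    table: pd.DataFrame
    fc_vs_igg_a: pd.Series
    fc_vs_igg_b: pd.Series

    @property
    def counts(self) -> tuple[int, int]:
        return significant_counts(self.table)


def run_comparison(
    matrix: AbundanceMatrix,
    spec: ComparisonSpec,
    bait: str,
    thresholds: Thresholds = Thresholds(),
) -> ComparisonResult:
    """Full comparison: IgG filters, intersection, bait normalization, test.

    ``matrix`` must be imputed (no missing values). The bait is always part
    of the compared set when it passes both IgG filters; its fold change is
    1 by construction after normalization.
    """
    retained_a, fc_a = igg_filter(matrix, spec.side_a, thresholds.igg_fc_min)
    retained_b, fc_b = igg_filter(matrix, spec.side_b, thresholds.igg_fc_min)
    compared = intersect_for_comparison(retained_a, retained_b)
    cols_a = matrix.design.samples_for(*spec.side_a)
    cols_b = matrix.design.samples_for(*spec.side_b)
    normalized = bait_normalize(matrix, bait, samples=cols_a + cols_b)
    proteins = sorted(compared)
    table = differential_enrichment(
        normalized.values.loc[proteins, cols_a],
        normalized.values.loc[proteins, cols_b],
        thresholds,
    )
    return ComparisonResult(
        spec=spec,
        retained_a=retained_a,
        retained_b=retained_b,
        compared=compared,
        table=table,
        fc_vs_igg_a=fc_a,
        fc_vs_igg_b=fc_b,
    )
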