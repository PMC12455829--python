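"""Single-cell SWI/SNF detection and co-expression independence analysis.

A cell is "positive" for a gene when its count reaches the detection
threshold (default 1). Subtype detection, components-per-cell summaries
and the pairwise independence test all operate on this binarization, so
running them on raw counts or pre-binarized flags is equivalent.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.io import mmread

from ._types import ValidationError
from .catalog import ComplexCatalog, Subtype

__all__ = [
    "read_sc_matrix",
    "binarize",
    "positive_fraction",
    "call_subtypes",
    "coexpression_independence",
    "components_per_cell",
    "CoexpressionResult",
]


def read_sc_matrix(
    path: str | Path,
    genes_path: str | Path | None = None,
    cells_path: str | Path | None = None,
) -> pd.DataFrame:
    """Gene x cell count matrix from TSV, or MatrixMarket plus name files."""
    path = Path(path)
    if path.suffix == ".mtx":
        if genes_path is None or cells_path is None:
            raise ValidationError("MTX input needs gene and cell name files")
        mat = np.asarray(mmread(path).todense())
        genes = Path(genes_path).read_text().split()
        cells = Path(cells_path).read_text().split()
        if mat.shape != (len(genes), len(cells)):
            raise ValidationError(
                f"MTX shape {mat.shape} does not match names "
                f"({len(genes)} genes, {len(cells)} cells)"
            )
        frame = pd.DataFrame(mat, index=genes, columns=cells)
    else:
        frame = pd.read_csv(path, sep="\t", index_col=0)
    if (frame.to_numpy() < 0).any():
        raise ValidationError("negative counts are not allowed")
    return frame


def binarize(matrix: pd.DataFrame, min_count: int = 1) -> pd.DataFrame:
    if (matrix.to_numpy() < 0).any():
        raise ValidationError("negative counts are not allowed")
    return (matrix >= min_count)


def positive_fraction(
    matrix: pd.DataFrame, genes, min_count: int = 1
) -> tuple[pd.Series, list[str]]:
    """Per-gene fraction of positive cells; absent genes reported aside."""
    if matrix.shape[1] == 0:
        raise ValidationError("matrix has zero cells")
    flags = binarize(matrix, min_count)
    present = [g for g in genes if g in matrix.index]
    not_found = [g for g in genes if g not in matrix.index]
    fractions = flags.loc[present].mean(axis=1).rename("positive_fraction")
    return fractions, not_found


def _subtype_rows(
    matrix: pd.DataFrame, catalog: ComplexCatalog
) -> dict[str, list[str]]:
    """Matrix row names per subtype (alias-aware), plus core rows."""
    mapping = catalog.match_genes(matrix.index)
    by_gene: dict[str, str] = {}
    for row_name, gene in mapping.items():
        by_gene.setdefault(gene, row_name)
    out: dict[str, list[str]] = {}
    for st in Subtype:
        members = catalog.subtype_members(st)
        out[st.value] = [by_gene[g] for g in sorted(members) if g in by_gene]
    out["core"] = [by_gene[g] for g in sorted(catalog.core_genes()) if g in by_gene]
    return out


def call_subtypes(
    matrix: pd.DataFrame,
    catalog: ComplexCatalog,
    require_core: bool = True,
    min_count: int = 1,
) -> tuple[pd.DataFrame, dict]:
    """Per-cell subtype detection and the subtype-combination distribution.

    A cell is positive for a subtype when at least one subtype-specific
    component is detected. With ``require_core`` only cells positive for
    at least one core component are summarized.
    """
    rows = _subtype_rows(matrix, catalog)
    if not any(rows[st.value] for st in Subtype):
        raise ValidationError("no subtype-specific genes present in the matrix")
    flags = binarize(matrix, min_count)
    calls = pd.DataFrame(index=matrix.columns)
    for st in Subtype:
        members = rows[st.value]
        calls[st.value] = flags.loc[members].any(axis=0) if members else False
    calls["core_positive"] = (
        flags.loc[rows["core"]].any(axis=0) if rows["core"] else False
    )
    considered = calls[calls["core_positive"]] if require_core else calls
    n = len(considered)
    n_subtypes = considered[[st.value for st in Subtype]].sum(axis=1)
    summary = {
        "n_cells_total": int(len(calls)),
        "n_cells_considered": int(n),
        "require_core": require_core,
        "subtype_fraction": {
            st.value: (float(considered[st.value].mean()) if n else 0.0)
            for st in Subtype
        },
        "n_subtypes_distribution": {
            k: (float((n_subtypes == k).mean()) if n else 0.0) for k in range(4)
        },
    }
    return calls, summary


@dataclass(frozen=True)
class CoexpressionResult:
    gene_i: str
    gene_j: str
    observed_joint: float
    expected_joint: float
    dependency_ratio: float
    p_value: float
    method: str
    n_cells: int


def coexpression_independence(
    matrix: pd.DataFrame,
    gene_i: str,
    gene_j: str,
    method: str = "fisher_exact",
    n_perm: int = 1000,
    seed: int = 0,
    min_count: int = 1,
    randomized: bool = False,
) -> CoexpressionResult:
    """Test whether two genes are detected in the same cells by chance.

    The observed joint positive fraction is compared with the product of
    the marginal positive fractions; the dependency ratio is
    observed/expected (NaN when the expectation is zero). The p-value
    comes from a two-sided Fisher exact test on the 2x2 detection table,
    or from a label-permutation null. ``randomized`` switches the
    permutation p-value to uniform tie-breaking (exactly uniform under the
    null; useful for calibration studies).
    """
    for g in (gene_i, gene_j):
        if g not in matrix.index:
            raise ValidationError(f"gene {g!r} absent from the matrix")
    n = matrix.shape[1]
    if n < 1:
        raise ValidationError("matrix has zero cells")
    x = binarize(matrix.loc[[gene_i]], min_count).to_numpy()[0]
    y = binarize(matrix.loc[[gene_j]], min_count).to_numpy()[0]
    n11 = int(np.sum(x & y))
    n10 = int(np.sum(x & ~y))
    n01 = int(np.sum(~x & y))
    n00 = n - n11 - n10 - n01
    p_i = (n11 + n10) / n
    p_j = (n11 + n01) / n
    observed = n11 / n
    expected = p_i * p_j
    ratio = observed / expected if expected > 0 else float("nan")
    if method == "fisher_exact":
        _, p_value = stats.fisher_exact([[n11, n10], [n01, n00]], alternative="two-sided")
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        stat_obs = abs(n11 - expected * n)
        y_work = y.copy()
        exceed = 0
        ties = 0
        for _ in range(n_perm):
            rng.shuffle(y_work)
            stat = abs(int(np.sum(x & y_work)) - expected * n)
            if stat > stat_obs:
                exceed += 1
            elif stat == stat_obs:
                ties += 1
        if randomized:
            p_value = (exceed + rng.uniform() * (ties + 1)) / (n_perm + 1)
        else:
            p_value = (exceed + ties + 1) / (n_perm + 1)
    else:
        raise ValidationError(f"unknown method {method!r}")
    return CoexpressionResult(
        gene_i=gene_i,
        gene_j=gene_j,
        observed_joint=observed,
        expected_joint=expected,
        dependency_ratio=ratio,
        p_value=float(p_value),
        method=method,
        n_cells=n,
    )


def components_per_cell(
    matrix: pd.DataFrame,
    catalog: ComplexCatalog,
    min_count: int = 1,
    band: tuple[int, int] | None = None,
) -> tuple[pd.Series, dict]:
    """Per-cell count of detected catalog components, with a histogram.

    ``band = (lo, hi)`` additionally reports the fraction of cells whose
    count lies in the inclusive band.
    """
    mapping = catalog.match_genes(matrix.index)
    rows = list(mapping)
    flags = binarize(matrix.loc[rows], min_count) if rows else None
    counts = (
        flags.sum(axis=0) if flags is not None
        else pd.Series(0, index=matrix.columns)
    ).rename("n_components")
    histogram = counts.value_counts().sort_index()
    summary: dict = {
        "n_catalog_genes_present": len(rows),
        "histogram": {int(k): int(v) for k, v in histogram.items()},
    }
    if band is not None:
        lo, hi = band
        summary["band"] = [lo, hi]
        summary["band_fraction"] = float(((counts >= lo) & (counts <= hi)).mean())
    return counts, summary
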