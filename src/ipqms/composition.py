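"""Annotation-stratified summaries of enrichment tables.

Tags enrichment results with catalog classes and curated gene lists, then
summarizes: subtype-specific mean enrichment, bait-per-complex
stoichiometry, mean interactome enrichment, and overlap between regulated
gene sets and IP-enriched protein sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._types import AbundanceMatrix, ValidationError
from .catalog import ComplexCatalog, SubunitClass

__all__ = [
    "AnnotationLists",
    "read_gene_list",
    "annotate_enrichment",
    "subtype_enrichment_mean",
    "bait_stoichiometry_ratio",
    "interactome_mean_enrichment",
    "expression_interactome_overlap",
]


def read_gene_list(path: str | Path) -> tuple[set[str], str]:
    """One-symbol-per-line gene list; ``#`` lines form the provenance note."""
    provenance: list[str] = []
    genes: set[str] = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            provenance.append(line.lstrip("#").strip())
        else:
            genes.add(line.upper())
    return genes, " ".join(provenance)


@dataclass
class AnnotationLists:
    known_bait_interactors: set[str] = field(default_factory=set)
    transcription_factors: set[str] = field(default_factory=set)
    histone_variants: set[str] = field(default_factory=set)
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.known_bait_interactors = {g.upper() for g in self.known_bait_interactors}
        self.transcription_factors = {g.upper() for g in self.transcription_factors}
        self.histone_variants = {g.upper() for g in self.histone_variants}

    @classmethod
    def from_files(
        cls,
        interactors: str | Path | None = None,
        tfs: str | Path | None = None,
        histones: str | Path | None = None,
    ) -> "AnnotationLists":
        lists = cls()
        if interactors:
            lists.known_bait_interactors, prov = read_gene_list(interactors)
            lists.provenance["known_bait_interactors"] = prov
        if tfs:
            lists.transcription_factors, prov = read_gene_list(tfs)
            lists.provenance["transcription_factors"] = prov
        if histones:
            lists.histone_variants, prov = read_gene_list(histones)
            lists.provenance["histone_variants"] = prov
        return lists


def annotate_enrichment(
    table: pd.DataFrame,
    catalog: ComplexCatalog,
    lists: AnnotationLists | None = None,
) -> pd.DataFrame:
    """Tag each protein with its catalog class and list memberships.

    Annotation is purely additive: all statistic columns are preserved
    unchanged. Symbol matching is case-insensitive with alias expansion
    from the catalog.
    """
    lists = lists or AnnotationLists()
    out = table.copy()
    classes: list[str] = []
    groups: list[str] = []
    for protein in out.index:
        rec = catalog.resolve(str(protein))
        classes.append(rec.subunit_class.value if rec else "")
        groups.append((rec.paralog_group or "") if rec else "")
    out["subunit_class"] = classes
    out["paralog_group"] = groups
    upper = pd.Index([str(p).upper() for p in out.index])
    out["known_interactor"] = upper.isin(lists.known_bait_interactors)
    out["transcription_factor"] = upper.isin(lists.transcription_factors)
    out["histone_variant"] = upper.isin(lists.histone_variants)
    return out


def subtype_enrichment_mean(
    annotated: pd.DataFrame, classes: set[str] | list[str]
) -> tuple[float, list[str]]:
    """Arithmetic mean fold change over detected members of given classes.

    Returns the mean and the audit list of member proteins it was taken
    over. Errors when no member of those classes is detected.
    """
    if "subunit_class" not in annotated.columns:
        raise ValidationError("table is not annotated (missing subunit_class)")
    wanted = {SubunitClass(c).value for c in classes}
    mask = annotated["subunit_class"].isin(wanted) & annotated["fold_change"].notna()
    members = list(annotated.index[mask])
    if not members:
        raise ValidationError(f"no detected members of classes {sorted(wanted)}")
    mean = float(annotated.loc[members, "fold_change"].mean())
    return mean, members


def bait_stoichiometry_ratio(
    matrix: AbundanceMatrix,
    fusion_protein: str,
    normalizer: str,
    ip_a: tuple[str, str],
    ip_b: tuple[str, str],
) -> float:
    """How much more fusion protein per complex one IP carries than another.

    Both IPs are normalized against the ``normalizer`` (complex-defining
    bait, e.g. BRG1) per replicate; the ratio of the fusion protein's mean
    normalized abundance in ``ip_a`` over ``ip_b`` is returned.
    """
    if fusion_protein not in matrix.values.index:
        raise ValidationError(f"fusion protein {fusion_protein!r} absent from matrix")
    from .enrichment import bait_normalize  # local import avoids cycle

    cols_a = matrix.design.samples_for(*ip_a)
    cols_b = matrix.design.samples_for(*ip_b)
    normalized = bait_normalize(matrix, normalizer, samples=cols_a + cols_b)
    row = normalized.values.loc[fusion_protein]
    return float(row[cols_a].mean() / row[cols_b].mean())


def interactome_mean_enrichment(
    table: pd.DataFrame, exclude: set[str] | None = None
) -> tuple[float, int]:
    """Mean fold change over all proteins not in the exclusion set.

    The exclusion set typically holds the catalog core components and the
    bait. Returns (mean fold change, n proteins averaged).
    """
    exclude = {e.upper() for e in (exclude or set())}
    mask = ~pd.Index([str(p).upper() for p in table.index]).isin(exclude)
    mask &= table["fold_change"].notna().to_numpy()
    included = table.loc[mask, "fold_change"]
    if included.empty:
        raise ValidationError("no proteins left after exclusion")
    return float(included.mean()), int(len(included))


def expression_interactome_overlap(
    upregulated: dict[str, set[str]],
    enriched: dict[str, set[str]],
    detected: set[str] | None = None,
) -> dict[str, dict[str, float]]:
    """Overlap between per-condition upregulated genes and enriched proteins.

    For each condition present in both inputs: the overlap count, the
    fraction of upregulated genes enriched in the matching condition, and
    (when ``detected`` is given) the fraction of upregulated genes present
    in the IP data that are enriched in the matching condition.
    """
    out: dict[str, dict[str, float]] = {}
    for cond, up in upregulated.items():
        up = {g.upper() for g in up}
        enr = {g.upper() for g in enriched.get(cond, set())}
        overlap = up & enr
        entry: dict[str, float] = {
            "n_upregulated": len(up),
            "n_overlap": len(overlap),
            "fraction_upregulated_enriched": (len(overlap) / len(up)) if up else 0.0,
        }
        if detected is not None:
            det = {g.upper() for g in detected}
            up_detected = up & det
            entry["n_upregulated_detected"] = len(up_detected)
            entry["fraction_detected_enriched"] = (
                len(overlap & det) / len(up_detected) if up_detected else 0.0
            )
        out[cond] = entry
    return out
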