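"""SWI/SNF subunit catalog: subtype classes, paralog groups, aliases.

The default catalog ships as a versioned TSV data file covering the 29
genes encoding SWI/SNF subunits, partitioned into six classes: components
shared by all subtypes (``core_all``), components present only in cBAF and
PBAF (``core_cbaf_pbaf``), subtype-specific components
(``cbaf_specific`` / ``pbaf_specific`` / ``gbaf_specific``) and the
ATPase module around BRG1/BRM (``atpase_module``). Paralog groups mark
subunits assembled in a mutually exclusive manner (e.g. BAF60A/B/C).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from ._types import ValidationError

__all__ = [
    "SubunitClass",
    "Subtype",
    "SubunitRecord",
    "ComplexCatalog",
    "load_catalog",
    "subtype_members",
]


class SubunitClass(str, enum.Enum):
    CORE_ALL = "core_all"
    CORE_CBAF_PBAF = "core_cbaf_pbaf"
    CBAF_SPECIFIC = "cbaf_specific"
    PBAF_SPECIFIC = "pbaf_specific"
    GBAF_SPECIFIC = "gbaf_specific"
    ATPASE_MODULE = "atpase_module"


class Subtype(str, enum.Enum):
    CBAF = "cbaf"
    PBAF = "pbaf"
    GBAF = "gbaf"


_SUBTYPE_CLASS = {
    Subtype.CBAF: SubunitClass.CBAF_SPECIFIC,
    Subtype.PBAF: SubunitClass.PBAF_SPECIFIC,
    Subtype.GBAF: SubunitClass.GBAF_SPECIFIC,
}

#: classes treated as "core components" for QC and exclusion sets
CORE_CLASSES = (SubunitClass.CORE_ALL, SubunitClass.CORE_CBAF_PBAF)


@dataclass(frozen=True)
class SubunitRecord:
    gene_symbol: str
    subunit_class: SubunitClass
    paralog_group: str | None = None
    protein_aliases: tuple[str, ...] = ()


@dataclass
class ComplexCatalog:
    records: list[SubunitRecord]
    is_default: bool = False
    _by_symbol: dict[str, SubunitRecord] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        seen: dict[str, SubunitRecord] = {}
        for rec in self.records:
            key = rec.gene_symbol.upper()
            if key in seen:
                raise ValidationError(f"duplicate gene_symbol {rec.gene_symbol!r}")
            seen[key] = rec
        # paralog groups may not straddle subunit classes
        groups: dict[str, SubunitClass] = {}
        for rec in self.records:
            if not rec.paralog_group:
                continue
            prev = groups.setdefault(rec.paralog_group, rec.subunit_class)
            if prev is not rec.subunit_class:
                raise ValidationError(
                    f"paralog group {rec.paralog_group!r} spans classes "
                    f"{prev.value} and {rec.subunit_class.value}"
                )
        # alias lookup (case-insensitive), aliases and symbols share a namespace
        lookup = dict(seen)
        for rec in self.records:
            for alias in rec.protein_aliases:
                akey = alias.upper()
                if akey in lookup and lookup[akey] is not rec:
                    raise ValidationError(
                        f"alias {alias!r} collides with another catalog entry"
                    )
                lookup[akey] = rec
        object.__setattr__(self, "_by_symbol", lookup)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def genes(self) -> list[str]:
        return [rec.gene_symbol for rec in self.records]

    def resolve(self, symbol: str) -> SubunitRecord | None:
        """Catalog record for a gene symbol or protein alias, else None."""
        return self._by_symbol.get(symbol.upper())

    def class_members(self, subunit_class: SubunitClass | str) -> set[str]:
        cls = SubunitClass(subunit_class)
        return {r.gene_symbol for r in self.records if r.subunit_class is cls}

    def core_genes(self) -> set[str]:
        """Core components (shared by all subtypes plus cBAF/PBAF-shared)."""
        out: set[str] = set()
        for cls in CORE_CLASSES:
            out |= self.class_members(cls)
        return out

    def subtype_members(self, subtype: Subtype | str) -> set[str]:
        try:
            st = Subtype(subtype)
        except ValueError as exc:
            raise ValidationError(f"unknown subtype {subtype!r}") from exc
        return self.class_members(_SUBTYPE_CLASS[st])

    def paralog_groups(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for rec in self.records:
            if rec.paralog_group:
                out.setdefault(rec.paralog_group, set()).add(rec.gene_symbol)
        return out

    def match_genes(self, symbols) -> dict[str, str]:
        """Map external symbols to catalog gene symbols via alias expansion."""
        out: dict[str, str] = {}
        for s in symbols:
            rec = self.resolve(str(s))
            if rec is not None:
                out[str(s)] = rec.gene_symbol
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_symbol": [r.gene_symbol for r in self.records],
                "subunit_class": [r.subunit_class.value for r in self.records],
                "paralog_group": [r.paralog_group or "" for r in self.records],
                "aliases": ["|".join(r.protein_aliases) for r in self.records],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _record_from_row(row: pd.Series) -> SubunitRecord:
    try:
        cls = SubunitClass(str(row["subunit_class"]).strip())
    except ValueError as exc:
        raise ValidationError(
            f"unknown subunit_class {row['subunit_class']!r} "
            f"for {row['gene_symbol']!r}"
        ) from exc
    aliases_raw = row.get("aliases", "")
    aliases = tuple(
        a.strip() for a in str(aliases_raw).split("|") if a.strip()
    ) if pd.notna(aliases_raw) else ()
    group_raw = row.get("paralog_group", "")
    group = str(group_raw).strip() if pd.notna(group_raw) else ""
    return SubunitRecord(
        gene_symbol=str(row["gene_symbol"]).strip(),
        subunit_class=cls,
        paralog_group=group or None,
        protein_aliases=aliases,
    )


def load_catalog(path: str | Path | None = None) -> ComplexCatalog:
    """Load a subunit catalog TSV, or the shipped SWI/SNF default.

    The TSV must carry a header with columns ``gene_symbol``,
    ``subunit_class``, ``paralog_group``, ``aliases`` (pipe-separated).
    """
    is_default = path is None
    if is_default:
        source = resources.files("ipqms.data").joinpath("swisnf_catalog.tsv")
        with resources.as_file(source) as p:
            frame = pd.read_csv(p, sep="\t", dtype=str)
    else:
        frame = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_symbol", "subunit_class"}
    missing = required - set(frame.columns)
    if missing:
        raise ValidationError(f"catalog missing columns: {sorted(missing)}")
    records = [_record_from_row(row) for _, row in frame.iterrows()]
    return ComplexCatalog(records, is_default=is_default)


def subtype_members(catalog: ComplexCatalog, subtype: Subtype | str) -> set[str]:
    """Subtype-specific gene set (excludes core classes)."""
    return catalog.subtype_members(subtype)
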