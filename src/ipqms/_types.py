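"""Shared data containers for IP-QMS tables.

Two light wrappers around :class:`pandas.DataFrame` carry the package's
state between stages: :class:`Design` (the sample sheet mapping columns of
the quantification table to immunoprecipitations) and
:class:`AbundanceMatrix` (protein x sample abundances plus provenance).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

IGG = "IgG"

DESIGN_COLUMNS = ("sample_id", "ip_target", "cell_context", "replicate", "is_control")


class ValidationError(ValueError):
    """Raised when an input table violates its schema contract."""


def _as_bool(x) -> bool:
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    s = str(x).strip().lower()
    if s in {"true", "1", "yes", "t"}:
        return True
    if s in {"false", "0", "no", "f"}:
        return False
    raise ValidationError(f"cannot interpret {x!r} as boolean")


@dataclass(frozen=True)
class Design:
    """Sample design: which column belongs to which IP.

    ``table`` columns: sample_id, ip_target, cell_context, replicate,
    is_control. IgG controls carry ``ip_target == "IgG"`` and
    ``is_control == True``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in DESIGN_COLUMNS if c not in t.columns]
        if missing:
            raise ValidationError(f"design missing columns: {missing}")
        t = t.copy()
        t["replicate"] = t["replicate"].astype(int)
        t["is_control"] = t["is_control"].map(_as_bool)
        if t["sample_id"].duplicated().any():
            dups = sorted(t.loc[t["sample_id"].duplicated(), "sample_id"])
            raise ValidationError(f"duplicate sample_id(s): {dups}")
        key = t[["ip_target", "cell_context", "replicate"]].apply(tuple, axis=1)
        if key.duplicated().any():
            raise ValidationError("duplicate (ip_target, cell_context, replicate) rows")
        # every non-control IP needs >= 2 replicates and a matched IgG group
        for (target, context), grp in t[~t["is_control"]].groupby(
            ["ip_target", "cell_context"]
        ):
            if len(grp) < 2:
                raise ValidationError(
                    f"IP {target}:{context} has {len(grp)} replicate(s); need >= 2"
                )
            igg = t[(t["is_control"]) & (t["cell_context"] == context)]
            if igg.empty:
                raise ValidationError(f"no IgG control group in context {context!r}")
        object.__setattr__(self, "table", t.reset_index(drop=True))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def ips(self, include_controls: bool = False) -> list[tuple[str, str]]:
        t = self.table if include_controls else self.table[~self.table["is_control"]]
        seen: list[tuple[str, str]] = []
        for target, context in t[["ip_target", "cell_context"]].itertuples(index=False):
            if (target, context) not in seen:
                seen.append((target, context))
        return seen

    def samples_for(self, ip_target: str, cell_context: str) -> list[str]:
        t = self.table
        sel = t[(t["ip_target"] == ip_target) & (t["cell_context"] == cell_context)]
        if sel.empty:
            raise ValidationError(f"no samples for IP {ip_target}:{cell_context}")
        return list(sel.sort_values("replicate")["sample_id"])

    def igg_samples(self, cell_context: str) -> list[str]:
        t = self.table
        sel = t[(t["is_control"]) & (t["cell_context"] == cell_context)]
        if sel.empty:
            raise ValidationError(f"no IgG control samples in context {cell_context!r}")
        return list(sel.sort_values("replicate")["sample_id"])

    def control_samples(self) -> list[str]:
        return list(self.table.loc[self.table["is_control"], "sample_id"])

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Design":
        sep = "," if str(path).endswith(".csv") else "\t"
        return cls(pd.read_csv(path, sep=sep))


@dataclass
class AbundanceMatrix:
    """Protein x sample abundance table with its design attached.

    Missing values are NaN. ``provenance`` is one of ``raw``, ``imputed``,
    ``normalized``.
    """

    values: pd.DataFrame
    design: Design
    provenance: str = "raw"

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            dups = sorted(set(v.index[v.index.duplicated()]))
            raise ValidationError(f"duplicate protein id(s): {dups}")
        table_cols = set(v.columns)
        design_cols = set(self.design.sample_ids)
        if table_cols != design_cols:
            extra = sorted(table_cols - design_cols)
            missing = sorted(design_cols - table_cols)
            raise ValidationError(
                f"matrix/design mismatch: samples only in matrix {extra}, "
                f"only in design {missing}"
            )
        v = v[self.design.sample_ids].astype(float)
        if (v.to_numpy() < 0).any():
            raise ValidationError("negative abundances are not allowed")
        self.values = v

    @property
    def proteins(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def with_values(self, values: pd.DataFrame, provenance: str | None = None) -> "AbundanceMatrix":
        return AbundanceMatrix(values, self.design, provenance or self.provenance)

    def subset(self, proteins: Iterable[str]) -> "AbundanceMatrix":
        keep = [p for p in self.proteins if p in set(proteins)]
        return AbundanceMatrix(self.values.loc[keep], self.design, self.provenance)

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="protein")
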