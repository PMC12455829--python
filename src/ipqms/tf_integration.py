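"""Three-evidence transcription-factor classification.

Each TF carries one call per evidence stream: chromatin-motif enrichment
(``cond_a`` / ``cond_b`` / ``shared_open`` / ``none``), IP enrichment and
RNA regulation (``cond_a`` / ``cond_b`` / ``none``). The integrated label
follows a 2-of-3 same-direction rule with conflict precedence:

1. any two streams calling opposite directions -> ``mixed``;
2. a ``shared_open`` motif together with any directional call -> ``mixed``
   (a "varying pattern");
3. >= 2 streams agreeing on one direction -> ``a_specific``/``b_specific``;
4. ``shared_open`` motif and no directional call -> ``shared``;
5. otherwise (< 2 informative streams) -> ``unassigned``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

from ._types import ValidationError

__all__ = ["TFLabel", "classify_tf", "classify_table", "LABELS"]

MOTIF_DOMAIN = {"cond_a", "cond_b", "shared_open", "none"}
DIRECTIONAL_DOMAIN = {"cond_a", "cond_b", "none"}
LABELS = ("a_specific", "b_specific", "shared", "mixed", "unassigned")
_STREAMS = ("motif", "ip", "rna")


@dataclass(frozen=True)
class TFLabel:
    tf: str
    label: str
    supporting_streams: tuple[str, ...]


def classify_tf(
    motif_call: str, ip_call: str, rna_call: str, tf: str = ""
) -> TFLabel:
    """Integrate the three evidence calls for one transcription factor."""
    if motif_call not in MOTIF_DOMAIN:
        raise ValidationError(f"bad motif_call {motif_call!r}")
    for name, call in (("ip_call", ip_call), ("rna_call", rna_call)):
        if call not in DIRECTIONAL_DOMAIN:
            raise ValidationError(f"bad {name} {call!r}")
    calls = dict(zip(_STREAMS, (motif_call, ip_call, rna_call)))
    a_streams = tuple(s for s, c in calls.items() if c == "cond_a")
    b_streams = tuple(s for s, c in calls.items() if c == "cond_b")
    shared = motif_call == "shared_open"
    if a_streams and b_streams:
        return TFLabel(tf, "mixed", a_streams + b_streams)
    if shared and (a_streams or b_streams):
        return TFLabel(tf, "mixed", ("motif",) + a_streams + b_streams)
    if len(a_streams) >= 2:
        return TFLabel(tf, "a_specific", a_streams)
    if len(b_streams) >= 2:
        return TFLabel(tf, "b_specific", b_streams)
    if shared:
        return TFLabel(tf, "shared", ("motif",))
    return TFLabel(tf, "unassigned", ())


def classify_table(evidence: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Classify every TF in an evidence table.

    ``evidence`` columns: ``tf``, ``motif_call``, ``ip_call``, ``rna_call``
    (or ``tf`` as the index). Returns the label table plus per-label
    counts; also flags the display subset of TFs informative in at least
    two streams.
    """
    df = evidence.reset_index() if "tf" not in evidence.columns else evidence.copy()
    required = {"tf", "motif_call", "ip_call", "rna_call"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"evidence table missing columns: {sorted(missing)}")
    if df["tf"].duplicated().any():
        dups = sorted(df.loc[df["tf"].duplicated(), "tf"])
        raise ValidationError(f"duplicate TF(s): {dups}")
    rows = []
    for rec in df.itertuples(index=False):
        result = classify_tf(rec.motif_call, rec.ip_call, rec.rna_call, tf=rec.tf)
        informative = sum(
            c != "none" for c in (rec.motif_call, rec.ip_call, rec.rna_call)
        )
        rows.append(
            {
                "tf": rec.tf,
                "label": result.label,
                "supporting_streams": "|".join(result.supporting_streams),
                "n_informative": informative,
                "display": informative >= 2,
            }
        )
    columns = ["tf", "label", "supporting_streams", "n_informative", "display"]
    labels = pd.DataFrame(rows, columns=columns).set_index("tf").sort_index()
    counts = {label: 0 for label in LABELS}
    counts.update(Counter(labels["label"]))
    return labels, counts
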