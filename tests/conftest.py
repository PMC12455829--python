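from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ipqms._types import AbundanceMatrix, Design
from ipqms.catalog import load_catalog


@pytest.fixture(scope="session")
def catalog():
    return load_catalog()


def make_design(baits=(("BRG1", "MLS"),), n_reps=3, igg_reps=3):
    """Design with the given bait IPs plus an IgG group per context."""
    rows = []
    for target, context in baits:
        for r in range(1, n_reps + 1):
            rows.append((f"{target}_{context}_r{r}", target, context, r, False))
    for context in sorted({c for _, c in baits}):
        for r in range(1, igg_reps + 1):
            rows.append((f"IgG_{context}_r{r}", "IgG", context, r, True))
    return Design(
        pd.DataFrame(
            rows,
            columns=["sample_id", "ip_target", "cell_context", "replicate", "is_control"],
        )
    )


def make_matrix(values: dict[str, list[float]], design: Design) -> AbundanceMatrix:
    """Abundance matrix from protein -> per-sample value lists."""
    frame = pd.DataFrame.from_dict(values, orient="index", columns=design.sample_ids)
    return AbundanceMatrix(frame, design)


@pytest.fixture
def toy_design():
    return make_design()


def binomial_halfwidth(p: float, n: int, z: float = 1.96) -> float:
    return z * np.sqrt(p * (1 - p) / n)
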