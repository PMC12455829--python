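"""Synthetic IP-QMS, single-cell and TF-evidence data with known truth.

The IP generator draws log-normal base abundances per protein and builds
each sample column multiplicatively: an IgG background level, a planted
per-class enrichment factor for bait IPs, a dedicated bait self-enrichment
factor, and log-normal replicate noise. Values below the detection floor
are censored to missing (missing-not-at-random by construction), which is
what downstream lowest-detected-value imputation targets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._types import IGG, AbundanceMatrix, Design, ValidationError
from .catalog import ComplexCatalog

__all__ = [
    "IPSimConfig",
    "simulate_ip_experiment",
    "simulate_sc_counts",
    "simulate_tf_evidence",
    "study_like_config",
    "planted_fold_change",
    "joint_probability_for_odds",
    "ip_key",
]

MOTIF_VALUES = ("cond_a", "cond_b", "shared_open", "none")
DIRECTIONAL_VALUES = ("cond_a", "cond_b", "none")


def ip_key(target: str, context: str) -> str:
    return f"{target}:{context}"


@dataclass
class IPSimConfig:
    """Parameters of the synthetic IP-QMS experiment.

    ``planted_enrichment`` maps a protein class (a catalog subunit-class
    name, or ``bait`` / ``interactor`` / ``background``) to a mapping of
    ``"TARGET:CONTEXT"`` IP keys to multiplicative enrichment factors over
    the IgG background. Unlisted combinations default to 1.0.
    """

    n_proteins: int = 500
    baits: list[tuple[str, str]] = field(
        default_factory=lambda: [("BRG1", "MLS"), ("BRG1", "EWS"), ("DDIT3", "MLS")]
    )
    n_replicates: int = 3
    base_abundance: tuple[float, float] = (3.0, 1.0)  # natural-log mu, sigma
    igg_background_fraction: float = 0.1
    planted_enrichment: dict[str, dict[str, float]] = field(default_factory=dict)
    bait_factor: float = 20.0
    interactor_fraction: float = 0.2
    detection_floor: float = 0.0
    replicate_cv: float = 0.2
    bait_replicate_cv: float | None = None  # None: baits get replicate_cv too
    seed: int = 0
    protein_names: list[str] | None = None

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValidationError("n_proteins must be >= 1")
        if self.n_replicates < 2:
            raise ValidationError("n_replicates must be >= 2")
        if not 0.0 <= self.igg_background_fraction <= 1.0:
            raise ValidationError("igg_background_fraction must be in [0, 1]")
        if self.bait_factor <= 0:
            raise ValidationError("bait_factor must be > 0")
        if self.detection_floor < 0:
            raise ValidationError("detection_floor must be >= 0")
        if self.replicate_cv < 0:
            raise ValidationError("replicate_cv must be >= 0")
        for cls, per_ip in self.planted_enrichment.items():
            for key, factor in per_ip.items():
                if factor <= 0:
                    raise ValidationError(
                        f"planted factor for {cls}/{key} must be > 0, got {factor}"
                    )


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with unit mean and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def _protein_universe(
    config: IPSimConfig, catalog: ComplexCatalog | None
) -> tuple[list[str], pd.Series]:
    """Protein names plus their true class labels.

    Each bait gene gets its own class label (its gene symbol) so planted
    factors can address baits individually, e.g. the amount of BRG1 pulled
    down by a fusion-protein IP.
    """
    named: list[tuple[str, str]] = []
    if catalog is not None:
        for rec in catalog.records:
            named.append((rec.gene_symbol, rec.subunit_class.value))
    bait_genes = {b for b, _ in config.baits}
    for gene in sorted(bait_genes):
        if not any(name == gene for name, _ in named):
            named.append((gene, gene))
        else:
            named = [
                (name, gene if name == gene else cls) for name, cls in named
            ]
    if config.protein_names is not None:
        missing = bait_genes - set(config.protein_names)
        if missing:
            raise ValidationError(
                f"bait gene(s) absent from protein namespace: {sorted(missing)}"
            )
    n_named = len(named)
    if config.n_proteins < n_named:
        raise ValidationError(
            f"n_proteins={config.n_proteins} smaller than the {n_named} named proteins"
        )
    n_fill = config.n_proteins - n_named
    n_interactors = int(round(config.interactor_fraction * n_fill))
    width = max(4, len(str(config.n_proteins)))
    for i in range(n_fill):
        cls = "interactor" if i < n_interactors else "background"
        named.append((f"PROT{i + 1:0{width}d}", cls))
    names = [n for n, _ in named]
    classes = pd.Series([c for _, c in named], index=names, name="true_class")
    return names, classes


def simulate_ip_experiment(
    config: IPSimConfig, catalog: ComplexCatalog | None = None
) -> tuple[AbundanceMatrix, pd.DataFrame]:
    """Generate an abundance matrix plus an aligned ground-truth table.

    Returns ``(matrix, truth)`` where ``truth`` holds one row per protein
    with its ``true_class`` and one ``factor@TARGET:CONTEXT`` column per
    bait IP giving the realized enrichment factor over IgG background.
    """
    rng = np.random.default_rng(config.seed)
    names, classes = _protein_universe(config, catalog)
    n = len(names)

    contexts = sorted({c for _, c in config.baits})
    rows = []
    for target, context in config.baits:
        for r in range(1, config.n_replicates + 1):
            rows.append((f"{target}_{context}_r{r}", target, context, r, False))
    for context in contexts:
        for r in range(1, config.n_replicates + 1):
            rows.append((f"{IGG}_{context}_r{r}", IGG, context, r, True))
    design = Design(
        pd.DataFrame(
            rows,
            columns=["sample_id", "ip_target", "cell_context", "replicate", "is_control"],
        )
    )

    mu, sigma = config.base_abundance
    base = rng.lognormal(mean=mu, sigma=sigma, size=n)

    # per-protein enrichment factor for each bait IP
    factors = pd.DataFrame(1.0, index=names, columns=[ip_key(t, c) for t, c in config.baits])
    for target, context in config.baits:
        key = ip_key(target, context)
        per_ip = {
            cls: spec.get(key, 1.0) for cls, spec in config.planted_enrichment.items()
        }
        col = classes.map(lambda cls: per_ip.get(cls, 1.0)).astype(float)
        col.loc[classes.index == target] = config.bait_factor
        factors[key] = col.to_numpy()

    bait_rows = np.array([name in {b for b, _ in config.baits} for name in names])
    values = np.empty((n, len(design.sample_ids)))
    for j, row in enumerate(design.table.itertuples(index=False)):
        noise = _lognormal_noise(rng, config.replicate_cv, n)
        if config.bait_replicate_cv is not None:
            noise[bait_rows] = _lognormal_noise(
                rng, config.bait_replicate_cv, int(bait_rows.sum())
            )
        level = base * config.igg_background_fraction
        if not row.is_control:
            level = level * factors[ip_key(row.ip_target, row.cell_context)].to_numpy()
        values[:, j] = level * noise
    frame = pd.DataFrame(values, index=names, columns=design.sample_ids)
    if config.detection_floor > 0:
        frame = frame.mask(frame < config.detection_floor)

    truth = pd.concat(
        [classes, factors.rename(columns=lambda k: f"factor@{k}")], axis=1
    )
    truth.index.name = "protein"
    matrix = AbundanceMatrix(frame, design, provenance="raw")
    return matrix, truth


def planted_fold_change(
    truth: pd.DataFrame,
    side_a: tuple[str, str],
    side_b: tuple[str, str],
    normalizer: str | None = None,
) -> pd.Series:
    """True per-protein fold change for a comparison (ratio of factors).

    With ``normalizer`` set (the bait used for per-replicate
    normalization), the ratio is additionally divided by the normalizer's
    own factor ratio — the quantity the bait-normalized pipeline targets.
    """
    a = truth[f"factor@{ip_key(*side_a)}"]
    b = truth[f"factor@{ip_key(*side_b)}"]
    fc = a / b
    if normalizer is not None:
        fc = fc / (a.loc[normalizer] / b.loc[normalizer])
    return fc.rename("true_fold_change")


def study_like_config(**overrides) -> IPSimConfig:
    """Config emulating the study design: two BRG1 IPs plus a DDIT3 IP.

    All complex classes and interactors are pulled down 4-fold over IgG in
    every bait IP; BRG1 itself is recovered at the bait factor in the
    DDIT3 IP (the fusion pulls down whole complexes), and the fusion is
    present at a modest level in the BRG1 IPs in its own context. Override
    any field, including ``planted_enrichment``, via keyword arguments.
    """
    defaults = IPSimConfig()
    bait_factor = overrides.get("bait_factor", defaults.bait_factor)
    baits = overrides.get("baits", defaults.baits)
    keys = [ip_key(t, c) for t, c in baits]
    pulled = [
        "core_all",
        "core_cbaf_pbaf",
        "cbaf_specific",
        "pbaf_specific",
        "gbaf_specific",
        "atpase_module",
        "interactor",
    ]
    planted: dict[str, dict[str, float]] = {
        cls: {k: 4.0 for k in keys} for cls in pulled
    }
    planted["BRG1"] = {k: bait_factor for k in keys}
    planted["DDIT3"] = {ip_key("BRG1", "MLS"): 4.0}
    for cls, spec in overrides.pop("planted_enrichment", {}).items():
        planted.setdefault(cls, {}).update(spec)
    return IPSimConfig(planted_enrichment=planted, **overrides)


def joint_probability_for_odds(p_i: float, p_j: float, odds: float) -> float:
    """P(both positive) for given marginals and a target odds ratio.

    Solves the 2x2 table with fixed margins and odds ratio ``odds``
    (Plackett construction); ``odds == 1`` gives independence.
    """
    if odds == 1.0:
        return p_i * p_j
    s = 1.0 + (p_i + p_j) * (odds - 1.0)
    disc = s * s - 4.0 * odds * (odds - 1.0) * p_i * p_j
    p11 = (s - math.sqrt(max(disc, 0.0))) / (2.0 * (odds - 1.0))
    lo = max(0.0, p_i + p_j - 1.0)
    hi = min(p_i, p_j)
    return min(max(p11, lo), hi)


def simulate_sc_counts(
    n_cells: int,
    gene_probs: dict[str, float],
    dependency: tuple[str, str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Binary gene x cell detection matrix with optional planted dependency.

    ``dependency = (gene_i, gene_j, odds_multiplier)`` plants the given
    odds ratio between the two genes while keeping their marginal
    detection probabilities intact.
    """
    if n_cells < 1:
        raise ValidationError("n_cells must be >= 1")
    for gene, p in gene_probs.items():
        if not 0.0 <= p <= 1.0:
            raise ValidationError(f"probability for {gene!r} outside [0, 1]: {p}")
    rng = np.random.default_rng(seed)
    genes = list(gene_probs)
    data = {
        g: (rng.random(n_cells) < gene_probs[g]).astype(np.int64) for g in genes
    }
    if dependency is not None:
        gi, gj, odds = dependency
        if odds <= 0:
            raise ValidationError("odds_multiplier must be > 0")
        for g in (gi, gj):
            if g not in gene_probs:
                raise ValidationError(f"dependency gene {g!r} not in gene_probs")
        p_i, p_j = gene_probs[gi], gene_probs[gj]
        p11 = joint_probability_for_odds(p_i, p_j, odds)
        # draw the pair jointly from the 2x2 cell probabilities
        u = rng.random(n_cells)
        cell11 = u < p11
        cell10 = (u >= p11) & (u < p_i)
        cell01 = (u >= p_i) & (u < p_i + (p_j - p11))
        data[gi] = (cell11 | cell10).astype(np.int64)
        data[gj] = (cell11 | cell01).astype(np.int64)
    frame = pd.DataFrame(
        data, index=[f"cell{i + 1}" for i in range(n_cells)]
    ).T
    frame.index.name = "gene"
    return frame


_NOISELESS_PATTERNS = {
    "a_specific": [
        ("cond_a", "cond_a", "cond_a"),
        ("cond_a", "cond_a", "none"),
        ("cond_a", "none", "cond_a"),
        ("none", "cond_a", "cond_a"),
    ],
    "b_specific": [
        ("cond_b", "cond_b", "cond_b"),
        ("cond_b", "cond_b", "none"),
        ("cond_b", "none", "cond_b"),
        ("none", "cond_b", "cond_b"),
    ],
    "shared": [("shared_open", "none", "none")],
    "unassigned": [
        ("none", "none", "none"),
        ("cond_a", "none", "none"),
        ("none", "cond_b", "none"),
        ("none", "none", "cond_a"),
    ],
}


def simulate_tf_evidence(
    n_tfs: int,
    label_mix: dict[str, float],
    noise_rate: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Three-stream TF evidence table plus the generating truth labels.

    Evidence is drawn consistent with each truth label, then every cell is
    independently corrupted with probability ``noise_rate`` (replaced by a
    uniformly chosen different value from its stream's domain).
    """
    if n_tfs < 0:
        raise ValidationError("n_tfs must be >= 0")
    if not 0.0 <= noise_rate <= 1.0:
        raise ValidationError("noise_rate must be in [0, 1]")
    unknown = set(label_mix) - set(_NOISELESS_PATTERNS)
    if unknown:
        raise ValidationError(f"unknown truth label(s): {sorted(unknown)}")
    total = sum(label_mix.values())
    if not math.isclose(total, 1.0, abs_tol=1e-9):
        raise ValidationError(f"label_mix proportions must sum to 1, got {total}")
    rng = np.random.default_rng(seed)
    labels = rng.choice(
        list(label_mix), size=n_tfs, p=np.asarray(list(label_mix.values()))
    )
    rows = []
    for label in labels:
        patterns = _NOISELESS_PATTERNS[label]
        motif, ipc, rna = patterns[rng.integers(len(patterns))]
        calls = [motif, ipc, rna]
        domains = (MOTIF_VALUES, DIRECTIONAL_VALUES, DIRECTIONAL_VALUES)
        for k in range(3):
            if rng.random() < noise_rate:
                alternatives = [v for v in domains[k] if v != calls[k]]
                calls[k] = alternatives[rng.integers(len(alternatives))]
        rows.append(calls)
    tf_names = [f"TF{i + 1:04d}" for i in range(n_tfs)]
    evidence = pd.DataFrame(
        rows, columns=["motif_call", "ip_call", "rna_call"], index=tf_names
    )
    evidence.index.name = "tf"
    truth = pd.Series(labels, index=tf_names, name="true_label")
    truth.index.name = "tf"
    return evidence.reset_index(), truth
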