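"""End-to-end orchestration: ingest -> QC -> filter -> compare -> annotate.

Driven by a single YAML config; emits per-stage TSVs, a summary JSON and a
reproducibility manifest. Bait IPs failing the core-enrichment QC gate are
excluded from comparisons (logged), never silently dropped.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from ._types import AbundanceMatrix, ValidationError
from .catalog import CORE_CLASSES, ComplexCatalog, load_catalog
from .composition import (
    AnnotationLists,
    annotate_enrichment,
    interactome_mean_enrichment,
    subtype_enrichment_mean,
)
from .enrichment import ComparisonSpec, Thresholds, run_comparison, significant_counts
from .ingest import apply_quant_filter, impute_lowest_detected, qc_bait_ip, read_abundance

logger = logging.getLogger("ipqms.pipeline")

__all__ = ["RunConfig", "run_pipeline"]

EXIT_OK = 0
EXIT_VALIDATION = 2
EXIT_QC_ONLY = 3


@dataclass
class RunConfig:
    matrix: str
    design: str
    bait: str
    comparisons: list[dict] = field(default_factory=list)
    catalog: str | None = None
    thresholds: dict = field(default_factory=dict)
    min_quantified_samples: int = 1
    drop_control_only: bool = True
    qc_core_min: float = 1.5
    qc_max_failing: int = 1
    interactors_list: str | None = None
    tf_list: str | None = None
    histone_list: str | None = None
    out_dir: str = "ipqms_out"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        config = cls(**raw)
        config.validate()
        return config

    def validate(self) -> None:
        for name in ("matrix", "design"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise ValidationError(f"{name} file not found: {p}")
        for name in ("catalog", "interactors_list", "tf_list", "histone_list"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ValidationError(f"{name} file not found: {p}")
        if not self.comparisons:
            raise ValidationError("config defines no comparisons")
        for comp in self.comparisons:
            for side in ("side_a", "side_b"):
                if side not in comp or len(comp[side]) != 2:
                    raise ValidationError(
                        f"comparison {comp!r} needs side_a/side_b as [target, context]"
                    )

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def comparison_specs(self) -> list[ComparisonSpec]:
        return [
            ComparisonSpec(
                side_a=tuple(c["side_a"]),
                side_b=tuple(c["side_b"]),
                label=c.get("label", ""),
            )
            for c in self.comparisons
        ]

    def thresholds_obj(self) -> Thresholds:
        return Thresholds(**self.thresholds)


def _comparison_summary(
    annotated: pd.DataFrame, catalog: ComplexCatalog, bait: str
) -> dict:
    n_a, n_b = significant_counts(annotated, bait=bait)
    summary: dict = {"n_significant_a": n_a, "n_significant_b": n_b}
    classes = sorted({c for c in annotated["subunit_class"] if c})
    per_class = {}
    for cls in classes:
        mean, members = subtype_enrichment_mean(annotated, {cls})
        per_class[cls] = {"n_detected": len(members), "mean_fold_change": mean}
    summary["per_class"] = per_class
    exclude = catalog.core_genes() | {bait}
    try:
        mean, n = interactome_mean_enrichment(annotated, exclude)
        summary["interactome_mean_fold_change"] = mean
        summary["interactome_n"] = n
    except ValidationError:
        pass
    return summary


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the manifest dictionary."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    catalog = load_catalog(config.catalog)
    thresholds = config.thresholds_obj()
    lists = AnnotationLists.from_files(
        interactors=config.interactors_list,
        tfs=config.tf_list,
        histones=config.histone_list,
    )

    manifest: dict = {
        "config_hash": config.config_hash(),
        "package_version": __version__,
        "thresholds": asdict(thresholds),
        "seed": config.seed,
        "stages": {},
        "comparisons": {},
        "timestamps": {"started": datetime.now(timezone.utc).isoformat()},
    }

    matrix = read_abundance(config.matrix, config.design)
    n_input = len(matrix.proteins)
    manifest["stages"]["ingest"] = {"n_proteins": n_input}
    logger.info("ingested %d proteins x %d samples", n_input, len(matrix.values.columns))

    filtered, drops = apply_quant_filter(
        matrix, config.min_quantified_samples, config.drop_control_only
    )
    manifest["stages"]["quant_filter"] = {
        "n_input": n_input,
        "n_retained": len(filtered.proteins),
        "n_below_min_quantified": drops.n_below_min_quantified,
        "n_control_only": drops.n_control_only,
    }
    logger.info(
        "quant filter: kept %d, dropped %d under-quantified + %d IgG-only",
        len(filtered.proteins), drops.n_below_min_quantified, drops.n_control_only,
    )

    imputed = impute_lowest_detected(filtered)
    manifest["stages"]["imputation"] = {
        "n_input": len(filtered.proteins),
        "n_retained": len(imputed.proteins),
        "n_imputed_cells": int(filtered.values.isna().to_numpy().sum()),
    }
    imputed.to_tsv(out_dir / "abundance_imputed.tsv")

    qc = qc_bait_ip(imputed, catalog, config.qc_core_min, config.qc_max_failing)
    qc.to_frame().to_csv(out_dir / "qc_report.tsv", sep="\t", index=False)
    failing = set(qc.failing_ips())
    manifest["stages"]["qc"] = {
        "n_input": len(imputed.proteins),
        "n_retained": len(imputed.proteins),
        "failing_ips": [f"{t}:{c}" for t, c in sorted(failing)],
    }
    for target, context in sorted(failing):
        logger.warning("QC gate failed for %s IP in %s; excluded", target, context)

    any_comparison_run = False
    qc_skips = 0
    for spec in config.comparison_specs():
        if spec.side_a in failing or spec.side_b in failing:
            manifest["comparisons"][spec.label] = {"skipped": "qc_gate_failure"}
            logger.warning("comparison %s skipped: QC gate failure", spec.label)
            qc_skips += 1
            continue
        result = run_comparison(imputed, spec, config.bait, thresholds)
        annotated = annotate_enrichment(result.table, catalog, lists)
        annotated.to_csv(out_dir / f"enrichment_{spec.label}.tsv", sep="\t")
        entry = {
            "n_retained_a": len(result.retained_a),
            "n_retained_b": len(result.retained_b),
            "n_compared": len(result.compared),
            **_comparison_summary(annotated, catalog, config.bait),
        }
        manifest["comparisons"][spec.label] = entry
        any_comparison_run = True
        logger.info(
            "comparison %s: %d compared, %d/%d significant",
            spec.label, entry["n_compared"],
            entry["n_significant_a"], entry["n_significant_b"],
        )

    manifest["timestamps"]["finished"] = datetime.now(timezone.utc).isoformat()
    manifest["exit_code"] = (
        EXIT_OK if any_comparison_run or qc_skips == 0 else EXIT_QC_ONLY
    )
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    summary = {
        label: entry for label, entry in manifest["comparisons"].items()
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2))
    return manifest
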