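"""End-to-end orchestration of the translatome analysis stages.

Runs detection filtering, per-fraction ratios, relative translatability,
concordance calls, regulation classification and summaries, then the
optional qPCR, UTR and enrichment stages, writing TSV/JSON reports plus a
run log into the output directory.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib.metadata import version
from pathlib import Path

import pandas as pd

from . import enrichment as enrichment_mod
from . import qpcr as qpcr_mod
from . import utr as utr_mod
from .expression import (
    filter_detected,
    read_expression_table,
    read_fasta_utrs,
)
from .translatability import (
    Thresholds,
    call_regulated,
    classify_table,
    condition_ratio,
    relative_translatability,
    summarize_classes,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    matrix: str
    design: str
    out_dir: str
    flags: str | None = None
    ct: str | None = None
    reference_gene: str = "HPRT1"
    efficiency: float = 2.0
    utr_positive: str | None = None
    utr_negative: str | None = None
    utr_neutral: str | None = None
    gene_sets: str | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    seed: int = 0

    def to_dict(self) -> dict:
        out = {
            "matrix": self.matrix,
            "design": self.design,
            "out_dir": self.out_dir,
            "flags": self.flags,
            "ct": self.ct,
            "reference_gene": self.reference_gene,
            "efficiency": self.efficiency,
            "utr_positive": self.utr_positive,
            "utr_negative": self.utr_negative,
            "utr_neutral": self.utr_neutral,
            "gene_sets": self.gene_sets,
            "thresholds": {
                "up": self.thresholds.up,
                "down": self.thresholds.down,
                "inclusive": self.thresholds.inclusive,
            },
            "seed": self.seed,
        }
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        thr = data.pop("thresholds", None)
        config = cls(**data)
        if thr:
            config.thresholds = Thresholds(**thr)
        return config


def _stage(name):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except PipelineError:
            raise
        except Exception as err:
            raise PipelineError(name, err) from err

    return wrap


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all configured stages and write the report bundle.

    Returns the summary dictionary that is also written to summary.json.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("translatome")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        pkg_version = version("translatome")
    except Exception:  # pragma: no cover - only when not installed
        pkg_version = "unknown"
    logger.info("translatome version %s", pkg_version)
    logger.info("config: %s", json.dumps(config.to_dict(), sort_keys=True))

    try:
        for name, path in (("matrix", config.matrix), ("design", config.design)):
            if not Path(path).exists():
                raise PipelineError(name, FileNotFoundError(f"{name} path {path} does not exist"))

        matrix, design = _stage("read")(
            read_expression_table, config.matrix, config.design, config.flags
        )
        matrix = _stage("filter")(filter_detected, matrix, design)
        poly = _stage("ratios")(condition_ratio, matrix, design, "polysomal")
        tot = _stage("ratios")(condition_ratio, matrix, design, "total")
        table = _stage("translatability")(relative_translatability, poly, tot)
        calls = _stage("calls")(call_regulated, table, config.thresholds)
        classes = _stage("classify")(classify_table, table, config.thresholds)
        summary = _stage("summarize")(summarize_classes, classes, table, config.thresholds)

        frame = table.to_frame()
        frame["call"] = [c.value for c in calls]
        frame["class"] = [c.value for c in classes]
        frame.to_csv(out_dir / "translatability.tsv", sep="\t", index_label="gene_id")

        report = {
            "version": pkg_version,
            "seed": config.seed,
            "config": config.to_dict(),
            "n_genes_input": matrix.n_genes,
            "classification": summary.to_dict(),
        }

        if config.ct:
            ct_table = _stage("qpcr")(qpcr_mod.read_ct_table, config.ct)
            qpcr_results = _stage("qpcr")(
                qpcr_mod.analyze_ct_table, ct_table, config.reference_gene, config.efficiency
            )
            qpcr_results.to_csv(out_dir / "qpcr_results.tsv", sep="\t", index=False)
            report["qpcr"] = {"n_genes": int(qpcr_results["gene"].nunique())}

        utr_paths = {
            "positive": config.utr_positive,
            "negative": config.utr_negative,
            "neutral": config.utr_neutral,
        }
        if any(utr_paths.values()):
            sets = {
                label: (
                    _stage("utr")(read_fasta_utrs, path, label) if path else None
                )
                for label, path in utr_paths.items()
            }
            utr_report = _stage("utr")(
                utr_mod.compare_utr_sets, sets["positive"], sets["negative"], sets["neutral"]
            )
            tables = [
                utr_mod.feature_table(s) for s in sets.values() if s is not None and len(s)
            ]
            pd.concat(tables, ignore_index=True).to_csv(
                out_dir / "utr_features.tsv", sep="\t", index=False
            )
            with open(out_dir / "utr_comparison.json", "w") as fh:
                json.dump(utr_report, fh, indent=2, sort_keys=True)
            report["utr"] = {"n_pairs": len(utr_report["pairs"])}

        if config.gene_sets:
            universe = set(table.gene_ids)
            collection = _stage("enrichment")(
                enrichment_mod.read_gene_sets, config.gene_sets, universe
            )
            regulated = [g for g, c in calls.items() if c.value in ("UP", "DOWN")]
            rows = _stage("enrichment")(
                enrichment_mod.hypergeometric_enrichment, regulated, collection
            )
            rows.to_csv(out_dir / "enrichment.tsv", sep="\t", index=False)
            report["enrichment"] = {"n_categories": int(len(rows))}

        with open(out_dir / "summary.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        logger.info("pipeline complete; outputs in %s", out_dir)
        return report
    except PipelineError as err:
        (out_dir / "INCOMPLETE").write_text(str(err) + "\n")
        logger.error("%s", err)
        raise
    finally:
        root.removeHandler(handler)
        handler.close()
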