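"""Polysome-profiling translatome analysis toolkit.

Computes knockdown/control expression ratios per RNA fraction, the
relative-translatability ratio-of-ratios (RR), concordance-thresholded
translational calls and a polysome-vs-total regulation taxonomy, plus
ddCt qPCR validation, 5'UTR feature comparisons, gene-set
over-representation and a fully seeded synthetic-data generator.
"""

from importlib.resources import files

import pandas as pd

from .expression import (
    ExpressionMatrix,
    SampleDesign,
    UtrSet,
    filter_detected,
    read_expression_table,
    read_fasta_utrs,
)
from .translatability import (
    Call,
    ClassCountSummary,
    RegulationClass,
    Thresholds,
    TranslatabilityTable,
    call_regulated,
    classify_gene,
    classify_table,
    condition_ratio,
    count_threshold_calls,
    relative_translatability,
    summarize_classes,
)

__version__ = "0.1.0"

__all__ = [
    "Call",
    "ClassCountSummary",
    "ExpressionMatrix",
    "RegulationClass",
    "SampleDesign",
    "Thresholds",
    "TranslatabilityTable",
    "UtrSet",
    "call_regulated",
    "classify_gene",
    "classify_table",
    "condition_ratio",
    "count_threshold_calls",
    "filter_detected",
    "load_candidate_genes",
    "read_expression_table",
    "read_fasta_utrs",
    "relative_translatability",
    "summarize_classes",
]


def load_candidate_genes() -> pd.DataFrame:
    """Bundled candidate-gene fold-change table used for validation.

    Columns: gene_id, group, poly_ratio, tot_ratio, rr (all fold changes
    knockdown vs control, printed at one decimal).
    """
    path = files("translatome").joinpath("data/candidate_genes.tsv")
    with path.open() as fh:
        return pd.read_csv(fh, sep="\t")
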