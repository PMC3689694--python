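"""5'UTR feature extraction and distribution comparison.

Extracts GC content and length per sequence, bins them into equal-width
classes (defaults: 11 GC classes over [0, 100], 21 length classes), and
compares regulated vs neutral sets with the two-sample Kolmogorov-Smirnov
test (exact p for small samples, asymptotic otherwise).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .expression import UtrSet

GC_CLASSES = 11
LENGTH_CLASSES = 21

#: switch from the exact two-sample KS p-value to the asymptotic one when
#: n1 * n2 exceeds this product
EXACT_KS_MAX_PRODUCT = 10_000


@dataclass(frozen=True)
class BinnedDistribution:
    edges: tuple[float, ...]
    percentages: tuple[float, ...]

    def __post_init__(self) -> None:
        total = sum(self.percentages)
        if self.percentages and abs(total - 100.0) > 1e-9:
            raise ValueError(f"percentages sum to {total}, expected 100")

    def to_dict(self) -> dict:
        return {"edges": list(self.edges), "percentages": list(self.percentages)}


@dataclass(frozen=True)
class KsResult:
    d: float
    p: float
    n1: int
    n2: int
    mode: str  # "exact" or "asymptotic"

    def to_dict(self) -> dict:
        return {"D": self.d, "p": self.p, "n1": self.n1, "n2": self.n2, "mode": self.mode}


def gc_content(sequence: str) -> float:
    """GC percentage of a nucleotide sequence, case-insensitive.

    N bases are excluded from both numerator and denominator; a sequence of
    only Ns has undefined GC and returns NaN.
    """
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    denom = gc + at
    if denom == 0:
        return math.nan
    return 100.0 * gc / denom


def feature_table(utr_set: UtrSet) -> pd.DataFrame:
    """Per-gene GC percent and length for one UtrSet.

    Genes whose GC is undefined (all-N sequences) are excluded.
    """
    rows = []
    for gene, seq in utr_set.records.items():
        gc = gc_content(seq)
        if math.isnan(gc):
            continue
        rows.append({"gene_id": gene, "set": utr_set.label, "gc_percent": gc, "length": len(seq)})
    return pd.DataFrame(rows, columns=["gene_id", "set", "gc_percent", "length"])


def bin_distribution(values, n_classes: int, lo: float, hi: float) -> BinnedDistribution:
    """Equal-width class percentages over [lo, hi], last class right-inclusive."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("no values to bin")
    if n_classes < 1:
        raise ValueError("need at least one class")
    if lo >= hi:
        raise ValueError(f"invalid range [{lo}, {hi}]")
    out_of_range = arr[(arr < lo) | (arr > hi)]
    if out_of_range.size:
        raise ValueError(f"value {out_of_range[0]} outside [{lo}, {hi}]")
    counts, edges = np.histogram(arr, bins=n_classes, range=(lo, hi))
    pct = 100.0 * counts / arr.size
    # guard against float drift so percentages sum exactly to 100
    pct[-1] += 100.0 - pct.sum()
    return BinnedDistribution(edges=tuple(edges), percentages=tuple(pct))


def ks_two_sample(a, b) -> KsResult:
    """Two-sample Kolmogorov-Smirnov test.

    D is the supremum ECDF distance.  The p-value is exact while
    n1 * n2 <= 10,000 and asymptotic (effective-n Kolmogorov distribution)
    beyond that.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = int(a.size), int(b.size)
    if n1 * n2 <= EXACT_KS_MAX_PRODUCT:
        result = stats.ks_2samp(a, b, method="exact")
        return KsResult(
            d=float(result.statistic), p=float(min(result.pvalue, 1.0)),
            n1=n1, n2=n2, mode="exact",
        )
    d = float(stats.ks_2samp(a, b, method="asymp").statistic)
    # Kolmogorov limit distribution with the effective-n small-sample
    # correction en + 0.12 + 0.11/en (Numerical Recipes convention)
    en = math.sqrt(n1 * n2 / (n1 + n2))
    p = float(stats.kstwobign.sf(d * (en + 0.12 + 0.11 / en)))
    return KsResult(d=d, p=min(p, 1.0), n1=n1, n2=n2, mode="asymptotic")


def _summary_stats(values: np.ndarray) -> dict:
    return {
        "n": int(values.size),
        "mean": float(values.mean()),
        "median": float(np.median(values)),
        "sd": float(values.std(ddof=1)) if values.size > 1 else 0.0,
    }


def compare_utr_sets(
    positive: UtrSet | None,
    negative: UtrSet | None,
    neutral: UtrSet | None,
    gc_classes: int = GC_CLASSES,
    length_classes: int = LENGTH_CLASSES,
) -> dict:
    """Full comparison report for up / down / neutral UTR sets.

    Per non-empty set: feature table, GC and length class distributions and
    summary statistics.  Per pair of non-empty sets: KS results for GC and
    length.  Empty or missing sets are skipped.
    """
    sets = {
        "positive": positive,
        "negative": negative,
        "neutral": neutral,
    }
    features: dict[str, pd.DataFrame] = {}
    for name, utr_set in sets.items():
        if utr_set is None or len(utr_set) == 0:
            continue
        table = feature_table(utr_set)
        if not table.empty:
            features[name] = table

    max_len = max((int(t["length"].max()) for t in features.values()), default=1)
    report: dict = {"sets": {}, "pairs": {}}
    for name, table in features.items():
        gc = table["gc_percent"].to_numpy()
        lengths = table["length"].to_numpy(dtype=float)
        report["sets"][name] = {
            "n": int(len(table)),
            "gc_distribution": bin_distribution(gc, gc_classes, 0.0, 100.0).to_dict(),
            "length_distribution": bin_distribution(
                lengths, length_classes, 0.0, float(max_len)
            ).to_dict(),
            "gc_summary": _summary_stats(gc),
            "length_summary": _summary_stats(lengths),
        }

    names = list(features)
    for i, first in enumerate(names):
        for second in names[i + 1:]:
            pair_key = f"{first}_vs_{second}"
            report["pairs"][pair_key] = {
                "gc": ks_two_sample(
                    features[first]["gc_percent"], features[second]["gc_percent"]
                ).to_dict(),
                "length": ks_two_sample(
                    features[first]["length"], features[second]["length"]
                ).to_dict(),
            }
    return report


def features_frame(report_sets: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Concatenate per-set feature tables into one exportable frame."""
    if not report_sets:
        return pd.DataFrame(columns=["gene_id", "set", "gc_percent", "length"])
    return pd.concat(report_sets.values(), ignore_index=True)
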