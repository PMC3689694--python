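"""Relative-translatability statistic and regulation classification.

For each retained gene, knockdown/control intensity ratios are computed per
replicate within each RNA fraction (polysomal, total).  The per-replicate
relative translatability is their quotient

    rr_i = poly_ratio_i / tot_ratio_i

and a gene is called translationally regulated when rr_i clears the
up/down thresholds concordantly in every replicate.  Genes are further
placed in a mutually exclusive taxonomy that separates polysome-driven
regulation, buffering (total changes with constant polysome load),
opposite-direction changes and concomitant changes.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, SampleDesign, DEFAULT_FLOOR_FACTOR

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Thresholds:
    """Up/down fold-change thresholds shared by ratio directions and RR.

    ``inclusive`` decides whether values exactly at a threshold count as
    changed (>= / <=) rather than strictly beyond it.
    """

    up: float = 1.5
    down: float = 0.67
    inclusive: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.down < 1 < self.up):
            raise ValueError(f"need down < 1 < up, got down={self.down}, up={self.up}")

    def is_up(self, value: float) -> bool:
        return value >= self.up if self.inclusive else value > self.up

    def is_down(self, value: float) -> bool:
        return value <= self.down if self.inclusive else value < self.down

    def direction(self, value: float) -> int:
        """+1 above the up threshold, -1 below the down threshold, 0 within."""
        if self.is_up(value):
            return 1
        if self.is_down(value):
            return -1
        return 0


class RegulationClass(enum.Enum):
    """Mutually exclusive regulation groups for a retained gene."""

    POLY_ONLY_UP = "POLY_ONLY_UP"
    POLY_ONLY_DOWN = "POLY_ONLY_DOWN"
    BUFFERED_UP = "BUFFERED_UP"
    BUFFERED_DOWN = "BUFFERED_DOWN"
    OPPOSITE = "OPPOSITE"
    CONCOMITANT_UNMODIFIED = "CONCOMITANT_UNMODIFIED"
    OTHER_MODIFIED = "OTHER_MODIFIED"
    UNCHANGED = "UNCHANGED"


class Call(enum.Enum):
    UP = "UP"
    DOWN = "DOWN"
    NOT_RETAINED = "NOT_RETAINED"


@dataclass(frozen=True)
class TranslatabilityTable:
    """Per-gene, per-replicate ratios and RR with geometric-mean summaries."""

    poly_ratios: pd.DataFrame  # genes x replicates
    tot_ratios: pd.DataFrame
    rr: pd.DataFrame
    poly_summary: pd.Series
    tot_summary: pd.Series
    rr_summary: pd.Series

    @property
    def gene_ids(self) -> list[str]:
        return list(self.rr.index)

    @property
    def replicates(self) -> list[int]:
        return list(self.rr.columns)

    def to_frame(self) -> pd.DataFrame:
        """Flat per-gene table suitable for TSV export."""
        out = pd.DataFrame(index=self.rr.index)
        for rep in self.replicates:
            out[f"poly_ratio_r{rep}"] = self.poly_ratios[rep]
            out[f"tot_ratio_r{rep}"] = self.tot_ratios[rep]
            out[f"rr_r{rep}"] = self.rr[rep]
        out["poly_geomean"] = self.poly_summary
        out["tot_geomean"] = self.tot_summary
        out["rr_geomean"] = self.rr_summary
        return out


@dataclass
class ClassCountSummary:
    """Counts per regulation class plus headline totals."""

    class_counts: dict[RegulationClass, int]
    n_expressed: int
    n_rr_modified: int
    n_tot_modified: int

    def to_dict(self) -> dict:
        return {
            "class_counts": {c.value: n for c, n in self.class_counts.items()},
            "n_expressed": self.n_expressed,
            "n_rr_modified": self.n_rr_modified,
            "n_tot_modified": self.n_tot_modified,
        }


def condition_ratio(
    matrix: ExpressionMatrix,
    design: SampleDesign,
    fraction: str,
    floor_factor: float = DEFAULT_FLOOR_FACTOR,
) -> pd.DataFrame:
    """Per-gene knockdown/control ratio for each replicate of one fraction.

    Only genes retained for this fraction (per the detection filter) appear
    in the result.  Zero intensities are floored first.
    """
    matrix.validate_against(design)
    replicates = design.replicates(fraction)
    if not replicates:
        raise ValueError(f"no complete replicate pairs for fraction {fraction!r}")
    all_reps = sorted(
        set(design.table.loc[design.table["fraction"] == fraction, "replicate"].astype(int))
    )
    incomplete = [r for r in all_reps if r not in replicates]
    if incomplete:
        raise ValueError(
            f"missing paired sample for ({fraction!r}, replicate {incomplete[0]})"
        )
    values = matrix.floored_values(floor_factor)
    genes = matrix.retained_genes(fraction)
    ratios = pd.DataFrame(index=pd.Index(genes, name="gene_id"), columns=replicates, dtype=float)
    for rep in replicates:
        kd = design.sample_for("knockdown", fraction, rep)
        ctrl = design.sample_for("control", fraction, rep)
        ratios[rep] = values.loc[genes, kd] / values.loc[genes, ctrl]
    return ratios


def _geomean(frame: pd.DataFrame) -> pd.Series:
    return np.exp(np.log(frame.astype(float)).mean(axis=1))


def relative_translatability(
    poly_ratios: pd.DataFrame, tot_ratios: pd.DataFrame
) -> TranslatabilityTable:
    """Combine per-fraction ratio tables into RR per replicate + summaries.

    Genes present in only one fraction are dropped (inner join) and logged.
    """
    if list(poly_ratios.columns) != list(tot_ratios.columns):
        raise ValueError(
            f"replicate labels differ: {list(poly_ratios.columns)} vs {list(tot_ratios.columns)}"
        )
    common = poly_ratios.index.intersection(tot_ratios.index)
    lost = len(poly_ratios.index.union(tot_ratios.index)) - len(common)
    if lost:
        logger.info("dropped %d genes absent from one fraction", lost)
    poly = poly_ratios.loc[common].astype(float)
    tot = tot_ratios.loc[common].astype(float)
    for name, frame in (("poly", poly), ("tot", tot)):
        arr = frame.to_numpy()
        if arr.size and ((arr <= 0).any() or not np.isfinite(arr).all()):
            raise ValueError(f"{name} ratios must be finite and > 0")
    rr = poly / tot
    return TranslatabilityTable(
        poly_ratios=poly,
        tot_ratios=tot,
        rr=rr,
        poly_summary=_geomean(poly),
        tot_summary=_geomean(tot),
        rr_summary=_geomean(rr),
    )


def call_regulated(
    table: TranslatabilityTable,
    thresholds: Thresholds = Thresholds(),
    allow_single_replicate: bool = False,
) -> pd.Series:
    """UP/DOWN/NOT_RETAINED call per gene from per-replicate RR concordance.

    UP requires every replicate's RR to clear the up threshold; DOWN
    likewise for the down threshold; anything discordant or within the band
    is NOT_RETAINED.
    """
    n_reps = len(table.replicates)
    if n_reps < 2:
        if not allow_single_replicate:
            raise ValueError("need >=2 replicates for concordance calls")
        logger.warning("single-replicate calls enabled; that replicate decides")
    rr = table.rr
    if thresholds.inclusive:
        up = rr.ge(thresholds.up).all(axis=1)
        down = rr.le(thresholds.down).all(axis=1)
    else:
        up = rr.gt(thresholds.up).all(axis=1)
        down = rr.lt(thresholds.down).all(axis=1)
    calls = pd.Series(Call.NOT_RETAINED, index=rr.index, dtype=object)
    calls[up] = Call.UP
    calls[down] = Call.DOWN
    return calls


def classify_gene(
    poly_summary: float,
    tot_summary: float,
    rr_summary: float,
    thresholds: Thresholds = Thresholds(),
) -> RegulationClass:
    """Deterministic regulation class from summary poly, tot and RR values.

    The grid crosses the poly/tot change directions with the RR band:

    * RR within the band: concomitant same-direction changes are
      CONCOMITANT_UNMODIFIED, everything else UNCHANGED.
    * RR beyond a threshold: poly changed alone -> POLY_ONLY_*; total
      changed alone with constant polysome load -> BUFFERED_* (named for
      the RR direction); both changed in opposite directions -> OPPOSITE;
      any residual pattern -> OTHER_MODIFIED.
    """
    for name, v in (("poly", poly_summary), ("tot", tot_summary), ("rr", rr_summary)):
        if not (np.isfinite(v) and v > 0):
            raise ValueError(f"{name} summary must be finite and > 0, got {v}")
    poly_dir = thresholds.direction(poly_summary)
    tot_dir = thresholds.direction(tot_summary)
    rr_dir = thresholds.direction(rr_summary)

    if rr_dir == 0:
        if poly_dir != 0 and poly_dir == tot_dir:
            return RegulationClass.CONCOMITANT_UNMODIFIED
        return RegulationClass.UNCHANGED

    if poly_dir != 0 and tot_dir == 0:
        return RegulationClass.POLY_ONLY_UP if poly_dir > 0 else RegulationClass.POLY_ONLY_DOWN
    if poly_dir == 0 and tot_dir != 0:
        if tot_dir < 0 and rr_dir > 0:
            return RegulationClass.BUFFERED_UP
        if tot_dir > 0 and rr_dir < 0:
            return RegulationClass.BUFFERED_DOWN
        return RegulationClass.OTHER_MODIFIED
    if poly_dir != 0 and tot_dir != 0 and poly_dir != tot_dir:
        return RegulationClass.OPPOSITE
    return RegulationClass.OTHER_MODIFIED


def classify_table(
    table: TranslatabilityTable, thresholds: Thresholds = Thresholds()
) -> pd.Series:
    """Vector of RegulationClass over a TranslatabilityTable's genes."""
    return pd.Series(
        [
            classify_gene(p, t, r, thresholds)
            for p, t, r in zip(table.poly_summary, table.tot_summary, table.rr_summary)
        ],
        index=table.rr.index,
        dtype=object,
    )


def summarize_classes(
    classes: pd.Series,
    table: TranslatabilityTable | None = None,
    thresholds: Thresholds = Thresholds(),
) -> ClassCountSummary:
    """Count genes per regulation class and derive headline totals."""
    counts = {cls: 0 for cls in RegulationClass}
    for cls in classes:
        counts[cls] += 1
    unmodified = {RegulationClass.CONCOMITANT_UNMODIFIED, RegulationClass.UNCHANGED}
    n_rr_modified = sum(n for cls, n in counts.items() if cls not in unmodified)
    if table is not None:
        n_tot_modified = int(
            sum(thresholds.direction(v) != 0 for v in table.tot_summary)
        )
    else:
        n_tot_modified = 0
    return ClassCountSummary(
        class_counts=counts,
        n_expressed=int(len(classes)),
        n_rr_modified=n_rr_modified,
        n_tot_modified=n_tot_modified,
    )


def count_threshold_calls(
    rr_values, thresholds: Thresholds = Thresholds()
) -> tuple[int, int]:
    """Count RR values meeting the up and down thresholds.

    Accepts any iterable of positive RR values and returns
    ``(n_up, n_down)``.
    """
    values = np.asarray(list(rr_values), dtype=float)
    if values.size and ((values <= 0).any() or not np.isfinite(values).all()):
        raise ValueError("RR values must be finite and > 0")
    n_up = int(sum(thresholds.is_up(v) for v in values))
    n_down = int(sum(thresholds.is_down(v) for v in values))
    return n_up, n_down
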