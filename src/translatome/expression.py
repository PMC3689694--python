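"""Expression-matrix data model and I/O.

Holds normalized two-fraction (polysomal / total cytoplasmic) intensities
together with the sample design and per-sample detection flags, and applies
the detection filter: a gene is kept for a fraction's analysis if it is
flagged detected in at least one sample of at least one condition group
(knockdown or control) of that fraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

CONDITIONS = ("knockdown", "control")
FRACTIONS = ("polysomal", "total")

#: relative floor applied to zero intensities before ratio computation,
#: as a multiple of the median positive intensity
DEFAULT_FLOOR_FACTOR = 1e-6


class ExpressionError(ValueError):
    """Raised on malformed expression inputs."""


@dataclass(frozen=True)
class SampleDesign:
    """Maps each sample to a (condition, fraction, replicate) triple."""

    table: pd.DataFrame  # index: sample_id; columns: condition, fraction, replicate

    def __post_init__(self) -> None:
        required = {"condition", "fraction", "replicate"}
        missing = required - set(self.table.columns)
        if missing:
            raise ExpressionError(f"design missing columns: {sorted(missing)}")
        if self.table.index.duplicated().any():
            dups = self.table.index[self.table.index.duplicated()].tolist()
            raise ExpressionError(f"duplicate sample ids in design: {dups}")
        bad_cond = set(self.table["condition"]) - set(CONDITIONS)
        if bad_cond:
            raise ExpressionError(f"unknown conditions: {sorted(bad_cond)}")
        bad_frac = set(self.table["fraction"]) - set(FRACTIONS)
        if bad_frac:
            raise ExpressionError(f"unknown fractions: {sorted(bad_frac)}")
        reps = self.table["replicate"]
        if not (reps.astype(int) == reps).all() or (reps.astype(int) < 1).any():
            raise ExpressionError("replicate ids must be positive integers")
        triples = self.table[["condition", "fraction", "replicate"]]
        if triples.duplicated().any():
            dup = triples[triples.duplicated()].iloc[0]
            raise ExpressionError(
                "duplicate (condition, fraction, replicate) triple: "
                f"({dup['condition']}, {dup['fraction']}, {dup['replicate']})"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def replicates(self, fraction: str) -> list[int]:
        """Replicate ids for which the fraction has both conditions."""
        sub = self.table[self.table["fraction"] == fraction]
        out = []
        for rep, grp in sub.groupby("replicate"):
            if set(grp["condition"]) == set(CONDITIONS):
                out.append(int(rep))
        return sorted(out)

    def sample_for(self, condition: str, fraction: str, replicate: int) -> str:
        mask = (
            (self.table["condition"] == condition)
            & (self.table["fraction"] == fraction)
            & (self.table["replicate"] == replicate)
        )
        hits = self.table.index[mask]
        if len(hits) != 1:
            raise ExpressionError(
                f"no sample for ({condition}, {fraction}, replicate {replicate})"
            )
        return hits[0]

    def samples_for(self, condition: str, fraction: str) -> list[str]:
        mask = (self.table["condition"] == condition) & (
            self.table["fraction"] == fraction
        )
        return list(self.table.index[mask])


@dataclass(frozen=True)
class ExpressionMatrix:
    """Nonnegative intensities and detection flags for genes x samples.

    ``retained`` (genes x fractions, bool) is populated by
    :func:`filter_detected`; until then analyses treat every gene as
    retained for every fraction.
    """

    values: pd.DataFrame
    detected: pd.DataFrame
    retained: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ExpressionError(f"duplicate gene id: {dup!r}")
        arr = self.values.to_numpy(dtype=float, copy=False)
        if arr.size and not np.isfinite(arr).all():
            gi, si = np.argwhere(~np.isfinite(arr))[0]
            raise ExpressionError(
                f"non-finite value at ({self.values.index[gi]}, {self.values.columns[si]})"
            )
        if arr.size and (arr < 0).any():
            gi, si = np.argwhere(arr < 0)[0]
            raise ExpressionError(
                f"negative value at ({self.values.index[gi]}, {self.values.columns[si]})"
            )
        if not self.detected.index.equals(self.values.index) or not self.detected.columns.equals(
            self.values.columns
        ):
            raise ExpressionError("detection flags must have the matrix's shape and labels")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_genes(self) -> int:
        return len(self.values.index)

    def retained_genes(self, fraction: str) -> list[str]:
        if self.retained is None:
            return self.gene_ids
        return list(self.retained.index[self.retained[fraction]])

    def validate_against(self, design: SampleDesign) -> None:
        matrix_samples = set(self.values.columns)
        design_samples = set(design.sample_ids)
        if matrix_samples != design_samples:
            only_matrix = sorted(matrix_samples - design_samples)
            only_design = sorted(design_samples - matrix_samples)
            raise ExpressionError(
                "matrix/design sample mismatch: "
                f"matrix-only={only_matrix}, design-only={only_design}"
            )

    def floored_values(self, floor_factor: float = DEFAULT_FLOOR_FACTOR) -> pd.DataFrame:
        """Replace zero intensities by a small epsilon before ratio work.

        Epsilon is ``floor_factor`` times the median positive intensity, so
        ordering is preserved and division by zero cannot occur.
        """
        arr = self.values.to_numpy(dtype=float)
        n_zero = int((arr == 0).sum())
        if n_zero == 0:
            return self.values.astype(float)
        positives = arr[arr > 0]
        eps = floor_factor * (np.median(positives) if positives.size else 1.0)
        logger.warning("floored %d zero intensities to %.3g", n_zero, eps)
        return self.values.astype(float).where(self.values > 0, eps)


@dataclass(frozen=True)
class UtrSet:
    """A labelled collection of 5'UTR sequences keyed by gene id."""

    label: str
    records: dict[str, str]

    def __post_init__(self) -> None:
        for gene, seq in self.records.items():
            if not seq:
                raise ExpressionError(f"empty sequence for {gene!r} in set {self.label!r}")

    def __len__(self) -> int:
        return len(self.records)


def read_design(path) -> SampleDesign:
    table = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in table.columns:
        raise ExpressionError(f"design file {path} lacks a sample_id column")
    return SampleDesign(table.set_index("sample_id"))


def read_expression_table(
    path, design_path, flags_path=None
) -> tuple[ExpressionMatrix, SampleDesign]:
    """Read a genes-x-samples TSV plus its design (and optional flag TSV).

    The matrix TSV has a ``gene_id`` first column and one column per sample.
    A missing flags file means every cell is treated as detected.
    """
    design = read_design(design_path)
    raw = pd.read_csv(path, sep="\t", dtype={0: str})
    gene_col = raw.columns[0]
    if raw[gene_col].duplicated().any():
        dup = raw[gene_col][raw[gene_col].duplicated()].iloc[0]
        raise ExpressionError(f"duplicate gene id: {dup!r}")
    values = raw.set_index(gene_col)
    values.index.name = "gene_id"
    try:
        values = values.astype(float)
    except (TypeError, ValueError):
        for col in values.columns:
            coerced = pd.to_numeric(values[col], errors="coerce")
            bad = coerced.isna() & values[col].notna()
            if bad.any():
                gene = values.index[bad][0]
                raise ExpressionError(
                    f"non-numeric value at ({gene}, {col}): {values.loc[gene, col]!r}"
                ) from None
        raise
    if flags_path is not None:
        flags_raw = pd.read_csv(flags_path, sep="\t", dtype={0: str})
        detected = flags_raw.set_index(flags_raw.columns[0]).astype(int).astype(bool)
        detected.index.name = "gene_id"
        detected = detected.reindex(index=values.index, columns=values.columns)
        if detected.isna().any().any():
            raise ExpressionError("detection flags do not cover the full matrix")
    else:
        detected = pd.DataFrame(True, index=values.index, columns=values.columns)
    matrix = ExpressionMatrix(values=values, detected=detected)
    matrix.validate_against(design)
    return matrix, design


def write_expression_table(matrix: ExpressionMatrix, path, flags_path=None) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene_id")
    if flags_path is not None:
        matrix.detected.astype(int).to_csv(flags_path, sep="\t", index_label="gene_id")


def write_design(design: SampleDesign, path) -> None:
    design.table.to_csv(path, sep="\t", index_label="sample_id")


def filter_detected(matrix: ExpressionMatrix, design: SampleDesign) -> ExpressionMatrix:
    """Apply the detection filter.

    A gene is retained for a fraction if it is detected in >=1 sample of at
    least one condition group (knockdown or control) within that fraction.
    Genes retained for neither fraction are dropped from the matrix.
    """
    matrix.validate_against(design)
    retained = pd.DataFrame(False, index=matrix.values.index, columns=list(FRACTIONS))
    for fraction in FRACTIONS:
        keep = pd.Series(False, index=matrix.values.index)
        for condition in CONDITIONS:
            samples = design.samples_for(condition, fraction)
            if samples:
                keep |= matrix.detected[samples].any(axis=1)
        retained[fraction] = keep
    any_kept = retained.any(axis=1)
    n_dropped = int((~any_kept).sum())
    if n_dropped:
        logger.info("detection filter dropped %d genes", n_dropped)
    return ExpressionMatrix(
        values=matrix.values.loc[any_kept],
        detected=matrix.detected.loc[any_kept],
        retained=retained.loc[any_kept],
    )


_NUCLEOTIDES = set("ACGTN")


def read_fasta_utrs(path, label: str) -> UtrSet:
    """Read one FASTA file of 5'UTR sequences into a labelled UtrSet.

    Sequences are uppercased; ids must be unique and the alphabet is
    restricted to ACGTN.
    """
    records: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in records:
            raise ExpressionError(f"duplicate FASTA id {record.id!r} in {path}")
        seq = str(record.seq).upper()
        bad = set(seq) - _NUCLEOTIDES
        if bad:
            raise ExpressionError(
                f"record {record.id!r} contains non-nucleotide characters {sorted(bad)}"
            )
        if not seq:
            raise ExpressionError(f"record {record.id!r} has an empty sequence")
        records[record.id] = seq
    if not records:
        raise ExpressionError(f"no FASTA records found in {path}")
    return UtrSet(label=label, records=records)


def annotate_retained(matrix: ExpressionMatrix, retained: pd.DataFrame) -> ExpressionMatrix:
    return replace(matrix, retained=retained)
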