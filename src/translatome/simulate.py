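"""Synthetic data with planted ground truth for every pipeline input.

Generates expression matrices with genes planted in each regulation class,
UTR FASTA sets with controlled GC shifts over a shared length distribution,
and long-format Ct tables with planted fold changes.  Everything is
reproducible bit-for-bit from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, SampleDesign, UtrSet
from .translatability import RegulationClass

# (poly fold, tot fold) planted on the knockdown condition for each class,
# expressed in units of the configured up/down effects
_CLASS_FOLDS = {
    RegulationClass.POLY_ONLY_UP: ("up", "none"),
    RegulationClass.POLY_ONLY_DOWN: ("down", "none"),
    RegulationClass.BUFFERED_UP: ("none", "down"),
    RegulationClass.BUFFERED_DOWN: ("none", "up"),
    RegulationClass.OPPOSITE: ("up", "down"),
    RegulationClass.CONCOMITANT_UNMODIFIED: ("up", "up"),
    RegulationClass.OTHER_MODIFIED: ("up_squared", "up"),
    RegulationClass.UNCHANGED: ("none", "none"),
}


@dataclass(frozen=True)
class SimulationConfig:
    n_genes: int = 2000
    replicates: int = 2
    class_sizes: dict = field(default_factory=dict)  # RegulationClass -> count
    effect_up: float = 2.0
    effect_down: float = 0.5
    noise_sd_log2: float = 0.1
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 2.0
    detection_dropout_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.replicates < 1:
            raise ValueError("replicates must be positive")
        if not (self.effect_up > 1 and 0 < self.effect_down < 1):
            raise ValueError("need effect_up > 1 and 0 < effect_down < 1")
        if self.noise_sd_log2 < 0:
            raise ValueError("noise_sd_log2 must be >= 0")
        if not 0 <= self.detection_dropout_rate <= 1:
            raise ValueError("detection_dropout_rate must be in [0, 1]")
        total = sum(self.class_sizes.values())
        if total > self.n_genes:
            raise ValueError(
                f"class sizes sum to {total} but only {self.n_genes} genes requested"
            )


def _fold(config: SimulationConfig, kind: str) -> float:
    if kind == "none":
        return 1.0
    if kind == "up":
        return config.effect_up
    if kind == "down":
        return config.effect_down
    if kind == "up_squared":
        return config.effect_up**2
    raise AssertionError(kind)


def simulate_polysome_dataset(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, SampleDesign, pd.DataFrame]:
    """Simulate a paired two-fraction knockdown/control expression dataset.

    Control intensities are log-normal around per-gene baselines; knockdown
    intensities multiply in the planted per-class fold change; every sample
    gets independent log2-normal noise.  Returns (matrix, design, truth)
    where truth has one row per gene with its planted class and folds.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    gene_ids = [f"gene{i + 1:05d}" for i in range(n)]

    classes: list[RegulationClass] = []
    for cls, size in config.class_sizes.items():
        cls = RegulationClass(cls)
        classes.extend([cls] * int(size))
    classes.extend([RegulationClass.UNCHANGED] * (n - len(classes)))

    poly_folds = np.array([_fold(config, _CLASS_FOLDS[c][0]) for c in classes])
    tot_folds = np.array([_fold(config, _CLASS_FOLDS[c][1]) for c in classes])
    fold_by_fraction = {"polysomal": poly_folds, "total": tot_folds}

    baselines = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, size=n)

    columns: dict[str, np.ndarray] = {}
    design_rows = []
    for fraction in ("polysomal", "total"):
        for rep in range(1, config.replicates + 1):
            for condition in ("knockdown", "control"):
                short = {"polysomal": "poly", "total": "tot"}[fraction]
                cond = {"knockdown": "kd", "control": "ctrl"}[condition]
                sample_id = f"{short}_{cond}_r{rep}"
                noise = rng.normal(0.0, config.noise_sd_log2, size=n)
                log2_fold = (
                    np.log2(fold_by_fraction[fraction]) if condition == "knockdown" else 0.0
                )
                columns[sample_id] = 2.0 ** (baselines + log2_fold + noise)
                design_rows.append(
                    {
                        "sample_id": sample_id,
                        "condition": condition,
                        "fraction": fraction,
                        "replicate": rep,
                    }
                )

    values = pd.DataFrame(columns, index=pd.Index(gene_ids, name="gene_id"))
    detected = pd.DataFrame(True, index=values.index, columns=values.columns)
    if config.detection_dropout_rate > 0:
        low = baselines <= np.quantile(baselines, 0.25)
        drop = rng.random(size=values.shape) < config.detection_dropout_rate
        drop[~low, :] = False
        detected = detected & ~drop

    design = SampleDesign(
        pd.DataFrame(design_rows).set_index("sample_id")
    )
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "planted_class": [c.value for c in classes],
            "poly_fold": poly_folds,
            "tot_fold": tot_folds,
        }
    ).set_index("gene_id")
    return ExpressionMatrix(values=values, detected=detected), design, truth


def simulate_utr_sets(
    n_per_set: int,
    gc_shift_positive: float = 15.0,
    gc_shift_negative: float = -15.0,
    length_median: float = 150.0,
    length_sd_log: float = 0.5,
    baseline_gc: float = 0.5,
    seed: int = 0,
) -> tuple[UtrSet, UtrSet, UtrSet]:
    """Three UTR sets sharing a length distribution but with shifted GC.

    Shifts are in GC percentage points applied to the per-base GC
    probability and clamped to (0.05, 0.95); lengths are log-normal with
    the given median for all three sets.
    """
    if not 0 < baseline_gc < 1:
        raise ValueError(f"baseline GC probability must be in (0, 1), got {baseline_gc}")
    if n_per_set < 1:
        raise ValueError("n_per_set must be positive")
    rng = np.random.default_rng(seed)
    shifts = {"positive": gc_shift_positive, "negative": gc_shift_negative, "neutral": 0.0}
    sets = []
    for label, shift in shifts.items():
        p_gc = float(np.clip(baseline_gc + shift / 100.0, 0.05, 0.95))
        records = {}
        lengths = np.maximum(
            1, np.round(rng.lognormal(np.log(length_median), length_sd_log, n_per_set))
        ).astype(int)
        for i, length in enumerate(lengths):
            is_gc = rng.random(length) < p_gc
            strong = rng.integers(0, 2, size=length)  # picks within {G,C} / {A,T}
            bases = np.where(is_gc, np.where(strong == 1, "G", "C"), np.where(strong == 1, "A", "T"))
            records[f"{label}_utr{i + 1:04d}"] = "".join(bases)
        sets.append(UtrSet(label=label, records=records))
    return tuple(sets)


def simulate_qpcr(
    genes: dict,
    n_experiments: int = 4,
    ct_noise_sd: float = 0.1,
    seed: int = 0,
    reference_gene: str = "HPRT1",
    fractions: tuple[str, ...] = ("polysomal", "total"),
    n_technical: int = 3,
    reference_ct: float = 20.0,
    target_ct: float = 25.0,
) -> pd.DataFrame:
    """Long-format Ct table with planted knockdown/control fold changes.

    ``genes`` maps target gene id -> planted ratio (> 0), applied in every
    fraction.  The reference gene sits at a constant Ct in both conditions;
    the knockdown target Ct is lowered by log2(ratio) relative to control.
    Independent N(0, ct_noise_sd) noise is added per technical replicate.
    """
    for gene, ratio in genes.items():
        if ratio <= 0:
            raise ValueError(f"planted ratio for {gene!r} must be > 0, got {ratio}")
    if n_experiments < 1:
        raise ValueError("need at least one experiment")
    rng = np.random.default_rng(seed)
    rows = []
    all_genes = {reference_gene: 1.0, **genes}
    for fraction in fractions:
        for exp in range(1, n_experiments + 1):
            for gene, ratio in all_genes.items():
                base = reference_ct if gene == reference_gene else target_ct
                for condition in ("control", "knockdown"):
                    ct_center = base
                    if condition == "knockdown" and gene != reference_gene:
                        ct_center = base - np.log2(ratio)
                    for tech in range(1, n_technical + 1):
                        rows.append(
                            {
                                "gene": gene,
                                "condition": condition,
                                "fraction": fraction,
                                "experiment": exp,
                                "tech_rep": tech,
                                "ct": ct_center + rng.normal(0.0, ct_noise_sd),
                            }
                        )
    return pd.DataFrame(rows)
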