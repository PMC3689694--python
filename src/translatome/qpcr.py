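"""ddCt relative quantification with reference-gene normalization.

Ratios are knockdown/control per experiment, normalized to a reference
(housekeeping) gene:

    dCt_kd   = Ct(target, kd)   - Ct(ref, kd)
    dCt_ctrl = Ct(target, ctrl) - Ct(ref, ctrl)
    ratio    = E ** -(dCt_kd - dCt_ctrl)

with amplification efficiency E (default 2).  Ratios across independent
experiments are tested with a two-tailed one-sample t test of log(ratio)
against 0, which is the paired knockdown-vs-control test on the log scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

CT_COLUMNS = ["gene", "condition", "fraction", "experiment", "tech_rep", "ct"]

#: a technical replicate deviating from the triplicate median by more than
#: this many cycles is flagged (never dropped)
DEFAULT_OUTLIER_CYCLES = 0.5


@dataclass(frozen=True)
class MeanCt:
    value: float
    outlier_flags: tuple[bool, ...]

    @property
    def has_outlier(self) -> bool:
        return any(self.outlier_flags)


@dataclass(frozen=True)
class RatioTestResult:
    mean_ratio: float  # geometric mean across experiments
    sem: float  # arithmetic SEM of the ratios (error-bar convention)
    t: float
    p: float
    n: int
    degenerate_variance: bool = False


def read_ct_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = set(CT_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    ct = table["ct"].astype(float)
    if not np.isfinite(ct).all():
        raise ValueError("Ct values must be finite")
    return table


def mean_ct(
    technical_cts, outlier_cycles: float = DEFAULT_OUTLIER_CYCLES
) -> MeanCt:
    """Arithmetic mean of technical-replicate Cts with outlier flagging.

    Replicates deviating more than ``outlier_cycles`` from the median are
    flagged but kept in the mean.
    """
    cts = np.asarray(list(technical_cts), dtype=float)
    if cts.size == 0:
        raise ValueError("no technical replicates supplied")
    if not np.isfinite(cts).all():
        raise ValueError("Ct values must be finite")
    median = float(np.median(cts))
    flags = tuple(bool(abs(c - median) > outlier_cycles) for c in cts)
    return MeanCt(value=float(cts.mean()), outlier_flags=flags)


def ddct_ratio(
    target_kd: float,
    ref_kd: float,
    target_ctrl: float,
    ref_ctrl: float,
    efficiency: float = 2.0,
) -> float:
    """Relative knockdown/control expression from four mean Cts."""
    if efficiency <= 1:
        raise ValueError(f"amplification efficiency must exceed 1, got {efficiency}")
    for v in (target_kd, ref_kd, target_ctrl, ref_ctrl):
        if not math.isfinite(v):
            raise ValueError("Ct values must be finite")
    ddct = (target_kd - ref_kd) - (target_ctrl - ref_ctrl)
    return efficiency ** (-ddct)


def ratio_test(ratios) -> RatioTestResult:
    """Two-tailed test of H0: ratio == 1 across >=2 independent experiments.

    Implemented as a one-sample t test of log(ratio) against 0.  If the
    log-ratios have exactly zero variance the result is degenerate: p = 1
    when they all equal 0, otherwise p = 0 with a flag.
    """
    arr = np.asarray(list(ratios), dtype=float)
    if arr.size < 2:
        raise ValueError("need >=2 experiments for the ratio test")
    if (arr <= 0).any() or not np.isfinite(arr).all():
        raise ValueError("ratios must be finite and > 0")
    logs = np.log(arr)
    n = arr.size
    mean_ratio = float(np.exp(logs.mean()))
    sem = float(arr.std(ddof=1) / math.sqrt(n))
    sd_log = logs.std(ddof=1)
    if sd_log == 0.0:
        if logs.mean() == 0.0:
            return RatioTestResult(mean_ratio, sem, t=0.0, p=1.0, n=n)
        return RatioTestResult(
            mean_ratio, sem, t=math.inf if logs.mean() > 0 else -math.inf,
            p=0.0, n=n, degenerate_variance=True,
        )
    t = float(logs.mean() / (sd_log / math.sqrt(n)))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 1))
    return RatioTestResult(mean_ratio, sem, t=t, p=p, n=n)


def analyze_ct_table(
    ct_table: pd.DataFrame,
    reference_gene: str,
    efficiency: float = 2.0,
    outlier_cycles: float = DEFAULT_OUTLIER_CYCLES,
) -> pd.DataFrame:
    """Full ddCt analysis of a long-format Ct table.

    Returns one row per (gene, fraction): per-experiment ratios are computed
    against the reference gene, then aggregated with :func:`ratio_test`.
    """
    table = ct_table.copy()
    missing = set(CT_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    if reference_gene not in set(table["gene"]):
        raise ValueError(f"reference gene {reference_gene!r} absent from Ct table")

    means: dict[tuple, MeanCt] = {}
    for key, grp in table.groupby(["gene", "condition", "fraction", "experiment"]):
        means[key] = mean_ct(grp["ct"], outlier_cycles)

    rows = []
    targets = sorted(set(table["gene"]) - {reference_gene})
    fractions = sorted(set(table["fraction"]))
    for gene in targets:
        for fraction in fractions:
            experiments = sorted(
                {
                    k[3]
                    for k in means
                    if k[0] == gene and k[2] == fraction
                }
            )
            ratios = []
            flagged = False
            for exp in experiments:
                try:
                    tk = means[(gene, "knockdown", fraction, exp)]
                    tc = means[(gene, "control", fraction, exp)]
                    rk = means[(reference_gene, "knockdown", fraction, exp)]
                    rc = means[(reference_gene, "control", fraction, exp)]
                except KeyError as err:
                    raise ValueError(
                        f"incomplete Ct data for {gene}/{fraction} experiment {exp}: {err}"
                    ) from None
                flagged |= any(m.has_outlier for m in (tk, tc, rk, rc))
                ratios.append(
                    ddct_ratio(tk.value, rk.value, tc.value, rc.value, efficiency)
                )
            result = ratio_test(ratios)
            rows.append(
                {
                    "gene": gene,
                    "fraction": fraction,
                    "n_experiments": result.n,
                    "mean_ratio": result.mean_ratio,
                    "sem": result.sem,
                    "t": result.t,
                    "p": result.p,
                    "degenerate_variance": result.degenerate_variance,
                    "ct_outlier_flag": flagged,
                }
            )
    return pd.DataFrame(rows)
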