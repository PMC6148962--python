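"""Expression quantification and differential-expression filtering.

The label-free workflow modelled here: keep features quantified in every
sample (complete cases), log2-transform, centre each sample on its median,
then per-feature two-sample tests with Benjamini-Hochberg adjustment and a
fold-change gate.  A feature is called differential only when all three
gates agree: |log2 fold change| >= log2(fc_cutoff), raw p < p_cutoff and
BH q <= fdr_cutoff; each threshold is independently configurable because
published pipelines vary in which gates they apply.

RPKM (reads per kilobase of exon per million mapped reads) is provided for
RNA-seq inputs:  rpkm = reads / ((mapped/1e6) * (length/1e3)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import QuantMatrix
from .errors import ValidationError


def rpkm(exon_reads, mapped_reads, exon_length):
    """Reads per kilobase of exon per million mapped reads.

    ``exon_reads`` may be a scalar or array; ``mapped_reads`` is the
    library's total mapped read count and ``exon_length`` the summed exon
    length in bases.  Both must be positive.
    """
    mapped_reads = np.asarray(mapped_reads, dtype=float)
    exon_length = np.asarray(exon_length, dtype=float)
    if np.any(mapped_reads <= 0):
        raise ValidationError("mapped_reads must be positive")
    if np.any(exon_length <= 0):
        raise ValidationError("exon_length must be positive")
    value = np.asarray(exon_reads, dtype=float) / (
        (mapped_reads / 1e6) * (exon_length / 1e3))
    return float(value) if value.ndim == 0 else value


def log2_median_normalize(qm: QuantMatrix,
                          zeros_as_missing: bool = True) -> QuantMatrix:
    """log2-transform and centre every sample (column) on its median.

    Zeros become missing before the log by default (log2(0) undefined).
    After normalization every column's median over observed entries is 0,
    which makes the operation idempotent up to the scale tag.
    """
    if qm.scale == "log2":
        raise ValidationError("matrix already on log2 scale")
    values = qm.data.astype(float).copy()
    if zeros_as_missing:
        values = values.mask(values == 0)
    elif (values == 0).any().any():
        raise ValidationError("zero intensity with zeros_as_missing=False")
    empty = values.columns[values.isna().all(axis=0)]
    if len(empty):
        raise ValidationError(f"column(s) fully missing: {list(empty)}")
    logged = np.log2(values)
    centred = logged - logged.median(axis=0, skipna=True)
    return QuantMatrix(centred, scale="log2")


def complete_case_filter(qm: QuantMatrix) -> QuantMatrix:
    """Keep features quantified in every sample (no missing value)."""
    keep = ~qm.data.isna().any(axis=1)
    return QuantMatrix(qm.data.loc[keep].copy(), qm.scale)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def percent(count: int, total: int, decimals: int = 2) -> float:
    """Percentage rounded half-away-from-zero at ``decimals`` places."""
    if total <= 0:
        raise ValidationError("total must be positive")
    exact = Decimal(count) / Decimal(total) * 100
    quantum = Decimal(1).scaleb(-decimals)
    return float(exact.quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass
class DESummary:
    """Counts and printed-precision percentages of a DE run."""

    n_features: int
    n_significant: int
    n_up: int
    n_down: int
    pct_up: float
    pct_down: float


def two_sample_de(qm: QuantMatrix, groups: dict, group_a: str, group_b: str,
                  fc_cutoff: float = 2.0, p_cutoff: float = 0.05,
                  fdr_cutoff: float = 0.05,
                  equal_var: bool = False):
    """Per-feature two-sample t-test on a log2 matrix.

    ``groups`` maps sample id to group label.  Welch's unequal-variance
    test is the default (``equal_var=True`` switches to Student's).
    log2 fold change is mean(group_b) - mean(group_a); ``direction`` is
    up/down/ns with significance requiring the fold-change, raw-p and BH-q
    gates simultaneously.  Zero-variance features with equal means are
    reported with p = 1 under a warning rather than NaN.

    Returns ``(results, summary)`` where ``results`` is a DataFrame with
    columns feature, log2_fc, p_value, q_value, direction.
    """
    if qm.scale != "log2":
        raise ValidationError("two_sample_de expects a log2-scale matrix")
    cols_a = [s for s in qm.samples if groups.get(s) == group_a]
    cols_b = [s for s in qm.samples if groups.get(s) == group_b]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValidationError(
            f"need >= 2 samples per group, got {len(cols_a)} {group_a!r} "
            f"and {len(cols_b)} {group_b!r}")
    a = qm.data[cols_a].to_numpy(dtype=float)
    b = qm.data[cols_b].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        t_res = stats.ttest_ind(b, a, axis=1, equal_var=equal_var)
    p = np.asarray(t_res.pvalue, dtype=float)
    log2_fc = np.nanmean(b, axis=1) - np.nanmean(a, axis=1)
    degenerate = np.isnan(p)
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} feature(s) with zero "
                      "variance in both groups; p set to 1", UserWarning,
                      stacklevel=2)
        p = np.where(degenerate, 1.0, p)
    q = bh_adjust(p)
    lfc_gate = np.abs(log2_fc) >= np.log2(fc_cutoff)
    significant = lfc_gate & (p < p_cutoff) & (q <= fdr_cutoff)
    direction = np.where(~significant, "ns",
                         np.where(log2_fc > 0, "up", "down"))
    results = pd.DataFrame({
        "feature": qm.features, "log2_fc": log2_fc, "p_value": p,
        "q_value": q, "direction": direction})
    n_up = int((direction == "up").sum())
    n_down = int((direction == "down").sum())
    n_sig = n_up + n_down
    summary = DESummary(
        n_features=len(results), n_significant=n_sig, n_up=n_up,
        n_down=n_down,
        pct_up=percent(n_up, n_sig) if n_sig else 0.0,
        pct_down=percent(n_down, n_sig) if n_sig else 0.0)
    return results, summary
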