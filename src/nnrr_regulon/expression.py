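"""Detection-filtered differential expression.

A gene counts as differentially expressed between two groups when all
three of the following hold, mirroring standard microarray practice for
present/marginal/absent (P/M/A) call data:

* detection — called present or marginal in at least ``min_called`` of the
  replicates of at least one group (default 2 of 3);
* significance — two-sided pooled-variance Student t-test on log2
  intensities with p below ``p_threshold`` (default 0.01);
* effect size — signed fold change of the linear-scale group means at or
  beyond ``fc_threshold`` (default 2).

Signed fold change is the ratio of group means reported as -(1/ratio)
when the ratio is below 1, so its magnitude is always >= 1 and its sign
gives the direction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

PRESENT_CALLS = frozenset({"P", "M"})


@dataclass(frozen=True)
class Contrast:
    """A named numerator-vs-denominator sample comparison."""

    name: str
    numerator_samples: tuple[str, ...]
    denominator_samples: tuple[str, ...]

    def __post_init__(self) -> None:
        num, den = set(self.numerator_samples), set(self.denominator_samples)
        if num & den:
            raise ValueError(f"contrast {self.name}: groups overlap: "
                             f"{sorted(num & den)}")
        if len(num) < 2 or len(den) < 2:
            raise ValueError(f"contrast {self.name}: each group needs >= 2 "
                             "samples")


@dataclass(frozen=True)
class ContrastResult:
    gene_id: str
    mean_num: float
    mean_den: float
    fc: float
    p: float
    detected: bool
    significant: bool


def validate_matrix(matrix: pd.DataFrame) -> None:
    if matrix.isna().any().any():
        raise ValueError("expression matrix contains missing values")
    if (matrix.values < 0).any():
        raise ValueError("expression matrix contains negative intensities")


def filter_detected(calls: pd.DataFrame, samples: Sequence[str],
                    min_called: int = 2) -> set[str]:
    """Genes called P or M in at least *min_called* of *samples*."""
    missing = [s for s in samples if s not in calls.columns]
    if missing:
        raise KeyError(f"unknown sample ids: {missing}")
    sub = calls[list(samples)]
    n_called = sub.isin(PRESENT_CALLS).sum(axis=1)
    return set(sub.index[n_called >= min_called])


def signed_fold_change(mean_num: float, mean_den: float) -> float:
    """Signed ratio of two positive means; |result| >= 1 always."""
    if mean_num <= 0 or mean_den <= 0:
        raise ValueError("group means must be positive for a fold change")
    if mean_num >= mean_den:
        return mean_num / mean_den
    return -(mean_den / mean_num)


def gene_t_test(values_num: Sequence[float], values_den: Sequence[float],
                log_transform: bool = True) -> float:
    """Two-sided pooled-variance Student t-test p-value.

    Intensities are log2-transformed by default (variance stabilization);
    a t statistic undefined through zero variance in both groups is
    resolved conservatively: p = 1 when the means agree, p = 0 otherwise
    (infinite evidence of a difference is impossible with real noise, so
    the latter only occurs on degenerate synthetic input).
    """
    a = np.asarray(values_num, dtype=float)
    b = np.asarray(values_den, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 values per group")
    if log_transform:
        if (a <= 0).any() or (b <= 0).any():
            raise ValueError("log transform requires positive intensities")
        a, b = np.log2(a), np.log2(b)
    if np.var(a) == 0 and np.var(b) == 0:
        logger.warning("zero variance in both groups; degenerate input")
        return 1.0 if np.mean(a) == np.mean(b) else 0.0
    res = stats.ttest_ind(a, b, equal_var=True)
    return float(res.pvalue)


def differential_genes(matrix: pd.DataFrame, calls: pd.DataFrame,
                       contrast: Contrast, p_threshold: float = 0.01,
                       fc_threshold: float = 2.0, min_called: int = 2,
                       detection_rule: str = "either",
                       log_transform: bool = True,
                       p_adjust: str = "none") -> list[ContrastResult]:
    """Per-gene fold change, p-value, and detection/significance flags.

    ``detection_rule`` decides how P/M/A calls gate testing: ``"either"``
    (default) keeps a gene detected in at least one of the two groups — a
    gene absent under one condition but induced under the other stays
    testable; ``"both"`` requires detection in both groups.

    ``p_adjust="bh"`` thresholds Benjamini-Hochberg-adjusted p-values
    instead of raw ones; the default ``"none"`` keeps the raw-threshold
    convention (reported p-values are always raw).
    """
    if detection_rule not in ("either", "both"):
        raise ValueError(f"unknown detection_rule {detection_rule!r}")
    if p_adjust not in ("none", "bh"):
        raise ValueError(f"unknown p_adjust {p_adjust!r}")
    validate_matrix(matrix)
    if matrix.empty:
        warnings.warn("empty expression matrix; no genes to test")
        return []
    num, den = list(contrast.numerator_samples), list(contrast.denominator_samples)
    for s in num + den:
        if s not in matrix.columns:
            raise KeyError(f"sample {s!r} not in expression matrix")

    det_num = filter_detected(calls, num, min_called)
    det_den = filter_detected(calls, den, min_called)
    detected = (det_num | det_den) if detection_rule == "either" \
        else (det_num & det_den)

    # vectorized pooled-variance t-test on log2 values
    a = matrix[num].to_numpy(dtype=float)
    b = matrix[den].to_numpy(dtype=float)
    if log_transform:
        if (a <= 0).any() or (b <= 0).any():
            raise ValueError("log transform requires positive intensities")
        la, lb = np.log2(a), np.log2(b)
    else:
        la, lb = a, b
    n1, n2 = la.shape[1], lb.shape[1]
    m1, m2 = la.mean(axis=1), lb.mean(axis=1)
    v1 = la.var(axis=1, ddof=1)
    v2 = lb.var(axis=1, ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    df = n1 + n2 - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        p = 2 * stats.t.sf(np.abs(t), df)
    degenerate = sp2 == 0
    p = np.where(degenerate & (m1 == m2), 1.0, p)
    p = np.where(degenerate & (m1 != m2), 0.0, p)
    p_for_threshold = stats.false_discovery_control(p) \
        if (p_adjust == "bh" and len(p)) else p

    results: list[ContrastResult] = []
    mean_num_arr = a.mean(axis=1)
    mean_den_arr = b.mean(axis=1)
    for i, gene in enumerate(matrix.index):
        fc = signed_fold_change(float(mean_num_arr[i]), float(mean_den_arr[i]))
        det = gene in detected
        sig = (det and p_for_threshold[i] < p_threshold
               and abs(fc) >= fc_threshold)
        results.append(ContrastResult(
            gene_id=str(gene),
            mean_num=float(mean_num_arr[i]),
            mean_den=float(mean_den_arr[i]),
            fc=fc,
            p=float(p[i]),
            detected=det,
            significant=bool(sig),
        ))
    return results


def results_frame(results: Iterable[ContrastResult]) -> pd.DataFrame:
    df = pd.DataFrame([r.__dict__ for r in results])
    return df.set_index("gene_id") if not df.empty else df


def write_results(results: Iterable[ContrastResult], path: str | Path) -> None:
    results_frame(results).to_csv(path, sep="\t")


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    """Expression or calls TSV: first column gene id, one column per sample."""
    return pd.read_csv(path, sep="\t", index_col=0)
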