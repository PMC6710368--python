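"""Efficiency-corrected relative quantification of qRT-PCR data.

The Pfaffl method expresses the relative transcription of a target gene in
a sample group versus a control group, normalized to a reference gene
(here the sigma-factor gene sigA by default):

    ratio = E_target ** dCq_target / E_ref ** dCq_ref

where E is the per-assay amplification efficiency in fold per cycle
(2 = perfect doubling) and dCq = mean Cq(control) - mean Cq(sample) for
that gene. Replicate Cq values are averaged arithmetically before the
difference — Cq is already a log-scale quantity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

REQUIRED_COLUMNS = ("sample_id", "gene", "Cq")
DEFAULT_EFFICIENCY = 2.0


@dataclass(frozen=True)
class PfafflResult:
    gene: str
    comparison: str
    ratio: float
    fc: float  # signed fold-change equivalent: ratio if >=1 else -1/ratio


def _check_efficiency(e: float, label: str) -> None:
    if not (1.0 < e <= 2.0):
        raise ValueError(
            f"{label} efficiency must be in (1, 2] fold/cycle, got {e}")


def pfaffl_ratio(e_target: float, dcq_target: float,
                 e_ref: float, dcq_ref: float) -> float:
    """ratio = E_t**dCq_t / E_r**dCq_r with dCq = Cq(control) - Cq(sample)."""
    _check_efficiency(e_target, "target")
    _check_efficiency(e_ref, "reference")
    return e_target ** dcq_target / e_ref ** dcq_ref


def signed_fc(ratio: float) -> float:
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    return ratio if ratio >= 1 else -1.0 / ratio


def read_cq_csv(path: str | Path) -> pd.DataFrame:
    cq = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in cq.columns]
    if missing:
        raise ValueError(f"Cq table {path} lacks columns {missing}")
    if (cq["Cq"] <= 0).any():
        raise ValueError("Cq values must be positive")
    return cq


def _group_mean_cq(cq: pd.DataFrame, gene: str, group: str) -> float:
    sub = cq[(cq["gene"] == gene) & (cq["group"] == group)]
    if sub.empty:
        raise ValueError(f"no Cq rows for gene {gene!r} in group {group!r}")
    return float(sub["Cq"].mean())


def _efficiency_of(cq: pd.DataFrame, gene: str) -> float:
    if "efficiency" not in cq.columns:
        return DEFAULT_EFFICIENCY
    vals = cq.loc[cq["gene"] == gene, "efficiency"].dropna().unique()
    if len(vals) == 0:
        return DEFAULT_EFFICIENCY
    if len(vals) > 1:
        raise ValueError(f"conflicting efficiencies for assay {gene!r}: "
                         f"{sorted(vals)}")
    return float(vals[0])


def relative_expression(cq: pd.DataFrame, target_gene: str,
                        ref_gene: str = "sigA", *,
                        control_group: str, sample_group: str,
                        group_column: str = "group") -> PfafflResult:
    """Pfaffl ratio of *target_gene* in sample vs control, normalized.

    The table needs columns sample_id, gene, Cq, a group column, and
    optionally a per-assay ``efficiency`` column (default 2.0 when absent).
    Replicate Cq rows are averaged per (group, gene) before the deltas.
    """
    cq = cq.rename(columns={group_column: "group"})
    for gene in (target_gene, ref_gene):
        for grp in (control_group, sample_group):
            if cq[(cq["gene"] == gene) & (cq["group"] == grp)].empty:
                raise ValueError(
                    f"missing Cq data: gene {gene!r}, group {grp!r}")
    dcq_t = (_group_mean_cq(cq, target_gene, control_group)
             - _group_mean_cq(cq, target_gene, sample_group))
    dcq_r = (_group_mean_cq(cq, ref_gene, control_group)
             - _group_mean_cq(cq, ref_gene, sample_group))
    ratio = pfaffl_ratio(_efficiency_of(cq, target_gene), dcq_t,
                         _efficiency_of(cq, ref_gene), dcq_r)
    return PfafflResult(
        gene=target_gene,
        comparison=f"{sample_group} vs {control_group}",
        ratio=ratio,
        fc=signed_fc(ratio),
    )


def write_results(results: list[PfafflResult], path: str | Path) -> None:
    pd.DataFrame([r.__dict__ for r in results]).to_csv(
        path, sep="\t", index=False)
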