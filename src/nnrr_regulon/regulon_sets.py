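"""Directional set intersection of the two regulon contrasts.

The mapped regulon is the overlap of two differential-expression sets —
mutant-vs-wild-type under anoxic denitrifying growth, and wild-type
anoxic-vs-oxic — narrowed to genes induced by anoxia in the wild type and
simultaneously downregulated in the regulator mutant (the signature of a
positively controlled target).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .expression import ContrastResult

logger = logging.getLogger(__name__)


@dataclass
class RegulonSets:
    set_mutant_diff: set[str]
    set_wt_anoxia_diff: set[str]
    overlap: set[str]
    nnrr_activated: set[str] = field(default_factory=set)

    @property
    def counts(self) -> dict[str, int]:
        return {
            "mutant_diff": len(self.set_mutant_diff),
            "wt_anoxia_diff": len(self.set_wt_anoxia_diff),
            "overlap": len(self.overlap),
            "nnrr_activated": len(self.nnrr_activated),
        }

    def validate(self) -> None:
        assert self.overlap <= self.set_mutant_diff
        assert self.overlap <= self.set_wt_anoxia_diff
        assert self.nnrr_activated <= self.overlap


def intersect_contrasts(result_mutant: Sequence[ContrastResult],
                        result_wt: Sequence[ContrastResult],
                        strict_universe: bool = False) -> RegulonSets:
    """Overlap of the significant gene sets of the two contrasts.

    Genes present in one result but absent from the other are treated as
    non-significant where missing and logged; with ``strict_universe`` a
    mismatch raises instead, listing the orphans.
    """
    genes_a = {r.gene_id for r in result_mutant}
    genes_b = {r.gene_id for r in result_wt}
    orphans = genes_a ^ genes_b
    if orphans:
        msg = (f"{len(orphans)} genes present in only one contrast "
               f"(e.g. {sorted(orphans)[:5]})")
        if strict_universe:
            raise ValueError("gene universes differ: " + msg)
        logger.warning(msg)
    sig_a = {r.gene_id for r in result_mutant if r.significant}
    sig_b = {r.gene_id for r in result_wt if r.significant}
    sets = RegulonSets(
        set_mutant_diff=sig_a,
        set_wt_anoxia_diff=sig_b,
        overlap=sig_a & sig_b,
    )
    return sets


def nnrr_activated(sets: RegulonSets,
                   result_mutant: Sequence[ContrastResult],
                   result_wt: Sequence[ContrastResult],
                   fc_threshold: float = 2.0) -> set[str]:
    """Overlap genes induced in the WT contrast and down in the mutant.

    "Induced" means fc >= +fc_threshold in WT-anoxia-vs-oxia; "down"
    means fc <= -fc_threshold in mutant-vs-WT. The result is stored on
    *sets* and returned.
    """
    fc_mut = {r.gene_id: r.fc for r in result_mutant}
    fc_wt = {r.gene_id: r.fc for r in result_wt}
    activated = {
        g for g in sets.overlap
        if fc_wt.get(g, 0.0) >= fc_threshold
        and fc_mut.get(g, 0.0) <= -fc_threshold
    }
    sets.nnrr_activated = activated
    sets.validate()
    return activated


def cross_reference(geneset: Iterable[str],
                    external_list: Iterable[str]) -> tuple[set[str], int]:
    """Intersection with an externally defined gene list, plus its size."""
    inter = set(geneset) & set(external_list)
    return inter, len(inter)


def write_venn_json(sets: RegulonSets, path: str | Path) -> None:
    """Six counts mirroring the two-circle overlap diagram."""
    c = sets.counts
    payload = {
        "mutant_diff_total": c["mutant_diff"],
        "wt_anoxia_diff_total": c["wt_anoxia_diff"],
        "overlap": c["overlap"],
        "nnrr_activated": c["nnrr_activated"],
        "mutant_diff_only": c["mutant_diff"] - c["overlap"],
        "wt_anoxia_diff_only": c["wt_anoxia_diff"] - c["overlap"],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def plot_venn(sets: RegulonSets, path: str | Path) -> None:
    """Two-circle overlap figure drawn with plain matplotlib patches."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Circle

    c = sets.counts
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.add_patch(Circle((0.38, 0.5), 0.32, alpha=0.4, color="lightgray"))
    ax.add_patch(Circle((0.62, 0.5), 0.32, alpha=0.4, color="dimgray"))
    ax.text(0.25, 0.5, str(c["mutant_diff"] - c["overlap"]), ha="center")
    ax.text(0.50, 0.5, str(c["overlap"]), ha="center")
    ax.text(0.75, 0.5, str(c["wt_anoxia_diff"] - c["overlap"]), ha="center")
    ax.text(0.25, 0.88, f"mutant vs WT ({c['mutant_diff']})", ha="center")
    ax.text(0.75, 0.12, f"WT anoxia vs oxia ({c['wt_anoxia_diff']})",
            ha="center")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.axis("off")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
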