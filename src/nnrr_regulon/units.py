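"""Transcriptional-unit (operon) grouping and promoter-window extraction.

Operon membership is predicted with a distance rule: consecutive genes on
the same strand whose intergenic gap does not exceed ``max_gap`` are chained
into one transcriptional unit. The motif search then targets the promoter
of each unit's lead gene — the transcription-direction-first member.

Promoter positions are reported relative to the translation start: offset
-1 is the base immediately 5' of the first base of the start codon, in the
unit's transcription orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

from .genome import Gene, GenomeAnnotation, reverse_complement


@dataclass(frozen=True)
class TranscriptionalUnit:
    """Ordered same-strand gene group, 5'→3' in transcription direction."""

    unit_id: str
    locus_tags: tuple[str, ...]
    strand: str

    @property
    def lead_gene(self) -> str:
        return self.locus_tags[0]

    @property
    def operon_string(self) -> str | None:
        if len(self.locus_tags) == 1:
            return None
        return "-".join(self.locus_tags)


def group_units(annotation: GenomeAnnotation, candidate_genes: Iterable[str],
                max_gap: int = 200) -> list[TranscriptionalUnit]:
    """Partition candidate genes into transcriptional units.

    Chains are built over the full annotation (consecutive genes, same
    strand, intergenic gap <= ``max_gap``); each unit is the candidate
    members of one chain, ordered in transcription direction. A candidate
    separated from the next chain member only by a non-candidate gene thus
    stays in the same unit. Each candidate lands in exactly one unit.
    """
    candidates = set(candidate_genes)
    missing = candidates - set(annotation.locus_tags)
    if missing:
        raise KeyError(f"candidate genes not in annotation: {sorted(missing)}")

    chains: list[list[Gene]] = []
    for gene in annotation:  # annotation is sorted by start
        if (chains
                and gene.strand == chains[-1][-1].strand
                and gene.start - chains[-1][-1].end - 1 <= max_gap):
            chains[-1].append(gene)
        else:
            chains.append([gene])

    units: list[TranscriptionalUnit] = []
    for chain in chains:
        members = [g for g in chain if g.locus_tag in candidates]
        if not members:
            continue
        if members[0].strand == "-":
            members = members[::-1]  # transcription runs right-to-left
        units.append(TranscriptionalUnit(
            unit_id=members[0].locus_tag,
            locus_tags=tuple(g.locus_tag for g in members),
            strand=members[0].strand,
        ))
    return units


Truncation = Literal["none", "upstream_gene", "replicon_edge"]


@dataclass(frozen=True)
class PromoterWindow:
    """Upstream search sequence of a unit's lead gene.

    ``sequence`` reads 5'→3' toward the gene (reverse-complemented for
    minus-strand units); the last base sits at offset -1 from the first
    base of the start codon. ``anchor`` is the forward-strand coordinate of
    the start codon's first base; together with the strand it maps offsets
    back to genome coordinates.
    """

    unit_id: str
    sequence: str
    strand: str
    anchor: int
    replicon_length: int
    circular: bool = False
    truncated_by: Truncation = "none"

    def __len__(self) -> int:
        return len(self.sequence)

    def offset_of_index(self, i: int) -> int:
        """Signed offset (upstream negative) of window index *i*."""
        if not 0 <= i < len(self.sequence):
            raise IndexError(i)
        return i - len(self.sequence)

    def genome_coord_of_offset(self, offset: int) -> int:
        """1-based forward-strand coordinate of a signed upstream offset."""
        if not -len(self.sequence) <= offset <= -1:
            raise ValueError(f"offset {offset} outside window")
        coord = self.anchor + offset if self.strand == "+" else self.anchor - offset
        if self.circular:
            coord = (coord - 1) % self.replicon_length + 1
        return coord


def _fetch(genome: str, start: int, end: int, circular: bool) -> str:
    """Forward-strand subsequence, 1-based inclusive, wrapping if circular."""
    n = len(genome)
    if 1 <= start and end <= n:
        return genome[start - 1:end]
    if not circular:
        raise ValueError(f"coordinates {start}..{end} outside linear replicon")
    return "".join(genome[(i - 1) % n] for i in range(start, end + 1))


def promoter_window(unit: TranscriptionalUnit, genome: str,
                    annotation: GenomeAnnotation, max_window: int = 600,
                    clip_at_upstream_gene: bool = False) -> PromoterWindow:
    """Up to ``max_window`` bases immediately 5' of the lead gene's start.

    On a linear replicon the window is truncated at the sequence edge; with
    ``clip_at_upstream_gene`` it is also truncated at the nearest upstream
    gene boundary (off by default: reported box positions may legitimately
    overlap upstream ORFs).
    """
    lead = annotation[unit.lead_gene]
    n = annotation.length
    truncated: Truncation = "none"
    want = max_window

    if unit.strand == "+":
        anchor = lead.start
        avail = anchor - 1 if not annotation.circular else n - lead.length
        if clip_at_upstream_gene:
            bounds = [g.end for g in annotation
                      if g.end < lead.start and g.locus_tag != lead.locus_tag]
            if bounds:
                gap = lead.start - 1 - max(bounds)
                if gap < want:
                    want, truncated = gap, "upstream_gene"
        if want > avail:
            want = avail
            truncated = truncated if truncated != "none" else "replicon_edge"
        seq = _fetch(genome, anchor - want, anchor - 1, annotation.circular) \
            if want > 0 else ""
    else:
        anchor = lead.end
        avail = n - anchor if not annotation.circular else n - lead.length
        if clip_at_upstream_gene:
            bounds = [g.start for g in annotation
                      if g.start > lead.end and g.locus_tag != lead.locus_tag]
            if bounds:
                gap = min(bounds) - 1 - lead.end
                if gap < want:
                    want, truncated = gap, "upstream_gene"
        if want > avail:
            want = avail
            truncated = truncated if truncated != "none" else "replicon_edge"
        seq = reverse_complement(
            _fetch(genome, anchor + 1, anchor + want, annotation.circular)) \
            if want > 0 else ""

    return PromoterWindow(
        unit_id=unit.unit_id,
        sequence=seq,
        strand=unit.strand,
        anchor=anchor,
        replicon_length=n,
        circular=annotation.circular,
        truncated_by=truncated,
    )
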