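"""FixK2-box consensus model and mismatch-tolerant promoter scanning.

The FixK2 binding site is a 14 bp palindromic consensus, TTGA/C-N6-T/GCAA
(IUPAC ``TTGMNNNNNNKCAA``). Scoring is a Hamming distance restricted to the
eight constrained positions (1-4 and 11-14 in 1-based motif coordinates);
the six central spacer positions never contribute. Because the model equals
its own reverse complement, a window and its reverse complement always score
identically, so every genomic position yields at most one reported hit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .genome import reverse_complement
from .units import PromoterWindow, TranscriptionalUnit

CONSENSUS_IUPAC = "TTGMNNNNNNKCAA"

_IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "M": "AC", "K": "GT", "R": "AG", "Y": "CT",
    "S": "CG", "W": "AT", "N": "ACGT",
}
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class MotifModel:
    """Degenerate consensus with per-position allowed base sets."""

    iupac: str = CONSENSUS_IUPAC
    ambiguous_is_mismatch: bool = True

    def __post_init__(self) -> None:
        for ch in self.iupac:
            if ch not in _IUPAC_SETS:
                raise ValueError(f"unsupported IUPAC code {ch!r}")

    @property
    def width(self) -> int:
        return len(self.iupac)

    @property
    def allowed(self) -> tuple[frozenset[str], ...]:
        return tuple(frozenset(_IUPAC_SETS[ch]) for ch in self.iupac)

    @property
    def constrained_positions(self) -> tuple[int, ...]:
        """1-based positions that can contribute mismatches (non-N)."""
        return tuple(i + 1 for i, ch in enumerate(self.iupac) if ch != "N")

    def is_palindromic(self) -> bool:
        rc = {"A": "T", "C": "G", "G": "C", "T": "A",
              "M": "K", "K": "M", "R": "Y", "Y": "R",
              "S": "S", "W": "W", "N": "N"}
        return self.iupac == "".join(rc[ch] for ch in reversed(self.iupac))

    def allowed_table(self) -> np.ndarray:
        """Boolean (width, 5) table over A,C,G,T,ambiguous codes."""
        table = np.zeros((self.width, 5), dtype=bool)
        for i, bases in enumerate(self.allowed):
            for b in bases:
                table[i, _BASE_INDEX[b]] = True
            table[i, 4] = (len(bases) == 4) or not self.ambiguous_is_mismatch
        return table


def mismatch_count(window14: str, model: MotifModel | None = None) -> int:
    """Mismatches of a 14-base window against the consensus.

    Counts the constrained positions whose base falls outside the allowed
    set; ambiguous bases (anything not A/C/G/T) count as mismatches by
    default (``model.ambiguous_is_mismatch``).
    """
    model = model or MotifModel()
    if len(window14) != model.width:
        raise ValueError(
            f"window must be {model.width} bases, got {len(window14)}")
    return int(_mismatch_vector(_encode(window14.upper()), model)[0])


def _encode(seq: str) -> np.ndarray:
    codes = np.full(len(seq), 4, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        codes[np.frombuffer(seq.encode(), dtype=np.uint8)
              == ord(base)] = idx
    return codes


def _mismatch_vector(codes: np.ndarray, model: MotifModel) -> np.ndarray:
    """Mismatch count for every 14-mer start position in *codes*."""
    w = model.width
    n = len(codes) - w + 1
    if n <= 0:
        return np.zeros(0, dtype=np.int64)
    table = model.allowed_table()
    windows = np.lib.stride_tricks.sliding_window_view(codes, w)[:n]
    ok = table[np.arange(w)[None, :], windows]
    return (~ok).sum(axis=1)


@dataclass(frozen=True)
class MotifHit:
    """A scored motif occurrence in a promoter window.

    ``position`` is the signed offset of the 5'-most motif base relative to
    the first base of the lead gene's start codon, in the unit's transcription
    orientation (upstream negative). ``strand_of_hit`` is relative to the
    coding strand; with a palindromic model it is informational only.
    """

    unit_id: str
    position: int
    strand_of_hit: str  # "same" | "opposite"
    sequence_14mer: str
    mismatches: int


def scan_promoter(window: PromoterWindow, model: MotifModel | None = None,
                  max_mm: int = 2) -> list[MotifHit]:
    """All motif occurrences with at most *max_mm* mismatches.

    Both strands are examined; the palindromic model scores them
    identically, so each start position is reported once, in coding-strand
    coordinates, sorted by (mismatches ascending, |position| ascending).
    """
    model = model or MotifModel()
    seq = window.sequence.upper()
    if len(seq) < model.width:
        return []
    mm_fwd = _mismatch_vector(_encode(seq), model)
    mm_rev = _mismatch_vector(_encode(reverse_complement(seq)), model)[::-1]
    hits: list[MotifHit] = []
    for i in np.nonzero(np.minimum(mm_fwd, mm_rev) <= max_mm)[0]:
        mm = int(min(mm_fwd[i], mm_rev[i]))
        strand = "same" if mm_fwd[i] <= mm_rev[i] else "opposite"
        hits.append(MotifHit(
            unit_id=window.unit_id,
            position=window.offset_of_index(int(i)),
            strand_of_hit=strand,
            sequence_14mer=seq[i:i + model.width],
            mismatches=mm,
        ))
    hits.sort(key=lambda h: (h.mismatches, abs(h.position)))
    return hits


def best_hit(hits: Sequence[MotifHit]) -> Optional[MotifHit]:
    """Fewest mismatches; ties by smallest |position|, then coding strand."""
    if not hits:
        return None
    return min(hits, key=lambda h: (h.mismatches, abs(h.position),
                                    0 if h.strand_of_hit == "same" else 1))


def assign_divergent(box: MotifHit, unit_fwd: TranscriptionalUnit,
                     unit_rev: TranscriptionalUnit,
                     annotation) -> tuple[MotifHit, MotifHit]:
    """Assign one intergenic box to both units of a divergent promoter pair.

    *box* must carry the position already expressed in ``unit_fwd``'s frame
    (the "+"-strand unit). The two returned hits describe the same genomic
    14-mer, each with the signed position in its own unit's coordinate frame.

    For a head-to-head pair — reverse-strand unit ending at forward
    coordinate ``e``, forward-strand unit starting at ``s`` — a box whose
    5'-most base (forward strand) sits at forward coordinate ``f`` has
    position ``f - s`` for the forward unit and ``e - (f + 13)`` for the
    reverse unit; the two positions sum to ``-(gap + 14)`` where
    ``gap = s - e - 1`` is the intergenic length.
    """
    if unit_fwd.strand != "+" or unit_rev.strand != "-":
        raise ValueError("assign_divergent expects a (+ strand, - strand) "
                         "unit pair in that order")
    lead_fwd = annotation[unit_fwd.lead_gene]
    lead_rev = annotation[unit_rev.lead_gene]
    if lead_rev.end >= lead_fwd.start:
        raise ValueError("units are not divergently oriented with a shared "
                         "intergenic region")
    width = len(box.sequence_14mer)
    f = lead_fwd.start + box.position          # forward coord of 5'-most base
    if not (lead_rev.end < f and f + width - 1 < lead_fwd.start):
        raise ValueError(
            f"box at forward {f}..{f + width - 1} lies outside the shared "
            f"intergenic region {lead_rev.end + 1}..{lead_fwd.start - 1}")
    pos_rev = lead_rev.end - (f + width - 1)
    hit_fwd = MotifHit(unit_fwd.unit_id, box.position, box.strand_of_hit,
                       box.sequence_14mer, box.mismatches)
    hit_rev = MotifHit(unit_rev.unit_id, pos_rev,
                       box.strand_of_hit,
                       reverse_complement(box.sequence_14mer), box.mismatches)
    return hit_fwd, hit_rev


@dataclass(frozen=True)
class CandidateRecord:
    """One row of the candidate table (published-candidate-table layout)."""

    locus_tag: str
    fc_mutant: float
    fc_wt: float
    gene_name: str | None = None
    product: str | None = None
    position: int | None = None
    motif: str | None = None
    operon_string: str | None = None


def annotate_candidates(
    units: Iterable[TranscriptionalUnit],
    hits_by_unit: dict[str, MotifHit],
    fc_mutant: dict[str, float],
    fc_wt: dict[str, float],
    activated_genes: set[str],
    products: dict[str, str] | None = None,
    gene_names: dict[str, str] | None = None,
) -> list[CandidateRecord]:
    """Emit the per-gene candidate table.

    One record per activated member gene of every unit that has a box;
    the motif and its position are attached only to the unit's lead row.
    Units without any hit are excluded entirely.
    """
    products = products or {}
    gene_names = gene_names or {}
    records: list[CandidateRecord] = []
    for unit in units:
        hit = hits_by_unit.get(unit.unit_id)
        if hit is None:
            continue
        members = [t for t in unit.locus_tags if t in activated_genes]
        if not members:
            continue
        operon = unit.operon_string if len(unit.locus_tags) > 1 else None
        for tag in members:
            is_lead = tag == unit.lead_gene
            records.append(CandidateRecord(
                locus_tag=tag,
                fc_mutant=fc_mutant[tag],
                fc_wt=fc_wt[tag],
                gene_name=gene_names.get(tag),
                product=products.get(tag),
                position=hit.position if is_lead else None,
                motif=hit.sequence_14mer if is_lead else None,
                operon_string=operon,
            ))
    return records
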