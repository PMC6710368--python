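"""Genome annotation container and FASTA/GFF3 input/output.

Coordinates follow the GFF3 convention throughout: 1-based, inclusive,
always given on the forward strand regardless of the gene's own strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


@dataclass(frozen=True)
class Gene:
    """One annotated gene: 1-based inclusive forward-strand coordinates."""

    locus_tag: str
    start: int
    end: int
    strand: str  # "+" or "-"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"invalid coordinates for {self.locus_tag}: "
                f"start={self.start}, end={self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class GenomeAnnotation:
    """Ordered gene annotation for a single replicon."""

    replicon_id: str
    length: int
    genes: list[Gene] = field(default_factory=list)
    circular: bool = False

    def __post_init__(self) -> None:
        self.genes = sorted(self.genes, key=lambda g: (g.start, g.end))
        tags = [g.locus_tag for g in self.genes]
        if len(tags) != len(set(tags)):
            dup = sorted({t for t in tags if tags.count(t) > 1})
            raise ValueError(f"duplicate locus_tags: {dup}")
        seen: set[tuple[int, int, str]] = set()
        for g in self.genes:
            if g.end > self.length:
                raise ValueError(
                    f"{g.locus_tag} extends past replicon end "
                    f"({g.end} > {self.length})"
                )
            key = (g.start, g.end, g.strand)
            if key in seen:
                raise ValueError(f"duplicate gene interval {key}")
            seen.add(key)
        self._by_tag = {g.locus_tag: g for g in self.genes}

    def __iter__(self) -> Iterator[Gene]:
        return iter(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __getitem__(self, locus_tag: str) -> Gene:
        return self._by_tag[locus_tag]

    def __contains__(self, locus_tag: str) -> bool:
        return locus_tag in self._by_tag

    @property
    def locus_tags(self) -> list[str]:
        return [g.locus_tag for g in self.genes]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(sequence: str, replicon_id: str, path: str | Path) -> None:
    rec = SeqRecord(Seq(sequence), id=replicon_id, description="")
    SeqIO.write([rec], str(path), "fasta")


def read_fasta(path: str | Path) -> tuple[str, str]:
    """Return (replicon_id, sequence) of the single record in *path*."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"expected exactly one FASTA record in {path}, "
                         f"found {len(records)}")
    rec = records[0]
    return rec.id, str(rec.seq).upper()


# ---------------------------------------------------------------------------
# GFF3 (gene features with locus_tag attribute)
# ---------------------------------------------------------------------------

def write_gff3(annotation: GenomeAnnotation, path: str | Path) -> None:
    lines = ["##gff-version 3",
             f"##sequence-region {annotation.replicon_id} 1 {annotation.length}"]
    if annotation.circular:
        lines.append(f"# {annotation.replicon_id} is circular")
    for g in annotation.genes:
        attrs = f"ID=gene-{g.locus_tag};locus_tag={g.locus_tag}"
        lines.append("\t".join([
            annotation.replicon_id, "nnrr_regulon", "gene",
            str(g.start), str(g.end), ".", g.strand, ".", attrs,
        ]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path: str | Path, circular: bool = False) -> GenomeAnnotation:
    """Parse `gene` features carrying a locus_tag attribute."""
    replicon_id = None
    length = 0
    genes: list[Gene] = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("##sequence-region"):
            _, rid, _start, end = line.split()
            replicon_id, length = rid, int(end)
            continue
        if not line or line.startswith("#"):
            if line.strip().endswith("is circular"):
                circular = True
            continue
        fields = line.split("\t")
        if len(fields) != 9 or fields[2] != "gene":
            continue
        seqid, _src, _type, start, end, _score, strand, _phase, attrs = fields
        replicon_id = replicon_id or seqid
        attr_map = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
        tag = attr_map.get("locus_tag") or attr_map.get("ID")
        if tag is None:
            raise ValueError(f"gene feature without locus_tag in {path}: {line}")
        genes.append(Gene(tag, int(start), int(end), strand))
    if replicon_id is None:
        raise ValueError(f"no sequence-region or gene features found in {path}")
    length = length or max(g.end for g in genes)
    return GenomeAnnotation(replicon_id, length, genes, circular=circular)


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())
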