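"""Synthetic genomes, planted regulatory boxes, and matched expression data.

Every downstream stage of the pipeline is testable without external data:
this module builds annotated replicons with independent uniform-background
sequence, plants FixK2-box instances (0-2 mismatches against the
consensus) upstream of the lead genes of chosen transcriptional units, and
simulates normalized expression intensities with log-normal multiplicative
noise plus present/marginal/absent detection calls, so that planted fold
changes and box positions are exactly recoverable ground truth.

Study conditions emulated by the defaults: three biological replicates per
(strain, condition) group and two contrasts — regulator-mutant vs wild
type under anoxic denitrifying growth, and wild type anoxic vs oxic — with
planted regulon effects of |FC| >= 2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import Contrast
from .genome import Gene, GenomeAnnotation, reverse_complement
from .motif import MotifModel, mismatch_count

BASES = "ACGT"

STRAINS = ("WT", "nnrR", "fixK2")
CONDITIONS = ("oxic", "microoxic", "anoxic_NO3")


class SizingError(ValueError):
    """Requested genes do not fit the replicon length."""


class PlacementError(ValueError):
    """A planted box would collide with an annotated gene body."""


# ---------------------------------------------------------------------------
# sample design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Sample:
    sample_id: str
    strain: str
    condition: str
    replicate: int


@dataclass
class SampleDesign:
    samples: list[Sample]

    def group(self, strain: str, condition: str) -> tuple[str, ...]:
        return tuple(s.sample_id for s in self.samples
                     if s.strain == strain and s.condition == condition)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(s) for s in self.samples])


def default_design(n_replicates: int = 3) -> SampleDesign:
    """Three replicates each of WT oxic, WT anoxic, and mutant anoxic."""
    samples = [
        Sample(f"{strain}_{cond}_{r}", strain, cond, r)
        for strain, cond in (("WT", "oxic"), ("WT", "anoxic_NO3"),
                             ("nnrR", "anoxic_NO3"))
        for r in range(1, n_replicates + 1)
    ]
    return SampleDesign(samples)


def contrast_mutant_vs_wt(design: SampleDesign) -> Contrast:
    return Contrast("nnrR_anoxia_vs_WT_anoxia",
                    design.group("nnrR", "anoxic_NO3"),
                    design.group("WT", "anoxic_NO3"))


def contrast_wt_anoxia_vs_oxia(design: SampleDesign) -> Contrast:
    return Contrast("WT_anoxia_vs_WT_oxia",
                    design.group("WT", "anoxic_NO3"),
                    design.group("WT", "oxic"))


# ---------------------------------------------------------------------------
# planted truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BoxSpec:
    """One planted box upstream of a unit's lead gene.

    ``offset_upstream`` is the positive distance of the 5'-most motif base
    from the first base of the start codon (scan reports -offset);
    ``strand`` is the orientation the instance was sampled in, relative to
    the unit's coding strand; ``planted_14mer`` is the coding-orientation
    readout (filled by :func:`plant_boxes`).
    """

    offset_upstream: int
    strand: str = "+"
    mismatches: int = 0
    planted_14mer: str | None = None


@dataclass(frozen=True)
class GeneEffect:
    fc_wt_anoxia_vs_oxia: float
    fc_mutant_vs_wt: float


@dataclass
class PlantedTruth:
    """Ground truth for parameter-recovery tests."""

    regulon_units: list[str] = field(default_factory=list)
    boxes: dict[str, BoxSpec] = field(default_factory=dict)
    gene_effects: dict[str, GeneEffect] = field(default_factory=dict)
    unit_members: dict[str, tuple[str, ...]] = field(default_factory=dict)
    divergent_pairs: list[tuple[str, str]] = field(default_factory=list)

    def validate(self, model: MotifModel | None = None) -> None:
        model = model or MotifModel()
        gene_owner: dict[str, str] = {}
        for unit, members in self.unit_members.items():
            for g in members:
                if g in gene_owner:
                    raise ValueError(f"gene {g} in two units "
                                     f"({gene_owner[g]}, {unit})")
                gene_owner[g] = unit
        for unit, box in self.boxes.items():
            if box.offset_upstream <= 0:
                raise ValueError(f"offset must be positive for {unit}")
            if box.planted_14mer is not None:
                mm = mismatch_count(box.planted_14mer, model)
                if mm != box.mismatches:
                    raise ValueError(
                        f"{unit}: planted 14-mer has {mm} mismatches, "
                        f"declared {box.mismatches}")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "regulon_units": self.regulon_units,
            "boxes": {u: asdict(b) for u, b in self.boxes.items()},
            "gene_effects": {g: asdict(e)
                             for g, e in self.gene_effects.items()},
            "unit_members": {u: list(m) for u, m in self.unit_members.items()},
            "divergent_pairs": [list(p) for p in self.divergent_pairs],
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PlantedTruth":
        raw = json.loads(Path(path).read_text())
        return cls(
            regulon_units=raw["regulon_units"],
            boxes={u: BoxSpec(**b) for u, b in raw["boxes"].items()},
            gene_effects={g: GeneEffect(**e)
                          for g, e in raw["gene_effects"].items()},
            unit_members={u: tuple(m)
                          for u, m in raw["unit_members"].items()},
            divergent_pairs=[tuple(p) for p in raw["divergent_pairs"]],
        )


def ratio_from_fc(fc: float) -> float:
    """Signed fold change -> multiplicative ratio (|fc| >= 1 required)."""
    if abs(fc) < 1:
        raise ValueError(f"signed fold change must have |fc| >= 1, got {fc}")
    return fc if fc >= 1 else -1.0 / fc


# ---------------------------------------------------------------------------
# genome generation
# ---------------------------------------------------------------------------

def generate_genome(n_genes: int, mean_gene_len: int = 900,
                    mean_gap: int = 400, frac_reverse: float = 0.3,
                    seed: int = 0, *, replicon_id: str = "synthrep1",
                    length: int | None = None,
                    circular: bool = False) -> tuple[str, GenomeAnnotation]:
    """Random annotated replicon with non-overlapping genes.

    Gene lengths and intergenic gaps are Poisson-distributed around their
    means; background sequence is i.i.d. uniform over A/C/G/T; the first
    codon of every gene (in its own orientation) is set to ATG. Output is
    deterministic given the seed.
    """
    if n_genes < 2:
        raise ValueError("need n_genes >= 2")
    if mean_gene_len <= 0 or mean_gap <= 0:
        raise ValueError("lengths and gaps must be positive")
    rng = np.random.default_rng(seed)
    gene_lens = np.maximum(rng.poisson(mean_gene_len, n_genes), 60)
    gaps = np.maximum(rng.poisson(mean_gap, n_genes + 1), 30)
    strands = np.where(rng.random(n_genes) < frac_reverse, "-", "+")

    genes: list[Gene] = []
    pos = 1 + gaps[0]
    for i in range(n_genes):
        start = int(pos)
        end = start + int(gene_lens[i]) - 1
        genes.append(Gene(f"sg{i + 1:04d}", start, end, str(strands[i])))
        pos = end + 1 + gaps[i + 1]
    needed = int(pos) - 1
    if length is not None and needed > length:
        raise SizingError(
            f"{n_genes} genes need {needed} bp, replicon length is {length}")
    total = length or needed

    seq = rng.choice(list(BASES), size=total)
    sequence = "".join(seq)
    for g in genes:
        sequence = _write_segment(
            sequence, g.start if g.strand == "+" else g.end - 2,
            "ATG" if g.strand == "+" else reverse_complement("ATG"))
    annotation = GenomeAnnotation(replicon_id, total, genes, circular=circular)
    return sequence, annotation


def _write_segment(genome: str, start_1based: int, segment: str) -> str:
    i = start_1based - 1
    return genome[:i] + segment + genome[i + len(segment):]


# ---------------------------------------------------------------------------
# box planting
# ---------------------------------------------------------------------------

def _sample_motif_instance(model: MotifModel, n_mismatches: int,
                           rng: np.random.Generator) -> str:
    """A 14-mer with exactly *n_mismatches* at constrained positions."""
    allowed = model.allowed
    bases = [str(rng.choice(sorted(s))) for s in allowed]
    constrained = [i for i, s in enumerate(allowed) if len(s) < 4]
    hit_positions = rng.choice(len(constrained), size=n_mismatches,
                               replace=False)
    for k in np.atleast_1d(hit_positions):
        i = constrained[int(k)]
        outside = sorted(set(BASES) - allowed[i])
        bases[i] = str(rng.choice(outside))
    return "".join(bases)


def _box_span(lead: Gene, offset: int, width: int = 14) -> tuple[int, int]:
    """Forward-strand coordinates covered by a box at -offset."""
    if lead.strand == "+":
        start = lead.start - offset
        return start, start + width - 1
    end = lead.end + offset
    return end - width + 1, end


def plant_boxes(genome: str, annotation: GenomeAnnotation,
                truth: PlantedTruth, seed: int = 0, *,
                model: MotifModel | None = None,
                allow_gene_overlap: bool = False,
                ) -> tuple[str, PlantedTruth]:
    """Write one 14-mer per declared box into the genome sequence.

    Box offsets are interpreted in each unit's transcription frame; the
    degenerate consensus positions are filled randomly and the declared
    number of mismatches is introduced at randomly chosen constrained
    positions. Planting refuses to overwrite any annotated gene body
    unless ``allow_gene_overlap`` is set. For divergent promoter pairs the
    same genomic 14-mer is recorded for both flanking units, each in its
    own coordinate frame.
    """
    model = model or MotifModel()
    rng = np.random.default_rng(seed)
    new_boxes: dict[str, BoxSpec] = {}
    derived_partner = {a: b for a, b in truth.divergent_pairs}

    for unit_id, box in truth.boxes.items():
        lead = annotation[unit_id if unit_id in annotation
                          else truth.unit_members[unit_id][0]]
        if box.offset_upstream < model.width:
            raise PlacementError(
                f"{unit_id}: offset {box.offset_upstream} cannot hold a "
                f"{model.width} bp box fully upstream")
        span = _box_span(lead, box.offset_upstream, model.width)
        if span[0] < 1 or span[1] > annotation.length:
            raise PlacementError(f"{unit_id}: box span {span} outside replicon")
        if not allow_gene_overlap:
            for g in annotation:
                if span[0] <= g.end and g.start <= span[1]:
                    raise PlacementError(
                        f"{unit_id}: box at forward {span[0]}..{span[1]} "
                        f"overlaps gene {g.locus_tag} "
                        f"({g.start}..{g.end})")
        instance = _sample_motif_instance(model, box.mismatches, rng)
        coding_readout = instance if box.strand == "+" \
            else reverse_complement(instance)
        forward_seq = coding_readout if lead.strand == "+" \
            else reverse_complement(coding_readout)
        genome = _write_segment(genome, span[0], forward_seq)
        new_boxes[unit_id] = BoxSpec(box.offset_upstream, box.strand,
                                     box.mismatches, coding_readout)
        partner = derived_partner.get(unit_id)
        if partner is not None:
            plead = annotation[partner if partner in annotation
                               else truth.unit_members[partner][0]]
            if plead.strand == lead.strand:
                raise ValueError(f"divergent pair ({unit_id}, {partner}) "
                                 "must be on opposite strands")
            if plead.strand == "+":
                p_offset = plead.start - span[0]
            else:
                p_offset = span[1] - plead.end
            if p_offset < model.width:
                raise PlacementError(
                    f"shared box for ({unit_id}, {partner}) is not in the "
                    "intergenic region")
            new_boxes[partner] = BoxSpec(
                p_offset, box.strand, box.mismatches,
                reverse_complement(coding_readout))

    out = PlantedTruth(
        regulon_units=list(truth.regulon_units),
        boxes=new_boxes,
        gene_effects=dict(truth.gene_effects),
        unit_members=dict(truth.unit_members),
        divergent_pairs=list(truth.divergent_pairs),
    )
    out.validate(model)
    return genome, out


# ---------------------------------------------------------------------------
# expression simulation
# ---------------------------------------------------------------------------

def simulate_expression(truth: PlantedTruth, design: SampleDesign,
                        gene_ids: Sequence[str], *, base_mean: float = 500.0,
                        cv: float = 0.15, seed: int = 0,
                        baseline_sigma: float = 0.5,
                        absent_genes: Iterable[str] = (),
                        absent_mean: float = 20.0,
                        call_absent_below: float = 100.0,
                        call_marginal_below: float = 150.0,
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Normalized intensities and P/M/A calls with planted fold changes.

    Per-gene baselines are log-normal around ``base_mean`` (spread
    ``baseline_sigma`` in natural-log units); condition means multiply the
    baseline by the planted ratios; measurement noise is multiplicative
    log-normal with coefficient of variation ``cv``, so the expected
    linear-scale ratio between groups equals the planted fold change and
    non-regulon genes have expected FC = 1. Calls are thresholded on
    intensity with a marginal band. Genes in ``absent_genes`` are driven
    to ``absent_mean`` in every sample and end up called A throughout.
    """
    if cv <= 0:
        raise ValueError("cv must be positive")
    for g, eff in truth.gene_effects.items():
        ratio_from_fc(eff.fc_wt_anoxia_vs_oxia)
        ratio_from_fc(eff.fc_mutant_vs_wt)
    rng = np.random.default_rng(seed)
    gene_ids = list(gene_ids)
    absent = set(absent_genes)
    n_genes, n_samples = len(gene_ids), len(design.samples)

    baseline = base_mean * np.exp(
        rng.normal(0.0, baseline_sigma, n_genes) - baseline_sigma ** 2 / 2)
    baseline[[i for i, g in enumerate(gene_ids) if g in absent]] = absent_mean

    means = np.tile(baseline[:, None], (1, n_samples))
    for i, g in enumerate(gene_ids):
        eff = truth.gene_effects.get(g)
        if eff is None or g in absent:
            continue
        r_wt = ratio_from_fc(eff.fc_wt_anoxia_vs_oxia)
        r_mut = ratio_from_fc(eff.fc_mutant_vs_wt)
        for j, s in enumerate(design.samples):
            if s.condition == "anoxic_NO3":
                means[i, j] *= r_wt
                if s.strain == "nnrR":
                    means[i, j] *= r_mut

    sigma = np.sqrt(np.log1p(cv ** 2))
    noise = np.exp(rng.normal(0.0, sigma, (n_genes, n_samples))
                   - sigma ** 2 / 2)
    values = means * noise

    matrix = pd.DataFrame(values, index=gene_ids, columns=design.sample_ids)
    matrix.index.name = "gene_id"
    calls = pd.DataFrame(
        np.where(values < call_absent_below, "A",
                 np.where(values < call_marginal_below, "M", "P")),
        index=gene_ids, columns=design.sample_ids)
    calls.index.name = "gene_id"
    return matrix, calls


# ---------------------------------------------------------------------------
# Cq simulation (forward model of the Pfaffl inverse)
# ---------------------------------------------------------------------------

def simulate_cq(true_ratios: Mapping[str, float],
                efficiencies: Mapping[str, float] | None = None, *,
                cq_noise_sd: float = 0.0, seed: int = 0,
                n_replicates: int = 3, ref_gene: str = "sigA",
                control_group: str = "WT", sample_group: str = "mutant",
                base_cq: float = 22.0) -> pd.DataFrame:
    """Cq table whose Pfaffl inversion recovers *true_ratios* in expectation.

    The reference assay is held constant across groups (dCq_ref = 0); each
    target's sample-group Cq is shifted by -log_E(ratio) cycles so that
    ratio = E_t**dCq_t / E_r**dCq_r holds exactly at zero noise. Gaussian
    noise of ``cq_noise_sd`` cycles is added per replicate reaction.
    """
    efficiencies = dict(efficiencies or {})
    for gene, ratio in true_ratios.items():
        if ratio <= 0:
            raise ValueError(f"ratio must be positive for {gene}")
    rng = np.random.default_rng(seed)
    rows = []

    def add(gene: str, group: str, cq_mean: float) -> None:
        e = efficiencies.get(gene, 2.0)
        if not (1.0 < e <= 2.0):
            raise ValueError(f"efficiency for {gene} must be in (1, 2]")
        for r in range(1, n_replicates + 1):
            rows.append({
                "sample_id": f"{group}_{r}",
                "group": group,
                "gene": gene,
                "Cq": cq_mean + rng.normal(0.0, cq_noise_sd)
                if cq_noise_sd > 0 else cq_mean,
                "efficiency": e,
            })

    add(ref_gene, control_group, base_cq)
    add(ref_gene, sample_group, base_cq)
    for gene, ratio in true_ratios.items():
        e_t = efficiencies.get(gene, 2.0)
        dcq_t = np.log(ratio) / np.log(e_t)
        add(gene, control_group, base_cq)
        add(gene, sample_group, base_cq - dcq_t)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full scenario: genome + truth + expression + Cq in one seeded build
# ---------------------------------------------------------------------------

@dataclass
class Scenario:
    sequence: str
    annotation: GenomeAnnotation
    truth: PlantedTruth
    design: SampleDesign
    matrix: pd.DataFrame
    calls: pd.DataFrame
    cq: pd.DataFrame

    def write_all(self, outdir: str | Path) -> dict[str, Path]:
        from .genome import write_fasta, write_gff3
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fasta",
            "annotation": outdir / "annotation.gff3",
            "expression": outdir / "expression.tsv",
            "calls": outdir / "calls.tsv",
            "design": outdir / "design.tsv",
            "truth": outdir / "truth.json",
            "cq": outdir / "cq.csv",
        }
        write_fasta(self.sequence, self.annotation.replicon_id,
                    paths["genome"])
        write_gff3(self.annotation, paths["annotation"])
        self.matrix.to_csv(paths["expression"], sep="\t")
        self.calls.to_csv(paths["calls"], sep="\t")
        self.design.to_frame().to_csv(paths["design"], sep="\t", index=False)
        self.truth.to_json(paths["truth"])
        self.cq.to_csv(paths["cq"], index=False)
        return paths


def make_scenario(seed: int = 0, *, n_background: int = 40,
                  unit_sizes: Sequence[int] = (1, 7, 1, 3, 2),
                  include_divergent_pair: bool = True,
                  mean_gene_len: int = 600, operon_gap: int = 120,
                  spacer_gap: int = 700, cv: float = 0.15,
                  n_replicates: int = 3,
                  base_mean: float = 500.0) -> Scenario:
    """Seeded end-to-end synthetic study.

    Lays out background singleton genes interleaved with planted regulon
    transcriptional units (sizes from ``unit_sizes``; members share a
    strand and sit ``operon_gap`` bp apart, well under the 200 bp grouping
    default) plus, optionally, one divergent head-to-head promoter pair
    sharing a single box. Every regulon gene receives an anoxia induction
    and a mutant downregulation beyond the |FC| >= 2 thresholds; boxes are
    planted with 0-2 mismatches at offsets drawn from the published-table-like
    range 20-200 bp upstream.
    """
    rng = np.random.default_rng(seed)
    plan: list[dict] = []     # unit plans
    layout: list[tuple[str, int, str]] = []   # (kind, size, strand)

    n_units = len(unit_sizes)
    background_per_slot = max(1, n_background // (n_units + 2))
    mismatch_cycle = [0, 1, 2]
    for k, size in enumerate(unit_sizes):
        for _ in range(background_per_slot):
            layout.append(("bg", 1, "+" if rng.random() > 0.3 else "-"))
        strand = "+" if rng.random() > 0.4 else "-"
        layout.append(("unit", size, strand))
        plan.append({"size": size, "strand": strand,
                     "mismatches": mismatch_cycle[k % 3]})
    if include_divergent_pair:
        layout.append(("divpair", 2, "-+"))
    for _ in range(background_per_slot):
        layout.append(("bg", 1, "+"))

    genes: list[Gene] = []
    unit_records: list[dict] = []
    pos = 1 + spacer_gap
    gi = 0
    plan_i = 0

    def next_tag() -> str:
        nonlocal gi
        gi += 1
        return f"sg{gi:04d}"

    for kind, size, strand in layout:
        if kind == "bg":
            glen = int(max(60, rng.poisson(mean_gene_len)))
            tag = next_tag()
            genes.append(Gene(tag, pos, pos + glen - 1, strand))
            pos += glen + spacer_gap
        elif kind == "unit":
            members = []
            coords = []
            for m in range(size):
                glen = int(max(60, rng.poisson(mean_gene_len)))
                tag = next_tag()
                genes.append(Gene(tag, pos, pos + glen - 1, strand))
                members.append(tag)
                coords.append((pos, pos + glen - 1))
                pos += glen + (operon_gap if m < size - 1 else spacer_gap)
            if strand == "-":
                members = members[::-1]
            unit_records.append({**plan[plan_i], "members": tuple(members),
                                 "divergent_with": None})
            plan_i += 1
        else:  # divergent head-to-head pair: '-' gene then '+' gene
            glen_a = int(max(60, rng.poisson(mean_gene_len)))
            tag_a = next_tag()
            genes.append(Gene(tag_a, pos, pos + glen_a - 1, "-"))
            pos += glen_a + 320  # shared intergenic promoter region
            glen_b = int(max(60, rng.poisson(mean_gene_len)))
            tag_b = next_tag()
            genes.append(Gene(tag_b, pos, pos + glen_b - 1, "+"))
            pos += glen_b + spacer_gap
            unit_records.append({"size": 1, "strand": "+", "mismatches": 0,
                                 "members": (tag_b,),
                                 "divergent_with": tag_a})
            unit_records.append({"size": 1, "strand": "-", "mismatches": 0,
                                 "members": (tag_a,), "derived": True,
                                 "divergent_with": None})

    total = pos - 1 + spacer_gap
    sequence = "".join(rng.choice(list(BASES), size=total))
    annotation = GenomeAnnotation("synthrep1", total, genes)
    for g in genes:
        sequence = _write_segment(
            sequence, g.start if g.strand == "+" else g.end - 2,
            "ATG" if g.strand == "+" else reverse_complement("ATG"))

    truth = PlantedTruth()
    for rec in unit_records:
        lead = rec["members"][0]
        truth.regulon_units.append(lead)
        truth.unit_members[lead] = rec["members"]
        for g in rec["members"]:
            fc_wt = round(float(10 ** rng.uniform(0.5, 1.5)), 1)
            fc_mut = -round(float(10 ** rng.uniform(0.4, 1.2)), 1)
            truth.gene_effects[g] = GeneEffect(fc_wt, fc_mut)
        if rec.get("derived"):
            continue  # box arrives via the divergent partner
        offset = int(rng.integers(20, 200))
        truth.boxes[lead] = BoxSpec(offset_upstream=offset,
                                    mismatches=rec["mismatches"])
        if rec["divergent_with"] is not None:
            truth.divergent_pairs.append((lead, rec["divergent_with"]))

    sequence, truth = plant_boxes(sequence, annotation, truth,
                                  seed=int(rng.integers(2 ** 31)))

    design = default_design(n_replicates)
    matrix, calls = simulate_expression(
        truth, design, annotation.locus_tags, base_mean=base_mean, cv=cv,
        seed=int(rng.integers(2 ** 31)))

    qpcr_genes = sorted(truth.gene_effects)[:4]
    true_ratios = {g: ratio_from_fc(truth.gene_effects[g].fc_mutant_vs_wt)
                   for g in qpcr_genes}
    cq = simulate_cq(true_ratios, cq_noise_sd=0.15,
                     seed=int(rng.integers(2 ** 31)),
                     control_group="WT_anoxia", sample_group="nnrR_anoxia")
    return Scenario(sequence, annotation, truth, design, matrix, calls, cq)
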