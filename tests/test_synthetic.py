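"""Generator invariants: genomes, planted boxes, expression, Cq tables."""

import io

import numpy as np
import pytest

from nnrr_regulon.genome import reverse_complement
from nnrr_regulon.motif import MotifModel, mismatch_count, scan_promoter
from nnrr_regulon.synthetic import (BoxSpec, GeneEffect, PlacementError,
                                    PlantedTruth, SizingError, default_design,
                                    generate_genome, make_scenario,
                                    plant_boxes, simulate_cq,
                                    simulate_expression)
from nnrr_regulon.units import group_units, promoter_window


class TestGenerateGenome:
    def test_coordinates_strictly_increasing(self):
        _, ann = generate_genome(n_genes=10, seed=1)
        starts = [g.start for g in ann]
        assert starts == sorted(starts)
        for a, b in zip(ann.genes, ann.genes[1:]):
            assert a.end < b.start  # non-overlapping

    def test_forced_reverse_strand(self):
        _, ann = generate_genome(n_genes=2, frac_reverse=1.0, seed=2)
        assert all(g.strand == "-" for g in ann)

    def test_same_seed_identical_output(self, tmp_path):
        from nnrr_regulon.genome import write_fasta, write_gff3
        outputs = []
        for run in range(2):
            seq, ann = generate_genome(n_genes=8, seed=42)
            fa, gff = tmp_path / f"g{run}.fa", tmp_path / f"g{run}.gff3"
            write_fasta(seq, ann.replicon_id, fa)
            write_gff3(ann, gff)
            outputs.append((fa.read_bytes(), gff.read_bytes()))
        assert outputs[0] == outputs[1]

    def test_sizing_error_when_genes_do_not_fit(self):
        with pytest.raises(SizingError):
            generate_genome(n_genes=20, mean_gene_len=1000, length=5000,
                            seed=0)

    def test_start_codons_written(self):
        seq, ann = generate_genome(n_genes=6, seed=3)
        for g in ann:
            codon = seq[g.start - 1:g.start + 2] if g.strand == "+" \
                else reverse_complement(seq[g.end - 3:g.end])
            assert codon == "ATG"

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            generate_genome(n_genes=1)
        with pytest.raises(ValueError):
            generate_genome(n_genes=5, mean_gap=0)


class TestPlantBoxes:
    def _single_gene(self, strand="+"):
        seq, ann = generate_genome(n_genes=3, mean_gap=800, seed=5,
                                   frac_reverse=0.0 if strand == "+" else 1.0)
        return seq, ann

    def test_perfect_box_recovered_at_declared_offset(self):
        seq, ann = self._single_gene()
        tag = ann.locus_tags[1]
        truth = PlantedTruth(regulon_units=[tag], unit_members={tag: (tag,)},
                             boxes={tag: BoxSpec(86, mismatches=0)})
        seq, truth = plant_boxes(seq, ann, truth, seed=1)
        (unit,) = group_units(ann, {tag})
        hits = scan_promoter(promoter_window(unit, seq, ann), max_mm=0)
        assert any(h.position == -86 and h.mismatches == 0 for h in hits)

    def test_planted_mismatch_count_is_exact(self):
        seq, ann = self._single_gene("-")
        tag = ann.locus_tags[1]
        for mm in (0, 1, 2):
            truth = PlantedTruth(unit_members={tag: (tag,)},
                                 boxes={tag: BoxSpec(100, mismatches=mm)})
            _, planted = plant_boxes(seq, ann, truth, seed=mm)
            assert mismatch_count(planted.boxes[tag].planted_14mer) == mm

    def test_two_mismatch_box_invisible_at_max_mm_one(self):
        """Planted at 2 mismatches, scanned at max_mm=1 -> position absent."""
        seq, ann = self._single_gene()
        tag = ann.locus_tags[1]
        truth = PlantedTruth(unit_members={tag: (tag,)},
                             boxes={tag: BoxSpec(120, mismatches=2)})
        seq, _ = plant_boxes(seq, ann, truth, seed=9)
        (unit,) = group_units(ann, {tag})
        hits = scan_promoter(promoter_window(unit, seq, ann), max_mm=1)
        assert all(h.position != -120 for h in hits)

    def test_offset_too_small_for_box_rejected(self):
        seq, ann = self._single_gene()
        tag = ann.locus_tags[1]
        truth = PlantedTruth(unit_members={tag: (tag,)},
                             boxes={tag: BoxSpec(10)})
        with pytest.raises(PlacementError, match="fully upstream"):
            plant_boxes(seq, ann, truth)

    def test_gene_body_collision_rejected(self):
        seq, ann = generate_genome(n_genes=3, mean_gap=100, seed=6,
                                   frac_reverse=0.0)
        tag = ann.locus_tags[1]
        truth = PlantedTruth(unit_members={tag: (tag,)},
                             boxes={tag: BoxSpec(400)})  # reaches prior gene
        with pytest.raises(PlacementError, match="overlaps gene"):
            plant_boxes(seq, ann, truth)

    def test_divergent_pair_shares_one_box(self, scenario):
        """Both flanking units record the same genomic 14-mer."""
        ((fwd_unit, rev_unit),) = scenario.truth.divergent_pairs
        box_fwd = scenario.truth.boxes[fwd_unit]
        box_rev = scenario.truth.boxes[rev_unit]
        assert box_rev.planted_14mer \
            == reverse_complement(box_fwd.planted_14mer)
        assert box_fwd.mismatches == box_rev.mismatches

    def test_truth_json_round_trip(self, scenario, tmp_path):
        path = tmp_path / "truth.json"
        scenario.truth.to_json(path)
        back = PlantedTruth.from_json(path)
        assert back.boxes == scenario.truth.boxes
        assert back.gene_effects == scenario.truth.gene_effects
        assert back.divergent_pairs == scenario.truth.divergent_pairs


class TestSimulateExpression:
    def test_fold_change_recovery_monte_carlo(self):
        """True FC=+8, cv=0.1, n=3: estimated FC in [4,16] essentially always."""
        design = default_design()
        truth = PlantedTruth(gene_effects={
            f"g{i}": GeneEffect(8.0, -2.0) for i in range(1500)})
        matrix, _ = simulate_expression(truth, design, list(truth.gene_effects),
                                        cv=0.1, seed=11)
        wt_anx = list(design.group("WT", "anoxic_NO3"))
        wt_ox = list(design.group("WT", "oxic"))
        fc = matrix[wt_anx].mean(axis=1) / matrix[wt_ox].mean(axis=1)
        frac_in = float(((fc >= 4) & (fc <= 16)).mean())
        assert frac_in > 0.99

    def test_null_genes_have_unit_expected_fc(self):
        design = default_design()
        matrix, _ = simulate_expression(PlantedTruth(), design,
                                        [f"g{i}" for i in range(2000)],
                                        cv=0.1, seed=12)
        wt_anx = list(design.group("WT", "anoxic_NO3"))
        wt_ox = list(design.group("WT", "oxic"))
        log_fc = np.log2(matrix[wt_anx].mean(axis=1)
                         / matrix[wt_ox].mean(axis=1))
        assert abs(float(log_fc.mean())) < 0.02

    def test_forced_absent_gene_called_A_everywhere(self):
        design = default_design()
        _, calls = simulate_expression(PlantedTruth(), design, ["gA", "gB"],
                                       seed=13, absent_genes=["gA"],
                                       baseline_sigma=0.0)
        assert (calls.loc["gA"] == "A").all()
        assert (calls.loc["gB"] == "P").all()

    def test_cv_validation(self):
        with pytest.raises(ValueError, match="cv"):
            simulate_expression(PlantedTruth(), default_design(), ["g"],
                                cv=0.0)

    def test_effect_magnitude_validation(self):
        truth = PlantedTruth(gene_effects={"g": GeneEffect(0.5, -2.0)})
        with pytest.raises(ValueError, match="fc"):
            simulate_expression(truth, default_design(), ["g"])


class TestSimulateCq:
    def test_ratio_eight_gives_three_cycles(self):
        """ratio 8 with E=2 and a flat reference -> dCq difference of 3."""
        cq = simulate_cq({"g": 8.0}, cq_noise_sd=0.0)
        mean = cq.groupby(["gene", "group"])["Cq"].mean()
        dcq_target = mean[("g", "WT")] - mean[("g", "mutant")]
        dcq_ref = mean[("sigA", "WT")] - mean[("sigA", "mutant")]
        assert dcq_target - dcq_ref == pytest.approx(3.0, abs=1e-12)

    def test_bad_ratio_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            simulate_cq({"g": -1.0})

    def test_bad_efficiency_rejected(self):
        with pytest.raises(ValueError, match="efficiency"):
            simulate_cq({"g": 2.0}, {"g": 2.5})


class TestScenario:
    def test_every_regulon_gene_has_suprathreshold_effects(self, scenario):
        for eff in scenario.truth.gene_effects.values():
            assert eff.fc_wt_anoxia_vs_oxia >= 2.0
            assert eff.fc_mutant_vs_wt <= -2.0

    def test_units_recoverable_by_grouping(self, scenario):
        units = group_units(scenario.annotation,
                            set(scenario.truth.gene_effects))
        got = {u.unit_id: u.locus_tags for u in units}
        for unit_id, members in scenario.truth.unit_members.items():
            assert got[unit_id] == members

    def test_scenario_determinism(self, scenario):
        again = make_scenario(seed=7)
        assert again.sequence == scenario.sequence
        assert again.matrix.equals(scenario.matrix)
        assert again.cq.equals(scenario.cq)

    def test_write_all_emits_text_formats(self, scenario, tmp_path):
        paths = scenario.write_all(tmp_path)
        for p in paths.values():
            assert p.exists()
            assert p.stat().st_size > 0
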