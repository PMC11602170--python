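"""Operon assembly, junction validation and gate layouts."""

import pytest
from Bio.Seq import Seq

from syntce.assembly import (
    LayoutError,
    Part,
    assemble_operon,
    distance_class,
    gate_layout,
    part_from_candidate,
    scan_internal_rbs,
    validate_junction,
    validate_operon,
)
from syntce.design import SynTCESpec, assemble_syntce, filter_candidate
from syntce.fixtures import FixtureSpec, make_fixture_linker, make_fixture_switch
from syntce.seqcore import (
    SeqValidationError,
    find_overlap_motif,
    junction_frame,
    scan_stop_codons,
)


def _protein(rna: str) -> str:
    """Independent re-translation via Biopython's genetic code."""
    return str(Seq(rna.replace("U", "T")).translate())


class TestPartInvariants:
    def test_orf_must_start_with_aug(self):
        with pytest.raises(SeqValidationError, match="AUG"):
            Part("bad", "orf", "GCAUAA")

    def test_orf_internal_stop_rejected(self):
        with pytest.raises(SeqValidationError, match="internal"):
            Part("bad", "orf", "AUGUAAGCAUAA")

    def test_orf_frame_multiple_of_three(self):
        with pytest.raises(SeqValidationError, match="multiple of 3"):
            Part("bad", "orf", "AUGGCAUAAC")

    def test_syntce_requires_geometry_metadata(self):
        with pytest.raises(SeqValidationError, match="stem_len"):
            Part("bad", "syntce", "GCAUGCAGAGGAGAUCGCAUGCUAAUG")


class TestAssembleOperon:
    def test_two_orf_coupling_retranslates(self, fixture_orfs, tce_parts):
        sw = make_fixture_switch(seed=1)
        design = assemble_operon(
            [sw, fixture_orfs[0], tce_parts[0], fixture_orfs[1]]
        )
        assert len(design.junctions) == 1
        s = str(design.transcript)
        orfs = design.orf_regions()
        assert len(orfs) == 2
        for region in orfs:
            protein = _protein(s[region.start:region.end])
            assert protein.endswith("*")
            assert "*" not in protein[:-1]
        up, down = orfs
        assert down.start % 3 == junction_frame(up.start % 3)

    def test_three_output_chain(self, fixture_orfs, tce_parts):
        design = assemble_operon(
            [fixture_orfs[0], tce_parts[0], fixture_orfs[1],
             tce_parts[1], fixture_orfs[2]]
        )
        assert len(design.junctions) == 2
        assert len(design.orf_regions()) == 3
        s = str(design.transcript)
        for junction in design.junctions:
            p = junction.stop_region.start
            assert find_overlap_motif(s[p:p + 5]) == [0]

    def test_orf_after_orf_is_layout_error(self, fixture_orfs):
        with pytest.raises(LayoutError, match="layout"):
            assemble_operon([fixture_orfs[0], fixture_orfs[1]])

    def test_misplaced_linker_is_layout_error(self, fixture_orfs):
        linker = make_fixture_linker(FixtureSpec(seed=3), length=30)
        with pytest.raises(LayoutError):
            assemble_operon([linker, fixture_orfs[0]])

    def test_chaining_is_associative(self, fixture_orfs, tce_parts):
        """Assembling A-t-B then extending by (t, C) must equal assembling
        A-t-B-t-C in one pass, residue for residue."""
        two = assemble_operon(
            [fixture_orfs[0], tce_parts[0], fixture_orfs[1]]
        )
        extended = assemble_operon(
            list(two.parts) + [tce_parts[1], fixture_orfs[2]]
        )
        direct = assemble_operon(
            [fixture_orfs[0], tce_parts[0], fixture_orfs[1],
             tce_parts[1], fixture_orfs[2]]
        )
        assert str(extended.transcript) == str(direct.transcript)

    def test_linker_between_orf_and_tce(self, fixture_orfs, tce_parts):
        linker = make_fixture_linker(FixtureSpec(seed=3), length=60)
        design = assemble_operon(
            [fixture_orfs[0], linker, tce_parts[0], fixture_orfs[1]]
        )
        report = validate_junction(design, 0)
        assert report.intergenic_distance == -1
        # the linker lengthens the upstream cistron by exactly its length
        plain = assemble_operon(
            [fixture_orfs[0], tce_parts[0], fixture_orfs[1]]
        )
        assert (design.junctions[0].upstream_run_nt
                - plain.junctions[0].upstream_run_nt) == 60


class TestJunctionValidation:
    def test_uraug_junction_reports_minus_one_optimal(
        self, fixture_orfs, tce_parts
    ):
        design = assemble_operon(
            [fixture_orfs[0], tce_parts[0], fixture_orfs[1]]
        )
        report = validate_junction(design, 0)
        assert report.intergenic_distance == -1
        assert report.distance_class == "optimal"
        assert report.structure_check.passed
        assert report.warnings == ()

    @pytest.mark.parametrize(
        "distance, expected",
        [(-1, "optimal"), (0, "optimal"), (5, "optimal"),
         (6, "degrading"), (8, "degrading"), (14, "degrading"),
         (15, "poor"), (30, "poor")],
    )
    def test_distance_classes(self, distance, expected):
        assert distance_class(distance) == expected

    def test_distance_classes_exhaustive_thresholds(self):
        for d in range(-1, 31):
            expected = ("optimal" if d <= 5
                        else "degrading" if d <= 14 else "poor")
            assert distance_class(d) == expected
        with pytest.raises(SeqValidationError):
            distance_class(-2)

    def test_long_linker_warnings(self, fixture_orfs, tce_parts):
        fx = FixtureSpec(seed=11)
        long_linker = make_fixture_linker(fx, name="long", length=3501 // 3 * 3)
        design = assemble_operon(
            [fixture_orfs[0], long_linker, tce_parts[0], fixture_orfs[1]]
        )
        report = validate_junction(design, 0)
        assert any("converged" in w for w in report.warnings)
        mid_linker = make_fixture_linker(fx, name="mid", length=1200)
        design2 = assemble_operon(
            [fixture_orfs[0], mid_linker, tce_parts[0], fixture_orfs[1]]
        )
        report2 = validate_junction(design2, 0)
        assert any("decays" in w for w in report2.warnings)
        assert not any("converged" in w for w in report2.warnings)

    def test_missing_junction_index(self, fixture_orfs, tce_parts):
        design = assemble_operon(
            [fixture_orfs[0], tce_parts[0], fixture_orfs[1]]
        )
        with pytest.raises(LayoutError, match="no junction"):
            validate_junction(design, 5)


class TestGateLayouts:
    def _switches(self, n):
        return [
            make_fixture_switch(name=f"sw{i}", trigger=chr(65 + i), seed=i)
            for i in range(n)
        ]

    def test_or_gate_two_switches(self, fixture_orfs):
        design = gate_layout("OR", self._switches(2), [fixture_orfs[0]])
        switches = [r for r in design.annotations
                    if r.label.startswith("switch:")]
        assert len(switches) == 2
        assert all(r.start % 3 == 0 for r in switches)
        table = design.metadata["truth_table"]
        assert table[()] == "OFF"
        assert table[("A",)] == table[("B",)] == table[("A", "B")] == "ON"

    def test_or_gate_six_switches(self, fixture_orfs):
        design = gate_layout("OR", self._switches(6), [fixture_orfs[0]])
        assert len([r for r in design.annotations
                    if r.label.startswith("switch:")]) == 6

    def test_or_gate_seven_switches_unsupported(self, fixture_orfs):
        with pytest.raises(LayoutError, match="2-6"):
            gate_layout("OR", self._switches(7), [fixture_orfs[0]])

    def test_and_gate_truth_table(self, fixture_orfs):
        sw = Part("and_sw", "switch",
                  make_fixture_switch(seed=9).sequence,
                  metadata={"inputs": ["A", "B"]})
        design = gate_layout("AND", [sw], [fixture_orfs[0]])
        table = design.metadata["truth_table"]
        assert table[("A", "B")] == "ON"
        assert table[()] == table[("A",)] == table[("B",)] == "OFF"

    def test_nand_gate_truth_table(self, fixture_orfs):
        design = gate_layout("NAND", self._switches(2), [fixture_orfs[0]])
        table = design.metadata["truth_table"]
        assert table[("A", "B")] == "OFF"
        assert table[()] == table[("A",)] == table[("B",)] == "ON"

    def test_nimply_gate_truth_table(self, fixture_orfs):
        sw = Part("ni_sw", "switch",
                  make_fixture_switch(seed=9).sequence,
                  metadata={"inputs": ["A", "B"]})
        design = gate_layout("NIMPLY", [sw], [fixture_orfs[0]])
        table = design.metadata["truth_table"]
        assert table[("A",)] == "ON"
        assert table[()] == table[("B",)] == table[("A", "B")] == "OFF"

    def test_multi_output_gate_chains_syntces(self, fixture_orfs, tce_parts):
        design = gate_layout(
            "OR", self._switches(2), fixture_orfs[:2], tce_parts[:1]
        )
        assert len(design.junctions) == 1
        assert len(design.orf_regions()) == 2

    def test_multi_output_gate_designs_default_syntces(self, fixture_orfs):
        design = gate_layout("OR", self._switches(2), fixture_orfs[:2])
        assert len(design.junctions) == 1
        assert validate_junction(design, 0).structure_check.passed

    def test_out_of_frame_switch_rejected(self, fixture_orfs):
        bad = Part("bad_sw", "switch", "ACGUA")  # 5 nt
        good = make_fixture_switch(seed=2)
        with pytest.raises(LayoutError, match="frame"):
            gate_layout("OR", [bad, good], [fixture_orfs[0]])


class TestInternalRbsScan:
    def test_embedded_sd_site_found(self, model, config):
        linker = ("CUCUCUCAUCUCUCUCUCU" + "AGAGGAGA" + "CUCAU"
                  + "AUG" + "CUCUCUCUCCUC")
        hits = scan_internal_rbs(linker, None, model, None, config)
        assert len(hits) == 1
        pos, score = hits[0]
        assert linker[pos:pos + 3] == "AUG"
        assert score.total < config.internal_rbs_threshold

    def test_clean_fixture_linker_has_no_hits(self, model, config):
        linker = make_fixture_linker(FixtureSpec(seed=13), length=300)
        assert scan_internal_rbs(str(linker.sequence), None, model,
                                 None, config) == []

    def test_hit_count_monotone_in_threshold(self, model, config):
        linker = ("CUCUCUCAUCUCUCUCUCU" + "AGAGGAGA" + "CUCAU"
                  + "AUGCUC" + "GAGGA" + "GUCUC" + "GUG" + "CUCCUC")
        counts = [
            len(scan_internal_rbs(linker, None, model, thr, config))
            for thr in (-12.0, -6.0, -2.0, 2.0, 8.0)
        ]
        assert counts == sorted(counts)
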