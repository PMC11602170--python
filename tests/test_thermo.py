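"""Thermodynamic layer against independent brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import oracles
from syntce.config import DesignConfig
from syntce.seqcore import NucSeq, Region, SeqValidationError, revcomp, to_rna
from syntce.thermo import (
    asd_duplex_dG,
    default_energy_model,
    enumerate_hairpins,
    hairpin_structure_check,
    local_structure_score,
    rbs_strength,
    spacing_penalty,
    stem_dG,
)

ANTI_SD = "ACCUCCUUA"

stems = st.text(alphabet="ACGU", min_size=2, max_size=10)


class TestEnergyModel:
    def test_covers_all_36_stacks(self, model):
        assert len(model.stack_table) == 36

    def test_rotational_symmetry(self, model):
        for key, dg in model.stack_table.items():
            top, bot = key.split("/")
            assert model.stack_table[f"{bot[::-1]}/{top[::-1]}"] == dg

    def test_hairpin_penalties_positive_and_eventually_increasing(self, model):
        values = [model.hairpin_loop(n) for n in range(3, 31)]
        assert all(v > 0 for v in values)
        tail = values[6:]  # sizes >= 9
        assert all(b >= a for a, b in zip(tail, tail[1:]))

    def test_loop_below_3_rejected(self, model):
        with pytest.raises(SeqValidationError):
            model.hairpin_loop(2)


# Hand-picked stems spanning compositions, lengths and terminal pairs.
HAND_PICKED_STEMS = [
    "GC", "AU", "GU", "CG", "GCGCGC", "AUAUAU", "GGGGGG", "CCCCCC",
    "ACGU", "GCAU", "AGCU", "GGCC", "UUUAAA", "GACUGA", "CUGACG",
    "GCGAUA", "AUGCAU", "CCGGAA", "UGCAUG", "GCCGGC",
]


class TestStemDG:
    def test_empty_and_single_nt_are_zero(self, model):
        assert stem_dG("", model) == 0.0
        assert stem_dG("G", model) == 0.0

    @pytest.mark.parametrize("stem", HAND_PICKED_STEMS)
    def test_matches_manual_table_summation(self, stem, model):
        assert stem_dG(stem, model) == pytest.approx(
            oracles.stem_dg_by_hand(stem), abs=1e-12
        )

    def test_strong_pairs_beat_weak_pairs(self, model):
        assert stem_dG("GCGCGC", model) < stem_dG("AUAUAU", model)

    @given(stems)
    def test_additivity_of_one_appended_pair(self, s, ):
        """Appending a base pair adds exactly one stack term plus the
        change in terminal corrections."""
        model = default_energy_model()
        extended = s + "G"
        delta = stem_dG(extended, model) - stem_dG(s, model)
        expected = model.stack(s[-1], "G", {"A": "U", "U": "A", "C": "G",
                                            "G": "C"}[s[-1]], "C")
        expected -= model.terminal_penalty(s[-1], {"A": "U", "U": "A",
                                                   "C": "G", "G": "C"}[s[-1]])
        if len(s) == 1:
            expected += model.terminal_penalty(s[0], {"A": "U", "U": "A",
                                                      "C": "G", "G": "C"}[s[0]])
        assert delta == pytest.approx(expected, abs=1e-12)

    @given(stems, st.data())
    def test_strengthening_any_weak_pair_never_raises_energy(self, s, data):
        """Replacing an A-U pair by G-C anywhere in a stem can only
        stabilize it — the strong/weak base-composition trend."""
        model = default_energy_model()
        weak_positions = [i for i, b in enumerate(s) if b in "AU"]
        if not weak_positions:
            return
        i = data.draw(st.sampled_from(weak_positions))
        strong = data.draw(st.sampled_from("GC"))
        mutated = s[:i] + strong + s[i + 1:]
        assert stem_dG(mutated, model) <= stem_dG(s, model) + 1e-12


class TestAsdDuplex:
    def test_perfect_duplex_equals_manual_sum(self, model):
        window_seq = str(revcomp(ANTI_SD))
        dg, region = asd_duplex_dG(
            NucSeq(window_seq), Region(0, len(window_seq)), ANTI_SD, model
        )
        expected = sum(
            oracles.STACKS[(window_seq[k:k + 2],
                            ANTI_SD[::-1][k] + ANTI_SD[::-1][k + 1])]
            for k in range(len(window_seq) - 1)
        )
        assert dg == pytest.approx(expected, abs=1e-12)
        assert (region.start, region.end) == (0, len(window_seq))

    def test_no_pairable_run_returns_zero(self, model):
        # poly-C cannot pair the G-free anti-SD tail at all
        dg, region = asd_duplex_dG(
            NucSeq("CCCCCCCC"), Region(0, 8), ANTI_SD, model
        )
        assert dg == 0.0
        assert len(region) == 0

    def test_window_shift_leaves_energy_unchanged(self, model):
        sd_site = "AGAGGAGA"
        mrna = NucSeq("GCAUCGAUCG" + sd_site + "CAUCGAUCGAUCGAUCGAU")
        dg_tight, _ = asd_duplex_dG(mrna, Region(8, 20), ANTI_SD, model)
        dg_wide, _ = asd_duplex_dG(mrna, Region(0, len(mrna)), ANTI_SD, model)
        assert dg_tight == pytest.approx(dg_wide)

    def test_out_of_bounds_window_rejected(self, model):
        with pytest.raises(SeqValidationError, match="window"):
            asd_duplex_dG(NucSeq("ACGU"), Region(0, 10), ANTI_SD, model)

    def test_equals_brute_force_on_random_windows(self, model):
        rng = np.random.default_rng(2024)
        bases = np.array(list("ACGU"))
        for _ in range(100):
            n = int(rng.integers(9, 31))
            window = "".join(bases[rng.integers(0, 4, n)])
            dg, _ = asd_duplex_dG(NucSeq(window), Region(0, n), ANTI_SD, model)
            assert dg == pytest.approx(
                oracles.duplex_dg_by_enumeration(window, ANTI_SD), abs=1e-12
            )


class TestSpacingPenalty:
    def test_zero_at_optimum(self, config):
        assert spacing_penalty(config.optimal_spacing, config) == 0.0

    def test_monotone_away_from_optimum(self, config):
        assert spacing_penalty(2, config) > spacing_penalty(4, config)
        assert spacing_penalty(9, config) > spacing_penalty(6, config)

    def test_matches_closed_form_for_spacings_0_to_15(self, config):
        for s in range(16):
            assert spacing_penalty(s, config) == pytest.approx(
                oracles.spacing_penalty_closed_form(
                    s, config.optimal_spacing,
                    config.spacing_stiffness_compressed,
                    config.spacing_stiffness_stretched,
                )
            )

    def test_negative_spacing_rejected(self, config):
        with pytest.raises(SeqValidationError):
            spacing_penalty(-1, config)


def _construct(spacer_len: int) -> str:
    # inert C-spacer (C cannot pair the G-free anti-SD tail); the best
    # duplex pairs the GAGGAG core, whose last paired base sits 1 nt
    # before the spacer, so spacing = spacer_len + 1
    return "CUCUCUCUCU" + "AGAGGAGA" + "C" * spacer_len + "AUG" + "GCU"


class TestRbsStrength:
    def test_optimal_construct_has_zero_spacing_penalty(self, model, config):
        mrna = _construct(config.optimal_spacing - 1)
        start = mrna.index("AUG", 10)
        score = rbs_strength(NucSeq(mrna), start, ANTI_SD, model, config)
        assert score.dG_spacing == 0.0
        assert score.spacing == config.optimal_spacing
        # the duplex covers the SD site and its energy is the brute-force one
        assert score.dG_rRNA_mRNA == pytest.approx(
            oracles.duplex_dg_by_enumeration(mrna[:start], ANTI_SD), abs=1e-12
        )

    def test_stretched_spacer_same_duplex_worse_total(self, model, config):
        s5 = rbs_strength(NucSeq(_construct(4)), _construct(4).index("AUG", 10),
                          ANTI_SD, model, config)
        mrna12 = _construct(11)
        s12 = rbs_strength(NucSeq(mrna12), mrna12.index("AUG", 10),
                           ANTI_SD, model, config)
        assert s12.dG_rRNA_mRNA == pytest.approx(s5.dG_rRNA_mRNA)
        assert s12.total > s5.total

    def test_locality_far_upstream_context_ignored(self, model, config):
        mrna = _construct(4)
        start = mrna.index("AUG", 10)
        prefix = "GCAU" * 13  # 52 nt, well outside the 20-nt search window
        shifted = rbs_strength(NucSeq(prefix + mrna), len(prefix) + start,
                               ANTI_SD, model, config)
        base = rbs_strength(NucSeq(mrna), start, ANTI_SD, model, config)
        assert shifted.total == pytest.approx(base.total)
        assert shifted.spacing == base.spacing

    def test_non_aug_position_rejected(self, model, config):
        with pytest.raises(SeqValidationError, match="AUG"):
            rbs_strength(NucSeq("AGAGGAGACCCCCGGG"), 10, ANTI_SD, model, config)

    def test_total_decomposes_exactly(self, model, config):
        for spacer in range(0, 12):
            mrna = _construct(spacer)
            score = rbs_strength(NucSeq(mrna), mrna.index("AUG", 10),
                                 ANTI_SD, model, config)
            assert score.total == score.dG_rRNA_mRNA + score.dG_spacing

    def test_no_duplex_gets_maximal_spacing_penalty(self, model, config):
        mrna = "CACACACACACACACACAC" + "AUG" + "GCA"
        score = rbs_strength(NucSeq(mrna), 19, ANTI_SD, model, config)
        assert score.dG_rRNA_mRNA == 0.0
        assert score.total == pytest.approx(
            spacing_penalty(config.max_spacing, config)
        )


LOOP12 = "ACAGAGGAGAUC"


class TestHairpinStructureCheck:
    def test_designed_gc_stem_passes_and_matches_components(self, model, config):
        stem5 = "GCCGCG"
        window = stem5 + LOOP12 + str(revcomp(stem5))
        result = hairpin_structure_check(window, 6, 12, model, config)
        assert result.passed
        assert result.designed_dG == pytest.approx(
            oracles.stem_dg_by_hand(stem5) + oracles.loop_penalty(12)
        )

    def test_enumeration_agrees_with_brute_force(self, model):
        rng = np.random.default_rng(7)
        bases = np.array(list("ACGU"))
        for _ in range(20):
            window = "".join(bases[rng.integers(0, 4, 24)])
            ours = {(i, j, L): dg for i, j, L, dg in
                    enumerate_hairpins(window, model)}
            assert ours == pytest.approx(
                oracles.hairpins_by_enumeration(window)
            )

    def test_shifted_registration_of_same_hairpin_not_competing(
        self, model, config
    ):
        """A quasi-palindromic stem's minimum-energy fold is the designed
        hairpin extended by one pair; with the RBS span supplied it still
        passes, without it the strict minimum rule rejects it."""
        from syntce.seqcore import Region

        window = "GGGGGG" + LOOP12 + "CCCCCC"
        strict = hairpin_structure_check(window, 6, 12, model, config)
        assert not strict.passed
        relaxed = hairpin_structure_check(window, 6, 12, model, config,
                                          rbs=Region(8, 16))
        assert relaxed.passed

    def test_no_stem_first_generation_fails(self, model, config):
        # stem length 0: only the loop penalty remains, far above threshold
        result = hairpin_structure_check(LOOP12, 0, 12, model, config)
        assert not result.passed
        assert result.designed_dG == pytest.approx(oracles.loop_penalty(12))
        assert result.designed_dG > config.structure_threshold

    def test_scrambled_stem3_not_formable(self, model, config):
        stem5 = "GCCGCG"
        window = stem5 + LOOP12 + "AAAAAA"  # stem3 cannot pair stem5
        result = hairpin_structure_check(window, 6, 12, model, config)
        assert not result.passed
        assert result.designed_dG == math.inf
        assert "not formable" in result.reason

    def test_length_mismatch_rejected(self, model, config):
        with pytest.raises(SeqValidationError, match="length"):
            hairpin_structure_check("ACGU", 6, 12, model, config)


class TestLocalStructureScore:
    def test_unstructured_window_scores_zero(self, model):
        mrna = "CACACACACACACACA" + "AUG" + "ACACACACACACA"
        assert local_structure_score(mrna, 16, model) == 0.0

    def test_hairpin_near_start_scores_negative(self, model):
        # a strong 14-nt hairpin immediately upstream of the start codon,
        # fully inside the +-15 nt scan window
        mrna = "CACACACACACACA" + "GCCGC" + "GAAA" + "GCGGC" + "AUG" + "ACACA"
        assert local_structure_score(mrna, 28, model) < -3.0

    def test_fold_engine_plug_in_is_used(self, model):
        calls = []

        def engine(seq):
            calls.append(seq)
            return "." * len(seq), -12.5

        score = local_structure_score("GCGCGCAUGGCGCGC", 6, model,
                                      fold_engine=engine)
        assert score == -12.5
        assert calls  # the plug-in actually ran


class TestViennaRnaTrendCrossCheck:
    """Independent folding engine agrees on stability ordering and sign."""

    def test_designed_hairpins_rank_like_rnafold(self):
        import RNA

        windows = [
            stem5 + LOOP12 + str(revcomp(NucSeq(stem5)))
            for stem5 in ("GCCGCG", "GCAUGC", "AUAUAU")
        ]
        ours = [
            hairpin_structure_check(w, 6, 12).designed_dG for w in windows
        ]
        theirs = [RNA.fold(w)[1] for w in windows]
        assert sorted(range(3), key=lambda i: ours[i]) == sorted(
            range(3), key=lambda i: theirs[i]
        )
        assert ours[0] < 0 and theirs[0] < 0
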