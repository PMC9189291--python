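"""Construct bookkeeping: L arithmetic, controls, library generation, logo."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from forceprofile.constructs import (
    DEFAULT_REPEAT_BOUNDARIES,
    SECM_AP_SEQUENCE,
    ArrestPeptide,
    ConstructSpec,
    RepeatAlignment,
    build_construct,
    distance_to_ptc,
    generate_library,
    logo_information,
    make_controls,
    repeats_spanned,
)


class TestArrestPeptide:
    def test_default_is_secm(self):
        ap = ArrestPeptide()
        assert ap.sequence == SECM_AP_SEQUENCE
        assert ap.length == 17
        assert ap.is_active

    def test_proline_to_ala_inactivates(self):
        mutated = ArrestPeptide().proline_to_ala()
        assert mutated.sequence.endswith("A")
        assert not mutated.is_active
        assert mutated.length == 17


class TestConstructArithmetic:
    @pytest.mark.parametrize(
        "domain, linker, expected_L",
        [(239, 23, 279), (0, 0, 17), (199, 8, 224), (164, 8, 189)],
    )
    def test_L(self, domain, linker, expected_L):
        spec = ConstructSpec("c", domain, linker)
        assert spec.L == expected_L
        assert build_construct(spec).L == expected_L

    @pytest.mark.parametrize("linker, expected", [(23, 40), (8, 25), (0, 17)])
    def test_distance_to_ptc(self, linker, expected):
        c = build_construct(ConstructSpec("c", 239, linker))
        assert distance_to_ptc(c) == expected
        assert c.L - c.distance_to_ptc == 239

    def test_tail_separates_chains_by_23(self, full_construct):
        assert full_construct.full_length - full_construct.arrested_length == 23

    def test_short_construct_carries_n_terminal_segment(self):
        short = build_construct(ConstructSpec("s", 50, 8))  # L = 75 <= 110
        long = build_construct(ConstructSpec("l", 239, 8))
        assert short.spec.n_term_visualization
        assert not long.spec.n_term_visualization
        # 154-residue segment present only in the short chain
        assert short.arrested_length == 154 + 4 + 50 + 8 + 17
        assert long.arrested_length == 4 + 239 + 8 + 17

    def test_domain_longer_than_sequence_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            build_construct(ConstructSpec("c", 10, 5), domain_sequence="AAA")

    def test_negative_lengths_rejected(self):
        with pytest.raises(ValueError):
            ConstructSpec("c", -1, 5)
        with pytest.raises(ValueError):
            ConstructSpec("c", 5, -1)


class TestControls:
    def test_full_length_control_ap_ends_in_ala(self):
        fl, _ = make_controls(ConstructSpec("L279", 239, 23))
        assert fl.ap.sequence.endswith("A")
        assert fl.control_kind == "full_length_control"

    def test_arrest_control_has_no_tail(self):
        _, ac = make_controls(ConstructSpec("L279", 239, 23))
        c = build_construct(ac)
        assert c.full_length == c.arrested_length

    def test_controls_keep_L(self):
        spec = ConstructSpec("L279", 239, 23)
        fl, ac = make_controls(spec)
        assert fl.L == ac.L == spec.L == 279

    def test_controls_of_controls_rejected(self):
        fl, _ = make_controls(ConstructSpec("L279", 239, 23))
        with pytest.raises(ValueError):
            make_controls(fl)


class TestLibrary:
    def test_default_library_span(self):
        lib = generate_library(239)
        Ls = [s.L for s in lib]
        assert 295 in Ls  # linker 39, full domain
        assert 264 in Ls  # linker 8, full domain
        assert 224 in Ls and 189 in Ls  # the truncation-peak constructs

    def test_sorted_decreasing_unique(self):
        Ls = [s.L for s in generate_library(239)]
        assert all(a > b for a, b in zip(Ls, Ls[1:]))

    def test_truncation_stage_steps_by_trunc_step(self):
        lib = generate_library(239)
        trunc = sorted(
            (s.L for s in lib if s.linker_length == 8 and s.domain_length < 239),
            reverse=True,
        )
        assert all(a - b == 5 for a, b in zip(trunc, trunc[1:]))

    def test_regeneration_is_identical(self):
        assert generate_library(239) == generate_library(239)

    def test_empty_library_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            generate_library(239, L_min=300)

    def test_invariants_hold_for_every_member(self):
        for spec in generate_library(239):
            c = build_construct(spec)
            assert c.full_length - c.arrested_length == 23
            assert c.L - c.distance_to_ptc == spec.domain_length


class TestRepeatsSpanned:
    @pytest.mark.parametrize(
        "domain_length, expected",
        [(239, (7, 0)), (199, (5, 19)), (164, (4, 17)), (0, (0, 0))],
    )
    def test_examples(self, domain_length, expected):
        span = repeats_spanned(domain_length)
        assert (span.n_full_repeats, span.tail_length) == expected

    def test_agrees_with_brute_force_scan(self):
        b = DEFAULT_REPEAT_BOUNDARIES
        for d in range(0, 240):
            n = 0
            while n + 1 < len(b) and b[n + 1] <= d:
                n += 1
            span = repeats_spanned(d)
            assert span.n_full_repeats == n
            assert span.tail_length == d - b[n]

    def test_bad_boundaries_rejected(self):
        with pytest.raises(ValueError):
            repeats_spanned(10, [0, 5, 3, 20])
        with pytest.raises(ValueError):
            repeats_spanned(300, DEFAULT_REPEAT_BOUNDARIES)


class TestLogo:
    def test_fully_conserved_column(self):
        res = logo_information(RepeatAlignment(["A"] * 7))
        assert res.information[0] == pytest.approx(math.log2(20), abs=1e-12)

    def test_uniform_column_has_zero_bits(self):
        res = logo_information(RepeatAlignment(list("ACDEFGHIKLMNPQRSTVWY")))
        assert res.information[0] == pytest.approx(0.0, abs=1e-12)

    def test_two_state_column(self):
        res = logo_information(RepeatAlignment(["A", "A", "G", "G"]))
        assert res.information[0] == pytest.approx(math.log2(20) - 1.0, abs=1e-12)

    def test_gaps_excluded_from_counts(self):
        with_gaps = logo_information(RepeatAlignment(["A", "A", "-", "-"]))
        without = logo_information(RepeatAlignment(["A", "A"]))
        assert with_gaps.information[0] == pytest.approx(without.information[0])

    def test_all_gap_column_flagged(self):
        res = logo_information(RepeatAlignment(["-A", ".A"]))
        assert res.all_gap[0] and not res.all_gap[1]
        assert np.isnan(res.information[0])

    @given(
        st.lists(
            st.text(alphabet="ACDG-", min_size=6, max_size=6), min_size=2, max_size=8
        )
    )
    def test_row_permutation_invariance_and_bounds(self, rows):
        aln = RepeatAlignment(rows)
        res = logo_information(aln)
        rev = logo_information(RepeatAlignment(rows[::-1]))
        np.testing.assert_allclose(res.information, rev.information, equal_nan=True)
        finite = res.information[~np.isnan(res.information)]
        assert np.all(finite >= 0) and np.all(finite <= math.log2(20) + 1e-12)
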