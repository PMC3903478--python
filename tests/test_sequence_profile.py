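"""Composition, acid-excess reconstruction, alignment and motif calls."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from _oracles import dp_align_score
from lyase_profile.errors import ConfigurationError, MalformedInputError
from lyase_profile.panel_data import REFERENCE_PANEL
from lyase_profile.sequence_profile import (
    AnchorReference,
    acid_excess_from_percentages,
    classify_family,
    composition,
    global_align,
    load_default_anchors,
    locate_mio_motif,
)
from lyase_profile.structure_io import ChainSequence
from lyase_profile.synthetic_data import generate_sequence

seq_strategy = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=200)


def make_seq(residues: str, source_id: str = "q") -> ChainSequence:
    return ChainSequence(source_id=source_id, residues=residues)


class TestComposition:
    def test_no_ionizable_residues(self):
        prof = composition(make_seq("AAAA"))
        assert prof.chain_length == 4
        assert prof.acid_excess == 0
        assert prof.cys_count == 0

    def test_direct_counts(self):
        prof = composition(make_seq("DDEEKR"))
        assert (prof.counts["D"], prof.counts["E"]) == (2, 2)
        assert (prof.counts["K"], prof.counts["R"]) == (1, 1)
        assert prof.acid_excess == 2

    def test_empty_sequence_rejected(self):
        with pytest.raises(MalformedInputError):
            composition(ChainSequence(source_id="x", residues=""))

    @given(seq_strategy, st.randoms(use_true_random=False))
    def test_permutation_invariance(self, residues, rnd):
        shuffled = list(residues)
        rnd.shuffle(shuffled)
        a = composition(make_seq(residues))
        b = composition(make_seq("".join(shuffled)))
        assert a.counts == b.counts
        assert a.acid_excess == b.acid_excess

    @given(seq_strategy)
    def test_counts_sum_to_length(self, residues):
        prof = composition(make_seq(residues))
        assert sum(prof.counts.values()) == prof.chain_length == len(residues)


class TestAcidExcessReconstruction:
    @pytest.mark.parametrize(
        "row", [r for r in REFERENCE_PANEL if r.acid_excess_consistent], ids=lambda r: r.label
    )
    def test_reconstructs_published_rows(self, row):
        assert acid_excess_from_percentages(
            row.chain_length, row.asp_pct, row.glu_pct, row.lys_pct, row.arg_pct
        ) == row.acid_excess

    def test_zero_percentages(self):
        assert acid_excess_from_percentages(100, 0, 0, 0, 0) == 0

    def test_ties_round_away_from_zero(self):
        assert acid_excess_from_percentages(100, 2.5, 0, 0, 0) == 3
        assert acid_excess_from_percentages(100, 0, 0, 2.5, 0) == -3

    @given(seq_strategy)
    def test_rounding_error_bound(self, residues):
        """Reconstruction from 1-decimal percentages stays within the
        worst-case rounding bound ceil(0.2% of length)."""
        prof = composition(make_seq(residues))
        recon = acid_excess_from_percentages(
            prof.chain_length,
            prof.rounded_percentage("D"),
            prof.rounded_percentage("E"),
            prof.rounded_percentage("K"),
            prof.rounded_percentage("R"),
        )
        bound = math.ceil(prof.chain_length * 0.2 / 100)
        assert abs(recon - prof.acid_excess) <= bound


class TestGlobalAlign:
    def test_identical_sequences(self):
        res = global_align(make_seq("DEKAY"), make_seq("DEKAY"))
        assert res.percent_identity == 100.0
        assert res.query_to_ref == {i: i for i in range(1, 6)}

    def test_small_pair_against_enumerated_optimum(self):
        res = global_align(make_seq("DEK"), make_seq("DGK"))
        assert res.percent_identity == pytest.approx(100 * 2 / 3)
        assert res.score == dp_align_score("DEK", "DGK") == 9.0

    def test_degapped_alignment_reproduces_inputs(self):
        res = global_align(make_seq("DEKAYWQ"), make_seq("DAY"))
        assert res.aligned_query.replace("-", "") == "DEKAYWQ"
        assert res.aligned_reference.replace("-", "") == "DAY"

    @pytest.mark.parametrize("seed", range(25))
    def test_score_matches_independent_dp_oracle(self, seed):
        rng = np.random.default_rng(1000 + seed)
        alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        a = "".join(rng.choice(alphabet, size=rng.integers(1, 9)))
        b = "".join(rng.choice(alphabet, size=rng.integers(1, 9)))
        res = global_align(make_seq(a), make_seq(b))
        assert res.score == pytest.approx(dp_align_score(a, b))

    def test_unknown_matrix_lists_available(self):
        with pytest.raises(ConfigurationError, match="BLOSUM"):
            global_align(make_seq("DEK"), make_seq("DEK"), matrix="NOSUCH")


@pytest.fixture(scope="module")
def anchors():
    return load_default_anchors()


class TestMotifCalls:
    def test_identity_query_finds_annotated_mio(self, anchors):
        anchor = anchors[0]
        call = locate_mio_motif(anchor.sequence, anchor)
        assert call.mio_start == anchor.mio_start

    def test_truncated_query_shifts_mio(self, anchors):
        anchor = anchors[0]
        query = make_seq(anchor.sequence.residues[10:])
        call = locate_mio_motif(query, anchor)
        assert call.mio_start == anchor.mio_start - 10

    def test_alignment_anchoring_beats_leftmost_scan(self, anchors):
        """A decoy ASG earlier in the sequence must not be reported."""
        anchor = anchors[0]
        residues = list(anchor.sequence.residues)
        assert "".join(residues[20:23]) != "ASG"
        residues[20:23] = list("ASG")
        query = make_seq("".join(residues))
        call = locate_mio_motif(query, anchor)
        assert call.mio_start == anchor.mio_start  # not 21

    def test_mutated_mio_site_reports_absent(self, anchors):
        anchor = anchors[0]
        residues = list(anchor.sequence.residues)
        residues[anchor.mio_start] = "A"  # the Ser of ASG -> A
        call = locate_mio_motif(make_seq("".join(residues)), anchor)
        assert call.mio_start is None

    def test_planted_motif_in_generated_sequence(self, anchors):
        anchor = anchors[0]
        # mutate a copy of the anchor, keeping the ASG plant site intact
        rng = np.random.default_rng(5)
        residues = list(anchor.sequence.residues)
        for i in rng.choice(len(residues), size=20, replace=False):
            if not (anchor.mio_start - 3 <= i + 1 <= anchor.mio_start + 3):
                residues[i] = "ACDEFGHIKLMNPQRTVWY"[rng.integers(19)]
        call = locate_mio_motif(make_seq("".join(residues)), anchor)
        assert call.mio_start == anchor.mio_start


class TestClassifyFamily:
    def test_anchor_self_classification(self, anchors):
        for anchor in anchors:
            call = classify_family(anchor.sequence, anchors)
            assert call.family == anchor.family
            assert call.anchor_identity == 100.0

    @pytest.mark.parametrize("dyad,family", [("FL", "PAL"), ("SH", "HAL"),
                                             ("HL", "TAL"), ("HQ", "TAL"),
                                             ("GG", "ambiguous")])
    def test_planted_dyads(self, anchors, dyad, family):
        base = anchors[0]
        residues = list(base.sequence.residues)
        p1, p2 = base.dyad_positions
        residues[p1 - 1], residues[p2 - 1] = dyad[0], dyad[1]
        call = classify_family(make_seq("".join(residues)), anchors)
        assert call.selectivity_pair == dyad
        assert call.family == family

    def test_unrelated_sequence_is_non_mio(self, anchors):
        seq, _ = generate_sequence(length=250, seed=99)
        call = classify_family(seq, anchors)
        assert call.family == "non-MIO"
        assert call.mio_start is None

    def test_empty_anchor_set_rejected(self):
        with pytest.raises(ConfigurationError):
            classify_family(make_seq("DEK"), [])

    def test_low_identity_threshold_configurable(self, anchors):
        anchor = anchors[0]
        call = classify_family(anchor.sequence, anchors, identity_threshold=100.0)
        assert call.family == anchor.family  # identity is exactly 100

    def test_generated_hal_like_sequence(self, anchors):
        """A synthetic sequence carrying ASG and an SH dyad anchors as HAL."""
        base = anchors[1]  # PAL anchor backbone
        residues = list(base.sequence.residues)
        p1, p2 = base.dyad_positions
        residues[p1 - 1], residues[p2 - 1] = "S", "H"
        call = classify_family(make_seq("".join(residues)), anchors)
        assert call.family == "HAL"
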