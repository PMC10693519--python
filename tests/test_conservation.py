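"""Per-column conservation scoring, domain labelling, anchored coordinates."""

import numpy as np
import pytest

from seizurescope import (
    ConservationModel,
    anchor_coordinates,
    label_domains,
    score_pair_columns,
    summarize_segments,
)
from seizurescope.conservation import ConservationResults, choose_reference_subunit


class TestScorePairColumns:
    def test_identity_sequence_gives_diagonal_values(
        self, alignment_factory, custom_matrix
    ):
        aln = alignment_factory("ACG", {"mouse": "ACG"})
        track = score_pair_columns(aln, aln.non_human_ids[0], custom_matrix)
        expected = [custom_matrix.score(c, c) for c in "ACG"]
        np.testing.assert_allclose(track.scores, expected)

    def test_offset_gaps_score_as_indels(self, alignment_factory, custom_matrix):
        # columns: (A,A) match, (C,-) indel, (-,C) indel, (G,G) match
        aln = alignment_factory("AC-G", {"mouse": "A-CG"})
        track = score_pair_columns(aln, aln.non_human_ids[0], custom_matrix)
        expected = [
            custom_matrix.score("A", "A"),
            -0.5,
            -0.5,
            custom_matrix.score("G", "G"),
        ]
        np.testing.assert_allclose(track.scores, expected)

    def test_dual_gap_scores_zero(self, alignment_factory, custom_matrix):
        aln = alignment_factory("A-", {"mouse": "--"})
        track = score_pair_columns(aln, aln.non_human_ids[0], custom_matrix)
        np.testing.assert_allclose(track.scores, [-0.5, 0.0])

    def test_every_column_is_table_value_or_gap_score(
        self, alignment_factory, custom_matrix
    ):
        aln = alignment_factory("ACDEF-GHIK", {"rat": "A-DEFWG-IK"})
        track = score_pair_columns(aln, aln.non_human_ids[0], custom_matrix)
        assert track.n_columns == aln.n_columns
        table_vals = set(np.round(custom_matrix.normalized_scores.ravel(), 12))
        for s in track.scores:
            assert round(s, 12) in table_vals or s in (-0.5, 0.0)

    def test_unknown_character_reports_column(
        self, alignment_factory, custom_matrix
    ):
        aln = alignment_factory("ACG", {"rat": "AXG"})
        with pytest.raises(ValueError, match="column 2"):
            score_pair_columns(aln, aln.non_human_ids[0], custom_matrix)

    def test_scoring_human_against_itself_rejected(
        self, alignment_factory, custom_matrix
    ):
        aln = alignment_factory("ACG", {"rat": "ACG"})
        with pytest.raises(ValueError, match="reference against itself"):
            score_pair_columns(aln, aln.human_reference_id, custom_matrix)

    def test_self_score_mean_matches_composition_closed_form(
        self, alignment_factory, custom_matrix
    ):
        # scoring a sequence against an identical copy: the mean equals the
        # mean of normalized diagonal values over the residue composition
        seq = "AARRNNDDCCWWYYVVLLII"
        aln = alignment_factory(seq, {"rat": seq})
        track = score_pair_columns(aln, aln.non_human_ids[0], custom_matrix)
        closed_form = np.mean([custom_matrix.score(c, c) for c in seq])
        assert track.mean_score() == pytest.approx(closed_form, abs=1e-12)


class TestLabelDomains:
    def test_all_columns_ecd_when_boundary_at_end(
        self, alignment_factory, annotation_factory
    ):
        aln = alignment_factory("CADGE", {"rat": "CADGE"})
        ann = annotation_factory("SUB1", ecd_end=5, anchor=1)
        assert label_domains(aln, ann) == ["ECD"] * 5

    def test_gap_column_inherits_preceding_region(
        self, alignment_factory, annotation_factory
    ):
        # human row C A - G D with ECD ending at residue 2: the gap column
        # (3) inherits ECD from residue 2; columns 4-5 are non-ECD
        aln = alignment_factory("CA-GD", {"rat": "CAAGD"})
        ann = annotation_factory("SUB1", ecd_end=2, anchor=1)
        assert label_domains(aln, ann) == ["ECD", "ECD", "ECD", "non-ECD", "non-ECD"]

    def test_boundary_past_sequence_end_rejected(
        self, alignment_factory, annotation_factory
    ):
        aln = alignment_factory("CADG", {"rat": "CADG"})
        ann = annotation_factory("SUB1", ecd_end=9, anchor=1)
        with pytest.raises(ValueError, match="exceeds human sequence length"):
            label_domains(aln, ann)

    def test_nonpositive_boundary_rejected(self, annotation_factory):
        with pytest.raises(ValueError, match="ecd_end"):
            annotation_factory("SUB1", ecd_end=0, anchor=0)

    def test_anchor_must_be_cysteine(self, alignment_factory, annotation_factory):
        aln = alignment_factory("AADG", {"rat": "AADG"})
        ann = annotation_factory("SUB1", ecd_end=4, anchor=1)
        with pytest.raises(ValueError, match="expected cysteine"):
            label_domains(aln, ann)


class TestAnchorCoordinates:
    def _aln_with_anchor_at(self, factory, n_leading_gapped_cols, subunit):
        # human: leading residues, then the anchor C; shifting the anchor
        # column by padding alignment columns before it
        pad = "A" * n_leading_gapped_cols
        seq = pad + "C" + "DEFG"
        return factory(seq, {"rat": seq}, subunit_id=subunit)

    def test_offsets_align_all_anchor_columns(
        self, alignment_factory, annotation_factory
    ):
        alns, anns = {}, {}
        anchors = {"S1": 15, "S2": 5, "S3": 25}
        for sub, lead in anchors.items():
            alns[sub] = self._aln_with_anchor_at(alignment_factory, lead, sub)
            anns[sub] = annotation_factory(sub, ecd_end=lead + 2, anchor=lead + 1)
        cmap = anchor_coordinates(alns, anns, "S1")
        anchored = {
            sub: alns[sub].column_of_human_position(anns[sub].anchor_residue)
            + cmap.ecd_offset[sub]
            for sub in alns
        }
        assert len(set(anchored.values())) == 1
        assert anchored["S1"] == 16  # reference keeps identity numbering

    def test_reference_offset_is_zero(self, alignment_factory, annotation_factory):
        aln = self._aln_with_anchor_at(alignment_factory, 3, "S1")
        ann = annotation_factory("S1", ecd_end=5, anchor=4)
        cmap = anchor_coordinates({"S1": aln}, {"S1": ann}, "S1")
        assert cmap.ecd_offset["S1"] == 0

    def test_offset_sign_follows_reference_minus_own(
        self, alignment_factory, annotation_factory
    ):
        alns = {
            "R": self._aln_with_anchor_at(alignment_factory, 10, "R"),
            "O": self._aln_with_anchor_at(alignment_factory, 4, "O"),
        }
        anns = {
            "R": annotation_factory("R", ecd_end=12, anchor=11),
            "O": annotation_factory("O", ecd_end=6, anchor=5),
        }
        cmap = anchor_coordinates(alns, anns, "R")
        assert cmap.ecd_offset["O"] == (11 - 5)

    def test_missing_reference_rejected(self, alignment_factory, annotation_factory):
        aln = self._aln_with_anchor_at(alignment_factory, 2, "S1")
        ann = annotation_factory("S1", ecd_end=4, anchor=3)
        with pytest.raises(ValueError, match="reference subunit"):
            anchor_coordinates({"S1": aln}, {"S1": ann}, "MISSING")

    def test_longest_human_sequence_chosen_as_fallback(self, alignment_factory):
        alns = {
            "SHORT": alignment_factory("CAD", {"rat": "CAD"}, subunit_id="SHORT"),
            "LONG": alignment_factory("CADEFG", {"rat": "CADEFG"}, subunit_id="LONG"),
        }
        assert choose_reference_subunit(alns) == "LONG"


class TestSummarizeSegments:
    def test_identity_segment_mean_is_diagonal_mean(
        self, alignment_factory, annotation_factory, custom_matrix
    ):
        seq = "CWADGKLMNP"
        aln = alignment_factory(seq, {"rat": seq})
        ann = annotation_factory(
            "SUB1", ecd_end=10, anchor=1, segments={"A": (2, 4), "TM1": (5, 8)}
        )
        track = score_pair_columns(aln, aln.non_human_ids[0], custom_matrix)
        out = summarize_segments(track, aln, ann)
        assert list(out["segment"]) == ["A", "TM1"]  # canonical ordering
        expect_a = np.mean([custom_matrix.score(c, c) for c in seq[1:4]])
        assert out.loc[0, "mean_score"] == pytest.approx(expect_a)
        assert out.loc[0, "n_columns"] == 3

    def test_fully_deleted_segment_scores_indel(
        self, alignment_factory, annotation_factory, custom_matrix
    ):
        aln = alignment_factory("CWADGK", {"rat": "CW---K"})
        ann = annotation_factory("SUB1", ecd_end=6, anchor=1, segments={"B": (3, 5)})
        track = score_pair_columns(aln, aln.non_human_ids[0], custom_matrix)
        out = summarize_segments(track, aln, ann)
        assert out.loc[0, "mean_score"] == pytest.approx(-0.5)

    def test_invalid_segment_span_rejected(self, annotation_factory):
        with pytest.raises(ValueError, match="invalid span"):
            annotation_factory("SUB1", ecd_end=6, anchor=1, segments={"A": (5, 3)})


class TestModelAndPlots:
    @pytest.fixture()
    def fitted(self, alignment_factory, annotation_factory, custom_matrix):
        seq = "CWADGKCLMN"
        aln = alignment_factory(seq, {"rat": seq, "mouse": "CWADGKCLMD"})
        ann = annotation_factory(
            "SUB1", ecd_end=7, anchor=7, segments={"A": (2, 4), "TM1": (8, 10)}
        )
        return ConservationModel(
            {"SUB1": aln}, custom_matrix, {"SUB1": ann}
        ).fit()

    def test_one_track_per_non_human_row(self, fitted):
        assert len(fitted.tracks) == 2
        assert {t.species for t in fitted.tracks} == {"rat", "mouse"}

    def test_nonecd_plot_coordinates_start_at_one(self, fitted):
        for t in fitted.tracks:
            nonecd_x = [
                x for x, lab in zip(t.plot_x, t.domain_labels) if lab == "non-ECD"
            ]
            assert nonecd_x[0] == 1
            assert all(b > a for a, b in zip(nonecd_x, nonecd_x[1:]))

    def test_plot_writes_one_panel_per_domain_part(self, fitted, tmp_path):
        written = fitted.plot_tracks(tmp_path / "tracks")
        assert len(written) == 2
        for p in written:
            assert p.exists() and p.stat().st_size > 0

    def test_plot_without_tracks_rejected(self, fitted, tmp_path):
        empty = ConservationResults(fitted.model, fitted.coordinate_map, [])
        with pytest.raises(ValueError, match="no tracks"):
            empty.plot_tracks(tmp_path / "x")

    def test_summary_lists_all_tracks(self, fitted):
        text = fitted.summary()
        assert "SUB1" in text and "rat" in text and "mouse" in text
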