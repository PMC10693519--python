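"""Cross-species conservation profiling of receptor subunits.

Each non-human ortholog is scored column-by-column against the human
reference of its subunit alignment using the normalized substitution matrix:
residue-residue columns take the rescaled BLOSUM value in [0, 1], columns
with a gap in exactly one row take the indel score (-0.5), dual-gap columns
take 0.

Plot coordinates follow an anchored two-part system.  The alignment is split
at the end of the extracellular domain (ECD) into an ECD part and a non-ECD
part.  ECD columns of the reference subunit (by default the one with the
longest human sequence, GABRR1 in the full receptor family) are numbered
1..n; every other subunit's ECD numbering is shifted so that the alignment
column holding the second cys-loop cysteine lands on the same coordinate as
the reference's.  Non-ECD columns are numbered from 1 independently for
every subunit.

Use :class:`ConservationModel` to assemble alignments, matrix and
annotations, and :meth:`ConservationModel.fit` to obtain a
:class:`ConservationResults` with per-column score tracks, per-segment
summaries and plotting.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .alignments import SEGMENT_ORDER, SegmentAnnotation, SubunitAlignment
from .matrices import GAP_CHAR, ScoringMatrix

ECD = "ECD"
NON_ECD = "non-ECD"


@dataclass(frozen=True)
class PositionScoreTrack:
    """Per-column substitution scores of one non-human row vs the human one.

    ``scores[i]`` is the score of alignment column ``i+1``;
    ``domain_labels[i]`` is ``"ECD"`` or ``"non-ECD"``; ``plot_x[i]`` the
    anchored plotting coordinate within that domain part.
    """

    subunit_id: str
    sequence_id: str
    species: str
    scores: np.ndarray
    domain_labels: tuple[str, ...]
    plot_x: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.scores)
        if not (len(self.domain_labels) == len(self.plot_x) == n):
            raise ValueError("track fields must have equal length")

    @property
    def n_columns(self) -> int:
        return len(self.scores)

    def mean_score(self) -> float:
        return float(np.mean(self.scores))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "column": np.arange(1, self.n_columns + 1),
                "plot_x": self.plot_x,
                "domain": list(self.domain_labels),
                "score": self.scores,
            }
        )


@dataclass(frozen=True)
class CoordinateMap:
    """Anchored plot coordinates for a set of subunit alignments.

    ``ecd_offset[subunit]`` is added to a subunit's ECD column numbers so
    that all cys-loop anchor columns share the reference subunit's anchor
    coordinate.  Non-ECD numbering always restarts at 1.
    """

    reference_subunit_id: str
    ecd_offset: dict[str, int]
    anchor_coordinate: int
    nonecd_start: int = 1


def score_pair_columns(
    alignment: SubunitAlignment,
    other_id: str,
    matrix: ScoringMatrix,
    annotation: SegmentAnnotation | None = None,
    coordinate_map: CoordinateMap | None = None,
) -> PositionScoreTrack:
    """Score one non-human row against the human reference, column-wise.

    Domain labels and plot coordinates are attached when an annotation (and
    optionally a coordinate map) is supplied; otherwise every column is
    labelled ECD with identity coordinates.
    """
    if other_id == alignment.human_reference_id:
        raise ValueError("cannot score the human reference against itself")
    human = alignment.human_row.sequence
    other = alignment.row(other_id).sequence
    allowed = set(matrix.alphabet) | {GAP_CHAR}
    scores = np.empty(alignment.n_columns)
    for i, (hx, ox) in enumerate(zip(human, other)):
        for ch in (hx, ox):
            if ch not in allowed:
                raise ValueError(
                    f"character {ch!r} at alignment column {i + 1} is outside "
                    "the matrix alphabet"
                )
        scores[i] = matrix.score(hx, ox)

    if annotation is None:
        labels = tuple([ECD] * alignment.n_columns)
        plot_x = np.arange(1, alignment.n_columns + 1)
    else:
        labels = tuple(label_domains(alignment, annotation))
        offset = 0
        if coordinate_map is not None:
            offset = coordinate_map.ecd_offset[alignment.subunit_id]
        plot_x = np.empty(alignment.n_columns, dtype=int)
        nonecd_counter = 0
        for i, lab in enumerate(labels):
            if lab == ECD:
                plot_x[i] = (i + 1) + offset
            else:
                nonecd_counter += 1
                plot_x[i] = nonecd_counter
    row = alignment.row(other_id)
    return PositionScoreTrack(
        subunit_id=alignment.subunit_id,
        sequence_id=other_id,
        species=row.species,
        scores=scores,
        domain_labels=labels,
        plot_x=plot_x,
    )


def label_domains(
    alignment: SubunitAlignment, annotation: SegmentAnnotation
) -> list[str]:
    """Label each alignment column ECD or non-ECD.

    The split is defined on the human sequence: a column is ECD iff the human
    residue at or before it is <= ``ecd_end``.  Gap columns inherit the label
    of the nearest preceding human residue; leading gaps are ECD.
    """
    annotation.validate_against(alignment)
    positions = alignment.human_position_of_column()
    return [ECD if pos <= annotation.ecd_end else NON_ECD for pos in positions]


def anchor_coordinates(
    alignments: dict[str, SubunitAlignment],
    annotations: dict[str, SegmentAnnotation],
    reference_subunit_id: str,
) -> CoordinateMap:
    """Build the anchored ECD coordinate system across subunit alignments.

    The reference subunit keeps identity ECD numbering (column k -> k); every
    other subunit receives the integer offset that moves its cys-loop anchor
    column onto the reference's anchor coordinate.
    """
    if reference_subunit_id not in alignments:
        raise ValueError(f"reference subunit {reference_subunit_id!r} not supplied")
    anchor_cols: dict[str, int] = {}
    for subunit, aln in alignments.items():
        ann = annotations[subunit]
        ann.validate_against(aln)
        anchor_cols[subunit] = aln.column_of_human_position(ann.anchor_residue)
    ref_anchor = anchor_cols[reference_subunit_id]
    offsets = {
        subunit: ref_anchor - col for subunit, col in anchor_cols.items()
    }
    return CoordinateMap(
        reference_subunit_id=reference_subunit_id,
        ecd_offset=offsets,
        anchor_coordinate=ref_anchor,
    )


def choose_reference_subunit(alignments: dict[str, SubunitAlignment]) -> str:
    """Pick the subunit with the longest (ungapped) human sequence.

    Mirrors tying the reference choice to the longest sequence in the
    receptor family; ties break lexicographically for determinism.
    """
    return min(
        alignments,
        key=lambda s: (-alignments[s].human_ungapped_length(), s),
    )


def summarize_segments(
    track: PositionScoreTrack,
    alignment: SubunitAlignment,
    annotation: SegmentAnnotation,
) -> pd.DataFrame:
    """Per-segment mean/min conservation scores for one track.

    Segment spans (human coordinates) are converted to alignment columns via
    the human row; dual-gap columns (no residue in either row) are excluded
    from the means.  Rows are ordered A..G then TM1..TM4.
    """
    if track.n_columns != alignment.n_columns:
        raise ValueError("track and alignment width differ")
    human = alignment.human_row.sequence
    other = alignment.row(track.sequence_id).sequence
    records = []
    ordered = sorted(
        annotation.segments,
        key=lambda n: (SEGMENT_ORDER.index(n) if n in SEGMENT_ORDER else 99, n),
    )
    for name in ordered:
        start, end = annotation.segments[name]
        col_lo = alignment.column_of_human_position(start)
        col_hi = alignment.column_of_human_position(end)
        cols = [
            c
            for c in range(col_lo, col_hi + 1)
            if not (human[c - 1] == GAP_CHAR and other[c - 1] == GAP_CHAR)
        ]
        vals = track.scores[[c - 1 for c in cols]]
        records.append(
            {
                "segment": name,
                "mean_score": float(np.mean(vals)) if len(vals) else np.nan,
                "min_score": float(np.min(vals)) if len(vals) else np.nan,
                "n_columns": len(cols),
            }
        )
    return pd.DataFrame(records)


class ConservationModel:
    """Conservation profiling of subunit orthologs against human references.

    Parameters
    ----------
    alignments : dict[str, SubunitAlignment]
        One multiple alignment per subunit.
    matrix : ScoringMatrix
        The normalized scoring scheme (see :func:`build_custom_matrix`).
    annotations : dict[str, SegmentAnnotation]
        Segment/ECD/anchor annotations per subunit.
    reference_subunit_id : str, optional
        Subunit anchoring the ECD coordinate system.  Defaults to the
        subunit with the longest human sequence.
    """

    def __init__(
        self,
        alignments: dict[str, SubunitAlignment],
        matrix: ScoringMatrix,
        annotations: dict[str, SegmentAnnotation],
        reference_subunit_id: str | None = None,
    ) -> None:
        if not alignments:
            raise ValueError("no alignments supplied")
        missing = sorted(set(alignments) - set(annotations))
        if missing:
            raise ValueError(f"no annotation for subunits: {missing}")
        self.alignments = dict(sorted(alignments.items()))
        self.matrix = matrix
        self.annotations = annotations
        if reference_subunit_id is None:
            reference_subunit_id = choose_reference_subunit(self.alignments)
        elif reference_subunit_id not in self.alignments:
            fallback = choose_reference_subunit(self.alignments)
            import logging

            logging.getLogger(__name__).warning(
                "reference subunit %s absent; falling back to longest human "
                "sequence %s",
                reference_subunit_id,
                fallback,
            )
            reference_subunit_id = fallback
        self.reference_subunit_id = reference_subunit_id

    def fit(self) -> "ConservationResults":
        """Score every non-human row of every alignment; build coordinates."""
        cmap = anchor_coordinates(
            self.alignments, self.annotations, self.reference_subunit_id
        )
        tracks: list[PositionScoreTrack] = []
        for subunit, aln in self.alignments.items():
            for other_id in aln.non_human_ids:
                tracks.append(
                    score_pair_columns(
                        aln,
                        other_id,
                        self.matrix,
                        annotation=self.annotations[subunit],
                        coordinate_map=cmap,
                    )
                )
        return ConservationResults(model=self, coordinate_map=cmap, tracks=tracks)


class ConservationResults:
    """Fitted conservation profile: tracks, coordinates, summaries, plots."""

    def __init__(
        self,
        model: ConservationModel,
        coordinate_map: CoordinateMap,
        tracks: list[PositionScoreTrack],
    ) -> None:
        self.model = model
        self.coordinate_map = coordinate_map
        self.tracks = tracks

    def track(self, subunit_id: str, sequence_id: str) -> PositionScoreTrack:
        for t in self.tracks:
            if t.subunit_id == subunit_id and t.sequence_id == sequence_id:
                return t
        raise KeyError(f"no track for {subunit_id}/{sequence_id}")

    def tracks_frame(self) -> pd.DataFrame:
        """All tracks as one long table (subunit, sequence, column, score)."""
        frames = []
        for t in self.tracks:
            df = t.to_frame()
            df.insert(0, "sequence_id", t.sequence_id)
            df.insert(0, "subunit_id", t.subunit_id)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def segment_summary(self) -> pd.DataFrame:
        """Per-segment mean/min scores for every track, one long table."""
        frames = []
        for t in self.tracks:
            df = summarize_segments(
                t,
                self.model.alignments[t.subunit_id],
                self.model.annotations[t.subunit_id],
            )
            df.insert(0, "sequence_id", t.sequence_id)
            df.insert(0, "subunit_id", t.subunit_id)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def summary(self) -> str:
        """Human-readable overview of the fitted conservation profile."""
        lines = [
            "Conservation profile",
            "====================",
            f"subunits:          {len(self.model.alignments)}",
            f"reference subunit: {self.coordinate_map.reference_subunit_id} "
            f"(anchor coordinate {self.coordinate_map.anchor_coordinate})",
            f"tracks:            {len(self.tracks)}",
            "",
            f"{'subunit':<10} {'sequence':<28} {'mean':>7} {'min':>7}",
        ]
        for t in self.tracks:
            lines.append(
                f"{t.subunit_id:<10} {t.sequence_id:<28} "
                f"{t.mean_score():>7.3f} {float(np.min(t.scores)):>7.2f}"
            )
        return "\n".join(lines)

    def write_outputs(self, out_dir: str | Path) -> list[Path]:
        """Write score-track and segment-summary TSVs; return paths."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = []
        p = out / "score_tracks.tsv"
        self.tracks_frame().to_csv(p, sep="\t", index=False, float_format="%.6f")
        paths.append(p)
        p = out / "segment_summary.tsv"
        self.segment_summary().to_csv(p, sep="\t", index=False, float_format="%.6f")
        paths.append(p)
        return paths

    def plot_tracks(self, out_path: str | Path) -> list[Path]:
        """Plot score tracks, one panel per domain part (ECD / non-ECD).

        Segment spans of the reference subunit are drawn as shaded, labelled
        bands.  ``out_path`` is the output stem; one file per panel is
        written (``<stem>_ecd.png``, ``<stem>_nonecd.png``) and the list of
        written paths returned.
        """
        if not self.tracks:
            raise ValueError("no tracks to plot")
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        out_path = Path(out_path)
        out_path.parent.mkdir(parents=True, exist_ok=True)
        written = []
        ref = self.coordinate_map.reference_subunit_id
        ref_aln = self.model.alignments[ref]
        ref_ann = self.model.annotations[ref]
        ref_labels = label_domains(ref_aln, ref_ann)
        ref_offset = self.coordinate_map.ecd_offset[ref]

        for part, suffix in ((ECD, "ecd"), (NON_ECD, "nonecd")):
            fig, ax = plt.subplots(figsize=(12, 4))
            for t in self.tracks:
                mask = [lab == part for lab in t.domain_labels]
                xs = t.plot_x[mask]
                ys = t.scores[mask]
                if len(xs) == 0:
                    continue
                ax.plot(xs, ys, lw=0.8, label=f"{t.subunit_id}|{t.species}")
            # reference-subunit segment bands in this part's coordinates
            nonecd_counter = 0
            col_coord = {}
            for i, lab in enumerate(ref_labels):
                if lab == ECD:
                    col_coord[i + 1] = ((i + 1) + ref_offset, ECD)
                else:
                    nonecd_counter += 1
                    col_coord[i + 1] = (nonecd_counter, NON_ECD)
            for name, (start, end) in ref_ann.segments.items():
                c_lo = ref_aln.column_of_human_position(start)
                c_hi = ref_aln.column_of_human_position(end)
                x_lo, part_lo = col_coord[c_lo]
                x_hi, part_hi = col_coord[c_hi]
                if part_lo != part or part_hi != part:
                    continue
                ax.axvspan(x_lo, x_hi, alpha=0.15, color="grey")
                ax.text(
                    (x_lo + x_hi) / 2,
                    1.05,
                    name,
                    ha="center",
                    va="bottom",
                    fontsize=8,
                )
            if part == ECD:
                ax.axvline(
                    self.coordinate_map.anchor_coordinate,
                    color="k",
                    ls="--",
                    lw=0.8,
                )
            ax.set_xlabel(f"{part} alignment position (anchored)")
            ax.set_ylabel("substitution score")
            ax.set_ylim(-0.6, 1.15)
            ax.legend(fontsize=7, ncol=2)
            p = out_path.parent / f"{out_path.name}_{suffix}.png"
            fig.savefig(p, dpi=120)
            plt.close(fig)
            written.append(p)
        return written
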