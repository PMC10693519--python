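"""Containers and I/O for per-subunit ortholog alignments and annotations.

One :class:`SubunitAlignment` holds the multiple sequence alignment of a
single receptor subunit (e.g. GABRA1) across species, with a designated
human reference row.  Segment annotations (binding-site loops A-G, the four
membrane-spanning helices, the end of the extracellular domain and the
cys-loop anchor cysteine) are given in human 1-based sequence coordinates
and are mapped onto alignment columns through the human row.

FASTA headers follow the convention ``>SUBUNIT|SPECIES|ACCESSION`` with the
first two fields mandatory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .matrices import GAP_CHAR

#: Canonical segment ordering for reports: binding-site loops then TM helices.
SEGMENT_ORDER: tuple[str, ...] = (
    "A", "B", "C", "D", "E", "F", "G", "TM1", "TM2", "TM3", "TM4",
)


@dataclass(frozen=True)
class AlignmentRow:
    """One aligned sequence: identifier, species label, gapped sequence."""

    sequence_id: str
    species: str
    sequence: str


@dataclass(frozen=True)
class SubunitAlignment:
    """A per-subunit multiple alignment with a human reference row."""

    subunit_id: str
    rows: tuple[AlignmentRow, ...]
    human_reference_id: str

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError(f"alignment {self.subunit_id}: no rows")
        widths = {len(r.sequence) for r in self.rows}
        if len(widths) != 1:
            raise ValueError(
                f"alignment {self.subunit_id}: rows have unequal lengths {sorted(widths)}"
            )
        if self.human_reference_id not in {r.sequence_id for r in self.rows}:
            raise ValueError(
                f"alignment {self.subunit_id}: human reference "
                f"{self.human_reference_id!r} not among rows"
            )

    @property
    def n_columns(self) -> int:
        return len(self.rows[0].sequence)

    def row(self, sequence_id: str) -> AlignmentRow:
        for r in self.rows:
            if r.sequence_id == sequence_id:
                return r
        raise KeyError(f"no row {sequence_id!r} in alignment {self.subunit_id}")

    @property
    def human_row(self) -> AlignmentRow:
        return self.row(self.human_reference_id)

    @property
    def non_human_ids(self) -> list[str]:
        return [
            r.sequence_id for r in self.rows if r.sequence_id != self.human_reference_id
        ]

    def human_ungapped_length(self) -> int:
        return sum(1 for c in self.human_row.sequence if c != GAP_CHAR)

    def human_position_of_column(self) -> list[int]:
        """Human residue index (1-based) at or before each column; 0 before
        the first human residue.  Gap columns inherit the preceding index."""
        out, pos = [], 0
        for c in self.human_row.sequence:
            if c != GAP_CHAR:
                pos += 1
            out.append(pos)
        return out

    def column_of_human_position(self, position: int) -> int:
        """1-based alignment column holding human residue ``position``."""
        if position < 1:
            raise ValueError(f"human position must be >= 1, got {position}")
        pos = 0
        for col, c in enumerate(self.human_row.sequence, start=1):
            if c != GAP_CHAR:
                pos += 1
                if pos == position:
                    return col
        raise ValueError(
            f"human position {position} beyond ungapped length {pos} "
            f"in alignment {self.subunit_id}"
        )


@dataclass(frozen=True)
class SegmentAnnotation:
    """Segment spans plus ECD end and cys-loop anchor, in human coordinates.

    ``segments`` maps segment name -> (start, end), 1-based inclusive on the
    ungapped human sequence.  ``ecd_end`` is the last extracellular-domain
    residue; ``anchor_residue`` the second cysteine of the cys-loop, which
    must lie inside the ECD.
    """

    subunit_id: str
    segments: dict[str, tuple[int, int]] = field(default_factory=dict)
    ecd_end: int = 0
    anchor_residue: int = 0

    def __post_init__(self) -> None:
        for name, (start, end) in self.segments.items():
            if not (1 <= start <= end):
                raise ValueError(
                    f"{self.subunit_id}: segment {name} has invalid span "
                    f"({start}, {end})"
                )
        if self.ecd_end < 1:
            raise ValueError(f"{self.subunit_id}: ecd_end must be >= 1")
        if not (1 <= self.anchor_residue <= self.ecd_end):
            raise ValueError(
                f"{self.subunit_id}: anchor residue {self.anchor_residue} "
                f"must lie in the ECD (1..{self.ecd_end})"
            )

    def validate_against(self, alignment: SubunitAlignment) -> None:
        """Check coordinates fit the human row; anchor must be a cysteine."""
        human_len = alignment.human_ungapped_length()
        if self.ecd_end > human_len:
            raise ValueError(
                f"{self.subunit_id}: ecd_end {self.ecd_end} exceeds human "
                f"sequence length {human_len}"
            )
        for name, (start, end) in self.segments.items():
            if end > human_len:
                raise ValueError(
                    f"{self.subunit_id}: segment {name} end {end} exceeds "
                    f"human sequence length {human_len}"
                )
        ungapped = alignment.human_row.sequence.replace(GAP_CHAR, "")
        residue = ungapped[self.anchor_residue - 1]
        if residue != "C":
            raise ValueError(
                f"{self.subunit_id}: anchor residue {self.anchor_residue} is "
                f"{residue!r}, expected cysteine"
            )


def _parse_header(header: str) -> tuple[str, str, str]:
    parts = header.split("|")
    if len(parts) < 2:
        raise ValueError(
            f"FASTA header {header!r} must be SUBUNIT|SPECIES[|ACCESSION]"
        )
    subunit, species = parts[0], parts[1]
    accession = parts[2] if len(parts) > 2 else ""
    return subunit, species, accession


def read_alignment_fasta(
    path: str | Path,
    human_species: str = "human",
    subunit_id: str | None = None,
) -> SubunitAlignment:
    """Read one aligned FASTA file into a :class:`SubunitAlignment`.

    The human reference row is the (unique) record whose species field
    matches ``human_species`` case-insensitively.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    rows, human_ids, subunits = [], [], set()
    for rec in records:
        subunit, species, _ = _parse_header(rec.id)
        subunits.add(subunit)
        rows.append(
            AlignmentRow(
                sequence_id=rec.id, species=species, sequence=str(rec.seq).upper()
            )
        )
        if species.lower() == human_species.lower():
            human_ids.append(rec.id)
    if len(subunits) > 1:
        raise ValueError(f"{path}: mixed subunits in one alignment: {sorted(subunits)}")
    if len(human_ids) != 1:
        raise ValueError(
            f"{path}: expected exactly one {human_species!r} row, found {len(human_ids)}"
        )
    return SubunitAlignment(
        subunit_id=subunit_id or subunits.pop(),
        rows=tuple(rows),
        human_reference_id=human_ids[0],
    )


def write_alignment_fasta(alignment: SubunitAlignment, path: str | Path) -> None:
    """Write an alignment back to aligned FASTA (full-width rows)."""
    with open(path, "w") as fh:
        for r in alignment.rows:
            fh.write(f">{r.sequence_id}\n{r.sequence}\n")


def read_annotation_tsv(path: str | Path) -> dict[str, SegmentAnnotation]:
    """Read a segment-annotation TSV into per-subunit annotations.

    Columns: ``subunit_id, segment_name, start, end``.  Rows with
    ``segment_name`` of ``ECD_END`` or ``CYS_ANCHOR`` carry the respective
    position in ``start`` (``end`` ignored).
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"subunit_id": str})
    required = {"subunit_id", "segment_name", "start", "end"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: annotation TSV needs columns {sorted(required)}")
    out: dict[str, SegmentAnnotation] = {}
    for subunit, grp in df.groupby("subunit_id", sort=True):
        segments: dict[str, tuple[int, int]] = {}
        ecd_end = anchor = 0
        for row in grp.itertuples(index=False):
            name = str(row.segment_name)
            if name == "ECD_END":
                ecd_end = int(row.start)
            elif name == "CYS_ANCHOR":
                anchor = int(row.start)
            else:
                segments[name] = (int(row.start), int(row.end))
        out[subunit] = SegmentAnnotation(
            subunit_id=subunit,
            segments=segments,
            ecd_end=ecd_end,
            anchor_residue=anchor,
        )
    return out


def write_annotation_tsv(
    annotations: dict[str, SegmentAnnotation], path: str | Path
) -> None:
    rows = []
    for subunit in sorted(annotations):
        ann = annotations[subunit]
        for name in sorted(
            ann.segments,
            key=lambda n: (SEGMENT_ORDER.index(n) if n in SEGMENT_ORDER else 99, n),
        ):
            start, end = ann.segments[name]
            rows.append((subunit, name, start, end))
        rows.append((subunit, "ECD_END", ann.ecd_end, ann.ecd_end))
        rows.append((subunit, "CYS_ANCHOR", ann.anchor_residue, ann.anchor_residue))
    pd.DataFrame(rows, columns=["subunit_id", "segment_name", "start", "end"]).to_csv(
        path, sep="\t", index=False
    )
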