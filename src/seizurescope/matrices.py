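"""Substitution matrices for cross-species conservation scoring.

The conservation pipeline compares each non-human receptor-subunit ortholog
to its human counterpart position by position.  The similarity scale is a
linearly rescaled BLOSUM90: the 20x20 core of the published half-bit table is
mapped onto [0, 1], while alignment gaps receive fixed scores outside that
range (-0.5 for a residue aligned to a gap, 0 for a gap aligned to a gap).
On this scale 1 means "identical to the most conserved identity pair", 0
means "the least favourable residue exchange in the table", and negative
values only ever arise from indels.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from Bio.Align import substitution_matrices

#: The 20 canonical amino acids, in the row order of NCBI BLAST matrices.
STANDARD_RESIDUES: str = "ARNDCQEGHILKMFPSTWYV"

#: Character used for alignment gaps throughout the package.
GAP_CHAR: str = "-"

#: Gap scores of the custom scoring scheme.
DEFAULT_INDEL_SCORE: float = -0.5
DEFAULT_DUAL_GAP_SCORE: float = 0.0


@dataclass(frozen=True)
class RawSubstitutionMatrix:
    """A symmetric integer substitution matrix over the 20 standard residues.

    Parameters
    ----------
    alphabet : str
        Residue one-letter codes, in table order (no duplicates).
    scores : numpy.ndarray
        Square integer table, ``scores[i, j]`` being the score of aligning
        ``alphabet[i]`` with ``alphabet[j]``.  Must be symmetric.
    name : str
        Free-text identifier, e.g. ``"BLOSUM90"``.
    """

    alphabet: str
    scores: np.ndarray
    name: str = ""
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(set(self.alphabet)) != len(self.alphabet):
            raise ValueError("matrix alphabet contains duplicate residues")
        scores = np.asarray(self.scores, dtype=float)
        if scores.shape != (len(self.alphabet), len(self.alphabet)):
            raise ValueError(
                f"score table shape {scores.shape} does not match "
                f"alphabet of length {len(self.alphabet)}"
            )
        asym = np.argwhere(scores != scores.T)
        if asym.size:
            i, j = asym[0]
            raise ValueError(
                "substitution matrix is not symmetric: "
                f"score({self.alphabet[i]},{self.alphabet[j]}) != "
                f"score({self.alphabet[j]},{self.alphabet[i]})"
            )
        object.__setattr__(self, "scores", scores)
        object.__setattr__(
            self, "_index", {aa: i for i, aa in enumerate(self.alphabet)}
        )

    def score(self, x: str, y: str) -> float:
        """Raw score of aligning residue ``x`` with residue ``y``."""
        return float(self.scores[self._index[x], self._index[y]])

    @property
    def min(self) -> float:
        return float(self.scores.min())

    @property
    def max(self) -> float:
        return float(self.scores.max())


@dataclass(frozen=True)
class ScoringMatrix:
    """The normalized scoring scheme: rescaled residue table plus gap scores.

    ``normalized_scores`` is the affine image of the raw table on [0, 1]
    (minimum mapped to 0, maximum to 1); ``indel_score`` applies whenever
    exactly one of the two aligned characters is a gap, ``dual_gap_score``
    when both are.
    """

    alphabet: str
    normalized_scores: np.ndarray
    indel_score: float
    dual_gap_score: float
    source: RawSubstitutionMatrix
    normalization_min: float
    normalization_max: float
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "_index", {aa: i for i, aa in enumerate(self.alphabet)}
        )

    def score(self, x: str, y: str) -> float:
        """Score an aligned character pair, applying the gap rules.

        Both characters gaps -> ``dual_gap_score``; exactly one a gap ->
        ``indel_score``; otherwise the normalized table value.
        """
        xg = x == GAP_CHAR
        yg = y == GAP_CHAR
        if xg and yg:
            return self.dual_gap_score
        if xg or yg:
            return self.indel_score
        try:
            return float(self.normalized_scores[self._index[x], self._index[y]])
        except KeyError as exc:
            raise KeyError(f"residue {exc.args[0]!r} not in matrix alphabet") from exc


def load_raw_matrix(path_or_handle, name: str | None = None) -> RawSubstitutionMatrix:
    """Read a substitution matrix in NCBI BLAST format.

    Lines starting with ``#`` are comments; the first data line lists the
    column residues and each following line is a residue label plus its row
    of integer scores.  Ambiguity and stop columns (B, Z, X, J, U, O, ``*``)
    are dropped and the table is restricted to the 20 standard residues
    before any downstream normalization.

    Raises
    ------
    ValueError
        If the table is asymmetric or a standard residue row is missing.
    """
    if hasattr(path_or_handle, "read"):
        mat = substitution_matrices.read(path_or_handle)
        label = name or "matrix"
    else:
        with open(path_or_handle) as fh:
            mat = substitution_matrices.read(fh)
        label = name or str(path_or_handle)
    missing = [aa for aa in STANDARD_RESIDUES if aa not in mat.alphabet]
    if missing:
        raise ValueError(f"matrix file lacks rows for standard residues: {missing}")
    table = np.array(
        [[mat[x, y] for y in STANDARD_RESIDUES] for x in STANDARD_RESIDUES]
    )
    return RawSubstitutionMatrix(alphabet=STANDARD_RESIDUES, scores=table, name=label)


def load_bundled_blosum90() -> RawSubstitutionMatrix:
    """Load the BLOSUM90 table bundled with the package."""
    text = (
        resources.files("seizurescope.data").joinpath("blosum90.ncbi.txt").read_text()
    )
    return load_raw_matrix(io.StringIO(text), name="BLOSUM90")


def build_custom_matrix(
    raw: RawSubstitutionMatrix,
    indel_score: float = DEFAULT_INDEL_SCORE,
    dual_gap_score: float = DEFAULT_DUAL_GAP_SCORE,
) -> ScoringMatrix:
    """Rescale a raw matrix linearly onto [0, 1] and attach gap scores.

    ``normalized(x, y) = (raw(x, y) - min) / (max - min)`` over the 20x20
    core; the raw extremes are recorded on the result so the rescaling is
    invertible.  A constant raw table has no defined rescaling and is
    rejected.
    """
    lo, hi = raw.min, raw.max
    if hi <= lo:
        raise ValueError("constant raw matrix: linear normalization undefined")
    normalized = (raw.scores - lo) / (hi - lo)
    return ScoringMatrix(
        alphabet=raw.alphabet,
        normalized_scores=normalized,
        indel_score=float(indel_score),
        dual_gap_score=float(dual_gap_score),
        source=raw,
        normalization_min=lo,
        normalization_max=hi,
    )
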