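"""Synthetic inputs with known ground truth for both pipelines.

Two generators:

* :func:`simulate_orthologs` mutates a human reference sequence into
  per-species orthologs with per-segment substitution and indel rates,
  emitting the true multiple alignment (the simulation knows the homology,
  so no aligner is involved) plus a truth record of realized events.
  Substituted residues are drawn from a softmax over the raw BLOSUM90 row
  of the original residue (identity excluded), so likely exchanges are
  biochemically plausible ones.

* :func:`simulate_reports` draws a drug x AE count table from a single
  multinomial whose cell probabilities are an independence product
  ``p_i * q_j`` multiplied by a relative reporting ratio ``lambda`` for
  spiked pairs (lambda = 1 elsewhere), renormalized.  Spiked pairs are the
  planted disproportionality signals.

Both are pure functions of (config, seed).  :func:`make_fixture_bundle`
writes a small self-consistent directory of files in exactly the formats
the analysis modules read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .alignments import (
    AlignmentRow,
    SegmentAnnotation,
    SubunitAlignment,
    write_alignment_fasta,
    write_annotation_tsv,
)
from .disproportionality import ReportTable
from .matrices import (
    GAP_CHAR,
    STANDARD_RESIDUES,
    RawSubstitutionMatrix,
    load_bundled_blosum90,
)

__all__ = [
    "SegmentRates",
    "OrthologSimConfig",
    "AEReportSimConfig",
    "simulate_orthologs",
    "simulate_reports",
    "make_fixture_bundle",
]


@dataclass(frozen=True)
class SegmentRates:
    """Divergence rates for one span of the reference (1-based inclusive)."""

    name: str
    start: int
    end: int
    p_sub: float
    p_indel: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.p_sub <= 1:
            raise ValueError(f"segment {self.name}: p_sub outside [0, 1]")
        if not 0 <= self.p_indel <= 1:
            raise ValueError(f"segment {self.name}: p_indel outside [0, 1]")
        if not 1 <= self.start <= self.end:
            raise ValueError(f"segment {self.name}: invalid span")


@dataclass(frozen=True)
class OrthologSimConfig:
    """Configuration for the ortholog simulator.

    ``segments`` assign rates to spans of the reference; positions not
    covered by any segment use ``default_p_sub`` / ``default_p_indel``.
    """

    subunit_id: str
    reference: str
    species: tuple[str, ...]
    segments: tuple[SegmentRates, ...] = ()
    default_p_sub: float = 0.05
    default_p_indel: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.reference:
            raise ValueError("empty reference sequence")
        bad = set(self.reference) - set(STANDARD_RESIDUES)
        if bad:
            raise ValueError(f"reference contains non-standard residues: {sorted(bad)}")
        if not self.species:
            raise ValueError("at least one species required")
        for seg in self.segments:
            if seg.end > len(self.reference):
                raise ValueError(
                    f"segment {seg.name} extends past the reference "
                    f"({seg.end} > {len(self.reference)})"
                )

    def rates_per_position(self) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """(p_sub, p_indel, segment name) for every reference position."""
        n = len(self.reference)
        p_sub = np.full(n, self.default_p_sub)
        p_indel = np.full(n, self.default_p_indel)
        names = [""] * n
        for seg in self.segments:
            p_sub[seg.start - 1 : seg.end] = seg.p_sub
            p_indel[seg.start - 1 : seg.end] = seg.p_indel
            for i in range(seg.start - 1, seg.end):
                names[i] = seg.name
        return p_sub, p_indel, names


def _substitution_distributions(
    raw: RawSubstitutionMatrix, temperature: float = 1.0
) -> dict[str, tuple[str, np.ndarray]]:
    """Per-residue softmax over raw matrix row scores, identity excluded."""
    out = {}
    for x in raw.alphabet:
        targets = [y for y in raw.alphabet if y != x]
        scores = np.array([raw.score(x, y) for y in targets]) / temperature
        w = np.exp(scores - scores.max())
        out[x] = ("".join(targets), w / w.sum())
    return out


def simulate_orthologs(
    config: OrthologSimConfig,
    raw_matrix: RawSubstitutionMatrix | None = None,
) -> tuple[SubunitAlignment, dict]:
    """Simulate species orthologs of a reference; return alignment + truth.

    Per species and per reference position: with the position's ``p_sub``
    the residue is replaced by a draw from the BLOSUM-softmax conditional;
    with ``p_indel`` an indel occurs, equally likely a deletion of the
    residue or an insertion of a uniform random residue after it.  The true
    alignment is assembled directly: deletions become gaps in the species
    row, insertions become extra columns gapped in every other row.

    The truth record holds, per species and segment name, the realized
    substitution/indel counts and the configured rates.
    """
    if raw_matrix is None:
        raw_matrix = load_bundled_blosum90()
    rng = np.random.default_rng(config.seed)
    p_sub, p_indel, seg_names = config.rates_per_position()
    subst = _substitution_distributions(raw_matrix)
    n = len(config.reference)

    # per-species event lists
    species_chars: dict[str, list[str]] = {}
    insertions: dict[str, dict[int, str]] = {}  # species -> {position: residue}
    truth: dict = {"per_species": {}, "segments": {}}
    for seg in config.segments:
        truth["segments"][seg.name] = {
            "start": seg.start,
            "end": seg.end,
            "p_sub": seg.p_sub,
            "p_indel": seg.p_indel,
        }

    for sp in config.species:
        chars = list(config.reference)
        ins: dict[int, str] = {}
        counts: dict[str, dict[str, int]] = {}
        sub_draw = rng.random(n)
        indel_draw = rng.random(n)
        for i in range(n):
            seg = seg_names[i]
            c = counts.setdefault(seg, {"substitutions": 0, "indels": 0, "positions": 0})
            c["positions"] += 1
            if sub_draw[i] < p_sub[i]:
                targets, weights = subst[chars[i]]
                chars[i] = targets[rng.choice(len(targets), p=weights)]
                c["substitutions"] += 1
            if indel_draw[i] < p_indel[i]:
                c["indels"] += 1
                if rng.random() < 0.5:
                    chars[i] = GAP_CHAR  # deletion in this species
                else:
                    ins[i] = STANDARD_RESIDUES[rng.choice(len(STANDARD_RESIDUES))]
        species_chars[sp] = chars
        insertions[sp] = ins
        truth["per_species"][sp] = counts

    # assemble the multiple alignment: reference positions in order, each
    # followed by one insertion column per species that inserted there
    human_id = f"{config.subunit_id}|human|ref"
    ids = {sp: f"{config.subunit_id}|{sp}|sim" for sp in config.species}
    cols_human: list[str] = []
    cols_sp: dict[str, list[str]] = {sp: [] for sp in config.species}
    for i in range(n):
        cols_human.append(config.reference[i])
        for sp in config.species:
            cols_sp[sp].append(species_chars[sp][i])
        for sp in config.species:
            if i in insertions[sp]:
                cols_human.append(GAP_CHAR)
                for sp2 in config.species:
                    cols_sp[sp2].append(
                        insertions[sp][i] if sp2 == sp else GAP_CHAR
                    )
    rows = [AlignmentRow(human_id, "human", "".join(cols_human))]
    rows += [
        AlignmentRow(ids[sp], sp, "".join(cols_sp[sp])) for sp in config.species
    ]
    alignment = SubunitAlignment(
        subunit_id=config.subunit_id,
        rows=tuple(rows),
        human_reference_id=human_id,
    )
    return alignment, truth


@dataclass(frozen=True)
class AEReportSimConfig:
    """Configuration for the spontaneous-report simulator.

    Marginals default to uniform.  ``spikes`` plant disproportionality:
    pair (drug_i, term_j) receives relative reporting ratio lambda.
    """

    n_drugs: int
    n_terms: int
    n_reports: int
    drug_marginals: tuple[float, ...] = ()
    term_marginals: tuple[float, ...] = ()
    spikes: tuple[tuple[int, int, float], ...] = ()  # (drug idx, term idx, lambda)
    seed: int = 0
    drug_prefix: str = "drug"
    term_prefix: str = "term"

    def __post_init__(self) -> None:
        if self.n_reports < 1:
            raise ValueError("n_reports must be positive")
        for name, marg, k in (
            ("drug", self.drug_marginals, self.n_drugs),
            ("term", self.term_marginals, self.n_terms),
        ):
            if marg:
                if len(marg) != k:
                    raise ValueError(f"{name} marginals length != n_{name}s")
                if abs(sum(marg) - 1.0) > 1e-9:
                    raise ValueError(f"{name} marginals must sum to 1")
        for i, j, lam in self.spikes:
            if not (0 <= i < self.n_drugs and 0 <= j < self.n_terms):
                raise ValueError(f"spike ({i}, {j}) outside the table")
            if lam <= 0:
                raise ValueError("spike lambda must be positive")

    def drug_names(self) -> list[str]:
        width = len(str(self.n_drugs - 1))
        return [f"{self.drug_prefix}{i:0{width}d}" for i in range(self.n_drugs)]

    def term_names(self) -> list[str]:
        width = len(str(self.n_terms - 1))
        return [f"{self.term_prefix}{j:0{width}d}" for j in range(self.n_terms)]


def simulate_reports(config: AEReportSimConfig) -> tuple[ReportTable, dict]:
    """Draw a count-mode report table; return it with the truth record.

    Cell probability: ``p_i * q_j * lambda_ij / Z`` with Z normalizing the
    total mass; counts are one multinomial draw of ``n_reports``.
    """
    rng = np.random.default_rng(config.seed)
    p = (
        np.array(config.drug_marginals)
        if config.drug_marginals
        else np.full(config.n_drugs, 1 / config.n_drugs)
    )
    q = (
        np.array(config.term_marginals)
        if config.term_marginals
        else np.full(config.n_terms, 1 / config.n_terms)
    )
    lam = np.ones((config.n_drugs, config.n_terms))
    for i, j, l in config.spikes:
        lam[i, j] = l
    probs = p[:, None] * q[None, :] * lam
    probs /= probs.sum()
    counts = rng.multinomial(config.n_reports, probs.ravel()).reshape(probs.shape)

    drugs = config.drug_names()
    terms = config.term_names()
    ii, jj = np.nonzero(counts)
    df = pd.DataFrame(
        {
            "drug": [drugs[i] for i in ii],
            "ae_term": [terms[j] for j in jj],
            "count": counts[ii, jj],
        }
    )
    truth = {
        "n_reports": config.n_reports,
        "spikes": [
            {"drug": drugs[i], "ae_term": terms[j], "lambda": l}
            for i, j, l in config.spikes
        ],
        "cell_probs_sum": float(probs.sum()),
    }
    return ReportTable.from_counts(df), truth


def expand_to_records(table: ReportTable) -> pd.DataFrame:
    """Expand a count table into single-drug single-term record rows."""
    rows = []
    rid = 0
    for r in table.counts.itertuples(index=False):
        for _ in range(r.count):
            rows.append((f"r{rid:07d}", r.drug, r.ae_term))
            rid += 1
    return pd.DataFrame(rows, columns=["report_id", "drug", "ae_term"])


# --- fixture bundle -------------------------------------------------------

# Human GABA-A subunit-like reference for the bundled fixture: 120 residues
# with the cys-loop second cysteine at position 70 and the ECD ending at 80.
_FIXTURE_REFERENCE = (
    "MDEKTTGWLLQVAANPKSFTRILDRLSEIAGVKMSDHQPLGTWFEDNKMAVQKHTGLPCE"
    "SNALDEWMRCFKQGHITSVLREWAKNGTLFIRSWAVLPMGHTYAQRILDKESNVPFGWLE"
)
_FIXTURE_SEGMENTS = (
    SegmentRates("A", 6, 15, 0.02, 0.0),
    SegmentRates("B", 18, 27, 0.05, 0.0),
    SegmentRates("C", 30, 39, 0.10, 0.01),
    SegmentRates("D", 42, 51, 0.15, 0.01),
    SegmentRates("E", 54, 62, 0.20, 0.01),
    SegmentRates("F", 64, 68, 0.08, 0.0),
    SegmentRates("G", 72, 79, 0.12, 0.01),
    SegmentRates("TM1", 81, 90, 0.03, 0.0),
    SegmentRates("TM2", 92, 100, 0.06, 0.0),
    SegmentRates("TM3", 102, 110, 0.25, 0.02),
    SegmentRates("TM4", 112, 120, 0.30, 0.02),
)
_FIXTURE_ECD_END = 80
_FIXTURE_ANCHOR = 70  # 'C' in the reference above


def make_fixture_bundle(out_dir: str | Path, seed: int = 1) -> dict[str, Path]:
    """Write a desk-scale, fully regenerable input bundle.

    Contents: one 3-species subunit alignment with segment annotations, one
    count-mode report table (10 drugs x 8 terms, 2 spiked pairs strong
    enough to be retained under default thresholds), a seizure-like term
    group file, an in-silico hit-flag table, and the YAML configs used.
    Byte-identical for a fixed seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    assert _FIXTURE_REFERENCE[_FIXTURE_ANCHOR - 1] == "C"
    ortho_cfg = OrthologSimConfig(
        subunit_id="GABR_SIM1",
        reference=_FIXTURE_REFERENCE,
        species=("mouse", "rat", "zebrafish"),
        segments=_FIXTURE_SEGMENTS,
        default_p_sub=0.05,
        default_p_indel=0.01,
        seed=seed,
    )
    alignment, _ = simulate_orthologs(ortho_cfg)
    paths["alignment"] = out / "GABR_SIM1.aln.fasta"
    write_alignment_fasta(alignment, paths["alignment"])

    annotation = SegmentAnnotation(
        subunit_id="GABR_SIM1",
        segments={s.name: (s.start, s.end) for s in _FIXTURE_SEGMENTS},
        ecd_end=_FIXTURE_ECD_END,
        anchor_residue=_FIXTURE_ANCHOR,
    )
    paths["annotations"] = out / "annotations.tsv"
    write_annotation_tsv({"GABR_SIM1": annotation}, paths["annotations"])

    # reports: 10 drugs x 8 terms, seizure group = last 3 terms; two pairs
    # spiked at lambda 12 so retention is robust across seeds
    report_cfg = AEReportSimConfig(
        n_drugs=10,
        n_terms=8,
        n_reports=20000,
        spikes=((1, 5, 12.0), (4, 7, 12.0)),
        seed=seed + 1000,
    )
    table, report_truth = simulate_reports(report_cfg)
    paths["reports"] = out / "reports.tsv"
    table.counts.to_csv(paths["reports"], sep="\t", index=False)

    group_terms = report_cfg.term_names()[5:]
    paths["term_group"] = out / "seizure_terms.txt"
    paths["term_group"].write_text(
        "# seizure-class AE terms (simulated)\n" + "\n".join(group_terms) + "\n"
    )

    spiked_drugs = sorted({s["drug"] for s in report_truth["spikes"]})
    hits = pd.DataFrame(
        {
            "drug": spiked_drugs + [report_cfg.drug_names()[0]],
            "model": ["SIM-PAM-model"] * len(spiked_drugs) + ["SIM-PAM-model"],
            "fit_score": [41.2, 38.7, 35.0][: len(spiked_drugs) + 1],
        }
    )
    paths["hits"] = out / "hits.tsv"
    hits.to_csv(paths["hits"], sep="\t", index=False)

    config = {
        "seed": seed,
        "orthologs": {
            "subunit_id": ortho_cfg.subunit_id,
            "species": list(ortho_cfg.species),
            "default_p_sub": ortho_cfg.default_p_sub,
            "default_p_indel": ortho_cfg.default_p_indel,
        },
        "reports": {
            "n_drugs": report_cfg.n_drugs,
            "n_terms": report_cfg.n_terms,
            "n_reports": report_cfg.n_reports,
            "spikes": [list(s) for s in report_cfg.spikes],
        },
        "truth": {"spiked_pairs": report_truth["spikes"]},
    }
    paths["config"] = out / "bundle_config.yaml"
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return paths
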