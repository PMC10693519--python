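"""Disproportionality analysis of spontaneous adverse-event reports.

Drug x adverse-event (AE) report tables are screened for pairs reported
disproportionately often relative to an independence expectation.  For each
pair a 2x2 contingency table is formed over reports::

                      AE term    other terms
        drug             a            b
        other drugs      c            d

and two statistics are computed:

* the proportional reporting ratio, ``PRR = (a/(a+b)) / (c/(c+d))``;
* the shrinkage information component,
  ``IC = log2((a + 1/2) / (E + 1/2))`` with ``E = (a+b)(a+c)/N``, and the
  lower bound of its 95% credibility interval,
  ``IC025 = IC - 3.3 (a + 1/2)^(-1/2) - 2 (a + 1/2)^(-3/2)``.

A pair raises a signal when ``PRR >= 2``, ``IC025 > 0`` and ``a >= 5``
(all thresholds adjustable).  :class:`DisproportionalityModel` wraps a
report table; :meth:`~DisproportionalityModel.fit` computes the statistics
and returns :class:`DisproportionalityResults` carrying the signal table,
retention flags and the seizure-burden summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TermGroup",
    "ReportTable",
    "DisproportionalityModel",
    "DisproportionalityResults",
    "prr",
    "ic_with_bound",
    "apply_retention",
    "read_term_group",
]

IC_SHRINKAGE = 0.5  # added to both observed and expected counts
IC025_C1 = 3.3  # leading credibility-interval coefficient, units of (a+1/2)^-1/2
IC025_C2 = 2.0  # curvature correction, units of (a+1/2)^-3/2


@dataclass(frozen=True)
class TermGroup:
    """A flat set of AE terms standing in for one MedDRA class subtree."""

    name: str
    terms: frozenset[str]
    case_insensitive: bool = True

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValueError(f"term group {self.name!r} is empty")
        if self.case_insensitive:
            object.__setattr__(
                self, "terms", frozenset(t.lower() for t in self.terms)
            )

    def __contains__(self, term: str) -> bool:
        return (term.lower() if self.case_insensitive else term) in self.terms


def read_term_group(path: str | Path, name: str | None = None) -> TermGroup:
    """Read a term-group file: one term per line, ``#`` comments allowed."""
    terms = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            terms.append(line)
    return TermGroup(name=name or Path(path).stem, terms=frozenset(terms))


class ReportTable:
    """A drug x AE report table, in record or count mode.

    Record mode: one row per (report_id, drug, ae_term) mention; a report
    may list several drugs and terms, and each unique (drug, term) pair
    within a report counts once.  Count mode: pre-aggregated rows of
    (drug, ae_term, count).
    """

    def __init__(self, counts: pd.DataFrame, mode: str):
        required = {"drug", "ae_term", "count"}
        if not required.issubset(counts.columns):
            raise ValueError(f"count table needs columns {sorted(required)}")
        c = counts["count"]
        if (c < 0).any():
            raise ValueError("negative report counts")
        if not np.array_equal(c, c.astype(int)):
            raise ValueError("non-integer report counts")
        self.counts = (
            counts.astype({"count": int})
            .groupby(["drug", "ae_term"], as_index=False)["count"]
            .sum()
            .sort_values(["drug", "ae_term"], ignore_index=True)
        )
        self.mode = mode

    @classmethod
    def from_records(cls, records: pd.DataFrame) -> "ReportTable":
        """Build from record-level rows (report_id, drug, ae_term)."""
        required = {"report_id", "drug", "ae_term"}
        if not required.issubset(records.columns):
            raise ValueError(f"record table needs columns {sorted(required)}")
        dedup = records.drop_duplicates(["report_id", "drug", "ae_term"])
        counts = (
            dedup.groupby(["drug", "ae_term"], as_index=False)
            .size()
            .rename(columns={"size": "count"})
        )
        return cls(counts, mode="record")

    @classmethod
    def from_counts(cls, counts: pd.DataFrame) -> "ReportTable":
        return cls(counts.copy(), mode="count")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ReportTable":
        """Read a TSV, auto-detecting record vs count layout from headers."""
        df = pd.read_csv(path, sep="\t", comment="#")
        if "report_id" in df.columns:
            return cls.from_records(df)
        if "count" in df.columns:
            return cls.from_counts(df)
        raise ValueError(
            f"{path}: expected record columns (report_id, drug, ae_term) or "
            "count columns (drug, ae_term, count)"
        )

    @property
    def grand_total(self) -> int:
        return int(self.counts["count"].sum())

    def drug_totals(self) -> pd.Series:
        return self.counts.groupby("drug")["count"].sum()

    def term_totals(self) -> pd.Series:
        return self.counts.groupby("ae_term")["count"].sum()

    def aggregate_contingency(self) -> pd.DataFrame:
        """One 2x2 per observed (drug, term) pair: columns a, b, c, d, N."""
        df = self.counts.rename(columns={"count": "a"}).copy()
        drug_tot = self.drug_totals()
        term_tot = self.term_totals()
        N = self.grand_total
        df["b"] = df["drug"].map(drug_tot) - df["a"]
        df["c"] = df["ae_term"].map(term_tot) - df["a"]
        df["d"] = N - df["a"] - df["b"] - df["c"]
        df["N"] = N
        return df


def prr(a: float, b: float, c: float, d: float) -> float:
    """Proportional reporting ratio of one 2x2 table.

    Undefined (NaN) when the drug has no reports (``a + b = 0``) or no other
    drug reports the term (``c = 0``): such pairs can never be retained.
    """
    if a + b == 0 or c == 0:
        return float("nan")
    return (a / (a + b)) / (c / (c + d))


def ic_with_bound(a: float, expected: float) -> tuple[float, float]:
    """Shrinkage information component and its 95% credibility lower bound.

    ``IC = log2((a + 1/2)/(E + 1/2))``;
    ``IC025 = IC - 3.3 (a + 1/2)^(-1/2) - 2 (a + 1/2)^(-3/2)``.
    The penalty is strictly positive for every finite ``a``, so IC025 < IC
    always.
    """
    if expected < 0:
        raise ValueError("expected count must be non-negative")
    a_s = a + IC_SHRINKAGE
    ic = float(np.log2(a_s / (expected + IC_SHRINKAGE)))
    ic025 = ic - IC025_C1 * a_s ** (-0.5) - IC025_C2 * a_s ** (-1.5)
    return ic, ic025


def apply_retention(
    stats: pd.DataFrame,
    prr_min: float = 2.0,
    min_reports: int = 5,
    require_ic025_positive: bool = True,
) -> pd.Series:
    """Signal-retention rule over a statistics frame (a, prr, ic025).

    Retained iff ``prr >= prr_min`` (inclusive), ``ic025 > 0`` (strict,
    when required) and ``a >= min_reports`` (inclusive).  NaN PRR (undefined:
    sole-reporter or zero-margin pairs) never passes.
    """
    keep = (stats["prr"] >= prr_min) & (stats["a"] >= min_reports)
    if require_ic025_positive:
        keep &= stats["ic025"] > 0
    return keep.fillna(False).astype(bool)


class DisproportionalityModel:
    """Disproportionality screening of a spontaneous-report table.

    Parameters
    ----------
    reports : ReportTable
        The full drug x AE table (all terms, not just the group of
        interest): the 2x2 margins are computed over everything.
    term_group : TermGroup, optional
        AE group to restrict signals to (e.g. the seizure class subtree).
        Margins still use the full table; only pairs whose term belongs to
        the group appear among the results.
    """

    def __init__(self, reports: ReportTable, term_group: TermGroup | None = None):
        self.reports = reports
        self.term_group = term_group

    @classmethod
    def from_tsv(
        cls, path: str | Path, term_group_path: str | Path | None = None
    ) -> "DisproportionalityModel":
        group = read_term_group(term_group_path) if term_group_path else None
        return cls(ReportTable.read_tsv(path), term_group=group)

    def fit(
        self,
        prr_min: float = 2.0,
        min_reports: int = 5,
        require_ic025_positive: bool = True,
    ) -> "DisproportionalityResults":
        """Compute PRR / IC / IC025 for every pair and apply retention.

        Retained iff ``PRR >= prr_min`` (inclusive), ``IC025 > 0`` when
        required (strict), and ``a >= min_reports`` (inclusive).  Pairs with
        undefined PRR are never retained.
        """
        if self.reports.grand_total == 0:
            raise ValueError("empty report table")
        df = self.reports.aggregate_contingency()
        a = df["a"].to_numpy(float)
        b = df["b"].to_numpy(float)
        c = df["c"].to_numpy(float)
        d = df["d"].to_numpy(float)
        N = df["N"].to_numpy(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            df["prr"] = np.where(
                (a + b > 0) & (c > 0), (a / (a + b)) / (c / (c + d)), np.nan
            )
        df["expected"] = (a + b) * (a + c) / N
        a_s = a + IC_SHRINKAGE
        df["ic"] = np.log2(a_s / (df["expected"] + IC_SHRINKAGE))
        df["ic025"] = df["ic"] - IC025_C1 * a_s**-0.5 - IC025_C2 * a_s**-1.5
        df["retained"] = apply_retention(
            df,
            prr_min=prr_min,
            min_reports=min_reports,
            require_ic025_positive=require_ic025_positive,
        )
        in_group = (
            df["ae_term"].map(lambda t: t in self.term_group)
            if self.term_group is not None
            else pd.Series(True, index=df.index)
        )
        df["in_group"] = in_group
        return DisproportionalityResults(
            model=self,
            signals=df,
            thresholds={
                "prr_min": prr_min,
                "min_reports": min_reports,
                "require_ic025_positive": require_ic025_positive,
            },
        )


@dataclass
class BurdenSummary:
    """Seizure-burden breakdown over retained signal pairs.

    All percentages use retained reports only; ``group_total`` is the sum
    of retained pair counts within the term group.
    """

    group_total: int
    pair_table: pd.DataFrame  # drug, ae_term, a, drug_ae_pct, pool_share
    drug_table: pd.DataFrame  # drug, seizure_reports, burden_pct, pool_share
    ae_pie: pd.DataFrame  # ae_term, reports, pie_share
    top_coverage_terms: list[str] = field(default_factory=list)
    top_by_burden: list[str] = field(default_factory=list)
    top_by_pool_share: list[str] = field(default_factory=list)

    @property
    def intersection(self) -> set[str]:
        return set(self.top_by_burden) & set(self.top_by_pool_share)


class DisproportionalityResults:
    """Fitted disproportionality screen: signal table plus summaries."""

    def __init__(
        self,
        model: DisproportionalityModel,
        signals: pd.DataFrame,
        thresholds: dict,
    ):
        self.model = model
        self.signals = signals
        self.thresholds = thresholds

    @property
    def retained(self) -> pd.DataFrame:
        """Retained pairs within the term group (if one was supplied)."""
        df = self.signals
        return df[df["retained"] & df["in_group"]].reset_index(drop=True)

    def burden(self, k: int = 10, coverage: float = 0.98) -> BurdenSummary:
        """Burden summaries over the retained in-group pairs.

        * per pair: ``drug_ae_pct`` = retained pair reports / drug total
          reports x 100 (drug total over the full table);
        * per drug: ``burden_pct`` = the drug's cumulative retained group
          reports / drug total reports x 100, and ``pool_share`` = the
          drug's retained group reports / group total x 100;
        * per AE: ``pie_share`` analogous per term;
        * ``top_coverage_terms``: the smallest prefix of terms (by
          descending total retained count, ties lexicographic) whose
          cumulative share reaches ``coverage``;
        * top-k drug lists by burden and by pool share, with deterministic
          tie-breaking (descending value, then drug name).
        """
        ret = self.retained
        if ret.empty:
            raise ValueError("nothing to summarize: no retained pairs in group")
        group_total = int(ret["a"].sum())
        drug_totals = self.model.reports.drug_totals()

        pair = ret[["drug", "ae_term", "a"]].copy()
        pair["drug_ae_pct"] = pair["a"] / pair["drug"].map(drug_totals) * 100
        pair["pool_share"] = pair["a"] / group_total * 100

        drug = (
            pair.groupby("drug", as_index=False)["a"]
            .sum()
            .rename(columns={"a": "seizure_reports"})
        )
        drug["burden_pct"] = (
            drug["seizure_reports"] / drug["drug"].map(drug_totals) * 100
        )
        drug["pool_share"] = drug["seizure_reports"] / group_total * 100

        pie = (
            pair.groupby("ae_term", as_index=False)["a"]
            .sum()
            .rename(columns={"a": "reports"})
        )
        pie["pie_share"] = pie["reports"] / group_total * 100
        pie = pie.sort_values(
            ["reports", "ae_term"], ascending=[False, True], ignore_index=True
        )

        cum = pie["pie_share"].cumsum()
        # smallest prefix whose cumulative share reaches the coverage level
        n_cov = int(np.searchsorted(cum.to_numpy(), coverage * 100 - 1e-9) + 1)
        top_coverage = pie["ae_term"].head(n_cov).tolist()

        by_burden = drug.sort_values(
            ["burden_pct", "drug"], ascending=[False, True]
        )["drug"].head(k).tolist()
        by_pool = drug.sort_values(
            ["pool_share", "drug"], ascending=[False, True]
        )["drug"].head(k).tolist()

        return BurdenSummary(
            group_total=group_total,
            pair_table=pair.sort_values(["drug", "ae_term"], ignore_index=True),
            drug_table=drug.sort_values("drug", ignore_index=True),
            ae_pie=pie,
            top_coverage_terms=top_coverage,
            top_by_burden=by_burden,
            top_by_pool_share=by_pool,
        )

    def rank_and_intersect(self, k: int = 10) -> set[str]:
        """Drugs in both top-k lists (by burden and by pool share)."""
        return self.burden(k=k).intersection

    def summary(self) -> str:
        """Text summary of the screen, statsmodels-style."""
        df = self.signals
        ret = self.retained
        lines = [
            "Disproportionality screen",
            "=========================",
            f"reports (grand total):   {self.model.reports.grand_total}",
            f"drug-AE pairs observed:  {len(df)}",
            f"thresholds:              PRR >= {self.thresholds['prr_min']}, "
            f"IC025 > 0: {self.thresholds['require_ic025_positive']}, "
            f"a >= {self.thresholds['min_reports']}",
            f"retained pairs in group: {len(ret)} "
            f"({int(ret['a'].sum()) if len(ret) else 0} reports)",
            "",
        ]
        if len(ret):
            show = ret.sort_values("ic025", ascending=False).head(15)
            lines.append(
                f"{'drug':<16} {'ae_term':<26} {'a':>6} {'PRR':>8} "
                f"{'IC':>7} {'IC025':>7}"
            )
            for r in show.itertuples(index=False):
                lines.append(
                    f"{r.drug:<16} {r.ae_term:<26} {r.a:>6d} {r.prr:>8.2f} "
                    f"{r.ic:>7.2f} {r.ic025:>7.2f}"
                )
        return "\n".join(lines)

    def write_signals_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        cols = [
            "drug", "ae_term", "a", "b", "c", "d", "expected",
            "prr", "ic", "ic025", "retained", "in_group",
        ]
        self.signals[cols].to_csv(path, sep="\t", index=False, float_format="%.6f")
        return path
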