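"""Combined red-flag report joining pharmacovigilance and in-silico evidence.

A drug is *dual-source* flagged when it both raises a pharmacovigilance
alert (at least one retained disproportionality signal in the term group)
and hits at least one in-silico profiling model; evidence from a single
source yields a *single-source* flag.  In-silico hits are consumed as data
(drug, model, fit score) — the profiler itself is outside this package.
Drug names are matched exactly after case-folding and whitespace trimming;
no fuzzy matching.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .disproportionality import DisproportionalityResults

FLAG_NONE = "none"
FLAG_SINGLE = "single-source"
FLAG_DUAL = "dual-source"


def read_hit_flags(path: str | Path) -> pd.DataFrame:
    """Read an in-silico hit table TSV (drug, model, fit_score).

    ``fit_score`` is treated as an opaque ordinal (may be empty); duplicate
    (drug, model) rows are an error.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"drug", "model"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: hit table needs columns {sorted(required)}")
    if "fit_score" not in df.columns:
        df["fit_score"] = pd.NA
    if (df["fit_score"].dropna() < 0).any():
        raise ValueError("fit_score must be non-negative when present")
    key = df["drug"].str.strip().str.lower() + "\x00" + df["model"].str.strip()
    dups = key[key.duplicated()]
    if len(dups):
        raise ValueError(f"duplicate (drug, model) rows in hit table: {len(dups)}")
    return df


def integrate_flags(
    results: DisproportionalityResults,
    hits: pd.DataFrame,
    k: int = 10,
) -> pd.DataFrame:
    """Join PV alerts with in-silico hits into the red-flag table.

    Returns one row per drug (union of both sources) with columns
    ``drug, has_pv_alert, pv_burden_rank, in_silico_models, flag_level``,
    sorted by flag level (dual > single > none) then burden rank then name.
    """
    # validate duplicates even for pre-loaded frames
    key = hits["drug"].str.strip().str.lower() + "\x00" + hits["model"].astype(str)
    if key.duplicated().any():
        raise ValueError("duplicate (drug, model) rows in hit table")

    retained = results.retained
    pv_drugs = sorted(set(retained["drug"].str.strip().str.lower()))
    try:
        burden = results.burden(k=k)
        ranked = burden.drug_table.sort_values(
            ["burden_pct", "drug"], ascending=[False, True], ignore_index=True
        )
        rank_map = {
            d.strip().lower(): i + 1 for i, d in enumerate(ranked["drug"])
        }
    except ValueError:
        rank_map = {}

    hit_models: dict[str, list[str]] = {}
    display: dict[str, str] = {}
    for r in hits.itertuples(index=False):
        name = str(r.drug).strip()
        hit_models.setdefault(name.lower(), []).append(str(r.model))
        display.setdefault(name.lower(), name)
    for r in retained.itertuples(index=False):
        display.setdefault(r.drug.strip().lower(), r.drug.strip())

    rows = []
    for drug_key in sorted(set(pv_drugs) | set(hit_models)):
        has_pv = drug_key in pv_drugs
        models = sorted(hit_models.get(drug_key, []))
        if has_pv and models:
            level = FLAG_DUAL
        elif has_pv or models:
            level = FLAG_SINGLE
        else:
            level = FLAG_NONE
        rows.append(
            {
                "drug": display[drug_key],
                "has_pv_alert": has_pv,
                "pv_burden_rank": rank_map.get(drug_key, pd.NA),
                "in_silico_models": ";".join(models),
                "flag_level": level,
            }
        )
    order = {FLAG_DUAL: 0, FLAG_SINGLE: 1, FLAG_NONE: 2}
    df = pd.DataFrame(rows)
    df["_lvl"] = df["flag_level"].map(order)
    df["_rank"] = [r if pd.notna(r) else 10**9 for r in df["pv_burden_rank"]]
    df = df.sort_values(["_lvl", "_rank", "drug"], ignore_index=True).drop(
        columns=["_lvl", "_rank"]
    )
    return df
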