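"""Presence/absence matrices, count/percentage summaries, run reports.

Percentages are rendered the way phyletic surveys print them: round half
up at one decimal, with a trailing ``.0`` trimmed — 13 of 646 genomes is
"2%", 150 of 646 is "23.2%".  A genome is BMC-positive when any of the
six pathway columns is true, counted once however many BMC types it
carries.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .config import DEFAULT_CONFIG, PipelineConfig
from .model import BmcscanError, Genome, PATHWAYS
from .pipeline import DetectionResult, detect
from . import __version__ as _pkg_version

META_COLUMNS = ["species", "phylum"]


def format_pct(k: int, n: int) -> str:
    """Percentage string with round-half-up at 1 decimal, '.0' trimmed."""
    if n <= 0:
        raise BmcscanError("denominator must be positive")
    value = (
        Decimal(100) * Decimal(k) / Decimal(n)
    ).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    if value == value.to_integral_value():
        return f"{int(value)}%"
    return f"{value}%"


def pct_value(k: int, n: int) -> float:
    """The same rounded percentage as a number (23.2 for '23.2%')."""
    return float(
        (Decimal(100) * Decimal(k) / Decimal(n)).quantize(
            Decimal("0.1"), rounding=ROUND_HALF_UP
        )
    )


def build_presence_matrix(
    genomes: list[Genome], result: DetectionResult
) -> pd.DataFrame:
    """One row per genome: six pathway columns, standalone and form columns."""
    rows = {}
    for g in genomes:
        rows[g.genome_id] = {"species": g.species, "phylum": g.phylum}
        for pw in PATHWAYS:
            rows[g.genome_id][pw] = False
    for locus in result.loci:
        if locus.pathway in PATHWAYS:
            rows[locus.genome_id][locus.pathway] = True
    for call in result.standalone:
        rows[call.genome_id].setdefault(f"standalone_{call.pathway}", False)
        rows[call.genome_id][f"standalone_{call.pathway}"] = True
    if not result.forms.empty:
        for _, r in result.forms.iterrows():
            rows[r["genome_id"]][f"form_{r['form']}"] = True
    df = pd.DataFrame.from_dict(rows, orient="index")
    with pd.option_context("future.no_silent_downcasting", True):
        df = df.fillna(False).infer_objects(copy=False)
    df.index.name = "genome_id"
    # stable column order: metadata, pathways, then the optional columns
    extra = sorted(c for c in df.columns if c not in META_COLUMNS + list(PATHWAYS))
    return df[META_COLUMNS + list(PATHWAYS) + extra]


def summarize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages per column plus the any-BMC aggregate."""
    if matrix.empty:
        raise BmcscanError("empty presence matrix")
    n = len(matrix)
    trait_cols = [c for c in matrix.columns if c not in META_COLUMNS]
    records = []
    any_bmc = matrix[list(PATHWAYS)].any(axis=1)
    records.append(
        {
            "trait": "any_BMC",
            "count": int(any_bmc.sum()),
            "total": n,
            "percent": pct_value(int(any_bmc.sum()), n),
            "percent_str": format_pct(int(any_bmc.sum()), n),
        }
    )
    for col in trait_cols:
        k = int(matrix[col].astype(bool).sum())
        records.append(
            {
                "trait": col,
                "count": k,
                "total": n,
                "percent": pct_value(k, n),
                "percent_str": format_pct(k, n),
            }
        )
    return pd.DataFrame(records, columns=["trait", "count", "total", "percent", "percent_str"])


def phylum_breakdown(matrix: pd.DataFrame) -> pd.DataFrame:
    """BMC-positive counts and percentages within each phylum."""
    if "phylum" not in matrix.columns:
        raise BmcscanError("presence matrix lacks phylum labels")
    any_bmc = matrix[list(PATHWAYS)].any(axis=1)
    records = []
    for phylum, grp in matrix.groupby("phylum", sort=True):
        if len(grp) == 0:
            continue
        k = int(any_bmc.loc[grp.index].sum())
        records.append(
            {
                "phylum": phylum,
                "positive": k,
                "genomes": len(grp),
                "percent": pct_value(k, len(grp)),
                "percent_str": format_pct(k, len(grp)),
            }
        )
    return pd.DataFrame(
        records, columns=["phylum", "positive", "genomes", "percent", "percent_str"]
    )


def run_report(
    genomes: list[Genome],
    bundle,
    config: PipelineConfig = DEFAULT_CONFIG,
    seed: int | None = None,
) -> dict:
    """Detect, classify, summarize; returns a JSON-serializable report."""
    if not genomes:
        raise BmcscanError("empty cohort")
    result = detect(genomes, bundle, config)
    matrix = build_presence_matrix(genomes, result)
    from .io import locus_table, ortholog_table, standalone_table

    report = {
        "version": _pkg_version,
        "seed": seed,
        "config": config.to_dict(),
        "n_genomes": len(genomes),
        "ortholog_calls": ortholog_table(result.calls).to_dict("records"),
        "loci": locus_table(result.loci).to_dict("records"),
        "standalone_calls": standalone_table(result.standalone).to_dict("records"),
        "forms": result.forms.to_dict("records"),
        "presence_matrix": matrix.reset_index().to_dict("records"),
        "summary": summarize(matrix).to_dict("records"),
        "phylum_breakdown": phylum_breakdown(matrix).to_dict("records"),
    }
    return report
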