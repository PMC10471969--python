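"""Full-length transcript isoform quantification from full-span reads.

Only reads overlapping both the first and last annotated exon ("full-span")
are used, so every internal exon call reflects splicing rather than
truncation.  Each full-span read yields an exon-presence bit pattern
(1 = retained, 0 = excluded); patterns are counted per allele and
normalized to proportions.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd

from .exon_usage import ExonCallSet

ISOFORM_COLUMNS = ["sample_id", "allele", "pattern", "n_reads", "proportion"]


def select_full_span(callsets: Iterable[ExonCallSet]) -> list[ExonCallSet]:
    """Keep callsets whose first and last exon are RETAINED.

    By the flanking rule an internal exon of such a read is necessarily
    RETAINED or EXCLUDED, so the surviving callsets have fully determined
    patterns.
    """
    return [cs for cs in callsets if cs.is_full_span()]


def quantify_isoforms(
    full_span: Iterable[ExonCallSet], sample_id: str
) -> pd.DataFrame:
    """Count exon-presence patterns per allele and normalize to proportions.

    Rows are ordered by allele, then descending read count, ties broken by
    pattern lexicographic order, so output is deterministic.
    """
    counts: dict[tuple[str, str], int] = {}
    for cs in full_span:
        key = (str(cs.allele), cs.pattern())
        counts[key] = counts.get(key, 0) + 1
    totals: dict[str, int] = {}
    for (allele, _), n in counts.items():
        totals[allele] = totals.get(allele, 0) + n
    rows = [
        (sample_id, allele, pattern, n, n / totals[allele])
        for (allele, pattern), n in counts.items()
    ]
    df = pd.DataFrame(rows, columns=ISOFORM_COLUMNS)
    return (
        df.sort_values(
            ["allele", "n_reads", "pattern"], ascending=[True, False, True]
        ).reset_index(drop=True)
    )


def filter_rare_isoforms(
    table: pd.DataFrame,
    min_reads: int = 1,
    min_samples: int = 1,
    hard_filter: bool = False,
) -> pd.DataFrame:
    """Flag (or drop) weakly supported isoform patterns.

    A pattern of an allele is *rare* when no single sample supports it with
    ≥ ``min_reads`` reads *and* it is seen in fewer than ``min_samples``
    samples — the signature of low-level expression or technical artifacts.
    By default rare rows are only annotated (column ``rare``); with
    ``hard_filter`` they are removed and proportions renormalized per
    (sample, allele).
    """
    if min_reads < 1:
        raise ValueError("min_reads must be ≥ 1")
    df = table.copy()
    support = df.groupby(["allele", "pattern"]).agg(
        max_reads=("n_reads", "max"), n_samples=("sample_id", "nunique")
    )
    rare_keys = set(
        support[
            (support["max_reads"] < min_reads) & (support["n_samples"] < min_samples)
        ].index
    )
    df["rare"] = [
        (allele, pattern) in rare_keys
        for allele, pattern in zip(df["allele"], df["pattern"])
    ]
    if not hard_filter:
        return df
    kept = df[~df["rare"]].drop(columns="rare").copy()
    totals = kept.groupby(["sample_id", "allele"])["n_reads"].transform("sum")
    kept["proportion"] = kept["n_reads"] / totals
    return kept.reset_index(drop=True)


def inclusion_from_isoforms(table: pd.DataFrame, allele: str) -> list[float]:
    """Pattern-weighted per-exon inclusion rates for one allele.

    Equals the retention rate computed from the same full-span reads.
    """
    sub = table[table["allele"] == allele]
    if sub.empty:
        return []
    n_exons = len(sub["pattern"].iloc[0])
    total = sub["n_reads"].sum()
    return [
        float(
            sum(
                n for pat, n in zip(sub["pattern"], sub["n_reads"]) if pat[k] == "1"
            )
            / total
        )
        for k in range(n_exons)
    ]


def write_isoforms(table: pd.DataFrame, path: str | Path) -> None:
    out = table.copy()
    out["proportion"] = out["proportion"].map(lambda p: f"{p:.6f}")
    out.to_csv(path, sep="\t", index=False)


def pattern_matrix(table: pd.DataFrame, allele: str) -> pd.DataFrame:
    """Per-pattern × per-sample proportion matrix for one allele."""
    sub = table[table["allele"] == allele]
    return sub.pivot_table(
        index="pattern", columns="sample_id", values="proportion", fill_value=0.0
    )
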