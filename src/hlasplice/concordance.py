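"""Replicate concordance of exon-retention estimates.

Given exon-usage tables from two replicate samples of the same donor, pairs
rows on (allele, exon) and summarizes the differences Bland-Altman style:
per-row retention rates from each replicate, their difference, and the mean
coverage across replicates, plus per-locus-class aggregates (mean absolute
difference and the fraction of estimates within a tolerance).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .nomenclature import AlleleName, LocusClass

DEFAULT_TOLERANCES = (0.02, 0.04)

CONCORDANCE_COLUMNS = [
    "locus_class",
    "allele",
    "exon_index",
    "mean_coverage",
    "rate_rep1",
    "rate_rep2",
    "difference",
]


class ConcordanceError(ValueError):
    """Raised when replicate tables cannot be paired."""


@dataclass
class ConcordanceSummary:
    """Paired per-(allele, exon) rates and per-class aggregates."""

    rows: pd.DataFrame
    mean_abs_diff: dict[str, float]
    fraction_within: dict[tuple[str, float], float]

    def overall_mean_abs_diff(self) -> float:
        return float(self.rows["difference"].abs().mean())


def compare_replicates(
    usage_rep1: pd.DataFrame,
    usage_rep2: pd.DataFrame,
    tolerances: Sequence[float] = DEFAULT_TOLERANCES,
) -> ConcordanceSummary:
    """Pair two usage tables on (allele, exon) and summarize rate differences.

    Only rows where both replicates pass the class read threshold and have a
    defined retention rate are aggregated.  Aggregates are reported per
    locus class; ``fraction_within`` uses |difference| ≤ tolerance.
    """
    a1 = set(usage_rep1["allele"])
    a2 = set(usage_rep2["allele"])
    if a1.isdisjoint(a2):
        raise ConcordanceError(
            f"replicate tables share no alleles (rep1: {sorted(a1)}; rep2: {sorted(a2)})"
        )
    keep = ["allele", "exon_index", "retention_rate", "n_reads_allele", "passes_threshold"]
    merged = usage_rep1[keep].merge(
        usage_rep2[keep], on=["allele", "exon_index"], suffixes=("_1", "_2")
    )
    merged = merged[
        merged["passes_threshold_1"] & merged["passes_threshold_2"]
    ].dropna(subset=["retention_rate_1", "retention_rate_2"])

    rows = pd.DataFrame(
        {
            "locus_class": [
                AlleleName.parse(a).locus_class.value for a in merged["allele"]
            ],
            "allele": merged["allele"].to_numpy(),
            "exon_index": merged["exon_index"].to_numpy(),
            "mean_coverage": (
                (merged["n_reads_allele_1"] + merged["n_reads_allele_2"]) / 2
            ).to_numpy(),
            "rate_rep1": merged["retention_rate_1"].to_numpy(),
            "rate_rep2": merged["retention_rate_2"].to_numpy(),
            "difference": (
                merged["retention_rate_1"] - merged["retention_rate_2"]
            ).to_numpy(),
        },
        columns=CONCORDANCE_COLUMNS,
    )

    mean_abs: dict[str, float] = {}
    frac_within: dict[tuple[str, float], float] = {}
    for cls, grp in rows.groupby("locus_class"):
        abs_diff = grp["difference"].abs()
        mean_abs[str(cls)] = float(abs_diff.mean())
        for tol in tolerances:
            frac_within[(str(cls), float(tol))] = float((abs_diff <= tol).mean())
    return ConcordanceSummary(rows, mean_abs, frac_within)


def aggregates_json(summary: ConcordanceSummary) -> dict:
    """JSON-serializable view of the aggregates."""
    return {
        "mean_abs_diff": summary.mean_abs_diff,
        "fraction_within": {
            f"{cls}@{tol:g}": v for (cls, tol), v in summary.fraction_within.items()
        },
        "n_rows": int(len(summary.rows)),
    }
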