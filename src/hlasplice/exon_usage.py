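"""Per-read exon status calls and allele-level exon utilization.

For each read aligned to an allele, every annotated exon is called:

* **RETAINED** — any aligned block overlaps the exon by at least one base;
* **EXCLUDED** — no overlap, *and* some exon 5' of it and some exon 3' of it
  are retained, so the read demonstrably spans the exon's position and the
  absence is splicing rather than truncation;
* **UNASSESSED** — no overlap and no retained flank on one side (the read is
  5'- or 3'-truncated relative to this exon and carries no splicing
  information for it).

Truncation is pervasive in oligo(dT)-primed nanopore cDNA (reads lose their
5' ends), so distinguishing EXCLUDED from UNASSESSED is what keeps the
exon-retention statistic unbiased.  The retention rate for an exon is
``retained / (retained + excluded)`` over an allele's reads; alleles enter
the analysis only with ≥20 reads (class I) or ≥10 reads (class II).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .alignment import AlignedRead
from .nomenclature import AlleleName, LocusClass
from .reference import AlleleReference, ReferenceBundle

#: Minimum reads for an allele to enter the analysis, by locus class.
READ_THRESHOLDS: dict[LocusClass, int] = {
    LocusClass.CLASS_I: 20,
    LocusClass.CLASS_II: 10,
}

USAGE_COLUMNS = [
    "sample_id",
    "allele",
    "exon_index",
    "n_retained",
    "n_excluded",
    "n_unassessed",
    "retention_rate",
    "n_reads_allele",
    "passes_threshold",
]


class ExonStatus(str, Enum):
    RETAINED = "RETAINED"
    EXCLUDED = "EXCLUDED"
    UNASSESSED = "UNASSESSED"


@dataclass(frozen=True)
class ExonCallSet:
    """Per-exon status calls for one read against one allele."""

    read_id: str
    allele: AlleleName
    calls: tuple[ExonStatus, ...]

    def is_full_span(self) -> bool:
        """True if the read overlaps both terminal exons (no 5'/3' truncation)."""
        return (
            self.calls[0] is ExonStatus.RETAINED
            and self.calls[-1] is ExonStatus.RETAINED
        )

    def pattern(self) -> str:
        """Bit string over exons (1 retained / 0 excluded); full-span reads only."""
        if not self.is_full_span():
            raise ValueError(f"{self.read_id}: pattern undefined for truncated read")
        return "".join("1" if c is ExonStatus.RETAINED else "0" for c in self.calls)


def call_exons(read: AlignedRead, allele: AlleleReference) -> ExonCallSet:
    """Call RETAINED / EXCLUDED / UNASSESSED for each exon of ``allele``.

    An exon is retained on any ≥1-base overlap with an aligned block;
    excluded only when flanked by retained exons on both sides; otherwise
    unassessed.
    """
    if read.allele != allele.name:
        raise ValueError(
            f"read {read.read_id} aligned to {read.allele}, not {allele.name}"
        )
    if read.blocks[-1][1] > len(allele.sequence):
        raise ValueError(
            f"read {read.read_id} blocks exceed {allele.name} length"
        )
    overlapped = [
        any(bs < end and be > start for bs, be in read.blocks)
        for start, end in allele.exons
    ]
    retained_idx = [i for i, o in enumerate(overlapped) if o]
    calls = []
    for i, o in enumerate(overlapped):
        if o:
            calls.append(ExonStatus.RETAINED)
        elif retained_idx and retained_idx[0] < i < retained_idx[-1]:
            calls.append(ExonStatus.EXCLUDED)
        else:
            calls.append(ExonStatus.UNASSESSED)
    return ExonCallSet(read.read_id, allele.name, tuple(calls))


def call_exons_bulk(
    reads: Iterable[AlignedRead], bundle: ReferenceBundle
) -> list[ExonCallSet]:
    """Call exons for every read against its bundle allele."""
    by_name = {str(a.name): a for a in bundle.alleles}
    return [call_exons(r, by_name[str(r.allele)]) for r in reads]


def aggregate_usage(
    callsets: Iterable[ExonCallSet],
    bundle: ReferenceBundle,
    sample_id: str,
    denominator: Literal["assessable", "all"] = "assessable",
) -> pd.DataFrame:
    """Aggregate per-read calls to a per-(allele, exon) usage table.

    One row per annotated exon of every bundle allele, even for alleles with
    no reads or below the class read threshold (``passes_threshold`` marks
    the latter).  ``retention_rate`` divides by retained+excluded reads by
    default; ``denominator="all"`` divides by all reads assigned to the
    allele instead (a sensitivity mode — truncated reads then count against
    retention).
    """
    counts: dict[tuple[str, int], np.ndarray] = {
        (str(a.name), k): np.zeros(3, dtype=int)
        for a in bundle.alleles
        for k in range(a.n_exons)
    }
    n_reads: dict[str, int] = {str(a.name): 0 for a in bundle.alleles}
    order = [ExonStatus.RETAINED, ExonStatus.EXCLUDED, ExonStatus.UNASSESSED]
    for cs in callsets:
        key = str(cs.allele)
        if key not in n_reads:
            raise KeyError(f"callset allele {key} not in bundle {bundle.sample_id}")
        n_reads[key] += 1
        for k, status in enumerate(cs.calls):
            counts[(key, k)][order.index(status)] += 1

    rows = []
    for a in bundle.alleles:
        key = str(a.name)
        threshold = READ_THRESHOLDS[a.locus_class]
        for k in range(a.n_exons):
            n_ret, n_exc, n_un = counts[(key, k)]
            denom = n_ret + n_exc if denominator == "assessable" else n_reads[key]
            rate = n_ret / denom if denom > 0 else np.nan
            rows.append(
                (
                    sample_id, key, k + 1, int(n_ret), int(n_exc), int(n_un),
                    rate, n_reads[key], n_reads[key] >= threshold,
                )
            )
    return pd.DataFrame(rows, columns=USAGE_COLUMNS)


@dataclass
class SnpPartition:
    """Exon retention rates partitioned by a splice-site SNP genotype.

    ``table`` has one row per (sample, allele) with its genotype symbol at
    the SNP, the donor's zygosity over both alleles, and the retention rate
    for the chosen exon.  ``medians`` maps genotype symbol → median rate;
    ``medians_by_zygosity`` maps (zygosity, symbol) → median rate.
    """

    exon_index: int
    table: pd.DataFrame
    medians: dict[str, float]
    medians_by_zygosity: dict[tuple[str, str], float]
    ungrouped: list[tuple[str, str]]


def partition_by_snp(
    usage: pd.DataFrame,
    snp_map: Mapping[tuple[str, str], str],
    exon_index: int,
) -> SnpPartition:
    """Group per-allele retention rates for one exon by splice-site genotype.

    ``snp_map`` maps (sample_id, allele) → "G" (acceptor intact) or "A"
    (acceptor lost), as for rs28688207 upstream of HLA-DQB1 exon 5.  Donor
    zygosity is derived from the sample's mapped alleles ("AG" heterozygous,
    "AA"/"GG" homozygous).  Alleles absent from the map go to ``ungrouped``.
    """
    sub = usage[(usage["exon_index"] == exon_index) & usage["passes_threshold"]]
    zygosity_by_sample: dict[str, str] = {}
    for sample in sub["sample_id"].unique():
        symbols = sorted(
            {v for (s, _a), v in snp_map.items() if s == sample}
        )
        zygosity_by_sample[sample] = "".join(symbols) * (2 // max(len(symbols), 1))
    rows = []
    ungrouped = []
    for _, row in sub.iterrows():
        key = (row["sample_id"], row["allele"])
        symbol = snp_map.get(key)
        if symbol is None:
            ungrouped.append(key)
            continue
        rows.append(
            (
                row["sample_id"], row["allele"], symbol,
                zygosity_by_sample.get(row["sample_id"], symbol * 2),
                row["retention_rate"],
            )
        )
    table = pd.DataFrame(
        rows, columns=["sample_id", "allele", "genotype", "zygosity", "retention_rate"]
    ).dropna(subset=["retention_rate"])
    medians = {
        g: float(grp["retention_rate"].median())
        for g, grp in table.groupby("genotype")
    }
    medians_by_zyg = {
        (z, g): float(grp["retention_rate"].median())
        for (z, g), grp in table.groupby(["zygosity", "genotype"])
    }
    return SnpPartition(exon_index, table, medians, medians_by_zyg, ungrouped)


def write_usage(usage: pd.DataFrame, path: str | Path) -> None:
    """Write a usage table as a diffable TSV (6-decimal fixed-point rates)."""
    out = usage.copy()
    out["retention_rate"] = out["retention_rate"].map(
        lambda r: "" if pd.isna(r) else f"{r:.6f}"
    )
    out.to_csv(path, sep="\t", index=False)


def read_usage(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"allele": str})
    df["retention_rate"] = pd.to_numeric(df["retention_rate"], errors="coerce")
    df["passes_threshold"] = df["passes_threshold"].astype(bool)
    return df[USAGE_COLUMNS]


def locus_medians(usage: pd.DataFrame) -> dict[str, float]:
    """Median per-(allele, exon) retention rate by locus, threshold-passing rows only."""
    sub = usage[usage["passes_threshold"]].dropna(subset=["retention_rate"]).copy()
    sub["locus"] = sub["allele"].str.split("*").str[0]
    return {
        locus: float(grp["retention_rate"].median())
        for locus, grp in sub.groupby("locus")
    }


def write_locus_medians(usage: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(locus_medians(usage), fh, indent=2, sort_keys=True)
        fh.write("\n")
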