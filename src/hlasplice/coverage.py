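"""Per-allele depth, breadth-at-depth summaries, and gene-body coverage profiles.

Depth is computed over the full genomic allele reference (introns included),
so breadth figures are not inflated by exon-only coverage.  Gene-body
profiles length-normalize each allele's depth into percentile bins and scale
to the allele's own maximum, making 3'-bias visible across alleles with very
different expression levels — the characteristic signature of oligo(dT)
priming and read truncation in nanopore cDNA.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .alignment import AlignedRead
from .nomenclature import AlleleName
from .reference import AlleleReference

DEFAULT_THRESHOLDS = (10, 25, 50, 75, 100)

BREADTH_COLUMNS = ["sample_id", "allele", "threshold", "fraction_at_depth", "meets_90pct"]


@dataclass(frozen=True)
class CoverageProfile:
    """Per-position read depth over one allele's reference."""

    allele: AlleleName
    depth: np.ndarray
    n_reads: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "depth", np.asarray(self.depth, dtype=np.int64))


def compute_depth(
    reads: Iterable[AlignedRead], allele: AlleleReference
) -> CoverageProfile:
    """Depth[i] = number of aligned blocks covering position i."""
    length = len(allele.sequence)
    diff = np.zeros(length + 1, dtype=np.int64)
    n = 0
    for read in reads:
        if read.allele != allele.name:
            raise ValueError(f"read {read.read_id} not aligned to {allele.name}")
        n += 1
        for start, end in read.blocks:
            if not 0 <= start < end <= length:
                raise ValueError(
                    f"read {read.read_id}: block [{start},{end}) outside "
                    f"{allele.name} (length {length})"
                )
            diff[start] += 1
            diff[end] -= 1
    return CoverageProfile(allele.name, np.cumsum(diff[:-1]), n)


def breadth_at(
    profile: CoverageProfile,
    thresholds: Sequence[int] = DEFAULT_THRESHOLDS,
    breadth_cut: float = 0.9,
    sample_id: str = "",
) -> pd.DataFrame:
    """Fraction of positions with depth ≥ X per threshold X, with a 90%-breadth flag."""
    if any(t <= 0 for t in thresholds):
        raise ValueError("thresholds must be positive")
    depth = profile.depth
    rows = []
    for x in thresholds:
        frac = float(np.mean(depth >= x)) if depth.size else 0.0
        rows.append((sample_id, str(profile.allele), int(x), frac, frac >= breadth_cut))
    return pd.DataFrame(rows, columns=BREADTH_COLUMNS)


def breadth_summary(
    profiles: Iterable[CoverageProfile],
    thresholds: Sequence[int] = DEFAULT_THRESHOLDS,
    breadth_cut: float = 0.9,
    sample_id: str = "",
) -> pd.DataFrame:
    """Concatenated breadth rows for many alleles (one sample)."""
    frames = [breadth_at(p, thresholds, breadth_cut, sample_id) for p in profiles]
    if not frames:
        return pd.DataFrame(columns=BREADTH_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def percent_alleles_meeting(
    breadth: pd.DataFrame,
) -> pd.DataFrame:
    """Per-locus percentage of alleles meeting the breadth cut at each threshold.

    Reproduces the layout of a per-locus coverage summary table: rows are
    loci, columns are depth thresholds, values are percentages of (sample,
    allele) entries whose breadth flag is set.
    """
    df = breadth.copy()
    df["locus"] = df["allele"].str.split("*").str[0]
    out = (
        df.groupby(["locus", "threshold"])["meets_90pct"]
        .mean()
        .mul(100.0)
        .unstack("threshold")
    )
    out.columns = [f"{int(c)}X" for c in out.columns]
    return out


def _bin_normalize(depth: np.ndarray, n_bins: int) -> np.ndarray | None:
    """Mean depth within n_bins equal-width position bins, scaled to own max."""
    if depth.size == 0 or depth.max() == 0:
        return None
    edges = np.linspace(0, depth.size, n_bins + 1).astype(int)
    binned = np.array(
        [depth[edges[i]: edges[i + 1]].mean() if edges[i + 1] > edges[i] else 0.0
         for i in range(n_bins)]
    )
    return binned / binned.max()


def gene_body_profile(
    profiles: Iterable[CoverageProfile], n_bins: int = 100
) -> pd.DataFrame:
    """Binned, max-scaled coverage profiles aggregated across alleles.

    Returns per-bin median and the inner 50% (p25-p75) and inner 90%
    (p5-p95) bands.  Zero or empty profiles are skipped.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be ≥ 2")
    normalized = []
    for p in profiles:
        b = _bin_normalize(p.depth, n_bins)
        if b is None:
            import logging
            logging.getLogger(__name__).warning(
                "skipping zero-coverage profile for %s", p.allele
            )
            continue
        normalized.append(b)
    if not normalized:
        return pd.DataFrame(
            columns=["bin", "median", "p25", "p75", "p5", "p95"]
        )
    mat = np.vstack(normalized)
    return pd.DataFrame(
        {
            "bin": np.arange(n_bins),
            "median": np.median(mat, axis=0),
            "p25": np.percentile(mat, 25, axis=0),
            "p75": np.percentile(mat, 75, axis=0),
            "p5": np.percentile(mat, 5, axis=0),
            "p95": np.percentile(mat, 95, axis=0),
        }
    )


def three_prime_bias(
    profile: CoverageProfile, tail_fraction: float = 0.2
) -> float:
    """Mean depth over the 3'-most tail divided by the 5'-most tail.

    Returns NaN when the 5' tail has zero mean (ratio undefined).  A flat
    profile gives 1.0; 3'-biased coverage gives > 1.
    """
    if not 0 < tail_fraction <= 0.5:
        raise ValueError("tail_fraction must be in (0, 0.5]")
    depth = profile.depth
    k = max(1, int(round(depth.size * tail_fraction)))
    head = float(depth[:k].mean())
    tail = float(depth[-k:].mean())
    if head == 0.0:
        return float("nan")
    return tail / head
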