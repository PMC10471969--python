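"""Synthetic allele databases and spliced long-read simulation.

Emulates the statistical structure of oligo(dT)-primed nanopore cDNA
sequencing of HLA transcripts:

* **isoform mixtures** — each read draws an exon-presence pattern from a
  per-allele categorical mixture (e.g. 72% all-exons / 28% skip-exon-5 for
  a DQB1-like allele with an intact splice acceptor);
* **5' truncation** — with a configurable probability a read keeps only a
  geometric-tailed 3' portion of its transcript, producing the 3' coverage
  bias characteristic of oligo(dT) priming and in-sequencing truncation;
* **cross-allele contamination** — a small fraction of reads is emitted
  under the label of the other same-locus allele, mimicking misalignment
  between near-identical alleles.

Reads are emitted both as a perfect spliced SAM (intron/skip gaps as N
operations; tests downstream logic independent of any aligner) and as FASTQ
with optional substitution errors (feeds the external-aligner wrapper),
together with a per-read truth table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .nomenclature import AlleleName
from .reference import AlleleReference

TRUTH_COLUMNS = [
    "read_id",
    "true_allele",
    "aligned_allele",
    "true_pattern",
    "truncation_point",
    "contaminated",
]

_BASES = np.array(list("ACGT"))


class SimConfigError(ValueError):
    """Raised for inconsistent simulation configurations."""


@dataclass
class SimConfig:
    """Configuration for the toy database and read simulator.

    Parameters
    ----------
    seed
        Single seed for all randomness.
    alleles
        List of (allele name string, exon lengths, intron lengths); intron
        list is one shorter than the exon list.
    isoform_mixtures
        allele name → {pattern bit string → probability}; each mixture sums
        to 1 and every pattern has terminal bits set (a transcript always
        contains the first and last exon).
    n_reads
        allele name → number of reads to simulate.
    truncation_rate
        Probability a read is 5'-truncated.
    truncation_geom_p
        Geometric parameter for the retained 3' exonic length of truncated
        reads (mean retained length = 1/p).
    contamination_rate
        Probability a read is emitted under the other same-locus allele's
        label (requires a same-locus partner with the same exon count).
    per_base_error
        Substitution rate applied to FASTQ output only; the SAM stays
        perfect.
    divergence
        Number of substitutions distinguishing same-locus alleles that share
        an exon/intron layout.
    n_decoy_reads
        Extra random (non-HLA) reads written to the FASTQ only, for
        exercising candidate-read selection.
    """

    seed: int
    alleles: list[tuple[str, tuple[int, ...], tuple[int, ...]]]
    isoform_mixtures: Mapping[str, Mapping[str, float]]
    n_reads: Mapping[str, int]
    truncation_rate: float = 0.0
    truncation_geom_p: float = 1.0 / 800.0
    contamination_rate: float = 0.0
    per_base_error: float = 0.0
    divergence: int = 20
    n_decoy_reads: int = 0
    decoy_length: int = 500

    def __post_init__(self) -> None:
        if not self.alleles:
            raise SimConfigError("config lists no alleles")
        for name, exon_lengths, intron_lengths in self.alleles:
            AlleleName.parse(name)
            if not exon_lengths or any(x <= 0 for x in exon_lengths):
                raise SimConfigError(f"{name}: exon lengths must be positive")
            if any(x <= 0 for x in intron_lengths):
                raise SimConfigError(f"{name}: intron lengths must be positive")
            if len(intron_lengths) != len(exon_lengths) - 1:
                raise SimConfigError(
                    f"{name}: need {len(exon_lengths) - 1} introns, "
                    f"got {len(intron_lengths)}"
                )
        n_exons = {name: len(ex) for name, ex, _ in self.alleles}
        for allele, mixture in self.isoform_mixtures.items():
            if allele not in n_exons:
                raise SimConfigError(f"mixture for unknown allele {allele}")
            total = sum(mixture.values())
            if abs(total - 1.0) > 1e-9:
                raise SimConfigError(f"{allele}: mixture sums to {total}, not 1")
            for pattern in mixture:
                if len(pattern) != n_exons[allele]:
                    raise SimConfigError(
                        f"{allele}: pattern {pattern} length != exon count"
                    )
                if set(pattern) - {"0", "1"} or pattern[0] != "1" or pattern[-1] != "1":
                    raise SimConfigError(
                        f"{allele}: pattern {pattern} must be binary with terminal 1s"
                    )
        for rate_name in ("truncation_rate", "contamination_rate", "per_base_error"):
            rate = getattr(self, rate_name)
            if not 0.0 <= rate <= 1.0:
                raise SimConfigError(f"{rate_name}={rate} outside [0,1]")
        if not 0.0 < self.truncation_geom_p <= 1.0:
            raise SimConfigError("truncation_geom_p must be in (0,1]")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "alleles": [
                [name, list(ex), list(intr)] for name, ex, intr in self.alleles
            ],
            "isoform_mixtures": {
                a: dict(m) for a, m in self.isoform_mixtures.items()
            },
            "n_reads": dict(self.n_reads),
            "truncation_rate": self.truncation_rate,
            "truncation_geom_p": self.truncation_geom_p,
            "contamination_rate": self.contamination_rate,
            "per_base_error": self.per_base_error,
            "divergence": self.divergence,
            "n_decoy_reads": self.n_decoy_reads,
            "decoy_length": self.decoy_length,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            payload = json.load(fh)
        payload["alleles"] = [
            (name, tuple(ex), tuple(intr)) for name, ex, intr in payload["alleles"]
        ]
        return cls(**payload)


def make_toy_db(config: SimConfig) -> list[AlleleReference]:
    """Generate seeded random allele sequences with the configured layouts.

    Same-locus alleles sharing an exon/intron layout are copies of the first
    allele's sequence with ``config.divergence`` random substitutions, so
    they are near-identical the way real HLA allele pairs are.
    """
    rng = np.random.default_rng(config.seed)
    refs: list[AlleleReference] = []
    base_seq: dict[tuple[str, tuple, tuple], np.ndarray] = {}
    for name_str, exon_lengths, intron_lengths in config.alleles:
        name = AlleleName.parse(name_str)
        total = sum(exon_lengths) + sum(intron_lengths)
        layout_key = (name.locus, tuple(exon_lengths), tuple(intron_lengths))
        if layout_key in base_seq:
            seq = base_seq[layout_key].copy()
            k = min(config.divergence, total)
            pos = rng.choice(total, size=k, replace=False)
            for p in pos:
                choices = [b for b in "ACGT" if b != seq[p]]
                seq[p] = choices[rng.integers(len(choices))]
        else:
            seq = rng.choice(_BASES, size=total)
            base_seq[layout_key] = seq.copy()
        exons = []
        pos = 0
        for i, ex_len in enumerate(exon_lengths):
            exons.append((pos, pos + ex_len))
            pos += ex_len
            if i < len(intron_lengths):
                pos += intron_lengths[i]
        refs.append(AlleleReference(name, "".join(seq), tuple(exons)))
    return refs


@dataclass
class SimOutput:
    """Paths and truth table produced by :func:`simulate_reads`."""

    sam_path: Path
    fastq_path: Path
    truth_path: Path
    truth: pd.DataFrame


def _contamination_partner(
    ref: AlleleReference, db: Sequence[AlleleReference]
) -> AlleleReference | None:
    for other in db:
        if (
            other.name.locus == ref.name.locus
            and other.name != ref.name
            and other.n_exons == ref.n_exons
        ):
            return other
    return None


def _read_blocks(
    ref: AlleleReference, pattern: str, retained_3p: int | None
) -> list[tuple[int, int]]:
    """Aligned blocks for a pattern, optionally 5'-truncated.

    ``retained_3p`` is the number of exonic bases kept from the 3' end; the
    5' remainder (including whole exons) is dropped.
    """
    blocks = [ref.exons[k] for k, bit in enumerate(pattern) if bit == "1"]
    if retained_3p is None:
        return blocks
    kept: list[tuple[int, int]] = []
    remaining = retained_3p
    for start, end in reversed(blocks):
        size = end - start
        if remaining >= size:
            kept.append((start, end))
            remaining -= size
        else:
            kept.append((end - remaining, end))
            remaining = 0
        if remaining == 0:
            break
    return list(reversed(kept))


def _cigar(blocks: Sequence[tuple[int, int]]) -> str:
    parts = []
    for i, (start, end) in enumerate(blocks):
        if i > 0:
            parts.append(f"{start - blocks[i - 1][1]}N")
        parts.append(f"{end - start}M")
    return "".join(parts)


def simulate_reads(
    config: SimConfig, db: Sequence[AlleleReference], out_dir: str | Path
) -> SimOutput:
    """Simulate spliced reads per the configured mixtures; write SAM/FASTQ/truth.

    The SAM holds perfect alignments (blocks = retained exon intervals,
    introns and skipped exons as N), coordinate-sorted; contaminated reads
    appear under the partner allele's name with the partner's coordinates.
    The truth TSV has one row per read.
    """
    rng = np.random.default_rng(config.seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    by_name = {str(a.name): a for a in db}
    for allele in config.n_reads:
        if allele not in by_name:
            raise SimConfigError(f"n_reads references unknown allele {allele}")

    sam_records: list[tuple[str, int, str, str, str]] = []  # ref, pos, qname, cigar, seq
    fastq_records: list[tuple[str, str]] = []
    truth_rows: list[tuple] = []

    for allele_str in sorted(config.n_reads):
        ref = by_name[allele_str]
        mixture = config.isoform_mixtures.get(allele_str)
        if mixture is None:
            raise SimConfigError(f"no isoform mixture for {allele_str}")
        patterns = sorted(mixture)
        probs = np.array([mixture[p] for p in patterns])
        partner = _contamination_partner(ref, db)
        n = int(config.n_reads[allele_str])
        safe = allele_str.replace("*", "_").replace(":", "-")
        for i in range(n):
            pattern = patterns[rng.choice(len(patterns), p=probs)]
            contaminated = (
                partner is not None and rng.random() < config.contamination_rate
            )
            target = partner if contaminated else ref
            retained_3p: int | None = None
            if rng.random() < config.truncation_rate:
                retained_3p = int(rng.geometric(config.truncation_geom_p))
            blocks = _read_blocks(target, pattern, retained_3p)
            seq = "".join(target.sequence[s:e] for s, e in blocks)
            read_id = f"sim_{safe}_{i:05d}"
            sam_records.append(
                (str(target.name), blocks[0][0], read_id, _cigar(blocks), seq)
            )
            fastq_seq = _mutate(seq, config.per_base_error, rng)
            fastq_records.append((read_id, fastq_seq))
            truth_rows.append(
                (
                    read_id,
                    allele_str,
                    str(target.name),
                    pattern,
                    blocks[0][0] if retained_3p is not None else "",
                    contaminated,
                )
            )

    for j in range(config.n_decoy_reads):
        seq = "".join(rng.choice(_BASES, size=config.decoy_length))
        read_id = f"decoy_{j:05d}"
        fastq_records.append((read_id, seq))
        truth_rows.append((read_id, "decoy", "", "", "", False))

    sam_path = out / "simulated.sam"
    ref_order = sorted(by_name)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [
            {"SN": name, "LN": len(by_name[name].sequence)} for name in ref_order
        ],
    }
    sam_records.sort(key=lambda r: (ref_order.index(r[0]), r[1], r[2]))
    with pysam.AlignmentFile(str(sam_path), "w", header=header) as af:
        for ref_name, pos, qname, cigar, seq in sam_records:
            rec = pysam.AlignedSegment(af.header)
            rec.query_name = qname
            rec.reference_name = ref_name
            rec.reference_start = pos
            rec.cigarstring = cigar
            rec.query_sequence = seq
            rec.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            rec.mapping_quality = 60
            rec.flag = 0
            af.write(rec)

    fastq_path = out / "simulated.fastq"
    with open(fastq_path, "w") as fh:
        for read_id, seq in fastq_records:
            fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")

    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    truth_path = out / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    return SimOutput(sam_path, fastq_path, truth_path, truth)


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0.0 or not seq:
        return seq
    arr = np.array(list(seq))
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    for p in hits:
        choices = [b for b in "ACGT" if b != arr[p]]
        arr[p] = choices[rng.integers(len(choices))]
    return "".join(arr)
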