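"""Aligned-block extraction from spliced alignments, and the two-pass aligner wrapper.

A spliced cDNA alignment encodes which parts of the reference a read covers:
match/mismatch and deletion operations consume reference inside a contiguous
block, while N (intron skip) operations split blocks.  All downstream exon
logic works on these reference-coordinate blocks, so it is agnostic to how
the SAM was produced — the external-aligner wrapper here is strictly
optional plumbing.
"""

from __future__ import annotations

import logging
import re
import shutil
import subprocess
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pysam

from .nomenclature import AlleleName
from .reference import ReferenceBundle

logger = logging.getLogger(__name__)

Interval = tuple[int, int]

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_REF_CONSUMING = set("MDN=X")


class CigarError(ValueError):
    """Raised for malformed CIGAR strings."""


class AlignmentIOError(RuntimeError):
    """Raised for unreadable alignment files or reference mismatches."""


@dataclass(frozen=True)
class AlignedRead:
    """One read's reference-coordinate aligned blocks.

    ``blocks`` are 0-based half-open intervals, sorted, non-overlapping, with
    gaps corresponding exclusively to intron (N) skips.
    """

    read_id: str
    allele: AlleleName
    blocks: tuple[Interval, ...]
    is_primary: bool = True
    mapq: int = 0

    def __post_init__(self) -> None:
        prev_end = None
        for start, end in self.blocks:
            if end <= start:
                raise ValueError(f"{self.read_id}: empty block [{start},{end})")
            if prev_end is not None and start < prev_end:
                raise ValueError(f"{self.read_id}: blocks overlap or unsorted")
            prev_end = end

    @property
    def reference_span(self) -> Interval:
        return (self.blocks[0][0], self.blocks[-1][1])


def parse_cigar(cigar: str | Sequence[tuple[str, int]]) -> list[tuple[str, int]]:
    """Normalize a CIGAR string or (op, length) sequence to an op list."""
    if isinstance(cigar, str):
        ops = [(m.group(2), int(m.group(1))) for m in _CIGAR_RE.finditer(cigar)]
        if "".join(f"{n}{op}" for op, n in ops) != cigar:
            raise CigarError(f"invalid CIGAR string {cigar!r}")
        return ops
    out = []
    for op, n in cigar:
        if op not in "MIDNSHP=X":
            raise CigarError(f"invalid CIGAR operation {op!r}")
        out.append((op, int(n)))
    return out


def blocks_from_cigar(
    ref_start: int, cigar: str | Sequence[tuple[str, int]]
) -> list[Interval]:
    """Reference-coordinate aligned blocks implied by a CIGAR.

    M/=/X and D advance the reference within the current block; N closes the
    block and opens a new one past the skip; I/S/H/P consume no reference.
    A zero-length skip (or zero-length leading block) never yields an empty
    block: adjacent blocks merge across zero-length gaps.
    """
    if ref_start < 0:
        raise CigarError(f"negative reference start {ref_start}")
    blocks: list[Interval] = []
    block_start = ref_start
    pos = ref_start
    for op, n in parse_cigar(cigar):
        if op in "M=XD":
            pos += n
        elif op == "N":
            if pos > block_start:
                blocks.append((block_start, pos))
            pos += n
            block_start = pos
        # I, S, H, P: no reference consumed
    if pos > block_start:
        blocks.append((block_start, pos))
    # merge blocks separated by zero-length skips
    merged: list[Interval] = []
    for start, end in blocks:
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(end, merged[-1][1]))
        else:
            merged.append((start, end))
    return [tuple(b) for b in merged]


def load_alignments(
    sam_path: str | Path,
    bundle: ReferenceBundle,
    min_mapq: int = 0,
) -> list[AlignedRead]:
    """Extract primary, mapped, non-supplementary records as AlignedReads.

    Secondary and supplementary alignments are dropped so each molecule
    contributes a single exon pattern.  Reads aligned to references absent
    from the bundle are dropped with a logged count.  No MAPQ filter is
    applied by default.
    """
    bundle_names = set(bundle.names())
    reads: list[AlignedRead] = []
    n_foreign = 0
    try:
        af = pysam.AlignmentFile(str(sam_path), check_sq=False)
    except (OSError, ValueError) as exc:
        raise AlignmentIOError(f"cannot read {sam_path}: {exc}") from exc
    with af:
        for rec in af.fetch(until_eof=True):
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.mapping_quality < min_mapq:
                continue
            ref_name = rec.reference_name
            if ref_name not in bundle_names:
                n_foreign += 1
                continue
            allele = bundle.allele(ref_name)
            blocks = blocks_from_cigar(rec.reference_start, rec.cigarstring or "")
            if not blocks:
                continue
            if blocks[-1][1] > len(allele.sequence):
                raise AlignmentIOError(
                    f"{rec.query_name}: alignment extends past end of {ref_name}"
                )
            reads.append(
                AlignedRead(
                    read_id=rec.query_name,
                    allele=allele.name,
                    blocks=tuple(blocks),
                    is_primary=True,
                    mapq=rec.mapping_quality,
                )
            )
    if n_foreign:
        logger.warning(
            "%s: dropped %d reads aligned to references not in bundle %s",
            sam_path, n_foreign, bundle.sample_id,
        )
    return reads


def run_two_pass_alignment(
    reads_fastq: str | Path,
    cds_fasta: str | Path,
    bundle_fasta: str | Path,
    junc_bed: str | Path,
    out_dir: str | Path,
    aligner: str = "minimap2",
    threads: int = 1,
) -> Path:
    """Two-pass spliced alignment: CDS screen, then donor-specific realignment.

    Pass 1 aligns all reads to the HLA coding sequences in spliced long-read
    mode with secondary alignments suppressed; any read with a primary
    alignment becomes a candidate.  Pass 2 realigns only candidates to the
    per-sample genomic reference with junction hints.  Returns the pass-2
    SAM path.  This is a thin subprocess wrapper; downstream logic works
    identically on externally supplied SAM.
    """
    if shutil.which(aligner) is None:
        raise AlignmentIOError(f"spliced aligner {aligner!r} not found on PATH")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pass1_sam = out / "pass1.cds.sam"
    candidates_fq = out / "candidates.fastq"
    pass2_sam = out / "pass2.donor.sam"

    def _run(cmd: list[str], sam_out: Path) -> None:
        with open(sam_out, "w") as fh:
            proc = subprocess.run(
                cmd, stdout=fh, stderr=subprocess.PIPE, text=True
            )
        if proc.returncode != 0:
            raise AlignmentIOError(
                f"{' '.join(cmd)} failed (exit {proc.returncode}):\n{proc.stderr}"
            )

    base = [aligner, "-a", "-x", "splice", "--secondary=no", "-t", str(threads)]
    _run(base + [str(cds_fasta), str(reads_fastq)], pass1_sam)

    candidate_ids = set()
    with pysam.AlignmentFile(str(pass1_sam), check_sq=False) as af:
        for rec in af.fetch(until_eof=True):
            if not rec.is_unmapped:
                candidate_ids.add(rec.query_name)

    n_written = _filter_fastq(reads_fastq, candidate_ids, candidates_fq)
    if n_written == 0:
        logger.warning("no candidate HLA reads in %s; emitting empty SAM", reads_fastq)
        with pysam.AlignmentFile(str(pass1_sam), check_sq=False) as af:
            header = af.header
        with open(pass2_sam, "w") as fh:
            fh.write(str(header))
        return pass2_sam

    _run(
        base + ["--junc-bed", str(junc_bed), str(bundle_fasta), str(candidates_fq)],
        pass2_sam,
    )
    return pass2_sam


def _filter_fastq(src: str | Path, keep_ids: set[str], dst: Path) -> int:
    n = 0
    with open(src) as fin, open(dst, "w") as fout:
        while True:
            header = fin.readline()
            if not header:
                break
            rest = [fin.readline() for _ in range(3)]
            parts = header[1:].split()
            rid = parts[0] if parts else ""
            if rid in keep_ids:
                fout.write(header)
                fout.writelines(rest)
                n += 1
    return n
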