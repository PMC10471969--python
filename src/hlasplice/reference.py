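"""Donor-specific HLA reference construction.

The pipeline aligns reads to *genomic* allele sequences (exons and introns)
rather than to a universal genome, because HLA loci are too polymorphic for a
single reference.  This module parses an allele database serialized as
FASTA (genomic sequence per allele, record ID = full allele name) plus a
BED6 file of exon intervals, resolves each donor's typed alleles to
full-resolution database alleles, and writes per-sample reference bundles
(FASTA + exon BED + a BED12 junction file usable as spliced-aligner junction
hints).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .nomenclature import (
    AlleleName,
    AlleleResolutionError,
    LocusClass,
    lowest_consistent,
)

Interval = tuple[int, int]


class ReferenceValidationError(ValueError):
    """Raised for inconsistent allele database content."""


@dataclass(frozen=True)
class AlleleReference:
    """One HLA allele: genomic plus-strand sequence with ordered exon intervals.

    Exon coordinates are 0-based half-open on the allele's own sequence.
    """

    name: AlleleName
    sequence: str
    exons: tuple[Interval, ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ReferenceValidationError(f"{self.name}: allele has no exons")
        prev_end = 0
        for i, (start, end) in enumerate(self.exons):
            if not (0 <= start < end <= len(self.sequence)):
                raise ReferenceValidationError(
                    f"{self.name}: exon {i + 1} [{start},{end}) outside sequence "
                    f"of length {len(self.sequence)}"
                )
            if start < prev_end:
                raise ReferenceValidationError(
                    f"{self.name}: exon {i + 1} overlaps or precedes exon {i}"
                )
            prev_end = end

    @property
    def locus_class(self) -> LocusClass:
        return self.name.locus_class

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def junctions(self) -> list[tuple[int, int]]:
        """(donor, acceptor) pairs between consecutive exons: exon_i end → exon_{i+1} start."""
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]


@dataclass(frozen=True)
class SampleGenotype:
    """A donor's typed alleles: mapping locus → 1-2 AlleleNames.

    Homozygous loci may list the same name twice; they collapse to a single
    reference allele downstream.
    """

    sample_id: str
    calls: Mapping[str, tuple[AlleleName, ...]]

    def __post_init__(self) -> None:
        for locus, names in self.calls.items():
            if not 1 <= len(names) <= 2:
                raise ReferenceValidationError(
                    f"{self.sample_id}: locus {locus} has {len(names)} calls"
                )
            if any(n.locus != locus for n in names):
                raise ReferenceValidationError(
                    f"{self.sample_id}: allele under wrong locus key {locus}"
                )


@dataclass(frozen=True)
class ReferenceBundle:
    """Per-sample reference: resolved alleles plus their splice junctions."""

    sample_id: str
    alleles: tuple[AlleleReference, ...]
    #: (allele name string, donor position, acceptor position)
    junctions: tuple[tuple[str, int, int], ...]

    def allele(self, name: str | AlleleName) -> AlleleReference:
        key = str(name)
        for a in self.alleles:
            if str(a.name) == key:
                return a
        raise KeyError(f"allele {key} not in bundle {self.sample_id}")

    def names(self) -> list[str]:
        return [str(a.name) for a in self.alleles]


def parse_allele_db(fasta_path: str | Path, exon_bed_path: str | Path) -> list[AlleleReference]:
    """Load an allele database from FASTA (sequences) + BED (exons).

    Every FASTA record ID must be a parseable allele name and must have at
    least one exon row in the BED file.
    """
    seqs: dict[str, str] = {}
    names: dict[str, AlleleName] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        try:
            name = AlleleName.parse(rec.id)
        except ValueError as exc:
            raise ReferenceValidationError(
                f"FASTA record {rec.id!r}: {exc}"
            ) from exc
        seqs[rec.id] = str(rec.seq).upper()
        names[rec.id] = name

    exons: dict[str, list[Interval]] = {rid: [] for rid in seqs}
    with open(exon_bed_path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ReferenceValidationError(
                    f"{exon_bed_path}:{line_no}: expected ≥3 BED columns"
                )
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if chrom not in seqs:
                raise ReferenceValidationError(
                    f"{exon_bed_path}:{line_no}: unknown allele {chrom!r}"
                )
            exons[chrom].append((start, end))

    refs = []
    for rid, seq in seqs.items():
        if not exons[rid]:
            raise ReferenceValidationError(f"allele {rid} has no exon annotations")
        refs.append(
            AlleleReference(names[rid], seq, tuple(sorted(exons[rid])))
        )
    return refs


def resolve_allele(typed: AlleleName, db: Sequence[AlleleReference]) -> AlleleReference:
    """Pick the database allele with the lowest name consistent with ``typed``.

    Consistency means ``typed`` is a field-prefix of the database name (same
    locus, same leading fields).  "Lowest" compares fields numerically,
    position by position; full-field ties prefer no expression suffix.
    """
    if not db:
        raise AlleleResolutionError("empty allele database")
    by_name = {a.name: a for a in db}
    best = lowest_consistent(typed, by_name.keys())
    return by_name[best]


def build_reference_bundle(
    genotype: SampleGenotype, db: Sequence[AlleleReference]
) -> ReferenceBundle:
    """Resolve a donor genotype to a deduplicated per-sample reference bundle."""
    resolved: dict[str, AlleleReference] = {}
    for locus in sorted(genotype.calls):
        for typed in genotype.calls[locus]:
            ref = resolve_allele(typed, db)
            resolved.setdefault(str(ref.name), ref)
    junctions = tuple(
        (name, donor, acceptor)
        for name, ref in resolved.items()
        for donor, acceptor in ref.junctions()
    )
    return ReferenceBundle(genotype.sample_id, tuple(resolved.values()), junctions)


def read_genotypes(tsv_path: str | Path) -> list[SampleGenotype]:
    """Read genotype TSV with columns sample_id, locus, allele1, allele2.

    allele2 may be empty (hemizygous) or repeat allele1 (homozygous).
    """
    calls: dict[str, dict[str, list[AlleleName]]] = {}
    with open(tsv_path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"sample_id", "locus", "allele1"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ReferenceValidationError(
                f"{tsv_path}: expected columns sample_id, locus, allele1[, allele2]"
            )
        for row in reader:
            sample = row["sample_id"]
            locus = row["locus"]
            names = [AlleleName.parse(row["allele1"])]
            if row.get("allele2"):
                names.append(AlleleName.parse(row["allele2"]))
            calls.setdefault(sample, {})[locus] = names
    return [
        SampleGenotype(sample, {loc: tuple(v) for loc, v in loci.items()})
        for sample, loci in calls.items()
    ]


def write_allele_db(
    db: Sequence[AlleleReference], fasta_path: str | Path, exon_bed_path: str | Path
) -> None:
    """Serialize an allele database in the FASTA + exon BED6 dialect."""
    records = [
        SeqRecord(Seq(a.sequence), id=str(a.name), description="") for a in db
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    with open(exon_bed_path, "w") as fh:
        for a in db:
            for k, (start, end) in enumerate(a.exons, 1):
                fh.write(f"{a.name}\t{start}\t{end}\t{a.name}|exon_{k}\t0\t+\n")


def write_bundle(bundle: ReferenceBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write a bundle as FASTA + exon BED6 + BED12 junction-hint file.

    The BED12 file has one line per allele whose blocks are its exons — the
    form spliced aligners accept as junction hints.  ``parse_allele_db`` on
    the written FASTA/BED reproduces the bundle's alleles exactly.
    """
    if not bundle.alleles:
        raise ReferenceValidationError(f"bundle {bundle.sample_id} has no alleles")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out / f"{bundle.sample_id}.ref.fasta",
        "exon_bed": out / f"{bundle.sample_id}.exons.bed",
        "junc_bed": out / f"{bundle.sample_id}.junctions.bed",
    }

    records = [
        SeqRecord(Seq(a.sequence), id=str(a.name), description="")
        for a in bundle.alleles
    ]
    SeqIO.write(records, str(paths["fasta"]), "fasta")

    with open(paths["exon_bed"], "w") as fh:
        for a in bundle.alleles:
            for k, (start, end) in enumerate(a.exons, 1):
                fh.write(f"{a.name}\t{start}\t{end}\t{a.name}|exon_{k}\t0\t+\n")

    with open(paths["junc_bed"], "w") as fh:
        for a in bundle.alleles:
            start = a.exons[0][0]
            end = a.exons[-1][1]
            sizes = ",".join(str(e - s) for s, e in a.exons) + ","
            starts = ",".join(str(s - start) for s, _ in a.exons) + ","
            fh.write(
                f"{a.name}\t{start}\t{end}\t{a.name}|transcript\t0\t+\t"
                f"{start}\t{end}\t0\t{a.n_exons}\t{sizes}\t{starts}\n"
            )
    return paths
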