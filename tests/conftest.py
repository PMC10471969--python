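"""Shared fixtures: a DQB1-like two-allele toy database and simulated reads.

The toy locus mirrors HLA-DQB1: six exons including a 24-nt exon 5, two
near-identical alleles in one donor, one allele retaining exon 5 in 72% of
transcripts (intact splice acceptor) and the other skipping it entirely
(acceptor lost).
"""

from __future__ import annotations

import numpy as np
import pytest

from hlasplice import (
    AlleleName,
    SampleGenotype,
    SimConfig,
    build_reference_bundle,
    make_toy_db,
)

DQB1_EXONS = (100, 270, 282, 111, 24, 200)
DQB1_INTRONS = (500, 400, 300, 200, 100)

ALLELE_G = "DQB1*05:03:01:01"  # intact splice acceptor (rs28688207 G)
ALLELE_A = "DQB1*05:01:01:01"  # lost splice acceptor (rs28688207 A)


def dqb1_config(**overrides) -> SimConfig:
    defaults = dict(
        seed=20230818,
        alleles=[
            (ALLELE_G, DQB1_EXONS, DQB1_INTRONS),
            (ALLELE_A, DQB1_EXONS, DQB1_INTRONS),
        ],
        isoform_mixtures={
            ALLELE_G: {"111111": 0.72, "111101": 0.28},
            ALLELE_A: {"111101": 1.0},
        },
        n_reads={ALLELE_G: 500, ALLELE_A: 500},
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def config() -> SimConfig:
    return dqb1_config()


@pytest.fixture(scope="session")
def toy_db(config):
    return make_toy_db(config)


@pytest.fixture(scope="session")
def bundle(toy_db):
    genotype = SampleGenotype(
        "cDNA001",
        {"DQB1": (AlleleName.parse("DQB1*05:03"), AlleleName.parse("DQB1*05:01"))},
    )
    return build_reference_bundle(genotype, toy_db)


@pytest.fixture(scope="session")
def sim(config, toy_db, tmp_path_factory):
    from hlasplice import simulate_reads

    out = tmp_path_factory.mktemp("sim")
    return simulate_reads(config, toy_db, out)


def brute_force_exon_calls(
    blocks, exons, ref_length
) -> list[str]:
    """Per-base oracle for exon status calling.

    Builds a boolean coverage vector from the aligned blocks; an exon is
    retained iff any covered base falls inside it, excluded iff uncovered
    but flanked by retained exons on both sides, else unassessed.
    """
    cov = np.zeros(ref_length, dtype=bool)
    for start, end in blocks:
        cov[start:end] = True
    overlapped = [bool(cov[s:e].any()) for s, e in exons]
    retained = [i for i, o in enumerate(overlapped) if o]
    out = []
    for i, o in enumerate(overlapped):
        if o:
            out.append("RETAINED")
        elif retained and min(retained) < i < max(retained):
            out.append("EXCLUDED")
        else:
            out.append("UNASSESSED")
    return out


def brute_force_cigar_blocks(ref_start: int, ops) -> list[tuple[int, int]]:
    """Per-base oracle for CIGAR block extraction.

    Walks the CIGAR marking every reference position consumed inside an
    alignment block (M/=/X/D) versus skipped (N); blocks are the maximal
    runs of consecutively marked positions.
    """
    marked = []
    pos = ref_start
    for op, n in ops:
        if op in "M=XD":
            marked.extend(range(pos, pos + n))
            pos += n
        elif op == "N":
            pos += n
    blocks = []
    for p in marked:
        if blocks and p == blocks[-1][1]:
            blocks[-1][1] = p + 1
        else:
            blocks.append([p, p + 1])
    return [tuple(b) for b in blocks]
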