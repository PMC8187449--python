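"""Shared test utilities: independent oracles and record builders."""

from __future__ import annotations

import numpy as np
import pysam

from lvsplicemap import Feature, VectorGenome


def brute_force_junctions(cigar: str, ref_start: int, min_intron: int = 0):
    """Independent per-base CIGAR walker used as the junction-extraction oracle.

    Parses the string character by character and enumerates every reference
    base an operation touches, recording the first and last base of each
    reference-skip (and of each promoted long deletion).
    """
    ops = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            assert num, f"bad CIGAR {cigar!r}"
            ops.append((int(num), ch))
            num = ""
    assert not num, f"bad CIGAR {cigar!r}"

    pos = ref_start
    junctions = []
    for length, op in ops:
        if op in "MDN=X":
            touched = [pos + i for i in range(length)]
            if op == "N" or (op == "D" and min_intron > 0 and length >= min_intron):
                junctions.append((touched[0], touched[-1]))
            pos = touched[-1] + 1
        elif op in "ISHP":
            pass  # no reference bases consumed
        else:
            raise AssertionError(f"unexpected op {op!r}")
    return junctions


def random_cigar(rng: np.random.Generator) -> tuple[str, int]:
    """A random valid gapped CIGAR string plus a random reference start."""
    parts = []
    if rng.random() < 0.3:
        parts.append(f"{rng.integers(1, 50)}S")
    n_blocks = int(rng.integers(1, 6))
    for i in range(n_blocks):
        parts.append(f"{rng.integers(1, 300)}M")
        if i < n_blocks - 1:
            gap_op = rng.choice(["N", "D", "I"], p=[0.6, 0.3, 0.1])
            hi = 2000 if gap_op == "N" else 80
            parts.append(f"{rng.integers(1, hi)}{gap_op}")
    if rng.random() < 0.3:
        parts.append(f"{rng.integers(1, 50)}S")
    return "".join(parts), int(rng.integers(0, 500))


def toy_genome(features, length=10000, r3_end=None, name="toy"):
    """A small genome with an SD1 donor added unless the caller provides one."""
    feats = list(features)
    if not any(f.name == "SD1" for f in feats):
        feats.append(Feature("SD1", 300, 301, "splice_donor", "non-HIV1"))
    return VectorGenome(
        name=name, length=length, features=feats, r3_end=r3_end or length
    )


def make_record(
    name: str,
    cigar: str,
    ref_start: int,
    genome: VectorGenome,
    flag: int = 0,
) -> pysam.AlignedSegment:
    """Hand-build a single alignment record against a genome."""
    header = pysam.AlignmentHeader.from_references([genome.name], [genome.length])
    rec = pysam.AlignedSegment(header)
    rec.query_name = name
    rec.flag = flag
    rec.reference_id = 0
    rec.reference_start = ref_start
    rec.mapping_quality = 60
    rec.cigarstring = cigar
    return rec


def hiv1_content_bruteforce(genome: VectorGenome, limit: int | None = None) -> int:
    """Per-base membership count over HIV-1 spans (union counted once)."""
    stop = genome.length if limit is None else limit
    covered = np.zeros(stop, dtype=bool)
    for f in genome.features:
        if f.origin == "HIV1" and f.start < stop:
            covered[f.start : min(f.end, stop)] = True
    return int(covered.sum())
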