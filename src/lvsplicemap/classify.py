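"""Read-level classification of spliced long-read alignments.

Implements the per-read procedure applied to each vector library:

* **near-full-length (NFL) selection** — a read must align at least one
  nucleotide upstream of the canonical splice donor SD1 to witness whether
  the transcript is spliced; only NFL reads enter per-transcript statistics;
* **junction extraction** — a CIGAR walk turning every reference-skip
  operation (optionally long deletions, for aligner dialects that emit them)
  into a (donor, acceptor) coordinate pair;
* **splice-site assignment** — each junction end is matched to the nearest
  catalogued donor/acceptor within a tolerance window, or labelled
  ``novel@<coord>``;
* **readthrough detection** — alignments ending beyond the 3' R boundary are
  transcripts that escaped cleavage at the canonical 3' end.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
import pysam

from .errors import AnnotationError, ConfigurationError, InputError
from .vector_model import VectorGenome

logger = logging.getLogger(__name__)

DEFAULT_TOLERANCE = 8  # nt; typical nanopore junction placement wobble

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_CIGAR_OPS = "MIDNSHP=X"
# operations that consume reference bases
_REF_CONSUMERS = {0, 2, 3, 7, 8}  # M, D, N, =, X


@dataclass(frozen=True)
class Junction:
    """A labelled splice junction (first / last intronic base)."""

    donor_coord: int
    acceptor_coord: int
    donor_label: str
    acceptor_label: str

    def __post_init__(self) -> None:
        if self.donor_coord >= self.acceptor_coord:
            raise ValueError("donor coordinate must precede acceptor coordinate")
        if not self.donor_label or not self.acceptor_label:
            raise ValueError("junction labels must be non-empty")

    @property
    def label(self) -> str:
        return f"{self.donor_label}-{self.acceptor_label}"

    @property
    def is_novel(self) -> bool:
        return self.donor_label.startswith("novel@") or self.acceptor_label.startswith("novel@")


@dataclass
class SpliceSiteCatalog:
    """Named donor/acceptor coordinates with canonical flags.

    Canonical sites are the major donor SD1 and acceptor SA7 used by spliced
    HIV-1 RNAs; CD*/CA* numbered sites are cryptic.
    """

    donors: dict[str, int]
    acceptors: dict[str, int]
    canonical: frozenset[str] = frozenset({"SD1", "SA7"})

    def __post_init__(self) -> None:
        for label, mapping in (("donor", self.donors), ("acceptor", self.acceptors)):
            coords = list(mapping.values())
            if len(set(coords)) != len(coords):
                raise ConfigurationError(f"duplicate {label} coordinates in catalog")
        if "SD1" not in self.donors:
            raise ConfigurationError("catalog lacks the canonical donor SD1")

    @property
    def sd1_coord(self) -> int:
        return self.donors["SD1"]

    @classmethod
    def from_genome(cls, genome: VectorGenome) -> "SpliceSiteCatalog":
        return cls(donors=genome.donors(), acceptors=genome.acceptors())


@dataclass
class ReadClassification:
    read_id: str
    nfl: bool
    junctions: list[Junction]
    unspliced: bool
    readthrough: bool
    ref_start: int
    ref_end: int

    def __post_init__(self) -> None:
        if self.unspliced and self.junctions:
            raise ValueError("an unspliced read cannot carry junctions")
        if self.ref_start >= self.ref_end:
            raise ValueError("ref_start must precede ref_end")


def parse_cigar(cigar: str | Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Normalize a CIGAR string or pysam-style tuple list to (op, length) pairs."""
    if not isinstance(cigar, str):
        ops = list(cigar)
        for op, length in ops:
            if not (0 <= op <= 8) or length <= 0:
                raise AnnotationError(f"malformed CIGAR operation ({op}, {length})")
        return ops
    matched = "".join(m.group(0) for m in _CIGAR_RE.finditer(cigar))
    if not cigar or matched != cigar:
        raise AnnotationError(f"malformed CIGAR string {cigar!r}")
    return [
        (_CIGAR_OPS.index(m.group(2)), int(m.group(1))) for m in _CIGAR_RE.finditer(cigar)
    ]


def extract_junctions(
    cigar: str | Iterable[tuple[int, int]],
    ref_start: int,
    min_intron: int = 0,
) -> list[tuple[int, int]]:
    """Splice junctions implied by a gapped alignment.

    Every reference-skip (N) operation yields one ``(donor, acceptor)`` pair
    where the donor is the first skipped base and the acceptor the last.
    When ``min_intron`` > 0, deletion (D) operations at least that long are
    promoted to junctions as well; shorter deletions merely advance along the
    reference.
    """
    if ref_start < 0:
        raise AnnotationError("ref_start must be >= 0")
    junctions = []
    pos = ref_start
    for op, length in parse_cigar(cigar):
        if op == 3 or (op == 2 and min_intron > 0 and length >= min_intron):
            junctions.append((pos, pos + length - 1))
        if op in _REF_CONSUMERS:
            pos += length
    return junctions


def is_near_full_length(ref_start: int, catalog: SpliceSiteCatalog) -> bool:
    """True iff the alignment covers at least one nucleotide upstream of SD1."""
    return ref_start < catalog.sd1_coord


def is_readthrough(ref_end: int, genome: VectorGenome) -> bool:
    """True iff the alignment extends beyond the 3' R boundary."""
    return ref_end > genome.r3_end


def assign_site(coord: int, sites: Mapping[str, int], tolerance: int) -> str:
    """Nearest catalogued site within ``tolerance`` nt, else ``novel@<coord>``.

    Equidistant ties resolve toward the lower coordinate.
    """
    if tolerance < 0:
        raise ConfigurationError("tolerance must be >= 0")
    best = None
    for name, site_coord in sites.items():
        dist = abs(coord - site_coord)
        if dist > tolerance:
            continue
        key = (dist, site_coord)
        if best is None or key < best[0]:
            best = (key, name)
    return best[1] if best else f"novel@{coord}"


def _iter_records(
    alignments: str | Path | pysam.AlignmentFile | Iterable[pysam.AlignedSegment],
) -> Iterator[pysam.AlignedSegment]:
    if isinstance(alignments, (str, Path)):
        with pysam.AlignmentFile(str(alignments), check_sq=False) as fh:
            yield from fh
    else:
        yield from alignments


def classify_alignments(
    alignments: str | Path | pysam.AlignmentFile | Iterable[pysam.AlignedSegment],
    genome: VectorGenome,
    catalog: SpliceSiteCatalog | None = None,
    tolerance: int = DEFAULT_TOLERANCE,
    min_intron: int = 0,
) -> list[ReadClassification]:
    """Classify every retained primary alignment against the vector genome.

    Secondary and supplementary records are discarded (one record per
    molecule); reverse-strand alignments are dropped with a logged count
    because the vector transcript is single-stranded sense RNA.
    """
    catalog = catalog or SpliceSiteCatalog.from_genome(genome)
    n_total = n_secondary = n_reverse = n_unmapped = 0
    out: list[ReadClassification] = []
    for rec in _iter_records(alignments):
        n_total += 1
        if rec.is_unmapped:
            n_unmapped += 1
            continue
        if rec.is_secondary or rec.is_supplementary:
            n_secondary += 1
            continue
        if rec.reference_name != genome.name:
            raise InputError(
                f"alignment reference {rec.reference_name!r} does not match "
                f"genome {genome.name!r}"
            )
        if rec.is_reverse:
            n_reverse += 1
            continue
        pairs = extract_junctions(rec.cigartuples, rec.reference_start, min_intron)
        junctions = [
            Junction(
                donor_coord=d,
                acceptor_coord=a,
                donor_label=assign_site(d, catalog.donors, tolerance),
                acceptor_label=assign_site(a, catalog.acceptors, tolerance),
            )
            for d, a in pairs
        ]
        nfl = is_near_full_length(rec.reference_start, catalog)
        out.append(
            ReadClassification(
                read_id=rec.query_name,
                nfl=nfl,
                junctions=junctions,
                unspliced=nfl and not junctions,
                readthrough=is_readthrough(rec.reference_end, genome),
                ref_start=rec.reference_start,
                ref_end=rec.reference_end,
            )
        )
    if n_reverse:
        logger.warning("dropped %d reverse-strand alignments", n_reverse)
    logger.info(
        "classification: %d records -> %d kept, %d secondary/supplementary, "
        "%d reverse-strand, %d unmapped, %d non-NFL among kept",
        n_total,
        len(out),
        n_secondary,
        n_reverse,
        n_unmapped,
        sum(1 for c in out if not c.nfl),
    )
    return out


def classifications_to_frame(classifications: list[ReadClassification]) -> pd.DataFrame:
    """Tabular (TSV-ready) view of read classifications."""
    return pd.DataFrame(
        {
            "read_id": [c.read_id for c in classifications],
            "nfl": [c.nfl for c in classifications],
            "n_junctions": [len(c.junctions) for c in classifications],
            "junction_chain": [
                ";".join(j.label for j in c.junctions) for c in classifications
            ],
            "junction_coords": [
                ";".join(f"{j.donor_coord}-{j.acceptor_coord}" for j in c.junctions)
                for c in classifications
            ],
            "unspliced": [c.unspliced for c in classifications],
            "readthrough": [c.readthrough for c in classifications],
            "ref_start": [c.ref_start for c in classifications],
            "ref_end": [c.ref_end for c in classifications],
        }
    )


def frame_to_classifications(frame: pd.DataFrame) -> list[ReadClassification]:
    """Inverse of :func:`classifications_to_frame` (labels are kept verbatim)."""
    out = []
    for row in frame.itertuples(index=False):
        junctions = []
        if isinstance(row.junction_chain, str) and row.junction_chain:
            chains = row.junction_chain.split(";")
            coords = row.junction_coords.split(";")
            for chain, coord in zip(chains, coords):
                # site labels never contain '-', so one split is unambiguous
                d_lbl, a_lbl = chain.split("-", 1)
                d, a = coord.split("-")
                junctions.append(Junction(int(d), int(a), d_lbl, a_lbl))
        out.append(
            ReadClassification(
                read_id=str(row.read_id),
                nfl=bool(row.nfl),
                junctions=junctions,
                unspliced=bool(row.unspliced),
                readthrough=bool(row.readthrough),
                ref_start=int(row.ref_start),
                ref_end=int(row.ref_end),
            )
        )
    return out
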