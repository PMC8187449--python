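"""Annotated lentiviral vector genomes and HIV-1 sequence accounting.

A vector genome is modelled as a named reference of known length carrying a
sorted list of typed features.  Span features (``hiv1_span``, ``ltr_part``,
``transgene_span``, ``other``) use 0-based half-open coordinates; splice sites
are 1-nt point features where a donor's coordinate is the first intronic base
and an acceptor's coordinate is the last intronic base.

The accounting operations answer the vector-design questions: how much
HIV-1-derived sequence a genome carries, how much of that survives reverse
transcription into the provirus (sequence downstream of the 3' R boundary is
not transferred), and how many nucleotides a derived design removes relative
to its parent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import AnnotationError, ConfigurationError, ConsistencyError

logger = logging.getLogger(__name__)

FEATURE_KINDS = frozenset(
    {"splice_donor", "splice_acceptor", "hiv1_span", "ltr_part", "transgene_span", "other"}
)
POINT_KINDS = frozenset({"splice_donor", "splice_acceptor"})
ORIGINS = frozenset({"HIV1", "non-HIV1"})


@dataclass(frozen=True)
class Feature:
    """A typed interval on the vector reference (0-based, half-open)."""

    name: str
    start: int
    end: int
    kind: str
    origin: str

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise AnnotationError(f"feature {self.name!r}: unknown kind {self.kind!r}")
        if self.origin not in ORIGINS:
            raise AnnotationError(f"feature {self.name!r}: unknown origin {self.origin!r}")
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"feature {self.name!r}: invalid interval [{self.start}, {self.end})"
            )
        if self.kind in POINT_KINDS and self.end != self.start + 1:
            raise AnnotationError(
                f"feature {self.name!r}: splice sites are 1-nt point features"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class VectorGenome:
    """A vector reference with sorted features and the 3' R boundary.

    ``r3_end`` is the 0-based exclusive coordinate of the 3' R boundary:
    alignments ending beyond it are readthrough transcripts and sequence at or
    beyond it is excluded from the reverse-transcribed provirus.
    """

    name: str
    length: int
    features: list[Feature]
    r3_end: int
    sequence: str | None = None

    def __post_init__(self) -> None:
        self.features = sorted(self.features, key=lambda f: (f.start, -f.end, f.name))
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise AnnotationError(f"duplicate feature names: {', '.join(dup)}")
        for f in self.features:
            if f.end > self.length:
                raise AnnotationError(
                    f"feature {f.name!r} end {f.end} exceeds genome length {self.length}"
                )
        if not (0 < self.r3_end <= self.length):
            raise ConfigurationError(
                f"r3_end {self.r3_end} outside genome [1, {self.length}]"
            )
        if self.sequence is not None and len(self.sequence) != self.length:
            raise AnnotationError("sequence length does not match declared genome length")
        self.sd1  # noqa: B018 - validates presence of the canonical donor

    @property
    def sd1(self) -> Feature:
        """The canonical splice donor feature (must be named SD1)."""
        for f in self.features:
            if f.name == "SD1":
                if f.kind != "splice_donor":
                    raise ConfigurationError("feature SD1 is not of kind splice_donor")
                return f
        raise ConfigurationError(
            f"genome {self.name!r} lacks the required canonical donor feature 'SD1'"
        )

    def feature(self, name: str) -> Feature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def donors(self) -> dict[str, int]:
        return {f.name: f.start for f in self.features if f.kind == "splice_donor"}

    def acceptors(self) -> dict[str, int]:
        return {f.name: f.start for f in self.features if f.kind == "splice_acceptor"}

    def hiv1_intervals(self) -> list[tuple[int, int]]:
        return [(f.start, f.end) for f in self.features if f.origin == "HIV1"]


@dataclass
class DeletionAccounting:
    """Nucleotide accounting of a parent -> derived vector redesign.

    ``removed_features`` attributes the removed HIV-1 nucleotides to named
    features.  A negative entry means the derived genome retains sequence that
    in the parent was nested inside another feature (e.g. an RRE repositioned
    outside its original env span); entries always sum to ``removed_hiv1_nt``.
    """

    parent_name: str
    derived_name: str
    removed_hiv1_nt: int
    removed_features: list[tuple[str, int]] = field(default_factory=list)
    provirus: bool = False

    def __post_init__(self) -> None:
        if self.removed_hiv1_nt < 0:
            raise ConsistencyError(
                f"derived genome {self.derived_name!r} has more HIV-1 sequence "
                f"than parent {self.parent_name!r}"
            )
        if sum(n for _, n in self.removed_features) != self.removed_hiv1_nt:
            raise ConsistencyError("per-feature breakdown does not sum to the total")


def _union_length(intervals: Iterable[tuple[int, int]]) -> int:
    """Total length of the union of half-open intervals (overlaps counted once)."""
    total = 0
    cur_start = cur_end = None
    for start, end in sorted(intervals):
        if cur_end is None:
            cur_start, cur_end = start, end
        elif start <= cur_end:
            cur_end = max(cur_end, end)
        else:
            total += cur_end - cur_start
            cur_start, cur_end = start, end
    if cur_end is not None:
        total += cur_end - cur_start
    return total


def hiv1_content(genome: VectorGenome) -> int:
    """Length of the union of HIV-1-origin spans in the genomic RNA."""
    return _union_length(genome.hiv1_intervals())


def provirus_hiv1_content(genome: VectorGenome) -> int:
    """HIV-1 content restricted to coordinates < r3_end.

    Sequence downstream of the 3' R boundary travels with the genomic RNA but
    is excluded from reverse transcription and so never reaches the
    integrated provirus.
    """
    clipped = [
        (s, min(e, genome.r3_end)) for s, e in genome.hiv1_intervals() if s < genome.r3_end
    ]
    return _union_length(clipped)


def _exclusive_lengths(
    genome: VectorGenome, rank: dict[str, int], provirus: bool
) -> dict[str, int]:
    """Attribute each base of the HIV-1 union to one covering feature.

    Nested/overlapping spans (e.g. the RRE inside env) would otherwise be
    double counted; each base goes to the covering feature with the smallest
    rank so per-feature contributions sum exactly to the union length.
    """
    limit = genome.r3_end if provirus else genome.length
    owner = np.full(limit, -1, dtype=np.int64)
    feats = [f for f in genome.features if f.origin == "HIV1"]
    # paint lowest-priority first so higher-priority features overwrite
    for f in sorted(feats, key=lambda f: rank.get(f.name, len(rank)), reverse=True):
        end = min(f.end, limit)
        if f.start < end:
            owner[f.start:end] = rank.get(f.name, len(rank))
    out: dict[str, int] = {}
    by_rank = {rank.get(f.name, len(rank)): f.name for f in feats}
    vals, counts = np.unique(owner[owner >= 0], return_counts=True)
    for v, c in zip(vals.tolist(), counts.tolist()):
        out[by_rank[v]] = c
    return out


def deletion_accounting(
    parent: VectorGenome, derived: VectorGenome, provirus: bool = False
) -> DeletionAccounting:
    """How many HIV-1 nucleotides a derived design removes from its parent.

    With ``provirus=True`` the comparison is restricted to sequence that
    survives reverse transcription (coordinates < r3_end in each genome).
    """
    parent_names = {f.name for f in parent.features}
    for f in derived.features:
        if f.name in parent_names and len(f) > len(parent.feature(f.name)):
            raise ConsistencyError(
                f"derived feature {f.name!r} ({len(f)} nt) is longer than the "
                f"parent's ({len(parent.feature(f.name))} nt)"
            )
    content = provirus_hiv1_content if provirus else hiv1_content
    total = content(parent) - content(derived)

    # Per-feature breakdown via union-exclusive lengths.  The parent's feature
    # precedence (genomic order) is reused for the derived genome so that a
    # span shrinking onto a nested feature is attributed consistently.
    parent_feats = [f for f in parent.features if f.origin == "HIV1"]
    rank = {f.name: i for i, f in enumerate(parent_feats)}
    excl_p = _exclusive_lengths(parent, rank, provirus)
    excl_d = _exclusive_lengths(derived, rank, provirus)
    breakdown = []
    for name in list(excl_p) + [n for n in excl_d if n not in excl_p]:
        diff = excl_p.get(name, 0) - excl_d.get(name, 0)
        if diff != 0:
            breakdown.append((name, diff))
    return DeletionAccounting(
        parent_name=parent.name,
        derived_name=derived.name,
        removed_hiv1_nt=total,
        removed_features=breakdown,
        provirus=provirus,
    )


# ---------------------------------------------------------------------------
# Annotation IO: single-record FASTA + BED6 with two extension columns
# (kind, origin); tab-separated, '#' comments allowed.
# ---------------------------------------------------------------------------

def _parse_bed_line(line: str, lineno: int, length: int | None) -> Feature:
    cols = line.rstrip("\n").split("\t")
    if len(cols) < 8:
        raise AnnotationError(
            f"BED line {lineno}: expected 8 tab-separated columns, got {len(cols)}"
        )
    _, start_s, end_s, name, _score, strand, kind, origin = cols[:8]
    try:
        start, end = int(start_s), int(end_s)
    except ValueError as exc:
        raise AnnotationError(f"BED line {lineno}: non-integer coordinates") from exc
    if strand != "+":
        raise AnnotationError(f"BED line {lineno}: only '+' strand features are supported")
    if start >= end:
        raise AnnotationError(f"BED line {lineno}: start {start} >= end {end}")
    if length is not None and end > length:
        raise AnnotationError(
            f"BED line {lineno}: feature {name!r} end {end} exceeds sequence length {length}"
        )
    try:
        return Feature(name=name, start=start, end=end, kind=kind, origin=origin)
    except AnnotationError as exc:
        raise AnnotationError(f"BED line {lineno}: {exc}") from exc


def _read_bed(bed_path: Path, length: int | None) -> list[Feature]:
    features: list[Feature] = []
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            features.append(_parse_bed_line(line, lineno, length))
    names = [f.name for f in features]
    if len(set(names)) != len(names):
        dup = sorted({n for n in names if names.count(n) > 1})
        raise AnnotationError(f"duplicate feature names in {bed_path}: {', '.join(dup)}")
    # point features at the same coordinate with different kinds are ambiguous
    points: dict[int, str] = {}
    for f in features:
        if f.kind in POINT_KINDS:
            prev = points.setdefault(f.start, f.kind)
            if prev != f.kind:
                raise AnnotationError(
                    f"conflicting point features at coordinate {f.start}: {prev} vs {f.kind}"
                )
    return features


def _r3_boundary(features: Sequence[Feature], length: int) -> int:
    for f in features:
        if f.name == "R3":
            return f.end
    logger.warning("no feature named 'R3'; using the genome end as the 3' R boundary")
    return length


def load_annotation(fasta_path: str | Path, bed_path: str | Path) -> VectorGenome:
    """Load a vector genome from a single-record FASTA plus its BED annotation."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise AnnotationError(
            f"{fasta_path}: expected exactly one FASTA record, found {len(records)}"
        )
    rec = records[0]
    seq = str(rec.seq).upper()
    features = _read_bed(Path(bed_path), len(seq))
    genome = VectorGenome(
        name=rec.id,
        length=len(seq),
        features=features,
        r3_end=_r3_boundary(features, len(seq)),
        sequence=seq,
    )
    return genome


def load_bed_annotation(bed_path: str | Path, name: str | None = None) -> VectorGenome:
    """Load a genome from BED alone (accounting does not need the sequence).

    The genome length is taken as the largest feature end.
    """
    features = _read_bed(Path(bed_path), None)
    if not features:
        raise AnnotationError(f"{bed_path}: no features")
    length = max(f.end for f in features)
    return VectorGenome(
        name=name or Path(bed_path).stem,
        length=length,
        features=features,
        r3_end=_r3_boundary(features, length),
    )


def write_annotation(genome: VectorGenome, fasta_path: str | Path, bed_path: str | Path) -> None:
    """Write the genome back out as FASTA + extended BED."""
    if genome.sequence is None:
        raise ConfigurationError("genome has no sequence to write")
    with open(fasta_path, "w") as fh:
        fh.write(f">{genome.name}\n")
        seq = genome.sequence
        for i in range(0, len(seq), 60):
            fh.write(seq[i : i + 60] + "\n")
    with open(bed_path, "w") as fh:
        fh.write("# chrom\tstart\tend\tname\tscore\tstrand\tkind\torigin\n")
        for f in genome.features:
            fh.write(
                f"{genome.name}\t{f.start}\t{f.end}\t{f.name}\t0\t+\t{f.kind}\t{f.origin}\n"
            )
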