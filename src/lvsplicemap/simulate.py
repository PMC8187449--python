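"""Direct-cDNA-like long-read simulator with ground truth.

Emulates the statistical structure of nanopore direct-cDNA libraries made
from lentiviral vector transcripts:

* reads are 3'-anchored with geometric 5' truncation (library prep initiates
  at the transcript 3' end, so 5' ends are variably incomplete);
* each read derives from one isoform of a weighted mixture, where an isoform
  is an ordered chain of splice junctions (the unspliced genome has none);
* a configurable subpopulation reads through the 3' R boundary into
  downstream plasmid sequence instead of ending at the canonical cleavage
  site;
* junction boundaries receive small integer jitter mimicking spliced-aligner
  placement wobble (equal shift of both ends, preserving intron length).

Reads are emitted directly as gapped alignment records (skip operations encode
the junctions), keeping the analysis loop closed without an external aligner;
FASTQ output is available for users who want to run one.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from .errors import ConfigurationError
from .vector_model import VectorGenome


@dataclass(frozen=True)
class Isoform:
    """A transcript isoform: an ordered junction chain plus a mixture weight.

    Junction coordinates are 0-based on the reference: the donor coordinate is
    the first intronic base and the acceptor coordinate the last intronic
    base, so the intron occupies ``[donor, acceptor + 1)``.
    """

    name: str
    junctions: tuple[tuple[int, int], ...]
    weight: float

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ConfigurationError(f"isoform {self.name!r}: negative weight")
        prev_end = -1
        for donor, acceptor in self.junctions:
            if donor >= acceptor:
                raise ConfigurationError(
                    f"isoform {self.name!r}: donor {donor} >= acceptor {acceptor}"
                )
            if donor <= prev_end:
                raise ConfigurationError(
                    f"isoform {self.name!r}: junctions overlap or are unordered"
                )
            prev_end = acceptor
        object.__setattr__(self, "junctions", tuple(map(tuple, self.junctions)))


@dataclass
class SimulationConfig:
    """Everything needed to generate one synthetic library."""

    genome: VectorGenome
    isoforms: list[Isoform]
    readthrough_prob: float = 0.30
    readthrough_extension: tuple[int, int] = (50, 400)
    truncation_mean: float = 1000.0
    wobble_sd: float = 0.0
    n_reads: int = 1000
    seed: int = 0
    min_read_length: int = 200  # 3' anchor that truncation may not remove

    def __post_init__(self) -> None:
        if not self.isoforms:
            raise ConfigurationError("isoform list is empty")
        if not any(len(iso.junctions) == 0 for iso in self.isoforms):
            raise ConfigurationError("isoform mixture must include an unspliced isoform")
        total = sum(iso.weight for iso in self.isoforms)
        if total <= 0:
            raise ConfigurationError("isoform weights must sum to a positive number")
        if not 0.0 <= self.readthrough_prob <= 1.0:
            raise ConfigurationError("readthrough_prob must be in [0, 1]")
        lo, hi = self.readthrough_extension
        if not 0 <= lo <= hi:
            raise ConfigurationError("readthrough_extension must satisfy 0 <= min <= max")
        if self.genome.r3_end + hi > self.genome.length:
            raise ConfigurationError(
                "readthrough extension would run past the end of the reference"
            )
        if self.truncation_mean < 0 or self.wobble_sd < 0:
            raise ConfigurationError("distribution parameters must be non-negative")
        if self.n_reads < 1:
            raise ConfigurationError("n_reads must be >= 1")
        for iso in self.isoforms:
            for donor, acceptor in iso.junctions:
                if not (0 <= donor and acceptor < self.genome.r3_end):
                    raise ConfigurationError(
                        f"isoform {iso.name!r}: junction ({donor}, {acceptor}) outside "
                        f"the transcribed genome [0, {self.genome.r3_end})"
                    )

    @property
    def weights(self) -> np.ndarray:
        w = np.array([iso.weight for iso in self.isoforms], dtype=float)
        return w / w.sum()


def _exon_blocks(junctions: Sequence[tuple[int, int]], end: int) -> list[list[int]]:
    """Half-open exon blocks of a transcript running from 0 to ``end``."""
    blocks, pos = [], 0
    for donor, acceptor in junctions:
        blocks.append([pos, donor])
        pos = acceptor + 1
    blocks.append([pos, end])
    return blocks


def _truncate_blocks(blocks: list[list[int]], offset: int) -> list[list[int]]:
    """Drop ``offset`` transcript bases from the 5' end of the block chain."""
    out = []
    remaining = offset
    for start, end in blocks:
        size = end - start
        if remaining >= size:
            remaining -= size
            continue
        out.append([start + remaining, end])
        remaining = 0
    return out


def _cigar_and_seq(
    blocks: list[list[int]], sequence: str | None
) -> tuple[list[tuple[int, int]], str | None]:
    cig: list[tuple[int, int]] = []
    seq_parts = []
    for i, (start, end) in enumerate(blocks):
        if i:
            cig.append((pysam.CREF_SKIP, start - blocks[i - 1][1]))
        cig.append((pysam.CMATCH, end - start))
        if sequence is not None:
            seq_parts.append(sequence[start:end])
    return cig, ("".join(seq_parts) if sequence is not None else None)


def simulate(config: SimulationConfig) -> tuple[list[pysam.AlignedSegment], pd.DataFrame]:
    """Generate aligned reads plus a per-read ground-truth table.

    Deterministic for a fixed ``config.seed``.  Truth junction lists record
    the isoform definition before wobble; ``junctions_observed`` additionally
    restricts to junctions surviving the 5' truncation of that read.
    """
    rng = np.random.default_rng(config.seed)
    genome = config.genome
    weights = config.weights
    header = pysam.AlignmentHeader.from_references([genome.name], [genome.length])

    records: list[pysam.AlignedSegment] = []
    truth_rows = []
    geom_p = 1.0 / (config.truncation_mean + 1.0)
    for i in range(config.n_reads):
        read_id = f"read{i:06d}"
        iso = config.isoforms[int(rng.choice(len(weights), p=weights))]
        readthrough = bool(rng.random() < config.readthrough_prob)
        end = genome.r3_end
        if readthrough:
            lo, hi = config.readthrough_extension
            end += int(rng.integers(lo, hi + 1))
        blocks = _exon_blocks(iso.junctions, end)
        transcript_len = sum(e - s for s, e in blocks)
        trunc = int(rng.geometric(geom_p)) - 1 if config.truncation_mean > 0 else 0
        trunc = min(trunc, max(transcript_len - config.min_read_length, 0))
        read_blocks = _truncate_blocks(blocks, trunc)
        ref_start = read_blocks[0][0]
        observed = [
            (d, a) for d, a in iso.junctions if d >= ref_start
        ]

        # jitter: equal signed shift of both boundaries of each junction,
        # clamped so every match block keeps at least one base
        if config.wobble_sd > 0:
            for j in range(1, len(read_blocks)):
                shift = int(np.rint(rng.normal(0.0, config.wobble_sd)))
                lo_s = read_blocks[j - 1][0] + 1 - read_blocks[j - 1][1]
                hi_s = read_blocks[j][1] - 1 - read_blocks[j][0]
                shift = int(np.clip(shift, lo_s, hi_s))
                read_blocks[j - 1][1] += shift
                read_blocks[j][0] += shift

        cigar, seq = _cigar_and_seq(read_blocks, genome.sequence)
        rec = pysam.AlignedSegment(header)
        rec.query_name = read_id
        rec.flag = 0
        rec.reference_id = 0
        rec.reference_start = ref_start
        rec.mapping_quality = 60
        rec.cigartuples = cigar
        if seq is not None:
            rec.query_sequence = seq
            rec.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
        records.append(rec)
        truth_rows.append(
            {
                "read_id": read_id,
                "isoform": iso.name,
                "junctions": ";".join(f"{d}-{a}" for d, a in iso.junctions),
                "junctions_observed": ";".join(f"{d}-{a}" for d, a in observed),
                "readthrough": readthrough,
                "start": ref_start,
                "end": read_blocks[-1][1],
            }
        )
    truth = pd.DataFrame(truth_rows)
    return records, truth


def write_outputs(
    records: list[pysam.AlignedSegment],
    truth: pd.DataFrame,
    out_dir: str | Path,
    genome: VectorGenome,
    fastq: bool = False,
    substitution_rate: float = 0.0,
    indel_rate: float = 0.0,
    noise_seed: int = 0,
) -> dict[str, Path]:
    """Write a coordinate-sorted, indexed BAM, the truth TSV and optional FASTQ.

    FASTQ noise is applied to emitted base calls only; alignment records are
    written exactly as simulated.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "bam": out_dir / "reads.bam",
        "truth": out_dir / "truth.tsv",
    }
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": genome.name, "LN": genome.length}],
        }
    )
    with pysam.AlignmentFile(str(paths["bam"]), "wb", header=header) as bam:
        for rec in sorted(records, key=lambda r: (r.reference_start, r.query_name)):
            out = pysam.AlignedSegment(header)
            out.query_name = rec.query_name
            out.flag = rec.flag
            out.reference_id = 0
            out.reference_start = rec.reference_start
            out.mapping_quality = rec.mapping_quality
            out.cigartuples = rec.cigartuples
            if rec.query_sequence:
                out.query_sequence = rec.query_sequence
                out.query_qualities = rec.query_qualities
            bam.write(out)
    pysam.index(str(paths["bam"]))
    truth.to_csv(paths["truth"], sep="\t", index=False)

    if fastq:
        rng = np.random.default_rng(noise_seed)
        paths["fastq"] = out_dir / "reads.fastq"
        bases = np.array(list("ACGT"))
        with open(paths["fastq"], "w") as fh:
            for rec in records:
                seq = rec.query_sequence or ""
                if seq and (substitution_rate > 0 or indel_rate > 0):
                    arr = list(seq)
                    out_seq = []
                    for b in arr:
                        r = rng.random()
                        if r < indel_rate / 2:
                            continue  # deletion
                        if r < indel_rate:
                            out_seq.append(str(bases[rng.integers(4)]))  # insertion
                        if rng.random() < substitution_rate:
                            b = str(bases[rng.integers(4)])
                        out_seq.append(b)
                    seq = "".join(out_seq)
                fh.write(f"@{rec.query_name}\n{seq}\n+\n{'I' * len(seq)}\n")
    return paths


def analytic_summary(
    config: SimulationConfig, tolerance: float | None = None
) -> dict:
    """Expected library statistics implied by a simulation configuration.

    Returns the unspliced percentage, readthrough percentage, splice events
    per transcript and per-junction event shares (keyed by coordinate pair).
    When ``tolerance`` is given and junction jitter is enabled, also returns
    ``label_retention``: the probability that a jittered junction stays within
    the site-assignment window and keeps its catalog label.
    """
    from scipy.stats import norm

    weights = config.weights
    n_junc = np.array([len(iso.junctions) for iso in config.isoforms])
    events = float((weights * n_junc).sum())
    shares: dict[tuple[int, int], float] = {}
    for w, iso in zip(weights, config.isoforms):
        for j in iso.junctions:
            shares[j] = shares.get(j, 0.0) + w
    shares = {j: v / events for j, v in shares.items()} if events else {}
    retention = 1.0
    if tolerance is not None and config.wobble_sd > 0:
        retention = float(2 * norm.cdf((tolerance + 0.5) / config.wobble_sd) - 1)
    return {
        "pct_unspliced": 100.0 * float(weights[n_junc == 0].sum()),
        "pct_readthrough": 100.0 * config.readthrough_prob,
        "events_per_transcript": events,
        "junction_shares": shares,
        "label_retention": retention,
    }
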