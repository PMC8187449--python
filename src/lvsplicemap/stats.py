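"""Library-level splicing statistics and exports.

From per-read classifications this module computes the per-library summary
reported for each sequenced vector: the percentage of unspliced transcripts,
the percentage of transcripts reading through the 3' R boundary, the mean
number of splice events per transcript, and a per-junction count table with
each junction's percentage of total splicing events.  All per-transcript
percentages are over near-full-length (NFL) reads, the only reads that can
witness the 5' splicing status.

Two percentage columns are carried per junction:

* ``pct_of_events`` — share of *all* splice events in the denominator set
  (sums to 100 over the unfiltered table);
* ``pct_of_assigned`` — share of events whose both ends matched a catalogued
  site.  Junction-boundary jitter beyond the assignment tolerance produces
  scattered novel labels at a known rate; restricting the denominator to
  assigned events removes that dilution and estimates the true usage share
  of each catalogued junction without bias.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path

import pandas as pd

from .classify import ReadClassification
from .errors import EmptyInputError
from .vector_model import VectorGenome

logger = logging.getLogger(__name__)

DEFAULT_MIN_SUPPORT = 10  # junction annotation threshold: independent reads

SUMMARY_ROWS = ("n_nfl", "pct_unspliced", "pct_readthrough", "events_per_transcript")


@dataclass(frozen=True)
class JunctionCount:
    donor_label: str
    acceptor_label: str
    donor_coord: int  # representative (first observed) coordinates
    acceptor_coord: int
    read_count: int
    pct_of_events: float
    pct_of_assigned: float

    @property
    def label(self) -> str:
        return f"{self.donor_label}-{self.acceptor_label}"


@dataclass
class SpliceSummary:
    library: str
    n_nfl: int
    pct_unspliced: float
    pct_readthrough: float
    pct_readthrough_all: float  # whole-library variant, logged alongside
    events_per_transcript: float
    junction_table: list[JunctionCount]
    denominator_mode: str = "nfl_only"

    def junction(self, label: str) -> JunctionCount:
        for jc in self.junction_table:
            if jc.label == label:
                return jc
        raise KeyError(label)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "donor_label": jc.donor_label,
                    "acceptor_label": jc.acceptor_label,
                    "donor_coord": jc.donor_coord,
                    "acceptor_coord": jc.acceptor_coord,
                    "read_count": jc.read_count,
                    "pct_of_events": jc.pct_of_events,
                    "pct_of_assigned": jc.pct_of_assigned,
                }
                for jc in self.junction_table
            ]
        )


def summarize(
    classifications: list[ReadClassification],
    denominator_mode: str = "nfl_only",
    library: str = "library",
) -> SpliceSummary:
    """Library-level splicing statistics from read classifications.

    ``denominator_mode`` selects the read set whose splice events form the
    per-junction percentage denominator: ``nfl_only`` (default; matches the
    per-transcript rows) or ``whole_library`` (every retained read, the
    alternative reading of the per-junction percentages).
    """
    if denominator_mode not in ("nfl_only", "whole_library"):
        raise ValueError(f"unknown denominator_mode {denominator_mode!r}")
    nfl = [c for c in classifications if c.nfl]
    if not nfl:
        raise EmptyInputError("no near-full-length reads")
    n_nfl = len(nfl)
    n_unspliced = sum(1 for c in nfl if c.unspliced)
    n_readthrough = sum(1 for c in nfl if c.readthrough)
    nfl_events = sum(len(c.junctions) for c in nfl)

    denom_set = nfl if denominator_mode == "nfl_only" else list(classifications)
    counts: dict[tuple[str, str], list] = {}  # label pair -> [count, d, a, novel]
    assigned_total = 0
    for c in denom_set:
        for j in c.junctions:
            key = (j.donor_label, j.acceptor_label)
            entry = counts.setdefault(key, [0, j.donor_coord, j.acceptor_coord, j.is_novel])
            entry[0] += 1
            assigned_total += not j.is_novel
    total_events = sum(e[0] for e in counts.values())

    table = [
        JunctionCount(
            donor_label=d,
            acceptor_label=a,
            donor_coord=dc,
            acceptor_coord=ac,
            read_count=n,
            pct_of_events=100.0 * n / total_events if total_events else 0.0,
            pct_of_assigned=(
                0.0 if novel or not assigned_total else 100.0 * n / assigned_total
            ),
        )
        for (d, a), (n, dc, ac, novel) in sorted(
            counts.items(), key=lambda kv: (-kv[1][0], kv[0])
        )
    ]
    pct_rt_all = (
        100.0 * sum(1 for c in classifications if c.readthrough) / len(classifications)
        if classifications
        else 0.0
    )
    logger.info(
        "library %s: %d NFL reads, whole-library readthrough %.2f%%",
        library,
        n_nfl,
        pct_rt_all,
    )
    return SpliceSummary(
        library=library,
        n_nfl=n_nfl,
        pct_unspliced=100.0 * n_unspliced / n_nfl,
        pct_readthrough=100.0 * n_readthrough / n_nfl,
        pct_readthrough_all=pct_rt_all,
        events_per_transcript=nfl_events / n_nfl,
        junction_table=table,
        denominator_mode=denominator_mode,
    )


def filter_junctions(summary: SpliceSummary, min_support: int = DEFAULT_MIN_SUPPORT) -> SpliceSummary:
    """Restrict the junction table to junctions with enough supporting reads.

    Library-level percentages are left untouched; only the annotated table
    shrinks, mirroring the at-least-N-independent-reads annotation rule used
    for sashimi-style junction displays.
    """
    return replace(
        summary,
        junction_table=[jc for jc in summary.junction_table if jc.read_count >= min_support],
    )


def sig_round(x: float, figures: int = 3) -> float:
    """Round to a number of significant figures (display only)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, figures - 1 - int(math.floor(math.log10(abs(x)))))


def _summary_frame(summaries: list[SpliceSummary]) -> pd.DataFrame:
    """Side-by-side layout: one row per statistic/junction, one column per library."""
    rows: dict[str, dict[str, float]] = {name: {} for name in SUMMARY_ROWS}
    for s in summaries:
        rows["n_nfl"][s.library] = s.n_nfl
        rows["pct_unspliced"][s.library] = s.pct_unspliced
        rows["pct_readthrough"][s.library] = s.pct_readthrough
        rows["events_per_transcript"][s.library] = s.events_per_transcript
        for jc in s.junction_table:
            rows.setdefault(f"pct_events:{jc.label}", {})[s.library] = jc.pct_of_events
    frame = pd.DataFrame(rows).T
    frame.index.name = "statistic"
    return frame


def export(
    summaries: SpliceSummary | list[SpliceSummary],
    out_dir: str | Path,
    genome: VectorGenome | None = None,
    plot: bool = False,
) -> dict[str, Path]:
    """Write the summary TSV, per-junction BED files and optional arc plots.

    The summary TSV keeps full float precision so it round-trips exactly; the
    companion ``report.txt`` applies 3-significant-figure display rounding.
    Junction BED rows span donor to acceptor (half-open), scored by read count.
    """
    if isinstance(summaries, SpliceSummary):
        summaries = [summaries]
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    frame = _summary_frame(summaries)
    paths["summary"] = out_dir / "summary.tsv"
    # %.17g guarantees the doubles survive the text round trip exactly
    frame.to_csv(paths["summary"], sep="\t", float_format="%.17g")

    pretty = frame.map(lambda v: sig_round(v) if isinstance(v, float) else v)
    paths["report"] = out_dir / "report.txt"
    paths["report"].write_text(pretty.to_string() + "\n")

    for s in summaries:
        bed = out_dir / f"junctions_{s.library}.bed"
        paths[f"bed:{s.library}"] = bed
        chrom = genome.name if genome is not None else s.library
        with open(bed, "w") as fh:
            for jc in s.junction_table:
                fh.write(
                    f"{chrom}\t{jc.donor_coord}\t{jc.acceptor_coord + 1}\t"
                    f"{jc.label}\t{jc.read_count}\t+\n"
                )
    if plot:
        for s in summaries:
            paths[f"plot:{s.library}"] = plot_arcs(s, out_dir / f"arcs_{s.library}.png", genome)
    return paths


def load_summary_frame(path: str | Path) -> pd.DataFrame:
    """Read back the summary TSV written by :func:`export`."""
    return pd.read_csv(path, sep="\t", index_col="statistic", float_precision="round_trip")


def plot_arcs(summary: SpliceSummary, path: str | Path, genome: VectorGenome | None = None) -> Path:
    """A minimal coverage-free sashimi-style arc plot of junction usage."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    fig, ax = plt.subplots(figsize=(9, 3))
    table = summary.junction_table
    for jc in table:
        d, a = jc.donor_coord, jc.acceptor_coord
        xs = np.linspace(d, a, 100)
        height = 0.2 + 0.8 * jc.read_count / max(j.read_count for j in table)
        ys = height * np.sin(np.pi * (xs - d) / (a - d))
        ax.plot(xs, ys, lw=1 + 3 * height)
        ax.text((d + a) / 2, height, f"{jc.label} ({jc.read_count})", ha="center", fontsize=6)
    if genome is not None:
        ax.set_xlim(0, genome.length)
    ax.set_yticks([])
    ax.set_xlabel("reference position (nt)")
    ax.set_title(summary.library)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
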