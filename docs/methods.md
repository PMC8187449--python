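# Methods

## Genome model and coordinate conventions

A vector genome is a single forward-strand reference with typed features.
All coordinates are 0-based half-open, matching BED; the annotation format is
BED6 plus two extension columns (`kind`, `origin`).  Splice sites are 1-nt
point features with a fixed convention: a donor's coordinate is the first
intronic base, an acceptor's the last, so an intron occupies
`[donor, acceptor + 1)` and a junction is written `(donor, acceptor)`.  One
convention had to be fixed; this one makes the junction tuple identical to
the reference-skip arithmetic of a gapped alignment.

HIV-1 origin is an annotation column, never inferred from sequence: the
nucleotide accounting is definitional (which designed elements derive from
HIV-1), not alignment-based.  HIV-1 content is the length of the union of
HIV-1-origin spans, so nested features (the RRE inside env) are counted
once.  Provirus content clips the union at the 3' R boundary `r3_end`,
because sequence downstream of the 3' R is excluded from reverse
transcription and never reaches the integrated provirus.

Deletion accounting reports `content(parent) − content(derived)` plus a
per-feature breakdown.  The breakdown attributes each base of the union to
exactly one covering feature using the parent's genomic feature order, so
the entries always sum to the total.  When an element is repositioned rather
than deleted (an RRE moved downstream of the 3' R), the genomic-RNA
breakdown shows the enclosing span as fully removed and the repositioned
element as a negative (retained) entry; the provirus-restricted breakdown is
clean because the repositioned element no longer counts at all.

### Bundled designs

The real plasmid sequences are not public, so the bundled pLV-family designs
are laid out from the known feature lengths (gag 364 nt, retained 21/60 nt;
env 858 nt containing the 351 nt RRE; R 97 nt, U5 84 nt, etc.) at synthetic
but internally consistent absolute coordinates, with a synthetic random
nucleotide sequence per design.  Every accounting statement about these
designs (850 nt removed from the genomic RNA, 1201 nt from the provirus)
follows from the lengths alone and is therefore exact.  Splice-site
positions are likewise synthetic, with neighbouring sites kept ≥ 60 nt apart
so that site assignment is unambiguous at the default tolerance.

One geometric choice deserves note: SA7 is placed upstream of the cryptic
donor CD3 within the deletable 3' portion of env.  This makes two-junction
transcripts `[SD1–SA7, CD3–CAx]` possible, which is the only arrangement
under which the measured per-library statistics (events per transcript
exceeding the spliced-read fraction, with the observed junction shares) are
simultaneously realizable.  Biologically it corresponds to transcripts that
splice SD1→SA7 and then splice again from a downstream cryptic donor.

## Read classification

* Only primary, forward-strand, mapped records are classified; secondary and
  supplementary records are dropped so that each molecule is counted once,
  and reverse-strand records are dropped (the vector transcript is sense
  RNA) with a logged count.  Every input record is accounted for in the log.
* **Near-full-length (NFL)**: alignment start strictly upstream of SD1
  (`ref_start < SD1`), i.e. at least one aligned nucleotide upstream of the
  donor.  Soft/hard clips do not extend the span — clipped bases are not
  evidence of upstream coverage.  Only NFL reads can distinguish spliced
  from 5'-truncated, so all per-transcript statistics are over NFL reads.
* **Junction extraction** is a CIGAR walk: every reference-skip (`N`)
  operation yields one junction.  Deletions (`D`) of at least `min_intron`
  nt can optionally be promoted to junctions (default disabled; 30 nt is a
  reasonable setting) for aligner dialects that encode introns as long
  deletions.  Short deletions and insertions never produce junctions.
* **Site assignment**: each junction end is assigned to the nearest
  catalogued donor/acceptor within ± `tolerance` nt (default 8, typical
  nanopore junction placement wobble), ties broken toward the lower
  coordinate, otherwise labelled `novel@coord`.  Raising the tolerance can
  only reduce the number of novel labels.  Junction identity for counting is
  the labelled pair; distinct novel coordinates are distinct junctions.
* **Readthrough**: alignment end beyond `r3_end`.  Unspliced and
  readthrough are independent flags — nothing makes them exclusive.

## Library statistics

Over NFL reads: `pct_unspliced` (zero-junction reads), `pct_readthrough`,
and `events_per_transcript` (junction events / NFL reads; events in
readthrough reads count identically).  A whole-library readthrough
percentage is logged alongside, since the published presentation does not
pin down that denominator.

Per-junction percentages come in two denominators:

* `pct_of_events`: share of all splice events in the denominator set
  (default `nfl_only`; `whole_library` is available as a switch because the
  alternative reading counts every junction-spanning read in the library).
  The unfiltered column sums to 100.
* `pct_of_assigned`: share of events whose both ends matched a catalogued
  site.  Boundary jitter beyond the assignment tolerance relabels a known
  fraction of junctions as novel (see below); excluding those from the
  denominator removes that dilution, so this column is the unbiased
  estimator of a catalogued junction's true usage share and is what the
  acceptance script reports.

The junction table can be filtered to junctions with ≥ `min_support` reads
(default 10, the usual annotation threshold for sashimi-style displays);
filtering never touches the library-level percentages.  Exports are a
full-precision summary TSV (exact round-trip), a 3-significant-figure
human-readable report, a junction BED (donor, acceptor + 1, label, read
count) per library, and an optional arc plot.

## The simulator

Each read: draw an isoform from the weighted mixture; draw readthrough with
probability `readthrough_prob` (alignment end `r3_end` + Uniform[min, max]
extension, default 50–400 nt — only the readthrough *fraction* matters for
the statistics, so the extension law is nominal); draw a 5' truncation
offset `T ~ Geometric` (mean `truncation_mean`, default 1000 nt) in
transcript coordinates, clamped so at least `min_read_length` (200 nt) of
the 3' anchor survives; map the truncated transcript through the junction
chain to reference blocks; jitter each surviving junction by a rounded
`Normal(0, wobble_sd)` offset applied equally to both boundaries (intron
length preserved — placement ambiguity without changing event identity),
clamped so every match block keeps ≥ 1 base; emit the result as a gapped
alignment record.  Truth rows record the pre-jitter isoform junctions, the
post-truncation observable junctions, the readthrough flag and the start
coordinate.  Fixed seed ⇒ byte-identical truth output.

Because every junction donor lies at or downstream of SD1, an NFL read
always retains its full junction chain, and NFL status (`T` < SD1 offset)
is independent of isoform — so among NFL reads the isoform fractions equal
the configured weights exactly in expectation.  With mean truncation
1000 nt, ≈ 39 % of reads are NFL.

What the generator does **not** emulate: nanopore base-call error profiles
and homopolymer artifacts (FASTQ noise is a simple uniform
substitution/indel model applied after alignment emission), chimeric or
antisense reads, host-genome alignments, coverage biases along the
transcript beyond the geometric truncation, and any sequence-dependent
splice-site strength.  Passing tests therefore demonstrate that the
analysis stack is correct under the declared generative model, not that a
real basecaller/aligner pipeline is free of artifacts upstream of it.

### Library presets

Per sequenced vector, isoform weights are solved so the analytic statistics
equal the measured per-library values (unspliced fraction, readthrough
fraction, events per transcript, major junction shares), with small
unannotated junctions absorbing the residual share.  One measured pair is
jointly infeasible under the definitions: a spliced read carries ≥ 1
junction, so events/transcript ≥ 1 − unspliced; for the env-deleted library
(15.3 % unspliced, 0.83 events/transcript reported) the preset keeps the
unspliced fraction and realizes the feasible minimum 0.847.

## Numerical and statistical choices

* Jitter label loss: with `wobble_sd` = 4 and tolerance 8, the probability
  that a junction's rounded offset exceeds the window is
  `q = 2(1 − Φ(8.5/4)) ≈ 0.034`.  Analytic expectations for labelled
  junction shares are multiplied by `1 − q`; the assigned-denominator
  percentage needs no correction because all catalogued junctions lose the
  same fraction.
* Recovery tests compare estimates to analytic values at 3 binomial
  standard errors at n = 5000 reads per library; the published-value mirror
  runs n = 20000 reads per library so that 3 SE sits inside the ± 2
  percentage-point comparison band.  The acceptance script also uses 20000
  reads per library (≈ 4 s each end to end).
* Degenerate inputs: zero NFL reads is an explicit error (the statistics
  are undefined); an empty record set still yields valid empty outputs from
  the writer; a mixture with only the unspliced isoform, or zero
  readthrough probability, produce exactly the degenerate libraries one
  expects.
* Determinism: a single seed drives the simulator; classification and
  statistics are seed-free by construction, so replaying any pipeline on
  the same inputs reproduces every output byte.

## Known limitations

* Synthetic coordinates: junction positions and the genome layout are
  internally consistent but arbitrary, so coordinate-level outputs (BED
  tracks) are comparable only within this package's designs.
* Real libraries require an external spliced aligner upstream; aligner
  idiosyncrasies (junction snapping to splice motifs, supplementary
  alignments of chimeras) are outside the generator's model.
* The per-junction percentage denominator in the published presentation is
  ambiguous (junction-spanning reads vs events, NFL vs whole library); both
  modes are implemented and the choice is surfaced, but cross-study
  comparisons should state the denominator.
* No statistical testing between libraries is provided; the statistics are
  descriptive, as in the presentation they mirror.
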