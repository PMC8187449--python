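# lvsplicemap

Splice-site usage, 3'-readthrough and HIV-1 sequence accounting for
lentiviral vector genomes, from spliced long-read alignments.

## The problem

HIV-1-derived lentiviral vectors still carry substantial viral sequence
(often > 1.5 kb) beyond what transduction strictly requires: a 5' leader with
the major splice donor SD1, a gag fragment, an env fragment containing the
Rev-response element (RRE) and the canonical splice acceptor SA7, the cPPT,
and LTR-derived R/U5 parts.  Two questions matter for vector design:

1. **How much HIV-1 sequence does a redesign remove** — from the genomic RNA,
   and from the integrated provirus (sequence downstream of the 3' R boundary
   is never reverse transcribed, so an element repositioned there ships with
   the virion but not with the provirus)?
2. **What does the vector transcript pool look like** — what fraction of
   genomes is unspliced (the only packageable species), which canonical and
   cryptic donor/acceptor pairs are used, and how many transcripts read
   through the 3' R into plasmid backbone?

Nanopore direct-cDNA sequencing answers question 2 because single reads span
whole transcripts, but the reads are 3'-anchored with ragged 5' ends and
noisy junction boundaries.  `lvsplicemap` implements the complete analysis:
read selection, junction extraction and labelling, readthrough detection,
library statistics, and the deletion accounting — plus a ground-truthed
simulator of such libraries so that every stage is testable end to end.

## Model and definitions

For a vector genome of length *L* with canonical donor SD1 at coordinate
*s* and 3' R boundary *r* (0-based, half-open):

- a read with reference span *[b, e)* is **near-full-length (NFL)** iff
  *b < s* (it covers at least one nucleotide upstream of SD1, so it can
  witness the transcript's splicing status);
- each reference-skip in its alignment is a **junction** *(d, a)* where *d*
  is the first and *a* the last intronic base; each end is assigned to the
  nearest catalogued splice site within ± 8 nt (configurable), else labelled
  `novel@coord`;
- the read is **readthrough** iff *e > r*;
- per library: `% unspliced` = NFL reads with zero junctions / NFL reads,
  `% readthrough` = NFL readthrough reads / NFL reads,
  `events/transcript` = junction events in NFL reads / NFL reads, and each
  junction's `% of total splicing events` = its supporting reads / all
  junction events (an assigned-only denominator is also reported);
- HIV-1 content is the length of the union of HIV-1-origin feature spans;
  provirus content restricts that union to coordinates < *r*.

## Worked example

Accounting for the combined gag/env redesign (bundled vector designs):

```
$ lvsplicemap account --parent pLV --derived pLV-RREgag21
feature removed_nt
gag     343
env     507
total_removed_hiv1_nt   850
parent_hiv1_nt  1926
derived_hiv1_nt 1076
```

343 nt of gag (all but the first 21 nt) and 507 nt of env (all but the
351 nt RRE) are removed: 850 nt less HIV-1 sequence in the genomic RNA.
Repositioning the RRE downstream of the 3' R additionally excludes it from
reverse transcription:

```
$ lvsplicemap account --parent pLV --derived "pLV-gag21-3'RRE" --provirus
feature removed_nt
gag     343
env     858
total_removed_hiv1_nt   1201
```

End-to-end on a simulated pLV-like library (5000 reads, seed 7):

```
$ lvsplicemap e2e --preset pLV --n-reads 5000 --seed 7 --out demo/
$ cat demo/report.txt
                     pLV
statistic
n_nfl               1990.000
pct_unspliced          4.380
pct_readthrough       28.600
events_per_transcript  1.110
pct_events:SD1-SA7    53.600
pct_events:SD1-CA6    13.200
pct_events:CD3-CA6     8.690
...
```

Of 5000 simulated reads, 1990 are near-full-length; 4.4 % of those are
unspliced genomes, 28.6 % read through the 3' R, and transcripts average
1.11 splice events, with SD1→SA7 the dominant junction — matching the
preset's configured mixture.  `demo/recovery.json` lists each estimate next
to its analytic value under the generator; `demo/junctions_pLV.bed` holds
the junction-count track (junctions with ≥ 10 supporting reads) for
sashimi-style display.

The same stages are available separately (`simulate`, `classify`,
`summarize`) and as library functions.

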