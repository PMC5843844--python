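# igpipe

Tools for optimising *ex vivo* memory-B-cell expansion conditions and for
verifying, by barcoded IgH deep sequencing, that the optimised culture does
not alter the immunoglobulin genotype.

The package has two halves that share one workflow:

1. **A full-factorial design-of-experiments (DoE) engine.** Four expansion
   stimuli — IL-21, the TLR agonists R848 and CpG ODN2006, and CD40 signal
   strength delivered as a CD154⁺ feeder-cell ratio — are varied over a 3⁴
   grid of 81 culture conditions with secreted Ig (ELISA) as readout. A
   balanced N-way ANOVA decomposes response variance into first-order and
   second-order terms; each term's *sensitivity index* is its variance
   fraction

   SIᵢ = SS_term / SS_total ∈ [0, 1],

   with F-tests against the residual mean square and p-values reported to
   four decimals. The optimal condition takes, for every factor with a
   significant first-order effect, the level maximising its marginal mean;
   non-significant factors fall back to their lowest dose.

2. **A barcoded IgH amplicon pipeline.** Paired MiSeq reads from a
   constant-primer RT library (universal handle + 14-nt `NNNNTNNNNTNNNN`
   molecular barcode + isotype-specific tail) are median-Phred filtered
   (> 34), merged on an identical > 50 bp overlap, oriented V-primer →
   constant primer, barcode-checked at the conserved T positions, isotype-
   assigned by shared 10-mers against the first 50 bp of each constant
   reference, trimmed, and collapsed to one consensus per (barcode, isotype)
   group retained at > 80 % positionwise certainty. A simplified junction
   annotator then assigns germline V/J genes by local alignment, checks the
   reading frame, and reports somatic hypermutation (% mismatched
   nucleotides over the aligned V, FR1-primer span excluded) and CDRH3
   length in nucleotides (codons strictly between the V 2nd-CYS and the J
   W/F anchor). Repertoire summaries test isotype-composition and SHM
   stability across a 10-day culture.

A synthetic-data module generates both kinds of input — clonal IgH
molecules with a full truth ledger, paired FASTQ with substitution errors,
and balanced factorial response tables with known effects — so every stage
is testable offline against ground truth.

Intended users: immunology labs optimising B-cell culture protocols and
groups building or validating UMI-based BCR repertoire pipelines.

## Worked example

Simulate a 3-donor triplicate 3⁴ screen with known effects (increasing
IL-21, R848 and CD40 effects, an IL-21×CD40 synergy, a truly null CpG) and
analyse it:

```bash
igpipe doe simulate --seed 3 --out table.csv
igpipe doe analyze --responses table.csv --out doe_out
```

`doe_out/anova_total.tsv` (abridged):

```
     term  order        SS  df       F  p_display     index
    donor      0 3.067e+04   2    2458     0.0000    0.4447
     IL21      1 1.824e+04   2    1462     0.0000    0.2645
      CpG      1     1.114   2 0.08928     0.9146 1.615e-05
     R848      1      6199   2   496.8     0.0000   0.08989
     CD40      1      8293   2   664.6     0.0000    0.1203
IL21:CD40      2      1145   4   45.88     0.0000    0.0166
 residual      0      4330 694     NaN        NaN   0.06279
    total      0 6.896e+04 728     NaN        NaN         1
```

IL-21, R848 and CD40 carry significant first-order variance, the injected
IL-21×CD40 interaction is the only significant second-order term, and CpG is
indistinguishable from noise. The selector therefore reports

```
optimal conditions: {"total": {"levels": {"IL21": "100", "CpG": "0",
  "R848": "0.5", "CD40": "1:1"}, ...}}
```

i.e. 100 ng/ml IL-21, 0.5 µg/ml R848, a 1:1 feeder ratio, and CpG dropped
to zero dose.

For the sequencing half, simulate a repertoire and push it through the
cascade:

```bash
igpipe simulate-reads --seed 17 --n-clones 50 --molecules-per-clone 4 \
    --shm-rate 0.03 --error-rate 0.002 --out sim
igpipe process --r1 sim/R1.fastq --r2 sim/R2.fastq \
    --refs sim/germline.fasta --anchors sim/anchors.tsv \
    --scheme sim/scheme.yaml --out run
```

```
simulated 200 molecules -> 4000 read pairs
merge: in=4000 out=2405
orient: in=2405 out=2326
barcode: in=2326 out=2316
isotype: in=2316 out=2316
trim: in=2316 out=2316
consensus_records: in=257 out=257
annotation: in=257 out=256
```

Roughly 40 % of pairs fail the exact-overlap merge at a 0.2 %/base error
rate (any mismatch in the ~150 bp overlap discards the pair); the surviving
reads collapse into 257 consensus groups — the 200 true molecules plus a
tail of barcode-error singleton families — and all but one annotate as
productive IgH rearrangements. `run/read_ledger.tsv` accounts for every
input pair and `run/rearrangements.tsv` holds the AIRR-style per-molecule
calls (V/J, SHM %, CDRH3 length, isotype).

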