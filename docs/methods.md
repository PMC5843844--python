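# Methods

This note records the models, parameter choices and numerical conventions
behind `igpipe`, and what the synthetic-data tests do and do not establish
about real data.

## Factorial design and variance decomposition

The screen is a balanced full factorial over four stimuli at three dose
levels each (81 conditions): IL-21 at 10/50/100 ng/ml, CpG ODN2006 at
0/0.25/1 µg/ml, R848 at 0/0.25/0.5 µg/ml, and CD40 stimulation as the
CD154⁺ feeder-to-memory-B-cell ratio at 1:5/1:2/1:1. Donors contribute an
additive blocking term (three donors, triplicate wells per condition in the
reference configuration).

On a balanced grid the effect subspaces are orthogonal, so sums of squares
come directly from means:

* first order: `SS_A = Σ_a n_a (ȳ_a − ȳ)²`
* second order: `SS_AB = Σ_ab n_ab (ȳ_ab − ȳ_a − ȳ_b + ȳ)²`
* donor block: same form as a first-order term
* interactions above order 2 are pooled into the residual.

F statistics divide each term's mean square by the residual mean square;
p-values come from the F distribution and are rounded to four decimals for
display only. The *sensitivity index* of a term is defined as
`SS_term / SS_total` (an η²-style variance fraction): the term "sensitivity
index" has no unique formula in the DoE literature, and the SS fraction is
the normalised quantity that makes first- and second-order effects directly
comparable. Normalising by `SS_total` rather than `SS_model` was a
deliberate choice; the residual fraction is reported alongside so either
view is recoverable. Donor blocking is on by default and toggleable —
averaging donors first is the other defensible reading, and both are
supported.

Degenerate tables (zero total variance) return an all-zero index report
with an explicit flag rather than raising, so pipelines stay composable.
Analysis runs on the raw Ig readout scale; a log transform is a caller-side
option, not a default, because the screen's readout is reported raw.

Optimal-condition selection: for each factor with first-order p < α
(default 0.05), take the level with the highest marginal mean, ties broken
toward the lower dose; non-significant factors default to their lowest/zero
dose. This reproduces the logic by which a stimulus with no detectable
effect is dropped from the final cocktail.

Head-to-head comparisons of a handful of final conditions use a classical
two-way ANOVA with Tukey's HSD post hoc (studentized-range adjusted), via
statsmodels; the factorial decomposition above is implemented in-package
and cross-checked in tests against both a brute-force group-mean oracle and
statsmodels OLS ANOVA.

## Read-processing cascade

Thresholds (all strict inequalities where noted) live in one config object:
median Phred > 34; identical overlap > 50 bp for pair merging; k = 10 for
isotype k-mer matching against the first 50 bp of each constant reference;
group sequence certainty > 0.80; FR1 primer located with ≤ 2 mismatches;
members further than ±2 nt from the group modal length dropped before
consensus scoring.

Conventions worth making explicit:

* **"Identical" overlap is literal**: zero mismatches, longest qualifying
  overlap wins, deterministic. Overlap quality takes the per-position
  maximum of the two reads (bases are identical by construction).
* **Barcode**: the constant-primer sequences all carry a 14-nt
  `NNNNTNNNNTNNNN` barcode between the universal handle and the isotype
  tail, so the barcode is 14 nt with conserved T at 1-based positions 5 and
  10 (the prose pattern with a trailing T reads the first base of the IGHM
  tail as part of the template; the primer sequences are authoritative).
* **Group key is (barcode, isotype)**: barcodes live inside
  isotype-specific primers, so a cross-isotype barcode collision must not
  merge molecules.
* **Sequence certainty** is the mean over positions of the plurality-base
  fraction among the group's modal-length members. It is computable for any
  group size, equals pairwise identity for n = 2, and a singleton group has
  certainty 1.0 by vacuous agreement. Whether the original cascade built a
  consensus or merely filtered reads is not recoverable from its
  description; this implementation emits a consensus and keeps support and
  membership so the filter-only view is recoverable.
* Consensus ties break by highest summed Phred, then alphabetically —
  fully deterministic.
* Coordinates are 0-based half-open internally; 1-based only in prose.
* U bases in the 3' universal primer are matched as T; chimeric reads
  (handle on both strands) are binned separately rather than silently
  dropped.
* Every input pair appears in a per-read ledger with the stage reached and
  reject reason, so stage counts conserve the input total by construction.

Out of scope by design: indel-aware consensus, barcode error-correction
networks, sample demultiplexing.

## Annotation

A deliberately simplified junction annotator replaces full IMGT-style
numbering, because downstream analysis consumes exactly two statistics that
are well-defined without it. V and J genes are assigned by local alignment
(k-mer-seeded candidate ranking, then Smith–Waterman with match +1,
mismatch −1, gap open −4, extend −1); retention requires ≥ 80 % identity
over ≥ 100 aligned nt for V and ≥ 25 nt for J — configurable stand-ins for
a BLAST significance screen. Reading frame is inherited from germline V
codon phase; a sequence fails if translation to the end of the J alignment
hits a stop codon or the J alignment sits in a different codon phase than
the V (so a 1-nt junction indel fails).

SHM is the percentage of mismatched nucleotides over the aligned V span,
excluding gap columns (indels are not mutation events here) and excluding
the FR1-primer-covered span: primer bases are synthetic copies of the
primer, not the template, and counting them would mask true mutations.

CDRH3 is the codons strictly between the V 2nd-CYS codon and the J W/F
anchor codon, reported in nucleotides with both anchors excluded; an IMGT
junction is 6 nt longer. The anchor codon must still read TGG/TTT/TTC in
the query; a mutated-away motif leaves CDRH3 undefined rather than guessed.

## Synthetic data

The simulator emulates the library design end to end: amplicons run
FR1-primer → V → junction → J → first 50 bp of constant region →
revcomp(barcode) → revcomp(handle), paired 300 bp reads cover the two ends
with a true overlap of `2·300 − |amplicon|` (~100–140 bp for the ~470 nt
toy amplicons), and substitution errors are applied per base at a flat
Phred profile (Q38 default).

Toy references are generated, not fetched: six 300-nt V alleles whose 5'
ends are the six multiplex FR1 primers of the default scheme (mutually ≤ 90 % identical
bodies, frame 0, terminal TGT as the 2nd-CYS), four 48-nt J alleles opening
with TGG, and five 50-bp constant references whose 3' ends
reverse-complement the scheme's isotype primer tails. Generation avoids
frame-0 stop codons; SHM substitutions likewise re-draw the target base
when a substitution would create a stop, which keeps the injected per-site
rate intact while guaranteeing productive molecules — a deliberate
simplification that makes truth recovery exact rather than
stop-codon-censored.

Default conditions: isotype mixtures per sorted subset (IgM⁺ subsets
essentially IgM, the double-negative subset a stable IgG/IgA mixture),
codon-aligned CDRH3 lengths spanning 30–66 nt, CDRH3 drawn per clone and
SHM drawn per molecule, barcodes unique per run (a collision-rate knob
exists for stress tests).

**UMI family depth is 20 reads per molecule by default.** This matters
under the literal exact-overlap merge: at a 0.2 %/base error rate roughly
40 % of pairs carry a mismatch somewhere in the overlap and are discarded,
and a further ~3 % leave their family through an error in the
single-covered barcode region. Families therefore need enough reads that
the merge-surviving membership stays ≥ 3, where the plurality consensus
out-votes single-coverage errors; at depth 20 the probability of a family
shrinking to ≤ 2 survivors is negligible and molecule-exact recovery is
complete, whereas at depth ~3 a substantial fraction of families survive
as singletons or pairs whose consensus inherits unvoted errors. Deep
oversampling of RT molecules is the norm in UMI-based BCR-seq libraries
(25+ PCR cycles), so this default reflects realistic practice rather than
an algorithmic requirement.

What passing synthetic tests do **not** show about real data: no indels
(sequencing or SHM), no PCR chimeras or error motifs, no quality drift
along the read, real germline allele sets are far more similar than the
toy set (V misassignment is harder in practice), and real UMI families
have skewed size distributions. The pipeline's thresholds are the library
defaults, not values validated on real MiSeq runs.

## Repertoire stability

The claim "isotype proportions remain stable over culture" is made
assertable as: total-variation distance between isotype fraction vectors
plus a chi-square homogeneity test on the counts; the SHM trajectory is the
day-10 minus day-0 mean difference with a seeded percentile bootstrap CI
(10⁴ resamples, α = 0.01 by default). Calibration runs use one molecule per
clone, because the clone — not the transcript — is the independent sampling
unit for isotype: clone-clustered counts overdisperse the chi-square and
inflate its false-positive rate. At the analysis level the same concern is
addressed by the clonality-aware collapse (consensus records are already
one-per-molecule; collapsing further to clones is the caller's choice).
Baseline IgG1/IgA1 reads in IgM⁺ subsets (plasmablast carry-over from
sorting) are handled by an analysis flag, not excluded by default.

## Problem sizes

Self-checks run at desk scale: 2 000 molecules for round-trip recovery
(zero-error at family depth 3, 0.2 % error at depth 20), 500 molecules per
SHM level across {0, 1, 3, 6} %, 2 000 independent clones for the CDRH3
goodness-of-fit, 100 seeded screens for DoE recovery and 100 seeded
three-day runs of 300 clones/day for stability calibration. All generators
take a mandatory seed and are byte-deterministic given it.
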