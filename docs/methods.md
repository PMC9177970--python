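# Methods

This note documents the models, conventions and numerical choices behind
`splicecode`, and what the synthetic data generator does and does not
emulate.

## Coordinate conventions

Internal CDS coordinates are 1-based inclusive, numbered from the first
position of the first codon; BED I/O is 0-based half-open, and the two meet
only in the converter pair `cds_to_bed`/`bed_to_cds`. RNA letters are
normalized to DNA (U→T) at read time. These two rules eliminate the usual
±1 drift between loop numbering and interval arithmetic.

## Consensus scanning

The EF-hand chelation loop is matched with a 12-position constraint list
parsed from a PROSITE-style string (square brackets = permitted set,
parentheses = forbidden set, `x` = any). All overlapping matches are
reported in left-to-right order; pairing of EF-hands into lobes is not
modelled. The ambiguity letter `X` is handled conservatively: it never
satisfies a permitted set and never proves a violation of a forbidden set.
S100 membership is input metadata (a gene list), because the S100
pseudoloop has 14 residues and cannot fit the 12-position pattern; non-EF
coordinating residues come from curated per-gene codon positions, with no
structural inference.

## Hexamer profile statistics

The profile value at nt position *i* is the score of the hexamer
**starting** at *i*, not of every hexamer covering *i*; core position 1 is
the loop's first nt, so the 108-nt motif spans positions −35..72. Region
means pool over sequence × member-position pairs, and the reported
`n_positions` is that pooled count. Hexamers spanning the loop boundary use
real flanking CDS context; windows lacking context simply do not contribute
to those positions (per-position `n_seq` bookkeeping). Position means use
exact (`fsum`) accumulation, so profiles are invariant under permutation of
the input sequences.

The coordinating-residue region CR defaults to loop codons {1, 3, 5, 9, 12}
— the side-chain carboxyl ligands plus the water-bridged position 9. Codon
7 contacts the ion through its backbone carbonyl, so its wobble identity is
unconstrained by chelation; it is excluded by default and can be added via
configuration.

The control-exon background trims the first nt and the last three nt of
every exon before pooling hexamer-start scores, because those positions
belong to the 3′ and 5′ splice-site consensus rather than to the exon
interior. Pooling is position-weighted (every surviving hexamer start
counts once); an exon-weighted variant would weight short exons up and is
not what the pooled mean is meant to estimate here.

## Codon-level ratios

Each hexamer contributes its four 3-mer substrings (offsets 0–3), so *n*
hexamers always yield exactly 4*n* codon tokens. With pseudocount π the
frequency ratio for codon *c* is

    ln(ESEf/ESSf) = ln[(nE(c)+π)/(NE+64π)] − ln[(nS(c)+π)/(NS+64π)]

computed as a **difference of logarithms** so that swapping the two hexamer
sets negates every value exactly in floating point. π = 0.5 (Haldane) is
the default for all ratio statistics; π = 0 is permitted and degrades to
±∞/NaN when zero counts occur. Dinucleotide log-odds use the same smoothing
over the 5 overlapping dinucleotides per hexamer.

## Codon usage

RSCU is count over the equal-usage family expectation; unobserved families
are NaN rather than 0. CAI follows the geometric-mean-of-w convention with
Met, Trp and stop codons excluded (single-codon families carry no usage
information); users comparing against tools that include them can compute
w directly from `relative_adaptiveness`.

The expected-CAI null preserves the amino-acid **sequence** (not merely its
composition) and resamples each codon within its synonymous family under
weights ∝ t^GC(codon). The single GC-affinity parameter t is solved by
bisection until the sampler's expected GC equals the query's GC within
0.1% — one interpretable parameter rather than an opaque resampling
recipe. The null mean, SD and the fraction of null CAIs at or above the
query are returned; with a uniform reference all w = 1 and the null is
degenerate at CAI = 1.

Usage-bias contrasts between two synonymous codons use the exact two-sided
binomial test (point-probability method, ties included), which is exact at
the sample sizes loop-position contrasts produce (a few hundred loops).
A codon is *fragile* when one of its nine single-nt neighbours is a stop
codon (TAA/TAG/TGA), *robust* otherwise; Glu and Cys codons are fragile,
Asp and His codons robust.

## Exon architecture

A split is indexed by the **first loop nt downstream of the intron**:
an intron between CDS nt *p* and *p*+1 has loop-relative position
*p* − loopStart + 2. An intron immediately before loop nt 1 is position 1
(within); an intron immediately after loop nt 36 is outside. This keeps
exactly 36 within-loop positions out of the 108 motif positions, matching
the uniform expectation loopLen/motifLen = 1/3; the alternative upstream
convention is available behind a flag because edge conventions of published
split counts are usually unstated and totals cannot disambiguate them.

The within-loop binomial test is exact and two-sided (point-probability
method). For 112 within-loop splits of 262 this gives p = 0.0016; the
one-sided enrichment tail is half that. The positional χ² against a uniform
distribution over loop positions pools adjacent positions into equal bins
until every bin has expected count ≥ 1 (the pooling is logged). Exon counts
per motif are the number of distinct exons overlapping the motif span,
binned {1, 2, ≥3}; contingency tests use Pearson χ² without continuity
correction.

## Interval randomization enrichment

Segments are re-placed independently and uniformly over all valid start
positions across the workspace (each placement fully inside one workspace
interval, lengths preserved, placements may overlap each other — the
simpler independent-placement null; an exclusion constraint is not
reproduced). The default statistic is total nucleotide overlap
(`NT_OVERLAP`); `SEGMENT_HITS` counts segments touching ≥ 1 annotation,
since published "peak enrichment" claims are frequently ambiguous between
the two. The empirical p is one-sided for enrichment with the add-one rule
p = (1 + #{sim ≥ obs})/(nSims + 1), so it is never 0 and never smaller
than 1/(nSims+1); depletion is available behind a flag. Annotations are
clipped to the workspace and merged before testing, making results
invariant to how annotations were split. BH correction flags q < 0.01.
The desk-scale default is 10,000 simulations per test; all computations
are vectorized over (simulations × segments), grouped by segment length.

## Synthetic data generator

The generator's defaults are the study conditions the statistics are
designed for: 296 canonical, 66 noncanonical and 15 S100 motifs, one motif
per gene, with 20–60 random flanking codons per side.

* **Loop residues** are drawn position-wise from editable distributions
  that honour the consensus and digitize the qualitative composition of
  canonical loops: Asp ≈ ¼ of loop residues, Glu ≈ ⅛, roughly half charged,
  Gly dominant at position 6, Ile/Leu/Val at position 8. Noncanonical loops
  are canonical draws with one deliberately violating substitution; S100
  pseudoloops are 14 residues led by Ser.
* **Reverse translation** uses per-position codon weights at loop codons 1
  (GAC 0.63 / GAT 0.37) and 12 (GAG 0.672 / GAA 0.328 within Glu), and
  family-uniform weights elsewhere in the loop; sequence outside the loop
  uses a coarse human-like codon usage table authored in code (editable;
  also the default CAI reference).
* **Exon splits**: the per-motif intron count is drawn from the canonical
  (79:178:39), noncanonical (15:47:4) and S100 (7:8:0) one/two/≥3-exon
  proportions. Positions come either from a uniform law over the 108 motif
  positions (within-loop fraction exactly ⅓ in expectation) or from a
  two-cluster law: with probability 0.427 a within-loop position sampled
  from 10 N-terminal and 4 C-terminal cluster positions (weights 0.7/0.3),
  otherwise a uniform outside-loop motif position. Donor dinucleotides are
  GT with 1% GC.
* **Hexamer sets**: ESE/ESS sets of 1182 and 1090 disjoint hexamers.
  GA-dinucleotide enrichment is produced by exponentially tilting sampling
  weights by the per-hexamer GA count (w^nGA for ESEs, w^−nGA for ESSs) and
  calibrating w by bisection against the realized GA frequency ratio; this
  reaches the programmed factor to within sampling noise of the finite sets
  (the achieved ratio is logged). Scores are Normal(1.5, 0.5) for ESEs,
  Normal(−1.5, 0.5) for ESSs, Normal(0, 0.3) for neutral hexamers, giving
  stochastic dominance of ESE over ESS scores.
* **Peaks**: placement probabilities over all enumerable valid starts are
  exponentially tilted in each start's annotation overlap, with the tilt
  solved by bisection so the expected per-peak overlap equals the
  programmed fold times the uniform null mean. This makes the programmed
  fold exact in expectation for the NT-overlap statistic the enrichment
  test measures (a naive inside/outside mixture undershoots when peak
  length is comparable to annotation length). With fold 1 placement is
  exactly uniform, so padding annotations cannot manufacture signal.

All generator outputs are bit-reproducible under a fixed seed, and the
generated CDS always translates to the generated protein.

What the generator does **not** emulate: real genome coordinates and
chromatin context (each gene is its own pseudo-chromosome), phylogenetic
structure, empirical eCLIP peak-length distributions (peak length is fixed
per run), intronic sequence, alternative splicing isoforms, and any
correlation between a loop's splicing scores and its split positions.
Passing tests therefore demonstrate that the statistics recover programmed
effects of realistic magnitude at study-scale sample sizes — not that real
exons behave this way.

## Pipeline determinism and problem sizes

All pipeline randomness flows from one seed through a fixed spawn order of
child generators, so a configuration reproduces byte-identical reports.
Default problem sizes — 377 genes, 500 control exons, 500-draw expected-CAI
nulls per loop, six peak samples × four paddings × 10,000 simulations —
complete in a couple of minutes on one CPU; the test suite and the
acceptance script use the same sizes or smaller ones chosen to keep each
check tight and fast while leaving sampling error well inside the asserted
tolerances.

## Known limitations

* The consensus scanner reports every matching window; curating overlapping
  matches into non-redundant motif records is left to the caller.
* The expected-CAI sampler matches GC in expectation, not per draw;
  sequences whose GC is outside the achievable synonymous range fall back
  to the boundary weight with a warning.
* The positional χ² pooling rule is coarse (equal-width bins); with very
  few splits the test degrades to a single bin and is reported as NaN.
* `SEGMENT_HITS` saturates for dense annotation sets; `NT_OVERLAP` is the
  better-behaved default.
* Empirical p-values are bounded below by 1/(nSims+1); q-values inherit
  that granularity.
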