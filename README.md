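# splicecode

Exonic sequences do not only encode protein: they carry auxiliary splicing
signals — exonic splicing enhancers (ESEs) and silencers (ESSs) — that decide
how reliably an exon is kept in the mature mRNA. `splicecode` quantifies this
splicing potential for exon segments that encode **protein Ca²⁺-binding
sites**, in particular the 12-residue chelation loop of EF-hand motifs, and
provides every statistical tool needed to ask whether codons for
Ca²⁺-coordinating residues are favoured by the splicing code.

The package is aimed at computational biologists studying the interplay of
protein and splicing codes: it takes protein/CDS FASTA, hexamer score tables,
gene models in CDS coordinates and BED peak sets, and returns positional and
region-level splicing-potential statistics, codon-usage bias measures,
exon-split enrichment tests and randomization-based peak-overlap enrichment.

## What it computes

* **EF-hand consensus scanning** — PROSITE-style matching of the 12-position
  loop consensus
  `D-(W)-[DNS]-(ILVFYW)-[DENSTG]-[DNQGHRK]-(GP)-[LIVMC]-[DENQSTAGC]-x-x-[DE]`
  (square brackets: permitted residues; parentheses: residues not allowed),
  with mapping of matches into CDS nucleotide coordinates and classification
  into canonical / noncanonical / S100 / non-EF-hand motifs.
* **Hexamer splicing-potential profiles** — the value at nt position *i* is
  the mean score of the hexamer *starting* at *i* over loop-aligned windows;
  region summaries pool sequence × position scores for the loop (EFL), the
  Ca²⁺-coordinating codons (CR, default loop codons {1,3,5,9,12}), the whole
  motif (EFM) and the motif minus the loop (ROEF), against a control-exon
  background trimmed of the first nt and last three nt of every exon.
* **Codon-level splicing statistics** — each hexamer contributes its four
  3-mer substrings; per codon *c* the log frequency ratio is

  `ln(ESEf/ESSf) = ln[(nE(c)+π)/(NE+64π)] − ln[(nS(c)+π)/(NS+64π)]`,

  with pseudocount π = 0.5 by default, plus the ESEc/ESSc count ratio and
  per-dinucleotide log-odds (e.g. GA enrichment in ESEs).
* **Codon usage bias** — RSCU, CAI (geometric mean of w(c) = RSCU/RSCUmax,
  Met/Trp/stop excluded), an expected-CAI null from GC- and amino-acid-matched
  synonymous re-encodings, exact two-sided binomial tests for two-codon usage
  contrasts, fragile/robust codon classification (single-nt mutability to a
  stop codon) and per-codon Pearson correlations.
* **Exon architecture** — intron insertion points mapped into loop-relative
  coordinates (position = first loop nt downstream of the intron), exon-count
  contingencies (χ²), within-loop split enrichment against the uniform
  36/108 expectation (exact binomial), split-position clusters and
  loop-to-splice-site distances.
* **Interval randomization enrichment** — a GAT-style test that re-places
  peak segments uniformly within a workspace, with nucleotide-overlap or
  segment-hit statistics, annotation padding sweeps, add-one empirical
  p-values and Benjamini–Hochberg correction (significance at q < 0.01).
* **Synthetic data generation** — study-shaped inputs for every stage:
  consensus-conforming loops with Asp-dominated residue frequencies, codon
  usage biased at loop codons 1 (GAC:GAU = 0.63:0.37) and 12, two-cluster
  exon splits, GA-enriched ESE hexamer sets and peak sets with a programmable
  fold enrichment.

## Worked example

Run the full pipeline on a freshly simulated study (296 canonical, 66
noncanonical and 15 S100 EF-hand genes — the class sizes the statistics are
designed for):

```bash
splicecode run --seed 3 --out report.json
```

Selected numbers from `report.json` (printed by the code, seed 3):

* `scan` — `n_canonical: 296`, `n_recovered_by_scan: 296`: the consensus
  scanner recovers every generated canonical loop at its recorded
  coordinate.
* `per_class_region_summaries.CANONICAL.regions` — mean hexamer scores
  `EFL 0.30 > CR 0.28 > EFM 0.17 > ROEF 0.11` against a control background
  of `0.09`: splicing potential concentrates on the chelation loop, as the
  generator programs through GA-rich coordinating codons.
* `codon_usage.loop_codon_bias` — loop codon 1 `GAC` fraction `0.59`
  (exact binomial p = 0.04 against the reference 0.535): one seed's sample
  of 296 loops scatters around the programmed 0.63 bias.
* `exon_structure.split_enrichment.both` — `pct_within = 39.8%` versus the
  uniform expectation `33.3%` (binomial p = 0.02); distinct split positions
  `10` in the N-terminal cluster and `4` around codon 12, exactly the
  programmed cluster geometry.
* `enrichment_runs` — the three peak samples simulated with fold 3 report
  `fold 2.4–3.2` with `significant_q01: true` at every padding (0/3/6/9
  nt); the three null samples report `fold 0.93–1.00` and are never called.

Individual stages are available as subcommands (`scan`, `profile`,
`codon-table`, `codon-usage`, `splits`, `enrich`, `simulate`) and as plain
library functions (`splicecode.scan_protein`, `splicecode.enrichment_test`,
…).

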