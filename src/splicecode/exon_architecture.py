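"""Intron insertion points mapped into motif/loop coordinates.

Split-position convention (stated prominently because published analyses of
this kind rarely state theirs): a split is indexed by the **first loop nt
downstream of the intron**.  An intron falling between CDS nt ``p`` and
``p+1`` relative to a loop starting at ``loopStart`` has

    loopRelativePosition = p - loopStart + 2

so an intron immediately before loop nt 1 is position 1 (within the loop),
and an intron immediately after the last loop nt is outside.  This keeps
exactly ``loopLengthNt`` within-loop positions, matching the 36/108 uniform
expectation for a 36-nt loop inside a 108-nt motif.  The alternative
convention (index by the last upstream loop nt) is available via
``convention="upstream"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .formats import GeneModel, MotifRecord

logger = logging.getLogger("splicecode")


@dataclass(frozen=True)
class SplitEvent:
    gene_id: str
    motif_id: str
    cds_insertion_point: int  # intron falls between this CDS nt and the next
    loop_relative_position: int
    within_loop: bool
    loop_length_nt: int


@dataclass
class SplitEnrichment:
    n_splits: int
    observed_within: int
    expected_within: float
    observed_outside: int
    expected_outside: float
    pct_within: float
    binomial_p: float
    chi2_positional: float
    chi2_p: float

    def as_dict(self) -> dict:
        return self.__dict__.copy()


def map_splits(models: Sequence[GeneModel], motifs: Sequence[MotifRecord],
               convention: str = "downstream") -> list[SplitEvent]:
    """One :class:`SplitEvent` per (intron insertion point x overlapping motif).

    An insertion point ``p`` overlaps a motif when it separates motif-context
    nucleotides under the downstream-indexing convention, i.e.
    ``motifStart-1 <= p <= motifEnd-1`` (exactly ``motifLengthNt`` positions).
    """
    if convention not in ("downstream", "upstream"):
        raise ValueError(f"unknown split convention {convention!r}")
    shift = 2 if convention == "downstream" else 1
    by_gene: dict[str, list[tuple[int, MotifRecord]]] = {}
    for i, motif in enumerate(motifs):
        by_gene.setdefault(motif.gene_id, []).append((i, motif))
    events: list[SplitEvent] = []
    for model in models:
        for i, motif in by_gene.get(model.gene_id, []):
            if motif.motif_end > model.cds_length:
                raise ValueError(
                    f"{model.gene_id}: motif ends at {motif.motif_end} beyond "
                    f"CDS length {model.cds_length}"
                )
            for p in model.insertion_points():
                if not (motif.cds_motif_start - 1 <= p <= motif.motif_end - 1):
                    continue
                rel = p - motif.loop_start + shift
                within = 1 <= rel <= motif.loop_length_nt
                events.append(
                    SplitEvent(
                        gene_id=model.gene_id,
                        motif_id=f"{motif.gene_id}:{i}",
                        cds_insertion_point=p,
                        loop_relative_position=rel,
                        within_loop=within,
                        loop_length_nt=motif.loop_length_nt,
                    )
                )
    logger.info("map_splits: %d events from %d genes x %d motifs",
                len(events), len(models), len(motifs))
    return events


def count_motif_exons(models: Sequence[GeneModel], motifs: Sequence[MotifRecord]
                      ) -> tuple[dict[str, int], dict[str, list[int]]]:
    """Exon count per motif plus a class x {1, 2, >=3} contingency.

    The exon count is the number of distinct exons whose CDS interval
    overlaps the motif span.
    """
    model_by_gene = {m.gene_id: m for m in models}
    per_motif: dict[str, int] = {}
    contingency: dict[str, list[int]] = {}
    for i, motif in enumerate(motifs):
        model = model_by_gene.get(motif.gene_id)
        if model is None:
            continue
        n = sum(
            1
            for start, end in model.exons
            if start <= motif.motif_end and end >= motif.cds_motif_start
        )
        per_motif[f"{motif.gene_id}:{i}"] = n
        row = contingency.setdefault(motif.motif_class, [0, 0, 0])
        row[min(n, 3) - 1] += 1
    return per_motif, contingency


def chi2_contingency(table: Sequence[Sequence[float]]) -> tuple[float, int, float]:
    """Pearson chi-square for an r x k contingency table, no continuity
    correction.  Zero row/column marginals are an error."""
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero marginal")
    res = stats.chi2_contingency(arr, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def split_enrichment(events: Sequence[SplitEvent], loop_len: int = 36,
                     motif_len: int = 108) -> SplitEnrichment:
    """Within-loop enrichment of exon splits against the uniform expectation.

    Under uniform intron placement across the motif the expected within-loop
    count is ``nSplits * loop_len / motif_len``.  The binomial test is exact
    and two-sided (point-probability method).  The positional chi-square
    compares observed within-loop counts per nt position against uniform,
    pooling adjacent positions until every bin has expected count >= 1.
    """
    n = len(events)
    if n < 1:
        raise ValueError("need at least one split event")
    p0 = loop_len / motif_len
    observed_within = sum(1 for e in events if e.within_loop)
    expected_within = n * p0
    binom_p = float(stats.binomtest(observed_within, n, p0,
                                    alternative="two-sided").pvalue)

    within_positions = [e.loop_relative_position for e in events if e.within_loop]
    if within_positions:
        n_bins = max(1, min(loop_len, int(len(within_positions))))
        edges = np.linspace(0.5, loop_len + 0.5, n_bins + 1)
        counts, _ = np.histogram(within_positions, bins=edges)
        if n_bins < loop_len:
            logger.info("split_enrichment: pooled %d loop positions into %d bins",
                        loop_len, n_bins)
        if n_bins > 1:
            chi2_res = stats.chisquare(counts)
            chi2_stat, chi2_p = float(chi2_res.statistic), float(chi2_res.pvalue)
        else:
            chi2_stat, chi2_p = float("nan"), float("nan")
    else:
        chi2_stat, chi2_p = float("nan"), float("nan")

    return SplitEnrichment(
        n_splits=n,
        observed_within=observed_within,
        expected_within=expected_within,
        observed_outside=n - observed_within,
        expected_outside=n - expected_within,
        pct_within=100.0 * observed_within / n,
        binomial_p=binom_p,
        chi2_positional=chi2_stat,
        chi2_p=chi2_p,
    )


def split_position_clusters(events: Sequence[SplitEvent],
                            n_terminal_nts: tuple[int, int] = (1, 18),
                            c_terminal_nts: tuple[int, int] = (31, 36),
                            ) -> tuple[int, int]:
    """Distinct within-loop split positions in the N-terminal half (default
    loop codons 1-6) and the C-terminal region (default codons 11-12)."""
    n_lo, n_hi = n_terminal_nts
    c_lo, c_hi = c_terminal_nts
    n_set = {e.loop_relative_position for e in events
             if e.within_loop and n_lo <= e.loop_relative_position <= n_hi}
    c_set = {e.loop_relative_position for e in events
             if e.within_loop and c_lo <= e.loop_relative_position <= c_hi}
    return len(n_set), len(c_set)


def loop_to_splice_site_distances(models: Sequence[GeneModel],
                                  motifs: Sequence[MotifRecord],
                                  max_exon_len: int = 400,
                                  ) -> list[tuple[str, int, int]]:
    """Per-loop distances (dist3ss, dist5ss) for loops inside a single exon.

    ``dist3ss = loopStart - exonStart``; ``dist5ss = exonEnd - loopEnd``.
    Loops in exons of length >= ``max_exon_len`` are filtered out; loops
    spanning an exon boundary are excluded with a warning.
    """
    model_by_gene = {m.gene_id: m for m in models}
    out: list[tuple[str, int, int]] = []
    spanning = 0
    for i, motif in enumerate(motifs):
        model = model_by_gene.get(motif.gene_id)
        if model is None:
            continue
        host = None
        for start, end in model.exons:
            if start <= motif.loop_start and motif.loop_end <= end:
                host = (start, end)
                break
        if host is None:
            spanning += 1
            continue
        start, end = host
        if end - start + 1 >= max_exon_len:
            continue
        out.append((f"{motif.gene_id}:{i}", motif.loop_start - start,
                    end - motif.loop_end))
    if spanning:
        logger.warning("loop_to_splice_site_distances: %d loops span exon "
                       "boundaries and were excluded", spanning)
    return out


def donor_class(models: Sequence[GeneModel]) -> dict[str, list[str]]:
    """Classify each intron's recorded donor dinucleotide as GT/GC/OTHER."""
    out: dict[str, list[str]] = {}
    for model in models:
        n_introns = len(model.exons) - 1
        donors = model.donor_dinucs
        classes: list[str] = []
        for k in range(n_introns):
            if k < len(donors) and donors[k]:
                d = donors[k].upper().replace("U", "T")
                classes.append(d if d in ("GT", "GC") else "OTHER")
            else:
                logger.warning("donor_class: %s intron %d lacks donor annotation",
                               model.gene_id, k + 1)
                classes.append("OTHER")
        out[model.gene_id] = classes
    return out
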