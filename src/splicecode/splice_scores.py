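"""Hexamer splicing-potential statistics.

This is the scoring core of the package: positional hexamer-score profiles
across loop-aligned CDS windows, region means (loop, coordinating residues,
whole motif, rest-of-motif), codon-level frequency and count ratios between
the ESE and ESS hexamer classes, the trimmed control-exon background, and
dinucleotide log-odds between the two hexamer sets.

Profile indexing convention: the value at nt position ``i`` is the score of
the hexamer *starting* at ``i`` (not any hexamer covering ``i``), with core
position 1 being the loop's first nt.  Flanking positions are negative or
beyond the core length.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .formats import HexamerTable, normalize_nt

logger = logging.getLogger("splicecode")

ALL_CODONS = ["".join(p) for p in itertools.product("ACGT", repeat=3)]
ALL_DINUCS = ["".join(p) for p in itertools.product("ACGT", repeat=2)]

REGION_NAMES = ("EFL", "CR", "EFM", "ROEF", "CONTROL")


@dataclass(frozen=True)
class LoopWindow:
    """A CDS window aligned on a loop: ``seq[core_offset:core_offset+core_len]``
    is the loop core; the rest is genuine flanking CDS context."""

    seq: str
    core_offset: int
    core_len: int

    def __post_init__(self) -> None:
        if not (0 <= self.core_offset and
                self.core_offset + self.core_len <= len(self.seq)):
            raise ValueError("core does not fit inside the window sequence")


@dataclass
class PositionalProfile:
    """Mean hexamer score per start position, core position 1 = loop nt 1."""

    positions: list[int]
    mean_score: np.ndarray
    n_seq: np.ndarray
    ess_start_count: np.ndarray

    def as_dict(self) -> dict:
        return {
            "positions": list(self.positions),
            "mean_score": [float(x) for x in self.mean_score],
            "n_seq": [int(x) for x in self.n_seq],
            "ess_start_count": [int(x) for x in self.ess_start_count],
        }


@dataclass
class RegionScoreSummary:
    region_name: str
    mean_score: float
    n_positions: int
    sem: float
    values: np.ndarray | None = field(default=None, repr=False)

    def as_dict(self) -> dict:
        return {
            "region_name": self.region_name,
            "mean_score": self.mean_score,
            "n_positions": self.n_positions,
            "sem": self.sem,
        }


@dataclass
class CodonSplicingTable:
    """Per-codon token counts and frequencies in the ESE vs ESS hexamer sets.

    ``ln_ratio`` is ln(ESEf/ESSf) with a symmetric pseudocount; ``count_ratio``
    is the smoothed ESEc/ESSc count ratio.
    """

    ese_count: dict[str, int]
    ess_count: dict[str, int]
    ese_freq: dict[str, float]
    ess_freq: dict[str, float]
    ln_ratio: dict[str, float]
    count_ratio: dict[str, float]
    pseudocount: float

    def as_rows(self) -> list[dict]:
        return [
            {
                "codon": c,
                "eseCount": self.ese_count[c],
                "essCount": self.ess_count[c],
                "eseFreq": self.ese_freq[c],
                "essFreq": self.ess_freq[c],
                "lnRatio": self.ln_ratio[c],
                "countRatio": self.count_ratio[c],
            }
            for c in ALL_CODONS
        ]


# ---------------------------------------------------------------------------
# Positional profiles and region means
# ---------------------------------------------------------------------------


def _window_start_scores(window: LoopWindow, table: HexamerTable):
    """Yield (core_position, score, is_ess) for every hexamer start."""
    seq = normalize_nt(window.seq)
    for j in range(len(seq) - 5):
        hexamer = seq[j : j + 6]
        try:
            entry = table.entries[hexamer]
        except KeyError:
            raise KeyError(
                f"hexamer {hexamer!r} absent from score table"
            ) from None
        yield j - window.core_offset + 1, entry.score, entry.label == "ESS"


def positional_profile(windows: Sequence[LoopWindow],
                       table: HexamerTable) -> PositionalProfile:
    """Mean hexamer-start score per position over loop-aligned windows.

    Windows may provide unequal flanking context; a window contributes only
    to positions it covers, and ``n_seq`` records per-position coverage.
    """
    if not windows:
        raise ValueError("no windows supplied")
    core_lens = {w.core_len for w in windows}
    if len(core_lens) != 1:
        raise ValueError(f"core lengths differ: {sorted(core_lens)}")
    values: dict[int, list[float]] = {}
    ess: dict[int, int] = {}
    for window in windows:
        for pos, score, is_ess in _window_start_scores(window, table):
            values.setdefault(pos, []).append(score)
            ess[pos] = ess.get(pos, 0) + int(is_ess)
    positions = sorted(values)
    logger.info(
        "positional_profile: %d windows, core %d nt, positions %d..%d",
        len(windows), core_lens.pop(), positions[0], positions[-1],
    )
    # fsum: exact accumulation, so the profile is invariant under any
    # permutation of the input sequence list
    return PositionalProfile(
        positions=positions,
        mean_score=np.array([math.fsum(values[p]) / len(values[p])
                             for p in positions]),
        n_seq=np.array([len(values[p]) for p in positions]),
        ess_start_count=np.array([ess[p] for p in positions]),
    )


def region_mean(windows: Sequence[LoopWindow], regions: Mapping[str, Iterable[int]],
                table: HexamerTable) -> list[RegionScoreSummary]:
    """Mean hexamer-start score pooled over (sequence x member position).

    Each window contributes one hexamer score per region position it covers;
    ``n_positions`` counts the pooled pairs.
    """
    region_sets = {name: frozenset(pos) for name, pos in regions.items()}
    for name, pos_set in region_sets.items():
        if not pos_set:
            raise ValueError(f"region {name!r} is empty")
    values: dict[str, list[float]] = {name: [] for name in region_sets}
    for window in windows:
        for pos, score, _ in _window_start_scores(window, table):
            for name, pos_set in region_sets.items():
                if pos in pos_set:
                    values[name].append(score)
    out: list[RegionScoreSummary] = []
    for name, vals in values.items():
        if not vals:
            raise ValueError(f"region {name!r} covered by no window position")
        arr = np.asarray(vals)
        sem = float(arr.std(ddof=1) / math.sqrt(len(arr))) if len(arr) > 1 else 0.0
        out.append(RegionScoreSummary(name, float(arr.mean()), len(arr), sem, arr))
    return out


def control_exon_background(exons: Sequence[str],
                            table: HexamerTable) -> RegionScoreSummary:
    """Pooled hexamer-score background over control exons.

    The first nt and the last three nts of every exon are trimmed before
    scoring, because those positions shape the 3'ss and 5'ss consensus.
    Exons shorter than 10 nt (no hexamer survives trimming) are skipped.
    """
    values: list[float] = []
    skipped = 0
    for exon in exons:
        seq = normalize_nt(exon)
        if len(seq) < 10:
            skipped += 1
            continue
        trimmed = seq[1:-3]
        for j in range(len(trimmed) - 5):
            values.append(table.score(trimmed[j : j + 6]))
    if skipped:
        logger.warning("control_exon_background: skipped %d exons shorter than 10 nt",
                       skipped)
    if not values:
        raise ValueError("no control exon long enough to score")
    arr = np.asarray(values)
    sem = float(arr.std(ddof=1) / math.sqrt(len(arr))) if len(arr) > 1 else 0.0
    logger.info("control_exon_background: %d exons, %d hexamer positions",
                len(exons) - skipped, len(arr))
    return RegionScoreSummary("CONTROL", float(arr.mean()), len(arr), sem, arr)


# ---------------------------------------------------------------------------
# Codon-level statistics
# ---------------------------------------------------------------------------


def codon_tokens_from_hexamers(hexamers: Iterable[str]) -> dict[str, int]:
    """Count codon tokens: each hexamer contributes its four length-3
    substrings (offsets 0..3), so total tokens = 4 x number of hexamers."""
    counts: dict[str, int] = {}
    n = 0
    for hexamer in hexamers:
        h = normalize_nt(hexamer)
        if len(h) != 6 or not set(h) <= set("ACGT"):
            raise ValueError(f"not a hexamer: {hexamer!r}")
        n += 1
        for off in range(4):
            codon = h[off : off + 3]
            counts[codon] = counts.get(codon, 0) + 1
    logger.info("codon_tokens_from_hexamers: %d hexamers -> %d tokens", n, 4 * n)
    return counts


def build_codon_splicing_table(ese_hexamers: Sequence[str],
                               ess_hexamers: Sequence[str],
                               pseudocount: float = 0.5) -> CodonSplicingTable:
    """Per-codon ESE-vs-ESS frequency and count ratios.

    With pseudocount pi the log frequency ratio is

        ln[ (nE(c)+pi)/(NE+64*pi) / (nS(c)+pi)/(NS+64*pi) ]

    and the count ratio is (nE(c)+pi)/(nS(c)+pi).  pi=0 is permitted when no
    zero counts occur.
    """
    if not ese_hexamers or not ess_hexamers:
        raise ValueError("both hexamer lists must be non-empty")
    pi = float(pseudocount)
    ese_counts = codon_tokens_from_hexamers(ese_hexamers)
    ess_counts = codon_tokens_from_hexamers(ess_hexamers)
    n_ese = sum(ese_counts.values())
    n_ess = sum(ess_counts.values())
    ese_count = {c: ese_counts.get(c, 0) for c in ALL_CODONS}
    ess_count = {c: ess_counts.get(c, 0) for c in ALL_CODONS}
    ese_freq = {c: ese_count[c] / n_ese for c in ALL_CODONS}
    ess_freq = {c: ess_count[c] / n_ess for c in ALL_CODONS}
    ln_ratio: dict[str, float] = {}
    count_ratio: dict[str, float] = {}
    for c in ALL_CODONS:
        fe = (ese_count[c] + pi) / (n_ese + 64 * pi)
        fs = (ess_count[c] + pi) / (n_ess + 64 * pi)
        # log difference (not log of the quotient) so that swapping the two
        # hexamer sets negates every ratio exactly; with pi=0, zero counts
        # degrade to +-inf (one side empty) or NaN (both empty)
        if fe > 0 and fs > 0:
            ln_ratio[c] = math.log(fe) - math.log(fs)
        elif fe == 0 and fs == 0:
            ln_ratio[c] = float("nan")
        else:
            ln_ratio[c] = float("-inf") if fe == 0 else float("inf")
        num, den = ese_count[c] + pi, ess_count[c] + pi
        if den > 0:
            count_ratio[c] = num / den
        else:
            count_ratio[c] = float("nan") if num == 0 else float("inf")
    return CodonSplicingTable(ese_count, ess_count, ese_freq, ess_freq,
                              ln_ratio, count_ratio, pi)


def dinucleotide_enrichment(ese_hexamers: Sequence[str],
                            ess_hexamers: Sequence[str],
                            pseudocount: float = 0.5) -> dict[str, float]:
    """Per-dinucleotide log-odds ln(fESE(d)/fESS(d)).

    Each hexamer contributes its five overlapping dinucleotides; counts are
    smoothed with the pseudocount before forming frequencies.
    """
    if not ese_hexamers or not ess_hexamers:
        raise ValueError("both hexamer lists must be non-empty")

    def dinuc_counts(hexamers: Sequence[str]) -> tuple[dict[str, int], int]:
        counts = {d: 0 for d in ALL_DINUCS}
        total = 0
        for hexamer in hexamers:
            h = normalize_nt(hexamer)
            if len(h) != 6:
                raise ValueError(f"not a hexamer: {hexamer!r}")
            for j in range(5):
                counts[h[j : j + 2]] += 1
                total += 1
        return counts, total

    pi = float(pseudocount)
    ce, ne = dinuc_counts(ese_hexamers)
    cs, ns = dinuc_counts(ess_hexamers)
    return {
        d: math.log((ce[d] + pi) / (ne + 16 * pi))
        - math.log((cs[d] + pi) / (ns + 16 * pi))
        for d in ALL_DINUCS
    }


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------


def compare_groups(groups: Mapping[str, Sequence[float]],
                   test: str = "t") -> tuple[float, float]:
    """Two-sided comparison of >= 2 groups.

    ``test``: ``t`` (pooled-variance two-sample), ``mannwhitney``
    (Wilcoxon-Mann-Whitney) or ``anova`` (one-way).  Degenerate inputs
    (zero variance everywhere) give ``(nan, nan)`` with a warning.
    """
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    for name, arr in zip(groups, arrays):
        if len(arr) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 values")
    if all(arr.std() == 0 for arr in arrays) and test != "mannwhitney":
        pooled = np.concatenate(arrays)
        if pooled.std() == 0:
            logger.warning("compare_groups: degenerate (zero variance), returning NA")
            return float("nan"), float("nan")
    if test == "t":
        if len(arrays) != 2:
            raise ValueError("t-test requires exactly two groups")
        res = stats.ttest_ind(arrays[0], arrays[1], equal_var=True)
    elif test == "mannwhitney":
        if len(arrays) != 2:
            raise ValueError("Mann-Whitney requires exactly two groups")
        res = stats.mannwhitneyu(arrays[0], arrays[1], alternative="two-sided")
    elif test == "anova":
        res = stats.f_oneway(*arrays)
    else:
        raise ValueError(f"unknown test {test!r}")
    return float(res.statistic), float(res.pvalue)
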