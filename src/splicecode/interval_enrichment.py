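"""Randomization test for overlap enrichment of peak segments in annotations.

Given peak segments (e.g. CLIP peaks), annotation intervals (e.g. exonic
segments coding for Ca2+-binding loops) and a workspace (the universe in
which peaks may occur, e.g. transcribed regions), the test re-places every
segment independently and uniformly over all valid start positions inside
the workspace, preserving segment lengths, and compares the observed overlap
statistic to the simulated null distribution:

    p = (1 + #{sim >= observed}) / (nSims + 1)

Statistics: ``NT_OVERLAP`` (total overlapping nucleotides, the default) or
``SEGMENT_HITS`` (number of segments intersecting at least one annotation).
Placed segments may overlap each other (independent placement null).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .formats import EnrichmentResult, GenomicIntervalSet, Interval

logger = logging.getLogger("splicecode")

STATISTICS = ("NT_OVERLAP", "SEGMENT_HITS")


@dataclass
class Workspace:
    """Merged universe of intervals within which segments may be placed."""

    intervals: GenomicIntervalSet

    def __post_init__(self) -> None:
        self.intervals = self.intervals.merged()
        if len(self.intervals) == 0:
            raise ValueError("workspace is empty")

    def max_interval_length(self) -> int:
        return max(iv.end - iv.start for iv in self.intervals)


class _GlobalAxis:
    """Maps (chrom, pos) pairs onto one linear axis so every computation is a
    plain 1-D array operation."""

    def __init__(self, *interval_sets: GenomicIntervalSet) -> None:
        max_end: dict[str, int] = {}
        for ivs in interval_sets:
            for iv in ivs:
                max_end[iv.chrom] = max(max_end.get(iv.chrom, 0), iv.end)
        self.offsets: dict[str, int] = {}
        run = 0
        for chrom in sorted(max_end):
            self.offsets[chrom] = run
            run += max_end[chrom] + 1
        self.length = run

    def project(self, ivs: GenomicIntervalSet) -> np.ndarray:
        """(n, 2) array of [start, end) on the global axis, sorted by start."""
        arr = np.array(
            [(self.offsets[iv.chrom] + iv.start, self.offsets[iv.chrom] + iv.end)
             for iv in ivs],
            dtype=np.int64,
        ).reshape(-1, 2)
        return arr[np.argsort(arr[:, 0], kind="stable")]


class _Coverage:
    """Cumulative-coverage function of a merged interval union on the axis:
    C(x) = number of covered positions below x."""

    def __init__(self, merged: np.ndarray) -> None:
        self.starts = merged[:, 0]
        self.ends = merged[:, 1]
        lengths = self.ends - self.starts
        self.cum = np.concatenate([[0], np.cumsum(lengths)])

    def __call__(self, x: np.ndarray) -> np.ndarray:
        j = np.searchsorted(self.starts, x, side="right") - 1
        jc = np.clip(j, 0, len(self.starts) - 1)
        inside = np.clip(x - self.starts[jc], 0, self.ends[jc] - self.starts[jc])
        out = self.cum[jc] + inside
        return np.where(j < 0, 0, out)

    def overlaps(self, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        return self(ends) - self(starts)


def _merge_rows(arr: np.ndarray) -> np.ndarray:
    if len(arr) == 0:
        return arr.reshape(0, 2)
    out = [list(arr[0])]
    for s, e in arr[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.array(out, dtype=np.int64)


def observed_overlap(segments: GenomicIntervalSet,
                     annotations: GenomicIntervalSet,
                     statistic: str = "NT_OVERLAP") -> float:
    """Overlap statistic between two interval sets in genome coordinates."""
    if statistic not in STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}")
    if len(segments) == 0 or len(annotations) == 0:
        return 0.0
    axis = _GlobalAxis(segments, annotations)
    cov = _Coverage(_merge_rows(axis.project(annotations)))
    seg = axis.project(segments)
    ov = cov.overlaps(seg[:, 0], seg[:, 1])
    if statistic == "NT_OVERLAP":
        return float(ov.sum())
    return float((ov > 0).sum())


def _placement_tables(ws_rows: np.ndarray, lengths: np.ndarray):
    """For each unique segment length, the cumulative valid-start counts per
    workspace interval.  Raises if a length fits nowhere."""
    ws_len = ws_rows[:, 1] - ws_rows[:, 0]
    tables = {}
    for L in np.unique(lengths):
        valid = np.maximum(0, ws_len - L + 1)
        total = int(valid.sum())
        if total == 0:
            raise ValueError(f"segment of length {int(L)} longer than every "
                             f"workspace interval")
        tables[int(L)] = (np.concatenate([[0], np.cumsum(valid)]), total)
    return tables


def _place(rng: np.random.Generator, ws_rows: np.ndarray, cum: np.ndarray,
           total: int, size: int) -> np.ndarray:
    u = rng.integers(0, total, size=size)
    j = np.searchsorted(cum, u, side="right") - 1
    return ws_rows[j, 0] + (u - cum[j])


def randomize_segments(segments: GenomicIntervalSet, workspace: Workspace,
                       seed: int | np.random.Generator) -> GenomicIntervalSet:
    """Place every segment uniformly over all valid start positions across
    workspace intervals (each placement fully inside one interval)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    axis = _GlobalAxis(workspace.intervals, segments)
    ws_rows = axis.project(workspace.intervals)
    lengths = np.array([iv.end - iv.start for iv in segments], dtype=np.int64)
    tables = _placement_tables(ws_rows, lengths)
    rev_offsets = sorted(((off, chrom) for chrom, off in axis.offsets.items()))
    offs = np.array([o for o, _ in rev_offsets], dtype=np.int64)
    chroms = [c for _, c in rev_offsets]
    placed: list[Interval] = []
    for iv, L in zip(segments, lengths):
        cum, total = tables[int(L)]
        start = int(_place(rng, ws_rows, cum, total, 1)[0])
        k = int(np.searchsorted(offs, start, side="right") - 1)
        local = start - int(offs[k])
        placed.append(Interval(chroms[k], local, local + int(L), iv.name, iv.score))
    return GenomicIntervalSet(placed, ncols=segments.ncols)


def enrichment_test(segments: GenomicIntervalSet,
                    annotations: GenomicIntervalSet,
                    workspace: Workspace,
                    n_sims: int = 10_000,
                    seed: int | np.random.Generator = 0,
                    statistic: str = "NT_OVERLAP",
                    sample_id: str = "sample",
                    alternative: str = "enrichment",
                    _chunk: int = 500) -> EnrichmentResult:
    """Randomization enrichment test of ``segments`` within ``annotations``.

    Annotations are clipped to the workspace for both the observed and the
    simulated statistic.  The empirical p is one-sided for enrichment by
    default (``alternative="depletion"`` flips the tail) and can never be 0
    thanks to the add-one rule.
    """
    if statistic not in STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}")
    if n_sims < 100:
        raise ValueError("n_sims must be >= 100")
    if alternative not in ("enrichment", "depletion"):
        raise ValueError(f"unknown alternative {alternative!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if len(segments) == 0 or len(annotations) == 0:
        logger.warning("enrichment_test[%s]: empty segments or annotations",
                       sample_id)
        return EnrichmentResult(sample_id, 0.0, 0.0, 0.0, float("nan"), 1.0)

    axis = _GlobalAxis(workspace.intervals, segments, annotations)
    ws_rows = axis.project(workspace.intervals)
    ws_cov = _Coverage(ws_rows)
    ann_rows = _merge_rows(axis.project(annotations))
    # clip annotations to the workspace
    clipped: list[list[int]] = []
    for s, e in ann_rows:
        j0 = np.searchsorted(ws_rows[:, 1], s, side="right")
        for ws_s, ws_e in ws_rows[j0:]:
            if ws_s >= e:
                break
            cs, ce = max(s, ws_s), min(e, ws_e)
            if cs < ce:
                clipped.append([cs, ce])
    if not clipped:
        logger.warning("enrichment_test[%s]: annotations do not intersect "
                       "workspace", sample_id)
        return EnrichmentResult(sample_id, 0.0, 0.0, 0.0, float("nan"), 1.0)
    cov = _Coverage(_merge_rows(np.array(clipped, dtype=np.int64)))

    seg_rows = axis.project(segments)
    lengths = seg_rows[:, 1] - seg_rows[:, 0]
    obs_per_seg = cov.overlaps(seg_rows[:, 0], seg_rows[:, 1])
    observed = float(obs_per_seg.sum() if statistic == "NT_OVERLAP"
                     else (obs_per_seg > 0).sum())

    tables = _placement_tables(ws_rows, lengths)
    null = np.zeros(n_sims)
    done = 0
    while done < n_sims:
        block = min(_chunk, n_sims - done)
        total_stat = np.zeros(block)
        for L in np.unique(lengths):
            idx = lengths == L
            n_seg = int(idx.sum())
            cum, total = tables[int(L)]
            starts = _place(rng, ws_rows, cum, total, block * n_seg)
            ov = cov.overlaps(starts, starts + int(L)).reshape(block, n_seg)
            if statistic == "NT_OVERLAP":
                total_stat += ov.sum(axis=1)
            else:
                total_stat += (ov > 0).sum(axis=1)
        null[done : done + block] = total_stat
        done += block

    if alternative == "enrichment":
        extreme = int((null >= observed - 1e-9).sum())
    else:
        extreme = int((null <= observed + 1e-9).sum())
    p = (1 + extreme) / (n_sims + 1)
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1))
    if null_mean == 0:
        fold = (observed + 1.0) / (null_mean + 1.0)
        logger.warning("enrichment_test[%s]: null mean 0, fold computed with "
                       "+1 smoothing", sample_id)
    else:
        fold = observed / null_mean
    logger.info("enrichment_test[%s]: %s obs=%.0f null=%.1f+-%.1f fold=%.3f "
                "p=%.2g (nSims=%d)", sample_id, statistic, observed, null_mean,
                null_sd, fold, p, n_sims)
    return EnrichmentResult(sample_id, observed, null_mean, null_sd, fold, p)


def pad_annotations(annotations: GenomicIntervalSet, pad: int,
                    workspace: Workspace | None = None) -> GenomicIntervalSet:
    """Extend every interval by ``pad`` nt on both sides, clip to the
    workspace when given, and merge the result."""
    if pad < 0:
        raise ValueError("pad must be >= 0")
    padded = GenomicIntervalSet(
        [Interval(iv.chrom, max(0, iv.start - pad), iv.end + pad, iv.name, iv.score)
         for iv in annotations],
        ncols=annotations.ncols,
    )
    if workspace is None:
        return padded.merged()
    out: list[Interval] = []
    ws_by_chrom: dict[str, list[Interval]] = {}
    for iv in workspace.intervals:
        ws_by_chrom.setdefault(iv.chrom, []).append(iv)
    for iv in padded.merged():
        for ws in ws_by_chrom.get(iv.chrom, []):
            s, e = max(iv.start, ws.start), min(iv.end, ws.end)
            if s < e:
                out.append(Interval(iv.chrom, s, e))
    return GenomicIntervalSet(out, ncols=3).merged()


def bh_correct(p_values: Sequence[float], alpha: float = 0.01
               ) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up q-values and a significance flag at
    ``q < alpha`` (default 0.01)."""
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        return np.array([]), np.array([], dtype=bool)
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q, q < alpha
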