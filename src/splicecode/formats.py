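"""Readers, writers and shared domain types.

Conventions used throughout the package:

* CDS coordinates are **1-based inclusive**, matching the convention of
  numbering a coding sequence from the first position of the first codon.
* BED input/output is **0-based half-open**; the converters in this module
  are the only place the two systems meet.
* RNA alphabets are normalized to DNA (``U`` -> ``T``) at read time; all
  internal sequence logic is DNA-alphabet.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml
from Bio import SeqIO

logger = logging.getLogger("splicecode")

NT_ALPHABET = set("ACGT")
HEXAMER_LABELS = ("ESE", "ESS", "NEUTRAL")
MOTIF_CLASSES = ("CANONICAL", "NONCANONICAL", "S100", "NONEF")

# Coordinating loop codons: side-chain ligands at 1, 3, 5 and 12, water-bridged
# ligand at 9.  Codon 7 (backbone carbonyl) is excluded by default and can be
# added through configuration.
DEFAULT_COORDINATING_CODONS = frozenset({1, 3, 5, 9, 12})


class FormatError(ValueError):
    """Raised when an external file violates its expected schema."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HexamerEntry:
    score: float
    label: str


@dataclass
class HexamerTable:
    """Per-hexamer splicing score and ESE/ESS/NEUTRAL class label.

    Higher scores predict stronger exon inclusion.  Keys are length-6 DNA
    strings; RNA input is normalized on construction.
    """

    entries: dict[str, HexamerEntry] = field(default_factory=dict)

    def __post_init__(self) -> None:
        normalized: dict[str, HexamerEntry] = {}
        for hexamer, entry in self.entries.items():
            h = normalize_nt(hexamer)
            if len(h) != 6 or not set(h) <= NT_ALPHABET:
                raise FormatError(f"invalid hexamer {hexamer!r}")
            if entry.label not in HEXAMER_LABELS:
                raise FormatError(f"invalid hexamer label {entry.label!r}")
            if h in normalized:
                raise FormatError(f"duplicate hexamer {h!r}")
            normalized[h] = entry
        self.entries = normalized

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, hexamer: str) -> bool:
        return normalize_nt(hexamer) in self.entries

    def score(self, hexamer: str) -> float:
        h = normalize_nt(hexamer)
        if h not in self.entries:
            raise KeyError(f"hexamer {h!r} not in table")
        return self.entries[h].score

    def label(self, hexamer: str) -> str:
        h = normalize_nt(hexamer)
        if h not in self.entries:
            raise KeyError(f"hexamer {h!r} not in table")
        return self.entries[h].label

    def members(self, label: str) -> list[str]:
        return sorted(h for h, e in self.entries.items() if e.label == label)

    def class_counts(self) -> dict[str, int]:
        counts = {label: 0 for label in HEXAMER_LABELS}
        for entry in self.entries.values():
            counts[entry.label] += 1
        return counts


@dataclass
class MotifRecord:
    """One Ca2+-binding motif in CDS coordinates (1-based inclusive)."""

    gene_id: str
    motif_class: str
    cds_motif_start: int
    motif_length_nt: int
    loop_start: int
    loop_length_nt: int
    coordinating_codons: frozenset[int] = DEFAULT_COORDINATING_CODONS
    coordinating_cds_positions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.motif_class not in MOTIF_CLASSES:
            raise ValueError(f"invalid motif class {self.motif_class!r}")
        if self.loop_start < self.cds_motif_start:
            raise ValueError(
                f"{self.gene_id}: loop start {self.loop_start} precedes motif "
                f"start {self.cds_motif_start}"
            )
        if self.loop_end > self.motif_end:
            raise ValueError(f"{self.gene_id}: loop extends past motif end")

    @property
    def loop_end(self) -> int:
        return self.loop_start + self.loop_length_nt - 1

    @property
    def motif_end(self) -> int:
        return self.cds_motif_start + self.motif_length_nt - 1

    @property
    def loop_frame(self) -> int:
        """Frame (0/1/2) of the loop's first nt within the codon grid."""
        return (self.loop_start - 1) % 3


@dataclass
class GeneModel:
    """Ordered exons of one gene in CDS coordinates (1-based inclusive)."""

    gene_id: str
    exons: list[tuple[int, int]]
    donor_dinucs: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.gene_id}: gene model without exons")
        prev_end = None
        for start, end in self.exons:
            if start > end:
                raise ValueError(f"{self.gene_id}: exon with start > end")
            if prev_end is not None and start != prev_end + 1:
                raise FormatError(
                    f"{self.gene_id}: exons are not contiguous in CDS space "
                    f"(exon starting at {start} after exon ending at {prev_end})"
                )
            prev_end = end
        if self.donor_dinucs and len(self.donor_dinucs) != len(self.exons) - 1:
            raise ValueError(
                f"{self.gene_id}: expected {len(self.exons) - 1} donor "
                f"dinucleotides, got {len(self.donor_dinucs)}"
            )

    @property
    def cds_length(self) -> int:
        return self.exons[-1][1]

    def insertion_points(self) -> list[int]:
        """CDS positions p such that an intron falls between nt p and p+1."""
        return [end for _, end in self.exons[:-1]]


@dataclass(frozen=True)
class Interval:
    chrom: str
    start: int  # 0-based
    end: int  # half-open
    name: str = "."
    score: float = 0.0


@dataclass
class GenomicIntervalSet:
    """A list of BED-style intervals (0-based half-open)."""

    intervals: list[Interval] = field(default_factory=list)
    ncols: int = 5

    def __post_init__(self) -> None:
        for iv in self.intervals:
            if iv.start < 0:
                raise FormatError(f"negative interval start: {iv}")
            if iv.start >= iv.end:
                raise FormatError(f"interval start >= end: {iv}")

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def sorted(self) -> "GenomicIntervalSet":
        return GenomicIntervalSet(
            sorted(self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)),
            ncols=self.ncols,
        )

    def merged(self) -> "GenomicIntervalSet":
        """Union of intervals, merging overlapping or bookended runs."""
        out: list[Interval] = []
        for iv in self.sorted():
            if out and iv.chrom == out[-1].chrom and iv.start <= out[-1].end:
                if iv.end > out[-1].end:
                    out[-1] = Interval(iv.chrom, out[-1].start, iv.end)
            else:
                out.append(Interval(iv.chrom, iv.start, iv.end))
        return GenomicIntervalSet(out, ncols=3)

    def total_length(self) -> int:
        return sum(iv.end - iv.start for iv in self.merged())


@dataclass
class EnrichmentResult:
    """Observed vs simulated-null overlap for one sample x annotation test."""

    sample_id: str
    observed: float
    null_mean: float
    null_sd: float
    fold: float
    p_empirical: float
    q_bh: float = float("nan")

    def as_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "observed": self.observed,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "fold": self.fold,
            "p_empirical": self.p_empirical,
            "q_bh": self.q_bh,
        }


# ---------------------------------------------------------------------------
# Sequence I/O
# ---------------------------------------------------------------------------


def normalize_nt(seq: str) -> str:
    return seq.upper().replace("U", "T")


def read_fasta(path: str | Path, alphabet: str = "nt") -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(id, sequence), ...]`` preserving order.

    ``alphabet='nt'`` uppercases and normalizes U->T; ``alphabet='protein'``
    uppercases only.  Duplicate record ids and empty sequences are errors.
    """
    path = Path(path)
    if alphabet not in ("nt", "protein"):
        raise ValueError(f"unknown alphabet {alphabet!r}")
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FormatError(
                        f"{path}: malformed FASTA header at line {lineno}: "
                        f"expected '>'"
                    )
                break
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    out: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: empty sequence for record {rec.id!r}")
        if alphabet == "nt":
            seq = normalize_nt(seq)
        out.append((rec.id, seq))
    logger.info("read_fasta: %d records from %s (%s mode)", len(out), path, alphabet)
    return out


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as handle:
        for rec_id, seq in records:
            handle.write(f">{rec_id}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Hexamer tables
# ---------------------------------------------------------------------------


def read_hexamer_table(path: str | Path) -> HexamerTable:
    """Read a TSV with columns ``hexamer``, ``score``, ``label``."""
    df = pd.read_csv(path, sep="\t", dtype={"hexamer": str, "label": str})
    required = {"hexamer", "score", "label"}
    if not required <= set(df.columns):
        raise FormatError(
            f"{path}: hexamer table must have columns {sorted(required)}, "
            f"found {list(df.columns)}"
        )
    entries: dict[str, HexamerEntry] = {}
    for row in df.itertuples(index=False):
        h = normalize_nt(str(row.hexamer))
        if len(h) != 6 or not set(h) <= NT_ALPHABET:
            raise FormatError(f"{path}: invalid hexamer {row.hexamer!r}")
        if h in entries:
            raise FormatError(f"{path}: duplicate hexamer {h!r}")
        entries[h] = HexamerEntry(score=float(row.score), label=str(row.label))
    table = HexamerTable(entries)
    counts = table.class_counts()
    logger.info(
        "read_hexamer_table: %d hexamers from %s (ESE=%d, ESS=%d, NEUTRAL=%d)",
        len(table), path, counts["ESE"], counts["ESS"], counts["NEUTRAL"],
    )
    return table


def write_hexamer_table(table: HexamerTable, path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("hexamer\tscore\tlabel\n")
        for h in sorted(table.entries):
            e = table.entries[h]
            handle.write(f"{h}\t{e.score:.6g}\t{e.label}\n")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def read_bed(path: str | Path) -> GenomicIntervalSet:
    """Read BED3+ (extra columns beyond 5 are ignored)."""
    intervals: list[Interval] = []
    ncols = 3
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 0:
                raise FormatError(f"{path}:{lineno}: negative start {start}")
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start {start} >= end {end}")
            name = fields[3] if len(fields) > 3 else "."
            try:
                score = float(fields[4]) if len(fields) > 4 else 0.0
            except ValueError:
                score = 0.0
            ncols = max(ncols, min(len(fields), 5))
            intervals.append(Interval(chrom, start, end, name, score))
    return GenomicIntervalSet(intervals, ncols=ncols)


def write_bed(intervals: GenomicIntervalSet, path: str | Path) -> None:
    with open(path, "w") as handle:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if intervals.ncols >= 4:
                fields.append(iv.name)
            if intervals.ncols >= 5:
                fields.append(f"{iv.score:g}")
            handle.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Gene models and motif tables
# ---------------------------------------------------------------------------


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read a TSV of ``geneId exonIndex cdsStart cdsEnd [donorDinuc]`` rows.

    Exons must tile the CDS contiguously; a gap or overlap between
    consecutive exons raises :class:`FormatError` naming the gene.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"geneId", "exonIndex", "cdsStart", "cdsEnd"}
    if not required <= set(df.columns):
        raise FormatError(
            f"{path}: gene model table must have columns {sorted(required)}"
        )
    models: list[GeneModel] = []
    for gene_id, group in df.groupby("geneId", sort=False):
        group = group.sort_values("exonIndex")
        exons = [(int(r.cdsStart), int(r.cdsEnd)) for r in group.itertuples()]
        donors: list[str] = []
        if "donorDinuc" in group.columns:
            donors = [
                str(d) for d in group["donorDinuc"].tolist()[:-1] if pd.notna(d)
            ]
            if len(donors) != len(exons) - 1:
                donors = []
        models.append(GeneModel(str(gene_id), exons, donors))
    logger.info("read_gene_models: %d genes from %s", len(models), path)
    return models


def write_gene_models(models: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("geneId\texonIndex\tcdsStart\tcdsEnd\tdonorDinuc\n")
        for model in models:
            for k, (start, end) in enumerate(model.exons):
                donor = ""
                if model.donor_dinucs and k < len(model.exons) - 1:
                    donor = model.donor_dinucs[k]
                handle.write(f"{model.gene_id}\t{k + 1}\t{start}\t{end}\t{donor}\n")


def read_motifs_tsv(path: str | Path) -> list[MotifRecord]:
    df = pd.read_csv(path, sep="\t")
    records: list[MotifRecord] = []
    for row in df.itertuples(index=False):
        coord = frozenset(
            int(x) for x in str(row.coordinatingCodons).split(",") if x not in ("", "nan")
        )
        extra = ()
        raw = getattr(row, "coordinatingCdsPositions", "")
        if isinstance(raw, str) and raw:
            extra = tuple(int(x) for x in raw.split(","))
        records.append(
            MotifRecord(
                gene_id=str(row.geneId),
                motif_class=str(row.motifClass),
                cds_motif_start=int(row.cdsMotifStart),
                motif_length_nt=int(row.motifLengthNt),
                loop_start=int(row.loopStart),
                loop_length_nt=int(row.loopLengthNt),
                coordinating_codons=coord,
                coordinating_cds_positions=extra,
            )
        )
    return records


def write_motifs_tsv(records: Sequence[MotifRecord], path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write(
            "geneId\tmotifClass\tcdsMotifStart\tmotifLengthNt\tloopStart\t"
            "loopLengthNt\tloopFrame\tcoordinatingCodons\tcoordinatingCdsPositions\n"
        )
        for rec in records:
            coord = ",".join(str(c) for c in sorted(rec.coordinating_codons))
            extra = ",".join(str(p) for p in rec.coordinating_cds_positions)
            handle.write(
                f"{rec.gene_id}\t{rec.motif_class}\t{rec.cds_motif_start}\t"
                f"{rec.motif_length_nt}\t{rec.loop_start}\t{rec.loop_length_nt}\t"
                f"{rec.loop_frame}\t{coord}\t{extra}\n"
            )


# ---------------------------------------------------------------------------
# Coordinate converters (the only place 1-based CDS and BED meet)
# ---------------------------------------------------------------------------


def cds_to_bed(chrom: str, start_1based: int, end_1based: int, name: str = ".",
               score: float = 0.0) -> Interval:
    return Interval(chrom, start_1based - 1, end_1based, name, score)


def bed_to_cds(iv: Interval) -> tuple[int, int]:
    return iv.start + 1, iv.end


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


def load_config(path: str | Path) -> dict:
    """Load a flat YAML key-value configuration file."""
    with open(path) as handle:
        data = yaml.safe_load(handle)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise FormatError(f"{path}: config must be a mapping")
    return data
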