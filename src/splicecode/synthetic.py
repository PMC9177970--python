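"""Synthetic data generator for every pipeline input.

The generator emulates the statistical structure the analysis assumes, so
that every stage is testable without downloads:

* EF-hand loops drawn position-wise from residue distributions honouring the
  12-position consensus (Asp-dominated, ~half charged residues);
* coding sequences reverse-translated with a usage bias at loop codons 1
  (GAC:GAT = 0.63:0.37) and 12 (GAG:GAA ~ 0.67:0.33) and human-like family
  weights elsewhere;
* exon splits placed either uniformly across the 108-nt motif or in two
  clusters (N-terminal loop half and around codon 12);
* disjoint ESE/ESS hexamer sets with a programmable GA-dinucleotide
  enrichment in the ESE class and stochastically dominant ESE scores;
* peak sets with a programmable fold enrichment over motif-coding intervals.

All outputs are bit-reproducible under a fixed seed, and generated CDS
always translate back to the generated proteins.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .codon_usage import GENETIC_CODE, HUMAN_LIKE_USAGE_PER1000, synonymous_families
from .formats import (
    GeneModel,
    GenomicIntervalSet,
    HexamerEntry,
    HexamerTable,
    Interval,
    MotifRecord,
)
from .interval_enrichment import Workspace, _Coverage, _GlobalAxis, _merge_rows
from .motifs import EFHAND_LOOP_PATTERN, ConsensusPattern, parse_prosite_pattern

logger = logging.getLogger("splicecode")

ALL_HEXAMERS = ["".join(p) for p in itertools.product("ACGT", repeat=6)]

# Default per-position loop residue distributions.  These digitize the
# qualitative picture for canonical loops -- Asp ~ a quarter of all loop
# residues, Glu over an eighth, charged residues roughly half -- while
# honouring the consensus constraints at every position.  They are editable
# configuration, not hard-coded truth.
DEFAULT_LOOP_RESIDUE_FREQS: tuple[dict[str, float], ...] = (
    {"D": 1.0},
    {"K": 0.3, "A": 0.2, "R": 0.15, "Q": 0.1, "E": 0.1, "V": 0.1, "T": 0.05},
    {"D": 0.65, "N": 0.25, "S": 0.10},
    {"D": 0.25, "N": 0.2, "K": 0.2, "G": 0.15, "R": 0.1, "A": 0.1},
    {"D": 0.5, "N": 0.15, "S": 0.15, "G": 0.1, "E": 0.05, "T": 0.05},
    {"G": 0.8, "K": 0.05, "R": 0.05, "N": 0.05, "D": 0.05},
    {"T": 0.25, "K": 0.2, "Y": 0.15, "E": 0.1, "S": 0.1, "R": 0.1, "A": 0.1},
    {"I": 0.45, "L": 0.3, "V": 0.2, "M": 0.04, "C": 0.01},
    {"D": 0.3, "S": 0.2, "N": 0.15, "T": 0.15, "E": 0.1, "G": 0.05, "A": 0.05},
    {"A": 0.2, "E": 0.2, "K": 0.15, "R": 0.1, "D": 0.1, "T": 0.1, "L": 0.1,
     "F": 0.05},
    {"E": 0.35, "A": 0.15, "K": 0.15, "D": 0.1, "R": 0.1, "L": 0.1, "S": 0.05},
    {"E": 0.9, "D": 0.1},
)

# Residues guaranteed to violate the consensus at the given position, used to
# derive noncanonical loops from canonical draws.
_VIOLATIONS: dict[int, str] = {1: "K", 2: "W", 7: "P", 8: "K", 12: "K"}

# Per-position codon weights at the Ca2+-anchoring loop codons; family-uniform
# weights apply elsewhere in the loop, human-like weights outside it.
LOOP_CODON1_ASP = {"GAC": 0.63, "GAT": 0.37}
LOOP_CODON12_GLU = {"GAG": 182 / 271, "GAA": 89 / 271}
LOOP_CODON12_ASP = {"GAC": 0.75, "GAT": 0.25}
S100_CODON1_SER = {"TCG": 0.35, "TCT": 0.13, "TCC": 0.13, "TCA": 0.13,
                   "AGT": 0.13, "AGC": 0.13}

# Motif-level intron counts per class (fractions of 1-, 2- and >=3-exon
# motifs among canonical, noncanonical and S100 EF-hands).
EXON_COUNT_WEIGHTS = {
    "CANONICAL": (79, 178, 39),
    "NONCANONICAL": (15, 47, 4),
    "S100": (7, 8, 0),
}


@dataclass
class SplitModel:
    mode: str = "two_cluster"  # or "uniform"
    cluster_weights: tuple[float, float] = (0.7, 0.3)
    n_cluster_positions: tuple[int, ...] = (2, 4, 5, 7, 9, 10, 13, 15, 17, 18)
    c_cluster_positions: tuple[int, ...] = (31, 33, 34, 36)
    within_loop_prob: float = 0.427

    def validate(self) -> None:
        if self.mode not in ("uniform", "two_cluster"):
            raise ValueError(f"unknown split mode {self.mode!r}")
        if abs(sum(self.cluster_weights) - 1.0) > 1e-9:
            raise ValueError("cluster weights must sum to 1")
        if not 0.0 <= self.within_loop_prob <= 1.0:
            raise ValueError("within_loop_prob must be in [0, 1]")


@dataclass
class HexamerModel:
    n_ese: int = 1182
    n_ess: int = 1090
    ga_enrichment: float = 3.0

    def validate(self) -> None:
        if self.n_ese + self.n_ess > 4096:
            raise ValueError("n_ese + n_ess must not exceed 4096")
        if self.n_ese < 1 or self.n_ess < 1:
            raise ValueError("hexamer set sizes must be positive")
        if self.ga_enrichment < 1.0:
            raise ValueError("ga_enrichment must be >= 1")


@dataclass
class PeakModel:
    n_peaks: int = 1000
    peak_length: int = 30
    fold_in_motifs: float = 3.0

    def validate(self) -> None:
        if self.fold_in_motifs < 1.0:
            raise ValueError("fold_in_motifs must be >= 1")
        if self.n_peaks < 1 or self.peak_length < 1:
            raise ValueError("peak model sizes must be positive")


@dataclass
class SimulationConfig:
    """Ground-truth parameters of one synthetic study."""

    seed: int = 0
    n_canonical: int = 296
    n_noncanonical: int = 66
    n_s100: int = 15
    n_control_exons: int = 500
    flank_codon_range: tuple[int, int] = (20, 60)
    loop_residue_freqs: tuple[dict[str, float], ...] = DEFAULT_LOOP_RESIDUE_FREQS
    split_model: SplitModel = field(default_factory=SplitModel)
    hexamer_model: HexamerModel = field(default_factory=HexamerModel)
    peak_model: PeakModel = field(default_factory=PeakModel)

    def validate(self) -> None:
        self.split_model.validate()
        self.hexamer_model.validate()
        self.peak_model.validate()
        pattern = parse_prosite_pattern(EFHAND_LOOP_PATTERN)
        validate_loop_freqs(self.loop_residue_freqs, pattern)

    def as_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        cfg = cls()
        for key, value in data.items():
            if key == "split_model":
                cfg.split_model = SplitModel(**value)
            elif key == "hexamer_model":
                cfg.hexamer_model = HexamerModel(**value)
            elif key == "peak_model":
                cfg.peak_model = PeakModel(**value)
            elif key == "loop_residue_freqs":
                cfg.loop_residue_freqs = tuple(dict(d) for d in value)
            elif hasattr(cfg, key):
                default = getattr(cfg, key)
                if isinstance(default, tuple):
                    value = tuple(value)
                setattr(cfg, key, value)
            else:
                raise ValueError(f"unknown simulation config key {key!r}")
        cfg.validate()
        return cfg


def validate_loop_freqs(freqs: Sequence[dict[str, float]],
                        pattern: ConsensusPattern) -> None:
    """Every supported residue must satisfy its position's constraint and
    every distribution must sum to 1."""
    if len(freqs) != 12:
        raise ValueError("loop residue distributions must cover 12 positions")
    for i, (dist, constraint) in enumerate(zip(freqs, pattern.positions), start=1):
        if abs(sum(dist.values()) - 1.0) > 1e-9:
            raise ValueError(f"loop position {i}: probabilities must sum to 1")
        for aa, p in dist.items():
            if p < 0:
                raise ValueError(f"loop position {i}: negative probability")
            if p > 0 and not constraint.matches(aa):
                raise ValueError(
                    f"loop position {i}: residue {aa!r} violates the consensus"
                )


# ---------------------------------------------------------------------------
# Sequence-level helpers
# ---------------------------------------------------------------------------

_FAMILIES = synonymous_families()

_BACKGROUND_AA = {
    aa: sum(HUMAN_LIKE_USAGE_PER1000[c] for c in codons)
    for aa, codons in _FAMILIES.items()
    if aa != "*"
}


def _sample_discrete(rng: np.random.Generator, items: Sequence[str],
                     weights: Sequence[float], size: int | None = None):
    p = np.asarray(weights, dtype=float)
    p = p / p.sum()
    idx = rng.choice(len(items), size=size, p=p)
    if size is None:
        return items[int(idx)]
    return [items[int(i)] for i in np.asarray(idx)]


def _sample_background_protein(rng: np.random.Generator, n: int) -> str:
    aas = sorted(_BACKGROUND_AA)
    weights = [_BACKGROUND_AA[a] for a in aas]
    return "".join(_sample_discrete(rng, aas, weights, n))


def _codon_for(rng: np.random.Generator, aa: str,
               override: dict[str, float] | None = None,
               family_uniform: bool = False) -> str:
    if override is not None:
        codons = sorted(override)
        return _sample_discrete(rng, codons, [override[c] for c in codons])
    codons = _FAMILIES[aa]
    if family_uniform:
        weights = [1.0] * len(codons)
    else:
        weights = [HUMAN_LIKE_USAGE_PER1000[c] for c in codons]
    return _sample_discrete(rng, codons, weights)


def translate(cds: str) -> str:
    if len(cds) % 3 != 0:
        raise ValueError("CDS length not divisible by 3")
    return "".join(GENETIC_CODE[cds[i:i + 3]] for i in range(0, len(cds), 3))


# ---------------------------------------------------------------------------
# Gene simulation
# ---------------------------------------------------------------------------


def _sample_loop(rng: np.random.Generator, cfg: SimulationConfig,
                 motif_class: str) -> str:
    residues = [
        _sample_discrete(rng, sorted(d), [d[a] for a in sorted(d)])
        for d in cfg.loop_residue_freqs
    ]
    if motif_class == "NONCANONICAL":
        pos = int(_sample_discrete(rng, sorted(map(str, _VIOLATIONS)),
                                   [1.0] * len(_VIOLATIONS)))
        residues[pos - 1] = _VIOLATIONS[pos]
        return "".join(residues)
    if motif_class == "S100":
        # 14-residue pseudoloop: Ser-led, then a generic tail.
        tail = _sample_background_protein(rng, 13)
        return "S" + tail
    return "".join(residues)


def _reverse_translate_loop(rng: np.random.Generator, loop: str,
                            motif_class: str) -> str:
    codons: list[str] = []
    for k, aa in enumerate(loop, start=1):
        override = None
        if motif_class in ("CANONICAL", "NONCANONICAL"):
            if k == 1 and aa == "D":
                override = LOOP_CODON1_ASP
            elif k == 12 and aa == "E":
                override = LOOP_CODON12_GLU
            elif k == 12 and aa == "D":
                override = LOOP_CODON12_ASP
        elif motif_class == "S100" and k == 1 and aa == "S":
            override = S100_CODON1_SER
        codons.append(_codon_for(rng, aa, override=override, family_uniform=True))
    return "".join(codons)


def _sample_split_positions(rng: np.random.Generator, cfg: SimulationConfig,
                            n_introns: int, motif: MotifRecord) -> list[int]:
    """CDS insertion points p (intron between nt p and p+1) inside the motif."""
    model = cfg.split_model
    lo = motif.cds_motif_start - 1
    hi = motif.motif_end - 1  # inclusive; motif_length_nt candidate positions
    loop_positions = set(range(motif.loop_start - 1,
                               motif.loop_start - 1 + motif.loop_length_nt))
    outside_positions = [p for p in range(lo, hi + 1) if p not in loop_positions]
    chosen: set[int] = set()
    guard = 0
    while len(chosen) < n_introns and guard < 1000:
        guard += 1
        if model.mode == "uniform":
            p = int(rng.integers(lo, hi + 1))
        elif rng.random() < model.within_loop_prob:
            if rng.random() < model.cluster_weights[0]:
                positions = model.n_cluster_positions
            else:
                positions = model.c_cluster_positions
            rel = min(int(positions[rng.integers(0, len(positions))]),
                      motif.loop_length_nt)
            p = motif.loop_start + rel - 2
        else:
            p = outside_positions[int(rng.integers(0, len(outside_positions)))]
        chosen.add(p)
    return sorted(chosen)


def simulate_efhand_genes(config: SimulationConfig,
                          rng: np.random.Generator | int | None = None
                          ) -> tuple[list[tuple[str, str]],
                                     list[tuple[str, str]],
                                     list[MotifRecord],
                                     list[GeneModel]]:
    """Generate proteins, CDS, motif records and gene models for all classes.

    Every gene carries exactly one Ca2+-binding motif; coordinates in the
    returned :class:`MotifRecord` objects are correct by construction and the
    CDS translates to the protein under the standard code.
    """
    config.validate()
    if rng is None or isinstance(rng, int):
        rng = np.random.default_rng(config.seed if rng is None else rng)
    proteins: list[tuple[str, str]] = []
    cds_records: list[tuple[str, str]] = []
    motifs: list[MotifRecord] = []
    models: list[GeneModel] = []
    class_plan = (
        ["CANONICAL"] * config.n_canonical
        + ["NONCANONICAL"] * config.n_noncanonical
        + ["S100"] * config.n_s100
    )
    lo, hi = config.flank_codon_range
    for idx, motif_class in enumerate(class_plan, start=1):
        gene_id = f"GENE{idx:04d}"
        flank_l = int(rng.integers(lo, hi + 1))
        flank_r = int(rng.integers(lo, hi + 1))
        loop_aa = _sample_loop(rng, config, motif_class)
        helix_l = _sample_background_protein(rng, 12)
        helix_r = _sample_background_protein(rng, 12)
        protein = (
            _sample_background_protein(rng, flank_l)
            + helix_l + loop_aa + helix_r
            + _sample_background_protein(rng, flank_r)
        )
        loop_cds = _reverse_translate_loop(rng, loop_aa, motif_class)
        other = protein[: flank_l + 12] , protein[flank_l + 12 + len(loop_aa):]
        cds = (
            "".join(_codon_for(rng, aa) for aa in other[0])
            + loop_cds
            + "".join(_codon_for(rng, aa) for aa in other[1])
        )
        cds_motif_start = 3 * flank_l + 1
        loop_start = cds_motif_start + 36
        motif = MotifRecord(
            gene_id=gene_id,
            motif_class=motif_class,
            cds_motif_start=cds_motif_start,
            motif_length_nt=72 + 3 * len(loop_aa),
            loop_start=loop_start,
            loop_length_nt=3 * len(loop_aa),
        )
        weights = EXON_COUNT_WEIGHTS[motif_class]
        n_introns = int(_sample_discrete(rng, ["0", "1", "2"], weights))
        splits = _sample_split_positions(rng, config, n_introns, motif)
        bounds = [0] + splits + [len(cds)]
        exons = [(bounds[i] + 1, bounds[i + 1]) for i in range(len(bounds) - 1)]
        donors = ["GC" if rng.random() < 0.01 else "GT" for _ in splits]
        proteins.append((gene_id, protein))
        cds_records.append((gene_id, cds))
        motifs.append(motif)
        models.append(GeneModel(gene_id, exons, donors))
    logger.info(
        "simulate_efhand_genes: %d genes (%d canonical, %d noncanonical, %d S100)",
        len(class_plan), config.n_canonical, config.n_noncanonical, config.n_s100,
    )
    return proteins, cds_records, motifs, models


def simulate_control_exons(config: SimulationConfig,
                           rng: np.random.Generator | int | None = None
                           ) -> list[str]:
    """Control coding exons with human-like codon usage and no motif."""
    if rng is None or isinstance(rng, int):
        rng = np.random.default_rng(config.seed if rng is None else rng)
    exons: list[str] = []
    for _ in range(config.n_control_exons):
        n_codons = int(rng.integers(20, 101))
        protein = _sample_background_protein(rng, n_codons)
        exons.append("".join(_codon_for(rng, aa) for aa in protein))
    return exons


# ---------------------------------------------------------------------------
# Hexamer set simulation
# ---------------------------------------------------------------------------


def _ga_counts() -> np.ndarray:
    return np.array(
        [sum(1 for j in range(5) if h[j:j + 2] == "GA") for h in ALL_HEXAMERS]
    )


def _ga_freq(hexamers: Sequence[str]) -> float:
    total = sum(
        1 for h in hexamers for j in range(5) if h[j:j + 2] == "GA"
    )
    return total / (5 * len(hexamers))


def simulate_hexamer_sets(config: SimulationConfig,
                          rng: np.random.Generator | int | None = None
                          ) -> tuple[list[str], list[str], HexamerTable]:
    """Disjoint ESE/ESS hexamer sets plus a full 4096-entry score table.

    GA-dinucleotide frequency in the ESE set exceeds the ESS set by the
    configured factor: sampling weights are exponentially tilted by the
    per-hexamer GA count (``w**nGA`` for ESEs, ``w**-nGA`` for ESSs), with
    ``w`` calibrated by bisection against the realized frequency ratio.
    Scores are drawn so ESE scores stochastically dominate ESS scores.
    """
    model = config.hexamer_model
    model.validate()
    if rng is None or isinstance(rng, int):
        rng = np.random.default_rng(config.seed if rng is None else rng)
    nga = _ga_counts()
    n_ese, n_ess = model.n_ese, model.n_ess
    target = model.ga_enrichment

    # feasibility: best case puts the most GA-rich hexamers in the ESE set
    # and GA-free hexamers in the ESS set (smoothed to avoid division by 0)
    top = np.sort(nga)[::-1][:n_ese]
    max_ratio = (top.sum() / (5 * n_ese)) / (0.5 / (5 * n_ess))
    if target > max_ratio:
        raise ValueError(
            f"ga_enrichment {target} not achievable (max ~{max_ratio:.1f})"
        )

    def sample_sets(log_w: float, child: np.random.Generator
                    ) -> tuple[list[str], list[str]]:
        w_ess = np.exp(-log_w * nga)
        ess_idx = child.choice(4096, size=n_ess, replace=False,
                               p=w_ess / w_ess.sum())
        mask = np.ones(4096, dtype=bool)
        mask[ess_idx] = False
        pool = np.flatnonzero(mask)
        w_ese = np.exp(log_w * nga[pool])
        ese_idx = pool[child.choice(len(pool), size=n_ese, replace=False,
                                    p=w_ese / w_ese.sum())]
        return ([ALL_HEXAMERS[i] for i in np.sort(ese_idx)],
                [ALL_HEXAMERS[i] for i in np.sort(ess_idx)])

    base_seed = int(rng.integers(0, 2**31 - 1))
    if target == 1.0:
        log_w = 0.0
        ese, ess = sample_sets(log_w, np.random.default_rng(base_seed))
    else:
        # bisection on the realized (sampled) GA frequency ratio; each
        # evaluation uses a deterministic child generator
        lo_w, hi_w = 0.0, 6.0
        ese = ess = None
        for it in range(14):
            mid = 0.5 * (lo_w + hi_w)
            child = np.random.default_rng((base_seed, it))
            ese, ess = sample_sets(mid, child)
            achieved = _ga_freq(ese) / max(_ga_freq(ess), 0.5 / (5 * n_ess))
            if achieved < target:
                lo_w = mid
            else:
                hi_w = mid
        log_w = 0.5 * (lo_w + hi_w)
        child = np.random.default_rng((base_seed, 99))
        ese, ess = sample_sets(log_w, child)
        achieved = _ga_freq(ese) / max(_ga_freq(ess), 0.5 / (5 * n_ess))
        logger.info("simulate_hexamer_sets: target GA ratio %.2f, achieved %.2f "
                    "(log_w=%.3f)", target, achieved, log_w)

    ese_set, ess_set = set(ese), set(ess)
    entries: dict[str, HexamerEntry] = {}
    for h in ALL_HEXAMERS:
        if h in ese_set:
            entries[h] = HexamerEntry(float(rng.normal(1.5, 0.5)), "ESE")
        elif h in ess_set:
            entries[h] = HexamerEntry(float(rng.normal(-1.5, 0.5)), "ESS")
        else:
            entries[h] = HexamerEntry(float(rng.normal(0.0, 0.3)), "NEUTRAL")
    return ese, ess, HexamerTable(entries)


# ---------------------------------------------------------------------------
# Peak simulation
# ---------------------------------------------------------------------------


def simulate_peaks(config: SimulationConfig,
                   annotations: GenomicIntervalSet,
                   workspace: Workspace,
                   rng: np.random.Generator | int | None = None,
                   fold: float | None = None,
                   name_prefix: str = "peak") -> GenomicIntervalSet:
    """Place peaks so their expected per-peak annotation overlap is ``fold``
    times the uniform-placement null mean.

    Placement probabilities over all valid starts are exponentially tilted in
    the start's annotation overlap, with the tilt solved by bisection; with
    ``fold=1`` placement is exactly uniform, so padding the annotations
    cannot manufacture signal.
    """
    model = config.peak_model
    model.validate()
    if fold is None:
        fold = model.fold_in_motifs
    if fold < 1.0:
        raise ValueError("fold must be >= 1")
    if rng is None or isinstance(rng, int):
        rng = np.random.default_rng(config.seed if rng is None else rng)

    axis = _GlobalAxis(workspace.intervals, annotations)
    ws_rows = axis.project(workspace.intervals)
    ann_rows = _merge_rows(axis.project(annotations))
    ws_cov = _Coverage(ws_rows)
    ann_total = int((ann_rows[:, 1] - ann_rows[:, 0]).sum())
    inside = int(ws_cov.overlaps(ann_rows[:, 0], ann_rows[:, 1]).sum())
    if inside != ann_total:
        raise ValueError("annotation intervals are not contained in the workspace")
    cov = _Coverage(ann_rows)

    L = model.peak_length
    starts_list = []
    for ws_s, ws_e in ws_rows:
        if ws_e - ws_s >= L:
            starts_list.append(np.arange(ws_s, ws_e - L + 1))
    if not starts_list:
        raise ValueError(f"no workspace interval can hold a {L}-nt peak")
    all_starts = np.concatenate(starts_list)
    if len(all_starts) > 20_000_000:
        raise ValueError("workspace too large for exhaustive start enumeration")
    ov = cov.overlaps(all_starts, all_starts + L).astype(float)
    mu0 = float(ov.mean())
    target_mean = fold * mu0
    if target_mean > ov.max():
        raise ValueError(f"fold {fold} not achievable (max {ov.max() / mu0:.1f})")

    if fold == 1.0 or mu0 == 0.0:
        theta = 0.0
    else:
        lo_t, hi_t = 0.0, 1.0
        def tilted_mean(theta: float) -> float:
            w = np.exp(theta * (ov - ov.max()))
            return float((w * ov).sum() / w.sum())
        while tilted_mean(hi_t) < target_mean and hi_t < 200:
            hi_t *= 2
        for _ in range(80):
            mid = 0.5 * (lo_t + hi_t)
            if tilted_mean(mid) < target_mean:
                lo_t = mid
            else:
                hi_t = mid
        theta = 0.5 * (lo_t + hi_t)

    w = np.exp(theta * (ov - ov.max()))
    idx = rng.choice(len(all_starts), size=model.n_peaks, p=w / w.sum())
    starts = all_starts[idx]

    rev = sorted(((off, chrom) for chrom, off in axis.offsets.items()))
    offs = np.array([o for o, _ in rev], dtype=np.int64)
    chroms = [c for _, c in rev]
    peaks: list[Interval] = []
    for i, g_start in enumerate(np.sort(starts)):
        k = int(np.searchsorted(offs, g_start, side="right") - 1)
        local = int(g_start - offs[k])
        peaks.append(Interval(chroms[k], local, local + L,
                              f"{name_prefix}{i:05d}", 0.0))
    logger.info("simulate_peaks: %d peaks of %d nt, fold=%.2f (theta=%.4f)",
                model.n_peaks, L, fold, theta)
    return GenomicIntervalSet(peaks, ncols=5)
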