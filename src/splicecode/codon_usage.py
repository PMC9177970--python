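"""Codon usage statistics: RSCU, CAI, expected CAI, bias tests, fragility.

RSCU (relative synonymous codon usage) is the observed count of a codon
divided by the count expected under equal use of its synonymous family.
CAI (codon adaptation index) is the geometric mean of relative adaptiveness
values w(c) = RSCU(c)/max RSCU in family, computed against a reference usage
table with the customary exclusion of Met, Trp and stop codons.

The expected-CAI baseline re-encodes the query's amino-acid sequence with
synonymous codons sampled under a single GC-affinity weight tuned so the
sampler's expected GC content matches the query, separating genuine codon
preference from GC/amino-acid composition artifacts.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .formats import normalize_nt

logger = logging.getLogger("splicecode")

ALL_CODONS = ["".join(p) for p in itertools.product("ACGT", repeat=3)]

# Standard genetic code (DNA alphabet).
GENETIC_CODE: dict[str, str] = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

STOP_CODONS = frozenset(c for c, aa in GENETIC_CODE.items() if aa == "*")
SENSE_CODONS = [c for c in ALL_CODONS if c not in STOP_CODONS]


def synonymous_families(genetic_code: dict[str, str] | None = None) -> dict[str, list[str]]:
    code = genetic_code or GENETIC_CODE
    families: dict[str, list[str]] = {}
    for codon, aa in code.items():
        families.setdefault(aa, []).append(codon)
    for aa in families:
        families[aa].sort()
    return families


# Coarse human-like codon usage per 1000 codons (synthetic defaults used by
# the data generator and as a default CAI reference; editable via config).
HUMAN_LIKE_USAGE_PER1000: dict[str, float] = {
    "TTT": 17.6, "TTC": 20.3, "TTA": 7.7, "TTG": 12.9,
    "CTT": 13.2, "CTC": 19.6, "CTA": 7.2, "CTG": 39.6,
    "ATT": 16.0, "ATC": 20.8, "ATA": 7.5, "ATG": 22.0,
    "GTT": 11.0, "GTC": 14.5, "GTA": 7.1, "GTG": 28.1,
    "TCT": 15.2, "TCC": 17.7, "TCA": 12.2, "TCG": 4.4,
    "CCT": 17.5, "CCC": 19.8, "CCA": 16.9, "CCG": 6.9,
    "ACT": 13.1, "ACC": 18.9, "ACA": 15.1, "ACG": 6.1,
    "GCT": 18.4, "GCC": 27.7, "GCA": 15.8, "GCG": 7.4,
    "TAT": 12.2, "TAC": 15.3, "TAA": 1.0, "TAG": 0.8,
    "CAT": 10.9, "CAC": 15.1, "CAA": 12.3, "CAG": 34.2,
    "AAT": 17.0, "AAC": 19.1, "AAA": 24.4, "AAG": 31.9,
    "GAT": 21.8, "GAC": 25.1, "GAA": 29.0, "GAG": 39.6,
    "TGT": 10.6, "TGC": 12.6, "TGA": 1.6, "TGG": 13.2,
    "CGT": 4.5, "CGC": 10.4, "CGA": 6.2, "CGG": 11.4,
    "AGT": 12.1, "AGC": 19.5, "AGA": 12.2, "AGG": 12.0,
    "GGT": 10.8, "GGC": 22.2, "GGA": 16.5, "GGG": 16.5,
}


@dataclass
class CodonUsageTable:
    """Per-codon counts, per-1000 usage, RSCU and family assignment."""

    count: dict[str, float]
    per1000: dict[str, float]
    rscu: dict[str, float]
    family: dict[str, str]

    def as_rows(self) -> list[dict]:
        return [
            {
                "codon": c,
                "aminoAcid": self.family[c],
                "count": self.count[c],
                "per1000": self.per1000[c],
                "rscu": self.rscu[c],
            }
            for c in ALL_CODONS
        ]


def per1000(counts: dict[str, float]) -> dict[str, float]:
    """Usage normalized to occurrences per 1000 codons."""
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("total codon count must be positive")
    return {c: 1000.0 * n / total for c, n in counts.items()}


def rscu(counts: dict[str, float],
         genetic_code: dict[str, str] | None = None) -> CodonUsageTable:
    """Build a :class:`CodonUsageTable`, computing RSCU per synonymous family.

    RSCU(c) = count(c) / (family total / family size); families with zero
    total get RSCU = NaN.
    """
    code = genetic_code or GENETIC_CODE
    for codon in counts:
        if normalize_nt(codon) not in code:
            raise ValueError(f"codon {codon!r} not in genetic code")
    full = {c: float(counts.get(c, 0.0)) for c in code}
    families = synonymous_families(code)
    rscu_vals: dict[str, float] = {}
    for aa, codons in families.items():
        total = sum(full[c] for c in codons)
        for c in codons:
            if total > 0:
                rscu_vals[c] = full[c] / (total / len(codons))
            else:
                rscu_vals[c] = float("nan")
    return CodonUsageTable(
        count=full,
        per1000=per1000(full) if sum(full.values()) > 0 else {c: 0.0 for c in full},
        rscu=rscu_vals,
        family={c: code[c] for c in code},
    )


def relative_adaptiveness(reference: CodonUsageTable) -> dict[str, float]:
    """w(c) = RSCU(c) / max RSCU in the synonymous family."""
    families = synonymous_families()
    w: dict[str, float] = {}
    for aa, codons in families.items():
        if aa == "*":
            continue
        vals = [reference.rscu[c] for c in codons]
        if any(math.isnan(v) for v in vals):
            for c in codons:
                w[c] = float("nan")
            continue
        top = max(vals)
        for c in codons:
            w[c] = reference.rscu[c] / top if top > 0 else float("nan")
    return w


def _split_codons(sequence: str) -> list[str]:
    seq = normalize_nt(sequence)
    if len(seq) % 3 != 0:
        raise ValueError(f"CDS length {len(seq)} not divisible by 3")
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]


def cai(sequence: str, reference: CodonUsageTable) -> float:
    """Codon adaptation index of a CDS against a reference usage table.

    Geometric mean of w over codons, excluding Met, Trp and stop codons
    (single-codon families carry no usage information).
    """
    w = relative_adaptiveness(reference)
    families = synonymous_families()
    log_sum, n = 0.0, 0
    for codon in _split_codons(sequence):
        aa = GENETIC_CODE.get(codon)
        if aa is None:
            raise ValueError(f"unknown codon {codon!r}")
        if aa in ("M", "W", "*"):
            continue
        wc = w[codon]
        if math.isnan(wc):
            raise ValueError(f"reference RSCU undefined for family of {codon!r}")
        log_sum += math.log(max(wc, 1e-12))
        n += 1
    if n == 0:
        raise ValueError("no informative codons for CAI")
    return math.exp(log_sum / n)


def _gc_count(codon: str) -> int:
    return sum(1 for b in codon if b in "GC")


def expected_cai(sequence: str, reference: CodonUsageTable, n_random: int,
                 seed: int | np.random.Generator,
                 gc_tolerance: float = 1e-3) -> dict[str, float]:
    """Null CAI distribution for random synonymous re-encodings of ``sequence``.

    The amino-acid sequence is preserved exactly; each codon is resampled
    within its synonymous family under weights proportional to ``t**gc(c)``,
    with the single GC-affinity parameter ``t`` tuned by bisection until the
    sampler's expected GC content matches the query's GC content (within
    ``gc_tolerance``, a fraction of sequence GC).  Returns the null mean and
    sd of CAI plus ``p_greater``, the fraction of random sequences with CAI
    at or above the query's.
    """
    if n_random < 2:
        raise ValueError("n_random must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    codons = _split_codons(sequence)
    families = synonymous_families()
    aa_seq = [GENETIC_CODE[c] for c in codons]
    target_gc = sum(_gc_count(c) for c in codons) / (3 * len(codons))

    # family choices per position (stop codons resampled within stop family)
    choices = [families[aa] for aa in aa_seq]
    gc_arrays = [np.array([_gc_count(c) for c in fam]) for fam in choices]

    def expected_gc(log_t: float) -> float:
        total = 0.0
        for gcs in gc_arrays:
            w = np.exp(log_t * gcs)
            total += float((w * gcs).sum() / w.sum())
        return total / (3 * len(codons))

    lo, hi = -30.0, 30.0
    if expected_gc(lo) > target_gc or expected_gc(hi) < target_gc:
        logger.warning("expected_cai: target GC %.3f outside achievable range; "
                       "using boundary weight", target_gc)
        log_t = lo if expected_gc(lo) > target_gc else hi
    else:
        for _ in range(100):
            mid = 0.5 * (lo + hi)
            if expected_gc(mid) < target_gc:
                lo = mid
            else:
                hi = mid
            if hi - lo < 1e-12:
                break
        log_t = 0.5 * (lo + hi)
    achieved = expected_gc(log_t)
    if abs(achieved - target_gc) > gc_tolerance:
        logger.warning("expected_cai: achieved GC %.4f vs target %.4f", achieved,
                       target_gc)

    w_ref = relative_adaptiveness(reference)
    # per-position sampling probabilities and log-w values
    sampled_logw = np.zeros((n_random, 0))
    cols: list[np.ndarray] = []
    for fam, gcs in zip(choices, gc_arrays):
        aa = GENETIC_CODE[fam[0]]
        probs = np.exp(log_t * gcs)
        probs = probs / probs.sum()
        idx = rng.choice(len(fam), size=n_random, p=probs)
        if aa in ("M", "W", "*"):
            continue
        logw = np.array([math.log(max(w_ref[c], 1e-12)) for c in fam])
        cols.append(logw[idx])
    if not cols:
        raise ValueError("no informative codons for expected CAI")
    mat = np.column_stack(cols)
    cais = np.exp(mat.mean(axis=1))
    query = cai(sequence, reference)
    result = {
        "mean": float(cais.mean()),
        "sd": float(cais.std(ddof=1)),
        "p_greater": float((cais >= query - 1e-12).mean()),
        "query_cai": query,
        "gc_affinity_log_t": float(log_t),
    }
    logger.info("expected_cai: n=%d, mean=%.4f, sd=%.4f, query=%.4f",
                n_random, result["mean"], result["sd"], query)
    return result


def usage_bias_test(observed: tuple[int, int], reference_p: float) -> float:
    """Exact two-sided binomial test for a 2-codon usage contrast.

    ``observed = (k, n-k)`` successes/failures; ``reference_p`` is the
    expected success fraction.  Two-sidedness sums point probabilities
    <= P(k), ties included.
    """
    k, rest = observed
    n = k + rest
    if n < 1:
        raise ValueError("need at least one observation")
    if not 0.0 < reference_p < 1.0:
        raise ValueError("reference fraction must be in (0, 1)")
    return float(stats.binomtest(k, n, reference_p, alternative="two-sided").pvalue)


def codon_fragility(codon: str,
                    genetic_code: dict[str, str] | None = None) -> str:
    """Classify a sense codon as FRAGILE or ROBUST.

    FRAGILE codons can mutate to a stop codon by a single-nt substitution;
    ROBUST codons need at least two point mutations.
    """
    code = genetic_code or GENETIC_CODE
    c = normalize_nt(codon)
    if c not in code:
        raise ValueError(f"unknown codon {codon!r}")
    stops = {cd for cd, aa in code.items() if aa == "*"}
    if c in stops:
        raise ValueError(f"stop codon {c!r} has no fragility class")
    for pos in range(3):
        for base in "ACGT":
            if base == c[pos]:
                continue
            if c[:pos] + base + c[pos + 1 :] in stops:
                return "FRAGILE"
    return "ROBUST"


def correlate_codon_vectors(x: dict[str, float], y: dict[str, float],
                            subset: set[str] | None = None) -> tuple[float, float]:
    """Pearson correlation of two per-codon vectors restricted to ``subset``.

    Returns ``(nan, nan)`` when either restricted vector has zero variance.
    """
    codons = sorted(subset) if subset is not None else sorted(set(x) & set(y))
    if len(codons) < 3:
        raise ValueError("need at least 3 codons")
    xa = np.array([x[c] for c in codons], dtype=float)
    ya = np.array([y[c] for c in codons], dtype=float)
    if xa.std() == 0 or ya.std() == 0:
        logger.warning("correlate_codon_vectors: zero variance, returning NA")
        return float("nan"), float("nan")
    r, p = stats.pearsonr(xa, ya)
    return float(r), float(p)
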