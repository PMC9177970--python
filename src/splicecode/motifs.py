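"""EF-hand consensus scanning and motif classification.

The 12-residue Ca2+-chelation loop of canonical EF-hands is described by a
PROSITE-style pattern in which square brackets list permitted residues,
parentheses list residues *not* allowed, and ``x`` matches anything:

    D-(W)-[DNS]-(ILVFYW)-[DENSTG]-[DNQGHRK]-(GP)-[LIVMC]-[DENQSTAGC]-x-x-[DE]

Matching is reimplemented here so that protein sequences can be scanned and
mapped onto their coding sequences without external services.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

from .formats import MotifRecord

logger = logging.getLogger("splicecode")

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")

EFHAND_LOOP_PATTERN = (
    "D-(W)-[DNS]-(ILVFYW)-[DENSTG]-[DNQGHRK]-(GP)-[LIVMC]-[DENQSTAGC]-x-x-[DE]"
)


class ConstraintKind(Enum):
    REQUIRED = "required"
    FORBIDDEN = "forbidden"
    ANY = "any"


@dataclass(frozen=True)
class Constraint:
    kind: ConstraintKind
    residues: frozenset[str] = frozenset()

    def matches(self, aa: str) -> bool:
        # Ambiguity letter X: conservative -- it never satisfies a REQUIRED
        # set, but cannot be shown to violate a FORBIDDEN set.
        if self.kind is ConstraintKind.ANY:
            return True
        if aa == "X":
            return self.kind is ConstraintKind.FORBIDDEN
        if self.kind is ConstraintKind.REQUIRED:
            return aa in self.residues
        return aa not in self.residues


@dataclass(frozen=True)
class ConsensusPattern:
    """Ordered 12-position constraint list for the EF-hand loop."""

    positions: tuple[Constraint, ...]

    def __post_init__(self) -> None:
        if len(self.positions) != 12:
            raise ValueError(
                f"consensus pattern must have 12 positions, got {len(self.positions)}"
            )

    def __len__(self) -> int:
        return len(self.positions)

    def matches(self, window: str) -> bool:
        if len(window) != len(self.positions):
            return False
        return all(c.matches(aa) for c, aa in zip(self.positions, window))


def parse_prosite_pattern(text: str) -> ConsensusPattern:
    """Parse a PROSITE-style ``-``-separated pattern into 12 constraints.

    Tokens: a single residue letter (required), ``[XY]`` (permitted set),
    ``(XY)`` (forbidden set), ``x`` (any).
    """
    tokens = [t.strip() for t in text.strip().split("-")]
    if len(tokens) != 12:
        raise ValueError(f"pattern must have 12 elements, got {len(tokens)}")
    constraints: list[Constraint] = []
    for token in tokens:
        if token == "x":
            constraints.append(Constraint(ConstraintKind.ANY))
        elif token.startswith("[") and token.endswith("]"):
            residues = frozenset(token[1:-1].upper())
            _check_residues(token, residues)
            constraints.append(Constraint(ConstraintKind.REQUIRED, residues))
        elif token.startswith("(") and token.endswith(")"):
            residues = frozenset(token[1:-1].upper())
            _check_residues(token, residues)
            constraints.append(Constraint(ConstraintKind.FORBIDDEN, residues))
        elif len(token) == 1 and token.upper() in AA_ALPHABET:
            constraints.append(
                Constraint(ConstraintKind.REQUIRED, frozenset(token.upper()))
            )
        else:
            raise ValueError(f"unknown pattern token {token!r}")
    return ConsensusPattern(tuple(constraints))


def _check_residues(token: str, residues: frozenset[str]) -> None:
    if not residues or not residues <= AA_ALPHABET:
        raise ValueError(f"invalid residue set in pattern token {token!r}")


def scan_protein(seq: str, pattern: ConsensusPattern) -> list[int]:
    """Return 1-based start positions of every 12-mer window matching
    ``pattern``, in left-to-right order.  Overlapping matches are all
    reported; an empty list means no match.
    """
    seq = seq.upper()
    width = len(pattern)
    return [
        i + 1
        for i in range(len(seq) - width + 1)
        if pattern.matches(seq[i : i + width])
    ]


def map_loop_to_cds(protein_match_start: int, cds_length: int,
                    loop_length_aa: int = 12) -> tuple[int, int]:
    """Map a 1-based protein match start to 1-based inclusive CDS nt bounds.

    ``loop_start = 3*(match_start-1) + 1``; the loop spans
    ``3*loop_length_aa`` nucleotides.
    """
    if protein_match_start < 1:
        raise ValueError("protein match start must be >= 1")
    loop_start = 3 * (protein_match_start - 1) + 1
    loop_end = loop_start + 3 * loop_length_aa - 1
    if cds_length < loop_end:
        raise ValueError(
            f"CDS of {cds_length} nt too short for loop ending at nt {loop_end}"
        )
    return loop_start, loop_end


def classify_motif(record: MotifRecord, loop_seq: str,
                   pattern: ConsensusPattern | None = None,
                   s100_genes: set[str] | None = None) -> str:
    """Assign one of CANONICAL / NONCANONICAL / S100 / NONEF.

    S100 membership is input metadata (a gene list): the S100 pseudoloop has
    14 residues and does not fit the 12-position consensus.  A record with
    curated Ca2+-contact positions but no EF-hand loop annotation is NONEF.
    """
    if s100_genes and record.gene_id in s100_genes:
        return "S100"
    if record.coordinating_cds_positions and record.loop_length_nt not in (36, 42):
        return "NONEF"
    if pattern is None:
        pattern = parse_prosite_pattern(EFHAND_LOOP_PATTERN)
    if len(loop_seq) == 12 and pattern.matches(loop_seq.upper()):
        return "CANONICAL"
    if record.loop_length_nt == 36:
        return "NONCANONICAL"
    return "NONEF"
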