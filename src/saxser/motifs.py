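"""Degenerate, variable-gap RNA-motif scanning.

Implements the two MEX3 recognition elements — e.g. the nematode-derived
element (A/G/U)(G/U)AGN0-8U(U/A/C)UA and the hMEX3C-style element
(A/G/U)(G/U)AGN0-8(A/G/U)(A/U)(A/U)(A/G/U) — as head + variable spacer
N_{a–b} + tail patterns, scanned exhaustively over a single 5′→3′ strand.
Every (start, gap length) combination is reported, including overlaps:
multiplicity of recognition sites is exactly what the scan is for.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd

from .model_io import RnaSequence

__all__ = [
    "MotifPattern",
    "MotifMatch",
    "CE_MEX3_ELEMENT",
    "HMEX3C_ELEMENT",
    "parse_pattern",
    "scan_sequence",
    "scan_report",
]

CE_MEX3_ELEMENT = "(A/G/U)(G/U)AGN0-8U(U/A/C)UA"
HMEX3C_ELEMENT = "(A/G/U)(G/U)AGN0-8(A/G/U)(A/U)(A/U)(A/G/U)"

_BASES = set("ACGU")


class MotifGrammarError(ValueError):
    pass


@dataclass(frozen=True)
class MotifPattern:
    """head · N_{gap_min–gap_max} · tail, each position a set of allowed bases."""

    head: tuple[frozenset[str], ...]
    gap_min: int
    gap_max: int
    tail: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        if not self.head:
            raise MotifGrammarError("pattern head must be non-empty")
        if not 0 <= self.gap_min <= self.gap_max:
            raise MotifGrammarError("need 0 <= gap_min <= gap_max")

    def canonical(self) -> str:
        def pos(s: frozenset[str]) -> str:
            bases = sorted(s)
            return bases[0] if len(bases) == 1 else "(" + "/".join(bases) + ")"

        head = "".join(pos(p) for p in self.head)
        tail = "".join(pos(p) for p in self.tail)
        if not self.tail and self.gap_min == 0 and self.gap_max == 0:
            return head
        return f"{head}N{self.gap_min}-{self.gap_max}{tail}"


@dataclass(frozen=True)
class MotifMatch:
    """A single placement, 1-based inclusive coordinates on the given strand."""

    start: int
    gap_len: int
    end: int
    matched_text: str


_TOKEN = re.compile(
    r"\(([ACGUT](?:/[ACGUT])*)\)"  # alternative set
    r"|N_?(\d+)[-–](\d+)_?"        # variable spacer, hyphen or en dash
    r"|([ACGUT])"                  # single base
)


def parse_pattern(text: str) -> MotifPattern:
    """Parse a motif string into a structured pattern.

    Grammar: single bases, parenthesized alternatives "(A/G/U)", and at
    most one variable spacer "N0-8" (underscore-delimited and en-dash
    variants accepted).  T is normalized to U.
    """
    cleaned = text.replace(" ", "").upper()
    positions: list[frozenset[str]] = []
    spacer: tuple[int, int] | None = None
    spacer_at: int | None = None
    idx = 0
    while idx < len(cleaned):
        m = _TOKEN.match(cleaned, idx)
        if m is None:
            raise MotifGrammarError(f"cannot parse pattern at ...{cleaned[idx:]!r}")
        if m.group(1) is not None:
            alts = frozenset(b.replace("T", "U") for b in m.group(1).split("/"))
            if not alts:
                raise MotifGrammarError("empty alternative set")
            positions.append(alts)
        elif m.group(2) is not None:
            if spacer is not None:
                raise MotifGrammarError("pattern may contain only one N spacer")
            spacer = (int(m.group(2)), int(m.group(3)))
            spacer_at = len(positions)
        else:
            positions.append(frozenset(m.group(4).replace("T", "U")))
        idx = m.end()
    if spacer is None:
        return MotifPattern(head=tuple(positions), gap_min=0, gap_max=0, tail=())
    if spacer_at == 0:
        raise MotifGrammarError("pattern head must be non-empty (spacer first)")
    return MotifPattern(
        head=tuple(positions[:spacer_at]),
        gap_min=spacer[0],
        gap_max=spacer[1],
        tail=tuple(positions[spacer_at:]),
    )


def _block_matches(bases: str, at: int, block: tuple[frozenset[str], ...]) -> bool:
    return all(bases[at + k] in allowed for k, allowed in enumerate(block))


def scan_sequence(seq: RnaSequence, pattern: MotifPattern) -> list[MotifMatch]:
    """All (start, gap length) placements of a pattern on one strand.

    Exhaustive enumeration, sorted by (start, gap_len); coordinates are
    1-based inclusive in the reported matches.
    """
    bases = seq.bases
    nh, nt = len(pattern.head), len(pattern.tail)
    matches: list[MotifMatch] = []
    for start0 in range(0, len(bases) - nh + 1):
        if not _block_matches(bases, start0, pattern.head):
            continue
        for gap in range(pattern.gap_min, pattern.gap_max + 1):
            tail_at = start0 + nh + gap
            if tail_at + nt > len(bases):
                break
            if _block_matches(bases, tail_at, pattern.tail):
                end0 = tail_at + nt  # exclusive
                matches.append(
                    MotifMatch(
                        start=start0 + 1,
                        gap_len=gap,
                        end=end0,
                        matched_text=bases[start0:end0],
                    )
                )
    return matches


def scan_report(
    seqs: list[RnaSequence], patterns: list[MotifPattern]
) -> pd.DataFrame:
    """Tabulate all matches per (sequence, pattern), overlaps included."""
    rows = []
    for seq in seqs:
        for pattern in patterns:
            for m in scan_sequence(seq, pattern):
                rows.append(
                    {
                        "seq_id": seq.id,
                        "pattern": pattern.canonical(),
                        "start": m.start,
                        "gap": m.gap_len,
                        "end": m.end,
                        "matched_text": m.matched_text,
                    }
                )
    return pd.DataFrame(
        rows, columns=["seq_id", "pattern", "start", "gap", "end", "matched_text"]
    )
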