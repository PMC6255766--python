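"""Tandem repeats, conserved motifs and stem-loops in control-region sequences.

The mitochondrial control region (D-loop) of softshell turtles carries
variable-number tandem repeats — e.g. (ATTAT)_8 and (TATTA)_20 — a conserved
CSB-1 motif 5'-GACATA-3', and a stable stem-loop marking the light-strand
replication origin.  This module detects all three with exact, deterministic
scans:

* tandem repeats by exhaustive period scan (default periods 1-60) with
  maximal extension, fractional final copies, primitive motifs only, and the
  smallest period winning for any locus;
* IUPAC-aware exact motif matching (overlapping hits included);
* hairpin candidates where a contiguous stem of Watson-Crick/wobble pairs
  (default 2-7 pairs) encloses a loop of 4-23 nt, deduplicated to the
  locally maximal stem per loop.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from math import ceil
from typing import List, Optional, Tuple

from Bio.Data.IUPACData import ambiguous_dna_values

from .genome_io import reverse_complement
from .trna_structure import MISMATCH, WATSON_CRICK, WOBBLE, classify_pair

__all__ = [
    "TandemRepeat",
    "StemLoopCandidate",
    "find_tandem_repeats",
    "scan_motif",
    "find_stem_loops",
    "is_primitive",
    "CSB1_MOTIF",
]

#: conserved sequence block 1 motif of trionychid control regions
CSB1_MOTIF = "GACATA"


@dataclass(frozen=True)
class TandemRepeat:
    """A maximal exact tandem repeat: ``motif`` tiled ``copies`` times.

    ``copies`` may be fractional (a partial final copy); coordinates are
    1-based inclusive on the scanned sequence.
    """

    motif: str
    period: int
    copies: float
    start: int
    end: int

    @property
    def span(self) -> int:
        return self.end - self.start + 1

    def tiled(self) -> str:
        """The repeat text reconstructed from motif and copies."""
        return (self.motif * ceil(self.copies))[: self.span]


@dataclass(frozen=True)
class StemLoopCandidate:
    """A hairpin: ``stem_len`` contiguous WC/wobble pairs around a loop."""

    stem_len: int
    loop_len: int
    start: int
    end: int
    pair_classes: Tuple[str, ...]

    @property
    def n_wobble(self) -> int:
        return sum(1 for c in self.pair_classes if c == WOBBLE)

    @property
    def n_watson_crick(self) -> int:
        return sum(1 for c in self.pair_classes if c == WATSON_CRICK)


def is_primitive(motif: str) -> bool:
    """True when the motif is not a whole power of a shorter string."""
    n = len(motif)
    for q in range(1, n):
        if n % q == 0 and motif == motif[:q] * (n // q):
            return False
    return True


def find_tandem_repeats(
    seq: str,
    min_period: int = 1,
    max_period: int = 60,
    min_copies: float = 2.0,
    max_mismatch_frac: float = 0.0,
) -> List[TandemRepeat]:
    """Exact tandem repeats by exhaustive period scan with maximal extension.

    For every period p, maximal runs of the self-match relation
    ``seq[i] == seq[i - p]`` define periodic spans; a span of length L
    reports ``copies = L / p``.  Non-primitive motifs are dropped (their
    smaller-period description is found separately), and overlapping reports
    are collapsed so that for any locus the longest span — and at equal span
    the smallest period — wins.

    Only exact repeats are supported (``max_mismatch_frac`` must be 0); the
    repeats reported for this family's control regions are exact, and the
    fractional-copy notation covers partial final copies.
    """
    if max_mismatch_frac != 0.0:
        raise ValueError("only exact repeats are supported (max_mismatch_frac=0)")
    seq = seq.upper()
    n = len(seq)
    candidates: List[TandemRepeat] = []
    for p in range(min_period, min(max_period, n // 2) + 1):
        i = p
        while i < n:
            if seq[i] != seq[i - p]:
                i += 1
                continue
            run_start = i
            while i < n and seq[i] == seq[i - p]:
                i += 1
            span = (i - run_start) + p  # matched run plus the leading copy
            copies = span / p
            start0 = run_start - p
            motif = seq[start0 : start0 + p]
            if copies >= min_copies and is_primitive(motif):
                candidates.append(
                    TandemRepeat(
                        motif=motif,
                        period=p,
                        copies=copies,
                        start=start0 + 1,
                        end=start0 + span,
                    )
                )
    # collapse: longest span first (smaller period breaks ties), drop any
    # candidate contained in a kept span
    candidates.sort(key=lambda r: (-r.span, r.period, r.start))
    kept: List[TandemRepeat] = []
    for cand in candidates:
        if any(k.start <= cand.start and cand.end <= k.end for k in kept):
            continue
        kept.append(cand)
    kept.sort(key=lambda r: r.start)
    return kept


def _iupac_regex(motif: str) -> str:
    parts = []
    for ch in motif.upper():
        values = ambiguous_dna_values.get(ch)
        if values is None:
            raise ValueError(f"not an IUPAC DNA code: {ch!r}")
        parts.append(ch if len(values) == 1 else f"[{values}]")
    return "".join(parts)


def scan_motif(seq: str, motif: str, search_revcomp: bool = False) -> List[int]:
    """1-based start positions of all exact (IUPAC-aware) motif matches.

    With ``search_revcomp`` the reverse complement of the motif is scanned
    too and its hit positions (on the given strand, leftmost base) merged in.
    Overlapping occurrences are all reported.
    """
    if len(motif) < 4:
        raise ValueError("motif must be at least 4 nt")
    seq = seq.upper()
    patterns = [_iupac_regex(motif)]
    if search_revcomp:
        patterns.append(_iupac_regex(reverse_complement(motif)))
    hits = set()
    for pat in patterns:
        for m in re.finditer(f"(?=({pat}))", seq):
            hits.add(m.start() + 1)
    return sorted(hits)


def find_stem_loops(
    seq: str,
    stem_bounds: Tuple[int, int] = (2, 7),
    loop_bounds: Tuple[int, int] = (4, 23),
) -> List[StemLoopCandidate]:
    """Hairpin candidates ranked by stem length, then fewest non-WC pairs.

    A candidate is a window ``stem + loop + stem'`` where every stem pair
    (outermost-first) is Watson-Crick or wobble.  For each loop placement
    only the longest valid stem is kept (the locally maximal hairpin).
    """
    seq = seq.upper()
    n = len(seq)
    smin, smax = stem_bounds
    lmin, lmax = loop_bounds
    out: List[StemLoopCandidate] = []
    for loop_start in range(n):
        for loop_len in range(lmin, lmax + 1):
            loop_end = loop_start + loop_len  # exclusive
            if loop_end > n:
                break
            # grow the stem outward from the loop until a mismatch/bounds
            classes_in_first = []
            s = 0
            while s < smax and loop_start - s - 1 >= 0 and loop_end + s < n:
                cls = classify_pair(seq[loop_start - s - 1], seq[loop_end + s])
                if cls == MISMATCH:
                    break
                classes_in_first.append(cls)
                s += 1
            if s >= smin:
                out.append(
                    StemLoopCandidate(
                        stem_len=s,
                        loop_len=loop_len,
                        start=loop_start - s + 1,
                        end=loop_end + s,
                        pair_classes=tuple(reversed(classes_in_first)),
                    )
                )
    out.sort(key=lambda c: (-c.stem_len, len(c.pair_classes) - c.n_watson_crick, c.start))
    return out
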