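"""Constrained cloverleaf folding of mitochondrial tRNA genes.

A tRNA sequence (DNA register, 55-95 nt) is decomposed into the classic four
arms by exhaustive search over admissible arm geometries:

    acceptor stem        6-8 pairs
    DHU arm              absent, or 3-4 pairs with a 4-12 nt loop
    anticodon arm        4-6 pairs with a fixed 7 nt loop
    variable loop        3-23 nt
    T(psi)C arm          4-5 pairs with a 4-9 nt loop

The decomposition tiles the input exactly:

    acc5 . dhu5 . dhuloop . dhu3 . ac5 . acloop(7) . ac3 . varloop
         . t5 . tloop . t3 . acc3

Each candidate geometry is scored 2*(Watson-Crick) + 1*(wobble, G.T in DNA
register) - 1*(mismatch) over all stem pairs, and the best admissible
geometry wins.  Ties prefer arm lengths closest to the canonical (7,4,5,5),
then the smallest variable loop, then lexicographic geometry order, making
the fold fully deterministic.  A geometry is admissible when no stem is
mostly unpaired (at most 1 mismatch per stem, 2 in the longer acceptor
stem); if no admissible geometry exists the sequence is reported unfoldable
(``None``) rather than forced into a cloverleaf.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

__all__ = [
    "WATSON_CRICK",
    "WOBBLE",
    "MISMATCH",
    "classify_pair",
    "Arm",
    "CloverleafStructure",
    "FoldBounds",
    "fold_cloverleaf",
    "classify_pairs",
    "compare_across_species",
    "SpeciesComparison",
    "ARM_NAMES",
]

WATSON_CRICK = "watson_crick"
WOBBLE = "wobble"
MISMATCH = "mismatch"

ARM_NAMES = ("acceptor", "dhu", "anticodon", "t_arm")

_WC_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_WOBBLE_PAIRS = {("G", "T"), ("T", "G")}


def classify_pair(b5: str, b3: str) -> str:
    """Watson-Crick / wobble (G.T) / mismatch classification of one stem pair."""
    if (b5, b3) in _WC_PAIRS:
        return WATSON_CRICK
    if (b5, b3) in _WOBBLE_PAIRS:
        return WOBBLE
    return MISMATCH


@dataclass(frozen=True)
class Arm:
    """A stem-loop arm: 5' stem strand, loop, 3' stem strand."""

    stem5: str
    loop: str
    stem3: str

    def __post_init__(self):
        if len(self.stem5) != len(self.stem3):
            raise ValueError("stem strands must have equal length")

    @property
    def n_pairs(self) -> int:
        return len(self.stem5)

    @property
    def pairs(self) -> Tuple[Tuple[str, str], ...]:
        """Base pairs outermost-first: stem5[i] with stem3[-1-i]."""
        return tuple(zip(self.stem5, reversed(self.stem3)))

    def flatten(self) -> str:
        return self.stem5 + self.loop + self.stem3


@dataclass(frozen=True)
class CloverleafStructure:
    """A four-arm cloverleaf decomposition of a tRNA sequence."""

    acceptor5: str
    dhu: Optional[Arm]
    anticodon_arm: Arm
    variable_loop: str
    t_arm: Arm
    acceptor3: str

    @property
    def acceptor_pairs(self) -> Tuple[Tuple[str, str], ...]:
        return tuple(zip(self.acceptor5, reversed(self.acceptor3)))

    @property
    def anticodon(self) -> str:
        """Center 3 nt of the 7-nt anticodon loop."""
        return self.anticodon_arm.loop[2:5]

    @property
    def arm_lengths(self) -> Tuple[int, int, int, int]:
        """(acceptor, dhu, anticodon, t) stem pair counts; dhu 0 when absent."""
        return (
            len(self.acceptor5),
            self.dhu.n_pairs if self.dhu else 0,
            self.anticodon_arm.n_pairs,
            self.t_arm.n_pairs,
        )

    def arm_pairs(self) -> Dict[str, Tuple[Tuple[str, str], ...]]:
        return {
            "acceptor": self.acceptor_pairs,
            "dhu": self.dhu.pairs if self.dhu else (),
            "anticodon": self.anticodon_arm.pairs,
            "t_arm": self.t_arm.pairs,
        }

    def flatten(self) -> str:
        """Reconstruct the input sequence from the decomposition."""
        dhu = self.dhu.flatten() if self.dhu else ""
        return (
            self.acceptor5
            + dhu
            + self.anticodon_arm.flatten()
            + self.variable_loop
            + self.t_arm.flatten()
            + self.acceptor3
        )

    @property
    def score(self) -> int:
        return _score_pairs(
            p for pairs in self.arm_pairs().values() for p in pairs
        )

    @property
    def pair_class_profile(self) -> Tuple[Tuple[str, ...], ...]:
        """Per-arm tuple of pair classes (outermost-first); comparison key."""
        return tuple(
            tuple(classify_pair(*p) for p in self.arm_pairs()[arm])
            for arm in ARM_NAMES
        )


def _score_pairs(pairs: Iterable[Tuple[str, str]]) -> int:
    score = 0
    for b5, b3 in pairs:
        cls = classify_pair(b5, b3)
        score += 2 if cls == WATSON_CRICK else (1 if cls == WOBBLE else -1)
    return score


def _stem_mismatches(pairs: Iterable[Tuple[str, str]]) -> int:
    return sum(1 for p in pairs if classify_pair(*p) == MISMATCH)


@dataclass(frozen=True)
class FoldBounds:
    """Arm-geometry search space of :func:`fold_cloverleaf`."""

    acceptor: Tuple[int, int] = (6, 8)
    dhu: Tuple[int, int] = (3, 4)          # 0 (absent) always admissible too
    dhu_loop: Tuple[int, int] = (4, 12)
    anticodon: Tuple[int, int] = (4, 6)
    anticodon_loop: int = 7
    variable_loop: Tuple[int, int] = (3, 23)
    t_stem: Tuple[int, int] = (4, 5)
    t_loop: Tuple[int, int] = (4, 9)
    min_length: int = 55
    max_length: int = 95
    max_mismatch_per_stem: int = 1
    max_mismatch_acceptor: int = 2

CANONICAL_ARMS = (7, 4, 5, 5)


def _geometries(n: int, bounds: FoldBounds):
    """All (a, d, dl, c, v, t, tl) tuples tiling a length-n sequence."""
    for a in range(bounds.acceptor[0], bounds.acceptor[1] + 1):
        dhu_options = [(0, 0)] + [
            (d, dl)
            for d in range(bounds.dhu[0], bounds.dhu[1] + 1)
            for dl in range(bounds.dhu_loop[0], bounds.dhu_loop[1] + 1)
        ]
        for d, dl in dhu_options:
            for c in range(bounds.anticodon[0], bounds.anticodon[1] + 1):
                for t in range(bounds.t_stem[0], bounds.t_stem[1] + 1):
                    for tl in range(bounds.t_loop[0], bounds.t_loop[1] + 1):
                        v = n - (2 * a + 2 * d + dl + 2 * c
                                 + bounds.anticodon_loop + 2 * t + tl)
                        if bounds.variable_loop[0] <= v <= bounds.variable_loop[1]:
                            yield a, d, dl, c, v, t, tl


def _build(seq: str, geom: Tuple[int, ...], bounds: FoldBounds) -> CloverleafStructure:
    a, d, dl, c, v, t, tl = geom
    i = 0
    acc5 = seq[i : i + a]; i += a
    dhu = None
    if d:
        dhu = Arm(seq[i : i + d], seq[i + d : i + d + dl], seq[i + d + dl : i + 2 * d + dl])
        i += 2 * d + dl
    acl = bounds.anticodon_loop
    ac = Arm(seq[i : i + c], seq[i + c : i + c + acl], seq[i + c + acl : i + 2 * c + acl])
    i += 2 * c + acl
    var = seq[i : i + v]; i += v
    t_arm = Arm(seq[i : i + t], seq[i + t : i + t + tl], seq[i + t + tl : i + 2 * t + tl])
    i += 2 * t + tl
    acc3 = seq[i:]
    return CloverleafStructure(acc5, dhu, ac, var, t_arm, acc3)


def fold_cloverleaf(
    seq: str,
    anticodon_hint: Optional[str] = None,
    bounds: FoldBounds = FoldBounds(),
) -> Optional[CloverleafStructure]:
    """Best-scoring admissible cloverleaf, or ``None`` when unfoldable.

    ``anticodon_hint`` (a 3-mer, DNA register) restricts the search to
    geometries that place the hint at the center of the anticodon loop.
    """
    seq = seq.upper()
    if not (bounds.min_length <= len(seq) <= bounds.max_length):
        raise ValueError(
            f"tRNA length {len(seq)} outside [{bounds.min_length}, {bounds.max_length}]"
        )
    best = None
    best_key = None
    for geom in _geometries(len(seq), bounds):
        structure = _build(seq, geom, bounds)
        if anticodon_hint and structure.anticodon != anticodon_hint.upper():
            continue
        arm_pairs = structure.arm_pairs()
        if _stem_mismatches(arm_pairs["acceptor"]) > bounds.max_mismatch_acceptor:
            continue
        if any(
            _stem_mismatches(arm_pairs[arm]) > bounds.max_mismatch_per_stem
            for arm in ("dhu", "anticodon", "t_arm")
        ):
            continue
        a, d, dl, c, v, t, tl = geom
        canon_dist = sum(
            abs(x - y) for x, y in zip((a, d, c, t), CANONICAL_ARMS)
        )
        # maximize score; then prefer canonical arms, small variable loop
        key = (-structure.score, canon_dist, v, geom)
        if best_key is None or key < best_key:
            best, best_key = structure, key
    return best


def classify_pairs(structure: CloverleafStructure) -> Dict[str, Dict[str, int]]:
    """Per-arm counts of Watson-Crick / wobble / mismatch pairs."""
    out = {}
    for arm, pairs in structure.arm_pairs().items():
        counts = {WATSON_CRICK: 0, WOBBLE: 0, MISMATCH: 0}
        for p in pairs:
            counts[classify_pair(*p)] += 1
        out[arm] = counts
    return out


@dataclass(frozen=True)
class SpeciesComparison:
    """Cross-species variability of one tRNA's folded structure."""

    n_species: int
    anticodon: str
    arm_length_ranges: Dict[str, Tuple[int, int]]
    variable_loop_range: Tuple[int, int]
    pooled_pair_classes: Dict[str, Dict[str, int]]
    n_sharing_modal_profile: int
    all_identical: bool
    total_non_wc: int
    high_non_wc: bool  # >= 10 wobble+mismatch pairs pooled across species


def compare_across_species(
    structures: Dict[str, CloverleafStructure],
    high_non_wc_threshold: int = 10,
) -> SpeciesComparison:
    """Summarize one tRNA's structural variability across species.

    All structures must carry the same anticodon (the tRNA's identity);
    mixing different tRNAs is an error.  The "profile" of a structure is its
    arm-length tuple together with the per-arm pair-class strings, so
    ``all_identical`` means every species folds the tRNA the same way.
    """
    if len(structures) < 2:
        raise ValueError("need structures from at least 2 species")
    anticodons = {s.anticodon for s in structures.values()}
    if len(anticodons) != 1:
        raise ValueError(f"mixed tRNA identities (anticodons {sorted(anticodons)})")

    folds = list(structures.values())
    arm_ranges = {}
    for i, arm in enumerate(ARM_NAMES):
        lengths = [f.arm_lengths[i] for f in folds]
        arm_ranges[arm] = (min(lengths), max(lengths))
    vl = [len(f.variable_loop) for f in folds]

    pooled = {arm: {WATSON_CRICK: 0, WOBBLE: 0, MISMATCH: 0} for arm in ARM_NAMES}
    for f in folds:
        for arm, counts in classify_pairs(f).items():
            for cls, n in counts.items():
                pooled[arm][cls] += n

    profiles = [(f.arm_lengths, f.pair_class_profile) for f in folds]
    modal = max(set(profiles), key=profiles.count)
    n_modal = profiles.count(modal)

    total_non_wc = sum(
        pooled[arm][WOBBLE] + pooled[arm][MISMATCH] for arm in ARM_NAMES
    )
    return SpeciesComparison(
        n_species=len(folds),
        anticodon=anticodons.pop(),
        arm_length_ranges=arm_ranges,
        variable_loop_range=(min(vl), max(vl)),
        pooled_pair_classes=pooled,
        n_sharing_modal_profile=n_modal,
        all_identical=n_modal == len(folds),
        total_non_wc=total_non_wc,
        high_non_wc=total_non_wc >= high_non_wc_threshold,
    )
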