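"""Base composition, A+T content, and strand-asymmetry skews.

AT skew = (A - T)/(A + T) and GC skew = (G - C)/(G + C), computed on base
counts of the analyzed string.  Mitochondrial strand conventions follow the
comparative-mitogenomics practice: protein-coding genes are pooled 5'->3'
(light-strand genes reverse-complemented first), while tRNA and rRNA genes
are pooled in their native heavy-strand register of the genome text.

Ambiguous bases are excluded from the skew denominators, and A+T% is
computed over unambiguous bases only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Union

from .genome_io import (
    MitoGenomeRecord,
    NucleotideSequence,
    extract_feature_sequence,
    extract_native_sequence,
)

__all__ = ["CompositionStats", "compute_composition", "partition_composition", "PARTITIONS"]

PARTITIONS = ("genome", "PCG", "tRNA", "rRNA", "CR")


@dataclass(frozen=True)
class CompositionStats:
    """A/C/G/T/other counts with derived A+T%, AT skew and GC skew."""

    a: int
    c: int
    g: int
    t: int
    other: int

    @property
    def length(self) -> int:
        return self.a + self.c + self.g + self.t + self.other

    @property
    def unambiguous(self) -> int:
        return self.a + self.c + self.g + self.t

    @property
    def at_percent(self) -> Optional[float]:
        n = self.unambiguous
        return 100.0 * (self.a + self.t) / n if n else None

    @property
    def gc_percent(self) -> Optional[float]:
        n = self.unambiguous
        return 100.0 * (self.g + self.c) / n if n else None

    @property
    def at_skew(self) -> Optional[float]:
        at = self.a + self.t
        return (self.a - self.t) / at if at else None

    @property
    def gc_skew(self) -> Optional[float]:
        gc = self.g + self.c
        return (self.g - self.c) / gc if gc else None

    def __add__(self, other: "CompositionStats") -> "CompositionStats":
        return CompositionStats(
            self.a + other.a,
            self.c + other.c,
            self.g + other.g,
            self.t + other.t,
            self.other + other.other,
        )


def compute_composition(seq: Union[str, NucleotideSequence]) -> CompositionStats:
    """Count bases and derive composition statistics; empty input is an error."""
    residues = seq.residues if isinstance(seq, NucleotideSequence) else seq.upper()
    if not residues:
        raise ValueError("cannot compute composition of an empty sequence")
    a = residues.count("A")
    c = residues.count("C")
    g = residues.count("G")
    t = residues.count("T")
    return CompositionStats(a=a, c=c, g=g, t=t, other=len(residues) - a - c - g - t)


def partition_composition(record: MitoGenomeRecord) -> Dict[str, CompositionStats]:
    """Composition per partition: genome, PCG, tRNA, rRNA, CR.

    The PCG pool concatenates oriented CDS (L-strand genes reverse-
    complemented); tRNA and rRNA pools use the native genome text; the CR is
    taken as annotated.  Feature sequences are pooled as extracted, so bases
    inside gene overlaps contribute to every feature that covers them.
    """
    if not record.has_sequence:
        raise ValueError(f"record {record.species!r} has no sequence")
    pools: Dict[str, str] = {p: "" for p in PARTITIONS}
    pools["genome"] = record.sequence.residues
    for feat in record.features:
        if feat.category == "PCG":
            pools["PCG"] += extract_feature_sequence(record, feat.name).residues
        elif feat.category in ("tRNA", "rRNA", "CR"):
            pools[feat.category] += extract_native_sequence(record, feat.name)
    out = {}
    for part, pooled in pools.items():
        if pooled:
            out[part] = compute_composition(pooled)
    return out
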