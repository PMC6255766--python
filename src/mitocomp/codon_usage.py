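"""Codon counting and relative synonymous codon usage (RSCU).

Fixed to the vertebrate mitochondrial genetic code (NCBI transl_table 2:
AGA/AGG are stops, ATA is Met, TGA is Trp).  RSCU for codon j of amino acid
i with n_i synonymous codons is

    RSCU_ij = x_ij / ((1/n_i) * sum_j x_ij),

so within each amino-acid family the RSCU values sum to the family size and
uniform usage gives RSCU 1 everywhere.  Stop codons are tallied separately
and excluded from RSCU, matching the convention of the common codon-usage
tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional

import pandas as pd
from Bio.Data import CodonTable

__all__ = [
    "VERTEBRATE_MITO_TABLE_ID",
    "genetic_code",
    "translate_codon",
    "CodonCounts",
    "RscuTable",
    "count_codons",
    "compute_rscu",
]

VERTEBRATE_MITO_TABLE_ID = 2

_BASES = "TCAG"
ALL_CODONS = tuple(a + b + c for a in _BASES for b in _BASES for c in _BASES)


def genetic_code(code_id: int = VERTEBRATE_MITO_TABLE_ID) -> CodonTable.CodonTable:
    """The Biopython codon table for ``code_id`` (unambiguous DNA)."""
    return CodonTable.unambiguous_dna_by_id[code_id]


def translate_codon(codon: str, code_id: int = VERTEBRATE_MITO_TABLE_ID) -> str:
    """One-letter amino acid, or ``*`` for a stop codon."""
    table = genetic_code(code_id)
    return "*" if codon in table.stop_codons else table.forward_table[codon]


def synonymous_families(code_id: int = VERTEBRATE_MITO_TABLE_ID) -> Dict[str, List[str]]:
    """Mapping amino acid -> its codons (stops excluded), in TCAG order."""
    table = genetic_code(code_id)
    fams: Dict[str, List[str]] = {}
    for codon in ALL_CODONS:
        if codon in table.stop_codons:
            continue
        fams.setdefault(table.forward_table[codon], []).append(codon)
    return fams


@dataclass
class CodonCounts:
    """Codon tallies over a set of oriented CDS under one genetic code."""

    counts: Dict[str, int]
    stop_counts: Dict[str, int] = field(default_factory=dict)
    ambiguous_skipped: int = 0
    code_id: int = VERTEBRATE_MITO_TABLE_ID

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def __add__(self, other: "CodonCounts") -> "CodonCounts":
        if self.code_id != other.code_id:
            raise ValueError("cannot add counts under different genetic codes")
        merged = dict(self.counts)
        for k, v in other.counts.items():
            merged[k] = merged.get(k, 0) + v
        stops = dict(self.stop_counts)
        for k, v in other.stop_counts.items():
            stops[k] = stops.get(k, 0) + v
        return CodonCounts(
            merged, stops, self.ambiguous_skipped + other.ambiguous_skipped, self.code_id
        )


def count_codons(
    cds_list: Iterable[str], code_id: int = VERTEBRATE_MITO_TABLE_ID
) -> CodonCounts:
    """Count codons over 5'->3' CDS strings.

    The trailing 1-2 nt of a CDS whose length is not a multiple of 3 (an
    incomplete stop codon) are dropped.  Stop codons are counted apart from
    sense codons; codons containing IUPAC ambiguity codes are skipped with a
    tally; anything outside the IUPAC alphabet is an error.
    """
    table = genetic_code(code_id)
    stop_set = set(table.stop_codons)
    counts = {c: 0 for c in ALL_CODONS}
    stops: Dict[str, int] = {}
    skipped = 0
    iupac = set("ACGTNRYSWKMBDHV")
    for cds in cds_list:
        cds = cds.upper()
        bad = set(cds) - iupac
        if bad:
            raise ValueError(f"CDS contains non-IUPAC characters: {sorted(bad)}")
        usable = len(cds) - (len(cds) % 3)
        for i in range(0, usable, 3):
            codon = cds[i : i + 3]
            if set(codon) - set("ACGT"):
                skipped += 1
            elif codon in stop_set:
                stops[codon] = stops.get(codon, 0) + 1
            else:
                counts[codon] += 1
    return CodonCounts(counts=counts, stop_counts=stops,
                       ambiguous_skipped=skipped, code_id=code_id)


@dataclass
class RscuTable:
    """Per-codon RSCU with amino-acid grouping; ``None`` for unused families."""

    rscu: Dict[str, Optional[float]]
    amino_acid: Dict[str, str]
    counts: Dict[str, int]
    code_id: int = VERTEBRATE_MITO_TABLE_ID

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "codon": c,
                "amino_acid": self.amino_acid[c],
                "count": self.counts[c],
                "rscu": self.rscu[c],
            }
            for c in self.rscu
        ]
        return (
            pd.DataFrame(rows)
            .sort_values(["amino_acid", "codon"])
            .reset_index(drop=True)
        )


def compute_rscu(counts: CodonCounts) -> RscuTable:
    """RSCU per sense codon; families with zero total get ``None`` throughout."""
    fams = synonymous_families(counts.code_id)
    rscu: Dict[str, Optional[float]] = {}
    aa_of: Dict[str, str] = {}
    for aa, codons in fams.items():
        total = sum(counts.counts.get(c, 0) for c in codons)
        for c in codons:
            aa_of[c] = aa
            if total == 0:
                rscu[c] = None
            else:
                rscu[c] = counts.counts.get(c, 0) / (total / len(codons))
    return RscuTable(
        rscu=rscu,
        amino_acid=aa_of,
        counts={c: counts.counts.get(c, 0) for c in aa_of},
        code_id=counts.code_id,
    )
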