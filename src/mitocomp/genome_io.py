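"""Reading, writing and circular-coordinate handling of annotated mitogenomes.

The in-memory containers mirror a typical vertebrate mitochondrial annotation:
an ordered list of features (13 protein-coding genes, 22 tRNAs, 2 rRNAs and one
control region) on a closed-circular molecule.  Coordinates are 1-based and
inclusive throughout, matching the convention of published gene tables; a
feature that spans the origin of the circle is stored as two segments (e.g.
``(15565, 16796), (1, 58)``), never with ``end < start``.

Two input routes are supported: a plain tab-separated feature table (the
primary fixture carrier, requiring no sequence) and GenBank flat files parsed
with Biopython, from which the sequence is attached when present.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence, Tuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

__all__ = [
    "NucleotideSequence",
    "FeatureRecord",
    "MitoGenomeRecord",
    "read_feature_table",
    "write_feature_table",
    "read_genbank",
    "write_genbank",
    "read_fasta",
    "write_fasta",
    "extract_feature_sequence",
    "extract_native_sequence",
    "reverse_complement",
    "CATEGORIES",
]

CATEGORIES = ("PCG", "tRNA", "rRNA", "CR")

_IUPAC_DNA = set("ACGTNRYSWKMBDHV")
_COMPLEMENT = str.maketrans(
    "ACGTNRYSWKMBDHV",
    "TGCANYRSWMKVHDB",
)


def reverse_complement(seq: str) -> str:
    """Reverse complement of an IUPAC DNA string (ambiguity-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeIOError(ValueError):
    """Malformed annotation input (bad coordinates, duplicate names...)."""


@dataclass(frozen=True)
class NucleotideSequence:
    """An upper-case IUPAC DNA string with circularity and declared length."""

    residues: str
    circular: bool = True
    declared_length: Optional[int] = None

    def __post_init__(self):
        res = self.residues.upper()
        object.__setattr__(self, "residues", res)
        bad = set(res) - _IUPAC_DNA
        if bad:
            raise GenomeIOError(f"non-IUPAC characters in sequence: {sorted(bad)}")
        if self.declared_length is None:
            object.__setattr__(self, "declared_length", len(res))
        elif res and len(res) != self.declared_length:
            raise GenomeIOError(
                f"sequence length {len(res)} != declared length {self.declared_length}"
            )

    def __len__(self) -> int:
        return self.declared_length


@dataclass(frozen=True)
class FeatureRecord:
    """One annotated gene/region on the circle.

    ``segments`` is an ordered tuple of 1-based inclusive ``(start, end)``
    pairs; more than one segment only for origin-spanning features.  Strand is
    ``"H"`` (heavy, the published ``+``) or ``"L"`` (light, ``-``).  The
    ``annotated_*`` fields carry values printed in a source table verbatim;
    they are never trusted for arithmetic.
    """

    name: str
    category: str
    strand: str
    segments: Tuple[Tuple[int, int], ...]
    anticodon: Optional[str] = None
    annotated_start_codon: Optional[str] = None
    annotated_stop_codon: Optional[str] = None
    annotated_size: Optional[int] = None

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise GenomeIOError(f"{self.name}: unknown category {self.category!r}")
        if self.strand not in ("H", "L"):
            raise GenomeIOError(f"{self.name}: strand must be 'H' or 'L'")
        if not self.segments:
            raise GenomeIOError(f"{self.name}: no segments")
        for s, e in self.segments:
            if not (1 <= s <= e):
                raise GenomeIOError(
                    f"{self.name}: invalid segment ({s}, {e}); need 1 <= start <= end"
                )
        if self.anticodon is not None and self.category != "tRNA":
            raise GenomeIOError(f"{self.name}: anticodon on non-tRNA feature")

    @property
    def length(self) -> int:
        """Feature length in bp, circular-aware (sum over segments)."""
        return sum(e - s + 1 for s, e in self.segments)

    @property
    def first_start(self) -> int:
        return self.segments[0][0]

    @property
    def last_end(self) -> int:
        """End coordinate of the final segment (the linearized end)."""
        return self.segments[-1][1]

    @property
    def wraps_origin(self) -> bool:
        return len(self.segments) > 1


@dataclass
class MitoGenomeRecord:
    """An annotated (optionally sequenced) circular mitochondrial genome."""

    species: str
    features: list = field(default_factory=list)
    sequence: Optional[NucleotideSequence] = None
    accession: Optional[str] = None
    genome_length: Optional[int] = None

    def __post_init__(self):
        if self.genome_length is None and self.sequence is not None:
            self.genome_length = len(self.sequence)
        names = [f.name for f in self.features]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise GenomeIOError(f"duplicate feature names: {dupes}")
        if self.genome_length is not None:
            for f in self.features:
                for s, e in f.segments:
                    if e > self.genome_length:
                        raise GenomeIOError(
                            f"{f.name}: segment ({s}, {e}) beyond genome "
                            f"length {self.genome_length}"
                        )
        self.features = sorted(self.features, key=lambda f: (f.first_start, f.name))

    def feature(self, name: str) -> FeatureRecord:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(f"no feature named {name!r}")

    def by_category(self, category: str) -> list:
        return [f for f in self.features if f.category == category]

    @property
    def has_sequence(self) -> bool:
        return self.sequence is not None and bool(self.sequence.residues)


# ---------------------------------------------------------------------------
# feature-table TSV dialect
# ---------------------------------------------------------------------------

_TSV_REQUIRED = ["name", "category", "strand", "start", "end"]
_STRAND_ALIASES = {"H": "H", "+": "H", "L": "L", "-": "L", "−": "L"}


def read_feature_table(
    path, genome_length: int, species: str = "", accession: Optional[str] = None
) -> MitoGenomeRecord:
    """Read the tab-separated feature-coordinate table dialect.

    Required columns: ``name, category, strand, start, end``; optional:
    ``start2, end2`` (second segment of an origin-spanning feature),
    ``anticodon``, ``start_codon``, ``stop_codon``, ``size`` (printed size,
    carried as annotation only).  Missing values are ``.`` or empty.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#", skip_blank_lines=True)
    if df.empty and not set(_TSV_REQUIRED) <= set(df.columns):
        return MitoGenomeRecord(
            species=species, features=[], genome_length=genome_length, accession=accession
        )
    missing = [c for c in _TSV_REQUIRED if c not in df.columns]
    if missing:
        raise GenomeIOError(f"feature table missing columns: {missing}")

    def _get(row, col):
        v = row.get(col)
        if v is None or (isinstance(v, float) and pd.isna(v)) or v in (".", ""):
            return None
        return str(v).strip()

    features = []
    for idx, row in df.iterrows():
        rowno = idx + 2  # header is line 1
        name = _get(row, "name")
        try:
            strand = _STRAND_ALIASES[_get(row, "strand")]
            start, end = int(_get(row, "start")), int(_get(row, "end"))
            segments = [(start, end)]
            s2, e2 = _get(row, "start2"), _get(row, "end2")
            if (s2 is None) != (e2 is None):
                raise GenomeIOError("start2/end2 must be given together")
            if s2 is not None:
                segments.append((int(s2), int(e2)))
            size = _get(row, "size")
            feat = FeatureRecord(
                name=name,
                category=_get(row, "category"),
                strand=strand,
                segments=tuple(segments),
                anticodon=_get(row, "anticodon"),
                annotated_start_codon=_get(row, "start_codon"),
                annotated_stop_codon=_get(row, "stop_codon"),
                annotated_size=int(size) if size is not None else None,
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise GenomeIOError(f"row {rowno} ({name!r}): {exc}") from exc
        for s, e in feat.segments:
            if e > genome_length:
                raise GenomeIOError(
                    f"row {rowno} ({name!r}): coordinate {e} beyond genome "
                    f"length {genome_length}"
                )
        features.append(feat)
    return MitoGenomeRecord(
        species=species, features=features, genome_length=genome_length,
        accession=accession,
    )


def write_feature_table(record: MitoGenomeRecord, path) -> None:
    """Write the TSV dialect read by :func:`read_feature_table`."""
    rows = []
    for f in record.features:
        (s1, e1) = f.segments[0]
        (s2, e2) = f.segments[1] if f.wraps_origin else (None, None)
        rows.append(
            {
                "name": f.name,
                "category": f.category,
                "strand": f.strand,
                "start": s1,
                "end": e1,
                "start2": s2 if s2 is not None else ".",
                "end2": e2 if e2 is not None else ".",
                "anticodon": f.anticodon or ".",
                "start_codon": f.annotated_start_codon or ".",
                "stop_codon": f.annotated_stop_codon or ".",
                "size": f.annotated_size if f.annotated_size is not None else ".",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GenBank / FASTA via Biopython
# ---------------------------------------------------------------------------

_GB_CATEGORY = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA", "D-loop": "CR"}


def read_genbank(path) -> MitoGenomeRecord:
    """Read an annotated mitogenome from a GenBank flat file.

    ``complement(...)`` locations map to strand L; ``join(a..L, 1..b)``
    locations map to two segments.  A file without an ORIGIN block yields a
    record whose ``sequence`` is ``None`` (an explicit no-sequence state).
    """
    seqrec = SeqIO.read(str(path), "genbank")
    seq_str = str(seqrec.seq).upper()
    has_seq = bool(seq_str) and set(seq_str) != {"N"}
    genome_length = len(seqrec.seq) if len(seqrec.seq) else None

    features = []
    seen = set()
    for gb_feat in seqrec.features:
        if gb_feat.type not in _GB_CATEGORY:
            continue
        category = _GB_CATEGORY[gb_feat.type]
        quals = gb_feat.qualifiers
        name = (quals.get("gene") or quals.get("product") or quals.get("note") or ["?"])[0]
        if name in seen:
            continue  # gene + CDS pairs refer to the same locus
        seen.add(name)
        strand = "L" if gb_feat.location.strand == -1 else "H"
        # join order in the file is biological order: (high..L, 1..b) for an
        # origin-spanning feature; keep it.
        segments = tuple(
            (int(p.start) + 1, int(p.end)) for p in gb_feat.location.parts
        )
        anticodon = None
        if category == "tRNA" and "anticodon" in quals:
            anticodon = quals["anticodon"][0].upper()
        features.append(
            FeatureRecord(
                name=name,
                category=category,
                strand=strand,
                segments=segments,
                anticodon=anticodon,
                annotated_start_codon=(quals.get("codon_start_note") or [None])[0],
                annotated_stop_codon=(quals.get("stop_codon_note") or [None])[0],
            )
        )
    return MitoGenomeRecord(
        species=seqrec.annotations.get("organism", seqrec.id),
        features=features,
        sequence=NucleotideSequence(seq_str, circular=True) if has_seq else None,
        accession=seqrec.id if seqrec.id != "<unknown id>" else None,
        genome_length=genome_length,
    )


def write_genbank(record: MitoGenomeRecord, path) -> None:
    """Write a GenBank flat file (deterministic output for a given record)."""
    if not record.has_sequence:
        raise GenomeIOError("cannot write GenBank without a sequence")
    seqrec = SeqRecord(
        Seq(record.sequence.residues),
        id=record.accession or "SYNTH0001",
        name=(record.accession or "SYNTH0001").split(".")[0][:16],
        description=f"{record.species} mitochondrion, complete genome",
    )
    seqrec.annotations["molecule_type"] = "DNA"
    seqrec.annotations["topology"] = "circular"
    seqrec.annotations["organism"] = record.species
    seqrec.annotations["date"] = "01-JAN-2020"  # fixed: byte-identical output
    gb_type = {v: k for k, v in _GB_CATEGORY.items()}
    for f in record.features:
        strand = -1 if f.strand == "L" else 1
        locs = [
            FeatureLocation(s - 1, e, strand=strand) for s, e in f.segments
        ]
        location = locs[0] if len(locs) == 1 else CompoundLocation(locs)
        quals = {"gene": [f.name]}
        if f.anticodon:
            quals["anticodon"] = [f.anticodon]
        if f.annotated_start_codon:
            quals["codon_start_note"] = [f.annotated_start_codon]
        if f.annotated_stop_codon:
            quals["stop_codon_note"] = [f.annotated_stop_codon]
        seqrec.features.append(
            SeqFeature(location, type=gb_type[f.category], qualifiers=quals)
        )
    SeqIO.write([seqrec], str(path), "genbank")


def read_fasta(path) -> NucleotideSequence:
    seqrec = SeqIO.read(str(path), "fasta")
    return NucleotideSequence(str(seqrec.seq).upper(), circular=True)


def write_fasta(record: MitoGenomeRecord, path, line_width: int = 70) -> None:
    if not record.has_sequence:
        raise GenomeIOError("cannot write FASTA without a sequence")
    header = record.accession or record.species.replace(" ", "_") or "genome"
    res = record.sequence.residues
    with open(path, "w") as fh:
        fh.write(f">{header} {record.species}\n")
        for i in range(0, len(res), line_width):
            fh.write(res[i : i + line_width] + "\n")


# ---------------------------------------------------------------------------
# sequence extraction
# ---------------------------------------------------------------------------

def extract_native_sequence(record: MitoGenomeRecord, name: str) -> str:
    """Feature sequence in the genome's own (heavy-strand) register.

    Segments are concatenated in order across the origin; no reverse
    complementing regardless of strand.
    """
    if not record.has_sequence:
        raise GenomeIOError(f"record {record.species!r} has no sequence")
    feat = record.feature(name)
    res = record.sequence.residues
    parts = []
    for s, e in feat.segments:
        if e > len(res):
            raise GenomeIOError(f"{name}: segment ({s}, {e}) beyond sequence end")
        parts.append(res[s - 1 : e])
    return "".join(parts)


def extract_feature_sequence(record: MitoGenomeRecord, name: str) -> NucleotideSequence:
    """Oriented 5'->3' feature sequence (L-strand features reverse-complemented)."""
    feat = record.feature(name)
    raw = extract_native_sequence(record, name)
    if feat.strand == "L":
        raw = reverse_complement(raw)
    return NucleotideSequence(raw, circular=False)
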