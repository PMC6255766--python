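"""Synthetic circular mitogenomes with known ground truth.

The generator emits a 16.8 kb circular genome carrying the 37-gene
vertebrate mitochondrial layout (13 PCGs, 22 tRNAs, 2 rRNAs, one control
region spanning the origin), with

* partition-specific A+T content and AT/GC skews realized by weighted base
  sampling in unconstrained positions;
* protein-coding genes that start with ATN codons and end with complete or
  incomplete stop codons following their layout template;
* tRNA genes designed as foldable cloverleafs (complement-paired stems, so
  stem sampling is A+T-neutral);
* a control region with planted tandem repeats — by default (ATTAT)_8, a
  49 bp motif twice, (AT)_7 and (TATTA)_20 with 151/781/87 bp spacers —
  plus a GACATA motif and a planted stem-loop.

Every generated genome comes with a :class:`GenomeTruth` record whose
fields are recomputed from the emitted sequence at generation time, so
pipeline-vs-truth comparisons are exact by construction.  A single integer
seed drives all randomness; identical (spec, seed) inputs give
byte-identical output.

Known deliberate compromise: where layout features overlap (six loci in the
default layout), the later-written feature wins the shared bases and
downstream CDS start codons are re-imposed afterwards, so an upstream
feature's final bases may deviate from its design; the truth record flags
such features as "clobbered".
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from math import ceil
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .codon_usage import VERTEBRATE_MITO_TABLE_ID, ALL_CODONS, genetic_code
from .datasets import nilssonia_nigricans_annotation
from .genome_io import (
    FeatureRecord,
    MitoGenomeRecord,
    NucleotideSequence,
    reverse_complement,
)
from .trna_structure import (
    Arm,
    CloverleafStructure,
    FoldBounds,
    CANONICAL_ARMS,
    _geometries,
)

__all__ = [
    "GenomeSpec",
    "GenomeTruth",
    "DivergentPairTruth",
    "CrRepeatPlan",
    "generate_genome",
    "generate_divergent_pair",
    "mutate_genome",
    "design_trna",
    "base_probabilities",
]

_BASES = ("A", "C", "G", "T")
_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}


def base_probabilities(at: float, at_skew: float, gc_skew: float) -> np.ndarray:
    """(pA, pC, pG, pT) realizing an A+T fraction and AT/GC skews."""
    if not 0.0 < at < 1.0:
        raise ValueError("A+T target must be in (0, 1)")
    gc = 1.0 - at
    p = np.array(
        [
            at * (1.0 + at_skew) / 2.0,
            gc * (1.0 - gc_skew) / 2.0,
            gc * (1.0 + gc_skew) / 2.0,
            at * (1.0 - at_skew) / 2.0,
        ]
    )
    if (p < 0).any():
        raise ValueError("skew targets incompatible with A+T target")
    return p


def _expected_at_nonstop(p: np.ndarray, stop_codons: frozenset) -> float:
    """Expected per-base A+T of codons sampled from p, stops rejected."""
    idx = {b: i for i, b in enumerate(_BASES)}
    total_p = 0.0
    total_at = 0.0
    for codon in ALL_CODONS:
        if codon in stop_codons:
            continue
        pc = p[idx[codon[0]]] * p[idx[codon[1]]] * p[idx[codon[2]]]
        total_p += pc
        total_at += pc * sum(1 for b in codon if b in "AT")
    return total_at / (3.0 * total_p)


def _solve_codon_at(
    target_at: float, at_skew: float, gc_skew: float, stop_codons: frozenset
) -> np.ndarray:
    """Base probabilities whose stop-rejected codon sampling hits target A+T.

    Rejecting stop codons (which are A/T-rich under the mitochondrial code)
    depresses realized A+T below the nominal base frequencies; this solves
    for the compensating nominal A+T by bisection.
    """
    lo, hi = 0.02, 0.98
    for _ in range(60):
        mid = (lo + hi) / 2.0
        if _expected_at_nonstop(base_probabilities(mid, at_skew, gc_skew), stop_codons) < target_at:
            lo = mid
        else:
            hi = mid
    return base_probabilities((lo + hi) / 2.0, at_skew, gc_skew)


def _sample(p: np.ndarray, n: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(_BASES, size=n, p=p / p.sum()))


# ---------------------------------------------------------------------------
# specification and truth containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CrRepeatPlan:
    """One planted tandem repeat: motif (or a random motif of motif_length),
    integer copy number, and the spacer preceding it within the CR."""

    motif: Optional[str]
    copies: int
    gap_before: int
    motif_length: Optional[int] = None

    def length(self) -> int:
        period = len(self.motif) if self.motif else self.motif_length
        return period * self.copies


_DEFAULT_CR_REPEATS = (
    CrRepeatPlan("ATTAT", 8, 10),
    CrRepeatPlan(None, 2, 151, motif_length=49),
    CrRepeatPlan("AT", 7, 781),
    CrRepeatPlan("TATTA", 20, 87),
)


@dataclass(frozen=True)
class GenomeSpec:
    """Study conditions for one synthetic genome.

    The defaults emulate the black softshell turtle mitogenome: 16,796 bp,
    the published 37-gene layout, genome A+T 62.16% with AT skew 0.197 and
    GC skew -0.400, partition A+T of 61.26% (PCG), 63.82% (tRNA), 61.47%
    (rRNA) and 68.52% (CR), and the four control-region repeats with their
    151/781/87 bp spacers.
    """

    genome_length: int = 16796
    layout: Optional[Tuple[FeatureRecord, ...]] = None  # default: bundled table
    at_genome: float = 0.6216
    at_skew: float = 0.197
    gc_skew: float = -0.400
    at_pcg: Optional[float] = 0.6126
    at_trna: Optional[float] = 0.6382
    at_rrna: Optional[float] = 0.6147
    at_cr: Optional[float] = 0.6852
    cr_at_skew: float = 0.07
    cr_gc_skew: float = -0.374
    cr_repeats: Tuple[CrRepeatPlan, ...] = _DEFAULT_CR_REPEATS
    cr_motif: str = "GACATA"
    species: str = "synthetic softshell mitogenome"
    code_id: int = VERTEBRATE_MITO_TABLE_ID

    def partition_at(self, partition: str) -> float:
        value = {
            "PCG": self.at_pcg,
            "tRNA": self.at_trna,
            "rRNA": self.at_rrna,
            "CR": self.at_cr,
        }.get(partition)
        return self.at_genome if value is None else value

    def resolved_layout(self) -> Tuple[FeatureRecord, ...]:
        if self.layout is not None:
            return tuple(self.layout)
        return tuple(nilssonia_nigricans_annotation().features)


@dataclass
class PlantedRepeat:
    motif: str
    period: int
    copies: float
    cr_start: int  # 1-based within the CR
    cr_end: int


@dataclass
class TrnaTruth:
    name: str
    designed_geometry: Tuple[int, ...]  # (a, d, dl, c, v, t, tl)
    designed_arm_lengths: Tuple[int, int, int, int]
    anticodon: str
    designed_sequence: str  # oriented 5'->3'
    clobbered: bool = False  # overlap repair changed >=1 base


@dataclass
class GenomeTruth:
    """Ground truth recomputed from the emitted genome."""

    spec: GenomeSpec
    seed: int
    base_counts: Dict[str, int]
    partition_base_counts: Dict[str, Dict[str, int]]
    planted_repeats: List[PlantedRepeat]
    cr_motif_position: int  # 1-based within the CR
    cr_stem_loop: Tuple[int, int, int]  # (cr_start, stem_len, loop_len)
    trna: Dict[str, TrnaTruth]
    cds_start_codons: Dict[str, str]
    cds_stop_tails: Dict[str, str]

    def at_fraction(self, partition: str = "genome") -> float:
        counts = (
            self.base_counts
            if partition == "genome"
            else self.partition_base_counts[partition]
        )
        total = sum(counts.values())
        return (counts.get("A", 0) + counts.get("T", 0)) / total


# ---------------------------------------------------------------------------
# tRNA design
# ---------------------------------------------------------------------------

#: below this length a designed tRNA drops its DHU arm, as vertebrate
#: mitochondrial tRNA-Ser(AGY) does
DHU_LESS_MAX_LENGTH = 63


def _pick_geometry(
    length: int,
    bounds: FoldBounds = FoldBounds(),
    dhu_less: Optional[bool] = None,
) -> Tuple[int, ...]:
    """Canonical-closest admissible geometry for a tRNA of this length."""
    if dhu_less is None:
        dhu_less = length <= DHU_LESS_MAX_LENGTH
    best = None
    for geom in _geometries(length, bounds):
        a, d, dl, c, v, t, tl = geom
        if dhu_less != (d == 0):
            continue
        canon = sum(abs(x - y) for x, y in zip((a, d, c, t), CANONICAL_ARMS))
        key = (canon, abs(a - 7), abs(dl - 8), abs(tl - 7), v, geom)
        if best is None or key < best:
            best = key
    if best is None:
        raise ValueError(f"no admissible cloverleaf geometry for length {length}")
    return best[-1]


def design_trna(
    geometry: Tuple[int, ...],
    anticodon: str,
    rng: np.random.Generator,
    probs: Optional[np.ndarray] = None,
    wobble_positions: int = 0,
) -> Tuple[str, CloverleafStructure]:
    """Build a cloverleaf-foldable tRNA from an arm geometry.

    Stems are sampled on the 5' side and complemented on the 3' side
    (Watson-Crick throughout, A+T-neutral); ``wobble_positions`` innermost
    acceptor pairs are converted G-C -> G-T / A-T -> G-T to plant wobbles.
    The anticodon sits at the center of the 7 nt anticodon loop.
    """
    if probs is None:
        probs = np.full(4, 0.25)
    a, d, dl, c, v, t, tl = geometry

    def stem_pair(n: int) -> Tuple[str, str]:
        s5 = _sample(probs, n, rng)
        s3 = "".join(_COMPLEMENT[b] for b in reversed(s5))
        return s5, s3

    acc5, acc3 = stem_pair(a)
    if wobble_positions:
        w = min(wobble_positions, a)
        # make the innermost w acceptor pairs G.T wobbles
        acc5 = acc5[: a - w] + "G" * w
        acc3 = "T" * w + acc3[w:]
    dhu = None
    if d:
        d5, d3 = stem_pair(d)
        dhu = Arm(d5, _sample(probs, dl, rng), d3)
    c5, c3 = stem_pair(c)
    loop = _sample(probs, 2, rng) + anticodon.upper() + _sample(probs, 2, rng)
    ac_arm = Arm(c5, loop, c3)
    t5, t3 = stem_pair(t)
    t_arm = Arm(t5, _sample(probs, tl, rng), t3)
    structure = CloverleafStructure(
        acceptor5=acc5,
        dhu=dhu,
        anticodon_arm=ac_arm,
        variable_loop=_sample(probs, v, rng),
        t_arm=t_arm,
        acceptor3=acc3,
    )
    return structure.flatten(), structure


# ---------------------------------------------------------------------------
# CDS design
# ---------------------------------------------------------------------------

def _sample_codon(probs: np.ndarray, stops: frozenset, rng: np.random.Generator) -> str:
    while True:
        codon = _sample(probs, 3, rng)
        if codon not in stops:
            return codon


def _stop_tail(length: int, template: Optional[str], stops: frozenset) -> str:
    """Frame-consistent stop tail: template when compatible, else TAA/T/TA."""
    r = length % 3
    template = (template or "").strip("()")
    if r == 0:
        return template if template in stops else "TAA"
    if r == 1:
        return template if len(template) == 1 and template in "ACGT" else "T"
    return template if len(template) == 2 else "TA"


def _design_cds(
    length: int,
    start_template: Optional[str],
    stop_template: Optional[str],
    probs: np.ndarray,
    stops: frozenset,
    rng: np.random.Generator,
) -> str:
    start = start_template if start_template in ("ATG", "ATA", "ATT", "ATC") else "ATG"
    tail = _stop_tail(length, stop_template, stops)
    middle = length - 3 - len(tail)
    codons = [_sample_codon(probs, stops, rng) for _ in range(middle // 3)]
    return start + "".join(codons) + tail


# ---------------------------------------------------------------------------
# control-region design
# ---------------------------------------------------------------------------

def _design_cr(
    length: int,
    spec: GenomeSpec,
    rng: np.random.Generator,
) -> Tuple[str, List[PlantedRepeat], int, Tuple[int, int, int]]:
    plans = list(spec.cr_repeats)
    pure_at = sum(
        p.length()
        for p in plans
        if p.motif is not None and set(p.motif) <= {"A", "T"}
    )
    planned = sum(p.gap_before + p.length() for p in plans)
    if planned >= length:
        raise ValueError(
            f"CR repeat plan needs {planned} bp but the CR is {length} bp"
        )
    motif_at = sum(1 for b in spec.cr_motif if b in "AT")
    fill_len = length - pure_at - len(spec.cr_motif)
    target_at = spec.partition_at("CR")
    fill_at = (target_at * length - pure_at - motif_at) / fill_len
    fill_at = min(max(fill_at, 0.05), 0.95)
    fill_probs = base_probabilities(fill_at, spec.cr_at_skew, spec.cr_gc_skew)

    parts: List[str] = []
    planted: List[PlantedRepeat] = []
    pos = 0  # 0-based length so far

    # the conserved motif and a stem-loop go inside the longest spacer
    longest_idx = max(range(len(plans)), key=lambda i: plans[i].gap_before)
    stem_len, loop_len = 5, 7
    motif_pos = stem_pos = None

    for i, plan in enumerate(plans):
        spacer = _sample(fill_probs, plan.gap_before, rng)
        if i == longest_idx and plan.gap_before >= len(spec.cr_motif) + 2 * stem_len + loop_len + 40:
            # plant GACATA and a hairpin at fixed interior offsets
            m_off = plan.gap_before // 4
            spacer = (
                spacer[:m_off] + spec.cr_motif + spacer[m_off + len(spec.cr_motif):]
            )
            motif_pos = pos + m_off + 1
            s_off = plan.gap_before // 2
            stem5 = _sample(fill_probs, stem_len, rng)
            hairpin = (
                stem5
                + _sample(fill_probs, loop_len, rng)
                + "".join(_COMPLEMENT[b] for b in reversed(stem5))
            )
            spacer = spacer[:s_off] + hairpin + spacer[s_off + len(hairpin):]
            stem_pos = pos + s_off + 1
        parts.append(spacer)
        pos += len(spacer)
        motif = plan.motif
        if motif is None:
            while True:
                motif = _sample(fill_probs, plan.motif_length, rng)
                from .control_region import is_primitive

                if is_primitive(motif):
                    break
        text = motif * plan.copies
        planted.append(
            PlantedRepeat(
                motif=motif,
                period=len(motif),
                copies=float(plan.copies),
                cr_start=pos + 1,
                cr_end=pos + len(text),
            )
        )
        parts.append(text)
        pos += len(text)
    parts.append(_sample(fill_probs, length - pos, rng))
    cr = list("".join(parts))
    assert len(cr) == length

    # break periodic extension at repeat flanks so planted (period, copies)
    # are recovered exactly
    for rep in planted:
        s0, e0, p = rep.cr_start - 1, rep.cr_end - 1, rep.period
        if s0 - 1 >= 0 and cr[s0 - 1] == cr[s0 - 1 + p]:
            cr[s0 - 1] = _different_base(cr[s0 - 1 + p], rng)
        if e0 + 1 < length and cr[e0 + 1] == cr[e0 + 1 - p]:
            cr[e0 + 1] = _different_base(cr[e0 + 1 - p], rng)
    return "".join(cr), planted, motif_pos or 0, (stem_pos or 0, stem_len, loop_len)


def _different_base(base: str, rng: np.random.Generator) -> str:
    options = [b for b in _BASES if b != base]
    return options[int(rng.integers(len(options)))]


# ---------------------------------------------------------------------------
# genome assembly
# ---------------------------------------------------------------------------

def _write_span(
    genome: List[str], segments: Sequence[Tuple[int, int]], text: str
) -> None:
    i = 0
    for s, e in segments:
        n = e - s + 1
        genome[s - 1 : e] = list(text[i : i + n])
        i += n
    assert i == len(text)


def _read_span(genome: List[str], segments: Sequence[Tuple[int, int]]) -> str:
    return "".join("".join(genome[s - 1 : e]) for s, e in segments)


def generate_genome(
    spec: GenomeSpec = GenomeSpec(), seed: int = 0
) -> Tuple[MitoGenomeRecord, GenomeTruth]:
    """Emit a synthetic annotated mitogenome plus its ground truth.

    Deterministic in (spec, seed).  Intergenic gaps and overlaps follow the
    layout exactly (the features carry the layout coordinates); sequence
    content realizes the composition targets in expectation.
    """
    rng = np.random.default_rng(seed)
    layout = spec.resolved_layout()
    L = spec.genome_length
    for feat in layout:
        for s, e in feat.segments:
            if e > L:
                raise ValueError(
                    f"layout feature {feat.name} ({s}-{e}) exceeds genome "
                    f"length {L}"
                )
    table = genetic_code(spec.code_id)
    stops = frozenset(table.stop_codons)

    genome_probs = base_probabilities(spec.at_genome, spec.at_skew, spec.gc_skew)
    pcg_probs = _solve_codon_at(spec.partition_at("PCG"), spec.at_skew, spec.gc_skew, stops)
    trna_probs = base_probabilities(spec.partition_at("tRNA"), 0.0, 0.0)
    rrna_probs = base_probabilities(spec.partition_at("rRNA"), spec.at_skew, spec.gc_skew)

    genome = list(_sample(genome_probs, L, rng))

    trna_truth: Dict[str, TrnaTruth] = {}
    planted_repeats: List[PlantedRepeat] = []
    cr_motif_pos = 0
    cr_stem = (0, 0, 0)

    for feat in sorted(layout, key=lambda f: (f.first_start, f.name)):
        if feat.category == "rRNA":
            _write_span(genome, feat.segments, _sample(rrna_probs, feat.length, rng))
        elif feat.category == "tRNA":
            geometry = _pick_geometry(feat.length)
            anticodon = feat.anticodon or _sample(trna_probs, 3, rng)
            oriented, structure = design_trna(geometry, anticodon, rng, trna_probs)
            text = oriented if feat.strand == "H" else reverse_complement(oriented)
            _write_span(genome, feat.segments, text)
            trna_truth[feat.name] = TrnaTruth(
                name=feat.name,
                designed_geometry=geometry,
                designed_arm_lengths=structure.arm_lengths,
                anticodon=anticodon,
                designed_sequence=oriented,
            )
        elif feat.category == "PCG":
            oriented = _design_cds(
                feat.length,
                feat.annotated_start_codon,
                feat.annotated_stop_codon,
                pcg_probs,
                stops,
                rng,
            )
            text = oriented if feat.strand == "H" else reverse_complement(oriented)
            _write_span(genome, feat.segments, text)
        elif feat.category == "CR":
            cr_text, planted_repeats, cr_motif_pos, cr_stem = _design_cr(
                feat.length, spec, rng
            )
            _write_span(genome, feat.segments, cr_text)

    # repair pass: downstream CDS start codons win inside overlaps
    for feat in sorted(layout, key=lambda f: (f.first_start, f.name)):
        if feat.category != "PCG":
            continue
        start = feat.annotated_start_codon
        start = start if start in ("ATG", "ATA", "ATT", "ATC") else "ATG"
        if feat.strand == "H":
            s = feat.first_start
            genome[s - 1 : s + 2] = list(start)
        else:
            e = feat.last_end
            genome[e - 3 : e] = list(reverse_complement(start))

    sequence = "".join(genome)
    record = MitoGenomeRecord(
        species=spec.species,
        features=list(layout),
        sequence=NucleotideSequence(sequence, circular=True),
        accession=f"SYN{seed:06d}"[:12],
        genome_length=L,
    )

    # ---- truth, recomputed from the emitted text -------------------------
    for name, truth in trna_truth.items():
        feat = record.feature(name)
        realized = _read_span(genome, feat.segments)
        if feat.strand == "L":
            realized = reverse_complement(realized)
        truth.clobbered = realized != truth.designed_sequence

    cds_starts: Dict[str, str] = {}
    cds_tails: Dict[str, str] = {}
    for feat in layout:
        if feat.category != "PCG":
            continue
        oriented = _read_span(genome, feat.segments)
        if feat.strand == "L":
            oriented = reverse_complement(oriented)
        cds_starts[feat.name] = oriented[:3]
        r = feat.length % 3 or 3
        cds_tails[feat.name] = oriented[-r:]

    partition_counts: Dict[str, Dict[str, int]] = {}
    pools: Dict[str, str] = {"PCG": "", "tRNA": "", "rRNA": "", "CR": ""}
    for feat in layout:
        text = _read_span(genome, feat.segments)
        if feat.category == "PCG" and feat.strand == "L":
            text = reverse_complement(text)
        pools[feat.category] += text
    for part, pooled in pools.items():
        partition_counts[part] = dict(Counter(pooled))

    cr_feat = next(f for f in layout if f.category == "CR")
    cr_realized = _read_span(genome, cr_feat.segments)
    for rep in planted_repeats:
        expected = (rep.motif * ceil(rep.copies))[: rep.cr_end - rep.cr_start + 1]
        realized = cr_realized[rep.cr_start - 1 : rep.cr_end]
        if realized != expected:
            raise AssertionError(
                f"generator bug: planted repeat {rep.motif} not realized"
            )

    truth = GenomeTruth(
        spec=spec,
        seed=seed,
        base_counts=dict(Counter(sequence)),
        partition_base_counts=partition_counts,
        planted_repeats=planted_repeats,
        cr_motif_position=cr_motif_pos,
        cr_stem_loop=cr_stem,
        trna=trna_truth,
        cds_start_codons=cds_starts,
        cds_stop_tails=cds_tails,
    )
    return record, truth


# ---------------------------------------------------------------------------
# divergent CDS pairs
# ---------------------------------------------------------------------------

def _apply_codon_mutations(
    codons: List[str],
    syn_rate: float,
    nonsyn_rate: float,
    aa: Dict[str, str],
    stops: set,
    rng: np.random.Generator,
) -> Tuple[List[str], int, int, List[int]]:
    """Per-position codon-aware substitutions that never create stops.

    The event type is decided by the uniform draw alone; a drawn event with
    no admissible change at that position is dropped, so realized counts
    stay proportional to the planted rates.
    """
    derived = list(codons)
    n_syn = n_nonsyn = 0
    changed: List[int] = []
    for ci in range(len(derived)):
        if derived[ci] in stops or set(derived[ci]) - set(_BASES):
            continue  # terminal stop codons / ambiguity stay untouched
        for pos in range(3):
            codon = derived[ci]
            syn_alts, nonsyn_alts = [], []
            for b in _BASES:
                if b == codon[pos]:
                    continue
                alt = codon[:pos] + b + codon[pos + 1 :]
                if alt in stops:
                    continue
                (syn_alts if aa[alt] == aa[codon] else nonsyn_alts).append(alt)
            u = rng.random()
            if u < syn_rate:
                if syn_alts:
                    derived[ci] = syn_alts[int(rng.integers(len(syn_alts)))]
                    n_syn += 1
                    changed.append(3 * ci + pos)
            elif u < syn_rate + nonsyn_rate:
                if nonsyn_alts:
                    derived[ci] = nonsyn_alts[int(rng.integers(len(nonsyn_alts)))]
                    n_nonsyn += 1
                    changed.append(3 * ci + pos)
    return derived, n_syn, n_nonsyn, changed


def mutate_genome(
    record: MitoGenomeRecord,
    species: str,
    syn_rate: float = 0.05,
    nonsyn_rate: float = 0.005,
    noncoding_rate: float = 0.03,
    code_id: int = VERTEBRATE_MITO_TABLE_ID,
    seed: int = 0,
) -> Tuple[MitoGenomeRecord, Dict[str, Tuple[int, int]]]:
    """A diverged relative of a synthetic genome, for comparative stages.

    Protein-coding genes evolve codon-aware (synonymous / nonsynonymous
    rates per position, stops never created, start codons kept); all other
    positions substitute uniformly at ``noncoding_rate``.  Returns the new
    record and per-gene (synonymous, nonsynonymous) change counts.
    """
    if not record.has_sequence:
        raise ValueError("need a sequenced genome to mutate")
    rng = np.random.default_rng(seed)
    table = genetic_code(code_id)
    stops = set(table.stop_codons)
    aa = table.forward_table
    genome = list(record.sequence.residues)

    coding = set()
    for feat in record.features:
        if feat.category == "PCG":
            for s, e in feat.segments:
                coding.update(range(s - 1, e))
    for i in range(len(genome)):
        if i not in coding and rng.random() < noncoding_rate:
            genome[i] = _different_base(genome[i], rng)

    per_gene: Dict[str, Tuple[int, int]] = {}
    for feat in record.features:
        if feat.category != "PCG":
            continue
        oriented = _read_span(genome, feat.segments)
        original = _read_span(list(record.sequence.residues), feat.segments)
        if feat.strand == "L":
            original = reverse_complement(original)
        usable = len(original) - len(original) % 3
        codons = [original[i : i + 3] for i in range(0, usable, 3)]
        mutable = codons[1:]  # keep the start codon
        mutated, n_syn, n_nonsyn, _ = _apply_codon_mutations(
            mutable, syn_rate, nonsyn_rate, aa, stops, rng
        )
        new_cds = codons[0] + "".join(mutated) + original[usable:]
        text = new_cds if feat.strand == "H" else reverse_complement(new_cds)
        _write_span(genome, feat.segments, text)
        per_gene[feat.name] = (n_syn, n_nonsyn)

    mutated_record = MitoGenomeRecord(
        species=species,
        features=list(record.features),
        sequence=NucleotideSequence("".join(genome), circular=True),
        accession=f"SYNM{seed:05d}"[:12],
        genome_length=record.genome_length,
    )
    return mutated_record, per_gene


@dataclass
class DivergentPairTruth:
    """Realized substitution history of one simulated CDS pair."""

    n_codons: int
    planted_syn_rate: float
    planted_nonsyn_rate: float
    n_syn_applied: int
    n_nonsyn_applied: int
    changed_positions: List[int]  # 0-based nucleotide offsets


def generate_divergent_pair(
    cds_length_codons: int,
    planted_syn_rate: float,
    planted_nonsyn_rate: float,
    code_id: int = VERTEBRATE_MITO_TABLE_ID,
    seed: int = 0,
) -> Tuple[str, str, DivergentPairTruth]:
    """An ancestor CDS and a derived copy with planted substitution rates.

    At every codon position a synonymous single-base change is applied with
    probability ``planted_syn_rate`` (when one exists), else a
    nonsynonymous, non-stop change with probability ``planted_nonsyn_rate``.
    Changes are classified against the current (possibly already mutated)
    codon, and stop codons are never created.  Rates must satisfy
    ``0 <= syn + nonsyn <= 1`` and stay well below saturation for the
    downstream NG86 estimates to be defined.
    """
    if planted_syn_rate < 0 or planted_nonsyn_rate < 0:
        raise ValueError("rates must be nonnegative")
    if planted_syn_rate + planted_nonsyn_rate > 1:
        raise ValueError("rates must sum to at most 1")
    if cds_length_codons < 1:
        raise ValueError("need at least one codon")
    rng = np.random.default_rng(seed)
    table = genetic_code(code_id)
    stops = set(table.stop_codons)
    sense = [c for c in ALL_CODONS if c not in stops]
    aa = table.forward_table

    ancestor = [sense[int(rng.integers(len(sense)))] for _ in range(cds_length_codons)]
    derived, n_syn, n_nonsyn, changed = _apply_codon_mutations(
        ancestor, planted_syn_rate, planted_nonsyn_rate, aa, stops, rng
    )
    truth = DivergentPairTruth(
        n_codons=cds_length_codons,
        planted_syn_rate=planted_syn_rate,
        planted_nonsyn_rate=planted_nonsyn_rate,
        n_syn_applied=n_syn,
        n_nonsyn_applied=n_nonsyn,
        changed_positions=changed,
    )
    return "".join(ancestor), "".join(derived), truth
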