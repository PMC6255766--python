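"""Pairwise molecular-evolution statistics and a distance phylogeny stage.

The substitution analysis follows the Nei-Gojobori (1986) counting method:
synonymous (S) and nonsynonymous (N) site totals are per-codon fractions of
single-nucleotide changes that preserve the amino acid, averaged over both
sequences; observed differences (Sd, Nd) average over all mutational paths
between differing codons, excluding paths that pass through stop codons;
the proportions pS = Sd/S and pN = Nd/N are Jukes-Cantor corrected,

    d = -(3/4) * ln(1 - (4/3) p),

undefined ("saturated") when p >= 3/4.  Ka/Ks < 1 indicates purifying
selection.

Nucleotide distances use the Kimura two-parameter model separating the
transition proportion P from the transversion proportion Q:

    d = 1/2 ln(1/(1 - 2P - Q)) + 1/4 ln(1/(1 - 2Q)).

Trees are built with Saitou-Nei neighbor joining, which recovers additive
distance matrices exactly; this is a deliberately lightweight stand-in for
model-based maximum-likelihood inference.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import permutations
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .codon_usage import VERTEBRATE_MITO_TABLE_ID, genetic_code

__all__ = [
    "CodonAlignment",
    "KaKsRecord",
    "DistanceMatrix",
    "align_codons_pairwise",
    "ng86",
    "summarize_kaks",
    "k2p_distance",
    "k2p_matrix",
    "concatenate_pcgs",
    "nj_tree",
]

GAP = "-"
_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}
_BASES = "ACGT"


# ---------------------------------------------------------------------------
# codon-aware pairwise alignment (protein-guided global alignment)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CodonAlignment:
    """Two gapped CDS rows of equal length divisible by 3; whole-codon gaps."""

    a: str
    b: str

    def __post_init__(self):
        if len(self.a) != len(self.b):
            raise ValueError("alignment rows differ in length")
        if len(self.a) % 3:
            raise ValueError("alignment length not divisible by 3")

    @property
    def n_codons(self) -> int:
        return len(self.a) // 3

    def ungapped(self) -> Tuple[str, str]:
        return self.a.replace(GAP, ""), self.b.replace(GAP, "")

    def codon_pairs(self) -> List[Tuple[str, str]]:
        return [
            (self.a[i : i + 3], self.b[i : i + 3]) for i in range(0, len(self.a), 3)
        ]

    def transpose(self) -> "CodonAlignment":
        return CodonAlignment(self.b, self.a)


def _translate(cds: str, code_id: int) -> str:
    table = genetic_code(code_id)
    aas = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        codon = cds[i : i + 3]
        if set(codon) - set(_BASES):
            aas.append("X")
        elif codon in table.stop_codons:
            aas.append("*")
        else:
            aas.append(table.forward_table[codon])
    return "".join(aas)


def align_codons_pairwise(
    cds_a: str,
    cds_b: str,
    code_id: int = VERTEBRATE_MITO_TABLE_ID,
    match: int = 1,
    mismatch: int = 0,
    gap: int = -1,
) -> CodonAlignment:
    """Global protein-guided alignment back-mapped to whole-codon gaps.

    Translated sequences are aligned with Needleman-Wunsch (match +1,
    mismatch 0, gap -1 by default) and the protein alignment is mapped back
    onto the codons.  Internal stop codons trigger a warning and align as a
    mismatch state (``*`` scores as mismatch against everything, itself
    included).  Tie-breaking is deterministic: prefer the diagonal move,
    then a gap in row a.
    """
    cds_a, cds_b = cds_a.upper(), cds_b.upper()
    if len(cds_a) < 3 or len(cds_b) < 3:
        raise ValueError("both CDS must be at least one codon long")
    prot_a, prot_b = _translate(cds_a, code_id), _translate(cds_b, code_id)
    for name, prot in (("a", prot_a), ("b", prot_b)):
        if "*" in prot[:-1]:
            warnings.warn(
                f"internal stop codon in CDS {name}; treated as mismatch state",
                stacklevel=2,
            )

    def score(x: str, y: str) -> int:
        if x == "*" or y == "*" or x == "X" or y == "X":
            return mismatch
        return match if x == y else mismatch

    n, m = len(prot_a), len(prot_b)
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    H[:, 0] = gap * np.arange(n + 1)
    H[0, :] = gap * np.arange(m + 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            H[i, j] = max(
                H[i - 1, j - 1] + score(prot_a[i - 1], prot_b[j - 1]),
                H[i, j - 1] + gap,
                H[i - 1, j] + gap,
            )
    # traceback: diagonal, then gap in a (consume b), then gap in b
    i, j = n, m
    cols: List[Tuple[Optional[int], Optional[int]]] = []
    while i > 0 or j > 0:
        if (
            i > 0
            and j > 0
            and H[i, j] == H[i - 1, j - 1] + score(prot_a[i - 1], prot_b[j - 1])
        ):
            cols.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif j > 0 and H[i, j] == H[i, j - 1] + gap:
            cols.append((None, j - 1))
            j -= 1
        else:
            cols.append((i - 1, None))
            i -= 1
    cols.reverse()
    row_a, row_b = [], []
    for ia, jb in cols:
        row_a.append(cds_a[3 * ia : 3 * ia + 3] if ia is not None else GAP * 3)
        row_b.append(cds_b[3 * jb : 3 * jb + 3] if jb is not None else GAP * 3)
    return CodonAlignment("".join(row_a), "".join(row_b))


# ---------------------------------------------------------------------------
# Nei-Gojobori (1986) Ka/Ks with Jukes-Cantor correction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KaKsRecord:
    """NG86 sites, differences and corrected rates for one aligned pair."""

    S: float
    N: float
    Sd: float
    Nd: float
    pS: Optional[float]
    pN: Optional[float]
    Ks: Optional[float]
    Ka: Optional[float]
    ratio: Optional[float]
    codons_compared: int
    codons_excluded: int

    @property
    def saturated(self) -> bool:
        return (self.pS is not None and self.Ks is None) or (
            self.pN is not None and self.Ka is None
        )


def _syn_site_fractions(codon: str, code_id: int) -> float:
    """Synonymous-site count of one codon (sum of per-position fractions).

    At each position the fraction of single-nucleotide changes that are
    synonymous is computed over the non-stop alternatives (mutations to stop
    codons are not counted as possible changes, mirroring the exclusion of
    stop-crossing paths in the difference count).
    """
    table = genetic_code(code_id)
    stops = set(table.stop_codons)
    aa = table.forward_table[codon]
    s = 0.0
    for pos in range(3):
        syn = valid = 0
        for base in _BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if alt in stops:
                continue
            valid += 1
            if table.forward_table[alt] == aa:
                syn += 1
        if valid:
            s += syn / valid
    return s


def _path_differences(ca: str, cb: str, code_id: int) -> Tuple[float, float]:
    """(Sd, Nd) between two codons, averaged over stop-free mutational paths."""
    table = genetic_code(code_id)
    stops = set(table.stop_codons)
    diff_pos = [p for p in range(3) if ca[p] != cb[p]]
    if not diff_pos:
        return 0.0, 0.0

    def walk(order) -> Optional[Tuple[int, int]]:
        sd = nd = 0
        cur = ca
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            if nxt in stops and nxt != cb:
                return None  # path passes through a stop codon
            if nxt in stops or cur in stops:
                sd_step = 0  # change into/out of a stop endpoint: nonsynonymous
            else:
                sd_step = int(table.forward_table[cur] == table.forward_table[nxt])
            sd += sd_step
            nd += 1 - sd_step
            cur = nxt
        return sd, nd

    results = [r for r in map(walk, permutations(diff_pos)) if r is not None]
    if not results:
        # every path blocked by stops: fall back to counting all changes as
        # nonsynonymous along an arbitrary order
        return 0.0, float(len(diff_pos))
    sd = sum(r[0] for r in results) / len(results)
    nd = sum(r[1] for r in results) / len(results)
    return sd, nd


def jukes_cantor(p: float) -> Optional[float]:
    """JC69 correction; ``None`` at saturation (p >= 3/4)."""
    if p >= 0.75:
        return None
    if p == 0.0:
        return 0.0
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p)


def ng86(
    alignment: CodonAlignment, code_id: int = VERTEBRATE_MITO_TABLE_ID
) -> KaKsRecord:
    """Nei-Gojobori sites/differences and Jukes-Cantor corrected Ka, Ks.

    Codon pairs containing gaps, ambiguity codes or stop codons are excluded
    pairwise.  ``Ks``/``Ka`` are ``None`` when the corresponding proportion
    is saturated; ``ratio`` is ``None`` when either rate is undefined or
    ``Ks == 0``.
    """
    table = genetic_code(code_id)
    stops = set(table.stop_codons)
    S = N = Sd = Nd = 0.0
    used = excluded = 0
    for ca, cb in alignment.codon_pairs():
        if (
            set(ca) - set(_BASES)
            or set(cb) - set(_BASES)
            or ca in stops
            or cb in stops
        ):
            excluded += 1
            continue
        used += 1
        s_a = _syn_site_fractions(ca, code_id)
        s_b = _syn_site_fractions(cb, code_id)
        S += (s_a + s_b) / 2.0
        N += 3.0 - (s_a + s_b) / 2.0
        sd, nd = _path_differences(ca, cb, code_id)
        Sd += sd
        Nd += nd
    pS = Sd / S if S > 0 else None
    pN = Nd / N if N > 0 else None
    Ks = jukes_cantor(pS) if pS is not None else None
    Ka = jukes_cantor(pN) if pN is not None else None
    ratio = None
    if Ka is not None and Ks is not None and Ks > 0:
        ratio = Ka / Ks
    return KaKsRecord(
        S=S, N=N, Sd=Sd, Nd=Nd, pS=pS, pN=pN, Ks=Ks, Ka=Ka, ratio=ratio,
        codons_compared=used, codons_excluded=excluded,
    )


def summarize_kaks(
    per_gene: Mapping[str, Sequence[KaKsRecord]],
) -> "pd.DataFrame":
    """Per-gene mean +/- SD of the Ka/Ks ratio, ascending by mean.

    Pairs with an undefined ratio are excluded from the mean and reported in
    ``n_excluded``.  SD is the sample standard deviation across pairwise
    comparisons (0 with a single defined pair); a gene with no defined
    ratios gets a null summary row.
    """
    import pandas as pd

    rows = []
    for gene, records in per_gene.items():
        ratios = [r.ratio for r in records if r.ratio is not None]
        n_exc = sum(1 for r in records if r.ratio is None)
        if ratios:
            mean = float(np.mean(ratios))
            sd = float(np.std(ratios, ddof=1)) if len(ratios) > 1 else 0.0
        else:
            mean = sd = None
        rows.append(
            {"gene": gene, "n_pairs": len(ratios), "n_excluded": n_exc,
             "mean_kaks": mean, "sd_kaks": sd}
        )
    df = pd.DataFrame(rows)
    return df.sort_values(
        "mean_kaks", na_position="last", kind="mergesort"
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# K2P distance
# ---------------------------------------------------------------------------

def k2p_distance(row_a: str, row_b: str) -> Optional[float]:
    """Kimura two-parameter distance between equal-length aligned rows.

    Columns with gaps or ambiguity in either row are excluded.  Returns
    ``None`` ("saturated") when a logarithm argument is non-positive.
    """
    if len(row_a) != len(row_b):
        raise ValueError("aligned rows differ in length")
    row_a, row_b = row_a.upper(), row_b.upper()
    n = ts = tv = 0
    for x, y in zip(row_a, row_b):
        if x not in _BASES or y not in _BASES:
            continue
        n += 1
        if x == y:
            continue
        same_class = (x in _PURINES) == (y in _PURINES)
        if same_class:
            ts += 1
        else:
            tv += 1
    if n == 0:
        raise ValueError("no comparable columns")
    P, Q = ts / n, tv / n
    arg1 = 1.0 - 2.0 * P - Q
    arg2 = 1.0 - 2.0 * Q
    if arg1 <= 0 or arg2 <= 0:
        return None
    return 0.5 * math.log(1.0 / arg1) + 0.25 * math.log(1.0 / arg2)


# ---------------------------------------------------------------------------
# concatenation
# ---------------------------------------------------------------------------

def concatenate_pcgs(
    gene_alignments: Mapping[str, Mapping[str, str]],
) -> Tuple[Dict[str, str], List[Tuple[str, int, int]]]:
    """Concatenate per-gene alignments into a supermatrix + partition map.

    ``gene_alignments`` maps gene -> (taxon -> aligned row).  A taxon missing
    from a gene receives an all-gap block of that gene's width.  The
    partition map lists ``(gene, start, end)`` in 1-based inclusive
    supermatrix coordinates.
    """
    taxa: List[str] = []
    for gene, aln in gene_alignments.items():
        labels = list(aln)
        if len(labels) != len(set(labels)):
            raise ValueError(f"duplicate taxon labels in gene {gene}")
        for t in labels:
            if t not in taxa:
                taxa.append(t)
    supermatrix: Dict[str, List[str]] = {t: [] for t in taxa}
    partitions: List[Tuple[str, int, int]] = []
    offset = 0
    for gene, aln in gene_alignments.items():
        widths = {len(s) for s in aln.values()}
        if len(widths) != 1:
            raise ValueError(f"gene {gene}: rows of unequal length")
        width = widths.pop()
        partitions.append((gene, offset + 1, offset + width))
        offset += width
        for t in taxa:
            supermatrix[t].append(aln.get(t, GAP * width))
    return {t: "".join(parts) for t, parts in supermatrix.items()}, partitions


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric nonnegative distance matrix with labelled taxa."""

    labels: Tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix diagonal is not zero")
        if (v < -1e-12).any():
            raise ValueError("negative distances")

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def k2p_matrix(rows: Mapping[str, str]) -> DistanceMatrix:
    """Pairwise K2P distances over a dict of equal-length aligned rows.

    A saturated pair is an error here (the matrix must be complete).
    """
    labels = tuple(rows)
    n = len(labels)
    v = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = k2p_distance(rows[labels[i]], rows[labels[j]])
            if d is None:
                raise ValueError(
                    f"saturated K2P distance between {labels[i]} and {labels[j]}"
                )
            v[i, j] = v[j, i] = d
    return DistanceMatrix(labels, v)


def _fmt_branch(x: float) -> str:
    if x < 0:
        warnings.warn("negative NJ branch length clamped to 0", stacklevel=3)
        x = 0.0
    return f"{x:.10g}"


def nj_tree(matrix: DistanceMatrix) -> str:
    """Saitou-Nei neighbor joining; returns an unrooted tree in newick form.

    Deterministic: the joined pair minimizes the Q criterion with ties broken
    by label order; negative branch lengths are clamped to zero with a
    warning.  On an additive matrix the true topology and branch lengths are
    recovered exactly.
    """
    n = len(matrix.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    # active nodes: (sort_key, newick_fragment); distances in a dict-of-dicts
    nodes: List[str] = list(matrix.labels)
    frag: Dict[str, str] = {l: l for l in nodes}
    d: Dict[Tuple[str, str], float] = {}
    for i, a in enumerate(nodes):
        for j, b in enumerate(nodes):
            if i < j:
                d[(a, b)] = d[(b, a)] = float(matrix.values[i, j])

    while len(nodes) > 3:
        m = len(nodes)
        r = {a: sum(d[(a, b)] for b in nodes if b != a) for a in nodes}
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                a, b = nodes[i], nodes[j]
                q = (m - 2) * d[(a, b)] - r[a] - r[b]
                key = (q, a, b)
                if best is None or key < best:
                    best = key
        _, a, b = best
        dab = d[(a, b)]
        la = dab / 2.0 + (r[a] - r[b]) / (2.0 * (m - 2))
        lb = dab - la
        new = f"({frag[a]}:{_fmt_branch(la)},{frag[b]}:{_fmt_branch(lb)})"
        u = min(a, b)  # internal node inherits a deterministic sort key
        nodes = [x for x in nodes if x not in (a, b)]
        for k in nodes:
            duk = (d[(a, k)] + d[(b, k)] - dab) / 2.0
            d[(u, k)] = d[(k, u)] = duk
        nodes.append(u)
        nodes.sort()
        frag[u] = new

    a, b, c = nodes
    la = (d[(a, b)] + d[(a, c)] - d[(b, c)]) / 2.0
    lb = (d[(a, b)] + d[(b, c)] - d[(a, c)]) / 2.0
    lc = (d[(a, c)] + d[(b, c)] - d[(a, b)]) / 2.0
    return (
        f"({frag[a]}:{_fmt_branch(la)},{frag[b]}:{_fmt_branch(lb)},"
        f"{frag[c]}:{_fmt_branch(lc)});"
    )
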