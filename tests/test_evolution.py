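"""Alignment, NG86 vs a brute-force oracle, K2P, concatenation and NJ."""

import itertools
import math

import dendropy
import numpy as np
import pytest
from Bio.Seq import Seq

from mitocomp.evolution import (
    CodonAlignment,
    DistanceMatrix,
    align_codons_pairwise,
    concatenate_pcgs,
    k2p_distance,
    k2p_matrix,
    ng86,
    nj_tree,
    summarize_kaks,
)

# ---------------------------------------------------------------------------
# independent NG86 oracle: translation through Bio.Seq, explicit enumeration
# ---------------------------------------------------------------------------

BASES = "ACGT"
CODONS = ["".join(c) for c in itertools.product(BASES, repeat=3)]
AA = {c: str(Seq(c).translate(table=2)) for c in CODONS}
SENSE = [c for c in CODONS if AA[c] != "*"]


def oracle_sites(codon):
    """Synonymous sites by explicit neighbor enumeration (stops excluded)."""
    total = 0.0
    for pos in range(3):
        neighbors = [
            codon[:pos] + b + codon[pos + 1 :]
            for b in BASES
            if b != codon[pos]
        ]
        valid = [n for n in neighbors if AA[n] != "*"]
        if valid:
            total += sum(AA[n] == AA[codon] for n in valid) / len(valid)
    return total


def oracle_differences(ca, cb):
    """(Sd, Nd) averaged over stop-free change orderings, by recursion."""

    def paths(cur, remaining):
        if not remaining:
            return [(0, 0)]
        out = []
        for pos in remaining:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            if AA[nxt] == "*" and nxt != cb:
                continue
            step_syn = int(AA[cur] == AA[nxt]) if "*" not in (AA[cur], AA[nxt]) else 0
            for sd, nd in paths(nxt, remaining - {pos}):
                out.append((sd + step_syn, nd + (1 - step_syn)))
        return out

    remaining = {p for p in range(3) if ca[p] != cb[p]}
    results = paths(ca, remaining)
    if not results:
        return 0.0, float(len(remaining))
    return (
        sum(r[0] for r in results) / len(results),
        sum(r[1] for r in results) / len(results),
    )


class TestAlignment:
    def test_identical_cds_align_gapless(self):
        aln = align_codons_pairwise("ATGGCTAAA", "ATGGCTAAA")
        assert aln.a == aln.b == "ATGGCTAAA"

    def test_hand_alignment_with_codon_gap(self):
        aln = align_codons_pairwise("ATGGCTAAA", "ATGAAA")
        assert aln.a == "ATGGCTAAA"
        assert aln.b == "ATG---AAA"

    def test_swapping_arguments_transposes(self):
        fwd = align_codons_pairwise("ATGGCTAAA", "ATGAAA")
        rev = align_codons_pairwise("ATGAAA", "ATGGCTAAA")
        assert (rev.a, rev.b) == (fwd.b, fwd.a)

    def test_internal_stop_warns(self):
        with pytest.warns(UserWarning, match="internal stop"):
            align_codons_pairwise("ATGTAAAAA", "ATGGCTAAA")

    def test_whole_codon_gaps_only(self):
        aln = align_codons_pairwise("ATGGCTACTAAA", "ATGACTAAA")
        for i in range(0, len(aln.a), 3):
            for row in (aln.a, aln.b):
                codon = row[i : i + 3]
                assert codon == "---" or "-" not in codon


class TestNg86:
    def test_identical_sequences_zero_rates(self):
        rec = ng86(align_codons_pairwise("ATGGCTAAA", "ATGGCTAAA"))
        assert rec.Ka == 0.0 and rec.Ks == 0.0

    def test_worked_single_synonymous_difference(self):
        rec = ng86(align_codons_pairwise("ATGGCTAAA", "ATGGCCAAA"))
        assert rec.S == pytest.approx(5 / 3)
        assert rec.Sd == pytest.approx(1.0)
        assert rec.Nd == pytest.approx(0.0)
        assert rec.Ka == pytest.approx(0.0)
        assert rec.Ks == pytest.approx(-0.75 * math.log(0.2), abs=1e-4)  # ~1.207

    def test_site_counts_partition_total(self):
        rec = ng86(CodonAlignment("ATGGCTAAACTT", "ATGGCCAAACTA"))
        assert rec.S + rec.N == pytest.approx(3 * rec.codons_compared)

    def test_symmetry_under_sequence_swap(self):
        a, b = "ATGGCTACTCGA", "ATGACTACCCGC"
        r1 = ng86(CodonAlignment(a, b))
        r2 = ng86(CodonAlignment(b, a))
        for attr in ("S", "N", "Sd", "Nd"):
            assert getattr(r1, attr) == pytest.approx(getattr(r2, attr))

    def test_gapped_and_stop_codons_excluded(self):
        rec = ng86(CodonAlignment("ATG---TAAGCT", "ATGCCCTTTGCC"))
        assert rec.codons_compared == 2  # ATG and GCT columns only
        assert rec.codons_excluded == 2

    def test_saturation_reported_as_null(self):
        # every codon pair differs synonymously: pS = 1 >= 3/4
        rec = ng86(CodonAlignment("GCT" * 4, "GCC" * 4))
        assert rec.pS == pytest.approx(1.0)
        assert rec.Ks is None and rec.saturated

    def test_sites_match_oracle_on_all_sense_codons(self):
        from mitocomp.evolution import _syn_site_fractions

        for codon in SENSE:
            assert _syn_site_fractions(codon, 2) == pytest.approx(
                oracle_sites(codon)
            ), codon

    def test_differences_match_oracle_on_all_sense_pairs(self):
        from mitocomp.evolution import _path_differences

        for ca in SENSE:
            for cb in SENSE:
                got = _path_differences(ca, cb, 2)
                want = oracle_differences(ca, cb)
                assert got == pytest.approx(want), (ca, cb)


class TestSummaries:
    def _rec(self, ratio):
        return type("R", (), {"ratio": ratio})()

    def test_mean_and_sd(self):
        df = summarize_kaks({"g": [self._rec(0.5), self._rec(0.5)]})
        row = df.iloc[0]
        assert row.mean_kaks == pytest.approx(0.5)
        assert row.sd_kaks == pytest.approx(0.0)

    def test_null_ratios_excluded_with_count(self):
        df = summarize_kaks({"g": [self._rec(1.0), self._rec(None)]})
        row = df.iloc[0]
        assert row.mean_kaks == pytest.approx(1.0)
        assert row.n_excluded == 1

    def test_genes_ordered_ascending(self):
        df = summarize_kaks(
            {
                "slow": [self._rec(0.04)],
                "fast": [self._rec(1.1)],
                "mid": [self._rec(0.5)],
            }
        )
        assert list(df.gene) == ["slow", "mid", "fast"]

    def test_all_null_gene_gets_null_summary(self):
        df = summarize_kaks({"g": [self._rec(None)]})
        assert df.iloc[0].mean_kaks is None or np.isnan(df.iloc[0].mean_kaks)

    def test_planted_purifying_selection_recovered(self):
        from mitocomp.synthetic_data import generate_divergent_pair

        records = []
        for seed in range(5):
            a, b, _ = generate_divergent_pair(200, 0.08, 0.008, seed=seed)
            records.append(ng86(align_codons_pairwise(a, b)))
        df = summarize_kaks({"gene": records})
        assert df.iloc[0].mean_kaks < 1.0


class TestK2P:
    def test_identical_rows_zero(self):
        assert k2p_distance("ACGT", "ACGT") == 0.0

    def test_single_transition_in_four_sites(self):
        assert k2p_distance("AAAA", "AAAG") == pytest.approx(
            0.5 * math.log(2.0), abs=1e-4
        )  # ~0.3466

    def test_saturated_transversions_null(self):
        assert k2p_distance("AAAA", "CCCC") is None

    def test_gapped_columns_excluded(self):
        assert k2p_distance("AC-T", "ACNT") == 0.0

    def test_reduces_to_jc_under_symmetric_changes(self):
        # P = Q = p/2 makes K2P equal the one-parameter correction
        # -1/2 ln(1-2P-Q) - 1/4 ln(1-2Q) with P=2/12, Q=2/12
        row_a = "AAAAAAAAAAAA"
        row_b = "GAAAAACAAAAT"  # 1 transition, 2 transversions in 12
        d = k2p_distance(row_a, row_b)
        P, Q = 1 / 12, 2 / 12
        expected = -0.5 * math.log(1 - 2 * P - Q) - 0.25 * math.log(1 - 2 * Q)
        assert d == pytest.approx(expected)


class TestConcatenation:
    def test_supermatrix_width_and_partition_map(self):
        genes = {
            "g1": {"A": "ATGGCTAAA", "B": "ATGGCCAAA"},
            "g2": {"A": "ATGACTACTAAA", "B": "ATGACCACCAAA"},
        }
        matrix, parts = concatenate_pcgs(genes)
        assert len(matrix["A"]) == 21
        assert parts == [("g1", 1, 9), ("g2", 10, 21)]

    def test_missing_taxon_gets_gap_block(self):
        genes = {
            "g1": {"A": "ATGGCT", "B": "ATGGCC"},
            "g2": {"A": "ATGACT"},
        }
        matrix, _ = concatenate_pcgs(genes)
        assert matrix["B"].endswith("------")

    def test_partition_map_round_trips(self):
        genes = {
            "g1": {"A": "ATGGCT", "B": "ATGGCC"},
            "g2": {"A": "ATGACTACT", "B": "ATGACCACC"},
        }
        matrix, parts = concatenate_pcgs(genes)
        for gene, start, end in parts:
            for taxon in genes[gene]:
                assert matrix[taxon][start - 1 : end] == genes[gene][taxon]


def _additive_from_tree(n_taxa, rng):
    """Build a random tree; return (labels, matrix) with exact path distances."""
    labels = [f"t{i}" for i in range(n_taxa)]
    dist = {l: {} for l in labels}
    clusters = [[l] for l in labels]
    depth = {l: 0.0 for l in labels}  # distance from cluster root to leaf
    while len(clusters) > 1:
        idx = sorted(rng.choice(len(clusters), size=2, replace=False))
        cb = clusters.pop(idx[1])
        ca = clusters.pop(idx[0])
        la, lb = rng.uniform(0.05, 1.0, size=2)
        for x in ca:
            for y in cb:
                d = (depth[x] + la) + (depth[y] + lb)
                dist[x][y] = dist[y][x] = d
        for x in ca:
            depth[x] += la
        for y in cb:
            depth[y] += lb
        clusters.append(ca + cb)
    values = np.zeros((n_taxa, n_taxa))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i != j:
                values[i, j] = dist[a][b]
    return labels, values


class TestNeighborJoining:
    def test_four_taxon_additive_recovery(self):
        # tree ((A:2,B:3):1,(C:4,D:5)) gives these path distances
        m = np.array(
            [[0, 5, 7, 8], [5, 0, 8, 9], [7, 8, 0, 9], [8, 9, 9, 0]], float
        )
        newick = nj_tree(DistanceMatrix(("A", "B", "C", "D"), m))
        self._assert_distances_match(newick, ("A", "B", "C", "D"), m)

    def test_three_taxon_closed_form(self):
        m = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        newick = nj_tree(DistanceMatrix(("A", "B", "C"), m))
        tree = dendropy.Tree.get(data=newick, schema="newick")
        lengths = {
            leaf.taxon.label: leaf.edge.length for leaf in tree.leaf_node_iter()
        }
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0})

    def test_label_permutation_only_permutes_leaves(self):
        rng = np.random.default_rng(7)
        labels, values = _additive_from_tree(5, rng)
        perm = [3, 1, 4, 0, 2]
        permuted = DistanceMatrix(
            tuple(labels[i] for i in perm), values[np.ix_(perm, perm)]
        )
        t1 = dendropy.Tree.get(
            data=nj_tree(DistanceMatrix(tuple(labels), values)), schema="newick",
            taxon_namespace=dendropy.TaxonNamespace(labels),
        )
        t2 = dendropy.Tree.get(
            data=nj_tree(permuted), schema="newick",
            taxon_namespace=t1.taxon_namespace,
        )
        assert (
            dendropy.calculate.treecompare.symmetric_difference(t1, t2) == 0
        )

    @pytest.mark.parametrize("n_taxa", [5, 6, 7, 8])
    def test_random_additive_matrices_recovered_exactly(self, n_taxa):
        for seed in range(5):
            rng = np.random.default_rng(1000 * n_taxa + seed)
            labels, values = _additive_from_tree(n_taxa, rng)
            newick = nj_tree(DistanceMatrix(tuple(labels), values))
            self._assert_distances_match(newick, labels, values)

    def test_agrees_with_independent_nj_implementation(self):
        rng = np.random.default_rng(99)
        labels, values = _additive_from_tree(6, rng)
        # perturb away from additivity; topology should still agree
        noise = rng.uniform(0, 0.01, size=values.shape)
        noise = (noise + noise.T) / 2
        np.fill_diagonal(noise, 0)
        values = values + noise
        mine = nj_tree(DistanceMatrix(tuple(labels), values))
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=_pdm_csv(labels, values), delimiter=","
        )
        theirs = pdm.nj_tree()
        ns = theirs.taxon_namespace
        t1 = dendropy.Tree.get(data=mine, schema="newick", taxon_namespace=ns)
        assert (
            dendropy.calculate.treecompare.symmetric_difference(
                t1, theirs
            ) == 0
        )

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(("A", "B"), np.array([[0, 1], [1, 0]], float)))

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(("A", "B", "C"), np.array(
                [[0, 1, 2], [1, 0, 3], [9, 3, 0]], float
            ))

    @staticmethod
    def _assert_distances_match(newick, labels, values):
        tree = dendropy.Tree.get(data=newick, schema="newick")
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i < j:
                    got = pdm.distance(taxa[a], taxa[b])
                    assert got == pytest.approx(values[i, j], abs=1e-9), (a, b)


def _pdm_csv(labels, values):
    import io

    buf = io.StringIO()
    buf.write("," + ",".join(labels) + "\n")
    for i, l in enumerate(labels):
        buf.write(l + "," + ",".join(str(v) for v in values[i]) + "\n")
    buf.seek(0)
    return buf


class TestK2PMatrix:
    def test_matrix_from_rows(self):
        rows = {"A": "AAAA" * 2, "B": "AAAG" * 2, "C": "AAAACAAG"}
        dm = k2p_matrix(rows)
        assert dm.values.shape == (3, 3)
        assert dm.values.trace() == 0.0
        assert dm.get("A", "B") > 0

    def test_saturated_pair_is_error(self):
        with pytest.raises(ValueError, match="saturated"):
            k2p_matrix({"A": "AAAA", "B": "GGGG"})
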