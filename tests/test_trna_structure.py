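"""Cloverleaf folding: planted-geometry recovery, pair classes, comparisons."""

import numpy as np
import pytest

from mitocomp.synthetic_data import design_trna, _pick_geometry
from mitocomp.trna_structure import (
    MISMATCH,
    WATSON_CRICK,
    WOBBLE,
    classify_pair,
    classify_pairs,
    compare_across_species,
    fold_cloverleaf,
)


def _strong_trna(geometry, anticodon="GAA", seed=0):
    """A fixture tRNA with GC-only stems and A-only loops: its designed fold
    is the unique score maximum, so the folder must recover it exactly."""
    rng = np.random.default_rng(seed)
    probs = np.array([0.0, 0.5, 0.5, 0.0])  # stems G/C only
    seq, designed = design_trna(geometry, anticodon, rng, probs)
    # overwrite loops and variable loop with A (pairs with nothing here)
    from mitocomp.trna_structure import Arm, CloverleafStructure

    def a_loop(arm):
        return Arm(arm.stem5, "A" * len(arm.loop), arm.stem3)

    rebuilt = CloverleafStructure(
        acceptor5=designed.acceptor5,
        dhu=a_loop(designed.dhu) if designed.dhu else None,
        anticodon_arm=Arm(
            designed.anticodon_arm.stem5,
            "AA" + anticodon + "AA",
            designed.anticodon_arm.stem3,
        ),
        variable_loop="A" * len(designed.variable_loop),
        t_arm=a_loop(designed.t_arm),
        acceptor3=designed.acceptor3,
    )
    return rebuilt.flatten(), rebuilt


class TestPairClassification:
    @pytest.mark.parametrize(
        "pair,expected",
        [
            (("A", "T"), WATSON_CRICK),
            (("T", "A"), WATSON_CRICK),
            (("G", "C"), WATSON_CRICK),
            (("G", "T"), WOBBLE),
            (("T", "G"), WOBBLE),
            (("A", "G"), MISMATCH),
            (("A", "A"), MISMATCH),
        ],
    )
    def test_pair_classes(self, pair, expected):
        assert classify_pair(*pair) == expected


class TestFolding:
    def test_recovers_planted_canonical_geometry(self):
        # 7/4/5/5 arms with an 8 nt variable loop: 72 nt in total
        geometry = (7, 4, 8, 5, 8, 5, 7)  # (a, d, dl, c, v, t, tl)
        seq, designed = _strong_trna(geometry)
        assert len(seq) == 72
        fold = fold_cloverleaf(seq)
        assert fold is not None
        assert fold.arm_lengths == (7, 4, 5, 5)
        assert fold.flatten() == seq
        counts = classify_pairs(fold)
        assert sum(c[MISMATCH] for c in counts.values()) == 0

    def test_dhu_less_fixture_reports_absent_arm(self):
        geometry = (7, 0, 0, 5, 14, 5, 7)  # 62 nt, no DHU
        seq, _ = _strong_trna(geometry, anticodon="GCT")
        assert len(seq) == 62
        fold = fold_cloverleaf(seq, anticodon_hint="GCT")
        assert fold is not None
        assert fold.dhu is None
        assert fold.anticodon == "GCT"

    def test_unpairable_sequence_is_unfoldable(self):
        # A and C never pair with each other (no WC, no wobble)
        seq = ("AAC" * 24)[:70]
        assert fold_cloverleaf(seq) is None

    def test_length_bounds_enforced(self):
        with pytest.raises(ValueError, match="length"):
            fold_cloverleaf("ACGT" * 10)  # 40 nt, too short

    def test_determinism(self):
        seq, _ = _strong_trna((7, 4, 8, 5, 6, 5, 7), seed=5)
        a = fold_cloverleaf(seq)
        b = fold_cloverleaf(seq)
        assert a == b

    def test_score_monotone_in_pair_quality(self):
        """Turning a planted mismatch into a WC pair never lowers the score."""
        geometry = (7, 4, 8, 5, 6, 5, 7)
        seq, designed = _strong_trna(geometry)
        # plant a mismatch at the outermost acceptor pair
        broken = ("A" if seq[-1] != "T" else "C") + seq[1:]
        fold_broken = fold_cloverleaf(broken)
        fold_clean = fold_cloverleaf(seq)
        assert fold_broken is not None
        assert fold_clean.score >= fold_broken.score

    def test_anticodon_hint_constrains_placement(self, synthetic_record):
        from mitocomp.genome_io import extract_feature_sequence

        for feat in synthetic_record.by_category("tRNA")[:6]:
            seq = extract_feature_sequence(synthetic_record, feat.name).residues
            fold = fold_cloverleaf(seq, anticodon_hint=feat.anticodon)
            assert fold is not None
            assert fold.anticodon == feat.anticodon

    def test_reconstruction_invariant_on_generator_output(
        self, synthetic_record, synthetic_truth
    ):
        from mitocomp.genome_io import extract_feature_sequence

        n_match = n_clean = 0
        for feat in synthetic_record.by_category("tRNA"):
            seq = extract_feature_sequence(synthetic_record, feat.name).residues
            fold = fold_cloverleaf(seq, anticodon_hint=feat.anticodon)
            assert fold is not None, feat.name
            assert fold.flatten() == seq, feat.name
            truth = synthetic_truth.trna[feat.name]
            if not truth.clobbered:
                n_clean += 1
                if fold.arm_lengths == truth.designed_arm_lengths:
                    n_match += 1
        # documented tolerance: >= 80% of unclobbered tRNAs refold to the
        # designed geometry (alternatives may tie-break differently)
        assert n_match >= 0.8 * n_clean

    def test_planted_wobble_pairs_classified(self):
        rng = np.random.default_rng(3)
        probs = np.array([0.0, 0.5, 0.5, 0.0])
        seq, designed = design_trna(
            (7, 4, 8, 5, 6, 5, 7), "GAA", rng, probs, wobble_positions=2
        )
        counts = classify_pairs(designed)
        assert counts["acceptor"][WOBBLE] == 2


class TestGeometrySelection:
    def test_short_trnas_drop_dhu(self):
        assert _pick_geometry(62)[1] == 0

    def test_standard_lengths_keep_dhu(self):
        for length in (68, 70, 72, 76):
            a, d, dl, c, v, t, tl = _pick_geometry(length)
            assert d > 0, length


class TestComparison:
    def _structures(self, n, vary_variable_loop=False):
        out = {}
        for i in range(n):
            v = 6 + (i % 3 if vary_variable_loop else 0)
            geometry = (7, 4, 8, 5, v, 5, 7)
            seq, designed = _strong_trna(geometry, seed=0)
            out[f"sp{i}"] = designed
        return out

    def test_identical_structures_flagged(self):
        summary = compare_across_species(self._structures(13))
        assert summary.all_identical
        assert summary.n_sharing_modal_profile == 13

    def test_variable_loop_variation_recorded(self):
        summary = compare_across_species(self._structures(6, vary_variable_loop=True))
        assert summary.arm_length_ranges["acceptor"] == (7, 7)
        assert summary.variable_loop_range == (6, 8)

    def test_mixed_identities_rejected(self):
        a = self._structures(2)
        seq, other = _strong_trna((7, 4, 8, 5, 6, 5, 7), anticodon="TAC")
        a["other"] = other
        with pytest.raises(ValueError, match="mixed"):
            compare_across_species(a)

    def test_high_non_wc_flag(self):
        rng = np.random.default_rng(0)
        probs = np.array([0.0, 0.5, 0.5, 0.0])
        structures = {}
        for i in range(6):
            _, designed = design_trna(
                (7, 4, 8, 5, 6, 5, 7), "GAA", rng, probs, wobble_positions=2
            )
            structures[f"sp{i}"] = designed
        summary = compare_across_species(structures)
        assert summary.total_non_wc >= 10
        assert summary.high_non_wc
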