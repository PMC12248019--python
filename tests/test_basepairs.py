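"""Base-pair annotation, ingestion, topology, and F1 conventions."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import naassess as na
from naassess.basepairs import (BasePair, aggregate_f1, best_f1,
                                classify_topology, ingest_pairs,
                                parse_dotbracket, score_f1)


def brute_force_topology(pairs):
    """Literal O(n^2) crossing/singlet predicates (independent oracle)."""
    canon = sorted((p.i, p.j) for p in pairs
                   if p.klass == "canonical" and not p.intermolecular)
    crossed, singlet = set(), set()
    pair_set = set(canon)
    for (i, j) in canon:
        for (k, l) in canon:
            if (k, l) == (i, j):
                continue
            if i < k < j < l or k < i < l < j:
                crossed.add((i, j))
    for (i, j) in canon:
        if (i + 1, j - 1) not in pair_set and (i - 1, j + 1) not in pair_set:
            singlet.add((i, j))
    return crossed, singlet


class TestAnnotation:
    def test_hairpin_recovers_input_pairs(self, hairpin):
        pairs = na.annotate_pairs(hairpin)
        canon = {(p.i, p.j) for p in pairs if p.klass == "canonical"}
        assert canon == {(1, 12), (2, 11), (3, 10), (4, 9)}

    def test_extended_strand_has_no_pairs(self):
        s = na.build_structure(na.SecStructSpec("AAAAGGGG", "........"), seed=1)
        assert na.annotate_pairs(s) == []

    def test_duplex_pairs_are_intermolecular(self, duplex):
        pairs = na.annotate_pairs(duplex)
        canon = [p for p in pairs if p.klass == "canonical"]
        assert len(canon) == 6
        assert all(p.intermolecular for p in canon)

    def test_chain_without_base_atoms_warns(self, hairpin):
        s = hairpin.copy()
        for res in s.chains[0].residues:
            res.atoms.pop("N1", None)
            res.atoms.pop("N3", None)
        with pytest.warns(UserWarning, match="lacks base atoms"):
            assert na.annotate_pairs(s) == []


class TestIngestion:
    @pytest.mark.parametrize("text,expected", [
        ("((..))", {(1, 6), (2, 5)}),
        ("((..[[..))..]]", {(1, 10), (2, 9), (5, 14), (6, 13)}),
        ("..", set()),
        ("(<{[.]}>)", {(1, 9), (2, 8), (3, 7), (4, 6)}),
        ("AA..aa", {(1, 6), (2, 5)}),
    ])
    def test_dotbracket_decoding(self, text, expected):
        assert set(parse_dotbracket(text)) == expected

    @pytest.mark.parametrize("bad", ["((.)", ".))", "(]"])
    def test_unbalanced_brackets_report_position(self, bad):
        with pytest.raises(ValueError, match="position"):
            parse_dotbracket(bad)

    def test_chain_break_not_a_position(self):
        assert set(parse_dotbracket("((&))")) == {(1, 4), (2, 3)}

    def test_dotbracket_file(self, tmp_path):
        f = tmp_path / "ss.dbn"
        f.write_text(">t\nGGAACC\n((..))\n")
        pairs = ingest_pairs(f, format="dotbracket")
        assert {(p.i, p.j) for p in pairs} == {(1, 6), (2, 5)}

    def test_csv_with_duplicate_pair(self, tmp_path):
        f = tmp_path / "pairs.csv"
        f.write_text("chain_i,res_i,chain_j,res_j,klass\n"
                     "A,1,A,12,canonical\n"
                     "A,1,A,12,canonical\n"
                     "A,2,B,5,noncanonical\n")
        with pytest.warns(UserWarning, match="duplicate"):
            pairs = ingest_pairs(f, format="csv")
        assert len(pairs) == 2
        assert sum(p.intermolecular for p in pairs) == 1


class TestTopology:
    def test_crossed_and_singlet_worked_example(self):
        pairs = [BasePair(1, 10), BasePair(2, 9), BasePair(5, 15)]
        inv = classify_topology(pairs)
        assert {(p.i, p.j) for p in inv.crossed} == {(1, 10), (2, 9), (5, 15)}
        assert {(p.i, p.j) for p in inv.singlet} == {(5, 15)}

    def test_nested_stem_is_neither(self):
        inv = classify_topology([BasePair(1, 10), BasePair(2, 9), BasePair(3, 8)])
        assert not inv.crossed and not inv.singlet

    def test_lone_pair_is_singlet(self):
        inv = classify_topology([BasePair(4, 20)])
        assert not inv.crossed
        assert {(p.i, p.j) for p in inv.singlet} == {(4, 20)}

    def test_intermolecular_kept_out_of_topology(self):
        pairs = [BasePair(1, 10), BasePair(5, 15, intermolecular=True)]
        inv = classify_topology(pairs)
        assert not inv.crossed
        assert len(inv.intermolecular) == 1

    def test_empty_input(self):
        inv = classify_topology([])
        assert not inv.all_canonical and not inv.crossed and not inv.singlet

    @pytest.mark.parametrize("seed", range(40))
    def test_agrees_with_brute_force_on_random_structures(self, seed):
        spec = na.random_secstruct(60, seed=seed)
        raw = parse_dotbracket(spec.structure)
        pairs = [BasePair(i, j) for i, j in raw]
        inv = classify_topology(pairs)
        crossed, singlet = brute_force_topology(pairs)
        assert {(p.i, p.j) for p in inv.crossed} == crossed
        assert {(p.i, p.j) for p in inv.singlet} == singlet

    def test_crossing_is_symmetric(self):
        for seed in range(20):
            spec = na.random_secstruct(50, seed=seed)
            pairs = [BasePair(i, j) for i, j in parse_dotbracket(spec.structure)]
            inv = classify_topology(pairs)
            crossed = {(p.i, p.j) for p in inv.crossed}
            for (i, j) in crossed:
                partners = [(k, l) for (k, l) in
                            ((q.i, q.j) for q in inv.all_canonical)
                            if i < k < j < l or k < i < l < j]
                assert partners, f"({i},{j}) marked crossed without a partner"
                assert all((k, l) in crossed for k, l in partners)


class TestF1:
    def test_identity_scores_one(self):
        p = [BasePair(1, 10), BasePair(2, 9)]
        assert score_f1(p, list(p)).f1 == 1.0

    def test_partial_recall(self):
        pred = [BasePair(1, 10)]
        target = [BasePair(1, 10), BasePair(3, 8)]
        s = score_f1(pred, target)
        assert (s.precision, s.recall) == (1.0, 0.5)
        assert s.f1 == pytest.approx(2 / 3)

    def test_overprediction_scores_zero(self):
        s = score_f1([BasePair(1, 10)], [])
        assert s.f1 == 0.0 and not s.null_score

    def test_dual_absence_is_null(self):
        s = score_f1([], [])
        assert s.null_score and s.f1 is None

    def test_pairs_touching_unresolved_nucleotides_ignored(self):
        pred = [BasePair(1, 10), BasePair(2, 9)]
        target = [BasePair(1, 10)]
        s = score_f1(pred, target, unresolved={9})
        assert s.precision == 1.0 and s.recall == 1.0

    def test_removing_unresolved_never_changes_recall(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            target = {BasePair(int(i), int(i) + 10)
                      for i in rng.choice(50, size=5, replace=False)}
            pred = set(target) | {BasePair(60, 75)}
            base = score_f1(pred, target)
            masked = score_f1(pred, target, unresolved={60})
            assert masked.recall == base.recall

    @given(st.sets(st.tuples(st.integers(1, 30), st.integers(31, 60)),
                   max_size=8),
           st.sets(st.tuples(st.integers(1, 30), st.integers(31, 60)),
                   max_size=8))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_swap_symmetry_and_bounds(self, a, b):
        pa = [BasePair(i, j) for i, j in a]
        pb = [BasePair(i, j) for i, j in b]
        s_ab, s_ba = score_f1(pa, pb), score_f1(pb, pa)
        if s_ab.null_score:
            assert s_ba.null_score
        else:
            assert 0.0 <= s_ab.f1 <= 1.0
            if s_ab.precision is not None and s_ab.recall is not None:
                assert s_ab.precision == s_ba.recall
                assert s_ab.f1 == pytest.approx(s_ba.f1)


class TestAggregation:
    def test_best_of_models(self):
        scores = [score_f1([BasePair(1, 5)], [BasePair(1, 5), BasePair(2, 4)]),
                  score_f1([BasePair(1, 5), BasePair(2, 4)],
                           [BasePair(1, 5), BasePair(2, 4)])]
        assert best_f1(scores).f1 == 1.0

    def test_null_beats_numeric_across_references(self):
        scores = [score_f1([], [BasePair(1, 5)]),  # 0 against one reference
                  score_f1([], [])]                # null against the other
        assert best_f1(scores).null_score

    def test_missing_submission_contributes_zero(self):
        table = {"g": {"T1": [score_f1([BasePair(1, 5)], [BasePair(1, 5)])]}}
        means = aggregate_f1(table, targets=["T1", "T2"])
        assert means["g"] == pytest.approx(0.5)  # (1.0 + 0) / 2

    def test_null_targets_drop_out_of_mean(self):
        table = {"g": {"T1": [score_f1([], [])],
                       "T2": [score_f1([BasePair(1, 5)], [BasePair(1, 5)])]}}
        assert aggregate_f1(table, targets=["T1", "T2"])["g"] == 1.0

    def test_all_null_group_is_null(self):
        table = {"g": {"T1": [score_f1([], [])]}}
        assert aggregate_f1(table, targets=["T1"])["g"] is None
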