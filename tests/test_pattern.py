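"""Expression/sensitivity pattern normalization and Phi ranking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dascreen.pattern import (ExpressionExperiment, SensitivityPattern,
                              TargetPattern, aggregate_expression,
                              fitting_score, normalize_pattern, rank_by_phi,
                              read_expression_csv, select_top,
                              target_patterns, write_expression_csv)

LINES3 = ["x1", "x2", "x3"]


def exp(eid, iso, values):
    return ExpressionExperiment(eid, iso, values)


class TestAggregateExpression:
    def test_single_experiment_is_identity(self):
        e = exp("e1", "A", {"x1": 1.0, "x2": 2.0})
        assert aggregate_expression([e], "A") == {"x1": 1.0, "x2": 2.0}

    def test_mean_of_two(self):
        es = [exp("e1", "A", {"x": 2.0, "y": 0.0}),
              exp("e2", "A", {"x": 4.0, "y": 1.0})]
        assert aggregate_expression(es, "A")["x"] == pytest.approx(3.0)

    def test_available_case_mean_with_missing_lines(self):
        es = [exp(f"e{i}", "B", {"x": float(i), "y": 0.0}) for i in range(4)]
        es += [exp("e4", "B", {"y": 9.0, "z": 1.0}),
               exp("e5", "B", {"y": 9.0, "z": 3.0})]
        agg = aggregate_expression(es, "B")
        assert agg["x"] == pytest.approx(np.mean([0, 1, 2, 3]))
        assert agg["z"] == pytest.approx(2.0)

    def test_missing_isoform_is_error(self):
        with pytest.raises(ValueError, match="no experiments"):
            aggregate_expression([exp("e1", "A", {"x": 1, "y": 2})], "Z")


class TestNormalizePattern:
    def test_symmetric_case(self):
        out = normalize_pattern(dict(zip(LINES3, [1.0, 2.0, 3.0])))
        assert [out[l] for l in LINES3] == pytest.approx([-1.0, 0.0, 1.0])

    def test_constant_input_maps_to_zeros(self):
        out = normalize_pattern(dict(zip(LINES3, [5.0, 5.0, 5.0])))
        assert all(v == 0.0 for v in out.values())

    def test_asymmetric_hand_example(self):
        # mean 2, deviations (-2, -1, 3), max abs 3
        out = normalize_pattern(dict(zip(LINES3, [0.0, 1.0, 5.0])))
        assert [out[l] for l in LINES3] == pytest.approx([-2 / 3, -1 / 3, 1.0])

    def test_fewer_than_two_lines_rejected(self):
        with pytest.raises(ValueError):
            normalize_pattern({"x": 1.0})

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1),
           st.floats(0.01, 100.0), st.floats(-50.0, 50.0))
    def test_positive_affine_invariance(self, seed, a, b):
        rng = np.random.default_rng(seed)
        v = rng.normal(0, 10, size=rng.integers(2, 40))
        if np.ptp(v) == 0:
            v[0] += 1.0
        lines = [f"x{i}" for i in range(len(v))]
        base = normalize_pattern(dict(zip(lines, v)))
        scaled = normalize_pattern(dict(zip(lines, a * v + b)))
        negated = normalize_pattern(dict(zip(lines, -a * v + b)))
        for l in lines:
            assert scaled[l] == pytest.approx(base[l], abs=1e-9)
            assert negated[l] == pytest.approx(-base[l], abs=1e-9)

    def test_output_bounds_and_centering(self, rng):
        v = rng.normal(0, 3, 25)
        out = np.array(list(normalize_pattern(
            {f"x{i}": x for i, x in enumerate(v)}).values()))
        assert np.abs(out).max() == pytest.approx(1.0)
        assert np.all(np.abs(out) <= 1.0)
        assert out.sum() == pytest.approx(0.0, abs=1e-9)


class TestFittingScore:
    def test_identical_patterns_zero(self):
        p = dict(zip(LINES3, [0.5, -1.0, 1.0]))
        assert fitting_score(p, p) == 0.0

    def test_maximal_disagreement(self):
        nep = {"x1": 1.0, "x2": -1.0}
        ngi = {"x1": -1.0, "x2": 1.0}
        assert fitting_score(nep, ngi) == pytest.approx(4.0)

    def test_matches_elementwise_loop_oracle(self, rng):
        lines = [f"x{i}" for i in range(10)]
        a = dict(zip(lines, rng.uniform(-1, 1, 10)))
        b = dict(zip(lines, rng.uniform(-1, 1, 10)))
        oracle = sum(abs(a[l] - b[l]) for l in lines)
        assert fitting_score(a, b) == pytest.approx(oracle)

    def test_small_intersection_error_names_lines(self):
        with pytest.raises(ValueError, match="x2"):
            fitting_score({"x1": 0.0, "x2": 1.0}, {"x1": 0.0, "x9": 1.0})

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_metric_properties_on_random_triples(self, seed):
        rng = np.random.default_rng(seed)
        lines = [f"x{i}" for i in range(8)]
        x, y, z = (dict(zip(lines, rng.uniform(-1, 1, 8))) for _ in range(3))
        assert fitting_score(x, x) == 0.0
        assert fitting_score(x, y) == pytest.approx(fitting_score(y, x))
        assert fitting_score(x, z) <= \
            fitting_score(x, y) + fitting_score(y, z) + 1e-12


class TestRanking:
    def _targets(self, rng, isoforms=("A", "B", "C"), n_lines=12):
        lines = [f"x{i}" for i in range(n_lines)]
        return [TargetPattern(iso, normalize_pattern(
            dict(zip(lines, rng.normal(size=n_lines)))), 1)
            for iso in isoforms]

    def test_single_molecule_single_isoform_phi_equals_Phi(self, rng):
        targets = self._targets(rng, isoforms=("A",))
        lines = list(targets[0].nep)
        sp = SensitivityPattern("m", normalize_pattern(
            dict(zip(lines, rng.normal(size=len(lines))))))
        [fs] = rank_by_phi([sp], targets)
        assert fs.Phi == pytest.approx(fs.phi["A"])
        assert fs.rank == 1

    def test_pattern_matching_molecule_ranks_first_with_Phi_zero(self, rng):
        lines = [f"x{i}" for i in range(10)]
        nep = normalize_pattern(dict(zip(lines, rng.normal(size=10))))
        targets = [TargetPattern(iso, nep, 1) for iso in "ABC"]
        perfect = SensitivityPattern("hit", dict(nep))
        others = [SensitivityPattern(f"m{i}", normalize_pattern(
            dict(zip(lines, rng.normal(size=10))))) for i in range(5)]
        scores = rank_by_phi([perfect] + others, targets)
        assert scores[0].molecule_id == "hit"
        assert scores[0].Phi == pytest.approx(0.0)
        assert scores[0].rank == 1

    def test_ordering_matches_full_enumeration_oracle(self, rng):
        targets = self._targets(rng)
        lines = list(targets[0].nep)
        mols = [SensitivityPattern(f"m{i:02d}", normalize_pattern(
            dict(zip(lines, rng.normal(size=len(lines))))))
            for i in range(20)]
        scores = rank_by_phi(mols, targets)
        oracle = sorted(
            ((np.mean([fitting_score(t.nep, m.ngi) for t in targets]),
              m.molecule_id) for m in mols))
        assert [s.molecule_id for s in scores] == [mid for _, mid in oracle]
        assert [s.rank for s in scores] == list(range(1, 21))
        assert all(s.Phi == pytest.approx(phi)
                   for s, (phi, _) in zip(scores, oracle))

    def test_ties_broken_by_id(self):
        nep = {"x1": 1.0, "x2": -1.0}
        targets = [TargetPattern("A", nep, 1)]
        mols = [SensitivityPattern(mid, dict(nep)) for mid in
                ["zeta", "alpha", "mid"]]
        scores = rank_by_phi(mols, targets)
        assert [s.molecule_id for s in scores] == ["alpha", "mid", "zeta"]

    def test_select_top_slice_and_bounds(self, rng):
        targets = self._targets(rng)
        lines = list(targets[0].nep)
        mols = [SensitivityPattern(f"m{i:03d}", normalize_pattern(
            dict(zip(lines, rng.normal(size=len(lines))))))
            for i in range(106)]
        scores = rank_by_phi(mols, targets)
        top24 = select_top(scores, 24)
        ordered = [s.molecule_id for s in sorted(scores,
                                                 key=lambda s: s.rank)]
        assert top24 == ordered[:24]
        assert select_top(scores, 1) == [ordered[0]]
        assert select_top(scores, 1000) == ordered


class TestExpressionCsv:
    def test_round_trip(self, tmp_path, rng):
        es = [exp(f"{iso}_e{j}", iso,
                  {f"x{i}": float(rng.normal()) for i in range(5)})
              for iso in "AB" for j in range(2)]
        path = tmp_path / "expr.csv"
        write_expression_csv(es, path)
        back = read_expression_csv(path)
        assert [(e.experiment_id, e.isoform) for e in back] == \
            [(e.experiment_id, e.isoform) for e in es]
        for e1, e2 in zip(back, es):
            assert e1.values == pytest.approx(e2.values)

    def test_target_patterns_keeps_isoform_order(self, rng):
        es = [exp("c1", "C", {"x": 1.0, "y": 2.0}),
              exp("a1", "A", {"x": 3.0, "y": 0.0})]
        pats = target_patterns(es)
        assert [p.isoform for p in pats] == ["C", "A"]
        assert pats[0].n_experiments == 1
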