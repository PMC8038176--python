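"""Template building and the descriptor affinity score (DAS)."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dascreen.template import (DasScore, Template, TemplateEntry,
                               apply_das_cutoff, build_template, das_score,
                               score_matrix)
from .conftest import make_matrix


def brute_force_das(values, mu, sigma, eps_abs=1e-9):
    """Independent per-descriptor loop oracle for DAS."""
    n_eval = n_in = 0
    for v, m, s in zip(values, mu, sigma):
        if np.isnan(v):
            continue
        n_eval += 1
        eps = max(eps_abs, eps_abs * abs(m))
        if m - s - eps <= v <= m + s + eps:
            n_in += 1
    return n_in / n_eval, n_eval, n_in


def template_from_arrays(mu, sigma, built_from=10):
    entries = [TemplateEntry(f"d{j}", float(m), float(s), built_from)
               for j, (m, s) in enumerate(zip(mu, sigma))]
    return Template("synthetic-v1", entries, built_from)


class TestBuildTemplate:
    def test_two_actives_population_sd(self, matrix_factory):
        t = build_template(matrix_factory([[1.0], [3.0]]))
        assert t.entries[0].mu == pytest.approx(2.0)
        assert t.entries[0].sigma == pytest.approx(1.0)  # divide by N
        assert t.entries[0].n_used == 2

    def test_single_active_is_degenerate_all_sigma_zero(self, matrix_factory):
        t = build_template(matrix_factory([[5.0, -2.0]]))
        assert t.degenerate
        assert all(e.sigma == 0.0 for e in t.entries)

    def test_duplicating_actives_leaves_template_unchanged(self,
                                                           matrix_factory):
        values = [[1.0, 4.0], [3.0, 8.0], [2.0, 6.0]]
        t1 = build_template(matrix_factory(values))
        t2 = build_template(matrix_factory(values * 2))
        for e1, e2 in zip(t1.entries, t2.entries):
            assert e1.mu == pytest.approx(e2.mu)
            assert e1.sigma == pytest.approx(e2.sigma)

    def test_empty_matrix_rejected(self, matrix_factory):
        with pytest.raises(ValueError):
            build_template(make_matrix(np.empty((0, 3))))

    def test_all_missing_descriptor_dropped(self, matrix_factory):
        m = matrix_factory([[1.0, np.nan], [2.0, np.nan]])
        t = build_template(m)
        assert [e.name for e in t.entries] == ["d0"]

    def test_json_round_trip(self, tmp_path, matrix_factory):
        t = build_template(matrix_factory([[1.0, 4.0], [3.0, 8.0]]))
        t.to_json(tmp_path / "t.json")
        back = Template.from_json(tmp_path / "t.json")
        assert back == t


class TestDasScore:
    def test_query_at_mu_scores_one(self, matrix_factory):
        t = build_template(matrix_factory([[1.0, 4.0], [3.0, 8.0]]))
        q = pd.Series({"d0": 2.0, "d1": 6.0}, name="q")
        assert das_score(q, t).das == 1.0

    def test_query_at_mu_plus_two_sigma_scores_zero(self, matrix_factory):
        t = build_template(matrix_factory([[1.0, 4.0], [3.0, 8.0]]))
        q = pd.Series({"d0": 4.0, "d1": 10.0}, name="q")  # mu + 2*sigma
        assert das_score(q, t).das == 0.0

    def test_three_of_five_in_range(self):
        t = template_from_arrays(np.zeros(5), np.ones(5))
        q = pd.Series({f"d{j}": v for j, v in
                       enumerate([0.5, -0.5, 0.9, 5.0, -5.0])}, name="q")
        s = das_score(q, t)
        assert s.das == pytest.approx(0.6)
        assert (s.n_evaluated, s.n_in_range) == (5, 3)

    def test_sigma_zero_entries_satisfiable_at_boundary(self):
        t = template_from_arrays([2.0], [0.0], built_from=1)
        q = pd.Series({"d0": 2.0}, name="q")
        assert das_score(q, t).das == 1.0

    def test_missing_query_descriptors_shrink_denominator(self):
        t = template_from_arrays(np.zeros(4), np.ones(4))
        q = pd.Series({"d0": 0.0, "d1": 9.0, "d2": np.nan, "d3": np.nan},
                      name="q")
        s = das_score(q, t)
        assert s.n_evaluated == 2
        assert s.das == pytest.approx(0.5)

    def test_all_missing_is_error(self):
        t = template_from_arrays([0.0], [1.0])
        with pytest.raises(ValueError, match="undefined"):
            das_score(pd.Series({"d0": np.nan}, name="q"), t)

    def test_descriptor_set_mismatch_rejected(self, matrix_factory):
        t = build_template(matrix_factory([[1.0], [3.0]]))
        other = make_matrix([[2.0]], set_id="other-set")
        with pytest.raises(ValueError, match="mismatch"):
            score_matrix(other, t)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(1, 30)
        mu = rng.normal(0, 10, n)
        sigma = np.abs(rng.normal(0, 2, n))
        values = rng.normal(0, 10, n)
        values[rng.random(n) < 0.2] = np.nan
        if np.all(np.isnan(values)):
            values[0] = 0.0
        t = template_from_arrays(mu, sigma)
        q = pd.Series(dict(zip(t.names, values)), name="q")
        s = das_score(q, t)
        das, n_eval, n_in = brute_force_das(values, mu, sigma)
        assert s.das == pytest.approx(das, abs=0)
        assert (s.n_evaluated, s.n_in_range) == (n_eval, n_in)
        assert 0.0 <= s.das <= 1.0

    def test_flipping_one_descriptor_changes_das_by_one_over_n(self):
        rng = np.random.default_rng(7)
        mu, sigma = rng.normal(size=20), np.abs(rng.normal(size=20)) + 0.1
        t = template_from_arrays(mu, sigma)
        values = mu + 3 * sigma  # everything out of range
        q1 = pd.Series(dict(zip(t.names, values)), name="q")
        values2 = values.copy()
        values2[5] = mu[5]  # flip one into range
        q2 = pd.Series(dict(zip(t.names, values2)), name="q")
        delta = das_score(q2, t).das - das_score(q1, t).das
        assert delta == pytest.approx(1 / 20)

    def test_widening_sigma_never_decreases_das(self):
        rng = np.random.default_rng(11)
        mu, sigma = rng.normal(size=30), np.abs(rng.normal(size=30))
        values = rng.normal(0, 5, size=30)
        q = lambda t: pd.Series(dict(zip(t.names, values)), name="q")
        base = das_score(q(template_from_arrays(mu, sigma)),
                         template_from_arrays(mu, sigma)).das
        for k in (1.5, 2.0, 10.0):
            wide = template_from_arrays(mu, k * sigma)
            assert das_score(q(wide), wide).das >= base

    def test_actives_score_positive_against_own_template(self,
                                                         matrix_factory):
        rng = np.random.default_rng(3)
        m = matrix_factory(rng.normal(0, 1, (20, 15)))
        t = build_template(m)
        for s in score_matrix(m, t):
            assert s.das > 0


class TestApplyDasCutoff:
    def _scores(self, values):
        return [DasScore(f"m{i}", v, 10, int(round(v * 10)))
                for i, v in enumerate(values)]

    def test_cutoff_zero_keeps_all_in_order(self):
        scores = self._scores([0.3, 0.9, 0.1])
        assert apply_das_cutoff(scores, 0.0) == ["m0", "m1", "m2"]

    def test_cutoff_one_without_perfect_scores_empty(self):
        assert apply_das_cutoff(self._scores([0.3, 0.9]), 1.0) == []

    def test_invalid_cutoff_rejected(self):
        with pytest.raises(ValueError):
            apply_das_cutoff([], 1.5)

    def test_matches_direct_filter_oracle_on_100_scores(self, rng):
        values = rng.random(100)
        scores = self._scores(values)
        expected = [f"m{i}" for i, v in enumerate(values) if v >= 0.8]
        assert apply_das_cutoff(scores, 0.8) == expected
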