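"""Statistics tests: GSVA scoring vs a hand-executed random walk, ComBat,
mixed-model association, BH-FDR, AUC and exact Fisher tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from pmlsubtypes import (auc, bh_fdr, combat_adjust, enrichment, fisher_tests,
                        gsva_scores, mixed_association)

from conftest import make_dataset


# -- GSVA ----------------------------------------------------------------------

def oracle_gsva(values: pd.DataFrame, set_genes: list[str], tau: float = 1.0):
    """Hand-executed scoring: explicit loops for kernel CDF, ranks and walk."""
    x = values.to_numpy(dtype=float)
    p, n = x.shape
    genes = list(values.index)
    z = np.zeros_like(x)
    for i in range(p):
        s = x[i].std(ddof=1)
        h = s / 4 if s > 0 else 1.0
        for j in range(n):
            z[i, j] = np.mean([sps.norm.cdf((x[i, j] - x[i, k]) / h)
                               for k in range(n)])
    in_set = [genes.index(g) for g in set_genes]
    out = []
    for j in range(n):
        order = sorted(range(p), key=lambda i: (-z[i, j], i))
        ranks = {g: r + 1 for r, g in enumerate(order)}
        rstat = {i: abs(p / 2 - ranks[i]) for i in range(p)}
        denom = sum(rstat[i] ** tau for i in in_set)
        nu, vmax, vmin = 0.0, -math.inf, math.inf
        for i in order:
            if i in in_set:
                nu += rstat[i] ** tau / denom
            else:
                nu -= 1.0 / (p - len(in_set))
            vmax, vmin = max(vmax, nu), min(vmin, nu)
        out.append(max(vmax, 0.0) + min(vmin, 0.0))
    return np.array(out)


class TestGsva:
    def test_identical_samples_identical_scores(self):
        rng = np.random.default_rng(0)
        col = rng.normal(0, 1, 8)
        vals = np.column_stack([col, rng.normal(0, 1, 8), col, rng.normal(0, 1, 8)])
        ds = make_dataset(vals)
        m = gsva_scores(ds, {"S": ["g1", "g2", "g3"]})
        assert m.scores.loc["S", "s1"] == pytest.approx(m.scores.loc["S", "s3"], abs=1e-12)

    def test_hand_walk_oracle(self):
        rng = np.random.default_rng(1)
        ds = make_dataset(rng.normal(0, 1, (7, 5)))
        for genes in (["g1", "g2"], ["g2", "g5", "g7"], ["g1", "g3", "g4", "g6"]):
            m = gsva_scores(ds, {"S": genes})
            expected = oracle_gsva(ds.values, genes)
            assert np.allclose(m.scores.loc["S"].to_numpy(), expected, atol=1e-12)

    def test_top_ranked_set_scores_positive(self):
        # set genes dominate expression in sample 1 -> positive walk score;
        # a bottom-ranked complement scores negative there
        vals = np.array([
            [9.0, 1.0, 0.5],
            [8.0, 0.5, 1.0],
            [0.2, 5.0, 4.0],
            [0.1, 4.0, 5.0],
            [0.3, 4.5, 4.5],
        ])
        ds = make_dataset(vals)
        m = gsva_scores(ds, {"top": ["g1", "g2"], "bottom": ["g3", "g4", "g5"]})
        assert m.scores.loc["top", "s1"] > 0
        assert m.scores.loc["bottom", "s1"] < 0

    def test_monotone_response_to_in_set_upshift(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(0, 1, (10, 6))
        ds = make_dataset(vals)
        genes = ["g1", "g2", "g3"]
        before = gsva_scores(ds, {"S": genes}).scores.loc["S", "s2"]
        shifted = vals.copy()
        shifted[:3, 1] += 3.0
        after = gsva_scores(make_dataset(shifted), {"S": genes}).scores.loc["S", "s2"]
        assert after >= before - 1e-12

    def test_small_set_marked_undefined(self):
        rng = np.random.default_rng(3)
        ds = make_dataset(rng.normal(0, 1, (6, 4)))
        m = gsva_scores(ds, {"tiny": ["g1"], "ok": ["g1", "g2"]})
        assert "tiny" in m.undefined_sets
        assert m.scores.loc["tiny"].isna().all()
        assert m.scores.loc["ok"].notna().all()


# -- ComBat --------------------------------------------------------------------

class TestCombat:
    def test_single_batch_identity(self):
        rng = np.random.default_rng(4)
        vals = pd.DataFrame(rng.normal(0, 1, (20, 10)))
        batch = pd.Series(["A"] * 10, index=vals.columns)
        out = combat_adjust(vals, batch)
        assert np.abs(out.to_numpy() - vals.to_numpy()).max() < 1e-8

    def test_constant_shift_between_batches_removed(self):
        # a pure location shift: batch B repeats batch A's (per-gene
        # standardized) values plus a constant, so batch effects are identical
        # across genes and the EB posterior removes them exactly
        rng = np.random.default_rng(5)
        e = rng.normal(0, 1, (30, 10))
        e = (e - e.mean(axis=1, keepdims=True)) / e.std(axis=1, ddof=1, keepdims=True)
        mu = rng.normal(5, 1, (30, 1))
        vals = np.hstack([mu + e, mu + e + 3.0])
        df = pd.DataFrame(vals)
        batch = pd.Series(["A"] * 10 + ["B"] * 10, index=df.columns)
        out = combat_adjust(df, batch).to_numpy()
        gap = out[:, :10].mean(axis=1) - out[:, 10:].mean(axis=1)
        assert np.abs(gap).max() < 1e-6

    def test_batch_free_data_nearly_unchanged(self):
        rng = np.random.default_rng(6)
        vals = pd.DataFrame(rng.normal(0, 1, (50, 100)) + rng.normal(0, 2, (50, 1)))
        batch = pd.Series(["A"] * 50 + ["B"] * 50, index=vals.columns)
        out = combat_adjust(vals, batch).to_numpy()
        for g in range(50):
            r = np.corrcoef(out[g], vals.to_numpy()[g])[0, 1]
            assert r >= 0.99

    def test_singleton_batch_rejected(self):
        vals = pd.DataFrame(np.random.default_rng(7).normal(0, 1, (5, 5)))
        batch = pd.Series(["A", "A", "A", "A", "B"], index=vals.columns)
        with pytest.raises(ValueError, match="single sample"):
            combat_adjust(vals, batch)


# -- mixed-model association ---------------------------------------------------

def simulate_repeated(rng, n_subjects, per_subject, n_responses, effect=0.0, rho=0.3):
    n = n_subjects * per_subject
    subj = np.repeat(np.arange(n_subjects), per_subject)
    group = np.repeat(rng.random(n_subjects) < 0.5, per_subject)
    u = rng.normal(0, np.sqrt(rho / (1 - rho)), (n_subjects, n_responses))
    y = u[subj] + rng.normal(0, 1, (n, n_responses))
    y[group] += effect
    y = y / np.sqrt(1.0 / (1 - rho))          # total variance 1
    resp = pd.DataFrame(y.T, index=[f"r{i}" for i in range(n_responses)])
    # "treated" sorts after "control", so the treated level carries the coefficient
    return resp, np.where(group, "treated", "control"), [f"S{s}" for s in subj]


class TestMixedAssociation:
    def test_single_sample_per_subject_equals_ols(self):
        rng = np.random.default_rng(8)
        n = 40
        resp = pd.DataFrame(rng.normal(0, 1, (5, n)),
                            index=[f"r{i}" for i in range(5)])
        group = rng.choice(["a", "b"], n)
        subj = [f"S{i}" for i in range(n)]
        res = mixed_association(resp, group, subj)
        assert res.rho == 0.0
        x = np.column_stack([np.ones(n), (group == "b").astype(float)])
        for r in resp.index:
            y = resp.loc[r].to_numpy()
            beta, res_ss, *_ = np.linalg.lstsq(x, y, rcond=None)
            s2 = res_ss[0] / (n - 2)
            se = np.sqrt(s2 * np.linalg.inv(x.T @ x)[1, 1])
            t = beta[1] / se
            p = 2 * sps.t.sf(abs(t), n - 2)
            assert res.table.loc[r, "estimate"] == pytest.approx(beta[1], abs=1e-8)
            assert res.table.loc[r, "se"] == pytest.approx(se, abs=1e-8)
            assert res.table.loc[r, "pvalue"] == pytest.approx(p, abs=1e-8)

    def test_recovers_within_subject_correlation(self):
        rng = np.random.default_rng(9)
        resp, group, subj = simulate_repeated(rng, 60, 3, 150, rho=0.4)
        res = mixed_association(resp, group, subj)
        assert res.rho == pytest.approx(0.4, abs=0.06)

    def test_planted_effect_recovered(self):
        rng = np.random.default_rng(10)
        ests = []
        for _ in range(20):
            resp, group, subj = simulate_repeated(rng, 40, 3, 5, rho=0.3)
            resp.iloc[0] += np.where(np.array(group) == "treated", 1.0, 0.0)
            res = mixed_association(resp, group, subj)
            ests.append(res.table.loc["r0", "estimate"])
        assert np.mean(ests) == pytest.approx(1.0, abs=0.15)

    def test_all_one_subject_rejected(self):
        resp = pd.DataFrame(np.random.default_rng(11).normal(0, 1, (3, 10)))
        with pytest.raises(ValueError, match="one subject"):
            mixed_association(resp, ["a"] * 5 + ["b"] * 5, ["S1"] * 10)


# -- small inference utilities -------------------------------------------------

class TestBhFdr:
    def test_all_equal_p(self):
        q = bh_fdr([0.3, 0.3, 0.3])
        assert np.allclose(q, 0.3)

    def test_hand_step_up(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.5])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.5])

    def test_q_never_below_p_fuzz(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            p = rng.uniform(0, 1, rng.integers(1, 30))
            q = bh_fdr(p)
            assert (q >= p - 1e-12).all()

    def test_empty(self):
        assert bh_fdr([]).size == 0


class TestAuc:
    def test_perfect_separation(self):
        assert auc([1, 2, 3, 10, 11], [0, 0, 0, 1, 1]) == 1.0

    def test_tied_toy_equals_pair_counting(self):
        scores = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 5.0])
        labels = np.array([0, 0, 1, 0, 1, 1], dtype=bool)
        wins = ties = 0
        for i in np.where(labels)[0]:
            for j in np.where(~labels)[0]:
                if scores[i] > scores[j]:
                    wins += 1
                elif scores[i] == scores[j]:
                    ties += 1
        expected = (wins + 0.5 * ties) / (labels.sum() * (~labels).sum())
        assert auc(scores, labels) == pytest.approx(expected, abs=1e-12)

    def test_permutation_mean_half(self):
        rng = np.random.default_rng(13)
        scores = rng.normal(0, 1, 30)
        vals = [auc(scores, rng.permutation([1] * 15 + [0] * 15)) for _ in range(1000)]
        assert np.mean(vals) == pytest.approx(0.5, abs=0.01)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(14)
        scores = rng.normal(0, 1, 40)
        labels = rng.random(40) < 0.4
        a1 = auc(scores, labels)
        a2 = auc(np.exp(3 * scores), labels)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_one_class_empty_rejected(self):
        with pytest.raises(ValueError):
            auc([1, 2, 3], [1, 1, 1])


def oracle_rxc_exact(table: np.ndarray) -> float:
    """Independent exact test: enumerate all tables with the same margins."""
    rows, cols = table.sum(axis=1), table.sum(axis=0)
    n = table.sum()
    lognum = (sum(math.lgamma(v + 1) for v in rows)
              + sum(math.lgamma(v + 1) for v in cols) - math.lgamma(n + 1))

    def prob(t):
        return math.exp(lognum - sum(math.lgamma(v + 1) for v in np.ravel(t)))

    r, c = table.shape
    cells = []
    # enumerate row by row via cartesian products bounded by margins
    def all_tables(remaining_cols, row_idx):
        if row_idx == r - 1:
            if all(v >= 0 for v in remaining_cols):
                yield [list(remaining_cols)]
            return
        target = rows[row_idx]
        ranges = [range(min(target, remaining_cols[j]) + 1) for j in range(c)]
        for combo in itertools.product(*ranges):
            if sum(combo) != target:
                continue
            rest = tuple(remaining_cols[j] - combo[j] for j in range(c))
            for tail in all_tables(rest, row_idx + 1):
                yield [list(combo)] + tail

    p_obs = prob(table)
    total = 0.0
    for t in all_tables(tuple(cols), 0):
        pt = prob(np.array(t))
        if pt <= p_obs * (1 + 1e-9):
            total += pt
    return min(total, 1.0)


class TestFisher:
    def test_diagonal_2x2_hand_enumeration(self):
        p = fisher_tests(np.array([[5, 0], [0, 5]]))
        assert p == pytest.approx(2 / 252, rel=1e-9)

    def test_proportional_table_p_one(self):
        p = fisher_tests(np.array([[2, 4], [3, 6]]))
        assert p == pytest.approx(1.0)

    def test_2x3_exact_matches_enumeration_oracle(self):
        table = np.array([[5, 2, 3], [1, 6, 3]])
        assert table.sum() == 20
        p = fisher_tests(table)
        assert p == pytest.approx(oracle_rxc_exact(table), abs=1e-10)

    def test_3x3_exact_matches_enumeration_oracle(self):
        table = np.array([[4, 0, 1], [1, 3, 1], [0, 2, 3]])
        p = fisher_tests(table)
        assert p == pytest.approx(oracle_rxc_exact(table), abs=1e-10)

    def test_monte_carlo_close_to_exact(self):
        table = np.array([[5, 2, 3], [1, 6, 3]])
        exact = fisher_tests(table)
        mc = fisher_tests(table, seed=1, max_total_exact=1)
        assert mc == pytest.approx(exact, abs=0.01)

    def test_degenerate_margin_p_one(self):
        assert fisher_tests(np.array([[0, 0], [3, 4]])) == 1.0


class TestEnrichment:
    def test_module_equals_pathway_closed_form(self):
        universe = [f"g{i}" for i in range(100)]
        module = universe[:10]
        res = enrichment(module, {"path": module}, universe)
        expected = 1.0 / math.comb(100, 10)
        assert res.loc["path", "pvalue"] == pytest.approx(expected, rel=1e-9)

    def test_zero_overlap_near_one(self):
        universe = [f"g{i}" for i in range(100)]
        res = enrichment(universe[:5], {"path": universe[90:]}, universe)
        assert res.loc["path", "pvalue"] > 0.5

    def test_module_equals_universe_all_p_one(self):
        universe = [f"g{i}" for i in range(30)]
        res = enrichment(universe, {"a": universe[:7], "b": universe[5:20]}, universe)
        assert (res["pvalue"] == 1.0).all()

    def test_module_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            enrichment(["x"], {"p": ["a"]}, ["a", "b"])
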