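"""t-tests, BKY two-stage FDR, DEP calls, Kruskal-Wallis and Dunn."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multitest import fdrcorrection_twostage

from dbscreen.differential import (
    DepConfig,
    bky_two_stage_fdr,
    call_deps,
    dep_table,
    dunn_posthoc,
    kruskal_wallis,
    multi_t_test,
)
from dbscreen.matrix import ValidationError


def _frame(rows: np.ndarray, columns: list[str]) -> pd.DataFrame:
    return pd.DataFrame(
        rows,
        index=pd.Index([f"G{i}" for i in range(len(rows))], name="protein"),
        columns=columns,
    )


class TestMultiTTest:
    def test_identical_groups(self):
        rows = np.tile([1.0, 2.0, 3.0, 1.0, 2.0, 3.0], (4, 1))
        df = _frame(rows, ["A1", "A2", "A3", "B1", "B2", "B3"])
        res = multi_t_test(df, ["A1", "A2", "A3"], ["B1", "B2", "B3"])
        assert (res["t"] == 0).all()
        assert (res["p_value"] == 1).all()
        assert (res["log2_fold_change"] == 0).all()

    def test_exact_location_shift(self):
        df = _frame(
            np.array([[1.0, 2.0, 3.0, 3.0, 4.0, 5.0]]),
            ["A1", "A2", "A3", "B1", "B2", "B3"],
        )
        res = multi_t_test(df, ["A1", "A2", "A3"], ["B1", "B2", "B3"])
        assert res["log2_fold_change"].iloc[0] == pytest.approx(-2.0)

    def test_against_textbook_pooled_t(self):
        """50-protein random matrix vs the closed-form two-sample t."""
        rng = np.random.default_rng(12)
        df = _frame(rng.normal(10, 1, (50, 9)), [f"S{i}" for i in range(9)])
        ga, gb = [f"S{i}" for i in range(4)], [f"S{i}" for i in range(4, 9)]
        res = multi_t_test(df, ga, gb, variant="student")
        for g in df.index:
            a, b = df.loc[g, ga].to_numpy(), df.loc[g, gb].to_numpy()
            na, nb = len(a), len(b)
            sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
            t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
            p = 2 * stats.t.sf(abs(t), na + nb - 2)
            assert abs(res.loc[g, "t"] - t) < 1e-10
            assert abs(res.loc[g, "p_value"] - p) < 1e-10


class TestBkyTwoStage:
    def test_single_small_p_is_discovered(self):
        # stage 1 at alpha' = 0.05/1.05 rejects p = 0.004, so all (the one)
        # hypotheses are rejected at stage 1
        reject, q, m0 = bky_two_stage_fdr([0.004], alpha=0.05)
        assert reject.tolist() == [True]
        assert m0 == 0

    def test_all_ones_yields_nothing(self):
        reject, q, _ = bky_two_stage_fdr(np.ones(20), alpha=0.05)
        assert not reject.any()
        assert (q == 1.0).all()

    def test_out_of_range_p_is_error(self):
        with pytest.raises(ValidationError):
            bky_two_stage_fdr([0.5, 1.5])

    @pytest.mark.parametrize("case", range(30))
    def test_discovery_sets_match_independent_oracle(self, case):
        """Mixed null/alternative p-vectors against the independently
        implemented two-stage procedure in statsmodels."""
        rng = np.random.default_rng(1000 + case)
        m = int(rng.integers(5, 200))
        n_alt = int(rng.integers(0, m // 2 + 1))
        p = np.concatenate(
            [rng.beta(0.1, 10, n_alt), rng.uniform(0, 1, m - n_alt)]
        )
        rng.shuffle(p)
        reject, _, _ = bky_two_stage_fdr(p, alpha=0.05)
        oracle_reject, _, _, _ = fdrcorrection_twostage(
            p, alpha=0.05, method="bky", maxiter=1
        )
        assert reject.tolist() == oracle_reject.tolist()

    def test_q_discovery_consistency(self):
        rng = np.random.default_rng(5)
        p = np.concatenate([rng.beta(0.1, 10, 30), rng.uniform(0, 1, 170)])
        reject, q, m0 = bky_two_stage_fdr(p, alpha=0.05)
        # q <= alpha iff discovered (when the two-stage ran both stages)
        assert 0 < m0 < len(p)
        assert set(np.flatnonzero(q <= 0.05)) == set(np.flatnonzero(reject))


class TestCallDeps:
    def _results(self, q, log2fc):
        return pd.DataFrame(
            {
                "t": np.zeros(len(q)),
                "p_value": q,  # passthrough; BKY of tiny vector keeps order
                "log2_fold_change": log2fc,
                "fold_change_linear": np.exp2(log2fc),
            },
            index=pd.Index([f"G{i}" for i in range(len(q))], name="protein"),
        )

    def test_cutoff_rules(self):
        res = self._results(
            q=[1e-6, 1e-6, 1e-6], log2fc=[1.5, 0.5, -3.0]
        )
        out = call_deps(res, DepConfig(fold_change_basis="log2_means"))
        assert out["is_dep"].tolist() == [True, False, True]
        assert out["direction"].tolist() == ["up", "none", "down"]

    def test_q_above_cutoff_never_dep(self):
        res = self._results(q=[0.5], log2fc=[3.0])
        out = call_deps(res, DepConfig())
        assert not out["is_dep"].any()

    def test_lowering_q_cutoff_never_adds_deps(self):
        rng = np.random.default_rng(8)
        res = self._results(
            q=rng.uniform(0, 1, 100), log2fc=rng.normal(0, 2, 100)
        )
        loose = call_deps(res, DepConfig(q_cutoff=0.05))
        tight = call_deps(res, DepConfig(q_cutoff=0.005))
        assert set(tight.index[tight["is_dep"]]) <= set(loose.index[loose["is_dep"]])


class TestKruskalWallis:
    def test_three_group_closed_form(self):
        h, p = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert h == pytest.approx(7.2)
        assert p == pytest.approx(stats.chi2.sf(7.2, 2))

    def test_identical_values(self):
        h, p = kruskal_wallis([[5, 5], [5, 5, 5]])
        assert (h, p) == (0.0, 1.0)

    def test_tie_corrected_h_over_exhaustive_partitions(self):
        """Heavy-ties toy, N = 8: the tie-corrected H agrees with an
        independently coded rank-sum formula over every exhaustive
        partition of the pooled values."""
        pooled = np.array([1.0, 1.0, 2.0, 2.0, 2.0, 3.0, 3.0, 1.0])
        sizes = (3, 3, 2)
        n = len(pooled)
        ranks = stats.rankdata(pooled)
        _, counts = np.unique(pooled, return_counts=True)
        tie_factor = 1.0 - (counts**3 - counts).sum() / (n**3 - n)

        def oracle_h(assign):
            # 12/(N(N+1)) * sum R_i^2/n_i - 3(N+1), divided by the tie factor
            h = 12.0 / (n * (n + 1)) * sum(
                ranks[list(ix)].sum() ** 2 / len(ix) for ix in assign
            ) - 3.0 * (n + 1)
            return h / tie_factor

        idx = set(range(n))
        checked = 0
        for g1 in combinations(idx, sizes[0]):
            rest = idx - set(g1)
            for g2 in combinations(sorted(rest), sizes[1]):
                g3 = tuple(sorted(rest - set(g2)))
                groups = [pooled[list(ix)] for ix in (g1, g2, g3)]
                h, p = kruskal_wallis(groups)
                assert h == pytest.approx(oracle_h((g1, g2, g3)), abs=1e-10)
                if h > 0:
                    assert p == pytest.approx(stats.chi2.sf(h, 2), abs=1e-12)
                checked += 1
        assert checked == 560  # C(8,3) * C(5,3) ordered partitions



class TestDunn:
    def test_identical_groups_adjusted_p_one(self):
        res = dunn_posthoc([[1, 2, 3], [1, 2, 3]])
        assert res["p_adjusted"].iloc[0] == 1.0

    def test_closed_form_z_without_ties(self):
        groups = [[1.0, 2.0, 3.0], [4.0, 5.0, 6.0], [7.0, 8.0, 9.0]]
        res = dunn_posthoc(groups, labels=["a", "b", "c"])
        n = 9
        s2 = n * (n + 1) / 12  # no ties
        expected_ab = (2.0 - 5.0) / np.sqrt(s2 * (1 / 3 + 1 / 3))
        row = res[(res["group_a"] == "a") & (res["group_b"] == "b")].iloc[0]
        assert abs(row["z"] - expected_ab) < 1e-10

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(2)
        groups = [rng.normal(loc, 1, 6) for loc in (0, 0.5, 1.0, 2.0)]
        res = dunn_posthoc(groups)
        assert (res["p_adjusted"] >= res["p_value"] - 1e-15).all()
        assert (res["p_adjusted"] <= 1.0).all()


def test_power_recovery_in_newborn_vs_adult_design(demo_cohort):
    """Injected |log2 shift| >= 2 proteins are recovered with high
    sensitivity at n = 40 vs 8, and in the right direction."""
    from dbscreen.preprocess import impute_downshift, log2_transform, normalize_actb
    from dbscreen.preprocess import ImputeParams, filter_by_evidence

    matrix, meta, truth = demo_cohort
    newborns = list(meta.index[meta["group"] == "healthy_newborn"])
    adults = list(meta.index[meta["group"] == "healthy_adult"])
    filtered = filter_by_evidence(matrix, 2, newborns)
    imputed = impute_downshift(
        log2_transform(normalize_actb(filtered)), ImputeParams(seed=1)
    )
    deps = dep_table(imputed.values, newborns, adults)
    shifts = truth.effects.query("effect == 'newborn_shift'")
    strong = shifts[shifts["log2_shift"].abs() >= 2]
    hits = 0
    for _, row in strong.iterrows():
        protein = row["protein"]
        if protein not in deps.index:
            continue
        want = "up" if row["log2_shift"] > 0 else "down"
        hits += deps.loc[protein, "is_dep"] and deps.loc[protein, "direction"] == want
    assert hits / len(strong) >= 0.9
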