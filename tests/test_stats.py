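"""Statistical layer against hand-computation and enumeration oracles."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hypoperf import stats as hs


def _long(values, groups, timepoints=None):
    """Build a long table from a subjects x timepoints array."""
    values = np.asarray(values, float)
    n, t = values.shape
    timepoints = timepoints or [f"t{j}" for j in range(t)]
    rows = [
        {"subject": f"s{i}", "group": groups[i], "timepoint": timepoints[j],
         "value": values[i, j]}
        for i in range(n) for j in range(t)
    ]
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_2x2_toy_table_matches_hand_decomposition(self):
        # groups A (subjects s0, s1) and B (s2, s3); 2 timepoints
        y = np.array([[1.0, 2.0], [2.0, 3.0], [4.0, 6.0], [5.0, 7.0]])
        res = hs.mixed_anova(_long(y, ["A", "A", "B", "B"]))
        # hand computation: grand = 3.75
        # subject means: 1.5, 2.5, 5.0, 6.0; group means: 2.0, 5.5
        ss_group = 2 * (2 * (2.0 - 3.75) ** 2 + 2 * (5.5 - 3.75) ** 2)   # 24.5
        ss_bsub = 2 * ((1.5 - 3.75) ** 2 + (2.5 - 3.75) ** 2
                       + (5.0 - 3.75) ** 2 + (6.0 - 3.75) ** 2)          # 26.5
        ss_sw = ss_bsub - ss_group                                       # 2.0
        # time means: 3.0, 4.5; cells: A(1.5,2.5) B(4.5,6.5)
        ss_time = 4 * ((3.0 - 3.75) ** 2 + (4.5 - 3.75) ** 2)            # 4.5
        ss_cells = 2 * ((1.5 - 3.75) ** 2 + (2.5 - 3.75) ** 2
                        + (4.5 - 3.75) ** 2 + (6.5 - 3.75) ** 2)         # 29.25
        ss_int = ss_cells - ss_group - ss_time                           # 0.25
        assert res.table.loc["group", "ss"] == pytest.approx(ss_group, abs=1e-10)
        assert res.table.loc["subject(group)", "ss"] == pytest.approx(ss_sw, abs=1e-10)
        assert res.table.loc["time", "ss"] == pytest.approx(ss_time, abs=1e-10)
        assert res.table.loc["group:time", "ss"] == pytest.approx(ss_int, abs=1e-10)
        f_group = (ss_group / 1) / (ss_sw / 2)
        assert res.table.loc["group", "F"] == pytest.approx(f_group, abs=1e-10)

    def test_flat_noiseless_data_gives_zero_f(self):
        y = np.ones((6, 3))
        res = hs.mixed_anova(_long(y, ["A"] * 3 + ["B"] * 3))
        assert res.table.loc["group", "ss"] == pytest.approx(0.0, abs=1e-12)
        assert res.table.loc["group:time", "ss"] == pytest.approx(0.0, abs=1e-12)

    def test_single_subject_per_group_rejected(self):
        y = np.random.default_rng(0).random((2, 3))
        with pytest.raises(ValueError, match=">= 2 subjects"):
            hs.mixed_anova(_long(y, ["A", "B"]))

    def test_missing_cell_rejected(self):
        y = np.random.default_rng(0).random((4, 3))
        df = _long(y, ["A", "A", "B", "B"])
        df = df.drop(df.index[1])
        with pytest.raises(ValueError, match="missing"):
            hs.mixed_anova(df)

    def test_matches_pingouin_on_unbalanced_groups(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(1)
        y = rng.normal(size=(10, 7)) + np.linspace(0, 1, 7)
        df = _long(y, ["A"] * 6 + ["B"] * 4)
        res = hs.mixed_anova(df)
        aov = pg.mixed_anova(data=df, dv="value", within="timepoint",
                             between="group", subject="subject")
        ref = {r.Source: r for r in aov.itertuples()}
        assert res.table.loc["group", "F"] == pytest.approx(ref["group"].F, rel=1e-9)
        assert res.table.loc["time", "F"] == pytest.approx(
            ref["timepoint"].F, rel=1e-9
        )
        assert res.table.loc["group:time", "F"] == pytest.approx(
            ref["Interaction"].F, rel=1e-9
        )

    @given(st.integers(2, 5), st.integers(2, 5), st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_ss_conservation(self, n_per_group, n_time, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(size=(2 * n_per_group, n_time))
        res = hs.mixed_anova(_long(y, ["A"] * n_per_group + ["B"] * n_per_group))
        assert res.table["ss"].sum() == pytest.approx(res.ss_total, rel=1e-9)


class TestEtaSquared:
    def test_bounds(self):
        y = np.random.default_rng(2).random((6, 3))
        res = hs.mixed_anova(_long(y, ["A"] * 3 + ["B"] * 3))
        for eff in ("group", "time", "group:time"):
            assert 0.0 <= hs.eta_squared(res, eff) <= 1.0

    def test_zero_effect(self):
        y = np.tile(np.array([1.0, 2.0, 3.0]), (6, 1))
        res = hs.mixed_anova(_long(y, ["A"] * 3 + ["B"] * 3))
        assert hs.eta_squared(res, "group") == pytest.approx(0.0, abs=1e-12)

    def test_all_variance_in_one_effect(self):
        # only the time effect varies -> eta^2(time) = 1
        y = np.tile(np.array([1.0, 2.0, 4.0]), (4, 1))
        res = hs.mixed_anova(_long(y, ["A", "A", "B", "B"]))
        assert hs.eta_squared(res, "time") == pytest.approx(1.0, rel=1e-12)

    def test_generated_effect_share_recovered(self):
        # plant a pure group shift on top of unit noise and compare the
        # recovered eta^2 with the value computed from the realised data
        rng = np.random.default_rng(3)
        y = rng.normal(size=(20, 4))
        y[10:] += 1.0
        res = hs.mixed_anova(_long(y, ["A"] * 10 + ["B"] * 10))
        grand = y.mean()
        ss_tot = ((y - grand) ** 2).sum()
        gm = y[:10].mean(), y[10:].mean()
        ss_group = 4 * 10 * ((gm[0] - grand) ** 2 + (gm[1] - grand) ** 2)
        assert hs.eta_squared(res, "group") == pytest.approx(
            ss_group / ss_tot, rel=1e-9
        )


class TestLsd:
    def test_two_groups_equals_omnibus_t(self):
        rng = np.random.default_rng(4)
        y = rng.normal(size=(8, 3))
        y[4:] += 2.0
        res = hs.mixed_anova(_long(y, ["A"] * 4 + ["B"] * 4))
        post = hs.lsd_posthoc(res, "group")
        assert len(post) == 1
        assert post.t[0] ** 2 == pytest.approx(res.table.loc["group", "F"], rel=1e-9)
        assert post.p[0] == pytest.approx(res.p_value("group"), rel=1e-9)

    def test_three_group_toy_matches_explicit_formula(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=(9, 2))
        y[3:6] += 1.5
        y[6:] += 3.0
        groups = ["A"] * 3 + ["B"] * 3 + ["C"] * 3
        res = hs.mixed_anova(_long(y, groups))
        post = hs.lsd_posthoc(res, "group")
        # explicit-formula oracle on subject means
        sm = y.mean(axis=1)
        mse = sum(((sm[i:i + 3] - sm[i:i + 3].mean()) ** 2).sum()
                  for i in (0, 3, 6)) / 6
        from scipy import stats as sps

        for _, row in post.iterrows():
            ia = {"A": 0, "B": 3, "C": 6}[row.a]
            ib = {"A": 0, "B": 3, "C": 6}[row.b]
            t = (sm[ia:ia + 3].mean() - sm[ib:ib + 3].mean()) / np.sqrt(
                mse * (1 / 3 + 1 / 3)
            )
            assert row.t == pytest.approx(t, rel=1e-9)
            assert row.p == pytest.approx(2 * sps.t.sf(abs(t), 6), rel=1e-9)

    def test_refused_without_significant_omnibus(self):
        y = np.random.default_rng(6).normal(size=(6, 2)) * 0.01
        res = hs.mixed_anova(_long(y, ["A"] * 3 + ["B"] * 3))
        if res.p_value("group") >= 0.05:
            with pytest.raises(ValueError, match="omnibus"):
                hs.lsd_posthoc(res, "group")
        post = hs.lsd_posthoc(res, "group", override=True)
        assert len(post) == 1

    def test_identical_cells_p_one(self):
        y = np.tile(np.array([1.0, 2.0]), (6, 1))
        res = hs.mixed_anova(_long(y, ["A"] * 3 + ["B"] * 3))
        post = hs.lsd_posthoc(res, override=True, per_timepoint=True)
        assert (post.p == 1.0).all()


class TestMannWhitney:
    def test_identical_singletons(self):
        r = hs.mann_whitney_exact([1.0], [1.0])
        assert r["p"] == 1.0

    def test_fully_separated_five_vs_five(self):
        r = hs.mann_whitney_exact([1, 2, 3, 4, 5], [6, 7, 8, 9, 10])
        assert r["p"] == pytest.approx(2 / 252, rel=1e-12)
        assert r["method"] == "exact"

    def test_exact_equals_enumeration_oracle_all_small_partitions(self):
        # oracle: enumerate every assignment of ranks 1..N to sample A
        for n_total in range(2, 9):
            for n_a in range(1, n_total):
                values = np.arange(1.0, n_total + 1)
                n_b = n_total - n_a
                # null distribution of U by full enumeration
                us = []
                for comb in combinations(range(n_total), n_a):
                    ra = sum(c + 1 for c in comb)
                    us.append(ra - n_a * (n_a + 1) / 2)
                us = np.array(us)
                for comb in combinations(range(n_total), n_a):
                    a = values[list(comb)]
                    b = np.delete(values, list(comb))
                    mine = hs.mann_whitney_exact(a, b)
                    ra = a.sum()
                    u = ra - n_a * (n_a + 1) / 2
                    p_oracle = min(1.0, 2 * min((us <= u).mean(), (us >= u).mean()))
                    assert mine["p"] == pytest.approx(p_oracle, rel=1e-12), (
                        n_a, n_b, a.tolist()
                    )

    def test_tied_data_matches_permutation_oracle(self):
        rng = np.random.default_rng(7)
        a = np.array([1.0, 2.0, 2.0, 3.0, 5.0, 5.0, 6.0, 7.0, 8.0, 8.0, 9.0])
        b = np.array([2.0, 3.0, 3.0, 4.0, 5.0, 7.0, 7.0, 9.0, 9.0, 10.0])
        mine = hs.mann_whitney_exact(a, b)
        assert mine["method"] == "normal"
        pooled = np.concatenate([a, b])
        from scipy.stats import rankdata

        n = len(a)

        def ustat(perm):
            return rankdata(pooled)[perm].sum() - n * (n + 1) / 2

        u_obs = abs(hs.mann_whitney_exact(a, b)["U"] - len(a) * len(b) / 2)
        count = 0
        n_perm = 20000
        for i in range(n_perm):
            perm = rng.permutation(len(pooled))[:n]
            ranks = rankdata(pooled)
            u = ranks[perm].sum() - n * (n + 1) / 2
            if abs(u - len(a) * len(b) / 2) >= u_obs - 1e-9:
                count += 1
        p_mc = count / n_perm
        assert mine["p"] == pytest.approx(p_mc, abs=4 * np.sqrt(p_mc * (1 - p_mc) / n_perm) + 0.01)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            hs.mann_whitney_exact([], [1.0])


class TestTTestAndBonferroni:
    def test_identical_samples_p_one(self):
        r = hs.t_test_unpaired([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r["t"] == 0.0 and r["p"] == 1.0

    def test_textbook_hand_computation(self):
        a = np.array([5.0, 6.0, 7.0])
        b = np.array([1.0, 2.0, 3.0])
        # pooled s^2 = (2 + 2) / 4 = 1; t = 4 / sqrt(1 * 2/3)
        r = hs.t_test_unpaired(a, b)
        assert r["t"] == pytest.approx(4.0 / np.sqrt(2.0 / 3.0), rel=1e-12)
        from scipy import stats as sps

        assert r["p"] == pytest.approx(2 * sps.t.sf(r["t"], 4), rel=1e-12)

    def test_zero_variance_equal_means(self):
        r = hs.t_test_unpaired([2.0, 2.0], [2.0, 2.0])
        assert r["p"] == 1.0

    def test_bonferroni_scales_and_caps(self):
        assert hs.bonferroni([0.03], 2)[0] == pytest.approx(0.06)
        assert hs.bonferroni([0.7], 3)[0] == 1.0
        assert np.allclose(hs.bonferroni([0.01, 0.02]), [0.02, 0.04])
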