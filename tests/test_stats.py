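"""Tests for the split-plot ANOVA, sphericity correction and follow-ups.

The ANOVA is checked three independent ways: a worked toy example with sums
of squares computed by hand, a general-linear-model oracle built from
statsmodels OLS fits on random balanced designs, and pingouin's mixed ANOVA
for the single-between-factor case.
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import helmert

from avoidsim.model import ConfigurationError
from avoidsim.stats import (
    DataIntegrityError,
    bonferroni_ttests,
    gg_epsilon,
    mixed_anova,
    session_summary,
    weight_trajectory_summary,
)


def make_design(rng, n_between, levels, n_subj, k, effect=0.0):
    """Random balanced split-plot data set in long format."""
    rows = []
    subj = 0
    for cell in itertools.product(*[range(l) for l in levels[:n_between]]):
        for _ in range(n_subj):
            base = rng.normal()
            for w in range(k):
                y = base + rng.normal() + effect * w * (1 + sum(cell))
                rows.append((f"s{subj}", *[f"f{i}l{c}" for i, c in enumerate(cell)], w, y))
            subj += 1
    cols = ["subj"] + [f"f{i}" for i in range(n_between)] + ["w", "y"]
    return pd.DataFrame(rows, columns=cols)


def glm_oracle(data, dv, within, subject, between):
    """Split-plot F tests assembled from statsmodels OLS decompositions."""
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    frame = data.rename(columns={dv: "yy"})
    terms = "*".join([f"C({b}, Sum)" for b in between] + [f"C({within}, Sum)"])
    fit = ols(f"yy ~ {terms}", data=frame).fit()
    table = sm.stats.anova_lm(fit, typ=2)

    ss = {}
    for name, row in table.iterrows():
        if name == "Residual":
            continue
        effect = (
            name.replace(", Sum)", ")").replace("C(", "").replace(")", "")
            .replace(", Sum", "")
        )
        ss[tuple(effect.split(":"))] = row["sum_sq"]

    # between-subject stratum via a subjects-only fit
    subj_fit = ols("yy ~ C(subj)", data=frame.rename(columns={subject: "subj"})).fit()
    ss_between_total = subj_fit.ess
    k = data[within].nunique()
    between_effect_ss = sum(v for key, v in ss.items() if within not in key)
    within_effect_ss = sum(v for key, v in ss.items() if within in key)
    ss_subj_err = ss_between_total - between_effect_ss
    ss_total = np.sum((frame["yy"] - frame["yy"].mean()) ** 2)
    ss_within_err = ss_total - ss_between_total - within_effect_ss

    n_subj = data[subject].nunique()
    n_cells = int(np.prod([data[b].nunique() for b in between]))
    df_subj = n_subj - n_cells
    df_within = df_subj * (k - 1)
    out = {}
    for key, value in ss.items():
        df1 = np.prod([data[f].nunique() - 1 for f in key])
        if within in key:
            F = (value / df1) / (ss_within_err / df_within)
        else:
            F = (value / df1) / (ss_subj_err / df_subj)
        out[":".join(key)] = (value, F)
    return out, ss_subj_err, ss_within_err


class TestToyExample:
    """2 groups x 2 subjects x 2 sessions, sums of squares worked by hand."""

    @pytest.fixture()
    def toy(self):
        rows = [
            ("s1", "A", 1, 2.0), ("s1", "A", 2, 4.0),
            ("s2", "A", 1, 4.0), ("s2", "A", 2, 6.0),
            ("s3", "B", 1, 6.0), ("s3", "B", 2, 10.0),
            ("s4", "B", 1, 8.0), ("s4", "B", 2, 11.0),
        ]
        return pd.DataFrame(rows, columns=["subj", "grp", "sess", "y"])

    def test_hand_computed_decomposition(self, toy):
        tab = mixed_anova(toy, "y", within="sess", subject="subj", between=["grp"])
        assert tab["grp"].ss == pytest.approx(45.125)
        assert tab["sess"].ss == pytest.approx(15.125)
        assert tab["grp:sess"].ss == pytest.approx(1.125)
        assert tab.ss_subject_error == pytest.approx(6.25)
        assert tab.ss_within_error == pytest.approx(0.25)
        assert tab["grp"].F == pytest.approx(45.125 / 3.125)
        assert tab["sess"].F == pytest.approx(121.0)
        assert tab["grp:sess"].F == pytest.approx(9.0)
        assert tab["grp"].eta_p2 == pytest.approx(45.125 / 51.375)
        assert (tab["grp"].df1, tab["grp"].df2) == (1.0, 2.0)
        assert tab.epsilon == 1.0  # only two within levels

    def test_eta_identity_from_f_and_dfs(self, toy):
        """eta_p2 equals F*df1 / (F*df1 + df2) at uncorrected dfs."""
        tab = mixed_anova(toy, "y", within="sess", subject="subj", between=["grp"])
        for res in tab.effects:
            ident = res.F * res.df1 / (res.F * res.df1 + res.df2)
            assert res.eta_p2 == pytest.approx(ident, rel=1e-10)


class TestOracleEquivalence:
    def test_fifty_random_designs_match_glm(self):
        rng = np.random.default_rng(2024)
        for trial in range(50):
            n_between = rng.integers(1, 4)
            levels = [int(rng.integers(2, 4)) for _ in range(n_between)]
            n_subj = int(rng.integers(2, 4))
            k = int(rng.integers(2, 5))
            data = make_design(rng, n_between, levels, n_subj, k,
                               effect=rng.uniform(0, 1))
            between = [f"f{i}" for i in range(n_between)]
            tab = mixed_anova(data, "y", within="w", subject="subj", between=between)
            oracle, o_subj, o_within = glm_oracle(data, "y", "w", "subj", between)
            assert tab.ss_subject_error == pytest.approx(o_subj, abs=1e-8)
            assert tab.ss_within_error == pytest.approx(o_within, abs=1e-8)
            for res in tab.effects:
                key = res.effect
                o_ss, o_F = oracle[key]
                assert res.ss == pytest.approx(o_ss, abs=1e-8), key
                assert res.F == pytest.approx(o_F, abs=1e-8), key

    def test_matches_pingouin_single_between(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        data = make_design(rng, 1, [2], 8, 4, effect=0.3)
        ours = mixed_anova(data, "y", within="w", subject="subj", between=["f0"])
        theirs = pg.mixed_anova(data=data, dv="y", within="w",
                                subject="subj", between="f0")
        ref = {row.Source: row for row in theirs.itertuples()}
        assert ours["f0"].F == pytest.approx(ref["f0"].F, rel=1e-9)
        assert ours["w"].F == pytest.approx(ref["w"].F, rel=1e-9)
        assert ours["f0:w"].F == pytest.approx(ref["Interaction"].F, rel=1e-9)
        assert ours["f0"].eta_p2 == pytest.approx(ref["f0"].np2, rel=1e-9)

    def test_sum_of_squares_conservation(self):
        rng = np.random.default_rng(77)
        for _ in range(10):
            data = make_design(rng, 2, [2, 3], 3, 4, effect=0.5)
            tab = mixed_anova(data, "y", within="w", subject="subj",
                              between=["f0", "f1"])
            total = sum(r.ss for r in tab.effects) + tab.ss_subject_error + tab.ss_within_error
            assert total == pytest.approx(tab.ss_total, abs=1e-8)


class TestDegenerateAndInvalid:
    def test_constant_data_gives_zero_f(self):
        rows = [(f"s{i}", "A" if i < 2 else "B", w, 1.0)
                for i in range(4) for w in range(3)]
        data = pd.DataFrame(rows, columns=["subj", "grp", "w", "y"])
        tab = mixed_anova(data, "y", within="w", subject="subj", between=["grp"])
        assert all(r.F == 0.0 for r in tab.effects)

    def test_unbalanced_design_rejected(self):
        rng = np.random.default_rng(1)
        data = make_design(rng, 1, [2], 3, 3)
        data = data[data.subj != "s0"]
        with pytest.raises(DataIntegrityError):
            mixed_anova(data, "y", within="w", subject="subj", between=["f0"])

    def test_missing_within_level_rejected(self):
        rng = np.random.default_rng(1)
        data = make_design(rng, 1, [2], 3, 3)
        data = data.drop(data[(data.subj == "s0") & (data.w == 2)].index)
        with pytest.raises(DataIntegrityError):
            mixed_anova(data, "y", within="w", subject="subj", between=["f0"])


class TestGGEpsilon:
    def test_compound_symmetry_gives_one(self):
        S = np.full((4, 4), 0.3) + np.eye(4) * 0.7
        assert gg_epsilon(S) == pytest.approx(1.0)

    def test_rank_one_centered_covariance_hits_lower_bound(self):
        # covariance whose double-centered form is rank 1, k = 3
        x = np.array([1.0, 0.0, -1.0])
        S = np.outer(x, x)
        assert gg_epsilon(S) == pytest.approx(0.5)

    def test_matches_contrast_formula(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            k = int(rng.integers(2, 7))
            A = rng.normal(size=(k + 3, k))
            S = A.T @ A / (k + 2)
            C = helmert(k)  # orthonormal contrast, rows orthogonal to 1
            M = C @ S @ C.T
            lam = np.linalg.eigvalsh(M)
            naive = np.sum(lam) ** 2 / ((k - 1) * np.sum(lam**2))
            naive = np.clip(naive, 1 / (k - 1), 1.0)
            assert gg_epsilon(S) == pytest.approx(naive, rel=1e-10)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(2, 8), st.integers(0, 10**6))
    def test_bounds_property(self, k, seed):
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(k + 2, k))
        eps = gg_epsilon(A.T @ A)
        assert 1.0 / (k - 1) - 1e-12 <= eps <= 1.0 + 1e-12

    def test_reported_fractional_dfs_imply_valid_epsilon(self):
        # F(3.91, 140.6) on 11 and 396 df corresponds to eps ~ 0.355
        assert 1 / 11 <= 3.91 / 11 <= 1


class TestBonferroniTTests:
    def test_effect_size_r_from_reported_t(self):
        # t(18) = -3.044 must recover r = 0.58 (2 dp); build two n=10 samples
        # with exactly that pooled t by construction
        d = 3.044 * np.sqrt(2 / 10)  # mean difference at unit pooled variance
        base = np.array([-1.5, -1, -0.5, -0.25, 0, 0, 0.25, 0.5, 1, 1.5])
        base = base / base.std(ddof=1)
        [res] = bonferroni_ttests([("fem", base, base + d)])
        assert res.t == pytest.approx(-3.044, abs=1e-9)
        assert res.df == 18
        assert round(res.r, 2) == 0.58

    def test_identical_samples(self):
        x = np.arange(5.0)
        [res] = bonferroni_ttests([("same", x, x.copy())])
        assert res.t == 0.0 and res.r == 0.0

    def test_adjusted_p_is_capped(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=8), rng.normal(size=8)
        [res] = bonferroni_ttests([("a", x, y)], family_size=50)
        assert res.p_adjusted == min(1.0, res.p_raw * 50)
        assert res.p_adjusted <= 1.0

    def test_small_sample_rejected(self):
        with pytest.raises(ConfigurationError):
            bonferroni_ttests([("tiny", [1.0], [2.0, 3.0])])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6), st.integers(1, 30))
    def test_r_and_p_bounds(self, seed, family):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=6), rng.normal(size=6)
        [res] = bonferroni_ttests([("x", x, y)], family_size=family)
        assert 0.0 <= res.r <= 1.0
        assert res.p_raw <= res.p_adjusted <= 1.0


class TestSessionSummary:
    def make_trials(self, responses, latencies=None, itrs=0):
        n = len(responses)
        return pd.DataFrame({
            "sim": "s0", "phase": "acquisition", "session": 1,
            "trial": np.arange(1, n + 1),
            "response": responses,
            "latency": latencies if latencies is not None else [54] * n,
            "itr_seg1": itrs, "itr_seg2": itrs, "itr_seg3": itrs,
        })

    def test_proportion_avoidance(self):
        trials = self.make_trials(["avoidance"] * 5 + ["none"] * 15)
        out = session_summary(trials)
        assert out.prop_avoidance.iloc[0] == pytest.approx(0.25)

    def test_all_max_latency(self):
        trials = self.make_trials(["none"] * 20)
        assert session_summary(trials).mean_latency.iloc[0] == 54

    def test_zero_itrs(self):
        trials = self.make_trials(["none"] * 20)
        out = session_summary(trials)
        assert out[["itr_seg1", "itr_seg2", "itr_seg3", "mean_itr"]].iloc[0].sum() == 0

    def test_incomplete_records_rejected(self):
        a = self.make_trials(["none"] * 20)
        b = a.copy()
        b["sim"] = "s1"
        b = b.iloc[:-1]  # s1 misses a trial
        with pytest.raises(DataIntegrityError):
            session_summary(pd.concat([a, b], ignore_index=True))


class TestWeightSummary:
    def test_mean_of_two_constant_trajectories(self):
        rows = []
        for sim, value in (("a", 1.0), ("b", 3.0)):
            for trial in (1, 2):
                rows.append((sim, "acquisition", 1, trial, "warning", value, 0.5))
        w = pd.DataFrame(rows, columns=["sim", "phase", "session", "trial",
                                        "channel", "v", "m_press"])
        out = weight_trajectory_summary(w)
        assert np.allclose(out.v_mean, 2.0)
        assert np.allclose(out.m_press_mean, 0.5)

    def test_single_simulation_returns_own_trajectory(self):
        w = pd.DataFrame({
            "sim": "a", "phase": "acquisition", "session": 1,
            "trial": [1, 2], "channel": "warning", "v": [0.1, 0.2],
            "m_press": [0.0, 0.0],
        })
        out = weight_trajectory_summary(w)
        assert list(out.v_mean) == [0.1, 0.2]
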