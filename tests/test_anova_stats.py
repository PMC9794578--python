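import numpy as np
import pandas as pd
import pytest

from averp.anova_stats import DesignError, gg_epsilon, mixed_anova, pairwise, simple_effects
from conftest import make_long_table
from oracle_anova import brute_force_mixed_anova


def _res(df, wfs):
    return mixed_anova(df, "y", "subject", between=["A"], within=wfs).set_index("effect")


@pytest.fixture(scope="module")
def modality_table():
    rng = np.random.default_rng(0)
    rows = []
    for g, n in (("older", 18), ("younger", 20)):
        for s in range(n):
            for m in ("V", "A", "AV"):
                rows.append({"subject": f"{g}{s}", "age": g, "modality": m,
                             "y": rng.normal()})
    return pd.DataFrame(rows)


class TestDegreesOfFreedom:
    """df bookkeeping at the study's group sizes (18 + 20 subjects)."""

    def test_three_level_within_df(self, modality_table):
        res = mixed_anova(modality_table, "y", "subject",
                          between=["age"], within=["modality"]).set_index("effect")
        assert (res.loc["modality", "df_num"], res.loc["modality", "df_den"]) == (2, 72)

    def test_between_df(self, modality_table):
        res = mixed_anova(modality_table, "y", "subject",
                          between=["age"], within=["modality"]).set_index("effect")
        assert (res.loc["age", "df_num"], res.loc["age", "df_den"]) == (1, 36)

    def test_five_level_within_df(self):
        rng = np.random.default_rng(1)
        rows = [{"subject": f"{g}{s}", "age": g, "roi": f"r{r}", "y": rng.normal()}
                for g, n in (("older", 18), ("younger", 20))
                for s in range(n) for r in range(5)]
        res = mixed_anova(pd.DataFrame(rows), "y", "subject",
                          between=["age"], within=["roi"]).set_index("effect")
        assert (res.loc["roi", "df_num"], res.loc["roi", "df_den"]) == (4, 144)


class TestOracleEquivalence:
    @pytest.mark.parametrize("shape", [(2, 6, 3), (2, 5, 2, 4), (3, 4, 2, 3)])
    def test_matches_brute_force(self, shape, rng):
        Y = rng.normal(size=shape)
        df, wfs = make_long_table(Y)
        res = _res(df, wfs)
        for eff, o in brute_force_mixed_anova(Y).items():
            row = res.loc[eff]
            assert row["df_num"] == o["df_num"] and row["df_den"] == o["df_den"]
            assert row["F"] == pytest.approx(o["F"], rel=1e-8)

    def test_matches_pingouin_balanced(self, rng):
        """Independent library cross-check on a one-within mixed design."""
        pg = pytest.importorskip("pingouin")
        Y = rng.normal(size=(2, 10, 4))
        df, wfs = make_long_table(Y)
        res = _res(df, wfs)
        ref = pg.mixed_anova(data=df, dv="y", within="W1", subject="subject",
                             between="A").set_index("Source")
        assert res.loc["A", "F"] == pytest.approx(ref.loc["A", "F"], rel=1e-10)
        assert res.loc["W1", "F"] == pytest.approx(ref.loc["W1", "F"], rel=1e-10)
        assert res.loc["A x W1", "F"] == pytest.approx(ref.loc["Interaction", "F"], rel=1e-10)


class TestGreenhouseGeisser:
    def test_identity_covariance_gives_one(self):
        assert gg_epsilon(np.eye(4)) == pytest.approx(1.0)

    def test_rank_one_covariance_gives_lower_bound(self):
        v = np.array([1.0, 2.0, -1.0, 0.5])
        assert gg_epsilon(np.outer(v, v)) == pytest.approx(1.0 / 4)

    def test_random_psd_matches_direct_formula(self, rng):
        A = rng.normal(size=(5, 5))
        S = A @ A.T
        q = 5
        direct = np.trace(S) ** 2 / (q * np.trace(S @ S))
        assert gg_epsilon(S) == pytest.approx(max(1 / q, min(1.0, direct)))

    def test_non_symmetric_rejected(self):
        with pytest.raises(ValueError):
            gg_epsilon(np.array([[1.0, 2.0], [0.0, 1.0]]))

    def test_two_level_within_epsilon_exactly_one(self, rng):
        Y = rng.normal(size=(2, 8, 2))
        df, wfs = make_long_table(Y)
        res = _res(df, wfs)
        assert res.loc["W1", "eps_gg"] == pytest.approx(1.0)
        assert res.loc["W1", "p_gg"] == pytest.approx(res.loc["W1", "p"])

    def test_epsilon_within_bounds_random_data(self, rng):
        for _ in range(10):
            Y = rng.normal(size=(2, 9, 5))
            df, wfs = make_long_table(Y)
            eps = _res(df, wfs).loc["W1", "eps_gg"]
            assert 1 / 4 <= eps <= 1.0


class TestPartialEtaSquared:
    def test_in_unit_interval_and_matches_definition(self, rng):
        Y = rng.normal(size=(2, 6, 3)) + np.array([0.0, 0.5, 1.0])
        df, wfs = make_long_table(Y)
        res = _res(df, wfs)
        o = brute_force_mixed_anova(Y)["W1"]
        assert res.loc["W1", "pes"] == pytest.approx(o["ss"] / (o["ss"] + o["ss_err"]), rel=1e-8)
        assert ((res["pes"] >= 0) & (res["pes"] <= 1)).all()


class TestValidation:
    def test_missing_cell_rejected(self, rng):
        Y = rng.normal(size=(2, 4, 3))
        df, wfs = make_long_table(Y)
        with pytest.raises(DesignError):
            mixed_anova(df.iloc[:-1], "y", "subject", between=["A"], within=wfs)

    def test_duplicate_cell_rejected(self, rng):
        Y = rng.normal(size=(2, 4, 3))
        df, wfs = make_long_table(Y)
        dup = pd.concat([df, df.iloc[[0]]], ignore_index=True)
        with pytest.raises(DesignError):
            mixed_anova(dup, "y", "subject", between=["A"], within=wfs)

    def test_single_subject_group_rejected(self, rng):
        Y = rng.normal(size=(2, 4, 3))
        df, wfs = make_long_table(Y)
        sub = df[df["subject"] != "g0s0"]
        sub = sub[~((sub["A"] == "a0") & (sub["subject"].isin(["g0s1", "g0s2"])))]
        with pytest.raises(DesignError):
            mixed_anova(sub, "y", "subject", between=["A"], within=wfs)


class TestSimpleEffects:
    def test_flat_level_gives_null_result(self, rng):
        """No target-factor differences at one conditioning level -> F ~ 0."""
        rows = []
        for g in range(2):
            for s in range(6):
                base = rng.normal()
                for c in range(2):
                    for t in range(3):
                        effect = 0.0 if c == 0 else 2.0 * t
                        rows.append({"subject": f"g{g}s{s}", "A": f"a{g}",
                                     "C": f"c{c}", "T": f"t{t}",
                                     "y": base + effect + 1e-6 * rng.normal()})
        df = pd.DataFrame(rows)
        se = simple_effects(df, "y", "subject", target="T", conditioning=["C"],
                            between=["A"], within=["C", "T"]).set_index("C")
        assert se.loc["c0", "p"] > 0.5
        assert se.loc["c1", "p"] < 1e-6

    def test_crossover_interaction_both_significant(self, rng):
        rows = []
        for g, sign in (("a0", 1.0), ("a1", -1.0)):
            for s in range(10):
                for t, d in (("t0", 1.0), ("t1", -1.0)):
                    rows.append({"subject": f"{g}s{s}", "A": g, "T": t,
                                 "y": sign * d * 3.0 + rng.normal(scale=0.5)})
        df = pd.DataFrame(rows)
        se = simple_effects(df, "y", "subject", target="T", conditioning=["A"],
                            between=["A"], within=["T"]).set_index("A")
        assert (se["p"] < 0.01).all()

    def test_equals_mixed_anova_on_subset(self, rng):
        Y = rng.normal(size=(2, 6, 2, 3))
        df, wfs = make_long_table(Y)
        se = simple_effects(df, "y", "subject", target="W2", conditioning=["W1"],
                            between=["A"], within=wfs).set_index("W1")
        for lev in ("l0", "l1"):
            sub = df[df["W1"] == lev]
            ref = mixed_anova(sub, "y", "subject", between=["A"],
                              within=["W2"]).set_index("effect")
            assert se.loc[lev, "F"] == pytest.approx(ref.loc["W2", "F"], rel=1e-10)


class TestPairwise:
    def test_three_level_factor_gives_three_pairs(self, rng):
        df = pd.DataFrame({"subject": np.repeat([f"s{i}" for i in range(6)], 3),
                           "m": ["V", "A", "AV"] * 6, "y": rng.normal(size=18)})
        out = pairwise(df, "y", "subject", "m", paired=True)
        assert len(out) == 3

    def test_identical_distributions_p_near_one(self):
        df = pd.DataFrame({"subject": [f"s{i}" for i in range(8)] * 2,
                           "m": ["x"] * 8 + ["y"] * 8,
                           "y": list(range(8)) * 2})
        out = pairwise(df, "y", "subject", "m", paired=True)
        assert out["mean_diff"].iloc[0] == pytest.approx(0.0)

    def test_paired_t_matches_closed_form(self, rng):
        from scipy import stats
        a = rng.normal(size=10)
        b = a + 0.8 + rng.normal(scale=0.5, size=10)
        df = pd.DataFrame({"subject": [f"s{i}" for i in range(10)] * 2,
                           "m": ["x"] * 10 + ["y"] * 10,
                           "y": np.concatenate([a, b])})
        out = pairwise(df, "y", "subject", "m", paired=True)
        d = a - b
        t_ref = d.mean() / (d.std(ddof=1) / np.sqrt(10))
        assert out["t"].iloc[0] == pytest.approx(t_ref, rel=1e-10)
        assert out["p"].iloc[0] == pytest.approx(
            2 * stats.t.sf(abs(t_ref), 9), rel=1e-10)

    def test_holm_correction_monotone(self, rng):
        df = pd.DataFrame({"subject": np.repeat([f"s{i}" for i in range(8)], 3),
                           "m": ["V", "A", "AV"] * 8,
                           "y": rng.normal(size=24) + np.tile([0, 1, 2], 8)})
        out = pairwise(df, "y", "subject", "m", paired=True, correction="holm")
        assert (out["p_corr"] >= out["p"] - 1e-15).all()
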