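import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from inclinefield import (
    DesignError,
    factorial_anova,
    one_way_anova,
    partial_eta_sq,
    rm_anova_expected_observed,
    rm_anova_mixed,
    tukey_hsd,
)

# ---------------------------------------------------------------------------
# independent design-matrix oracle: sums of squares by sequential least
# squares on explicit dummy matrices (orthogonal on balanced designs)
# ---------------------------------------------------------------------------


def _dummies(col):
    return pd.get_dummies(col).to_numpy(dtype=float)


def _interact(*mats):
    out = mats[0]
    for m in mats[1:]:
        out = np.einsum("ij,ik->ijk", out, m).reshape(len(out), -1)
    return out


def _rss(X, y):
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return float(np.sum((y - X @ beta) ** 2))


def factorial_oracle(df, factors, response):
    y = df[response].to_numpy(dtype=float)
    n = len(y)
    X = np.ones((n, 1))
    rss_prev = _rss(X, y)
    ss = {}
    for r in range(1, len(factors) + 1):
        for term in itertools.combinations(factors, r):
            X = np.hstack([X, _interact(*[_dummies(df[f]) for f in term])])
            rss_new = _rss(X, y)
            ss[" x ".join(term)] = rss_prev - rss_new
            rss_prev = rss_new
    ss["residual"] = rss_prev
    return ss


def mixed_oracle(df, between, within, response, subject):
    """Split-plot oracle: between stratum from the subject-mean model,
    within stratum from models that absorb subject dummies."""
    y = df[response].to_numpy(dtype=float)
    w = df[within].nunique()
    subj = df.groupby(subject, observed=True).agg(
        {response: "mean", **{b: "first" for b in between}}
    )
    ss = dict(factorial_oracle(subj.reset_index(), between, response))
    ss = {k: v * w for k, v in ss.items()}
    ss["subjects_error"] = ss.pop("residual")

    X = np.hstack([np.ones((len(y), 1)), _dummies(df[subject])])
    rss_prev = _rss(X, y)
    for r in range(0, len(between) + 1):
        for bsub in itertools.combinations(between, r):
            term = (within,) + bsub
            X = np.hstack([X, _interact(*[_dummies(df[f]) for f in term])])
            rss_new = _rss(X, y)
            ss[" x ".join(term)] = rss_prev - rss_new
            rss_prev = rss_new
    ss["within_error"] = rss_prev
    return ss


def random_factorial(rng, levels=(3, 7), n=4, effects=True):
    rows = []
    for combo in itertools.product(*[range(k) for k in levels]):
        mu = sum((i + 1) * c for i, c in enumerate(combo)) if effects else 0.0
        for s in range(n):
            rows.append(
                {
                    "species": f"sp{combo[0]}",
                    "inclination": combo[1] if len(combo) > 1 else 0,
                    "subject_id": f"s{combo}-{s}",
                    "response": mu + rng.normal(0, 2),
                }
            )
    return pd.DataFrame(rows)


class TestPartialEtaSquared:
    def test_printed_species_row_identity(self):
        # the headline effect-size identity at its printed precision
        assert round(partial_eta_sq(76.7, 2, 189), 4) == 0.4480

    def test_zero_f_gives_zero(self):
        assert partial_eta_sq(0.0, 3, 10) == 0.0

    def test_matches_ss_ratio(self, rng):
        df = random_factorial(rng)
        res = factorial_anova(df)
        oracle = factorial_oracle(df, ["species", "inclination"], "response")
        for e in res.effects:
            ss_based = oracle[e.name] / (oracle[e.name] + oracle["residual"])
            assert e.eta_p2 == pytest.approx(ss_based, abs=1e-9)
            assert e.eta_p2 == pytest.approx(
                e.F * e.df1 / (e.F * e.df1 + e.df2), abs=1e-12
            )


class TestFactorialAnova:
    def test_all_equal_responses_give_zero_f(self):
        df = random_factorial(np.random.default_rng(0), effects=True)
        df["response"] = 5.0
        res = factorial_anova(df)
        for e in res.effects:
            assert e.F == 0.0

    def test_zero_within_cell_variance_flagged_degenerate(self):
        rows = []
        for sp in ("a", "b"):
            for inc in (0, 1):
                mu = 10.0 if (sp, inc) == ("b", 1) else 0.0
                for s in range(2):
                    rows.append(
                        dict(species=sp, inclination=inc, subject_id=f"{sp}{inc}{s}", response=mu)
                    )
        res = factorial_anova(pd.DataFrame(rows))
        assert res.degenerate
        assert np.isinf(res["species x inclination"].F)

    def test_unbalanced_design_rejected_with_cells_named(self):
        df = random_factorial(np.random.default_rng(1), levels=(2, 2), n=3)
        df = df.iloc[:-1]
        with pytest.raises(DesignError, match="unbalanced"):
            factorial_anova(df)

    def test_matches_design_matrix_oracle(self, rng):
        for _ in range(20):
            df = random_factorial(rng, levels=(3, 4), n=3)
            res = factorial_anova(df)
            oracle = factorial_oracle(df, ["species", "inclination"], "response")
            for e in res.effects:
                assert e.ss == pytest.approx(oracle[e.name], abs=1e-8)
            assert res.error_ss["residual"] == pytest.approx(
                oracle["residual"], abs=1e-8
            )

    def test_p_monotone_decreasing_in_f(self):
        ps = [float(sps.f.sf(F, 3, 20)) for F in (0.5, 1.0, 2.0, 4.0, 8.0)]
        assert all(a > b for a, b in zip(ps, ps[1:]))


def random_mixed(rng, n_between=(2, 3), n_subj=4, n_within=4, effect=1.0):
    rows = []
    levels = [range(k) for k in n_between]
    for combo in itertools.product(*levels):
        for s in range(n_subj):
            sid = f"s{combo}-{s}"
            base = rng.normal(0, 1)
            for wlev in range(n_within):
                rows.append(
                    {
                        "species": f"sp{combo[0]}",
                        "inclination": combo[1] if len(combo) > 1 else 0,
                        "subject_id": sid,
                        "sector": f"w{wlev}",
                        "response": base + effect * wlev * (combo[0] + 1) + rng.normal(0, 1),
                    }
                )
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_constant_within_levels_give_zero_within_f(self, rng):
        df = random_mixed(rng, effect=0.0)
        wide = df.pivot_table(index="subject_id", columns="sector", values="response")
        flat = df.copy()
        flat["response"] = flat.groupby("subject_id")["response"].transform("mean")
        res = rm_anova_mixed(flat, between=["species", "inclination"], within="sector")
        assert res["sector"].F == pytest.approx(0.0, abs=1e-18)

    def test_two_level_within_equals_squared_paired_t(self, rng):
        # single between-cell design: within F must equal the paired t^2
        rows = []
        for s in range(12):
            base = rng.normal(0, 1)
            rows.append(dict(species="a", inclination=0, subject_id=f"s{s}", sector="w0", response=base + rng.normal(0, 1)))
            rows.append(dict(species="a", inclination=0, subject_id=f"s{s}", sector="w1", response=base + 1.0 + rng.normal(0, 1)))
        df = pd.DataFrame(rows)
        # need a 2-level between factor for the engine; split into two halves
        df["grp"] = np.where(df["subject_id"].str[1:].astype(int) < 6, "g0", "g1")
        res = rm_anova_mixed(df, between=["grp"], within="sector")
        wide = df.pivot_table(index=["subject_id", "grp"], columns="sector", values="response").reset_index()
        d = wide["w0"] - wide["w1"]
        # paired t within the split-plot: t^2 pooled over groups equals the
        # sector F when group sizes are equal
        g0 = d[wide["grp"] == "g0"]
        g1 = d[wide["grp"] == "g1"]
        pooled_var = (g0.var(ddof=1) * (len(g0) - 1) + g1.var(ddof=1) * (len(g1) - 1)) / (
            len(d) - 2
        )
        t2 = (d.mean() / np.sqrt(pooled_var / len(d))) ** 2
        assert res["sector"].F == pytest.approx(t2, rel=1e-9)

    def test_matches_design_matrix_oracle(self, rng):
        for _ in range(10):
            df = random_mixed(rng)
            res = rm_anova_mixed(df, between=["species", "inclination"], within="sector")
            oracle = mixed_oracle(
                df, ["species", "inclination"], "sector", "response", "subject_id"
            )
            for e in res.effects:
                assert e.ss == pytest.approx(oracle[e.name], abs=1e-8), e.name
            assert res.error_ss["subjects"] == pytest.approx(
                oracle["subjects_error"], abs=1e-8
            )
            assert res.error_ss["within"] == pytest.approx(
                oracle["within_error"], abs=1e-8
            )

    def test_agrees_with_pingouin_single_between(self, rng):
        pg = pytest.importorskip("pingouin")
        df = random_mixed(rng, n_between=(2,), n_subj=6, n_within=3)
        mine = rm_anova_mixed(df, between=["species"], within="sector")
        theirs = pg.mixed_anova(
            data=df, dv="response", within="sector", subject="subject_id", between="species"
        ).set_index("Source")
        assert mine["species"].F == pytest.approx(theirs.loc["species", "F"], rel=1e-9)
        assert mine["sector"].F == pytest.approx(theirs.loc["sector", "F"], rel=1e-9)
        assert mine["sector x species"].F == pytest.approx(
            theirs.loc["Interaction", "F"], rel=1e-9
        )

    def test_missing_within_level_rejected(self, rng):
        df = random_mixed(rng)
        df = df[~((df.subject_id == df.subject_id.iloc[0]) & (df.sector == "w0"))]
        with pytest.raises(DesignError):
            rm_anova_mixed(df, between=["species", "inclination"], within="sector")

    def test_split_plot_df_structure(self, rng):
        """3 species x 7 inclinations x 10 subjects x 12 sectors yields the
        canonical df pairs: between (2, 189), within main (11, 2079)."""
        df = random_mixed(rng, n_between=(3, 7), n_subj=10, n_within=12, effect=0.1)
        res = rm_anova_mixed(df, between=["species", "inclination"], within="sector")
        assert (res["species"].df1, res["species"].df2) == (2, 189)
        assert (res["inclination"].df1, res["inclination"].df2) == (6, 189)
        assert (res["sector"].df1, res["sector"].df2) == (11, 2079)


class TestExpectedObserved:
    def _table(self, rng, shift=0.0, interaction=0.0):
        rows = []
        for inc in range(7):
            for s in range(10):
                sid = f"i{inc}s{s}"
                exp = rng.normal(10, 1)
                obs = exp + shift + interaction * inc + rng.normal(0, 0.5)
                rows.append(dict(subject_id=sid, inclination=inc, condition="expected", response=exp))
                rows.append(dict(subject_id=sid, inclination=inc, condition="observed", response=obs))
        return pd.DataFrame(rows)

    def test_observed_equals_expected_gives_zero_within_f(self, rng):
        df = self._table(rng, shift=0.0)
        df.loc[df.condition == "observed", "response"] = df.loc[
            df.condition == "expected", "response"
        ].to_numpy()
        res = rm_anova_expected_observed(df)
        assert res["condition"].F == pytest.approx(0.0, abs=1e-18)

    def test_constant_offset_hits_within_not_interaction(self, rng):
        df = self._table(rng, shift=5.0, interaction=0.0)
        res = rm_anova_expected_observed(df)
        assert res["condition"].p < 1e-6
        assert res["condition x inclination"].p > 0.01

    def test_matches_oracle(self, rng):
        df = self._table(rng, shift=3.0, interaction=0.5)
        res = rm_anova_expected_observed(df)
        oracle = mixed_oracle(df, ["inclination"], "condition", "response", "subject_id")
        for e in res.effects:
            assert e.ss == pytest.approx(oracle[e.name], abs=1e-8)


class TestOneWayAnova:
    def test_equal_means_near_zero_f(self):
        groups = [np.array([1.0, 2.0, 3.0]), np.array([2.0, 1.0, 3.0])]
        res = one_way_anova(groups)
        assert res["group"].F == pytest.approx(0.0, abs=1e-12)

    def test_two_groups_f_equals_t_squared(self, rng):
        a, b = rng.normal(0, 1, 8), rng.normal(1, 1, 8)
        res = one_way_anova([a, b])
        t, p = sps.ttest_ind(a, b)
        assert res["group"].F == pytest.approx(t**2, rel=1e-10)
        assert res["group"].p == pytest.approx(p, rel=1e-10)

    def test_matches_textbook_ss(self, rng):
        groups = [rng.normal(i, 1, 5) for i in range(3)]
        res = one_way_anova(groups)
        f, p = sps.f_oneway(*groups)
        assert res["group"].F == pytest.approx(f, rel=1e-10)
        assert res["group"].p == pytest.approx(p, rel=1e-10)
        assert (res["group"].df1, res["group"].df2) == (2, 12)


class TestTukeyHSD:
    def test_identical_groups_nothing_significant(self):
        g = np.array([1.0, 2.0, 3.0, 4.0])
        res = tukey_hsd([g, g + 0.01, g - 0.01])
        assert res.significant_pairs() == []

    def test_shifted_group_pairs_significant(self, rng):
        base = rng.normal(0, 1, 10)
        shifted = rng.normal(10, 1, 10)
        res = tukey_hsd([base, rng.normal(0, 1, 10), shifted], ["a", "b", "c"])
        sig = set(map(frozenset, res.significant_pairs()))
        assert frozenset(("a", "c")) in sig
        assert frozenset(("b", "c")) in sig
        assert frozenset(("a", "b")) not in sig

    @pytest.mark.parametrize(
        "k,df,q_expected",
        [
            (3, 12, 3.773),  # published studentized-range table entries
            (2, 60, 2.829),
            (4, 20, 3.958),
            (5, 30, 4.102),
        ],
    )
    def test_q_critical_values_match_published_table(self, k, df, q_expected):
        q = sps.studentized_range.ppf(0.95, k, df)
        assert q == pytest.approx(q_expected, abs=2e-3)

    def test_p_consistent_with_q_distribution(self, rng):
        groups = [rng.normal(i * 0.8, 1, 6) for i in range(3)]
        res = tukey_hsd(groups)
        df_err = 15
        for row in res.table.itertuples():
            p_from_q = float(sps.studentized_range.sf(row.q, 3, df_err))
            assert row.p == pytest.approx(p_from_q, abs=1e-6)
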