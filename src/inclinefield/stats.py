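"""The statistical layer: balanced factorial and split-plot ANOVAs,
one-way ANOVA, Tukey HSD, and partial eta-squared.

All designs here are balanced by construction (equal group sizes per
cell), which the engine verifies before decomposing.  Sums of squares are
computed by inclusion-exclusion over marginal means: for a term T (a set
of factors), the per-observation effect is

    e_T = sum over subsets S of T of (-1)^(|T|-|S|) * mean over the S margin

and SS_T is the sum of e_T^2 over observations — the classical balanced
decomposition, identical to sequential least squares on an orthogonal
design.  The split-plot (mixed repeated-measures) layout tests
between-subject terms against subjects-within-cells and within-subject
terms against the subject-by-within residual, with uncorrected degrees of
freedom by default; a Greenhouse-Geisser correction of the within tests
is available behind a flag.

Partial eta-squared is SS_effect / (SS_effect + SS_error of its stratum),
which for any reported effect equals F*df1 / (F*df1 + df2).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DesignError

ALPHA = 0.05


def partial_eta_sq(F: float, df1: int, df2: int) -> float:
    """Partial eta-squared recovered from an F statistic and its df pair."""
    if F < 0 or df1 < 1 or df2 < 1:
        raise ValueError("need F >= 0, df1 >= 1, df2 >= 1")
    if np.isinf(F):
        return 1.0
    return (F * df1) / (F * df1 + df2)


@dataclass(frozen=True)
class EffectResult:
    name: str
    ss: float
    df1: int
    df2: int
    F: float
    p: float
    eta_p2: float
    error_stratum: str = "residual"


@dataclass
class AnovaResult:
    """Effect table of one ANOVA, plus its error strata."""

    effects: list[EffectResult]
    error_ss: dict[str, float]
    error_df: dict[str, int]
    design: str = ""
    degenerate: bool = False  # zero error variance somewhere

    def __getitem__(self, name: str) -> EffectResult:
        for e in self.effects:
            if e.name == name:
                return e
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "effect": [e.name for e in self.effects],
                "SS": [e.ss for e in self.effects],
                "df1": [e.df1 for e in self.effects],
                "df2": [e.df2 for e in self.effects],
                "F": [e.F for e in self.effects],
                "p": [e.p for e in self.effects],
                "eta_p2": [e.eta_p2 for e in self.effects],
                "error_stratum": [e.error_stratum for e in self.effects],
            }
        )


def _term_ss(data: pd.DataFrame, response: str, term: tuple[str, ...]) -> float:
    """Balanced SS of a term by inclusion-exclusion of marginal means."""
    n = len(data)
    e = np.zeros(n)
    k = len(term)
    grand = data[response].mean()
    for r in range(k + 1):
        for S in itertools.combinations(term, r):
            sign = (-1.0) ** (k - r)
            if S:
                m = data.groupby(list(S), observed=True)[response].transform("mean")
                e += sign * m.to_numpy()
            else:
                e += sign * grand
    return float(np.sum(e**2))


def _term_df(data: pd.DataFrame, term: tuple[str, ...]) -> int:
    df = 1
    for f in term:
        df *= data[f].nunique() - 1
    return df


def _check_balance(data: pd.DataFrame, factors: list[str], unit: str) -> int:
    """Verify equal unit counts per factor cell; return the per-cell count."""
    counts = data.groupby(factors, observed=True)[unit].nunique()
    full = 1
    for f in factors:
        full *= data[f].nunique()
    if len(counts) != full or counts.nunique() != 1:
        offending = counts[counts != counts.max()]
        raise DesignError(
            f"unbalanced design: cells {list(offending.index)} have "
            f"{list(offending.values)} {unit}s, others {int(counts.max())}"
        )
    return int(counts.iloc[0])


def _assemble(
    effects: list[tuple[str, float, int, str]],
    error_ss: dict[str, float],
    error_df: dict[str, int],
    design: str,
) -> AnovaResult:
    rows = []
    degenerate = False
    # numerical-zero scale: SS below this is roundoff, not signal
    scale = sum(ss for _, ss, _, _ in effects) + sum(error_ss.values())
    zero_tol = 1e-12 * max(scale, 1e-300)
    for name, ss, df1, stratum in effects:
        ss_err = error_ss[stratum]
        df2 = error_df[stratum]
        ms_err = ss_err / df2 if df2 > 0 else np.nan
        ms = ss / df1
        if ms_err <= zero_tol / max(df2, 1):
            F = np.inf if ms > zero_tol else 0.0
            degenerate = True
        else:
            F = ms / ms_err
        p = float(sps.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
        if F == 0.0 and ms_err == 0.0:
            p = 1.0
        rows.append(
            EffectResult(
                name=name,
                ss=ss,
                df1=df1,
                df2=df2,
                F=float(F),
                p=p,
                eta_p2=partial_eta_sq(float(F), df1, df2),
                error_stratum=stratum,
            )
        )
    return AnovaResult(
        effects=rows,
        error_ss=error_ss,
        error_df=error_df,
        design=design,
        degenerate=degenerate,
    )


def factorial_anova(
    tbl: pd.DataFrame,
    factors: list[str] = ("species", "inclination"),
    response: str = "response",
    subject: str = "subject_id",
) -> AnovaResult:
    """Between-subjects factorial ANOVA on a balanced layout.

    One observation per subject; main effects and all interactions are
    tested against the pooled within-cell residual.  Factors with a single
    level are dropped (with the corresponding reduction of the model).
    """
    factors = [f for f in factors if tbl[f].nunique() > 1]
    if not factors:
        raise DesignError("no factor with 2+ levels")
    data = tbl.copy()
    n_per_cell = _check_balance(data, factors, subject)
    if n_per_cell < 2:
        raise DesignError("need at least 2 replicates per cell")
    grand = data[response].mean()
    ss_total = float(np.sum((data[response] - grand) ** 2))
    effects = []
    ss_model = 0.0
    for r in range(1, len(factors) + 1):
        for term in itertools.combinations(factors, r):
            ss = _term_ss(data, response, term)
            ss_model += ss
            effects.append((" x ".join(term), ss, _term_df(data, term), "residual"))
    cells = int(np.prod([data[f].nunique() for f in factors]))
    error_ss = {"residual": max(ss_total - ss_model, 0.0)}
    error_df = {"residual": len(data) - cells}
    return _assemble(effects, error_ss, error_df, design="factorial")


def _gg_epsilon(wide: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the within-subject covariance."""
    S = np.cov(wide, rowvar=False)
    k = S.shape[0]
    dbar = np.diag(S).mean()
    gbar = S.mean()
    rowbar = S.mean(axis=1)
    num = (k * (dbar - gbar)) ** 2
    den = (k - 1) * (np.sum(S**2) - 2 * k * np.sum(rowbar**2) + k**2 * gbar**2)
    return float(num / den) if den > 0 else 1.0


def rm_anova_mixed(
    tbl: pd.DataFrame,
    between: list[str] = ("species", "inclination"),
    within: str = "sector",
    response: str = "response",
    subject: str = "subject_id",
    gg_correction: bool = False,
) -> AnovaResult:
    """Split-plot ANOVA: between-subject factors crossed with one
    within-subject factor.

    Each subject must contribute every within level exactly once and each
    between cell the same number of subjects.  Between terms are tested
    against subjects-within-cells; the within main effect and its
    interactions with the between terms are tested against the
    subject-by-within residual.  ``gg_correction`` rescales the df of the
    within-stratum tests by the Greenhouse-Geisser epsilon.
    """
    between = [f for f in between if tbl[f].nunique() > 1]
    if not between:
        raise DesignError("no between factor with 2+ levels")
    data = tbl.copy()
    w = data[within].nunique()
    per_subj = data.groupby(subject, observed=True)[within].agg(["count", "nunique"])
    bad = per_subj[(per_subj["count"] != w) | (per_subj["nunique"] != w)]
    if len(bad):
        raise DesignError(
            f"subjects {list(bad.index)} do not have each of the {w} "
            f"within levels exactly once"
        )
    n_per_cell = _check_balance(data, between, subject)
    if n_per_cell < 2:
        raise DesignError("need at least 2 subjects per between cell")
    cells = int(np.prod([data[f].nunique() for f in between]))

    grand = data[response].mean()
    ss_total = float(np.sum((data[response] - grand) ** 2))

    # between-subject stratum
    subj_means = data.groupby(subject, observed=True)[response].transform("mean")
    ss_between_total = float(np.sum((subj_means - grand) ** 2))
    effects = []
    ss_bterms = 0.0
    for r in range(1, len(between) + 1):
        for term in itertools.combinations(between, r):
            ss = _term_ss(data, response, term)
            ss_bterms += ss
            effects.append((" x ".join(term), ss, _term_df(data, term), "subjects"))
    ss_subj_err = max(ss_between_total - ss_bterms, 0.0)
    df_subj_err = cells * (n_per_cell - 1)

    # within-subject stratum
    ss_wterms = 0.0
    for r in range(0, len(between) + 1):
        for bsub in itertools.combinations(between, r):
            term = (within,) + bsub
            ss = _term_ss(data, response, term)
            ss_wterms += ss
            name = " x ".join(term)
            effects.append((name, ss, _term_df(data, term), "within"))
    ss_within_err = max(ss_total - ss_between_total - ss_wterms, 0.0)
    df_within_err = cells * (n_per_cell - 1) * (w - 1)

    error_ss = {"subjects": ss_subj_err, "within": ss_within_err}
    error_df = {"subjects": df_subj_err, "within": df_within_err}
    res = _assemble(effects, error_ss, error_df, design="split-plot")

    if gg_correction and w > 2:
        wide = (
            data.pivot_table(index=subject, columns=within, values=response)
            .to_numpy()
        )
        eps = _gg_epsilon(wide)
        corrected = []
        for e in res.effects:
            if e.error_stratum == "within":
                df1 = e.df1 * eps
                df2 = e.df2 * eps
                p = float(sps.f.sf(e.F, df1, df2))
                corrected.append(
                    EffectResult(e.name, e.ss, e.df1, e.df2, e.F, p, e.eta_p2, e.error_stratum)
                )
            else:
                corrected.append(e)
        res.effects = corrected
        res.design = f"split-plot (GG eps={eps:.4f})"
    return res


def rm_anova_expected_observed(
    tbl: pd.DataFrame,
    between: str = "inclination",
    within: str = "condition",
    response: str = "response",
    subject: str = "subject_id",
) -> AnovaResult:
    """Expected-vs-observed repeated-measures ANOVA for one species.

    A two-level within factor (expected / observed strip distance) crossed
    with inclination between subjects; a thin wrapper over the split-plot
    engine.
    """
    return rm_anova_mixed(
        tbl, between=[between], within=within, response=response, subject=subject
    )


def one_way_anova(groups: list[np.ndarray]) -> AnovaResult:
    """One-way ANOVA over independent groups (need not be balanced)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise DesignError("need 2+ groups with 2+ observations each")
    all_y = np.concatenate(groups)
    grand = all_y.mean()
    ss_between = float(sum(len(g) * (g.mean() - grand) ** 2 for g in groups))
    ss_within = float(sum(np.sum((g - g.mean()) ** 2) for g in groups))
    df1 = len(groups) - 1
    df2 = len(all_y) - len(groups)
    return _assemble(
        [("group", ss_between, df1, "residual")],
        {"residual": ss_within},
        {"residual": df2},
        design="one-way",
    )


@dataclass
class TukeyResult:
    """Pairwise Tukey HSD comparisons at family-wise alpha = 0.05."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)
    alpha: float = ALPHA

    def significant_pairs(self) -> list[tuple[str, str]]:
        sig = self.table[self.table["significant"]]
        return list(zip(sig["group1"], sig["group2"]))


def tukey_hsd(
    groups: list[np.ndarray], labels: list[str] | None = None, alpha: float = ALPHA
) -> TukeyResult:
    """Tukey's honest significant difference over all group pairs.

    p-values come from the studentized range distribution with the pooled
    within-group mean square; the per-pair q statistic and the simultaneous
    confidence interval are reported alongside.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise DesignError("need 2+ groups with 2+ observations each")
    if labels is None:
        labels = [f"group{i}" for i in range(len(groups))]
    k = len(groups)
    df_err = sum(len(g) for g in groups) - k
    mse = sum(np.sum((g - g.mean()) ** 2) for g in groups) / df_err
    res = sps.tukey_hsd(*groups)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = float(groups[i].mean() - groups[j].mean())
            se_q = np.sqrt(mse / 2.0 * (1.0 / len(groups[i]) + 1.0 / len(groups[j])))
            q = abs(diff) / se_q if se_q > 0 else np.inf
            p = float(res.pvalue[i, j])
            ci = res.confidence_interval(confidence_level=1 - alpha)
            rows.append(
                {
                    "group1": labels[i],
                    "group2": labels[j],
                    "mean_diff": diff,
                    "q": float(q),
                    "p": p,
                    "ci_low": float(ci.low[i, j]),
                    "ci_high": float(ci.high[i, j]),
                    "significant": p < alpha,
                }
            )
    return TukeyResult(table=pd.DataFrame(rows), alpha=alpha)
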