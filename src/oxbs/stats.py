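"""Group statistics: two-way sex x age ANOVA, SNK post hoc, BH correction.

Endpoints (e.g. autosomal mCG, chrX hmCG, upstream-shore hmCG) are
analysed by a two-way fixed-effects ANOVA with factors sex and age;
factors or interactions passing alpha are followed by Student-Newman-Keuls
(SNK) step-down studentized-range pairwise testing, and p-values are
Benjamini-Hochberg adjusted within declared endpoint families (one family
per figure-panel-like group of endpoints).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import studentized_range
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AnovaResult",
    "two_way_anova",
    "snk_posthoc",
    "bh_adjust",
    "run_family",
]


@dataclass
class AnovaResult:
    """F/p per effect plus the pieces SNK needs."""

    table: pd.DataFrame            # index: sex, age, sex:age; columns F, p, df
    ms_error: float
    df_error: int
    cell_means: pd.DataFrame       # index (sex, age) -> mean, n
    balanced: bool
    zero_variance: bool = False


def _check_design(df: pd.DataFrame) -> tuple:
    counts = df.groupby(["sex", "age"], observed=True).size()
    if (counts < 2).any() or counts.size < 4:
        raise ValueError("two-way ANOVA needs >= 2 replicates in every sex x age cell")
    return bool(counts.nunique() == 1), counts


def two_way_anova(values, sex, age) -> AnovaResult:
    """Two-way fixed-effects ANOVA with interaction.

    Balanced designs use the classical sums-of-squares decomposition
    (Types I/II/III coincide); unbalanced input falls back to Type II with
    a warning flag in the result.
    """
    df = pd.DataFrame({"value": np.asarray(values, dtype=float),
                       "sex": list(sex), "age": list(age)})
    balanced, counts = _check_design(df)
    if not balanced:
        import warnings

        warnings.warn("unbalanced design: using Type II sums of squares")
    model = smf.ols("value ~ C(sex) * C(age)", data=df).fit()
    zero_variance = model.ssr < 1e-14 * max(1.0, float(np.var(df["value"])) , 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        aov = sm.stats.anova_lm(model, typ=2)
    rename = {"C(sex)": "sex", "C(age)": "age", "C(sex):C(age)": "sex:age"}
    aov = aov.rename(index=rename)
    table = aov.loc[["sex", "age", "sex:age"], ["F", "PR(>F)", "df"]]
    table.columns = ["F", "p", "df"]
    if zero_variance:
        table["p"] = np.nan
    cell = df.groupby(["sex", "age"], observed=True)["value"].agg(["mean", "size"])
    cell.columns = ["mean", "n"]
    df_error = int(aov.loc["Residual", "df"])
    ms_error = float(aov.loc["Residual", "sum_sq"] / df_error)
    return AnovaResult(table=table, ms_error=ms_error, df_error=df_error,
                       cell_means=cell, balanced=balanced,
                       zero_variance=bool(zero_variance))


def snk_posthoc(means: dict, ms_error: float, df_error: int, n_per_group,
                alpha: float = 0.05) -> pd.DataFrame:
    """Student-Newman-Keuls step-down studentized-range pairwise decisions.

    Means are sorted; the comparison of the r-th and s-th ordered means
    uses the critical value of the studentized range for a span of
    |r - s| + 1 means.  A span contained in a non-significant wider span is
    not tested (declared non-significant), which enforces SNK coherence.
    Unequal group sizes use the harmonic mean n (flagged via the
    ``harmonic_n`` column).
    """
    labels = list(means)
    mu = np.array([means[k] for k in labels], dtype=float)
    order = np.argsort(mu)
    labels = [labels[i] for i in order]
    mu = mu[order]
    k = len(mu)
    if np.isscalar(n_per_group):
        ns = np.full(k, float(n_per_group))
    else:
        ns = np.array([float(n_per_group[lab]) for lab in labels])
    harmonic = k / np.sum(1.0 / ns)
    unequal = bool(len(set(ns)) > 1)
    se = np.sqrt(ms_error / harmonic)

    sig = {}

    def test_span(i, j, allowed):
        r = j - i + 1
        if (i, j) in sig:
            return
        if not allowed:
            significant, q_obs, q_crit = False, np.nan, np.nan
        elif se == 0:
            # degenerate zero error variance: any separation is declared
            significant, q_obs, q_crit = bool(mu[j] > mu[i]), np.inf, np.nan
        else:
            q_obs = (mu[j] - mu[i]) / se
            q_crit = float(studentized_range.ppf(1.0 - alpha, r, df_error))
            significant = bool(q_obs > q_crit)
        sig[(i, j)] = (q_obs, q_crit, significant)
        if r > 2:
            test_span(i, j - 1, allowed and significant)
            test_span(i + 1, j, allowed and significant)

    if k >= 2:
        test_span(0, k - 1, True)
        # fill any untested nested spans as non-significant
        for i in range(k):
            for j in range(i + 1, k):
                if (i, j) not in sig:
                    sig[(i, j)] = (np.nan, np.nan, False)

    rows = []
    for (i, j), (q_obs, q_crit, significant) in sorted(sig.items()):
        rows.append(
            {
                "group_low": labels[i],
                "group_high": labels[j],
                "diff": mu[j] - mu[i],
                "span": j - i + 1,
                "q": q_obs,
                "q_crit": q_crit,
                "significant": significant,
                "harmonic_n": harmonic,
                "unequal_n": unequal,
            }
        )
    return pd.DataFrame(rows)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def run_family(endpoints: pd.DataFrame, design: pd.DataFrame, families: dict,
               alpha: float = 0.05) -> pd.DataFrame:
    """ANOVA per endpoint, BH within families, SNK on passing effects.

    ``endpoints`` is long-form (sample_id, endpoint, value); ``families``
    maps family name -> list of endpoint ids.  Returns a tidy table with
    one row per endpoint x effect, BH-adjusted within (family, effect),
    and SNK cell-mean comparisons for effects passing alpha on the raw p.
    """
    merged = endpoints.merge(design, on="sample_id", how="left")
    rows = []
    snk_frames = []
    for family, members in families.items():
        for endpoint in members:
            sub = merged[merged["endpoint"] == endpoint]
            missing = set(design["sample_id"]) - set(sub["sample_id"])
            if missing or len(sub) == 0:
                raise ValueError(
                    f"endpoint {endpoint!r} missing values for samples: {sorted(missing)}"
                )
            res = two_way_anova(sub["value"], sub["sex"], sub["age"])
            for effect in ("sex", "age", "sex:age"):
                rows.append(
                    {
                        "family": family,
                        "endpoint": endpoint,
                        "effect": effect,
                        "F": res.table.loc[effect, "F"],
                        "df": res.table.loc[effect, "df"],
                        "p": res.table.loc[effect, "p"],
                    }
                )
            for effect, keys in (("sex", ["sex"]), ("age", ["age"]),
                                 ("sex:age", ["sex", "age"])):
                p = res.table.loc[effect, "p"]
                if np.isfinite(p) and p < alpha:
                    grp = sub.groupby(keys, observed=True)["value"].agg(["mean", "size"])
                    means = {
                        (k if isinstance(k, str) else "/".join(map(str, k))): v
                        for k, v in grp["mean"].items()
                    }
                    ns = {
                        (k if isinstance(k, str) else "/".join(map(str, k))): v
                        for k, v in grp["size"].items()
                    }
                    snk = snk_posthoc(means, res.ms_error, res.df_error, ns, alpha=alpha)
                    snk.insert(0, "endpoint", endpoint)
                    snk.insert(1, "effect", effect)
                    snk_frames.append(snk)
    results = pd.DataFrame(rows)
    results["p_adj"] = np.nan
    for (family, effect), sub in results.groupby(["family", "effect"], observed=True):
        finite = sub["p"].notna()
        if finite.any():
            results.loc[sub.index[finite], "p_adj"] = bh_adjust(sub.loc[finite, "p"])
    snk_table = (
        pd.concat(snk_frames, ignore_index=True) if snk_frames else pd.DataFrame()
    )
    results.attrs["snk"] = snk_table
    return results
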