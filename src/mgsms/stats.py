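"""The statistical battery applied to pipeline outputs.

- Two-way repeated-measures ANOVA (microstate class x task interval) with
  Greenhouse-Geisser correction and Tukey HSD restricted to within-state
  across-interval contrasts.  Every subject contributes one mean per cell,
  so the design is within-subjects; a plain (between-cells) two-way ANOVA is
  available as an option and both df conventions are reported.
- One-way ANOVA across the 8 polarity states (memory interval) with Tukey.
- Wilcoxon signed-rank contrasts for paired subject means (high/low error
  groups, near/far conditions), zero differences dropped.
- Pooled Pearson correlation between saccade error and TP(D+ -> D-) over
  subject x target-position means.

The named transition contrasts report unadjusted p-values alongside a
Benjamini-Hochberg column, since many transitions are tested at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sst
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests


@dataclass
class StatResult:
    """One test's outcome: effect table, optional post-hoc table, extras."""

    test: str
    effects: pd.DataFrame
    n: int
    posthoc: pd.DataFrame | None = None
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# ANOVAs


def anova2_tukey(
    table: pd.DataFrame,
    dv: str = "coverage",
    repeated: bool = True,
    posthoc: bool = True,
) -> StatResult:
    """Two-way ANOVA of a microstate parameter over class x interval.

    ``table`` holds subject-level means with columns subject, state,
    interval and the dependent variable; the 4 x 3 design must be complete
    for every subject.  The repeated-measures form (default) reports
    sphericity-corrected (Greenhouse-Geisser) p-values next to the
    uncorrected ones; ``repeated=False`` instead fits the plain two-way
    ANOVA with interaction on the cell values.
    """
    need = {"subject", "state", "interval", dv}
    if not need <= set(table.columns):
        raise ValueError(f"table must have columns {sorted(need)}")
    counts = table.groupby("subject", observed=True).size()
    cells = table["state"].nunique() * table["interval"].nunique()
    bad = counts[counts != cells]
    if len(bad):
        raise ValueError(
            f"incomplete design for subject(s) {bad.index.tolist()}: "
            f"expected {cells} cells"
        )
    if repeated:
        effects = pg.rm_anova(
            data=table,
            dv=dv,
            within=["state", "interval"],
            subject="subject",
            detailed=True,
        )
    else:
        df = table.rename(columns={dv: "value"})
        model = ols("value ~ C(state) * C(interval)", data=df).fit()
        effects = anova_lm(model, typ=2).reset_index(names="Source")
    post = None
    if posthoc:
        cell = table["state"].astype(str) + ":" + table["interval"].astype(str)
        tuk = pairwise_tukeyhsd(table[dv].to_numpy(), cell.to_numpy())
        post = pd.DataFrame(
            tuk.summary().data[1:], columns=tuk.summary().data[0]
        )
        # the contrasts of interest: same state, different interval
        s1 = post["group1"].str.split(":").str[0]
        s2 = post["group2"].str.split(":").str[0]
        post = post[s1 == s2].reset_index(drop=True)
    return StatResult(
        test="anova2_rm" if repeated else "anova2",
        effects=effects,
        posthoc=post,
        n=int(table["subject"].nunique()),
    )


def anova1_tukey(table: pd.DataFrame, dv: str = "duration_ms") -> StatResult:
    """One-way ANOVA over the 8 polarity states with Tukey HSD.

    ``table`` holds one value per subject per state (memory-interval means).
    """
    if table["state"].nunique() < 2:
        raise ValueError("need at least 2 states")
    groups = [g[dv].to_numpy() for _, g in table.groupby("state", observed=True)]
    f, p = sst.f_oneway(*groups)
    k = len(groups)
    n = sum(len(g) for g in groups)
    effects = pd.DataFrame(
        {"Source": ["state"], "F": [f], "ddof1": [k - 1], "ddof2": [n - k], "p_unc": [p]}
    )
    tuk = pairwise_tukeyhsd(table[dv].to_numpy(), table["state"].to_numpy())
    post = pd.DataFrame(tuk.summary().data[1:], columns=tuk.summary().data[0])
    return StatResult(
        test="anova1",
        effects=effects,
        posthoc=post,
        n=int(table["subject"].nunique()),
    )


# ---------------------------------------------------------------------------
# paired contrasts and correlation


def signedrank(group_a: np.ndarray, group_b: np.ndarray) -> StatResult:
    """Two-sided Wilcoxon signed-rank test on paired subject values.

    Zero differences are dropped (the classical Wilcoxon convention).  When
    every difference is zero the test is degenerate and p = 1 is reported.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("groups must be paired (equal length)")
    if a.size < 5:
        raise ValueError("need at least 5 pairs")
    diffs = a - b
    nz = diffs[diffs != 0]
    if nz.size == 0:
        effects = pd.DataFrame({"W": [0.0], "p_unc": [1.0]})
        return StatResult(
            test="signedrank", effects=effects, n=a.size,
            extras={"warning": "all paired differences are zero"},
        )
    stat, p = sst.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided")
    effects = pd.DataFrame({"W": [float(stat)], "p_unc": [float(p)]})
    return StatResult(
        test="signedrank",
        effects=effects,
        n=int(a.size),
        extras={"median_diff": float(np.median(diffs)), "n_nonzero": int(nz.size)},
    )


def corr_error_tp(
    table: pd.DataFrame,
    error_col: str = "error_dva",
    tp_col: str = "tp",
) -> StatResult:
    """Pooled Pearson correlation over subject x target-position means.

    Rows with an undefined transition probability are dropped, so n can fall
    below subjects x positions; dropped cells are reported.
    """
    sub = table[[error_col, tp_col]].dropna()
    n = len(sub)
    if n < 3:
        raise ValueError("need at least 3 rows for a correlation")
    r, p = sst.pearsonr(sub[error_col], sub[tp_col])
    effects = pd.DataFrame({"r": [float(r)], "p_unc": [float(p)]})
    return StatResult(
        test="pearson",
        effects=effects,
        n=n,
        extras={"n_dropped": int(len(table) - n)},
    )


def condition_contrast(
    table: pd.DataFrame,
    entries: tuple[tuple[str, str], ...] = (("A-", "D-"), ("D-", "C+")),
    value_col: str = "tp",
) -> StatResult:
    """Near/far signed-rank contrast for each named transition.

    ``table`` holds per-(subject, condition, from, to) TP means.  Subjects
    missing either condition for an entry are dropped pairwise.  Reports the
    unadjusted p per entry plus a Benjamini-Hochberg adjusted column.
    """
    rows = []
    ns = []
    for src, dst in entries:
        sub = table[(table["from"] == src) & (table["to"] == dst)]
        wide = sub.pivot_table(
            index="subject", columns="condition", values=value_col
        ).dropna()
        if len(wide) < 5 or not {"near", "far"} <= set(wide.columns):
            rows.append({"from": src, "to": dst, "W": np.nan, "p_unc": np.nan,
                         "median_diff": np.nan, "n": len(wide)})
            continue
        res = signedrank(wide["far"].to_numpy(), wide["near"].to_numpy())
        rows.append(
            {
                "from": src,
                "to": dst,
                "W": res.effects["W"].iloc[0],
                "p_unc": res.effects["p_unc"].iloc[0],
                "median_diff": res.extras.get("median_diff", 0.0),
                "n": res.n,
            }
        )
        ns.append(res.n)
    out = pd.DataFrame(rows)
    ok = out["p_unc"].notna()
    out["p_bh"] = np.nan
    if ok.any():
        out.loc[ok, "p_bh"] = multipletests(out.loc[ok, "p_unc"], method="fdr_bh")[1]
    return StatResult(
        test="condition_contrast",
        effects=out,
        n=int(min(ns)) if ns else 0,
    )
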