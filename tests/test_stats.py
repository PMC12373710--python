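"""The statistical battery: correctness against independent references and
degenerate-input behavior.  (Calibration and power live in the acceptance
suite.)"""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sst

from mgsms import stats as st


def anova_table(rng, n_subjects=17, effect=None):
    rows = []
    for s in range(n_subjects):
        for state in "ABCD":
            for interval in ("fixation", "visual", "memory"):
                v = rng.normal(0.25, 0.01)
                if effect:
                    v += effect(state, interval)
                rows.append((s, state, interval, v))
    return pd.DataFrame(rows, columns=["subject", "state", "interval", "coverage"])


class TestTwoWayAnova:
    def test_within_subject_null_is_not_significant(self):
        rng = np.random.default_rng(100)
        res = st.anova2_tukey(anova_table(rng))
        inter = res.effects[res.effects["Source"].str.contains(r"\*")]
        assert float(inter["p_unc"].iloc[0]) > 0.05
        assert float(inter["F"].iloc[0]) < 3.0

    def test_f_matches_statsmodels_anovarm(self):
        # independent reference implementation on the same fixed table
        from statsmodels.stats.anova import AnovaRM

        rng = np.random.default_rng(101)
        table = anova_table(rng)
        res = st.anova2_tukey(table)
        ref = AnovaRM(
            table, depvar="coverage", subject="subject",
            within=["state", "interval"],
        ).fit().anova_table
        ours = {
            str(r["Source"]): float(r["F"]) for _, r in res.effects.iterrows()
        }
        assert ours["state"] == pytest.approx(ref.loc["state", "F Value"], abs=1e-8)
        assert ours["interval"] == pytest.approx(ref.loc["interval", "F Value"], abs=1e-8)
        assert ours["state * interval"] == pytest.approx(
            ref.loc["state:interval", "F Value"], abs=1e-8
        )

    def test_planted_interaction_detected_with_tukey(self):
        rng = np.random.default_rng(102)
        effect = lambda s, iv: -0.05 if (s == "C" and iv == "memory") else 0.0
        res = st.anova2_tukey(anova_table(rng, effect=effect))
        inter = res.effects[res.effects["Source"].str.contains(r"\*")]
        assert float(inter["p_unc"].iloc[0]) < 0.01
        row = res.posthoc[
            (res.posthoc["group1"] == "C:fixation")
            & (res.posthoc["group2"] == "C:memory")
        ]
        assert bool(row["reject"].iloc[0])

    def test_posthoc_restricted_to_within_state_contrasts(self):
        rng = np.random.default_rng(103)
        res = st.anova2_tukey(anova_table(rng))
        s1 = res.posthoc["group1"].str.split(":").str[0]
        s2 = res.posthoc["group2"].str.split(":").str[0]
        assert (s1 == s2).all()
        assert len(res.posthoc) == 12  # 4 states x 3 interval pairs

    def test_incomplete_design_rejected(self):
        rng = np.random.default_rng(104)
        table = anova_table(rng).iloc[:-1]
        with pytest.raises(ValueError, match="incomplete"):
            st.anova2_tukey(table)

    def test_plain_two_way_option(self):
        rng = np.random.default_rng(105)
        res = st.anova2_tukey(anova_table(rng), repeated=False)
        assert res.test == "anova2"
        assert {"F", "Source"} <= set(res.effects.columns)


class TestOneWayAnova:
    def test_identical_groups_give_p_one(self):
        rows = [
            {"subject": s, "state": g, "duration_ms": 40.0 + s}
            for s in range(10)
            for g in ("A+", "A-", "B+", "B-")
        ]
        res = st.anova1_tukey(pd.DataFrame(rows))
        assert float(res.effects["F"].iloc[0]) == pytest.approx(0.0)
        assert float(res.effects["p_unc"].iloc[0]) == pytest.approx(1.0)

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(106)
        rows = [
            {"subject": s, "state": g, "duration_ms": rng.normal(40, 3)}
            for s in range(12)
            for g in ("A+", "B+", "C+", "D+")
        ]
        df = pd.DataFrame(rows)
        res = st.anova1_tukey(df)
        groups = [g["duration_ms"].to_numpy() for _, g in df.groupby("state")]
        f, p = sst.f_oneway(*groups)
        assert float(res.effects["F"].iloc[0]) == pytest.approx(f, abs=1e-12)

    def test_planted_d_increment_flagged_by_tukey(self):
        rng = np.random.default_rng(107)
        rows = []
        for s in range(17):
            for g in ("A+", "A-", "B+", "B-", "C+", "C-", "D+", "D-"):
                v = rng.normal(40.0, 2.0) + (8.0 if g.startswith("D") else 0.0)
                rows.append({"subject": s, "state": g, "duration_ms": v})
        res = st.anova1_tukey(pd.DataFrame(rows))
        assert float(res.effects["p_unc"].iloc[0]) < 0.001
        dplus = res.posthoc[
            (res.posthoc["group1"].str.startswith("D"))
            != (res.posthoc["group2"].str.startswith("D"))
        ]
        assert dplus["reject"].astype(bool).mean() > 0.9


class TestSignedRank:
    def test_identical_groups(self):
        x = np.arange(8.0)
        res = st.signedrank(x, x)
        assert float(res.effects["p_unc"].iloc[0]) == 1.0
        assert "warning" in res.extras

    def test_matches_exact_enumeration_oracle(self):
        # brute force over all sign assignments for small n
        rng = np.random.default_rng(108)
        for _ in range(5):
            d = rng.normal(0.3, 1.0, size=9)
            res = st.signedrank(d, np.zeros_like(d))
            w_obs, p_obs = float(res.effects["W"].iloc[0]), float(res.effects["p_unc"].iloc[0])
            ranks = sst.rankdata(np.abs(d))
            w_plus = ranks[d > 0].sum()
            n = d.size
            # null distribution of W+ by enumeration of 2^n sign patterns
            stats = [
                sum(r for r, s in zip(ranks, signs) if s)
                for signs in itertools.product([False, True], repeat=n)
            ]
            stats = np.asarray(stats)
            lo = min(w_plus, n * (n + 1) / 2 - w_plus)
            assert w_obs == pytest.approx(lo)
            p_exact = min(
                1.0,
                2 * min(
                    (stats <= w_plus).mean(), (stats >= w_plus).mean()
                ),
            )
            assert p_obs == pytest.approx(p_exact, abs=1e-12)

    def test_requires_five_pairs(self):
        with pytest.raises(ValueError):
            st.signedrank(np.ones(3), np.zeros(3))


class TestPearson:
    def test_exactly_linear_data(self):
        x = np.linspace(0, 1, 30)
        table = pd.DataFrame({"error_dva": x, "tp": 2 * x + 1})
        res = st.corr_error_tp(table)
        assert float(res.effects["r"].iloc[0]) == pytest.approx(1.0)
        assert float(res.effects["p_unc"].iloc[0]) < 1e-20

    def test_nan_rows_dropped_and_counted(self):
        rng = np.random.default_rng(109)
        table = pd.DataFrame(
            {"error_dva": rng.normal(size=20), "tp": rng.normal(size=20)}
        )
        table.loc[3:6, "tp"] = np.nan
        res = st.corr_error_tp(table)
        assert res.n == 16
        assert res.extras["n_dropped"] == 4

    def test_null_r_magnitude_at_n195(self):
        rng = np.random.default_rng(110)
        inside = 0
        for _ in range(100):
            table = pd.DataFrame(
                {"error_dva": rng.normal(size=195), "tp": rng.normal(size=195)}
            )
            r = float(st.corr_error_tp(table).effects["r"].iloc[0])
            inside += abs(r) < 0.14  # ~2 SE at this n
        assert inside >= 90


class TestConditionContrast:
    def _table(self, rng, shift=0.0):
        rows = []
        for s in range(17):
            for src, dst in (("A-", "D-"), ("D-", "C+")):
                base = rng.normal(0.14, 0.02)
                rows.append(
                    {"subject": s, "condition": "near", "from": src, "to": dst, "tp": base}
                )
                extra = shift if (src, dst) == (("A-", "D-")) else 0.0
                rows.append(
                    {
                        "subject": s,
                        "condition": "far",
                        "from": src,
                        "to": dst,
                        "tp": base + rng.normal(0.0, 0.01) + extra,
                    }
                )
        return pd.DataFrame(rows)

    def test_identical_conditions_give_p_one(self):
        rows = []
        for s in range(8):
            for cond in ("near", "far"):
                rows.append(
                    {"subject": s, "condition": cond, "from": "A-", "to": "D-", "tp": 0.1 + s / 100}
                )
        res = st.condition_contrast(pd.DataFrame(rows), entries=(("A-", "D-"),))
        assert float(res.effects["p_unc"].iloc[0]) == 1.0

    def test_planted_entry_detected_others_null(self):
        rng = np.random.default_rng(111)
        res = st.condition_contrast(self._table(rng, shift=0.05))
        eff = res.effects.set_index(["from", "to"])
        assert eff.loc[("A-", "D-"), "p_unc"] < 0.01
        assert eff.loc[("D-", "C+"), "p_unc"] > 0.05

    def test_row_count_matches_requested_entries(self):
        rng = np.random.default_rng(112)
        res = st.condition_contrast(
            self._table(rng), entries=(("A-", "D-"), ("D-", "C+"))
        )
        assert len(res.effects) == 2
        assert "p_bh" in res.effects.columns
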